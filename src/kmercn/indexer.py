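"""Build the catalog of analyzable k-mers from a reference genome.

Stages: enumerate canonical k-mer occurrences, keep single-copy k-mers,
drop candidates with too many substitution near-matches, then annotate
retained k-mers with their unique genomic position, flanking GC fraction
and control-region membership, and serialize the catalog in chromosomal
order.
"""

from __future__ import annotations

import gzip
import hashlib
import json
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np

from .codec import MAX_K, canonical_vals, encode_windows, revcomp_vals, sequence_codes

__all__ = [
    "IndexerConfig",
    "OccurrenceTable",
    "ControlRegions",
    "KmerCatalog",
    "IndexFormatError",
    "ParameterMismatchError",
    "ConsistencyError",
    "read_fasta",
    "enumerate_occurrences",
    "select_candidates",
    "near_match_count",
    "near_match_counts",
    "filter_catalog",
    "locate_and_annotate",
    "build_catalog",
    "prepare_control",
    "write_index",
    "read_index",
    "write_index_tsv",
]

_INDEX_MAGIC = b"KMCNIDX1"
_INDEX_VERSION = 1


class IndexFormatError(ValueError):
    """Corrupt, truncated, or wrong-magic index file."""


class ParameterMismatchError(ValueError):
    """Index on disk was built with different parameters than expected."""


class ConsistencyError(RuntimeError):
    """Internal invariant violated (e.g. retained k-mer not found exactly once)."""


@dataclass(frozen=True)
class IndexerConfig:
    """Parameters of the catalog build.

    ``edit_distance`` is the substitution-only (Hamming) search radius;
    ``max_near`` is a strict upper bound: candidates are retained iff
    their near-match occurrence total is < max_near.
    """

    k: int = 30
    edit_distance: int = 2
    max_near: int = 100
    gc_window_bp: int = 400
    threads: int = 1

    def __post_init__(self) -> None:
        if not 1 <= self.k <= MAX_K:
            raise ValueError(f"k must be in [1, {MAX_K}]")
        if self.edit_distance not in (0, 1, 2):
            raise ValueError("edit_distance must be 0, 1, or 2")
        if self.max_near < 1:
            raise ValueError("max_near must be >= 1")
        if self.gc_window_bp < 1:
            raise ValueError("gc_window_bp must be >= 1")
        if self.threads < 1:
            raise ValueError("threads must be >= 1")


# ---------------------------------------------------------------------------
# FASTA input
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a (optionally gzipped) FASTA file into [(name, sequence), ...]."""
    from Bio import SeqIO

    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as handle:
        return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(handle, "fasta")]


def _as_seq_items(sequences) -> list[tuple[str, str]]:
    if isinstance(sequences, Mapping):
        return list(sequences.items())
    return list(sequences)


# ---------------------------------------------------------------------------
# Occurrence enumeration
# ---------------------------------------------------------------------------

@dataclass
class OccurrenceTable:
    """Canonical k-mer -> exact occurrence count over the whole reference."""

    k: int
    keys: np.ndarray    # sorted canonical encodings, uint64
    counts: np.ndarray  # int64, parallel to keys

    def __len__(self) -> int:
        return self.keys.size

    def get(self, value: int) -> int:
        i = int(np.searchsorted(self.keys, np.uint64(value)))
        if i < self.keys.size and int(self.keys[i]) == int(value):
            return int(self.counts[i])
        return 0

    def dual(self) -> tuple[np.ndarray, np.ndarray]:
        """Both-orientation key array (sorted) plus source index per entry.

        Lets near-match search test raw (non-canonical) variant values
        directly without canonicalizing each one.
        """
        rc = revcomp_vals(self.keys, self.k)
        dual = np.concatenate([self.keys, rc])
        src = np.concatenate([np.arange(self.keys.size), np.arange(self.keys.size)])
        order = np.argsort(dual, kind="stable")
        return dual[order], src[order]


def enumerate_occurrences(sequences, k: int) -> OccurrenceTable:
    """Count every valid length-k window of every sequence under canonical encoding."""
    parts = []
    for _, seq in _as_seq_items(sequences):
        _, vals = encode_windows(seq, k)
        if vals.size:
            parts.append(canonical_vals(vals, k))
    if not parts:
        return OccurrenceTable(k, np.empty(0, dtype=np.uint64), np.empty(0, dtype=np.int64))
    allvals = np.concatenate(parts)
    keys, counts = np.unique(allvals, return_counts=True)
    return OccurrenceTable(k, keys.astype(np.uint64), counts.astype(np.int64))


def select_candidates(occurrences: OccurrenceTable) -> np.ndarray:
    """Exactly the canonical k-mers with a single exact occurrence."""
    return occurrences.keys[occurrences.counts == 1]


# ---------------------------------------------------------------------------
# Near-match (Hamming neighborhood) search
# ---------------------------------------------------------------------------

def _substitution_deltas(k: int, j: int) -> np.ndarray:
    """XOR masks generating all substitution patterns at Hamming distance 1..j.

    XOR-ing a 2-bit field with a nonzero 2-bit value enumerates exactly the
    three alternative bases at that position.
    """
    deltas: list[int] = []
    if j >= 1:
        for p in range(k):
            for d in (1, 2, 3):
                deltas.append(d << (2 * p))
    if j >= 2:
        for p1 in range(k):
            for p2 in range(p1 + 1, k):
                for d1 in (1, 2, 3):
                    for d2 in (1, 2, 3):
                        deltas.append((d1 << (2 * p1)) | (d2 << (2 * p2)))
    return np.array(deltas, dtype=np.uint64)


_FILTER_BITS = 26


def near_match_counts(
    candidates: np.ndarray, occurrences: OccurrenceTable, j: int
) -> np.ndarray:
    """Near-match occurrence totals for an array of canonical candidates.

    For each candidate, sums the genome occurrence counts of all *distinct*
    canonical k-mers at substitution distance 1..j, excluding the candidate
    itself.  De-duplication on canonical identity prevents double counting
    when two raw variants are reverse complements of each other.
    """
    cands = np.ascontiguousarray(candidates, dtype=np.uint64)
    out = np.zeros(cands.size, dtype=np.int64)
    if j == 0 or cands.size == 0 or len(occurrences) == 0:
        return out
    k = occurrences.k
    dual, src = occurrences.dual()
    # cheap membership pre-filter on low bits: almost all variants miss
    mask = np.uint64((1 << _FILTER_BITS) - 1)
    bitmap = np.zeros(1 << _FILTER_BITS, dtype=bool)
    bitmap[(dual & mask).astype(np.int64)] = True
    hits_c: list[np.ndarray] = []
    hits_k: list[np.ndarray] = []
    for delta in _substitution_deltas(k, j):
        var = cands ^ delta
        maybe = bitmap[(var & mask).astype(np.int64)]
        if not maybe.any():
            continue
        ci = np.flatnonzero(maybe)
        vh = var[maybe]
        pos = np.searchsorted(dual, vh)
        pos = np.minimum(pos, dual.size - 1)
        found = dual[pos] == vh
        if found.any():
            hits_c.append(ci[found])
            hits_k.append(src[pos[found]])
    if not hits_c:
        return out
    pc = np.concatenate(hits_c)
    pk = np.concatenate(hits_k)
    # de-duplicate (candidate, canonical neighbor) pairs
    n_keys = np.uint64(len(occurrences))
    code = pc.astype(np.uint64) * n_keys + pk.astype(np.uint64)
    uniq = np.unique(code)
    upc = (uniq // n_keys).astype(np.int64)
    upk = (uniq % n_keys).astype(np.int64)
    keep = occurrences.keys[upk] != cands[upc]  # exclude the candidate itself
    near = np.bincount(
        upc[keep], weights=occurrences.counts[upk[keep]].astype(np.float64),
        minlength=cands.size,
    )
    return near.astype(np.int64)


def near_match_count(candidate, occurrences: OccurrenceTable, j: int) -> int:
    """Near-match total for one candidate (straightforward set-based route)."""
    from .codec import EncodedKmer, canonical

    k = occurrences.k
    value = candidate.value if isinstance(candidate, EncodedKmer) else int(candidate)
    if j == 0:
        return 0
    variants: set[int] = set()
    for delta in _substitution_deltas(k, j):
        v = value ^ int(delta)
        variants.add(canonical(EncodedKmer(v, k)).value)
    variants.discard(canonical(EncodedKmer(value, k)).value)
    return sum(occurrences.get(v) for v in variants)


def filter_catalog(
    candidates: np.ndarray, occurrences: OccurrenceTable, config: IndexerConfig
) -> np.ndarray:
    """Retain candidates with strictly fewer than ``max_near`` near matches.

    Work is partitioned into ``threads`` chunks; results are concatenated in
    order so the retained set is invariant to the thread count.
    """
    cands = np.asarray(candidates, dtype=np.uint64)
    if cands.size == 0:
        return cands
    chunks = np.array_split(cands, config.threads)
    near = np.concatenate(
        [near_match_counts(c, occurrences, config.edit_distance) for c in chunks if c.size]
    )
    return cands[near < config.max_near]


# ---------------------------------------------------------------------------
# Control regions
# ---------------------------------------------------------------------------

def _merge_intervals(iv: list[tuple[int, int]]) -> tuple[np.ndarray, np.ndarray]:
    """Merge overlapping/abutting 0-based half-open intervals."""
    starts: list[int] = []
    ends: list[int] = []
    for s, e in sorted(iv):
        if e <= s:
            raise ValueError(f"invalid interval [{s}, {e})")
        if starts and s <= ends[-1]:
            ends[-1] = max(ends[-1], e)
        else:
            starts.append(s)
            ends.append(e)
    return np.array(starts, dtype=np.int64), np.array(ends, dtype=np.int64)


@dataclass
class ControlRegions:
    """Merged, non-overlapping intervals assumed copy-number invariant."""

    regions: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)

    @classmethod
    def from_intervals(cls, intervals: Iterable[tuple[str, int, int]]) -> "ControlRegions":
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, s, e in intervals:
            by_chrom.setdefault(chrom, []).append((int(s), int(e)))
        return cls({c: _merge_intervals(iv) for c, iv in by_chrom.items()})

    @classmethod
    def from_bed(cls, path: str | Path) -> "ControlRegions":
        intervals = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                f = line.split("\t")
                intervals.append((f[0], int(f[1]), int(f[2])))
        return cls.from_intervals(intervals)

    def to_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chrom in self.regions:
                starts, ends = self.regions[chrom]
                for s, e in zip(starts, ends):
                    fh.write(f"{chrom}\t{s}\t{e}\n")

    def intervals(self) -> Iterator[tuple[str, int, int]]:
        for chrom, (starts, ends) in self.regions.items():
            for s, e in zip(starts, ends):
                yield chrom, int(s), int(e)

    def contains(self, chrom: str, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
        """True where [start, end) lies entirely within one control interval."""
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        if chrom not in self.regions:
            return np.zeros(starts.size, dtype=bool)
        rs, re = self.regions[chrom]
        i = np.searchsorted(rs, starts, side="right") - 1
        ok = i >= 0
        i = np.maximum(i, 0)
        return ok & (ends <= re[i]) & (starts >= rs[i])


def prepare_control(
    chrom_sizes: Mapping[str, int],
    exclude: Iterable[tuple[str, int, int]] = (),
) -> ControlRegions:
    """Complement exclusion intervals against chromosome lengths.

    Mirrors the usual preparation: merge everything known to be
    copy-number variable (plus whole chromosomes absent from
    ``chrom_sizes``) and emit the remaining genome as the include set.
    """
    excl: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_sizes}
    for chrom, s, e in exclude:
        if chrom in excl:
            excl[chrom].append((int(s), int(e)))
    include: list[tuple[str, int, int]] = []
    for chrom, size in chrom_sizes.items():
        if not excl[chrom]:
            include.append((chrom, 0, int(size)))
            continue
        starts, ends = _merge_intervals(excl[chrom])
        prev = 0
        for s, e in zip(starts, ends):
            s = max(0, min(int(s), int(size)))
            e = max(0, min(int(e), int(size)))
            if s > prev:
                include.append((chrom, prev, s))
            prev = max(prev, e)
        if prev < size:
            include.append((chrom, prev, int(size)))
    return ControlRegions.from_intervals(include)


# ---------------------------------------------------------------------------
# Catalog
# ---------------------------------------------------------------------------

@dataclass
class KmerCatalog:
    """Genomic-ordered records of retained unique k-mers.

    Arrays are parallel; records are sorted by (chromosome order as in the
    input FASTA, start ascending), and every ``value`` is distinct.
    """

    k: int
    edit_distance: int
    max_near: int
    gc_window_bp: int
    sequences: list[tuple[str, int]]      # (name, length) in FASTA order
    chrom_id: np.ndarray                  # uint32
    start: np.ndarray                     # int64, 0-based 5' position
    value: np.ndarray                     # uint64 canonical encodings
    is_control: np.ndarray                # bool
    gc_fraction: np.ndarray               # float64 in [0, 1]

    def __len__(self) -> int:
        return self.value.size

    @property
    def chrom_names(self) -> list[str]:
        return [name for name, _ in self.sequences]

    def checksum(self) -> str:
        h = hashlib.sha256()
        h.update(
            json.dumps(
                [self.k, self.edit_distance, self.max_near, self.gc_window_bp, self.sequences]
            ).encode()
        )
        h.update(self.value.tobytes())
        h.update(self.start.tobytes())
        return h.hexdigest()

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, KmerCatalog):
            return NotImplemented
        return (
            (self.k, self.edit_distance, self.max_near, self.gc_window_bp, self.sequences)
            == (other.k, other.edit_distance, other.max_near, other.gc_window_bp, other.sequences)
            and np.array_equal(self.chrom_id, other.chrom_id)
            and np.array_equal(self.start, other.start)
            and np.array_equal(self.value, other.value)
            and np.array_equal(self.is_control, other.is_control)
            and np.array_equal(self.gc_fraction, other.gc_fraction)
        )


def locate_and_annotate(
    retained: np.ndarray,
    sequences,
    control: ControlRegions,
    config: IndexerConfig,
) -> KmerCatalog:
    """Attach position, GC context, and control flags to the retained set.

    GC fraction is (G+C)/(A+C+G+T) over a ``gc_window_bp`` window centered
    on the k-mer midpoint, clipped at chromosome ends; ``is_control`` is
    true iff [start, start+k) lies entirely within a control interval.
    """
    k = config.k
    items = _as_seq_items(sequences)
    rsort = np.sort(np.asarray(retained, dtype=np.uint64))
    chrom_parts, start_parts, value_parts, ctl_parts, gc_parts = [], [], [], [], []
    n_found = 0
    for cid, (name, seq) in enumerate(items):
        starts, vals = encode_windows(seq, k)
        if vals.size == 0:
            continue
        canon = canonical_vals(vals, k)
        pos = np.searchsorted(rsort, canon)
        pos = np.minimum(pos, max(rsort.size - 1, 0))
        hit = (rsort.size > 0) & (rsort[pos] == canon)
        if not np.any(hit):
            continue
        sel_start = starts[hit]
        sel_val = canon[hit]
        n_found += sel_val.size

        codes, valid = sequence_codes(seq)
        is_gc = valid & ((codes == 1) | (codes == 3))
        csg = np.concatenate(([0], np.cumsum(is_gc, dtype=np.int64)))
        csv = np.concatenate(([0], np.cumsum(valid, dtype=np.int64)))
        mid = sel_start + k // 2
        half = config.gc_window_bp // 2
        lo = np.clip(mid - half, 0, len(seq))
        hi = np.clip(mid + (config.gc_window_bp - half), 0, len(seq))
        denom = csv[hi] - csv[lo]
        gc = np.where(denom > 0, (csg[hi] - csg[lo]) / np.maximum(denom, 1), 0.0)

        ctl = control.contains(name, sel_start, sel_start + k)

        chrom_parts.append(np.full(sel_val.size, cid, dtype=np.uint32))
        start_parts.append(sel_start)
        value_parts.append(sel_val)
        ctl_parts.append(ctl)
        gc_parts.append(gc)
    if n_found != rsort.size:
        raise ConsistencyError(
            f"retained {rsort.size} k-mers but located {n_found} occurrences"
        )

    def cat(parts, dtype):
        if not parts:
            return np.empty(0, dtype=dtype)
        return np.concatenate(parts).astype(dtype)

    return KmerCatalog(
        k=k,
        edit_distance=config.edit_distance,
        max_near=config.max_near,
        gc_window_bp=config.gc_window_bp,
        sequences=[(name, len(seq)) for name, seq in items],
        chrom_id=cat(chrom_parts, np.uint32),
        start=cat(start_parts, np.int64),
        value=cat(value_parts, np.uint64),
        is_control=cat(ctl_parts, bool),
        gc_fraction=cat(gc_parts, np.float64),
    )


def build_catalog(sequences, control: ControlRegions, config: IndexerConfig) -> KmerCatalog:
    """Full indexing stage: enumerate -> unique -> near-match filter -> annotate."""
    items = _as_seq_items(sequences)
    occ = enumerate_occurrences(items, config.k)
    cands = select_candidates(occ)
    retained = filter_catalog(cands, occ, config)
    return locate_and_annotate(retained, items, control, config)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def write_index(catalog: KmerCatalog, path: str | Path) -> None:
    """Write the documented binary layout: magic, JSON header, fixed-width arrays."""
    header = {
        "version": _INDEX_VERSION,
        "k": catalog.k,
        "edit_distance": catalog.edit_distance,
        "max_near": catalog.max_near,
        "gc_window_bp": catalog.gc_window_bp,
        "sequences": catalog.sequences,
        "n_records": len(catalog),
        "checksum": catalog.checksum(),
    }
    hj = json.dumps(header).encode()
    with open(path, "wb") as fh:
        fh.write(_INDEX_MAGIC)
        fh.write(struct.pack("<Q", len(hj)))
        fh.write(hj)
        fh.write(catalog.chrom_id.astype("<u4").tobytes())
        fh.write(catalog.start.astype("<i8").tobytes())
        fh.write(catalog.value.astype("<u8").tobytes())
        fh.write(catalog.is_control.astype("u1").tobytes())
        fh.write(catalog.gc_fraction.astype("<f8").tobytes())


def read_index(path: str | Path, expect: IndexerConfig | None = None) -> KmerCatalog:
    """Read an index; optionally verify its parameters against ``expect``."""
    with open(path, "rb") as fh:
        blob = fh.read()
    if blob[: len(_INDEX_MAGIC)] != _INDEX_MAGIC:
        raise IndexFormatError(f"{path}: not a k-mer index (bad magic)")
    off = len(_INDEX_MAGIC)
    if len(blob) < off + 8:
        raise IndexFormatError(f"{path}: truncated header length")
    (hlen,) = struct.unpack_from("<Q", blob, off)
    off += 8
    if len(blob) < off + hlen:
        raise IndexFormatError(f"{path}: truncated header")
    try:
        header = json.loads(blob[off : off + hlen].decode())
    except (UnicodeDecodeError, json.JSONDecodeError) as exc:
        raise IndexFormatError(f"{path}: unreadable header") from exc
    off += hlen
    if header.get("version") != _INDEX_VERSION:
        raise IndexFormatError(f"{path}: unsupported version {header.get('version')}")
    n = int(header["n_records"])
    sizes = [4 * n, 8 * n, 8 * n, n, 8 * n]
    if len(blob) - off != sum(sizes):
        raise IndexFormatError(
            f"{path}: expected {sum(sizes)} bytes of records, found {len(blob) - off}"
        )

    def take(nbytes: int, dtype) -> np.ndarray:
        nonlocal off
        arr = np.frombuffer(blob, dtype=dtype, count=n, offset=off).copy()
        off += nbytes
        return arr

    catalog = KmerCatalog(
        k=int(header["k"]),
        edit_distance=int(header["edit_distance"]),
        max_near=int(header["max_near"]),
        gc_window_bp=int(header["gc_window_bp"]),
        sequences=[(str(a), int(b)) for a, b in header["sequences"]],
        chrom_id=take(4 * n, "<u4"),
        start=take(8 * n, "<i8"),
        value=take(8 * n, "<u8"),
        is_control=take(n, "u1").astype(bool),
        gc_fraction=take(8 * n, "<f8"),
    )
    if catalog.checksum() != header["checksum"]:
        raise IndexFormatError(f"{path}: record checksum mismatch")
    if expect is not None:
        got = (catalog.k, catalog.edit_distance, catalog.max_near, catalog.gc_window_bp)
        want = (expect.k, expect.edit_distance, expect.max_near, expect.gc_window_bp)
        if got != want:
            raise ParameterMismatchError(
                f"{path}: index parameters {got} do not match expected {want}"
            )
    return catalog


def write_index_tsv(catalog: KmerCatalog, path: str | Path) -> None:
    """Human-readable dump: chrom, start, end, k-mer, is_control, gc_fraction."""
    from .codec import EncodedKmer, decode_kmer

    names = catalog.chrom_names
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tkmer\tis_control\tgc_fraction\n")
        for cid, s, v, c, g in zip(
            catalog.chrom_id, catalog.start, catalog.value, catalog.is_control,
            catalog.gc_fraction,
        ):
            kmer = decode_kmer(EncodedKmer(int(v), catalog.k))
            fh.write(f"{names[cid]}\t{s}\t{s + catalog.k}\t{kmer}\t{int(c)}\t{g:.6f}\n")
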