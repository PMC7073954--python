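"""Stream read sequences and tabulate occurrence counts of catalog k-mers.

Input arrives on a text stream (typically standard input) in FASTQ, FASTA,
or one-sequence-per-line form, auto-detected from the first character.
Duplicate/secondary/QC filtering is expected upstream (e.g.
``samtools fasta -F 3840 in.cram | kmercn count ...``); whatever arrives
is counted.
"""

from __future__ import annotations

import json
import struct
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Iterator, Sequence

import numpy as np

from .codec import canonical_vals, encode_windows
from .indexer import KmerCatalog

__all__ = [
    "CountTable",
    "StreamFormatError",
    "CatalogMismatchError",
    "CountsFormatError",
    "stream_sequences",
    "count_sequence",
    "count_stream",
    "merge_counts",
    "write_counts",
    "read_counts",
]

_COUNTS_MAGIC = b"KMCNCNT1"
_COUNTS_VERSION = 1


class StreamFormatError(ValueError):
    """Malformed input record (names the failing record index)."""


class CatalogMismatchError(ValueError):
    """Counts were built against a different catalog than the one supplied."""


class CountsFormatError(ValueError):
    """Corrupt or truncated counts file."""


@dataclass
class CountTable:
    """Per-catalog-k-mer occurrence counts, in catalog (chromosomal) order."""

    counts: np.ndarray            # int64, length == catalog size
    total_reads: int
    total_kmers_scanned: int
    catalog_checksum: str

    @classmethod
    def zeros(cls, catalog: KmerCatalog) -> "CountTable":
        return cls(
            counts=np.zeros(len(catalog), dtype=np.int64),
            total_reads=0,
            total_kmers_scanned=0,
            catalog_checksum=catalog.checksum(),
        )


def stream_sequences(stream: IO[str]) -> Iterator[str]:
    """Yield uppercase sequences from FASTQ / FASTA / raw line input.

    The format is auto-detected from the first character: '@' FASTQ,
    '>' FASTA, anything else one sequence per line.  Headers and quality
    lines are discarded.
    """
    first = stream.read(1)
    if first == "":
        return
    if first == "@":
        yield from _stream_fastq(stream)
    elif first == ">":
        yield from _stream_fasta(stream)
    else:
        rest = stream.readline()
        line = (first + rest).strip()
        if line:
            yield line.upper()
        for line in stream:
            line = line.strip()
            if line:
                yield line.upper()


def _stream_fastq(stream: IO[str]) -> Iterator[str]:
    # the leading '@' of record 0 was already consumed by the caller
    idx = 0
    header = stream.readline()
    while True:
        if header == "":
            return
        seq_line = stream.readline()
        if seq_line == "":
            raise StreamFormatError(f"FASTQ record {idx}: missing sequence line")
        seq = seq_line.rstrip("\n")
        plus = stream.readline()
        if plus == "" or not plus.startswith("+"):
            raise StreamFormatError(f"FASTQ record {idx}: missing '+' separator line")
        qual_line = stream.readline()
        if qual_line == "":
            raise StreamFormatError(f"FASTQ record {idx}: missing quality line")
        qual = qual_line.rstrip("\n")
        if len(seq) != len(qual):
            raise StreamFormatError(
                f"FASTQ record {idx}: sequence length {len(seq)} != quality length {len(qual)}"
            )
        yield seq.upper()
        idx += 1
        header = stream.readline()
        if header != "" and not header.startswith("@"):
            raise StreamFormatError(f"FASTQ record {idx}: header does not start with '@'")


def _stream_fasta(stream: IO[str]) -> Iterator[str]:
    # the leading '>' of record 0 was already consumed by the caller
    stream.readline()  # remainder of the first header
    chunks: list[str] = []
    for line in stream:
        if line.startswith(">"):
            if chunks:
                yield "".join(chunks).upper()
                chunks = []
        else:
            chunks.append(line.strip())
    if chunks:
        yield "".join(chunks).upper()


class _CatalogLookup:
    """Value-sorted view of the catalog for vectorized membership lookups."""

    def __init__(self, catalog: KmerCatalog):
        self.k = catalog.k
        self.order = np.argsort(catalog.value)
        self.sorted_vals = catalog.value[self.order]

    def accumulate(self, seq: str, counts: np.ndarray) -> int:
        """Count catalog hits from every valid window of ``seq``.

        Returns the number of valid windows scanned.
        """
        _, vals = encode_windows(seq, self.k)
        if vals.size == 0:
            return 0
        canon = canonical_vals(vals, self.k)
        if self.sorted_vals.size:
            pos = np.searchsorted(self.sorted_vals, canon)
            pos = np.minimum(pos, self.sorted_vals.size - 1)
            hit = self.sorted_vals[pos] == canon
            if hit.any():
                np.add.at(counts, self.order[pos[hit]], 1)
        return int(vals.size)


def count_sequence(seq: str, catalog: KmerCatalog, table: CountTable) -> CountTable:
    """Tabulate one sequence into ``table`` (updated in place and returned)."""
    lut = _CatalogLookup(catalog)
    table.total_kmers_scanned += lut.accumulate(seq.upper(), table.counts)
    table.total_reads += 1
    return table


def count_stream(
    source: IO[str] | Iterable[str],
    catalog: KmerCatalog,
    workers: int = 1,
    batch_reads: int = 10_000,
) -> CountTable:
    """Count catalog k-mer occurrences over a whole read stream.

    Reads are gathered into fixed-size batches; batch b is assigned to
    worker ``b % workers``, each worker keeps its own table, and the
    tables are merged at the end — so results are identical for any
    worker count (the feeder/consumer determinism contract).  Batches are
    joined with an 'N' separator before encoding, which invalidates every
    window that would span two reads.
    """
    if workers < 1:
        raise ValueError("workers must be >= 1")
    seqs: Iterable[str]
    if hasattr(source, "read"):
        seqs = stream_sequences(source)  # type: ignore[arg-type]
    else:
        seqs = iter(source)  # type: ignore[assignment]
    lut = _CatalogLookup(catalog)
    tables = [CountTable.zeros(catalog) for _ in range(workers)]
    batch: list[str] = []
    b = 0

    def flush() -> None:
        nonlocal b
        if not batch:
            return
        t = tables[b % workers]
        t.total_kmers_scanned += lut.accumulate("N".join(batch), t.counts)
        t.total_reads += len(batch)
        batch.clear()
        b += 1

    for seq in seqs:
        batch.append(seq.upper())
        if len(batch) >= batch_reads:
            flush()
    flush()
    return merge_counts(tables)


def merge_counts(tables: Sequence[CountTable]) -> CountTable:
    """Element-wise sum of count tables built against the same catalog."""
    if not tables:
        raise ValueError("no tables to merge")
    ref = tables[0]
    for t in tables[1:]:
        if t.catalog_checksum != ref.catalog_checksum:
            raise CatalogMismatchError("cannot merge counts from different catalogs")
        if t.counts.size != ref.counts.size:
            raise CatalogMismatchError("count tables differ in length")
    return CountTable(
        counts=np.sum([t.counts for t in tables], axis=0).astype(np.int64),
        total_reads=sum(t.total_reads for t in tables),
        total_kmers_scanned=sum(t.total_kmers_scanned for t in tables),
        catalog_checksum=ref.catalog_checksum,
    )


def write_counts(table: CountTable, path: str | Path) -> None:
    header = {
        "version": _COUNTS_VERSION,
        "n": int(table.counts.size),
        "total_reads": int(table.total_reads),
        "total_kmers_scanned": int(table.total_kmers_scanned),
        "catalog_checksum": table.catalog_checksum,
    }
    hj = json.dumps(header).encode()
    with open(path, "wb") as fh:
        fh.write(_COUNTS_MAGIC)
        fh.write(struct.pack("<Q", len(hj)))
        fh.write(hj)
        fh.write(table.counts.astype("<i8").tobytes())


def read_counts(path: str | Path, catalog: KmerCatalog | None = None) -> CountTable:
    """Read a counts file; if a catalog is given, verify the binding checksum."""
    with open(path, "rb") as fh:
        blob = fh.read()
    if blob[: len(_COUNTS_MAGIC)] != _COUNTS_MAGIC:
        raise CountsFormatError(f"{path}: not a counts file (bad magic)")
    off = len(_COUNTS_MAGIC)
    if len(blob) < off + 8:
        raise CountsFormatError(f"{path}: truncated header length")
    (hlen,) = struct.unpack_from("<Q", blob, off)
    off += 8
    if len(blob) < off + hlen:
        raise CountsFormatError(f"{path}: truncated header")
    header = json.loads(blob[off : off + hlen].decode())
    off += hlen
    n = int(header["n"])
    if len(blob) - off != 8 * n:
        raise CountsFormatError(f"{path}: expected {8 * n} bytes of counts")
    table = CountTable(
        counts=np.frombuffer(blob, dtype="<i8", count=n, offset=off).copy(),
        total_reads=int(header["total_reads"]),
        total_kmers_scanned=int(header["total_kmers_scanned"]),
        catalog_checksum=str(header["catalog_checksum"]),
    )
    if catalog is not None and table.catalog_checksum != catalog.checksum():
        raise CatalogMismatchError(
            f"{path}: counts were built against a different catalog"
        )
    return table
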