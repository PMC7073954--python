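"""Independent reference implementations used to check the production code.

These deliberately avoid the package's neighborhood-enumeration /
hash-lookup machinery: distances come from direct pairwise comparison and
counting from plain Python dictionaries.
"""

from __future__ import annotations

from collections import Counter

import numpy as np

from kmercn.codec import revcomp_vals

_M5 = np.uint64(0x5555555555555555)

_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}


def revcomp_str(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


def canonical_str(seq: str) -> str:
    """String-level canonical form (ties broken by the 2-bit encoding order)."""
    from kmercn.codec import canonical, decode_kmer, encode_kmer

    return decode_kmer(canonical(encode_kmer(seq)))


def _hamming_vals(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Per-pair count of differing 2-bit fields."""
    z = a ^ b
    return np.bitwise_count((z | (z >> np.uint64(1))) & _M5).astype(np.int64)


def allpairs_near_counts(cands: np.ndarray, occ, j: int, chunk: int = 512) -> np.ndarray:
    """Literal all-pairs scan: every candidate against every genome k-mer.

    Canonical Hamming distance is min over the key's two orientations;
    near total sums occurrence counts of keys at distance 1..j.  Quadratic
    — intended for genomes up to a few tens of kb.
    """
    k = occ.k
    keys, counts = occ.keys, occ.counts
    rck = revcomp_vals(keys, k)
    out = np.zeros(cands.size, dtype=np.int64)
    for lo in range(0, cands.size, chunk):
        c = cands[lo : lo + chunk, None]
        d = np.minimum(
            _hamming_vals(c, keys[None, :]), _hamming_vals(c, rck[None, :])
        )
        near = (d >= 1) & (d <= j) & (keys[None, :] != c)
        out[lo : lo + chunk] = (near * counts[None, :]).sum(axis=1)
    return out


def blocked_near_counts(cands: np.ndarray, occ, j: int) -> np.ndarray:
    """Exact near-match totals via pigeonhole block partitioning.

    Splitting k positions into three blocks, any pair within Hamming
    distance <= 2 agrees exactly on at least one whole block, so joining
    candidates with (both orientations of) the genome keys on each block
    value and measuring the distance of every joined pair enumerates all
    qualifying pairs.  Exact for j <= 2; scales to large k-mer sets.
    """
    if j > 2:
        raise ValueError("pigeonhole split into 3 blocks is exact only for j <= 2")
    k = occ.k
    keys, counts = occ.keys, occ.counts
    out = np.zeros(cands.size, dtype=np.int64)
    if j == 0 or cands.size == 0 or keys.size == 0:
        return out
    targets = np.concatenate([keys, revcomp_vals(keys, k)])
    tsrc = np.concatenate([np.arange(keys.size), np.arange(keys.size)])
    # block b covers 2-bit positions [edges[b], edges[b+1])
    edges = [0, k // 3, 2 * k // 3, k]
    pair_codes: list[np.ndarray] = []
    for b in range(3):
        lo_bit, hi_bit = 2 * edges[b], 2 * edges[b + 1]
        mask = np.uint64(((1 << (hi_bit - lo_bit)) - 1) << lo_bit)
        tb = targets & mask
        cb = cands & mask
        order = np.argsort(tb, kind="stable")
        tb_sorted = tb[order]
        lo = np.searchsorted(tb_sorted, cb, side="left")
        hi = np.searchsorted(tb_sorted, cb, side="right")
        n_pairs = hi - lo
        total = int(n_pairs.sum())
        if total == 0:
            continue
        ci = np.repeat(np.arange(cands.size), n_pairs)
        offs = np.arange(total) - np.repeat(
            np.concatenate(([0], np.cumsum(n_pairs)[:-1])), n_pairs
        )
        ti = order[np.repeat(lo, n_pairs) + offs]
        d = _hamming_vals(cands[ci], targets[ti])
        okd = (d >= 1) & (d <= j)
        if okd.any():
            pair_codes.append(
                ci[okd].astype(np.uint64) * np.uint64(keys.size)
                + tsrc[ti[okd]].astype(np.uint64)
            )
    if not pair_codes:
        return out
    uniq = np.unique(np.concatenate(pair_codes))
    upc = (uniq // np.uint64(keys.size)).astype(np.int64)
    upk = (uniq % np.uint64(keys.size)).astype(np.int64)
    keep = keys[upk] != cands[upc]
    out = np.bincount(
        upc[keep], weights=counts[upk].astype(np.float64)[keep], minlength=cands.size
    ).astype(np.int64)
    return out


def oracle_retained_set(sequences, k: int, j: int, max_near: int, blocked: bool = True):
    """Brute-force retained set: unique exact k-mers whose near total < max_near."""
    from kmercn.indexer import enumerate_occurrences, select_candidates

    occ = enumerate_occurrences(sequences, k)
    cands = select_candidates(occ)
    fn = blocked_near_counts if blocked else allpairs_near_counts
    near = fn(cands, occ, j)
    return set(int(v) for v in cands[near < max_near])


def naive_count_reads(reads, catalog) -> np.ndarray:
    """Plain-dictionary counter over catalog k-mers (string level throughout)."""
    from kmercn.codec import EncodedKmer, decode_kmer

    k = catalog.k
    index = {
        decode_kmer(EncodedKmer(int(v), k)): i for i, v in enumerate(catalog.value)
    }
    counts = np.zeros(len(catalog), dtype=np.int64)
    table = str.maketrans("ACGT", "TGCA")
    for read in reads:
        read = read.upper()
        for i in range(len(read) - k + 1):
            w = read[i : i + k]
            if any(c not in "ACGT" for c in w):
                continue
            rc = w.translate(table)[::-1]
            hit = index.get(w)
            if hit is None:
                hit = index.get(rc)
            if hit is not None:
                counts[hit] += 1
    return counts
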