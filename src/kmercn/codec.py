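"""2-bit k-mer encoding, canonicalization, hashing, and the open-addressing table.

Each base is packed into two bits taken from bits 1-2 of its ASCII code
(A=0, C=1, T=2, G=3), so a 64-bit word holds up to 32 bases with the 3'
base in the least-significant slot.  Under this code the complement of a
base is ``code ^ 2``, which makes reverse complementation a handful of
bitwise operations.  A k-mer and its reverse complement are treated as
one entity by keeping the numerically smaller ("canonical") encoding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MAX_K",
    "EncodedKmer",
    "KmerRejected",
    "TableFullError",
    "KmerHashTable",
    "encode_kmer",
    "decode_kmer",
    "revcomp_encoded",
    "canonical",
    "djb2",
    "hash_index",
    "revcomp_vals",
    "canonical_vals",
    "sequence_codes",
    "encode_windows",
]

MAX_K = 32

#: code -> base, where code = (ascii >> 1) & 3
_BASES = "ACTG"
_VALID_ASCII = frozenset(b"ACGT")

_U64 = (1 << 64) - 1
_M2 = 0x3333333333333333  # swap adjacent 2-bit fields
_M4 = 0x0F0F0F0F0F0F0F0F  # swap nibbles
_COMP = 0xAAAAAAAAAAAAAAAA  # XOR 0b10 in every 2-bit field


class KmerRejected(ValueError):
    """A window holds a base outside {A,C,G,T} (N or other ambiguity code).

    Deliberately distinct from :class:`ValueError` misuse errors so callers
    can skip the offending window and continue.
    """


@dataclass(frozen=True)
class EncodedKmer:
    """A <=32-mer packed 2 bits/base into a 64-bit value, 3' base in the LSBs."""

    value: int
    k: int

    def __post_init__(self) -> None:
        if not 1 <= self.k <= MAX_K:
            raise ValueError(f"k must be in [1, {MAX_K}], got {self.k}")
        if not 0 <= self.value < (1 << (2 * self.k)):
            raise ValueError(f"value {self.value:#x} has bits above position {2 * self.k - 1}")

    def __str__(self) -> str:
        return decode_kmer(self)


def encode_kmer(seq: str) -> EncodedKmer:
    """Pack a DNA string (case-insensitive) into an :class:`EncodedKmer`.

    Raises :class:`KmerRejected` for any character outside {A,C,G,T},
    including N, and :class:`ValueError` for an out-of-range length.
    """
    if not 1 <= len(seq) <= MAX_K:
        raise ValueError(f"k-mer length must be in [1, {MAX_K}], got {len(seq)}")
    try:
        raw = seq.upper().encode("ascii")
    except UnicodeEncodeError as exc:
        raise KmerRejected(f"non-ASCII character in k-mer {seq!r}") from exc
    value = 0
    for ch in raw:
        if ch not in _VALID_ASCII:
            raise KmerRejected(f"ambiguous or invalid base {chr(ch)!r} in k-mer {seq!r}")
        value = (value << 2) | ((ch >> 1) & 3)
    return EncodedKmer(value, len(raw))


def decode_kmer(x: EncodedKmer) -> str:
    """Inverse of :func:`encode_kmer` (always uppercase)."""
    out = []
    v = x.value
    for _ in range(x.k):
        out.append(_BASES[v & 3])
        v >>= 2
    return "".join(reversed(out))


def _revcomp_value(value: int, k: int) -> int:
    v = value ^ (_COMP & ((1 << (2 * k)) - 1))
    v = ((v >> 2) & _M2) | ((v & _M2) << 2) & _U64
    v = ((v >> 4) & _M4) | ((v & _M4) << 4) & _U64
    v = int.from_bytes((v & _U64).to_bytes(8, "little"), "big")
    return v >> (64 - 2 * k)


def revcomp_encoded(x: EncodedKmer) -> EncodedKmer:
    """Reverse complement entirely in 2-bit space (complement = code ^ 2)."""
    return EncodedKmer(_revcomp_value(x.value, x.k), x.k)


def canonical(x: EncodedKmer) -> EncodedKmer:
    """The smaller of a k-mer's encoding and its reverse complement's."""
    rc = _revcomp_value(x.value, x.k)
    return EncodedKmer(min(x.value, rc), x.k)


def djb2(data: bytes, seed: int = 5381) -> int:
    """Classic multiplicative DJB2 (h = h*33 + byte) with 64-bit wraparound."""
    h = seed
    for b in data:
        h = (h * 33 + b) & _U64
    return h


def _value_of(x: EncodedKmer | int) -> int:
    return x.value if isinstance(x, EncodedKmer) else int(x)


def hash_index(x: EncodedKmer | int, capacity: int) -> int:
    """DJB2 of the encoded value's 8 bytes (MSB first) modulo ``capacity``."""
    if capacity < 1:
        raise ValueError("capacity must be >= 1")
    return djb2(_value_of(x).to_bytes(8, "big")) % capacity


class TableFullError(RuntimeError):
    """No empty cell reachable along the probe direction."""


class KmerHashTable:
    """Open-addressing table with half-dependent linear probing.

    A probe starting in the lower half of the array walks toward increasing
    indices; one starting in the upper half walks toward decreasing indices.
    There is no wraparound: the table must be sized so probes terminate
    (see :meth:`capacity_for`).  Parallel integer payload arrays (occurrence
    counts, near-match tallies, successor links, ...) can be attached with
    :meth:`add_payload`.
    """

    def __init__(self, capacity: int):
        if capacity < 1:
            raise ValueError("capacity must be >= 1")
        self.capacity = int(capacity)
        self._keys = np.zeros(self.capacity, dtype=np.uint64)
        self._occupied = np.zeros(self.capacity, dtype=bool)
        self._n = 0
        self.payloads: dict[str, np.ndarray] = {}

    @staticmethod
    def capacity_for(n_keys: int) -> int:
        """Next power of two >= 2x the expected key count (load factor <= 0.5)."""
        return 1 << max(1, int(2 * max(1, n_keys) - 1).bit_length())

    def add_payload(self, name: str, dtype=np.int64) -> np.ndarray:
        arr = np.zeros(self.capacity, dtype=dtype)
        self.payloads[name] = arr
        return arr

    @property
    def n_occupied(self) -> int:
        return self._n

    def _walk(self, value: int):
        """Yield cell indices from the hash index along the probe direction."""
        start = hash_index(value, self.capacity)
        step = 1 if start < self.capacity // 2 else -1
        i = start
        while 0 <= i < self.capacity:
            yield i
            i += step

    def insert(self, x: EncodedKmer | int) -> int:
        """Store ``x`` and return its cell; idempotent for present keys."""
        value = _value_of(x)
        for i in self._walk(value):
            if not self._occupied[i]:
                if self._n >= self.capacity:
                    raise TableFullError("table is full")
                self._keys[i] = value
                self._occupied[i] = True
                self._n += 1
                return i
            if int(self._keys[i]) == value:
                return i
        raise TableFullError(
            f"probe for {value:#x} ran off the array edge (capacity {self.capacity})"
        )

    def lookup(self, x: EncodedKmer | int) -> int | None:
        """Cell index of ``x``, or None; never scans past an empty cell."""
        value = _value_of(x)
        for i in self._walk(value):
            if not self._occupied[i]:
                return None
            if int(self._keys[i]) == value:
                return i
        return None


# ---------------------------------------------------------------------------
# Vectorized counterparts used by the indexing and counting stages.
# ---------------------------------------------------------------------------

def revcomp_vals(values: np.ndarray, k: int) -> np.ndarray:
    """Reverse complement an array of encoded values (uint64) for length k."""
    v = np.asarray(values, dtype=np.uint64)
    v = v ^ np.uint64(_COMP & ((1 << (2 * k)) - 1))
    v = ((v >> np.uint64(2)) & np.uint64(_M2)) | ((v & np.uint64(_M2)) << np.uint64(2))
    v = ((v >> np.uint64(4)) & np.uint64(_M4)) | ((v & np.uint64(_M4)) << np.uint64(4))
    v = v.byteswap()
    if k < MAX_K:
        v = v >> np.uint64(64 - 2 * k)
    return v


def canonical_vals(values: np.ndarray, k: int) -> np.ndarray:
    """Element-wise min(value, revcomp(value))."""
    v = np.asarray(values, dtype=np.uint64)
    return np.minimum(v, revcomp_vals(v, k))


def sequence_codes(seq: str) -> tuple[np.ndarray, np.ndarray]:
    """Map a sequence to per-base 2-bit codes plus a validity mask.

    Lowercase (soft-masked) bases are uppercased; anything outside
    {A,C,G,T} — N and other IUPAC ambiguity codes included — is flagged
    invalid.
    """
    raw = np.frombuffer(seq.encode("ascii", "replace"), dtype=np.uint8)
    up = raw & np.uint8(0xDF)  # ASCII uppercase for letters
    valid = (up == 65) | (up == 67) | (up == 71) | (up == 84)
    codes = (up >> np.uint8(1)) & np.uint8(3)
    return codes, valid


def encode_windows(seq: str, k: int, chunk: int = 1 << 19) -> tuple[np.ndarray, np.ndarray]:
    """Encode every valid length-k window of ``seq``.

    Returns ``(starts, values)`` where starts are 0-based 5' offsets of
    windows free of invalid bases and values are the forward-strand
    encodings (not canonicalized).
    """
    if not 1 <= k <= MAX_K:
        raise ValueError(f"k must be in [1, {MAX_K}]")
    codes, valid = sequence_codes(seq)
    n = codes.size
    if n < k:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.uint64)
    nw = n - k + 1
    cs = np.concatenate(([0], np.cumsum(~valid)))
    ok = (cs[k:] - cs[:-k]) == 0
    weights = np.uint64(1) << (np.uint64(2) * np.arange(k - 1, -1, -1, dtype=np.uint64))
    values = np.empty(nw, dtype=np.uint64)
    win = np.lib.stride_tricks.sliding_window_view(codes, k)
    for lo in range(0, nw, chunk):
        hi = min(lo + chunk, nw)
        values[lo:hi] = (win[lo:hi].astype(np.uint64) * weights).sum(axis=1, dtype=np.uint64)
    starts = np.flatnonzero(ok).astype(np.int64)
    return starts, values[ok]
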