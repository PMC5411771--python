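"""Recursive (rolling) canonical multi-hashing of DNA k-mers.

The hash of a k-mer is a rotate-and-xor combination of four fixed 64-bit
per-base constants, position-encoded by bit rotation::

    fwd(s) = XOR_{j=0..k-1} rotl64(SEED[s_j], k - 1 - j)

This cyclic-polynomial form admits an O(1) update when the window slides
one base to the right, and the hash of the reverse complement rolls in
the same way on the opposite strand.  The *canonical* value of a k-mer is
``min(fwd, rc)``, identical for a k-mer and its reverse complement, so a
single value represents both strands.  Additional hash values for Bloom
filters are derived from the canonical value by a cheap deterministic
mixing schedule, without rehashing the k-mer.

Two parallel implementations are provided and cross-checked by tests:

* a scalar API (:func:`hash_direct`, :class:`KmerWindow`, :class:`Kmer`)
  operating on Python integers, used by the graph traversal; and
* a vectorised API (:func:`window_hashes`, :func:`multi_hash`) operating
  on numpy ``uint64`` arrays, used by the bulk loading/scanning passes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "InvalidBaseError",
    "EndOfSegment",
    "Kmer",
    "KmerWindow",
    "encode",
    "decode",
    "revcomp",
    "hash_direct",
    "rc_hash_direct",
    "canonical_hash_direct",
    "first_window",
    "roll_forward",
    "canonical_hash",
    "multi_hash",
    "window_hashes",
    "canonical_window_hashes",
    "segment_window_hashes",
]

MASK64 = (1 << 64) - 1

# Fixed per-base 64-bit seed constants, committed for cross-platform
# reproducibility.  A/C/G/T -> codes 0/1/2/3; complement(code) == 3 - code.
SEED_A = 0x3C8BFBB395C60474
SEED_C = 0x3193C18562A02B4C
SEED_G = 0x20323ED082572324
SEED_T = 0x295549F54BE24456

_SEEDS = (SEED_A, SEED_C, SEED_G, SEED_T)
_SEEDS_RC = (SEED_T, SEED_G, SEED_C, SEED_A)  # seed of the complement base

# Multi-hash schedule constants (splitmix64-style finaliser).
_MULTI_SEED = 0x90B45D39FB6DA1FA
_MIX_1 = 0xBF58476D1CE4E5B9
_MIX_2 = 0x94D049BB133111EB

BASES = "ACGT"

_CODE_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _CODE_LUT[ord(_b)] = _i
    _CODE_LUT[ord(_b.lower())] = _i

_BASE_LUT = np.frombuffer(b"ACGT", dtype=np.uint8)

_U64 = np.uint64


def _rotl_int(x: int, r: int) -> int:
    r &= 63
    if r == 0:
        return x
    return ((x << r) | (x >> (64 - r))) & MASK64


def _rotr_int(x: int, r: int) -> int:
    return _rotl_int(x, 64 - (r & 63))


# Rotation tables: _ROT_FWD[b, r] = rotl(SEED[b], r); likewise for the
# complement-base seeds.  Shape (4, 64), uint64.
_ROT_FWD = np.array(
    [[_rotl_int(s, r) for r in range(64)] for s in _SEEDS], dtype=_U64
)
_ROT_RC = np.array(
    [[_rotl_int(s, r) for r in range(64)] for s in _SEEDS_RC], dtype=_U64
)

_COMPLEMENT = bytes.maketrans(b"ACGTacgt", b"TGCATGCA")


class InvalidBaseError(ValueError):
    """A sequence contains a character outside A/C/G/T."""

    def __init__(self, position: int, char: str):
        self.position = position
        self.char = char
        super().__init__(
            f"invalid base {char!r} at position {position}; expected A/C/G/T"
        )


class EndOfSegment(Exception):
    """Raised when rolling past the last window of a segment."""


def encode(seq: str) -> np.ndarray:
    """Encode an A/C/G/T string (case-insensitive) to codes 0..3.

    Raises :class:`InvalidBaseError` naming the first offending position.
    """
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = _CODE_LUT[raw]
    bad = np.nonzero(codes == 255)[0]
    if bad.size:
        pos = int(bad[0])
        raise InvalidBaseError(pos, seq[pos])
    return codes


def decode(codes: np.ndarray) -> str:
    return _BASE_LUT[codes].tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T string (uppercased output kept as-is)."""
    return seq.translate(_COMPLEMENT)[::-1]


def hash_direct(seq: str, k: int) -> int:
    """From-scratch forward-strand hash of a single k-mer.

    ``seq`` must be exactly ``k`` bases over A/C/G/T (case-insensitive).
    """
    if len(seq) != k:
        raise ValueError(f"sequence length {len(seq)} != k={k}")
    codes = encode(seq)
    v = 0
    for j in range(k):
        v ^= _rotl_int(_SEEDS[codes[j]], k - 1 - j)
    return v


def rc_hash_direct(seq: str, k: int) -> int:
    """From-scratch hash of the reverse complement of a k-mer."""
    if len(seq) != k:
        raise ValueError(f"sequence length {len(seq)} != k={k}")
    codes = encode(seq)
    v = 0
    for j in range(k):
        v ^= _rotl_int(_SEEDS_RC[codes[j]], j)
    return v


def canonical_hash_direct(seq: str, k: int) -> int:
    """Strand-symmetric hash of a single k-mer (min of both strands)."""
    return min(hash_direct(seq, k), rc_hash_direct(seq, k))


@dataclass(frozen=True)
class KmerWindow:
    """A k-length window over a DNA segment with both strand hashes.

    Invariants: ``pos + k <= len(segment)``; ``fwd_hash`` and ``rc_hash``
    equal the from-scratch hashes of the window and its reverse
    complement.
    """

    segment: str
    k: int
    pos: int
    fwd_hash: int
    rc_hash: int

    @property
    def bases(self) -> str:
        return self.segment[self.pos : self.pos + self.k]


def first_window(segment: str, k: int, pos: int = 0) -> KmerWindow:
    """Open the window at ``pos`` (hashes computed from scratch)."""
    if pos + k > len(segment):
        raise ValueError(f"window [{pos}, {pos + k}) exceeds segment length")
    sub = segment[pos : pos + k]
    return KmerWindow(segment, k, pos, hash_direct(sub, k), rc_hash_direct(sub, k))


def roll_forward(prev: KmerWindow) -> KmerWindow:
    """Slide the window one base right; both hashes update in O(1)."""
    k = prev.k
    if prev.pos + k >= len(prev.segment):
        raise EndOfSegment(
            f"window at pos {prev.pos} is the last of the segment"
        )
    seg = prev.segment
    out = _CODE_LUT[ord(seg[prev.pos])]
    new = _CODE_LUT[ord(seg[prev.pos + k])]
    if out == 255:
        raise InvalidBaseError(prev.pos, seg[prev.pos])
    if new == 255:
        raise InvalidBaseError(prev.pos + k, seg[prev.pos + k])
    fwd = _rotl_int(prev.fwd_hash, 1) ^ _rotl_int(_SEEDS[out], k) ^ _SEEDS[new]
    rc = (
        _rotr_int(prev.rc_hash, 1)
        ^ _rotr_int(_SEEDS_RC[out], 1)
        ^ _rotl_int(_SEEDS_RC[new], k - 1)
    )
    return KmerWindow(seg, k, prev.pos + 1, fwd, rc)


def canonical_hash(w: KmerWindow) -> int:
    """Canonical (strand-symmetric) value of a window: min(fwd, rc)."""
    return min(w.fwd_hash, w.rc_hash)


@dataclass(frozen=True)
class Kmer:
    """An oriented k-mer held as codes plus incrementally-maintained hashes.

    Used by graph traversal: :meth:`extend_right` appends one base in
    O(1) hash work, :meth:`revcomp` flips orientation by swapping the two
    strand hashes.
    """

    codes: tuple
    fwd: int
    rc: int

    @classmethod
    def from_codes(cls, codes) -> "Kmer":
        codes = tuple(int(c) for c in codes)
        k = len(codes)
        fwd = 0
        rc = 0
        for j, c in enumerate(codes):
            fwd ^= _rotl_int(_SEEDS[c], k - 1 - j)
            rc ^= _rotl_int(_SEEDS_RC[c], j)
        return cls(codes, fwd, rc)

    @classmethod
    def from_string(cls, seq: str) -> "Kmer":
        return cls.from_codes(encode(seq))

    @property
    def k(self) -> int:
        return len(self.codes)

    @property
    def bases(self) -> str:
        return "".join(BASES[c] for c in self.codes)

    @property
    def canonical(self) -> int:
        return min(self.fwd, self.rc)

    def extend_right(self, b: int) -> "Kmer":
        """The successor k-mer obtained by shifting left and appending base b."""
        k = len(self.codes)
        out = self.codes[0]
        fwd = _rotl_int(self.fwd, 1) ^ _rotl_int(_SEEDS[out], k) ^ _SEEDS[b]
        rc = (
            _rotr_int(self.rc, 1)
            ^ _rotr_int(_SEEDS_RC[out], 1)
            ^ _rotl_int(_SEEDS_RC[b], k - 1)
        )
        return Kmer(self.codes[1:] + (b,), fwd, rc)

    def revcomp(self) -> "Kmer":
        return Kmer(tuple(3 - c for c in reversed(self.codes)), self.rc, self.fwd)


def _splitmix_int(x: int) -> int:
    x &= MASK64
    x ^= x >> 30
    x = (x * _MIX_1) & MASK64
    x ^= x >> 27
    x = (x * _MIX_2) & MASK64
    x ^= x >> 31
    return x


def _splitmix_arr(x: np.ndarray) -> np.ndarray:
    x = x.astype(_U64, copy=True)
    x ^= x >> _U64(30)
    x *= _U64(_MIX_1)
    x ^= x >> _U64(27)
    x *= _U64(_MIX_2)
    x ^= x >> _U64(31)
    return x


def multi_hash(base, h: int, seed: int = 0):
    """Derive ``h`` 64-bit hash values from a base value without rehashing.

    Stream 0 is the (seed-adjusted) base value itself; stream ``i`` mixes
    ``base ^ i * MULTI_SEED`` through a splitmix64 finaliser.  Accepts a
    Python int (returns a list of ints) or a uint64 array (returns an
    ``(h, n)`` array).
    """
    if h < 1:
        raise ValueError(f"h must be >= 1, got {h}")
    if isinstance(base, np.ndarray):
        eff = base.astype(_U64, copy=False)
        if seed:
            eff = eff ^ _U64(_splitmix_int(seed))
        out = np.empty((h, eff.size), dtype=_U64)
        out[0] = eff
        for i in range(1, h):
            out[i] = _splitmix_arr(eff ^ _U64((i * _MULTI_SEED) & MASK64))
        return out
    eff = base & MASK64
    if seed:
        eff ^= _splitmix_int(seed)
    vals = [eff]
    for i in range(1, h):
        vals.append(_splitmix_int(eff ^ ((i * _MULTI_SEED) & MASK64)))
    return vals


def _rotl_arr(x: np.ndarray, r: np.ndarray) -> np.ndarray:
    r = r & _U64(63)
    return (x << r) | (x >> ((_U64(64) - r) & _U64(63)))


def window_hashes(codes: np.ndarray, k: int):
    """Forward and reverse-complement hashes of every k-window of ``codes``.

    Vectorised closed form of the rolling recurrence: with
    ``g[i] = rotl(SEED[c_i], -i)`` the window hash is the sliding-window
    xor of ``g`` rotated back by ``k - 1 + w``, so a prefix-xor gives all
    windows in O(n).  Returns ``(fwd, rc)`` uint64 arrays of length
    ``len(codes) - k + 1``.
    """
    n = codes.size - k + 1
    if n <= 0:
        e = np.empty(0, dtype=_U64)
        return e, e.copy()
    idx = np.arange(codes.size, dtype=_U64)
    neg = (_U64(64) - (idx & _U64(63))) & _U64(63)

    g = _ROT_FWD[codes, neg]
    px = np.zeros(codes.size + 1, dtype=_U64)
    np.bitwise_xor.accumulate(g, out=px[1:])
    w = np.arange(n, dtype=_U64)
    fwd = _rotl_arr(px[k : k + n] ^ px[:n], (_U64(k - 1) + w))

    gr = _ROT_RC[codes, idx & _U64(63)]
    np.bitwise_xor.accumulate(gr, out=px[1:])
    rc = _rotl_arr(px[k : k + n] ^ px[:n], (_U64(64) - (w & _U64(63))))
    return fwd, rc


def canonical_window_hashes(codes: np.ndarray, k: int) -> np.ndarray:
    """Canonical hash of every k-window of ``codes`` (vectorised)."""
    fwd, rc = window_hashes(codes, k)
    return np.minimum(fwd, rc)


def segment_window_hashes(cat_codes: np.ndarray, starts: np.ndarray,
                          lengths: np.ndarray, k: int):
    """Canonical window hashes for many segments concatenated into one array.

    ``starts``/``lengths`` delimit segments inside ``cat_codes``; windows
    that would span a segment boundary are dropped.  Segments shorter
    than ``k`` contribute zero windows.  Returns ``(canon, counts)``
    where ``counts[j]`` is the number of windows of segment ``j`` and
    ``canon`` lists them in segment order.
    """
    starts = np.asarray(starts, dtype=np.int64)
    lengths = np.asarray(lengths, dtype=np.int64)
    counts = np.maximum(lengths - k + 1, 0)
    total = int(counts.sum())
    if total == 0 or cat_codes.size < k:
        return np.empty(0, dtype=_U64), counts
    canon = canonical_window_hashes(cat_codes, k)
    # window indices: for segment j, starts[j] .. starts[j] + counts[j] - 1
    offs = np.repeat(np.cumsum(counts) - counts, counts)
    sel = np.arange(total, dtype=np.int64) - offs + np.repeat(starts, counts)
    return canon[sel], counts
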