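"""Bloom filters for canonical k-mer sets, with FPR analytics and sizing.

Three roles share one core structure:

* :class:`BloomFilter` — an m-bit probabilistic set with h hash
  functions; no false negatives, false-positive rate governed by
  ``FPR = (1 - (1 - 1/m)^(h n))^h``.
* :class:`CascadingBloomFilter` — a chain of c equal-sized filters
  implementing occurrence-count thresholding: a key is added to the
  first level where it is absent, so level i holds keys seen at least
  i+1 times (up to false positives) and the last level is the set of
  *solid* k-mers.
* the *tracking* filter (a plain :class:`BloomFilter` of the same size)
  recording k-mers already emitted in unitigs.

All levels of a cascade reuse the same hash values for a key, and the
total memory footprint of an assembly is ``(c + 1) * m`` bits: c cascade
levels plus the equal-sized tracking filter.

Filters store one logical bit per numpy byte for query speed; ``m`` is
the logical size in bits and is what the sizing arithmetic and the
serialised form use.
"""

from __future__ import annotations

import math
import struct
from dataclasses import dataclass, field

import numpy as np

from .hashing import multi_hash

__all__ = [
    "BloomParams",
    "BloomFilter",
    "CascadingBloomFilter",
    "ExactKmerSet",
    "SizingRequest",
    "fpr_analytic",
    "fpr_approx",
    "size_for_fpr",
    "total_memory",
    "chance_connection_probability",
]

_U64 = np.uint64

_MAGIC = b"BTIG"
_FORMAT_VERSION = 1
MIN_FILTER_BITS = 8


@dataclass(frozen=True)
class BloomParams:
    """Filter geometry: m bits, h hash functions, hash seed."""

    m: int
    h: int = 4
    seed: int = 0

    def __post_init__(self):
        if self.m < MIN_FILTER_BITS:
            raise ValueError(f"m must be >= {MIN_FILTER_BITS} bits, got {self.m}")
        if self.m % 8:
            raise ValueError(f"m must be byte-granular (multiple of 8), got {self.m}")
        if self.h < 1:
            raise ValueError(f"h must be >= 1, got {self.h}")


class BloomFilter:
    """Probabilistic set of 64-bit keys (canonical k-mer hashes)."""

    def __init__(self, params: BloomParams):
        self.params = params
        self.bits = np.zeros(params.m, dtype=np.uint8)
        self.inserts = 0

    @property
    def m(self) -> int:
        return self.params.m

    @property
    def h(self) -> int:
        return self.params.h

    def _positions(self, keys: np.ndarray) -> np.ndarray:
        """(h, n) array of bit positions for a uint64 key array."""
        return multi_hash(keys, self.params.h, self.params.seed) % _U64(self.m)

    def _positions_int(self, key: int) -> list:
        return [v % self.m for v in multi_hash(key, self.params.h, self.params.seed)]

    def insert(self, key: int) -> None:
        """Set all h bits of the key's bit signature."""
        for p in self._positions_int(key):
            self.bits[p] = 1
        self.inserts += 1

    def contains(self, key: int) -> bool:
        """True iff every position of the key's bit signature is set."""
        return all(self.bits[p] for p in self._positions_int(key))

    def insert_batch(self, keys: np.ndarray) -> None:
        keys = np.asarray(keys, dtype=_U64)
        if keys.size == 0:
            return
        self.bits[self._positions(keys).ravel()] = 1
        self.inserts += keys.size

    def contains_batch(self, keys: np.ndarray) -> np.ndarray:
        keys = np.asarray(keys, dtype=_U64)
        if keys.size == 0:
            return np.zeros(0, dtype=bool)
        pos = self._positions(keys)
        out = self.bits[pos[0]].astype(bool)
        for i in range(1, pos.shape[0]):
            out &= self.bits[pos[i]].astype(bool)
        return out

    @property
    def popcount(self) -> int:
        return int(self.bits.sum())

    @property
    def occupancy(self) -> float:
        return self.popcount / self.m

    @property
    def fpr(self) -> float:
        """Realised FPR from bit occupancy: P(all h probes hit set bits)."""
        return self.occupancy ** self.params.h

    def save(self, path, k: int = 0, c: int = 1) -> None:
        """Binary dump: header (magic, version, m, h, c, k, seed) + LE bit vector."""
        with open(path, "wb") as fh:
            fh.write(_MAGIC)
            fh.write(
                struct.pack(
                    "<5Q", _FORMAT_VERSION, self.m, self.h, c, k
                )
            )
            fh.write(struct.pack("<q", self.params.seed))
            fh.write(np.packbits(self.bits, bitorder="little").tobytes())

    @classmethod
    def load(cls, path):
        """Load a dumped filter; returns ``(filter, k, c)``."""
        with open(path, "rb") as fh:
            if fh.read(4) != _MAGIC:
                raise ValueError(f"{path}: not a bloomtig filter dump")
            version, m, h, c, k = struct.unpack("<5Q", fh.read(40))
            if version != _FORMAT_VERSION:
                raise ValueError(f"{path}: unsupported format version {version}")
            (seed,) = struct.unpack("<q", fh.read(8))
            raw = np.frombuffer(fh.read(m // 8), dtype=np.uint8)
        f = cls(BloomParams(int(m), int(h), int(seed)))
        f.bits = np.unpackbits(raw, bitorder="little")[: f.m].copy()
        return f, int(k), int(c)


class CascadingBloomFilter:
    """Chain of c equal-sized Bloom filters for occurrence thresholding.

    Inserting a key adds it to the first level where it is not already
    present, so after j collision-free insertions the key occupies the
    first j levels.  The last level approximates membership of the
    multiset elements with count >= c.
    """

    def __init__(self, params: BloomParams, c: int):
        if c < 1:
            raise ValueError(f"cascade depth c must be >= 1, got {c}")
        self.c = c
        self.params = params
        self.levels = [BloomFilter(params) for _ in range(c)]

    def insert(self, key: int) -> None:
        for lvl in self.levels:
            if not lvl.contains(key):
                lvl.insert(key)
                return
        # present in every level already: no-op

    def insert_batch(self, keys: np.ndarray) -> None:
        """Insert a batch of keys, honouring within-batch multiplicities.

        Equivalent to inserting the keys one at a time: a key occurring t
        times in the batch deepens its cascade membership by t levels
        (capped at c), using the level occupancy as seen at batch start.
        """
        keys = np.asarray(keys, dtype=_U64)
        if keys.size == 0:
            return
        uniq, counts = np.unique(keys, return_counts=True)
        pos = self.levels[0]._positions(uniq)  # shared across levels
        presence = np.empty((self.c, uniq.size), dtype=bool)
        for i, lvl in enumerate(self.levels):
            p = lvl.bits[pos[0]].astype(bool)
            for j in range(1, pos.shape[0]):
                p &= lvl.bits[pos[j]].astype(bool)
            presence[i] = p
        remaining = counts.copy()
        for _ in range(self.c):
            absent_any = ~presence.all(axis=0)
            active = (remaining > 0) & absent_any
            if not active.any():
                break
            first_absent = np.argmin(presence[:, active], axis=0)
            act_idx = np.nonzero(active)[0]
            for lvl_i in range(self.c):
                sel = act_idx[first_absent == lvl_i]
                if sel.size:
                    self.levels[lvl_i].bits[pos[:, sel].ravel()] = 1
                    self.levels[lvl_i].inserts += sel.size
                    presence[lvl_i, sel] = True
            remaining[act_idx] -= 1

    def solid_contains(self, key: int) -> bool:
        """Membership in the last level only (the solid k-mer set)."""
        return self.levels[-1].contains(key)

    def solid_contains_batch(self, keys: np.ndarray) -> np.ndarray:
        return self.levels[-1].contains_batch(keys)

    @property
    def solid(self) -> BloomFilter:
        return self.levels[-1]

    def retain_last(self) -> BloomFilter:
        """Free all levels but the last (done after the loading pass)."""
        last = self.levels[-1]
        self.levels = [last]
        return last


class ExactKmerSet:
    """Exact (zero-FPR) drop-in for a Bloom filter's query interface.

    Backs the de Bruijn graph with a plain hash set of canonical k-mer
    hashes; used to build constructed test instances and oracles.
    """

    def __init__(self, keys=()):
        self._set = set(int(k) for k in keys)

    def insert(self, key: int) -> None:
        self._set.add(int(key))

    def contains(self, key: int) -> bool:
        return int(key) in self._set

    def insert_batch(self, keys) -> None:
        self._set.update(int(k) for k in np.asarray(keys, dtype=_U64))

    def contains_batch(self, keys) -> np.ndarray:
        keys = np.asarray(keys, dtype=_U64)
        return np.fromiter(
            (int(k) in self._set for k in keys), dtype=bool, count=keys.size
        )

    def __len__(self) -> int:
        return len(self._set)


@dataclass(frozen=True)
class SizingRequest:
    """Inputs for memory-budget sizing: n distinct keys, target FPR, h."""

    n: int
    target_fpr: float
    h: int = 4

    def __post_init__(self):
        if self.n < 0:
            raise ValueError(f"n must be >= 0, got {self.n}")
        if not (0.0 < self.target_fpr < 1.0):
            raise ValueError(
                f"target_fpr must lie in (0, 1), got {self.target_fpr}"
            )
        if self.h < 1:
            raise ValueError(f"h must be >= 1, got {self.h}")


def fpr_analytic(m: int, h: int, n: int) -> float:
    """Exact expected false-positive rate ``(1 - (1 - 1/m)^(h n))^h``."""
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    if h < 1:
        raise ValueError(f"h must be >= 1, got {h}")
    if n < 0:
        raise ValueError(f"n must be >= 0, got {n}")
    if n == 0:
        return 0.0
    if m == 1:
        return 1.0
    return (1.0 - math.exp(h * n * math.log1p(-1.0 / m))) ** h


def fpr_approx(m: int, h: int, n: int) -> float:
    """Exponential approximation ``(1 - e^(-h n / m))^h``."""
    if m < 1 or h < 1 or n < 0:
        raise ValueError("require m >= 1, h >= 1, n >= 0")
    return (1.0 - math.exp(-h * n / m)) ** h


def size_for_fpr(req: SizingRequest) -> int:
    """Smallest byte-granular m with ``fpr_analytic(m, h, n) <= target``."""
    if req.n == 0:
        return MIN_FILTER_BITS
    # start from the exponential-approximation inversion, then bisect the
    # exact form on byte-granular sizes
    m0 = -req.h * req.n / math.log1p(-req.target_fpr ** (1.0 / req.h))
    lo, hi = MIN_FILTER_BITS // 8, max(MIN_FILTER_BITS, int(m0 * 2)) // 8 + 1
    while fpr_analytic(hi * 8, req.h, req.n) > req.target_fpr:
        lo, hi = hi, hi * 2
    while lo < hi:
        mid = (lo + hi) // 2
        if fpr_analytic(mid * 8, req.h, req.n) <= req.target_fpr:
            hi = mid
        else:
            lo = mid + 1
    return hi * 8


def total_memory(per_level_bits: int, c: int) -> int:
    """Total filter bits: c cascade levels + the equal-sized tracking filter."""
    if c < 1:
        raise ValueError(f"c must be >= 1, got {c}")
    return (c + 1) * per_level_bits


def chance_connection_probability(fpr: float, k: int, o: int) -> float:
    """Probability that false positives join two k-mers overlapping by o bases.

    Two true k-mers overlapping by ``o < k - 1`` bases need a chain of
    ``k - 1 - o`` false-positive k-mers to appear connected, giving
    ``fpr ** (k - 1 - o)``; the probability decays exponentially as the
    overlap shrinks.
    """
    if not (0.0 <= fpr <= 1.0):
        raise ValueError(f"fpr must lie in [0, 1], got {fpr}")
    if o < 0 or o > k - 1:
        raise ValueError(f"overlap o must lie in [0, k-1], got o={o}, k={k}")
    return float(fpr) ** (k - 1 - o)
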