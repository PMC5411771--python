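"""Synthetic data, the exact-counting reference assembler, and contiguity metrics.

The generator emulates the shape of a short-read Illumina experiment:
uniform random genomes, single-end reads of fixed length drawn uniformly
from either strand, and i.i.d. substitution errors.  Defaults follow the
benchmark conditions used throughout the test-bed: 100 bp reads at
75-fold coverage with 0.5% substitution errors.

:func:`exact_unitigs` is a deliberately plain reference implementation
of the whole unitig algorithm — exact hash-table k-mer counting, string
k-mers, a Python-set tracking filter — with the same traversal semantics
as the Bloom-filter assembler.  At negligible Bloom FPR the two must
produce identical canonical unitig multisets, which is the headline
verification oracle: it exercises the rolling hashes, the cascading
filter, and the vectorised scanning passes against straight-line code
that shares none of them.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from .hashing import BASES, revcomp
from .io import ReadRecord

__all__ = [
    "SimConfig",
    "simulate_genome",
    "simulate_reads",
    "unique_junction_genome",
    "exact_unitigs",
    "n50_ng50",
    "fpr_sweep",
]

_BASE_LUT = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimConfig:
    """Synthetic experiment shape.

    genome_length: haploid genome size in bases.  read_length /
    coverage: single-end reads of this length to this mean fold
    coverage.  error_rate: per-base substitution probability.
    repeat_spec: optional ``(unit_length, copies)`` — a genomic segment
    copied to multiple loci to create true branch points.  seed: RNG
    seed; all outputs are deterministic given the config.
    """

    genome_length: int = 1_000_000
    read_length: int = 100
    coverage: float = 75.0
    error_rate: float = 0.005
    seed: int = 0
    repeat_spec: tuple | None = None

    def __post_init__(self):
        if not (0.0 <= self.error_rate < 1.0):
            raise ValueError(f"error_rate must lie in [0, 1), got {self.error_rate}")
        if self.coverage <= 0:
            raise ValueError(f"coverage must be > 0, got {self.coverage}")


def _decode(codes: np.ndarray) -> str:
    return _BASE_LUT[codes].tobytes().decode("ascii")


def simulate_genome(cfg: SimConfig) -> str:
    """Uniform random genome; repeat_spec plants exact repeat copies."""
    rng = np.random.default_rng([cfg.seed, 0])
    codes = rng.integers(0, 4, cfg.genome_length, dtype=np.uint8)
    if cfg.repeat_spec is not None:
        unit_len, copies = cfg.repeat_spec
        if unit_len > cfg.genome_length:
            raise ValueError("repeat unit longer than genome")
        src = int(rng.integers(0, cfg.genome_length - unit_len + 1))
        unit = codes[src : src + unit_len].copy()
        placed = [(src, src + unit_len)]
        while len(placed) < copies:
            p = int(rng.integers(0, cfg.genome_length - unit_len + 1))
            if all(p + unit_len <= a or p >= b for a, b in placed):
                codes[p : p + unit_len] = unit
                placed.append((p, p + unit_len))
    return _decode(codes)


def simulate_reads(genome: str, cfg: SimConfig):
    """Single-end reads with uniform starts, random strand, substitution errors.

    Read count is ``round(coverage * genome_length / read_length)``.
    Returns a list of :class:`ReadRecord` (quality omitted).
    """
    G, L = len(genome), cfg.read_length
    if L > G:
        raise ValueError("read_length exceeds genome length")
    rng = np.random.default_rng([cfg.seed, 1])
    n = int(round(cfg.coverage * G / L))
    gcodes = np.frombuffer(genome.encode("ascii"), dtype=np.uint8)
    lut = np.zeros(256, dtype=np.uint8)
    for i, b in enumerate(BASES):
        lut[ord(b)] = i
    gcodes = lut[gcodes]
    starts = rng.integers(0, G - L + 1, n)
    mat = gcodes[starts[:, None] + np.arange(L)]
    rev = rng.random(n) < 0.5
    mat[rev] = 3 - mat[rev, ::-1]
    if cfg.error_rate > 0:
        err = rng.random((n, L)) < cfg.error_rate
        shift = rng.integers(1, 4, (n, L), dtype=np.uint8)
        mat = np.where(err, (mat + shift) % 4, mat)
    return [
        ReadRecord(f"read_{i}", _decode(mat[i])) for i in range(n)
    ]


def unique_junction_genome(length: int, k: int, seed: int = 0,
                           max_tries: int = 100) -> str:
    """A random genome whose canonical (k-1)-mers are all distinct.

    Such a genome induces a perfectly linear de Bruijn graph at word
    size k, so error-free reads must assemble into a single unitig equal
    to the genome (up to reverse complement).
    """
    for t in range(max_tries):
        g = simulate_genome(SimConfig(genome_length=length, seed=seed + 1000 * t))
        seen = set()
        ok = True
        for i in range(length - k + 2):
            w = g[i : i + k - 1]
            c = min(w, revcomp(w))
            if c in seen:
                ok = False
                break
            seen.add(c)
        if ok:
            return g
    raise RuntimeError(
        f"no genome with unique canonical {k - 1}-mers in {max_tries} tries"
    )


# ---------------------------------------------------------------------------
# Exact-counting reference assembler (the verification oracle)
# ---------------------------------------------------------------------------


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _canon(s: str) -> str:
    r = revcomp(s)
    return s if s <= r else r


def _acgt_runs(seq: str):
    run = []
    for ch in seq.upper():
        if ch in "ACGT":
            run.append(ch)
        elif run:
            yield "".join(run)
            run = []
    if run:
        yield "".join(run)


def exact_unitigs(reads, k: int, c: int, lookahead: int | None = None,
                  min_unitig_len: int | None = None):
    """Reference unitig assembly with exact counts and zero false positives.

    Implements the identical pipeline semantics — solid reads in input
    order, branch-point splitting, look-ahead pruning with the same
    depth and node budget, incoming-fork halting, tracking-set
    deduplication — over a plain ``Counter`` of canonical k-mer strings.
    Returns the sorted list of canonical unitig sequences (the multiset
    the Bloom-filter assembler must reproduce at negligible FPR).
    """
    depth = lookahead if lookahead is not None else k
    budget = 16 * depth
    min_len = min_unitig_len if min_unitig_len is not None else k

    recs = []
    for i, r in enumerate(reads):
        if isinstance(r, ReadRecord):
            recs.append(r.sequence)
        else:
            recs.append(str(r))

    counts = Counter()
    for seq in recs:
        for run in _acgt_runs(seq):
            for i in range(len(run) - k + 1):
                counts[_canon(run[i : i + k])] += 1
    solid = {s for s, n in counts.items() if n >= c}

    def succs(kmer):
        tail = kmer[1:]
        return [b for b in BASES if _canon(tail + b) in solid]

    def survives(kmer):
        # generation-bounded breadth-first walk, frontier deduplicated by
        # canonical form; budget exhaustion counts as survival
        frontier = {_canon(kmer): kmer}
        visited = 0
        for _ in range(depth):
            visited += len(frontier)
            if visited > budget:
                return True
            nxt = {}
            for s in frontier.values():
                tail = s[1:]
                for b in BASES:
                    cand = tail + b
                    cc = _canon(cand)
                    if cc in solid:
                        nxt.setdefault(cc, cand)
            if not nxt:
                return False
            frontier = nxt
        return True

    surv_cache = {}

    def surviving(kmer):
        cs = succs(kmer)
        if len(cs) <= 1:
            return cs
        hit = surv_cache.get(kmer)
        if hit is None:
            hit = [b for b in cs if survives(kmer[1:] + b)]
            surv_cache[kmer] = hit
        return hit

    def extend_dir(kmer):
        appended = []
        start = _canon(kmer)
        while True:
            cs = succs(kmer)
            if not cs:
                break
            if len(cs) == 1:
                b = cs[0]
            else:
                sv = surviving(kmer)
                if len(sv) != 1:
                    break
                b = sv[0]
            nxt = kmer[1:] + b
            back = revcomp(nxt)
            if len(succs(back)) >= 2 and len(surviving(back)) >= 2:
                break
            kmer = nxt
            appended.append(b)
            if _canon(kmer) == start:
                break
        return "".join(appended)

    tracking = set()
    out = []
    for seq in recs:
        runs = [r for r in _acgt_runs(seq) if len(r) >= k]
        nwin = sum(len(r) - k + 1 for r in runs)
        if nwin == 0:
            continue
        if not all(
            _canon(run[i : i + k]) in solid
            for run in runs
            for i in range(len(run) - k + 1)
        ):
            continue
        for run in runs:
            n = len(run) - k + 1
            # split at true forks; trim read head/tail lying on false branches
            spans = []
            a = 0
            stop = False
            for j in range(n - 1):
                win, nxt_win = run[j : j + k], run[j + 1 : j + 1 + k]
                out_surv = in_surv = None
                if len(succs(win)) >= 2:
                    out_surv = surviving(win)
                if len(succs(revcomp(nxt_win))) >= 2:
                    in_surv = [_COMP[b] for b in surviving(revcomp(nxt_win))]
                tail_false = out_surv is not None and len(out_surv) < 2 \
                    and run[j + k] not in out_surv
                head_false = in_surv is not None and len(in_surv) < 2 \
                    and run[j] not in in_surv
                if tail_false:
                    if not head_false:
                        spans.append((a, j))
                    stop = True
                    break
                if head_false:
                    a = j + 1
                elif (out_surv is not None and len(out_surv) >= 2) or (
                    in_surv is not None and len(in_surv) >= 2
                ):
                    spans.append((a, j))
                    a = j + 1
            if not stop:
                spans.append((a, n - 1))
            for a, b in spans:
                seg = run[a : b + k]
                kmers = [_canon(seg[i : i + k]) for i in range(len(seg) - k + 1)]
                if all(km in tracking for km in kmers):
                    continue
                right = extend_dir(seg[-k:])
                left = revcomp(extend_dir(revcomp(seg[:k])))
                full = left + seg + right
                tracking.update(
                    _canon(full[i : i + k]) for i in range(len(full) - k + 1)
                )
                if len(full) >= min_len:
                    out.append(_canon(full))
    return sorted(out)


def n50_ng50(lengths, genome_size: int | None = None):
    """Assembly contiguity metrics.

    N50: the largest L such that sequences of length >= L sum to at
    least half the total assembly length.  NG50: the same with half the
    *genome* size as the target; returned as None when genome_size is
    not given, and 0 when the assembly does not reach half the genome.
    """
    lengths = sorted((int(x) for x in lengths), reverse=True)
    if not lengths:
        return 0, (None if genome_size is None else 0)
    half = sum(lengths) / 2
    acc = 0
    n50 = 0
    for length in lengths:
        acc += length
        if acc >= half:
            n50 = length
            break
    if genome_size is None:
        return n50, None
    ghalf = genome_size / 2
    acc = 0
    for length in lengths:
        acc += length
        if acc >= ghalf:
            return n50, length
    return n50, 0


def fpr_sweep(cfg: SimConfig, per_level_bits: list, k: int = 31, c: int = 3,
              h: int = 4, lookahead: int | None = None):
    """Assemble one simulated data set at several fixed filter sizes.

    Emulates the memory-sweep experiment design: the FPR is not set
    directly but follows from the per-level allocation.  Returns one
    dict per size with the realised solid-filter FPR, contiguity and
    traversal-cost metrics.
    """
    from .assemble import AssemblyParams, assemble

    genome = simulate_genome(cfg)
    reads = simulate_reads(genome, cfg)
    points = []
    for bits in per_level_bits:
        params = AssemblyParams(
            k=k, c=c, mem_bits=int(bits), h=h, seed=cfg.seed, lookahead=lookahead
        )
        unitigs, report = assemble(reads, params)
        lengths = [u.length for u in unitigs]
        n50, ng50 = n50_ng50(lengths, genome_size=cfg.genome_length)
        points.append(
            {
                "per_level_bits": int(bits),
                "fpr_percent": report.solid_fpr_percent,
                "level1_fpr_percent": report.fpr_percent,
                "unitigs": report.unitig_count,
                "n50": n50,
                "ng50": ng50,
                "traversal_steps": report.traversal_steps,
            }
        )
    return points
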