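"""Two-pass Bloom-filter unitig assembly.

Pass 1 loads every canonical k-mer of every read into a cascading Bloom
filter; the last cascade level — k-mers occurring at least ``c`` times —
is kept as the *solid* k-mer set and the earlier levels are freed.

Pass 2 walks the reads again in input order.  A read whose k-mers are
all solid is a *solid read*; it is split at surviving branch points of
the de Bruijn graph, and each resulting seed segment that still carries
at least one k-mer absent from the tracking filter is extended left and
right through the graph, one base per unique surviving extension,
halting at dead ends and true forks.  The k-mers of each emitted unitig
are recorded in the tracking filter so that later reads from the same
neighbourhood are skipped rather than re-assembled.

Bulk scanning (k-mer extraction, solidity and tracking prechecks, branch
detection) is vectorised over chunks of reads; only the per-unitig
extension walk and the rare look-ahead resolutions run k-mer by k-mer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import hashing as _h
from .bloom import (
    BloomFilter,
    BloomParams,
    CascadingBloomFilter,
    fpr_analytic,
    size_for_fpr,
    SizingRequest,
    total_memory,
)
from .graph import ProbabilisticDBG
from .hashing import (
    Kmer,
    canonical_window_hashes,
    segment_window_hashes,
    window_hashes,
)
from .io import ReadRecord, read_sequences

__all__ = [
    "AssemblyParams",
    "AssemblyReport",
    "SeedSegment",
    "Unitig",
    "load_pass",
    "is_solid_read",
    "split_at_branches",
    "extend_seed",
    "assemble",
    "solid_read_percent",
]

_U64 = np.uint64

# per-base seed constants as uint64 arrays, plus their (k-1)-rotated forms,
# used to derive branch-candidate hashes from neighbouring window hashes
_SEED_ARR = np.array(_h._SEEDS, dtype=_U64)
_SEED_RC_ARR = np.array(_h._SEEDS_RC, dtype=_U64)


def _rot_tables(k: int):
    r = (k - 1) % 64
    return _h._ROT_FWD[:, r], _h._ROT_RC[:, r]


@dataclass
class AssemblyParams:
    """Assembly configuration.

    k: k-mer size (odd recommended so no k-mer is its own reverse
    complement).  c: minimum k-mer occurrence threshold = number of
    cascade levels (2-4 is the useful range).  mem_bits: per-level filter
    size in bits; if None the filter is sized from an exact distinct-
    k-mer count to meet ``target_fpr``.  h: hash functions per filter.
    lookahead: branch look-ahead depth in nodes (default k).
    min_unitig_len: shortest unitig to emit (default k).  seed: hash/RNG
    seed.  chunk_bases: batch size of the vectorised scanning passes.
    max_steps: optional cap on extension steps per direction.
    """

    k: int
    c: int = 3
    mem_bits: int | None = None
    target_fpr: float = 0.05
    h: int = 4
    lookahead: int | None = None
    min_unitig_len: int | None = None
    seed: int = 0
    chunk_bases: int = 4_000_000
    max_steps: int | None = None

    def __post_init__(self):
        if self.k < 3:
            raise ValueError(f"k must be >= 3, got {self.k}")
        if self.c < 1:
            raise ValueError(f"c must be >= 1, got {self.c}")
        if self.lookahead is not None and self.lookahead < 1:
            raise ValueError("lookahead must be >= 1")

    @property
    def lookahead_depth(self) -> int:
        return self.lookahead if self.lookahead is not None else self.k

    @property
    def min_len(self) -> int:
        return self.min_unitig_len if self.min_unitig_len is not None else self.k


@dataclass
class SeedSegment:
    """A maximal solid, branch-free stretch of a read; a unitig seed."""

    sequence: str
    source_read: str
    span: tuple

    def __post_init__(self):
        if len(self.sequence) != self.span[1] - self.span[0]:
            raise ValueError("span does not match sequence length")


@dataclass
class Unitig:
    """An assembled unitig with the id of the read that seeded it."""

    id: int
    sequence: str
    seed_id: str

    @property
    def length(self) -> int:
        return len(self.sequence)


def solid_read_percent(n_solid: int, n_total: int) -> float:
    """Percentage of solid reads, as printed in run reports."""
    if n_total <= 0:
        return 0.0
    return 100.0 * n_solid / n_total


@dataclass
class AssemblyReport:
    """Run statistics emitted alongside the unitigs."""

    k: int
    c: int
    h: int
    per_level_bits: int
    allocated_bits: int
    n_reads: int = 0
    n_solid_reads: int = 0
    distinct_kmers: int = 0
    total_kmers: int = 0
    fpr_percent: float = 0.0
    solid_fpr_percent: float = 0.0
    unitig_count: int = 0
    total_bases: int = 0
    n50: int = 0
    traversal_steps: int = 0

    @property
    def solid_read_percent(self) -> float:
        return solid_read_percent(self.n_solid_reads, self.n_reads)

    def key_values(self):
        return [
            ("k", self.k),
            ("kc", self.c),
            ("hashes", self.h),
            ("per_level_bits", self.per_level_bits),
            ("allocated_bits", self.allocated_bits),
            ("reads", self.n_reads),
            ("solid_reads", self.n_solid_reads),
            ("solid_read_percent", f"{self.solid_read_percent:.1f}"),
            ("distinct_kmers", self.distinct_kmers),
            ("total_kmers", self.total_kmers),
            ("fpr_percent", f"{self.fpr_percent:.2f}"),
            ("solid_fpr_percent", f"{self.solid_fpr_percent:.2f}"),
            ("unitigs", self.unitig_count),
            ("unitig_bases", self.total_bases),
            ("n50", self.n50),
            ("traversal_steps", self.traversal_steps),
        ]

    def text(self) -> str:
        lines = [
            f"k={self.k} kc={self.c} h={self.h} "
            f"per-level bits={self.per_level_bits} "
            f"total filter bits={self.allocated_bits}",
            f"reads: {self.n_reads}  solid: {self.n_solid_reads} "
            f"({self.solid_read_percent:.1f}%)",
            f"k-mers: {self.total_kmers} total, {self.distinct_kmers} distinct; "
            f"expected FPR {self.fpr_percent:.2f}% "
            f"(solid level, realised: {self.solid_fpr_percent:.2f}%)",
            f"unitigs: {self.unitig_count} ({self.total_bases} bp, N50 {self.n50})",
            f"traversal steps: {self.traversal_steps}",
        ]
        return "\n".join(lines)


class _DistinctCounter:
    """Exact distinct count over uint64 streams via periodic np.unique merges."""

    def __init__(self, compact_at: int = 16_000_000):
        self._parts = []
        self._pending = 0
        self._compact_at = compact_at

    def add(self, arr: np.ndarray) -> None:
        if arr.size == 0:
            return
        self._parts.append(arr)
        self._pending += arr.size
        if self._pending > self._compact_at:
            self._compact()

    def _compact(self) -> None:
        merged = np.unique(np.concatenate(self._parts))
        self._parts = [merged]
        self._pending = merged.size

    def count(self) -> int:
        if not self._parts:
            return 0
        self._compact()
        return self._parts[0].size


def _iter_reads(source):
    """Yield ReadRecords from a path, an iterable of records/strings, or a
    zero-argument callable returning such an iterable (re-iterable source)."""
    if isinstance(source, (str, Path)):
        yield from read_sequences(source)
        return
    if callable(source):
        source = source()
    for i, r in enumerate(source):
        if isinstance(r, ReadRecord):
            yield r
        else:
            yield ReadRecord(f"read_{i}", str(r))


def _split_acgt(seq: str):
    """ACGT runs of a read as (offset, codes) pairs; N etc. split the read."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = _h._CODE_LUT[raw]
    bad = codes == 255
    if not bad.any():
        return [(0, codes)]
    segs = []
    pos = 0
    while pos < len(seq):
        if bad[pos]:
            pos += 1
            continue
        nxt = pos
        while nxt < len(seq) and not bad[nxt]:
            nxt += 1
        segs.append((pos, codes[pos:nxt]))
        pos = nxt
    return segs


def _read_chunks(reads, chunk_bases: int):
    """Group reads into chunks of roughly chunk_bases total sequence."""
    chunk, total = [], 0
    for rec in reads:
        chunk.append(rec)
        total += len(rec.sequence)
        if total >= chunk_bases:
            yield chunk
            chunk, total = [], 0
    if chunk:
        yield chunk


def _chunk_windows(chunk, k: int):
    """Canonical window hashes of every read in a chunk.

    Returns ``(canon, read_nwin)``: all window hashes in read order and
    the number of windows per read (0 for reads with no >=k ACGT run).
    """
    seg_codes, seg_lens, read_idx = [], [], []
    read_nwin = np.zeros(len(chunk), dtype=np.int64)
    for i, rec in enumerate(chunk):
        for _, codes in _split_acgt(rec.sequence):
            if codes.size >= k:
                seg_codes.append(codes)
                seg_lens.append(codes.size)
                read_idx.append(i)
    if not seg_codes:
        return np.empty(0, dtype=_U64), read_nwin
    cat = np.concatenate(seg_codes)
    lens = np.asarray(seg_lens, dtype=np.int64)
    starts = np.cumsum(lens) - lens
    canon, counts = segment_window_hashes(cat, starts, lens, k)
    np.add.at(read_nwin, np.asarray(read_idx), counts)
    return canon, read_nwin


def _load(reads_source, params: AssemblyParams):
    """Pass 1: insert all k-mers into the cascade; count distinct exactly."""
    mem_bits = params.mem_bits
    if mem_bits is None:
        # presampling pass: exact distinct count, then size for target FPR
        counter = _DistinctCounter()
        for chunk in _read_chunks(_iter_reads(reads_source), params.chunk_bases):
            canon, _ = _chunk_windows(chunk, params.k)
            counter.add(canon)
        n_est = counter.count()
        mem_bits = size_for_fpr(
            SizingRequest(n=n_est, target_fpr=params.target_fpr, h=params.h)
        )
    bp = BloomParams(m=mem_bits, h=params.h, seed=params.seed)
    cascade = CascadingBloomFilter(bp, params.c)
    counter = _DistinctCounter()
    total = 0
    for chunk in _read_chunks(_iter_reads(reads_source), params.chunk_bases):
        canon, _ = _chunk_windows(chunk, params.k)
        cascade.insert_batch(canon)
        counter.add(canon)
        total += canon.size
    return cascade, counter.count(), total, mem_bits


def load_pass(reads, params: AssemblyParams):
    """Load all read k-mers into a cascading Bloom filter.

    Returns ``(cascade, distinct)`` where ``distinct`` is the exact
    number of distinct canonical k-mers seen (used for FPR reporting and
    automatic sizing).
    """
    cascade, distinct, _, _ = _load(reads, params)
    return cascade, distinct


def is_solid_read(read, solid_filter, k: int) -> bool:
    """True iff the read has >= 1 k-mer and every k-mer of every ACGT run
    is in the solid filter."""
    seq = read.sequence if isinstance(read, ReadRecord) else str(read)
    nwin = 0
    for _, codes in _split_acgt(seq):
        if codes.size < k:
            continue
        canon = canonical_window_hashes(codes, k)
        nwin += canon.size
        if not solid_filter.contains_batch(canon).all():
            return False
    return nwin > 0


def _seed_windows(codes: np.ndarray, graph: ProbabilisticDBG):
    """Branch-free window spans of one ACGT run, after look-ahead pruning.

    Raw successor/predecessor degrees of every junction are computed
    vectorised from the rolling window hashes; only junctions with raw
    degree >= 2 are resolved with (memoised) look-ahead walks.  The run
    is cut at true forks on either strand.  Where the read itself
    follows a branch that look-ahead classifies as false — a dead-end
    tip of recurrent-error or false-positive k-mers — the offending head
    or tail of the read is trimmed rather than seeded: its k-mers lie on
    a branch the traversal would ignore, so seeding them would re-walk
    and duplicate the surrounding unitig.

    Returns a list of inclusive window spans ``(a, b)``.
    """
    k = graph.k
    n = codes.size - k + 1
    if n <= 0:
        return []
    if n == 1:
        return [(0, 0)]
    fwd, rc = window_hashes(codes, k)
    rot_f, rot_rc = _rot_tables(k)

    out_base = codes[k:]  # last base of window w+1, w = 0..n-2
    fs = fwd[1:] ^ _SEED_ARR[out_base]
    rs = rc[1:] ^ rot_rc[out_base]
    succ_present = np.empty((4, n - 1), dtype=bool)
    for b in range(4):
        cand = np.minimum(fs ^ _SEED_ARR[b], rs ^ rot_rc[b])
        succ_present[b] = graph.solid.contains_batch(cand)
    outdeg = succ_present.sum(axis=0)

    in_base = codes[: n - 1]  # first base of window w, predecessors of w+1
    fp = fwd[:-1] ^ rot_f[in_base]
    rp = rc[:-1] ^ _SEED_RC_ARR[in_base]
    pred_present = np.empty((4, n - 1), dtype=bool)
    for b in range(4):
        cand = np.minimum(fp ^ rot_f[b], rp ^ _SEED_RC_ARR[b])
        pred_present[b] = graph.solid.contains_batch(cand)
    indeg = pred_present.sum(axis=0)

    def node_at(j):
        return Kmer(
            tuple(int(x) for x in codes[j : j + k]), int(fwd[j]), int(rc[j])
        )

    spans = []
    a = 0
    for j in np.nonzero((outdeg >= 2) | (indeg >= 2))[0]:
        j = int(j)
        out_surv = in_surv = None
        if outdeg[j] >= 2:
            out_surv = graph.surviving_successor_bases(node_at(j))
        if indeg[j] >= 2:
            # surviving predecessors of window j+1, as prepended base codes
            rc_surv = graph.surviving_successor_bases(node_at(j + 1).revcomp())
            in_surv = tuple(3 - b for b in rc_surv)
        tail_false = out_surv is not None and len(out_surv) < 2 \
            and int(codes[j + k]) not in out_surv
        head_false = in_surv is not None and len(in_surv) < 2 \
            and int(codes[j]) not in in_surv
        if tail_false:
            if not head_false and j >= a:
                spans.append((a, j))
            return spans  # remainder of the run lies on a false branch
        if head_false:
            a = j + 1  # head up to j lies on a false branch: drop it
        elif (out_surv is not None and len(out_surv) >= 2) or (
            in_surv is not None and len(in_surv) >= 2
        ):
            spans.append((a, j))  # true fork: cut, keep both sides
            a = j + 1
    spans.append((a, n - 1))
    return spans


def split_at_branches(read, graph: ProbabilisticDBG):
    """Split a solid read into branch-free seed segments.

    The read's walk through the graph is cut wherever a k-mer has two or
    more surviving successors, or the following k-mer has two or more
    surviving predecessors; N characters also split the read, and read
    ends that follow look-ahead-pruned false branches are trimmed.
    Segments overlap by k-1 bases at each cut so their k-mer walks tile
    the retained part of the read.
    """
    k = graph.k
    rid = read.id if isinstance(read, ReadRecord) else "seed"
    seq = read.sequence if isinstance(read, ReadRecord) else str(read)
    segments = []
    for off, codes in _split_acgt(seq):
        if codes.size < k:
            continue
        for a, b in _seed_windows(codes, graph):
            segments.append(
                SeedSegment(
                    sequence=_h.decode(codes[a : b + k]),
                    source_read=rid,
                    span=(off + a, off + b + k),
                )
            )
    return segments


def _extend_direction(state: Kmer, graph: ProbabilisticDBG, max_steps):
    """Greedy extension in the direction of ``state``; returns appended codes."""
    appended = []
    start_canon = state.canonical
    while True:
        cands = graph.successors(state)
        if not cands:
            break
        if len(cands) == 1:
            b, nxt = cands[0]
        else:
            survivors = graph.surviving_successor_bases(state, cands)
            if len(survivors) != 1:
                break  # dead end after pruning, or a true fork: halt
            b = survivors[0]
            nxt = state.extend_right(b)
        # incoming-branch rule: halt if the accepted successor has >= 2
        # surviving predecessors (it starts a different unitig)
        back_node = nxt.revcomp()
        back = graph.successors(back_node)
        if len(back) >= 2:
            if len(graph.surviving_successor_bases(back_node, back)) >= 2:
                break
        state = nxt
        appended.append(b)
        if state.canonical == start_canon:
            break  # closed a cycle
        if max_steps is not None and len(appended) >= max_steps:
            break
    return appended


def extend_seed(seg: SeedSegment, graph: ProbabilisticDBG, tracking: BloomFilter,
                min_unitig_len: int | None = None, uid: int = 0,
                max_steps: int | None = None):
    """Extend a seed segment into a unitig, or skip it.

    If every k-mer of the segment is already in the tracking filter the
    segment is skipped (a previous unitig covered it).  Otherwise the
    segment is extended right from its last k-mer and left from its
    first (via the reverse complement), all k-mers of the result are
    inserted into the tracking filter, and the unitig is returned if it
    reaches ``min_unitig_len`` (default k).
    """
    k = graph.k
    codes = _h.encode(seg.sequence)
    canon = canonical_window_hashes(codes, k)
    if tracking.contains_batch(canon).all():
        return None
    fwd, rc = window_hashes(codes, k)
    last = Kmer(tuple(int(x) for x in codes[-k:]), int(fwd[-1]), int(rc[-1]))
    right = _extend_direction(last, graph, max_steps)
    first = Kmer(tuple(int(x) for x in codes[:k]), int(fwd[0]), int(rc[0]))
    left = _extend_direction(first.revcomp(), graph, max_steps)
    left_codes = [3 - b for b in reversed(left)]
    full = np.concatenate(
        [
            np.asarray(left_codes, dtype=np.uint8),
            codes,
            np.asarray(right, dtype=np.uint8),
        ]
    )
    tracking.insert_batch(canonical_window_hashes(full, k))
    min_len = min_unitig_len if min_unitig_len is not None else k
    if full.size < min_len:
        return None
    return Unitig(id=uid, sequence=_h.decode(full), seed_id=seg.source_read)


def assemble(reads, params: AssemblyParams):
    """Run the full two-pass unitig assembly.

    ``reads`` may be a FASTA/FASTQ path, a list of ReadRecords or
    strings, or a zero-argument callable returning an iterable (the
    source is iterated once per pass).  Returns ``(unitigs, report)``.
    """
    cascade, distinct, total_kmers, mem_bits = _load(reads, params)
    solid = cascade.retain_last()
    tracking = BloomFilter(BloomParams(m=mem_bits, h=params.h, seed=params.seed))
    graph = ProbabilisticDBG(solid, params.k, lookahead=params.lookahead_depth)

    report = AssemblyReport(
        k=params.k,
        c=params.c,
        h=params.h,
        per_level_bits=mem_bits,
        allocated_bits=total_memory(mem_bits, params.c),
        distinct_kmers=distinct,
        total_kmers=total_kmers,
        fpr_percent=100.0 * fpr_analytic(mem_bits, params.h, distinct),
        solid_fpr_percent=100.0 * solid.fpr,
    )

    unitigs = []
    for chunk in _read_chunks(_iter_reads(reads), params.chunk_bases):
        canon, read_nwin = _chunk_windows(chunk, params.k)
        report.n_reads += len(chunk)
        if canon.size == 0:
            continue
        solid_w = solid.contains_batch(canon)
        tracked_w = tracking.contains_batch(canon)
        has_win = read_nwin > 0
        win_starts = (np.cumsum(read_nwin) - read_nwin)[has_win]
        bad = np.add.reduceat((~solid_w).astype(np.int64), win_starts) \
            if win_starts.size else np.empty(0, dtype=np.int64)
        fresh = np.add.reduceat((~tracked_w).astype(np.int64), win_starts) \
            if win_starts.size else np.empty(0, dtype=np.int64)
        read_ids = np.nonzero(has_win)[0]
        is_solid = bad == 0
        report.n_solid_reads += int(is_solid.sum())
        win_start_all = np.cumsum(read_nwin) - read_nwin
        for ridx in read_ids[is_solid & (fresh > 0)]:
            ridx = int(ridx)
            # the chunk-level novelty check is stale by the time earlier
            # reads of the chunk have been extended: recheck live
            lo = int(win_start_all[ridx])
            rw = canon[lo : lo + int(read_nwin[ridx])]
            if tracking.contains_batch(rw).all():
                continue
            rec = chunk[ridx]
            for seg in split_at_branches(rec, graph):
                u = extend_seed(
                    seg,
                    graph,
                    tracking,
                    min_unitig_len=params.min_len,
                    uid=len(unitigs),
                    max_steps=params.max_steps,
                )
                if u is not None:
                    unitigs.append(u)

    lengths = [u.length for u in unitigs]
    report.unitig_count = len(unitigs)
    report.total_bases = sum(lengths)
    report.n50 = _n50(lengths)
    report.traversal_steps = graph.steps
    return unitigs, report


def _n50(lengths):
    if not lengths:
        return 0
    arr = sorted(lengths, reverse=True)
    half = sum(arr) / 2
    acc = 0
    for length in arr:
        acc += length
        if acc >= half:
            return length
    return 0
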