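"""Probabilistic de Bruijn graph over a solid-k-mer filter.

Only nodes (canonical k-mers) are stored; edges are discovered at query
time by testing the four single-base extensions of the current k-mer
against the backing filter.  Because the filter may return false
positives, traversal uses a bounded *look-ahead*: at a branching point
each candidate extension is explored up to ``depth`` nodes (default k),
and a branch whose every path dead-ends within ``depth`` nodes is
classified as a false branch and ignored.  A branch point with two or
more surviving extensions is a true fork and halts unitig extension.

The backing set only needs ``contains``/``contains_batch``; a
:class:`~bloomtig.bloom.BloomFilter`, the last level of a cascading
filter, or an exact hash set all work.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .hashing import BASES, Kmer

__all__ = ["BranchCall", "ProbabilisticDBG"]


@dataclass(frozen=True)
class BranchCall:
    """Classification of a node's outgoing extensions after look-ahead.

    kinds: ``dead_end`` (no extensions found), ``unique`` (exactly one
    surviving extension), ``false_branch_pruned`` (extensions existed but
    every one was a short false branch), ``true_branch`` (>= 2 surviving
    extensions; traversal must halt).
    """

    kind: str
    surviving_extensions: tuple


class ProbabilisticDBG:
    """De Bruijn graph with filter-backed membership and look-ahead.

    ``steps`` counts node visits (successor-query batches), including
    those spent inside look-ahead walks; it is the traversal-cost metric
    reported by the assembler.
    """

    def __init__(self, solid, k: int, lookahead: int | None = None,
                 lookahead_budget: int | None = None):
        if lookahead is not None and lookahead < 1:
            raise ValueError(f"lookahead depth must be >= 1, got {lookahead}")
        self.solid = solid
        self.k = k
        self.depth = lookahead if lookahead is not None else k
        # node budget per look-ahead walk; exhausting it (dense false-
        # positive neighbourhoods, cycles) conservatively counts as survival
        self.budget = lookahead_budget if lookahead_budget is not None else 16 * self.depth
        self.steps = 0
        self._surv_cache: dict = {}

    def successors(self, x: Kmer) -> list:
        """Bases b whose single-base right-extension of x is in the filter.

        Returns ``[(b, successor_kmer), ...]`` with b a code 0..3.
        """
        self.steps += 1
        out = []
        contains = self.solid.contains
        for b in range(4):
            nxt = x.extend_right(b)
            if contains(nxt.canonical):
                out.append((b, nxt))
        return out

    def predecessors(self, x: Kmer) -> list:
        """Predecessor k-mers, via a successor query on the reverse complement."""
        rc = x.revcomp()
        return [(3 - b, s.revcomp()) for b, s in self.successors(rc)]

    def branch_survives(self, cand: Kmer, depth: int | None = None) -> bool:
        """True iff some path from ``cand`` extends beyond ``depth`` nodes.

        Bounded breadth-first walk by generation; ``cand`` itself counts
        as node 1, so a branch of length <= depth (a dead-end tip) does
        not survive.  Frontiers are deduplicated by canonical hash, and
        each membership probe of a generation is one batched filter
        query.  Exhausting the node budget (dense false-positive
        neighbourhoods, short cycles) conservatively counts as survival.
        """
        depth = self.depth if depth is None else depth
        frontier = [cand]
        visited = 0
        for _ in range(depth):
            visited += len(frontier)
            if visited > self.budget:
                return True
            self.steps += len(frontier)
            cands = []
            for node in frontier:
                for b in range(4):
                    cands.append(node.extend_right(b))
            present = self.solid.contains_batch(
                np.fromiter((c.canonical for c in cands), dtype=np.uint64,
                            count=len(cands))
            )
            nxt = {}
            for c, ok in zip(cands, present):
                if ok:
                    nxt.setdefault(c.canonical, c)
            if not nxt:
                return False
            frontier = list(nxt.values())
        return True

    def surviving_successor_bases(self, x: Kmer, cands=None) -> tuple:
        """Base codes of the extensions of ``x`` surviving look-ahead.

        With a single present candidate, look-ahead is skipped (a unique
        continuation is followed as-is).  Results for branching nodes are
        memoised per forward-strand hash: the same junction is consulted
        by every read that crosses it.
        """
        if cands is None:
            cached = self._surv_cache.get(x.fwd)
            if cached is not None:
                return cached
            cands = self.successors(x)
        if len(cands) <= 1:
            return tuple(b for b, _ in cands)
        cached = self._surv_cache.get(x.fwd)
        if cached is not None:
            return cached
        surviving = tuple(b for b, s in cands if self.branch_survives(s))
        self._surv_cache[x.fwd] = surviving
        return surviving

    def lookahead_classify(self, x: Kmer, depth: int | None = None) -> BranchCall:
        """Classify the outgoing extensions of ``x`` after false-branch pruning.

        A single candidate is accepted without look-ahead (a unique
        continuation is followed as-is); with two or more candidates each
        is kept only if its branch survives the look-ahead walk.
        """
        cands = self.successors(x)
        if not cands:
            return BranchCall("dead_end", ())
        if len(cands) == 1:
            return BranchCall("unique", (BASES[cands[0][0]],))
        surviving = tuple(
            BASES[b] for b, s in cands if self.branch_survives(s, depth)
        )
        if not surviving:
            return BranchCall("false_branch_pruned", ())
        if len(surviving) == 1:
            return BranchCall("unique", surviving)
        return BranchCall("true_branch", surviving)
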