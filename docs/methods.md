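# Methods

## The model

`bloomtig` implements the unitig stage of a Bloom-filter de Bruijn graph
assembler for short sequencing reads.  The de Bruijn graph at word size
k is never materialised: only its nodes — canonical k-mers, a k-mer and
its reverse complement treated as one entity — are stored, in a Bloom
filter, and edges are discovered at traversal time by querying the four
possible single-base extensions of the current k-mer.  A Bloom filter of
m bits with h hash functions holding n distinct keys answers membership
with no false negatives and a false-positive rate

    FPR = (1 − (1 − 1/m)^(h·n))^h  ≈  (1 − e^(−h·n/m))^h ,

so the graph seen by the traversal is the true graph plus a sprinkling
of phantom nodes whose density is set by the memory budget.

Assembly makes two passes over the reads.

**Pass 1 — cascading occurrence filter.**  Every k-mer of every read is
inserted into a chain of c equal-sized Bloom filters: a key goes into
the first filter that does not already contain it, so filter i holds
keys seen at least i times.  The last filter — keys with occurrence
count ≥ c — is kept as the *solid* k-mer set and the earlier levels are
freed.  Because most sequencing errors produce k-mers seen once or
twice, thresholds c in 2–4 remove the bulk of error nodes.  All levels
reuse the same hash values for a key, as does the tracking filter below;
total filter memory is exactly (c+1)·m bits.

**Pass 2 — solid-read seeding and extension.**  A read whose k-mers are
all solid (a *solid read*) is the unit of seeding.  It is split at
branch points of the graph, and each branch-free segment that still
contains a k-mer not yet recorded in the *tracking* Bloom filter is
extended left and right, one base at a time, until a dead end or a true
fork.  All k-mers of the emitted unitig are then added to the tracking
filter, so later reads from the same neighbourhood are skipped and the
output carries no wholesale duplicates.  Reads are processed in input
order; with fixed parameters and seed the output is byte-identical
across runs.

**Look-ahead.**  Bloom false positives and recurrent errors attach short
spurious branches to real paths.  At every branching point the traversal
explores each candidate branch up to `lookahead` nodes (default k) with
a breadth-first walk; a branch whose every path dead-ends within that
distance is a false branch and is ignored.  If two or more branches
survive, the fork is real and extension halts.  Extension also halts
when the next node has two or more surviving predecessors (standard
unitig semantics; it keeps unitig boundaries independent of which seed
reaches a junction first).  A unique candidate is followed without
look-ahead — otherwise genuine terminal k-mers near sequence ends would
be pruned.

The breadth-first walk carries a node budget (16·depth); exhausting it —
dense false-positive neighbourhoods, short cycles such as homopolymer
self-loops — conservatively counts as survival.  An earlier greedy
one-level variant was rejected: it lets a false branch inherit survival
from nested false-positive forks, which at operating FPRs of 5–10%
misclassifies essentially every false branch as real.  For a false
branch, survival under the BFS requires an unbroken chain of depth
phantom nodes, with probability roughly (4·FPR)^depth — vanishing below
~15% FPR and appreciable above ~20%, which is exactly the contiguity
cliff the memory sweep shows.

**Seed trimming.**  When the read being split itself walks onto a branch
that look-ahead classifies as false — the signature of a recurrent error
within k bases of a read end, which builds a solid dead-end tip — the
offending head or tail of the read is trimmed rather than seeded.  Such
tips can never be covered by the tracking filter (no unitig contains
them), so without trimming every read carrying one would pass the
novelty check and re-extend, duplicating the surrounding unitig
wholesale; on a 50 kb test instance this produced five genomes' worth of
output.  Trimmed stretches are at most `lookahead` windows long by
construction (a longer read continuation would have survived).

## Parameters

| parameter | default | meaning |
|---|---|---|
| k | (required) | k-mer size, bases; odd values avoid self-reverse-complement k-mers |
| c (`--kc`) | 3 | minimum k-mer occurrence = cascade depth; useful range 2–4 |
| mem_bits (`-b`) | auto | per-level filter size in bits; fixed budget mode |
| target_fpr (`--fpr`) | 0.05 | sizing target when mem_bits is absent, applied to an exact distinct-k-mer count from a presampling pass; 5–10% balances memory and run time |
| h (`-H`) | 4 | hash functions per filter |
| lookahead | k | branch look-ahead depth in nodes |
| min_unitig_len | k | shortest unitig emitted; below this an output is a bare seed fragment |
| seed | 0 | hash seed; with identical inputs makes runs bit-identical |

Filter sizes are byte-granular; bit positions are `hash mod m`; the four
per-base 64-bit constants of the rolling hash are committed in source so
hashes are identical across platforms and sessions.

## Hashing

The k-mer hash is a cyclic-polynomial (rotate–xor) combination of fixed
per-base constants, rolled in O(1) per base for both strands at once;
the canonical value is min(forward, reverse-complement) hash, which
preserves the rolling property and strand symmetry.  Additional filter
hashes derive from the canonical value by a splitmix64-style schedule
(stream 0 is the value itself), so h probes never rehash the sequence.
The bulk passes evaluate the same recurrences in closed form over numpy
arrays (prefix-xor of position-rotated constants); scalar and vectorised
paths are cross-checked in the tests, and the exact polynomial is frozen
by golden-value tests.

## Synthetic data and what it does (not) show

`simdata` emulates the shape of the experimental setups the method
targets: uniform random genomes; single-end 100 bp reads at 75-fold
coverage drawn uniformly from both strands; i.i.d. substitution errors
at 0.5% (no indels — substitutions are the dominant short-read error
mode and the one the cascade is designed to remove); optional planted
exact repeats to create true forks.  Deterministic given the config.

What it does not emulate: coverage bias, quality-correlated and
position-dependent error rates, indels, adapter artefacts, polyploidy or
heterozygosity, and genuine genomic repeat structure beyond planted
units.  Passing tests therefore demonstrate the correctness of the data
structures and traversal semantics under controlled conditions, not
assembly quality on real libraries.  Uniform random read starts rarely
cover the first and last k-mers of a genome at depth ≥ c, so exact
whole-genome reconstruction tests use systematically tiling reads.

The reference assembler `exact_unitigs` re-implements the complete
pipeline semantics — solid reads in input order, splitting with
trimming, the same look-ahead walk and budget accounting, tracking-set
deduplication — over a plain hash table of canonical k-mer *strings*
with exact counts.  It shares no code or data structures with the Bloom
path (string slicing vs rolling hashes, Python sets vs bit vectors, per
read loops vs vectorised batches), so multiset equality of canonical
unitig sequences at negligible FPR is a stringent end-to-end check of
the probabilistic stack.

## Numerical and degenerate-input choices

- Sizing inverts the exact FPR form by bisection on byte-granular m;
  n = 0 sizes to the 8-bit minimum.
- Cascade insertion is batched per chunk of reads: within-batch
  multiplicities are honoured exactly (a key occurring t times deepens
  its membership by t levels against the occupancy at batch start), so
  batch and one-at-a-time insertion set identical bits at identical
  counts; they can differ only through false-positive bit collisions
  inside one chunk.  Chunk size is a fixed default, keeping runs
  deterministic.
- Reads are split at non-ACGT characters before k-mer extraction; runs
  shorter than k contribute nothing; case is folded.
- A read shorter than k is never solid; an empty input yields an empty
  assembly and an all-zero report.
- Extension carries a cycle guard (stop on returning to the walk's
  start k-mer) so circular sequences terminate; plasmid-style circles
  are otherwise out of scope.
- Tracking-filter false positives can suppress a genuine unitig whose
  seed's novel k-mers all collide; accepted, as the tracking filter is
  sized like a cascade level and the probability falls with its FPR.

## Test-tier problem sizes

The committed verification suite runs at desk scale: oracle equivalence
on twenty seeded instances of 5–50 kb at 30–75× and 0–1% errors with
filters sized at target FPR 1e-4 (comfortably inside the ≤ 0.1% regime
where false-positive-induced output differences are improbable across
the whole suite); whole-genome reconstruction at 4 kb for k in
{15, 21, 31}; and the memory-sweep experiment on a 100 kb genome at
75× / 0.5% errors with a four-point filter ladder spanning ~1–20%
solid-filter FPR.  `scripts/fpr_sweep.py` runs the same experiment at
its full 1 Mb default for standalone use (tens of minutes on one core).

## Known limitations

- Contiguity begins to erode slightly below 10% FPR on *uncorrected*
  reads: an error bubble whose weakest k-mer has count c−1 is promoted
  into the solid set with probability about the solid-level FPR,
  creating a real fork.  Error-corrected libraries (the intended
  upstream for production use) have almost no such borderline sites.
  At 20% FPR and beyond, surviving false branches halt extension
  frequently and NG50 collapses — the expected failure mode.
- Paired-end contig building, scaffolding, gap filling, and read
  correction are upstream/downstream stages and out of scope.
- The level-1 Eq.-1 FPR reported for heavily error-laden inputs can be
  large even when the solid level (the graph actually traversed) is
  nearly clean; the report prints both.
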