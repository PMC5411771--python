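#!/usr/bin/env python
"""Memory-sweep experiment: assembly quality and cost vs Bloom filter size.

Assembles one simulated data set at a series of fixed per-level filter
allocations and tabulates the realised solid-filter FPR, NG50, unitig
count, and traversal step count per point — the FPR is controlled
indirectly through the allocation, as in a real memory-budgeted run.

The full-size benchmark (1 Mb genome, 75x coverage, 0.5% errors, k=31,
c=3) takes tens of minutes on one core; pass a smaller --genome-length
for a quick look.

Usage:  python scripts/fpr_sweep.py --seed 42 --out sweep.tsv
"""

from __future__ import annotations

import argparse
import sys
from pathlib import Path

from bloomtig.simdata import SimConfig, fpr_sweep


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=42)
    ap.add_argument("--genome-length", type=int, default=1_000_000)
    ap.add_argument("--coverage", type=float, default=75.0)
    ap.add_argument("--error-rate", type=float, default=0.005)
    ap.add_argument("-k", type=int, default=31)
    ap.add_argument("--kc", type=int, default=3)
    ap.add_argument(
        "--bits",
        type=int,
        nargs="+",
        default=None,
        help="Per-level filter sizes in bits (default: a 5-point ladder "
        "scaled to the genome length).",
    )
    ap.add_argument("--out", type=Path, default=None, help="TSV output path.")
    args = ap.parse_args()

    bits = args.bits
    if bits is None:
        # ladder spanning roughly 1%..20% solid-filter FPR at 75x / 0.5% errors
        scale = args.genome_length / 100_000
        bits = [int(b * scale) for b in (1_000_000, 700_000, 540_000, 410_000)]

    cfg = SimConfig(
        genome_length=args.genome_length,
        read_length=100,
        coverage=args.coverage,
        error_rate=args.error_rate,
        seed=args.seed,
    )
    points = fpr_sweep(cfg, bits, k=args.k, c=args.kc)

    cols = ["per_level_bits", "fpr_percent", "level1_fpr_percent",
            "unitigs", "n50", "ng50", "traversal_steps"]
    lines = ["\t".join(cols)]
    for p in points:
        lines.append("\t".join(str(p[c]) for c in cols))
    table = "\n".join(lines) + "\n"
    if args.out:
        args.out.write_text(table)
    sys.stdout.write(table)


if __name__ == "__main__":
    main()
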