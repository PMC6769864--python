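#!/usr/bin/env python
"""Sliding-window nucleotide diversity along the mitogenome.

Scans the composite cohort with 200-np windows (25-np step) and reports the
peak window, which should fall in the hypervariable control region
(D-loop, np 15909-16315) of the simulated frame.
"""

import argparse
from pathlib import Path

from mitolineage import (build_site_index, default_motif_table, diversity_scan,
                         generate_cohort, yunling_composition)

ROOT = Path(__file__).resolve().parents[1]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--window", type=int, default=200)
    ap.add_argument("--step", type=int, default=25)
    args = ap.parse_args()

    table = default_motif_table()
    aln, truth = generate_cohort(yunling_composition(seed=args.seed), table)
    prof = diversity_scan(aln, build_site_index(aln), args.window, args.step)

    res = ROOT / "results"
    res.mkdir(exist_ok=True)
    prof.to_tsv(res / "diversity_profile.tsv")
    peak = prof.peak()
    lo, hi = truth.hotspot
    inside = lo <= (peak.start_np + peak.end_np) / 2 <= hi
    print(f"peak Pi = {peak.Pi:.4f} in window np {int(peak.start_np)}-{int(peak.end_np)}")
    print(f"planted hotspot: np {lo}-{hi}; peak inside: {inside}")
    print(f"wrote {res / 'diversity_profile.tsv'}")


if __name__ == "__main__":
    main()
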