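#!/usr/bin/env python
"""Score the library: frequencies, read filter, per-variant log2 enrichment.

Reads the simulated count table, filters to >=5 input / >=1 output reads (no
pseudocounts), computes Enr = log2(f_post/f_pre) with frequencies fixed
before filtering, and reports the AU-content correlation.
"""

import argparse
from pathlib import Path

from utrselect import au_correlation, normalize_scores, score_library
from utrselect.io import read_counts, write_scores

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--results", type=Path, default=Path("results"))
args = parser.parse_args()

counts = read_counts(args.results / "simulation" / "counts.tsv")
variants = score_library(counts)
write_scores(args.results / "scores.tsv", variants)

ns = normalize_scores(variants["enr"].to_numpy())
print(f"{len(counts)} variants in, {len(variants)} pass the read filter")
print(f"library mean Enr {variants.enr.mean():.3f} "
      f"(sd {variants.enr.std():.3f}, min {ns.enr_min:.3f})")
print(f"AU content vs Enr: Pearson r = {au_correlation(variants):.3f}")
print(f"wrote {args.results}/scores.tsv")
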