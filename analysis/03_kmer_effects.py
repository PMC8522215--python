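#!/usr/bin/env python
"""Exhaustive k-mer effect tables: mean Enr of containing vs lacking groups.

For each requested k, tabulates every k-mer's containing/lacking group means
with s.e.m. and rank, and prints the extremes — the planted efficiency
element and its overlap-mers should top the ranking, G-rich k-mers sink it.
"""

import argparse
from pathlib import Path

import pandas as pd

from utrselect import kmer_summary
from utrselect.io import read_counts
from utrselect.enrichment import score_library

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--results", type=Path, default=Path("results"))
parser.add_argument("--k", type=int, action="append", default=None)
args = parser.parse_args()
k_list = args.k or [6]

variants = score_library(read_counts(args.results / "simulation" / "counts.tsv"))
for k in k_list:
    tab = kmer_summary(variants, k)
    out = args.results / f"kmers_k{k}.tsv"
    tab.to_csv(out, sep="\t", index=False)
    ranked = tab.sort_values("rank")
    print(f"k={k}: mean carriers per k-mer {tab.n_with.mean():.0f} "
          f"(sd {tab.n_with.std():.0f}, min {tab.n_with.min()})")
    print("top ranks:")
    print(ranked.head(5)[["kmer", "rank", "n_with", "mean_with", "sem_with"]]
          .to_string(index=False))
    print("bottom ranks:")
    print(ranked.tail(3)[["kmer", "rank", "n_with", "mean_with", "sem_with"]]
          .to_string(index=False))
    print(f"wrote {out}")
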