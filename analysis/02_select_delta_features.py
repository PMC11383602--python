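#!/usr/bin/env python
"""Delta features and the two-stage filter (segmentation ICC, redundancy).

Reads the four feature tables from step 01, forms post - pre delta values,
drops features unstable against the alternative segmentation (ICC < 0.75)
and prunes redundant ones (pairwise Spearman |rho| >= 0.85), then writes
the filtered delta table and a per-feature retention report.
"""

import argparse
from pathlib import Path

import pandas as pd

from deltarad.selection import delta_table, select_features, spearman_abs_max


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()

    read = lambda n: pd.read_csv(args.results / f"{n}.tsv", sep="\t", index_col=0)
    pre, post = read("features_pre"), read("features_post")
    pre_alt, post_alt = read("features_pre_altseg"), read("features_post_altseg")

    raw_delta = delta_table(pre, post)
    seg_a = pd.concat([pre, post], keys=["pre", "post"])
    seg_b = pd.concat([pre_alt, post_alt], keys=["pre", "post"])
    delta, report = select_features(raw_delta, seg_a, seg_b)

    counts = report["reason"].value_counts()
    print(f"delta features: {raw_delta.shape[1]} total -> {delta.shape[1]} retained")
    print(f"  dropped for segmentation instability (ICC < 0.75): {counts.get('icc_fail', 0)}")
    print(f"  pruned as redundant (|rho| >= 0.85):               {counts.get('corr_pruned', 0)}")
    print(f"  max residual pairwise |Spearman rho|: {spearman_abs_max(delta):.4f}")

    delta.to_csv(args.results / "delta_features.tsv", sep="\t", float_format="%.10g")
    report.to_csv(args.results / "retention_report.tsv", sep="\t")


if __name__ == "__main__":
    main()
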