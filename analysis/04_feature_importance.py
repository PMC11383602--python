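#!/usr/bin/env python
"""Univariate importance of each delta feature for the cluster split.

Scores every filtered delta feature by its symmetrized two-class ROC area
against the cluster labels from step 03 and retains the response-defining
subset (classification score >= 0.9).
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from deltarad.importance import auc_importance


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()

    delta = pd.read_csv(args.results / "delta_features.tsv", sep="\t", index_col=0)
    labels = json.loads((args.results / "cluster_report.json").read_text())["labels"]

    res = auc_importance(delta, pd.Series(labels), threshold=0.9)
    retained = res[res["retained"]].sort_values("score", ascending=False)
    print(f"response-defining features (score >= 0.9): {len(retained)} of {len(res)}")
    print(retained.head(10).to_string(float_format=lambda v: f"{v:.3f}"))

    res.to_csv(args.results / "importance.tsv", sep="\t", float_format="%.6g")


if __name__ == "__main__":
    main()
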