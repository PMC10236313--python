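#!/usr/bin/env python
"""Binding-site occupancy and promoter methylation dynamics across
stimulation: colocalization fractions before/after, bound-enhancer
fractions by activity class, and the promoter H3K9me2 post/pre ratios
for inducible versus control genes.

Writes results/tables/occupancy_summary.tsv and me2_dynamics.tsv.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--fixture", type=Path, default=ROOT / "results" / "fixture")
    parser.add_argument("--run", type=Path, default=ROOT / "results" / "run")
    args = parser.parse_args()

    out_dir = ROOT / "results" / "tables"
    out_dir.mkdir(parents=True, exist_ok=True)
    summary = json.loads((args.run / "summary.json").read_text())

    coloc = pd.read_csv(args.run / "colocalization.tsv", sep="\t")
    coloc.to_csv(out_dir / "occupancy_summary.tsv", sep="\t", index=False)
    print("factor-site colocalization (% of sites):")
    print(coloc.to_string(index=False))
    pre = coloc.query("scope == 'all' and condition == 'unstim'").iloc[0]
    post = coloc.query("scope == 'all' and condition == 'stim'").iloc[0]
    print(f"\npromoter overlap rises from {pre.promoter:.0f}% to "
          f"{post.promoter:.0f}% with stimulation (enhancer overlap "
          f"{pre.enhancer:.0f}% -> {post.enhancer:.0f}%)")
    bf = summary["bound_fractions"]
    print(f"bound enhancers overall: {100 * bf['overall']:.1f}% "
          f"(active {100 * bf['active']:.0f}%, "
          f"intermediate {100 * bf['intermediate']:.0f}%, "
          f"poised {100 * bf['poised']:.0f}%)")

    truth = pd.read_csv(args.fixture / "truth.tsv", sep="\t")
    gene_sets = truth[truth.kind == "gene"][["feature_id", "me2_set"]]
    frames = []
    for cond in ("unstim", "stim"):
        df = pd.read_csv(args.run / f"promoter_signal_{cond}.tsv", sep="\t")
        frames.append(df.set_index("gene").ratio.rename(cond))
    ratios = pd.concat(frames, axis=1).join(
        gene_sets.set_index("feature_id")).dropna(subset=["me2_set"])
    ratios = ratios[ratios.me2_set != ""]
    ratios["post_pre"] = ratios.stim / ratios.unstim
    ratios.to_csv(out_dir / "me2_dynamics.tsv", sep="\t")
    means = ratios.groupby("me2_set").post_pre.mean()
    print("\npromoter H3K9me2 (input-normalized) post/pre stimulation:")
    print(means.to_string())
    print("(planted: 2-fold loss at inducible promoters, none at random)")


if __name__ == "__main__":
    main()
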