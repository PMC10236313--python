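#!/usr/bin/env python
"""Compare enhancer qualification and eRNA filtering against the planted
ground truth: every decoy should be rejected (or excluded) for exactly
the reason it was built to violate.

Writes results/tables/enhancer_recovery.tsv and erna_recovery.tsv.
"""

import argparse
from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--fixture", type=Path, default=ROOT / "results" / "fixture")
    parser.add_argument("--run", type=Path, default=ROOT / "results" / "run")
    args = parser.parse_args()

    truth = pd.read_csv(args.fixture / "truth.tsv", sep="\t")
    enh_truth = truth[truth.kind == "enhancer"].copy()
    enh_truth["id"] = (enh_truth.chrom + ":" + enh_truth.start.astype(str)
                       + "-" + enh_truth.end.astype(str))
    calls = pd.read_csv(args.run / "enhancer_calls.tsv", sep="\t")
    merged = enh_truth.merge(calls, on="id", suffixes=("_truth", ""))

    merged["qualification_correct"] = (
        merged.qualified == merged.expected_qualified
    ) & (
        merged.expected_qualified
        | (merged.rejection_reasons.fillna("") == merged.expected_rejection)
    )
    out_dir = ROOT / "results" / "tables"
    out_dir.mkdir(parents=True, exist_ok=True)
    cols = ["id", "subkind", "expected_qualified", "qualified",
            "expected_rejection", "rejection_reasons", "expected_location",
            "location_class", "qualification_correct"]
    merged[cols].to_csv(out_dir / "enhancer_recovery.tsv", sep="\t", index=False)
    n_ok = merged.qualification_correct.sum()
    print(f"qualification: {n_ok}/{len(merged)} peaks match the manifest")
    by_reason = merged[~merged.expected_qualified.astype(bool)].groupby(
        "expected_rejection").qualification_correct.mean()
    print("decoy classes recovered correctly:")
    print(by_reason.to_string())

    erna = pd.read_csv(args.run / "erna_loci.tsv", sep="\t")
    em = enh_truth[enh_truth.erna_class != "none"].merge(erna, on="id")
    em["filter_correct"] = (
        ((em.erna_class == "true") & em.passed)
        | ((em.erna_class != "true")
           & (em.exclusion_reasons.fillna("") == em.expected_erna_excluded))
    )
    em[["id", "erna_class", "expected_erna_excluded", "passed",
        "exclusion_reasons", "filter_correct"]].to_csv(
        out_dir / "erna_recovery.tsv", sep="\t", index=False)
    print(f"\neRNA filters: {em.filter_correct.sum()}/{len(em)} loci match "
          f"({(em.erna_class == 'true').sum()} true, "
          f"{(em.erna_class != 'true').sum()} decoys)")


if __name__ == "__main__":
    main()
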