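#!/usr/bin/env python
"""Assign species from subgenome coverage and report the confusion matrix."""

import os
import sys

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

import pandas as pd

from brachykit.species_id import CoverageSummary, classify_summaries
from brachykit.synthetic_data import default_subgenome_setup

OUT = os.path.join(os.path.dirname(__file__), "..", "results")


def main() -> None:
    cov = pd.read_csv(f"{OUT}/coverage.tsv", sep="\t")
    truth = pd.read_csv(f"{OUT}/coverage.truth.tsv", sep="\t")
    submap, lengths = default_subgenome_setup()
    summaries = [
        CoverageSummary(
            sample=s,
            covered_fraction=dict(zip(grp["chrom"], grp["covered_fraction"])),
            total_reads=int(grp["total_reads"].iloc[0]),
        )
        for s, grp in cov.groupby("sample")
    ]
    calls = classify_summaries(summaries, submap, lengths)
    calls.to_csv(f"{OUT}/species_calls.tsv", sep="\t", index=False)

    merged = calls.merge(truth, on="sample")
    confusion = pd.crosstab(merged["species"], merged["label"])
    confusion.to_csv(f"{OUT}/species_confusion.tsv", sep="\t")
    accuracy = (merged["label"] == merged["species"]).mean()
    print("confusion matrix (rows = truth, cols = call):")
    print(confusion)
    print(f"label recovery: {accuracy:.3f}")


if __name__ == "__main__":
    main()
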