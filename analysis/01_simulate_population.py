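#!/usr/bin/env python
"""Simulate the study's raw inputs: genotyped panel, GBS coverage profiles,
and the two climate-chamber scenarios.

Writes under results/: the replicated genotype panel (TSV + VCF + truth
labels), a mixed-species coverage panel, and 2015 / 2050 climate series.
"""

import os
import sys

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

import pandas as pd

from brachykit import io
from brachykit.synthetic_data import (
    ClimateSpec,
    PopulationSpec,
    gen_climate,
    gen_coverage,
    gen_genotypes,
)

OUT = os.path.join(os.path.dirname(__file__), "..", "results")
SEED = 2018


def main() -> None:
    os.makedirs(OUT, exist_ok=True)

    # replicated panel: 2 subgroups, clonal families, 18.5% missing calls
    spec = PopulationSpec(
        n_subgroups=2,
        n_families_per_subgroup=5,
        n_accessions_per_family=6,
        n_replicates_per_accession=3,
        within_family_divergence=0.003,
        n_snps=4000,
        missing_rate=0.185,
        seed=SEED,
    )
    panel, truth = gen_genotypes(spec)
    io.write_genotype_tsv(panel, f"{OUT}/panel.genotypes.tsv")
    io.write_vcf(panel, f"{OUT}/panel.genotypes.vcf")
    truth.to_csv(f"{OUT}/panel.truth.tsv", sep="\t", index=False)
    print(f"panel: {panel.n_samples} samples x {panel.n_snps} SNPs "
          f"({truth['accession'].nunique()} accessions)")

    # coverage panel across the species complex
    summaries, cov_truth = gen_coverage(
        [("distachyon", 35), ("stacei", 10), ("hybridum", 45), ("low_coverage", 5)],
        noise_sd=0.03,
        seed=SEED + 1,
    )
    rows = [
        {"sample": s.sample, "chrom": c, "covered_fraction": f, "total_reads": s.total_reads}
        for s in summaries
        for c, f in s.covered_fraction.items()
    ]
    pd.DataFrame(rows).to_csv(f"{OUT}/coverage.tsv", sep="\t", index=False)
    cov_truth.to_csv(f"{OUT}/coverage.truth.tsv", sep="\t", index=False)
    print(f"coverage: {len(summaries)} samples across 4 species classes")

    # climate scenarios: Winter sowing, present vs +2 C future profile
    for name, offset in (("2015", 0.0), ("2050", 2.0)):
        series = gen_climate(ClimateSpec(warming_offset=offset, n_days=200))
        io.write_climate_tsv(series, f"{OUT}/climate_{name}.tsv")
        print(f"climate {name}: {len(series)} records, "
              f"mean {series['temp_C'].mean():.2f} C")


if __name__ == "__main__":
    main()
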