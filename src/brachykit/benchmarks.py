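"""Simulation-calibrated benchmark studies for the pipeline.

Each function regenerates its synthetic inputs from a seed, runs the
relevant pipeline stage, and returns the measured quantity.  They are the
computational backbone of ``scripts/acceptance.py`` and of the end-to-end
tests; problem sizes are desk-scale versions of the study design (74-line
HapMap panel, clonal families, 18.5% missingness).
"""

from __future__ import annotations

import numpy as np

from .gwas_scan import LmmScanner, permutation_threshold, pve_from_lod
from .imputation import ImputationConfig, evaluate_imputation, maf_ladder, prune_redundant
from .pheno_derive import broad_sense_heritability
from .synthetic_data import PhenoSimSpec, PopulationSpec, gen_genotypes, gen_phenotypes

__all__ = [
    "imputation_success",
    "heritability_recovery",
    "pve_recovery",
    "threshold_calibration",
]


def _seeds(seed: int, n: int, stream: int) -> np.ndarray:
    """Independent child seeds (< 2^31) for one benchmark stream."""
    return np.random.SeedSequence(entropy=seed, spawn_key=(stream,)).generate_state(
        n
    ) % (2**31)


def imputation_success(
    seed: int = 0, n_seeds: int = 5, mask_rate: float = 0.185
) -> float:
    """Mean masked-call restoration rate of the two-stage imputer.

    Panel per seed: 100 accessions in 10 clonal families (within-family
    divergence 0.3%), 5,000 SNPs in 50-SNP LD blocks, fully observed; the
    study's missingness rate is applied as the masking rate.  The ladder up
    to the pre-imputation MAF filter runs first; success is measured over
    adjacent fill + NN imputation with unfilled calls counted as failures.
    """
    rates = []
    for s in _seeds(seed, n_seeds, stream=1):
        spec = PopulationSpec(
            n_subgroups=2,
            n_families_per_subgroup=5,
            n_accessions_per_family=10,
            within_family_divergence=0.003,
            n_snps=5000,
            ld_block_size_snps=50,
            missing_rate=0.0,
            seed=int(s),
        )
        matrix, _ = gen_genotypes(spec)
        cfg = ImputationConfig()
        matrix = maf_ladder(prune_redundant(matrix), "pre", cfg)
        rates.append(
            evaluate_imputation(matrix, mask_rate, cfg, seed=int(s) + 1)
        )
    return float(np.mean(rates))


def heritability_recovery(
    seed: int = 0,
    n_seeds: int = 20,
    true_h2: float = 0.96,
    n_genotypes: int = 100,
    n_reps: int = 5,
) -> float:
    """Mean REML broad-sense heritability estimate at a known generative H².

    Phenotypes are genotype effects N(0, H²) plus replicate residuals
    N(0, 1 - H²) — the balanced replicated design of the preliminary
    flowering experiment.
    """
    import pandas as pd

    ests = []
    for s in _seeds(seed, n_seeds, stream=2):
        rng = np.random.default_rng(int(s))
        g = rng.normal(0.0, np.sqrt(true_h2), n_genotypes)
        vals = g[:, None] + rng.normal(0.0, np.sqrt(1.0 - true_h2), (n_genotypes, n_reps))
        df = pd.DataFrame(
            {"genotype": np.repeat(np.arange(n_genotypes), n_reps), "value": vals.ravel()}
        )
        ests.append(broad_sense_heritability(df))
    return float(np.mean(ests))


def _unrelated_panel(seed: int, n: int = 74, n_snps: int = 2000) -> tuple:
    """Unrelated inbred genotypes over two chromosomes, independent SNPs."""
    spec = PopulationSpec(
        n_subgroups=1,
        n_families_per_subgroup=n,
        n_accessions_per_family=1,
        within_family_divergence=0.0,
        n_snps=n_snps,
        n_chromosomes=2,
        ld_block_size_snps=1,
        missing_rate=0.0,
        seed=seed,
    )
    return gen_genotypes(spec)


def pve_recovery(
    seed: int = 0,
    n_seeds: int = 20,
    generative_pve: float = 0.62,
    polygenic_h2: float = 0.10,
) -> float:
    """Mean percent variance explained recovered at the scan peak.

    Per seed: 74 unrelated genotypes x 2,000 SNPs on two chromosomes, one
    QTL at a common SNP with the generative variance fraction, plus
    polygenic and residual noise; LOCO mixed-model scan; PVE from the
    likelihood ratio at the peak SNP, on the percent scale.
    """
    pves = []
    for s in _seeds(seed, n_seeds, stream=3):
        matrix, _ = _unrelated_panel(int(s))
        maf = matrix.maf()
        candidates = np.flatnonzero(
            (np.asarray(matrix.chrom) == matrix.chrom[0]) & (maf > 0.35)
        )
        locus = int(candidates[len(candidates) // 2])
        pheno_spec = PhenoSimSpec(
            qtl_loci=[(locus, generative_pve)],
            polygenic_h2=polygenic_h2,
            n_replicates=1,
            seed=int(s) + 1,
        )
        traits, _ = gen_phenotypes(matrix, pheno_spec, envs=("2015",))
        y = (
            traits.groupby("sample")["value"].mean().loc[matrix.samples].to_numpy()
        )
        scanner = LmmScanner(matrix, kinship_mode="loco")
        result = scanner.scan(y)
        pves.append(pve_from_lod(result.table["lod"].max(), matrix.n_samples))
    return float(np.mean(pves))


def threshold_calibration(
    seed: int = 0,
    n_datasets: int = 200,
    n_perm: int = 200,
    alpha: float = 0.05,
) -> float:
    """Empirical genome-wide type-I error of the permutation threshold.

    For each null dataset (74 unrelated genotypes x 2,000 SNPs, phenotype
    pure noise) the threshold is derived from ``n_perm`` phenotype
    permutations at level ``alpha``; a freshly simulated null phenotype is
    then scanned and its maximum LOD compared against the threshold.
    Returns the exceedance fraction.
    """
    exceed = 0
    for s in _seeds(seed, n_datasets, stream=4):
        matrix, _ = _unrelated_panel(int(s))
        rng = np.random.default_rng(int(s) + 1)
        y = rng.standard_normal(matrix.n_samples)
        scanner = LmmScanner(matrix, kinship_mode="loco")
        threshold, _ = permutation_threshold(
            scanner, y, n_perm=n_perm, alpha=alpha, seed=int(s) + 2
        )
        y_fresh = rng.standard_normal(matrix.n_samples)
        exceed += scanner.max_lod(y_fresh) > threshold
    return float(exceed / n_datasets)
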