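"""Synthetic genotypes, coverage profiles, climate series and phenotypes.

The generators emulate the statistical structure of the study system so that
every downstream stage can be exercised and calibrated without the original
sequencing data:

* genotypes — a hierarchy of subgroups (fixed divergence at 6.5% of sites
  between subgroups by default), clonal families of near-identical inbred
  accessions (0.1–0.4% within-lineage divergence), block-structured LD, and
  18.5% missing calls;
* coverage — per-subgenome covered-fraction signatures of the two diploids,
  the allotetraploid, and low-coverage failures;
* climate — diurnal + seasonal sinusoidal temperature with a square-wave
  photoperiod, for a present-day and a warmed scenario;
* phenotypes — the generative mirror of the mixed model the scan fits:
  QTL effects + polygenic term with IBS-kinship covariance + genotype-specific
  environment shift (G×E) + replicate residual.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeMatrix
from .genotype_core import ibs_distance
from .species_id import CoverageSummary

__all__ = [
    "PopulationSpec",
    "ClimateSpec",
    "PhenoSimSpec",
    "SPECIES_SIGNATURES",
    "default_subgenome_setup",
    "gen_genotypes",
    "gen_coverage",
    "gen_climate",
    "gen_phenotypes",
]

#: Per-founder, per-SNP probability of departing from its block haplotype.
#: Erodes the otherwise perfect within-block correlation so that adjacent
#: SNPs are correlated but not identical, as in real short-range LD.
FOUNDER_BLOCK_NOISE = 0.02


# ======================================================================
# Genotypes
# ======================================================================
@dataclass
class PopulationSpec:
    """Structure of the simulated inbred panel.

    Defaults mirror the study system: two subgroups with fixed differences at
    6.5% of sites, clonal families diverging at 0.3% of SNPs per generation
    step, and 18.5% missing calls.
    """

    n_subgroups: int = 2
    fixed_divergence_between_subgroups: float = 0.065
    n_families_per_subgroup: int = 5
    n_accessions_per_family: int = 10
    within_family_divergence: float = 0.003
    n_replicates_per_accession: int = 1
    n_snps: int = 5000
    n_chromosomes: int = 5
    chromosome_length_bp: int = 5_000_000
    ld_block_size_snps: int = 50
    maf_floor: float = 0.10
    missing_rate: float = 0.185
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "n_subgroups",
            "n_families_per_subgroup",
            "n_accessions_per_family",
            "n_replicates_per_accession",
            "n_snps",
            "n_chromosomes",
            "chromosome_length_bp",
            "ld_block_size_snps",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in (
            "fixed_divergence_between_subgroups",
            "within_family_divergence",
            "missing_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0,1]")
        if not 0.0 <= self.maf_floor < 0.5:
            raise ValueError("maf_floor must be in [0, 0.5)")
        # each subgroup gets d/2 private fixed sites; the total allocation
        # cannot exceed the genome
        if self.n_subgroups * self.fixed_divergence_between_subgroups / 2 > 1:
            raise ValueError(
                "requested fixed-divergence fractions sum above 1 across subgroups"
            )
        if self.n_chromosomes > self.n_snps:
            raise ValueError("more chromosomes than SNPs")


def _snp_coordinates(spec: PopulationSpec) -> tuple[np.ndarray, np.ndarray]:
    """Evenly spaced 1-based positions; SNPs split across chromosomes."""
    base = spec.n_snps // spec.n_chromosomes
    extra = spec.n_snps % spec.n_chromosomes
    chrom, pos = [], []
    for c in range(spec.n_chromosomes):
        n = base + (1 if c < extra else 0)
        spacing = max(spec.chromosome_length_bp // (n + 1), 1)
        chrom.extend([f"Bd{c + 1}"] * n)
        pos.extend(spacing * (np.arange(n) + 1))
    return np.array(chrom, dtype=object), np.array(pos, dtype=np.int64)


def gen_genotypes(spec: PopulationSpec) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Generate the inbred panel and its truth labels.

    Founders (one per clonal family) sample alleles in LD blocks of
    ``ld_block_size_snps`` consecutive SNPs: each block carries two
    complementary haplotypes whose population frequency is drawn uniformly
    on ``[maf_floor, 1 - maf_floor]``.  Each subgroup additionally carries a
    private set of ``d/2 * n_snps`` sites fixed for the alternate allele
    (reference-fixed elsewhere), so every subgroup pair is fixed-different at
    fraction ``d`` of sites.  Accessions are founder copies with independent
    per-SNP mutations at ``within_family_divergence``; replicates are
    technical copies of the accession genome.  Missing calls are injected
    MCAR at ``missing_rate``, independently per replicate.

    Returns the matrix plus a truth table (sample, subgroup, family,
    accession).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    m = spec.n_snps
    chrom, pos = _snp_coordinates(spec)

    # --- subgroup-private fixed sites --------------------------------
    n_private = int(round(spec.fixed_divergence_between_subgroups / 2 * m))
    perm = rng.permutation(m)
    private_sites = [
        perm[g * n_private : (g + 1) * n_private] for g in range(spec.n_subgroups)
    ]

    # --- block haplotypes --------------------------------------------
    # block boundaries restart at each chromosome
    block_id = np.empty(m, dtype=np.int64)
    next_block = 0
    for c in pd.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        ids = next_block + np.arange(len(idx)) // spec.ld_block_size_snps
        block_id[idx] = ids
        next_block = ids[-1] + 1
    n_blocks = next_block
    block_freq = rng.uniform(spec.maf_floor, 1.0 - spec.maf_floor, size=n_blocks)
    # orientation: which allele (0 or 2) haplotype "1" carries at each SNP
    hap1_allele = rng.integers(0, 2, size=m) * 2

    # --- founders -----------------------------------------------------
    n_founders = spec.n_subgroups * spec.n_families_per_subgroup
    hap_choice = rng.random((n_founders, n_blocks)) < block_freq  # (f, blocks)
    founders = np.where(
        hap_choice[:, block_id], hap1_allele, 2 - hap1_allele
    ).astype(np.int8)
    flips = rng.random((n_founders, m)) < FOUNDER_BLOCK_NOISE
    founders = np.where(flips, 2 - founders, founders)
    for g in range(spec.n_subgroups):
        row_idx = np.arange(
            g * spec.n_families_per_subgroup, (g + 1) * spec.n_families_per_subgroup
        )
        for h, sites in enumerate(private_sites):
            if len(sites):
                founders[np.ix_(row_idx, sites)] = 2 if h == g else 0

    # --- accessions and replicates -----------------------------------
    samples, labels, rows = [], [], []
    for g in range(spec.n_subgroups):
        for f in range(spec.n_families_per_subgroup):
            founder = founders[g * spec.n_families_per_subgroup + f]
            for a in range(spec.n_accessions_per_family):
                acc_name = f"sg{g + 1}_f{f + 1}_a{a + 1}"
                mut = rng.random(m) < spec.within_family_divergence
                accession = np.where(mut, 2 - founder, founder)
                # replicates are technical copies of the accession genome;
                # they differ only through independent missingness below
                for r in range(spec.n_replicates_per_accession):
                    name = (
                        acc_name
                        if spec.n_replicates_per_accession == 1
                        else f"{acc_name}_r{r + 1}"
                    )
                    samples.append(name)
                    labels.append((name, g + 1, f + 1, acc_name))
                    rows.append(accession)
    calls = np.stack(rows).astype(np.int8)
    if spec.missing_rate > 0:
        calls[rng.random(calls.shape) < spec.missing_rate] = MISSING

    matrix = GenotypeMatrix(samples=samples, chrom=chrom, pos=pos, calls=calls)
    truth = pd.DataFrame(labels, columns=["sample", "subgroup", "family", "accession"])
    return matrix, truth


# ======================================================================
# Coverage
# ======================================================================
#: Mean covered fraction on the (distachyon, stacei) subgenomes per species.
#: Diploids pile essentially all reads on their own subgenome; the
#: allotetraploid covers both, with the distachyon share of covered bases
#: near 0.31 (the asymmetric GBS tag yield implied by the narrow
#: hybridum interval).
SPECIES_SIGNATURES: dict[str, tuple[float, float]] = {
    "distachyon": (0.60, 0.002),
    "stacei": (0.002, 0.60),
    "hybridum": (0.25, 0.55),
    "low_coverage": (0.02, 0.02),
}

#: Default total read counts (median GBS yield vs a failed library).
_TOTAL_READS = {"default": 564_000, "low_coverage": 50_000}


def default_subgenome_setup() -> tuple[dict[str, str], dict[str, int]]:
    """Pseudoreference layout: 5 distachyon + 10 stacei chromosomes.

    Returns (subgenome map, chromosome lengths in bp) roughly proportional to
    the 270 Mb / 230 Mb genome sizes.
    """
    submap: dict[str, str] = {}
    lengths: dict[str, int] = {}
    for i in range(1, 6):
        submap[f"Bd{i}"] = "distachyon"
        lengths[f"Bd{i}"] = 54_000_000
    for i in range(1, 11):
        submap[f"Bs{i}"] = "stacei"
        lengths[f"Bs{i}"] = 23_000_000
    return submap, lengths


def gen_coverage(
    species_mix: list[tuple[str, int]],
    noise_sd: float = 0.02,
    seed: int = 0,
) -> tuple[list[CoverageSummary], pd.DataFrame]:
    """Simulate per-chromosome covered fractions for a panel.

    ``noise_sd`` is a relative (multiplicative) depth-noise scale: each
    chromosome's covered fraction is its species signature times
    ``1 + N(0, noise_sd)``, truncated to [0, 1].  ``low_coverage`` samples
    get fewer than 100,000 total reads.

    Returns the summaries plus a truth table (sample, species).
    """
    rng = np.random.default_rng(seed)
    submap, lengths = default_subgenome_setup()
    summaries, rows = [], []
    idx = 0
    for species, count in species_mix:
        if species not in SPECIES_SIGNATURES:
            raise ValueError(f"unknown species label {species!r}")
        mean_d, mean_s = SPECIES_SIGNATURES[species]
        reads = _TOTAL_READS["low_coverage" if species == "low_coverage" else "default"]
        for _ in range(count):
            idx += 1
            name = f"acc{idx:04d}"
            fractions = {}
            for chrom_name, sub in submap.items():
                mean = mean_d if sub == "distachyon" else mean_s
                value = mean * (1.0 + rng.normal(0.0, noise_sd))
                fractions[chrom_name] = float(np.clip(value, 0.0, 1.0))
            summaries.append(
                CoverageSummary(
                    sample=name, covered_fraction=fractions, total_reads=reads
                )
            )
            rows.append({"sample": name, "species": species})
    return summaries, pd.DataFrame(rows)


# ======================================================================
# Climate
# ======================================================================
@dataclass
class ClimateSpec:
    """Sinusoidal stand-in for the chamber's logged climate programme.

    Temperature is mean + seasonal sinusoid (period 365 d, southern-
    hemisphere phase: warmest mid-January) + diurnal sinusoid (period 24 h,
    warmest 15:00) + ``warming_offset`` (the future-scenario delta).  PAR is
    a square wave: ``par_day`` inside the photoperiod (centred on noon),
    zero outside.
    """

    start_day: int = 152          # June 1, a Winter sowing
    n_days: int = 200
    cadence_minutes: int = 5
    mean_temp: float = 16.0
    diurnal_amplitude: float = 6.0
    seasonal_amplitude: float = 7.0
    warming_offset: float = 0.0
    day_length_hours: float = 12.0
    par_day: float = 500.0

    def validate(self) -> None:
        if self.cadence_minutes < 1 or 1440 % self.cadence_minutes != 0:
            raise ValueError("cadence must divide 24 h")
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")
        if not 0.0 <= self.day_length_hours <= 24.0:
            raise ValueError("day_length_hours outside [0, 24]")
        if self.par_day < 0:
            raise ValueError("par_day must be non-negative")


def gen_climate(spec: ClimateSpec) -> pd.DataFrame:
    """Generate the climate series: one row per cadence step.

    Columns: ``day`` (days since sowing, float), ``timestamp`` (nominal ISO
    datetime), ``temp_C``, ``par``.
    """
    spec.validate()
    per_day = 1440 // spec.cadence_minutes
    k = np.arange(spec.n_days * per_day)
    day = k * (spec.cadence_minutes / 1440.0)
    doy = spec.start_day + day
    hour = (day % 1.0) * 24.0
    temp = (
        spec.mean_temp
        + spec.seasonal_amplitude * np.cos(2 * np.pi * (doy - 15.0) / 365.0)
        + spec.diurnal_amplitude * np.cos(2 * np.pi * (hour - 15.0) / 24.0)
        + spec.warming_offset
    )
    half = spec.day_length_hours / 2.0
    daylight = (hour >= 12.0 - half) & (hour < 12.0 + half)
    par = np.where(daylight, spec.par_day, 0.0)
    timestamp = pd.Timestamp("2015-01-01") + pd.to_timedelta(
        (spec.start_day - 1) * 1440 + k * spec.cadence_minutes, unit="m"
    )
    return pd.DataFrame(
        {"day": day, "timestamp": timestamp, "temp_C": temp, "par": par}
    )


# ======================================================================
# Phenotypes
# ======================================================================
@dataclass
class PhenoSimSpec:
    """Generative mixed model for replicated phenotypes in two environments.

    ``qtl_loci`` lists ``(snp_index, variance_fraction)`` pairs; when
    ``target_pve_per_qtl`` is set it overrides every locus' fraction.  The
    genotype-level terms (QTL, polygenic, G×E shift) are shared across
    replicates; the polygenic term has covariance proportional to the IBS
    kinship of the panel.  The total phenotypic variance is 1 by
    construction, so fractions are directly comparable with estimated PVE
    and heritability.
    """

    qtl_loci: list[tuple[int, float]] = field(default_factory=list)
    target_pve_per_qtl: float | None = None
    polygenic_h2: float = 0.0
    n_replicates: int = 4
    gxe_shift: float = 0.0
    qtl_loci_env_specific: list[tuple[int, float]] = field(default_factory=list)
    seed: int = 0

    def qtl_fractions(self) -> list[tuple[int, float]]:
        if self.target_pve_per_qtl is not None:
            return [(j, self.target_pve_per_qtl) for j, _ in self.qtl_loci]
        return list(self.qtl_loci)

    def validate(self) -> None:
        total = sum(f for _, f in self.qtl_fractions()) + self.polygenic_h2
        if total > 1.0 + 1e-9:
            raise ValueError(
                f"generative variance fractions sum to {total:.3f} > 1"
            )
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if not 0.0 <= self.polygenic_h2 <= 1.0:
            raise ValueError("polygenic_h2 outside [0,1]")


def _qtl_component(geno: GenotypeMatrix, locus: int, fraction: float) -> np.ndarray:
    """Mean-imputed, variance-standardised QTL contribution of one locus."""
    z = geno.calls[:, locus].astype(float)
    obs = z != MISSING
    if not np.any(obs):
        raise ValueError(f"QTL locus {locus} has no observed calls")
    z[~obs] = z[obs].mean()
    var = z.var()
    if var == 0:
        raise ValueError(f"QTL locus {locus} is monomorphic")
    z = (z - z.mean()) / np.sqrt(var)
    return np.sqrt(fraction) * z


def gen_phenotypes(
    geno: GenotypeMatrix,
    spec: PhenoSimSpec,
    envs: tuple[str, ...] = ("2015", "2050"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate replicated phenotypes under the generative mixed model.

    Environment-shared genotype terms: QTL effects and the polygenic draw.
    The G×E shift (scale ``gxe_shift``) and any ``qtl_loci_env_specific``
    effects apply to the second and later environments only, so the first
    environment is the reference scenario.  Residuals are iid per plant.

    Returns ``(trait_table, truth)``: the trait table has one row per plant
    (sample, environment, replicate, value); ``truth`` records the
    genotype-level genetic value per sample and environment.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = geno.n_samples

    genetic = np.zeros(n)
    for locus, fraction in spec.qtl_fractions():
        genetic = genetic + _qtl_component(geno, locus, fraction)

    if spec.polygenic_h2 > 0:
        K = 1.0 - ibs_distance(geno, allow_undefined=False).values
        np.fill_diagonal(K, 1.0)
        w, U = np.linalg.eigh(K)
        w = np.clip(w, 0.0, None)
        u = U @ (np.sqrt(w) * rng.standard_normal(n))
        genetic = genetic + np.sqrt(spec.polygenic_h2) * u

    resid_var = max(
        1.0 - sum(f for _, f in spec.qtl_fractions()) - spec.polygenic_h2, 0.0
    )
    resid_sd = np.sqrt(resid_var)

    gxe = rng.standard_normal(n) * spec.gxe_shift
    env_qtl = np.zeros(n)
    for locus, fraction in spec.qtl_loci_env_specific:
        env_qtl = env_qtl + _qtl_component(geno, locus, fraction)

    rows, truth_rows = [], []
    for e_idx, env in enumerate(envs):
        g_env = genetic + (gxe + env_qtl if e_idx > 0 else 0.0)
        for i, s in enumerate(geno.samples):
            truth_rows.append(
                {"sample": s, "environment": env, "genetic_value": g_env[i]}
            )
            for r in range(spec.n_replicates):
                rows.append(
                    {
                        "sample": s,
                        "environment": env,
                        "replicate": r + 1,
                        "value": g_env[i] + resid_sd * rng.standard_normal(),
                    }
                )
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)
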