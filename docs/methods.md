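# Methods

This note records the models behind each stage, the defaults and why, what
the synthetic generators do and do not emulate, and the numerical choices
made where the design was genuinely open.

## Species assignment from subgenome coverage

Input is the fraction of each chromosome of the concatenated
*B. distachyon* + *B. stacei* pseudoreference covered by at least three
uniquely-mapped reads (multimapper-flagged depth records are ignored;
positions absent from the input count as depth 0). Chromosome fractions are
aggregated per subgenome as a length-weighted mean — upstream depth tools
report per-chromosome proportions, and the length-weighted mean is the
natural whole-subgenome aggregate. The normalized distachyon
proportion is the ratio `p_d / (p_d + p_s)`: the minimal monotone map onto
[0, 1] consistent with the threshold positions (*B. stacei* near 0,
*B. distachyon* near 1). Threshold groups follow strict
inequalities evaluated in order (<0.03, <0.28, <0.34, then ≤0.94 for the
upper intermediate so that the partition is exhaustive against >0.94), and
a total read count below 100,000 pre-empts everything as `low_coverage`.

## Lineage clustering and replicate retention

IBS distance between two inbred samples is the mean of |gᵢ−gⱼ|/2 over
jointly observed SNPs with the {0, 2} homozygote coding (heterozygotes, if
retained by policy, contribute ½). Pairs with no jointly observed SNPs are
an explicit error unless the caller opts into NaN.

Lineages come from a single-linkage dendrogram whose merge heights are
scanned in increasing order against a running mean and SD of the heights
accepted so far; the first height whose z-score exceeds 3.5 (configurable)
sets the cut, and components below it are the genotype lineages. Fewer than
three merges, or no outlying merge, collapses everything into one lineage.
When a run of accepted heights has zero SD (exact ties, in practice only
duplicate samples at distance 0), an absolute gap of 0.01 IBS is required
before a height is declared outlying — a z-score is undefined there, and
0.01 sits between replicate noise (≲0.005) and lineage divergence (≳0.05).

Accessions whose replicates split across lineages keep the majority
lineage's replicates; exact ties keep the single replicate with the least
missing data.

Fixed divergence between two groups counts SNPs at which all non-missing
calls are one homozygote in one group and the opposite homozygote in the
other, over SNPs observed in both groups. Family-level mutation and
missingness in a simulated panel erode fixation relative to the founder
value — the generator's divergence parameter is defined on founders.

## Imputation ladder

The GWAS preparation chain is: drop non-variant SNPs; collapse redundant
adjacent duplicates (identical at every jointly observed sample, with at
least one — the only checkable reading of "not different"), keeping the
member with fewer missing calls (tie: the downstream SNP is dropped);
MAF < 3% filter; adjacent fill; nearest-neighbour imputation; MAF < 5%
filter. MAF is always computed on non-missing calls.

Adjacent fill copies a call that is missing at one of two identical
adjacent SNPs from the other, in a single left-to-right pass per
chromosome, never across chromosome boundaries.

NN imputation scores accession similarity as the agreement fraction over up
to 50 SNPs on each side of the target SNP (within the chromosome), then
lets the five most similar accessions with an observed call vote; the
majority genotype is imputed. Vote ties extend to the next-closest observed
accession until resolved; similarity ties break by sample order; both rules
are deterministic and logged. Votes read only original calls — never
freshly imputed ones — so the result is independent of SNP visit order and
observed calls are never altered. Calls that no informative neighbour can
reach stay missing, and the masking-based evaluator counts them as
failures (the conservative reading of "success rate").

## Trait derivation

Thermal time accumulates `(T − 2 °C) × Δt` per logging interval whenever
the interval's starting temperature exceeds the 2 °C base; gating and
increment use the same (starting) temperature — the literal reading of the
running recursion, and at 5-minute cadence the alternatives differ
negligibly. Photothermal units accumulate `ΔTT × PAR` per interval; the
literal product of *cumulative* thermal time with instantaneous PAR is
dimensionally unstable and is provided only behind `mode="cumulative"`.
Both accumulators are additive over abutting intervals and exact for
piecewise-constant series; gaps wider than twice the cadence trigger a
warning.

Growth rates are ΔGS/Δt between the observations nearest Huan stage 1 and
stage 3 (GR1) and nearest stages 3 and 5 (GR2); anchor ties take the
earlier observation, and windows the data cannot span yield a missing
trait. Clock time (days) is the denominator — the stage formulas use
logged time, not thermal time; a thermal-time variant can be had by passing
a thermal-time-indexed series. The phyllochron is `(T₂ − Tₑ)/GS₂` at the
~three-leaf observation. Growth efficiencies divide biomass at ear
emergence by the climate accumulations from seedling emergence to ear
emergence; non-flowering plants get missing values. The four energy-use
efficiencies are fixed ratios of respiration, quantum yield, height
and leaf-3 length; zero denominators yield missing values.

Broad-sense heritability uses a REML random-intercept model (genotype as
grouping factor; statsmodels MixedLM) with H² = σ²G/(σ²G+σ²E) clipped to
[0, 1]. The degenerate zero-within-variance case short-circuits to 1. The
estimator shows |bias| ≤ 0.03 across H² ∈ {0.2, …, 0.96} at 100 genotypes
× 5 replicates (tested).

## Mixed-model scan

Per scanning locus, `y = xβ + zγ + u + ε` with `u ~ N(0, K σ²g)` and
`ε ~ N(0, I σ²)`; y holds per-genotype trait means. K is IBS kinship
(1 − distance, unit diagonal) computed without the scanned chromosome
(LOCO) to avoid proximal contamination. Per chromosome, the null variance
ratio h = σ²g/(σ²g+σ²) is estimated by REML on the eigendecomposition of
K over a 100-point grid (resolution 0.01 — well below the LOD's
sensitivity to h), then held fixed while each SNP is tested by generalized
least squares in the whitened model — the standard
"population-parameters-previously-determined" approximation. The statistic
is LOD = (n/2)·log10(RSS₀/RSS₁), the log10 likelihood ratio; with identity
kinship it equals the OLS likelihood-ratio LOD to 1e-6 (tested against
statsmodels). Missing genotype codes are mean-imputed per SNP before the
fit; SNPs with no residual variance after whitening get LOD 0.

The genome-wide threshold permutes y across samples, rescans (variance
components re-estimated per permutation, keeping the permuted statistic
exchangeable with the observed one), records the per-permutation maximum
LOD, and returns the order statistic of rank ⌈(1−α)·n_perm⌉. PVE at a
locus is 1 − exp(−2ΔLL/n), reported in percent. QTL are called greedily by
descending LOD: each peak absorbs significant SNPs within 50 kb, carries a
100-kb candidate window (truncated at position 1) and, when a GFF3 gene
table is supplied, the genes intersecting the window. The G×E scan maps
per-genotype differences of environment trait means — the simplest
response the generative G×E structure can produce; a joint interaction
model was deliberately left out of scope.

## LD decay

r² is the squared Pearson correlation of allele dose over jointly observed
samples, for all SNP pairs within consecutive non-overlapping windows of
2000 SNPs (windows never span chromosomes; terminal partial windows are
processed). Pairs with fewer than 10 joint samples — where r² is unstable
at panel sizes near 74 — or zero variance are skipped. Pairs are binned by
distance (1 kb); r²max is the first populated bin's mean, and the
half-decay distance is the midpoint of the nearest later bin whose mean
drops to r²max/2 — an empirical binned estimator chosen over curve
fitting as the minimal well-defined one; windows that never decay are
undefined and excluded from the genome median/IQR.

## Synthetic data

The generators reproduce the *statistical* structure the pipeline assumes,
not sequence-level realism.

**Genotypes.** Founders (one per clonal family) draw alleles in LD blocks
of `ld_block_size_snps` consecutive SNPs: each block carries two
complementary haplotypes at a frequency uniform on
[maf_floor, 1−maf_floor], and a 2% per-SNP departure rate erodes the
otherwise perfect within-block correlation so adjacent SNPs are correlated
but not duplicated. Each subgroup owns a private set of d/2 of the SNPs
fixed for the alternate allele, making every subgroup pair fixed-different
at fraction d (default 6.5%, the between-subgroup value; the generalisation
to >2 subgroups keeps all pairwise divergences equal). Accessions mutate
from their founder at `within_family_divergence` per SNP (default 0.3%,
mid-range of the study system's 0.1–0.4% within-lineage divergence); replicates
are technical copies; missingness is injected MCAR (default 18.5%) — no
missingness mechanism is documented for the real data, so MCAR is the
neutral choice. Mean r² between block SNPs falls linearly with the
same-block probability, halving at half the block length — the closed form
the LD tests check.

**Coverage.** Species signatures give the two diploids ~0.6 covered
fraction on their own subgenome and ~0.002 on the other (multimapping
bleed); the allotetraploid covers both with a distachyon share of 0.31,
inside the narrow *hybridum* interval, which reflects asymmetric tag
yield between subgenomes. Noise is multiplicative — covered fraction times
(1 + N(0, noise_sd)), truncated to [0, 1] — because sequencing-depth
variation scales with the signal; additive noise of the same magnitude on
a near-zero off-subgenome fraction would smear the diploids across the
0.03 boundary and no classifier could meet the recovery requirement.
`low_coverage` samples get 50,000 total reads, below the 100,000 gate.

**Climate.** Temperature is mean + seasonal sinusoid (period 365 d,
southern-hemisphere phase, warmest mid-January) + diurnal sinusoid (period
24 h, warmest 15:00) + a scenario warming offset; PAR is a square wave over
a noon-centred photoperiod. This is a deliberate simplification of the
solar-model-driven chamber programme: it preserves cadence, diurnal and
seasonal structure and the scenario contrast, not radiation geometry.

**Phenotypes.** The generative mirror of the scan model: per-locus QTL
contributions standardised to their target variance fractions, a polygenic
draw with covariance proportional to the panel's IBS kinship, a
genotype-specific environment shift (G×E) plus optional
environment-specific QTL applied to the non-reference scenario, and iid
replicate residuals; total variance is 1 by construction so generative
fractions are directly comparable with estimated PVE and H².

What passing tests therefore show: the algorithms recover the structure
they assume, at the study's parameter ranges and sample sizes. What they do
not show: robustness to non-MCAR missingness, coalescent LD patterns,
genotyping-error structure, selection, or admixture — none of which the
generators emulate.

## Benchmark problem sizes

The calibrated benchmarks (`brachykit.benchmarks`, driven by
`scripts/acceptance.py`) use desk-scale versions of the study design,
chosen so the full set runs in about a minute: imputation on 100 accessions
in 10 clonal families × 5,000 SNPs, masked at the 18.5% missingness rate,
averaged over 5 seeds; heritability at 100 genotypes × 5 replicates,
generative H² 0.96, 20 seeds; PVE recovery at 74 unrelated genotypes ×
2,000 SNPs on two chromosomes with a single 62%-variance QTL plus 10%
polygenic background, 20 seeds (an unstructured panel keeps the
likelihood-ratio PVE on the generative scale — under strong structure the
LOCO whitening absorbs part of the denominator); threshold calibration on
200 null datasets with 200 permutations each at α = 0.05. The analysis
drivers under `analysis/` use similar sizes and fixed seeds throughout;
all generators are bit-reproducible for a fixed seed.

## Known limitations

- The NN imputer is O(windows × samples²) per SNP; it is sized for
  reduced-representation panels (10⁴–10⁵ SNPs, ≤ a few hundred samples),
  not whole-genome matrices.
- The z-score tree cut emulates the referenced clustering behaviour but is
  sensitive to the first few merge heights on very small panels (< ~10
  samples).
- PVE from the likelihood ratio is mildly optimistic at the selected peak
  (winner's curse); the benchmark shows ≈ +3 points at n = 74.
- The G×E difference scan cannot separate interaction from scale effects;
  traits should be on comparable scales across environments.
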