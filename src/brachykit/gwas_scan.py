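"""Linear mixed-model genome scan with LOCO-IBS kinship.

The association model per scanning locus is

    y = x beta + z gamma + u + e,   u ~ N(0, K sigma_g^2),  e ~ N(0, I sigma^2)

with y the per-genotype trait means, x an intercept (plus optional
covariates), z the coded genotype at the locus, and K the identity-by-state
kinship estimated with the scanned chromosome left out (LOCO) to avoid
proximal contamination of the polygenic term.

Variance components are estimated once per chromosome under the null by
REML on the eigendecomposition of K, then held fixed while every SNP on the
chromosome is tested by generalized least squares; the statistic is
LOD = (n/2) * log10(RSS_null / RSS_alt) in the whitened model, the log10
likelihood ratio.  The genome-wide threshold is the empirical (1 - alpha)
quantile of the per-permutation maximum LOD over phenotype permutations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeMatrix
from .genotype_core import ibs_distance

logger = logging.getLogger(__name__)

__all__ = [
    "kinship_ibs",
    "LmmScanner",
    "ScanResult",
    "QTLRecord",
    "permutation_threshold",
    "pve_from_lod",
    "variance_explained",
    "call_qtl",
    "gxe_response",
]

_H_GRID = np.linspace(0.0, 0.99, 100)


def kinship_ibs(
    matrix: GenotypeMatrix, exclude_chromosome: str | None = None
) -> np.ndarray:
    """IBS kinship ``K = 1 - d_IBS`` with unit diagonal.

    With ``exclude_chromosome`` the distance uses only SNPs on the other
    chromosomes (the LOCO kinship for a scan of that chromosome).
    """
    if exclude_chromosome is not None:
        keep = np.flatnonzero(matrix.chrom != exclude_chromosome)
        if len(keep) == 0:
            raise ValueError(
                f"excluding {exclude_chromosome!r} leaves no SNPs for kinship"
            )
        matrix = matrix.take_snps(keep)
    K = 1.0 - ibs_distance(matrix, allow_undefined=False).values
    np.fill_diagonal(K, 1.0)
    return K


def _mean_imputed_dosage(matrix: GenotypeMatrix) -> np.ndarray:
    """Float calls with missing codes replaced by the SNP mean."""
    Z = matrix.calls.astype(np.float64)
    miss = matrix.calls == MISSING
    if np.any(miss):
        obs = ~miss
        with np.errstate(invalid="ignore"):
            col_mean = np.where(
                obs.sum(axis=0) > 0,
                np.where(obs, Z, 0).sum(axis=0) / np.maximum(obs.sum(axis=0), 1),
                0.0,
            )
        Z = np.where(miss, col_mean[None, :], Z)
    return Z


@dataclass
class ScanResult:
    """Per-SNP scan table plus the model summary.

    ``table`` columns: chrom, pos, lod, effect.  ``h2_by_chrom`` holds the
    null REML heritability used to whiten each chromosome's tests;
    ``threshold`` and ``n_perm`` are filled by the permutation step.
    """

    table: pd.DataFrame
    h2_by_chrom: dict[str, float]
    threshold: float | None = None
    n_perm: int = 0
    permutation_seed: int | None = None

    def significant(self) -> pd.DataFrame:
        if self.threshold is None:
            raise ValueError("no threshold set; run the permutation step first")
        return self.table[self.table["lod"] >= self.threshold]


@dataclass
class QTLRecord:
    trait: str
    environment: str
    chrom: str
    peak_pos: int
    peak_lod: float
    window_start: int
    window_end: int
    pve_percent: float
    member_positions: list[int] = field(default_factory=list)
    genes: list[str] = field(default_factory=list)


class _ChromosomeContext:
    """Eigen-structure of one chromosome's LOCO kinship, reused across
    phenotypes and permutations."""

    def __init__(self, lam: np.ndarray, U: np.ndarray, Z_rot: np.ndarray):
        self.lam = lam
        self.U = U
        self.Z_rot = Z_rot
        n = len(lam)
        # grid quantities for the intercept-only REML fast path
        self.V = _H_GRID[:, None] * lam[None, :] + (1.0 - _H_GRID[:, None])
        self.W = 1.0 / self.V
        self.sumlog = np.log(self.V).sum(axis=1)
        self.c = U.T @ np.ones(n)
        self.S_cc = self.W @ (self.c**2)


class LmmScanner:
    """Precomputes per-chromosome LOCO structures for fast repeated scans.

    Parameters
    ----------
    matrix
        Imputed genotype panel (one row per genotype in the phenotype
        vector's order).
    kinship_mode
        ``"loco"`` (default), ``"global"`` or ``"none"`` (identity kinship,
        equivalent to ordinary least squares).
    """

    def __init__(self, matrix: GenotypeMatrix, kinship_mode: str = "loco"):
        if kinship_mode not in ("loco", "global", "none"):
            raise ValueError(f"unknown kinship mode {kinship_mode!r}")
        self.matrix = matrix
        self.kinship_mode = kinship_mode
        self.samples = list(matrix.samples)
        self.n = matrix.n_samples
        if self.n < 20:
            logger.warning("only %d samples; scan power will be poor", self.n)
        chroms = matrix.chromosomes()
        if kinship_mode == "loco" and len(chroms) < 2:
            raise ValueError("LOCO kinship needs at least two chromosomes")
        dosage = _mean_imputed_dosage(matrix)
        self.contexts: dict[str, _ChromosomeContext] = {}
        K_global = None
        if kinship_mode == "global":
            K_global = kinship_ibs(matrix)
        for c in chroms:
            snps = np.flatnonzero(matrix.chrom == c)
            if kinship_mode == "none":
                lam = np.ones(self.n)
                U = np.eye(self.n)
            else:
                K = K_global if K_global is not None else kinship_ibs(matrix, exclude_chromosome=c)
                lam, U = np.linalg.eigh(K)
                lam = np.clip(lam, 0.0, None)
            self.contexts[c] = _ChromosomeContext(lam, U, U.T @ dosage[:, snps])

    # ------------------------------------------------------------------
    def _fit_chromosome(self, ctx: _ChromosomeContext, y: np.ndarray):
        """Null REML over the h grid, then GLS stats for every SNP.

        Returns (h2, lod array, effect array, whitened RSS0).
        """
        n = self.n
        y_rot = ctx.U.T @ y
        if self.kinship_mode == "none":
            best = 0
        else:
            S_cy = ctx.W @ (ctx.c * y_rot)
            S_yy = ctx.W @ (y_rot**2)
            rss = np.maximum(S_yy - S_cy**2 / ctx.S_cc, 1e-300)
            reml = -0.5 * ((n - 1) * np.log(rss / (n - 1)) + ctx.sumlog + np.log(ctx.S_cc))
            best = int(np.argmax(reml))
        h2 = float(_H_GRID[best])
        sw = np.sqrt(ctx.W[best])
        ys = sw * y_rot
        cs = sw * ctx.c
        Zs = sw[:, None] * ctx.Z_rot
        cc = cs @ cs
        y_t = ys - cs * (cs @ ys) / cc
        Z_t = Zs - cs[:, None] * ((cs @ Zs) / cc)[None, :]
        rss0 = float(y_t @ y_t)
        b = Z_t.T @ y_t
        zz = np.einsum("ij,ij->j", Z_t, Z_t)
        ok = zz > 1e-10 * n
        with np.errstate(divide="ignore", invalid="ignore"):
            rss1 = np.where(ok, rss0 - b**2 / np.where(ok, zz, 1.0), rss0)
            rss1 = np.maximum(rss1, 1e-300)
            lod = np.where(ok, (n / 2.0) * np.log10(rss0 / rss1), 0.0)
            effect = np.where(ok, b / np.where(ok, zz, 1.0), 0.0)
        if rss0 <= 0:
            lod = np.zeros_like(lod)
            effect = np.zeros_like(effect)
        return h2, lod, effect

    def scan(self, y: np.ndarray | pd.Series) -> ScanResult:
        """Genome scan of one phenotype vector (aligned to the panel)."""
        y = np.asarray(y, dtype=float)
        if y.shape != (self.n,):
            raise ValueError(f"phenotype length {y.shape} != {self.n} samples")
        if np.any(np.isnan(y)):
            raise ValueError("phenotype vector has missing values")
        frames = []
        h2_by_chrom = {}
        for c, ctx in self.contexts.items():
            snps = np.flatnonzero(self.matrix.chrom == c)
            h2, lod, effect = self._fit_chromosome(ctx, y)
            h2_by_chrom[c] = h2
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": self.matrix.chrom[snps],
                        "pos": self.matrix.pos[snps],
                        "lod": lod,
                        "effect": effect,
                    }
                )
            )
        return ScanResult(pd.concat(frames, ignore_index=True), h2_by_chrom)

    def max_lod(self, y: np.ndarray) -> float:
        """Genome-wide maximum LOD (fast path used by permutations)."""
        best = 0.0
        for ctx in self.contexts.values():
            _, lod, _ = self._fit_chromosome(ctx, y)
            m = float(lod.max()) if len(lod) else 0.0
            best = max(best, m)
        return best


def permutation_threshold(
    scanner: LmmScanner,
    y: np.ndarray | pd.Series,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> tuple[float, np.ndarray]:
    """Genome-wide LOD threshold from phenotype permutations.

    The phenotype vector is permuted across samples ``n_perm`` times; each
    permutation is rescanned (variance components re-estimated) and its
    genome-wide maximum LOD recorded.  The threshold is the order statistic
    of rank ``ceil((1 - alpha) * n_perm)`` of those maxima.  Returns
    ``(threshold, maxima)``.
    """
    if n_perm < 20:
        raise ValueError("need at least 20 permutations")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    maxima = np.empty(n_perm)
    for p in range(n_perm):
        maxima[p] = scanner.max_lod(rng.permutation(y))
    rank = int(np.ceil((1.0 - alpha) * n_perm))
    threshold = float(np.sort(maxima)[rank - 1])
    return threshold, maxima


def pve_from_lod(lod: float, n: int) -> float:
    """Percent of phenotypic variance explained at a locus.

    Uses the likelihood-ratio relation ``PVE = 1 - exp(-2 dLL / n)`` with
    ``dLL = lod * ln 10``; returned on the percent scale.
    """
    return float((1.0 - 10.0 ** (-2.0 * lod / n)) * 100.0)


def variance_explained(scanner: LmmScanner, y: np.ndarray, chrom: str, pos: int) -> float:
    """PVE (percent) of the SNP at ``chrom:pos`` for phenotype ``y``."""
    result = scanner.scan(y)
    row = result.table[(result.table["chrom"] == chrom) & (result.table["pos"] == pos)]
    if len(row) == 0:
        raise ValueError(f"no SNP at {chrom}:{pos}")
    return pve_from_lod(float(row["lod"].iloc[0]), scanner.n)


def call_qtl(
    scan: ScanResult,
    threshold: float,
    n_samples: int,
    window_bp: int = 100_000,
    annotation: pd.DataFrame | None = None,
    trait: str = "",
    environment: str = "",
) -> list[QTLRecord]:
    """Group significant SNPs into QTL around descending-LOD peaks.

    Each QTL is a peak SNP plus every significant SNP within
    ``window_bp / 2`` of it on the same chromosome; its candidate window is
    the peak +/- ``window_bp / 2`` (truncated at position 1).  When a gene
    annotation table (chrom, start, end, gene_id) is supplied, genes whose
    span intersects the window are listed.
    """
    sig = scan.table[scan.table["lod"] >= threshold].copy()
    records: list[QTLRecord] = []
    half = window_bp // 2
    while len(sig):
        peak = sig.loc[sig["lod"].idxmax()]
        same = sig["chrom"] == peak["chrom"]
        near = same & ((sig["pos"] - peak["pos"]).abs() <= half)
        members = sorted(int(p) for p in sig.loc[near, "pos"])
        win_start = max(1, int(peak["pos"]) - half)
        win_end = int(peak["pos"]) + half
        genes: list[str] = []
        if annotation is not None:
            hits = annotation[
                (annotation["chrom"] == peak["chrom"])
                & (annotation["start"] <= win_end)
                & (annotation["end"] >= win_start)
            ]
            genes = list(hits["gene_id"])
        records.append(
            QTLRecord(
                trait=trait,
                environment=environment,
                chrom=str(peak["chrom"]),
                peak_pos=int(peak["pos"]),
                peak_lod=float(peak["lod"]),
                window_start=win_start,
                window_end=win_end,
                pve_percent=pve_from_lod(float(peak["lod"]), n_samples),
                member_positions=members,
                genes=genes,
            )
        )
        sig = sig[~near]
    return records


def gxe_response(
    trait_means: pd.DataFrame, env_a: str, env_b: str, samples: list[str]
) -> np.ndarray:
    """Per-genotype environment difference ``mean_B - mean_A`` aligned to
    ``samples``; genotypes missing in either environment are an error (drop
    them from the panel first)."""
    pivot = trait_means.pivot_table(
        index="genotype", columns="environment", values="value", aggfunc="mean"
    )
    missing = [
        s for s in samples
        if s not in pivot.index
        or pd.isna(pivot.loc[s].get(env_a))
        or pd.isna(pivot.loc[s].get(env_b))
    ]
    if missing:
        raise ValueError(
            f"genotypes missing a trait mean in one environment: {missing[:5]}"
        )
    return (pivot.loc[samples, env_b] - pivot.loc[samples, env_a]).to_numpy()
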