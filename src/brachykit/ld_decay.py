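"""Linkage-disequilibrium decay in consecutive SNP windows.

Within each window of 2000 consecutive SNPs, r-squared (squared Pearson
correlation of allele counts over jointly observed samples) is computed for
every SNP pair, binned by physical distance, and the half-decay distance —
the nearest distance at which mean r-squared falls to half the first bin's
mean — is extracted.  Genome-wide LD is summarised as the median and
interquartile range of half-decay distances over windows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeMatrix

__all__ = [
    "LDDecayResult",
    "pairwise_r2",
    "half_decay",
    "genome_ld_summary",
]

#: r-squared is unstable on fewer joint samples than this; such pairs are
#: skipped.
MIN_JOINT_SAMPLES = 10


@dataclass
class LDDecayResult:
    windows: pd.DataFrame        # chrom, snp_start, snp_end, bp_span, r2_max, half_decay_bp
    median_half_decay_bp: float  # NaN when no window has a defined decay
    iqr_half_decay_bp: tuple[float, float]


def pairwise_r2(
    matrix: GenotypeMatrix, snp_index: np.ndarray | None = None
) -> pd.DataFrame:
    """All-pairs (distance, r2) within one window of SNPs.

    Pairs with fewer than ``MIN_JOINT_SAMPLES`` jointly observed samples or
    zero variance at either SNP are dropped.  Returns columns ``distance_bp``
    and ``r2``.
    """
    sub = matrix if snp_index is None else matrix.take_snps(snp_index)
    if sub.n_snps < 2:
        return pd.DataFrame({"distance_bp": [], "r2": []})
    if len(set(sub.chrom)) > 1:
        raise ValueError("r2 window must lie within one chromosome")
    X = (sub.calls.T / 2.0).astype(np.float64)       # (m, n) allele dose {0,1}
    M = (sub.calls.T != MISSING).astype(np.float64)
    A = np.where(sub.calls.T == MISSING, 0.0, X)
    n = M @ M.T                                       # joint counts
    s_x = A @ M.T                                     # sum x_j over joint obs
    s_xy = A @ A.T
    with np.errstate(invalid="ignore", divide="ignore"):
        n_safe = np.maximum(n, 1.0)
        cov = s_xy - s_x * s_x.T / n_safe
        var_x = s_x - s_x**2 / n_safe                 # x in {0,1} so x^2 = x
        var_y = var_x.T
        r2 = cov**2 / (var_x * var_y)
    valid = (n >= MIN_JOINT_SAMPLES) & (var_x > 0) & (var_y > 0)
    iu = np.triu_indices(sub.n_snps, k=1)
    keep = valid[iu]
    dist = np.abs(sub.pos[iu[0]] - sub.pos[iu[1]])
    return pd.DataFrame({"distance_bp": dist[keep], "r2": r2[iu][keep]})


def half_decay(pairs: pd.DataFrame, bin_bp: int = 1000) -> tuple[float, float]:
    """Distance at which binned mean r2 first drops to half its maximum.

    Pairs are binned by distance (``bin_bp`` wide); ``r2_max`` is the mean
    r2 of the first populated bin; the half-decay distance is the midpoint
    of the nearest later bin whose mean r2 is at most ``r2_max / 2``.
    Returns ``(r2_max, half_decay_bp)``; the distance is NaN when the decay
    level is never reached (including the single-populated-bin case).
    """
    if len(pairs) == 0:
        return np.nan, np.nan
    bins = (pairs["distance_bp"].to_numpy() // bin_bp).astype(int)
    means = pd.Series(pairs["r2"].to_numpy()).groupby(bins).mean()
    first = means.index[0]
    r2_max = float(means.iloc[0])
    for b, m in means.iloc[1:].items():
        if m <= r2_max / 2.0:
            return r2_max, float(b * bin_bp + bin_bp / 2.0)
    return r2_max, np.nan


def genome_ld_summary(
    matrix: GenotypeMatrix, window_snps: int = 2000, bin_bp: int = 1000
) -> LDDecayResult:
    """Half-decay distances over consecutive non-overlapping SNP windows.

    Windows never span chromosomes; a partial window at a chromosome end is
    processed as-is.  The genome summary (median, IQR) covers only windows
    with a defined half-decay.
    """
    rows = []
    for c in matrix.chromosomes():
        idx = np.flatnonzero(matrix.chrom == c)
        for start in range(0, len(idx), window_snps):
            window = idx[start : start + window_snps]
            if len(window) < 2:
                continue
            pairs = pairwise_r2(matrix, window)
            r2_max, hd = half_decay(pairs, bin_bp=bin_bp)
            rows.append(
                {
                    "chrom": c,
                    "snp_start": int(window[0]),
                    "snp_end": int(window[-1]),
                    "bp_span": int(matrix.pos[window[-1]] - matrix.pos[window[0]]),
                    "r2_max": r2_max,
                    "half_decay_bp": hd,
                }
            )
    windows = pd.DataFrame(rows)
    defined = windows["half_decay_bp"].dropna() if len(windows) else pd.Series(dtype=float)
    if len(defined) == 0:
        warnings.warn("no window reached half-maximal r2; summary is empty", stacklevel=2)
        return LDDecayResult(windows, np.nan, (np.nan, np.nan))
    return LDDecayResult(
        windows,
        float(defined.median()),
        (float(defined.quantile(0.25)), float(defined.quantile(0.75))),
    )
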