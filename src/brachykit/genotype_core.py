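"""Variant filtering, IBS distance and genotype-lineage clustering.

The panel is highly inbred, so calls are coded {0, 2, missing}; heterozygous
calls surviving upstream are treated as genotyping error and recoded missing
under the default policy.  Pairwise identity-by-state (IBS) distance over
jointly observed SNPs drives both lineage clustering (which technical
replicates / clones belong to the same inbred genotype) and the kinship
matrix used later by the mixed-model scan.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .core import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "DistanceMatrix",
    "GenotypeClustering",
    "filter_variants",
    "ibs_distance",
    "cluster_lineages",
    "retain_replicates",
    "fixed_divergence",
]


@dataclass
class DistanceMatrix:
    """Symmetric IBS distance matrix with per-pair joint-observation counts."""

    samples: list[str]
    values: np.ndarray          # (n, n) distances in [0, 1], zero diagonal
    joint_counts: np.ndarray    # (n, n) number of jointly observed SNPs

    def __post_init__(self) -> None:
        n = len(self.samples)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise ValueError("distance matrix not symmetric")


@dataclass
class GenotypeClustering:
    assignment: dict[str, int]      # sample -> lineage id (1-based)
    cut_height: float | None
    z: float

    def members(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for s, g in self.assignment.items():
            out.setdefault(g, []).append(s)
        return out

    @property
    def n_lineages(self) -> int:
        return len(set(self.assignment.values()))


# ----------------------------------------------------------------------
def filter_variants(
    matrix: GenotypeMatrix,
    min_quality: float = 20.0,
    min_maf: float = 0.02,
    het_policy: str = "to_missing",
) -> GenotypeMatrix:
    """Apply the WGS-style variant filters.

    Heterozygous calls are recoded first (policy ``to_missing`` or ``keep``),
    then SNPs failing ``quality > min_quality`` (when qualities are present)
    or ``MAF >= min_maf`` are dropped.  MAF is computed on non-missing calls.
    """
    if het_policy not in ("to_missing", "keep"):
        raise ValueError(f"unknown het policy {het_policy!r}")
    out = matrix.copy()
    if het_policy == "to_missing":
        n_het = int(np.sum(out.calls == 1))
        if n_het:
            out.calls[out.calls == 1] = MISSING
            logger.info("recoded %d heterozygous calls to missing", n_het)

    keep = np.ones(out.n_snps, dtype=bool)
    if out.qual is not None and min_quality > 0:
        qual_ok = np.nan_to_num(np.asarray(out.qual, float), nan=np.inf) > min_quality
        logger.info("dropping %d SNPs on quality", int(np.sum(~qual_ok)))
        keep &= qual_ok
    if min_maf > 0:
        maf_ok = out.maf() >= min_maf
        logger.info("dropping %d SNPs on MAF", int(np.sum(keep & ~maf_ok)))
        keep &= maf_ok
    result = out.take_snps(np.flatnonzero(keep))
    if result.n_snps == 0:
        warnings.warn("all SNPs removed by variant filters", stacklevel=2)
    return result


def ibs_distance(
    matrix: GenotypeMatrix, allow_undefined: bool = False
) -> DistanceMatrix:
    """Pairwise IBS distance: mean of ``|g_i - g_j| / 2`` over joint SNPs.

    With the inbred {0, 2} coding each jointly observed SNP contributes 0
    (identical) or 1 (opposite homozygotes); heterozygotes, if retained,
    contribute 1/2 against either homozygote.  Pairs with zero jointly
    observed SNPs are an error unless ``allow_undefined`` (then NaN).
    """
    if matrix.n_samples < 2:
        raise ValueError("need at least two samples")
    G = matrix.calls.astype(np.float64)
    obs = (matrix.calls != MISSING).astype(np.float64)
    V = np.where(matrix.calls == MISSING, 0.0, G / 2.0)
    S = V * V
    # sum over joint SNPs of (v_i - v_j)^2 == sum |g_i-g_j|/2 for {0,1} values;
    # for heterozygote 1/2 values the |.|/2 reading needs the absolute value,
    # handled below only when hets are present.
    joint = obs @ obs.T
    if np.any(matrix.calls == 1):
        n = matrix.n_samples
        num = np.zeros((n, n))
        for i in range(n):
            # V is g/2, so |V_i - V_j| is already |g_i - g_j|/2
            diff = np.abs(V[i] - V) * (obs[i] * obs)
            num[i] = diff.sum(axis=1)
    else:
        num = S @ obs.T + obs @ S.T - 2.0 * (V @ V.T)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(joint > 0, num / np.maximum(joint, 1), np.nan)
    np.fill_diagonal(d, 0.0)
    d = np.clip(d, 0.0, 1.0, out=d)
    d = (d + d.T) / 2.0
    undefined = (joint == 0) & ~np.eye(matrix.n_samples, dtype=bool)
    if np.any(undefined) and not allow_undefined:
        i, j = np.argwhere(undefined)[0]
        raise ValueError(
            f"no jointly observed SNPs for pair ({matrix.samples[i]}, "
            f"{matrix.samples[j]}); pass allow_undefined to get NaN"
        )
    d[undefined] = np.nan
    return DistanceMatrix(
        samples=list(matrix.samples), values=d, joint_counts=joint.astype(int)
    )


def cluster_lineages(dist: DistanceMatrix, z: float = 3.5) -> GenotypeClustering:
    """Cut a single-linkage dendrogram at the first outlying merge height.

    Merge heights are scanned in increasing order; each height is compared,
    as a z-score, against the running mean and standard deviation of the
    heights already accepted.  The first height whose z-score exceeds ``z``
    defines the cut; connected components below it are the genotype
    lineages.  With fewer than 3 merges (or no outlier) everything is one
    lineage.
    """
    if np.any(np.isnan(dist.values)):
        raise ValueError("distance matrix has undefined pairs")
    n = len(dist.samples)
    if n < 2:
        return GenotypeClustering({s: 1 for s in dist.samples}, None, z)
    Z = linkage(squareform(dist.values, checks=False), method="single")
    heights = Z[:, 2]
    cut_height: float | None = None
    if len(heights) >= 3:
        for i in range(2, len(heights)):
            prior = heights[:i]
            sd = float(np.std(prior, ddof=1))
            mean = float(np.mean(prior))
            if sd == 0.0:
                # exact height ties happen only for duplicate samples; demand
                # a real gap (1% IBS) before calling the jump an outlier
                if heights[i] - mean > 0.01:
                    cut_height = float(heights[i])
                    break
                continue
            if (heights[i] - mean) / sd > z:
                cut_height = float(heights[i])
                break
    else:
        logger.info("fewer than 3 merges; all samples in one lineage")
    if cut_height is None:
        labels = np.ones(n, dtype=int)
    else:
        labels = fcluster(Z, t=cut_height * (1 - 1e-12), criterion="distance")
    # relabel lineages deterministically by first-sample appearance
    remap: dict[int, int] = {}
    assignment: dict[str, int] = {}
    for s, lab in zip(dist.samples, labels):
        remap.setdefault(int(lab), len(remap) + 1)
        assignment[s] = remap[int(lab)]
    return GenotypeClustering(assignment, cut_height, z)


def retain_replicates(
    clustering: GenotypeClustering,
    accession_of: dict[str, str],
    missingness: dict[str, float],
) -> set[str]:
    """Resolve accessions whose replicates split across lineages.

    Per accession: keep the replicates in the lineage holding the majority of
    that accession's replicates; on a tie keep the single replicate with the
    lowest missing-data fraction.
    """
    kept: set[str] = set()
    by_accession: dict[str, list[str]] = {}
    for sample in clustering.assignment:
        if sample not in accession_of:
            raise ValueError(f"sample {sample!r} has no accession label")
        by_accession.setdefault(accession_of[sample], []).append(sample)
    for _, samples in by_accession.items():
        counts: dict[int, list[str]] = {}
        for s in samples:
            counts.setdefault(clustering.assignment[s], []).append(s)
        max_n = max(len(v) for v in counts.values())
        majority = [g for g, v in counts.items() if len(v) == max_n]
        if len(majority) == 1:
            kept.update(counts[majority[0]])
        else:
            tied = [s for g in majority for s in counts[g]]
            kept.add(min(tied, key=lambda s: (missingness[s], s)))
    return kept


def fixed_divergence(
    matrix: GenotypeMatrix, groups: dict[str, int] | list[int] | np.ndarray
) -> float:
    """Fraction of SNPs fixed-different between two groups of samples.

    A SNP counts when every non-missing call in one group is one homozygote
    and every non-missing call in the other group is the opposite homozygote,
    with at least one observed call per group.  The denominator is the number
    of SNPs with at least one observed call in each group.
    """
    if isinstance(groups, dict):
        g = np.array([groups[s] for s in matrix.samples])
    else:
        g = np.asarray(groups)
    labels = np.unique(g)
    if len(labels) != 2:
        raise ValueError("exactly two groups required")
    masks = [g == lab for lab in labels]
    obs = matrix.calls != MISSING
    stats = []
    for m in masks:
        sub = matrix.calls[m]
        sub_obs = obs[m]
        n_obs = sub_obs.sum(axis=0)
        all0 = np.all((sub == 0) | ~sub_obs, axis=0) & (n_obs > 0)
        all2 = np.all((sub == 2) | ~sub_obs, axis=0) & (n_obs > 0)
        stats.append((n_obs, all0, all2))
    both_observed = (stats[0][0] > 0) & (stats[1][0] > 0)
    if not np.any(both_observed):
        raise ValueError("no SNP observed in both groups")
    fixed = (stats[0][1] & stats[1][2]) | (stats[0][2] & stats[1][1])
    return float(np.sum(fixed & both_observed) / np.sum(both_observed))
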