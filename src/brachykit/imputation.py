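"""GWAS-preparation chain: pruning, MAF ladder, adjacent fill, NN imputation.

The chain mirrors how a sparse inbred GBS/WGS call set is made scan-ready:

1. drop non-variant SNPs and redundant adjacent duplicates (keeping the copy
   with fewer missing calls);
2. pre-imputation MAF filter (<3% out);
3. adjacent-SNP fill: where two neighbouring SNPs carry identical observed
   genotypes, each one's missing calls are copied from the other;
4. windowed nearest-neighbour imputation: similarity between accessions over
   the 50 SNPs flanking each side of the target SNP, majority genotype of
   the five most similar accessions with an observed call;
5. post-imputation MAF filter (<5% out).

A masking-based evaluator measures the fraction of held-out calls restored.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "ImputationConfig",
    "prune_redundant",
    "adjacent_fill",
    "nn_impute",
    "maf_ladder",
    "evaluate_imputation",
    "run_ladder",
]


@dataclass
class ImputationConfig:
    flank_snps: int = 50
    k_neighbors: int = 5
    maf_pre: float = 0.03
    maf_post: float = 0.05

    def validate(self) -> None:
        if self.flank_snps < 1 or self.k_neighbors < 1:
            raise ValueError("flank_snps and k_neighbors must be >= 1")
        if not 0.0 <= self.maf_pre <= self.maf_post <= 0.5:
            raise ValueError("need 0 <= maf_pre <= maf_post <= 0.5")


# ----------------------------------------------------------------------
def _pairs_identical(a: np.ndarray, b: np.ndarray) -> bool:
    """True when two SNP columns agree at every jointly observed sample,
    with at least one such sample."""
    joint = (a != MISSING) & (b != MISSING)
    return bool(np.any(joint)) and bool(np.all(a[joint] == b[joint]))


def prune_redundant(matrix: GenotypeMatrix) -> GenotypeMatrix:
    """Drop non-variant SNPs, then collapse redundant adjacent duplicates.

    A SNP is non-variant when its observed calls carry no minor allele.  For
    each adjacent pair (within a chromosome) identical at every jointly
    observed sample, the member with more missing calls is dropped (tie:
    the downstream one goes).  The pass is left-to-right: the surviving
    member is compared against the next SNP in turn.
    """
    obs = matrix.observed()
    n_obs = obs.sum(axis=0)
    alt = np.where(obs, matrix.calls, 0).sum(axis=0)
    variant = (n_obs > 0) & (alt > 0) & (alt < 2 * n_obs)
    out = matrix.take_snps(np.flatnonzero(variant))

    missing_per_snp = np.sum(out.calls == MISSING, axis=0)
    keep = np.ones(out.n_snps, dtype=bool)
    for c in out.chromosomes():
        idx = np.flatnonzero(out.chrom == c)
        current = 0
        for nxt in range(1, len(idx)):
            a, b = idx[current], idx[nxt]
            if _pairs_identical(out.calls[:, a], out.calls[:, b]):
                if missing_per_snp[a] > missing_per_snp[b]:
                    keep[a] = False
                    current = nxt
                else:  # tie drops the downstream member
                    keep[b] = False
            else:
                current = nxt
    dropped = int(np.sum(~keep))
    if dropped:
        logger.info("prune_redundant: dropped %d adjacent duplicates", dropped)
    return out.take_snps(np.flatnonzero(keep))


def adjacent_fill(matrix: GenotypeMatrix) -> GenotypeMatrix:
    """Copy missing calls between identical adjacent SNPs.

    One left-to-right pass per chromosome: for each adjacent pair whose
    observed genotypes agree at every jointly observed sample, a call
    missing at one SNP but observed at the other is copied across (in both
    directions).  Fills never cross chromosome boundaries.
    """
    out = matrix.copy()
    for c in out.chromosomes():
        idx = np.flatnonzero(out.chrom == c)
        for k in range(len(idx) - 1):
            a, b = idx[k], idx[k + 1]
            ca, cb = out.calls[:, a], out.calls[:, b]
            if _pairs_identical(ca, cb):
                fill_b = (cb == MISSING) & (ca != MISSING)
                fill_a = (ca == MISSING) & (cb != MISSING)
                out.calls[fill_b, b] = ca[fill_b]
                out.calls[fill_a, a] = cb[fill_a]
    return out


# ----------------------------------------------------------------------
def _window_similarity(
    calls: np.ndarray, window: np.ndarray, targets: np.ndarray
) -> np.ndarray:
    """Agreement fraction between ``targets`` rows and all samples over the
    window SNPs (NaN when no joint observations)."""
    W = calls[:, window]
    obs = (W != MISSING).astype(np.float64)
    v = np.where(W == MISSING, 0, W // 2).astype(np.float64)  # {0,1}
    p = v * obs
    q = (1.0 - v) * obs
    agree = p[targets] @ p.T + q[targets] @ q.T
    joint = obs[targets] @ obs.T
    with np.errstate(invalid="ignore"):
        return np.where(joint > 0, agree / np.maximum(joint, 1), np.nan)


def nn_impute(
    matrix: GenotypeMatrix, cfg: ImputationConfig | None = None
) -> GenotypeMatrix:
    """Windowed nearest-neighbour imputation of missing calls.

    For each missing call (sample s, SNP j): accession similarity is the
    agreement fraction over up to ``flank_snps`` SNPs on each side of j
    within the chromosome; the ``k_neighbors`` most similar accessions with
    an observed call at j vote, and the majority genotype is imputed.  Vote
    ties are resolved by extending to the next-closest observed accession;
    similarity ties break by sample order.  Only original calls are read, so
    the result is independent of the SNP visit order, and observed calls are
    never altered.  Calls no neighbour can inform stay missing.
    """
    cfg = cfg or ImputationConfig()
    cfg.validate()
    if np.any(matrix.calls == 1):
        raise ValueError("heterozygous calls present; recode them first")
    out = matrix.copy()
    original = matrix.calls  # votes read these, never fresh imputations
    n = matrix.n_samples
    left_missing = 0
    for c in matrix.chromosomes():
        idx = np.flatnonzero(matrix.chrom == c)
        for w, j in enumerate(idx):
            col = original[:, j]
            targets = np.flatnonzero(col == MISSING)
            if len(targets) == 0:
                continue
            lo = max(w - cfg.flank_snps, 0)
            window = np.concatenate([idx[lo:w], idx[w + 1 : w + 1 + cfg.flank_snps]])
            if len(window) == 0:
                left_missing += len(targets)
                continue
            sim = _window_similarity(original, window, targets)
            observed_at_j = col != MISSING
            for row, s in enumerate(targets):
                sims = sim[row]
                valid = observed_at_j & ~np.isnan(sims)
                valid[s] = False
                cand = np.flatnonzero(valid)
                if len(cand) == 0:
                    left_missing += 1
                    continue
                order = cand[np.lexsort((cand, -sims[cand]))]
                votes = {0: 0, 2: 0}
                decided = None
                for rank, t in enumerate(order):
                    votes[int(col[t])] += 1
                    if rank + 1 >= cfg.k_neighbors and votes[0] != votes[2]:
                        decided = 0 if votes[0] > votes[2] else 2
                        break
                if decided is None:
                    if votes[0] != votes[2]:
                        decided = 0 if votes[0] > votes[2] else 2
                    else:
                        left_missing += 1
                        continue
                out.calls[s, j] = decided
    if left_missing:
        logger.info("nn_impute: %d calls left missing", left_missing)
    return out


def maf_ladder(matrix: GenotypeMatrix, stage: str, cfg: ImputationConfig | None = None) -> GenotypeMatrix:
    """Staged MAF filter: drop SNPs with MAF strictly below the threshold
    (3% before imputation, 5% after, by default)."""
    cfg = cfg or ImputationConfig()
    cfg.validate()
    if stage not in ("pre", "post"):
        raise ValueError("stage must be 'pre' or 'post'")
    threshold = cfg.maf_pre if stage == "pre" else cfg.maf_post
    keep = matrix.maf() >= threshold
    return matrix.take_snps(np.flatnonzero(keep))


def run_ladder(
    matrix: GenotypeMatrix, cfg: ImputationConfig | None = None
) -> GenotypeMatrix:
    """Full preparation ladder: prune, MAF-pre, adjacent fill, NN impute,
    MAF-post."""
    cfg = cfg or ImputationConfig()
    out = prune_redundant(matrix)
    out = maf_ladder(out, "pre", cfg)
    out = adjacent_fill(out)
    out = nn_impute(out, cfg)
    return maf_ladder(out, "post", cfg)


def evaluate_imputation(
    matrix: GenotypeMatrix,
    mask_rate: float,
    cfg: ImputationConfig | None = None,
    seed: int = 0,
) -> float:
    """Mask observed calls at ``mask_rate``, re-impute, return the fraction
    restored to the held-out truth.

    Calls the imputer leaves missing count as failures.  Only the fill and
    NN stages run on the masked matrix (the SNP set is held fixed so masked
    truth and imputed calls stay aligned).
    """
    if not 0.0 < mask_rate < 1.0:
        raise ValueError("mask_rate must be in (0, 1)")
    cfg = cfg or ImputationConfig()
    rng = np.random.default_rng(seed)
    obs = matrix.observed()
    if not np.any(obs):
        raise ValueError("no observed calls to mask")
    mask = obs & (rng.random(matrix.calls.shape) < mask_rate)
    masked = matrix.copy()
    masked.calls[mask] = MISSING
    imputed = nn_impute(adjacent_fill(masked), cfg)
    restored = np.sum((imputed.calls[mask] == matrix.calls[mask]))
    return float(restored / np.sum(mask))
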