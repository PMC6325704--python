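"""Core genotype container shared by every stage of the pipeline.

Genotype calls use the inbred coding: 0 = reference homozygote,
2 = alternate homozygote, 1 = heterozygote (only present before WGS-style
filtering), and ``MISSING`` (-1) for no-calls.  Samples are rows, SNPs are
columns; SNP coordinates are 1-based and strictly increasing within a
chromosome, following the VCF convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

MISSING: int = -1

__all__ = ["MISSING", "GenotypeMatrix"]


@dataclass
class GenotypeMatrix:
    """Samples x biallelic-SNPs call matrix with genomic coordinates.

    Parameters
    ----------
    samples
        Sample identifiers, one per row of ``calls``.
    chrom
        Chromosome name per SNP.
    pos
        1-based position per SNP, strictly increasing within chromosome.
    calls
        ``(n_samples, n_snps)`` int8 array in {0, 1, 2, MISSING}.
    ref, alt
        Optional allele labels per SNP.
    qual
        Optional per-SNP variant quality.
    """

    samples: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    calls: np.ndarray
    ref: np.ndarray | None = None
    alt: np.ndarray | None = None
    qual: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.pos)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.samples)} samples x {len(self.pos)} SNPs"
            )
        if len(self.chrom) != len(self.pos):
            raise ValueError("chrom and pos length mismatch")
        for c in np.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on {c}")

    # ------------------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.pos)

    def observed(self) -> np.ndarray:
        """Boolean mask of non-missing calls."""
        return self.calls != MISSING

    def missing_fraction_per_sample(self) -> np.ndarray:
        if self.n_snps == 0:
            return np.zeros(self.n_samples)
        return np.mean(self.calls == MISSING, axis=1)

    def maf(self) -> np.ndarray:
        """Minor allele frequency per SNP, computed on non-missing calls.

        Heterozygotes (code 1) contribute one alternate allele; homozygotes
        contribute zero or two.  SNPs with no observed calls get MAF 0.
        """
        obs = self.observed()
        n_obs = obs.sum(axis=0)
        alt_dose = np.where(obs, self.calls, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p_alt = np.where(n_obs > 0, alt_dose / (2.0 * n_obs), 0.0)
        return np.minimum(p_alt, 1.0 - p_alt)

    # ------------------------------------------------------------------
    def take_snps(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return replace(
            self,
            chrom=self.chrom[index],
            pos=self.pos[index],
            calls=self.calls[:, index],
            ref=None if self.ref is None else np.asarray(self.ref)[index],
            alt=None if self.alt is None else np.asarray(self.alt)[index],
            qual=None if self.qual is None else np.asarray(self.qual)[index],
        )

    def take_samples(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return replace(
            self,
            samples=[self.samples[i] for i in index],
            calls=self.calls[index, :],
        )

    def copy(self) -> "GenotypeMatrix":
        return replace(self, calls=self.calls.copy())

    def chromosomes(self) -> list[str]:
        """Chromosome names in order of first appearance."""
        seen: dict[str, None] = {}
        for c in self.chrom:
            seen.setdefault(c, None)
        return list(seen)
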