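"""Coverage-based species assignment within the Brachypodium complex.

GBS reads from each accession are aligned to a B. hybridum pseudoreference
(the concatenated B. distachyon and B. stacei genomes).  The fraction of each
chromosome covered by at least three uniquely-mapped reads separates the two
diploids (reads pile on one subgenome only) from the allotetraploid
B. hybridum (reads on both).  A normalized distachyon proportion
``p_d / (p_d + p_s)`` is thresholded into five classes, with an extra
low-coverage class for samples with fewer than 100,000 reads in total.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CoverageSummary",
    "SpeciesCall",
    "MIN_TOTAL_READS",
    "LABELS_IN_ORDER",
    "depth_to_covered_fraction",
    "aggregate_subgenomes",
    "normalize_proportion",
    "classify_species",
    "classify_summaries",
]

#: Below this read total a sample is called ``low_coverage`` outright.
MIN_TOTAL_READS = 100_000

#: Class labels in order of increasing normalized distachyon proportion.
LABELS_IN_ORDER = (
    "stacei",
    "intermediate_stacei_hybridum",
    "hybridum",
    "intermediate_hybridum_distachyon",
    "distachyon",
)

# Upper bounds of the normalized-proportion classes.  The first three are
# strict ("<"), the fourth is inclusive ("<=") so that distachyon is the
# class stays the strict ">0.94".
_BOUNDS = (0.03, 0.28, 0.34, 0.94)


@dataclass
class CoverageSummary:
    """Per-chromosome covered fractions and total read count for one sample."""

    sample: str
    covered_fraction: dict[str, float] = field(default_factory=dict)
    total_reads: int = 0

    def __post_init__(self) -> None:
        for c, f in self.covered_fraction.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"covered fraction {f} for {c} outside [0,1]")
        if self.total_reads < 0:
            raise ValueError("total_reads must be non-negative")


@dataclass
class SpeciesCall:
    sample: str
    p_distachyon: float
    p_stacei: float
    normalized_proportion: float
    label: str


def depth_to_covered_fraction(
    depth_records: pd.DataFrame,
    chromosome_lengths: dict[str, int],
    sample: str = "",
    total_reads: int = 0,
    min_depth: int = 3,
) -> CoverageSummary:
    """Collapse BED-like depth records into per-chromosome covered fractions.

    ``depth_records`` needs columns ``chrom``, ``start``, ``end`` (0-based
    half-open, as in BED), ``depth`` and ``unique`` (truthy when the depth
    comes from uniquely-mapped reads).  A position counts as covered when its
    unique-read depth is at least ``min_depth``; positions absent from the
    records count as depth 0, and multimapper-flagged records are ignored
    entirely.
    """
    required = {"chrom", "start", "end", "depth", "unique"}
    if not required.issubset(depth_records.columns):
        raise ValueError(f"depth records need columns {sorted(required)}")
    covered_bp = {c: 0 for c in chromosome_lengths}
    for rec in depth_records.itertuples(index=False):
        if rec.chrom not in chromosome_lengths:
            raise ValueError(f"unknown chromosome {rec.chrom!r} in depth records")
        length = chromosome_lengths[rec.chrom]
        if rec.end > length or rec.start < 0:
            raise ValueError(
                f"record {rec.start}-{rec.end} beyond length of {rec.chrom}"
            )
        if bool(rec.unique) and rec.depth >= min_depth:
            covered_bp[rec.chrom] += rec.end - rec.start
    fractions = {
        c: covered_bp[c] / chromosome_lengths[c] for c in chromosome_lengths
    }
    return CoverageSummary(
        sample=sample, covered_fraction=fractions, total_reads=total_reads
    )


def aggregate_subgenomes(
    cov: CoverageSummary,
    subgenome_map: dict[str, str],
    chromosome_lengths: dict[str, int] | None = None,
) -> tuple[float, float]:
    """Length-weighted mean covered fraction per subgenome.

    Returns ``(p_distachyon, p_stacei)``.  With no ``chromosome_lengths``
    all chromosomes weigh equally.
    """
    sums = {"distachyon": 0.0, "stacei": 0.0}
    weights = {"distachyon": 0.0, "stacei": 0.0}
    for chrom, frac in cov.covered_fraction.items():
        if chrom not in subgenome_map:
            raise ValueError(f"chromosome {chrom!r} missing from subgenome map")
        sub = subgenome_map[chrom]
        if sub not in sums:
            raise ValueError(f"unknown subgenome label {sub!r}")
        w = 1.0 if chromosome_lengths is None else float(chromosome_lengths[chrom])
        sums[sub] += w * frac
        weights[sub] += w
    if weights["distachyon"] == 0 or weights["stacei"] == 0:
        raise ValueError("both subgenomes must be represented in the map")
    return sums["distachyon"] / weights["distachyon"], sums["stacei"] / weights["stacei"]


def normalize_proportion(p_distachyon: float, p_stacei: float) -> float:
    """Normalized distachyon proportion ``p_d / (p_d + p_s)`` in [0, 1]."""
    if p_distachyon < 0 or p_stacei < 0:
        raise ValueError("subgenome proportions must be non-negative")
    total = p_distachyon + p_stacei
    if total == 0:
        raise ZeroDivisionError(
            "both subgenome proportions are zero; treat sample as low coverage"
        )
    return p_distachyon / total


def classify_species(normalized: float, total_reads: int) -> str:
    """Threshold-group species label for one sample.

    ``low_coverage`` pre-empts everything below 100,000 total reads; otherwise
    the label is a step function of the normalized distachyon proportion:
    stacei (<0.03), intermediate stacei/hybridum (<0.28), hybridum (<0.34),
    intermediate hybridum/distachyon (<=0.94), distachyon (>0.94).
    """
    if not 0.0 <= normalized <= 1.0:
        raise ValueError(f"normalized proportion {normalized} outside [0,1]")
    if total_reads < MIN_TOTAL_READS:
        return "low_coverage"
    for label, bound in zip(LABELS_IN_ORDER, _BOUNDS):
        if normalized < bound:
            return label
    if normalized <= _BOUNDS[-1]:
        return LABELS_IN_ORDER[-2]
    return LABELS_IN_ORDER[-1]


def classify_summaries(
    summaries: list[CoverageSummary],
    subgenome_map: dict[str, str],
    chromosome_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Run the full assignment on a panel; one row per sample.

    Samples whose subgenome proportions are both zero are labelled
    ``low_coverage`` (no usable signal) with NaN normalized proportion.
    """
    rows = []
    for cov in summaries:
        p_d, p_s = aggregate_subgenomes(cov, subgenome_map, chromosome_lengths)
        try:
            norm = normalize_proportion(p_d, p_s)
            label = classify_species(norm, cov.total_reads)
        except ZeroDivisionError:
            norm, label = np.nan, "low_coverage"
        rows.append(
            {
                "sample": cov.sample,
                "p_distachyon": p_d,
                "p_stacei": p_s,
                "normalized": norm,
                "label": label,
            }
        )
    return pd.DataFrame(rows)
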