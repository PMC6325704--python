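import numpy as np
import pytest

from brachykit.core import MISSING, GenotypeMatrix


def make_matrix(rows, chrom=None, pos=None, samples=None, qual=None):
    """Build a small GenotypeMatrix from a list of per-sample call lists.

    ``None`` entries become missing calls.
    """
    calls = np.array(
        [[MISSING if v is None else v for v in r] for r in rows], dtype=np.int8
    )
    n, m = calls.shape
    if chrom is None:
        chrom = ["chr1"] * m
    if pos is None:
        pos = []
        counter = {}
        for c in chrom:
            counter[c] = counter.get(c, 0) + 1
            pos.append(counter[c] * 100)
    if samples is None:
        samples = [f"s{i + 1}" for i in range(n)]
    return GenotypeMatrix(
        samples=samples,
        chrom=np.array(chrom, dtype=object),
        pos=np.array(pos),
        calls=calls,
        qual=None if qual is None else np.asarray(qual, dtype=float),
    )


@pytest.fixture
def clonal_panel():
    """Small clonal-family panel with truth labels: 2 subgroups x 2 families
    x 3 accessions x 2 replicates, 18.5% missing."""
    from brachykit.synthetic_data import PopulationSpec, gen_genotypes

    spec = PopulationSpec(
        n_subgroups=2,
        n_families_per_subgroup=2,
        n_accessions_per_family=3,
        n_replicates_per_accession=2,
        within_family_divergence=0.003,
        n_snps=2000,
        missing_rate=0.185,
        seed=77,
    )
    return gen_genotypes(spec)
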