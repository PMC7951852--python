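import numpy as np
import pytest

from introscan.io import GenotypeMatrix, Region, RegionSet, TaxonMap


@pytest.fixture
def simple_taxon_map():
    return TaxonMap({
        "a1": "A", "a2": "A", "b1": "B", "c1": "C", "o1": "O",
    })


def make_matrix(dosage, samples, taxon_map, chrom=None, pos=None,
                includes_invariant=False, alt=None):
    """Build a GenotypeMatrix from a plain dosage array (tests' workhorse)."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n_sites = dosage.shape[0]
    return GenotypeMatrix(
        chrom=np.asarray(chrom if chrom is not None else ["chr1"] * n_sites,
                         dtype=object),
        pos=np.asarray(pos if pos is not None else np.arange(n_sites),
                       dtype=np.int64),
        ref=np.asarray(["A"] * n_sites, dtype=object),
        alt=np.asarray(alt if alt is not None else ["T"] * n_sites, dtype=object),
        dosage=dosage,
        samples=list(samples),
        taxon_map=taxon_map,
        includes_invariant=includes_invariant,
    )


@pytest.fixture
def one_region():
    return RegionSet([Region("g1", "chr1", 0, 1000)])
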