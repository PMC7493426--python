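import numpy as np
import pytest

from msatclone.genotype_io import (
    AllelePair,
    GenotypeDataset,
    IndividualRecord,
    LocusDef,
)


def make_individual(id, species, calls, population=None):
    pairs = {}
    for locus, val in calls.items():
        pairs[locus] = AllelePair.missing() if val is None else AllelePair(*val)
    return IndividualRecord(id, species, population or species, pairs)


@pytest.fixture
def toy_loci():
    return [LocusDef("LA", motif_length=4), LocusDef("LB", motif_length=2)]


@pytest.fixture
def toy_dataset(toy_loci):
    """2 species x 2 individuals over 2 loci, one MISSING call."""
    inds = [
        make_individual("a1", "sp1", {"LA": (150, 154), "LB": (90, 92)}),
        make_individual("a2", "sp1", {"LA": (150, 150), "LB": None}),
        make_individual("b1", "sp2", {"LA": (150, 158), "LB": (90, 90)}),
        make_individual("b2", "sp2", {"LA": (154, 158), "LB": (92, 94)}),
    ]
    return GenotypeDataset(toy_loci, inds, max_missing=1)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_dataset(rng, n_loci=4, n_ind=8, n_species=2, missing_rate=0.1,
                   motif=4, n_alleles=5):
    """Random valid dataset for property tests (alleles on the motif ladder)."""
    loci = [LocusDef(f"L{i}", motif_length=motif) for i in range(n_loci)]
    inds = []
    for k in range(n_ind):
        sp = f"sp{k % n_species}"
        calls = {}
        n_missing = 0
        for l in loci:
            if rng.random() < missing_rate and n_missing < n_loci - 1:
                calls[l.name] = AllelePair.missing()
                n_missing += 1
            else:
                a = 100 + motif * int(rng.integers(n_alleles))
                b = 100 + motif * int(rng.integers(n_alleles))
                calls[l.name] = AllelePair(a, b)
        inds.append(IndividualRecord(f"i{k}", sp, sp, calls))
    return GenotypeDataset(loci, inds, max_missing=None)
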