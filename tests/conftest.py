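import numpy as np
import pytest

from baiminer import synthetic_data as sd


@pytest.fixture(scope="session")
def bai_refs():
    """Synthetic bai reference proteins shared across tests."""
    return sd.bai_reference_proteins()


@pytest.fixture(scope="session")
def table1_contig(bai_refs):
    """A contig carrying the complete ten-gene operon layout."""
    spec = sd.OperonSpec(sd.TABLE1_LAYOUT)
    contig, intervals = sd.build_contig(spec, codon_seed=7)
    return contig, intervals


@pytest.fixture(scope="session")
def three_families():
    """Three independent protein families for partition-recovery tests.

    Ancestors are unrelated random proteins (pairwise identity ~6%);
    members sit at 98% identity to their ancestor, i.e. ~96% to each
    other.  Returns (members, planted-cluster-label mapping).
    """
    rng = np.random.default_rng(11)
    members, planted = [], {}
    for k in range(3):
        anc = sd.random_protein(177, rng, f"fam{k}anc")
        fam = sd.mutate_family(sd.FamilySpec(anc, 8, 0.98, seed=500 + k))
        for m in fam:
            planted[m.id] = k
        members.extend(fam)
    return members, planted
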