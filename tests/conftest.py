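import pytest

from nthiso.domain_scan import DOMAIN_I, DOMAIN_III, DomainHit
from nthiso.io import load_fixture_matrix, load_topologies
from nthiso.isoform import Architecture, assemble_architecture
from nthiso.synthetic import SequenceSpec, make_isoform_sequence
from nthiso.tm_scan import TMHelix, TMStretch


@pytest.fixture(scope="session")
def table2_matrix():
    return load_fixture_matrix()


@pytest.fixture(scope="session")
def topologies():
    return load_topologies()


@pytest.fixture(scope="session")
def alpha_beta_record():
    return make_isoform_sequence(SequenceSpec(isoform="ALPHA_BETA", seed=1))


@pytest.fixture(scope="session")
def beta_alpha_record():
    return make_isoform_sequence(SequenceSpec(isoform="BETA_ALPHA", seed=1))


def make_architecture(n_between: int, n_after: int = 0) -> Architecture:
    """Hand-built αβ-style architecture with ``n_between`` helices between
    domain I and domain III (each helix 20 residues, 10 apart)."""
    hits = [DomainHit(DOMAIN_I, 0, 24, 96.0)]
    pos = 40
    helices = []
    for _ in range(n_between):
        helices.append(TMHelix(pos, pos + 20, 3.8))
        pos += 30
    hits.append(DomainHit(DOMAIN_III, pos + 10, pos + 34, 96.0))
    pos += 50
    trailing = []
    for _ in range(n_after):
        trailing.append(TMHelix(pos, pos + 20, 3.8))
        pos += 30
    stretches = []
    if helices:
        stretches.append(TMStretch(tuple(helices)))
    if trailing:
        stretches.append(TMStretch(tuple(trailing)))
    return assemble_architecture(hits, stretches)
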