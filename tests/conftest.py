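import numpy as np
import pytest

from exopba.design import CohortDesign, crc_cohort_design
from exopba.panel import PanelDefinition, ReadLayout, default_panel


@pytest.fixture(scope="session")
def panel115() -> PanelDefinition:
    return default_panel()


@pytest.fixture(scope="session")
def layout() -> ReadLayout:
    return ReadLayout()


@pytest.fixture()
def small_panel() -> PanelDefinition:
    return PanelDefinition((
        ("P1", "AAAACCCC"),
        ("P2", "GGGGTTTT"),
        ("P3", "ACGTACGT"),
        ("P4", "TTTTAAAA"),
    ))


def make_tiny_design(panel: PanelDefinition, n_clusters: int = 2,
                     exosomes_per_sample: int = 300,
                     groups=(("HC", 1),)) -> CohortDesign:
    """Two well-separated clusters over the first four panel proteins."""
    p = panel.size
    sig = np.full((n_clusters, p), 1e-6)
    sig[0, 0], sig[0, 1] = 0.5, 0.5
    if n_clusters > 1:
        sig[1, 2], sig[1, 3] = 0.5, 0.5
    pi = np.full(n_clusters, 1.0 / n_clusters)
    mixing = {g: pi.copy() for g, _ in groups}
    return CohortDesign(
        groups=tuple(groups),
        n_clusters=n_clusters,
        protein_names=panel.names,
        cluster_names=tuple(f"C{i+1}" for i in range(n_clusters)),
        signatures=sig,
        mixing=mixing,
        exosomes_per_sample=exosomes_per_sample,
    )


@pytest.fixture()
def tiny_design(panel115) -> CohortDesign:
    return make_tiny_design(panel115)


@pytest.fixture(scope="session")
def fixture_design() -> CohortDesign:
    return crc_cohort_design()
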