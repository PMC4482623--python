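import networkx as nx
import pytest

from lsed.synthetic import SyntheticSpec, SyntheticTruth, generate, emit_files


@pytest.fixture
def triangle() -> nx.Graph:
    return nx.Graph([("a", "b"), ("b", "c"), ("a", "c")])


@pytest.fixture
def path3() -> nx.Graph:
    return nx.Graph([("a", "b"), ("b", "c")])


@pytest.fixture(scope="session")
def small_spec() -> SyntheticSpec:
    """A fast three-compartment generator spec for pipeline tests."""
    return SyntheticSpec(
        seed=7,
        compartment_sizes=(120, 80, 50),
        multi_localization_prob=0.2,
        edges_per_node=3,
        hub_quantile=0.1,
        p_ess_hub=0.6,
        p_ess_nonhub=0.1,
    )


@pytest.fixture(scope="session")
def small_truth(small_spec) -> SyntheticTruth:
    return generate(small_spec)


@pytest.fixture(scope="session")
def dataset_dir(small_truth, tmp_path_factory):
    """Emitted text files for the small synthetic dataset."""
    directory = tmp_path_factory.mktemp("dataset")
    return emit_files(small_truth, directory)
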