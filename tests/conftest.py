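import numpy as np
import pytest
from hypothesis import settings

from ogfamily.datamodel import load_gras_counts, load_gras_taxonomy, load_gras_registry
from ogfamily.orthogroup import HitTable, build_orthogroups
from ogfamily.pairalign import ScoringScheme
from ogfamily.simulate import SimConfig, simulate_dataset, registry_from_tree
from ogfamily.datamodel import load_taxonomy

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def scheme():
    return ScoringScheme.blosum62()


@pytest.fixture(scope="session")
def gras_matrix():
    return load_gras_counts()


@pytest.fixture(scope="session")
def gras_taxonomy():
    return load_gras_taxonomy()


@pytest.fixture(scope="session")
def gras_registry():
    return load_gras_registry()


@pytest.fixture(scope="session")
def sim_default():
    """One default-condition dataset (29 ancestral genes, 8 species)."""
    cfg = SimConfig(seed=1)
    records, truth = simulate_dataset(cfg)
    return cfg, records, truth


@pytest.fixture(scope="session")
def sim_registry(sim_default):
    cfg, _, _ = sim_default
    return registry_from_tree(load_taxonomy(cfg.species_tree))


@pytest.fixture(scope="session")
def sim_inference(sim_default, sim_registry, scheme):
    """Hit table and inferred orthogroups for the default dataset."""
    _, records, _ = sim_default
    hits = HitTable.from_records(records, scheme)
    ogs, unassigned = build_orthogroups(records, hits, sim_registry)
    return hits, ogs, unassigned


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
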