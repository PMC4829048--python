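import numpy as np
import pytest

from pedpop import SimConfig, default_panel, simulate_population


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def population(panel):
    """Small population with ~175 individuals across 10 years."""
    return simulate_population(SimConfig(seed=11, n_founders=60, n_years=10), panel)


@pytest.fixture(scope="session")
def large_population(panel):
    """Larger population (~130 alive) for spatial and sweep experiments."""
    return simulate_population(SimConfig(seed=11, n_founders=150, n_years=12), panel)


def truth_links(pop, present):
    """Directed (offspring, role, parent) links with both members present."""
    links = set()
    for iid in present:
        ind = pop.individuals[iid]
        if ind.dam_id in present:
            links.add((iid, "dam", ind.dam_id))
        if ind.sire_id in present:
            links.add((iid, "sire", ind.sire_id))
    return links


def predicted_links(pedigree_result):
    links = set()
    for row in pedigree_result.assignments.itertuples():
        if row.dam_id is not None:
            links.add((row.offspring_id, "dam", row.dam_id))
        if row.sire_id is not None:
            links.add((row.offspring_id, "sire", row.sire_id))
    return links


def precision_recall(truth, predicted):
    tp = len(truth & predicted)
    precision = tp / len(predicted) if predicted else float("nan")
    recall = tp / len(truth) if truth else float("nan")
    return precision, recall


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
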