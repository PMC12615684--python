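import numpy as np
import pytest

import grnclamp as gc


@pytest.fixture(scope="session")
def toggle():
    topo, anno = gc.make_toggle_switch()
    return topo, anno


@pytest.fixture(scope="session")
def toggle_J(toggle):
    topo, _ = toggle
    return gc.interaction_matrix(topo)


@pytest.fixture(scope="session")
def random_grn5():
    return gc.make_random_grn(gc.FixtureSpec(n_nodes=5, n_edges=8, seed=3))


@pytest.fixture(scope="session")
def toggle_ensemble(toggle):
    """A modest toggle-switch ODE ensemble shared across tests."""
    topo, _ = toggle
    config = gc.EnsembleConfig(n_models=80, n_ics=50)
    return gc.build_ensemble(topo, config, seed=11, e_marker="A")


@pytest.fixture(scope="session")
def toggle_classifier(toggle_ensemble):
    k = min(25, len(toggle_ensemble.processed))
    return gc.StateClassifier.from_ensemble(toggle_ensemble, k=k)


@pytest.fixture(scope="session")
def toggle_bistable(toggle_ensemble, toggle_classifier):
    """Bistable models whose endpoints the KNN classifier labels correctly."""
    models = gc.classifier_consistent(toggle_ensemble.bistable(),
                                      toggle_classifier)
    assert models, "fixture ensemble must yield classifier-consistent models"
    return models
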