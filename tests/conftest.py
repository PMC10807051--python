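"""Shared fixtures: toy models, networks, expansions.

Session scope for anything requiring integration or expansion work, so
the suite builds each expensive object once.  Every fixture is fully
deterministic (fixed seeds).
"""

from __future__ import annotations

import pytest

from memgrow import fixtures as fx
from memgrow.expansion import expand_model


@pytest.fixture(scope="session")
def toy_spec() -> fx.ToySpec:
    return fx.ToySpec(seed=1)


@pytest.fixture(scope="session")
def base_model(toy_spec):
    return fx.make_toy_base_model(toy_spec)


@pytest.fixture(scope="session")
def candidate_net():
    return fx.candidate_subnetwork()


@pytest.fixture(scope="session")
def candidate_omics(candidate_net):
    return fx.make_synthetic_omics(candidate_net.nodes, seed=7)


@pytest.fixture(scope="session")
def expanded_candidate(base_model, candidate_net, candidate_omics):
    """The candidate-shaped expansion: toy base (incl. STAT1) + 9-gene/14-edge net."""
    model, report = expand_model(base_model, candidate_net, candidate_omics)
    return model, report


@pytest.fixture(scope="session")
def small_spec() -> fx.ToySpec:
    return fx.ToySpec(seed=3, n_base_genes=3, n_new_genes=2, n_edges=3)


@pytest.fixture(scope="session")
def small_expanded(small_spec):
    base = fx.make_toy_base_model(small_spec)
    net = fx.make_toy_network(small_spec)
    omics = fx.make_synthetic_omics(net.nodes, seed=11)
    model, report = expand_model(base, net, omics)
    return model, report, net


GRID_STEP = 3.0 / 14  # log10 step of the 15-point / 3-decade grid


@pytest.fixture(scope="session")
def recovery_fit(small_expanded):
    """Ground-truth K_A recovery experiments (first and last regulation
    in generation order shifted two grid steps off default, noise-free
    data, single sequential pass), shared by calibration and acceptance
    tests."""
    model, report, net = small_expanded
    new_keys = [
        tuple(p["id"].split("__")) for p in report.provenance if p["entity"] == "tar"
    ]
    experiments = fx.ka_recovery_experiment(model, new_keys)
    return {"keys": new_keys, "experiments": experiments, "model": model}
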