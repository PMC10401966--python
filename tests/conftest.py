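import numpy as np
import pytest

import clustox as cx
from clustox.synthetic import INACTIVE


@pytest.fixture(scope="session")
def sim_default():
    """One default simulated study, shared read-only across tests."""
    config = cx.SimulationConfig(seed=11)
    matrix, truth = cx.simulate_activity_matrix(config)
    annotations = cx.simulate_annotations(truth, config)
    collection = cx.simulate_pathways(truth, config)
    fingerprints = cx.simulate_fingerprints(truth, config)
    return {"config": config, "matrix": matrix, "truth": truth,
            "annotations": annotations, "collection": collection,
            "fingerprints": fingerprints}


def truth_assignment(truth, compound_ids):
    """Cluster assignment equal to the planted groups (inactive = one cluster)."""
    labels = np.array([truth.group_of_compound[cid] for cid in compound_ids])
    return cx.ClusterAssignment(list(compound_ids), labels)


@pytest.fixture(scope="session")
def truth_clusters(sim_default):
    return truth_assignment(sim_default["truth"],
                            sim_default["matrix"].compound_ids)


def pytest_configure(config):
    # hypothesis: derandomised, modest budget, no deadline flakiness on 1 CPU
    try:
        from hypothesis import settings, HealthCheck
        settings.register_profile(
            "ci", derandomize=True, max_examples=50, deadline=None,
            suppress_health_check=[HealthCheck.too_slow])
        settings.load_profile("ci")
    except ImportError:
        pass
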