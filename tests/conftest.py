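import numpy as np
import pytest

import steppedwedge as sw


@pytest.fixture(scope="session")
def design():
    return sw.default_design()


@pytest.fixture(scope="session")
def replica(design):
    """Replica dataset with the canonical count identities (seed 1)."""
    return sw.generate_replica(design, seed=1)


@pytest.fixture(scope="session")
def replica_spike(design):
    """Replica dataset carrying the 7-event cluster-period spike."""
    counts = sw.ReplicaCounts(spike=sw.default_spike(design))
    return sw.generate_replica(design, counts, seed=1)


@pytest.fixture(scope="session")
def derived_replica(replica, design):
    return sw.derive(replica, design)


@pytest.fixture(scope="session")
def small_cohort(design):
    """Moderate parametric cohort with a raised event rate, for fast fits."""
    from scipy.special import logit

    params = sw.CohortParams(safety_baseline_logit=float(logit(0.02)),
                             safety_intervention_log_or=np.log(2.0))
    return sw.generate_parametric(design, params, n=6000, seed=5)
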