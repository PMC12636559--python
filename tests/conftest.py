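import numpy as np
import pytest

from foxcircuit import (
    GeneratorConfig,
    LifParams,
    SweepConfig,
    generate_reference,
    run_sweep,
)
from foxcircuit.lesion import default_conditions


@pytest.fixture(scope="session")
def reference():
    """Reference hourglass connectome with its generation ground truth."""
    return generate_reference(GeneratorConfig())


@pytest.fixture(scope="session")
def reference_graph(reference):
    return reference[0]


@pytest.fixture(scope="session")
def ground_truth(reference):
    return reference[1]


@pytest.fixture(scope="session")
def bottleneck_grid(reference_graph):
    """Default weight x rate sweep, intact vs fox-silenced, 5 trials/cell.

    Session-scoped: this is the expensive simulation shared by the
    bottleneck-suppression and monotonicity checks.
    """
    conds = default_conditions(reference_graph)
    sweep = SweepConfig(
        conditions={"intact": conds["intact"],
                    "fox_silenced": conds["fox_silenced"]},
        n_trials=5, base_seed=0)
    return run_sweep(reference_graph, LifParams(), sweep)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
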