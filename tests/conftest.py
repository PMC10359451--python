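import numpy as np
import pandas as pd
import pytest

from cogrci.battery import PARAMETER_NAMES
from cogrci.rci import ControlReference, fit_control_reference
from cogrci.simulate import SimulationConfig


@pytest.fixture(scope="session")
def iid_normal_reference() -> ControlReference:
    """Reference fitted to 5000 controls i.i.d. N(0,1) per parameter."""
    rng = np.random.default_rng(1234)
    change = pd.DataFrame(rng.standard_normal((5000, 7)), columns=list(PARAMETER_NAMES))
    baseline = pd.DataFrame(rng.standard_normal((5000, 7)), columns=list(PARAMETER_NAMES))
    return fit_control_reference(change, baseline)


@pytest.fixture()
def unit_reference() -> ControlReference:
    """Hand-built reference: mean 0, SD 1 everywhere, independent scaling √7."""
    params = list(PARAMETER_NAMES)
    zeros = {p: 0.0 for p in params}
    ones = {p: 1.0 for p in params}
    ref = ControlReference(
        mean_change=dict(zeros),
        sd_change=dict(ones),
        mean_baseline=dict(zeros),
        sd_baseline=dict(ones),
        sd_sum_z_change=np.sqrt(7.0),
        sd_sum_z_baseline=np.sqrt(7.0),
        n_control=114,
    )
    # pre-cache subset scalings under independence so no z-matrix is needed
    from itertools import combinations

    for k in range(5, 8):
        for combo in combinations(params, k):
            key = "|".join(sorted(combo))
            ref.subset_scalings_change[key] = np.sqrt(float(k))
            ref.subset_scalings_baseline[key] = np.sqrt(float(k))
    return ref


@pytest.fixture(scope="session")
def small_cohort():
    """A study-shaped synthetic cohort (n=301/114) with its config."""
    from cogrci.simulate import generate_control_cohort, generate_surgical_cohort

    cfg = SimulationConfig(seed=7)
    control = generate_control_cohort(cfg)
    surgical = generate_surgical_cohort(cfg)
    return cfg, control, surgical
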