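import numpy as np
import pytest

import raschtraj as rt
from raschtraj.synthetic_cohort import FormPlan


@pytest.fixture(scope="session")
def bank():
    return rt.make_default_item_bank()


@pytest.fixture(scope="session")
def plan():
    return rt.default_form_plan()


@pytest.fixture(scope="session")
def no_dif_plan():
    """Form plan in which the alternate forms are truly equivalent."""
    return FormPlan(dif_items=(), dif_shifts={})


@pytest.fixture(scope="session")
def null_cohort(no_dif_plan):
    """A DIF-free, moderately sized cohort with complete follow-up."""
    spec = rt.default_cohort_spec(n_persons=400, dropout_rate=0.0, seed=42)
    responses, abilities = rt.simulate_cohort(spec, plan=no_dif_plan)
    return spec, responses, abilities


@pytest.fixture(scope="session")
def null_calibration(null_cohort):
    _, responses, _ = null_cohort
    return rt.calibrate(responses)


def pcm_probs_oracle(theta, thresholds):
    """Literal evaluation of the PCM closed form by direct summation."""
    import math

    terms = []
    for k in range(len(thresholds) + 1):
        s = sum(theta - tau for tau in thresholds[:k])
        terms.append(math.exp(s))
    z = sum(terms)
    return [t / z for t in terms]


@pytest.fixture(scope="session")
def probs_oracle():
    return pcm_probs_oracle
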