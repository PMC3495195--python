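import numpy as np
import pytest

from pedometer_cea import pipeline as pl
from pedometer_cea.disease_model import EpiParameters


@pytest.fixture(scope="session")
def inputs():
    """Default pipeline inputs (synthetic survey, population, epidemiology)."""
    return pl.build_inputs(seed=1)


@pytest.fixture(scope="session")
def base_report(inputs):
    return pl.run_base_case(inputs=inputs)


@pytest.fixture(scope="session")
def psa_results(inputs):
    """A moderate shared PSA run used by several distributional checks."""
    from pedometer_cea.psa import run_psa

    return run_psa(300, 11, pipeline_inputs=inputs)


def make_epi(diseases=("a", "b"), ages=(50, 51, 52, 53), *, incidence=0.0,
             excess=0.0, prevalence=0.0, other_mortality=0.0, rr_inactive=1.0,
             rr_insufficient=1.0, rr_comorbidity=1.0, utility=1.0,
             disease_cost=0.0, unrelated_cost=0.0, reference_utility=1.0):
    """Small hand-specified parameter set with scalar-filled tables."""
    D, A = len(diseases), len(ages)
    full = lambda v, shape: np.broadcast_to(np.asarray(v, dtype=float), shape).copy()
    rr_pa = np.ones((D, 3))
    rr_pa[:, 0] = rr_inactive
    rr_pa[:, 1] = rr_insufficient
    rr_c = np.full((D, D), rr_comorbidity)
    np.fill_diagonal(rr_c, 1.0)
    return EpiParameters(
        diseases=diseases,
        ages=np.array(ages),
        incidence=full(incidence, (D, A, 2)),
        excess_mortality=full(excess, (D, A, 2)),
        prevalence=full(prevalence, (D, A, 2)),
        rr_pa=rr_pa,
        rr_comorbidity=rr_c,
        utility=full(utility, (D,)),
        disease_cost=full(disease_cost, (D, A, 2)),
        unrelated_cost=full(unrelated_cost, (A, 2)),
        other_mortality=full(other_mortality, (A, 2)),
        reference_utility=full(reference_utility, (A, 2)),
    )
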