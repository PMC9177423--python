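"""Shared fixtures: small simulated inputs and reduced-MCMC fits.

Expensive posterior fits are session-scoped so several tests can interrogate
the same posterior.
"""

import numpy as np
import pandas as pd
import pytest

import clonekinetics as ck
from clonekinetics.model import MCMCConfig, OverdispersionEstimate
from clonekinetics.simulate import LONGITUDINAL_COLUMNS


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def od_calibrated():
    """A fixed overdispersion estimate matching the generator's beta_od=120."""
    return OverdispersionEstimate(mu_od=120.0, sigma_od=15.0, n_posterior=1000)


@pytest.fixture(scope="session")
def fast_mcmc():
    return MCMCConfig(iterations=1600, leapfrog_steps=40, chains=2, seed=42)


def exact_logistic_dataset(b=0.2, u=-12.0, depth=10_000, ages=(55, 60, 65, 70, 75)):
    """Noise-free counts rounded from an exact logistic trajectory."""
    rows = []
    for a in ages:
        q = 1.0 / (1.0 + np.exp(-(b * a + u)))
        rows.append(("i1", "c1", "GENEX", "", "missense", float(a), depth,
                     int(round(depth * q))))
    return ck.LongitudinalDataset(df=pd.DataFrame(rows, columns=LONGITUDINAL_COLUMNS))


@pytest.fixture(scope="session")
def single_clone_fit(od_calibrated, fast_mcmc):
    """Posterior for one noiseless logistic clone (b=0.2, u=-12)."""
    ds = exact_logistic_dataset()
    od = OverdispersionEstimate(mu_od=500.0, sigma_od=50.0, n_posterior=1000)
    fit = ck.fit_trajectories(ds, od, fast_mcmc)
    return ds, fit


@pytest.fixture(scope="session")
def small_cohort(od_calibrated):
    """A 3-gene, 36-clone cohort drawn from the hierarchical model."""
    return ck.sample_model_cohort(
        {"GENE_A": 0.0, "GENE_B": 0.05, "GENE_C": 0.15},
        clones_per_gene=12,
        ages=[55, 60, 65, 70, 75, 80],
        depth=3000,
        beta_od=120.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_cohort_fit(small_cohort, od_calibrated):
    fit = ck.fit_trajectories(
        small_cohort, od_calibrated,
        MCMCConfig(iterations=2000, leapfrog_steps=50, chains=2, seed=9),
    )
    return small_cohort, fit


@pytest.fixture(scope="session")
def colony_history():
    """A WF history with one established driver clone at moderate fraction."""
    cfg = ck.WFConfig(
        n_hsc=50_000,
        generations_per_year=2.0,
        total_years=75.0,
        drivers=(ck.Driver("SF3B1:K666N", 0.10, 60),),
        seed=11,
    )
    return ck.simulate_wf_conditioned(cfg)


@pytest.fixture(scope="session")
def colony_tree(colony_history):
    return ck.sample_colony_tree(
        colony_history, n_colonies=96, mutation_rate_per_year=18.0, seed=13
    )
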