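import warnings

import numpy as np
import pytest

import egfrtraj as et

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def small_cohort():
    """Fully observed cohort of 120 subjects for fast model tests."""
    cfg = et.CohortConfig(n_subjects=120, missing_rate=0.0, seed=7)
    return et.generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_design(small_cohort):
    """Standardized design on two predictors (TNFR1 main, KIM1 slope)."""
    c = small_cohort
    design_cov, stats = et.transform_predictors(
        c.covariates.drop(columns="subject_id"))
    design_cov.index = c.covariates["subject_id"].to_numpy()
    spec = et.ModelSpec(["TNFR1", "KIM1"], prior_family="student_t_weak",
                        mcmc=et.McmcConfig(chains=2, warmup=150, draws=250,
                                           seed=3))
    design = et.build_design(c.records, design_cov, spec,
                             stats_fp=et.stats_fingerprint(stats))
    return design, spec


@pytest.fixture(scope="session")
def small_fit(small_design):
    design, spec = small_design
    draws, diag = et.fit_blmm(design, spec)
    return design, spec, draws, diag


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20230329)
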