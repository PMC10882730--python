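"""Shared fixtures: one default synthetic study and its two-stage fit.

The heavy MCMC fits are session-scoped so diagnostics, reporting and
acceptance checks all reuse the same posterior objects.
"""

import numpy as np
import pytest

from refrate import (
    MCMCConfig,
    SyntheticTruth,
    adjust_denominator,
    fit_referral_glmm,
    fit_stcar,
    simulate_study,
)


@pytest.fixture(scope="session")
def study():
    """Default-scale synthetic study (100 areas, 8 study years + 1 extra)."""
    return simulate_study(SyntheticTruth(seed=3))


@pytest.fixture(scope="session")
def stcar_fit(study):
    return fit_stcar(
        study.panel,
        study.lattice,
        MCMCConfig(iterations=4000, burn_in=2000, thinning=4, seed=2),
    )


@pytest.fixture(scope="session")
def adjusted(study, stcar_fit):
    return adjust_denominator(stcar_fit, study.panel)


@pytest.fixture(scope="session")
def glmm_fit(study, adjusted):
    return fit_referral_glmm(
        study.referrals,
        adjusted,
        MCMCConfig(iterations=8000, burn_in=4000, thinning=4, seed=7),
    )
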