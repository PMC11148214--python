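import numpy as np
import pandas as pd
import pytest

from gdmliver import CohortSimConfig, GwasSimConfig, simulate_cohort, simulate_gwas_pair
from gdmliver.cohort import add_derived_biomarkers, apply_inclusion_exclusion, classify_gdm


def make_record(**kw):
    """One well-formed cohort row; keyword overrides."""
    base = dict(
        id="P1", age=28.0, bmi=21.0, weight_gain=12.0, ga_weeks=10.0,
        education="college-or-above", gravidity=1, parity=0,
        smoking="no", alcohol="no",
        alt=13.0, ast=17.0, ggt=11.0, alp=49.0,
        tc=4.6, tg=1.3, ldl_c=2.3, hdl_c=1.8,
        fbg=4.4, pbg1h=7.4, pbg2h=6.4, hx_flags="",
    )
    base.update(kw)
    return base


@pytest.fixture
def record_factory():
    return make_record


@pytest.fixture(scope="session")
def analytic_cohort():
    """A mid-sized synthetic cohort run through the standard preparation:
    exclusions applied, derived indices and diagnosis attached."""
    df, truth = simulate_cohort(CohortSimConfig(n=6000, seed=20240521))
    retained, _ = apply_inclusion_exclusion(df)
    retained = add_derived_biomarkers(retained)
    status = classify_gdm(retained)
    retained = pd.concat([retained, status[["is_gdm", "subtype"]]], axis=1)
    return retained, truth


@pytest.fixture(scope="session")
def gwas_pair():
    cfg = GwasSimConfig(m_snps=120, seed=7, theta=0.25)
    return simulate_gwas_pair(cfg)
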