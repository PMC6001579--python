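import numpy as np
import pytest

from femeta import MetaInput, StudySummary, validate_input


def build_meta(estimates, ses, ns=None, model="known", df_resid=None) -> MetaInput:
    """Assemble a MetaInput from parallel arrays (known-sigma by default)."""
    estimates = np.asarray(estimates, dtype=float)
    ses = np.asarray(ses, dtype=float)
    if ns is None:
        ns = np.full(estimates.size, 100, dtype=int)
    studies = [
        StudySummary(
            study_id=f"s{i + 1}",
            estimate=float(b),
            se=float(s),
            n=int(n),
            variance_model=model,
            df_resid=df_resid,
        )
        for i, (b, s, n) in enumerate(zip(estimates, ses, ns))
    ]
    return validate_input(studies)


@pytest.fixture
def symmetric_pair() -> MetaInput:
    """Two equal-precision studies at 0 and 2 (Q = 2, pooled estimate 1)."""
    return build_meta([0.0, 2.0], [1.0, 1.0])


@pytest.fixture
def unequal_pair() -> MetaInput:
    """Studies at (1, 3) with se (1, 2): pooled estimate 1.4, Q = 0.8."""
    return build_meta([1.0, 3.0], [1.0, 2.0], ns=[100, 300])


@pytest.fixture
def heterogeneous_six() -> MetaInput:
    """Six estimated-variance mean-difference studies with real heterogeneity."""
    rng = np.random.default_rng(20240915)
    betas = np.array([-3.5, -2.9, -2.2, -1.6, -1.0, -0.4])
    n = 50
    sigma2_within = 6.25
    s2 = sigma2_within * rng.chisquare(n - 2, size=6) / (n - 2)
    se = np.sqrt(4.0 * s2 / n)
    est = rng.normal(betas, np.sqrt(4.0 * sigma2_within / n))
    return build_meta(est, se, ns=np.full(6, n), model="pooled_normal")
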