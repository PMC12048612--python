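import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from repeatrisk.simulate import GroupSpec, PlantedRisk, SyntheticConfig, generate_cohort

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


# ---------------------------------------------------------------------------
# Independent oracles (kept deliberately naive)
# ---------------------------------------------------------------------------


def fisher_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by full hypergeometric enumeration."""
    from math import comb

    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = comb(n, c1)

    def prob(k: int) -> float:
        return comb(r1, k) * comb(r2, c1 - k) / denom

    p_obs = prob(a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    return sum(p for k in range(lo, hi + 1) if (p := prob(k)) <= p_obs * (1 + 1e-9))


def bh_oracle(pvalues) -> np.ndarray:
    """Benjamini-Hochberg by its definition: p(i)*n/i with trailing minima."""
    p = np.asarray(pvalues, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    scaled = p[order] * n / np.arange(1, n + 1)
    scaled = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(scaled, 1.0)
    return out


def newton_logistic_oracle(X, y, iters: int = 60) -> np.ndarray:
    """Plain Newton-Raphson maximum likelihood for logistic regression."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    beta = np.zeros(X.shape[1])
    for _ in range(iters):
        p = 1.0 / (1.0 + np.exp(-(X @ beta)))
        grad = X.T @ (y - p)
        hess = X.T @ (X * (p * (1 - p))[:, None])
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-13:
            break
    return beta


# ---------------------------------------------------------------------------
# Shared cohorts
# ---------------------------------------------------------------------------


def two_arm_config(
    n_case=800,
    n_con=800,
    case_group="ANX",
    planted_risk=None,
    age_mean=58.0,
    age_sd=8.0,
    age_range=(48.0, 90.0),
    hd_rate=0.0,
    **kwargs,
):
    """Case/control config with all subjects in the older stratum by default."""
    return SyntheticConfig(
        groups=(
            (case_group, GroupSpec(n_case, age_mean, age_sd, 0.58)),
            ("CON", GroupSpec(n_con, age_mean, age_sd, 0.63)),
        ),
        age_range=age_range,
        planted_risk=planted_risk or PlantedRisk(),
        hd_carrier_rate=hd_rate,
        **kwargs,
    )


@pytest.fixture(scope="session")
def null_cohort() -> pd.DataFrame:
    """Seeded cohort with no planted effects (ANX vs CON, older ages)."""
    return generate_cohort(two_arm_config(n_case=600, n_con=600), seed=101)


@pytest.fixture(scope="session")
def mixed_cohort() -> pd.DataFrame:
    """Small three-group cohort spanning both age strata."""
    cfg = SyntheticConfig(
        groups=(
            ("MDD", GroupSpec(500, 49.2, 14.1, 0.585)),
            ("ANX", GroupSpec(200, 37.7, 12.1, 0.582)),
            ("CON", GroupSpec(400, 49.6, 13.8, 0.630)),
        ),
    )
    return generate_cohort(cfg, seed=202)


@pytest.fixture(scope="session")
def fixture_200():
    """Fixed 200-subject design + labels for fit comparisons."""
    cfg = two_arm_config(n_case=100, n_con=100)
    cohort = generate_cohort(cfg, seed=303)
    y = (cohort["group"] == "ANX").astype(float).to_numpy()
    return cohort, y
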