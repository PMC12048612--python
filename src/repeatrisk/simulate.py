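"""Seeded synthetic-cohort generator.

Generates case-control cohorts with the statistical structure the
analysis modules assume: discrete CAG allele pairs on 7-39 with a
right-skewed marginal (mean 18.4, SD 3.2), a positive within-subject
allele correlation (sorted-pair Pearson r = 0.36) produced by a
Gaussian copula whose latent correlation is calibrated by bisection,
rare reduced-penetrance alleles (36-39) at a configurable carrier rate,
group-specific age and sex structure, and configurable planted
allele-risk and allele-phenotype effects for parameter-recovery
experiments.

Generation is a pure function of (config, seed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .phenoreg import orthogonalize_a1

logger = logging.getLogger(__name__)

RISK_TERMS = ("A1", "A2", "A1sq", "A2sq", "A1xA2")

_CANONICAL_EDGES = np.array([13, 21, 27, 36, 40])
_CANONICAL_LETTERS = np.array(list("abcde"))


def _canonical_labels(a1: np.ndarray, a2: np.ndarray) -> np.ndarray:
    """Vectorized canonical-scheme genotype-combination labels."""
    c1 = _CANONICAL_LETTERS[np.digitize(a1, _CANONICAL_EDGES)]
    c2 = _CANONICAL_LETTERS[np.digitize(a2, _CANONICAL_EDGES)]
    swap = c1 > c2
    lo = np.where(swap, c2, c1)
    hi = np.where(swap, c1, c2)
    return np.char.add(lo, hi)

# calibration caches (pure functions of their keys)
_PMF_CACHE: dict = {}
_RHO_CACHE: dict = {}


# ---------------------------------------------------------------------------
# Allele marginal and copula
# ---------------------------------------------------------------------------


def allele_pmf(
    mean: float = 18.4, sd: float = 3.2, support: tuple[int, int] = (7, 39)
) -> pd.Series:
    """Discretized, truncated gamma pmf moment-matched to (mean, sd).

    A gamma density is integrated over unit bins centred on each integer
    of the support, truncated and renormalized; the gamma parameters are
    adjusted numerically so that the *discrete* distribution has exactly
    the requested mean and standard deviation.  Right-skewed, like
    population CAG repeat distributions.
    """
    key = (round(mean, 6), round(sd, 6), support)
    if key in _PMF_CACHE:
        return _PMF_CACHE[key]
    lo, hi = support
    ks = np.arange(lo, hi + 1)

    def discretized(params):
        shape, scale = params
        edges = np.concatenate([[ks[0] - 0.5], ks + 0.5])
        cdf = stats.gamma.cdf(edges, a=shape, scale=scale)
        w = np.diff(cdf)
        w = w / w.sum()
        return w

    def moments_gap(params):
        w = discretized(np.exp(params))  # log-parametrized to stay positive
        m = float(w @ ks)
        s = float(np.sqrt(w @ (ks - m) ** 2))
        return [m - mean, s - sd]

    shape0 = (mean / sd) ** 2
    scale0 = sd**2 / mean
    sol = optimize.fsolve(moments_gap, np.log([shape0, scale0]), full_output=True)
    x, info, ier, msg = sol
    if ier != 1:
        raise ValueError(f"could not moment-match the allele pmf: {msg}")
    pmf = pd.Series(discretized(np.exp(x)), index=ks, name="pmf")
    _PMF_CACHE[key] = pmf
    return pmf


def _pairs_from_latent(z: np.ndarray, rho: float, cum: np.ndarray, ks: np.ndarray):
    """Map latent standard-normal pairs through the discrete marginal, sorted."""
    w = rho * z[:, 0] + np.sqrt(max(1.0 - rho**2, 0.0)) * z[:, 1]
    u1 = stats.norm.cdf(z[:, 0])
    u2 = stats.norm.cdf(w)
    v1 = ks[np.searchsorted(cum, u1, side="left").clip(max=len(ks) - 1)]
    v2 = ks[np.searchsorted(cum, u2, side="left").clip(max=len(ks) - 1)]
    return np.minimum(v1, v2), np.maximum(v1, v2)


def calibrate_rho(
    pmf: pd.Series,
    target_r: float,
    pilot_n: int = 100_000,
    tol: float = 0.002,
    pilot_seed: int = 20_240_701,
) -> float:
    """Latent Gaussian-copula correlation giving the target sorted-pair r.

    Bisection over the latent rho using a fixed pilot sample of latent
    normals (common random numbers), so the result is deterministic.
    Raises if no sorting-compatible rho can reach the target.
    """
    key = (tuple(np.round(pmf.to_numpy(), 10)), tuple(pmf.index), round(target_r, 4))
    if key in _RHO_CACHE:
        return _RHO_CACHE[key]
    rng = np.random.default_rng(pilot_seed)
    z = rng.standard_normal((pilot_n, 2))
    ks = pmf.index.to_numpy()
    cum = np.cumsum(pmf.to_numpy())

    def post_sort_r(rho):
        a1, a2 = _pairs_from_latent(z, rho, cum, ks)
        return float(np.corrcoef(a1, a2)[0, 1])

    lo, hi = -0.999, 0.999
    r_lo, r_hi = post_sort_r(lo), post_sort_r(hi)
    if not (r_lo - tol <= target_r <= r_hi + tol):
        raise ValueError(
            f"target r={target_r} unreachable by sorted copula pairs "
            f"(achievable range [{r_lo:.3f}, {r_hi:.3f}])"
        )
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        r_mid = post_sort_r(mid)
        if abs(r_mid - target_r) <= tol:
            _RHO_CACHE[key] = mid
            return mid
        if r_mid < target_r:
            lo = mid
        else:
            hi = mid
    mid = 0.5 * (lo + hi)
    _RHO_CACHE[key] = mid
    return mid


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupSpec:
    """Size and demographic structure of one diagnostic group."""

    n: int
    age_mean: float
    age_sd: float
    female_prop: float

    def __post_init__(self):
        if self.n < 0:
            raise ValueError("group size must be >= 0")


@dataclass(frozen=True)
class PlantedRisk:
    """Planted case-probability model on the allele terms.

    ``coef_all`` applies everywhere; ``coef_younger``/``coef_older`` add
    stratum-specific contributions (stratum boundary ``age_split``,
    older inclusive).  Terms are the raw centered polynomial terms of
    the risk model, centered at ``center``.  ``step_threshold`` adds
    ``step_logor`` to the log-odds whenever A2 >= threshold (optionally
    restricted to one stratum) — a continuous-scale risk step placed at
    a repeat count.  ``combo_logor`` instead plants log-odds offsets on
    canonical genotype-combination labels (e.g. ``(("bc", log(2.2)),)``),
    which makes the carrier-vs-rest odds ratio of that combination equal
    the planted value exactly.
    """

    intercept: float = 0.0
    coef_all: tuple[tuple[str, float], ...] = ()
    coef_younger: tuple[tuple[str, float], ...] = ()
    coef_older: tuple[tuple[str, float], ...] = ()
    step_threshold: Optional[int] = None
    step_logor: float = 0.0
    step_stratum: str = "all"  # all | younger | older
    combo_logor: tuple[tuple[str, float], ...] = ()
    combo_stratum: str = "all"
    age_split: float = 48.0
    center: float = 18.4

    def is_null(self) -> bool:
        return (
            not self.coef_all
            and not self.coef_younger
            and not self.coef_older
            and not self.combo_logor
            and (self.step_threshold is None or self.step_logor == 0.0)
        )

    def logit(self, a1: np.ndarray, a2: np.ndarray, age: np.ndarray) -> np.ndarray:
        x1 = a1 - self.center
        x2 = a2 - self.center
        terms = {"A1": x1, "A2": x2, "A1sq": x1**2, "A2sq": x2**2, "A1xA2": x1 * x2}
        older = age >= self.age_split
        eta = np.full(a1.shape, self.intercept, dtype=float)
        for name, c in self.coef_all:
            eta += c * terms[name]
        for name, c in self.coef_younger:
            eta += np.where(older, 0.0, c * terms[name])
        for name, c in self.coef_older:
            eta += np.where(older, c * terms[name], 0.0)
        if self.step_threshold is not None and self.step_logor != 0.0:
            in_step = a2 >= self.step_threshold
            if self.step_stratum == "older":
                in_step = in_step & older
            elif self.step_stratum == "younger":
                in_step = in_step & ~older
            eta += np.where(in_step, self.step_logor, 0.0)
        if self.combo_logor:
            labels = _canonical_labels(np.asarray(a1), np.asarray(a2))
            in_stratum = np.ones(a1.shape, dtype=bool)
            if self.combo_stratum == "older":
                in_stratum = older
            elif self.combo_stratum == "younger":
                in_stratum = ~older
            for label, logor in self.combo_logor:
                eta += np.where((labels == label) & in_stratum, logor, 0.0)
        return eta

    def case_probability(self, a1, a2, age) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self.logit(a1, a2, age)))


@dataclass(frozen=True)
class PlantedPhenotype:
    """Planted linear phenotype on standardized allele/covariate terms.

    ``betas`` maps term names (A1orth, A2, age, sex, status, eICV,
    A1orth_x_A2, A1orth_x_age, A2_x_age) to standardized effect sizes.
    ``conditional_beta`` adds an A1orth effect active only where
    A2 >= ``conditional_threshold`` (an A2-conditional, nonlinear
    effect).  Residual noise tops total variance up to ~1 so planted
    betas are recovered as standardized coefficients; ``offset`` and
    ``scale`` then map the z-scale outcome to measurement units.
    """

    name: str
    betas: tuple[tuple[str, float], ...] = ()
    conditional_threshold: Optional[int] = None
    conditional_beta: float = 0.0
    offset: float = 0.0
    scale: float = 1.0


def _default_groups() -> tuple[tuple[str, GroupSpec], ...]:
    return (
        ("MDD", GroupSpec(n=2136, age_mean=49.2, age_sd=14.1, female_prop=0.585)),
        ("ANX", GroupSpec(n=493, age_mean=37.7, age_sd=12.1, female_prop=0.582)),
        ("CON", GroupSpec(n=1566, age_mean=49.6, age_sd=13.8, female_prop=0.630)),
    )


@dataclass(frozen=True)
class SyntheticConfig:
    """Full generative recipe for one synthetic cohort."""

    groups: tuple[tuple[str, GroupSpec], ...] = field(default_factory=_default_groups)
    allele_mean: float = 18.4
    allele_sd: float = 3.2
    allele_support: tuple[int, int] = (7, 39)
    pair_r: float = 0.36
    hd_carrier_rate: float = 1.0 / 500.0
    age_range: tuple[float, float] = (17.0, 90.0)
    planted_risk: PlantedRisk = field(default_factory=PlantedRisk)
    planted_phenotypes: tuple[PlantedPhenotype, ...] = ()
    eicv_mean: float = 1450.0
    eicv_sd: float = 130.0
    coil_levels: tuple[str, ...] = ("12ch", "32ch")
    seed: Optional[int] = None

    def with_seed(self, seed: int) -> "SyntheticConfig":
        return replace(self, seed=seed)

    @property
    def group_dict(self) -> dict[str, GroupSpec]:
        return dict(self.groups)


# ---------------------------------------------------------------------------
# Drawing
# ---------------------------------------------------------------------------


def draw_allele_pair(
    config: SyntheticConfig, rng: np.random.Generator, size: int = 1
) -> tuple[np.ndarray, np.ndarray]:
    """Draw `size` sorted allele pairs (a1 <= a2) from the copula model."""
    pmf = allele_pmf(config.allele_mean, config.allele_sd, config.allele_support)
    rho = calibrate_rho(pmf, config.pair_r)
    z = rng.standard_normal((size, 2))
    return _pairs_from_latent(z, rho, np.cumsum(pmf.to_numpy()), pmf.index.to_numpy())


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float, size: int
) -> np.ndarray:
    out = rng.normal(mean, sd, size)
    bad = (out < lo) | (out > hi)
    for _ in range(1000):
        k = int(bad.sum())
        if k == 0:
            return out
        out[bad] = rng.normal(mean, sd, k)
        bad = (out < lo) | (out > hi)
    raise RuntimeError("age truncation rejection failed to converge")


def generate_cohort(config: SyntheticConfig, seed: Optional[int] = None) -> pd.DataFrame:
    """Generate one cohort table.

    Group labels are assigned by the planted logistic risk: candidate
    subjects are drawn from each group's demographic model and accepted
    into a case group with probability equal to their planted case
    probability (controls with the complement), until the requested
    group sizes are met — case-control sampling from the planted
    population model.  Reduced-penetrance alleles (36-39) are then
    injected by overwriting A2 in a Bernoulli-selected subset.
    """
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    lo_age, hi_age = config.age_range
    frames = []
    for group, spec in config.groups:
        if spec.n == 0:
            continue
        rows = {"age": [], "sex": [], "a1": [], "a2": []}
        have, drawn = 0, 0
        while have < spec.n:
            m = max(int((spec.n - have) * 2.5), 64)
            drawn += m
            if drawn > 500 * max(spec.n, 1) + 10_000:
                raise RuntimeError(
                    f"group {group}: planted risk makes requested size infeasible"
                )
            age = _truncated_normal(rng, spec.age_mean, spec.age_sd, lo_age, hi_age, m)
            sex = np.where(rng.random(m) < spec.female_prop, "female", "male")
            a1, a2 = draw_allele_pair(config, rng, size=m)
            p = config.planted_risk.case_probability(a1, a2, age)
            accept = rng.random(m) < (1.0 - p if group == "CON" else p)
            take = min(int(accept.sum()), spec.n - have)
            idx = np.flatnonzero(accept)[:take]
            rows["age"].append(age[idx])
            rows["sex"].append(sex[idx])
            rows["a1"].append(a1[idx])
            rows["a2"].append(a2[idx])
            have += take
        frame = pd.DataFrame({k: np.concatenate(v) for k, v in rows.items()})
        frame.insert(0, "group", group)
        frames.append(frame)
    cohort = pd.concat(frames, ignore_index=True)
    cohort.insert(0, "id", [f"S{i:05d}" for i in range(len(cohort))])

    # reduced-penetrance HD-range injection (overwrite A2)
    if config.hd_carrier_rate > 0:
        carriers = rng.random(len(cohort)) < config.hd_carrier_rate
        cohort.loc[carriers, "a2"] = rng.integers(36, 40, int(carriers.sum()))
    cohort["a1"] = cohort["a1"].astype(int)
    cohort["a2"] = cohort["a2"].astype(int)
    cohort["age"] = cohort["age"].round(1)

    if config.planted_phenotypes:
        _attach_phenotypes(cohort, config, rng)
    return cohort


def _attach_phenotypes(
    cohort: pd.DataFrame, config: SyntheticConfig, rng: np.random.Generator
) -> None:
    n = len(cohort)
    cohort["eICV"] = rng.normal(config.eicv_mean, config.eicv_sd, n).round(1)
    cohort["coil"] = rng.choice(list(config.coil_levels), n)

    def z(x):
        return (x - x.mean()) / x.std(ddof=1)

    a1o = orthogonalize_a1(cohort["a1"].to_numpy(float), cohort["a2"].to_numpy(float))
    comp = {
        "A1orth": z(a1o),
        "A2": z(cohort["a2"].to_numpy(float)),
        "age": z(cohort["age"].to_numpy(float)),
        "sex": (cohort["sex"] == "male").to_numpy(float),
        "status": (cohort["group"] != "CON").to_numpy(float),
        "eICV": z(cohort["eICV"].to_numpy(float)),
    }
    comp["A1orth_x_A2"] = comp["A1orth"] * comp["A2"]
    comp["A1orth_x_age"] = comp["A1orth"] * comp["age"]
    comp["A2_x_age"] = comp["A2"] * comp["age"]

    for pheno in config.planted_phenotypes:
        signal = np.zeros(n)
        for term, beta in pheno.betas:
            signal += beta * comp[term]
        if pheno.conditional_threshold is not None and pheno.conditional_beta != 0.0:
            mask = cohort["a2"].to_numpy() >= pheno.conditional_threshold
            signal += pheno.conditional_beta * comp["A1orth"] * mask
        resid_var = max(1.0 - float(np.var(signal, ddof=1)), 0.05)
        y = signal + rng.normal(0.0, np.sqrt(resid_var), n)
        cohort[pheno.name] = pheno.offset + pheno.scale * y


# ---------------------------------------------------------------------------
# Recovery experiments
# ---------------------------------------------------------------------------


def recovery_experiment(
    config: SyntheticConfig,
    reps: int,
    stages: Sequence[str] = ("association",),
    base_seed: int = 0,
    case_group: str = "ANX",
    stratum: str = "older",
    combinations: Sequence[str] = ("bb", "bc"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Repeat generate -> analyse and summarize recovery of planted effects.

    Per rep, the cohort is regenerated with seed ``base_seed + rep`` and
    the requested pipeline stages are run.  Returns (per-rep estimates,
    summary) where the summary reports mean estimate, bias against the
    planted truth (where defined), empirical SD, and 95%-CI coverage.
    Failed reps are recorded, not raised.
    """
    from .association import AnalysisConfig, run_category_association
    from .riskmodel import CagRiskModel

    if reps < 2:
        raise ValueError("need reps >= 2")
    records, failures = [], 0
    for rep in range(reps):
        try:
            cohort = generate_cohort(config, seed=base_seed + rep)
            if "association" in stages:
                screen = run_category_association(
                    cohort,
                    config=AnalysisConfig(),
                    case_group=case_group,
                    stratum=stratum,
                    compute_omnibus=False,
                )
                for r in screen.results:
                    if r.combination in combinations:
                        records.append(
                            {
                                "rep": rep,
                                "stage": "association",
                                "param": f"or_{r.combination}",
                                "estimate": r.or_estimate,
                                "ci_low": r.ci_low,
                                "ci_high": r.ci_high,
                                "p": r.p,
                            }
                        )
            if "risk" in stages:
                fit = CagRiskModel.from_cohort(
                    cohort, case_groups=(case_group,), stratum=stratum
                ).fit()
                raw = fit.params_raw
                for term in RISK_TERMS:
                    records.append(
                        {
                            "rep": rep,
                            "stage": "risk",
                            "param": f"beta_{term}",
                            "estimate": float(raw[term]),
                            "ci_low": np.nan,
                            "ci_high": np.nan,
                            "p": float(fit.pvalues[term]),
                        }
                    )
        except Exception as exc:  # noqa: BLE001 - reps must not abort the experiment
            failures += 1
            logger.warning("rep %d failed: %s", rep, exc)
    per_rep = pd.DataFrame(records)

    truth: dict[str, float] = {}
    pr = config.planted_risk
    for label, logor in pr.combo_logor:
        # carrier-vs-rest OR of a combination-label offset is exact
        truth[f"or_{label}"] = float(np.exp(logor))
    if pr.step_threshold is not None and pr.step_logor:
        # a repeat-threshold step attenuates in the carrier-vs-rest table
        truth.setdefault("or_bc", float(np.exp(pr.step_logor)))
    rows = []
    if not per_rep.empty:
        for param, sub in per_rep.groupby("param"):
            est = sub["estimate"].to_numpy()
            t = truth.get(param, np.nan)
            cover = np.nan
            if np.isfinite(t) and sub["ci_low"].notna().all():
                cover = float(
                    np.mean((sub["ci_low"] <= t) & (t <= sub["ci_high"]))
                )
            rows.append(
                {
                    "param": param,
                    "truth": t,
                    "mean": float(est.mean()),
                    "bias": float(est.mean() - t) if np.isfinite(t) else np.nan,
                    "empirical_sd": float(est.std(ddof=1)),
                    "ci95_coverage": cover,
                    "reps": int(sub["rep"].nunique()),
                    "failures": failures,
                }
            )
    summary = pd.DataFrame(rows)
    return per_rep, summary
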