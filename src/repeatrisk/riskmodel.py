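"""Two-allele nonlinear logistic risk model with Gram-Schmidt
orthonormalized design, age stratification and relative-risk surfaces.

The model regresses case-control status on five allele terms

    A1, A2, A1^2, A2^2, A1 x A2

(alleles mean-centered before squaring / forming the product).  Because
A1 and A2 are intrinsically correlated (r ~ 0.36 in the population this
package models), the columns are sequentially orthonormalized
(modified Gram-Schmidt in the listed order, with the intercept as the
implicit first direction) before fitting; the recorded basis-change
matrix makes coefficients reportable in either basis, and fitted
probabilities are identical in both.

The central objects follow the statsmodels convention: build a
:class:`CagRiskModel` from data, call :meth:`~CagRiskModel.fit`, and
work with the returned :class:`CagRiskResults` (coefficient table,
``summary()``, ``relative_risk_surface()``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)

TERM_NAMES = ("A1", "A2", "A1sq", "A2sq", "A1xA2")
#: age-interaction terms kept in the pooled model (plus the main age factor)
REPORTED_AGE_INTERACTIONS = ("A1", "A2", "A2sq", "A1xA2")


class DesignError(ValueError):
    pass


@dataclass
class DesignMatrix:
    """Design of the five allele terms plus intercept.

    ``exog`` holds the intercept as column 0 followed by the five terms
    in :data:`TERM_NAMES` order.  ``transform`` maps raw columns to
    orthonormal ones: ``Q = X @ transform.T`` with ``transform``
    lower-triangular (sequential orthogonalization).
    """

    exog: np.ndarray
    names: tuple[str, ...]
    basis: str  # "raw" | "orthonormal"
    means: tuple[float, float]  # centering means of (a1, a2)
    transform: Optional[np.ndarray] = None

    @property
    def n(self) -> int:
        return self.exog.shape[0]


def _raw_columns(a1: np.ndarray, a2: np.ndarray, means: tuple[float, float]) -> np.ndarray:
    x1 = a1 - means[0]
    x2 = a2 - means[1]
    return np.column_stack([np.ones_like(x1), x1, x2, x1**2, x2**2, x1 * x2])


def build_design(a1: Sequence[float], a2: Sequence[float]) -> DesignMatrix:
    """Raw-basis design: intercept + centered A1, A2, A1^2, A2^2, A1xA2."""
    a1 = np.asarray(a1, dtype=float)
    a2 = np.asarray(a2, dtype=float)
    if a1.shape != a2.shape or a1.ndim != 1:
        raise DesignError("a1 and a2 must be 1-d arrays of equal length")
    if a1.size < 10:
        raise DesignError("need at least 10 subjects for an identifiable design")
    means = (float(a1.mean()), float(a2.mean()))
    return DesignMatrix(
        exog=_raw_columns(a1, a2, means),
        names=("const",) + TERM_NAMES,
        basis="raw",
        means=means,
    )


def orthonormalize(design: DesignMatrix, rtol: float = 1e-10) -> DesignMatrix:
    """Modified Gram-Schmidt over the design columns, intercept first.

    Columns are orthogonalized sequentially in their stated order and
    scaled to unit Euclidean norm.  Raises :class:`DesignError` naming
    the first column that is (numerically) linearly dependent on its
    predecessors.
    """
    if design.basis != "raw":
        raise DesignError("expected a raw-basis design")
    X = design.exog.astype(float).copy()
    n, k = X.shape
    Q = np.empty_like(X)
    # R upper-triangular with X = Q R; transform = inv(R).T is lower-triangular
    R = np.zeros((k, k))
    for j in range(k):
        v = X[:, j].copy()
        norm0 = np.linalg.norm(v)
        for i in range(j):
            R[i, j] = Q[:, i] @ v
            v -= R[i, j] * Q[:, i]
        norm = np.linalg.norm(v)
        if norm <= rtol * max(norm0, 1.0):
            raise DesignError(
                f"column {design.names[j]!r} is linearly dependent on earlier columns"
            )
        R[j, j] = norm
        Q[:, j] = v / norm
    transform = np.linalg.inv(R).T
    return DesignMatrix(
        exog=Q,
        names=design.names,
        basis="orthonormal",
        means=design.means,
        transform=transform,
    )


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------


class CagRiskModel:
    """Binomial logistic model of case status on the two-allele terms.

    Parameters
    ----------
    endog : array-like of {0, 1}
        Case-control status (1 = case).
    a1, a2 : array-like of int
        Lower and higher CAG repeat counts per subject.
    age_factor : array-like of {0, 1}, optional
        Two-level age factor (1 = older stratum).  When given, the design
        additionally contains the factor and its interactions with the
        allele terms (``interactions`` selects which).
    interactions : {"reported", "full"}
        With an age factor, "reported" includes age x {A1, A2, A2sq,
        A1xA2}; "full" includes age x all five terms so that the pooled
        model spans the two stratified fits exactly.
    """

    def __init__(
        self,
        endog,
        a1,
        a2,
        age_factor=None,
        interactions: str = "reported",
        stratum: str = "pooled",
    ):
        self.endog = np.asarray(endog, dtype=float)
        if set(np.unique(self.endog)) - {0.0, 1.0}:
            raise ValueError("endog must be binary 0/1")
        if self.endog.min() == self.endog.max():
            raise ValueError("both case and control labels must be present")
        self.a1 = np.asarray(a1, dtype=float)
        self.a2 = np.asarray(a2, dtype=float)
        self.stratum = stratum
        self.design_raw = build_design(self.a1, self.a2)
        self.design = orthonormalize(self.design_raw)
        self.exog_names = list(self.design.names)
        self._exog = self.design.exog
        self.age_factor = None
        if age_factor is not None:
            self.age_factor = np.asarray(age_factor, dtype=float)
            terms = TERM_NAMES if interactions == "full" else REPORTED_AGE_INTERACTIONS
            cols = [self.age_factor]
            names = ["age"]
            idx = {name: i for i, name in enumerate(self.design.names)}
            for t in terms:
                cols.append(self.age_factor * self.design.exog[:, idx[t]])
                names.append(f"age_x_{t}")
            self._exog = np.column_stack([self.design.exog] + [np.column_stack(cols)])
            self.exog_names = list(self.design.names) + names

    @classmethod
    def from_cohort(
        cls,
        cohort: pd.DataFrame,
        case_groups: Sequence[str] = ("MDD", "ANX"),
        control_group: str = "CON",
        stratum: str = "pooled",
        age_split: float = 48.0,
        interactions: str = "reported",
    ) -> "CagRiskModel":
        """Build the model from a cohort table (columns group, age, a1, a2)."""
        df = cohort[cohort["group"].isin(list(case_groups) + [control_group])]
        age_factor = None
        if stratum == "older":
            df = df[df["age"] >= age_split]
        elif stratum == "younger":
            df = df[df["age"] < age_split]
        elif stratum == "pooled":
            age_factor = (df["age"] >= age_split).astype(float).to_numpy()
        else:
            raise ValueError(f"unknown stratum {stratum!r}")
        if df.empty:
            raise ValueError(f"stratum {stratum!r} is empty")
        endog = df["group"].isin(case_groups).astype(float).to_numpy()
        return cls(
            endog,
            df["a1"].to_numpy(),
            df["a2"].to_numpy(),
            age_factor=age_factor,
            interactions=interactions,
            stratum=stratum,
        )

    def fit(self, tol: float = 1e-10, maxiter: int = 100) -> "CagRiskResults":
        """Maximum likelihood by IRLS; returns a :class:`CagRiskResults`."""
        glm = sm.GLM(self.endog, self._exog, family=sm.families.Binomial())
        import warnings

        converged = True
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = glm.fit(maxiter=maxiter, tol=tol, scale=1.0)
        converged = bool(getattr(res, "converged", True))
        params = np.asarray(res.params)
        if not np.all(np.isfinite(params)) or np.max(np.abs(params)) > 1e4:
            converged = False  # diverging norms: likely complete separation
        if not converged:
            logger.warning("logistic fit flagged as non-converged (stratum %s)", self.stratum)
        return CagRiskResults(model=self, _glm_results=res, converged=converged)


@dataclass
class CagRiskResults:
    """Fitted two-allele risk model (orthonormal basis).

    ``params``/``bse``/``pvalues`` are indexed by ``model.exog_names``;
    ``params_raw`` back-transforms the five allele terms (and intercept)
    into the raw centered-polynomial basis.
    """

    model: CagRiskModel
    _glm_results: object
    converged: bool

    @property
    def params(self) -> pd.Series:
        return pd.Series(np.asarray(self._glm_results.params), index=self.model.exog_names)

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.asarray(self._glm_results.bse), index=self.model.exog_names)

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series(np.asarray(self._glm_results.pvalues), index=self.model.exog_names)

    @property
    def deviance(self) -> float:
        return float(self._glm_results.deviance)

    @property
    def n_iter(self) -> int:
        return int(len(self._glm_results.fit_history.get("deviance", [])) - 1)

    @property
    def fittedvalues(self) -> np.ndarray:
        return np.asarray(self._glm_results.fittedvalues)

    @property
    def params_raw(self) -> pd.Series:
        """Allele-term coefficients mapped back to the raw centered basis."""
        gamma = np.asarray(self._glm_results.params)[:6]
        beta = self.model.design.transform.T @ gamma
        return pd.Series(beta, index=self.model.design.names)

    @property
    def base_rate(self) -> float:
        """Case proportion of the fitted subsample."""
        return float(self.model.endog.mean())

    def predict_proba(self, a1, a2, older=None) -> np.ndarray:
        """Predicted case probability for integer allele pairs."""
        a1 = np.asarray(a1, dtype=float)
        a2 = np.asarray(a2, dtype=float)
        X = _raw_columns(a1, a2, self.model.design.means)
        eta = X @ self.params_raw.to_numpy()
        if self.model.age_factor is not None:
            if older is None:
                raise ValueError("pooled model: pass older=0/1")
            older = np.broadcast_to(np.asarray(older, dtype=float), a1.shape)
            names = self.model.exog_names
            gamma = np.asarray(self._glm_results.params)
            eta = eta + gamma[names.index("age")] * older
            # interaction columns were formed from orthonormal term columns
            idx = {name: i for i, name in enumerate(self.model.design.names)}
            Tmat = self.model.design.transform  # q_j = sum_k T[j,k] x_k
            for j, name in enumerate(names):
                if name.startswith("age_x_"):
                    term = name[len("age_x_"):]
                    q_row = Tmat[idx[term]]
                    eta = eta + gamma[j] * older * (X @ q_row)
        return 1.0 / (1.0 + np.exp(-eta))

    def relative_risk_surface(self, extrapolate: bool = False) -> pd.DataFrame:
        return relative_risk_surface(self, extrapolate=extrapolate)

    def summary(self) -> str:
        rows = pd.DataFrame(
            {"coef": self.params, "std err": self.bse, "P>|z|": self.pvalues}
        )
        head = (
            f"Two-allele CAG logistic risk model ({self.model.stratum} stratum)\n"
            f"n = {len(self.model.endog)}, cases = {int(self.model.endog.sum())}, "
            f"deviance = {self.deviance:.3f}, converged = {self.converged}\n"
            f"(coefficients in the orthonormal basis; see params_raw for the raw basis)\n"
        )
        return head + rows.to_string(float_format=lambda v: f"{v: .4f}")


def fit_logistic(design: DesignMatrix, labels, tol: float = 1e-10, maxiter: int = 100):
    """Fit a logistic regression on an explicit design matrix.

    Functional convenience over :class:`statsmodels` GLM; returns the
    GLMResults object (params, bse, pvalues, deviance, converged).
    """
    labels = np.asarray(labels, dtype=float)
    if labels.min() == labels.max():
        raise ValueError("both labels must be present")
    import warnings

    glm = sm.GLM(labels, design.exog, family=sm.families.Binomial())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = glm.fit(maxiter=maxiter, tol=tol, scale=1.0)
    return res


@dataclass
class AgeModelSet:
    younger: CagRiskResults
    older: CagRiskResults
    pooled: CagRiskResults


def fit_age_models(
    cohort: pd.DataFrame,
    age_split: float = 48.0,
    case_groups: Sequence[str] = ("MDD", "ANX"),
    interactions: str = "reported",
) -> AgeModelSet:
    """Stratified (younger/older) fits plus the pooled fit with an age factor."""
    kw = dict(case_groups=case_groups, age_split=age_split)
    sets = {}
    for stratum in ("younger", "older"):
        sub = cohort[
            (cohort["age"] >= age_split) if stratum == "older" else (cohort["age"] < age_split)
        ]
        if sub.empty:
            raise ValueError(f"age split {age_split} leaves the {stratum} stratum empty")
        sets[stratum] = CagRiskModel.from_cohort(cohort, stratum=stratum, **kw).fit()
    pooled = CagRiskModel.from_cohort(
        cohort, stratum="pooled", interactions=interactions, **kw
    ).fit()
    return AgeModelSet(younger=sets["younger"], older=sets["older"], pooled=pooled)


def relative_risk_surface(
    results: CagRiskResults, extrapolate: bool = False, older=None
) -> pd.DataFrame:
    """Relative-risk grid over (a1, a2) allele combinations.

    Relative risk per cell = predicted case probability / case proportion
    of the fitted subsample, so values > 1 mark combinations with
    elevated risk.  Without extrapolation only combinations observed in
    the data appear; with it, the full integer rectangle of the data
    range (a1 <= a2) is covered and unobserved cells are flagged.
    """
    if not results.converged:
        raise ValueError("refusing to build a surface from a non-converged fit")
    base = results.base_rate
    if base <= 0.0 or base >= 1.0:
        raise ValueError("degenerate baseline case proportion")
    m = results.model
    observed = pd.DataFrame({"a1": m.a1.astype(int), "a2": m.a2.astype(int)})
    n_obs = observed.groupby(["a1", "a2"]).size()
    if extrapolate:
        lo1, hi1 = int(m.a1.min()), int(m.a1.max())
        lo2, hi2 = int(m.a2.min()), int(m.a2.max())
        cells = [
            (i, j)
            for i in range(lo1, hi1 + 1)
            for j in range(max(i, lo2), hi2 + 1)
        ]
    else:
        cells = list(n_obs.index)
    a1 = np.array([c[0] for c in cells], dtype=float)
    a2 = np.array([c[1] for c in cells], dtype=float)
    if m.age_factor is not None and older is None:
        raise ValueError("pooled model: pass older=0/1 to evaluate the surface")
    prob = results.predict_proba(a1, a2, older=older)
    return pd.DataFrame(
        {
            "a1": a1.astype(int),
            "a2": a2.astype(int),
            "relative_risk": prob / base,
            "extrapolated": [c not in n_obs.index for c in cells],
            "n_observed": [int(n_obs.get(c, 0)) for c in cells],
        }
    )


def surface_from_params(
    params_raw: Sequence[float],
    means: tuple[float, float],
    base_rate: float,
    cells: Sequence[tuple[int, int]],
) -> pd.DataFrame:
    """Relative-risk surface from explicit raw-basis coefficients.

    Useful for null or hand-specified models: ``params_raw`` is
    (const, A1, A2, A1sq, A2sq, A1xA2) on the centered raw basis with
    ``const = logit(base_rate)`` giving the intercept-only surface == 1.
    """
    a1 = np.array([c[0] for c in cells], dtype=float)
    a2 = np.array([c[1] for c in cells], dtype=float)
    X = _raw_columns(a1, a2, means)
    prob = 1.0 / (1.0 + np.exp(-(X @ np.asarray(params_raw, dtype=float))))
    return pd.DataFrame(
        {"a1": a1.astype(int), "a2": a2.astype(int), "relative_risk": prob / base_rate}
    )
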