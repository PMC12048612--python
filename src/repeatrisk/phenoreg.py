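"""Orthogonalized-allele regressions for quantitative and binary
phenotypes.

The shorter allele A1 is residualized against the longer allele A2
(``A1_orth``) so that both can enter one regression without
collinearity.  Volumetric outcomes are modelled on age, sex,
case-control status, estimated intracranial volume (eICV), scanner coil
type, A2, A1_orth and the interactions A1_orth x A2, age x A1_orth and
age x A2, with standardized coefficients; clinical outcomes reuse the
same engine with age as a two-level factor (median split at 50 years)
and a logistic variant (Nagelkerke pseudo-R^2) for binary outcomes.
A normative-deviation transform expresses a measured volume as the
percentage deviation from the volume predicted by a reference-sample
covariate model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .association import fdr_adjust

logger = logging.getLogger(__name__)

#: model terms reported per outcome, in table order
PHENO_TERMS = (
    "status",
    "A1orth",
    "A2",
    "age",
    "A1orth_x_A2",
    "A1orth_x_age",
    "A2_x_age",
)


def orthogonalize_a1(a1: Sequence[float], a2: Sequence[float]) -> np.ndarray:
    """Residualize A1 on A2 (least squares with intercept).

    The result has exactly zero sample correlation with A2 and replaces
    A1 in regressions that also contain A2.
    """
    a1 = np.asarray(a1, dtype=float)
    a2 = np.asarray(a2, dtype=float)
    if a1.shape != a2.shape or a1.ndim != 1 or a1.size < 3:
        raise ValueError("a1 and a2 must be equal-length 1-d arrays, n >= 3")
    if np.ptp(a2) == 0:
        raise ValueError("A2 is constant; cannot orthogonalize")
    x2c = a2 - a2.mean()
    slope = (x2c @ (a1 - a1.mean())) / (x2c @ x2c)
    return a1 - a1.mean() - slope * x2c


def normative_deviation(
    df: pd.DataFrame,
    outcome: str,
    reference_mask,
    covariates: Sequence[str] = ("age", "sex", "eICV", "coil"),
    min_reference: int = 50,
) -> pd.Series:
    """Percentage deviation of a measured volume from its normative
    prediction.

    A linear covariate model is fitted on the reference subjects only
    (``reference_mask``); every subject's deviation is then
    ``100 * (measured - predicted) / predicted``.  Records with a
    non-positive prediction are flagged as NaN with a warning.
    """
    mask = np.asarray(reference_mask, dtype=bool)
    ref = df[mask]
    if len(ref) < min_reference:
        raise ValueError(f"need >= {min_reference} reference subjects, got {len(ref)}")
    X = _covariate_matrix(df, covariates)
    model = sm.OLS(ref[outcome].to_numpy(dtype=float), X[mask]).fit()
    predicted = X @ model.params
    deviation = 100.0 * (df[outcome].to_numpy(dtype=float) - predicted) / predicted
    bad = predicted <= 0
    if bad.any():
        logger.warning("%d records with non-positive normative prediction flagged", bad.sum())
        deviation[bad] = np.nan
    return pd.Series(deviation, index=df.index, name=f"{outcome}_pct_dev")


def _covariate_matrix(df: pd.DataFrame, covariates: Sequence[str]) -> np.ndarray:
    cols = [np.ones(len(df))]
    for c in covariates:
        v = df[c]
        if v.dtype == object or str(v.dtype) == "category":
            dummies = pd.get_dummies(v, drop_first=True, dtype=float)
            cols.extend(dummies[c].to_numpy() for c in dummies)
        else:
            cols.append(v.to_numpy(dtype=float))
    return np.column_stack(cols)


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("constant column cannot be standardized")
    return (x - x.mean()) / sd


def _binary(series: pd.Series) -> np.ndarray:
    vals = pd.unique(series.dropna())
    if len(vals) > 2:
        raise ValueError(f"column {series.name!r} is not binary")
    mapping = {v: i for i, v in enumerate(sorted(vals, key=str))}
    return series.map(mapping).to_numpy(dtype=float)


class PhenotypeModel:
    """Regression of one phenotype on the orthogonalized allele terms.

    Standardization convention: the outcome (linear models) and every
    continuous predictor are z-scored; binary predictors stay 0/1;
    interaction columns are products of the standardized components.

    Parameters
    ----------
    df : DataFrame
        Complete-case table with columns ``a1``, ``a2``, ``age``,
        ``sex``, the outcome and any extra covariates.
    outcome : str
        Column to model.
    binary : bool
        Fit a logistic model (outcome must be binary).
    age_coding : {"continuous", "median_split"}
        Continuous z-scored age (volumetric models) or a two-level
        factor split at ``age_split`` years (clinical models).
    extra_covariates : sequence of str
        e.g. ``("status", "eICV", "coil")`` for the volumetric models.
    """

    def __init__(
        self,
        df: pd.DataFrame,
        outcome: str,
        binary: bool = False,
        age_coding: str = "continuous",
        age_split: float = 50.0,
        extra_covariates: Sequence[str] = (),
        min_n: int = 30,
    ):
        cols = ["a1", "a2", "age", "sex", outcome, *extra_covariates]
        data = df[cols].dropna()
        if len(data) < min_n:
            raise ValueError(f"only {len(data)} complete cases for {outcome!r} (< {min_n})")
        self.outcome = outcome
        self.binary = binary
        self.nobs = len(data)

        a1o = orthogonalize_a1(data["a1"].to_numpy(float), data["a2"].to_numpy(float))
        z_a1o = _zscore(a1o)
        z_a2 = _zscore(data["a2"].to_numpy(float))
        if age_coding == "continuous":
            z_age = _zscore(data["age"].to_numpy(float))
        elif age_coding == "median_split":
            z_age = (data["age"].to_numpy(float) >= age_split).astype(float)
        else:
            raise ValueError(f"unknown age_coding {age_coding!r}")

        design = {
            "const": np.ones(self.nobs),
            "sex": _binary(data["sex"]),
        }
        for cov in extra_covariates:
            v = data[cov]
            if v.dtype == object or str(v.dtype) == "category" or v.nunique() <= 2:
                if v.nunique() <= 2:
                    design[cov] = _binary(v)
                else:
                    dummies = pd.get_dummies(v, drop_first=True, dtype=float)
                    for dc in dummies:
                        design[f"{cov}[{dc}]"] = dummies[dc].to_numpy()
            else:
                design[cov] = _zscore(v.to_numpy(float))
        design["A1orth"] = z_a1o
        design["A2"] = z_a2
        design["age"] = z_age
        design["A1orth_x_A2"] = z_a1o * z_a2
        design["A1orth_x_age"] = z_a1o * z_age
        design["A2_x_age"] = z_a2 * z_age
        # canonical alias so "status" appears under its table name
        self.exog = pd.DataFrame(design)

        rank = np.linalg.matrix_rank(self.exog.to_numpy())
        if rank < self.exog.shape[1]:
            _, R = np.linalg.qr(self.exog.to_numpy())
            aliased = [
                self.exog.columns[j]
                for j in range(self.exog.shape[1])
                if abs(R[j, j]) < 1e-8
            ]
            raise ValueError(f"rank-deficient design; aliased terms: {aliased}")

        y = data[outcome].to_numpy()
        if binary:
            self.endog = _binary(data[outcome])
        else:
            self.endog = _zscore(y.astype(float))
        self.endog_sd = 1.0 if binary else float(np.std(y.astype(float), ddof=1))

    def fit(self) -> "PhenotypeResults":
        import warnings

        if self.binary:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.GLM(self.endog, self.exog, family=sm.families.Binomial()).fit()
            llf, lln = res.llf, res.llnull if hasattr(res, "llnull") else None
            if lln is None:
                null = sm.GLM(
                    self.endog, np.ones((self.nobs, 1)), family=sm.families.Binomial()
                ).fit()
                lln = null.llf
            n = self.nobs
            cox_snell = 1.0 - np.exp(2.0 * (lln - llf) / n)
            r2 = cox_snell / (1.0 - np.exp(2.0 * lln / n))
        else:
            res = sm.OLS(self.endog, self.exog).fit()
            r2 = res.rsquared_adj
        return PhenotypeResults(
            outcome=self.outcome,
            params=res.params,
            bse=res.bse,
            pvalues=res.pvalues,
            nobs=self.nobs,
            rsq=float(r2),
            binary=self.binary,
        )


@dataclass
class PhenotypeResults:
    """Standardized coefficient table for one outcome."""

    outcome: str
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    nobs: int
    rsq: float
    binary: bool

    def summary(self) -> str:
        kind = "logistic (Nagelkerke R2)" if self.binary else "linear (adj. R2)"
        rows = pd.DataFrame({"beta": self.params, "p": self.pvalues})
        return (
            f"Phenotype model: {self.outcome} [{kind} = {self.rsq:.3f}, n = {self.nobs}]\n"
            + rows.to_string(float_format=lambda v: f"{v: .4f}")
        )


def fit_phenotype_model(
    df: pd.DataFrame,
    outcomes: Sequence[str],
    binary: Optional[Sequence[bool]] = None,
    age_coding: str = "continuous",
    age_split: float = 50.0,
    extra_covariates: Sequence[str] = (),
    min_n: int = 30,
) -> pd.DataFrame:
    """Fit one model per outcome and FDR-adjust per term across the family.

    Returns a long table with columns outcome, term, beta, p, q, n, rsq;
    q-values are BH-adjusted within each term across the outcome family
    (matching per-column adjustment of a results table).
    """
    if binary is None:
        binary = [False] * len(outcomes)
    rows = []
    for outcome, is_bin in zip(outcomes, binary):
        fit = PhenotypeModel(
            df,
            outcome,
            binary=is_bin,
            age_coding=age_coding,
            age_split=age_split,
            extra_covariates=extra_covariates,
            min_n=min_n,
        ).fit()
        for term in fit.params.index:
            if term == "const":
                continue
            rows.append(
                {
                    "outcome": outcome,
                    "term": term,
                    "beta": float(fit.params[term]),
                    "p": float(fit.pvalues[term]),
                    "n": fit.nobs,
                    "rsq": fit.rsq,
                }
            )
    table = pd.DataFrame(rows)
    table["q"] = np.nan
    for term, idx in table.groupby("term").groups.items():
        table.loc[idx, "q"] = fdr_adjust(table.loc[idx, "p"].to_numpy())
    return table


def a2_split_profile(
    df: pd.DataFrame,
    outcome: str,
    split_positions: Sequence[int],
    age_coding: str = "continuous",
    extra_covariates: Sequence[str] = (),
    min_n: int = 30,
) -> pd.DataFrame:
    """Profile of the A1_orth effect across A2-defined subsamples.

    For each split position *s* the phenotype model is refitted within
    the low (A2 < s) and high (A2 >= s) subsamples and the A1_orth
    coefficient recorded.  Undersized subsamples are skipped with a
    warning.  Exposes nonlinear, A2-conditional effects of the shorter
    allele that the pooled interaction term can blur.
    """
    rows = []
    for s in split_positions:
        for side, sub in (("low", df[df["a2"] < s]), ("high", df[df["a2"] >= s])):
            if len(sub.dropna(subset=[outcome])) < min_n:
                logger.warning("split %d (%s side): subsample too small, skipped", s, side)
                continue
            try:
                fit = PhenotypeModel(
                    sub,
                    outcome,
                    age_coding=age_coding,
                    extra_covariates=extra_covariates,
                    min_n=min_n,
                ).fit()
            except ValueError as exc:
                logger.warning("split %d (%s side) skipped: %s", s, side, exc)
                continue
            rows.append(
                {
                    "split": int(s),
                    "side": side,
                    "beta_a1orth": float(fit.params["A1orth"]),
                    "p_a1orth": float(fit.pvalues["A1orth"]),
                    "n": fit.nobs,
                }
            )
    return pd.DataFrame(rows)


def item_subset_score(
    items: pd.DataFrame, subset: Sequence[str], name: str = "subset_score"
) -> pd.Series:
    """Sum a configurable subset of item columns into one score.

    Generic constructor for sub-scores such as the anhedonia-related
    subset of a depression inventory; the item list is supplied by
    configuration.
    """
    missing = [c for c in subset if c not in items.columns]
    if missing:
        raise KeyError(f"missing item columns: {missing}")
    return items[list(subset)].sum(axis=1).rename(name)
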