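"""Category-level case-control statistics.

Implements the odds-ratio screen over genotype combinations (e.g. "bb",
"bc"), with a minimum-count filter, Benjamini-Hochberg FDR within each
screen, an omnibus combination-by-status exact test, age stratification
at a configurable boundary, the b/c split-point robustness scan, and
ANOVA/ANCOVA comparisons of mean repeat counts between groups.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .alleles import CANONICAL_SCHEME, HD_FULL_LABEL, RangeScheme, combine

logger = logging.getLogger(__name__)

CONTROL_GROUP = "CON"


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable knobs of the category screen."""

    age_split: float = 48.0  # "older" stratum is age >= age_split (inclusive)
    min_count: int = 5  # min carriers per combination in BOTH diagnosis groups
    fdr_q: float = 0.05
    split_points: tuple[int, ...] = (19, 20, 21, 22, 23)

    def __post_init__(self) -> None:
        if self.min_count < 1:
            raise ValueError("min_count must be >= 1")
        if not 0 < self.fdr_q < 1:
            raise ValueError("fdr_q must lie in (0, 1)")


@dataclass
class ContingencyResult:
    """One genotype-combination x diagnosis 2x2 screen result."""

    combination: str
    stratum: str
    counts: tuple[int, int, int, int]  # case_carrier, case_non, con_carrier, con_non
    or_estimate: float
    ci_low: float
    ci_high: float
    p: float
    q: float = float("nan")


def odds_ratio(table: Sequence[int]) -> tuple[float, float, float]:
    """Cross-product odds ratio with a 95% Wald interval on the log scale.

    ``table`` is (case_carrier, case_noncarrier, control_carrier,
    control_noncarrier).  When any cell is zero the Haldane-Anscombe
    correction (+0.5 to every cell) is applied before both the estimate
    and the interval.
    """
    a, b, c, d = (float(x) for x in table)
    if min(a, b, c, d) < 0:
        raise ValueError("cell counts must be nonnegative")
    if a + b + c + d == 0:
        raise ValueError("table of all zeros")
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_est = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(0.975)
    log_or = np.log(or_est)
    return float(or_est), float(np.exp(log_or - z * se)), float(np.exp(log_or + z * se))


def fisher_exact(table: Sequence[int]) -> float:
    """Two-sided Fisher exact p for a 2x2 table.

    Two-sidedness by summation of hypergeometric probabilities no larger
    than the observed table's probability.
    """
    a, b, c, d = (int(x) for x in table)
    if min(a, b, c, d) < 0:
        raise ValueError("cell counts must be nonnegative")
    if a + b + c + d == 0:
        raise ValueError("table of all zeros")
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def fdr_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Cohort helpers
# ---------------------------------------------------------------------------


def _as_frame(subjects) -> pd.DataFrame:
    """Accept a DataFrame or an iterable of Subject records."""
    if isinstance(subjects, pd.DataFrame):
        return subjects
    return pd.DataFrame(
        {
            "id": [s.id for s in subjects],
            "group": [s.group for s in subjects],
            "sex": [s.sex for s in subjects],
            "age": [s.age for s in subjects],
            "a1": [s.a1 for s in subjects],
            "a2": [s.a2 for s in subjects],
        }
    )


def combination_labels(df: pd.DataFrame, scheme: RangeScheme) -> pd.Series:
    """Genotype-combination label per row, dropping fully penetrant flags."""
    labels = [combine(a1, a2, scheme) for a1, a2 in zip(df["a1"], df["a2"])]
    ser = pd.Series(labels, index=df.index, name="combination")
    n_hd = int((ser == HD_FULL_LABEL).sum())
    if n_hd:
        logger.warning("%d subjects with fully penetrant HD alleles excluded", n_hd)
    return ser


def select_stratum(df: pd.DataFrame, stratum: str, age_split: float) -> pd.DataFrame:
    if stratum == "all":
        return df
    if stratum == "older":
        return df[df["age"] >= age_split]
    if stratum == "younger":
        return df[df["age"] < age_split]
    raise ValueError(f"unknown stratum {stratum!r}")


def build_carrier_table(
    subjects,
    combination: str,
    case_group: str,
    scheme: RangeScheme = CANONICAL_SCHEME,
) -> tuple[int, int, int, int]:
    """2x2 counts (case_carrier, case_non, control_carrier, control_non).

    Carriers are subjects whose genotype combination equals
    ``combination``; noncarriers are all other subjects of the same
    diagnosis group in the (pre-filtered) roster.
    """
    df = _as_frame(subjects)
    df = df[df["group"].isin([case_group, CONTROL_GROUP])]
    if df.empty:
        raise ValueError("empty stratum")
    labels = combination_labels(df, scheme)
    keep = labels != HD_FULL_LABEL
    df, labels = df[keep], labels[keep]
    is_case = (df["group"] == case_group).to_numpy()
    is_carrier = (labels == combination).to_numpy()
    return (
        int(np.sum(is_case & is_carrier)),
        int(np.sum(is_case & ~is_carrier)),
        int(np.sum(~is_case & is_carrier)),
        int(np.sum(~is_case & ~is_carrier)),
    )


# ---------------------------------------------------------------------------
# Omnibus exact association on the K x 2 combination-by-status table
# ---------------------------------------------------------------------------


def _log_table_prob(table: np.ndarray) -> float:
    """Log probability of an r x c table under fixed margins (Fisher model)."""
    table = np.asarray(table, dtype=float)
    return float(
        gammaln(table.sum(axis=1) + 1).sum()
        + gammaln(table.sum(axis=0) + 1).sum()
        - gammaln(table.sum() + 1)
        - gammaln(table + 1).sum()
    )


def omnibus_exact_test(
    table: np.ndarray, n_resamples: int = 2000, seed: int = 0
) -> float:
    """Monte-Carlo Fisher exact test for an r x c contingency table.

    Samples tables with the observed margins (Patefield's algorithm) and
    reports the fraction whose probability does not exceed the observed
    table's, with the +1 correction that keeps the estimate a valid p.
    For 2 x 2 input the exact 2 x 2 test is used directly.
    """
    table = np.asarray(table, dtype=int)
    if table.shape == (2, 2):
        return fisher_exact(table.ravel())
    dist = stats.random_table(table.sum(axis=1), table.sum(axis=0))
    rng = np.random.default_rng(seed)
    samples = dist.rvs(n_resamples, random_state=rng)
    obs = _log_table_prob(table)
    log_probs = np.array([_log_table_prob(t) for t in samples])
    hits = int(np.sum(log_probs <= obs + 1e-9))
    return float((hits + 1) / (n_resamples + 1))


# ---------------------------------------------------------------------------
# The category screen
# ---------------------------------------------------------------------------


@dataclass
class CategoryAssociation:
    """Output of one case-group x stratum screen."""

    case_group: str
    stratum: str
    scheme: RangeScheme
    results: list[ContingencyResult] = field(default_factory=list)
    omnibus_p: float = float("nan")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "case_group": self.case_group,
                "stratum": self.stratum,
                "split_point": self.scheme.split_bc,
                "combination": r.combination,
                "n_case_carrier": r.counts[0],
                "n_case_non": r.counts[1],
                "n_con_carrier": r.counts[2],
                "n_con_non": r.counts[3],
                "or": r.or_estimate,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "p": r.p,
                "q": r.q,
            }
            for r in self.results
        ]
        return pd.DataFrame(rows)


def run_category_association(
    subjects,
    scheme: RangeScheme = CANONICAL_SCHEME,
    config: AnalysisConfig = AnalysisConfig(),
    case_group: str = "MDD",
    stratum: str = "all",
    omnibus_seed: int = 0,
    compute_omnibus: bool = True,
) -> CategoryAssociation:
    """Screen every genotype combination against case-control status.

    A combination is screened only if it has at least ``config.min_count``
    carriers in BOTH the case group and the control group; q-values are
    BH-adjusted across the combinations emitted for this one
    case-group x stratum family.  The omnibus combination-by-status
    exact association p is computed over the same roster.
    """
    df = _as_frame(subjects)
    df = select_stratum(df, stratum, config.age_split)
    df = df[df["group"].isin([case_group, CONTROL_GROUP])]
    if df.empty or (df["group"] == case_group).sum() == 0:
        raise ValueError(f"stratum {stratum!r} lacks {case_group} subjects")

    labels = combination_labels(df, scheme)
    keep = labels != HD_FULL_LABEL
    df, labels = df[keep], labels[keep]
    is_case = (df["group"] == case_group).to_numpy()
    n_case, n_con = int(is_case.sum()), int((~is_case).sum())

    counts = (
        pd.DataFrame({"combination": labels, "case": is_case})
        .groupby("combination")["case"]
        .agg(case_carrier="sum", total="count")
    )
    counts["con_carrier"] = counts["total"] - counts["case_carrier"]

    out = CategoryAssociation(case_group=case_group, stratum=stratum, scheme=scheme)

    if compute_omnibus:
        # omnibus K x 2 table over all observed combinations
        omni = counts[["case_carrier", "con_carrier"]].to_numpy()
        out.omnibus_p = omnibus_exact_test(omni, seed=omnibus_seed)

    eligible = counts[
        (counts["case_carrier"] >= config.min_count)
        & (counts["con_carrier"] >= config.min_count)
    ]
    if eligible.empty:
        logger.warning(
            "no combination passes the min-count filter (%d) for %s/%s",
            config.min_count,
            case_group,
            stratum,
        )
        return out

    for comb, row in eligible.iterrows():
        table = (
            int(row["case_carrier"]),
            n_case - int(row["case_carrier"]),
            int(row["con_carrier"]),
            n_con - int(row["con_carrier"]),
        )
        or_est, lo, hi = odds_ratio(table)
        out.results.append(
            ContingencyResult(
                combination=str(comb),
                stratum=stratum,
                counts=table,
                or_estimate=or_est,
                ci_low=lo,
                ci_high=hi,
                p=fisher_exact(table),
            )
        )
    qs = fdr_adjust([r.p for r in out.results])
    for r, q in zip(out.results, qs):
        r.q = float(q)
    return out


def split_point_scan(
    subjects,
    config: AnalysisConfig = AnalysisConfig(),
    case_group: str = "MDD",
    stratum: str = "older",
) -> pd.DataFrame:
    """Recompute the bb and bc odds ratios while moving the b/c boundary.

    Returns one row per (split point, combination in {bb, bc}) with the
    OR, CI, Fisher p and within-split BH q.
    """
    frames = []
    for split in config.split_points:
        screen = run_category_association(
            subjects,
            scheme=RangeScheme(split),
            config=config,
            case_group=case_group,
            stratum=stratum,
            compute_omnibus=False,
        )
        frame = screen.to_frame()
        frames.append(frame[frame["combination"].isin(["bb", "bc"])])
    scan = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    return scan


def scan_log_or_diff(scan: pd.DataFrame) -> pd.Series:
    """Signed log OR(bc) - log OR(bb) per split point, from a split-scan table."""
    wide = scan.pivot_table(index="split_point", columns="combination", values="or")
    return np.log(wide["bc"]) - np.log(wide["bb"])


def mean_comparison(
    subjects,
    case_group: str,
    covariates: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """ANOVA (or ANCOVA with age/sex covariates) of mean A1 and A2.

    Compares the case group against controls; returns one row per allele
    with the group-factor F statistic and p-value.
    """
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    df = _as_frame(subjects)
    df = df[df["group"].isin([case_group, CONTROL_GROUP])].copy()
    if df["group"].nunique() < 2:
        raise ValueError("need both the case group and controls")
    if (df.groupby("group").size() < 2).any():
        raise ValueError("each group needs at least 2 members")

    terms = ["C(group)"] + [
        f"C({c})" if c == "sex" else c for c in (covariates or [])
    ]
    rows = []
    for allele in ("a1", "a2"):
        model = smf.ols(f"{allele} ~ {' + '.join(terms)}", data=df).fit()
        table = anova_lm(model, typ=2)
        rows.append(
            {
                "allele": allele.upper(),
                "F": float(table.loc["C(group)", "F"]),
                "p": float(table.loc["C(group)", "PR(>F)"]),
                "n": int(model.nobs),
            }
        )
    return pd.DataFrame(rows)


def carrier_frequency_reciprocal(n_carriers: int, n_subjects: int) -> int:
    """Per-subject carrier frequency expressed as a reciprocal ("1 in N").

    Half-up rounding, e.g. 2 carriers among 2629 subjects -> 1315.
    """
    if n_carriers <= 0:
        raise ValueError("need at least one carrier")
    return int(np.floor(n_subjects / n_carriers + 0.5))


def enumerate_combinations(scheme: RangeScheme = CANONICAL_SCHEME) -> list[str]:
    """All 15 distinct unordered category-pair labels under a 5-bin scheme."""
    letters = list(scheme.bins)
    return ["".join(sorted(p)) for p in itertools.combinations_with_replacement(letters, 2)]
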