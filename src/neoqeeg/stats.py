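"""Clinical outcome statistics.

Implements the outcome side of the analysis: ADOS-2 risk
categorisation with verbal/non-verbal cut-offs, 2x2 exposure-outcome
tables with odds ratios and diagnostic metrics, univariable and
multivariable logistic regression (Wald inference, likelihood-ratio
omnibus test, Nagelkerke R²), Mann-Whitney U tests, developmental
quotient transformations, ordinary linear models and a collinearity
check (tolerance/VIF). Logistic and linear fits are backed by
statsmodels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd
from itertools import combinations

from scipy import stats as sstats
import statsmodels.api as sm

__all__ = [
    "RISK_NO", "RISK_MILD_MODERATE", "RISK_HIGH", "ADOSResult",
    "classify_ados_risk", "ados_any_risk", "ContingencyTable2x2",
    "OddsRatioResult", "odds_ratio", "DiagnosticMetrics",
    "diagnostic_metrics", "LogisticFit", "logistic_fit",
    "PerfectSeparationError", "MannWhitneyResult", "mann_whitney_u",
    "transform_dq", "inverse_transform_dq", "linear_model",
    "collinearity_check", "round_half_up",
]


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero (the convention of printed percentages)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


# --------------------------------------------------------------------------
# ADOS-2 risk categorisation
# --------------------------------------------------------------------------

RISK_NO = "no_risk"
RISK_MILD_MODERATE = "mild_moderate"
RISK_HIGH = "high"


@dataclass(frozen=True)
class ADOSResult:
    """ADOS-2 total score with its risk category."""

    total_score: int
    verbal: bool
    category: str


def classify_ados_risk(total_score: int, verbal: bool) -> ADOSResult:
    """Map an ADOS-2 (Toddler Module) total score to its risk category.

    Non-verbal children: 0-9 no risk, 10-13 mild/moderate, >13 high.
    Verbal children: 0-7 no risk, 8-11 mild/moderate, >11 high.
    """
    if total_score < 0:
        raise ValueError("ADOS-2 total score cannot be negative")
    lo, hi = (7, 11) if verbal else (9, 13)
    if total_score <= lo:
        cat = RISK_NO
    elif total_score <= hi:
        cat = RISK_MILD_MODERATE
    else:
        cat = RISK_HIGH
    return ADOSResult(int(total_score), bool(verbal), cat)


def ados_any_risk(total_score: int, verbal: bool) -> bool:
    """Dichotomised ASD outcome: any risk (mild/moderate or high) vs none."""
    return classify_ados_risk(total_score, verbal).category != RISK_NO


# --------------------------------------------------------------------------
# 2x2 tables
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ContingencyTable2x2:
    """Exposure x outcome counts.

    ``a``: exposed & outcome-positive, ``b``: exposed & outcome-negative,
    ``c``: unexposed & outcome-positive, ``d``: unexposed &
    outcome-negative.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        for name in "abcd":
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"cell {name}={v} must be a non-negative integer")
        if self.total == 0:
            raise ValueError("table must contain at least one count")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    @classmethod
    def from_binary(cls, exposure, outcome) -> "ContingencyTable2x2":
        """Cross-tabulate two boolean vectors (pairs with missing values dropped)."""
        e = pd.Series(exposure)
        o = pd.Series(outcome)
        keep = e.notna() & o.notna()
        e = e[keep].astype(bool).to_numpy()
        o = o[keep].astype(bool).to_numpy()
        return cls(int((e & o).sum()), int((e & ~o).sum()),
                   int((~e & o).sum()), int((~e & ~o).sum()))


@dataclass(frozen=True)
class OddsRatioResult:
    """Cross-product odds ratio with 95% Wald confidence interval."""

    odds_ratio: float
    ci_low: float
    ci_high: float
    log_or: float
    se_log_or: float
    corrected: bool  # Haldane-Anscombe +0.5 applied (some cell was zero)


def odds_ratio(t: ContingencyTable2x2) -> OddsRatioResult:
    """Odds ratio ``(a·d)/(b·c)`` with 95% Wald CI on the log scale.

    If any cell is zero, the Haldane-Anscombe correction adds 0.5 to all
    four cells (flagged in the result), guaranteeing a finite estimate.
    """
    cells = [t.a, t.b, t.c, t.d]
    corrected = any(v == 0 for v in cells)
    if corrected:
        cells = [v + 0.5 for v in cells]
    a, b, c, d = cells
    log_or = math.log(a * d / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return OddsRatioResult(
        odds_ratio=math.exp(log_or),
        ci_low=math.exp(log_or - 1.959963984540054 * se),
        ci_high=math.exp(log_or + 1.959963984540054 * se),
        log_or=log_or, se_log_or=se, corrected=corrected)


@dataclass(frozen=True)
class DiagnosticMetrics:
    """Sensitivity, specificity, PPV and NPV as proportions in [0, 1].

    A metric whose denominator is zero is ``None`` (undefined), never 0.
    """

    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None

    def as_percent(self) -> dict:
        """Metrics rounded half-up to integer percent (reporting convention)."""
        return {k: (None if v is None else int(round_half_up(100 * v)))
                for k, v in self.__dict__.items()}


def diagnostic_metrics(t: ContingencyTable2x2) -> DiagnosticMetrics:
    """2x2 diagnostic metrics treating exposure as the test result.

    sens = a/(a+c), spec = d/(b+d), ppv = a/(a+b), npv = d/(c+d).
    """
    def frac(num, den):
        return None if den == 0 else num / den

    return DiagnosticMetrics(
        sensitivity=frac(t.a, t.a + t.c),
        specificity=frac(t.d, t.b + t.d),
        ppv=frac(t.a, t.a + t.b),
        npv=frac(t.d, t.c + t.d))


# --------------------------------------------------------------------------
# logistic regression
# --------------------------------------------------------------------------

class PerfectSeparationError(RuntimeError):
    """The outcome is perfectly predicted; the MLE does not exist."""


@dataclass
class LogisticFit:
    """Multivariable logistic fit with Wald inference.

    ``table`` has one row per coefficient with columns B, SE, p, OR,
    ci_low, ci_high. ``model_chi2`` is the likelihood-ratio omnibus test
    against the intercept-only model.
    """

    table: pd.DataFrame
    model_chi2: float
    model_df: int
    model_p: float
    nagelkerke_r2: float
    converged: bool
    n: int

    def odds_ratio(self, name: str) -> float:
        return float(self.table.loc[name, "OR"])


def _check_separation(X: pd.DataFrame, y: np.ndarray) -> None:
    # a single column (or its complement) that perfectly predicts y
    for col in X.columns:
        if col == "const":
            continue
        x = X[col].to_numpy(dtype=float)
        levels = np.unique(x)
        if levels.size <= 10:  # categorical-ish predictor
            by_level = [np.unique(y[x == v]) for v in levels]
            if all(u.size == 1 for u in by_level) and np.unique(y).size == 2:
                raise PerfectSeparationError(
                    f"predictor {col!r} perfectly separates the outcome")
        else:
            ys = y[np.argsort(x, kind="stable")]
            if (np.diff(ys) >= 0).all() or (np.diff(ys) <= 0).all():
                raise PerfectSeparationError(
                    f"predictor {col!r} perfectly separates the outcome")


def logistic_fit(X, y, add_intercept: bool = True,
                 maxiter: int = 50, tol: float = 1e-8) -> LogisticFit:
    """Maximum-likelihood logistic regression with Wald inference.

    ``X`` is a DataFrame (or array) of predictors; an intercept column
    is prepended unless ``add_intercept`` is False. Fitting uses
    iteratively reweighted least squares (Newton) with convergence
    tolerance ``tol``; Wald standard errors come from the inverse
    observed information. The result carries coefficient table, the
    likelihood-ratio omnibus χ² against the intercept-only model, and
    Nagelkerke's R². A constant outcome yields a flagged
    (``converged=False``) result; a perfectly separating predictor
    raises :class:`PerfectSeparationError` naming it.
    """
    X = pd.DataFrame(X).copy()
    y = np.asarray(y, dtype=float)
    if X.shape[0] != y.size:
        raise ValueError("X and y lengths differ")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("y must be binary (0/1)")
    if add_intercept:
        X.insert(0, "const", 1.0)
    if X.shape[0] <= X.shape[1]:
        raise ValueError("need more observations than parameters")
    n = X.shape[0]
    names = list(X.columns)
    p_slopes = len(names) - (1 if "const" in names else 0)

    if np.unique(y).size < 2:
        # intercept-only degenerate outcome: MLE diverges
        nan_tab = pd.DataFrame(np.nan, index=names,
                               columns=["B", "SE", "p", "OR", "ci_low", "ci_high"])
        return LogisticFit(nan_tab, np.nan, p_slopes, np.nan, np.nan,
                           converged=False, n=n)

    _check_separation(X, y)

    model = sm.Logit(y, X.to_numpy(dtype=float))
    try:
        res = model.fit(method="newton", maxiter=maxiter, tol=tol, disp=0)
        converged = bool(res.mle_retvals.get("converged", True))
    except Exception as err:  # e.g. statsmodels' own separation guard
        if "erfect" in str(err):
            raise PerfectSeparationError(str(err)) from err
        raise

    params = pd.Series(res.params, index=names)
    se = pd.Series(res.bse, index=names)
    z = params / se
    pvals = 2 * sstats.norm.sf(np.abs(z))
    ci = 1.959963984540054 * se
    with np.errstate(over="ignore"):  # near-separation inflates SEs; CI -> inf
        table = pd.DataFrame({
            "B": params, "SE": se, "p": pvals, "OR": np.exp(params),
            "ci_low": np.exp(params - ci), "ci_high": np.exp(params + ci),
        })

    ll1 = res.llf
    ll0 = res.llnull
    chi2 = 2.0 * (ll1 - ll0)
    model_p = float(sstats.chi2.sf(chi2, p_slopes)) if p_slopes else np.nan
    r2_cs = 1.0 - math.exp(2.0 * (ll0 - ll1) / n)
    r2_max = 1.0 - math.exp(2.0 * ll0 / n)
    nagelkerke = r2_cs / r2_max if r2_max > 0 else np.nan
    return LogisticFit(table, float(chi2), p_slopes, model_p,
                       float(nagelkerke), converged, n)


# --------------------------------------------------------------------------
# Mann-Whitney U
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class MannWhitneyResult:
    """U statistic of the first sample with a two-sided p-value."""

    u: float
    p: float
    method: str  # "exact" or "asymptotic"


def mann_whitney_u(x, y) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test.

    Uses exact enumeration when the combined sample size is at most 12
    and there are no ties; otherwise the normal approximation with
    midranks, tie-corrected variance and continuity correction. Two
    identical constant samples give p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.unique(pooled).size == 1:
        return MannWhitneyResult(u=x.size * y.size / 2.0, p=1.0,
                                 method="degenerate")
    has_ties = np.unique(pooled).size < pooled.size
    if x.size + y.size <= 12 and not has_ties:
        res = sstats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        return MannWhitneyResult(float(res.statistic), float(res.pvalue), "exact")
    res = sstats.mannwhitneyu(x, y, alternative="two-sided",
                              method="asymptotic", use_continuity=True)
    return MannWhitneyResult(float(res.statistic), float(min(res.pvalue, 1.0)),
                             "asymptotic")


# --------------------------------------------------------------------------
# DQ transforms and linear models
# --------------------------------------------------------------------------

def transform_dq(values, kind: str) -> np.ndarray:
    """Transform developmental quotients: ``log`` -> ln(v), ``reciprocal`` -> 1/v."""
    v = np.asarray(values, dtype=float)
    if (v <= 0).any():
        raise ValueError("DQ values must be positive for transformation")
    if kind == "log":
        return np.log(v)
    if kind == "reciprocal":
        return 1.0 / v
    raise ValueError(f"unknown transform kind {kind!r}")


def inverse_transform_dq(values, kind: str) -> np.ndarray:
    """Inverse of :func:`transform_dq`, for reporting on the original scale."""
    v = np.asarray(values, dtype=float)
    if kind == "log":
        return np.exp(v)
    if kind == "reciprocal":
        return 1.0 / v
    raise ValueError(f"unknown transform kind {kind!r}")


def linear_model(X, y, add_intercept: bool = True):
    """Ordinary least squares with coefficient t-tests (statsmodels result).

    Raises on a rank-deficient design, naming a collinear column pair.
    """
    X = pd.DataFrame(X).copy()
    y = np.asarray(y, dtype=float)
    if add_intercept:
        X.insert(0, "const", 1.0)
    if X.shape[0] <= X.shape[1]:
        raise ValueError("need more observations than parameters")
    A = X.to_numpy(dtype=float)
    if np.linalg.matrix_rank(A) < A.shape[1]:
        for c1, c2 in combinations(X.columns, 2):
            pair = X[[c1, c2]].to_numpy(dtype=float)
            if np.linalg.matrix_rank(pair) < 2:
                raise ValueError(f"design is rank deficient: columns {c1!r} "
                                 f"and {c2!r} are collinear")
        raise ValueError("design matrix is rank deficient")
    return sm.OLS(y, X).fit()


def collinearity_check(X) -> pd.DataFrame:
    """Variance inflation factor and tolerance of every predictor.

    ``VIF_j = 1 / (1 - R²_j)`` from regressing predictor j on the
    others (with intercept); perfect collinearity is reported as
    infinite VIF and zero tolerance.
    """
    X = pd.DataFrame(X).astype(float)
    if X.shape[1] < 2:
        raise ValueError("need at least two predictors")
    rows = {}
    for col in X.columns:
        others = sm.add_constant(X.drop(columns=[col]).to_numpy())
        target = X[col].to_numpy()
        if np.linalg.matrix_rank(others) < others.shape[1]:
            r2 = 1.0  # remaining predictors already dependent
        else:
            r2 = sm.OLS(target, others).fit().rsquared
        if r2 >= 1.0 - 1e-12:
            vif, tol = np.inf, 0.0
        else:
            vif = 1.0 / (1.0 - r2)
            tol = 1.0 - r2
        rows[col] = {"tolerance": tol, "vif": vif}
    return pd.DataFrame.from_dict(rows, orient="index")
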