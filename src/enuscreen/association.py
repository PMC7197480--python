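"""Per-line association of candidate loci with health traits and longevity.

The screen's association layer fits, per founder line:

* proportional-odds (cumulative-logit) models for each ordinal trait —
  the composite health score and the five individual parameters — with
  carrier indicators as covariates,
* ordinary linear models for body weight at 8 wk,
* parametric accelerated-failure-time (AFT) survival models across four
  families (exponential, Weibull, log-normal, log-logistic), with the
  final family chosen by AIC,
* marginal scans per locus and pairwise gene-gene interaction scans
  (main effects plus a product term), fixed effects only,
* Kaplan-Meier medians and the Mantel-Cox (log-rank) comparison, plus
  the 2^-ddCt qPCR fold change and the two-sample t-test.

Ordinal and linear fits go through statsmodels, the Weibull/log-normal/
log-logistic AFT fits through lifelines; the exponential AFT is fitted
through its Poisson-likelihood equivalence (event indicator regressed
with a log-exposure offset), whose censored-data log-likelihood is then
evaluated exactly.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import (
    KaplanMeierFitter,
    LogLogisticAFTFitter,
    LogNormalAFTFitter,
    WeibullAFTFitter,
)
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats
from statsmodels.miscmodels.ordinal_model import OrderedModel
from statsmodels.stats.multitest import multipletests

from .scoring import InvalidInputError

SURVIVAL_FAMILIES = ("exponential", "weibull", "lognormal", "loglogistic")


class DegenerateOutcomeError(ValueError):
    """Raised when an ordinal outcome has fewer than two observed levels."""


# ---------------------------------------------------------------------------
# proportional-odds (cumulative logit)
# ---------------------------------------------------------------------------


@dataclass
class OrdinalFit:
    """Cumulative-logit fit: P(Y <= j | x) = logistic(theta_j - x beta)."""

    cutpoints: np.ndarray  # theta_1 < ... < theta_{K-1}
    coefficients: Dict[str, float]
    standard_errors: Dict[str, float]
    wald_p_values: Dict[str, float]
    log_likelihood: float
    converged: bool
    n_obs: int
    levels: Tuple[int, ...]

    def category_probabilities(self, x: np.ndarray) -> np.ndarray:
        """Fitted P(Y = j | x) for each observed level (rows sum to 1)."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        beta = np.array(list(self.coefficients.values()))
        eta = x @ beta if beta.size else np.zeros(x.shape[0])
        theta = np.concatenate([[-np.inf], self.cutpoints, [np.inf]])
        cum = 1.0 / (1.0 + np.exp(-(theta[None, :] - eta[:, None])))
        return np.diff(cum, axis=1)


def _as_design(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X.astype(float).reset_index(drop=True)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1 and X.shape[1] > 1:
        X = X.T
    return pd.DataFrame(X, columns=[f"x{i}" for i in range(X.shape[1])])


def fit_proportional_odds(y, X=None) -> OrdinalFit:
    """Maximum-likelihood proportional-odds fit on the observed levels.

    Unobserved categories are collapsed away (a cumulative model needs
    every fitted level observed).  Non-convergence (e.g. separation) is
    reported through ``converged``, never silently.
    """
    y = np.asarray(y)
    levels = tuple(int(v) for v in np.unique(y))
    if len(levels) < 2:
        raise DegenerateOutcomeError(
            f"ordinal outcome has a single observed level {levels}"
        )
    codes = np.searchsorted(levels, y)
    y_cat = pd.Series(
        pd.Categorical(codes, categories=range(len(levels)), ordered=True)
    )
    if X is None or (hasattr(X, "shape") and np.size(X) == 0):
        design = None
        names: List[str] = []
    else:
        design = _as_design(X)
        if len(design) != len(y):
            raise InvalidInputError("y and X lengths differ")
        rank = np.linalg.matrix_rank(design.to_numpy())
        if rank < design.shape[1]:
            raise InvalidInputError("collinear design matrix")
        names = list(design.columns)
    model = OrderedModel(y_cat, design, distr="logit")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(method="bfgs", maxiter=500, disp=False)
    converged = bool(res.mle_retvals.get("converged", False))
    cutpoints = model.transform_threshold_params(np.asarray(res.params))[1:-1]
    params = np.asarray(res.params)
    se = np.asarray(res.bse)
    pvals = np.asarray(res.pvalues)
    return OrdinalFit(
        cutpoints=np.asarray(cutpoints, dtype=float),
        coefficients={n: float(params[i]) for i, n in enumerate(names)},
        standard_errors={n: float(se[i]) for i, n in enumerate(names)},
        wald_p_values={n: float(pvals[i]) for i, n in enumerate(names)},
        log_likelihood=float(res.llf),
        converged=converged,
        n_obs=len(y),
        levels=levels,
    )


# ---------------------------------------------------------------------------
# linear models
# ---------------------------------------------------------------------------


@dataclass
class LinearFit:
    coefficients: Dict[str, float]
    standard_errors: Dict[str, float]
    t_statistics: Dict[str, float]
    p_values: Dict[str, float]
    residual_variance: float
    n_obs: int


def fit_linear(y, X) -> LinearFit:
    """Ordinary least squares with classical t-tests (intercept added)."""
    y = np.asarray(y, dtype=float)
    design = _as_design(X)
    if len(design) != len(y):
        raise InvalidInputError("y and X lengths differ")
    exog = sm.add_constant(design, has_constant="add")
    if len(y) <= exog.shape[1]:
        raise InvalidInputError("need n > number of design columns")
    rank = np.linalg.matrix_rank(exog.to_numpy())
    if rank < exog.shape[1]:
        # name the first aliased column for the caller
        for j in range(1, exog.shape[1]):
            if np.linalg.matrix_rank(exog.to_numpy()[:, : j + 1]) < j + 1:
                raise InvalidInputError(
                    f"design is rank deficient: column {exog.columns[j]!r} is aliased"
                )
    res = sm.OLS(y, exog).fit()
    names = list(exog.columns)
    return LinearFit(
        coefficients={n: float(res.params[n]) for n in names},
        standard_errors={n: float(res.bse[n]) for n in names},
        t_statistics={n: float(res.tvalues[n]) for n in names},
        p_values={n: float(res.pvalues[n]) for n in names},
        residual_variance=float(res.mse_resid) if res.df_resid > 0 else 0.0,
        n_obs=len(y),
    )


# ---------------------------------------------------------------------------
# parametric AFT survival with AIC selection
# ---------------------------------------------------------------------------


@dataclass
class SurvivalFit:
    """AFT fit: log T = intercept + x beta + sigma * error(family)."""

    family: str
    baseline_params: Dict[str, float]
    coefficients: Dict[str, float]
    standard_errors: Dict[str, float]
    p_values: Dict[str, float]
    log_likelihood: float
    n_params: int
    converged: bool
    n_obs: int

    @property
    def aic(self) -> float:
        return 2.0 * self.n_params - 2.0 * self.log_likelihood


_LIFELINES_FITTERS = {
    "weibull": WeibullAFTFitter,
    "lognormal": LogNormalAFTFitter,
    "loglogistic": LogLogisticAFTFitter,
}


def _fit_exponential(times, events, design: Optional[pd.DataFrame]) -> SurvivalFit:
    # Exponential AFT MLE via Poisson-GLM equivalence: with event indicator
    # d_i and offset log t_i, the Poisson log rate gamma satisfies
    # hazard_i = exp(x gamma) = exp(-(b0 + x beta)), so beta = -gamma.
    n = len(times)
    if design is None:
        exog = np.ones((n, 1))
        names = ["const"]
    else:
        exog = sm.add_constant(design, has_constant="add")
        names = list(exog.columns)
        exog = exog.to_numpy()
    glm = sm.GLM(
        events, exog, family=sm.families.Poisson(), offset=np.log(times)
    ).fit()
    gamma = np.asarray(glm.params)
    beta = -gamma
    lin = exog @ beta
    loglik = float(np.sum(events * (-lin) - times * np.exp(-lin)))
    se = np.asarray(glm.bse)
    pv = np.asarray(glm.pvalues)
    cov_names = names[1:]
    return SurvivalFit(
        family="exponential",
        baseline_params={"log_scale": float(beta[0])},
        coefficients={n_: float(beta[i + 1]) for i, n_ in enumerate(cov_names)},
        standard_errors={n_: float(se[i + 1]) for i, n_ in enumerate(cov_names)},
        p_values={n_: float(pv[i + 1]) for i, n_ in enumerate(cov_names)},
        log_likelihood=loglik,
        n_params=len(names),
        converged=bool(glm.converged),
        n_obs=n,
    )


def fit_survival(times, events, X=None, family: str = "weibull") -> SurvivalFit:
    """Right-censored AFT maximum likelihood for one family."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0 or np.any(times <= 0):
        raise InvalidInputError("times must be positive and non-empty")
    if events.sum() < 1:
        raise InvalidInputError("at least one event required")
    if family not in SURVIVAL_FAMILIES:
        raise InvalidInputError(f"unknown family {family!r}; use {SURVIVAL_FAMILIES}")
    design = None if X is None or np.size(X) == 0 else _as_design(X)
    if family == "exponential":
        return _fit_exponential(times, events, design)

    df = pd.DataFrame({"time": times, "event": events})
    cov_names: List[str] = []
    if design is not None:
        for c in design.columns:
            df[c] = design[c].to_numpy()
            cov_names.append(c)
    fitter = _LIFELINES_FITTERS[family]()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fitter.fit(df, duration_col="time", event_col="event")
        converged = True
    except ConvergenceError:
        return SurvivalFit(
            family=family,
            baseline_params={},
            coefficients={},
            standard_errors={},
            p_values={},
            log_likelihood=-np.inf,
            n_params=len(cov_names) + 2,
            converged=False,
            n_obs=len(times),
        )
    params = fitter.params_
    primary = params.index.get_level_values(0)[0]  # lambda_ / mu_ / alpha_
    summary = fitter.summary
    coefs, ses, pvs = {}, {}, {}
    for c in cov_names:
        coefs[c] = float(params[(primary, c)])
        ses[c] = float(summary.loc[(primary, c), "se(coef)"])
        pvs[c] = float(summary.loc[(primary, c), "p"])
    baseline = {
        f"{lvl0}:{lvl1}": float(v)
        for (lvl0, lvl1), v in params.items()
        if lvl1 == "Intercept"
    }
    return SurvivalFit(
        family=family,
        baseline_params=baseline,
        coefficients=coefs,
        standard_errors=ses,
        p_values=pvs,
        log_likelihood=float(fitter.log_likelihood_),
        n_params=len(params),
        converged=converged,
        n_obs=len(times),
    )


def select_by_aic(fits: Sequence[SurvivalFit]) -> SurvivalFit:
    """Minimum-AIC fit; ties -> fewer parameters, then fixed family order."""
    usable = [f for f in fits if f.converged and np.isfinite(f.aic)]
    if not usable:
        raise InvalidInputError("no converged survival fit to select from")
    return min(
        usable,
        key=lambda f: (round(f.aic, 9), f.n_params, SURVIVAL_FAMILIES.index(f.family)),
    )


def fit_survival_best(times, events, X=None) -> SurvivalFit:
    """Fit all four AFT families and return the AIC-selected one."""
    fits = []
    for fam in SURVIVAL_FAMILIES:
        try:
            fits.append(fit_survival(times, events, X, family=fam))
        except (InvalidInputError, np.linalg.LinAlgError):
            continue
    return select_by_aic(fits)


# ---------------------------------------------------------------------------
# Kaplan-Meier / log-rank / small utilities
# ---------------------------------------------------------------------------


def logrank_test(times, events, group) -> Tuple[float, float]:
    """Mantel-Cox log-rank chi-square statistic and p-value for two groups."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    group = np.asarray(group)
    labels = np.unique(group)
    if len(labels) != 2:
        raise InvalidInputError(f"exactly two groups required, got {len(labels)}")
    a = group == labels[0]
    if a.all() or (~a).all():
        raise InvalidInputError("one group is empty")
    if events.sum() < 1:
        raise InvalidInputError("at least one event required")
    res = _ll_logrank(times[a], times[~a], events[a], events[~a])
    return float(res.test_statistic), float(res.p_value)


def km_median(times, events) -> Optional[float]:
    """Kaplan-Meier median: first time S(t) <= 0.5, or None if never reached."""
    kmf = KaplanMeierFitter()
    kmf.fit(np.asarray(times, dtype=float), np.asarray(events, dtype=int))
    med = kmf.median_survival_time_
    return None if np.isinf(med) else float(med)


def ddct_fold_change(
    ct_target_sample: float,
    ct_ref_sample: float,
    ct_target_control: float,
    ct_ref_control: float,
) -> float:
    """Relative expression by 2^-ddCt against a reference transcript."""
    cts = (ct_target_sample, ct_ref_sample, ct_target_control, ct_ref_control)
    if not all(math.isfinite(c) for c in cts):
        raise InvalidInputError("Ct values must be finite")
    ddct = (ct_target_sample - ct_ref_sample) - (ct_target_control - ct_ref_control)
    return 2.0 ** (-ddct)


def two_sample_t(a, b) -> Tuple[float, float]:
    """Classical pooled-variance two-sample Student's t-test."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InvalidInputError("each group needs at least two observations")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


# ---------------------------------------------------------------------------
# marginal and pairwise scans
# ---------------------------------------------------------------------------


@dataclass
class ScanResult:
    """Tidy marginal and interaction association tables for one line."""

    marginal: pd.DataFrame
    interactions: pd.DataFrame
    skipped: List[Tuple[str, str]] = field(default_factory=list)  # (locus, reason)


def _locus_testable(g: np.ndarray) -> Optional[str]:
    carriers = int(np.nansum(g))
    non = int(np.sum(~np.isnan(g))) - carriers
    if carriers < 2:
        return f"only {carriers} carriers (< 2)"
    if non < 2:
        return f"only {non} non-carriers (< 2)"
    return None


def _fit_one(trait_kind, y, X, events=None):
    """(effect, p, family, converged) for the last design column."""
    last = X.columns[-1]
    if trait_kind == "ordinal":
        try:
            fit = fit_proportional_odds(y, X)
        except DegenerateOutcomeError:
            return np.nan, np.nan, "ordinal", False
        return (
            fit.coefficients.get(last, np.nan),
            fit.wald_p_values.get(last, np.nan),
            "ordinal",
            fit.converged,
        )
    if trait_kind == "linear":
        fit = fit_linear(y, X)
        return fit.coefficients[last], fit.p_values[last], "linear", True
    if trait_kind == "survival":
        best = fit_survival_best(y, events, X)
        return (
            best.coefficients.get(last, np.nan),
            best.p_values.get(last, np.nan),
            best.family,
            best.converged,
        )
    raise InvalidInputError(f"unknown trait kind {trait_kind!r}")


def scan_line(
    data: pd.DataFrame,
    loci: Sequence[str],
    ordinal_traits: Sequence[str] = (),
    linear_traits: Sequence[str] = (),
    survival_cols: Optional[Tuple[str, str]] = ("survival_days", "event"),
    bh: bool = False,
) -> ScanResult:
    """Marginal per-locus and pairwise interaction scans over all traits.

    ``data`` holds one row per animal with trait columns and 0/1 carrier
    columns.  Loci with fewer than 2 carriers or 2 non-carriers are
    skipped with a recorded reason.  Interaction models include both main
    effects plus the product term; the reported interaction effect and
    p-value belong to the product term.  Fixed effects only.  With
    ``bh``, Benjamini-Hochberg q-values are appended across the scan.
    """
    if not loci:
        raise InvalidInputError("at least one locus required")
    missing = [l for l in loci if l not in data.columns]
    if missing:
        raise InvalidInputError(f"loci absent from data: {missing}")

    skipped: List[Tuple[str, str]] = []
    testable = []
    for locus in loci:
        reason = _locus_testable(data[locus].to_numpy(dtype=float))
        if reason is None:
            testable.append(locus)
        else:
            skipped.append((locus, reason))

    traits: List[Tuple[str, str]] = [(t, "ordinal") for t in ordinal_traits]
    traits += [(t, "linear") for t in linear_traits]
    if survival_cols is not None:
        traits.append((survival_cols[0], "survival"))

    marg_rows, int_rows = [], []
    for trait, kind in traits:
        if kind == "survival":
            sub = data.dropna(subset=[trait, survival_cols[1], *testable])
            y = sub[trait].to_numpy(dtype=float)
            events = sub[survival_cols[1]].to_numpy(dtype=int)
        else:
            sub = data.dropna(subset=[trait, *testable])
            y = sub[trait].to_numpy(dtype=float)
            events = None
        for locus in testable:
            X = sub[[locus]]
            try:
                eff, p, fam, conv = _fit_one(kind, y, X, events)
            except InvalidInputError:
                eff, p, fam, conv = np.nan, np.nan, kind, False
            marg_rows.append(
                {"trait": trait, "locus": locus, "effect": eff, "p_value": p,
                 "model_family": fam, "converged": conv}
            )
        for i in range(len(testable)):
            for j in range(i + 1, len(testable)):
                l1, l2 = testable[i], testable[j]
                X = sub[[l1, l2]].copy()
                prod = f"{l1}:{l2}"
                X[prod] = X[l1] * X[l2]
                if X[prod].nunique() < 2 or np.linalg.matrix_rank(X.to_numpy()) < 3:
                    continue  # no double carriers observed, or aliased
                try:
                    eff, p, fam, conv = _fit_one(kind, y, X, events)
                except InvalidInputError:
                    eff, p, fam, conv = np.nan, np.nan, kind, False
                int_rows.append(
                    {"trait": trait, "locus1": l1, "locus2": l2, "effect": eff,
                     "p_value": p, "model_family": fam, "converged": conv}
                )

    marginal = pd.DataFrame(
        marg_rows,
        columns=["trait", "locus", "effect", "p_value", "model_family", "converged"],
    )
    interactions = pd.DataFrame(
        int_rows,
        columns=["trait", "locus1", "locus2", "effect", "p_value",
                 "model_family", "converged"],
    )
    if bh:
        for df in (marginal, interactions):
            df["q_value"] = np.nan
            ok = df["p_value"].notna()
            if ok.any():
                df.loc[ok, "q_value"] = multipletests(
                    df.loc[ok, "p_value"], method="fdr_bh"
                )[1]
    return ScanResult(marginal=marginal, interactions=interactions, skipped=skipped)
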