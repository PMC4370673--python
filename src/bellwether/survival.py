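"""Censored time-to-detection analysis of presence/absence field surveys.

Each survey of a pond runs until the species is confirmed or a 30-minute
cap is reached, so the time to detection (TTD) plays the role of a
survival time and a survey with no detection is right-censored at the
cap.  Covariates (year, survey method, seasonal window, observer) enter
an accelerated failure time (AFT) model::

    log T = x' beta + sigma * eps

with eps standard Gumbel-minimum (Weibull TTD), standard normal
(log-normal TTD) or Gumbel with sigma fixed at 1 (exponential TTD).
Fitting is by maximum likelihood; right-censored records contribute
log S(t), events log f(t).

On top of the fit sit three procedures:

- exhaustive AIC model selection over subsets of the main effects and
  any two-way interactions whose parents are included;
- predicted mean TTD per category of a covariate, by marginal
  standardisation over the empirical covariate distribution;
- a permutation test whose statistic is the ratio of the maximum to the
  minimum predicted mean TTD across the categories of a focal
  covariate, with focal labels reshuffled across records and the model
  refitted for every resample.

Ponds where the species was never found in any survey are excluded by
:func:`filter_ever_detected` before fitting (they violate the premise
that every survey would eventually succeed); the complementary
partition is returned so an all-pond sensitivity fit can be run.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field as dc_field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.tools.numdiff import approx_fprime, approx_hess

__all__ = [
    "SurveyRecord",
    "TTDModelFit",
    "PermutationResult",
    "FitError",
    "CENSOR_MINUTES",
    "CANONICAL_LEVELS",
    "records_to_frame",
    "filter_ever_detected",
    "fit_ttd_model",
    "select_model_aic",
    "permutation_test",
    "survival_curves",
]

CENSOR_MINUTES = 30.0

#: Canonical category orderings (first entry = treatment reference).
CANONICAL_LEVELS: dict[str, list[str]] = {
    "year": ["2009", "2010"],
    "window": ["early", "middle", "late"],
    "method": ["day_visual", "dipnet", "night_visual"],
}

FAMILIES = ("weibull", "exponential", "lognormal")

Term = "str | tuple[str, str]"


class FitError(RuntimeError):
    """Maximum-likelihood fit failed to converge."""


@dataclass(frozen=True)
class SurveyRecord:
    """One pond visit: covariates plus a possibly-censored TTD."""

    pond_id: str
    year: int
    window: str
    method: str
    observer: str
    time_min: float
    detected: bool

    def __post_init__(self) -> None:
        if not (0.0 < self.time_min <= CENSOR_MINUTES):
            raise ValueError(
                f"time_min must be in (0, {CENSOR_MINUTES:g}], got {self.time_min}"
            )
        if not self.detected and self.time_min != CENSOR_MINUTES:
            raise ValueError("censored records must have time_min at the censor bound")


def records_to_frame(records) -> pd.DataFrame:
    """Normalise a record collection to the canonical survey DataFrame."""
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        df = pd.DataFrame(
            [
                {
                    "pond": r.pond_id,
                    "year": r.year,
                    "window": r.window,
                    "method": r.method,
                    "observer": r.observer,
                    "time_min": r.time_min,
                    "detected": r.detected,
                }
                for r in records
            ]
        )
    missing = {"pond", "year", "window", "method", "observer", "time_min", "detected"} - set(
        df.columns
    )
    if missing:
        raise ValueError(f"survey table missing columns: {sorted(missing)}")
    return df


def filter_ever_detected(records) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition surveys by whether their pond ever yielded a detection.

    Returns ``(included, excluded)`` DataFrames; ``included`` holds all
    surveys of ponds with at least one detection over the whole study,
    ``excluded`` the ponds that never produced one.
    """
    df = records_to_frame(records)
    if len(df) == 0:
        raise ValueError("no survey records supplied")
    ever = df.groupby("pond")["detected"].transform("any")
    return df[ever].reset_index(drop=True), df[~ever].reset_index(drop=True)


# ---------------------------------------------------------------------------
# design matrix


def _observed_levels(df: pd.DataFrame, var: str) -> list[str]:
    obs = sorted(df[var].astype(str).unique())
    canon = CANONICAL_LEVELS.get(var)
    if canon is not None:
        return [v for v in canon if v in obs] + [v for v in obs if v not in canon]
    return obs


def _normalize_terms(terms):
    mains: list[str] = []
    inters: list[tuple[str, str]] = []
    for t in terms:
        if isinstance(t, str):
            mains.append(t)
        else:
            a, b = sorted(t)
            inters.append((a, b))
    mains = sorted(set(mains))
    inters = sorted(set(inters))
    for a, b in inters:
        if a not in mains or b not in mains:
            raise ValueError(f"interaction ({a},{b}) requires both main effects")
    return tuple(mains), tuple(inters)


def _design_matrix(df, terms, levels=None):
    """Treatment-coded design matrix with intercept.

    ``levels`` fixes the level universe per variable (used when
    predicting on data whose columns were forced to a single category);
    by default levels are those observed in ``df``.

    Returns (X, column names, levels per variable).
    """
    mains, inters = _normalize_terms(terms)
    n = len(df)
    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["intercept"]
    dummies: dict[str, dict[str, np.ndarray]] = {}
    used_levels: dict[str, list[str]] = {}
    for var in mains:
        lv = list(levels[var]) if levels is not None else _observed_levels(df, var)
        used_levels[var] = lv
        vals = df[var].astype(str).to_numpy()
        unknown = set(vals) - set(lv)
        if unknown:
            raise ValueError(f"unknown {var} level(s): {sorted(unknown)}")
        dummies[var] = {v: (vals == v).astype(float) for v in lv}
        for v in lv[1:]:
            cols.append(dummies[var][v])
            names.append(f"{var}[{v}]")
    for a, b in inters:
        for va in used_levels[a][1:]:
            for vb in used_levels[b][1:]:
                cols.append(dummies[a][va] * dummies[b][vb])
                names.append(f"{a}[{va}]:{b}[{vb}]")
    return np.column_stack(cols), names, used_levels


# ---------------------------------------------------------------------------
# likelihood


def _negloglik(theta, X, logt, event, family):
    k = X.shape[1]
    beta = theta[:k]
    sigma = 1.0 if family == "exponential" else math.exp(theta[k])
    z = (logt - X @ beta) / sigma
    if family == "lognormal":
        ll = np.where(
            event,
            -math.log(sigma) - logt + stats.norm.logpdf(z),
            stats.norm.logsf(z),
        )
    else:  # weibull / exponential: Gumbel-min error
        ez = np.exp(np.clip(z, -700.0, 700.0))
        ll = np.where(event, -math.log(sigma) - logt + z - ez, -ez)
    return -float(ll.sum())


def _negloglik_grad(theta, X, logt, event, family):
    k = X.shape[1]
    beta = theta[:k]
    est_scale = family != "exponential"
    sigma = math.exp(theta[k]) if est_scale else 1.0
    z = (logt - X @ beta) / sigma
    if family == "lognormal":
        # phi(z)/S(z) in log space for numerical stability
        h = np.exp(stats.norm.logpdf(z) - stats.norm.logsf(z))
        dldz = np.where(event, -z, -h)
        dl_dlogsig = np.where(event, z * z - 1.0, h * z)
    else:
        ez = np.exp(np.clip(z, -700.0, 700.0))
        dldz = np.where(event, 1.0 - ez, -ez)
        dl_dlogsig = np.where(event, -1.0 - z * (1.0 - ez), z * ez)
    grad_beta = (X.T @ dldz) / sigma
    if est_scale:
        return np.append(grad_beta, -float(dl_dlogsig.sum()))
    return grad_beta


def _fit_mle(X, logt, event, family):
    k = X.shape[1]
    est_scale = family != "exponential"
    x0 = np.zeros(k + (1 if est_scale else 0))
    x0[0] = float(np.mean(logt))
    args = (X, logt, event, family)
    res = optimize.minimize(
        _negloglik, x0, args=args, jac=_negloglik_grad, method="BFGS",
        options={"gtol": 1e-8, "maxiter": 500},
    )
    if not res.success or not np.isfinite(res.fun):
        start = res.x if np.all(np.isfinite(res.x)) else x0
        res2 = optimize.minimize(
            _negloglik, start, args=args, method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20_000,
                     "maxfev": 20_000},
        )
        if np.isfinite(res2.fun) and (
            not np.isfinite(res.fun) or res2.fun <= res.fun + 1e-6
        ):
            res = res2
    if not np.all(np.isfinite(res.x)) or not np.isfinite(res.fun):
        raise FitError(f"AFT fit did not converge ({family}): {res.message}")
    return res


@dataclass(frozen=True)
class TTDModelFit:
    """Fitted accelerated failure time model for time to detection."""

    family: str
    terms: tuple
    param_names: tuple[str, ...]
    params: np.ndarray  # beta coefficients, then log-scale unless exponential
    cov: np.ndarray | None
    loglik: float
    aic: float
    n: int
    n_events: int
    data: pd.DataFrame = dc_field(repr=False, default=None)
    levels: Mapping[str, list[str]] = dc_field(default_factory=dict)

    @property
    def scale(self) -> float:
        """AFT scale sigma (fixed at 1 for the exponential family)."""
        if self.family == "exponential":
            return 1.0
        return math.exp(self.params[-1])

    def coefficients(self) -> pd.Series:
        return pd.Series(self.params[: len(self.param_names)],
                         index=list(self.param_names))

    def coefficient_se(self) -> pd.Series:
        if self.cov is None:
            raise ValueError("fit was computed without a covariance matrix")
        se = np.sqrt(np.diag(self.cov))[: len(self.param_names)]
        return pd.Series(se, index=list(self.param_names))

    # -- prediction -------------------------------------------------------

    def _linear_predictor(self, df: pd.DataFrame, params: np.ndarray) -> np.ndarray:
        X, names, _ = _design_matrix(df, self.terms, levels=self.levels)
        assert tuple(names) == self.param_names
        return X @ params[: len(self.param_names)]

    def _mean_from_eta(self, eta: np.ndarray, params: np.ndarray) -> np.ndarray:
        if self.family == "weibull":
            return np.exp(eta) * special.gamma(1.0 + math.exp(params[-1]))
        if self.family == "lognormal":
            return np.exp(eta + math.exp(params[-1]) ** 2 / 2.0)
        return np.exp(eta)

    def _standardized_mean(self, focal: str, level: str, params: np.ndarray) -> float:
        forced = self.data.copy()
        forced[focal] = level
        eta = self._linear_predictor(forced, params)
        return float(self._mean_from_eta(eta, params).mean())

    def predicted_mean_ttd(self, focal: str, with_se: bool = True) -> pd.DataFrame:
        """Predicted mean TTD (minutes) per category of ``focal``.

        Marginal standardisation: every record has its ``focal`` value
        forced to the category, the model-implied mean TTD is computed
        per record and averaged over the empirical covariate
        distribution.  Standard errors come from the delta method on
        the ML covariance.
        """
        if focal not in self.levels:
            raise ValueError(f"{focal!r} is not a fitted covariate of this model")
        rows = []
        for level in self.levels[focal]:
            m = self._standardized_mean(focal, level, self.params)
            se = np.nan
            if with_se:
                if self.cov is None:
                    raise ValueError("fit was computed without a covariance matrix")
                g = approx_fprime(
                    self.params,
                    lambda p, lv=level: self._standardized_mean(focal, lv, p),
                    centered=True,
                )
                se = float(np.sqrt(g @ self.cov @ g))
            rows.append({"category": level, "mean_ttd": m, "se": se})
        return pd.DataFrame(rows).set_index("category")

    def ratio_statistic(self, focal: str) -> float:
        """max/min of per-category predicted mean TTD (always >= 1)."""
        means = self.predicted_mean_ttd(focal, with_se=False)["mean_ttd"]
        return float(means.max() / means.min())


def fit_ttd_model(
    records,
    terms,
    family: str = "weibull",
    compute_cov: bool = True,
) -> TTDModelFit:
    """Maximum-likelihood AFT fit of time to detection with censoring.

    Parameters
    ----------
    records : DataFrame or iterable of SurveyRecord
        Survey table; ``detected == False`` rows are right-censored.
    terms : iterable
        Covariate names, plus 2-tuples for two-way interactions (both
        parents must also appear as main effects).
    family : {"weibull", "exponential", "lognormal"}
    compute_cov : bool
        Skip the (finite-difference Hessian) covariance when only point
        predictions are needed, e.g. inside permutation refits.

    Returns
    -------
    TTDModelFit
        Coefficients, covariance, log-likelihood, AIC (``2k - 2 logL``
        counting the scale parameter when estimated) and prediction
        methods.
    """
    if family not in FAMILIES:
        raise ValueError(f"family must be one of {FAMILIES}")
    df = records_to_frame(records).reset_index(drop=True)
    event = df["detected"].to_numpy(bool)
    if event.sum() < 1:
        raise ValueError("need at least one detection event to fit")
    X, names, levels = _design_matrix(df, terms)
    logt = np.log(df["time_min"].to_numpy(float))
    res = _fit_mle(X, logt, event, family)
    k = len(res.x)
    cov = None
    if compute_cov:
        hess = approx_hess(res.x, _negloglik, args=(X, logt, event, family))
        try:
            cov = np.linalg.inv(hess)
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(hess)
    for var, lv in levels.items():
        ev_by = df.groupby(df[var].astype(str))["detected"].any()
        if not ev_by.all():
            warnings.warn(
                f"all records censored in {var} level(s) "
                f"{list(ev_by.index[~ev_by])}: predicted mean TTD unbounded there",
                stacklevel=2,
            )
    mains, inters = _normalize_terms(terms)
    return TTDModelFit(
        family=family,
        terms=mains + inters,
        param_names=tuple(names),
        params=res.x.copy(),
        cov=cov,
        loglik=-res.fun,
        aic=2.0 * k + 2.0 * res.fun,
        n=len(df),
        n_events=int(event.sum()),
        data=df,
        levels=levels,
    )


# ---------------------------------------------------------------------------
# model selection


def _candidate_models(main_effects: Sequence[str]) -> list[tuple]:
    """All subsets of main effects crossed with all subsets of the
    two-way interactions whose parents are in the subset."""
    out: list[tuple] = []
    for r in range(len(main_effects) + 1):
        for mains in itertools.combinations(sorted(main_effects), r):
            pairs = list(itertools.combinations(mains, 2))
            for ri in range(len(pairs) + 1):
                for inters in itertools.combinations(pairs, ri):
                    out.append(tuple(mains) + tuple(inters))
    return out


def _terms_label(terms) -> str:
    parts = [t if isinstance(t, str) else f"{t[0]}:{t[1]}" for t in terms]
    return " + ".join(parts) if parts else "(intercept)"


def select_model_aic(
    records,
    main_effects: Sequence[str] = ("method", "year", "window", "observer"),
    family: str = "weibull",
) -> tuple[TTDModelFit, pd.DataFrame]:
    """Exhaustive AIC selection over main-effect subsets and their
    two-way interactions.

    Returns the minimum-AIC fit and the full AIC table (one row per
    candidate, sorted by AIC).  Ties break towards fewer parameters,
    then lexicographic term order.
    """
    df = records_to_frame(records)
    rows = []
    fits: dict[str, TTDModelFit] = {}
    for terms in _candidate_models(main_effects):
        label = _terms_label(terms)
        try:
            fit = fit_ttd_model(df, terms, family=family, compute_cov=False)
        except (FitError, ValueError) as exc:
            rows.append({"terms": label, "k": np.nan, "loglik": np.nan,
                         "aic": np.inf, "error": str(exc)})
            continue
        fits[label] = fit
        rows.append({"terms": label, "k": len(fit.params),
                     "loglik": fit.loglik, "aic": fit.aic, "error": ""})
    table = (
        pd.DataFrame(rows)
        .sort_values(["aic", "k", "terms"], kind="mergesort")
        .reset_index(drop=True)
    )
    best_label = table.iloc[0]["terms"]
    if best_label not in fits:
        raise FitError("no candidate model converged")
    # refit the winner with its covariance for downstream prediction SEs
    best = fit_ttd_model(df, fits[best_label].terms, family=family)
    return best, table


# ---------------------------------------------------------------------------
# permutation test


@dataclass(frozen=True)
class PermutationResult:
    """Outcome of the ratio-statistic permutation test."""

    focal: str
    observed_statistic: float
    null_statistics: np.ndarray
    p_value: float
    n_failed: int = 0

    @property
    def n_perm(self) -> int:
        return len(self.null_statistics)


def permutation_test(
    records,
    focal: str,
    n_perm: int = 10_000,
    rng: np.random.Generator | None = None,
    terms=None,
    family: str = "weibull",
    exhaustive: bool = False,
) -> PermutationResult:
    """Permutation test of a focal covariate's effect on mean TTD.

    The statistic is the ratio of the maximum to the minimum predicted
    mean TTD across the focal covariate's categories (>= 1 by
    construction).  Null resamples shuffle the focal labels across
    records — every other column held fixed as collected — refit the
    same model, and recompute the ratio; the p-value is the proportion
    of resamples with a statistic at least as large as observed.

    ``terms`` defaults to the minimum-AIC model's terms joined with the
    focal main effect.  ``exhaustive=True`` enumerates every distinct
    rearrangement of the focal labels instead of sampling (only
    feasible for very small tables) and yields the exact permutation
    p-value; ``n_perm`` is then ignored.

    Resamples whose refit fails are dropped and counted in
    ``n_failed``; a warning is issued if more than 1% are lost.
    """
    df = records_to_frame(records).reset_index(drop=True)
    if df[focal].astype(str).nunique() < 2:
        raise ValueError(f"focal covariate {focal!r} needs >= 2 categories")
    if rng is None:
        rng = np.random.default_rng()
    if terms is None:
        best, _ = select_model_aic(df, family=family)
        terms = set(best.terms) | {focal}
    mains, inters = _normalize_terms(terms)
    terms = mains + inters

    observed_fit = fit_ttd_model(df, terms, family=family, compute_cov=False)
    observed = observed_fit.ratio_statistic(focal)

    labels = df[focal].to_numpy()
    if exhaustive:
        resamples = [np.array(p) for p in sorted(set(itertools.permutations(labels)))]
    else:
        resamples = (rng.permutation(labels) for _ in range(n_perm))

    null_stats: list[float] = []
    n_failed = 0
    for shuffled in resamples:
        permuted = df.copy()
        permuted[focal] = shuffled
        try:
            fit = fit_ttd_model(permuted, terms, family=family, compute_cov=False)
            null_stats.append(fit.ratio_statistic(focal))
        except (FitError, ValueError):
            n_failed += 1
    total = len(null_stats) + n_failed
    if total and n_failed / total > 0.01:
        warnings.warn(
            f"{n_failed}/{total} permutation refits failed and were dropped",
            stacklevel=2,
        )
    null_arr = np.asarray(null_stats)
    p = float(np.mean(null_arr >= observed)) if len(null_arr) else float("nan")
    return PermutationResult(
        focal=focal,
        observed_statistic=observed,
        null_statistics=null_arr,
        p_value=p,
        n_failed=n_failed,
    )


# ---------------------------------------------------------------------------
# survival curves


def survival_curves(
    fit: TTDModelFit,
    focal: str,
    times: np.ndarray | None = None,
) -> pd.DataFrame:
    """Population-averaged survival curves S(t) per focal category.

    For each category, every record's focal value is forced to it and
    the per-record survival functions are averaged, giving the model's
    fraction of surveys still running (no detection yet) at each time.
    Curves start at 1 and are non-increasing; categories detected
    faster lie lower.

    Returns a DataFrame indexed by time (minutes), one column per
    category.
    """
    if times is None:
        times = np.linspace(0.0, CENSOR_MINUTES, 121)
    times = np.asarray(times, float)
    sigma = fit.scale
    out = {}
    focal_levels = fit.levels.get(focal) or _observed_levels(fit.data, focal)
    for level in focal_levels:
        forced = fit.data.copy()
        forced[focal] = level
        eta = fit._linear_predictor(forced, fit.params)
        with np.errstate(divide="ignore"):
            logt = np.log(times)[:, None]
        z = (logt - eta[None, :]) / sigma
        if fit.family == "lognormal":
            s = stats.norm.sf(z)
        else:
            s = np.exp(-np.exp(np.clip(z, -700.0, 700.0)))
        s[times == 0.0, :] = 1.0
        out[level] = s.mean(axis=1)
    return pd.DataFrame(out, index=pd.Index(times, name="time_min"))
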