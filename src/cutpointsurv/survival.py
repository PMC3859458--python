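"""From-scratch right-censored survival statistics.

Implements the estimators the learn/validate analysis relies on:

* Kaplan–Meier product-limit curves with Greenwood variance and a
  Brookmeyer–Crowley median confidence interval on the log(−log) scale;
* the two-sample log-rank test with hypergeometric variance;
* multivariable Cox proportional-hazards regression maximizing the
  Efron-ties partial likelihood by Newton–Raphson with step halving.

The Cox partial likelihood depends on event-time ordering only, so all
routines here are invariant under strictly increasing transformations of
the time axis. Efron's tie correction is used throughout because survival
recorded at month granularity produces tied event times routinely.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConvergenceError, DegenerateDataError, DomainError, RankDeficiencyError

__all__ = [
    "KMCurve",
    "LogRankResult",
    "CoxFit",
    "km_estimate",
    "km_median_ci",
    "logrank_test",
    "cox_fit",
    "coxph",
    "cox_score_test",
    "CoxPHRegressor",
]

_Z95 = stats.norm.ppf(0.975)


# ---------------------------------------------------------------------------
# Kaplan–Meier
# ---------------------------------------------------------------------------

@dataclass
class KMCurve:
    """Product-limit survival estimate.

    ``event_times`` holds the distinct times with at least one observed
    event; ``survival[i]`` is S(t) for t in [event_times[i],
    event_times[i+1]). S is 1 before the first event time. ``greenwood_var``
    is the Greenwood variance of S at each event time. The median and its
    95% CI follow the "smallest t with S(t) <= 0.5" convention; an interval
    endpoint the data cannot determine is ``None`` (reported as NA).
    """

    event_times: np.ndarray
    n_risk: np.ndarray
    n_event: np.ndarray
    survival: np.ndarray
    greenwood_var: np.ndarray
    n_total: int
    n_events_total: int
    median: float | None
    median_ci: tuple[float | None, float | None]
    ci_lower: np.ndarray = field(repr=False, default=None)
    ci_upper: np.ndarray = field(repr=False, default=None)

    def survival_at(self, t: float) -> float:
        """S(t) as a right-continuous step function."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.event_times,
                "n_risk": self.n_risk,
                "n_event": self.n_event,
                "survival": self.survival,
                "greenwood_var": self.greenwood_var,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def plot(self, ax=None, label: str | None = None):
        """Step plot of the curve (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = np.concatenate([[0.0], self.event_times])
        s = np.concatenate([[1.0], self.survival])
        ax.step(t, s, where="post", label=label)
        ax.set_xlabel("time (months)")
        ax.set_ylabel("survival probability")
        ax.set_ylim(0, 1.05)
        if label:
            ax.legend()
        return ax

    def summary(self) -> dict:
        return {
            "n": self.n_total,
            "events": self.n_events_total,
            "median": self.median,
            "median_ci_95": list(self.median_ci),
        }


def _validate_surv(times, events):
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        raise DegenerateDataError("empty survival sample")
    if np.any(~np.isfinite(times)) or np.any(times <= 0):
        bad = np.flatnonzero(~(np.isfinite(times) & (times > 0)))
        raise DomainError(f"survival times must be positive and finite; bad indices {bad.tolist()[:5]}")
    ev = np.asarray(events, dtype=float)
    if not np.all(np.isin(ev, (0.0, 1.0))):
        raise ValueError("event indicators must be 0 or 1")
    return times, ev.astype(int)


def km_estimate(times, events, alpha: float = 0.05) -> KMCurve:
    """Kaplan–Meier estimate from right-censored data.

    Records censored at an event time are counted at risk for that time
    (censoring is taken to occur after the tied events).
    """
    times, events = _validate_surv(times, events)
    n = times.size
    order = np.argsort(times, kind="stable")
    t, e = times[order], events[order]

    ev_times = np.unique(t[e == 1])
    if ev_times.size == 0:
        return KMCurve(
            event_times=np.empty(0),
            n_risk=np.empty(0, dtype=int),
            n_event=np.empty(0, dtype=int),
            survival=np.empty(0),
            greenwood_var=np.empty(0),
            n_total=n,
            n_events_total=0,
            median=None,
            median_ci=(None, None),
            ci_lower=np.empty(0),
            ci_upper=np.empty(0),
        )

    # n at risk at t_j: all with observed time >= t_j
    n_risk = n - np.searchsorted(t, ev_times, side="left")
    d = np.array([int(np.sum((t == tt) & (e == 1))) for tt in ev_times])
    frac = 1.0 - d / n_risk
    survival = np.cumprod(frac)

    # Greenwood: Var S(t) = S(t)^2 * sum d/(n(n-d)); last term may be inf
    with np.errstate(divide="ignore", invalid="ignore"):
        gsum = np.cumsum(np.where(n_risk > d, d / (n_risk * (n_risk - d.astype(float))), np.inf))
        gvar = survival**2 * gsum
    gvar = np.where(survival == 0.0, 0.0, gvar)

    lo, hi = _cloglog_band(survival, gsum, alpha)
    median = _qtime(ev_times, survival, 0.5)
    med_lo = _qtime(ev_times, lo, 0.5)
    med_hi = _qtime(ev_times, hi, 0.5)

    return KMCurve(
        event_times=ev_times,
        n_risk=n_risk,
        n_event=d,
        survival=survival,
        greenwood_var=gvar,
        n_total=n,
        n_events_total=int(d.sum()),
        median=median,
        median_ci=(med_lo, med_hi),
        ci_lower=lo,
        ci_upper=hi,
    )


def _cloglog_band(survival, gsum, alpha):
    """Pointwise CI on the log(−log S) scale ('exponential Greenwood')."""
    z = stats.norm.ppf(1 - alpha / 2)
    lo = np.zeros_like(survival)
    hi = np.ones_like(survival)
    with np.errstate(divide="ignore", invalid="ignore"):
        for i, s in enumerate(survival):
            if s <= 0.0:
                lo[i], hi[i] = 0.0, 0.0
            elif s >= 1.0:
                lo[i], hi[i] = 1.0, 1.0
            else:
                se = math.sqrt(gsum[i]) / abs(math.log(s))
                lo[i] = s ** math.exp(z * se)
                hi[i] = s ** math.exp(-z * se)
    return lo, hi


def _qtime(times, curve, q):
    """Smallest time at which the curve drops to <= q, else None."""
    idx = np.flatnonzero(curve <= q)
    return float(times[idx[0]]) if idx.size else None


def km_median_ci(curve: KMCurve):
    """Median survival and its 95% CI (Brookmeyer–Crowley band inversion)."""
    return curve.median, curve.median_ci


# ---------------------------------------------------------------------------
# Log-rank
# ---------------------------------------------------------------------------

@dataclass
class LogRankResult:
    statistic: float
    df: int
    p_value: float

    def to_json(self) -> str:
        return json.dumps(
            {"statistic": self.statistic, "df": self.df, "p_value": self.p_value, "method": "log-rank"}
        )


def logrank_test(times, events, group) -> LogRankResult:
    """Two-sample log-rank test.

    ``group`` is any two-level labelling. The statistic is
    (sum(O−E))² / sum(V) over pooled event times with hypergeometric
    variance, referred to chi-square(1).
    """
    times, events = _validate_surv(times, events)
    group = np.asarray(group)
    levels = np.unique(group)
    if levels.size != 2:
        raise DegenerateDataError(f"log-rank requires exactly 2 non-empty groups, got {levels.size}")
    g1 = group == levels[0]

    ev_times = np.unique(times[events == 1])
    o_minus_e = 0.0
    var = 0.0
    for tt in ev_times:
        at_risk = times >= tt
        n = int(at_risk.sum())
        n1 = int((at_risk & g1).sum())
        dead = (times == tt) & (events == 1)
        d = int(dead.sum())
        d1 = int((dead & g1).sum())
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var <= 0.0:
        return LogRankResult(statistic=0.0, df=1, p_value=1.0)
    stat = o_minus_e**2 / var
    return LogRankResult(statistic=float(stat), df=1, p_value=float(stats.chi2.sf(stat, 1)))


# ---------------------------------------------------------------------------
# Cox proportional hazards (Efron ties)
# ---------------------------------------------------------------------------

@dataclass
class CoxFit:
    terms: list[str]
    coef: np.ndarray
    se: np.ndarray
    hazard_ratios: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    p_values: np.ndarray
    loglik: float
    loglik_null: float
    n: int
    n_events: int
    converged: bool
    n_iter: int
    ties_method: str = "efron"

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.coef,
                "se": self.se,
                "HR": self.hazard_ratios,
                "HR_ci_lower": self.ci_lower,
                "HR_ci_upper": self.ci_upper,
                "p": self.p_values,
            },
            index=self.terms,
        )

    def to_dict(self) -> dict:
        return {
            "terms": self.terms,
            "coef": self.coef.tolist(),
            "se": self.se.tolist(),
            "hazard_ratios": self.hazard_ratios.tolist(),
            "ci_95_lower": self.ci_lower.tolist(),
            "ci_95_upper": self.ci_upper.tolist(),
            "p_values": self.p_values.tolist(),
            "loglik": self.loglik,
            "loglik_null": self.loglik_null,
            "n": self.n,
            "n_events": self.n_events,
            "converged": self.converged,
            "ties_method": self.ties_method,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict())


class _EfronPrep:
    """Sorted arrays and event-group bookkeeping, shared across NR iterations."""

    __slots__ = ("t", "e", "X", "ev_idx", "grp_first_risk", "grp_d", "gidx", "a", "grp_starts", "n_events")

    def __init__(self, X, time, event):
        order = np.argsort(time, kind="stable")
        self.t = time[order]
        self.e = event[order]
        self.X = X[order]
        self.ev_idx = np.flatnonzero(self.e == 1)
        ev_t = self.t[self.ev_idx]
        uniq, starts, counts = np.unique(ev_t, return_index=True, return_counts=True)
        self.grp_starts = starts
        self.grp_d = counts
        self.grp_first_risk = np.searchsorted(self.t, uniq, side="left")
        # flattened (group j, within-tie index l) pairs for the Efron sum
        self.gidx = np.repeat(np.arange(uniq.size), counts)
        offsets = np.repeat(starts, counts)
        self.a = (np.arange(self.ev_idx.size) - offsets) / np.repeat(counts, counts).astype(float)
        self.n_events = int(self.ev_idx.size)


def _efron_ll_grad_info(beta, prep: _EfronPrep, want_derivs=True):
    X, t = prep.X, prep.t
    eta = X @ beta
    eta = eta - eta.mean()  # invariant shift, guards exp overflow
    w = np.exp(eta)

    S0 = np.cumsum(w[::-1])[::-1]
    wX = w[:, None] * X
    S1 = np.cumsum(wX[::-1], axis=0)[::-1]

    ev = prep.ev_idx
    D0 = np.add.reduceat(w[ev], prep.grp_starts)
    D1 = np.add.reduceat(wX[ev], prep.grp_starts, axis=0)

    g = prep.gidx
    a = prep.a
    phi = S0[prep.grp_first_risk][g] - a * D0[g]
    ll = float(eta[ev].sum() - np.log(phi).sum())
    if not want_derivs:
        return ll, None, None

    Z1 = S1[prep.grp_first_risk][g] - a[:, None] * D1[g]
    mu = Z1 / phi[:, None]
    grad = X[ev].sum(axis=0) - mu.sum(axis=0)

    wXX = wX[:, :, None] * X[:, None, :]
    S2 = np.cumsum(wXX[::-1], axis=0)[::-1]
    D2 = np.add.reduceat(wXX[ev], prep.grp_starts, axis=0)
    Z2 = S2[prep.grp_first_risk][g] - a[:, None, None] * D2[g]
    info = (Z2 / phi[:, None, None]).sum(axis=0) - mu.T @ mu
    return ll, grad, info


def _check_design(X, names, time, event):
    """Full-rank check restricted to subjects ever at risk at an event time."""
    ev_times = time[event == 1]
    if ev_times.size == 0:
        raise DegenerateDataError("Cox model requires at least one observed event")
    at_risk = time >= ev_times.min()
    Xr = X[at_risk]
    const = [names[j] for j in range(X.shape[1]) if np.ptp(Xr[:, j]) == 0.0]
    if const:
        raise RankDeficiencyError(f"terms constant on the risk sets: {const}")
    Xc = Xr - Xr.mean(axis=0)
    if np.linalg.matrix_rank(Xc) < X.shape[1]:
        # greedy: name columns whose removal restores full rank
        bad = []
        for j in range(X.shape[1]):
            keep = [k for k in range(X.shape[1]) if k != j]
            if np.linalg.matrix_rank(Xc[:, keep]) == len(keep):
                bad.append(names[j])
        raise RankDeficiencyError(f"collinear terms: {bad or names}")


def coxph(
    X,
    time,
    event,
    names: list[str] | None = None,
    max_iter: int = 25,
    tol: float = 1e-9,
    beta0=None,
    check_rank: bool = True,
) -> CoxFit:
    """Fit a Cox model on a numeric design matrix.

    Newton–Raphson on the Efron partial likelihood with step halving on
    overshoot; converged when the relative change in the partial
    log-likelihood falls below ``tol``. Standard errors come from the
    inverse observed information; CIs are Wald on the log scale,
    exponentiated.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    n, p = X.shape
    if names is None:
        names = [f"x{j}" for j in range(p)]
    if check_rank:
        _check_design(X, names, time, event)
    prep = _EfronPrep(X, time, event)

    beta = np.zeros(p) if beta0 is None else np.asarray(beta0, dtype=float).copy()
    ll, grad, info = _efron_ll_grad_info(beta, prep)
    ll_null = ll if beta0 is None else _efron_ll_grad_info(np.zeros(p), prep, want_derivs=False)[0]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(info, grad, rcond=None)[0]
        # step halving on overshoot
        new_beta, new_ll = beta + step, -np.inf
        for _ in range(32):
            new_ll = _efron_ll_grad_info(new_beta, prep, want_derivs=False)[0]
            if new_ll >= ll - 1e-12:
                break
            step *= 0.5
            new_beta = beta + step
        delta = abs(new_ll - ll)
        beta = new_beta
        ll, grad, info = _efron_ll_grad_info(beta, prep)
        if np.max(np.abs(beta)) > 50.0:
            worst = names[int(np.argmax(np.abs(beta)))]
            raise ConvergenceError(
                f"partial likelihood appears monotone in term '{worst}' "
                f"(|coef| > 50 after {it} iterations; possible perfect separation)"
            )
        if delta < tol * (abs(ll) + tol):
            converged = True
            break

    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        # a flat likelihood direction (tiny strata) leaves the information
        # singular at the optimum; pseudo-inverse keeps the fit usable
        cov = np.linalg.pinv(info)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    with np.errstate(over="ignore"):  # huge SE on a flat direction -> inf bound
        lo = np.exp(beta - _Z95 * se)
        hi = np.exp(beta + _Z95 * se)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, beta / se, np.inf)
    pvals = 2 * stats.norm.sf(np.abs(z))
    return CoxFit(
        terms=list(names),
        coef=beta,
        se=se,
        hazard_ratios=np.exp(beta),
        ci_lower=lo,
        ci_upper=hi,
        p_values=pvals,
        loglik=float(ll),
        loglik_null=float(ll_null),
        n=n,
        n_events=prep.n_events,
        converged=converged,
        n_iter=it,
    )


def cox_fit(data: pd.DataFrame, terms: list[str], duration_col: str = "os_months", event_col: str = "event", **kwargs) -> CoxFit:
    """Fit a Cox model on numeric columns of a data frame."""
    X = data[terms].to_numpy(dtype=float)
    return coxph(X, data[duration_col].to_numpy(float), data[event_col].to_numpy(int), names=list(terms), **kwargs)


def cox_score_test(x, time, event) -> float:
    """Score (Rao) chi-square statistic at beta = 0 for a single covariate.

    On a two-group comparison with untied event times this equals the
    log-rank statistic — the classical identity linking the two tests.
    """
    X = np.asarray(x, dtype=float).reshape(-1, 1)
    prep = _EfronPrep(X, np.asarray(time, float), np.asarray(event, int))
    _, grad, info = _efron_ll_grad_info(np.zeros(1), prep)
    return float(grad[0] ** 2 / info[0, 0])


class CoxPHRegressor:
    """scikit-learn-style Cox proportional-hazards estimator.

    ``fit(X, y)`` takes a design matrix and ``y`` as an (n, 2) array of
    (duration, event). Fitted attributes: ``coef_``, ``se_``,
    ``hazard_ratios_``, ``fit_`` (the full :class:`CoxFit`).
    """

    def __init__(self, max_iter: int = 25, tol: float = 1e-9):
        self.max_iter = max_iter
        self.tol = tol

    def get_params(self, deep: bool = True) -> dict:
        return {"max_iter": self.max_iter, "tol": self.tol}

    def set_params(self, **params):
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X, y, feature_names: list[str] | None = None):
        y = np.asarray(y, dtype=float)
        if y.ndim != 2 or y.shape[1] != 2:
            raise ValueError("y must be an (n, 2) array of (duration, event)")
        self.fit_ = coxph(X, y[:, 0], y[:, 1].astype(int), names=feature_names, max_iter=self.max_iter, tol=self.tol)
        self.coef_ = self.fit_.coef
        self.se_ = self.fit_.se
        self.hazard_ratios_ = self.fit_.hazard_ratios
        self.n_features_in_ = len(self.fit_.terms)
        return self

    def predict(self, X):
        """Linear predictor (log relative hazard)."""
        return np.asarray(X, dtype=float) @ self.coef_

    def score(self, X, y):
        """Maximized partial log-likelihood of this model's coefficients on new data."""
        y = np.asarray(y, dtype=float)
        prep = _EfronPrep(np.asarray(X, float), y[:, 0], y[:, 1].astype(int))
        return _efron_ll_grad_info(self.coef_, prep, want_derivs=False)[0]
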