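"""Outcome-based Bayesian cut-point selection for a treatment-predictive marker.

The procedure dichotomizes a continuous marker at a candidate threshold c
and asks how well the Cox model

    h(t | x) = h0(t) * exp(b1*treat + b'z + g1*I(marker >= c)
                           + g2*treat*I(marker >= c))

explains the observed survival, profiling the maximized Efron partial
log-likelihood over c. With a uniform prior over a grid of observed marker
values, exponentiating the profile log-likelihood yields a (pseudo-)
posterior over cut-points; its weighted median is the operational
threshold and a central 95% credible interval quantifies its uncertainty.

Variable selection alternates a *screen* phase (rank candidate markers by
the BIC-approximated log Bayes factor of their best interaction model
against the current model, and candidate covariates by the analogous
main-effect evidence) with a *build* phase (refit the joint model and drop
terms whose evidence has fallen below the threshold), iterating to a fixed
point. The default evidence threshold (log BF = 3) is the conventional
"positive evidence" bar and controls the false-positive rate of
interaction discovery, which null-simulation tests verify.

Everything is deterministic: no MCMC, a fixed grid, and lexicographic
tie-breaking between equally supported candidates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import BoundaryError, DegenerateDataError, InsufficientDataError
from .survival import CoxFit, coxph

__all__ = [
    "CandidateSet",
    "ModelSelectionConfig",
    "CutpointPosterior",
    "SelectedModel",
    "CandidateEvidence",
    "profile_partial_loglik",
    "cutpoint_posterior",
    "extract_cutoff",
    "screen_variables",
    "select_model",
    "CutpointSelector",
    "encode_covariates",
]

#: Covariate name -> (design column names, builder)
_COVARIATE_ENCODERS = {
    "age": (["age_years"], lambda df: [df["age_years"].to_numpy(float)]),
    "sex": (["sex_female"], lambda df: [(df["sex"] == "female").to_numpy(float)]),
    "histology": (
        ["histology_squamous", "histology_other"],
        lambda df: [
            (df["histology"] == "squamous").to_numpy(float),
            (df["histology"] == "other").to_numpy(float),
        ],
    ),
}


def encode_covariates(data: pd.DataFrame, covariates: list[str]):
    """Numeric design columns for named covariates.

    ``sex`` becomes a female indicator, ``histology`` two indicators with
    adenocarcinoma as the reference level, ``age`` enters linearly in
    years. A covariate named directly after a numeric column passes
    through unchanged.
    """
    cols, names = [], []
    for cov in covariates:
        if cov in _COVARIATE_ENCODERS:
            enc_names, builder = _COVARIATE_ENCODERS[cov]
            names.extend(enc_names)
            cols.extend(builder(data))
        elif cov in data.columns:
            names.append(cov)
            cols.append(data[cov].to_numpy(float))
        else:
            raise KeyError(f"unknown covariate {cov!r}")
    if not cols:
        return np.empty((len(data), 0)), []
    return np.column_stack(cols), names


@dataclass
class CandidateSet:
    """Predictors considered for treatment interaction vs prognosis only."""

    markers: list[str] = field(default_factory=lambda: ["ercc1_std", "rrm1_std"])
    covariates: list[str] = field(default_factory=lambda: ["age", "sex", "histology"])

    def __post_init__(self):
        if not self.markers:
            raise DegenerateDataError("CandidateSet requires at least one marker")


@dataclass
class ModelSelectionConfig:
    """Tunable knobs of the screen/build selection loop.

    grid_quantile_range: interior quantile span of observed marker values
        admitted as candidate cut-points (protects against near-empty
        groups at the extremes).
    grid_max_points: cap on the grid size; when a cohort has more unique
        marker values than this, evenly spaced order statistics are used
        (adjacent order statistics are likelihood-equivalent cut-points).
    evidence_threshold: minimum log Bayes factor (BIC-approximated) for a
        term to enter or survive the build phase; 3 is the conventional
        "positive evidence" bar.
    max_iterations: cap on screen/build cycles before the selector returns
        its last model flagged non-converged.
    """

    grid_quantile_range: tuple[float, float] = (0.10, 0.90)
    grid_max_points: int = 50
    evidence_threshold: float = 3.0
    max_iterations: int = 10
    prior: str = "uniform"

    def validate(self):
        lo, hi = self.grid_quantile_range
        if not (0.0 < lo < hi < 1.0):
            raise DegenerateDataError("grid_quantile_range must satisfy 0 < lower < upper < 1")
        if self.max_iterations < 1:
            raise DegenerateDataError("max_iterations must be >= 1")
        if self.prior != "uniform":
            raise DegenerateDataError(f"unsupported prior {self.prior!r}")
        if self.grid_max_points < 3:
            raise DegenerateDataError("grid_max_points must be >= 3")


@dataclass
class CutpointPosterior:
    """Posterior over candidate cut-points on the standardized scale."""

    grid: np.ndarray
    log_weights: np.ndarray  # unnormalized log posterior ordinates
    weights: np.ndarray  # normalized
    posterior_median: float
    credible_interval: tuple[float, float]

    def cdf(self) -> np.ndarray:
        return np.cumsum(self.weights)

    def to_dict(self) -> dict:
        return {
            "grid": self.grid.tolist(),
            "weights": self.weights.tolist(),
            "posterior_median": self.posterior_median,
            "credible_interval_95": list(self.credible_interval),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    def to_csv(self, path) -> None:
        pd.DataFrame({"cutpoint": self.grid, "weight": self.weights}).to_csv(path, index=False)


@dataclass
class CandidateEvidence:
    name: str
    kind: str  # "interaction" or "main"
    log_bf: float
    best_cutpoint: float | None = None


@dataclass
class SelectedModel:
    """Result of the screen/build loop."""

    main_effects: list[str]
    interaction_marker: str | None
    posterior: CutpointPosterior | None
    cutoff: float | None
    fit: CoxFit
    converged: bool
    history: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "main_effects": self.main_effects,
            "interaction_marker": self.interaction_marker,
            "cutoff": self.cutoff,
            "posterior": self.posterior.to_dict() if self.posterior else None,
            "fit": self.fit.to_dict(),
            "converged": self.converged,
            "history": self.history,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict())


# ---------------------------------------------------------------------------
# Profile likelihood over cut-points
# ---------------------------------------------------------------------------

def _base_design(data: pd.DataFrame, covariates: list[str], treatment_col: str):
    treat = (data[treatment_col] == "experimental").to_numpy(float)
    if treat.min() == treat.max():
        raise DegenerateDataError("dataset must contain both treatment arms")
    Z, znames = encode_covariates(data, covariates)
    return treat, Z, znames


def _interaction_loglik(treat, Z, znames, marker_vals, cutpoint, time, event, beta0=None):
    ind = (marker_vals >= cutpoint).astype(float)
    if ind.min() == ind.max():
        raise BoundaryError(f"cut-point {cutpoint} leaves one marker group empty")
    X = np.column_stack([treat, Z, ind, treat * ind])
    names = ["treatment", *znames, "marker_high", "treatment:marker_high"]
    fit = coxph(X, time, event, names=names, beta0=beta0, check_rank=False)
    return fit


def profile_partial_loglik(
    data: pd.DataFrame,
    marker: str,
    cutpoint: float,
    covariates: list[str] = (),
    treatment_col: str = "arm",
    duration_col: str = "os_months",
    event_col: str = "event",
) -> float:
    """Maximized Efron partial log-likelihood of the interaction model at one cut-point.

    The model contains treatment, the named covariates, I(marker >= c) and
    the treatment x indicator interaction. A dataset with zero events has
    an empty partial likelihood and returns 0. Depends on event-time
    ordering only.
    """
    time = data[duration_col].to_numpy(float)
    event = data[event_col].to_numpy(int)
    if event.sum() == 0:
        return 0.0
    treat, Z, znames = _base_design(data, list(covariates), treatment_col)
    fit = _interaction_loglik(treat, Z, znames, data[marker].to_numpy(float), cutpoint, time, event)
    return fit.loglik


def _cutpoint_grid(values: np.ndarray, config: ModelSelectionConfig) -> np.ndarray:
    lo, hi = np.quantile(values, config.grid_quantile_range)
    grid = np.unique(values)
    grid = grid[(grid >= lo) & (grid <= hi)]
    if grid.size > config.grid_max_points:
        idx = np.unique(np.linspace(0, grid.size - 1, config.grid_max_points).round().astype(int))
        grid = grid[idx]
    return grid


def _scan_grid(data, marker, covariates, config, treatment_col, duration_col, event_col):
    """Profile log-likelihood at every admissible grid point (warm-started)."""
    time = data[duration_col].to_numpy(float)
    event = data[event_col].to_numpy(int)
    if event.sum() == 0:
        raise DegenerateDataError("cut-point scan requires at least one event")
    treat, Z, znames = _base_design(data, list(covariates), treatment_col)
    marker_vals = data[marker].to_numpy(float)
    grid = _cutpoint_grid(marker_vals, config)

    keep, lls = [], []
    beta = None
    for c in grid:
        try:
            fit = _interaction_loglik(treat, Z, znames, marker_vals, c, time, event, beta0=beta)
        except BoundaryError:
            continue
        except Exception:
            # a pathological cut-point (e.g. separation) is skipped, not fatal
            beta = None
            continue
        beta = fit.coef
        keep.append(c)
        lls.append(fit.loglik)
    if len(keep) < 3:
        raise InsufficientDataError(
            f"only {len(keep)} admissible cut-points for {marker!r}; need >= 3"
        )
    return np.asarray(keep), np.asarray(lls)


def cutpoint_posterior(
    data: pd.DataFrame,
    marker: str,
    covariates: list[str] = (),
    config: ModelSelectionConfig | None = None,
    treatment_col: str = "arm",
    duration_col: str = "os_months",
    event_col: str = "event",
) -> CutpointPosterior:
    """Pseudo-posterior over cut-points: prior x exp(profile partial log-lik)."""
    config = config or ModelSelectionConfig()
    config.validate()
    grid, lls = _scan_grid(data, marker, covariates, config, treatment_col, duration_col, event_col)
    log_w = lls - lls.max()  # uniform prior: constant shift only
    w = np.exp(log_w)
    w /= w.sum()
    cdf = np.cumsum(w)

    def _q(q):  # smallest grid value with cumulative weight >= q
        return float(grid[min(np.searchsorted(cdf, q), grid.size - 1)])

    median = _q(0.5)
    ci = (_q(0.025), _q(0.975))
    return CutpointPosterior(grid=grid, log_weights=lls, weights=w, posterior_median=median, credible_interval=ci)


def extract_cutoff(posterior: CutpointPosterior) -> float:
    """Weighted-median cut-off: smallest grid value with cumulative weight >= 0.5."""
    cdf = np.cumsum(posterior.weights)
    idx = min(np.searchsorted(cdf, 0.5), posterior.grid.size - 1)
    return float(posterior.grid[idx])


# ---------------------------------------------------------------------------
# Screen / build selection
# ---------------------------------------------------------------------------

def _fit_model(data, covariates, marker, cutoff, treatment_col, duration_col, event_col) -> CoxFit:
    time = data[duration_col].to_numpy(float)
    event = data[event_col].to_numpy(int)
    treat, Z, znames = _base_design(data, covariates, treatment_col)
    cols = [treat]
    names = ["treatment"]
    if Z.shape[1]:
        cols.append(Z)
        names.extend(znames)
    if marker is not None:
        ind = (data[marker].to_numpy(float) >= cutoff).astype(float)
        cols.append(np.column_stack([ind, treat * ind]))
        names.extend(["marker_high", "treatment:marker_high"])
    X = np.column_stack(cols)
    return coxph(X, time, event, names=names)


def _n_events(data, event_col):
    return int(np.asarray(data[event_col]).sum())


def screen_variables(
    data: pd.DataFrame,
    candidates: CandidateSet,
    config: ModelSelectionConfig | None = None,
    current_covariates: list[str] = (),
    current_marker: str | None = None,
    current_cutoff: float | None = None,
    treatment_col: str = "arm",
    duration_col: str = "os_months",
    event_col: str = "event",
) -> list[CandidateEvidence]:
    """Rank candidate terms by BIC-approximated log Bayes factors.

    For a marker, the evidence compares its best interaction model (over
    the cut-point grid) against the current model; the BIC penalty charges
    the two extra parameters (indicator + interaction) at log(n_events)
    each, halved. For a covariate, the analogous main-effect comparison.
    Candidates already in the model are not re-screened. Ties break
    lexicographically by name for deterministic runs.
    """
    config = config or ModelSelectionConfig()
    config.validate()
    cur_cov = list(current_covariates)
    pen_n = max(_n_events(data, event_col), 2)
    base = _fit_model(data, cur_cov, current_marker, current_cutoff, treatment_col, duration_col, event_col)

    out: list[CandidateEvidence] = []
    for marker in candidates.markers:
        if marker == current_marker:
            continue
        if current_marker is not None:
            continue  # one interaction marker per model
        try:
            grid, lls = _scan_grid(data, marker, cur_cov, config, treatment_col, duration_col, event_col)
        except (InsufficientDataError, DegenerateDataError):
            continue
        best = int(np.argmax(lls))
        log_bf = lls[best] - base.loglik - 0.5 * 2 * np.log(pen_n)
        out.append(CandidateEvidence(marker, "interaction", float(log_bf), float(grid[best])))
    for cov in candidates.covariates:
        if cov in cur_cov:
            continue
        k = len(_COVARIATE_ENCODERS[cov][0]) if cov in _COVARIATE_ENCODERS else 1
        fit = _fit_model(data, cur_cov + [cov], current_marker, current_cutoff, treatment_col, duration_col, event_col)
        log_bf = fit.loglik - base.loglik - 0.5 * k * np.log(pen_n)
        out.append(CandidateEvidence(cov, "main", float(log_bf)))
    out.sort(key=lambda e: (-e.log_bf, e.name))
    return out


def _term_evidence(data, covariates, marker, cutoff, config, treatment_col, duration_col, event_col):
    """Evidence for each term currently in the model, vs the model without it."""
    pen_n = max(_n_events(data, event_col), 2)
    full = _fit_model(data, covariates, marker, cutoff, treatment_col, duration_col, event_col)
    ev = {}
    for cov in covariates:
        rest = [c for c in covariates if c != cov]
        k = len(_COVARIATE_ENCODERS[cov][0]) if cov in _COVARIATE_ENCODERS else 1
        red = _fit_model(data, rest, marker, cutoff, treatment_col, duration_col, event_col)
        ev[cov] = full.loglik - red.loglik - 0.5 * k * np.log(pen_n)
    if marker is not None:
        red = _fit_model(data, covariates, None, None, treatment_col, duration_col, event_col)
        ev[marker] = full.loglik - red.loglik - 0.5 * 2 * np.log(pen_n)
    return ev, full


def select_model(
    data: pd.DataFrame,
    candidates: CandidateSet | None = None,
    config: ModelSelectionConfig | None = None,
    treatment_col: str = "arm",
    duration_col: str = "os_months",
    event_col: str = "event",
) -> SelectedModel:
    """Iterated screen/build selection of prognostic and predictive terms.

    Screen: add the best candidate whose evidence exceeds the threshold
    (conditional on the current model). Build: refit the joint model and
    drop any included term whose evidence has fallen below the threshold.
    Stops at a fixed point or after ``max_iterations`` cycles (the latter
    returns the last model flagged non-converged). A selected marker's
    cut-point is the weighted median of its posterior, recomputed whenever
    the covariate set changes.
    """
    candidates = candidates or CandidateSet()
    # de-duplicate while preserving order
    candidates = CandidateSet(
        markers=list(dict.fromkeys(candidates.markers)),
        covariates=list(dict.fromkeys(candidates.covariates)),
    )
    config = config or ModelSelectionConfig()
    config.validate()
    kw = dict(treatment_col=treatment_col, duration_col=duration_col, event_col=event_col)

    covs: list[str] = []
    marker: str | None = None
    cutoff: float | None = None
    posterior: CutpointPosterior | None = None
    history: list[dict] = []
    converged = False

    for it in range(config.max_iterations):
        changed = False
        # --- screen phase: add the single best candidate over threshold
        evidence = screen_variables(
            data, candidates, config, current_covariates=covs,
            current_marker=marker, current_cutoff=cutoff, **kw,
        )
        added = None
        if evidence and evidence[0].log_bf > config.evidence_threshold:
            top = evidence[0]
            if top.kind == "interaction":
                posterior = cutpoint_posterior(data, top.name, covs, config, **kw)
                marker, cutoff = top.name, extract_cutoff(posterior)
            else:
                covs.append(top.name)
            added = top.name
            changed = True
        # --- build phase: refit jointly, drop weak terms
        if marker is not None and posterior is not None:
            # covariate set may have changed since the posterior was formed
            posterior = cutpoint_posterior(data, marker, covs, config, **kw)
            cutoff = extract_cutoff(posterior)
        ev, _ = _term_evidence(data, covs, marker, cutoff, config, **kw)
        dropped = [t for t, e in sorted(ev.items()) if e < config.evidence_threshold]
        for t in dropped:
            if t == marker:
                marker, cutoff, posterior = None, None, None
            else:
                covs.remove(t)
            changed = True
        history.append({"iteration": it, "added": added, "dropped": dropped,
                        "covariates": list(covs), "marker": marker})
        if not changed:
            converged = True
            break

    final = _fit_model(data, covs, marker, cutoff, **kw)
    return SelectedModel(
        main_effects=list(covs),
        interaction_marker=marker,
        posterior=posterior,
        cutoff=cutoff,
        fit=final,
        converged=converged,
        history=history,
    )


class CutpointSelector:
    """scikit-learn-style wrapper around the screen/build selector.

    ``fit(data)`` runs model selection on a standardized cohort frame and
    exposes ``model_``, ``cutoff_`` and ``posterior_``; ``predict(data)``
    labels patients 'high'/'low' by the learned threshold on the selected
    marker column.
    """

    def __init__(
        self,
        markers: tuple[str, ...] = ("ercc1_std", "rrm1_std"),
        covariates: tuple[str, ...] = ("age", "sex", "histology"),
        grid_quantile_range: tuple[float, float] = (0.10, 0.90),
        grid_max_points: int = 50,
        evidence_threshold: float = 3.0,
        max_iterations: int = 10,
    ):
        self.markers = markers
        self.covariates = covariates
        self.grid_quantile_range = grid_quantile_range
        self.grid_max_points = grid_max_points
        self.evidence_threshold = evidence_threshold
        self.max_iterations = max_iterations

    def get_params(self, deep: bool = True) -> dict:
        return {
            "markers": self.markers,
            "covariates": self.covariates,
            "grid_quantile_range": self.grid_quantile_range,
            "grid_max_points": self.grid_max_points,
            "evidence_threshold": self.evidence_threshold,
            "max_iterations": self.max_iterations,
        }

    def set_params(self, **params):
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def _config(self) -> ModelSelectionConfig:
        return ModelSelectionConfig(
            grid_quantile_range=tuple(self.grid_quantile_range),
            grid_max_points=self.grid_max_points,
            evidence_threshold=self.evidence_threshold,
            max_iterations=self.max_iterations,
        )

    def fit(self, data: pd.DataFrame, y=None):
        self.model_ = select_model(
            data,
            CandidateSet(markers=list(self.markers), covariates=list(self.covariates)),
            self._config(),
        )
        self.cutoff_ = self.model_.cutoff
        self.posterior_ = self.model_.posterior
        self.marker_ = self.model_.interaction_marker
        return self

    def predict(self, data: pd.DataFrame) -> np.ndarray:
        if not hasattr(self, "model_"):
            raise RuntimeError("CutpointSelector is not fitted")
        if self.marker_ is None:
            raise DegenerateDataError("no interaction marker was selected; nothing to classify")
        return np.where(data[self.marker_].to_numpy(float) >= self.cutoff_, "high", "low")
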