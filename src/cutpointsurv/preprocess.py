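"""Marker-score preprocessing and threshold classification.

Raw in-situ protein scores (AQUA-type, bounded 0–255) are right-skewed, so
every analysis works on log2-transformed scores standardized robustly:
subtract the sample median and divide by the median absolute deviation
(MAD, optionally scaled by the normal-consistency constant 1.4826). The
standardized scale makes a learned cut-off portable across cohorts as a
scaled distance from each cohort's own median; both cohorts in a
learn/validate analysis are standardized with their *own* parameters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .errors import DegenerateDataError, DomainError

#: MAD multiplier making the MAD a consistent estimator of the standard
#: deviation under normality (the default of common statistical software).
NORMAL_MAD_CONSTANT = 1.4826

__all__ = [
    "NORMAL_MAD_CONSTANT",
    "StandardizationParams",
    "MarkerThreshold",
    "MarkerStandardizer",
    "log2_transform",
    "fit_standardization",
    "apply_standardization",
    "classify_marker",
    "filter_stage_iv",
]


@dataclass
class StandardizationParams:
    """Robust location/scale of a cohort's log2 marker scores."""

    center: float
    scale: float
    mad_constant: float = NORMAL_MAD_CONSTANT

    def __post_init__(self):
        if not (np.isfinite(self.scale) and self.scale > 0):
            raise DegenerateDataError(f"standardization scale must be positive, got {self.scale}")

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "StandardizationParams":
        return cls(**json.loads(s))


@dataclass
class MarkerThreshold:
    """A cut-off on the standardized log2 scale; scores >= cutoff are 'high'."""

    cutoff_std: float
    boundary_rule: str = "ge"  # score == cutoff classifies high

    def __post_init__(self):
        if not np.isfinite(self.cutoff_std):
            raise DomainError("threshold must be finite")
        if self.boundary_rule != "ge":
            raise DomainError(f"unsupported boundary rule {self.boundary_rule!r}")

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "MarkerThreshold":
        return cls(**json.loads(s))


def log2_transform(scores):
    """Elementwise base-2 log; raises DomainError naming any non-positive score."""
    x = np.asarray(scores, dtype=float)
    bad = np.flatnonzero(~(x > 0))
    if bad.size:
        raise DomainError(f"log2 requires strictly positive scores; offending indices {bad.tolist()[:5]}")
    return np.log2(x)


def fit_standardization(log_scores, mad_constant: float = NORMAL_MAD_CONSTANT) -> StandardizationParams:
    """Median/MAD location-scale fit on log2 scores.

    The median of an even-sized sample is the mean of the two central order
    statistics. All-identical input has MAD 0 and raises.
    """
    x = np.asarray(log_scores, dtype=float)
    if np.unique(x).size < 2:
        raise DegenerateDataError("cannot standardize: fewer than 2 distinct values")
    center = float(np.median(x))
    raw_mad = float(np.median(np.abs(x - center)))
    if raw_mad == 0.0:
        raise DegenerateDataError("cannot standardize: MAD is zero (more than half the values tied)")
    return StandardizationParams(center=center, scale=mad_constant * raw_mad, mad_constant=mad_constant)


def apply_standardization(log_scores, params: StandardizationParams):
    """(x − center) / scale, elementwise; an order-preserving affine map."""
    return (np.asarray(log_scores, dtype=float) - params.center) / params.scale


def classify_marker(std_scores, threshold: MarkerThreshold) -> np.ndarray:
    """Dichotomize standardized scores: 'high' iff score >= cutoff, else 'low'."""
    x = np.asarray(std_scores, dtype=float)
    if np.any(~np.isfinite(x)):
        raise DomainError("standardized scores must be finite")
    out = np.where(x >= threshold.cutoff_std, "high", "low")
    return out if out.ndim else out[()]


class MarkerStandardizer:
    """scikit-learn-style transformer: log2 then median/MAD standardization.

    Fit on the raw marker columns of one cohort; transform maps raw scores
    to the standardized log2 scale. Fitted attribute ``params_`` maps
    column name (or index) to :class:`StandardizationParams`.
    """

    def __init__(self, mad_constant: float = NORMAL_MAD_CONSTANT, log_transform: bool = True):
        self.mad_constant = mad_constant
        self.log_transform = log_transform

    def get_params(self, deep: bool = True) -> dict:
        return {"mad_constant": self.mad_constant, "log_transform": self.log_transform}

    def set_params(self, **params):
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def _columns(self, X):
        if isinstance(X, pd.DataFrame):
            return list(X.columns), [X[c].to_numpy(float) for c in X.columns]
        arr = np.atleast_2d(np.asarray(X, dtype=float))
        return list(range(arr.shape[1])), [arr[:, j] for j in range(arr.shape[1])]

    def fit(self, X, y=None):
        names, cols = self._columns(X)
        self.params_ = {}
        for name, col in zip(names, cols):
            logged = log2_transform(col) if self.log_transform else np.asarray(col, float)
            self.params_[name] = fit_standardization(logged, mad_constant=self.mad_constant)
        self.n_features_in_ = len(names)
        return self

    def transform(self, X):
        if not hasattr(self, "params_"):
            raise RuntimeError("MarkerStandardizer is not fitted")
        names, cols = self._columns(X)
        out = []
        for name, col in zip(names, cols):
            if name not in self.params_:
                raise KeyError(f"column {name!r} was not seen during fit")
            logged = log2_transform(col) if self.log_transform else np.asarray(col, float)
            out.append(apply_standardization(logged, self.params_[name]))
        res = np.column_stack(out)
        if isinstance(X, pd.DataFrame):
            return pd.DataFrame(res, columns=names, index=X.index)
        return res

    def fit_transform(self, X, y=None):
        return self.fit(X, y).transform(X)


def filter_stage_iv(data):
    """Drop stage-IIIB records, keeping stage IV only.

    Accepts a DataFrame with a ``stage`` column (or a TrialDataset); returns
    the same type. Raises if no stage-IV records remain.
    """
    from .simulate import TrialDataset  # local import avoids a cycle

    if isinstance(data, TrialDataset):
        filtered = filter_stage_iv(data.records)
        return TrialDataset(records=filtered, cohort_label=data.cohort_label, provenance=data.provenance)
    keep = data["stage"] == "IV"
    removed = int((~keep).sum())
    if removed:
        import logging

        logging.getLogger(__name__).info("filter_stage_iv: removed %d non-IV records", removed)
    out = data.loc[keep].reset_index(drop=True)
    if out.empty:
        raise DegenerateDataError("no stage-IV records remain after filtering")
    return out
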