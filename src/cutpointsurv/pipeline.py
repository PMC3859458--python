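"""Learn-then-validate orchestration.

One cohort (the learning trial) is used to select prognostic/predictive
terms and the marker threshold; the threshold is then frozen and applied
to an independent cohort, which supplies all the hypothesis tests. The
two stages communicate only through a serialized :class:`LearnResult`, so
validation can never leak information back into threshold estimation.

Each cohort is standardized with its *own* median/MAD, so the frozen
threshold is a scaled distance from each trial's median marker score
rather than an absolute level — the reading that makes a threshold
portable across cohorts whose raw score distributions differ.
"""

from __future__ import annotations

import json
import logging
import time as _time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assoc import TestResult, mcnemar_exact
from .cutpoint import (
    CandidateSet,
    ModelSelectionConfig,
    SelectedModel,
    cutpoint_posterior,
    encode_covariates,
    extract_cutoff,
    select_model,
)
from .errors import CutpointSurvError, DegenerateDataError
from .preprocess import (
    MarkerThreshold,
    StandardizationParams,
    apply_standardization,
    classify_marker,
    filter_stage_iv,
    fit_standardization,
    log2_transform,
    NORMAL_MAD_CONSTANT,
)
from .simulate import TrialDataset
from .survival import KMCurve, LogRankResult, coxph, km_estimate, logrank_test

logger = logging.getLogger(__name__)

__all__ = [
    "LearnResult",
    "ValidationReport",
    "run_learning",
    "run_validation",
    "compare_classifications",
    "GROUPINGS",
]

#: marker design column -> raw score column
_MARKER_RAW = {"ercc1_std": "ercc1_score", "rrm1_std": "rrm1_score"}

GROUPINGS = ("control-arm", "pooled-gc", "carboplatin-high")

_CARBOPLATIN_REGIMENS = ("GC", "DC")
_NON_CARBOPLATIN_REGIMENS = ("GD", "DV")


def _as_frame(data) -> pd.DataFrame:
    return data.records if isinstance(data, TrialDataset) else data


def _standardize_cohort(df: pd.DataFrame, mad_constant: float):
    """Per-cohort log2 + median/MAD standardization of both marker columns."""
    out = df.copy()
    params = {}
    for std_col, raw_col in _MARKER_RAW.items():
        logged = log2_transform(out[raw_col].to_numpy(float))
        p = fit_standardization(logged, mad_constant=mad_constant)
        out[std_col] = apply_standardization(logged, p)
        params[std_col] = p
    return out, params


@dataclass
class LearnResult:
    """Everything the validation stage is allowed to see."""

    threshold: MarkerThreshold
    marker: str  # standardized design column, e.g. "ercc1_std"
    marker_selected: bool  # False if no interaction crossed the evidence bar
    standardization: dict  # std column -> StandardizationParams (learning cohort)
    mad_constant: float
    model: SelectedModel | None
    provenance: dict = field(default_factory=dict)

    @property
    def raw_marker_column(self) -> str:
        return _MARKER_RAW[self.marker]

    def to_dict(self) -> dict:
        return {
            "threshold": {"cutoff_std": self.threshold.cutoff_std, "boundary_rule": self.threshold.boundary_rule},
            "marker": self.marker,
            "marker_selected": self.marker_selected,
            "standardization": {
                k: {"center": p.center, "scale": p.scale, "mad_constant": p.mad_constant}
                for k, p in self.standardization.items()
            },
            "mad_constant": self.mad_constant,
            "model": self.model.to_dict() if self.model else None,
            "provenance": self.provenance,
        }

    def to_json(self, indent: int | None = None) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True)

    @classmethod
    def from_json(cls, s: str) -> "LearnResult":
        d = json.loads(s)
        return cls(
            threshold=MarkerThreshold(**d["threshold"]),
            marker=d["marker"],
            marker_selected=d["marker_selected"],
            standardization={k: StandardizationParams(**v) for k, v in d["standardization"].items()},
            mad_constant=d["mad_constant"],
            model=None,  # the fitted model object is not needed downstream
            provenance=d.get("provenance", {}),
        )


def run_learning(
    data,
    candidates: CandidateSet | None = None,
    config: ModelSelectionConfig | None = None,
    mad_constant: float = NORMAL_MAD_CONSTANT,
) -> LearnResult:
    """Learn the operational threshold on one cohort.

    Stage-IV filter -> log2 -> per-cohort standardization -> screen/build
    model selection -> weighted-median cut-off of the selected marker's
    posterior. If no marker interaction crosses the evidence bar, the
    threshold is taken from the top-ranked marker's posterior and
    ``marker_selected`` is False, so callers can distinguish a validated
    predictive marker from a fallback split.
    """
    t0 = _time.perf_counter()
    df = _as_frame(data)
    if df["arm"].nunique() < 2:
        raise DegenerateDataError("learning cohort must contain both treatment arms")
    if int(df["event"].sum()) < 10:
        raise DegenerateDataError("learning cohort must contain at least 10 events")
    candidates = candidates or CandidateSet()
    config = config or ModelSelectionConfig()

    try:
        df = filter_stage_iv(df)
        df, params = _standardize_cohort(df, mad_constant)
        model = select_model(df, candidates, config)
        if model.interaction_marker is not None:
            marker, cutoff, selected = model.interaction_marker, model.cutoff, True
        else:
            marker = candidates.markers[0]
            post = cutpoint_posterior(df, marker, model.main_effects, config)
            cutoff, selected = extract_cutoff(post), False
    except CutpointSurvError as exc:
        raise type(exc)(f"[learning] {exc}") from exc

    logger.info("run_learning: %.2fs, marker=%s cutoff=%.4f selected=%s",
                _time.perf_counter() - t0, marker, cutoff, selected)
    return LearnResult(
        threshold=MarkerThreshold(cutoff_std=float(cutoff)),
        marker=marker,
        marker_selected=selected,
        standardization=params,
        mad_constant=mad_constant,
        model=model,
        provenance={
            "n_stage_iv": int(len(df)),
            "n_events": int(df["event"].sum()),
            "candidates": {"markers": candidates.markers, "covariates": candidates.covariates},
        },
    )


@dataclass
class GroupResult:
    label: str
    n: int
    n_events: int
    km: KMCurve | None

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "n": self.n,
            "n_events": self.n_events,
            "km": self.km.summary() if self.km else None,
        }


@dataclass
class ValidationReport:
    """Threshold-stratified analysis of an independent cohort."""

    grouping: str
    threshold: MarkerThreshold
    marker: str
    n_cohort: int  # after stage filtering
    n_high: int
    n_low: int
    groups: list[GroupResult]
    logrank: LogRankResult | None
    cox: dict | None  # CoxFit.to_dict() of the adjusted model
    cox_contrast_term: str | None
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "grouping": self.grouping,
            "threshold_std": self.threshold.cutoff_std,
            "marker": self.marker,
            "n_cohort": self.n_cohort,
            "n_high": self.n_high,
            "n_low": self.n_low,
            "groups": [g.to_dict() for g in self.groups],
            "logrank": None if self.logrank is None else {
                "statistic": self.logrank.statistic, "df": self.logrank.df, "p_value": self.logrank.p_value
            },
            "cox": self.cox,
            "cox_contrast_term": self.cox_contrast_term,
            "notes": self.notes,
        }

    def to_json(self, indent: int | None = None) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True)

    def to_markdown(self) -> str:
        lines = [f"# Validation report — {self.grouping}", ""]
        lines.append(f"Threshold (standardized): {self.threshold.cutoff_std:.4f} on `{self.marker}`")
        lines.append(f"Cohort n = {self.n_cohort} (high {self.n_high}, low {self.n_low})")
        lines.append("")
        lines.append("| group | n | events | median OS | 95% CI |")
        lines.append("|---|---|---|---|---|")
        for g in self.groups:
            if g.km is None:
                lines.append(f"| {g.label} | {g.n} | {g.n_events} | — | — |")
                continue
            med = "NA" if g.km.median is None else f"{g.km.median:.1f}"
            lo, hi = g.km.median_ci
            ci = f"{'NA' if lo is None else f'{lo:.1f}'} to {'NA' if hi is None else f'{hi:.1f}'}"
            lines.append(f"| {g.label} | {g.n} | {g.n_events} | {med} | {ci} |")
        lines.append("")
        if self.logrank is not None:
            lines.append(f"Log-rank: chi2 = {self.logrank.statistic:.3f}, p = {self.logrank.p_value:.4g}")
        if self.cox is not None:
            i = self.cox["terms"].index(self.cox_contrast_term)
            lines.append(
                f"Adjusted Cox ({self.cox_contrast_term}): HR = {self.cox['hazard_ratios'][i]:.3f} "
                f"(95% CI {self.cox['ci_95_lower'][i]:.3f} to {self.cox['ci_95_upper'][i]:.3f}; "
                f"p = {self.cox['p_values'][i]:.4g})"
            )
        for note in self.notes:
            lines.append(f"_Note: {note}_")
        return "\n".join(lines) + "\n"


def _grouping_frame(df: pd.DataFrame, grouping: str, labels: np.ndarray):
    """Subset + binary group labels for the requested contrast."""
    if grouping == "control-arm":
        mask = (df["arm"] == "control").to_numpy()
        glab = labels[mask]
        contrast = "low_marker"
        indicator = (glab == "low").astype(float)
    elif grouping == "pooled-gc":
        mask = (df["regimen"] == "GC").to_numpy()
        glab = labels[mask]
        contrast = "low_marker"
        indicator = (glab == "low").astype(float)
    elif grouping == "carboplatin-high":
        mask = (labels == "high") & df["regimen"].isin(_CARBOPLATIN_REGIMENS + _NON_CARBOPLATIN_REGIMENS).to_numpy()
        reg = df.loc[mask, "regimen"]
        glab = np.where(reg.isin(_CARBOPLATIN_REGIMENS), "carboplatin", "non-carboplatin")
        contrast = "carboplatin"
        indicator = (glab == "carboplatin").astype(float)
    else:
        raise ValueError(f"unknown grouping {grouping!r}; choose from {GROUPINGS}")
    return mask, np.asarray(glab), contrast, indicator


def run_validation(data, learn_result: LearnResult, grouping: str = "pooled-gc") -> ValidationReport:
    """Apply a frozen threshold to an independent cohort and test it.

    Stage-IV filter -> log2 -> *validation-cohort* standardization ->
    classify by the frozen threshold -> per-group Kaplan-Meier with median
    OS and CI, log-rank test, and a Cox model for the contrast adjusted
    for age, sex and histology. Contrasts the data cannot support (an
    empty group, or a stratum with no events) are reported as undefined
    rather than raising.
    """
    t0 = _time.perf_counter()
    df = filter_stage_iv(_as_frame(data))
    df, _ = _standardize_cohort(df, learn_result.mad_constant)
    labels = classify_marker(df[learn_result.marker].to_numpy(float), learn_result.threshold)
    n_high = int((labels == "high").sum())
    n_low = int((labels == "low").sum())

    mask, glab, contrast, indicator = _grouping_frame(df, grouping, labels)
    sub = df.loc[mask].reset_index(drop=True)
    notes: list[str] = []
    groups: list[GroupResult] = []
    for lev in sorted(set(glab.tolist())):
        m = glab == lev
        km = None
        if m.sum() > 0:
            km = km_estimate(sub.loc[m, "os_months"], sub.loc[m, "event"])
        groups.append(GroupResult(label=str(lev), n=int(m.sum()), n_events=int(sub.loc[m, "event"].sum()), km=km))

    logrank = None
    cox = None
    levels = sorted(set(glab.tolist()))
    if len(levels) != 2 or any(g.n_events == 0 for g in groups):
        notes.append("contrast undefined: a stratum is empty or has no events")
    else:
        try:
            logrank = logrank_test(sub["os_months"], sub["event"], glab)
            Z, znames = encode_covariates(sub, ["age", "sex", "histology"])
            X = np.column_stack([indicator, Z])
            fit = coxph(X, sub["os_months"].to_numpy(float), sub["event"].to_numpy(int),
                        names=[contrast, *znames])
            cox = fit.to_dict()
        except CutpointSurvError as exc:
            notes.append(f"contrast undefined: {exc}")
            logrank, cox = None, None

    logger.info("run_validation[%s]: %.2fs", grouping, _time.perf_counter() - t0)
    return ValidationReport(
        grouping=grouping,
        threshold=learn_result.threshold,
        marker=learn_result.marker,
        n_cohort=int(len(df)),
        n_high=n_high,
        n_low=n_low,
        groups=groups,
        logrank=logrank,
        cox=cox,
        cox_contrast_term=contrast if cox is not None else None,
        notes=notes,
    )


@dataclass
class ClassificationComparison:
    """Agreement between two high/low labelings of the same patients."""

    table: dict  # {"high_high": .., "high_low": .., "low_high": .., "low_low": ..}
    n_discordant_01: int  # a low, b high
    n_discordant_10: int  # a high, b low
    mcnemar: TestResult

    def to_dict(self) -> dict:
        return {
            "table": self.table,
            "n_discordant_01": self.n_discordant_01,
            "n_discordant_10": self.n_discordant_10,
            "mcnemar_p": self.mcnemar.p_value,
        }


def compare_classifications(labels_a, labels_b) -> ClassificationComparison:
    """2x2 agreement table + exact McNemar test for paired classifications."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError(f"label vectors differ in length: {a.shape} vs {b.shape}")
    hh = int(((a == "high") & (b == "high")).sum())
    hl = int(((a == "high") & (b == "low")).sum())
    lh = int(((a == "low") & (b == "high")).sum())
    ll = int(((a == "low") & (b == "low")).sum())
    return ClassificationComparison(
        table={"high_high": hh, "high_low": hl, "low_high": lh, "low_low": ll},
        n_discordant_01=lh,
        n_discordant_10=hl,
        mcnemar=mcnemar_exact(lh, hl),
    )
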