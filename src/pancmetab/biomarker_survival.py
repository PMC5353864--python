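"""Single-metabolite survival biomarker evaluation.

ROC analysis with the Youden-optimal threshold (sensitivity, specificity,
predictive values at the sample prevalence), Kaplan-Meier curves for the
strata defined by that threshold, and the two-group log-rank test.  The
motivating use case is tissue ethanolamine in resected pancreatic
adenocarcinoma: a high concentration marks short-term survivors, so the
positive class of the ROC is the short-term survivor and the classification
direction is "high value = positive".

AUC equals the Mann-Whitney pair-count statistic U1/(n1*n2) with ties
counted half (the trapezoidal ROC integral makes this exact); the AUC
standard error uses the Hanley-McNeil formula.
"""
from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _lifelines_logrank

from .assignments_io import SampleMetadata

log = logging.getLogger(__name__)

DIRECTIONS = ("high_positive", "low_positive")


@dataclass
class RocResult:
    thresholds: np.ndarray  # observed-value scale, one per sweep point
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    auc_se: float
    direction: str
    n_pos: int
    n_neg: int
    tp: np.ndarray = field(repr=False, default=None)
    fp: np.ndarray = field(repr=False, default=None)


@dataclass(frozen=True)
class ThresholdReport:
    threshold: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    youden_j: float


@dataclass
class KmCurve:
    timeline: np.ndarray  # starts at 0
    survival: np.ndarray  # step values, non-increasing from 1
    event_times: np.ndarray
    n_at_risk: np.ndarray  # at each event time
    censor_times: np.ndarray

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.timeline, t, side="right") - 1
        return float(self.survival[max(idx, 0)])


def roc_curve(values, labels, direction: str = "high_positive") -> RocResult:
    """Threshold sweep over the distinct observed values.

    ``labels`` are truthy for the positive class.  ``direction`` states
    whether high or low values predict the positive class; for
    ``low_positive`` the sweep runs over ascending values.  Endpoints (0,0)
    and (1,1) are always present; AUC is the trapezoidal integral.
    """
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {DIRECTIONS}")
    values = np.asarray(values, dtype=float)
    y = np.asarray(labels).astype(bool)
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")

    score = values if direction == "high_positive" else -values
    # sweep: predict positive when score >= cutoff, cutoffs descending
    cuts = np.unique(score)[::-1]
    tp = np.array([(y & (score >= c)).sum() for c in cuts])
    fp = np.array([(~y & (score >= c)).sum() for c in cuts])
    tp = np.concatenate(([0], tp))
    fp = np.concatenate(([0], fp))
    thresholds = np.concatenate(([np.inf], cuts))
    if direction == "low_positive":
        thresholds = -thresholds
    tpr = tp / n_pos
    fpr = fp / n_neg
    auc = float(np.trapezoid(tpr, fpr))
    # Hanley-McNeil standard error
    q1 = auc / (2 - auc)
    q2 = 2 * auc**2 / (1 + auc)
    var = (
        auc * (1 - auc)
        + (n_pos - 1) * (q1 - auc**2)
        + (n_neg - 1) * (q2 - auc**2)
    ) / (n_pos * n_neg)
    return RocResult(
        thresholds=thresholds, tpr=tpr, fpr=fpr, auc=auc,
        auc_se=float(np.sqrt(max(var, 0.0))), direction=direction,
        n_pos=n_pos, n_neg=n_neg, tp=tp, fp=fp,
    )


def youden_threshold(roc: RocResult, values=None) -> ThresholdReport:
    """Threshold maximizing J = sensitivity + specificity - 1.

    Ties go to the point with higher specificity.  The reported threshold is
    the midpoint between the adjacent distinct observed values spanning the
    chosen cut (when ``values`` is provided), so that classification is
    stable under small perturbations.
    """
    j = roc.tpr - roc.fpr
    # ties -> higher specificity (lower fpr); sweep order has fpr ascending
    best = int(np.lexsort((roc.fpr, -j))[0])
    sens = float(roc.tpr[best])
    spec = float(1 - roc.fpr[best])
    tp = int(roc.tp[best])
    fp = int(roc.fp[best])
    fn = roc.n_pos - tp
    tn = roc.n_neg - fp
    ppv = tp / (tp + fp) if tp + fp else 0.0
    npv = tn / (tn + fn) if tn + fn else 0.0

    thr = float(roc.thresholds[best])
    if values is not None and np.isfinite(thr):
        distinct = np.unique(np.asarray(values, dtype=float))
        i = int(np.searchsorted(distinct, thr))
        if roc.direction == "high_positive":
            # cut lies between distinct[i-1] and distinct[i] == thr
            if i > 0:
                thr = float((distinct[i - 1] + distinct[i]) / 2)
        else:
            # positive side is values <= thr; cut between thr and next value
            if i + 1 < len(distinct):
                thr = float((distinct[i] + distinct[i + 1]) / 2)
    return ThresholdReport(
        threshold=thr, sensitivity=sens, specificity=spec,
        ppv=ppv, npv=npv, youden_j=sens + spec - 1.0,
    )


def kaplan_meier(times, events) -> KmCurve:
    """Product-limit survival estimate (right censoring, standard at-risk
    convention for censoring at an event time)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(bool)
    if np.any(times < 0):
        raise ValueError("negative survival time")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    timeline = kmf.survival_function_.index.to_numpy(dtype=float)
    survival = kmf.survival_function_["KM_estimate"].to_numpy(dtype=float)
    table = kmf.event_table
    event_rows = table[table["observed"] > 0]
    return KmCurve(
        timeline=timeline,
        survival=survival,
        event_times=event_rows.index.to_numpy(dtype=float),
        n_at_risk=event_rows["at_risk"].to_numpy(dtype=int),
        censor_times=np.sort(times[~events]),
    )


def log_rank_test(times_a, events_a, times_b, events_b) -> dict:
    """Two-group log-rank chi-square (1 df) with hypergeometric variance."""
    times_a = np.asarray(times_a, dtype=float)
    times_b = np.asarray(times_b, dtype=float)
    events_a = np.asarray(events_a).astype(bool)
    events_b = np.asarray(events_b).astype(bool)
    if times_a.size == 0 or times_b.size == 0:
        raise ValueError("both groups must be non-empty")
    if not events_a.any() and not events_b.any():
        warnings.warn("no events in either group; log-rank undefined, p = 1")
        return {"chi2": 0.0, "p": 1.0}
    res = _lifelines_logrank(times_a, times_b, events_a, events_b)
    return {"chi2": float(res.test_statistic), "p": float(res.p_value)}


@dataclass
class BiomarkerReport:
    metabolite: str
    roc: RocResult
    threshold: ThresholdReport
    km_low: KmCurve | None
    km_high: KmCurve | None
    logrank: dict | None
    n_low: int
    n_high: int
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "metabolite": self.metabolite,
            "auc": self.roc.auc,
            "auc_se": self.roc.auc_se,
            "direction": self.roc.direction,
            "threshold": self.threshold.threshold,
            "sensitivity": self.threshold.sensitivity,
            "specificity": self.threshold.specificity,
            "ppv": self.threshold.ppv,
            "npv": self.threshold.npv,
            "youden_j": self.threshold.youden_j,
            "n_low": self.n_low,
            "n_high": self.n_high,
            "logrank_chi2": self.logrank["chi2"] if self.logrank else None,
            "logrank_p": self.logrank["p"] if self.logrank else None,
            "warnings": self.warnings,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    def roc_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "threshold": self.roc.thresholds,
            "tpr": self.roc.tpr,
            "fpr": self.roc.fpr,
        })


def evaluate_biomarker(
    quant: pd.DataFrame,
    meta: Sequence[SampleMetadata],
    metabolite: str = "ethanolamine",
    direction: str = "high_positive",
) -> BiomarkerReport:
    """Full single-metabolite evaluation on the labelled survivor samples.

    Positive class: short-term survivor (with the default direction, a high
    concentration predicts short-term survival).  Strata for the
    Kaplan-Meier comparison are low/high concentration relative to the
    Youden threshold.
    """
    if metabolite not in quant.columns:
        raise KeyError(
            f"metabolite {metabolite!r} not quantified; available: "
            f"{list(quant.columns)}"
        )
    labelled = [
        m for m in meta
        if m.survival_group in ("long", "short") and m.sample_id in quant.index
    ]
    if not labelled:
        raise ValueError("no samples with a long/short survivor label")
    values = quant.loc[[m.sample_id for m in labelled], metabolite].to_numpy(float)
    y_pos = np.array([m.survival_group == "short" for m in labelled])

    roc = roc_curve(values, y_pos, direction=direction)
    thr = youden_threshold(roc, values=values)

    notes: list[str] = []
    with_surv = [
        (m, v) for m, v in zip(labelled, values)
        if m.survival_time_months is not None and m.event is not None
    ]
    km_low = km_high = None
    logrank = None
    n_low = n_high = 0
    if with_surv:
        low = [(m, v) for m, v in with_surv if v < thr.threshold]
        high = [(m, v) for m, v in with_surv if v >= thr.threshold]
        n_low, n_high = len(low), len(high)
        if low:
            km_low = kaplan_meier(
                [m.survival_time_months for m, _ in low],
                [m.event for m, _ in low],
            )
        if high:
            km_high = kaplan_meier(
                [m.survival_time_months for m, _ in high],
                [m.event for m, _ in high],
            )
        if n_low >= 2 and n_high >= 2:
            logrank = log_rank_test(
                [m.survival_time_months for m, _ in low],
                [m.event for m, _ in low],
                [m.survival_time_months for m, _ in high],
                [m.event for m, _ in high],
            )
        else:
            notes.append("a stratum has < 2 samples; log-rank not computed")
            log.warning("degenerate stratum (n_low=%d, n_high=%d)", n_low, n_high)
    else:
        notes.append("no survival times available; Kaplan-Meier skipped")
    return BiomarkerReport(
        metabolite=metabolite, roc=roc, threshold=thr,
        km_low=km_low, km_high=km_high, logrank=logrank,
        n_low=n_low, n_high=n_high, warnings=notes,
    )
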