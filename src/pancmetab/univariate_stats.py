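"""Two-group metabolite comparisons (mean +/- SD, Mann-Whitney U).

Mirrors the structure of the published group-comparison tables: for every
quantified metabolite, group means and SDs to 4 decimals and a two-sided
Mann-Whitney U test.  The exact null distribution is used for small
tie-free comparisons (combined n <= 20, which covers the study's smallest
9-vs-8 contrasts); otherwise the normal approximation with tie and
continuity corrections.  No multiple-testing correction is applied, and the
output says so explicitly.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .assignments_io import SampleMetadata

EXACT_LIMIT = 20  # combined sample size up to which the exact null is used

GROUPINGS = ("tissue", "chemo_within_PP", "chemo_within_PA", "survival")


@dataclass(frozen=True)
class TestResult:
    metabolite: str
    group_means: dict  # label -> (mean, sd)
    group_n: dict  # label -> n
    u_statistic: float
    p_value: float
    method: str  # exact | normal_approx
    significant: bool


def mann_whitney_u(a: Sequence[float], b: Sequence[float]) -> tuple[float, float, str]:
    """Two-sided Mann-Whitney U; returns (min(U1, U2), p, method)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    if a.size + b.size <= EXACT_LIMIT and not has_ties:
        method = "exact"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    else:
        method = "normal_approx"
        res = stats.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=True
        )
    u1 = float(res.statistic)
    u = min(u1, a.size * b.size - u1)
    return u, float(min(res.pvalue, 1.0)), method


def _split(meta: Sequence[SampleMetadata], grouping: str):
    """Return (label_a, ids_a, label_b, ids_b) for a named contrast."""
    if grouping == "tissue":
        a = [m.sample_id for m in meta if m.tissue == "PP" and not m.neoadjuvant_chemo]
        b = [m.sample_id for m in meta if m.tissue == "PA" and not m.neoadjuvant_chemo]
        return "PP", a, "PA", b
    if grouping == "chemo_within_PP":
        a = [m.sample_id for m in meta if m.tissue == "PP" and not m.neoadjuvant_chemo]
        b = [m.sample_id for m in meta if m.tissue == "PP" and m.neoadjuvant_chemo]
        return "no_chemo", a, "chemo", b
    if grouping == "chemo_within_PA":
        a = [m.sample_id for m in meta if m.tissue == "PA" and not m.neoadjuvant_chemo]
        b = [m.sample_id for m in meta if m.tissue == "PA" and m.neoadjuvant_chemo]
        return "no_chemo", a, "chemo", b
    if grouping == "survival":
        a = [m.sample_id for m in meta if m.survival_group == "long"]
        b = [m.sample_id for m in meta if m.survival_group == "short"]
        return "long", a, "short", b
    raise ValueError(f"unknown grouping {grouping!r}; choose from {GROUPINGS}")


def compare_groups(
    quant: pd.DataFrame,
    meta: Sequence[SampleMetadata],
    grouping: str = "tissue",
    alpha: float = 0.05,
) -> list[TestResult]:
    """One TestResult per quantified metabolite for a named two-group contrast."""
    label_a, ids_a, label_b, ids_b = _split(meta, grouping)
    ids_a = [i for i in ids_a if i in quant.index]
    ids_b = [i for i in ids_b if i in quant.index]
    if not ids_a or not ids_b:
        raise ValueError(f"grouping {grouping!r} yields an empty group")
    if min(len(ids_a), len(ids_b)) < 2:
        import warnings

        warnings.warn(f"grouping {grouping!r}: a group has < 2 samples")
    results = []
    for met in quant.columns:
        va = quant.loc[ids_a, met].to_numpy(dtype=float)
        vb = quant.loc[ids_b, met].to_numpy(dtype=float)
        u, p, method = mann_whitney_u(va, vb)
        results.append(TestResult(
            metabolite=met,
            group_means={
                label_a: (round(float(va.mean()), 4), round(float(va.std(ddof=1)), 4)),
                label_b: (round(float(vb.mean()), 4), round(float(vb.std(ddof=1)), 4)),
            },
            group_n={label_a: len(va), label_b: len(vb)},
            u_statistic=u,
            p_value=p,
            method=method,
            significant=p < alpha,
        ))
    return results


def results_to_frame(results: Sequence[TestResult]) -> pd.DataFrame:
    """Long-format table mirroring the published layout (one row per
    metabolite and group, 4-decimal means, uncorrected p-values)."""
    rows = []
    for r in results:
        for label, (mean, sd) in r.group_means.items():
            rows.append({
                "metabolite": r.metabolite,
                "group": label,
                "n": r.group_n[label],
                "mean": f"{mean:.4f}",
                "sd": f"{sd:.4f}",
                "u_statistic": r.u_statistic,
                "p_value": r.p_value,
                "method": r.method,
                "significant": r.significant,
                "correction": "uncorrected",
            })
    return pd.DataFrame(rows)
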