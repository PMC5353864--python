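"""Synthetic cohorts: metabolite concentrations, survival outcomes, spectra.

The generator emulates the study conditions of the tissue cohorts: two-class
tissue comparisons (healthy parenchyma vs adenocarcinoma), chemotherapy
subgroups, and long- vs short-term survivor groups, with per-group metabolite
concentration distributions taken from the packaged design files (printed
group means and SDs, in nmol/mg).  Concentrations are drawn from
zero-truncated Gaussians (the tables report arithmetic mean and SD; clamping
at zero would pile mass on the boundary, so the truncated density is sampled
exactly instead).  Spectra are rendered as sums of Lorentzian lines at the
assigned chemical shifts, with peak area proportional to molar amount times
proton count, plus an optional smooth baseline and Gaussian noise.
"""
from __future__ import annotations

import io
import re
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .assignments_io import (
    AssignmentTable,
    SampleMetadata,
    Spectrum1D,
    load_assignments,
)

BUILTIN_DESIGNS = ("table2", "table3", "table4", "table5")

#: anomeric equilibrium used to split a total glucose amount over the two
#: designated anomer peaks (approx. aqueous alpha:beta ratio)
ALPHA_GLUCOSE_FRACTION = 0.36

#: tissue amounts analyzed ranged over 15-20 mg; weights are drawn uniformly
WEIGHT_RANGE_MG = (15.0, 20.0)


@dataclass(frozen=True)
class GroupSpec:
    """One cohort group: sample count plus per-metabolite (mean, sd)."""

    label: str
    n: int
    stats: dict[str, tuple[float, float]]
    tissue: str = "PA"
    neoadjuvant_chemo: bool = False
    survival_group: str = "unknown"

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"group {self.label}: n must be >= 2")
        for met, (mean, sd) in self.stats.items():
            if mean < 0 or sd < 0:
                raise ValueError(f"group {self.label}, {met}: negative mean or sd")


@dataclass(frozen=True)
class CohortDesign:
    groups: tuple[GroupSpec, ...]
    #: optional within-pathway correlation (Gaussian copula), default independent
    correlation: float = 0.0
    #: metabolite blocks sharing the correlation; ignored when correlation == 0
    pathway_blocks: tuple[tuple[str, ...], ...] = ()

    def __post_init__(self) -> None:
        if not (0.0 <= self.correlation < 1.0):
            raise ValueError("correlation must be in [0, 1)")
        if not self.groups:
            raise ValueError("design needs at least one group")

    @property
    def metabolites(self) -> tuple[str, ...]:
        return tuple(self.groups[0].stats)


@dataclass(frozen=True)
class SpectrumSynthParams:
    """Rendering parameters for synthetic 1D spectra.

    ``linewidth`` is the Lorentzian half-width at half-maximum in ppm; the
    default is narrow enough that the closest pair of designated
    quantification peaks (0.02 ppm apart) remain resolvable in their
    integration windows.  ``response_factor`` converts nmol x proton into
    integrated intensity area (the same factor applies to the external
    reference scan, which is what makes the quantification self-consistent).
    """

    linewidth: float = 1e-3
    noise_sd: float = 0.0
    baseline_amplitude: float = 0.0
    points: int = 262144
    ppm_range: tuple[float, float] = (0.20, 8.00)
    response_factor: float = 1.0
    #: render only the designated quantification peaks (True) or every
    #: assigned resonance group (False; more realistic, more overlap)
    quantify_peaks_only: bool = True

    def __post_init__(self) -> None:
        if self.linewidth <= 0:
            raise ValueError("linewidth must be > 0")
        if self.points < 2:
            raise ValueError("points must be >= 2")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.ppm_range[0] >= self.ppm_range[1]:
            raise ValueError("ppm_range must be (lo, hi) with lo < hi")


@dataclass(frozen=True)
class SurvivalSimParams:
    """Exponential survival model per survivor group.

    ``scale`` is the exponential mean in months.  Observation times of
    labelled groups are truncated to the window that defines the label
    (long: > 36 months, short: < 12 months), since in the emulated study the
    labels are assigned from the observed outcome; ``unknown`` samples get
    the untruncated exponential.  Events are Bernoulli(1 - censor_rate).
    """

    groups: dict[str, tuple[float, float]] = field(default_factory=lambda: {
        "long": (60.0, 0.1),
        "short": (8.0, 0.1),
        "unknown": (24.0, 0.1),
    })

    def __post_init__(self) -> None:
        for label, (scale, censor_rate) in self.groups.items():
            if scale <= 0:
                raise ValueError(f"{label}: scale must be > 0")
            if not (0.0 <= censor_rate < 1.0):
                raise ValueError(f"{label}: censor_rate must be in [0, 1)")


# ---------------------------------------------------------------------------
# designs
# ---------------------------------------------------------------------------

_GROUP_RE = re.compile(
    r"^#\s*group\s+(\S+):\s*n=(\d+)\s+tissue=(\S+)\s+chemo=(\S+)\s+survival=(\S+)"
)


def load_design(name_or_path: str | Path) -> CohortDesign:
    """Load a packaged design (``table2`` ... ``table5``) or a design CSV."""
    if str(name_or_path) in BUILTIN_DESIGNS:
        text = resources.files("pancmetab.data").joinpath(
            f"design_{name_or_path}.csv"
        ).read_text()
    else:
        text = Path(name_or_path).read_text()
    return parse_design(text)


def parse_design(text: str) -> CohortDesign:
    lines = text.splitlines()
    headers: list[tuple[str, int, str, bool, str]] = []
    for line in lines:
        m = _GROUP_RE.match(line)
        if m:
            label, n, tissue, chemo, survival = m.groups()
            headers.append((label, int(n), tissue, chemo == "yes", survival))
    if not headers:
        raise ValueError("design file declares no '# group ...' headers")
    body = "\n".join(l for l in lines if not l.startswith("#"))
    df = pd.read_csv(io.StringIO(body))
    groups = []
    for label, n, tissue, chemo, survival in headers:
        stats = {
            row["metabolite"]: (float(row[f"{label}_mean"]), float(row[f"{label}_sd"]))
            for _, row in df.iterrows()
        }
        groups.append(GroupSpec(
            label=label, n=n, stats=stats, tissue=tissue,
            neoadjuvant_chemo=chemo, survival_group=survival,
        ))
    return CohortDesign(groups=tuple(groups))


# ---------------------------------------------------------------------------
# concentrations
# ---------------------------------------------------------------------------

def _truncated_normal_from_z(z: np.ndarray, mean: float, sd: float) -> np.ndarray:
    """Map standard-normal draws to a zero-truncated Gaussian via the
    probability transform (exact truncated density; smooth at zero)."""
    if sd == 0:
        return np.full_like(z, mean)
    a = (0.0 - mean) / sd
    u = stats.norm.cdf(z)
    # clip away exact 0/1 to keep ppf finite
    u = np.clip(u, 1e-15, 1 - 1e-15)
    return stats.truncnorm.ppf(u, a=a, b=np.inf, loc=mean, scale=sd)


def simulate_concentrations(
    design: CohortDesign,
    seed: int,
    assignments: AssignmentTable | None = None,
) -> tuple[pd.DataFrame, list[SampleMetadata]]:
    """Draw a cohort's concentration table (samples x metabolites, nmol/mg).

    Column order follows the assignment table's quantified metabolites where
    the design covers them.  Tissue weights are drawn uniformly on the
    15-20 mg analytic range.  Reproducible given ``seed``.
    """
    if assignments is None:
        assignments = load_assignments()
    order = [m for m in assignments.quantified_metabolites if m in design.metabolites]
    extra = [m for m in design.metabolites if m not in order]
    columns = order + extra

    rng = np.random.default_rng(seed)
    block_of: dict[str, int] = {}
    for bi, block in enumerate(design.pathway_blocks):
        for met in block:
            block_of.setdefault(met, bi)

    rows: list[np.ndarray] = []
    meta: list[SampleMetadata] = []
    for group in design.groups:
        z = rng.standard_normal((group.n, len(columns)))
        if design.correlation > 0:
            # Gaussian copula: shared factor per pathway block
            rho = design.correlation
            shared: dict[int, np.ndarray] = {}
            for j, met in enumerate(columns):
                bi = block_of.get(met)
                if bi is None:
                    continue
                if bi not in shared:
                    shared[bi] = rng.standard_normal(group.n)
                z[:, j] = np.sqrt(rho) * shared[bi] + np.sqrt(1 - rho) * z[:, j]
        values = np.empty_like(z)
        for j, met in enumerate(columns):
            mean, sd = group.stats[met]
            values[:, j] = _truncated_normal_from_z(z[:, j], mean, sd)
        rows.append(values)
        weights = rng.uniform(*WEIGHT_RANGE_MG, size=group.n)
        for i in range(group.n):
            meta.append(SampleMetadata(
                sample_id=f"{group.label}-{i + 1:03d}",
                tissue=group.tissue,
                neoadjuvant_chemo=group.neoadjuvant_chemo,
                survival_group=group.survival_group,
                weight_mg=float(weights[i]),
            ))
    quant = pd.DataFrame(
        np.vstack(rows), index=[m.sample_id for m in meta], columns=columns
    )
    quant.index.name = "sample_id"
    return quant, meta


# ---------------------------------------------------------------------------
# spectra
# ---------------------------------------------------------------------------

def _lorentzian(ppm: np.ndarray, center: float, hwhm: float, area: float) -> np.ndarray:
    return area * (hwhm / np.pi) / ((ppm - center) ** 2 + hwhm**2)


def _render_groups(quants, weight_mg, assignments, params):
    lo, hi = params.ppm_range
    ppm = np.linspace(hi, lo, params.points)
    intensity = np.zeros_like(ppm)
    for met, conc in quants.items():
        groups = assignments.groups_for(met)
        if not groups:
            raise ValueError(f"metabolite {met!r} has no assigned resonance group")
        if params.quantify_peaks_only:
            groups = [g for g in groups if g.quantify]
            if not groups:
                raise ValueError(f"metabolite {met!r} has no quantification peak")
        nmol = conc * weight_mg
        for g in groups:
            if g.quantify and not (lo < g.shift_1h < hi):
                raise ValueError(
                    f"ppm_range {params.ppm_range} does not cover the "
                    f"{met} quantification peak at {g.shift_1h} ppm"
                )
            frac = 1.0
            if met == "glucose":
                frac = (
                    ALPHA_GLUCOSE_FRACTION
                    if g.metabolite_name.startswith("alpha")
                    else 1.0 - ALPHA_GLUCOSE_FRACTION
                )
            area = params.response_factor * nmol * frac * g.n_protons
            if area:
                intensity += _lorentzian(ppm, g.shift_1h, params.linewidth, area)
    return ppm, intensity


def synthesize_spectrum(
    quants: Mapping[str, float],
    weight_mg: float,
    assignments: AssignmentTable,
    params: SpectrumSynthParams = SpectrumSynthParams(),
    seed: int = 0,
    sample_id: str = "synthetic",
) -> Spectrum1D:
    """Render one spectrum from a concentration record (nmol/mg).

    Each resonance group contributes a Lorentzian of integrated area
    ``response_factor x nmol x n_protons`` (glucose split over its two anomer
    peaks); a smooth Gaussian-hump baseline and white noise are optional.
    Noiseless, baseline-free rendering is linear in the concentrations.
    """
    ppm, intensity = _render_groups(quants, weight_mg, assignments, params)
    if params.baseline_amplitude:
        intensity = intensity + params.baseline_amplitude * np.exp(
            -((ppm - 4.0) ** 2) / 8.0
        )
    if params.noise_sd:
        rng = np.random.default_rng(seed)
        intensity = intensity + rng.normal(0.0, params.noise_sd, size=ppm.size)
    return Spectrum1D(
        ppm=ppm,
        intensity=intensity,
        sample_id=sample_id,
        weight_mg=weight_mg,
        meta={"synthetic": True, "linewidth_ppm": params.linewidth},
    )


def synthesize_reference_scan(
    params: SpectrumSynthParams = SpectrumSynthParams(),
    amount_nmol: float = 3000.0,
    assignments: AssignmentTable | None = None,
    seed: int = 0,
) -> Spectrum1D:
    """External lactate reference (3 umol by default), same response factor
    and rendering conditions as the tissue scans."""
    if assignments is None:
        assignments = load_assignments()
    lo, hi = params.ppm_range
    ppm = np.linspace(hi, lo, params.points)
    intensity = np.zeros_like(ppm)
    for g in assignments.groups_for("lactate"):
        area = params.response_factor * amount_nmol * g.n_protons
        intensity += _lorentzian(ppm, g.shift_1h, params.linewidth, area)
    if params.noise_sd:
        rng = np.random.default_rng(seed)
        intensity = intensity + rng.normal(0.0, params.noise_sd, size=ppm.size)
    return Spectrum1D(
        ppm=ppm,
        intensity=intensity,
        sample_id="lactate-reference",
        weight_mg=1.0,
        meta={"synthetic": True, "reference_nmol": amount_nmol},
    )


def median_quantification_peak_height(
    quants: Mapping[str, float],
    weight_mg: float,
    assignments: AssignmentTable,
    params: SpectrumSynthParams,
) -> float:
    """Median noiseless peak height over the designated quantification peaks
    (used to express noise levels as a fraction of typical peak height)."""
    heights = []
    for met, conc in quants.items():
        for g in assignments.groups_for(met):
            if not g.quantify:
                continue
            frac = 1.0
            if met == "glucose":
                frac = (
                    ALPHA_GLUCOSE_FRACTION
                    if g.metabolite_name.startswith("alpha")
                    else 1.0 - ALPHA_GLUCOSE_FRACTION
                )
            area = params.response_factor * conc * weight_mg * frac * g.n_protons
            heights.append(area / (np.pi * params.linewidth))
    if not heights:
        raise ValueError("no quantification peaks in the record")
    return float(np.median(heights))


def synthesize_cohort(
    quant: pd.DataFrame,
    metadata: Sequence[SampleMetadata],
    assignments: AssignmentTable,
    params: SpectrumSynthParams = SpectrumSynthParams(),
    seed: int = 0,
    noise_fraction: float = 0.0,
) -> list[Spectrum1D]:
    """Render one spectrum per cohort sample.

    ``noise_fraction`` > 0 sets each spectrum's white-noise SD to that
    fraction of its median quantification-peak height (overriding
    ``params.noise_sd``).
    """
    rng = np.random.default_rng(seed)
    spectra = []
    for meta in metadata:
        record = quant.loc[meta.sample_id].to_dict()
        p = params
        if noise_fraction > 0:
            p = replace(params, noise_sd=noise_fraction * median_quantification_peak_height(
                record, meta.weight_mg, assignments, params
            ))
        spectra.append(synthesize_spectrum(
            record, meta.weight_mg, assignments, p,
            seed=int(rng.integers(2**31 - 1)), sample_id=meta.sample_id,
        ))
    return spectra


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------

def simulate_survival(
    metadata: Sequence[SampleMetadata],
    params: SurvivalSimParams = SurvivalSimParams(),
    seed: int = 0,
) -> list[SampleMetadata]:
    """Attach exponential survival times and event indicators.

    Labelled survivor groups are drawn from the exponential conditioned on
    the window defining the label (long: > 36 months via memorylessness,
    short: < 12 months via inverse CDF); ``unknown`` samples use the plain
    exponential.  ``event`` is Bernoulli(1 - censor_rate).  Reproducible
    given ``seed``.
    """
    rng = np.random.default_rng(seed)
    out: list[SampleMetadata] = []
    for meta in metadata:
        if meta.survival_group not in params.groups:
            raise KeyError(
                f"{meta.sample_id}: no survival parameters for group "
                f"{meta.survival_group!r}"
            )
        scale, censor_rate = params.groups[meta.survival_group]
        if meta.survival_group == "long":
            time = 36.0 + rng.exponential(scale)
        elif meta.survival_group == "short":
            u = rng.uniform(0.0, 1.0 - np.exp(-12.0 / scale))
            time = -scale * np.log1p(-u)
        else:
            time = rng.exponential(scale)
        event = bool(rng.uniform() >= censor_rate)
        out.append(replace(meta, survival_time_months=float(time), event=event))
    return out
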