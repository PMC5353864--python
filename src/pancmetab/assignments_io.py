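"""Packaged assignment table, metabolic network, and spectrum/metadata I/O.

The assignment table transcribes the 1H/13C resonance assignments of the 31
metabolites identified in intact pancreatic tissue by 1D CPMG HRMAS NMR,
together with the designated quantification peaks (well-defined resonances
without overlap) of the 18 quantifiable metabolites.  Glucose is the single
metabolite with two designated peaks (alpha and beta anomeric C1H); the two
printed anomer rows share the canonical name ``glucose`` and their amounts
are summed at quantification time.

Spectra are exchanged as two-column ppm/intensity text (tab separated, with
``# key: value`` header lines) or, read-only, as a minimal JCAMP-DX-like
dialect.  The ppm axis is stored in decreasing order (NMR display
convention); readers normalize the direction.
"""
from __future__ import annotations

import csv
import io
import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

PPM_LO = 0.70
PPM_HI = 7.50

TISSUE_LABELS = ("PP", "PA")
SURVIVAL_GROUPS = ("long", "short", "unknown")

METADATA_COLUMNS = (
    "sample_id",
    "tissue",
    "neoadjuvant_chemo",
    "survival_group",
    "survival_time_months",
    "event",
    "weight_mg",
)


class SpectrumParseError(ValueError):
    """Raised for malformed spectrum files (non-numeric rows, bad axis...)."""


class MetadataError(ValueError):
    """Raised for invalid sample-metadata rows."""


class ConfigurationError(RuntimeError):
    """Raised when a packaged data file is missing or corrupted."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ResonanceGroup:
    """One assigned resonance of a metabolite.

    ``metabolite_name`` is the name as printed in the assignment table (the
    glucose anomers are separate entries); ``canonical`` merges the anomers
    and lower-cases names for joining against concentration tables.
    ``quantify`` marks the designated quantification peak(s).
    """

    metabolite_name: str
    canonical: str
    group_label: str
    shift_1h: float
    shift_13c: float | None
    n_protons: int
    quantify: bool

    def __post_init__(self) -> None:
        if self.n_protons < 1:
            raise ValueError(
                f"{self.metabolite_name} {self.group_label}: n_protons must be >= 1"
            )
        if self.quantify and not (PPM_LO <= self.shift_1h <= PPM_HI):
            raise ValueError(
                f"{self.metabolite_name} {self.group_label}: quantification peak "
                f"at {self.shift_1h} ppm outside [{PPM_LO}, {PPM_HI}]"
            )


@dataclass(frozen=True)
class AssignmentTable:
    """Ordered collection of resonance groups for the identified metabolites."""

    groups: tuple[ResonanceGroup, ...]

    def __post_init__(self) -> None:
        per_name: dict[str, int] = {}
        for g in self.groups:
            if g.quantify:
                per_name[g.canonical] = per_name.get(g.canonical, 0) + 1
        for name, count in per_name.items():
            limit = 2 if name == "glucose" else 1
            if count > limit:
                raise ValueError(f"{name}: {count} quantification peaks (max {limit})")

    @property
    def metabolites(self) -> tuple[str, ...]:
        """Distinct printed metabolite names, in table order (31 entries)."""
        seen: dict[str, None] = {}
        for g in self.groups:
            seen.setdefault(g.metabolite_name, None)
        return tuple(seen)

    @property
    def quantified_metabolites(self) -> tuple[str, ...]:
        """Canonical names carrying a quantification peak, in table order (18)."""
        seen: dict[str, None] = {}
        for g in self.groups:
            if g.quantify:
                seen.setdefault(g.canonical, None)
        return tuple(seen)

    def quantify_groups(self, canonical: str) -> tuple[ResonanceGroup, ...]:
        out = tuple(
            g for g in self.groups if g.canonical == canonical and g.quantify
        )
        if not out:
            raise KeyError(f"no quantification peak for {canonical!r}")
        return out

    def groups_for(self, canonical: str) -> tuple[ResonanceGroup, ...]:
        return tuple(g for g in self.groups if g.canonical == canonical)


@dataclass
class Spectrum1D:
    """A 1D NMR spectrum: decreasing ppm axis, matching intensities, and
    acquisition annotations (sample weight in mg is required downstream)."""

    ppm: np.ndarray
    intensity: np.ndarray
    sample_id: str = ""
    weight_mg: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.ppm.ndim != 1 or self.ppm.shape != self.intensity.shape:
            raise SpectrumParseError("ppm and intensity must be 1-D and equal length")
        if self.ppm.size < 2:
            raise SpectrumParseError("spectrum needs at least 2 points")
        d = np.diff(self.ppm)
        if np.all(d > 0):  # normalize to decreasing
            self.ppm = self.ppm[::-1].copy()
            self.intensity = self.intensity[::-1].copy()
        elif not np.all(d < 0):
            raise SpectrumParseError("axis not strictly monotone")
        if self.weight_mg is not None and self.weight_mg <= 0:
            raise SpectrumParseError(f"weight_mg must be > 0, got {self.weight_mg}")

    def ascending(self) -> tuple[np.ndarray, np.ndarray]:
        """Axis and intensities in increasing-ppm order (for integration)."""
        return self.ppm[::-1], self.intensity[::-1]


@dataclass(frozen=True)
class SampleMetadata:
    sample_id: str
    tissue: str
    neoadjuvant_chemo: bool
    survival_group: str = "unknown"
    survival_time_months: float | None = None
    event: bool | None = None
    weight_mg: float | None = None

    def __post_init__(self) -> None:
        if self.tissue not in TISSUE_LABELS:
            raise MetadataError(f"{self.sample_id}: unknown tissue label {self.tissue!r}")
        if self.survival_group not in SURVIVAL_GROUPS:
            raise MetadataError(
                f"{self.sample_id}: unknown survival group {self.survival_group!r}"
            )
        if self.weight_mg is not None and self.weight_mg <= 0:
            raise MetadataError(f"{self.sample_id}: weight_mg must be positive")
        t = self.survival_time_months
        if t is not None:
            if t < 0:
                raise MetadataError(f"{self.sample_id}: negative survival time")
            if self.survival_group == "long" and t <= 36:
                raise MetadataError(
                    f"{self.sample_id}: long-term survivor with time {t} <= 36 months"
                )
            if self.survival_group == "short" and t >= 12:
                raise MetadataError(
                    f"{self.sample_id}: short-term survivor with time {t} >= 12 months"
                )


@dataclass(frozen=True)
class MetabolicNetwork:
    """Pathway adjacency plus the ordered pathway-group comparisons."""

    nodes: tuple[str, ...]
    edges: tuple[tuple[str, str], ...]
    group_comparisons: tuple[tuple[str, ...], ...]

    def __post_init__(self) -> None:
        node_set = set(self.nodes)
        for a, b in self.edges:
            if a not in node_set or b not in node_set:
                raise ValueError(f"edge ({a}, {b}) references unknown node")
        for grp in self.group_comparisons:
            for m in grp:
                if m not in node_set:
                    raise ValueError(f"group member {m!r} is not a network node")

    def n_components(self) -> int:
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return nx.number_connected_components(g)


# ---------------------------------------------------------------------------
# packaged data
# ---------------------------------------------------------------------------

def _packaged(name: str) -> str:
    try:
        return resources.files("pancmetab.data").joinpath(name).read_text()
    except (FileNotFoundError, ModuleNotFoundError) as exc:
        raise ConfigurationError(f"packaged data file {name!r} missing") from exc


def load_assignments() -> AssignmentTable:
    """Load the packaged assignment table (31 metabolites, 18 quantifiable)."""
    text = _packaged("assignments.csv")
    rows = [r for r in csv.DictReader(
        line for line in text.splitlines() if not line.startswith("#")
    )]
    if not rows:
        raise ConfigurationError("assignments.csv is empty")
    groups = []
    try:
        for r in rows:
            c13 = r["shift_13c"].strip()
            groups.append(ResonanceGroup(
                metabolite_name=r["metabolite"],
                canonical=r["canonical"],
                group_label=r["group_label"],
                shift_1h=float(r["shift_1h"]),
                shift_13c=float(c13) if c13 else None,
                n_protons=int(r["n_protons"]),
                quantify=r["quantify"].strip() == "1",
            ))
    except (KeyError, ValueError) as exc:
        raise ConfigurationError(f"assignments.csv is corrupted: {exc}") from exc
    return AssignmentTable(groups=tuple(groups))


def parse_network(text: str) -> MetabolicNetwork:
    nodes: list[str] = []
    edges: list[tuple[str, str]] = []
    groups: list[tuple[str, ...]] = []
    section = None
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line in ("[nodes]", "[edges]", "[groups]"):
            section = line[1:-1]
            continue
        if section == "nodes":
            nodes.append(line)
        elif section == "edges":
            parts = [p.strip() for p in line.split("--")]
            if len(parts) != 2:
                raise ValueError(f"malformed edge line: {raw!r}")
            edges.append((parts[0], parts[1]))
        elif section == "groups":
            groups.append(tuple(p.strip() for p in line.split(",")))
        else:
            raise ValueError(f"content outside any section: {raw!r}")
    return MetabolicNetwork(tuple(nodes), tuple(edges), tuple(groups))


def load_network() -> MetabolicNetwork:
    """Load the packaged metabolic network and its 12 group comparisons."""
    return parse_network(_packaged("network.txt"))


def read_network(path: str | Path) -> MetabolicNetwork:
    return parse_network(Path(path).read_text())


# ---------------------------------------------------------------------------
# spectrum I/O
# ---------------------------------------------------------------------------

_HEADER_RE = re.compile(r"^#\s*([^:]+?)\s*:\s*(.*)$")


def _coerce(value: str):
    for cast in (int, float):
        try:
            return cast(value)
        except ValueError:
            pass
    return value


def read_spectrum(
    path: str | Path,
    dialect: str = "tsv",
    weight_mg: float | None = None,
) -> Spectrum1D:
    """Read a 1D spectrum.

    ``dialect`` is ``tsv`` (two numeric columns with optional ``# key: value``
    headers) or ``jcamp`` (minimal JCAMP-DX-like block, read-only).  A
    ``weight_mg`` header key in the file wins over the ``weight_mg`` argument
    (typically sourced from the metadata table); a conflict is logged.
    """
    path = Path(path)
    if dialect == "tsv":
        meta, x, y = _read_tsv(path)
    elif dialect == "jcamp":
        meta, x, y = _read_jcamp(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    header_weight = meta.pop("weight_mg", None)
    if header_weight is not None and weight_mg is not None and (
        abs(float(header_weight) - weight_mg) > 1e-9
    ):
        log.warning(
            "%s: weight_mg header (%s) overrides supplied value (%s)",
            path.name, header_weight, weight_mg,
        )
    weight = float(header_weight) if header_weight is not None else weight_mg
    if weight is None:
        raise SpectrumParseError(f"{path.name}: missing weight_mg")
    sample_id = str(meta.pop("sample_id", path.stem))
    return Spectrum1D(
        ppm=x, intensity=y, sample_id=sample_id, weight_mg=weight, meta=meta
    )


def _read_tsv(path: Path):
    meta: dict = {}
    xs: list[float] = []
    ys: list[float] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        m = _HEADER_RE.match(line)
        if m:
            meta[m.group(1)] = _coerce(m.group(2))
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if parts[0].lower() in ("ppm",):  # column header row
            continue
        if len(parts) < 2:
            raise SpectrumParseError(f"{path.name}:{lineno}: expected two columns")
        try:
            xs.append(float(parts[0]))
            ys.append(float(parts[1]))
        except ValueError as exc:
            raise SpectrumParseError(
                f"{path.name}:{lineno}: non-numeric row {raw!r}"
            ) from exc
    return meta, np.array(xs), np.array(ys)


def _read_jcamp(path: Path):
    """Minimal JCAMP-DX-like reader: ``##KEY=value`` records and an
    ``##XYDATA=(XY..XY)`` block of ``x y`` pairs, one pair per line."""
    meta: dict = {}
    xs: list[float] = []
    ys: list[float] = []
    in_data = False
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("##"):
            key, _, value = line[2:].partition("=")
            key = key.strip().lower()
            if key == "xydata":
                in_data = True
                continue
            if key == "end":
                in_data = False
                continue
            meta[key] = _coerce(value.strip())
            continue
        if in_data:
            parts = line.replace(",", " ").split()
            if len(parts) < 2:
                raise SpectrumParseError(f"{path.name}:{lineno}: expected x y pair")
            try:
                xs.append(float(parts[0]))
                ys.append(float(parts[1]))
            except ValueError as exc:
                raise SpectrumParseError(
                    f"{path.name}:{lineno}: non-numeric row {raw!r}"
                ) from exc
    if not xs:
        raise SpectrumParseError(f"{path.name}: no XYDATA block found")
    return meta, np.array(xs), np.array(ys)


def write_spectrum(spectrum: Spectrum1D, path: str | Path) -> None:
    """Write the tsv dialect (headers, then ppm/intensity columns)."""
    path = Path(path)
    buf = io.StringIO()
    buf.write(f"# sample_id: {spectrum.sample_id}\n")
    if spectrum.weight_mg is not None:
        buf.write(f"# weight_mg: {float(spectrum.weight_mg)!r}\n")
    for key, value in spectrum.meta.items():
        buf.write(f"# {key}: {value}\n")
    buf.write("ppm\tintensity\n")
    for x, y in zip(spectrum.ppm, spectrum.intensity):
        buf.write(f"{float(x)!r}\t{float(y)!r}\n")
    path.write_text(buf.getvalue())


# ---------------------------------------------------------------------------
# metadata I/O
# ---------------------------------------------------------------------------

def _parse_bool(value, row: int, column: str) -> bool:
    s = str(value).strip().lower()
    if s in ("1", "true", "yes", "y"):
        return True
    if s in ("0", "false", "no", "n"):
        return False
    raise MetadataError(f"row {row}: cannot parse {column}={value!r} as boolean")


def read_metadata(path: str | Path) -> list[SampleMetadata]:
    """Read the sample-metadata CSV; validates every row (row index reported)."""
    df = pd.read_csv(path, comment="#", dtype=str)
    missing = set(METADATA_COLUMNS[:4]) - set(df.columns)
    if missing:
        raise MetadataError(f"metadata file missing columns: {sorted(missing)}")
    records: list[SampleMetadata] = []
    for i, row in df.iterrows():
        def opt(col):
            v = row.get(col)
            if v is None or (isinstance(v, float) and np.isnan(v)) or str(v) == "" or str(v) == "nan":
                return None
            return v

        try:
            time = opt("survival_time_months")
            event = opt("event")
            weight = opt("weight_mg")
            records.append(SampleMetadata(
                sample_id=str(row["sample_id"]),
                tissue=str(row["tissue"]).strip(),
                neoadjuvant_chemo=_parse_bool(row["neoadjuvant_chemo"], i, "neoadjuvant_chemo"),
                survival_group=str(opt("survival_group") or "unknown").strip(),
                survival_time_months=float(time) if time is not None else None,
                event=_parse_bool(event, i, "event") if event is not None else None,
                weight_mg=float(weight) if weight is not None else None,
            ))
        except MetadataError as exc:
            raise MetadataError(f"row {i}: {exc}") from exc
    return records


def write_metadata(records: Sequence[SampleMetadata], path: str | Path) -> None:
    rows = []
    for r in records:
        rows.append({
            "sample_id": r.sample_id,
            "tissue": r.tissue,
            "neoadjuvant_chemo": r.neoadjuvant_chemo,
            "survival_group": r.survival_group,
            "survival_time_months": r.survival_time_months,
            "event": r.event,
            "weight_mg": r.weight_mg,
        })
    pd.DataFrame(rows, columns=list(METADATA_COLUMNS)).to_csv(path, index=False)
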