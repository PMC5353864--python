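"""Spectral bucketing and weight normalization.

Each 1D spectrum is integrated over fixed 0.01-ppm buckets between 0.70 and
7.50 ppm (680 buckets by default) by trapezoidal integration on the native
grid, then divided by the sample weight.  The resulting samples x buckets
matrix is the input of the multivariate analysis.
"""
from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

from .assignments_io import Spectrum1D


@dataclass(frozen=True)
class BucketingParams:
    lo: float = 0.70
    hi: float = 7.50
    width: float = 0.01

    def __post_init__(self) -> None:
        if self.lo >= self.hi:
            raise ValueError("lo must be < hi")
        if self.width <= 0:
            raise ValueError("width must be > 0")
        ratio = (self.hi - self.lo) / self.width
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError("(hi - lo) must be an integer multiple of width")

    @property
    def n_buckets(self) -> int:
        return round((self.hi - self.lo) / self.width)

    @property
    def boundaries(self) -> np.ndarray:
        return self.lo + self.width * np.arange(self.n_buckets + 1)

    @property
    def centers(self) -> np.ndarray:
        return self.lo + self.width * (np.arange(self.n_buckets) + 0.5)


@dataclass
class BucketMatrix:
    sample_ids: list[str]
    bucket_centers: np.ndarray
    values: np.ndarray  # samples x buckets, integral units per mg

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.bucket_centers)):
            raise ValueError("values shape does not match ids/centers")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("bucket matrix contains non-finite values")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.values,
            index=self.sample_ids,
            columns=[f"{c:.3f}" for c in self.bucket_centers],
        )
        df.index.name = "sample_id"
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, float_format="%.10g")

    @classmethod
    def from_csv(cls, path: str | Path) -> "BucketMatrix":
        df = pd.read_csv(path, index_col="sample_id", comment="#")
        return cls(
            sample_ids=[str(s) for s in df.index],
            bucket_centers=np.array([float(c) for c in df.columns]),
            values=df.to_numpy(dtype=float),
        )


def bucket_spectrum(spectrum: Spectrum1D, params: BucketingParams = BucketingParams()) -> np.ndarray:
    """Integrate one spectrum over the bucket grid (trapezoid, native grid).

    Bucket j covers [lo + j*width, lo + (j+1)*width); boundaries are shared,
    so the bucket sum telescopes to the whole-range trapezoidal integral.
    """
    x, y = spectrum.ascending()
    if x[0] > params.lo + 1e-12 or x[-1] < params.hi - 1e-12:
        raise ValueError(
            f"spectrum axis [{x[0]:.4f}, {x[-1]:.4f}] does not cover the "
            f"bucketing range [{params.lo}, {params.hi}]"
        )
    bounds = params.boundaries
    inner = x[(x > params.lo) & (x < params.hi)]
    grid = np.union1d(bounds, inner)
    vals = np.interp(grid, x, y)
    cum = cumulative_trapezoid(vals, grid, initial=0.0)
    idx = np.searchsorted(grid, bounds)
    return np.diff(cum[idx])


def normalize_by_weight(vector: np.ndarray, weight_mg: float) -> np.ndarray:
    """Divide a bucket (or concentration) vector by the sample weight."""
    if weight_mg <= 0:
        raise ValueError(f"weight_mg must be > 0, got {weight_mg}")
    return np.asarray(vector, dtype=float) / weight_mg


def build_bucket_matrix(
    spectra: Sequence[Spectrum1D],
    params: BucketingParams = BucketingParams(),
) -> BucketMatrix:
    """Bucket and weight-normalize a cohort, rows in input order."""
    if not spectra:
        raise ValueError("no spectra")
    rows = []
    ids = []
    for s in spectra:
        try:
            if s.weight_mg is None:
                raise ValueError("missing weight_mg")
            rows.append(normalize_by_weight(bucket_spectrum(s, params), s.weight_mg))
            ids.append(s.sample_id)
        except ValueError as exc:
            raise ValueError(f"sample {s.sample_id!r}: {exc}") from exc
    return BucketMatrix(
        sample_ids=ids, bucket_centers=params.centers, values=np.vstack(rows)
    )
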