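"""Static and dynamic (time-resolved) functional connectivity.

Static connectivity is the ordinary Pearson correlation between two
regions' full time series.  Dynamic connectivity uses the multiplication
of temporal derivatives (MTD): first-difference each region's series,
normalise each derivative series by its whole-run standard deviation,
form pairwise products per derivative sample, and smooth the product
series with a simple moving average over ``w`` consecutive samples.

Conventions (these make the documented tolerances hold):

* the derivative standard deviation is the population (``ddof=0``)
  standard deviation of the whole run, with no window subscript;
* windows are trailing, ``t .. t+w-1`` in derivative samples, stride 1,
  yielding ``W = T - w`` coupling frames indexed by window start;
* a region with zero derivative variance contributes coupling 0 and a
  warning is emitted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .preprocess_io import ParcellatedTimeSeries

__all__ = ["StaticFC", "DynamicFC", "static_fc", "mtd", "mtd_seed"]


@dataclass
class StaticFC:
    """N x N symmetric Pearson correlation matrix with region labels.

    Self-connections are kept on the diagonal (=1) but are meant to be
    excluded from downstream statistics.
    """

    matrix: np.ndarray
    region_labels: Sequence[str]
    constant_regions: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.region_labels = list(self.region_labels)
        if self.matrix.shape != (len(self.region_labels),) * 2:
            raise ValueError("matrix must be N x N with N = len(region_labels)")

    def row(self, label: str) -> np.ndarray:
        return self.matrix[self.region_labels.index(label)]

    def upper_triangle(self) -> np.ndarray:
        """Vector of the E = N(N-1)/2 unique off-diagonal edges."""
        iu = np.triu_indices(self.matrix.shape[0], k=1)
        return self.matrix[iu]


@dataclass
class DynamicFC:
    """Windowed MTD coupling: either a full W x N x N tensor or a
    W x N seed slice (one row per frame for a single seed region)."""

    data: np.ndarray
    window: int
    region_labels: Sequence[str]
    seed_label: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.region_labels = list(self.region_labels)
        expected = 2 if self.seed_label is not None else 3
        if self.data.ndim != expected:
            raise ValueError(
                f"expected {expected}-D coupling array, got {self.data.ndim}-D"
            )

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    def seed_slice(self, label: str) -> np.ndarray:
        """W x N coupling of one seed region to every region."""
        if self.seed_label is not None:
            if label != self.seed_label:
                raise ValueError(f"this DynamicFC holds only seed {self.seed_label!r}")
            return self.data
        return self.data[:, self.region_labels.index(label), :]


def static_fc(ts: ParcellatedTimeSeries) -> StaticFC:
    """Pearson correlation matrix of all region pairs.

    Constant (zero-variance) regions get correlation 0 to every other
    region (diagonal stays 1) and are flagged with a warning.
    """
    if ts.n_timepoints < 3:
        raise ValueError("need at least 3 time points for correlation")
    constant = np.ptp(ts.data, axis=0) == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant region(s); correlations set to 0",
            RuntimeWarning,
            stacklevel=2,
        )
    safe = ts.data.copy()
    # give constant columns unit noise-free variance placeholder, zero later
    safe[:, constant] = np.arange(ts.n_timepoints)[:, None]
    mat = np.corrcoef(safe, rowvar=False)
    mat[constant, :] = 0.0
    mat[:, constant] = 0.0
    np.fill_diagonal(mat, 1.0)
    return StaticFC(mat, ts.region_labels, constant_regions=constant)


def _normalized_derivatives(ts: ParcellatedTimeSeries) -> np.ndarray:
    """(T-1) x N first differences, each column z-scored over the whole
    run (population standard deviation); zero-variance columns become 0.

    Centering makes the w=1 time-mean coupling equal the Pearson
    correlation of the derivative series exactly; the derivative mean of
    a BOLD run is tiny anyway ((x_T - x_0)/(T-1))."""
    dt = np.diff(ts.data, axis=0)
    sigma = dt.std(axis=0)  # population (n) denominator
    zero = sigma == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} region(s) with zero derivative variance; "
            "their coupling is defined as 0",
            RuntimeWarning,
            stacklevel=3,
        )
    sigma_safe = np.where(zero, 1.0, sigma)
    z = (dt - dt.mean(axis=0)) / sigma_safe
    z[:, zero] = 0.0
    return z


def _moving_average(x: np.ndarray, w: int) -> np.ndarray:
    """Trailing moving average of length ``w`` along axis 0."""
    cs = np.cumsum(x, axis=0, dtype=float)
    out = cs[w - 1 :].copy()
    out[1:] -= cs[: -w]
    return out / w


def mtd(ts: ParcellatedTimeSeries, w: int = 5) -> DynamicFC:
    """Full multiplication-of-temporal-derivatives coupling tensor.

    Returns ``W = T - w`` frames of N x N coupling, each frame the mean of
    ``w`` consecutive normalised-derivative products.
    """
    if w < 1 or w > ts.n_timepoints - 2:
        raise ValueError(f"window w must satisfy 1 <= w <= T-2, got {w}")
    z = _normalized_derivatives(ts)
    prod = np.einsum("ti,tj->tij", z, z)
    smoothed = _moving_average(prod, w)
    return DynamicFC(smoothed, window=w, region_labels=ts.region_labels)


def mtd_seed(ts: ParcellatedTimeSeries, seed_label: str, w: int = 5) -> DynamicFC:
    """Seed-row MTD (W x N) without materialising the full tensor.

    Equals the corresponding rows of :func:`mtd` exactly.
    """
    if w < 1 or w > ts.n_timepoints - 2:
        raise ValueError(f"window w must satisfy 1 <= w <= T-2, got {w}")
    z = _normalized_derivatives(ts)
    s = ts.region_labels.index(seed_label)
    prod = z[:, [s]] * z
    smoothed = _moving_average(prod, w)
    return DynamicFC(smoothed, window=w, region_labels=ts.region_labels,
                     seed_label=seed_label)
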