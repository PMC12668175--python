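"""Containers, TSV input/output and post-preprocessing denoising.

This module holds the in-memory data types shared across the pipeline
(parcellated BOLD time series, confound tables, network partitions and
parcel geometry) together with strict TSV readers/writers and the two
denoising steps applied to parcel-averaged series: nuisance (confound)
regression and zero-phase band-pass filtering.

All readers validate and refuse malformed input rather than coercing it;
missing values are never imputed.
"""

from __future__ import annotations


from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

GROUP_LABELS = ("delirious", "non_delirious")

__all__ = [
    "GROUP_LABELS",
    "ParcellatedTimeSeries",
    "ConfoundTable",
    "NetworkPartition",
    "ParcelGeometry",
    "read_parcellated_timeseries",
    "write_parcellated_timeseries",
    "read_manifest",
    "write_manifest",
    "read_partition",
    "write_partition",
    "read_centroids",
    "write_centroids",
    "read_expression_table",
    "write_expression_table",
    "regress_confounds",
    "bandpass",
]


# ---------------------------------------------------------------------------
# data types
# ---------------------------------------------------------------------------


@dataclass
class ParcellatedTimeSeries:
    """One subject's T x N parcel-averaged BOLD matrix.

    Parameters
    ----------
    subject_id : str
        Unique subject identifier.
    group : str
        Outcome group, one of ``"delirious"`` / ``"non_delirious"``.
    data : ndarray, shape (T, N)
        BOLD samples (arbitrary units), one column per region.
    region_labels : sequence of str
        N unique region names; nucleus columns are named ``"LC"`` and
        ``"nbM"`` by convention.
    tr_seconds : float
        Repetition time (sampling interval) in seconds.
    """

    subject_id: str
    group: str
    data: np.ndarray
    region_labels: Sequence[str]
    tr_seconds: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.region_labels = list(self.region_labels)
        if self.group not in GROUP_LABELS:
            raise ValueError(
                f"group must be one of {GROUP_LABELS}, got {self.group!r}"
            )
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D (T x N) matrix")
        if self.data.shape[0] < 3:
            raise ValueError("time series must have at least 3 time points")
        if not np.all(np.isfinite(self.data)):
            t, n = np.argwhere(~np.isfinite(self.data))[0]
            raise ValueError(
                f"non-finite value at time point {t}, region "
                f"{self.region_labels[n] if n < len(self.region_labels) else n}"
            )
        if len(self.region_labels) != self.data.shape[1]:
            raise ValueError("region_labels length must match data columns")
        if len(set(self.region_labels)) != len(self.region_labels):
            raise ValueError("region_labels must be unique")
        if not self.tr_seconds > 0:
            raise ValueError("tr_seconds must be positive")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_regions(self) -> int:
        return self.data.shape[1]

    def column(self, label: str) -> np.ndarray:
        """Return the series of a single named region."""
        return self.data[:, self.region_labels.index(label)]


@dataclass
class ConfoundTable:
    """T x K nuisance-regressor matrix (motion, WM/CSF, FD, ...)."""

    data: np.ndarray
    columns: Sequence[str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.columns = list(self.columns)
        if self.data.ndim != 2:
            raise ValueError("confound data must be 2-D")
        if len(self.columns) != self.data.shape[1]:
            raise ValueError("column names must match confound columns")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("confound table contains non-finite values")


@dataclass
class NetworkPartition:
    """Assignment of every region to exactly one network module.

    Module ids are contiguous integers starting at 0.
    """

    region_labels: Sequence[str]
    module_ids: np.ndarray

    def __post_init__(self) -> None:
        self.region_labels = list(self.region_labels)
        self.module_ids = np.asarray(self.module_ids, dtype=int)
        if self.module_ids.ndim != 1:
            raise ValueError("module_ids must be 1-D")
        if len(self.region_labels) != self.module_ids.size:
            raise ValueError("one module id per region required")
        uniq = np.unique(self.module_ids)
        if not np.array_equal(uniq, np.arange(uniq.size)):
            raise ValueError("module ids must be contiguous from 0")

    @property
    def n_modules(self) -> int:
        return int(self.module_ids.max()) + 1

    @property
    def n_regions(self) -> int:
        return self.module_ids.size

    def indicator(self) -> np.ndarray:
        """N x M 0/1 membership matrix."""
        out = np.zeros((self.n_regions, self.n_modules))
        out[np.arange(self.n_regions), self.module_ids] = 1.0
        return out

    def subset(self, labels: Sequence[str]) -> "NetworkPartition":
        """Partition restricted to ``labels`` (module ids recompacted)."""
        idx = [self.region_labels.index(l) for l in labels]
        ids = self.module_ids[idx]
        _, compact = np.unique(ids, return_inverse=True)
        return NetworkPartition(list(labels), compact)


@dataclass
class ParcelGeometry:
    """Unit-sphere centroid per region plus a hemisphere label (L/R)."""

    region_labels: Sequence[str]
    coords: np.ndarray
    hemisphere: np.ndarray

    def __post_init__(self) -> None:
        self.region_labels = list(self.region_labels)
        self.coords = np.asarray(self.coords, dtype=float)
        self.hemisphere = np.asarray(self.hemisphere, dtype=object)
        if self.coords.shape != (len(self.region_labels), 3):
            raise ValueError("coords must be N x 3")
        norms = np.linalg.norm(self.coords, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-9):
            raise ValueError("centroids must be unit-norm within 1e-9")
        if not set(np.unique(self.hemisphere)) <= {"L", "R"}:
            raise ValueError("hemisphere labels must be 'L' or 'R'")

    @property
    def n_regions(self) -> int:
        return len(self.region_labels)

    def hemisphere_indices(self, hemi: str) -> np.ndarray:
        return np.flatnonzero(self.hemisphere == hemi)


# ---------------------------------------------------------------------------
# TSV I/O (tab-separated, UTF-8, '.' decimal, mandatory header)
# ---------------------------------------------------------------------------


def _read_numeric_tsv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, sep="\t", header=0)
    except pd.errors.ParserError as exc:  # ragged rows etc.
        raise ValueError(f"{path}: malformed TSV ({exc})") from exc
    if df.columns.str.match(r"^Unnamed").all() or df.shape[1] == 0:
        raise ValueError(f"{path}: missing header row")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"{path}: non-numeric value {df[col].iloc[row]!r} at row "
                f"{row}, column {col!r}"
            )
        if coerced.isna().any():
            row = int(np.flatnonzero(coerced.isna().to_numpy())[0])
            raise ValueError(f"{path}: missing value at row {row}, column {col!r}")
        df[col] = coerced
    return df


def read_parcellated_timeseries(
    path: str | Path,
    subject_id: str,
    group: str,
    tr_seconds: float,
) -> ParcellatedTimeSeries:
    """Read one subject's T x N TSV (header = region labels, rows = TRs)."""
    df = _read_numeric_tsv(path)
    return ParcellatedTimeSeries(
        subject_id=subject_id,
        group=group,
        data=df.to_numpy(dtype=float),
        region_labels=list(df.columns),
        tr_seconds=tr_seconds,
    )


def write_parcellated_timeseries(ts: ParcellatedTimeSeries, path: str | Path) -> None:
    pd.DataFrame(ts.data, columns=ts.region_labels).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Cohort manifest: subject_id, group, delta_change, ptau (+ extras)."""
    df = pd.read_csv(path, sep="\t", header=0, dtype={"subject_id": str})
    required = {"subject_id", "group", "delta_change", "ptau"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: manifest missing columns {sorted(missing)}")
    bad = ~df["group"].isin(GROUP_LABELS)
    if bad.any():
        raise ValueError(
            f"{path}: unknown group label {df.loc[bad, 'group'].iloc[0]!r}"
        )
    return df


def write_manifest(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_partition(path: str | Path) -> NetworkPartition:
    df = pd.read_csv(path, sep="\t", header=0)
    if not {"region", "network_id"} <= set(df.columns):
        raise ValueError(f"{path}: partition TSV needs region and network_id")
    return NetworkPartition(df["region"].astype(str).tolist(),
                            df["network_id"].to_numpy(dtype=int))


def write_partition(partition: NetworkPartition, path: str | Path) -> None:
    pd.DataFrame(
        {"region": partition.region_labels, "network_id": partition.module_ids}
    ).to_csv(path, sep="\t", index=False)


def read_centroids(path: str | Path) -> ParcelGeometry:
    df = pd.read_csv(path, sep="\t", header=0)
    need = {"region", "x", "y", "z", "hemisphere"}
    if not need <= set(df.columns):
        raise ValueError(f"{path}: centroid TSV needs columns {sorted(need)}")
    return ParcelGeometry(
        df["region"].astype(str).tolist(),
        df[["x", "y", "z"]].to_numpy(dtype=float),
        df["hemisphere"].to_numpy(),
    )


def write_centroids(geometry: ParcelGeometry, path: str | Path) -> None:
    pd.DataFrame(
        {
            "region": geometry.region_labels,
            "x": geometry.coords[:, 0],
            "y": geometry.coords[:, 1],
            "z": geometry.coords[:, 2],
            "hemisphere": geometry.hemisphere,
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_expression_table(path: str | Path) -> pd.DataFrame:
    """Region x gene expression TSV with a leading ``region`` column."""
    df = pd.read_csv(path, sep="\t", header=0)
    if "region" not in df.columns:
        raise ValueError(f"{path}: expression TSV needs a region column")
    return df.set_index("region")


def write_expression_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=True, index_label="region",
              float_format="%.10g")


# ---------------------------------------------------------------------------
# denoising
# ---------------------------------------------------------------------------


def regress_confounds(
    ts: ParcellatedTimeSeries, confounds: ConfoundTable
) -> ParcellatedTimeSeries:
    """Replace every region's series by its least-squares residual.

    The design matrix is ``[intercept | confound columns]``; residuals are
    orthogonal to every confound column.  Exactly the columns given are
    regressed (derivative/quadratic expansion is the caller's choice).
    """
    if confounds.data.shape[0] != ts.n_timepoints:
        raise ValueError(
            f"confound rows ({confounds.data.shape[0]}) must match time "
            f"series length ({ts.n_timepoints})"
        )
    X = np.column_stack([np.ones(ts.n_timepoints), confounds.data])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # locate collinear columns via the QR diagonal
        r_diag = np.abs(np.diag(np.linalg.qr(X)[1]))
        tol = r_diag.max() * max(X.shape) * np.finfo(float).eps
        names = ["intercept"] + list(confounds.columns)
        bad = [names[i] for i in np.flatnonzero(r_diag <= tol)]
        raise ValueError(f"rank-deficient confound design; collinear: {bad}")
    beta, *_ = np.linalg.lstsq(X, ts.data, rcond=None)
    resid = ts.data - X @ beta
    return replace(ts, data=resid)


def bandpass(
    ts: ParcellatedTimeSeries,
    low_hz: float = 0.01,
    high_hz: float = 0.1,
) -> ParcellatedTimeSeries:
    """Zero-phase Butterworth band-pass (order 2 per direction).

    Realised as a forward-backward second-order-section filter, so the
    effective amplitude response is the squared Butterworth magnitude and
    the phase is exactly zero.  Pass-band sinusoids (mid-band) keep their
    amplitude within a few percent; DC and far stop-band content is
    attenuated by more than 90%.
    """
    nyquist = 1.0 / (2.0 * ts.tr_seconds)
    if not 0 < low_hz < high_hz:
        raise ValueError("need 0 < low_hz < high_hz")
    if high_hz >= nyquist:
        raise ValueError(
            f"high_hz ({high_hz}) must be below the Nyquist frequency "
            f"({nyquist:.4g} Hz for TR={ts.tr_seconds}s)"
        )
    sos = sps.butter(2, [low_hz, high_hz], btype="bandpass",
                     fs=1.0 / ts.tr_seconds, output="sos")
    filtered = sps.sosfiltfilt(sos, ts.data, axis=0)
    return replace(ts, data=np.ascontiguousarray(filtered))


def denoise(
    ts: ParcellatedTimeSeries,
    confounds: ConfoundTable | None = None,
    low_hz: float = 0.01,
    high_hz: float = 0.1,
) -> ParcellatedTimeSeries:
    """Confound regression followed by band-pass (regress-then-filter)."""
    out = regress_confounds(ts, confounds) if confounds is not None else ts
    return bandpass(out, low_hz=low_hz, high_hz=high_hz)
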