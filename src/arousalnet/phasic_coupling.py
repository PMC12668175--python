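"""Phasic nucleus peaks and peak-locked network-topology profiles.

Phasic events in a nucleus BOLD series are time points at least two
standard deviations above the run mean, away from the run edges, and
separated by a minimum number of TRs.  For each subject the z-scored
global participation coefficient is averaged at fixed TR lags (-5..+5)
around the detected peaks ("peak-triggered averaging"), and the per-lag
group difference is assessed with a permutation Welch t-test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .preprocess_io import GROUP_LABELS

__all__ = [
    "PeakSet",
    "CrossCorrProfile",
    "detect_phasic_peaks",
    "peak_locked_profile",
    "compare_profiles",
    "welch_t",
]


@dataclass
class PeakSet:
    """Ordered phasic-peak frame indices for one subject and nucleus."""

    indices: np.ndarray
    threshold: float
    subject_id: str = ""
    nucleus: str = ""

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)

    @property
    def n_peaks(self) -> int:
        return self.indices.size


@dataclass
class CrossCorrProfile:
    """Peak-locked association values over lags -max_lag..+max_lag."""

    values: np.ndarray
    lags: np.ndarray
    n_peaks: int
    degenerate: bool = False


def detect_phasic_peaks(
    signal: np.ndarray,
    threshold_sd: float = 2.0,
    margin: int = 10,
    min_separation: int = 10,
    subject_id: str = "",
    nucleus: str = "",
) -> PeakSet:
    """Find phasic peaks: samples >= mean + threshold_sd * SD.

    Whole-run (population) moments define the threshold.  Candidates
    within ``margin`` TRs of either end are discarded; among candidates
    closer than ``min_separation`` the larger value wins (earlier index
    on ties).
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise ValueError("signal must be 1-D")
    if x.size <= 2 * margin:
        raise ValueError("series shorter than twice the edge margin")
    mu, sd = x.mean(), x.std()
    if sd == 0:
        warnings.warn("zero-variance signal; no peaks detected",
                      RuntimeWarning, stacklevel=2)
        return PeakSet(np.empty(0, dtype=int), threshold=mu,
                       subject_id=subject_id, nucleus=nucleus)
    thr = mu + threshold_sd * sd
    cand = np.flatnonzero(x >= thr)
    cand = cand[(cand >= margin) & (cand < x.size - margin)]
    # resolve separation conflicts: larger value first, then earlier index
    order = np.lexsort((cand, -x[cand]))
    accepted: list[int] = []
    for i in cand[order]:
        if all(abs(i - j) >= min_separation for j in accepted):
            accepted.append(int(i))
    return PeakSet(np.sort(accepted), threshold=thr,
                   subject_id=subject_id, nucleus=nucleus)


def peak_locked_profile(
    global_pc: np.ndarray,
    peaks: PeakSet,
    max_lag: int = 5,
    frame_offset: int = 0,
) -> CrossCorrProfile:
    """Mean z-scored global PC at fixed lags around each peak.

    ``frame_offset`` is subtracted from the BOLD peak indices to align
    them with the coupling/PC frame axis (the pipeline passes 1, the
    first-difference offset; window-start indexing keeps the remainder).
    Peaks whose lagged index falls outside the run are skipped for that
    lag; a constant PC trace or an empty peak set yields a flagged zero
    profile.
    """
    pc = np.asarray(global_pc, dtype=float)
    lags = np.arange(-max_lag, max_lag + 1)
    sd = pc.std()
    if peaks.n_peaks == 0 or np.ptp(pc) == 0:
        return CrossCorrProfile(np.zeros(lags.size), lags, peaks.n_peaks,
                                degenerate=True)
    z = (pc - pc.mean()) / sd
    centers = peaks.indices - frame_offset
    values = np.zeros(lags.size)
    for k, lag in enumerate(lags):
        idx = centers + lag
        idx = idx[(idx >= 0) & (idx < z.size)]
        values[k] = z[idx].mean() if idx.size else 0.0
    return CrossCorrProfile(values, lags, peaks.n_peaks)


def welch_t(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Unequal-variance t statistic along axis 0 (0 where degenerate)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    va = a.var(axis=0, ddof=1) / a.shape[0]
    vb = b.var(axis=0, ddof=1) / b.shape[0]
    denom = np.sqrt(va + vb)
    diff = a.mean(axis=0) - b.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, diff / np.where(denom > 0, denom, 1.0), 0.0)
    return t


def compare_profiles(
    profiles: np.ndarray,
    groups: Sequence[str],
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-lag permutation Welch t-test between groups.

    Two-sided p-values use the add-one convention
    ``(#{|t_perm| >= |t_obs|} + 1) / (n_perm + 1)``.
    """
    X = np.asarray(profiles, dtype=float)
    groups = np.asarray(groups, dtype=object)
    if X.ndim != 2 or groups.shape[0] != X.shape[0]:
        raise ValueError("profiles must be subjects x lags with one group "
                         "label per subject")
    present = set(np.unique(groups))
    if not present <= set(GROUP_LABELS) or len(present) < 2:
        raise ValueError("both groups must be present")
    if min((groups == g).sum() for g in GROUP_LABELS) < 2:
        raise ValueError("each group needs at least 2 subjects")
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives very coarse p-values",
                      RuntimeWarning, stacklevel=2)
    is_a = groups == GROUP_LABELS[0]
    t_obs = welch_t(X[is_a], X[~is_a])
    rng = np.random.default_rng(seed)
    n_a = int(is_a.sum())
    count = np.zeros(X.shape[1])
    for _ in range(n_perm):
        perm = rng.permutation(X.shape[0])
        t_p = welch_t(X[perm[:n_a]], X[perm[n_a:]])
        count += np.abs(t_p) >= np.abs(t_obs)
    pvals = (count + 1.0) / (n_perm + 1.0)
    lags = np.arange(-(X.shape[1] // 2), X.shape[1] // 2 + 1)
    if lags.size != X.shape[1]:
        lags = np.arange(X.shape[1])
    return pd.DataFrame({"lag": lags, "t": t_obs, "p": pvals})
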