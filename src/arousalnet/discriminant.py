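"""Group discrimination of seed dynamic-connectivity time points.

Seed coupling frames (one row per subject-frame, one column per cortical
region) are concatenated across subjects and time, z-scored per column,
and separated with a two-class Fisher discriminant computed by
eigen-decomposition of the (shrinkage-regularised) pooled within-class
covariance.  Class priors are balanced at (0.5, 0.5) regardless of group
sizes.  Frames inherit their subject's group.

The discriminant axis is oriented so the delirious class has positive
mean score.  The frames with the largest |score| (top 5% by default) are
the maximally discriminating time points; averaging the seed coupling
over those frames per group and differencing yields the group-contrast
map.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.covariance import ledoit_wolf

from .preprocess_io import GROUP_LABELS

__all__ = ["LDAResult", "ContrastMap", "fit_lda", "select_top_timepoints",
           "contrast_dfc"]

POSITIVE_CLASS = "delirious"


@dataclass
class LDAResult:
    """Fitted two-class discriminant in standardized feature space."""

    coefficients: np.ndarray          # N-vector on the discriminant axis
    scores: np.ndarray                # one real per stacked frame
    class_means: np.ndarray           # 2 x N standardized means (del, non)
    feature_labels: Sequence[str]
    dropped_features: np.ndarray      # bool mask of zero-variance columns
    shrinkage: float
    selected_frames: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.feature_labels = list(self.feature_labels)


@dataclass
class ContrastMap:
    """Per-region group difference of coupling at selected frames."""

    values: np.ndarray
    feature_labels: Sequence[str]
    missing_group: str | None = None

    def __post_init__(self) -> None:
        self.feature_labels = list(self.feature_labels)


def _validate_groups(frame_groups: np.ndarray) -> np.ndarray:
    frame_groups = np.asarray(frame_groups, dtype=object)
    present = set(np.unique(frame_groups))
    if not present <= set(GROUP_LABELS):
        raise ValueError(f"unknown group label(s): {sorted(present - set(GROUP_LABELS))}")
    if len(present) < 2:
        raise ValueError("both classes must be present to fit a discriminant")
    return frame_groups


def fit_lda(
    seed_dfc: np.ndarray,
    frame_groups: Sequence[str],
    priors: tuple[float, float] = (0.5, 0.5),
    shrinkage: float | None = None,
    feature_labels: Sequence[str] | None = None,
) -> LDAResult:
    """Two-class Fisher discriminant on stacked seed coupling frames.

    Parameters
    ----------
    seed_dfc : ndarray, shape (frames, N)
        Concatenated seed coupling (subjects x time stacked along rows).
    frame_groups : sequence
        Group label per frame (inherited from the subject).
    priors : pair
        Class priors; balanced by default.  With equal priors the prior
        term drops out of the scores.
    shrinkage : float or None
        Blend of the pooled within-class covariance toward its diagonal;
        ``None`` chooses the intensity analytically (Ledoit-Wolf).
    """
    X = np.asarray(seed_dfc, dtype=float)
    if X.ndim != 2:
        raise ValueError("seed_dfc must be 2-D (frames x regions)")
    groups = _validate_groups(np.asarray(frame_groups))
    if groups.shape[0] != X.shape[0]:
        raise ValueError("one group label per frame required")
    if feature_labels is None:
        feature_labels = [f"r{i}" for i in range(X.shape[1])]

    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    dropped = sd == 0
    if dropped.any():
        warnings.warn(
            f"{int(dropped.sum())} zero-variance feature(s) dropped",
            RuntimeWarning, stacklevel=2,
        )
    sd_safe = np.where(dropped, 1.0, sd)
    Z = (X - mu) / sd_safe
    Z[:, dropped] = 0.0
    keep = ~dropped
    Zk = Z[:, keep]

    is_pos = groups == POSITIVE_CLASS
    mu_pos = Zk[is_pos].mean(axis=0)
    mu_neg = Zk[~is_pos].mean(axis=0)

    centered = Zk.copy()
    centered[is_pos] -= mu_pos
    centered[~is_pos] -= mu_neg
    n = centered.shape[0]
    Sw = centered.T @ centered / n
    if shrinkage is None:
        # analytic intensity toward the scaled identity, applied toward
        # the diagonal of Sw (both keep the trace)
        _, shrinkage = ledoit_wolf(centered, assume_centered=True)
    gamma = float(np.clip(shrinkage, 0.0, 1.0))
    S = (1.0 - gamma) * Sw + gamma * np.diag(np.diag(Sw))

    evals, evecs = np.linalg.eigh(S)
    tol = max(evals.max(), 0.0) * 1e-12 + 1e-300
    inv = np.where(evals > tol, 1.0 / np.maximum(evals, tol), 0.0)
    d = mu_pos - mu_neg
    w_keep = evecs @ (inv * (evecs.T @ d))

    w = np.zeros(X.shape[1])
    w[keep] = w_keep
    # equal-prior decision axis: score = z @ w - 0.5 (mu_pos + mu_neg) w
    # + log(p1/p0); with balanced priors the log term vanishes
    const = -0.5 * (mu_pos + mu_neg) @ w_keep + math.log(priors[0] / priors[1])
    scores = Z @ w + const
    if scores[is_pos].mean() < scores[~is_pos].mean():
        w, scores = -w, -scores  # orientation: delirious mean positive

    class_means = np.zeros((2, X.shape[1]))
    class_means[0, keep] = mu_pos
    class_means[1, keep] = mu_neg
    return LDAResult(
        coefficients=w,
        scores=scores,
        class_means=class_means,
        feature_labels=feature_labels,
        dropped_features=dropped,
        shrinkage=gamma,
    )


def select_top_timepoints(result: LDAResult, fraction: float = 0.05) -> np.ndarray:
    """Indices of the frames with the largest |discriminant score|.

    Exactly ``ceil(fraction * n_frames)`` indices are returned; ties at
    the threshold are broken in favour of earlier frames.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    scores = np.abs(result.scores)
    n_sel = math.ceil(fraction * scores.size)
    order = np.lexsort((np.arange(scores.size), -scores))
    selected = np.sort(order[:n_sel])
    result.selected_frames = selected
    return selected


def contrast_dfc(
    seed_dfc: np.ndarray,
    selected: np.ndarray,
    frame_groups: Sequence[str],
    feature_labels: Sequence[str] | None = None,
) -> ContrastMap:
    """Delirious-minus-non-delirious mean coupling at selected frames."""
    X = np.asarray(seed_dfc, dtype=float)
    groups = np.asarray(frame_groups, dtype=object)
    selected = np.asarray(selected, dtype=int)
    if selected.size == 0:
        raise ValueError("selected frame set must be non-empty")
    if feature_labels is None:
        feature_labels = [f"r{i}" for i in range(X.shape[1])]
    sel_groups = groups[selected]
    missing = None
    means = {}
    for g in GROUP_LABELS:
        mask = sel_groups == g
        if mask.any():
            means[g] = X[selected[mask]].mean(axis=0)
        else:
            # fall back to the group's mean over all of its frames
            missing = g
            warnings.warn(
                f"group {g!r} absent from selected frames; using its full-"
                "run mean", RuntimeWarning, stacklevel=2,
            )
            means[g] = X[groups == g].mean(axis=0)
    values = means["delirious"] - means["non_delirious"]
    return ContrastMap(values, feature_labels, missing_group=missing)
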