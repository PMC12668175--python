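"""Group-level inference: edge-wise permutation tests, outcome models.

Edge-wise group differences in static connectivity use a Welch t
statistic per edge with a permutation null built by shuffling group
labels (add-one p-values; optional max-statistic family-wise control).

Delirium outcome models are binomial GLMs fitted by iteratively
reweighted least squares: outcome ~ predictor, ~ covariate, ~ additive,
or ~ interaction (main effects plus product).  Predictor and covariate
are standardized before fitting, so coefficients are per SD.  Models are
ranked by the Akaike Information Criterion, AIC = -2 loglik + 2k, an
identity re-verified on every fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .connectivity import StaticFC
from .preprocess_io import GROUP_LABELS

__all__ = [
    "EdgeTestResult",
    "RegressionResult",
    "fc_stack",
    "permutation_ttest_edges",
    "fit_delirium_logistic",
    "compare_models_aic",
    "bh_fdr",
    "biomarker_correlation",
]

MODEL_FORMS = ("predictor_only", "covariate_only", "additive", "interaction")


@dataclass
class EdgeTestResult:
    """Per-edge Welch t, permutation p, optional FWE-corrected p."""

    t: np.ndarray
    p: np.ndarray
    p_fwe: np.ndarray | None
    group_means: dict
    degenerate: np.ndarray
    n_perm: int

    def ranking(self) -> np.ndarray:
        """Edge indices sorted by (p ascending, |t| descending)."""
        return np.lexsort((-np.abs(self.t), self.p))


@dataclass
class RegressionResult:
    """One fitted binomial GLM outcome model."""

    form: str
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    loglik: float
    aic: float
    n_obs: int
    converged: bool
    separation_flag: bool = False
    dropped_terms: list = field(default_factory=list)

    @property
    def n_params(self) -> int:
        return len(self.params)


def fc_stack(fcs: Sequence[StaticFC]) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Stack the unique off-diagonal edges of many FC matrices.

    Returns (subjects x E matrix, list of (i, j) edge index pairs).
    """
    n = fcs[0].matrix.shape[0]
    iu = np.triu_indices(n, k=1)
    X = np.stack([fc.matrix[iu] for fc in fcs])
    return X, list(zip(iu[0].tolist(), iu[1].tolist()))


def _welch_components(s1, ss1, n1, s2, ss2, n2):
    """Welch t from per-group sums and sums of squares (ddof=1)."""
    m1, m2 = s1 / n1, s2 / n2
    v1 = np.clip(ss1 / n1 - m1 * m1, 0.0, None) * (n1 / (n1 - 1))
    v2 = np.clip(ss2 / n2 - m2 * m2, 0.0, None) * (n2 / (n2 - 1))
    denom = np.sqrt(v1 / n1 + v2 / n2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, (m1 - m2) / np.where(denom > 0, denom, 1.0), 0.0)
    return t


def permutation_ttest_edges(
    edge_matrix: np.ndarray,
    groups: Sequence[str],
    n_perm: int = 1000,
    seed: int = 0,
    fwe: bool = False,
    chunk: int = 200,
) -> EdgeTestResult:
    """Edge-wise permutation Welch t-test between the two groups.

    Parameters
    ----------
    edge_matrix : ndarray, shape (subjects, E)
        One row per subject of vectorised unique edges.
    groups : sequence
        Group label per subject.
    fwe : bool
        Additionally compute family-wise corrected p-values from the
        permutation distribution of the maximum |t| across edges.
    chunk : int
        Permutations processed per block (memory control at large E).
    """
    X = np.asarray(edge_matrix, dtype=float)
    groups = np.asarray(groups, dtype=object)
    if X.ndim != 2 or groups.shape[0] != X.shape[0]:
        raise ValueError("edge_matrix must be subjects x E with one label "
                         "per subject")
    present = set(np.unique(groups))
    if not present <= set(GROUP_LABELS) or len(present) < 2:
        raise ValueError("both groups must be present")
    is_a = groups == GROUP_LABELS[0]
    n1, n2 = int(is_a.sum()), int((~is_a).sum())
    if min(n1, n2) < 2:
        raise ValueError("each group needs at least 2 subjects")

    X2 = X * X
    tot_s, tot_ss = X.sum(axis=0), X2.sum(axis=0)
    s1, ss1 = X[is_a].sum(axis=0), X2[is_a].sum(axis=0)
    t_obs = _welch_components(s1, ss1, n1, tot_s - s1, tot_ss - ss1, n2)
    degenerate = (X.var(axis=0) == 0)
    t_obs[degenerate] = 0.0

    rng = np.random.default_rng(seed)
    abs_obs = np.abs(t_obs)
    count = np.zeros(X.shape[1])
    max_null = np.empty(n_perm) if fwe else None
    done = 0
    while done < n_perm:
        b = min(chunk, n_perm - done)
        sel = np.zeros((b, X.shape[0]))
        for r in range(b):
            sel[r, rng.choice(X.shape[0], size=n1, replace=False)] = 1.0
        s1p = sel @ X
        ss1p = sel @ X2
        t_p = _welch_components(s1p, ss1p, n1, tot_s - s1p, tot_ss - ss1p, n2)
        abs_p = np.abs(t_p)
        count += (abs_p >= abs_obs).sum(axis=0)
        if fwe:
            max_null[done : done + b] = abs_p.max(axis=1)
        done += b
    p = (count + 1.0) / (n_perm + 1.0)
    p[degenerate] = 1.0
    p_fwe = None
    if fwe:
        exceed = (max_null[None, :] >= abs_obs[:, None]).sum(axis=1)
        p_fwe = (exceed + 1.0) / (n_perm + 1.0)
        p_fwe[degenerate] = 1.0
    group_means = {
        GROUP_LABELS[0]: X[is_a].mean(axis=0),
        GROUP_LABELS[1]: X[~is_a].mean(axis=0),
    }
    return EdgeTestResult(t=t_obs, p=p, p_fwe=p_fwe, group_means=group_means,
                          degenerate=degenerate, n_perm=n_perm)


def _standardize(x: np.ndarray, name: str, dropped: list) -> np.ndarray | None:
    sd = x.std()
    if sd == 0:
        dropped.append(name)
        return None
    return (x - x.mean()) / sd


def fit_delirium_logistic(
    outcome: np.ndarray,
    predictor: np.ndarray,
    covariate: np.ndarray,
    form: str = "interaction",
) -> RegressionResult:
    """Binomial GLM (IRLS) for the delirium outcome.

    ``interaction`` includes both main effects and the product term of
    the standardized predictor and covariate.  Zero-variance terms are
    dropped with a flag (an all-zero predictor and covariate reduce the
    model to intercept-only).  Perfect separation is detected and
    flagged, never silently reported as a valid fit.
    """
    if form not in MODEL_FORMS:
        raise ValueError(f"form must be one of {MODEL_FORMS}")
    y = np.asarray(outcome, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("outcome must contain both classes")
    dropped: list[str] = []
    terms: dict[str, np.ndarray] = {}
    p = _standardize(np.asarray(predictor, float), "predictor", dropped)
    c = _standardize(np.asarray(covariate, float), "covariate", dropped)
    if form in ("predictor_only", "additive", "interaction") and p is not None:
        terms["predictor"] = p
    if form in ("covariate_only", "additive", "interaction") and c is not None:
        terms["covariate"] = c
    if form == "interaction" and p is not None and c is not None:
        terms["predictor:covariate"] = p * c
    names = ["intercept"] + list(terms)
    X = np.column_stack([np.ones_like(y)] + list(terms.values()))

    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        model = sm.GLM(y, X, family=sm.families.Binomial())
        try:
            res = model.fit(maxiter=100)
        except PerfectSeparationError:
            nan = pd.Series(np.full(len(names), np.nan), index=names)
            return RegressionResult(
                form=form, params=nan, bse=nan.copy(), pvalues=nan.copy(),
                loglik=float("nan"), aic=float("nan"), n_obs=int(y.size),
                converged=False, separation_flag=True, dropped_terms=dropped,
            )
        except Exception as exc:  # pragma: no cover - defensive
            raise RuntimeError(f"logistic fit failed for form {form!r}: {exc}")
    if not getattr(res, "converged", True):
        raise RuntimeError(
            f"IRLS did not converge within 100 iterations for form {form!r}"
        )
    fitted = res.fittedvalues
    separation = bool(
        np.all((fitted > 1 - 1e-8) == (y == 1)) and np.all(np.abs(fitted - y) < 1e-8)
    ) or any("Perfect" in str(w.message) for w in caught)

    aic = -2.0 * res.llf + 2.0 * X.shape[1]
    if not np.isclose(aic, res.aic, rtol=0, atol=1e-6):
        raise AssertionError("AIC identity -2 loglik + 2k violated")
    return RegressionResult(
        form=form,
        params=pd.Series(res.params, index=names),
        bse=pd.Series(res.bse, index=names),
        pvalues=pd.Series(res.pvalues, index=names),
        loglik=float(res.llf),
        aic=float(aic),
        n_obs=int(y.size),
        converged=bool(res.converged),
        separation_flag=separation,
        dropped_terms=dropped,
    )


def compare_models_aic(results: Sequence[RegressionResult]) -> pd.DataFrame:
    """Rank fitted models by AIC (ascending; stable for ties).

    All models must be fitted on the same subjects, otherwise their AICs
    are not comparable.
    """
    if len(results) < 2:
        raise ValueError("need at least two models to compare")
    n = {r.n_obs for r in results}
    if len(n) > 1:
        raise ValueError(f"models fitted on differing subject sets: n={sorted(n)}")
    df = pd.DataFrame(
        {
            "form": [r.form for r in results],
            "aic": [r.aic for r in results],
            "loglik": [r.loglik for r in results],
            "n_params": [r.n_params for r in results],
        }
    )
    df = df.sort_values("aic", kind="stable").reset_index(drop=True)
    df["delta_aic"] = df["aic"] - df["aic"].iloc[0]
    return df


def bh_fdr(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def biomarker_correlation(
    subject_values: np.ndarray, biomarker: np.ndarray
) -> tuple[float, float, float]:
    """Pearson correlation of a per-subject measure with a biomarker.

    Returns (r, two-sided t-based p, BH q).  For a single call the BH
    adjustment is the identity; apply :func:`bh_fdr` across region sets
    to obtain joint q-values.
    """
    x = np.asarray(subject_values, dtype=float)
    y = np.asarray(biomarker, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValueError("need matched samples with n >= 4")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("values must be finite")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero-variance input")
    r, p = stats.pearsonr(x, y)
    q = bh_fdr(np.array([p]))[0]
    return float(r), float(p), float(q)
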