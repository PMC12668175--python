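"""Regional gene-expression association with network topology maps.

The pipeline mirrors standard transcriptomic-imaging practice: per-gene
outlier-robust scaled-sigmoid normalisation followed by z-scoring across
regions; principal-component reduction of the gene panel keeping the
smallest number of components whose cumulative explained variance
reaches a threshold (80% by default); correlation of each component's
regional scores with a topology map, assessed against a spatial null
built by spinning parcel centroids on the sphere; Benjamini-Hochberg
correction across components; and Williams-Hotelling tests comparing
the dependent correlations (which share the topology map) pairwise.

The default cholinergic gene panel holds nicotinic and muscarinic
receptor subunits, synthesis/transport genes and degradation enzymes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import linear_sum_assignment
from scipy.special import expit
from scipy.stats import special_ortho_group

from .group_inference import bh_fdr
from .preprocess_io import ParcelGeometry

__all__ = [
    "CHOLINERGIC_PANEL",
    "GeneExpressionMatrix",
    "ComponentSet",
    "SpinTestResult",
    "normalize_expression",
    "pca_expression",
    "select_k",
    "spin_permutation",
    "spin_rotation_permutation",
    "williams_hotelling",
    "rank_components",
    "effect_size_class",
]

#: Cholinergic receptor / neurotransmission / clearance gene panel:
#: nicotinic subunits, muscarinic receptors, synthesis (CHAT), choline
#: and vesicular ACh transporters, and the two degradation esterases.
CHOLINERGIC_PANEL = [
    "CHRNA1", "CHRNA2", "CHRNA3", "CHRNA4", "CHRNA5", "CHRNA6", "CHRNA7",
    "CHRNB1", "CHRNB2", "CHRNB3", "CHRNB4",
    "CHRM1", "CHRM2", "CHRM3", "CHRM4", "CHRM5",
    "CHAT", "SLC18A3", "SLC44A2", "SLC44A5", "SLC5A7", "SLC44A1",
    "ACHE", "BCHE",
]


@dataclass
class GeneExpressionMatrix:
    """N regions x G genes expression with a normalisation state flag."""

    values: np.ndarray
    gene_symbols: Sequence[str]
    region_labels: Sequence[str]
    state: str = "raw"  # raw | sigmoid | zscored

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_symbols = list(self.gene_symbols)
        self.region_labels = list(self.region_labels)
        if self.values.shape != (len(self.region_labels), len(self.gene_symbols)):
            raise ValueError("values must be regions x genes")
        if self.state not in ("raw", "sigmoid", "zscored"):
            raise ValueError("state must be raw, sigmoid or zscored")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression contains non-finite values")

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]


@dataclass
class ComponentSet:
    """Principal components of the gene panel retained at a variance cut."""

    loadings: np.ndarray          # G x k, unit eigenvectors
    scores: np.ndarray            # N x k regional component scores
    explained_ratio: np.ndarray   # full spectrum, non-increasing
    eigenvalues: np.ndarray       # full spectrum of the gene covariance
    k: int
    var_threshold: float


@dataclass
class SpinTestResult:
    """Observed map correlation with its spatial-rotation null."""

    observed: float
    p_spin: float
    n_perm: int
    method: str
    null_sample: np.ndarray


def normalize_expression(raw: GeneExpressionMatrix) -> GeneExpressionMatrix:
    """Outlier-robust scaled-sigmoid normalisation, then z-scoring.

    Per gene x: ``sigmoid((x - median) / (IQR / 1.35))``, min-max rescaled
    to [0, 1], then z-scored across regions.  The IQR/1.35 scale makes
    the sigmoid slope match a normal SD, so moderate values map almost
    linearly while extreme outliers saturate.
    """
    if raw.state != "raw":
        raise ValueError("expected a raw expression matrix")
    X = raw.values
    med = np.median(X, axis=0)
    q75, q25 = np.percentile(X, [75, 25], axis=0)
    iqr = q75 - q25
    zero = iqr == 0
    if zero.any():
        sym = [raw.gene_symbols[g] for g in np.flatnonzero(zero)]
        raise ValueError(f"zero IQR for gene(s) {sym}; cannot normalise")
    S = expit((X - med) / (iqr / 1.35))
    S = (S - S.min(axis=0)) / (S.max(axis=0) - S.min(axis=0))
    Z = (S - S.mean(axis=0)) / S.std(axis=0)
    return GeneExpressionMatrix(Z, raw.gene_symbols, raw.region_labels,
                                state="zscored")


def select_k(explained_ratio: np.ndarray, var_threshold: float) -> int:
    """Smallest k whose cumulative explained variance reaches the cut."""
    if not 0 < var_threshold <= 1:
        raise ValueError("var_threshold must be in (0, 1]")
    cum = np.cumsum(explained_ratio)
    return int(np.searchsorted(cum, var_threshold - 1e-12) + 1)


def pca_expression(
    mat: GeneExpressionMatrix, var_threshold: float = 0.8
) -> ComponentSet:
    """PCA of the z-scored gene matrix, keeping 80% cumulative variance.

    Eigen-decomposition of the gene-gene correlation structure (the
    population covariance of z-scored columns); the eigenvalue sum
    therefore equals the number of genes.  Component signs are fixed so
    each loading vector's largest-|value| entry is positive.
    """
    if mat.state != "zscored":
        raise ValueError("pca_expression expects a z-scored matrix")
    if mat.n_regions <= mat.n_genes:
        warnings.warn("fewer regions than genes; components may be unstable",
                      RuntimeWarning, stacklevel=2)
    X = mat.values
    n = X.shape[0]
    C = X.T @ X / n  # population covariance of z-scored columns
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1]
    evals, evecs = np.clip(evals[order], 0.0, None), evecs[:, order]
    ratio = evals / evals.sum()
    k = select_k(ratio, var_threshold)
    V = evecs[:, :k]
    flip = np.sign(V[np.argmax(np.abs(V), axis=0), np.arange(k)])
    flip[flip == 0] = 1.0
    V = V * flip
    scores = X @ V
    return ComponentSet(loadings=V, scores=scores, explained_ratio=ratio,
                        eigenvalues=evals, k=k, var_threshold=var_threshold)


# ---------------------------------------------------------------------------
# spin permutation
# ---------------------------------------------------------------------------


def spin_rotation_permutation(
    geometry: ParcelGeometry, rotation: np.ndarray
) -> np.ndarray:
    """Region permutation induced by one rotation of the sphere.

    The rotation is applied to the right-hemisphere centroids and its
    x-mirrored version to the left hemisphere; rotated centroids are
    matched back to original ones by optimal (Hungarian) assignment on
    geodesic distance, which guarantees a bijection.  Entry ``perm[i]``
    is the source region whose value region ``i`` receives.
    """
    mirror = np.diag([-1.0, 1.0, 1.0])
    perm = np.empty(geometry.n_regions, dtype=int)
    for hemi, R in (("R", rotation), ("L", mirror @ rotation @ mirror)):
        idx = geometry.hemisphere_indices(hemi)
        if idx.size == 0:
            continue
        pts = geometry.coords[idx]
        rotated = pts @ R.T
        cost = -pts @ rotated.T  # maximise cosine similarity
        rows, cols = linear_sum_assignment(cost)
        perm[idx[rows]] = idx[cols]
    return perm


def _map_correlation(a: np.ndarray, b: np.ndarray, method: str) -> float:
    if method == "pearson":
        return float(np.corrcoef(a, b)[0, 1])
    if method == "spearman":
        return float(stats.spearmanr(a, b).statistic)
    raise ValueError("method must be 'pearson' or 'spearman'")


def spin_permutation(
    map_a: np.ndarray,
    map_b: np.ndarray,
    geometry: ParcelGeometry,
    n_perm: int = 1000,
    method: str = "spearman",
    seed: int = 0,
) -> SpinTestResult:
    """Spatial-null correlation test between two regional maps.

    The null rotates ``map_a``'s parcel assignment with uniformly random
    3-D rotations (mirrored across hemispheres) and recomputes the
    correlation with ``map_b``; the two-sided p-value uses the add-one
    convention on |r|.
    """
    a = np.asarray(map_a, dtype=float)
    b = np.asarray(map_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("maps must be 1-D and of equal length")
    if a.size != geometry.n_regions:
        raise ValueError("geometry does not cover the maps")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("maps must be finite")
    for hemi in ("L", "R"):
        pts = geometry.coords[geometry.hemisphere_indices(hemi)]
        if pts.shape[0] != np.unique(np.round(pts, 12), axis=0).shape[0]:
            raise ValueError(f"duplicate centroids in hemisphere {hemi}")
    if method == "spearman":
        # a permutation commutes with ranking, so pre-rank both maps and
        # use Pearson on ranks inside the loop
        a_work = stats.rankdata(a)
        b_work = stats.rankdata(b)
        corr = lambda x, y: float(np.corrcoef(x, y)[0, 1])
    elif method == "pearson":
        a_work, b_work = a, b
        corr = lambda x, y: float(np.corrcoef(x, y)[0, 1])
    else:
        raise ValueError("method must be 'pearson' or 'spearman'")
    observed = corr(a_work, b_work)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        R = special_ortho_group.rvs(3, random_state=rng)
        perm = spin_rotation_permutation(geometry, R)
        null[i] = corr(a_work[perm], b_work)
    p = (np.sum(np.abs(null) >= abs(observed)) + 1.0) / (n_perm + 1.0)
    return SpinTestResult(observed=float(observed), p_spin=float(p),
                          n_perm=n_perm, method=method, null_sample=null)


# ---------------------------------------------------------------------------
# dependent-correlation comparison
# ---------------------------------------------------------------------------


def williams_hotelling(
    r12: float, r13: float, r23: float, n: int
) -> tuple[float, float, int]:
    """Williams' t for two dependent correlations sharing variable 1.

    Compares r12 against r13 given the correlation r23 between the two
    non-shared variables.  Returns (T, two-sided p, df) with df = n - 3.
    T is antisymmetric in (r12, r13) and exactly 0 when they are equal.
    """
    if n < 5:
        raise ValueError("need n >= 5")
    for r in (r12, r13):
        if not -1 < r < 1:
            raise ValueError("correlations must lie in (-1, 1)")
    if not -1 <= r23 <= 1:
        raise ValueError("correlations must lie in [-1, 1]")
    df = n - 3
    if r12 == r13:
        # equal correlations (e.g. a component against its duplicate)
        return 0.0, 1.0, int(df)
    det = 1 - r12**2 - r13**2 - r23**2 + 2 * r12 * r13 * r23
    if det <= 0:
        raise ValueError("inconsistent correlation triple (non-PSD)")
    rbar = 0.5 * (r12 + r13)
    denom = 2 * ((n - 1) / (n - 3)) * det + rbar**2 * (1 - r23) ** 3
    T = (r12 - r13) * np.sqrt((n - 1) * (1 + r23) / denom)
    p = 2 * stats.t.sf(abs(T), df)
    return float(T), float(p), int(df)


def effect_size_class(r: float) -> str:
    """Correlation effect-size label (|r| = 0.1 / 0.3 / 0.5 cuts)."""
    a = abs(r)
    if a < 0.1:
        return "negligible"
    if a < 0.3:
        return "small"
    if a < 0.5:
        return "medium"
    return "large"


def rank_components(
    results: Sequence[SpinTestResult],
    n: int,
    scores: np.ndarray,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Rank component-map associations and compare them pairwise.

    Parameters
    ----------
    results : sequence of SpinTestResult
        One spin test per component against the same topology map.
    n : int
        Number of regions the correlations were computed over.
    scores : ndarray, shape (N, k)
        Regional component scores, needed for the correlations between
        components that enter the Williams-Hotelling comparisons.

    Returns
    -------
    (component_table, pairwise_table)
        Components with FDR q, |r| ranking and effect-size class; and
        all k(k-1)/2 pairwise Williams-Hotelling tests with FDR.
    """
    k = len(results)
    if k < 2:
        raise ValueError("need at least 2 components")
    scores = np.asarray(scores, dtype=float)
    if scores.shape[1] != k:
        raise ValueError("scores must have one column per component")
    method = results[0].method
    rvals = np.array([r.observed for r in results])
    pvals = np.array([r.p_spin for r in results])
    q = bh_fdr(pvals)
    order = np.argsort(-np.abs(rvals), kind="stable")
    rank = np.empty(k, dtype=int)
    rank[order] = np.arange(1, k + 1)
    comp_table = pd.DataFrame(
        {
            "component": np.arange(1, k + 1),
            "r": rvals,
            "p_spin": pvals,
            "q_fdr": q,
            "rank": rank,
            "effect_size": [effect_size_class(r) for r in rvals],
        }
    )
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            r23 = _map_correlation(scores[:, i], scores[:, j], method)
            T, p, df = williams_hotelling(rvals[i], rvals[j], r23, n)
            rows.append({"comp_a": i + 1, "comp_b": j + 1, "r23": r23,
                         "T": T, "p": p, "df": df})
    pair_table = pd.DataFrame(rows)
    pair_table["q_fdr"] = bh_fdr(pair_table["p"].to_numpy())
    return comp_table, pair_table
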