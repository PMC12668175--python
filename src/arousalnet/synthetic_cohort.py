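"""Synthetic preoperative-cohort generator.

Because the clinical resting-state data are ethics-restricted, every
downstream stage is exercised on a generated cohort carrying the
statistical structure those stages assume:

* per-subject T x (N+2) BOLD series drawn from a block-structured
  covariance — correlated within network modules, more weakly between
  them, with the between-module coupling lower in the delirious group
  (plants segregation);
* two appended nucleus columns, ``LC`` and ``nbM``, whose coupling to
  frontal / posterior cortical parcels is shifted in the delirious group
  (noradrenergic hypo-, cholinergic hyper-connectivity);
* Poisson-placed phasic bursts on the nucleus columns, each followed at
  a fixed TR lag by a topology response: a shared global signal after LC
  bursts (drives integration) and module-confined signals after nbM
  bursts (drive segregation);
* a binary delirium outcome whose conditional law given the subject's
  measured segregation summary and the covariate is logistic with a
  pure interaction term (the covariate is drawn conditionally on group
  and measured PC, which induces exactly that logistic form);
* spatially autocorrelated gene-expression maps on the parcel sphere.

Identical configuration and seed reproduce the cohort bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .connectivity import static_fc
from .gene_association import CHOLINERGIC_PANEL, GeneExpressionMatrix
from .preprocess_io import (
    NetworkPartition,
    ParcelGeometry,
    ParcellatedTimeSeries,
    write_centroids,
    write_expression_table,
    write_manifest,
    write_parcellated_timeseries,
    write_partition,
)
from .topology import participation_frame

__all__ = [
    "CohortConfig",
    "CohortBundle",
    "generate_spherical_centroids",
    "generate_cohort",
    "generate_gene_maps",
    "write_cohort",
]

NUCLEUS_LABELS = ("LC", "nbM")


@dataclass
class CohortConfig:
    """Study-condition parameters of the synthetic cohort.

    Defaults emulate the analysed cohort: 60 + 60 subjects, 210 TRs of
    2.6 s, 400 cortical parcels in 17 networks, plus the two arousal
    nuclei.  Correlation and shift defaults are chosen for testability
    (the source study reports group maps, not effect sizes).
    """

    n_delirious: int = 60
    n_control: int = 60
    n_regions: int = 400
    n_networks: int = 17
    n_timepoints: int = 210
    tr_seconds: float = 2.6
    within_module_r: float = 0.35
    between_module_r_control: float = 0.12
    between_module_r_delirium: float = 0.06
    between_module_r_sd: float = 0.06  # per-subject heterogeneity
    nucleus_baseline_r: float = 0.10
    nbm_coupling_shift: float = 0.15
    lc_coupling_shift: float = -0.15
    n_affected: int = 30
    peak_rate: float = 8.0
    peak_topology_lag: int = 1
    peak_amplitude_factor: float = 4.0
    burst_width: int = 3
    integration_bump: float = 1.2
    segregation_bump: float = 1.2
    interaction_beta: float = -1.5
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("within_module_r", "between_module_r_control",
                     "between_module_r_delirium", "nucleus_baseline_r"):
            v = getattr(self, name)
            if not -1 < v < 1:
                raise ValueError(f"{name} must lie in (-1, 1), got {v}")
        if not 0 <= self.within_module_r < 1:
            raise ValueError("within_module_r must lie in [0, 1)")
        if self.n_regions < 2 or self.n_regions % 2:
            raise ValueError("n_regions must be an even count >= 2")
        if self.n_networks < 1 or self.n_networks > self.n_regions:
            raise ValueError("n_networks must lie in [1, n_regions]")
        if self.n_timepoints < 8:
            raise ValueError("n_timepoints too small")
        if self.noise_sd <= 0 or self.tr_seconds <= 0:
            raise ValueError("noise_sd and tr_seconds must be positive")
        if self.n_affected > self.n_regions // 2:
            raise ValueError("n_affected cannot exceed half the parcels")


@dataclass
class CohortBundle:
    """Everything the pipeline consumes, plus the planted ground truth."""

    config: CohortConfig
    timeseries: list
    partition: NetworkPartition
    geometry: ParcelGeometry
    outcomes: pd.Series       # subject_id -> 1 (delirious) / 0
    covariates: pd.DataFrame  # subject_id -> delta_change, ptau
    truth: dict

    def __post_init__(self) -> None:
        ids = [ts.subject_id for ts in self.timeseries]
        if list(self.outcomes.index) != ids or list(self.covariates.index) != ids:
            raise ValueError("one outcome and covariate row per subject, "
                             "in subject order")
        n_cortex = self.partition.n_regions
        for key in ("lc_affected", "nbm_affected"):
            idx = np.asarray(self.truth[key])
            if idx.size and (idx.min() < 0 or idx.max() >= n_cortex):
                raise ValueError(f"truth[{key!r}] lists invalid region indices")

    @property
    def groups(self) -> dict:
        return {ts.subject_id: ts.group for ts in self.timeseries}

    def manifest(self) -> pd.DataFrame:
        rows = pd.DataFrame(
            {
                "subject_id": [ts.subject_id for ts in self.timeseries],
                "group": [ts.group for ts in self.timeseries],
            }
        )
        return pd.concat(
            [rows, self.covariates.reset_index(drop=True)], axis=1
        )


def generate_spherical_centroids(n_regions: int, seed: int) -> ParcelGeometry:
    """Mirror-symmetric quasi-uniform parcel centroids on the unit sphere.

    Half the regions lie on the right hemisphere (x > 0) on a Fibonacci
    lattice folded onto the hemisphere, rotated about the x-axis by a
    seed-dependent angle; the left hemisphere is the x-mirror image.
    """
    if n_regions < 2:
        raise ValueError("need at least 2 regions")
    if n_regions % 2:
        raise ValueError("n_regions must be even (hemispheres must balance)")
    half = n_regions // 2
    i = np.arange(half)
    golden = (1 + 5**0.5) / 2
    z = 1 - (2 * i + 1) / half  # midpoints, quasi-uniform in z over (-1, 1)
    theta = 2 * np.pi * i / golden
    r = np.sqrt(np.clip(1 - z * z, 0, None))
    pts = np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
    pts[:, 0] = np.abs(pts[:, 0]) + 1e-6  # fold onto x > 0
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    # seed-dependent rotation about x keeps the hemisphere split
    ang = np.random.default_rng(seed).uniform(0, 2 * np.pi)
    rot = np.array(
        [[1, 0, 0],
         [0, np.cos(ang), -np.sin(ang)],
         [0, np.sin(ang), np.cos(ang)]]
    )
    right = pts @ rot.T
    left = right * np.array([-1.0, 1.0, 1.0])
    coords = np.vstack([left, right])
    labels = [f"ctx_{i:03d}" for i in range(n_regions)]
    hemis = np.array(["L"] * half + ["R"] * half, dtype=object)
    return ParcelGeometry(labels, coords, hemis)


def _nearest_psd(cov: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Eigenvalue-clipped nearest-PSD repair, unit diagonal restored."""
    evals, evecs = np.linalg.eigh(cov)
    if evals.min() >= eps:
        return cov
    clipped = (evecs * np.clip(evals, eps, None)) @ evecs.T
    d = np.sqrt(np.diag(clipped))
    out = clipped / np.outer(d, d)
    if np.linalg.eigvalsh(out).min() < -1e-10:
        raise ValueError("covariance not PSD after repair")
    return out


def _subject_covariance(cfg: CohortConfig, module_ids: np.ndarray,
                        delirious: bool, between: float,
                        frontal: np.ndarray,
                        posterior: np.ndarray) -> np.ndarray:
    n = cfg.n_regions
    same = module_ids[:, None] == module_ids[None, :]
    C = np.where(same, cfg.within_module_r, between)
    full = np.empty((n + 2, n + 2))
    full[:n, :n] = C
    lc = np.full(n, cfg.nucleus_baseline_r)
    nbm = np.full(n, cfg.nucleus_baseline_r)
    if delirious:
        lc[frontal] += cfg.lc_coupling_shift
        nbm[posterior] += cfg.nbm_coupling_shift
    full[n, :n] = full[:n, n] = lc
    full[n + 1, :n] = full[:n, n + 1] = nbm
    full[n, n + 1] = full[n + 1, n] = cfg.nucleus_baseline_r
    np.fill_diagonal(full, 1.0)
    return _nearest_psd(full)


def _place_bursts(rng: np.random.Generator, cfg: CohortConfig) -> np.ndarray:
    """Poisson number of burst onset times, edge-avoiding, separated."""
    margin, min_sep = 10, 10
    n = rng.poisson(cfg.peak_rate)
    times: list[int] = []
    candidates = rng.integers(margin, cfg.n_timepoints - margin,
                              size=max(4 * n, 1))
    for t in candidates:
        if len(times) >= n:
            break
        if all(abs(int(t) - u) >= min_sep for u in times):
            times.append(int(t))
    return np.array(sorted(times), dtype=int)


def _half_cosine(width: int) -> np.ndarray:
    return np.sin(np.pi * (np.arange(width) + 0.5) / width)


def _add_bump(column: np.ndarray, t0: int, width: int, amp: float) -> None:
    hi = min(t0 + width, column.shape[0])
    column[t0:hi] += amp * _half_cosine(width)[: hi - t0]


def generate_cohort(config: CohortConfig) -> CohortBundle:
    """Draw the full synthetic cohort for the given configuration."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    geometry = generate_spherical_centroids(cfg.n_regions, cfg.seed)
    module_ids = np.arange(cfg.n_regions) * cfg.n_networks // cfg.n_regions
    cortical_labels = list(geometry.region_labels)
    partition = NetworkPartition(cortical_labels, module_ids)

    # anterior (largest y) and posterior (smallest y) parcel sets
    y = geometry.coords[:, 1]
    frontal = np.sort(np.argsort(-y)[: cfg.n_affected])
    posterior = np.sort(np.argsort(y)[: cfg.n_affected])

    n_total = cfg.n_delirious + cfg.n_control
    labels_full = cortical_labels + list(NUCLEUS_LABELS)
    module_sizes = np.bincount(module_ids, minlength=cfg.n_networks)

    timeseries = []
    peak_truth: dict[str, dict[str, np.ndarray]] = {}
    pc_summary = np.empty(n_total)
    nbm_mean_fc = np.empty(n_total)
    groups = (["delirious"] * cfg.n_delirious + ["non_delirious"] * cfg.n_control)
    subject_ids = [f"sub-{i + 1:03d}" for i in range(n_total)]

    amp = cfg.peak_amplitude_factor * cfg.noise_sd
    for s, (sid, group) in enumerate(zip(subject_ids, groups)):
        delirious = group == "delirious"
        # per-subject heterogeneity in between-module coupling keeps the
        # group PC distributions overlapping, as in real cohorts
        base = (cfg.between_module_r_delirium if delirious
                else cfg.between_module_r_control)
        between = float(np.clip(
            rng.normal(base, cfg.between_module_r_sd),
            -0.3, cfg.within_module_r - 0.02))
        cov = _subject_covariance(cfg, module_ids, delirious, between,
                                  frontal, posterior)
        chol = np.linalg.cholesky(cov + 1e-10 * np.eye(cov.shape[0]))
        Z = rng.standard_normal((cfg.n_timepoints, cfg.n_regions + 2))
        X = cfg.noise_sd * (Z @ chol.T)

        bursts = {}
        for nucleus in NUCLEUS_LABELS:
            times = _place_bursts(rng, cfg)
            bursts[nucleus] = times
            col = cfg.n_regions + NUCLEUS_LABELS.index(nucleus)
            for t0 in times:
                _add_bump(X[:, col], t0, cfg.burst_width, amp)
        # lagged topology response
        for t0 in bursts["LC"]:
            start = t0 + cfg.peak_topology_lag
            if start < cfg.n_timepoints:
                bump = (cfg.integration_bump * cfg.noise_sd
                        * _half_cosine(cfg.burst_width))
                hi = min(start + cfg.burst_width, cfg.n_timepoints)
                X[start:hi, : cfg.n_regions] += bump[: hi - start, None]
        for t0 in bursts["nbM"]:
            start = t0 + cfg.peak_topology_lag
            if start < cfg.n_timepoints:
                signs = rng.choice([-1.0, 1.0], size=cfg.n_networks)
                bump = (cfg.segregation_bump * cfg.noise_sd
                        * _half_cosine(cfg.burst_width))
                hi = min(start + cfg.burst_width, cfg.n_timepoints)
                X[start:hi, : cfg.n_regions] += (
                    bump[: hi - start, None] * signs[module_ids][None, :]
                )
        peak_truth[sid] = bursts

        ts = ParcellatedTimeSeries(sid, group, X, labels_full, cfg.tr_seconds)
        timeseries.append(ts)

        # measured segregation summary: global PC of the time-averaged
        # coupling (correlation of the derivative series)
        dt = np.diff(X[:, : cfg.n_regions], axis=0)
        coupling = np.corrcoef(dt, rowvar=False)
        pc_summary[s] = participation_frame(coupling, partition).mean()
        nbm_mean_fc[s] = float(
            np.mean(static_fc(ts).row("nbM")[: cfg.n_regions])
        )

    # covariate drawn conditionally on (group, measured PC): the induced
    # conditional law of the outcome given (PC, C) is logistic with
    # interaction coefficient interaction_beta on z(PC)*C
    d = np.array([g == "delirious" for g in groups], dtype=float)
    pc_sd = pc_summary.std()
    z_pc = (pc_summary - pc_summary.mean()) / pc_sd if pc_sd > 0 else np.zeros(n_total)
    delta = cfg.interaction_beta / 2.0
    covariate = (2 * d - 1) * delta * z_pc + rng.standard_normal(n_total)
    ptau = 0.5 * (nbm_mean_fc - nbm_mean_fc.mean()) / max(nbm_mean_fc.std(), 1e-12)
    ptau = ptau + 0.5 * rng.standard_normal(n_total) + 2.0

    outcomes = pd.Series(d.astype(int), index=pd.Index(subject_ids,
                                                       name="subject_id"))
    covariates = pd.DataFrame(
        {"delta_change": covariate, "ptau": ptau},
        index=pd.Index(subject_ids, name="subject_id"),
    )
    truth = {
        "lc_affected": frontal,
        "nbm_affected": posterior,
        "lc_shift": cfg.lc_coupling_shift,
        "nbm_shift": cfg.nbm_coupling_shift,
        "peak_times": peak_truth,
        "peak_topology_lag": cfg.peak_topology_lag,
        "interaction_beta": cfg.interaction_beta,
        "pc_summary": pd.Series(pc_summary, index=outcomes.index),
        "module_sizes": module_sizes,
    }
    return CohortBundle(cfg, timeseries, partition, geometry, outcomes,
                        covariates, truth)


def generate_gene_maps(
    n_regions: int,
    n_genes: int,
    spatial_scale: float,
    planted_gradient: dict | None,
    geometry: ParcelGeometry,
    seed: int,
) -> GeneExpressionMatrix:
    """Spatially autocorrelated regional expression maps.

    Each gene is a Gaussian-process draw over geodesic distance between
    parcel centroids (squared-exponential kernel, length-scale
    ``spatial_scale`` in radians) plus white noise.  ``planted_gradient``
    optionally adds a shared anterior-posterior (y-axis) gradient to a
    gene subset: ``{"gene_indices": [...], "weight": float}``.
    """
    if spatial_scale <= 0:
        raise ValueError("spatial_scale must be positive")
    if geometry.n_regions != n_regions:
        raise ValueError(
            f"geometry holds {geometry.n_regions} regions, expected {n_regions}"
        )
    rng = np.random.default_rng(seed)
    gram = np.clip(geometry.coords @ geometry.coords.T, -1.0, 1.0)
    theta = np.arccos(gram)
    K = np.exp(-(theta**2) / (2 * spatial_scale**2))
    # the kernel is numerically semidefinite at large scales: use an
    # eigen-clipped square root rather than Cholesky
    evals, evecs = np.linalg.eigh(K)
    L = evecs * np.sqrt(np.clip(evals, 0.0, None))
    smooth = L @ rng.standard_normal((n_regions, n_genes))
    values = smooth + 0.3 * rng.standard_normal((n_regions, n_genes))
    if planted_gradient is not None:
        idx = np.asarray(planted_gradient["gene_indices"], dtype=int)
        weight = float(planted_gradient.get("weight", 1.0))
        grad = geometry.coords[:, 1]
        grad = (grad - grad.mean()) / grad.std()
        values[:, idx] += weight * grad[:, None]
    symbols = (list(CHOLINERGIC_PANEL) if n_genes == len(CHOLINERGIC_PANEL)
               else [f"GENE{i:03d}" for i in range(n_genes)])
    return GeneExpressionMatrix(values, symbols, geometry.region_labels,
                                state="raw")


def write_cohort(bundle: CohortBundle, outdir: str | Path,
                 genes: GeneExpressionMatrix | None = None) -> None:
    """Write the cohort as the TSV layout the readers consume."""
    outdir = Path(outdir)
    (outdir / "timeseries").mkdir(parents=True, exist_ok=True)
    for ts in bundle.timeseries:
        write_parcellated_timeseries(
            ts, outdir / "timeseries" / f"{ts.subject_id}.tsv"
        )
    write_manifest(bundle.manifest(), outdir / "manifest.tsv")
    write_partition(bundle.partition, outdir / "partition.tsv")
    write_centroids(bundle.geometry, outdir / "centroids.tsv")
    if genes is not None:
        df = pd.DataFrame(genes.values, index=genes.region_labels,
                          columns=genes.gene_symbols)
        write_expression_table(df, outdir / "genes.tsv")
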