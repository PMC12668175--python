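"""End-to-end analysis over a (synthetic or on-disk) cohort.

Runs every stage in order on parcellated series: static FC, seed and
full MTD dynamic connectivity, time-resolved participation coefficient,
integrated/segregated state clustering, edge-wise permutation tests,
seed LDA with top-time-point contrast maps, phasic peak-locked
profiles with per-lag group tests, outcome logistic models with AIC
ranking, biomarker correlation, and the gene-expression association.

Results are returned as a nested dict of plain tables/arrays and can be
written out as TSVs.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import (
    connectivity,
    discriminant,
    gene_association,
    group_inference,
    phasic_coupling,
    synthetic_cohort,
    topology,
)

from .synthetic_cohort import NUCLEUS_LABELS, CohortBundle, CohortConfig

__all__ = ["run_pipeline", "subject_level_measures", "write_results"]


def subject_level_measures(
    bundle: CohortBundle, window: int = 5
) -> dict:
    """Per-subject connectivity and topology measures.

    For each subject: static FC edge vector and nucleus seed rows, seed
    MTD slices, the PC time course from the full cortical MTD tensor
    (computed transiently, never stored), its global trace, and peak
    sets for both nuclei.
    """
    cfg = bundle.config
    n_cortex = cfg.n_regions
    cortical = bundle.partition.region_labels
    part = bundle.partition

    pc_frames = []        # per subject W x N
    global_traces = []
    seed_dfc = {n: [] for n in NUCLEUS_LABELS}
    edge_rows = []
    seed_fc = {n: [] for n in NUCLEUS_LABELS}
    peaks = {n: [] for n in NUCLEUS_LABELS}
    for ts in bundle.timeseries:
        fc = connectivity.static_fc(ts)
        edge_rows.append(fc.matrix[np.triu_indices(n_cortex + 2, k=1)])
        for nuc in NUCLEUS_LABELS:
            seed_fc[nuc].append(fc.row(nuc)[:n_cortex])
            sl = connectivity.mtd_seed(ts, nuc, w=window)
            seed_dfc[nuc].append(sl.data[:, :n_cortex])
            peaks[nuc].append(
                phasic_coupling.detect_phasic_peaks(
                    ts.column(nuc), subject_id=ts.subject_id, nucleus=nuc
                )
            )
        sub = type(ts)(ts.subject_id, ts.group, ts.data[:, :n_cortex],
                       cortical, ts.tr_seconds)
        dfc = connectivity.mtd(sub, w=window)
        pc = topology.participation_timecourse(dfc, part)
        pc_frames.append(pc.data)
        global_traces.append(pc.global_trace)
    return {
        "pc_frames": pc_frames,
        "global_traces": global_traces,
        "seed_dfc": seed_dfc,
        "edge_matrix": np.stack(edge_rows),
        "seed_fc": {n: np.stack(v) for n, v in seed_fc.items()},
        "peaks": peaks,
        "window": window,
    }


def _two_sample_perm_p(a: np.ndarray, b: np.ndarray, n_perm: int,
                       rng: np.random.Generator) -> float:
    """Two-sided permutation p for a difference of means."""
    obs = abs(a.mean() - b.mean())
    pooled = np.concatenate([a, b])
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        if abs(perm[: a.size].mean() - perm[a.size :].mean()) >= obs:
            count += 1
    return (count + 1) / (n_perm + 1)


def run_pipeline(
    config: CohortConfig | None = None,
    bundle: CohortBundle | None = None,
    window: int = 5,
    n_perm: int = 1000,
    kmeans_n_init: int = 100,
    spin_perm: int = 1000,
    lda_fraction: float = 0.05,
    gene_spatial_scale: float = 0.5,
    seed: int = 0,
) -> dict:
    """Run every analysis stage and return a nested results dict."""
    if bundle is None:
        bundle = synthetic_cohort.generate_cohort(config or CohortConfig())
    cfg = bundle.config
    rng = np.random.default_rng(seed)
    groups_by_subject = bundle.groups
    subject_ids = [ts.subject_id for ts in bundle.timeseries]
    group_arr = np.array([groups_by_subject[s] for s in subject_ids],
                         dtype=object)

    measures = subject_level_measures(bundle, window=window)
    results: dict = {"config": asdict(cfg)}

    # --- participation coefficient and states -------------------------
    mean_pc = np.array([f.mean() for f in measures["pc_frames"]])
    is_del = group_arr == "delirious"
    results["mean_pc"] = {
        "delirious": float(mean_pc[is_del].mean()),
        "non_delirious": float(mean_pc[~is_del].mean()),
        "per_subject": pd.Series(mean_pc, index=subject_ids),
        "permutation_p": _two_sample_perm_p(
            mean_pc[is_del], mean_pc[~is_del], n_perm, rng
        ),
    }
    stacked_pc = np.vstack(measures["pc_frames"])
    frames_per_subject = measures["pc_frames"][0].shape[0]
    row_subjects = np.repeat(subject_ids, frames_per_subject)
    states = topology.classify_states(stacked_pc, n_init=kmeans_n_init,
                                      seed=seed)
    occupancy, per_subject_occ = topology.state_occupancy(
        states, row_subjects, groups_by_subject
    )
    results["states"] = {
        "occupancy": occupancy,
        "per_subject": per_subject_occ,
        "cluster_mean_pc": states.cluster_mean_pc,
    }

    # --- edge-wise static FC group test -------------------------------
    edge_test = group_inference.permutation_ttest_edges(
        measures["edge_matrix"], group_arr, n_perm=n_perm,
        seed=int(rng.integers(2**31)),
    )
    results["edge_test"] = edge_test
    # seed-specific static differences (group means of seed rows)
    results["seed_fc_contrast"] = {
        nuc: measures["seed_fc"][nuc][is_del].mean(axis=0)
        - measures["seed_fc"][nuc][~is_del].mean(axis=0)
        for nuc in NUCLEUS_LABELS
    }

    # --- seed LDA -------------------------------------------------------
    results["lda"] = {}
    for nuc in NUCLEUS_LABELS:
        stack = np.vstack(measures["seed_dfc"][nuc])
        frame_groups = np.repeat(group_arr, stack.shape[0] // len(subject_ids))
        fit = discriminant.fit_lda(stack, frame_groups,
                                   feature_labels=bundle.partition.region_labels)
        sel = discriminant.select_top_timepoints(fit, fraction=lda_fraction)
        contrast = discriminant.contrast_dfc(
            stack, sel, frame_groups,
            feature_labels=bundle.partition.region_labels,
        )
        results["lda"][nuc] = {"fit": fit, "selected": sel,
                               "contrast": contrast}

    # --- phasic peak-locked profiles ------------------------------------
    results["phasic"] = {}
    for nuc in NUCLEUS_LABELS:
        profiles = []
        for trace, pk in zip(measures["global_traces"],
                             measures["peaks"][nuc]):
            prof = phasic_coupling.peak_locked_profile(
                trace, pk, max_lag=5, frame_offset=1
            )
            profiles.append(prof.values)
        profiles = np.vstack(profiles)
        stats_table = phasic_coupling.compare_profiles(
            profiles, group_arr, n_perm=n_perm,
            seed=int(rng.integers(2**31)),
        )
        results["phasic"][nuc] = {
            "profiles": profiles,
            "mean_profile": {
                "delirious": profiles[is_del].mean(axis=0),
                "non_delirious": profiles[~is_del].mean(axis=0),
            },
            "stats": stats_table,
        }

    # --- outcome models -------------------------------------------------
    outcome = bundle.outcomes.to_numpy()
    covariate = bundle.covariates["delta_change"].to_numpy()
    fits = [
        group_inference.fit_delirium_logistic(outcome, mean_pc, covariate,
                                              form=f)
        for f in group_inference.MODEL_FORMS
    ]
    results["logistic"] = {
        "fits": {f.form: f for f in fits},
        "aic_ranking": group_inference.compare_models_aic(fits),
    }
    nbm_fc_mean = measures["seed_fc"]["nbM"].mean(axis=1)
    r, p, q = group_inference.biomarker_correlation(
        nbm_fc_mean, bundle.covariates["ptau"].to_numpy()
    )
    results["biomarker"] = {"r": r, "p": p, "q": q}

    # --- gene association -----------------------------------------------
    pc_map = stacked_pc.mean(axis=0)  # regional mean PC over all subjects
    grad_genes = np.arange(8)
    genes_raw = synthetic_cohort.generate_gene_maps(
        cfg.n_regions, len(gene_association.CHOLINERGIC_PANEL),
        gene_spatial_scale,
        {"gene_indices": grad_genes, "weight": 1.0},
        bundle.geometry, seed=int(rng.integers(2**31)),
    )
    genes = gene_association.normalize_expression(genes_raw)
    comps = gene_association.pca_expression(genes, var_threshold=0.8)
    spin_results = [
        gene_association.spin_permutation(
            comps.scores[:, j], pc_map, bundle.geometry, n_perm=spin_perm,
            method="spearman", seed=int(rng.integers(2**31)),
        )
        for j in range(comps.k)
    ]
    comp_table, pair_table = gene_association.rank_components(
        spin_results, n=cfg.n_regions, scores=comps.scores
    )
    results["genes"] = {
        "components": comps,
        "spin": spin_results,
        "component_table": comp_table,
        "pairwise_table": pair_table,
    }
    results["_bundle"] = bundle
    return results


def write_results(results: dict, outdir: str | Path) -> None:
    """Persist the main result tables as TSV/JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results["mean_pc"]["per_subject"].rename("mean_pc").to_csv(
        outdir / "mean_pc.tsv", sep="\t"
    )
    results["states"]["per_subject"].to_csv(outdir / "occupancy.tsv", sep="\t")
    et = results["edge_test"]
    pd.DataFrame({"t": et.t, "p": et.p}).to_csv(
        outdir / "edge_test.tsv", sep="\t", index_label="edge"
    )
    for nuc, block in results["lda"].items():
        pd.DataFrame(
            {
                "region": block["contrast"].feature_labels,
                "coefficient": block["fit"].coefficients,
                "contrast": block["contrast"].values,
            }
        ).to_csv(outdir / f"lda_{nuc}.tsv", sep="\t", index=False)
    for nuc, block in results["phasic"].items():
        block["stats"].to_csv(outdir / f"phasic_{nuc}.tsv", sep="\t",
                              index=False)
    results["logistic"]["aic_ranking"].to_csv(
        outdir / "aic_ranking.tsv", sep="\t", index=False
    )
    results["genes"]["component_table"].to_csv(
        outdir / "gene_components.tsv", sep="\t", index=False
    )
    results["genes"]["pairwise_table"].to_csv(
        outdir / "gene_pairwise.tsv", sep="\t", index=False
    )
    summary = {
        "mean_pc_delirious": results["mean_pc"]["delirious"],
        "mean_pc_non_delirious": results["mean_pc"]["non_delirious"],
        "mean_pc_permutation_p": results["mean_pc"]["permutation_p"],
        "occupancy": results["states"]["occupancy"].to_dict(),
        "best_model": results["logistic"]["aic_ranking"]["form"].iloc[0],
        "biomarker_r": results["biomarker"]["r"],
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2))
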