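import numpy as np
import pytest

from arousalnet.connectivity import static_fc
from arousalnet.preprocess_io import read_manifest, read_parcellated_timeseries
from arousalnet.synthetic_cohort import (
    CohortConfig,
    generate_cohort,
    generate_gene_maps,
    generate_spherical_centroids,
    write_cohort,
)
from conftest import small_config


class TestCentroids:
    def test_unit_norm(self):
        geo = generate_spherical_centroids(400, seed=1)
        np.testing.assert_allclose(
            np.linalg.norm(geo.coords, axis=1), 1.0, atol=1e-12)

    def test_hemispheres_mirror(self):
        geo = generate_spherical_centroids(4, seed=7)
        left = geo.coords[geo.hemisphere_indices("L")]
        right = geo.coords[geo.hemisphere_indices("R")]
        assert left.shape == right.shape == (2, 3)
        mirrored = left * np.array([-1.0, 1.0, 1.0])
        # mirroring x -> -x maps the left set onto the right set
        for p in mirrored:
            assert np.min(np.linalg.norm(right - p, axis=1)) < 1e-9

    def test_deterministic(self):
        a = generate_spherical_centroids(400, seed=1)
        b = generate_spherical_centroids(400, seed=1)
        np.testing.assert_array_equal(a.coords, b.coords)

    def test_odd_count_rejected(self):
        with pytest.raises(ValueError, match="even"):
            generate_spherical_centroids(401, seed=0)

    def test_quasi_uniform_coverage(self):
        # mean nearest-neighbour spacing within a hemisphere should be
        # tight around its median (no large holes or clumps)
        geo = generate_spherical_centroids(200, seed=3)
        right = geo.coords[geo.hemisphere_indices("R")]
        d = np.arccos(np.clip(right @ right.T, -1, 1))
        np.fill_diagonal(d, np.inf)
        nn = d.min(axis=1)
        assert nn.max() / np.median(nn) < 4.0


class TestCohort:
    def test_default_shapes(self):
        cfg = CohortConfig(n_delirious=2, n_control=2, seed=0)
        bundle = generate_cohort(cfg)
        assert len(bundle.timeseries) == 4
        assert bundle.timeseries[0].data.shape == (210, 402)
        assert bundle.timeseries[0].region_labels[-2:] == ["LC", "nbM"]
        assert bundle.partition.n_modules == 17

    def test_bit_identical_under_same_seed(self):
        cfg = small_config(seed=9)
        a, b = generate_cohort(cfg), generate_cohort(cfg)
        for ta, tb in zip(a.timeseries, b.timeseries):
            np.testing.assert_array_equal(ta.data, tb.data)
        np.testing.assert_array_equal(a.covariates.to_numpy(),
                                      b.covariates.to_numpy())

    def test_different_seed_differs(self):
        a = generate_cohort(small_config(seed=1))
        b = generate_cohort(small_config(seed=2))
        assert not np.array_equal(a.timeseries[0].data, b.timeseries[0].data)

    def test_outcomes_match_group_counts(self):
        bundle = generate_cohort(small_config())
        assert bundle.outcomes.sum() == 5
        assert (bundle.outcomes == 0).sum() == 5

    def test_truth_indices_valid(self):
        bundle = generate_cohort(small_config())
        for key in ("lc_affected", "nbm_affected"):
            idx = np.asarray(bundle.truth[key])
            assert idx.size == 8
            assert idx.min() >= 0 and idx.max() < 40

    def test_planted_nbm_hyperconnectivity_recovered(self):
        """Mean static nbM FC over the affected parcels must be higher in
        the delirious group in nearly every seeded replicate."""
        wins = 0
        for rep in range(50):
            cfg = small_config(n_delirious=8, n_control=8,
                               nbm_coupling_shift=0.3, seed=1000 + rep)
            bundle = generate_cohort(cfg)
            affected = bundle.truth["nbm_affected"]
            means = {"delirious": [], "non_delirious": []}
            for ts in bundle.timeseries:
                fc = static_fc(ts)
                means[ts.group].append(fc.row("nbM")[affected].mean())
            if np.mean(means["delirious"]) > np.mean(means["non_delirious"]):
                wins += 1
        assert wins >= 48  # >= 95% of 50 replicates

    def test_planted_lc_hypoconnectivity_recovered(self):
        wins = 0
        for rep in range(20):
            cfg = small_config(n_delirious=8, n_control=8,
                               lc_coupling_shift=-0.3, seed=2000 + rep)
            bundle = generate_cohort(cfg)
            affected = bundle.truth["lc_affected"]
            means = {"delirious": [], "non_delirious": []}
            for ts in bundle.timeseries:
                means[ts.group].append(
                    static_fc(ts).row("LC")[affected].mean())
            if np.mean(means["delirious"]) < np.mean(means["non_delirious"]):
                wins += 1
        assert wins >= 18

    def test_nucleus_bursts_cross_two_sd_threshold(self):
        from arousalnet.phasic_coupling import detect_phasic_peaks

        # a 4-SD-amplitude bump against a threshold the bursts themselves
        # inflate detects ~85% of events; require a clear majority
        bundle = generate_cohort(small_config(seed=4))
        found, planted_total = 0, 0
        for ts in bundle.timeseries:
            for nucleus in ("LC", "nbM"):
                planted = bundle.truth["peak_times"][ts.subject_id][nucleus]
                planted_total += len(planted)
                det = detect_phasic_peaks(ts.column(nucleus)).indices
                found += sum(np.min(np.abs(det - t)) <= 2 if det.size else 0
                             for t in planted)
        assert planted_total > 0
        assert found / planted_total >= 0.7

    def test_segregation_planted_in_delirious_group(self):
        # lower between-module coupling must depress the measured PC
        cfg = small_config(n_delirious=15, n_control=15,
                          between_module_r_control=0.20,
                          between_module_r_delirium=0.05, seed=11)
        bundle = generate_cohort(cfg)
        pc = bundle.truth["pc_summary"]
        groups = bundle.groups
        del_pc = pc[[s for s in pc.index if groups[s] == "delirious"]]
        ctl_pc = pc[[s for s in pc.index if groups[s] == "non_delirious"]]
        assert del_pc.mean() < ctl_pc.mean()

    def test_round_trip_through_writers(self, tmp_path):
        cfg = small_config(n_delirious=2, n_control=2)
        bundle = generate_cohort(cfg)
        write_cohort(bundle, tmp_path)
        mf = read_manifest(tmp_path / "manifest.tsv")
        assert len(mf) == 4
        ts = read_parcellated_timeseries(
            tmp_path / "timeseries" / "sub-001.tsv", "sub-001",
            mf.group.iloc[0], cfg.tr_seconds)
        np.testing.assert_allclose(ts.data, bundle.timeseries[0].data,
                                   atol=1e-9)

    @pytest.mark.parametrize("bad", [
        dict(within_module_r=1.2),
        dict(n_regions=41),
        dict(between_module_r_control=-1.0),
        dict(noise_sd=0.0),
    ])
    def test_invalid_config_rejected(self, bad):
        with pytest.raises(ValueError):
            small_config(**bad)


def moran_like(values, coords, k=5):
    """Average correlation between each region and its k nearest
    neighbours' mean — positive under spatial autocorrelation."""
    d = np.arccos(np.clip(coords @ coords.T, -1, 1))
    np.fill_diagonal(d, np.inf)
    neigh = np.argsort(d, axis=1)[:, :k]
    neighbour_mean = values[neigh].mean(axis=1)
    return np.corrcoef(values, neighbour_mean)[0, 1]


class TestGeneMaps:
    def test_spatial_autocorrelation_positive(self, geometry_100):
        genes = generate_gene_maps(100, 24, 0.5, None, geometry_100, seed=3)
        rng = np.random.default_rng(0)
        stats_obs, stats_null = [], []
        for g in range(genes.n_genes):
            v = genes.values[:, g]
            stats_obs.append(moran_like(v, geometry_100.coords))
            stats_null.append(
                moran_like(rng.permutation(v), geometry_100.coords))
        assert np.mean(stats_obs) > np.mean(stats_null) + 0.2
        assert np.mean(stats_obs) > 0.3

    def test_small_scale_limit_is_white(self, geometry_100):
        genes = generate_gene_maps(100, 24, 1e-4, None, geometry_100, seed=3)
        obs = [moran_like(genes.values[:, g], geometry_100.coords)
               for g in range(24)]
        assert abs(np.mean(obs)) < 0.1

    def test_deterministic(self, geometry_100):
        a = generate_gene_maps(100, 6, 0.5, None, geometry_100, seed=8)
        b = generate_gene_maps(100, 6, 0.5, None, geometry_100, seed=8)
        np.testing.assert_array_equal(a.values, b.values)

    def test_geometry_mismatch_rejected(self, geometry_100):
        with pytest.raises(ValueError, match="geometry"):
            generate_gene_maps(60, 4, 0.5, None, geometry_100, seed=0)

    def test_panel_symbols_used_for_24_genes(self, geometry_100):
        genes = generate_gene_maps(100, 24, 0.5, None, geometry_100, seed=0)
        assert genes.gene_symbols[0] == "CHRNA1"
        assert genes.gene_symbols[-1] == "BCHE"
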