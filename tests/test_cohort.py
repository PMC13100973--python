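"""Synthetic cohort generator: calibration, determinism, structure."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from frailtybrain import (CohortConfig, ConfigurationError, GroupSpec,
                          ItemSpec, generate_connectivity,
                          generate_frailty_scores, generate_item_table,
                          simulate_cohort)
from frailtybrain.cohort import edge_index, edge_names
from frailtybrain.frailty import compute_frailty_index
from frailtybrain.neuro import MassUnivariateOLS


class TestFrailtyScores:
    def test_group_means_match_configured_values(self, table1_scores):
        frailty, group = table1_scores
        for label, n, mean, sd in (("CU", 1924, 0.14, 0.065),
                                   ("AD", 1126, 0.24, 0.075),
                                   ("FTLD", 411, 0.27, 0.10)):
            emp = frailty[group == label].mean()
            assert abs(emp - mean) < 3 * sd / np.sqrt(n), label

    def test_degenerate_sd_collapses_to_mean(self):
        cfg = CohortConfig(groups=(GroupSpec("G", 50, 0.3, 1e-9),), seed=0)
        frailty, _ = generate_frailty_scores(cfg)
        assert np.allclose(frailty, 0.3, atol=1e-7)

    def test_same_seed_reproduces_scores(self):
        cfg = CohortConfig(seed=11)
        a, _ = generate_frailty_scores(cfg)
        b, _ = generate_frailty_scores(CohortConfig(seed=11))
        assert (a == b).all()

    def test_scores_within_unit_interval(self, table1_scores):
        frailty, _ = table1_scores
        assert frailty.between(0, 1).all()

    def test_larger_mean_gives_stochastically_larger_scores(self):
        cfg = CohortConfig(groups=(GroupSpec("lo", 800, 0.1, 0.08),
                                   GroupSpec("hi", 800, 0.4, 0.08)), seed=3)
        frailty, group = generate_frailty_scores(cfg)
        u = stats.mannwhitneyu(frailty[group == "hi"], frailty[group == "lo"],
                               alternative="greater")
        assert u.pvalue < 1e-6

    @pytest.mark.parametrize("bad", [
        dict(groups=(GroupSpec("G", 0, 0.2, 0.1),)),
        dict(groups=(GroupSpec("G", 10, 0.2, 0.0),)),
        dict(groups=(GroupSpec("G", 10, 1.5, 0.1),)),
        dict(missing_rate=1.0),
        dict(n_scanners=0),
    ])
    def test_invalid_config_names_offending_field(self, bad):
        with pytest.raises(ConfigurationError):
            CohortConfig(**bad, seed=0)


class TestItemTable:
    def test_zero_probabilities_give_all_zero_table(self):
        groups = (GroupSpec("G", 40, 0.2, 0.05),)
        items = tuple(ItemSpec(f"i{k}", "physical", {"G": 0.0})
                      for k in range(30))
        cfg = CohortConfig(groups=groups, items=items, seed=0)
        frailty, group = generate_frailty_scores(cfg)
        table = generate_item_table(cfg, frailty, group)
        assert (table == 0).all().all()

    def test_missingness_rate_recovered(self):
        cfg = CohortConfig(groups=(GroupSpec("G", 1000, 0.2, 0.05),),
                           missing_rate=0.1, seed=5)
        frailty, group = generate_frailty_scores(cfg)
        table = generate_item_table(cfg, frailty, group)
        n_cells = table.size
        frac = table.isna().to_numpy().mean()
        se = np.sqrt(0.1 * 0.9 / n_cells)
        assert abs(frac - 0.1) < 3 * se

    def test_index_group_means_match_configured_frailty_means(self,
                                                              table1_config):
        # per-group deficit probability defaults to the group mean frailty,
        # so the deficit-accumulation index mean recovers it
        frailty, group = generate_frailty_scores(table1_config)
        table = generate_item_table(table1_config, frailty, group)
        fi = compute_frailty_index(table)
        for g in ("CU", "AD", "FTLD"):
            spec = next(s for s in table1_config.groups if s.label == g)
            emp = fi.loc[(group == g).to_numpy(), "index"].mean()
            se = np.sqrt(spec.frailty_mean * (1 - spec.frailty_mean)
                         / (32 * spec.n))
            assert abs(emp - spec.frailty_mean) < 4 * se, g

    def test_fewer_than_30_items_warns(self):
        groups = (GroupSpec("G", 10, 0.2, 0.05),)
        items = tuple(ItemSpec(f"i{k}", "physical", {"G": 0.2})
                      for k in range(5))
        cfg = CohortConfig(groups=groups, items=items, seed=0)
        frailty, group = generate_frailty_scores(cfg)
        with pytest.warns(UserWarning, match="30 items"):
            generate_item_table(cfg, frailty, group)


class TestRoiVolumes:
    def _config(self, slopes, noise, n=200, n_scanners=1):
        groups = (GroupSpec("G", n, 0.3, 0.1),)
        return CohortConfig(groups=groups, n_regions=4,
                            roi_intercepts=np.full(4, 8.0),
                            roi_slopes={"G": np.full(4, slopes)},
                            roi_noise_sd=noise, n_scanners=n_scanners,
                            scanner_offsets=np.zeros((n_scanners, 4)), seed=2)

    def test_zero_noise_volumes_exactly_linear(self):
        cfg = self._config(-2.0, 0.0)
        cohort = simulate_cohort(cfg)
        pred = 8.0 - 2.0 * cohort.frailty_truth.to_numpy()
        for col in cohort.roi_volumes:
            assert np.allclose(cohort.roi_volumes[col], pred)

    def test_negative_slope_yields_negative_correlation(self):
        cfg = self._config(-2.0, 0.3, n=500)
        cohort = simulate_cohort(cfg)
        for col in cohort.roi_volumes:
            r = np.corrcoef(cohort.frailty_truth, cohort.roi_volumes[col])[0, 1]
            assert r < 0

    def test_null_slopes_give_uniform_regression_pvalues(self):
        pvals = []
        for seed in range(30):
            groups = (GroupSpec("G", 60, 0.3, 0.1),)
            cfg = CohortConfig(groups=groups, n_regions=6,
                               roi_intercepts=np.full(6, 8.0),
                               roi_slopes={"G": np.zeros(6)},
                               roi_noise_sd=0.5, n_scanners=1,
                               scanner_offsets=np.zeros((1, 6)), seed=seed)
            cohort = simulate_cohort(cfg)
            res = MassUnivariateOLS(cohort.roi_volumes,
                                    cohort.frailty_truth).fit()
            pvals.extend(res.table["p_frailty"])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_nonpositive_volumes_warn(self):
        cfg = self._config(-100.0, 0.0)
        with pytest.warns(UserWarning, match="non-positive"):
            simulate_cohort(cfg)


class TestConnectivity:
    def test_symmetry_and_edge_count(self):
        cfg = CohortConfig(groups=(GroupSpec("G", 5, 0.3, 0.1),),
                           n_regions=116, seed=0)
        assert cfg.n_edges == 6670  # 116 * 115 / 2
        frailty, group = generate_frailty_scores(cfg)
        conn = generate_connectivity(cfg, frailty, group)
        assert conn.shape == (5, 6670)
        cohort = simulate_cohort(CohortConfig(
            groups=(GroupSpec("G", 3, 0.3, 0.1),), n_regions=6, seed=0))
        for pid in cohort.connectivity.index:
            mat = cohort.connectivity_matrix(pid)
            assert np.allclose(mat, mat.T)
            assert np.allclose(np.diag(mat), 0)

    def test_zero_noise_zero_slope_gives_identical_baselines(self):
        cfg = CohortConfig(groups=(GroupSpec("G", 8, 0.3, 0.1),),
                           n_regions=5, edge_noise_sd=0.0, seed=0)
        frailty, group = generate_frailty_scores(cfg)
        conn = generate_connectivity(cfg, frailty, group)
        assert (conn.nunique() == 1).all()

    def test_edge_names_cover_strict_upper_triangle(self):
        names = edge_names(["A", "B", "C"])
        assert names == ["A|B", "A|C", "B|C"]
        ii, jj = edge_index(3)
        assert (ii < jj).all()


def test_simulated_cohort_is_bit_reproducible(tmp_path):
    cfg = dict(groups=(GroupSpec("X", 30, 0.2, 0.06),
                       GroupSpec("Y", 25, 0.3, 0.08)),
               n_regions=4, missing_rate=0.05, seed=42)
    a = simulate_cohort(CohortConfig(**cfg))
    b = simulate_cohort(CohortConfig(**cfg))
    pd.testing.assert_frame_equal(a.item_table, b.item_table)
    pd.testing.assert_frame_equal(a.roi_volumes, b.roi_volumes)
    pd.testing.assert_frame_equal(a.connectivity, b.connectivity)
    pd.testing.assert_series_equal(a.scanner, b.scanner)
    paths = a.write(tmp_path)
    assert all((tmp_path / p.split("/")[-1]).exists() for p in paths.values())
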