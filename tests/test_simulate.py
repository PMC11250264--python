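"""Generative model: determinism, rate conservation and the coupling."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chisquare, pearsonr

import coorigin as co


class TestReference:
    def test_lowmap_count_forced_by_config(self):
        cfg = co.SimConfig(n_windows=10, lowmap_fraction=0.2, seed=1)
        layout, mapp, gaps = co.simulate_reference(cfg)
        tiled = co.tile_windows(layout, co.WindowFilterConfig())
        frac = mapp.covered_bases(tiled) / cfg.window_size
        assert int((frac < 0.92).sum()) == 2
        assert len(gaps) == 0

    def test_same_seed_byte_identical_tracks(self, tmp_path):
        cfg = co.SimConfig(n_windows=10, lowmap_fraction=0.2, seed=1)
        paths = []
        for name in ("a.bed", "b.bed"):
            _, mapp, _ = co.simulate_reference(cfg)
            p = tmp_path / name
            mapp.to_bed(p)
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]

    def test_single_window_rejected(self):
        with pytest.raises(ValueError):
            co.simulate_reference(co.SimConfig(n_windows=1))


class TestAccessibility:
    def test_equalization_and_shape(self, small_sim_config, small_windows):
        am = co.simulate_accessibility(small_sim_config, small_windows)
        assert am.equalized.shape == (small_windows.n, 6)
        np.testing.assert_allclose(am.equalized.sum(axis=0),
                                   small_sim_config.equalize_total, rtol=1e-6)

    def test_zero_cell_variance_makes_columns_identical(self, small_windows):
        cfg = co.SimConfig(n_windows=120, cell_sigma=0.0, seed=2)
        am = co.simulate_accessibility(cfg, small_windows)
        for col in am.equalized.columns[1:]:
            np.testing.assert_allclose(am.equalized[col],
                                       am.equalized[am.equalized.columns[0]], rtol=1e-9)

    def test_default_pairwise_correlation_in_band(self, small_windows):
        rs = []
        for seed in range(100):
            cfg = co.SimConfig(n_windows=120, seed=seed)
            am = co.simulate_accessibility(cfg, small_windows)
            c = np.corrcoef(am.equalized.to_numpy().T)
            rs.append(c[np.triu_indices_from(c, k=1)].mean())
        assert 0.2 < np.mean(rs) < 0.95

    def test_deterministic_under_seed(self, small_sim_config, small_windows):
        a = co.simulate_accessibility(small_sim_config, small_windows)
        b = co.simulate_accessibility(small_sim_config, small_windows)
        pd.testing.assert_frame_equal(a.equalized, b.equalized)


class TestTumor:
    def test_rate_conservation(self, small_sim_config, small_windows, small_access):
        _, truth = co.simulate_tumor(small_sim_config, small_windows, small_access, "stem")
        assert truth.window_rates.sum() == pytest.approx(
            small_sim_config.total_mutations, rel=1e-9)

    def test_unknown_origin_rejected(self, small_sim_config, small_windows, small_access):
        with pytest.raises(ValueError):
            co.simulate_tumor(small_sim_config, small_windows, small_access, "paneth")

    def test_beta_zero_counts_uniform(self, small_windows):
        """chi-square GOF vs uniform not rejected at alpha=0.01 in >=95% of seeds."""
        ok = 0
        n_seeds = 100
        for seed in range(n_seeds):
            cfg = co.SimConfig(n_windows=120, coupling_beta=0.0,
                               total_mutations=6000, seed=seed)
            access = co.simulate_accessibility(cfg, small_windows)
            ts, _ = co.simulate_tumor(cfg, small_windows, access, "stem")
            counts = np.bincount(
                small_windows.locate("chr1", ts.variants["Pos"].to_numpy() - 1),
                minlength=small_windows.n)
            if chisquare(counts).pvalue >= 0.01:
                ok += 1
        assert ok >= 0.95 * n_seeds

    def test_strong_coupling_anticorrelates(self, small_windows):
        cfg = co.SimConfig(n_windows=120, coupling_beta=2.0, total_mutations=10000, seed=3)
        access = co.simulate_accessibility(cfg, small_windows)
        ts, _ = co.simulate_tumor(cfg, small_windows, access, "goblet")
        counts = np.bincount(
            small_windows.locate("chr1", ts.variants["Pos"].to_numpy() - 1),
            minlength=small_windows.n)
        r = pearsonr(counts, access.equalized["goblet"]).statistic
        assert r < -0.5

    def test_coupling_monotone_in_beta(self, small_windows):
        """Mean |rank correlation(counts, origin accessibility)| is
        non-decreasing in beta. Rank correlation because the coupling
        exp(-beta*z) is monotone but nonlinear in the accessibility, so
        Pearson on the raw scale understates strong coupling."""
        from scipy.stats import spearmanr

        means = []
        for beta in (0.0, 0.5, 1.0, 2.0):
            rs = []
            for seed in range(50):
                cfg = co.SimConfig(n_windows=120, coupling_beta=beta,
                                   total_mutations=5000, seed=seed)
                access = co.simulate_accessibility(cfg, small_windows)
                ts, _ = co.simulate_tumor(cfg, small_windows, access, "stem")
                counts = np.bincount(
                    small_windows.locate("chr1", ts.variants["Pos"].to_numpy() - 1),
                    minlength=small_windows.n)
                rs.append(abs(spearmanr(counts, access.equalized["stem"]).statistic))
            means.append(np.mean(rs))
        assert all(a <= b + 1e-9 for a, b in zip(means, means[1:]))

    def test_degenerate_vaf_limit_retains_everything(self, small_windows):
        cfg = co.SimConfig(n_windows=120, subclonal_fraction=0.0,
                           clonal_vaf_conc=float("inf"), purity=0.8,
                           total_mutations=2000, seed=5)
        access = co.simulate_accessibility(cfg, small_windows)
        ts, truth = co.simulate_tumor(cfg, small_windows, access, "tuft")
        assert (ts.vafs == 0.4).all()
        res = co.clonal_filter(ts)
        assert res.retained_fraction == 1.0
        assert truth.clonal_flags.all()

    def test_subclonal_vafs_sit_below_clonal(self, small_sim_config, small_windows,
                                             small_access):
        ts, truth = co.simulate_tumor(small_sim_config, small_windows, small_access, "stem")
        clonal = ts.vafs[truth.clonal_flags]
        sub = ts.vafs[~truth.clonal_flags]
        assert sub.mean() < clonal.mean()


class TestCohort:
    def test_cohort_shapes_and_determinism(self):
        cfg = co.SimConfig(
            n_windows=60, total_mutations=1000, seed=8,
            cohort_spec=(co.CohortSpec("IBD-CRC", 5, {"goblet": 0.6, "BEST4": 0.4}),
                         co.CohortSpec("sCRC", 7, {"stem": 1.0})))
        tumors, labels, truths = co.simulate_cohort(cfg)
        assert len(tumors) == len(truths) == 12
        assert labels["cohort"].value_counts().to_dict() == {"sCRC": 7, "IBD-CRC": 5}
        assert (labels.loc[labels["cohort"] == "sCRC", "true_origin"] == "stem").all()
        tumors2, labels2, _ = co.simulate_cohort(cfg)
        pd.testing.assert_frame_equal(labels, labels2)
        pd.testing.assert_frame_equal(tumors[0].variants, tumors2[0].variants)

    def test_invalid_mixture_rejected(self):
        with pytest.raises(ValueError, match="sums to"):
            co.CohortSpec("A", 3, {"stem": 0.5, "goblet": 0.4})

    def test_empty_cohort_spec_rejected(self):
        cfg = co.SimConfig(n_windows=10, cohort_spec=())
        with pytest.raises(ValueError):
            co.simulate_cohort(cfg)


class TestFragments:
    def test_fragment_realization_matches_profile(self, small_sim_config, small_windows,
                                                  small_access):
        frag, barcodes, classes = co.simulate_fragments(
            small_sim_config, small_windows, small_access)
        ann = co.CellAnnotation(barcodes.set_index("barcode")["cluster"],
                                classes.set_index("cluster")["class"])
        raw, discarded = co.aggregate_fragments(frag, ann, small_windows)
        assert discarded == 0
        assert (raw.sum(axis=0) == small_sim_config.fragments_per_type).all()
        eq = co.equalize(raw).equalized
        for ct in small_access.cell_types:
            r = pearsonr(eq[ct], small_access.equalized[ct]).statistic
            assert r > 0.99
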