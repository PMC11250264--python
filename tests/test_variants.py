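"""VCF ingestion, clonal filtering and per-window counting."""

import numpy as np
import pandas as pd
import pytest

import coorigin as co


def make_ts(vafs, tumor_id="t", chrom="chr1", positions=None):
    vafs = list(vafs)
    if positions is None:
        positions = [1000 * (i + 1) for i in range(len(vafs))]
    df = pd.DataFrame({
        "Chromosome": chrom, "Pos": positions,
        "Ref": "A", "Alt": "T", "VAF": vafs,
    })
    return co.TumorVariantSet(tumor_id, df)


def write_vcf_text(path, body, info='##INFO=<ID=AF,Number=A,Type=Float,Description="af">'):
    header = "\n".join([
        "##fileformat=VCFv4.2",
        "##contig=<ID=chr1,length=3000000>",
        info,
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="ad">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="dp">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tTUMOR",
    ])
    path.write_text(header + "\n" + body)


class TestReadVcf:
    def test_af_info_preferred(self, tmp_path):
        p = tmp_path / "a.vcf"
        write_vcf_text(p, "chr1\t100\t.\tA\tG\t.\tPASS\tAF=0.31\tAD:DP\t70,30:100\n")
        ts = co.read_somatic_vcf(p)
        assert ts.tumor_id == "a"
        assert ts.vafs.tolist() == [pytest.approx(0.31)]

    def test_ad_dp_fallback(self, tmp_path):
        p = tmp_path / "b.vcf"
        write_vcf_text(p, "chr1\t100\t.\tA\tG\t.\tPASS\t.\tAD:DP\t3,7:10\n")
        assert co.read_somatic_vcf(p).vafs.tolist() == [pytest.approx(0.7)]

    def test_zero_depth_is_an_error_naming_the_record(self, tmp_path):
        p = tmp_path / "c.vcf"
        write_vcf_text(p, "chr1\t100\t.\tA\tG\t.\tPASS\t.\tAD:DP\t0,0:0\n")
        with pytest.raises(ValueError, match="chr1:100"):
            co.read_somatic_vcf(p)

    def test_multiallelic_split_and_filtered_records_dropped(self, tmp_path):
        p = tmp_path / "d.vcf"
        write_vcf_text(p, (
            "chr1\t100\t.\tA\tG,C\t.\tPASS\tAF=0.4,0.2\tAD:DP\t40,40,20:100\n"
            "chr1\t200\t.\tT\tG\t.\tlowqual\tAF=0.5\tAD:DP\t50,50:100\n"
        ))
        ts = co.read_somatic_vcf(p)
        assert ts.n_variants == 2
        assert ts.vafs.tolist() == [pytest.approx(0.4), pytest.approx(0.2)]

    def test_roundtrip_through_simulator_writer(self, tmp_path, small_sim_config,
                                                small_windows, small_access):
        ts, _ = co.simulate_tumor(small_sim_config, small_windows, small_access,
                                  "goblet", tumor_id="rt")
        layout = co.GenomeLayout([co.Chromosome("chr1", small_sim_config.n_windows
                                                * small_sim_config.window_size)])
        from coorigin.simulate import write_vcf

        path = tmp_path / "rt.vcf"
        write_vcf(ts, layout, path)
        back = co.read_somatic_vcf(path)
        assert back.n_variants == ts.n_variants
        np.testing.assert_allclose(back.vafs, ts.vafs, atol=5e-7)


class TestClonalFilter:
    def test_hand_computed_example(self):
        res = co.clonal_filter(make_ts([0.5, 0.5, 0.5, 0.1]))
        assert res.mean_vaf == pytest.approx(0.4)
        assert res.sd_vaf == pytest.approx(0.2)
        assert res.threshold == pytest.approx(0.2)
        assert res.retained_fraction == pytest.approx(0.75)
        assert res.n_retained == 3

    def test_equal_vafs_all_retained(self):
        res = co.clonal_filter(make_ts([0.4] * 5))
        assert res.sd_vaf == 0.0
        assert res.threshold == pytest.approx(0.4)
        assert res.retained_fraction == 1.0

    def test_threshold_floored_at_zero(self):
        res = co.clonal_filter(make_ts([0.01, 0.5]), co.ClonalFilterConfig(sd_multiplier=5))
        assert res.threshold == 0.0

    def test_single_variant_keeps_all_with_warning(self):
        with pytest.warns(UserWarning):
            res = co.clonal_filter(make_ts([0.3]))
        assert res.warning is not None
        assert res.n_retained == 1

    def test_retention_monotone_in_sd_multiplier(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            ts = make_ts(rng.beta(8, 8, size=50))
            kept = [co.clonal_filter(ts, co.ClonalFilterConfig(k)).n_retained
                    for k in (0.5, 1.0, 2.0)]
            assert kept[0] <= kept[1] <= kept[2]

    def test_idempotent_at_fixed_threshold(self):
        rng = np.random.default_rng(9)
        ts = make_ts(rng.beta(5, 5, size=100))
        res = co.clonal_filter(ts)
        again = res.retained[res.retained["VAF"] >= res.threshold]
        assert len(again) == res.n_retained


class TestCounting:
    def _simple_windows(self, n=3):
        layout = co.GenomeLayout([co.Chromosome("chr1", n * 1_000_000)])
        track = co.IntervalTrack.from_intervals([("chr1", 0, n * 1_000_000)])
        return co.build_windows(layout, track, co.IntervalTrack(), co.WindowFilterConfig())

    def test_one_based_position_boundaries(self):
        ws = self._simple_windows()
        res = co.clonal_filter(make_ts([0.5, 0.5], positions=[1_000_000, 1_000_001]))
        counts, discarded = co.count_per_window(res, ws)
        # pos 1,000,000 is the last base of window 0; pos 1,000,001 opens window 1
        assert counts.tolist() == [1, 1, 0]
        assert discarded == 0

    def test_variants_in_dropped_windows_are_discarded(self):
        layout = co.GenomeLayout([co.Chromosome("chr1", 2_000_000)])
        track = co.IntervalTrack.from_intervals([("chr1", 1_000_000, 2_000_000)])
        ws = co.build_windows(layout, track, co.IntervalTrack(), co.WindowFilterConfig())
        res = co.clonal_filter(make_ts([0.5] * 5, positions=[10, 20, 30, 40, 50]))
        counts, discarded = co.count_per_window(res, ws)
        assert counts.tolist() == [0]
        assert discarded == 5

    def test_unknown_chromosome_is_an_error(self):
        ws = self._simple_windows()
        res = co.clonal_filter(make_ts([0.5, 0.5], chrom="chr99"))
        with pytest.raises(KeyError):
            co.count_per_window(res, ws)

    def test_conservation_and_tmb(self, small_sim_config, small_windows, small_access):
        ts, _ = co.simulate_tumor(small_sim_config, small_windows, small_access,
                                  "stem", tumor_id="c")
        res = co.clonal_filter(ts)
        counts, discarded = co.count_per_window(res, small_windows)
        assert counts.sum() + discarded == res.n_retained == co.compute_tmb(res)


class TestMatrix:
    def test_normalize_rows(self):
        m = co.MutationMatrix(pd.DataFrame([[2, 4, 6], [1, 1, 1]],
                                           index=["a", "b"], columns=[0, 1, 2]))
        norm = co.normalize_rows(m)
        assert norm.loc["a"].tolist() == [0.5, 1.0, 1.5]
        assert norm.loc["b"].tolist() == [1.0, 1.0, 1.0]

    def test_row_mean_exactly_one_on_random_rows(self):
        rng = np.random.default_rng(3)
        counts = pd.DataFrame(rng.poisson(5, size=(20, 40)) + 1)
        norm = co.normalize_rows(co.MutationMatrix(counts))
        np.testing.assert_allclose(norm.mean(axis=1), 1.0, atol=1e-12)

    def test_all_zero_row_names_the_tumor(self):
        m = co.MutationMatrix(pd.DataFrame([[1, 2], [0, 0]],
                                           index=["good", "bad"], columns=[0, 1]))
        with pytest.raises(ValueError, match="bad"):
            co.normalize_rows(m)

    def test_matrix_tsv_roundtrip(self, tmp_path):
        m = co.MutationMatrix(pd.DataFrame([[1, 2], [3, 4]],
                                           index=["a", "b"], columns=[0, 1]),
                              pd.Series({"a": 5, "b": 0}))
        path = tmp_path / "m.tsv"
        m.to_tsv(path)
        back = co.MutationMatrix.from_tsv(path)
        pd.testing.assert_frame_equal(back.counts, m.counts)
        assert back.discarded.tolist() == [5, 0]
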