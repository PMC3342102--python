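"""Relative expression, band classification, replicate summaries, t-test."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pirnaprofiler import (
    LibraryProfile,
    TransposonCounts,
    classify_band,
    compare_profiles,
    percent_reduction,
    relative_expression,
    rpm_normalize,
    summarize_replicates,
    two_sample_t,
)


class TestRelativeExpression:
    def test_baseline_equals_sample(self):
        assert relative_expression(400.0, 400.0) == 1.0

    def test_arithmetic(self):
        assert relative_expression(240.0, 400.0) == pytest.approx(0.6)

    def test_zero_baseline_gives_missing_marker(self):
        assert math.isnan(relative_expression(10.0, 0.0))

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            relative_expression(-1.0, 5.0)

    @given(st.floats(0.01, 100), st.floats(0.01, 100), st.floats(0.01, 100))
    @settings(max_examples=200, deadline=None)
    def test_scale_equivariance(self, sample, baseline, c):
        re1 = relative_expression(sample, baseline)
        re2 = relative_expression(sample * c, baseline * c)
        assert re2 == pytest.approx(re1, rel=1e-9)
        assert classify_band(re1) == classify_band(re2)
        assert percent_reduction(re1) == pytest.approx(percent_reduction(re2), rel=1e-9)


class TestClassifyBand:
    @pytest.mark.parametrize(
        "re,band",
        [
            (0.6, "unchanged"), (1.6, "unchanged"),  # inclusive boundaries
            (0.59, "reduced"), (1.61, "elevated"),
            (0.0, "reduced"), (1.0, "unchanged"), (5.0, "elevated"),
        ],
    )
    def test_boundaries(self, re, band):
        assert classify_band(re) == band

    def test_branch_free_oracle_on_random_values(self, rng):
        values = rng.uniform(0, 3, size=10_000)
        names = ["reduced", "unchanged", "elevated"]
        for re in values:
            oracle = names[int(re >= 0.6) + int(re > 1.6)]
            assert classify_band(float(re)) == oracle

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            classify_band(-0.1)
        with pytest.raises(ValueError):
            classify_band(math.nan)


class TestSummaries:
    def test_constant_replicates(self):
        s = summarize_replicates([1.0, 1.0, 1.0])
        assert s.mean == 1.0 and s.sd == 0.0 and s.n == 3

    def test_closed_form_sample_sd(self):
        s = summarize_replicates([2.0, 4.0])
        assert s.mean == 3.0
        assert s.sd == pytest.approx(math.sqrt(2))

    def test_single_value_sd_undefined(self):
        s = summarize_replicates([5.0])
        assert s.mean == 5.0 and math.isnan(s.sd)

    @pytest.mark.parametrize("mean_re,pct", [(0.6, 40.0), (1.0, 0.0), (1.25, -25.0)])
    def test_percent_reduction(self, mean_re, pct):
        assert percent_reduction(mean_re) == pytest.approx(pct)


class TestTwoSampleT:
    def test_identical_groups(self):
        assert two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == (0.0, 1.0)

    def test_matches_pooled_variance_closed_form(self):
        a, b = [2.1, 1.9, 2.0], [1.0, 1.1, 0.9]
        na, nb = len(a), len(b)
        sp2 = ((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1)) / (na + nb - 2)
        expected_t = (np.mean(a) - np.mean(b)) / math.sqrt(sp2 * (1 / na + 1 / nb))
        t, p = two_sample_t(a, b)
        assert t == pytest.approx(expected_t)
        assert 0 < p < 0.05

    def test_degenerate_zero_variance(self):
        assert two_sample_t([1.0, 1.0], [1.0, 1.0]) == (0.0, 1.0)
        with pytest.warns(UserWarning):
            t, p = two_sample_t([2.0, 2.0], [1.0, 1.0])
        assert math.isinf(t) and p == 0.0

    def test_group_size_contract(self):
        with pytest.raises(ValueError):
            two_sample_t([1.0], [1.0, 2.0])


def _profile(lib_id, sense, anti, denom=1_000_000):
    counts = [TransposonCounts(t, sense[t], anti[t]) for t in sense]
    return LibraryProfile(lib_id, denom, rpm_normalize(counts, denom), 50.0, 1.0)


class TestCompareProfiles:
    def test_records_and_summary_shapes(self):
        base = _profile("wt", {"A": 100, "B": 200}, {"A": 300, "B": 100})
        kg1 = _profile("kg1", {"A": 60, "B": 200}, {"A": 180, "B": 100})
        kg2 = _profile("kg2", {"A": 58, "B": 210}, {"A": 190, "B": 90})
        records, summary = compare_profiles(base, [kg1, kg2])
        assert len(records) == 2 * 3 * 2  # transposons x strand classes x libraries
        row = summary[(summary.transposon_id == "A") & (summary.strand_class == "total")]
        mean_re = float(row["mean_re"].iloc[0])
        assert mean_re == pytest.approx(((240 / 400) + (248 / 400)) / 2)
        assert float(row["percent_reduction"].iloc[0]) == pytest.approx(100 * (1 - mean_re))

    def test_reduced_band_for_scaled_transposon(self):
        base = _profile("wt", {"A": 1000}, {"A": 1000})
        kg = _profile("kg", {"A": 500}, {"A": 500})
        records, _ = compare_profiles(base, [kg])
        assert set(records["band"]) == {"reduced"}

    def test_zero_baseline_emits_missing_record(self):
        base = _profile("wt", {"A": 0}, {"A": 0})
        kg = _profile("kg", {"A": 10}, {"A": 10})
        records, summary = compare_profiles(base, [kg])
        assert records["re"].isna().all()
        assert records["band"].isna().all()
        assert summary["mean_re"].isna().all()

    def test_heatmap_renders_three_band_colors(self, tmp_path):
        import matplotlib

        matplotlib.use("Agg")
        from pirnaprofiler.compare import plot_re_heatmap

        base = _profile("wt", {"A": 1000, "B": 1000, "C": 1000},
                        {"A": 1000, "B": 1000, "C": 1000})
        kg = _profile("kg", {"A": 500, "B": 1000, "C": 2000},
                      {"A": 500, "B": 1000, "C": 2000})
        records, _ = compare_profiles(base, [kg])
        ax = plot_re_heatmap(records)
        ax.figure.savefig(tmp_path / "heatmap.png")
        assert (tmp_path / "heatmap.png").stat().st_size > 0

    def test_multiple_baselines_use_mean_rpm_and_t_test(self):
        wt1 = _profile("wt1", {"A": 90}, {"A": 110})
        wt2 = _profile("wt2", {"A": 110}, {"A": 90})
        kg1 = _profile("kg1", {"A": 50}, {"A": 50})
        kg2 = _profile("kg2", {"A": 52}, {"A": 48})
        records, summary = compare_profiles([wt1, wt2], [kg1, kg2])
        total = records[(records.strand_class == "total")]
        assert total["re"].to_list() == pytest.approx([0.5, 0.5])
        row = summary[summary.strand_class == "total"].iloc[0]
        assert not math.isnan(row["t"]) and not math.isnan(row["p"])
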