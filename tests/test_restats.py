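"""RE counting (with centromere clause), distributions, Gaussian peak model."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hdnacap import (
    GaussianPeakModel,
    SubsampleScheme,
    ValidationError,
    count_res,
    count_res_population,
    fit_gaussian,
    fwhm_from_width,
    re_distribution,
    regress_xc_vs_nmarkers,
    subsample_analysis,
)
from hdnacap import test_normality as normality_check
from hdnacap.genome import ChromosomeModel
from hdnacap.restats import GaussianPeakResults, gaussian_peak


def exact_results(y0, area, x_c, w):
    """A results object with exactly known parameters (no fitting noise)."""
    return GaussianPeakResults(
        y0=y0, area=area, x_c=x_c, w=w, stderr={}, r_squared=1.0,
        nobs=13, converged=True,
    )

CHR = ChromosomeModel("Chr19", 15_900_000, 5_300_000, 6_700_000)
# 12 loci at 1..12 Mbp; the centromere sits between loci 5 and 6 (5.0 / 7.0 excluded)
POS12 = np.arange(1, 13, dtype=np.int64) * 1_000_000


def naive_re_count(present, positions, chrom):
    """Literal restatement of the counting rule, scanned pairwise.

    Each hDNA-positive locus belongs to an event; a positive locus adjacent
    to the previous positive locus joins its event, except that a pair with
    the centromere interval strictly between them starts a new event.
    """
    events = 0
    prev_present = False
    prev_pos = None
    for p, pos in zip(present, positions):
        if p:
            if not prev_present:
                events += 1
            elif (prev_pos < chrom.centromere_start_bp
                  and pos >= chrom.centromere_end_bp):
                events += 1
            prev_pos = pos
        prev_present = p
    return events


class TestCountRes:
    def test_two_runs_without_centromere(self):
        chrom = ChromosomeModel("C", 20_000_000, 15_000_000, 16_000_000)
        assert count_res([True, True, False, True], POS12[:4], chrom) == 2

    def test_pair_flanking_centromere_counts_twice(self):
        # loci at 5 and 6 Mbp? use 5.0 and 7.0 around [5.3, 6.7)
        pos = np.array([5_000_000, 7_000_000])
        assert count_res([True, True], pos, CHR) == 2
        assert naive_re_count([True, True], pos, CHR) == 2

    @pytest.mark.parametrize(
        "calls,expected",
        [
            ([False] * 5, 0),
            ([True] + [False] * 4, 1),
            ([True] * 5, 1),
        ],
    )
    def test_degenerate_patterns(self, calls, expected):
        pos = POS12[7:12]  # one side of the centromere
        assert count_res(calls, pos, CHR) == expected

    def test_missing_loci_are_dropped_not_bridged(self):
        pos = POS12[7:11]
        calls = ["present", "missing", "present", "absent"]
        # after dropping the missing locus, the two present loci are adjacent
        assert count_res(calls, pos, CHR) == 1

    def test_unordered_positions_rejected(self):
        with pytest.raises(ValidationError, match="increasing"):
            count_res([True, False], [200, 100], CHR)

    @given(
        present=st.lists(st.booleans(), min_size=1, max_size=12),
        gap=st.integers(0, 12),
    )
    @settings(max_examples=300, deadline=None)
    def test_matches_naive_oracle(self, present, gap):
        n = len(present)
        pos = POS12[:n]
        # centromere in the gap before locus `gap` (0 = before all, n = after all)
        if gap == 0:
            cen = (100_000, 500_000)
        elif gap >= n:
            cen = (14_000_000, 15_000_000)
        else:
            cen = (int(pos[gap - 1]) + 200_000, int(pos[gap]) - 200_000)
        chrom = ChromosomeModel("Chr19", 15_900_000, *cen)
        assert count_res(present, pos, chrom) == naive_re_count(present, pos, chrom)

    def test_population_counter_agrees_with_scalar(self, chrom, panel):
        rng = np.random.default_rng(0)
        ids = panel.marker_ids
        vals = rng.choice(["present", "absent", "missing"], size=(40, len(ids)),
                          p=[0.4, 0.5, 0.1])
        matrix = pd.DataFrame(vals, columns=ids,
                              index=[f"i{j}" for j in range(40)])
        counts = count_res_population(matrix, panel, chrom)
        pos = panel.positions(chrom.name)
        for j in range(40):
            assert counts.iloc[j] == count_res(list(vals[j]), pos, chrom)

    def test_count_bounded_by_present_loci_plus_one(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            n = int(rng.integers(1, 13))
            present = rng.random(n) < 0.5
            c = count_res(present, POS12[:n], CHR)
            assert c <= present.sum() + 1


class TestReDistribution:
    def test_proportions(self):
        dist = re_distribution([2, 2, 3])
        assert dist[2] == pytest.approx(2 / 3)
        assert dist[3] == pytest.approx(1 / 3)

    def test_single_individual(self):
        dist = re_distribution([4])
        assert dist.to_dict() == {4: 1.0}

    @given(st.lists(st.integers(0, 15), min_size=1, max_size=200))
    @settings(max_examples=100, deadline=None)
    def test_sums_to_one(self, counts):
        assert re_distribution(counts).sum() == pytest.approx(1.0)

    def test_empty_population_is_error(self):
        with pytest.raises(ValidationError, match="empty"):
            re_distribution([])


class TestNormality:
    def test_normal_sample_not_rejected(self):
        # continuous normal draws: non-rejection even at large n; rounding
        # to integer counts adds a discreteness distance that K-S detects,
        # so this check uses the un-rounded sample
        rng = np.random.default_rng(12)
        res = normality_check(rng.normal(5.0, 1.4, 10_000))
        assert res.p_value > 0.05

    def test_uniform_sample_rejected(self):
        rng = np.random.default_rng(13)
        draws = rng.integers(0, 21, 10_000)
        res = normality_check(draws)
        assert res.p_value < 0.01

    def test_small_sample_is_precondition_error(self):
        with pytest.raises(ValidationError, match="n >= 5"):
            normality_check([1, 2, 3])

    def test_constant_sample_flagged_degenerate(self):
        res = normality_check([3] * 10)
        assert res.degenerate

    def test_lilliefors_variant_runs(self):
        rng = np.random.default_rng(14)
        res = normality_check(np.round(rng.normal(5, 1.4, 500)), lilliefors=True)
        assert res.method == "lilliefors"
        assert 0.0 <= res.p_value <= 1.0


class TestGaussianPeakModel:
    def test_zero_residual_recovery(self):
        k = np.arange(0, 13, dtype=float)
        true = dict(y0=0.02, area=0.9, x_c=5.4, w=2.886)
        y = gaussian_peak(k, true["y0"], true["area"], true["x_c"], true["w"])
        res = GaussianPeakModel(x=k, y=y).fit()
        assert res.converged
        for name, val in true.items():
            assert getattr(res, name) == pytest.approx(val, rel=1e-6)
        assert res.r_squared == pytest.approx(1.0, abs=1e-10)

    def test_fwhm_of_printed_width(self):
        # w = 1.209 corresponds to FWHM 1.424 at 3-decimal table rounding
        assert fwhm_from_width(1.209) == pytest.approx(1.424, abs=2e-3)

    def test_fwhm_sigma_ratio_invariant(self):
        rng = np.random.default_rng(21)
        for _ in range(20):
            k = np.arange(0, 12, dtype=float)
            y = gaussian_peak(
                k, rng.uniform(0, 0.05), rng.uniform(0.5, 1.5),
                rng.uniform(2, 9), rng.uniform(1, 4),
            ) + rng.normal(0, 0.005, k.size)
            res = GaussianPeakModel(x=k, y=y).fit()
            if res.converged:
                assert res.fwhm / res.sigma == pytest.approx(
                    2.0 * math.sqrt(2.0 * math.log(2.0)), abs=1e-12
                )
                assert res.sigma == res.w / 2.0

    def test_recovery_from_large_simulated_sample(self):
        rng = np.random.default_rng(22)
        draws = np.round(rng.normal(5.4, 1.443, 10_000)).astype(int)
        res = fit_gaussian(re_distribution(draws))
        assert res.converged
        assert res.x_c == pytest.approx(5.4, abs=0.05)

    def test_too_few_bins_is_precondition_error(self):
        with pytest.raises(ValidationError, match=">= 4"):
            GaussianPeakModel(x=[0, 1, 2], y=[0.2, 0.6, 0.2])

    def test_nonconvergence_returns_flagged_result(self):
        # NaN data cannot be fitted; expect a diagnostics-carrying result
        res = GaussianPeakModel(x=[0, 1, 2, 3], y=[np.nan, 1, 2, 1]).fit()
        assert not res.converged
        assert res.message

    def test_median_xc_tracks_sample_mean(self):
        """Across seeded populations the fitted center matches the mean count."""
        rng = np.random.default_rng(23)
        errs = []
        for _ in range(20):
            draws = np.round(rng.normal(rng.uniform(3, 7), rng.uniform(1, 2),
                                        5000)).astype(int)
            res = fit_gaussian(re_distribution(draws))
            if res.converged:
                errs.append(abs(res.x_c - draws.mean()))
        assert np.median(errs) < 0.1


class TestIntegralPmSigma:
    def test_closed_form_without_baseline(self):
        res = exact_results(y0=0.0, area=1.0, x_c=5.4, w=2.886)
        expect = math.erf(1.0 / math.sqrt(2.0))
        assert res.integral_pm_sigma() == pytest.approx(expect, abs=1e-8)

    def test_area_scales_integral(self):
        res = exact_results(y0=0.0, area=0.85, x_c=5.4, w=2.886)
        assert res.integral_pm_sigma() == pytest.approx(
            0.85 * math.erf(1.0 / math.sqrt(2.0)), abs=1e-8
        )

    def test_baseline_adds_2_sigma_times_y0(self):
        res = exact_results(y0=0.01, area=1.0, x_c=5.4, w=2.0)
        full = res.integral_pm_sigma(include_baseline=True)
        bare = res.integral_pm_sigma(include_baseline=False)
        assert full - bare == pytest.approx(0.01 * 2.0 * res.sigma, rel=1e-9)
        assert full == pytest.approx(math.erf(1 / math.sqrt(2)) + 0.02, abs=1e-8)

    def test_summary_renders(self):
        k = np.arange(0, 13, dtype=float)
        res = GaussianPeakModel(x=k, y=gaussian_peak(k, 0.0, 1.0, 5.0, 2.0)).fit()
        text = res.summary()
        assert "x_c" in text and "FWHM" in text


@pytest.fixture(scope="module")
def call_matrix(chrom, panel):
    """Synthetic call matrix with tract-like correlation along the chromosome."""
    rng = np.random.default_rng(30)
    n = 300
    pos = panel.positions(chrom.name)
    rows = []
    for _ in range(n):
        k = rng.poisson(5)
        starts = rng.uniform(0, chrom.length_bp, k)
        ends = starts + rng.exponential(1.5e6, k)
        present = np.zeros(len(pos), dtype=bool)
        for s, e in zip(starts, ends):
            present |= (pos >= s) & (pos < e)
        rows.append(np.where(present, "present", "absent"))
    return pd.DataFrame(rows, columns=panel.marker_ids,
                        index=[f"i{j}" for j in range(n)])


class TestSubsampling:
    def test_full_panel_size_equals_unsubsampled(self, call_matrix, panel, chrom):
        scheme = SubsampleScheme(sizes=(79,), reps=2, seed=1)
        summary, fits = subsample_analysis(call_matrix, panel, chrom, scheme)
        direct = count_res_population(call_matrix, panel, chrom)
        assert summary.iloc[0].mean_re == pytest.approx(direct.mean())

    def test_seeded_scheme_reproducible(self, call_matrix, panel, chrom):
        scheme = SubsampleScheme(sizes=(14, 41), reps=3, seed=7)
        s1, f1 = subsample_analysis(call_matrix, panel, chrom, scheme)
        s2, f2 = subsample_analysis(call_matrix, panel, chrom, scheme)
        pd.testing.assert_frame_equal(s1, s2)
        pd.testing.assert_frame_equal(f1, f2)

    def test_mean_re_nondecreasing_in_panel_size(self, call_matrix, panel, chrom):
        scheme = SubsampleScheme(sizes=(14, 24, 41, 60, 79), reps=20, seed=3)
        summary, _ = subsample_analysis(call_matrix, panel, chrom, scheme)
        means = summary.sort_values("size")["mean_re"].to_numpy()
        assert np.all(np.diff(means) >= 0)

    def test_oversized_subsample_is_error(self, call_matrix, panel, chrom):
        with pytest.raises(ValidationError, match="exceeds"):
            subsample_analysis(
                call_matrix, panel, chrom, SubsampleScheme(sizes=(100,), reps=1, seed=0)
            )


class TestXcRegression:
    def test_collinear_points_have_unit_r2(self):
        res = regress_xc_vs_nmarkers([(10, 1.0), (20, 2.0), (30, 3.0)])
        assert res.r_squared == pytest.approx(1.0)

    def test_published_style_points(self):
        """OLS on the five (marker count, mean RE) pairs of the dense-panel series."""
        pts = [(14, 2.1), (24, 2.7), (41, 3.7), (60, 4.6), (79, 5.4)]
        res = regress_xc_vs_nmarkers(pts)
        assert res.slope == pytest.approx(0.05070, abs=5e-4)
        assert res.r_squared == pytest.approx(0.9944, abs=1e-3)
        assert res.p_value < 0.05

    def test_two_points_is_precondition_error(self):
        with pytest.raises(ValidationError, match=">= 3"):
            regress_xc_vs_nmarkers([(10, 1.0), (20, 2.0)])
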