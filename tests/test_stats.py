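import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from dnmlineage.genome import GenomeModel
from dnmlineage.stats import (SPECTRUM_CLASSES, build_spectrum,
                              compare_spectrum, expected_dnm_count,
                              extrapolate_human, fold_increase,
                              poisson_hotspot_test, rbc_folate,
                              round_half_up, sex_bias_test,
                              substitution_class, window_counts)


class TestRateArithmetic:
    def test_mouse_spontaneous_expectation(self):
        value = expected_dnm_count(5.4e-9, 2.7e9, 2)
        assert value == pytest.approx(29.16)
        assert round_half_up(value) == 29

    def test_zero_rate(self):
        assert expected_dnm_count(0.0, 2.7e9, 2) == 0.0

    def test_human_product(self):
        assert expected_dnm_count(1.2e-8, 3.2e9, 2) == pytest.approx(76.8)

    def test_linearity(self):
        base = expected_dnm_count(1e-9, 1e9, 1)
        assert expected_dnm_count(3e-9, 1e9, 1) == pytest.approx(3 * base)
        assert expected_dnm_count(1e-9, 5e9, 1) == pytest.approx(5 * base)
        assert expected_dnm_count(1e-9, 1e9, 2) == pytest.approx(2 * base)

    def test_fold_increase(self):
        assert fold_increase(87.6, 29.16) == pytest.approx(3.004, abs=1e-3)
        assert fold_increase(29.16, 29.16) == 1.0
        assert fold_increase(211, 29.16) == pytest.approx(7.236, abs=1e-3)
        with pytest.raises(ValueError):
            fold_increase(10, 0)

    def test_extrapolate_human_defaults(self):
        out = extrapolate_human(fold=3.0)
        assert out["expected_dnms"] == pytest.approx(210.0)
        assert round_half_up(out["expected_deleterious"]) == 6


class TestSubstitutionClasses:
    @pytest.mark.parametrize("ref,alt,expected", [
        ("C", "T", "G:C>A:T"), ("G", "A", "G:C>A:T"),
        ("A", "C", "A:T>C:G"), ("T", "G", "A:T>C:G"),
        ("G", "T", "G:C>T:A"), ("A", "G", "A:T>G:C"),
    ])
    def test_strand_collapse(self, ref, alt, expected):
        assert substitution_class(ref, alt) == expected

    @pytest.mark.parametrize("ref,alt", [("A", "A"), ("N", "T"), ("CA", "T")])
    def test_non_snv_rejected(self, ref, alt):
        with pytest.raises(ValueError):
            substitution_class(ref, alt)

    def test_twelve_raw_substitutions_cover_six_classes(self):
        comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
        pairs = [(r, a) for r in "ACGT" for a in "ACGT" if r != a]
        assert len(pairs) == 12
        for r, a in pairs:
            assert substitution_class(r, a) \
                == substitution_class(comp[r], comp[a])


class TestBuildSpectrum:
    def test_empty(self):
        table = build_spectrum(pd.DataFrame(columns=["ref", "alt"]))
        assert table.total == 0
        assert (table.proportions == 0).all()

    def test_one_record_per_raw_substitution(self):
        pairs = [(r, a) for r in "ACGT" for a in "ACGT" if r != a]
        records = pd.DataFrame(pairs, columns=["ref", "alt"])
        table = build_spectrum(records)
        assert (table.counts == 2).all()
        assert table.total == 12

    def test_reverse_complement_invariance(self, rng):
        comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
        pairs = [(r, a) for r in "ACGT" for a in "ACGT" if r != a]
        idx = rng.integers(0, 12, size=500)
        records = pd.DataFrame([pairs[i] for i in idx],
                               columns=["ref", "alt"])
        flipped = pd.DataFrame([(comp[r], comp[a])
                                for r, a in zip(records["ref"],
                                                records["alt"])],
                               columns=["ref", "alt"])
        pd.testing.assert_series_equal(build_spectrum(records).counts,
                                       build_spectrum(flipped).counts)

    def test_indels_ignored(self):
        records = pd.DataFrame({"ref": ["C", "CT"], "alt": ["T", "C"]})
        assert build_spectrum(records).total == 1


class TestCompareSpectrum:
    def test_shifted_fractions_detected(self, rng):
        counts = np.full(20, 100)
        null = rng.binomial(100, 0.53, size=20) / 100
        shifted = null - 0.2
        out = compare_spectrum(shifted, counts, 0.53, rng)
        assert out.pvalue < 0.05

    def test_matched_fractions_not_rejected(self, rng):
        counts = np.full(20, 100)
        fractions = rng.binomial(100, 0.53, size=20) / 100
        out = compare_spectrum(fractions, counts, 0.53, rng)
        assert out.pvalue > 0.01

    def test_single_sample_rejected(self, rng):
        with pytest.raises(ValueError):
            compare_spectrum([0.5], [100], 0.53, rng)


class TestWindowCounts:
    GENOME = GenomeModel(chromosomes=[("chr1", 2_500_000),
                                      ("chr2", 1_000_000)])

    def test_tiling_and_terminal_window(self):
        windows = window_counts(pd.DataFrame(columns=["chrom", "pos"]),
                                self.GENOME, 1_000_000)
        assert len(windows) == 3 + 1
        last_chr1 = windows[windows["chrom"] == "chr1"].iloc[-1]
        assert last_chr1["length"] == 500_000
        assert (windows["count"] == 0).all()

    def test_all_records_in_one_window(self):
        records = pd.DataFrame({"chrom": ["chr1"] * 5, "pos": [10] * 5})
        windows = window_counts(records, self.GENOME, 1_000_000)
        assert windows["count"].iloc[0] == 5
        assert windows["count"].sum() == 5

    def test_one_based_position_boundary(self):
        # pos == window size is the last base of the first window;
        # pos == window size + 1 opens the second
        records = pd.DataFrame({"chrom": ["chr1", "chr1"],
                                "pos": [1_000_000, 1_000_001]})
        windows = window_counts(records, self.GENOME, 1_000_000)
        chr1 = windows[windows["chrom"] == "chr1"].reset_index(drop=True)
        assert chr1.loc[0, "count"] == 1
        assert chr1.loc[1, "count"] == 1

    def test_conservation(self, rng):
        records = pd.DataFrame({
            "chrom": rng.choice(["chr1", "chr2"], size=300),
            "pos": rng.integers(1, 1_000_000, size=300)})
        windows = window_counts(records, self.GENOME, 250_000)
        assert windows["count"].sum() == 300

    def test_out_of_range_rejected(self):
        records = pd.DataFrame({"chrom": ["chr2"], "pos": [2_000_000]})
        with pytest.raises(ValueError):
            window_counts(records, self.GENOME, 250_000)


def _window_frame(counts):
    return pd.DataFrame({"chrom": "chr1", "start": 0, "end": 1000,
                         "length": 1000, "count": counts})


class TestPoissonHotspotTest:
    def test_single_extreme_window_rejected_and_flagged(self, rng):
        counts = rng.poisson(3, size=100)
        counts[0] = 30  # 10x the mean
        out = poisson_hotspot_test(_window_frame(counts), alpha=0.05,
                                   hotspot_threshold=14)
        assert out.reject_poisson
        assert out.dispersion_direction == "over"
        assert len(out.hotspots) == 1 and out.hotspots["count"].iloc[0] == 30

    def test_constant_counts_underdispersed(self):
        out = poisson_hotspot_test(_window_frame(np.full(50, 4)))
        assert out.dispersion_direction == "under"
        assert out.dispersion_statistic == pytest.approx(0.0)

    def test_too_few_windows_rejected(self):
        with pytest.raises(ValueError):
            poisson_hotspot_test(_window_frame(np.array([1, 2, 3])))
        with pytest.raises(ValueError):
            poisson_hotspot_test(_window_frame(np.array([])))

    def test_null_not_rejected_most_of_the_time(self, rng):
        rejections = sum(
            poisson_hotspot_test(_window_frame(rng.poisson(5, 100)),
                                 hotspot_threshold=10 ** 9).reject_poisson
            for _ in range(100))
        assert rejections <= 15


class TestSexBias:
    def test_identical_counts_give_zero_statistic(self):
        out = sex_bias_test([80, 90, 100], [80, 90, 100])
        assert out.statistic == 0.0
        assert out.pvalue == pytest.approx(1.0)
        assert out.extra["male_median"] == 90

    def test_medians_reported(self):
        out = sex_bias_test([63, 82, 83, 133], [62, 70, 82, 94])
        assert out.extra["male_median"] == pytest.approx(82.5)

    def test_power_against_doubled_rate(self, rng):
        hits = 0
        reps = 300
        for _ in range(reps):
            male = rng.poisson(80, 10)
            female = rng.poisson(160, 10)
            if sex_bias_test(male, female).pvalue < 0.05:
                hits += 1
        assert hits / reps >= 0.95

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            sex_bias_test([], [1, 2])


class TestRbcFolate:
    def test_whole_blood_all_cells(self):
        assert rbc_folate(10, 0, 100) == pytest.approx(10.0)

    def test_worked_example_at_half_hct(self):
        # 10/50*100 - 10*50/50 = 20 - 10
        assert rbc_folate(10, 10, 50) == pytest.approx(10.0)

    def test_negative_result_warns(self):
        with pytest.warns(UserWarning):
            value = rbc_folate(0, 5, 40)
        assert value == pytest.approx(-7.5)

    def test_zero_hct_rejected(self):
        with pytest.raises(ValueError):
            rbc_folate(10, 5, 0)
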