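"""Variant filtering, LOESS, and the four interval-detection procedures."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from wgsmap.errors import (
    InsufficientDataError,
    NoClusterError,
    NoIntervalError,
    NoSignalError,
)
from wgsmap.mapping import (
    BinStats,
    FrequencySeries,
    MappingInterval,
    VariantCallSet,
    binned_homozygous_frequency,
    call_variants,
    candidate_variants,
    detect_cluster_interval,
    detect_gap_interval,
    detect_peak_interval,
    filter_homozygous,
    fit_loess,
    frequency_floor_filter,
    intervals_to_bed,
    reciprocal_interval,
    snp_frequency_series,
    subtract_background,
)
from wgsmap.readsim import AlleleCountTable, SNPPanel


def make_counts(rows):
    df = pd.DataFrame(rows, columns=["chromosome", "position", "ref", "alt",
                                     "alt_count", "depth", "site_class"])
    df["ref_count"] = df["depth"] - df["alt_count"]
    return AlleleCountTable(df[["chromosome", "position", "ref", "alt",
                                "ref_count", "alt_count", "depth", "site_class"]])


def make_calls(rows, **kw):
    return call_variants(make_counts(rows), **kw)


class TestCallFilters:
    def test_min_reads_rule(self):
        calls = make_calls([
            ("I", 100, "A", "T", 2, 20, "panel"),   # below threshold
            ("I", 200, "A", "T", 3, 20, "panel"),   # at threshold
            ("I", 300, "A", "T", 5, 0, "panel"),
        ])
        # depth-0 rows are rejected by the count-table invariant upstream;
        # construct a 0-depth row directly instead
        calls = make_calls([
            ("I", 100, "A", "T", 2, 20, "panel"),
            ("I", 200, "A", "T", 3, 20, "panel"),
            ("I", 300, "A", "T", 0, 0, "panel"),
        ])
        assert list(calls.passing) == [False, True, False]
        assert calls.calls.loc[1, "alt_fraction"] == pytest.approx(0.15)
        assert np.isnan(calls.calls.loc[2, "alt_fraction"])

    def test_frequency_floor(self):
        calls = make_calls([
            ("I", 100, "A", "T", 4, 100, "panel"),   # 4% < floor
            ("I", 200, "A", "T", 6, 100, "panel"),   # 6% passes
        ])
        floored = frequency_floor_filter(calls, 0.05)
        assert list(floored.passing) == [False, True]
        identity = frequency_floor_filter(calls, 0.0)
        assert list(identity.passing) == list(calls.passing)

    @given(
        min_reads=st.integers(0, 10), min_reads2=st.integers(0, 10),
        floor=st.floats(0, 0.5), floor2=st.floats(0, 0.5),
    )
    @settings(max_examples=40, deadline=None)
    def test_filter_monotonicity(self, min_reads, min_reads2, floor, floor2):
        """Stricter thresholds never enlarge the surviving call set."""
        rng = np.random.default_rng(55)
        depth = rng.integers(0, 40, size=80)
        alt = np.array([rng.integers(0, d + 1) for d in depth])
        rows = [("I", int(i + 1), "A", "T", int(a), int(d), "panel")
                for i, (a, d) in enumerate(zip(alt, depth))]
        lo_r, hi_r = sorted([min_reads, min_reads2])
        lo_f, hi_f = sorted([floor, floor2])
        loose = frequency_floor_filter(make_calls(rows, min_reads=lo_r), lo_f)
        strict = frequency_floor_filter(make_calls(rows, min_reads=hi_r), hi_f)
        loose_set = set(loose.passing_calls()["position"])
        strict_set = set(strict.passing_calls()["position"])
        assert strict_set <= loose_set

    def test_homozygous_filter_thresholds(self):
        calls = make_calls([
            ("I", 100, "A", "T", 14, 14, "background"),  # depth 14: removed
            ("I", 200, "A", "T", 16, 20, "background"),  # 80% exactly: removed
            ("I", 300, "A", "T", 19, 20, "background"),  # 95%: kept, not full
            ("I", 400, "A", "T", 20, 20, "background"),  # 100%: kept, full
        ])
        hom = filter_homozygous(calls, min_depth=15, min_fraction=0.8)
        assert list(hom.calls["position"]) == [300, 400]
        assert list(hom.calls["full_homozygous"]) == [False, True]


class TestFrequencySeries:
    def test_failed_panel_sites_enter_at_zero(self):
        panel = SNPPanel(pd.DataFrame({
            "chromosome": ["I", "I"], "position": [100, 200],
            "ref": ["A", "A"], "alt": ["T", "T"], "source": ["map", "map"],
        }))
        calls = make_calls([
            ("I", 100, "A", "T", 10, 20, "panel"),
            ("I", 200, "A", "T", 1, 20, "panel"),   # fails min_reads
            ("I", 300, "A", "T", 10, 20, "background"),
        ])
        series = snp_frequency_series(calls, panel, {"I": 1000})
        assert list(series.data["position"]) == [100, 200]
        assert list(series.data["frequency"]) == [0.5, 0.0]

    def test_empty_chromosome_flagged_not_fatal(self):
        panel = SNPPanel(pd.DataFrame({
            "chromosome": ["I"], "position": [100],
            "ref": ["A"], "alt": ["T"], "source": ["map"],
        }))
        calls = make_calls([("I", 100, "A", "T", 10, 20, "panel")])
        series = snp_frequency_series(calls, panel, {"I": 1000, "II": 1000})
        assert series.empty_chromosomes == ["II"]


def linear_series(n=200, length=2_000_000, f=lambda x: 0.5 * np.ones_like(x),
                  chrom="I", seed=0):
    rng = np.random.default_rng(seed)
    pos = np.sort(rng.integers(1, length, size=n))
    return FrequencySeries(
        pd.DataFrame({"chromosome": chrom, "position": pos,
                      "frequency": f(pos.astype(float))}),
        {chrom: length},
    )


class TestLoess:
    def test_constant_series_fits_constant(self):
        series = linear_series(f=lambda x: np.full_like(x, 0.5))
        curve = fit_loess(series)
        grid, vals = curve.on("I")
        assert np.allclose(vals, 0.5, atol=1e-9)
        assert grid[0] == 1 and grid[-1] == 2_000_000

    def test_global_linear_fit_matches_least_squares(self):
        """span=1, degree=1 reduces LOESS toward an ordinary regression line."""
        length = 2_000_000
        series = linear_series(f=lambda x: 0.2 + 0.3 * x / length, seed=1)
        curve = fit_loess(series, span=1.0, degree=1, clip=None)
        grid, vals = curve.on("I")
        x = series.data["position"].to_numpy(float)
        y = series.data["frequency"].to_numpy(float)
        slope, intercept = np.polyfit(x, y, 1)
        expected = intercept + slope * grid
        # Tricube weighting differs from uniform OLS weights, but on an
        # exactly linear signal both recover the line.
        assert np.allclose(vals, expected, atol=1e-9)

    def test_v_shape_minimum_near_locus(self):
        length = 2_000_000
        locus = 1_200_000

        def v(x):
            return np.abs(x - locus) / length

        series = linear_series(n=400, f=v, seed=2)
        curve = fit_loess(series, span=0.1, degree=2)
        grid, vals = curve.on("I")
        assert abs(grid[np.argmin(vals)] - locus) <= 3 * curve.grid_step

    def test_fit_stays_within_data_range(self):
        rng = np.random.default_rng(3)
        series = linear_series(n=300, f=lambda x: rng.uniform(0.2, 0.8, x.size),
                               seed=3)
        curve = fit_loess(series, clip=None)
        _, vals = curve.on("I")
        y = series.data["frequency"]
        assert vals.min() >= y.min() - 0.05 and vals.max() <= y.max() + 0.05

    def test_agrees_with_statsmodels_lowess(self):
        """Local-linear fit cross-checked against the statsmodels LOWESS."""
        import statsmodels.api as sm

        length = 2_000_000
        series = linear_series(
            n=500, f=lambda x: 0.5 + 0.3 * np.sin(2 * np.pi * x / length),
            seed=4)
        x = series.data["position"].to_numpy(float)
        y = series.data["frequency"].to_numpy(float)
        grid = np.linspace(1, length, 50)
        sm_vals = sm.nonparametric.lowess(y, x, frac=0.3, it=0, xvals=grid)
        from wgsmap.mapping import _loess_1d

        mine = _loess_1d(x, y, grid, span=0.3, degree=1)
        assert np.max(np.abs(mine - sm_vals)) < 0.02

    def test_too_few_points_is_explicit(self):
        series = linear_series(n=5)
        with pytest.raises(InsufficientDataError):
            fit_loess(series)


class TestGapDetection:
    def test_no_interval_when_curve_above_threshold(self):
        series = linear_series(f=lambda x: np.full_like(x, 0.5))
        curve = fit_loess(series)
        assert detect_gap_interval(series, curve, 0.1) == []

    def test_gap_localized_on_v_profile(self):
        length, locus = 2_000_000, 1_200_000
        series = linear_series(
            n=500, f=lambda x: np.minimum(np.abs(x - locus) / (0.4 * length), 0.5),
            seed=5)
        curve = fit_loess(series, span=0.05)
        (iv,) = detect_gap_interval(series, curve, 0.1)
        assert iv.contains("I", locus)
        assert iv.length < length / 2
        assert iv.score > 0


class TestBinnedPeak:
    def make_bins(self, freqs, chrom="II"):
        rows = [{"chromosome": chrom, "start": i * 500_000 + 1,
                 "n_panel_sites": 10, "n_called_homozygous": int(f * 10),
                 "normalized_frequency": f} for i, f in enumerate(freqs)]
        return BinStats(pd.DataFrame(rows), 500_000, 0.95)

    def test_empty_bin_guarded(self):
        panel = SNPPanel(pd.DataFrame({
            "chromosome": ["I"], "position": [100],
            "ref": ["A"], "alt": ["T"], "source": ["map"],
        }))
        calls = make_calls([("I", 100, "A", "T", 20, 20, "panel")])
        bins = binned_homozygous_frequency(calls, panel, {"I": 2_000_000})
        sub = bins.bins
        assert sub.loc[sub["start"] == 1, "normalized_frequency"].item() == 1.0
        assert (sub.loc[sub["start"] > 500_000, "normalized_frequency"] == 0).all()

    def test_half_fraction_sites_never_homozygous(self):
        panel = SNPPanel(pd.DataFrame({
            "chromosome": "I", "position": np.arange(1, 50) * 10_000,
            "ref": "A", "alt": "T", "source": "map",
        }))
        rows = [("I", int(p), "A", "T", 10, 20, "panel")
                for p in panel.sites["position"]]
        bins = binned_homozygous_frequency(make_calls(rows), panel, {"I": 2_000_000})
        assert (bins.bins["normalized_frequency"] == 0).all()

    def test_single_nonzero_bin(self):
        bins = self.make_bins([0, 0, 0.8, 0, 0])
        iv = detect_peak_interval(bins)
        assert (iv.start, iv.end) == (1_000_001, 1_500_000)
        assert not iv.degenerate

    def test_flat_profile_degenerate(self):
        bins = self.make_bins([0.5] * 6)
        iv = detect_peak_interval(bins)
        assert iv.degenerate
        assert (iv.start, iv.end) == (1, 3_000_000)

    def test_all_zero_is_no_signal(self):
        with pytest.raises(NoSignalError):
            detect_peak_interval(self.make_bins([0, 0, 0]))

    def test_plateau_contains_argmax(self):
        bins = self.make_bins([0.2, 0.9, 1.0, 0.95, 0.3, 1.0])
        iv = detect_peak_interval(bins, plateau_drop=0.2)
        # the run holding an argmax bin and the longest extent wins
        assert (iv.start, iv.end) == (500_001, 2_000_000)


class TestBackgroundSubtraction:
    ROWS = [("I", 100, "A", "T", 20, 20, "background"),
            ("I", 200, "A", "G", 20, 20, "background"),
            ("II", 300, "C", "T", 20, 20, "background")]

    def test_identical_sets_cancel(self):
        a = make_calls(self.ROWS)
        assert len(subtract_background(a, make_calls(self.ROWS)).calls) == 0

    def test_disjoint_sets_pass_through(self):
        other = make_calls([("III", 999, "G", "C", 20, 20, "background")])
        out = subtract_background(make_calls(self.ROWS), other)
        assert len(out.calls) == len(self.ROWS)

    def test_allele_aware_matching(self):
        ref = make_calls([("I", 100, "A", "G", 20, 20, "background")])
        out = subtract_background(make_calls(self.ROWS), ref)
        # same position, different alt allele: retained
        assert ("I", 100) in set(zip(out.calls["chromosome"], out.calls["position"]))

    def test_reference_failing_calls_do_not_subtract(self):
        ref = make_calls([("I", 100, "A", "T", 1, 20, "background")])  # < 3 reads
        out = subtract_background(make_calls(self.ROWS), ref)
        assert len(out.calls) == len(self.ROWS)

    def test_constructed_30_shared_70_novel(self):
        shared = [("I", 1000 + i, "A", "T", 20, 20, "background") for i in range(30)]
        novel = [("II", 5000 + i, "C", "G", 20, 20, "background") for i in range(70)]
        sample = make_calls(shared + novel)
        reference = make_calls(shared)
        out = subtract_background(sample, reference)
        assert len(out.calls) == 70

    def test_positional_tolerance(self):
        ref = make_calls([("I", 102, "A", "T", 20, 20, "background")])
        sample = make_calls(self.ROWS)
        assert len(subtract_background(sample, ref, position_tolerance=0).calls) == 3
        assert len(subtract_background(sample, ref, position_tolerance=5).calls) == 2


class TestClusterDetection:
    def hom(self, rows):
        return filter_homozygous(make_calls(rows))

    def test_single_chain_spans_first_to_last(self):
        rows = [("V", int(p), "A", "T", 20, 20, "background")
                for p in [1e6, 1.5e6, 2.2e6, 3.0e6]]
        iv = detect_cluster_interval(self.hom(rows), max_gap=2e6, min_members=3)
        assert (iv.start, iv.end) == (1_000_000, 3_000_000)
        assert iv.score == 1.0

    def test_enrichment_score_is_chain_share(self):
        rows = ([("V", int(1e6 + i * 2e5), "A", "T", 20, 20, "background")
                 for i in range(8)]
                + [("II", int(5e6), "A", "T", 20, 20, "background"),
                   ("III", int(6e6), "A", "T", 20, 20, "background")])
        iv = detect_cluster_interval(self.hom(rows))
        assert iv.chromosome == "V"
        assert iv.score == pytest.approx(8 / 10)

    def test_scattered_calls_raise_no_cluster(self):
        rows = [(c, int(1e6), "A", "T", 20, 20, "background")
                for c in ["I", "II", "III", "IV", "V", "X"]]
        with pytest.raises(NoClusterError):
            detect_cluster_interval(self.hom(rows), max_gap=2e6, min_members=3)


class TestReciprocal:
    def hom_segment(self, lo, hi, n=20, chrom="V", frac=1.0):
        pos = np.linspace(lo, hi, n).astype(int)
        rows = [(chrom, int(p), "A", "T", int(frac * 20), 20, "background")
                for p in pos]
        return filter_homozygous(make_calls(rows))

    def test_identical_samples_recover_single_sample_interval(self):
        hom = self.hom_segment(5_000_000, 10_000_000)
        single = detect_cluster_interval(hom)
        rec = reciprocal_interval(hom, hom, {"V": 20_000_000})
        assert (rec.start, rec.end) == (single.start, single.end)

    def test_offset_samples_intersect(self):
        """Both samples cover all sites; only the co-homozygous span is called."""
        pos = np.linspace(4_000_000, 14_000_000, 60).astype(int)

        def sample(lo, hi):
            rows = [("V", int(p), "A", "T",
                     20 if lo <= p <= hi else 6, 20, "background")
                    for p in pos]
            calls = make_calls(rows)
            return filter_homozygous(calls), calls

        hom_a, calls_a = sample(4_000_000, 10_000_000)   # left-marked pool
        hom_b, calls_b = sample(7_000_000, 14_000_000)   # right-marked pool
        rec = reciprocal_interval(hom_a, hom_b, {"V": 20_000_000},
                                  calls_a=calls_a, calls_b=calls_b)
        # co-homozygous overlap is [7,10] Mb; outside it the average is 0.65
        assert rec.start < 8_000_000 < 9_000_000 < rec.end
        assert rec.start > 5_500_000 and rec.end < 11_500_000

    def test_never_reaching_threshold_is_explicit(self):
        a = self.hom_segment(1_000_000, 2_000_000, frac=1.0)
        b = self.hom_segment(15_000_000, 16_000_000, frac=1.0)
        with pytest.raises(NoIntervalError):
            reciprocal_interval(a, b, {"V": 20_000_000}, threshold=0.95)


class TestCandidates:
    CALLS = [("I", 900, "A", "T", 20, 20, "background"),
             ("I", 1500, "C", "G", 20, 20, "background"),
             ("I", 2000, "G", "A", 18, 20, "background"),
             ("II", 1500, "T", "C", 20, 20, "background")]

    def interval(self, start=1000, end=2000):
        return MappingInterval("I", start, end, "gap", 1.0)

    def test_closed_interval_boundaries(self):
        hom = filter_homozygous(make_calls(self.CALLS))
        out = candidate_variants(hom, self.interval())
        assert list(out["position"]) == [1500, 2000]  # end inclusive

    def test_empty_overlap(self):
        hom = filter_homozygous(make_calls(self.CALLS))
        assert len(candidate_variants(hom, self.interval(3000, 4000))) == 0

    def test_annotation_prioritizes_protein_altering(self):
        hom = filter_homozygous(make_calls(self.CALLS))
        ann = pd.DataFrame({
            "chromosome": ["I", "I"], "position": [1500, 2000],
            "gene": ["geneA", "geneB"],
            "effect_class": ["synonymous", "nonsynonymous"],
        })
        out = candidate_variants(hom, self.interval(), ann)
        assert list(out["position"]) == [2000, 1500]

    def test_bed_export_is_zero_based_half_open(self, tmp_path):
        p = tmp_path / "iv.bed"
        intervals_to_bed([self.interval()], p)
        chrom, start, end, method, _ = p.read_text().split()
        assert (chrom, start, end, method) == ("I", "999", "2000", "gap")
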