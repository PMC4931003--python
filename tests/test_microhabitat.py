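"""Operative-temperature profiling, suitability and comparisons."""

import datetime

import numpy as np
import pytest

from thermoreg import (
    MicrohabitatGeneratorConfig,
    OperativeRecord,
    PreferredRange,
    compare_microhabitats,
    hourly_suitability,
    summarize_operative,
    thermal_quality,
)


def _rec(micro, hour_min, t_e, model="M1", day=1):
    return OperativeRecord(
        model_id=model,
        microhabitat=micro,
        date=datetime.date(2012, 8, day),
        time=float(hour_min),
        t_e=t_e,
    )


class TestSummarize:
    def test_single_cell_summary(self, reported_ptr):
        recs = [_rec("moss", 10 * 60 + m, t) for m, t in [(0, 20.0), (5, 21.0), (10, 22.0)]]
        prof = summarize_operative(recs, reported_ptr)
        row = prof.table.loc[("moss", 10)]
        assert row["n"] == 3
        assert row["mean"] == pytest.approx(21.0)
        assert row["sd"] == pytest.approx(1.0)
        assert (row["min"], row["max"]) == (20.0, 22.0)
        assert prof.global_mean == pytest.approx(21.0)

    def test_all_inside_ptr_fraction_one(self, reported_ptr):
        recs = [_rec("grass", 11 * 60 + 5 * i, 31.5 + 0.05 * i) for i in range(5)]
        prof = summarize_operative(recs, reported_ptr)
        assert np.all(prof.table["frac_in_ptr"] == 1.0)

    def test_records_outside_window_excluded(self, reported_ptr):
        recs = [_rec("soil", 10 * 60, 15.0), _rec("soil", 3 * 60, 5.0)]
        prof = summarize_operative(recs, reported_ptr, hours=(9, 18))
        assert prof.n_total == 1

    def test_generator_mean_matches_analytic_model(self, operative_records, reported_ptr):
        cfg = MicrohabitatGeneratorConfig()
        prof = summarize_operative(operative_records, reported_ptr)
        analytic = cfg.analytic_mean()
        se = prof.global_sd / np.sqrt(prof.n_total)
        assert abs(prof.global_mean - analytic) < 2.0 * se


class TestSuitability:
    def test_constructed_coverage(self, reported_ptr):
        # rock_south tracks the PTR at midday, flat_rock in the morning.
        recs = [_rec("flat_rock", h * 60, 31.5) for h in range(9, 13)]
        recs += [_rec("rock_south", h * 60, 32.0) for h in range(13, 18)]
        prof = summarize_operative(recs, reported_ptr)
        suit = hourly_suitability(prof)
        assert suit.all_hours_covered
        assert set(suit.flags) == set(range(9, 18))

    def test_all_cold_no_coverage(self, reported_ptr):
        recs = [_rec("soil", h * 60, 20.0) for h in range(9, 18)]
        suit = hourly_suitability(summarize_operative(recs, reported_ptr))
        assert not any(suit.flags.values())
        assert not suit.all_hours_covered

    def test_generator_defaults_cover_all_hours(self, operative_records, reported_ptr):
        prof = summarize_operative(operative_records, reported_ptr)
        assert hourly_suitability(prof).all_hours_covered

    def test_monotone_in_ptr_breadth(self, operative_records):
        """Widening the set-point range can only turn flags on."""
        narrow = PreferredRange(31.18, 32.50)
        wide = PreferredRange(29.18, 34.50)
        f_narrow = hourly_suitability(
            summarize_operative(operative_records, narrow)
        ).flags
        f_wide = hourly_suitability(
            summarize_operative(operative_records, wide)
        ).flags
        for h, flag in f_narrow.items():
            if flag:
                assert f_wide[h]

    def test_hourly_mean_criterion(self, reported_ptr):
        recs = [_rec("moss", 10 * 60, 25.0), _rec("moss", 10 * 60 + 5, 38.0)]
        prof = summarize_operative(recs, reported_ptr)
        # mean 31.5 is inside the PTR even though no reading is
        assert hourly_suitability(prof, criterion="hourly_mean").flags[10]
        assert not hourly_suitability(prof, criterion="any_reading").flags[10]


class TestThermalQuality:
    def test_all_inside_gives_zero(self, reported_ptr):
        recs = [_rec("moss", 10 * 60, 31.5), _rec("moss", 11 * 60, 32.0)]
        assert thermal_quality(recs, reported_ptr).mean == 0.0

    def test_single_reading_arithmetic(self, reported_ptr):
        recs = [_rec("soil", 12 * 60, 21.60)]
        assert thermal_quality(recs, reported_ptr).values[0] == pytest.approx(9.58)

    def test_generator_within_ten_percent_of_analytic_expectation(
        self, operative_records, reported_ptr
    ):
        cfg = MicrohabitatGeneratorConfig()
        de = thermal_quality(operative_records, reported_ptr)
        expected = cfg.analytic_mean_deviation(reported_ptr)
        assert abs(de.mean - expected) < 0.1 * expected

    def test_pooled_mean_is_weighted_mean_over_microhabitats(
        self, operative_records, reported_ptr
    ):
        """Conservation under partition: the pooled mean d_e equals
        the n-weighted mean of per-microhabitat means."""
        pooled = thermal_quality(operative_records, reported_ptr)
        per = {}
        for m in set(r.microhabitat for r in operative_records):
            sub = [r for r in operative_records if r.microhabitat == m]
            d = thermal_quality(sub, reported_ptr)
            per[m] = (d.mean, len(d))
        weighted = sum(m * n for m, n in per.values()) / sum(n for _, n in per.values())
        assert pooled.mean == pytest.approx(weighted, rel=1e-12)


class TestCompareMicrohabitats:
    def test_generator_defaults_mirror_field_grouping(
        self, operative_records, reported_ptr
    ):
        """Sun-exposed flat rock, moss and south-facing rock are
        statistically interchangeable and rank nearest the set-point
        range; sheltered categories rank last."""
        comp = compare_microhabitats(operative_records, reported_ptr)
        assert comp.kruskal.p_value < 1e-6
        assert comp.kruskal.df == (8,)
        warm = {"flat_rock", "moss", "rock_south"}
        ranked = [m for m, _ in comp.ranking]
        assert set(ranked[:3]) == warm
        for a in warm:
            for b in warm:
                if a < b:
                    assert comp.nemenyi.loc[a, b] > 0.05
        # grass / east / west mutually distinct
        mid = ["grass", "rock_east", "rock_west"]
        for a in mid:
            for b in mid:
                if a < b:
                    assert comp.nemenyi.loc[a, b] < 0.01

    def test_order_invariance(self, reported_ptr):
        rng = np.random.default_rng(5)
        recs = [
            _rec(m, (9 + i % 9) * 60, 20.0 + rng.normal())
            for i, m in enumerate(
                ["moss", "soil", "grass"] * 20
            )
        ]
        comp1 = compare_microhabitats(recs, reported_ptr)
        comp2 = compare_microhabitats(recs[::-1], reported_ptr)
        assert comp1.kruskal.statistic == pytest.approx(comp2.kruskal.statistic)
        assert comp1.kruskal.p_value == pytest.approx(comp2.kruskal.p_value)
        assert [m for m, _ in comp1.ranking] == [m for m, _ in comp2.ranking]
        for (_, d1), (_, d2) in zip(comp1.ranking, comp2.ranking):
            assert d1 == pytest.approx(d2)

    def test_ranking_shift_invariance(self, reported_ptr):
        """Adding a constant to every temperature and both PTR bounds
        leaves the suitability ranking unchanged."""
        rng = np.random.default_rng(6)
        base = [
            _rec(m, 12 * 60, t + rng.normal())
            for m, t in [("moss", 30.0), ("soil", 15.0), ("grass", 22.0)]
            for _ in range(10)
        ]
        shifted = [
            OperativeRecord(r.model_id, r.microhabitat, r.date, r.time, r.t_e + 5.0)
            for r in base
        ]
        ptr_shift = PreferredRange(reported_ptr.lower + 5.0, reported_ptr.upper + 5.0)
        r1 = [m for m, _ in compare_microhabitats(base, reported_ptr).ranking]
        r2 = [m for m, _ in compare_microhabitats(shifted, ptr_shift).ranking]
        assert r1 == r2

    def test_needs_three_microhabitats(self, reported_ptr):
        recs = [_rec("moss", 10 * 60, 20.0), _rec("soil", 10 * 60, 15.0)]
        with pytest.raises(ValueError, match=">= 3"):
            compare_microhabitats(recs, reported_ptr)
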