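"""Lunar phase assignment and the circular/Monte Carlo test battery."""

import datetime as dt

import numpy as np
import pytest

from infradian import (
    Cohort,
    CycleSeries,
    InsufficientDataError,
    LunarConfig,
    ParameterError,
    PhaseCountTable,
    SimulationParams,
    chi_square_uniformity,
    circular_mean_per_woman,
    circular_smooth,
    count_onsets_by_phase,
    generate_cohort,
    lunar_phase_angle,
    monte_carlo_shift_test,
    phase_bin,
    rayleigh_grouped,
    rayleigh_per_woman,
)
from infradian import reference

CONFIG = LunarConfig()
EPOCH_DATE = dt.datetime(2000, 1, 6, 18, 14)


def _one_cycle_series(woman_id, start):
    return CycleSeries(woman_id, start, (29,))


class TestPhaseAngle:
    def test_epoch_is_new_moon(self):
        assert lunar_phase_angle(EPOCH_DATE) == pytest.approx(0.0)

    def test_periodicity(self):
        later = EPOCH_DATE + dt.timedelta(days=CONFIG.synodic_period)
        a = lunar_phase_angle(later)
        # circular distance to 0 deg (float roundoff may land at 360 - eps)
        assert abs((a + 180) % 360 - 180) < 1e-6

    def test_half_period_is_full_moon(self):
        mid = EPOCH_DATE + dt.timedelta(days=14.765)
        assert lunar_phase_angle(mid) == pytest.approx(180.0, abs=0.01)

    def test_dates_before_epoch_wrap_positively(self):
        a = lunar_phase_angle(dt.date(1960, 3, 1))
        assert 0 <= a < 360


class TestPhaseBin:
    @pytest.mark.parametrize(
        "angle, name",
        [(0.0, "new"), (180.0, "full"), (22.4, "new"), (22.6, "waxing_crescent"),
         (337.6, "new"), (90.0, "first_quarter")],
    )
    def test_centered_sector_convention(self, angle, name):
        assert phase_bin(angle) == name

    def test_out_of_range_rejected(self):
        with pytest.raises(ParameterError):
            phase_bin(360.0)


class TestCounts:
    def test_counts_sum_to_cycle_total(self, small_cohort):
        table = count_onsets_by_phase(small_cohort)
        assert table.total == small_cohort.n_cycles

    def test_onsets_at_new_moon_all_in_new_bin(self):
        series = tuple(
            _one_cycle_series(
                f"W{k}",
                (EPOCH_DATE + dt.timedelta(days=round(k * CONFIG.synodic_period))).date(),
            )
            for k in range(10)
        )
        table = count_onsets_by_phase(Cohort(series))
        assert table.counts[0] == 10 and table.total == 10

    def test_matches_per_cycle_brute_force(self, null_cohort):
        table = count_onsets_by_phase(null_cohort)
        brute = np.zeros(8, dtype=int)
        from infradian.lunar import PHASE_NAMES

        for s in null_cohort:
            for onset in s.onset_dates():
                brute[PHASE_NAMES.index(phase_bin(lunar_phase_angle(onset)))] += 1
        assert tuple(brute) == table.counts

    def test_phase_angles_invariant_under_synodic_shift(self):
        dates = [dt.date(1990, 5, 17), dt.date(2003, 11, 2)]
        for d in dates:
            a0 = lunar_phase_angle(d)
            a1 = lunar_phase_angle(
                dt.datetime(d.year, d.month, d.day)
                + dt.timedelta(days=CONFIG.synodic_period)
            )
            assert abs((a1 - a0 + 180) % 360 - 180) < 1e-3


class TestChiSquare:
    def test_published_total_rows(self):
        assert chi_square_uniformity(reference.EUROPEAN_TOTAL).p_value == pytest.approx(
            0.0214, abs=0.0005
        )
        assert chi_square_uniformity(
            reference.NORTH_AMERICAN_TOTAL
        ).p_value == pytest.approx(0.0952, abs=0.0005)

    def test_equal_counts_are_uniform(self):
        res = chi_square_uniformity(PhaseCountTable((1000,) * 8))
        assert res.statistic == 0 and res.p_value == 1

    def test_statistic_invariant_under_rotation(self):
        counts = reference.EUROPEAN_TOTAL.counts
        rotated = PhaseCountTable(counts[3:] + counts[:3])
        assert chi_square_uniformity(rotated).statistic == pytest.approx(
            chi_square_uniformity(reference.EUROPEAN_TOTAL).statistic
        )

    def test_empty_table_rejected(self):
        with pytest.raises(InsufficientDataError):
            chi_square_uniformity(PhaseCountTable((0,) * 8))


class TestRayleighGrouped:
    def test_published_total_rows(self):
        assert rayleigh_grouped(reference.EUROPEAN_TOTAL).p_value == pytest.approx(
            0.0056, abs=0.0005
        )
        assert rayleigh_grouped(
            reference.NORTH_AMERICAN_TOTAL
        ).p_value == pytest.approx(0.0226, abs=0.0005)

    def test_uniform_counts_cancel(self):
        res = rayleigh_grouped(PhaseCountTable((500,) * 8))
        assert res.rbar == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_single_bin_maximal_resultant(self):
        res = rayleigh_grouped(PhaseCountTable((0, 0, 0, 0, 300, 0, 0, 0)))
        assert res.rbar == pytest.approx(1.0)
        assert res.mean_direction == pytest.approx(180.0)

    def test_z_invariant_direction_rotates_under_rotation(self):
        counts = reference.NORTH_AMERICAN_TOTAL.counts
        base = rayleigh_grouped(reference.NORTH_AMERICAN_TOTAL)
        rot = rayleigh_grouped(PhaseCountTable(counts[2:] + counts[:2]))
        assert rot.statistic == pytest.approx(base.statistic)
        assert (base.mean_direction - rot.mean_direction) % 360 == pytest.approx(90.0)


class TestPerWoman:
    def test_single_onset_angle(self):
        d = (EPOCH_DATE + dt.timedelta(days=CONFIG.synodic_period / 4)).date()
        m = circular_mean_per_woman(_one_cycle_series("A", d))
        # day-resolution truncation to midnight keeps the angle within a day's phase step
        assert m == pytest.approx(90.0, abs=13.0)

    def test_vector_sum_of_two_angles(self):
        s = CycleSeries("A", dt.date(2000, 1, 1), (28, 30))
        a0, a1 = [lunar_phase_angle(d) for d in s.onset_dates()]
        expected = np.degrees(
            np.arctan2(
                np.sin(np.radians([a0, a1])).sum(), np.cos(np.radians([a0, a1])).sum()
            )
        ) % 360
        assert circular_mean_per_woman(s) == pytest.approx(expected)

    def test_antipodal_onsets_are_undefined(self, monkeypatch):
        # force two exactly opposite angles through the day-resolution grid
        from infradian import lunar as lunar_mod

        s = CycleSeries("A", dt.date(2000, 1, 1), (10, 10))
        monkeypatch.setattr(
            lunar_mod, "_onset_days_since_epoch",
            lambda series, config: np.array([0.0, config.synodic_period / 2]),
        )
        assert lunar_mod.circular_mean_per_woman(s) is None

    def test_identical_mean_angles_maximal_z(self):
        start = (EPOCH_DATE + dt.timedelta(days=3)).date()
        cohort = Cohort(tuple(_one_cycle_series(f"W{k}", start) for k in range(20)))
        res = rayleigh_per_woman(cohort)
        assert res.statistic == pytest.approx(20.0)
        assert res.p_value < 1e-6

    def test_requires_two_defined_means(self):
        cohort = Cohort((_one_cycle_series("A", dt.date(2000, 1, 1)),))
        with pytest.raises(InsufficientDataError):
            rayleigh_per_woman(cohort)

    def test_null_cohort_not_significant(self):
        cohort = generate_cohort(200, SimulationParams(n_cycles=12), seed=99)
        assert rayleigh_per_woman(cohort).p_value > 0.01


class TestShiftTest:
    def test_seed_reproducibility(self, null_cohort):
        a = monte_carlo_shift_test(null_cohort, n_iter=200, seed=1)
        b = monte_carlo_shift_test(null_cohort, n_iter=200, seed=1)
        assert a.ranks == b.ranks

    def test_observed_counts_match_direct_binning(self, null_cohort):
        res = monte_carlo_shift_test(null_cohort, n_iter=100, seed=2)
        assert res.observed.counts == count_onsets_by_phase(null_cohort).counts

    def test_null_cohort_ranks_not_extreme(self):
        # a single uncoupled cohort: ranks should sit inside the central band
        cohort = generate_cohort(150, SimulationParams(n_cycles=15), seed=3)
        res = monte_carlo_shift_test(cohort, n_iter=500, seed=4)
        assert all(0.001 < r < 0.999 for r in res.ranks)

    def test_coupled_cohort_flags_preferred_phase(self):
        params = SimulationParams(
            mu=29.53, sigma=2.0, osc_amplitude=0, ar1=0, jump_prob=0,
            lunar_kappa=2.0, lunar_mu=0.0, n_cycles=24,
        )
        cohort = generate_cohort(200, params, seed=5)
        res = monte_carlo_shift_test(cohort, n_iter=500, seed=6)
        assert res.ranks[0] > 0.975
        assert res.significant[0]

    def test_bonferroni_tightens_flags(self, null_cohort):
        raw = monte_carlo_shift_test(null_cohort, n_iter=300, seed=7)
        adj = monte_carlo_shift_test(null_cohort, n_iter=300, seed=7, bonferroni=True)
        assert sum(adj.significant) <= sum(raw.significant)


class TestCircularSmooth:
    def test_uniform_counts_constant_density(self):
        grid, dens = circular_smooth(PhaseCountTable((100,) * 8))
        # constant up to the sub-percent ripple of 45-deg-spaced kernels
        assert (dens.max() - dens.min()) / dens.mean() < 0.01

    def test_mass_conservation(self):
        table = PhaseCountTable((5, 40, 120, 30, 8, 3, 2, 12))
        grid, dens = circular_smooth(table, bandwidth=25.0)
        integral = np.sum(dens) * (360.0 / len(grid))
        assert integral == pytest.approx(table.total, rel=1e-6)

    def test_mode_near_raw_modal_bin(self):
        table = PhaseCountTable((5, 40, 120, 30, 8, 3, 2, 12))
        grid, dens = circular_smooth(table, bandwidth=25.0)
        mode = grid[np.argmax(dens)]
        assert abs((mode - 90.0 + 180) % 360 - 180) <= 45.0
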