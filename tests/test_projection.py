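import numpy as np
import pytest
from scipy import optimize

from thermopop import demography as dm
from thermopop import projection as pj
from thermopop import weather as w

from conftest import constant_weather


def _constant_curve(value: float) -> dm.ThermalPerformanceCurve:
    return dm.ThermalPerformanceCurve(
        "quadratic", (value, 0.0, 0.0), domain=(-50.0, 60.0)
    )


class TestBuildMatrix:
    def test_structure_is_first_row_plus_subdiagonal(self, schedule):
        M = pj.build_matrix(schedule, 22.0).array
        mask = np.zeros_like(M, dtype=bool)
        mask[0, :] = True
        mask[np.arange(1, 50), np.arange(49)] = True
        assert np.all(M[~mask] == 0.0)
        assert np.count_nonzero(M) <= 2 * 50 - 1

    def test_no_survival_out_of_last_class(self, schedule):
        M = pj.build_matrix(schedule, 22.0).array
        assert np.all(M[:, -1][1:] == 0.0)

    def test_cold_temperature_gives_zero_fecundity_and_subunit_eigenvalue(self, schedule):
        M = pj.build_matrix(schedule, -10.0)
        assert np.all(M.array[0, :] == 0.0)
        lam, _ = pj.dominant_eigen(M)
        assert lam < 1.0

    def test_shift_schedule_gives_pure_age_advance(self, shift_schedule):
        M = pj.build_matrix(shift_schedule, 20.0).array
        expected = np.zeros((50, 50))
        expected[np.arange(1, 50), np.arange(49)] = 1.0
        np.testing.assert_array_equal(M, expected)

    def test_eigenvalue_matches_euler_lotka_root(self):
        # constant survival p, reproduction f only at age 10:
        # lambda solves lambda**10 = f * p**9
        p, f = 0.9, 3.0
        weights = np.zeros(50)
        weights[9] = 1.0
        sched = dm.DemographicSchedule(
            {(1, 50): _constant_curve(p)}, weights, _constant_curve(f),
            sex_ratio_divisor=1.0,
        )
        lam, _ = pj.dominant_eigen(pj.build_matrix(sched, 20.0))
        root = optimize.brentq(lambda x: x**10 - f * p**9, 0.5, 5.0)
        assert lam == pytest.approx(root, abs=1e-10)

    def test_nonfinite_temperature_rejected(self, schedule):
        with pytest.raises(pj.ProjectionError):
            pj.build_matrix(schedule, float("nan"))


class TestProjectDay:
    def test_zero_vector_stays_zero(self, schedule):
        M = pj.build_matrix(schedule, 22.0)
        np.testing.assert_array_equal(pj.project_day(np.zeros(50), M), np.zeros(50))

    def test_shift_matrix_advances_a_cohort(self, shift_schedule):
        M = pj.build_matrix(shift_schedule, 20.0)
        n = np.zeros(50)
        n[40] = 100.0  # age 41
        out = pj.project_day(n, M)
        assert out[41] == 100.0
        assert out.sum() == 100.0

    def test_cohort_dies_after_last_age_class(self, shift_schedule):
        M = pj.build_matrix(shift_schedule, 20.0)
        n = np.zeros(50)
        n[40] = 100.0  # age 41
        for _ in range(9):
            n = pj.project_day(n, M)
        assert n[49] == 100.0  # age 50 after 9 advances
        n = pj.project_day(n, M)
        assert np.all(n == 0.0)

    def test_negative_input_rejected(self, schedule):
        M = pj.build_matrix(schedule, 22.0)
        bad = np.zeros(50)
        bad[3] = -1.0
        with pytest.raises(pj.ProjectionError):
            pj.project_day(bad, M)


class TestInitPopulation:
    def test_default_is_100_flies_over_ages_41_to_50(self):
        n = pj.init_population()
        assert n.sum() == 100.0
        np.testing.assert_array_equal(n[40:50], np.full(10, 10.0))
        assert np.all(n[:40] == 0.0)

    def test_zero_total_gives_zero_vector(self):
        assert np.all(pj.init_population(total=0.0) == 0.0)

    def test_single_class_initialization(self):
        n = pj.init_population(total=7.0, ages=(50, 50))
        assert n[49] == 7.0
        assert n.sum() == 7.0

    def test_bad_age_range_rejected(self):
        with pytest.raises(pj.ProjectionError):
            pj.init_population(ages=(45, 60))


class TestStageTally:
    def test_default_init_is_all_adults(self):
        t = pj.stage_tally(pj.init_population())
        assert (t.eggs, t.larvae, t.pupae, t.adults) == (0.0, 0.0, 0.0, 100.0)

    def test_band_widths(self):
        t = pj.stage_tally(np.ones(50))
        assert (t.eggs, t.larvae, t.pupae, t.adults) == (3.0, 4.0, 2.0, 41.0)

    def test_zero_vector(self):
        t = pj.stage_tally(np.zeros(50))
        assert t.total == 0.0


class TestDominantEigen:
    def test_reproduction_free_matrix_has_zero_growth(self, shift_schedule):
        lam, dist = pj.dominant_eigen(pj.build_matrix(shift_schedule, 20.0))
        assert lam == 0.0

    def test_two_class_hand_computed_case(self):
        # p1 = 0.5, f2 = 4 => lambda = sqrt(2)
        A = np.array([[0.0, 4.0], [0.5, 0.0]])
        lam, dist = pj.dominant_eigen(pj.LeslieMatrix(array=A, temperature=20.0))
        assert lam == pytest.approx(np.sqrt(2.0), abs=1e-12)
        # stable distribution: n1/n2 = lambda / p1... check M w = lambda w
        np.testing.assert_allclose(A @ dist, lam * dist, atol=1e-12)
        assert dist.sum() == pytest.approx(1.0)

    def test_all_zero_matrix_is_degenerate(self):
        lam, dist = pj.dominant_eigen(pj.LeslieMatrix(np.zeros((50, 50)), 20.0))
        assert lam == 0.0
        assert dist is None

    def test_agrees_with_power_iteration_oracle(self, schedule):
        # independent oracle: plain power iteration on random valid matrices
        rng = np.random.default_rng(17)
        for _ in range(10):
            k = 30
            A = np.zeros((k, k))
            A[0, :] = rng.uniform(0.0, 3.0, k)
            A[np.arange(1, k), np.arange(k - 1)] = rng.uniform(0.1, 1.0, k - 1)
            v = np.ones(k)
            lam_pi = 0.0
            for _ in range(20000):
                nv = A @ v
                lam_new = np.linalg.norm(nv)
                v = nv / lam_new
                if abs(lam_new - lam_pi) < 1e-14:
                    break
                lam_pi = lam_new
            lam, _ = pj.dominant_eigen(pj.LeslieMatrix(A, 0.0))
            assert lam == pytest.approx(lam_pi, abs=1e-10)


class TestBiofix:
    def test_constant_optimum_weather_fires_at_first_full_window(self, schedule):
        series = constant_weather(22.0, n_days=30)
        date = pj.detect_biofix(series, schedule, window=7, persistence=3)
        assert date == series.dates[6].date()

    def test_cold_weather_never_fires(self, schedule):
        series = constant_weather(2.0, n_days=60)
        with pytest.raises(pj.NoBiofix):
            pj.detect_biofix(series, schedule)

    def test_short_series_is_insufficient_data(self, schedule):
        series = constant_weather(22.0, n_days=5)
        with pytest.raises(pj.ProjectionError):
            pj.detect_biofix(series, schedule, window=7, persistence=3)

    def test_spring_crossing_found_within_persistence_of_bruteforce_scan(self, schedule):
        series = w.synth_weather(12.0, 8.0, 0.0, 0.0, "2013-01-01", 365, seed=0)
        window, persistence = 7, 3
        date = pj.detect_biofix(series, schedule, window=window, persistence=persistence)
        # oracle: brute-force lambda(T) scan on the trailing-window means
        tmean = series.tmean
        lams = []
        for i in range(window - 1, len(tmean)):
            t_bar = tmean[i - window + 1 : i + 1].mean()
            lams.append(pj.dominant_eigen(pj.build_matrix(schedule, t_bar))[0])
        crossing = next(i for i, lam in enumerate(lams) if lam > 1.0) + window - 1
        crossing_date = series.dates[crossing].date()
        assert abs((date - crossing_date).days) <= persistence


class TestRunSeason:
    def test_lethal_day_extinguishes_population(self, schedule):
        series = constant_weather(-20.0, n_days=3)
        traj = pj.run_season(series, schedule, biofix=series.dates[0].date())
        assert traj.totals[0] == 100.0
        assert traj.totals[1] == 0.0
        assert np.isnan(traj.log10_totals[1])
        assert traj.frame["extinct"].iloc[1]

    def test_constant_temperature_growth_matches_eigenvalue(self, schedule):
        T = 22.0
        series = constant_weather(T, n_days=201)
        traj = pj.run_season(series, schedule, biofix=series.dates[0].date())
        lam, sad = pj.dominant_eigen(pj.build_matrix(schedule, T))
        days = np.arange(150, 201)
        slope = np.polyfit(days, traj.log10_totals[150:201], 1)[0]
        assert slope == pytest.approx(np.log10(lam), abs=1e-6)
        v = traj.vectors[200] / traj.vectors[200].sum()
        assert np.abs(v - sad).sum() < 1e-6

    def test_deterministic_under_identical_inputs(self, schedule, temperate_weather):
        a = pj.run_season(temperate_weather, schedule, biofix="auto")
        b = pj.run_season(temperate_weather, schedule, biofix="auto")
        np.testing.assert_array_equal(a.vectors, b.vectors)
        assert a.biofix == b.biofix

    def test_biofix_outside_range_rejected(self, schedule, temperate_weather):
        with pytest.raises(Exception):
            pj.run_season(temperate_weather, schedule, biofix="2020-01-01")

    def test_conservation_and_nonnegativity_every_day(self, schedule, temperate_weather):
        traj = pj.run_season(temperate_weather, schedule, biofix="auto")
        assert np.all(traj.vectors >= 0.0)
        for vec, tally in zip(traj.vectors, traj.tallies()):
            assert tally.total == pytest.approx(vec.sum(), rel=1e-12)

    def test_cold_weather_trajectory_never_increases(self, schedule):
        # entirely below every curve's lower critical limit
        series = constant_weather(-5.0, n_days=40)
        traj = pj.run_season(series, schedule, biofix=series.dates[0].date())
        assert np.all(np.diff(traj.totals) <= 1e-12)

    def test_mortality_multiplier_hook_scales_survival(self, schedule):
        series = constant_weather(22.0, n_days=60)
        base = pj.run_season(series, schedule, biofix=series.dates[0].date())
        culled = pj.run_season(
            series, schedule, biofix=series.dates[0].date(),
            mortality_multiplier=np.full(50, 0.5),
        )
        assert culled.totals[-1] < base.totals[-1]

    def test_trajectory_csv_has_standard_columns(self, schedule, tmp_path):
        series = constant_weather(22.0, n_days=20)
        traj = pj.run_season(series, schedule, biofix=series.dates[0].date())
        path = tmp_path / "traj.csv"
        traj.to_csv(str(path))
        header = path.read_text().splitlines()[0].split(",")
        for col in ("date", "age_1", "age_50", "eggs", "larvae", "pupae",
                    "adults", "total", "log10_total"):
            assert col in header


class TestSeasonalPeaks:
    def test_hot_summer_profile_is_bimodal(self, schedule, hot_summer_weather):
        traj = pj.run_season(hot_summer_weather, schedule, biofix="auto")
        assert len(pj.seasonal_peaks(traj)) == 2

    def test_temperate_profile_has_single_late_peak(self, schedule, temperate_weather):
        traj = pj.run_season(temperate_weather, schedule, biofix="auto")
        peaks = pj.seasonal_peaks(traj)
        assert len(peaks) == 1
        # the single peak falls in the latter half of the projection
        assert peaks[0] > len(traj.dates) // 2
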