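import numpy as np
import pandas as pd
import pytest

from cotswatch import outbreak_dynamics as od
from cotswatch import synthetic_reefscape as synth
from cotswatch.surveillance_io import ThresholdConfig

from _oracles import oracle_detect_outbreak, oracle_reef_year_density


def _timeline(density, start_year=2010, sector="S"):
    density = np.asarray(density, dtype=float)
    years = np.arange(start_year, start_year + len(density))
    return od.SectorOutbreakTimeline(
        sector_id=sector, years=years, density=density,
        imputed=np.zeros(len(density), bool),
    )


class TestReefYearDensity:
    def test_max_across_programs_wins(self):
        tows = pd.DataFrame(
            [{"reef_id": "A", "year": 2015, "program": "LTMP", "cots_count": c}
             for c in (0, 1, 2)]
            + [{"reef_id": "A", "year": 2015, "program": "CONTROL", "cots_count": c}
               for c in (1, 3)]
        )
        out = od.reef_year_density(tows)
        assert len(out) == 1
        assert out.iloc[0]["mean_cots_per_tow"] == 2.0
        assert out.iloc[0]["source_program"] == "CONTROL"
        assert out.iloc[0]["programs_seen"] == "CONTROL,LTMP"

    def test_single_program_is_plain_mean(self):
        tows = pd.DataFrame(
            [{"reef_id": "A", "year": 2015, "program": "LTMP", "cots_count": c}
             for c in (2, 4)]
        )
        out = od.reef_year_density(tows)
        assert out.iloc[0]["mean_cots_per_tow"] == 3.0
        assert out.iloc[0]["source_program"] == "LTMP"

    def test_matches_brute_force_on_random_fixture(self):
        rng = np.random.default_rng(2)
        tows = pd.DataFrame(
            {
                "reef_id": rng.choice(["A", "B", "C"], 300),
                "year": rng.integers(2012, 2016, 300),
                "program": rng.choice(["LTMP", "RJFMP", "CONTROL"], 300),
                "cots_count": rng.poisson(0.8, 300),
            }
        )
        out = od.reef_year_density(tows).set_index(["reef_id", "year"])
        expected = oracle_reef_year_density(tows)
        assert len(out) == len(expected)
        for key, (mean, _prog) in expected.items():
            assert out.loc[key, "mean_cots_per_tow"] == pytest.approx(mean)


class TestClassifyReefStatus:
    @pytest.mark.parametrize(
        "density,expected",
        [
            (0.05, "below"),
            (0.15, "potential"),
            (0.5, "established"),
            (1.2, "severe"),
            (0.11, "below"),       # strict crossing of the potential threshold
            (0.22, "potential"),   # strict crossing of the established threshold
            (1.0, "severe"),       # severe boundary inclusive
        ],
    )
    def test_threshold_ladder(self, density, expected, thresholds):
        assert od.classify_reef_status(density, thresholds).value == expected

    def test_negative_density_rejected(self, thresholds):
        with pytest.raises(ValueError):
            od.classify_reef_status(-0.1, thresholds)


class TestSectorSeries:
    def test_unweighted_mean_of_reefs(self, registry):
        dens = pd.DataFrame(
            [{"reef_id": "R11", "sector_id": "North", "year": 2014,
              "mean_cots_per_tow": 0.2},
             {"reef_id": "R12", "sector_id": "North", "year": 2014,
              "mean_cots_per_tow": 0.4}]
        )
        tl = od.sector_density_series(dens, registry)[0]
        assert tl.density[0] == pytest.approx(0.3)

    def test_interior_gap_interpolated_and_flagged(self, registry):
        dens = pd.DataFrame(
            [{"reef_id": "R11", "sector_id": "North", "year": 2014,
              "mean_cots_per_tow": 0.1},
             {"reef_id": "R11", "sector_id": "North", "year": 2016,
              "mean_cots_per_tow": 0.3}]
        )
        tl = od.sector_density_series(dens, registry)[0]
        assert list(tl.years) == [2014, 2015, 2016]
        assert tl.density[1] == pytest.approx(0.2)
        assert list(tl.imputed) == [False, True, False]


class TestDetectOutbreakPeriod:
    def test_sub_threshold_series_has_no_window(self, thresholds):
        out = od.detect_outbreak_period(_timeline([0.05] * 6), thresholds)
        assert out.outbreak is None

    def test_single_year_exceedance_fails_persistence(self, thresholds):
        out = od.detect_outbreak_period(
            _timeline([0.05, 0.15, 0.09, 0.05, 0.04, 0.05]), thresholds
        )
        assert out.outbreak is None

    def test_full_criterion_trace(self, thresholds):
        """Inception at the first of two above-potential years, escalation at
        the established crossing, start one year prior, window closed by the
        two sub-potential years."""
        out = od.detect_outbreak_period(
            _timeline([0.05, 0.15, 0.25, 0.30, 0.08, 0.06], start_year=2011),
            thresholds,
        )
        w = out.outbreak
        assert w is not None
        assert (w.start_year, w.inception_year, w.escalation_year) == (2011, 2012, 2013)
        assert (w.decline_year, w.end_year, w.ongoing) == (2015, 2016, False)

    def test_established_inception_override_demands_higher_bar(self, thresholds):
        series = [0.05, 0.15, 0.15, 0.25, 0.30, 0.08, 0.06]
        default = od.detect_outbreak_period(_timeline(series), thresholds, False)
        stricter = od.detect_outbreak_period(_timeline(series), thresholds, True)
        assert default.outbreak.inception_year < stricter.outbreak.inception_year

    def test_no_decline_marks_ongoing_to_last_year(self, thresholds):
        out = od.detect_outbreak_period(
            _timeline([0.05, 0.2, 0.3, 0.5, 0.4], start_year=2015), thresholds
        )
        assert out.outbreak.ongoing
        assert out.outbreak.end_year == 2019
        assert out.outbreak.decline_year is None

    def test_short_series_hard_error(self, thresholds):
        with pytest.raises(ValueError, match="too short"):
            od.detect_outbreak_period(_timeline([0.1, 0.2]), thresholds)

    def test_agrees_with_enumeration_oracle_on_random_series(self, thresholds):
        rng = np.random.default_rng(17)
        grid = np.array([0.0, 0.05, 0.09, 0.11, 0.12, 0.2, 0.22, 0.25, 0.5, 1.0, 1.5])
        for case in range(2000):
            n = int(rng.integers(3, 13))
            dens = rng.choice(grid, n)
            override = bool(rng.integers(0, 2))
            got = od.detect_outbreak_period(
                _timeline(dens), thresholds, override
            ).outbreak
            exp = oracle_detect_outbreak(
                range(2010, 2010 + n), dens, thresholds, override
            )
            if exp is None:
                assert got is None, f"case {case}: {dens}"
            else:
                assert got is not None, f"case {case}: {dens}"
                for k, v in exp.items():
                    assert getattr(got, k) == v, f"case {case} field {k}: {dens}"

    def test_uniform_density_lift_never_delays_inception(self, thresholds):
        rng = np.random.default_rng(23)
        for _ in range(300):
            n = int(rng.integers(4, 12))
            dens = rng.uniform(0, 0.5, n)
            lift = float(rng.uniform(0.01, 0.5))
            base = od.detect_outbreak_period(_timeline(dens), thresholds).outbreak
            lifted = od.detect_outbreak_period(
                _timeline(dens + lift), thresholds
            ).outbreak
            if base is not None:
                assert lifted is not None
                assert lifted.inception_year <= base.inception_year


class TestWindowRecoveryOnScenarios:
    def test_detected_windows_overlap_truth_windows(self, thresholds):
        """On limited scenarios the windows detected from noisy tow data
        should closely overlap the windows in the noiseless truth series."""
        hits = 0
        seeds = range(10)
        for seed in seeds:
            bundle = synth.generate_scenario("limited", seed)
            ok = True
            for sector, grp in bundle.truth.groupby("sector_id"):
                series = grp.groupby("year")["true_density"].mean()
                truth_w = od.detect_outbreak_period(
                    _timeline(series.to_numpy(), start_year=int(series.index[0])),
                    thresholds,
                ).outbreak
                dens = od.reef_year_density(bundle.tows)
                tl = [
                    t
                    for t in od.sector_density_series(dens, bundle.registry)
                    if t.sector_id == sector
                ][0]
                obs_w = od.detect_outbreak_period(tl, thresholds).outbreak
                if truth_w is None or obs_w is None:
                    ok = truth_w is None and obs_w is None
                    continue
                a = set(range(truth_w.start_year, truth_w.end_year + 1))
                b = set(range(obs_w.start_year, obs_w.end_year + 1))
                if len(a & b) / len(a | b) < 0.6:
                    ok = False
            hits += ok
        assert hits >= 9
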