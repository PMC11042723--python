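import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from cotswatch import hierarchical_inference as hi


class TestPosteriorSummary:
    def test_standard_normal_draws_match_closed_form(self):
        rng = np.random.default_rng(0)
        draws = rng.standard_normal(20000)
        s = hi.posterior_summary(draws, "z")
        se = 3.0 / np.sqrt(draws.size)  # generous MC tolerance
        assert abs(s.median) < 4 * se
        assert s.ci90[0] == pytest.approx(-1.645, abs=0.05)
        assert s.ci90[1] == pytest.approx(1.645, abs=0.05)
        assert s.ci66[0] == pytest.approx(-0.954, abs=0.05)
        assert 50.0 <= s.prob_direction <= 52.0

    def test_point_mass_draws(self):
        s = hi.posterior_summary(np.full(600, 5.0))
        assert s.median == 5.0
        assert s.ci66 == (5.0, 5.0) and s.ci90 == (5.0, 5.0)
        assert s.prob_direction == 100.0

    def test_prob_direction_reports_dominant_mass(self):
        draws = np.concatenate([np.ones(680), -np.ones(320)])
        assert hi.posterior_summary(draws).prob_direction == pytest.approx(68.0)

    def test_intervals_nested(self):
        draws = np.random.default_rng(1).exponential(1.0, 5000)
        s = hi.posterior_summary(draws)
        assert s.ci90[0] <= s.ci66[0] <= s.ci66[1] <= s.ci90[1]

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError, match="500"):
            hi.posterior_summary(np.ones(100))


class TestFoldChange:
    @pytest.mark.parametrize(
        "a,b,expected", [(1.50, 0.21, 50 / 7), (3.0, 3.0, 1.0), (3.6, 1.6, 2.25)]
    )
    def test_ratio(self, a, b, expected):
        assert hi.fold_change(a, b) == pytest.approx(expected, rel=1e-9)

    def test_published_medians_round_to_sevenfold(self):
        assert round(hi.fold_change(1.50, 0.21)) == 7

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            hi.fold_change(1.0, 0.0)


def test_compress_keeps_unit_interval_open():
    y = np.array([0.0, 0.5, 1.0])
    z = hi.compress_unit_interval(y)
    assert np.all((z > 0) & (z < 1))
    assert z[1] == pytest.approx(0.5)


class TestWaveComparisonModel:
    def _values(self, response, sectors=("A",), waves=(3, 4), reefs=5):
        rows = []
        for s in sectors:
            for w in waves:
                for r in range(reefs):
                    rows.append(
                        {"reef_id": f"{s}{r}", "sector_id": s, "wave": w,
                         "response": response}
                    )
        return pd.DataFrame(rows)

    def test_constant_responses_give_null_contrast(self):
        out = hi.fit_wave_comparison_model(
            self._values(0.5), hi.ModelSpec(family="gaussian"), seed=2
        )
        contrast = out["contrasts"][0]
        assert contrast.median == pytest.approx(0.0, abs=0.05)
        assert contrast.ci90[0] < 0 < contrast.ci90[1]

    def test_single_wave_sector_reports_cell_without_contrast(self):
        df = pd.concat(
            [self._values(0.5, sectors=("A",)),
             self._values(0.4, sectors=("B",), waves=(4,))]
        )
        out = hi.fit_wave_comparison_model(
            df, hi.ModelSpec(family="gaussian"), seed=2
        )
        labels = [c.label for c in out["cells"]]
        assert "B|wave4" in labels
        assert all(not c.label.startswith("B:") for c in out["contrasts"])
        assert len(out["contrasts"]) == 1

    def test_outbreak_reef_filter(self):
        df = self._values(0.5)
        kept = hi.filter_outbreak_reefs(
            df, {r: (0.5 if r.endswith("0") else 0.05) for r in df["reef_id"]}, 0.11
        )
        assert set(kept["reef_id"]) == {"A0"}


class TestSectorCoverModel:
    def test_degenerate_single_category_data(self):
        tows = pd.DataFrame(
            [{"sector_id": "S", "reef_id": "R1", "year": y, "cover_category": 3}
             for y in (2014, 2015) for _ in range(20)]
        )
        out = hi.fit_sector_cover_model(tows, seed=5)
        assert len(out) == 2
        for _, row in out.iterrows():
            assert row["median"] == pytest.approx(0.405, abs=0.02)
            assert row["ci90_lo"] < row["median"] < row["ci90_hi"]

    def test_tow_order_invariance_up_to_mc_error(self):
        rng = np.random.default_rng(9)
        rows = []
        for reef in ("R1", "R2"):
            for year in (2014, 2015):
                cats = rng.integers(1, 5, 12)
                rows += [
                    {"sector_id": "S", "reef_id": reef, "year": year,
                     "cover_category": int(c)} for c in cats
                ]
        tows = pd.DataFrame(rows)
        a = hi.fit_sector_cover_model(tows, seed=5)
        b = hi.fit_sector_cover_model(
            tows.sample(frac=1.0, random_state=1), seed=5
        )
        assert np.allclose(a["median"], b["median"], atol=0.02)

    def test_reported_effects_converge_at_default_settings(self):
        rng = np.random.default_rng(12)
        rows = []
        for r, reef in enumerate(["R1", "R2", "R3"]):
            for year in (2014, 2015, 2016):
                mu = expit(logit(0.3) + 0.2 * (year - 2015) + 0.1 * r)
                cats = np.clip(
                    np.digitize(rng.beta(mu * 40, (1 - mu) * 40, 10),
                                [0.10, 0.30, 0.50, 0.75]),
                    0, 5,
                )
                rows += [
                    {"sector_id": "S", "reef_id": reef, "year": year,
                     "cover_category": int(c) + 1} for c in cats
                ]
        out = hi.fit_sector_cover_model(pd.DataFrame(rows), seed=3)
        assert (out["rhat_max"] < 1.05).all()


class TestTrajectorySmoother:
    def test_linear_signal_recovered_within_noise_band(self):
        rng = np.random.default_rng(7)
        x = np.tile(np.arange(7), 12)
        y = -6.0 * x + rng.normal(0, 4.0, x.size)
        df = pd.DataFrame(
            {"sector_id": "S", "years_since_onset": x, "relative_change_pct": y}
        )
        out = hi.fit_trajectory_smoother(df)
        for _, row in out.iterrows():
            assert abs(row["fit"] - (-6.0 * row["years_since_onset"])) < 4.0
            assert row["ci95_lo"] <= row["fit"] <= row["ci95_hi"]

    def test_constant_zero_input_gives_flat_curve(self):
        x = np.tile(np.arange(7), 3)
        df = pd.DataFrame(
            {"sector_id": "S", "years_since_onset": x,
             "relative_change_pct": np.zeros(x.size)}
        )
        out = hi.fit_trajectory_smoother(df)
        assert np.allclose(out["fit"], 0.0, atol=1e-6)

    def test_insufficient_points_skipped_with_warning(self, caplog):
        df = pd.DataFrame(
            {"sector_id": "S", "years_since_onset": [0, 1, 2],
             "relative_change_pct": [0.0, 1.0, 2.0]}
        )
        with caplog.at_level("WARNING"):
            out = hi.fit_trajectory_smoother(df)
        assert out.empty


class TestEffortModel:
    def test_identical_categories_have_overlapping_nulls(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(
            {
                "annual_pp_per_year": rng.normal(0.0, 1.0, 60),
                "category": np.repeat(["a", "b", "c"], 20),
                "sector_id": np.tile(["s1", "s2"], 30),
            }
        )
        out = hi.fit_effort_model(df, seed=4)
        for summary in out["categories"].values():
            assert summary.ci90[0] < 0 < summary.ci90[1]
        assert out["diagnostics"]["rhat_max"] < 1.01

    def test_small_category_warned_not_dropped(self, caplog):
        df = pd.DataFrame(
            {
                "annual_pp_per_year": [1.0, -1.0, 0.5, 0.2, 0.1, -0.3, 3.0],
                "category": ["a"] * 6 + ["b"],
                "sector_id": ["s"] * 7,
            }
        )
        with caplog.at_level("WARNING"):
            out = hi.fit_effort_model(df, seed=4)
        assert "b" in out["categories"]
        assert any("1 reef" in r.message for r in caplog.records)


def test_diagnostics_always_reported():
    df = pd.DataFrame(
        {
            "annual_pp_per_year": [0.0, 1.0, 0.5, -0.5],
            "category": ["a", "b", "a", "b"],
            "sector_id": ["s1", "s2", "s2", "s1"],
        }
    )
    out = hi.fit_effort_model(df, seed=1)
    diag = out["diagnostics"]
    assert {"rhat", "rhat_max", "converged"} <= set(diag)
    assert diag["chains"] == 3 and diag["iterations"] == 4000
    assert diag["burn_in"] == 1000 and diag["thin"] == 5
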