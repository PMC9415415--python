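"""Scene matching, record assembly and the emergence filter."""

import datetime as dt
import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from croptime import (COMBINATIONS, CombinationSpec, TemporalStacker,
                      apply_emergence_filter, assemble_training_table,
                      build_record, calendar_2019, descriptor_columns,
                      match_scenes)
from croptime.calendars import AcquisitionCalendar
from croptime.spectral import DESCRIPTORS_PER_SCENE, SoilLine
from croptime.stacking import SceneSelection


def d2019(month, day):
    return dt.date(2019, month, day)


class TestCombinationSpec:
    @pytest.mark.parametrize("comb,n", [("C1", 33), ("C2", 22), ("C3", 33), ("C4", 22)])
    def test_descriptor_counts(self, comb, n):
        spec = COMBINATIONS[comb]
        assert spec.n_descriptors == n
        assert spec.n_descriptors == 11 * spec.n_scenes
        assert len(descriptor_columns(comb)) == n

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            CombinationSpec("X", (15, 30))     # lag 0 missing
        with pytest.raises(ValueError):
            CombinationSpec("X", (0, 30, 15))  # not increasing


class TestMatchScenes:
    def test_reference_calendar_matches(self):
        dates = calendar_2019().cloud_free
        analysis = d2019(7, 6)
        assert match_scenes(dates, analysis, "C1").matched_dates == (
            d2019(7, 6), d2019(6, 6), d2019(5, 7))
        assert match_scenes(dates, analysis, "C3").matched_dates == (
            d2019(7, 6), d2019(6, 21), d2019(6, 6))

    def test_missing_lag_returns_none(self):
        only = (d2019(7, 6),)
        assert match_scenes(only, d2019(7, 6), "C4") is None

    def test_analysis_date_must_be_cloud_free(self):
        with pytest.raises(ValueError, match="cloud-free"):
            match_scenes((d2019(7, 6),), d2019(7, 7), "C4")

    def test_tie_breaks_toward_earlier_scene(self):
        # targets 15 days back; two scenes equidistant by 2 days
        dates = (d2019(6, 19), d2019(6, 23), d2019(7, 6))
        sel = match_scenes(dates, d2019(7, 6), "C4")
        assert sel.matched_dates == (d2019(7, 6), d2019(6, 19))

    def test_order_independence(self):
        dates = list(calendar_2019().cloud_free)
        sel = match_scenes(dates, d2019(8, 5), "C1")
        sel_rev = match_scenes(dates[::-1], d2019(8, 5), "C1")
        assert sel == sel_rev

    @given(st.lists(st.integers(0, 180), min_size=1, max_size=40, unique=True),
           st.sampled_from(["C1", "C2", "C3", "C4"]))
    @settings(max_examples=60, derandomize=True)
    def test_agrees_with_exhaustive_oracle(self, offsets, comb):
        """Brute force over all in-tolerance date assignments, minimising
        total lag error with ties resolved toward earlier dates."""
        base = dt.date(2019, 4, 1)
        dates = sorted(base + dt.timedelta(days=o) for o in offsets)
        analysis = dates[-1]
        spec = COMBINATIONS[comb]
        sel = match_scenes(dates, analysis, spec)

        candidates = []
        for lag in spec.lags:
            target = analysis - dt.timedelta(days=lag)
            cands = [d for d in dates
                     if abs((d - target).days) <= spec.tolerance]
            candidates.append((target, cands))
        if any(not c for _, c in candidates):
            assert sel is None
            return
        best = min(
            itertools.product(*(c for _, c in candidates)),
            key=lambda combo: (sum(abs((d - t).days)
                                   for d, (t, _) in zip(combo, candidates)),
                               combo))
        assert sel is not None
        assert sel.matched_dates == best


class TestBuildRecord:
    def features_for(self, dates, value=0.2):
        return {d: np.full(len(DESCRIPTORS_PER_SCENE), value) for d in dates}

    def test_three_scene_record_has_33_descriptors(self):
        sel = SceneSelection(d2019(7, 6), (d2019(7, 6), d2019(6, 6), d2019(5, 7)))
        rec = build_record("P1", sel, self.features_for(sel.matched_dates), "corn")
        assert sum(k not in ("plot_id", "crop_label", "analysis_date")
                   for k in rec) == 33

    def test_two_scene_record_has_22_descriptors(self):
        sel = SceneSelection(d2019(7, 6), (d2019(7, 6), d2019(6, 21)))
        rec = build_record("P1", sel, self.features_for(sel.matched_dates), "bean")
        assert sum(k not in ("plot_id", "crop_label", "analysis_date")
                   for k in rec) == 22

    def test_scene_major_descriptor_order(self):
        sel = SceneSelection(d2019(7, 6), (d2019(7, 6), d2019(6, 6)))
        rec = build_record("P1", sel, self.features_for(sel.matched_dates), "corn")
        keys = [k for k in rec if k not in ("plot_id", "crop_label", "analysis_date")]
        assert keys == [f"{n}_0" for n in DESCRIPTORS_PER_SCENE] + \
                       [f"{n}_30" for n in DESCRIPTORS_PER_SCENE]

    def test_missing_scene_features_error(self):
        sel = SceneSelection(d2019(7, 6), (d2019(7, 6), d2019(6, 6)))
        with pytest.raises(KeyError, match="no features"):
            build_record("P1", sel, self.features_for([d2019(7, 6)]), "corn")


def toy_records():
    """Six records; two carry one sub-threshold WDVI scene."""
    rows = []
    for i, (w0, w30) in enumerate([(0.2, 0.1), (0.3, 0.004), (0.15, 0.2),
                                   (0.004, 0.25), (0.08, 0.05), (0.01, 0.01)]):
        rows.append({"plot_id": f"P{i}", "crop_label": "corn",
                     "analysis_date": d2019(7, 6),
                     "B2_0": 0.1, "WDVI_0": w0, "B2_30": 0.1, "WDVI_30": w30})
    return pd.DataFrame(rows)


class TestEmergenceFilter:
    def test_toy_table_survivors(self):
        out = apply_emergence_filter(toy_records(), threshold=0.005)
        assert len(out) == 4
        assert set(out["plot_id"]) == {"P0", "P2", "P4", "P5"}

    def test_lagged_scope_ignores_current_scene(self):
        df = toy_records()
        df.loc[0, "WDVI_0"] = 0.001   # current scene bare, lagged fine
        out = apply_emergence_filter(df, scope="lagged")
        assert "P0" in set(out["plot_id"])
        out_all = apply_emergence_filter(df, scope="all")
        assert "P0" not in set(out_all["plot_id"])

    @given(st.floats(0.0, 0.5), st.floats(0.0, 0.5))
    @settings(max_examples=40, derandomize=True)
    def test_threshold_monotonicity(self, t1, t2):
        lo, hi = sorted((t1, t2))
        df = toy_records()
        assert len(apply_emergence_filter(df, hi)) <= len(apply_emergence_filter(df, lo))


class TestAssembleTrainingTable:
    def test_c1_feasible_dates_follow_monthly_four_stage_pattern(self, survey_ds, soil_line):
        table = assemble_training_table(
            survey_ds.table, survey_ds.calendar, "C1", soil_line,
            analysis_dates=survey_ds.config.analysis_dates)
        expected = {d2019(6, 6), d2019(7, 6), d2019(8, 5), d2019(9, 4)}
        assert set(table["analysis_date"]) == expected
        # a permanently covered alfalfa plot contributes one row per stage
        alfalfa = table[table["crop_label"] == "alfalfa"]
        assert (alfalfa.groupby("plot_id").size() == 4).all()

    def test_two_plots_four_dates_all_emerged(self, soil_line):
        """Fully covered plots yield one record per feasible analysis date."""
        from croptime.synthetic import ScenarioConfig, generate_dataset
        cfg = ScenarioConfig(class_counts={"alfalfa": 2}, n_bare_plots=0,
                             calendar=calendar_2019(),
                             analysis_dates=(d2019(6, 6), d2019(7, 6),
                                             d2019(8, 5), d2019(9, 4)))
        ds = generate_dataset(cfg, seed=2)
        table = assemble_training_table(ds.table, ds.calendar, "C1", soil_line,
                                        analysis_dates=cfg.analysis_dates)
        assert len(table) == 8

    def test_empty_when_no_lag_partner(self, soil_line, survey_ds):
        lone = AcquisitionCalendar(dates=(d2019(7, 6),))
        sub = survey_ds.table[survey_ds.table["date"] == d2019(7, 6)]
        with pytest.warns(UserWarning, match="no feasible"):
            table = assemble_training_table(sub, lone, "C2", soil_line)
        assert table.empty

    def test_descriptor_columns_complete_and_finite(self, survey_ds, soil_line):
        table = assemble_training_table(
            survey_ds.table, survey_ds.calendar, "C3", soil_line,
            analysis_dates=survey_ds.config.analysis_dates)
        cols = descriptor_columns("C3")
        assert list(table.columns) == ["plot_id", "crop_label", "analysis_date"] + cols
        assert np.isfinite(table[cols].to_numpy()).all()


class TestTemporalStacker:
    def test_estimates_soil_line_from_bare_rows(self, survey_ds):
        stacker = TemporalStacker(calendar=survey_ds.calendar, combination="C4",
                                  analysis_dates=survey_ds.config.analysis_dates)
        out = stacker.fit_transform(survey_ds.table)
        assert stacker.soil_line_.slope_a == pytest.approx(1.62, abs=0.01)
        assert stacker.feature_names_out_ == descriptor_columns("C4")
        assert not out.empty

    def test_fixed_soil_line_and_params_roundtrip(self, survey_ds):
        stacker = TemporalStacker(calendar=survey_ds.calendar, combination="C2",
                                  soil_line=SoilLine(1.62))
        params = stacker.get_params()
        assert params["combination"] == "C2"
        stacker.set_params(combination="C4").fit(survey_ds.table)
        assert stacker.spec_.id == "C4"
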