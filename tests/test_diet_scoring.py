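import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dietomics import diet_scoring as ds
from dietomics.errors import (
    ConfigurationError,
    DegenerateDataError,
    InputError,
    StratumError,
)


# ---------------------------------------------------------------------------
# FFQ validity filter
# ---------------------------------------------------------------------------

class TestValidateFFQ:
    @pytest.mark.parametrize("sex,blanks,kcal,expect", [
        ("female", 12, 3999, True),   # just under every bound
        ("female", 12, 4000, False),  # female caloric ceiling
        ("male", 0, 4200, False),     # male caloric ceiling
        ("male", 0, 4199, True),
        ("female", 13, 2000, False),  # blank-item rule
        ("male", 13, 2000, False),
        ("female", 0, 600, True),     # caloric floor is inclusive
        ("female", 0, 599, False),
    ])
    def test_boundaries(self, sex, blanks, kcal, expect):
        ok, reason = ds.validate_ffq(kcal, blanks, sex)
        assert ok is expect
        assert (reason == "") is expect

    def test_reason_names_first_failed_rule(self):
        ok, reason = ds.validate_ffq(200, 20, "male")
        assert not ok and "blank" in reason

    def test_unknown_sex_raises(self):
        with pytest.raises(InputError):
            ds.validate_ffq(2000, 0, "other")

    def test_missing_energy_invalid(self):
        ok, reason = ds.validate_ffq(np.nan, 0, "female")
        assert not ok and "missing" in reason

    def test_table_wrapper(self, intake_table, sex_series):
        out = ds.validate_ffq_table(intake_table, sex_series)
        assert out["valid"].all()
        bad = intake_table.copy()
        bad.iloc[0, bad.columns.get_loc("energy_kcal")] = 100.0
        out = ds.validate_ffq_table(bad, sex_series)
        assert not out["valid"].iloc[0] and out["valid"].iloc[1:].all()


# ---------------------------------------------------------------------------
# Anchored component scoring
# ---------------------------------------------------------------------------

def _anchored(direction="direct", anchors=(0.0, 4.0)):
    return ds.ComponentSpec("c", "f", "anchored_linear", direction=direction,
                            points_min=0, points_max=10, anchors=anchors)


class TestAnchoredComponent:
    def test_best_anchor_scores_max(self):
        assert ds.score_anchored_component(4.0, _anchored()) == 10

    def test_worst_anchor_scores_min(self):
        assert ds.score_anchored_component(0.0, _anchored()) == 0

    def test_midpoint_is_linear(self):
        assert ds.score_anchored_component(2.0, _anchored()) == 5

    def test_clamped_beyond_anchors(self):
        assert ds.score_anchored_component(9.0, _anchored()) == 10
        assert ds.score_anchored_component(-1.0, _anchored()) == 0

    def test_reverse_through_anchor_order(self):
        spec = _anchored(direction="reverse", anchors=(4.0, 0.0))
        assert ds.score_anchored_component(0.0, spec) == 10
        assert ds.score_anchored_component(4.0, spec) == 0

    def test_missing_anchors_rejected(self):
        with pytest.raises(ConfigurationError):
            ds.ComponentSpec("c", "f", "anchored_linear")

    def test_equal_anchors_rejected(self):
        with pytest.raises(ConfigurationError):
            _anchored(anchors=(2.0, 2.0))

    @given(st.floats(0, 10), st.floats(0, 10))
    def test_direct_monotone(self, a, b):
        lo, hi = min(a, b), max(a, b)
        spec = _anchored()
        assert ds.score_anchored_component(lo, spec) <= \
            ds.score_anchored_component(hi, spec)

    def test_per_sex_anchors(self):
        spec = ds.ComponentSpec(
            "wg", "whole_grains", "anchored_linear", sex_specific=True,
            anchors={"male": (0.0, 2.0), "female": (0.0, 1.0)})
        assert ds.score_anchored_component(1.0, spec, "female") == 10
        assert ds.score_anchored_component(1.0, spec, "male") == 5


# ---------------------------------------------------------------------------
# Quantile rank scoring
# ---------------------------------------------------------------------------

def brute_force_quintiles(values, points):
    """Independent oracle: sort, split into equal fifths, map sorted position
    back to a score (valid for distinct values and n divisible by 5)."""
    order = np.argsort(np.asarray(values))
    n = len(values)
    out = np.empty(n)
    per_bin = n // 5
    for rank_pos, idx in enumerate(order):
        out[idx] = points[min(rank_pos // per_bin, 4)]
    return out


class TestQuantileRank:
    def test_distinct_1_to_100_exact_fifths(self):
        vals = np.arange(1, 101, dtype=float)
        got = ds.quantile_rank_scores(vals, 5, "direct", [1, 2, 3, 4, 5])
        expected = brute_force_quintiles(vals, [1, 2, 3, 4, 5])
        np.testing.assert_array_equal(got, expected)
        for score in (1, 2, 3, 4, 5):
            assert (got == score).sum() == 20

    def test_top_quintile_gets_max(self):
        vals = np.arange(1, 101, dtype=float)
        got = ds.quantile_rank_scores(vals, 5, "direct", [1, 2, 3, 4, 5])
        assert got[vals > np.quantile(vals, 0.8)].min() == 5

    def test_reverse_maps_q1_to_max(self):
        vals = np.arange(1, 101, dtype=float)
        got = ds.quantile_rank_scores(vals, 5, "reverse", [1, 2, 3, 4, 5])
        assert got[0] == 5 and got[-1] == 1

    def test_tie_with_cutpoint_falls_low(self):
        # cut-points of 1..10 quartiles: 3.25, 5.5, 7.75 -> place a value at 5.5
        vals = np.array([1, 2, 3, 4, 5, 5.5, 6, 7, 8, 9, 10.0])
        cuts = np.quantile(vals, [0.25, 0.5, 0.75])
        got = ds.quantile_rank_scores(vals, 4, "direct", [0, 1, 2, 3])
        at_cut = np.isclose(vals, cuts[1])
        if at_cut.any():
            assert (got[at_cut] <= 1).all()

    def test_sex_stratified(self):
        vals = np.concatenate([np.arange(1, 41), np.arange(101, 141)]).astype(float)
        sex = np.array(["female"] * 40 + ["male"] * 40)
        got = ds.quantile_rank_scores(vals, 4, "direct", [0, 1, 2, 3], by_sex=sex)
        # each stratum spans the full score range despite disjoint supports
        for s in ("female", "male"):
            assert set(got[sex == s]) == {0, 1, 2, 3}

    def test_stratum_too_small(self):
        with pytest.raises(StratumError):
            ds.quantile_rank_scores([1.0, 2.0, 3.0], 5, "direct", [1, 2, 3, 4, 5])

    def test_zero_inflation_merges_down_with_warning(self):
        vals = np.array([0.0] * 90 + list(range(1, 11)))
        with pytest.warns(UserWarning, match="duplicate quantile"):
            got = ds.quantile_rank_scores(vals, 5, "direct", [1, 2, 3, 4, 5])
        assert (got[vals == 0] == 1).all()          # lowest applicable bin
        assert got[vals > 0].max() == 5

    def test_nan_rejected(self):
        with pytest.raises(InputError):
            ds.quantile_rank_scores([1.0, np.nan] * 5, 5, "direct",
                                    [1, 2, 3, 4, 5])

    @given(st.integers(0, 2 ** 32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_permutation_equivariance(self, seed):
        r = np.random.default_rng(seed)
        vals = r.random(50)
        perm = r.permutation(50)
        base = ds.quantile_rank_scores(vals, 5, "direct", [1, 2, 3, 4, 5])
        permuted = ds.quantile_rank_scores(vals[perm], 5, "direct",
                                           [1, 2, 3, 4, 5])
        np.testing.assert_array_equal(base[perm], permuted)


# ---------------------------------------------------------------------------
# Alcohol window scoring
# ---------------------------------------------------------------------------

class TestAlcoholWindow:
    spec = ds.ComponentSpec("alcohol", "alcohol_g_day", "alcohol_window",
                            points_min=0, points_max=1,
                            window={"male": (10.0, 25.0), "female": (5.0, 15.0)})

    def test_inside_window(self):
        assert ds.score_alcohol_window(10.0, self.spec, "female") == 1

    def test_zero_is_underconsumption(self):
        assert ds.score_alcohol_window(0.0, self.spec, "female") == 0

    def test_just_above_high_bound(self):
        assert ds.score_alcohol_window(15.0, self.spec, "female") == 1
        assert ds.score_alcohol_window(15.0001, self.spec, "female") == 0

    def test_sex_specific_bounds(self):
        assert ds.score_alcohol_window(20.0, self.spec, "male") == 1
        assert ds.score_alcohol_window(20.0, self.spec, "female") == 0

    def test_negative_alcohol_rejected(self):
        with pytest.raises(InputError):
            ds.score_alcohol_window(-1.0, self.spec, "male")

    def test_nondrinker_partial_credit(self):
        spec = ds.ComponentSpec("alcohol", "a", "alcohol_window",
                                points_min=0, points_max=10,
                                nondrinker_points=2.5, window=(7.0, 21.0))
        assert ds.score_alcohol_window(0.0, spec, "female") == 2.5

    def test_window_required(self):
        with pytest.raises(ConfigurationError):
            ds.ComponentSpec("alcohol", "a", "alcohol_window")


# ---------------------------------------------------------------------------
# Whole-index scoring
# ---------------------------------------------------------------------------

class TestDefaultConfigs:
    def test_ahei_composition(self):
        cfg = ds.default_ahei_config()
        assert len(cfg.components) == 11
        assert all(c.points_max == 10 for c in cfg.components)
        assert cfg.expected_max == 110

    def test_dash_composition(self):
        cfg = ds.default_dash_config()
        assert len(cfg.components) == 8
        assert all((c.points_min, c.points_max) == (1, 5) for c in cfg.components)
        assert cfg.expected_max == 40
        reverse = {c.name for c in cfg.components if c.direction == "reverse"}
        assert reverse == {"sodium", "red_processed_meat", "ssb"}

    def test_mds_composition(self):
        cfg = ds.default_mds_config()
        quartile = [c for c in cfg.components if c.method == "quartile_rank"]
        alcohol = [c for c in cfg.components if c.method == "alcohol_window"]
        assert len(quartile) == 8 and len(alcohol) == 1
        assert all(c.sex_specific for c in quartile)
        assert cfg.expected_max == 25

    def test_wrong_expected_max_fails_fast(self):
        cfg = ds.default_dash_config()
        with pytest.raises(ConfigurationError, match="sum"):
            ds.DietIndexConfig("DASH", cfg.components, expected_max=41)


class TestConfigSerialization:
    @pytest.mark.parametrize("name", ["AHEI", "DASH", "MDS"])
    def test_yaml_roundtrip(self, name, tmp_path):
        cfg = ds.default_config(name)
        path = tmp_path / f"{name.lower()}.yaml"
        ds.save_index_config(cfg, path)
        back = ds.load_index_config(path)
        assert ds.config_to_dict(back) == ds.config_to_dict(cfg)
        assert back.expected_max == cfg.expected_max

    def test_bad_dict_rejected(self):
        with pytest.raises(ConfigurationError):
            ds.config_from_dict({"index_name": "AHEI"})


class TestScoreIndex:
    def test_ahei_best_profile_scores_110(self):
        cfg = ds.default_ahei_config()
        row = ds.extreme_profile(cfg, "best", sex="female")
        intakes = pd.DataFrame([row], index=pd.Index(["p1"]))
        sex = pd.Series(["female"], index=["p1"])
        out = ds.score_index(intakes, cfg, sex)
        assert out.loc["p1", "total"] == 110

    def test_ahei_worst_profile_scores_0(self):
        cfg = ds.default_ahei_config()
        row = ds.extreme_profile(cfg, "worst", sex="male")
        intakes = pd.DataFrame([row], index=pd.Index(["p1"]))
        sex = pd.Series(["male"], index=["p1"])
        out = ds.score_index(intakes, cfg, sex)
        assert out.loc["p1", "total"] == 0

    def _with_extreme(self, intake_table, sex_series, cfg, which, sex):
        row = ds.extreme_profile(cfg, which, sex=sex, reference=intake_table)
        intakes = pd.concat([
            intake_table,
            pd.DataFrame([row], index=pd.Index(["extreme"]))])
        sexes = pd.concat([sex_series, pd.Series([sex], index=["extreme"])])
        return ds.score_index(intakes, cfg, sexes)

    def test_dash_best_participant_scores_40(self, intake_table, sex_series):
        out = self._with_extreme(intake_table, sex_series,
                                 ds.default_dash_config(), "best", "female")
        assert out.loc["extreme", "total"] == 40

    def test_dash_worst_participant_scores_8(self, intake_table, sex_series):
        out = self._with_extreme(intake_table, sex_series,
                                 ds.default_dash_config(), "worst", "female")
        assert out.loc["extreme", "total"] == 8

    def test_mds_best_participant_scores_25(self, intake_table, sex_series):
        out = self._with_extreme(intake_table, sex_series,
                                 ds.default_mds_config(), "best", "male")
        assert out.loc["extreme", "total"] == 25

    def test_mds_worst_participant_scores_0(self, intake_table, sex_series):
        out = self._with_extreme(intake_table, sex_series,
                                 ds.default_mds_config(), "worst", "male")
        assert out.loc["extreme", "total"] == 0

    def test_totals_are_component_sums(self, intake_table, sex_series):
        out = ds.score_index(intake_table, ds.default_dash_config(), sex_series)
        comp = out.drop(columns="total").sum(axis=1)
        np.testing.assert_allclose(out["total"], comp)

    def test_bounds_on_random_cohorts(self, small_cohort):
        for name, (lo, hi) in (("AHEI", (0, 110)), ("DASH", (8, 40)),
                               ("MDS", (0, 25))):
            cfg = ds.default_config(name)
            out = ds.score_index(small_cohort.intakes,
                                 cfg, small_cohort.covariates["sex"])
            assert out["total"].between(lo, hi).all()

    def test_missing_field_rejected(self, intake_table, sex_series):
        cfg = ds.default_dash_config()
        with pytest.raises(InputError, match="sodium"):
            ds.score_index(intake_table.drop(columns="sodium_mg"), cfg,
                           sex_series)

    def test_sex_required_for_mds(self, intake_table):
        with pytest.raises(InputError):
            ds.score_index(intake_table, ds.default_mds_config(), sex=None)


class TestStandardizeIndex:
    def test_closed_form_1_2_3(self):
        np.testing.assert_allclose(ds.standardize_index([1, 2, 3]), [-1, 0, 1])

    def test_mean_zero_sd_one(self, rng):
        z = ds.standardize_index(rng.random(100) * 40)
        assert abs(z.mean()) < 1e-10
        assert abs(z.std(ddof=1) - 1) < 1e-10

    def test_location_invariance(self, rng):
        x = rng.random(50)
        np.testing.assert_allclose(ds.standardize_index(x),
                                   ds.standardize_index(x + 17.3), atol=1e-9)

    def test_rank_order_preserved(self, rng):
        x = rng.random(50)
        z = ds.standardize_index(x)
        np.testing.assert_array_equal(np.argsort(x), np.argsort(z))

    def test_constant_rejected(self):
        with pytest.raises(DegenerateDataError):
            ds.standardize_index([3.0, 3.0, 3.0])
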