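"""Frailty index: binarization rules, screening ledger, scoring, variants."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from frailtybrain import (ConfigurationError, DegenerateDataError,
                          HealthItemSpec, SchemaError, binarize_items,
                          compute_frailty_index, default_item_specs,
                          screen_items, variant_index)


def spec(name, rule, domain="physical", tag=None):
    return HealthItemSpec(name, domain, "continuous", rule, tag)


class TestBinarize:
    def test_identity_rule_passes_binary_values(self):
        raw = pd.DataFrame({"a": [0, 1, 1, 0]})
        out = binarize_items(raw, [spec("a", {"kind": "identity"})])
        assert out["a"].tolist() == [0, 1, 1, 0]

    def test_threshold_is_closed_on_deficit_side(self):
        raw = pd.DataFrame({"sbp": [139.9, 140.0, 140.1]})
        out = binarize_items(raw, [spec("sbp", {"kind": "ge", "cut": 140.0})])
        assert out["sbp"].tolist() == [0, 1, 1]  # value == cut -> deficit

    def test_lt_rule_open_lower_tail(self):
        raw = pd.DataFrame({"mmse": [23.0, 24.0, 30.0]})
        out = binarize_items(raw, [spec("mmse", {"kind": "lt", "cut": 24.0})])
        assert out["mmse"].tolist() == [1, 0, 0]

    def test_outside_rule_band_edges(self):
        raw = pd.DataFrame({"bmi": [18.4, 18.5, 25.0, 29.9, 30.0]})
        out = binarize_items(
            raw, [spec("bmi", {"kind": "outside", "low": 18.5, "high": 30.0})])
        assert out["bmi"].tolist() == [1, 0, 0, 0, 1]

    def test_missing_raw_value_stays_missing(self):
        raw = pd.DataFrame({"a": [1.0, np.nan]})
        out = binarize_items(raw, [spec("a", {"kind": "identity"})])
        assert out["a"].isna().tolist() == [False, True]

    def test_unmapped_value_becomes_missing(self):
        raw = pd.DataFrame({"a": [0, 1, 2]})
        out = binarize_items(raw, [spec("a", {"kind": "identity"})])
        assert out["a"].isna().tolist() == [False, False, True]

    def test_column_without_spec_raises_schema_error(self):
        with pytest.raises(SchemaError):
            binarize_items(pd.DataFrame({"mystery": [1]}), [])

    def test_default_spec_set_has_32_unique_items(self):
        specs = default_item_specs()
        assert len(specs) == 32
        assert len({s.name for s in specs}) == 32
        tags = {s.sensitivity_tag for s in specs if s.sensitivity_tag}
        assert tags == {"CDR", "MMSE", "GAD7", "GDS_SF"}
        assert sum(s.sensitivity_tag == "CDR" for s in specs) == 8


class TestScreening:
    @pytest.fixture()
    def fixture_table(self, rng):
        n = 1000
        base = {f"ok{k}": (rng.random(n) < 0.3).astype(float)
                for k in range(5)}
        tab = pd.DataFrame(base)
        tab["rare"] = 0.0
        tab.loc[:4, "rare"] = 1.0            # 0.5% prevalence
        tab["common"] = 1.0
        tab.loc[:149, "common"] = 0.0        # 85% prevalence
        tab["holey"] = (rng.random(n) < 0.3).astype(float)
        tab.loc[:199, "holey"] = np.nan      # 20% missing
        tab["dup"] = tab["ok0"]              # r = 1 with ok0
        return tab

    def test_each_rule_fires_with_correct_ledger_code(self, fixture_table):
        ledger = screen_items(fixture_table)
        t = ledger.table
        assert t.loc["rare", "decision"] == "dropped_rare"
        assert t.loc["common", "decision"] == "dropped_common"
        assert t.loc["holey", "decision"] == "dropped_missing"
        dropped_corr = {i for i in ("ok0", "dup")
                        if t.loc[i, "decision"] == "dropped_correlated"}
        assert len(dropped_corr) == 1  # exactly one of the pair
        assert set(t.index) == set(fixture_table.columns)

    def test_vif_drop(self, rng):
        n = 2000
        a = (rng.random(n) < 0.5).astype(float)
        b = (rng.random(n) < 0.5).astype(float)
        c = (rng.random(n) < 0.5).astype(float)
        # s is a near-deterministic function of a, b, c -> huge VIF but
        # pairwise correlations all moderate
        s = ((a + b + c) >= 2).astype(float)
        flip = rng.random(n) < 0.02
        s[flip] = 1 - s[flip]
        tab = pd.DataFrame({"a": a, "b": b, "c": c, "s": s})
        ledger = screen_items(tab, max_corr=0.95, max_vif=3.0)
        assert (ledger.table["decision"] == "dropped_vif").any()

    def test_screening_is_idempotent(self, fixture_table):
        first = screen_items(fixture_table)
        second = screen_items(fixture_table[first.retained])
        assert second.retained == first.retained
        assert (second.table["decision"] == "kept").all()

    def test_all_items_dropped_raises(self):
        tab = pd.DataFrame({"a": [1.0] * 100, "b": [1.0] * 100})
        with pytest.raises(DegenerateDataError):
            screen_items(tab)

    def test_correlated_tiebreak_drops_item_with_more_missing(self, rng):
        x = (rng.random(400) < 0.4).astype(float)
        tab = pd.DataFrame({
            "full": x, "gappy": x,
            "other": (rng.random(400) < 0.4).astype(float)})
        tab.loc[:19, "gappy"] = np.nan  # 5% missing, below the 15% gate
        ledger = screen_items(tab)
        assert ledger.table.loc["gappy", "decision"] == "dropped_correlated"
        assert ledger.table.loc["full", "decision"] == "kept"


class TestIndexArithmetic:
    def test_zero_deficits_gives_zero_index(self):
        tab = pd.DataFrame([np.zeros(32)])
        out = compute_frailty_index(tab)
        assert out.loc[0, "index"] == 0.0
        assert bool(out.loc[0, "included"])

    def test_observed_denominator_scoring(self):
        row = np.zeros(32)
        row[:8] = 1.0
        row[30:] = np.nan  # 30 of 32 observed (93.75%), 8 deficits
        out = compute_frailty_index(pd.DataFrame([row]))
        assert out.loc[0, "n_observed"] == 30
        assert out.loc[0, "index"] == pytest.approx(8 / 30)
        assert bool(out.loc[0, "included"])

    def test_below_completeness_gate_excluded(self):
        row = np.ones(32)
        row[24:] = np.nan  # 24 of 32 observed = 75% < 80%
        out = compute_frailty_index(pd.DataFrame([row]))
        assert not bool(out.loc[0, "included"])
        assert np.isnan(out.loc[0, "index"])

    def test_exactly_at_gate_included(self):
        row = np.zeros(30)
        row[24:] = np.nan  # 24/30 = 80% exactly
        out = compute_frailty_index(pd.DataFrame([row]))
        assert bool(out.loc[0, "included"])


class TestVariants:
    @pytest.fixture()
    def specs(self):
        return default_item_specs()

    @pytest.fixture()
    def deficits(self, specs, rng):
        tab = pd.DataFrame(
            (rng.random((50, 32)) < 0.25).astype(float),
            columns=[s.name for s in specs])
        return tab

    def test_empty_exclusion_matches_full_index(self, deficits, specs):
        full = compute_frailty_index(deficits)
        var = variant_index(deficits, specs, ())
        pd.testing.assert_series_equal(full["index"], var["index"])

    def test_cdr_exclusion_shrinks_denominator(self, deficits, specs):
        var = variant_index(deficits, specs, ("CDR",))
        assert var["n_items"].iloc[0] == 24  # 32 - 8 CDR items

    def test_deficits_only_in_excluded_items_give_zero(self, specs):
        row = pd.Series(0.0, index=[s.name for s in specs])
        for s in specs:
            if s.sensitivity_tag == "CDR":
                row[s.name] = 1.0
        var = variant_index(pd.DataFrame([row]), specs, ("CDR",))
        assert var["index"].iloc[0] == 0.0

    def test_unknown_tag_raises(self, deficits, specs):
        with pytest.raises(ConfigurationError):
            variant_index(deficits, specs, ("NOPE",))


class TestProperties:
    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 32 - 1))
    def test_index_in_unit_interval_and_monotone(self, seed):
        rng = np.random.default_rng(seed)
        tab = pd.DataFrame((rng.random((10, 12)) < 0.3).astype(float))
        tab = tab.mask(rng.random(tab.shape) < 0.1)
        out = compute_frailty_index(tab, min_completeness=0.5)
        ok = out["index"].dropna()
        assert ok.between(0, 1).all()
        # flipping one observed 0 to 1 never decreases the index
        flipped = tab.copy()
        for i in flipped.index:
            zeros = flipped.columns[flipped.loc[i].eq(0.0)]
            if len(zeros):
                flipped.loc[i, zeros[0]] = 1.0
        out2 = compute_frailty_index(flipped, min_completeness=0.5)
        both = out["index"].notna() & out2["index"].notna()
        assert (out2.loc[both, "index"] >= out.loc[both, "index"] - 1e-12).all()

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 32 - 1))
    def test_item_order_never_changes_results(self, seed):
        rng = np.random.default_rng(seed)
        tab = pd.DataFrame((rng.random((20, 8)) < 0.4).astype(float),
                           columns=list("abcdefgh"))
        perm = list(rng.permutation(list("abcdefgh")))
        a = compute_frailty_index(tab)
        b = compute_frailty_index(tab[perm])
        pd.testing.assert_series_equal(a["index"], b["index"])
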