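"""Sign classification, summaries, proportion regressions, rank reshuffling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import pivotdfe as pdfe
from pivotdfe.signcalls import BENEFICIAL, DELETERIOUS, NEUTRAL


class TestClassifySign:
    def test_beneficial_example(self):
        # z(0.995) = 2.5758...; CI = 0.05 +/- 0.025758
        call, lo, hi = pdfe.classify_sign(0.05, 0.01, level=0.99)
        assert call == BENEFICIAL
        assert lo == pytest.approx(0.0242, abs=5e-4)
        assert hi == pytest.approx(0.0758, abs=5e-4)

    def test_ci_overlapping_zero_is_neutral(self):
        call, lo, hi = pdfe.classify_sign(0.02, 0.01, level=0.99)
        assert lo < 0 < hi
        assert call == NEUTRAL

    def test_zero_effect_is_neutral(self):
        assert pdfe.classify_sign(0.0, 0.5)[0] == NEUTRAL
        assert pdfe.classify_sign(0.0, 0.0)[0] == NEUTRAL

    def test_negative_se_raises(self):
        with pytest.raises(ValueError):
            pdfe.classify_sign(0.1, -0.01)

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(effect=st.floats(-1, 1, allow_nan=False),
           se=st.floats(0, 0.5, allow_nan=False),
           bump=st.floats(0, 1, allow_nan=False))
    def test_monotone_in_effect_magnitude(self, effect, se, bump):
        """Pushing the effect further from zero never de-calls it."""
        call0 = pdfe.classify_sign(effect, se)[0]
        moved = effect + bump if effect >= 0 else effect - bump
        call1 = pdfe.classify_sign(moved, se)[0]
        if call0 == BENEFICIAL:
            assert call1 == BENEFICIAL
        if call0 == DELETERIOUS:
            assert call1 == DELETERIOUS


def _calls(rows):
    return pd.DataFrame(rows, columns=["mutation", "strain", "environment",
                                       "value", "se", "ci_lo", "ci_hi", "call"])


class TestSignSummary:
    def test_one_of_each_gives_thirds(self):
        calls = _calls([
            ("m1", "s1", "e1", 0.1, 0.01, 0.07, 0.13, BENEFICIAL),
            ("m2", "s1", "e1", -0.1, 0.01, -0.13, -0.07, DELETERIOUS),
            ("m3", "s1", "e1", 0.0, 0.01, -0.03, 0.03, NEUTRAL)])
        context, _ = pdfe.sign_summary(calls)
        assert context["frac_beneficial"].iloc[0] == pytest.approx(1 / 3)
        assert context["frac_deleterious"].iloc[0] == pytest.approx(1 / 3)

    def test_sign_switching_across_environments(self):
        calls = _calls([
            ("m1", "s1", "envA", 0.1, 0.01, 0.07, 0.13, BENEFICIAL),
            ("m1", "s1", "envB", -0.1, 0.01, -0.13, -0.07, DELETERIOUS),
            ("m2", "s1", "envA", 0.1, 0.01, 0.07, 0.13, BENEFICIAL),
            ("m2", "s1", "envB", 0.1, 0.01, 0.07, 0.13, BENEFICIAL)])
        _, mutation = pdfe.sign_summary(calls)
        by = mutation.set_index("mutation")["sign_switching"]
        assert bool(by["m1"]) and not bool(by["m2"])

    def test_all_neutral_gives_zero_proportions(self):
        calls = _calls([(f"m{i}", "s1", "e1", 0.0, 1.0, -2.0, 2.0, NEUTRAL)
                        for i in range(5)])
        context, _ = pdfe.sign_summary(calls)
        assert (context[["frac_beneficial", "frac_deleterious"]] == 0).all().all()


class TestRegressProportions:
    def _growth(self, lams):
        return pdfe.GrowthRateTable(pd.DataFrame({
            "strain": [f"s{i}" for i in range(len(lams))],
            "environment": "e1", "value": lams, "se": 0.0}))

    def test_exactly_linear_proportions(self):
        lams = [0.1, 0.2, 0.3, 0.4]
        context = pd.DataFrame({
            "strain": [f"s{i}" for i in range(4)], "environment": "e1",
            "n": 10, "frac_beneficial": [0.8, 0.6, 0.4, 0.2],
            "frac_deleterious": [0.1, 0.2, 0.3, 0.4]})
        out = pdfe.regress_sign_proportions(context, self._growth(lams))
        ben = out[out["call"] == "beneficial"].iloc[0]
        assert ben["slope"] == pytest.approx(-2.0)
        assert ben["r2"] == pytest.approx(1.0)

    def test_constant_proportions_give_zero_slope(self):
        context = pd.DataFrame({
            "strain": [f"s{i}" for i in range(4)], "environment": "e1",
            "n": 10, "frac_beneficial": 0.25, "frac_deleterious": 0.5})
        out = pdfe.regress_sign_proportions(context,
                                            self._growth([0.1, 0.2, 0.3, 0.4]))
        assert (out["slope"] == 0).all()
        assert np.allclose(out["p"], 1.0)

    def test_too_few_strains_raises(self):
        context = pd.DataFrame({
            "strain": ["s0", "s1"], "environment": "e1", "n": 10,
            "frac_beneficial": [0.1, 0.2], "frac_deleterious": [0.1, 0.2]})
        with pytest.raises(ValueError, match=">=3 strains"):
            pdfe.regress_sign_proportions(context, self._growth([0.1, 0.2]))

    def test_beneficial_fraction_declines_with_growth(self, default_dataset):
        """Negative-mean slopes imply fewer beneficial calls in fast strains."""
        growth, effects, _ = default_dataset
        calls = pdfe.classify_table(effects)
        context, _ = pdfe.sign_summary(calls)
        out = pdfe.regress_sign_proportions(context, growth)
        ben = out[out["call"] == "beneficial"]
        assert (ben["slope"] < 0).all()


class TestRankReshuffle:
    def test_reversed_order_reshuffles_everything(self):
        df = pd.DataFrame({"strain": ["a", "b"] * 2,
                           "environment": ["e1", "e1", "e2", "e2"],
                           "value": [1.0, 2.0, 2.0, 1.0]})
        frac, _ = pdfe.rank_reshuffle(df, "strain")
        assert frac == 1.0

    def test_identical_order_reshuffles_nothing(self):
        df = pd.DataFrame({"strain": ["a", "b", "c"] * 2,
                           "environment": ["e1"] * 3 + ["e2"] * 3,
                           "value": [3.0, 2.0, 1.0, 30.0, 20.0, 10.0]})
        frac, _ = pdfe.rank_reshuffle(df, "strain")
        assert frac == 0.0

    def test_four_items_hand_enumerated(self):
        # e1 order: A>B>C>D (top: A,B); e2 order: A>C>D>B (top: A,C)
        # A top twice -> no; B top e1, bottom e2 -> yes;
        # C bottom e1, top e2 -> yes; D bottom twice -> no => 0.5
        df = pd.DataFrame({
            "strain": list("ABCD") * 2,
            "environment": ["e1"] * 4 + ["e2"] * 4,
            "value": [4, 3, 2, 1, 4, 1, 3, 2]})
        frac, detail = pdfe.rank_reshuffle(df, "strain")
        assert frac == pytest.approx(0.5)
        assert set(detail.loc[detail["reshuffled"], "strain"]) == {"B", "C"}

    def test_odd_count_middle_item_in_top_half(self):
        # n=3 -> top half is 2 items; e1 top {A,B}; e2 top {C,B}
        df = pd.DataFrame({
            "strain": list("ABC") * 2,
            "environment": ["e1"] * 3 + ["e2"] * 3,
            "value": [3, 2, 1, 1, 2, 3]})
        frac, _ = pdfe.rank_reshuffle(df, "strain")
        assert frac == pytest.approx(2 / 3)

    def test_single_environment_raises(self):
        df = pd.DataFrame({"strain": ["a", "b"], "environment": "e1",
                           "value": [1.0, 2.0]})
        with pytest.raises(ValueError):
            pdfe.rank_reshuffle(df, "strain")


class TestSignFdr:
    def _truth(self, effects_df):
        return pdfe.GroundTruth(
            slopes=pd.Series(dtype=float), pivots=pd.Series(dtype=float),
            eta=pd.DataFrame(), effects=effects_df, growth=pd.DataFrame(),
            reference_mutations=[], reference_effects=pd.DataFrame(),
            config=pdfe.GeneratorConfig())

    def test_hand_built_fdr(self):
        """5 non-neutral calls, 2 with the wrong sign -> FDR 0.4."""
        rows, true_rows = [], []
        specs = [(BENEFICIAL, 1.0), (BENEFICIAL, 1.0), (BENEFICIAL, -1.0),
                 (DELETERIOUS, 1.0), (DELETERIOUS, -1.0)] + [(NEUTRAL, 0.0)] * 5
        for i, (call, true) in enumerate(specs):
            rows.append((f"m{i}", "s1", "e1", true, 0.1, true - 0.2,
                         true + 0.2, call))
            true_rows.append({"mutation": f"m{i}", "strain": "s1",
                              "environment": "e1", "true_effect": true})
        res = pdfe.estimate_sign_fdr(_calls(rows), self._truth(pd.DataFrame(true_rows)))
        assert res["fdr"] == pytest.approx(0.4)
        assert res["n_discoveries"] == 5

    def test_noise_free_data_has_zero_fdr(self, noise_free_dataset):
        _, effects, truth = noise_free_dataset
        calls = pdfe.classify_table(effects)
        res = pdfe.estimate_sign_fdr(calls, truth)
        assert res["fdr"] == 0.0
        assert res["n_discoveries"] > 0
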