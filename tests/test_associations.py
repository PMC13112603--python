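"""Stratified estimators: FE logistic vs closed forms, MH oracle, descriptives."""

import math

import numpy as np
import pandas as pd
import pytest

import schoolwells as sw
from schoolwells.associations import (AssociationSpec, SeparationError, TwoByTwo,
                                      fe_logistic, mh_odds_ratio, tabulate)


def _expand(tables):
    """Turn {stratum: TwoByTwo} into aligned outcome/exposure/stratum vectors."""
    y, e, s = [], [], []
    for label, t in tables.items():
        y += [1] * t.a + [0] * t.b + [1] * t.c + [0] * t.d
        e += [1] * (t.a + t.b) + [0] * (t.c + t.d)
        s += [label] * t.n
    return np.array(y, bool), np.array(e, bool), np.array(s, object)


class TestTabulate:
    def test_one_record_per_cell(self):
        y = [1, 0, 1, 0]
        e = [1, 1, 0, 0]
        tables = tabulate(y, e, ["st"] * 4)
        assert tables["st"] == TwoByTwo(1, 1, 1, 1)

    def test_two_strata(self):
        y, e, s = _expand({"A": TwoByTwo(1, 1, 1, 1), "B": TwoByTwo(1, 1, 1, 1)})
        tables = tabulate(y, e, s)
        assert tables == {"A": TwoByTwo(1, 1, 1, 1), "B": TwoByTwo(1, 1, 1, 1)}

    def test_matches_naive_loop_on_random_vectors(self):
        rng = np.random.default_rng(5)
        y = rng.random(500) < 0.4
        e = rng.random(500) < 0.3
        s = rng.choice(list("ABCD"), 500)
        tables = tabulate(y, e, s)
        for label in "ABCD":
            a = b = c = d = 0
            for yi, ei, si in zip(y, e, s):
                if si != label:
                    continue
                if ei and yi: a += 1
                elif ei: b += 1
                elif yi: c += 1
                else: d += 1
            assert tables[label] == TwoByTwo(a, b, c, d)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            tabulate([1], [1, 0], ["a", "a"])


class TestMantelHaenszel:
    def test_single_stratum_is_cross_product_ratio(self):
        res = mh_odds_ratio({"s": TwoByTwo(20, 10, 10, 20)})
        assert res.odds_ratio == pytest.approx(4.0)
        assert res.ci95_low < 4.0 < res.ci95_high

    def test_replicated_strata_pool_to_same_or(self):
        res = mh_odds_ratio({"s1": TwoByTwo(20, 10, 10, 20), "s2": TwoByTwo(20, 10, 10, 20)})
        assert res.odds_ratio == pytest.approx(4.0)

    def test_pooled_or_within_stratum_or_range(self):
        rng = np.random.default_rng(17)
        for _ in range(300):
            tables = {i: TwoByTwo(*(int(v) for v in rng.integers(1, 40, 4))) for i in range(5)}
            per_stratum = [t.a * t.d / (t.b * t.c) for t in tables.values()]
            res = mh_odds_ratio(tables)
            assert min(per_stratum) - 1e-9 <= res.odds_ratio <= max(per_stratum) + 1e-9

    def test_uninformative_strata_dropped(self):
        tables = {"ok": TwoByTwo(20, 10, 10, 20), "no_exposure": TwoByTwo(0, 0, 15, 25)}
        res = mh_odds_ratio(tables)
        assert res.odds_ratio == pytest.approx(4.0)
        assert res.n_strata_dropped == 1

    def test_all_uninformative_raises(self):
        with pytest.raises(ValueError):
            mh_odds_ratio({"x": TwoByTwo(0, 0, 5, 5)})

    def test_zero_pooled_margin_flagged_inestimable(self):
        res = mh_odds_ratio({"s": TwoByTwo(5, 0, 0, 5)})  # S = 0
        assert not res.estimable


class TestFixedEffectsLogistic:
    def test_single_stratum_matches_closed_form(self):
        y, e, s = _expand({"s": TwoByTwo(20, 10, 10, 20)})
        res = fe_logistic(y, e, s)
        assert res.log_or == pytest.approx(math.log(4.0), abs=1e-4)
        assert abs(res.odds_ratio - 4.0) / 4.0 < 1e-6

    def test_outcome_invariant_stratum_is_inert(self):
        base = {"s1": TwoByTwo(20, 10, 10, 20), "s2": TwoByTwo(12, 9, 14, 22)}
        y1, e1, s1 = _expand(base)
        with_invariant = dict(base)
        with_invariant["dead"] = TwoByTwo(0, 7, 0, 9)  # no outcome variation
        y2, e2, s2 = _expand(with_invariant)
        r1, r2 = fe_logistic(y1, e1, s1), fe_logistic(y2, e2, s2)
        assert abs(r1.odds_ratio - r2.odds_ratio) < 1e-8
        assert r2.n_strata_dropped == 1

    def test_matches_statsmodels_on_random_stratified_data(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(23)
        n = 2000
        s = rng.choice(list("ABCDE"), n)
        e = rng.random(n) < 0.3
        alpha = {k: v for k, v in zip("ABCDE", [-1.0, -0.5, 0.0, 0.4, 0.8])}
        logits = np.array([alpha[si] for si in s]) + 0.5 * e
        y = rng.random(n) < 1 / (1 + np.exp(-logits))
        res = fe_logistic(y, e, s)
        X = np.column_stack([e.astype(float)] + [(s == k).astype(float) for k in "ABCDE"])
        sm_fit = sm.Logit(y.astype(float), X).fit(disp=0)
        assert res.log_or == pytest.approx(sm_fit.params[0], abs=1e-6)
        assert res.se_log_or == pytest.approx(sm_fit.bse[0], rel=1e-4)

    def test_agrees_with_mh_on_balanced_scenes(self):
        rng = np.random.default_rng(31)
        for rep in range(20):
            tables = {}
            for i in range(5):
                base = rng.uniform(0.3, 0.6)
                n_exp, n_un = 100, 100
                a = rng.binomial(n_exp, min(0.95, base * 1.5))
                c = rng.binomial(n_un, base)
                tables[i] = TwoByTwo(a, n_exp - a, c, n_un - c)
            y, e, s = _expand(tables)
            fe = fe_logistic(y, e, s)
            mh = mh_odds_ratio(tables)
            assert abs(fe.odds_ratio - mh.odds_ratio) / mh.odds_ratio < 0.05

    def test_exposure_constant_in_every_stratum_raises(self):
        y = np.array([1, 0, 1, 0], bool)
        e = np.array([1, 1, 1, 1], bool)
        with pytest.raises((SeparationError, ValueError)):
            fe_logistic(y, e, ["a", "a", "b", "b"])

    def test_permuted_labels_have_null_or(self):
        """Breaking the exposure-outcome link drives the mean log-OR to zero."""
        rng = np.random.default_rng(41)
        n = 4000
        s = rng.choice(list("ABCDE"), n)
        e = rng.random(n) < 0.3
        logits = -0.2 + 0.9 * e
        y = rng.random(n) < 1 / (1 + np.exp(-logits))
        log_ors, ses = [], []
        for _ in range(100):
            e_perm = e.copy()
            for k in "ABCDE":
                m = np.flatnonzero(s == k)
                e_perm[m] = e_perm[rng.permutation(m)]
            res = fe_logistic(y, e_perm, s)
            log_ors.append(res.log_or)
            ses.append(res.se_log_or)
        mean_lor = np.mean(log_ors)
        se_mean = np.mean(ses) / math.sqrt(len(log_ors))
        assert abs(mean_lor) < 3 * se_mean


class TestAssociationSuite:
    def test_tables_layout_cardinality(self, small_scene_tables):
        spec = AssociationSpec(subsets=("all", "per-urbanicity"))
        res = sw.run_association_suite(small_scene_tables["exposure"],
                                       small_scene_tables["profiles"], spec)
        assert len(res[res.subset == "all"]) == 9  # 3 buffers x 3 characteristics
        assert len(res[res.subset.str.startswith("urbanicity:")]) == 27

    def test_top_producing_state_subset_restricts_states(self):
        rng = np.random.default_rng(3)
        n = 800
        states = rng.choice(["TX", "OK", "NY", "MA"], n)
        prof = pd.DataFrame({
            "school_id": [f"S{i}" for i in range(n)],
            "state_code": states, "county_fips": "0", "urbanicity": "Rural",
            "predominant_nh_white_50": rng.random(n) < 0.5,
            "predominant_hispanic_50": rng.random(n) < 0.2,
            "predominant_frl_50": rng.random(n) < 0.5,
        })
        exp = pd.DataFrame({"school_id": prof.school_id,
                            "exposed_800m": rng.random(n) < 0.3})
        spec = AssociationSpec(buffers=(800,), subsets=("top_producing_states",))
        res = sw.run_association_suite(exp, prof, spec)
        n_top = ((states == "TX") | (states == "OK")).sum()
        assert (res.n_outcome_yes + res.n_outcome_no <= n_top).all()

    def test_empty_cell_flagged_not_raised(self):
        prof = pd.DataFrame({"school_id": ["S1"], "state_code": ["SA"], "county_fips": ["0"],
                             "urbanicity": ["Rural"],
                             "predominant_nh_white_50": [True],
                             "predominant_hispanic_50": [False],
                             "predominant_frl_50": [True]})
        exp = pd.DataFrame({"school_id": ["S1"], "exposed_800m": [True]})
        spec = AssociationSpec(buffers=(800,), subsets=("per-urbanicity",))
        res = sw.run_association_suite(exp, prof, spec)
        metro = res[res.subset == "urbanicity:Metropolitan"]
        assert (~metro.estimable).all()


class TestDescriptiveTable:
    def test_stated_quantile_convention(self):
        prof = pd.DataFrame({"school_id": list("abcd"),
                             "prop_frl": [0.10, 0.20, 0.30, 0.40]})
        exp = pd.DataFrame({"school_id": list("abcd"),
                            "exposed_800m": [True] * 4})
        out = sw.descriptive_table(exp, prof, radii=(800,), characteristics=("frl",))
        row = out[(out.exposure_class == "exposed_800m")].iloc[0]
        assert row["median"] == pytest.approx(25.0)
        assert row["iqr_low"] == pytest.approx(17.5)
        assert row["iqr_high"] == pytest.approx(32.5)

    def test_single_school_class_degenerate(self):
        prof = pd.DataFrame({"school_id": ["a"], "prop_frl": [0.5]})
        exp = pd.DataFrame({"school_id": ["a"], "exposed_800m": [True]})
        out = sw.descriptive_table(exp, prof, radii=(800,), characteristics=("frl",))
        row = out.iloc[0]
        assert row["mean"] == row["median"] == row["iqr_low"] == row["iqr_high"] == 50.0

    def test_empty_class_flagged(self):
        prof = pd.DataFrame({"school_id": ["a"], "prop_frl": [0.5]})
        exp = pd.DataFrame({"school_id": ["a"], "exposed_800m": [False]})
        out = sw.descriptive_table(exp, prof, radii=(800,), characteristics=("frl",))
        assert out[out.exposure_class == "exposed_800m"]["empty"].iloc[0]

    def test_exposure_classes_nested(self, small_scene_tables):
        out = sw.descriptive_table(small_scene_tables["exposure"], small_scene_tables["profiles"])
        n_by_class = out.groupby("exposure_class")["n_schools"].first()
        assert n_by_class["exposed_800m"] <= n_by_class["exposed_1600m"] <= n_by_class["exposed_10000m"]
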