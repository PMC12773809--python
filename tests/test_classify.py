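"""Split arithmetic, grid search, evaluation metrics and leakage guards."""

import numpy as np
import pandas as pd
import pytest

from netomics import preprocess as pp
from netomics.classify import (
    ModelSpec, build_model_inputs, evaluate_probabilities, external_validate,
    fit_eval, grid_search_gbt, stratified_split,
)


def _labels(n_case, n_control):
    idx = [f"S{i:04d}" for i in range(n_case + n_control)]
    return pd.Series(["case"] * n_case + ["control"] * n_control, index=idx)


class TestStratifiedSplit:
    def test_cohort_scale_arithmetic(self):
        plan = stratified_split(_labels(213, 92), test_frac=0.2, seed=0)
        assert plan.n_train == 244
        assert plan.n_test == 61

    def test_balanced_ten_samples(self):
        y = _labels(5, 5)
        plan = stratified_split(y, test_frac=0.2, seed=1)
        assert plan.n_test == 2
        assert set(y.loc[plan.test]) == {"case", "control"}

    def test_deterministic_and_disjoint(self):
        y = _labels(30, 20)
        a = stratified_split(y, seed=7)
        b = stratified_split(y, seed=7)
        assert list(a.train) == list(b.train) and list(a.test) == list(b.test)
        assert set(a.train).isdisjoint(a.test)
        assert set(a.train) | set(a.test) == set(y.index)

    def test_per_class_fraction_within_one_sample(self):
        y = _labels(47, 23)
        plan = stratified_split(y, test_frac=0.2, seed=3)
        for c in ("case", "control"):
            n_c = (y == c).sum()
            n_test_c = (y.loc[plan.test] == c).sum()
            assert abs(n_test_c - n_c * 0.2) <= 1.0

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError):
            stratified_split(_labels(5, 5), test_frac=1.2)


class TestGridSearch:
    def _xy(self, n=60, seed=0, separable=False):
        rng = np.random.default_rng(seed)
        y = np.array(["case"] * (n // 2) + ["control"] * (n - n // 2))
        X = pd.DataFrame(rng.standard_normal((n, 5)),
                         columns=[f"f{j}" for j in range(5)])
        if separable:
            X["f0"] = (y == "case") * 2.0  # one perfect feature
        return X, y

    def test_singleton_grid_returned(self):
        X, y = self._xy()
        grid = {"n_estimators": [50], "max_depth": [2],
                "learning_rate": [0.1], "subsample": [1.0]}
        best, table = grid_search_gbt(X, y, grid, seed=0)
        assert best == {"n_estimators": 50, "max_depth": 2,
                        "learning_rate": 0.1, "subsample": 1.0}
        assert len(table) == 1

    def test_separable_data_near_perfect_cv_auc(self):
        X, y = self._xy(separable=True)
        grid = {"n_estimators": [50], "max_depth": [2],
                "learning_rate": [0.1], "subsample": [1.0]}
        _, table = grid_search_gbt(X, y, grid, seed=0)
        assert table["mean_auc"].max() >= 0.99

    def test_cv_table_bookkeeping(self):
        X, y = self._xy()
        grid = {"n_estimators": [20, 40], "max_depth": [2, 3],
                "learning_rate": [0.1], "subsample": [1.0]}
        _, table = grid_search_gbt(X, y, grid, seed=1)
        assert len(table) == 4
        assert {"mean_auc", "sd_auc"} <= set(table.columns)


class TestFitEval:
    def test_confusion_derived_metrics(self):
        # TP=9 FN=1 FP=2 TN=8 at threshold 0.5
        y = np.array(["case"] * 10 + ["control"] * 10)
        prob = np.array([0.9] * 9 + [0.1] + [0.8] * 2 + [0.2] * 8)
        rep = evaluate_probabilities(y, prob, boot_B=100, seed=0)
        assert rep.confusion == {"tp": 9, "fn": 1, "fp": 2, "tn": 8}
        assert rep["sensitivity"][0] == pytest.approx(0.9)
        assert rep["specificity"][0] == pytest.approx(0.8)
        assert rep["f1"][0] == pytest.approx(18 / 21)
        assert rep["accuracy"][0] == pytest.approx(17 / 20)

    def test_perfect_probabilities(self):
        y = np.array(["case"] * 6 + ["control"] * 6)
        prob = (y == "case").astype(float)
        rep = evaluate_probabilities(y, prob, boot_B=200, seed=1)
        for metric in ("auc", "accuracy", "sensitivity", "specificity", "f1"):
            pt, lo, hi = rep[metric]
            assert pt == 1.0 and lo == 1.0 and hi == 1.0

    def test_auc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(2)
        y = np.array(["case", "control"] * 25)
        prob = rng.uniform(0.01, 0.99, 50)
        a = evaluate_probabilities(y, prob, boot_B=10, seed=0)["auc"][0]
        b = evaluate_probabilities(y, 1 / (1 + np.exp(-7 * (prob - 0.4))),
                                   boot_B=10, seed=0)["auc"][0]
        assert a == pytest.approx(b)

    def test_bootstrap_ci_contains_point(self):
        rng = np.random.default_rng(3)
        y = np.array(["case"] * 30 + ["control"] * 30)
        prob = np.clip(rng.normal((y == "case") * 0.4 + 0.3, 0.2), 0, 1)
        rep = evaluate_probabilities(y, prob, boot_B=500, seed=4)
        for pt, lo, hi in rep.metrics.values():
            assert lo <= pt <= hi
            assert 0.0 <= lo and hi <= 1.0

    def test_null_test_auc_near_half(self):
        rng = np.random.default_rng(5)
        n = 200
        y = np.array(["case", "control"] * (n // 2))
        Xtr = pd.DataFrame(rng.standard_normal((n, 10)))
        Xte = pd.DataFrame(rng.standard_normal((100, 10)))
        Xtr.columns = Xtr.columns.astype(str)
        Xte.columns = Xte.columns.astype(str)
        yte = np.array(["case", "control"] * 50)
        rep, _ = fit_eval(Xtr, y, Xte, yte, params={"n_estimators": 50, "max_depth": 2},
                          boot_B=50, seed=6)
        assert abs(rep["auc"][0] - 0.5) < 0.1

    def test_single_class_test_set_rejected(self):
        y = np.array(["case"] * 5)
        with pytest.raises(ValueError, match="single class"):
            evaluate_probabilities(y, np.linspace(0, 1, 5))


class TestModelInputs:
    def _blocks(self):
        rng = np.random.default_rng(0)
        idx = [f"S{i}" for i in range(10)]
        meth = pd.DataFrame(rng.normal(size=(10, 6)), index=idx,
                            columns=[f"cg{j}" for j in range(6)])
        expr = pd.DataFrame(rng.normal(size=(10, 8)), index=idx,
                            columns=[f"G{j}" for j in range(8)])
        return {"methylation": meth, "expression": expr}

    def test_disjoint_union_sizes(self):
        blocks = self._blocks()
        sig = {"methylation": ["cg0", "cg1"], "expression": ["G0", "G1", "G2"]}
        tables, inv = build_model_inputs(sig, ["G5", "G6"], blocks)
        assert tables["MO"].shape[1] == 5
        assert tables["TR"].shape[1] == 2
        assert tables["MO-TR"].shape[1] == 7  # disjoint: |MO| + |TR|

    def test_absorbed_regulators(self):
        blocks = self._blocks()
        sig = {"expression": ["G0", "G1", "G2"]}
        tables, _ = build_model_inputs(sig, ["G1", "G2"], blocks)
        assert list(tables["MO-TR"].columns) == list(tables["MO"].columns)

    def test_inclusion_exclusion(self):
        blocks = self._blocks()
        sig = {"expression": ["G0", "G1", "G2", "G3"]}
        regs = ["G2", "G3", "G4", "G5"]
        tables, inv = build_model_inputs(sig, regs, blocks)
        brute = set(sig["expression"]) | set(regs)
        assert tables["MO-TR"].shape[1] == len(brute)
        assert inv["unresolved_regulators"] == []

    def test_unresolvable_regulators_reported_and_all_lost_rejected(self):
        blocks = self._blocks()
        sig = {"expression": ["G0"]}
        _, inv = build_model_inputs(sig, ["G1", "NOPE"], blocks)
        assert inv["unresolved_regulators"] == ["NOPE"]
        with pytest.raises(ValueError):
            build_model_inputs(sig, ["NOPE"], blocks)


class TestLeakage:
    def test_test_rows_never_touch_fitting(self):
        """Poisoning held-out rows must not change scaler or grid choice."""
        rng = np.random.default_rng(7)
        y = pd.Series(["case"] * 30 + ["control"] * 30,
                      index=[f"S{i}" for i in range(60)])
        X = pd.DataFrame(rng.standard_normal((60, 5)), index=y.index,
                         columns=[f"f{j}" for j in range(5)])
        plan = stratified_split(y, seed=0)
        poisoned = X.copy()
        poisoned.loc[plan.test] = 1e6  # sentinel garbage in held-out rows
        s1 = pp.zscore_fit(X.loc[plan.train])
        s2 = pp.zscore_fit(poisoned.loc[plan.train])
        pd.testing.assert_series_equal(s1.mean, s2.mean)
        grid = {"n_estimators": [20, 40], "max_depth": [2],
                "learning_rate": [0.1], "subsample": [1.0]}
        b1, t1 = grid_search_gbt(X.loc[plan.train], y.loc[plan.train].to_numpy(),
                                 grid, seed=1)
        b2, t2 = grid_search_gbt(poisoned.loc[plan.train],
                                 y.loc[plan.train].to_numpy(), grid, seed=1)
        assert b1 == b2
        pd.testing.assert_frame_equal(t1, t2)


class TestExternalValidation:
    def _setup(self, hide_frac=0.0, seed=0):
        rng = np.random.default_rng(seed)
        n, p = 80, 20
        feats = [f"cg{j}" for j in range(10)] + [f"G{j}" for j in range(10)]
        y = pd.Series(["case"] * 40 + ["control"] * 40,
                      index=[f"S{i}" for i in range(n)])
        X = pd.DataFrame(rng.standard_normal((n, p)), index=y.index, columns=feats)
        X.iloc[:, :4] += (y == "case").to_numpy()[:, None] * 1.5
        ext_y = pd.Series(["case"] * 15 + ["control"] * 15,
                          index=[f"E{i}" for i in range(30)])
        ext = pd.DataFrame(rng.standard_normal((30, p)), index=ext_y.index,
                           columns=feats)
        ext.iloc[:, :4] += (ext_y == "case").to_numpy()[:, None] * 1.5
        if hide_frac:
            hidden = list(rng.choice(feats, size=int(p * hide_frac), replace=False))
            ext = ext.drop(columns=hidden)
        else:
            hidden = []
        spec = ModelSpec(features=feats, train_X=X, train_y=y,
                         params={"n_estimators": 30, "max_depth": 2})
        return spec, ext, ext_y, hidden

    def test_full_intersection_equals_direct_pipeline(self):
        spec, ext, ext_y, _ = self._setup()
        rep, inv = external_validate(spec, ext, ext_y.to_numpy(), boot_B=50, seed=1)
        assert inv["n_intersected"] == 20 and inv["n_lost"] == 0
        scaler = pp.zscore_fit(spec.train_X)
        rep2, _ = fit_eval(pp.zscore_apply(scaler, spec.train_X), spec.train_y,
                           pp.zscore_apply(scaler, ext), ext_y.to_numpy(),
                           params=spec.params, boot_B=50, seed=1)
        assert rep["auc"][0] == pytest.approx(rep2["auc"][0])

    def test_dropout_inventory_lists_hidden_features(self):
        spec, ext, ext_y, hidden = self._setup(hide_frac=0.5, seed=2)
        rep, inv = external_validate(spec, ext, ext_y.to_numpy(), boot_B=50, seed=1,
                                     modality_of=lambda f: "meth" if f.startswith("cg")
                                     else "expr")
        assert sorted(inv["lost"]) == sorted(hidden)
        assert sum(inv["per_modality"].values()) == inv["n_intersected"]

    def test_empty_intersection_rejected(self):
        spec, ext, ext_y, _ = self._setup()
        with pytest.raises(ValueError, match="intersection"):
            external_validate(spec, ext.rename(columns=lambda c: "zz" + c),
                              ext_y.to_numpy())
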