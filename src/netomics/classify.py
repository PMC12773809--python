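"""Final supervised classification with gradient-boosted trees.

Three feature sets are compared: the multi-omics signature (MO), the
expression features of the topological regulators (TR), and their
union (MO-TR). The protocol mirrors a stratified 80/20 split, 5-fold
grid-search tuning on the training set only, and held-out evaluation
with percentile-bootstrap 95% confidence intervals.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from xgboost import XGBClassifier

from .preprocess import ScalerState, zscore_apply, zscore_fit
from .splsda import FeatureSignature

DEFAULT_GRID = {
    "n_estimators": [100, 300],
    "max_depth": [2, 3, 4],
    "learning_rate": [0.05, 0.1],
    "subsample": [0.8, 1.0],
}


@dataclass
class SplitPlan:
    """Stratified train/test allocation."""

    train: pd.Index
    test: pd.Index
    test_frac: float
    seed: int

    @property
    def n_train(self) -> int:
        return len(self.train)

    @property
    def n_test(self) -> int:
        return len(self.test)


def stratified_split(labels: pd.Series, test_frac: float = 0.2,
                     seed: int = 0) -> SplitPlan:
    """Per-class largest-remainder allocation to the test set.

    The total test size is round(n * test_frac); per-class counts start
    at the floor of class_n * test_frac and the remaining slots go to
    the classes with the largest fractional remainders. Membership is a
    seeded shuffle within class.
    """
    if not (0 < test_frac < 1):
        raise ValueError("test_frac must lie in (0, 1)")
    labels = pd.Series(labels)
    counts = labels.value_counts()
    if (counts < 2).any():
        raise ValueError("every class needs at least 2 members")
    n_test_total = int(round(len(labels) * test_frac))
    classes = sorted(counts.index)
    exact = {c: counts[c] * test_frac for c in classes}
    alloc = {c: int(np.floor(exact[c])) for c in classes}
    short = n_test_total - sum(alloc.values())
    remainders = sorted(classes, key=lambda c: (-(exact[c] - alloc[c]), c))
    for c in remainders[:short]:
        alloc[c] += 1
    rng = np.random.default_rng(seed)
    test_ids = []
    for c in classes:
        members = labels.index[labels == c].to_numpy()
        perm = rng.permutation(len(members))
        test_ids.extend(members[perm[: alloc[c]]])
    test = pd.Index([i for i in labels.index if i in set(test_ids)])
    train = pd.Index([i for i in labels.index if i not in set(test_ids)])
    return SplitPlan(train=train, test=test, test_frac=test_frac, seed=seed)


def _grid_points(param_grid: dict) -> list[dict]:
    keys = list(param_grid)
    return [dict(zip(keys, vals)) for vals in itertools.product(*(param_grid[k] for k in keys))]


def _make_xgb(params: dict, seed: int) -> XGBClassifier:
    return XGBClassifier(**params, random_state=seed, n_jobs=1,
                         eval_metric="logloss", tree_method="hist")


def _binary_y(y: np.ndarray, positive: str) -> np.ndarray:
    return (np.asarray(y) == positive).astype(int)


def grid_search_gbt(X: pd.DataFrame, y, param_grid: dict | None = None,
                    k: int = 5, seed: int = 0,
                    positive: str = "case") -> tuple[dict, pd.DataFrame]:
    """Exhaustive grid search by mean stratified-CV AUC.

    Ties break toward fewer trees, then shallower depth. Returns the
    winning parameter dict and the full CV table (one row per grid
    point with mean and sd AUC).
    """
    if param_grid is None:
        param_grid = DEFAULT_GRID
    points = _grid_points(param_grid)
    if not points:
        raise ValueError("empty parameter grid")
    yb = _binary_y(y, positive)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    rows = []
    for params in points:
        aucs = []
        for tr, te in skf.split(X, yb):
            if len(np.unique(yb[tr])) < 2 or len(np.unique(yb[te])) < 2:
                raise ValueError("single-class fold; reduce k or rebalance")
            clf = _make_xgb(params, seed)
            clf.fit(X.iloc[tr], yb[tr])
            prob = clf.predict_proba(X.iloc[te])[:, 1]
            aucs.append(roc_auc_score(yb[te], prob))
        rows.append({**params, "mean_auc": float(np.mean(aucs)),
                     "sd_auc": float(np.std(aucs, ddof=1))})
    table = pd.DataFrame(rows)
    order = table.sort_values(
        ["mean_auc", "n_estimators", "max_depth"],
        ascending=[False, True, True], kind="stable")
    best = {k_: order.iloc[0][k_] for k_ in param_grid}
    best = {k_: (int(v) if float(v).is_integer() and k_ in ("n_estimators", "max_depth")
                 else float(v)) for k_, v in best.items()}
    return best, table


@dataclass
class MetricsReport:
    """Point estimates with 95% percentile-bootstrap CIs."""

    metrics: dict[str, tuple[float, float, float]]  # name -> (point, lo, hi)
    confusion: dict[str, int]
    threshold: float
    boot_B: int
    seed: int
    extra: dict = field(default_factory=dict)

    def __getitem__(self, name: str) -> tuple[float, float, float]:
        return self.metrics[name]

    def to_frame(self) -> pd.DataFrame:
        rows = [{"metric": m, "estimate": p, "ci_lower": lo, "ci_upper": hi}
                for m, (p, lo, hi) in self.metrics.items()]
        return pd.DataFrame(rows)


def _point_metrics(yb: np.ndarray, prob: np.ndarray, threshold: float) -> dict[str, float]:
    pred = (prob >= threshold).astype(int)
    tp = int(((pred == 1) & (yb == 1)).sum())
    fn = int(((pred == 0) & (yb == 1)).sum())
    fp = int(((pred == 1) & (yb == 0)).sum())
    tn = int(((pred == 0) & (yb == 0)).sum())
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    acc = (tp + tn) / len(yb)
    prec = tp / (tp + fp) if tp + fp else 0.0
    f1 = 2 * prec * sens / (prec + sens) if prec + sens else 0.0
    auc = roc_auc_score(yb, prob) if len(np.unique(yb)) == 2 else np.nan
    return {"auc": float(auc), "accuracy": acc, "sensitivity": sens,
            "specificity": spec, "f1": f1,
            "_confusion": {"tp": tp, "fn": fn, "fp": fp, "tn": tn}}


def evaluate_probabilities(y_true, prob, positive: str = "case",
                           threshold: float = 0.5, boot_B: int = 2000,
                           seed: int = 0) -> MetricsReport:
    """Metrics + stratified percentile-bootstrap CIs from predicted probabilities."""
    yb = _binary_y(y_true, positive)
    if len(np.unique(yb)) < 2:
        raise ValueError("evaluation set contains a single class; AUC undefined")
    prob = np.asarray(prob, dtype=float)
    point = _point_metrics(yb, prob, threshold)
    confusion = point.pop("_confusion")
    rng = np.random.default_rng(seed)
    pos = np.flatnonzero(yb == 1)
    neg = np.flatnonzero(yb == 0)
    boot = {m: [] for m in point}
    for _ in range(boot_B):
        idx = np.concatenate([rng.choice(pos, size=pos.size, replace=True),
                              rng.choice(neg, size=neg.size, replace=True)])
        bm = _point_metrics(yb[idx], prob[idx], threshold)
        bm.pop("_confusion")
        for m, v in bm.items():
            boot[m].append(v)
    metrics = {}
    for m, p in point.items():
        lo, hi = np.percentile(boot[m], [2.5, 97.5])
        metrics[m] = (p, float(min(lo, p)), float(max(hi, p)))
    return MetricsReport(metrics=metrics, confusion=confusion, threshold=threshold,
                         boot_B=boot_B, seed=seed)


def fit_eval(train_X: pd.DataFrame, train_y, test_X: pd.DataFrame, test_y,
             params: dict | None = None, positive: str = "case",
             threshold: float = 0.5, boot_B: int = 2000,
             seed: int = 0) -> tuple[MetricsReport, XGBClassifier]:
    """Fit on the full training set, evaluate on the held-out test set."""
    params = params or {}
    clf = _make_xgb(params, seed)
    clf.fit(train_X, _binary_y(train_y, positive))
    prob = clf.predict_proba(test_X)[:, 1]
    report = evaluate_probabilities(test_y, prob, positive=positive,
                                    threshold=threshold, boot_B=boot_B, seed=seed)
    return report, clf


def build_model_inputs(signature: FeatureSignature | dict[str, list[str]],
                       regulators: list[str],
                       blocks: dict[str, pd.DataFrame],
                       expression_block: str = "expression"
                       ) -> tuple[dict[str, pd.DataFrame], dict]:
    """Assemble the MO / TR / MO-TR feature tables.

    MO concatenates every block's signature features; TR takes the
    regulator genes' expression features (unresolvable IDs are reported
    and dropped); MO-TR is their deduplicated union.
    """
    if isinstance(signature, FeatureSignature):
        sig = {b: signature.features(b) for b in signature.per_block}
    else:
        sig = {b: list(f) for b, f in signature.items()}
    mo_parts = []
    for bname, feats in sig.items():
        if bname not in blocks:
            raise KeyError(f"signature block {bname!r} missing from blocks")
        mo_parts.append(blocks[bname][feats])
    mo = pd.concat(mo_parts, axis=1)
    mo = mo.loc[:, ~mo.columns.duplicated()]

    expr = blocks[expression_block]
    resolvable = [r for r in regulators if r in expr.columns]
    unresolved = [r for r in regulators if r not in expr.columns]
    if not resolvable:
        raise ValueError("no regulator resolves against the expression block")
    tr = expr[resolvable]

    motr = pd.concat([mo, tr], axis=1)
    motr = motr.loc[:, ~motr.columns.duplicated()]
    inventory = {
        "mo_features": int(mo.shape[1]),
        "tr_features": int(tr.shape[1]),
        "motr_features": int(motr.shape[1]),
        "unresolved_regulators": unresolved,
        "per_block_signature": {b: len(f) for b, f in sig.items()},
    }
    return {"MO": mo, "TR": tr, "MO-TR": motr}, inventory


@dataclass
class ModelSpec:
    """Everything needed to refit a model on a feature subset."""

    features: list[str]
    train_X: pd.DataFrame
    train_y: pd.Series
    params: dict
    positive: str = "case"


def external_validate(spec: ModelSpec, external_X: pd.DataFrame, external_y,
                      modality_of=None, boot_B: int = 2000,
                      seed: int = 0) -> tuple[MetricsReport, dict]:
    """Refit on features intersected with the external platform and evaluate.

    Features are matched by exact ID; the model is refit on the source
    training data restricted to the intersection (z-scored on training
    statistics), then scored on the external cohort. The inventory
    reports intersected and lost features, per modality when a
    ``modality_of`` mapping is supplied.
    """
    inter = [f for f in spec.features if f in external_X.columns]
    lost = [f for f in spec.features if f not in external_X.columns]
    if not inter:
        raise ValueError("empty feature intersection with the external dataset")
    scaler = zscore_fit(spec.train_X[inter])
    Xtr = zscore_apply(scaler, spec.train_X[inter])
    Xex = zscore_apply(scaler, external_X[inter])
    report, _ = fit_eval(Xtr, spec.train_y, Xex, external_y, params=spec.params,
                         positive=spec.positive, boot_B=boot_B, seed=seed)
    inventory: dict = {"n_intersected": len(inter), "n_lost": len(lost),
                       "intersected": inter, "lost": lost}
    if modality_of is not None:
        per_mod: dict[str, int] = {}
        for f in inter:
            per_mod[modality_of(f)] = per_mod.get(modality_of(f), 0) + 1
        inventory["per_modality"] = per_mod
    report.extra["feature_inventory"] = {k: v for k, v in inventory.items()
                                         if k not in ("intersected", "lost")}
    return report, inventory
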