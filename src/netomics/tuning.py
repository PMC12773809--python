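"""Hyperparameter selection by balanced error rate and bootstrap stability.

The balanced error rate (BER) — the mean of per-class misclassification
fractions — drives every choice so the minority class is never washed
out. Cross-validation is stratified k-fold with repeated randomized
partitions; feature-selection reproducibility is quantified by
stratified bootstrap resampling with fixed (ncomp, keepX).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from . import splsda
from ._utils import check_rng


def ber(y_true, y_pred) -> float:
    """Balanced error rate: mean over classes of the per-class error fraction."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have the same length")
    errs = []
    for c in np.unique(y_true):
        mask = y_true == c
        errs.append(float(np.mean(y_pred[mask] != c)))
    return float(np.mean(errs))


@dataclass
class CVResult:
    """Mean/sd BER per grid point over all fold x repeat evaluations."""

    table: pd.DataFrame  # columns depend on the search; always mean_ber, sd_ber
    k: int
    repeats: int
    seed: int


def _fold_bers(fit_fn, predict_fn, X, y, k: int, repeats: int, seed: int) -> np.ndarray:
    y = np.asarray(y)
    counts = pd.Series(y).value_counts()
    if (counts < k).any():
        small = counts[counts < k].index[0]
        raise ValueError(f"class {small!r} has fewer than k={k} members")
    bers = []
    for r in range(repeats):
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=(seed + r) % 2**31)
        for tr, te in skf.split(np.zeros(len(y)), y):
            model = fit_fn(_take(X, tr), y[tr])
            pred = predict_fn(model, _take(X, te))
            bers.append(ber(y[te], pred))
    return np.asarray(bers)


def _take(X, idx):
    """Row-subset a matrix, a DataFrame, or a list/dict of blocks."""
    if isinstance(X, dict):
        return {k: _take(v, idx) for k, v in X.items()}
    if isinstance(X, (list, tuple)):
        return [_take(v, idx) for v in X]
    if isinstance(X, pd.DataFrame):
        return X.iloc[idx]
    return np.asarray(X)[idx]


def cv_ber(fit_fn, predict_fn, X, y, k: int = 5, repeats: int = 1,
           seed: int = 0) -> tuple[float, float, np.ndarray]:
    """Repeated stratified k-fold BER: (mean, sd, all fold x repeat values)."""
    bers = _fold_bers(fit_fn, predict_fn, X, y, k, repeats, seed)
    return float(bers.mean()), float(bers.std(ddof=1)) if len(bers) > 1 else 0.0, bers


def tune_ncomp(X, y, max_comp: int = 6, k: int = 5, repeats: int = 10,
               seed: int = 0, **fit_kwargs) -> tuple[int, CVResult]:
    """Pick the component count by the one-standard-error rule.

    Dense models (keepX = all features) with 1..max_comp components are
    cross-validated; the smallest H whose mean BER is within one pooled
    standard error of the global minimum wins.
    """
    if max_comp < 1:
        raise ValueError("max_comp must be >= 1")
    rows = []
    for h in range(1, max_comp + 1):
        def fit_fn(Xtr, ytr, h=h):
            return splsda.splsda_fit(Xtr, ytr, ncomp=h, **fit_kwargs)

        def predict_fn(model, Xte):
            return splsda.splsda_predict(model, Xte)[0]

        mean, sd, bers = cv_ber(fit_fn, predict_fn, X, y, k=k, repeats=repeats, seed=seed)
        rows.append({"ncomp": h, "mean_ber": mean, "sd_ber": sd,
                     "se_ber": sd / np.sqrt(len(bers))})
    table = pd.DataFrame(rows)
    best = table["mean_ber"].min()
    best_se = float(table.loc[table["mean_ber"].idxmin(), "se_ber"])
    chosen = int(table.loc[table["mean_ber"] <= best + best_se, "ncomp"].min())
    return chosen, CVResult(table=table, k=k, repeats=repeats, seed=seed)


def keepx_grid(kind: str = "single") -> list[int]:
    """Candidate feature counts per component.

    ``single``: 3..30 step 3, 30..60 step 6, 60..150 step 15,
    150..300 step 30 (single-omics search). ``integrative``: 10..50
    step 5, nine candidates (multiblock search).
    """
    if kind == "single":
        vals = (list(range(3, 31, 3)) + list(range(36, 61, 6))
                + list(range(75, 151, 15)) + list(range(180, 301, 30)))
        return vals
    if kind == "integrative":
        return list(range(10, 51, 5))
    raise ValueError(f"unknown grid kind {kind!r}")


def tune_keepx(X, y, ncomp: int, grid: list[int] | None = None, k: int = 5,
               repeats: int = 10, seed: int = 0,
               **fit_kwargs) -> tuple[list[int], CVResult]:
    """Greedy per-component keepX search by CV BER.

    Components are tuned sequentially: with components 1..h-1 fixed at
    their chosen values, every grid value is evaluated for component h
    and the smallest value whose mean BER sits within one standard
    error of the component's minimum is kept (the BER surface is flat
    near the optimum, so a raw minimizer would wander; the
    one-standard-error rule prefers the sparser model). The full BER
    surface (|grid| x ncomp entries) is returned.
    """
    if grid is None:
        grid = keepx_grid("single")
    if not grid:
        raise ValueError("grid must be nonempty")
    p = (X.shape[1] if hasattr(X, "shape") else np.asarray(X).shape[1])
    grid = sorted({min(g, p) for g in grid})
    chosen: list[int] = []
    rows = []
    for h in range(1, ncomp + 1):
        surface = []
        for g in grid:
            keepX = chosen + [g]

            def fit_fn(Xtr, ytr, keepX=keepX, h=h):
                return splsda.splsda_fit(Xtr, ytr, ncomp=h, keepX=keepX, **fit_kwargs)

            def predict_fn(model, Xte):
                return splsda.splsda_predict(model, Xte)[0]

            mean, sd, bers = cv_ber(fit_fn, predict_fn, X, y, k=k, repeats=repeats,
                                    seed=seed)
            rows.append({"component": h, "keepX": g, "mean_ber": mean, "sd_ber": sd})
            surface.append((g, mean, sd / np.sqrt(len(bers))))
        best_mean, best_se = min((m, se) for _, m, se in surface)
        chosen.append(int(min(g for g, m, _ in surface if m <= best_mean + best_se)))
    table = pd.DataFrame(rows)
    return chosen, CVResult(table=table, k=k, repeats=repeats, seed=seed)


@dataclass
class StabilityScores:
    """Per-feature selection frequency over B bootstrap refits."""

    frequencies: pd.Series  # feature -> count/B
    B: int
    counts: pd.Series

    def above(self, threshold: float) -> list[str]:
        return list(self.frequencies[self.frequencies >= threshold].index)


def _stratified_resample(y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """With-replacement resample preserving class counts."""
    idx = []
    for c in np.unique(y):
        members = np.flatnonzero(y == c)
        idx.append(rng.choice(members, size=members.size, replace=True))
    return np.concatenate(idx)


def bootstrap_stability(X, y, ncomp: int, keepX, B: int = 1000, seed: int = 0,
                        **fit_kwargs) -> StabilityScores:
    """Selection frequency of each feature over B stratified bootstrap refits.

    Each resample redraws samples with replacement within class, refits
    sparse PLS-DA at fixed (ncomp, keepX), and counts a feature as
    selected if it has a nonzero loading on any component.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    y = np.asarray(y)
    Xf = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X))
    rng = check_rng(seed)
    counts = pd.Series(0, index=Xf.columns, dtype=int)
    for _ in range(B):
        idx = _stratified_resample(y, rng)
        model = splsda.splsda_fit(Xf.iloc[idx], y[idx], ncomp=ncomp, keepX=keepX,
                                  **fit_kwargs)
        sig = splsda.select_features(model)
        counts.loc[sig.features("block0")] += 1
    freq = counts / B
    return StabilityScores(frequencies=freq.rename("frequency"), B=B, counts=counts)
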