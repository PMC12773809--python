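"""Sparse PLS-DA and multiblock (DIABLO-style) integration.

Single-block sparse PLS-DA finds, per component, a sparse unit feature
loading u and outcome loading v maximizing cov(X u, Y v) with Y a
centered one-hot class indicator; exactly ``keepX`` features receive
nonzero loadings via soft-thresholding at the (keepX+1)-th largest
magnitude. The multiblock extension couples several omics blocks
through a symmetric design matrix C, maximizing

    sum_{i<j} c_ij cov(X_i u_i, X_j u_j)   (outcome as an extra block,
                                            c_{i,Y} = 1)

by block-coordinate ascent. Blocks are deflated on their own scores;
the outcome is deflated once per component on the mean block score, so
a single block plus outcome reduces exactly to sparse PLS-DA.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ConvergenceError", "SplsModel", "DiabloModel", "FeatureSignature",
    "uniform_design", "splsda_fit", "splsda_predict",
    "diablo_fit", "diablo_predict", "select_features",
    "save_model", "load_model",
]


class ConvergenceError(RuntimeError):
    """Raised when a component does not converge; carries the iteration count."""

    def __init__(self, message: str, n_iter: int):
        super().__init__(message)
        self.n_iter = n_iter


def _one_hot(y: np.ndarray, classes: np.ndarray) -> np.ndarray:
    return (y[:, None] == classes[None, :]).astype(float)


def _soft_threshold_keepx(z: np.ndarray, keepx: int) -> np.ndarray:
    """Sparse unit vector: keep the keepx largest |z|, shrink by the next one.

    Ties at the threshold would zero survivors under shrinkage; in that
    (measure-zero) case the update falls back to hard thresholding so
    the nonzero count stays exactly keepx. Ties in the ranking itself
    break by input order (stable sort).
    """
    p = z.size
    if keepx >= p:
        u = z.copy()
    else:
        order = np.argsort(-np.abs(z), kind="stable")
        support = order[:keepx]
        lam = np.abs(z[order[keepx]])
        u = np.zeros(p)
        shrunk = np.abs(z[support]) - lam
        if np.any(shrunk <= 0):
            u[support] = z[support]  # tie fallback: hard threshold
        else:
            u[support] = np.sign(z[support]) * shrunk
    nrm = np.linalg.norm(u)
    if nrm == 0:
        raise ValueError("zero loading update (degenerate input)")
    return u / nrm


def uniform_design(n_blocks: int, w: float = 0.1) -> np.ndarray:
    """(n_blocks+1)-square design: block-block weight w, block-outcome 1."""
    if not (0 <= w <= 1):
        raise ValueError("design weight must lie in [0, 1]")
    d = np.full((n_blocks + 1, n_blocks + 1), w)
    d[:, -1] = 1.0
    d[-1, :] = 1.0
    np.fill_diagonal(d, 0.0)
    return d


def _check_design(design: np.ndarray, n_blocks: int) -> np.ndarray:
    design = np.asarray(design, dtype=float)
    if design.shape != (n_blocks + 1, n_blocks + 1):
        raise ValueError(f"design must be {(n_blocks + 1,) * 2} (blocks + outcome)")
    if not np.allclose(design, design.T):
        raise ValueError("design matrix must be symmetric")
    if (design < 0).any() or (design > 1).any():
        raise ValueError("design entries must lie in [0, 1]")
    if np.abs(np.diag(design)).max() > 0:
        raise ValueError("design diagonal must be zero")
    return design


@dataclass
class _BlockFit:
    """Per-block component stack (internal)."""

    features: pd.Index
    x_mean: np.ndarray
    x_scale: np.ndarray
    U: np.ndarray  # p x H sparse loadings (unit norm columns)
    T: np.ndarray  # n x H scores
    P: np.ndarray  # p x H regression (deflation) loadings
    C: np.ndarray  # classes x H outcome loadings for prediction
    keepX: list[int]


@dataclass
class DiabloModel:
    """Fitted multiblock sparse PLS-DA model."""

    classes: np.ndarray
    block_names: list[str]
    blocks: dict[str, _BlockFit]
    design: np.ndarray
    ncomp: int
    y_mean: np.ndarray
    V: np.ndarray  # classes x H outcome-block loadings
    train_onehot: np.ndarray | None = None
    objective_history: list[list[float]] = field(default_factory=list)
    n_iter: list[int] = field(default_factory=list)


@dataclass
class SplsModel:
    """Fitted single-block sparse PLS-DA model (thin wrapper over one block)."""

    classes: np.ndarray
    fit: _BlockFit
    ncomp: int
    y_mean: np.ndarray
    V: np.ndarray
    train_onehot: np.ndarray | None = None
    objective_history: list[list[float]] = field(default_factory=list)
    n_iter: list[int] = field(default_factory=list)

    @property
    def keepX(self) -> list[int]:
        return self.fit.keepX

    @property
    def loadings(self) -> pd.DataFrame:
        return pd.DataFrame(self.fit.U, index=self.fit.features,
                            columns=[f"comp{h + 1}" for h in range(self.ncomp)])

    @property
    def scores(self) -> np.ndarray:
        return self.fit.T


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    X = np.asarray(X, dtype=float)
    return pd.DataFrame(X, columns=[f"f{i}" for i in range(X.shape[1])])


def _normalize_keepx(keepX, ncomp: int, p: int, label: str) -> list[int]:
    if keepX is None:
        keepX = [p] * ncomp
    if np.isscalar(keepX):
        keepX = [int(keepX)] * ncomp
    keepX = [int(k) for k in keepX]
    if len(keepX) != ncomp:
        raise ValueError(f"{label}: keepX needs one value per component")
    for k in keepX:
        if not (1 <= k <= p):
            raise ValueError(f"{label}: keepX={k} outside [1, {p}]")
    return keepX


def _fit_multiblock(Xs: list[pd.DataFrame], y, ncomp: int, keepXs, design,
                    scale: bool, tol: float, max_iter: int) -> DiabloModel:
    """Shared block-coordinate core for both single- and multiblock fits."""
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("y must contain at least two classes")
    n = len(y)
    names = [f"block{i}" for i in range(len(Xs))]
    frames = [_as_frame(X) for X in Xs]
    for f in frames:
        if len(f) != n:
            raise ValueError("blocks and labels are not sample-aligned")
    design = _check_design(design, len(frames))

    rank_bound = min(n - 1, min(f.shape[1] for f in frames))
    if not (1 <= ncomp <= rank_bound):
        raise ValueError(f"ncomp must lie in [1, {rank_bound}]")
    keepXs = [_normalize_keepx(k, ncomp, f.shape[1], nm)
              for k, f, nm in zip(keepXs, frames, names)]

    means = [f.to_numpy(dtype=float).mean(axis=0) for f in frames]
    scales = []
    Xc = []
    for f, m in zip(frames, means):
        arr = f.to_numpy(dtype=float) - m
        s = arr.std(axis=0, ddof=1) if scale else np.ones(arr.shape[1])
        s = np.where(s == 0, 1.0, s)
        scales.append(s)
        Xc.append(arr / s)
    Y = _one_hot(y, classes)
    y_mean = Y.mean(axis=0)
    Yc = Y - y_mean

    B = len(Xc)
    Us = [np.zeros((X.shape[1], ncomp)) for X in Xc]
    Ts = [np.zeros((n, ncomp)) for _ in Xc]
    Ps = [np.zeros((X.shape[1], ncomp)) for X in Xc]
    Cs = [np.zeros((classes.size, ncomp)) for _ in Xc]
    V = np.zeros((classes.size, ncomp))
    histories: list[list[float]] = []
    iters: list[int] = []

    for h in range(ncomp):
        # init outcome loading from the design-weighted cross-covariance stack
        M = np.vstack([design[i, B] * (Xc[i].T @ Yc) for i in range(B)])
        _, _, vt = np.linalg.svd(M, full_matrices=False)
        v = vt[0]
        v /= np.linalg.norm(v)
        tY = Yc @ v
        ts = [np.zeros(n) for _ in range(B)]
        us = [None] * B
        history: list[float] = []
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            prev = ([None if u is None else u.copy() for u in us],
                    [t.copy() for t in ts], v.copy(), tY.copy())
            max_change = 0.0
            for i in range(B):
                target = design[i, B] * tY
                for j in range(B):
                    if j != i:
                        target = target + design[i, j] * ts[j]
                z = Xc[i].T @ target
                u_new = _soft_threshold_keepx(z, keepXs[i][h])
                if us[i] is not None:
                    max_change = max(max_change, np.linalg.norm(u_new - us[i]))
                else:
                    max_change = np.inf
                us[i] = u_new
                ts[i] = Xc[i] @ u_new
            zv = Yc.T @ sum(design[i, B] * ts[i] for i in range(B))
            v_new = zv / np.linalg.norm(zv)
            max_change = max(max_change, np.linalg.norm(v_new - v))
            v = v_new
            tY = Yc @ v

            obj = sum(design[i, j] * float(ts[i] @ ts[j])
                      for i in range(B) for j in range(i + 1, B))
            obj += sum(design[i, B] * float(ts[i] @ tY) for i in range(B))
            if history and obj < history[-1] - tol * (1 + abs(history[-1])):
                # the thresholded update stalled: revert to the previous
                # iterate (the objective maximum seen) and stop
                us, ts, v, tY = prev
                converged = True
                break
            history.append(obj)
            if max_change < tol:
                converged = True
                break
        if not converged:
            raise ConvergenceError(
                f"component {h + 1} did not converge in {max_iter} iterations", it)
        histories.append(history)
        iters.append(it)

        tbar = np.mean(ts, axis=0)
        for i in range(B):
            t = ts[i]
            tt = float(t @ t)
            Us[i][:, h] = us[i]
            Ts[i][:, h] = t
            Ps[i][:, h] = (Xc[i].T @ t) / tt
            Cs[i][:, h] = (Yc.T @ t) / tt
            Xc[i] = Xc[i] - np.outer(t, Ps[i][:, h])
        V[:, h] = v
        tbt = float(tbar @ tbar)
        if tbt > 0:
            Yc = Yc - np.outer(tbar, (Yc.T @ tbar) / tbt)

    blocks = {
        nm: _BlockFit(features=frames[i].columns, x_mean=means[i], x_scale=scales[i],
                      U=Us[i], T=Ts[i], P=Ps[i], C=Cs[i], keepX=keepXs[i])
        for i, nm in enumerate(names)
    }
    return DiabloModel(classes=classes, block_names=names, blocks=blocks,
                       design=design, ncomp=ncomp, y_mean=y_mean, V=V,
                       train_onehot=Y, objective_history=histories, n_iter=iters)


def splsda_fit(X, y, ncomp: int, keepX=None, scale: bool = False,
               tol: float = 1e-6, max_iter: int = 100) -> SplsModel:
    """Fit single-block sparse PLS-DA.

    ``keepX`` gives the per-component nonzero budget (defaults to all
    features, i.e. dense PLS-DA). Blocks are column-centered; set
    ``scale=True`` for unit-variance scaling.
    """
    design = uniform_design(1, 0.0)
    model = _fit_multiblock([X], y, ncomp, [keepX], design, scale, tol, max_iter)
    fit = model.blocks["block0"]
    return SplsModel(classes=model.classes, fit=fit, ncomp=ncomp,
                     y_mean=model.y_mean, V=model.V, train_onehot=model.train_onehot,
                     objective_history=model.objective_history, n_iter=model.n_iter)


def diablo_fit(blocks, y, ncomp: int, keepX=None, design=None, scale: bool = False,
               tol: float = 1e-6, max_iter: int = 100,
               block_names: list[str] | None = None) -> DiabloModel:
    """Fit the multiblock model on sample-aligned blocks.

    ``blocks`` is a list (or dict) of samples x features matrices;
    ``keepX`` a per-block list of per-component budgets; ``design`` the
    (n_blocks+1)-square symmetric weight matrix (defaults to 0.1
    block-block, 1 block-outcome).
    """
    if isinstance(blocks, dict):
        block_names = list(blocks.keys())
        blocks = list(blocks.values())
    n_blocks = len(blocks)
    if design is None:
        design = uniform_design(n_blocks)
    if keepX is None:
        keepX = [None] * n_blocks
    if len(keepX) != n_blocks:
        raise ValueError("keepX needs one entry per block")
    model = _fit_multiblock(blocks, y, ncomp, keepX, design, scale, tol, max_iter)
    if block_names is not None:
        model.blocks = {new: model.blocks[old]
                        for new, old in zip(block_names, model.block_names)}
        model.block_names = list(block_names)
    return model


def _block_scores(fit: _BlockFit, Xnew: pd.DataFrame) -> np.ndarray:
    Xc = (Xnew.to_numpy(dtype=float) - fit.x_mean) / fit.x_scale
    # W(P'W)^-1 maps centered data to the score space of the deflation sequence
    Wstar = fit.U @ np.linalg.pinv(fit.P.T @ fit.U)
    return Xc @ Wstar


def _centroid_scores(T_train: np.ndarray, y_train_onehot: np.ndarray,
                     Tn: np.ndarray) -> np.ndarray:
    """Negative Euclidean distance to each training class centroid."""
    scores = np.empty((Tn.shape[0], y_train_onehot.shape[1]))
    for c in range(y_train_onehot.shape[1]):
        cent = T_train[y_train_onehot[:, c] > 0].mean(axis=0)
        scores[:, c] = -np.linalg.norm(Tn - cent, axis=1)
    return scores


def _scores_for_block(fit: _BlockFit, Xnew, y_mean, distance: str,
                      train_labels_onehot: np.ndarray | None) -> np.ndarray:
    Xnew = _as_frame(Xnew)
    if not Xnew.columns.equals(fit.features):
        raise ValueError("feature set/order differs from training block")
    Tn = _block_scores(fit, Xnew)
    if distance == "max_dist":
        return Tn @ fit.C.T + y_mean
    if distance == "centroid_dist":
        if train_labels_onehot is None:
            raise ValueError("model lacks stored training memberships")
        return _centroid_scores(fit.T, train_labels_onehot, Tn)
    raise ValueError(f"unknown distance {distance!r}")


def splsda_predict(model: SplsModel, Xnew, distance: str = "max_dist"):
    """Predict class labels and class score matrix for new samples."""
    scores = _scores_for_block(model.fit, Xnew, model.y_mean,
                               distance, model.train_onehot)
    labels = model.classes[np.argmax(scores, axis=1)]
    return labels, scores


def diablo_predict(model: DiabloModel, blocks_new, scheme: str = "average",
                   distance: str = "max_dist"):
    """Combine per-block predictions; returns (labels, per-block score dict)."""
    if isinstance(blocks_new, dict):
        missing = [b for b in model.block_names if b not in blocks_new]
        if missing:
            raise ValueError(f"missing block(s): {missing}")
        blocks_new = [blocks_new[b] for b in model.block_names]
    if len(blocks_new) != len(model.block_names):
        raise ValueError("wrong number of blocks")
    per_block = {}
    for name, Xb in zip(model.block_names, blocks_new):
        per_block[name] = _scores_for_block(model.blocks[name], Xb, model.y_mean,
                                            distance, model.train_onehot)
    stacked = np.stack(list(per_block.values()), axis=0)
    mean_scores = stacked.mean(axis=0)
    if scheme == "average":
        labels = model.classes[np.argmax(mean_scores, axis=1)]
    elif scheme == "majority_vote":
        votes = np.argmax(stacked, axis=2)  # blocks x samples
        labels = np.empty(stacked.shape[1], dtype=model.classes.dtype)
        for s in range(stacked.shape[1]):
            counts = np.bincount(votes[:, s], minlength=model.classes.size)
            winners = np.flatnonzero(counts == counts.max())
            if winners.size == 1:
                labels[s] = model.classes[winners[0]]
            else:  # tie -> average fallback
                labels[s] = model.classes[np.argmax(mean_scores[s])]
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    return labels, per_block


@dataclass
class FeatureSignature:
    """Per-block union of features with a nonzero loading on any component."""

    per_block: dict[str, pd.DataFrame]  # columns: feature, max_abs_loading, first_component

    def features(self, block: str) -> list[str]:
        return list(self.per_block[block]["feature"])

    @property
    def total_unique(self) -> int:
        return sum(len(df) for df in self.per_block.values())

    def sizes(self) -> dict[str, int]:
        return {b: len(df) for b, df in self.per_block.items()}


def select_features(model) -> FeatureSignature:
    """Extract the selected signature from a fitted model.

    Order is stable: features appear in block input order, deduplicated
    across components; each carries its max |loading| and the first
    component selecting it.
    """
    if isinstance(model, SplsModel):
        items = {"block0": model.fit}
    else:
        items = model.blocks
    per_block = {}
    for name, fit in items.items():
        U = fit.U
        nz = np.abs(U) > 0
        selected = nz.any(axis=1)
        rows = []
        for idx in np.flatnonzero(selected):
            comps = np.flatnonzero(nz[idx])
            rows.append({
                "feature": fit.features[idx],
                "max_abs_loading": float(np.abs(U[idx]).max()),
                "first_component": int(comps[0] + 1),
            })
        per_block[name] = pd.DataFrame(rows, columns=["feature", "max_abs_loading",
                                                      "first_component"])
    return FeatureSignature(per_block=per_block)


def save_model(model: DiabloModel | SplsModel, path: str | Path) -> None:
    """Serialize loadings as sparse triplets plus metadata to one JSON file."""
    if isinstance(model, SplsModel):
        blocks = {"block0": model.fit}
        kind = "splsda"
        design = uniform_design(1, 0.0)
        block_names = ["block0"]
    else:
        blocks, kind = model.blocks, "diablo"
        design, block_names = model.design, model.block_names
    payload = {
        "kind": kind,
        "classes": [str(c) for c in model.classes],
        "ncomp": model.ncomp,
        "y_mean": model.y_mean.tolist(),
        "V": model.V.tolist(),
        "design": np.asarray(design).tolist(),
        "block_names": block_names,
        "blocks": {},
    }
    for name in block_names:
        fit = blocks[name]
        trip = [(int(i), int(h), float(fit.U[i, h]))
                for i, h in zip(*np.nonzero(fit.U))]
        payload["blocks"][name] = {
            "features": [str(f) for f in fit.features],
            "x_mean": fit.x_mean.tolist(),
            "x_scale": fit.x_scale.tolist(),
            "keepX": fit.keepX,
            "loadings": trip,
            "P": fit.P.tolist(),
            "C": fit.C.tolist(),
            "T": fit.T.tolist(),
        }
    Path(path).write_text(json.dumps(payload))


def load_model(path: str | Path):
    payload = json.loads(Path(path).read_text())
    classes = np.array(payload["classes"])
    ncomp = payload["ncomp"]
    blocks = {}
    for name, bp in payload["blocks"].items():
        p = len(bp["features"])
        U = np.zeros((p, ncomp))
        for i, h, val in bp["loadings"]:
            U[i, h] = val
        blocks[name] = _BlockFit(
            features=pd.Index(bp["features"]), x_mean=np.array(bp["x_mean"]),
            x_scale=np.array(bp["x_scale"]), U=U, T=np.array(bp["T"]),
            P=np.array(bp["P"]), C=np.array(bp["C"]), keepX=list(bp["keepX"]))
    y_mean = np.array(payload["y_mean"])
    V = np.array(payload["V"])
    if payload["kind"] == "splsda":
        return SplsModel(classes=classes, fit=blocks["block0"], ncomp=ncomp,
                         y_mean=y_mean, V=V)
    return DiabloModel(classes=classes, block_names=payload["block_names"],
                       blocks=blocks, design=np.array(payload["design"]),
                       ncomp=ncomp, y_mean=y_mean, V=V)
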