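"""End-to-end orchestration of the six analysis stages.

Stage order: complete-case alignment -> stratified split ->
train-fitted preprocessing -> (optional) tuning -> multiblock sparse
PLS-DA fit and signature extraction -> network topology (hidden nodes,
propagation, stability) -> MO/TR/MO-TR classifier construction,
grid search and held-out evaluation -> optional external validation.
All randomness derives from one global seed via per-stage CRC32-derived
seeds, so any stage re-run in isolation reproduces its in-pipeline
stream.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify, nettopo, preprocess, splsda, tuning
from ._utils import derive_seed
from .datatypes import MultiOmicsDataset, OmicsBlock
from .io import read_labels, read_matrix


class StageError(RuntimeError):
    """Pipeline failure annotated with the failing stage and partial manifest."""

    def __init__(self, stage: str, cause: Exception, manifest: dict):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.manifest = manifest


@dataclass
class PipelineConfig:
    """Paths, per-stage switches and parameter snapshot for one run."""

    block_paths: dict[str, str]            # block name -> matrix TSV
    labels_path: str
    edges_path: str | None = None
    out_dir: str = "netomics_run"
    seed: int = 0
    features_as_rows: bool = True
    modalities: dict[str, str] = field(default_factory=dict)
    test_frac: float = 0.2
    # preprocessing
    meth_is_beta: bool = False
    variance_top: dict[str, int] = field(default_factory=dict)  # block -> k
    # model
    ncomp: int = 2
    keepx: dict[str, list[int]] | None = None   # block -> per-component budgets
    design_weight: float = 0.1
    tune: bool = False
    tune_max_comp: int = 3
    tune_repeats: int = 3
    cv_folds: int = 5
    # network topology
    hn_alpha: float = 0.05
    np_restart: float = 0.5
    np_n_perm: int = 200
    np_top_frac: float = 0.01
    robustness_reps: int = 20
    criticality_top: int = 50
    # classification
    classifier_grid: dict = field(default_factory=lambda: {
        "n_estimators": [100], "max_depth": [2, 3],
        "learning_rate": [0.1], "subsample": [1.0]})
    boot_B: int = 500
    external_block_paths: dict[str, str] | None = None
    external_labels_path: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(**raw)

    def validate(self) -> None:
        for name, p in self.block_paths.items():
            if not Path(p).exists():
                raise FileNotFoundError(f"block {name!r}: {p} does not exist")
        if not Path(self.labels_path).exists():
            raise FileNotFoundError(f"labels: {self.labels_path} does not exist")
        if self.edges_path and not Path(self.edges_path).exists():
            raise FileNotFoundError(f"edges: {self.edges_path} does not exist")


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (pd.Index,)):
        return list(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def _write_json(payload: dict, path: Path) -> None:
    path.write_text(json.dumps(payload, indent=1, sort_keys=True, default=_json_default))


def load_dataset(config: PipelineConfig) -> tuple[MultiOmicsDataset, list[str]]:
    """Read blocks and labels; keep only samples present in every table."""
    blocks = {}
    for name, path in config.block_paths.items():
        blocks[name] = read_matrix(path, name=name,
                                   modality=config.modalities.get(name, name),
                                   features_as_rows=config.features_as_rows)
    labels = read_labels(config.labels_path)
    common = labels.index
    for b in blocks.values():
        common = common.intersection(b.samples)
    dropped = sorted(set(labels.index) - set(common))
    common = pd.Index([s for s in labels.index if s in set(common)])
    aligned = [OmicsBlock(b.name, b.modality, b.data.loc[common])
               for b in blocks.values()]
    return MultiOmicsDataset(aligned, labels.loc[common]), dropped


def preprocess_blocks(dataset: MultiOmicsDataset, train_idx: pd.Index,
                      config: PipelineConfig) -> dict[str, pd.DataFrame]:
    """Modality-specific normalization with train-fitted choices.

    Feature filters (low-count removal, variance ranking) are decided
    on training samples and applied to all; per-sample normalizations
    (size factors, median centering) are sample-local by construction.
    """
    out = {}
    for blk in dataset.blocks:
        X = blk.data
        mod = blk.modality
        if mod == "methylation":
            if config.meth_is_beta:
                X = preprocess.beta_to_mvalue(X)
        elif mod == "expression":
            _, removed = preprocess.filter_low_counts(X.loc[train_idx])
            X = X.drop(columns=removed)
            X, _ = preprocess.median_ratio_normalize(X)
            X = np.log2(X + 1)  # variance stabilization after size-factor scaling
        elif mod == "proteomics":
            if (X.to_numpy() > 0).all():
                X = preprocess.log2_median_center(X)
        k = config.variance_top.get(blk.name)
        if k:
            _, kept = preprocess.variance_topk(X.loc[train_idx], k)
            X = X[kept]
        out[blk.name] = X
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and return the run manifest."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}, "config": config.__dict__.copy()}
    manifest["config"] = {k: v for k, v in manifest["config"].items()}

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            try:
                result = fn()
            except Exception as exc:  # noqa: BLE001 - annotate and re-raise
                _write_json(manifest, out_dir / "manifest.json")
                raise StageError(name, exc, manifest) from exc
            manifest["stages"][name] = {
                "seed": derive_seed(config.seed, name),
                "wall_clock_s": round(time.perf_counter() - t0, 3),
            }
            return result
        return deco

    inputs = {n: _sha256(p) for n, p in config.block_paths.items()}
    inputs["labels"] = _sha256(config.labels_path)
    if config.edges_path:
        inputs["edges"] = _sha256(config.edges_path)
    manifest["input_sha256"] = inputs

    @stage("load")
    def _load():
        return load_dataset(config)

    dataset, dropped = _load
    manifest["dropped_samples"] = dropped
    manifest["n_samples"] = dataset.n_samples

    @stage("split")
    def _split():
        return classify.stratified_split(dataset.labels, config.test_frac,
                                         seed=derive_seed(config.seed, "split"))

    plan = _split
    manifest["n_train"], manifest["n_test"] = plan.n_train, plan.n_test

    @stage("preprocess")
    def _prep():
        return preprocess_blocks(dataset, plan.train, config)

    blocks = _prep
    y = dataset.labels
    y_train = y.loc[plan.train]

    @stage("tune")
    def _tune():
        keepx = config.keepx
        ncomp = config.ncomp
        if config.tune:
            seed = derive_seed(config.seed, "tune")
            grid = tuning.keepx_grid("integrative")
            keepx = {}
            for name, X in blocks.items():
                chosen, _ = tuning.tune_keepx(X.loc[plan.train], y_train.to_numpy(),
                                              ncomp=ncomp, grid=grid, k=config.cv_folds,
                                              repeats=config.tune_repeats, seed=seed)
                keepx[name] = chosen
        if keepx is None:
            keepx = {name: [20] * ncomp for name in blocks}
        return ncomp, keepx

    ncomp, keepx = _tune
    manifest["ncomp"], manifest["keepx"] = ncomp, keepx

    @stage("integrate")
    def _integrate():
        design = splsda.uniform_design(len(blocks), config.design_weight)
        model = splsda.diablo_fit({n: X.loc[plan.train] for n, X in blocks.items()},
                                  y_train.to_numpy(), ncomp=ncomp,
                                  keepX=[keepx[n] for n in blocks], design=design)
        sig = splsda.select_features(model)
        rows = []
        for bname, df in sig.per_block.items():
            for _, r in df.iterrows():
                rows.append({"block": bname, **r.to_dict()})
        pd.DataFrame(rows).to_csv(out_dir / "signature.tsv", sep="\t", index=False)
        splsda.save_model(model, out_dir / "diablo_model.json")
        return model, sig

    model, signature = _integrate
    manifest["signature_sizes"] = signature.sizes()

    regulators: list[str] = []
    if config.edges_path:
        @stage("nettopo")
        def _nettopo():
            net = nettopo.read_edge_list(config.edges_path)
            node_set = set(net.graph.nodes())
            seeds = {f for b in signature.per_block
                     for f in signature.features(b) if f in node_set}
            if not seeds:
                raise ValueError("no signature feature maps onto the network")
            seed = derive_seed(config.seed, "nettopo")
            hn = nettopo.hidden_nodes(net, seeds, alpha=config.hn_alpha)
            np_scores = nettopo.network_propagation(
                net, seeds, restart=config.np_restart, n_perm=config.np_n_perm,
                top_frac=config.np_top_frac, seed=seed)
            hn.to_csv(out_dir / "hidden_nodes.tsv", sep="\t", index=False)
            np_scores.to_csv(out_dir / "network_propagation.tsv", sep="\t", index=False)
            regs = sorted(set(hn.loc[hn["significant"], "node"])
                          | set(np_scores.loc[np_scores["significant"], "node"]))
            top_deg = sorted(net.graph.degree, key=lambda kv: -kv[1])
            crit_nodes = [v for v, _ in top_deg[: config.criticality_top]]
            report = nettopo.stability_report(net, regulators=set(regs),
                                              reps=config.robustness_reps, seed=seed,
                                              criticality_nodes=crit_nodes)
            _write_json(report, out_dir / "stability_report.json")
            return regs
        regulators = _nettopo
    manifest["n_regulators"] = len(regulators)

    @stage("classify")
    def _classify():
        seed = derive_seed(config.seed, "classify")
        reg_list = regulators or []
        if reg_list:
            tables, inventory = classify.build_model_inputs(
                signature, reg_list, blocks)
        else:
            tables, inventory = classify.build_model_inputs(
                signature, list(blocks["expression"].columns[:1]), blocks)
            tables = {"MO": tables["MO"]}
        results = {}
        for mname, table in tables.items():
            scaler = preprocess.zscore_fit(table.loc[plan.train])
            Xtr = preprocess.zscore_apply(scaler, table.loc[plan.train])
            Xte = preprocess.zscore_apply(scaler, table.loc[plan.test])
            best, cv_table = classify.grid_search_gbt(
                Xtr, y_train.to_numpy(), config.classifier_grid,
                k=config.cv_folds, seed=seed)
            report, _ = classify.fit_eval(Xtr, y_train.to_numpy(), Xte,
                                          y.loc[plan.test].to_numpy(), params=best,
                                          boot_B=config.boot_B, seed=seed)
            results[mname] = {"params": best, "metrics": report.metrics,
                              "confusion": report.confusion}
            cv_table.to_csv(out_dir / f"cv_{mname}.tsv", sep="\t", index=False)
        rows = []
        for mname, res in results.items():
            for metric, (pt, lo, hi) in res["metrics"].items():
                rows.append({"model": mname, "metric": metric, "estimate": round(pt, 4),
                             "ci_lower": round(lo, 4), "ci_upper": round(hi, 4)})
        pd.DataFrame(rows).to_csv(out_dir / "metrics.tsv", sep="\t", index=False)
        _write_json(results, out_dir / "metrics.json")
        return results, inventory

    results, inventory = _classify
    manifest["feature_inventory"] = inventory
    manifest["models"] = {m: {k: v for k, v in res.items() if k != "metrics"}
                          for m, res in results.items()}

    _write_json(manifest, out_dir / "manifest.json")
    return manifest
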