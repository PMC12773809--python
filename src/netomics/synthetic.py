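"""Synthetic multi-omics cohorts and interaction networks.

The generator emulates the statistical structure a two-class blood /
CSF multi-omics study presents to the analysis: three omics blocks
(Gaussian methylation M-values, negative-binomial expression counts
with per-sample library-size factors, Gaussian log2 proteomic
intensities) that share class-linked latent components through sparse
block-specific signatures, plus a scale-free protein-interaction
network containing the signature genes and planted high-degree
"regulator" nodes. Every downstream stage of the pipeline is testable
against the planted ground truth with no external download.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .datatypes import MultiOmicsDataset, OmicsBlock
from .nettopo import InteractionNetwork, write_edge_list


@dataclass
class BlockConfig:
    """Per-block simulation settings.

    ``n_signature`` features load on the shared latent components; the
    rest are pure noise. ``nb_dispersion`` and ``libsize_sd`` only
    apply to the counts (expression) modality.
    """

    n_features: int = 300
    n_signature: int = 20
    noise_sd: float = 1.0
    nb_dispersion: float = 0.4
    libsize_sd: float = 0.3

    def validate(self, name: str) -> None:
        if self.n_signature > self.n_features:
            raise ValueError(f"{name}: n_signature > n_features")
        if not np.isfinite([self.noise_sd, self.nb_dispersion, self.libsize_sd]).all():
            raise ValueError(f"{name}: non-finite block parameter")
        if self.noise_sd <= 0:
            raise ValueError(f"{name}: noise_sd must be positive")
        if self.nb_dispersion < 0 or self.libsize_sd < 0:
            raise ValueError(f"{name}: negative dispersion parameter")


@dataclass
class SimConfig:
    """Two-class multi-omics simulation settings.

    ``effect_size`` is the mean shift delta applied to the scores of the
    first ``n_disc_latent`` latent components for case samples; a
    single latent dimension then separates the classes with oracle
    AUC Phi(delta / sqrt(2)).
    """

    n_samples: int = 300
    class_proportions: tuple[float, float] = (0.7, 0.3)  # (case, control)
    n_latent: int = 2
    n_disc_latent: int = 2
    effect_size: float = 1.5
    blocks: dict[str, BlockConfig] = field(default_factory=lambda: {
        "methylation": BlockConfig(n_features=300, n_signature=20, noise_sd=1.0),
        "expression": BlockConfig(n_features=300, n_signature=20, noise_sd=0.3),
        "proteomics": BlockConfig(n_features=200, n_signature=20, noise_sd=1.0),
    })
    seed: int = 0

    def validate(self) -> None:
        p = np.asarray(self.class_proportions, dtype=float)
        if p.shape != (2,) or not np.isfinite(p).all():
            raise ValueError("class_proportions must be two finite fractions")
        if not ((0 < p) & (p < 1)).all() or abs(p.sum() - 1.0) > 1e-12:
            raise ValueError("class_proportions must lie in (0,1) and sum to 1")
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if self.n_latent < 1:
            raise ValueError("n_latent must be >= 1")
        if self.n_disc_latent > self.n_latent:
            raise ValueError("n_disc_latent > n_latent")
        if not np.isfinite(self.effect_size) or self.effect_size < 0:
            raise ValueError("effect_size must be a nonnegative finite real")
        for name, blk in self.blocks.items():
            blk.validate(name)


@dataclass
class NetSimConfig:
    """Scale-free interaction-network simulation settings."""

    n_nodes: int = 800
    attachment: int = 3  # edges per new node (preferential attachment)
    n_regulators: int = 15
    regulator_seed_bias: float = 5.0  # multiplier on regulator-signature edge probability
    seed: int = 0

    def validate(self) -> None:
        if self.n_nodes < 3:
            raise ValueError("n_nodes must be >= 3")
        if self.attachment < 1 or self.attachment >= self.n_nodes:
            raise ValueError("attachment must satisfy 1 <= attachment < n_nodes")
        if self.n_regulators >= self.n_nodes:
            raise ValueError("n_regulators must be < n_nodes")
        if self.regulator_seed_bias < 1:
            raise ValueError("regulator_seed_bias must be >= 1")


_ID_FORMATS = {
    "methylation": "cg{:05d}",
    "expression": "G{:04d}",
    "proteomics": "P{:04d}",
}


def _feature_ids(modality: str, p: int) -> list[str]:
    fmt = _ID_FORMATS.get(modality, modality[:1].upper() + "{:04d}")
    return [fmt.format(i) for i in range(p)]


def gene_id(i: int) -> str:
    """Canonical gene node ID shared by the expression block and the network."""
    return _ID_FORMATS["expression"].format(i)


def gen_multiomics(config: SimConfig) -> MultiOmicsDataset:
    """Draw one two-class multi-omics dataset.

    Latent scores L are standard normal (n_samples x n_latent), with the
    first ``n_disc_latent`` columns shifted by +effect_size for cases.
    Signature features are loading * L(+ noise); loadings are uniform in
    +/-[0.5, 1.5] with random sign, each signature feature assigned to
    one latent component round-robin so every component carries part of
    the block signature. Same seed, same config => bit-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    n = config.n_samples
    n_case = int(round(n * config.class_proportions[0]))
    n_case = min(max(n_case, 1), n - 1)
    y = np.array(["case"] * n_case + ["control"] * (n - n_case))
    rng.shuffle(y)
    samples = pd.Index([f"S{i:04d}" for i in range(n)], name="sample_id")
    labels = pd.Series(y, index=samples, name="class")
    is_case = y == "case"

    L = rng.standard_normal((n, config.n_latent))
    L[is_case, : config.n_disc_latent] += config.effect_size

    blocks: list[OmicsBlock] = []
    truth: dict[str, list[str]] = {}
    for name, blk in config.blocks.items():
        p, s = blk.n_features, blk.n_signature
        ids = _feature_ids(name, p)
        comp = np.arange(s) % config.n_latent  # round-robin component assignment
        load = rng.uniform(0.5, 1.5, size=s) * rng.choice([-1.0, 1.0], size=s)
        signal = np.zeros((n, p))
        if s:
            signal[:, :s] = L[:, comp] * load

        if name == "expression":
            # log-linear predictor -> NB counts scaled by library factors
            base = rng.normal(3.5, 1.0, size=p)
            eta = base + signal
            libfac = np.exp(rng.normal(0.0, blk.libsize_sd, size=n))
            mu = np.exp(eta) * libfac[:, None]
            if blk.nb_dispersion > 0:
                shape = 1.0 / blk.nb_dispersion
                lam = rng.gamma(shape, mu * blk.nb_dispersion)
            else:
                lam = mu
            X = rng.poisson(lam).astype(np.int64)
        elif name == "methylation":
            base = rng.normal(0.0, 2.0, size=p)  # M-value baseline spread
            X = base + signal + rng.normal(0.0, blk.noise_sd, size=(n, p))
        else:
            base = rng.normal(10.0, 1.0, size=p)  # log2 intensity baseline
            X = base + signal + rng.normal(0.0, blk.noise_sd, size=(n, p))

        df = pd.DataFrame(X, index=samples, columns=pd.Index(ids, name="feature_id"))
        blocks.append(OmicsBlock(name, name, df))
        truth[name] = ids[:s]

    latent = pd.DataFrame(L, index=samples,
                          columns=[f"latent{j + 1}" for j in range(config.n_latent)])
    return MultiOmicsDataset(blocks, labels, truth, latent=latent)


def gen_network(config: NetSimConfig, signature_nodes: list[str]) -> InteractionNetwork:
    """Scale-free interaction network with planted over-connected regulators.

    Preferential attachment gives the scale-free backbone; then each of
    ``n_regulators`` non-signature nodes gains an extra edge to each
    signature node independently with probability
    min(1, (bias-1) * attachment / n_signature), so bias 1 reduces to a
    plain preferential-attachment graph and the expected number of extra
    seed edges per regulator is about (bias-1) * attachment.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    ids = [gene_id(i) for i in range(config.n_nodes)]
    missing = set(signature_nodes) - set(ids)
    if missing:
        raise ValueError(f"signature nodes outside node ID space: {sorted(missing)[:3]}")

    g_int = nx.barabasi_albert_graph(config.n_nodes, config.attachment,
                                     seed=int(rng.integers(2**31)))
    g = nx.relabel_nodes(g_int, dict(enumerate(ids)))

    sig = list(signature_nodes)
    non_sig = [v for v in ids if v not in set(sig)]
    n_reg = min(config.n_regulators, len(non_sig))
    regulators = list(rng.choice(non_sig, size=n_reg, replace=False)) if n_reg else []

    if sig and regulators and config.regulator_seed_bias > 1:
        p_extra = min(1.0, (config.regulator_seed_bias - 1) * config.attachment / len(sig))
        for r in regulators:
            hits = rng.random(len(sig)) < p_extra
            for s_node, hit in zip(sig, hits):
                if hit and s_node != r:
                    g.add_edge(r, s_node)

    # robustness/criticality metrics assume a dominant component
    comps = sorted(nx.connected_components(g), key=len, reverse=True)
    if len(comps) > 1:
        main = list(comps[0])
        for comp in comps[1:]:
            u = sorted(comp)[int(rng.integers(len(comp)))]
            v = main[int(rng.integers(len(main)))]
            g.add_edge(u, v)

    for u, v in g.edges():
        g.edges[u, v]["weight"] = float(np.round(rng.uniform(0.4, 1.0), 3))

    return InteractionNetwork(g, regulators=set(regulators))


def write_fixture(dataset: MultiOmicsDataset, network: InteractionNetwork | None,
                  outdir: str | Path, features_as_rows: bool = True) -> dict[str, str]:
    """Write a fixture bundle: per-block TSV, labels TSV, edge list, truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}
    for blk in dataset.blocks:
        path = outdir / f"{blk.name}.tsv"
        mat = blk.data.T if features_as_rows else blk.data
        mat.to_csv(path, sep="\t")
        paths[blk.name] = str(path)
    labels_path = outdir / "labels.tsv"
    dataset.labels.rename("class").to_frame().to_csv(labels_path, sep="\t")
    paths["labels"] = str(labels_path)
    truth = {k: list(v) for k, v in dataset.truth.items()}
    if network is not None:
        edges_path = outdir / "edges.tsv"
        write_edge_list(network, edges_path)
        paths["edges"] = str(edges_path)
        truth["regulators"] = sorted(network.regulators)
    truth_path = outdir / "truth.json"
    truth_path.write_text(json.dumps(truth, indent=1, sort_keys=True))
    paths["truth"] = str(truth_path)
    return paths
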