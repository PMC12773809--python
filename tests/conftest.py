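"""Shared fixtures: small synthetic datasets, networks, and one
session-scoped end-to-end pipeline double-run on the standard fixture."""

from __future__ import annotations

import numpy as np
import pytest

from netomics.pipeline import PipelineConfig, run_pipeline
from netomics.synthetic import (
    NetSimConfig, SimConfig, gen_multiomics, gen_network, write_fixture,
)


@pytest.fixture(scope="session")
def small_dataset():
    """80-sample three-block dataset with planted 20-feature signatures."""
    return gen_multiomics(SimConfig(n_samples=80, seed=2))


@pytest.fixture(scope="session")
def small_network(small_dataset):
    """300-node scale-free network seeded with the expression signature."""
    return gen_network(NetSimConfig(n_nodes=300, n_regulators=10, seed=2),
                       small_dataset.truth["expression"])


@pytest.fixture(scope="session")
def proteomics_xy(small_dataset):
    X = small_dataset.block("proteomics").data
    y = small_dataset.labels.to_numpy()
    return X, y


@pytest.fixture(scope="session")
def log_blocks(small_dataset):
    """Blocks on an analysis-ready scale (counts log2-transformed)."""
    return {
        b.name: (np.log2(b.data + 1) if b.name == "expression" else b.data)
        for b in small_dataset.blocks
    }


@pytest.fixture(scope="session")
def pipeline_runs(tmp_path_factory):
    """Full pipeline run twice with one seed on the packaged-scale fixture.

    Returns (config, run directory A, run directory B); the fixture is
    the standard study-scale condition: n=300 samples, 3 blocks,
    800-node network.
    """
    root = tmp_path_factory.mktemp("pipeline")
    ds = gen_multiomics(SimConfig(n_samples=300, seed=9))
    net = gen_network(NetSimConfig(n_nodes=800, seed=9), ds.truth["expression"])
    paths = write_fixture(ds, net, root / "fixture")
    dirs = []
    config = None
    for name in ("runA", "runB"):
        config = PipelineConfig(
            block_paths={b.name: paths[b.name] for b in ds.blocks},
            labels_path=paths["labels"], edges_path=paths["edges"],
            out_dir=str(root / name), seed=17,
            np_n_perm=100, boot_B=200, criticality_top=20, robustness_reps=10,
        )
        run_pipeline(config)
        dirs.append(root / name)
    return config, dirs[0], dirs[1]
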