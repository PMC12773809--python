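"""Core containers shared across the pipeline.

Matrices are pandas DataFrames with samples as rows and features as
columns; every block of a multi-omics dataset shares one sample index in
one order. Class labels are a pandas Series aligned to that index with
values ``"case"`` / ``"control"`` (or any two nominal labels).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

MODALITIES = ("methylation", "expression", "proteomics")


@dataclass
class OmicsBlock:
    """One samples x features matrix with a block name and modality tag."""

    name: str
    modality: str
    data: pd.DataFrame  # samples x features

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ValueError(f"duplicate sample ID {dup!r} in block {self.name!r}")
        if self.data.columns.has_duplicates:
            dup = self.data.columns[self.data.columns.duplicated()][0]
            raise ValueError(f"duplicate feature ID {dup!r} in block {self.name!r}")

    @property
    def samples(self) -> pd.Index:
        return self.data.index

    @property
    def features(self) -> pd.Index:
        return self.data.columns

    @property
    def shape(self):
        return self.data.shape


@dataclass
class MultiOmicsDataset:
    """Aligned omics blocks plus class labels and optional ground truth.

    ``truth`` (populated by the synthetic generator) maps block name to
    the list of planted signature feature IDs, plus the key
    ``"regulators"`` for planted network regulators when present.
    """

    blocks: list[OmicsBlock]
    labels: pd.Series
    truth: dict[str, list[str]] = field(default_factory=dict)
    latent: pd.DataFrame | None = None  # simulated latent scores, when known

    def __post_init__(self) -> None:
        idx = self.blocks[0].samples
        for b in self.blocks[1:]:
            if not b.samples.equals(idx):
                raise ValueError(
                    f"block {b.name!r} sample index differs from {self.blocks[0].name!r}"
                )
        if not self.labels.index.equals(idx):
            raise ValueError("labels index does not match block sample index")
        for name, feats in self.truth.items():
            blk = {b.name: b for b in self.blocks}.get(name)
            if blk is None:
                continue
            missing = set(feats) - set(blk.features)
            if missing:
                raise ValueError(f"truth features absent from block {name!r}: {sorted(missing)[:3]}")

    @property
    def samples(self) -> pd.Index:
        return self.blocks[0].samples

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def block(self, name: str) -> OmicsBlock:
        for b in self.blocks:
            if b.name == name:
                return b
        raise KeyError(name)

    def subset(self, sample_ids) -> "MultiOmicsDataset":
        """Row-subset every block and the labels, preserving the given order."""
        blocks = [OmicsBlock(b.name, b.modality, b.data.loc[sample_ids]) for b in self.blocks]
        return MultiOmicsDataset(blocks, self.labels.loc[sample_ids], dict(self.truth))
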