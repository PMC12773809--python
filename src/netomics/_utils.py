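"""Shared helpers: seed derivation, multiple-testing adjustment."""

from __future__ import annotations

import zlib

import numpy as np
from statsmodels.stats.multitest import multipletests

MAX_SEED = 2**31 - 1


def derive_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: CRC32 of ``"<seed>:<stage>"``.

    Stable across processes and Python versions (unlike ``hash``), so a
    stage re-run in isolation reproduces the in-pipeline stream.
    """
    return zlib.crc32(f"{global_seed}:{stage}".encode()) & MAX_SEED


def adjust_pvalues(p: np.ndarray, method: str = "bh") -> np.ndarray:
    """Multiple-testing adjustment; ``bh`` (Benjamini-Hochberg) or ``bonferroni``."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    key = {"bh": "fdr_bh", "bonferroni": "bonferroni"}[method]
    return multipletests(p, method=key)[1]


def check_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)
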