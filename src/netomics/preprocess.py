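"""Block-specific normalization and filtering.

All operations take and return pandas DataFrames with samples as rows
and features as columns, preserve sample IDs, and never reorder
samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

_BETA_EPS = 1e-6  # boundary clip before the logit


def beta_to_mvalue(beta: pd.DataFrame) -> pd.DataFrame:
    """Methylation beta values to M-values: M = log2(beta / (1 - beta)).

    Betas are clipped to [1e-6, 1 - 1e-6] before the logit so boundary
    values stay finite.
    """
    arr = np.asarray(beta, dtype=float)
    if np.nanmin(arr) < 0 or np.nanmax(arr) > 1:
        raise ValueError("beta values must lie in [0, 1]")
    clipped = np.clip(arr, _BETA_EPS, 1 - _BETA_EPS)
    m = np.log2(clipped / (1 - clipped))
    return pd.DataFrame(m, index=beta.index, columns=beta.columns)


def mvalue_to_beta(m: pd.DataFrame) -> pd.DataFrame:
    """Inverse of :func:`beta_to_mvalue` (up to the boundary clip)."""
    arr = np.asarray(m, dtype=float)
    beta = 2.0**arr / (1 + 2.0**arr)
    return pd.DataFrame(beta, index=m.index, columns=m.columns)


def filter_low_counts(counts: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Drop features whose median raw count across samples is below 1.

    Returns the filtered matrix (survivor order preserved) and the list
    of removed feature IDs.
    """
    arr = np.asarray(counts)
    if (arr < 0).any():
        raise ValueError("counts must be nonnegative")
    med = counts.median(axis=0)
    keep = med >= 1
    removed = list(counts.columns[~keep])
    return counts.loc[:, keep], removed


def median_ratio_normalize(counts: pd.DataFrame,
                           reference: pd.Series | None = None
                           ) -> tuple[pd.DataFrame, pd.Series]:
    """Median-of-ratios (DESeq2-style) library-size normalization.

    The reference is the per-feature geometric mean over samples,
    computed only on features with no zero count; each sample's size
    factor is the median over those reference features of
    count/reference, and the normalized matrix is count/size-factor.
    Passing a precomputed ``reference`` (feature -> value, e.g. learned
    on training samples) keeps the reference fixed across datasets.
    """
    arr = np.asarray(counts, dtype=float)
    if reference is None:
        positive = (arr > 0).all(axis=0)
        if not positive.any():
            raise ValueError("median-of-ratios needs at least one feature with "
                             "all-positive counts; none found")
        ref = np.exp(np.log(arr[:, positive]).mean(axis=0))  # geometric mean
        ref = pd.Series(ref, index=counts.columns[positive], name="reference")
    else:
        ref = reference
    ratios = counts[ref.index].to_numpy() / ref.to_numpy()
    size_factors = np.median(ratios, axis=1)
    sf = pd.Series(size_factors, index=counts.index, name="size_factor")
    normalized = counts.div(sf, axis=0)
    return normalized, sf


def variance_topk(X: pd.DataFrame, k: int) -> tuple[pd.DataFrame, list[str]]:
    """Keep the k features of largest sample variance (ties by input order)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k >= X.shape[1]:
        return X, list(X.columns)
    var = X.var(axis=0, ddof=1).to_numpy()
    # stable sort on -variance keeps input order among ties
    order = np.argsort(-var, kind="stable")[:k]
    keep_idx = np.sort(order)  # survivors in input order
    kept = list(X.columns[keep_idx])
    return X.iloc[:, keep_idx], kept


def log2_median_center(intensities: pd.DataFrame) -> pd.DataFrame:
    """log2 transform then per-sample median centering (proteomics)."""
    arr = np.asarray(intensities, dtype=float)
    if (arr <= 0).any():
        raise ValueError("intensities must be strictly positive")
    logged = np.log2(arr)
    centered = logged - np.median(logged, axis=1, keepdims=True)
    return pd.DataFrame(centered, index=intensities.index, columns=intensities.columns)


@dataclass
class ScalerState:
    """Per-feature mean/sd learned on training samples only."""

    mean: pd.Series
    sd: pd.Series
    zero_variance: list[str]


def zscore_fit(train: pd.DataFrame) -> ScalerState:
    mean = train.mean(axis=0)
    sd = train.std(axis=0, ddof=0)
    zero_var = list(train.columns[sd == 0])
    return ScalerState(mean=mean, sd=sd, zero_variance=zero_var)


def zscore_apply(state: ScalerState, X: pd.DataFrame) -> pd.DataFrame:
    """Standardize with training statistics; zero-variance features map to 0."""
    if not X.columns.equals(state.mean.index):
        raise ValueError("feature set/order differs from the fitted scaler")
    sd = state.sd.replace(0.0, 1.0)
    out = (X - state.mean) / sd
    if state.zero_variance:
        out[state.zero_variance] = 0.0
    return out
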