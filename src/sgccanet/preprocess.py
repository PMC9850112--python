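"""Retained data-preparation steps before the multi-block fit.

CpG methylation arrives as beta values in [0, 1] with missing entries; it is
filtered by missingness, imputed from nearest sample neighbours, and moved to
the M-value scale log2(b/(1-b)) where Gaussian-model methods behave better.
Every block is finally rescaled by the square root of its leading covariance
eigenvalue so that no omic dominates the joint fit merely through scale: after
scaling, the first eigenvalue of each block's covariance is 1, and a block's
influence on the fit depends on how its variance is spread, not on its units.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .blocks import OmicsBlock
from .exceptions import DegenerateDataError, ImputationError, ValidationError

logger = logging.getLogger(__name__)


def filter_missing_features(block: OmicsBlock, max_missing_fraction: float = 0.25) -> OmicsBlock:
    """Drop features whose missing fraction is strictly greater than the threshold.

    The boundary is exclusive: a feature missing in exactly
    ``max_missing_fraction`` of samples is retained.
    """
    if not 0 <= max_missing_fraction < 1:
        raise ValidationError("max_missing_fraction must be in [0, 1)")
    frac = block.data.isna().mean(axis=0)
    keep = frac.index[(frac <= max_missing_fraction).to_numpy()]
    if len(keep) == 0:
        raise DegenerateDataError("all features removed by missingness filter")
    return OmicsBlock(block.data.loc[:, keep], block.omic_type)


def knn_impute(block: OmicsBlock, k: int = 10) -> OmicsBlock:
    """Replace each missing cell by the mean of the feature in the k nearest samples.

    Neighbours are samples; distance is plain Euclidean over the features
    observed in both samples.  Only samples observing the feature are
    candidate neighbours, and all imputations are computed from the original
    observed entries (no sequential fill-in).
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    X = block.values
    if not np.isnan(X).any():
        return block
    n = X.shape[0]
    obs = ~np.isnan(X)
    if (~obs).all(axis=1).any():
        raise ImputationError("a sample has all features missing")
    out = X.copy()
    # pairwise squared distances over co-observed features
    for i in range(n):
        miss_i = np.where(~obs[i])[0]
        if miss_i.size == 0:
            continue
        d2 = np.full(n, np.inf)
        for j in range(n):
            if j == i:
                continue
            both = obs[i] & obs[j]
            if not both.any():
                continue
            diff = X[i, both] - X[j, both]
            d2[j] = float(diff @ diff)
        for f in miss_i:
            cand = np.where(obs[:, f] & np.isfinite(d2))[0]
            if cand.size == 0:
                raise ImputationError(
                    f"no neighbour with co-observed features observes feature index {f}"
                )
            order = cand[np.argsort(d2[cand], kind="stable")]
            nearest = order[:k]
            out[i, f] = X[nearest, f].mean()
    return OmicsBlock(pd.DataFrame(out, index=block.data.index, columns=block.data.columns),
                      block.omic_type)


def beta_to_mvalue(beta_block: OmicsBlock, eps: float = 1e-6) -> OmicsBlock:
    """M = log2(b / (1 - b)) after clamping b into [eps, 1 - eps]."""
    if not 0 < eps < 0.5:
        raise ValidationError("eps must be in (0, 0.5)")
    B = beta_block.values
    finite = B[~np.isnan(B)]
    if finite.size and (finite.min() < 0 or finite.max() > 1):
        raise ValidationError("beta values must lie in [0, 1]")
    Bc = np.clip(B, eps, 1 - eps)
    M = np.log2(Bc / (1 - Bc))
    return OmicsBlock(pd.DataFrame(M, index=beta_block.data.index, columns=beta_block.data.columns),
                      beta_block.omic_type)


def first_eigenvalue(block: OmicsBlock) -> float:
    """Largest eigenvalue of the column-centered block's sample covariance (1/(n-1))."""
    X = block.values
    if np.isnan(X).any():
        raise ValidationError("block has missing values; impute first")
    Xc = X - X.mean(axis=0)
    s = np.linalg.svd(Xc, compute_uv=False)
    n = X.shape[0]
    return float(s[0] ** 2 / (n - 1))


def scale_block_by_first_eigenvalue(block: OmicsBlock) -> OmicsBlock:
    """Divide the block by sqrt(lambda_1) of its covariance so lambda_1 becomes 1."""
    lam1 = first_eigenvalue(block)
    if lam1 <= 1e-12:
        raise DegenerateDataError("zero-variance block cannot be eigenvalue-scaled")
    return OmicsBlock(block.data / np.sqrt(lam1), block.omic_type)
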