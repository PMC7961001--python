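"""Two-stage RNA-seq normalization.

Stage one removes sequencing-depth differences with the median-of-ratios
size factor estimator: each sample's factor is the median, over genes with
strictly positive counts in every sample, of the ratio of that sample's
count to the gene's geometric mean across samples. Stage two rescales each
sample so that its mean expression over all genes equals a common target
(1000 by default), putting samples from different cohorts on one scale.

No log transform is applied anywhere; all downstream survival and
enrichment work consumes the linear mean-rescaled matrix.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import CountMatrix, ExpressionMatrix
from .errors import EstimationError

__all__ = [
    "compute_size_factors",
    "apply_size_factors",
    "rescale_sample_means",
    "normalize",
]

DEFAULT_TARGET_MEAN = 1000.0


def compute_size_factors(counts: CountMatrix) -> pd.Series:
    """Median-of-ratios size factors, one per sample.

    Reference genes are those with strictly positive counts in all samples;
    the per-gene pseudo-reference is the geometric mean across samples.
    The median uses the midpoint of the two central values for even counts.

    Raises
    ------
    EstimationError
        If no gene is positive in every sample.
    """
    values = counts.data.to_numpy(dtype=float)
    reference = (values > 0).all(axis=1)
    if not reference.any():
        n_with_zero = int((values == 0).any(axis=1).sum())
        raise EstimationError(
            "no gene is positive in all samples; "
            f"{n_with_zero} of {values.shape[0]} genes contain zeros"
        )
    ref = values[reference]
    log_geomean = np.log(ref).mean(axis=1)
    ratios = np.log(ref) - log_geomean[:, None]
    factors = np.exp(np.median(ratios, axis=0))
    return pd.Series(factors, index=counts.data.columns, name="size_factor")


def apply_size_factors(counts: CountMatrix, size_factors: pd.Series) -> ExpressionMatrix:
    """Divide each sample column by its size factor."""
    missing = [s for s in counts.data.columns if s not in size_factors.index]
    if missing:
        raise EstimationError(f"no size factor for samples {missing[:5]}")
    sf = size_factors.reindex(counts.data.columns)
    if (sf <= 0).any() or sf.isna().any():
        raise EstimationError("size factors must be positive")
    normalized = counts.data.astype(float).div(sf, axis=1)
    return ExpressionMatrix(normalized, stage="size_factor_normalized")


def rescale_sample_means(
    expr: ExpressionMatrix, target: float = DEFAULT_TARGET_MEAN
) -> ExpressionMatrix:
    """Scale every sample so its mean over all genes (zeros included) is ``target``."""
    if target <= 0:
        raise ValueError("target mean must be positive")
    means = expr.data.mean(axis=0)
    zero = means[means <= 0]
    if len(zero):
        raise EstimationError(f"zero-mean samples: {list(zero.index)[:5]}")
    rescaled = expr.data.mul(target / means, axis=1)
    return ExpressionMatrix(rescaled, stage="mean_rescaled")


def normalize(counts: CountMatrix, target: float = DEFAULT_TARGET_MEAN):
    """Run both normalization stages; returns (expression, size_factors)."""
    sf = compute_size_factors(counts)
    expr = rescale_sample_means(apply_size_factors(counts, sf), target)
    return expr, sf
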