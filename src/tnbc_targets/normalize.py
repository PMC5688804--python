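"""Transforms applied before any statistics.

Expression counts are made comparable across samples by upper-quartile
scaling and moved to the log2(x+1) scale the mixture classifier and the
moderated-t engine operate on. Methylation beta fractions are quantile
normalized across samples and logit transformed into M-values,
M = log2(beta / (1 - beta)), the scale used for differential testing.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, TableFormatError

#: Clipping bound applied to beta values before the logit transform.
BETA_EPS = 1e-3


def upper_quartile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Scale each sample by the 75th percentile of its nonzero counts.

    The quartile uses the nearest-rank rule (index ``ceil(0.75 * n)`` of the
    ascending sort of the nonzero values). Every sample is divided by its own
    quartile and multiplied by the across-sample mean quartile, so after
    normalization the 75th nonzero percentile is equal across samples and
    the operation is idempotent up to floating tolerance.
    """
    if matrix.unit not in ("counts", "uq_normalized"):
        raise TableFormatError(f"upper-quartile normalization expects counts, got {matrix.unit!r}")
    values = matrix.data.to_numpy(dtype=float)
    quartiles = np.empty(values.shape[1])
    for j, sample in enumerate(matrix.samples):
        nonzero = np.sort(values[:, j][values[:, j] > 0])
        if nonzero.size == 0:
            raise TableFormatError(f"sample {sample!r} has no nonzero counts")
        quartiles[j] = nonzero[int(np.ceil(0.75 * nonzero.size)) - 1]
    scaled = values / quartiles * quartiles.mean()
    return ExpressionMatrix(
        pd.DataFrame(scaled, index=matrix.genes, columns=matrix.samples), unit="uq_normalized"
    )


def log2p1(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Elementwise log2(x + 1); maps counts/normalized values monotonically."""
    if matrix.unit not in ("counts", "uq_normalized"):
        raise TableFormatError(f"log2p1 expects counts or uq_normalized, got {matrix.unit!r}")
    return ExpressionMatrix(np.log2(matrix.data + 1.0), unit="log2p1_uq")


def beta_to_m(beta):
    """Logit transform: M = log2(beta / (1 - beta)).

    Beta values are clipped into [BETA_EPS, 1 - BETA_EPS] first so boundary
    fractions never produce infinite M. Accepts scalars, arrays, Series or
    DataFrames and preserves the container type.
    """
    clipped = np.clip(beta, BETA_EPS, 1.0 - BETA_EPS)
    return np.log2(clipped / (1.0 - clipped))


def m_to_beta(m):
    """Inverse logit: beta = 2^M / (1 + 2^M), mapping all of R into (0, 1)."""
    return 1.0 / (1.0 + np.exp2(np.negative(m)))


def quantile_normalize(frame: pd.DataFrame) -> pd.DataFrame:
    """Force every sample (column) onto the mean-order-statistic distribution.

    Each column is replaced by the across-sample mean of order statistics at
    its ranks; ties within a column receive the mean of the reference values
    they span, so tied inputs stay tied.
    """
    values = frame.to_numpy(dtype=float)
    n, k = values.shape
    order = np.argsort(values, axis=0, kind="mergesort")
    sorted_values = np.take_along_axis(values, order, axis=0)
    reference = sorted_values.mean(axis=1)
    out = np.empty_like(values)
    for j in range(k):
        ranks = np.empty(n, dtype=np.int64)
        ranks[order[:, j]] = np.arange(n)
        col = reference[ranks]
        # average the reference values spanned by each tie group
        uniq, inverse = np.unique(values[:, j], return_inverse=True)
        if uniq.size < n:
            sums = np.bincount(inverse, weights=col, minlength=uniq.size)
            counts = np.bincount(inverse, minlength=uniq.size)
            col = (sums / counts)[inverse]
        out[:, j] = col
    return pd.DataFrame(out, index=frame.index, columns=frame.columns)
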