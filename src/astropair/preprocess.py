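"""Expression matrix construction: log-CPM, low-expression filter,
cyclic loess normalization, and row z-scoring.

Matrices are pandas DataFrames with genes as rows and samples as columns.
Raw count matrices hold non-negative integers; log matrices hold log2 units.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from statsmodels.nonparametric.smoothers_lowess import lowess


def log_cpm(counts: pd.DataFrame, offset: float = 0.5) -> pd.DataFrame:
    """log2 counts-per-million with a pseudo-count offset.

    value = log2((count + offset) / (library_size + 2*offset) * 1e6)

    The doubled offset in the denominator keeps the transform scale-invariant
    to library depth and bounded away from -inf at zero counts.
    """
    lib = counts.sum(axis=0)
    zero = lib[lib <= 0]
    if len(zero):
        raise ValueError(f"zero library size for sample(s): {list(zero.index)}")
    return np.log2((counts + offset) / (lib + 2.0 * offset) * 1e6)


def filter_low_expression(counts: pd.DataFrame, min_cpm: float = 1.0,
                          max_fraction: float = 0.5) -> pd.DataFrame:
    """Drop unexpressed and lowly expressed genes.

    Genes with zero total reads are removed, then genes whose CPM falls
    below ``min_cpm`` in strictly more than ``max_fraction`` of samples.
    Gene order is preserved; the operation is idempotent.
    """
    counts = counts.loc[counts.sum(axis=1) > 0]
    lib = counts.sum(axis=0)
    cpm = counts / lib * 1e6
    low_frac = (cpm < min_cpm).mean(axis=1)
    kept = counts.loc[low_frac <= max_fraction]
    if kept.empty:
        warnings.warn("no genes left after low-expression filtering")
    return kept


def cyclic_loess_normalize(
    logexpr: pd.DataFrame,
    span: float = 0.7,
    n_cycles: int = 3,
    delta_frac: float = 0.01,
) -> pd.DataFrame:
    """Cyclic loess normalization of a genes x samples log2 matrix.

    For every unordered sample pair (visited in fixed column order), a loess
    smooth of M = x_i - x_j against A = (x_i + x_j)/2 is fit and half the
    trend is subtracted from sample i and added to sample j, leaving each
    pair's A values untouched. The full sweep is repeated ``n_cycles`` times.

    ``delta_frac`` sets the lowess interpolation granularity as a fraction of
    the A range (speed/accuracy trade-off of the smoother).
    """
    if logexpr.shape[1] < 2:
        warnings.warn("fewer than 2 samples; cyclic loess is the identity")
        return logexpr.copy()
    X = logexpr.to_numpy(dtype=float).copy()
    n = X.shape[1]
    for _ in range(n_cycles):
        for i, j in itertools.combinations(range(n), 2):
            A = 0.5 * (X[:, i] + X[:, j])
            M = X[:, i] - X[:, j]
            delta = delta_frac * (A.max() - A.min())
            trend = lowess(M, A, frac=span, it=0, delta=delta,
                           return_sorted=False)
            X[:, i] -= trend / 2.0
            X[:, j] += trend / 2.0
    return pd.DataFrame(X, index=logexpr.index, columns=logexpr.columns)


def zscore_rows(logexpr: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Row-wise z-scores (sample sd, n-1 denominator) for heatmap display.

    Returns the scaled matrix and a boolean Series flagging constant rows,
    which are mapped to all-zero.
    """
    if logexpr.shape[1] < 2:
        raise ValueError("z-scoring requires at least 2 samples")
    mu = logexpr.mean(axis=1)
    sd = logexpr.std(axis=1, ddof=1)
    constant = sd == 0
    safe_sd = sd.mask(constant, 1.0)
    z = logexpr.sub(mu, axis=0).div(safe_sd, axis=0)
    z.loc[constant] = 0.0
    return z, constant.rename("constant")


class LogCPM(TransformerMixin, BaseEstimator):
    """Transformer wrapper around :func:`log_cpm` (stateless)."""

    def __init__(self, offset: float = 0.5):
        self.offset = offset

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        return log_cpm(X, offset=self.offset)


class LowExpressionFilter(TransformerMixin, BaseEstimator):
    """Transformer that learns the kept-gene index on fit and reapplies it."""

    def __init__(self, min_cpm: float = 1.0, max_fraction: float = 0.5):
        self.min_cpm = min_cpm
        self.max_fraction = max_fraction

    def fit(self, X, y=None):
        self.kept_genes_ = filter_low_expression(
            X, min_cpm=self.min_cpm, max_fraction=self.max_fraction
        ).index
        return self

    def transform(self, X):
        return X.loc[self.kept_genes_]


class CyclicLoessNormalizer(TransformerMixin, BaseEstimator):
    """Transformer wrapper around :func:`cyclic_loess_normalize`."""

    def __init__(self, span: float = 0.7, n_cycles: int = 3):
        self.span = span
        self.n_cycles = n_cycles

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        return cyclic_loess_normalize(X, span=self.span, n_cycles=self.n_cycles)
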