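"""Deterministic feature encodings and transforms for the molecular layers.

Covers the three transforms used upstream of model building: dummy coding of
SNP genotypes into dominant/recessive indicator pairs, the M-value transform
of methylation beta values, and median-of-ratios normalization of sequencing
counts followed by a log transform.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

__all__ = [
    "snp_dummy_code",
    "beta_to_mvalue",
    "mvalue_to_beta",
    "normalize_counts_log",
    "size_factors",
    "filter_features",
]

logger = logging.getLogger(__name__)

_MVALUE_EPS = 1e-6


def snp_dummy_code(genotypes: pd.DataFrame) -> pd.DataFrame:
    """Expand minor-allele counts into two indicator columns per SNP.

    Genotype 0 maps to (0, 1), genotype 1 to (1, 0) and genotype 2 to (1, 1),
    so that shrunken coefficients on the pair read as 'no/small' dominant and
    'no/small' recessive effects.  Column ids get suffixes ``.d`` and ``.r``.

    Note the homozygous-reference genotype maps to (0, 1), not (0, 0); this
    follows the coding convention stated with the method and differs from
    some common dominant/recessive codings.
    """
    values = genotypes.to_numpy()
    valid = np.isin(values, (0, 1, 2))
    if not valid.all():
        i, j = np.argwhere(~valid)[0]
        raise ValueError(
            f"invalid genotype {values[i, j]!r} at sample "
            f"{genotypes.index[i]!r}, SNP {genotypes.columns[j]!r}; expected 0/1/2"
        )
    values = values.astype(int)
    n, k = values.shape
    out = np.empty((n, 2 * k), dtype=float)
    out[:, 0::2] = (values >= 1).astype(float)  # dominant: carries >= 1 minor allele
    out[:, 1::2] = (values != 1).astype(float)  # recessive-side indicator
    cols = np.empty(2 * k, dtype=object)
    cols[0::2] = [f"{c}.d" for c in genotypes.columns]
    cols[1::2] = [f"{c}.r" for c in genotypes.columns]
    return pd.DataFrame(out, index=genotypes.index, columns=list(cols))


def beta_to_mvalue(beta, eps: float = _MVALUE_EPS):
    """M-value transform of methylation beta values: log2(beta / (1 - beta)).

    Beta values at or beyond the open interval (0, 1) are clamped to
    [eps, 1 - eps] (logged), since the transform diverges at the boundary.
    """
    arr = np.asarray(beta, dtype=float)
    if ((arr < 0) | (arr > 1)).any():
        raise ValueError("beta values must lie in [0, 1]")
    n_clamped = int(((arr < eps) | (arr > 1 - eps)).sum())
    if n_clamped:
        logger.info("clamped %d beta values to [%g, %g]", n_clamped, eps, 1 - eps)
    clamped = np.clip(arr, eps, 1 - eps)
    m = np.log2(clamped / (1 - clamped))
    if isinstance(beta, pd.DataFrame):
        return pd.DataFrame(m, index=beta.index, columns=beta.columns)
    if isinstance(beta, pd.Series):
        return pd.Series(m, index=beta.index)
    return m if m.ndim else float(m)


def mvalue_to_beta(m):
    """Inverse of :func:`beta_to_mvalue`: beta = 2^M / (2^M + 1)."""
    arr = np.asarray(m, dtype=float)
    beta = 1.0 / (1.0 + 2.0 ** (-arr))
    return beta if beta.ndim else float(beta)


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factor per sample.

    The reference profile is the geometric mean across samples of each
    feature that is positive in every sample; a sample's size factor is the
    median over those features of count / reference.
    """
    values = counts.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("counts must be non-negative")
    positive = (values > 0).all(axis=0)
    if not positive.any():
        raise ValueError("no feature with positive counts in every sample")
    sub = values[:, positive]
    log_ref = np.log(sub).mean(axis=0)
    sf = np.exp(np.median(np.log(sub) - log_ref, axis=1))
    return pd.Series(sf, index=counts.index, name="size_factor")


def normalize_counts_log(counts: pd.DataFrame) -> pd.DataFrame:
    """Median-of-ratios normalization followed by log(x + 1).

    Integer-valued count matrix in, real design matrix out; each sample's
    counts are divided by its size factor before the log transform.
    """
    sf = size_factors(counts)
    normalized = counts.to_numpy(dtype=float) / sf.to_numpy()[:, None]
    return pd.DataFrame(np.log1p(normalized), index=counts.index, columns=counts.columns)


def filter_features(
    df: pd.DataFrame, min_variance: float = 0.0, max_missing: float = 0.0
) -> pd.DataFrame:
    """Generic feature filter: drop columns with too many missing values,
    then columns whose variance (over non-missing entries) is too small."""
    missing_frac = df.isna().mean(axis=0)
    kept = df.loc[:, missing_frac <= max_missing]
    if min_variance > 0:
        variances = kept.var(axis=0, ddof=0)
        kept = kept.loc[:, variances > min_variance]
    return kept
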