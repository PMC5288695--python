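"""Expression normalisation and transforms.

FPKM here uses the full contig length and raw library size (column sum of
counts): after de novo assembly no fragment-length model is available,
and only relative profiles feed the downstream categorisation and
clustering stages.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def fpkm(
    counts: pd.DataFrame,
    lengths: pd.Series,
    library_sizes: pd.Series | None = None,
) -> pd.DataFrame:
    """Fragments per kilobase of transcript per million mapped reads.

    value = 1e9 * count / (length_bp * library_size).  Library sizes
    default to the per-sample count totals.
    """
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = lengths.index[lengths.isna()].tolist()[:5]
        raise ValueError(f"missing lengths for contigs: {missing}")
    if (lengths <= 0).any():
        raise ValueError("contig lengths must be positive")
    if library_sizes is None:
        library_sizes = counts.sum(axis=0)
    else:
        library_sizes = library_sizes.reindex(counts.columns)
    if (library_sizes <= 0).any():
        raise ValueError("library sizes must be positive")
    out = counts.astype(float).div(lengths, axis=0).div(library_sizes, axis=1) * 1e9
    return out


def log2_median_center(matrix: pd.DataFrame, pseudo: float = 1.0) -> pd.DataFrame:
    """log2(value + pseudo), centred so every row's median is exactly 0."""
    if pseudo <= 0:
        raise ValueError("pseudo-count must be > 0")
    logged = np.log2(matrix + pseudo)
    return logged.sub(logged.median(axis=1), axis=0)


def tmm_factors(
    counts: pd.DataFrame,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> pd.Series:
    """Trimmed-mean-of-M-values normalisation factors.

    The reference sample is the one whose upper-quartile (of non-zero
    CPM) is closest to the mean upper-quartile.  For every other sample,
    genes expressed in both are ranked by M (log-ratio vs reference) and
    A (average log abundance); the most extreme ``trim_m`` of M values
    and ``trim_a`` of A values are dropped on each side, and the factor is
    2 to the precision-weighted mean of the remaining M values.  Factors
    are rescaled to have product 1, so they carry composition only —
    library size is handled separately.
    """
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least two samples")
    lib = counts.sum(axis=0).astype(float)
    if (lib == 0).any():
        raise ValueError("a sample has zero total counts")
    mat = counts.to_numpy(dtype=float)
    n_samples = mat.shape[1]

    # reference: upper quartile of non-zero relative abundances
    uq = np.empty(n_samples)
    for j in range(n_samples):
        nz = mat[mat[:, j] > 0, j] / lib.iloc[j]
        uq[j] = np.quantile(nz, 0.75) if nz.size else 0.0
    ref = int(np.argmin(np.abs(uq - uq.mean())))

    log_factors = np.zeros(n_samples)
    for j in range(n_samples):
        if j == ref:
            continue
        log_factors[j] = _tmm_pair(
            mat[:, j], mat[:, ref], lib.iloc[j], lib.iloc[ref], trim_m, trim_a
        )
    factors = 2.0 ** log_factors
    factors /= np.exp(np.mean(np.log(factors)))  # geometric mean 1 => product 1
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    trim_m: float,
    trim_a: float,
) -> float:
    keep = (obs > 0) & (ref > 0)
    if keep.sum() < 1:
        return 0.0
    p_obs = obs[keep] / lib_obs
    p_ref = ref[keep] / lib_ref
    m = np.log2(p_obs / p_ref)
    a = 0.5 * np.log2(p_obs * p_ref)
    # asymptotic variance of M from binomial sampling (delta method)
    w = (lib_obs - obs[keep]) / (lib_obs * obs[keep]) + (lib_ref - ref[keep]) / (
        lib_ref * ref[keep]
    )
    n = m.size
    lo_m, hi_m = np.floor(n * trim_m) + 1, n - np.floor(n * trim_m)
    lo_a, hi_a = np.floor(n * trim_a) + 1, n - np.floor(n * trim_a)
    rank_m = _rank(m)
    rank_a = _rank(a)
    keep2 = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep2.any() or w[keep2].sum() == 0:
        return 0.0
    return float(np.sum(m[keep2] / w[keep2]) / np.sum(1.0 / w[keep2]))


def _rank(x: np.ndarray) -> np.ndarray:
    order = np.argsort(x, kind="stable")
    ranks = np.empty_like(order, dtype=float)
    ranks[order] = np.arange(1, x.size + 1)
    return ranks


def cpm(counts: pd.DataFrame, library_sizes: pd.Series | None = None) -> pd.DataFrame:
    """Counts per million mapped reads."""
    if library_sizes is None:
        library_sizes = counts.sum(axis=0)
    else:
        library_sizes = library_sizes.reindex(counts.columns)
    if (library_sizes <= 0).any():
        raise ValueError("library sizes must be positive")
    return counts.astype(float).div(library_sizes, axis=1) * 1e6
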