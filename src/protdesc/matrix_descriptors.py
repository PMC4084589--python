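"""Fixed-length descriptors computed from an N x 20 profile matrix (PSSM or
SMR) or, for the spectral ones, from any rectangular protein matrix.

Seven descriptors: average blocks (AB, 400), single average (SA/SAN, 400),
autocovariance matrix (AM, 300), pseudo-PSSM (PP, 320), singular values
(SVD), 2-D discrete cosine transform (DCT, 400) and profile n-grams
(BGR 400 / TGR 8000).
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.fft import dctn as _dctn
from scipy.special import expit as _sigmoid

from .core import DescriptorVector, ProfileMatrix, ProteinRecord

#: maximum lag for the autocovariance and pseudo-PSSM descriptors
LAG_MAX = 15


def _mat(mat: ProfileMatrix | np.ndarray) -> np.ndarray:
    if isinstance(mat, ProfileMatrix):
        return mat.values
    return np.asarray(mat, dtype=float)


def average_blocks(mat: ProfileMatrix | np.ndarray) -> DescriptorVector:
    """Local averages of 20 consecutive row blocks (each about 5% of the
    sequence) per column; block boundaries at round(z*N/20)."""
    m = _mat(mat)
    n = m.shape[0]
    if n < 20:
        raise ValueError(f"average_blocks: needs N >= 20 rows, got {n}")
    bounds = np.round(np.arange(21) * n / 20).astype(int)
    out = np.vstack([m[lo:hi].mean(axis=0)
                     for lo, hi in zip(bounds[:-1], bounds[1:])])
    return DescriptorVector(out.ravel(), "AB", 400)


def single_average(mat: ProfileMatrix | np.ndarray,
                   record: ProteinRecord, *,
                   normalize: bool = False) -> DescriptorVector:
    """Per-amino-acid row averages: SA(z,j) is the mean of Mat(i,j) over
    the positions i whose residue is the z-th amino acid; rows for absent
    amino acids are zero.  With ``normalize=True`` an elementwise sigmoid
    is applied to Mat first (the SAN variant)."""
    m = _mat(mat)
    idx = record.indices()
    if m.shape[0] != idx.size:
        raise ValueError(f"single_average: matrix has {m.shape[0]} rows but "
                         f"sequence has {idx.size} canonical residues")
    if normalize:
        m = _sigmoid(m)
    out = np.zeros((20, 20))
    for z in range(20):
        rows = m[idx == z]
        if rows.size:
            out[z] = rows.mean(axis=0)
    return DescriptorVector(out.ravel(), "SAN" if normalize else "SA", 400)


def autocovariance_matrix(mat: ProfileMatrix | np.ndarray,
                          lag_max: int = LAG_MAX) -> DescriptorVector:
    """Column-wise autocovariance at lags 1..15 with the column mean
    subtracted: AM(lag,j) = (1/(N-lag)) * sum_i dev(i,j)*dev(i+lag,j)."""
    m = _mat(mat)
    n = m.shape[0]
    if n <= lag_max:
        raise ValueError(f"autocovariance_matrix: needs N > {lag_max}, "
                         f"got {n}")
    dev = m - m.mean(axis=0, keepdims=True)
    out = np.empty((lag_max, m.shape[1]))
    for lag in range(1, lag_max + 1):
        out[lag - 1] = (dev[:n - lag] * dev[lag:]).sum(axis=0) / (n - lag)
    return DescriptorVector(out.ravel(), "AM", lag_max * m.shape[1])


def row_standardize(m: np.ndarray, *,
                    strict_printed_formula: bool = False) -> np.ndarray:
    """Row-wise standardization used by the pseudo-PSSM descriptor.

    Each row is centred by its mean and divided by its root-mean-square
    deviation (a z-score).  ``strict_printed_formula=True`` divides by the
    mean squared deviation instead (no square root).  Zero-variance rows
    map to zero rows with a warning.
    """
    m = np.asarray(m, dtype=float)
    centered = m - m.mean(axis=1, keepdims=True)
    var = (centered ** 2).mean(axis=1, keepdims=True)
    denom = var if strict_printed_formula else np.sqrt(var)
    zero = denom[:, 0] == 0
    if zero.any():
        warnings.warn(f"{zero.sum()} constant rows mapped to zero during "
                      "row standardization")
    with np.errstate(invalid="ignore", divide="ignore"):
        e = np.where(denom == 0, 0.0, centered / np.where(denom == 0, 1.0,
                                                          denom))
    return e


def pseudo_pssm(mat: ProfileMatrix | np.ndarray, lag_max: int = LAG_MAX, *,
                strict_printed_formula: bool = False) -> DescriptorVector:
    """Pseudo-PSSM: 20 column means of the row-standardized matrix E,
    followed by the mean squared lag-differences
    (1/(N-lag)) * sum_i [E(i,j)-E(i+lag,j)]^2 for lags 1..15 (320 values).
    """
    m = _mat(mat)
    n = m.shape[0]
    if n <= lag_max:
        raise ValueError(f"pseudo_pssm: needs N > {lag_max}, got {n}")
    e = row_standardize(m, strict_printed_formula=strict_printed_formula)
    out = np.empty(20 + lag_max * 20)
    out[:20] = e.mean(axis=0)
    for lag in range(1, lag_max + 1):
        diff = e[:n - lag] - e[lag:]
        out[20 + (lag - 1) * 20:20 + lag * 20] = \
            (diff ** 2).sum(axis=0) / (n - lag)
    return DescriptorVector(out, "PP", 20 + lag_max * 20)


def svd_descriptor(mat: np.ndarray, pad_to: int | None = None
                   ) -> DescriptorVector:
    """Singular values in descending order, zero-padded to ``pad_to`` when
    a fixed length is needed for a classifier table."""
    m = _mat(mat)
    s = np.linalg.svd(m, compute_uv=False)
    if pad_to is not None:
        if len(s) > pad_to:
            s = s[:pad_to]
        else:
            s = np.pad(s, (0, pad_to - len(s)))
    return DescriptorVector(s, "SVD", len(s))


def dct_descriptor(mat: np.ndarray, keep: int = 20) -> DescriptorVector:
    """2-D orthonormal DCT-II; retain the top-left ``keep`` x ``keep``
    low-frequency block, row-major (400 coefficients by default).
    Matrices smaller than the block are zero-padded first."""
    m = _mat(mat)
    rows = max(m.shape[0], keep)
    cols = max(m.shape[1], keep)
    if (rows, cols) != m.shape:
        padded = np.zeros((rows, cols))
        padded[:m.shape[0], :m.shape[1]] = m
        m = padded
    coeff = _dctn(m, type=2, norm="ortho")
    return DescriptorVector(coeff[:keep, :keep].ravel(), "DCT", keep * keep)


def ngram_matrix(mat: ProfileMatrix | np.ndarray
                 ) -> tuple[DescriptorVector, DescriptorVector]:
    """Profile 2-gram and 3-gram accumulations:
    BGR(i,j) = sum_z Mat(z,i)*Mat(z+1,j) and
    TGR(i,j,k) = sum_z Mat(z,i)*Mat(z+1,j)*Mat(z+2,k),
    flattened with the row-major linear index."""
    m = _mat(mat)
    if m.shape[0] < 3:
        raise ValueError(f"ngram_matrix: needs N >= 3 rows, got {m.shape[0]}")
    bgr = m[:-1].T @ m[1:]
    tgr = np.einsum("zi,zj,zk->ijk", m[:-2], m[1:-1], m[2:])
    return (DescriptorVector(bgr.ravel(), "BGR", 400),
            DescriptorVector(tgr.ravel(), "TGR", 8000))
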