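"""Matrix representations of a protein.

Five representations feed the descriptor layer:

* **PSSM** — N x 20 position-specific scoring matrix, either parsed from a
  PSI-BLAST profile or built from a frequency-ratio matrix ``w`` against a
  substitution matrix ``Y`` as ``PSSM(i,j) = sum_k w(i,k) * Y(j,k)``.
* **SMR** — substitution-matrix representation: row ``i`` is the
  substitution-matrix row of residue ``p_i``.
* **PR** — property response matrix ``PRM(i,j) = index(p_i,d) +
  index(p_j,d)``, treated as a grayscale image and resized to 250 x 250
  when larger.
* **WAVE** — continuous Meyer-wavelet scalogram of the property-encoded
  sequence at scales 1..100.
* **DM** — Euclidean distance matrix of the C-alpha backbone.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pywt
from scipy.spatial.distance import pdist, squareform
from skimage.transform import resize as _sk_resize

from .core import (PhysicochemicalProperty, ProfileMatrix, ProteinRecord,
                   SubstitutionMatrix)

#: images larger than this (per side) are shrunk before texture extraction
MAX_IMAGE_SIDE = 250
#: number of continuous-wavelet decomposition scales
N_WAVE_SCALES = 100


@dataclass
class SquareProteinImage:
    """A square real matrix treated as a grayscale image (PR, DM, or a
    resized WAVE scalogram)."""

    values: np.ndarray
    source: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("image must be a 2-D matrix")

    @property
    def side(self) -> int:
        return self.values.shape[0]


@dataclass
class PropertyProfile:
    """The property-encoded numeric sequence ``PP(i) = index(p_i, d)``
    (distinct from the pseudo-PSSM descriptor)."""

    values: np.ndarray
    property_id: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


@dataclass
class Scalogram:
    """Continuous-wavelet coefficients, one row per scale 1..100."""

    values: np.ndarray
    scales: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[0] != len(self.scales):
            raise ValueError("one coefficient row per scale required")


def build_pssm_from_profile(w: np.ndarray,
                            y: SubstitutionMatrix) -> ProfileMatrix:
    """PSSM(i,j) = sum_k w(i,k) * Y(j,k) for a frequency-ratio matrix *w*."""
    w = np.asarray(w, dtype=float)
    if w.ndim != 2 or w.shape[1] != 20:
        raise ValueError(f"frequency matrix must be N x 20, got {w.shape}")
    return ProfileMatrix(values=w @ y.entries.T, source="pssm")


def build_smr(record: ProteinRecord, m: SubstitutionMatrix) -> ProfileMatrix:
    """Substitution-matrix representation: row i = M row of residue p_i."""
    idx = record.indices()
    if idx.size == 0:
        raise ValueError(f"record {record.id}: no canonical residues")
    return ProfileMatrix(values=m.entries[idx], source="smr",
                         residues=record.canonical_sequence)


def property_profile(record: ProteinRecord,
                     d: PhysicochemicalProperty) -> PropertyProfile:
    """Encode the sequence numerically by the property value of each
    canonical residue."""
    idx = record.indices()
    if idx.size == 0:
        raise ValueError(f"record {record.id}: no canonical residues")
    return PropertyProfile(values=d.vector()[idx], property_id=d.id)


def build_pr(record: ProteinRecord, d: PhysicochemicalProperty,
             max_side: int = MAX_IMAGE_SIDE) -> SquareProteinImage:
    """Property response matrix PRM(i,j) = index(p_i,d) + index(p_j,d),
    resized (bilinear, downward only) to ``max_side`` when larger."""
    pp = property_profile(record, d).values
    prm = pp[:, None] + pp[None, :]
    if prm.shape[0] > max_side:
        prm = _sk_resize(prm, (max_side, max_side), order=1,
                         anti_aliasing=False, preserve_range=True)
    return SquareProteinImage(values=prm, source="pr")


def build_dm(coords: np.ndarray) -> SquareProteinImage:
    """Euclidean distance matrix of an ordered C-alpha backbone."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3 or coords.shape[0] < 2:
        raise ValueError("need at least 2 three-dimensional coordinates")
    return SquareProteinImage(values=squareform(pdist(coords)), source="dm")


# -- continuous Meyer wavelet transform -------------------------------------

@lru_cache(maxsize=1)
def _meyer_integral(precision: int = 10) -> tuple[np.ndarray, float]:
    """Cumulative integral of the discrete-Meyer wavelet function, sampled
    on its support."""
    _, psi, x = pywt.Wavelet("dmey").wavefun(level=precision)
    step = x[1] - x[0]
    return np.cumsum(psi) * step, step


def meyer_cwt(signal: np.ndarray, scales: np.ndarray) -> np.ndarray:
    """Continuous wavelet transform with the Meyer wavelet.

    Uses the standard integrated-wavelet convolution algorithm: the
    coefficient at scale ``a`` is the derivative of the convolution of the
    signal with the resampled antiderivative of ``psi``, scaled by
    ``-sqrt(a)``.  Returns a (len(scales), len(signal)) array.
    """
    signal = np.asarray(signal, dtype=float)
    int_psi, step = _meyer_integral()
    support = (len(int_psi) - 1) * step
    out = np.empty((len(scales), len(signal)))
    for row, scale in enumerate(scales):
        j = (np.arange(scale * support + 1) / (scale * step)).astype(np.intp)
        j = j[j < len(int_psi)]
        kernel = int_psi[j][::-1]
        conv = np.convolve(signal, kernel)
        coef = -np.sqrt(scale) * np.diff(conv)
        lo = (len(coef) - len(signal)) // 2
        out[row] = coef[lo:lo + len(signal)]
    return out


def build_wave(record: ProteinRecord, d: PhysicochemicalProperty,
               n_scales: int = N_WAVE_SCALES) -> Scalogram:
    """Meyer continuous-wavelet scalogram of the property profile at
    scales 1..``n_scales``."""
    pp = property_profile(record, d).values
    if len(pp) < 2:
        raise ValueError("wavelet representation needs at least 2 residues")
    scales = np.arange(1, n_scales + 1)
    return Scalogram(values=meyer_cwt(pp, scales), scales=scales)


def wave_image(scalogram: Scalogram,
               max_width: int = MAX_IMAGE_SIDE) -> SquareProteinImage:
    """The scalogram as an image for matrix/texture descriptors, shrunk in
    width to ``max_width`` columns for long sequences (same rule as PR)."""
    vals = scalogram.values
    if vals.shape[1] > max_width:
        vals = _sk_resize(vals, (vals.shape[0], max_width), order=1,
                          anti_aliasing=False, preserve_range=True)
    return SquareProteinImage(values=vals, source="wave")
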