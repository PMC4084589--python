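"""Image-texture descriptors on protein matrices.

A protein matrix (distance matrix, property response matrix, scalogram or
profile) is min-max scaled to [0, 255] and treated as a grayscale image,
then summarized either globally or on three horizontal bands:

* **LBP-HF** — rotation-invariant features built from discrete Fourier
  transform magnitudes of uniform local-binary-pattern histogram orbits,
  concatenated for (P=16, R=2) and (P=8, R=1): 138 + 38 = 176 values.
* **LPQ** — local phase quantization: the sign-quantized short-term
  Fourier phase at four low frequencies, estimated with a
  Gaussian-derivative quadrature filter pair, as a normalized 256-bin
  histogram per window radius (3 and 5): 512 values.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from numpy.fft import fftshift, ifft, ifftshift
from skimage.feature import local_binary_pattern

from .core import DescriptorVector, ProfileMatrix
from .representations import SquareProteinImage

#: LBP parameterizations (neighbors P, radius R) in concatenation order
LBP_PARAMS: tuple[tuple[int, int], ...] = ((16, 2), (8, 1))
#: LPQ window radii in concatenation order
LPQ_RADII: tuple[int, ...] = (3, 5)


def to_grayscale(mat) -> np.ndarray:
    """Min-max scale a matrix to the [0, 255] intensity range.

    Constant matrices map to mid-gray (127.5)."""
    if isinstance(mat, (SquareProteinImage, ProfileMatrix)):
        mat = mat.values
    m = np.asarray(mat, dtype=float)
    lo, hi = m.min(), m.max()
    if hi == lo:
        return np.full_like(m, 127.5)
    return (m - lo) * (255.0 / (hi - lo))


def _pad_min_size(img: np.ndarray, min_side: int) -> np.ndarray:
    """Zero-pad an image so both sides reach ``min_side`` (narrow profile
    matrices fed to windowed operators)."""
    rows = max(img.shape[0], min_side)
    cols = max(img.shape[1], min_side)
    if (rows, cols) == img.shape:
        return img
    out = np.zeros((rows, cols))
    out[:img.shape[0], :img.shape[1]] = img
    return out


# ---------------------------------------------------------------------------
# LBP histogram Fourier

def _rotl(value: int, shift: int, bits: int) -> int:
    mask = (1 << bits) - 1
    return ((value << shift) | (value >> (bits - shift))) & mask


@lru_cache(maxsize=None)
def _uniform_orbits(p: int) -> tuple[tuple[int, ...], ...]:
    """For each number of set bits n=1..P-1, the P rotations of the
    contiguous n-bit uniform pattern."""
    orbits = []
    for n in range(1, p):
        base = (1 << n) - 1
        orbits.append(tuple(_rotl(base, r, p) for r in range(p)))
    return tuple(orbits)


def lbp_hf_single(img: np.ndarray, p: int, r: int) -> np.ndarray:
    """LBP-HF features for one (P, R) parameterization.

    The non-rotation-invariant LBP code histogram is grouped into the P
    rotational orbits of each uniform pattern class; per orbit the DFT
    magnitudes at frequencies 0..P/2 are kept (invariant to cyclic shifts,
    hence to image rotation), plus the all-zeros bin, the all-ones bin and
    the total non-uniform mass: (P-1)*(P/2+1) + 3 values.
    """
    if min(img.shape) < 2 * r + 1:
        raise ValueError(f"image {img.shape} too small for LBP radius {r}")
    import warnings
    with warnings.catch_warnings():
        # float input is intentional; thresholding noise is the caller's
        # concern (the public entry point quantizes to 8-bit first)
        warnings.filterwarnings("ignore", message=".*floating-point images.*")
        codes = local_binary_pattern(img, p, r,
                                     method="default").astype(np.intp)
    interior = codes[r:-r, r:-r]
    hist = np.bincount(interior.ravel(), minlength=2 ** p).astype(float)
    hist /= interior.size
    feats: list[float] = []
    uniform_mass = hist[0] + hist[-1]
    for orbit in _uniform_orbits(p):
        h = hist[list(orbit)]
        uniform_mass += h.sum()
        feats.extend(np.abs(np.fft.rfft(h)))
    feats.append(hist[0])
    feats.append(hist[-1])
    feats.append(max(0.0, 1.0 - uniform_mass))
    return np.array(feats)


def lbp_hf(img, params: tuple[tuple[int, int], ...] = LBP_PARAMS
           ) -> DescriptorVector:
    """Rotation-invariant LBP histogram-Fourier descriptor, concatenating
    the (16, 2) and (8, 1) parameterizations (138 + 38 = 176 values)."""
    gray = to_grayscale(img)
    gray = _pad_min_size(gray, 2 * max(r for _, r in params) + 1)
    # 8-bit quantization: LBP thresholds intensities, float noise would flip bits
    gray = np.round(gray).astype(np.uint8)
    feats = [lbp_hf_single(gray, p, r) for p, r in params]
    out = np.concatenate(feats)
    return DescriptorVector(out, "LHF", len(out))


# ---------------------------------------------------------------------------
# local phase quantization

@lru_cache(maxsize=None)
def _lpq_filters(radius: int) -> tuple[np.ndarray, np.ndarray]:
    """1-D LPQ filter pair for a window of side 2*radius+1, defined in the
    frequency domain: a Gaussian low-pass w0 and a one-sided
    Gaussian-derivative-shaped band-pass w1 (a quadrature pair in the
    spatial domain)."""
    win = 2 * radius + 1
    x = np.arange(-radius, radius + 1)
    u = np.arange(1, radius + 1)
    sigma = 8.0 / (win - 1)
    g0 = np.exp(-(x ** 2) * (np.sqrt(2) * sigma) ** 2)
    g1 = np.concatenate([np.zeros(radius), [0.0],
                         u * np.exp(-(u ** 2) * sigma ** 2)])
    w0 = np.real(fftshift(ifft(ifftshift(g0))))
    w1 = fftshift(ifft(ifftshift(g1)))
    w0 /= np.abs(w0).sum()
    w1 /= np.abs(w1).sum()
    return w0, w1


def _sep_conv(img: np.ndarray, row_f: np.ndarray,
              col_f: np.ndarray) -> np.ndarray:
    """Separable valid-mode 2-D convolution (column filter down the rows,
    row filter across the columns)."""
    tmp = np.apply_along_axis(lambda c: np.convolve(c, col_f, mode="valid"),
                              0, img.astype(complex))
    return np.apply_along_axis(lambda r: np.convolve(r, row_f, mode="valid"),
                               1, tmp)


def lpq_single(img: np.ndarray, radius: int) -> np.ndarray:
    """256-bin normalized LPQ histogram for one window radius.

    The short-term Fourier transform is evaluated at the four frequencies
    [a,0], [0,a], [a,a], [a,-a]; the signs of the 8 real/imaginary parts
    form a byte per pixel."""
    win = 2 * radius + 1
    if min(img.shape) < win:
        raise ValueError(f"image {img.shape} too small for LPQ radius "
                         f"{radius}")
    w0, w1 = _lpq_filters(radius)
    w2 = np.conj(w1)
    resp = [
        _sep_conv(img, w1, w0),   # frequency [a, 0]
        _sep_conv(img, w0, w1),   # frequency [0, a]
        _sep_conv(img, w1, w1),   # frequency [a, a]
        _sep_conv(img, w1, w2),   # frequency [a, -a]
    ]
    bits = np.zeros(resp[0].shape, dtype=np.intp)
    bit = 0
    for f in resp:
        for part in (f.real, f.imag):
            bits |= (part >= 0).astype(np.intp) << bit
            bit += 1
    hist = np.bincount(bits.ravel(), minlength=256).astype(float)
    return hist / hist.sum()


def lpq(img, radii: tuple[int, ...] = LPQ_RADII) -> DescriptorVector:
    """Blur-robust LPQ descriptor, concatenating the normalized histograms
    for window radii 3 and 5 (2 x 256 = 512 values)."""
    gray = to_grayscale(img)
    gray = _pad_min_size(gray, 2 * max(radii) + 1)
    feats = [lpq_single(gray, r) for r in radii]
    out = np.concatenate(feats)
    return DescriptorVector(out, "LPQ", len(out))


# ---------------------------------------------------------------------------
# local (three-band) evaluation

def local3(img, base_op) -> DescriptorVector:
    """Apply a global texture operator to three equal horizontal bands
    (remainder rows go to the last band) and concatenate top-to-bottom."""
    if isinstance(img, (SquareProteinImage, ProfileMatrix)):
        img = img.values
    img = np.asarray(img, dtype=float)
    n = img.shape[0]
    if n < 3:
        raise ValueError("image must have at least 3 rows for local "
                         "evaluation")
    step = n // 3
    bands = [img[:step], img[step:2 * step], img[2 * step:]]
    parts = [base_op(b) for b in bands]
    out = np.concatenate([np.asarray(p) for p in parts])
    return DescriptorVector(out, f"{parts[0].descriptor_id}_L", len(out))
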