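"""Fixed-length descriptors computed directly from the amino-acid sequence.

Ten descriptors: amino-acid composition (AAC, 20), 2-grams (400),
quasiresidue couple (QRC, 1200), autocovariance pseudo-composition (AC,
20+m), AAIndexLoc (65), global encoding (GE), physicochemical 2-grams
(P2G, 800), reduced-alphabet n-grams (NG), split amino-acid composition
(SAC, 60) and the discrete-wavelet descriptor (DW, 52).

All descriptors operate on the canonical residues of a record
(non-standard residues are excluded before counting); linear 20x20 cell
indices follow the row-major flattening of the alphabetical order.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pywt
from scipy.fft import dct as _dct
from sklearn.cluster import KMeans

from .core import (CANONICAL_ORDER, DescriptorVector, PhysicochemicalProperty,
                   ProteinRecord, property_stats)
from .representations import property_profile

#: the six physicochemical classes used by global encoding
GE_CLASSES = ("AVLIMC", "FWYH", "STNQ", "KR", "DE", "GP")

#: the five reduced alphabets for the n-gram descriptor, as group strings
NG_ALPHABETS: dict[str, tuple[str, ...]] = {
    "A1": tuple(CANONICAL_ORDER),
    "A2": ("LVIM", "C", "A", "G", "S", "T", "P", "FY", "W", "E", "D", "N",
           "Q", "KR", "H"),
    "A3": ("LVIMC", "AG", "ST", "P", "FYW", "EDNQ", "KR", "H"),
    "A4": ("LVIMC", "ASGTP", "FYW", "EDNQ", "KRH"),
    "A5": ("LVIMC", "ASGTP", "FYW", "EDNQKRH"),
}
#: n-gram order per alphabet (2-grams for A1/A2, 3-grams for A3/A4/A5)
NG_ORDER = {"A1": 2, "A2": 2, "A3": 3, "A4": 3, "A5": 3}


def _seq_indices(record: ProteinRecord, min_n: int, who: str) -> np.ndarray:
    idx = record.indices()
    if idx.size < min_n:
        raise ValueError(f"{who}: needs at least {min_n} canonical residues, "
                         f"got {idx.size}")
    return idx


def aac(record: ProteinRecord) -> DescriptorVector:
    """Amino-acid composition: fraction of each amino acid, AS(i)=h(i)/N."""
    idx = _seq_indices(record, 1, "aac")
    counts = np.bincount(idx, minlength=20).astype(float)
    return DescriptorVector(counts / idx.size, "AAC", 20)


def two_gram(record: ProteinRecord) -> DescriptorVector:
    """Adjacent-couple counts normalized by sequence length,
    2G(k)=h(i,j)/N at k=j+20(i-1)."""
    idx = _seq_indices(record, 2, "two_gram")
    grid = np.zeros((20, 20))
    np.add.at(grid, (idx[:-1], idx[1:]), 1.0)
    return DescriptorVector(grid.ravel() / idx.size, "2G", 400)


def qrc(record: ProteinRecord, d: PhysicochemicalProperty,
        orders: tuple[int, ...] = (1, 2, 3)) -> DescriptorVector:
    """Quasiresidue couple: for each order m, cell (i,j) accumulates
    index(i,d)+index(j,d) over the positions where residues i and j occur
    at distance m, normalized by N-m; the per-order 400-vectors are
    concatenated (1200 values for m=1..3)."""
    idx = _seq_indices(record, max(orders) + 1, "qrc")
    vals = d.vector()
    parts = []
    for m in orders:
        grid = np.zeros((20, 20))
        a, b = idx[:-m], idx[m:]
        np.add.at(grid, (a, b), vals[a] + vals[b])
        parts.append(grid.ravel() / (idx.size - m))
    return DescriptorVector(np.concatenate(parts), "QRC",
                            400 * len(orders), property_id=d.id)


def autocovariance(record: ProteinRecord, d: PhysicochemicalProperty,
                   m: int = 20, *, sqrt_sigma: bool = False
                   ) -> DescriptorVector:
    """Pseudo-amino-acid autocovariance: the 20 composition values followed
    by m sequence-order correlation factors at lags 1..m, normalized by the
    property dispersion (mean squared deviation by default; set
    ``sqrt_sigma`` for the standard-deviation variant)."""
    idx = _seq_indices(record, m + 1, "autocovariance")
    mu, sigma = property_stats(d, sqrt_sigma=sqrt_sigma)
    if sigma == 0:
        raise ValueError(f"property {d.id} is degenerate (zero dispersion)")
    centered = d.vector()[idx] - mu
    n = idx.size
    out = np.empty(20 + m)
    out[:20] = np.asarray(aac(record))
    for lag in range(1, m + 1):
        out[19 + lag] = (centered[:n - lag] * centered[lag:]).sum() \
            / (sigma * (n - lag))
    return DescriptorVector(out, "AC", 20 + m, property_id=d.id)


def _five_groups(d: PhysicochemicalProperty, seed: int = 0) -> np.ndarray:
    """K-means grouping of the 20 property values into 5 levels, relabelled
    by ascending group-minimum value."""
    vals = d.vector()
    if len(np.unique(vals)) < 5:
        raise ValueError(f"property {d.id}: fewer than 5 distinct values, "
                         "5-level grouping is degenerate")
    km = KMeans(n_clusters=5, n_init=100, random_state=seed)
    labels = km.fit_predict(vals.reshape(-1, 1))
    mins = [vals[labels == g].min() for g in range(5)]
    relabel = np.empty(5, dtype=np.intp)
    relabel[np.argsort(mins)] = np.arange(5)
    return relabel[labels]


def aaindexloc(record: ProteinRecord, d: PhysicochemicalProperty,
               seed: int = 0) -> DescriptorVector:
    """AAIndexLoc: amino-acid composition (20), property-weighted
    composition AS(i)*index(i,d) (20), and the 5x5 dipeptide composition
    over a five-level k-means grouping of the property values (25)."""
    idx = _seq_indices(record, 2, "aaindexloc")
    comp = np.asarray(aac(record))
    weighted = comp * d.vector()
    groups = _five_groups(d, seed=seed)
    g = groups[idx]
    pair = np.zeros((5, 5))
    np.add.at(pair, (g[:-1], g[1:]), 1.0)
    pair /= (idx.size - 1)
    return DescriptorVector(np.concatenate([comp, weighted, pair.ravel()]),
                            "AA", 65, property_id=d.id)


def ge_partitions() -> list[tuple[tuple[int, ...], tuple[int, ...]]]:
    """The 10 partitions of the six classes into two subsets of three.

    Canonical enumeration: the subset containing class 1 is paired with
    each 2-combination of the remaining five classes, in lexicographic
    order."""
    rest = range(1, 6)
    parts = []
    for pair in combinations(rest, 2):
        first = (0,) + pair
        second = tuple(sorted(set(range(6)) - set(first)))
        parts.append((first, second))
    return parts


def _segments(n: int, depth: int) -> list[tuple[int, int]]:
    """Nested-halves segmentation: level l contributes 2^(l-1) equal
    segments; depth 1 is the whole sequence."""
    segs = []
    for level in range(1, depth + 1):
        k = 2 ** (level - 1)
        bounds = np.linspace(0, n, k + 1).round().astype(int)
        segs.extend(zip(bounds[:-1], bounds[1:]))
    return segs


def global_encoding(record: ProteinRecord, depth: int = 1
                    ) -> DescriptorVector:
    """Global encoding over six physicochemical classes.

    For each of the 10 two-way partitions of the classes, the protein is
    re-encoded as a binary characteristic sequence (1 when the residue's
    class falls in the first subset) and four measures are emitted per
    segment: frequency of 0s, frequency of 1s, and the 0->1 and 1->0
    transition frequencies.  ``depth`` controls the nested-halves
    segmentation (depth 1 = whole sequence, 40 values)."""
    idx = _seq_indices(record, 2, "global_encoding")
    class_of = np.empty(20, dtype=np.intp)
    for c, members in enumerate(GE_CLASSES):
        for aa in members:
            class_of[CANONICAL_ORDER.index(aa)] = c
    cls = class_of[idx]
    feats = []
    for first, _ in ge_partitions():
        cs = np.isin(cls, first).astype(np.intp)
        for lo, hi in _segments(len(cs), depth):
            seg = cs[lo:hi]
            n = len(seg)
            ones = seg.sum() / n if n else 0.0
            if n >= 2:
                diff = np.diff(seg)
                t01 = (diff == 1).sum() / (n - 1)
                t10 = (diff == -1).sum() / (n - 1)
            else:
                t01 = t10 = 0.0
            feats.extend([1.0 - ones, ones, t01, t10])
    dim = 40 * (2 ** depth - 1)
    return DescriptorVector(np.array(feats), "GE", dim)


def p2g(record: ProteinRecord, d: PhysicochemicalProperty
        ) -> DescriptorVector:
    """Physicochemical 2-grams: each couple (i,j) contributes the pair
    (h(i,j)*index(i,d)/(N-1), h(i,j)*index(j,d)/(N-1)); pairs are stored
    interleaved in couple order (800 values)."""
    idx = _seq_indices(record, 2, "p2g")
    grid = np.zeros((20, 20))
    np.add.at(grid, (idx[:-1], idx[1:]), 1.0)
    vals = d.vector()
    first = grid * vals[:, None] / (idx.size - 1)
    second = grid * vals[None, :] / (idx.size - 1)
    out = np.stack([first.ravel(), second.ravel()], axis=1).ravel()
    return DescriptorVector(out, "P2G", 800, property_id=d.id)


def ngram(record: ProteinRecord, alphabet: str = "A1") -> DescriptorVector:
    """N-gram composition over a reduced amino-acid alphabet.

    The sequence is translated to group symbols, then n-gram occurrence
    counts (n=2 for A1/A2, n=3 for A3/A4/A5) are normalized by N.  A1 is
    the full alphabet, so ``ngram(seq, "A1")`` equals :func:`two_gram`.
    """
    if alphabet not in NG_ALPHABETS:
        raise ValueError(f"unknown alphabet {alphabet!r}")
    groups = NG_ALPHABETS[alphabet]
    n = NG_ORDER[alphabet]
    idx = _seq_indices(record, n, f"ngram[{alphabet}]")
    group_of = np.empty(20, dtype=np.intp)
    for g, members in enumerate(groups):
        for aa in members:
            group_of[CANONICAL_ORDER.index(aa)] = g
    trans = group_of[idx]
    a = len(groups)
    counts = np.zeros(a ** n)
    if n == 2:
        flat = trans[:-1] * a + trans[1:]
    else:
        flat = (trans[:-2] * a + trans[1:-1]) * a + trans[2:]
    np.add.at(counts, flat, 1.0)
    return DescriptorVector(counts / idx.size, f"NG_{alphabet}", a ** n)


def sac(record: ProteinRecord, terminus: int = 20) -> DescriptorVector:
    """Split amino-acid composition over the N-terminus block, the middle
    region and the C-terminus block (three 20-vectors, 60 values).

    For short sequences the termini may overlap and the middle region may
    be empty; an empty region encodes as zeros."""
    seq = record.canonical_sequence
    if len(seq) < 2:
        raise ValueError("sac: needs at least 2 canonical residues")
    n_term = seq[:terminus]
    c_term = seq[-terminus:]
    middle = seq[terminus:-terminus] if len(seq) > 2 * terminus else ""

    def comp(part: str) -> np.ndarray:
        if not part:
            return np.zeros(20)
        return np.asarray(aac(ProteinRecord(record.id, part)))

    out = np.concatenate([comp(n_term), comp(middle), comp(c_term)])
    return DescriptorVector(out, "SAC", 60)


def discrete_wavelet(record: ProteinRecord, d: PhysicochemicalProperty,
                     wavelet: str = "bior3.3", levels: int = 4,
                     n_dct: int = 5) -> DescriptorVector:
    """Four-scale biorthogonal discrete-wavelet descriptor of the property
    profile.

    Per decomposition level: the first five DCT coefficients of the
    approximation plus max/min/mean/std of the approximation and of the
    detail coefficients — 13 features x 4 levels = 52.
    """
    idx = _seq_indices(record, 16, "discrete_wavelet")
    signal = property_profile(record, d).values
    feats = []
    approx = signal
    for _ in range(levels):
        approx, detail = pywt.dwt(approx, wavelet, mode="symmetric")
        if len(approx) < n_dct:
            raise ValueError("sequence too short for the requested "
                             "decomposition depth")
        coeffs = _dct(approx, type=2, norm="ortho")[:n_dct]
        feats.extend(coeffs)
        for band in (approx, detail):
            feats.extend([band.max(), band.min(), band.mean(), band.std()])
    return DescriptorVector(np.array(feats), "DW",
                            levels * (n_dct + 8), property_id=d.id)
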