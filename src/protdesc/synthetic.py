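"""Seeded generators for every input the toolkit consumes: random protein
sequences, blastpgp-style profile matrices, toy C-alpha backbones, and a
labelled two-class benchmark with matched synthetic profiles.

All generators are pure functions of their parameters and seed.  The
matched profile of a sequence is its one-hot encoding scaled to 10 plus
seeded integer noise in [-3, 3], clipped to [-10, 10]; this preserves the
sequence/matrix coherence that the per-amino-acid grouping descriptors
rely on, while mimicking the integer log-odds range of real profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import CANONICAL_ORDER, ProfileMatrix, ProteinRecord


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)


def random_protein(length: int, weights, seed,
                   record_id: str = "synthetic") -> ProteinRecord:
    """A protein with residues drawn independently from a 20-symbol
    distribution."""
    if length < 1:
        raise ValueError("length must be positive")
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (20,) or weights.min() < 0 or weights.sum() <= 0:
        raise ValueError("weights must be 20 nonnegative values with a "
                         "positive sum")
    weights = weights / weights.sum()
    rng = _rng(seed)
    letters = rng.choice(list(CANONICAL_ORDER), size=length, p=weights)
    return ProteinRecord(id=record_id, sequence="".join(letters))


def random_profile_matrix(n: int, mode: str = "log_odds",
                          seed=0) -> ProfileMatrix:
    """A random N x 20 profile: nonnegative rows summing to 1 in
    ``frequency`` mode, integers in [-10, 10] in ``log_odds`` mode."""
    rng = _rng(seed)
    if mode == "frequency":
        raw = rng.dirichlet(np.ones(20), size=n)
        return ProfileMatrix(values=raw, source="pssm")
    if mode == "log_odds":
        raw = rng.integers(-10, 11, size=(n, 20)).astype(float)
        return ProfileMatrix(values=raw, source="pssm")
    raise ValueError(f"unknown mode {mode!r}")


def toy_backbone(m: int, geometry: str = "helix", seed=0) -> np.ndarray:
    """An (M, 3) toy C-alpha trace: collinear unit-spaced points
    (``line``) or an ideal alpha-helix spiral (rise 1.5 A per residue,
    radius 2.3 A, 3.6 residues per turn)."""
    if m < 2:
        raise ValueError("backbone needs at least 2 points")
    if geometry == "line":
        coords = np.zeros((m, 3))
        coords[:, 0] = np.arange(m)
        return coords
    if geometry == "helix":
        t = np.arange(m)
        angle = 2 * np.pi * t / 3.6
        return np.column_stack([2.3 * np.cos(angle), 2.3 * np.sin(angle),
                                1.5 * t])
    raise ValueError(f"unknown geometry {geometry!r}")


def synthetic_profile_for(record: ProteinRecord, seed=0,
                          scale: float = 10.0) -> ProfileMatrix:
    """The matched synthetic profile of a sequence: one-hot x 10 plus
    integer noise in [-3, 3], clipped to [-10, 10]."""
    rng = _rng(seed)
    idx = record.indices()
    mat = np.zeros((idx.size, 20))
    mat[np.arange(idx.size), idx] = scale
    mat += rng.integers(-3, 4, size=mat.shape)
    return ProfileMatrix(values=np.clip(mat, -10, 10), source="pssm",
                         residues=record.canonical_sequence)


@dataclass
class SyntheticSpec:
    """Study conditions for the two-class benchmark.

    Defaults: 100 proteins per class, lengths uniform in [50, 150] (long
    enough for every descriptor), and disjoint composition supports — the
    two classes draw from the first and last ten amino acids of the
    alphabet respectively, a separable-by-construction signal.
    """

    n_per_class: int = 100
    length_range: tuple[int, int] = (50, 150)
    composition_bias: dict[str, np.ndarray] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.composition_bias:
            self.composition_bias = disjoint_bias()
        if self.length_range[0] < 16:
            raise ValueError("minimum length must be >= 16 (discrete-"
                             "wavelet descriptor requirement)")
        for label, w in self.composition_bias.items():
            w = np.asarray(w, dtype=float)
            if w.min() < 0 or abs(w.sum() - 1) > 1e-9:
                raise ValueError(f"class {label}: weights must be a "
                                 "distribution")


def disjoint_bias() -> dict[str, np.ndarray]:
    """Two composition distributions with disjoint supports (first ten
    versus last ten amino acids, uniform within the support)."""
    a = np.zeros(20)
    a[:10] = 0.1
    b = np.zeros(20)
    b[10:] = 0.1
    return {"pos": a, "neg": b}


def null_bias() -> dict[str, np.ndarray]:
    """Identical uniform compositions for both classes (no signal)."""
    u = np.full(20, 0.05)
    return {"pos": u.copy(), "neg": u.copy()}


def two_class_dataset(spec: SyntheticSpec, with_profiles: bool = False):
    """A labelled two-class protein list (optionally with matched
    synthetic profiles), reproducible from ``spec.seed``."""
    if len(spec.composition_bias) != 2:
        raise ValueError("the benchmark generator defines two classes")
    rng = np.random.default_rng(spec.seed)
    records: list[ProteinRecord] = []
    profiles: list[ProfileMatrix] = []
    for label, weights in sorted(spec.composition_bias.items()):
        for i in range(spec.n_per_class):
            length = int(rng.integers(spec.length_range[0],
                                      spec.length_range[1] + 1))
            rec = random_protein(length, weights, rng,
                                 record_id=f"{label}_{i:04d}")
            rec.label = label
            records.append(rec)
            if with_profiles:
                profiles.append(synthetic_profile_for(rec, rng))
    return (records, profiles) if with_profiles else records
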