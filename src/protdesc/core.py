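"""Core domain types: alphabet, physicochemical properties, substitution
matrices, protein records and profile matrices.

The 20 canonical amino acids are kept in alphabetical one-letter order
``A C D E F G H I K L M N P Q R S T V W Y``.  Every linear index of the
form ``k = j + 20*(i-1)`` used by the descriptors maps to the row-major
flattening of a 20x20 grid over this order (0-based internally).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

CANONICAL_ORDER = "ACDEFGHIKLMNPQRSTVWY"
#: residues that occur in real data but are not one of the 20 canonical types
NONSTANDARD_RESIDUES = frozenset("BJOUXZ")


@dataclass(frozen=True)
class AminoAcidAlphabet:
    """The ordered 20-letter amino-acid alphabet with a bijective
    symbol <-> position mapping."""

    symbols: tuple[str, ...] = tuple(CANONICAL_ORDER)

    def __post_init__(self) -> None:
        if len(self.symbols) != 20 or len(set(self.symbols)) != 20:
            raise ValueError("alphabet must contain exactly 20 distinct symbols")

    def index_of(self, symbol: str) -> int:
        """0-based position of *symbol* in the alphabet."""
        try:
            return self.symbols.index(symbol)
        except ValueError:
            raise KeyError(f"not a canonical amino acid: {symbol!r}") from None

    def __len__(self) -> int:
        return 20

    def __iter__(self):
        return iter(self.symbols)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.symbols


ALPHABET = AminoAcidAlphabet()
_AA_TO_INDEX = {a: i for i, a in enumerate(CANONICAL_ORDER)}


def encode_sequence(sequence: str) -> np.ndarray:
    """Map a canonical sequence to 0-based alphabet indices."""
    try:
        return np.fromiter((_AA_TO_INDEX[a] for a in sequence), dtype=np.intp,
                           count=len(sequence))
    except KeyError as exc:
        raise ValueError(f"non-canonical residue {exc.args[0]!r}") from None


@dataclass
class PhysicochemicalProperty:
    """One AAindex-style amino-acid scale: 20 numerical values, one per
    canonical residue.

    ``mu`` and ``sigma`` are the normalization factors used by the
    autocovariance descriptors: the mean of the 20 values and, by default,
    their mean squared deviation (a variance; pass ``sqrt_sigma=True`` to
    :func:`property_stats` for the standard-deviation variant).
    """

    id: str
    values: dict[str, float]
    description: str = ""

    def __post_init__(self) -> None:
        missing = [a for a in CANONICAL_ORDER if a not in self.values]
        if missing:
            raise ValueError(
                f"property {self.id}: missing values for {''.join(missing)}")

    def __getitem__(self, aa: str) -> float:
        return self.values[aa]

    def vector(self) -> np.ndarray:
        """The 20 values in alphabet order."""
        return np.array([self.values[a] for a in CANONICAL_ORDER], dtype=float)

    @property
    def mu(self) -> float:
        return property_stats(self)[0]

    @property
    def sigma(self) -> float:
        return property_stats(self)[1]


def property_stats(prop: PhysicochemicalProperty, *,
                   sqrt_sigma: bool = False) -> tuple[float, float]:
    """Mean and dispersion of a property over the 20 amino acids.

    ``sigma`` defaults to the mean squared deviation (no square root); with
    ``sqrt_sigma=True`` the square-rooted (standard deviation) variant is
    returned instead.
    """
    v = prop.vector()
    mu = float(v.mean())
    sigma = float(((v - mu) ** 2).mean())
    if sqrt_sigma:
        sigma = float(np.sqrt(sigma))
    return mu, sigma


def select_random_properties(table: list[PhysicochemicalProperty], k: int,
                             seed: int) -> list[PhysicochemicalProperty]:
    """Seeded selection of *k* distinct properties from *table*."""
    if k > len(table):
        raise ValueError(f"cannot select {k} properties from a table of "
                         f"{len(table)}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(table), size=k, replace=False)
    return [table[i] for i in idx]


@dataclass
class SubstitutionMatrix:
    """A 20x20 substitution matrix with rows/columns in alphabet order."""

    name: str
    entries: np.ndarray

    def __post_init__(self) -> None:
        self.entries = np.asarray(self.entries, dtype=float)
        if self.entries.shape != (20, 20):
            raise ValueError(
                f"substitution matrix {self.name}: shape {self.entries.shape} "
                "!= (20, 20)")

    def row(self, aa: str) -> np.ndarray:
        return self.entries[_AA_TO_INDEX[aa]]

    def __getitem__(self, pair: tuple[str, str]) -> float:
        a, b = pair
        return float(self.entries[_AA_TO_INDEX[a], _AA_TO_INDEX[b]])


@dataclass
class ProteinRecord:
    """A protein sequence with optional class label.

    Non-canonical residues (B, J, O, U, X, Z) are flagged; all counting
    descriptors and property lookups operate on :attr:`canonical_sequence`,
    and the effective length ``N`` counts canonical residues only.
    """

    id: str
    sequence: str
    label: str | None = None
    has_nonstandard: bool = field(init=False, default=False)

    def __post_init__(self) -> None:
        self.sequence = "".join(self.sequence.split()).upper()
        if not self.sequence:
            raise ValueError(f"record {self.id}: empty sequence")
        bad = set(self.sequence) - set(CANONICAL_ORDER)
        unknown = bad - NONSTANDARD_RESIDUES
        if unknown:
            raise ValueError(
                f"record {self.id}: unknown residues {sorted(unknown)}")
        self.has_nonstandard = bool(bad)

    @property
    def canonical_sequence(self) -> str:
        if not self.has_nonstandard:
            return self.sequence
        return "".join(a for a in self.sequence if a in _AA_TO_INDEX)

    @property
    def n(self) -> int:
        """Effective length: number of canonical residues."""
        return len(self.canonical_sequence)

    def indices(self) -> np.ndarray:
        """0-based alphabet indices of the canonical residues."""
        return encode_sequence(self.canonical_sequence)


@dataclass
class ProfileMatrix:
    """An N x 20 numeric matrix over sequence positions x amino acids
    (a PSSM or substitution-matrix representation)."""

    values: np.ndarray
    source: str = "pssm"
    residues: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != 20:
            raise ValueError(f"profile matrix must be N x 20, got "
                             f"{self.values.shape}")
        if self.values.shape[0] < 1:
            raise ValueError("profile matrix must have at least one row")

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class DescriptorVector:
    """A fixed-length numeric feature vector with a declared dimensionality
    contract."""

    values: np.ndarray
    descriptor_id: str
    declared_dim: int
    property_id: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if len(self.values) != self.declared_dim:
            raise ValueError(
                f"{self.descriptor_id}: got {len(self.values)} values, "
                f"declared {self.declared_dim}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"{self.descriptor_id}: non-finite values")

    def __len__(self) -> int:
        return self.declared_dim

    def __array__(self, dtype=None, copy=None) -> np.ndarray:
        return np.asarray(self.values, dtype=dtype)


def _warn(msg: str) -> None:
    warnings.warn(msg, stacklevel=3)
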