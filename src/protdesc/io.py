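"""Readers and writers for the external formats the toolkit touches:
FASTA sequences, AAindex flat files, blastpgp ``-Q`` PSSM text, PDB
C-alpha backbones and whitespace-delimited substitution matrices."""

from __future__ import annotations

import logging
import warnings
from importlib import resources
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Align import substitution_matrices as _bio_submat
from Bio.PDB import PDBParser
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import (CANONICAL_ORDER, PhysicochemicalProperty, ProfileMatrix,
                   ProteinRecord, SubstitutionMatrix)

logger = logging.getLogger(__name__)

# residue order of the two value rows following an AAindex "I" line
_AAINDEX_ROW_ORDER = "ARNDCQEGHILKMFPSTWYV"


class FormatError(ValueError):
    """A file does not conform to its declared external format."""


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a FASTA file into :class:`ProteinRecord` objects.

    Sequences are case-folded to upper case and whitespace-stripped;
    residues outside the canonical 20 are flagged on the record.
    """
    records = []
    for entry in SeqIO.parse(str(path), "fasta"):
        seq = str(entry.seq)
        if not seq:
            raise FormatError(f"{path}: entry {entry.id!r} has an empty "
                              "sequence")
        records.append(ProteinRecord(id=entry.id, sequence=seq))
    return records


def write_fasta(records: list[ProteinRecord], path: str | Path) -> None:
    entries = [SeqRecord(Seq(r.sequence), id=r.id, description="")
               for r in records]
    SeqIO.write(entries, str(path), "fasta")


# ---------------------------------------------------------------------------
# AAindex property tables

def load_property_table(path: str | Path) -> list[PhysicochemicalProperty]:
    """Parse an AAindex-dialect flat file into physicochemical properties.

    Entries whose 20 values are all 0 or 1 (binary indicator scales) are
    excluded.  Entries with fewer than 20 numeric values (e.g. ``NA``
    placeholders) are rejected with a warning; a value that fails to parse
    as a number raises a :class:`FormatError` naming the accession.
    """
    text = Path(path).read_text()
    table: list[PhysicochemicalProperty] = []
    for block in text.split("//"):
        block = block.strip()
        if not block:
            continue
        accession, description, values = _parse_aaindex_entry(block)
        if accession is None:
            continue
        if values is None or len(values) < 20:
            warnings.warn(f"AAindex entry {accession}: fewer than 20 values, "
                          "rejected")
            continue
        if set(values) <= {0.0, 1.0}:
            # indicator scale; excluded from the property table
            continue
        table.append(PhysicochemicalProperty(
            id=accession,
            values=dict(zip(_AAINDEX_ROW_ORDER, values)),
            description=description))
    if not table:
        logger.warning("no usable property entries in %s", path)
    return table


def _parse_aaindex_entry(block: str):
    accession = None
    description = ""
    values: list[float] | None = None
    lines = block.splitlines()
    for i, line in enumerate(lines):
        key = line[:1]
        if key == "H":
            accession = line[1:].strip()
        elif key == "D":
            description = line[1:].strip()
        elif key == "I":
            values = []
            for row in lines[i + 1:i + 3]:
                for token in row.split():
                    if token.upper() in ("NA", "NA."):
                        continue
                    try:
                        values.append(float(token))
                    except ValueError:
                        raise FormatError(
                            f"AAindex entry {accession}: cannot parse value "
                            f"{token!r}") from None
            break
    return accession, description, values


def bundled_property_table() -> list[PhysicochemicalProperty]:
    """The property table shipped with the package: a 30-entry synthetic
    stand-in in AAindex format (one genuine hydropathy scale plus seeded
    synthetic scales), sufficient for every property-parameterized
    descriptor."""
    with resources.as_file(resources.files("protdesc.data")
                           / "aaindex_synthetic_subset.txt") as p:
        return load_property_table(p)


# ---------------------------------------------------------------------------
# blastpgp -Q PSSM text

def parse_psiblast_pssm(path: str | Path, block: str = "log_odds"
                        ) -> ProfileMatrix:
    """Parse a PSI-BLAST ``-Q`` profile file into an N x 20 matrix.

    The file carries two 20-column blocks per residue row: position-specific
    log-odds scores followed by weighted observed percentages.  ``block``
    selects which one ("log_odds", the default, or "percent").  Columns are
    reordered from the file's header order to the package's alphabetical
    amino-acid order.  The residue column is retained for cross-checks.
    """
    if block not in ("log_odds", "percent"):
        raise ValueError(f"unknown block {block!r}")
    lines = Path(path).read_text().splitlines()
    header_order: list[str] | None = None
    rows: list[np.ndarray] = []
    residues: list[str] = []
    last_good = 0
    for lineno, line in enumerate(lines, start=1):
        tokens = line.split()
        if not tokens:
            continue
        if header_order is None:
            if all(t in CANONICAL_ORDER and len(t) == 1 for t in tokens) \
                    and len(tokens) in (20, 40):
                header_order = tokens[:20]
            continue
        if not tokens[0].isdigit():
            continue  # trailing K/lambda statistics
        if len(tokens) < 22:
            raise FormatError(f"{path}:{lineno}: expected at least 22 "
                              f"columns, got {len(tokens)} (last good row at "
                              f"line {last_good})")
        residue = tokens[1]
        try:
            if block == "log_odds":
                scores = [float(t) for t in tokens[2:22]]
            else:
                if len(tokens) < 42:
                    raise FormatError(
                        f"{path}:{lineno}: percentage block needs 42 columns,"
                        f" got {len(tokens)}")
                scores = [float(t) for t in tokens[22:42]]
        except ValueError:
            raise FormatError(f"{path}:{lineno}: non-numeric score "
                              f"(last good row at line {last_good})") from None
        rows.append(np.array(scores))
        residues.append(residue)
        last_good = lineno
    if header_order is None or not rows:
        raise FormatError(f"{path}: no PSSM table found (last good line "
                          f"{last_good})")
    mat = np.vstack(rows)
    order = [header_order.index(a) for a in CANONICAL_ORDER]
    return ProfileMatrix(values=mat[:, order], source="pssm",
                         residues="".join(residues))


def write_pssm_text(profile: ProfileMatrix, path: str | Path) -> None:
    """Write a profile in the blastpgp ``-Q`` layout (log-odds block
    duplicated into the percentage block) so it round-trips through
    :func:`parse_psiblast_pssm`."""
    residues = profile.residues or "A" * profile.n
    with open(path, "w") as fh:
        fh.write("\nLast position-specific scoring matrix computed\n")
        header = " ".join(f"{a:>3}" for a in CANONICAL_ORDER)
        fh.write("          " + header + " " + header + "\n")
        for i, row in enumerate(profile.values, start=1):
            cells = " ".join(f"{v:>3.0f}" for v in row)
            fh.write(f"{i:5d} {residues[i - 1]} {cells} {cells}\n")


# ---------------------------------------------------------------------------
# PDB backbones

def read_backbone(path: str | Path) -> np.ndarray:
    """Extract the ordered C-alpha coordinates from a PDB file.

    Only the first model is read; for altloc duplicates the
    highest-occupancy location is kept (Bio.PDB's default selection).
    Returns an (M, 3) float array.
    """
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("protein", str(path))
    try:
        model = next(structure.get_models())
    except StopIteration:
        raise FormatError(f"{path}: no models in PDB file") from None
    coords = []
    for residue in model.get_residues():
        if "CA" in residue:
            coords.append(residue["CA"].get_coord())
    if not coords:
        raise FormatError(f"{path}: no C-alpha atoms found")
    return np.array(coords, dtype=float)


def write_pdb_ca(coords: np.ndarray, path: str | Path) -> None:
    """Write a minimal C-alpha-only PDB file (one ALA residue per point)."""
    coords = np.asarray(coords, dtype=float)
    with open(path, "w") as fh:
        for i, (x, y, z) in enumerate(coords, start=1):
            fh.write(f"ATOM  {i:5d}  CA  ALA A{i:4d}    "
                     f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# substitution matrices

def load_substitution_matrix(name: str = "DAYHOFF") -> SubstitutionMatrix:
    """Load a named 20x20 substitution matrix (DAYHOFF, PAM250, BLOSUM62,
    ...) and reorder it to the package's alphabet order."""
    m = _bio_submat.load(name)
    entries = np.empty((20, 20))
    for i, a in enumerate(CANONICAL_ORDER):
        for j, b in enumerate(CANONICAL_ORDER):
            entries[i, j] = m[a, b]
    return SubstitutionMatrix(name=name, entries=entries)


def read_substitution_matrix(path: str | Path,
                             name: str | None = None) -> SubstitutionMatrix:
    """Read a whitespace-delimited 20x20 matrix file.

    An optional single-letter header row (and leading residue column) in any
    order is honoured; a bare 20x20 numeric table is assumed to already be in
    alphabet order.
    """
    lines = [ln.split() for ln in Path(path).read_text().splitlines()
             if ln.strip() and not ln.lstrip().startswith("#")]
    order = list(CANONICAL_ORDER)
    if lines and all(len(t) == 1 and t.isalpha() for t in lines[0]):
        order = [t.upper() for t in lines[0]]
        lines = lines[1:]
    rows = []
    for tokens in lines:
        if tokens and tokens[0].isalpha() and len(tokens[0]) == 1:
            tokens = tokens[1:]
        rows.append([float(t) for t in tokens])
    mat = np.array(rows, dtype=float)
    if mat.shape != (20, 20):
        raise FormatError(f"{path}: expected a 20x20 matrix, got {mat.shape}")
    idx = [order.index(a) for a in CANONICAL_ORDER]
    return SubstitutionMatrix(name=name or Path(path).stem,
                              entries=mat[np.ix_(idx, idx)])
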