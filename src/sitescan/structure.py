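"""PDB-format structure parsing with residue context and secondary-structure labels.

The internal model is deliberately flat: an ordered list of atom records plus a
per-residue secondary-structure map. Atoms keep their file order, residues are
identified by ``(chain_id, residue_number, insertion_code)`` in PDB auth
numbering, and only the first NMR model of a multi-model file is read.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from Bio.Data.IUPACData import protein_letters_3to1

logger = logging.getLogger(__name__)

#: Recognised secondary-structure codes (DSSP-style vocabulary).
SS_CODES = frozenset(
    {"3Helix", "4Helix", "5Helix", "Bridge", "Strand", "Turn", "Bend",
     "Coil", "Het", "Unknown"}
)

#: DSSP single-letter code -> catalog label, for sidecar files.
DSSP_TO_LABEL = {
    "G": "3Helix", "H": "4Helix", "I": "5Helix", "B": "Bridge",
    "E": "Strand", "T": "Turn", "S": "Bend", "": "Coil", "-": "Coil",
    "C": "Coil",
}

# PDB HELIX record class -> label; classes other than 1/3/5 fall back to Coil.
_HELIX_CLASS_TO_LABEL = {1: "4Helix", 3: "3Helix", 5: "5Helix"}

_STANDARD_AA_3TO1 = {k.upper(): v for k, v in protein_letters_3to1.items()}

_KNOWN_ELEMENTS = {"C", "N", "O", "S"}


class PDBParseError(ValueError):
    """Raised for unparseable PDB text; carries the offending line number."""


@dataclass(frozen=True)
class AtomRecord:
    serial: int
    atom_name: str
    element: str  # one of C, N, O, S, OTHER
    residue_name: str
    chain_id: str
    residue_number: int
    insertion_code: str
    coord: np.ndarray
    altloc: str = ""
    is_hetero: bool = False
    occupancy: float = 1.0
    bfactor: float = 0.0

    @property
    def residue_key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_number, self.insertion_code)


@dataclass
class Structure:
    atoms: list[AtomRecord]
    ss_labels: dict[tuple[str, int, str], str] = field(default_factory=dict)
    resolution: float | None = None
    id: str = "structure"

    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain_id)
        return list(seen)

    def residue_atoms(self, key: tuple[str, int, str]) -> list[AtomRecord]:
        return [a for a in self.atoms if a.residue_key == key]

    def coords(self) -> np.ndarray:
        if not self.atoms:
            return np.zeros((0, 3))
        return np.stack([a.coord for a in self.atoms])


@dataclass(frozen=True)
class ChainSequence:
    chain_id: str
    sequence: str
    residue_keys: tuple[tuple[int, str], ...]

    def __post_init__(self):
        if len(self.sequence) != len(self.residue_keys):
            raise ValueError("sequence and residue_keys must align 1:1")


def _derive_element(atom_name: str, element_field: str) -> str:
    """Bucket an atom into {C, N, O, S, OTHER}.

    Uses the PDB element column when present, otherwise the first alphabetic
    character of the atom name (digits such as in ``1HB`` are skipped).
    """
    el = element_field.strip().upper()
    if not el:
        for ch in atom_name:
            if ch.isalpha():
                el = ch.upper()
                break
    return el if el in _KNOWN_ELEMENTS else "OTHER"


def _parse_float(text: str, what: str, lineno: int) -> float:
    try:
        return float(text)
    except ValueError:
        raise PDBParseError(
            f"line {lineno}: malformed {what} field {text.strip()!r}"
        ) from None


def parse_pdb(text: str, structure_id: str = "structure") -> Structure:
    """Parse PDB-format text into a :class:`Structure`.

    ATOM/HETATM records become atom records (first model only); HELIX/SHEET
    headers translate to per-residue secondary-structure labels; REMARK 2
    resolution is captured when present. Alternate locations are collapsed to
    the highest-occupancy conformer (ties broken by file order).
    """
    atoms: list[AtomRecord] = []
    helix_ranges: list[tuple[str, int, int, str]] = []
    sheet_ranges: list[tuple[str, int, int]] = []
    resolution: float | None = None

    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6]
        if rec == "ENDMDL":
            break  # first model only
        if rec.startswith("REMARK") and line[7:10].strip() == "2":
            tokens = line.split()
            for i, tok in enumerate(tokens):
                if tok == "RESOLUTION." and i + 1 < len(tokens):
                    try:
                        resolution = float(tokens[i + 1])
                    except ValueError:
                        pass
            continue
        if rec.startswith("HELIX"):
            try:
                chain = line[19].strip()
                start = int(line[21:25])
                end = int(line[33:37])
                helix_class = int(line[38:40]) if line[38:40].strip() else 1
            except (ValueError, IndexError):
                logger.warning("skipping malformed HELIX record at line %d", lineno)
                continue
            helix_ranges.append(
                (chain, start, end,
                 _HELIX_CLASS_TO_LABEL.get(helix_class, "Coil"))
            )
            continue
        if rec.startswith("SHEET"):
            try:
                chain = line[21].strip()
                start = int(line[22:26])
                end = int(line[33:37])
            except (ValueError, IndexError):
                logger.warning("skipping malformed SHEET record at line %d", lineno)
                continue
            sheet_ranges.append((chain, start, end))
            continue
        if rec not in ("ATOM  ", "HETATM"):
            continue

        if len(line) < 54:
            raise PDBParseError(f"line {lineno}: truncated coordinate record")
        x = _parse_float(line[30:38], "x coordinate", lineno)
        y = _parse_float(line[38:46], "y coordinate", lineno)
        z = _parse_float(line[46:54], "z coordinate", lineno)
        coord = np.array([x, y, z], dtype=float)
        if not np.all(np.isfinite(coord)):
            raise PDBParseError(f"line {lineno}: non-finite coordinate")
        atom_name = line[12:16].strip()
        if not atom_name:
            raise PDBParseError(f"line {lineno}: empty atom name")
        try:
            serial = int(line[6:11])
        except ValueError:
            serial = len(atoms) + 1
        occupancy = 1.0
        if len(line) >= 60 and line[54:60].strip():
            occupancy = _parse_float(line[54:60], "occupancy", lineno)
        bfactor = 0.0
        if len(line) >= 66 and line[60:66].strip():
            bfactor = _parse_float(line[60:66], "B-factor", lineno)
        element_field = line[76:78] if len(line) >= 78 else ""
        try:
            residue_number = int(line[22:26])
        except ValueError:
            raise PDBParseError(
                f"line {lineno}: malformed residue number {line[22:26]!r}"
            ) from None
        atoms.append(
            AtomRecord(
                serial=serial,
                atom_name=atom_name,
                element=_derive_element(atom_name, element_field),
                residue_name=line[17:20].strip(),
                chain_id=line[21].strip(),
                residue_number=residue_number,
                insertion_code=line[26].strip() if len(line) > 26 else "",
                coord=coord,
                altloc=line[16].strip(),
                is_hetero=(rec == "HETATM"),
                occupancy=occupancy,
                bfactor=bfactor,
            )
        )

    if not atoms:
        raise PDBParseError("no parseable ATOM or HETATM records found")

    atoms = _collapse_altlocs(atoms)
    structure = Structure(atoms=atoms, resolution=resolution, id=structure_id)
    header = _header_ss_labels(atoms, helix_ranges, sheet_ranges)
    structure.ss_labels = header
    return structure


def _collapse_altlocs(atoms: list[AtomRecord]) -> list[AtomRecord]:
    """Keep a single conformer per atom: highest occupancy, ties by file order."""
    best: dict[tuple, tuple[int, AtomRecord]] = {}
    order: list[tuple] = []
    for idx, atom in enumerate(atoms):
        key = (atom.chain_id, atom.residue_number, atom.insertion_code,
               atom.residue_name, atom.atom_name)
        if key not in best:
            best[key] = (idx, atom)
            order.append(key)
        elif atom.occupancy > best[key][1].occupancy:
            best[key] = (best[key][0], atom)
    return [replace(best[k][1], altloc="") for k in order]


def _header_ss_labels(atoms, helix_ranges, sheet_ranges):
    labels: dict[tuple[str, int, str], str] = {}
    for atom in atoms:
        if atom.residue_key not in labels:
            labels[atom.residue_key] = "Het" if atom.is_hetero else "Unknown"
    for chain, start, end, label in helix_ranges:
        for key in labels:
            if key[0] == chain and start <= key[1] <= end and labels[key] != "Het":
                labels[key] = label
    for chain, start, end in sheet_ranges:
        for key in labels:
            if key[0] == chain and start <= key[1] <= end and labels[key] != "Het":
                labels[key] = "Strand"
    return labels


def serialize_pdb(structure: Structure) -> str:
    """Write a structure back to minimal PDB text (ATOM/HETATM records only)."""
    lines = []
    if structure.resolution is not None:
        lines.append(
            f"REMARK   2 RESOLUTION. {structure.resolution:8.2f} ANGSTROMS."
        )
    for atom in structure.atoms:
        rec = "HETATM" if atom.is_hetero else "ATOM  "
        name = atom.atom_name
        # PDB convention: 1-3 char names start in column 14
        name_field = f" {name:<3s}" if len(name) < 4 else name[:4]
        x, y, z = atom.coord
        lines.append(
            f"{rec}{atom.serial:5d} {name_field}{atom.altloc or ' ':1s}"
            f"{atom.residue_name:>3s} {atom.chain_id or ' ':1s}"
            f"{atom.residue_number:4d}{atom.insertion_code or ' ':1s}   "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{atom.bfactor:6.2f}"
            f"          {atom.element if atom.element != 'OTHER' else '':>2s}"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"


def three_to_one(residue_name: str) -> str:
    """3-letter residue code to 1-letter; unknown residues map to ``X``."""
    return _STANDARD_AA_3TO1.get(residue_name.upper(), "X")


def one_to_three(letter: str) -> str | None:
    for three, one in _STANDARD_AA_3TO1.items():
        if one == letter.upper():
            return three
    return None


def extract_sequence(structure: Structure, chain_id: str) -> ChainSequence:
    """Extract the chain's amino-acid sequence with a residue-key map.

    One letter per distinct standard-residue key in ATOM-record order; waters
    and hetero residues are excluded; non-standard amino acids become ``X``.
    """
    available = structure.chains()
    if chain_id not in available:
        raise KeyError(
            f"chain {chain_id!r} not found; available chains: {available}"
        )
    letters: list[str] = []
    keys: list[tuple[int, str]] = []
    seen: set[tuple[int, str]] = set()
    for atom in structure.atoms:
        if atom.chain_id != chain_id or atom.is_hetero:
            continue
        if atom.residue_name in ("HOH", "DOD", "WAT"):
            continue
        key = (atom.residue_number, atom.insertion_code)
        if key in seen:
            continue
        seen.add(key)
        keys.append(key)
        letters.append(three_to_one(atom.residue_name))
    return ChainSequence(chain_id=chain_id, sequence="".join(letters),
                         residue_keys=tuple(keys))


def read_ss_sidecar(text: str) -> list[tuple[str, int, str, str]]:
    """Parse a DSSP-style sidecar TSV: columns chain, resnum, icode, ss_code.

    ``ss_code`` may be either a single DSSP letter or a full label.
    """
    rows = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if parts[0].lower() in ("chain",):  # header
            continue
        if len(parts) < 4:
            raise ValueError(f"sidecar line {lineno}: expected 4 columns")
        chain, resnum, icode, code = parts[0], parts[1], parts[2], parts[3]
        label = DSSP_TO_LABEL.get(code.strip(), code.strip())
        if label not in SS_CODES:
            raise ValueError(
                f"sidecar line {lineno}: unknown SS code {code!r}"
            )
        rows.append((chain.strip(), int(resnum), icode.strip(), label))
    return rows


def assign_secondary_structure(
    structure: Structure,
    sidecar: list[tuple[str, int, str, str]] | None = None,
) -> Structure:
    """Finalize per-residue secondary-structure labels.

    Header-derived labels (already on the structure after parsing) are kept;
    a sidecar, when given, overrides them. Unlabeled residues default to
    Unknown and hetero residues to Het. Sidecar entries referencing unknown
    residues are skipped with a warning.
    """
    labels = dict(structure.ss_labels)
    for atom in structure.atoms:
        if atom.residue_key not in labels:
            labels[atom.residue_key] = "Het" if atom.is_hetero else "Unknown"
    if sidecar:
        for chain, resnum, icode, label in sidecar:
            key = (chain, resnum, icode)
            if key not in labels:
                warnings.warn(
                    f"sidecar references unknown residue {key}; entry skipped",
                    stacklevel=2,
                )
                continue
            labels[key] = label
    structure.ss_labels = labels
    return structure
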