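"""Atom-centered microenvironment descriptors.

A microenvironment is the spherical neighborhood of a point of interest,
summarized shell by shell: six concentric shells of 1.25 Å thickness by
default, each accumulating 80 physicochemical properties (atom types,
chemical groups, element-typed scalar atom properties, residue identities and
classes, secondary structure), for a 480-element vector.

The property roster is data-driven: a versioned TSV catalog fixes the order,
names and accumulation rule of every slot, so the vector layout is stable and
auditable rather than hard-coded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

import numpy as np

from .structure import AtomRecord, Structure


@dataclass(frozen=True)
class ShellConfig:
    """Radial shell geometry: ``n_shells`` half-open shells of ``thickness_A``."""

    n_shells: int = 6
    thickness_A: float = 1.25

    def __post_init__(self):
        if self.n_shells < 1:
            raise ValueError("n_shells must be >= 1")
        if self.thickness_A <= 0:
            raise ValueError("thickness_A must be positive")

    @property
    def outer_radius(self) -> float:
        return self.n_shells * self.thickness_A


DEFAULT_SHELLS = ShellConfig()


def shell_index(distance: float, config: ShellConfig = DEFAULT_SHELLS) -> int | None:
    """Map a center distance to its shell, or None beyond the outer radius.

    Shells are half-open ``[k*t, (k+1)*t)`` so every distance below the outer
    radius falls in exactly one shell.
    """
    if distance < 0:
        raise ValueError("distance must be non-negative")
    if distance >= config.outer_radius:
        return None
    return int(distance // config.thickness_A)


# ---------------------------------------------------------------------------
# Physicochemical lookup tables
# ---------------------------------------------------------------------------

HYDROPHOBIC_RESIDUES = {"ALA", "VAL", "LEU", "ILE", "PRO", "PHE", "MET", "TRP"}
CHARGED_RESIDUES = {"ASP", "GLU", "LYS", "ARG", "HIS"}
POLAR_RESIDUES = {"SER", "THR", "CYS", "TYR", "ASN", "GLN",
                  "ASP", "GLU", "LYS", "ARG", "HIS"}
BASIC_RESIDUES = {"LYS", "ARG", "HIS"}
ACIDIC_RESIDUES = {"ASP", "GLU"}
STANDARD_RESIDUES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}
NONPOLAR_RESIDUES = STANDARD_RESIDUES - POLAR_RESIDUES

_BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}

_CHEMICAL_GROUPS: dict[str, set[tuple[str, str]]] = {
    "Hydroxyl": {("SER", "OG"), ("THR", "OG1"), ("TYR", "OH")},
    "Amide": {("ASN", "CG"), ("ASN", "OD1"), ("ASN", "ND2"),
              ("GLN", "CD"), ("GLN", "OE1"), ("GLN", "NE2")},
    "Amine": {("LYS", "NZ"), ("ARG", "NE"), ("ARG", "NH1"), ("ARG", "NH2")},
    "RingSystem": {
        ("PHE", a) for a in ("CG", "CD1", "CD2", "CE1", "CE2", "CZ")
    } | {
        ("TYR", a) for a in ("CG", "CD1", "CD2", "CE1", "CE2", "CZ")
    } | {
        ("TRP", a) for a in ("CG", "CD1", "CD2", "NE1", "CE2", "CE3",
                             "CZ2", "CZ3", "CH2")
    } | {
        ("HIS", a) for a in ("CG", "ND1", "CD2", "CE1", "NE2")
    } | {
        ("PRO", a) for a in ("N", "CA", "CB", "CG", "CD")
    },
}

# van der Waals sphere volumes (4/3 pi r^3, Bondi radii), Å^3
_VDW_VOLUME = {
    "C": 4.0 / 3.0 * math.pi * 1.70 ** 3,
    "N": 4.0 / 3.0 * math.pi * 1.55 ** 3,
    "O": 4.0 / 3.0 * math.pi * 1.52 ** 3,
    "S": 4.0 / 3.0 * math.pi * 1.80 ** 3,
    "OTHER": 4.0 / 3.0 * math.pi * 1.65 ** 3,
}

# Nominal partial charges on charged side-chain groups at physiological pH
_ATOM_CHARGE = {
    ("ASP", "OD1"): -0.5, ("ASP", "OD2"): -0.5,
    ("GLU", "OE1"): -0.5, ("GLU", "OE2"): -0.5,
    ("LYS", "NZ"): 1.0,
    ("ARG", "NH1"): 0.5, ("ARG", "NH2"): 0.5,
    ("HIS", "ND1"): 0.25, ("HIS", "NE2"): 0.25,
}

# Kyte-Doolittle hydropathy index, per residue
_KYTE_DOOLITTLE = {
    "ILE": 4.5, "VAL": 4.2, "LEU": 3.8, "PHE": 2.8, "CYS": 2.5, "MET": 1.9,
    "ALA": 1.8, "GLY": -0.4, "THR": -0.7, "SER": -0.8, "TRP": -0.9,
    "TYR": -1.3, "PRO": -1.6, "HIS": -3.2, "GLU": -3.5, "GLN": -3.5,
    "ASP": -3.5, "ASN": -3.5, "LYS": -3.9, "ARG": -4.5,
}

# Side-chain heavy-atom counts, for spreading the residue hydropathy evenly
# over side-chain atoms (GLY's "side chain" is its CA).
_SIDECHAIN_ATOM_COUNT = {
    "ALA": 1, "ARG": 7, "ASN": 4, "ASP": 4, "CYS": 2, "GLN": 5, "GLU": 5,
    "GLY": 1, "HIS": 6, "ILE": 4, "LEU": 4, "LYS": 5, "MET": 4, "PHE": 7,
    "PRO": 3, "SER": 2, "THR": 3, "TRP": 10, "TYR": 8, "VAL": 3,
}


def _is_sidechain(atom: AtomRecord) -> bool:
    if atom.residue_name == "GLY":
        return atom.atom_name == "CA"
    return atom.atom_name not in _BACKBONE_ATOMS


def atom_hydrophobicity(atom: AtomRecord) -> float:
    """Kyte-Doolittle residue hydropathy divided over side-chain atoms."""
    kd = _KYTE_DOOLITTLE.get(atom.residue_name)
    if kd is None or not _is_sidechain(atom):
        return 0.0
    return kd / _SIDECHAIN_ATOM_COUNT[atom.residue_name]


def atom_charge(atom: AtomRecord) -> float:
    return _ATOM_CHARGE.get((atom.residue_name, atom.atom_name), 0.0)


def atom_vdw_volume(atom: AtomRecord) -> float:
    return _VDW_VOLUME.get(atom.element, _VDW_VOLUME["OTHER"])


# ---------------------------------------------------------------------------
# Property catalog
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PropertyDef:
    group: str
    name: str
    rule: str
    params: str

    @property
    def label(self) -> str:
        return f"{self.group}.{self.name}"


@dataclass(frozen=True)
class PropertyCatalog:
    """Ordered, versioned roster of per-shell properties."""

    properties: tuple[PropertyDef, ...]
    version: str = "1"

    def __post_init__(self):
        labels = [p.label for p in self.properties]
        if len(set(labels)) != len(labels):
            raise ValueError("property names must be unique within the catalog")

    @property
    def size(self) -> int:
        return len(self.properties)

    def index_of(self, label: str) -> int:
        for i, p in enumerate(self.properties):
            if p.label == label:
                return i
        raise KeyError(label)


def parse_catalog(text: str) -> PropertyCatalog:
    version = "unversioned"
    props: list[PropertyDef] = []
    for line in text.splitlines():
        if line.startswith("#"):
            if "catalog_version:" in line:
                version = line.split("catalog_version:", 1)[1].strip()
            continue
        if not line.strip():
            continue
        parts = line.split("\t")
        if parts[0] == "group":
            continue
        group, name, rule = parts[0], parts[1], parts[2]
        params = parts[3] if len(parts) > 3 else ""
        props.append(PropertyDef(group, name, rule, params))
    return PropertyCatalog(properties=tuple(props), version=version)


@lru_cache(maxsize=1)
def default_catalog() -> PropertyCatalog:
    text = resources.files("sitescan.data").joinpath(
        "property_catalog.tsv").read_text()
    return parse_catalog(text)


# ---------------------------------------------------------------------------
# Per-atom contributions and the featurizer
# ---------------------------------------------------------------------------

def _residue_name_bucket(residue_name: str) -> str:
    if residue_name in STANDARD_RESIDUES or residue_name == "HOH":
        return residue_name
    return "OTHER"


def atom_contributions(
    atom: AtomRecord,
    ss_label: str,
    catalog: PropertyCatalog | None = None,
    solvent_accessibility: float = 0.0,
) -> dict[str, float]:
    """Sparse map of property label -> contribution for a single atom.

    Indicator properties contribute 1 where the atom matches; element-typed
    scalar properties contribute the atom's scalar value into the matching
    element bucket and into the ANY bucket. Unknown atom or residue names
    fall into the OTHER buckets rather than erroring.
    """
    catalog = catalog or default_catalog()
    res_bucket = _residue_name_bucket(atom.residue_name)
    scalars = {
        "VDWVolume": atom_vdw_volume(atom),
        "Charge": atom_charge(atom),
        "Hydrophobicity": atom_hydrophobicity(atom),
        "Mobility": atom.bfactor,
        "SolventAccessibility": solvent_accessibility,
    }
    out: dict[str, float] = {}
    for prop in catalog.properties:
        value = 0.0
        if prop.rule == "atom_element":
            value = 1.0 if atom.element == prop.params else 0.0
        elif prop.rule == "atom_any":
            value = 1.0
        elif prop.rule == "chemical_group":
            if prop.params == "Carbonyl":
                value = 1.0 if (not atom.is_hetero
                                and atom.atom_name in ("C", "O")) else 0.0
            elif prop.params == "Peptide":
                value = 1.0 if (not atom.is_hetero
                                and atom.atom_name in ("N", "CA", "C", "O")) else 0.0
            else:
                members = _CHEMICAL_GROUPS[prop.params]
                value = 1.0 if (atom.residue_name, atom.atom_name) in members else 0.0
        elif prop.rule == "scalar":
            scalar_key, bucket = prop.params.split(",")
            if bucket == "ANY" or atom.element == bucket:
                value = scalars[scalar_key]
        elif prop.rule == "residue_name":
            value = 1.0 if res_bucket == prop.params else 0.0
        elif prop.rule == "residue_class":
            rn = atom.residue_name
            value = 1.0 if (
                (prop.params == "Hydrophobic" and rn in HYDROPHOBIC_RESIDUES)
                or (prop.params == "Charged" and rn in CHARGED_RESIDUES)
                or (prop.params == "Polar" and rn in POLAR_RESIDUES)
                or (prop.params == "NonPolar" and rn in NONPOLAR_RESIDUES)
                or (prop.params == "Basic" and rn in BASIC_RESIDUES)
                or (prop.params == "Acidic" and rn in ACIDIC_RESIDUES)
            ) else 0.0
        elif prop.rule == "ss":
            value = 1.0 if ss_label == prop.params else 0.0
        else:
            raise ValueError(f"unknown accumulation rule {prop.rule!r}")
        if value != 0.0:
            out[prop.label] = value
    return out


@dataclass
class FeatureVector:
    values: np.ndarray
    names: list[str]
    center: np.ndarray
    source_id: str = ""

    def __post_init__(self):
        if len(self.values) != len(self.names):
            raise ValueError("values and names must align")

    def __len__(self) -> int:
        return len(self.values)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.values))


def feature_names(config: ShellConfig = DEFAULT_SHELLS,
                  catalog: PropertyCatalog | None = None) -> list[str]:
    """Slot labels ``shellK.group.name`` in vector order (shell-major)."""
    catalog = catalog or default_catalog()
    return [
        f"shell{k}.{prop.label}"
        for k in range(config.n_shells)
        for prop in catalog.properties
    ]


def featurize(
    structure: Structure,
    center: np.ndarray,
    config: ShellConfig = DEFAULT_SHELLS,
    catalog: PropertyCatalog | None = None,
    solvent_accessibility: dict[tuple, float] | None = None,
    source_id: str = "",
) -> FeatureVector:
    """Accumulate per-shell property contributions around ``center``.

    Every atom within the outer radius (the center atom included, landing in
    shell 0) adds its contributions to its shell's slots; everything farther
    away is invisible. The result is a pure function of geometry and residue
    context — rigid motions of structure and center together leave it
    unchanged, as does atom order.

    Parameters
    ----------
    solvent_accessibility
        Optional per-atom table keyed by ``(chain_id, residue_number,
        insertion_code, atom_name)``; atoms without an entry contribute 0.
    """
    catalog = catalog or default_catalog()
    center = np.asarray(center, dtype=float)
    if center.shape != (3,) or not np.all(np.isfinite(center)):
        raise ValueError("center must be a finite 3-vector")
    size = catalog.size
    values = np.zeros(config.n_shells * size)
    if structure.atoms:
        dists = np.linalg.norm(structure.coords() - center, axis=1)
        label_index = {p.label: i for i, p in enumerate(catalog.properties)}
        for atom, dist in zip(structure.atoms, dists):
            shell = shell_index(float(dist), config)
            if shell is None:
                continue
            ss = structure.ss_labels.get(
                atom.residue_key, "Het" if atom.is_hetero else "Unknown")
            sa = 0.0
            if solvent_accessibility is not None:
                sa = solvent_accessibility.get(
                    (*atom.residue_key, atom.atom_name), 0.0)
            for label, value in atom_contributions(
                    atom, ss, catalog, solvent_accessibility=sa).items():
                values[shell * size + label_index[label]] += value
    return FeatureVector(
        values=values,
        names=feature_names(config, catalog),
        center=center,
        source_id=source_id or structure.id,
    )
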