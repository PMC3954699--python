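"""Deterministic synthetic-input generators.

Everything downstream is testable without any database download:

* :func:`make_toy_pdb` writes well-formed PDB text for atoms placed at
  prescribed radii from the origin, so shell geometry is exactly controlled;
* :func:`make_scored_set` emits labeled probability blocks whose achievable
  precisions are known by construction, for exercising threshold selection;
* :func:`make_gaussian_sites` draws two-class Gaussian feature data with a
  controllable class separation d' along a fixed unit direction — an idealized
  stand-in for positive/negative microenvironment vectors with a known
  attainable recall at any precision.

All generators are pure functions of their spec (plus seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .evaluation import PooledPredictions
from .microenvironment import STANDARD_RESIDUES
from .site_examples import Provenance, TrainingSet
from .structure import Structure, parse_pdb

_VALID_RESIDUES = STANDARD_RESIDUES | {"HOH"}


@dataclass(frozen=True)
class ToyAtom:
    element: str
    atom_name: str
    residue_name: str
    chain: str = "A"
    resnum: int = 1
    radius: float = 0.0
    direction: tuple[float, float, float] = (1.0, 0.0, 0.0)


@dataclass
class ToyStructureSpec:
    atoms: list[ToyAtom]
    ss: dict[tuple[str, int], str] | None = None
    resolution: float | None = None

    def __post_init__(self):
        if not self.atoms:
            raise ValueError("spec must place at least one atom")
        for a in self.atoms:
            if a.radius < 0:
                raise ValueError("radii must be non-negative")
            norm = float(np.linalg.norm(a.direction))
            if abs(norm - 1.0) > 1e-6 and a.radius > 0:
                raise ValueError("directions must be unit-norm")
            if a.residue_name not in _VALID_RESIDUES:
                raise ValueError(f"unknown residue name {a.residue_name!r}")
            if not a.atom_name:
                raise ValueError("atom name must be non-empty")


def make_toy_pdb(spec: ToyStructureSpec) -> str:
    """Emit PDB text placing each atom at ``radius * direction``."""
    lines = []
    if spec.resolution is not None:
        lines.append(
            f"REMARK   2 RESOLUTION. {spec.resolution:8.2f} ANGSTROMS.")
    for serial, atom in enumerate(spec.atoms, start=1):
        coord = np.asarray(atom.direction, dtype=float) * atom.radius
        hetero = atom.residue_name == "HOH"
        rec = "HETATM" if hetero else "ATOM  "
        name = atom.atom_name
        name_field = f" {name:<3s}" if len(name) < 4 else name[:4]
        x, y, z = coord
        el = atom.element.strip().upper()
        lines.append(
            f"{rec}{serial:5d} {name_field} {atom.residue_name:>3s} "
            f"{atom.chain:1s}{atom.resnum:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
            f"          {el:>2s}"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"


def make_toy_structure(spec: ToyStructureSpec,
                       structure_id: str = "toy") -> Structure:
    """Parse the generated PDB text back into a structure (round-trip by
    construction), applying any spec-level secondary-structure labels."""
    structure = parse_pdb(make_toy_pdb(spec), structure_id=structure_id)
    if spec.ss:
        for (chain, resnum), label in spec.ss.items():
            structure.ss_labels[(chain, resnum, "")] = label
    return structure


@dataclass(frozen=True)
class ScoreBlock:
    count: int
    label: int  # 1 positive, 0 negative
    score: float

    def __post_init__(self):
        if self.count < 1:
            raise ValueError("block count must be >= 1")
        if not 0.0 < self.score < 1.0:
            raise ValueError("scores must lie strictly inside (0, 1)")
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")


@dataclass
class ScoredSetSpec:
    blocks: list[ScoreBlock]

    def __post_init__(self):
        labels = {b.label for b in self.blocks}
        if labels != {0, 1}:
            raise ValueError("need at least one positive and one negative block")


def make_scored_set(spec: ScoredSetSpec) -> PooledPredictions:
    """Expand score blocks into pooled predictions with known achievable
    precisions (every example nominally from fold 0)."""
    y, p = [], []
    for block in spec.blocks:
        y.extend([block.label] * block.count)
        p.extend([block.score] * block.count)
    return PooledPredictions(
        y_true=np.array(y, dtype=int),
        p_positive=np.array(p, dtype=float),
        fold_id=np.zeros(len(y), dtype=int),
    )


@dataclass(frozen=True)
class GaussianSiteSpec:
    n_pos: int
    n_neg: int
    dim: int = 480
    separation: float = 8.0  # d' between class means, in pooled-sd units
    seed: int = 0

    def __post_init__(self):
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValueError("need at least one example per class")
        if self.separation < 0:
            raise ValueError("separation must be non-negative")


def make_gaussian_sites(spec: GaussianSiteSpec) -> TrainingSet:
    """Two-class isotropic Gaussian feature data.

    Positives ~ N(+d'/2 u, I), negatives ~ N(-d'/2 u, I) with u the
    normalized all-ones direction, so every feature is weakly informative —
    the dense-descriptor analogue rather than a single give-away column.
    """
    rng = np.random.default_rng(spec.seed)
    u = np.ones(spec.dim) / np.sqrt(spec.dim)
    shift = 0.5 * spec.separation * u
    Xp = rng.standard_normal((spec.n_pos, spec.dim)) + shift
    Xn = rng.standard_normal((spec.n_neg, spec.dim)) - shift
    X = np.vstack([Xp, Xn])
    y = np.concatenate([np.ones(spec.n_pos, dtype=int),
                        np.zeros(spec.n_neg, dtype=int)])
    prov = [
        Provenance(structure_id=f"synthetic{'P' if lbl else 'N'}{i}",
                   chain_id="A", residue_number=i + 1, insertion_code="",
                   atom_name="X")
        for i, lbl in enumerate(y)
    ]
    return TrainingSet(
        X=X, y=y, provenance=prov,
        feature_names=[f"f{i}" for i in range(spec.dim)],
        catalog_version="synthetic",
        seed=spec.seed,
    )


def random_toy_spec(rng: np.random.Generator, n_atoms: int = 12,
                    max_radius: float = 10.0) -> ToyStructureSpec:
    """A random toy structure for property tests: standard residues, random
    directions, radii uniform on [0, max_radius]."""
    residues = sorted(STANDARD_RESIDUES)
    atoms = []
    for i in range(n_atoms):
        v = rng.standard_normal(3)
        v /= np.linalg.norm(v)
        atoms.append(ToyAtom(
            element=str(rng.choice(["C", "N", "O", "S"])),
            atom_name=str(rng.choice(["CA", "CB", "N", "O", "SG", "OD1"])),
            residue_name=str(rng.choice(residues)),
            chain="A",
            resnum=i + 1,
            radius=float(rng.uniform(0.0, max_radius)),
            direction=tuple(v),
        ))
    return ToyStructureSpec(atoms=atoms)
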