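"""Building labeled training sets for functional-site models.

Positives come from sequence-motif matches: a PROSITE-style pattern with a
conserved position is matched against chain sequences, and the conserved
residue's functional atom supplies the microenvironment center. Structures
with identical chain sequences are collapsed to one representative (best
X-ray resolution). Negatives are atoms of the same residue and atom type
drawn uniformly without replacement from a user-supplied pool of structures
known not to carry the site.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .microenvironment import (DEFAULT_SHELLS, FeatureVector, PropertyCatalog,
                               ShellConfig, default_catalog, feature_names,
                               featurize)
from .structure import AtomRecord, ChainSequence, Structure, one_to_three

logger = logging.getLogger(__name__)

AA_LETTERS = "ACDEFGHIKLMNPQRSTVWY"


class PatternSyntaxError(ValueError):
    """PROSITE grammar violation; carries the character offset."""

    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (offset {offset})")
        self.offset = offset


@dataclass(frozen=True)
class PatternElement:
    """One position class of a PROSITE pattern.

    kind: 'literal' (one residue), 'class' ([...]), 'exclusion' ({...}) or
    'any' (x wildcard); min_repeat/max_repeat expand ``(n)`` / ``(n,m)``.
    """

    kind: str
    residues: str
    min_repeat: int = 1
    max_repeat: int = 1

    def regex(self) -> str:
        if self.kind == "literal":
            core = self.residues
        elif self.kind == "class":
            core = f"[{self.residues}]"
        elif self.kind == "exclusion":
            core = f"[^{self.residues}]"
        elif self.kind == "any":
            core = "."
        else:
            raise ValueError(self.kind)
        if (self.min_repeat, self.max_repeat) == (1, 1):
            return core
        if self.min_repeat == self.max_repeat:
            return f"{core}{{{self.min_repeat}}}"
        return f"{core}{{{self.min_repeat},{self.max_repeat}}}"


@dataclass(frozen=True)
class ParsedPattern:
    elements: tuple[PatternElement, ...]
    anchored_start: bool = False
    anchored_end: bool = False

    def regex(self) -> str:
        return "".join(e.regex() for e in self.elements)


_REPEAT_RE = re.compile(r"\((\d+)(?:,(\d+))?\)")


def parse_pattern(text: str) -> ParsedPattern:
    """Parse a PROSITE grammar string into an ordered element list.

    Supports '-'-separated elements, the x wildcard, [..] alternatives,
    {..} exclusions, (n)/(n,m) repeats and the '<'/'>' anchors; a trailing
    period (PROSITE's terminator) is ignored.
    """
    text = text.strip()
    if text.endswith("."):
        text = text[:-1]
    anchored_start = text.startswith("<")
    if anchored_start:
        text = text[1:]
    anchored_end = text.endswith(">")
    if anchored_end:
        text = text[:-1]
    if not text:
        raise PatternSyntaxError("empty pattern", 0)

    elements: list[PatternElement] = []
    offset = 0
    for token in text.split("-"):
        if not token:
            raise PatternSyntaxError("empty element", offset)
        body = token
        min_rep = max_rep = 1
        m = _REPEAT_RE.search(token)
        if m:
            if m.end() != len(token):
                raise PatternSyntaxError("repeat must end the element", offset)
            body = token[: m.start()]
            min_rep = int(m.group(1))
            max_rep = int(m.group(2)) if m.group(2) else min_rep
            if min_rep == 0 or max_rep < min_rep:
                raise PatternSyntaxError("invalid repeat count", offset)
        if "(" in body or ")" in body:
            raise PatternSyntaxError("unbalanced parentheses", offset)
        if body.startswith("["):
            if not body.endswith("]") or len(body) < 3:
                raise PatternSyntaxError("unbalanced [ ]", offset)
            kind, residues = "class", body[1:-1]
        elif body.startswith("{"):
            if not body.endswith("}") or len(body) < 3:
                raise PatternSyntaxError("unbalanced { }", offset)
            kind, residues = "exclusion", body[1:-1]
        elif body in ("x", "X"):
            kind, residues = "any", ""
        elif len(body) == 1 and body.upper() in AA_LETTERS:
            kind, residues = "literal", body.upper()
        else:
            raise PatternSyntaxError(f"unrecognized element {body!r}", offset)
        if kind in ("class", "exclusion"):
            residues = residues.upper()
            bad = [c for c in residues if c not in AA_LETTERS]
            if bad:
                raise PatternSyntaxError(
                    f"unknown residue letter {bad[0]!r}", offset)
        elements.append(PatternElement(kind, residues, min_rep, max_rep))
        offset += len(token) + 1
    return ParsedPattern(tuple(elements), anchored_start, anchored_end)


@dataclass(frozen=True)
class SitePattern:
    """A functional-site definition: motif + conserved position + atom.

    ``conserved_index`` is 1-based into the matched span (the paper's Table-2
    convention: the index of the conserved position within the pattern).
    """

    name: str
    pattern: str
    conserved_index: int
    residue_name: str
    functional_atom: str

    def parsed(self) -> ParsedPattern:
        return parse_pattern(self.pattern)


@dataclass(frozen=True)
class PatternMatch:
    chain_id: str
    start: int  # 0-based offset into the chain sequence
    matched_span: str
    conserved_residue_key: tuple[int, str]


def match_pattern(pattern: SitePattern, seq: ChainSequence) -> list[PatternMatch]:
    """All matches of the pattern in a chain sequence (overlaps allowed).

    The sequence is scanned at every offset; at each matching offset the
    greedy (leftmost-longest) span is reported. The conserved position is
    the ``conserved_index``-th residue of the span; matches whose conserved
    residue disagrees with the pattern's stated residue are dropped with a
    warning.
    """
    parsed = pattern.parsed()
    regex = re.compile(parsed.regex())
    want_letter = None
    three = pattern.residue_name.upper()
    from .structure import three_to_one
    want_letter = three_to_one(three)

    starts = range(len(seq.sequence))
    if parsed.anchored_start:
        starts = range(1)
    out: list[PatternMatch] = []
    for i in starts:
        m = regex.match(seq.sequence, i)
        if not m:
            continue
        if parsed.anchored_end and m.end() != len(seq.sequence):
            continue
        span = m.group(0)
        pos = i + pattern.conserved_index - 1
        if pos >= i + len(span) or pos >= len(seq.sequence):
            warnings.warn(
                f"{pattern.name}: conserved index {pattern.conserved_index} "
                f"outside match at offset {i}; dropped", stacklevel=2)
            continue
        if want_letter != "X" and seq.sequence[pos] != want_letter:
            warnings.warn(
                f"{pattern.name}: conserved residue {seq.sequence[pos]!r} at "
                f"offset {pos} does not match {three}; dropped", stacklevel=2)
            continue
        out.append(PatternMatch(
            chain_id=seq.chain_id,
            start=i,
            matched_span=span,
            conserved_residue_key=seq.residue_keys[pos],
        ))
    return out


class MissingAtomError(KeyError):
    """Conserved residue lacks the functional atom (e.g. truncated side chain)."""


def extract_positive(
    structure: Structure, match: PatternMatch, pattern: SitePattern
) -> np.ndarray:
    """Coordinate of the functional atom in the match's conserved residue."""
    key = (match.chain_id, *match.conserved_residue_key)
    for atom in structure.atoms:
        if atom.residue_key == key and atom.atom_name == pattern.functional_atom:
            return atom.coord
    raise MissingAtomError(
        f"{structure.id}: residue {key} has no atom {pattern.functional_atom}")


def collect_positives(
    structure: Structure, matches: list[PatternMatch], pattern: SitePattern
) -> list[tuple[np.ndarray, tuple[str, int, str]]]:
    """Functional-atom coordinates for all matches, skipping (and logging)
    conserved residues with a missing functional atom."""
    out = []
    for match in matches:
        try:
            coord = extract_positive(structure, match, pattern)
        except MissingAtomError as exc:
            logger.warning("positive skipped: %s", exc)
            continue
        out.append((coord, (match.chain_id, *match.conserved_residue_key)))
    return out


def deduplicate(
    entries: list[tuple[str, ChainSequence, float | None]],
) -> list[tuple[str, ChainSequence, float | None]]:
    """One representative per group of identical sequences.

    Best (smallest) numeric resolution wins; unknown resolution loses to any
    numeric value; remaining ties break to the lexicographically smallest
    structure id. Output is sorted by id and independent of input order.
    """
    groups: dict[str, list[tuple[str, ChainSequence, float | None]]] = {}
    for entry in entries:
        groups.setdefault(entry[1].sequence, []).append(entry)

    def rank(entry):
        sid, _, res = entry
        return (res is None, res if res is not None else 0.0, sid)

    reps = [min(members, key=rank) for members in groups.values()]
    return sorted(reps, key=lambda e: e[0])


def sample_negatives(
    pool: list[tuple[str, AtomRecord]],
    residue_name: str,
    atom_name: str,
    n: int,
    seed: int,
    allow_short: bool = False,
) -> list[tuple[str, AtomRecord]]:
    """Draw ``n`` distinct same-residue/same-atom atoms uniformly, without
    replacement, from the pool.

    The pool must already exclude structures positive for the site (the
    caller's contract). With ``allow_short`` a pool smaller than ``n``
    returns the whole eligible pool with a warning instead of erroring.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    eligible = [
        (sid, atom) for sid, atom in pool
        if atom.residue_name == residue_name and atom.atom_name == atom_name
    ]
    if len(eligible) < n:
        if not allow_short:
            raise ValueError(
                f"eligible pool has {len(eligible)} atoms, fewer than the "
                f"requested {n}; pass allow_short to take the whole pool")
        warnings.warn(
            f"eligible pool ({len(eligible)}) smaller than requested ({n}); "
            "returning entire pool", stacklevel=2)
        return list(eligible)
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(eligible), size=n, replace=False)
    return [eligible[i] for i in np.sort(idx)]


@dataclass(frozen=True)
class Provenance:
    structure_id: str
    chain_id: str
    residue_number: int
    insertion_code: str
    atom_name: str


@dataclass
class TrainingSet:
    """Aligned feature matrix, labels (1=site, 0=non-site) and provenance."""

    X: np.ndarray
    y: np.ndarray
    provenance: list[Provenance]
    feature_names: list[str]
    catalog_version: str
    seed: int | None = None

    def __post_init__(self):
        if not (len(self.X) == len(self.y) == len(self.provenance)):
            raise ValueError("vectors, labels and provenance must align")

    @property
    def n_positive(self) -> int:
        return int(np.sum(self.y == 1))

    @property
    def n_negative(self) -> int:
        return int(np.sum(self.y == 0))


def build_training_set(
    positives: list[tuple[Structure, np.ndarray, Provenance]],
    negatives: list[tuple[Structure, np.ndarray, Provenance]],
    config: ShellConfig = DEFAULT_SHELLS,
    catalog: PropertyCatalog | None = None,
    seed: int | None = None,
) -> TrainingSet:
    """Featurize positive and negative centers into an aligned training set."""
    if not positives or not negatives:
        raise ValueError("both positives and negatives are required")
    catalog = catalog or default_catalog()
    rows, labels, prov = [], [], []
    for examples, label in ((positives, 1), (negatives, 0)):
        for structure, center, p in examples:
            fv = featurize(structure, center, config, catalog)
            rows.append(fv.values)
            labels.append(label)
            prov.append(p)
    X = np.stack(rows)
    return TrainingSet(
        X=X,
        y=np.array(labels, dtype=int),
        provenance=prov,
        feature_names=feature_names(config, catalog),
        catalog_version=catalog.version,
        seed=seed,
    )


def write_training_set(ts: TrainingSet, path: str) -> None:
    """Export a training set as TSV: feature columns, label, provenance."""
    import pandas as pd

    df = pd.DataFrame(ts.X, columns=ts.feature_names)
    df["label"] = ts.y
    df["structure_id"] = [p.structure_id for p in ts.provenance]
    df["chain_id"] = [p.chain_id for p in ts.provenance]
    df["residue_number"] = [p.residue_number for p in ts.provenance]
    df["insertion_code"] = [p.insertion_code for p in ts.provenance]
    df["atom_name"] = [p.atom_name for p in ts.provenance]
    with open(path, "w") as fh:
        fh.write(f"# catalog_version: {ts.catalog_version}\n")
        if ts.seed is not None:
            fh.write(f"# seed: {ts.seed}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_training_set(path: str) -> TrainingSet:
    import pandas as pd

    import io

    catalog_version = "unversioned"
    seed = None
    with open(path) as fh:
        lines = fh.readlines()
    body = []
    for line in lines:
        if line.startswith("#"):
            if "catalog_version:" in line:
                catalog_version = line.split("catalog_version:", 1)[1].strip()
            elif "seed:" in line:
                seed = int(line.split("seed:", 1)[1].strip())
        else:
            body.append(line)
    df = pd.read_csv(io.StringIO("".join(body)), sep="\t")
    meta_cols = ["label", "structure_id", "chain_id", "residue_number",
                 "insertion_code", "atom_name"]
    feature_cols = [c for c in df.columns if c not in meta_cols]
    df["insertion_code"] = df["insertion_code"].fillna("")
    prov = [
        Provenance(structure_id=str(r.structure_id), chain_id=str(r.chain_id),
                   residue_number=int(r.residue_number),
                   insertion_code=str(r.insertion_code),
                   atom_name=str(r.atom_name))
        for r in df.itertuples()
    ]
    return TrainingSet(
        X=df[feature_cols].to_numpy(dtype=float),
        y=df["label"].to_numpy(dtype=int),
        provenance=prov,
        feature_names=feature_cols,
        catalog_version=catalog_version,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Site-definition table I/O
# ---------------------------------------------------------------------------

def parse_site_table(text: str) -> list[SitePattern]:
    """Read a site-definitions TSV: name, pattern, conserved_index,
    residue_name, functional_atom. The pattern column may be empty (patterns
    are external inputs); such entries carry an empty pattern string."""
    out = []
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if parts[0] == "name":
            continue
        if len(parts) < 5:
            raise ValueError(f"site table row needs 5 columns: {line!r}")
        out.append(SitePattern(
            name=parts[0],
            pattern=parts[1],
            conserved_index=int(parts[2]),
            residue_name=parts[3],
            functional_atom=parts[4],
        ))
    return out


def load_site_table() -> list[SitePattern]:
    """The bundled table of 20 reference functional-site definitions."""
    text = resources.files("sitescan.data").joinpath(
        "site_definitions.tsv").read_text()
    return parse_site_table(text)


# Standard side-chain atom rosters, for sanity-checking functional atoms.
_RESIDUE_ATOMS = {
    "ALA": {"CB"},
    "ARG": {"CB", "CG", "CD", "NE", "CZ", "NH1", "NH2"},
    "ASN": {"CB", "CG", "OD1", "ND2"},
    "ASP": {"CB", "CG", "OD1", "OD2"},
    "CYS": {"CB", "SG"},
    "GLN": {"CB", "CG", "CD", "OE1", "NE2"},
    "GLU": {"CB", "CG", "CD", "OE1", "OE2"},
    "GLY": set(),
    "HIS": {"CB", "CG", "ND1", "CD2", "CE1", "NE2"},
    "ILE": {"CB", "CG1", "CG2", "CD1"},
    "LEU": {"CB", "CG", "CD1", "CD2"},
    "LYS": {"CB", "CG", "CD", "CE", "NZ"},
    "MET": {"CB", "CG", "SD", "CE"},
    "PHE": {"CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "PRO": {"CB", "CG", "CD"},
    "SER": {"CB", "OG"},
    "THR": {"CB", "OG1", "CG2"},
    "TRP": {"CB", "CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"},
    "TYR": {"CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ", "OH"},
    "VAL": {"CB", "CG1", "CG2"},
}
_BACKBONE = {"N", "CA", "C", "O", "OXT"}


def validate_site_table(sites: list[SitePattern]) -> list[str]:
    """Flag site definitions whose functional atom is not a standard atom of
    the stated residue (e.g. a HIS entry claiming atom SG)."""
    flagged = []
    for site in sites:
        allowed = _RESIDUE_ATOMS.get(site.residue_name.upper())
        if allowed is None:
            flagged.append(f"{site.name}: unknown residue {site.residue_name}")
            continue
        if site.functional_atom not in allowed | _BACKBONE:
            flagged.append(
                f"{site.name}: {site.residue_name} has no atom "
                f"{site.functional_atom}")
    return flagged
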