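"""Trained site models: scanning structures and (de)serialization.

A :class:`SiteModel` bundles a fitted classifier with everything needed to
apply it honestly later: the selected grid parameter, the decision threshold
chosen at the target precision, the precision/recall achieved on pooled
cross-validation predictions, and the property-catalog version the training
vectors were computed with. Scanning refuses to run against a different
catalog version — a silently re-ordered descriptor would corrupt every
probability.
"""

from __future__ import annotations

import base64
import datetime
import io
import json
from dataclasses import dataclass, field

import joblib
import numpy as np

from .microenvironment import (DEFAULT_SHELLS, PropertyCatalog, ShellConfig,
                               default_catalog, featurize)
from .site_examples import SitePattern
from .structure import Structure

MODEL_FORMAT_VERSION = 1


class CatalogMismatchError(ValueError):
    """Model and featurizer disagree on the property catalog version."""


@dataclass
class SiteModel:
    site: str
    kind: str  # "nb" | "svm"
    classifier: object  # NBModel or SVMModel; must expose predict_proba
    param: float
    threshold: float
    precision: float
    recall: float
    catalog_version: str
    created: str = field(
        default_factory=lambda: datetime.datetime.now(
            datetime.timezone.utc).isoformat())

    def __post_init__(self):
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie strictly inside (0, 1)")
        if self.kind not in ("nb", "svm"):
            raise ValueError("kind must be 'nb' or 'svm'")

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self.classifier.predict_proba(X)


@dataclass(frozen=True)
class SiteHit:
    structure_id: str
    chain_id: str
    residue_number: int
    insertion_code: str
    residue_name: str
    atom_name: str
    p_positive: float
    call: bool


def scan_structure(
    structure: Structure,
    model: SiteModel,
    pattern: SitePattern,
    config: ShellConfig = DEFAULT_SHELLS,
    catalog: PropertyCatalog | None = None,
) -> list[SiteHit]:
    """Score every candidate functional atom in the structure.

    Candidates are atoms named ``pattern.functional_atom`` in non-hetero
    residues named ``pattern.residue_name`` — the same centering rule the
    training examples used. Hits come back sorted by descending probability
    (ties by chain/residue for stable output).
    """
    catalog = catalog or default_catalog()
    if catalog.version != model.catalog_version:
        raise CatalogMismatchError(
            f"model was trained with catalog {model.catalog_version!r} but "
            f"the featurizer uses {catalog.version!r}")
    hits = []
    for atom in structure.atoms:
        if atom.is_hetero or atom.residue_name != pattern.residue_name:
            continue
        if atom.atom_name != pattern.functional_atom:
            continue
        fv = featurize(structure, atom.coord, config, catalog)
        p = float(model.predict_proba(fv.values.reshape(1, -1))[0, 1])
        hits.append(SiteHit(
            structure_id=structure.id,
            chain_id=atom.chain_id,
            residue_number=atom.residue_number,
            insertion_code=atom.insertion_code,
            residue_name=atom.residue_name,
            atom_name=atom.atom_name,
            p_positive=p,
            call=p >= model.threshold,
        ))
    hits.sort(key=lambda h: (-h.p_positive, h.chain_id, h.residue_number,
                             h.insertion_code))
    return hits


def save_model(model: SiteModel, path: str) -> None:
    """Serialize to a JSON envelope with a base64 parameter blob."""
    buf = io.BytesIO()
    joblib.dump(model.classifier, buf)
    envelope = {
        "format_version": MODEL_FORMAT_VERSION,
        "site": model.site,
        "kind": model.kind,
        "param": model.param,
        "threshold": model.threshold,
        "precision": model.precision,
        "recall": model.recall,
        "catalog_version": model.catalog_version,
        "created": model.created,
        "blob": base64.b64encode(buf.getvalue()).decode("ascii"),
    }
    with open(path, "w") as fh:
        json.dump(envelope, fh)


def load_model(path: str) -> SiteModel:
    with open(path) as fh:
        envelope = json.load(fh)
    version = envelope.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"unsupported model format version {version!r} "
            f"(expected {MODEL_FORMAT_VERSION})")
    try:
        blob = base64.b64decode(envelope["blob"], validate=True)
        classifier = joblib.load(io.BytesIO(blob))
    except Exception as exc:
        raise ValueError(f"corrupted model blob in {path}: {exc}") from exc
    return SiteModel(
        site=envelope["site"],
        kind=envelope["kind"],
        classifier=classifier,
        param=envelope["param"],
        threshold=envelope["threshold"],
        precision=envelope["precision"],
        recall=envelope["recall"],
        catalog_version=envelope["catalog_version"],
        created=envelope["created"],
    )
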