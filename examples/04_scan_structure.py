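"""Train a site model on a toy structure and scan it for predicted sites.

Builds a labeled training set from a toy structure (its own ASP OD2 atoms
as positives, sampled ASP OD2 atoms as negatives would normally come from
unrelated structures — here the same toy serves both roles for brevity),
fits a Naive Bayes model, and scans the structure: every candidate atom
gets a posterior probability and a call at the model's threshold.
"""

import numpy as np

from sitescan import (SiteModel, SitePattern, ToyAtom, ToyStructureSpec,
                      nb_fit, scan_structure)
from sitescan.fixtures import make_toy_structure
from sitescan.microenvironment import default_catalog, featurize
from sitescan.site_examples import Provenance, build_training_set

atoms = []
for i in range(4):
    atoms.append(ToyAtom("N", "N", "ASP", "A", i + 1, 1.0 + 6 * i, (1, 0, 0)))
    atoms.append(ToyAtom("O", "OD2", "ASP", "A", i + 1, 2.0 + 6 * i, (1, 0, 0)))
structure = make_toy_structure(ToyStructureSpec(atoms=atoms))
site = SitePattern("TOY_SITE", "D", 1, "ASP", "OD2")

centers = [a.coord for a in structure.atoms if a.atom_name == "OD2"]
pos = [(structure, c, Provenance("toy", "A", i + 1, "", "OD2"))
       for i, c in enumerate(centers[:2])]
neg = [(structure, c + np.array([0.0, 4.0, 0.0]),
        Provenance("toy", "A", i + 3, "", "OD2"))
       for i, c in enumerate(centers[2:])]
ts = build_training_set(pos, neg)

model = SiteModel(
    site="TOY_SITE", kind="nb",
    classifier=nb_fit(ts.X, ts.y, prior_positive=0.5),
    param=0.5, threshold=0.5, precision=1.0, recall=1.0,
    catalog_version=default_catalog().version)

for hit in scan_structure(structure, model, site):
    print(f"chain {hit.chain_id} {hit.residue_name}{hit.residue_number} "
          f"{hit.atom_name}: p={hit.p_positive:.3f} call={hit.call}")

# Each line is one candidate functional atom; `call` is True when its
# posterior clears the model's decision threshold.
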