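"""Compute a microenvironment descriptor for a hand-built toy structure.

Places three atoms at controlled distances from the origin and featurizes
the origin: six 1.25 Å shells times 80 physicochemical properties = 480
slots. Only atoms inside the 7.5 Å outer radius contribute.
"""

import numpy as np

from sitescan import ToyAtom, ToyStructureSpec, featurize
from sitescan.fixtures import make_toy_structure

spec = ToyStructureSpec(atoms=[
    ToyAtom("C", "CA", "ALA", "A", 1, radius=0.5, direction=(1, 0, 0)),
    ToyAtom("N", "N", "GLY", "A", 2, radius=2.0, direction=(0, 1, 0)),
    ToyAtom("O", "O", "SER", "A", 3, radius=7.6, direction=(0, 0, 1)),
])
structure = make_toy_structure(spec)
fv = featurize(structure, center=np.zeros(3))

print(f"vector length: {len(fv)}")
nonzero = {name: v for name, v in fv.as_dict().items() if v}
print(f"nonzero slots: {len(nonzero)}")
for name in sorted(nonzero):
    if "AtomName" in name or "ResidueName" in name:
        print(f"  {name} = {nonzero[name]:g}")

# The carbon at 0.5 Å lands in shell 0, the nitrogen at 2.0 Å in shell 1,
# and the oxygen at 7.6 Å is beyond the outer radius and invisible: the
# shell0/shell1 AtomName counts above reflect exactly that geometry.
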