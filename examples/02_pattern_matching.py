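"""Match a sequence motif and extract the functional-atom coordinate.

A site definition pairs a PROSITE-style pattern with a conserved position
and a functional atom. Matching the pattern against a chain sequence
resolves the conserved residue; the functional atom of that residue is the
point the microenvironment descriptor is centered on.
"""

from sitescan import SitePattern, extract_positive, match_pattern, parse_pdb
from sitescan.structure import extract_sequence

pdb_text = """\
ATOM      1  CA  VAL A  10       0.000   0.000   0.000  1.00 10.00           C
ATOM      2  N   ASP A  11       1.000   0.000   0.000  1.00 10.00           N
ATOM      3  CA  ASP A  11       2.000   0.500   0.000  1.00 10.00           C
ATOM      4  OD2 ASP A  11       3.000   1.500   0.500  1.00 10.00           O
ATOM      5  CA  THR A  12       4.000   0.000   0.000  1.00 10.00           C
ATOM      6  CA  GLY A  13       6.000   0.000   0.000  1.00 10.00           C
ATOM      7  CA  SER A  14       8.000   0.000   0.000  1.00 10.00           C
END
"""

structure = parse_pdb(pdb_text, structure_id="demo")
seq = extract_sequence(structure, "A")
print(f"chain A sequence: {seq.sequence}")

# aspartyl-protease-like motif: conserved ASP followed by T-G
site = SitePattern(name="DEMO_SITE", pattern="D-[TS]-G",
                   conserved_index=1, residue_name="ASP",
                   functional_atom="OD2")
matches = match_pattern(site, seq)
for m in matches:
    coord = extract_positive(structure, m, site)
    print(f"match {m.matched_span!r} at offset {m.start}; conserved ASP at "
          f"residue {m.conserved_residue_key[0]}; OD2 coordinate {coord}")

# The printed coordinate is the training/scanning center for this site:
# models are built from microenvironments around exactly such atoms.
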