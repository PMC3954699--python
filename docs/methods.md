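# Methods

## Microenvironment descriptor

The descriptor summarizes the spherical neighborhood of a point of interest
in `n_shells` concentric half-open shells `[k·t, (k+1)·t)` of thickness
`t = 1.25 Å` (defaults: 6 shells, outer radius 7.5 Å). Every atom whose
center-distance falls below the outer radius contributes to exactly one
shell; an atom coinciding with the center contributes to shell 0, keeping
the descriptor a pure function of geometry. Accumulation is plain summation:
counts for indicator properties, value sums for scalars, with no per-shell
normalization — scale handling is the classifier's job (standardization for
the SVM, binning for Naïve Bayes).

### The 80-property catalog

The roster is shipped as a versioned TSV (`data/property_catalog.tsv`) and
the vector length asserts against the catalog size, not a constant. Groups:

| group | slots | accumulation |
|---|---|---|
| AtomName (C, N, O, S, ANY, OTHER) | 6 | element-bucket counts; ANY counts every atom |
| ChemicalGroup (Hydroxyl, Amide, Amine, Carbonyl, RingSystem, Peptide) | 6 | membership counts from residue/atom-name tables |
| AtomProperties (5 scalars × element buckets C/N/O/S/OTHER/ANY) | 30 | per-atom scalar sums |
| ResidueName (20 standard + HOH + OTHER) | 22 | residue-identity counts per atom |
| ResidueProperties (Hydrophobic, Charged, Polar, NonPolar, Basic, Acidic) | 6 | residue-class counts per atom |
| SecondaryStructure (3Helix, 4Helix, 5Helix, Bridge, Strand, Turn, Bend, Coil, Het, Unknown) | 10 | per-residue label counts per atom |

The element-typing of the five scalar atom properties (30 slots rather than
5) is this package's resolution of an under-determined roster: the published
property list names 55 labels while the documented per-shell total is 80.
Typing each scalar by element bucket is chemically natural (an oxygen's
partial charge and a carbon's are different signals) and reaches the
documented total exactly; the catalog file isolates this choice so an
alternative roster is a data edit, not a code change.

Scalar sources: van der Waals volumes are Bondi-radius sphere volumes per
element; partial charges are nominal physiological-pH charges on charged
side-chain groups (ASP/GLU carboxylates −0.5 per oxygen, LYS NZ +1, ARG
guanidinium +0.5 per NH, HIS imidazole +0.25 per ring nitrogen);
hydrophobicity is the residue's Kyte–Doolittle index divided evenly over its
side-chain heavy atoms (GLY's CA carries its value); mobility is the atom's
B-factor from the coordinate record; solvent accessibility defaults to 0
and is populated only from a user-supplied per-atom sidecar, since no
geometric computation is attempted.

## Structure model

PDB text is parsed directly into a flat atom list (file order preserved,
first NMR model only). Alternate locations collapse to the
highest-occupancy conformer, ties to the first in file. Waters are retained
as atoms (the catalog has an HOH slot) but excluded from chain sequences.
Secondary structure comes from HELIX/SHEET header records (helix classes
1/3/5 → 4Helix/3Helix/5Helix, other classes → Coil, SHEET → Strand) or from
a DSSP-style sidecar TSV, which overrides the header; unlabeled residues
are Unknown, hetero residues Het. Residues are identified by
(chain, author residue number, insertion code) throughout.

## Training examples

Pattern grammar: `-`-separated elements; literals, `[..]` alternatives,
`{..}` exclusions, `x` wildcards, `(n)`/`(n,m)` repeats, `<`/`>` anchors.
Matching scans every sequence offset and reports the greedy
(leftmost-longest) span per matching offset; overlapping matches all become
positives. The conserved position is the k-th residue of the matched span
(1-based); matches whose conserved residue disagrees with the site's stated
residue type are dropped with a warning. "100% sequence similarity" for
deduplication is exact string equality of extracted chain sequences — the
strictest, fully deterministic reading — with the best (numerically
smallest) resolution winning and unknown resolutions losing to any number.

Negative sampling draws uniformly without replacement from the eligible
(same residue name, same atom name) atoms of a caller-supplied pool; the
caller is responsible for excluding structures positive for the site, since
site membership is an input here, not something the sampler can compute. A
pool smaller than the request errors by default (`allow_short` downgrades
this to a warning and returns the whole pool). The RNG is a seeded
`numpy` generator; the seed is recorded in the training-set provenance.

The bundled site-definitions table ships the 20 reference functional
families (conserved index, residue, functional atom) with the pattern
column empty — pattern strings are database content the user supplies. One
row (PA2_HIS) names atom SG on a histidine, which histidine does not have;
the row ships as published and `validate_site_table` flags it (NE2 is the
plausible intent).

## Classifiers

**Naïve Bayes** (from scratch): per-feature 5-bin histograms, equal-width
over the pooled training [min, max]; a constant feature gets a catch-all
central bin flanked by empty bins; out-of-range query values clamp into the
edge bins. Bin counts receive Laplace +1 smoothing. The positive prior P is
supplied, not estimated — at ~1:100 imbalance the prior is the
precision/recall knob. Posteriors are computed in log space, so 480
per-feature likelihoods of order 1e-3 cannot underflow. Equal-width pooled
binning is the simplest reproducible reading of "a histogram of five bins";
equal-frequency or per-class variants are defensible alternatives the
design leaves to the catalog of future options.

**SVM**: linear kernel only; features standardized with training-fold
mean/sd (raw count accumulations spanning orders of magnitude would cripple
the margin solver; the statistics are part of the model). Probability
calibration is Platt's sigmoid fitted on internal cross-validated decision
values (`CalibratedClassifierCV(..., method="sigmoid", ensemble=False)`),
i.e. the classic probabilistic-SVM recipe; neither the quadratic program
nor the calibration optimizer is re-derived. No class weighting beyond the
cost C — imbalance is handled by stratification and thresholding.

## Evaluation

Stratified 5-fold cross-validation (per-class fold sizes within ±1, seeded
shuffle) yields one held-out probability per example; folds are pooled and
treated as a single continuous experiment, accepting that per-fold
probability scales differ slightly — no per-fold recalibration. The PR
curve enumerates one operating point per distinct probability (call
positive when p ≥ t) plus the trivial all-negative point (precision
undefined there; it is never selectable). Threshold selection minimizes
|precision − target|; ties prefer precision ≥ target, then higher recall,
then higher threshold. Grid selection maximizes recall at that operating
point, ties to the smaller parameter value; the misclassification count of
each grid value is logged for diagnostics, but recall-at-target-precision
governs — the two rules can disagree and the recall rule matches the
method's stated use case. Default grids: C ∈ {2⁻⁵, 2⁻³, …, 2¹⁵},
P ∈ {0.01, 0.05, 0.1, 0.2, …, 0.9, 0.99}, both overridable.

Recall confidence intervals use the Wilson score method (well-behaved near
0 and 1, where these recalls live), delegated to statsmodels and
cross-checked against the closed form in the tests.

The domain-annotator comparison scores per-example predicted-domain sets
against a site → acceptable-domains mapping: a positive example is a TP if
any predicted domain intersects the mapped set, a negative an FP on any
intersection. Sites with an empty mapping are unscorable by design.

## Synthetic data and what tests show

The generators produce: toy PDB text with atoms at exact radii (shell
geometry is controlled to the thousandth of an Ångstrom); score sets whose
achievable precisions are known by counting; and two-class isotropic
Gaussian feature data with separation d′ along the normalized all-ones
direction, so every feature is weakly informative — the dense-descriptor
analogue, chosen over a single give-away column. The synthetic-classifier
experiments use 200 positives vs 2,000 negatives (the 1:10 ratio keeps the
pooled experiment small while preserving meaningful imbalance; real
training sets run ~1:100 with tens of thousands of negatives, which the
same code paths handle — the sampler test draws 50,000 from a 60,000 pool).

What passing tests do **not** show: that real microenvironment vectors are
as benign as isotropic Gaussians (real features are correlated,
integer-valued and heavy-tailed), that the bundled scalar tables match any
particular published featurizer's, or that header-derived secondary
structure matches DSSP output. The descriptor contract, the probability
machinery, and the selection logic are what the suite pins down.

## Numerical choices and degenerate inputs

Shell boundaries are half-open so no distance is double-counted; descriptor
equality under rigid motion is exact to 1e-9 per slot. An empty structure
featurizes to the zero vector rather than erroring. NB posteriors are
exact to the brute-force Bayes enumeration at 1e-12 on discrete toys.
Thresholds of exactly 0/1 (saturated posteriors) are clamped by 1e-9 when
persisted in a site model. Model serialization is a JSON envelope with a
base64 joblib blob; loading verifies the format version, and scanning
verifies the catalog version before computing a single probability.

## Known limitations

No mmCIF input; first model only; no geometric solvent accessibility or
DSSP computation; linear SVM only; no sub-100%-identity homology
clustering; scanning is restricted to the model's residue/atom type rather
than all atoms, mirroring how training examples are centered.
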