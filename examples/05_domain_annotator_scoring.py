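"""Score a sequence-level domain annotator against site-level truth.

A domain annotator predicts family domains per sequence, not atomic sites.
To compare it with a site predictor, each site maps to a set of acceptable
domains; a positive example counts as a true positive when any predicted
domain intersects that set. Sites without a mapping are unscorable.
"""

from sitescan import mapped_confusion
from sitescan.evaluation import UnscorableSiteError, load_domain_mapping

mapping = load_domain_mapping()
print(f"bundled mapping covers {sum(1 for v in mapping.values() if v)} "
      f"scorable sites of {len(mapping)}")

# four examples for the aspartyl-protease site: (label, predicted domains)
examples = [
    (1, {"Eukaryotic aspartyl protease"}),           # found -> TP
    (1, {"Protein kinase domain"}),                  # missed -> FN
    (0, {"Retroviral aspartyl protease"}),           # false alarm -> FP
    (0, set()),                                      # clean -> TN
]
op = mapped_confusion(examples, mapping, "ASP_PROTEASE")
print(f"ASP_PROTEASE: TP={op.tp} FP={op.fp} FN={op.fn} TN={op.tn} "
      f"precision={op.precision:.2f} recall={op.recall:.2f}")

try:
    mapped_confusion(examples, mapping, "ZINC_PROTEASE")
except UnscorableSiteError as exc:
    print(f"ZINC_PROTEASE: {exc}")

# Precision/recall here are the annotator's, measured on the site's own
# positive/negative examples through the domain mapping.
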