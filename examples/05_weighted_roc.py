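"""Superfamily-weighted ROC and pAUC of a ranked homology hit list.

Hits are labeled from a SCOP-style annotation (same superfamily = TP,
cross-fold = FP, same fold/different superfamily = unknown), weighted by
1/|query superfamily|, and scored by the partial AUC up to one weighted
false positive per query on average.
"""

from profgen.evaluation import (
    ScopAnnotation,
    label_hits,
    pauc,
    relative_sensitivity,
    weighted_roc,
)

annotation = ScopAnnotation(
    {
        "d1": ("a", "a.1", "a.1.1", "a.1.1.1"),
        "d2": ("a", "a.1", "a.1.1", "a.1.1.2"),
        "d3": ("a", "a.2", "a.2.1", "a.2.1.1"),
        "d4": ("b", "b.1", "b.1.1", "b.1.1.1"),
    }
)
hits = [
    ("d1", "d2", 1e-12),  # true homolog, found first
    ("d3", "d4", 1e-4),   # cross-class false positive
    ("d2", "d1", 1e-3),   # true homolog, found late
]
labeled = label_hits(hits, annotation)
print("labels:", [h.label for h in labeled])

curve = weighted_roc(labeled, annotation)
print("weighted ROC points (FP, TP):", list(zip(curve.fp.round(2), curve.tp.round(2))))

fp_budget = annotation.n_superfamilies  # one FP per query on average
value = pauc(curve, fp_budget, tp_max=curve.tp[-1])
print(f"pAUC (FP budget = {fp_budget} superfamilies): {value:.3f}")
print(f"relative sensitivity vs a method with pAUC 0.5: {relative_sensitivity(value, 0.5):.2f}")
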