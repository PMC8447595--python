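"""Diagnostics: how much of the variance is technical?

PCA and hierarchical clustering show whether samples group by batch; PVCA
turns that intuition into numbers by attributing the leading principal
components' variance to annotated factors via random-effects models.
"""

import msbatch as mb

table, annotation, features, _ = mb.simulate(mb.SimulationSpec(seed=42))
normalized = mb.normalize_median(table)

pca = mb.pca_scores(normalized, annotation)
print("PC variance fractions:", [f"{v:.1%}" for v in pca.variance_fraction[:4]])
print(f"({pca.n_features_dropped} incomplete features dropped)")

pv = mb.pvca(normalized, annotation, ["MS_batch", "group"])
print("\nPVCA weighted variance proportions:")
print(pv.proportions.round(3).to_string())
print("a large MS_batch share means feature-level correction is required.")

tab, v = mb.confounding_report(annotation, "MS_batch", "group")
print(f"\nCramer's V(MS_batch, group) = {v:.3f}")
print("V near 0: the design is balanced, batch effects are correctable;")
print("V = 1 would mean batch and biology cannot be separated at all.")
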