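"""Recover a planted gland-enriched protein set from an intensity matrix.

Simulates a tissue panel in which 40 of 500 proteins are 100-fold elevated
in the femoral-gland columns (half the log-effect in seminal fluid), runs
the filter -> z-score -> k-means -> PCA-loading selection, and compares
the result with the planted truth.
"""

import glandscreen as gs

spec = gs.SimulationSpec(n_proteins=500, mean_length=60, sd_length=10,
                         planted_enriched=40, enrichment_fold=100.0,
                         missing_rate=0.1, seed=3)
proteome = gs.simulate_proteome(spec)
matrix, truth = gs.simulate_intensity_matrix(spec, proteome)

result = gs.call_enrichment(matrix, k=6, loading_quantile=0.75, seed=3)

inter = truth & result.enriched_set
union = truth | result.enriched_set
print(f"planted: {len(truth)}, selected: {len(result.enriched_set)}, "
      f"unique-to-gland: {len(result.unique_set)}")
print(f"overlap with planted truth: {len(inter)} "
      f"(Jaccard {len(inter) / len(union):.3f})")
print("top of the gland-intensity ranking:", ", ".join(result.ranking[:5]))
# A Jaccard near 1 means the cluster + loading rule found the planted
# proteins and almost nothing else; at enrichment_fold=1 the same call
# returns an uncorrelated set (no false discovery of structure).
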