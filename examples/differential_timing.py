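"""Call differential replication timing between control and cohesin-depleted
conditions on simulated data with known shifted domains.

Three domains are flipped early<->late by 2 log2 units in the treated
condition. The differential caller standardises per-bin profile differences
into Z scores, converts to two-sided normal p-values, and applies
Benjamini-Hochberg FDR at alpha 0.05 over mappable bins.
"""

import numpy as np

from replitime import (
    GenomeLayout,
    SimulationSpec,
    analyze_condition_pair,
    median_inter_bin_distance,
    simulate_condition_pair,
)

spec = SimulationSpec(
    layout=GenomeLayout.from_pairs([("chr1", 25_000_000), ("chr2", 25_000_000)]),
    depth=800.0,
    n_shifted_domains=3,
    shift_size=2.0,
)
experiment = simulate_condition_pair(spec, seed=3)
analysis = analyze_condition_pair(
    experiment.control, experiment.treated, experiment.truth.mappability
)
result = analysis.differential

truth = experiment.truth
mappable = truth.mappability.values > 0.5
shifted = truth.shifted_bins & mappable
sig = result.significant

print(f"included (mappable, valid in both) bins: {result.n_included}")
print(f"significant bins (FDR-adjusted p < 0.05): {result.n_significant}")
print(f"truly shifted mappable bins:             {shifted.sum()}")
print(f"of which called significant:             {sig[shifted].sum()}")
print(f"false calls outside perturbed regions:   "
      f"{(sig & ~truth.shifted_bins & ~truth.partial_bins).sum()}")
print(f"median distance between significant bins: "
      f"{median_inter_bin_distance(result):,.0f} bases")
# Clustered significant bins (median distance ~ one bin, 50 kb) indicate
# coherent domains of timing change; on null data significant bins are rare
# and dispersed.
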