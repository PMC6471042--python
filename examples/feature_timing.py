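"""Score annotated features by weighted RT in both conditions and select
differentially expressed genes with the standard cutoffs.

Weighted RT summarises all four S-phase fractions into one per-bin value
(1 = earliest, 0 = latest). Feature sets are scored by the mean weighted RT
of overlapping bins; genes pass as induced/repressed with linear fold
change > 2 (or < 1/2), adjusted p < 0.05, and RPKM >= 0.5.
"""

import numpy as np

from replitime import (
    GenomeLayout,
    IntervalSet,
    SimulationSpec,
    analyze_condition_pair,
    paired_feature_rt,
    select_de_genes,
    simulate_condition_pair,
    simulate_gene_table,
)

spec = SimulationSpec(
    layout=GenomeLayout.from_pairs([("chr1", 20_000_000), ("chr2", 20_000_000)])
)
experiment = simulate_condition_pair(spec, seed=5)
analysis = analyze_condition_pair(
    experiment.control, experiment.treated, experiment.truth.mappability
)

rng = np.random.default_rng(5)
genes, truth = simulate_gene_table(spec, rng)
induced, repressed = select_de_genes(genes)
print(f"gene table rows: {len(genes)}; induced: {len(induced)}, repressed: {len(repressed)}")

# score the two DE sets plus random control intervals by weighted RT
random_sites = IntervalSet.from_records(
    [("chr1", int(s), int(s) + 10_000) for s in rng.integers(0, 19_000_000, size=40)]
)
feature_sets = {
    "induced_genes": induced,
    "repressed_genes": repressed,
    "random_sites": random_sites,
}
long_df, summary = paired_feature_rt(
    analysis.control.weighted, analysis.treated.weighted, feature_sets
)
print(summary.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
# pearson_r near 1 with a tiny mean absolute difference says feature-level
# replication timing is unchanged between conditions — the expected outcome
# here, since the simulated DE genes are placed without regard to the
# (unshifted) timing landscape.
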