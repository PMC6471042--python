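# replitime

Analysis of genome-wide DNA replication timing from Repli-seq experiments:
nascent DNA is BrdU-labelled, cells are sorted (or synchronously released)
into S-phase fractions, and each fraction's DNA is sequenced. The proportion
of reads a locus contributes to early versus late fractions measures when it
replicates. `replitime` turns per-fraction read counts into smoothed
replication-timing (RT) profiles, tests for timing differences between two
conditions (e.g. cohesin-depleted versus control cells), scores annotated
features by timing, and relates timing to 3D-genome structure by classifying
TAD boundaries against Hi-C contact domains and building RT metaplots around
them. A synthetic-data generator with full ground truth makes every stage
testable end to end.

## The statistics at the core

For each 50 kb bin *b* (aggregated from spike-filtered 1 kb windows, spikes
being count Z-scores > 2.5):

- **E/L RT**: `rt_b = log2(E_b / L_b)` where `E` and `L` are the early- and
  late-fraction counts (S1/S3 for four sorted fractions, 4h/10h for three
  synchronized timepoints), each scaled to reads per million. Profiles being
  compared are jointly quantile-normalized and loess-smoothed (tricube local
  linear regression, fixed 300 kb genomic span).
- **Differential timing**: `d_b = rt_control,b − rt_treated,b` over mappable
  bins (mappability > 0.5) valid in both profiles;
  `Z_b = (d_b − mean(d)) / sd(d)`; two-sided normal p-values with
  Benjamini–Hochberg adjustment; significant ⇔ adjusted p < 0.05.
- **Weighted RT**: `wrt_b = Σ_i w_i f_ib / Σ_i f_ib` over all fractions'
  reads-per-million `f_ib`, with weights decreasing from earliest to latest
  fraction — a single 0–1 timing scale (1 = earliest).
- **Boundary classes**: a control TAD boundary is *compartment-proximal* if
  an A/B compartment boundary lies within 500 kb, else *invariant* if a
  boundary of the perturbed condition lies within 500 kb, else
  *Scc1-dependent*. RT metaplots average the profile over ±5 Mb windows per
  class, each window oriented so its earlier-replicating side lies left.

## Worked example

`examples/differential_timing.py` simulates a 2 × 25 Mb genome in which
three ~1 Mb domains flip timing by 2 log2 units in the treated condition,
then runs the full pipeline:

```
included (mappable, valid in both) bins: 928
significant bins (FDR-adjusted p < 0.05): 53
truly shifted mappable bins:             54
of which called significant:             53
false calls outside perturbed regions:   0
median distance between significant bins: 50,000 bases
```

53 of the 54 perturbed bins are recovered with no false calls; the 50 kb
median inter-bin distance says the calls form contiguous domains rather than
scattered noise (dispersed, far-apart significant bins are the signature of
experimental noise instead of biology). The other example scripts cover
profile fidelity against a known landscape (`simulate_and_profile.py`,
Pearson r ≈ 0.99), boundary classification and metaplot contrast
(`boundary_classes.py`: RT step 0.49 log2 units at invariant boundaries
versus 0.02 at random positions), and feature-level weighted RT with
differential-expression gene selection (`feature_timing.py`).

A thin CLI mirrors the stages: `replitime simulate | binify | rt | diff |
boundaries | features | correlate | run` (see `replitime --help`).

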