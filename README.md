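# plinet

Phase-lag-index brain network analysis for pre/post ("task aftereffect")
EEG designs: band-limited functional connectivity, weighted-graph and
maximum-spanning-tree topology, and the two-group statistical layer, with a
synthetic coupled-oscillator cohort generator for ground-truth validation.

## The problem

Comparing resting-state brain networks immediately before and after a
cognitive task can expose reorganization that baseline comparisons miss —
for example between healthy older adults and people with mild cognitive
impairment (MCI). The analysis chain has three stages:

1. **Connectivity.** For each ~2 s epoch and frequency band (delta
   0.5–4 Hz, theta 4–8, lower alpha 8–10, upper alpha 10–13, beta
   13–20 Hz), the phase lag index between every electrode pair:

   PLI = | ⟨ sign( sin(φᵢ − φⱼ) ) ⟩ₜ | ∈ [0, 1],

   the asymmetry of the instantaneous phase-difference distribution — 1
   for a consistent nonzero lag, 0 for symmetric or zero-lag/antiphase
   relations, which makes it insensitive to volume conduction and
   reference choice.

2. **Topology.** On the resulting weighted graph: the weighted clustering
   coefficient (mean triangle intensity, the geometric mean of
   max-normalized edge weights) and the weighted characteristic path
   length (mean shortest sum of reciprocal weights), each normalized by
   its mean over the five bands; and on the maximum spanning tree (Kruskal
   backbone, M vertices, M−1 edges, so all subjects are compared at equal
   density): leaf number, diameter, per-vertex eccentricity, and
   betweenness centrality, each normalized by its maximum possible value
   (M−1 for the distance-based measures, (M−1)(M−2)/2 for betweenness).
   Large leaf number and betweenness with small diameter and eccentricity
   indicate an integrated, star-like topology; the opposite a
   decentralized, path-like one.

3. **Statistics.** Per-subject epoch averages; iterative Grubbs outlier
   screening; pre-task group differences by permutation test with
   Benjamini–Hochberg FDR across bands; pre→post modelling with linear
   mixed models (timepoint × group interaction, age/gender/education
   covariates, subject random intercept) with FDR across bands and
   per-group follow-ups; and vertex-wise post/pre eccentricity ratios
   compared between groups with a max-t permutation test controlling the
   family-wise error across electrodes.

Because no recordings are distributed with this package, a synthetic
generator produces cohorts with known pairwise phase-lag coupling,
realistic design and demographics (58 controls / 41 MCI, 30 epochs × 64
channels × 1,024 samples at 500 Hz by default), and injectable
group×timepoint hub effects, so every claim the pipeline makes is testable
against ground truth. See `docs/methods.md` for models, defaults and
limitations.

## Worked example

Simulate one recording in the theta band where channel 0 drives channels
1–7 with coupling strength κ = 0.8 at lag π/4, then recover the hub:

```python
import math
import numpy as np

from plinet import (
    CouplingSpec, CouplingEdge, generate_subject_epochs,
    bandpass, instantaneous_phase, pli_epoch,
    WeightedGraph, maximum_spanning_tree, tree_metrics, normalize_tree_metrics,
)
from plinet.spectral import band_by_name

theta = band_by_name("theta")
spec = CouplingSpec(
    band=theta,
    pairs={(0, c): CouplingEdge(lag=math.pi / 4, kappa=0.8) for c in range(1, 8)},
    noise_sd=0.3,
)
epochs = generate_subject_epochs(spec, n_epochs=30, epoch_samples=1024,
                                 sampling_rate=500.0, seed=7, n_channels=16)

pli = np.mean(
    [pli_epoch(instantaneous_phase(bandpass(e, theta, 500.0), theta)).weights
     for e in epochs.data], axis=0)
print(f"hub-pair PLI  (0,1): {pli[0, 1]:.3f}")
print(f"background PLI (8,9): {pli[8, 9]:.3f}")

tree = maximum_spanning_tree(WeightedGraph(pli))
m = normalize_tree_metrics(tree_metrics(tree), 16)
print(f"leaf number: {m.leaf_number} (normalized {m.leaf_number_norm:.2f})")
print(f"diameter: {m.diameter} (normalized {m.diameter_norm:.2f})")
print(f"max betweenness: {m.max_betweenness} (normalized {m.max_betweenness_norm:.2f})")
print(f"mean eccentricity: {m.mean_eccentricity:.2f}")
```

prints

```
hub-pair PLI  (0,1): 1.000
background PLI (8,9): 0.315
leaf number: 11 (normalized 0.73)
diameter: 6 (normalized 0.40)
max betweenness: 83 (normalized 0.79)
mean eccentricity: 4.75
```

The driven pairs reach the PLI ceiling while uncoupled channels sit at the
band's finite-sample null (~0.3 for theta-filtered 1,024-sample epochs —
well above the 0.025 i.i.d. chance level because band-limited phases are
autocorrelated). The spanning tree is star-like around the hub: many
leaves, high maximum betweenness, small diameter. On 16 random uncoupled
channels these metrics drift toward the path-like end instead.

Full cohort runs go through the pipeline (or the `plinet` CLI: `simulate`,
`reject`, `connect`, `metrics`, `stats`, `run`):

```python
from plinet.pipeline import RunConfig, AnalysisConfig, run_pipeline
from plinet.synth import CohortConfig, EffectSpec

config = RunConfig(
    output_dir="out",
    bands=("theta",),
    cohort=CohortConfig(n_control=12, n_mci=12, n_epochs_per_subject=10,
                        n_channels=16, epoch_samples=512, seed=1),
    coupling={"theta": {"noise_sd": 0.3}},
    effect=EffectSpec(target_group="MCI", target_timepoint="post",
                      hub_channels=(0,), coupling_increment=0.8),
    analysis=AnalysisConfig(n_perm=1000, seed=1),
)
report = run_pipeline(config)   # writes measures.csv, results.csv, report.json, ...
```

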