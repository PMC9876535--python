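# Methods

`plinet` implements a task-aftereffect resting-state EEG network analysis:
from epoched multichannel signals to band-limited phase-lag-index (PLI)
connectivity, to weighted-graph and maximum-spanning-tree (MST) topology
measures, to pre/post two-group statistics. A synthetic coupled-oscillator
cohort generator provides ground truth for every stage. This note records
the model, the defaults and why, the numerical choices, and what the
synthetic validation does and does not establish.

## Spectral decomposition and phase

Epochs (default 1,024 samples at 500 Hz, i.e. ~2.05 s) are analysed in the
five canonical bands: delta 0.5–4 Hz, theta 4–8 Hz, lower alpha 8–10 Hz,
upper alpha 10–13 Hz, beta 13–20 Hz. Filtering uses a zero-phase
(forward–backward) 4th-order Butterworth band-pass, applied per epoch with
reflective padding of one epoch length. A zero-phase IIR design was chosen
because phase distortion would bias the PLI directly; per-epoch filtering
reflects that epochs are the unit of analysis and need not be contiguous.

Instantaneous phase is the angle of the analytic (Hilbert) signal of the
band-limited trace. Because the FFT Hilbert transform assumes periodicity,
the epoch is reflectively extended by one epoch length on each side and the
central segment kept; without this, edge phase errors alone measurably
depress the PLI of perfectly coupled pairs.

Epoch rejection discards any epoch whose absolute amplitude exceeds a
threshold on any channel at any sample. The default threshold is 100 µV
(the conventional artifact criterion at this scale); it is configurable.

## Phase lag index

For two phase series, PLI = |⟨sign(sin(φ_i − φ_j))⟩| ∈ [0, 1]. Working
through sin(Δφ) avoids phase-wrapping branch issues. Two numerical
conventions matter:

* `sign(0) := 0` — samples with Δφ exactly 0 or π contribute nothing;
* |sin Δφ| < 1e-9 is treated as exactly zero, so the defining invariance
  (PLI = 0 for zero-lag and antiphase relations, hence insensitivity to
  volume conduction and reference choice) holds despite floating-point π.

The finite-sample chance level of the estimator on independent phases is
E|mean of n i.i.d. ±1 signs| ≈ √(2/(πn)) ≈ 0.025 at n = 1024. For
*band-limited* signals the phases are autocorrelated within an epoch, so
the null PLI of uncoupled channels is substantially higher (≈ 0.2–0.4
depending on bandwidth). Both levels are verified in the test suite; null
comparisons for generated data therefore always use a matched Monte-Carlo
null rather than the i.i.d. formula.

## Weighted-graph measures

The PLI matrix defines a dense weighted graph on the electrodes. Triangle
intensity is the geometric mean of the triangle's three edge weights, each
normalized by the maximum weight in the graph. The weighted clustering
coefficient of a vertex averages intensity over **all** (M−1)(M−2)/2
triangles through it, zero-weight triangles contributing zero. On a dense
PLI graph this complete-graph denominator is the only well-defined reading:
degree-based denominators would require a threshold that is never
introduced. The global coefficient is the vertex mean.

Path length uses reciprocal weights: the inverse weighted length of a path
is Σ 1/w over its edges, the weighted distance the minimum over connecting
paths (Dijkstra; zero weights are absent edges, disconnected pairs are
infinite and propagate — with a log entry — into the characteristic path
length, the mean over unordered vertex pairs).

For band-profile comparisons each subject-level weighted measure is
normalized by its mean over the five bands, **after** epoch averaging (the
normalization operates on subject-level band profiles; the stage ordering
is a package decision since either order is defensible).

## Maximum spanning tree

Kruskal's algorithm on the dense PLI matrix, scanning edges by (descending
weight, ascending lexicographic vertex pair). The explicit tie-break makes
the tree deterministic across runs and platforms — PLI ties are common at
low precision and different tie rules give different, equally maximal
trees. Zero-weight edges are admissible (with a warning) so a spanning tree
always exists. Edge weights are discarded after construction; every tree
has M vertices and M−1 edges, which is what makes tree topology comparable
across subjects without density bias.

Tree measures (distances in edges along the unique path): leaf number
(degree-1 vertices), diameter, per-vertex eccentricity, and betweenness
centrality — the number of unordered vertex pairs whose unique path crosses
the vertex, computed via component sizes of the vertex-deleted forest:
BC(v) = C(M−1, 2) − Σ_c C(size_c, 2). Normalization divides leaf number,
diameter and eccentricity by M−1 and betweenness by (M−1)(M−2)/2 — the
maxima attained by the star (leaf number, betweenness) and the path
(diameter, eccentricity), verified against the nine-vertex star/path
worked examples (8/2/28/1.9 and 2/8/16/6.2). Mean eccentricity is also
normalized by M−1; since the worked examples are unnormalized, this is the
convention we adopt and document rather than a testable fact.

## Statistical layer

Per-epoch measures are averaged to one value per subject × timepoint ×
band × measure. The analysis then proceeds:

1. **Outlier screening.** Iterative two-sided Grubbs test (critical value
   from the Student-t quantile formula), default α = 0.05, applied per
   group × measure × band on subject-level values pooled over both
   timepoints; a flagged subject is excluded from that measure × band
   everywhere. The iteration stops when nothing is flagged or fewer than 3
   values remain; zero-variance samples yield no outliers.
2. **Pre-task group differences.** Two-sided permutation test on the
   difference of group means, Monte-Carlo p = (1 + #{|stat*| ≥ |stat|}) /
   (n_perm + 1), default 10,000 permutations, seed mandatory; exact
   enumeration available for small groups. Benjamini–Hochberg FDR across
   the five bands within each measure. (BH-adjusted values are monotone and
   dominate the raw p-values; they are *not* idempotent, so only the former
   are asserted.)
3. **Mixed models.** value ~ timepoint + group + timepoint×group + age +
   gender + education with a subject random intercept (REML). Coding:
   pre=0/post=1, control=0/MCI=1, female=0/male=1, age and education
   mean-centred — the interaction coefficient is then the MCI-specific
   pre→post increment. Inference is by Wald z tests on the fixed effects
   (statsmodels MixedLM); calibration simulations confirm near-nominal
   type-I error at the cohort sizes used here. A random timepoint slope is
   available as an option but is weakly identified with only two occasions
   per subject, so the default is intercept-only. Singular fits are
   flagged, never silently accepted; subjects missing a timepoint are
   dropped with a log entry. FDR across bands per effect family; per-group
   follow-up models run where the timepoint or interaction effect survives
   FDR at 0.05.
4. **Vertex maps.** Where the mean-eccentricity interaction is significant
   (or when forced by configuration), per-vertex post/pre eccentricity
   ratios (ratio < 1 ⇔ the vertex became more central) are compared between
   groups with a two-sample pooled-variance t per vertex, referred to the
   permutation distribution of the maximum |t| over vertices — family-wise
   error control across channels with the same +1-corrected p-value
   convention.

## Synthetic cohort generator

The generator defines the study conditions: 58 controls and 41 MCI
subjects by default, each with pre- and post-task recordings of 30 epochs
× 64 channels × 1,024 samples at 500 Hz; covariates drawn per group from
the cohort demographics (age 71.1 ± 6.2 vs 73.7 ± 7.2 years, education
15.3 ± 2.3 vs 14.5 ± 2.4 years, 91% vs 85% female), independent of the
signal model unless an effect couples them.

Each channel carries a constant-amplitude oscillator cos φ(t) whose
instantaneous frequency wanders slowly inside the band: f(t) = f_mid +
0.6·(bandwidth/2)·tanh(g(t)), with g low-pass-filtered white noise (cutoff
min(half-bandwidth, 2 Hz), unit RMS). The constant envelope is deliberate:
with Gaussian-envelope narrowband noise the instantaneous phase is
ill-conditioned at envelope dips, and even a perfectly coupled pair (κ = 1)
failed to recover PLI > 0.99 after the analysis chain; with the
constant-envelope oscillator κ = 1 recovers PLI = 1.0 exactly in every
band. Coupling is lagged-copy mixing, x_j = κ·cos(φ_i − δ) + (1 −
κ)·(independent oscillator); lags δ ≡ 0 (mod π) are rejected because the
PLI is blind to them; expected PLI is monotone in κ (verified by
Monte-Carlo over a κ grid). Optional broadband Gaussian sensor noise is
added on top. Chains of couplings are resolved source-before-target and
cycles rejected.

A group×timepoint effect raises κ by a configured increment on all pairs
incident to designated hub channels in one design cell only (creating
absent pairs at lag π/4; a background pair driving the same target is
replaced). A strong increment drives that cell's MST toward a star centred
on the hub — the recoverable analogue of a shift toward integrated,
hub-dominated post-task topology in the patient group.

Determinism: every recording's seed derives from (cohort seed, subject
index, timepoint index, band index) via `SeedSequence`, so identical
configurations are bit-identical, and epochs are regenerated lazily rather
than held in memory.

**What the generator does not emulate:** volume conduction and a common
reference (the very confounds PLI is designed to resist), 1/f broadband
background, artifacts (blinks, muscle), spatial correlation structure of a
real montage, and between-subject variability beyond sampling noise
(coupling strengths are identical within a group). Passing tests therefore
establish correctness and calibration of the *pipeline*, not realism of
any particular effect size in real recordings.

## Problem sizes and runtime choices

Library defaults are full study scale (64 channels, 1,024-sample epochs,
30 epochs, 58/41 subjects, 10,000 permutations). Tests and the acceptance
script run the same code at reduced scale, chosen once as the smallest
sizes at which each property is meaningfully testable: oracle equivalence
on ≤ 7-vertex graphs and ≤ 10-vertex trees (exhaustive enumeration),
PLI recovery on 2-channel pairs at the full 1,024-sample epoch length,
null calibration over 500 simulated datasets (15/15 subjects, 32 vertices,
199 permutations), LMM recovery over 200 simulations at 40/40 subjects,
pipeline-level checks at 8–16 channels, 256-sample epochs, 3–8 subjects
per group. Calibration assertions use three-binomial-standard-error bands
around the nominal level; the FWE check is one-sided (at or below nominal),
as max-t is conservative by construction under positive dependence.

## Known limitations

* Wald z (not t) inference for mixed-model fixed effects; anticonservative
  for very small cohorts, negligible at the simulated sizes.
* The Grubbs screen pools timepoints; a per-timepoint variant is not
  implemented.
* No thresholded/binarized graph analysis, weighted PLI, directed
  connectivity, or tree-hierarchy statistic.
* On-disk formats are delimited text and JSON only; standard EEG container
  formats would enter through a reader producing `EpochSet` objects.
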