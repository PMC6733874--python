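# Methods

## The analysis model

A well of 8 larvae is filmed at 25 frames/s through a two-assay battery
(assay 1: six low-amplitude acoustic taps at 10 s spacing over 60 s;
assay 2: three 10 s violet-light pulses, 10 s on / 10 s off, over 60 s).
The motion index is the sum over pixels of absolute intensity differences
between consecutive frames; `MI[t]` carries the timestamp of the later
frame, and stimulus windows are half-open `[onset, onset+duration)`.
Normalization follows `nMI = (MI − min MI)/max MI` — the divisor is
deliberately `max`, not `max − min`, so the output maximum is
`(max−min)/max` and need not reach 1; a constant trace maps to zeros and an
all-zero trace is degenerate (flagged, not an error, inside the pipeline).

Response magnitudes are means over repeated events of the window-maximum
MI. Windows include a 1 s post-stimulus tail (configurable) because a
startle bout outlasts a 70 ms tap; the tail length is a free choice, as is
the tie-break (earliest sample) for equal maxima. Startle AUC uses plain
trapezoidal integration over the raw stimulus window. Z-scores use the
sample (n−1) SD, and "normalized 0–1" is min–max rescaling across the well
set — the only reading that actually yields the stated range.

The **phenoscore** of a well is the Pearson correlation between its raw MI
trace and a reference profile (equivalently 1 minus the correlation
distance), so it lives in [−1, +1], is invariant to positive affine
transforms of either trace, and is symmetric. A fully immobilized
(zero-variance) well scores 0 with a degenerate flag. Traces are compared
on the raw MI grid; lengths may differ by at most one sample (truncated),
anything more is an error.

The **reference profile** is the average of a 12-of-36 subset of replicate
positive-control wells chosen to maximize
`J(S) = mean pairwise r within S − λ · mean r(members of S, DMSO wells)`
with λ = 1. The optimizer is simulated annealing with swap-one-member
proposals, Metropolis acceptance, geometric cooling (×0.995/iteration,
20 000 iterations) and an initial temperature set to the SD of `J` over 100
random subsets; the best subset ever visited is returned, so the answer
never falls below the chain's own optimum. On instances small enough to
enumerate (≤ 8 candidates) the annealer matches exhaustive search in the
test suite.

**Significance cutoffs** are upper quantiles of a simulated null: vehicle
wells generated under the null model and scored against the frozen
reference (the 1 − α quantile per level α). The assay-quality summary is
the standard Z-factor plus a two-sample KS test. Note two deliberate
non-goals: the historically printed cutoffs (0.51/0.71) and a printed
Z-factor of 0.7 are not reproduction targets here — the Z-factor closed
form applied to control means/SDs of (0.7, 0.11) vs (0.1, 0.05) gives 0.2,
and the cutoff-simulation recipe behind those printed values is not
specified anywhere reproducible. The package validates the closed forms and
the quantile machinery instead.

**Hit calling** ranks compounds by mean phenoscore over replicate wells
(mean, not max, for robustness), breaks ties lexicographically by compound
ID so the top-k rule is deterministic, and calls the top k (default 125)
hits. The **immobilization index** is an artifact-defined formalization of
"suppressed light response": `1 − clip(violet_mag / median DMSO
violet_mag, 0, 1)`, 1 meaning fully immobilized. Non-hit compounds with
mean immobilization ≥ 0.9 and phenoscore below the hit floor are toxic;
everything else is inactive; vehicle wells are controls.

**Dose–response** fits are 4-parameter logistic curves on log10
concentration via least squares with multi-start initialization (every
tested concentration × two Hill slopes), EC50 constrained to the tested
span × [0.1, 10]. Flat responses and failed fits return `converged=False`
with diagnostics instead of raising. **Efficacy windows** mark each ladder
concentration strong when its mean phenoscore reaches a cutoff
(conventionally the simulated 5% cutoff) and report the longest contiguous
strong run (first run on ties). The **reproducibility rate** is the
fraction of primary hits whose retests reach the strong criterion at ≥ 1
concentration.

**Cheminformatics.** Tanimoto similarity `|a∧b|/|a∨b|` (an all-zero pair
is defined as 1 — identical emptiness — with a warning, configurable to 0);
average-linkage agglomerative clustering on 1 − Tanimoto, cut to an exact
cluster count; guilt-by-association enrichment
`EF = (annotated fraction among top n)/(background fraction)` with a
hypergeometric upper-tail p-value, an optional rank-permutation p-value,
and Benjamini–Hochberg adjustment across targets (the full
similarity-ensemble machinery with extreme-value background fits is out of
scope — EF is the generic statistic). `npKi = 4 + (−log10 Ki)` with Ki in
the panel's stated unit; micromolar by default, recorded in the panel
metadata because the convention is not universal.

## The synthetic-data generator

No public raw data accompanies this kind of screen, so the generator *is*
the study condition. One well's trace is

    MI(t) = m_w · [ g_b(c)·b(t) + g_a(c)·A(t) + g_v(c)·V(t) ] + ε(t),  clipped at 0

- `b(t)`: baseline activity — Gaussian noise smoothed with a 1 s kernel,
  scaled to relative SD 0.25, clipped positive, times a baseline level of
  2 (arbitrary MI units).
- `A(t)`: alpha-function startle kernels `u·e^{1−u}`, `u = t/0.5 s`, at the
  tap onsets; vehicle peak amplitude 1.9. Each event gets per-well latency
  jitter (Gaussian) and lognormal amplitude jitter — the dominant
  biological variability of startle responses, and the main source of
  well-to-well decorrelation in the positive class.
- `V(t)`: sustained boxcar of amplitude 1.5 per light pulse with an
  exponential onset transient (relative amplitude 1, τ = 0.7 s).
- `m_w ~ lognormal(0, well_noise_sd)`: per-well sensitivity.
- `ε(t)`: white measurement noise, scaled by `sqrt(8/n_fish)` — group size
  acts as a noise-variance divisor only; inter-fish interaction is not
  modeled.

Concentration acts through a Hill law `f(c)` (default EC50 1 µM, slope 2
for the archetype compound; screens run at 10 µM, the reference at
6.25 µM, dose ladders at 7 half-log steps 0.1–100 µM); every class gain
interpolates `g = 1 + f·(g_class − 1)` between vehicle and the class
asymptote, as do the jitter parameters. A second, descending Hill arm
(`ec50_hi`, slope 2) produces the bell-shaped responses behind narrow
efficacy windows.

Class asymptotes (baseline / acoustic / violet gain; well, measurement
noise; latency, amplitude jitter):

| class          | g_b  | g_a | g_v  | σ_well | σ_meas | lat (s) | amp  |
|----------------|------|-----|------|--------|--------|---------|------|
| dmso/inactive  | 1    | 1   | 1    | 0.08   | 0.92   | 0.05    | 0.10 |
| etomidate_like | 0.35 | 5.0 | 0.12 | 0.50   | 1.35   | 0.25    | 0.40 |
| toxic          | 0    | 0   | 0    | 0      | 0.02   | —       | —    |
| stimulant      | 2.0  | 1.5 | 1.2  | 0.25   | 1.0    | 0.15    | 0.25 |

These constants are the generator's documented calibration: they were set,
once, so that the full pipeline (annealed reference, then correlation
scoring) reproduces the control-arm phenoscore statistics the analysis is
designed around — positive wells ≈ 0.71 ± 0.11, vehicle wells ≈ 0.2 ±
0.05 — while also satisfying the generator's separation contracts
(acoustic-magnitude AUROC ≥ 0.95, phenoscore AUROC ≥ 0.99 between the
classes, silent toxic wells). An earlier calibration that carried all
positive-class decorrelation in white measurement noise met the phenoscore
targets but drowned the window-maximum response magnitudes; shifting that
variance into event-level startle jitter is both the more faithful
behavioral model and the reason the magnitude contracts hold.

Randomness contract: every generator takes one root seed and derives
hierarchical per-well substreams (`SeedSequence([seed, stream, index])`),
so identical inputs are bit-identical and adding wells never perturbs
existing ones.

What the generator does **not** emulate: swim kinematics or per-larva
movement (frame synthesis is blob-based, only to exercise the per-pixel
motion index), plate-position and batch effects, habituation across
repeated taps, compound solubility/absorption artifacts, and any real
chemical structure (fingerprints are random bit vectors with planted
cluster structure; SMILES handling exists but synthetic libraries bypass
it). Passing tests therefore demonstrate the *analysis machinery* —
scoring, optimization, calling, fitting, enrichment — under a controlled
generative model, not performance on real screening data.

## Numerical choices and degenerate inputs

- Pearson correlations via `numpy.corrcoef`; annealing objective evaluated
  from precomputed correlation matrices.
- 4PL fitting via bounded `scipy.optimize.curve_fit`; a perfectly flat
  response short-circuits to `converged=False` (EC50 unidentifiable).
- Linkage ties resolved by scipy's smallest-index rule; clustering is
  deterministic given input order and invariant to permutation up to
  relabeling.
- Quantiles via `numpy.quantile` (linear interpolation); α = 1 maps to the
  null minimum.
- Zero-variance wells score 0 with a degenerate flag; zero-variance
  references, zero-SD magnitude vectors, and identical group means raise
  or flag (`z_factor = −inf`) rather than propagating NaNs.
- Problem sizes used by the test suite and the acceptance script (36+36
  reference wells, 472+472 control wells, 200-compound screens, 100-seed
  fit-recovery batches, 1000-replicate null calibrations) were chosen as
  the smallest sizes at which the Monte-Carlo error is comfortably below
  each assertion's tolerance.

## Known limitations

- The immobilization index is this package's own formalization; real
  screens may define the axis differently.
- Permutation p-values are valid but discrete (and hence slightly
  conservative); the KS p-value is likewise a step function — calibration
  tests check rejection rates, not exact uniformity.
- The annealing optimum is only guaranteed relative to its own proposal
  chain; global optimality is verified exhaustively only on small
  instances.
- Enrichment assumes exchangeable compounds under the null; structural
  correlation between hits (which planted clusters deliberately create)
  can inflate enrichment of targets annotated to those clusters — that is
  the guilt-by-association signal itself, not a bug, but it means p-values
  are not independent across targets.
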