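# Methods

This note documents the models, estimators and design choices behind
somnonet: a pipeline that takes stage-scored multi-channel sleep EEG,
estimates directed (Granger-causal) connectivity between the 19 electrodes
of the 10-20 montage, reduces each connectivity matrix to a small-world
coefficient, and compares the coefficients between groups.  A synthetic
cohort generator supplies ground-truth data for every stage of the chain.

## Epoch selection and segmentation

For each analysed vigilance state (wakefulness before sleep onset,
slow-wave-sleep stages 3 and 4, and REM sleep) the pipeline takes the
chronologically *first three* artifact-free 20-s scoring epochs and divides
each into four contiguous 5-s segments, i.e. twelve segments per
subject-stage.  Fixing the count (rather than using all available epochs)
keeps the estimator's variance identical across states and subjects.
Scoring epochs are fixed at 20 s so selected epochs align one-to-one with
scored epochs; time is 0-based with half-open [onset, onset + 20 s)
intervals.  Wake epochs are only eligible before the first non-wake scoring
epoch; sleep-stage epochs are eligible regardless of sleep-cycle position.
Artifact status is an input mask: visual artifact and graphoelement
screening is upstream of this package.

Spectral homogeneity of the twelve segments is quantified per frequency
band as the coefficient of variation (sample std / mean, ddof = 1) of the
channel-averaged Welch band power across segments.  The default threshold
is CV <= 0.5 in every band.  The report is informational: subjects are
never rejected on it, because no quantitative exclusion rule is defined for
this check and silently dropping subjects would change the group tests.

## VAR model and Granger causality

One vector autoregressive model

    x_t = sum_{k=1..p} A_k x_{t-k} + e_t,   cov(e_t) = Sigma

is fitted per subject x stage by pooling the twelve segments as independent
trials: per-segment means are removed, the first p samples of each segment
serve only as lags, and the least-squares regressions are stacked.  Sigma
uses the degrees-of-freedom denominator N - n*p.  The model order is chosen
by BIC (default; AIC available) over 1..p_max on a common response sample
(all candidates trimmed at p_max so the criteria are comparable);
ties go to the smaller order.

Time-domain conditional Granger causality for an ordered pair (j -> i),
given the remaining 17 channels, is

    F(j -> i | rest) = ln( Sigma'_ii / Sigma_ii ),

where Sigma' is the innovation covariance of the *reduced* model without
channel j.  Reduced models are not refit from data: the full model's
autocovariance sequence is computed (companion-form discrete Lyapunov
equation, then the Yule-Walker recursion) out to the lag where it has
decayed below 1e-7 of its spectral radius envelope (capped at 192 lags),
and the reduced model is solved from that sequence by Whittle's multivariate
Levinson-Durbin recursion.  One reduced model per *source* channel yields
the F values for all 18 of its targets, so a 19-channel matrix costs 19
reduced solves.  This single-full-model route is what makes the spectral
decomposition below integrate back to F; refitting reduced models from data
at the same finite order does not have that property, because the reduced
process is generically VARMA rather than VAR(p).

### Spectral decomposition

The spectral causality follows Geweke's conditional construction with the
innovation-partition refinement.  Writing H(lambda) = A(lambda)^-1 for the
full model's transfer function and B(lambda) for the inverse transfer
function of the reduced model (without source j), the reduced-innovation
process of target i has spectral factor Phi(lambda) = B(lambda) H_keep(lambda).
The causality at frequency lambda is the log ratio of that process's total
spectrum to the part driven by the target's own full-model innovation,

    f(j -> i | rest)(lambda) = ln [ (Phi Sigma Phi*)_ii / |Phi_i c|^2 Sigma_ii ],

where c is the column that partializes the other channels' innovations on
the target's (c_k = Sigma_ki / Sigma_ii).  This variant is exact: it matches
the bivariate closed form pointwise to machine precision and its average
over [0, Nyquist] reproduces the time-domain F at ~1e-13 relative error on
both population and estimated models.  The superficially similar "reduced
spectrum minus partialized source contribution" denominator, which is
sometimes used, systematically *undershoots* the time-domain value whenever
the conditioning set contains a confounder (we measured a deficit of a
factor ~2 on a three-node confounder motif), which is why it was rejected.

The spectral grid is 1024 uniform points on [0, Nyquist] (512 in the
default end-to-end configuration); polynomial transfer functions are
evaluated by rFFT when the grid permits.  Band matrices for delta
[0.25, 3), theta [3, 8), alpha [8, 12), sigma [12, 16) and beta [16, 32) Hz
are bandwidth-normalized trapezoidal integrals of f; band edges are
half-open and inserted into the grid by linear interpolation, which makes
band integrals exactly additive.  Every subject-stage records a consistency
report comparing the full-range frequency average with the time-domain
matrix (default tolerance 1% relative, on pairs with F > 0.01).

Values are clamped to >= 0; the largest clamped magnitude is stored and is
at numerical-noise level (< 1e-10) on well-conditioned fits.  Causality is
invariant under common amplitude rescaling of all channels.

The default is pairwise-*conditional* causality (each pair conditioned on
the remaining 17 channels).  A bivariate mode (`mode="bivariate"`) is
available behind a configuration flag: each ordered pair is assessed on its
own marginal pair process, solved from the full model's autocovariance, so
indirect influences routed through third channels register as causality.
The two modes answer different questions and are not interchangeable; the
conditional default matches the multivariate reading of "all possible
pairwise combinations" of electrodes.

## Small-world coefficient

Each connectivity matrix is symmetrized by averaging the two directions,
thresholded to a fixed edge density (default 0.2, i.e. the ceil(0.2 x 171)
= 35 strongest pairs of the 19-node graph; ties break lexicographically),
and binarized.  Fixed density makes the coefficient comparable across
subjects, which the group comparisons require.  The coefficient is

    omega = mean(L_rand) / L - C / mean(C_latt),

with C the mean Watts-Strogatz clustering coefficient (degree < 2
contributes 0), L the characteristic path length (mean shortest-path over
connected ordered pairs; disconnected pairs are excluded and counted), and
the reference terms averaged over 20 degree-preserving surrogate ensembles:
Maslov-Sneppen double-edge-swap randomization (10 swaps per edge — at this
budget L_rand already equals that of fully random degree-matched graphs)
and latticization in which swaps are accepted only when they strictly
reduce the total ring distance of edge endpoints (50 swaps per edge with an
early stop after a swap-free pass; the strict-decrease rule stalls long
before 10 swaps per edge have been useful).  omega is clamped to [-1, 1]
with the pre-clamp value recorded; near 0 means small-world, positive more
random-like, negative more lattice-like.

Two finite-size facts are worth knowing.  First, at n = 19 and mean degree
4 a *perfect* ring lattice has omega ~ -0.24, not -1: the random reference's
path length (2.11) is already 76% of the lattice's (2.78), and even the
Moore bound only allows L_rand/L >= 0.68.  The -1 asymptote needs n >> k.
Second, below mean degree ~4 the lattice reference contains no triangles,
so C/C_latt (and hence |omega| before clamping) is unbounded; the clamp is
doing real work there, and omega should not be interpreted quantitatively
at such densities.

## Group statistics

Reporting mirrors a sex-difference cohort study: medians with P25-P75
(linear interpolation, type-7 quartiles), two-sample Wilcoxon rank-sum
(Mann-Whitney) tests between men and women (exact enumeration when the
pooled tie-free sample has n <= 12, otherwise the normal approximation with
tie and continuity corrections; the method used is recorded per row),
Spearman rank correlations (mid-ranks for ties; binary sex coded woman = 1
so a positive sign means higher values in women), and Bonferroni correction.
The correction family is the five band tests within each stage block
(m = 5); time-domain tests use the global alpha.  The family size is a
configuration knob and is printed in every output, since the choice is a
convention rather than a mathematical necessity.

Four tables are produced: demographics (age, BDI) by sex; small-world
coefficients by stage x domain with the sex comparison; sex-SWC Spearman
correlations over all subjects; and BDI-SWC correlations within each sex
stratum.

## Synthetic cohorts

No recordings ship with the package, so the generator builds data whose
causal ground truth is known, with the statistical structure the analysis
is meant to detect.

**Coupling graphs.** Per subject and stage, a directed Watts-Strogatz-style
graph on 19 nodes: a directed ring lattice (out-edges to the mean_degree/2
= 2 nearest neighbours per side) whose edge targets are rewired with
probability p, conserving every out-degree.  The rewiring probability is
the ground-truth small-worldness dial: ensemble-mean omega of these graphs
rises monotonically with p.

**Stage dynamics.** Each graph is embedded in a stable VAR (default order
3): every channel receives AR(2) damped-oscillator self-dynamics with a
pole pair at one of the stage's characteristic frequencies (wake:
alpha-dominated 10 Hz with a beta component; stages 3/4: delta 0.8-1.2 Hz;
REM: mixed theta/alpha/beta), pole radius ~0.92 with small per-channel
jitter; every graph edge contributes a lag-1 cross coefficient
weight x coupling_strength (default 0.25).  If the companion spectral
radius exceeds the margin (default 0.9) the lag-k coefficients are scaled
by s^k, which scales every companion eigenvalue by s exactly, so stability
is guaranteed in one step.  Innovations are independent per channel with
~5 uV standard deviation.  Recordings concatenate per-stage blocks (16
scoring epochs per stage by default; tests use fewer), each with a burn-in
of 10x the model order discarded; fs = 200 Hz keeps the 32 Hz beta edge
well below Nyquist.  The artifact mask is i.i.d. Bernoulli per scoring
epoch (default 10% artifactual).

**Cohort structure.** 28 men and 16 women by default.  Men's REM rewiring
probabilities are drawn around 0.05, women's around 0.15 (uniform +-0.07,
clipped to [0, 1]); stage-3/4 and wake parameters are identical across
sexes.  The +-0.07 between-subject spread is deliberately wider than the
binomial realization noise of the rewiring itself (sd ~0.04 at p = 0.15
over 76 edges), so that a subject's *parameter* is recoverable from their
realized topology — with a much narrower spread the within-women
correlation target below would drown in realization noise.  Within women,
the BDI score is rank-coupled to the REM rewiring probability through a
Gaussian copula with Pearson parameter 2 sin(pi rho_s / 6) for a target
Spearman rho_s (default 0.6); men's BDI is independent of topology.  BDI
marginals approximate the reported cohort (women median ~4, men ~1);
ages ~25 (men) and ~23 (women).  Setting both rewiring centers equal and
rho_s = 0 yields an exchangeable null cohort.

**What the generator does not emulate:** real EEG morphology (spindles,
K-complexes, eye movements), volume conduction and reference effects,
non-stationarity within stages, realistic artifact structure, or any
physiological sex difference beyond the network-topology effect.  Passing
tests therefore demonstrate that the *pipeline* recovers the planted
structure, not that the physiological claims hold on real recordings.

## BDI-13 scoring

The 13-item short-form Beck Depression Inventory is scored 0-3 per item,
total 0-39, with severity labels 0-4 none, 5-7 subclinical, 8-15 moderate,
>= 16 severe.  (Descriptions of the instrument sometimes state an item
range of 1-3, which is inconsistent with the 0-39 total; 0-3 is the
instrument's convention and the only reading compatible with both.)

## Numerical choices and degenerate inputs

- Reduced-model lag horizon: decay tolerance 1e-7 of rho^k, floor
  max(2p, 8), cap 192.  The Geweke integration identity is insensitive to
  this once the autocovariance has decayed (verified from 64 to 800 lags).
- Transfer functions: batched matrix inversion; a grid point with condition
  number > 1e12 raises a spectral error rather than returning garbage.
- Clamping: negative causalities (numerical noise) clamp to 0 and the
  magnitude is recorded; spectral denominators are floored at the smallest
  positive double before the log.
- Thresholding ties in matrix_to_graph break by fixed lexicographic pair
  order, so graphs are reproducible across platforms.
- Disconnected graphs: path length excludes disconnected pairs and records
  their count; a graph with no connected pair raises an undefined-metric
  error, which the orchestrator records as a per-unit failure.
- C_latt = 0 with C = 0 contributes 0 to omega (the clustering ratio term
  is dropped); C_latt = 0 with C > 0 clamps to the -1 bound.
- Determinism: one master seed derives all per-subject, per-stage and
  per-surrogate seeds via `numpy` SeedSequence keys, so any stage can be
  re-run in isolation with identical results.

## Problem sizes in the shipped tests

The test suite exercises the full chain at sizes chosen for a laptop-class
single-CPU run: 12 x 1000-sample segments per subject-stage (the analysis
geometry), cohorts of 44 subjects at the coupling-graph level for the
20-seed pattern checks, 6+6-subject cohorts for the 200-seed null
calibration, and a 2-subject end-to-end EEG run.  The acceptance script's
stress suite spans 10-60 nodes at densities 0.1-0.4 with 50 seeds per cell
and 20 surrogates per graph.

## Known limitations

- Scalp-level analysis only; no source localization, no volume-conduction
  correction.  Granger causality between scalp channels mixes genuine
  cortical interactions with reference and conduction effects.
- The conditional spectral decomposition assumes the fitted VAR is an
  adequate description; gross model misspecification shows up in the
  integration report, which is recorded but does not halt the run.
- Binary undirected graphs at one fixed density; weighted or directed
  network variants and other small-world indices are out of scope.
- The rank-sum normal approximation is conservative for heavily tied
  samples; heavy ties can arise when many subjects share degenerate
  (boundary) generator parameters.
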