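# Methods

`corticoflow` implements a directed functional-connectivity analysis for
trial-epoched, source-localized EEG ROI time series: a whole-cortex
temporal non-reversibility measure, normalized directed transfer entropy
(NDTE) with circular-shift surrogate inference, a Monte-Carlo functional
hub search, and a within-subject factorial analysis of the
non-reversibility scores. This note describes the models, the estimators,
the defaults and the choices made where the design was genuinely open.

## Data model and synthetic generator

The unit of data is an epoched block: a `(trials, rois, time)` array for
one participant and one experimental condition (attention: active/passive x
cue: intensity/spectral x motion: looming/receding), with a sampling rate
and a parcellation. The default parcellation is the 68-area
Desikan-Killiany cortical atlas; any ROI count is supported.

The synthetic generator draws every block from a stationary linear Gaussian
vector autoregression (VAR). This family was chosen because every estimator
in the pipeline is covariance-based, so closed-form oracles exist for
testing, and because it gives a ground-truth axis for the quantity of
interest: a stationary Gaussian VAR with a **symmetric** coupling matrix and
equal noise variances has symmetric lagged cross-covariances and is
statistically time-reversible, while directed (asymmetric) coupling breaks
that symmetry. Irreversibility is therefore controlled by a single
`asymmetry` parameter that mixes the antisymmetric part of a random base
matrix into its symmetrized version; the coupling is rescaled to a fixed
spectral radius (0.65) so reversible and irreversible variants have
comparable dynamic range. Trials are independent realizations (mirroring
epoched recordings with decorrelating inter-trial intervals), each run
through a burn-in of at least 10x the model order. Stationarity is enforced
by rejecting any network whose companion-form spectral radius reaches 1.

Group datasets emulate the recorded study's conditions: 28 participants, a
2x2x2 within-subject design, 68 ROIs, 1 kHz sampling, 300-sample epochs
(the 0-300 ms post-change analysis window), 40 trials per cell. Between-
participant variability is injected by jittering every coupling weight by
`1 + N(0, 0.05)`. The planted condition effect adds coupling asymmetry
0.45 to the looming x intensity cells on top of a base asymmetry of 0.15.
That effect size was fixed once at design time by a power sizing so that
the planted interaction is reliably detectable at the desk-scale problem
sizes used in the tests (28 participants, 6 ROIs, 8 trials of 200 samples);
at that scale the motion x cue interaction is detected in essentially every
replicate, comfortably above the 0.8 power the test suite requires.

What the generator does **not** emulate: volume conduction / source leakage
(instantaneous mixing across ROIs), 1/f spectra, evoked transients,
artifacts, or non-Gaussian dynamics. Passing tests therefore demonstrate
estimator correctness and statistical calibration on linear Gaussian
networks with known structure — not robustness to leakage or nonstationary
evoked components in real EEG.

## Preprocessing

Trial counts are equalized across the conditions of each participant by
pseudo-selection: the block's recording order is split into as many
contiguous strata as trials to keep and one trial is drawn per stratum, so
kept trials remain spread over the recording. The analysis window (default
0-0.3 s relative to the change event) is cut as a half-open sample
interval. Every series is then double-differenced (`x[t+2] - 2x[t+1] +
x[t]`), unconditionally: broadband EEG is non-stationary over an evoked
epoch and differencing restores stationarity; a KPSS + ADF battery (both at
alpha = 0.05, a series counts stationary only if KPSS fails to reject *and*
ADF rejects) is run before and after for the log, but the pipeline never
branches on it, so the procedure is deterministic.

The shift/embedding depth `T` shared by both connectivity stages is the
first local minimum of the autocorrelation function. Per-trial, per-ROI
ACFs are averaged within block and across the study, and the first-minimum
rule is applied to the grand-average curve (averaging curves before
locating the minimum is more stable than averaging per-series minima; the
per-block alternative is available as `aggregate="mean_lag"`). When the ACF
decays monotonically there is no local minimum; the fallback ladder is
first zero-crossing, then the `max_lag` cap (default 20), logged. A
`t_lag` override pins `T` for either stage.

## Non-reversibility (NR)

For each block, the lag-`T` correlation matrix `FS(i, j) = corr(x_i(t),
x_j(t+T))` is computed per trial and averaged across trials (averaging
avoids spurious transitions across trial boundaries; pooled concatenation
is available as `trial_mode="concatenate"`). The same is done after
flipping each trial in time. Both matrices are mapped elementwise to
Gaussian mutual information, `I = -1/2 ln(1 - r^2)` (nats; |r| clamped at
1 - 1e-9), and

    NR = mean over ROI pairs of (FS_forward_MI - FS_reversal_MI)^2 .

The diagonal is excluded by default (`include_diagonal=False`): self-lagged
terms carry no cross-ROI directionality and only dilute the mean. NR is
nonnegative, zero iff the two matrices agree, invariant to ROI relabeling
and per-ROI affine rescaling, and shrinks toward zero for i.i.d. noise as
the series grows. One NR scalar per participant x condition feeds the
factorial analysis.

## Normalized directed transfer entropy

For source X and target Y with pasts of depth `T` (newest-first,
`X^i = [X_i, ..., X_{i-(T-1)}]`), the directed statistic is

    F_XY = I(Y_{i+1}; X^i | Y^i) / I(Y_{i+1}; X^i, Y^i) ,

the conditional mutual information between the source past and the target's
immediate future given the target's own past, normalized by the total
predictive information both pasts carry. All entropies are Gaussian,
estimated from the joint sample covariance of `(Y_future, X_past, Y_past)`
within a single trial (no cross-trial pooling); the dimension constants
cancel, leaving log-determinant combinations of principal submatrices. A
diagonal jitter of 1e-10 is added once if a covariance is numerically
non-PD; failures are recorded as missing (NaN), never as zero, so
significance masking cannot be biased by silent failures. The ratio is
clipped to [0, 1] (clip events are logged and rare on well-conditioned
data), and F is defined as 0 when the normalizer falls below 1e-12.

One estimator caveat worth stating: for a pair of *white-noise* series the
numerator and denominator are both pure plug-in estimation bias and their
ratio is approximately Beta(T/2, T/2)-distributed — F itself carries no
signal there. For autocorrelated signals (the realistic regime, and the
regime the pipeline produces), the target's own past dominates the
normalizer and F of an unconnected pair is close to 0. In either regime the
inference is carried by the surrogate test, not by the raw F value.

Per trial, F is computed for every ordered ROI pair into a matrix with
targets (inflow) along rows and sources (outflow) along columns, zero
diagonal. The surrogate path evaluates the observed pair and all of its
surrogates in one batched covariance/slogdet computation.

## Surrogate significance, aggregation and C_All

Null distributions per directed pair come from circular time-shift
surrogates (default 100 iterations per pair, rebuilt per trial): the
source series is rotated by an offset drawn uniformly from `[T+1, n-(T+1)]`
— the minimum rotation guarantees the original lag-T alignment cannot be
reproduced — which preserves the marginal distribution and (up to edge
effects) the autocorrelation while destroying cross-series alignment.
Rotating the source rather than the target removes the coupling under test
while leaving the conditioning set (the target's past) intact; the
alternative is available as `surrogate_target="target"`. The one-sided
p-value uses the add-one rule, `p = (1 + #{F_surr >= F_obs}) / (1 + n_iter)`,
strictly positive as required by the normal-quantile transform.

P-values are combined with Stouffer's method twice: across trials within
each participant, then across participants (`1 - Phi(sum_k Phi^{-1}(1 -
p_k) / sqrt(K))`, inputs clipped to [1e-15, 1 - 1e-15]). Missing pairs are
excluded from the corresponding sum and logged; a pair missing everywhere
yields no p-value. Benjamini-Hochberg FDR at q = 0.05 is applied within
each condition over all tested directed pairs (68 x 67 by default; never
pooled across conditions), and the resulting binary mask zeroes the
trial-and-participant-averaged F matrix to give the condition connectivity
matrix `C_All`.

## Flow vectors and hub search

Inflow per ROI is the row sum of `C_All`, outflow the column sum (their
totals agree exactly). The hub score of a subset k is

    G_hub(k) = sum_k C_All_k + a * sum_k G_in(k) - b * sum_k G_out(k)

with (a, b) = (1, 1) for inflow and (-1, -1) for outflow hubs. The
within-subset term sums the full subset x subset submatrix (both
directions); the alternative directed-only reading is a one-line change in
`_subset_score`. `G_in`/`G_out` are the full-matrix flows of each member,
matching the printed use of the global flow vectors. Subset significance
uses 1000 Monte-Carlo permutations, each substituting one uniformly chosen
member with a uniformly chosen non-member and recomputing `G_hub`, with the
add-one p-value. The search sorts ROIs by the mode's flow (descending, ties
broken by ROI index and logged), starts from the top ROI and grows the
prefix while its p-value stays below alpha = 0.05; the full growth trace
(score and p per step) is always returned.

Two properties of this procedure deserve note. First, the substitution test
is anti-conservative for larger prefixes: the tested prefix is by
construction the top-s set by flow, so most substitutions lower the score,
and the search can extend a genuine hub by weak extra members; for that
reason the search result should be read together with its growth trace.
Second, exactly tied flows (which occur on hand-built matrices, not on
estimated connectivity) can mask a genuine two-ROI hub at step one, because
substituting one co-hub for the other ties the singleton score. On
simulated near-equal double hubs, both hubs top the ranking and jointly
enter the final set in the large majority of runs.

`top_fraction_filter` (default 30% of nonzero edges, ties at the cutoff all
retained) exists for display and export only and is never used in
inference.

## Factorial analysis

One NR value per participant and cell enters a repeated-measures ANOVA with
within-subject factors attention, cue and motion: three main effects, three
two-way interactions, the three-way interaction, each tested against its
participant-by-effect error term. All factors have two levels, so every
effect is a single-df contrast and sphericity holds trivially. Partial eta
squared is `F*df1 / (F*df1 + df2)`, which equals `SS_effect / (SS_effect +
SS_error)` exactly in this balanced design. Participants with incomplete
crossings are excluded listwise and logged. Interaction follow-ups run a
separate ANOVA per level of the split factor (default: cue) with p-values
multiplied by the number of follow-ups and capped at 1.

## Numerical and reproducibility choices

- Natural logarithm (nats) everywhere.
- Correlations clamped at |r| = 1 - 1e-9 before the MI map; covariance
  jitter 1e-10; normalizer tolerance 1e-12; Stouffer clip 1e-15.
- All randomness derives from one master seed via `numpy` `SeedSequence`
  counter-based spawning (generator, trial equalization, surrogate offsets,
  hub permutations), so any participant/condition/stage subset is
  reproducible in isolation and full reruns are bit-identical.
- Degenerate inputs fail loudly: constant series (ACF, stationarity),
  zero-variance ROIs (named in the error), inverted or out-of-range
  windows, non-stationary couplings, subsets covering the whole
  parcellation.

## Problem sizes used in the test suite

The statistical tests run at desk scale, chosen to finish in minutes while
leaving comfortable margins: chain recovery uses 3 ROIs x 500 samples x 100
seeds; hub recovery 10 ROIs x 3 trials x 400 samples x 100 seeds per flow
direction; FDR control 6 ROIs x 2 participants x 4 trials with 25 surrogate
iterations x 50 seeds; the factorial power check 28 participants x 8
conditions x 8 trials x 200 samples x 6 ROIs x 200 replicates; and the
demonstration pipeline 5 participants x 6 ROIs x 10 trials with the full
100-surrogate, 1000-permutation protocol. The acceptance script re-runs the
same computations at the sizes recorded in its output.

## Known limitations

- Gaussian, linear estimators throughout: nonlinear or cross-frequency
  coupling is invisible by design (no kernel/kNN transfer entropy).
- No leakage correction: on real source-localized EEG, instantaneous
  mixing inflates zero-lag dependence and can bias directed estimates; the
  generator does not model it, so the tests do not probe it.
- The normalized F of a white-noise pair is uninformative (see above);
  inference must go through the surrogate test.
- The hub substitution test is anti-conservative for larger subsets; read
  final sets together with their growth traces.
- Per-trial covariances at 68 ROIs need epochs comfortably longer than
  `2T + 2` samples after differencing; short windows with large `T` degrade
  conditioning (failures are recorded as missing pairs).
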