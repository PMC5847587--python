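# Methods

This note documents the models, numerical choices, and design decisions
behind `devfmri`, and what the synthetic generator does and does not
emulate.

## Analysis pipeline

### Acquisition geometry

All analyses assume one functional run of `n_volumes` TRs (default 168 at
TR = 2 s) of which the first `discarded_leading` (default 10: pre-stimulus
rest plus opening logos) are never analyzed, leaving a 158-TR analysis
window reported as "TRs 11:168". TR indices are 1-based and inclusive
everywhere — in files, in event tables, and in reports.

### Timecourse preparation

The preparation order is fixed: detect artifacts → interpolate → nuisance
regression → high-pass → voxel averaging per ROI → set artifact TRs
missing. Choices worth knowing:

* **Artifact detection.** A TR is flagged when the composite motion step
  relative to the previous TR exceeds 2 mm, or the global signal (mean over
  all series) deviates from its mean by > 3 s.d. The composite-motion
  helper combines translation deltas (Euclidean norm) with rotation deltas
  projected at a configurable 65 mm head radius; the global-signal s.d. is
  computed on the full run before scrubbing. Both conventions are
  configurable because rigid standards do not exist.
* **Interpolation.** Nearest unflagged neighbor; equidistant ties go to the
  *preceding* TR (deterministic and causal). Idempotent by construction.
* **Scrubbing.** One indicator regressor per flagged TR, which makes the
  residual at that TR exactly zero regardless of the interpolated value;
  interpolation still matters because the noise-component PCA and the
  high-pass basis see the filled-in data.
* **Noise components.** The first five principal-component time series of
  the (per-voxel temporally centered) noise-voxel matrix, computed after
  interpolation. Voxel series are not variance-normalized; with roughly
  homogeneous noise regions the difference is negligible and the
  unnormalized convention keeps the components' variance ordering
  interpretable.
* **M1 regression.** For connectivity analyses the interpolated (otherwise
  raw) bilateral-M1 average is regressed from the ToM and pain series —
  not from the M1 series themselves, where self-regression would leave the
  two hemispheres as exact mirror images. This guards the network
  summaries against global developmental signal shared with motor cortex.
* **High-pass.** Residualization against a discrete-cosine basis with
  `floor(2·N·TR/cutoff)` functions (cutoff 100 s → 6 regressors at the
  default geometry), the convention of SPM-style pipelines. Measured on
  sines: a 50 s period passes at ≥ 0.99 amplitude, a 400 s period is
  attenuated by > 90%. The constant term is always removed.

Subjects with ≥ ⅓ of TRs flagged are excluded before any group statistic.

### Network correlations

Fisher z = atanh(r) over pairwise-complete analyzed TRs. Pairwise (rather
than listwise) deletion keeps the most data per pair; with a shared
artifact mask the two coincide. |r| = 1 is capped at 1 − 1e−15 with a
logged warning so degenerate inputs stay finite. Within-network summaries
average unordered distinct same-network pairs; the non-bilateral variants
drop left/right homologue pairs, which carry the strongest correlations in
young children and could otherwise mask network immaturity.

Partial rank correlations residualize the rank-transformed variables on
the rank-transformed covariates (intercept included) and correlate the
residuals — Pearson for the Spearman variant (t-test p, df = n − 2 − k),
Kendall tau-b with the normal-approximation p for the Kendall variant
(ties are routine in item-count scores, hence tau-b). With no covariates
both reduce exactly to the plain rank correlation.

OLS regressions default to a fully standardized scale — response *and*
predictors z-scored — so a binary group effect appears as a magnitude-
order-one coefficient comparable across measures; this is the scale on
which such effects are conventionally reported for these analyses, and a
raw-scale mode is available. This was a genuinely open choice: published
group coefficients near ±1 on Fisher-z outcomes whose raw spread is ~0.1
are only reachable if the response is standardized too.

### Reverse correlation

Per-TR one-tailed (positive) one-sample t-tests across subjects at
α = 0.05 uncorrected; the level is deliberately exposed in configuration
because any specific uncorrected α is a convention. Subjects missing at a
TR drop out of that TR's test, so the df varies across TRs; an all-missing
TR is non-significant and logged. Events are runs of ≥ 2 consecutive
significant TRs; a single significant TR is never an event. Peaks take the
earliest TR on ties; equal peak magnitudes rank by earlier onset. Child
analyses reuse adult-defined events; a separate detection call on any
child subgroup supports group-specific event discovery.

### Overlap permutation null

Both event sequences are rebuilt independently per permutation: durations
preserved as a multiset, order uniformly scrambled, interior gaps ≥ 1 TR
(adjacent same-network events would merge into one), flanks ≥ 0, and the
leftover non-event TRs distributed *uniformly over all valid integer gap
compositions* (stars-and-bars after reserving one TR per interior gap).
Uniform-over-compositions is the least-informative reading of "a random
proportion of zeros between events", and it makes the sampler exactly
enumerable on small cases — the test suite checks the empirical placement
distribution against exhaustive enumeration. The p-value counts
permutations with overlap **≤** observed (ties included). For the
canonical structure (7 ToM events/33 TRs, 12 pain events/42 TRs, 158 TRs)
the null mean overlap is ≈ 33·42/158 ≈ 8.8 TRs and P(overlap ≤ 1) lands
near 0.005–0.01.

### Functional maturity

Pearson correlation between a child's network-average timecourse —
averaged *without* per-ROI z-normalization — and the adult template (per-TR
mean over adults passing exclusion; children never contribute), over
jointly non-missing TRs in the analysis window (pairwise deletion).
Maturity is then regressed (standardized OLS) on across-network z,
within-network z, age, and motion, plus the reverse regression and the
behavior/false-belief contrasts.

### Behavior

The battery score is the proportion correct of 24 matched items; the
false-belief composite counts 6 items (pass 5–6, inconsistent 3–4, fail
0–2), classified only for ages 3–5 (others `not_applicable`). The two
control items are validated but only logged on failure. The six FB items
are scored as separate columns from the 24 matched items; whether the
published battery embedded them among the 24 is ambiguous, and keeping
them separate makes both readings computable. DCCS enters as a given 0–3
summary; trial-level scoring is out of scope.

## The synthetic cohort generator

The generator exists so that every stage is testable without imaging data.
Per subject the ROI×TR matrix is

  x_i(t) = w_N·u_N(t) + c_N·a(t) + A_N·R_N(t) + b·p_k(t) + g·G(t)
           + physio + drift + ε_i(t) + spikes,

with u_N a within-network latent, a(t) a single cross-network coupling
latent with network-signed loadings, R_N the HRF-convolved event
regressor (unit variance over the window), p_k extra shared signal for
bilateral pairs, G a small global signal, and ε i.i.d. unit-variance
noise. Spikes are large additive deviations at randomly chosen TRs that
simultaneously push the motion trace over the 2 mm threshold, so artifact
detection, scrubbing, interpolation, and the exclusion rule are exercised
jointly.

**Moment matching.** Loadings are solved per subject from target Fisher-z
moments that interpolate linearly in age between age-3 and adult
endpoints: within-ToM 0.21 → 0.48, within-Pain 0.23 → 0.35, across
+0.05 → −0.17 (adult reference age 25, clipped outside [3, 25]). A target
pair correlation r requires shared variance v = r·s²/(1 − r) against the
non-shared variance s²; the within budget is then split into the event
term A², the coupling share |cov|, and the bilateral share, with the
within-network latent taking the remainder (floored at zero with a
warning). The across-network covariance budget subtracts the
event-regressor cross-covariance A_T·A_P·ρ_R before sizing the coupling
loadings. Realized post-pipeline moments land within a few hundredths of
the targets; the test suite checks them to ±0.10, a deliberately generous
calibration band.

**Two developmental axes.** Within-network integration follows
chronological age; cross-network coupling and event amplitude follow a
*developmental age* = age + N(0, 2 y) jitter, shared with the behavioral
ability latent. Conditional on age, a child who is developmentally ahead
therefore has more anti-correlated networks, larger event responses, a
more adult-like timecourse, and a better battery score — so the maturity
regressions find an across-network effect but no within-network effect
given age, which is exactly the structure those analyses are meant to
detect, as generator ground truth rather than accident.

**Event structure.** The default event table partitions 33 ToM event TRs
over 7 events and 42 pain event TRs over 12 events (the analyzed 158 TRs
minus 125/116 non-event TRs; where printed totals in seconds disagree with
these TR counts by one TR, the TR counts win). Durations come from a
truncated-normal draw (floor 2 TRs, fixed internal seed, draw s.d.
inflated ×1.8 to offset the shrinkage from flooring and exact-sum repair)
targeting mean/s.d. ≈ 9.7(4.2) s and 7.2(4.7) s; realized s.d.s are
somewhat below the targets because a 2-TR floor at a 3.5-TR mean caps the
achievable spread. Events interleave across networks with exactly one TR
where a ToM event's last TR is a pain event's first. Per-event amplitudes
decay linearly with rank label so ranking is recoverable. The HRF is a
double gamma with 5 s peak and 15 s undershoot sampled at the TR; event
regressor peaks therefore lag onsets by ~2–3 TRs, and detected event
boundaries in simulated data are hemodynamically delayed copies of the
table — boundary-recovery tests use direct boxcars instead.

**Cohort composition.** Default 122 children (ages 3.5–12, bottom-heavy:
65 of 122 under six, matching the developmental sampling such studies
need) and 33 adults (18–39). Child artifact rates average ~10.5 flagged
TRs vs. ~2.8 for adults, independent of age. The behavioral model is a
logistic item-response model: ability linear in developmental age, 24 item
difficulties spanning the 3–12-year ability range, 6 easier false-belief
items near the 4–5-year level, near-ceiling control items, and a weakly
age-related DCCS (0–3) for under-sixes.

**What the generator does not emulate.** No voxel-level image synthesis,
no physiological (cardiac/respiratory) noise structure, no registration or
smoothing artifacts, no age-dependent hemodynamics, no spatial
autocorrelation between ROIs beyond the explicit latents. Passing tests
therefore demonstrate that the *analysis code* recovers the statistical
structure it targets under realistic noise, artifact, and sample-size
conditions — not that any particular empirical developmental claim holds
in real data.

## Problem sizes and determinism

Simulation-based tests use the cohort sizes of the study design they
emulate (n = 122 children, n = 33 adults, 17 three-year-olds), 20
replicate cohorts for detection-rate checks, and 10,000 permutations for
the overlap null; all stochastic stages take explicit seeds and the
pipeline writes a manifest (config hash, seeds, versions) from which a run
is byte-identically reproducible. Degenerate inputs fail loudly:
constant series where a correlation is required, rank-deficient designs
(with the collinear columns named), all-flagged runs, infeasible event
durations, out-of-range composites.

## Known limitations

* The ART-style composite-motion formula and the global-signal scrubbing
  order are conventions, not standards; both are configurable and the
  defaults are documented above.
* The per-TR test level for event discovery (α = .05 uncorrected) is a
  convention; event counts depend on it.
* Partial Kendall p-values use the tau-b normal approximation on rank
  residuals; at n < ~15 they are approximate.
* The default ROI centers are nominal MNI coordinates for synthetic work
  and sphere extraction; real studies should supply their own ROI table.
* The generator's event amplitudes are bounded by the within-network
  correlation budget (a strongly event-driven network is necessarily
  internally correlated), so very large evoked responses cannot coexist
  with low within-network correlations in simulated data.
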