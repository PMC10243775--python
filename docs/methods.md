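# Methods

## Problem and model

`netgc` infers *directed* functional connectivity between cortical
patches from multichannel MEG-style sensor recordings.  A directed
Granger-causal (GC) link j → i exists when the past activity of patch j
improves the statistical prediction of patch i's activity beyond what
patch i's own past (and everything else in the model) provides.

The generative model is a linear state-space system.  Source activity
x_t ∈ R^n (n scalar components spread over P cortical patches, k
components per patch) follows a second-order vector autoregression,

    x_t = A1 x_{t-1} + A2 x_{t-2} + w_t,     w_t ~ N(0, Q),

and is observed through a known forward (gain) matrix G with isotropic
sensor noise,

    y_t = G x_t + v_t,                        v_t ~ N(0, r I).

Cross-patch coupling lives in the off-diagonal k×k blocks of A1 and A2.
The model is fit *directly in sensor space* — there is no intermediate
source-localization step whose spatial bias would otherwise propagate
into both endpoints of every connectivity estimate.

## Estimation

Parameters (A1, A2, diagonal Q, scalar r) are estimated by penalized
EM on the companion form z_t = [x_t; x_{t-1}]:

- **E-step**: Kalman filter and Rauch–Tung–Striebel smoother, written
  with numba.  The Riccati recursions converge geometrically, so the
  covariance sequences are frozen once consecutive iterates agree to
  1e-12 (steady-state filtering); only the mean recursions continue.
  The approximation error is ~1e-13 in the log-likelihood, far below
  the 1e-8 slack allowed on the EM trace.  Setting `freeze_tol=0`
  disables freezing.
- **M-step** (ECM — each update is a conditional maximizer, so the
  penalized objective is non-decreasing): closed-form row-wise update
  of [A1 A2] with a group-ridge penalty (λ/2)·Σ‖cross-patch entries‖²;
  then the innovation variances q_ii; then r.
- **ECME for r**: every fifth iteration r is instead set by a bounded
  1-D search on the *observed-data* likelihood.  The plain EM update
  for r converges sublinearly when the optimum sits near the noiseless
  boundary; the direct search jumps there.  Candidates are accepted
  only when they do not decrease the likelihood, preserving the
  monotone trace.
- **Initialization** is deterministic and data-driven: a ridge source
  estimate x̂ = (GᵀG + αI)⁻¹Gᵀy (α = 0.1·tr(GᵀG)/n), a row-wise OLS
  VAR(2) on x̂ (shrunk to companion spectral radius ≤ 0.98 if needed),
  residual variances for Q and r.  Fits are therefore reproducible
  without any seed.
- Data are standardized by their global RMS before fitting, which makes
  deviances and detected networks exactly invariant to sensor scaling.
- r is floored at 1e-3 on the standardized scale (−30 dB of total data
  power).  For exactly noiseless synthetic data the likelihood's
  infimum in r sits at the boundary r = 0 and EM would crawl forever;
  the floor is shared by full and reduced fits so their comparison
  stays meaningful.  q_ii is floored at 1e-10.

The penalty weight λ is chosen by held-out log-likelihood: fit on the
first 80% of samples for each candidate in a small grid, score the
Kalman filter likelihood of the remaining 20%, keep the best.

## Link testing

For every ordered patch pair (j → i) a reduced model is refit with the
(i ← j) blocks of A1 and A2 constrained to zero, warm-started from the
full fit.  The test statistic is the deviance

    D_{j→i} = 2 (obj_full − obj_reduced),  floored at 0,

where `obj` is the penalized objective (log-likelihood minus penalty;
with λ = 0 this is the plain likelihood ratio).  The penalized scale is
used because full and reduced *optima* are nested on it — any reduced
solution is a feasible full-model point — whereas their raw likelihoods
need not be once λ > 0.  Two safeguards make the non-negativity
structural rather than aspirational: reduced refits get a generous
iteration budget (200; stopping them at a couple of dozen iterations
demonstrably inflates the deviances of pairs that reverse a strong true
link), and if a reduced refit nevertheless ends above the full fit, the
full fit is re-run warm-started from that solution before any deviance
is computed.  A pre-floor deviance below −1e-6 aborts the analysis.

D is referred to a chi-square distribution with df = 2·k_src·k_dst (two
lags × the zeroed cross-block), after an *empirical-null scale
calibration*: because the tested map is sparse (almost all ordered pairs
are null), the median deviance per df class estimates the null scale,
and all deviances are divided by max(1, median(D)/median(χ²_df)) before
the p-values are formed.  The calibration matters because latent-state
estimation can systematically inflate null deviances in unlucky
configurations — when two nodes share a strong driver or sit on a
strong reverse link, the imperfectly inferred source of one genuinely
helps predict the other, a bias that persists at full convergence and
grows with recording length.  Median matching restores the chi-square
reference in such maps (observed scales up to ~1.3 at the simulated
operating points) and leaves well-calibrated maps untouched, at a small
power cost (~5% of true links in simulation).  The raw chi-square
p-values are reported alongside the calibrated ones.

This scale calibration is a deliberately simpler substitute for the
original network-localized GC method's debiased, non-central-chi-square
reference, which is not reproduced here; the calibration quality is
demonstrated empirically by the FDR simulations below.

Significance over the map of m = P(P−1) tested pairs is controlled with
the Benjamini–Yekutieli step-up rule at q = 0.001 (0.1% FDR): reject the
k largest-ranked p-values with p_(k) ≤ k·q/(m·c(m)), c(m) = Σ 1/i,
valid under arbitrary dependence; ties at the threshold value are all
rejected.  Each recording (subject × visit) is analysed independently.

An independent comparator, `two_stage_oracle`, fits per-pair
least-squares VAR models on *known* source time courses (synthetic data
only) and applies the same chi-square/BY machinery.  On noiseless
identity-gain instances the sensor-space pipeline and this oracle detect
identical networks; this equivalence is asserted in the test suite.

## ROI summaries and clinical statistics

Detected patch-level networks are collapsed to percentage arrays:
4 bilateral categories (FPC→FPC, FPC→nonFPC, nonFPC→FPC,
nonFPC→nonFPC, hemispheres pooled), where FPC — frontoparietal cortex —
is the union of the `precentral`, `paracentral` and `postcentral`
atlas labels; and, for patients only, 16 lateralized categories
crossing {FPC, nonFPC} × {ipsilesional, contralesional} for source and
destination.  Percentages of the total significant link count are used
instead of absolute counts because the absolute number of detections
varies with recording quality.  Zero-link networks yield a flagged
degenerate summary and are excluded from group aggregation.

Recovery classification: a patient is *favourable* when strictly more
than half of the cognitive measures scored at both visits 2 and 3
(MoCA plus up to five z-scored tests: HVLT, verbal fluency, trail
making, ipsilesional pegboard, SDMT) strictly improve; ties count as
non-improvement.  If the visit-3 battery is missing entirely, the MoCA
change alone decides (flagged `fallback_used`).  Applied to the bundled
six-patient reference table this rule reproduces the published
favourable/unfavourable labels exactly (3 favourable), which is the
reason this particular operationalization — test-level counting with
MoCA included — was frozen.  Impairment flags use z < −1.5 (strict).

Group and visit comparisons on the summary tables use paired t-tests
within group across visits (paired by subject id) and Welch two-sample
t-tests between groups (the groups are independent and of unequal size,
so a paired test is not applicable), Bonferroni-corrected with family
size equal to the category count (4 or 16).  Zero-variance contrasts
are reported as NaN rather than a fabricated p-value.  Stars: * <0.05,
** <0.01, *** <0.001 on adjusted p.

## Synthetic data generator

The generator emulates the structure of a longitudinal minor-stroke
resting-state study so that every downstream stage is testable without
real recordings:

- **Source dynamics**: per-component AR(2) poles resonate at 15–23 Hz
  (beta band) with radii 0.86–0.94; cross-patch blocks are dense at the
  component level, scaled by `coupling_strength`, placed exactly on the
  ground-truth directed edge set, and shrunk by factors of 0.9 until
  the companion spectral radius is ≤ 0.95.  Two further adjustments
  keep the dynamics physically sensible: cross blocks are shrunk until
  no node's stationary variance exceeds twice its uncoupled baseline
  (a cross coefficient at the receiver's resonance otherwise amplifies
  the donor's variance enormously, making the driven node nearly
  deterministic — at which point indirect chains become genuine
  latent-state predictors and weak coupling no longer holds), and the
  innovation variances are then rebalanced so stationary variances sit
  near 1 (grossly uneven source scales badly condition estimation).
  Coefficients are never rescaled to fix variances.
- **Forward model**: patch base topographies drawn from a random
  orthonormal set with a controlled overlap perturbation (0.15), since
  lead fields of distant patches at realistic sensor counts (157) are
  near-orthogonal; within-patch component columns are correlated
  (coherence 0.7).  Columns are unit-normalized.
- **Recordings**: 157 channels, 60 s at 1 kHz by default, isotropic
  Gaussian sensor noise at 25% of the noiseless signal RMS (no empirical SNR
  is being matched; this is a free parameter of the scenario).  Desk-scale tests generate directly at 50 Hz, which the
  preprocessing contract explicitly permits.
- **Cohort scenario** (defaults = the emulated study conditions): six
  patients, four controls, three visits.  Edge sets of 60 directed
  links are sampled with a binomial number of FPC-touching links around
  the per-group per-visit target fraction — patients 0.10 → 0.38 → 0.38,
  controls 0.38 throughout (random pairing over the 84-patch space with
  ~19% FPC patches gives ~0.34) — and with the share of patients'
  inter-hemispheric links oriented ipsilesional→contralesional set to
  0.30 → 0.75 → 0.75 across visits.  At visit 3 the favourable patients
  (and only they) reduce their inter-hemispheric share from 0.45 to
  0.18.  Controls keep one edge distribution across visits.  Clinical
  scores improve everywhere from visit 1 to 2; between visits 2 and 3
  every measure moves by at least 0.4 z-units (up for favourable
  patients, down otherwise) against 0.05 score noise, so the recovery
  classifier is decidable in practice.

What the generator does **not** emulate: artefacts (blinks, cardiac,
line noise — the cleaning stages are identity hooks on synthetic data),
realistic BEM lead-field physics, head movement, inter-subject
anatomical variability, or 1/f background spectra.  Passing tests
therefore demonstrate the correctness and calibration of the analysis
machinery under the assumed model class, not robustness to real-world
artefact structure.

The bundled patch→atlas lookup for the 84-patch (ico-1) space is a
fixed synthetic convention (every Desikan–Killiany label occurs; 8 FPC
patches per hemisphere), *not* an anatomically derived mapping; users
with real data must supply their own.

## Preprocessing

Extract (discard 5 s, keep 55 s; first sample at ceil(discard·fs)),
decimate 1 kHz → 50 Hz in cascaded FIR stages (≥40 dB anti-alias
attenuation; output length floor(n·fs_target/fs)), then a zero-phase
FIR band-pass 13–25 Hz applied forward–backward (Hamming design,
~3.3·fs/Δf taps, 2 Hz transition).  50 Hz sampling puts the upper beta
edge essentially at Nyquist, so the kernel degenerates to a high-pass
at 13 Hz there — no energy exists above Nyquist after decimation.  The
default chain output is exactly 2750 samples per channel.

## Problem sizes used in tests and the acceptance script

Statistical checks run at desk scale, chosen so the full suite and the
acceptance script each complete comfortably on one CPU: FDR simulations
use 6-patch (test suite; 8 s at 50 Hz) and 10-patch (acceptance script;
12 s at 50 Hz, 24 sensors) single-component networks with 200
replicates; oracle-equivalence instances use ≤5 patches; the
duration-sufficiency check compares detections from the first 40 s
against the full 55 s of the same simulated recording; the longitudinal
scenario check runs the generator on the full 84-patch space but
evaluates ground-truth networks (the statistics under test do not
depend on the EM stage, which has its own criteria).  Empirically the
40 s/55 s Jaccard agreement is 1.0 at these sizes and the measured FDR
at q = 0.001 is far below nominal (BY under the harmonic correction is
conservative).

## Known limitations

- The chi-square reference for deviances is approximate at finite
  sample size and with estimated (smoothed) source activity; BY's
  conservatism absorbs the residual miscalibration at the operating
  points we test, but extreme sensor collinearity or much longer
  recordings could change that balance.
- The forward model is assumed known and exact; forward-model error is
  not modelled.
- Q is constrained diagonal in estimation (innovations independent
  across components); the generator satisfies this by construction.
- Group comparisons with n = 6 vs 4 have little power; the scenario
  defaults plant large effects on purpose.
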