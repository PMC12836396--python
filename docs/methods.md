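# Methods

This note documents the models, estimators and design choices behind
`dyadnirs`, including the points where the underlying methodology is
genuinely open and the package had to commit to one reading.

## Synthetic dyadic data generator

The generator (`dyadnirs.synthetic`) defines the study conditions every
other stage is tested under. Each simulated participant's concentration
field is

    ΔHbO₂(c, t) = a_cond · r_cond(t) + h_c sin(2π f_hb t + φ) + g(t) + ε(c, t)
    ΔHHb(c, t)  = −⅓ ΔHbO₂-deterministic part + independent noise

with

* **task response** `a_cond · r_cond(t)`: the condition's 15 s boxcar
  convolved with the canonical HRF, normalised to unit peak so the
  amplitude `a_cond` (default 5·10⁻⁴ concentration units for both
  conditions) *is* the peak evoked response and equals the GLM beta in
  the noiseless limit;
* **cardiac component**: a 1 Hz sinusoid with common phase across
  channels and ±20% per-channel amplitude jitter (default amplitude
  5·10⁻⁴) — large enough that every clean channel shows a detectable
  0.8–1.2 Hz spectral peak, which is what the QC heartbeat rule keys on;
* **systemic drift** `g(t)`: a channel-common low-pass (<0.08 Hz)
  Gaussian process (default amplitude 8·10⁻⁴), the target of global mean
  removal and the reason the across-channel average signal has realistic
  power;
* **white channel noise** ε (default SD 3·10⁻⁴);
* **coupling** (optional): a band-limited Gaussian process centred on
  `coupling_period_s` (default 20 s) with ±30% relative bandwidth, added
  *identically* to both partners' target-ROI channels during live runs
  only. Shared components are generated on a 50 Hz master clock and
  cubically interpolated to each site's sampling grid, so the two sites'
  different rates (12.34 vs 8.13 Hz) sample the same underlying process.

Concentrations map to three-wavelength intensities by inverting the
modified Beer–Lambert law with the packaged extinction table, so the
preprocessing stage recovers them exactly when noise is zero (round-trip
checked to 10⁻⁶; the only discrepancy is an exact per-channel constant
from estimating the baseline intensity by the run mean).

Amplitudes are on a mM-like scale (5·10⁻⁴ ≈ 0.5 µM), keeping
optical-density excursions near 10⁻², the realistic regime for
continuous-wave fNIRS.

What the generator does **not** emulate: motion artefacts, spatially
heterogeneous sensitivity (no photon-transport modelling; channel
positions are a Fibonacci lattice on a 90 mm scalp shell), serially
correlated physiological noise beyond the cardiac and systemic terms,
subject-specific anatomy, or any behavioural contingency between
partners. Passing tests therefore demonstrate that the *pipeline*
recovers what it is designed to recover under its stated signal model —
not that real recordings satisfy that model.

### Coupling bandwidth (a deliberate choice)

The coupling injection model is the package's own construction; its
purpose is recoverability. The ±30% relative bandwidth was chosen once,
jointly with the coherence smoothing window (below): wide enough that
two *independent* participants' coupling components phase-decorrelate
within the smoothing window (so shuffled dyads show no spurious
condition effect), narrow enough to stay specific to the target scale.

## Preprocessing

* **MBLL**: ΔOD = −log₁₀(I/I₀), I₀ = whole-run temporal mean per
  channel/wavelength; per-sample least squares on the 3×2 system; result
  scaled by 1/(separation × DPF). Extinction coefficients (mM⁻¹cm⁻¹ at
  780/805/830 nm) follow the standard published haemoglobin tabulations
  and DPF = 6.0 at all wavelengths; because vendor constants are
  unavailable, concentrations are in arbitrary-but-consistent units,
  which every downstream statistic (t, F, MSC) is invariant to. Both
  tables are configurable.
* **Resampling before filtering**: rational-ratio polyphase resampling
  to the common 8.13 Hz rate (the lower of the two site rates), then the
  4th-order Butterworth 0.01–0.2 Hz band-pass applied forward and
  backward (zero phase; the two-pass application squares the magnitude
  response, so cut-offs sit at −6 dB).
* **Global mean removal**: per chromophore, the channels × samples
  matrix is decomposed by SVD and the leading spatial component(s)
  subtracted (default 1 component). The removed component is by
  construction the one explaining the most variance; excluded channels
  neither contribute to nor receive the projection.
* **QC thresholds**: mirrored = corr(HbO₂, HHb) < −0.98 (the
  "perfectly mirrored" criterion needs an operational cut-off; −0.98 is
  configurable and far below the ≈ −0.9 correlation that physiological
  anticorrelation plus noise produces); saturation = >1% of samples at
  the channel's intensity ceiling; heartbeat = 0.8–1.2 Hz band power
  under 2× the neighbouring-band power; high RMS = channel RMS > 10× the
  RMS of the across-channel average signal.

## Co-localisation and ROIs

The kernel is `K_ij = exp(−σ d_ij²)` with `d` in **mm** and σ = 0.01
(units mm⁻², decay length 10 mm — localised smoothing that preserves
spatial specificity). The published typography of this formula is
ambiguous between `exp(−σd²)` and `exp(−d²/σ)`; the first is the default
and the second is selectable (`form="inverse"`). Weights are stored as a
(mask × input) matrix whose *rows* (one per mask channel) are normalised
to unit sum — the transpose of the input × mask layout in which the same
normalisation is described column-wise. This normalisation is what makes
the mapping preserve constants and relative amplitudes; QC-excluded
channels are dropped with their weights and the remainder renormalised.

Channel→ROI assignment is nearest-centroid against a packaged table of
approximate MNI centroids for the 14 bilateral regions (both hemispheres
pooled per region). The centroids are literature-typical values shipped
as versioned CSV; probabilistic atlas registration is out of scope.

## Activation GLM

Design: one regressor per condition (task boxcar ⊛ canonical
double-gamma HRF, peak delay 6 s, undershoot delay 16 s, dispersions
1 s, peak:undershoot 6, 32 s support, unit-peak normalised) plus an
intercept; rest is implicit baseline. Fit: plain OLS on HbDiff per
channel — no prewhitening, a documented limitation that biases
single-subject p-values under autocorrelated noise but leaves betas
unbiased, and the group inference uses only betas. Group test: paired
(one-sample on within-participant differences) t-test, forced by the
study layout (n participants, df = n−1). FDR: Benjamini–Hochberg
step-up.

## Inter-brain coherence

Residual route: channels → mask → ROI-average (HHb, the chromophore
less contaminated by systemic noise) → GLM → residuals → WTC, so shared
task structure cannot masquerade as coupling. The CWT uses PyWavelets'
complex-Gaussian family (default derivative order 3, configurable 1–8),
scales mapped from the period grid through the wavelet's centre
frequency. Default grid: log-spaced, `p_k = 2.5 · 2^(k/4)` s for
k = 0…15 (2.5–33.6 s); a linear 2.5 s-increment grid is available. The
two published descriptions of the grid (octaves/voices vs fixed
increments) are inconsistent and some reported periods fall on neither
construction; both grids are provided and neither is claimed to be the
original.

**Smoothing window.** MSC is unity without smoothing (guarded by a
regression test), so the smoother sets the estimator's resolution-
variance trade-off. The window is a moving average in time spanning
`window_periods` periods at each scale, with no cross-scale smoothing.
The default is **3 periods**. A 1-period window was implemented and
measured first: with ~120 s condition runs it leaves so few independent
segments that any two signals with power at a scale read as coherent
there (baseline MSC ≈ 0.65–0.7), and injected coupling of moderate
strength becomes statistically inseparable from the shuffled-dyad
baseline. Three periods restores the separation (baseline ≈ 0.3;
measured ≈ 90% detection of coupling whose direct cross-spectral
coherence is ≈ 0.3) while keeping ~6–8 independent windows per run at
the 20 s scale. The window remains configurable.

The WTC is computed once over the whole session and MSC averaged over
the time samples of each condition's runs (rather than re-running the
transform per 120 s segment): the result is identical in the interior
and avoids doubling edge effects at run boundaries. Cone-of-influence
samples are included by default (an exclusion flag exists); dyad-level
values at the longest scales therefore mix in some edge-affected
samples, symmetrically across conditions and dyad types.

Shuffled dyads: a seeded random derangement of the cross-site pairing —
every shuffled pair takes one participant from each site and nobody
keeps their real partner. With 2 dyads the unique swap is returned; with
1 dyad no derangement exists and the call errors.

## Group statistics

Per period: (1) paired t-test live vs static within real dyads;
(2) two-way fixed-effects ANOVA with factors dyad type (real/shuffled)
and condition (live/static), each dyad × condition value one
observation, so df_error = N_obs − 4 (76 for 20+20 dyads). The
between-cells layout is forced by that df; a repeated-measures variant
is noted but not default. Degenerate inputs (all values equal) report
F = 0, p = 1 rather than 0/0. Period-wise p-values are uncorrected by
default with an optional BH-FDR column; whether multiplicity across the
16 periods should be corrected is left to the analyst.

## Synchronisation protocol

Single-line ASCII over TCP: client sends `HELLO <site>`, server
broadcasts `START <unix_time>` once all expected clients are connected,
then closes the connections (no in-task messaging by design). Clients
retry connection 5 times with exponential backoff (configurable). Logs
are append-only text (`ISO8601 TAB site TAB event TAB detail`,
microsecond precision) and round-trip losslessly. The offset estimator
matches events of the same class by occurrence order and reports
`(t_A − t_B) − ground_truth_offset` per event; the ground-truth clock
difference between site computers must be measured externally.
Trans-Atlantic latency cannot be reproduced here; validation is
loopback-only (sub-millisecond lags over 200 handshake cycles), which
exercises the protocol logic and the estimator arithmetic, not the
network.

## Numerical and testing notes

* Test problem sizes: single-repeat sessions (240 s) and 2–8 dyads for
  most tests; the calibration and power checks run 150 and 100
  simulated experiments at residual level (8 and 20 dyads each), which
  exercises the coherence and ANOVA stages at study-like dyad counts
  while keeping the whole suite within a few minutes.
* Resampling output length is ceil(n·up/down) under the exact rational
  rate ratio; partners can end one sample apart and are trimmed to the
  common length before coherence.
* The MBLL baseline I₀ is estimated from the data, so recovered
  concentrations are changes about the run mean; comparisons are made
  after demeaning.
* Seeds: every stochastic component takes an explicit seed; identical
  seeds give bit-identical datasets and pipeline outputs (hash-checked
  in tests).

## Known limitations

No motion-artefact correction and no short-separation regression (the
modelled acquisition has neither auxiliary physiology nor short
channels). No prewhitening in the GLM. MSC is symmetric: no
directionality (leader/follower) inference. The ANOVA treats within-dyad
condition values as independent observations, inflating df relative to a
mixed model — retained deliberately to match the study layout it
implements. The synthetic positions and ROI centroids are plausible
stand-ins, not subject anatomy.
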