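# Methods

## Experimental design being modeled

Two run types are generated and analyzed, both at TR = 1 s:

* **Localizer** (240 s): four alternations of 30-s rest and 30-s
  full-contrast stimulus blocks, used only for voxel selection.
* **Contrast adaptation** (890 s × 3 runs): 30 s rest, then a 60-s
  adaptation pedestal (intermediate contrast), then 24 test trials —
  4 repetitions of each of 6 conditions (increment/decrement × 1, 3,
  6 s), in seeded random order, each followed by 30 s of adaptation
  stimulus.  Increments raise the adapted contrast (positive BOLD
  deflection), decrements lower it (negative deflection).

## Forward model (synthetic data)

Each voxel's raw series is
`baseline_level · (1 + (drive ⊛ HRF + noise)/100)` with:

* **Neural drive** — a boxcar per stimulus, evaluated at 10-Hz internal
  resolution (sub-second HRF onset delays and times-to-peak make TR
  resolution too coarse), then convolved with the voxel's two-gamma HRF
  and sampled at TR.  Decrements are sign-flipped drives at a
  configurable magnitude ratio (default 0.6) relative to increments,
  reproducing their weaker responses and lower SNR.  The adaptation
  pedestal decays exponentially from its onset amplitude toward
  `amplitude × plateau_fraction` (default 0.5) — the stimulus stays on
  screen, so the drive settles on a plateau rather than returning to
  zero.  The (amplitude, decay, plateau) parametrization is the
  package's own; only the qualitative shape (fast rise, slow decay to a
  pedestal) is constrained by the phenomenon being emulated.
* **Injected nonlinearity** (all off by default): per-duration gain
  factors on the drive amplitude; square onset/offset bursts emulating
  transient neural activity at contrast changes; exponential
  within-stimulus habituation.  With all of them off the voxel is an
  exactly linear time-invariant system — the ground truth against which
  the linearity statistics are validated.  Presets: `overest`
  (gain 1.6/1.15/1.0 for 1/3/6 s plus transients of amplitude 0.8,
  width 0.5 s), `underest` (0.65/0.9/1.0, no transients), `mixed`
  (increments as `overest`; decrement 1-s gain drawn per voxel from
  U[0.6, 1.6], so decrement patterns span under- to overestimation).
* **Noise** — white Gaussian noise (default SD 0.5% signal, a typical
  3-T single-voxel level), low-frequency sinusoidal drifts (defaults
  0.003 and 0.008 Hz at 0.3/0.2% — below the 0.0125 Hz high-pass so the
  filters can remove them) and a linear trend (0.5%/run).
* **Ground-truth HRFs** are drawn per voxel from a physiologically
  plausible sub-box of the restricted fitting bounds (μ₁∈[4,7] s,
  μ₂∈[9,14] s, β₁,β₂∈[0.8,1.4] s⁻¹, c∈[0.2,0.6], t_onset∈[0,1.5] s,
  A∈[2,6]); the full restricted box admits degenerate shapes (β → 0)
  that no cortical voxel shows.
* **Determinism** — every voxel draws from an independent stream spawned
  from the master seed, so identical (config, seed) reproduce datasets
  bit-exactly and adding voxels never perturbs earlier ones.

What the generator does **not** emulate: head motion, spatial
autocorrelation and smoothing, physiological (cardiac/respiratory)
noise structure, temporal autocorrelation of the white-noise floor
(an AR(1) surrogate null is available for the selection stage),
retinotopy, or sub-TR contrast ramps.  Passing tests therefore
demonstrate correctness of the statistics and pipeline on data with the
assumed structure, not robustness to every artifact of real scanner
data.

## Preprocessing

Filtering uses hard-cutoff DFT masks with the mean and linear trend
removed before each filtering and not restored (the convention of the
Fourier-filter tools this emulates).  Bins strictly outside the pass
band are zeroed; in the component high-pass, the DC and components 1..k
inclusive are removed (the protocol retains signal from component 12
while cutting at component 10, so either inclusivity convention
preserves signal; inclusive removal is fixed for determinism).  Note
that detrend-then-mask is not exactly idempotent — a least-squares line
is not orthogonal to the pass band — while the mask alone is a
projection.

Adaptation-run chain, in order: discard the first 90 volumes (baseline
and adaptation phase, whose rising trend would contaminate a linear
detrend) → percent signal change about the retained-part mean → linear
detrend of the test period → 0.2 Hz low-pass → per-condition trial
recombination (a d-s trial at onset t covers samples [t, t+d+30), i.e.
31 samples for a 1-s trial — "volumes 201–231" in 1-based convention
for an onset 200 s into the run; 12 trials over 3 runs, 372 samples for
the 1-s condition) → high-pass at the 10th DFT component of the
recombined course (10/372 s ≈ 0.0269 Hz for the 1-s condition) →
average the 12 trials → keep the first 25 samples.  Localizer chain:
percent conversion, detrend, 0.0125–0.2 Hz band-pass.

Trial windows use 0-based half-open sample intervals internally; a
non-integer (duration+30)/TR is a hard error rather than an
interpolation case (TR = 1 s in all in-scope designs).

## Voxel selection

FIR deconvolution with window L = 25 samples (matching the
measured-response length), least squares with an intercept;
r² = 1 − SS_res/SS_tot clipped to [0, 1] (a zero-variance course returns
0).  The null distribution pools statistics of time-point-shuffled
courses pushed through the identical preprocessing; per-voxel empirical
false-positive rates use (1 + #{null ≥ obs})/(1 + n) so p-values are
never exactly zero.  BH-FDR correction, then face-connected (6-neighbor)
cluster filtering with a minimum size (default 4 voxels) and a
positivity requirement on the mean estimated impulse response over
0–15 s (the localizer stimulus must elicit a signal increment).

At desk scale, the q threshold must respect the resolution of the null:
with n permutation samples the smallest attainable corrected rate is
≈ (1/(n+1))·(m/k), so the protocol default q = 0.001 requires null sizes
in the 10⁴–10⁵ range (available via `--full-null`); examples and tests
use q = 0.01–0.05 with 150–1000 null samples.

## Linearity and deviation statistics

Predictions truncate to 25 samples after summation of shifted copies.
The Dice null shuffles time points of the percent-converted per-run
courses, re-runs the filter chain, rebuilds measured responses and
predictions from the shuffled data and pools all six (pair × response
type) Dice values per draw; chance thresholds are upper-tail null
quantiles, BH-corrected across voxels (step-up on the observed values)
when observed values are supplied.  Because the six values per draw are
correlated, calibration checks compare against binomial error at the
number of draws, not the number of pooled samples.

HRF fitting: trust-region-reflective bounded least squares on the
residual between the measured 25 samples and the boxcar-convolved signed
HRF (model evaluated at 0.1-s resolution, sampled at volume times);
10 seeded Latin-hypercube starts within bounds; tolerances 1e-8 with at
most 600 residual evaluations per start (on filtered responses no exact
fit exists and tighter tolerances only burn evaluations without changing
the recovered amplitudes; noise-free recovery is exact to ~1e-13
relative).  The amplitude is the extremum of the signed HRF itself on
[t_onset, t_onset + μ₂] — the peak, excluding the post-peak
undershoot/overshoot — taken as a magnitude.  An all-zero response is
fitted exactly by A = 0.  Restricted bounds: μ₁∈[0.5,8], μ₂∈[4,16],
β₁,β₂∈[0,5], c∈[0,1], t_onset∈[0,5], A∈[0,20] (A in percent-signal
units); flexible bounds relax μ and t_onset to [0,24] and β, A to
[0,∞).  The contrast index, not the amplitude ratio, is the primary
deviation statistic (bounded, symmetric under pair exchange); both are
reported and satisfy contrast = (ratio−1)/(ratio+1).

## SNR and group statistics

All trials of a response type across the three durations (36 for three
full runs) are truncated to 25 samples and concatenated, making the task
periodicity 25 s/cycle (0.04 Hz).  SNR = DFT magnitude at the task bin
over the mean magnitude in 0.33–0.50 Hz (endpoints inclusive); an
alternative band of all non-DC frequencies except the task bin is
available as a robustness check.  Median split sends values equal to the
median to the low group (configurable, since an odd count must break the
tie somewhere).  Wilcoxon signed-rank tests drop zero differences and
use the tie-corrected normal approximation for n > 25, exact enumeration
otherwise; KS one-sample tests compare a contrast distribution against a
zero-mean normal with the distribution's own standard deviation.
Reported test families are BH-corrected at 0.05.

## Problem sizes and tolerances used in the test suite

The suite validates: exact design arithmetic (sub-second); statistic
identities on random vectors; the zero-noise linearity oracle at 20
voxels (per-condition median Dice ≥ 0.99, per-voxel |contrast| ≤ 0.05 —
the protocol 0.2 Hz low-pass removes a little genuine high-frequency
energy from 1-s responses, so individual Dice values can reach 0.989);
pattern reproduction at 50 noisy voxels with the `mixed` preset;
selection and Dice-threshold calibration on pure-noise datasets
(50 datasets × 8 voxels; 300 independent shuffle draws) within two
binomial standard errors; BH against a brute-force step-up oracle on
1000 random p-vectors; and HRF amplitude recovery over 100 seeded fits
(median error < 2% noise-free, < 15% at noise SD = 20% of peak).

## Known limitations

* The measured response carries no explicit baseline term: the component
  high-pass removes the trial-window mean, so fitted amplitudes are of
  mean-removed responses (consistent across durations, hence neutral for
  the contrast index).
* Null distributions are pooled across voxels, not per voxel.
* Voxels are pooled across the dataset; no participant-level hierarchy.
* The cluster-size criterion and connectivity rule are parameterized
  (defaults: 6-neighbor, minimum 4) because no principled value exists
  without a stimulus-geometry model.
* The localizer signal-band estimate has the spectral resolution of a
  finite run (1/240 Hz); onset transients can leak the estimated lower
  edge one bin below the block fundamental.
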