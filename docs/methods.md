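# Methods

This note documents the models, conventions, and design choices behind
`tmsep`, in the order the pipeline applies them.

## Trial structure and normalization

A trial spans −500 to +1000 ms around a stimulus onset; the first 500 ms
are the baseline. All windows and bins are half-open, `[t0, t1)`, so no
spike is counted twice at an edge. Times are stored in seconds (64-bit
floats, time 0 = recording start) and reported peri-stimulus in
milliseconds; the conversion lives in the binning layer.

Counts per bin (default 1 ms) divided by the bin width give instantaneous
firing rate; each trial's mean baseline rate is subtracted from every bin
of that trial, including the baseline bins. The baseline mean of every
normalized trial is therefore exactly zero by construction — an invariant
the tests assert to float precision. Trial averages are arithmetic means;
population averages weight animals equally (mean of per-animal means), so
an animal contributing more trials does not dominate.

## Smoothing and the empirical significance band

Trial-averaged trains are smoothed with a Gaussian kernel, σ = 2 ms,
truncated at ±4σ, renormalized to unit sum, reflective boundary. The
significance band is the 2.5th/97.5th percentile of the *smoothed* averaged
train's own baseline bins. Computing the band on the same (smoothed) train
it is compared against keeps band and trace commensurate; the alternative —
band from raw bins against a smoothed trace — mixes two different
variances.

Percentiles use the Weibull (type-6) plotting position, interpolating order
statistics at `p·(n+1)`. This estimator is exceedance-unbiased: for
continuous i.i.d. samples, the probability that a new draw falls beyond the
estimated quantile is exactly α/2 per tail, which is precisely the per-bin
type-I error the band is meant to control. (The more common type-7
position `1 + p·(n−1)` is biased anticonservative here by ~0.4 percentage
points at n = 500, which matters because smoothing also correlates
neighboring baseline bins and inflates the exceedance rate slightly.) The
acceptance script measures the realized two-sided rate at ≈ 0.056 on null
sessions — the residual excess above 0.05 is the correlation effect of the
2 ms kernel, not the quantile convention.

With discrete (unsmoothed) trial-averaged counts, ties at the threshold
make the band conservative (realized rate ≈ 0.02); this is why the band is
always taken on the smoothed train in the long-latency analysis.

## Phasic events and phase labels

Per polarity independently, maximal runs of bins beyond a threshold are
found inside the search window; runs of the same polarity separated by
sub-threshold gaps ≤ 10 ms are merged first (accommodating jitter), then
merged runs with extent strictly greater than 10 ms are kept. Onset and
offset are the outer edges of the first and last bin. "More than 10 ms" is
strict: ≥ 11 bins at 1 ms.

Labels follow the canonical sequence: excitations peaking inside 1–6 ms are
`short_latency`; the first excitation peaking after 6 ms is
`intermediate_excitation`; the first inhibition after it, `inhibition`; the
first excitation after that inhibition, `rebound_excitation`; anything else
stays `unclassified` (at a 5% per-bin rate, a few short unclassified
crossings per 1000 post-stimulus bins are expected and harmless).

The end-to-end pipeline searches phase events from 6 ms on: the multiphasic
rhythm is a 6–300 ms phenomenon, and under PA-like stimulation the large
1–4.5 ms bursts would otherwise merge into the intermediate excitation
(their gap is below the 10 ms tolerance). The 1–6 ms window instead gets
its own analysis at 0.5 ms bins, unsmoothed — a 2 ms kernel would smear
sub-millisecond structure, and a >10 ms duration rule cannot apply inside a
5 ms window — reporting the significant bins per intensity. Phase windows
are detected on the highest-intensity averaged train and applied to the
trials of all intensities when extracting per-trial phase rates, so the
mixed model sees a common definition of each phase.

## Mixed model

Per-trial phase firing rate is modeled as
`y_ij = b0 + beta * x_ij + u_i + e_ij` with intensity `x` in raw %MT
(uncentered) and a random intercept `u_i` per animal. Estimation is REML,
profiled in the single variance ratio θ = σ²_animal/σ²: for fixed θ the
covariance is block compound-symmetric, so the GLS normal equations reduce
to per-group sums, and θ is optimized by a bounded derivative-free search
on [0, 10⁶] with tolerance 10⁻¹⁰; the boundary θ = 0 is checked explicitly
and reported, not treated as an error. The fit matches a general-purpose
REML implementation to well below 10⁻⁶ relative on the slope (asserted in
the tests against statsmodels' MixedLM).

The fixed effect is tested with F = (β̂/se)², denominator degrees of
freedom by the Satterthwaite approximation computed from the REML observed
information (numerical Hessian in the two variance components), falling
back to the containment value n − G − 1 at a boundary fit. Exact
Kenward-Roger is not implemented; on this one-random-intercept design the
two agree closely, and the calibration test pins the realized type-I error
to [0.03, 0.07] at nominal 0.05 on a 7-animal × 4-intensity design. A
parametric bootstrap of the F statistic under the fitted null model is
available when distributional assumptions are in doubt.

The Wilcoxon rank-sum test (for simple two-sample comparisons such as motor
thresholds between coil orientations) enumerates all rank assignments
exactly for combined n ≤ 20 and uses the tie-corrected normal
approximation otherwise.

## Spike detection

Traces are bandpass filtered 300–5000 Hz with a 4th-order Butterworth
applied forward-backward (zero phase), the same anti-causal convention used
for EMG. Background noise SD is estimated as median(|x|)/0.6745 over
non-excluded samples — equal to the SD for Gaussian noise and barely
inflated by spikes (a 0.5 ms deflection at 50 spikes/s occupies 2.5% of
samples and shifts the estimate by ≤ ~4%; the plain SD more than doubles
under the same contamination). Spikes are local extrema of the configured
polarity beyond k·σ̂; polarity defaults to negative (extracellular somatic
spikes are predominantly negative-going) and k to 4. A dead time of 0.8 ms
(≈ one refractory period) suppresses secondary crossings. Blanking
intervals are padded by 2 ms (about one impulse-response length of the
300 Hz high-pass edge) before detection so that ringing from the blanking
discontinuity cannot masquerade as spikes.

## Synthetic data

The generator emulates the *point-process statistics* of layer V multiunit
activity around a TMS pulse, not biophysics. Rates are piecewise-constant
peri-stimulus profiles λ(t) = max(0, λ₀ + Σ components); spike times are
drawn by Lewis–Shedler thinning, which is exact for piecewise-constant
rates. Flooring at zero (rather than rejecting negative rates) lets
suppression components model inhibition naturally.

Preset profiles ("calibrated" to the evoked shapes the analysis targets)
use a baseline of 15 events/s — a typical anesthetized layer V multiunit
level; only normalized rates matter downstream, so the absolute level is a
package constant. At 120 %MT the components are: an excitation plateau
8–32 ms with an inner step 16–24 ms (peak ≈ 20 ms, +70 events/s), complete
suppression 40–150 ms (−15), rebound excitation 170–280 ms (+25), and — for
PA orientation only — short-latency bursts at 1–1.5 ms (+400) and
2.5–4.5 ms (+250). Amplitudes scale linearly with intensity, zero at and
below 80 %MT, so excitations grow and the suppression deepens with
stimulus strength. Evoked sessions default to 60 trials per condition: the
inhibition can at most reach −λ₀, and at 40 trials the expected band
half-width (≈ √(λ₀/Δ/n_trials) · 1.96 / √(kernel gain) ≈ 14 events/s)
equals that depth, so reliable recovery of the planted inhibition needs the
extra trials; the null-calibration runs keep 40 trials since nothing is
planted there.

Continuous traces are rendered at 40 kHz as waveform templates (biphasic,
1 ms, 80 µV negative-leading trough) summed at spike times over white
Gaussian noise (8 µV), with samples inside the −0.2 to +0.8 ms blanking
window zeroed and the intervals recorded for exclusion downstream. EMG
traces carry a biphasic 4 ms, 300 µV motor-unit template at the planted
latency on the contralateral channel only. The low-gain monitor generator
integrates a given current through the input capacitance
(V = (1/C_in)∫I dt), the exact inverse of the charge computation.

What the generator does *not* emulate: stimulation artifacts (induction,
polarization decay, vibration), bursting/refractory spike-train structure,
electrode drift, or correlated noise. Passing tests therefore demonstrate
the correctness and calibration of the analysis under its own statistical
assumptions, not robustness to every failure mode of real recordings.

## Charge monitoring

I(t) = C_in·dV/dt via central differences (one-sided at the edges) — local,
robust, and accurate to O(Δt²) at 40 kHz for ms-scale transients. Positive
and negative phases are integrated separately by the trapezoid rule; the
bipolar total |q⁺| + |q⁻| is compared against the 150 and 800 pC
microstimulation thresholds as safety *factors* only — the report never
gates execution. C_in is hardware-specific and therefore a required user
input; the pipeline demo uses 10 pF with a ±7.5 nA, 50 µs-per-phase test
pulse. The cable voltage-divider utility models the electrode as a purely
resistive source of its impedance magnitude at the probe frequency and the
cable as a shunt capacitance: attenuation = 1 − 1/√(1 + (2πfRC)²).

## EMG

EMG is bandpass filtered 100–1000 Hz, zero-phase 4th-order Butterworth.
Onset latency is the first post-stimulus time (after a 2 ms blank) at which
the rectified trace exceeds the detection threshold for ≥ 1 ms
continuously; the threshold is the larger of 3× the robust SD of the
rectified baseline (last 100 ms pre-stimulus) and 20% of the rectified
post-stimulus maximum. The relative term is needed because zero-phase
filtering spreads a large response acausally: its leading skirt can exceed
any purely noise-derived threshold several ms early at high SNR. Both
terms scale with the trace, so the estimate is amplitude-scale invariant;
recovery bias on planted 11 ms responses is ≤ 0.3 ms for SNR ≥ 10. All
three constants are configurable. Laterality is the contra/ipsi ratio of
mean rectified post-stimulus area (infinite, flagged, when the ipsilateral
area is zero).

## Reproducibility

Every stochastic component takes a seed and uses an isolated
`numpy.random.Generator`; identical seed and configuration give
bit-identical spike trains, traces, and downstream tables. The pipeline
writes a manifest (configuration, seed, package version, output list) and
re-running it reproduces all outputs exactly. Problem sizes in the test
suite (e.g., 200 null sessions for the band calibration, 100 seeds for
phase recovery, 1000 simulations for the F-test calibration) are chosen so
Monte-Carlo error is comfortably below the asserted tolerances while the
suite stays quick on a single CPU.

## Known limitations

- The empirical band controls the *per-bin* error rate; no correction for
  simultaneous inference across bins is applied (by design, matching the
  procedure it implements).
- The mixed model supports exactly one random intercept — no random
  slopes or crossed designs.
- Phase windows come from the highest-intensity average; if phase timing
  shifted strongly with intensity, per-condition windows would be needed.
- The synthetic blanking zeroes samples, which creates discontinuities a
  hardware blanking circuit avoids; detection pads excluded intervals to
  compensate, and planted spikes inside the pad are deliberately excluded
  from sensitivity scoring.
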