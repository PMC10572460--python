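# Methods

`epiphys` quantifies four recording modalities from a PTZ-kindling
epilepsy experiment — astrocyte calcium imaging, whole-cell synaptic
currents, extracellular field potentials, and chronic LFP — and ships
synthetic generators that emulate each modality with known ground truth,
so every analysis stage can be verified end to end without access to the
original recordings. This note documents the models, the parameters that
matter, the numerical choices, and what the synthetic data do and do not
establish.

## Astrocyte calcium transients

Per-soma fluorescence traces (arbitrary units, nominally 1 Hz frames for
5 min, so ~300 frames) are analysed as follows.

**Baseline.** F0 is the mean of a quiet window of at least 30 consecutive
frames. The window is chosen automatically: among all candidate windows
whose sample SD is within 1.5x of the minimum, the one with the lowest
mean is taken, and the choice is then refined once — events are detected
against the provisional baseline, and if any overlap the window, the best
window not intersecting any event is used instead. The lowest-mean rule
matters because the plateau of a long slow transient is exactly as flat
as true baseline but sits high; a pure minimum-variance rule can land on
such a plateau, from which no upward event is visible and the refinement
pass cannot recover. Transients are positive-going, so "flat and low"
identifies quiescence. A manual `(start, end)` window can always be
supplied; if no activity-free window exists, an error asks for one.

**Normalisation.** `dff[t] = ((F[t]-bg) - (F0-bg)) / (F0-bg)` after
subtracting a scalar background `bg`; F0 <= bg is rejected as degenerate.

**Detection.** An event is a maximal run of frames with
`dff >= k_sd * sd0` lasting at least `min_frames` frames, with defaults
`k_sd = 2` (baseline SDs) and `min_frames = 5`. Both boundaries are
closed: exactly 2 SD and exactly 5 frames are accepted. Onset/offset
frames are 0-based and inclusive; duration is frame count x frame period,
never resampled.

**Multi-peak splitting.** Within an event, the trough between two local
maxima cuts the event into independent transients when it falls to <= 50%
of a reference amplitude. Two readings of the splitting rule are
implemented behind `mode`: `"adjacent"` (default) references the smaller
flanking peak; `"global"` references the event's global maximum. The two
printed criteria the rule descends from are ambiguous, so neither reading
is asserted as canonical; the mode is recorded in the run configuration.
Fragments shorter than `min_frames` are discarded; the cut assigns the
trough frame to the earlier fragment, keeping fragments contiguous.

**Classification.** Durations below the cut-off are fast transients (FT),
at or above it slow transients (ST). The default cut-off is 23.1 s — the
75th percentile of the pooled duration distribution in the reference
dataset; `derive_cutoff` recomputes it for any pooled sample using linear
interpolation between order statistics (the "type-7" percentile, the most
widespread convention; recorded in output metadata). The tie at the
boundary goes to ST because the fast class is defined by strict
"< cut-off". Note that a demo run pooling two conditions with elevated ST
fractions will derive a larger percentile than 23.1 s; classification
nevertheless uses the configured constant unless the caller passes the
derived value deliberately.

**Summaries.** Per cell: event count, mean duration, ST percentage, and
the FT/ST count ratio — an inverse index of astroglial calcium
excitability (more slow transients, lower index). With zero ST events the
ratio is reported missing (NaN), never as a division error. Count ratios
and rate ratios coincide here because all recordings have equal length.

## Spontaneous and evoked synaptic currents

**Spontaneous PSCs.** Detection operates on the polarity-rectified,
median-subtracted sweep, lightly smoothed (1.25 ms boxcar). Peaks must
exceed a threshold (default 3x a robust noise SD estimated by median
absolute deviation), be separated by at least 5 ms, and have prominence
at least equal to the threshold — the prominence requirement prevents
noise maxima riding on an event's decay from double-counting it.
Amplitude is the smoothed peak minus a local pre-event baseline (median
over 20-5 ms before the peak), which discounts the residual decay of any
preceding event. Frequency is count divided by sweep duration. Two known
small biases: peak-selection on a noisy extremum inflates amplitudes by
roughly half the post-smoothing noise SD (~2-3% at SNR 10), and events
closer than the kernel rise time merge (<1% of events at 1 Hz). The
frequency estimate is unbiased within 2 standard errors over 200 sweeps.

**Paired-pulse ratio.** PPR = A2/A1, baseline-to-peak amplitudes in a
2-50 ms window after each of exactly two stimuli (conventional interval
100 ms); baseline is the 10 ms pre-stimulus mean. With `decay_correction`
(default on) a single exponential is fitted to the last 40% of the
inter-stimulus segment and its extrapolation is subtracted before
measuring A2. A first response below 3x the baseline noise SD makes the
ratio undefined and raises. PPR is invariant under any positive gain.

**E/I balance.** Compound PSCs recorded at -40 mV contain an early inward
(excitatory) and a delayed outward (inhibitory) phase. After baseline
subtraction and a 2 ms stimulus-artifact blank, the negative-clipped part
of the post-stimulus trace is the excitatory component and the
positive-clipped part the inhibitory one: peaks are the extrema
magnitudes, areas the trapezoidal integrals in pA*ms, and both the peak
and the area E/I ratio are always reported (which one a given figure
uses is a caller decision). A missing outward phase yields zero
inhibitory magnitudes and NaN ratios, not infinities. By construction
exc_area + inh_area equals the rectified post-stimulus area.

## Field potentials

`measure_fepsp` reads one sweep per stimulus intensity: fiber volley =
largest negative deflection in a fast window (2-4.5 ms post-stimulus),
fEPSP amplitude = baseline-to-trough in a 4.5-50 ms window, slope = a
least-squares line over the 20-80% amplitude span of the falling limb
(the field's convention; the study never defines its own), and the
population spike = a positive-going notch inside the fEPSP trough with
prominence >= 10% of the fEPSP amplitude (an absolute-mV criterion is
available; a floor of 7x the baseline noise SD keeps noise from passing
as a notch). Input-output curves are ordered by intensity;
`compare_io` reports the amplitude ratio at each shared intensity plus
the mean; the Ps threshold is the lowest tested intensity with a
detected spike, snapped to the tested grid. `fc_ppr_effect` handles
paired before/after PPR designs (e.g. fluorocitrate perfusion) via the
paired branch of the statistics module.

## LFP

Recordings are 1 kHz, optionally band-passed 0.1-100 Hz with a zero-phase
forward-backward Butterworth filter (no group-delay bias on event times).

**Multitaper PSD.** 4000 ms segments with 500 ms overlap, time-bandwidth
product 5, 9 Slepian tapers (scipy's DPSS, unit energy), eigenspectra
averaged over tapers and segments, one-sided density in mV^2/Hz. The
frequency resolution is 1/segment-duration (0.25 Hz) and the integral of
the PSD matches the signal variance within a few percent (Parseval);
agreement with MNE's multitaper estimator at the same bandwidth is
checked in the test suite. Requesting more than 2*NW-1 tapers warns about
degraded concentration but proceeds. Note the 2.5 Hz analysis bandwidth
smears a spectral line by +/-1.25 Hz; narrow-band questions should lower
`time_bandwidth`.

**Band power** integrates the PSD over a band (default 1-3 Hz, the
low-frequency band that dominates during ictal activity) with
interpolated band edges, so adjacent bands add exactly.

**Event detection.** The study scored interictal spikes and
after-discharges manually; automation here is a repository decision, not
a claim about the original procedure, and all thresholds are exposed.
Interictal spikes: deflections of either polarity above 5 robust SDs
whose half-amplitude width lies in 20-70 ms. After-discharges: intervals
where the 250 ms-smoothed Hilbert envelope stays above median + 4 robust
SDs for at least 2 s; summarised as incidence per minute, latency from
the injection marker (missing without one), per-episode durations, and
1-3 Hz band power. With a 250 ms smoothing window, detected AD borders
are accurate to a few hundred ms — scheduled durations are recovered
within +/-0.5 s at high amplitude, not to one sample.

## Statistics

Every group comparison runs through a normality gate: Shapiro-Wilk at
alpha = 0.05 on each sample, with the Kolmogorov-Smirnov result (on
standardised values) reported alongside; Shapiro-Wilk governs when they
disagree. All samples normal -> Student's two-tailed t (paired variant
when flagged); otherwise Mann-Whitney U (Wilcoxon signed-rank when
paired). Three or more groups: one-way ANOVA or Kruskal-Wallis, followed
by pairwise tests with Bonferroni adjustment `min(1, m*p)` over the m
pairs. Constant samples are treated as non-normal. Paired samples with no
non-zero differences short-circuit to a p = 1 "no difference" result
rather than erroring inside the signed-rank test. Each result records
which test ran and why. The gated two-sample path holds its type-I error
within [0.03, 0.07] at alpha = 0.05 over 2000 simulations. The unit of
analysis (cell, slice, animal) is whatever the caller passes; the module
does no nesting correction.

## Synthetic generators

The generators define the verification conditions; they aim for
recoverability and controlled effects, not biophysical realism (no
conductance-based models, no kindling-progression dynamics).

**Calcium** (`CaSimConfig`): 300 frames at 1 Hz, baseline 3000 AU over a
200 AU background, Gaussian noise 30 AU — comfortably above the
2000-unit minimum brightness used for cell inclusion, with amplitudes
(mean 10x noise SD) giving SNR ~10. Events arrive at 1.2 per minute; a
Bernoulli draw (`st_fraction`, default 0.25 to mirror a 75th-percentile
cut-off) picks the class; durations are lognormal — FT: exp(N(ln 9, 0.3))
s, ST: exp(N(ln 40, 0.2)) s — placing >=99% of each class on its side of
23.1 s. Durations are clamped at the 5-frame detectability floor, since
shorter excursions are by definition not events under the detection
criterion. The transient profile rises linearly over ~10% of its
duration, holds a plateau, and falls geometrically over the last ~15% to
just above threshold, so the supra-threshold span equals the drawn
duration exactly and duration recovery is well-posed; a 3-frame
sub-threshold tail follows. Frames 0-29 are kept event-free so a
baseline window always exists; placements keep a 2-frame margin and are
drawn uniformly among all feasible onsets, longest events first. If an
event cannot fit even in an empty trace the config is rejected; if a
feasible config draws a Poisson count that overflows the recording, the
surplus events are censored — injected nowhere and absent from ground
truth — so ground-truth closure holds exactly. `merged_fraction`
generates two-peak complexes with a trough at 40% of the smaller peak to
exercise the splitting rule; `amp_unit_au` decouples the amplitude and
threshold unit from `noise_sd` so truly noiseless traces (exact recovery
up to discretisation) can be generated.

**Spontaneous PSCs** (`PscSimConfig`): Poisson event times, lognormal
amplitudes (mean 20, SD 5 pA — positive by construction), unit-peak
biexponential kernel (rise 1.5 ms, decay 12 ms), 4 kHz sampling, Gaussian
noise 2 pA. Paired-pulse sweeps superimpose two kernels with peaks A1 and
A1 x PPR; because responses are additive, the configured PPR is exactly
recoverable once the residual decay of response 1 is subtracted — the
same convention the analyzer implements. Compound PSCs build each
component as a half-sine whose width follows from the requested peak and
area (`w = pi*area/(2*peak)`); the lobes are disjoint in time, so
zero-crossing decomposition is exact on noiseless sweeps.

**Field potentials**: stimulus artifact (blanked by the analyzer), fiber
volley linear in intensity (0.004 mV/µA), fEPSP amplitude = gain x Hill
function of intensity (I50 = 60 µA, coefficient 2 — standard saturating
input-output phenomenology), and a population-spike notch (25% of the
fEPSP amplitude) from the configured threshold intensity upward. Because
every postsynaptic component scales with the gain parameter, a condition
effect on synaptic strength is a pure fold-change at every intensity —
which is what lets a "2x gain" condition be recovered as a 2.0 amplitude
ratio across the curve.

**LFP** (`LfpSimConfig`): 1/f ("pink") background by default (0.05 mV
SD), resembling cortical LFP; after-discharges are Tukey-windowed
oscillations at a dominant frequency; interictal spikes are Gaussian
deflections whose FWHM equals the scheduled width. Overlapping scheduled
ADs are rejected; spike widths outside 20-70 ms are rejected.

**What passing these tests shows — and does not.** Recovery on this
synthetic data establishes that the implementations compute their
definitions correctly and meet their printed constants, and that the
configured group effects survive the full pipeline. It does not establish
performance on real recordings, whose transients have variable kinetics,
bleaching and motion artifacts, overlapping events, non-Gaussian and
non-stationary noise, and whose seizures are far less stereotyped than a
windowed oscillation.

## Problem sizes and determinism

Every generator and every pipeline stage is seeded; identical config and
seed regenerate outputs byte-identically. Demo and test problem sizes —
12 cells per condition, 8-10 sweeps per synaptic metric, five-intensity
input-output families, 90-120 s LFP records, 50-200 seeds for calibration
loops and 2000 simulations for the type-I check — were chosen as the
smallest sizes at which the recovered quantities are stable to well
within the tolerances being asserted. The acceptance script recomputes
the headline fEPSP fold-change from scratch at those sizes.
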