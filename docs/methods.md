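# Methods

`organoidkit` implements the computational chain used to phenotype
cerebral organoids and monolayer neuron cultures across four assay
families: multi-electrode-array (MEA) electrophysiology, targeted LC-MS
metabolomics/lipidomics, Seahorse mitochondrial stress tests and RT-QuIC
amyloid seeding assays. Every stage can be exercised on synthetic data
with recorded ground truth; this note describes the models, the defaults
and why, the numerical choices, and what the synthetic benchmarks do and
do not demonstrate.

## Signal conditioning

Two acquisition protocols are modelled. Organoid MEA recordings
(25 kHz) are conditioned for spike detection with a 300–2500 Hz
band-pass (4th-order Butterworth). The upstream acquisition software
describes this setting as a "high-pass 300–2500 Hz"; a high-pass has a
single corner, so the two printed corners are implemented as a band-pass.
Multiwell monolayer recordings (20 kHz) use a 300 Hz high-pass
(order 2) followed by a 3500 Hz low-pass (order 4), both Butterworth.
All filters run forward-backward (zero-phase) by default so that event
times are not shifted between conditioning variants; a single-pass mode
is available for acquisition-faithful emulation. Edge transients are
handled by `filtfilt`'s reflective padding (3x the filter length).

Oscillation analysis operates at 1 kHz. Downsampling applies a
linear-phase Kaiser-window FIR low-pass before each decimation stage
(the ratio is factored into stages of at most 8, e.g. the 25x ratio for
25 000 → 1000 Hz runs as 5 x 5); each stage passes 0.4x and stops 0.5x
of its output rate at
>= 60 dB, so the final stage passes 400 Hz and stops 500 Hz. Filtering
is forward-backward, which doubles the stop-band attenuation and keeps
pulse peaks within one output sample.

## Spike and burst detection

Thresholds follow the mean ± k·SD rule with k = 4, where the mean and SD
are computed over an initial baseline window of the *conditioned* trace
(30 s for organoid recordings, 10 s for multiwell). A flat baseline
(SD = 0) raises a data-quality error rather than detecting everything —
a flat channel is a broken channel. Each excursion beyond the threshold
yields one event timestamped at its extremum; a 2 ms dead time prevents
one biphasic waveform from being counted twice. Both one-sided (negative
or positive) and two-sided detection are provided; the original
acquisition convention is unknowable, so two-sided is the default, while
recovery benchmarks use negative-polarity detection because the
synthetic waveform — like the extracellular action potential it mimics —
has a dominant negative lobe. At 4·SD, two-sided detection on band-passed
Gaussian noise produces ~0.2–0.3 false events/s (upcrossing theory), so
one-sided detection materially improves precision at low firing rates.

A burst is any maximal group of spikes in which some 100 ms window
contains at least 4 spikes (both thresholds configurable); overlapping
qualifying windows merge, and episode boundaries are the first and last
member spikes. The implementation anchors candidate windows at spikes —
any qualifying window can be slid left onto a spike without losing
members — and is verified exactly against a brute-force all-windows
oracle.

Burst periodicity is estimated from burst onsets binned at 100 ms: the
unbiased autocorrelation is computed to a 10 s maximum lag and
normalized by the variance, and the periodicity is the lag of the
dominant positive peak. Two numerical choices make this well defined.
First, the significance floor is the white-noise bound `3/sqrt(n_bins)`;
a floor based on the SD of the autocorrelation tail would be inflated by
the harmonic peaks themselves for strongly periodic trains. Second, for
a periodic comb the peaks at the period and its integer multiples are
analytically equal under unbiased normalization, so floating-point noise
would select an arbitrary harmonic; ties within 5% of the highest peak
therefore resolve to the smallest lag, the fundamental. Estimates
require at least 3 episodes; degenerate inputs return "absent".

Summary statistics are spike rate (Hz), burst rate (per minute) and the
periodicity (s). Per-electrode trains can be pooled into one population
train before burst analysis, matching the population-level reporting of
MEA studies.

## Band decomposition and relative power

The 1 kHz signal is decomposed with a continuous analytic Morlet wavelet
over a log-spaced frequency axis (1–200 Hz, 16 voices per octave), and
band-limited signals are reconstructed by the delta-function inverse
restricted to the voices inside each band. Bands are delta 1–4 Hz
(the conventional "< 4 Hz" with a 1 Hz floor to keep DC and drift out),
theta 5–8, alpha 9–13, beta 14–32, low gamma 33–80 and upper gamma
100–200 Hz. The gaps between printed band edges are preserved, so the
six relative powers sum to less than 1 by construction.

The Morlet centre-frequency parameter is omega_0 = 16. The wavelet's
fractional bandwidth is sigma_f/f = 1/omega_0; the parameter was chosen
so that the band-edge transition stays well inside the narrowest
fractional band (theta) and inside low gamma's lower edge. Measured on
unit sinusoids at 2, 6, 11, 20, 40 and 150 Hz, in-band relative power is
>= 0.99 and leakage into any other band <= 0.002; with the textbook
omega_0 = 6 the transition at low gamma's 33 Hz edge is ~1 sigma from a
40 Hz tone and in-band recovery drops to ~0.75, which is why the wider
setting is the default. White-noise "tiling" (six band powers plus the
gap power) recovers ~92% of the total; the remaining deficit is the
smooth transition at band edges and is inherent to any finite-bandwidth
filter bank.

The inverse-transform normalization is calibrated empirically: for each
band, a unit sinusoid at the band's geometric centre is decomposed and
reconstructed, and the gain correction that restores unit amplitude is
cached. This makes the in-band gain exactly 1 at the calibration
frequency regardless of wavelet convention, and because the transform is
linear it guarantees amplitude linearity (doubling the signal quadruples
every absolute band power and leaves relative powers unchanged).

Band power is the Welch periodogram average (Hann window, 2000 ms
window, 1000 ms overlap — 2000/1000 samples at 1 kHz) integrated over
1–200 Hz. Relative power divides each band's power by the total Welch
power of the *unfiltered* downsampled signal over 1–200 Hz, which bounds
each fraction by 1 and makes profiles comparable across recordings; a
per-band/sum-of-bands alternative is exposed via `denominator="bands"`.

## LC-MS post-processing and statistics

The chain runs in a fixed, logged order: MRM selection → missingness
filter → minimum-value imputation → QC CV filter → total-sum
normalization → statistics. MRM selection runs first so that the
missingness fraction is computed on the quantifying transition only.
Choices within each step:

* **MRM score** — mean study-sample signal divided by the feature's SD
  across QC injections (mean alone without QC); exact ties keep the
  first-listed transition and are logged.
* **Missingness** — a feature is discarded when strictly more than 50%
  of *study* samples are missing (QC injections are policed by the CV
  filter); NaN/blank/"NA" encode missing, zeros are observed values.
* **Imputation** — remaining missing cells take the lowest registered
  signal in the whole filtered table (detection-limit behaviour); a
  per-feature mode is available.
* **QC CV** — sample SD / mean over >= 2 QC injections; features with
  CV > 30% are discarded. CVs are computed on raw (pre-normalization)
  signals, since filtering precedes normalization in the chain.
* **TSN** — each sample's signals divided by that sample's total.

Differential statistics report `log2fc = log2(mean_case/mean_control)`
on group means of normalized signals, two-sided p-values (Student's t by
default; Welch and Mann-Whitney selectable), `-log10(p)` for web-diagram
export, and Benjamini–Hochberg q-values. BH runs within each analyte
class by default (metabolites and lipids are separate panels),
configurable to whole-panel. A zero group mean flags the feature's fold
change as undefined instead of raising. Z-score matrices centre and
scale each feature across study samples (sample SD, ddof 1); zero-SD
features become all-zero rows with a flag.

Note that TSN is compositional: a fold change injected into a large
fraction of the panel is partially absorbed into the normalization
totals. The effect-recovery benchmark therefore injects balanced ±1
effects; sign agreement is >= 99% at n = 5/group and CV <= 30%.

## Seahorse parameters

Traces are partitioned into four phases by the injection times
(oligomycin, FCCP, rotenone/antimycin A, validated to be in canonical
order). Non-mitochondrial respiration is the mean OCR after
rotenone/antimycin; basal is the *last baseline reading* minus non-mito
(the convention the assay schematic depicts — a mean-of-phase mode is a
one-line change via the phase masks); maximal is the highest post-FCCP
reading minus non-mito; ATP-linked is the last baseline reading minus
the lowest post-oligomycin reading. Negative values are flagged, never
clipped, and maximal < basal flags "no spare capacity". Rates can be
normalized once to total protein (pmol/min/ug); double normalization is
an error.

## RT-QuIC seeding calls

The positivity rule: threshold = 10% of the maximum fluorescence
anywhere on the plate before the horizon (40 h for prion and
alpha-synuclein presets, 50 h for tau); a well is positive when any
pre-horizon reading strictly exceeds the threshold; a sample is positive
when the positive fraction of its replicate wells strictly exceeds 25%
(so 1 of 4 is negative, 2 of 4 positive). By default each well's initial
reading is subtracted first: applied to raw signal the rule degenerates,
because on a plate with no amplification the maximum is just baseline
fluorescence and every well trivially exceeds 10% of it. Per-well
background subtraction restores the rule's intent (responding to ThT
fluorescence *increase*) while keeping its scale invariance — rescaling
the whole plate never changes a call. A raw-signal mode is retained via
`baseline_subtract=False`.

## Synthetic data: what it emulates, and what it does not

* **MEA recordings** — Gaussian noise plus a biphasic template (~1 ms,
  dominant negative lobe, amplitude defined at the negative peak in
  multiples of the noise SD) at Poisson tonic spike times, plus bursts
  (Poisson onsets thinned to forbid overlap, fixed intra-burst ISI, or
  exactly periodic onsets when a period is configured), plus sinusoidal
  oscillations at representative in-band frequencies (2, 6, 11, 20, 40,
  150 Hz) with configured RMS amplitudes. Not modelled: biophysical
  waveform diversity, electrode drift, artifacts, 1/f background — so
  detection benchmarks bound performance under ideal stationary noise,
  not on real tissue.
* **Omics tables** — log-normal signals (biological CV 20% by default,
  a typical organoid replicate spread), group effects as log-mean
  shifts, detection-limit (lowest-quantile, MNAR) censoring, QC
  injections centred on pooled material with configured CV. Not
  modelled: correlated features, batch drift, retention-time effects.
* **OCR traces** — four noiseless-or-Gaussian plateaus, 3 reads per
  phase at 6 min spacing, injections annotated midway between phases.
* **RT-QuIC plates** — logistic ThT rise clamped to baseline before the
  lag time (midpoint at lag + 3 rise constants, rise constant 1.5 h),
  plateau ~200 000 AU over ~5000 AU baseline, reads every 45 min;
  negative wells flat. Not modelled: spontaneous conversion of negative
  wells at long incubation times.

All generators are bit-reproducible for a fixed seed.

## Benchmark problem sizes

The shipped test suite and `scripts/acceptance.py` use: 500 random spike
sets (<= 200 spikes) for the burst-oracle equivalence; six 60 s
single-channel recordings at 25 kHz (amplitudes 8–10x noise SD, 2 Hz
rate) for spike recovery; six 16 s single-band recordings for the
band-power chain; a 60-onset comb for periodicity; 200 replicate null
tables (1000 features, 5 vs 5) for FDR control; 100 random plateau
configurations for the Seahorse arithmetic; and 4-replicate plates at
0–4 positive wells for the seeding rule. These sizes give stable
estimates (e.g. ~700+ true spikes pooled for recall/precision) while
keeping the whole suite under a minute of compute.

## Known limitations

* The organoid band-pass family/order is not derivable from the
  acquisition software's description; 4th-order Butterworth zero-phase
  is a documented stand-in (configurable).
* Periodicity is estimated from burst onsets; a spike-train
  autocorrelation mode exists but burst-onset is the default.
* The CWT reconstruction loses a few percent of variance at band edges;
  comparisons between *relative* powers of the same band across
  recordings are unaffected, but absolute cross-band sums do not tile
  the spectrum.
* `differential` assumes approximately log-normal, independent
  features; TSN-induced compositional correlation is not corrected.
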