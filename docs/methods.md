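# Methods

This note documents the models, parameter choices and numerical decisions
behind `finpam`, and states what the synthetic-data generator does and does
not emulate — hence what a passing test suite does and does not demonstrate
about real recordings.

## Calibration and schedules

Counts convert to pressure per sample (`p = c · 10^((−S−G−M)/20)` µPa), so
calibration commutes with every downstream linear spectral estimate. The
defaults (S = −164 dB re 1 V/µPa, G = 22 dB, M = 84 dB → +58 dB) describe an
AURAL-class recorder; no frequency-dependent sensitivity correction is
applied. Duty cycles are `(record_minutes, period_minutes)` with one file
per period; a 5/60 duty records 1/12 of elapsed time. Analysis subsampling
("every n-th file of every m-th day") anchors at the first file and first
day — the phase is not otherwise constrained, so it is configurable — and is
implemented as a projection: the output frame records the applied scheme
and re-applying it is a no-op. Day counts are end-exclusive and leap-aware.
Timestamps are UTC everywhere except the diel layer, which applies the
fixed site convention UTC − 3 h 40 min (true solar time of 56° W; no
daylight saving).

## Spectral estimation and the LTS

Welch PSDs use the segment length as FFT size, mean removal only, one-sided
density scaling (unit-variance white noise → flat density `1/Nyquist`).
Window presets follow the three analysis chains: Hamming/50% at 2¹⁴ points
for LTS and FIN (2.0 Hz bins at 32 768 Hz), Hanning/50% at 20 000 points
for occurrence screening (1.6384 Hz bins, printed as 1.6 Hz), and
Hanning/90% at 334 points for call counting on 500 Hz decimated audio. The
334-point/90% configuration is taken as authoritative for the counting
chain; a nominal "1.5 s FFT length" quoted for that chain is mutually
inconsistent with 334 points at 500 Hz and is not used.

"Quietest 10 s" selection minimises broadband mean-square pressure (after
removing the file mean) over windows at a 1-s hop, earliest window winning
ties. The metric is deliberately broadband: mooring flow/shackle noise is
broadband, and a band-limited metric would bias against the very bands
being measured. The LTS holds one PSD column per analysed file; missing
files are NaN columns, never interpolated.

## FIN indices

`FIN = 10 log₁₀(S_sig / (0.5 (S_lo + S_hi)))` on mean linear densities. The
ratio is expressed in dB (a power quantity) — the published convention
plots these indices on dB axes. Band membership is by bin centre in the
closed interval, so with 2-Hz bins "86–88 Hz" averages exactly the 86 and
88 Hz bins; this resolves a genuine ambiguity in how 1-Hz-labelled bands
map onto coarser grids, and is documented rather than hidden. Zero combined
noise density yields +inf, which the series layer converts to missing. The
14-day running mean is time-based and centred, `[t−7 d, t+7 d)`, truncated
at the edges, NaN-skipping: on a 2-h grid an interior window holds exactly
168 samples. Whether multi-sample reduction should average ratios or dB
values is genuinely open in the literature; the dB mean is the default here
(`running_mean` operates on the dB series), and callers can average linear
ratios themselves if they prefer. FIN21 contamination by blue whale Z-calls
is reported, not corrected.

## The pulse detector

Manual audio-visual screening cannot be reproduced; the detector is a
declared methodological substitute whose performance is characterised on
synthetic ground truth.

Pipeline: decimate to ~125 Hz; spectrogram with a ~0.5 s Hann window, 1/8
hop and 4× zero-padded FFT (ridge placement to ~0.5 Hz rather than 2 Hz
quantisation); whiten by subtracting each frequency row's temporal median;
score each frame as the mean whitened level along the 28→15 Hz, 1-s sweep
trajectory; pick local maxima above 7 dB with 0.5 s minimum separation.
The working signal is reflect-padded by 1.5 s so calls at file edges still
receive a full kernel span.

Each candidate is classified from its spectro-temporal ridge (per-frame
argmax in 12–32 Hz):

* **zcall** — a time-contiguous, near-constant (σ < 1.5 Hz) tonal in
  25–29 Hz lasting ≥ 1.5 s anywhere in a 3.2-s look-back. Checked first:
  the step-down of a Z-call otherwise mimics a sweep.
* **fin20** — within the sweep's own window (−0.05 to 1.1 s), the
  contiguous active run (frames within 8 dB of the event peak) through the
  loudest mid-sweep frame must span ≥ 8 Hz, fall at ≤ −6 Hz/s
  (energy-weighted fit), drop from its early to late third, and stay inside
  12–32 Hz. Restricting to the contiguous run is what keeps neighbouring
  calls in a song sequence from corrupting the geometry.
* **chorus** — frames where the 15–30 Hz band stands ≥ 3 dB above a
  35–55 Hz reference for ≥ 60 s. The contrast is taken on absolute levels
  with a 10th-percentile baseline, because a chorus covering most of a file
  is invisible to median whitening. Inside chorus frames only candidates
  whose score clears the threshold by a further 4 dB count as calls —
  the automated analogue of logging only "clearly individual" signals.
* **other** — anything else; never counted.

Measured operating point (synthetic validation, 100 files, call SNR
10–20 dB over the floor, Z-calls present): recall ≈ 0.95–0.97, precision
≈ 0.99–1.0; recall ≈ 0.91 for isolated pulses at exactly 10 dB SNR; zero
false fin20 detections over 100 noise-only files at the default threshold.
These numbers characterise the detector *on the generator's call
morphology*; real calls vary in sweep rate and bandwidth, so the operating
point on real data must be re-estimated against an annotated subset.

## Counting, censoring, occurrence

CAB = total calls / total counted minutes × 60 over usable intervals.
Censored intervals (> 100 detections: calls merge beyond countability) and
excluded intervals (broadband 10–100 Hz level above the deployment's 95th
percentile — "excessive noise" has no absolute definition, so the gate is a
deployment quantile, configurable) are omitted from both numerator and
denominator. DAO scans a day's files in order and stops at the first fin20
event (later files are never loaded); chorus and Z-calls never set
presence. No song/non-song separation is attempted.

## Environment

The Deines equation is evaluated per bin and per beam, then beams are
dB-averaged (the combination rule is not standardised; the arithmetic dB
mean is the package's choice). Only C = −159.1 dB is an instrument-certified
constant for the 76.8 kHz Workhorse Longranger; the remaining defaults
(L_DBM = 10 log₁₀ 16 m, P_DBW = 10 log₁₀ 14 W, α = 0.024 dB/m,
Kc = 0.45 dB/count, Er = 40 counts) are plausible configuration values and
must be replaced by the deployment's calibration sheet for absolute levels.
Relative structure (diel cycles, seasonal peaks) is insensitive to them.
For the upward-looking geometry, bin depth = instrument depth − along-beam
range; the analysis range is 50–200 m (the upper 50 m are unreliable near
ice; a 50–300 m variant mentioned in places is available via the
`depth_range` argument). Migration amplitude = monthly mean noon
(10:00–14:00 local) minus midnight (22:00–02:00 local) backscatter-maximum
depth; positive for normal DVM, negative for an inverted cycle.

Ice averaging is an unweighted mean over pixels whose centres lie within
the great-circle radius (sphere of 6371 km); queries whose disc reaches the
grid's outer pixel ring are rejected rather than silently truncated.
Disc area uses the planar π r², adequate to well under 1% at 30 km.

## Diel statistics

Solar altitude uses the standard low-accuracy fractional-year expansion
(declination and equation-of-time Fourier series), good to a few tenths of
a degree — ample for a ±12° threshold. Boundary altitudes (exactly 0° or
−12°) classify as twilight; intervals take the regime of their midpoint.
The Kruskal–Wallis test is scipy's tie-corrected implementation wrapped to
report df, the χ² critical value at α, and the convention H = 0, p = 1 for
all-identical groups (where the tie correction is 0/0). One observation per
usable 10-min file is the default test unit. Null calibration on 1000
seeded replicates gives a type-I error within 0.05 ± 0.02; a 2× median
shift in one regime at n = 50/group is rejected in > 80% of replicates
(power threshold chosen as an implementation sanity bar).

## The synthetic-data generator

The generator emulates the study conditions, not arbitrary audio:

* **Calls.** The 20-Hz pulse is a linear 28→15 Hz, 1-s chirp,
  Tukey-tapered (10% per end) to avoid splatter into the noise bands;
  a 0.9-probability companion tone at 86 Hz sits 3 dB below it. The Z-call
  surrogate is ~1.8 s of 27 Hz tonal, a fast step to 19 Hz and a short
  tail; its morphology parameters are template fields. Call amplitudes are
  set by in-band SNR over the white noise floor (75 dB re 1 µPa²/Hz by
  default), drawn uniform 10–25 dB.
* **Seasonality.** Expected calls per 10-min interval follow a piecewise
  log-linear profile: onset 1 March, peak 84 calls/10 min on 12 May, offset
  17 July, edge rates 1% of peak, near-zero background outside. Counts per
  interval are Poisson; within an interval pulses form a song-like train
  (inter-pulse interval 7–15 s, compressed when the train no longer fits —
  the regime where real calls merge and counting is censored).
* **Chorus coupling.** Each file carries diffuse band noise in 15–30 Hz and
  85–89 Hz whose spectral density is proportional to the instantaneous call
  rate (+1.5 dB re the floor at 1 call/10 min) — the energy of many distant,
  unresolved callers. This is the feature that makes FIN track call
  abundance through the quietest-window LTS: tenfold rate, +10 dB in-band.
  The chorus bands are spectral brick-wall noise; filter skirts would leak
  into the bracing 80–82/92–94 Hz noise bands and corrupt the index. The
  85–89 Hz band keeps ≥ 3 Hz clearance from those bands so Welch-window
  leakage stays negligible.
* **Recorder.** Pressure is quantised to 16-bit counts through the inverse
  calibration before analysis, and WAV output is canonical RIFF with
  `YYYYMMDD_HHMMSS.wav` names. All randomness derives from one seed via
  per-file `SeedSequence` spawns: outputs are byte-identical across runs
  and any single file can be re-rendered in isolation.
* **ADCP and ice.** Ensembles every 3 h 45 min (45 pings × 5 min); a
  Gaussian scattering layer (mean depth 125 m, σ 30 m, +20 dB over a −95 dB
  background) oscillates in local time — deepest at noon — with the
  requested total displacement; echo counts come from inverting the Deines
  equation, quantised to 0–255 with ±1 count beam noise. The layer mean is
  chosen so a 100-m excursion stays inside the 50–200 m analysis range.
  The ice field is a Gaussian seasonal envelope peaking in early September,
  scaled by `winter_peak_fraction`, modulated by a fixed southeast-heavy
  spatial pattern on a 6.25 km grid.

**What the generator does not emulate** — and therefore what passing tests
do not establish about real data: coloured and non-stationary ambient
spectra (only white floor + white storm transients), sound propagation
(multipath, normal modes, range-dependent loss), call-morphology
variability between individuals and seasons, recorder self-noise and clock
drift, real Z-call harmonic structure, and chorus built from actual
overlapping distant calls rather than Gaussian band noise. Detector and FIN
results on synthetic data are validations of the *pipeline logic and its
statistical behaviour*, not of field performance.

## Scaled problem sizes

The year-scale analyses run on a reduced but structurally faithful
configuration chosen as the package's standard validation size: 60-s files
four times daily at 512 Hz, preserving the 2-Hz PSD bins of the full-rate
chain (nfft 256) and all band definitions. Detector validation uses 100
one-minute files at 500 Hz. At these sizes a full synthetic year runs in
seconds and the entire validation suite in a few minutes on one CPU.

The tenfold-rate FIN comparison is made between two days on the log-linear
rising limb of the profile (expected rates 0.5× and 0.05× peak). On the
limb the 14-day mean of a log-linear series is unbiased; at the seasonal
maximum the smoothing kink would deflate the value by ~1 dB and conflate
two effects. The measured rise (~9.1–9.5 dB against the ideal 10) is
slightly compressed because the quietest-window selection preferentially
picks low-chorus windows — a bias that is stronger at high rates — and
because the band SNR saturates toward the noise floor at the low end; both
effects are properties of the quietest-window LTS method itself, not of
the generator.

## Known limitations

* The detector's thresholds are calibrated on the generator's morphology;
  use on real data requires re-validation against an annotated subset.
* FIN21 in the presence of strong Z-call activity is contaminated by
  design (reported, not corrected); a config flag can mask intervals whose
  detections are Z-call dominated.
* Absolute MVBS levels depend on uncertified instrument constants; only
  C is certified.
* The 86-Hz component's real bandwidth statistics (e.g. 85.6 ± 1.5 Hz)
  are properties of field recordings; the generator's tone is narrower.
* Chorus-dominated intervals suppress call counting (as manual screening
  would); CAB during extreme chorus therefore reflects censoring, not
  silence.
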