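# finpam

Passive-acoustic monitoring of fin whale (*Balaenoptera physalus*) 20-Hz
pulses from moored polar hydrophone recordings, with the environmental
context needed to interpret their seasonality: zooplankton proxy
backscatter from an ADCP and satellite-style sea-ice concentration.

The package is aimed at marine-mammal ecologists working with duty-cycled
autonomous recorders (AURAL- or SonoVault-class instruments). It implements
the full chain from raw 16-bit WAV counts to seasonal call metrics, driven
either by real recordings or by a built-in, ground-truthed synthetic-data
generator so every stage can be exercised and validated without any
download.

## What it computes

**Calibration.** Recorder counts *c* map to sound pressure level through the
hydrophone sensitivity *S*, amplifier gain *G* and digital gain *M*:

    SPL [dB re 1 µPa] = 20 log₁₀(c) − S − G − M

With the default constants (S = −164 dB re 1 V/µPa, G = 22 dB, M = 84 dB)
the whole chain is a single additive constant of +58 dB.

**Long-term spectrogram (LTS).** One Welch PSD per analysed file, computed
on the *quietest 10 s* of that file (the window minimising broadband
mean-square pressure), which suppresses mooring flow and shackle noise.

**FIN indices.** Band signal-to-noise ratios of a call band against two
bracing noise bands, on mean linear spectral densities S:

    FIN [dB] = 10 log₁₀( S_sig / (0.5 (S_lo + S_hi)) )

Presets cover the Antarctic conventions FIN21 (20–22 Hz vs 8–10 / 30–32 Hz)
and FIN86 (86–88 Hz vs 80–82 / 92–94 Hz) plus the band rows used by other
studies. Because a calibration error shifts all three bands equally, FIN is
invariant under constant dB offsets. A change in the number of audible
calls N maps to a level change of 10 log₁₀(N₂/N₁) dB — ten times the calls,
ten more dB.

**Call metrics.** An automated spectrogram cross-correlation detector for
the ~1 s, 28→15 Hz downsweep (with ridge-based classification separating
blue whale Z-calls and the 15–30 Hz chorus of distant callers) feeds:

* **CAB** — call abundance: counted calls per hour over usable intervals,
  with ">100 calls / 10 min" censoring and broadband noise-gate exclusion;
* **DAO** — daily acoustic occurrence: a day is "present" at the first
  clearly individual pulse; chorus never sets presence.

**Environment.** ADCP echo intensity E becomes mean volume backscatter
strength via the Deines sonar equation

    MVBS = C + 10 log₁₀[(Tx + 273.16) R²] − L_DBM − P_DBW + 2αR + Kc (E − Er)

restricted to the 50–200 m analysis range; noon/midnight
backscatter-maximum depths give the diel vertical migration amplitude.
Daily sea-ice concentration is averaged over all pixels within a 30 km
radius of the site (≈ 2.8 × 10³ km², mirroring the acoustic detection
range).

**Diel statistics.** Solar altitude splits every interval into light /
twilight (0° to −12°) / dark regimes (local time = UTC − 3 h 40 min), and a
tie-corrected Kruskal–Wallis test compares call abundance across regimes
(critical value 5.99 at df = 2, α = 0.05).

## Worked example

```python
import numpy as np
from finpam import CalibrationSpec, counts_to_spl
from finpam.synthetic_data import ScenarioConfig, SeasonalProfile, RecordingSynthesizer
from finpam.spectral_analysis import PsdConfig, build_lts
from finpam.fin_index import BAND_PRESETS, fin_series
from finpam.call_analysis import detect_pulses

calib = CalibrationSpec()
print("combined constant:", calib.constant_db, "dB")    # 58.0 dB
print("SPL of c=100:", counts_to_spl(100, calib))       # 98.0 dB re 1 µPa

# a ground-truthed synthetic year (scaled: 60-s files, 4/day, 512 Hz)
config = ScenarioConfig.scaled_year(rng_seed=1, zcall_rate_per_10min=0.3)
profile = SeasonalProfile()          # onset 1 Mar, peak 12 May, offset 17 Jul
synth = RecordingSynthesizer(config, profile)
print("files in year:", len(synth))                     # 1460

events = detect_pulses(synth.segment(530))              # a mid-May file
print({e.call_class for e in events})                   # {'fin20'}

lts = build_lts(synth.iter_segments(),
                PsdConfig(nfft=256, window_shape="hamming",
                          overlap_fraction=0.5, sample_rate=512.0))
series = fin_series(lts, BAND_PRESETS["fin86"], smooth_days=14.0)
i = int(np.nanargmax(series.snr_db_smoothed))
print(f"FIN86 peak {series.snr_db_smoothed[i]:.1f} dB on {lts.times[i].date()}")
# FIN86 peak 18.0 dB on 2013-05-11
```

The smoothed FIN86 maximum lands in mid-May because the generator's call
rate (and with it the diffuse chorus energy in the call bands) peaks on
12 May; the 14-day running mean shifts it by at most a few days.

A full pipeline run (synthesis → LTS → FIN → calls → DAO → environment →
diel test → report) is one command:

```bash
finpam all --seed 1 --outdir finpam_out
```

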