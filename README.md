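# optophys

Analysis pipeline for in vivo recording sessions combining fiber photometry,
striatal unit recordings, opto-evoked local field potentials, and open-field
tracking — together with a synthetic-session generator that provides ground
truth for every stage, so the whole pipeline is testable without any
external data.

## What it does

| Module | Purpose |
| --- | --- |
| `optophys.synthetic` | Deterministic generators: bleached photometry traces with Poisson calcium transients, rate-modulated Poisson spike trains, stimulus-locked LFP deflections whose amplitude changes at a manipulation time, and reflected random-walk locomotion. Ground truth is always written beside the signals. |
| `optophys.protocols` | Stimulation schedules as explicit pulse-onset lists: 0.2 Hz test pulses, 5 Hz LFS (4500 pulses), theta-burst TBS (400 pulses), and two-block 60 Hz HFS (36,000 pulses) with block boundaries. |
| `optophys.photometry` | Sliding-window (2 min) dF/F normalization, >5% dF/F transient detection with a 1 s inter-event interval, artifact screening for fluorophore-only controls, 60-s binning and percent-of-pre time-courses. |
| `optophys.units` | 60-s firing-rate binning; potentiated / depressed / non-modulated classification via paired t-tests with Bonferroni correction and the >100% / <100% percent-of-pre direction rule. |
| `optophys.evoked` | ±100 ms trial extraction around test pulses, per-trial peak-to-peak amplitudes, wire-responsiveness screening, amplitude time-courses, and 25 ms OFF/ON evoked-firing analysis. |
| `optophys.spectral` | Bartlett-tapered averaged power spectra (512 frequency values spanning 0–100 Hz, 50% overlap), percent-of-total normalization, and the five-band power table (delta/theta/beta/low-gamma/high-gamma). |
| `optophys.behavior` | Instant velocity (1 s path length), 60-s binned percent-of-pre velocity time-courses, windowed distance moved, and the one-sided 3-SD subject-exclusion rule. |

All file formats are plain text: `time,value` CSV for traces, one timestamp
per row for spikes and pulses, `time,x,y` for tracks, JSON for manifests and
ground truth. Optional HDF5 bundling via `optophys.io.bundle_hdf5`.

## CLI

Everything is reachable through one entry point:

```bash
# build a stimulation schedule
optophys protocol build hfs --out hfs.csv

# generate a full synthetic session (photometry + units + LFP + track)
optophys simulate full-session --seed 1 --out session/

# photometry pipeline
optophys photometry normalize session/photometry.csv --out dff.csv
optophys photometry detect dff.csv --out events.csv
optophys photometry bin events.csv --out binned.csv
optophys photometry summary binned.csv --out summary.json

# unit classification and evoked analysis
optophys units classify session/unit*.csv --out calls.csv
optophys evoked classify session/lfp.csv session/schedule.csv --out lfp_call.json
optophys evoked firing session/unit0.csv session/schedule.csv --out firing.json

# spectra and locomotion
optophys spectral psd session/lfp.csv --out psd.csv
optophys spectral bands psd.csv --out bands.csv
optophys behavior velocity session/track.csv --out velocity.csv
```

## Conventions

- Bins are half-open `[left, right)` everywhere; an event on an edge goes to
  the later bin.
- dF/F uses the mean of a centered 2-min window (clipped at trace edges) as
  F; dF = x − F.
- Transient pruning is greedy in descending amplitude (ties → earlier time).
- The headline evoked amplitude is max − min over the 100 ms after pulse
  onset; the 100 ms before onset serves the responsiveness screen only.
- Default test windows pair minutes 11–30 of the pre period with minutes
  11–30 of the post period (bins 41–60 of the session); all windows are
  configurable.
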