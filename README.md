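# kymotrace

Analysis toolkit for single-molecule fluorescence kymographs of DNA-binding
proteins on tethered DNA (optical-tweezers / confocal line-scan experiments,
e.g. C-trap instruments), plus a ground-truthed simulator so every stage can
be validated without instrument data.

A kymograph is a 2D photon-count image built from repeated 1D line scans of a
single ~48.5 kb DNA molecule suspended between two beads: position on one
axis, time on the other. A bound fluorescent protein appears as a streak.
From such images, `kymotrace` extracts:

* **Tracks** — per-line Gaussian fits give subpixel line centers, which are
  linked frame to frame and then *curated*: GFP-derived fluorophores blink
  for up to ~2 s, so track fragments at the same position (< 100 nm) with
  off times < 2 s are reconnected into one binding event.
* **Dwell-time kinetics** — the cumulative residence time distribution
  CRTD(t) = #{dwells ≥ t} is fitted with an exponential-mixture survival
  model N·Σᵢ fᵢ·e^(−t/τᵢ) (1–3 components, BIC-selected). Apparent lifetimes
  are corrected for photobleaching per component via rate subtraction,
  1/τ_c = 1/τ_obs − 1/τ_b, where τ_b comes from a single-exponential fit to
  1-s-binned counts of immobilized fluorophores. The fraction-weighted
  average Σᵢ fᵢτᵢ summarizes each fit; K_d = k_off/k_on when an association
  rate is supplied.
* **Diffusion** — MSD(nΔt) = 1/(N−n)·Σᵢ(x_{i+n}−x_i)² fitted with
  2D(nΔt)^α + y over the initial linear portion; fits with R² < 0.8 or using
  < 10 % of the curve are excluded, tracks shorter than 1 s use α fixed at 1,
  and events are called motile when D exceeds a localization-noise floor.
* **Colocalization** — two-color events pair up when data points agree
  within 200 nm and 400 ms, and each event is sorted into one of **11
  classes**: 2 single-color plus the 3×3 grid of arrival order (A first /
  together / B first) × departure order.
* **smFRET** — per-frame donor/acceptor intensities with flanking-band
  background (6–9 px either side of the tracked line), donor bleed-through
  subtraction (the eGFP→mCherry calibration is 9.0 %), 10× downsampling,
  proximity-ratio efficiency E = I_A/(I_A+I_D) and distance
  r = R₀·(1/E − 1)^(1/6).
* **Binding-site maps** — event positions interpolate to genomic
  coordinates, cluster into sites (single linkage), and compare against
  nickase recognition-site scans (Nt.BspQI, 5′-GCTCTTCN-3′, nicking one
  nucleotide 3′ of the recognition sequence on either strand) of a FASTA
  reference.

The `simulate` module generates kymographs with Poisson photon statistics
over Gaussian point-spread profiles, Poisson binding at discrete damage
sites, exponential-mixture dwells, 1D Brownian motion, per-fluorophore
photobleaching clocks (running only during exposure, so pulsed excitation
stretches lifetimes), and blinking — with a complete ground-truth record for
recovery tests.

## Worked example

```python
import numpy as np
from kymotrace import simulate, tracking, kinetics

cfg = simulate.SimulationConfig(
    n_lines=30000,                       # 990 s at ~30 lines/s
    damage_sites=list(range(2000, 47000, 1550)),
    arrival_rate=0.012,                  # events / s / site
    dwell_components=[(5.0, 1.0)],       # true lifetime 5 s
    photobleach_lifetime=20.0,           # fluorophore survives ~20 s
    seed=1,
)
kymo, truth = simulate.simulate_kymograph(cfg)
tracks = tracking.track_kymograph(kymo, max_step=0.3, min_amplitude=20.0)
durations = [t.duration for t in tracks]
fit = kinetics.fit_exponentials(kinetics.build_crtd(durations), 1)
print(f"observed tau = {fit.lifetimes[0]:.2f} s")
print(f"corrected tau = {kinetics.correct_fit(fit, 20.0).lifetimes[0]:.2f} s")
```

```
observed tau = 4.54 s
corrected tau = 5.87 s
```

The observed lifetime sits near the analytic bleach-biased value
1/(1/5 + 1/20) = 4 s; the photobleaching correction restores it to within
sampling error of the true 5 s (this 990-s run contains ~340 events; the
acceptance workflow below uses a longer run for tighter statistics).

Published benchmark fits ship in `kymotrace.benchmarks`; for example the
catalytically dead OGG1 K249Q variant (lifetimes 8.9 s at 78 % and 183 s at
22 % after correction) gives a weighted average of 47.2 s — 23-fold longer
than the 2.0 s of wild-type OGG1 on the same oxidatively damaged DNA.

A command-line interface mirrors the library:
`kymotrace simulate|track|kinetics|diffusion|colocalize|fret|sites|all`.

## Layout

```
src/kymotrace/
  simulate.py    ground-truthed synthetic kymographs
  io.py          TIFF/HDF5 kymographs, CSV tracks, FASTA, JSON config
  tracking.py    detection, linking, blink-gap curation
  kinetics.py    CRTD fitting, photobleaching, rates, K_d
  diffusion.py   MSD and anomalous-diffusion fits
  colocal.py     two-color classification (11 classes)
  fret.py        smFRET efficiency and distance
  sites.py       genome mapping and nickase-site scans
  validation.py  end-to-end ground-truth recovery workflows
  cli.py         command-line pipeline
```

See `docs/methods.md` for the underlying models, parameter defaults, and
known limitations.
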