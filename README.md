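# ciliamotion

Quantify the passive oscillation of renal primary cilia from intravital
time-lapse fluorescence movies — and simulate such movies with known
ground truth so the whole measurement chain can be validated end to end.

## The problem

In the proximal tubule of a live, anesthetized mouse, GFP-labeled
primary cilia do not simply protrude into the lumen: high filtrate flow
bends them nearly parallel to the apical wall at a fixed point above the
base, and pulsatile flow can drive them back and forth through an arc of
roughly 106° at roughly 4.6 Hz, with most of each cycle spent bent along
the wall and whole fields moving in unison. When flow stops, the motion
ceases and cilia extend nearly perpendicularly into the lumen. Turning
movies of this behavior into numbers requires a chain of image-analysis
steps, each of which can silently bias the result. `ciliamotion`
packages that chain for microscopists and quantitative biologists:

1. **range-of-motion projection** — temporal mean showing the swept envelope;
2. **arc-path fit** — hinge, radius, and angular span of the tip path;
3. **kymograph** — line-scan intensity along the swept arc vs time;
4. **tip-angle trace** — robust per-frame tip angle θ(t);
5. **statistics** — dominant frequency by Hann-windowed FFT with
   parabolic peak refinement, total sweep angle, dwell-time fraction per
   tenth of the path, pairwise phase-locking (PLV) across a field, and a
   motion-state classification (`oscillating` / `static_bent` /
   `static_perpendicular`).

Because raw intravital recordings of this phenomenon are not publicly
deposited, the package includes a first-class synthetic generator: a
hinged filament driven by θ(t) = θ_min + S·u(t)^p with
u = (1 + sin(2πft + φ))/2, rendered with a Gaussian PSF, GFP-dilution
photon budgets, background autofluorescence, and Poisson noise. See
`docs/methods.md` for the model, its assumptions and its limits.

## Worked example

```bash
ciliamotion simulate --scenario renal_anesthetized --seed 1 --out sim/
ciliamotion analyze --movie sim/movie.tif --out analysis/
ciliamotion compare --report analysis/report.json \
    --truth sim/truth_traces.csv --traces analysis/traces.csv \
    --out metrics.json
```

The same chain from Python:

```python
import ciliamotion as cm

scenario = cm.get_scenario("renal_anesthetized")   # 26 fps x 40 s, seed 1
stack, truth = cm.simulate_field(scenario)         # 1040-frame movie + ground truth
report, art = cm.analyze_movie(stack)

c = report["cilia"][0]
print(round(c["frequency"]["frequency_hz"], 3))    # 4.58
print(round(c["sweep_angle_deg"], 1))              # 108.7
print(round(c["dwell_fractions"][0], 3))           # 0.53
print(c["motion_class"])                           # oscillating
```

The printed numbers mean: the beat frequency recovered through the full
noisy pipeline is 4.58 Hz (the generator's drive, to well within the
0.025 Hz spectral resolution of a 40 s record); the measured min–max
sweep is 108.7° (the configured 106° arc plus ~2–3° of noise-driven
excursion at the extremes); the wall-proximal tenth of the path holds
53% of the observation time — the majority, and far more than any
other decile; and the cilium is classified as oscillating. Analyzing a
`death`-scenario movie instead fails arc fitting with an
insufficient-motion error (there is no swept path to fit), and its
angle trace classifies as `static_perpendicular`.

`analysis/` also receives the kymograph (CSV) and the estimated trace
(CSV), and every report embeds the resolved configuration and seed, so
identical manifests reproduce identical reports.

## Layout

```
src/ciliamotion/
  simulate.py     scenario presets, drive law, renderer, Poisson sampling
  movie.py        MovieStack container
  movie_io.py     TIFF + sidecar, YAML/JSON configs, CSV traces, JSON reports
  extraction.py   projection, arc fit, kymograph, tip-angle trace
  oscillation.py  frequency, sweep, dwell, synchrony, classification
  pipeline.py     simulate/analyze/compare orchestration
  cli.py          `ciliamotion` command-line interface
```
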