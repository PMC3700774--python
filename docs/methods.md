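# Methods

## Scientific setting

Primary cilia of the renal proximal tubule are solitary, immotile (9+0)
protrusions thought to act as flow sensors. Intravital imaging of a
GFP-labeled ciliary membrane marker shows that under anesthesia these
cilia can oscillate passively in the lumen: they bend at a regular point
above the base, sweep an arc of roughly 106°, beat at roughly
4.6 Hz (compatible with anesthetized heart-rate-driven pulsatile
filtrate flow), spend the majority of each cycle bent along the tubule
wall in the downstream direction, move in unison across a field, and —
when flow stops at death — relax to stand nearly perpendicular to the
wall. `ciliamotion` implements the measurement chain for these
observations (projection → arc fit → kymograph → tip-angle trace →
spectral and occupancy statistics) together with a synthetic movie
generator so that every stage can be validated end to end against known
ground truth without access to raw intravital recordings.

## Kinematic model (generator)

The cilium is modeled as a rigid distal segment of length `distal_length`
pivoting about a fixed hinge `hinge_height` pixels above its base on the
wall. The in-plane tip angle follows a phenomenological saturating
drive

    θ(t) = θ_min + S · u(t)^p,    u(t) = (1 + sin(2π f t + φ)) / 2

with sweep span `S`, drive frequency `f`, phase `φ`, and dwell exponent
`p ≥ 1`. This is deliberately *not* an elastohydrodynamic simulation:
only the tip path is analyzed downstream, and the single shape
parameter `p` reproduces the wall-biased occupancy (p = 1 recovers a
sinusoid and hence the arcsine occupancy law; larger `p` concentrates
time near the wall-parallel extreme). The closed form gives the
fraction of a cycle spent in the lowest tenth of the sweep as
`1/2 + arcsin(2·0.1^(1/p) − 1)/π`: 0.477 at p = 3, 0.540 at p = 4. The
default is **p = 4**, the smallest integer exponent for which the
wall-proximal decile holds a strict majority of the cycle, as observed.
With `f = 0` and `S = 0` the cilium rests at 90° (the post-mortem
posture); reversal episodes, when enabled, mirror θ → 180° − θ for
exponentially distributed durations arriving as a Poisson process.

Default (`renal_anesthetized`) parameters: f = 4.58 Hz, S = 106°,
θ_min = 4°, p = 4, φ = −90°, 26 frames/s for 40 s (1040 frames),
hinge height 4 px, distal length 20 px on a 64×64 px frame. Two
phenotype presets: `death` (f = 0, S = 0 → rest at 90°) and
`steady_flow` (f = 0, pinned at 15° via φ = −90°, with rare reversals
at 0.02 events/s lasting 0.3 s on average).

## Optics and noise (generator)

Each filament (base → hinge ⊥ wall; hinge → tip at θ) is sampled at
≤ 0.25 px steps; samples deposit their share of the photon budget onto
the pixel grid by bilinear splatting and the image is convolved with an
isotropic Gaussian PSF (σ = 1.5 px), so expected signal per cilium is
independent of θ. The per-cilium budget is the per-cell budget divided
by `cilia_per_cell`, modeling dilution of a membrane GFP marker across
cilia number (≈150 cilia/cell in trachea vs ≈15 in ependyma vs ≈5 in
choroid plexus give 1 : 10 : 30 per-cilium brightness at equal
expression). Defaults: 80 photons per pixel of filament length per
frame on a background of 10 photons/px (strong autofluorescence is
typical of this tissue), i.e. a peak filament contrast of ≈ 21 photons —
a deliberately modest SNR. Frames are Poisson-sampled and quantized to
8 or 16 bits; saturated counts are clipped and logged, never wrapped.

What the generator does **not** emulate: filament flexure (the arc is
perfectly circular), motion blur within a frame, focus drift, tissue
motion/breathing artifacts, structured (non-uniform) autofluorescence,
photobleaching, and detector read noise. Passing tests therefore
demonstrate correctness of the measurement chain under the stated
kinematics and shot-noise optics, not robustness to every artifact of
real intravital data.

## Measurement chain

1. **Range-of-motion projection** — per-pixel temporal mean (the
   classic "average fluorescence over the record" view), plus the
   per-pixel temporal variance used downstream.
2. **Arc-path fit** — the envelope mask is thresholded robustly
   (median + max(5 × 1.4826·MAD, 2% of peak)) and reduced to its
   largest connected component. The hinge is found in two stages:
   (a) the blink index `(var − mean)/(mean − bg)²`, which estimates the
   off/on odds of a pixel and is ≈ 0 for the persistently lit stalk and
   hinge core, yields an initial estimate as the intensity-weighted
   centroid of low-blink pixels; (b) when frames are available, the
   estimate is refined as the least-squares common pivot of per-frame
   filament principal-axis lines (two passes, the second excluding the
   hub so the proximal stalk cannot bias the fit). Radius is 0.9× the
   maximum mask distance from the hinge; the span is the smallest
   sector holding 99% of mask pixels in a PSF-scale annulus at that
   radius. Movies whose envelope shows almost no intermittent signal
   (< 10% of mask pixels with blink ≥ 0.33) are rejected as
   insufficient motion — a static filament has no fittable sweep — and
   the user supplies an `ArcPath` manually.
3. **Kymograph** — bilinear line-scan at each equal-angle bin center on
   the tip circle, averaged over a few radially inward offsets spanning
   4.5 px (a line scan with width). Because the filament is radial
   about the hinge, inward samples cross it at the same angle but at
   full, untapered intensity; this keeps columns robust where the tip
   fades into the PSF. Equal angle on a circle is equal arc length, so
   "each tenth of the path" is well defined.
4. **Tip-angle trace** — per column, background = median, threshold =
   background + 3×MAD; the angle is the intensity-weighted centroid of
   the contiguous supra-threshold run containing the column maximum
   (isolated noise bins are thereby ignored). Columns with no signal
   are flagged `low_signal` and interpolated; > 50% such columns is an
   error.

## Statistics

- **Dominant frequency** — mean-subtracted, Hann-windowed FFT; the peak
  is searched above max(0.2 Hz, 2/T) and below Nyquist and refined by
  parabolic interpolation of log-power, beating the 1/T = 0.025 Hz bin
  resolution honestly. Validity requires SNR ≥ 5 (peak power over
  median non-DC power) and ≥ 2 observed cycles; peaks within 2
  resolution steps of Nyquist raise an aliasing flag. The estimate also
  carries the fraction of variance within ±2 resolution steps of the
  peak, distinguishing a sustained rhythm from a lone transient.
- **Sweep** — min–max of the trace (default) or the 1–99 percentile
  span (robust to brief reversals).
- **Dwell fractions** — occupancy per equal-angle bin of the observed
  min–max span over the whole record (a per-cycle option would change
  little for the ≈183 cycles of a default record); fractions sum to 1.
- **Synchrony** — pairwise phase-locking value (PLV) of analytic-signal
  phases. When the field has a consensus dominant frequency (≥ 2 valid
  estimates within 2 resolution steps of their median) each trace is
  band-passed to ±2 resolution steps around it first; without a
  consensus rhythm there is nothing to lock to and broadband phases are
  compared (narrowband filtering of independent noise would otherwise
  manufacture PLV ≈ 0.4–0.5 from only T·BW ≈ 4 independent phase
  samples).
- **Classification** — `oscillating` requires a valid frequency, a
  robust sweep ≥ 10°, and ≥ 20% of variance in the peak band; otherwise
  the circular mean angle separates `static_perpendicular`
  ([70°, 110°], the post-mortem posture) from `static_bent`. The
  robust sweep and band-variance guards exist because a single
  reversal boxcar in an otherwise pinned trace has a large min–max
  sweep and a high-leakage low-frequency peak, yet is not an
  oscillation.

The reported "4.58 ± 0.2 Hz" style spread is kept as three distinct
quantities: the spectral resolution of one record (1/T), the per-record
peak width, and the across-record SD of estimates; the test suite
bounds the last by ±0.2 Hz over seeds 1–20.

## Numerical choices and degenerate inputs

- Angles: degrees externally, radians internally; 0° = downstream
  wall-parallel, 90° = perpendicular; image origin top-left, y down.
- Frame k is stamped k/fps; frame count = floor(fps × duration);
  movies shorter than 4 frames are rejected.
- All randomness flows from `numpy.random.default_rng` seeded by
  (scenario seed, cilium index, stream key), so every stochastic output
  is reproducible and per-cilium draws are independent of each other
  and of the Poisson stream. Same seed ⇒ byte-identical movies.
- Constant traces: frequency estimate invalid ("no spectral peak"),
  sweep 0, dwell fractions undefined (error).
- Dwell bin indexing puts the right edge of the span in the last bin;
  ties at bin boundaries go to the higher bin (floor convention).
- The trace container enforces uniform sampling (to 1 ns) at
  construction, so spectral code never sees irregular timestamps.

## Problem sizes

The default scenario is deliberately desk-scale: 1040 frames of
64×64 px render and analyze in a few seconds; the multi-seed recovery
suites (seeds 1–20 for frequency spread, 1–10 for angle error) complete
in well under a minute on one core.

## Known limitations

- Auto arc fitting handles one cilium per field; crowded fields need
  one user-supplied `ArcPath` per cilium (by design).
- The arc model cannot represent non-circular tip paths (flexural
  deviations project onto the nearest arc).
- Angles are clipped to [0, 180°]; sweeps whose fitted sector crosses
  those limits are truncated at the boundary.
- Frequency estimates above Nyquist are unrecoverable (flagged, not
  corrected); at 26 fps the usable band ends at 13 Hz.
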