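"""Per-cilium and per-field oscillation statistics.

Covers the statistics used to characterize renal ciliary oscillation:
dominant beat frequency by windowed FFT with parabolic peak refinement,
total sweep angle, dwell-time occupancy per tenth of the swept path,
pairwise phase-locking (field synchrony), and a three-way motion-state
classification (oscillating / static bent along the wall / static
perpendicular to it).
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import signal as sps
from scipy import stats as sstats

from .errors import ConfigError, StageError
from .traces import AngleTrace

__all__ = [
    "FrequencyEstimate",
    "dominant_frequency",
    "sweep_angle",
    "dwell_fractions",
    "synchrony",
    "classify_motion",
    "MOTION_OSCILLATING",
    "MOTION_STATIC_BENT",
    "MOTION_STATIC_PERPENDICULAR",
]

logger = logging.getLogger(__name__)

MOTION_OSCILLATING = "oscillating"
MOTION_STATIC_BENT = "static_bent"
MOTION_STATIC_PERPENDICULAR = "static_perpendicular"

#: lowest frequency (Hz) ever considered a peak; also bounded by 2/duration
MIN_PEAK_HZ = 0.2
#: peak-power / median-non-DC-power required for a valid estimate
DEFAULT_SNR_THRESHOLD = 5.0
#: minimum sweep (degrees, robust span) for the oscillating class
MIN_OSCILLATION_SWEEP_DEG = 10.0
#: minimum share of variance in the peak band for a sustained rhythm
MIN_BAND_VARIANCE_FRACTION = 0.2


@dataclass
class FrequencyEstimate:
    """Dominant-frequency estimate of an angle trace.

    ``resolution`` is the spectral bin width 1/duration; ``snr`` is peak
    power over the median non-DC power; ``band_variance_fraction`` is the
    share of total variance within ±2 resolution steps of the peak (a
    sustained oscillation concentrates variance there, a lone transient
    does not).  Invalid estimates are returned, never dropped.
    """

    frequency: float  # Hz
    peak_power: float
    resolution: float  # Hz, = 1/duration
    snr: float
    valid: bool
    reason: str = ""
    aliasing_suspected: bool = False
    band_variance_fraction: float = float("nan")

    def to_dict(self) -> dict:
        return {
            "frequency_hz": self.frequency,
            "peak_power": self.peak_power,
            "resolution_hz": self.resolution,
            "snr": self.snr,
            "valid": self.valid,
            "reason": self.reason,
            "aliasing_suspected": self.aliasing_suspected,
            "band_variance_fraction": self.band_variance_fraction,
        }


def _check_uniform(trace: AngleTrace) -> float:
    if trace.n_frames < 4:
        raise StageError("need at least 4 frames for spectral analysis")
    dt = np.diff(trace.times)
    if np.ptp(dt) > 1e-9:
        raise StageError("non-uniform timestamps; resample before spectral analysis")
    return trace.fps


def dominant_frequency(
    trace: AngleTrace, snr_threshold: float = DEFAULT_SNR_THRESHOLD
) -> FrequencyEstimate:
    """FFT dominant frequency of an angle trace.

    Mean-subtracted, Hann-windowed DFT; the peak is the maximum power at
    frequencies above max(0.2 Hz, 2/duration) and below Nyquist, refined
    by parabolic interpolation over the peak and its neighbours on the
    log-power scale.  Validity requires snr >= ``snr_threshold`` and at
    least two observed cycles; a peak within two resolution steps of
    Nyquist raises the aliasing flag.
    """
    fps = _check_uniform(trace)
    n = trace.n_frames
    duration = n / fps
    resolution = 1.0 / duration

    x = trace.angles - trace.angles.mean()
    total_var = float(np.var(x))
    invalid = lambda reason: FrequencyEstimate(  # noqa: E731
        frequency=float("nan"),
        peak_power=0.0,
        resolution=resolution,
        snr=0.0,
        valid=False,
        reason=reason,
    )
    if total_var < 1e-12:
        return invalid("no spectral peak")

    w = sps.windows.hann(n, sym=False)
    spec = np.fft.rfft(x * w)
    power = np.abs(spec) ** 2
    freqs = np.fft.rfftfreq(n, d=1.0 / fps)

    fmin = max(MIN_PEAK_HZ, 2.0 / duration)
    cand = (freqs >= fmin) & (freqs < fps / 2)
    if not cand.any():
        return invalid("record too short for any resolvable frequency")
    idx = np.nonzero(cand)[0]
    k = idx[int(np.argmax(power[idx]))]
    pk = power[k]
    if pk <= 0:
        return invalid("no spectral peak")

    # parabolic refinement on log power (exact for a Gaussian-ish peak)
    if 1 <= k < len(power) - 1 and power[k - 1] > 0 and power[k + 1] > 0:
        lm, l0, lp = np.log(power[k - 1]), np.log(power[k]), np.log(power[k + 1])
        denom = lm - 2 * l0 + lp
        delta = 0.5 * (lm - lp) / denom if abs(denom) > 1e-300 else 0.0
        delta = float(np.clip(delta, -0.5, 0.5))
    else:
        delta = 0.0
    f_hat = (k + delta) * resolution

    nondc = power[1:]
    med = float(np.median(nondc))
    snr = float(pk / med) if med > 0 else float("inf")

    band = np.abs(freqs - f_hat) <= 2.0 * resolution
    band_frac = float(power[band].sum() / power.sum()) if power.sum() > 0 else 0.0

    aliasing = abs(f_hat - fps / 2) <= 2.0 * resolution
    valid = True
    reason = ""
    if snr < snr_threshold:
        valid, reason = False, f"snr {snr:.2f} below threshold {snr_threshold:g}"
    elif f_hat * duration < 2.0:
        valid, reason = False, "too few cycles"
    return FrequencyEstimate(
        frequency=float(f_hat),
        peak_power=float(pk),
        resolution=resolution,
        snr=snr,
        valid=valid,
        reason=reason,
        aliasing_suspected=bool(aliasing),
        band_variance_fraction=band_frac,
    )


def sweep_angle(trace: AngleTrace, method: str = "minmax") -> float:
    """Total angle traveled: span of the tip-angle trace.

    ``minmax`` (default) is max − min over quality-ok frames; ``percentile``
    is the robust 1–99 percentile span, insensitive to brief excursions
    such as posture reversals.
    """
    ok = trace.ok
    if not ok.any():
        raise StageError("all frames are low_signal; sweep undefined")
    a = trace.angles[ok]
    if a.size < 2:
        raise StageError("need at least 2 usable frames for a sweep")
    if method == "minmax":
        return float(a.max() - a.min())
    if method == "percentile":
        lo, hi = np.percentile(a, [1.0, 99.0])
        return float(hi - lo)
    raise ConfigError(f"unknown sweep method {method!r}")


def dwell_fractions(trace: AngleTrace, n_bins: int = 10) -> np.ndarray:
    """Occupancy fraction per equal-angle bin of the observed sweep.

    The observed [min, max] span (quality-ok frames) is split into
    ``n_bins`` equal-angle bins; bin 0 is wall-proximal (lowest angle).
    Fractions sum to 1.
    """
    if n_bins < 1:
        raise ConfigError("n_bins must be >= 1")
    ok = trace.ok
    a = trace.angles[ok]
    if a.size == 0:
        raise StageError("all frames are low_signal; dwell undefined")
    lo, hi = float(a.min()), float(a.max())
    if hi <= lo:
        raise StageError("zero sweep span; dwell fractions undefined")
    idx = np.floor((a - lo) / (hi - lo) * n_bins).astype(int)
    idx = np.clip(idx, 0, n_bins - 1)  # right edge joins the last bin
    counts = np.bincount(idx, minlength=n_bins)
    return counts / a.size


# ---------------------------------------------------------------------------
# synchrony
# ---------------------------------------------------------------------------

def _analytic_phase(x: np.ndarray, fps: float, band: Optional[tuple]) -> np.ndarray:
    """Instantaneous phase via the analytic signal, optionally band-passed.

    Band-passing is done by masking the FFT: positive frequencies inside
    the band are kept (doubled), everything else zeroed — this is the
    analytic signal of the band-passed series directly.
    """
    x = x - x.mean()
    n = x.size
    X = np.fft.fft(x)
    freqs = np.fft.fftfreq(n, d=1.0 / fps)
    mask = freqs > 0
    if band is not None:
        mask &= (freqs >= band[0]) & (freqs <= band[1])
    Xa = np.zeros_like(X)
    Xa[mask] = 2.0 * X[mask]
    za = np.fft.ifft(Xa)
    return np.angle(za)


def synchrony(
    traces: list, snr_threshold: float = DEFAULT_SNR_THRESHOLD
) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise phase-locking values and mean phase differences of a field.

    When the field has a consensus dominant frequency (at least two
    traces with valid estimates agreeing within two resolution steps of
    their median), each trace is band-passed to ±2 resolution steps
    around it before phase extraction — synchrony "in unison" is a
    phase-level claim at the common beat frequency.  Without a consensus
    rhythm there is nothing to lock to, so broadband analytic phases are
    compared instead (independent noise then scores near zero rather
    than the spuriously high values narrowband filtering would induce).

    Returns ``(plv, phase_diff_deg)``: PLV is symmetric with unit
    diagonal in [0, 1]; phase differences are antisymmetric, degrees.
    """
    if len(traces) < 2:
        raise StageError("synchrony needs at least 2 traces")
    n = traces[0].n_frames
    fps = traces[0].fps
    for tr in traces[1:]:
        if tr.n_frames != n:
            raise StageError("traces must have equal length")
        if abs(tr.fps - fps) > 1e-9:
            raise StageError("traces must share a frame rate")
    resolution = fps / n

    ests = [dominant_frequency(tr, snr_threshold=snr_threshold) for tr in traces]
    valid_f = np.array([e.frequency for e in ests if e.valid])
    band = None
    if valid_f.size >= 2:
        f0 = float(np.median(valid_f))
        if np.all(np.abs(valid_f - f0) <= 2.0 * resolution):
            band = (max(f0 - 2.0 * resolution, resolution), f0 + 2.0 * resolution)
    if band is None:
        logger.info("no consensus dominant frequency; using broadband phases")

    phases = [_analytic_phase(tr.angles.astype(float), fps, band) for tr in traces]
    m = len(traces)
    plv = np.eye(m)
    dphi = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            z = np.exp(1j * (phases[i] - phases[j])).mean()
            plv[i, j] = plv[j, i] = abs(z)
            d = math.degrees(np.angle(z))
            dphi[i, j] = d
            dphi[j, i] = -d
    return plv, dphi


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def classify_motion(trace: AngleTrace, freq: Optional[FrequencyEstimate] = None) -> str:
    """Three-way motion state of one cilium.

    ``oscillating`` requires a valid dominant frequency whose peak band
    holds a sustained share of the variance, plus a robust (1–99
    percentile) sweep of at least 10° — the percentile span, not
    min–max, so that rare posture reversals in an otherwise static
    cilium do not masquerade as oscillation.  Otherwise the circular
    mean angle decides: near-perpendicular rest ([70°, 110°], the
    posture after death when flow stops) vs bent along the wall.
    """
    if freq is None:
        freq = dominant_frequency(trace)
    robust_sweep = sweep_angle(trace, method="percentile")
    if (
        freq.valid
        and robust_sweep >= MIN_OSCILLATION_SWEEP_DEG
        and (
            not np.isfinite(freq.band_variance_fraction)
            or freq.band_variance_fraction >= MIN_BAND_VARIANCE_FRACTION
        )
    ):
        return MOTION_OSCILLATING
    mean_angle = float(
        sstats.circmean(trace.angles[trace.ok], high=360.0, low=0.0)
    )
    if mean_angle > 180.0:
        mean_angle -= 360.0
    if 70.0 <= mean_angle <= 110.0:
        return MOTION_STATIC_PERPENDICULAR
    return MOTION_STATIC_BENT
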