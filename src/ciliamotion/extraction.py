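"""Recover the tip path and per-frame tip angle from a movie.

The chain mirrors how oscillating cilia are quantified from intravital
recordings: a temporal-mean projection shows the full envelope swept by
the filament; the swept path is modeled as a circular arc about the fixed
bend point (hinge); repeated line-scans along that arc build a kymograph;
and a robust per-column centroid turns the kymograph into a tip-angle
trace.

Angle convention matches :mod:`ciliamotion.traces`: degrees in the image
plane, 0° along +x (downstream), 90° toward −y (into the lumen).  The
path coordinate is angular about the hinge — on a circle, equal angle is
equal arc length, which makes "each tenth of the total path" unambiguous
once the span is fixed.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage

from .errors import ConfigError, InsufficientMotionError, StageError, TraceUnreliableError
from .movie import MovieStack
from .traces import AngleTrace

__all__ = [
    "RangeOfMotionMap",
    "ArcPath",
    "Kymograph",
    "range_of_motion",
    "fit_arc_path",
    "extract_kymograph",
    "tip_angle_trace",
]

logger = logging.getLogger(__name__)

#: minimum angular extent (degrees) for arc fitting to make sense
MIN_SPAN_DEG = 5.0


@dataclass
class RangeOfMotionMap:
    """Temporal mean (and variance) projection of a movie window.

    The mean image is the classic range-of-motion view — average
    fluorescence over the window displaying the envelope of motion.  The
    per-pixel temporal variance is carried along because it separates the
    stationary filament base (shot noise only) from the swept region
    (on/off blinking), which is what hinge detection exploits.
    """

    image: np.ndarray  # (H, W) mean intensities
    variance: np.ndarray  # (H, W) temporal variance
    n_frames_used: int
    time_window: float  # s

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=float)
        self.variance = np.asarray(self.variance, dtype=float)
        if self.image.shape != self.variance.shape:
            raise ConfigError("mean and variance maps must share a shape")


@dataclass
class ArcPath:
    """Circular arc swept by a cilium tip, binned in equal angles."""

    hinge: tuple  # (x, y) pixels
    radius: float  # pixels
    angle_start: float  # degrees
    angle_end: float  # degrees
    n_bins: int = 100

    def __post_init__(self) -> None:
        self.hinge = (float(self.hinge[0]), float(self.hinge[1]))
        if not self.radius > 0:
            raise ConfigError("arc radius must be > 0")
        if not self.angle_start < self.angle_end:
            raise ConfigError("angle_start must be < angle_end")
        if self.n_bins < 2:
            raise ConfigError("n_bins must be >= 2")

    @property
    def span(self) -> float:
        return self.angle_end - self.angle_start

    @property
    def bin_edges(self) -> np.ndarray:
        return np.linspace(self.angle_start, self.angle_end, self.n_bins + 1)

    @property
    def bin_centers(self) -> np.ndarray:
        e = self.bin_edges
        return 0.5 * (e[:-1] + e[1:])

    def points(self, angles_deg) -> np.ndarray:
        """(x, y) pixel coordinates on the circle at the given angles."""
        a = np.deg2rad(np.asarray(angles_deg, dtype=float))
        x = self.hinge[0] + self.radius * np.cos(a)
        y = self.hinge[1] - self.radius * np.sin(a)
        return np.column_stack([x, y])

    def to_dict(self) -> dict:
        return {
            "hinge": list(self.hinge),
            "radius": self.radius,
            "angle_start": self.angle_start,
            "angle_end": self.angle_end,
            "n_bins": self.n_bins,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "ArcPath":
        return cls(
            hinge=tuple(data["hinge"]),
            radius=float(data["radius"]),
            angle_start=float(data["angle_start"]),
            angle_end=float(data["angle_end"]),
            n_bins=int(data.get("n_bins", 100)),
        )


@dataclass
class Kymograph:
    """Path-bin × frame intensity matrix from line-scans along an arc."""

    matrix: np.ndarray  # (n_bins, T)
    arc: ArcPath
    fps: float
    in_frame: np.ndarray = None  # type: ignore[assignment]  # per-bin validity

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.in_frame is None:
            self.in_frame = np.ones(self.matrix.shape[0], dtype=bool)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.arc.n_bins:
            raise ConfigError("kymograph rows must equal arc n_bins")

    @property
    def n_frames(self) -> int:
        return int(self.matrix.shape[1])


# ---------------------------------------------------------------------------
# range of motion
# ---------------------------------------------------------------------------

def range_of_motion(movie: MovieStack, window: Optional[float] = None) -> RangeOfMotionMap:
    """Per-pixel temporal mean (and variance) over the first ``window`` s.

    With ``window`` omitted the whole movie is used, reproducing the
    "average fluorescence over the record" projection.
    """
    if window is None:
        k = movie.n_frames
    else:
        if window <= 0:
            raise ConfigError("window must be > 0 seconds")
        if window > movie.duration + 1e-9:
            raise ConfigError(
                f"window {window} s exceeds movie duration {movie.duration:.3f} s"
            )
        k = max(1, int(round(window * movie.fps)))
    frames = np.asarray(movie.frames[:k], dtype=float)
    return RangeOfMotionMap(
        image=frames.mean(axis=0),
        variance=frames.var(axis=0),
        n_frames_used=k,
        time_window=k / movie.fps,
    )


# ---------------------------------------------------------------------------
# arc fitting
# ---------------------------------------------------------------------------

def _foreground_mask(image: np.ndarray) -> tuple[np.ndarray, float]:
    """Above-background mask of the motion envelope, largest component only."""
    bg = float(np.median(image))
    mad = float(np.median(np.abs(image - bg)))
    noise = 1.4826 * mad
    peak = float(image.max())
    if peak <= bg:
        raise InsufficientMotionError("range-of-motion map is featureless")
    thresh = bg + max(5.0 * noise, 0.02 * (peak - bg))
    mask = image > thresh
    if not mask.any():
        raise InsufficientMotionError("no pixels above background in the map")
    labels, n = ndimage.label(mask)
    if n > 1:
        sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
        mask = labels == (1 + int(np.argmax(sizes)))
    return mask, bg


def _hinge_from_variance(rom: RangeOfMotionMap, mask: np.ndarray, bg: float) -> tuple:
    """Locate the hinge as the centroid of the persistently lit pixels.

    For a pixel that is lit a fraction p of frames at amplitude A over
    background, (var − mean) / (mean − bg)² estimates (1 − p)/p (the
    Poisson part cancels through the subtracted mean): ≈ 0 for the
    always-on proximal stalk and hinge core, large for the swept fan.
    """
    mean_sig = np.clip(rom.image - bg, 1e-9, None)
    blink = (rom.variance - rom.image) / mean_sig**2
    static = mask & (blink < 0.33)
    if not static.any():
        ys, xs = np.nonzero(mask)
        i = int(np.argmin(blink[mask]))
        return (float(xs[i]), float(ys[i]))
    ys, xs = np.nonzero(static)
    w = mean_sig[ys, xs]
    return (float(np.average(xs, weights=w)), float(np.average(ys, weights=w)))


def _refine_hinge_by_lines(
    movie: MovieStack, mask: np.ndarray, hinge0: tuple, n_lines: int = 200
) -> tuple:
    """Refine the hinge as the common pivot of per-frame filament lines.

    Every frame's filament is (nearly) a ray through the hinge; the
    least-squares point closest to all per-frame principal-axis lines is
    therefore the hinge.  Two passes: the second excludes pixels near the
    current hinge estimate so the proximal stalk (which is not collinear
    with the distal segment) cannot bias the fit.
    """
    T = movie.n_frames
    stride = max(1, T // n_lines)
    frames = np.asarray(movie.frames[::stride], dtype=float)
    ys, xs = np.nonzero(mask)
    hinge = hinge0
    for exclude_r in (0.0, None):
        if exclude_r is None:
            # exclude the hub: stalk plus near-hinge fan core
            rr = np.hypot(xs - hinge[0], ys - hinge[1])
            rmax = float(rr.max()) if rr.size else 0.0
            keep = rr > max(3.0, 0.25 * rmax)
        else:
            keep = np.ones(xs.shape, dtype=bool)
        if keep.sum() < 8:
            break
        kx, ky = xs[keep], ys[keep]
        A = np.zeros((2, 2))
        b = np.zeros(2)
        for fr in frames:
            w = fr[ky, kx]
            bg = float(np.median(fr))
            noise = 1.4826 * float(np.median(np.abs(fr - bg)))
            # suppress shot noise so only filament pixels carry weight
            w = np.clip(w - (bg + 3.0 * noise), 0.0, None)
            tot = w.sum()
            if tot <= 0:
                continue
            cx = float(np.dot(w, kx)) / tot
            cy = float(np.dot(w, ky)) / tot
            dx, dy = kx - cx, ky - cy
            cov = np.array(
                [
                    [np.dot(w, dx * dx), np.dot(w, dx * dy)],
                    [np.dot(w, dx * dy), np.dot(w, dy * dy)],
                ]
            ) / tot
            evals, evecs = np.linalg.eigh(cov)
            v = evecs[:, int(np.argmax(evals))]
            n = np.array([-v[1], v[0]])  # unit normal to the filament line
            P = np.outer(n, n) * tot
            A += P
            b += P @ np.array([cx, cy])
        if np.linalg.cond(A) > 1e8:
            logger.debug("line-intersection hinge refinement ill-conditioned; keeping %s", hinge)
            return hinge
        sol = np.linalg.solve(A, b)
        hinge = (float(sol[0]), float(sol[1]))
    return hinge


def _smallest_sector(angles_deg: np.ndarray, coverage: float = 0.99) -> tuple:
    """Smallest circular sector (start, end) containing ``coverage`` of angles."""
    a = np.sort(np.mod(angles_deg, 360.0))
    n = a.size
    m = max(1, int(math.ceil(coverage * n)))
    ext = np.concatenate([a, a + 360.0])
    spans = ext[m - 1 : m - 1 + n] - a
    i = int(np.argmin(spans))
    start = a[i]
    end = ext[i + m - 1]
    # map back near the principal branch used for tip angles
    if start > 180.0:
        start -= 360.0
        end -= 360.0
    return float(start), float(end)


def fit_arc_path(
    rom: RangeOfMotionMap,
    movie: Optional[MovieStack] = None,
    hinge_hint: Optional[tuple] = None,
    n_bins: int = 100,
) -> ArcPath:
    """Fit the tip's swept arc from the range-of-motion projection.

    The hinge is the hint if given; otherwise it is located from the
    temporal statistics (the non-moving base persists across frames) and,
    when the movie is available, refined as the least-squares common
    pivot of per-frame filament lines.  The radius is 0.9× the maximum
    mask distance from the hinge; the span is the smallest sector holding
    99% of the mask pixels within a PSF-scale annulus around that radius.
    """
    mask, bg = _foreground_mask(rom.image)
    # motion gate: a swept fan blinks on and off; a static filament does not.
    mean_sig = np.clip(rom.image - bg, 1e-9, None)
    blink = (rom.variance - rom.image) / mean_sig**2
    moving_frac = float((blink[mask] >= 0.33).mean())
    if moving_frac < 0.1:
        raise InsufficientMotionError(
            f"only {moving_frac:.0%} of envelope pixels show intermittent signal: "
            "insufficient motion; supply ArcPath manually"
        )
    if hinge_hint is not None:
        hinge = (float(hinge_hint[0]), float(hinge_hint[1]))
    else:
        hinge = _hinge_from_variance(rom, mask, bg)
        if movie is not None:
            hinge = _refine_hinge_by_lines(movie, mask, hinge)

    ys, xs = np.nonzero(mask)
    r = np.hypot(xs - hinge[0], ys - hinge[1])
    rmax = float(r.max())
    if rmax <= 0:
        raise InsufficientMotionError("motion envelope collapses onto the hinge")
    radius = 0.9 * rmax

    tol = max(2.0, 0.15 * radius)
    annulus = np.abs(r - radius) <= tol
    if annulus.sum() < 3:
        raise InsufficientMotionError(
            "too few envelope pixels at the tip radius; supply ArcPath manually"
        )
    ang = np.degrees(np.arctan2(-(ys[annulus] - hinge[1]), xs[annulus] - hinge[0]))
    start, end = _smallest_sector(ang, coverage=0.99)
    if end - start < MIN_SPAN_DEG:
        raise InsufficientMotionError(
            f"angular extent {end - start:.2f} deg < {MIN_SPAN_DEG} deg: "
            "insufficient motion; supply ArcPath manually"
        )
    return ArcPath(hinge=hinge, radius=radius, angle_start=start, angle_end=end, n_bins=n_bins)


# ---------------------------------------------------------------------------
# kymograph
# ---------------------------------------------------------------------------

def extract_kymograph(
    movie: MovieStack, arc: ArcPath, scan_width: float = 4.5
) -> Kymograph:
    """Line-scan the movie along the arc, every frame.

    Each kymograph entry is the bilinear-interpolated intensity at the
    equal-angle bin center on the tip circle, averaged over a few
    radially inward offsets spanning ``scan_width`` pixels (a line scan
    with width).  Because the filament is radial about the hinge, inward
    samples cross it at the same angle but at full, untapered intensity,
    which keeps the scan robust where the tip itself fades into the PSF.
    Set ``scan_width=0`` for a pure single-radius scan.
    """
    H, W = movie.frame_shape
    pts = arc.points(arc.bin_centers)  # (n_bins, 2) as (x, y)
    in_frame = (
        (pts[:, 0] >= 0) & (pts[:, 0] <= W - 1) & (pts[:, 1] >= 0) & (pts[:, 1] <= H - 1)
    )
    if not in_frame.any():
        raise StageError("arc path lies entirely outside the frame")
    if not in_frame.all():
        logger.warning(
            "%d of %d arc bins fall outside the frame and were clipped",
            int((~in_frame).sum()),
            arc.n_bins,
        )
    if scan_width > 0:
        n_off = max(2, int(math.ceil(scan_width / 1.5)) + 1)
        offsets = np.linspace(0.0, -min(scan_width, 0.6 * arc.radius), n_off)
    else:
        offsets = np.array([0.0])
    a = np.deg2rad(arc.bin_centers)
    radii = arc.radius + offsets[:, None]  # (n_off, n_bins)
    x = arc.hinge[0] + radii * np.cos(a)[None, :]
    y = arc.hinge[1] - radii * np.sin(a)[None, :]
    coords = np.stack([y.ravel(), x.ravel()])  # (row, col) for map_coordinates
    T = movie.n_frames
    matrix = np.empty((arc.n_bins, T), dtype=float)
    for t in range(T):
        vals = ndimage.map_coordinates(
            np.asarray(movie.frames[t], dtype=float), coords, order=1, mode="constant"
        ).reshape(len(offsets), arc.n_bins)
        matrix[:, t] = vals.mean(axis=0)
    return Kymograph(matrix=matrix, arc=arc, fps=movie.fps, in_frame=in_frame)


# ---------------------------------------------------------------------------
# tip-angle trace
# ---------------------------------------------------------------------------

def tip_angle_trace(kymo: Kymograph) -> AngleTrace:
    """Per-frame tip angle from the kymograph.

    Per column: background is the column median; qualifying bins exceed
    background + 3× the column MAD; the angle is the intensity-weighted
    centroid of bin centers over the contiguous qualifying run containing
    the column maximum (isolated supra-threshold noise bins are ignored).
    Columns with no qualifying bin are flagged ``low_signal`` and filled
    by linear interpolation; more than 50% such columns is an error.
    """
    M = kymo.matrix
    n_bins, T = M.shape
    if T < 2:
        raise StageError("kymograph has fewer than 2 frames")
    centers = kymo.arc.bin_centers
    valid_bins = kymo.in_frame
    if valid_bins.sum() < 2:
        raise StageError("fewer than 2 arc bins inside the frame")
    angles = np.full(T, np.nan)
    low = np.zeros(T, dtype=bool)
    sub = M[valid_bins]
    sub_centers = centers[valid_bins]
    for t in range(T):
        col = sub[:, t]
        bg = float(np.median(col))
        mad = float(np.median(np.abs(col - bg)))
        thr = bg + 3.0 * mad
        above = col > thr
        if mad == 0:
            above = col > bg
        if not above.any():
            low[t] = True
            continue
        # contiguous run around the global maximum
        k = int(np.argmax(col))
        if not above[k]:
            low[t] = True
            continue
        lo = k
        while lo > 0 and above[lo - 1]:
            lo -= 1
        hi = k
        while hi < col.size - 1 and above[hi + 1]:
            hi += 1
        w = col[lo : hi + 1] - bg
        angles[t] = float(np.average(sub_centers[lo : hi + 1], weights=w))
    n_low = int(low.sum())
    if n_low > 0.5 * T:
        raise TraceUnreliableError(
            f"trace unreliable: {n_low}/{T} frames lack signal above threshold"
        )
    if n_low:
        good = np.nonzero(~low)[0]
        angles[low] = np.interp(np.nonzero(low)[0], good, angles[good])
    angles = np.clip(angles, 0.0, 180.0)
    times = np.arange(T, dtype=float) / kymo.fps
    return AngleTrace(times=times, angles=angles, low_signal=low)
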