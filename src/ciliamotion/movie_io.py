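"""File formats: multi-frame TIFF movies with JSON sidecars, CSV traces,
YAML/JSON scenario and analysis configs, JSON reports.

Frame rate deliberately lives in a sidecar JSON next to the TIFF rather
than in TIFF frame-interval tags, which are dialect-ridden; an explicit
value beats an inferred one.  All schemas carry a ``schema_version``.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import tifffile
import yaml

from .errors import ConfigError, InputError, MovieParseError
from .movie import MovieStack
from .simulate import CiliumScenario
from .traces import AngleTrace

__all__ = [
    "SCHEMA_VERSION",
    "AnalysisConfig",
    "read_movie",
    "write_movie",
    "sidecar_path_for",
    "load_scenario",
    "save_scenario",
    "load_analysis_config",
    "read_traces_csv",
    "write_traces_csv",
    "write_report",
    "read_report",
]

logger = logging.getLogger(__name__)

SCHEMA_VERSION = "1"


def sidecar_path_for(movie_path) -> Path:
    return Path(movie_path).with_suffix(".json")


# ---------------------------------------------------------------------------
# movies
# ---------------------------------------------------------------------------

def write_movie(stack: MovieStack, path, sidecar_path=None) -> Path:
    """Write a multi-frame grayscale TIFF plus its JSON sidecar."""
    path = Path(path)
    sidecar = Path(sidecar_path) if sidecar_path else sidecar_path_for(path)
    frames = stack.frames
    if frames.dtype not in (np.uint8, np.uint16):
        raise InputError(
            f"movie frames must be uint8 or uint16 for TIFF output, got {frames.dtype}"
        )
    tifffile.imwrite(path, frames, photometric="minisblack")
    meta = {
        "schema_version": SCHEMA_VERSION,
        "fps": stack.fps,
        "pixel_size_um": stack.pixel_size_um,
        "bit_depth": stack.bit_depth,
        "n_frames": stack.n_frames,
        "source": stack.source,
    }
    sidecar.write_text(json.dumps(meta, indent=2) + "\n")
    return path


def read_movie(path, sidecar_path=None) -> MovieStack:
    """Read a multi-frame grayscale TIFF; fps comes from the sidecar.

    Intensities are preserved bit-exactly.  RGB input is rejected with
    advice to extract a channel; a missing or fps-less sidecar is an
    error (there is no default frame rate).  Truncated files produce a
    structured error naming the first unreadable frame.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"movie file not found: {path}")
    sidecar = Path(sidecar_path) if sidecar_path else sidecar_path_for(path)
    if not sidecar.exists():
        raise InputError(
            f"sidecar JSON not found: {sidecar}; frame rate must be supplied "
            "explicitly (never inferred from TIFF tags)"
        )
    meta = json.loads(sidecar.read_text())
    if "fps" not in meta or meta["fps"] is None:
        raise InputError(f"sidecar {sidecar} lacks required key 'fps'")
    fps = float(meta["fps"])
    if fps <= 0:
        raise ConfigError("fps must be > 0")

    frames = []
    try:
        tif = tifffile.TiffFile(path)
    except Exception as exc:  # unreadable header
        raise MovieParseError(f"cannot open TIFF {path}: frame 0 unreadable ({exc})")
    with tif:
        for i, page in enumerate(tif.pages):
            try:
                arr = page.asarray()
            except Exception as exc:
                raise MovieParseError(
                    f"TIFF {path} truncated or corrupt at frame {i}: {exc}"
                ) from exc
            if arr.ndim == 3:
                raise InputError(
                    f"frame {i} of {path} is multi-channel (shape {arr.shape}); "
                    "extract a single grayscale channel before analysis"
                )
            frames.append(arr)
    if not frames:
        raise MovieParseError(f"TIFF {path} contains no frames (frame 0 missing)")
    expected = meta.get("n_frames")
    if expected is not None and len(frames) < int(expected):
        # tifffile tolerates truncation by dropping unreachable pages
        raise MovieParseError(
            f"TIFF {path} truncated: frame {len(frames)} missing "
            f"(sidecar declares {expected} frames)"
        )
    stack = MovieStack(
        frames=np.stack(frames),
        fps=fps,
        pixel_size_um=meta.get("pixel_size_um"),
        source=str(path),
        bit_depth=meta.get("bit_depth"),
    )
    if not stack.usable_for_motion:
        logger.warning("%s has a single frame; unusable for motion analysis", path)
    return stack


# ---------------------------------------------------------------------------
# configs
# ---------------------------------------------------------------------------

def _load_structured(path) -> dict:
    path = Path(path)
    if not path.exists():
        raise InputError(f"config file not found: {path}")
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"config {path} must be a mapping, got {type(data).__name__}")
    return data


def load_scenario(path) -> CiliumScenario:
    """Load a scenario config (YAML or JSON).

    Unknown keys are rejected; omitted keys take the anesthetized-renal
    defaults, which the output report records for provenance.
    """
    data = _load_structured(path)
    data.pop("schema_version", None)
    return CiliumScenario.from_dict(data)


def save_scenario(scenario: CiliumScenario, path) -> Path:
    path = Path(path)
    payload = {"schema_version": SCHEMA_VERSION, **scenario.to_dict()}
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(payload, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(payload, sort_keys=False))
    return path


@dataclass
class AnalysisConfig:
    """Options for the analyze stage."""

    movie: Optional[str] = None
    sidecar: Optional[str] = None
    arc_paths: tuple = ()  # explicit arc specs (dicts); empty -> auto-fit one
    hinge_hint: Optional[tuple] = None
    kymo_bins: int = 100
    dwell_bins: int = 10
    sweep_method: str = "minmax"  # or "percentile"
    snr_threshold: float = 5.0
    out_dir: Optional[str] = None
    log_level: str = "INFO"
    seed: int = 1

    def __post_init__(self) -> None:
        if self.kymo_bins < 2:
            raise ConfigError("kymo_bins must be >= 2")
        if self.dwell_bins < 1:
            raise ConfigError("dwell_bins must be >= 1")
        if self.sweep_method not in ("minmax", "percentile"):
            raise ConfigError("sweep_method must be 'minmax' or 'percentile'")
        if self.snr_threshold <= 0:
            raise ConfigError("snr_threshold must be > 0")
        if isinstance(self.arc_paths, list):
            self.arc_paths = tuple(self.arc_paths)
        if self.hinge_hint is not None:
            self.hinge_hint = tuple(float(v) for v in self.hinge_hint)

    def to_dict(self) -> dict:
        out = {}
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, tuple):
                v = list(v)
            out[f.name] = v
        return out

    @classmethod
    def from_dict(cls, data: dict) -> "AnalysisConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(
                f"unknown analysis keys: {sorted(unknown)}; known: {sorted(known)}"
            )
        return cls(**data)


def load_analysis_config(path) -> AnalysisConfig:
    data = _load_structured(path)
    data.pop("schema_version", None)
    return AnalysisConfig.from_dict(data)


# ---------------------------------------------------------------------------
# traces
# ---------------------------------------------------------------------------

def write_traces_csv(traces, path) -> Path:
    """Write angle traces as CSV (frame, time_s, cilium_id, angle_deg, quality)."""
    path = Path(path)
    rows = []
    for cid, tr in enumerate(traces):
        rows.append(
            pd.DataFrame(
                {
                    "frame": np.arange(tr.n_frames),
                    "time_s": tr.times,
                    "cilium_id": cid,
                    "angle_deg": tr.angles,
                    "quality": tr.quality,
                }
            )
        )
    pd.concat(rows, ignore_index=True).to_csv(path, index=False, float_format="%.17g")
    return path


def read_traces_csv(path) -> list:
    path = Path(path)
    if not path.exists():
        raise InputError(f"trace CSV not found: {path}")
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"frame", "time_s", "cilium_id", "angle_deg"}
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"trace CSV {path} lacks columns {sorted(missing)}")
    traces = []
    for _, grp in df.groupby("cilium_id", sort=True):
        grp = grp.sort_values("frame")
        low = (
            grp["quality"].to_numpy() == "low_signal"
            if "quality" in grp
            else np.zeros(len(grp), dtype=bool)
        )
        traces.append(
            AngleTrace(
                times=grp["time_s"].to_numpy(),
                angles=grp["angle_deg"].to_numpy(),
                low_signal=low,
            )
        )
    return traces


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def write_report(report: dict, path) -> Path:
    path = Path(path)
    payload = {"schema_version": SCHEMA_VERSION, **_jsonable(report)}
    path.write_text(json.dumps(payload, indent=2) + "\n")
    return path


def read_report(path) -> dict:
    path = Path(path)
    if not path.exists():
        raise InputError(f"report not found: {path}")
    return json.loads(path.read_text())
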