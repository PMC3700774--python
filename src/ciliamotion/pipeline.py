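"""Orchestration: simulate -> analyze -> compare.

These are the library-level entry points behind the CLI subcommands; they
return plain dictionaries (reports, manifests, metrics) that serialize
directly to the versioned JSON schemas in :mod:`ciliamotion.movie_io`.
Every report embeds the fully resolved configuration and seed, so two
runs with identical manifests produce identical reports.
"""
from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional

import numpy as np

from . import __version__
from .errors import InputError, StageError
from .extraction import (
    ArcPath,
    extract_kymograph,
    fit_arc_path,
    range_of_motion,
    tip_angle_trace,
)
from .movie import MovieStack
from .movie_io import (
    SCHEMA_VERSION,
    AnalysisConfig,
    read_movie,
    write_movie,
    write_report,
    write_traces_csv,
)
from .oscillation import classify_motion, dominant_frequency, dwell_fractions, sweep_angle, synchrony
from .simulate import CiliumScenario, simulate_field
from .traces import AngleTrace

__all__ = ["run_simulate", "analyze_movie", "run_analyze", "compare_traces"]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# simulate
# ---------------------------------------------------------------------------

def run_simulate(scenario: CiliumScenario, out_dir, force: bool = False) -> dict:
    """Simulate a field and persist movie + sidecar + truth CSV + manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    movie_path = out / "movie.tif"
    if movie_path.exists() and not force:
        raise InputError(f"{movie_path} exists; pass force=True/--force to overwrite")
    stack, truth = simulate_field(scenario)
    write_movie(stack, movie_path)
    truth_path = out / "truth_traces.csv"
    write_traces_csv(truth, truth_path)
    manifest = {
        "schema_version": SCHEMA_VERSION,
        "software_version": __version__,
        "command": "simulate",
        "seed": scenario.seed,
        "scenario": scenario.to_dict(),
        "outputs": {
            "movie": movie_path.name,
            "sidecar": movie_path.with_suffix(".json").name,
            "truth_traces": truth_path.name,
        },
        "n_frames": stack.n_frames,
    }
    write_report(manifest, out / "manifest.json")
    return manifest


# ---------------------------------------------------------------------------
# analyze
# ---------------------------------------------------------------------------

def _stage(name: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except StageError as exc:
        raise StageError(f"stage '{name}' failed: {exc}") from exc


def analyze_movie(
    movie: MovieStack,
    config: Optional[AnalysisConfig] = None,
) -> tuple[dict, dict]:
    """Run the full chain on an in-memory movie.

    range-of-motion projection -> arc-path fit (or user arcs) ->
    kymograph -> tip-angle trace -> frequency / sweep / dwell /
    classification, plus field synchrony when several cilia are traced.

    Returns ``(report, artifacts)`` where ``artifacts`` holds the
    intermediate objects (map, arcs, kymographs, traces) for optional
    persistence or inspection.
    """
    if config is None:
        config = AnalysisConfig()
    if not movie.usable_for_motion:
        raise InputError("single-frame movie: motion analysis impossible")

    rom = _stage("range_of_motion", range_of_motion, movie)
    if config.arc_paths:
        arcs = [ArcPath.from_dict(d) for d in config.arc_paths]
        for arc in arcs:
            arc.n_bins = config.kymo_bins
    else:
        arcs = [
            _stage(
                "fit_arc_path",
                fit_arc_path,
                rom,
                movie=movie,
                hinge_hint=config.hinge_hint,
                n_bins=config.kymo_bins,
            )
        ]

    per_cilium = []
    kymos = []
    traces = []
    for cid, arc in enumerate(arcs):
        kymo = _stage("extract_kymograph", extract_kymograph, movie, arc)
        trace = _stage("tip_angle_trace", tip_angle_trace, kymo)
        freq = _stage("dominant_frequency", dominant_frequency, trace, config.snr_threshold)
        sweep = _stage("sweep_angle", sweep_angle, trace, config.sweep_method)
        dwell = _stage("dwell_fractions", dwell_fractions, trace, config.dwell_bins)
        mclass = _stage("classify_motion", classify_motion, trace, freq)
        per_cilium.append(
            {
                "cilium_id": cid,
                "arc": arc.to_dict(),
                "frequency": freq.to_dict(),
                "sweep_angle_deg": sweep,
                "sweep_method": config.sweep_method,
                "dwell_fractions": dwell.tolist(),
                "motion_class": mclass,
                "n_low_signal_frames": int(trace.low_signal.sum()),
            }
        )
        kymos.append(kymo)
        traces.append(trace)

    report = {
        "software_version": __version__,
        "command": "analyze",
        "config": config.to_dict(),
        "seed": config.seed,
        "movie": {
            "source": movie.source,
            "n_frames": movie.n_frames,
            "fps": movie.fps,
            "frame_shape": list(movie.frame_shape),
        },
        "cilia": per_cilium,
    }
    if len(traces) >= 2:
        plv, dphi = _stage("synchrony", synchrony, traces, config.snr_threshold)
        report["field"] = {
            "synchrony_plv": plv.tolist(),
            "mean_phase_diff_deg": dphi.tolist(),
        }
    artifacts = {"range_of_motion": rom, "arcs": arcs, "kymographs": kymos, "traces": traces}
    return report, artifacts


def run_analyze(config: AnalysisConfig, out_dir=None, persist: bool = True) -> dict:
    """File-level analyze: read movie per config, run the chain, persist."""
    if not config.movie:
        raise InputError("analysis config must name a movie")
    movie = read_movie(config.movie, config.sidecar)
    report, artifacts = analyze_movie(movie, config)
    if persist:
        out = Path(out_dir or config.out_dir or ".")
        out.mkdir(parents=True, exist_ok=True)
        write_report(report, out / "report.json")
        write_traces_csv(artifacts["traces"], out / "traces.csv")
        for cid, kymo in enumerate(artifacts["kymographs"]):
            np.savetxt(
                out / f"kymograph_c{cid}.csv", kymo.matrix, delimiter=",", fmt="%.17g"
            )
    return report


# ---------------------------------------------------------------------------
# compare
# ---------------------------------------------------------------------------

def compare_traces(report: dict, truth: list, est_traces: Optional[list] = None) -> dict:
    """Recovery metrics of an analysis report against ground-truth traces.

    Per cilium: absolute frequency error (Hz), absolute sweep error
    (degrees), per-frame angle RMS error (degrees, when the estimated
    traces are supplied), and total-variation distance between estimated
    and true dwell-fraction vectors.
    """
    cilia = report.get("cilia", [])
    if len(cilia) != len(truth):
        raise InputError(
            f"report has {len(cilia)} cilia but truth has {len(truth)}: id mismatch"
        )
    if est_traces is not None and len(est_traces) != len(cilia):
        raise InputError("est_traces length must match report cilia: id mismatch")
    out = []
    for entry, true_tr in zip(cilia, truth):
        true_freq = dominant_frequency(true_tr)
        true_sweep = sweep_angle(true_tr)
        true_dwell = dwell_fractions(true_tr, len(entry["dwell_fractions"]))
        f_est = entry["frequency"]["frequency_hz"]
        freq_err = (
            abs(f_est - true_freq.frequency)
            if (np.isfinite(f_est) and true_freq.valid)
            else float("nan")
        )
        sweep_err = abs(entry["sweep_angle_deg"] - true_sweep)
        dwell_tv = 0.5 * float(
            np.abs(np.asarray(entry["dwell_fractions"]) - true_dwell).sum()
        )
        rms = float("nan")
        if est_traces is not None:
            est_tr: AngleTrace = est_traces[entry["cilium_id"]]
            if est_tr.n_frames != true_tr.n_frames:
                raise InputError("trace length mismatch between report and truth")
            rms = float(
                np.sqrt(np.mean((est_tr.angles - true_tr.angles) ** 2))
            )
        out.append(
            {
                "cilium_id": entry["cilium_id"],
                "frequency_error_hz": freq_err,
                "sweep_error_deg": sweep_err,
                "angle_rms_error_deg": rms,
                "dwell_tv_distance": dwell_tv,
            }
        )
    return {"software_version": __version__, "command": "compare", "cilia": out}
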