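"""Motion extraction: projection, arc fitting, kymograph, tip-angle trace."""
import numpy as np
import pytest

import ciliamotion as cm
from ciliamotion.extraction import (
    ArcPath,
    Kymograph,
    RangeOfMotionMap,
    extract_kymograph,
    fit_arc_path,
    range_of_motion,
    tip_angle_trace,
)
from ciliamotion.movie import MovieStack
from ciliamotion.movie_io import AnalysisConfig

TRUE_HINGE = (32.0, 48.0)  # renal default: base (32, 52), hinge_height 4


# ---------------------------------------------------------------------------
# range of motion
# ---------------------------------------------------------------------------

class TestRangeOfMotion:
    def test_constant_movie_mean_equals_frame(self):
        frames = np.full((5, 8, 8), 3.0)
        rom = range_of_motion(MovieStack(frames=frames, fps=26.0))
        assert np.allclose(rom.image, 3.0)
        assert rom.n_frames_used == 5

    def test_mean_of_alternating_frames(self):
        frames = np.stack([np.zeros((4, 4)), np.full((4, 4), 2.0)])
        rom = range_of_motion(MovieStack(frames=frames, fps=2.0))
        assert np.allclose(rom.image, 1.0)

    def test_window_selects_prefix(self):
        frames = np.stack([np.full((4, 4), v) for v in (0.0, 0.0, 8.0, 8.0)])
        rom = range_of_motion(MovieStack(frames=frames, fps=2.0), window=1.0)
        assert np.allclose(rom.image, 0.0)
        with pytest.raises(cm.ConfigError):
            range_of_motion(MovieStack(frames=frames, fps=2.0), window=0.0)
        with pytest.raises(cm.ConfigError):
            range_of_motion(MovieStack(frames=frames, fps=2.0), window=10.0)

    def test_envelope_covers_ground_truth_masks(self, noiseless_renal, renal_scenario):
        """Thresholded projection covers >=95% of the union of per-frame
        half-max filament masks (oracle built from the noiseless render)."""
        stack, _ = noiseless_renal
        frames = np.asarray(stack.frames)
        union = np.zeros(frames.shape[1:], bool)
        for k in range(frames.shape[0]):
            sig = frames[k] - renal_scenario.background
            union |= sig > 0.5 * sig.max()
        rom = range_of_motion(stack)
        from ciliamotion.extraction import _foreground_mask

        mask, _ = _foreground_mask(rom.image)
        assert (mask & union).sum() / union.sum() >= 0.95


# ---------------------------------------------------------------------------
# arc fitting
# ---------------------------------------------------------------------------

class TestFitArcPath:
    def test_recovers_known_hinge_and_usable_radius(self, renal_sim, renal_scenario):
        stack, _ = renal_sim
        rom = range_of_motion(stack)
        arc = fit_arc_path(rom, movie=stack)
        assert np.hypot(arc.hinge[0] - TRUE_HINGE[0], arc.hinge[1] - TRUE_HINGE[1]) < 2.0
        # scan circle must transect the distal segment below its tip
        assert 0.85 * renal_scenario.distal_length <= arc.radius <= 1.05 * renal_scenario.distal_length
        # fitted sector must contain the true sweep
        assert arc.angle_start <= renal_scenario.wall_angle_min + 2
        assert arc.angle_end >= renal_scenario.wall_angle_min + renal_scenario.sweep_span - 2

    def test_analytic_annular_sector_span(self):
        """A perfect annular sector drawn analytically is recovered to
        within one path-bin width."""
        H = W = 128
        yy, xx = np.mgrid[0:H, 0:W]
        hinge = (64.0, 64.0)
        r = np.hypot(xx - hinge[0], yy - hinge[1])
        ang = np.degrees(np.arctan2(-(yy - hinge[1]), xx - hinge[0]))
        sector = (r >= 30) & (r <= 45) & (ang >= 20) & (ang <= 120)
        image = np.where(sector, 100.0, 0.0)
        rom = RangeOfMotionMap(
            image=image, variance=image * 100.0, n_frames_used=10, time_window=1.0
        )
        arc = fit_arc_path(rom, hinge_hint=hinge, n_bins=100)
        bin_width = arc.span / arc.n_bins
        assert abs(arc.span - 100.0) <= max(bin_width, 1.0) + 0.5
        assert abs(arc.angle_start - 20.0) <= 1.5
        assert abs(arc.angle_end - 120.0) <= 1.5

    def test_static_movie_raises_insufficient_motion(self):
        sc = cm.get_scenario("death", duration=10.0)
        stack, _ = cm.simulate_field(sc)
        rom = range_of_motion(stack)
        with pytest.raises(cm.InsufficientMotionError):
            fit_arc_path(rom, movie=stack)


# ---------------------------------------------------------------------------
# kymograph
# ---------------------------------------------------------------------------

class TestKymograph:
    def test_uniform_movie_gives_uniform_kymograph(self):
        frames = np.full((6, 64, 64), 5.0)
        stack = MovieStack(frames=frames, fps=26.0)
        arc = ArcPath(hinge=(32, 48), radius=15.0, angle_start=0.0, angle_end=120.0)
        kymo = extract_kymograph(stack, arc)
        assert np.allclose(kymo.matrix, 5.0)

    def test_delta_tip_argmax_tracks_known_angle(self):
        radius = 25.0
        hinge = (40.0, 50.0)
        true_angles = np.linspace(10.0, 110.0, 20)
        frames = np.zeros((20, 96, 96))
        for k, a in enumerate(true_angles):
            x = hinge[0] + radius * np.cos(np.deg2rad(a))
            y = hinge[1] - radius * np.sin(np.deg2rad(a))
            frames[k, int(round(y)), int(round(x))] = 100.0
        stack = MovieStack(frames=frames, fps=26.0)
        arc = ArcPath(hinge=hinge, radius=radius, angle_start=0.0, angle_end=120.0, n_bins=50)
        kymo = extract_kymograph(stack, arc, scan_width=0.0)
        bin_width = arc.span / arc.n_bins
        for k, a in enumerate(true_angles):
            best = arc.bin_centers[int(np.argmax(kymo.matrix[:, k]))]
            assert abs(best - a) <= bin_width

    def test_arc_outside_frame_raises(self):
        stack = MovieStack(frames=np.zeros((4, 16, 16)), fps=26.0)
        arc = ArcPath(hinge=(500.0, 500.0), radius=10.0, angle_start=0.0, angle_end=90.0)
        with pytest.raises(cm.StageError):
            extract_kymograph(stack, arc)

    def test_renal_kymograph_finite_nonnegative(self, renal_analysis):
        _, art = renal_analysis
        M = art["kymographs"][0].matrix
        assert np.isfinite(M).all() and (M >= 0).all()


# ---------------------------------------------------------------------------
# tip-angle trace
# ---------------------------------------------------------------------------

class TestTipAngleTrace:
    def _arc(self, n_bins=100):
        return ArcPath(hinge=(0, 0), radius=10.0, angle_start=0.0, angle_end=100.0, n_bins=n_bins)

    def test_single_bright_bin_gives_bin_center(self):
        arc = self._arc(n_bins=10)
        M = np.zeros((10, 8))
        for t in range(8):
            M[t % 10, t] = 50.0
        tr = tip_angle_trace(Kymograph(matrix=M, arc=arc, fps=26.0))
        assert np.allclose(tr.angles, arc.bin_centers[np.arange(8) % 10])

    def test_all_flat_columns_unreliable(self):
        arc = self._arc()
        M = np.full((100, 10), 2.0)
        with pytest.raises(cm.TraceUnreliableError):
            tip_angle_trace(Kymograph(matrix=M, arc=arc, fps=26.0))

    def test_noiseless_chain_rms_below_2_degrees(self, noiseless_renal):
        stack, truth = noiseless_renal
        _, art = cm.analyze_movie(stack)
        err = art["traces"][0].angles - truth[0].angles
        assert np.sqrt(np.mean(err**2)) < 2.0

    def test_steady_flow_movie_mean_angle_below_45(self):
        """High steady flow pins the cilium near the wall."""
        stack, _ = cm.simulate_field(cm.get_scenario("steady_flow"))
        cfg = AnalysisConfig(
            arc_paths=(
                {"hinge": [32.0, 48.0], "radius": 18.0, "angle_start": 0.0, "angle_end": 180.0},
            )
        )
        _, art = cm.analyze_movie(stack, cfg)
        assert art["traces"][0].angles.mean() < 45.0


# ---------------------------------------------------------------------------
# chain properties
# ---------------------------------------------------------------------------

class TestChainProperties:
    def test_rotation_equivariance(self):
        """Rotating the movie by 90 deg shifts recovered angles by 90."""
        sc = cm.CiliumScenario(
            wall_angle_min=95.0, sweep_span=70.0, duration=10.0,
            base_positions=((36.0, 56.0),),
        )
        frames, _ = cm.render_movie(sc)
        stack = MovieStack(frames=frames, fps=sc.fps)
        _, art = cm.analyze_movie(stack)
        a0 = art["traces"][0].angles
        # exact pixel permutation: clockwise rotation, angle -> angle - 90
        rot = np.rot90(frames, k=3, axes=(1, 2)).copy()
        stack_r = MovieStack(frames=rot, fps=sc.fps)
        _, art_r = cm.analyze_movie(stack_r)
        a1 = art_r["traces"][0].angles
        offset = a0 - a1
        assert abs(np.median(offset) - 90.0) < 1.0
        assert np.percentile(np.abs(offset - np.median(offset)), 95) < 1.0

    def test_bin_count_consistency(self, noiseless_renal):
        """Tip traces from 100- and 200-bin kymographs agree within one
        coarse bin width."""
        stack, _ = noiseless_renal
        rom = range_of_motion(stack)
        arc = fit_arc_path(rom, movie=stack, n_bins=100)
        coarse = tip_angle_trace(extract_kymograph(stack, arc))
        import dataclasses

        arc2 = dataclasses.replace(arc, n_bins=200)
        fine = tip_angle_trace(extract_kymograph(stack, arc2))
        bin_width = arc.span / arc.n_bins
        assert np.max(np.abs(coarse.angles - fine.angles)) <= bin_width

    def test_noisy_recovery_median_error_below_3_degrees(self):
        """Across seeds 1-10 of the noisy pipeline the median per-frame
        angle error stays below 3 degrees."""
        errs = []
        for seed in range(1, 11):
            stack, truth = cm.simulate_field(
                cm.get_scenario("renal_anesthetized", seed=seed)
            )
            _, art = cm.analyze_movie(stack)
            errs.append(np.median(np.abs(art["traces"][0].angles - truth[0].angles)))
        assert np.median(errs) < 3.0
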