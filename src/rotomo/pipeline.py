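"""End-to-end orchestration of the rotation-tomography workflow.

``run_pipeline`` chains the stages of the autonomous reconstruction
workflow: simulate (or load) a rotation video, detect and crop the cell,
segment and center-align every frame, seed Harris features and track them by
optical flow, convert tracks to a fused rotation-angle series, reconstruct
the volume by filtered back-projection and — when ground truth is available
— reconstruct the limited-angle baseline and write the metric comparison.
Every stage's outputs and a structured parameter log land in the run
directory; re-running with the same configuration and seed reproduces all
numeric outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.optimize import isotonic_regression

from . import io as rio
from .errors import FusionGap, OrbitDegenerate, RotomoError, ValidationError
from .evaluate import compare_methods, tracking_report
from .phantom import (
    PhantomSpec,
    ProjectionStack,
    default_phantom_spec,
    make_phantom,
    render_rotation_video,
)
from .preprocess import (
    center_align,
    crop_stabilize,
    detect_cell,
    min_enclosing_circle,
    segment_cell,
    smooth_circles,
)
from .reconstruct import ReconConfig, limited_angle_reconstruct, reconstruct_volume, spatial_filter
from .rotation_tracking import (
    AngleSeries,
    FeatureTrack,
    fit_orbit,
    harris_features,
    track_flow,
    track_to_angles,
)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "estimate_angles"]


@dataclass
class PipelineConfig:
    """Configuration of one end-to-end run.

    Exactly one of ``phantom`` (simulate) or ``input_path`` (load a recorded
    stack) must be set.  ``seed`` drives every stochastic stage.
    """

    phantom: PhantomSpec | None = None
    input_path: str | None = None
    out_dir: str = "rotomo_run"
    seed: int = 0
    # simulation
    n_frames: int = 180
    total_angle: float = 180.0
    # preprocessing
    crop_size: int = 128
    polarity: str = "bright"
    min_area: float = 50.0
    smooth_window: int = 9
    # tracking
    max_features: int = 16
    min_distance: int = 5
    harris_k: float = 0.04
    flow_window: int = 21
    flow_levels: int = 3
    fb_threshold: float = 1.0
    direction: int = 1
    min_orbit_radius: float = 5.0
    refine_iters: int = 5
    stagnation_window: int = 5
    stagnation_tol: float = 1.0
    # reconstruction
    reconstruct: bool = True
    recon: ReconConfig = field(default_factory=ReconConfig)
    limited_range: float = 160.0
    post_smooth_sigma: float = 0.0
    # evaluation
    evaluate: bool = True

    def validate(self) -> None:
        if (self.phantom is None) == (self.input_path is None):
            raise ValidationError(
                "exactly one of phantom spec or input path must be set"
            )
        if self.direction not in (1, -1):
            raise ValidationError("direction must be +1 or -1")


@dataclass
class PipelineResult:
    """In-memory handles to everything a run produced."""

    out_dir: Path
    angles: AngleSeries
    volume: "object"
    truth_angles: np.ndarray | None = None
    tracking: "object | None" = None
    comparison: "object | None" = None
    log: dict = field(default_factory=dict)


def estimate_angles(
    aligned: ProjectionStack,
    masks: list,
    circles: list,
    cfg: PipelineConfig,
) -> tuple[AngleSeries, list]:
    """Harris seeding, bidirectional optical-flow tracking, joint angle fusion.

    Features are seeded on the first frame and tracked forward, and seeded
    on the last frame and tracked backward: a feature is typically clean up
    to its transit across the cell silhouette and unreliable after it, so
    the two passes together cover both arcs.  Per-feature angle series use
    the current rotation estimate to pick the arcsine branch; tracks whose
    overall angular span is implausible for the constant-rate drive are
    discarded, and the per-frame angle is solved jointly with per-feature
    anchor biases by two-way weighted least squares with per-sample Tukey
    biweight robustness (a tracker that silently slips produces a smooth but
    discordant series; robust weights suppress exactly those samples).  A
    feature's base weight is the square of ``orbit_radius × geometric
    sensitivity`` — lateral pixels of displacement per radian of rotation.
    The whole estimate is refined alternately for ``cfg.refine_iters``
    rounds: orbit refits against the updated angle series, and a per-frame
    common-mode lateral offset (alignment jitter, shared by all features)
    estimated as the median orbit residual.  The final series is projected
    onto monotone non-decreasing angles (the device rotates one way) and
    anchored at 0°.  Tracks with an orbit radius below
    ``cfg.min_orbit_radius`` pixels carry almost no angular information per
    pixel step and are dropped.
    """
    n = len(aligned)
    nominal = np.arange(n) * (cfg.total_angle / n)

    def run_pass(stack: ProjectionStack, pass_masks: list, id_offset: int):
        seeds = harris_features(
            stack.frames[0], pass_masks[0], max_n=cfg.max_features,
            min_distance=cfg.min_distance, k=cfg.harris_k,
        )
        tracks = track_flow(
            stack, seeds, masks=pass_masks, window=cfg.flow_window,
            levels=cfg.flow_levels, fb_threshold=cfg.fb_threshold,
        )
        for tr in tracks:
            tr.feature_id += id_offset
        return tracks

    tracks = run_pass(aligned, masks, 0)
    reversed_stack = ProjectionStack(frames=list(reversed(aligned.frames)))
    for tr_rev in run_pass(reversed_stack, list(reversed(masks)), len(tracks)):
        tracks.append(
            FeatureTrack(
                feature_id=tr_rev.feature_id,
                positions=tr_rev.positions[::-1].copy(),
                valid=tr_rev.valid[::-1].copy(),
                response=tr_rev.response,
            )
        )

    def build(regressor: np.ndarray, delta: np.ndarray):
        """Orbit fits and branch-resolved angle series for every track.

        ``regressor`` is the current rotation estimate used both as the
        sinusoid-fit abscissa and for arcsine branch selection; ``delta`` is
        the per-frame common-mode lateral offset subtracted from all tracks.
        Tracks whose overall angular span is outside 0.5-1.5× the span the
        constant-rate drive implies are rejected outright: a tracker stuck
        on the static silhouette reports almost no rotation, and such tracks
        agree with each other, so they must not reach the joint solve.
        """
        raws: dict[int, np.ndarray] = {}
        scores: dict[int, np.ndarray] = {}
        orbits: dict[int, tuple] = {}
        for tr in tracks:
            pos = tr.positions.copy()
            pos[:, 1] -= delta
            trc = FeatureTrack(tr.feature_id, pos, tr.valid, tr.response)
            try:
                orbit = fit_orbit(trc, circles[0], nominal_angles=regressor)
            except OrbitDegenerate:
                continue
            if orbit.orbit_radius < cfg.min_orbit_radius:
                continue
            ang, sens = track_to_angles(
                trc, orbit, direction=cfg.direction, nominal_angles=regressor
            )
            finite = np.flatnonzero(np.isfinite(ang))
            if len(finite) < 20:
                continue
            span = ang[finite[-1]] - ang[finite[0]]
            nominal_span = regressor[finite[-1]] - regressor[finite[0]]
            if nominal_span > 0 and not 0.5 <= span / nominal_span <= 1.5:
                continue
            raws[tr.feature_id] = ang
            scores[tr.feature_id] = np.nan_to_num(sens) * orbit.orbit_radius
            orbits[tr.feature_id] = (orbit, pos)
        return raws, scores, orbits

    def angle_solve(raws, scores, keep, theta0, iters=10, tukey_c=3.5):
        """Robust two-way least squares for theta_i and per-feature anchors.

        Model: raw_f[i] = theta_i + b_f + noise.  Solving for the per-frame
        angle directly (rather than chaining increments) keeps every frame's
        error local; the anchor biases b_f absorb each feature's arbitrary
        zero point under a weighted zero-mean gauge.  From the second sweep
        on, sample weights are multiplied by a Tukey biweight of the current
        residual (scale = 1.4826·MAD, floored at 0.5°), which suppresses
        corrupted arcs of otherwise usable tracks.  The Tukey constant is set
        below the classic 4.685 because corrupted arcs are heavy, structured
        contamination rather than occasional outliers.
        """
        base = np.zeros((len(keep), n))
        series = np.zeros((len(keep), n))
        for j, f in enumerate(keep):
            finite = np.isfinite(raws[f])
            series[j, finite] = raws[f][finite]
            base[j, finite] = scores[f][finite] ** 2
        anchors = np.zeros(len(keep))
        theta = theta0.copy()
        weights = base.copy()
        for sweep in range(iters):
            den = weights.sum(axis=0)
            num = (weights * (series - anchors[:, None])).sum(axis=0)
            theta = np.where(den > 0, num / np.where(den > 0, den, 1.0), theta)
            row_w = weights.sum(axis=1)
            anchors = np.where(
                row_w > 0,
                (weights * (series - theta[None, :])).sum(axis=1)
                / np.where(row_w > 0, row_w, 1.0),
                anchors,
            )
            anchors -= (row_w * anchors).sum() / row_w.sum()
            if sweep >= 1:
                resid = series - anchors[:, None] - theta[None, :]
                scale = max(0.5, 1.4826 * float(np.median(np.abs(resid[base > 0]))))
                u = resid / (tukey_c * scale)
                weights = np.where(np.abs(u) < 1, base * (1 - u**2) ** 2, 0.0)
        return theta - theta[0], weights

    regressor = nominal.copy()
    delta = np.zeros(n)
    theta = nominal.copy()
    keep: list[int] = []
    weights = None
    raws: dict[int, np.ndarray] = {}
    for _ in range(cfg.refine_iters):
        raws, scores, orbits = build(regressor, delta)
        if not raws:
            raise FusionGap(0)
        keep = sorted(raws)
        theta, weights = angle_solve(raws, scores, keep, regressor)
        # common-mode lateral offset: median positional residual of the
        # features against their orbit models (damped update)
        resids = np.full((len(keep), n), np.nan)
        for j, f in enumerate(keep):
            orbit, pos = orbits[f]
            model = orbit.orbit_radius * np.sin(
                np.radians(regressor) + np.radians(orbit.phase0)
            )
            r_ = pos[:, 1] - orbit.axis_col - model
            r_[np.abs(r_) > 2.5] = np.nan
            resids[j] = r_
        with np.errstate(all="ignore"):
            step = np.nanmedian(resids, axis=0)
        step[~np.isfinite(step)] = 0.0
        delta = delta + 0.8 * step
        regressor = theta

    # monotone projection (rotation is one-way) and anchoring at 0
    frame_weight = weights.sum(axis=0) if weights is not None else None
    iso = isotonic_regression(theta, weights=frame_weight, increasing=True)
    fused_theta = np.asarray(iso.x) - float(iso.x[0])

    source = np.full(n, -1, dtype=int)
    if weights is not None and len(keep):
        dominant = np.argmax(weights, axis=0)
        covered = weights.sum(axis=0) > 0
        source[covered] = np.asarray(keep)[dominant[covered]]
    fused = AngleSeries(
        fused=fused_theta,
        raw={f: raws[f] for f in keep},
        source_feature=source,
    )
    return fused, tracks


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Execute the full workflow; see the module docstring for the stages."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: dict = {"seed": cfg.seed, "stages": {}}

    def fail(stage: str, exc: Exception) -> RotomoError:
        log["failed_stage"] = stage
        (out / "log.json").write_text(json.dumps(log, indent=2, default=str))
        return RotomoError(f"pipeline stage {stage!r} failed: {exc}")

    # -- acquire ------------------------------------------------------------
    truth_vol = None
    try:
        if cfg.phantom is not None:
            spec = cfg.phantom
            if spec.seed != cfg.seed:
                from dataclasses import replace

                spec = replace(spec, seed=cfg.seed)
            stack = render_rotation_video(spec, cfg.n_frames, cfg.total_angle)
            truth_vol = make_phantom(spec)
            log["stages"]["simulate"] = {
                "n_frames": cfg.n_frames, "total_angle": cfg.total_angle,
                "grid_size": spec.grid_size, "voxel_size": spec.voxel_size,
                "noise_sigma_frac": spec.noise.gaussian_sigma_frac,
            }
        else:
            stack = rio.read_stack(cfg.input_path)
            log["stages"]["load"] = {"path": cfg.input_path, "n_frames": len(stack)}
        rio.write_stack(stack, out / "stack.tif")
    except RotomoError:
        raise
    except Exception as exc:  # pragma: no cover - defensive
        raise fail("acquire", exc)

    # -- detect / crop ------------------------------------------------------
    try:
        boxes = [detect_cell(f, cfg.min_area, polarity=cfg.polarity)
                 for f in stack.frames]
        cropped = crop_stabilize(stack, boxes, cfg.crop_size, cfg.smooth_window)
        log["stages"]["detect_crop"] = {
            "crop_size": cfg.crop_size, "polarity": cfg.polarity,
            "min_area": cfg.min_area, "smooth_window": cfg.smooth_window,
        }
    except RotomoError as exc:
        raise fail("detect_crop", exc)

    # -- segment / align ----------------------------------------------------
    try:
        masks = [segment_cell(f, polarity=cfg.polarity) for f in cropped.frames]
        circles = [min_enclosing_circle(m) for m in masks]
        aligned = center_align(cropped, smooth_circles(circles, cfg.smooth_window))
        # masks/circles recomputed on aligned frames for downstream stages
        masks = [segment_cell(f, polarity=cfg.polarity) for f in aligned.frames]
        circles = [min_enclosing_circle(m) for m in masks]
        rio.write_masks(masks, out / "masks.tif")
        rio.write_circles_tsv(circles, out / "circles.tsv")
        rio.write_stack(aligned, out / "aligned.tif")
        log["stages"]["segment_align"] = {"n_masks": len(masks)}
    except RotomoError as exc:
        raise fail("segment_align", exc)

    # -- track / fuse -------------------------------------------------------
    try:
        fused, tracks = estimate_angles(aligned, masks, circles, cfg)
        rio.write_tracks_tsv(tracks, out / "tracks.tsv")
        rio.write_angles_tsv(fused, out / "angles_est.tsv")
        log["stages"]["track"] = {
            "max_features": cfg.max_features, "min_distance": cfg.min_distance,
            "harris_k": cfg.harris_k, "flow_window": cfg.flow_window,
            "flow_levels": cfg.flow_levels, "fb_threshold": cfg.fb_threshold,
            "direction": cfg.direction, "n_tracks": len(tracks),
            "n_fused": len(fused.raw),
        }
    except RotomoError as exc:
        raise fail("track", exc)

    # -- reconstruct --------------------------------------------------------
    volume = None
    if cfg.reconstruct:
        try:
            volume = reconstruct_volume(aligned, fused, cfg.recon)
            if cfg.post_smooth_sigma > 0:
                volume = spatial_filter(volume, cfg.post_smooth_sigma, mask=True)
            rio.write_volume(volume, out / "volume.tif")
            log["stages"]["reconstruct"] = {
                "filter": cfg.recon.filter,
                "interpolation": cfg.recon.interpolation,
                "angle_weighting": cfg.recon.angle_weighting,
                "circle_mask": cfg.recon.circle_mask,
                "post_smooth_sigma": cfg.post_smooth_sigma,
            }
        except RotomoError as exc:
            raise fail("reconstruct", exc)

    # -- evaluate -----------------------------------------------------------
    result = PipelineResult(
        out_dir=out, angles=fused, volume=volume,
        truth_angles=stack.truth_angles, log=log,
    )
    if cfg.evaluate and stack.truth_angles is not None:
        try:
            result.tracking = tracking_report(fused, stack.truth_angles)
            report: dict = {
                "tracking_mean_error_deg": result.tracking.mean_error,
                "tracking_max_error_deg": result.tracking.max_error,
            }
            if truth_vol is not None and volume is not None:
                limited = limited_angle_reconstruct(
                    aligned, stack.truth_angles, cfg.recon, cfg.limited_range
                )
                if cfg.post_smooth_sigma > 0:
                    limited = spatial_filter(limited, cfg.post_smooth_sigma, mask=True)
                rio.write_volume(limited, out / "volume_limited.tif")
                result.comparison = compare_methods(volume, limited, truth_vol)
                report["metrics_full"] = result.comparison.proposed.as_dict()
                report["metrics_limited"] = result.comparison.conventional.as_dict()
                report["relative_change_pct"] = result.comparison.relative_change
            (out / "report.json").write_text(json.dumps(report, indent=2))
            lines = [f"{k}\t{v}" for k, v in report.items()]
            (out / "report.txt").write_text("\n".join(lines) + "\n")
            log["stages"]["evaluate"] = {"limited_range": cfg.limited_range}
        except RotomoError as exc:
            raise fail("evaluate", exc)

    (out / "log.json").write_text(json.dumps(log, indent=2, default=str))
    return result
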