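"""Rotation-angle estimation from tracked surface features.

A point feature rigidly attached to a sphere rotating about the vertical
image axis moves laterally as ``col(t) - axis_col = r sin(phi0 + theta_t)``,
where ``r`` is the feature's orbit radius in pixels and ``theta_t`` the cell
rotation angle.  Inverting the sine recovers the angle, but the derivative
``d(col)/d(theta) = r cos(...)`` vanishes when the feature approaches the
cell silhouette: there, pixel quantization dominates and the estimated angle
stagnates (a plateau of up to tens of degrees).  The cure is to track
several features at once and, frame by frame, accumulate the angle
increment of the feature that currently has the best lateral leverage.

Steps implemented here:

1. Harris corners inside the cell mask seed the tracker.
2. A pyramidal Lucas-Kanade tracker (implemented in-package) follows each
   feature with subpixel precision and a forward-backward validity check.
3. A sinusoid least-squares fit per feature recovers its orbit radius and
   phase.
4. Arcsine conversion with monotone branch continuation yields a raw angle
   series per feature plus a geometric sensitivity ``|cos theta|``.
5. Stagnation intervals are flagged; fusion selects the best feature per
   frame and accumulates increments into one monotone series anchored at 0°.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.feature import corner_harris, corner_peaks
from skimage.transform import pyramid_gaussian

from .errors import EmptyFeatureSet, FusionGap, OrbitDegenerate, ValidationError
from .phantom import ProjectionFrame, ProjectionStack
from .preprocess import CellMask, EnclosingCircle

__all__ = [
    "FeatureTrack",
    "AngleSeries",
    "OrbitModel",
    "harris_features",
    "track_flow",
    "fit_orbit",
    "track_to_angles",
    "detect_stagnation",
    "select_concordant",
    "fuse_tracks",
    "mean_angle_error",
]


@dataclass
class FeatureTrack:
    """One feature's per-frame subpixel position with validity flags."""

    feature_id: int
    positions: np.ndarray  # (n_frames, 2) as (row, col); NaN where invalid
    valid: np.ndarray  # (n_frames,) bool
    response: float  # Harris response at initialization

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if len(self.positions) != len(self.valid):
            raise ValidationError("positions and valid flags must align")


@dataclass(frozen=True)
class OrbitModel:
    """Sinusoid model of a feature's lateral motion on the rotating sphere."""

    axis_col: float  # pixel column of the rotation axis
    orbit_radius: float  # pixels
    phase0: float  # degrees; feature phase at frame 0


@dataclass
class AngleSeries:
    """Per-frame rotation-angle estimates assigned to the projections."""

    fused: np.ndarray  # degrees, fused[0] = 0, non-decreasing
    raw: dict[int, np.ndarray] = field(default_factory=dict)
    source_feature: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.fused = np.asarray(self.fused, dtype=float)

    def __len__(self) -> int:
        return len(self.fused)


def highpass(img: np.ndarray, sigma: float = 8.0) -> np.ndarray:
    """Suppress the smooth cell-body background, keep blob/corner detail.

    Parallel projections of a cell are dominated by the dome-shaped line
    integral of the cytoplasm, which barely changes during rotation; the
    features that *do* move (bead and organelle blobs) ride on top of it as
    small bumps.  Subtracting a Gaussian-blurred copy removes the dome so
    that brightness constancy holds for the moving detail — both the Harris
    detector and the Lucas-Kanade tracker operate on this representation.
    """
    img = np.asarray(img, dtype=float)
    if sigma <= 0:
        return img
    return img - ndimage.gaussian_filter(img, sigma)


def harris_features(
    frame: ProjectionFrame,
    mask: CellMask,
    max_n: int = 10,
    min_distance: int = 5,
    k: float = 0.04,
    rel_threshold: float = 0.01,
    highpass_sigma: float = 8.0,
) -> list[tuple[float, float, float]]:
    """Strongest Harris corners inside the (eroded) cell mask.

    Returns up to ``max_n`` ``(row, col, response)`` triples sorted by
    descending response, non-maximum suppressed at ``min_distance``.  The
    mask is eroded by ``min_distance`` so silhouette-edge responses — which
    are not material points of the rotating cell — are excluded.  Corners
    are detected on the high-pass filtered frame (see :func:`highpass`).
    """
    if not mask.pixels.any():
        raise EmptyFeatureSet("empty mask")
    if np.ptp(np.asarray(frame.pixels)) == 0:
        raise EmptyFeatureSet("uniform frame has no corners")
    img = highpass(frame.pixels, highpass_sigma)
    response = corner_harris(img, k=k, sigma=1.5)
    interior = ndimage.binary_erosion(mask.pixels, iterations=max(1, min_distance))
    if not interior.any() or response[interior].max() <= 0:
        raise EmptyFeatureSet("no Harris corner above threshold inside the mask")
    response_masked = np.where(interior, response, -np.inf)
    peaks = corner_peaks(
        response_masked,
        min_distance=min_distance,
        threshold_rel=rel_threshold,
        num_peaks=max_n,
    )
    feats = [(float(r), float(c), float(response[r, c])) for r, c in peaks]
    feats.sort(key=lambda t: -t[2])
    if not feats:
        raise EmptyFeatureSet("no Harris corner above threshold inside the mask")
    return feats


# ---------------------------------------------------------------------------
# Pyramidal Lucas-Kanade tracking


def _sample_patch(img: np.ndarray, center: np.ndarray, radius: int) -> np.ndarray | None:
    """Bilinear patch of side 2r+1 around a subpixel center; None off-image."""
    r0, c0 = center
    h, w = img.shape
    if not (radius <= r0 <= h - 1 - radius and radius <= c0 <= w - 1 - radius):
        return None
    offs = np.arange(-radius, radius + 1, dtype=float)
    rows = r0 + offs
    cols = c0 + offs
    grid = np.meshgrid(rows, cols, indexing="ij")
    return ndimage.map_coordinates(img, grid, order=1, mode="nearest")


def _lk_single_level(
    img0: np.ndarray,
    img1: np.ndarray,
    p0: np.ndarray,
    guess: np.ndarray,
    radius: int,
    n_iter: int,
    eps: float,
) -> np.ndarray | None:
    """Iterative Lucas-Kanade at one pyramid level; returns displacement."""
    patch0 = _sample_patch(img0, p0, radius)
    if patch0 is None:
        return None
    gr, gc = np.gradient(patch0)
    g = np.array([[np.sum(gr * gr), np.sum(gr * gc)],
                  [np.sum(gr * gc), np.sum(gc * gc)]])
    g += 1e-6 * np.eye(2) * max(g[0, 0] + g[1, 1], 1e-12)
    v = guess.astype(float).copy()
    for _ in range(n_iter):
        patch1 = _sample_patch(img1, p0 + v, radius)
        if patch1 is None:
            return None
        diff = patch0 - patch1
        b = np.array([np.sum(diff * gr), np.sum(diff * gc)])
        try:
            dv = np.linalg.solve(g, b)
        except np.linalg.LinAlgError:
            return None
        v += dv
        if np.hypot(*dv) < eps:
            break
    return v


def _lk_pyramidal(
    pyr0: list[np.ndarray],
    pyr1: list[np.ndarray],
    p0: np.ndarray,
    radius: int,
    n_iter: int = 20,
    eps: float = 0.01,
) -> np.ndarray | None:
    """Coarse-to-fine Lucas-Kanade; returns the new position or None."""
    levels = len(pyr0)
    v = np.zeros(2)
    for lev in range(levels - 1, -1, -1):
        scale = 2.0**lev
        vl = _lk_single_level(
            pyr0[lev], pyr1[lev], p0 / scale, v / scale, radius, n_iter, eps
        )
        if vl is None:
            if lev > 0:
                continue  # window does not fit the coarse level; refine below
            return None
        v = vl * scale
    return p0 + v


def _pyramids(frames: np.ndarray, levels: int) -> list[list[np.ndarray]]:
    return [
        list(pyramid_gaussian(f, max_layer=levels - 1, downscale=2,
                              preserve_range=True, channel_axis=None))
        for f in frames
    ]


def _centroid_refine(
    img: np.ndarray,
    p: np.ndarray,
    radius: int = 4,
    n_iter: int = 3,
    guard: float = 1.5,
) -> np.ndarray:
    """Snap a position to the local blob centroid of a high-pass image.

    The tracked features are compact intensity blobs (surface beads,
    organelles); re-estimating the blob centroid each frame removes the
    drift that frame-to-frame template tracking accumulates.  The refinement
    is rejected (the input returned) when it would move more than ``guard``
    pixels — e.g. when a neighbouring structure would capture the window.
    """
    p_in = np.asarray(p, dtype=float)
    p_cur = p_in.copy()
    rr, cc = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    for _ in range(n_iter):
        r0, c0 = int(round(p_cur[0])), int(round(p_cur[1]))
        if not (
            radius <= r0 < img.shape[0] - radius
            and radius <= c0 < img.shape[1] - radius
        ):
            return p_in
        win = img[r0 - radius : r0 + radius + 1, c0 - radius : c0 + radius + 1]
        win = np.clip(win - np.median(win), 0.0, None)
        total = win.sum()
        if total <= 0:
            return p_in
        p_new = np.array(
            [r0 + np.sum(rr * win) / total, c0 + np.sum(cc * win) / total]
        )
        if np.hypot(*(p_new - p_in)) > guard:
            return p_in
        p_cur = p_new
    return p_cur


def track_flow(
    stack: ProjectionStack,
    seeds: list[tuple[float, float, float]],
    masks: list[CellMask] | None = None,
    window: int = 21,
    levels: int = 3,
    fb_threshold: float = 1.0,
    highpass_sigma: float = 8.0,
    blob_refine_radius: int = 4,
) -> list[FeatureTrack]:
    """Track seed features through the stack by pyramidal Lucas-Kanade flow.

    ``seeds`` are ``(row, col, response)`` triples from frame 0.  Flow is
    computed on high-pass filtered frames (see :func:`highpass`) so the
    nearly static cell-body dome does not anchor the tracker, and each
    Lucas-Kanade prediction is refined to the local blob centroid
    (``blob_refine_radius``; 0 disables), which removes template drift.  A
    feature is invalidated from the first frame where the forward-backward
    check error exceeds ``fb_threshold`` pixels, the patch leaves the frame,
    or (when ``masks`` are given) the feature leaves the cell mask.  Once
    invalid, a feature stays invalid (no re-detection).
    """
    frames = stack.as_array().astype(float)
    if highpass_sigma > 0:
        frames = np.stack([highpass(f, highpass_sigma) for f in frames])
    n = len(frames)
    radius = window // 2
    pyrs = _pyramids(frames, levels)

    def refine(i: int, p: np.ndarray) -> np.ndarray:
        if blob_refine_radius <= 0:
            return p
        return _centroid_refine(frames[i], p, radius=blob_refine_radius)

    tracks = []
    for fid, (row, col, resp) in enumerate(seeds):
        positions = np.full((n, 2), np.nan)
        valid = np.zeros(n, dtype=bool)
        p = refine(0, np.array([row, col], dtype=float))
        positions[0] = p
        valid[0] = True
        for i in range(n - 1):
            if not valid[i]:
                break
            p1 = _lk_pyramidal(pyrs[i], pyrs[i + 1], p, radius)
            if p1 is None:
                break
            p_back = _lk_pyramidal(pyrs[i + 1], pyrs[i], p1, radius)
            if p_back is None or np.hypot(*(p_back - p)) > fb_threshold:
                break
            p1 = refine(i + 1, p1)
            if masks is not None:
                r_i, c_i = int(round(p1[0])), int(round(p1[1]))
                m = masks[i + 1].pixels
                if not (0 <= r_i < m.shape[0] and 0 <= c_i < m.shape[1]) or not m[r_i, c_i]:
                    break
            positions[i + 1] = p1
            valid[i + 1] = True
            p = p1
        tracks.append(FeatureTrack(feature_id=fid, positions=positions,
                                   valid=valid, response=resp))
    return tracks


# ---------------------------------------------------------------------------
# Orbit geometry


def fit_orbit(
    track: FeatureTrack,
    circle: EnclosingCircle,
    nominal_angles: np.ndarray | None = None,
    axis_col: float | None = None,
    inlier_tol: float = 1.5,
) -> OrbitModel:
    """Robust least-squares sinusoid fit of a track's lateral motion.

    Fits ``col(t) = axis_col + c + A sin(theta_t) + B cos(theta_t)`` over the
    valid frames, with ``theta_t`` the nominal uniform angle grid (the device
    drives rotation at constant speed; the grid is a regressor, not the
    estimate).  ``orbit_radius = hypot(A, B)``, ``phase0 = atan2(B, A)``; the
    intercept ``c`` absorbs sub-pixel residual centering error.

    A track can be clean on one arc and corrupted on another (typically after
    the feature crosses the cell silhouette), so candidate fits are computed
    on sliding sub-windows as well as the full track, scored by their inlier
    count at ``inlier_tol`` pixels over all valid frames, and the winner is
    refit on its inliers.  Falls back to the peak lateral excursion when the
    fit is ill-conditioned, and clamps the radius to the enclosing-circle
    radius + 1 px.
    """
    valid = track.valid
    if valid.sum() < 5:
        raise OrbitDegenerate("need at least 5 valid positions")
    n = len(valid)
    if nominal_angles is None:
        nominal_angles = np.arange(n) * (180.0 / n)
    if axis_col is None:
        axis_col = circle.center_col

    cols = track.positions[valid, 1]
    if np.ptp(cols) < 1e-9 or np.std(cols) < 1e-6:
        raise OrbitDegenerate("track has no lateral variance")

    th = np.radians(np.asarray(nominal_angles, dtype=float)[valid])
    design = np.column_stack([np.sin(th), np.cos(th), np.ones_like(th)])
    u = cols - axis_col
    m = len(u)

    def lstsq(rows: np.ndarray):
        sol, _, rank, sv = np.linalg.lstsq(design[rows], u[rows], rcond=None)
        ill = rank < 3 or (sv[0] > 0 and sv[-1] / sv[0] < 1e-8)
        return sol, ill

    # candidate windows: full track plus overlapping thirds and halves
    windows = [np.arange(m)]
    for frac in (3, 2):
        size = m // frac
        if size >= 10:
            step = max(1, size // 2)
            for start in range(0, m - size + 1, step):
                windows.append(np.arange(start, start + size))
    best_sol, best_inliers, best_ill = None, None, True
    for rows in windows:
        sol, ill = lstsq(rows)
        if ill:
            continue
        inliers = np.abs(u - design @ sol) <= inlier_tol
        if best_inliers is None or inliers.sum() > best_inliers.sum():
            best_sol, best_inliers, best_ill = sol, inliers, False
    if not best_ill:
        for _ in range(2):  # refit on the consensus inlier set
            if best_inliers.sum() < 5:
                break
            sol, ill = lstsq(np.flatnonzero(best_inliers))
            if ill:
                break
            best_sol = sol
            best_inliers = np.abs(u - design @ sol) <= inlier_tol

    if best_ill:
        radius = float(np.max(np.abs(u)))
        phase0 = float(np.degrees(np.arcsin(np.clip(u[0] / max(radius, 1e-9), -1, 1))))
        intercept = 0.0
    else:
        a_sin, b_cos, intercept = best_sol
        radius = float(np.hypot(a_sin, b_cos))
        phase0 = float(np.degrees(np.arctan2(b_cos, a_sin)))
    if radius < 1e-9:
        raise OrbitDegenerate("fitted orbit radius is zero")
    radius = min(radius, circle.radius + 1.0)
    return OrbitModel(axis_col=float(axis_col + intercept), orbit_radius=radius,
                      phase0=phase0)


def track_to_angles(
    track: FeatureTrack,
    orbit: OrbitModel,
    direction: int = 1,
    backtrack_tol: float = 2.0,
    max_step: float = 10.0,
    nominal_angles: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Arcsine conversion of lateral displacement to rotation angle.

    Per frame ``psi = arcsin(clamp(u / r))`` with ``u = col - axis_col``.
    The arcsine is two-branched (``psi`` vs ``180° - psi``, modulo 360°); the
    feature phase ``alpha`` is disambiguated in one of two ways:

    * ``nominal_angles`` given (a rotator driven at a known rate): the branch
      candidate nearest the nominal phase ``phase0 + nominal_angles[i]`` is
      chosen independently per frame, so a tracking glitch at one frame never
      corrupts the rest of the series;
    * otherwise: sequential continuation — the phase moves monotonically in
      the known rotation ``direction``, allowing ``backtrack_tol`` degrees of
      regression and ``max_step`` degrees of advance per frame (the phase
      holds when no branch candidate lies in that band).

    Returns ``(angles, sensitivities)``: ``angles[i] = alpha_i - alpha_0`` in
    degrees on the direction-adjusted phase (NaN where the track is invalid)
    and the geometric sensitivity ``sqrt(1 - (u/r)^2) = |cos alpha|``, which
    vanishes where a lateral pixel step corresponds to a large orientation
    change (the feature is crossing the cell silhouette).
    """
    if direction not in (1, -1):
        raise ValidationError("direction must be +1 or -1")
    n = len(track.valid)
    angles = np.full(n, np.nan)
    sens = np.full(n, np.nan)
    r = orbit.orbit_radius

    # flipping the lateral coordinate (direction -1) reflects the fitted
    # phase to phase0 + 180°
    phase_ref = orbit.phase0 if direction == 1 else orbit.phase0 + 180.0
    u_all = (track.positions[:, 1] - orbit.axis_col) * direction

    def nearest_branch(psi: float, target: float) -> float:
        best = None
        for base in (psi, 180.0 - psi):
            k = round((target - base) / 360.0)
            for cand in (base + 360.0 * k, base + 360.0 * (k + 1), base + 360.0 * (k - 1)):
                if best is None or abs(cand - target) < abs(best - target):
                    best = cand
        return best

    if nominal_angles is not None:
        nominal = np.asarray(nominal_angles, dtype=float)
        if len(nominal) != n:
            raise ValidationError("one nominal angle per frame is required")
        alpha0 = None
        for i in range(n):
            if not track.valid[i]:
                if alpha0 is not None:
                    break  # contiguous-prefix contract
                continue
            x = np.clip(u_all[i] / r, -1.0, 1.0)
            psi = float(np.degrees(np.arcsin(x)))
            sens[i] = float(np.sqrt(max(0.0, 1.0 - x * x)))
            alpha = nearest_branch(psi, phase_ref + nominal[i])
            if alpha0 is None:
                alpha0 = alpha
            angles[i] = alpha - alpha0
        return angles, sens

    alpha_prev = None
    alpha0 = None
    inc_prev = 0.0  # momentum: last accepted phase increment
    for i in range(n):
        if not track.valid[i]:
            if alpha_prev is not None:
                break  # contiguous-prefix contract: stop at first dropout
            continue
        x = np.clip(u_all[i] / r, -1.0, 1.0)
        psi = float(np.degrees(np.arcsin(x)))
        sens[i] = float(np.sqrt(max(0.0, 1.0 - x * x)))
        if alpha_prev is None:
            # disambiguate the starting hemisphere with the fitted phase
            cand = min(
                (psi, 180.0 - psi),
                key=lambda cnd: abs((cnd - phase_ref + 180) % 360 - 180),
            )
            alpha0 = alpha_prev = cand
            angles[i] = 0.0
            continue
        expected = alpha_prev + inc_prev
        best = None
        for base in (psi, 180.0 - psi):
            k = round((expected - base) / 360.0)
            for cand in (base + 360.0 * (k - 1), base + 360.0 * k, base + 360.0 * (k + 1)):
                if not (alpha_prev - backtrack_tol <= cand <= alpha_prev + max_step):
                    continue
                if best is None or abs(cand - expected) < abs(best - expected):
                    best = cand
        if best is None:  # no candidate in the admissible band: hold the phase
            best = alpha_prev
        angles[i] = best - alpha0
        inc_prev = float(np.clip(best - alpha_prev, 0.0, max_step))
        alpha_prev = best
    return angles, sens


def detect_stagnation(
    raw: np.ndarray, window: int = 5, tol: float = 1.0
) -> list[tuple[int, int]]:
    """Maximal frame intervals where the angle stalls.

    A frame belongs to a stagnation interval when some sliding window of
    ``window`` frames containing it changes by less than ``tol`` degrees in
    total.  Returns inclusive ``(start, end)`` intervals.
    """
    if window < 2:
        raise ValidationError("window must be at least 2")
    raw = np.asarray(raw, dtype=float)
    n = len(raw)
    flagged = np.zeros(n, dtype=bool)
    for i in range(n - window + 1):
        seg = raw[i : i + window]
        if np.any(np.isnan(seg)):
            continue
        if abs(seg[-1] - seg[0]) < tol:
            flagged[i : i + window] = True
    intervals = []
    i = 0
    while i < n:
        if flagged[i]:
            j = i
            while j + 1 < n and flagged[j + 1]:
                j += 1
            intervals.append((i, j))
            i = j + 1
        else:
            i += 1
    return intervals


def select_concordant(
    raws: dict[int, np.ndarray],
    scores: dict[int, np.ndarray],
    tol: float = 2.0,
    min_overlap: int = 20,
) -> list[int]:
    """Select the mutually consistent subset of per-feature angle series.

    All features observe the same rotation, so trustworthy series agree with
    each other up to a constant anchor offset, while a feature whose tracker
    silently slipped agrees with nothing.  The pairwise deviation is the
    score-weighted mean absolute difference after removing the weighted mean
    offset (anchor-invariant); the selection grows greedily from the tightest
    pair, adding features whose mean deviation to the current set is ≤
    ``tol`` degrees.  Returns feature ids; falls back to the single
    highest-scored feature when no pair agrees.
    """
    ids = sorted(raws)
    if len(ids) <= 1:
        return ids

    dev: dict[tuple[int, int], float] = {}
    for i, f in enumerate(ids):
        for g in ids[i + 1 :]:
            both = np.isfinite(raws[f]) & np.isfinite(raws[g])
            w = (scores[f] * scores[g])[both]
            if both.sum() < min_overlap or w.sum() <= 0:
                dev[(f, g)] = np.inf
                continue
            d = (raws[f] - raws[g])[both]
            offset = float(np.sum(w * d) / np.sum(w))
            dev[(f, g)] = float(np.sum(w * np.abs(d - offset)) / np.sum(w))

    def get(f: int, g: int) -> float:
        return dev[(f, g)] if (f, g) in dev else dev[(g, f)]

    finite_pairs = sorted((v, k) for k, v in dev.items() if np.isfinite(v))
    if not finite_pairs or finite_pairs[0][0] > tol:
        # nothing agrees: keep the feature with the largest total score
        return [max(ids, key=lambda f: float(np.sum(scores[f] ** 2)))]
    selected = list(finite_pairs[0][1])
    for f in ids:
        if f in selected:
            continue
        ds = [get(f, g) for g in selected]
        if np.mean(ds) <= tol:
            selected.append(f)
    return sorted(selected)


def fuse_tracks(
    raws: dict[int, np.ndarray],
    sensitivities: dict[int, np.ndarray],
    responses: dict[int, float] | None = None,
    max_step: float = 10.0,
) -> AngleSeries:
    """Fuse per-feature angle series into one monotone rotation estimate.

    Per frame, the angle *increments* of all features valid across the
    ``i-1 -> i`` step are combined with weights proportional to the square of
    their sensitivity score (quantization error of the arcsine conversion is
    inversely proportional to the score, so squared-score weighting is the
    inverse-variance combination); the weighted increment is accumulated,
    which keeps the series continuous when features drop in and out.  With a
    single feature this reduces to that feature's own series.  Negative
    increments are clipped to 0 (physical rotation is one-way) and increments
    are capped at ``max_step`` degrees.  ``fused[0] = 0`` by definition.
    ``source_feature`` records the dominant (highest-weight) feature per
    frame, ties broken by Harris response.
    """
    if not raws:
        raise FusionGap(0)
    ids = sorted(raws)
    n = len(raws[ids[0]])
    for fid in ids:
        if len(raws[fid]) != n or len(sensitivities[fid]) != n:
            raise ValidationError("all series must share the frame count")
    responses = responses or {fid: 0.0 for fid in ids}

    fused = np.zeros(n)
    source = np.full(n, -1, dtype=int)
    usable0 = [fid for fid in ids if np.isfinite(raws[fid][0])]
    if not usable0:
        raise FusionGap(0)
    source[0] = max(usable0, key=lambda f: (sensitivities[f][0], responses[f]))
    for i in range(1, n):
        weights, incs, cands = [], [], []
        for fid in ids:
            if np.isfinite(raws[fid][i]) and np.isfinite(raws[fid][i - 1]):
                s = 0.5 * (sensitivities[fid][i] + sensitivities[fid][i - 1])
                weights.append(s * s)
                incs.append(raws[fid][i] - raws[fid][i - 1])
                cands.append(fid)
        if not cands:
            raise FusionGap(i)
        weights = np.asarray(weights)
        total = weights.sum()
        if total > 0:
            inc = float(np.dot(weights, incs) / total)
            source[i] = max(
                zip(cands, weights), key=lambda t: (t[1], responses[t[0]])
            )[0]
        else:  # all features at a sensitivity minimum: plain average
            inc = float(np.mean(incs))
            source[i] = max(cands, key=lambda f: responses[f])
        fused[i] = fused[i - 1] + float(np.clip(inc, 0.0, max_step))
    return AngleSeries(fused=fused, raw=dict(raws), source_feature=source)


def mean_angle_error(fused: AngleSeries | np.ndarray, truth: np.ndarray) -> float:
    """Mean absolute per-frame difference, in degrees."""
    est = fused.fused if isinstance(fused, AngleSeries) else np.asarray(fused, float)
    truth = np.asarray(truth, dtype=float)
    if len(est) != len(truth):
        raise ValidationError("angle series lengths differ")
    return float(np.mean(np.abs(est - truth)))
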