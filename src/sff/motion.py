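"""Rigid ROI tracking across cine frames by exhaustive NCC search.

Tissue motion between successive frames of a B-mode cine loop is modelled as
a rigid translation plus rotation of the region of interest.  For each
successive frame pair the tracker samples the candidate (dx, dy, theta) grid
exhaustively, scores each candidate by normalized cross-correlation against
the previous frame's ROI pixels, and composes the per-pair winners into
cumulative transforms relative to frame 0.  When the primary (tumor) ROI is
too featureless to correlate reliably, a feature-rich alternative ROI is
tracked instead and its transforms applied to the tumor ROI.

Transform convention: a :class:`RigidTransform` maps frame-0 coordinates to
frame-t coordinates, rotating by ``theta`` degrees about a fixed center
(the frame-0 ROI centroid unless stated otherwise) and then translating by
``(dy, dx)`` in (row, col) pixels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import (
    DegenerateInputError,
    DegenerateWindowError,
    DimensionError,
    TrackingInfeasibleError,
)

DEFAULT_FEATURE_VAR_THRESHOLD = 1e-4


@dataclass(frozen=True)
class RigidTransform:
    """Rigid motion: rotation by ``theta`` (degrees) about a center, then a
    translation of ``dx`` columns and ``dy`` rows."""

    dx: float = 0.0
    dy: float = 0.0
    theta: float = 0.0

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(0.0, 0.0, 0.0)

    def apply(
        self, rows: np.ndarray, cols: np.ndarray, center: tuple[float, float]
    ) -> tuple[np.ndarray, np.ndarray]:
        """Map frame-0 (row, col) coordinates to their frame-t positions."""
        t = np.deg2rad(self.theta)
        c, s = np.cos(t), np.sin(t)
        r0 = np.asarray(rows, dtype=float) - center[0]
        c0 = np.asarray(cols, dtype=float) - center[1]
        return (
            c * r0 - s * c0 + center[0] + self.dy,
            s * r0 + c * c0 + center[1] + self.dx,
        )

    def inverse(self) -> "RigidTransform":
        """Transform undoing this one (about the same center)."""
        t = np.deg2rad(self.theta)
        c, s = np.cos(t), np.sin(t)
        # invert (dy, dx) through the reverse rotation
        dy = -(c * self.dy + s * self.dx)
        dx = -(-s * self.dy + c * self.dx)
        return RigidTransform(dx=dx, dy=dy, theta=-self.theta)


@dataclass(frozen=True)
class SearchBounds:
    """Exhaustive-search grid: translations in 1 px steps within +-8 px and
    rotations in 0.5 degree steps within +-5 degrees by default."""

    max_shift: int = 8
    shift_step: float = 1.0
    max_rot: float = 5.0
    rot_step: float = 0.5
    ncc_floor: float = 0.2

    def shift_grid(self) -> np.ndarray:
        n = int(round(self.max_shift / self.shift_step))
        return np.arange(-n, n + 1) * self.shift_step

    def rot_grid(self) -> np.ndarray:
        if self.max_rot <= 0:
            return np.zeros(1)
        n = int(round(self.max_rot / self.rot_step))
        return np.arange(-n, n + 1) * self.rot_step


@dataclass
class TrackedSeries:
    """Cumulative per-frame transforms and their pairwise NCC scores."""

    transforms: list[RigidTransform]
    ncc_scores: np.ndarray
    center: tuple[float, float]
    roi_used: str = "primary"
    failed: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))


def ncc(window_a: np.ndarray, window_b: np.ndarray) -> float:
    """Zero-mean, unit-variance normalized cross-correlation in [-1, 1]."""
    a = np.asarray(window_a, dtype=float).ravel()
    b = np.asarray(window_b, dtype=float).ravel()
    if a.shape != b.shape:
        raise DimensionError(f"window shapes differ: {a.size} vs {b.size}")
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na < 1e-12 or nb < 1e-12:
        raise DegenerateWindowError("window has (near-)zero intensity variance")
    return float(np.clip(a @ b / (na * nb), -1.0, 1.0))


def _sample(frame: np.ndarray, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    return ndimage.map_coordinates(
        frame, [rows, cols], order=1, mode="reflect", prefilter=False
    )


def _ncc_search_integer_shifts(
    frame: np.ndarray,
    base_r: np.ndarray,
    base_c: np.ndarray,
    t0: np.ndarray,
    tnorm: float,
    max_shift: int,
) -> tuple[float, float, float]:
    """Best NCC over all integer (dy, dx) shifts of non-integer base coords.

    Bilinear sampling at ``base + (dy, dx)`` reuses one gathered
    ``(npix, 2m+2, 2m+2)`` neighborhood: the four bilinear corner products
    are shifted views of it, so every candidate shift is scored without
    resampling.  Equivalent to, and much faster than, per-shift
    ``map_coordinates``.
    """
    fr = np.floor(base_r).astype(int)
    fc = np.floor(base_c).astype(int)
    ar = (base_r - fr)[:, None, None]
    ac = (base_c - fc)[:, None, None]
    off = np.arange(-max_shift, max_shift + 2)
    rows = np.clip(fr[:, None, None] + off[None, :, None], 0, frame.shape[0] - 1)
    cols = np.clip(fc[:, None, None] + off[None, None, :], 0, frame.shape[1] - 1)
    patches = frame[rows, cols]  # (npix, 2m+2, 2m+2)
    smp = (
        (1 - ar) * (1 - ac) * patches[:, :-1, :-1]
        + (1 - ar) * ac * patches[:, :-1, 1:]
        + ar * (1 - ac) * patches[:, 1:, :-1]
        + ar * ac * patches[:, 1:, 1:]
    )  # (npix, 2m+1, 2m+1): candidate (dy, dx) = (off[iy], off[ix])
    n = smp.shape[0]
    sum_s = smp.sum(axis=0)
    sum_s2 = np.einsum("pyx,pyx->yx", smp, smp)
    dot = np.einsum("p,pyx->yx", t0, smp)
    var = np.maximum(sum_s2 - sum_s**2 / n, 0.0)
    denom = np.sqrt(var) * tnorm
    with np.errstate(invalid="ignore", divide="ignore"):
        score = np.where(denom > 1e-12, dot / denom, -np.inf)
    iy, ix = np.unravel_index(int(np.argmax(score)), score.shape)
    return float(score[iy, ix]), float(off[iy]), float(off[ix])


def roi_feature_score(frame: np.ndarray, roi: np.ndarray) -> float:
    """Intensity variance within the ROI on one frame (texture richness)."""
    mask = np.asarray(roi, dtype=bool)
    if not mask.any():
        raise DegenerateInputError("ROI is empty")
    return float(np.var(np.asarray(frame, dtype=float)[mask]))


def select_tracking_roi(
    frames: np.ndarray,
    primary: np.ndarray,
    alternatives: tuple[np.ndarray, ...] = (),
    var_threshold: float = DEFAULT_FEATURE_VAR_THRESHOLD,
    labels: tuple[str, ...] | None = None,
) -> tuple[np.ndarray, str]:
    """Pick the ROI to track: the primary if feature-rich enough, else the
    highest-scoring alternative; error if nothing offers usable texture."""
    frames = np.asarray(frames, dtype=float)
    frame0 = frames[0]
    if labels is None:
        labels = ("primary",) + tuple(f"alt_{i}" for i in range(len(alternatives)))
    primary_score = roi_feature_score(frame0, primary)
    if primary_score >= var_threshold:
        return np.asarray(primary, dtype=bool), labels[0]
    scored = [
        (roi_feature_score(frame0, alt), i) for i, alt in enumerate(alternatives)
    ]
    scored = [(s, i) for s, i in scored if s >= var_threshold]
    if not scored:
        raise TrackingInfeasibleError(
            "no ROI has enough intensity variance to track "
            f"(threshold {var_threshold:g})"
        )
    best_score, best_i = max(scored)
    return np.asarray(alternatives[best_i], dtype=bool), labels[best_i + 1]


def track_roi(
    frames: np.ndarray,
    roi: np.ndarray,
    bounds: SearchBounds | None = None,
    roi_label: str = "primary",
) -> TrackedSeries:
    """Track an ROI through a cine sequence by exhaustive NCC maximization.

    For each successive frame pair, every (theta, dy, dx) candidate on the
    search grid is scored by the NCC between the previous frame's tracked ROI
    pixels and the candidate-transformed pixels of the next frame (bilinear
    sampling); the winners compose cumulatively relative to frame 0.  A pair
    whose best NCC falls below ``bounds.ncc_floor`` is flagged as a tracking
    failure but the best transform is still applied.
    """
    bounds = bounds or SearchBounds()
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3 or frames.shape[0] < 2:
        raise DegenerateInputError("need a (n_frames, M, N) stack with >= 2 frames")
    mask = np.asarray(roi, dtype=bool)
    if mask.shape != frames.shape[1:]:
        raise DimensionError("ROI shape does not match frame shape")
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise DegenerateInputError("ROI is empty")
    margin = bounds.max_shift
    if (
        rows.min() < margin
        or cols.min() < margin
        or rows.max() >= frames.shape[1] - margin
        or cols.max() >= frames.shape[2] - margin
    ):
        raise DegenerateInputError(
            f"ROI must keep a margin >= max_shift ({margin} px) from the frame edge"
        )
    center = (float(rows.mean()), float(cols.mean()))
    rows = rows.astype(float)
    cols = cols.astype(float)

    shift_1d = bounds.shift_grid()
    dys, dxs = np.meshgrid(shift_1d, shift_1d, indexing="ij")
    shifts = np.column_stack([dys.ravel(), dxs.ravel()])  # (K, 2) as (dy, dx)
    thetas = bounds.rot_grid()

    n = frames.shape[0]
    transforms = [RigidTransform.identity()]
    scores = [1.0]
    failed = [False]
    cur = RigidTransform.identity()

    for k in range(1, n):
        prev_rows, prev_cols = cur.apply(rows, cols, center)
        template = _sample(frames[k - 1], prev_rows, prev_cols)
        t0 = template - template.mean()
        tnorm = np.linalg.norm(t0)
        if tnorm < 1e-12:
            # featureless template: keep the previous transform, flag the frame
            transforms.append(cur)
            scores.append(0.0)
            failed.append(True)
            continue
        # rotation preserves the centroid, so the current ROI centroid is just
        # the original center plus the accumulated translation
        ck = (center[0] + cur.dy, center[1] + cur.dx)
        integer_grid = float(bounds.shift_step) == 1.0
        best_score = -np.inf
        best = (0.0, 0.0, 0.0)  # (theta, dy, dx)
        for theta in thetas:
            t = np.deg2rad(theta)
            c, s = np.cos(t), np.sin(t)
            r0 = prev_rows - ck[0]
            c0 = prev_cols - ck[1]
            base_r = c * r0 - s * c0 + ck[0]
            base_c = s * r0 + c * c0 + ck[1]
            if integer_grid:
                sc, dy, dx = _ncc_search_integer_shifts(
                    frames[k], base_r, base_c, t0, tnorm, bounds.max_shift
                )
                if sc > best_score:
                    best_score = sc
                    best = (float(theta), dy, dx)
                continue
            cand_r = base_r[None, :] + shifts[:, 0:1]
            cand_c = base_c[None, :] + shifts[:, 1:2]
            vals = _sample(frames[k], cand_r.ravel(), cand_c.ravel()).reshape(
                shifts.shape[0], -1
            )
            vm = vals - vals.mean(axis=1, keepdims=True)
            denom = np.linalg.norm(vm, axis=1) * tnorm
            with np.errstate(invalid="ignore", divide="ignore"):
                score = np.where(denom > 1e-12, vm @ t0 / denom, -np.inf)
            idx = int(np.argmax(score))
            if score[idx] > best_score:
                best_score = float(score[idx])
                best = (float(theta), float(shifts[idx, 0]), float(shifts[idx, 1]))
        dtheta, ddy, ddx = best
        cur = RigidTransform(dx=cur.dx + ddx, dy=cur.dy + ddy, theta=cur.theta + dtheta)
        transforms.append(cur)
        scores.append(best_score)
        failed.append(best_score < bounds.ncc_floor)

    return TrackedSeries(
        transforms=transforms,
        ncc_scores=np.asarray(scores),
        center=center,
        roi_used=roi_label,
        failed=np.asarray(failed),
    )


def warp_to_reference(
    frame: np.ndarray, transform: RigidTransform, center: tuple[float, float]
) -> np.ndarray:
    """Resample a frame into frame-0 coordinates given its tracked transform."""
    frame = np.asarray(frame, dtype=float)
    gr, gc = np.mgrid[0 : frame.shape[0], 0 : frame.shape[1]]
    sr, sc = transform.apply(gr.ravel(), gc.ravel(), center)
    return _sample(frame, sr, sc).reshape(frame.shape)


@dataclass
class IntensitySeries:
    """Median ROI intensity over time, min-max normalized, with summary stats."""

    median: np.ndarray
    normalized: np.ndarray
    peak_intensity: float
    rise_index: int
    times: np.ndarray | None = None

    @property
    def rise_time_s(self) -> float | None:
        if self.times is None:
            return None
        return float(self.times[self.rise_index])


def roi_intensity_series(
    frames: np.ndarray,
    tracked: TrackedSeries,
    roi: np.ndarray,
    times: np.ndarray | None = None,
) -> IntensitySeries:
    """Median intensity over the motion-corrected ROI, per frame.

    The median is robust to a minority of outlier pixels; the series is
    min-max normalized to [0, 1] (all zeros, with a warning, if constant).
    The rise index is the first frame reaching 90% of the peak.
    """
    frames = np.asarray(frames, dtype=float)
    mask = np.asarray(roi, dtype=bool)
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise DegenerateInputError("ROI is empty")
    if len(tracked.transforms) != frames.shape[0]:
        raise DimensionError("tracked series length does not match frame count")
    med = np.empty(frames.shape[0])
    for k, tf in enumerate(tracked.transforms):
        r, c = tf.apply(rows.astype(float), cols.astype(float), tracked.center)
        med[k] = np.median(_sample(frames[k], r, c))
    span = med.max() - med.min()
    if span < 1e-12:
        warnings.warn(
            "ROI intensity series is constant; normalized series set to zeros",
            RuntimeWarning,
            stacklevel=2,
        )
        norm = np.zeros_like(med)
        rise = 0
    else:
        norm = (med - med.min()) / span
        rise = int(np.argmax(norm >= 0.9))
    return IntensitySeries(
        median=med,
        normalized=norm,
        peak_intensity=float(med.max()),
        rise_index=rise,
        times=None if times is None else np.asarray(times, dtype=float),
    )
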