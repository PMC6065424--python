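"""Per-pixel spectral Fiedler field (SFF) maps and contrast quantification.

The transform slides an odd ``window x window`` neighborhood over every pixel
of a [0, 1]-normalized grayscale frame (reflect-padded at the borders), builds
the column-similarity graph of each neighborhood and records its Fiedler
value.  The raw contrast matrix ``C`` is then Gaussian low-pass filtered into
the SFF map ``F``; contrast change against a pre-injection baseline frame is
the variation map ``V_t = F_t - F_0``, and a region-of-interest is quantified
as the mean map value over its pixels.

The per-pixel graph construction is algebraically identical to
:func:`sff.spectral.build_graph` applied to each neighborhood; here the
pairwise column distances of all neighborhoods are accumulated with shifted
difference images and running vertical sums, and the eigenproblems are solved
in one batched call, which keeps whole-frame transforms fast.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import ConfigurationError, ConsistencyError, DegenerateInputError
from .spectral import DEFAULT_ZERO_TOL, KernelParams, fiedler_values_batched

DEFAULT_WINDOW = 9
DEFAULT_FILTER_SIGMA = 2.0
#: guard for relative increments against a (near-)zero reference value
PERCENT_EPS = 1e-9


@dataclass
class SFFMap:
    """Raw contrast matrix ``C`` and its low-pass-filtered SFF map ``F``."""

    contrast: np.ndarray
    filtered: np.ndarray
    window: int
    params: KernelParams
    filter_sigma: float
    frame_index: int = 0
    time_s: float = 0.0

    @property
    def shape(self) -> tuple[int, int]:
        return self.contrast.shape


@dataclass
class VariationMap:
    """Contrast change ``V_t = F_t - F_0`` between two SFF maps."""

    values: np.ndarray
    baseline_index: int
    current_index: int

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def _validate_image(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise DegenerateInputError(f"image must be 2-D, got ndim={img.ndim}")
    if not np.all(np.isfinite(img)):
        raise ValueError("image contains non-finite values")
    if img.min() < -1e-9 or img.max() > 1.0 + 1e-9:
        raise ValueError("image must be normalized to [0, 1]")
    return img


def column_distance_tensor(image: np.ndarray, window: int) -> np.ndarray:
    """Squared distances between the columns of every window, shape (M, N, w, w).

    ``out[i, j, a, b]`` is the squared Euclidean distance between columns
    ``a`` and ``b`` of the reflect-padded ``window x window`` neighborhood
    centered at pixel ``(i, j)``.
    """
    m, n = image.shape
    w = window
    half = w // 2
    padded = np.pad(image, half, mode="reflect")
    out = np.zeros((m, n, w, w))
    for d in range(1, w):
        q = (padded[:, :-d] - padded[:, d:]) ** 2
        cs = np.cumsum(q, axis=0)
        cs = np.vstack([np.zeros((1, q.shape[1])), cs])
        vert = cs[w:] - cs[:-w]  # vertical window sums, shape (m, n + w - 1 - d)
        for a in range(w - d):
            block = vert[:, a : a + n]
            out[:, :, a, a + d] = block
            out[:, :, a + d, a] = block
    return out


def sff_map(
    image: np.ndarray,
    window: int = DEFAULT_WINDOW,
    params: KernelParams | None = None,
    filter_sigma: float = DEFAULT_FILTER_SIGMA,
    zero_tol: float = DEFAULT_ZERO_TOL,
    frame_index: int = 0,
    time_s: float = 0.0,
) -> SFFMap:
    """Transform one frame into its per-pixel Fiedler-value contrast map.

    Four steps per pixel: extract the centered neighborhood, build its column
    graph, record the Fiedler value as ``c_ij``, then Gaussian-filter the full
    matrix ``C`` (scale ``filter_sigma``, kernel truncated at 4 sigma) into
    the SFF map ``F``.
    """
    params = params or KernelParams()
    img = _validate_image(image)
    if window < 3 or window % 2 == 0:
        raise ConfigurationError(f"window must be an odd integer >= 3, got {window}")
    if window > min(img.shape):
        raise ConfigurationError(
            f"window {window} exceeds image dimensions {img.shape}"
        )
    if not (np.isfinite(filter_sigma) and filter_sigma > 0):
        raise ConfigurationError(f"filter_sigma must be positive, got {filter_sigma}")
    m, n = img.shape
    d2 = column_distance_tensor(img, window)
    omega = np.exp(-d2 / (2.0 * params.sigma**2))
    adj = omega <= params.r
    diag = np.arange(window)
    adj[:, :, diag, diag] = False
    contrast = fiedler_values_batched(
        adj.reshape(m * n, window, window), zero_tol=zero_tol
    ).reshape(m, n)
    filtered = ndimage.gaussian_filter(contrast, sigma=filter_sigma, truncate=4.0)
    return SFFMap(
        contrast=contrast,
        filtered=filtered,
        window=window,
        params=params,
        filter_sigma=filter_sigma,
        frame_index=frame_index,
        time_s=time_s,
    )


def variation_map(current: SFFMap, baseline: SFFMap) -> VariationMap:
    """Contrast-change contour map of ``current`` against the baseline frame."""
    if current.shape != baseline.shape:
        raise ConsistencyError(
            f"map shapes differ: {current.shape} vs {baseline.shape}"
        )
    if current.window != baseline.window or current.params != baseline.params:
        raise ConsistencyError("maps were computed with different window/kernel params")
    if current.filter_sigma != baseline.filter_sigma:
        raise ConsistencyError("maps were filtered at different scales")
    return VariationMap(
        values=current.filtered - baseline.filtered,
        baseline_index=baseline.frame_index,
        current_index=current.frame_index,
    )


def roi_contrast(contrast_map: SFFMap | VariationMap | np.ndarray, roi: np.ndarray) -> float:
    """Mean map value over the ROI (sum of values divided by ROI area).

    For an :class:`SFFMap` the filtered map ``F`` is quantified; for a
    :class:`VariationMap` the difference values; a bare array is used as-is.
    """
    if isinstance(contrast_map, SFFMap):
        values = contrast_map.filtered
    elif isinstance(contrast_map, VariationMap):
        values = contrast_map.values
    else:
        values = np.asarray(contrast_map, dtype=float)
    mask = np.asarray(roi, dtype=bool)
    if mask.shape != values.shape:
        raise ConsistencyError(f"ROI shape {mask.shape} != map shape {values.shape}")
    if not mask.any():
        raise DegenerateInputError("ROI is empty")
    return float(values[mask].mean())


def conventional_subtraction(
    current: np.ndarray, baseline: np.ndarray, roi: np.ndarray
) -> tuple[np.ndarray, float]:
    """Direct pixel-by-pixel intensity subtraction baseline.

    Returns the raw difference image of two motion-compensated frames and its
    mean over the ROI — the comparison standard the spectral transform is
    judged against.
    """
    cur = np.asarray(current, dtype=float)
    base = np.asarray(baseline, dtype=float)
    if cur.shape != base.shape:
        raise ConsistencyError(f"frame shapes differ: {cur.shape} vs {base.shape}")
    mask = np.asarray(roi, dtype=bool)
    if mask.shape != cur.shape:
        raise ConsistencyError(f"ROI shape {mask.shape} != frame shape {cur.shape}")
    if not mask.any():
        raise DegenerateInputError("ROI is empty")
    diff = cur - base
    return diff, float(diff[mask].mean())


def percent_increment(value_t: float, value_0: float, eps: float = PERCENT_EPS) -> float:
    """Relative change of a quantifier against its pre-injection reference, in %.

    ``100 * (value_t - value_0) / max(|value_0|, eps)``.  A reference below
    ``eps`` with a non-negligible change is unstable: a signed infinity is
    returned with a warning rather than a spurious finite percentage.
    """
    delta = value_t - value_0
    if abs(value_0) < eps:
        if abs(delta) < eps:
            return 0.0
        warnings.warn(
            "percent_increment: reference value is ~0, increment is unstable",
            RuntimeWarning,
            stacklevel=2,
        )
        return math.copysign(math.inf, delta)
    return 100.0 * delta / abs(value_0)
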