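"""Vessel-center extraction, relative drug-diffusion estimates and group tests.

Bright, persistent regions of the contrast-variation map ``V_t`` mark where
circulating contrast agent concentrates, i.e. perfused vessels.  Thresholding
``V_t`` inside the tumor mask, cleaning the binary result with morphological
opening and closing, and taking connected-component centroids yields vessel
centers.  Treating each center as an instantaneous point source of drug and
superposing the Green's-function solution of 2-D isotropic diffusion

    u(x) = sum_k w_k * exp(-||x - x_k||^2 / (4 D t))

gives a relative (0-1 normalized) map of expected drug penetration, where the
single effective spread ``D_t = D * t`` (pixels^2) is the only free parameter.
Cohorts imaged at different temperatures are compared by two-sample t-tests
on their percent contrast increments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from skimage import measure, morphology

from .errors import ConsistencyError, DegenerateInputError, ParameterError
from .transform import VariationMap

DEFAULT_MIN_PATCH_PX = 5
DEFAULT_THRESHOLD_PERCENTILE = 95.0
DEFAULT_D_T = 25.0


@dataclass
class VesselCenters:
    """Centroids of suprathreshold patches of a variation map."""

    centers: list[tuple[float, float]]
    patch_sizes: list[int]
    threshold_used: float
    weights: list[float]

    def __len__(self) -> int:
        return len(self.centers)


@dataclass
class DiffusionEstimate:
    """Relative drug-penetration map, min-max normalized inside the mask."""

    values: np.ndarray
    d_t: float
    mask: np.ndarray


@dataclass
class GroupComparison:
    """Two-sample t-test between two groups of percent increments."""

    group_labels: tuple[str, str]
    statistic: float
    p_value: float
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def extract_vessel_centers(
    vmap: VariationMap | np.ndarray,
    tumor_mask: np.ndarray,
    threshold: float | None = None,
    min_patch_px: int = DEFAULT_MIN_PATCH_PX,
    morph_size: int = 3,
    intensity_weighted: bool = False,
) -> VesselCenters:
    """Threshold + morphological cleanup + connected-component centroids.

    ``threshold=None`` uses the 95th percentile of the in-mask values.  The
    binary map is opened then closed with a ``morph_size`` square structuring
    element; components smaller than ``min_patch_px`` are discarded.  An empty
    result is a valid outcome (no vessel visible yet).
    """
    values = vmap.values if isinstance(vmap, VariationMap) else np.asarray(vmap, float)
    mask = np.asarray(tumor_mask, dtype=bool)
    if mask.shape != values.shape:
        raise ConsistencyError(f"mask shape {mask.shape} != map shape {values.shape}")
    if not mask.any():
        raise DegenerateInputError("tumor mask is empty")
    if threshold is None:
        threshold = float(np.percentile(values[mask], DEFAULT_THRESHOLD_PERCENTILE))
    binary = (values >= threshold) & mask
    footprint = np.ones((morph_size, morph_size), dtype=bool)
    binary = morphology.opening(binary, footprint)
    binary = morphology.closing(binary, footprint)
    binary &= mask
    labels = measure.label(binary, connectivity=2)
    centers: list[tuple[float, float]] = []
    sizes: list[int] = []
    weights: list[float] = []
    for region in measure.regionprops(labels, intensity_image=values):
        if region.area < min_patch_px:
            continue
        if intensity_weighted:
            centers.append(tuple(map(float, region.centroid_weighted)))
        else:
            centers.append(tuple(map(float, region.centroid)))
        sizes.append(int(region.area))
        weights.append(float(region.intensity_mean))
    return VesselCenters(
        centers=centers, patch_sizes=sizes, threshold_used=float(threshold), weights=weights
    )


def diffusion_map(
    centers: VesselCenters | Sequence[tuple[float, float]],
    source_weights: Sequence[float] | None,
    d_t: float,
    mask: np.ndarray,
) -> DiffusionEstimate:
    """Superposed point-source diffusion profile, 0-1 normalized in the mask.

    ``source_weights`` default to the per-center mean map intensities when a
    :class:`VesselCenters` is passed, otherwise to 1.
    """
    if isinstance(centers, VesselCenters):
        pts = centers.centers
        if source_weights is None:
            source_weights = centers.weights
    else:
        pts = list(centers)
    if len(pts) == 0:
        raise DegenerateInputError("need at least one vessel center")
    if not (np.isfinite(d_t) and d_t > 0):
        raise ParameterError(f"D_t must be positive, got {d_t}")
    mask = np.asarray(mask, dtype=bool)
    w = np.ones(len(pts)) if source_weights is None else np.asarray(source_weights, float)
    if w.shape[0] != len(pts):
        raise ConsistencyError("one source weight per center is required")
    gr, gc = np.mgrid[0 : mask.shape[0], 0 : mask.shape[1]].astype(float)
    values = np.zeros(mask.shape)
    for (r, c), wk in zip(pts, w):
        values += wk * np.exp(-((gr - r) ** 2 + (gc - c) ** 2) / (4.0 * d_t))
    values = np.where(mask, values, 0.0)
    inside = values[mask]
    span = inside.max() - inside.min()
    if span > 0:
        values = np.where(mask, (values - inside.min()) / span, 0.0)
    return DiffusionEstimate(values=values, d_t=float(d_t), mask=mask)


def compare_groups(
    increments_a: Sequence[float],
    increments_b: Sequence[float],
    alpha: float = 0.05,
    labels: tuple[str, str] = ("a", "b"),
    welch: bool = False,
) -> GroupComparison:
    """Two-sample t-test (pooled variance by default, Welch by flag)."""
    a = np.asarray(increments_a, dtype=float)
    b = np.asarray(increments_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise DegenerateInputError("each group needs at least 2 values")
    if not (0.0 < alpha < 1.0):
        raise ParameterError(f"alpha must be in (0, 1), got {alpha}")
    res = stats.ttest_ind(a, b, equal_var=not welch)
    p = float(res.pvalue)
    if not np.isfinite(p):  # identical zero-variance groups
        p = 1.0
    return GroupComparison(
        group_labels=labels, statistic=float(res.statistic), p_value=p, alpha=alpha
    )


@dataclass
class TemperatureSummary:
    """Group curves, endpoint table and pairwise tests for a cohort experiment."""

    curves: pd.DataFrame
    endpoints: pd.DataFrame
    tests: pd.DataFrame


def temperature_experiment(
    runs: Mapping[str, Sequence[pd.DataFrame]],
    alpha: float = 0.05,
    welch: bool = False,
) -> TemperatureSummary:
    """Summarize per-animal increment series by temperature group.

    ``runs`` maps a group label (e.g. "37C") to per-animal data frames with
    columns ``frame_index``, ``sff_percent`` and ``conventional_percent``.
    Returns mean +- sd increment curves per group and method, endpoint
    (last-frame) summaries, and all pairwise two-sample t-tests on the
    endpoint increments for both methods.  Groups with fewer than 2 animals
    are excluded with a warning.
    """
    methods = ("sff", "conventional")
    usable: dict[str, Sequence[pd.DataFrame]] = {}
    for group, animals in runs.items():
        if len(animals) < 2:
            warnings.warn(
                f"group {group!r} has <2 animals and is excluded", RuntimeWarning,
                stacklevel=2,
            )
            continue
        usable[group] = animals

    curve_rows = []
    endpoint_rows = []
    endpoints: dict[tuple[str, str], np.ndarray] = {}
    for group, animals in usable.items():
        for method in methods:
            col = f"{method}_percent"
            stack = np.vstack([df[col].to_numpy(dtype=float) for df in animals])
            frame_idx = animals[0]["frame_index"].to_numpy()
            mean = stack.mean(axis=0)
            sd = stack.std(axis=0, ddof=1)
            for i, fi in enumerate(frame_idx):
                curve_rows.append(
                    {
                        "group": group,
                        "method": method,
                        "frame_index": int(fi),
                        "mean": mean[i],
                        "sd": sd[i],
                    }
                )
            end = stack[:, -1]
            endpoints[(group, method)] = end
            endpoint_rows.append(
                {
                    "group": group,
                    "method": method,
                    "mean": end.mean(),
                    "sd": end.std(ddof=1),
                    "n": end.size,
                }
            )

    test_rows = []
    for ga, gb in combinations(usable.keys(), 2):
        for method in methods:
            cmp_res = compare_groups(
                endpoints[(ga, method)],
                endpoints[(gb, method)],
                alpha=alpha,
                labels=(ga, gb),
                welch=welch,
            )
            test_rows.append(
                {
                    "pair": f"{ga} vs {gb}",
                    "method": method,
                    "t": cmp_res.statistic,
                    "p": cmp_res.p_value,
                    "significant": cmp_res.significant,
                }
            )
    return TemperatureSummary(
        curves=pd.DataFrame(curve_rows),
        endpoints=pd.DataFrame(endpoint_rows),
        tests=pd.DataFrame(test_rows),
    )
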