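"""End-to-end orchestration: track -> compensate -> transform -> quantify.

The pipeline reproduces the full contrast-imaging workflow on a cine stack:
rigid motion tracking of a feature-rich ROI, resampling of every frame into
baseline coordinates, the spectral Fiedler transform of each compensated
frame, variation maps against the pre-injection baseline, ROI quantification
(spectral and conventional-subtraction), and optional vessel-center /
diffusion outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .downstream import DiffusionEstimate, VesselCenters, diffusion_map, extract_vessel_centers
from .errors import DegenerateInputError
from .io import ROIMask, write_stack
from .motion import (
    SearchBounds,
    TrackedSeries,
    select_tracking_roi,
    track_roi,
    warp_to_reference,
)
from .spectral import KernelParams
from .transform import (
    SFFMap,
    VariationMap,
    conventional_subtraction,
    percent_increment,
    roi_contrast,
    sff_map,
    variation_map,
)


@dataclass
class PipelineResult:
    """Everything one pipeline run produces."""

    tracked: TrackedSeries
    compensated: np.ndarray  # (n, M, N) motion-compensated frames
    maps: list[SFFMap]
    variations: list[VariationMap]
    quantification: pd.DataFrame
    vessels: VesselCenters | None = None
    diffusion: DiffusionEstimate | None = None
    provenance: dict = field(default_factory=dict)


def search_bounds_from_config(config: RunConfig) -> SearchBounds:
    return SearchBounds(
        max_shift=config.max_shift,
        shift_step=config.shift_step,
        max_rot=config.max_rot,
        rot_step=config.rot_step,
        ncc_floor=config.ncc_floor,
    )


def quantify_series(
    compensated: np.ndarray,
    maps: list[SFFMap],
    variations: list[VariationMap],
    roi: ROIMask,
    times: np.ndarray,
    baseline_index: int = 0,
) -> pd.DataFrame:
    """Per-frame quantification table for one ROI.

    Columns: spectral ROI contrast (Eq.-8-style masked mean of the filtered
    map), the conventional subtraction increment (mean raw difference over
    the ROI), the spectral percent increment against the baseline frame, and
    the conventional percent increment of the mean ROI intensity.
    """
    mask = roi.mask
    base_frame = compensated[baseline_index]
    sff_q = np.array([roi_contrast(m, mask) for m in maps])
    conv_inc = np.array(
        [conventional_subtraction(f, base_frame, mask)[1] for f in compensated]
    )
    mean_int = np.array([float(f[mask].mean()) for f in compensated])
    rows = []
    for t in range(compensated.shape[0]):
        rows.append(
            {
                "frame_index": t,
                "time_s": float(times[t]),
                "roi_label": roi.label,
                "sff_contrast": sff_q[t],
                "conventional_increment": conv_inc[t],
                "percent_increment": percent_increment(sff_q[t], sff_q[baseline_index]),
                "conventional_percent": percent_increment(
                    mean_int[t], mean_int[baseline_index]
                ),
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(
    frames: np.ndarray,
    times: np.ndarray,
    config: RunConfig,
    tumor_roi: ROIMask,
    alt_rois: tuple[ROIMask, ...] = (),
    outdir: str | Path | None = None,
    compute_vessels: bool = False,
) -> PipelineResult:
    """Run the full workflow on a cine stack; optionally write all outputs."""
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3 or frames.shape[0] < 2:
        raise DegenerateInputError("need >= 2 frames to run the pipeline")
    times = np.asarray(times, dtype=float)
    params = KernelParams(sigma=config.sigma, r=config.r)
    bounds = search_bounds_from_config(config)

    track_mask, roi_used = select_tracking_roi(
        frames,
        tumor_roi.mask,
        tuple(r.mask for r in alt_rois),
        var_threshold=config.feature_var_threshold,
        labels=(tumor_roi.label,) + tuple(r.label for r in alt_rois),
    )
    tracked = track_roi(frames, track_mask, bounds, roi_label=roi_used)

    compensated = np.stack(
        [
            warp_to_reference(frames[k], tracked.transforms[k], tracked.center)
            for k in range(frames.shape[0])
        ]
    )
    maps = [
        sff_map(
            compensated[k],
            window=config.window,
            params=params,
            filter_sigma=config.filter_sigma,
            zero_tol=config.zero_tol,
            frame_index=k,
            time_s=float(times[k]),
        )
        for k in range(frames.shape[0])
    ]
    baseline = maps[config.baseline_index]
    variations = [variation_map(m, baseline) for m in maps]
    table = quantify_series(
        compensated, maps, variations, tumor_roi, times, config.baseline_index
    )

    vessels = None
    diffusion = None
    if compute_vessels:
        vessels = extract_vessel_centers(
            variations[-1],
            tumor_roi.mask,
            threshold=config.vessel_threshold,
            min_patch_px=config.vessel_min_patch_px,
            morph_size=config.morph_size,
        )
        if len(vessels):
            diffusion = diffusion_map(vessels, None, config.d_t, tumor_roi.mask)

    provenance = {
        "version": __version__,
        "config": config.to_dict(),
        "n_frames": int(frames.shape[0]),
        "shape": list(frames.shape[1:]),
        "tracking_roi": roi_used,
    }
    result = PipelineResult(
        tracked=tracked,
        compensated=compensated,
        maps=maps,
        variations=variations,
        quantification=table,
        vessels=vessels,
        diffusion=diffusion,
        provenance=provenance,
    )
    if outdir is not None:
        _write_outputs(result, Path(outdir))
    return result


def _write_outputs(result: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    write_stack(outdir / "contrast_C.tif", np.stack([m.contrast for m in result.maps]))
    write_stack(outdir / "sff_F.tif", np.stack([m.filtered for m in result.maps]))
    write_stack(outdir / "variation_V.tif", np.stack([v.values for v in result.variations]))
    write_stack(outdir / "compensated.tif", result.compensated)
    result.quantification.to_csv(outdir / "quantification.csv", index=False)
    (outdir / "provenance.json").write_text(
        json.dumps(result.provenance, indent=2, sort_keys=True)
    )
    if result.vessels is not None:
        pd.DataFrame(
            {
                "row": [c[0] for c in result.vessels.centers],
                "col": [c[1] for c in result.vessels.centers],
                "patch_px": result.vessels.patch_sizes,
                "weight": result.vessels.weights,
            }
        ).to_csv(outdir / "vessel_centers.csv", index=False)
    if result.diffusion is not None:
        write_stack(outdir / "diffusion.tif", result.diffusion.values)
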