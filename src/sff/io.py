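"""Reading/writing image stacks and region-of-interest definitions.

Coordinate convention used everywhere in the package: 0-based (row, col)
pixel coordinates with the origin at the top-left; rectangles are half-open
in width/height (``x, y`` is the top-left pixel, ``width x height`` pixels
are covered).  Intensities are normalized to [0, 1] by the acquisition bit
depth (8- or 16-bit), never per-frame, so temporal intensity changes survive
normalization.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from .errors import FormatError, ValidationError

_FRAME_SUFFIXES = (".png", ".tif", ".tiff")


@dataclass
class ROIMask:
    """Boolean pixel mask with a label."""

    mask: np.ndarray
    label: str = "roi"


def _normalize_frames(raw: np.ndarray, source: str) -> np.ndarray:
    if raw.dtype == np.uint8:
        return raw.astype(float) / 255.0
    if raw.dtype == np.uint16:
        return raw.astype(float) / 65535.0
    if np.issubdtype(raw.dtype, np.floating):
        arr = raw.astype(float)
        if not np.all(np.isfinite(arr)):
            raise FormatError(f"{source}: float frames contain non-finite values")
        if arr.min() < -1e-6 or arr.max() > 1.0 + 1e-6:
            raise FormatError(f"{source}: float frames must already be in [0, 1]")
        return np.clip(arr, 0.0, 1.0)
    raise FormatError(f"{source}: unsupported dtype {raw.dtype}")


def read_stack(path: str | Path) -> tuple[np.ndarray, dict]:
    """Load a grayscale cine stack from a multi-page TIFF or a frame directory.

    Returns ``(frames, meta)`` with frames shaped (n, M, N), float in [0, 1],
    in page order (TIFF) or lexicographic filename order (directory).
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file or directory: {path}")
    if path.is_dir():
        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in _FRAME_SUFFIXES
        )
        if not files:
            raise FormatError(f"no frames found in directory {path}")
        frames = []
        dtype = None
        shape = None
        for f in files:
            try:
                raw = np.asarray(iio.imread(f))
            except Exception as exc:  # noqa: BLE001 - report the filename
                raise FormatError(f"could not read frame {f}: {exc}") from exc
            if raw.ndim != 2:
                raise FormatError(f"{f}: expected a 2-D grayscale frame")
            if dtype is None:
                dtype, shape = raw.dtype, raw.shape
            elif raw.dtype != dtype or raw.shape != shape:
                raise FormatError(
                    f"{f}: mixed shapes/bit depths in directory "
                    f"({raw.shape}/{raw.dtype} vs {shape}/{dtype})"
                )
            frames.append(raw)
        raw_stack = np.stack(frames)
        source = str(path)
    else:
        try:
            raw_stack = np.asarray(tifffile.imread(path))
        except Exception as exc:  # noqa: BLE001
            raise FormatError(f"could not read stack {path}: {exc}") from exc
        if raw_stack.ndim == 2:
            raw_stack = raw_stack[None]
        if raw_stack.ndim != 3:
            raise FormatError(f"{path}: expected a 2-D or 3-D grayscale stack")
        source = str(path)
    stack = _normalize_frames(raw_stack, source)
    meta = {
        "source": source,
        "n_frames": stack.shape[0],
        "shape": tuple(stack.shape[1:]),
        "dtype": str(raw_stack.dtype),
    }
    return stack, meta


def write_stack(path: str | Path, stack: np.ndarray) -> None:
    """Write a float map stack (or single map) as float32 TIFF."""
    arr = np.asarray(stack, dtype=np.float32)
    tifffile.imwrite(Path(path), arr, photometric="minisblack")


def rasterize_polygon(vertices: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Even-odd (ray-casting) polygon fill evaluated at pixel centers."""
    verts = np.asarray(vertices, dtype=float)
    if verts.ndim != 2 or verts.shape[1] != 2 or verts.shape[0] < 3:
        raise ValidationError("polygon needs >= 3 (row, col) vertices")
    gr, gc = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
    inside = np.zeros(shape, dtype=bool)
    n = verts.shape[0]
    for i in range(n):
        r1, c1 = verts[i]
        r2, c2 = verts[(i + 1) % n]
        crosses = (r1 > gr) != (r2 > gr)
        with np.errstate(divide="ignore", invalid="ignore"):
            c_at = (c2 - c1) * (gr - r1) / (r2 - r1) + c1
        inside ^= crosses & (gc < c_at)
    return inside


def load_roi(path: str | Path, shape: tuple[int, int]) -> ROIMask:
    """Load a JSON ROI (rectangle or polygon) as a boolean mask.

    Rectangle schema: ``{"x": col, "y": row, "width": w, "height": h}``.
    Polygon schema: ``{"vertices": [[row, col], ...]}`` (even-odd interior).
    An optional ``"label"`` names the ROI.
    """
    path = Path(path)
    try:
        spec = json.loads(path.read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise ValidationError(f"could not parse ROI file {path}: {exc}") from exc
    return roi_from_dict(spec, shape, default_label=path.stem)


def roi_from_dict(
    spec: dict, shape: tuple[int, int], default_label: str = "roi"
) -> ROIMask:
    label = str(spec.get("label", default_label))
    mask = np.zeros(shape, dtype=bool)
    if {"x", "y", "width", "height"} <= spec.keys():
        x, y = int(spec["x"]), int(spec["y"])
        w, h = int(spec["width"]), int(spec["height"])
        if w <= 0 or h <= 0:
            raise ValidationError("rectangle width/height must be positive")
        mask[max(y, 0) : y + h, max(x, 0) : x + w] = True
    elif "vertices" in spec:
        mask = rasterize_polygon(np.asarray(spec["vertices"], dtype=float), shape)
    else:
        raise ValidationError(
            "ROI must define either x/y/width/height or a vertices list"
        )
    if not mask.any():
        raise ValidationError(f"ROI {label!r} has an empty interior on shape {shape}")
    return ROIMask(mask=mask, label=label)
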