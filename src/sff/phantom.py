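"""Synthetic cine B-mode phantom with ground truth for every pipeline stage.

The generator emulates the acquisitions the pipeline is designed for: a cine
loop of grayscale frames (100 frames at 20 f/s by default) of speckled tissue
in which echogenic contrast agent accumulates slowly inside one or more blob
regions after a pre-injection baseline frame, while a static bright artifact
band (skin line / reverberation) and frame-to-frame rigid motion corrupt the
raw intensities.

Image model per frame t (in frame-0 "tissue" coordinates, then warped by the
ground-truth rigid transform):

    scene_t = (tissue + sum_b amp_b(t) * profile_b + artifacts) * speckle_t
    frame_t = clip(gain_t * warp(scene_t, T_t) + electronic_noise_t, 0, 1)

* speckle is a multiplicative Rayleigh field smoothed by a small Gaussian
  point-spread (sigma = 1 px) and normalized to unit mean.  Most of it is a
  static scatterer realization that moves with the tissue; a configurable
  fraction (``speckle_decorrelation``) is redrawn each frame, emulating
  electronic noise and sub-resolution scatterer motion;
* blob accumulation follows the saturating law
  ``amp_b(t) = peak * (1 - exp(-rate * t))`` with t in frames, so frame 0 is
  always the pre-injection baseline (amplitude 0);
* ``gain_t`` is per-frame multiplicative gain jitter and ``electronic_noise``
  small additive Gaussian noise — the acquisition nuisances that make direct
  pixel subtraction noisy in practice;
* motion is either absent, a user-supplied list of transforms, or a bounded
  integer random walk (rotation about the image center).

Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
from scipy import ndimage

from .errors import ConfigurationError
from .motion import RigidTransform

RAYLEIGH_MEAN = np.sqrt(np.pi / 2.0)  # mean of Rayleigh(scale=1)


@dataclass(frozen=True)
class Blob:
    """An accumulating contrast region: a tapered disc whose added amplitude
    grows as ``peak * (1 - exp(-rate * t))`` with t in frames."""

    center: tuple[float, float]
    radius: float
    peak_amplitude: float = 0.35
    rate: float = 0.08
    edge_width: float = 2.0

    def amplitude(self, t: np.ndarray | float) -> np.ndarray | float:
        return self.peak_amplitude * (1.0 - np.exp(-self.rate * np.asarray(t, float)))


@dataclass(frozen=True)
class ArtifactBand:
    """A static bright horizontal band (e.g. skin line) spanning given rows."""

    row_start: int
    row_stop: int
    amplitude: float = 0.45
    col_start: int | None = None
    col_stop: int | None = None


@dataclass
class PhantomConfig:
    """Full description of one synthetic cine acquisition."""

    shape: tuple[int, int] = (128, 128)
    n_frames: int = 100
    fps: float = 20.0
    background: float = 0.25
    tissue_texture_amp: float = 0.04
    tissue_texture_sigma: float = 4.0
    speckle_scale: float = 1.0
    speckle_smooth_sigma: float = 1.0
    speckle_decorrelation: float = 0.15
    gain_jitter_std: float = 0.03
    electronic_noise_std: float = 0.005
    blobs: list[Blob] = field(default_factory=list)
    artifacts: list[ArtifactBand] = field(default_factory=list)
    motion: str = "none"  # "none" | "random_walk" | "fixed"
    motion_transforms: list[RigidTransform] | None = None
    motion_step: int = 1
    motion_bound: int = 6
    rotation_step: float = 0.0  # degrees per frame step in the random walk
    rotation_bound: float = 0.0
    seed: int = 1234

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ConfigurationError("n_frames must be >= 2")
        if self.motion not in ("none", "random_walk", "fixed"):
            raise ConfigurationError(f"unknown motion mode {self.motion!r}")
        if self.motion == "fixed" and (
            self.motion_transforms is None
            or len(self.motion_transforms) != self.n_frames
        ):
            raise ConfigurationError(
                "motion='fixed' needs one transform per frame"
            )
        # per-pixel nominal amplitude at full accumulation (geometry-aware:
        # a blob and an artifact only add up where they actually overlap)
        peak_map = np.full(self.shape, self.background + self.tissue_texture_amp)
        for band in self.artifacts:
            c0 = 0 if band.col_start is None else band.col_start
            c1 = self.shape[1] if band.col_stop is None else band.col_stop
            peak_map[band.row_start : band.row_stop, c0:c1] += band.amplitude
        for blob in self.blobs:
            profile, _ = _blob_profile(self.shape, blob)
            peak_map += blob.peak_amplitude * profile
        peak_scene = float(peak_map.max())
        if peak_scene > 1.0 + 1e-9:
            raise ConfigurationError(
                f"nominal scene amplitude {peak_scene:.3f} exceeds the [0, 1] "
                "clipping margin; reduce background/blob/artifact amplitudes"
            )

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.fps


@dataclass
class PhantomTruth:
    """Ground truth consistent with the generated frames by construction."""

    blob_supports: np.ndarray  # (n_blobs, M, N) bool, frame-0 coordinates
    blob_masks: np.ndarray  # (n_frames, n_blobs, M, N) bool, per-frame coords
    transforms: list[RigidTransform]
    amplitudes: np.ndarray  # (n_frames, n_blobs)
    artifact_mask: np.ndarray  # (M, N) bool, frame-0 coordinates
    background_mask: np.ndarray  # static background, away from blobs/artifacts
    tumor_roi: np.ndarray  # quantification ROI around the blob(s)
    center: tuple[float, float]  # rotation center of the motion model


@dataclass
class CineRun:
    """One generated acquisition: frames, time stamps, truth and its config."""

    frames: np.ndarray  # (n_frames, M, N) float in [0, 1]
    times: np.ndarray
    truth: PhantomTruth
    config: PhantomConfig


def _normalized_speckle(
    rng: np.random.Generator, shape: tuple[int, int], scale: float, smooth: float
) -> np.ndarray:
    """Unit-mean Rayleigh speckle field with PSF-scale spatial correlation.

    The envelope of a Gaussian-smoothed complex circular Gaussian field is
    exactly Rayleigh-distributed at every pixel (fully developed speckle,
    point SNR ~1.91) while inheriting the point-spread correlation length —
    smoothing the intensities directly would destroy the speckle contrast.
    """
    re = rng.standard_normal(shape)
    im = rng.standard_normal(shape)
    if smooth > 0:
        re = ndimage.gaussian_filter(re, smooth)
        im = ndimage.gaussian_filter(im, smooth)
    env = np.hypot(re, im)  # Rayleigh-distributed (scale set by the PSF)
    # normalize by the *empirical* mean so the multiplicative field has unit
    # mean exactly per realization (the analytic mean would leave a static
    # few-percent bias on small grids); the Rayleigh scale parameter cancels
    return env / max(env.mean(), 1e-12)


def _blob_profile(shape: tuple[int, int], blob: Blob) -> tuple[np.ndarray, np.ndarray]:
    gr, gc = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
    dist = np.hypot(gr - blob.center[0], gc - blob.center[1])
    profile = np.clip((blob.radius - dist) / max(blob.edge_width, 1e-6), 0.0, 1.0)
    support = dist <= blob.radius
    return profile, support


def _motion_transforms(config: PhantomConfig, rng: np.random.Generator) -> list[RigidTransform]:
    if config.motion == "fixed":
        return list(config.motion_transforms)  # type: ignore[arg-type]
    if config.motion == "none":
        return [RigidTransform.identity() for _ in range(config.n_frames)]
    transforms = [RigidTransform.identity()]
    dx = dy = 0.0
    theta = 0.0
    for _ in range(1, config.n_frames):
        dx += config.motion_step * int(rng.integers(-1, 2))
        dy += config.motion_step * int(rng.integers(-1, 2))
        dx = float(np.clip(dx, -config.motion_bound, config.motion_bound))
        dy = float(np.clip(dy, -config.motion_bound, config.motion_bound))
        if config.rotation_step > 0:
            theta += config.rotation_step * int(rng.integers(-1, 2))
            theta = float(np.clip(theta, -config.rotation_bound, config.rotation_bound))
        transforms.append(RigidTransform(dx=dx, dy=dy, theta=theta))
    return transforms


def _warp_scene(
    scene: np.ndarray, transform: RigidTransform, center: tuple[float, float], order: int = 1
) -> np.ndarray:
    """frame(x) = scene(T^-1(x)): the scene moves forward by the transform."""
    inv = transform.inverse()
    gr, gc = np.mgrid[0 : scene.shape[0], 0 : scene.shape[1]].astype(float)
    sr, sc = inv.apply(gr.ravel(), gc.ravel(), center)
    return ndimage.map_coordinates(
        scene, [sr, sc], order=order, mode="reflect", prefilter=False
    ).reshape(scene.shape)


def generate_cine(config: PhantomConfig) -> CineRun:
    """Generate one deterministic cine acquisition with ground truth."""
    rng = np.random.default_rng(config.seed)
    m, n = config.shape
    center = ((m - 1) / 2.0, (n - 1) / 2.0)

    texture = rng.standard_normal((m, n))
    texture = ndimage.gaussian_filter(texture, config.tissue_texture_sigma)
    texture /= max(texture.std(), 1e-12)
    # background is the expected *post-speckle* level: the speckle multiplier
    # is normalized to unit mean, so no further rescaling is needed
    tissue = np.clip(config.background + config.tissue_texture_amp * texture, 0.02, None)

    artifact_map = np.zeros((m, n))
    artifact_mask = np.zeros((m, n), dtype=bool)
    for band in config.artifacts:
        c0 = 0 if band.col_start is None else band.col_start
        c1 = n if band.col_stop is None else band.col_stop
        artifact_map[band.row_start : band.row_stop, c0:c1] += band.amplitude
        artifact_mask[band.row_start : band.row_stop, c0:c1] = True
    if config.artifacts:
        artifact_map = ndimage.gaussian_filter(artifact_map, 1.0)

    profiles = []
    supports = []
    for blob in config.blobs:
        profile, support = _blob_profile((m, n), blob)
        profiles.append(profile)
        supports.append(support)
    n_blobs = len(config.blobs)
    blob_supports = (
        np.stack(supports) if n_blobs else np.zeros((0, m, n), dtype=bool)
    )

    transforms = _motion_transforms(config, rng)
    speckle_static = _normalized_speckle(
        rng, (m, n), config.speckle_scale, config.speckle_smooth_sigma
    )
    rho = config.speckle_decorrelation

    frames = np.empty((config.n_frames, m, n))
    amplitudes = np.zeros((config.n_frames, n_blobs))
    blob_masks = np.zeros((config.n_frames, n_blobs, m, n), dtype=bool)
    for t in range(config.n_frames):
        speckle = speckle_static
        if rho > 0:
            fresh = _normalized_speckle(
                rng, (m, n), config.speckle_scale, config.speckle_smooth_sigma
            )
            speckle = (1.0 - rho) * speckle_static + rho * fresh
        scene = tissue + artifact_map
        for b, blob in enumerate(config.blobs):
            amp = float(blob.amplitude(t))
            amplitudes[t, b] = amp
            scene = scene + amp * profiles[b]
        scene = scene * speckle
        warped = _warp_scene(scene, transforms[t], center)
        gain = 1.0 + config.gain_jitter_std * float(rng.standard_normal())
        noise = config.electronic_noise_std * rng.standard_normal((m, n))
        frames[t] = np.clip(gain * warped + noise, 0.0, 1.0)
        for b in range(n_blobs):
            moved = _warp_scene(
                blob_supports[b].astype(float), transforms[t], center, order=0
            )
            blob_masks[t, b] = moved > 0.5

    background_mask = ~artifact_mask.copy()
    for b in range(n_blobs):
        background_mask &= ~ndimage.binary_dilation(blob_supports[b], iterations=3)
    pad = config.motion_bound + 2
    border = np.zeros((m, n), dtype=bool)
    border[pad : m - pad, pad : n - pad] = True
    background_mask &= border
    if config.artifacts:
        background_mask &= ~ndimage.binary_dilation(artifact_mask, iterations=3)

    tumor_roi = _default_tumor_roi(config, blob_supports, artifact_mask)

    truth = PhantomTruth(
        blob_supports=blob_supports,
        blob_masks=blob_masks,
        transforms=transforms,
        amplitudes=amplitudes,
        artifact_mask=artifact_mask,
        background_mask=background_mask,
        tumor_roi=tumor_roi,
        center=center,
    )
    return CineRun(frames=frames, times=config.times, truth=truth, config=config)


def _default_tumor_roi(
    config: PhantomConfig, blob_supports: np.ndarray, artifact_mask: np.ndarray
) -> np.ndarray:
    """Rectangular quantification ROI: the blob neighborhood, deliberately
    large enough to also contain nearby artifact pixels, as a manually drawn
    tumor ROI would."""
    m, n = config.shape
    mask = np.zeros((m, n), dtype=bool)
    if not config.blobs:
        mask[m // 4 : 3 * m // 4, n // 4 : 3 * n // 4] = True
        return mask
    rows, cols = np.nonzero(blob_supports.any(axis=0) | artifact_mask)
    pad = 6
    r0 = max(int(rows.min()) - pad, 0)
    r1 = min(int(rows.max()) + pad + 1, m)
    c0 = max(int(cols.min()) - pad, 0)
    c1 = min(int(cols.max()) + pad + 1, n)
    mask[r0:r1, c0:c1] = True
    return mask


def default_phantom_config(seed: int = 1234, n_frames: int = 40) -> PhantomConfig:
    """The pinned default acceptance phantom: 128x128, 40 frames, one
    accumulating blob (radius 10), one static artifact band, translation-only
    random-walk motion."""
    return PhantomConfig(
        shape=(128, 128),
        n_frames=n_frames,
        fps=20.0,
        blobs=[Blob(center=(84.0, 70.0), radius=10.0, peak_amplitude=0.35, rate=0.08)],
        artifacts=[
            ArtifactBand(row_start=40, row_stop=48, amplitude=0.4, col_start=30, col_stop=110)
        ],
        motion="random_walk",
        seed=seed,
    )


def phantom_config_from_dict(data: dict) -> PhantomConfig:
    """Build a :class:`PhantomConfig` from a plain (YAML-friendly) dict."""
    data = dict(data)
    if "shape" in data:
        data["shape"] = tuple(data["shape"])
    data["blobs"] = [
        Blob(center=tuple(b["center"]), radius=b["radius"],
             peak_amplitude=b.get("peak_amplitude", 0.35),
             rate=b.get("rate", 0.08), edge_width=b.get("edge_width", 2.0))
        for b in data.get("blobs", [])
    ]
    data["artifacts"] = [ArtifactBand(**a) for a in data.get("artifacts", [])]
    if data.get("motion_transforms"):
        data["motion_transforms"] = [
            RigidTransform(**t) for t in data["motion_transforms"]
        ]
    return PhantomConfig(**data)


def load_phantom_config(path: str | Path | None = None) -> PhantomConfig:
    """Load a phantom config YAML; with no path, the pinned default fixture
    shipped with the package."""
    import yaml

    if path is None:
        source = resources.files("sff").joinpath("data/default_phantom.yaml")
        text = source.read_text()
    else:
        text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    return phantom_config_from_dict(data)


DEFAULT_COHORT_RATES: Mapping[str, float] = {"37C": 0.01, "39C": 0.03, "42C": 0.06}
DEFAULT_COHORT_SIZES: Mapping[str, int] = {"37C": 5, "39C": 5, "42C": 6}


def cohort_base_config(seed: int = 0, n_frames: int = 40) -> PhantomConfig:
    """Reduced-size per-animal acquisition used in simulated cohorts."""
    return PhantomConfig(
        shape=(64, 64),
        n_frames=n_frames,
        fps=20.0,
        blobs=[Blob(center=(40.0, 32.0), radius=8.0, peak_amplitude=0.35, rate=0.03)],
        artifacts=[
            ArtifactBand(row_start=14, row_stop=19, amplitude=0.4, col_start=12, col_stop=52)
        ],
        motion="none",
        seed=seed,
    )


@dataclass
class Cohort:
    """Independent cine runs per animal, grouped by temperature label."""

    runs: dict[str, list[CineRun]]
    rates: dict[str, float]
    seed: int

    @property
    def n_animals(self) -> int:
        return sum(len(v) for v in self.runs.values())


def generate_cohorts(
    rates: Mapping[str, float] | None = None,
    n_per_group: Mapping[str, int] | None = None,
    seed: int = 0,
    base_config: PhantomConfig | None = None,
    rate_jitter: float = 0.10,
) -> Cohort:
    """Simulate temperature cohorts with ordered accumulation rates.

    Defaults mirror the three-temperature design (5/5/6 animals); each animal
    gets an independent child seed and a log-normal jitter on its group rate
    (within-group biological variability).
    """
    rates = dict(DEFAULT_COHORT_RATES if rates is None else rates)
    n_per_group = dict(DEFAULT_COHORT_SIZES if n_per_group is None else n_per_group)
    if set(rates) != set(n_per_group):
        raise ConfigurationError("rates and n_per_group must share the same groups")
    for g, size in n_per_group.items():
        if size < 1:
            raise ConfigurationError(f"group {g!r} has nonpositive size {size}")
        if rates[g] <= 0:
            raise ConfigurationError(f"group {g!r} has nonpositive rate {rates[g]}")
    base = base_config or cohort_base_config()
    master = np.random.default_rng(seed)
    runs: dict[str, list[CineRun]] = {}
    for group in sorted(rates):
        runs[group] = []
        for _ in range(n_per_group[group]):
            child_seed = int(master.integers(0, 2**31 - 1))
            rate = rates[group] * float(
                np.exp(rate_jitter * master.standard_normal())
            )
            blobs = [
                Blob(
                    center=b.center,
                    radius=b.radius,
                    peak_amplitude=b.peak_amplitude,
                    rate=rate,
                    edge_width=b.edge_width,
                )
                for b in base.blobs
            ]
            cfg = replace(base, blobs=blobs, seed=child_seed)
            runs[group].append(generate_cine(cfg))
    return Cohort(runs=runs, rates=dict(rates), seed=seed)


def generate_patch_suite(
    n: int, size: tuple[int, int] = (9, 9), seed: int = 0
) -> list[np.ndarray]:
    """Deterministic suite of [0, 1] patches spanning flat to speckled regimes.

    Always starts with the special cases (constant patch, the two-level
    3-column patch whose window graph is a 3-node path, a checkerboard), then
    cycles uniform / low-variance / high-variance / speckle-like random
    patches until ``n`` patches exist.
    """
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    rng = np.random.default_rng(seed)
    patches: list[np.ndarray] = []
    patches.append(np.full(size, 0.5))
    patches.append(np.tile(np.array([[0.0, 0.0, 0.5]]), (3, 1)))
    rr, cc = np.mgrid[0 : size[0], 0 : size[1]]
    patches.append(((rr + cc) % 2).astype(float))
    while len(patches) < n:
        regime = len(patches) % 4
        if regime == 0:
            p = rng.uniform(0.0, 1.0, size)
        elif regime == 1:
            p = np.clip(0.5 + 0.02 * rng.standard_normal(size), 0.0, 1.0)
        elif regime == 2:
            p = np.clip(0.5 + 0.35 * rng.standard_normal(size), 0.0, 1.0)
        else:
            p = np.clip(
                0.3 * rng.rayleigh(scale=1.0, size=size) / RAYLEIGH_MEAN, 0.0, 1.0
            )
        patches.append(p)
    return patches[:n]
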