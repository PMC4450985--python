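"""Synthetic smFISH stack generator with known ground truth.

A synthetic stack is built the way widefield single-molecule images are
usually emulated: point emitters of chosen magnitude are sprinkled on an
empty voxel grid, convolved with a separable 3D Gaussian approximation of
the microscope point spread function, summed with a structured background
(baseline + smooth gradient + broad autofluorescence-like blobs), blurred
with a final light Gaussian filter, and topped with additive Gaussian
camera noise. Because the emitter positions and magnitudes are known, the
whole detection/classification pipeline can be scored without any real
microscopy data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal

from .stacks import GroundTruth, ImageStack, ValidationError

__all__ = [
    "BackgroundParams",
    "SimulationConfig",
    "generate_psf",
    "generate_background",
    "place_point_sources",
    "synthesize_stack",
    "simulate_stack",
    "signal_intensity_metric",
    "spot_density_metric",
    "DensityInfeasibleError",
]


class DensityInfeasibleError(ValidationError):
    """Requested spot density cannot be placed at the required separation."""


@dataclass
class BackgroundParams:
    """Structured-background model: baseline + linear gradient + Gaussian blobs.

    Stands in for an empty-specimen acquisition: ``baseline`` is diffuse
    unbound-probe fluorescence plus camera offset, the gradient mimics uneven
    illumination, and the broad blobs mimic autofluorescent bodies.
    """

    baseline: float = 120.0
    gradient_amplitude: float = 30.0
    n_blobs: int = 12
    blob_amplitude: float = 40.0
    blob_sigma: float = 24.0

    def validate(self) -> None:
        if self.baseline < 0 or self.gradient_amplitude < 0 or self.blob_amplitude < 0:
            raise ValidationError("background levels must be non-negative")
        if self.n_blobs < 0:
            raise ValidationError("n_blobs must be >= 0")
        if self.n_blobs > 0 and self.blob_sigma <= 0:
            raise ValidationError("blob_sigma must be > 0")


@dataclass
class SimulationConfig:
    """Everything needed to synthesize one stack, including the RNG seed.

    Defaults emulate a realistic widefield smFISH acquisition: diffraction-
    limited emitters (sigma_xy 1.3 px, sigma_z 1.8 planes), a light final
    blur, moderate camera noise, and emitter magnitudes that put the
    stack-level signal-intensity metric in the mid single digits.
    """

    shape: tuple[int, int, int] = (25, 256, 256)
    n_spots: int = 60
    magnitude_mean: float = 5000.0
    magnitude_cv: float = 0.2
    min_separation: float = 6.0
    psf_sigma_xy: float = 1.3
    psf_sigma_z: float = 1.8
    post_blur_sigma: float = 0.5
    background_params: BackgroundParams = field(default_factory=BackgroundParams)
    noise_sd: float = 4.0
    seed: int = 0
    stack_id: str = "sim"

    def validate(self) -> None:
        nz, ny, nx = self.shape
        if nz < 1 or ny < 32 or nx < 32:
            raise ValidationError(f"shape too small: {self.shape}")
        if self.n_spots < 0:
            raise ValidationError("n_spots must be >= 0")
        if self.min_separation < 0:
            raise ValidationError("min_separation must be >= 0")
        if self.psf_sigma_xy <= 0 or self.psf_sigma_z <= 0:
            raise ValidationError("PSF sigmas must be > 0")
        if self.post_blur_sigma < 0 or self.noise_sd < 0:
            raise ValidationError("post_blur_sigma and noise_sd must be >= 0")
        if self.magnitude_mean <= 0 or self.magnitude_cv < 0:
            raise ValidationError("magnitude_mean > 0 and magnitude_cv >= 0 required")
        self.background_params.validate()


def generate_psf(
    psf_sigma_xy: float, psf_sigma_z: float, truncate_radius: float = 3.0
) -> np.ndarray:
    """Separable 3D Gaussian PSF kernel on an odd grid, normalized to sum 1.

    ``truncate_radius`` is the half-width of the support in units of sigma.
    """
    if psf_sigma_xy <= 0 or psf_sigma_z <= 0:
        raise ValidationError("PSF sigmas must be > 0")
    if truncate_radius <= 0:
        raise ValidationError("truncate_radius must be > 0")
    rz = max(1, int(np.ceil(truncate_radius * psf_sigma_z)))
    rxy = max(1, int(np.ceil(truncate_radius * psf_sigma_xy)))
    z = np.arange(-rz, rz + 1, dtype=np.float64)
    xy = np.arange(-rxy, rxy + 1, dtype=np.float64)
    gz = np.exp(-0.5 * (z / psf_sigma_z) ** 2)
    gxy = np.exp(-0.5 * (xy / psf_sigma_xy) ** 2)
    kernel = gz[:, None, None] * gxy[None, :, None] * gxy[None, None, :]
    return kernel / kernel.sum()


def generate_background(
    shape: tuple[int, int, int],
    params: BackgroundParams | None = None,
    seed: int = 0,
    stack_id: str = "background",
) -> ImageStack:
    """Synthesize a structured, non-negative background stack.

    Deterministic for a given (shape, params, seed): blob centers and the
    gradient direction are the only random choices.
    """
    params = params or BackgroundParams()
    params.validate()
    nz, ny, nx = shape
    rng = np.random.default_rng(seed)
    bg = np.full(shape, float(params.baseline), dtype=np.float64)

    if params.gradient_amplitude > 0:
        # Random in-plane direction; ramp spans [0, amplitude] across the stack.
        theta = rng.uniform(0, 2 * np.pi)
        yy, xx = np.meshgrid(
            np.linspace(0, 1, ny), np.linspace(0, 1, nx), indexing="ij"
        )
        ramp = np.cos(theta) * yy + np.sin(theta) * xx
        ramp = ramp - ramp.min()
        if ramp.max() > 0:
            ramp = ramp / ramp.max()
        bg += params.gradient_amplitude * ramp[None, :, :]

    for _ in range(params.n_blobs):
        cz = rng.uniform(0, nz - 1)
        cy = rng.uniform(0, ny - 1)
        cx = rng.uniform(0, nx - 1)
        zz = np.arange(nz, dtype=np.float64)
        yy = np.arange(ny, dtype=np.float64)
        xx = np.arange(nx, dtype=np.float64)
        # Blobs are axially squashed the way out-of-focus bodies appear.
        gz = np.exp(-0.5 * ((zz - cz) / max(params.blob_sigma / 4.0, 1.0)) ** 2)
        gy = np.exp(-0.5 * ((yy - cy) / params.blob_sigma) ** 2)
        gx = np.exp(-0.5 * ((xx - cx) / params.blob_sigma) ** 2)
        bg += params.blob_amplitude * gz[:, None, None] * gy[None, :, None] * gx[None, None, :]

    return ImageStack(voxels=bg, stack_id=stack_id)


def place_point_sources(config: SimulationConfig) -> GroundTruth:
    """Sprinkle ``n_spots`` point sources at >= ``min_separation`` spacing.

    Placement is rejection sampling with a retry cap; magnitudes are drawn
    from Normal(mean, cv*mean) truncated to be positive. Deterministic for a
    given config seed.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x5057]))
    nz, ny, nx = config.shape
    placed: list[tuple[int, int, int]] = []
    max_tries = max(1000, 200 * config.n_spots)
    tries = 0
    while len(placed) < config.n_spots:
        if tries >= max_tries:
            raise DensityInfeasibleError(
                f"could not place {config.n_spots} sources at separation "
                f">= {config.min_separation} in {config.shape} "
                f"after {max_tries} attempts"
            )
        tries += 1
        z = int(rng.integers(0, nz))
        y = int(rng.integers(0, ny))
        x = int(rng.integers(0, nx))
        ok = True
        for pz, py, px in placed:
            d2 = (z - pz) ** 2 + (y - py) ** 2 + (x - px) ** 2
            if d2 < config.min_separation**2:
                ok = False
                break
        if ok:
            placed.append((z, y, x))

    sd = config.magnitude_cv * config.magnitude_mean
    mags = []
    for _ in range(config.n_spots):
        m = float(rng.normal(config.magnitude_mean, sd)) if sd > 0 else config.magnitude_mean
        while m <= 0:
            m = float(rng.normal(config.magnitude_mean, sd))
        mags.append(m)

    sources = [(z, y, x, m) for (z, y, x), m in zip(placed, mags)]
    return GroundTruth(sources=sources, stack_id=config.stack_id)


def synthesize_stack(
    truth: GroundTruth, background: ImageStack, config: SimulationConfig
) -> ImageStack:
    """Render sources over a background into a finished synthetic stack.

    output = GaussianBlur(background + PSF * delta(sources), post_blur)
             + N(0, noise_sd), clipped at 0. The in-memory result stays
    float; uint16 quantization happens only on file write.
    """
    config.validate()
    truth.validate_against(background)
    delta = np.zeros(background.shape, dtype=np.float64)
    for z, y, x, mag in truth.sources:
        delta[z, y, x] += mag

    if truth.sources:
        psf = generate_psf(config.psf_sigma_xy, config.psf_sigma_z)
        sig = signal.fftconvolve(delta, psf, mode="same")
    else:
        sig = delta

    img = background.voxels + sig
    if config.post_blur_sigma > 0:
        img = ndimage.gaussian_filter(img, sigma=config.post_blur_sigma)
    if config.noise_sd > 0:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x401]))
        img = img + rng.normal(0.0, config.noise_sd, size=img.shape)
    img = np.clip(img, 0.0, None)
    return ImageStack(voxels=img, stack_id=truth.stack_id)


def simulate_stack(
    config: SimulationConfig, background: ImageStack | None = None
) -> tuple[ImageStack, GroundTruth]:
    """Convenience driver: background (unless given) + sources + rendering."""
    config.validate()
    if background is None:
        background = generate_background(
            config.shape, config.background_params, seed=config.seed
        )
    elif background.shape != tuple(config.shape):
        raise ValidationError(
            f"background shape {background.shape} != config shape {config.shape}"
        )
    truth = place_point_sources(config)
    stack = synthesize_stack(truth, background, config)
    return stack, truth


def signal_intensity_metric(stack: ImageStack, truth: GroundTruth) -> float:
    """Stack-level signal intensity in units of image standard deviations.

    (mean intensity at the source voxels - mean of all voxels) / sd of all
    voxels. This is the x-axis of the quality sweep.
    """
    if not truth.sources:
        raise ValidationError("signal_intensity_metric needs >= 1 source")
    truth.validate_against(stack)
    v = stack.voxels
    sd = float(v.std())
    if sd == 0:
        raise ValidationError("undefined metric: image standard deviation is 0")
    coords = truth.coordinates()
    at_sources = v[coords[:, 0], coords[:, 1], coords[:, 2]]
    return float((at_sources.mean() - v.mean()) / sd)


def spot_density_metric(stack: ImageStack, truth: GroundTruth) -> float:
    """Mean Euclidean voxel distance from any voxel to its nearest source."""
    if not truth.sources:
        raise ValidationError("spot_density_metric needs >= 1 source")
    truth.validate_against(stack)
    mask = np.ones(stack.shape, dtype=bool)
    coords = truth.coordinates()
    mask[coords[:, 0], coords[:, 1], coords[:, 2]] = False
    dist = ndimage.distance_transform_edt(mask)
    return float(dist.mean())
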