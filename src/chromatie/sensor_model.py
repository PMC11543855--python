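"""Between the optical field and the recorded file.

Spectral channel definition (LED emission × Bayer filter response), the
single-shot three-channel capture through the chromatic train, optional
Bayer mosaic/demosaic, intensity-only transmission through a coherent
fiber bundle, and photon + read noise.

Wavelengths cross this module's API in nanometres (the field's customary
unit for spectra); they are converted to µm where fields are built.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .optics_core import OpticalTrain, SampledGrid, _transfer_bound, fresnel_propagate
from .phantoms import PhasePhantom

__all__ = [
    "SpectrumCurve",
    "ChannelSpec",
    "SpectralCapture",
    "FiberBundleSpec",
    "NoiseModel",
    "default_led_spectrum",
    "default_bayer_filters",
    "effective_wavelengths",
    "channels_from_train",
    "simulate_capture",
    "fiber_bundle_transmit",
    "add_noise",
    "bayer_mosaic",
    "demosaic_bilinear",
    "hex_pitch_from_density",
]

log = logging.getLogger(__name__)

NM_PER_UM = 1e3
CHANNEL_NAMES = ("R", "G", "B")


@dataclass(frozen=True)
class SpectrumCurve:
    """Sampled spectral curve: sorted wavelengths (nm), non-negative weights."""

    wavelengths: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "wavelengths", np.asarray(self.wavelengths, dtype=float))
        object.__setattr__(self, "weights", np.asarray(self.weights, dtype=float))
        if self.wavelengths.size < 3:
            raise ValueError("a spectrum needs at least 3 samples")
        if self.wavelengths.shape != self.weights.shape:
            raise ValueError("wavelengths and weights must have the same length")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if np.any(self.weights < 0) or not np.any(self.weights > 0):
            raise ValueError("weights must be non-negative and not all zero")

    def sample(self, grid_nm: np.ndarray) -> np.ndarray:
        return np.interp(grid_nm, self.wavelengths, self.weights, left=0.0, right=0.0)


def _gaussian(x: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((x - mu) / sigma) ** 2)


def default_led_spectrum() -> SpectrumCurve:
    """Synthetic stand-in for a phosphor white LED: blue pump + broad phosphor."""
    nm = np.arange(380.0, 751.0)
    w = 0.9 * _gaussian(nm, 455.0, 18.0) + _gaussian(nm, 560.0, 90.0)
    return SpectrumCurve(nm, w)


def default_bayer_filters() -> dict[str, SpectrumCurve]:
    """Synthetic stand-in Bayer responses, tuned so the product of each curve
    with :func:`default_led_spectrum` peaks at 625 / 530 / 455 nm exactly."""
    nm = np.arange(380.0, 751.0)
    centers = {"R": 631.2914, "G": 526.7009, "B": 453.1331}
    sigmas = {"R": 28.0, "G": 30.0, "B": 20.0}
    return {
        name: SpectrumCurve(nm, _gaussian(nm, centers[name], sigmas[name]))
        for name in CHANNEL_NAMES
    }


def effective_wavelengths(
    source: SpectrumCurve,
    bayer: dict[str, SpectrumCurve],
    resolution_nm: float = 0.25,
) -> dict[str, float]:
    """Per-channel peak of the source × filter spectral product, in nm.

    The product is sampled on a fine common grid and the discrete argmax is
    refined by quadratic interpolation through its three neighbours.  A
    channel whose product vanishes everywhere (no spectral overlap) raises.
    """
    out: dict[str, float] = {}
    for name, filt in bayer.items():
        lo = max(source.wavelengths[0], filt.wavelengths[0])
        hi = min(source.wavelengths[-1], filt.wavelengths[-1])
        if hi <= lo:
            raise ValueError(f"channel {name}: source and filter do not overlap")
        grid = np.arange(lo, hi + resolution_nm, resolution_nm)
        product = source.sample(grid) * filt.sample(grid)
        if not np.any(product > 0):
            raise ValueError(f"channel {name}: degenerate (all-zero) spectral product")
        i = int(np.argmax(product))
        if 0 < i < grid.size - 1:
            y0, y1, y2 = product[i - 1 : i + 2]
            denom = y0 - 2.0 * y1 + y2
            shift = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
            out[name] = float(grid[i] + shift * resolution_nm)
        else:
            out[name] = float(grid[i])
    return out


@dataclass(frozen=True)
class ChannelSpec:
    """One spectral channel of the single-shot capture.

    ``equivalent_defocus`` (µm, signed) is the propagation distance from the
    channel's own focused image plane to the fixed sensor plane.  With the
    sensor at the green image plane and positive z running toward the
    detector, red (shorter focal length, image formed earlier) carries a
    positive defocus and blue a negative one.
    """

    name: str
    center_wavelength: float  # nm
    equivalent_defocus: float  # µm

    def __post_init__(self) -> None:
        if self.center_wavelength <= 0:
            raise ValueError("center_wavelength must be positive (nm)")

    @property
    def wavelength_um(self) -> float:
        return self.center_wavelength / NM_PER_UM


def channels_from_train(
    train: OpticalTrain,
    wavelengths_nm: tuple[float, float, float] = (625.0, 530.0, 455.0),
    reference: str = "G",
) -> tuple[ChannelSpec, ChannelSpec, ChannelSpec]:
    """Derive per-channel equivalent defocus from the chromatic focal law.

    The metalens disperses focus linearly, λ·dz = −z·dλ at the nominal
    focal distance, so two spectral channels sample the object's diffraction
    pattern at planes separated by ``f·δλ/λ`` — the separation the
    through-focus calibration recovers (≈180 µm for the red–green pair of a
    1 mm lens).  The reference (green) channel defines z = 0 at the sensor;
    red, focusing earlier, is recorded past its focus (positive defocus) and
    blue before it (negative):

        equivalent_defocus(λ) = f_design · (λ − λ_ref)/λ_ref.

    Conjugate-plane bookkeeping and the per-channel magnification disparity
    of the single-lens train are idealized into this equivalent defocus,
    exactly as the solver treats the data.
    """
    if len(set(wavelengths_nm)) != 3:
        raise ValueError("channel wavelengths must be distinct")
    names = dict(zip(CHANNEL_NAMES, sorted(wavelengths_nm, reverse=True)))
    lam_ref = names[reference]
    return tuple(
        ChannelSpec(name, lam, train.focal_length * (lam - lam_ref) / lam_ref)
        for name, lam in names.items()
    )


@dataclass
class SpectralCapture:
    """Three co-registered intensity planes — the single-shot measurement."""

    grid: SampledGrid
    planes: np.ndarray  # (3, H, W), order matches `channels`
    channels: tuple[ChannelSpec, ChannelSpec, ChannelSpec]
    exposure_scale: float = 1.0

    def __post_init__(self) -> None:
        self.planes = np.asarray(self.planes, dtype=float)
        if self.planes.shape != (3, *self.grid.shape):
            raise ValueError(
                f"planes must be (3, {self.grid.n_rows}, {self.grid.n_cols}), "
                f"got {self.planes.shape}"
            )
        if not np.all(np.isfinite(self.planes)):
            raise ValueError("capture intensities must be finite")
        if np.any(self.planes < 0):
            raise ValueError("capture intensities must be non-negative")
        if len({c.center_wavelength for c in self.channels}) != 3:
            raise ValueError("channel wavelengths must be distinct")

    def plane(self, name: str) -> np.ndarray:
        for spec, p in zip(self.channels, self.planes):
            if spec.name == name:
                return p
        raise KeyError(f"no channel named {name!r}")

    def channel(self, name: str) -> ChannelSpec:
        for spec in self.channels:
            if spec.name == name:
                return spec
        raise KeyError(f"no channel named {name!r}")


@dataclass(frozen=True)
class NoiseModel:
    """Photon shot noise plus Gaussian read noise.

    ``photon_scale`` is the expected photon count at unit intensity;
    ``read_noise_sd`` is in the same (intensity) units as the planes.
    """

    photon_scale: float = 1e4
    read_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.photon_scale < 0 or self.read_noise_sd < 0:
            raise ValueError("noise magnitudes must be non-negative")


def _channel_quadrature(
    name: str,
    source: SpectrumCurve,
    filters: dict[str, SpectrumCurve],
    n_nodes: int,
) -> np.ndarray:
    """Equal-weight wavelength nodes (nm) at quantiles of the channel's
    source × filter spectral product — a midpoint rule in its CDF."""
    grid_nm = np.arange(380.0, 751.0)
    product = source.sample(grid_nm) * filters[name].sample(grid_nm)
    cdf = np.cumsum(product)
    if cdf[-1] <= 0:
        raise ValueError(f"channel {name}: degenerate spectral product")
    cdf /= cdf[-1]
    quantiles = (np.arange(n_nodes) + 0.5) / n_nodes
    return np.interp(quantiles, cdf, grid_nm)


def simulate_capture(
    phantom: PhasePhantom,
    train: OpticalTrain | None = None,
    channels: tuple[ChannelSpec, ChannelSpec, ChannelSpec] | None = None,
    noise: NoiseModel | None = None,
    mosaic: bool = False,
    pad: bool = True,
    spectral_samples: int = 7,
    source: SpectrumCurve | None = None,
    filters: dict[str, SpectrumCurve] | None = None,
) -> SpectralCapture:
    """Single-shot three-channel capture of a phantom through the chromatic train.

    Per channel the phantom's exit field is built at the channel wavelength
    (phase scales as 1/λ for a height object) and propagated by the channel's
    equivalent defocus; the sensor records intensity.

    The illumination is partially coherent: a broadband LED filtered by the
    Bayer response gives each channel a finite linewidth, so the recorded
    intensity averages ``spectral_samples`` wavelength nodes drawn from the
    channel's source × filter product (packaged default curves unless
    ``source``/``filters`` are given).  Each node carries its own phase
    (1/λ dispersion) and its own defocus from the chromatic focal law, which
    smears high-frequency defocus fringes exactly as a low-coherence source
    does.  ``spectral_samples=1`` gives the fully coherent (monochromatic)
    limit.  Polychromatic capture needs a ``train`` for the dispersion
    scale; with explicit ``channels`` only, the capture is monochromatic.

    With ``mosaic`` the planes are RGGB-sampled and bilinearly demosaiced;
    with ``noise`` Poisson photon noise and Gaussian read noise are applied
    under the stated seed.
    """
    if channels is None:
        if train is None:
            raise ValueError("provide either a train or explicit channels")
        channels = channels_from_train(train)
    polychromatic = spectral_samples > 1 and train is not None
    if polychromatic:
        source = source if source is not None else default_led_spectrum()
        filters = filters if filters is not None else default_bayer_filters()

    bound = _transfer_bound(
        SampledGrid(2 * phantom.grid.n_rows, 2 * phantom.grid.n_cols, phantom.grid.pixel_pitch)
        if pad
        else phantom.grid
    )
    planes = []
    for spec in channels:
        if abs(spec.wavelength_um * spec.equivalent_defocus) > bound:
            warnings.warn(
                f"channel {spec.name}: defocus {spec.equivalent_defocus:.0f} µm exceeds "
                f"the alias-safe range (λ|z| = "
                f"{abs(spec.wavelength_um * spec.equivalent_defocus):.0f} "
                f"> {bound:.0f} µm²)",
                stacklevel=2,
            )
        if polychromatic:
            nodes = _channel_quadrature(spec.name, source, filters, spectral_samples)
            # chromatic focal law maps each node to its own defocus
            zs = spec.equivalent_defocus + train.focal_length * (
                nodes - spec.center_wavelength
            ) / train.design_wavelength
        else:
            nodes = np.array([spec.center_wavelength])
            zs = np.array([spec.equivalent_defocus])
        intensity = np.zeros(phantom.grid.shape)
        for lam_nm, z in zip(nodes, zs):
            field = phantom.to_field(lam_nm / NM_PER_UM)
            intensity += fresnel_propagate(field, z, pad=pad).intensity()
        planes.append(intensity / len(nodes))
    planes = np.stack(planes)

    if mosaic:
        raw = bayer_mosaic(planes)
        planes = demosaic_bilinear(raw)

    capture = SpectralCapture(phantom.grid, planes, tuple(channels))
    if noise is not None:
        capture = add_noise(capture, noise)
    return capture


def add_noise(capture: SpectralCapture, noise: NoiseModel) -> SpectralCapture:
    """Apply Poisson photon noise then additive Gaussian read noise.

    Reproducible under the model's seed; the returned capture is a new
    object (inputs are never mutated).
    """
    if noise.photon_scale <= 0:
        raise ValueError("photon_scale must be positive to apply shot noise")
    rng = np.random.default_rng(noise.seed)
    noisy = rng.poisson(noise.photon_scale * capture.planes) / noise.photon_scale
    if noise.read_noise_sd > 0:
        noisy = noisy + rng.normal(0.0, noise.read_noise_sd, size=noisy.shape)
    noisy = np.clip(noisy, 0.0, None)
    return SpectralCapture(capture.grid, noisy, capture.channels, capture.exposure_scale)


# --- Bayer mosaic ------------------------------------------------------------


def bayer_mosaic(planes: np.ndarray) -> np.ndarray:
    """Sample three planes onto a single RGGB raw frame."""
    r, g, b = planes
    raw = np.empty_like(g)
    raw[0::2, 0::2] = r[0::2, 0::2]
    raw[0::2, 1::2] = g[0::2, 1::2]
    raw[1::2, 0::2] = g[1::2, 0::2]
    raw[1::2, 1::2] = b[1::2, 1::2]
    return raw


def demosaic_bilinear(raw: np.ndarray) -> np.ndarray:
    """Bilinear demosaic of an RGGB raw frame back to three full planes."""
    h, w = raw.shape
    masks = {
        "R": np.zeros((h, w), dtype=bool),
        "G": np.zeros((h, w), dtype=bool),
        "B": np.zeros((h, w), dtype=bool),
    }
    masks["R"][0::2, 0::2] = True
    masks["G"][0::2, 1::2] = True
    masks["G"][1::2, 0::2] = True
    masks["B"][1::2, 1::2] = True
    kernel = np.array([[1.0, 2.0, 1.0], [2.0, 4.0, 2.0], [1.0, 2.0, 1.0]])
    planes = []
    for name in CHANNEL_NAMES:
        samples = np.where(masks[name], raw, 0.0)
        num = ndimage.convolve(samples, kernel, mode="mirror")
        den = ndimage.convolve(masks[name].astype(float), kernel, mode="mirror")
        planes.append(num / den)
    return np.stack(planes)


# --- Coherent fiber bundle ---------------------------------------------------


def hex_pitch_from_density(cores_per_mm2: float) -> float:
    """Lattice pitch (µm) of a hexagonal packing with the given areal density.

    Density of a hex lattice is 2/(√3·pitch²); 18,000 cores/mm² gives
    pitch ≈ 8.0 µm.
    """
    if cores_per_mm2 <= 0:
        raise ValueError("density must be positive")
    density_per_um2 = cores_per_mm2 * 1e-6
    return float(np.sqrt(2.0 / (np.sqrt(3.0) * density_per_um2)))


@dataclass(frozen=True)
class FiberBundleSpec:
    """Hexagonal coherent fiber bundle geometry (lengths in µm).

    Defaults reconcile 3 µm cores with an 18,000 cores/mm² hex packing
    (pitch ≈ 8 µm).  ``extent`` limits the bundle footprint; ``None`` covers
    the whole capture grid.
    """

    core_diameter: float = 3.0
    lattice_pitch: float = 8.0
    extent: float | None = None
    cladding_level: float = 0.0

    def __post_init__(self) -> None:
        if self.core_diameter <= 0:
            raise ValueError("core_diameter must be positive")
        if self.lattice_pitch < self.core_diameter:
            raise ValueError("lattice_pitch must be at least the core diameter")

    def core_centers(self, grid: SampledGrid) -> np.ndarray:
        """(N, 2) array of (x, y) hex-lattice core centres covering the grid."""
        half_h, half_w = (e / 2.0 for e in grid.extent)
        if self.extent is not None:
            half_h = min(half_h, self.extent / 2.0)
            half_w = min(half_w, self.extent / 2.0)
        row_step = self.lattice_pitch * np.sqrt(3.0) / 2.0
        core_r = self.core_diameter / 2.0
        centers = []
        j = 0
        y = -half_h + core_r
        while y <= half_h - core_r:
            x_off = (j % 2) * self.lattice_pitch / 2.0
            x = -half_w + core_r + x_off
            while x <= half_w - core_r:
                centers.append((x, y))
                x += self.lattice_pitch
            y += row_step
            j += 1
        return np.asarray(centers)


def fiber_bundle_transmit(capture: SpectralCapture, spec: FiberBundleSpec) -> SpectralCapture:
    """Intensity-only transmission through a coherent fiber bundle.

    Each fiber core integrates the intensity over its disk and re-emits it
    as a constant over the same disk at the proximal end (per-core flux is
    preserved); inter-core cladding is set to a fixed dark level.  The same
    lattice acts on all three channels, imprinting an identical honeycomb
    spatial-frequency signature at 1/lattice_pitch on each.
    """
    grid = capture.grid
    if grid.pixel_pitch > spec.core_diameter / 2.0:
        raise ValueError(
            f"grid pitch {grid.pixel_pitch} µm too coarse to resolve "
            f"{spec.core_diameter} µm cores (need ≤ core_diameter/2)"
        )
    centers = spec.core_centers(grid)
    if centers.size == 0:
        raise ValueError("bundle extent holds no cores inside the capture grid")
    x, y = grid.coordinates()
    pts = np.column_stack([np.broadcast_to(x, grid.shape).ravel(),
                           np.broadcast_to(y, grid.shape).ravel()])
    dist, idx = cKDTree(centers).query(pts, k=1)
    in_core = dist <= spec.core_diameter / 2.0
    core_id = np.where(in_core, idx, -1)

    n_cores = len(centers)
    counts = np.bincount(core_id[in_core], minlength=n_cores).astype(float)
    out = np.empty_like(capture.planes)
    for c, plane in enumerate(capture.planes):
        sums = np.bincount(core_id[in_core], weights=plane.ravel()[in_core],
                           minlength=n_cores)
        means = np.divide(sums, counts, out=np.zeros(n_cores), where=counts > 0)
        flat = np.full(pts.shape[0], spec.cladding_level)
        flat[in_core] = means[core_id[in_core]]
        out[c] = flat.reshape(grid.shape)
    log.info("fiber_bundle_transmit: %d cores, %.1f%% fill factor",
             n_cores, 100.0 * in_core.mean())
    return SpectralCapture(grid, out, capture.channels, capture.exposure_scale)
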