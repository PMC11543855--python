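"""Synthetic ground-truth phase targets.

Pure-phase phantoms carry a physical height map h(x, y) (µm) and a
refractive-index contrast δn against the surround; the optical phase at a
wavelength λ is ``φ = 2π·h·δn/λ``, so phase scales exactly as 1/λ for a
fixed phantom.  With no absorption the target is perfectly transparent at
focus (I ≡ 1).

Three families emulate the experimental targets of chromatic-defocus QPI:
a binary Siemens star resolution target, a Gaussian random phase screen
standing in for a commercial precision diffuser, and overlapping helical
ribbons mimicking filamentous algae (spirogyra-like strands).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage

from .optics_core import ComplexField, SampledGrid

__all__ = [
    "PhasePhantom",
    "DiffuserSpec",
    "siemens_star",
    "precision_diffuser",
    "filament_phantom",
    "talbot_onset",
]

#: Nominal design wavelength (µm): the green channel the solver works at.
NOMINAL_WAVELENGTH_UM = 0.530


@dataclass
class PhasePhantom:
    """Ground-truth target: height map (µm) plus index contrast δn."""

    grid: SampledGrid
    height: np.ndarray
    index_contrast: float
    absorption: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.height = np.asarray(self.height, dtype=float)
        if self.height.shape != self.grid.shape:
            raise ValueError("height map shape does not match grid")
        if np.any(self.height < 0):
            raise ValueError("height must be non-negative")
        if self.index_contrast <= 0:
            raise ValueError("index_contrast must be positive")
        if self.absorption is not None:
            self.absorption = np.asarray(self.absorption, dtype=float)
            if self.absorption.shape != self.grid.shape:
                raise ValueError("absorption map shape does not match grid")
            if np.any((self.absorption < 0) | (self.absorption > 1)):
                raise ValueError("absorption must lie in [0, 1]")

    def phase_at(self, wavelength: float) -> np.ndarray:
        """Optical phase (radians) at wavelength λ (µm): 2π·h·δn/λ."""
        if wavelength <= 0:
            raise ValueError("wavelength must be positive (µm)")
        return 2.0 * np.pi * self.height * self.index_contrast / wavelength

    def transmittance(self) -> np.ndarray:
        if self.absorption is None:
            return np.ones(self.grid.shape)
        return 1.0 - self.absorption

    def to_field(self, wavelength: float) -> ComplexField:
        """Exit field just after the phantom under unit plane-wave illumination."""
        return ComplexField.from_intensity_phase(
            self.grid, self.transmittance(), self.phase_at(wavelength), wavelength
        )

    # --- export: float TIFF height map + JSON sidecar -----------------------

    def save(self, path: str | Path) -> None:
        path = Path(path)
        tifffile.imwrite(path, self.height.astype(np.float32), photometric="minisblack")
        sidecar = {
            "index_contrast": self.index_contrast,
            "pixel_pitch_um": self.grid.pixel_pitch,
            **self.meta,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "PhasePhantom":
        path = Path(path)
        height = np.asarray(tifffile.imread(path), dtype=float)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        grid = SampledGrid(*height.shape, sidecar["pixel_pitch_um"])
        return cls(grid, height, sidecar["index_contrast"], meta=sidecar)


@dataclass(frozen=True)
class DiffuserSpec:
    """Statistics of a designer-disordered phase screen.

    ``feature_size`` is the 1/e autocorrelation width of the screen (µm);
    ``divergence_angle`` the 1/e half-width (degrees) of the far-field
    scattered beam for plane-wave illumination.
    """

    feature_size: float = 7.0
    divergence_angle: float = 5.0
    seed: int = 0
    index_contrast: float = 0.52

    def __post_init__(self) -> None:
        if self.feature_size <= 0:
            raise ValueError("feature_size must be positive")
        if not 0.0 < self.divergence_angle < 20.0:
            raise ValueError("divergence_angle must lie in (0°, 20°)")


def siemens_star(
    grid: SampledGrid,
    n_spokes: int = 36,
    height: float = 0.25,
    index_contrast: float = 0.52,
    radius: float | None = None,
) -> PhasePhantom:
    """Binary Siemens star: alternating raised/flat angular sectors.

    ``n_spokes`` must be even (equal spoke/gap sectors); the local spoke
    period at radius ρ is 2πρ/n_spokes, so spatial frequency grows toward
    the centre.  Defaults match a 250 nm tall star in glass (n = 1.52,
    δn = 0.52 in air).  Edges are hard (the ground truth is exactly binary).
    """
    if n_spokes % 2 != 0 or n_spokes < 4:
        raise ValueError("n_spokes must be even and at least 4")
    if height < 0:
        raise ValueError("height must be non-negative")
    x, y = grid.coordinates()
    theta = np.arctan2(y, x)
    sector = np.floor(theta / (2.0 * np.pi / n_spokes)).astype(int)
    spokes = (sector % 2 == 0).astype(float)
    if radius is None:
        radius = 0.45 * min(grid.extent)
    spokes[grid.radius() > radius] = 0.0
    return PhasePhantom(
        grid,
        height * spokes,
        index_contrast if height > 0 else max(index_contrast, 1e-6),
        meta={"generator": "siemens_star", "n_spokes": n_spokes,
              "height_um": height, "radius_um": radius},
    )


def spoke_masks(
    phantom: PhasePhantom, inner_radius: float, outer_radius: float, erode: int = 2
) -> tuple[np.ndarray, np.ndarray]:
    """Interior masks of spokes and gaps of a star phantom within an annulus.

    Masks are eroded ``erode`` pixels away from the binary edges so that
    plateau statistics exclude edge diffraction/discretization pixels.
    """
    r = phantom.grid.radius()
    annulus = (r >= inner_radius) & (r <= outer_radius)
    raised = phantom.height > 0.5 * phantom.height.max()
    if erode > 0:
        structure = np.ones((3, 3), dtype=bool)
        spoke = ndimage.binary_erosion(raised, structure, iterations=erode)
        gap = ndimage.binary_erosion(~raised, structure, iterations=erode)
    else:
        spoke, gap = raised, ~raised
    return spoke & annulus, gap & annulus


def precision_diffuser(
    spec: DiffuserSpec,
    grid: SampledGrid,
    nominal_wavelength: float = NOMINAL_WAVELENGTH_UM,
) -> PhasePhantom:
    """Gaussian random phase screen emulating a precision diffuser.

    A white-noise field is smoothed with a Gaussian kernel to a Gaussian
    autocorrelation of 1/e width ``feature_size`` and scaled so the RMS
    phase-gradient magnitude equals ``tan(divergence) * 2π/λ`` — the local
    tilt that gives the far-field scattered beam its stated 1/e half-width.
    Bitwise reproducible for a fixed seed.
    """
    if spec.feature_size < 2.0 * grid.pixel_pitch:
        raise ValueError(
            f"feature_size {spec.feature_size} µm under-resolved by pitch "
            f"{grid.pixel_pitch} µm (need ≥ 2 px)"
        )
    rng = np.random.default_rng(spec.seed)
    noise = rng.standard_normal(grid.shape)
    # Gaussian smoothing with σ_k gives ACF exp(-r²/(4σ_k²)); 1/e width = 2σ_k.
    sigma_px = 0.5 * spec.feature_size / grid.pixel_pitch
    screen = ndimage.gaussian_filter(noise, sigma_px, mode="wrap")
    screen -= screen.mean()

    gy, gx = np.gradient(screen, grid.pixel_pitch)
    rms_grad = np.sqrt(np.mean(gx**2 + gy**2))
    target_slope = np.tan(np.radians(spec.divergence_angle)) * 2.0 * np.pi / nominal_wavelength
    phase = screen * (target_slope / rms_grad) if rms_grad > 0 else screen

    height = phase * nominal_wavelength / (2.0 * np.pi * spec.index_contrast)
    height -= height.min()
    return PhasePhantom(
        grid,
        height,
        spec.index_contrast,
        meta={"generator": "precision_diffuser", "feature_size_um": spec.feature_size,
              "divergence_angle_deg": spec.divergence_angle, "seed": spec.seed},
    )


def filament_phantom(
    grid: SampledGrid,
    n_filaments: int = 3,
    diameter: float = 10.0,
    max_phase_range: float = 10.0 * np.pi,
    seed: int = 0,
    index_contrast: float = 0.14,
    nominal_wavelength: float = NOMINAL_WAVELENGTH_UM,
    helix_period: float = 60.0,
) -> PhasePhantom:
    """Overlapping smooth ribbons with helical height modulation.

    An idealization of filamentous algae: each strand is a straight ribbon
    of raised-cosine cross-section (``diameter`` wide, µm) whose height is
    modulated helically along its axis (``helix_period``, µm — the pitch
    of the chloroplast-band spiral); crossings add.  The raised-cosine
    profile tapers to zero slope at the strand boundary, as a turgid
    membrane-bounded cell does — no hard edges, so the phase gradient stays
    bounded by ≈ π·range/diameter.  The summed height map is rescaled so
    the peak-to-peak phase at the nominal wavelength equals
    ``max_phase_range`` (within discretization).
    """
    if n_filaments > 0 and diameter < 3.0 * grid.pixel_pitch:
        raise ValueError("filament diameter must span at least 3 pixels")
    height = np.zeros(grid.shape)
    if n_filaments > 0:
        rng = np.random.default_rng(seed)
        x, y = grid.coordinates()
        radius = diameter / 2.0
        for _ in range(n_filaments):
            angle = rng.uniform(0.0, np.pi)
            offset = rng.uniform(-0.3, 0.3) * min(grid.extent)
            phase0 = rng.uniform(0.0, 2.0 * np.pi)
            nx, ny = -np.sin(angle), np.cos(angle)  # ribbon normal
            dist = x * nx + y * ny - offset
            along = x * np.cos(angle) + y * np.sin(angle)
            inside = np.abs(dist) < radius
            profile = np.zeros(grid.shape)
            profile[inside] = np.cos(0.5 * np.pi * dist[inside] / radius) ** 2
            twist = 0.6 + 0.4 * np.cos(2.0 * np.pi * along / helix_period + phase0)
            height += profile * twist
        peak_to_peak = height.max() - height.min()
        target_height_range = max_phase_range * nominal_wavelength / (
            2.0 * np.pi * index_contrast
        )
        if peak_to_peak > 0:
            height *= target_height_range / peak_to_peak
        height -= height.min()
    return PhasePhantom(
        grid,
        height,
        index_contrast,
        meta={"generator": "filament_phantom", "n_filaments": n_filaments,
              "diameter_um": diameter, "max_phase_range_rad": max_phase_range,
              "seed": seed},
    )


def talbot_onset(feature_size: float, wavelength: float) -> float:
    """Defocus distance where caustics first form behind a periodic-ish screen.

    The Talbot-style estimate ``δz = 2p²/λ`` for nominal feature size p;
    all lengths in µm.
    """
    if feature_size <= 0 or wavelength <= 0:
        raise ValueError("feature_size and wavelength must be positive")
    return 2.0 * feature_size**2 / wavelength
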