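"""Scalar paraxial wave optics on sampled grids.

Field representation, Fresnel propagation (transfer-function and
impulse-response kernels), the hyperboloid metalens phase profile and its
chromatic focal law, the transport-of-intensity / transport-of-phase rate
evaluators, and digital refocusing.

Unit conventions: every length in this module is in micrometres (µm),
including wavelengths.  Phase is in radians.  Wavelengths expressed in
nanometres enter only at the sensor/configuration layer and are converted
there (:func:`chromatie.sensor_model` and :mod:`chromatie.cli_io`).

Sign conventions: forward propagation carries ``exp(+ikz)`` and positive z
runs toward the detector; a converging lens multiplies the field by
``exp(-i*phi(r))`` with ``phi(r)`` from :func:`hyperboloid_phase`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SampledGrid",
    "ComplexField",
    "OpticalTrain",
    "DefocusKernel",
    "hyperboloid_phase",
    "focal_at_wavelength",
    "chromatic_focal_shift",
    "fresnel_propagate",
    "tie_rhs",
    "tpe_rhs",
    "refocus_stack",
]

log = logging.getLogger(__name__)


class AliasingWarning(UserWarning):
    """Raised when a forced Fresnel kernel violates its sampling bound."""


@dataclass(frozen=True)
class SampledGrid:
    """Pixel-centred sampling lattice.

    The origin sits at the array centre (pixel ``n // 2``); x increases with
    column index and y with row index.  ``pixel_pitch`` is in µm.
    """

    n_rows: int
    n_cols: int
    pixel_pitch: float

    def __post_init__(self) -> None:
        if self.pixel_pitch <= 0:
            raise ValueError("pixel_pitch must be positive")
        if self.n_rows < 8 or self.n_cols < 8:
            raise ValueError("grid must be at least 8x8")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def extent(self) -> tuple[float, float]:
        """Physical (height, width) of the field of view in µm."""
        return (self.n_rows * self.pixel_pitch, self.n_cols * self.pixel_pitch)

    def coordinates(self) -> tuple[np.ndarray, np.ndarray]:
        """Return broadcastable (x, y) coordinate arrays in µm."""
        x = (np.arange(self.n_cols) - self.n_cols // 2) * self.pixel_pitch
        y = (np.arange(self.n_rows) - self.n_rows // 2) * self.pixel_pitch
        return x[None, :], y[:, None]

    def radius(self) -> np.ndarray:
        x, y = self.coordinates()
        return np.hypot(x, y)

    def angular_frequencies(self) -> tuple[np.ndarray, np.ndarray]:
        """Angular spatial frequencies (kx, ky) in rad/µm, FFT layout."""
        kx = 2.0 * np.pi * np.fft.fftfreq(self.n_cols, d=self.pixel_pitch)
        ky = 2.0 * np.pi * np.fft.fftfreq(self.n_rows, d=self.pixel_pitch)
        return kx[None, :], ky[:, None]

    def k_squared(self) -> np.ndarray:
        kx, ky = self.angular_frequencies()
        return kx**2 + ky**2


@dataclass
class ComplexField:
    """Sampled scalar electric field ``E = sqrt(I) * exp(i*phi)``.

    ``wavelength`` is in µm.  ``amplitude`` is a complex array over ``grid``.
    """

    grid: SampledGrid
    amplitude: np.ndarray
    wavelength: float

    def __post_init__(self) -> None:
        self.amplitude = np.asarray(self.amplitude, dtype=complex)
        if self.amplitude.shape != self.grid.shape:
            raise ValueError(
                f"amplitude shape {self.amplitude.shape} does not match grid {self.grid.shape}"
            )
        if self.wavelength <= 0:
            raise ValueError("wavelength must be positive (µm)")
        if not np.all(np.isfinite(self.amplitude)):
            raise ValueError("field amplitude contains non-finite values")

    @classmethod
    def from_intensity_phase(
        cls, grid: SampledGrid, intensity: np.ndarray, phase: np.ndarray, wavelength: float
    ) -> "ComplexField":
        intensity = np.asarray(intensity, dtype=float)
        if np.any(intensity < 0):
            raise ValueError("intensity must be non-negative")
        return cls(grid, np.sqrt(intensity) * np.exp(1j * np.asarray(phase)), wavelength)

    @property
    def wavenumber(self) -> float:
        """k = 2π/λ in rad/µm."""
        return 2.0 * np.pi / self.wavelength

    def intensity(self) -> np.ndarray:
        return np.abs(self.amplitude) ** 2

    def phase(self) -> np.ndarray:
        return np.angle(self.amplitude)


@dataclass(frozen=True)
class OpticalTrain:
    """Thin-lens imaging geometry of the metalens train.

    All lengths in µm except ``design_wavelength`` which is in nm (it names
    the spectral channel the focal length is quoted at).  The conjugates must
    satisfy 1/z_o + 1/z_i = 1/f.
    """

    aperture_radius: float
    focal_length: float
    design_wavelength: float
    object_distance: float
    image_distance: float

    def __post_init__(self) -> None:
        for name in ("aperture_radius", "focal_length", "design_wavelength",
                     "object_distance", "image_distance"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        lhs = 1.0 / self.object_distance + 1.0 / self.image_distance
        rhs = 1.0 / self.focal_length
        if abs(lhs - rhs) > 1e-9 * rhs:
            raise ValueError(
                "conjugates violate thin-lens equation: "
                f"1/{self.object_distance} + 1/{self.image_distance} != 1/{self.focal_length}"
            )
        if not 0.0 < self.numerical_aperture < 1.0:
            raise ValueError("paraxial NA must lie in (0, 1)")

    @classmethod
    def two_f(
        cls,
        focal_length: float,
        aperture_radius: float,
        design_wavelength: float = 530.0,
    ) -> "OpticalTrain":
        """Unit-magnification 2f–2f configuration (object and image at 2f)."""
        return cls(
            aperture_radius=aperture_radius,
            focal_length=focal_length,
            design_wavelength=design_wavelength,
            object_distance=2.0 * focal_length,
            image_distance=2.0 * focal_length,
        )

    @property
    def magnification(self) -> float:
        return self.image_distance / self.object_distance

    @property
    def numerical_aperture(self) -> float:
        return self.aperture_radius / self.focal_length


@dataclass(frozen=True)
class DefocusKernel:
    """Fresnel defocus kernel h_z for a (distance, wavelength) pair, µm.

    ``propagation_distance`` is signed; zero means the identity kernel.
    The continuous kernel is ``exp(ikz)/(iλz) * exp(iπ(x²+y²)/(λz))`` whose
    transfer function is ``exp(ikz) * exp(-iπλz(fx²+fy²))``.
    """

    propagation_distance: float
    wavelength: float

    def __post_init__(self) -> None:
        if self.wavelength <= 0:
            raise ValueError("wavelength must be positive (µm)")

    @property
    def zeta(self) -> float:
        """The combined variable ζ = λ·z (µm²) the diffraction pattern depends on."""
        return self.wavelength * self.propagation_distance

    def transfer_function(self, grid: SampledGrid) -> np.ndarray:
        k2 = grid.k_squared()
        z, lam = self.propagation_distance, self.wavelength
        # exp(-i π λ z f²) with k = 2π f  →  exp(-i λ z k² / 4π)
        return np.exp(1j * 2.0 * np.pi * z / lam) * np.exp(-1j * lam * z * k2 / (4.0 * np.pi))

    def impulse_response(self, grid: SampledGrid) -> np.ndarray:
        z, lam = self.propagation_distance, self.wavelength
        if z == 0.0:
            raise ValueError("impulse response is undefined at z = 0 (identity)")
        x, y = grid.coordinates()
        r2 = x**2 + y**2
        k = 2.0 * np.pi / lam
        h = np.exp(1j * k * z) / (1j * lam * z) * np.exp(1j * np.pi * r2 / (lam * z))
        return h * grid.pixel_pitch**2  # quadrature weight for the convolution


def hyperboloid_phase(grid: SampledGrid, focal_length: float, wavelength: float) -> np.ndarray:
    """Exact hyperboloid metalens phase profile, radians over the grid.

    ``phi(r) = (2π/λ) (sqrt(r² + f²) − f)``, evaluated pointwise with no
    paraxial expansion.  ``phi(0) = 0`` and the profile grows with r; a
    focusing lens applies ``exp(-i*phi(r))`` to an incoming plane wave.

    Parameters are in µm.
    """
    if focal_length <= 0 or wavelength <= 0:
        raise ValueError("focal_length and wavelength must be positive")
    r = grid.radius()
    return (2.0 * np.pi / wavelength) * (np.hypot(r, focal_length) - focal_length)


def focal_at_wavelength(f_ref: float, lambda_ref: float, lam: float) -> float:
    """Chromatic focal length of the hyperboloid metalens: λ·f is conserved.

    The lens behaves as a longitudinal grating with linear chromatic
    dispersion δf/f = −δλ/λ, i.e. ``f(λ) = λ_ref · f_ref / λ``.  The two
    wavelengths may be in any one unit (nm or µm) as long as they agree;
    the result carries the unit of ``f_ref``.
    """
    if f_ref <= 0 or lambda_ref <= 0 or lam <= 0:
        raise ValueError("focal length and wavelengths must be positive")
    return lambda_ref * f_ref / lam


def chromatic_focal_shift(f_ref: float, lambda_ref: float, delta_lambda: float) -> float:
    """Linearized chromatic focal shift |δf| = f·δλ/λ of the metalens.

    This is the differential form ``λ δf = −f δλ`` of the focal law,
    evaluated at the reference wavelength; the returned magnitude is the
    focal-plane separation between channels spaced ``delta_lambda`` apart.
    """
    if f_ref <= 0 or lambda_ref <= 0:
        raise ValueError("focal length and wavelength must be positive")
    return f_ref * abs(delta_lambda) / lambda_ref


def _transfer_bound(grid: SampledGrid) -> float:
    """Largest alias-safe |λz| for the transfer-function kernel, µm²."""
    return min(grid.n_rows, grid.n_cols) * grid.pixel_pitch**2


def _mirror_pad(amplitude: np.ndarray) -> np.ndarray:
    n, m = amplitude.shape
    return np.pad(amplitude, ((n // 2, n - n // 2), (m // 2, m - m // 2)), mode="symmetric")


def fresnel_propagate(
    field: ComplexField,
    distance: float,
    kernel: str = "auto",
    pad: bool = True,
) -> ComplexField:
    """Propagate a field by a signed distance (µm) under the Fresnel model.

    ``kernel='auto'`` selects the transfer-function (frequency-domain chirp)
    path while the anti-aliasing bound ``λ|z| ≤ N·pitch²`` holds and the
    spatial impulse-response kernel beyond it; forcing a kernel outside its
    sampling bound emits :class:`AliasingWarning` with the violated bound.

    ``pad=True`` mirror-pads the field by a factor of two before the FFT to
    suppress periodic wraparound, then crops.  Energy conservation and the
    exact z → −z inverse hold on the unpadded (periodic) path.
    """
    if distance == 0.0:
        return ComplexField(field.grid, field.amplitude.copy(), field.wavelength)

    amp = _mirror_pad(field.amplitude) if pad else field.amplitude
    work_grid = SampledGrid(*amp.shape, field.grid.pixel_pitch)
    dk = DefocusKernel(distance, field.wavelength)

    bound = _transfer_bound(work_grid)
    zeta = abs(dk.zeta)
    if kernel == "auto":
        kernel = "transfer" if zeta <= bound else "impulse"
    elif kernel == "transfer" and zeta > bound:
        warnings.warn(
            f"transfer-function kernel aliased: λ|z| = {zeta:.1f} µm² exceeds "
            f"N·pitch² = {bound:.1f} µm²",
            AliasingWarning,
            stacklevel=2,
        )
    elif kernel == "impulse" and zeta < bound:
        warnings.warn(
            f"impulse-response kernel under-sampled: λ|z| = {zeta:.1f} µm² is below "
            f"N·pitch² = {bound:.1f} µm²",
            AliasingWarning,
            stacklevel=2,
        )

    if kernel == "transfer":
        out = np.fft.ifft2(np.fft.fft2(amp) * dk.transfer_function(work_grid))
    elif kernel == "impulse":
        out = _convolve_linear(amp, np.fft.ifftshift(dk.impulse_response(work_grid)))
    else:
        raise ValueError(f"unknown kernel {kernel!r}")

    if pad:
        n, m = field.grid.shape
        out = out[n // 2 : n // 2 + n, m // 2 : m // 2 + m]
    return ComplexField(field.grid, out, field.wavelength)


def _convolve_linear(amp: np.ndarray, kernel_centered: np.ndarray) -> np.ndarray:
    """Linear (zero-padded) 2D convolution of equal-shape arrays via FFT."""
    n, m = amp.shape
    shape = (2 * n, 2 * m)
    fa = np.fft.fft2(amp, s=shape)
    fk = np.fft.fft2(np.fft.fftshift(kernel_centered), s=shape)
    full = np.fft.ifft2(fa * fk)
    return full[n // 2 : n // 2 + n, m // 2 : m // 2 + m]


def _gradients(arr: np.ndarray, pitch: float) -> tuple[np.ndarray, np.ndarray]:
    """(d/dx, d/dy): second-order central differences, one-sided at edges."""
    gy, gx = np.gradient(arr, pitch)
    return gx, gy


def tie_rhs(
    intensity: np.ndarray,
    phase: np.ndarray,
    wavelength: float,
    pixel_pitch: float,
) -> np.ndarray:
    """Transport-of-intensity rate dI/dz = −(λ/2π) ∇·(I∇φ), per µm.

    ``intensity`` and ``phase`` are maps on a shared grid; ``wavelength``
    and ``pixel_pitch`` in µm.  Gradients and divergence are second-order
    central differences.
    """
    intensity = np.asarray(intensity, dtype=float)
    phase = np.asarray(phase, dtype=float)
    if intensity.shape != phase.shape:
        raise ValueError(f"shape mismatch: intensity {intensity.shape} vs phase {phase.shape}")
    if np.any(intensity < 0):
        raise ValueError("intensity must be non-negative")
    gx, gy = _gradients(phase, pixel_pitch)
    fx, fy = intensity * gx, intensity * gy
    div = _gradients(fx, pixel_pitch)[0] + _gradients(fy, pixel_pitch)[1]
    return -(wavelength / (2.0 * np.pi)) * div


def tpe_rhs(
    intensity: np.ndarray,
    phase: np.ndarray,
    wavelength: float,
    pixel_pitch: float,
    intensity_floor: float = 1e-6,
) -> np.ndarray:
    """Transport-of-phase rate dφ/dz, radians per µm.

    The axial phase evolution is the imaginary part of the paraxial wave
    equation for ``sqrt(I) e^{iφ}``:

        dφ/dz = (λ/4π) [ −|∇φ|² + ∇²I/(2I) − |∇I|²/(4I²) ]

    (the bracket is twice ``∇²√I/√I − |∇φ|²`` rewritten in I).  Intensity is
    clamped at ``intensity_floor`` before division; the number of clamped
    pixels is logged.
    """
    intensity = np.asarray(intensity, dtype=float)
    phase = np.asarray(phase, dtype=float)
    if intensity.shape != phase.shape:
        raise ValueError(f"shape mismatch: intensity {intensity.shape} vs phase {phase.shape}")
    clamped = int(np.count_nonzero(intensity < intensity_floor))
    if clamped:
        log.info("tpe_rhs: clamped %d pixels at intensity floor %g", clamped, intensity_floor)
    I = np.maximum(intensity, intensity_floor)

    px, py = _gradients(phase, pixel_pitch)
    ix, iy = _gradients(I, pixel_pitch)
    lap_i = _gradients(ix, pixel_pitch)[0] + _gradients(iy, pixel_pitch)[1]
    bracket = -(px**2 + py**2) + lap_i / (2.0 * I) - (ix**2 + iy**2) / (4.0 * I**2)
    return (wavelength / (4.0 * np.pi)) * bracket


def refocus_stack(
    field: ComplexField,
    targets: list[tuple[float, float]],
    pad: bool = True,
) -> list[np.ndarray]:
    """Digitally refocus a retrieved field to a list of (λ, z) targets.

    Each target propagates the same complex amplitude with the Fresnel
    kernel at that wavelength/distance (both µm) and records the intensity.
    Because the kernel chirp depends only on ζ = λ·z, two targets with equal
    products yield identical intensity patterns — the hyperspectral
    extrapolation underpinning spectral/defocus equivalence.
    """
    out = []
    for lam, z in targets:
        if lam <= 0:
            raise ValueError("target wavelength must be positive")
        probe = ComplexField(field.grid, field.amplitude, lam)
        out.append(fresnel_propagate(probe, z, pad=pad).intensity())
    return out
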