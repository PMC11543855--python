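"""The inverse problem: quantitative phase from a single chromatic capture.

The spectral intensity derivative dI/dλ across the RGB channels is the
through-focus derivative dI/dz in disguise (the chromatic focal law makes
ζ = λ·z the propagation variable, so λ dz = −z dλ).  The solver estimates
the derivative from two or three channels, inverts the transport-of-
intensity equation by a double FFT-Poisson solution with Tikhonov
regularization (Helmholtz decomposition I∇φ = ∇ψ), refines the phase
iteratively against the full Fresnel forward model, and converts phase to
physical height.

The recovered phase is mean-zero (the zero-frequency mode is unobservable
in a differential measurement — the gauge choice) and unwrapped by
construction: the Poisson integrations never constrain φ to [0, 2π].

A pleasant cancellation makes the method work for dispersionless height
objects: the phase scales as 1/λ while the TIE rate carries a factor λ, so
the finite-difference (I_R − I_G)/Δz estimates −(λ_G/2π)∇·(I∇φ_G) with no
chromatic bias to first order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .optics_core import ComplexField, SampledGrid, fresnel_propagate
from .sensor_model import ChannelSpec, SpectralCapture

__all__ = [
    "SolverParams",
    "DerivativeEstimate",
    "RetrievalResult",
    "spectral_to_defocus",
    "estimate_dI",
    "poisson_solve",
    "tie_invert",
    "iterative_refine",
    "phase_to_height",
    "calibrate_channel_defocus",
]

log = logging.getLogger(__name__)

DERIVATIVE_MODES = ("two_channel_RG", "two_channel_GB", "three_channel")


@dataclass(frozen=True)
class SolverParams:
    """Tunables of the spectral TIE solver.

    ``epsilon`` / ``epsilon_prime`` (µm⁻², units of k²) regularize the two
    Poisson inversions; ``None`` resolves to four times the fundamental
    mode's k² for the capture grid, i.e. ``4·(2π/(N·pitch))²`` — calibrated
    once on the star target and then held constant between calibration and
    measurement.  ``intensity_floor`` guards the ∇ψ/I division (relative to
    unit background).  ``rescale_channels`` enables an optional per-channel
    affine magnification compensation (off by default; single-lens trains
    magnify each color slightly differently).

    ``ctf_wiener`` stabilizes the iterative refinement at high spatial
    frequencies: the plain TIE linearization is only valid while the
    defocus contrast-transfer argument γ = λ|z|k²/4π is small, and the
    transfer oscillates and changes sign past γ = π.  Updates are weighted
    by the regularized inverse T/(T² + α) of the linearized spectral
    transfer T(k) (see the refinement routine), with α = ``ctf_wiener``;
    ``None`` disables the correction (plain TIE updates at all k).

    ``channel_linewidth_nm`` is the 1-σ spectral width of each color
    channel (source × Bayer product; ≈27 nm for the packaged curves).  A
    finite linewidth smears each channel's defocus over the chromatic
    focal law, multiplying its transfer by the coherence envelope
    exp(−(γ·σ_λ/|λ_c−λ_G|)²/2): beyond the coherence-limited band the data
    carry no phase contrast, and the gain damps instead of amplifying
    model noise.  ``None`` assumes fully coherent (monochromatic) channels.
    """

    epsilon: float | None = None
    epsilon_prime: float | None = None
    max_iterations: int = 10
    relative_tolerance: float = 1e-3
    derivative_mode: str = "two_channel_RG"
    intensity_floor: float = 0.05
    central_plane: str = "G"
    rescale_channels: dict[str, float] | None = None
    ctf_wiener: float | None = 0.05
    channel_linewidth_nm: float | None = 27.0

    def __post_init__(self) -> None:
        if self.epsilon is not None and self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.epsilon_prime is not None and self.epsilon_prime <= 0:
            raise ValueError("epsilon_prime must be positive")
        if not 0.0 < self.intensity_floor < 0.5:
            raise ValueError("intensity_floor must lie in (0, 0.5)")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be at least 1")
        if self.derivative_mode not in DERIVATIVE_MODES:
            raise ValueError(f"derivative_mode must be one of {DERIVATIVE_MODES}")

    def resolved(self, grid: SampledGrid) -> "SolverParams":
        """Fill in grid-dependent regularizer defaults."""
        k_fund_sq = (2.0 * np.pi / (min(grid.n_rows, grid.n_cols) * grid.pixel_pitch)) ** 2
        eps = self.epsilon if self.epsilon is not None else 4.0 * k_fund_sq
        eps_p = self.epsilon_prime if self.epsilon_prime is not None else 4.0 * k_fund_sq
        return replace(self, epsilon=eps, epsilon_prime=eps_p)


@dataclass
class DerivativeEstimate:
    """Spectral intensity derivative with its defocus equivalence.

    ``d_intensity_d_lambda`` is per nm; ``equivalent_dz`` (µm) is the
    defocus change corresponding to the spectral spacing ``d_lambda`` (nm),
    so the through-focus rate is ``dI/dz = dI/dλ · d_lambda / equivalent_dz``.
    """

    d_intensity_d_lambda: np.ndarray
    equivalent_dz: float
    d_lambda: float
    central_intensity: np.ndarray
    central_wavelength: float  # nm

    def __post_init__(self) -> None:
        if self.equivalent_dz == 0.0:
            raise ValueError("equivalent_dz must be non-zero")

    def d_intensity_d_z(self) -> np.ndarray:
        return self.d_intensity_d_lambda * (self.d_lambda / self.equivalent_dz)


@dataclass
class RetrievalResult:
    """Recovered phase (radians, mean-zero, unwrapped), height (µm), diagnostics."""

    phase: np.ndarray
    height: np.ndarray
    residual_history: list[float]
    iterations_used: int
    converged: bool
    params: SolverParams

    @property
    def monotone(self) -> bool:
        """Whether the residual history is non-increasing after iteration 1."""
        h = self.residual_history
        return all(b <= a * (1.0 + 1e-12) for a, b in zip(h[1:], h[2:]))


def spectral_to_defocus(
    channels: tuple[ChannelSpec, ...],
    nominal_z: float,
    nominal_lambda: float,
) -> dict[str, float]:
    """Per-channel focus shift implied by the chromatic law λ dz = −z dλ.

    Returns ``dz_i = −nominal_z (λ_i − nominal_λ)/nominal_λ`` — the shift of
    the channel's focus along z (red focuses earlier, so its shift is
    negative).  Note the sign convention differs from
    :class:`~chromatie.sensor_model.ChannelSpec.equivalent_defocus`, which
    is the offset of the fixed sensor plane from the channel's focus (the
    negative of the focus shift, scaled to the image conjugate).
    ``nominal_z`` in µm, wavelengths in nm.
    """
    if nominal_z <= 0 or nominal_lambda <= 0:
        raise ValueError("nominal_z and nominal_lambda must be positive")
    return {
        c.name: -nominal_z * (c.center_wavelength - nominal_lambda) / nominal_lambda
        for c in channels
    }


def _maybe_rescale(plane: np.ndarray, factor: float | None) -> np.ndarray:
    """Optional per-channel affine magnification compensation about the centre."""
    if factor is None or factor == 1.0:
        return plane
    zoomed = ndimage.zoom(plane, factor, order=1, mode="nearest")
    h, w = plane.shape
    zh, zw = zoomed.shape
    if zh >= h:
        top, left = (zh - h) // 2, (zw - w) // 2
        return zoomed[top : top + h, left : left + w]
    pad_h, pad_w = h - zh, w - zw
    return np.pad(
        zoomed,
        ((pad_h // 2, pad_h - pad_h // 2), (pad_w // 2, pad_w - pad_w // 2)),
        mode="edge",
    )


def estimate_dI(capture: SpectralCapture, params: SolverParams) -> DerivativeEstimate:
    """Estimate dI/dλ from the capture's channels.

    Two-channel modes take the plain finite difference over the pair (the
    central plane is the shorter-wavelength member — green for RG).  The
    three-channel mode fits a per-pixel weighted least-squares slope of I
    against λ over the unequally spaced wavelengths, with inverse-spacing
    weights; for planes exactly linear in λ the fit returns the slope to
    machine precision.  The central plane/wavelength is green either way.
    """
    planes = {c.name: p for c, p in zip(capture.channels, capture.planes)}
    lam = {c.name: c.center_wavelength for c in capture.channels}
    dz = {c.name: c.equivalent_defocus for c in capture.channels}
    if params.rescale_channels:
        planes = {
            n: _maybe_rescale(p, params.rescale_channels.get(n)) for n, p in planes.items()
        }

    central = params.central_plane
    if central == "mean":
        central_intensity = np.mean(list(planes.values()), axis=0)
        central_wavelength = lam["G"]
    else:
        central_intensity = planes[central]
        central_wavelength = lam[central]

    if params.derivative_mode.startswith("two_channel"):
        a, b = params.derivative_mode[-2], params.derivative_mode[-1]  # e.g. "R","G"
        d_lambda = lam[a] - lam[b]
        if d_lambda == 0.0:
            raise ValueError("degenerate derivative: identical channel wavelengths")
        didl = (planes[a] - planes[b]) / d_lambda
        equivalent_dz = dz[a] - dz[b]
    else:
        lams = np.array([lam[n] for n in ("R", "G", "B")])
        zs = np.array([dz[n] for n in ("R", "G", "B")])
        stack = np.stack([planes[n] for n in ("R", "G", "B")])
        # inverse-spacing weights for the unequal δλ
        w = np.array(
            [1.0 / abs(lams[0] - lams[1]), 1.0, 1.0 / abs(lams[1] - lams[2])]
        )
        w[1] = 0.5 * (w[0] + w[2])
        lbar = np.sum(w * lams) / np.sum(w)
        denom = np.sum(w * (lams - lbar) ** 2)
        didl = np.tensordot(w * (lams - lbar), stack, axes=(0, 0)) / denom
        # matching linearization of the λ → defocus mapping
        dz_slope = np.sum(w * (lams - lbar) * zs) / denom
        d_lambda = lams[0] - lams[2]
        equivalent_dz = dz_slope * d_lambda

    return DerivativeEstimate(
        d_intensity_d_lambda=didl,
        equivalent_dz=equivalent_dz,
        d_lambda=d_lambda,
        central_intensity=central_intensity,
        central_wavelength=central_wavelength,
    )


def poisson_solve(source: np.ndarray, regularizer: float, pixel_pitch: float) -> np.ndarray:
    """Solve ∇²ψ = source spectrally with a Tikhonov-regularized eigenvalue.

    The Laplacian Fourier-transforms to −(kx² + ky²); division uses the
    regularized eigenvalue −(k² + ε), attenuating mode k by k²/(k² + ε).
    The source mean (the unobservable zero mode) is subtracted first and
    logged; the returned potential is mean-zero.
    """
    source = np.asarray(source, dtype=float)
    grid = SampledGrid(*source.shape, pixel_pitch)
    mean = source.mean()
    if abs(mean) > 0:
        log.debug("poisson_solve: subtracting source mean %.3g", mean)
    s_hat = np.fft.fft2(source - mean)
    psi_hat = -s_hat / (grid.k_squared() + regularizer)
    psi_hat[0, 0] = 0.0
    return np.real(np.fft.ifft2(psi_hat))


def _spectral_gradient(arr: np.ndarray, grid: SampledGrid) -> tuple[np.ndarray, np.ndarray]:
    kx, ky = grid.angular_frequencies()
    a_hat = np.fft.fft2(arr)
    gx = np.real(np.fft.ifft2(1j * kx * a_hat))
    gy = np.real(np.fft.ifft2(1j * ky * a_hat))
    return gx, gy


def _spectral_divergence(fx: np.ndarray, fy: np.ndarray, grid: SampledGrid) -> np.ndarray:
    kx, ky = grid.angular_frequencies()
    return np.real(np.fft.ifft2(1j * kx * np.fft.fft2(fx) + 1j * ky * np.fft.fft2(fy)))


def tie_invert(
    deriv: DerivativeEstimate,
    params: SolverParams,
    pixel_pitch: float,
) -> np.ndarray:
    """Invert the TIE for phase by the double Poisson solution.

    Stage 1 substitutes I∇φ = ∇ψ (Helmholtz decomposition), turning the TIE
    into ∇²ψ = −(2π/λ)·dI/dz, solved spectrally with ε.  Stage 2 recovers
    φ from ∇²φ = ∇·(∇ψ/I) with ε′, flooring I.  Derivatives inside the
    stage-2 right-hand side are spectral, consistent with the Fourier
    solver.  The returned phase is mean-zero and unwrapped by construction.
    """
    params = params.resolved(SampledGrid(*deriv.central_intensity.shape, pixel_pitch))
    grid = SampledGrid(*deriv.central_intensity.shape, pixel_pitch)
    didz = deriv.d_intensity_d_z()
    if not np.any(didz):
        log.info("tie_invert: all-zero derivative, returning zero phase")
        return np.zeros(grid.shape)
    lam_um = deriv.central_wavelength * 1e-3
    source = -(2.0 * np.pi / lam_um) * didz
    psi = poisson_solve(source, params.epsilon, pixel_pitch)

    gx, gy = _spectral_gradient(psi, grid)
    intensity = np.maximum(deriv.central_intensity, params.intensity_floor)
    rhs = _spectral_divergence(gx / intensity, gy / intensity, grid)
    phi = poisson_solve(rhs, params.epsilon_prime, pixel_pitch)
    return phi - phi.mean()


def _derivative_coefficients(
    capture: SpectralCapture, params: SolverParams
) -> dict[str, float]:
    """Per-channel weights a_c of the linear derivative estimate Σ a_c I_c."""
    lam = {c.name: c.center_wavelength for c in capture.channels}
    if params.derivative_mode.startswith("two_channel"):
        a, b = params.derivative_mode[-2], params.derivative_mode[-1]
        d_lambda = lam[a] - lam[b]
        return {a: 1.0 / d_lambda, b: -1.0 / d_lambda}
    lams = np.array([lam[n] for n in ("R", "G", "B")])
    w = np.array([1.0 / abs(lams[0] - lams[1]), 1.0, 1.0 / abs(lams[1] - lams[2])])
    w[1] = 0.5 * (w[0] + w[2])
    lbar = np.sum(w * lams) / np.sum(w)
    denom = np.sum(w * (lams - lbar) ** 2)
    coeff = w * (lams - lbar) / denom
    return dict(zip(("R", "G", "B"), coeff))


def _ctf_update_gain(
    capture: SpectralCapture,
    deriv: DerivativeEstimate,
    params: SolverParams,
) -> np.ndarray | None:
    """Wiener-style spectral gain correcting the defocus contrast transfer.

    For a weak 1/λ-dispersive phase object, the spectral derivative
    estimate maps a phase mode φ̂(k) to T(k)·φ̂(k) after the TIE inversion,
    where

        T(k) = (4π/(λ_G k²)) · (dλ/Δz) · Σ_c a_c · sin(γ_c) · λ_G / λ_c,
        γ_c = λ_c z_c k² / 4π,

    with a_c the channel weights of the derivative.  The TIE linearization
    assumes T ≈ 1; past the first transfer lobe T oscillates and changes
    sign, so refinement updates are weighted by T/(T² + α) — the regularized
    inverse of the linearized transfer, sign-correct in every lobe and
    bounded at the transfer zeros (α = ``ctf_wiener``).  Updates then
    converge across the full spatial-frequency band instead of only where
    the plain TIE is valid.
    """
    alpha = params.ctf_wiener
    if alpha is None:
        return None
    grid = capture.grid
    k2 = grid.k_squared()
    coeffs = _derivative_coefficients(capture, params)
    lam_g = deriv.central_wavelength
    total = np.zeros(grid.shape)
    for c in capture.channels:
        if c.name not in coeffs:
            continue
        gamma = c.wavelength_um * c.equivalent_defocus * k2 / (4.0 * np.pi)
        term = np.sin(gamma)
        d_lam = abs(c.center_wavelength - lam_g)
        if params.channel_linewidth_nm is not None and d_lam > 0:
            # finite channel linewidth smears γ via the chromatic focal law
            sigma_gamma = gamma * params.channel_linewidth_nm / d_lam
            term = term * np.exp(-0.5 * sigma_gamma**2)
        total += coeffs[c.name] * term * lam_g / c.center_wavelength
    lam_g_um = lam_g * 1e-3
    with np.errstate(divide="ignore", invalid="ignore"):
        T = (4.0 * np.pi / (lam_g_um * k2)) * (
            deriv.d_lambda / deriv.equivalent_dz
        ) * total
    T[0, 0] = 1.0  # zero mode is gauge-fixed elsewhere
    gain = T / (T**2 + alpha)
    # where the transfer is negligible the data carry no phase information:
    # freeze those modes instead of pumping model noise into them
    gain[np.abs(T) < 0.1] = 0.0
    return gain


def _predict_planes(
    phase: np.ndarray,
    capture: SpectralCapture,
    central_intensity: np.ndarray,
    central_wavelength: float,
    pad: bool = True,
) -> np.ndarray:
    """Forward-model the channel intensities from a candidate phase.

    The focal-plane field takes the central (green) measured intensity as
    amplitude and rescales the phase to each channel's wavelength (a height
    object's phase goes as 1/λ) before Fresnel propagation to the channel's
    equivalent defocus.  The prediction is monochromatic at each channel's
    effective wavelength, as in the spectral TIE treatment; the gain
    shaping in the refinement accounts for the channel linewidth instead.
    """
    amp = np.sqrt(np.clip(central_intensity, 0.0, None))
    planes = []
    for spec in capture.channels:
        scale = central_wavelength / spec.center_wavelength
        f = ComplexField(capture.grid, amp * np.exp(1j * phase * scale), spec.wavelength_um)
        planes.append(fresnel_propagate(f, spec.equivalent_defocus, pad=pad).intensity())
    return np.stack(planes)


def iterative_refine(
    capture: SpectralCapture,
    params: SolverParams | None = None,
    index_contrast: float = 0.52,
) -> RetrievalResult:
    """Full spectral-TIE retrieval with iterative residual refinement.

    Each iteration forward-propagates the current field to every channel's
    equivalent defocus, forms the residual between measured and predicted
    intensities, re-estimates the residual derivative, and adds its TIE
    inversion to the phase.  Iteration stops at ``relative_tolerance`` on
    the residual-derivative norm, at ``max_iterations``, or when the
    residual grows twice in a row (divergence guard: the best iterate is
    returned and the result flagged non-converged).

    The first pass (zero phase) reproduces the plain linear TIE estimate;
    subsequent passes remove the linearization bias, recover the
    low frequencies attenuated by the regularizers, and accumulate large
    (multi-2π) phase ranges without wrapping.
    """
    params = (params or SolverParams()).resolved(capture.grid)
    pitch = capture.grid.pixel_pitch

    deriv0 = estimate_dI(capture, params)
    gain = _ctf_update_gain(capture, deriv0, params)

    def shaped(update: np.ndarray) -> np.ndarray:
        if gain is None:
            return update
        return np.real(np.fft.ifft2(np.fft.fft2(update) * gain))

    denom = float(np.linalg.norm(deriv0.d_intensity_d_lambda))
    if denom == 0.0:
        log.info("iterative_refine: uniform capture, zero phase")
        zero = np.zeros(capture.grid.shape)
        return RetrievalResult(zero, zero.copy(), [0.0], 0, True, params)

    phase = np.zeros(capture.grid.shape)
    best_phase, best_res = phase, np.inf
    history: list[float] = []
    grew = 0
    iterations = 0
    converged = False
    for iterations in range(1, params.max_iterations + 1):
        predicted = _predict_planes(
            phase, capture, deriv0.central_intensity, deriv0.central_wavelength
        )
        residual = capture.planes - predicted
        # a channel-constant offset keeps the planes non-negative without
        # touching the derivative (channel differences are offset-invariant)
        offset = 1.0 + max(0.0, -float(residual.min()))
        residual_capture = SpectralCapture(
            capture.grid, residual + offset, capture.channels
        )
        deriv_r = estimate_dI(residual_capture, params)
        # the +1 offset is constant across channels and cancels in the difference
        deriv_r.central_intensity = deriv0.central_intensity
        res = float(np.linalg.norm(deriv_r.d_intensity_d_lambda)) / denom
        history.append(res)
        if res < best_res:
            best_res, best_phase = res, phase
        if res < params.relative_tolerance:
            converged = True
            break
        if len(history) >= 3 and history[-1] > history[-2] > history[-3]:
            log.warning("iterative_refine: residual grew twice, stopping at best iterate")
            phase = best_phase
            break
        phase = phase + shaped(tie_invert(deriv_r, params, pitch))
    else:
        # budget exhausted: the final update was applied but never evaluated;
        # keep it while the residual was still improving, else fall back
        if history[-1] > best_res:
            phase = best_phase

    phase = phase - phase.mean()
    lam_um = 0.530 if not capture.channels else capture.channel("G").wavelength_um
    height = phase_to_height(phase, lam_um, index_contrast)
    return RetrievalResult(phase, height, history, iterations, converged, params)


def phase_to_height(phase: np.ndarray, wavelength: float, index_contrast: float) -> np.ndarray:
    """Convert phase (radians) to physical height (µm): h = φ·λ/(2π·δn).

    ``wavelength`` in µm.  The mean-zero phase gauge carries over: heights
    are relative (step heights, not absolute thickness).
    """
    if index_contrast <= 0:
        raise ValueError("index_contrast must be positive")
    if wavelength <= 0:
        raise ValueError("wavelength must be positive (µm)")
    return np.asarray(phase) * wavelength / (2.0 * np.pi * index_contrast)


def calibrate_channel_defocus(
    capture: SpectralCapture,
    through_focus: list[tuple[float, np.ndarray]],
    channel: str,
) -> tuple[float, np.ndarray]:
    """Locate a channel's equivalent defocus against a through-focus stack.

    Normalized cross-correlation (zero-mean, unit-norm) between the channel
    plane and every stack slice, with parabolic sub-grid interpolation
    around the peak.  Returns ``(z_star, correlation_curve)``; a peak at a
    stack boundary raises (the stack does not bracket the defocus).
    """
    plane = capture.plane(channel)
    p = plane - plane.mean()
    pn = np.linalg.norm(p)
    zs = np.array([z for z, _ in through_focus])
    if np.any(np.diff(zs) <= 0):
        raise ValueError("through-focus z values must be strictly increasing")
    corr = np.empty(len(through_focus))
    for i, (_, img) in enumerate(through_focus):
        q = img - img.mean()
        qn = np.linalg.norm(q)
        corr[i] = float(np.sum(p * q) / (pn * qn)) if pn > 0 and qn > 0 else 0.0
    i = int(np.argmax(corr))
    if i == 0 or i == len(zs) - 1:
        raise ValueError(
            f"correlation peak at the stack boundary (z = {zs[i]:.1f} µm); "
            "extend the through-focus range"
        )
    y0, y1, y2 = corr[i - 1 : i + 2]
    denom = y0 - 2.0 * y1 + y2
    shift = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
    # local z spacing may be non-uniform; use the mean neighbour step
    step = 0.5 * (zs[i + 1] - zs[i - 1])
    return float(zs[i] + shift * step), corr
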