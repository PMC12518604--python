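"""Scalar diffraction from a phase aperture to the focal plane.

The workhorse propagator is the band-limited angular-spectrum method —
the exact spectral solution of the first Rayleigh–Sommerfeld integral —
with zero-padding against periodic wrap-around and the evanescent band
zeroed. A direct summation of the Rayleigh–Sommerfeld integral over
aperture samples serves as the small-grid oracle.

Intensities form either coherently, I = |Σ u_k|², or incoherently,
I = Σ |u_k|²; the incoherent rule combines the LCP/RCP channels of a
polarization-multiplexed design under unpolarized illumination.

Sign conventions: time dependence e^{−iωt}, so forward propagation
carries e^{+ikz} and a converging lens phase is −k(√(ρ²+f²)−f).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .design import LensDesignSpec, PhaseMap, design_phase
from .grids import Grid

__all__ = [
    "ComplexField",
    "IntensityMap",
    "aperture_field",
    "propagate_angular_spectrum",
    "propagate_direct",
    "intensity_coherent",
    "intensity_incoherent",
    "simulate_psf",
]


@dataclass
class ComplexField:
    """Sampled complex amplitude on a transverse plane."""

    values: np.ndarray
    grid: Grid
    wavelength_um: float
    plane_z_um: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("field must be a square 2-D grid")
        if self.wavelength_um <= 0:
            raise ValueError("wavelength must be positive")

    @property
    def power(self) -> float:
        """Total power, Σ|u|²·Δ²."""
        v = self.values
        return float(np.real(np.vdot(v, v)) * self.grid.step ** 2)


@dataclass
class IntensityMap:
    """Nonnegative intensity on a transverse plane."""

    values: np.ndarray
    grid: Grid
    plane_z_um: float = 0.0
    formation: str = "coherent"  # coherent | incoherent

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if np.any(self.values < 0):
            raise ValueError("intensity must be nonnegative")


def aperture_field(phase: PhaseMap, amplitude: float = 1.0) -> ComplexField:
    """Unit plane wave through a binary aperture carrying e^{iψ}."""
    dtype = np.complex64 if phase.values.dtype == np.float32 else np.complex128
    vals = np.exp(1j * phase.values.astype(float)).astype(dtype)
    vals *= phase.aperture_mask
    vals *= amplitude
    return ComplexField(values=vals, grid=phase.grid,
                        wavelength_um=phase.wavelength_nm * 1e-3)


def _pad_size(n: int, pad_factor: float) -> int:
    from scipy.fft import next_fast_len
    return next_fast_len(int(np.ceil(n * pad_factor)))


def propagate_angular_spectrum(field: ComplexField, distance: float, *,
                               pad_factor: float = 2.0,
                               band_limit: bool = True) -> ComplexField:
    """Band-limited angular-spectrum propagation over ``distance`` (μm).

    The transfer function H = exp(i·2πz·√(1/λ² − f_x² − f_y²)) is
    evaluated analytically on the padded frequency grid; evanescent
    components are zeroed. With ``band_limit`` the local-frequency
    criterion of the padded window additionally truncates the spectrum
    to suppress aliasing of the rapidly oscillating H at large z.
    The output is cropped back to the input window.
    """
    lam = field.wavelength_um
    if field.grid.step > lam / 2.0:
        raise ValueError(
            f"sampling step {field.grid.step:.3f} μm exceeds λ/2 = "
            f"{lam / 2:.3f} μm; the propagating/evanescent split is ill-defined")
    n = field.grid.n
    m = _pad_size(n, pad_factor)
    dtype = field.values.dtype if field.values.dtype in (np.complex64,
                                                         np.complex128) else np.complex128
    padded = np.zeros((m, m), dtype=dtype)
    padded[:n, :n] = field.values
    real_dtype = np.float32 if dtype == np.complex64 else np.float64

    fx = np.fft.fftfreq(m, d=field.grid.step).astype(real_dtype)
    fx2 = fx * fx
    arg = (1.0 / lam ** 2) - fx2[:, None] - fx2[None, :]
    propagating = arg > 0.0
    kz = 2.0 * np.pi * np.sqrt(np.where(propagating, arg, 0.0))
    H = np.exp((1j * distance) * kz).astype(dtype)
    H[~propagating] = 0.0
    if band_limit:
        # Matsushima-style limit: H is locally resolvable where
        # |f| <= f_lim = 1/(λ √(1 + (2 z Δf)²)) with Δf the padded bin width
        df = 1.0 / (m * field.grid.step)
        f_lim2 = 1.0 / (lam ** 2 * (1.0 + (2.0 * distance * df) ** 2))
        H[fx2[:, None] + fx2[None, :] > f_lim2] = 0.0

    spec = np.fft.fft2(padded)
    spec *= H
    del H
    out = np.fft.ifft2(spec)[:n, :n]
    return ComplexField(values=np.ascontiguousarray(out), grid=field.grid,
                        wavelength_um=lam,
                        plane_z_um=field.plane_z_um + distance)


def propagate_direct(field: ComplexField, distance: float,
                     output_grid: Grid | None = None,
                     output_points: np.ndarray | None = None, *,
                     max_n: int = 128, override_cost_guard: bool = False
                     ) -> ComplexField | np.ndarray:
    """Direct Rayleigh–Sommerfeld summation over aperture samples.

    Evaluates the first Rayleigh–Sommerfeld integral as a discrete sum,

        U(P) = Σ_q u_q · (z/r²)·(1/(2πr) − ik/(2π))·e^{ikr} · Δ²,

    at every point of ``output_grid`` (default: the input grid) or at
    arbitrary ``output_points`` (array of (x, y) μm; returns a 1-D
    complex array). O(N²·M) — guarded to input grids ≤ ``max_n``².
    """
    n = field.grid.n
    if n > max_n and not override_cost_guard:
        raise ValueError(
            f"direct summation on a {n}×{n} grid exceeds the cost guard "
            f"({max_n}×{max_n}); pass override_cost_guard=True to force")
    lam = field.wavelength_um
    k = 2.0 * np.pi / lam
    z = distance
    X, Y = field.grid.meshgrid()
    src = field.values.ravel()
    sx, sy = X.ravel(), Y.ravel()

    as_points = output_points is not None
    if as_points:
        pts = np.asarray(output_points, dtype=float).reshape(-1, 2)
    else:
        out_grid = output_grid or field.grid
        OX, OY = out_grid.meshgrid()
        pts = np.column_stack([OX.ravel(), OY.ravel()])

    out = np.empty(len(pts), dtype=np.complex128)
    area = field.grid.step ** 2
    chunk = max(1, int(2e6 // src.size))
    for a in range(0, len(pts), chunk):
        px = pts[a:a + chunk, 0][:, None]
        py = pts[a:a + chunk, 1][:, None]
        r2 = (px - sx) ** 2 + (py - sy) ** 2 + z * z
        r = np.sqrt(r2)
        kern = (z / r2) * (1.0 / (2.0 * np.pi * r) - 1j * k / (2.0 * np.pi))
        kern *= np.exp(1j * k * r)
        out[a:a + chunk] = kern @ src * area
    if as_points:
        return out
    return ComplexField(values=out.reshape(out_grid.n, out_grid.n),
                        grid=out_grid, wavelength_um=lam,
                        plane_z_um=field.plane_z_um + distance)


def _check_same_plane(fields: list[ComplexField]) -> None:
    if not fields:
        raise ValueError("need at least one field")
    g0 = fields[0].grid
    for f in fields[1:]:
        if f.grid != g0:
            raise ValueError("fields must share one sampling grid")


def intensity_coherent(fields: list[ComplexField]) -> IntensityMap:
    """I = |Σ u_k|² — mutually coherent superposition."""
    _check_same_plane(fields)
    total = fields[0].values.astype(np.complex128, copy=True)
    for f in fields[1:]:
        total += f.values
    return IntensityMap(values=np.abs(total) ** 2, grid=fields[0].grid,
                        plane_z_um=fields[0].plane_z_um, formation="coherent")


def intensity_incoherent(fields: list[ComplexField]) -> IntensityMap:
    """I = Σ |u_k|² — mutually incoherent superposition (e.g. LCP + RCP)."""
    _check_same_plane(fields)
    total = np.zeros(fields[0].values.shape, dtype=np.float64)
    for f in fields:
        total += np.abs(f.values) ** 2
    return IntensityMap(values=total, grid=fields[0].grid,
                        plane_z_um=fields[0].plane_z_um, formation="incoherent")


def focal_intensity(phases, focal_length_um: float, *,
                    pad_factor: float = 2.0) -> IntensityMap:
    """Propagate designed phase map(s) to the focal plane and form intensity.

    ``phases`` is one PhaseMap or a sequence (e.g. the LCP/RCP pair);
    multiple channels combine incoherently.
    """
    phase_list = list(phases) if isinstance(phases, (tuple, list)) else [phases]
    fields = []
    for ph in phase_list:
        u0 = aperture_field(ph)
        u0.values = u0.values.astype(np.complex64)
        fields.append(propagate_angular_spectrum(u0, focal_length_um,
                                                 pad_factor=pad_factor))
    if len(fields) == 1:
        return intensity_coherent(fields)
    return intensity_incoherent(fields)


def simulate_psf(spec: LensDesignSpec, grid: Grid | None = None, *,
                 seed: int | None = None, pad_factor: float = 2.0,
                 normalize: bool = False) -> IntensityMap:
    """Focal-plane intensity of a designed multifocal lens.

    Composition: design the phase map(s), illuminate with a unit plane
    wave through the binary circular aperture, propagate to the focal
    length, and form the intensity — coherently for single-channel
    designs, incoherently over the LCP/RCP channels for the
    polarization-hybrid method (unpolarized illumination).
    """
    if grid is None:
        grid = Grid.for_aperture(spec.diameter_um, step=0.2, margin=2.0)
    phase = design_phase(spec, grid, seed)
    out = focal_intensity(phase, spec.focal_length_um, pad_factor=pad_factor)
    if normalize:
        from .metrics import normalize_minmax
        out = normalize_minmax(out)
    return out
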