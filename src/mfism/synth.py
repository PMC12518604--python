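"""Synthetic microscope: phantoms and multifocal scan simulation.

Generates ScanStacks with the statistical structure the reconstruction
pipeline assumes, so every stage is testable without instrument data:
sub-resolution point emitters (30 nm fluorescent-bead class),
curvilinear filament phantoms (including a parallel pair at a stated
separation for two-point resolution tests), a flat fluorescent layer,
and an out-of-focus haze component.

Image formation per frame: the sample is rendered on the camera grid,
multiplied by the shifted excitation lattice, convolved with the
emission PSF, scaled to the photon budget, a wide offset-independent
haze term is added, then Poisson shot noise and Gaussian read noise are
applied. Noiseless formation is linear in the sample intensity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .ism import FocusLattice, ScanProtocol, ScanStack
from .metrics import GAUSS_FWHM, theoretical_fwhm
from .optics import IntensityMap

__all__ = [
    "SyntheticSample",
    "ImagingModel",
    "make_bead_sample",
    "make_filament_sample",
    "make_flat_sample",
    "simulate_scan",
    "make_default_fixture",
    "FIXTURES",
]


@dataclass
class SyntheticSample:
    """Ground-truth phantom: point emitters and/or filaments in a square field."""

    field_size_um: float
    emitters: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))
    #: list of (polyline (k,2) in μm, width_nm, intensity)
    filaments: list[tuple[np.ndarray, float, float]] = field(default_factory=list)
    flat_level: float = 0.0
    haze_level: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        self.emitters = np.asarray(self.emitters, dtype=float).reshape(-1, 3)
        if not 0.0 <= self.haze_level < 1.0:
            raise ValueError("haze_level must lie in [0, 1)")
        if np.any(self.emitters[:, 2] < 0):
            raise ValueError("emitter intensities must be nonnegative")
        fs = self.field_size_um
        if self.emitters.size and (
                self.emitters[:, :2].min() < 0 or self.emitters[:, :2].max() > fs):
            raise ValueError("emitters must lie inside the field")


@dataclass(frozen=True)
class ImagingModel:
    """Excitation/emission PSFs, camera pixel, photon budget and read noise.

    The excitation is either an ideal Gaussian lattice (``sigma_ex_nm``,
    fast mode) or a propagated focal-plane intensity from the optics
    layer (``excitation_map``, full-physics mode); the emission PSF is
    an isotropic Gaussian.
    """

    sigma_ex_nm: float
    sigma_em_nm: float
    camera_pixel_um: float
    photon_budget: float = 1000.0
    read_noise: float = 2.0
    excitation_map: IntensityMap | None = None

    @classmethod
    def from_na(cls, *, wavelength_ex_nm: float = 488.0,
                wavelength_em_nm: float = 520.0, numerical_aperture: float = 0.5,
                camera_pixel_um: float = 0.1875, **kwargs) -> "ImagingModel":
        """Gaussian PSFs at the diffraction limit of the stated objective."""
        return cls(
            sigma_ex_nm=theoretical_fwhm(wavelength_ex_nm, numerical_aperture)
            / GAUSS_FWHM,
            sigma_em_nm=theoretical_fwhm(wavelength_em_nm, numerical_aperture)
            / GAUSS_FWHM,
            camera_pixel_um=camera_pixel_um, **kwargs)


# ---------------------------------------------------------------------------
# phantoms
# ---------------------------------------------------------------------------

def make_bead_sample(n_beads: int, field_size_um: float, seed: int, *,
                     min_distance_um: float = 0.0, margin_um: float = 1.0,
                     max_tries: int = 10_000) -> SyntheticSample:
    """Uniformly random sub-resolution point emitters of unit intensity."""
    if n_beads < 1:
        raise ValueError("need at least one bead")
    rng = np.random.default_rng(seed)
    lo, hi = margin_um, field_size_um - margin_um
    if hi <= lo:
        raise ValueError("margin leaves no room for beads")
    placed: list[list[float]] = []
    tries = 0
    while len(placed) < n_beads:
        if tries >= max_tries:
            raise RuntimeError(
                f"could not place {n_beads} beads with min distance "
                f"{min_distance_um} μm in {max_tries} tries")
        tries += 1
        cand = rng.uniform(lo, hi, size=2)
        if min_distance_um > 0 and placed:
            d = np.linalg.norm(np.asarray(placed)[:, :2] - cand, axis=1)
            if d.min() < min_distance_um:
                continue
        placed.append([cand[0], cand[1], 1.0])
    return SyntheticSample(field_size_um=field_size_um,
                           emitters=np.asarray(placed), seed=seed)


def _random_walk_polyline(rng: np.random.Generator, field_size_um: float,
                          n_steps: int = 60, step_um: float = 0.25
                          ) -> np.ndarray:
    start = rng.uniform(0.2 * field_size_um, 0.8 * field_size_um, size=2)
    heading = rng.uniform(0, 2 * np.pi)
    pts = [start]
    for _ in range(n_steps):
        heading += rng.normal(0.0, 0.25)
        nxt = pts[-1] + step_um * np.array([np.cos(heading), np.sin(heading)])
        nxt = np.clip(nxt, 0.5, field_size_um - 0.5)
        pts.append(nxt)
    return np.asarray(pts)


def make_filament_sample(n_filaments: int, field_size_um: float,
                         width_nm: float, seed: int, *,
                         parallel_pair_sep_nm: float | None = 350.0
                         ) -> SyntheticSample:
    """Smooth random-walk filaments, optionally with one parallel pair.

    The pair consists of two straight vertical filaments separated by
    ``parallel_pair_sep_nm`` at the field centre — the ground truth for
    two-point resolution tests.
    """
    if width_nm * 1e-3 >= field_size_um:
        raise ValueError("filament width must be below the field size")
    rng = np.random.default_rng(seed)
    filaments: list[tuple[np.ndarray, float, float]] = []
    if parallel_pair_sep_nm is not None:
        half = parallel_pair_sep_nm * 1e-3 / 2.0
        cx = field_size_um / 2.0
        y = np.linspace(0.25 * field_size_um, 0.75 * field_size_um, 40)
        for sign in (-1.0, 1.0):
            line = np.column_stack([np.full_like(y, cx + sign * half), y])
            filaments.append((line, width_nm, 1.0))
    for _ in range(n_filaments):
        filaments.append((_random_walk_polyline(rng, field_size_um),
                          width_nm, 1.0))
    return SyntheticSample(field_size_um=field_size_um, filaments=filaments,
                           seed=seed)


def make_flat_sample(field_size_um: float, level: float = 1.0
                     ) -> SyntheticSample:
    """Spatially uniform fluorescent layer (seamlessness fixture)."""
    return SyntheticSample(field_size_um=field_size_um, flat_level=level)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _splat_points(canvas: np.ndarray, rows: np.ndarray, cols: np.ndarray,
                  amps: np.ndarray) -> None:
    """Bilinear subpixel splat of point masses onto a pixel grid."""
    r0 = np.floor(rows).astype(int)
    c0 = np.floor(cols).astype(int)
    fr, fc = rows - r0, cols - c0
    h, w = canvas.shape
    for dr, wr in ((0, 1.0 - fr), (1, fr)):
        for dc, wc in ((0, 1.0 - fc), (1, fc)):
            rr, cc = r0 + dr, c0 + dc
            ok = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
            np.add.at(canvas, (rr[ok], cc[ok]), amps[ok] * wr[ok] * wc[ok])


def render_sample(sample: SyntheticSample, pixel_um: float,
                  include_emitters: bool = True) -> np.ndarray:
    """Ground-truth emitter density on the camera grid (row 0 = y 0, x→col)."""
    n_px = int(round(sample.field_size_um / pixel_um))
    img = np.zeros((n_px, n_px), dtype=float)
    if sample.flat_level:
        img += sample.flat_level
    if include_emitters and sample.emitters.size:
        x, y, a = sample.emitters.T
        _splat_points(img, y / pixel_um, x / pixel_um, a)
    for (poly, width_nm, amp) in sample.filaments:
        poly = np.asarray(poly, dtype=float)
        seglen = np.linalg.norm(np.diff(poly, axis=0), axis=1)
        n_pts = max(2, int(np.ceil(seglen.sum() / (pixel_um / 3.0))))
        t = np.linspace(0, 1, n_pts)
        cum = np.concatenate([[0], np.cumsum(seglen)]) / max(seglen.sum(), 1e-12)
        xs = np.interp(t, cum, poly[:, 0])
        ys = np.interp(t, cum, poly[:, 1])
        dense = np.zeros_like(img)
        _splat_points(dense, ys / pixel_um, xs / pixel_um,
                      np.full(n_pts, amp / n_pts * seglen.sum() / pixel_um))
        sigma_px = width_nm * 1e-3 / GAUSS_FWHM / pixel_um
        if sigma_px > 0.05:
            dense = gaussian_filter(dense, sigma_px, mode="constant")
        img += dense
    return img


def _excitation_lattice(shape: tuple[int, int], positions_rc: np.ndarray,
                        sigma_px: float) -> np.ndarray:
    """Sum of unit-peak Gaussian foci at (possibly subpixel) positions."""
    out = np.zeros(shape, dtype=float)
    rad = max(3, int(np.ceil(5.0 * sigma_px)))
    idx = np.arange(-rad, rad + 1, dtype=float)
    h, w = shape
    for (r, c) in np.atleast_2d(positions_rc):
        r0, c0 = int(np.floor(r)), int(np.floor(c))
        gr = np.exp(-((idx - (r - r0)) ** 2) / (2 * sigma_px ** 2))
        gc = np.exp(-((idx - (c - c0)) ** 2) / (2 * sigma_px ** 2))
        patch = gr[:, None] * gc[None, :]
        rs, re = max(r0 - rad, 0), min(r0 + rad + 1, h)
        cs, ce = max(c0 - rad, 0), min(c0 + rad + 1, w)
        if rs >= re or cs >= ce:
            continue
        out[rs:re, cs:ce] += patch[rs - (r0 - rad):re - (r0 - rad),
                                   cs - (c0 - rad):ce - (c0 - rad)]
    return out


def _excitation_from_map(excitation_map: IntensityMap, shape: tuple[int, int],
                         pixel_um: float, shift_px: tuple[int, int]
                         ) -> np.ndarray:
    """Resample a propagated focal-plane intensity onto the camera grid.

    The map centre is anchored to the camera field centre; the pattern is
    shifted by +(kx, ky) camera pixels (x rightward, y down the rows),
    matching the scan-offset convention. Bilinear interpolation, zero
    outside the map.
    """
    from scipy.ndimage import map_coordinates
    h, w = shape
    ky, kx = shift_px
    # camera pixel -> position relative to the field centre, pattern
    # un-shifted (value at q is base(q - delta))
    dx = (np.arange(w) - (w - 1) / 2.0 - kx) * pixel_um
    dy_down = (np.arange(h) - (h - 1) / 2.0 - ky) * pixel_um
    rows, _ = excitation_map.grid.xy_to_rowcol(0.0, -dy_down)
    _, cols = excitation_map.grid.xy_to_rowcol(dx, 0.0)
    R, C = np.meshgrid(rows, cols, indexing="ij")
    return map_coordinates(excitation_map.values, [R, C], order=1,
                           mode="constant")


def _stamp_gaussian(canvas: np.ndarray, row: float, col: float,
                    amplitude: float, sigma_px: float) -> None:
    """Add a unit-integral Gaussian (times ``amplitude``) at a subpixel spot."""
    rad = max(3, int(np.ceil(5.0 * sigma_px)))
    r0, c0 = int(np.floor(row)), int(np.floor(col))
    idx = np.arange(-rad, rad + 1, dtype=float)
    gr = np.exp(-((idx - (row - r0)) ** 2) / (2 * sigma_px ** 2))
    gc = np.exp(-((idx - (col - c0)) ** 2) / (2 * sigma_px ** 2))
    patch = (amplitude / (2.0 * np.pi * sigma_px ** 2)) * gr[:, None] * gc[None, :]
    h, w = canvas.shape
    rs, re = max(r0 - rad, 0), min(r0 + rad + 1, h)
    cs, ce = max(c0 - rad, 0), min(c0 + rad + 1, w)
    if rs >= re or cs >= ce:
        return
    canvas[rs:re, cs:ce] += patch[rs - (r0 - rad):re - (r0 - rad),
                                  cs - (c0 - rad):ce - (c0 - rad)]


def expected_frames(sample: SyntheticSample, model: ImagingModel,
                    protocol: ScanProtocol, lattice: FocusLattice
                    ) -> np.ndarray:
    """Noiseless expected frame stack (before photon-budget scaling).

    Extended structures (flat level, filaments) are formed on the grid:
    (excitation × sample) ⊗ emission PSF. Point emitters are rendered
    analytically — excitation evaluated at the emitter, a unit-integral
    emission Gaussian stamped at its subpixel position — which avoids
    the pixel-splat broadening a grid render would add to point sources.
    """
    p = model.camera_pixel_um
    n_px = int(round(sample.field_size_um / p))
    shape = (n_px, n_px)
    flat_img = np.full(shape, float(sample.flat_level)) if sample.flat_level \
        else None
    sigma_ex_px = model.sigma_ex_nm * 1e-3 / p
    sigma_em_px = model.sigma_em_nm * 1e-3 / p
    offsets = protocol.offsets_px()
    frames = np.zeros((len(offsets), *shape), dtype=float)

    # point sources: the emitters plus a dense sampling of each filament
    # (amplitude = intensity per unit length × arc spacing, stamp width
    # folds the filament width into the emission PSF)
    points: list[tuple[float, float, float, float]] = []  # row, col, amp, sigma
    for (x, y, a) in sample.emitters:
        points.append((y / p, x / p, a, sigma_em_px))
    for (poly, width_nm, amp) in sample.filaments:
        poly = np.asarray(poly, dtype=float)
        seglen = np.linalg.norm(np.diff(poly, axis=0), axis=1)
        total = seglen.sum()
        spacing = p / 3.0
        n_pts = max(2, int(np.ceil(total / spacing)))
        t = np.linspace(0, 1, n_pts)
        cum = np.concatenate([[0], np.cumsum(seglen)]) / max(total, 1e-12)
        xs = np.interp(t, cum, poly[:, 0])
        ys = np.interp(t, cum, poly[:, 1])
        sigma_w_px = width_nm * 1e-3 / GAUSS_FWHM / p
        sigma_pt = float(np.hypot(sigma_em_px, sigma_w_px))
        amp_pt = amp * (total / n_pts)  # intensity per μm × arc spacing
        for (xx, yy) in zip(xs, ys):
            points.append((yy / p, xx / p, amp_pt, sigma_pt))

    for k, (ky, kx) in enumerate(offsets):
        foci = lattice.base_rc + [ky, kx]
        ex = (_excitation_from_map(model.excitation_map, shape, p, (ky, kx))
              if model.excitation_map is not None else None)
        if flat_img is not None:
            exg = ex if ex is not None else _excitation_lattice(
                shape, foci, sigma_ex_px)
            frames[k] = gaussian_filter(exg * flat_img, sigma_em_px,
                                        mode="constant")
        for (row, col, amp, sigma_pt) in points:
            if ex is not None:
                r_i = min(max(int(round(row)), 0), shape[0] - 1)
                c_i = min(max(int(round(col)), 0), shape[1] - 1)
                exval = float(ex[r_i, c_i])
            else:
                d2 = (foci[:, 0] - row) ** 2 + (foci[:, 1] - col) ** 2
                exval = float(np.exp(-d2 / (2 * sigma_ex_px ** 2)).sum())
            if exval * amp > 0:
                _stamp_gaussian(frames[k], row, col, amp * exval, sigma_pt)
    return frames


def simulate_scan(sample: SyntheticSample, model: ImagingModel,
                  protocol: ScanProtocol, lattice: FocusLattice | None = None,
                  seed: int = 0) -> ScanStack:
    """Simulate a complete NS² multifocal scan with noise and haze.

    The noiseless stack is scaled so its global maximum equals the
    photon budget; the haze term (sample blurred with a 5 μm Gaussian,
    offset-independent) contributes ``sample.haze_level`` of the total
    expected counts; Poisson shot noise and Gaussian read noise follow.
    A zero photon budget yields all-zero expected frames.
    """
    if model.photon_budget < 0:
        raise ValueError("photon budget must be nonnegative")
    p = model.camera_pixel_um
    if lattice is None:
        n_px = int(round(sample.field_size_um / p))
        pitch_px = int(round(protocol.pitch_um / p))
        lattice = FocusLattice.square(n_px, pitch_px, protocol.pitch_um)
    frames = expected_frames(sample, model, protocol, lattice)
    peak = frames.max()
    if peak > 0 and model.photon_budget > 0:
        frames *= model.photon_budget / peak
    else:
        frames[:] = 0.0
    if sample.haze_level > 0 and frames.sum() > 0:
        sample_img = render_sample(sample, p)
        haze = gaussian_filter(sample_img, 5.0 / p, mode="constant")
        haze_sum = haze.sum()
        if haze_sum > 0:
            total_per_frame = frames.sum(axis=(1, 2))
            h = sample.haze_level
            for k in range(len(frames)):
                frames[k] += (h / (1.0 - h)) * total_per_frame[k] * haze / haze_sum
    rng = np.random.default_rng(seed)
    noisy = rng.poisson(np.clip(frames, 0, None)).astype(float)
    if model.read_noise > 0:
        noisy += rng.normal(0.0, model.read_noise, size=noisy.shape)
    return ScanStack(frames=noisy, protocol=protocol, lattice=lattice,
                     seed=seed,
                     meta={"photon_budget": model.photon_budget,
                           "read_noise": model.read_noise,
                           "haze_level": sample.haze_level})


# ---------------------------------------------------------------------------
# fixture registry
# ---------------------------------------------------------------------------

def _beads_nm30():
    sample = make_bead_sample(25, 15.0, seed=7, min_distance_um=2.0)
    model = ImagingModel.from_na(camera_pixel_um=0.1875)
    return sample, model, ScanProtocol(pixel_size_um=0.1875, pitch_um=3.0)


def _filaments_350nm():
    sample = make_filament_sample(0, 9.0, width_nm=50.0, seed=11,
                                  parallel_pair_sep_nm=350.0)
    model = ImagingModel.from_na(camera_pixel_um=0.1875)
    return sample, model, ScanProtocol(pixel_size_um=0.1875, pitch_um=3.0)


def _flat_field():
    # bright uniform layer at high SNR: the seam test measures
    # reconstruction geometry, not shot noise
    sample = make_flat_sample(12.0)
    model = ImagingModel.from_na(camera_pixel_um=0.1875, read_noise=0.0,
                                 photon_budget=20000.0)
    return sample, model, ScanProtocol(pixel_size_um=0.1875, pitch_um=3.0)


def _haze_test():
    sample = make_bead_sample(9, 9.0, seed=13, min_distance_um=2.0)
    sample = replace(sample, haze_level=0.5)
    model = ImagingModel.from_na(camera_pixel_um=0.1875)
    return sample, model, ScanProtocol(pixel_size_um=0.1875, pitch_um=3.0)


#: Canonical small fixtures: 520/488 nm Gaussian PSFs at NA 0.5, 3 μm pitch,
#: camera pixel 187.5 nm (= pitch/16, so the NS = 16 offsets tile each cell).
FIXTURES = {
    "beads_nm30": _beads_nm30,
    "filaments_350nm": _filaments_350nm,
    "flat_field": _flat_field,
    "haze_test": _haze_test,
}


def make_default_fixture(name: str
                         ) -> tuple[SyntheticSample, ImagingModel, ScanProtocol]:
    """Return one of the documented (sample, model, protocol) fixtures."""
    try:
        factory = FIXTURES[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {sorted(FIXTURES)}") from None
    return factory()
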