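"""Multifocal metalens phase design by phase multiplexing.

A multifocal metalens is modelled as a sampled wrapped-phase aperture.
Each focus (i, j) of an n×n target grid is produced by a hyperbolic
single-lens phase laterally shifted to the focus position,

    φ_ij(x, y) = −(2π/λ) (√((x−x_ij)² + (y−y_ij)² + f²) − f),

and the sub-profiles are combined by one of four multiplexing
strategies:

``phase_addition``
    ψ_A = arg Σ e^{iφ_ij} — coherent superposition; interference-prone
    at small pitch.
``random``
    ψ_R = Σ φ_ij · L_ij with binary random matrices forming an exact
    partition of unity — interference-resistant, quality degrades with
    the number of multiplexed profiles.
``hybrid``
    checkerboard split of the focus grid by parity of i+j into even/odd
    sublattices, each built by phase addition, the two results combined
    with a two-mask random partition.
``polarization_hybrid``
    four sublattices by the individual parities of i and j; the LCP
    channel carries (even, even) ∪ (odd, odd) and the RCP channel the
    complement, so every focus's nearest neighbours are orthogonally
    polarized and mutually incoherent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .grids import Grid

__all__ = [
    "LensDesignSpec",
    "PhaseMap",
    "RandomPartition",
    "wrap_phase",
    "airy_unit",
    "focal_length_from_na",
    "field_of_view",
    "single_lens_phase",
    "phase_addition",
    "make_random_partition",
    "random_multiplexing",
    "hybrid_multiplexing",
    "polarization_hybrid_multiplexing",
    "design_phase",
]

METHODS = ("phase_addition", "random", "hybrid", "polarization_hybrid")

#: Coherent-sum magnitudes below this (times the profile count) are treated
#: as destructive cancellation; the phase is tie-broken to 0 and counted.
ARG_TIE_EPS = 1e-12


def wrap_phase(phi: np.ndarray) -> np.ndarray:
    """Wrap phase values (radians) into (−π, π]."""
    out = np.mod(np.asarray(phi) + np.pi, 2.0 * np.pi) - np.pi
    # mod may land exactly on −π; the canonical representative is +π
    return np.where(out <= -np.pi, out + 2.0 * np.pi, out)


def airy_unit(wavelength: float, numerical_aperture: float) -> float:
    """One Airy unit, 1.22·λ/NA, in the units of ``wavelength``."""
    if not 0.0 < numerical_aperture < 1.0:
        raise ValueError("numerical aperture must lie in (0, 1)")
    return 1.22 * wavelength / numerical_aperture


def focal_length_from_na(diameter: float, numerical_aperture: float) -> float:
    """Focal length under the marginal-ray sine convention.

    NA = sin θ with tan θ = (D/2)/f, hence f = (D/2)·√(1−NA²)/NA.
    """
    if diameter <= 0:
        raise ValueError("diameter must be positive")
    if not 0.0 < numerical_aperture < 1.0:
        raise ValueError("numerical aperture must lie in (0, 1)")
    na = numerical_aperture
    return (diameter / 2.0) * np.sqrt(1.0 - na * na) / na


@dataclass(frozen=True)
class LensDesignSpec:
    """Geometric and optical parameters of a multifocal design.

    Lengths mix the field's customary units: the wavelength is given in
    nm, all other lengths in μm. ``pitch_um`` is the nearest-neighbour
    spacing of the full n×n focus grid.
    """

    wavelength_nm: float
    numerical_aperture: float
    diameter_um: float
    foci_per_side: int
    pitch_um: float
    center_um: tuple[float, float] = (0.0, 0.0)
    method: str = "hybrid"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.wavelength_nm <= 0:
            raise ValueError("wavelength must be positive")
        if not 0.0 < self.numerical_aperture < 1.0:
            raise ValueError("numerical aperture must lie in (0, 1)")
        if self.diameter_um <= 0:
            raise ValueError("diameter must be positive")
        if self.foci_per_side < 1:
            raise ValueError("need at least one focus per side")
        if self.pitch_um <= 0:
            raise ValueError("pitch must be positive")
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; choose from {METHODS}")

    # -- unit plumbing -------------------------------------------------
    @property
    def wavelength_um(self) -> float:
        return self.wavelength_nm * 1e-3

    @property
    def focal_length_um(self) -> float:
        """Derived from the *individual* lens NA and the full aperture."""
        return focal_length_from_na(self.diameter_um, self.numerical_aperture)

    @property
    def airy_unit_um(self) -> float:
        return airy_unit(self.wavelength_um, self.numerical_aperture)

    @property
    def pitch_au(self) -> float:
        return self.pitch_um / self.airy_unit_um

    @classmethod
    def with_pitch_au(cls, pitch_au: float, *, wavelength_nm: float,
                      numerical_aperture: float, **kwargs) -> "LensDesignSpec":
        """Alternate entry form: pitch stated in Airy units."""
        au = airy_unit(wavelength_nm * 1e-3, numerical_aperture)
        return cls(wavelength_nm=wavelength_nm,
                   numerical_aperture=numerical_aperture,
                   pitch_um=pitch_au * au, **kwargs)

    # -- geometry ------------------------------------------------------
    def focus_position(self, i: int, j: int) -> tuple[float, float]:
        """Target lateral position (x, y) in μm of focus (i, j), 0-based."""
        n, s = self.foci_per_side, self.pitch_um
        x0, y0 = self.center_um
        return (x0 + (i - (n - 1) / 2.0) * s, y0 + (j - (n - 1) / 2.0) * s)

    def focus_positions(self) -> np.ndarray:
        """All n² target positions, shape (n², 2), row-major in (i, j)."""
        n = self.foci_per_side
        out = [self.focus_position(i, j) for i in range(n) for j in range(n)]
        return np.asarray(out, dtype=float)

    def check_fits_window(self, grid: Grid) -> None:
        extent = (self.foci_per_side - 1) * self.pitch_um + self.airy_unit_um
        if extent > grid.extent:
            raise ValueError(
                f"focus grid extent {extent:.1f} μm exceeds the "
                f"{grid.extent:.1f} μm simulation window")


@dataclass
class PhaseMap:
    """A sampled wrapped-phase aperture for one polarization channel."""

    values: np.ndarray            # radians, wrapped to (−π, π]
    grid: Grid
    aperture_mask: np.ndarray     # circular aperture; outside is inactive
    wavelength_nm: float
    polarization: str = "none"    # none | LCP | RCP
    provenance: str = ""          # which ψ this is (psi_A, psi_H, ...)
    seed: int | None = None
    #: positions where a coherent sum cancelled and arg was tie-broken to 0
    n_tie_broken: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("phase map must be a square 2-D grid")
        if self.polarization not in ("none", "LCP", "RCP"):
            raise ValueError("polarization must be none, LCP or RCP")


@dataclass
class RandomPartition:
    """Binary random matrices that exactly partition the sampling grid.

    Stored compactly as a label image; ``masks`` materializes the stack
    of L_k. At every position exactly one mask is 1 (partition of unity).
    """

    labels: np.ndarray  # integer label per grid position, in [0, count)
    count: int
    seed: int

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("partition needs at least one mask")
        if self.labels.min() < 0 or self.labels.max() >= self.count:
            raise ValueError("labels out of range")

    @property
    def masks(self) -> np.ndarray:
        """Boolean stack of shape (count, n, n)."""
        return self.labels[None, :, :] == np.arange(self.count)[:, None, None]

    def sparsity(self) -> np.ndarray:
        """Fraction of the grid assigned to each mask."""
        return np.bincount(self.labels.ravel(), minlength=self.count) / self.labels.size


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def _check_sampling(spec: LensDesignSpec, grid: Grid) -> None:
    nyquist = spec.wavelength_um / (2.0 * spec.numerical_aperture)
    if grid.step > nyquist:
        warnings.warn(
            f"sampling step {grid.step:.3f} μm exceeds λ/(2·NA) = "
            f"{nyquist:.3f} μm; the wrapped phase is aliased", stacklevel=3)


def _raw_lens_phase(spec: LensDesignSpec, i: int, j: int, grid: Grid,
                    dtype=np.float64) -> np.ndarray:
    """Unwrapped hyperbolic phase φ_ij on the grid (radians)."""
    xc, yc = spec.focus_position(i, j)
    f = spec.focal_length_um
    k = 2.0 * np.pi / spec.wavelength_um
    dx2 = ((grid.x - xc) ** 2).astype(dtype)
    dy2 = ((grid.y - yc) ** 2).astype(dtype)
    rho2 = dy2[:, None] + dx2[None, :]
    return (-k * (np.sqrt(rho2 + f * f) - f)).astype(dtype)


def single_lens_phase(spec: LensDesignSpec, i: int, j: int, grid: Grid) -> PhaseMap:
    """Hyperbolic lens phase focusing at the (i, j) target position.

    The phase is exact (no paraxial approximation) and wrapped to
    (−π, π]. Warns when the sampling step exceeds λ/(2·NA).
    """
    n = spec.foci_per_side
    if not (0 <= i < n and 0 <= j < n):
        raise IndexError(f"focus index ({i}, {j}) outside the {n}×{n} grid")
    _check_sampling(spec, grid)
    values = wrap_phase(_raw_lens_phase(spec, i, j, grid))
    return PhaseMap(values=values, grid=grid,
                    aperture_mask=grid.aperture_mask(spec.diameter_um),
                    wavelength_nm=spec.wavelength_nm,
                    provenance=f"phi_{i}{j}")


def _check_shared_grid(profiles: list[PhaseMap]) -> None:
    if not profiles:
        raise ValueError("need at least one phase profile")
    g0 = profiles[0].grid
    for p in profiles[1:]:
        if p.grid != g0 or p.values.shape != profiles[0].values.shape:
            raise ValueError("phase profiles must share one sampling grid")


def _arg_with_tiebreak(total: np.ndarray, count: int) -> tuple[np.ndarray, int]:
    """arg of a coherent sum; near-perfect cancellation is tie-broken to 0."""
    cancelled = np.abs(total) < ARG_TIE_EPS * count
    phase = wrap_phase(np.angle(total))
    phase = np.where(cancelled, 0.0, phase)
    return phase, int(cancelled.sum())


def phase_addition(profiles: list[PhaseMap]) -> PhaseMap:
    """Coherent phase-addition multiplexing: ψ_A = arg Σ e^{iφ_k}.

    Where the sum cancels (|Σ| below a documented epsilon times the
    profile count) the phase is set to 0 and the position counted in
    ``n_tie_broken``.
    """
    _check_shared_grid(profiles)
    total = np.zeros(profiles[0].values.shape, dtype=np.complex128)
    for p in profiles:
        total += np.exp(1j * p.values)
    values, n_ties = _arg_with_tiebreak(total, len(profiles))
    first = profiles[0]
    return PhaseMap(values=values, grid=first.grid,
                    aperture_mask=first.aperture_mask,
                    wavelength_nm=first.wavelength_nm,
                    provenance="psi_A", n_tie_broken=n_ties)


def make_random_partition(count: int, grid: Grid, seed: int) -> RandomPartition:
    """Per-position i.i.d. uniform assignment over ``count`` binary masks.

    The partition-of-unity condition holds exactly by construction and
    each mask's expected sparsity is 1/count.
    """
    if count < 1:
        raise ValueError("partition needs at least one mask")
    rng = np.random.default_rng(seed)
    labels = rng.integers(0, count, size=(grid.n, grid.n), dtype=np.int32)
    return RandomPartition(labels=labels, count=count, seed=seed)


def random_multiplexing(profiles: list[PhaseMap],
                        partition: RandomPartition) -> PhaseMap:
    """Random multiplexing: ψ_R = Σ φ_k·L_k, one profile per position."""
    _check_shared_grid(profiles)
    if partition.count != len(profiles):
        raise ValueError("partition mask count must equal the profile count")
    if partition.labels.shape != profiles[0].values.shape:
        raise ValueError("partition grid does not match the profiles")
    stack = np.stack([p.values for p in profiles])
    values = np.take_along_axis(stack, partition.labels[None], axis=0)[0]
    first = profiles[0]
    return PhaseMap(values=values, grid=first.grid,
                    aperture_mask=first.aperture_mask,
                    wavelength_nm=first.wavelength_nm,
                    provenance="psi_R", seed=partition.seed)


# ---------------------------------------------------------------------------
# composite strategies
# ---------------------------------------------------------------------------

def _exp_phase_sum(spec: LensDesignSpec, grid: Grid,
                   indices: list[tuple[int, int]]) -> np.ndarray:
    """Σ e^{iφ_ij} over the given focus indices, accumulated in complex64.

    Equivalent to summing ``exp(1j * single_lens_phase(...))`` but avoids
    materializing hundreds of full-resolution phase maps.
    """
    f = spec.focal_length_um
    k = 2.0 * np.pi / spec.wavelength_um
    total = np.zeros((grid.n, grid.n), dtype=np.complex64)
    x = grid.x.astype(np.float32)
    y = grid.y.astype(np.float32)
    ff = np.float32(f * f)
    for (i, j) in indices:
        xc, yc = spec.focus_position(i, j)
        rho2 = ((y - yc) ** 2)[:, None] + ((x - xc) ** 2)[None, :]
        phi = (-k) * (np.sqrt(rho2 + ff) - np.float32(f))
        total += np.cos(phi)
        total += 1j * np.sin(phi)
    return total


def _parity_indices(n: int) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """Checkerboard split of the n×n index grid by the parity of i+j."""
    even = [(i, j) for i in range(n) for j in range(n) if (i + j) % 2 == 0]
    odd = [(i, j) for i in range(n) for j in range(n) if (i + j) % 2 == 1]
    return even, odd


def hybrid_multiplexing(spec: LensDesignSpec, grid: Grid,
                        seed: int | None = None) -> PhaseMap:
    """Hybrid multiplexing: checkerboard split + two-mask random combination.

    The n×n focus grid is split into even/odd sublattices by the parity
    of i+j (nearest-neighbour spacing within each sublattice is s·√2);
    ψ_even and ψ_odd are built by phase addition and combined as
    ψ_H = ψ_even·L1 + ψ_odd·L2 with a two-mask random partition.
    """
    _check_sampling(spec, grid)
    seed = spec.seed if seed is None else seed
    n = spec.foci_per_side
    even, odd = _parity_indices(n)
    if not odd:  # n == 1: degenerate grid, reduces to the single lens
        return replace(single_lens_phase(spec, 0, 0, grid), provenance="psi_H",
                       seed=seed)
    psi_even, _ = _arg_with_tiebreak(_exp_phase_sum(spec, grid, even), len(even))
    psi_odd, _ = _arg_with_tiebreak(_exp_phase_sum(spec, grid, odd), len(odd))
    part = make_random_partition(2, grid, seed)
    values = np.where(part.labels == 0, psi_even, psi_odd)
    return PhaseMap(values=values, grid=grid,
                    aperture_mask=grid.aperture_mask(spec.diameter_um),
                    wavelength_nm=spec.wavelength_nm,
                    provenance="psi_H", seed=seed)


def _polarization_parity_indices(n: int) -> dict[str, list[tuple[int, int]]]:
    """Four sublattices by the individual parities of i and j.

    LCP carries (even, even) and (odd, odd); RCP carries the complement,
    so the four nearest neighbours of every focus are orthogonally
    polarized.
    """
    groups: dict[str, list[tuple[int, int]]] = {
        "LCP_even": [], "LCP_odd": [], "RCP_even": [], "RCP_odd": []}
    for i in range(n):
        for j in range(n):
            if i % 2 == 0 and j % 2 == 0:
                groups["LCP_even"].append((i, j))
            elif i % 2 == 1 and j % 2 == 1:
                groups["LCP_odd"].append((i, j))
            elif i % 2 == 1 and j % 2 == 0:
                groups["RCP_even"].append((i, j))
            else:
                groups["RCP_odd"].append((i, j))
    return groups


def polarization_hybrid_multiplexing(
        spec: LensDesignSpec, grid: Grid,
        seed: int | None = None) -> tuple[PhaseMap, PhaseMap]:
    """Polarization hybrid multiplexing: mutually staggered LCP/RCP arrays.

    Each polarization's even/odd sublattices are built by phase addition
    and combined with one *shared* two-mask random partition:
    ψ_LCP = ψ_LCP,even·L1 + ψ_LCP,odd·L2 and likewise for RCP. Returns
    the (LCP, RCP) phase maps; their intensities superimpose
    incoherently under unpolarized illumination.
    """
    _check_sampling(spec, grid)
    seed = spec.seed if seed is None else seed
    n = spec.foci_per_side
    if n % 2 == 1:
        warnings.warn("odd foci_per_side gives unequal LCP/RCP focus counts",
                      stacklevel=2)
    groups = _polarization_parity_indices(n)
    part = make_random_partition(2, grid, seed)
    mask = grid.aperture_mask(spec.diameter_um)
    out = []
    for pol in ("LCP", "RCP"):
        even_idx, odd_idx = groups[f"{pol}_even"], groups[f"{pol}_odd"]
        psi_even, _ = (_arg_with_tiebreak(_exp_phase_sum(spec, grid, even_idx),
                                          len(even_idx))
                       if even_idx else (np.zeros((grid.n, grid.n)), 0))
        psi_odd, _ = (_arg_with_tiebreak(_exp_phase_sum(spec, grid, odd_idx),
                                         len(odd_idx))
                      if odd_idx else (np.zeros((grid.n, grid.n)), 0))
        values = np.where(part.labels == 0, psi_even, psi_odd)
        out.append(PhaseMap(values=values, grid=grid, aperture_mask=mask,
                            wavelength_nm=spec.wavelength_nm, polarization=pol,
                            provenance=f"psi_{pol}", seed=seed))
    return out[0], out[1]


def design_phase(spec: LensDesignSpec, grid: Grid,
                 seed: int | None = None):
    """Dispatch on ``spec.method``; returns one PhaseMap or an (LCP, RCP) pair."""
    seed = spec.seed if seed is None else seed
    spec.check_fits_window(grid)
    if spec.method == "phase_addition":
        n = spec.foci_per_side
        idx = [(i, j) for i in range(n) for j in range(n)]
        values, n_ties = _arg_with_tiebreak(_exp_phase_sum(spec, grid, idx),
                                            len(idx))
        return PhaseMap(values=values, grid=grid,
                        aperture_mask=grid.aperture_mask(spec.diameter_um),
                        wavelength_nm=spec.wavelength_nm, provenance="psi_A",
                        n_tie_broken=n_ties)
    if spec.method == "random":
        # streaming equivalent of random_multiplexing over all n² profiles
        # (avoids holding n² full-resolution phase maps at once)
        n = spec.foci_per_side
        part = make_random_partition(n * n, grid, seed)
        values = np.zeros((grid.n, grid.n))
        for k, (i, j) in enumerate([(i, j) for i in range(n) for j in range(n)]):
            sel = part.labels == k
            if not sel.any():
                continue
            values[sel] = wrap_phase(_raw_lens_phase(spec, i, j, grid))[sel]
        return PhaseMap(values=values, grid=grid,
                        aperture_mask=grid.aperture_mask(spec.diameter_um),
                        wavelength_nm=spec.wavelength_nm, provenance="psi_R",
                        seed=seed)
    if spec.method == "hybrid":
        return hybrid_multiplexing(spec, grid, seed)
    return polarization_hybrid_multiplexing(spec, grid, seed)


def parity_phase_sums(spec: LensDesignSpec, grid: Grid
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Coherent sums Σ e^{iφ_ij} over the even and odd checkerboard sublattices.

    These depend only on the design geometry, not on the partition seed,
    so a family of hybrid designs differing only by seed can reuse them
    (and their total is the phase-addition sum over all foci).
    """
    even, odd = _parity_indices(spec.foci_per_side)
    s_even = _exp_phase_sum(spec, grid, even)
    s_odd = (_exp_phase_sum(spec, grid, odd) if odd
             else np.zeros_like(s_even))
    return s_even, s_odd


def hybrid_from_sums(spec: LensDesignSpec, grid: Grid,
                     sums: tuple[np.ndarray, np.ndarray], seed: int
                     ) -> PhaseMap:
    """Hybrid phase map from precomputed parity sums (seed only draws L1/L2)."""
    s_even, s_odd = sums
    n = spec.foci_per_side
    even, odd = _parity_indices(n)
    if not odd:
        return hybrid_multiplexing(spec, grid, seed)
    psi_even, _ = _arg_with_tiebreak(s_even, len(even))
    psi_odd, _ = _arg_with_tiebreak(s_odd, len(odd))
    part = make_random_partition(2, grid, seed)
    values = np.where(part.labels == 0, psi_even, psi_odd)
    return PhaseMap(values=values, grid=grid,
                    aperture_mask=grid.aperture_mask(spec.diameter_um),
                    wavelength_nm=spec.wavelength_nm,
                    provenance="psi_H", seed=seed)


def addition_from_sums(spec: LensDesignSpec, grid: Grid,
                       sums: tuple[np.ndarray, np.ndarray]) -> PhaseMap:
    """Phase-addition map from precomputed parity sums (their total)."""
    total = sums[0] + sums[1]
    values, n_ties = _arg_with_tiebreak(total, spec.foci_per_side ** 2)
    return PhaseMap(values=values, grid=grid,
                    aperture_mask=grid.aperture_mask(spec.diameter_um),
                    wavelength_nm=spec.wavelength_nm,
                    provenance="psi_A", n_tie_broken=n_ties)


def field_of_view(spec: LensDesignSpec) -> tuple[float, float]:
    """Lateral FOV n·s (μm) and angular FOV 2·arcsin((n·s/2)/f) (degrees)."""
    lateral = spec.foci_per_side * spec.pitch_um
    half = lateral / 2.0
    f = spec.focal_length_um
    angular = np.degrees(2.0 * np.arcsin(min(half / f, 1.0)))
    return lateral, angular
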