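"""Design-layer tests: lens phases, multiplexing strategies, unit plumbing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mfism import (Grid, LensDesignSpec, airy_unit, design_phase,
                   field_of_view, focal_length_from_na, hybrid_multiplexing,
                   make_random_partition, phase_addition,
                   polarization_hybrid_multiplexing, random_multiplexing,
                   single_lens_phase, wrap_phase)
from mfism.design import (_parity_indices, _polarization_parity_indices,
                          addition_from_sums, hybrid_from_sums,
                          parity_phase_sums)


# ---------------------------------------------------------------------------
# unit conversions
# ---------------------------------------------------------------------------

class TestUnits:
    def test_airy_unit_values(self):
        assert airy_unit(488.0, 0.7) == pytest.approx(850.514, abs=0.01)
        # 3 um pitch at 488 nm / NA 0.7 is 3.5 AU to one decimal
        assert round(3.0 / (airy_unit(488.0, 0.7) * 1e-3), 1) == 3.5
        # 2 AU at 633 nm / NA 0.7
        assert 2.0 * airy_unit(0.633, 0.7) == pytest.approx(2.206, abs=0.001)

    def test_airy_unit_rejects_bad_na(self):
        with pytest.raises(ValueError):
            airy_unit(488.0, 1.2)

    def test_focal_length_sine_convention(self):
        # f = (D/2) sqrt(1-NA^2)/NA evaluated independently
        assert focal_length_from_na(1000.0, 0.7) == pytest.approx(
            500.0 * np.sqrt(1 - 0.49) / 0.7, rel=1e-12)
        assert focal_length_from_na(1000.0, 0.7) == pytest.approx(510.10, abs=0.01)

    def test_focal_length_monotone_in_na(self):
        nas = [0.2, 0.4, 0.6, 0.8]
        fs = [focal_length_from_na(500.0, na) for na in nas]
        assert all(a > b for a, b in zip(fs, fs[1:]))

    def test_na_round_trip(self):
        d, na = 800.0, 0.63
        f = focal_length_from_na(d, na)
        assert d / np.sqrt(d * d + 4 * f * f) == pytest.approx(na, rel=1e-12)

    def test_field_of_view(self):
        spec = LensDesignSpec(wavelength_nm=488.0, numerical_aperture=0.7,
                              diameter_um=1000.0, foci_per_side=40, pitch_um=3.0)
        lateral, angular = field_of_view(spec)
        assert lateral == pytest.approx(120.0)
        assert round(angular, 1) == 13.5

    def test_field_of_view_single_focus(self):
        spec = LensDesignSpec(wavelength_nm=488.0, numerical_aperture=0.7,
                              diameter_um=100.0, foci_per_side=1, pitch_um=2.5)
        assert field_of_view(spec)[0] == pytest.approx(2.5)

    def test_pitch_au_entry_form(self):
        spec = LensDesignSpec.with_pitch_au(
            2.0, wavelength_nm=633.0, numerical_aperture=0.7,
            diameter_um=100.0, foci_per_side=12, method="polarization_hybrid")
        assert spec.pitch_um == pytest.approx(2.206, abs=0.001)
        assert spec.pitch_au == pytest.approx(2.0, rel=1e-12)


# ---------------------------------------------------------------------------
# phase primitives
# ---------------------------------------------------------------------------

@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.floats(min_value=-1e3, max_value=1e3, allow_nan=False))
def test_wrap_phase_range(phi):
    w = float(wrap_phase(phi))
    assert -np.pi < w <= np.pi
    # wrapping preserves the phasor
    assert np.exp(1j * w) == pytest.approx(np.exp(1j * phi), abs=1e-9)


class TestSingleLensPhase:
    def test_on_axis_cancellation(self, single_lens_spec):
        grid = Grid(n=65, step=0.2)  # odd: centre sample at the origin
        pm = single_lens_phase(single_lens_spec, 0, 0, grid)
        assert pm.values[32, 32] == pytest.approx(0.0, abs=1e-9)

    def test_zero_at_designated_focus(self):
        # focus shifted off-centre still carries zero phase at its own centre
        spec = LensDesignSpec(wavelength_nm=488.0, numerical_aperture=0.7,
                              diameter_um=100.0, foci_per_side=2, pitch_um=3.2)
        grid = Grid(n=65, step=0.2)
        pm = single_lens_phase(spec, 1, 0, grid)
        x, y = spec.focus_position(1, 0)  # (1.6, -1.6): on grid samples
        row, col = grid.xy_to_rowcol(x, y)
        assert pm.values[int(round(row)), int(round(col))] == pytest.approx(
            0.0, abs=1e-9)

    def test_matches_direct_scalar_evaluation(self, single_lens_spec):
        # phi(10, 0) = -(2 pi/lambda) (sqrt(10^2 + f^2) - f), wrapped
        grid = Grid(n=101, step=0.2)  # x = 10 um on-sample
        pm = single_lens_phase(single_lens_spec, 0, 0, grid)
        f = single_lens_spec.focal_length_um
        expect = float(wrap_phase(
            -(2 * np.pi / 0.488) * (np.hypot(10.0, f) - f)))
        row, col = grid.xy_to_rowcol(10.0, 0.0)
        assert pm.values[int(round(row)), int(round(col))] == pytest.approx(
            expect, abs=1e-6)

    def test_index_out_of_range(self, single_lens_spec, small_grid):
        with pytest.raises(IndexError):
            single_lens_phase(single_lens_spec, 1, 0, small_grid)

    def test_aliasing_warning(self, single_lens_spec):
        coarse = Grid(n=64, step=0.5)  # > lambda/(2 NA) = 0.349 um
        with pytest.warns(UserWarning, match="aliased"):
            single_lens_phase(single_lens_spec, 0, 0, coarse)


class TestPhaseAddition:
    def test_single_profile_identity(self, single_lens_spec, small_grid):
        pm = single_lens_phase(single_lens_spec, 0, 0, small_grid)
        out = phase_addition([pm])
        np.testing.assert_allclose(out.values, pm.values, atol=1e-12)

    def test_two_identical_profiles(self, single_lens_spec, small_grid):
        pm = single_lens_phase(single_lens_spec, 0, 0, small_grid)
        out = phase_addition([pm, pm])
        np.testing.assert_allclose(out.values, pm.values, atol=1e-9)

    def test_destructive_cancellation_tie_break(self, single_lens_spec,
                                                small_grid):
        pm = single_lens_phase(single_lens_spec, 0, 0, small_grid)
        import dataclasses
        shifted = dataclasses.replace(pm, values=wrap_phase(pm.values + np.pi))
        out = phase_addition([pm, shifted])
        assert np.all(out.values == 0.0)
        assert out.n_tie_broken == pm.values.size

    def test_mismatched_grids_rejected(self, single_lens_spec, small_grid):
        pm = single_lens_phase(single_lens_spec, 0, 0, small_grid)
        other = single_lens_phase(single_lens_spec, 0, 0, Grid(32, 0.2))
        with pytest.raises(ValueError):
            phase_addition([pm, other])
        with pytest.raises(ValueError):
            phase_addition([])

    def test_output_wrapped(self, single_lens_spec, small_grid):
        pms = [single_lens_phase(single_lens_spec, 0, 0, small_grid)]
        out = phase_addition(pms * 3)
        assert np.all(out.values > -np.pi) and np.all(out.values <= np.pi)


class TestRandomPartition:
    def test_single_mask_all_ones(self, small_grid):
        part = make_random_partition(1, small_grid, seed=0)
        assert np.all(part.masks[0])

    @pytest.mark.parametrize("count", [2, 3, 7])
    def test_partition_of_unity_exact(self, small_grid, count):
        part = make_random_partition(count, small_grid, seed=3)
        assert np.all(part.masks.sum(axis=0) == 1)

    def test_sparsity_within_three_binomial_sigma(self):
        # 1/n^2 sparsity on a 512^2 grid for count = 4
        part = make_random_partition(4, Grid(512, 0.2), seed=1)
        sigma = np.sqrt(0.25 * 0.75 / 512 ** 2)
        assert np.all(np.abs(part.sparsity() - 0.25) < 3 * sigma)

    def test_seed_determinism(self, small_grid):
        a = make_random_partition(4, small_grid, seed=9)
        b = make_random_partition(4, small_grid, seed=9)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_count_validation(self, small_grid):
        with pytest.raises(ValueError):
            make_random_partition(0, small_grid, seed=0)


class TestRandomMultiplexing:
    def test_trivial_partition_identity(self, single_lens_spec, small_grid):
        pm = single_lens_phase(single_lens_spec, 0, 0, small_grid)
        part = make_random_partition(1, small_grid, seed=0)
        out = random_multiplexing([pm], part)
        np.testing.assert_array_equal(out.values, pm.values)

    def test_constant_profiles_select_by_mask(self, single_lens_spec,
                                              small_grid):
        import dataclasses
        pm = single_lens_phase(single_lens_spec, 0, 0, small_grid)
        p0 = dataclasses.replace(pm, values=np.zeros_like(pm.values))
        p1 = dataclasses.replace(pm, values=np.full_like(pm.values, np.pi / 2))
        part = make_random_partition(2, small_grid, seed=5)
        out = random_multiplexing([p0, p1], part)
        np.testing.assert_array_equal(out.values,
                                      np.where(part.labels == 0, 0.0, np.pi / 2))

    def test_count_mismatch_rejected(self, single_lens_spec, small_grid):
        pm = single_lens_phase(single_lens_spec, 0, 0, small_grid)
        part = make_random_partition(3, small_grid, seed=0)
        with pytest.raises(ValueError):
            random_multiplexing([pm, pm], part)


# ---------------------------------------------------------------------------
# composite strategies
# ---------------------------------------------------------------------------

def _spec(n, method="hybrid", pitch=3.0, d=100.0, wl=488.0, na=0.7, seed=0):
    return LensDesignSpec(wavelength_nm=wl, numerical_aperture=na,
                          diameter_um=d, foci_per_side=n, pitch_um=pitch,
                          method=method, seed=seed)


class TestHybrid:
    def test_degenerate_n1_equals_single_lens(self, small_grid):
        spec = _spec(1)
        hy = hybrid_multiplexing(spec, small_grid, seed=4)
        sl = single_lens_phase(spec, 0, 0, small_grid)
        np.testing.assert_array_equal(hy.values, sl.values)

    def test_checkerboard_split_n2(self):
        even, odd = _parity_indices(2)
        assert set(even) == {(0, 0), (1, 1)}
        assert set(odd) == {(0, 1), (1, 0)}

    def test_sublattice_min_spacing_is_sqrt2_pitch(self):
        spec = _spec(6, pitch=2.0)
        even, odd = _parity_indices(6)
        for idx in (even, odd):
            pos = np.array([spec.focus_position(i, j) for (i, j) in idx])
            from scipy.spatial.distance import pdist
            assert pdist(pos).min() == pytest.approx(2.0 * np.sqrt(2), rel=1e-12)

    def test_values_from_parity_maps_via_partition(self, small_grid):
        spec = _spec(4, seed=11)
        sums = parity_phase_sums(spec, small_grid)
        hy = hybrid_from_sums(spec, small_grid, sums, seed=11)
        direct = hybrid_multiplexing(spec, small_grid, seed=11)
        np.testing.assert_array_equal(hy.values, direct.values)
        # every value comes from one of the two parity phase maps
        psi_even = np.angle(sums[0])
        psi_odd = np.angle(sums[1])
        match = (np.isclose(hy.values, wrap_phase(psi_even), atol=1e-6)
                 | np.isclose(hy.values, wrap_phase(psi_odd), atol=1e-6))
        assert match.all()

    def test_seed_reproducibility(self, small_grid):
        a = design_phase(_spec(4, seed=2), small_grid)
        b = design_phase(_spec(4, seed=2), small_grid)
        np.testing.assert_array_equal(a.values, b.values)

    def test_addition_from_sums_matches_design_phase(self, small_grid):
        spec = _spec(4, method="phase_addition")
        sums = parity_phase_sums(spec, small_grid)
        a = addition_from_sums(spec, small_grid, sums)
        b = design_phase(spec, small_grid)
        np.testing.assert_allclose(a.values, b.values, atol=1e-4)


class TestPolarizationHybrid:
    def test_parity_mapping_n2(self):
        groups = _polarization_parity_indices(2)
        lcp = set(groups["LCP_even"]) | set(groups["LCP_odd"])
        rcp = set(groups["RCP_even"]) | set(groups["RCP_odd"])
        assert lcp == {(0, 0), (1, 1)}
        assert rcp == {(0, 1), (1, 0)}

    def test_channel_counts_n12(self):
        groups = _polarization_parity_indices(12)
        n_lcp = len(groups["LCP_even"]) + len(groups["LCP_odd"])
        n_rcp = len(groups["RCP_even"]) + len(groups["RCP_odd"])
        assert n_lcp == n_rcp == 72

    def test_nearest_neighbors_orthogonally_polarized(self):
        groups = _polarization_parity_indices(6)
        lcp = set(groups["LCP_even"]) | set(groups["LCP_odd"])
        for (i, j) in lcp:
            for (di, dj) in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                nb = (i + di, j + dj)
                if 0 <= nb[0] < 6 and 0 <= nb[1] < 6:
                    assert nb not in lcp

    def test_returns_tagged_pair(self, small_grid):
        lcp, rcp = polarization_hybrid_multiplexing(_spec(
            2, method="polarization_hybrid"), small_grid, seed=1)
        assert lcp.polarization == "LCP" and rcp.polarization == "RCP"

    def test_odd_n_warns(self, small_grid):
        with pytest.warns(UserWarning, match="unequal"):
            polarization_hybrid_multiplexing(
                _spec(3, method="polarization_hybrid"), small_grid, seed=1)


class TestFocusGeometry:
    def test_positions_symmetric_about_center(self):
        spec = _spec(5, pitch=2.4)
        n = 5
        for i in range(n):
            for j in range(n):
                a = np.array(spec.focus_position(i, j))
                b = np.array(spec.focus_position(n - 1 - i, n - 1 - j))
                np.testing.assert_allclose(a + b, 2 * np.asarray(spec.center_um),
                                           atol=1e-12)

    def test_grid_fits_window_validation(self):
        spec = _spec(20, pitch=3.0, d=100.0)
        with pytest.raises(ValueError, match="exceeds"):
            spec.check_fits_window(Grid(160, 0.2))  # 32 um window < 57 um grid

    def test_all_phase_maps_wrapped(self, small_grid):
        for method in ("phase_addition", "random", "hybrid"):
            out = design_phase(_spec(2, method=method), small_grid)
            assert np.all(out.values > -np.pi) and np.all(out.values <= np.pi)
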