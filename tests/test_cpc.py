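from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cpcmorph.cpc import (
    CpcConfig,
    ELEMENT_NAMES,
    assemble_system,
    close_background,
    compute_cpc_volume,
    element_index,
    fit_voxel,
    fit_voxel_joint,
    solve_nnls,
    threshold_and_renormalize,
)
from cpcmorph.phantom import (
    apply_transfer_matrix,
    generate_phantom_pair,
    gm_to_csf_transfer,
    tiled_probability_volume,
)

from .conftest import nnls_active_set_oracle


def make_neighborhood(rng, n=27):
    """Random thresholded probability rows including the four unit vectors."""
    rows = rng.dirichlet(np.ones(4), size=n)
    rows[:4] = np.eye(4)
    return rows


class TestCloseBackground:
    def test_exact_closure(self):
        maps = close_background(np.full((1, 1, 1), 0.6), np.full((1, 1, 1), 0.3),
                                np.full((1, 1, 1), 0.1))
        assert maps.b[0, 0, 0] == pytest.approx(0.0)
        assert maps.voxel_validity.all()

    def test_arithmetic(self):
        maps = close_background(*(np.full((1, 1, 1), 0.2) for _ in range(3)))
        assert maps.b[0, 0, 0] == pytest.approx(0.4)

    def test_over_unity_flagged_invalid(self):
        maps = close_background(np.full((1, 1, 1), 0.7), np.full((1, 1, 1), 0.7),
                                np.zeros((1, 1, 1)))
        assert not maps.voxel_validity[0, 0, 0]
        assert maps.b[0, 0, 0] == 0.0

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="shape"):
            close_background(np.zeros((2, 2, 2)), np.zeros((2, 2, 2)), np.zeros((3, 2, 2)))


class TestThresholdAndRenormalize:
    def test_worked_example(self):
        out = threshold_and_renormalize(np.array([0.1, 0.5, 0.3, 0.1]), 0.2)
        np.testing.assert_allclose(out, [0.0, 0.625, 0.375, 0.0])

    def test_all_above_threshold_unchanged(self):
        p = np.array([0.25, 0.25, 0.25, 0.25])
        np.testing.assert_allclose(threshold_and_renormalize(p, 0.2), p)

    def test_identity_vector(self):
        p = np.array([1.0, 0.0, 0.0, 0.0])
        np.testing.assert_allclose(threshold_and_renormalize(p, 0.2), p)

    def test_all_zero_raises(self):
        with pytest.raises(ValueError):
            threshold_and_renormalize(np.array([0.05, 0.05, 0.05, 0.05]), 0.2)

    def test_bad_tau(self):
        with pytest.raises(ValueError):
            threshold_and_renormalize(np.array([0.25] * 4), 1.5)

    @given(st.lists(st.floats(0.0, 1.0), min_size=4, max_size=4).filter(lambda v: sum(v) > 0))
    @settings(max_examples=100, deadline=None)
    def test_output_on_simplex(self, values):
        p = np.array(values) / sum(values)
        out = threshold_and_renormalize(p, 0.2)
        assert out.sum() == pytest.approx(1.0, abs=1e-12)
        # survivors were >= tau and are rescaled upward (denominator <= 1)
        assert ((out == 0) | (out >= 0.2 - 1e-9)).all()


class TestAssembleSystem:
    def test_row_and_column_counts(self):
        rng = np.random.default_rng(0)
        neigh = make_neighborhood(rng)
        design, response = assemble_system(neigh, neigh, 0)
        assert design.shape == (27, 4)
        assert response.shape == (27,)

    def test_total_equations_and_unknowns(self):
        rng = np.random.default_rng(0)
        neigh = make_neighborhood(rng)
        total_rows = sum(assemble_system(neigh, neigh, t)[0].shape[0] for t in range(4))
        total_unknowns = sum(assemble_system(neigh, neigh, t)[0].shape[1] for t in range(4))
        assert total_rows == 108
        assert total_unknowns == 16

    def test_response_is_target_column(self):
        rng = np.random.default_rng(1)
        a, b = make_neighborhood(rng), make_neighborhood(rng)
        for t in range(4):
            _, response = assemble_system(a, b, t)
            np.testing.assert_array_equal(response, b[:, t])

    def test_bad_target(self):
        neigh = make_neighborhood(np.random.default_rng(0))
        with pytest.raises(ValueError):
            assemble_system(neigh, neigh, 5)


class TestSolveNnls:
    def test_exact_system(self):
        design = np.vstack([np.eye(4), np.eye(4)])
        x = np.array([0.5, 0.2, 0.2, 0.1])
        coeffs, residual = solve_nnls(design, np.concatenate([x, x]))
        np.testing.assert_allclose(coeffs, x, atol=1e-12)
        assert residual == pytest.approx(0.0, abs=1e-20)

    def test_nonnegativity_active(self):
        rng = np.random.default_rng(2)
        design = rng.uniform(0, 1, size=(27, 4))
        response = -design @ np.ones(4)
        coeffs, _ = solve_nnls(design, response)
        np.testing.assert_array_equal(coeffs, np.zeros(4))

    def test_underdetermined_raises(self):
        with pytest.raises(ValueError, match="underdetermined"):
            solve_nnls(np.eye(4)[:3], np.zeros(3))

    def test_zero_column_gives_zero_coeff(self):
        rng = np.random.default_rng(3)
        design = rng.uniform(0, 1, size=(27, 4))
        design[:, 2] = 0.0
        coeffs, _ = solve_nnls(design, rng.uniform(0, 1, size=27))
        assert coeffs[2] == 0.0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_active_set_oracle(self, seed):
        rng = np.random.default_rng(seed)
        design = rng.uniform(0, 1, size=(27, 4))
        response = rng.uniform(0, 1, size=27)
        coeffs, residual = solve_nnls(design, response)
        _, oracle_obj = nnls_active_set_oracle(design, response)
        assert residual == pytest.approx(oracle_obj, abs=1e-9)
        assert coeffs.min() >= 0


class TestFitVoxel:
    def test_identity_recovery(self, default_config):
        rng = np.random.default_rng(4)
        neigh = make_neighborhood(rng)
        fit = fit_voxel(neigh, neigh, default_config)
        np.testing.assert_allclose(fit.elements, np.eye(4), atol=1e-8)
        assert fit.identifiable.all()

    @pytest.mark.parametrize("phi", [0.1, 0.3, 0.5])
    def test_linear_map_recovery(self, phi, default_config):
        rng = np.random.default_rng(5)
        neigh = make_neighborhood(rng)
        transfer = gm_to_csf_transfer(phi)
        neigh_tt = neigh @ transfer.T
        fit = fit_voxel(neigh, neigh_tt, default_config)
        np.testing.assert_allclose(fit.elements, transfer, atol=1e-6)
        assert fit.element("g", "g") == pytest.approx(1 - phi, abs=1e-6)
        assert fit.element("g", "c") == pytest.approx(phi, abs=1e-6)

    def test_cap_applied(self):
        config = CpcConfig()  # cap 5.0
        # single active source at the threshold mapping to larger target
        neigh = np.tile([0.2, 0.0, 0.0, 0.8], (27, 1))
        neigh[::2] = [1.0, 0.0, 0.0, 0.0]
        neigh_tt = neigh.copy()
        neigh_tt[:, 2] = 10.0 * neigh[:, 0]  # forces F_gc = 10 pre-cap
        fit = fit_voxel(neigh, neigh_tt, config)
        assert fit.element("g", "c") == pytest.approx(5.0)

    def test_elements_within_bounds(self, default_config):
        rng = np.random.default_rng(6)
        for _ in range(20):
            fit = fit_voxel(make_neighborhood(rng), make_neighborhood(rng), default_config)
            assert fit.elements.min() >= 0.0
            assert fit.elements.max() <= default_config.cpc_cap

    def test_joint_solve_equivalence(self, default_config):
        rng = np.random.default_rng(7)
        for _ in range(5):
            a, b = make_neighborhood(rng), make_neighborhood(rng)
            sep = fit_voxel(a, b, default_config)
            joint = fit_voxel_joint(a, b, default_config)
            np.testing.assert_allclose(sep.elements, joint.elements, atol=1e-7)


class TestConfig:
    def test_cap_defaults_to_reciprocal_threshold(self):
        assert CpcConfig(prob_threshold=0.2).cpc_cap == pytest.approx(5.0)
        assert CpcConfig(prob_threshold=0.25).cpc_cap == pytest.approx(4.0)

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            CpcConfig(prob_threshold=1.2)

    def test_neighborhood_size(self):
        assert CpcConfig().neighborhood_size == 27
        assert CpcConfig(neighborhood_radius=2).neighborhood_size == 125


class TestComputeCpcVolume:
    def test_zero_atrophy_identity(self, small_spec, default_config):
        maps_t, maps_tt, _ = generate_phantom_pair(small_spec)
        vol = compute_cpc_volume(maps_t, maps_tt, default_config)
        mask = vol.identifiable.all(axis=0) & vol.validity_mask
        assert mask.any()
        F = vol.channels.reshape(4, 4, *vol.grid_shape)
        identity = np.eye(4)[:, :, None, None, None]
        dev = np.abs(F - identity).max(axis=(0, 1))
        assert dev[mask].mean() <= 1e-6

    def test_border_rule_7cube(self, default_config):
        maps = tiled_probability_volume((7, 7, 7))
        vol = compute_cpc_volume(maps, maps, default_config)
        expected = np.zeros((7, 7, 7), dtype=bool)
        expected[1:-1, 1:-1, 1:-1] = True
        np.testing.assert_array_equal(vol.validity_mask, expected)

    def test_atrophy_contrast(self, small_spec, default_config):
        spec = replace(small_spec, atrophy_rate=0.5)
        maps_t, maps_tt, truth = generate_phantom_pair(spec)
        vol = compute_cpc_volume(maps_t, maps_tt, default_config)
        gc = vol.element_map("g", "c")
        inside = truth.atrophy_mask & vol.validity_mask
        outside = ~truth.atrophy_mask & vol.validity_mask
        assert gc[inside].mean() > gc[outside].mean()

    @pytest.mark.parametrize("phi", [0.1, 0.3, 0.5])
    def test_volume_linear_map_recovery(self, phi, default_config):
        base = tiled_probability_volume((9, 9, 9))
        follow = apply_transfer_matrix(base, gm_to_csf_transfer(phi))
        vol = compute_cpc_volume(base, follow, default_config)
        m = vol.validity_mask
        assert np.abs(vol.element_map("g", "g")[m] - (1 - phi)).max() <= 1e-6
        assert np.abs(vol.element_map("g", "c")[m] - phi).max() <= 1e-6
        assert np.abs(vol.element_map("c", "c")[m] - 1.0).max() <= 1e-6
        assert np.abs(vol.element_map("w", "c")[m]).max() <= 1e-6

    def test_determinism(self, small_spec, default_config):
        spec = replace(small_spec, atrophy_rate=0.3, noise_sd=0.02)
        maps_t, maps_tt, _ = generate_phantom_pair(spec)
        a = compute_cpc_volume(maps_t, maps_tt, default_config)
        b = compute_cpc_volume(maps_t, maps_tt, default_config)
        np.testing.assert_array_equal(a.channels, b.channels)
        np.testing.assert_array_equal(a.validity_mask, b.validity_mask)

    def test_grid_mismatch(self, default_config):
        a = tiled_probability_volume((7, 7, 7))
        b = tiled_probability_volume((8, 8, 8))
        with pytest.raises(ValueError, match="grid mismatch"):
            compute_cpc_volume(a, b, default_config)

    def test_all_elements_bounded(self, small_spec, default_config):
        spec = replace(small_spec, atrophy_rate=0.6, noise_sd=0.05)
        maps_t, maps_tt, _ = generate_phantom_pair(spec)
        vol = compute_cpc_volume(maps_t, maps_tt, default_config)
        assert vol.channels.min() >= 0.0
        assert vol.channels.max() <= default_config.cpc_cap


def test_element_naming():
    assert len(ELEMENT_NAMES) == 16
    assert ELEMENT_NAMES[element_index("g", "c")] == "F_gc"
    assert ELEMENT_NAMES[element_index("b", "b")] == "F_bb"
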