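"""Numerical head phantom: geometry, susceptibility, fields, signal, Monte Carlo."""

from dataclasses import replace

import numpy as np
import pytest

from refrase import (InvalidSpecError, LABELS, PhantomSpec,
                     assign_susceptibility, build_geometry, compute_t2star,
                     draw_ssh_coeffs, monte_carlo, simulate_field,
                     simulate_phantom, simulate_signal, wrap_phase)
from refrase.harmonics import evaluate_ssh_field, n_basis


class TestGeometry:
    def test_brain_sphere_voxel_count(self):
        """Discretized brain sphere within 1% of (4/3) pi r^3."""
        labels = build_geometry(PhantomSpec(rng_seed=0))
        expected = 4.0 / 3.0 * np.pi * 48.0**3
        assert abs(labels.m_max.sum() - expected) / expected < 0.01

    def test_labels_partition_grid(self, labels48):
        lab = labels48.labels
        total = sum((lab == v).sum() for v in LABELS.values())
        assert total == lab.size
        present = set(np.unique(lab).tolist())
        assert present <= set(LABELS.values())

    def test_rim_structures_outside_brain_support(self, labels48):
        for name in ("cavity", "bubble"):
            assert not np.any(labels48.mask(name) & labels48.m_max)

    def test_control_regions_inside_brain(self, labels48):
        for name in ("R1", "R2", "R3"):
            m = labels48.mask(name)
            assert m.sum() > 0
            assert np.all(labels48.m_max[m])

    def test_seed_changes_cavities_not_brain(self, spec48):
        a = build_geometry(spec48)
        b = build_geometry(replace(spec48, rng_seed=spec48.rng_seed + 1))
        assert np.array_equal(a.m_max, b.m_max)
        assert a.spec.cavity_centers != b.spec.cavity_centers
        assert not np.array_equal(a.mask("cavity"), b.mask("cavity"))

    def test_invalid_region_placement_raises(self, spec48):
        n = spec48.grid_shape[0]
        c = (n - 1) / 2
        bad = replace(spec48, region_centers=(
            (c + spec48.brain_radius, c, c), (c, c, c), (c, c - 5, c)))
        with pytest.raises(InvalidSpecError, match="R1"):
            build_geometry(bad)

    def test_rim_structure_inside_brain_raises(self, spec48):
        c = (spec48.grid_shape[0] - 1) / 2
        bad = replace(spec48, bubble_center=(c, c, c))
        with pytest.raises(InvalidSpecError, match="bubble"):
            build_geometry(bad)


class TestSusceptibility:
    def test_printed_tissue_values(self, labels48):
        chi = assign_susceptibility(labels48)
        assert chi[labels48.mask("cavity")][0] == pytest.approx(0.36)
        assert chi[labels48.labels == 0][0] == pytest.approx(0.36)   # air
        assert chi[labels48.mask("skull")][0] == pytest.approx(-0.9)
        assert chi[labels48.mask("bubble")][0] == pytest.approx(-0.7)
        assert chi[labels48.mask("tissue")][0] == pytest.approx(-9.0)

    def test_control_region_contrasts(self, labels48):
        chi = assign_susceptibility(labels48)
        tissue = chi[labels48.mask("tissue")][0]
        r1 = chi[labels48.mask("R1")][0]
        r3 = chi[labels48.mask("R3")][0]
        assert r1 - tissue == pytest.approx(0.2)
        assert r3 - r1 == pytest.approx(0.1)

    def test_unknown_label_raises(self, labels48):
        from refrase.phantom import LabelVolume
        bad = LabelVolume(labels=np.full((4, 4, 4), 99, np.uint8),
                          m_max=np.ones((4, 4, 4), bool), spec=labels48.spec)
        with pytest.raises(ValueError, match="unknown"):
            assign_susceptibility(bad)


class TestField:
    def test_zero_inputs_zero_field(self, spec48):
        n = spec48.grid_shape[0]
        b, b_ssh, b_dip = simulate_field(np.zeros((n,) * 3),
                                         np.zeros(n_basis(spec48.ssh_order)),
                                         spec48)
        assert np.all(b == 0) and np.all(b_ssh == 0) and np.all(b_dip == 0)

    def test_single_coefficient_reproduces_basis_function(self, spec48):
        n = spec48.grid_shape[0]
        coeffs = np.zeros(n_basis(spec48.ssh_order))
        coeffs[3] = 2.0
        b, b_ssh, _ = simulate_field(np.zeros((n,) * 3), coeffs, spec48)
        expected = evaluate_ssh_field((n,) * 3, coeffs, origin=spec48.center)
        np.testing.assert_allclose(b_ssh, expected, atol=1e-12)
        np.testing.assert_allclose(b, expected, atol=1e-12)

    def test_linearity_in_susceptibility(self, spec48):
        n = spec48.grid_shape[0]
        rng = np.random.default_rng(8)
        chi1 = rng.standard_normal((n,) * 3)
        chi2 = rng.standard_normal((n,) * 3)
        z = np.zeros(n_basis(spec48.ssh_order))
        b12 = simulate_field(chi1 + chi2, z, spec48)[0]
        b1 = simulate_field(chi1, z, spec48)[0]
        b2 = simulate_field(chi2, z, spec48)[0]
        scale = np.abs(b12).max()
        np.testing.assert_allclose(b12, b1 + b2, atol=1e-10 * scale)

    def test_shape_mismatch_raises(self, spec48):
        with pytest.raises(ValueError, match="grid_shape"):
            simulate_field(np.zeros((8, 8, 8)), np.zeros(36), spec48)


class TestT2Star:
    def test_limits_of_the_relaxation_formula(self, spec48):
        n = 16
        mask = np.ones((n,) * 3, bool)
        # zero gradient -> T2* = T2
        t2s = compute_t2star(np.zeros((n,) * 3), spec48, mask)
        np.testing.assert_allclose(t2s, spec48.T2, atol=1e-12)
        # gradient norm 1/T2 -> T2* = T2/2 (ramp of slope 1/T2 Hz/voxel)
        ramp = (np.arange(n) / spec48.T2)[:, None, None] * np.ones((n,) * 3)
        t2s = compute_t2star(ramp, spec48, mask)
        np.testing.assert_allclose(t2s[4:-4], spec48.T2 / 2.0, atol=1e-9)

    def test_monotone_in_gradient_and_zero_outside(self, spec48):
        n = 16
        mask = np.zeros((n,) * 3, bool)
        mask[2:-2, 2:-2, 2:-2] = True
        slopes = [0.0, 5.0, 20.0, 80.0]
        vals = []
        for s in slopes:
            ramp = s * np.arange(n)[:, None, None] * np.ones((n,) * 3)
            t2s = compute_t2star(ramp, spec48, mask)
            vals.append(t2s[8, 8, 8])
            assert np.all(t2s[~mask] == 0.0)
        assert all(a > b for a, b in zip(vals, vals[1:]))


class TestSignal:
    def test_noise_free_magnitude_and_phase(self, phantom48_clean, spec48):
        series, gt = phantom48_clean
        alive = gt.t2star > 0
        # |S| -> M0 as t -> 0: check exact decay law at the first echo
        te = spec48.TEs[0]
        expected = gt.m0[alive] * np.exp(-te / gt.t2star[alive])
        np.testing.assert_allclose(series.magnitude[0][alive], expected, atol=1e-12)
        # phase(S) = wrap(2 pi b t) wherever there is signal
        for e, te in enumerate(spec48.TEs):
            w = wrap_phase(2 * np.pi * gt.b * te)
            np.testing.assert_allclose(series.phase[e][alive], w[alive], atol=1e-9)

    def test_magnitude_decays_across_echoes_in_brain(self, phantom48_clean):
        series, gt = phantom48_clean
        m = gt.labels.m_max
        for e in range(series.n_echoes - 1):
            assert np.all(series.magnitude[e + 1][m] <= series.magnitude[e][m] + 1e-12)

    def test_noise_std_matches_specification(self, phantom48, spec48):
        """In air (M0 = 0) the real part is pure noise with std sigma_noise."""
        series, gt = phantom48
        air = (gt.labels.labels == 0) & (gt.m0 == 0)
        assert air.sum() >= 10_000
        real = (series.magnitude[0] * np.cos(series.phase[0]))[air]
        assert abs(real.std() - spec48.sigma_noise) / spec48.sigma_noise < 0.05

    def test_negative_echo_time_rejected(self, phantom48_clean, spec48):
        _, gt = phantom48_clean
        bad = replace(spec48, TEs=(-0.004, 0.016))
        with pytest.raises((ValueError, InvalidSpecError)):
            simulate_signal(gt, bad)


class TestMonteCarlo:
    def test_instances_distinct_and_replayable(self, spec48):
        runs = monte_carlo(replace(spec48, rng_seed=5), 3, add_noise=False)
        fields = [gt.b_ssh for _, gt in runs]
        assert not np.array_equal(fields[0], fields[1])
        assert not np.array_equal(fields[1], fields[2])
        # replay from the recorded child spec is bit-identical
        _, gt0 = runs[0]
        series_r, gt_r = simulate_phantom(
            replace(gt0.labels.spec, cavity_centers=None, bubble_center=None),
            add_noise=False)
        np.testing.assert_array_equal(gt_r.b, gt0.b)
        np.testing.assert_array_equal(gt_r.labels.labels, gt0.labels.labels)

    def test_single_instance_allowed_zero_rejected(self, spec48):
        assert len(monte_carlo(spec48, 1, add_noise=False)) == 1
        with pytest.raises(ValueError):
            monte_carlo(spec48, 0)

    def test_coefficient_spread_matches_per_order_std(self, spec48):
        rng = np.random.default_rng(12)
        draws = np.stack([draw_ssh_coeffs(spec48, rng) for _ in range(4000)])
        for l, std in enumerate(spec48.ssh_coeff_std_per_order):
            block = draws[:, l * l:(l + 1) * (l + 1)]
            assert abs(block.std() - std) / std < 0.1


def test_simulation_replay_is_bit_identical(spec48):
    s1, g1 = simulate_phantom(spec48)
    s2, g2 = simulate_phantom(spec48)
    np.testing.assert_array_equal(s1.phase, s2.phase)
    np.testing.assert_array_equal(s1.magnitude, s2.magnitude)
    np.testing.assert_array_equal(g1.chi, g2.chi)
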