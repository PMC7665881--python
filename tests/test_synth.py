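"""Phantom generator: closed forms, forward models, scenes, populations."""

import numpy as np
import pytest

from qpirbc import (
    PhantomSpec,
    compose_scene,
    discocyte_thickness,
    hologram_forward,
    phase_forward,
    reconstruct_phase,
    sample_population,
)
from qpirbc.errors import ParameterError, SpecRejectionError, ValidationError
from qpirbc.morphology3d import ThicknessMap

TWO_PI = 2 * np.pi


class TestDiscocyteThickness:
    def test_center_thickness_is_c0(self, classic_spec):
        t = discocyte_thickness(classic_spec, (256, 256), 0.05, center_px=(128, 128))
        assert t.thickness[128, 128] == pytest.approx(0.81, rel=0.01)

    def test_closed_form_volume(self, classic_spec):
        # V = 2 pi R^2 (c0/3 + 2 c2/15 + 8 c4/105) = 2 pi R^2 * 0.9795
        t = discocyte_thickness(classic_spec, (256, 256), 0.05, center_px=(128, 128))
        grid_volume = t.thickness.sum() * 0.05 ** 2
        assert classic_spec.analytic_volume == pytest.approx(
            TWO_PI * 3.91 ** 2 * 0.9795, abs=0.01
        )
        assert grid_volume == pytest.approx(classic_spec.analytic_volume, rel=0.02)

    def test_dome_degenerate_case(self):
        dome = PhantomSpec("healthy", 3.0, (1.5, 0.0, 0.0), 0.06)
        t = discocyte_thickness(dome, (200, 200), 0.05, center_px=(100, 100))
        assert t.thickness[100, 100] == pytest.approx(1.5, rel=0.01)

    def test_negative_thickness_rejected(self):
        with pytest.raises(SpecRejectionError):
            PhantomSpec("healthy", 3.9, (0.1, 1.0, -2.0), 0.06)

    def test_unresolved_grid_rejected(self, classic_spec):
        with pytest.raises(ValidationError, match="20 px"):
            discocyte_thickness(classic_spec, (64, 64), 0.5)


class TestPhaseForward:
    def test_analytic_value(self):
        t = ThicknessMap(np.full((64, 64), 2.0), pixel_size=0.1)
        p = phase_forward(t, 0.06, 0.532)
        assert p.phase[0, 0] == pytest.approx(1.41726, abs=1e-4)

    def test_zero_thickness_zero_phase(self):
        t = ThicknessMap(np.zeros((64, 64)), pixel_size=0.1)
        assert np.all(phase_forward(t, 0.06, 0.532).phase == 0)

    def test_linearity_in_delta_n(self, classic_spec):
        t = discocyte_thickness(classic_spec, (128, 128), 0.1, center_px=(64, 64))
        p1 = phase_forward(t, 0.03, 0.532)
        p2 = phase_forward(t, 0.06, 0.532)
        assert np.allclose(p2.phase, 2 * p1.phase)


class TestHologramForward:
    def test_pure_fringes_at_carrier_bin(self):
        from qpirbc.holography import PhaseMap

        p = PhaseMap(np.zeros((256, 256)), pixel_size=0.1, wavelength=0.532)
        holo = hologram_forward(p, carrier=(0.0, 0.125), noise_sd=0.0)
        F = np.abs(np.fft.fft2(holo.intensity))
        F[0, 0] = 0
        iy, ix = np.unravel_index(np.argmax(F), F.shape)
        assert {(iy, ix), ((-iy) % 256, (-ix) % 256)} & {(0, 32)}

    def test_round_trip_rms(self, classic_spec):
        t = discocyte_thickness(classic_spec, (256, 256), 0.08, center_px=(128, 128))
        p = phase_forward(t, classic_spec.delta_n, 0.532)
        holo = hologram_forward(p, carrier=(0.25, 0.25), noise_sd=0.0)
        rec = reconstruct_phase(holo)
        rms = np.sqrt(np.mean((rec.phase - p.phase)[t.mask] ** 2))
        assert rms < 0.05

    def test_seeded_determinism(self, classic_spec):
        t = discocyte_thickness(classic_spec, (128, 128), 0.1, center_px=(64, 64))
        p = phase_forward(t, 0.06, 0.532)
        h1 = hologram_forward(p, noise_sd=300.0, rng_seed=5)
        h2 = hologram_forward(p, noise_sd=300.0, rng_seed=5)
        assert np.array_equal(h1.intensity, h2.intensity)

    @pytest.mark.parametrize("carrier", [(0.0, 0.01), (0.4, 0.4)])
    def test_carrier_separability_enforced(self, carrier):
        from qpirbc.holography import PhaseMap

        p = PhaseMap(np.zeros((128, 128)), pixel_size=0.1, wavelength=0.532)
        with pytest.raises(ParameterError, match="separable"):
            hologram_forward(p, carrier=carrier)


class TestSamplePopulation:
    def test_reproducible_specs(self):
        a = sample_population(3, rng_seed=42)
        b = sample_population(3, rng_seed=42)
        assert [s.shape_coeffs for s in a] == [s.shape_coeffs for s in b]

    def test_counts_and_classes(self):
        specs = sample_population((5, 7), rng_seed=0)
        classes = [s.cell_class for s in specs]
        assert classes.count("healthy") == 5 and classes.count("thal") == 7

    def test_analytic_population_contrasts(self):
        """ov and Delta75 contrasts hold on the analytic truth, >= 3 pooled SE."""
        specs = sample_population(200, rng_seed=3)
        ov = {"healthy": [], "thal": []}
        d75 = {"healthy": [], "thal": []}
        for s in specs:
            ov[s.cell_class].append(s.analytic_ov)
            d75[s.cell_class].append(s.analytic_delta_75)
        for vals, sign in ((ov, -1), (d75, +1)):
            mh, mt = np.mean(vals["healthy"]), np.mean(vals["thal"])
            se = np.sqrt(
                np.var(vals["healthy"]) / 200 + np.var(vals["thal"]) / 200
            )
            assert sign * (mt - mh) >= 3 * se

    @pytest.mark.parametrize("seed", range(10))
    def test_directionality_across_seed_sweep(self, seed):
        specs = sample_population(60, rng_seed=seed)
        ov = {"healthy": [], "thal": []}
        d75 = {"healthy": [], "thal": []}
        for s in specs:
            ov[s.cell_class].append(s.analytic_ov)
            d75[s.cell_class].append(s.analytic_delta_75)
        assert np.mean(ov["thal"]) < np.mean(ov["healthy"])
        assert np.mean(d75["thal"]) > np.mean(d75["healthy"])


class TestComposeScene:
    def test_five_cells_with_gap(self):
        specs = sample_population((3, 2), rng_seed=8)
        scene = compose_scene(specs, (520, 520), 0.1, min_gap_px=5.0, rng_seed=8)
        assert scene.labels.n_instances == 5
        assert len(scene.features_true) == 5
        # supports are disjoint
        total = sum((t.mask.sum() for t in scene.thickness.values()))
        assert (scene.labels.labels > 0).sum() == total

    def test_empty_scene(self):
        scene = compose_scene([], (128, 128), 0.1, rng_seed=0)
        assert scene.labels.n_instances == 0
        assert len(scene.features_true) == 0

    def test_seeded_determinism(self):
        specs = sample_population((2, 2), rng_seed=5)
        s1 = compose_scene(specs, (420, 420), 0.1, rng_seed=5)
        s2 = compose_scene(specs, (420, 420), 0.1, rng_seed=5)
        assert np.array_equal(s1.phase.phase, s2.phase.phase)
        assert np.array_equal(s1.labels.labels, s2.labels.labels)

    def test_truth_self_consistency(self):
        """features_true: ov = (2 pi dn / lambda) V per cell, exactly."""
        specs = sample_population((2, 2), rng_seed=6)
        scene = compose_scene(specs, (420, 420), 0.1, rng_seed=6)
        for spec, (_, row) in zip(specs, scene.features_true.iterrows()):
            expected = TWO_PI * spec.delta_n / spec.wavelength * row["volume_true_um3"]
            assert row["ov_true_rad_um2"] == pytest.approx(expected, rel=1e-6)

    def test_placement_failure_raises(self):
        specs = sample_population((4, 4), rng_seed=1)
        with pytest.raises(ValidationError, match="canvas"):
            compose_scene(specs, (150, 150), 0.1, rng_seed=1)


def test_end_to_end_parameter_recovery():
    """Noise-free phantoms through the full measurement chain: volume within
    3%, T0 within 5%, Delta75 within 10% of the analytic truth."""
    from qpirbc import thickness_from_phase
    from qpirbc.morphology3d import thickness_profile_features, volume_and_surface
    from qpirbc.synth import render_cell

    specs = sample_population((15, 15), rng_seed=17)
    for spec in specs:
        t_true, p, mask = render_cell(spec, pixel_size=0.08)
        t = thickness_from_phase(p, mask, spec.delta_n, spec.wavelength)
        v, _ = volume_and_surface(t)
        assert v == pytest.approx(spec.analytic_volume, rel=0.03)
        _, t0, d75 = thickness_profile_features(t)
        assert t0 == pytest.approx(spec.analytic_t0, abs=max(0.05 * spec.analytic_t0, 0.02))
        assert d75 == pytest.approx(spec.analytic_delta_75, rel=0.10)
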