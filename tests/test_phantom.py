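"""Phantom generator: presets, ground-truth fields, frame simulation."""

import numpy as np
import pytest

from panoce.exceptions import AliasingError, ValidationError
from panoce.phantom import (AcquisitionSpec, BackgroundLaw, InclusionSpec,
                            PhantomSpec, column_compliance,
                            default_acquisition, make_stiffness_field,
                            phantom_preset, simulate_frame_stream)

PRESETS = ("islet_poor", "islet_rich", "fibrotic", "pdac")


class TestPresets:
    def test_unknown_preset_raises_lookup_error(self):
        with pytest.raises(KeyError):
            phantom_preset("healthy")

    def test_islet_rich_preset_has_islet_inclusions(self):
        spec = phantom_preset("islet_rich")
        assert spec.inclusion_spec.area_fraction == pytest.approx(0.09)
        assert spec.inclusion_spec.modulus_range_kpa == (250.0, 450.0)
        assert spec.band_targets[0] == pytest.approx(0.38)

    def test_fibrotic_preset_targets_mid_band(self):
        spec = phantom_preset("fibrotic")
        assert spec.band_targets == pytest.approx((0.10, 0.80, 0.10))

    def test_islet_poor_preset_has_no_inclusions(self):
        assert phantom_preset("islet_poor").inclusion_spec is None

    @pytest.mark.parametrize("name", PRESETS)
    def test_presets_fully_populated_and_valid(self, name):
        spec = phantom_preset(name, rng_seed=7)
        spec.validate()
        assert spec.reference_stiffness_kpa == 100.0
        assert spec.rng_seed == 7
        assert sum(spec.band_targets) == pytest.approx(1.0)


class TestStiffnessField:
    @pytest.mark.parametrize("name", PRESETS)
    def test_band_fractions_match_targets_within_2pp(self, name):
        spec = phantom_preset(name, rng_seed=1)
        f = make_stiffness_field(spec)
        for got, want in zip(f.band_fractions(), spec.band_targets):
            assert abs(got - want) < 0.02

    def test_islet_poor_is_predominantly_soft(self):
        f = make_stiffness_field(phantom_preset("islet_poor", rng_seed=1))
        assert (f.tissue < 100).mean() >= 0.90

    def test_pdac_is_predominantly_stiff(self):
        f = make_stiffness_field(phantom_preset("pdac", rng_seed=1))
        assert (f.tissue > 250).mean() > 0.95

    def test_reference_layer_rows_are_exact(self):
        f = make_stiffness_field(phantom_preset("fibrotic", rng_seed=2))
        assert np.all(f.values_kpa[:f.reference_boundary_row] == 100.0)

    def test_degenerate_background_gives_constant_field(self, homogeneous_field):
        v = homogeneous_field.values_kpa
        assert np.ptp(v[homogeneous_field.reference_boundary_row:]) == 0.0
        assert np.allclose(v, 100.0, rtol=1e-12)

    def test_determinism_bit_identical(self):
        a = make_stiffness_field(phantom_preset("islet_rich", rng_seed=5))
        b = make_stiffness_field(phantom_preset("islet_rich", rng_seed=5))
        assert np.array_equal(a.values_kpa, b.values_kpa)

    def test_inconsistent_inclusion_spec_rejected(self):
        spec = phantom_preset("islet_rich")
        bad = PhantomSpec("custom", spec.background_distribution,
                          inclusion_spec=InclusionSpec(0.05, (300.0, 300.0)))
        with pytest.raises(ValidationError):
            make_stiffness_field(bad)

    def test_inclusions_must_exceed_background_95th_percentile(self):
        bg = BackgroundLaw("lognormal", np.log(150.0), 0.4)
        bad = PhantomSpec("custom", bg,
                          inclusion_spec=InclusionSpec(0.05, (200.0, 300.0)))
        with pytest.raises(ValidationError):
            bad.validate()


class TestFrameSimulation:
    def test_zero_displacement_gives_zero_phase(self, two_layer_field):
        acq = AcquisitionSpec(0.0, n_steps=3, phase_noise_sd_rad=0.0)
        stream = simulate_frame_stream(two_layer_field, acq, seed=0)
        diff = np.angle(stream.frames[1] * np.conj(stream.frames[0]))
        assert np.allclose(diff, 0.0)

    def test_homogeneous_closed_form_phase_ramp(self, homogeneous_stream,
                                                homogeneous_field):
        # single-layer solution: uniform strain d/D gives a linear phase
        # ramp of slope 4 pi n (d / D) / lambda0
        acq = homogeneous_stream.acquisition
        diff = np.angle(homogeneous_stream.frames[1] *
                        np.conj(homogeneous_stream.frames[0]))
        phase = np.unwrap(diff, axis=0)
        dz = acq.pixel_size_um[0]
        depth = homogeneous_field.values_kpa.shape[0] * dz
        expected_slope = acq.phase_per_um * \
            (acq.per_step_surface_displacement_um / depth)
        slopes = np.diff(phase, axis=0) / dz
        assert np.allclose(slopes, expected_slope, rtol=1e-9)

    def test_two_layer_phase_slope_ratio(self, two_layer_stream):
        diff = np.angle(two_layer_stream.frames[1] *
                        np.conj(two_layer_stream.frames[0]))
        phase = np.unwrap(diff, axis=0)
        slope_ref = np.diff(phase[10:70], axis=0).mean()
        slope_tissue = np.diff(phase[100:480], axis=0).mean()
        # strain inversely proportional to modulus: 100 kPa vs 50 kPa
        assert slope_tissue / slope_ref == pytest.approx(2.0, rel=1e-9)

    def test_conservation_per_column(self):
        """Surface displacement equals the depth-integral of strain in
        every column (one axial pixel quantization)."""
        field = make_stiffness_field(phantom_preset("islet_poor", rng_seed=3))
        acq = default_acquisition(field, phase_noise_sd_rad=0.0, speckle=False)
        stream = simulate_frame_stream(field, acq, seed=0)
        diff = np.angle(stream.frames[1] * np.conj(stream.frames[0]))
        u = np.unwrap(diff, axis=0) / acq.phase_per_um
        dz = acq.pixel_size_um[0]
        sigma = acq.per_step_surface_displacement_um / column_compliance(field).mean()
        expected = sigma * column_compliance(field)   # per-column displacement
        eps_max = (sigma / field.values_kpa).max()
        assert np.all(np.abs(u[-1] - expected) <= eps_max * dz + 1e-9)
        assert u[-1].mean() == pytest.approx(
            acq.per_step_surface_displacement_um, rel=1e-9)

    def test_determinism_bit_identical_stream(self, two_layer_field):
        acq = default_acquisition(two_layer_field)
        a = simulate_frame_stream(two_layer_field, acq, seed=11)
        b = simulate_frame_stream(two_layer_field, acq, seed=11)
        assert np.array_equal(a.frames, b.frames)

    def test_aliasing_error_with_advice(self, two_layer_field):
        acq = default_acquisition(two_layer_field)
        big = AcquisitionSpec(acq.per_step_surface_displacement_um * 50,
                              phase_noise_sd_rad=0.0)
        with pytest.raises(AliasingError, match="per_step_surface_displacement"):
            simulate_frame_stream(two_layer_field, big, seed=0)

    def test_pixel_size_mismatch_rejected(self, two_layer_field):
        acq = AcquisitionSpec(1.0, pixel_size_um=(8.0, 10.0))
        with pytest.raises(ValidationError):
            simulate_frame_stream(two_layer_field, acq, seed=0)

    def test_acquisition_validation(self):
        with pytest.raises(ValidationError):
            AcquisitionSpec(1.0, n_steps=1).validate()
        with pytest.raises(ValidationError):
            AcquisitionSpec(1.0, refractive_index=0.9).validate()
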