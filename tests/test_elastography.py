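"""Reference-layer stress calibration and elastogram reconstruction."""

import numpy as np
import pytest

from panoce.elastography import (ReferenceCurve, cumulative_stress,
                                 locate_reference_boundary,
                                 standardized_stiffness_map)
from panoce.exceptions import (DecompressionError, EmptyReferenceError,
                               StressWindowError, ValidationError)
from panoce.phantom import (AcquisitionSpec, StiffnessField,
                            default_acquisition, make_stiffness_field,
                            phantom_preset, simulate_frame_stream)
from panoce.strain import StrainMap, estimate_strain_stream


def const_strain_map(value, shape=(100, 40), mask=None):
    vals = np.full(shape, float(value))
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    return StrainMap(vals, (48.0, 50.0), mask, np.ones(shape))


class TestReferenceCurve:
    def test_linear_curve_validates(self):
        ReferenceCurve.linear(100.0).validate()

    def test_offset_curve_rejected(self):
        bad = ReferenceCurve(lambda e: 100.0 * e + 1.0, 100.0)
        with pytest.raises(ValidationError):
            bad.validate()

    def test_wrong_small_strain_slope_rejected(self):
        bad = ReferenceCurve(lambda e: 90.0 * e, 100.0)
        with pytest.raises(ValidationError):
            bad.validate()


class TestBoundary:
    def test_two_layer_boundary_within_two_pixels(self, two_layer_stream):
        sm = estimate_strain_stream(two_layer_stream)[0]
        row = locate_reference_boundary(sm, nominal_row=60)
        assert abs(row - 75) <= 2

    def test_homogeneous_fallback_with_warning(self, homogeneous_stream):
        sm = estimate_strain_stream(homogeneous_stream)[0]
        with pytest.warns(UserWarning, match="nominal"):
            row = locate_reference_boundary(sm, nominal_row=75)
        assert row == 75

    def test_boundary_outside_band_clamped_to_edge(self):
        # true step at row 160, search band ends at 150
        vals = np.full((300, 40), 0.002)
        vals[160:] = 0.006
        sm = StrainMap(vals, (48.0, 50.0), np.ones((300, 40), bool),
                       np.ones((300, 40)))
        row = locate_reference_boundary(sm, search_band_px=(25, 150),
                                        nominal_row=75)
        assert 140 <= row < 150


class TestCumulativeStress:
    def test_linear_curve_hand_example(self):
        # sigma = E * eps: four steps of 0.005 at 100 kPa -> 0.5 kPa each
        maps = [const_strain_map(0.005) for _ in range(4)]
        s = cumulative_stress(maps, ReferenceCurve.linear(100.0), boundary=50)
        assert np.allclose(s, [0.5, 1.0, 1.5, 2.0])

    def test_empty_reference_mask_raises(self):
        m = const_strain_map(0.005)
        m.mask[:50] = False
        with pytest.raises(EmptyReferenceError):
            cumulative_stress([m], ReferenceCurve.linear(), boundary=50)

    def test_zero_strain_single_step(self):
        s = cumulative_stress([const_strain_map(0.0)],
                              ReferenceCurve.linear(), boundary=50)
        assert s.tolist() == [0.0]

    def test_decompression_raises_with_increment_index(self):
        maps = [const_strain_map(0.005), const_strain_map(-0.004)]
        with pytest.raises(DecompressionError, match="increment 1"):
            cumulative_stress(maps, ReferenceCurve.linear(), boundary=50)


class TestStandardizedMap:
    def test_homogeneous_reference_parity(self, homogeneous_stream):
        with pytest.warns(UserWarning):
            smap = standardized_stiffness_map(homogeneous_stream)
        vals = smap.masked_values
        assert abs(vals.mean() - 100.0) <= 2.0
        assert 1.0 <= smap.standardization_stress_kpa <= 3.0

    def test_two_layer_per_layer_recovery(self, two_layer_stream):
        smap = standardized_stiffness_map(two_layer_stream)
        ref = smap.values_kpa[15:60][smap.mask[15:60]]
        tissue = smap.values_kpa[100:480][smap.mask[100:480]]
        assert abs(ref.mean() - 100.0) / 100.0 < 0.05
        assert abs(tissue.mean() - 50.0) / 50.0 < 0.05

    def test_window_never_reached(self, two_layer_field):
        acq = AcquisitionSpec(0.0, n_steps=4, phase_noise_sd_rad=0.0,
                              speckle=False)
        stream = simulate_frame_stream(two_layer_field, acq, seed=0)
        with pytest.raises(StressWindowError, match="more"):
            standardized_stiffness_map(stream, boundary_row=75)

    def test_window_overshot_in_one_step(self, homogeneous_field):
        acq = default_acquisition(homogeneous_field, step_stress_kpa=4.0,
                                  n_steps=3, phase_noise_sd_rad=0.0,
                                  speckle=False)
        stream = simulate_frame_stream(homogeneous_field, acq, seed=0)
        with pytest.raises(StressWindowError, match="smaller"):
            standardized_stiffness_map(stream, boundary_row=75)

    def test_scale_equivariance(self):
        """Doubling tissue moduli (with step stress doubled so strains are
        unchanged) doubles reconstructed moduli within 3 %."""
        base = make_stiffness_field(phantom_preset("fibrotic", rng_seed=6))
        doubled_vals = base.values_kpa.copy()
        doubled_vals[base.reference_boundary_row:] *= 2.0
        doubled = StiffnessField(doubled_vals, base.pixel_size_um,
                                 base.reference_boundary_row)
        maps = []
        for field, step in ((base, 0.25), (doubled, 0.5)):
            acq = default_acquisition(field, step_stress_kpa=step,
                                      phase_noise_sd_rad=0.0, speckle=False)
            stream = simulate_frame_stream(field, acq, seed=2)
            maps.append(standardized_stiffness_map(
                stream, target_stress_kpa=4.0, half_window_kpa=2.0,
                boundary_row=75))
        m = maps[0].mask & maps[1].mask
        m[:90] = False
        ratio = maps[1].values_kpa[m] / maps[0].values_kpa[m]
        assert np.all(np.abs(ratio - 2.0) < 0.06)

    @pytest.mark.parametrize("name", ["islet_rich", "fibrotic"])
    def test_recovery_correlation_above_0p9(self, name):
        field = make_stiffness_field(phantom_preset(name, rng_seed=3))
        acq = default_acquisition(field)
        stream = simulate_frame_stream(field, acq, seed=3)
        smap = standardized_stiffness_map(stream, boundary_row=75)
        m = smap.mask.copy()
        m[:90] = False
        r = np.corrcoef(field.values_kpa[m], smap.values_kpa[m])[0, 1]
        assert r > 0.9
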