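"""Stress-standardized Young's-modulus reconstruction.

Converts per-increment strain maps into an elastogram using the
calibrated reference silicone layer: the mean strain of the 100 kPa
silicone reports the applied stress, and the per-pixel tangent modulus
``E = d(sigma) / d(epsilon)`` is evaluated over the run of compression
increments whose cumulative stress lies inside the standardization
window (2 +- 1 kPa by default).  Standardizing the stress at which the
tangent modulus is read out compensates for the nonlinearity of soft
tissue: moduli from different samples are only comparable when measured
at the same stress.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .exceptions import (DecompressionError, EmptyReferenceError,
                         StressWindowError, ValidationError)
from .phantom import FrameStream
from .strain import StrainMap, estimate_strain_stream

__all__ = [
    "ReferenceCurve",
    "StiffnessMap",
    "locate_reference_boundary",
    "cumulative_stress",
    "standardized_stiffness_map",
]


@dataclass
class ReferenceCurve:
    """Stress-strain law of the calibration silicone.

    ``stress_of_strain`` maps cumulative strain to stress in kPa; it must
    pass through the origin, be strictly increasing, and have a
    small-strain slope equal to ``nominal_modulus_kpa`` within 1 %.  The
    calibration silicone is treated as linear by default
    (``sigma = 100 * epsilon`` kPa); the general curve hook exists
    because stress standardization is only meaningful for nonlinear
    materials.
    """

    stress_of_strain: Callable[[float], float]
    nominal_modulus_kpa: float = 100.0

    @classmethod
    def linear(cls, modulus_kpa: float = 100.0) -> "ReferenceCurve":
        return cls(lambda eps, m=modulus_kpa: m * eps, modulus_kpa)

    def validate(self) -> None:
        if abs(self.stress_of_strain(0.0)) > 1e-12:
            raise ValidationError("reference curve must pass through the origin")
        eps = 1e-6
        slope = self.stress_of_strain(eps) / eps
        if abs(slope - self.nominal_modulus_kpa) > 0.01 * self.nominal_modulus_kpa:
            raise ValidationError("small-strain slope deviates from the "
                                  "nominal reference modulus by more than 1 %")


@dataclass
class StiffnessMap:
    """Per-pixel tangent Young's modulus (kPa) with validity mask.

    ``values_kpa`` is NaN outside the mask.  ``standardization_stress_kpa``
    records the midpoint of the stress span the tangent modulus was
    evaluated over.
    """

    values_kpa: np.ndarray
    mask: np.ndarray
    standardization_stress_kpa: float
    pixel_size_um: tuple[float, float]
    reference_boundary_row: int | None = None

    @property
    def masked_values(self) -> np.ndarray:
        return self.values_kpa[self.mask]

    @property
    def mask_fraction(self) -> float:
        return float(self.mask.mean())


def _row_profile(strain: StrainMap) -> np.ndarray:
    """Masked mean strain per row (NaN where a row has no valid pixels)."""
    num = np.where(strain.mask, strain.values, 0.0).sum(axis=1)
    cnt = strain.mask.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(cnt > 0, num / np.maximum(cnt, 1), np.nan)


def locate_reference_boundary(strain: StrainMap,
                              search_band_px: tuple[int, int] = (25, 150),
                              contrast_window_px: int = 20,
                              min_log_contrast: float = 0.1,
                              nominal_row: int = 75) -> int:
    """Find the silicone/tissue boundary row from a strain map.

    Scans candidate rows inside ``search_band_px`` and returns the row
    maximizing the log-ratio contrast between the mean strain in the
    ``contrast_window_px`` rows above and below.  If no candidate shows a
    relative strain contrast above ``min_log_contrast`` (homogeneous map,
    or tissue with the same stiffness as the silicone) the configured
    nominal boundary row is returned with a warning.
    """
    if strain.mask.sum(axis=1).astype(bool).sum() < 20:
        raise ValidationError("need at least 20 valid rows to locate boundary")
    p = _row_profile(strain)
    n_rows = p.size
    lo = max(search_band_px[0], contrast_window_px)
    hi = min(search_band_px[1], n_rows - contrast_window_px)
    if hi <= lo:
        raise ValidationError("search band empty for this map size")
    eps_floor = 1e-12
    best_row, best_contrast = nominal_row, 0.0
    for r in range(lo, hi):
        above = np.nanmean(p[r - contrast_window_px:r])
        below = np.nanmean(p[r:r + contrast_window_px])
        if not (np.isfinite(above) and np.isfinite(below)):
            continue
        contrast = abs(np.log(max(below, eps_floor) / max(above, eps_floor)))
        if contrast > best_contrast:
            best_row, best_contrast = r, contrast
    if best_contrast < min_log_contrast:
        warnings.warn("no strain contrast found at the expected boundary "
                      "depth; falling back to the nominal reference-layer "
                      f"thickness (row {nominal_row})", stacklevel=2)
        return nominal_row
    return best_row


def cumulative_stress(strain_increments: Sequence[StrainMap],
                      ref_curve: ReferenceCurve, boundary: int,
                      guard_px: int = 6) -> np.ndarray:
    """Cumulative applied stress (kPa) after each compression increment.

    Per increment the reference-layer strain is the masked mean strain
    above the boundary (with a small guard band excluding the
    boundary-blurred rows); the cumulative reference strain is passed
    through the silicone stress-strain curve.  Decompression (negative
    reference strain) raises :class:`DecompressionError`.
    """
    if len(strain_increments) < 1:
        raise ValidationError("need at least one strain increment")
    stresses = np.empty(len(strain_increments))
    cum = 0.0
    for k, sm in enumerate(strain_increments):
        sl = slice(guard_px, boundary - guard_px)
        if sl.stop <= sl.start:
            sl = slice(0, boundary)
        m = sm.mask[sl]
        if not m.any():
            m = sm.mask[:boundary]
            if not m.any():
                raise EmptyReferenceError(
                    f"no valid reference-layer pixels in increment {k}")
            eps = float(sm.values[:boundary][m].mean())
        else:
            eps = float(sm.values[sl][m].mean())
        if eps < -1e-9:
            raise DecompressionError(
                f"reference strain decreased at increment {k} "
                f"(strain {eps:.2e}); frames must be ordered by "
                "increasing compression")
        cum += max(eps, 0.0)
        stresses[k] = ref_curve.stress_of_strain(cum)
    return stresses


def standardized_stiffness_map(stream: FrameStream,
                               ref_curve: ReferenceCurve | None = None,
                               target_stress_kpa: float = 2.0,
                               half_window_kpa: float = 1.0,
                               *,
                               avg_window: tuple[int, int] = (1, 1),
                               window_um: tuple[float, float] = (48.0, 50.0),
                               quality_threshold: float = 0.3,
                               boundary_row: int | None = None,
                               nominal_boundary_row: int | None = None,
                               modulus_floor_kpa: float = 1.0,
                               modulus_ceiling_kpa: float = 1000.0) -> StiffnessMap:
    """Reconstruct the stress-standardized elastogram from a frame stream.

    Selects the contiguous run of increments whose cumulative stresses
    lie in ``[target - half_window, target + half_window]`` and computes
    the per-pixel tangent modulus ``E = delta sigma / delta epsilon``
    across that run (endpoint differences, which avoids
    division-by-small-strain instabilities of per-increment averaging).
    Pixels with non-positive strain accumulation, poor quality in any
    increment, or moduli outside ``[floor, ceiling]`` are masked out --
    not clamped -- so downstream stiffness spectra are not distorted.
    """
    if ref_curve is None:
        ref_curve = ReferenceCurve.linear(100.0)
    ref_curve.validate()
    strains = estimate_strain_stream(stream, avg_window, window_um,
                                     quality_threshold)

    if nominal_boundary_row is None:
        if stream.truth is not None:
            nominal_boundary_row = stream.truth.reference_boundary_row
        else:
            nominal_boundary_row = int(round(300.0 /
                                             stream.acquisition.pixel_size_um[0]))
    if boundary_row is None:
        agg = StrainMap(
            values=np.mean([s.values for s in strains], axis=0),
            window_um=strains[0].window_um,
            mask=np.logical_and.reduce([s.mask for s in strains]),
            quality=np.mean([s.quality for s in strains], axis=0))
        boundary_row = locate_reference_boundary(agg,
                                                 nominal_row=nominal_boundary_row)

    n_ax = int(round(window_um[0] / stream.acquisition.pixel_size_um[0]))
    stresses = cumulative_stress(strains, ref_curve, boundary_row,
                                 guard_px=n_ax // 2 + 1)

    lo = target_stress_kpa - half_window_kpa
    hi = target_stress_kpa + half_window_kpa
    in_window = np.nonzero((stresses >= lo) & (stresses <= hi))[0]
    if in_window.size == 0:
        if stresses.max() < lo:
            raise StressWindowError(
                f"cumulative stress tops out at {stresses.max():.2f} kPa, "
                f"below the window [{lo}, {hi}] kPa; acquire more "
                "compression steps")
        raise StressWindowError(
            f"cumulative stress jumps across the window [{lo}, {hi}] kPa "
            "in a single step; use smaller compression steps")
    i0, i1 = int(in_window[0]), int(in_window[-1])

    sigma_before = stresses[i0 - 1] if i0 > 0 else 0.0
    dsigma = stresses[i1] - sigma_before
    run = strains[i0:i1 + 1]
    deps = np.sum([s.values for s in run], axis=0)
    valid = np.logical_and.reduce([s.mask for s in run])

    with np.errstate(invalid="ignore", divide="ignore"):
        E = np.where(deps > 0, dsigma / np.where(deps > 0, deps, 1.0), np.nan)
    mask = valid & (deps > 0) & (E >= modulus_floor_kpa) & (E <= modulus_ceiling_kpa)
    E = np.where(mask, E, np.nan)

    achieved = 0.5 * (sigma_before + stresses[i1])
    return StiffnessMap(E, mask, float(achieved),
                        stream.acquisition.pixel_size_um, boundary_row)
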