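"""Synthetic compression-OCE phantoms of pancreatic tissue.

This module generates ground-truth Young's-modulus fields for the four
morphological tissue types seen in pancreatectomy specimens (islet-poor
parenchyma, islet-rich parenchyma, fibrotic parenchyma, PDAC) and
simulates the complex-valued OCT frame streams a phase-sensitive
compression-OCE system would record while compressing such tissue through
a calibration silicone layer of known stiffness.

The mechanical model is deliberately simple: each image column behaves as
a stack of springs in series carrying a uniform uniaxial stress, so the
incremental strain at depth ``z`` is ``sigma / E(z, x)`` and the axial
displacement is the running depth-integral of strain from the probe
surface downward.  Lateral coupling and Poisson effects are ignored.
Interframe phase at depth ``z`` is ``4 * pi * n * u(z) / lambda0``
(wrapped), which is the quantity a phase-sensitive OCT system measures.

Speckle is modelled as a complex circular-Gaussian reflectivity that is
held fixed across frames (fully correlated speckle), with independent
per-pixel per-frame phase noise on top.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.stats import norm

from .exceptions import AliasingError, ValidationError

__all__ = [
    "TISSUE_TYPES",
    "BackgroundLaw",
    "InclusionSpec",
    "PhantomSpec",
    "StiffnessField",
    "AcquisitionSpec",
    "FrameStream",
    "phantom_preset",
    "make_stiffness_field",
    "default_acquisition",
    "simulate_frame_stream",
    "lognormal_from_band_fractions",
    "lognormal_from_stiff_tail",
]

TISSUE_TYPES = ("islet_poor", "islet_rich", "fibrotic", "pdac", "custom")

#: Stiffness band edges (kPa) used throughout: "soft" < 100, "stiff" > 250.
BAND_EDGES_KPA = (100.0, 250.0)


@dataclass(frozen=True)
class BackgroundLaw:
    """Parametric law for the background (acinar/fibrotic) tissue modulus.

    Only the log-normal family is supported: tissue moduli are strictly
    positive and right-skewed.  ``location`` and ``scale`` are the mean and
    standard deviation of ``log(E / 1 kPa)``.
    """

    family: str = "lognormal"
    location: float = math.log(100.0)
    scale: float = 0.3

    def __post_init__(self) -> None:
        if self.family != "lognormal":
            raise ValidationError(f"unsupported background family {self.family!r}")
        if self.scale < 0:
            raise ValidationError("background scale must be >= 0")

    def ppf(self, q):
        """Quantile function, in kPa."""
        if self.scale == 0:
            return np.full_like(np.asarray(q, dtype=float), math.exp(self.location))
        return np.exp(self.location + self.scale * norm.ppf(q))

    def cdf(self, x):
        if self.scale == 0:
            return np.where(np.asarray(x, dtype=float) >= math.exp(self.location), 1.0, 0.0)
        return norm.cdf((np.log(x) - self.location) / self.scale)

    def percentile(self, p: float) -> float:
        return float(self.ppf(np.asarray(p)))


def lognormal_from_band_fractions(p_soft: float, p_stiff: float,
                                  edges=BAND_EDGES_KPA) -> BackgroundLaw:
    """Solve a log-normal law from two band-fraction constraints.

    Finds (location, scale) such that ``P(E < edges[0]) = p_soft`` and
    ``P(E > edges[1]) = p_stiff``.
    """
    if not (0 < p_soft < 1 and 0 < p_stiff < 1 and p_soft + p_stiff < 1):
        raise ValidationError("band fractions must be in (0, 1) and sum below 1")
    z1 = norm.ppf(p_soft)
    z2 = norm.ppf(1.0 - p_stiff)
    scale = (math.log(edges[1]) - math.log(edges[0])) / (z2 - z1)
    location = math.log(edges[0]) - z1 * scale
    return BackgroundLaw("lognormal", location, scale)


def lognormal_from_stiff_tail(p_stiff: float, median_kpa: float,
                              edge: float = BAND_EDGES_KPA[1]) -> BackgroundLaw:
    """Solve a log-normal law from a stiff-tail constraint and a median.

    Finds (location, scale) with median ``median_kpa`` and
    ``P(E > edge) = p_stiff``.  Used for predominantly stiff tissue where
    the soft band is essentially empty and cannot pin the scale.
    """
    if not 0 < p_stiff < 1:
        raise ValidationError("p_stiff must be in (0, 1)")
    location = math.log(median_kpa)
    z = norm.ppf(1.0 - p_stiff)
    scale = (math.log(edge) - location) / z
    if scale <= 0:
        raise ValidationError("inconsistent tail constraint (median beyond edge)")
    return BackgroundLaw("lognormal", location, scale)


@dataclass(frozen=True)
class InclusionSpec:
    """Disc-shaped stiff inclusions emulating islets of Langerhans.

    Islets are rendered as discs spanning several OCE resolution cells
    (the system resolution is 30-50 um, so default diameters are
    60-200 um).  Each disc gets a single modulus drawn uniformly from
    ``modulus_range_kpa``.
    """

    area_fraction: float
    modulus_range_kpa: tuple[float, float]
    diameter_range_um: tuple[float, float] = (60.0, 200.0)


@dataclass
class PhantomSpec:
    """Full specification of a synthetic tissue phantom.

    Parameters
    ----------
    tissue_type
        One of ``islet_poor``, ``islet_rich``, ``fibrotic``, ``pdac`` or
        ``custom``.
    field_width_um, field_depth_um
        Lateral and axial extent of the simulated B-scan; defaults match
        a 4 mm scanning field and 2 mm imaging depth.
    reference_layer_thickness_um
        Thickness of the calibration silicone layer on top of the tissue.
    reference_stiffness_kpa
        Young's modulus of the calibration layer (100 kPa silicone).
    background_distribution
        Law of the background tissue modulus.
    inclusion_spec
        Optional stiff inclusions (islets); ``None`` for none.
    correlation_length_um
        Spatial correlation scale of the background stiffness texture;
        chosen comparable to the OCE resolution cell.
    modulus_floor_kpa, modulus_ceiling_kpa
        Physical clamp applied to generated moduli.
    band_targets
        Expected (soft, mid, stiff) fractions of the tissue region; used
        for self-checks and tests, populated by :func:`phantom_preset`.
    """

    tissue_type: str
    background_distribution: BackgroundLaw
    field_width_um: float = 4000.0
    field_depth_um: float = 2000.0
    reference_layer_thickness_um: float = 300.0
    reference_stiffness_kpa: float = 100.0
    inclusion_spec: InclusionSpec | None = None
    rng_seed: int = 0
    pixel_size_um: tuple[float, float] = (4.0, 10.0)
    correlation_length_um: float = 35.0
    modulus_floor_kpa: float = 10.0
    modulus_ceiling_kpa: float = 1000.0
    band_targets: tuple[float, float, float] | None = None

    def validate(self) -> None:
        if self.tissue_type not in TISSUE_TYPES:
            raise ValidationError(f"unknown tissue_type {self.tissue_type!r}")
        for name in ("field_width_um", "field_depth_um",
                     "reference_layer_thickness_um", "correlation_length_um"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        if self.reference_stiffness_kpa <= 0:
            raise ValidationError("reference_stiffness_kpa must be > 0")
        if any(p <= 0 for p in self.pixel_size_um):
            raise ValidationError("pixel sizes must be > 0")
        if self.reference_layer_thickness_um >= self.field_depth_um:
            raise ValidationError("reference layer thicker than the field")
        inc = self.inclusion_spec
        if inc is not None:
            if not 0 <= inc.area_fraction < 1:
                raise ValidationError("inclusion area_fraction must be in [0, 1)")
            lo, hi = inc.modulus_range_kpa
            if inc.area_fraction > 0 and not hi > lo > 0:
                raise ValidationError("inclusion modulus range empty or invalid")
            if inc.area_fraction > 0:
                p95 = self.background_distribution.percentile(0.95)
                if lo <= p95:
                    raise ValidationError(
                        "inclusion modulus lower bound must exceed the "
                        f"background 95th percentile ({p95:.1f} kPa)")
                dlo, dhi = inc.diameter_range_um
                if not dhi >= dlo > 0:
                    raise ValidationError("inclusion diameter range invalid")


@dataclass
class StiffnessField:
    """Ground-truth Young's modulus field (kPa) with calibration layer.

    Rows above ``reference_boundary_row`` hold the calibration silicone
    exactly at ``reference_stiffness_kpa``; rows below are tissue.
    """

    values_kpa: np.ndarray
    pixel_size_um: tuple[float, float]
    reference_boundary_row: int
    reference_stiffness_kpa: float = 100.0

    @property
    def tissue(self) -> np.ndarray:
        """View of the tissue region (below the calibration layer)."""
        return self.values_kpa[self.reference_boundary_row:]

    def band_fractions(self, edges=BAND_EDGES_KPA) -> tuple[float, float, float]:
        """(soft, mid, stiff) pixel fractions of the tissue region."""
        t = self.tissue
        n = t.size
        soft = float((t < edges[0]).sum()) / n
        stiff = float((t > edges[1]).sum()) / n
        return soft, 1.0 - soft - stiff, stiff

    def validate(self) -> None:
        v = self.values_kpa
        if not (np.isfinite(v).all() and (v > 0).all()):
            raise ValidationError("stiffness field must be positive and finite")
        ref = v[: self.reference_boundary_row]
        if ref.size and not np.all(ref == self.reference_stiffness_kpa):
            raise ValidationError("calibration layer rows must equal the "
                                  "reference stiffness exactly")


def _preset_specs() -> dict[str, PhantomSpec]:
    # Islet-poor parenchyma: homogeneous soft acinar tissue, essentially all
    # pixels below 100 kPa, no inclusions.  Target soft fraction 0.93 so the
    # defining ">= 90 % soft" property holds per realization.
    islet_poor_bg = lognormal_from_band_fractions(0.93, 0.002)
    # Islet-rich parenchyma: soft/mid background plus ~9 % stiff islet
    # inclusions at 250-450 kPa.  The overall soft fraction target is 38 %,
    # so the background soft fraction is 0.38 / (1 - 0.09).
    inc = InclusionSpec(area_fraction=0.09, modulus_range_kpa=(250.0, 450.0))
    rich_bg = lognormal_from_band_fractions(0.38 / (1 - inc.area_fraction), 0.005)
    rich_stiff = inc.area_fraction + (1 - inc.area_fraction) * 0.005
    rich_soft = 0.38
    # Fibrotic parenchyma: 10 % soft, 80 % mid-band, 10 % stiff.
    fibrotic_bg = lognormal_from_band_fractions(0.10, 0.10)
    # PDAC: > 95 % of pixels above 250 kPa, extensive areas beyond 400 kPa
    # (median set to 400 kPa).
    pdac_bg = lognormal_from_stiff_tail(0.97, 400.0)
    pdac_soft = float(pdac_bg.cdf(BAND_EDGES_KPA[0]))
    pdac_mid = float(pdac_bg.cdf(BAND_EDGES_KPA[1])) - pdac_soft
    return {
        "islet_poor": PhantomSpec(
            "islet_poor", islet_poor_bg,
            band_targets=(0.93, 0.068, 0.002)),
        "islet_rich": PhantomSpec(
            "islet_rich", rich_bg, inclusion_spec=inc,
            band_targets=(rich_soft, 1 - rich_soft - rich_stiff, rich_stiff)),
        "fibrotic": PhantomSpec(
            "fibrotic", fibrotic_bg,
            band_targets=(0.10, 0.80, 0.10)),
        "pdac": PhantomSpec(
            "pdac", pdac_bg,
            band_targets=(pdac_soft, pdac_mid, 0.97)),
    }


def phantom_preset(name: str, rng_seed: int = 0, **overrides) -> PhantomSpec:
    """Return a fully populated phantom spec for one of the four tissue types.

    Raises ``KeyError`` for unknown names.  Keyword overrides replace any
    :class:`PhantomSpec` field.
    """
    presets = _preset_specs()
    if name not in presets:
        raise KeyError(f"unknown phantom preset {name!r}; "
                       f"choose from {sorted(presets)}")
    spec = replace(presets[name], rng_seed=rng_seed, **overrides)
    spec.validate()
    return spec


def _grid_shape(spec: PhantomSpec) -> tuple[int, int, int]:
    dz, dx = spec.pixel_size_um
    n_rows = int(round(spec.field_depth_um / dz))
    n_cols = int(round(spec.field_width_um / dx))
    boundary = int(round(spec.reference_layer_thickness_um / dz))
    return n_rows, n_cols, boundary


def _correlated_lognormal(shape, law: BackgroundLaw, sigma_px, rng) -> np.ndarray:
    """Spatially correlated field with an *exactly* log-normal marginal.

    A white Gaussian field is smoothed to the requested correlation scale
    and then rank-mapped (probability-integral transform) onto the target
    log-normal quantiles, so the marginal band fractions of every
    realization match the law to within one pixel.
    """
    if law.scale == 0:
        return np.full(shape, math.exp(law.location))
    # generate padded and crop so boundary pixels have full-variance
    # neighbourhoods (reflection padding would shrink edge variance and
    # bias the rank map toward mid quantiles near the edges)
    pad = tuple(int(math.ceil(3 * s)) for s in sigma_px)
    g = rng.standard_normal((shape[0] + 2 * pad[0], shape[1] + 2 * pad[1]))
    g = gaussian_filter(g, sigma_px, mode="reflect")
    g = g[pad[0]:pad[0] + shape[0], pad[1]:pad[1] + shape[1]]
    flat = g.ravel()
    order = np.argsort(flat, kind="stable")
    n = flat.size
    quantiles = (np.arange(n) + 0.5) / n
    out = np.empty(n)
    out[order] = law.ppf(quantiles)
    return out.reshape(shape)


def _paint_inclusions(values: np.ndarray, inc: InclusionSpec,
                      pixel_size_um, rng) -> np.ndarray:
    """Paint non-overlapping elliptical (disc in physical units) inclusions
    until the requested pixel area fraction is reached."""
    dz, dx = pixel_size_um
    n_rows, n_cols = values.shape
    target_px = int(round(inc.area_fraction * values.size))
    painted = np.zeros(values.shape, dtype=bool)
    rejects = 0
    while painted.sum() < target_px:
        diam = rng.uniform(*inc.diameter_range_um)
        r_ax = diam / 2.0 / dz
        r_lat = diam / 2.0 / dx
        cz = rng.uniform(r_ax, n_rows - r_ax)
        cx = rng.uniform(r_lat, n_cols - r_lat)
        z0, z1 = max(0, int(cz - r_ax)), min(n_rows, int(math.ceil(cz + r_ax)) + 1)
        x0, x1 = max(0, int(cx - r_lat)), min(n_cols, int(math.ceil(cx + r_lat)) + 1)
        zz, xx = np.ogrid[z0:z1, x0:x1]
        disc = ((zz - cz) / r_ax) ** 2 + ((xx - cx) / r_lat) ** 2 <= 1.0
        if painted[z0:z1, x0:x1][disc].any():
            rejects += 1
            if rejects > 10000:
                raise ValidationError(
                    "could not place inclusions without overlap; "
                    "area fraction too high for the field size")
            continue
        modulus = rng.uniform(*inc.modulus_range_kpa)
        region = values[z0:z1, x0:x1]
        region[disc] = modulus
        painted[z0:z1, x0:x1] |= disc
    return painted


def make_stiffness_field(spec: PhantomSpec) -> StiffnessField:
    """Generate the ground-truth stiffness field for a phantom spec.

    Deterministic given ``spec.rng_seed``.  The tissue band fractions of
    the returned field match the spec's targets to well within 2
    percentage points by construction (rank-mapped marginal plus
    pixel-counted inclusion placement).
    """
    spec.validate()
    n_rows, n_cols, boundary = _grid_shape(spec)
    dz, dx = spec.pixel_size_um
    rng = np.random.default_rng(spec.rng_seed)

    sigma_px = (spec.correlation_length_um / dz, spec.correlation_length_um / dx)
    tissue = _correlated_lognormal((n_rows - boundary, n_cols),
                                   spec.background_distribution, sigma_px, rng)
    inc = spec.inclusion_spec
    if inc is not None and inc.area_fraction > 0:
        _paint_inclusions(tissue, inc, spec.pixel_size_um, rng)
    np.clip(tissue, spec.modulus_floor_kpa, spec.modulus_ceiling_kpa, out=tissue)

    values = np.empty((n_rows, n_cols))
    values[:boundary] = spec.reference_stiffness_kpa
    values[boundary:] = tissue
    fieldobj = StiffnessField(values, spec.pixel_size_um, boundary,
                              spec.reference_stiffness_kpa)
    fieldobj.validate()
    return fieldobj


@dataclass
class AcquisitionSpec:
    """Acquisition parameters of the simulated phase-sensitive OCT system.

    ``n_steps`` is the number of acquired frames; consecutive frames are
    separated by one compression increment of
    ``per_step_surface_displacement_um`` at the probe surface.  The
    refractive index is not a property of the OCT system but of the
    sample; 1.4 is a typical soft-tissue value.
    """

    per_step_surface_displacement_um: float
    n_steps: int = 17
    central_wavelength_um: float = 1.3
    refractive_index: float = 1.4
    pixel_size_um: tuple[float, float] = (4.0, 10.0)
    phase_noise_sd_rad: float = 0.1
    speckle: bool = True

    def validate(self) -> None:
        if self.central_wavelength_um <= 0:
            raise ValidationError("central_wavelength_um must be > 0")
        if self.refractive_index < 1:
            raise ValidationError("refractive_index must be >= 1")
        if self.n_steps < 2:
            raise ValidationError("need at least 2 frames (n_steps >= 2)")
        if self.per_step_surface_displacement_um < 0:
            raise ValidationError("per-step displacement must be >= 0")
        if self.phase_noise_sd_rad < 0:
            raise ValidationError("phase_noise_sd_rad must be >= 0")

    @property
    def phase_per_um(self) -> float:
        """Interframe phase per micrometre of axial displacement."""
        return 4.0 * math.pi * self.refractive_index / self.central_wavelength_um


@dataclass
class FrameStream:
    """Ordered complex B-scans under monotonically increasing compression."""

    frames: np.ndarray  # (n_frames, n_rows, n_cols) complex
    acquisition: AcquisitionSpec
    truth: StiffnessField | None = None

    def __len__(self) -> int:
        return self.frames.shape[0]

    def validate(self) -> None:
        if self.frames.ndim != 3 or self.frames.shape[0] < 2:
            raise ValidationError("frame stream needs >= 2 frames of equal shape")


def column_compliance(field: StiffnessField) -> np.ndarray:
    """Per-column series compliance ``sum_z dz / E(z, x)`` in um/kPa."""
    dz = field.pixel_size_um[0]
    return (dz / field.values_kpa).sum(axis=0)


def default_acquisition(field: StiffnessField, step_stress_kpa: float = 0.25,
                        n_steps: int = 17, **overrides) -> AcquisitionSpec:
    """Acquisition spec whose per-step displacement produces a stress
    increment of ``step_stress_kpa`` on the given field.

    Defaults (0.25 kPa per step, 16 increments) carry the cumulative
    stress to 4 kPa, comfortably through the 2 +- 1 kPa standardization
    window.
    """
    d = step_stress_kpa * float(column_compliance(field).mean())
    acq = AcquisitionSpec(per_step_surface_displacement_um=d, n_steps=n_steps,
                          pixel_size_um=field.pixel_size_um, **overrides)
    acq.validate()
    return acq


def simulate_frame_stream(field: StiffnessField, acq: AcquisitionSpec,
                          seed: int = 0) -> FrameStream:
    """Simulate a compression frame stream for a ground-truth field.

    Per compression step every image column carries the same uniform
    uniaxial stress (stress-controlled compression through the soft
    reference layer, series-spring columns); per-pixel incremental
    strain is ``sigma_step / E(z, x)`` and axial displacement is its
    depth integral from the probe surface downward.  The scalar step
    stress is ``d / mean(C_x)`` where ``d`` is the per-step surface
    displacement averaged over columns and ``C_x`` the per-column
    compliance, so each column's surface displacement is exactly the
    depth integral of its strain.  Speckle reflectivity is fixed across
    frames; Gaussian phase noise is added per pixel per frame.
    """
    acq.validate()
    if tuple(field.pixel_size_um) != tuple(acq.pixel_size_um):
        raise ValidationError("field and acquisition pixel sizes disagree")
    dz = field.pixel_size_um[0]
    E = field.values_kpa
    d = acq.per_step_surface_displacement_um

    sigma_step = d / float(column_compliance(field).mean())   # kPa, per step
    eps = sigma_step / E                                      # per-step strain
    max_grad = acq.phase_per_um * float(eps.max()) * dz
    if max_grad > math.pi:
        raise AliasingError(
            "implied wrapped phase gradient {:.2f} rad/pixel exceeds pi in the "
            "softest layer; reduce per_step_surface_displacement_um".format(max_grad))
    if eps.max() >= 0.1:
        raise ValidationError(
            "per-step strain reaches {:.3f} in the softest layer; local "
            "linearization invalid -- reduce per_step_surface_displacement_um"
            .format(float(eps.max())))

    u_step = np.cumsum(eps, axis=0) * dz            # um, per step
    phase_step = acq.phase_per_um * u_step          # rad, per step

    rng = np.random.default_rng(seed)
    if acq.speckle:
        r = (rng.standard_normal(E.shape) + 1j * rng.standard_normal(E.shape))
        r /= math.sqrt(2.0)
    else:
        r = np.ones(E.shape, dtype=complex)

    frames = np.empty((acq.n_steps,) + E.shape, dtype=complex)
    for k in range(acq.n_steps):
        phase = k * phase_step
        if acq.phase_noise_sd_rad > 0:
            phase = phase + rng.normal(0.0, acq.phase_noise_sd_rad, E.shape)
        frames[k] = r * np.exp(1j * phase)
    stream = FrameStream(frames, acq, truth=field)
    stream.validate()
    return stream
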