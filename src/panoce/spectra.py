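"""Stiffness spectra: ROI histograms, band fractions, stitching.

A "stiffness spectrum" is the normalized histogram of per-pixel Young's
modulus over a region of interest.  The two cut-offs reported for
pancreatic tissue -- 100 kPa separating soft acinar parenchyma and
250 kPa marking islet/tumour-grade stiffness -- are always kept on bin
edges so band fractions are exact sums of bins regardless of bin width.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ValidationError
from .elastography import StiffnessMap

__all__ = [
    "BAND_EDGES_KPA",
    "StiffnessSpectrum",
    "SpectrumFeatures",
    "default_bin_edges",
    "default_roi",
    "extract_roi",
    "stiffness_spectrum",
    "spectrum_features",
    "stitch_maps",
    "patient_mean_stiffness",
]

BAND_EDGES_KPA = (100.0, 250.0)

#: Minimum number of valid pixels for a spectrum used in classification.
MIN_SPECTRUM_PIXELS = 100


def default_bin_edges(bin_width_kpa: float = 25.0,
                      max_kpa: float = 1000.0) -> np.ndarray:
    """Histogram edges from 0 to ``max_kpa``; the width must divide the
    100/250 kPa band cut-offs so they land exactly on edges."""
    for edge in BAND_EDGES_KPA:
        if abs(edge / bin_width_kpa - round(edge / bin_width_kpa)) > 1e-9:
            raise ValidationError(
                f"bin width {bin_width_kpa} does not place {edge} kPa on an edge")
    n = int(round(max_kpa / bin_width_kpa))
    return np.linspace(0.0, n * bin_width_kpa, n + 1)


@dataclass
class StiffnessSpectrum:
    """Normalized modulus histogram over an ROI.

    ``values_kpa`` retains the underlying masked pixel values so summary
    statistics (mean, median) can be computed exactly rather than from
    bin centres.
    """

    bin_edges_kpa: np.ndarray
    fractions: np.ndarray
    n_pixels: int
    roi_um: tuple[float, float]
    values_kpa: np.ndarray


@dataclass
class SpectrumFeatures:
    """Band fractions and summary statistics of a stiffness spectrum."""

    p_soft: float       # fraction with E < 100 kPa
    p_mid: float        # fraction with 100 <= E <= 250 kPa
    p_stiff: float      # fraction with E > 250 kPa
    mean_kpa: float
    median_kpa: float
    n_pixels: int


def extract_roi(smap: StiffnessMap,
                roi_um: tuple[float, float, float, float]) -> StiffnessMap:
    """Extract a rectangular sub-map.

    ``roi_um`` is ``(top, left, depth, width)`` in micrometres in map
    coordinates.  Extents are converted to pixels by rounding to the
    nearest integer (ties to even).  The ROI must lie inside the map and,
    when the map records a reference boundary, entirely below it.
    """
    dz, dx = smap.pixel_size_um
    top, left, depth, width = roi_um
    r0 = int(np.round(top / dz))
    c0 = int(np.round(left / dx))
    nr = int(np.round(depth / dz))
    nc = int(np.round(width / dx))
    n_rows, n_cols = smap.values_kpa.shape
    if r0 < 0 or c0 < 0 or nr < 1 or nc < 1 or r0 + nr > n_rows or c0 + nc > n_cols:
        raise ValidationError(f"ROI {roi_um} falls outside the {n_rows}x{n_cols} map")
    if smap.reference_boundary_row is not None and r0 < smap.reference_boundary_row:
        raise ValidationError("ROI overlaps the reference silicone layer")
    sub = slice(r0, r0 + nr), slice(c0, c0 + nc)
    return StiffnessMap(smap.values_kpa[sub], smap.mask[sub],
                        smap.standardization_stress_kpa, smap.pixel_size_um,
                        smap.reference_boundary_row)


def default_roi(smap: StiffnessMap, depth_um: float = 350.0,
                width_um: float = 3200.0,
                offset_um: float = 48.0) -> tuple[float, float, float, float]:
    """Default analysis ROI: ~350 x 3200 um placed just below the
    reference boundary, laterally centred.

    ``offset_um`` (one axial processing window) skips the rows where the
    strain estimator straddles the silicone/tissue boundary.
    """
    dz, dx = smap.pixel_size_um
    boundary = smap.reference_boundary_row or 0
    top = boundary * dz + offset_um
    n_cols = smap.values_kpa.shape[1]
    left = max(0.0, (n_cols * dx - width_um) / 2.0)
    return (top, left, depth_um, width_um)


def stiffness_spectrum(smap: StiffnessMap,
                       bin_edges: np.ndarray | None = None,
                       roi_um: tuple[float, float] | None = None) -> StiffnessSpectrum:
    """Normalized histogram of the masked modulus values of a map."""
    if bin_edges is None:
        bin_edges = default_bin_edges()
    bin_edges = np.asarray(bin_edges, dtype=float)
    if bin_edges.ndim != 1 or bin_edges.size < 2 or np.any(np.diff(bin_edges) <= 0):
        raise ValidationError("bin edges must be a strictly increasing sequence")
    vals = smap.masked_values
    if vals.size < MIN_SPECTRUM_PIXELS:
        raise ValidationError(
            f"only {vals.size} masked pixels; need >= {MIN_SPECTRUM_PIXELS} "
            "for a spectrum")
    if vals.min() < bin_edges[0] or vals.max() > bin_edges[-1]:
        raise ValidationError("modulus values fall outside the bin range")
    counts, _ = np.histogram(vals, bins=bin_edges)
    if roi_um is None:
        dz, dx = smap.pixel_size_um
        roi_um = (smap.values_kpa.shape[0] * dz, smap.values_kpa.shape[1] * dx)
    return StiffnessSpectrum(bin_edges, counts / vals.size, int(vals.size),
                             roi_um, vals)


def spectrum_features(spec: StiffnessSpectrum,
                      band_edges=BAND_EDGES_KPA) -> SpectrumFeatures:
    """Band fractions (from bins) and exact mean/median (from pixels)."""
    edges = spec.bin_edges_kpa
    idx = []
    for e in band_edges:
        hits = np.nonzero(np.isclose(edges, e))[0]
        if hits.size == 0:
            raise ValidationError(f"band edge {e} kPa is not a histogram edge")
        idx.append(int(hits[0]))
    i_soft, i_stiff = idx
    p_soft = float(spec.fractions[:i_soft].sum())
    p_stiff = float(spec.fractions[i_stiff:].sum())
    p_mid = float(spec.fractions[i_soft:i_stiff].sum())
    return SpectrumFeatures(p_soft, p_mid, p_stiff,
                            float(spec.values_kpa.mean()),
                            float(np.median(spec.values_kpa)),
                            spec.n_pixels)


def stitch_maps(maps: list[StiffnessMap], overlap_um: float = 0.0) -> StiffnessMap:
    """Laterally stitch 2-4 adjacent elastograms.

    Overlapping columns are averaged where both maps are valid and take
    the single valid value where only one is; the mask is the union.
    Matches the acquisition practice of scanning a large specimen field
    as 3-4 overlapping OCE images.
    """
    if not 2 <= len(maps) <= 4:
        raise ValidationError("stitching expects 2-4 maps")
    n_rows = maps[0].values_kpa.shape[0]
    px = maps[0].pixel_size_um
    for m in maps[1:]:
        if m.values_kpa.shape[0] != n_rows:
            raise ValidationError("maps must share the same depth extent")
        if tuple(m.pixel_size_um) != tuple(px):
            raise ValidationError("maps must share the same pixel size")
    ov = int(np.round(overlap_um / px[1]))
    if ov < 0 or any(ov >= m.values_kpa.shape[1] for m in maps):
        raise ValidationError("overlap must be non-negative and smaller than "
                              "each map width")
    width = sum(m.values_kpa.shape[1] for m in maps) - ov * (len(maps) - 1)
    acc = np.zeros((n_rows, width))
    cnt = np.zeros((n_rows, width), dtype=int)
    col = 0
    for m in maps:
        w = m.values_kpa.shape[1]
        sl = slice(col, col + w)
        acc[:, sl] += np.where(m.mask, m.values_kpa, 0.0)
        cnt[:, sl] += m.mask.astype(int)
        col += w - ov
    mask = cnt > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = np.where(mask, acc / np.maximum(cnt, 1), np.nan)
    stress = float(np.mean([m.standardization_stress_kpa for m in maps]))
    return StiffnessMap(vals, mask, stress, px, maps[0].reference_boundary_row)


def patient_mean_stiffness(features: list[SpectrumFeatures]) -> float:
    """Per-patient mean stiffness: mean of the per-image ROI means.

    Mirrors the acquisition protocol of quantifying three OCE images per
    patient and averaging.
    """
    if not features:
        raise ValidationError("need at least one image's features")
    return float(np.mean([f.mean_kpa for f in features]))
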