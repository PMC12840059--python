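"""Phase-sensitive interframe strain estimation.

The core of compression OCE: the phase difference between two complex
B-scans acquired one compression increment apart is proportional to the
interframe axial displacement, ``phi = 4 * pi * n * u / lambda0``; local
axial strain is the depth-derivative of displacement, estimated as the
least-squares slope of the (locally unwrapped) phase inside a sliding
window.

Phase differences are always computed by vector averaging: the complex
products ``b * conj(a)`` are averaged before taking the argument, never
the raw angles, so the estimate is amplitude-weighted and immune to
wrapping artefacts at the +-pi boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import correlate1d, uniform_filter, uniform_filter1d

from .exceptions import ValidationError
from .phantom import FrameStream

__all__ = [
    "PhaseDiffMap",
    "StrainMap",
    "interframe_phase_difference",
    "estimate_axial_strain",
    "estimate_strain_stream",
]

#: Minimum processing-window extent (um): one OCE resolution cell.
MIN_WINDOW_UM = 30.0


def _wrap(x: np.ndarray) -> np.ndarray:
    """Wrap angles to (-pi, pi]."""
    return np.pi - np.mod(np.pi - x, 2.0 * np.pi)


@dataclass
class PhaseDiffMap:
    """Interframe phase difference in (-pi, pi] with a [0, 1] quality map.

    ``quality`` is the magnitude of the window-averaged complex product
    normalized by the averaged magnitude product (a local coherence).
    """

    values_rad: np.ndarray
    quality: np.ndarray


@dataclass
class StrainMap:
    """Local axial strain for one compression increment.

    ``mask`` is True where the estimate is trusted (window quality above
    threshold, |strain| below the linearization limit, window fully
    inside the image).  ``quality`` is the aggregated window coherence.
    """

    values: np.ndarray
    window_um: tuple[float, float]
    mask: np.ndarray
    quality: np.ndarray


def interframe_phase_difference(frame_a: np.ndarray, frame_b: np.ndarray,
                                avg_window: tuple[int, int] = (1, 1)) -> PhaseDiffMap:
    """Vector-averaged phase difference between two complex B-scans.

    Parameters
    ----------
    frame_a, frame_b
        Complex B-scans of identical shape; ``frame_b`` is the later frame.
    avg_window
        Averaging window in pixels (axial, lateral), at least 1x1.

    Returns
    -------
    PhaseDiffMap
        ``arg`` of the window-averaged ``frame_b * conj(frame_a)``.
    """
    a = np.asarray(frame_a)
    b = np.asarray(frame_b)
    if a.shape != b.shape or a.ndim != 2:
        raise ValidationError("frames must be 2D arrays of identical shape")
    if min(avg_window) < 1:
        raise ValidationError("avg_window must be at least 1x1")
    prod = b * np.conj(a)
    re = uniform_filter(prod.real, avg_window, mode="nearest")
    im = uniform_filter(prod.imag, avg_window, mode="nearest")
    denom = uniform_filter(np.abs(a) * np.abs(b), avg_window, mode="nearest")
    mag = np.hypot(re, im)
    with np.errstate(invalid="ignore", divide="ignore"):
        quality = np.where(denom > 0, np.clip(mag / denom, 0.0, 1.0), 0.0)
    return PhaseDiffMap(np.arctan2(im, re), quality)


def _slope_diff_weights(n_ax: int) -> np.ndarray:
    """Weights turning adjacent phase differences into the least-squares
    slope of the unwrapped phase over an ``n_ax``-sample window.

    For samples ``phi_k = sum_{j<k} d_j`` the LS slope ``sum_k a_k phi_k``
    with ``a_k = (k - mean) / sum (k - mean)^2`` equals ``sum_j A_j d_j``
    with ``A_j = -cumsum(a)_j`` -- a tent-shaped, positive kernel summing
    to 1.
    """
    k = np.arange(n_ax, dtype=float)
    a = k - k.mean()
    a /= (a ** 2).sum()
    return -np.cumsum(a)[:-1]


def estimate_axial_strain(pd: PhaseDiffMap,
                          window_um: tuple[float, float] = (48.0, 50.0),
                          wavelength_um: float = 1.3,
                          refractive_index: float = 1.4,
                          pixel_size_um: tuple[float, float] = (4.0, 10.0),
                          quality_threshold: float = 0.3,
                          max_strain: float = 0.1) -> StrainMap:
    """Local axial strain from an interframe phase-difference map.

    Per pixel, strain is ``lambda0 / (4 pi n)`` times the quality-weighted
    least-squares slope of the locally unwrapped phase versus physical
    depth inside the sliding window.  Local unwrapping uses the wrapped
    adjacent-pixel differences, valid while the per-pixel phase gradient
    stays below pi (the simulator enforces this precondition).
    """
    dz, dx = pixel_size_um
    n_ax = int(round(window_um[0] / dz))
    n_lat = max(1, int(round(window_um[1] / dx)))
    if n_ax < 3:
        raise ValidationError("window must span >= 3 axial pixels")
    if min(window_um) < MIN_WINDOW_UM:
        raise ValidationError(
            f"processing window must be >= {MIN_WINDOW_UM:.0f} um "
            "(one resolution cell) in each direction")
    values = pd.values_rad
    quality = pd.quality
    n_rows, n_cols = values.shape
    if n_ax > n_rows or n_lat > n_cols:
        raise ValidationError("processing window larger than the image")

    d = _wrap(np.diff(values, axis=0))          # (n_rows-1, n_cols)
    w = quality[:-1] * quality[1:]
    tent = _slope_diff_weights(n_ax)

    num = correlate1d(w * d, tent, axis=0, mode="constant")
    den = correlate1d(w, tent, axis=0, mode="constant")
    with np.errstate(invalid="ignore", divide="ignore"):
        slope_px = np.where(den > 1e-12, num / np.where(den > 0, den, 1.0), 0.0)

    # lateral quality-weighted boxcar
    if n_lat > 1:
        num2 = uniform_filter1d(slope_px * den, n_lat, axis=1, mode="nearest")
        den2 = uniform_filter1d(den, n_lat, axis=1, mode="nearest")
        with np.errstate(invalid="ignore", divide="ignore"):
            slope_px = np.where(den2 > 1e-12,
                                num2 / np.where(den2 > 0, den2, 1.0), 0.0)
    else:
        den2 = den

    strain = slope_px / dz * wavelength_um / (4.0 * np.pi * refractive_index)

    # pad the diff grid (n_rows-1) back to the pixel grid
    full = np.empty((n_rows, n_cols))
    full[:-1] = strain
    full[-1] = strain[-1]
    qfull = np.empty((n_rows, n_cols))
    qfull[:-1] = np.clip(den2, 0.0, 1.0)
    qfull[-1] = qfull[-2]

    mask = (qfull >= quality_threshold) & (np.abs(full) < max_strain)
    edge = n_ax // 2
    mask[:edge] = False
    mask[-edge - 1:] = False
    return StrainMap(full, tuple(window_um), mask, qfull)


def estimate_strain_stream(stream: FrameStream,
                           avg_window: tuple[int, int] = (1, 1),
                           window_um: tuple[float, float] = (48.0, 50.0),
                           quality_threshold: float = 0.3) -> list[StrainMap]:
    """Strain maps for every consecutive frame pair of a stream."""
    acq = stream.acquisition
    out = []
    for k in range(len(stream) - 1):
        pd = interframe_phase_difference(stream.frames[k], stream.frames[k + 1],
                                         avg_window)
        out.append(estimate_axial_strain(
            pd, window_um, acq.central_wavelength_um, acq.refractive_index,
            acq.pixel_size_um, quality_threshold))
    return out
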