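"""Readers and writers for the pipeline's on-disk formats.

Conventions: elastograms and ground-truth fields are 32-bit float
multi-page TIFFs in kPa with masked pixels stored as NaN; frame streams
live in HDF5 with complex data as paired real/imag arrays; phantom specs
and map metadata are JSON sidecars carrying units and mask semantics.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

from .exceptions import ValidationError
from .elastography import StiffnessMap
from .phantom import (AcquisitionSpec, BackgroundLaw, FrameStream,
                      InclusionSpec, PhantomSpec, StiffnessField)
from .spectra import SpectrumFeatures, StiffnessSpectrum

__all__ = [
    "write_stiffness_tiff", "read_stiffness_tiff",
    "write_field_tiff", "read_field_tiff",
    "write_frame_stream", "read_frame_stream",
    "phantom_spec_to_json", "phantom_spec_from_json",
    "spectrum_to_csv", "features_to_csv",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_stiffness_tiff(path, smap: StiffnessMap) -> None:
    """Elastogram as float32 TIFF (kPa, NaN = masked out) + JSON sidecar."""
    path = Path(path)
    vals = np.where(smap.mask, smap.values_kpa, np.nan).astype(np.float32)
    tifffile.imwrite(path, vals)
    meta = {
        "units": "kPa",
        "mask_semantics": "NaN pixels failed stress standardization",
        "pixel_size_um": list(smap.pixel_size_um),
        "standardization_stress_kpa": smap.standardization_stress_kpa,
        "reference_boundary_row": smap.reference_boundary_row,
        "mask_fraction": smap.mask_fraction,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")


def read_stiffness_tiff(path) -> StiffnessMap:
    path = Path(path)
    vals = tifffile.imread(path).astype(float)
    side = _sidecar(path)
    if side.exists():
        meta = json.loads(side.read_text())
        px = tuple(meta["pixel_size_um"])
        stress = float(meta["standardization_stress_kpa"])
        boundary = meta.get("reference_boundary_row")
    else:
        px, stress, boundary = (4.0, 10.0), math.nan, None
    mask = np.isfinite(vals)
    return StiffnessMap(np.where(mask, vals, np.nan), mask, stress, px, boundary)


def write_field_tiff(path, field: StiffnessField) -> None:
    """Ground-truth stiffness field as float32 TIFF + sidecar."""
    path = Path(path)
    tifffile.imwrite(path, field.values_kpa.astype(np.float32))
    meta = {
        "units": "kPa",
        "pixel_size_um": list(field.pixel_size_um),
        "reference_boundary_row": field.reference_boundary_row,
        "reference_stiffness_kpa": field.reference_stiffness_kpa,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")


def read_field_tiff(path) -> StiffnessField:
    path = Path(path)
    vals = tifffile.imread(path).astype(float)
    meta = json.loads(_sidecar(path).read_text())
    return StiffnessField(vals, tuple(meta["pixel_size_um"]),
                          int(meta["reference_boundary_row"]),
                          float(meta["reference_stiffness_kpa"]))


def write_frame_stream(path, stream: FrameStream) -> None:
    """Frame stream as HDF5: frames/{real,imag}, acquisition attrs,
    optional ground truth."""
    with h5py.File(path, "w") as h5:
        g = h5.create_group("frames")
        g.create_dataset("real", data=stream.frames.real, compression="gzip")
        g.create_dataset("imag", data=stream.frames.imag, compression="gzip")
        acq = h5.create_group("acquisition")
        for k, v in dataclasses.asdict(stream.acquisition).items():
            acq.attrs[k] = v
        if stream.truth is not None:
            t = h5.create_group("truth")
            t.create_dataset("values_kpa", data=stream.truth.values_kpa,
                             compression="gzip")
            t.attrs["pixel_size_um"] = stream.truth.pixel_size_um
            t.attrs["reference_boundary_row"] = stream.truth.reference_boundary_row
            t.attrs["reference_stiffness_kpa"] = stream.truth.reference_stiffness_kpa


def read_frame_stream(path) -> FrameStream:
    with h5py.File(path, "r") as h5:
        frames = h5["frames/real"][...] + 1j * h5["frames/imag"][...]
        a = dict(h5["acquisition"].attrs)
        acq = AcquisitionSpec(
            per_step_surface_displacement_um=float(a["per_step_surface_displacement_um"]),
            n_steps=int(a["n_steps"]),
            central_wavelength_um=float(a["central_wavelength_um"]),
            refractive_index=float(a["refractive_index"]),
            pixel_size_um=tuple(a["pixel_size_um"]),
            phase_noise_sd_rad=float(a["phase_noise_sd_rad"]),
            speckle=bool(a["speckle"]))
        truth = None
        if "truth" in h5:
            t = h5["truth"]
            truth = StiffnessField(t["values_kpa"][...],
                                   tuple(t.attrs["pixel_size_um"]),
                                   int(t.attrs["reference_boundary_row"]),
                                   float(t.attrs["reference_stiffness_kpa"]))
    return FrameStream(frames, acq, truth)


def phantom_spec_to_json(spec: PhantomSpec) -> str:
    d = dataclasses.asdict(spec)
    return json.dumps(d, indent=2, sort_keys=True)


def phantom_spec_from_json(text: str) -> PhantomSpec:
    d = json.loads(text)
    d["background_distribution"] = BackgroundLaw(**d["background_distribution"])
    if d.get("inclusion_spec") is not None:
        inc = d["inclusion_spec"]
        inc["modulus_range_kpa"] = tuple(inc["modulus_range_kpa"])
        inc["diameter_range_um"] = tuple(inc["diameter_range_um"])
        d["inclusion_spec"] = InclusionSpec(**inc)
    d["pixel_size_um"] = tuple(d["pixel_size_um"])
    if d.get("band_targets") is not None:
        d["band_targets"] = tuple(d["band_targets"])
    spec = PhantomSpec(**d)
    spec.validate()
    return spec


def spectrum_to_csv(path, spectrum: StiffnessSpectrum, sample_id: str) -> None:
    df = pd.DataFrame({
        "sample_id": sample_id,
        "bin_left": spectrum.bin_edges_kpa[:-1],
        "bin_right": spectrum.bin_edges_kpa[1:],
        "fraction": spectrum.fractions,
    })
    df.to_csv(path, index=False)


def features_to_csv(path, rows: list[dict]) -> None:
    pd.DataFrame(rows).to_csv(path, index=False)
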