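"""End-to-end pipeline: phantom or acquired data to classification.

``run_pipeline`` ties the stages together: simulate (or load) a frame
stream, reconstruct the stress-standardized elastogram, extract the
analysis ROI, compute the stiffness spectrum and its features, classify
the tissue and predict the islet-yield category, and write every product
plus a provenance record.  Given identical inputs and seeds the outputs
are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .classify import ClassifierThresholds, classify_tissue, predict_islet_yield
from .elastography import ReferenceCurve, StiffnessMap, standardized_stiffness_map
from .exceptions import ValidationError
from .io import (features_to_csv, read_frame_stream, read_stiffness_tiff,
                 spectrum_to_csv, write_field_tiff, write_frame_stream,
                 write_stiffness_tiff)
from .phantom import (TISSUE_TYPES, FrameStream, default_acquisition,
                      make_stiffness_field, phantom_preset,
                      simulate_frame_stream)
from .spectra import (default_bin_edges, default_roi, extract_roi,
                      spectrum_features, stiffness_spectrum)

__all__ = ["PipelineConfig", "run_preset", "analyze_map", "run_pipeline"]

PRESET_NAMES = tuple(t for t in TISSUE_TYPES if t != "custom")


@dataclass
class PipelineConfig:
    """All tunable pipeline constants in one validated place."""

    # stress standardization
    target_stress_kpa: float = 2.0
    half_window_kpa: float = 1.0
    reference_modulus_kpa: float = 100.0
    # simulated acquisition
    step_stress_kpa: float = 0.25
    n_frames: int = 17
    phase_noise_sd_rad: float = 0.1
    speckle: bool = True
    # strain estimation
    avg_window: tuple[int, int] = (1, 1)
    strain_window_um: tuple[float, float] = (48.0, 50.0)
    quality_threshold: float = 0.3
    # analysis ROI and spectra
    roi_depth_um: float = 350.0
    roi_width_um: float = 3200.0
    roi_offset_um: float = 48.0
    bin_width_kpa: float = 25.0
    modulus_floor_kpa: float = 1.0
    modulus_ceiling_kpa: float = 1000.0
    # classification / yield
    yield_range_kpa: tuple[float, float] = (75.0, 150.0)
    classifier: ClassifierThresholds = field(default_factory=ClassifierThresholds)
    # randomness
    seed: int = 1

    def validate(self) -> None:
        if self.half_window_kpa <= 0 or self.target_stress_kpa <= self.half_window_kpa:
            raise ValidationError("stress window must be positive and must not "
                                  "reach down to zero stress")
        if self.step_stress_kpa <= 0 or self.n_frames < 2:
            raise ValidationError("invalid acquisition settings")
        if not 0 <= self.quality_threshold <= 1:
            raise ValidationError("quality threshold must be in [0, 1]")
        if self.yield_range_kpa[0] >= self.yield_range_kpa[1]:
            raise ValidationError("yield range must be increasing")
        if self.modulus_floor_kpa <= 0 or self.modulus_ceiling_kpa <= self.modulus_floor_kpa:
            raise ValidationError("modulus floor/ceiling inconsistent")
        default_bin_edges(self.bin_width_kpa, self.modulus_ceiling_kpa)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "classifier" in d and isinstance(d["classifier"], dict):
            c = d["classifier"]
            if "islet_rich_stiff_range" in c:
                c["islet_rich_stiff_range"] = tuple(c["islet_rich_stiff_range"])
            d["classifier"] = ClassifierThresholds(**c)
        for k in ("avg_window", "strain_window_um", "yield_range_kpa"):
            if k in d:
                d[k] = tuple(d[k])
        cfg = cls(**d)
        cfg.validate()
        return cfg


def simulate_preset_stream(preset: str, seed: int,
                           config: PipelineConfig | None = None) -> FrameStream:
    """Phantom field + simulated frame stream for a preset and seed."""
    config = config or PipelineConfig()
    ss = np.random.SeedSequence(seed)
    field_seed, stream_seed = (int(s) & 0x7FFFFFFF for s in ss.generate_state(2))
    spec = phantom_preset(preset, rng_seed=field_seed)
    truth = make_stiffness_field(spec)
    acq = default_acquisition(truth, config.step_stress_kpa, config.n_frames,
                              phase_noise_sd_rad=config.phase_noise_sd_rad,
                              speckle=config.speckle)
    return simulate_frame_stream(truth, acq, stream_seed)


def reconstruct(stream: FrameStream,
                config: PipelineConfig | None = None) -> StiffnessMap:
    config = config or PipelineConfig()
    return standardized_stiffness_map(
        stream,
        ReferenceCurve.linear(config.reference_modulus_kpa),
        config.target_stress_kpa, config.half_window_kpa,
        avg_window=config.avg_window, window_um=config.strain_window_um,
        quality_threshold=config.quality_threshold,
        modulus_floor_kpa=config.modulus_floor_kpa,
        modulus_ceiling_kpa=config.modulus_ceiling_kpa)


def analyze_map(smap: StiffnessMap, config: PipelineConfig | None = None):
    """ROI extraction, spectrum, features, classification, yield."""
    config = config or PipelineConfig()
    roi = extract_roi(smap, default_roi(smap, config.roi_depth_um,
                                        config.roi_width_um,
                                        config.roi_offset_um))
    spectrum = stiffness_spectrum(
        roi, default_bin_edges(config.bin_width_kpa, config.modulus_ceiling_kpa))
    feats = spectrum_features(spectrum)
    tissue = classify_tissue(feats, config.classifier)
    yld = predict_islet_yield(feats.mean_kpa, config.yield_range_kpa)
    return roi, spectrum, feats, tissue, yld


def run_preset(preset: str, seed: int, config: PipelineConfig | None = None):
    """Full phantom pipeline for one preset/seed; returns all stage outputs."""
    config = config or PipelineConfig()
    stream = simulate_preset_stream(preset, seed, config)
    smap = reconstruct(stream, config)
    roi, spectrum, feats, tissue, yld = analyze_map(smap, config)
    return {"stream": stream, "map": smap, "roi": roi, "spectrum": spectrum,
            "features": feats, "tissue": tissue, "yield": yld}


def _features_row(sample_id, feats, tissue, yld) -> dict:
    return {
        "sample_id": sample_id,
        "p_soft": feats.p_soft, "p_mid": feats.p_mid, "p_stiff": feats.p_stiff,
        "mean_kpa": feats.mean_kpa, "median_kpa": feats.median_kpa,
        "n_pixels": feats.n_pixels,
        "label": tissue.label,
        "yield_category": yld.category,
        "yield_bound_pcs_per_g": yld.bound_pcs_per_g,
    }


def run_pipeline(config: PipelineConfig, input_spec: str, out_dir) -> dict:
    """Run the pipeline on a preset name, a frame-stream HDF5 file, or a
    pre-computed stiffness-map TIFF; write products to ``out_dir``.

    Returns a dict of output paths.  Idempotent: identical inputs and
    seeds produce byte-identical CSV/JSON outputs.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sample_id = Path(str(input_spec)).stem

    smap = None
    stream = None
    if str(input_spec) in PRESET_NAMES:
        stream = simulate_preset_stream(str(input_spec), config.seed, config)
        write_frame_stream(out / "stream.h5", stream)
        if stream.truth is not None:
            write_field_tiff(out / "truth.tif", stream.truth)
    else:
        path = Path(input_spec)
        if not path.exists():
            raise ValidationError(f"input {input_spec!r} is neither a preset "
                                  f"({', '.join(PRESET_NAMES)}) nor a file")
        if path.suffix in (".h5", ".hdf5"):
            stream = read_frame_stream(path)
        elif path.suffix in (".tif", ".tiff"):
            smap = read_stiffness_tiff(path)
        else:
            raise ValidationError(f"unrecognized input format {path.suffix!r}")

    if smap is None:
        smap = reconstruct(stream, config)
    _, spectrum, feats, tissue, yld = analyze_map(smap, config)

    paths = {
        "elastogram": out / "elastogram.tif",
        "spectrum": out / "spectrum.csv",
        "features": out / "features.csv",
        "classification": out / "classification.csv",
        "provenance": out / "provenance.json",
    }
    write_stiffness_tiff(paths["elastogram"], smap)
    spectrum_to_csv(paths["spectrum"], spectrum, sample_id)
    row = _features_row(sample_id, feats, tissue, yld)
    features_to_csv(paths["features"],
                    [{k: row[k] for k in ("sample_id", "p_soft", "p_mid",
                                          "p_stiff", "mean_kpa", "median_kpa",
                                          "n_pixels")}])
    features_to_csv(paths["classification"], [row])

    cfg_json = json.dumps(config.to_dict(), sort_keys=True)
    prov = {
        "input": str(input_spec),
        "seed": config.seed,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "config": config.to_dict(),
        "panoce_version": __version__,
        "standardization_stress_kpa": smap.standardization_stress_kpa,
        "mask_fraction": smap.mask_fraction,
    }
    paths["provenance"].write_text(json.dumps(prov, indent=2, sort_keys=True) + "\n")
    return {k: str(v) for k, v in paths.items()}
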