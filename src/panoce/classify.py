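"""Rule-based tissue classification and islet-yield prediction.

The four morphological classes of pancreatectomy specimens have
distinctive stiffness-spectrum signatures:

* **PDAC** -- almost all pixels above 250 kPa;
* **islet-poor parenchyma** -- almost all pixels below 100 kPa;
* **islet-rich parenchyma** -- soft background with a small but distinct
  stiff fraction (the islets);
* **fibrotic parenchyma** -- mid-band stiffness predominates.

Yield prediction is a two-threshold rule on the mean ROI stiffness: the
optimal range for efficient islet isolation is 75-150 kPa (high yield,
>= 120 islets per gram of digested tissue); stiffer samples (fibrosis or
tumour invasion) and softer samples (acinar tissue devoid of islets)
both give low yield (<= 110 pcs/g).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .exceptions import ValidationError
from .spectra import SpectrumFeatures

__all__ = [
    "ClassifierThresholds",
    "TissueClass",
    "YieldPrediction",
    "classify_tissue",
    "predict_islet_yield",
]


@dataclass(frozen=True)
class ClassifierThresholds:
    """Operational cut-offs of the rule-based classifier.

    Derived from the printed group spectra: PDAC exceeds 95 % stiff
    pixels, islet-poor parenchyma reaches 90 % soft pixels, islet-rich
    parenchyma shows a few-to-twenty percent stiff fraction on a soft
    (>= 25 %) background.
    """

    pdac_stiff_min: float = 0.95          # strict >
    islet_poor_soft_min: float = 0.90     # inclusive >=
    islet_rich_stiff_range: tuple[float, float] = (0.02, 0.20)
    islet_rich_soft_min: float = 0.25


@dataclass
class TissueClass:
    """Classification outcome with the trace of fired rules."""

    label: str
    features: SpectrumFeatures
    rule_trace: list[str] = field(default_factory=list)


@dataclass
class YieldPrediction:
    """Islet-yield category with the corresponding printed bound.

    ``high`` carries a lower bound of 120 pcs/g; ``low`` an upper bound
    of 110 pcs/g.  No continuous yield model is attempted.
    """

    category: str
    bound_pcs_per_g: float
    mean_stiffness_kpa: float


def classify_tissue(f: SpectrumFeatures,
                    thresholds: ClassifierThresholds | None = None) -> TissueClass:
    """Classify a sample from its spectrum features.

    Rules fire in a fixed order (PDAC, islet-poor, islet-rich, fibrotic
    fallback) so every feature vector receives exactly one label.
    """
    t = thresholds or ClassifierThresholds()
    trace: list[str] = []

    rule = (f"pdac: p_stiff={f.p_stiff:.3f} > {t.pdac_stiff_min}")
    if f.p_stiff > t.pdac_stiff_min:
        trace.append(rule + " -> fired")
        return TissueClass("pdac", f, trace)
    trace.append(rule + " -> no")

    rule = (f"islet_poor: p_soft={f.p_soft:.3f} >= {t.islet_poor_soft_min}")
    if f.p_soft >= t.islet_poor_soft_min:
        trace.append(rule + " -> fired")
        return TissueClass("islet_poor", f, trace)
    trace.append(rule + " -> no")

    lo, hi = t.islet_rich_stiff_range
    rule = (f"islet_rich: {lo} <= p_stiff={f.p_stiff:.3f} <= {hi} "
            f"and p_soft={f.p_soft:.3f} >= {t.islet_rich_soft_min}")
    if lo <= f.p_stiff <= hi and f.p_soft >= t.islet_rich_soft_min:
        trace.append(rule + " -> fired")
        return TissueClass("islet_rich", f, trace)
    trace.append(rule + " -> no")

    trace.append("fibrotic: fallback -> fired")
    return TissueClass("fibrotic", f, trace)


def predict_islet_yield(mean_stiffness_kpa: float,
                        optimal_range_kpa: tuple[float, float] = (75.0, 150.0)
                        ) -> YieldPrediction:
    """Predict the islet-yield category from mean ROI stiffness.

    Mean stiffness inside the optimal range (boundaries inclusive) maps
    to the high-yield category (>= 120 pcs/g); anything outside -- too
    stiff (fibrosis/PDAC) or too soft (islet-poor acinar tissue) -- maps
    to low yield (<= 110 pcs/g).
    """
    if not mean_stiffness_kpa > 0:
        raise ValidationError("mean stiffness must be positive")
    lo, hi = optimal_range_kpa
    if lo <= mean_stiffness_kpa <= hi:
        return YieldPrediction("high", 120.0, mean_stiffness_kpa)
    return YieldPrediction("low", 110.0, mean_stiffness_kpa)
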