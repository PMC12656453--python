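"""Hakanson potential ecological risk.

Single-element risk weights the single-factor index by an element-specific
toxic response factor, E_r = T_r * C / S, and the integrated risk RI of a
sample is the sum of its E_r values over all assessed elements.  With the
standard factors (Hg 40, Cd 30, As 10, Pb/Ni/Cu 5, Cr 2, Zn 1) a soil
exactly at background scores RI = 98.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .indices import _require_positive, single_factor
from .registry import ClassificationScale, Registry, ValidationError
from .samples import SampleSet


def eri(toxic_response, conc, screening):
    """Single-element potential ecological risk E_r = T_r * conc / screening."""
    t = _require_positive("toxic_response", toxic_response)
    return t * single_factor(conc, screening)


def integrated_ri(eri_vector) -> float:
    """Integrated potential ecological risk RI = sum of E_r over elements."""
    arr = np.asarray(eri_vector, dtype=float)
    if arr.size == 0:
        raise ValidationError("integrated_ri needs a non-empty E_r vector")
    return float(arr.sum())


def risk_class_proportions(values, scale: ClassificationScale) -> pd.Series:
    """Percentage of samples falling in each class of ``scale``.

    Only classes that occur are reported; percentages sum to 100.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValidationError("need at least one sample")
    labels = pd.Series([scale.classify(v) for v in values])
    counts = labels.value_counts()
    out = 100.0 * counts / values.size
    out.index.name = scale.name
    return out


@dataclass(frozen=True)
class EcoRiskTable:
    """Per-sample Hakanson risk results for a survey."""

    eri: pd.DataFrame          # sample x element E_r
    ri: pd.Series              # per-sample RI
    eri_class: pd.DataFrame
    ri_class: pd.Series

    def element_summary(self) -> pd.DataFrame:
        """Per-element mean E_r (the last columns of a Hakanson summary)."""
        out = pd.DataFrame({"eri_mean": self.eri.mean()})
        out.index.name = "element"
        return out

    def ri_class_proportions(self) -> pd.Series:
        counts = self.ri_class.value_counts()
        return 100.0 * counts / counts.sum()


def compute_eco_risk(samples: SampleSet, registry: Registry) -> EcoRiskTable:
    """Evaluate E_r per sample/element and RI per sample, with classes."""
    conc = samples.concentrations
    toxic = np.array(
        [registry.element(el).toxic_response for el in samples.elements]
    )
    screening = np.array(
        [registry.element(el).screening for el in samples.elements]
    )
    eri_df = pd.DataFrame(
        eri(toxic, conc.to_numpy(), screening),
        index=conc.index, columns=conc.columns,
    )
    ri = eri_df.sum(axis=1)
    ri.name = "ri"
    eri_scale = registry.scale("eri")
    ri_scale = registry.scale("ri")
    return EcoRiskTable(
        eri=eri_df,
        ri=ri,
        eri_class=eri_df.map(eri_scale.classify),
        ri_class=ri.map(ri_scale.classify),
    )
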