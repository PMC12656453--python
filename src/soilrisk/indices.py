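"""Pollution indices: geoaccumulation, single-factor, and Nemerow composite.

The geoaccumulation index compares a measured concentration C_n against
1.5 times its geochemical background B_n on a log2 scale,

    I_geo = log2(C_n / (1.5 * B_n)),

the single-factor index is the plain ratio P_i = C_i / S_i against a
screening value, and the Nemerow comprehensive index for one sample
combines the per-element single-factor indices with extra weight on the
worst element,

    P_N = sqrt((P_max^2 + P_avg^2) / 2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .registry import Registry, ValidationError
from .samples import SampleSet


def _require_positive(name: str, value) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
        raise ValidationError(f"{name} must be finite and > 0")
    return arr


def igeo(conc, background):
    """Geoaccumulation index I_geo = log2(conc / (1.5 * background)).

    Accepts scalars or arrays (broadcast); both inputs must be positive.
    Unbounded, monotone increasing in ``conc``; 0 at conc = 1.5*background.
    """
    c = _require_positive("conc", conc)
    b = _require_positive("background", background)
    return np.log2(c / (1.5 * b))


def single_factor(conc, screening):
    """Single-factor pollution index P_i = conc / screening."""
    c = _require_positive("conc", conc)
    s = _require_positive("screening", screening)
    return c / s


def nemerow(pi_vector) -> float:
    """Nemerow comprehensive index of one sample's single-factor indices.

    P_N = sqrt((max^2 + mean^2) / 2); satisfies
    max(P_max, P_avg)/sqrt(2) <= P_N <= P_max.
    """
    pi = np.asarray(pi_vector, dtype=float)
    if pi.size == 0:
        raise ValidationError("nemerow needs a non-empty index vector")
    _require_positive("pi_vector", pi)
    p_max = pi.max()
    p_avg = pi.mean()
    return float(np.sqrt((p_max**2 + p_avg**2) / 2.0))


@dataclass(frozen=True)
class IndexTable:
    """Per-sample pollution-index results.

    ``igeo`` and ``pi`` are sample x element DataFrames, ``pn`` a per-sample
    Series; the ``*_class`` members carry the corresponding labels.
    """

    igeo: pd.DataFrame
    pi: pd.DataFrame
    pn: pd.Series
    igeo_class: pd.DataFrame
    pi_class: pd.DataFrame
    pn_class: pd.Series

    def element_summary(self) -> pd.DataFrame:
        """Per-element mean I_geo / P_i with class labels.

        Means are means of the per-sample indices (so the mean I_geo is the
        mean of logs, not the log of the mean concentration).
        """
        out = pd.DataFrame(
            {"igeo_mean": self.igeo.mean(), "pi_mean": self.pi.mean()}
        )
        out.index.name = "element"
        return out

    def nemerow_class_proportions(self) -> pd.Series:
        """Percentage of samples per Nemerow class (sums to 100)."""
        counts = self.pn_class.value_counts()
        return 100.0 * counts / counts.sum()


def compute_indices(samples: SampleSet, registry: Registry) -> IndexTable:
    """Evaluate all three indices and their classifications for a survey.

    I_geo uses each element's background; P_i its screening value (equal to
    the background unless overridden).  Class labels come from the registry's
    ``igeo``, ``single_factor`` and ``nemerow`` scales, with values exactly on
    a breakpoint resolving to the lower class.
    """
    conc = samples.concentrations
    background = pd.Series(
        {el: registry.element(el).background for el in samples.elements}
    )
    screening = pd.Series(
        {el: registry.element(el).screening for el in samples.elements}
    )
    igeo_df = pd.DataFrame(
        igeo(conc.to_numpy(), background.to_numpy()),
        index=conc.index, columns=conc.columns,
    )
    pi_df = pd.DataFrame(
        single_factor(conc.to_numpy(), screening.to_numpy()),
        index=conc.index, columns=conc.columns,
    )
    pn = pi_df.apply(lambda row: nemerow(row.to_numpy()), axis=1)
    pn.name = "pn"

    igeo_scale = registry.scale("igeo")
    pi_scale = registry.scale("single_factor")
    pn_scale = registry.scale("nemerow")
    return IndexTable(
        igeo=igeo_df,
        pi=pi_df,
        pn=pn,
        igeo_class=igeo_df.map(igeo_scale.classify),
        pi_class=pi_df.map(pi_scale.classify),
        pn_class=pn.map(pn_scale.classify),
    )
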