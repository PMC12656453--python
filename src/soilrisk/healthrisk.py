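"""USEPA three-pathway human health risk engine.

Average daily doses (ADD, mg/kg/day) from incidental soil ingestion,
dermal contact, and inhalation of resuspended particles:

    ADD_ing = C * IngR * EF * ED / (BW * AT) * 1e-6
    ADD_der = C * SA * AF * ABS * EF * ED / (BW * AT) * 1e-6
    ADD_inh = C * InhR * EF * ED / (PEF * BW * AT)

with AT the carcinogenic averaging time for cancer risk and ED*365 for
non-carcinogenic risk.  The inhalation dose carries no 1e-6 factor: the
particle emission factor PEF (m3/kg) performs the mass conversion.

Non-carcinogenic risk: HQ = ADD / RfD per metal-pathway, HI = sum of HQ.
Carcinogenic risk: CR = ADD * SF per carcinogen-pathway, TCR = sum of CR.
A pathway with no reference dose or slope factor in the registry
contributes exactly zero and is reported as absent (NaN) in the tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .indices import _require_positive
from .registry import COHORTS, PATHWAYS, ExposureProfile, Registry, ValidationError
from .samples import SampleSet

logger = logging.getLogger(__name__)


def _averaging_time(profile: ExposureProfile, carcinogenic: bool) -> float:
    return profile.at_ca if carcinogenic else profile.at_nc


def add_ingestion(conc, profile: ExposureProfile, carcinogenic: bool = False):
    """ADD from incidental soil ingestion, mg/kg/day."""
    c = _require_positive("conc", conc)
    at = _averaging_time(profile, carcinogenic)
    return c * profile.ing_rate * profile.ef * profile.ed / (profile.bw * at) * 1e-6


def add_dermal(conc, profile: ExposureProfile, carcinogenic: bool = False):
    """ADD from dermal contact with soil, mg/kg/day."""
    c = _require_positive("conc", conc)
    at = _averaging_time(profile, carcinogenic)
    return (
        c * profile.sa * profile.af * profile.abs * profile.ef * profile.ed
        / (profile.bw * at) * 1e-6
    )


def add_inhalation(conc, profile: ExposureProfile, carcinogenic: bool = False):
    """ADD from inhalation of resuspended soil particles, mg/kg/day."""
    c = _require_positive("conc", conc)
    at = _averaging_time(profile, carcinogenic)
    return (
        c * profile.inh_rate * profile.ef * profile.ed
        / (profile.pef * profile.bw * at)
    )


_ADD_BY_PATHWAY = {
    "ingestion": add_ingestion,
    "dermal": add_dermal,
    "inhalation": add_inhalation,
}


def hazard_quotient(add, rfd) -> float:
    """Non-carcinogenic hazard quotient HQ = ADD / RfD."""
    if rfd is None or rfd <= 0:
        raise ValidationError("rfd must be > 0")
    return np.asarray(add, dtype=float) / rfd


def cancer_risk(add, sf) -> float:
    """Carcinogenic risk CR = ADD * SF."""
    if sf is None or sf <= 0:
        raise ValidationError("sf must be > 0")
    return np.asarray(add, dtype=float) * sf


def hazard_index(hq_values) -> float:
    """Hazard index: the sum of hazard quotients over metals and pathways."""
    arr = np.asarray(hq_values, dtype=float)
    if arr.size == 0:
        raise ValidationError("hazard_index needs at least one HQ")
    return float(arr.sum())


def total_cancer_risk(cr_values) -> float:
    """Total carcinogenic risk: the sum of CR over carcinogens and pathways."""
    arr = np.asarray(cr_values, dtype=float)
    if arr.size == 0:
        raise ValidationError("total_cancer_risk needs at least one CR")
    return float(arr.sum())


@dataclass(frozen=True)
class HealthRiskTable:
    """Per-metal x pathway x cohort risk tables.

    ``hq`` and ``cr`` have metals as rows and a (cohort, pathway|Total)
    MultiIndex on columns; absent pathways (no RfD/SF) are NaN.  ``hi`` and
    ``tcr`` are per-cohort totals; ``hq_contribution``/``cr_contribution``
    give each pathway's percentage share of the cohort total.
    """

    add_nc: pd.DataFrame
    add_ca: pd.DataFrame
    hq: pd.DataFrame
    cr: pd.DataFrame
    hi: pd.Series
    tcr: pd.Series
    hq_contribution: pd.DataFrame
    cr_contribution: pd.DataFrame

    def formatted(self, which: str = "hq") -> pd.DataFrame:
        """Scientific-notation view (3 significant digits) of hq or cr."""
        table = {"hq": self.hq, "cr": self.cr}[which]
        return table.map(lambda v: "—" if pd.isna(v) else f"{v:.2e}")


def _conc_means(concentrations, registry: Registry) -> pd.Series:
    if isinstance(concentrations, SampleSet):
        return concentrations.mean_concentrations()
    means = pd.Series(concentrations, dtype=float)
    return means


def aggregate_health_risk(
    concentrations,
    registry: Registry,
    cohorts: Sequence[str] = COHORTS,
) -> HealthRiskTable:
    """Full non-carcinogenic and carcinogenic risk tables.

    ``concentrations`` is either a :class:`SampleSet` (risks are computed on
    the per-element mean concentrations, the conventional deterministic point
    estimate) or a mapping element -> mean concentration in mg/kg.
    """
    means = _conc_means(concentrations, registry)
    metals = [m for m in means.index]
    carcinogens = [m for m in metals if registry.element(m).is_carcinogen]
    if not carcinogens:
        logger.warning("no carcinogen in registry: TCR will be 0")

    cols = pd.MultiIndex.from_product(
        [cohorts, [*PATHWAYS, "Total"]], names=["cohort", "pathway"]
    )
    add_nc = pd.DataFrame(index=metals, columns=cols, dtype=float)
    add_ca = pd.DataFrame(index=metals, columns=cols, dtype=float)
    hq = pd.DataFrame(index=metals, columns=cols, dtype=float)
    cr = pd.DataFrame(index=carcinogens, columns=cols, dtype=float)

    for cohort in cohorts:
        profile = registry.cohorts[cohort]
        for metal in metals:
            params = registry.element(metal)
            conc = float(means[metal])
            for pathway in PATHWAYS:
                dose_fn = _ADD_BY_PATHWAY[pathway]
                add_nc.loc[metal, (cohort, pathway)] = dose_fn(conc, profile, False)
                add_ca.loc[metal, (cohort, pathway)] = dose_fn(conc, profile, True)
                rfd = params.rfd.get(pathway)
                if rfd is None:
                    logger.info(
                        "%s/%s: no RfD for %s, HQ contributes 0",
                        metal, cohort, pathway,
                    )
                else:
                    hq.loc[metal, (cohort, pathway)] = hazard_quotient(
                        add_nc.loc[metal, (cohort, pathway)], rfd
                    )
                if metal in carcinogens:
                    sf = params.sf.get(pathway)
                    if sf is not None:
                        cr.loc[metal, (cohort, pathway)] = cancer_risk(
                            add_ca.loc[metal, (cohort, pathway)], sf
                        )
        for table in (add_nc, add_ca, hq, cr):
            pathway_block = table.loc[:, (cohort, list(PATHWAYS))]
            table.loc[:, (cohort, "Total")] = pathway_block.sum(
                axis=1, min_count=1
            ).to_numpy()

    hi = pd.Series(
        {c: np.nansum(hq.loc[:, (c, "Total")].to_numpy()) for c in cohorts},
        name="HI",
    )
    tcr = pd.Series(
        {
            c: (np.nansum(cr.loc[:, (c, "Total")].to_numpy()) if len(cr) else 0.0)
            for c in cohorts
        },
        name="TCR",
    )

    def _contribution(table: pd.DataFrame, totals: pd.Series) -> pd.DataFrame:
        out = pd.DataFrame(index=list(PATHWAYS), columns=list(cohorts), dtype=float)
        for c in cohorts:
            for p in PATHWAYS:
                col = table.loc[:, (c, p)] if len(table) else pd.Series(dtype=float)
                s = np.nansum(col.to_numpy()) if len(table) else 0.0
                out.loc[p, c] = 100.0 * s / totals[c] if totals[c] > 0 else np.nan
        out.index.name = "pathway"
        return out

    return HealthRiskTable(
        add_nc=add_nc,
        add_ca=add_ca,
        hq=hq,
        cr=cr,
        hi=hi,
        tcr=tcr,
        hq_contribution=_contribution(hq, hi),
        cr_contribution=_contribution(cr, tcr),
    )


def per_sample_hazard_index(
    samples: SampleSet, registry: Registry, cohort: str = "adult"
) -> pd.Series:
    """Per-sample HI distribution (extra beyond the mean-based point estimate).

    HI is linear in the concentration vector, so each sample's HI is the dot
    product of its concentrations with the per-unit-concentration HQ
    coefficients.
    """
    profile = registry.cohorts[cohort]
    coeffs = {}
    for metal in samples.elements:
        params = registry.element(metal)
        total = 0.0
        for pathway in PATHWAYS:
            rfd = params.rfd.get(pathway)
            if rfd is not None:
                total += float(_ADD_BY_PATHWAY[pathway](1.0, profile, False)) / rfd
        coeffs[metal] = total
    coeffs = pd.Series(coeffs)
    out = samples.concentrations @ coeffs
    out.name = f"HI[{cohort}]"
    return out
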