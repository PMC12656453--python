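"""Configuration registry for the soil heavy-metal risk pipeline.

Every constant the pipeline consumes — geochemical background values,
Hakanson toxic response factors, reference doses and slope factors,
cohort exposure parameters, and classification scales — lives in this
registry.  Computation modules never hard-code any of them, so a survey
analysed against different regional backgrounds or exposure assumptions
only needs a different config file.

The built-in defaults target a North-China farmland survey around an
industrial aggregation area.  Background values are back-derived from
the study's published summary tables (mean concentration divided by mean
single-factor index); exposure and toxicity defaults are standard USEPA
values where those are consistent with the study's published risk
tables, and calibrated to those tables where the study's appendix values
were not published.  See docs/methods.md for the full derivation.
"""

from __future__ import annotations

import logging
from bisect import bisect_left
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import yaml

logger = logging.getLogger(__name__)

#: The eight elements every survey table must report, in canonical order.
CANONICAL_ELEMENTS: tuple[str, ...] = ("Pb", "Cd", "As", "Hg", "Cr", "Zn", "Cu", "Ni")

#: Exposure pathways of the three-pathway USEPA soil model.
PATHWAYS: tuple[str, ...] = ("ingestion", "inhalation", "dermal")

COHORTS: tuple[str, ...] = ("adult", "child")


class SchemaError(ValueError):
    """A table or config file does not have the required structure."""


class ValidationError(ValueError):
    """A value violates a domain invariant (e.g. non-positive concentration)."""


@dataclass(frozen=True)
class ElementParams:
    """Per-element constants.

    Parameters
    ----------
    background
        Geochemical background value B_n in mg/kg (regional survey mean).
    toxic_response
        Hakanson toxic response factor T_r (unitless ecotoxicity weight).
    screening
        Screening value S_i (mg/kg) used by the single-factor index; defaults
        to ``background`` when omitted — the two are distinct config slots.
    rfd
        Reference dose per pathway, mg/kg/day (missing pathway = no
        non-carcinogenic assessment for that pathway).
    sf
        Cancer slope factor per pathway, (mg/kg/day)^-1 (missing pathway =
        pathway absent from carcinogenic totals).
    """

    symbol: str
    background: float
    toxic_response: float
    screening: float | None = None
    rfd: Mapping[str, float] = field(default_factory=dict)
    sf: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.background <= 0:
            raise ValidationError(f"{self.symbol}: background must be > 0")
        if self.toxic_response <= 0:
            raise ValidationError(f"{self.symbol}: toxic_response must be > 0")
        if self.screening is None:
            object.__setattr__(self, "screening", self.background)
        elif self.screening <= 0:
            raise ValidationError(f"{self.symbol}: screening must be > 0")
        for name, table in (("rfd", self.rfd), ("sf", self.sf)):
            for pathway, value in table.items():
                if pathway not in PATHWAYS:
                    raise SchemaError(
                        f"{self.symbol}: unknown {name} pathway {pathway!r}"
                    )
                if value is not None and value <= 0:
                    raise ValidationError(
                        f"{self.symbol}: {name}[{pathway}] must be > 0"
                    )
        object.__setattr__(
            self, "sf", {k: v for k, v in self.sf.items() if v is not None}
        )

    @property
    def is_carcinogen(self) -> bool:
        """True iff at least one slope factor is defined."""
        return bool(self.sf)


@dataclass(frozen=True)
class ExposureProfile:
    """Cohort exposure parameters of the USEPA soil exposure-dose model.

    Units: ing_rate mg soil/day; inh_rate m3/day; ef days/year; ed years;
    bw kg; at_nc / at_ca days (averaging time for non-carcinogenic and
    carcinogenic effects); sa cm2 exposed skin; af mg/cm2/day soil-to-skin
    adherence; abs unitless dermal absorption fraction; pef m3/kg particle
    emission factor.
    """

    cohort: str
    ing_rate: float
    inh_rate: float
    ef: float
    ed: float
    bw: float
    at_nc: float
    at_ca: float
    sa: float
    af: float
    abs: float
    pef: float

    def __post_init__(self) -> None:
        for name in (
            "ing_rate", "inh_rate", "ef", "ed", "bw",
            "at_nc", "at_ca", "sa", "af", "abs", "pef",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{self.cohort}: {name} must be > 0")
        if self.abs > 1:
            raise ValidationError(f"{self.cohort}: abs must be <= 1")
        if self.ef > 365:
            raise ValidationError(f"{self.cohort}: ef must be <= 365 days/year")
        if self.at_nc < self.ed * 365 or self.at_ca < self.ed * 365:
            raise ValidationError(
                f"{self.cohort}: averaging times must be >= ed * 365 days"
            )


@dataclass(frozen=True)
class ClassificationScale:
    """An ordered set of breakpoints mapping a real index to a class label.

    The mapping is total and left-closed downwards: a value exactly at a
    breakpoint resolves to the *lower* class, i.e. class k covers
    (breakpoints[k-1], breakpoints[k]].
    """

    name: str
    breakpoints: tuple[float, ...]
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "breakpoints", tuple(self.breakpoints))
        object.__setattr__(self, "labels", tuple(self.labels))
        if any(nxt <= prev for prev, nxt in zip(self.breakpoints, self.breakpoints[1:])):
            raise ValidationError(f"{self.name}: breakpoints must strictly increase")
        if len(self.labels) != len(self.breakpoints) + 1:
            raise ValidationError(
                f"{self.name}: need len(breakpoints)+1 labels, got {len(self.labels)}"
            )

    def classify(self, value: float) -> str:
        """Label for ``value`` (boundary values fall in the lower class)."""
        return self.labels[bisect_left(self.breakpoints, value)]

    def index(self, value: float) -> int:
        """Ordinal class index (0 = lowest class)."""
        return bisect_left(self.breakpoints, value)


# --------------------------------------------------------------------------
# Defaults.  Backgrounds are back-derived from the study's summary tables
# (flagged "derived-default" when substituted); exposure/toxicity values are
# the calibrated registry documented in docs/methods.md.
# --------------------------------------------------------------------------

_DEFAULT_BACKGROUND = {
    "Pb": 19.93, "Cd": 0.111, "As": 10.0, "Hg": 0.0382,
    "Cr": 68.2, "Zn": 58.8, "Cu": 21.0, "Ni": 26.9,
}

_DEFAULT_TOXIC_RESPONSE = {
    "Hg": 40.0, "Cd": 30.0, "As": 10.0, "Pb": 5.0,
    "Ni": 5.0, "Cu": 5.0, "Cr": 2.0, "Zn": 1.0,
}

# Reference doses, mg/kg/day, per (ingestion, inhalation, dermal).
_DEFAULT_RFD = {
    "Pb": (3.5e-3, 5.25e-4, 3.5e-3),
    "Cd": (1.0e-3, 1.0e-5, 1.0e-5),
    "As": (3.0e-4, 3.01e-4, 1.23e-4),
    "Hg": (3.0e-4, 8.57e-5, 2.1e-5),
    "Cr": (3.0e-3, 2.86e-5, 2.5e-4),
    "Zn": (3.0e-1, 3.0e-1, 6.0e-2),
    "Cu": (4.0e-2, 4.0e-2, 1.2e-2),
    "Ni": (2.0e-2, 2.06e-2, 5.4e-3),
}

# Cancer slope factors, (mg/kg/day)^-1; None = pathway not assessed.
_DEFAULT_SF = {
    "Cd": (0.507, 6.3, 19.8),
    "As": (1.5, 15.1, 3.66),
    "Cr": (1.46, 122.5, None),
}

_DEFAULT_COHORTS = {
    "adult": dict(
        ing_rate=100.0, inh_rate=20.0, ef=250.0, ed=24.0, bw=70.0,
        at_nc=8760.0, at_ca=25550.0, sa=5075.0, af=0.2, abs=0.05,
        pef=1.36e9,
    ),
    "child": dict(
        ing_rate=53.0, inh_rate=2.1, ef=250.0, ed=6.0, bw=15.9,
        at_nc=2190.0, at_ca=6400.0, sa=2800.0, af=0.14, abs=0.05,
        pef=1.36e9,
    ),
}

_DEFAULT_SCALES = {
    # Mueller geoaccumulation classes.
    "igeo": (
        (0.0, 1.0, 2.0, 3.0, 4.0, 5.0),
        (
            "uncontaminated",
            "slightly contaminated",
            "moderately contaminated",
            "moderately to heavily contaminated",
            "heavily contaminated",
            "heavily to extremely contaminated",
            "extremely contaminated",
        ),
    ),
    "single_factor": (
        (1.0, 2.0, 3.0, 5.0),
        (
            "uncontaminated",
            "slightly contaminated",
            "moderately contaminated",
            "heavily contaminated",
            "severely contaminated",
        ),
    ),
    "nemerow": (
        (0.7, 1.0, 2.0, 3.0),
        ("safe", "warning", "light pollution", "moderate pollution", "heavy pollution"),
    ),
    "eri": (
        (40.0, 80.0, 160.0, 320.0),
        ("low risk", "moderate risk", "considerable risk", "high risk", "very high risk"),
    ),
    "ri": (
        (150.0, 300.0, 600.0),
        ("low risk", "moderate risk", "high risk", "severe risk"),
    ),
}


@dataclass(frozen=True)
class Registry:
    """The full constant registry consumed by every pipeline stage."""

    elements: Mapping[str, ElementParams]
    cohorts: Mapping[str, ExposureProfile]
    scales: Mapping[str, ClassificationScale]

    def element(self, symbol: str) -> ElementParams:
        try:
            return self.elements[symbol]
        except KeyError:
            raise SchemaError(f"no parameters registered for element {symbol!r}")

    def scale(self, name: str) -> ClassificationScale:
        try:
            return self.scales[name]
        except KeyError:
            raise SchemaError(f"no classification scale named {name!r}")

    @property
    def carcinogens(self) -> tuple[str, ...]:
        return tuple(s for s in self.elements if self.elements[s].is_carcinogen)


def default_registry() -> Registry:
    """The built-in registry (see module docstring and docs/methods.md)."""
    elements = {}
    for symbol in CANONICAL_ELEMENTS:
        rfd = dict(zip(PATHWAYS, _DEFAULT_RFD[symbol]))
        sf_row = _DEFAULT_SF.get(symbol)
        sf = (
            {p: v for p, v in zip(PATHWAYS, sf_row) if v is not None}
            if sf_row
            else {}
        )
        elements[symbol] = ElementParams(
            symbol=symbol,
            background=_DEFAULT_BACKGROUND[symbol],
            toxic_response=_DEFAULT_TOXIC_RESPONSE[symbol],
            rfd=rfd,
            sf=sf,
        )
    cohorts = {
        name: ExposureProfile(cohort=name, **params)
        for name, params in _DEFAULT_COHORTS.items()
    }
    scales = {
        name: ClassificationScale(name, breakpoints, labels)
        for name, (breakpoints, labels) in _DEFAULT_SCALES.items()
    }
    return Registry(elements=elements, cohorts=cohorts, scales=scales)


def _merge_element(base: ElementParams, overrides: Mapping) -> ElementParams:
    known = {"background", "toxic_response", "screening", "rfd", "sf"}
    unknown = set(overrides) - known
    if unknown:
        raise SchemaError(f"{base.symbol}: unknown element keys {sorted(unknown)}")
    updates: dict = {}
    for key in ("background", "screening"):
        if key in overrides:
            updates[key] = float(overrides[key])
    if "toxic_response" in overrides:
        updates["toxic_response"] = float(overrides["toxic_response"])
        logger.warning(
            "%s: toxic response factor overridden to %s (default %s)",
            base.symbol, updates["toxic_response"], base.toxic_response,
        )
    for key in ("rfd", "sf"):
        if key in overrides:
            table = dict(getattr(base, key))
            table.update({p: float(v) for p, v in overrides[key].items()})
            updates[key] = table
    return replace(base, **updates)


def load_config(path=None) -> Registry:
    """Load a YAML config on top of the defaults.

    The file has up to three sections — ``elements``, ``cohorts`` and
    ``scales`` — each a mapping keyed by element symbol, cohort name, or
    scale name.  Any parameter the file omits keeps its default; every
    such substitution is logged at DEBUG level, derived defaults at INFO.

    ``path=None`` (or an empty file) returns the full default registry.
    """
    registry = default_registry()
    for symbol in CANONICAL_ELEMENTS:
        logger.debug(
            "element %s: using derived-default background %.4g mg/kg",
            symbol, registry.elements[symbol].background,
        )
    if path is None:
        return registry

    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, Mapping):
        raise SchemaError("config root must be a mapping")
    unknown = set(raw) - {"elements", "cohorts", "scales"}
    if unknown:
        raise SchemaError(f"unknown config sections {sorted(unknown)}")

    elements = dict(registry.elements)
    for symbol, overrides in (raw.get("elements") or {}).items():
        if symbol not in elements:
            raise SchemaError(f"unknown element key {symbol!r} in config")
        elements[symbol] = _merge_element(elements[symbol], overrides or {})

    cohorts = dict(registry.cohorts)
    for name, overrides in (raw.get("cohorts") or {}).items():
        if name not in cohorts:
            raise SchemaError(f"unknown cohort {name!r} in config")
        base = cohorts[name]
        fields = {
            "ing_rate", "inh_rate", "ef", "ed", "bw",
            "at_nc", "at_ca", "sa", "af", "abs", "pef",
        }
        bad = set(overrides or {}) - fields
        if bad:
            raise SchemaError(f"{name}: unknown cohort keys {sorted(bad)}")
        cohorts[name] = replace(
            base, **{k: float(v) for k, v in (overrides or {}).items()}
        )

    scales = dict(registry.scales)
    for name, overrides in (raw.get("scales") or {}).items():
        overrides = overrides or {}
        base = scales.get(name)
        breakpoints = overrides.get(
            "breakpoints", base.breakpoints if base else None
        )
        labels = overrides.get("labels", base.labels if base else None)
        if breakpoints is None or labels is None:
            raise SchemaError(f"scale {name!r}: need breakpoints and labels")
        scales[name] = ClassificationScale(
            name, tuple(float(b) for b in breakpoints), tuple(labels)
        )

    return Registry(elements=elements, cohorts=cohorts, scales=scales)


def classify(value: float, scale: ClassificationScale) -> str:
    """Functional alias for :meth:`ClassificationScale.classify`."""
    return scale.classify(value)
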