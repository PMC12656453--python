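"""Georeferenced sample tables: ingest, validation, and descriptive statistics."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .registry import CANONICAL_ELEMENTS, SchemaError, ValidationError

logger = logging.getLogger(__name__)

_ID_COLUMN = "sample_id"
_COORD_COLUMNS = ("x", "y")


@dataclass(frozen=True)
class SampleSet:
    """A validated survey table: one row per soil sample.

    ``data`` holds columns ``sample_id``, ``x``, ``y`` and one concentration
    column (mg/kg) per element.  Coordinates are planar (projected meters)
    unless ``crs`` declares otherwise; distances downstream are Euclidean in
    the declared plane.
    """

    data: pd.DataFrame
    elements: tuple[str, ...] = CANONICAL_ELEMENTS
    extra_elements: tuple[str, ...] = ()
    crs: str = "local-meters"

    def __post_init__(self) -> None:
        df = self.data
        required = [_ID_COLUMN, *_COORD_COLUMNS, *CANONICAL_ELEMENTS]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise SchemaError(f"sample table missing columns: {missing}")
        if df[_ID_COLUMN].duplicated().any():
            dupes = df.loc[df[_ID_COLUMN].duplicated(), _ID_COLUMN].tolist()
            raise ValidationError(f"duplicate sample_id values: {dupes}")
        coords = df[list(_COORD_COLUMNS)].to_numpy(dtype=float)
        if not np.isfinite(coords).all():
            raise ValidationError("non-finite coordinates")
        if pd.DataFrame(coords).duplicated().any():
            logger.warning("duplicate coordinate pairs present in sample table")
        all_elements = (*self.elements, *self.extra_elements)
        for element in all_elements:
            col = pd.to_numeric(df[element], errors="coerce")
            bad = ~np.isfinite(col) | (col <= 0)
            if bad.any():
                row = df.index[bad][0]
                raise ValidationError(
                    f"non-positive or non-numeric concentration: "
                    f"element {element!r}, row {row} "
                    f"(sample {df.loc[row, _ID_COLUMN]!r})"
                )
        if self.extra_elements:
            logger.warning(
                "non-canonical elements present: %s", list(self.extra_elements)
            )

    def __len__(self) -> int:
        return len(self.data)

    @property
    def concentrations(self) -> pd.DataFrame:
        """Concentration block, columns in canonical element order."""
        return self.data[list(self.elements)].astype(float)

    @property
    def coordinates(self) -> np.ndarray:
        """(n, 2) array of x/y coordinates."""
        return self.data[list(_COORD_COLUMNS)].to_numpy(dtype=float)

    @property
    def sample_ids(self) -> pd.Series:
        return self.data[_ID_COLUMN]

    def mean_concentrations(self) -> pd.Series:
        return self.concentrations.mean()


def from_dataframe(df: pd.DataFrame, crs: str = "local-meters") -> SampleSet:
    """Build a :class:`SampleSet` from an in-memory table.

    Columns beyond ``sample_id``/``x``/``y`` and the eight canonical elements
    are treated as extra analyzed elements (kept and flagged).
    """
    df = df.copy()
    known = {_ID_COLUMN, *_COORD_COLUMNS, *CANONICAL_ELEMENTS}
    extra = tuple(c for c in df.columns if c not in known)
    for c in (*_COORD_COLUMNS, *[e for e in CANONICAL_ELEMENTS if e in df.columns]):
        df[c] = pd.to_numeric(df[c], errors="coerce")
    for c in extra:
        df[c] = pd.to_numeric(df[c], errors="coerce")
    df[_ID_COLUMN] = df[_ID_COLUMN].astype(str)
    return SampleSet(data=df.reset_index(drop=True), extra_elements=extra, crs=crs)


def read_samples(
    path,
    element_columns: Mapping[str, str] | None = None,
    crs: str = "local-meters",
) -> SampleSet:
    """Read a delimited (comma or tab) UTF-8 sample table.

    The header row must name ``sample_id``, ``x``, ``y`` and the element
    columns; ``element_columns`` maps canonical symbols to differently
    named file columns (e.g. ``{"Pb": "lead_mgkg"}``).  Row order is
    preserved; units are assumed mg/kg.
    """
    df = pd.read_csv(path, sep=None, engine="python", encoding="utf-8")
    if element_columns:
        df = df.rename(columns={v: k for k, v in element_columns.items()})
    return from_dataframe(df, crs=crs)


def write_samples(samples: SampleSet, path) -> None:
    """Write the standard comma-delimited sample table (read_samples inverse)."""
    samples.data.to_csv(path, index=False)


def summary_statistics(samples: SampleSet) -> pd.DataFrame:
    """Per-element descriptive statistics.

    Returns a DataFrame indexed by element with columns ``min``, ``max``,
    ``mean``, ``median``, ``sd``, ``cv_percent``.  The standard deviation
    uses the n-1 denominator and ``cv_percent = 100 * sd / mean``.
    """
    if len(samples) < 2:
        raise ValidationError("summary statistics need at least 2 samples")
    conc = samples.concentrations
    out = pd.DataFrame(
        {
            "min": conc.min(),
            "max": conc.max(),
            "mean": conc.mean(),
            "median": conc.median(),
            "sd": conc.std(ddof=1),
        }
    )
    out["cv_percent"] = 100.0 * out["sd"] / out["mean"]
    out.index.name = "element"
    return out
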