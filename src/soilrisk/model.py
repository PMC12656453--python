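"""Model/Results facade tying the pipeline stages together.

`SoilRiskModel` holds a validated survey plus the constant registry and
analysis settings; `fit()` runs the requested stages and returns a
`SoilRiskResults` bundle carrying every table the analysis produces — the
descriptive statistics, pollution-index and ecological-risk tables, the
health-risk tables for both cohorts, the correlation/PCA source screen,
and the interpolated composite-index surfaces — together with a run
manifest that makes a run reproducible (input/config hashes, seed,
stages, version).
"""

from __future__ import annotations

import hashlib
import io
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .ecorisk import EcoRiskTable, compute_eco_risk, risk_class_proportions
from .healthrisk import HealthRiskTable, aggregate_health_risk
from .indices import IndexTable, compute_indices
from .registry import Registry, SchemaError, default_registry, load_config
from .samples import SampleSet, read_samples, summary_statistics
from .sources import CorrelationResult, PcaResult, pca, pearson_matrix
from .spatial import RasterField, default_grid, idw_interpolate

STAGES: tuple[str, ...] = (
    "summary", "indices", "ecorisk", "healthrisk", "sources", "spatial",
)


class StageError(RuntimeError):
    """A pipeline stage failed; the message is tagged with the stage name."""


def _hash_samples(samples: SampleSet) -> str:
    payload = samples.data.to_csv(index=False).encode("utf-8")
    return hashlib.sha256(payload).hexdigest()


def _hash_registry(registry: Registry) -> str:
    payload = repr(
        (
            sorted(registry.elements.items()),
            sorted(registry.cohorts.items()),
            sorted(registry.scales.items()),
        )
    ).encode("utf-8")
    return hashlib.sha256(payload).hexdigest()


class SoilRiskModel:
    """A farmland-soil heavy-metal survey ready for risk analysis.

    Parameters
    ----------
    samples
        The validated survey (:class:`~soilrisk.samples.SampleSet`).
    registry
        Constant registry; default is the built-in calibrated registry.
    grid_size, idw_power
        Interpolation settings for the spatial stage.
    pca_retention, pca_rotate
        Component retention rule ("kaiser" or an integer) and optional
        "varimax" rotation for the source-apportionment stage.
    seed
        Recorded in the manifest (the analysis itself is deterministic;
        the seed documents which synthetic survey was analysed).
    """

    def __init__(
        self,
        samples: SampleSet,
        registry: Registry | None = None,
        grid_size: int = 100,
        idw_power: float = 2.0,
        pca_retention="kaiser",
        pca_rotate: str | None = None,
        seed: int | None = None,
    ) -> None:
        self.samples = samples
        self.registry = registry if registry is not None else default_registry()
        self.grid_size = grid_size
        self.idw_power = idw_power
        self.pca_retention = pca_retention
        self.pca_rotate = pca_rotate
        self.seed = seed

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "SoilRiskModel":
        from .samples import from_dataframe

        return cls(from_dataframe(df), **kwargs)

    @classmethod
    def from_table(cls, path, config=None, **kwargs) -> "SoilRiskModel":
        registry = load_config(config) if config is not None else None
        return cls(read_samples(path), registry=registry, **kwargs)

    def fit(self, stages: Sequence[str] | None = None) -> "SoilRiskResults":
        """Run the requested stages (default: all) and bundle the results."""
        stages = tuple(stages) if stages is not None else STAGES
        unknown = set(stages) - set(STAGES)
        if unknown:
            raise SchemaError(f"unknown stages {sorted(unknown)}")
        results = SoilRiskResults(
            model=self,
            stages=stages,
            manifest={
                "samples_sha256": _hash_samples(self.samples),
                "config_sha256": _hash_registry(self.registry),
                "seed": self.seed,
                "stages": list(stages),
                "n_samples": len(self.samples),
                "software": f"soilrisk {__version__}",
                "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S", time.gmtime()),
            },
        )
        for stage in stages:
            try:
                getattr(results, f"_run_{stage}")()
            except Exception as exc:  # pragma: no cover - message formatting
                raise StageError(f"[{stage}] {exc}") from exc
        return results


@dataclass
class SoilRiskResults:
    """Everything one `fit()` produced.  Attributes are None for stages
    that were not requested."""

    model: SoilRiskModel
    stages: tuple[str, ...]
    manifest: dict
    summary_stats: pd.DataFrame | None = None
    indices: IndexTable | None = None
    ecorisk: EcoRiskTable | None = None
    health: HealthRiskTable | None = None
    correlation: CorrelationResult | None = None
    pca: PcaResult | None = None
    fields: dict = field(default_factory=dict)

    # ---- stages -----------------------------------------------------------
    def _run_summary(self) -> None:
        self.summary_stats = summary_statistics(self.model.samples)

    def _run_indices(self) -> None:
        self.indices = compute_indices(self.model.samples, self.model.registry)

    def _run_ecorisk(self) -> None:
        self.ecorisk = compute_eco_risk(self.model.samples, self.model.registry)

    def _run_healthrisk(self) -> None:
        self.health = aggregate_health_risk(self.model.samples, self.model.registry)

    def _run_sources(self) -> None:
        self.correlation = pearson_matrix(self.model.samples)
        self.pca = pca(
            self.model.samples,
            retention=self.model.pca_retention,
            rotate=self.model.pca_rotate,
        )

    def _run_spatial(self) -> None:
        if self.indices is None:
            self._run_indices()
        if self.ecorisk is None:
            self._run_ecorisk()
        xy = self.model.samples.coordinates
        grid = default_grid(xy, n=self.model.grid_size)
        for name, values in (("pn", self.indices.pn), ("ri", self.ecorisk.ri)):
            pts = np.column_stack([xy, values.to_numpy()])
            self.fields[name] = idw_interpolate(
                pts, grid=grid, power=self.model.idw_power
            )

    # ---- reporting --------------------------------------------------------
    def summary(self) -> str:
        """Human-readable report of every computed stage."""
        buf = io.StringIO()
        w = buf.write
        w(f"Soil heavy-metal risk assessment — {len(self.model.samples)} samples\n")
        w("=" * 66 + "\n")
        if self.summary_stats is not None:
            w("\nDescriptive statistics (mg/kg):\n")
            w(self.summary_stats.round(3).to_string() + "\n")
        if self.indices is not None:
            summary = self.indices.element_summary().round(3)
            igeo_scale = self.model.registry.scale("igeo")
            pi_scale = self.model.registry.scale("single_factor")
            summary["igeo_class"] = summary["igeo_mean"].map(igeo_scale.classify)
            summary["pi_class"] = summary["pi_mean"].map(pi_scale.classify)
            w("\nPollution indices (per-element means):\n")
            w(summary.to_string() + "\n")
            w("\nNemerow class proportions (% of samples):\n")
            w(self.indices.nemerow_class_proportions().round(2).to_string() + "\n")
        if self.ecorisk is not None:
            eco = self.ecorisk.element_summary().round(2)
            eri_scale = self.model.registry.scale("eri")
            eco["class"] = eco["eri_mean"].map(eri_scale.classify)
            w("\nPotential ecological risk (per-element mean E_r):\n")
            w(eco.to_string() + "\n")
            w(f"\nMean RI: {self.ecorisk.ri.mean():.2f}\n")
            w("RI class proportions (% of samples):\n")
            w(self.ecorisk.ri_class_proportions().round(2).to_string() + "\n")
        if self.health is not None:
            w("\nHealth risk (computed on mean concentrations):\n")
            for cohort in self.health.hi.index:
                w(
                    f"  {cohort}: HI = {self.health.hi[cohort]:.3f}, "
                    f"TCR = {self.health.tcr[cohort]:.3e}\n"
                )
            w("Pathway contributions to HI (%):\n")
            w(self.health.hq_contribution.round(2).to_string() + "\n")
        if self.pca is not None:
            w(
                f"\nPCA: {self.pca.n_retained} components retained, "
                f"cumulative contribution "
                f"{self.pca.retained_contribution:.2f}%\n"
            )
            w(self.pca.table().round(3).to_string() + "\n")
        if self.fields:
            for name, fld in self.fields.items():
                w(
                    f"\nIDW surface '{name}': {fld.grid.nx}x{fld.grid.ny} grid, "
                    f"range [{fld.values.min():.3f}, {fld.values.max():.3f}]\n"
                )
        return buf.getvalue()

    def save(self, outdir) -> Path:
        """Write every computed table (delimited text) plus the manifest."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        if self.summary_stats is not None:
            self.summary_stats.to_csv(outdir / "summary_statistics.csv")
        if self.indices is not None:
            self.indices.igeo.to_csv(outdir / "igeo.csv")
            self.indices.pi.to_csv(outdir / "single_factor.csv")
            self.indices.pn.to_csv(outdir / "nemerow.csv")
            self.indices.element_summary().to_csv(outdir / "index_summary.csv")
        if self.ecorisk is not None:
            self.ecorisk.eri.to_csv(outdir / "eri.csv")
            self.ecorisk.ri.to_csv(outdir / "ri.csv")
            self.ecorisk.element_summary().to_csv(outdir / "ecorisk_summary.csv")
            self.ecorisk.ri_class_proportions().to_csv(
                outdir / "ri_class_proportions.csv"
            )
        if self.health is not None:
            self.health.hq.to_csv(outdir / "hazard_quotients.csv")
            self.health.cr.to_csv(outdir / "cancer_risks.csv")
            self.health.hq_contribution.to_csv(outdir / "hq_contributions.csv")
            self.health.cr_contribution.to_csv(outdir / "cr_contributions.csv")
        if self.correlation is not None:
            self.correlation.r.to_csv(outdir / "correlation.csv")
            self.correlation.annotated().to_csv(outdir / "correlation_annotated.csv")
        if self.pca is not None:
            self.pca.table().to_csv(outdir / "pca_loadings.csv")
        for name, fld in self.fields.items():
            fld.to_ascii_grid(outdir / f"{name}.asc")
            fld.to_xyz().to_csv(outdir / f"{name}.xyz", index=False)
        with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(self.manifest, fh, indent=2, sort_keys=True)
        return outdir


def run_pipeline(
    samples: SampleSet,
    registry: Registry | None = None,
    stages: Sequence[str] | None = None,
    **kwargs,
) -> SoilRiskResults:
    """Functional convenience wrapper around SoilRiskModel(...).fit(...)."""
    return SoilRiskModel(samples, registry=registry, **kwargs).fit(stages=stages)
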