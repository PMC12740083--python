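"""Multi-dataset orchestration from a run configuration file.

A run reads one gene-age map and any number of DEG tables, computes the
combined/up/down enrichment tables, the age-shift test, per-stratum
direction balances and (with >= 2 datasets) the cross-dataset dispersion
summary, and writes everything under an output directory together with a
deterministic run manifest.  A dataset that fails ingestion is recorded as
failed and skipped; the others proceed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

from . import __version__
from .age_shift import AgeShift, AgeShiftResults
from .deg import partition_by_direction, read_deg_table
from .enrichment import EnrichmentResults, StratumEnrichment
from .errors import ConfigurationError
from .heterogeneity import direction_balance, dispersion_table
from .plotting import render_barchart
from .strata import StrataScale, load_gene_ages

logger = logging.getLogger("stratashift")

__all__ = ["DatasetSpec", "RunConfig", "RunResult", "run_analysis"]


@dataclass
class DatasetSpec:
    name: str
    path: str
    columns: dict = field(default_factory=dict)


@dataclass
class RunConfig:
    """Configuration of one analysis run (YAML on disk)."""

    gene_ages: str
    datasets: list[DatasetSpec]
    outdir: str
    gene_age_columns: dict = field(default_factory=dict)
    alpha: float = 0.05
    figures: bool = True
    figure_denominator: str = "per-direction"
    seed: int = 0

    def __post_init__(self) -> None:
        names = [d.name for d in self.datasets]
        if len(set(names)) != len(names):
            raise ConfigurationError("dataset names must be unique")
        if not 0 < self.alpha < 1:
            raise ConfigurationError("alpha must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        try:
            datasets = [
                DatasetSpec(name=d["name"], path=d["path"], columns=d.get("columns", {}))
                for d in raw["datasets"]
            ]
            return cls(
                gene_ages=raw["gene_ages"],
                datasets=datasets,
                outdir=raw["outdir"],
                gene_age_columns=raw.get("gene_age_columns", {}),
                alpha=raw.get("alpha", 0.05),
                figures=raw.get("figures", True),
                figure_denominator=raw.get("figure_denominator", "per-direction"),
                seed=raw.get("seed", 0),
            )
        except (KeyError, TypeError) as exc:
            raise ConfigurationError(f"malformed run config {path}: {exc}") from exc


@dataclass
class RunResult:
    outdir: Path
    enrichment: dict[str, dict[str, EnrichmentResults]]
    age_shifts: dict[str, AgeShiftResults]
    balances: dict[str, "object"]
    manifest: dict


def run_analysis(config: RunConfig) -> RunResult:
    """Execute the full pipeline for every dataset in the configuration."""
    scale = StrataScale.default()
    gene_ages = load_gene_ages(config.gene_ages, scale, config.gene_age_columns)
    universe = gene_ages.universe(scale)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "stratashift",
        "version": __version__,
        "parameters": {
            "alpha": config.alpha,
            "figure_denominator": config.figure_denominator,
            "seed": config.seed,
        },
        "gene_ages": {
            "path": str(config.gene_ages),
            "n_genes": len(gene_ages),
            "n_rejected": gene_ages.n_rejected,
            "n_duplicates": gene_ages.n_duplicates,
        },
        "datasets": {},
    }
    enrichment: dict[str, dict[str, EnrichmentResults]] = {}
    age_shifts: dict[str, AgeShiftResults] = {}
    balances: dict[str, object] = {}
    for ds in config.datasets:
        try:
            deg = read_deg_table(ds.path, ds.columns, name=ds.name).intersect(gene_ages)
            parts = partition_by_direction(deg)
            scopes = {"combined": deg, "up": parts["up"], "down": parts["down"]}
            tables = {}
            ds_dir = outdir / ds.name
            ds_dir.mkdir(exist_ok=True)
            for scope, subset in scopes.items():
                if subset.n == 0:
                    # an empty direction view is valid; emit an all-zero table
                    tables[scope] = None
                    continue
                res = StratumEnrichment(subset, universe, scale, scope=scope).fit(config.alpha)
                res.to_tsv(ds_dir / f"enrichment_{scope}.tsv")
                tables[scope] = res
            shift = AgeShift(deg, universe).fit()
            shift.to_frame().to_csv(ds_dir / "age_shift.tsv", sep="\t", index=False)
            if tables["up"] is not None and tables["down"] is not None:
                bal = direction_balance(tables["up"], tables["down"])
                bal.to_csv(ds_dir / "direction_balance.tsv", sep="\t", index=False)
                balances[ds.name] = bal
                if config.figures:
                    render_barchart(
                        tables["up"],
                        tables["down"],
                        universe,
                        flags=tables["combined"].flags.to_numpy(),
                        path=ds_dir / "enrichment.svg",
                        denominator=config.figure_denominator,
                    )
            enrichment[ds.name] = tables
            age_shifts[ds.name] = shift
            manifest["datasets"][ds.name] = {
                "path": str(ds.path),
                "status": "ok",
                "n": deg.n,
                "n_unmapped": deg.n_unmapped,
                "n_dropped_direction": deg.n_dropped_direction,
            }
            logger.info("dataset %s: n=%d, shift=%.3f, p=%.3e", ds.name, deg.n, shift.mean_shift, shift.p_value)
        except Exception as exc:  # noqa: BLE001 - per-dataset isolation is the contract
            manifest["datasets"][ds.name] = {"path": str(ds.path), "status": "failed", "error": str(exc)}
            logger.warning("dataset %s failed: %s", ds.name, exc)
    if age_shifts:
        summary = AgeShiftResults.frame_of(list(age_shifts.values()))
        summary.to_csv(outdir / "age_shift_summary.tsv", sep="\t", index=False)
    if len(balances) >= 2:
        dispersion_table(balances).to_csv(outdir / "heterogeneity.tsv", sep="\t", index=False)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return RunResult(
        outdir=outdir,
        enrichment=enrichment,
        age_shifts=age_shifts,
        balances=balances,
        manifest=manifest,
    )
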