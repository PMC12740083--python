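"""Ingestion of differentially expressed gene (DEG) tables.

A DEG set is a named list of gene symbols with an up/down direction label
(given directly or derived from the sign of an effect column).  Before any
statistics are run the set is intersected with the gene universe: genes
without an age assignment are dropped and counted, and a gene reported both
up and down (as happens when pooling cell types) is kept once with direction
"both".
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError
from .strata import GeneAgeMap, N_STRATA, normalize_symbols, _read_delimited

__all__ = ["DEGSet", "read_deg_table", "intersect_with_universe", "partition_by_direction"]

_DIRECTIONS = {"up", "down"}


@dataclass
class DEGSet:
    """A named set of DEGs with direction labels.

    ``records`` has columns ``gene``, ``direction`` (up/down/both) and
    ``effect`` (float, NaN when absent).  After intersection with a gene-age
    map it also has ``rank``, one row per unique gene, and ``n``/``n_unmapped``
    are populated.
    """

    name: str
    records: pd.DataFrame
    n_unmapped: int | None = None
    n_dropped_direction: int = 0
    intersected: bool = False

    @property
    def n(self) -> int:
        """Unique genes retained after universe intersection."""
        if not self.intersected:
            raise InputError(f"DEG set {self.name!r} has not been intersected with a universe")
        return len(self.records)

    @property
    def ranks(self) -> np.ndarray:
        if not self.intersected:
            raise InputError(f"DEG set {self.name!r} has not been intersected with a universe")
        return self.records["rank"].to_numpy()

    def stratum_counts(self) -> np.ndarray:
        """Genes per stratum rank 1..19 (length-19 vector)."""
        return np.bincount(self.ranks, minlength=N_STRATA + 1)[1:]

    def intersect(self, gene_ages: GeneAgeMap) -> "DEGSet":
        return intersect_with_universe(self, gene_ages)

    def partition(self) -> dict[str, "DEGSet"]:
        return partition_by_direction(self)

    def to_table(self, path: str | Path) -> None:
        self.records.to_csv(path, sep="\t", index=False)


def read_deg_table(
    path: str | Path,
    column_spec: Mapping[str, str] | None = None,
    name: str | None = None,
) -> DEGSet:
    """Read a delimited DEG table into a (pre-intersection) :class:`DEGSet`.

    The table needs a gene column plus a direction column (values matched
    case-insensitively against up/down) and/or a signed effect column.  When
    only the effect is present, strictly positive means up, strictly negative
    down, and zero rows are dropped and counted.  Rows whose direction cannot
    be parsed are likewise dropped and counted.

    Parameters
    ----------
    column_spec : mapping, optional
        Overrides for column names; keys "gene", "direction", "effect"
        (defaults: ``gene``, ``direction``, ``logfc``).
    """
    spec = {"gene": "gene", "direction": "direction", "effect": "logfc"}
    spec.update(column_spec or {})
    df = _read_delimited(path)
    if spec["gene"] not in df.columns:
        raise ConfigurationError(
            f"DEG table {path}: gene column {spec['gene']!r} not found (columns: {list(df.columns)})"
        )
    has_dir = spec["direction"] in df.columns
    has_eff = spec["effect"] in df.columns
    if not has_dir and not has_eff:
        raise ConfigurationError(
            f"DEG table {path}: need a direction column ({spec['direction']!r}) "
            f"or an effect column ({spec['effect']!r})"
        )
    genes = normalize_symbols(df[spec["gene"]])
    effect = pd.to_numeric(df[spec["effect"]], errors="coerce") if has_eff else pd.Series(np.nan, index=df.index)
    if has_dir:
        direction = df[spec["direction"]].astype(str).str.strip().str.lower()
        ok = direction.isin(_DIRECTIONS)
    else:
        direction = pd.Series(
            np.where(effect > 0, "up", np.where(effect < 0, "down", "")), index=df.index
        )
        ok = direction.isin(_DIRECTIONS)
    n_dropped = int((~ok).sum())
    records = pd.DataFrame(
        {"gene": genes[ok], "direction": direction[ok], "effect": effect[ok]}
    ).reset_index(drop=True)
    if len(records) == 0:
        raise InputError(f"DEG table {path}: no usable rows")
    return DEGSet(
        name=name or Path(path).stem,
        records=records,
        n_dropped_direction=n_dropped,
    )


def intersect_with_universe(deg: DEGSet, gene_ages: GeneAgeMap) -> DEGSet:
    """Restrict a DEG set to genes with an age assignment; one row per gene.

    Genes absent from the map are dropped and counted in ``n_unmapped``.
    A gene appearing with both directions collapses to direction "both";
    duplicate same-direction rows collapse to one (keeping the first
    effect value).  Idempotent.
    """
    rec = deg.records
    ranks = gene_ages.entries.reindex(rec["gene"])
    mapped = ranks.notna().to_numpy()
    already = deg.n_unmapped or 0
    rec = rec[mapped].copy()
    rec["rank"] = ranks[mapped].astype(np.int64).to_numpy()

    def _merge(group: pd.DataFrame) -> pd.Series:
        dirs = set(group["direction"])
        if "both" in dirs or ("up" in dirs and "down" in dirs):
            d = "both"
        else:
            d = next(iter(dirs))
        return pd.Series(
            {"direction": d, "effect": group["effect"].iloc[0], "rank": group["rank"].iloc[0]}
        )

    if rec["gene"].duplicated().any():
        merged = rec.groupby("gene", sort=False).apply(_merge, include_groups=False).reset_index()
    else:
        merged = rec.reset_index(drop=True)
    n_unmapped = already + int((~mapped).sum())
    return DEGSet(
        name=deg.name,
        records=merged[["gene", "direction", "effect", "rank"]],
        n_unmapped=n_unmapped,
        n_dropped_direction=deg.n_dropped_direction,
        intersected=True,
    )


def partition_by_direction(deg: DEGSet) -> dict[str, DEGSet]:
    """Split an intersected set into up/down views; "both" genes enter each."""
    if not deg.intersected:
        raise InputError("partition requires an intersected DEG set")
    out: dict[str, DEGSet] = {}
    for d in ("up", "down"):
        rec = deg.records[deg.records["direction"].isin({d, "both"})].reset_index(drop=True)
        out[d] = DEGSet(
            name=deg.name,
            records=rec,
            n_unmapped=deg.n_unmapped,
            n_dropped_direction=deg.n_dropped_direction,
            intersected=True,
        )
    return out
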