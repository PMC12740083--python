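"""Ordinal evolutionary-age scale, gene-age maps, and the baseline gene universe.

Phylostratigraphy assigns each protein-coding gene to the most distant clade
in which homologs are detectable.  Here the scale is the standard 19-level
ordinal hierarchy running from "All living organisms" (rank 1, genes shared
with unicellular life) to "Primates" (rank 19, the evolutionarily youngest
genes).  A :class:`GeneAgeMap` holds one rank per gene symbol; the induced
per-stratum counts form the baseline :class:`UniverseDistribution` against
which differentially expressed gene sets are judged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError

N_STRATA = 19

__all__ = [
    "N_STRATA",
    "StrataScale",
    "GeneAgeMap",
    "UniverseDistribution",
    "load_gene_ages",
    "universe_distribution",
    "normalize_symbols",
]


def _read_delimited(path: str | Path) -> pd.DataFrame:
    """Read a TSV/CSV file, inferring the delimiter from content."""
    return pd.read_csv(path, sep=None, engine="python", dtype=str, comment="#")


def normalize_symbols(symbols: pd.Series | list[str]) -> pd.Series:
    """Canonical gene-symbol form: uppercase, surrounding whitespace stripped.

    No alias resolution is attempted; unmapped symbols are reported downstream
    rather than guessed at.
    """
    s = pd.Series(symbols, dtype=str) if not isinstance(symbols, pd.Series) else symbols.astype(str)
    return s.str.strip().str.upper()


@dataclass(frozen=True)
class StrataScale:
    """The ordered 19-category evolutionary-age scale.

    Rank 1 is the most ancient category ("All living organisms", genes shared
    with unicellular lineages); rank 19 the youngest ("Primates").
    """

    names: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.names) != N_STRATA:
            raise ConfigurationError(
                f"strata scale must have exactly {N_STRATA} entries, got {len(self.names)}"
            )
        if len({n.lower() for n in self.names}) != N_STRATA:
            raise ConfigurationError("strata names must be unique (case-insensitive)")

    @classmethod
    def default(cls) -> "StrataScale":
        """The bundled canonical scale, one name per line in rank order."""
        text = resources.files("stratashift.data").joinpath("strata_names.txt").read_text()
        names = tuple(line.strip() for line in text.splitlines() if line.strip())
        return cls(names)

    @property
    def ranks(self) -> np.ndarray:
        return np.arange(1, N_STRATA + 1)

    def rank_of(self, label: str | int) -> int:
        """Resolve a stratum name (case-insensitive) or integer rank to a rank.

        Raises KeyError for unknown names or out-of-range ranks.
        """
        if isinstance(label, (int, np.integer)):
            r = int(label)
            if not 1 <= r <= N_STRATA:
                raise KeyError(f"stratum rank {r} outside 1..{N_STRATA}")
            return r
        text = str(label).strip()
        try:
            r = int(text)
        except ValueError:
            pass
        else:
            if not 1 <= r <= N_STRATA:
                raise KeyError(f"stratum rank {r} outside 1..{N_STRATA}")
            return r
        lowered = text.lower()
        for i, name in enumerate(self.names, start=1):
            if name.lower() == lowered:
                return i
        raise KeyError(f"unknown stratum name {label!r}")

    def name_of(self, rank: int) -> str:
        if not 1 <= rank <= N_STRATA:
            raise KeyError(f"stratum rank {rank} outside 1..{N_STRATA}")
        return self.names[rank - 1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"rank": self.ranks, "stratum": list(self.names)})


@dataclass
class GeneAgeMap:
    """Mapping of normalized gene symbols to stratum ranks.

    Attributes
    ----------
    entries : pandas.Series
        Index = normalized gene symbol (unique), values = int rank in 1..19.
    source_label : str
        Free-text provenance of the assignment.
    n_rejected : int
        Input rows discarded for unknown stratum labels.
    n_duplicates : int
        Input rows discarded as duplicate symbols (first occurrence kept).
    """

    entries: pd.Series
    source_label: str = ""
    n_rejected: int = 0
    n_duplicates: int = 0

    def __post_init__(self) -> None:
        if len(self.entries) == 0:
            raise InputError("gene-age map is empty")
        ranks = self.entries.to_numpy()
        if ranks.min() < 1 or ranks.max() > N_STRATA:
            raise InputError("gene-age map contains ranks outside 1..19")
        if self.entries.index.has_duplicates:
            raise InputError("gene-age map has duplicate symbols after normalization")
        self.entries = self.entries.astype(np.int64)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.entries.index

    def ranks_of(self, symbols) -> pd.Series:
        """Ranks for the given symbols; NaN where a symbol is not mapped."""
        return self.entries.reindex(normalize_symbols(list(symbols)))

    def universe(self, scale: StrataScale | None = None) -> "UniverseDistribution":
        return universe_distribution(self, scale or StrataScale.default())

    def to_table(self, path: str | Path, scale: StrataScale | None = None) -> None:
        """Write the canonical two-column TSV (gene, stratum name)."""
        scale = scale or StrataScale.default()
        df = pd.DataFrame(
            {
                "gene": self.entries.index,
                "stratum": [scale.name_of(r) for r in self.entries.to_numpy()],
            }
        )
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_table(
        cls,
        path: str | Path,
        scale: StrataScale | None = None,
        column_spec: Mapping[str, str] | None = None,
        source_label: str | None = None,
    ) -> "GeneAgeMap":
        return load_gene_ages(path, scale or StrataScale.default(), column_spec, source_label)


def load_gene_ages(
    path: str | Path,
    scale: StrataScale,
    column_spec: Mapping[str, str] | None = None,
    source_label: str | None = None,
) -> GeneAgeMap:
    """Load and validate a gene-age assignment table.

    The table must be delimited text with a gene column and a stratum column
    holding either stratum names (matched case-insensitively against the
    scale) or integer ranks in 1..19.  Rows with unknown stratum labels are
    rejected and counted; duplicate symbols keep the first occurrence and are
    counted.

    Parameters
    ----------
    column_spec : mapping, optional
        Overrides for column names; keys "gene" and "stratum"
        (defaults: ``gene``, ``stratum``).
    """
    spec = {"gene": "gene", "stratum": "stratum"}
    spec.update(column_spec or {})
    df = _read_delimited(path)
    for key in ("gene", "stratum"):
        if spec[key] not in df.columns:
            raise ConfigurationError(
                f"gene-age table {path}: required column {spec[key]!r} not found "
                f"(columns: {list(df.columns)})"
            )
    genes = normalize_symbols(df[spec["gene"]])
    ranks = np.empty(len(df), dtype=float)
    for i, label in enumerate(df[spec["stratum"]]):
        try:
            ranks[i] = scale.rank_of(label)
        except KeyError:
            ranks[i] = np.nan
    valid = ~np.isnan(ranks)
    n_rejected = int((~valid).sum())
    genes, ranks = genes[valid], ranks[valid]
    dup = genes.duplicated(keep="first")
    n_duplicates = int(dup.sum())
    genes, ranks = genes[~dup.to_numpy()], ranks[~dup.to_numpy()]
    if len(genes) == 0:
        raise InputError(f"gene-age table {path}: no valid rows")
    entries = pd.Series(ranks.astype(np.int64), index=pd.Index(genes, name="gene"))
    return GeneAgeMap(
        entries,
        source_label=source_label or str(path),
        n_rejected=n_rejected,
        n_duplicates=n_duplicates,
    )


@dataclass(frozen=True)
class UniverseDistribution:
    """Per-stratum composition of the gene universe.

    N is the universe size, M[s-1] the number of universe genes in stratum s;
    expected fractions M/N define the baseline against which enrichment of a
    gene subset is tested.
    """

    N: int
    M: np.ndarray  # shape (19,), int counts per rank 1..19

    def __post_init__(self) -> None:
        M = np.asarray(self.M, dtype=np.int64)
        object.__setattr__(self, "M", M)
        if M.shape != (N_STRATA,):
            raise InputError(f"M must have shape ({N_STRATA},)")
        if (M < 0).any():
            raise InputError("per-stratum counts must be nonnegative")
        if int(M.sum()) != self.N:
            raise InputError("per-stratum counts must sum to N")

    @property
    def fractions(self) -> np.ndarray:
        return self.M / self.N

    @property
    def mean_rank(self) -> float:
        ranks = np.arange(1, N_STRATA + 1)
        return float((ranks * self.M).sum() / self.N)

    @property
    def rank_multiset(self) -> np.ndarray:
        """The universe's stratum ranks expanded to one value per gene."""
        return np.repeat(np.arange(1, N_STRATA + 1), self.M)

    def to_frame(self, scale: StrataScale | None = None) -> pd.DataFrame:
        scale = scale or StrataScale.default()
        return pd.DataFrame(
            {
                "rank": np.arange(1, N_STRATA + 1),
                "stratum": list(scale.names),
                "M": self.M,
                "fraction": self.fractions,
            }
        )


def universe_distribution(gene_ages: GeneAgeMap, scale: StrataScale) -> UniverseDistribution:
    """Baseline distribution induced by a gene-age map (strata absent get M=0)."""
    counts = np.bincount(gene_ages.entries.to_numpy(), minlength=N_STRATA + 1)[1:]
    return UniverseDistribution(N=len(gene_ages), M=counts)
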