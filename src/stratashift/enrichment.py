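"""Per-stratum hypergeometric over-/under-representation analysis.

:class:`StratumEnrichment` is the model object: it binds an intersected DEG
set to a universe distribution, and ``fit`` produces an
:class:`EnrichmentResults` with one row per stratum — observed and expected
fractions, both one-sided tail p-values, Benjamini–Hochberg q-values
(corrected across the 19 strata, separately per tail), and a significance
flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .deg import DEGSet
from .errors import InputError
from .stats import bh_fdr, tail_probabilities
from .strata import N_STRATA, StrataScale, UniverseDistribution

__all__ = ["StratumEnrichment", "EnrichmentResults", "stratum_enrichment"]

_COLUMNS = [
    "stratum_rank",
    "stratum",
    "N",
    "M",
    "n",
    "k",
    "expected_fraction",
    "observed_fraction",
    "p_over",
    "p_under",
    "q_over",
    "q_under",
    "flag",
]


class StratumEnrichment:
    """Hypergeometric enrichment model for one DEG set against a universe.

    Parameters
    ----------
    deg_set : DEGSet
        Must already be intersected with the universe's gene-age map.
    universe : UniverseDistribution
        Baseline per-stratum composition (N genes, M per stratum).
    scale : StrataScale, optional
        Names for the 19 ranks; the bundled default when omitted.
    scope : str
        Label recorded in the results: "combined", "up" or "down".
    """

    def __init__(
        self,
        deg_set: DEGSet,
        universe: UniverseDistribution,
        scale: StrataScale | None = None,
        scope: str = "combined",
    ):
        if not deg_set.intersected:
            raise InputError("enrichment requires a DEG set intersected with the universe")
        if deg_set.n == 0:
            raise InputError(f"DEG set {deg_set.name!r} is empty after intersection")
        if deg_set.n > universe.N:
            raise InputError("DEG set larger than the universe")
        self.deg_set = deg_set
        self.universe = universe
        self.scale = scale or StrataScale.default()
        self.scope = scope

    def fit(self, alpha: float = 0.05) -> "EnrichmentResults":
        """Compute per-stratum tails, BH q-values and significance flags.

        BH correction is applied across the strata of this one dataset and
        tail; strata with M = 0 are untestable (both tails identically 1) and
        are excluded from the correction family but kept in the table.
        """
        if not 0 < alpha < 1:
            raise InputError("alpha must lie in (0, 1)")
        uni, deg = self.universe, self.deg_set
        N, n = uni.N, deg.n
        k = deg.stratum_counts()
        p_over = np.empty(N_STRATA)
        p_under = np.empty(N_STRATA)
        for s in range(N_STRATA):
            p_over[s], p_under[s] = tail_probabilities(N, int(uni.M[s]), n, int(k[s]))
        testable = uni.M > 0
        q_over = np.ones(N_STRATA)
        q_under = np.ones(N_STRATA)
        if testable.any():
            q_over[testable] = bh_fdr(p_over[testable])
            q_under[testable] = bh_fdr(p_under[testable])
        flag = np.where(
            (q_over < alpha) & ((q_over <= q_under) | (q_under >= alpha)),
            "over",
            np.where(q_under < alpha, "under", "none"),
        )
        table = pd.DataFrame(
            {
                "stratum_rank": np.arange(1, N_STRATA + 1),
                "stratum": list(self.scale.names),
                "N": N,
                "M": uni.M,
                "n": n,
                "k": k,
                "expected_fraction": uni.fractions,
                "observed_fraction": k / n,
                "p_over": p_over,
                "p_under": p_under,
                "q_over": q_over,
                "q_under": q_under,
                "flag": flag,
            }
        )
        return EnrichmentResults(
            dataset=deg.name, scope=self.scope, alpha=alpha, table=table, model=self
        )


@dataclass
class EnrichmentResults:
    """Fitted per-stratum enrichment table for one dataset and scope."""

    dataset: str
    scope: str
    alpha: float
    table: pd.DataFrame
    model: StratumEnrichment | None = None

    @property
    def flags(self) -> pd.Series:
        return self.table.set_index("stratum_rank")["flag"]

    def significant(self) -> pd.DataFrame:
        return self.table[self.table["flag"] != "none"]

    def summary(self) -> str:
        lines = [
            f"Stratum enrichment: dataset={self.dataset!r} scope={self.scope} "
            f"n={int(self.table['n'].iloc[0])} N={int(self.table['N'].iloc[0])} alpha={self.alpha}",
            f"{'rank':>4} {'stratum':<22} {'M':>6} {'k':>5} {'exp%':>7} {'obs%':>7} "
            f"{'q_over':>9} {'q_under':>9} flag",
        ]
        for _, r in self.table.iterrows():
            lines.append(
                f"{r.stratum_rank:>4} {r.stratum:<22} {r.M:>6} {r.k:>5} "
                f"{100 * r.expected_fraction:>6.2f}% {100 * r.observed_fraction:>6.2f}% "
                f"{r.q_over:>9.3g} {r.q_under:>9.3g} {r.flag if r.flag != 'none' else ''}"
            )
        return "\n".join(lines)

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "dataset": self.dataset,
            "scope": self.scope,
            "alpha": self.alpha,
            "table": self.table.to_dict(orient="records"),
        }
        import json

        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_tsv(
        cls, path: str | Path, dataset: str = "", scope: str = "combined", alpha: float = 0.05
    ) -> "EnrichmentResults":
        table = pd.read_csv(path, sep="\t")
        missing = [c for c in _COLUMNS if c not in table.columns]
        if missing:
            raise InputError(f"enrichment table {path}: missing columns {missing}")
        return cls(dataset=dataset, scope=scope, alpha=alpha, table=table[_COLUMNS])


def stratum_enrichment(
    universe: UniverseDistribution,
    deg_set: DEGSet,
    scale: StrataScale | None = None,
    alpha: float = 0.05,
    scope: str = "combined",
) -> EnrichmentResults:
    """Functional form of :class:`StratumEnrichment` + ``fit``."""
    return StratumEnrichment(deg_set, universe, scale=scale, scope=scope).fit(alpha=alpha)
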