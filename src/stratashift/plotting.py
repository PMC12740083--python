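"""Grouped bar charts of DEG percentages per stratum with significance stars."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .enrichment import EnrichmentResults
from .errors import InputError
from .strata import N_STRATA, UniverseDistribution

__all__ = ["render_barchart"]


def _percentages(table, denominator: str, combined_n: int) -> np.ndarray:
    k = table["k"].to_numpy(dtype=float)
    n = table["n"].to_numpy(dtype=float)
    if denominator == "per-direction":
        tot = n[0] if n[0] > 0 else 1.0
    elif denominator == "combined":
        tot = combined_n if combined_n > 0 else 1.0
    else:
        raise InputError(f"unknown denominator {denominator!r}")
    return 100.0 * k / tot


def render_barchart(
    table_up: EnrichmentResults,
    table_down: EnrichmentResults,
    universe: UniverseDistribution,
    flags=None,
    path: str | Path = "enrichment.svg",
    denominator: str = "per-direction",
    title: str | None = None,
):
    """Render the up/down/expected percentage bars with significance stars.

    Per stratum (rank order): % upregulated (blue), % downregulated
    (orange), expected % from the universe (green).  A red star marks
    over-represented strata, a black star under-represented ones, taken from
    ``flags`` (a length-19 sequence of over/under/none; typically the
    combined-scope enrichment flags).

    ``denominator`` chooses the percentage base: "per-direction" (each
    series sums to 100% over strata) or "combined" (both direction series
    are fractions of the combined set size).
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if len(table_up.table) != N_STRATA or len(table_down.table) != N_STRATA:
        raise InputError("enrichment tables must cover all 19 strata")
    combined_n = int(table_up.table["n"].iloc[0] + table_down.table["n"].iloc[0])
    up_pct = _percentages(table_up.table, denominator, combined_n)
    down_pct = _percentages(table_down.table, denominator, combined_n)
    exp_pct = 100.0 * universe.fractions
    if flags is None:
        flags = ["none"] * N_STRATA
    flags = list(flags)
    if len(flags) != N_STRATA:
        raise InputError("flags must have one entry per stratum")

    x = np.arange(N_STRATA)
    width = 0.28
    fig, ax = plt.subplots(figsize=(12, 5))
    ax.bar(x - width, up_pct, width, label="upregulated", color="tab:blue")
    ax.bar(x, down_pct, width, label="downregulated", color="tab:orange")
    ax.bar(x + width, exp_pct, width, label="expected", color="tab:green")
    top = np.maximum.reduce([up_pct, down_pct, exp_pct])
    for i, f in enumerate(flags):
        if f == "over":
            ax.text(x[i], top[i] + 0.8, "*", color="red", ha="center", fontsize=16, fontweight="bold")
        elif f == "under":
            ax.text(x[i], top[i] + 0.8, "*", color="black", ha="center", fontsize=16, fontweight="bold")
    labels = table_up.table["stratum"].tolist()
    ax.set_xticks(x)
    ax.set_xticklabels(labels, rotation=60, ha="right", fontsize=8)
    ax.set_ylabel("percentage of genes")
    ax.set_title(title or f"{table_up.dataset}: DEG distribution across evolutionary age strata")
    ax.legend()
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path)
    plt.close(fig)
    return path
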