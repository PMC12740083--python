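"""Direction heterogeneity of DEGs across strata and datasets.

For each stratum, the direction balance is the fraction of that stratum's
DEGs that are upregulated.  Comparing balances at the same stratum across
datasets gives a minimal heterogeneity statistic: the sample standard
deviation of the balance values.  This dispersion summary is a documented
extension — it makes the qualitative observation that tissues disagree in
the *direction* of their ancient-gene dysregulation computable; no canonical
formula exists for it in the field.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .enrichment import EnrichmentResults
from .errors import InputError
from .strata import N_STRATA

__all__ = ["direction_balance", "cross_dataset_dispersion", "dispersion_table"]


def direction_balance(table_up: EnrichmentResults, table_down: EnrichmentResults) -> pd.DataFrame:
    """Per-stratum up/down counts and balance n_up/(n_up+n_down).

    Both tables must describe the same dataset.  Genes labeled "both"
    upstream already count once in each direction view.  The balance is NaN
    where a stratum has no DEGs in either direction.
    """
    if table_up.dataset != table_down.dataset:
        raise InputError(
            f"mismatched datasets: {table_up.dataset!r} vs {table_down.dataset!r}"
        )
    up = table_up.table.set_index("stratum_rank")["k"]
    down = table_down.table.set_index("stratum_rank")["k"]
    if not up.index.equals(down.index):
        raise InputError("up/down tables cover different strata")
    total = up + down
    with np.errstate(invalid="ignore", divide="ignore"):
        balance = np.where(total > 0, up / total, np.nan)
    return pd.DataFrame(
        {
            "stratum_rank": up.index,
            "stratum": table_up.table["stratum"].to_numpy(),
            "n_up": up.to_numpy(),
            "n_down": down.to_numpy(),
            "balance": balance,
        }
    ).reset_index(drop=True)


def cross_dataset_dispersion(balances) -> float:
    """Sample SD (ddof=1) of per-dataset balances at one stratum.

    Requires at least two defined (non-NaN) values.
    """
    vals = np.asarray(balances, dtype=float)
    vals = vals[~np.isnan(vals)]
    if vals.size < 2:
        raise InputError("dispersion requires >= 2 defined balance values")
    return float(np.std(vals, ddof=1))


def dispersion_table(balance_frames: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Wide per-stratum balance table across datasets plus a dispersion column.

    Strata with fewer than two defined balances get NaN dispersion rather
    than an error, so a multi-dataset report never aborts on sparse strata.
    """
    if len(balance_frames) < 2:
        raise InputError("dispersion table requires >= 2 datasets")
    wide = pd.DataFrame({"stratum_rank": np.arange(1, N_STRATA + 1)})
    for name, frame in balance_frames.items():
        wide[name] = frame.set_index("stratum_rank")["balance"].reindex(wide["stratum_rank"]).to_numpy()
    vals = wide.drop(columns="stratum_rank").to_numpy(dtype=float)
    defined = (~np.isnan(vals)).sum(axis=1)
    sd = np.full(len(vals), np.nan)
    enough = defined >= 2
    if enough.any():
        sd[enough] = np.nanstd(vals[enough], axis=1, ddof=1)
    wide["dispersion"] = sd
    return wide
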