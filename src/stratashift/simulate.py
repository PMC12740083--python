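"""Synthetic gene universes and DEG sets with controlled atavistic structure.

The generator emulates exactly the statistical structure the enrichment and
age-shift tests assume: a fixed universe whose genes carry stratum ranks,
and a DEG subset drawn without replacement, either uniformly (the exact
hypergeometric null) or biased toward ancient strata.  The bias is a single
parameter beta >= 0: gene sampling weights are exp(-beta*(rank-1)), drawn
sequentially with renormalization.  Per-gene up/down directions follow a
logistic model in rank, so direction balance can vary by stratum.

Sampling without replacement with weights and renormalization is realized by
the Gumbel top-k trick (take the n largest log-weight + Gumbel keys), which
is distributionally identical to the sequential scheme and reduces to a
uniform draw at beta = 0.  The induced per-stratum counts follow the
multivariate Wallenius noncentral hypergeometric law; its mean equation is
inverted numerically to recover beta from an observed mean rank.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .deg import DEGSet
from .errors import ConfigurationError, InputError
from .strata import GeneAgeMap, N_STRATA, StrataScale, UniverseDistribution

__all__ = [
    "SyntheticConfig",
    "SyntheticBundle",
    "default_composition",
    "sample_universe",
    "sample_deg_set",
    "make_bundle",
    "expected_mean_rank",
    "estimate_beta",
    "BetaEstimate",
]

BETA_MAX = 50.0


def default_composition() -> np.ndarray:
    """The bundled 19-vector of per-stratum universe weights.

    Heavy mass on ranks 1 and 12 mimics the qualitative shape of genome-wide
    phylostratum composition (many genes trace to unicellular ancestors and
    to the bony-vertebrate expansion); it is a synthetic default, not an
    empirical genome census.
    """
    text = resources.files("stratashift.data").joinpath("default_composition.tsv").read_text()
    df = pd.read_csv(pd.io.common.StringIO(text), sep="\t")
    w = df.sort_values("rank")["weight"].to_numpy(dtype=float)
    return w


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic universe + DEG-set generator.

    Attributes
    ----------
    universe_size : int
        Number of genes in the synthetic universe.
    composition : array-like of 19 nonnegative weights summing to 1
        Per-stratum universe composition; bundled default when None.
    beta : float >= 0
        Ancientness bias of DEG sampling; weight exp(-beta*(rank-1)).
        beta = 0 is the exact null (uniform draw without replacement).
    n_deg : int
        DEG-set size (<= universe_size).
    p_up_intercept, p_up_slope : float
        Logistic direction model: P(up | rank) = expit(intercept + slope*rank).
    seed : int
        Seed for all randomness; identical configs give identical bundles.
    """

    universe_size: int = 19000
    composition: np.ndarray | None = None
    beta: float = 0.0
    n_deg: int = 500
    p_up_intercept: float = 0.0
    p_up_slope: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        comp = default_composition() if self.composition is None else np.asarray(self.composition, dtype=float)
        if comp.shape != (N_STRATA,):
            raise ConfigurationError(f"composition must have {N_STRATA} entries")
        if (comp < 0).any():
            raise ConfigurationError("composition weights must be nonnegative")
        total = comp.sum()
        if total == 0:
            raise ConfigurationError("composition is degenerate (all zero)")
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError("composition must sum to 1 within 1e-9")
        self.composition = comp
        if self.beta < 0:
            raise ConfigurationError("beta must be >= 0")
        if not 0 < self.n_deg <= self.universe_size:
            raise ConfigurationError("need 0 < n_deg <= universe_size")

    def to_jsonable(self) -> dict:
        d = asdict(self)
        d["composition"] = [float(x) for x in self.composition]
        return d


def sample_universe(config: SyntheticConfig, rng: np.random.Generator | None = None) -> GeneAgeMap:
    """Multinomial assignment of ``universe_size`` synthetic genes to strata.

    Gene symbols are G000001... in rank order; reproducible from the seed.
    """
    rng = rng or np.random.default_rng(config.seed)
    counts = rng.multinomial(config.universe_size, config.composition)
    ranks = np.repeat(np.arange(1, N_STRATA + 1), counts)
    symbols = [f"G{i:06d}" for i in range(1, config.universe_size + 1)]
    entries = pd.Series(ranks, index=pd.Index(symbols, name="gene"))
    return GeneAgeMap(entries, source_label=f"synthetic(seed={config.seed})")


def sample_deg_set(
    universe: GeneAgeMap,
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
    name: str = "synthetic_deg",
) -> DEGSet:
    """Draw a DEG set of size n_deg from the universe, biased by beta.

    Genes are sampled without replacement with weights exp(-beta*(rank-1))
    via Gumbel top-k (equivalent to sequential renormalized draws); at
    beta = 0 this is a uniform draw, the exact hypergeometric null.
    Directions are i.i.d. Bernoulli with P(up) = expit(intercept + slope*rank).
    Returns an already-intersected set (every gene has a rank).
    """
    if config.n_deg > len(universe):
        raise InputError("n_deg exceeds universe size")
    rng = rng or np.random.default_rng(config.seed)
    ranks = universe.entries.to_numpy()
    log_w = -config.beta * (ranks - 1).astype(float)
    keys = log_w + rng.gumbel(size=len(ranks))
    idx = np.argpartition(-keys, config.n_deg - 1)[: config.n_deg]
    idx = np.sort(idx)
    sel_ranks = ranks[idx]
    p_up = expit(config.p_up_intercept + config.p_up_slope * sel_ranks)
    is_up = rng.random(config.n_deg) < p_up
    records = pd.DataFrame(
        {
            "gene": universe.entries.index[idx],
            "direction": np.where(is_up, "up", "down"),
            "effect": np.where(is_up, 1.0, -1.0),
            "rank": sel_ranks,
        }
    )
    return DEGSet(name=name, records=records, n_unmapped=0, intersected=True)


@dataclass
class SyntheticBundle:
    """A generated universe + DEG set together with the true parameters."""

    gene_ages: GeneAgeMap
    deg_set: DEGSet
    config: SyntheticConfig

    def write(self, outdir: str | Path, scale: StrataScale | None = None) -> None:
        """Write universe.tsv / degs.tsv in the ingest dialects + truth.json."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.gene_ages.to_table(outdir / "universe.tsv", scale)
        self.deg_set.records[["gene", "direction", "effect"]].rename(
            columns={"effect": "logfc"}
        ).to_csv(outdir / "degs.tsv", sep="\t", index=False)
        (outdir / "truth.json").write_text(json.dumps(self.config.to_jsonable(), indent=2))


def make_bundle(config: SyntheticConfig, name: str = "synthetic_deg") -> SyntheticBundle:
    """Generate a universe and one DEG set from a single seeded stream."""
    rng = np.random.default_rng(config.seed)
    gene_ages = sample_universe(config, rng)
    deg = sample_deg_set(gene_ages, config, rng, name=name)
    return SyntheticBundle(gene_ages=gene_ages, deg_set=deg, config=config)


def _wallenius_mean_counts(beta: float, M: np.ndarray, n: int) -> np.ndarray:
    """Expected per-stratum counts of the weighted draw (Wallenius mean).

    Solves sum_s M_s * (1 - t**w_s) = n for t in (0,1) with weights
    w_s = exp(-beta*(rank-1)); mu_s = M_s * (1 - t**w_s).  Exact at beta=0
    and asymptotically exact for large strata otherwise.
    """
    N = int(M.sum())
    if n == N:
        return M.astype(float)
    w = np.exp(-beta * np.arange(N_STRATA, dtype=float))

    def f(log_t: float) -> float:
        t_pow = np.exp(w * log_t)  # t**w, stable for t in (0,1)
        return float((M * (1.0 - t_pow)).sum() - n)

    # f is decreasing in log_t; f(-inf) = N - n > 0, f(0) = -n < 0
    # the root in log t can be astronomically negative when beta is large
    # (young-strata weights underflow), so the bracket must expand far
    lo, hi = -1.0, 0.0
    while f(lo) <= 0:
        lo *= 4.0
        if lo < -1e300:  # pragma: no cover - numerically unreachable
            raise RuntimeError("Wallenius mean equation failed to bracket")
    log_t = brentq(f, lo, hi, xtol=1e-14, rtol=1e-14)
    return M * (1.0 - np.exp(w * log_t))


def expected_mean_rank(beta: float, universe: UniverseDistribution, n_deg: int) -> float:
    """Expected mean stratum rank of a size-n_deg draw at bias beta."""
    mu = _wallenius_mean_counts(beta, universe.M, n_deg)
    ranks = np.arange(1, N_STRATA + 1)
    return float((ranks * mu).sum() / mu.sum())


@dataclass(frozen=True)
class BetaEstimate:
    beta: float
    at_upper_bound: bool

    def __float__(self) -> float:
        return self.beta


def estimate_beta(
    deg_set: DEGSet | np.ndarray,
    universe: UniverseDistribution,
    beta_max: float = BETA_MAX,
) -> BetaEstimate:
    """Method-of-moments recovery of the ancientness bias beta.

    Finds the beta whose expected mean rank (under the weighted
    without-replacement sampling model, via the Wallenius mean equation)
    equals the observed mean rank.  Returns 0 when the observed mean rank is
    at or above the universe mean; returns ``beta_max`` flagged when the
    observed mean is below what any beta <= beta_max can produce.
    """
    ranks = deg_set.ranks if isinstance(deg_set, DEGSet) else np.asarray(deg_set)
    if ranks.size == 0:
        raise InputError("estimate_beta requires a nonempty gene set")
    obs = float(np.mean(ranks))
    n = int(ranks.size)
    if obs >= universe.mean_rank:
        return BetaEstimate(0.0, False)

    def g(beta: float) -> float:
        return expected_mean_rank(beta, universe, n) - obs

    if g(beta_max) >= 0:
        return BetaEstimate(beta_max, True)
    beta = brentq(g, 0.0, beta_max, xtol=1e-10)
    return BetaEstimate(float(beta), False)
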