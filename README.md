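# stratashift

Phylostratigraphic enrichment and evolutionary age-shift analysis of
differentially expressed gene (DEG) sets.

## The scientific problem

Phylostratigraphy assigns each protein-coding gene an evolutionary age: the
most distant clade in which homologs of the gene are still detectable.
Human genes are commonly binned into 19 ordinal *phylostrata* running from
**All living organisms** (rank 1, genes shared with unicellular life)
through Eukaryota, Metazoa, Bilateria, … to **Primates** (rank 19, the
youngest genes). Several programs in aging and cancer biology ask whether a
condition-associated gene set — for example, the genes differentially
expressed between old and young tissue — skews toward ancient strata
("atavistic" expression) relative to the genome-wide baseline.

`stratashift` is for computational biologists running that analysis. Given
a gene→stratum age table and one or more DEG tables (gene, up/down
direction, optional log-fold-change), it computes:

1. **Per-stratum over-/under-representation.** With a universe of `N` aged
   genes, `M` of them in stratum `s`, and a DEG set of `n` genes of which
   `k` fall in stratum `s`, the draw probability is hypergeometric,

   `P(X = k) = C(M, k) C(N−M, n−k) / C(N, n)`,

   and the one-sided tails `P(X ≥ k)` (over-representation) and
   `P(X ≤ k)` (under-representation) are computed exactly from
   log-factorials. Benjamini–Hochberg FDR correction is applied across the
   19 strata of each dataset, separately per tail; strata are flagged at
   an adjusted threshold (default q < 0.05).
2. **Mean evolutionary age shift.** The difference between the set's mean
   stratum rank and the universe's mean rank, in age categories (negative =
   skew toward ancient), tested with a tie-aware Mann–Whitney rank-sum test
   against the universe's rank multiset (exact by enumeration for small
   problems, tie-corrected normal approximation with continuity correction
   at scale).
3. **Direction heterogeneity.** Per-stratum up/down balance within each
   dataset and its cross-dataset dispersion.

A seeded synthetic-data generator produces gene universes with a
configurable stratum composition and DEG sets with a tunable ancientness
bias `beta` (sampling weights `exp(−beta·(rank−1))`, drawn without
replacement), so the entire pipeline — including type-I calibration and
parameter recovery — runs with no downloads.

## Worked example

```python
import stratashift as ss

# a synthetic universe of 19,000 genes and an ancient-biased DEG set
cfg = ss.SyntheticConfig(universe_size=19_000, n_deg=500, beta=0.5, seed=42)
bundle = ss.make_bundle(cfg)
universe = bundle.gene_ages.universe()

enr = ss.StratumEnrichment(bundle.deg_set, universe).fit(alpha=0.05)
print(enr.summary())
shift = ss.AgeShift(bundle.deg_set, universe).fit()
print(shift.summary())
print("estimated ancientness bias:", ss.estimate_beta(bundle.deg_set, universe))
```

prints (abridged):

```
Stratum enrichment: dataset='synthetic_deg' scope=combined n=500 N=19000 alpha=0.05
rank stratum                     M     k    exp%    obs%    q_over   q_under flag
   1 All living organisms     3700   362  19.47%  72.40%  2.1e-148         1 over
   2 Eukaryota                1318    72   6.94%  14.40%  2.37e-08         1 over
   3 Opisthokonta              555    18   2.92%   3.60%         1     0.953
   ...
  12 Euteleostomi             2679     2  14.10%   0.40%         1   2.3e-29 under
   ...
  19 Primates                  743     0   3.91%   0.00%         1  7.88e-09 under

Age shift: dataset='synthetic_deg' n=500
  mean age shift = -6.709 categories (negative = toward ancient strata)
  Mann-Whitney U = 1448010.5, two-sided p = 1.279e-157 [***]

estimated ancientness bias: BetaEstimate(beta=0.4839835501963748, at_upper_bound=False)
```

Reading: 72.4% of the biased DEG set lands in the most ancient stratum
against an expected 19.5%, so that stratum is flagged over-represented at
q ≈ 1e-148, while the young strata are under-represented; the set's mean
age sits 6.7 categories older than the genome baseline, and the
method-of-moments estimate recovers the generating bias (β̂ ≈ 0.48 for a
true β = 0.5).

Real data run the same way: load the age table with
`ss.load_gene_ages(path, ss.StrataScale.default())`, a DEG table with
`ss.read_deg_table(path)`, intersect with `.intersect(age_map)`, then fit
the same model objects — or drive everything from a YAML config:

```sh
stratashift analyze run.yaml      # tables, Table-1-style summary, figures
stratashift simulate --out bundle/ --beta 0.5 --seed 1
stratashift calibrate --out cal.json --replicates 1000
stratashift plot --up up.tsv --down down.tsv --combined combined.tsv -o fig.svg
```

`analyze` writes per-dataset enrichment TSVs (combined/up/down scopes), an
age-shift summary table, per-stratum direction balances, a cross-dataset
heterogeneity table, grouped bar charts (% up / % down / expected per
stratum, stars marking significant strata), and a deterministic run
manifest.

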