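# Methods

## Model and assumptions

The analysis treats a DEG set as a draw of `n` genes from a fixed,
finite universe of `N` aged protein-coding genes. Under the null
hypothesis of no age structure, the number `k` of set genes in a stratum
containing `M` universe genes is hypergeometric; over-representation is
judged by `P(X ≥ k)` and under-representation by `P(X ≤ k)`, both tails
including the observed count. The framework is purely combinatorial: no
expression magnitudes enter the test, only set membership, so results are
invariant to how the DEG calls were thresholded upstream (that choice is
the caller's responsibility and outside this package's scope).

The ordinal age scale has 19 fixed categories, rank 1 = "All living
organisms" (absorbing unicellular lineages) through rank 19 = "Primates".
The scale is ordinal: the mean age shift treats ranks as equally spaced
categories because no better-calibrated metric exists for phylostrata;
shifts are therefore reported in "age categories", not years.

## Statistical procedures and numerical choices

**Hypergeometric tails.** Computed from log-factorials (`gammaln`) and
summed with `logsumexp` over each side of the support independently, so
`p_over + p_under − pmf = 1` holds to ~1e-12 and tail values remain exact
far below double-precision underflow of individual binomials. Outside the
support the pmf is 0 and the tails saturate at 0/1. Negative parameters or
`M > N` raise a domain error rather than clamping.

**Multiple testing.** Benjamini–Hochberg step-up across the 19 strata of
one dataset, separately for the over-tail family and the under-tail
family. Rationale: each tail asks a distinct one-sided question, and stars
for the two directions are annotated independently. Strata with `M = 0`
are untestable (both tails identically 1); they stay in the table but are
excluded from the correction family so they cannot dilute it. A stratum is
flagged when its adjusted value falls below `alpha` (default 0.05,
configurable); if both tails pass, the smaller q wins, with ties going to
"over".

**Mann–Whitney test.** The set's rank multiset is compared against the
*full* universe rank multiset (not universe-minus-set), mirroring the
expected-fraction baseline `M/N`; for `n ≪ N` the difference is
negligible, and the full-universe convention keeps the two analyses'
baselines identical. With only 19 distinct values, ties dominate, so:
midranks throughout; for `n1·n2 ≤ 200` the exact permutation distribution
of the rank sum is computed by dynamic programming over the observed tie
pattern (doubled midranks are integers, so the distribution is an exact
integer convolution), with two-sided p = `min(1, 2·min(P(S≤s), P(S≥s)))`;
otherwise the normal approximation with tie-corrected variance

`var = n1·n2/12 · [(n+1) − Σ(t³−t)/(n(n−1))]`

and a 0.5 continuity correction. If both groups share a single common
value the test is degenerate and p = 1 by convention. Two-sided p-values
are reported because direction is carried separately by the sign of the
mean shift. Significance labels follow the conventional star scale
(*** p<0.001, ** p<0.01, * p<0.05).

**Direction handling.** Directions come from an up/down column or from the
sign of an effect column (zero effects dropped and counted). A gene
reported in both directions — common when pooling cell types — is kept
once in the combined set with label "both" and appears in each direction
view, so `|up| + |down| ≥ n` with equality iff no conflicts. Gene symbols
are normalized by uppercase+trim only; no alias resolution is attempted,
and genes without an age assignment are dropped and reported rather than
imputed.

**Heterogeneity.** The per-stratum direction balance is
`n_up/(n_up+n_down)` (undefined when both are 0). Cross-dataset
heterogeneity at a stratum is the sample SD (ddof=1) of the balances —
a deliberately minimal statistic, invariant under a global up↔down
relabeling. This summary is an extension supplied by this package; no
canonical formula exists in the literature for "heterogeneity of
direction", so the number should be read as descriptive, not inferential.

## Synthetic-data generator

The generator emulates exactly the structure the tests assume, nothing
more: a universe of `universe_size` genes multinomially assigned to strata
by a 19-weight composition vector, and a DEG set of `n_deg` genes drawn
without replacement with weights `exp(−beta·(rank−1))`. Sampling uses the
Gumbel top-k construction, which is distributionally identical to
sequential draws with renormalization (the induced per-stratum counts
follow the multivariate Wallenius noncentral hypergeometric law) and
reduces *exactly* to the uniform/hypergeometric null at `beta = 0`.
Directions are i.i.d. Bernoulli with `P(up|rank) = expit(intercept +
slope·rank)`, letting direction balance vary by stratum.

Defaults: `universe_size = 19,000` (the scale of a genome-wide
protein-coding assignment), `n_deg = 500` (a typical meta-signature size),
`beta = 0`, symmetric directions. The bundled default composition puts
heavy mass on ranks 1 and 12, mimicking the qualitative two-peak shape of
genome-wide phylostratum censuses (unicellular origin and the
bony-vertebrate expansion); it is explicitly synthetic, not an empirical
genome census. All minimum stratum weights are ≥ 0.03 so that every
stratum is statistically testable at `n = 500`: much smaller strata make
the discrete test's attainable size collapse well below the nominal level,
which would render per-stratum calibration checks uninformative.

What the generator does **not** emulate: expression magnitudes, per-cell
or per-sample noise, correlated gene modules, symbol aliasing, or
incomplete age-map coverage. Passing tests therefore demonstrate the
statistical machinery on sets with exactly the assumed sampling structure;
they say nothing about upstream DEG-calling quality on real data.

**Bias estimation.** `estimate_beta` inverts the method-of-moments
equation: the expected mean rank under the Wallenius model equals the
observed mean rank. Expected per-stratum counts solve the standard
Wallenius mean equation `Σ M_s (1 − t^{w_s}) = n` for `t ∈ (0,1)`
(computed in `log t` to survive extreme weights), and the outer root in
`beta` is found by Brent's method on `[0, 50]`. Observed mean rank at or
above the universe mean returns `beta = 0`; an observed mean below what
`beta = 50` can produce returns the bound, flagged. The estimator is
numerically consistent at the simulated conditions: at `n = 5,000` from a
19,000-gene universe its mean over 100 replicates reproduces the true
`beta` to three decimals (see `scripts/acceptance.py` output).

## Calibration and known limitations

Monte Carlo calibration (1,000 uniform null sets of 500 genes) shows
per-stratum over-tail rejection rates of 0.03–0.05 at nominal 0.05. The
shortfall is structural, not a defect: a one-sided test on a discrete
count can only reject with probability equal to the tail mass of its
rejection region, which lies strictly below the nominal level (0.041–0.050
for strata of 570–3,800 genes at `n = 500`). The test suite therefore
checks empirical rates against the analytically attained size of each
stratum's test, and separately that no stratum is anti-conservative. Users
comparing empirical false-positive rates against the nominal level should
expect the same conservative bias in any tool computing these tails
exactly.

Problem sizes used by the bundled studies — 1,000 null replicates at
`n = 500`, and 100 replicates per `beta` at `n = 5,000` — are the
package's standard simulation conditions; they give binomial/SE precision
comfortably finer than the effects being checked.

Other limitations: percentages in the bar charts use the per-direction
denominator by default (each series sums to 100%), switchable to the
combined-set denominator — published figures in this area rarely state the
choice, so it is explicit here; the ordinal mean shift weights all
category boundaries equally; and the package deliberately performs no
ortholog mapping, so cross-species DEG tables must arrive pre-mapped to
the symbols of the age table.
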