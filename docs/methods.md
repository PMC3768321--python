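# Methods

This note documents the models and numerical choices behind each stage of
the pipeline, what the synthetic generator does and does not emulate, and
the known limitations.

## Distances

The generalized Euclidean distance (GED) treats each character as
contributing a squared difference `δ²`: `δ = |x − y|` for ordered
characters, `δ = 1{x ≠ y}` for unordered ones.  A polymorphic cell scores
the minimum difference over its member states (a `mean` option averages
instead); this is the conservative convention of cladistic distance
software.  When one or both cells are missing the character's `δ²` is
imputed as the pair's weighted mean `δ²` over jointly scored characters,
and the distance is `sqrt(Σ_i w_i δ_i²)` over all N characters.  With
complete data the imputation is a no-op and GED equals the Euclidean
distance between state vectors, which is the oracle used in tests.  A pair
sharing no scored character has no defined distance and raises an error
rather than guessing.  Ordered characters use raw state differences, not
range-rescaled ones; rescaling can be expressed through the per-character
weights.  Character weights default to 1.

Phylogenetic distances are path sums of branch durations (Myr); the
square-root transform used when correlating them with morphological
distances stabilizes the variance of what is otherwise a sum of many
small independent increments.

## Ordination

Classical principal coordinates: Gower-centre `−½d²`, eigendecompose,
scores are eigenvectors scaled by `√λ` for positive eigenvalues.  Imputed
GEDs are generally not Euclidean-embeddable, so negative eigenvalues are
expected; they are logged and kept in the reported spectrum but produce no
axes, and no correction is applied by default (Lingoes and Cailliez are
available by flag).  Twenty axes are retained by default; if fewer
positive eigenvalues exist the result is truncated with a warning, not an
error.  Eigenvalues within `1e-10` (relative) of zero are snapped to zero
to avoid manufacturing spurious axes from numerical noise.  Axis signs
are arbitrary; every downstream statistic is sign-invariant, and tests
verify this by flipping axes.

## Morphospace

Ancestral positions for phylomorphospace are the Brownian-motion ML
estimates per axis: the joint minimizers of
`Σ_branches (Δx)²/duration`, obtained by solving the sparse linear system
in which every internal node is the 1/duration-weighted average of its
neighbours.  Zero-duration branches receive an epsilon (default `1e-8`
Myr, with a warning) to keep weights finite.

Spatial structure in PCo 1–3 uses Ripley's K,
`K(r) = V/(n(n−1)) Σ_{i≠j} e_ij 1{d_ij ≤ r}`, with the translation edge
correction `e_ij = V / Π_k (L_k − |Δx_k|)` inside an axis-aligned
observation box.  The box is the bounding box of the observed points
expanded by 5% per side — the analysis does not dictate a natural window,
so the box choice is configurable and recorded.  The r grid spans 0 to
half the shortest box edge (100 points).  The null reference is complete
spatial randomness (CSR): uniform points in the same box; the envelope is
the pointwise min/max of `nsim` simulated K curves (rank-1), so with
`nsim = 999` a pointwise exceedance has probability ≈ 1/1000 under CSR.
The envelope is pointwise, not global: simultaneous coverage over the
whole r grid is weaker, which is why verdicts are reported as the
fraction of r values above the envelope rather than a single p-value.

## Disparity

Four indices per taxon set, computed on the retained ordination axes:
sum and root-product of per-axis ranges (occupation), sum and
root-product of per-axis sample variances (spread; denominator m−1, zero
for singletons).  Root-products use the k-th root, computed as
`exp(mean(log))`; any zero range or variance makes the root-product
exactly 0, a degenerate case that is logged.  Uncertainty comes from
bootstrap resampling with replacement (default 1000 replicates) with
percentile 2.5/97.5 CIs; rarefied profiles resample at the smallest
group's size, which removes sample-size bias from the range indices in
particular.  Two groups differ "significantly" when their CIs are
disjoint — a deliberately conservative criterion.  Time-bin membership
uses the observed range: a taxon belongs to every bin `[end, start)` its
`[lad, fad]` interval overlaps, closed on the FAD side, so a range
touching a bin's younger boundary still counts there and a point range
falls in exactly one bin.

The default bin table is eleven Late Permian–Early Jurassic stage and
substage intervals anchored at the Permo-Triassic boundary (252 Ma) with
durations 5, 7, 4, 6, 7, 4, 12, 10, 5, 7 and 7 Myr (257–183 Ma overall);
for rate analyses the three Jurassic intervals are pooled, giving nine
bins.  Both tables are overridable.

## Time-calibration

Three a-posteriori variants date a topology from first appearances
(tips sit at their FAD, on the assumption that a terminal branch's
changes accrued before the taxon's first documented occurrence):

- `basic`: node age = oldest descendant FAD; zero branches allowed; the
  minimum-total-duration solution.
- `mbl`: after `basic`, every branch — terminal branches included — is
  forced to at least `mbl` Myr (default 1) by pushing ancestors older, so
  the output satisfies `duration ≥ mbl` everywhere.
- `equal`: the root is extended by `root_buffer` Myr (default 2) and each
  chain of zero-duration branches is re-spaced evenly over the time of
  the nearest ancestral positive branch.

All three are recorded in output metadata; when a study supplies its own
calibrated tree, reading that tree directly is preferred over re-dating.

## Rates

Change counts come from unordered-state parsimony, computed per character
by unit-cost dynamic programming over states (equivalent to Fitch on
binary trees, exact on polytomies, and uniform in its treatment of
missing cells — full state set — and polymorphisms — member set).
Ancestral states are then resolved in preorder: at each branch the child
state must preserve the minimal subtree cost; when changing now or deeper
costs the same, ACCTRAN changes on the current branch (changes accumulate
rootward) and DELTRAN keeps the parent state (changes deferred tipward).
Remaining ties go to the lowest state index — tie-breaking conventions
differ between programs, so per-branch placements are convention-dependent
even though the per-character total always equals the parsimony length
(oracle-verified against exhaustive enumeration).

Missing data make changes unobservable: a branch's `scorable_fraction` is
the fraction of characters coded at the relevant tip (terminal branches)
or coded by at least one tip on each side of the branch (internal
branches).  Corrected changes = raw / fraction; the rate is corrected
changes per Myr of branch duration.  Zero-rate branches carry no
information on the log scale and are excluded from rate analyses, and
non-zero rates are also provided log10-transformed.

Rate-homogeneity tests use a Poisson model for the **raw** count of branch
i with mean `λ_i · duration_i · scorable_fraction_i` — the completeness
correction enters as an exposure offset.  (Rescaling the counts themselves
and pretending the result is Poisson inflates the variance by the squared
correction factor and distorts the tests; the offset form keeps the same
rate estimates with a correctly specified likelihood.)  The global LRT
compares a single shared rate against per-branch rates (χ², branches−1
df); per-branch LRTs compare each branch against the pooled rest (1 df)
with Benjamini–Hochberg control at α = 0.05 across branches, flagging
high/low by the sign of the branch rate minus the pooled rate.

Calibration caveat, measured on the synthetic generator: with 150
characters and 40 taxa, a 5× rate elevation injected into one clade is
detected (≥1 high flag inside the clade) in essentially every replicate,
and under the homogeneous null the fraction of branches falsely flagged
stays below α (~0.04).  However, parsimony-reconstructed counts are not
exactly duration-proportional Poisson — homoplastic changes concentrate
on short internal branches and long branches saturate — so under the
end-to-end null the probability that *some* branch is flagged in a given
tree is well above α.  Per-branch flags should therefore be read as an
FDR-controlled screen, not as a family-wise-error-controlled test of
"any heterogeneity", and the global LRT inherits the same model misfit on
real (reconstructed) counts.

For rates through time, each included branch contributes its single rate
to every interval its duration overlaps; log10 rates are regressed (OLS)
on interval midpoints and the association is summarized by Kendall's τ
with the tie-corrected normal approximation.

## Statistical battery

Permutation tests use the +1 rule (the observed arrangement counts), so
`p ≥ 1/(nperm+1)`; all record statistic, permutation count and seed.
Mantel tests correlate upper triangles (Pearson/Spearman/Kendall) and
permute the second matrix's taxa; they are two-sided by default (a
one-sided option exists), with 999 permutations by default.  npMANOVA
computes the pseudo-F from among/within sums of squared Euclidean
distances on the retained axes and permutes group labels (9999 by
default, enough to resolve p ≈ 1e-4), with Bonferroni-adjusted pairwise
tests; ANOSIM ranks the distance matrix with mid-ranks and uses
`R = (mean between − mean within)/(M/2)`.  Kruskal–Wallis and
Mann–Whitney wrap scipy's tie-corrected statistics.  Generalized
differencing fits an OLS trend, estimates the residual lag-1
autocorrelation ρ, and returns the exact AR(1) GLS transform of the
residuals (`e_t − ρ e_{t−1}`, first element scaled by `sqrt(1−ρ²)`);
series shorter than 4 are refused because ρ is inestimable.

## Synthetic generator

The generator emulates a fossil-clade study: a birth–death tree
conditioned on total tip count with extinct tips retained (default 54
taxa; birth 0.09, death 0.045 per lineage-Myr, giving a tree height of a
few tens of Myr), anchored so the youngest tip sits at 183 Ma; characters
(default 150) with 2–5 states drawn mostly binary
(probabilities 0.55/0.25/0.12/0.08), evolved by equal-rates Mk with total
leaving rate 0.005 per Myr — a few changes per character over the tree,
the regime where parsimony is informative but homoplasy exists; invariant
columns resampled (cladistic matrices contain only variable characters);
per-taxon missingness uniform on (0.05, 0.55), mean ≈ 0.3, typical of
fossil matrices; observed ranges built from an exponential FAD lag toward
older ages (rate 0.5/Myr, truncated at the subtending branch) and an
exponential range duration (mean 3 Myr).  Groups are read off the
topology: the two largest disjoint clades holding between one sixth and
one half of the tips (keeping at least ~10% of tips outside both) become
the derived clades; the residue is the basal paraphyletic array.

What it does **not** emulate: character correlation and ordering
structure, clade-specific missingness (completeness is independent of
phylogenetic position), directional trends, and geographic/collection
biases in preservation.  Passing tests on these data therefore
demonstrate internal correctness and statistical calibration of the
machinery under a clean Mk world, not robustness to every pathology of
real matrices.

All randomness flows through one explicitly passed seeded generator; no
global random state is used anywhere.

## Problem sizes used in validation

The acceptance script and test suite run at desk scale chosen to keep the
Monte Carlo error of each check well below its assertion margin: 200
replicates for the rate power/false-flag experiment (40 taxa, 150
characters), 500 simulations for permutation-test size (compared against
the binomial 95% CI of α = 0.05), 10,000 characters for the Mk
closed-form check, exhaustive enumeration up to 6 tips / 120 label
permutations for the parsimony and Mantel oracles.

## Known limitations

- Parsimony change counts are minimum estimates; rates are accordingly
  lower bounds, compressed on long branches (saturation).
- ACCTRAN/DELTRAN placements beyond the per-character total depend on
  documented tie-breaking and need not match other software exactly.
- The K-function envelope is pointwise; the disparity CI-overlap
  criterion is conservative; both are reported as such rather than
  converted into single p-values.
- Internal-node positions are not included in disparity, and rates are
  assumed constant within a branch.
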