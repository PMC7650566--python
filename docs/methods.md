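# Methods

## Problem and data model

Four tropical tuna species — yellowfin (YFT, *Thunnus albacares*), bigeye
(BET, *T. obesus*), skipjack (SKJ, *Katsuwonus pelamis*) and longtail
(LOT, *T. tonggol*) — are tracked through five canning processing levels:
L1 frozen, L2 defrosted, L3 cooked, L4O canned in oil, L4B canned in
brine.  The barcode locus is a 236-column window of the mitochondrial
Cyt b gene, anchored to the *T. thynnus* mitogenome (NC_004901, positions
14665–14901).  Three fragments are amplifiable: AB spanning the full
window, and the mini-barcodes A and B used when DNA is too fragmented for
AB.  The package fixes A = columns 1–117 and B = columns 128–236; the
published fragment lengths (117 and 109 bp) do not tile the 236-bp window
(117 + 109 = 226), so a 10-column inter-primer region is left between
them.  This layout is a package convention — the true primer coordinates
inside AB are not public — and it is configurable in the panel config.

All coordinates are 1-based inclusive.  The alphabet is {A,C,G,T,N,-}; a
column containing N or a gap in any sequence involved in a comparison is
excluded from that comparison (ambiguity never counts as match or
mismatch).

## Distances, the barcode gap, diagnostic positions

The p-distance between two aligned sequences is the proportion of
differing bases among columns where both characters are in {A,C,G,T}.
Identity used for species assignment is the complement,
`100 · matches / comparable`, reported to two decimals.

With species labels known, the barcode gap is tested in a single pass:
pairwise distances are split into intra- and inter-specific sets and a gap
is declared when `inter.min > intra.max` and the gap width exceeds
`(X − 1) · intra.max` with relative gap width X = 1.5.  This is a
deliberate simplification of recursive barcode-gap partitioning, which
addresses de novo species delimitation; here the labels are given and the
question is only whether the reference panel supports threshold-based
assignment.  With no intra-specific pairs (one sequence per species),
`intra.max` is taken as 0.

A column is diagnostic for a focal species against a contrast set
(default: all other species) when the focal species is fixed for one base,
every contrasted species is fixed, and the focal base differs from every
contrasted base.  Both the one-vs-all and the pairwise mode are exposed,
since either reading of "diagnostic" is defensible; one-vs-all is the
default.  Columns are returned in ascending coordinate order.

## NS: substitutions along the processing chain

For each specimen at each level, nNS counts the fragment columns that
differ from the *same specimen's* L1 sequence (both bases informative),
and `NS% = 100 · nNS / L_f` where `L_f` is the length of the fragment
actually sequenced at that level (236, 117 or 109).  The fragment-length
denominator is an inference from the published group means, which are
reproduced exactly by k/109 and k/117 arithmetic (e.g. 7/109 = 6.42%); a
full-alignment denominator is available as an option.  Group means are
unweighted arithmetic averages of the *exact* per-specimen percentages;
only the group mean is display-rounded.  All percentages are reported to
two decimals, rounded half away from zero.

## Identification and concordance bookkeeping

Each query is scored against every panel record sliced to the query's
fragment.  The best identity (at two-decimal precision, which also
resolves ties the way multi-species rows with a single printed similarity
imply) determines the status: below the 98% threshold → AMBIGUOUS; several
species tied at the best identity → TIE; otherwise ASSIGNED.  Comparing
with the morphological label: ASSIGNED to the same species → CONCORDANT;
ASSIGNED elsewhere → MISIDENTIFIED; a TIE is MISIDENTIFIED in the default
strict mode even when the tie set contains the morphological species
(matching the published bookkeeping, which lists equal-similarity
multi-species assignments among the misidentified samples); a lenient mode
accepts such ties.  AMBIGUOUS and FAILED records count toward each cell's
total but never toward the concordant numerator, which is how
"34 concordant of 64" arithmetic treats them.

The packaged fixtures transcribe the study's printed tables.  The
misidentification table's low-similarity flag is inconsistent as printed
(three sub-98% rows lack it), so outcome classification uses the uniform
rule similarity < 98 → AMBIGUOUS; the concordance counts are unaffected.

## Synthetic panel construction

The generator plants the distance structure explicitly rather than hoping
a random process realises it:

* **Shared diagnostic columns** — `n_diagnostic_in_b` (default 7) columns
  inside fragment B where every species carries a distinct base.  These
  columns are diagnostic for every species and contribute to every
  pairwise inter-specific distance.  (This caps the generator at 4
  species, one per base.)
* **Private columns** — each species gets a set of private columns
  (outside B when space allows) where it alone differs from the consensus;
  the count is chosen so the planted pairwise difference count lands at
  the midpoint of the target inter-specific range (defaults [0.09, 0.14],
  giving 7 shared + 2×10 private = 27 differences on 236 columns,
  p ≈ 0.114).
* **Intra-specific noise** — sequences after each species' archetype
  receive 0–3 substitutions at neutral columns, bounded so that two noisy
  sequences stay inside the intra range (defaults [0, 0.05]) and noise on
  top of the planted differences cannot push any inter-specific distance
  past its upper bound.

Realised distances and diagnostic columns are verified post hoc and the
construction is retried on violation (it cannot violate by construction,
but the check is cheap insurance); an infeasible specification raises
after bounded retries.

## Degradation model

Substitution counts per level are Poisson with level-specific means
λ = {L1: 0, L2: 0.3, L3: 1.2, L4O: 2.5, L4B: 4.5}, applied to the columns
of the fragment amplified at that level.  The defaults are calibrated so
simulated group-mean NS% rises monotonically through the chain with brine
canning highest — at the default seed the per-level means are 0.00, 0.12,
0.59, 2.86, 6.36%, inside the ranges observed for real specimens (up to
6.42%).  A fraction `diagnostic_bias` (default 0.7) of the substitution
mass targets the species' diagnostic columns, reflecting the observation
that substitutions concentrate in diagnostic positions; the remainder is
uniform over the other eligible columns, and mass directed at a saturated
pool is truncated, never redirected.  Substituted bases are uniform over
the three alternatives to the specimen's own L1 base, so a substitution
never silently restores the reference state and the substitution set grows
monotonically along the chain (damage is cumulative because the same
individuals are tracked; an independent-per-level mode exists).

Fragment availability is drawn per level from a categorical table whose
defaults reproduce the observed pattern: AB at L1–L2; AB with occasional A
or failure at L3 (24:7:2 in 33); B with a rare A at L4O; B with a rare
failure at L4B.  Amplification outcome is independent of the substitution
count: fragmentation and base damage are reported as separate phenomena,
and a coupling between them is not identifiable from the available data.

Each individual's L1 haplotype is a randomly chosen panel sequence of its
species plus 0–2 substitutions at neutral columns, emulating
intra-specific haplotype variation.  All randomness flows through explicit
`numpy.random.Generator` seeds; no global state.

What the generator does **not** emulate: the chemistry of DNA damage
(deamination spectra, strand breaks), Sanger chromatogram noise, and —
critically — *directional* base damage.  Real canned-tuna data show
degraded sequences converging on other species' bases at diagnostic
positions (misidentifications at ≥98% identity, up to 100%); under the
uniform-alternatives model a substituted diagnostic column matches any
particular other species with probability 1/3, so full conversions are
rare events rather than the norm.  Passing simulation tests therefore
demonstrate the pipeline's accounting and the direction of the degradation
effect, not the real-world misidentification *rates*.

## Poisson mixed model

`fit_poisson_glmm` maximises the Laplace approximation to the marginal
likelihood of a Poisson log-link model with scalar random intercepts.  For
a single grouping factor the conditional mode of each group's intercept is
found by a damped, vectorised Newton solve, and each group contributes
`ℓ(û) − û²/(2σ²) − ½ log(1 + σ² Σᵢ μᵢ(û))`.  For two genuinely nested
factors (e.g. `species/individual`) the joint mode per outer block is
solved densely with the corresponding log-determinant correction.
Optimisation over (β, log σ) uses BFGS with finite-difference gradients,
starting from a log-mean intercept; standard errors come from a
central-difference Hessian at the optimum.  The fit is deterministic given
the data, invariant to record order, and checked in the tests against both
a plain IRLS Poisson regression (variance pinned at zero) and R's `lme4`
Laplace fitter (loglik, coefficients and variance agree to ~1e-4 on
simulated data).

The literal `(1 | Individual/Species)` expands to intercepts for
Individual and Individual:Species; with one species per individual the two
partitions coincide and only the summed variance is identified, so the
package collapses them and reports a single component.  Consequently the
default pipeline fit has 20 fixed-effect parameters + 1 variance
component.  L1 records (nNS = 0 by construction) stay in the model — the
interaction-vs-additive likelihood-ratio test needs all five level
categories to have its 12 degrees of freedom.  Treatment coding uses the
alphabetically first level (L1) and species as references.  Degenerate
input (all counts zero) is flagged, not fitted; a design with an empty
level×species cell drops the unidentifiable columns and sets a
`singular_design` flag.

Overdispersion follows the standard Pearson recipe: residuals
`(y − μ̂)/√μ̂` at the conditional means, ratio = Σr²/(n − p) with p = fixed
effects + variance components, and an upper-tail chi-square p-value on
Σr².  Ratios near 1 indicate Poisson-consistent dispersion.

## Numerical conventions

* Percentages: two decimals, half away from zero (exact rational
  arithmetic via `decimal` before rounding).
* Identity ties: resolved at the two-decimal display precision.
* Inner Newton solves: gradient tolerance 1e-10, step clipping ±4;
  outer BFGS: gradient tolerance 1e-6, max 200 iterations; the
  convergence flag reports the optimiser's honest status.
* p-distance with zero comparable columns and identification with no
  sequence are errors / FAILED, never silently 0.

## Problem sizes used in the checks

The test-suite simulations use the study's own design (33 individuals, 165
records) for pipeline-level checks; parameter-recovery uses 500
individuals × 5 levels over 200 replicates; overdispersion calibration
uses 100 individuals over 100 replicates.  The end-to-end
misidentification direction check (L4B above L2 under full diagnostic bias
with λ ≥ 7 on the B-fragment levels) runs 100 replicates on a doubled
cohort (6 individuals per species×area cell, 66 individuals): with
uniform-alternatives damage a full 7-column conversion has per-specimen
probability ≈ 0.06, so the paper-sized cohort leaves a single replicate
unable to resolve the direction reliably, while the aggregate rates
(≈ 6% at L4B versus 0% at L2) are unambiguous at either size.

## Known limitations

* The synthetic panel supports at most four species (distinct-base
  diagnostic columns) and plants a deliberately clean structure; real
  reference panels have rate heterogeneity, shared polymorphism and
  unbalanced sampling that the generator does not attempt.
* In-panel percent identity replaces a live database search; results
  depend on panel completeness exactly as a real search depends on
  database coverage.
* The GLMM handles scalar random intercepts with at most two nested
  grouping factors — the structure the pipeline needs — not arbitrary
  random-effect designs.
* The published test statistic of the level×species interaction is not
  reproducible without the study's unreleased sequence data; the model is
  validated structurally (degrees of freedom) and by simulation
  (parameter recovery, calibration) instead.
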