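# Methods

## Problem setting

Two paralogous proteins are aligned pairwise over L columns. For each
paralog, a set of alignment columns has been inferred to be under positive
selection (typically codeml M8 Bayes Empirical Bayes sites retained at
posterior Pr(ω>1) ≥ 0.75; the threshold is inclusive and configurable).
One paralog's sequence corresponds to a solved structure, so selected
columns can be placed on Cα coordinates. The scientific question: are the
two paralogs' selected sites *differentially clustered* — in distinct
alignment regions and/or distinct structural patches — as expected if
selection acted on different functional surfaces after duplication?

## Runs test with bootstrap null

The selected columns of both paralogs, in alignment order, form a category
string over {A_ONLY, B_ONLY, BOTH}. The statistic is the run count
R = (number of adjacent category changes) + 1, so 1 ≤ R ≤ string length;
clustering of each paralog's sites into contiguous regions yields small R.

Because the classical Wald–Wolfowitz normal approximation covers only two
categories, the null is simulated: in each of n_reps replicates (default
1000), every one of the L columns independently becomes selected in A with
probability p_A and in B with probability p_B; a doubly selected column is
BOTH; unselected columns are dropped; R is recorded. p_A and p_B are the
*marginal* observed proportions |A|/L and |B|/L, counting shared columns in
both — required for consistency, since the null marks a column BOTH exactly
when both Bernoulli draws succeed. The one-sided p-value is
#{R_sim ≤ R_obs}/n_reps, with no pseudo-count (the minimum attainable p is
0; n_reps is always reported next to it). A replicate whose simulated
string is empty scores 0 runs — below any observable count, hence
conservative; at realistic selection proportions the event has negligible
probability. The `exclude_both` variant removes shared columns from both
the observed and each simulated string, leaving a two-category test.

Position-wise Bernoulli draws are used rather than resampling the observed
142-long indicator strings with replacement; for independent columns the
two schemes coincide in distribution.

**Calibration.** When the null is simulated at the true generating
proportions, null p-values are near-uniform: the measured rejection rate at
α = 0.05 over 500 independent bundles sits inside the exact 99% binomial
interval (the acceptance script recomputes this). The *plug-in* procedure —
proportions re-estimated from each observed string, which is how the test
is run on real data — is intrinsically conservative (measured attained
level ≈ 0.02–0.04): conditioning the null on the observed site counts
removes the count-driven component of the run-count variance. Practically
this means p-values from the plug-in test understate significance slightly;
a significant result is therefore trustworthy, and marginal
non-significance should not be over-read.

## Plane-partition test

The "plane of best fit" is the ordinary-least-squares regression of the z
coordinate on (x, y), reported as a unit normal n and offset c (plane
n·x = c). OLS matches the described regression workflow but is not
coordinate-free; `method="pca"` fits the total-least-squares plane (normal
= smallest principal component), which is rotation-equivariant and is also
the prescribed fallback when the best plane is nearly vertical and the
normal equations are ill-conditioned (condition number > 1e10 raises with a
pointer to PCA). Normal signs are canonicalized (largest-magnitude
component positive) for determinism.

The perpendicular ("top/bottom") plane is under-determined — infinitely
many planes are orthogonal to the first — so its normal is chosen as the
direction of maximal Cα variance *within* the fitted plane, the only
coordinate-free choice; an isotropic in-plane spread (relative eigen-gap
< 1e-8) is an error. Residues with signed distance ≥ 0 take the second
label of the pair ("right"/"bottom"); the tie at exactly 0 is measure-zero
for real coordinates.

Per paralog, the observed number of selected sites on each side is
compared with E_side = n_sites × (side size / total residues) by
χ² = Σ (O−E)²/E with df = 1 (upper tail). A zero expected count raises; an
expected count < 5 warns. Sites selected in both paralogs enter each
paralog's observed vector (consistent with the neighbor test's
counted-twice rule). With discrete two-cell counts the attained level at
α = 0.05 is ≈ 0.03 — conservative, never anticonservative; the test suite
checks the level against the upper 99% binomial bound.

## Nearest-neighbor affiliation test

Each selected column, mapped to a residue, yields one *instance* per
paralog that selected it; a shared column yields two co-located instances
flagged `shared`. For every instance the Euclidean nearest other instance
is found, excluding itself and its co-located twin (otherwise every shared
site would trivially self-match at distance 0). Distance ties break by
lower residue index, then paralog A before B — deterministic and recorded
in the report. The neighbor counts as "same" when it belongs to the same
paralog *or* is shared. The four observed counts are compared with the
random-labeling expectation (nearest neighbor uniform among the other
n_A + n_B − 1 instances): E[A→same] = n_A(n_A−1)/(n_A+n_B−1), etc., which
preserves per-paralog totals. Following the original design the statistic
is referred to χ² with 3 degrees of freedom.

**Calibration.** Nearest-neighbor indicators are not independent, so the
χ²(3) reference is approximate in both directions: under label permutation
over fixed positions with no shared sites it is mildly conservative
(measured level ≈ 0.04), while under the full Bernoulli null *with* shared
sites it is markedly anticonservative (measured ≈ 0.3 at α = 0.05),
because the shared-neighbor-counts-as-same rule inflates same-paralog
tallies relative to an expectation that ignores sharing. The
`null="permutation"` option (default 10,000 label shuffles over the
occupied positions, empirical p = #{χ²_perm ≥ χ²_obs}/n_perm) is calibrated
(measured 0.05) and is the defensible choice when shared sites are
numerous; the χ² variant is retained as the method's canonical form.

## Alignment ↔ structure mapping

Columns are 1-based; residue indices are 1-based chain-sequential (the
i-th residue with a Cα atom), not author PDB numbering — an integer
`offset` reconciles the two. The ungapped reference row must match the
structure sequence at ≥ 95% identity (configurable); failure names the
first mismatching column. The mapping is strictly monotone and injective;
gap columns are unmapped, and unmapped selected columns are dropped with a
logged count. Percent identity offers both denominator conventions (all
columns vs columns without gaps) because published identity figures rarely
state which was used. PDB altloc duplicates keep the first-listed location
with a warning; for multi-model (NMR) files a single 1-based model is read,
defaulting to the first.

## Synthetic generator

`SyntheticSpec` defaults are the study conditions the tests were designed
around: L = 142 alignment columns / chain residues, p_A = 62/142 ≈ 0.437
and p_B = 30/142 ≈ 0.211 expected selection proportions. Chains are either
a freely jointed random walk (uniform random step directions, exact 3.8 Å
Cα–Cα spacing, no excluded volume) or an ideal α-helix (1.5 Å rise, 100°
twist, radius chosen so the spacing is exactly the bond length). Under the
null, sites are independent Bernoulli per column — *exactly* the runs-test
null. Under the clustered alternative, per-residue selection probabilities
are ∝ exp(−d(residue, focus)/λ), renormalized by water-filling (capping at
probability 1 and redistributing outward) so the expected count remains
n·p; as λ → ∞ this reduces exactly to the null. The paralog B alignment
row is mutated at columns selected in exactly one paralog, so sequence
divergence coincides with differential selection. Posteriors for selected
columns are drawn uniformly in [0.75, 1].

What the generator does *not* emulate: real protein compactness and
secondary-structure geometry, alignment gaps (injected only in dedicated
IO tests), correlation between selection strength and solvent exposure,
and posterior uncertainty in site identification. Passing tests therefore
demonstrate the statistical machinery, not robustness to codeml inference
error.

Randomness: one seeded generator per stage, derived from the spec seed via
`SeedSequence.spawn`, so structure geometry and site draws are independent
yet fully reproducible; every output records its seed.

## Problem sizes and numerical conventions

Simulation-based checks use: 20,000 replicates against the exhaustive
L = 3 enumeration (64 outcomes); 500 null bundles for type-I error; 100
seeds for block-clustered power; 150 bundles per arm for the
clustered-vs-null neighbor comparison; 40 seeds per point on the
power-monotonicity decay grid (λ = 50, 10, 2 Å). These sizes give binomial
standard errors small enough for the stated margins while keeping the full
suite fast. Chi-square p-values come from `scipy.stats.chi2.sf`; plane
fits solve the normal equations directly and refuse rank-deficient or
ill-conditioned inputs rather than silently regularizing. Reports
serialize with sorted keys so identical inputs and seeds reproduce
byte-identical JSON.

## Known limitations

- The plug-in runs test is conservative (see above); a studentized or
  double-bootstrap correction is out of scope.
- The χ²(3) affiliation reference ignores nearest-neighbor dependence and
  the shared-site rule's bias; use the permutation null when shared sites
  are common.
- OLS plane fitting depends on the coordinate frame of the deposited
  structure; PCA is the frame-free alternative and both are exposed.
- Only pairwise (two-paralog) comparisons are supported; no
  multiple-testing correction is applied across the seven reported
  p-values (the report notes the test count).
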