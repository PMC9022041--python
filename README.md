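# paraclust

Tests for whether positively selected sites in two **paralogous proteins**
are differentially clustered — along the linear sequence alignment and on a
shared 3D structure.

After a gene duplication, the two copies may partition the ancestral
function (subfunctionalization). One sequence-level signature of this is
that sites under positive selection (e.g. codeml M8 sites retained at a
Bayes Empirical Bayes posterior Pr(ω>1) ≥ 0.75) fall in *different regions*
of each paralog. `paraclust` implements three complementary tests of that
hypothesis, aimed at molecular evolution studies of rapidly diverging
protein families such as the abalone sperm acrosomal proteins:

1. **Multi-category runs test (bootstrap null).** Selected columns of the
   pairwise paralog alignment are labelled `A_ONLY` / `B_ONLY` / `BOTH` in
   order; the number of runs R (category changes + 1) is compared with a
   simulated null in which each of the L columns is selected independently
   in paralog A with probability p̂_A = |A|/L and in B with p̂_B = |B|/L.
   The one-sided p-value is #{R_sim ≤ R_obs}/n_reps: few, long runs mean
   regional clustering. A second variant drops the shared (`BOTH`) columns.
2. **Plane-of-best-fit partition.** A plane is fitted through the Cα atoms
   (OLS of z on (x, y); a PCA/total-least-squares plane via a flag),
   splitting the structure into "left"/"right"; a perpendicular plane along
   the maximal in-plane variance direction gives "top"/"bottom". Per
   paralog, observed side counts of selected sites are tested against
   E_side = n_sites × (residues on side / total residues) with a 1-df
   chi-square.
3. **Nearest-neighbor affiliation.** For every selected site instance
   (shared sites count once per paralog), the Euclidean nearest selected
   site is classified *same-paralog* or *other-paralog* (a shared neighbor
   counts as same); the 4-cell table (A→same, A→other, B→same, B→other) is
   compared to the random-labeling expectation P(same|A) = (n_A−1)/(n_A+n_B−1)
   with a 3-df chi-square, or with a label-permutation null.

A synthetic-data generator produces Cα chains (freely jointed random walk
or ideal α-helix, exact 3.8 Å spacing), matching gapless paralog alignments
and site sets under either the independent-selection null or a clustered
alternative (selection probability ∝ exp(−d/λ) around per-paralog foci), so
every stage is testable with no downloads.

## Worked example

```python
import json
import paraclust as pc

# a clustered synthetic bundle: foci at opposite chain ends, 4 Å decay
spec = pc.SyntheticSpec(
    seed=42,
    clustering=pc.SpatialClustering(focus_a=1, focus_b=142, decay_length=4.0),
)
structure, aln, sites_a, sites_b = pc.generate_bundle(spec)
report = pc.analyze(structure, aln, sites_a, sites_b, seed=0, n_reps=1000)
print(json.dumps(report.p_values(), indent=2))
```

prints

```
{
  "runs_three_category": 0.0,
  "runs_two_category": 0.0,
  "plane_main_a": 0.0014424586936788164,
  "plane_main_b": 0.17649999365374106,
  "plane_perpendicular_a": 6.181261605493176e-11,
  "plane_perpendicular_b": 0.0031707860580241455,
  "neighbor_affiliation": 1.2393957654085818e-08
}
```

This bundle has 56 selected sites in paralog A and 34 in B (9 shared). The
observed category string has 18 runs against a bootstrap null mean of ≈45,
so no simulated string was as clustered (p = 0, with n_reps = 1000 reported
alongside — no pseudo-count is added). The nearest-neighbor table is
(A→same, A→other, B→same, B→other) = (46, 10, 28, 6), far from the
random-labeling expectation, hence the tiny affiliation p-value. The plane
tests show paralog A's sites significantly enriched on one side of both
partitions. On a *null* bundle (no `clustering`), all seven p-values are
unremarkable.

The same pipeline runs from the shell:

```
paraclust simulate --seed 42 --out bundle/
paraclust runs-test --aln bundle/alignment.fasta \
    --sites-a bundle/sites_a.tsv --sites-b bundle/sites_b.tsv \
    --reps 1000 --seed 0
paraclust report --config config.json --out report.json
```

Real inputs are a PDB file (Cα atoms of one chain; for NMR ensembles one
model is selected), a FASTA/Clustal pairwise alignment of the two paralogs,
and per-paralog TSV site lists (`column<TAB>posterior`, filtered at the
posterior threshold, default 0.75).

## Documentation

`docs/methods.md` describes the statistical model behind each test, the
null-calibration properties (including where the chi-square reference is
conservative or anticonservative and why), the synthetic generator's
assumptions, and the package's numerical conventions.
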