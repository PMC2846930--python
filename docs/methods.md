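# Methods

## The problem

Given a family of homologous protein sequences related by a phylogenetic tree
with branch lengths in substitutions/site, how diverged is the family, on
average, from its last common ancestor?  The naive answer — the mean pairwise
(patristic) distance between sequences — is biased by the tree's topology:
closely related sequences are correlated, so densely sampled subclades drag
the average around, and the expectation changes with which and how many
sequences happen to be sampled.  The B-index is a tree-aware alternative whose
expectation, under a clock, does not depend on the sampling.

## The estimator

A rooted tree is reduced bottom-up into `(d, w)` *clusters*, where `d` is an
average divergence (substitutions/site) and `w` an effective number of
independent lineages:

- a terminal branch of length `d_i` is a cluster with `d = d_i`, `w = 1`;
- `k >= 2` sibling clusters `(d_1, w_1) … (d_k, w_k)` hanging from a stem
  branch of length `d_s` merge into

      d = (Σ_i w_i d_i) / (Σ_i w_i) + d_s
      w = (Σ_i w_i d_i + d_s) / d        (w = Σ_i w_i in the limit d → 0)

- at the root, `d_s = 0`; the final cluster gives the **B-index** `D` and the
  **size** `W`.

The merge is constructed so `d·w` is always the total branch length of the
summarized subtree (each merge adds the stem to the weighted child total), so
`D·W = L`, the tree length.  The constant in the recursion — the size-weighted
mean — makes `D` exact on clock-like trees:

- **ultrametric exactness**: if every root-to-tip path equals `T`, each
  cluster's `d` is its node's tip height, and `D = T` for any topology;
- **subsampling invariance**: any leaf subset *with the same common ancestor*
  gives the same `D`.  Note the qualifier: pruning re-roots at the subset's
  MRCA, so a subset nested inside one clade measures the (shallower)
  divergence from that ancestor instead.  The test suite draws subsets
  spanning the root split, plus one nested-clade case documenting the
  distinction;
- **scaling equivariance**: multiplying all branches by `c` multiplies `D`,
  `L` and the mean pairwise distance by `c` and leaves `W` unchanged.

`2D` plays the role of an unbiased pairwise distance (for two leaves it *is*
the patristic distance); on ultrametric trees the mean pairwise distance is
`<= 2D`, with equality exactly for star topologies.

### Multifurcations

The original description covers bifurcating forks only.  The k-ary merge
above is the natural generalization: it preserves `d·w` additivity (hence
`D·W = L`), and resolving a polytomy by successive pairwise merges with
zero-length stems yields the identical cluster in every merge order (a
property test enumerates all orders up to k = 6).  Internal multifurcations
are therefore handled natively.  A *basal* multifurcation, however, usually
means the tree is unrooted, so `compute_bindex` refuses it by default and
tells the user to root by outgroup; `allow_unrooted=True` opts into treating
the basal polytomy as a genuine multifurcating root.

### Family comparison

The relative differentiation rate of a focal family B against a reference
family C sampled from the same species is the ratio of their divergences,
`B_B/B_C`, equivalently of their tree lengths when sizes match.  The report
block prints, per family: Size (W), B-index (B), unbiased pairwise distance
(2B), L (B·W) and the mean patristic distance (Average D_ij), then the four
ratio rows B_B/B_C, L_B/L_C, D_B/D_C, W_B/W_C at 4 decimals.  Mismatched
species sets raise a warning, not an error: the published per-family tables
show the sampling was not always identical (the W ratios differ from 1).
Average D_ij is computed from tree patristic distances; whether the original
analysis used tree paths or direct sequence estimates is not stated, so the
patristic convention is declared here.

### Rooting and pruning conventions

`root_by_outgroup` returns only the ingroup clade, rooted at the ingroup-side
endpoint of the edge separating outgroup from ingroup; the separating edge
and all outgroup branches are excluded, so divergence is measured from the
ingroup's MRCA.  Whether the original analysis attributed part of the stem to
the ingroup is unknown; this convention is declared, not inferred.
`prune_to_leaves` keeps all pairwise patristic distances among kept leaves
(unary nodes collapse by summing lengths) and roots at the kept set's MRCA.

## Simulation model

`simulate_clock_tree` builds ultrametric trees by a pure-birth construction:
the root splits at time 0, the remaining `n − 2` split times are uniform on
`(0, T)` and applied in sorted order to a uniformly chosen pending lineage,
and all lineages terminate at exactly `T`.  This is the simplest process that
guarantees ultrametricity; nothing in the estimator depends on the topology
law.  Departure from the clock uses independent lognormal branch multipliers
with log-mean `−σ²/2` and log-sd `σ` (unit mean, the standard relaxed-clock
parameterization), so the expected tree length is unchanged.
`simulate_paralog_pair` emits a reference clock tree and a focal copy with
identical topology and species labels, every branch scaled by `r` and
optionally perturbed — the validation bed for rate-ratio recovery.

Defaults: `depth = 1.0` substitutions/site (a typical deep-vertebrate-family
scale), `rate_sigma = 0` (strict clock unless asked), `rate_ratio = 1`.
Recovery tests use `n = 16` leaves, `σ = 0.3` and `r ∈ {1, 3, 5}`, the regime
of a moderately relaxed clock and the fold-changes seen between fast paralog
families and their slow references.  What the generator does *not* emulate:
alignment/tree-inference error, long-branch attraction, among-site rate
variation, or correlated rates along lineages — a green recovery test
establishes correctness of the estimator on known trees, not robustness of
tree inference.

## Conservation statistics

Given an alignment, reference rows (e.g. the nine CCT paralogs) and a target
row, `conservation_tally` counts, per category of 1-based contact columns,
the columns where the target's residue type occurs among the reference types.
Reference gaps are ignored when forming a column's type set; a target gap
never matches (a missing residue cannot conserve a contact).  Percentages are
`100·matched/total`, rounded half-away-from-zero to 1 decimal and formatted
`"matched (percent)"`.  `global_similarity_range` reports the min and max,
over the references taken one at a time, of the percent of mutually non-gap
columns sharing a residue class — the "Global" column; the per-reference
convention is an explicit assumption, since a range over pairwise family
combinations would also be consistent with published tables.
`position_profile` renders per-column `"MAJ (min)"` profiles: letters at
frequency `>= minority_threshold` (default 0.5; published tables parenthesize
clearly rare variants but state no cutoff) form the majority string in
frequency order with alphabetical tie-breaks.

Residue equivalence defaults to strict identity.  An optional 6-class
chemical partition (small ACGPST / aliphatic ILMV / aromatic FWY / polar NQ /
basic HKR / acidic DE) must be selected explicitly, because the similarity
classes behind published "conserved similar types" counts were never defined.

## Numerical choices and edge cases

- Branch lengths must be finite and `>= 0`; negative lengths are rejected
  unless `clamp_negative=True` (some inference tools emit small negatives),
  and missing lengths are rejected unless `allow_missing_lengths=True`
  assigns 0.
- A merged cluster of total length 0 takes `w = Σ w_i`, the `ε → 0`
  continuity limit of the general formula (which is 0/0 there).
- `L` is *reported* as `D·W`; the independent branch sum is kept as a test
  oracle only, and the identity is verified to 1e-9 relative tolerance on
  1000 random binary and multifurcating trees.
- Ultrametric exactness is asserted to 1e-12 absolute (float accumulation
  along root-to-tip paths).
- Reports print 4 decimals (divergence tables) and 1 decimal (conservation
  percents); internal computation is full double precision.
- Species codes are leaf-label prefixes before a configurable delimiter
  (default `_`, as in `Hs_CCT8`).

## Known limitations

- No confidence intervals on `D`: the sources give none, and a bootstrap over
  sites would require the alignments, which are out of scope here.
- Branch lengths are taken as given; inference error propagates untouched.
- The simulator's pure-birth topology law is a convenience, not a biological
  claim.
- The conservation layer takes contact/substrate position lists as input
  (TSV); deriving them from structures is out of scope.
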