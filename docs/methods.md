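# Methods

This note documents the models and procedures implemented in `rescon`, the
defaults and why they were chosen, what the synthetic generators emulate,
and the numerical and design decisions a maintainer should know about.

## MSA handling and weighting (`rescon.msa_io`)

The toolkit works over the 20 standard amino acids, a gap state `-`, and an
ambiguity state `X`. All coordinates are 1-based: alignment columns
throughout, and "query coordinates" are ungapped indices into the query
row.

**Fragment removal.** A record's deletion fraction is the share of gap
characters it carries in the columns where the query is non-gap; records
strictly above the threshold (default 0.25) are removed. Anchoring the
denominator to the query makes the rule reproducible and independent of
alignment-wide gap structure, which fits a query-centered workflow.

**Redundancy purge.** Pairwise identity is computed over mutually non-gap
columns and normalized by the shorter non-gap length; clusters are formed
by single linkage at the threshold (default 0.95) and the first record in
input order represents each cluster. The query and any record whose id is
registered as a structure are always retained, because structure rows are
needed later for column-residue mapping even when redundant.

**Sequence weights.** Each record's weight is the inverse of the number of
records within 80% identity of it (inclusive). This neighbor-count inverse
at 80% is the convention of pseudo-likelihood DCA tools and is reused for
every weighted computation in the package (frequencies, pattern contrasts,
Potts fits).

**Frequencies.** Column profiles are weighted frequencies over 21 states
(20 residues + gap). `X` contributes no mass; the column is renormalized
over observed states. Conservation digits are integer tenths,
`floor(10 f)` capped at 9, so 0.73 renders as `7` (70–80%).

## Subgroup partitioning (`rescon.bpps`)

Each hierarchy level performs one binary split of the parent foreground:
foreground (containing the query, always) versus the rest. The model for a
candidate pattern position is a two-component binomial contrast on "residue
∈ R" match events:

    LLR(c, R) = l(F; θ̂_F) + l(B; θ̂_B) − l(F∪B; θ̂_pooled),

with weighted counts and Dirichlet(α = 0.5) smoothing of each θ̂. Records
with a gap or `X` at the position count as non-matches. Residue sets R are
restricted to subsets of the foreground modal residue's biochemical class
(the eight classes used for rendering), grown greedily from the modal
residue while the LLR improves. This is the smallest residue-set search
that still allows multi-residue patterns such as S/T or D/E.

The sampler alternates (a) Gibbs resampling of each record's membership
from its leave-one-out conditional posterior (a group-size prior times the
Bernoulli likelihood of its match vector under foreground vs. background
rates), and (b) a Metropolis inclusion toggle per column with acceptance
exp(LLR − θ), where θ = ln 10 per position penalizes pattern growth
(geometric prior). The foreground is initialized with the query plus its
10% nearest neighbors by identity, which anchors the split to the query's
lineage; the point estimate is the maximum a posteriori state over
post-burn-in sweeps (ties to the earliest sweep). Defaults: 300 sweeps,
100 burn-in, at most 25 pattern positions.

Reported positions must additionally clear a significance floor of 10 nats
of contrast LLR. Under the null an accepted position's LLR behaves like
χ²₁/2 inflated somewhat by the residue-set search; 10 nats keeps the
per-column false-positive rate near 10⁻⁵ while planted positions on
realistic foreground sizes score in the hundreds of nats. An empty
reported pattern is the "no subgroup signal" outcome.

The root (level-0) node is the whole MSA against an implicit background of
unrelated sequences; its pattern is the set of columns whose pooled modal
frequency exceeds a conservation floor (default 0.5), scored against a
same-size uniform pseudo-background. No tree is built anywhere; the
hierarchy is a chain of binary splits.

## Direct couplings (`rescon.dca`)

The Potts model (q = 21; `X` folded into the gap state) is fit by
minimizing the L2-regularized negative weighted pseudo-log-likelihood with
L-BFGS-B, all site-conditionals jointly but unconstrained, then
symmetrizing J as the average of the two site-conditional estimates.
Defaults λ_h = 0.01 and λ_J = 0.2 (L−1) follow the pseudo-likelihood DCA
convention; the optimizer stops at a gradient-norm tolerance scaled by the
effective sequence count or at `max_iter` (150 full fits, 50 inside
subsampling), whichever comes first. Contact recovery is insensitive to
full convergence, which is why the subsampling protocol may run at a
reduced budget; the summary records that it did. Internally the one-hot
design and matmuls use float32; objective and gradient are returned in
float64. Optimization from a zero start is deterministic, so refits on the
same records give identical scores regardless of record order.

Scores: each 20×20 amino-acid block of J is put in the zero-sum (Ising)
gauge, its Frobenius norm taken (gap states never enter), and APC applied
over the eligible columns: S′(i,j) = S(i,j) − S̄_i S̄_j / S̄. Columns with
gap frequency above 50% are excluded from the eligible pair set — gappy
columns produce spurious couplings — and the cutoff is configurable.
Rankings break score ties lexicographically on (i, j) so top-k sets are
deterministic.

**Subsampling rank stability.** For each seeded draw of `subsample_size`
records (without replacement), weights are recomputed, the model refit, and
each pair's membership in the top-k tallied for k ∈ {20, 10, 5, 2};
percentages are reported to 0.1. **Lineage specificity**: a pair is
flagged specific iff it never appears (not even once) in the top-k of any
background subsampling analysis on the same column frame. **Co-occurrence
deficit**: the ratio of the weighted joint frequency of the two columns'
modal residues to the product of their marginals; a ratio below 1 marks a
pair whose modal combination is depleted and therefore cannot be driving
the DC-score.

## Structures and contacts (`rescon.structure`)

Parsing (PDB or mmCIF, via gemmi) keeps amino-acid residues with heavy
atoms only; waters are dropped and altlocs resolved to the
highest-occupancy conformer (ties toward `A`). Column-residue mapping
aligns the query's ungapped sequence to the structure sequence globally
(identity scoring, affine gaps, free end gaps); identity coverage below
30% is a mapping failure, and mismatched aligned positions are tolerated
up to 5% of the map (beyond that only identical positions are kept).

The default contact definition is minimal heavy-atom distance ≤ 5.0 Å with
query-coordinate separation ≥ 5; a Cβ ≤ 8 Å mode is provided, and the
significance statistics accept either. Both are field conventions; nothing
downstream depends on the choice beyond the contact set itself. When two
chains are supplied, cross-chain (trans) pairs are eligible with the
separation rule waived, since inter-subunit contacts are exactly the
short-separation pairs the cis rule would discard.

## Significance statistics (`rescon.stats`)

All four statistics are cumulative hypergeometric tails P(X ≥ x) computed
in log space (`scipy.stats.hypergeom.logsf` behind the module surface), so
extreme significances do not underflow; p-values are carried as log10.

- **3D_S_DC** — urn: mapped, score-eligible column pairs; marked: contact
  pairs; draws: top-k DC-pairs for k in a ladder (default 5, 10, 20, 50,
  100, 200, all). Raw p is the minimum over the ladder; adjusted p
  multiplies by the number of cutoffs actually tested (Bonferroni).
- **DC_S_P** — marked set is pairs with ≥ 1 endpoint in the pattern (a
  both-endpoints mode is a flag); same ladder machinery. An insignificant
  result is annotated as "complementary constraints": the pattern and
  coupling constraints then carry non-redundant information.
- **3D_S_P** — single test, no ladder: pattern–pattern pairs drawn from
  the mapped-pair universe, contacts marked.
- **CL_S_P** — for each candidate center (default: the pattern residues)
  and each radius in {8, 10, 12, 16, 20} Å, the ball of mapped residues
  around the center is the draw and pattern residues are marked; adjusted
  p multiplies the minimum by centers × radii. The argmin center is
  reported as the cluster center.

Bonferroni over the searched alternatives makes every test conservative:
under null simulations the rate of adjusted p ≤ 0.05 sits well below 5%.
Multi-structure analyses are deliberately not cross-adjusted — each
structure is reported separately and ranked by the combined score
−log10(p_3D_DC) − log10(p_3D_P), computed from the log-space values so it
stays finite.

## Rendering (`rescon.reporting`)

Contrast alignments color pattern-matching residues by the eight-class
biochemical partition (nonpolar AVILMWFY, cysteine, acidic DE, basic KR,
polar STNQ, glycine, histidine, proline); everything else is gray. Hex
values for the named colors are fixed in the module. Below the sequence
rows come a selective-pressure bar row (log10(1 + LLR) rescaled to the
node maximum — heights are comparable within a node only), the
characteristic residue row, and its conservation digits. HTML output
escapes all sequence-derived text. Viewer scripts (PyMOL or ChimeraX
dialect) color each node's pattern residues, draw a rod per DC pair with
lineage-specific pairs on a distinct channel, and label the cluster
center; only mapped residues are referenced.

## Synthetic study conditions (`rescon.synth`)

The generators define the conditions under which the pipeline is tested:

- `sample_potts` — n independent single-site Gibbs chains (vectorized
  across chains), zero fields, couplings equal to `coupling_strength` on
  the matched-state diagonal of each planted pair. Each chain starts from
  a uniform random state and is burned in for 300 full sweeps; because
  chains are independent, emitted records need no thinning, and mixing is
  checked by comparing column marginals across independent runs. Recovery
  conditions: L = 30, 2,000 sequences, 5 planted pairs at strength 1.5.
- `make_subgrouped_msa` — i.i.d. uniform background columns; each group
  owns disjoint pattern columns where members carry the planted residue
  with probability 0.9 (the remaining mass drawn from the background).
  Recovery conditions: two groups of 150, L = 100, 8 columns each. Note
  that a column planted for one group also discriminates the other group
  by absence, so both groups' planted columns are legitimate recoveries.
- `make_toy_structure` — one pseudo-atom per residue on an extended helix
  (1.5 Å rise, 100° turn, 2.3 Å radius) or a self-avoiding random walk
  (3.8 Å steps); planted cluster members are relocated uniformly into a
  ball (10 of 150 residues, radius 10 Å in the power condition).

What these do **not** emulate: real amino-acid composition, phylogenetic
correlation between sequences (records are exchangeable given their
group), alignment errors, gap structure, side-chain geometry, or
database-scale MSAs. Passing the recovery and calibration suites therefore
demonstrates correctness of the machinery under its own model assumptions,
not performance on real superfamily data, where effective sequence
numbers, tree structure, and alignment quality dominate.

## Problem sizes and determinism

Defaults were chosen so a full pipeline run on the study conditions
completes in minutes on one CPU: 10-seed recovery runs for both couplings
(2,000 × 30 fits) and partitions (300 × 100 samplers), 1,000-replicate
null calibrations at toy scale, and 50-subsample stability at L = 12.
Every stochastic component takes an explicit seed; given the seed, sampler
trajectories, fits, and reports are bit-reproducible, and report JSON is
serialized with sorted keys so identical analyses round-trip
byte-identically.

## Known limitations

- The pseudo-likelihood fit is dense (O(L²q²) parameters); alignments with
  many hundreds of columns need patience or a reduced optimizer budget.
  Mean-field and sparse-inverse-covariance variants are out of scope.
- The partition sampler performs binary splits only; multi-way sibling
  structure must be expressed as successive levels.
- The significance suite assumes exchangeability of pairs/residues under
  the null; strong spatial or positional structure in the universe (e.g.
  contact density gradients) is absorbed only through the conservative
  Bonferroni adjustment.
- CL_S_P uses all mapped residues as the urn; restricting the population
  (e.g. to one domain) changes the p-value and is the caller's choice via
  `all_mapped_residues`.
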