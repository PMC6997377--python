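# rescon

Residue-constraint analysis for protein families: given a multiple sequence
alignment (MSA) with a designated query sequence, and optionally one or more
3D structures of the query or close homologs, `rescon` identifies

- **pattern residues** — positions conserved in the query's subgroup but not
  in related sequences, found by Bayesian partitioning with pattern
  selection (MCMC over memberships and pattern columns);
- **directly coupled column pairs** — DC-scores from a pseudo-likelihood
  Potts model with average product correction (APC), which disentangle
  direct from transitively induced covariation;
- **the statistical significance of their correlations** with each other
  and with 3D contacts, via conservative ball-in-urn (cumulative
  hypergeometric) tests.

It is aimed at protein scientists studying determinants of functional
specificity within large superfamilies (e.g. AAA+ ATPases), where
subgroup-discriminating conservation, compensating substitutions, and
spatial clustering of constrained residues each carry complementary
mechanistic signal.

## The model

**Patterns.** For a binary split of an alignment into foreground F and
background B, a position *c* with residue set *R* is scored by the contrast
log-likelihood ratio

    LLR(c, R) = l(F) + l(B) - l(F ∪ B)

where *l* is the weighted binomial log-likelihood of the "residue ∈ R"
events with Dirichlet(α = 0.5) smoothing. A Gibbs sampler resamples each
sequence's membership from its conditional posterior and toggles pattern
columns by Metropolis steps under a per-position prior penalty θ = ln 10;
the reported split is the maximum a posteriori state.

**Couplings.** An L-site, 21-state Potts model (fields *h*, couplings *J*)
is fit by L2-regularized, sequence-weighted pseudo-likelihood maximization
(λ_h = 0.01, λ_J = 0.2(L−1)). The DC-score of columns *i, j* is the
Frobenius norm of the zero-sum-gauged 20×20 block of J_ij, followed by APC:
S′ = S − (row mean × column mean) / grand mean.

**Significance.** Overlaps between top-k DC-pairs and contacts (3D_S_DC),
between pattern columns and top DC-pairs (DC_S_P), between pattern-pair
contacts and all mapped pairs (3D_S_P), and spatial clustering of pattern
residues in distance balls (CL_S_P) are all evaluated as cumulative
hypergeometric tails, minimized over a cutoff ladder (or center × radius
grid) and Bonferroni-adjusted by the number of alternatives searched.
Structures are ranked by −log10(p_3D_DC) − log10(p_3D_P).

## Worked example

Everything below runs on synthetic data generated by the package itself
(`rescon.synth`); no downloads are needed.

```python
import rescon

# 300 sequences, two planted subgroups, 8 discriminating columns each
aln, truth = rescon.make_subgrouped_msa([150, 150], 100, 8, 0.9, seed=11)
w = rescon.sequence_weights(aln)
nodes = rescon.partition_msa(aln, w, rescon.SamplerConfig(seed=5))
node = nodes[1]
print(len(node.foreground), node.pattern_columns()[:4])
# 150 [48, 37, 97, 83]

# Potts alignment with 5 planted coupled pairs; APC top-10 recovers them
aln2, truth2 = rescon.sample_potts(
    30, 2000, [(1, 15), (3, 7), (10, 20), (22, 29), (5, 25)],
    coupling_strength=1.5, seed=3)
scores = rescon.dca_scores(aln2, max_iter=100)
print(scores.top_pairs(5))
# [(3, 7), (1, 15), (10, 20), (5, 25), (22, 29)]

# Spatial clustering of 10 residues planted in a 10 Å ball of a 150-residue
# toy chain
import numpy as np
model, t3 = rescon.make_toy_structure(
    150, "extended_helix", planted_cluster=(list(range(40, 50)), 10.0), seed=2)
pts = np.vstack([r.coords[0] for r in model.residues])
D = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
res = rescon.cluster_significance(t3.cluster_members, list(range(1, 151)),
                                  distance=D)
print(round(res.log10_adjusted, 1), res.center, res.radius)
# -10.2 42 10.0
```

The first block recovers the planted subgroup split exactly (the level-1
foreground is the query's group) and ranks the planted columns by contrast
LLR. The second shows the five planted couplings as the five top APC
scores. The third reports the clustering significance: an adjusted p of
10^-10.2 for the ball of radius 10 Å around residue 42, i.e. the planted
cluster is recovered with its center.

From the shell, the same stages are available as subcommands:

```sh
rescon synth subgroups --seed 1 -o fixtures/
rescon filter --msa fixtures/subgroups.fasta --query g1_s0000 -o filtered.fasta
rescon bpps   --msa filtered.fasta --query g1_s0000 --seed 7 -o hierarchy.json
rescon dca    --msa filtered.fasta --query g1_s0000 -o scores.tsv
rescon stats  --msa filtered.fasta --query g1_s0000 \
              --structure toy.pdb --chain A -o report.json
```

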