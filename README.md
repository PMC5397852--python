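# lncprop

Pathway annotation for sets of long non-coding RNAs (lncRNAs) by global
network propagation.

Most lncRNAs have no direct functional annotation, and essential cellular
programs are often shaped by the *combinatorial* effect of many lncRNAs
(e.g. all lncRNAs differentially expressed in a tumour), not by one at a
time. `lncprop` identifies the biological pathways influenced by such a set:
it maps the lncRNAs onto a coding–non-coding gene correlation (CNC)
network — an undirected graph of lncRNAs and protein-coding genes linked by
consensus co-expression and protein–protein interactions — lets their
influence diffuse through the network, and asks which pathways' genes
cluster near the set. Because the propagation is global, it also finds
pathways whose genes are *not* directly co-expressed with the lncRNAs but
lie close to them in the network — the cases that co-expression-only
enrichment tools miss.

## The method

1. **CNC network construction** (optional; any edge list can be supplied).
   For each expression dataset (FPKM, ≥ 6 samples), genes with mean
   FPKM > 1 and FPKM variance in the top 75% are retained; every gene
   pair's Pearson correlation r is Fisher-transformed,
   z = ½[ln(1+r) − ln(1−r)] (SE 1/√(N−3)); per gene the z-scores are
   standardised to zero mean and unit variance, converted to two-sided
   normal p-values and Bonferroni-corrected over the pairs tested for that
   gene. A pair is co-expressed when its |r| ranks in the top 0.1% for
   both endpoint genes and both adjusted p-values are < 0.01. Pairs
   co-expressed with the same sign in ≥ 3 datasets become consensus edges,
   which are merged with protein–protein interactions. The merged network
   is scale-free (degree law P(k) ~ k^−γ, checked by a log–log
   least-squares fit).

2. **Random walk with restart (RWR).** With M the column-normalised
   adjacency and p⁰ uniform over the seed lncRNAs,

       p(t+1) = (1 − r) M p(t) + r p⁰ ,   r = 0.7,

   iterated from p⁰ until ‖p(t+1) − p(t)‖₁ < 10⁻¹⁰. Each protein-coding
   gene j gets a propagation score t_j = √p_j^∞, and the ranked list
   L = ⟨g₁ … g_n⟩ orders all coding genes by descending t_j.

3. **Weighted Kolmogorov–Smirnov enrichment.** For a pathway P (15–500
   coding genes in the network), walking down L:

       F_InP(i)  = Σ_{g_j∈P, j≤i} t_j^p / N_R ,   N_R = Σ_{g_j∈P} t_j^p
       F_NotP(i) = #{g_j∉P, j≤i} / N_NotP ,       p = 1

   and ES(P) = max_i [F_InP(i) − F_NotP(i)]. The pathway genes ranked at
   or before the peak are its **core genes**. Significance comes from a
   seed-permutation null: N random lncRNA sets of the same size are
   propagated (default N = 1000) and p = M/N with M the number of null ES
   values exceeding the observed one, followed by Benjamini–Hochberg FDR.

## Worked example

Synthetic data with known ground truth: a 1,000-node scale-free network
(100 lncRNAs), 5 seed lncRNAs, one pathway planted within two hops of the
seeds, and 20 size-matched random decoys.

```python
from lncprop import PathwayPropagation, SyntheticSpec, generate_cnc

bundle = generate_cnc(SyntheticSpec(rng_seed=1))
model = PathwayPropagation(
    bundle.network,
    bundle.seeds,
    [bundle.planted_pathway, *bundle.decoy_pathways],
)
results = model.fit(n_permutations=200, random_state=0)
print(results.summary(max_rows=5))
```

```
Pathway propagation results
================================================================
Network nodes:        1000 (100 lncRNA, 900 coding)
Network edges:        1996
Seeds mapped:         5 (0 dropped)
Restart probability:  0.7
RWR iterations:       18
Pathways scored:      21 (0 excluded by size)
Permutations:         200
Significant pathways: 1 (FDR < 0.01)
----------------------------------------------------------------
pathway_id                       name  size     es  p_value    fdr  peak_index core_genes
   PLANTED planted pathway near seeds    30 0.9701   0.0000 0.0000          56   30 genes
  DECOY017            random decoy 17    30 0.7619   0.0150 0.1050          61    4 genes
  DECOY004             random decoy 4    30 0.7516   0.0050 0.0525          63    4 genes
  DECOY002             random decoy 2    30 0.7256   0.0250 0.1313         124   10 genes
  DECOY006             random decoy 6    30 0.6680   0.1300 0.3900           4    1 genes
```

The planted pathway scores ES = 0.97 — its 30 genes sit near the top of
the propagation ranking, all 30 are core genes, and none of the 200
permuted seed sets reaches its score (p = 0/200) — while the random decoys
land in the null. `results.frame` gives the full table as a DataFrame,
`results.plot_running_sum("PLANTED")` draws the running-sum curve, and
`results.save("results.tsv")` writes the TSV.

The same analysis from the shell:

```bash
lncprop simulate --outdir fixtures --seed 1 --expression
lncprop run --network fixtures/edges.tsv --nodes fixtures/nodes.tsv \
            --seeds fixtures/seeds.txt --pathways fixtures/pathways.gmt \
            --out results.tsv --nperm 200 --seed 0
lncprop build-network --expression fixtures/expression_SYN1.tsv \
            --expression fixtures/expression_SYN2.tsv \
            --expression fixtures/expression_SYN3.tsv \
            --out-edges net.tsv --out-nodes nodes.tsv
```

`run` also writes a JSON manifest (`results.tsv.manifest.json`) that
records every parameter needed to replay the run exactly.

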