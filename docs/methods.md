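# Methods

## Model overview

`lncprop` treats lncRNA function annotation as a network-proximity problem.
The object being "fitted" is not a parametric likelihood but a diffusion
state: given a coding–non-coding (CNC) network G, a seed set S of lncRNAs
and a pathway collection, the model computes the stationary distribution of
a random walk with restart (RWR) anchored at S and summarises, per pathway,
how strongly the pathway's coding genes concentrate near S. Uncertainty is
quantified non-parametrically, by re-running the identical procedure from
random seed sets of the same size.

The three assumptions doing the work are:

1. **Guilt by network association.** A coding gene close to the seed
   lncRNAs in the co-expression/PPI graph is more likely to be regulated
   by them. The walk aggregates *all* paths, not just direct neighbours,
   weighting short, well-connected routes most.
2. **Set-level (combinatorial) influence.** Seeds restart the walk jointly
   with equal probability, so the ranking reflects the collective
   proximity to the whole set; no attempt is made to weight individual
   lncRNAs by effect size.
3. **Exchangeable null seeds.** Significance is measured against uniformly
   drawn lncRNA sets of equal size, i.e. the null hypothesis is "this ES
   could be produced by an arbitrary lncRNA set of the same cardinality on
   this network", not "pathway genes are randomly scattered".

## Co-expression extraction

Per dataset (FPKM matrix, ≥ 6 samples — below that a Pearson estimate on
expression profiles is mostly noise):

* **Expression filters.** Mean FPKM strictly > 1 and FPKM variance in the
  top 75% of all genes of the dataset. The variance cutoff is the value at
  the 25th-percentile rank position and is inclusive, so ties at the
  boundary are kept; a dataset of identical variances keeps every gene.
  Both filters use the unfiltered dataset as the reference population.
* **Correlation and transform.** Pearson r on FPKM values for every
  retained pair; Fisher z = ½[ln(1+r) − ln(1−r)], standard error 1/√(N−3).
  The SE is the textbook companion of the transform; because the z-scores
  are subsequently re-standardised per gene, only the convergence check on
  N depends on it.
* **Per-gene standardisation.** For each gene, the z-scores of its N−1
  pairs are standardised to zero mean and unit variance (sample SD,
  ddof = 1), converted to two-sided normal p-values, and
  Bonferroni-corrected by the per-gene family size (the N−1 pairs
  involving that gene). Each pair therefore carries two standardised
  scores and two adjusted p-values, one per endpoint.
* **Call rule.** A pair is co-expressed when its |r| ranks within the top
  0.1% of the pairs of *both* endpoints (ties at the rank boundary
  included; at fewer than 1000 genes the rule degenerates to "mutual best
  partner") and both endpoint-adjusted p-values are < 0.01. The
  conservative both-endpoint reading is the default; `endpoint_rule=
  "either"` switches to the permissive one.
* **Degenerate inputs.** Constant-expression genes are excluded before
  correlation (with a warning) rather than allowed to produce NaNs;
  perfectly correlated pairs have their z clipped just inside ±atanh(1−ε)
  rather than overflowing.

A note on the null behaviour: with a per-gene Bonferroni family of N−1,
the mutual-top-rank + p < 0.01 rule still passes a handful of pairs per
dataset in a fully independent matrix (on the order of 10⁻⁵ of tested
pairs at 1000 genes) — extreme order statistics of ~500k correlations are
not controlled by a family of 999. The cross-dataset consensus step is
what drives the practical false-call rate to zero, since a spurious pair
would have to recur, with the same sign, in three independent datasets.

* **Consensus.** A pair becomes a network edge when called with the same
  sign in ≥ 3 datasets (support = that count). Sign directions are counted
  separately; if, pathologically, both directions reach the threshold
  across many datasets, the higher-support direction wins and ties resolve
  to positive. Correlation signs are retained as edge metadata only — the
  walk runs on the unweighted, unsigned adjacency.

## Network assembly and QC

Consensus co-expression edges are unioned with PPI pairs; pairs present in
both carry provenance `both`. PPI nodes default to the coding biotype and
a declared lncRNA inside a PPI edge is rejected (PPIs connect proteins).
Zero-degree nodes are removed after merging; connected components are
labelled, and seeds in minor components are allowed — their walk mass
simply stays inside those components, which is the honest answer rather
than an error.

As structural QC, the degree distribution is fitted by least squares on
(log k, log P(k)) over degrees with nonzero frequency; γ is the negative
slope and R² comes from the same regression. The simple log–log fit (not a
maximum-likelihood exponent estimate) is deliberate: it is a goodness
check that the network is scale-free-like, not an estimator anyone should
interpret precisely. At least two distinct degrees are required; a regular
graph has no fit.

## Propagation

* M is the column-normalised 0/1 adjacency (each column divided by the
  node's degree), p⁰ puts mass 1/|S| on each mapped seed, and iteration
  p ← (1−r)Mp + rp⁰ starts *from p⁰* and stops when the L1 update is
  < 10⁻¹⁰. Because the update is a contraction with factor (1−r), about
  twenty iterations suffice at r = 0.7; a 10,000-iteration cap is an
  engineering guard only.
* Restart probability r = 0.7 by default. The stationary state is known to
  be only mildly sensitive to r across 0.1–0.9; 0.7 keeps the mass local
  enough that planted/nearby structure dominates.
* Seeds absent from the network are dropped with a logged warning and
  counted in the result; an entirely unmapped seed set is an error, as is
  a seed that maps to a coding node (sources are lncRNAs by contract).
* Scores: t_j = √p_j^∞ for coding genes. The square root compresses the
  head of the heavy-tailed stationary distribution so that the top-ranked
  genes do not completely dominate the weighted running sum; it is
  monotone, so the ranking itself is unchanged. L orders all coding genes
  by descending t_j with ties broken by ascending identifier —
  determinism here is required for reproducible core-gene sets.

## Enrichment and significance

* Running sum as in the README; N_R = Σ_P t_j^p normalises the weighted
  in-pathway fraction so both fractions terminate at 1 and ES is invariant
  to positive rescaling of the scores. Weight exponent p = 1 by default;
  p = 0 reduces exactly to the classic one-sided two-sample KS statistic
  (verified against an independent KS oracle in the tests).
* ES is the *signed* maximum of the running sum (one-sided, top-of-list
  enrichment), and the peak is the smallest index attaining it. Since the
  running sum always ends at zero, ES ≥ 0; an "all pathway genes at the
  bottom" configuration yields ES = 0 with the peak at the end, not a
  negative score.
* Pathway size = number of member genes present as coding network nodes,
  counted before anything else; sizes outside [15, 500] are excluded to
  avoid overly narrow or broad categories. Genes absent from the network
  are ignored everywhere.
* Permutations draw seed-count lncRNAs uniformly without replacement from
  all lncRNA nodes, re-run the walk once, and score *every* pathway
  against that one permuted ranking (one shared ranking per permutation;
  anything else is computationally out of the question at N = 1000).
  p = M/N with M the count of null ES *strictly* greater than observed;
  the (M+1)/(N+1) variant is available behind `pseudocount_pvalue` for
  users who dislike literal zeros. A null seed set that cannot reach a
  pathway at all contributes "no enrichment" to that pathway's null.
  BH FDR is applied across the scored pathways in input order.
* Core genes: pathway members at or before the peak, in rank order. The
  fold-change helper flags a core gene as differentially expressed when
  |log2(mean case / mean control)| strictly exceeds 1 (FC > 2 or
  FC < 0.5); zero means are replaced by a 0.01 pseudocount and marked,
  missing genes are reported as not evaluable.

## Synthetic data: what it emulates, what it does not

`generate_cnc` produces a preferential-attachment graph (scale-free, like
the real CNC network's degree law) with randomly placed lncRNAs, a seed
set, a planted pathway of coding genes within a chosen hop radius of the
seeds, and size-matched uniform decoy pathways. Proximity is the
ground-truth knob: the planted pathway *should* win, and the decoys trace
the null. `generate_fpkm` produces log-normal FPKM with planted
log-bivariate-normal pairs recurring with fixed signs across datasets.
Planted pairs use a small log-dispersion (0.15) because exponentiation
attenuates Pearson correlations — for negative pairs the attainable
FPKM-scale |r| is bounded by (1 − e^{−s²})/(e^{s²} − 1), which at the
background dispersion of 0.5 caps |r| near 0.78; at 0.15 the FPKM-scale
correlation stays within ~0.02 of the nominal ±0.98. Their log-means draw
from the top of the expression range (strongly co-regulated pairs modelled
as well-expressed), keeping them clear of the mean/variance filters.

Deliberately *not* modelled: count-level sequencing noise (negative
binomial), sample-size and depth heterogeneity across datasets,
batch/confounder structure, hub-biased biotype placement, or matching of
the degree exponent to any particular real network. Consequently, passing
tests demonstrate correctness, calibration and power of the *algorithms*
under clean planted structure; they do not certify recovery rates on real
RNA-Seq compendia, where filter interactions and confounding will lower
co-expression recall.

Default scales (1,000-node networks, 200 permutations, 100 replicates,
three 1,000 × 20 expression matrices) were chosen as the smallest sizes at
which the calibration and power properties are statistically meaningful;
everything is a pure function of its spec, so larger studies are one
parameter away.

## Known limitations

* Seeds are equally weighted; differential-expression effect sizes for the
  lncRNAs are ignored.
* The permutation null conditions on the network and seed-set size only;
  it does not degree-match the random seeds, so seed sets of unusual
  hubness are judged against typical lncRNAs.
* Empirical p-values are bounded below by 1/N; at N = 1000 the smallest
  reportable nonzero p is 0.001, and many pathways can tie at p = 0.
* The log–log degree fit is a QC statistic, not a rigorous power-law test.
* Consensus edges require identically labelled genes across datasets;
  identifier harmonisation is the caller's responsibility.
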