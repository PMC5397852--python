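"""Per-dataset co-expression extraction and cross-dataset consensus edges.

Co-expression relationships between genes (lncRNAs and protein-coding genes
alike) are extracted independently from each RNA-Seq expression dataset and
then reconciled across datasets: only gene pairs that are called co-expressed
with the same correlation sign in at least ``min_support`` datasets become
consensus edges of the coding--non-coding (CNC) network.

Within one dataset the pipeline is:

1. expression filtering -- genes with mean FPKM above a floor and FPKM
   variance in the top fraction of the dataset are retained;
2. Pearson correlation of every retained gene pair, Fisher z-transformed;
3. per-gene standardisation of the z-scores (zero mean, unit variance over
   the pairs involving that gene), two-sided normal p-values, Bonferroni
   correction over the pairs tested per gene;
4. a pair is called co-expressed when its \\|r\\| ranks within the top
   ``rank_fraction`` of the pairs of *both* endpoint genes and both
   endpoint-adjusted p-values fall below ``alpha``.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionDataset",
    "PairCorrelation",
    "ConsensusEdge",
    "filter_genes",
    "fisher_z",
    "dataset_coexpression",
    "consensus_edges",
]

#: Gene biotype labels understood throughout the package.
BIOTYPES = ("lncRNA", "coding")


@dataclass
class ExpressionDataset:
    """One study's FPKM expression matrix with per-gene biotypes.

    Parameters
    ----------
    dataset_id : str
        Label identifying the study the matrix came from.
    gene_ids : list of str
        Row identifiers; must be unique.
    biotypes : list of str
        Per-gene biotype, ``"lncRNA"`` or ``"coding"``, aligned with
        ``gene_ids``.
    values : ndarray of shape (n_genes, n_samples)
        Non-negative FPKM values. At least six samples are required, the
        floor below which a Pearson correlation estimate on expression
        profiles is too unstable to use.
    """

    dataset_id: str
    gene_ids: list[str]
    biotypes: list[str]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D genes x samples matrix")
        if len(self.gene_ids) != self.values.shape[0]:
            raise ValueError("gene_ids length does not match matrix rows")
        if len(self.biotypes) != len(self.gene_ids):
            raise ValueError("biotypes length does not match gene_ids")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError(f"duplicate gene ids in dataset {self.dataset_id!r}")
        unknown = set(self.biotypes) - set(BIOTYPES)
        if unknown:
            raise ValueError(f"unknown biotype(s): {sorted(unknown)}")
        if self.n_samples < 6:
            raise ValueError(
                f"dataset {self.dataset_id!r} has {self.n_samples} samples; "
                "at least six are required"
            )
        if np.any(self.values < 0) or not np.all(np.isfinite(self.values)):
            raise ValueError("FPKM values must be finite and non-negative")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        """Sample count N, the Fisher-z sample size."""
        return self.values.shape[1]

    def subset(self, keep: np.ndarray) -> "ExpressionDataset":
        """Return a copy restricted to the boolean row mask ``keep``."""
        idx = np.flatnonzero(keep)
        return ExpressionDataset(
            dataset_id=self.dataset_id,
            gene_ids=[self.gene_ids[i] for i in idx],
            biotypes=[self.biotypes[i] for i in idx],
            values=self.values[idx],
        )


@dataclass(frozen=True)
class PairCorrelation:
    """A co-expression call for one unordered gene pair in one dataset.

    ``gene_a`` sorts lexicographically before ``gene_b`` so that pairs have
    set semantics.  ``p_adj`` is the larger (binding) of the two
    endpoint-wise Bonferroni-adjusted p-values.
    """

    gene_a: str
    gene_b: str
    r: float
    z: float
    z_std_a: float
    z_std_b: float
    p_adj: float
    rank_pass_a: bool
    rank_pass_b: bool

    def __post_init__(self) -> None:
        if self.gene_a >= self.gene_b:
            raise ValueError("gene_a must sort before gene_b")

    @property
    def sign(self) -> int:
        return 1 if self.r > 0 else -1

    @property
    def pair(self) -> tuple[str, str]:
        return (self.gene_a, self.gene_b)


@dataclass(frozen=True)
class ConsensusEdge:
    """A gene pair co-expressed with the same sign in >= min_support datasets."""

    gene_a: str
    gene_b: str
    sign: int
    support: int

    def __post_init__(self) -> None:
        if self.gene_a >= self.gene_b:
            raise ValueError("gene_a must sort before gene_b")
        if self.sign not in (1, -1):
            raise ValueError("sign must be +1 or -1")

    @property
    def pair(self) -> tuple[str, str]:
        return (self.gene_a, self.gene_b)


def filter_genes(
    dataset: ExpressionDataset,
    min_mean_fpkm: float = 1.0,
    variance_keep_fraction: float = 0.75,
) -> ExpressionDataset:
    """Apply the expression filters: mean FPKM floor and variance rank cut.

    A gene survives when its mean FPKM strictly exceeds ``min_mean_fpkm``
    and its FPKM variance ranks within the top ``variance_keep_fraction``
    of all genes in the dataset.  The variance ranking is computed over all
    genes (before the mean filter), ties at the cutoff are kept, and the
    original gene order is preserved.

    Raises
    ------
    ValueError
        If the dataset is empty or no gene passes both filters.
    """
    if dataset.n_genes == 0:
        raise ValueError("dataset is empty")
    if not 0 < variance_keep_fraction <= 1:
        raise ValueError("variance_keep_fraction must be in (0, 1]")
    means = dataset.values.mean(axis=1)
    variances = dataset.values.var(axis=1, ddof=1)
    # inclusive cutoff: the value at the (1 - keep) rank position; ties kept
    order = np.sort(variances)
    cut_idx = int((1.0 - variance_keep_fraction) * dataset.n_genes)
    cutoff = order[min(cut_idx, dataset.n_genes - 1)]
    keep = (means > min_mean_fpkm) & (variances >= cutoff)
    if not keep.any():
        raise ValueError(
            f"no genes pass filters in dataset {dataset.dataset_id!r} "
            f"(mean FPKM > {min_mean_fpkm}, variance top "
            f"{variance_keep_fraction:.0%})"
        )
    return dataset.subset(keep)


def fisher_z(r: float) -> float:
    """Fisher z-transform of a Pearson correlation, 0.5*[ln(1+r) - ln(1-r)].

    Strictly increasing and odd on (-1, 1).  Raises ``ValueError`` for
    \\|r\\| >= 1 (degenerate correlation, e.g. duplicated expression
    vectors).
    """
    if not -1.0 < r < 1.0:
        raise ValueError(
            f"correlation r={r} is degenerate (|r| >= 1); "
            "check for duplicated expression vectors"
        )
    return 0.5 * (math.log1p(r) - math.log1p(-r))


def dataset_coexpression(
    dataset: ExpressionDataset,
    rank_fraction: float = 0.001,
    alpha: float = 0.01,
    endpoint_rule: str = "both",
) -> list[PairCorrelation]:
    """Call co-expressed gene pairs within one (already gene-filtered) dataset.

    Every gene pair's Pearson r is Fisher z-transformed (standard error
    1/sqrt(N-3), N = sample count).  For each gene the z-scores of all
    pairs involving it are standardised to zero mean and unit variance;
    standardised scores are converted to two-sided normal p-values and
    Bonferroni-corrected over the number of pairs tested for that gene.
    A pair is flagged co-expressed when its \\|r\\| rank is within the
    top/bottom ``rank_fraction`` for its endpoint genes and the
    endpoint-adjusted p-values fall below ``alpha`` -- for *both* endpoints
    under ``endpoint_rule="both"`` (default, conservative) or for at least
    one under ``"either"``.

    Returns the flagged pairs only, ordered lexicographically.
    """
    if endpoint_rule not in ("both", "either"):
        raise ValueError("endpoint_rule must be 'both' or 'either'")
    n = dataset.n_genes
    N = dataset.n_samples
    if N <= 3:
        raise ValueError("need more than 3 samples for the Fisher z standard error")
    if n < 2:
        return []

    variances = dataset.values.var(axis=1, ddof=1)
    zero_var = variances == 0
    if zero_var.any():
        bad = [dataset.gene_ids[i] for i in np.flatnonzero(zero_var)]
        logger.warning(
            "dataset %s: %d constant-expression gene(s) excluded from "
            "correlation: %s",
            dataset.dataset_id, len(bad), ", ".join(bad[:10]),
        )
        dataset = dataset.subset(~zero_var)
        n = dataset.n_genes
        if n < 2:
            return []

    ids = dataset.gene_ids
    R = np.corrcoef(dataset.values)
    np.clip(R, -1.0, 1.0, out=R)
    near_one = 1.0 - 1e-12
    off = ~np.eye(n, dtype=bool)
    if np.any(np.abs(R[off]) >= 1.0):
        logger.warning(
            "dataset %s: perfectly correlated gene pair(s); z clipped",
            dataset.dataset_id,
        )
    Z = np.arctanh(np.clip(R, -near_one, near_one))  # se = 1/sqrt(N-3)

    # per-gene standardisation over the n-1 pairs involving each gene
    Zo = np.where(off, Z, np.nan)
    mu = np.nanmean(Zo, axis=1, keepdims=True)
    sd = np.nanstd(Zo, axis=1, ddof=1, keepdims=True)
    sd = np.where(sd == 0, np.nan, sd)
    Zstd = (Zo - mu) / sd  # row i: z of pairs (i, .) standardised for gene i

    pvals = 2.0 * stats.norm.sf(np.abs(Zstd))
    p_adj = np.minimum(pvals * (n - 1), 1.0)  # Bonferroni per gene

    # per-gene |r| rank rule; ties at the boundary included
    absR = np.where(off, np.abs(R), -np.inf)
    k = max(1, math.ceil(rank_fraction * (n - 1)))
    kth = np.sort(absR, axis=1)[:, n - 1 - k]  # k-th largest per row
    rank_pass = absR >= kth[:, None]

    p_ok = p_adj < alpha
    pass_per_endpoint = rank_pass & p_ok  # row i: pair (i, j) passes for gene i
    if endpoint_rule == "both":
        flagged = pass_per_endpoint & pass_per_endpoint.T
    else:
        flagged = pass_per_endpoint | pass_per_endpoint.T
    flagged &= np.triu(off)

    out: list[PairCorrelation] = []
    for i, j in zip(*np.nonzero(flagged)):
        a, b = ids[i], ids[j]
        if a > b:
            a, b = b, a
            i, j = j, i
        out.append(
            PairCorrelation(
                gene_a=a,
                gene_b=b,
                r=float(R[i, j]),
                z=float(Z[i, j]),
                z_std_a=float(Zstd[i, j]),
                z_std_b=float(Zstd[j, i]),
                p_adj=float(max(p_adj[i, j], p_adj[j, i])),
                rank_pass_a=bool(rank_pass[i, j]),
                rank_pass_b=bool(rank_pass[j, i]),
            )
        )
    out.sort(key=lambda pc: pc.pair)
    return out


def consensus_edges(
    per_dataset_edges: list[list[PairCorrelation]],
    min_support: int = 3,
) -> list[ConsensusEdge]:
    """Reconcile per-dataset co-expression calls into consensus edges.

    A pair becomes a consensus edge when it is flagged co-expressed with the
    *same* correlation sign in at least ``min_support`` datasets; ``support``
    is that count.  Each sign direction is counted separately; a pair whose
    directions conflict and where no direction reaches ``min_support`` is
    dropped.  In the (cross-dataset) event that both directions reach
    ``min_support``, the higher-support direction wins, ties resolving to
    positive.
    """
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    counts: Counter[tuple[str, str, int]] = Counter()
    for calls in per_dataset_edges:
        seen = set()
        for pc in calls:
            key = (pc.gene_a, pc.gene_b, pc.sign)
            if key not in seen:  # one vote per dataset per direction
                counts[key] += 1
                seen.add(key)
    by_pair: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for (a, b, sign), c in counts.items():
        if c >= min_support:
            by_pair.setdefault((a, b), []).append((c, sign))
    out = []
    for (a, b), directions in by_pair.items():
        support, sign = max(directions, key=lambda t: (t[0], t[1]))
        out.append(ConsensusEdge(gene_a=a, gene_b=b, sign=sign, support=support))
    out.sort(key=lambda e: e.pair)
    return out
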