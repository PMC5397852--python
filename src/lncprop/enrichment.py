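"""Pathway scoring against the propagation-ranked gene list.

Pathways are scored with a Kolmogorov--Smirnov-like running-sum statistic
weighted by the propagation scores, in the spirit of GSEA.  Walking down the
ranked coding-gene list L, two running fractions are tracked at each
position i:

    F_InP(i)  = sum_{g_j in P, j <= i} t_j^p / N_R,   N_R = sum_{g_j in P} t_j^p
    F_NotP(i) = #{g_j not in P, j <= i} / N_NotP,     N_NotP = |L| - |P & L|

and the enrichment score ES(P) is the maximum of F_InP - F_NotP over i.  A
high ES means the pathway's genes concentrate at the top of L, i.e. near
the seed lncRNAs in the network.  Significance is assessed by a seed
permutation null: random lncRNA seed sets of the same size are propagated
and every pathway re-scored, giving an empirical p-value M/N (M = number of
null scores strictly greater than the observed ES), followed by
Benjamini--Hochberg FDR control.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from statsmodels.stats.multitest import multipletests

from .network import CNCNetwork
from .propagation import (
    PropagationConfig,
    PropagationResult,
    _power_iterate,
    column_normalize,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PathwayGeneSet",
    "EnrichmentResult",
    "PermutationOutcome",
    "filter_pathways",
    "enrichment_score",
    "core_genes",
    "empirical_pvalue",
    "permutation_test",
    "bh_fdr",
    "flag_differential_core_genes",
    "score_pathways",
]


@dataclass(frozen=True)
class PathwayGeneSet:
    """A named set of protein-coding gene identifiers (one GMT record)."""

    pathway_id: str
    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"pathway {self.pathway_id!r} has no genes")


@dataclass
class EnrichmentResult:
    """Per-pathway enrichment outcome.

    ``size`` counts the pathway genes present as coding nodes in the
    network; ``peak_index`` is the 1-based position in L where the running
    sum attains ES; ``core_genes`` are the pathway genes at or before that
    position, in rank order.  ``p_value``/``fdr`` are NaN when no
    permutations were run.
    """

    pathway_id: str
    name: str
    size: int
    es: float
    peak_index: int
    core_genes: list[str]
    p_value: float = float("nan")
    fdr: float = float("nan")
    weight_exponent: float = 1.0
    n_permutations: int = 0
    running_sum: np.ndarray | None = field(default=None, repr=False)


@dataclass(frozen=True)
class PermutationOutcome:
    """Null-distribution summary for one pathway."""

    p_value: float
    n_greater: int
    n_permutations: int
    null_mean: float
    null_sd: float


def filter_pathways(
    pathways: Iterable[PathwayGeneSet],
    net: CNCNetwork,
    min_size: int = 15,
    max_size: int = 500,
) -> list[PathwayGeneSet]:
    """Drop overly narrow or broad pathways.

    A pathway is kept when the number of its member genes present as
    *coding nodes of the network* lies in [min_size, max_size]; this count
    precedes every other step and is the "size" reported downstream.
    """
    coding = set(net.coding_nodes)
    kept = []
    for pw in pathways:
        n = len(pw.genes & coding)
        if min_size <= n <= max_size:
            kept.append(pw)
    return kept


def _network_size(pathway: PathwayGeneSet, net: CNCNetwork) -> int:
    return len(pathway.genes & set(net.coding_nodes))


def _running_sum(
    t: np.ndarray, member: np.ndarray, weight_exponent: float
) -> np.ndarray:
    """Running F_InP - F_NotP over a ranked score vector ``t``."""
    tw = np.where(member, t, 0.0) ** weight_exponent * member
    n_r = tw.sum()
    if n_r == 0:
        raise ValueError(
            "pathway unreachable from seeds (all propagation scores zero "
            "or no pathway gene in the ranked list)"
        )
    n_not = int((~member).sum())
    if n_not == 0:  # degenerate: pathway covers all of L
        f_not = np.zeros(len(t))
    else:
        f_not = np.cumsum(~member) / n_not
    f_in = np.cumsum(tw) / n_r
    return f_in - f_not


def enrichment_score(
    ranked: PropagationResult,
    pathway: PathwayGeneSet,
    weight_exponent: float = 1.0,
) -> tuple[float, int, np.ndarray]:
    """ES(P), its 1-based peak position, and the full running sum.

    The peak is the *smallest* index attaining the maximum, which makes the
    derived core-gene set deterministic.  ``weight_exponent=0`` reduces to
    the classic unweighted KS enrichment statistic; ``weight_exponent=1``
    (default) weights pathway genes by their propagation scores.
    """
    if ranked.ranked_list is None:
        raise ValueError("ranked list missing; run rank_coding_genes first")
    member = np.array([g in pathway.genes for g in ranked.ranked_list])
    rs = _running_sum(ranked.scores_array, member, weight_exponent)
    peak = int(np.argmax(rs))
    return float(rs[peak]), peak + 1, rs


def core_genes(
    ranked: PropagationResult,
    pathway: PathwayGeneSet,
    peak_index: int,
) -> list[str]:
    """Pathway genes at or before the running-sum peak, in rank order."""
    if ranked.ranked_list is None:
        raise ValueError("ranked list missing; run rank_coding_genes first")
    out = [
        g for g in ranked.ranked_list[:peak_index] if g in pathway.genes
    ]
    if not out:
        logger.warning(
            "pathway %s has an empty core set (peak before any member)",
            pathway.pathway_id,
        )
    return out


def empirical_pvalue(
    observed: float, nulls: Sequence[float], pseudocount: bool = False
) -> float:
    """Empirical p-value M/N, M = #{null > observed} (strict).

    With ``pseudocount=True`` the (M+1)/(N+1) variant is returned, which
    avoids literal zeros at the cost of a small conservative bias.
    """
    arr = np.asarray(nulls, dtype=float)
    m = int(np.sum(arr > observed))
    n = len(arr)
    if n == 0:
        return float("nan")
    if pseudocount:
        return (m + 1) / (n + 1)
    return m / n


def permutation_test(
    net: CNCNetwork,
    observed: Mapping[str, float],
    pathways: Sequence[PathwayGeneSet],
    cfg: PropagationConfig | None = None,
    seed_count: int | None = None,
    n_permutations: int = 1000,
    rng_seed: int = 0,
    weight_exponent: float = 1.0,
    pseudocount: bool = False,
) -> dict[str, PermutationOutcome]:
    """Seed-permutation null for every pathway.

    Each permutation draws ``seed_count`` lncRNA nodes uniformly without
    replacement from *all* lncRNA nodes of the network, reruns the random
    walk and the ranking once, and scores every pathway against that
    permuted ranking.  The per-pathway empirical p-value is M/N with M the
    number of null scores strictly greater than the observed ES.  The RNG
    seed is the caller's responsibility to record for reproducibility.
    """
    cfg = cfg or PropagationConfig()
    if seed_count is None or seed_count < 1:
        raise ValueError("seed_count must be >= 1")
    lnc = net.lncrna_nodes
    if len(lnc) < seed_count:
        raise ValueError(
            f"network has {len(lnc)} lncRNA nodes, fewer than "
            f"seed_count={seed_count}"
        )
    missing = [p.pathway_id for p in pathways if p.pathway_id not in observed]
    if missing:
        raise ValueError(f"observed ES missing for pathway(s): {missing}")

    M, nodes = column_normalize(net)
    index = {n: i for i, n in enumerate(nodes)}
    coding = np.array(net.coding_nodes)
    coding_idx = np.array([index[g] for g in coding])
    member_masks = np.stack(
        [np.isin(coding, sorted(p.genes)) for p in pathways]
    )  # (n_pathways, n_coding), in base coding order

    rng = np.random.default_rng(rng_seed)
    lnc_idx = np.array([index[s] for s in lnc])
    nulls = np.empty((len(pathways), n_permutations))
    n = len(coding)
    for perm in range(n_permutations):
        picked = rng.choice(lnc_idx, size=seed_count, replace=False)
        p0 = np.zeros(len(nodes))
        p0[picked] = 1.0 / seed_count
        p, _ = _power_iterate(M, p0, cfg)
        t = np.sqrt(p[coding_idx])
        order = np.lexsort((coding, -t))  # descending t, ties by gene id
        t_sorted = t[order]
        for k, mask in enumerate(member_masks):
            member = mask[order]
            tw = np.where(member, t_sorted, 0.0) ** weight_exponent * member
            n_r = tw.sum()
            if n_r == 0:
                # null seed set cannot reach the pathway: no enrichment
                nulls[k, perm] = -np.inf
                continue
            n_not = n - int(member.sum())
            rs = np.cumsum(tw) / n_r
            if n_not:
                rs = rs - np.cumsum(~member) / n_not
            nulls[k, perm] = rs.max()

    out = {}
    for k, pw in enumerate(pathways):
        row = nulls[k]
        finite = row[np.isfinite(row)]
        out[pw.pathway_id] = PermutationOutcome(
            p_value=empirical_pvalue(observed[pw.pathway_id], row, pseudocount),
            n_greater=int(np.sum(row > observed[pw.pathway_id])),
            n_permutations=n_permutations,
            null_mean=float(finite.mean()) if finite.size else float("nan"),
            null_sd=float(finite.std(ddof=1)) if finite.size > 1 else float("nan"),
        )
    return out


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini--Hochberg step-up adjustment, input order preserved."""
    arr = np.asarray(p_values, dtype=float)
    if arr.size == 0:
        return arr
    if np.any((arr < 0) | (arr > 1) | ~np.isfinite(arr)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


@dataclass(frozen=True)
class CoreGeneFoldChange:
    gene: str
    log2_fc: float
    flagged: bool
    evaluable: bool
    used_pseudocount: bool


def flag_differential_core_genes(
    core: Sequence[str],
    expr_case: Mapping[str, Sequence[float] | float],
    expr_control: Mapping[str, Sequence[float] | float],
    log2fc_threshold: float = 1.0,
    pseudocount: float = 0.01,
) -> list[CoreGeneFoldChange]:
    """Fold-change validation of core genes between two conditions.

    A gene is flagged differentially expressed when
    \\|log2(mean case FPKM / mean control FPKM)\\| strictly exceeds the
    threshold (default 1, i.e. FC > 2 or FC < 0.5).  A zero mean in either
    condition is replaced by ``pseudocount`` and marked; genes missing from
    either condition are reported as not evaluable.
    """
    out = []
    for gene in core:
        if gene not in expr_case or gene not in expr_control:
            out.append(CoreGeneFoldChange(gene, float("nan"), False, False, False))
            continue
        case = float(np.mean(np.atleast_1d(expr_case[gene])))
        ctrl = float(np.mean(np.atleast_1d(expr_control[gene])))
        used_pc = False
        if case == 0:
            case, used_pc = pseudocount, True
        if ctrl == 0:
            ctrl, used_pc = pseudocount, True
        lfc = float(np.log2(case / ctrl))
        out.append(
            CoreGeneFoldChange(
                gene, lfc, abs(lfc) > log2fc_threshold, True, used_pc
            )
        )
    return out


def score_pathways(
    ranked: PropagationResult,
    pathways: Sequence[PathwayGeneSet],
    net: CNCNetwork,
    weight_exponent: float = 1.0,
    keep_running_sum: bool = False,
) -> list[EnrichmentResult]:
    """Observed ES, peak and core genes for each pathway (no permutations)."""
    coding = set(net.coding_nodes)
    out = []
    for pw in pathways:
        es, peak, rs = enrichment_score(ranked, pw, weight_exponent)
        out.append(
            EnrichmentResult(
                pathway_id=pw.pathway_id,
                name=pw.name,
                size=len(pw.genes & coding),
                es=es,
                peak_index=peak,
                core_genes=core_genes(ranked, pw, peak),
                weight_exponent=weight_exponent,
                running_sum=rs if keep_running_sum else None,
            )
        )
    return out
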