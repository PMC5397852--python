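"""Model/Results interface tying propagation and enrichment together.

:class:`PathwayPropagation` is the front door of the package: it holds a
CNC network, a seed lncRNA set and a pathway collection, and ``fit()``
runs the full procedure -- random walk with restart from the seeds,
propagation-score ranking of the coding genes, weighted-KS enrichment of
every retained pathway, seed-permutation p-values and Benjamini--Hochberg
FDR -- returning a :class:`PathwayPropagationResults` with the per-pathway
estimates and a ``summary()`` table.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as lio
from .enrichment import (
    PathwayGeneSet,
    bh_fdr,
    permutation_test,
    score_pathways,
)
from .network import CNCNetwork, restrict_to_components
from .propagation import PropagationConfig, rank_coding_genes, rwr

logger = logging.getLogger(__name__)

__all__ = ["PathwayPropagation", "PathwayPropagationResults"]


class PathwayPropagation:
    """Pathway annotation of a lncRNA set by network propagation.

    Parameters
    ----------
    network : CNCNetwork
        The coding--non-coding network.  Zero-degree nodes are removed up
        front; seeds falling in small components simply keep their
        propagation mass inside those components.
    seeds : sequence of str
        The lncRNA identifiers of interest (source nodes).  Seeds absent
        from the network are dropped with a warning at fit time.
    pathways : sequence of PathwayGeneSet
        Candidate pathways; those with fewer than ``min_pathway_size`` or
        more than ``max_pathway_size`` member genes among the network's
        coding nodes are excluded before scoring.
    restart_probability, tolerance, max_iterations
        Random-walk parameters (see :class:`PropagationConfig`).
    weight_exponent : float
        Exponent p on the propagation scores in the running sum
        (default 1).
    pseudocount_pvalue : bool
        Use the (M+1)/(N+1) empirical p-value variant instead of M/N.
    """

    def __init__(
        self,
        network: CNCNetwork,
        seeds: Sequence[str],
        pathways: Sequence[PathwayGeneSet],
        restart_probability: float = 0.7,
        tolerance: float = 1e-10,
        max_iterations: int = 10_000,
        weight_exponent: float = 1.0,
        min_pathway_size: int = 15,
        max_pathway_size: int = 500,
        pseudocount_pvalue: bool = False,
    ):
        self.network, self.component_labels = restrict_to_components(network)
        self.seeds = list(seeds)
        self.config = PropagationConfig(
            restart_probability=restart_probability,
            tolerance=tolerance,
            max_iterations=max_iterations,
        )
        self.weight_exponent = weight_exponent
        self.min_pathway_size = min_pathway_size
        self.max_pathway_size = max_pathway_size
        self.pseudocount_pvalue = pseudocount_pvalue
        self.pathways = [
            pw for pw in pathways
            if min_pathway_size
            <= len(pw.genes & set(self.network.coding_nodes))
            <= max_pathway_size
        ]
        self.n_pathways_excluded = len(list(pathways)) - len(self.pathways)
        if self.n_pathways_excluded:
            logger.info(
                "%d pathway(s) outside the size window [%d, %d] excluded",
                self.n_pathways_excluded, min_pathway_size, max_pathway_size,
            )

    @classmethod
    def from_files(
        cls,
        edge_path,
        node_path,
        seeds_path,
        gmt_path,
        **kwargs,
    ) -> "PathwayPropagation":
        """Build the model from the interchange files on disk."""
        return cls(
            network=lio.read_network(edge_path, node_path),
            seeds=lio.read_seeds(seeds_path),
            pathways=lio.read_gmt(gmt_path),
            **kwargs,
        )

    def fit(
        self,
        n_permutations: int = 1000,
        random_state: int = 0,
    ) -> "PathwayPropagationResults":
        """Run propagation, enrichment and the permutation test.

        ``n_permutations=0`` skips the null entirely and returns ES-only
        results (p-value and FDR are NaN).
        """
        if not self.pathways:
            raise ValueError("no pathway passed the size filter")
        prop = rank_coding_genes(rwr(self.network, set(self.seeds), self.config),
                                 self.network)
        results = score_pathways(
            prop, self.pathways, self.network,
            weight_exponent=self.weight_exponent, keep_running_sum=True,
        )
        perm_summary: Mapping | None = None
        if n_permutations > 0:
            observed = {r.pathway_id: r.es for r in results}
            perm_summary = permutation_test(
                self.network,
                observed,
                self.pathways,
                self.config,
                seed_count=len(prop.seed_ids),
                n_permutations=n_permutations,
                rng_seed=random_state,
                weight_exponent=self.weight_exponent,
                pseudocount=self.pseudocount_pvalue,
            )
            pvals = [perm_summary[r.pathway_id].p_value for r in results]
            fdrs = bh_fdr(pvals)
            for r, p, q in zip(results, pvals, fdrs):
                r.p_value = float(p)
                r.fdr = float(q)
                r.n_permutations = n_permutations
        return PathwayPropagationResults(
            model=self,
            propagation=prop,
            results=results,
            permutations=perm_summary,
            n_permutations=n_permutations,
            random_state=random_state,
        )


class PathwayPropagationResults:
    """Fitted results: per-pathway ES, empirical p, FDR and core genes."""

    def __init__(self, model, propagation, results, permutations,
                 n_permutations, random_state):
        self.model = model
        self.propagation = propagation
        self.results = sorted(results, key=lambda r: (-r.es, r.pathway_id))
        self.permutations = permutations
        self.n_permutations = n_permutations
        self.random_state = random_state

    @property
    def frame(self) -> pd.DataFrame:
        """Results table, descending ES with ties broken by pathway id."""
        return lio.results_frame(self.results)

    def significant(self, fdr_threshold: float = 0.01) -> pd.DataFrame:
        df = self.frame
        return df[df["fdr"] < fdr_threshold]

    def save(self, path) -> None:
        lio.write_results(self.results, path)

    def plot_running_sum(self, pathway_id: str, ax=None):
        from .plotting import plot_running_sum

        for r in self.results:
            if r.pathway_id == pathway_id:
                return plot_running_sum(r, ax=ax)
        raise KeyError(f"no results for pathway {pathway_id!r}")

    def summary(self, fdr_threshold: float = 0.01, max_rows: int = 20) -> str:
        """Plain-text summary in the style of a model-fit report."""
        net = self.model.network
        prop = self.propagation
        lines = [
            "Pathway propagation results",
            "=" * 64,
            f"Network nodes:        {net.n_nodes} "
            f"({len(net.lncrna_nodes)} lncRNA, {len(net.coding_nodes)} coding)",
            f"Network edges:        {net.n_edges}",
            f"Seeds mapped:         {len(prop.seed_ids)} "
            f"({prop.n_dropped_seeds} dropped)",
            f"Restart probability:  {self.model.config.restart_probability}",
            f"RWR iterations:       {prop.n_iterations}",
            f"Pathways scored:      {len(self.results)} "
            f"({self.model.n_pathways_excluded} excluded by size)",
            f"Permutations:         {self.n_permutations}",
        ]
        if self.n_permutations > 0:
            n_sig = int(np.sum([r.fdr < fdr_threshold for r in self.results]))
            lines.append(
                f"Significant pathways: {n_sig} (FDR < {fdr_threshold})"
            )
        lines.append("-" * 64)
        df = self.frame.head(max_rows).copy()
        df["core_genes"] = [
            f"{len(r.core_genes)} genes"
            for r in self.results[:max_rows]
        ]
        lines.append(df.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
        return "\n".join(lines)
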