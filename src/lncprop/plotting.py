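"""Minimal QC plotting: the enrichment running-sum curve."""

from __future__ import annotations

from .enrichment import EnrichmentResult

__all__ = ["plot_running_sum"]


def plot_running_sum(result: EnrichmentResult, ax=None):
    """Plot F_InP - F_NotP along the ranked list, marking ES at the peak."""
    import matplotlib.pyplot as plt

    if result.running_sum is None:
        raise ValueError("result carries no running sum (refit with plotting on)")
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 3.5))
    rs = result.running_sum
    ax.plot(range(1, len(rs) + 1), rs, lw=1.2)
    ax.axhline(0.0, color="grey", lw=0.6)
    ax.axvline(result.peak_index, color="crimson", ls="--", lw=0.8)
    ax.annotate(
        f"ES = {result.es:.3f}",
        xy=(result.peak_index, result.es),
        xytext=(5, 5), textcoords="offset points", fontsize=9,
    )
    ax.set_xlabel("rank in L")
    ax.set_ylabel("running sum")
    ax.set_title(f"{result.pathway_id}: {result.name}", fontsize=10)
    return ax
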