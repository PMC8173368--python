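"""Multimodal intersection analysis (MIA).

MIA maps dissociated cell types onto tissue regions by comparing marker gene
sets from the two modalities: for every (cell type, region) pair it counts
the overlap k of the two marker sets within a common gene universe of size N
and asks, under the hypergeometric null of random draws, whether k is
surprisingly large (enrichment, upper tail P(X >= k)) or surprisingly small
(depletion, lower tail P(X <= k)).  Both tails include the observed k.

The display score is a signed log10 p-value: ``-log10(p_enrichment)`` when
the enrichment tail is the smaller, ``+log10(p_depletion)`` otherwise — so
enriched pairs score positive and depleted pairs negative, matching the
red/blue convention of MIA heatmaps.

The background universe is a modelling choice: by default the caller passes
the intersection of the gene ids present in both processed datasets (the
genes where an overlap is observable at all); a union universe is equally
accepted — the functions only require both sets to live inside it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import GeneSet

logger = logging.getLogger(__name__)

__all__ = ["MIAResult", "mia_pair", "mia_map", "assign_regions", "plot_mia_map"]

_P_FLOOR = 1e-300  # keeps log10 finite when a tail underflows


@dataclass
class MIAResult:
    """Cell-type x region overlap statistics.

    All matrices are indexed ``[cell_type, region]``.  ``p_enr`` and ``p_dep``
    are raw one-sided hypergeometric tails; ``p_enr_adj``/``p_dep_adj`` carry
    Benjamini-Hochberg adjustment over the whole map for convenience.
    """

    cell_types: list[str]
    regions: list[str]
    overlap: np.ndarray
    ct_sizes: np.ndarray
    region_sizes: np.ndarray
    universe_n: int
    p_enr: np.ndarray
    p_dep: np.ndarray
    score: np.ndarray
    p_enr_adj: np.ndarray
    p_dep_adj: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        """Long-form table: one row per (cell type, region) pair."""
        rows = []
        for i, ct in enumerate(self.cell_types):
            for j, rg in enumerate(self.regions):
                rows.append(
                    {
                        "cell_type": ct,
                        "region": rg,
                        "overlap_k": int(self.overlap[i, j]),
                        "ct_set_size": int(self.ct_sizes[i]),
                        "region_set_size": int(self.region_sizes[j]),
                        "universe_n": self.universe_n,
                        "p_enrichment": self.p_enr[i, j],
                        "p_depletion": self.p_dep[i, j],
                        "p_enrichment_adj": self.p_enr_adj[i, j],
                        "p_depletion_adj": self.p_dep_adj[i, j],
                        "score": self.score[i, j],
                    }
                )
        return pd.DataFrame(rows)


def _as_genes(s) -> frozenset:
    return frozenset(s.genes if isinstance(s, GeneSet) else s)


def mia_pair(set_a, set_b, universe) -> tuple[int, float, float]:
    """Hypergeometric overlap test for one pair of gene sets.

    With ``N = |universe|``, ``K = |A|``, ``n = |B|`` and ``k = |A & B|``
    (after restricting both sets to the universe), returns
    ``(k, P(X >= k), P(X <= k))`` for ``X ~ Hypergeometric(N, K, n)``.
    Genes outside the universe are dropped with a logged count.  An empty
    universe is an error; an empty set gives ``k = 0`` and an enrichment
    p-value of 1 with a warning in the log.
    """
    universe = frozenset(universe)
    if not universe:
        raise ValueError("the background universe is empty")
    a = _as_genes(set_a)
    b = _as_genes(set_b)
    dropped = len(a - universe) + len(b - universe)
    if dropped:
        logger.info("mia_pair: %d genes outside the universe dropped", dropped)
    a &= universe
    b &= universe
    if not a or not b:
        logger.warning("mia_pair: an empty gene set; overlap trivially 0")
    N, K, n, k = len(universe), len(a), len(b), len(a & b)
    p_enr = float(stats.hypergeom.sf(k - 1, N, K, n))
    p_dep = float(stats.hypergeom.cdf(k, N, K, n))
    return k, min(p_enr, 1.0), min(p_dep, 1.0)


def _bh(p: np.ndarray) -> np.ndarray:
    from statsmodels.stats.multitest import multipletests

    flat = p.ravel()
    return multipletests(flat, method="fdr_bh")[1].reshape(p.shape)


def mia_map(ct_sets: list[GeneSet], region_sets: list[GeneSet], universe) -> MIAResult:
    """Apply :func:`mia_pair` to every (cell type, region) pair."""
    if not ct_sets or not region_sets:
        raise ValueError("need at least one gene set on each side")
    universe = frozenset(universe)
    nct, nrg = len(ct_sets), len(region_sets)
    overlap = np.zeros((nct, nrg), dtype=np.int64)
    p_enr = np.ones((nct, nrg))
    p_dep = np.ones((nct, nrg))
    for i, cs in enumerate(ct_sets):
        for j, rs in enumerate(region_sets):
            overlap[i, j], p_enr[i, j], p_dep[i, j] = mia_pair(cs, rs, universe)
    score = np.where(
        p_enr <= p_dep,
        -np.log10(np.maximum(p_enr, _P_FLOOR)),
        np.log10(np.maximum(p_dep, _P_FLOOR)),
    )
    return MIAResult(
        cell_types=[s.name for s in ct_sets],
        regions=[s.name for s in region_sets],
        overlap=overlap,
        ct_sizes=np.array([len(_as_genes(s) & universe) for s in ct_sets]),
        region_sizes=np.array([len(_as_genes(s) & universe) for s in region_sets]),
        universe_n=len(universe),
        p_enr=p_enr,
        p_dep=p_dep,
        score=score,
        p_enr_adj=_bh(p_enr),
        p_dep_adj=_bh(p_dep),
    )


def assign_regions(res: MIAResult, min_score: float = 0.0) -> pd.DataFrame:
    """Best-scoring cell type per region.

    Regions whose best score falls below ``min_score`` are labelled
    ``unassigned``.  Score ties go to the lexicographically first cell type
    name (logged).
    """
    rows = []
    for j, region in enumerate(res.regions):
        col = res.score[:, j]
        best = col.max() if len(col) else -np.inf
        winners = sorted(res.cell_types[i] for i in np.flatnonzero(col == best))
        if len(winners) > 1:
            logger.info("region %s: score tie among %s; taking %s", region, winners, winners[0])
        assigned = winners[0] if best >= min_score else "unassigned"
        rows.append({"region": region, "cell_type": assigned, "score": float(best)})
    return pd.DataFrame(rows)


def plot_mia_map(res: MIAResult, path, cap: float = 10.0):
    """Write the signed-score heatmap (red = enrichment, blue = depletion)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(
        figsize=(1.2 * len(res.regions) + 3, 0.6 * len(res.cell_types) + 2)
    )
    data = np.clip(res.score, -cap, cap)
    im = ax.imshow(data, cmap="RdBu_r", vmin=-cap, vmax=cap, aspect="auto")
    ax.set_xticks(range(len(res.regions)), res.regions, rotation=45, ha="right")
    ax.set_yticks(range(len(res.cell_types)), res.cell_types)
    for i in range(len(res.cell_types)):
        for j in range(len(res.regions)):
            ax.text(j, i, str(res.overlap[i, j]), ha="center", va="center", fontsize=7)
    fig.colorbar(im, ax=ax, label="signed -log10 p (enrichment > 0)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
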