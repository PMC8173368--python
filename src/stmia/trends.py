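"""Monotone expression trends across an ordered series of stages.

A gene is called *gradually up-regulated* across an ordered stage series
(e.g. early -> mid -> late erythroblasts) when its per-stage mean normalized
expression is strictly increasing along the order and the bimodal LRT between
the first and last stages is significant after Benjamini-Hochberg adjustment
across all genes; *gradually down-regulated* is the mirror image.  An
optional per-step margin ``epsilon`` demands a minimum increase between
consecutive stages (default 0: any strict increase counts).

Also here: the balanced-subsample PCA view of an ordered comparison, which
draws the same number of units from every group before projecting onto the
first two principal components.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .preprocess import ClusterAssignment, NormalizedMatrix, balanced_subsample
from .markers import _loglik_stats

__all__ = ["gradual_genes", "balanced_stage_pca"]


def _stage_masks(nm: NormalizedMatrix, ca: ClusterAssignment, stage_order):
    if list(ca.unit_ids) != list(nm.unit_ids):
        order = {u: i for i, u in enumerate(nm.unit_ids)}
        if len(ca.unit_ids) != len(nm.unit_ids) or any(u not in order for u in ca.unit_ids):
            raise ValueError("stage assignment and matrix must cover the same units")
        perm = np.array([order[u] for u in ca.unit_ids])
        nm = NormalizedMatrix(nm.gene_ids, list(ca.unit_ids), nm.values[:, perm], nm.scale_target)
    if stage_order is None:
        stage_order = list(range(ca.k))
    if len(stage_order) < 2:
        raise ValueError("need at least 2 ordered stages")
    masks = []
    for label in stage_order:
        mask = ca.labels == label
        if mask.sum() < 2:
            raise ValueError(f"stage {label} has fewer than 2 units")
        masks.append(mask)
    return nm, stage_order, masks


def gradual_genes(
    nm: NormalizedMatrix,
    ca: ClusterAssignment,
    stage_order: list[int] | None = None,
    alpha: float = 0.05,
    epsilon: float = 0.0,
) -> pd.DataFrame:
    """Call gradually up-/down-regulated genes along a stage order.

    Parameters
    ----------
    nm, ca
        Normalized matrix and a cluster assignment whose labels are stages.
    stage_order
        Labels in biological order; defaults to ``0..k-1`` ascending.
    alpha
        BH-adjusted significance level for the first-vs-last-stage test.
    epsilon
        Minimum required per-step change in stage means.

    Returns
    -------
    DataFrame with one row per called gene: ``gene``, ``direction`` (``up`` or
    ``down``), ``mean_stage<i>`` columns in stage order, and
    ``p_adj_extremes``.
    """
    nm, stage_order, masks = _stage_masks(nm, ca, stage_order)
    means = np.stack([nm.values[:, m].mean(axis=1) for m in masks], axis=1)  # genes x stages
    diffs = np.diff(means, axis=1)
    up = (diffs > epsilon).all(axis=1)
    down = (diffs < -epsilon).all(axis=1)

    # first-vs-last bimodal LRT, vectorized over genes
    first, last = masks[0], masks[-1]

    def _suff(mask):
        V = nm.values[:, mask]
        pos = V > 0
        return mask.sum(), pos.sum(axis=1), V.sum(axis=1), (V**2).sum(axis=1)

    nf, mf, s1f, s2f = _suff(first)
    nl, ml, s1l, s2l = _suff(last)
    ll_split = _loglik_stats(nf, mf, s1f, s2f) + _loglik_stats(nl, ml, s1l, s2l)
    ll_joint = _loglik_stats(nf + nl, mf + ml, s1f + s1l, s2f + s2l)
    stat = np.maximum(2.0 * (ll_split - ll_joint), 0.0)
    pvals = np.where((mf + ml) == 0, 1.0, stats.chi2.sf(stat, df=3))
    p_adj = multipletests(pvals, method="fdr_bh")[1]

    called = (up | down) & (p_adj < alpha)
    idx = np.flatnonzero(called)
    out = pd.DataFrame(
        {
            "gene": [nm.gene_ids[i] for i in idx],
            "direction": np.where(up[idx], "up", "down"),
            **{
                f"mean_stage{si}": means[idx, s]
                for s, si in enumerate(range(len(stage_order)))
            },
            "p_adj_extremes": p_adj[idx],
        }
    )
    return out.sort_values(["direction", "gene"], ascending=[False, True]).reset_index(drop=True)


def balanced_stage_pca(
    nm: NormalizedMatrix,
    ca: ClusterAssignment,
    n_per_group: int = 50,
    seed: int = 0,
    n_components: int = 2,
) -> pd.DataFrame:
    """PCA of a group-balanced subsample of units.

    Draws ``n_per_group`` units from every cluster (error if any cluster is
    smaller), centers the expression matrix over the sampled units, and
    projects onto the top principal components.  Component signs are
    canonicalized so the largest-magnitude loading of each component is
    positive, making coordinates reproducible across runs up to exact
    arithmetic.

    Returns a frame with ``unit_id``, ``group`` and ``PC1..PCn`` columns.
    """
    sampled = balanced_subsample(ca, n_per_group, seed)
    order = {u: i for i, u in enumerate(nm.unit_ids)}
    cols = np.array([order[u] for u in sampled])
    X = nm.values[:, cols].T  # units x genes
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(X - X.mean(axis=0, keepdims=True))
    for c in range(n_components):
        loading = pca.components_[c]
        if loading[np.argmax(np.abs(loading))] < 0:
            coords[:, c] = -coords[:, c]
    label_of = dict(zip(ca.unit_ids, ca.labels))
    out = pd.DataFrame({"unit_id": sampled, "group": [label_of[u] for u in sampled]})
    for c in range(n_components):
        out[f"PC{c + 1}"] = coords[:, c]
    return out
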