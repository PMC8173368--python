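"""Per-cluster differential expression with the bimodal likelihood-ratio test.

The test models normalized single-cell expression as a mixture of a point
mass at zero (dropout) and a normal distribution on the positive values.  For
a sample of n values with m positives v_1..v_m the maximized log-likelihood is

    L = (n - m) log(1 - pi) + m log(pi) + sum_i log N(v_i; mu, sigma)

with pi = m/n (clamped to [1e-5, 1 - 1e-5]), mu the mean of the positives and
sigma their sample standard deviation (set to 1 when fewer than two positives
or when the positives are constant).  The statistic for groups A and B is

    2 [L(A) + L(B) - L(A u B)]

referred to a chi-square with 3 degrees of freedom (pi, mu, sigma each free
per group under the alternative).

``find_all_markers`` runs the test one-vs-rest per cluster with the
conventional gates: a gene is tested when max(pct_in, pct_out) >= min_pct and
|log fold change| >= logfc_threshold, and p-values are Benjamini-Hochberg
adjusted within each cluster's tested set.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import GeneSet
from .preprocess import ClusterAssignment, NormalizedMatrix

logger = logging.getLogger(__name__)

__all__ = ["bimod_lrt", "log_fold_change", "find_all_markers", "marker_sets"]

_PI_EPS = 1e-5
_LOG2PI = np.log(2.0 * np.pi)


def _loglik_stats(n, m, s1, s2):
    """Vectorized zero-inflated-normal log-likelihood from sufficient stats.

    ``n`` sample size, ``m`` number of positives, ``s1``/``s2`` sum and sum of
    squares of the positive values.  All arguments broadcast.
    """
    n = np.asarray(n, dtype=float)
    m = np.asarray(m, dtype=float)
    s1 = np.asarray(s1, dtype=float)
    s2 = np.asarray(s2, dtype=float)
    pi = np.clip(m / n, _PI_EPS, 1.0 - _PI_EPS)
    ll = (n - m) * np.log1p(-pi) + m * np.log(pi)
    with np.errstate(invalid="ignore", divide="ignore"):
        mu = np.where(m > 0, s1 / np.maximum(m, 1), 0.0)
        ss = np.maximum(s2 - m * mu**2, 0.0)  # sum of squared deviations
        var = np.where(m > 1, ss / np.maximum(m - 1, 1), 1.0)
    sd = np.sqrt(np.where(var > 1e-12, var, 1.0))
    norm_part = -0.5 * m * _LOG2PI - m * np.log(sd) - ss / (2.0 * sd**2)
    return ll + np.where(m > 0, norm_part, 0.0)


def _suffstats(v: np.ndarray):
    v = np.asarray(v, dtype=float)
    pos = v[v > 0]
    return v.size, pos.size, pos.sum(), (pos**2).sum()


def bimod_lrt(x, y) -> tuple[float, float]:
    """Bimodal LRT between two samples of normalized expression.

    Returns ``(statistic, p_value)``; the statistic is non-negative and the
    p-value comes from the chi-square upper tail with 3 degrees of freedom.
    Two all-zero samples short-circuit to ``(0.0, 1.0)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    if not (x > 0).any() and not (y > 0).any():
        return 0.0, 1.0
    nx, mx, s1x, s2x = _suffstats(x)
    ny, my, s1y, s2y = _suffstats(y)
    ll_split = _loglik_stats(nx, mx, s1x, s2x) + _loglik_stats(ny, my, s1y, s2y)
    ll_joint = _loglik_stats(nx + ny, mx + my, s1x + s1y, s2x + s2y)
    stat = float(2.0 * (ll_split - ll_joint))
    if stat < 0:
        # sample (ddof=1) standard deviations, matching reference behavior,
        # are not exact MLEs, so the split likelihood can dip slightly below
        # the joint one; clip to zero
        logger.debug("bimod LRT statistic %g < 0 clipped to 0", stat)
        stat = 0.0
    return stat, float(stats.chi2.sf(stat, df=3))


def log_fold_change(x, y) -> float:
    """Natural-log fold change of linear-scale means, with pseudo-mean 1.

    ``ln((mean(2**x - 1) + 1) / (mean(2**y - 1) + 1))`` — finite at all-zero
    input and antisymmetric under swapping the groups.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mx = np.expm1(x * np.log(2.0)).mean()
    my = np.expm1(y * np.log(2.0)).mean()
    return float(np.log((mx + 1.0) / (my + 1.0)))


def _cluster_stats(values: np.ndarray, mask: np.ndarray):
    """Per-gene sufficient statistics over the units selected by ``mask``."""
    V = values[:, mask]
    pos = V > 0
    m = pos.sum(axis=1)
    s1 = V.sum(axis=1)  # zeros contribute nothing
    s2 = (V**2).sum(axis=1)
    return mask.sum(), m, s1, s2, np.expm1(V * np.log(2.0)).mean(axis=1)


def find_all_markers(
    nm: NormalizedMatrix,
    ca: ClusterAssignment,
    logfc_threshold: float = 0.1,
    min_pct: float = 0.01,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-vs-rest bimodal-LRT marker table across all clusters.

    For each cluster, genes passing the detection gate
    (``max(pct_in, pct_out) >= min_pct``) and the effect gate
    (``|log_fc| >= logfc_threshold``) are tested against all other units;
    p-values are BH-adjusted within the cluster's tested set.  Clusters of
    size 1 are skipped with a warning.  Records are sorted by adjusted p,
    then decreasing |log_fc|, then gene id.

    ``alpha`` is carried as the default significance level for
    :func:`marker_sets`; the table itself keeps every tested gene.
    """
    if ca.k < 2:
        raise ValueError("marker detection needs at least 2 clusters")
    if list(ca.unit_ids) != list(nm.unit_ids):
        order = {u: i for i, u in enumerate(nm.unit_ids)}
        missing = [u for u in ca.unit_ids if u not in order]
        if missing or len(ca.unit_ids) != len(nm.unit_ids):
            raise ValueError("clustering and matrix must cover the same units")
        perm = np.array([order[u] for u in ca.unit_ids])
        nm = NormalizedMatrix(nm.gene_ids, list(ca.unit_ids), nm.values[:, perm], nm.scale_target)

    genes = np.array(nm.gene_ids)
    records = []
    for cluster in range(ca.k):
        mask = ca.labels == cluster
        if mask.sum() < 2:
            warnings.warn(f"cluster {cluster} has fewer than 2 units; skipped", stacklevel=2)
            continue
        n_in, m_in, s1_in, s2_in, lin_in = _cluster_stats(nm.values, mask)
        n_out, m_out, s1_out, s2_out, lin_out = _cluster_stats(nm.values, ~mask)
        pct_in = m_in / n_in
        pct_out = m_out / n_out
        lfc = np.log((lin_in + 1.0) / (lin_out + 1.0))
        tested = (np.maximum(pct_in, pct_out) >= min_pct) & (np.abs(lfc) >= logfc_threshold)
        if not tested.any():
            continue
        ll_split = _loglik_stats(n_in, m_in, s1_in, s2_in) + _loglik_stats(
            n_out, m_out, s1_out, s2_out
        )
        ll_joint = _loglik_stats(n_in + n_out, m_in + m_out, s1_in + s1_out, s2_in + s2_out)
        stat = np.maximum(2.0 * (ll_split - ll_joint), 0.0)
        degenerate = (m_in + m_out) == 0  # both groups all zero
        pvals = np.where(degenerate, 1.0, stats.chi2.sf(stat, df=3))
        idx = np.flatnonzero(tested)
        p_adj = multipletests(pvals[idx], method="fdr_bh")[1]
        frame = pd.DataFrame(
            {
                "gene": genes[idx],
                "cluster": cluster,
                "log_fc": lfc[idx],
                "p_value": pvals[idx],
                "p_adj": p_adj,
                "pct_in": pct_in[idx],
                "pct_out": pct_out[idx],
            }
        )
        records.append(frame)
    if not records:
        return pd.DataFrame(
            columns=["gene", "cluster", "log_fc", "p_value", "p_adj", "pct_in", "pct_out"]
        )
    table = pd.concat(records, ignore_index=True)
    table["_abs_lfc"] = table["log_fc"].abs()
    table = table.sort_values(
        ["cluster", "p_adj", "_abs_lfc", "gene"],
        ascending=[True, True, False, True],
        kind="mergesort",
    ).drop(columns="_abs_lfc")
    return table.reset_index(drop=True)


def marker_sets(
    mt: pd.DataFrame,
    alpha: float = 0.05,
    direction: str = "up",
    name_prefix: str = "cluster",
) -> dict[int, GeneSet]:
    """Significant marker genes per cluster, as gene sets.

    Keeps records with ``p_adj < alpha`` and positive log fold change
    (``direction="up"``; ``"down"`` selects negative).  A cluster with no
    significant markers yields an empty set with a warning.
    """
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    out: dict[int, GeneSet] = {}
    for cluster, sub in mt.groupby("cluster", sort=True):
        sig = sub[sub["p_adj"] < alpha]
        sig = sig[sig["log_fc"] > 0] if direction == "up" else sig[sig["log_fc"] < 0]
        if sig.empty:
            warnings.warn(f"cluster {cluster}: no significant {direction} markers", stacklevel=2)
        out[cluster] = GeneSet(
            name=f"{name_prefix}_{cluster}",
            description=f"{direction} markers, p_adj < {alpha}",
            genes=frozenset(sig["gene"]),
        )
    return out
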