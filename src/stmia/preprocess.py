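"""Quality control, normalization, clustering and subsampling.

The processing contract, in order:

1. unit filters — spots keep >= ``min_genes_per_spot`` detected genes; cells
   additionally drop when their mitochondrial UMI fraction *exceeds*
   ``max_mito_frac`` (strictly; a cell at exactly the threshold stays);
2. gene filter — keep genes detected in at least ``min_cells_per_gene`` units;
3. normalization — each unit's counts are scaled so its total matches the
   median pre-scaling total across units, then log2(1 + x) transformed;
4. variable-gene selection by linear-scale dispersion (variance/mean);
5. Ward-linkage hierarchical clustering on Euclidean distances over the
   selected genes, cut to k clusters, labels renumbered by decreasing size.

Detected-gene counts are evaluated on the matrix as passed in; filters are
applied once each (set ``iterative=True`` on :func:`apply_qc` to re-filter to
a fixed point).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import scipy.cluster.hierarchy

from .io import CountMatrix, GeneSet

logger = logging.getLogger(__name__)

__all__ = [
    "QCThresholds",
    "NormalizedMatrix",
    "ClusterAssignment",
    "filter_spots",
    "filter_cells",
    "filter_genes",
    "apply_qc",
    "normalize",
    "select_variable_genes",
    "cluster_hierarchical",
    "balanced_subsample",
]


@dataclass
class QCThresholds:
    min_genes_per_spot: int = 200
    min_genes_per_cell: int = 200
    max_mito_frac: float = 0.20
    min_cells_per_gene: int = 3

    def __post_init__(self) -> None:
        if min(self.min_genes_per_spot, self.min_genes_per_cell, self.min_cells_per_gene) < 0:
            raise ValueError("thresholds must be >= 0")
        if not 0 <= self.max_mito_frac <= 1:
            raise ValueError("max_mito_frac must lie in [0, 1]")


@dataclass
class NormalizedMatrix:
    """Median-scaled, log2-transformed expression on the CountMatrix axes.

    ``values[g, u] = log2(1 + counts[g, u] * scale_target / total_u)`` where
    ``scale_target`` is the median of the per-unit totals at normalization
    time.  Consequently ``sum_g (2**values[g, u] - 1) == scale_target`` for
    every unit.
    """

    gene_ids: list[str]
    unit_ids: list[str]
    values: np.ndarray
    scale_target: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.unit_ids)):
            raise ValueError("values shape does not match id lists")
        if self.values.size and self.values.min() < 0:
            raise ValueError("normalized values must be >= 0")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_units(self) -> int:
        return len(self.unit_ids)

    def linear(self) -> np.ndarray:
        """Back-transform to the median-scaled linear scale (2**v - 1)."""
        return np.expm1(self.values * np.log(2.0))

    def subset_genes(self, genes) -> "NormalizedMatrix":
        """Restrict to the given genes (a GeneSet or iterable of ids)."""
        wanted = set(genes.genes if isinstance(genes, GeneSet) else genes)
        rows = [i for i, g in enumerate(self.gene_ids) if g in wanted]
        if not rows:
            raise ValueError("none of the requested genes are in the matrix")
        return NormalizedMatrix(
            gene_ids=[self.gene_ids[i] for i in rows],
            unit_ids=list(self.unit_ids),
            values=self.values[rows, :],
            scale_target=self.scale_target,
        )

    def subset_units(self, index) -> "NormalizedMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return NormalizedMatrix(
            gene_ids=list(self.gene_ids),
            unit_ids=[self.unit_ids[i] for i in index],
            values=self.values[:, index],
            scale_target=self.scale_target,
        )


@dataclass
class ClusterAssignment:
    """A hard partition of units into k clusters labelled 0..k-1."""

    unit_ids: list[str]
    labels: np.ndarray
    k: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.shape != (len(self.unit_ids),):
            raise ValueError("labels length must match unit_ids")
        present = set(self.labels.tolist())
        if present != set(range(self.k)):
            raise ValueError(f"labels must cover 0..{self.k - 1} with no empty cluster")

    def members(self, label: int) -> list[str]:
        return [u for u, l in zip(self.unit_ids, self.labels) if l == label]


def _empty_result_error(cm: CountMatrix, keep: np.ndarray, what: str) -> None:
    if not keep.any():
        raise ValueError(
            f"{what} removed every unit ({cm.n_units} in, 0 out); "
            "check thresholds against the data"
        )


def filter_spots(cm: CountMatrix, th: QCThresholds) -> CountMatrix:
    """Drop spots detecting fewer than ``min_genes_per_spot`` genes."""
    if cm.unit_kind != "spot":
        raise ValueError("filter_spots expects a spot matrix")
    keep = cm.detected_genes_per_unit() >= th.min_genes_per_spot
    _empty_result_error(cm, keep, "spot filter")
    logger.info("spot filter: %d of %d spots retained", keep.sum(), cm.n_units)
    return cm.subset_units(keep)


def filter_cells(cm: CountMatrix, th: QCThresholds) -> CountMatrix:
    """Drop cells with too few genes or mitochondrial overload.

    A cell is removed when it detects fewer than ``min_genes_per_cell`` genes
    *or* when its mitochondrial UMI fraction strictly exceeds
    ``max_mito_frac``.  With no "MT-"-prefixed genes in the matrix the
    mitochondrial criterion is skipped with a warning.
    """
    if cm.unit_kind != "cell":
        raise ValueError("filter_cells expects a cell matrix")
    keep = cm.detected_genes_per_unit() >= th.min_genes_per_cell
    if cm.mito_gene_mask().any():
        keep &= cm.mito_fraction_per_unit() <= th.max_mito_frac
    else:
        warnings.warn(
            "no 'MT-'-prefixed genes found; mitochondrial filter skipped",
            stacklevel=2,
        )
    _empty_result_error(cm, keep, "cell filter")
    logger.info("cell filter: %d of %d cells retained", keep.sum(), cm.n_units)
    return cm.subset_units(keep)


def filter_genes(cm: CountMatrix, th: QCThresholds) -> CountMatrix:
    """Keep genes detected (count > 0) in at least ``min_cells_per_gene`` units."""
    keep = (cm.counts > 0).sum(axis=1) >= th.min_cells_per_gene
    if not keep.any():
        raise ValueError("gene filter removed every gene")
    logger.info("gene filter: %d of %d genes retained", keep.sum(), cm.n_genes)
    return cm.subset_genes(keep)


def apply_qc(
    cm: CountMatrix, th: QCThresholds, iterative: bool = False
) -> CountMatrix:
    """Unit filter then gene filter, once each (or to a fixed point)."""
    unit_filter = filter_spots if cm.unit_kind == "spot" else filter_cells
    out = filter_genes(unit_filter(cm, th), th)
    while iterative:
        before = (out.n_genes, out.n_units)
        out = filter_genes(unit_filter(out, th), th)
        if (out.n_genes, out.n_units) == before:
            break
    return out


def normalize(cm: CountMatrix) -> NormalizedMatrix:
    """Median-of-totals normalization followed by log2(1 + x).

    Every unit's counts are rescaled so its total equals the median total
    across units, then log2-transformed with pseudocount 1.  Units with zero
    total are an error — quality control removes them first.
    """
    totals = cm.total_counts_per_unit().astype(float)
    if cm.n_units == 0:
        raise ValueError("cannot normalize an empty matrix")
    if (totals == 0).any():
        zero = [cm.unit_ids[i] for i in np.flatnonzero(totals == 0)][:5]
        raise ValueError(f"units with zero total counts (e.g. {zero}); filter first")
    median_total = float(np.median(totals))
    values = np.log2(1.0 + cm.counts * (median_total / totals)[None, :])
    return NormalizedMatrix(
        gene_ids=list(cm.gene_ids),
        unit_ids=list(cm.unit_ids),
        values=values,
        scale_target=median_total,
    )


def select_variable_genes(nm: NormalizedMatrix, n_top: int) -> GeneSet:
    """The ``n_top`` genes with highest linear-scale dispersion.

    Dispersion is variance/mean of ``2**value - 1`` across units; genes with
    zero mean have dispersion 0.  Ties break lexicographically on gene id.
    """
    if n_top > nm.n_genes:
        raise ValueError(f"n_top={n_top} exceeds {nm.n_genes} genes")
    lin = nm.linear()
    mean = lin.mean(axis=1)
    var = lin.var(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        disp = np.where(mean > 0, var / mean, 0.0)
    order = sorted(range(nm.n_genes), key=lambda i: (-disp[i], nm.gene_ids[i]))
    chosen = frozenset(nm.gene_ids[i] for i in order[:n_top])
    return GeneSet(name=f"top_{n_top}_variable", description="dispersion-ranked", genes=chosen)


def cluster_hierarchical(nm: NormalizedMatrix, genes, k: int) -> ClusterAssignment:
    """Ward-linkage agglomerative clustering over the given genes, cut at k.

    ``genes`` may be a GeneSet or any iterable of gene ids; ids absent from
    the matrix are ignored.  Cluster labels are renumbered by decreasing
    cluster size (ties by first occurrence in the dendrogram cut).
    """
    if not 1 <= k <= nm.n_units:
        raise ValueError(f"k={k} out of range for {nm.n_units} units")
    wanted = set(genes.genes if isinstance(genes, GeneSet) else genes)
    rows = [i for i, g in enumerate(nm.gene_ids) if g in wanted]
    if not rows:
        raise ValueError("none of the requested genes are in the matrix")
    X = nm.values[rows, :].T  # units x genes
    if k == nm.n_units:
        raw = np.arange(nm.n_units)
    else:
        Z = scipy.cluster.hierarchy.linkage(X, method="ward")
        raw = scipy.cluster.hierarchy.fcluster(Z, t=k, criterion="maxclust") - 1
    # renumber by decreasing size; ties keep the smaller raw label first
    sizes = np.bincount(raw, minlength=raw.max() + 1)
    order = sorted(range(len(sizes)), key=lambda l: (-sizes[l], l))
    remap = {old: new for new, old in enumerate(order) if sizes[old] > 0}
    return ClusterAssignment(
        unit_ids=list(nm.unit_ids),
        labels=np.array([remap[l] for l in raw]),
        k=len(remap),
    )


def balanced_subsample(ca: ClusterAssignment, n_per_group: int, seed: int) -> list[str]:
    """Sample ``n_per_group`` unit ids from every cluster, without replacement.

    Deterministic under ``seed``; units within each cluster are considered in
    sorted-id order before sampling, so the draw does not depend on input
    order.  A cluster smaller than ``n_per_group`` is an error naming it.
    """
    rng = np.random.default_rng(seed)
    out: list[str] = []
    for label in range(ca.k):
        members = sorted(ca.members(label))
        if len(members) < n_per_group:
            raise ValueError(
                f"cluster {label} has {len(members)} units, fewer than "
                f"n_per_group={n_per_group}"
            )
        if len(members) == n_per_group:
            out.extend(members)
        else:
            idx = rng.choice(len(members), size=n_per_group, replace=False)
            out.extend(members[i] for i in np.sort(idx))
    return out
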