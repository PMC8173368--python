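"""Cell-cycle scoring and the quiescent/proliferative classification.

A cell's G1/S and G2/M scores are the arithmetic means of its normalized
expression over two core gene sets (43 G1/S genes, 54 G2/M genes, shipped as
package data; any GMT can be substituted).  Cells with both scores below a
threshold (default 2, on the pipeline's log2-normalized scale) are quiescent
(G1); remaining cells are proliferative and take the phase of the larger
score.
"""

from __future__ import annotations

import logging
from importlib import resources

import numpy as np
import pandas as pd

from .io import GeneSet, read_gmt

logger = logging.getLogger(__name__)

__all__ = [
    "default_cell_cycle_sets",
    "cc_scores",
    "cc_classify",
    "phase_fractions",
    "LABELS",
]

LABELS = ("G1_quiescent", "G1S", "G2M")


def default_cell_cycle_sets() -> tuple[GeneSet, GeneSet]:
    """The packaged core sets: (G1/S with 43 genes, G2/M with 54 genes)."""
    path = resources.files("stmia.data") / "cell_cycle_core.gmt"
    sets = {s.name: s for s in read_gmt(str(path))}
    return sets["G1S"], sets["G2M"]


def _set_scores(values: np.ndarray, gene_ids: list[str], gs: GeneSet) -> np.ndarray:
    index = {g: i for i, g in enumerate(gene_ids)}
    rows = [index[g] for g in sorted(gs.genes) if g in index]
    missing = len(gs.genes) - len(rows)
    if missing:
        logger.info("gene set %s: %d of %d genes absent from the matrix",
                    gs.name, missing, len(gs.genes))
    if not rows:
        raise ValueError(f"no gene of set {gs.name!r} is present in the matrix")
    return values[rows, :].mean(axis=0)


def cc_scores(nm, g1s: GeneSet, g2m: GeneSet) -> pd.DataFrame:
    """Per-unit set-average scores.

    Parameters
    ----------
    nm
        A :class:`~stmia.preprocess.NormalizedMatrix`.
    g1s, g2m
        Gene sets to average; genes absent from the matrix are dropped with a
        logged count, but each set must retain at least one gene.

    Returns
    -------
    DataFrame with columns ``unit_id, s_g1s, s_g2m``.
    """
    return pd.DataFrame(
        {
            "unit_id": nm.unit_ids,
            "s_g1s": _set_scores(nm.values, nm.gene_ids, g1s),
            "s_g2m": _set_scores(nm.values, nm.gene_ids, g2m),
        }
    )


def cc_classify(scores: pd.DataFrame, threshold: float = 2.0) -> pd.DataFrame:
    """Attach a phase label to each scored unit.

    Quiescent (``G1_quiescent``) iff both scores are strictly below
    ``threshold``; otherwise proliferative, labelled ``G2M`` when the G1/S
    score is the smaller and ``G1S`` when the G2/M score is the smaller.
    A tie between the two scores of a proliferative cell goes to ``G1S``
    (logged); the classification is total either way.
    """
    out = scores.copy()
    s1, s2 = out["s_g1s"].to_numpy(), out["s_g2m"].to_numpy()
    quiescent = (s1 < threshold) & (s2 < threshold)
    label = np.where(quiescent, "G1_quiescent", np.where(s1 < s2, "G2M", "G1S"))
    ties = (~quiescent) & (s1 == s2)
    if ties.any():
        logger.info("%d proliferative units with tied scores labelled G1S", ties.sum())
    out["label"] = label
    return out


def phase_fractions(calls: pd.DataFrame, ca=None) -> pd.DataFrame:
    """Per-cluster phase composition.

    ``calls`` is the output of :func:`cc_classify`; ``ca`` an optional
    :class:`~stmia.preprocess.ClusterAssignment` covering the same units (all
    units fall in one cluster when omitted).  Returns one row per cluster with
    the three phase fractions (summing to 1) and the proliferative fraction
    (G1S + G2M).
    """
    df = calls[["unit_id", "label"]].copy()
    if ca is None:
        df["cluster"] = 0
    else:
        mapping = dict(zip(ca.unit_ids, ca.labels))
        missing = [u for u in df["unit_id"] if u not in mapping]
        if missing:
            raise ValueError(f"{len(missing)} scored units missing from the clustering")
        df["cluster"] = [mapping[u] for u in df["unit_id"]]
    rows = []
    for cluster, sub in df.groupby("cluster", sort=True):
        n = len(sub)
        frac = {lab: (sub["label"] == lab).sum() / n for lab in LABELS}
        rows.append(
            {
                "cluster": cluster,
                "n_units": n,
                **frac,
                "proliferative": frac["G1S"] + frac["G2M"],
            }
        )
    return pd.DataFrame(rows)
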