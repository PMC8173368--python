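"""Canned planted-truth recovery experiments.

Each function runs one of the package's validation studies from scratch —
generating synthetic data, executing the relevant pipeline stages, and
scoring the result against the planted truth.  They back both the
reproducibility script and the acceptance test suite.

All randomness is controlled by the ``base_seed`` argument; per-replicate
seeds are derived deterministically from it.
"""

from __future__ import annotations

import math
from collections import Counter

import numpy as np
from scipy import stats

from .cellcycle import cc_classify, cc_scores, default_cell_cycle_sets
from .markers import bimod_lrt, find_all_markers, marker_sets
from .mia import assign_regions, mia_map, mia_pair
from .preprocess import (
    ClusterAssignment,
    QCThresholds,
    apply_qc,
    cluster_hierarchical,
    normalize,
    select_variable_genes,
)
from .simulate import SyntheticParams, generate_sc, generate_st, generate_stages
from .trends import gradual_genes

__all__ = [
    "hypergeom_enumeration_tails",
    "hypergeom_oracle_sweep",
    "bimod_null_calibration",
    "mia_recovery",
    "cellcycle_recovery",
    "trend_recovery",
]


def _replicate_seed(base_seed: int, i: int) -> int:
    return (base_seed * 1009 + i * 9973 + 1) % (2**31 - 1)


# ---------------------------------------------------------------------------
# hypergeometric tails vs exact enumeration


def hypergeom_enumeration_tails(N: int, K: int, n: int, k: int) -> tuple[float, float]:
    """Exact (P(X>=k), P(X<=k)) from integer binomial coefficients."""
    denom = math.comb(N, n)

    def pmf(j: int) -> float:
        return math.comb(K, j) * math.comb(N - K, n - j) / denom

    lo, hi = max(0, K + n - N), min(K, n)
    return (
        sum(pmf(j) for j in range(k, hi + 1)),
        sum(pmf(j) for j in range(lo, k + 1)),
    )


def hypergeom_oracle_sweep(max_n: int = 20) -> dict:
    """Compare mia_pair with exact enumeration over every (N<=max_n, K, n, k)."""
    import logging

    worst = 0.0
    cases = 0
    logging.disable(logging.WARNING)  # empty sets are expected in the sweep
    try:
        for N in range(1, max_n + 1):
            universe = [f"g{i}" for i in range(N)]
            for K in range(N + 1):
                A = set(universe[:K])
                for n in range(N + 1):
                    for k in range(max(0, K + n - N), min(K, n) + 1):
                        B = set(universe[:k]) | set(universe[K : K + n - k])
                        kk, pe, pd = mia_pair(A, B, universe)
                        oe, od = hypergeom_enumeration_tails(N, K, n, k)
                        worst = max(worst, abs(pe - oe), abs(pd - od))
                        cases += 1
                        if kk != k:
                            raise AssertionError(f"overlap mismatch at {(N, K, n, k)}")
    finally:
        logging.disable(logging.NOTSET)
    return {"max_abs_error": worst, "n_cases": cases}


# ---------------------------------------------------------------------------
# bimodal LRT null calibration


def bimod_null_calibration(
    n_replicates: int = 5000,
    n_per_group: int = 100,
    zero_prob: float = 0.5,
    mean: float = 2.0,
    sd: float = 1.0,
    base_seed: int = 0,
) -> dict:
    """Type-I behavior of the bimodal LRT under its own null model.

    Both groups are drawn from one zero-inflated (half-)normal distribution;
    reports the fraction of p-values below 0.05 and the Kolmogorov-Smirnov
    distance of the p-value sample from uniform.
    """
    rng = np.random.default_rng(base_seed)

    def draw() -> np.ndarray:
        zeros = rng.random(n_per_group) < zero_prob
        vals = np.abs(rng.normal(mean, sd, n_per_group))
        return np.where(zeros, 0.0, vals)

    pvals = np.array([bimod_lrt(draw(), draw())[1] for _ in range(n_replicates)])
    return {
        "frac_p_below_05": float((pvals < 0.05).mean()),
        "ks_distance_uniform": float(stats.kstest(pvals, "uniform").statistic),
        "n_replicates": n_replicates,
    }


# ---------------------------------------------------------------------------
# end-to-end MIA recovery


def _majority_map(ca: ClusterAssignment, planted: np.ndarray) -> dict[int, str]:
    return {
        lab: Counter(planted[ca.labels == lab]).most_common(1)[0][0]
        for lab in range(ca.k)
    }


def _process(cm, truth, k: int, n_top: int):
    nm = normalize(apply_qc(cm, QCThresholds()))
    ca = cluster_hierarchical(nm, select_variable_genes(nm, n_top), k)
    planted = truth.group_label.loc[nm.unit_ids].to_numpy()
    table = find_all_markers(nm, ca)
    prefix = "region" if cm.unit_kind == "spot" else "celltype"
    sets = marker_sets(table, name_prefix=prefix)
    return nm, ca, sets, _majority_map(ca, planted)


def mia_recovery(
    n_seeds: int = 20,
    base_seed: int = 0,
    n_groups: int = 5,
    units_per_group: int = 200,
    markers_per_group: int = 50,
    fold_change: float = 4.0,
    n_top: int = 300,
) -> dict:
    """Planted region<->cell-type correspondence recovered through the
    full pipeline (QC -> normalize -> cluster -> markers -> MIA).

    The single-cell side is generated without a cell-cycle program
    (all cells G1) so the experiment isolates the type structure it tests;
    the phase program has its own recovery experiment.
    """
    matches = regions = 0
    offdiag_ok = offdiag_total = 0
    per_seed_match = []
    for i in range(n_seeds):
        seed = _replicate_seed(base_seed, i)
        params = SyntheticParams(
            n_groups=n_groups,
            units_per_group=units_per_group,
            markers_per_group=markers_per_group,
            marker_fold_change=fold_change,
            phase_frac={"G1": 1.0, "S": 0.0, "G2M": 0.0},
            seed=seed,
        )
        st_cm, _, st_truth = generate_st(params)
        sc_cm, sc_truth = generate_sc(params)
        _, _, st_sets, st_map = _process(st_cm, st_truth, n_groups, n_top)
        sc_nm, _, sc_sets, sc_map = _process(sc_cm, sc_truth, n_groups, n_top)
        st_nm_genes = set(normalize(apply_qc(st_cm, QCThresholds())).gene_ids)
        universe = st_nm_genes & set(sc_nm.gene_ids)
        res = mia_map(list(sc_sets.values()), list(st_sets.values()), universe)
        assignment = assign_regions(res)
        seed_ok = 0
        for _, row in assignment.iterrows():
            regions += 1
            j = int(row["region"].split("_")[-1])
            if row["cell_type"] != "unassigned":
                ci = int(row["cell_type"].split("_")[-1])
                if sc_map[ci].split("_")[-1] == st_map[j].split("_")[-1]:
                    matches += 1
                    seed_ok += 1
        per_seed_match.append(seed_ok == n_groups)
        for i_ct in range(n_groups):
            for j_rg in range(n_groups):
                if sc_map[i_ct].split("_")[-1] != st_map[j_rg].split("_")[-1]:
                    offdiag_total += 1
                    offdiag_ok += res.p_enr[i_ct, j_rg] > 0.01
    return {
        "region_match_rate": matches / regions,
        "seeds_fully_matched_rate": float(np.mean(per_seed_match)),
        "offdiag_p_enr_above_01_rate": offdiag_ok / offdiag_total,
        "n_seeds": n_seeds,
    }


# ---------------------------------------------------------------------------
# cell-cycle phase recovery


def cellcycle_recovery(
    n_seeds: int = 20, base_seed: int = 0, n_cells: int = 1000
) -> dict:
    """Planted phase labels recovered by score-threshold classification."""
    g1s, g2m = default_cell_cycle_sets()
    mapping = {"G1": "G1_quiescent", "S": "G1S", "G2M": "G2M"}
    min_acc = 1.0
    max_prolif_err = 0.0
    accs = []
    for i in range(n_seeds):
        params = SyntheticParams(
            n_groups=5, units_per_group=n_cells // 5, seed=_replicate_seed(base_seed, i)
        )
        cm, truth = generate_sc(params)
        nm = normalize(apply_qc(cm, QCThresholds()))
        calls = cc_classify(cc_scores(nm, g1s, g2m))
        pred = calls.set_index("unit_id").loc[nm.unit_ids, "label"].to_numpy()
        true = np.array([mapping[p] for p in truth.phase_label.loc[nm.unit_ids]])
        for phase in ("G1_quiescent", "G1S", "G2M"):
            sel = true == phase
            acc = float((pred[sel] == phase).mean())
            accs.append(acc)
            min_acc = min(min_acc, acc)
        prolif_pred = float(np.isin(pred, ("G1S", "G2M")).mean())
        prolif_true = float(np.isin(true, ("G1S", "G2M")).mean())
        max_prolif_err = max(max_prolif_err, abs(prolif_pred - prolif_true))
    return {
        "min_per_phase_accuracy": min_acc,
        "mean_per_phase_accuracy": float(np.mean(accs)),
        "max_proliferative_fraction_error": max_prolif_err,
        "n_seeds": n_seeds,
    }


# ---------------------------------------------------------------------------
# gradual trend recovery


def trend_recovery(n_seeds: int = 20, base_seed: int = 0, n_stages: int = 3) -> dict:
    """Planted monotone genes recalled; false calls on flat genes bounded."""
    min_recall = 1.0
    max_false = 0.0
    reversal_exact = True
    for i in range(n_seeds):
        params = SyntheticParams(n_groups=n_stages, seed=_replicate_seed(base_seed, i))
        cm, truth = generate_stages(params)
        nm = normalize(apply_qc(cm, QCThresholds()))
        planted = truth.group_label.loc[nm.unit_ids].to_numpy()
        labels = np.array([int(s.split("_")[-1]) for s in planted])
        ca = ClusterAssignment(list(nm.unit_ids), labels, n_stages)
        res = gradual_genes(nm, ca)
        up = set(res[res.direction == "up"].gene)
        down = set(res[res.direction == "down"].gene)
        tu = truth.trend_up.genes & set(nm.gene_ids)
        td = truth.trend_down.genes & set(nm.gene_ids)
        flat = set(nm.gene_ids) - tu - td
        min_recall = min(min_recall, len(up & tu) / len(tu), len(down & td) / len(td))
        max_false = max(max_false, len((up | down) & flat) / len(flat))
        if i == 0:
            rev = gradual_genes(nm, ca, stage_order=list(range(n_stages))[::-1])
            reversal_exact = set(rev[rev.direction == "down"].gene) == up and (
                set(rev[rev.direction == "up"].gene) == down
            )
    return {
        "min_recall": min_recall,
        "max_false_call_rate_flat": max_false,
        "reversal_swaps_directions": reversal_exact,
        "n_seeds": n_seeds,
    }
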