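"""Planted-truth count simulators for spatial and single-cell experiments.

The generators emulate the statistical structure the downstream analysis
assumes, with every latent variable recorded:

* gene baselines are lognormal across genes, counts are negative binomial
  (gamma-Poisson) around them — the standard overdispersed model for UMI data;
* each region (spatial) or cell type (single cell) has a disjoint set of
  planted marker genes whose mean is multiplied by a known fold change inside
  the group;
* per-unit library sizes are lognormal;
* a fraction of genes are "MT-"-prefixed mitochondrial genes carrying a
  realistic share (~8%) of each unit's UMIs;
* a chosen fraction of units is degraded so quality control has something to
  remove: spots (and half of bad cells) are binomially downsampled until they
  detect fewer than 200 genes, the other half of bad cells get their
  mitochondrial share pushed above 20%;
* single cells carry a cell-cycle phase label; phase S cells express the
  packaged G1/S core set at ``cc_fold`` times baseline, phase G2/M cells the
  G2/M set, so set-average scores separate phases by construction.

Identical parameters and seed give bit-identical output.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import CountMatrix, GeneSet, POSITION_COLUMNS
from .cellcycle import default_cell_cycle_sets

__all__ = [
    "SyntheticParams",
    "SyntheticTruth",
    "generate_st",
    "generate_sc",
    "generate_stages",
]

# Scale constants of the generator (not exposed as knobs): the mitochondrial
# share of a healthy unit's UMIs, the baseline mean of a cell-cycle gene on
# the normalized linear scale, and the detected-gene / count targets used to
# build QC-failing units.
_MITO_SHARE = 0.08
_CC_BASELINE = 2.0**1.2 - 1.0  # log2(1 + baseline) == 1.2, well under score threshold 2
_LOW_QUALITY_TARGET_COUNTS = 120
_LOW_QUALITY_GENE_LIMIT = 200
_LOW_QUALITY_MITO_FRAC = 0.30


@dataclass
class SyntheticParams:
    """Knobs of the generator.

    ``n_groups`` is the number of spatial regions (``generate_st``), cell
    types (``generate_sc``) or ordered stages (``generate_stages``).
    ``nb_dispersion`` is the negative binomial size parameter r (variance
    mu + mu^2/r).  ``phase_frac`` only affects ``generate_sc``.
    """

    n_genes: int = 2000
    n_groups: int = 5
    units_per_group: int = 200
    markers_per_group: int = 50
    marker_fold_change: float = 4.0
    nb_dispersion: float = 2.0
    libsize_lognormal_mu: float = 0.0
    libsize_lognormal_sigma: float = 0.35
    mean_counts_per_unit: float = 6000.0
    mito_gene_frac: float = 0.01
    frac_low_quality: float = 0.1
    phase_frac: dict = field(
        default_factory=lambda: {"G1": 0.6, "S": 0.2, "G2M": 0.2}
    )
    cc_fold: float = 6.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0 or self.n_groups <= 0 or self.units_per_group <= 0:
            raise ValueError("n_genes, n_groups and units_per_group must be positive")
        if self.marker_fold_change <= 1:
            raise ValueError("marker_fold_change must be > 1")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if not 0 <= self.frac_low_quality < 1:
            raise ValueError("frac_low_quality must be in [0, 1)")
        if not 0 <= self.mito_gene_frac < 1:
            raise ValueError("mito_gene_frac must be in [0, 1)")
        if abs(sum(self.phase_frac.values()) - 1.0) > 1e-9:
            raise ValueError("phase_frac must sum to 1")
        if set(self.phase_frac) != {"G1", "S", "G2M"}:
            raise ValueError("phase_frac keys must be G1, S, G2M")
        n_cycle = sum(len(s) for s in default_cell_cycle_sets())
        n_mito = round(self.mito_gene_frac * self.n_genes)
        n_regular = self.n_genes - n_cycle - n_mito
        if self.markers_per_group * self.n_groups > n_regular:
            raise ValueError(
                f"markers_per_group x n_groups = "
                f"{self.markers_per_group * self.n_groups} exceeds the "
                f"{n_regular} non-mitochondrial, non-cycle genes available"
            )


@dataclass
class SyntheticTruth:
    """Everything the generator planted, for downstream recovery checks."""

    group_label: pd.Series  # unit id -> group name
    marker_sets: list[GeneSet]  # one per group, pairwise disjoint
    low_quality_flag: pd.Series  # unit id -> bool
    low_quality_route: pd.Series  # unit id -> "" | "few_genes" | "mito"
    phase_label: pd.Series | None = None  # cells only
    region_layout: dict | None = None  # ST only: group -> (row0, row1, ncols)
    trend_up: GeneSet | None = None  # stage series only
    trend_down: GeneSet | None = None

    def to_json(self, path) -> Path:
        payload = {
            "group_label": self.group_label.to_dict(),
            "marker_sets": {s.name: sorted(s.genes) for s in self.marker_sets},
            "low_quality_flag": {k: bool(v) for k, v in self.low_quality_flag.items()},
            "low_quality_route": self.low_quality_route.to_dict(),
            "phase_label": None if self.phase_label is None else self.phase_label.to_dict(),
            "region_layout": self.region_layout,
            "trend_up": None if self.trend_up is None else sorted(self.trend_up.genes),
            "trend_down": None if self.trend_down is None else sorted(self.trend_down.genes),
        }
        path = Path(path)
        path.write_text(json.dumps(payload, indent=1, sort_keys=True))
        return path


# ---------------------------------------------------------------------------
# internals


def _gene_panel(params: SyntheticParams):
    """Gene names and index blocks: regular | cycle | mito."""
    g1s, g2m = default_cell_cycle_sets()
    cycle_genes = sorted(g1s.genes) + sorted(g2m.genes)
    n_mito = round(params.mito_gene_frac * params.n_genes)
    n_regular = params.n_genes - len(cycle_genes) - n_mito
    regular = [f"GENE{i:05d}" for i in range(n_regular)]
    mito = [f"MT-SIM{i:03d}" for i in range(n_mito)]
    names = regular + cycle_genes + mito
    blocks = {
        "regular": np.arange(n_regular),
        "g1s": n_regular + np.arange(len(g1s.genes)),
        "g2m": n_regular + len(g1s.genes) + np.arange(len(g2m.genes)),
        "mito": n_regular + len(cycle_genes) + np.arange(n_mito),
    }
    return names, blocks


def _baselines(rng: np.random.Generator, params: SyntheticParams, blocks) -> np.ndarray:
    """Per-gene expected counts in an average unit, summing to the target total."""
    lam = np.zeros(params.n_genes)
    n_reg = blocks["regular"].size
    n_mito = blocks["mito"].size
    n_cycle = blocks["g1s"].size + blocks["g2m"].size
    lam_reg = rng.lognormal(mean=0.0, sigma=1.0, size=n_reg)
    lam_mito = rng.lognormal(mean=0.0, sigma=1.0, size=n_mito)
    cycle_total = n_cycle * _CC_BASELINE
    mito_total = _MITO_SHARE * params.mean_counts_per_unit if n_mito else 0.0
    reg_total = params.mean_counts_per_unit - cycle_total - mito_total
    if reg_total <= 0:
        raise ValueError("mean_counts_per_unit too small for the gene panel")
    lam[blocks["regular"]] = lam_reg * (reg_total / lam_reg.sum())
    if n_mito:
        lam[blocks["mito"]] = lam_mito * (mito_total / lam_mito.sum())
    lam[blocks["g1s"]] = _CC_BASELINE
    lam[blocks["g2m"]] = _CC_BASELINE
    return lam


def _nb_counts(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float
) -> np.ndarray:
    """Gamma-Poisson draw with per-entry means."""
    shape = dispersion
    lam = rng.gamma(shape, mean / shape)
    return rng.poisson(lam).astype(np.int64)


def _thin_below_gene_limit(rng: np.random.Generator, col: np.ndarray) -> np.ndarray:
    """Binomially downsample a unit's counts until it detects <200 genes.

    Thinning (rather than redrawing) preserves the gene rank structure of the
    unit, which is what degraded-but-real libraries look like.
    """
    total = col.sum()
    if total > _LOW_QUALITY_TARGET_COUNTS:
        col = rng.binomial(col, _LOW_QUALITY_TARGET_COUNTS / total)
    while (col > 0).sum() >= _LOW_QUALITY_GENE_LIMIT:
        col = rng.binomial(col, 0.5)
    return col


def _allocate(n: int, fracs: list[float]) -> list[int]:
    """Largest-remainder integer allocation of n units to fractions."""
    raw = [f * n for f in fracs]
    base = [math.floor(r) for r in raw]
    short = n - sum(base)
    order = np.argsort([b - r for b, r in zip(base, raw)])  # largest remainder first
    for i in order[:short]:
        base[i] += 1
    return base


def _group_counts(
    rng: np.random.Generator,
    params: SyntheticParams,
    lam: np.ndarray,
    fold: np.ndarray,  # genes x groups multiplicative effects
    group_of_unit: np.ndarray,
    extra_unit_fold: np.ndarray | None = None,  # genes x units (cell-cycle effects)
) -> np.ndarray:
    n_units = group_of_unit.size
    libsize = rng.lognormal(
        params.libsize_lognormal_mu, params.libsize_lognormal_sigma, size=n_units
    )
    mean = lam[:, None] * fold[:, group_of_unit] * libsize[None, :]
    if extra_unit_fold is not None:
        mean = mean * extra_unit_fold
    return _nb_counts(rng, mean, params.nb_dispersion)


def _marker_assignment(params: SyntheticParams, names, blocks, prefix: str):
    """Disjoint marker slices from the regular-gene block, plus the fold matrix."""
    m = params.markers_per_group
    fold = np.ones((params.n_genes, params.n_groups))
    marker_sets = []
    for g in range(params.n_groups):
        idx = blocks["regular"][g * m : (g + 1) * m]
        fold[idx, g] = params.marker_fold_change
        marker_sets.append(
            GeneSet(
                name=f"{prefix}_{g}",
                description=f"planted markers of {prefix}_{g}",
                genes=frozenset(names[i] for i in idx),
            )
        )
    return fold, marker_sets


def _pick_low_quality(
    rng: np.random.Generator, n_units: int, frac: float
) -> np.ndarray:
    n_lq = round(frac * n_units)
    return np.sort(rng.choice(n_units, size=n_lq, replace=False))


# ---------------------------------------------------------------------------
# public generators


def generate_st(params: SyntheticParams):
    """Synthetic spatial experiment.

    Returns ``(CountMatrix, positions, SyntheticTruth)``.  Spots sit on a
    rectangular array split into ``n_groups`` contiguous row blocks (the
    planted "regions"); each region's markers are ``marker_fold_change`` times
    their baseline inside the region.  ``frac_low_quality`` of spots are
    downsampled below 200 detected genes.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    names, blocks = _gene_panel(params)
    lam = _baselines(rng, params, blocks)
    fold, marker_sets = _marker_assignment(params, names, blocks, "region")

    n_units = params.n_groups * params.units_per_group
    group_of_unit = np.repeat(np.arange(params.n_groups), params.units_per_group)

    # deterministic row-major layout: each region is a block of array rows
    ncols = math.ceil(math.sqrt(n_units))
    rows_per_region = math.ceil(params.units_per_group / ncols)
    array_row = np.empty(n_units, dtype=np.int64)
    array_col = np.empty(n_units, dtype=np.int64)
    layout = {}
    for g in range(params.n_groups):
        base_row = g * rows_per_region
        within = np.arange(params.units_per_group)
        sel = group_of_unit == g
        array_row[sel] = base_row + within // ncols
        array_col[sel] = within % ncols
        layout[f"region_{g}"] = (int(base_row), int(base_row + rows_per_region), int(ncols))

    counts = _group_counts(rng, params, lam, fold, group_of_unit)
    lq = _pick_low_quality(rng, n_units, params.frac_low_quality)
    for u in lq:
        counts[:, u] = _thin_below_gene_limit(rng, counts[:, u])

    unit_ids = [f"SPOT{u:05d}-1" for u in range(n_units)]
    cm = CountMatrix(names, unit_ids, counts, unit_kind="spot")
    positions = pd.DataFrame(
        {
            "barcode": unit_ids,
            "in_tissue": 1,
            "array_row": array_row,
            "array_col": array_col,
            "pixel_row": array_row * 200.0,
            "pixel_col": array_col * 200.0,
        },
        columns=POSITION_COLUMNS,
    )
    flag = np.zeros(n_units, dtype=bool)
    flag[lq] = True
    route = np.where(flag, "few_genes", "")
    truth = SyntheticTruth(
        group_label=pd.Series(
            [f"region_{g}" for g in group_of_unit], index=unit_ids, name="region"
        ),
        marker_sets=marker_sets,
        low_quality_flag=pd.Series(flag, index=unit_ids),
        low_quality_route=pd.Series(route, index=unit_ids),
        region_layout=layout,
    )
    return cm, positions, truth


def generate_sc(params: SyntheticParams):
    """Synthetic single-cell experiment with planted cell types and phases.

    Marker genes match ``generate_st`` run with the same parameters: cell
    type ``celltype_g`` shares its marker genes with region ``region_g``, which
    is what multimodal intersection analysis is meant to recover.

    Cells are assigned G1 / S / G2M labels per ``phase_frac``; S cells express
    the packaged G1/S core set at ``cc_fold`` times baseline, G2M cells the
    G2/M set.  Low-quality cells split half/half between mitochondrial
    overload (>20% MT UMIs) and low library complexity (<200 detected genes).
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    names, blocks = _gene_panel(params)
    lam = _baselines(rng, params, blocks)
    fold, marker_sets = _marker_assignment(params, names, blocks, "celltype")

    n_units = params.n_groups * params.units_per_group
    group_of_unit = np.repeat(np.arange(params.n_groups), params.units_per_group)

    # phase labels: fixed counts per phase, shuffled across cells
    phases = ["G1", "S", "G2M"]
    alloc = _allocate(n_units, [params.phase_frac[p] for p in phases])
    phase_of_unit = np.repeat(np.arange(3), alloc)
    phase_of_unit = phase_of_unit[rng.permutation(n_units)]

    cc_fold = np.ones((params.n_genes, n_units))
    cc_fold[np.ix_(blocks["g1s"], np.flatnonzero(phase_of_unit == 1))] = params.cc_fold
    cc_fold[np.ix_(blocks["g2m"], np.flatnonzero(phase_of_unit == 2))] = params.cc_fold

    counts = _group_counts(rng, params, lam, fold, group_of_unit, extra_unit_fold=cc_fold)

    lq = _pick_low_quality(rng, n_units, params.frac_low_quality)
    n_mito_route = len(lq) // 2
    route = np.full(n_units, "", dtype=object)
    mito_rows = blocks["mito"]
    for i, u in enumerate(lq):
        if i < n_mito_route and mito_rows.size:
            # push the mitochondrial share above 20% by inflating one MT gene
            rest = counts[:, u].sum() - counts[mito_rows, u].sum()
            target = math.ceil(
                _LOW_QUALITY_MITO_FRAC / (1 - _LOW_QUALITY_MITO_FRAC) * rest
            )
            deficit = target - counts[mito_rows, u].sum()
            if deficit > 0:
                counts[mito_rows[0], u] += deficit
            route[u] = "mito"
        else:
            counts[:, u] = _thin_below_gene_limit(rng, counts[:, u])
            route[u] = "few_genes"

    unit_ids = [f"CELL{u:05d}-1" for u in range(n_units)]
    cm = CountMatrix(names, unit_ids, counts, unit_kind="cell")
    flag = np.zeros(n_units, dtype=bool)
    flag[lq] = True
    truth = SyntheticTruth(
        group_label=pd.Series(
            [f"celltype_{g}" for g in group_of_unit], index=unit_ids, name="celltype"
        ),
        marker_sets=marker_sets,
        low_quality_flag=pd.Series(flag, index=unit_ids),
        low_quality_route=pd.Series(route, index=unit_ids),
        phase_label=pd.Series([phases[p] for p in phase_of_unit], index=unit_ids),
    )
    return cm, truth


def generate_stages(params: SyntheticParams):
    """Synthetic ordered-stage series with planted monotone genes.

    ``n_groups`` ordered stages (``stage_0 < stage_1 < ...``);
    ``markers_per_group`` genes drift geometrically *up* from baseline to
    ``marker_fold_change`` x baseline across the stage order, the same number
    drift *down*; every other gene is flat.  Used to exercise gradual
    up-/down-regulation calling.
    """
    params.validate()
    if params.n_groups < 2:
        raise ValueError("a stage series needs at least 2 stages")
    rng = np.random.default_rng(params.seed)
    names, blocks = _gene_panel(params)
    lam = _baselines(rng, params, blocks)

    m = params.markers_per_group
    up_idx = blocks["regular"][:m]
    down_idx = blocks["regular"][m : 2 * m]
    S = params.n_groups
    profile = params.marker_fold_change ** (np.arange(S) / (S - 1))
    fold = np.ones((params.n_genes, S))
    fold[up_idx, :] = profile[None, :]
    fold[down_idx, :] = profile[::-1][None, :]

    n_units = S * params.units_per_group
    group_of_unit = np.repeat(np.arange(S), params.units_per_group)
    counts = _group_counts(rng, params, lam, fold, group_of_unit)

    lq = _pick_low_quality(rng, n_units, params.frac_low_quality)
    for u in lq:
        counts[:, u] = _thin_below_gene_limit(rng, counts[:, u])

    unit_ids = [f"UNIT{u:05d}-1" for u in range(n_units)]
    cm = CountMatrix(names, unit_ids, counts, unit_kind="spot")
    flag = np.zeros(n_units, dtype=bool)
    flag[lq] = True
    truth = SyntheticTruth(
        group_label=pd.Series(
            [f"stage_{g}" for g in group_of_unit], index=unit_ids, name="stage"
        ),
        marker_sets=[],
        low_quality_flag=pd.Series(flag, index=unit_ids),
        low_quality_route=pd.Series(np.where(flag, "few_genes", ""), index=unit_ids),
        trend_up=GeneSet("trend_up", "planted monotone up", frozenset(names[i] for i in up_idx)),
        trend_down=GeneSet(
            "trend_down", "planted monotone down", frozenset(names[i] for i in down_idx)
        ),
    )
    return cm, truth
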