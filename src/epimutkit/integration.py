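"""Cross-layer analyses linking methylation, annotation and expression.

Covers: inherent cell-type differential methylation from control
methylomes (one-way ANOVA on M-values across cell types), the partition
of exposure DMCs into inherently-variable vs core sites, counting DEGs
whose promoter or gene body hosts a DMC, nearest-promoter distances for
DMC sets, and the rank correlation between median promoter distance and
DEG count across cell types.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .intervals import AnnotationTrack, GeneAnnotation
from .methylation import BetaMatrix, mvalues

__all__ = [
    "PartitionResult",
    "ProximityResult",
    "DmcDegCounts",
    "inherent_celltype_dmcs",
    "partition_exposure_dmcs",
    "dmcs_in_degs",
    "promoter_proximity",
    "proximity_deg_correlation",
]


@dataclass
class PartitionResult:
    cell_type: str
    n_exposure: int
    n_inherent: int
    overlap: int
    fraction_overlapping: float
    core: set  # exposure DMCs outside the inherent set


@dataclass
class ProximityResult:
    """Nearest-promoter distances for one cell type's DMC set."""

    cell_type: str
    distances: np.ndarray  # bp, >= 0; nan when the chromosome has no promoter
    median_distance: float
    n_missing: int
    n_degs: int | None = None


@dataclass
class DmcDegCounts:
    n_degs: int
    promoter: int  # DEGs with >= 1 promoter DMC
    gene_body: int  # DEGs with >= 1 gene-body DMC (not mutually exclusive)
    unresolved: list[str] = field(default_factory=list)

    def fractions(self, denominator: int | None = None) -> dict[str, float]:
        d = self.n_degs if denominator is None else denominator
        if d <= 0:
            raise ValueError("denominator must be positive")
        return {"promoter": self.promoter / d, "gene_body": self.gene_body / d}


def anova_f(groups: Sequence[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise one-way ANOVA across >= 2 groups of replicate columns.

    Computed from the between/within sum-of-squares decomposition (an
    independent route from scipy's f_oneway, which tests use as an
    oracle).  Rows with zero within-group variance get p = 1 when group
    means agree and p = 0 otherwise.
    """
    k = len(groups)
    if k < 2:
        raise ValueError("need >= 2 groups")
    ns = np.array([g.shape[1] for g in groups])
    if np.any(ns < 2):
        raise ValueError("need >= 2 replicates per group")
    N = int(ns.sum())
    means = np.column_stack([g.mean(axis=1) for g in groups])
    grand = np.column_stack(groups).mean(axis=1)
    ssb = (ns * (means - grand[:, None]) ** 2).sum(axis=1)
    ssw = np.zeros_like(grand)
    for g, m in zip(groups, means.T):
        ssw += ((g - m[:, None]) ** 2).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ssb / (k - 1)) / (ssw / (N - k))
    p = np.ones_like(grand)
    ok = ssw > 0
    p[ok] = stats.f.sf(f[ok], k - 1, N - k)
    p[~ok & (ssb > 0)] = 0.0
    f[~ok] = 0.0
    return f, p


def inherent_celltype_dmcs(
    control_betas: Mapping[str, BetaMatrix],
    alpha: float = 0.05,
    eps: float = 0.01,
) -> set[tuple[str, int]]:
    """CpGs with inherent cell-type differential methylation.

    One-way ANOVA on control-arm M-values across the given cell types,
    BH-adjusted; returns the CpG coordinates with FDR <= alpha.  All
    matrices must share one CpG universe.
    """
    if len(control_betas) < 2:
        raise ValueError("need >= 2 cell types")
    names = sorted(control_betas)
    first = control_betas[names[0]]
    coords = first.coords()
    for name in names[1:]:
        if control_betas[name].coords() != coords:
            raise ValueError("cell types have mismatched CpG universes")
    groups = []
    for name in names:
        bm = control_betas[name]
        g = bm.arm_values("control")
        if g.shape[1] < 2:
            raise ValueError(f"{name}: need >= 2 control replicates")
        groups.append(mvalues(g, eps))
    _, p = anova_f(groups)
    fdr = multipletests(p, method="fdr_bh")[1]
    keep = fdr <= alpha
    return {coords[i] for i in np.where(keep)[0]}


def partition_exposure_dmcs(
    exposure_dmcs: Iterable[tuple[str, int]],
    inherent_set: Iterable[tuple[str, int]],
    cell_type: str = "",
) -> PartitionResult:
    """Split exposure DMCs into inherently-variable vs core sites."""
    exposure = set(exposure_dmcs)
    inherent = set(inherent_set)
    if not exposure:
        raise ValueError("empty exposure DMC set")
    overlap = exposure & inherent
    return PartitionResult(
        cell_type=cell_type,
        n_exposure=len(exposure),
        n_inherent=len(inherent),
        overlap=len(overlap),
        fraction_overlapping=len(overlap) / len(exposure),
        core=exposure - inherent,
    )


def dmcs_in_degs(
    dmcs: Iterable[tuple[str, int]],
    degs: Iterable[str],
    gene_model: Mapping[str, GeneAnnotation],
) -> DmcDegCounts:
    """Count DEGs carrying >= 1 DMC in their promoter / gene body.

    Categories overlap (a DEG may count in both); each DEG counts at most
    once per category regardless of how many DMCs it hosts.  DEGs missing
    from the gene model go to ``unresolved`` rather than being dropped
    silently.
    """
    dmc_by_chrom: dict[str, np.ndarray] = {}
    tmp: dict[str, list[int]] = {}
    for chrom, pos in dmcs:
        tmp.setdefault(chrom, []).append(pos)
    dmc_by_chrom = {c: np.sort(np.asarray(v, dtype=np.int64)) for c, v in tmp.items()}

    def has_dmc(chrom: str, iv: tuple[int, int]) -> bool:
        arr = dmc_by_chrom.get(chrom)
        if arr is None:
            return False
        lo = np.searchsorted(arr, iv[0], side="left")
        hi = np.searchsorted(arr, iv[1], side="left")
        return hi > lo

    deg_list = list(degs)
    n_prom = n_body = 0
    unresolved: list[str] = []
    for g in deg_list:
        ann = gene_model.get(g)
        if ann is None:
            unresolved.append(g)
            continue
        if has_dmc(ann.chrom, ann.promoter):
            n_prom += 1
        if has_dmc(ann.chrom, ann.body):
            n_body += 1
    return DmcDegCounts(len(deg_list), n_prom, n_body, unresolved)


def promoter_proximity(
    dmcs: Sequence[tuple[str, int]],
    promoter_track: AnnotationTrack,
    cell_type: str = "",
    n_degs: int | None = None,
) -> ProximityResult:
    """Distance from each DMC to the nearest promoter.

    0 inside a promoter; otherwise the bp gap to the nearest covered
    base.  DMCs on chromosomes without promoters get nan, are excluded
    from the median, and are tallied in ``n_missing``.
    """
    if promoter_track.n_intervals() == 0:
        raise ValueError("promoter track is empty")
    by_chrom: dict[str, list[int]] = {}
    order: list[tuple[str, int]] = []
    for i, (chrom, pos) in enumerate(dmcs):
        by_chrom.setdefault(chrom, []).append(i)
        order.append((chrom, pos))
    dist = np.full(len(order), np.nan)
    for chrom, idx in by_chrom.items():
        pos = np.asarray([order[i][1] for i in idx], dtype=np.int64)
        dist[np.asarray(idx)] = promoter_track.nearest_distance(chrom, pos)
    n_missing = int(np.isnan(dist).sum())
    finite = dist[~np.isnan(dist)]
    median = float(np.median(finite)) if len(finite) else float("nan")
    return ProximityResult(cell_type, dist, median, n_missing, n_degs)


def proximity_deg_correlation(
    results: Sequence[ProximityResult],
) -> tuple[float | None, float | None]:
    """Spearman rank correlation of median promoter distance vs DEG count.

    Across cell types (>= 3 required).  Returns (rho, p); (None, None)
    when either variable is constant and ranks are undefined.
    """
    if len(results) < 3:
        raise ValueError("need >= 3 cell types for a correlation")
    med = np.array([r.median_distance for r in results], dtype=float)
    degs = np.array([r.n_degs for r in results], dtype=float)
    if np.any(np.isnan(med)) or np.any(np.isnan(degs)):
        raise ValueError("all cell types need a median distance and a DEG count")
    if np.ptp(med) == 0 or np.ptp(degs) == 0:
        return None, None
    rho, p = stats.spearmanr(med, degs)
    return float(rho), float(p)
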