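"""Differential methylation calling.

Single-CpG calls (DMCs) are made either from array-style beta values
(per-CpG Welch test on M-values) or from sequencing-style
methylated/coverage counts (pooled two-proportion z-test).  Region calls
(DMRs) cluster CpGs along the genome and aggregate per-CpG p-values with
Stouffer's method.  Significance everywhere uses the dual rule: raw
p <= alpha AND Benjamini-Hochberg FDR <= alpha.

Beta values are methylation fractions in [0, 1]; testing happens on the
M-value (logit) scale where the statistic is far better behaved near the
0/1 boundaries, while effect sizes are reported on the beta scale.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "BetaMatrix",
    "MethylCountMatrix",
    "DMCRecord",
    "DMRRecord",
    "CountDMCResult",
    "mvalues",
    "welch_test",
    "dmc_test_table",
    "call_dmcs_array",
    "call_dmcs_counts",
    "classify_direction",
    "direction_counts",
    "call_dmrs",
    "overlap_sets",
]

ARMS = ("control", "treated")


def _check_sorted(chrom: np.ndarray, pos: np.ndarray) -> None:
    """Require chromosome-grouped input with strictly increasing positions."""
    seen: set[str] = set()
    last_chrom = None
    last_pos = -1
    for c, p in zip(chrom, pos):
        if c != last_chrom:
            if c in seen:
                raise ValueError(f"coordinates not grouped by chromosome: {c!r} recurs")
            seen.add(c)
            last_chrom, last_pos = c, -1
        if p <= last_pos:
            raise ValueError(f"positions not strictly increasing on {c!r} at {p}")
        last_pos = p


@dataclass
class BetaMatrix:
    """CpG x sample methylation fractions with treated/control arm labels."""

    chrom: np.ndarray
    pos: np.ndarray
    samples: list[str]
    arm: list[str]
    values: np.ndarray  # (n_cpg, n_samples), beta in [0, 1]

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.pos), len(self.samples)):
            raise ValueError("values shape does not match coordinates/samples")
        if len(self.arm) != len(self.samples):
            raise ValueError("one arm label per sample required")
        bad = set(self.arm) - set(ARMS)
        if bad:
            raise ValueError(f"unknown arm labels: {sorted(bad)}")
        if np.any((self.values < 0) | (self.values > 1)):
            raise ValueError("beta values must lie in [0, 1]")
        _check_sorted(self.chrom, self.pos)

    @property
    def n_cpgs(self) -> int:
        return len(self.pos)

    @property
    def cpg_ids(self) -> list[str]:
        return [f"{c}:{p}" for c, p in zip(self.chrom, self.pos)]

    def arm_values(self, arm: str) -> np.ndarray:
        cols = [i for i, a in enumerate(self.arm) if a == arm]
        return self.values[:, cols]

    def coords(self) -> list[tuple[str, int]]:
        return [(str(c), int(p)) for c, p in zip(self.chrom, self.pos)]


@dataclass
class MethylCountMatrix:
    """CpG x sample methylated / total read counts."""

    chrom: np.ndarray
    pos: np.ndarray
    samples: list[str]
    arm: list[str]
    meth: np.ndarray  # (n_cpg, n_samples) int
    coverage: np.ndarray

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.meth = np.asarray(self.meth, dtype=np.int64)
        self.coverage = np.asarray(self.coverage, dtype=np.int64)
        if self.meth.shape != self.coverage.shape:
            raise ValueError("meth and coverage shapes differ")
        if self.meth.shape != (len(self.pos), len(self.samples)):
            raise ValueError("count shape does not match coordinates/samples")
        if np.any(self.meth < 0) or np.any(self.coverage < 0):
            raise ValueError("counts must be non-negative")
        if np.any(self.meth > self.coverage):
            raise ValueError("methylated count exceeds coverage")
        _check_sorted(self.chrom, self.pos)


@dataclass(frozen=True)
class DMCRecord:
    cpg_id: str
    chrom: str
    pos: int
    mean_beta_control: float
    mean_beta_treated: float
    delta_beta: float
    p_value: float
    fdr: float
    direction: str  # 'hypo' | 'hyper'


@dataclass(frozen=True)
class DMRRecord:
    chrom: str
    start: int
    end: int
    cpg_ids: tuple[str, ...]
    n_cpgs: int
    p_value: float
    mean_delta_beta: float


@dataclass
class CountDMCResult:
    records: list[DMCRecord]
    n_tested: int
    n_filtered: int  # CpGs excluded by the coverage floor


def mvalues(beta: np.ndarray, eps: float = 0.01) -> np.ndarray:
    """Logit transform with boundary offset: log2((b + eps) / (1 - b + eps))."""
    beta = np.asarray(beta, dtype=float)
    return np.log2((beta + eps) / (1.0 - beta + eps))


def welch_test(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Welch two-sample t-test.

    Returns (t, p).  Rows with zero variance in both groups get p = 1 when
    the means agree and p = 0 when they differ (an infinite-t degeneracy).
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    nx, ny = x.shape[1], y.shape[1]
    if nx < 2 or ny < 2:
        raise ValueError("Welch test needs >=2 replicates per arm")
    mx, my = x.mean(axis=1), y.mean(axis=1)
    vx, vy = x.var(axis=1, ddof=1), y.var(axis=1, ddof=1)
    se2 = vx / nx + vy / ny
    diff = mx - my
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(se2)
        df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = np.ones_like(diff)
    ok = se2 > 0
    p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), df[ok])
    degenerate = ~ok & (diff != 0)
    p[degenerate] = 0.0
    t[~ok] = 0.0
    return t, p


def classify_direction(mean_beta_control: float, mean_beta_treated: float) -> str:
    """hypo when treated < control, hyper when treated > control."""
    if not (0 <= mean_beta_control <= 1 and 0 <= mean_beta_treated <= 1):
        raise ValueError("mean beta values must lie in [0, 1]")
    delta = mean_beta_treated - mean_beta_control
    if delta == 0:
        raise ValueError("zero delta-beta has no direction; caller must not emit it")
    return "hypo" if delta < 0 else "hyper"


def direction_counts(directions: Iterable[str]) -> tuple[int, int, int]:
    """(n_hypo, n_hyper, total) tally; total is always the exact sum."""
    n_hypo = n_hyper = 0
    for d in directions:
        if d == "hypo":
            n_hypo += 1
        elif d == "hyper":
            n_hyper += 1
        else:
            raise ValueError(f"unknown direction {d!r}")
    return n_hypo, n_hyper, n_hypo + n_hyper


def dmc_test_table(
    betas: BetaMatrix,
    design: Mapping[str, str] | None = None,
    eps: float = 0.01,
) -> pd.DataFrame:
    """Per-CpG Welch test of treated vs control on M-values.

    Returns the full test table (every CpG, no thresholding) with
    beta-scale means/deltas, raw p and BH FDR — the substrate both for DMC
    emission and for DMR aggregation.
    """
    arm = list(betas.arm) if design is None else [design[s] for s in betas.samples]
    t_cols = [i for i, a in enumerate(arm) if a == "treated"]
    c_cols = [i for i, a in enumerate(arm) if a == "control"]
    if len(t_cols) < 2 or len(c_cols) < 2:
        raise ValueError("need >=2 samples in each of the treated and control arms")
    m = mvalues(betas.values, eps)
    _, p = welch_test(m[:, t_cols], m[:, c_cols])
    mean_c = betas.values[:, c_cols].mean(axis=1)
    mean_t = betas.values[:, t_cols].mean(axis=1)
    fdr = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "cpg_id": betas.cpg_ids,
            "chrom": betas.chrom,
            "pos": betas.pos,
            "mean_beta_control": mean_c,
            "mean_beta_treated": mean_t,
            "delta_beta": mean_t - mean_c,
            "p_value": p,
            "fdr": fdr,
        }
    )


def _emit_records(table: pd.DataFrame, alpha: float) -> list[DMCRecord]:
    sig = table[
        (table["p_value"] <= alpha)
        & (table["fdr"] <= alpha)
        & (table["delta_beta"] != 0)
    ]
    return [
        DMCRecord(
            cpg_id=row.cpg_id,
            chrom=str(row.chrom),
            pos=int(row.pos),
            mean_beta_control=float(row.mean_beta_control),
            mean_beta_treated=float(row.mean_beta_treated),
            delta_beta=float(row.delta_beta),
            p_value=float(row.p_value),
            fdr=float(row.fdr),
            direction=classify_direction(row.mean_beta_control, row.mean_beta_treated),
        )
        for row in sig.itertuples(index=False)
    ]


def call_dmcs_array(
    betas: BetaMatrix,
    design: Mapping[str, str] | None = None,
    alpha: float = 0.05,
    eps: float = 0.01,
) -> list[DMCRecord]:
    """Call DMCs from a beta matrix (dual p/FDR <= alpha rule)."""
    return _emit_records(dmc_test_table(betas, design, eps), alpha)


def call_dmcs_counts(
    counts: MethylCountMatrix,
    design: Mapping[str, str] | None = None,
    alpha: float = 0.05,
    min_coverage: int = 10,
) -> CountDMCResult:
    """Call DMCs from methylated/coverage counts.

    Reads are pooled within each arm per CpG and the pooled fractions are
    compared with a two-proportion z-test (Haldane +0.5 correction whenever
    a 2x2 cell is zero).  CpGs whose pooled coverage in either arm falls
    below ``min_coverage`` are excluded and tallied, not tested.
    """
    arm = list(counts.arm) if design is None else [design[s] for s in counts.samples]
    t_cols = [i for i, a in enumerate(arm) if a == "treated"]
    c_cols = [i for i, a in enumerate(arm) if a == "control"]
    if len(t_cols) < 2 or len(c_cols) < 2:
        raise ValueError("need >=2 samples in each of the treated and control arms")
    mt = counts.meth[:, t_cols].sum(axis=1).astype(float)
    nt = counts.coverage[:, t_cols].sum(axis=1).astype(float)
    mc = counts.meth[:, c_cols].sum(axis=1).astype(float)
    nc = counts.coverage[:, c_cols].sum(axis=1).astype(float)

    keep = (nt >= min_coverage) & (nc >= min_coverage)
    n_filtered = int((~keep).sum())
    if not keep.any():
        return CountDMCResult([], 0, n_filtered)

    mt, nt, mc, nc = mt[keep], nt[keep], mc[keep], nc[keep]
    # Haldane correction where any cell of the pooled 2x2 table is zero
    zero_cell = (mt == 0) | (mc == 0) | (mt == nt) | (mc == nc)
    mt = np.where(zero_cell, mt + 0.5, mt)
    mc = np.where(zero_cell, mc + 0.5, mc)
    nt = np.where(zero_cell, nt + 1.0, nt)
    nc = np.where(zero_cell, nc + 1.0, nc)
    pt, pc = mt / nt, mc / nc
    pool = (mt + mc) / (nt + nc)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(pool * (1.0 - pool) * (1.0 / nt + 1.0 / nc))
        z = (pt - pc) / se
    p = np.where(se > 0, 2.0 * stats.norm.sf(np.abs(z)), 1.0)
    fdr = multipletests(p, method="fdr_bh")[1]
    table = pd.DataFrame(
        {
            "cpg_id": np.asarray(
                [f"{c}:{q}" for c, q in zip(counts.chrom[keep], counts.pos[keep])],
                dtype=object,
            ),
            "chrom": counts.chrom[keep],
            "pos": counts.pos[keep],
            "mean_beta_control": pc,
            "mean_beta_treated": pt,
            "delta_beta": pt - pc,
            "p_value": p,
            "fdr": fdr,
        }
    )
    return CountDMCResult(_emit_records(table, alpha), int(keep.sum()), n_filtered)


def stouffer_combine(p: np.ndarray) -> float:
    """Unweighted Stouffer combination of one-sided-equivalent p-values."""
    p = np.clip(np.asarray(p, dtype=float), 1e-300, 1.0)
    z = stats.norm.isf(p)
    return float(stats.norm.sf(z.sum() / np.sqrt(len(z))))


def call_dmrs(
    table: pd.DataFrame,
    max_gap: int = 1000,
    min_cpgs: int = 2,
    alpha: float = 0.05,
) -> list[DMRRecord]:
    """Cluster tested CpGs into regions and aggregate their p-values.

    Single-linkage clustering on the 1-D genomic coordinate: adjacent CpGs
    on the same chromosome join one cluster while their gap is <= max_gap.
    Member p-values are combined by Stouffer's method; clusters pass with
    combined p <= alpha and >= min_cpgs members.  The input must be the
    full per-CpG test table, sorted; unsorted input is an error, never
    silently reordered.
    """
    if max_gap <= 0:
        raise ValueError("max_gap must be positive")
    if min_cpgs < 2:
        raise ValueError("min_cpgs must be >= 2")
    chrom = np.asarray(table["chrom"], dtype=object)
    pos = np.asarray(table["pos"], dtype=np.int64)
    _check_sorted(chrom, pos)
    pvals = np.asarray(table["p_value"], dtype=float)
    delta = (
        np.asarray(table["delta_beta"], dtype=float)
        if "delta_beta" in table
        else np.full(len(pos), np.nan)
    )
    ids = (
        np.asarray(table["cpg_id"], dtype=object)
        if "cpg_id" in table
        else np.asarray([f"{c}:{p}" for c, p in zip(chrom, pos)], dtype=object)
    )

    if len(pos) == 0:
        return []
    new_cluster = np.ones(len(pos), dtype=bool)
    same = (chrom[1:] == chrom[:-1]) & (pos[1:] - pos[:-1] <= max_gap)
    new_cluster[1:] = ~same
    labels = np.cumsum(new_cluster) - 1

    records: list[DMRRecord] = []
    for lab in range(labels[-1] + 1):
        idx = np.where(labels == lab)[0]
        if len(idx) < min_cpgs:
            continue
        p_comb = stouffer_combine(pvals[idx])
        if p_comb <= alpha:
            records.append(
                DMRRecord(
                    chrom=str(chrom[idx[0]]),
                    start=int(pos[idx[0]]),
                    end=int(pos[idx[-1]]) + 1,
                    cpg_ids=tuple(ids[idx]),
                    n_cpgs=len(idx),
                    p_value=p_comb,
                    mean_delta_beta=float(np.nanmean(delta[idx])),
                )
            )
    return records


def overlap_sets(site_sets: Mapping[str, Iterable]) -> dict:
    """Exact Venn cell counts and pairwise Jaccard for named site sets.

    Venn cells are keyed by the sorted '&'-joined names of the sets a
    member belongs to (exclusive cells); singleton keys count elements
    private to that set.
    """
    names = sorted(site_sets)
    if len(names) < 2:
        raise ValueError("need at least two sets")
    sets = {n: set(site_sets[n]) for n in names}
    universe = set().union(*sets.values())
    venn: dict[str, int] = {}
    for member in universe:
        sig = "&".join(n for n in names if member in sets[n])
        venn[sig] = venn.get(sig, 0) + 1
    jaccard: dict[str, dict[str, float]] = {n: {} for n in names}
    for a, b in itertools.combinations(names, 2):
        union = len(sets[a] | sets[b])
        j = len(sets[a] & sets[b]) / union if union else float("nan")
        jaccard[a][b] = j
        jaccard[b][a] = j
    return {"sizes": {n: len(sets[n]) for n in names}, "venn": venn, "jaccard": jaccard}
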