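"""TMM-normalized differential expression calling.

The between-sample normalization is the trimmed mean of M-values (TMM):
for each sample against a reference, gene-wise log2 ratios (M) are
trimmed by 30% at both tails and by 5% at both tails of the average log
abundance (A), then averaged with inverse-variance (delta-method
binomial) weights; factors are rescaled to geometric mean 1.

The per-gene test is a negative-binomial Wald test on the log2 fold
change of TMM-normalized group means, with a method-of-moments tagwise
dispersion shrunk toward the common dispersion.  A gene is emitted only
when both the raw p-value and the Benjamini-Hochberg FDR are <= alpha.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CountMatrix",
    "DEGRecord",
    "tmm_factors",
    "cpm",
    "call_degs",
    "deg_direction_counts",
]


@dataclass
class CountMatrix:
    """Gene x sample non-negative integer read counts with arm labels."""

    genes: list[str]
    samples: list[str]
    arm: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.genes), len(self.samples)):
            raise ValueError("count shape does not match genes/samples")
        if len(self.arm) != len(self.samples):
            raise ValueError("one arm label per sample required")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)):
                raise ValueError("counts must be integers")
            self.counts = np.round(self.counts).astype(np.int64)

    @property
    def library_sizes(self) -> np.ndarray:
        return self.counts.sum(axis=0)


@dataclass(frozen=True)
class DEGRecord:
    gene: str
    log2_fold_change: float
    p_value: float
    fdr: float
    direction: str  # 'up' | 'down'


def tmm_factors(
    counts: CountMatrix | np.ndarray,
    reference: int | str | None = None,
    trim_m: float = 0.3,
    trim_a: float = 0.05,
) -> np.ndarray:
    """Per-sample TMM scaling factors, geometric mean exactly 1.

    ``reference``: sample index/id, or None to pick the sample whose
    upper-quartile count fraction is closest to the mean (the standard
    automatic choice).  Genes with a zero count in either the sample or
    the reference are excluded from that comparison.
    """
    if isinstance(counts, CountMatrix):
        y = counts.counts.astype(float)
        sample_ids = counts.samples
    else:
        y = np.asarray(counts, dtype=float)
        sample_ids = list(range(y.shape[1]))
    lib = y.sum(axis=0)
    if np.any(lib <= 0):
        raise ValueError("every sample must have a positive library size")
    frac = y / lib

    if reference is None:
        uq = np.array([np.quantile(frac[y[:, j] >= 0, j], 0.75) for j in range(y.shape[1])])
        ref = int(np.argmin(np.abs(uq - uq.mean())))
    elif isinstance(reference, str):
        ref = sample_ids.index(reference)
    else:
        ref = int(reference)

    log_factors = np.zeros(y.shape[1])
    for j in range(y.shape[1]):
        if j == ref:
            continue
        keep = (y[:, j] > 0) & (y[:, ref] > 0)
        if not keep.any():
            raise ValueError(f"sample {sample_ids[j]!r} shares no expressed genes with the reference")
        pj, pr = frac[keep, j], frac[keep, ref]
        m = np.log2(pj / pr)
        a = 0.5 * np.log2(pj * pr)
        w = (lib[j] - y[keep, j]) / (lib[j] * y[keep, j]) + (lib[ref] - y[keep, ref]) / (
            lib[ref] * y[keep, ref]
        )
        n = len(m)
        lo_m = np.floor(n * trim_m) + 1
        hi_m = n + 1 - lo_m
        lo_a = np.floor(n * trim_a) + 1
        hi_a = n + 1 - lo_a
        rm = stats.rankdata(m)
        ra = stats.rankdata(a)
        kept = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
        if kept.any() and np.any(w[kept] > 0):
            log_factors[j] = np.sum(m[kept] / w[kept]) / np.sum(1.0 / w[kept])
        else:
            log_factors[j] = 0.0
    factors = 2.0 ** log_factors
    return factors / np.exp(np.mean(np.log(factors)))


def cpm(counts: CountMatrix | np.ndarray, factors: np.ndarray | None = None) -> np.ndarray:
    """Counts per million over the effective (factor-scaled) library size."""
    y = counts.counts.astype(float) if isinstance(counts, CountMatrix) else np.asarray(counts, dtype=float)
    lib = y.sum(axis=0)
    if factors is None:
        factors = np.ones(y.shape[1])
    factors = np.asarray(factors, dtype=float)
    eff = lib * factors
    if np.any(eff <= 0):
        raise ValueError("zero effective library size")
    return y * 1e6 / eff


def _moment_dispersion(x: np.ndarray, scale: np.ndarray) -> np.ndarray:
    """Per-gene NB dispersion from CPM-scale replicate moments.

    For count K ~ NB(mu, phi) observed as x = c*K (c the per-sample CPM
    scale), Var(x) = c_bar*m + phi*m^2 with m the CPM mean; solve for phi.
    """
    m = x.mean(axis=1)
    v = x.var(axis=1, ddof=1)
    cbar = scale.mean()
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = (v - cbar * m) / m**2
    return np.clip(np.nan_to_num(phi, nan=0.0), 0.0, 50.0)


def call_degs(
    counts: CountMatrix,
    design: Mapping[str, str] | None = None,
    alpha: float = 0.05,
    min_cpm: float = 1.0,
    min_samples: int = 2,
    prior_df: float = 20.0,
) -> list[DEGRecord]:
    """Call differentially expressed genes, treated vs control.

    Genes below the expression floor (CPM >= min_cpm in >= min_samples
    samples) are filtered before testing; all-zero genes never reach the
    test.  Fold changes are treated over control on TMM-normalized CPMs.
    """
    arm = list(counts.arm) if design is None else [design[s] for s in counts.samples]
    t_cols = [i for i, a in enumerate(arm) if a == "treated"]
    c_cols = [i for i, a in enumerate(arm) if a == "control"]
    if len(t_cols) < 2 or len(c_cols) < 2:
        raise ValueError("need >=2 replicates in each arm")
    lib = counts.library_sizes
    if np.any(lib <= 0):
        raise ValueError("every sample must have a positive library size")

    factors = tmm_factors(counts)
    x = cpm(counts, factors)
    scale = 1e6 / (lib * factors)  # CPM units per single read, per sample

    expressed = (x >= min_cpm).sum(axis=1) >= min_samples
    if not expressed.any():
        return []
    xg = x[expressed]
    genes = [g for g, e in zip(counts.genes, expressed) if e]

    xt, xc = xg[:, t_cols], xg[:, c_cols]
    st, sc = scale[t_cols], scale[c_cols]
    nt, nc = len(t_cols), len(c_cols)

    phi_t = _moment_dispersion(xt, st)
    phi_c = _moment_dispersion(xc, sc)
    phi_tag = (phi_t * (nt - 1) + phi_c * (nc - 1)) / (nt + nc - 2)
    phi_common = float(np.median(phi_tag))
    df_tag = nt + nc - 2
    phi = (prior_df * phi_common + df_tag * phi_tag) / (prior_df + df_tag)

    c0 = 0.5  # pseudo-CPM keeping zero-mean arms finite
    mt, mc = xt.mean(axis=1), xc.mean(axis=1)
    lfc = np.log2((mt + c0) / (mc + c0))
    # delta-method variance of log2 of a group-mean CPM under NB sampling
    var_t = (st.mean() * mt + phi * mt**2) / nt
    var_c = (sc.mean() * mc + phi * mc**2) / nc
    ln2sq = np.log(2.0) ** 2
    se2 = var_t / ((mt + c0) ** 2 * ln2sq) + var_c / ((mc + c0) ** 2 * ln2sq)
    with np.errstate(divide="ignore", invalid="ignore"):
        wald = lfc / np.sqrt(se2)
    # moderated reference df: residual df plus the prior df the dispersion
    # shrinkage borrows across genes (limma-style augmentation)
    df_ref = (nt + nc - 2) + prior_df
    p = np.where(se2 > 0, 2.0 * stats.t.sf(np.abs(wald), df=df_ref), 1.0)
    p = np.where((se2 == 0) & (lfc != 0), 0.0, p)
    fdr = multipletests(p, method="fdr_bh")[1]

    records: list[DEGRecord] = []
    for g, l, pv, q in zip(genes, lfc, p, fdr):
        if pv <= alpha and q <= alpha and l != 0:
            records.append(
                DEGRecord(
                    gene=g,
                    log2_fold_change=float(l),
                    p_value=float(pv),
                    fdr=float(q),
                    direction="up" if l > 0 else "down",
                )
            )
    return records


def deg_direction_counts(records: list[DEGRecord]) -> tuple[int, int, int]:
    """(n_down, n_up, total); total is always the exact sum."""
    n_up = sum(1 for r in records if r.direction == "up")
    n_down = sum(1 for r in records if r.direction == "down")
    return n_down, n_up, n_down + n_up


def deg_frame(records: list[DEGRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene": r.gene,
                "log2_fold_change": r.log2_fold_change,
                "p_value": r.p_value,
                "fdr": r.fdr,
                "direction": r.direction,
            }
            for r in records
        ],
        columns=["gene", "log2_fold_change", "p_value", "fdr", "direction"],
    )
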