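"""Motif scanning and genomic-context statistics for CpG site sets.

Centered on estrogen response elements (EREs): the full palindromic
consensus GGTCANNNTGACC and the 6-bp half-site AGGTCA (whose reverse
complement is TGACCT).  Estrogen receptors bind half-sites in vivo, so
half-site proximity to epimutations is the main readout here: the census
of half-sites per annotation class, their frequency within a window of a
site set, hypergeometric enrichment of sites per class, and a
precedence-based per-site annotation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .intervals import AnnotationTrack

__all__ = [
    "MotifHit",
    "EnrichmentResult",
    "ProximityDensity",
    "IUPAC",
    "FULL_ERE",
    "HALF_SITE_FWD",
    "HALF_SITE_REV",
    "reverse_complement_iupac",
    "scan_motif",
    "ere_census",
    "window_motif_frequency",
    "annotate_sites",
    "enrichment",
]

FULL_ERE = "GGTCANNNTGACC"
HALF_SITE_FWD = "AGGTCA"
HALF_SITE_REV = "TGACCT"

# base -> bitmask; genome 'N' encodes to 0 and therefore matches no code
_BASE_BITS = {"A": 1, "C": 2, "G": 4, "T": 8}
IUPAC: dict[str, int] = {
    "A": 1, "C": 2, "G": 4, "T": 8,
    "R": 5, "Y": 10, "S": 6, "W": 9, "K": 12, "M": 3,
    "B": 14, "D": 13, "H": 11, "V": 7, "N": 15,
}
_IUPAC_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}

_ENC = np.zeros(256, dtype=np.uint8)
for _b, _v in _BASE_BITS.items():
    _ENC[ord(_b)] = _v
    _ENC[ord(_b.lower())] = _v

DEFAULT_PRECEDENCE = (
    "tss", "promoter", "tfbs", "cpg_island", "enhancer", "gene_body", "repeat",
)


@dataclass(frozen=True)
class MotifHit:
    chrom: str
    start: int
    end: int
    strand: str
    name: str
    matched: str

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class EnrichmentResult:
    track: str
    k: int  # sites in class
    n: int  # total sites
    K: int  # background CpGs in class
    N: int  # total background CpGs
    fold_enrichment: float | None
    p_value: float | None
    fdr: float | None


@dataclass
class ProximityDensity:
    name: str
    window: int
    per_site_counts: np.ndarray
    density_per_kb: float
    background_density_per_kb: float | None
    ratio: float | None
    rank_test_p: float | None


def reverse_complement_iupac(motif: str) -> str:
    try:
        return "".join(_IUPAC_COMPLEMENT[c] for c in reversed(motif.upper()))
    except KeyError as exc:
        raise ValueError(f"invalid IUPAC character {exc.args[0]!r}") from None


def _encode(seq: str) -> np.ndarray:
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _scan_one(enc: np.ndarray, motif: str, max_mismatches: int) -> np.ndarray:
    """Start positions where the motif matches with <= max_mismatches."""
    L = len(motif)
    n = len(enc)
    if n < L:
        return np.empty(0, dtype=np.int64)
    bits = np.array([IUPAC[c] for c in motif.upper()], dtype=np.uint8)
    mm = np.zeros(n - L + 1, dtype=np.int32)
    for i in range(L):
        mm += (enc[i : n - L + 1 + i] & bits[i]) == 0
    return np.where(mm <= max_mismatches)[0].astype(np.int64)


def scan_motif(
    sequences: Mapping[str, str],
    consensus: str,
    name: str | None = None,
    max_mismatches: int = 0,
    strands: str = "both",
) -> list[MotifHit]:
    """Scan every chromosome for an IUPAC consensus on one or both strands.

    Overlapping matches are all reported.  A minus-strand hit at interval
    [s, e) means the reverse complement of the forward sequence matches
    there; its ``matched`` field is reported in motif orientation.  Hits
    come back sorted by (chrom, start, strand) — deterministic.
    """
    consensus = consensus.upper()
    if not consensus:
        raise ValueError("empty consensus")
    for c in consensus:
        if c not in IUPAC:
            raise ValueError(f"invalid IUPAC character {c!r}")
    if strands not in ("both", "+", "-"):
        raise ValueError("strands must be 'both', '+' or '-'")
    motif_name = name or consensus
    L = len(consensus)
    hits: list[MotifHit] = []
    for chrom in sorted(sequences.keys()):
        seq = str(sequences[chrom])
        enc = _encode(seq)
        found: list[tuple[int, str]] = []
        if strands in ("both", "+"):
            found.extend((int(s), "+") for s in _scan_one(enc, consensus, max_mismatches))
        if strands in ("both", "-"):
            rc = reverse_complement_iupac(consensus)
            found.extend((int(s), "-") for s in _scan_one(enc, rc, max_mismatches))
        for s, strand in sorted(found):
            frag = seq[s : s + L].upper()
            if strand == "-":
                frag = "".join(_IUPAC_COMPLEMENT.get(b, "N") for b in reversed(frag))
            hits.append(MotifHit(chrom, s, s + L, strand, motif_name, frag))
    return hits


def _midpoints_by_chrom(hits: Sequence[MotifHit]) -> dict[str, np.ndarray]:
    by: dict[str, list[int]] = {}
    for h in hits:
        by.setdefault(h.chrom, []).append(h.midpoint)
    return {c: np.sort(np.asarray(v, dtype=np.int64)) for c, v in by.items()}


def ere_census(
    hits: Sequence[MotifHit],
    tracks: Mapping[str, AnnotationTrack],
) -> pd.DataFrame:
    """Per-annotation-class motif-hit counts and per-kb densities.

    A hit is attributed to a class when its midpoint lies inside any class
    interval; classes overlap, so one hit may count in several (no
    precedence here — this is a census, not a labeling).
    """
    if not tracks:
        raise ValueError("tracks must be nonempty")
    mids = _midpoints_by_chrom(hits)
    rows = []
    for name in sorted(tracks):
        track = tracks[name]
        count = sum(int(track.contains(c, m).sum()) for c, m in mids.items())
        bp = track.total_bp()
        rows.append(
            {
                "track": name,
                "n_hits": count,
                "total_bp": bp,
                "density_per_kb": count / (bp / 1000.0) if bp else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def window_motif_frequency(
    sites: Sequence[tuple[str, int]],
    hits: Sequence[MotifHit],
    window: int = 500,
    universe: Sequence[tuple[str, int]] | None = None,
    n_background_draws: int = 50,
    seed: int = 0,
    name: str = "sites",
) -> ProximityDensity:
    """Motif frequency within +/- window bp of each site, vs matched background.

    Per site, hits whose midpoint lies in the closed window
    [pos - window, pos + window] are counted; density is hits per kb of
    total window span.  The background re-draws equal-size CpG sets from
    the assayed universe (excluding the sites themselves) — DMCs can only
    occur at assayed CpGs, so random genome positions would be the wrong
    null.  A Mann-Whitney test compares per-site counts against the pooled
    background per-site counts.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if len(sites) == 0:
        raise ValueError("empty site set")
    mids = _midpoints_by_chrom(hits)

    def per_site(site_list: Sequence[tuple[str, int]]) -> np.ndarray:
        out = np.zeros(len(site_list), dtype=np.int64)
        for i, (chrom, pos) in enumerate(site_list):
            m = mids.get(chrom)
            if m is None:
                continue
            out[i] = np.searchsorted(m, pos + window, side="right") - np.searchsorted(
                m, pos - window, side="left"
            )
        return out

    counts = per_site(sites)
    span_kb = len(sites) * 2 * window / 1000.0
    density = counts.sum() / span_kb

    bg_density = None
    ratio = None
    rank_p = None
    if universe is not None and n_background_draws > 0:
        site_set = set(sites)
        pool = [u for u in universe if u not in site_set]
        if len(pool) >= len(sites):
            rng = np.random.default_rng(seed)
            pool_arr = np.arange(len(pool))
            bg_counts = []
            for _ in range(n_background_draws):
                pick = rng.choice(pool_arr, size=len(sites), replace=False)
                bg_counts.append(per_site([pool[i] for i in pick]))
            bg_all = np.concatenate(bg_counts)
            bg_density = float(bg_all.sum() / (len(bg_all) * 2 * window / 1000.0))
            if bg_density > 0 and density > 0:
                ratio = float(density / bg_density)
            if np.ptp(counts) > 0 or np.ptp(bg_all) > 0 or counts.mean() != bg_all.mean():
                rank_p = float(stats.mannwhitneyu(counts, bg_all, alternative="two-sided").pvalue)
    return ProximityDensity(
        name=name,
        window=window,
        per_site_counts=counts,
        density_per_kb=float(density),
        background_density_per_kb=bg_density,
        ratio=ratio,
        rank_test_p=rank_p,
    )


def annotate_sites(
    sites: Sequence[tuple[str, int]],
    tracks: Mapping[str, AnnotationTrack],
    precedence: Sequence[str] = DEFAULT_PRECEDENCE,
) -> tuple[list[str], dict[str, int]]:
    """Label each site with its highest-precedence containing class.

    Sites outside every track are 'intergenic'.  Tallies sum exactly to
    the number of sites.  Tracks absent from the input set are allowed in
    the precedence order (skipped); a precedence name that is neither a
    known class nor a provided track is an error.
    """
    known = set(DEFAULT_PRECEDENCE) | set(tracks)
    for name in precedence:
        if name not in known:
            raise ValueError(f"unknown track in precedence: {name!r}")
    order = [n for n in precedence if n in tracks]
    labels = ["intergenic"] * len(sites)
    assigned = np.zeros(len(sites), dtype=bool)
    by_chrom: dict[str, list[int]] = {}
    pos_arr = np.asarray([p for _, p in sites], dtype=np.int64)
    for i, (chrom, _) in enumerate(sites):
        by_chrom.setdefault(chrom, []).append(i)
    for name in order:
        track = tracks[name]
        for chrom, idx in by_chrom.items():
            idx_arr = np.asarray(idx)
            hit = track.contains(chrom, pos_arr[idx_arr])
            take = idx_arr[hit & ~assigned[idx_arr]]
            for i in take:
                labels[i] = name
            assigned[take] = True
    tallies: dict[str, int] = {}
    for lab in labels:
        tallies[lab] = tallies.get(lab, 0) + 1
    return labels, tallies


def enrichment(
    sites: Sequence[tuple[str, int]],
    tracks: Mapping[str, AnnotationTrack],
    universe: Sequence[tuple[str, int]],
) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of a site set per annotation class.

    fold = (k/n) / (K/N) with k sites and K universe CpGs in the class;
    p = P(X >= k) for X ~ Hypergeom(N, K, n); BH across classes.  Classes
    with no universe CpGs report null fold/p.
    """
    site_set = set(sites)
    uni_list = list(universe)
    if not site_set.issubset(set(uni_list)):
        raise ValueError("sites must be a subset of the background universe")
    n, N = len(site_set), len(uni_list)
    site_pos: dict[str, np.ndarray] = {}
    uni_pos: dict[str, np.ndarray] = {}
    for coll, store in ((site_set, site_pos), (uni_list, uni_pos)):
        tmp: dict[str, list[int]] = {}
        for chrom, pos in coll:
            tmp.setdefault(chrom, []).append(pos)
        for c, v in tmp.items():
            store[c] = np.asarray(v, dtype=np.int64)

    rows: list[EnrichmentResult] = []
    pvals: list[float] = []
    for name in sorted(tracks):
        track = tracks[name]
        k = sum(int(track.contains(c, p).sum()) for c, p in site_pos.items())
        K = sum(int(track.contains(c, p).sum()) for c, p in uni_pos.items())
        if K == 0:
            rows.append(EnrichmentResult(name, k, n, K, N, None, None, None))
            continue
        fold = (k / n) / (K / N) if n else float("nan")
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append(EnrichmentResult(name, k, n, K, N, fold, p, None))
        pvals.append(p)
    if pvals:
        fdrs = iter(multipletests(pvals, method="fdr_bh")[1])
        rows = [
            EnrichmentResult(r.track, r.k, r.n, r.K, r.N, r.fold_enrichment, r.p_value, float(next(fdrs)))
            if r.p_value is not None
            else r
            for r in rows
        ]
    return rows
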