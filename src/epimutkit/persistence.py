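"""Persistence accounting of epimutations across a cell-fate transition.

Given the feature sets of a parent (exposed) cell state and a derived
cell state, a PersistenceSummary splits them into conserved (present in
both), corrected (parent-only, lost during the transition) and de novo
(derived-only, newly arisen).  Matching is exact — CpG coordinate for
DMCs, gene id for DEGs — with an optional windowed mode for DMCs.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Hashable, Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "PersistenceSummary",
    "match_dmcs",
    "match_degs",
    "multigeneration_propagate",
]


def _round1(x: float) -> float:
    """Round half-up to one decimal (presentation convention for percentages)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class PersistenceSummary:
    """Conserved / corrected / de-novo accounting between two feature sets.

    The subtraction identities hold exactly by construction:
    corrected = parent - conserved and de_novo = derived - conserved.
    """

    parent_n: int
    derived_n: int
    conserved_n: int
    concordant_n: int | None = None  # direction-matched subset, when known

    def __post_init__(self) -> None:
        if min(self.parent_n, self.derived_n, self.conserved_n) < 0:
            raise ValueError("counts must be non-negative")
        if self.conserved_n > min(self.parent_n, self.derived_n):
            raise ValueError("conserved count exceeds a set size")
        if self.concordant_n is not None and self.concordant_n > self.conserved_n:
            raise ValueError("concordant count exceeds conserved count")

    @property
    def corrected_n(self) -> int:
        return self.parent_n - self.conserved_n

    @property
    def de_novo_n(self) -> int:
        return self.derived_n - self.conserved_n

    @property
    def conserved_pct_of_parent(self) -> float:
        if self.parent_n == 0:
            return float("nan")
        return _round1(100.0 * self.conserved_n / self.parent_n)

    @classmethod
    def from_counts(cls, parent_n: int, derived_n: int, conserved_n: int) -> "PersistenceSummary":
        return cls(parent_n, derived_n, conserved_n)

    def as_dict(self) -> dict:
        return {
            "parent_n": self.parent_n,
            "derived_n": self.derived_n,
            "conserved_n": self.conserved_n,
            "corrected_n": self.corrected_n,
            "de_novo_n": self.de_novo_n,
            "conserved_pct_of_parent": self.conserved_pct_of_parent,
            "concordant_n": self.concordant_n,
        }


def _as_unique(items: Iterable[Hashable], label: str) -> set:
    seq = list(items)
    out = set(seq)
    if len(out) != len(seq):
        raise ValueError(f"duplicate entries in {label} set; deduplicate upstream")
    return out


def match_dmcs(
    parent_dmcs: Iterable[tuple[str, int]],
    derived_dmcs: Iterable[tuple[str, int]],
    parent_directions: Mapping[tuple[str, int], str] | None = None,
    derived_directions: Mapping[tuple[str, int], str] | None = None,
    window: int = 0,
) -> PersistenceSummary:
    """Match DMC sets by exact CpG coordinate (default) or within a window.

    Direction-agnostic: a site counts as conserved whenever it recurs; if
    direction maps are supplied the direction-concordant subset is
    reported as ``concordant_n``.  ``window > 0`` relaxes matching to
    same-chromosome sites within that many bp (each parent site matches
    at most one derived site).
    """
    parent = _as_unique(parent_dmcs, "parent")
    derived = _as_unique(derived_dmcs, "derived")
    if window == 0:
        conserved = parent & derived
    else:
        by_chrom: dict[str, np.ndarray] = {}
        tmp: dict[str, list[int]] = {}
        for chrom, pos in derived:
            tmp.setdefault(chrom, []).append(pos)
        by_chrom = {c: np.sort(np.asarray(v, dtype=np.int64)) for c, v in tmp.items()}
        conserved = set()
        for chrom, pos in parent:
            arr = by_chrom.get(chrom)
            if arr is None:
                continue
            lo = np.searchsorted(arr, pos - window, side="left")
            hi = np.searchsorted(arr, pos + window, side="right")
            if hi > lo:
                conserved.add((chrom, pos))
    concordant = None
    if parent_directions is not None and derived_directions is not None and window == 0:
        concordant = sum(
            1 for c in conserved if parent_directions.get(c) == derived_directions.get(c)
        )
    return PersistenceSummary(len(parent), len(derived), len(conserved), concordant)


def match_degs(
    parent_degs: Iterable[str],
    derived_degs: Iterable[str],
    parent_directions: Mapping[str, str] | None = None,
    derived_directions: Mapping[str, str] | None = None,
) -> PersistenceSummary:
    """Match DEG sets by gene id."""
    parent = _as_unique(parent_degs, "parent")
    derived = _as_unique(derived_degs, "derived")
    conserved = parent & derived
    concordant = None
    if parent_directions is not None and derived_directions is not None:
        concordant = sum(
            1 for g in conserved if parent_directions.get(g) == derived_directions.get(g)
        )
    return PersistenceSummary(len(parent), len(derived), len(conserved), concordant)


def multigeneration_propagate(
    initial: Iterable[Hashable],
    universe: Sequence[Hashable],
    retention: float,
    de_novo: float,
    n_generations: int,
    seed: int = 0,
) -> list[PersistenceSummary]:
    """Iterate retention + de-novo induction over successive generations.

    Each generation keeps every current feature with probability
    ``retention`` and adds round(de_novo * |available|) new features drawn
    from the universe.  The expected burden converges to the fixed point
    d*U / (1 - r + d) of B' = rB + d(U - B).  Returns one summary per
    generation (parent = previous generation).
    """
    if not 0 <= retention <= 1 or not 0 <= de_novo <= 1:
        raise ValueError("rates must lie in [0, 1]")
    if n_generations < 1:
        raise ValueError("need >= 1 generation")
    rng = np.random.default_rng(seed % (2**31))
    universe = list(universe)
    current = _as_unique(initial, "initial")
    if not current <= set(universe):
        raise ValueError("initial features must lie in the universe")
    out: list[PersistenceSummary] = []
    for _gen in range(n_generations):
        members = sorted(current, key=repr)
        keep = rng.random(len(members)) < retention
        nxt = {m for m, k in zip(members, keep) if k}
        avail = sorted(set(universe) - current, key=repr)
        n_new = int(round(de_novo * len(avail)))
        if n_new > len(avail):
            raise ValueError("de-novo request exceeds available features")
        if n_new:
            pick = rng.choice(len(avail), size=n_new, replace=False)
            nxt.update(avail[i] for i in pick)
        out.append(PersistenceSummary(len(current), len(nxt), len(current & nxt)))
        current = nxt
    return out
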