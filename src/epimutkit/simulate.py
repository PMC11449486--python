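"""Ground-truth synthetic data generator.

Emulates the study design this toolkit analyzes: 3-replicate treated vs
3-replicate control arms for four cultured cell types (two somatic, one
pluripotent, one germ-cell-like), assayed at a fixed panel of genomic
CpGs.  The generator plants everything the downstream stages are supposed
to find — ERE half-sites at a configurable enhancer:promoter density
ratio, exposure DMCs with cell-type-specific hypo/hyper mixes and
annotation/ERE location biases, negative-binomial expression counts with
promoter-DMC-linked DEGs, and a reprogramming step (pluripotent -> germ
cell fate) that retains a small fraction of epimutations and induces new
ones de novo — and records the exact truth for every planted feature.

All randomness flows from the config seed; identical configs give
bit-identical outputs.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .context import HALF_SITE_FWD, HALF_SITE_REV, MotifHit
from .intervals import AnnotationTrack, GeneAnnotation
from .methylation import BetaMatrix, MethylCountMatrix
from .expression import CountMatrix

__all__ = [
    "CellProfile",
    "SimConfig",
    "GenomeModel",
    "TruthSet",
    "CapacityError",
    "ConfigError",
    "default_profiles",
    "simulate_genome",
    "simulate_methylome",
    "simulate_emseq_counts",
    "simulate_counts",
    "simulate_reprogramming",
]

RECEPTOR_STATES = ("ER_both", "ER_beta_only", "ER_none")


class ConfigError(ValueError):
    pass


class CapacityError(ValueError):
    """A requested feature density exceeds what the sequence can hold."""


@dataclass
class CellProfile:
    """Baseline methylome and exposure-response parameters of one cell type.

    ``hypo_fraction_of_dmcs`` sets the exact hypo:hyper split of planted
    exposure DMCs; ``location_bias`` steers planted DMCs toward one
    annotation class; ER-positive receptor states additionally bias
    planted DMCs toward CpGs near planted ERE half-sites.
    """

    name: str
    baseline_mean_methylation: float
    receptor_state: str
    hypo_fraction_of_dmcs: float
    location_bias: str
    n_planted_dmcs: int
    n_planted_degs: int
    deg_up_fraction: float = 0.6
    location_bias_strength: float | None = None  # None -> config default
    inherent_dmc_fraction: float | None = None  # planted DMCs at inherently variable CpGs

    def validate(self) -> None:
        if not 0 <= self.baseline_mean_methylation <= 1:
            raise ConfigError(f"{self.name}: baseline methylation outside [0, 1]")
        if self.receptor_state not in RECEPTOR_STATES:
            raise ConfigError(f"{self.name}: unknown receptor state {self.receptor_state!r}")
        if not 0 <= self.hypo_fraction_of_dmcs <= 1:
            raise ConfigError(f"{self.name}: hypo fraction outside [0, 1]")
        if not 0 <= self.deg_up_fraction <= 1:
            raise ConfigError(f"{self.name}: up fraction outside [0, 1]")
        if self.n_planted_dmcs < 0 or self.n_planted_degs < 0:
            raise ConfigError(f"{self.name}: planted counts must be >= 0")
        if self.location_bias_strength is not None and not 0 <= self.location_bias_strength <= 1:
            raise ConfigError(f"{self.name}: bias strength outside [0, 1]")
        if self.inherent_dmc_fraction is not None and not 0 <= self.inherent_dmc_fraction <= 1:
            raise ConfigError(f"{self.name}: inherent DMC fraction outside [0, 1]")


def default_profiles(n_cpgs: int = 20_000, n_genes: int = 800) -> list[CellProfile]:
    """The four study cell types at desk scale.

    Hypo fractions and up:down DEG splits follow the real cell-type
    contrasts (somatic/pluripotent hypo-dominant, germ hyper-dominant;
    germ baseline lowest — the hypomethylated germline ground state).
    Planted totals are the full-scale per-cell-type totals scaled to the
    synthetic panel: DMCs by n_cpgs relative to the 297,415-probe array,
    DEGs by n_genes relative to ~20,000 mouse genes (floor 1).
    """
    sc = n_cpgs / 297_415
    sg = n_genes / 20_000
    spec = [
        # name, baseline, receptors, (hypo, total dmcs), bias, (up, total degs), inherent
        ("sertoli", 0.75, "ER_both", (7385, 10407), "enhancer", (32, 35), 0.96),
        ("granulosa", 0.75, "ER_both", (6444, 10587), "enhancer", (2, 2), 0.96),
        ("ipsc", 0.70, "ER_beta_only", (9651, 13959), "enhancer", (694, 1037), 0.96),
        ("pgclc", 0.30, "ER_none", (2315, 7100), "promoter", (1046, 1890), 0.89),
    ]
    return [
        CellProfile(
            name, baseline, receptors,
            hypo_total[0] / hypo_total[1], bias,
            int(round(hypo_total[1] * sc)),
            max(1, int(round(up_total[1] * sg))),
            deg_up_fraction=up_total[0] / up_total[1],
            inherent_dmc_fraction=inherent,
        )
        for name, baseline, receptors, hypo_total, bias, up_total, inherent in spec
    ]


@dataclass
class SimConfig:
    """Simulation parameters; defaults reproduce the study conditions."""

    seed: int = 0
    n_replicates: int = 3
    n_cpgs: int = 20_000
    n_genes: int = 800
    cell_profiles: list[CellProfile] = field(default_factory=default_profiles)
    dose_scale: float = 1.0  # saturating multiplier on planted DMC/DEG counts
    reprogram_retention: float = 0.037
    reprogram_de_novo: float = 0.035
    reprogram_retention_deg: float = 0.084
    reprogram_de_novo_deg: float = 0.047
    ere_enhancer_density_ratio: float = 4.0
    ere_promoter_density_per_kb: float = 0.5
    ere_other_density_per_kb: float = 0.25  # gene bodies and repeats
    location_bias_strength: float = 0.7
    ere_proximity_bias: float = 0.7  # ER-positive profiles only
    ere_window: int = 500
    effect_delta_beta: float = 0.4
    noise_sd: float = 0.05  # replicate noise sd on the logit (M-value) scale
    inherent_fraction: float = 0.8  # CpGs with cell-type-private baselines
    shared_baseline: float = 0.6  # mean methylation of cell-type-invariant CpGs
    cpg_profile_sd: float = 1.5  # logit-scale spread of per-CpG baselines
    n_chroms: int = 5
    chrom_length: int = 2_000_000
    promoter_halfwidth: int = 1000
    gene_body_length: int = 5000
    emseq_depth: int = 30
    nb_dispersion: float = 0.05
    deg_lfc: float = 2.0
    deg_promoter_link: float = 0.6  # fraction of planted DEGs with a promoter DMC

    def validate(self) -> None:
        for frac_name in (
            "reprogram_retention", "reprogram_de_novo",
            "reprogram_retention_deg", "reprogram_de_novo_deg",
            "location_bias_strength", "ere_proximity_bias",
            "inherent_fraction", "deg_promoter_link",
        ):
            v = getattr(self, frac_name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{frac_name} outside [0, 1]")
        for pos_name in ("n_replicates", "n_genes", "n_chroms", "chrom_length",
                         "promoter_halfwidth", "gene_body_length", "emseq_depth"):
            if getattr(self, pos_name) <= 0:
                raise ConfigError(f"{pos_name} must be positive")
        if self.n_cpgs < 0:
            raise ConfigError("n_cpgs must be >= 0")
        if self.dose_scale < 0:
            raise ConfigError("dose_scale must be non-negative")
        if self.ere_enhancer_density_ratio <= 0:
            raise ConfigError("ere_enhancer_density_ratio must be positive")
        if self.n_replicates < 2:
            raise ConfigError("need >= 2 replicates per arm")
        names = [p.name for p in self.cell_profiles]
        if len(set(names)) != len(names):
            raise ConfigError("cell profile names must be unique")
        for p in self.cell_profiles:
            p.validate()
            if p.location_bias not in ("promoter", "enhancer"):
                raise ConfigError(f"{p.name}: unknown location bias track {p.location_bias!r}")

    def dose_multiplier(self) -> float:
        """Saturating dose response: 1 at the reference dose, plateau ~3x."""
        d = self.dose_scale
        return 3.0 * d / (2.0 + d) if d > 0 else 0.0


@dataclass
class TruthSet:
    """Planted ground truth: DMC coordinates with direction, DEGs with effect."""

    dmcs: dict[tuple[str, int], str] = field(default_factory=dict)  # -> 'hypo'|'hyper'
    degs: dict[str, float] = field(default_factory=dict)  # gene -> signed log2 FC

    @property
    def dmc_positions(self) -> set[tuple[str, int]]:
        return set(self.dmcs)

    @property
    def deg_genes(self) -> set[str]:
        return set(self.degs)


@dataclass
class GenomeModel:
    """A synthetic genome with annotation tracks and an assayed CpG panel."""

    chrom_lengths: dict[str, int]
    sequence: dict[str, str]
    tracks: dict[str, AnnotationTrack]
    genes: dict[str, GeneAnnotation]
    cpg_positions: dict[str, np.ndarray]  # sorted per chromosome
    planted_motifs: list[MotifHit]

    @property
    def tss(self) -> dict[str, tuple[str, int, str]]:
        return {g: (a.chrom, a.tss, a.strand) for g, a in self.genes.items()}

    def cpg_list(self) -> list[tuple[str, int]]:
        out: list[tuple[str, int]] = []
        for chrom in sorted(self.cpg_positions):
            out.extend((chrom, int(p)) for p in self.cpg_positions[chrom])
        return out

    @property
    def n_cpgs(self) -> int:
        return sum(len(v) for v in self.cpg_positions.values())


def _profile_rng(config: SimConfig, profile_name: str, stream: str) -> np.random.Generator:
    tag = zlib.crc32(f"{profile_name}/{stream}".encode()) % (2**31)
    return np.random.default_rng([config.seed % (2**31), tag])


def _place_in_intervals(
    rng: np.random.Generator,
    intervals: list[tuple[str, int, int]],
    n_sites: int,
    width: int,
    min_gap: int,
    occupied: dict[str, set[int]],
) -> list[tuple[str, int]]:
    """Place n_sites motif start positions uniformly inside the intervals,
    avoiding already-occupied footprints."""
    if n_sites == 0:
        return []
    lengths = np.array([e - s - width for _, s, e in intervals], dtype=float)
    lengths = np.clip(lengths, 0, None)
    if lengths.sum() <= 0:
        raise CapacityError("intervals too small for requested motif width")
    probs = lengths / lengths.sum()
    placed: list[tuple[str, int]] = []
    attempts = 0
    while len(placed) < n_sites:
        attempts += 1
        if attempts > 50 * n_sites + 100:
            raise CapacityError("requested motif density exceeds interval capacity")
        i = rng.choice(len(intervals), p=probs)
        chrom, s, e = intervals[i]
        if e - s <= width:
            continue
        start = int(rng.integers(s, e - width))
        occ = occupied.setdefault(chrom, set())
        footprint = range(start - min_gap, start + width + min_gap)
        if any(b in occ for b in footprint):
            continue
        occ.update(range(start, start + width))
        placed.append((chrom, start))
    return placed


def _scrub_stray_half_sites(
    seq_arrays: dict[str, np.ndarray],
    planted_starts: dict[str, set[int]],
    protected: dict[str, np.ndarray],
    rng: np.random.Generator,
) -> None:
    """Mutate away chance occurrences of the ERE half-site in the background.

    Random sequence produces the 6-mer AGGTCA (or its reverse complement)
    about once per kb, which would drown the planted density signal, so any
    occurrence that was not deliberately planted gets one base flipped.
    Planted motifs and planted CpG dinucleotides are never touched.
    """
    motifs = [np.frombuffer(m.encode(), dtype=np.uint8) for m in (HALF_SITE_FWD, HALF_SITE_REV)]
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    for chrom, arr in seq_arrays.items():
        prot = protected.get(chrom, np.zeros(len(arr), dtype=bool))
        keep = planted_starts.get(chrom, set())
        for _round in range(12):
            stray: list[int] = []
            for mot in motifs:
                L = len(mot)
                eq = np.ones(len(arr) - L + 1, dtype=bool)
                for i in range(L):
                    eq &= arr[i : len(arr) - L + 1 + i] == mot[i]
                stray.extend(int(s) for s in np.where(eq)[0] if s not in keep)
            if not stray:
                return_flag = True
                break
            for s in stray:
                free = [j for j in range(s, s + 6) if not prot[j]]
                if not free:
                    continue  # fully protected window; re-examined next round
                j = free[int(rng.integers(len(free)))]
                choices = bases[bases != arr[j]]
                arr[j] = choices[int(rng.integers(len(choices)))]
        else:
            raise CapacityError(f"could not scrub stray half-sites on {chrom}")


def simulate_genome(config: SimConfig) -> GenomeModel:
    """Build the synthetic genome: sequence, tracks, genes, CpG panel, EREs.

    Layout per gene slot (regular spacing, deterministic given the seed):
    promoter (TSS +/- promoter_halfwidth), gene body downstream of the
    TSS, a CpG island inside the promoter, two enhancers and one repeat in
    the intergenic stretch.  ERE half-sites are planted at
    ``ere_promoter_density_per_kb`` in promoters and at ``ratio`` times
    that per-bp density in enhancers (plus a light background in gene
    bodies and repeats, placed outside promoters/enhancers); stray chance
    occurrences of the half-site are scrubbed so planted density is the
    true density.  Every assayed CpG coordinate hosts a real 'CG' in the
    forward sequence.
    """
    config.validate()
    rng = np.random.default_rng([config.seed % (2**31), zlib.crc32(b"genome") % (2**31)])

    chroms = [f"chr{i + 1}" for i in range(config.n_chroms)]
    chrom_lengths = {c: config.chrom_length for c in chroms}
    seq_arrays = {
        c: rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=config.chrom_length)
        for c in chroms
    }

    # --- gene slots -------------------------------------------------------
    per_chrom = [config.n_genes // config.n_chroms] * config.n_chroms
    for i in range(config.n_genes % config.n_chroms):
        per_chrom[i] += 1
    pw = config.promoter_halfwidth
    body_len = config.gene_body_length
    # per-slot footprint: promoter + body + two enhancers + repeat + gaps
    slot_need = 3 * pw + body_len + 2900
    genes: dict[str, GeneAnnotation] = {}
    promoters: list[tuple[str, int, int]] = []
    bodies: list[tuple[str, int, int]] = []
    islands: list[tuple[str, int, int]] = []
    enhancers: list[tuple[str, int, int]] = []
    repeats: list[tuple[str, int, int]] = []
    tss_iv: list[tuple[str, int, int]] = []
    gi = 0
    for ci, chrom in enumerate(chroms):
        n_here = per_chrom[ci]
        if n_here == 0:
            continue
        spacing = config.chrom_length // n_here
        if spacing < slot_need:
            raise CapacityError(
                f"{config.n_genes} genes do not fit: slot {spacing} bp < {slot_need} bp needed"
            )
        for k in range(n_here):
            g0 = k * spacing
            tss = g0 + pw + 500
            strand = "+" if rng.random() < 0.5 else "-"
            prom = (tss - pw, tss + pw)
            body = (tss, tss + body_len)
            gid = f"gene{gi:05d}"
            genes[gid] = GeneAnnotation(gid, chrom, tss, strand, prom, body)
            promoters.append((chrom, *prom))
            bodies.append((chrom, *body))
            islands.append((chrom, prom[0] + 100, prom[0] + 600))
            tss_iv.append((chrom, tss, tss + 1))
            e1 = tss + body_len + 500
            enhancers.append((chrom, e1, e1 + pw))
            e2 = e1 + pw + 500
            enhancers.append((chrom, e2, e2 + pw))
            r0 = e2 + pw + 500
            repeats.append((chrom, r0, r0 + 800))
            gi += 1

    tracks = {
        "promoter": AnnotationTrack.from_records("promoter", promoters),
        "enhancer": AnnotationTrack.from_records("enhancer", enhancers),
        "gene_body": AnnotationTrack.from_records("gene_body", bodies),
        "cpg_island": AnnotationTrack.from_records("cpg_island", islands),
        "repeat": AnnotationTrack.from_records("repeat", repeats),
        "tss": AnnotationTrack.from_records("tss", tss_iv),
    }
    for t in tracks.values():
        t.validate_bounds(chrom_lengths)

    # --- plant ERE half-sites --------------------------------------------
    occupied: dict[str, set[int]] = {}
    width = len(HALF_SITE_FWD)
    prom_bp = tracks["promoter"].total_bp()
    enh_bp = tracks["enhancer"].total_bp()
    d_prom = config.ere_promoter_density_per_kb
    n_prom_sites = int(round(d_prom * prom_bp / 1000.0))
    n_enh_sites = int(round(d_prom * config.ere_enhancer_density_ratio * enh_bp / 1000.0))

    planted: list[tuple[str, int]] = []
    planted += _place_in_intervals(rng, promoters, n_prom_sites, width, 4, occupied)
    planted += _place_in_intervals(rng, enhancers, n_enh_sites, width, 4, occupied)
    # light background in gene bodies (outside promoters) and repeats
    body_free = [(c, s + pw, e) for c, s, e in bodies]  # skip promoter overlap
    for ivs in (body_free, repeats):
        bp = sum(e - s for _, s, e in ivs)
        n_bg = int(round(config.ere_other_density_per_kb * bp / 1000.0))
        planted += _place_in_intervals(rng, ivs, n_bg, width, 4, occupied)

    planted_motifs: list[MotifHit] = []
    planted_starts: dict[str, set[int]] = {}
    for chrom, start in planted:
        fwd = rng.random() < 0.5
        word = HALF_SITE_FWD if fwd else HALF_SITE_REV
        seq_arrays[chrom][start : start + width] = np.frombuffer(word.encode(), dtype=np.uint8)
        planted_motifs.append(
            MotifHit(chrom, start, start + width, "+" if fwd else "-", "ERE_half_site", HALF_SITE_FWD)
        )
        planted_starts.setdefault(chrom, set()).add(start)
    planted_motifs.sort(key=lambda h: (h.chrom, h.start, h.strand))

    protected = {c: np.zeros(config.chrom_length, dtype=bool) for c in chroms}
    for chrom, start in planted:
        protected[chrom][start : start + width] = True

    # --- plant the assayed CpG panel -------------------------------------
    cpg_positions: dict[str, np.ndarray] = {c: np.empty(0, dtype=np.int64) for c in chroms}
    if config.n_cpgs > 0:
        n_per = [config.n_cpgs // config.n_chroms] * config.n_chroms
        for i in range(config.n_cpgs % config.n_chroms):
            n_per[i] += 1
        for ci, chrom in enumerate(chroms):
            need = n_per[ci]
            if need == 0:
                continue
            if need * 4 > config.chrom_length:
                raise CapacityError("requested CpG density exceeds sequence capacity")
            occ = occupied.setdefault(chrom, set())
            chosen: list[int] = []
            attempts = 0
            while len(chosen) < need:
                attempts += 1
                if attempts > 60 * need + 1000:
                    raise CapacityError("could not place requested CpGs")
                p = int(rng.integers(0, config.chrom_length - 2))
                footprint = (p - 1, p, p + 1, p + 2)
                if any(b in occ for b in footprint):
                    continue
                occ.update((p, p + 1))
                chosen.append(p)
            pos = np.sort(np.asarray(chosen, dtype=np.int64))
            seq_arrays[chrom][pos] = ord("C")
            seq_arrays[chrom][pos + 1] = ord("G")
            protected[chrom][pos] = True
            protected[chrom][pos + 1] = True
            cpg_positions[chrom] = pos

    _scrub_stray_half_sites(seq_arrays, planted_starts, protected, rng)

    sequence = {c: a.tobytes().decode("ascii") for c, a in seq_arrays.items()}
    return GenomeModel(
        chrom_lengths=chrom_lengths,
        sequence=sequence,
        tracks=tracks,
        genes=genes,
        cpg_positions=cpg_positions,
        planted_motifs=planted_motifs,
    )


def _logit(x: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    x = np.clip(x, eps, 1 - eps)
    return np.log(x / (1 - x))


def _expit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _shared_cpg_fields(genome: GenomeModel, config: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    """(shared_dev, inherent_mask) for the CpG panel — identical for every
    cell type given one config, so the same CpGs are cell-type-invariant
    in every methylome drawn from that config."""
    n = genome.n_cpgs
    rng_shared = _profile_rng(config, "__shared__", "baseline")
    shared_dev = rng_shared.normal(0.0, config.cpg_profile_sd, size=n)
    inherent_mask = rng_shared.random(n) < config.inherent_fraction
    return shared_dev, inherent_mask


def _cpg_baseline(genome: GenomeModel, profile: CellProfile, config: SimConfig) -> np.ndarray:
    """Per-CpG mean methylation for one cell type.

    The ``inherent_fraction`` of CpGs carries a cell-type-private mean
    (the profile's baseline plus a private per-CpG deviation) — these are
    the inherently cell-type-variable CpGs an ANOVA across control
    methylomes recovers.  The remaining CpGs share one cell-type-invariant
    mean (a common anchor plus a shared deviation).
    """
    n = genome.n_cpgs
    shared_dev, inherent_mask = _shared_cpg_fields(genome, config)
    rng_prof = _profile_rng(config, profile.name, "baseline")
    private_dev = rng_prof.normal(0.0, config.cpg_profile_sd, size=n)
    private_mu = _logit(np.full(n, profile.baseline_mean_methylation)) + private_dev
    shared_mu = _logit(np.full(n, config.shared_baseline)) + shared_dev
    return _expit(np.where(inherent_mask, private_mu, shared_mu))


def _select_planted_sites(
    genome: GenomeModel,
    profile: CellProfile,
    config: SimConfig,
    n_plant: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Indices (into the flat CpG list) of planted DMC positions.

    Three independent biases combine.  With probability b (bias
    strength) a site is constrained to the profile's biased annotation
    track, otherwise unconstrained; for ER-positive profiles, with
    probability e it is constrained to CpGs within ``ere_window`` bp of a
    planted ERE half-site, otherwise unconstrained (so e = 0 is neutral,
    not avoidance).  The inherent split is exact two-sided: a fraction q
    (``inherent_dmc_fraction``) comes from inherently cell-type-variable
    CpGs and 1 - q from invariant CpGs.  Strata counts are allocated
    deterministically (rounded products); shortfalls spill to any free
    CpG.
    """
    coords = genome.cpg_list()
    n = len(coords)
    if n_plant > n:
        raise CapacityError("more planted DMCs requested than assayed CpGs")
    if profile.location_bias not in genome.tracks:
        raise ConfigError(f"profile references unknown track {profile.location_bias!r}")
    track = genome.tracks[profile.location_bias]
    in_track = np.zeros(n, dtype=bool)
    near_ere = np.zeros(n, dtype=bool)
    mids: dict[str, np.ndarray] = {}
    for h in genome.planted_motifs:
        mids.setdefault(h.chrom, [])
    for h in genome.planted_motifs:
        mids[h.chrom].append(h.midpoint)
    mids = {c: np.sort(np.asarray(v, dtype=np.int64)) for c, v in mids.items()}
    offset = 0
    for chrom in sorted(genome.cpg_positions):
        pos = genome.cpg_positions[chrom]
        if len(pos) == 0:
            continue
        sl = slice(offset, offset + len(pos))
        in_track[sl] = track.contains(chrom, pos)
        m = mids.get(chrom)
        if m is not None and len(m):
            cnt = np.searchsorted(m, pos + config.ere_window, side="right") - np.searchsorted(
                m, pos - config.ere_window, side="left"
            )
            near_ere[sl] = cnt > 0
        offset += len(pos)

    b = profile.location_bias_strength
    if b is None:
        b = config.location_bias_strength
    e = 0.0 if profile.receptor_state == "ER_none" else config.ere_proximity_bias
    _, inherent = _shared_cpg_fields(genome, config)
    q = profile.inherent_dmc_fraction
    if q is None:
        q = float(inherent.mean())  # neutral: proportional to availability

    keys = [
        (t_flag, e_flag, i_flag)
        for t_flag in (True, False)
        for e_flag in (True, False)
        for i_flag in (True, False)
    ]

    def stratum_mask(flags: tuple[bool, bool, bool]) -> np.ndarray:
        t_flag, e_flag, i_flag = flags
        m = inherent if i_flag else ~inherent  # exact two-sided split
        if t_flag:  # steering constraints: False leaves the dimension free
            m = m & in_track
        if e_flag:
            m = m & near_ere
        return m

    def stratum_p(flags: tuple[bool, bool, bool]) -> float:
        t_flag, e_flag, i_flag = flags
        return (
            (b if t_flag else 1.0 - b)
            * (e if e_flag else 1.0 - e)
            * (q if i_flag else 1.0 - q)
        )

    want = {flags: int(round(n_plant * stratum_p(flags))) for flags in keys}
    overshoot = sum(want.values()) - n_plant
    # absorb rounding drift in the largest stratum
    if overshoot != 0:
        largest = max(want, key=want.get)
        want[largest] -= overshoot

    chosen: list[np.ndarray] = []
    taken = np.zeros(n, dtype=bool)
    deficit = 0
    for flags in keys:
        pool = np.where(stratum_mask(flags) & ~taken)[0]
        k = min(max(want[flags], 0), len(pool))
        deficit += max(want[flags], 0) - k
        if k > 0:
            pick = rng.choice(pool, size=k, replace=False)
            taken[pick] = True
            chosen.append(pick)
    if deficit > 0:
        rest = np.where(~taken)[0]
        pick = rng.choice(rest, size=deficit, replace=False)
        chosen.append(pick)
    return np.concatenate(chosen) if chosen else np.empty(0, dtype=np.int64)


def simulate_methylome(
    genome: GenomeModel,
    profile: CellProfile,
    config: SimConfig,
) -> tuple[BetaMatrix, TruthSet]:
    """Draw control and treated beta matrices for one cell type.

    Replicate noise is a normal deviate of sd ``noise_sd`` on the logit
    scale, back-transformed — betas stay strictly inside (0, 1) with no
    boundary atoms, and the M-values downstream tests operate on are
    exactly normal.
    Planted DMCs shift the treated-arm mean by ``effect_delta_beta`` with
    the planted sign; the exact hypo count is
    round(hypo_fraction * n_planted).
    """
    config.validate()
    profile.validate()
    if config.n_replicates < 2:
        raise ConfigError("need >= 2 replicates per arm")
    coords = genome.cpg_list()
    n = len(coords)
    mu = _cpg_baseline(genome, profile, config)

    rng = _profile_rng(config, profile.name, "methylome")
    n_plant = int(round(profile.n_planted_dmcs * config.dose_multiplier()))
    truth = TruthSet()
    mu_control = mu.copy()
    mu_treated = mu.copy()
    if n_plant > 0 and n > 0:
        idx = _select_planted_sites(genome, profile, config, n_plant, rng)
        n_hypo = int(round(profile.hypo_fraction_of_dmcs * n_plant))
        # hypo needs methylation to lose: assign it to the most-methylated
        # planted sites (random tie-break), hyper to the rest
        order = np.argsort(-(mu[idx] + 1e-9 * rng.random(len(idx))), kind="stable")
        hypo_idx = idx[order[:n_hypo]]
        hyper_idx = idx[order[n_hypo:]]
        d = config.effect_delta_beta
        # re-anchor the control mean where the full shift would leave [0.02, 0.98]
        mu_control[hypo_idx] = np.clip(mu_control[hypo_idx], 0.02 + d, 0.98)
        mu_treated[hypo_idx] = mu_control[hypo_idx] - d
        mu_control[hyper_idx] = np.clip(mu_control[hyper_idx], 0.02, 0.98 - d)
        mu_treated[hyper_idx] = mu_control[hyper_idx] + d
        for i in hypo_idx:
            truth.dmcs[coords[i]] = "hypo"
        for i in hyper_idx:
            truth.dmcs[coords[i]] = "hyper"

    def draw(mu_arm: np.ndarray, n_rep: int) -> np.ndarray:
        z = rng.normal(0.0, 1.0, size=(len(mu_arm), n_rep))
        return _expit(_logit(mu_arm)[:, None] + config.noise_sd * z)

    vals = np.concatenate(
        [draw(mu_control, config.n_replicates), draw(mu_treated, config.n_replicates)], axis=1
    )
    samples = [f"{profile.name}_control_{r + 1}" for r in range(config.n_replicates)] + [
        f"{profile.name}_treated_{r + 1}" for r in range(config.n_replicates)
    ]
    arm = ["control"] * config.n_replicates + ["treated"] * config.n_replicates
    chrom = np.asarray([c for c, _ in coords], dtype=object)
    pos = np.asarray([p for _, p in coords], dtype=np.int64)
    return BetaMatrix(chrom, pos, samples, arm, vals), truth


def simulate_emseq_counts(
    beta_truth: BetaMatrix, depth: int, seed: int = 0
) -> MethylCountMatrix:
    """Sequencing-style counts from a beta matrix.

    Coverage per CpG per sample ~ Poisson(depth) floored at 1; methylated
    reads ~ Binomial(coverage, beta).
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng([seed % (2**31), zlib.crc32(b"emseq") % (2**31)])
    shape = beta_truth.values.shape
    cov = np.maximum(rng.poisson(depth, size=shape), 1)
    meth = rng.binomial(cov, beta_truth.values)
    return MethylCountMatrix(
        beta_truth.chrom, beta_truth.pos, list(beta_truth.samples), list(beta_truth.arm), meth, cov
    )


def simulate_counts(
    genome: GenomeModel,
    profile: CellProfile,
    truth: TruthSet,
    config: SimConfig,
) -> tuple[CountMatrix, TruthSet]:
    """Negative-binomial RNA-seq gene counts with planted DEGs.

    A fraction ``deg_promoter_link`` of planted DEGs is drawn from genes
    whose promoter hosts a planted DMC (the methylation-expression
    coupling observed in exposed cells); up/down counts are exact:
    n_up = round(deg_up_fraction * n_planted).  Per-sample library-size
    factors are drawn and recorded.
    """
    config.validate()
    profile.validate()
    gene_ids = sorted(genome.genes)
    if not gene_ids:
        raise ConfigError("gene set is empty")
    rng = _profile_rng(config, profile.name, "expression")
    n_genes = len(gene_ids)
    base = rng.lognormal(mean=5.0, sigma=1.0, size=n_genes)

    n_deg = int(round(profile.n_planted_degs * config.dose_multiplier()))
    n_deg = min(n_deg, n_genes)
    new_truth = TruthSet(dmcs=dict(truth.dmcs), degs=dict(truth.degs))
    lfc = np.zeros(n_genes)
    if n_deg > 0:
        promoter_dmc_genes = []
        dmc_by_chrom: dict[str, list[int]] = {}
        for (chrom, p), _d in truth.dmcs.items():
            dmc_by_chrom.setdefault(chrom, []).append(p)
        dmc_by_chrom = {c: np.sort(np.asarray(v)) for c, v in dmc_by_chrom.items()}
        for i, g in enumerate(gene_ids):
            ann = genome.genes[g]
            arr = dmc_by_chrom.get(ann.chrom)
            if arr is not None and np.searchsorted(arr, ann.promoter[1], side="left") > np.searchsorted(
                arr, ann.promoter[0], side="left"
            ):
                promoter_dmc_genes.append(i)
        n_link = min(int(round(n_deg * config.deg_promoter_link)), len(promoter_dmc_genes))
        linked = (
            rng.choice(np.asarray(promoter_dmc_genes), size=n_link, replace=False)
            if n_link
            else np.empty(0, dtype=np.int64)
        )
        rest_pool = np.setdiff1d(np.arange(n_genes), linked)
        others = rng.choice(rest_pool, size=n_deg - n_link, replace=False)
        deg_idx = np.concatenate([linked, others]).astype(np.int64)
        order = rng.permutation(n_deg)
        n_up = int(round(profile.deg_up_fraction * n_deg))
        up_idx = deg_idx[order[:n_up]]
        down_idx = deg_idx[order[n_up:]]
        lfc[up_idx] = config.deg_lfc
        lfc[down_idx] = -config.deg_lfc
        for i in up_idx:
            new_truth.degs[gene_ids[i]] = config.deg_lfc
        for i in down_idx:
            new_truth.degs[gene_ids[i]] = -config.deg_lfc

    n_rep = config.n_replicates
    lib_factors = rng.uniform(0.7, 1.3, size=2 * n_rep)
    arm = ["control"] * n_rep + ["treated"] * n_rep
    mu = np.empty((n_genes, 2 * n_rep))
    for j in range(2 * n_rep):
        fold = np.where(np.asarray(arm)[j] == "treated", 2.0 ** lfc, 1.0)
        mu[:, j] = base * lib_factors[j] * fold
    phi = config.nb_dispersion
    r = 1.0 / phi
    p = r / (r + mu)
    counts = rng.negative_binomial(r, p)
    samples = [f"{profile.name}_control_{k + 1}" for k in range(n_rep)] + [
        f"{profile.name}_treated_{k + 1}" for k in range(n_rep)
    ]
    cm = CountMatrix(gene_ids, samples, arm, counts)
    cm.lib_factors = lib_factors  # type: ignore[attr-defined]
    return cm, new_truth


def simulate_reprogramming(
    parent_truth: TruthSet,
    genome: GenomeModel,
    config: SimConfig,
    seed: int | None = None,
) -> TruthSet:
    """Apply one cell-fate transition to a planted truth set.

    Each parent DMC survives independently with probability
    ``reprogram_retention``; de-novo DMCs are drawn from non-parent
    assayed CpGs at rate ``reprogram_de_novo`` (a fraction of the
    available CpGs).  DEGs transition analogously with the DEG rates.
    """
    config.validate()
    rng = np.random.default_rng(
        [(config.seed if seed is None else seed) % (2**31), zlib.crc32(b"reprogram") % (2**31)]
    )
    derived = TruthSet()

    parent_dmcs = sorted(parent_truth.dmcs)
    keep = rng.random(len(parent_dmcs)) < config.reprogram_retention
    for coord, kept in zip(parent_dmcs, keep):
        if kept:
            derived.dmcs[coord] = parent_truth.dmcs[coord]
    avail = sorted(set(genome.cpg_list()) - set(parent_dmcs))
    n_new = int(round(config.reprogram_de_novo * len(avail)))
    if n_new > len(avail):
        raise CapacityError("de-novo DMC request exceeds available CpGs")
    if n_new:
        pick = rng.choice(len(avail), size=n_new, replace=False)
        for i in pick:
            derived.dmcs[avail[i]] = "hypo" if rng.random() < 0.5 else "hyper"

    parent_degs = sorted(parent_truth.degs)
    keep_g = rng.random(len(parent_degs)) < config.reprogram_retention_deg
    for g, kept in zip(parent_degs, keep_g):
        if kept:
            derived.degs[g] = parent_truth.degs[g]
    avail_g = sorted(set(genome.genes) - set(parent_degs))
    n_new_g = int(round(config.reprogram_de_novo_deg * len(avail_g)))
    if n_new_g > len(avail_g):
        raise CapacityError("de-novo DEG request exceeds available genes")
    if n_new_g:
        pick = rng.choice(len(avail_g), size=n_new_g, replace=False)
        sign = rng.random(n_new_g) < 0.5
        for i, s in zip(pick, sign):
            derived.degs[avail_g[i]] = config.deg_lfc * (1.0 if s else -1.0)
    return derived
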