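"""End-to-end synthetic run binding every stage of the toolkit.

simulate -> DMC/DMR calling -> DEG calling -> ERE census / enrichment /
proximity -> inherent-vs-exposure partition -> promoter proximity vs DEG
correlation -> reprogramming persistence.  The product is a single JSON
report containing the table-shaped summary blocks (per-cell-type
hypo/hyper DMC counts, up/down DEG counts, the ERE annotation census,
the partition fractions, and the conserved/corrected/de-novo persistence
accounting) plus an echo of every seed and threshold used.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import __version__
from .context import HALF_SITE_FWD, ere_census, enrichment, scan_motif, window_motif_frequency
from .expression import call_degs, deg_direction_counts
from .integration import (
    inherent_celltype_dmcs,
    partition_exposure_dmcs,
    promoter_proximity,
    proximity_deg_correlation,
    dmcs_in_degs,
)
from .io import dump_json
from .methylation import call_dmrs, direction_counts, dmc_test_table, _emit_records
from .persistence import match_degs, match_dmcs
from .simulate import SimConfig, simulate_counts, simulate_genome, simulate_methylome, simulate_reprogramming

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Thresholds and sizes for one end-to-end synthetic run."""

    seed: int = 0
    alpha: float = 0.05
    window: int = 500
    max_gap: int = 1000
    min_cpgs: int = 2
    min_coverage: int = 10
    min_cpm: float = 1.0
    n_background_draws: int = 20
    sim: SimConfig = field(default_factory=SimConfig)
    out_json: str | None = None

    def __post_init__(self) -> None:
        self.sim.seed = self.seed


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage on one synthetic dataset; returns the report dict."""
    sim = config.sim
    sim.validate()
    stage = "simulate_genome"
    try:
        genome = simulate_genome(sim)
        universe = genome.cpg_list()

        stage = "methylation"
        betas = {}
        truths = {}
        dmc_calls = {}
        dmr_calls = {}
        dmc_block = {}
        for profile in sim.cell_profiles:
            bm, truth = simulate_methylome(genome, profile, sim)
            betas[profile.name] = bm
            truths[profile.name] = truth
            table = dmc_test_table(bm)
            records = _emit_records(table, config.alpha)
            dmc_calls[profile.name] = records
            dmr_calls[profile.name] = call_dmrs(
                table, max_gap=config.max_gap, min_cpgs=config.min_cpgs, alpha=config.alpha
            )
            n_hypo, n_hyper, total = direction_counts(r.direction for r in records)
            dmc_block[profile.name] = {
                "hypomethylated": n_hypo,
                "hypermethylated": n_hyper,
                "total": total,
                "n_planted": len(truth.dmcs),
                "n_dmrs": len(dmr_calls[profile.name]),
            }

        stage = "expression"
        deg_calls = {}
        deg_block = {}
        for profile in sim.cell_profiles:
            cm, truth = simulate_counts(genome, profile, truths[profile.name], sim)
            truths[profile.name] = truth
            records = call_degs(cm, alpha=config.alpha, min_cpm=config.min_cpm)
            deg_calls[profile.name] = records
            n_down, n_up, total = deg_direction_counts(records)
            deg_block[profile.name] = {
                "down_regulated": n_down,
                "up_regulated": n_up,
                "total": total,
                "n_planted": len(truth.degs),
            }

        stage = "genomic_context"
        hits = scan_motif(genome.sequence, HALF_SITE_FWD, name="ERE_half_site")
        census = ere_census(hits, genome.tracks)
        census_block = {
            row["track"]: {"n_hits": int(row["n_hits"]), "density_per_kb": float(row["density_per_kb"])}
            for row in census.to_dict("records")
        }
        dens = {r["track"]: r["density_per_kb"] for r in census.to_dict("records")}
        census_block["enhancer_promoter_density_ratio"] = (
            dens["enhancer"] / dens["promoter"] if dens.get("promoter") else None
        )
        context_block = {}
        for profile in sim.cell_profiles:
            sites = [(r.chrom, r.pos) for r in dmc_calls[profile.name]]
            if not sites:
                context_block[profile.name] = None
                continue
            prox = window_motif_frequency(
                sites, hits, window=config.window, universe=universe,
                n_background_draws=config.n_background_draws, seed=config.seed,
                name=profile.name,
            )
            enr = enrichment(sites, genome.tracks, universe)
            context_block[profile.name] = {
                "ere_density_per_kb": prox.density_per_kb,
                "ere_background_density_per_kb": prox.background_density_per_kb,
                "ere_density_ratio": prox.ratio,
                "enrichment": [
                    {"track": e.track, "fold": e.fold_enrichment, "p": e.p_value, "fdr": e.fdr}
                    for e in enr
                ],
            }

        stage = "integration"
        inherent = inherent_celltype_dmcs(betas, alpha=config.alpha)
        partition_block = {"n_inherent_celltype_cpgs": len(inherent)}
        proximity_results = []
        dmc_deg_block = {}
        for profile in sim.cell_profiles:
            sites = [(r.chrom, r.pos) for r in dmc_calls[profile.name]]
            if sites:
                part = partition_exposure_dmcs(sites, inherent, cell_type=profile.name)
                partition_block[profile.name] = {
                    "n_exposure_dmcs": part.n_exposure,
                    "overlap_inherent": part.overlap,
                    "fraction_overlapping": part.fraction_overlapping,
                    "n_core": len(part.core),
                }
                prox = promoter_proximity(
                    sites, genome.tracks["promoter"], cell_type=profile.name,
                    n_degs=len(deg_calls[profile.name]),
                )
                proximity_results.append(prox)
                counts = dmcs_in_degs(sites, [r.gene for r in deg_calls[profile.name]], genome.genes)
                dmc_deg_block[profile.name] = {
                    "n_degs": counts.n_degs,
                    "degs_with_promoter_dmc": counts.promoter,
                    "degs_with_gene_body_dmc": counts.gene_body,
                }
        proximity_block = {
            r.cell_type: {"median_distance_bp": r.median_distance, "n_degs": r.n_degs}
            for r in proximity_results
        }
        if len(proximity_results) >= 3:
            rho, p = proximity_deg_correlation(proximity_results)
            proximity_block["spearman"] = {"rho": rho, "p": p}

        stage = "persistence"
        parent_name = (
            "ipsc" if "ipsc" in truths else sim.cell_profiles[0].name
        )
        parent = truths[parent_name]
        derived = simulate_reprogramming(parent, genome, sim)
        dmc_summary = match_dmcs(
            parent.dmc_positions, derived.dmc_positions, parent.dmcs, derived.dmcs
        )
        deg_summary = match_degs(parent.deg_genes, derived.deg_genes)
        persistence_block = {
            "parent_cell_type": parent_name,
            "dmcs": dmc_summary.as_dict(),
            "degs": deg_summary.as_dict(),
        }
    except Exception as exc:  # annotate the failing stage for the CLI
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    report = {
        "version": __version__,
        "seed": config.seed,
        "thresholds": {
            "alpha": config.alpha,
            "max_gap": config.max_gap,
            "min_cpgs": config.min_cpgs,
            "min_coverage": config.min_coverage,
            "min_cpm": config.min_cpm,
            "window": config.window,
        },
        "sim_config": {
            **{k: v for k, v in asdict(sim).items() if k != "cell_profiles"},
            "cell_profiles": [asdict(p) for p in sim.cell_profiles],
        },
        "dmc_counts": dmc_block,
        "deg_counts": deg_block,
        "ere_census": census_block,
        "ere_proximity": context_block,
        "partition": partition_block,
        "dmcs_in_degs": dmc_deg_block,
        "promoter_proximity": proximity_block,
        "persistence": persistence_block,
    }
    if config.out_json:
        Path(config.out_json).parent.mkdir(parents=True, exist_ok=True)
        dump_json(config.out_json, report)
    return report
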