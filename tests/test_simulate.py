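"""Ground-truth generator tests: determinism, planted invariants, recovery."""

import numpy as np
import pytest
from scipy import stats

import epimutkit as ek
from epimutkit.simulate import CapacityError, ConfigError

from conftest import small_sim_config


class TestGenome:
    def test_fixed_seed_is_bit_identical(self):
        g1 = ek.simulate_genome(small_sim_config(seed=7))
        g2 = ek.simulate_genome(small_sim_config(seed=7))
        assert g1.sequence == g2.sequence
        assert g1.planted_motifs == g2.planted_motifs
        for c in g1.cpg_positions:
            assert np.array_equal(g1.cpg_positions[c], g2.cpg_positions[c])

    def test_every_planted_cpg_hosts_cg(self, genome):
        for chrom, pos in genome.cpg_list():
            assert genome.sequence[chrom][pos : pos + 2] == "CG"

    def test_tracks_within_bounds_and_promoter_enhancer_disjoint(self, genome):
        for track in genome.tracks.values():
            track.validate_bounds(genome.chrom_lengths)
        prom = genome.tracks["promoter"]
        for chrom, start, end in genome.tracks["enhancer"]:
            assert not prom.contains(chrom, np.arange(start, end)).any()

    def test_each_gene_has_promoter_containing_its_tss(self, genome):
        for g in genome.genes.values():
            assert g.promoter[0] <= g.tss < g.promoter[1]
            assert g.body[0] <= g.tss < g.body[1]

    def test_planted_half_site_density_ratio(self, genome, half_site_hits):
        """4:1 enhancer:promoter per-bp half-site density by construction."""
        census = ek.ere_census(half_site_hits, genome.tracks)
        dens = dict(zip(census["track"], census["density_per_kb"]))
        assert dens["enhancer"] / dens["promoter"] == pytest.approx(4.0, rel=0.1)

    def test_scan_finds_exactly_the_planted_sites(self, genome, half_site_hits):
        # background occurrences are scrubbed, so the scan is the truth list
        assert {(h.chrom, h.start) for h in half_site_hits} == {
            (h.chrom, h.start) for h in genome.planted_motifs
        }

    def test_zero_cpgs_is_valid(self):
        cfg = small_sim_config()
        cfg.n_cpgs = 0
        g = ek.simulate_genome(cfg)
        assert g.n_cpgs == 0

    def test_over_capacity_gene_request_raises(self):
        cfg = small_sim_config()
        cfg.n_genes = 10_000
        with pytest.raises(CapacityError):
            ek.simulate_genome(cfg)


class TestMethylome:
    def test_null_profile_arms_are_exchangeable(self, genome):
        """No planted DMCs: pooled treated and control betas come from the
        same distribution (KS test non-significant at alpha=0.01)."""
        pvals = []
        for seed in range(3):
            cfg = small_sim_config(seed=seed)
            profile = ek.CellProfile("null", 0.5, "ER_none", 0.5, "promoter", 0, 0)
            bm, truth = ek.simulate_methylome(genome, profile, cfg)
            assert truth.dmcs == {}
            ks = stats.ks_2samp(bm.arm_values("treated").ravel(), bm.arm_values("control").ravel())
            pvals.append(ks.pvalue)
        assert sum(p < 0.01 for p in pvals) == 0

    def test_exact_hypo_count_from_fraction(self, genome):
        """hypo_fraction 2315/7100 with a 7100-scale request plants the exact
        split (here at 1/10 scale: 232 of 710)."""
        cfg = small_sim_config()
        profile = ek.CellProfile("germ", 0.3, "ER_none", 2315 / 7100, "promoter", 710, 0)
        _, truth = ek.simulate_methylome(genome, profile, cfg)
        n_hypo = sum(1 for d in truth.dmcs.values() if d == "hypo")
        assert len(truth.dmcs) == 710
        assert n_hypo == round(2315 / 7100 * 710) == 232

    def test_betas_in_unit_interval_and_truth_in_universe(self, genome, sim_config):
        profile = sim_config.cell_profiles[1]
        bm, truth = ek.simulate_methylome(genome, profile, sim_config)
        assert np.all((bm.values > 0) & (bm.values < 1))
        assert truth.dmc_positions <= set(genome.cpg_list())

    def test_caller_recovers_planted_dmcs(self, genome, sim_config):
        """Default effect (delta-beta 0.4, 3v3, noise sd 0.05): the Welch
        caller recovers >= 90% of planted sites against the truth list."""
        profile = sim_config.cell_profiles[2]
        bm, truth = ek.simulate_methylome(genome, profile, sim_config)
        called = {(r.chrom, r.pos) for r in ek.call_dmcs_array(bm)}
        sens = len(called & truth.dmc_positions) / len(truth.dmcs)
        assert sens >= 0.9

    def test_unknown_bias_track_is_config_error(self, genome):
        cfg = small_sim_config()
        profile = ek.CellProfile("x", 0.5, "ER_none", 0.5, "nonsense", 10, 0)
        with pytest.raises(ConfigError):
            ek.simulate_methylome(genome, profile, cfg)

    def test_determinism(self, genome, sim_config):
        profile = sim_config.cell_profiles[0]
        b1, t1 = ek.simulate_methylome(genome, profile, sim_config)
        b2, t2 = ek.simulate_methylome(genome, profile, sim_config)
        assert np.array_equal(b1.values, b2.values)
        assert t1.dmcs == t2.dmcs


class TestEmseqCounts:
    def make_beta(self, value, n=2000):
        return ek.BetaMatrix(
            np.array(["chr1"] * n, dtype=object),
            np.arange(0, 2 * n, 2),
            ["c0", "c1", "t0", "t1"],
            ["control", "control", "treated", "treated"],
            np.full((n, 4), value),
        )

    def test_beta_zero_gives_zero_methylated(self):
        counts = ek.simulate_emseq_counts(self.make_beta(0.0, n=100), depth=20)
        assert counts.meth.sum() == 0

    def test_beta_one_gives_full_methylation(self):
        counts = ek.simulate_emseq_counts(self.make_beta(1.0, n=100), depth=20)
        assert np.array_equal(counts.meth, counts.coverage)

    def test_binomial_expectation_at_half(self):
        """beta=0.5, depth=50, 10,000 draws: mean fraction within 0.5+/-0.01."""
        counts = ek.simulate_emseq_counts(self.make_beta(0.5, n=2500), depth=50, seed=5)
        frac = counts.meth.sum() / counts.coverage.sum()
        assert abs(frac - 0.5) < 0.01
        assert np.all(counts.coverage >= 1)
        assert np.all(counts.meth <= counts.coverage)


class TestCounts:
    def test_planted_up_down_truth_is_exact(self, genome):
        """694:343 up:down at full scale is recorded exactly in the truth."""
        cfg = small_sim_config()
        profile = ek.CellProfile(
            "ipsc_like", 0.7, "ER_beta_only", 0.7, "enhancer", 0, 1037,
            deg_up_fraction=694 / 1037,
        )
        cfg.n_genes = 1100
        cfg.n_cpgs = 500
        cfg.chrom_length = 6_200_000
        genome_big = ek.simulate_genome(cfg)
        cm, truth = ek.simulate_counts(genome_big, profile, ek.TruthSet(), cfg)
        ups = sum(1 for v in truth.degs.values() if v > 0)
        downs = sum(1 for v in truth.degs.values() if v < 0)
        assert (downs, ups) == (343, 694)
        assert len(truth.degs) == 1037

    def test_counts_are_nonnegative_integers(self, genome, sim_config):
        profile = sim_config.cell_profiles[3]
        cm, _ = ek.simulate_counts(genome, profile, ek.TruthSet(), sim_config)
        assert np.issubdtype(cm.counts.dtype, np.integer)
        assert (cm.counts >= 0).all()

    def test_deg_truth_subset_of_gene_universe(self, genome, sim_config):
        profile = sim_config.cell_profiles[2]
        _, truth = ek.simulate_counts(genome, profile, ek.TruthSet(), sim_config)
        assert truth.deg_genes <= set(genome.genes)


class TestReprogramming:
    def test_full_retention_no_de_novo_is_identity(self, genome, sim_config):
        profile = sim_config.cell_profiles[2]
        _, truth = ek.simulate_methylome(genome, profile, sim_config)
        cfg = small_sim_config()
        cfg.reprogram_retention = 1.0
        cfg.reprogram_de_novo = 0.0
        cfg.reprogram_retention_deg = 1.0
        cfg.reprogram_de_novo_deg = 0.0
        derived = ek.simulate_reprogramming(truth, genome, cfg)
        assert derived.dmcs == truth.dmcs

    def test_zero_rates_empty_derived(self, genome, sim_config):
        profile = sim_config.cell_profiles[2]
        _, truth = ek.simulate_methylome(genome, profile, sim_config)
        cfg = small_sim_config()
        cfg.reprogram_retention = 0.0
        cfg.reprogram_de_novo = 0.0
        derived = ek.simulate_reprogramming(truth, genome, cfg)
        assert derived.dmcs == {}

    def test_retained_count_within_binomial_interval(self, genome):
        """retention r on n parent sites: conserved ~ Binomial(n, r); the
        observation sits inside the 99% interval (mirrors the 3.7% regime)."""
        cfg = small_sim_config()
        profile = ek.CellProfile("big", 0.6, "ER_none", 0.5, "promoter", 2000, 0)
        _, truth = ek.simulate_methylome(genome, profile, cfg)
        cfg.reprogram_retention = 0.037
        cfg.reprogram_de_novo = 0.0
        n = len(truth.dmcs)
        conserved_counts = []
        for seed in range(5):
            derived = ek.simulate_reprogramming(truth, genome, cfg, seed=seed)
            s = ek.match_dmcs(truth.dmc_positions, derived.dmc_positions)
            assert s.conserved_n == s.derived_n  # no de novo
            conserved_counts.append(s.conserved_n)
        lo, hi = stats.binom.ppf([0.005, 0.995], n, 0.037)
        inside = sum(lo <= c <= hi for c in conserved_counts)
        assert inside >= 4
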