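"""Motif scanning, census, proximity and enrichment tests."""

import numpy as np
import pytest
from scipy import stats
from scipy.special import comb

import epimutkit as ek
from epimutkit.context import IUPAC, reverse_complement_iupac, scan_motif
from epimutkit.intervals import AnnotationTrack

COMP = str.maketrans("ACGT", "TGCA")


def revcomp(s):
    return s.translate(COMP)[::-1]


def naive_scan(seq, motif, max_mm):
    """Position-by-position oracle over both strands."""

    def match_count(frag, mot):
        n = 0
        for a, b in zip(frag, mot):
            bit = {"A": 1, "C": 2, "G": 4, "T": 8}.get(a, 0)
            if not bit & IUPAC[b]:
                n += 1
        return n

    hits = []
    L = len(motif)
    rc = reverse_complement_iupac(motif)
    for s in range(len(seq) - L + 1):
        frag = seq[s : s + L]
        if match_count(frag, motif) <= max_mm:
            hits.append((s, "+"))
        if match_count(frag, rc) <= max_mm:
            hits.append((s, "-"))
    return set(hits)


class TestScan:
    def test_direct_plus_strand_match(self):
        hits = scan_motif({"c": "TTAGGTCATT"}, "AGGTCA")
        assert [(h.start, h.end, h.strand) for h in hits] == [(2, 8, "+")]
        assert hits[0].matched == "AGGTCA"

    def test_reverse_complement_found_on_minus_strand(self):
        hits = scan_motif({"c": "TTAGGTCATT"}, "TGACCT")
        assert [(h.start, h.end, h.strand) for h in hits] == [(2, 8, "-")]
        assert hits[0].matched == "TGACCT"

    def test_matches_naive_oracle_with_mismatches(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=3000))
        for motif in ("AGGTCA", "GGTCANNNTGACC", "RYSWKM"):
            got = {(h.start, h.strand) for h in scan_motif({"c": seq}, motif, max_mismatches=1)}
            assert got == naive_scan(seq, motif, 1)

    def test_strand_symmetry_under_genome_reverse_complement(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=500))
        fwd = scan_motif({"c": seq}, "AGGTCA")
        rev = scan_motif({"c": revcomp(seq)}, "AGGTCA")
        L = len(seq)
        flipped = {(L - h.end, L - h.start, "-" if h.strand == "+" else "+") for h in rev}
        assert {(h.start, h.end, h.strand) for h in fwd} == flipped

    def test_genome_n_matches_nothing(self):
        assert scan_motif({"c": "NNNNNNNN"}, "NNNN") == []

    def test_invalid_iupac_is_an_error(self):
        with pytest.raises(ValueError, match="IUPAC"):
            scan_motif({"c": "ACGT"}, "AXGT")
        with pytest.raises(ValueError, match="empty"):
            scan_motif({"c": "ACGT"}, "")


class TestCensus:
    def track(self, name, ivs):
        return AnnotationTrack.from_records(name, ivs)

    def test_no_hits_gives_zero_counts(self):
        tracks = {"promoter": self.track("promoter", [("c", 0, 1000)])}
        df = ek.ere_census([], tracks)
        assert df["n_hits"].tolist() == [0]

    def test_midpoint_boundary_half_open(self):
        tracks = {"t": self.track("t", [("c", 103, 113)])}
        on_start = ek.MotifHit("c", 100, 106, "+", "m", "AGGTCA")  # midpoint 103
        on_end = ek.MotifHit("c", 110, 116, "+", "m", "AGGTCA")  # midpoint 113
        df = ek.ere_census([on_start, on_end], tracks)
        assert df["n_hits"].tolist() == [1]

    def test_hit_may_count_in_overlapping_classes(self):
        tracks = {
            "a": self.track("a", [("c", 0, 50)]),
            "b": self.track("b", [("c", 10, 60)]),
        }
        hit = ek.MotifHit("c", 20, 26, "+", "m", "AGGTCA")
        df = ek.ere_census([hit], tracks)
        assert df["n_hits"].tolist() == [1, 1]


class TestWindowFrequency:
    def test_no_hits_reports_null_ratio(self):
        res = ek.window_motif_frequency(
            [("c", 100)], [], universe=[("c", 100), ("c", 900)], n_background_draws=5
        )
        assert res.density_per_kb == 0
        assert res.ratio is None

    def test_sites_adjacent_to_every_motif_count_at_least_one(self):
        hits = [ek.MotifHit("c", p, p + 6, "+", "m", "AGGTCA") for p in range(0, 10_000, 400)]
        sites = [("c", p + 10) for p in range(0, 10_000, 400)]
        res = ek.window_motif_frequency(sites, hits, window=500)
        assert (res.per_site_counts >= 1).all()

    def test_empty_site_set_is_an_error(self):
        with pytest.raises(ValueError, match="empty"):
            ek.window_motif_frequency([], [], window=500)

    def test_er_positive_profile_beats_er_none(self, genome, half_site_hits):
        """Planted ERE-proximity bias (0.7 vs 0) shows up as a higher
        DMC-adjacent half-site density ratio for the ER-positive profile."""
        from conftest import small_sim_config

        cfg = small_sim_config()
        uni = genome.cpg_list()
        ratios = {}
        for state in ("ER_both", "ER_none"):
            profile = ek.CellProfile(state, 0.6, state, 0.5, "enhancer", 150, 0)
            _, truth = ek.simulate_methylome(genome, profile, cfg)
            res = ek.window_motif_frequency(
                sorted(truth.dmcs), half_site_hits, universe=uni,
                n_background_draws=20, seed=0,
            )
            ratios[state] = res.ratio
        assert ratios["ER_both"] > ratios["ER_none"]


class TestAnnotate:
    def test_precedence_and_intergenic(self):
        tracks = {
            "promoter": AnnotationTrack.from_records("promoter", [("c", 0, 100)]),
            "gene_body": AnnotationTrack.from_records("gene_body", [("c", 50, 200)]),
        }
        labels, tallies = ek.annotate_sites([("c", 60), ("c", 150), ("c", 500)], tracks)
        assert labels == ["promoter", "gene_body", "intergenic"]
        assert sum(tallies.values()) == 3

    def test_unknown_precedence_name_is_an_error(self):
        tracks = {"promoter": AnnotationTrack.from_records("promoter", [("c", 0, 10)])}
        with pytest.raises(ValueError, match="unknown track"):
            ek.annotate_sites([("c", 1)], tracks, precedence=("promoter", "bogus"))

    def test_tallies_match_brute_force_on_genome_sites(self, genome, rng):
        universe = genome.cpg_list()
        sites = [universe[i] for i in rng.choice(len(universe), 100, replace=False)]
        labels, tallies = ek.annotate_sites(sites, genome.tracks)
        assert sum(tallies.values()) == len(sites)
        order = [n for n in ek.context.DEFAULT_PRECEDENCE if n in genome.tracks]
        for site, label in zip(sites, labels):
            expect = "intergenic"
            for name in order:
                track = genome.tracks[name]
                if any(s <= site[1] < e for c, s, e in track if c == site[0]):
                    expect = name
                    break
            assert label == expect


class TestEnrichment:
    def test_forced_enrichment_fold(self, rng):
        universe = [("c", i) for i in range(1000)]
        track = AnnotationTrack.from_records("enhancer", [("c", 0, 100)])
        sites = [("c", i) for i in rng.choice(100, 50, replace=False)]
        rows = ek.enrichment(sites, {"enhancer": track}, universe)
        assert rows[0].fold_enrichment == pytest.approx(10.0)

    def test_uniform_sites_have_fold_near_one(self, rng):
        universe = [("c", i) for i in range(2000)]
        track = AnnotationTrack.from_records("t", [("c", 0, 1000)])
        folds = []
        for seed in range(20):
            r = np.random.default_rng(seed)
            sites = [("c", int(i)) for i in r.choice(2000, 300, replace=False)]
            folds.append(ek.enrichment(sites, {"t": track}, universe)[0].fold_enrichment)
        assert np.mean(folds) == pytest.approx(1.0, abs=0.05)

    def test_hypergeometric_tail_matches_exact_sum(self):
        """k=30, n=100, K=100, N=1000: fold 3.0 and p equals the exact
        sum-over-tail of hypergeometric point masses."""
        universe = [("c", i) for i in range(1000)]
        track = AnnotationTrack.from_records("t", [("c", 0, 100)])
        sites = [("c", i) for i in range(30)] + [("c", i) for i in range(100, 170)]
        rows = ek.enrichment(sites, {"t": track}, universe)
        assert rows[0].k == 30 and rows[0].n == 100
        assert rows[0].fold_enrichment == pytest.approx(3.0)
        exact = sum(
            comb(100, j, exact=True) * comb(900, 100 - j, exact=True)
            for j in range(30, 101)
        ) / comb(1000, 100, exact=True)
        assert rows[0].p_value == pytest.approx(float(exact), rel=1e-9)

    def test_empty_class_reports_null(self):
        universe = [("c", i) for i in range(100)]
        track = AnnotationTrack.from_records("t", [("other", 0, 10)])
        rows = ek.enrichment([("c", 1)], {"t": track}, universe)
        assert rows[0].fold_enrichment is None and rows[0].p_value is None

    def test_sites_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="subset"):
            ek.enrichment([("c", 5)], {}, [("c", 1)])
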