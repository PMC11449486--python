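"""Unit and property tests for DMC/DMR calling and site-set overlap."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import epimutkit as ek
from epimutkit.methylation import (
    BetaMatrix,
    call_dmrs,
    classify_direction,
    direction_counts,
    mvalues,
    stouffer_combine,
    dmc_test_table,
    welch_test,
)


def toy_beta(values, n_control=3, n_treated=3):
    values = np.asarray(values, dtype=float)
    n = len(values)
    samples = [f"c{i}" for i in range(n_control)] + [f"t{i}" for i in range(n_treated)]
    arm = ["control"] * n_control + ["treated"] * n_treated
    return BetaMatrix(
        np.array(["chr1"] * n, dtype=object),
        np.arange(10, 10 + 2 * n, 2),
        samples,
        arm,
        values,
    )


class TestWelchArrayCaller:
    def test_identical_arms_emit_nothing(self, rng):
        vals = rng.uniform(0.1, 0.9, size=(50, 3))
        bm = toy_beta(np.hstack([vals, vals]))
        assert ek.call_dmcs_array(bm) == []

    def test_matches_brute_force_welch_on_hand_set_betas(self, rng):
        """5 hand-set CpGs, 3v3: p-values agree with scipy's Welch test to 1e-12."""
        vals = np.array(
            [
                [0.10, 0.12, 0.11, 0.80, 0.85, 0.82],
                [0.50, 0.52, 0.49, 0.51, 0.50, 0.53],
                [0.95, 0.90, 0.93, 0.20, 0.25, 0.22],
                [0.40, 0.60, 0.50, 0.45, 0.55, 0.52],
                [0.01, 0.02, 0.015, 0.98, 0.97, 0.99],
            ]
        )
        bm = toy_beta(vals)
        table = dmc_test_table(bm)
        m = mvalues(vals)
        for i in range(5):
            expect = stats.ttest_ind(m[i, 3:], m[i, :3], equal_var=False).pvalue
            assert table["p_value"][i] == pytest.approx(expect, abs=1e-12)

    def test_zero_variance_equal_means_gets_p_one(self):
        vals = np.full((3, 6), 0.5)
        vals[1] = [0.2, 0.2, 0.2, 0.9, 0.9, 0.9]  # zero variance, different means
        table = dmc_test_table(toy_beta(vals))
        assert table["p_value"][0] == 1.0
        assert table["p_value"][2] == 1.0
        assert table["p_value"][1] == 0.0

    def test_single_replicate_arm_rejected(self):
        vals = np.random.default_rng(0).uniform(size=(5, 3))
        with pytest.raises(ValueError, match=">=2 samples"):
            dmc_test_table(toy_beta(vals, n_control=1, n_treated=2))

    def test_emitted_records_satisfy_dual_threshold_and_direction(self, rng):
        base = rng.uniform(0.3, 0.7, size=200)
        treated = base.copy()
        treated[:40] += 0.25 * np.where(rng.random(40) < 0.5, 1, -1)
        vals = np.clip(
            np.hstack(
                [
                    base[:, None] + rng.normal(0, 0.02, (200, 3)),
                    treated[:, None] + rng.normal(0, 0.02, (200, 3)),
                ]
            ),
            0.001,
            0.999,
        )
        records = ek.call_dmcs_array(toy_beta(vals))
        assert records
        for r in records:
            assert r.p_value <= 0.05 and r.fdr <= 0.05
            assert r.delta_beta != 0
            assert r.direction == ("hypo" if r.delta_beta < 0 else "hyper")
        n_hypo, n_hyper, total = direction_counts(r.direction for r in records)
        assert n_hypo + n_hyper == total == len(records)


class TestCountCaller:
    def make_counts(self, meth, cov):
        meth = np.asarray(meth)
        n = meth.shape[0]
        return ek.MethylCountMatrix(
            np.array(["chr1"] * n, dtype=object),
            np.arange(100, 100 + 2 * n, 2),
            ["c0", "c1", "t0", "t1"],
            ["control", "control", "treated", "treated"],
            meth,
            np.asarray(cov),
        )

    def test_extreme_pooled_table_is_emitted_as_hypo(self):
        """Pooled (90,10) vs (10,90) of n=100 each: z-test p < 1e-6, hypo."""
        counts = self.make_counts([[45, 45, 5, 5]], [[50, 50, 50, 50]])
        result = ek.call_dmcs_counts(counts, min_coverage=10)
        assert len(result.records) == 1
        rec = result.records[0]
        assert rec.p_value < 1e-6
        assert rec.direction == "hypo"
        # closed-form two-proportion z on the printed table
        z = (0.9 - 0.1) / np.sqrt(0.5 * 0.5 * (2 / 100))
        assert rec.p_value == pytest.approx(2 * stats.norm.sf(z), rel=1e-10)

    def test_identical_pooled_fractions_not_emitted(self):
        counts = self.make_counts([[20, 20, 20, 20]], [[40, 40, 40, 40]])
        result = ek.call_dmcs_counts(counts)
        assert result.records == []

    def test_low_coverage_sites_filtered_not_crashed(self):
        counts = self.make_counts([[1, 0, 1, 1], [2, 1, 0, 1]], [[2, 1, 2, 2], [3, 2, 1, 2]])
        result = ek.call_dmcs_counts(counts, min_coverage=10)
        assert result.records == []
        assert result.n_filtered == 2
        assert result.n_tested == 0


class TestDirection:
    @pytest.mark.parametrize(
        "control,treated,expect",
        [(0.8, 0.2, "hypo"), (0.2, 0.8, "hyper"), (0.51, 0.5, "hypo")],
    )
    def test_sign_cases(self, control, treated, expect):
        assert classify_direction(control, treated) == expect

    def test_zero_delta_is_contract_violation(self):
        with pytest.raises(ValueError, match="zero delta"):
            classify_direction(0.5, 0.5)

    def test_agrees_with_planted_truth(self, genome, sim_config):
        profile = sim_config.cell_profiles[0]
        bm, truth = ek.simulate_methylome(genome, profile, sim_config)
        records = ek.call_dmcs_array(bm)
        planted = [r for r in records if (r.chrom, r.pos) in truth.dmcs]
        assert planted
        assert all(truth.dmcs[(r.chrom, r.pos)] == r.direction for r in planted)


class TestDMR:
    def test_gap_clustering_and_min_cpgs(self):
        table = pd.DataFrame(
            {
                "chrom": ["chr1"] * 3,
                "pos": [100, 200, 5000],
                "p_value": [1e-6, 1e-6, 1e-9],
                "delta_beta": [0.3, 0.3, 0.3],
            }
        )
        regions = call_dmrs(table, max_gap=1000, min_cpgs=2)
        assert len(regions) == 1  # the singleton at 5000 fails min_cpgs
        assert (regions[0].start, regions[0].end, regions[0].n_cpgs) == (100, 201, 2)

    def test_stouffer_three_p05(self):
        """Three members at p=0.05 combine to p = norm.sf(3*1.6449/sqrt(3))."""
        assert stouffer_combine([0.05, 0.05, 0.05]) == pytest.approx(0.0021930504, rel=1e-6)

    def test_all_p_one_not_emitted(self):
        table = pd.DataFrame(
            {"chrom": ["chr1"] * 3, "pos": [10, 20, 30], "p_value": [1.0, 1.0, 1.0]}
        )
        assert call_dmrs(table, max_gap=100, min_cpgs=2) == []
        assert stouffer_combine([1.0, 1.0, 1.0]) >= 0.5

    def test_unsorted_input_is_an_error(self):
        table = pd.DataFrame(
            {"chrom": ["chr1", "chr1"], "pos": [200, 100], "p_value": [0.01, 0.01]}
        )
        with pytest.raises(ValueError, match="increasing"):
            call_dmrs(table)


class TestOverlapSets:
    def test_disjoint_and_identical(self):
        a = {("chr1", i) for i in range(5)}
        b = {("chr1", i) for i in range(10, 15)}
        out = ek.overlap_sets({"A": a, "B": b})
        assert out["venn"] == {"A": 5, "B": 5}
        out2 = ek.overlap_sets({"A": a, "B": set(a)})
        assert out2["venn"] == {"A&B": 5}
        assert out2["jaccard"]["A"]["B"] == 1.0

    def test_matches_brute_force_enumeration(self, rng):
        universe = list(range(1000))
        sets = {n: set(rng.choice(universe, 100, replace=False).tolist()) for n in "ABC"}
        out = ek.overlap_sets(sets)
        for member in set().union(*sets.values()):
            sig = "&".join(n for n in sorted(sets) if member in sets[n])
            assert sig in out["venn"]
        # exclusive cell counts re-derived by brute force
        for r in range(1, 4):
            for combo in itertools.combinations(sorted(sets), r):
                inside = set.intersection(*(sets[n] for n in combo))
                outside = set().union(*(sets[n] for n in sets if n not in combo), set())
                expect = len(inside - outside)
                got = out["venn"].get("&".join(combo), 0)
                assert got == expect


@settings(max_examples=30, deadline=None)
@given(st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=5, max_size=40))
def test_bh_emitted_set_is_subset_of_raw_alpha_set(pvals):
    """BH-adjusted values are monotone in p rank; the dual-threshold emitted
    set is always a subset of the raw p <= alpha set."""
    p = np.asarray(pvals)
    from statsmodels.stats.multitest import multipletests

    fdr = multipletests(p, method="fdr_bh")[1]
    order = np.argsort(p)
    assert np.all(np.diff(fdr[order]) >= -1e-12)
    emitted = (p <= 0.05) & (fdr <= 0.05)
    assert np.all(p[emitted] <= 0.05)
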