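"""Signature scores, rank tests vs exact oracles, permutation machinery."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from cforigin import normalization as nz
from cforigin import scoring as sc
from cforigin.atlas_basis import BasisMatrix
from cforigin.profiles import CellTypeProfile, TissueExpressionTable


def logged_matrix(values: dict, genes):
    df = pd.DataFrame(values, index=genes)
    meta = pd.DataFrame(
        {"plasma_ml": 1.0, "batch": "b", "bio_replicate": list(values)},
        index=list(values),
    )
    return nz.NormalizedCounts(values=df, stage="log_cpm_tmm", meta=meta)


def make_profile(genes):
    stats = pd.DataFrame({"gini": 0.9}, index=pd.Index(genes, name="gene"))
    return CellTypeProfile(cell_type="ct", native_tissue="t", genes=stats)


class TestSignatureScore:
    def test_sum_of_logged_values(self):
        m = logged_matrix({"s1": [2.0, 3.0, 9.0]}, ["g1", "g2", "g3"])
        s = sc.signature_score(m, {"g1", "g2"})
        assert s["s1"] == pytest.approx(5.0)

    def test_missing_genes_contribute_zero(self):
        m = logged_matrix({"s1": [2.0]}, ["g1"])
        assert sc.signature_score(m, {"g1", "absent"})["s1"] == pytest.approx(2.0)

    def test_empty_intersection_warns_zero(self):
        m = logged_matrix({"s1": [2.0]}, ["g1"])
        with pytest.warns(UserWarning, match="no profile gene"):
            s = sc.signature_score(m, {"zz"})
        assert s["s1"] == 0.0

    def test_stage_enforced(self):
        df = pd.DataFrame({"s1": [2.0]}, index=["g1"])
        meta = pd.DataFrame(
            {"plasma_ml": [1.0], "batch": "b", "bio_replicate": ["s1"]}, index=["s1"]
        )
        nc = nz.NormalizedCounts(values=df, stage="cpm_ml", meta=meta)
        with pytest.raises(ValueError, match="log_cpm_tmm"):
            sc.signature_score(nc, {"g1"})

    def test_monotone_in_expression(self):
        lo = logged_matrix({"s": [np.log1p(100.0)]}, ["g1"])
        hi = logged_matrix({"s": [np.log1p(200.0)]}, ["g1"])
        d = sc.signature_score(hi, {"g1"})["s"] - sc.signature_score(lo, {"g1"})["s"]
        assert d == pytest.approx(math.log(2), abs=0.01)


class TestDropoutFilter:
    def test_gene_zero_in_one_cohort_removed(self):
        prof = make_profile(["g1", "g2"])
        a = pd.DataFrame({"s1": [5, 1], "s2": [0, 2]}, index=["g1", "g2"])
        b = pd.DataFrame({"s3": [0, 1], "s4": [0, 3]}, index=["g1", "g2"])
        out = sc.dropout_filter(prof, a, b)
        assert out.gene_set == {"g2"}

    def test_single_nonzero_per_cohort_kept(self):
        prof = make_profile(["g1"])
        a = pd.DataFrame({"s1": [1], "s2": [0]}, index=["g1"])
        b = pd.DataFrame({"s3": [0], "s4": [2]}, index=["g1"])
        assert sc.dropout_filter(prof, a, b).gene_set == {"g1"}

    def test_all_removed_errors(self):
        prof = make_profile(["g1"])
        a = pd.DataFrame({"s1": [0]}, index=["g1"])
        b = pd.DataFrame({"s2": [1]}, index=["g1"])
        with pytest.raises(ValueError, match="dropout"):
            sc.dropout_filter(prof, a, b)


def mwu_exact_oracle(a, b, alternative):
    """Exact U-test p by enumerating all group assignments of the pooled values."""
    pooled = list(a) + list(b)
    n1 = len(a)

    def u_stat(group_a, group_b):
        return sum((x > y) + 0.5 * (x == y) for x in group_a for y in group_b)

    observed = u_stat(a, b)
    count = total = 0
    for comb in itertools.combinations(range(len(pooled)), n1):
        ga = [pooled[i] for i in comb]
        gb = [pooled[i] for i in range(len(pooled)) if i not in comb]
        u = u_stat(ga, gb)
        total += 1
        if alternative == "less":
            count += u <= observed
        elif alternative == "greater":
            count += u >= observed
        else:
            mean_u = len(a) * len(b) / 2
            count += abs(u - mean_u) >= abs(observed - mean_u)
    return count / total


class TestCompareCohorts:
    def test_identical_groups(self):
        comp = sc.compare_cohorts([1, 2, 3, 4], [1, 2, 3, 4])
        assert comp.p > 0.9
        assert comp.U == pytest.approx(8.0)

    def test_separated_groups_exact(self):
        comp = sc.compare_cohorts([1, 2, 3], [4, 5, 6], alternative="less")
        assert comp.U == 0
        assert comp.p == pytest.approx(1 / 20)
        assert comp.method == "exact"

    @pytest.mark.parametrize("alternative", ["less", "greater", "two-sided"])
    def test_matches_enumeration_oracle(self, rng, alternative):
        for _ in range(5):
            a = list(rng.choice(100, size=int(rng.integers(3, 7)), replace=False))
            b = list(
                rng.choice(np.arange(100, 200), size=int(rng.integers(3, 7)), replace=False)
            )
            comp = sc.compare_cohorts(a, b, alternative=alternative)
            assert comp.p == pytest.approx(mwu_exact_oracle(a, b, alternative), abs=1e-12)

    def test_u_range_invariant(self, rng):
        a, b = rng.random(10), rng.random(12)
        comp = sc.compare_cohorts(a, b)
        assert 0 <= comp.U <= len(a) * len(b)

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            sc.compare_cohorts([1, 2], [3, 4, 5])


class TestCalibratePvalues:
    def test_all_equal_scores(self):
        scores = np.ones(20)
        labels = np.array([0] * 10 + [1] * 10)
        p, null = sc.calibrate_pvalues(scores, labels, n_perm=1000, seed=0)
        assert p == pytest.approx(1000 / 1001)
        assert len(null) == 1000

    def test_lower_bound(self, rng):
        scores = np.concatenate([rng.random(10), rng.random(10) + 50])
        labels = np.array([0] * 10 + [1] * 10)
        p, _ = sc.calibrate_pvalues(scores, labels, n_perm=500, seed=0)
        assert p == pytest.approx(1 / 501)

    def test_deterministic(self, rng):
        scores = rng.random(16)
        labels = np.array([0, 1] * 8)
        p1, n1 = sc.calibrate_pvalues(scores, labels, n_perm=200, seed=3)
        p2, n2 = sc.calibrate_pvalues(scores, labels, n_perm=200, seed=3)
        assert p1 == p2
        assert np.array_equal(n1, n2)

    def test_requires_two_groups(self, rng):
        with pytest.raises(ValueError, match="2 groups"):
            sc.calibrate_pvalues(rng.random(5), np.zeros(5), n_perm=100)


def hypergeom_bruteforce(universe, draw, marked, at_least):
    """Enumerate all subsets of the universe of the draw size."""
    hits = total = 0
    for comb in itertools.combinations(range(universe), draw):
        total += 1
        if sum(1 for i in comb if i < marked) >= at_least:
            hits += 1
    return hits / total


class TestHypergeomOverlap:
    def test_no_overlap_tiny_sets(self):
        p = sc.hypergeom_overlap({"a"}, {"b"}, universe_size=10000)
        assert p == pytest.approx(1.0, abs=1e-3)

    def test_complete_sets(self):
        genes = {f"g{i}" for i in range(20)}
        assert sc.hypergeom_overlap(genes, genes, universe_size=20) == pytest.approx(1.0)

    def test_full_overlap_combinatorics(self):
        deg = {f"g{i}" for i in range(5)}
        p = sc.hypergeom_overlap(deg, deg, universe_size=20)
        assert p == pytest.approx(1 / math.comb(20, 5), rel=1e-12)

    def test_matches_subset_enumeration(self):
        # universe of 12, draw 4, 5 marked, overlap 3
        deg = {f"g{i}" for i in range(3)} | {"x1"}
        prof = {f"g{i}" for i in range(3)} | {"y1", "y2"}
        p = sc.hypergeom_overlap(deg, prof, universe_size=12)
        assert p == pytest.approx(hypergeom_bruteforce(12, 4, 5, 3), rel=1e-12)


class TestGiniPermutation:
    def make_table(self):
        cts = [f"ct{i}" for i in range(6)]
        specific = pd.DataFrame(0.01, index=[f"s{i}" for i in range(8)], columns=cts)
        for i in range(8):
            specific.iloc[i, i % 6] = 5.0
        flat = pd.DataFrame(1.0, index=[f"f{i}" for i in range(8)], columns=cts)
        return pd.concat([specific, flat])

    def test_maximal_separation_minimal_p(self):
        table = self.make_table()
        res = sc.gini_permutation_test(
            [f"s{i}" for i in range(8)], [f"f{i}" for i in range(8)], table,
            n_perm=1000, seed=0,
        )
        assert res["p"] == pytest.approx(1 / 1001)
        assert res["observed_diff"] > 0.5

    def test_same_distribution_large_p(self):
        table = self.make_table()
        res = sc.gini_permutation_test(
            [f"s{i}" for i in range(4)], [f"s{i}" for i in range(4, 8)], table,
            n_perm=1000, seed=1,
        )
        assert res["p"] > 0.05

    def test_empty_group_errors(self):
        with pytest.raises(ValueError, match="non-empty"):
            sc.gini_permutation_test([], ["f1"], self.make_table(), n_perm=100)

    def test_p_at_least_one_over_nplus1(self):
        table = self.make_table()
        res = sc.gini_permutation_test(
            [f"s{i}" for i in range(8)], [f"f{i}" for i in range(8)], table,
            n_perm=500, seed=2,
        )
        assert res["p"] >= 1 / 501

    def test_subset_relation_enforced(self):
        B = {"a", "b", "c"}
        with pytest.raises(ValueError, match="subset"):
            sc.tissue_specific_only_set(B, {"z"}, {"a"}, {"b"})
        T = sc.tissue_specific_only_set(B, {"a"}, {"a", "b"}, {"c"})
        assert T == {"b", "c"}


class TestUncaptured:
    def make_inputs(self, basis_genes, tissue_genes_by_tissue, sample_values):
        genes = sorted(set(basis_genes) | {g for gs in tissue_genes_by_tissue.values() for g in gs})
        tissues = list(tissue_genes_by_tissue)
        nx = pd.DataFrame(0.0, index=genes, columns=tissues)
        cat, spec = {}, {}
        for t, gs in tissue_genes_by_tissue.items():
            for g in gs:
                nx.loc[g, t] = 50.0
                cat[g] = "Tissue enriched"
                spec[g] = t
        for g in genes:
            cat.setdefault(g, "Low tissue specificity")
            spec.setdefault(g, "")
        table = TissueExpressionTable(
            nx=nx, category=pd.Series(cat), specific_tissues=pd.Series(spec)
        )
        values = pd.DataFrame({"s1": [sample_values.get(g, 0.0) for g in genes]}, index=genes)
        meta = pd.DataFrame(
            {"plasma_ml": [1.0], "batch": "b", "bio_replicate": ["s1"]}, index=["s1"]
        )
        cpm = nz.NormalizedCounts(values=values, stage="cpm_ml", meta=meta)
        bm = pd.DataFrame(
            1.0, index=pd.Index(sorted(basis_genes)), columns=["ct1", "ct2"]
        )
        basis = BasisMatrix(matrix=bm, gene_stats=pd.DataFrame())
        return cpm, basis, table

    def test_all_genes_in_basis_zero_tally(self):
        cpm, basis, table = self.make_inputs(
            ["g1", "g2"], {"testis": ["g1"], "liver": ["g2"]}, {"g1": 10, "g2": 10}
        )
        counts, _ = sc.uncaptured_tissue_genes(cpm, basis, table)
        assert (counts.values == 0).all()

    def test_planted_uncaptured_counted(self):
        cpm, basis, table = self.make_inputs(
            ["g1"], {"testis": ["t1", "t2", "t3"], "liver": ["g1"]},
            {"g1": 10, "t1": 5, "t2": 5, "t3": 5},
        )
        counts, summary = sc.uncaptured_tissue_genes(cpm, basis, table)
        assert counts.loc["testis", "s1"] == 3
        assert counts.loc["liver", "s1"] == 0  # g1 is in the basis rows
        assert summary.loc["testis", "mean"] == 3

    def test_low_nx_excluded(self):
        cpm, basis, table = self.make_inputs(
            ["g1"], {"testis": ["t1"], "liver": ["g1"]}, {"t1": 5, "g1": 2}
        )
        table.nx.loc["t1", "testis"] = 9.0  # below the NX >= 10 cut
        counts, _ = sc.uncaptured_tissue_genes(cpm, basis, table)
        assert counts.loc["testis", "s1"] == 0

    def test_anti_monotone_in_basis_rows(self):
        cpm, basis, table = self.make_inputs(
            ["g1", "t1"], {"testis": ["t1", "t2"], "liver": ["g1"]},
            {"g1": 10, "t1": 5, "t2": 5},
        )
        full, _ = sc.uncaptured_tissue_genes(cpm, basis, table)
        smaller = BasisMatrix(matrix=basis.matrix.loc[["g1"]], gene_stats=pd.DataFrame())
        reduced, _ = sc.uncaptured_tissue_genes(cpm, smaller, table)
        assert (reduced.values >= full.values).all()


class TestDetectMarkers:
    def make_db(self):
        return pd.DataFrame(
            {
                "cell_type": ["hep"] * 12 + ["neuron"] * 2 + ["mouse only"],
                "gene": [f"h{i}" for i in range(12)] + ["n0", "n1"] + ["m0"],
                "sensitivity": [0.95] * 15,
                "specificity": [0.05] * 15,
                "species": ["Hs"] * 14 + ["Mm"],
            }
        )

    def test_counts_and_display_rule(self):
        genes = [f"h{i}" for i in range(12)] + ["n0", "n1", "m0"]
        values = {
            "s1": [1.0] * 10 + [0.0] * 2 + [1.0, 0.0, 1.0],
            "s2": [1.0] * 10 + [0.0] * 2 + [0.0, 0.0, 1.0],
        }
        m = logged_matrix(values, genes)
        counts, shown = sc.detect_markers(m, self.make_db())
        assert counts.loc["hep", "s1"] == 10
        assert "hep" in shown  # mean 10 > 5
        assert "neuron" not in shown  # mean 0.5
        assert "mouse only" not in counts.index  # species filter

    def test_zero_expression_not_counted(self):
        m = logged_matrix({"s1": [0.0]}, ["h0"])
        counts, _ = sc.detect_markers(m, self.make_db())
        assert counts.loc["hep", "s1"] == 0

    def test_boundary_mean_five(self):
        genes = [f"h{i}" for i in range(12)]
        m5 = logged_matrix({"s1": [1.0] * 5 + [0.0] * 7, "s2": [1.0] * 5 + [0.0] * 7}, genes)
        counts, shown = sc.detect_markers(m5, self.make_db())
        assert counts.loc["hep"].mean() == 5.0 and "hep" not in shown
        m6 = logged_matrix({"s1": [1.0] * 6 + [0.0] * 6, "s2": [1.0] * 5 + [0.0] * 7}, genes)
        _, shown6 = sc.detect_markers(m6, self.make_db())
        assert "hep" in shown6  # mean 5.5 > 5
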