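"""Clustering, volcano flags, Fisher enrichment and BH adjustment vs oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from proteoconsensus import (
    GeneSet,
    GeneSetDB,
    SimConfig,
    Thresholds,
    ValidationError,
    bh_adjust,
    cluster_proteins,
    filter_terms,
    fisher_enrichment,
    simulate_experiment,
    simulate_gene_sets,
    standardize,
    volcano_table,
)


class TestStandardize:
    def test_closed_form_row(self):
        m = pd.DataFrame([[1.0, 2.0, 3.0]], index=["P1"])
        out, flat = standardize(m)
        assert out.loc["P1"].tolist() == [-1.0, 0.0, 1.0]
        assert flat == []

    def test_constant_row_becomes_zeros_and_is_flagged(self):
        m = pd.DataFrame([[5.0, 5.0, 5.0], [1.0, 2.0, 3.0]], index=["P1", "P2"])
        out, flat = standardize(m)
        assert (out.loc["P1"] == 0).all()
        assert flat == ["P1"]

    def test_output_moments_on_random_rows(self):
        rng = np.random.default_rng(3)
        m = pd.DataFrame(rng.normal(20, 4, size=(50, 8)))
        out, _ = standardize(m)
        assert np.allclose(out.mean(axis=1), 0, atol=1e-12)
        assert np.allclose(out.std(axis=1, ddof=1), 1, atol=1e-12)


def brute_force_complete_linkage(dist: np.ndarray):
    """O(n^3) agglomeration oracle returning sorted merge heights."""
    clusters = {i: {i} for i in range(len(dist))}
    heights = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            h = max(dist[i, j] for i in clusters[a] for j in clusters[b])
            if best is None or h < best[0]:
                best = (h, a, b)
        h, a, b = best
        heights.append(h)
        clusters[a] = clusters[a] | clusters[b]
        del clusters[b]
    return sorted(heights)


class TestClustering:
    def test_identical_rows_merge_first_at_height_zero(self):
        rng = np.random.default_rng(4)
        m = pd.DataFrame(rng.normal(0, 1, size=(5, 6)), index=[f"P{i}" for i in range(5)])
        m.loc["P1"] = m.loc["P0"] * 2 + 1  # perfectly correlated: d = 0
        res = cluster_proteins(m)
        first = res["linkage"][0]
        assert first[2] == pytest.approx(0.0, abs=1e-12)
        merged = {res["labels"][int(first[0])], res["labels"][int(first[1])]}
        assert merged == {"P0", "P1"}

    def test_anticorrelated_rows_merge_last(self):
        base = np.array([1.0, 2.0, 3.0, 2.5, 4.0])
        m = pd.DataFrame(
            [base, -base, base + np.array([0.1, -0.2, 0.15, 0.0, -0.1])],
            index=["P0", "P1", "P2"],
        )
        res = cluster_proteins(m)
        assert res["linkage"][-1][2] == pytest.approx(2.0, abs=0.1)

    def test_merge_heights_match_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        m = pd.DataFrame(rng.normal(0, 1, size=(12, 10)), index=[f"P{i:02d}" for i in range(12)])
        res = cluster_proteins(m)
        dist = 1 - np.corrcoef(m.to_numpy())
        np.fill_diagonal(dist, 0)
        expected = brute_force_complete_linkage(dist)
        assert np.allclose(sorted(res["linkage"][:, 2]), expected, atol=1e-10)

    def test_leaf_order_invariant_under_row_permutation(self):
        rng = np.random.default_rng(8)
        m = pd.DataFrame(rng.normal(0, 1, size=(10, 6)), index=[f"P{i}" for i in range(10)])
        res1 = cluster_proteins(m)
        res2 = cluster_proteins(m.sample(frac=1, random_state=1))
        assert res1["leaf_order"] == res2["leaf_order"]

    def test_zero_variance_rows_excluded(self):
        m = pd.DataFrame(
            [[1.0, 1.0, 1.0], [1.0, 2.0, 3.0], [3.0, 1.0, 2.0]], index=["flat", "a", "b"]
        )
        res = cluster_proteins(m)
        assert res["excluded"] == ["flat"]
        assert set(res["labels"]) == {"a", "b"}


class TestVolcano:
    def test_strict_boundary_flags(self):
        res = pd.DataFrame({
            "accession": ["P1", "P2"], "contrast": "short", "dataset": 1,
            "p": [0.05, 0.01], "delta_log2": [1.0, 0.678], "fc": [2.0, 1.6],
        })
        vt = volcano_table(res, Thresholds())
        assert not vt.loc[0, "pass_p"]          # p exactly at alpha fails
        assert vt.loc[0, "pass_fc"]
        assert vt.loc[1, "pass_both"]

    def test_flags_match_predicate_oracle(self):
        rng = np.random.default_rng(10)
        res = pd.DataFrame({
            "accession": [f"P{i}" for i in range(200)],
            "contrast": "long", "dataset": 3,
            "p": rng.uniform(0, 0.1, 200),
            "delta_log2": rng.normal(0, 1, 200),
        })
        res["fc"] = np.where(res["delta_log2"] >= 0, 2 ** res["delta_log2"], -(2 ** -res["delta_log2"]))
        th = Thresholds()
        vt = volcano_table(res, th)
        expected = (res["p"] < th.alpha) & (res["fc"].abs() > th.fc_abs)
        assert (vt["pass_both"] == expected).all()


def hypergeom_tail_oracle(a, n_de, k_term, n_bg):
    """P[X >= a] for X ~ Hypergeom(N=n_bg, K=k_term, n=n_de), by enumeration."""
    total = math.comb(n_bg, n_de)
    return sum(
        math.comb(k_term, i) * math.comb(n_bg - k_term, n_de - i)
        for i in range(a, min(n_de, k_term) + 1)
    ) / total


class TestFisher:
    def test_empty_de_set_gives_p_one(self):
        db = GeneSetDB([GeneSet("T1", "", ("G1", "G2"))])
        out = fisher_enrichment(set(), {"G1", "G2", "G3"}, db)
        assert (out["p"] == 1.0).all()

    def test_term_covering_background_gives_p_one(self):
        bg = {f"G{i}" for i in range(100)}
        de = {f"G{i}" for i in range(10)}
        db = GeneSetDB([GeneSet("ALL", "", tuple(sorted(bg)))])
        out = fisher_enrichment(de, bg, db)
        assert out.loc[0, "p"] == pytest.approx(1.0)

    def test_de_outside_background_rejected(self):
        db = GeneSetDB([GeneSet("T1", "", ("G1",))])
        with pytest.raises(ValidationError, match="GX"):
            fisher_enrichment({"GX"}, {"G1", "G2"}, db)

    def test_p_matches_exhaustive_hypergeometric_enumeration(self):
        """One-sided Fisher p on a 20-gene universe equals the combinatorial tail sum."""
        rng = np.random.default_rng(11)
        bg = [f"G{i:02d}" for i in range(20)]
        for trial in range(25):
            de = set(rng.choice(bg, size=rng.integers(1, 10), replace=False))
            term = tuple(rng.choice(bg, size=rng.integers(1, 15), replace=False))
            db = GeneSetDB([GeneSet("T", "", term)])
            out = fisher_enrichment(de, set(bg), db)
            a = len(de & set(term))
            expected = hypergeom_tail_oracle(a, len(de), len(term), 20)
            assert out.loc[0, "p"] == pytest.approx(expected, rel=1e-9)

    def test_counts_satisfy_invariants(self):
        rng = np.random.default_rng(12)
        bg = {f"G{i}" for i in range(50)}
        de = set(rng.choice(sorted(bg), size=12, replace=False))
        db = GeneSetDB([
            GeneSet(f"T{j}", "", tuple(rng.choice(sorted(bg), size=10, replace=False)))
            for j in range(8)
        ])
        out = fisher_enrichment(de, bg, db)
        assert (out["n_de_in_term"] <= np.minimum(out["n_de"], out["n_bg_in_term"])).all()
        assert (out["q"] >= out["p"] - 1e-12).all()
        assert out["q"].between(0, 1).all()


def bh_step_up_oracle(p):
    """Independent BH: q_i = min_{j >= i} p_(j) * m / j, mapped back to input order."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


class TestBH:
    def test_single_p_is_unchanged(self):
        assert bh_adjust([0.03]) == pytest.approx([0.03])

    def test_hand_computed_example(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert q == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_matches_independent_step_up_on_random_vectors(self):
        rng = np.random.default_rng(13)
        for _ in range(100):
            p = rng.uniform(0, 1, size=rng.integers(1, 40))
            assert bh_adjust(p) == pytest.approx(bh_step_up_oracle(p), rel=1e-12)

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.2])


class TestFilterTerms:
    @pytest.fixture()
    def rows(self):
        return pd.DataFrame({
            "term": ["T1", "T2", "T3", "T4"],
            "n_de_in_term": [4, 5, 10, 6],
            "q": [0.01, 0.01, 0.05, 0.2],
        })

    def test_boundary_semantics(self, rows):
        out = filter_terms(rows)
        # T1: exactly 4 DE members -> removed; T3: q exactly 0.05 -> removed
        assert out["term"].tolist() == ["T2"]

    def test_matches_predicate_oracle(self):
        rng = np.random.default_rng(14)
        rows = pd.DataFrame({
            "term": [f"T{i}" for i in range(100)],
            "n_de_in_term": rng.integers(0, 12, 100),
            "q": rng.uniform(0, 0.1, 100),
        })
        out = filter_terms(rows, q_max=0.05, min_de_in_term=4)
        expected = rows[(rows["q"] < 0.05) & (rows["n_de_in_term"] > 4)]
        assert out["term"].tolist() == expected["term"].tolist()


def test_planted_enrichment_is_recovered():
    """Terms built to oversample true-DE genes rank above null terms by q."""
    hits = 0
    n_seeds = 10
    for seed in range(n_seeds):
        cfg = SimConfig(n_human_proteins=400, n_mouse_proteins=1, de_fraction=0.15, seed=100 + seed)
        *_, truth = simulate_experiment(cfg)
        db = simulate_gene_sets(truth, n_terms=30, size_range=(15, 40), n_enriched_terms=3, seed=seed)
        de = set(truth.loc[truth["de_short"] | truth["de_long"], "gene"])
        out = fisher_enrichment(de, set(truth["gene"]), db)
        out["planted"] = [gs.description.startswith("enriched") for gs in db]
        if out.loc[out["planted"], "q"].mean() < out.loc[~out["planted"], "q"].mean():
            hits += 1
    assert hits / n_seeds >= 0.9
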