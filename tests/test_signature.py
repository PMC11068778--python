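"""Signature construction and scoring: t-tests, BH, permutation set test."""

import itertools
import math

import anndata as ad
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dtpkit import (
    GeneSignature,
    SimExpressionTruth,
    bh_adjust,
    build_intersection_signature,
    gen_labeled_expression,
    per_gene_tstat,
    permutation_set_test,
    score_cells,
)


def _adata(values, labels, genes=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[1])]
    return ad.AnnData(
        X=values,
        obs=pd.DataFrame(
            {"label": pd.Categorical(labels)},
            index=[f"c{i}" for i in range(values.shape[0])],
        ),
        var=pd.DataFrame(index=genes),
    )


def _pooled_t_oracle(a, b):
    """Textbook pooled-variance two-sample t and two-sided p."""
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1)) / (na + nb - 2)
    t = (np.mean(a) - np.mean(b)) / math.sqrt(sp2 * (1 / na + 1 / nb))
    p = 2 * stats.t.sf(abs(t), na + nb - 2)
    return t, p


class TestPerGeneTstat:
    def test_matches_textbook_formula(self):
        a, b = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        adata = _adata(np.array(a + b).reshape(6, 1), ["A"] * 3 + ["B"] * 3)
        table = per_gene_tstat(adata, target="A", normalize="raw")
        t_exp, p_exp = _pooled_t_oracle(a, b)
        assert table["t"].iloc[0] == pytest.approx(t_exp)
        assert table["t"].iloc[0] == pytest.approx(-3.674, abs=1e-3)
        assert table["p"].iloc[0] == pytest.approx(p_exp)
        assert table["p"].iloc[0] == pytest.approx(0.0214, abs=2e-4)
        assert table["direction"].iloc[0] == "down"

    def test_identical_classes_give_t0_p1(self):
        adata = _adata(np.ones((6, 3)), ["A"] * 3 + ["B"] * 3)
        table = per_gene_tstat(adata, target="A", normalize="raw")
        assert (table["t"] == 0).all()
        assert (table["p"] == 1).all()

    def test_label_swap_flips_every_t(self):
        rng = np.random.default_rng(1)
        x = rng.lognormal(0, 1, size=(12, 20))
        adata = _adata(x, ["A"] * 6 + ["B"] * 6)
        ta = per_gene_tstat(adata, target="A")["t"]
        tb = per_gene_tstat(adata, target="B")["t"]
        assert np.allclose(ta, -tb)

    def test_random_gene_matches_oracle_after_normalization(self):
        rng = np.random.default_rng(2)
        x = rng.lognormal(0, 1, size=(10, 5))
        adata = _adata(x, ["A"] * 5 + ["B"] * 5)
        table = per_gene_tstat(adata, target="A")
        norm = np.log1p(x / x.sum(axis=1, keepdims=True) * 1e4)
        for j in range(5):
            t_exp, p_exp = _pooled_t_oracle(norm[:5, j], norm[5:, j])
            assert table["t"].iloc[j] == pytest.approx(t_exp)
            assert table["p"].iloc[j] == pytest.approx(p_exp)

    def test_single_cell_class_fails(self):
        adata = _adata(np.ones((3, 2)), ["A", "B", "B"])
        with pytest.raises(ValueError):
            per_gene_tstat(adata, target="A")


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.07])[0] == pytest.approx(0.07)

    def test_step_up_hand_computation(self):
        assert bh_adjust([0.01, 0.02, 0.03]).tolist() == pytest.approx([0.03] * 3)

    def test_all_ones(self):
        assert bh_adjust([1.0, 1.0, 1.0]).tolist() == [1.0, 1.0, 1.0]

    def test_monotone_in_rank(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=50)
        q = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()
        assert (q >= p - 1e-12).all()

    def test_idempotent_rejection_set(self):
        rng = np.random.default_rng(4)
        p = np.concatenate([rng.uniform(0, 1e-4, 5), rng.uniform(size=45)])
        q1 = bh_adjust(p)
        q2 = bh_adjust(q1)
        for alpha in (0.01, 0.05, 0.2):
            assert ((q1 <= alpha) == (q2 <= alpha)).all()

    def test_out_of_range_fails(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


def _stat_table(up_genes, all_genes):
    q = pd.Series(1.0, index=all_genes)
    q[list(up_genes)] = 0.001
    return pd.DataFrame(
        {"q": q, "direction": ["up" if g in up_genes else "down" for g in all_genes]},
        index=all_genes,
    )


class TestBuildIntersectionSignature:
    GENES = list("ABCDEF")

    def test_intersection_of_up_sets(self):
        tables = {
            "t1": _stat_table({"A", "B", "C"}, self.GENES),
            "t2": _stat_table({"B", "C", "D"}, self.GENES),
            "t3": _stat_table({"C", "B"}, self.GENES),
        }
        sig = build_intersection_signature(tables)
        assert sig.genes == ["B", "C"]
        assert sig.provenance == ["t1", "t2", "t3"]

    def test_disjoint_sets_warn_and_return_empty(self):
        tables = {
            "t1": _stat_table({"A"}, self.GENES),
            "t2": _stat_table({"B"}, self.GENES),
        }
        with pytest.warns(UserWarning):
            sig = build_intersection_signature(tables)
        assert sig.is_empty

    def test_recovers_planted_genes_across_conditions(self):
        genes = [f"g{i:03d}" for i in range(200)]
        planted = genes[:30]
        tables = {}
        for seed, name in enumerate(["pc9", "h3122", "h358"]):
            truth = SimExpressionTruth(
                n_cells_per_class={"RD": 50, "nonRD": 50},
                genes=genes,
                signature_genes=planted,
                target_class="RD",
                effect_size=2.0,
                seed=seed,
            )
            tables[name] = per_gene_tstat(gen_labeled_expression(truth), target="RD")
        sig = build_intersection_signature(tables)
        assert set(sig.genes) == set(planted)


class TestPermutationSetTest:
    def test_exact_mode_matches_exhaustive_enumeration(self):
        # 3+3 cells: all 20 label splits enumerated independently
        rng = np.random.default_rng(5)
        x = rng.lognormal(0, 1, size=(6, 8))
        labels = ["A"] * 3 + ["B"] * 3
        adata = _adata(x, labels)
        sig_genes = ["g0", "g1", "g2"]
        res = permutation_set_test(
            adata, sig_genes, target="A", method="exact", normalize="raw"
        )
        assert res.n_permutations == 19

        def mean_t(mask):
            ts = [
                _pooled_t_oracle(x[mask, j], x[~mask, j])[0] for j in range(3)
            ]
            return np.mean(ts)

        obs_mask = np.array([True] * 3 + [False] * 3)
        t_obs = mean_t(obs_mask)
        assert res.t_obs == pytest.approx(t_obs)
        count = 0
        for combo in itertools.combinations(range(6), 3):
            mask = np.zeros(6, dtype=bool)
            mask[list(combo)] = True
            if abs(mean_t(mask)) >= abs(t_obs) - 1e-12:
                count += 1  # includes the observed labeling itself
        assert res.p == pytest.approx(count / 20)

    def test_null_pvalues_roughly_uniform(self):
        # no planted effect: sampled-permutation p over replicates ~ uniform
        pvals = []
        for seed in range(200):
            rng = np.random.default_rng(10_000 + seed)
            x = rng.lognormal(0, 1, size=(16, 12))
            adata = _adata(x, ["A"] * 8 + ["B"] * 8)
            res = permutation_set_test(
                adata, ["g0", "g1", "g2", "g3"], target="A", B=99,
                seed=seed, normalize="raw",
            )
            pvals.append(res.p)
        ks = stats.kstest(pvals, "uniform").statistic
        assert ks < 0.1

    def test_planted_effect_saturates_significance(self):
        genes = [f"g{i:03d}" for i in range(100)]
        truth = SimExpressionTruth(
            n_cells_per_class={"RD": 40, "nonRD": 40},
            genes=genes,
            signature_genes=genes[:20],
            target_class="RD",
            effect_size=2.0,
            seed=7,
        )
        adata = gen_labeled_expression(truth)
        res = permutation_set_test(adata, genes[:20], target="RD", B=200, seed=1)
        assert res.p == pytest.approx(1 / 201)
        assert res.t_obs > 0

    def test_invariant_to_class_relabeling(self):
        rng = np.random.default_rng(8)
        x = rng.lognormal(0, 1, size=(10, 6))
        adata = _adata(x, ["A"] * 5 + ["B"] * 5)
        pa = permutation_set_test(adata, ["g0", "g1"], target="A", B=99, seed=2).p
        pb = permutation_set_test(adata, ["g0", "g1"], target="B", B=99, seed=2).p
        assert pa == pb

    def test_empty_signature_fails(self):
        adata = _adata(np.ones((4, 2)), ["A", "A", "B", "B"])
        with pytest.raises(ValueError):
            permutation_set_test(adata, [], target="A")


class TestScoreCells:
    def test_single_gene_signature_returns_that_gene(self):
        x = np.array([[1.0, 9.0], [4.0, 6.0]])
        adata = _adata(x, ["A", "B"])
        scores = score_cells(adata, ["g0"], normalize="raw")
        assert scores.tolist() == [1.0, 4.0]

    def test_two_gene_mean(self):
        x = np.array([[2.0, 4.0]])
        adata = _adata(x, ["A"])
        # single cell is fine for scoring (no class structure needed)
        assert score_cells(adata, ["g0", "g1"], normalize="raw").iloc[0] == 3.0

    def test_planted_class_scores_higher(self):
        genes = [f"g{i:03d}" for i in range(150)]
        truth = SimExpressionTruth(
            n_cells_per_class={"RD": 40, "nonRD": 40},
            genes=genes,
            signature_genes=genes[:25],
            target_class="RD",
            effect_size=2.0,
            seed=9,
        )
        adata = gen_labeled_expression(truth)
        scores = score_cells(adata, genes[:25])
        rd = scores[(adata.obs["label"] == "RD").to_numpy()]
        non = scores[(adata.obs["label"] == "nonRD").to_numpy()]
        u = stats.mannwhitneyu(rd, non, alternative="greater")
        assert u.pvalue < 1e-6
        assert rd.mean() > non.mean()

    def test_missing_genes_policy(self):
        adata = _adata(np.ones((2, 2)), ["A", "B"])
        with pytest.raises(ValueError):
            score_cells(adata, ["g0", "nope"], normalize="raw")
        scores = score_cells(
            adata, ["g0", "nope"], normalize="raw", allow_missing=True
        )
        assert len(scores) == 2
        with pytest.raises(ValueError):
            score_cells(adata, ["nope"], normalize="raw", allow_missing=True)


def test_signature_requires_unique_genes():
    with pytest.raises(ValueError):
        GeneSignature(genes=["A", "A"])
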