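"""Alteration matrices, background model, pair tests."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from crisprselect.cooccur import (
    build_alteration_matrix,
    discover_pair_test,
    discover_screen,
    fisher_cooccurrence_screen,
    fisher_pair_test,
    fit_background,
)
from crisprselect.stats import fisher_exact_2x2


def toy_matrix(rows, genes=None, samples=None):
    arr = np.asarray(rows, dtype=np.int8)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    return pd.DataFrame(arr, index=genes, columns=samples)


class TestBuildMatrix:
    MUTS = pd.DataFrame([
        dict(sample="A", gene="TP53", variant_class="missense",
             pathogenicity_label="pathogenic"),
        dict(sample="A", gene="TP53", variant_class="stopgain",
             pathogenicity_label="pathogenic"),
        dict(sample="A", gene="TP53", variant_class="frameshift",
             pathogenicity_label="likely_pathogenic"),
        dict(sample="B", gene="TP53", variant_class="missense",
             pathogenicity_label="benign"),
        dict(sample="B", gene="RB1", variant_class="splice",
             pathogenicity_label="likely_pathogenic"),
    ])

    def test_multiple_variants_binarize_to_one(self):
        mats = build_alteration_matrix(self.MUTS, ["TP53", "RB1"], ["A", "B"])
        assert mats["all"].loc["TP53", "A"] == 1

    def test_benign_variants_filtered(self):
        mats = build_alteration_matrix(self.MUTS, ["TP53", "RB1"], ["A", "B"])
        assert mats["all"].loc["TP53", "B"] == 0
        assert mats["all"].loc["RB1", "B"] == 1

    def test_strata_kept_separate(self):
        mats = build_alteration_matrix(
            self.MUTS, ["TP53"], ["A", "B"], strata={"A": "WES", "B": "panel"}
        )
        assert set(mats) == {"WES", "panel"}
        assert list(mats["WES"].columns) == ["A"]

    def test_empty_table_warns_all_zero(self, caplog):
        empty = self.MUTS.iloc[0:0]
        mats = build_alteration_matrix(empty, ["TP53"], ["A"])
        assert mats["all"].to_numpy().sum() == 0

    def test_empty_gene_list_rejected(self):
        with pytest.raises(ValueError):
            build_alteration_matrix(self.MUTS, [])


class TestBackgroundModel:
    def test_uniform_margins_give_constant_density(self):
        # circulant pattern: every row and every column sums to 2 of 4
        M = toy_matrix([[1, 1, 0, 0], [0, 1, 1, 0], [0, 0, 1, 1], [1, 0, 0, 1]])
        bg = fit_background(M)
        np.testing.assert_allclose(bg.p.to_numpy(), 0.5, atol=1e-7)

    def test_margins_match_within_tolerance(self):
        rng = np.random.default_rng(0)
        M = toy_matrix((rng.random((12, 40)) < 0.25).astype(int))
        bg = fit_background(M, tol=1e-8)
        P, A = bg.p.to_numpy(), M.to_numpy()
        assert np.abs(P.sum(1) - A.sum(1)).max() < 1e-6
        assert np.abs(P.sum(0) - A.sum(0)).max() < 1e-6

    def test_three_by_three_matches_independent_solver(self):
        from scipy.optimize import root

        M = toy_matrix([[1, 1, 0], [1, 0, 0], [1, 1, 1]])
        # row margins (2,1,3): row 3 is all-one (degenerate); use another
        M = toy_matrix([[1, 1, 0], [1, 0, 0], [0, 1, 1]])
        bg = fit_background(M, tol=1e-12, max_iter=2000)

        r, c = M.to_numpy().sum(1), M.to_numpy().sum(0)

        def equations(theta):
            mu, nu = theta[:3], theta[3:]
            P = 1 / (1 + np.exp(-(mu[:, None] + nu[None, :])))
            return np.concatenate([P.sum(1) - r, (P.sum(0) - c)[:-1], [nu[0]]])

        sol = root(equations, np.zeros(6), tol=1e-14)
        mu, nu = sol.x[:3], sol.x[3:]
        P_ref = 1 / (1 + np.exp(-(mu[:, None] + nu[None, :])))
        np.testing.assert_allclose(bg.p.to_numpy(), P_ref, atol=1e-8)

    def test_degenerate_rows_reported_and_margins_still_match(self):
        M = toy_matrix([[0, 0, 0, 0], [1, 0, 1, 0], [1, 1, 0, 1]])
        bg = fit_background(M)
        assert bg.degenerate_genes == ("g0",)
        P, A = bg.p.to_numpy(), M.to_numpy()
        assert np.abs(P.sum(1) - A.sum(1)).max() < 1e-6


class TestDiscoverPairTest:
    def test_never_altered_gene_gives_p_one(self):
        M = toy_matrix([[0, 0, 0, 0], [1, 0, 1, 0]])
        bg = fit_background(M)
        res = discover_pair_test(M, bg, "g0", "g1", "exclusive")
        assert res.overlap == 0
        assert res.p == 1.0

    def test_matches_joint_enumeration_small_n(self):
        """Poisson-binomial overlap null vs explicit 2^(2n) enumeration
        of the joint alteration outcomes given the background."""
        rng = np.random.default_rng(3)
        n = 6
        M = toy_matrix((rng.random((4, n)) < 0.5).astype(int))
        bg = fit_background(M, tol=1e-10, max_iter=3000)
        pa = bg.p.loc["g0"].to_numpy()
        pb = bg.p.loc["g1"].to_numpy()
        k = int((M.loc["g0"].astype(bool) & M.loc["g1"].astype(bool)).sum())
        p_lo = p_up = 0.0
        for a_bits in itertools.product([0, 1], repeat=n):
            wa = math.prod(p if b else 1 - p for p, b in zip(pa, a_bits))
            for b_bits in itertools.product([0, 1], repeat=n):
                wb = math.prod(p if b else 1 - p for p, b in zip(pb, b_bits))
                s = sum(x and y for x, y in zip(a_bits, b_bits))
                p_lo += wa * wb * (s <= k)
                p_up += wa * wb * (s >= k)
        excl = discover_pair_test(M, bg, "g0", "g1", "exclusive").p
        cooc = discover_pair_test(M, bg, "g0", "g1", "cooccurring").p
        assert excl == pytest.approx(p_lo, abs=1e-10)
        assert cooc == pytest.approx(p_up, abs=1e-10)

    def test_symmetric_in_gene_order(self):
        rng = np.random.default_rng(4)
        M = toy_matrix((rng.random((5, 30)) < 0.3).astype(int))
        bg = fit_background(M)
        a = discover_pair_test(M, bg, "g1", "g3", "exclusive")
        b = discover_pair_test(M, bg, "g3", "g1", "exclusive")
        assert a.p == pytest.approx(b.p, abs=1e-14)

    def test_absent_gene_rejected(self):
        M = toy_matrix([[1, 0], [0, 1]])
        bg = fit_background(M)
        with pytest.raises(KeyError):
            discover_pair_test(M, bg, "g0", "nope")

    def test_single_stratum_screen_equals_direct_test(self):
        rng = np.random.default_rng(5)
        M = toy_matrix((rng.random((6, 40)) < 0.3).astype(int))
        res = discover_screen({"only": M}, [("g0", "g1")], "exclusive")
        bg = fit_background(M)
        direct = discover_pair_test(M, bg, "g0", "g1", "exclusive")
        assert res[0].p == pytest.approx(direct.p, abs=1e-12)


class TestFisherScreen:
    def test_delegates_to_fisher_exact(self):
        rng = np.random.default_rng(6)
        M = toy_matrix((rng.random((4, 25)) < 0.4).astype(int))
        [res] = fisher_cooccurrence_screen(M, [("g0", "g1")])
        a = M.loc["g0"].astype(bool).to_numpy()
        b = M.loc["g1"].astype(bool).to_numpy()
        table = [
            [int((a & b).sum()), int((a & ~b).sum())],
            [int((~a & b).sum()), int((~a & ~b).sum())],
        ]
        assert res.p == pytest.approx(fisher_exact_2x2(table).p, abs=1e-14)

    def test_identical_rows_are_maximal_cooccurrence(self):
        M = toy_matrix([[1, 1, 0, 0, 1, 0], [1, 1, 0, 0, 1, 0]])
        [res] = fisher_cooccurrence_screen(M, [("g0", "g1")])
        assert res.direction == "cooccurring"
        # minimal achievable two-sided p for these margins: the observed
        # table and its equally probable mirror
        assert res.p == pytest.approx(2 / math.comb(6, 3), abs=1e-12)

    def test_disjoint_covering_rows_are_exclusive(self):
        M = toy_matrix([[1, 1, 1, 0, 0, 0], [0, 0, 0, 1, 1, 1]])
        [res] = fisher_cooccurrence_screen(M, [("g0", "g1")])
        assert res.direction == "exclusive"
        assert res.p == pytest.approx(2 / math.comb(6, 3), abs=1e-12)

    def test_onesided_exclusive_tail(self):
        M = toy_matrix([[1, 1, 1, 0, 0, 0], [0, 0, 0, 1, 1, 1]])
        res = fisher_pair_test(M, "g0", "g1", "exclusive")
        assert res.p == pytest.approx(1 / math.comb(6, 3), abs=1e-12)
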