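import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from scipy.special import comb

from mstrans import enrichment as en
from mstrans.transcription import GeneSet


def hypergeom_upper_tail(k, N, nA, nB):
    """Brute-force enumeration of P(X >= k)."""
    total = comb(N, nB, exact=True)
    return sum(
        comb(nA, x, exact=True) * comb(N - nA, nB - x, exact=True)
        for x in range(k, min(nA, nB) + 1)
    ) / total


class TestModeratedDE:
    def _null(self, n_genes=300, n=8, seed=0):
        rng = np.random.default_rng(seed)
        expr = pd.DataFrame(
            rng.normal(7, 1, size=(2 * n, n_genes)),
            index=[f"s{i}" for i in range(2 * n)],
            columns=[f"g{i}" for i in range(n_genes)],
        )
        groups = pd.Series(
            ["case"] * n + ["control"] * n, index=expr.index
        )
        return expr, groups

    def test_d0_zero_recovers_ordinary_t(self):
        expr, groups = self._null(seed=1)
        res = en.moderated_de(expr, groups, d0_override=0)
        a = expr.iloc[:8].to_numpy()
        b = expr.iloc[8:].to_numpy()
        t, p = stats.ttest_ind(a, b)
        np.testing.assert_allclose(res.table["t_mod"], t, atol=1e-10)
        np.testing.assert_allclose(res.table["p"], p, atol=1e-10)

    def test_infinite_prior_uses_common_variance(self):
        expr, groups = self._null(seed=2)
        res = en.moderated_de(expr, groups, d0_override=math.inf)
        # all genes share one variance => |t| proportional to |lfc|
        ratio = res.table["t_mod"] / res.table["log2fc"]
        np.testing.assert_allclose(ratio, ratio.iloc[0], rtol=1e-10)

    def test_planted_up_gene_labelled(self):
        rng = np.random.default_rng(3)
        expr = pd.DataFrame(
            rng.normal(7, 0.1, size=(12, 50)),
            columns=[f"g{i}" for i in range(50)],
        )
        expr.iloc[:6, 0] += 2.0
        groups = pd.Series(["case"] * 6 + ["control"] * 6, index=expr.index)
        res = en.moderated_de(expr, groups)
        assert res.table.loc["g0", "label"] == "up"
        assert "g0" in res.up.genes

    def test_null_calibration(self):
        fracs = []
        for rep in range(20):
            expr, groups = self._null(n_genes=500, seed=100 + rep)
            res = en.moderated_de(expr, groups)
            fracs.append((res.table["p"] < 0.01).mean())
        assert np.mean(fracs) == pytest.approx(0.01, abs=0.005)

    def test_zero_variance_gene_errors(self):
        expr, groups = self._null()
        expr.iloc[:, 5] = 3.0
        with pytest.raises(ValueError, match="zero variance"):
            en.moderated_de(expr, groups)

    def test_estimated_d0_positive(self):
        expr, groups = self._null(seed=4)
        res = en.moderated_de(expr, groups)
        assert res.d0 > 0
        assert res.s0_sq > 0


class TestFisherOverlap:
    def test_paper_contingency(self):
        res = en.overlap_from_counts(
            k=176, nA=1932, nB=1092, N=20177, m_comparisons=2,
            alternative="two-sided",
        )
        assert res.pc == pytest.approx(5.43e-12, rel=2e-3)
        assert round(100 * res.background_fraction, 1) == 0.9

    def test_zero_overlap(self):
        res = en.overlap_from_counts(k=0, nA=5, nB=4, N=50)
        assert res.p == pytest.approx(1.0)
        assert res.pc == 1.0

    def test_small_enumeration_oracle(self):
        res = en.overlap_from_counts(k=3, nA=5, nB=4, N=20)
        assert res.p == pytest.approx(
            hypergeom_upper_tail(3, 20, 5, 4), abs=1e-12
        )

    @settings(max_examples=100, deadline=None)
    @given(st.data())
    def test_property_matches_enumeration(self, data):
        N = data.draw(st.integers(2, 30))
        nA = data.draw(st.integers(1, N))
        nB = data.draw(st.integers(1, N))
        k_lo = max(0, nA + nB - N)
        k = data.draw(st.integers(k_lo, min(nA, nB)))
        res = en.overlap_from_counts(k=k, nA=nA, nB=nB, N=N)
        assert res.p == pytest.approx(
            hypergeom_upper_tail(k, N, nA, nB), abs=1e-10
        )
        assert res.pc >= res.p - 1e-15

    def test_pc_monotone_in_m(self):
        r1 = en.overlap_from_counts(k=3, nA=5, nB=4, N=20, m_comparisons=1)
        r4 = en.overlap_from_counts(k=3, nA=5, nB=4, N=20, m_comparisons=4)
        assert r4.pc >= r1.pc

    def test_subset_validation(self):
        a = GeneSet("a", ("g1", "g2"))
        b = GeneSet("b", ("g2", "gX"))
        with pytest.raises(ValueError, match="gX"):
            en.fisher_overlap(a, b, ["g1", "g2", "g3"])

    def test_set_based_counts(self):
        a = GeneSet("a", ("g1", "g2", "g3"))
        b = GeneSet("b", ("g2", "g3", "g4"))
        res = en.fisher_overlap(a, b, [f"g{i}" for i in range(1, 11)])
        assert (res.k, res.nA, res.nB, res.N) == (2, 3, 3, 10)


class TestOverlapSummary:
    def test_figure_fractions(self):
        res = en.overlap_from_counts(k=176, nA=1932, nB=1092, N=20177)
        assert en.overlap_summary(res)["background_percent"] == 0.9
        res = en.overlap_from_counts(k=126, nA=2139, nB=1092, N=20177)
        assert en.overlap_summary(res)["background_percent"] == 0.6

    @pytest.mark.parametrize(
        "k,nB,expected",
        [(139, 1160, 0.12), (195, 1770, 0.11), (33, 684, 0.048), (71, 746, 0.095)],
    )
    def test_table_gene_ratios(self, k, nB, expected):
        res = en.overlap_from_counts(k=k, nA=2000, nB=nB, N=20177)
        assert en.overlap_summary(res)["gene_ratio"] == expected


class TestPSI:
    def test_perfectly_specific_gene(self):
        rng = np.random.default_rng(0)
        x = pd.DataFrame(
            rng.lognormal(0, 0.3, size=(150, 4)),
            columns=["astro", "neuron", "oligo", "micro"],
            index=[f"g{i}" for i in range(150)],
        )
        x.iloc[0] = [0.0, 12.0, 0.0, 0.0]
        res = en.psi_compute(x, B_perm=200, seed=1)
        assert res.psi.iloc[0]["neuron"] == pytest.approx(1 / 201)
        assert (res.psi.iloc[0].drop("neuron") >= 0.5).all()
        assert "g0" in res.enriched["neuron"].genes

    def test_null_calibration_single(self):
        rng = np.random.default_rng(1)
        x = pd.DataFrame(
            rng.lognormal(0, 0.5, size=(800, 4)), columns=list("abcd")
        )
        res = en.psi_compute(x, B_perm=300, seed=2)
        frac = (res.psi < 0.05).to_numpy().mean()
        assert frac == pytest.approx(0.05, abs=0.02)

    def test_rescaling_invariance(self):
        rng = np.random.default_rng(2)
        x = pd.DataFrame(
            rng.lognormal(0, 0.5, size=(100, 3)), columns=list("abc")
        )
        r1 = en.psi_compute(x, B_perm=150, seed=3)
        r2 = en.psi_compute(x * 100.0, B_perm=150, seed=3)
        pd.testing.assert_frame_equal(r1.psi, r2.psi)

    def test_planted_recovery_and_downstream_overlap(self):
        rng = np.random.default_rng(3)
        G = 2000
        genes = [f"g{i}" for i in range(G)]
        x = pd.DataFrame(
            rng.lognormal(1, 0.3, size=(G, 4)),
            columns=["astro", "neuron", "oligo", "micro"],
            index=genes,
        )
        planted = genes[:100]
        x.loc[planted] *= 0.2
        x.loc[planted, "neuron"] *= 40
        res = en.psi_compute(x, B_perm=400, seed=4)
        recovered = set(res.enriched["neuron"].genes) & set(planted)
        assert len(recovered) >= 90
        pls_neg = GeneSet("PLS1-", tuple(planted[:80]) + tuple(genes[200:220]))
        overlap = en.fisher_overlap(
            pls_neg, res.enriched["neuron"], genes, m_comparisons=4
        )
        assert overlap.pc < 0.05

    def test_validation(self):
        x = pd.DataFrame({"a": [1.0, 2.0]})
        with pytest.raises(ValueError, match="cell types"):
            en.psi_compute(x, B_perm=100)
        x2 = pd.DataFrame({"a": [1.0, -2.0], "b": [1.0, 2.0]})
        with pytest.raises(ValueError, match="non-negative"):
            en.psi_compute(x2, B_perm=100)


class TestORA:
    def test_full_universe_set_p_one(self):
        bg = [f"g{i}" for i in range(30)]
        query = GeneSet("q", tuple(bg[:5]))
        coll = {"all": GeneSet("all", tuple(bg))}
        res = en.ora_collection(query, coll, bg)
        assert res.loc[0, "p"] == pytest.approx(1.0)

    def test_query_equals_collection_set_minimal_p(self):
        bg = [f"g{i}" for i in range(12)]
        target = tuple(bg[:4])
        query = GeneSet("q", target)
        coll = {
            "hit": GeneSet("hit", target),
            "other": GeneSet("other", tuple(bg[4:8])),
        }
        res = en.ora_collection(query, coll, bg)
        assert res.loc[0, "set"] == "hit"
        # minimal attainable p by enumeration: all 4 of 4 drawn
        assert res.loc[0, "p"] == pytest.approx(
            hypergeom_upper_tail(4, 12, 4, 4), abs=1e-12
        )

    def test_planted_term_top_ranked(self):
        rng = np.random.default_rng(5)
        bg = [f"g{i}" for i in range(500)]
        pls_neg = tuple(bg[:50])
        term = tuple(pls_neg[:40]) + tuple(bg[100:110])
        coll = {
            "planted": GeneSet("planted", term),
            "noise1": GeneSet("n1", tuple(rng.choice(bg, 50, replace=False))),
            "noise2": GeneSet("n2", tuple(rng.choice(bg, 30, replace=False))),
        }
        res = en.ora_collection(GeneSet("q", pls_neg), coll, bg)
        assert res.loc[0, "set"] == "planted"
        assert res.loc[0, "pc"] < 0.05

    def test_empty_collection_errors(self):
        with pytest.raises(ValueError):
            en.ora_collection(GeneSet("q", ("a",)), {}, ["a"])
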