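"""Cis windows, pair building, additive regression and BH-FDR."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from cll_eqtl import eqtl_core as eq
from cll_eqtl import synthetic_data as synth


def gene(gene_id="g", chrom="1", strand="+", tss=1_000_000, tes=1_010_000, probes=("p1",)):
    return eq.GeneModel(gene_id, chrom, strand, tss, tes, tuple(probes))


class TestCisWindow:
    def test_plus_strand_offsets(self):
        win = eq.cis_window(gene())
        assert (win.start_bp, win.end_bp) == (700_000, 1_110_000)

    def test_minus_strand_mirrored(self):
        win = eq.cis_window(gene(strand="-", tss=1_010_000, tes=1_000_000))
        assert (win.start_bp, win.end_bp) == (900_000, 1_310_000)

    def test_clipped_at_chromosome_start(self):
        win = eq.cis_window(gene(tss=100_000, tes=110_000))
        assert win.start_bp == 1

    def test_strand_unaware_treats_minus_like_plus(self):
        win = eq.cis_window(
            gene(strand="-", tss=1_010_000, tes=1_000_000), strand_aware=False
        )
        assert (win.start_bp, win.end_bp) == (700_000, 1_110_000)

    def test_invalid_strand_orientation_rejected(self):
        with pytest.raises(ValueError):
            gene(strand="-", tss=1_000_000, tes=1_010_000)


class TestBuildPairs:
    def snps(self, positions, chrom="1"):
        return pd.DataFrame(
            {
                "snp_id": [f"s{i}" for i in range(len(positions))],
                "chrom": chrom,
                "pos": list(positions),
            }
        )

    def test_snp_exactly_at_window_start_included(self):
        pairs = eq.build_pairs(self.snps([700_000]), [gene()])
        assert len(pairs) == 1

    def test_snp_one_bp_outside_excluded(self):
        pairs = eq.build_pairs(self.snps([699_999]), [gene()])
        assert pairs.empty

    def test_probeless_gene_contributes_nothing(self):
        pairs = eq.build_pairs(self.snps([1_000_000]), [gene(probes=())])
        assert pairs.empty

    def test_deterministic_order_and_many_to_many(self):
        genes = [
            gene("gA", probes=("pa1", "pa2")),
            gene("gB", tss=1_005_000, tes=1_015_000, probes=("pb1",)),
        ]
        pairs = eq.build_pairs(self.snps([1_000_000, 1_002_000]), genes)
        assert len(pairs) == 6  # 2 SNPs × (2 + 1) probes
        assert list(pairs.columns) == ["snp_id", "probe_id", "gene_id"]
        resorted = pairs.sort_values(["snp_id", "probe_id"]).reset_index(drop=True)
        # order is (chrom, pos, probe_id): s0 rows precede s1 rows
        assert list(pairs["snp_id"][:3]) == ["s0"] * 3


class TestAdditiveRegression:
    def test_constant_expression_flat_slope(self):
        fit = eq.additive_regression([0, 1, 2, 1, 0], [3.0] * 5)
        assert fit.slope == pytest.approx(0.0)
        assert fit.raw_p == pytest.approx(1.0)

    def test_perfect_fit(self):
        fit = eq.additive_regression([0, 1, 2], [1.0, 2.0, 3.0])
        assert fit.slope == pytest.approx(1.0)
        assert fit.intercept == pytest.approx(1.0)

    def test_missing_pairs_dropped(self):
        g = [0, 1, 2, np.nan, 1]
        y = [1.0, 2.0, 3.0, 9.0, np.nan]
        fit = eq.additive_regression(g, y)
        assert fit.n_used == 3
        assert fit.slope == pytest.approx(1.0)

    def test_zero_variance_excluded(self):
        with pytest.raises(eq.UntestablePair):
            eq.additive_regression([1, 1, 1, 1], [1.0, 2.0, 3.0, 4.0])

    def test_too_few_samples_excluded(self):
        with pytest.raises(eq.UntestablePair):
            eq.additive_regression([0, 1], [1.0, 2.0])

    def test_p_value_agrees_with_permutation_oracle(self):
        rng = np.random.default_rng(0)
        n, n_perm = 60, 10_000
        for _ in range(25):
            g = rng.integers(0, 3, size=n).astype(float)
            if np.ptp(g) == 0:
                continue
            y = rng.standard_normal(n)
            fit = eq.additive_regression(g, y)
            # permutation distribution of |t| (equivalently |r|)
            perms = rng.permuted(np.tile(y, (n_perm, 1)), axis=1)
            out = eq.regress_many(np.tile(g, (n_perm, 1)), perms)
            p_perm = (1 + np.sum(np.abs(out["t_statistic"]) >= abs(fit.t_statistic) - 1e-12)) / (
                n_perm + 1
            )
            se = np.sqrt(fit.raw_p * (1 - fit.raw_p) / n_perm)
            assert abs(p_perm - fit.raw_p) < 3 * se + 2 / n_perm

    def test_regress_many_matches_linregress_rowwise(self):
        rng = np.random.default_rng(1)
        G = rng.integers(0, 3, size=(20, 30)).astype(float)
        Y = rng.standard_normal((20, 30))
        out = eq.regress_many(G, Y)
        for i in range(20):
            if np.ptp(G[i]) == 0:
                assert np.isnan(out["slope"][i])
                continue
            fit = stats.linregress(G[i], Y[i])
            assert out["slope"][i] == pytest.approx(fit.slope)
            assert out["raw_p"][i] == pytest.approx(fit.pvalue, rel=1e-9)


def naive_bh(p, m):
    """O(m²) reference: adjusted_i = min over j with p_j >= p_i of m*p_j/rank_j."""
    p = np.asarray(p, float)
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranks = np.empty(n, int)
    ranks[order] = np.arange(1, n + 1)
    adj = np.empty(n)
    for i in range(n):
        candidates = [
            min(1.0, m * p[j] / ranks[j]) for j in range(n) if p[j] >= p[i] or ranks[j] >= ranks[i]
        ]
        adj[i] = min(candidates)
    return adj


class TestBhAdjust:
    def test_hand_stepup_example(self):
        adj = eq.bh_adjust([0.01, 0.02, 0.03], m=3)
        assert adj == pytest.approx([0.03, 0.03, 0.03])

    def test_all_ones_capped(self):
        assert eq.bh_adjust([1.0, 1.0]) == pytest.approx([1.0, 1.0])

    def test_rejects_invalid_inputs(self):
        with pytest.raises(ValueError):
            eq.bh_adjust([0.0, 0.5])
        with pytest.raises(ValueError):
            eq.bh_adjust([0.1, 0.2], m=1)

    def test_matches_statsmodels_when_m_equals_length(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(2)
        for _ in range(50):
            p = rng.uniform(1e-6, 1, size=rng.integers(1, 40))
            _, sm_adj, _, _ = multipletests(p, method="fdr_bh")
            assert eq.bh_adjust(p) == pytest.approx(sm_adj, rel=1e-12)

    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=25), st.integers(0, 50))
    @settings(max_examples=200, deadline=None)
    def test_properties_and_naive_oracle(self, p, extra_m):
        p = np.asarray(p)
        m = p.size + extra_m
        adj = eq.bh_adjust(p, m=m)
        assert np.all(adj >= p - 1e-15)
        assert np.all(adj <= 1.0)
        # order isotonic with raw p
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)
        assert adj == pytest.approx(naive_bh(p, m), rel=1e-12)

    def test_rejection_set_equals_classical_stepup(self):
        rng = np.random.default_rng(3)
        for q in (0.05, 0.2):
            for _ in range(30):
                p = rng.uniform(1e-5, 1, size=50) ** 2
                adj = eq.bh_adjust(p)
                # classical: largest k with p_(k) <= k q / m
                srt = np.sort(p)
                ks = np.nonzero(srt <= (np.arange(1, 51) * q / 50))[0]
                thresh = srt[ks[-1]] if ks.size else 0.0
                assert np.array_equal(adj <= q, p <= thresh) or np.array_equal(
                    adj < q, p <= thresh
                )


class TestEffectDirection:
    @pytest.mark.parametrize(
        "slope,expected", [(-0.4, "down"), (0.4, "up"), (0.0, "undirected")]
    )
    def test_direction(self, slope, expected):
        assert eq.effect_direction(slope) == expected


class TestCallSignificant:
    def test_empty_input(self):
        sig, summary = eq.call_significant(pd.DataFrame())
        assert sig.empty
        assert summary == {"unique_snps": 0, "per_gene": {}}

    def test_snp_shared_between_genes_counts_once_overall(self):
        df = pd.DataFrame(
            {
                "snp_id": ["a", "a", "b"],
                "gene_id": ["g1", "g2", "g1"],
                "adjusted_p": [0.1, 0.1, 0.5],
            }
        )
        sig, summary = eq.call_significant(df, 0.2)
        assert summary["unique_snps"] == 1
        assert summary["per_gene"] == {"g1": 1, "g2": 1}


class TestPipelineInvariance:
    def test_results_invariant_to_sample_and_snp_order(self, study_fx):
        panel, expr = study_fx.panel, study_fx.expression
        pairs = eq.build_pairs(panel.loci, study_fx.genes)
        base = eq.run_pair_tests(panel, expr, pairs)
        rng = np.random.default_rng(0)
        s_order = rng.permutation(panel.n_samples)
        l_order = rng.permutation(len(panel.loci))
        from cll_eqtl.genotype_ld import GenotypePanel

        shuffled = GenotypePanel(
            sample_ids=[panel.sample_ids[i] for i in s_order],
            loci=panel.loci.iloc[l_order].reset_index(drop=True),
            genotypes=panel.genotypes[np.ix_(s_order, l_order)],
            haplotypes=None,
        )
        perm = eq.run_pair_tests(shuffled, expr, pairs)
        merged = base.merge(
            perm, on=["snp_id", "probe_id"], suffixes=("_a", "_b")
        )
        assert len(merged) == len(base)
        assert np.allclose(merged["slope_a"], merged["slope_b"])
        assert np.allclose(merged["raw_p_a"], merged["raw_p_b"])
        assert np.allclose(merged["adjusted_p_a"], merged["adjusted_p_b"])
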