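"""PWM log-odds scoring, exact score null, and allele-disruption tests."""

import itertools

import numpy as np
import pytest

from cll_eqtl import tfbs_pwm as tf


def uniform_pwm(length=3, motif_id="U"):
    return tf.PWM(motif_id, "uniform", np.full((length, 4), 10.0))


def consensus_pwm(consensus: str, strength=100.0, off=1.0, motif_id="C"):
    counts = np.full((len(consensus), 4), off)
    for i, base in enumerate(consensus):
        counts[i, tf.BASE_INDEX[base]] = strength
    return tf.PWM(motif_id, f"cons_{consensus}", counts)


class TestLogOdds:
    def test_uniform_counts_uniform_background_all_zero(self):
        assert np.allclose(tf.log_odds(uniform_pwm()), 0.0)

    def test_single_base_column_limit(self):
        # count 10 for A only, pseudocount -> 0: score(A) -> log2(4)
        pwm = tf.PWM("S", "single", np.array([[10.0, 0, 0, 0]]), pseudocount=1e-9)
        assert tf.log_odds(pwm)[0, 0] == pytest.approx(2.0, abs=1e-6)

    def test_hand_computed_toy_matrix(self):
        counts = np.array([[8.0, 0, 0, 2], [0, 5, 5, 0], [1, 1, 1, 7]])
        pwm = tf.PWM("T", "toy", counts, pseudocount=0.8)
        lom = tf.log_odds(pwm)
        bg = 0.25
        expected_00 = np.log2(((8 + 0.8 * 0.25) / (10 + 0.8)) / bg)
        expected_13 = np.log2(((0 + 0.8 * 0.25) / (10 + 0.8)) / bg)
        assert lom[0, 0] == pytest.approx(expected_00)
        assert lom[1, 3] == pytest.approx(expected_13)

    def test_zero_column_requires_pseudocount(self):
        with pytest.raises(ValueError):
            tf.PWM("Z", "zero", np.zeros((2, 4)), pseudocount=0.0)


class TestScanBest:
    def test_planted_consensus_is_best_window(self):
        pwm = consensus_pwm("ACGT")
        seq = "TTTTTACGTTTTT"
        score, offset, strand = tf.scan_best(seq, pwm)
        assert (offset, strand) == (5, "+")

    def test_reverse_complement_symmetry(self):
        pwm = consensus_pwm("ACGGT")
        rng = np.random.default_rng(0)
        for _ in range(10):
            seq = "".join(rng.choice(list("ACGT"), size=15))
            s1, _, _ = tf.scan_best(seq, pwm)
            s2, _, _ = tf.scan_best(tf.reverse_complement(seq), pwm)
            assert s2 == pytest.approx(s1)

    def test_matches_bruteforce_over_all_windows(self):
        pwm = consensus_pwm("ACG", strength=7, off=2)
        lom = tf.log_odds(pwm)
        rng = np.random.default_rng(1)
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGT"), size=8))
            best = -np.inf
            for s in (seq, tf.reverse_complement(seq)):
                for o in range(len(s) - 2):
                    sc = sum(lom[i, tf.BASE_INDEX[s[o + i]]] for i in range(3))
                    best = max(best, sc)
            got, _, _ = tf.scan_best(seq, pwm)
            assert got == pytest.approx(best)

    def test_center_restriction_ignores_far_windows(self):
        pwm = consensus_pwm("AAAA")
        # strong site far from the centre must not win a centred scan
        seq = "AAAA" + "CGCGCGC" + "T" + "CGCGCG"
        unrestricted, off_u, _ = tf.scan_best(seq, pwm)
        restricted, off_r, _ = tf.scan_best(seq, pwm, center=11)
        assert off_u == 0
        assert 8 <= off_r <= 11
        assert restricted < unrestricted

    def test_sequence_shorter_than_motif_rejected(self):
        with pytest.raises(ValueError):
            tf.scan_best("AC", consensus_pwm("ACGT"))


class TestExactScorePmf:
    def test_single_position_pmf_is_background_weighted_scores(self):
        pwm = tf.PWM("L1", "one", np.array([[5.0, 1, 1, 1]]))
        pmf = tf.exact_score_pmf(pwm, bin_width=0.001)
        assert pmf.probs.sum() == pytest.approx(1.0, abs=1e-9)
        lom = tf.log_odds(pwm)[0]
        binned = np.round(lom / 0.001).astype(int)
        expected = {}
        for b, base_bin in enumerate(binned):
            expected[base_bin] = expected.get(base_bin, 0.0) + 0.25
        assert dict(zip(pmf.bins.tolist(), pmf.probs.tolist())) == pytest.approx(expected)

    @pytest.mark.parametrize("length", [2, 3, 5])
    def test_matches_exhaustive_enumeration(self, length):
        rng = np.random.default_rng(length)
        counts = rng.integers(0, 20, size=(length, 4)).astype(float) + 0.5
        pwm = tf.PWM("E", "enum", counts)
        bw = 0.01
        pmf = tf.exact_score_pmf(pwm, bin_width=bw)
        lom = tf.log_odds(pwm)
        binned = np.round(lom / bw).astype(int)
        enum: dict[int, float] = {}
        for word in itertools.product(range(4), repeat=length):
            key = int(sum(binned[i, b] for i, b in enumerate(word)))
            enum[key] = enum.get(key, 0.0) + 0.25**length
        got = dict(zip(pmf.bins.tolist(), pmf.probs.tolist()))
        assert got == pytest.approx(enum, abs=1e-12)

    def test_mass_conservation_fuzz(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            counts = rng.uniform(0, 30, size=(rng.integers(1, 7), 4))
            pmf = tf.exact_score_pmf(tf.PWM("F", "fuzz", counts))
            assert pmf.probs.sum() == pytest.approx(1.0, abs=1e-9)

    def test_binding_p_monotone_in_score(self):
        pwm = consensus_pwm("ACGTA")
        pmf_f = tf.exact_score_pmf(pwm)
        pmf_r = tf.exact_score_pmf(pwm)
        scores = np.linspace(-5, 10, 30)
        ps = [tf.binding_p_value(s, pmf_f, pmf_r, 5) for s in scores]
        assert all(b <= a + 1e-12 for a, b in zip(ps, ps[1:]))

    def test_nonpositive_bin_width_rejected(self):
        with pytest.raises(ValueError):
            tf.exact_score_pmf(uniform_pwm(), bin_width=0.0)


def make_context(snp_id, left, right, a, b):
    return tf.AlleleContext(snp_id, left, right, a, b)


class TestAlleleEffect:
    def test_identical_alleles_no_difference(self):
        pwm = consensus_pwm("ACA")
        ctx = make_context("snp", "AC", "CA", "A", "A")
        res = tf.allele_effect(ctx, pwm, n_null=200, seed=0)
        assert res.delta == 0.0
        if res.difference_p is not None:
            assert res.difference_p == 1.0

    def test_uniform_pwm_flat_delta(self):
        pwm = uniform_pwm(3)
        ctx = make_context("snp", "AC", "CA", "A", "G")
        res = tf.allele_effect(ctx, pwm, n_null=200, seed=0)
        assert res.delta == pytest.approx(0.0)

    def test_small_n_null_rejected(self):
        with pytest.raises(ValueError):
            tf.allele_effect(
                make_context("s", "AC", "CA", "A", "G"), uniform_pwm(3), n_null=50
            )

    def test_difference_p_matches_enumeration_oracle(self):
        # 3-bp motif, F=2: enumerate all 4^4 flank patterns exactly
        pwm = consensus_pwm("ACG", strength=20, off=1)
        ctx = make_context("snp", "TA", "GT", "C", "T")
        res = tf.allele_effect(ctx, pwm, n_null=20_000, seed=5, alpha_binding=1.1)
        lom = tf.log_odds(pwm)
        lom_rc = tf.log_odds(
            tf.PWM("rc", "rc", pwm.counts[::-1, ::-1].copy())
        )
        delta_obs = abs(res.best_score_a - res.best_score_b)

        def best(seq):
            b = -np.inf
            codes = [tf.BASE_INDEX[c] for c in seq]
            for o in range(2, 3 + 2):  # windows overlapping centre col 2
                o0 = o - 2
                w = codes[o0 : o0 + 3]
                b = max(b, sum(lom[i, w[i]] for i in range(3)))
                b = max(b, sum(lom_rc[i, w[i]] for i in range(3)))
            return b

        exceed = 0
        total = 0
        for flank in itertools.product("ACGT", repeat=4):
            left, right = "".join(flank[:2]), "".join(flank[2:])
            d = abs(
                best(left + "C" + right) - best(left + "T" + right)
            )
            if d >= delta_obs - 1e-12:
                exceed += 1
            total += 1
        p_exact = exceed / total
        se = np.sqrt(p_exact * (1 - p_exact) / 20_000)
        assert abs(res.difference_p - p_exact) < 3 * se + 2 / 20_000

    def test_strand_symmetry_of_delta(self):
        pwm = consensus_pwm("ACGGA")
        ctx = make_context("snp", "ACGT", "TGCA", "G", "T")
        rc_ctx = make_context(
            "snp",
            tf.reverse_complement("TGCA"),
            tf.reverse_complement("ACGT"),
            "C",
            "A",
        )
        r1 = tf.allele_effect(ctx, pwm, n_null=200, seed=0, alpha_binding=1.1)
        r2 = tf.allele_effect(rc_ctx, pwm, n_null=200, seed=0, alpha_binding=1.1)
        assert r1.best_score_a == pytest.approx(r2.best_score_a)
        assert r1.best_score_b == pytest.approx(r2.best_score_b)
        assert abs(r1.delta) == pytest.approx(abs(r2.delta))


class TestScreenLibrary:
    def test_single_motif_m1_adjustment(self):
        pwm = consensus_pwm("ACGTA", strength=50)
        # consensus embedded with a centre SNP destroying its T
        ctx = make_context("snp", "TACG", "ATTT", "T", "G")
        df = tf.screen_library([ctx], [pwm], alpha=0.05, n_null=2000, seed=1)
        row = df.iloc[0]
        assert row["difference_p_bh"] == pytest.approx(row["difference_p"])
        assert bool(row["predicted"]) == (row["difference_p"] < 0.05)

    def test_empty_library_rejected(self):
        with pytest.raises(ValueError):
            tf.screen_library([], [])

    def test_null_only_prediction_rate_consistent_with_alpha(self):
        # no planted site: family-wise predictions should be rare under BH
        rng = np.random.default_rng(9)
        n_pred = 0
        n_runs = 10
        from cll_eqtl import synthetic_data as synth

        pwms = synth.simulate_pwms(4, 5, seed=123)
        for k in range(n_runs):
            seqs = rng.choice(list("ACGT"), size=(2, 9))
            ctxs = [
                make_context(
                    f"s{i}", "".join(s[:4]), "".join(s[5:]), s[4], "ACGT"[(tf.BASE_INDEX[s[4]] + 1) % 4]
                )
                for i, s in enumerate(seqs)
            ]
            df = tf.screen_library(ctxs, pwms, alpha=0.05, n_null=500, seed=k)
            n_pred += int(df["predicted"].sum())
        # 10 runs × 8 (context,motif) pairs, few tested; expect ~0 predictions
        assert n_pred <= 2
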