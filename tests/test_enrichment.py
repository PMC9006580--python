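"""Motif scanning (consensus + PWM) and Fisher/combined-score enrichment."""

import itertools
import math

import numpy as np
import pytest

from degentraj.enrichment import (
    IUPAC,
    MotifDefinition,
    benjamini_hochberg,
    fisher_enrichment_p,
    motif_enrichment,
    reverse_complement,
    scan_promoters,
)


def naive_consensus_scan(seq, consensus):
    """Oracle: plain double-loop IUPAC matcher over both strands."""
    def matches(s):
        w = len(consensus)
        for i in range(len(s) - w + 1):
            if all(s[i + j] in IUPAC[c] for j, c in enumerate(consensus)):
                return True
        return False
    return matches(seq) or matches(reverse_complement(seq))


def random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestScanning:
    def test_exact_substring_is_a_hit(self):
        m = MotifDefinition("m1", "EGR1", consensus="GCGGGGGCG")
        hits = scan_promoters({"geneA": "TTTGCGGGGGCGTTT", "geneB": "TTTTTTTT"}, [m])
        assert hits["m1"] == {"geneA"}

    def test_reverse_strand_match_is_a_hit(self):
        m = MotifDefinition("m1", "tf", consensus="GGGTACCC")
        seq = reverse_complement("TTGGGTACCCTT")
        hits = scan_promoters({"g": seq}, [m])
        assert hits["m1"] == {"g"}

    def test_degenerate_codes_match_their_alternatives(self):
        m = MotifDefinition("m1", "tf", consensus="ARYN")
        hits = scan_promoters({"g1": "CCAGCTCC", "g2": "CCAACTCC", "g3": "CCTTTTCC"}, [m])
        assert hits["m1"] >= {"g1", "g2"}

    def test_n_in_sequence_never_matches(self):
        m = MotifDefinition("m1", "tf", consensus="ACGT")
        hits = scan_promoters({"g": "AANGTAANGT"}, [m])
        assert hits["m1"] == set()

    def test_invalid_characters_name_the_record(self):
        m = MotifDefinition("m1", "tf", consensus="ACGT")
        with pytest.raises(ValueError, match="badgene"):
            scan_promoters({"badgene": "ACXT"}, [m])

    def test_planted_motif_counted_exactly_against_naive_oracle(self):
        rng = np.random.default_rng(0)
        motif = "GCGTGGGCG"
        promoters = {}
        planted = set()
        for i in range(20):
            seq = random_seq(rng, 300)
            if i < 7:
                pos = int(rng.integers(0, 290))
                seq = seq[:pos] + motif + seq[pos + len(motif):]
                planted.add(f"g{i}")
            promoters[f"g{i}"] = seq
        m = MotifDefinition("m1", "tf", consensus=motif)
        hits = scan_promoters(promoters, [m])
        oracle = {g for g, s in promoters.items() if naive_consensus_scan(s, motif)}
        assert hits["m1"] == oracle
        assert planted <= hits["m1"]

    def test_consensus_scan_agrees_with_naive_scanner_on_random_sequences(self):
        rng = np.random.default_rng(1)
        motifs = ["GCGGGGGCG", "TGASTCA", "RRCCGGYY"]
        seqs = {f"g{i}": random_seq(rng, 120) for i in range(250)}
        for cons in motifs:
            m = MotifDefinition(cons, cons, consensus=cons)
            hits = scan_promoters(seqs, [m])
            oracle = {g for g, s in seqs.items() if naive_consensus_scan(s, cons)}
            assert hits[cons] == oracle

    def test_pwm_scan_agrees_with_naive_log_odds_scanner(self):
        rng = np.random.default_rng(2)
        pwm = np.array([[0.85, 0.05, 0.05, 0.05],
                        [0.05, 0.85, 0.05, 0.05],
                        [0.05, 0.05, 0.85, 0.05],
                        [0.05, 0.05, 0.05, 0.85],
                        [0.25, 0.25, 0.25, 0.25]])
        m = MotifDefinition("p1", "tf", pwm=tuple(map(tuple, pwm)))
        seqs = {f"g{i}": random_seq(rng, 60) for i in range(200)}
        hits = scan_promoters(seqs, [m], pwm_threshold=0.8)

        from degentraj.enrichment import _pwm_log_odds
        lo = _pwm_log_odds(pwm)
        thresh = 0.8 * lo.max(axis=1).sum()
        base = {"A": 0, "C": 1, "G": 2, "T": 3}

        def naive(seq):
            for s in (seq, reverse_complement(seq)):
                for i in range(len(s) - len(pwm) + 1):
                    win = s[i:i + len(pwm)]
                    if "N" in win:
                        continue
                    if sum(lo[j, base[c]] for j, c in enumerate(win)) >= thresh:
                        return True
            return False

        oracle = {g for g, s in seqs.items() if naive(s)}
        assert hits["p1"] == oracle

    def test_pwm_rows_must_be_probabilities(self):
        with pytest.raises(ValueError, match="sum to 1"):
            MotifDefinition("bad", "tf", pwm=((0.5, 0.5, 0.5, 0.5),))


def brute_force_hypergeom_tail(a, n_list, n_hits, N):
    """Oracle: sum the hypergeometric pmf from combinatorial first principles."""
    total = 0.0
    for k in range(a, min(n_list, n_hits) + 1):
        total += (math.comb(n_hits, k) * math.comb(N - n_hits, n_list - k)
                  / math.comb(N, n_list))
    return total


class TestEnrichmentScores:
    def test_fisher_p_matches_hand_computed_tail(self):
        # a=3 of list 10, motif hits 4 of background 20
        p = fisher_enrichment_p(3, 10, 4, 20)
        expect = (math.comb(4, 3) * math.comb(16, 7) + math.comb(4, 4) * math.comb(16, 6)) \
            / math.comb(20, 10)
        assert p == pytest.approx(expect, rel=1e-12)
        assert p == pytest.approx(0.29102, abs=2e-5)

    def test_fisher_p_equals_brute_force_on_all_small_tables(self):
        for N in (8, 12, 20, 35, 50):
            for n_list in (2, N // 3, N // 2):
                for n_hits in (1, N // 4, N // 2):
                    for a in range(0, min(n_list, n_hits) + 1):
                        got = fisher_enrichment_p(a, n_list, n_hits, N)
                        want = brute_force_hypergeom_tail(a, n_list, n_hits, N)
                        assert got == pytest.approx(want, rel=1e-9, abs=1e-12)

    def test_fisher_p_matches_scipy_fisher_exact(self):
        from scipy.stats import fisher_exact
        a, n_list, n_hits, N = 5, 12, 9, 40
        table = [[a, n_hits - a], [n_list - a, N - n_hits - (n_list - a)]]
        assert fisher_enrichment_p(a, n_list, n_hits, N) == pytest.approx(
            fisher_exact(table, alternative="greater")[1], rel=1e-9)

    def test_saturated_motif_is_uninformative(self):
        bg = [f"g{i}" for i in range(30)]
        hits = {"m": set(bg)}
        tab = motif_enrichment(bg[:10], bg, hits, n_random=50, seed=0)
        assert tab.loc["m", "p_value"] == pytest.approx(1.0)

    def test_bh_adjustment_monotone_and_hand_checked(self):
        p = np.array([0.01, 0.04, 0.03, 0.5])
        adj = benjamini_hochberg(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()
        np.testing.assert_allclose(adj, [0.04, 0.053333333, 0.053333333, 0.5], atol=1e-8)

    def test_enriched_motif_scores_above_unenriched(self):
        rng = np.random.default_rng(3)
        bg = [f"g{i}" for i in range(200)]
        gene_list = bg[:40]
        enriched = set(bg[:30]) | set(rng.choice(bg[40:], 10, replace=False))
        flat = set(rng.choice(bg, 40, replace=False))
        tab = motif_enrichment(gene_list, bg, {"hot": enriched, "cold": flat},
                               n_random=100, seed=0)
        assert tab.loc["hot", "p_value"] < tab.loc["cold", "p_value"]
        assert tab.loc["hot", "combined_score"] > tab.loc["cold", "combined_score"]
        assert tab.index[0] == "hot"

    def test_random_gene_lists_are_calibrated(self):
        rng = np.random.default_rng(4)
        N = 60
        bg = [f"g{i}" for i in range(N)]
        hits = {f"m{j}": set(rng.choice(bg, 20, replace=False)) for j in range(4)}
        reject = 0
        trials = 400
        for _ in range(trials):
            gl = list(rng.choice(bg, 15, replace=False))
            ov = [len(hits[m] & set(gl)) for m in hits]
            for m, o in zip(hits, ov):
                if fisher_enrichment_p(o, 15, len(hits[m]), N) < 0.05:
                    reject += 1
        rate = reject / (trials * len(hits))
        assert rate <= 0.07  # discrete test is conservative at alpha=0.05

    def test_gene_list_outside_background_rejected(self):
        with pytest.raises(ValueError, match="subset"):
            motif_enrichment(["x"], ["a", "b"], {"m": {"a"}})
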