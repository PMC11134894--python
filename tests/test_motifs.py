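"""PWM scoring, positional profiles, peaksets, GSEA and feature enrichment."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from eprint_tools.core import GenomicInterval, Peak
from eprint_tools.motifs import (MotifModel, PeakSet, directional_gsea,
                                 encode_sequence, feature_enrichment_batch,
                                 gsea_batch, motif_feature_enrichment,
                                 motif_peakset, positional_profile,
                                 positional_profile_from_windows,
                                 read_matrix_motifs, read_meme_motifs,
                                 relative_logodds_score, scan_scores)
from eprint_tools.simulate import simulate_motif_windows

BASES = "ACGT"


def anti_consensus(motif):
    return "".join(BASES[i] for i in motif.pwm.argmin(axis=1))


@pytest.fixture
def gc_motif():
    pwm = np.array([[0.7, 0.1, 0.1, 0.1],
                    [0.05, 0.8, 0.05, 0.1],
                    [0.05, 0.05, 0.85, 0.05],
                    [0.1, 0.1, 0.1, 0.7],
                    [0.25, 0.25, 0.25, 0.25],
                    [0.6, 0.1, 0.2, 0.1]])
    return MotifModel("M_test", ["RBPX"], pwm)


class TestScoring:
    def test_consensus_scores_one(self, gc_motif):
        assert relative_logodds_score(gc_motif, gc_motif.consensus) \
            == pytest.approx(1.0)

    def test_anti_consensus_scores_zero(self, gc_motif):
        assert relative_logodds_score(gc_motif, anti_consensus(gc_motif)) \
            == pytest.approx(0.0)

    @given(st.text(alphabet="ACGT", min_size=6, max_size=6))
    @settings(max_examples=100, deadline=None)
    def test_score_always_in_unit_interval(self, seq):
        pwm = np.array([[0.7, 0.1, 0.1, 0.1]] * 6)
        m = MotifModel("m", [], pwm)
        s = relative_logodds_score(m, seq)
        assert 0.0 <= s <= 1.0
        if seq == m.consensus:
            assert s == pytest.approx(1.0)

    def test_ambiguous_base_is_neutral(self, gc_motif):
        s_n = relative_logodds_score(gc_motif, gc_motif.consensus[:2] + "N"
                                     + gc_motif.consensus[3:])
        assert 0.0 < s_n < 1.0

    def test_scan_matches_per_position_scoring(self, gc_motif):
        rng = np.random.default_rng(0)
        seq = "".join(np.array(list(BASES))[rng.integers(0, 4, 60)])
        scanned = scan_scores(gc_motif, encode_sequence(seq))
        direct = [relative_logodds_score(gc_motif, seq, i)
                  for i in range(60 - 6 + 1)]
        np.testing.assert_allclose(scanned, direct, atol=1e-12)

    def test_kmer_motif_consensus(self):
        m = MotifModel.from_kmer("GUGGUA", "k")
        assert m.consensus == "GTGGTA"
        assert relative_logodds_score(m, "GTGGTA") == pytest.approx(1.0)


class TestPositionalProfile:
    def test_planted_motif_peaks_at_zero(self, gc_motif):
        windows, _ = simulate_motif_windows(500, gc_motif.consensus, 0.9,
                                            seed=3)
        prof = positional_profile_from_windows(gc_motif, windows)
        assert prof.peak_position == 0
        assert prof.z[100] > 3
        assert abs(prof.z.mean()) < 1e-9
        assert prof.z.std() == pytest.approx(1.0)

    def test_null_sequences_bounded_z(self, gc_motif):
        exceed = 0
        for r in range(30):
            windows, _ = simulate_motif_windows(300, gc_motif.consensus, 0.0,
                                                seed=500 + r)
            prof = positional_profile_from_windows(gc_motif, windows)
            exceed += np.abs(prof.z).max() >= 4
        assert exceed <= 2

    def test_genome_based_profile(self, gc_motif):
        # plant consensus right at the anchor of a minus-strand peak
        cons = gc_motif.consensus
        rng = np.random.default_rng(9)
        seq = "".join(np.array(list(BASES))[rng.integers(0, 4, 600)])
        anchor = 300
        from eprint_tools.core import revcomp
        planted = (seq[:anchor - len(cons) + 1] + revcomp(cons)
                   + seq[anchor + 1:])
        peaks = [Peak(GenomicInterval("c", 250, anchor + 1, "-"), "p")]
        prof = positional_profile(gc_motif, peaks * 20, {"c": planted},
                                  half_window=50)
        assert prof.mean_score[50] == pytest.approx(1.0)

    def test_few_windows_warns(self, gc_motif):
        with pytest.warns(UserWarning, match="unstable"):
            positional_profile_from_windows(gc_motif, ["A" * 206] * 3)


class TestMotifPeakset:
    def test_inclusion_matches_bruteforce_window_scan(self, gc_motif):
        rng = np.random.default_rng(11)
        seq = "".join(np.array(list(BASES))[rng.integers(0, 4, 5000)])
        seqs = {"c": seq}
        peaks = []
        for i in range(60):
            s = int(rng.integers(100, 4800))
            peaks.append(Peak(GenomicInterval("c", s, s + 40,
                                              "+" if i % 2 else "-"),
                              f"p{i}"))
        ps = motif_peakset(gc_motif, peaks, seqs, half_window=25,
                           threshold=0.8)
        from eprint_tools.core import anchored_window
        for p in peaks:
            w = anchored_window(p, seqs, 25 + len(gc_motif) - 1)
            w = w[len(gc_motif) - 1:]
            best = max(relative_logodds_score(gc_motif, w, i)
                       for i in range(2 * 25 + 1))
            assert (p.peak_id in ps.peak_ids) == (best >= 0.8)

    def test_planted_and_anti_consensus(self, gc_motif):
        cons = gc_motif.consensus
        seqs = {"c": "T" * 100 + cons + anti_consensus(gc_motif) * 20}
        carrier = Peak(GenomicInterval("c", 97, 140, "+"), "hit")  # +3 offset
        non = Peak(GenomicInterval("c", 200, 240, "+"), "miss")
        ps = motif_peakset(gc_motif, [carrier, non], seqs)
        assert ps.peak_ids == {"hit"}


def es_oracle(values, hit):
    """Brute-force running-sum ES: plain Python, no vectorisation."""
    n_hit_weight = sum(abs(v) for v, h in zip(values, hit) if h)
    n_miss = len(values) - sum(hit)
    run, best = 0.0, 0.0
    for v, h in zip(values, hit):
        if h:
            run += abs(v) / n_hit_weight
        else:
            run -= 1.0 / n_miss
        if abs(run) > abs(best):
            best = run
    return best


class TestDirectionalGsea:
    def test_es_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(123)
        for rep in range(200):
            n = int(rng.integers(10, 200))
            values = np.sort(rng.normal(0, 1, n))[::-1]
            k = int(rng.integers(1, max(2, n // 3)))
            members = set(rng.choice(n, size=k, replace=False).tolist())
            ids = [f"p{i}" for i in range(n)]
            ranked = pd.Series(values, index=ids)
            res = directional_gsea(ranked, PeakSet("s", {ids[i] for i in
                                                         members}),
                                   n_perm=5, seed=rep)
            hit = [i in members for i in range(n)]
            assert res.es == pytest.approx(es_oracle(values, hit),
                                           abs=1e-12)

    def test_top_block_maximal_enrichment(self):
        rng = np.random.default_rng(1)
        values = np.sort(rng.normal(0, 1, 1000))[::-1]
        ids = [f"p{i}" for i in range(1000)]
        ranked = pd.Series(values, index=ids)
        res = directional_gsea(ranked, PeakSet("top", set(ids[:50])),
                               n_perm=200, seed=0)
        assert res.es > 0.9
        assert res.p < 0.02  # at the permutation floor
        assert res.nes > 2

    def test_reversed_ranking_negates_es(self):
        rng = np.random.default_rng(2)
        values = np.sort(rng.normal(0, 1, 200))[::-1]
        ids = [f"p{i}" for i in range(200)]
        members = set(rng.choice(ids, 20, replace=False))
        fwd = directional_gsea(pd.Series(values, index=ids),
                               PeakSet("s", members), n_perm=5, seed=0)
        rev = directional_gsea(pd.Series(-values[::-1], index=ids[::-1]),
                               PeakSet("s", members), n_perm=5, seed=0)
        assert fwd.es == pytest.approx(-rev.es, abs=1e-12)

    def test_deterministic_for_fixed_seed(self):
        rng = np.random.default_rng(3)
        values = np.sort(rng.normal(0, 1, 300))[::-1]
        ids = [f"p{i}" for i in range(300)]
        ranked = pd.Series(values, index=ids)
        members = set(rng.choice(ids, 30, replace=False))
        a = directional_gsea(ranked, PeakSet("s", members), 300, seed=42)
        b = directional_gsea(ranked, PeakSet("s", members), 300, seed=42)
        assert (a.es, a.nes, a.p) == (b.es, b.nes, b.p)

    def test_null_pvalues_approximately_uniform(self):
        rng = np.random.default_rng(4)
        values = np.sort(rng.normal(0, 1, 100))[::-1]
        ids = [f"p{i}" for i in range(100)]
        ranked = pd.Series(values, index=ids)
        ps = []
        for rep in range(200):
            members = set(np.asarray(ids)[rng.choice(100, 10,
                                                     replace=False)])
            res = directional_gsea(ranked, PeakSet("s", members),
                                   n_perm=200, rng=rng)
            ps.append(res.p)
        # directional p over same-sign permutations: uniform under the null
        assert sps.kstest(ps, "uniform").pvalue > 0.01

    def test_degenerate_sets_rejected(self):
        ranked = pd.Series([1.0, 0.5], index=["a", "b"])
        with pytest.raises(ValueError):
            directional_gsea(ranked, PeakSet("s", set()), 10)
        with pytest.raises(ValueError):
            directional_gsea(ranked, PeakSet("s", {"a", "b"}), 10)

    def test_planted_activity_recovery(self):
        # carriers of one motif shifted down; decoys stay null
        rng = np.random.default_rng(5)
        n = 2000
        ids = [f"p{i:05d}" for i in range(n)]
        values = rng.normal(0, 1, n)
        carriers = rng.random(n) < 0.1
        values[carriers] -= 1.0
        ranked = pd.Series(values, index=ids).sort_values(ascending=False)
        sets = [PeakSet("motifA", {i for i, c in zip(ids, carriers) if c})]
        for d in range(20):
            idx = rng.choice(n, size=int(carriers.sum()), replace=False)
            sets.append(PeakSet(f"decoy{d}", {ids[i] for i in idx}))
        df = gsea_batch(ranked, sets, n_perm=2000, seed=9).set_index("set_id")
        assert df.loc["motifA", "nes"] < 0
        assert df.loc["motifA", "padj"] < 0.05
        decoys = df.drop("motifA")
        assert (decoys["padj"] >= 0.05).mean() >= 0.9


def hypergeom_enumeration(k, M, K, n, tail):
    """Enumeration oracle: sum the hypergeometric pmf by combinatorics."""
    total = math.comb(M, n)
    if tail == "upper":
        ks = range(k, min(K, n) + 1)
    else:
        ks = range(0, k + 1)
    return sum(math.comb(K, kk) * math.comb(M - K, n - kk)
               for kk in ks) / total


class TestFeatureEnrichment:
    def test_all_intronic_set_closed_form(self):
        # universe 10 peaks (5 intronic), set of 5 all intronic: 1/252
        cats = {f"p{i}": ("IN" if i < 5 else "EX") for i in range(10)}
        ps = PeakSet("m", {f"p{i}" for i in range(5)})
        df = motif_feature_enrichment(ps, cats).set_index("category")
        assert df.loc["IN", "p_enrich"] == pytest.approx(1 / 252)
        assert df.loc["EX", "p_enrich"] == pytest.approx(1.0)
        assert df.loc["EX", "p_deplete"] == pytest.approx(
            hypergeom_enumeration(0, 10, 5, 5, "lower"))

    def test_proportional_set_not_significant(self):
        cats = {f"p{i}": ("IN" if i < 10 else "EX") for i in range(20)}
        ps = PeakSet("m", {f"p{i}" for i in list(range(5))
                           + list(range(10, 15))})
        df = motif_feature_enrichment(ps, cats)
        assert (df[["p_enrich", "p_deplete"]].min(axis=1) > 0.05).all()

    def test_matches_enumeration_on_small_universes(self):
        rng = np.random.default_rng(6)
        for _ in range(30):
            M = int(rng.integers(5, 26))
            cats = {f"p{i}": rng.choice(["IN", "EX", "UTR5"])
                    for i in range(M)}
            n = int(rng.integers(1, M))
            ps = PeakSet("m", set(rng.choice(list(cats), n, replace=False)))
            df = motif_feature_enrichment(ps, cats)
            for _, row in df.iterrows():
                in_cat = {p for p, c in cats.items() if c == row["category"]}
                k = len(ps.peak_ids & in_cat)
                assert row["p_enrich"] == pytest.approx(
                    hypergeom_enumeration(k, M, len(in_cat), n, "upper"))
                assert row["p_deplete"] == pytest.approx(
                    hypergeom_enumeration(k, M, len(in_cat), n, "lower"))

    def test_batch_adjusts_over_grid(self):
        cats = {f"p{i}": ("IN" if i % 2 else "EX") for i in range(12)}
        sets = [PeakSet("a", {"p0", "p2"}), PeakSet("b", {"p1", "p3"})]
        df = feature_enrichment_batch(sets, cats)
        assert len(df) == 4
        assert {"padj_enrich", "padj_deplete"} <= set(df.columns)


class TestMotifIO:
    def test_meme_reader(self, tmp_path):
        text = ("MEME version 4\n\nALPHABET= ACGT\n\n"
                "MOTIF M1 RBP1\n"
                "letter-probability matrix: alength= 4 w= 3\n"
                " 0.7 0.1 0.1 0.1\n 0.1 0.7 0.1 0.1\n 0.1 0.1 0.1 0.7\n")
        path = tmp_path / "m.meme"
        path.write_text(text)
        motifs = read_meme_motifs(path)
        assert len(motifs) == 1
        assert motifs[0].motif_id == "M1"
        assert motifs[0].consensus == "ACT"

    def test_matrix_reader_with_rbps(self, tmp_path):
        text = (">M151_0.6 HNRNPH2,HNRNPH1,HNRNPF\n"
                "0.1 0.1 0.7 0.1\n0.1 0.1 0.7 0.1\n0.1 0.1 0.1 0.7\n"
                "0.1 0.1 0.7 0.1\n")
        path = tmp_path / "m.txt"
        path.write_text(text)
        motifs = read_matrix_motifs(path)
        assert motifs[0].rbp_names == ["HNRNPH2", "HNRNPH1", "HNRNPF"]
        assert motifs[0].consensus == "GGTG"
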