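"""Markov background, Gibbs motif discovery, consensus, co-existing motifs."""

import math

import numpy as np
import pytest

from cresig._iupac import IUPAC_SETS, reverse_complement
from cresig.discovery import (
    MarkovBackground,
    encode,
    find_coexisting_motifs,
    gibbs_motif_search,
    pwm_consensus,
    site_set_score,
)
from cresig.patterns import MotifPattern, find_occurrences


def match_count(consensus: str, planted: str) -> int:
    """Positions where the planted base falls in the consensus code's set,
    best of forward and reverse-complement alignment."""

    def n(c, p):
        return sum(1 for cc, pp in zip(c, p) if pp in IUPAC_SETS[cc])

    return max(n(consensus, planted), n(consensus, reverse_complement(planted)))


def random_seqs(rng, n, length, gc=0.45):
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return {
        f"s{i}": "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=p)])
        for i in range(n)
    }


def plant(rng, seqs, word, fraction):
    planted = {}
    ids = sorted(seqs)
    chosen = rng.choice(len(ids), size=round(fraction * len(ids)), replace=False)
    for i in chosen:
        sid = ids[i]
        s = seqs[sid]
        off = int(rng.integers(0, len(s) - len(word) + 1))
        seqs[sid] = s[:off] + word + s[off + len(word) :]
        planted[sid] = off
    return planted


class TestBackground:
    def test_order0_on_polyA(self):
        bg = MarkovBackground.train(["A" * 1000], order=0)
        assert bg.cond[0, 0] > 0.99
        assert bg.cond[0].sum() == pytest.approx(1.0, abs=1e-12)

    def test_contexts_normalise(self):
        rng = np.random.default_rng(0)
        seqs = random_seqs(rng, 20, 500)
        for order in (0, 1, 2):
            bg = MarkovBackground.train(seqs.values(), order=order)
            assert np.allclose(bg.cond.sum(axis=1), 1.0, atol=1e-12)
            assert (bg.cond > 0).all()

    def test_order1_recovers_known_transitions(self):
        """Training on 100 kb generated from a known transition matrix
        recovers the conditional probabilities within 0.02."""
        rng = np.random.default_rng(1)
        trans = np.array(
            [
                [0.50, 0.20, 0.20, 0.10],
                [0.10, 0.40, 0.30, 0.20],
                [0.25, 0.25, 0.25, 0.25],
                [0.10, 0.10, 0.30, 0.50],
            ]
        )
        state = 0
        out = []
        for _ in range(100_000):
            state = rng.choice(4, p=trans[state])
            out.append("ACGT"[state])
        bg = MarkovBackground.train(["".join(out)], order=1)
        assert np.abs(bg.cond - trans).max() < 0.02

    def test_insufficient_data_rejected(self):
        with pytest.raises(ValueError, match="lower the order"):
            MarkovBackground.train(["ACGT" * 10], order=3)

    def test_window_logprobs_sum_position_logprobs(self):
        rng = np.random.default_rng(2)
        seqs = random_seqs(rng, 5, 400)
        bg = MarkovBackground.train(seqs.values(), order=1)
        e = encode(seqs["s0"])
        lp = bg.position_logprobs(e)
        win = bg.window_logprobs(e, 8)
        for i in (0, 50, 200):
            assert win[i] == pytest.approx(lp[i : i + 8].sum(), abs=1e-9)

    def test_n_invalidates_windows(self):
        bg = MarkovBackground.train(["ACGT" * 100], order=0)
        e = encode("ACGTNACGTACGT")
        win = bg.window_logprobs(e, 4)
        assert np.isnan(win[1]) and np.isnan(win[4])
        assert not np.isnan(win[5])


class TestConsensus:
    @pytest.mark.parametrize(
        "column,code",
        [
            ([1.0, 0, 0, 0], "A"),
            ([0.5, 0.5, 0, 0], "M"),
            ([0.3, 0.3, 0.3, 0.1], "V"),
            ([0.2, 0.2, 0.2, 0.4], "T"),  # nothing but T reaches 0.25
        ],
    )
    def test_column_codes(self, column, code):
        assert pwm_consensus(np.array([column])) == code


class TestScore:
    def test_score_matches_direct_computation(self):
        """The site-set log-likelihood-ratio equals an independently coded
        direct computation."""
        rng = np.random.default_rng(3)
        seqs = random_seqs(rng, 12, 300)
        bg = MarkovBackground.train(seqs.values(), order=1)
        w = 8
        sites = [(f"s{i}", int(rng.integers(0, 300 - w)), "+") for i in range(8)]
        sites += [("s9", 17, "-")]
        score, pfm = site_set_score(sites, seqs, bg, w)

        # independent: rebuild counts and probabilities from scratch
        base_index = {b: i for i, b in enumerate("ACGT")}
        counts = np.zeros((w, 4))
        words = []
        for sid, off, strand in sites:
            word = seqs[sid][off : off + w]
            if strand == "-":
                word = reverse_complement(word)
            words.append((sid, off, word))
            for j, b in enumerate(word):
                counts[j, base_index[b]] += 1
        theta = (counts + bg.marginal[None, :]) / (len(sites) + 1)
        expected = 0.0
        for sid, off, word in words:
            num = sum(math.log(theta[j, base_index[b]]) for j, b in enumerate(word))
            # background prob of the observed (forward) window
            seq = seqs[sid]
            den = 0.0
            for j in range(w):
                pos = off + j
                if pos == 0:
                    den += math.log(bg.marginal[base_index[seq[pos]]])
                else:
                    ctx = base_index[seq[pos - 1]]
                    den += math.log(bg.cond[ctx, base_index[seq[pos]]])
            expected += num - den
        assert score == pytest.approx(expected, abs=1e-9)


class TestGibbs:
    def test_determinism(self):
        rng = np.random.default_rng(4)
        seqs = random_seqs(rng, 20, 300)
        plant(rng, seqs, "CACGTGTC", 0.7)
        bg = MarkovBackground.train(seqs.values(), order=1)
        a = gibbs_motif_search(seqs, bg, width=8, iterations=60, restarts=2, seed=5)
        b = gibbs_motif_search(seqs, bg, width=8, iterations=60, restarts=2, seed=5)
        assert [m.sites for m in a] == [m.sites for m in b]
        assert [m.score for m in a] == [m.score for m in b]

    def test_planted_motif_recovered(self):
        rng = np.random.default_rng(6)
        seqs = random_seqs(rng, 50, 400)
        plant(rng, seqs, "CACGTGTC", 0.7)
        bg = MarkovBackground.train(seqs.values(), order=1)
        motifs = gibbs_motif_search(seqs, bg, width=8, iterations=120, restarts=4, seed=7)
        assert motifs and match_count(motifs[0].consensus(), "CACGTGTC") >= 7

    def test_null_scores_below_planted(self):
        rng = np.random.default_rng(8)
        null_seqs = random_seqs(rng, 40, 400)
        bg = MarkovBackground.train(null_seqs.values(), order=1)
        null = gibbs_motif_search(null_seqs, bg, width=8, iterations=80, restarts=3, seed=9)

        planted_seqs = random_seqs(rng, 40, 400)
        plant(rng, planted_seqs, "CACGTGTC", 0.7)
        bgp = MarkovBackground.train(planted_seqs.values(), order=1)
        found = gibbs_motif_search(planted_seqs, bgp, width=8, iterations=80, restarts=3, seed=9)
        null_score = null[0].score if null else 0.0
        assert found[0].score > null_score

    def test_too_few_sequences_rejected(self):
        bg = MarkovBackground.train(["ACGT" * 100], order=0)
        with pytest.raises(ValueError, match="at least 10"):
            gibbs_motif_search({"a": "ACGTACGTACGT"}, bg, width=8)

    def test_masking_prevents_site_reuse(self):
        """Two reported motifs never share more than half their sites."""
        rng = np.random.default_rng(10)
        seqs = random_seqs(rng, 40, 400)
        plant(rng, seqs, "CACGTGTC", 0.8)
        bg = MarkovBackground.train(seqs.values(), order=1)
        motifs = gibbs_motif_search(
            seqs, bg, width=8, n_motifs=2, iterations=80, restarts=3, seed=11
        )
        if len(motifs) == 2:
            first = {(sid, off) for sid, off, _ in motifs[0].sites}
            second = {(sid, off) for sid, off, _ in motifs[1].sites}
            overlap = sum(
                1
                for sid, off in second
                if any(s == sid and abs(o - off) < 8 for s, o in first)
            )
            assert overlap <= 0.5 * len(second)


class TestCoexisting:
    def build(self, seed=12, n=60, co_fraction=0.7):
        rng = np.random.default_rng(seed)
        seqs = random_seqs(rng, n, 500)
        plant(rng, seqs, "CACGTGTC", 1.0)  # anchor in every carrier sequence
        plant(rng, seqs, "TTGACCGA", co_fraction)
        bg = MarkovBackground.train(seqs.values(), order=1)
        return seqs, bg

    def test_coplanted_motif_recovered_anchor_not_rereported(self):
        seqs, bg = self.build()
        anchor = MotifPattern("ABRE", "CACGTGTC")
        motifs = find_coexisting_motifs(
            seqs, anchor, bg, width=8, iterations=120, restarts=4, seed=13
        )
        assert motifs
        cons = motifs[0].consensus()
        assert match_count(cons, "TTGACCGA") >= 7
        assert match_count(cons, "CACGTGTC") < 7

    def test_masking_invariant(self):
        """Reported sites never overlap anchor occurrences."""
        seqs, bg = self.build(seed=14)
        anchor = MotifPattern("ABRE", "CACGTGTC")
        motifs = find_coexisting_motifs(
            seqs, anchor, bg, width=8, iterations=80, restarts=3, seed=15
        )
        for motif in motifs:
            for sid, off, _ in motif.sites:
                anchor_offs = find_occurrences(seqs[sid], anchor.iupac)
                anchor_offs += find_occurrences(seqs[sid], reverse_complement(anchor.iupac))
                for a in anchor_offs:
                    assert off + 8 <= a or off >= a + 8

    def test_null_coexistence_weak(self):
        rng = np.random.default_rng(16)
        seqs = random_seqs(rng, 40, 400)
        plant(rng, seqs, "CACGTGTC", 1.0)
        bg = MarkovBackground.train(seqs.values(), order=1)
        anchor = MotifPattern("ABRE", "CACGTGTC")
        motifs = find_coexisting_motifs(
            seqs, anchor, bg, width=8, iterations=80, restarts=3, seed=17
        )
        # any motif found in pure background must not be a sharp 8-mer signal
        if motifs:
            assert len(motifs[0].sites) < 0.9 * len(seqs)
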