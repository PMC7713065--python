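"""PWM scanning: brute-force score equality, exact p-values, refinement."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from fnrscan.motifs import PWM, discover
from fnrscan.scanner import PWMScanner, refine, scan, score_pvalue

from conftest import GC65, NamedSeq, planted_promoter_set, random_seq


def brute_force_scores(pwm: PWM, seq: str) -> np.ndarray:
    """Per-window log-odds computed with plain Python arithmetic."""
    import math

    W = pwm.width
    out = []
    for i in range(len(seq) - W + 1):
        s = 0.0
        for j, ch in enumerate(seq[i : i + W]):
            b = "ACGT".index(ch)
            s += math.log2(pwm.matrix[j, b]) - math.log2(pwm.background[b])
        out.append(s)
    return np.array(out)


class TestScores:
    def test_scores_match_brute_force(self, rng):
        for _ in range(3):
            mat = rng.dirichlet(np.ones(4), size=6)
            pwm = PWM(mat, GC65)
            seq = random_seq(rng, 200)
            sc = PWMScanner(pwm=pwm).fit()
            got = sc.window_scores(seq)
            want = brute_force_scores(pwm, seq)
            assert np.abs(got - want).max() <= 1e-9

    def test_non_acgt_windows_skipped(self):
        pwm = PWM(np.full((2, 4), 0.25))
        sc = PWMScanner(pwm=pwm, p_max=1.0).fit()
        scores = sc.window_scores("ACNGT")
        assert np.isnan(scores[1]) and np.isnan(scores[2])
        hits = sc.scan(["ACNGT"])
        assert all(h.offset not in (1, 2) for h in hits)


class TestExactPValues:
    @pytest.mark.parametrize("W", [2, 3, 4, 5, 6])
    def test_dp_equals_enumeration(self, W):
        """DP p-values equal exhaustive 4^W enumeration at the same
        discretization, for every achievable score."""
        rng = np.random.default_rng(W)
        mat = rng.dirichlet(np.ones(4) * 0.8, size=W)
        bg = rng.dirichlet(np.ones(4) * 5)
        pwm = PWM(mat, bg / bg.sum())
        sc = PWMScanner(pwm=pwm).fit()
        words = np.array(list(itertools.product(range(4), repeat=W)))
        totals = sc.int_scores_[np.arange(W), words].sum(axis=1)
        probs = np.prod(sc.background_[words], axis=1)
        for t in np.unique(totals):
            p_enum = probs[totals >= t].sum()
            assert sc._pvalue_int(int(t)) == pytest.approx(p_enum, abs=1e-12)

    def test_width2_toy_continuous(self, toy_pwm):
        """Width-2 toy with well-separated scores: continuous-score p-values
        match enumeration to 1e-6 despite discretization."""
        sc = PWMScanner(pwm=toy_pwm).fit()
        words = list(itertools.product(range(4), repeat=2))
        lo = toy_pwm.log_odds()
        cont = {w: lo[0, w[0]] + lo[1, w[1]] for w in words}
        for w, s in cont.items():
            p_enum = sum(0.0625 for v in cont.values() if v >= s - 1e-9)
            assert sc.score_pvalue(s) == pytest.approx(p_enum, abs=1e-6)

    def test_uniform_pwm_degenerate_identity(self):
        pwm = PWM(np.full((4, 4), 0.25))
        assert score_pvalue(pwm, 0.0) == 1.0

    def test_max_score_p_is_argmax_mass(self):
        mat = np.array([[0.7, 0.1, 0.1, 0.1], [0.1, 0.7, 0.1, 0.1]])
        pwm = PWM(mat, np.full(4, 0.25))
        sc = PWMScanner(pwm=pwm).fit()
        max_score = float(np.log2(0.7 / 0.25) * 2)
        assert sc.score_pvalue(max_score) == pytest.approx(0.0625, abs=1e-12)

    def test_min_score_p_is_one(self, toy_pwm):
        sc = PWMScanner(pwm=toy_pwm).fit()
        lo = toy_pwm.log_odds()
        assert sc.score_pvalue(float(lo.min(axis=1).sum())) == 1.0

    def test_monotone_nonincreasing(self, toy_pwm):
        sc = PWMScanner(pwm=toy_pwm).fit()
        ps = [sc.score_pvalue(s) for s in np.linspace(-5, 5, 101)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))


class TestScan:
    def test_planted_consensus_found(self):
        proms, offsets, _ = planted_promoter_set(10, seed=31)
        m = discover(proms, n_motifs=1, restarts=5, seed=0)[0]
        hits = scan(m.pwm, proms, p_max=1e-4)
        best_by_seq = {}
        for h in hits:
            best_by_seq.setdefault(h.ref_id, h)
        for i, p in enumerate(proms):
            assert best_by_seq[p.ref_id].offset == offsets[i]

    def test_anti_consensus_has_no_hits(self):
        mat = np.tile([0.91, 0.03, 0.03, 0.03], (14, 1))
        pwm = PWM(mat, np.full(4, 0.25))
        worst = "C" * 200  # every window scores the PWM minimum
        assert scan(pwm, [worst], p_max=1e-4) == []

    def test_greedy_overlap_resolution(self, rng):
        """No two accepted hits within one sequence overlap by >= 1 bp."""
        mat = np.tile([0.85, 0.05, 0.05, 0.05], (6, 1))
        pwm = PWM(mat, GC65)
        seq = "".join(rng.choice(list("AC"), p=[0.7, 0.3], size=300))
        hits = scan(pwm, [seq], p_max=0.5)
        assert hits
        offs = sorted(h.offset for h in hits)
        assert all(b - a >= 6 for a, b in zip(offs, offs[1:]))

    def test_hits_sorted_by_p(self):
        proms, _, _ = planted_promoter_set(8, seed=90)
        m = discover(proms, n_motifs=1, restarts=5, seed=0)[0]
        hits = scan(m.pwm, proms, p_max=1e-3)
        ps = [h.p_value for h in hits]
        assert ps == sorted(ps)

    def test_both_strands_finds_reverse_site(self, rng):
        from Bio.Seq import Seq

        mat = np.array([[0.9, 0.04, 0.03, 0.03]] * 3
                       + [[0.03, 0.9, 0.04, 0.03]] * 3)
        pwm = PWM(mat, np.full(4, 0.25))
        site = "AAACCC"
        seq = random_seq(rng, 80, p=np.full(4, 0.25))
        planted = seq[:40] + str(Seq(site).reverse_complement()) + seq[46:]
        hits = scan(pwm, [planted], p_max=5e-3, both_strands=True)
        assert any(h.strand == "-" and h.offset == 40 for h in hits)


class TestRefine:
    def _promset(self):
        # the 40-promoter scenario: 12 planted among 40
        return planted_promoter_set(40, seed=61, n_planted=12)

    def test_planted_promoters_hit_positive(self):
        proms, offsets, _ = self._promset()
        from fnrscan.motifs import consensus_string

        rep = refine(proms[:12], proms, seed=1)
        assert set(p.ref_id for p in proms[:12]) <= set(rep.hit_positive)
        assert "TTGA" in consensus_string(rep.refined.pwm)

    def test_fixed_point(self):
        proms, _, _ = self._promset()
        rep = refine(proms[:12], proms, seed=1)
        again = refine(proms[:12], proms, seed=1, initial_motif=rep.refined)
        assert np.abs(again.refined.pwm.matrix - rep.refined.pwm.matrix).max() <= 1e-3

    def test_deterministic(self):
        proms, _, _ = self._promset()
        a = refine(proms[:12], proms, seed=4)
        b = refine(proms[:12], proms, seed=4)
        assert np.array_equal(a.refined.pwm.matrix, b.refined.pwm.matrix)
        assert a.hit_positive == b.hit_positive

    def test_no_hits_reports_initial_with_warning(self, caplog, rng):
        # seed motif from two tiny unrelated sequences; scan set is anti-matching
        proms = [NamedSeq("a", random_seq(rng, 60)), NamedSeq("b", random_seq(rng, 60))]
        targets = [NamedSeq("t", "C" * 60)]
        with caplog.at_level("WARNING", logger="fnrscan"):
            rep = refine(proms, targets, width=14, seed=0)
        assert not rep.refined_from_initial
        assert rep.refined is rep.initial
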