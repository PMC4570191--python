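"""Complementarity (expectation) scoring and target-site scanning."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirflow._seq import revcomp
from mirflow.targets import score_site, predict_targets

MIR = "TGGAGCTCCCTTCATTCCAAT"  # 21 nt


def _rand_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def _site_for(mirna):
    return revcomp(mirna)


def _mutate_target_at_mirna_pos(mirna, target, pos, new_base):
    """Replace the target base opposite 1-based miRNA position `pos`."""
    i = len(mirna) - pos
    return target[:i] + new_base + target[i + 1 :]


def _oracle_score(mirna, window):
    """Brute-force enumeration of all global alignments (small inputs)."""
    m, w = len(mirna), len(window)
    q = mirna[::-1]
    pos = [m - i for i in range(m)]
    comp = {"A": "T", "T": "A", "G": "C", "C": "G"}

    def seed(p):
        return 2.0 if 2 <= p <= 13 else 1.0

    def pen(mb, tb):
        if comp[mb] == tb:
            return 0.0
        if (mb, tb) in (("G", "T"), ("T", "G")):
            return 0.5
        return 1.0

    best = [float("inf")]

    def rec(i, j, acc):
        if acc >= best[0]:
            return
        if i == m and j == w:
            best[0] = acc
            return
        if i < m and j < w:
            rec(i + 1, j + 1, acc + pen(q[i], window[j]) * seed(pos[i]))
        if i < m:
            rec(i + 1, j, acc + 2.0 * seed(pos[i]))
        if j < w:
            f = seed(pos[i]) if i < m else seed(pos[m - 1])
            rec(i, j + 1, acc + 2.0 * f)

    rec(0, 0, 0.0)
    return best[0]


class TestScoreSite:
    def test_perfect_reverse_complement_scores_zero(self):
        assert score_site(MIR, _site_for(MIR))[0] == 0.0

    def test_wobble_outside_seed_costs_half(self):
        # position 15 of MIR is T; G:U wobble puts G opposite it
        assert MIR[14] == "T"
        target = _mutate_target_at_mirna_pos(MIR, _site_for(MIR), 15, "G")
        assert score_site(MIR, target)[0] == 0.5

    def test_wobble_in_seed_costs_double(self):
        assert MIR[4] == "G"
        target = _mutate_target_at_mirna_pos(MIR, _site_for(MIR), 5, "T")
        assert score_site(MIR, target)[0] == 1.0

    def test_window_shorter_than_mirna_raises(self):
        with pytest.raises(ValueError, match="shorter"):
            score_site(MIR, _site_for(MIR)[:-1])

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            m = int(rng.integers(8, 13))
            mir = _rand_seq(rng, m)
            wlen = m + int(rng.integers(0, 3))
            window = _rand_seq(rng, wlen)
            got, _ = score_site(mir, window)
            assert got == pytest.approx(_oracle_score(mir, window))

    def test_wobble_penalty_is_strand_direction_symmetric(self):
        """miRNA G over target T and miRNA T over target G both cost 0.5."""
        mir_g = "A" * 14 + "G" + "A" * 6  # G at position 15, outside the seed
        mir_t = "A" * 14 + "T" + "A" * 6
        t_g = _mutate_target_at_mirna_pos(mir_g, _site_for(mir_g), 15, "T")
        t_t = _mutate_target_at_mirna_pos(mir_t, _site_for(mir_t), 15, "G")
        assert score_site(mir_g, t_g)[0] == score_site(mir_t, t_t)[0] == 0.5

    @given(st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None)
    def test_breaking_a_match_never_lowers_expectation(self, seed):
        rng = np.random.default_rng(seed)
        mir = _rand_seq(rng, 21)
        target = _site_for(mir)
        base, _ = score_site(mir, target)
        pos = int(rng.integers(1, 22))
        i = 21 - pos
        bad = {"A": "C", "C": "A", "G": "A", "T": "C"}[mir[pos - 1]]
        mutated = target[:i] + bad + target[i + 1 :]
        worse, _ = score_site(mir, mutated)
        assert worse >= base


class TestPredictTargets:
    def test_exact_site_found_as_cleavage(self):
        rng = np.random.default_rng(1)
        t = _rand_seq(rng, 50) + _site_for(MIR) + _rand_seq(rng, 50)
        sites = predict_targets([("m1", MIR)], [("t1", t)])
        exact = [s for s in sites if s.expectation == 0.0]
        assert len(exact) == 1
        s = exact[0]
        assert (s.start, s.end) == (50, 71) and s.inhibition == "cleavage"

    def test_cutoff_zero_reports_only_perfect_sites(self):
        rng = np.random.default_rng(2)
        t = _rand_seq(rng, 40) + _site_for(MIR) + _rand_seq(rng, 40)
        sites = predict_targets([("m1", MIR)], [("t1", t)], cutoff=0.0)
        assert len(sites) == 1 and sites[0].expectation == 0.0

    def test_central_mismatch_marks_translational_inhibition(self):
        target = _mutate_target_at_mirna_pos(MIR, _site_for(MIR), 10, "C")
        assert MIR[9] not in ("G",)  # mutation is a real mismatch, not wobble
        rng = np.random.default_rng(3)
        t = _rand_seq(rng, 30) + target + _rand_seq(rng, 30)
        sites = predict_targets([("m1", MIR)], [("t1", t)], cutoff=3.0)
        assert sites and all(s.inhibition == "translation" for s in sites)

    def test_planted_sites_recovered_without_background(self):
        """All 10 planted near-perfect sites found; no background at cutoff 2."""
        rng = np.random.default_rng(42)
        mirnas = [(f"m{i}", _rand_seq(rng, 21)) for i in range(10)]
        transcripts = []
        planted = []
        for i, (mid, mir) in enumerate(mirnas):
            site = _site_for(mir)
            if i % 2:  # half the sites carry one non-seed wobble (<= 2)
                p = 16
                idx = len(mir) - p
                m = mir[p - 1]
                if m in ("G", "T"):
                    site = site[:idx] + {"G": "T", "T": "G"}[m] + site[idx + 1 :]
            pos = int(rng.integers(20, 200))
            t = _rand_seq(rng, pos) + site + _rand_seq(rng, 240 - pos)
            transcripts.append((f"t{i}", t))
            planted.append((mid, f"t{i}", pos))
        sites = predict_targets(mirnas, transcripts, cutoff=2.0)
        found = {(s.mirna_id, s.transcript_id) for s in sites}
        for mid, tid, _ in planted:
            assert (mid, tid) in found
        # every reported site is a planted one (no random background at 2.0)
        assert found == {(m, t) for m, t, _ in planted}

    def test_empty_inputs_raise(self):
        with pytest.raises(ValueError):
            predict_targets([], [("t1", "ACGT" * 30)])
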