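"""Folding, structure import, candidate extraction and duplex criteria."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirflow.annotate import Locus, identify_known, filter_ncrna, map_reference
from mirflow.hairpin import (
    PAIR_ENERGIES,
    PrecursorRecord,
    call_novel,
    evaluate_candidate,
    extract_candidates,
    fold,
    import_structure,
)
from mirflow.preprocess import SRNATag
from mirflow.simulate import SimulationConfig, make_hairpin, simulate_libraries
from mirflow import clean_reads, collapse


def _rand_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def _enumerate_best_energy(seq, min_loop=3):
    """Independent oracle: enumerate every non-crossing structure."""
    pe = {}
    for (a, b), e in PAIR_ENERGIES.items():
        pe[(a, b)] = e
        pe[(b, a)] = e

    def best(i, j):
        if j - i <= min_loop:
            return 0.0
        candidates = [best(i + 1, j)]
        for k in range(i + min_loop + 1, j + 1):
            e = pe.get((seq[i], seq[k]))
            if e is not None:
                right = best(k + 1, j) if k < j else 0.0
                candidates.append(e + best(i + 1, k - 1) + right)
        return min(candidates)

    return best(0, len(seq) - 1)


class TestFold:
    def test_gc_stem_hand_computed_energy(self):
        s = fold("GGGGAAAACCCC")
        assert s.dotbracket == "((((....))))"
        assert s.mfe == -12.0

    def test_unpairable_sequence_is_open(self):
        s = fold("AAAAAAA")
        assert s.dotbracket == "......." and s.mfe == 0.0

    def test_non_nucleotide_raises(self):
        with pytest.raises(ValueError, match="non-nucleotide"):
            fold("ACGTXACGTT")

    def test_matches_exhaustive_enumeration_up_to_15nt(self):
        rng = np.random.default_rng(3)
        for n in range(8, 16):
            for _ in range(4):
                seq = _rand_seq(rng, n)
                assert fold(seq).mfe == pytest.approx(_enumerate_best_energy(seq))

    def test_deterministic(self):
        seq = _rand_seq(np.random.default_rng(5), 40)
        assert fold(seq).dotbracket == fold(seq).dotbracket


class TestImportStructure:
    def test_valid_vienna_line_accepted(self):
        s = import_structure("GGGGAAAACCCC", "((((....))))", -11.2)
        assert s.mfe == -11.2 and s.pair_map[0] == 11

    def test_bracket_count_mismatch_rejected(self):
        with pytest.raises(ValueError, match="unbalanced"):
            import_structure("GGGGAAAACCCC", "((((....))).", -5.0)
        with pytest.raises(ValueError, match="length"):
            import_structure("GGGGAAAACCCC", "((((....)))", -5.0)

    def test_short_loop_rejected(self):
        with pytest.raises(ValueError, match="loop"):
            import_structure("GGAAGGAAACCCC", "(..(..)....).", -5.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            import_structure("GGGG", "(((....)))", -5.0)


class TestExtractCandidates:
    REF = {"t1": "A" * 600}

    def test_two_windows_contain_the_tag(self):
        tag = SRNATag("C" * 21, 1, 0)
        loc = Locus("t1", 100, 121, "+")
        cands = extract_candidates(tag, loc, self.REF)
        assert len(cands) == 2
        assert {c.arm for c in cands} == {"5p", "3p"}
        for c in cands:
            s, e = c.mature_span
            assert 0 <= s < e <= len(c.sequence)
            assert e - s == 21

    def test_window_clipped_at_transcript_start(self):
        tag = SRNATag("C" * 21, 1, 0)
        cands = extract_candidates(tag, Locus("t1", 5, 26, "+"), self.REF)
        assert all(c.mature_span[0] >= 0 for c in cands)
        assert len(cands) == 2

    def test_window_shorter_than_tag_yields_nothing(self):
        tag = SRNATag("C" * 21, 1, 0)
        assert extract_candidates(tag, Locus("t1", 0, 21, "+"), self.REF, window=10) == []


class TestEvaluateCandidate:
    def test_perfect_stem_accepted(self):
        prec = make_hairpin("ACGGATCCGTTCAAGGCCTAT", 6, 0, 0, seed=1)
        rep = evaluate_candidate(prec)
        assert rep.duplex_pairs == 21 and rep.bulge_nt == 0
        assert prec.structure.mfe <= -18
        assert rep.accepted and not rep.high_confidence

    def test_mfe_threshold_is_inclusive(self):
        prec = make_hairpin("ACGGATCCGTTCAAGGCCTAT", 6, 0, 0, seed=1)
        at = PrecursorRecord(
            "x", prec.sequence, prec.mature_span, "5p",
            structure=import_structure(prec.sequence, prec.structure.dotbracket, -18.0),
        )
        below = PrecursorRecord(
            "x", prec.sequence, prec.mature_span, "5p",
            structure=import_structure(prec.sequence, prec.structure.dotbracket, -17.9),
        )
        assert evaluate_candidate(at).mfe_ok
        assert not evaluate_candidate(below).mfe_ok
        assert not evaluate_candidate(below).accepted

    def test_five_bulges_fail_the_bulge_criterion(self):
        prec = make_hairpin("ACGGATCCGTTCAAGGCCTAT", 6, 0, 5, seed=2)
        rep = evaluate_candidate(prec)
        assert rep.bulge_nt == 5 and not rep.bulge_ok and not rep.accepted

    def test_star_observation_flags_high_confidence(self):
        prec = make_hairpin("ACGGATCCGTTCAAGGCCTAT", 6, 0, 0, seed=1)
        star = prec.star
        rep = evaluate_candidate(prec, [SRNATag(star, 1, 0)])
        assert rep.star_observed and rep.high_confidence

    @pytest.mark.parametrize("mm", [0, 1, 2])
    @pytest.mark.parametrize("bulges", [0, 1, 5])
    def test_parameter_recovery_on_constructed_precursors(self, mm, bulges):
        """Evaluation recovers the constructed pair and bulge counts exactly."""
        rng = np.random.default_rng(17)
        for seed in range(6):
            mature = _rand_seq(rng, int(rng.integers(18, 26)))
            prec = make_hairpin(mature, 8, mm, bulges, seed=seed)
            rep = evaluate_candidate(prec)
            assert rep.duplex_pairs == len(mature) - mm
            assert rep.bulge_nt == bulges + 2 * mm

    def test_monotonicity_mismatches_never_gain_pairs(self):
        rng = np.random.default_rng(23)
        for seed in range(5):
            mature = _rand_seq(rng, 22)
            pairs = [
                evaluate_candidate(make_hairpin(mature, 8, mm, 0, seed=seed)).duplex_pairs
                for mm in range(4)
            ]
            assert pairs == sorted(pairs, reverse=True)

    @given(st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None)
    def test_accepted_implies_all_criteria(self, seed):
        """Report consistency: accepted <=> all four criterion booleans."""
        rng = np.random.default_rng(seed)
        seq = _rand_seq(rng, int(rng.integers(60, 140)))
        s = int(rng.integers(0, len(seq) - 21))
        prec = PrecursorRecord("f", seq, (s, s + 21), "5p").folded()
        rep = evaluate_candidate(prec)
        assert rep.accepted == (
            rep.mature_len_ok and rep.pairs_ok and rep.mfe_ok and rep.bulge_ok
        )
        assert rep.high_confidence == (rep.accepted and rep.star_observed)


class TestCallNovel:
    def test_no_unannotated_tags_gives_empty_table(self, sim_dataset):
        df = call_novel([], sim_dataset.reference)
        assert df.empty and "mirna" in df.columns

    def test_identical_mature_at_two_loci_is_one_family(self):
        # one mismatch in the star so the tag maps only at its two planted
        # forward loci (a perfect star would also map as reverse complement)
        prec = make_hairpin("ACGGATCCGTTCAAGGCCTAT", 8, 1, 0, seed=3)
        rng = np.random.default_rng(8)
        pad = lambda n: _rand_seq(rng, n)
        ref = [
            ("t1", pad(60) + prec.sequence + pad(60)),
            ("t2", pad(40) + prec.sequence + pad(80)),
        ]
        tag = SRNATag(prec.mature, 8, 4)
        df = call_novel([tag], ref)
        assert len(df) == 1
        assert int(df.iloc[0]["loci"]) == 2

    def test_planted_hairpins_recovered_with_star_flags(self):
        """>=90% of adequately-expressed planted novel miRNAs are called,
        and observed star tags flag their precursors high-confidence."""
        expressed = 0
        recovered = 0
        for seed in (0, 1, 2, 3, 4):
            cfg = SimulationConfig(seed=seed, depth_per_library=30_000)
            ds = simulate_libraries(cfg)
            clean_vs, _ = clean_reads(ds.reads_vs, cfg.adapter5, cfg.adapter3)
            clean_rs, _ = clean_reads(ds.reads_rs, cfg.adapter5, cfg.adapter3)
            tags = collapse(clean_vs, clean_rs)
            retained, _ = filter_ncrna(tags, ds.ncrna_catalog)
            known = {a.tag.sequence for a in identify_known(retained, ds.mature_catalog)}
            unann = [t for t in retained if t.sequence not in known]
            df = call_novel(unann, ds.reference)
            called = set(df.mature)
            hc = set(df[df.high_confidence].mature)
            truth = ds.ledger.mirnas
            tag_counts = {t.sequence: t.total for t in tags}
            star_by_mature = {p.mature: p.star for p in ds.ledger.precursors}
            for row in truth[truth.novel].itertuples():
                if tag_counts.get(row.mature, 0) < 5:
                    continue
                expressed += 1
                if row.mature in called:
                    recovered += 1
                    if star_by_mature[row.mature] in tag_counts:
                        assert row.mature in hc
        assert expressed >= 20
        assert recovered / expressed >= 0.9
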