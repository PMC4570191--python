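"""Reference mapping, ncRNA filtering, known-miRNA identification, count tables."""

import numpy as np
import pytest

from mirflow._seq import revcomp
from mirflow.annotate import (
    Locus,
    build_count_table,
    family_name,
    filter_ncrna,
    format_ratio,
    identify_known,
    map_reference,
)
from mirflow.preprocess import SRNATag

TAG = "ACGTACGGTTCAAGGCCTATG"  # 21 nt


def _rand_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


class TestMapReference:
    def test_forward_locus_coordinates(self):
        ref = [("t1", "G" * 100 + TAG + "C" * 50)]
        loci = map_reference([SRNATag(TAG, 1, 0)], ref)[TAG]
        assert [(l.transcript_id, l.start, l.end, l.strand) for l in loci] == [
            ("t1", 100, 121, "+")
        ]

    def test_reverse_complement_locus(self):
        ref = [("t1", "G" * 30 + revcomp(TAG) + "C" * 30)]
        loci = map_reference([SRNATag(TAG, 1, 0)], ref)[TAG]
        assert loci == [Locus("t1", 30, 51, "-")]

    def test_unmapped_tag_is_flagged_not_dropped(self):
        loci = map_reference([SRNATag(TAG, 1, 0)], [("t1", "G" * 80)])
        assert loci[TAG] == []


class TestFilterNcrna:
    CAT = [("rRNA_1", "G" * 10 + TAG + "G" * 10), ("tRNA_1", "C" * 40)]

    def test_substring_match_removed_with_class(self):
        retained, removed = filter_ncrna([SRNATag(TAG, 1, 0)], self.CAT)
        assert retained == [] and removed[0][1] == "rRNA"

    def test_non_matching_tag_retained(self):
        other = "T" * 21
        retained, removed = filter_ncrna([SRNATag(other, 1, 0)], self.CAT)
        assert len(retained) == 1 and removed == []

    def test_first_matching_record_wins(self):
        cat = [("tRNA_a", TAG + "A" * 5), ("snoRNA_b", TAG + "C" * 5)]
        _, removed = filter_ncrna([SRNATag(TAG, 1, 0)], cat)
        assert removed[0][1] == "tRNA"

    def test_header_without_class_token_errors(self):
        with pytest.raises(ValueError, match="class token"):
            filter_ncrna([SRNATag(TAG, 1, 0)], [("mystery_1", "A" * 30)])


class TestIdentifyKnown:
    CATALOG = [("ath-miR156a", TAG), ("ath-miR157a", TAG[:-1] + "A")]

    def test_exact_match_zero_mismatches(self):
        asg = identify_known([SRNATag(TAG, 2, 1)], self.CATALOG)
        assert asg[0].mirna_id == "ath-miR156a" and asg[0].n_mismatches == 0

    def test_distance_three_rejected(self):
        far = "TTT" + TAG[3:]
        assert identify_known([SRNATag(far, 1, 0)], [("ath-miR156a", TAG)]) == []

    def test_empty_catalog_errors(self):
        with pytest.raises(ValueError):
            identify_known([SRNATag(TAG, 1, 0)], [])

    def test_matches_brute_force_hamming_oracle(self):
        """Assignments equal an independent all-pairs sliding-Hamming scan."""
        rng = np.random.default_rng(42)
        catalog = [(f"ath-miR{100+i}a", _rand_seq(rng, int(rng.integers(19, 25))))
                   for i in range(50)]
        tags = []
        for _ in range(200):
            if rng.random() < 0.5:
                base = catalog[int(rng.integers(0, 50))][1]
                seq = list(base)
                for _ in range(int(rng.integers(0, 4))):
                    p = int(rng.integers(0, len(seq)))
                    seq[p] = "ACGT"[int(rng.integers(0, 4))]
                tags.append("".join(seq))
            else:
                tags.append(_rand_seq(rng, int(rng.integers(18, 26))))
        tags = [SRNATag(s, 1, 0) for s in set(tags)]

        def oracle_best(seq):
            best = (10**9, None)
            for mid, cat in catalog:
                a, b = (seq, cat) if len(seq) <= len(cat) else (cat, seq)
                d = len(b) - len(a)
                if d > 2:
                    continue
                for off in range(d + 1):
                    mm = d + sum(x != y for x, y in zip(a, b[off:off + len(a)]))
                    if mm < best[0]:
                        best = (mm, mid)
            return best if best[0] <= 2 else None

        got = {a.tag.sequence: (a.n_mismatches, a.mirna_id)
               for a in identify_known(tags, catalog)}
        want = {t.sequence: oracle_best(t.sequence) for t in tags}
        want = {k: v for k, v in want.items() if v is not None}
        assert got == want


class TestFamilies:
    @pytest.mark.parametrize(
        "mid, fam",
        [
            ("ath-miR156a-5p", "miR156/157"),
            ("osa-miR157b", "miR156/157"),
            ("rsa-miR165-3p", "miR165/166"),
            ("ath-miR408", "miR408"),
            ("rsa-miRn2", "miRn2"),
        ],
    )
    def test_family_naming_and_merge(self, mid, fam):
        assert family_name(mid) == fam


class TestCountTable:
    N1, N2 = 18_948_210, 17_893_663

    def test_single_member_family_ratio(self):
        table = build_count_table([("miR408", "miR408", 4544, 740985)], self.N1, self.N2)
        row = table.families.iloc[0]
        assert row["total"] == 745529 and row["ratio"] == "163.07"

    def test_family_aggregation_and_ratio(self):
        rows = [(f"m{i}", "miR156/157", v, r) for i, (v, r) in
                enumerate([(100000, 50000), (100000, 50000), (66846, 50543)])]
        table = build_count_table(rows, self.N1, self.N2)
        fam = table.families.iloc[0]
        assert fam["count_vs"] == 266846 and fam["count_rs"] == 150543
        assert fam["total"] == 417389 and fam["ratio"] == "0.56"

    def test_zero_vs_ratio_is_dash(self):
        table = build_count_table([("miR535", "miR535", 0, 2797)], self.N1, self.N2)
        assert table.families.iloc[0]["ratio"] == "–"

    def test_zero_rs_ratio_is_zero(self):
        assert format_ratio(144, 0) == "0"

    def test_family_totals_invariant_under_member_order(self):
        rows = [("a", "f", 10, 1), ("b", "f", 5, 2), ("c", "f", 1, 3)]
        t1 = build_count_table(rows, 100, 100)
        t2 = build_count_table(rows[::-1], 100, 100)
        assert t1.families.equals(t2.families)


def test_every_tag_lands_in_exactly_one_bin(sim_dataset, sim_tags):
    """Partition: ncRNA-removed | known | unannotated covers all tags once."""
    tags = sim_tags["tags"]
    retained, removed = filter_ncrna(tags, sim_dataset.ncrna_catalog)
    assert len(retained) + len(removed) == len(tags)
    assignments = identify_known(retained, sim_dataset.mature_catalog)
    known = {a.tag.sequence for a in assignments}
    unann = [t for t in retained if t.sequence not in known]
    assert len(unann) + len(known) == len(retained)
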