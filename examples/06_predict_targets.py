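"""Score miRNA-target complementarity and scan transcripts for sites.

Penalties: mismatch 1.0, G:U wobble 0.5, gap 2.0, doubled at miRNA
positions 2-13 (the 5' seed).  Sites with total penalty ("expectation")
<= 3.0 are reported; a site mismatched at miRNA positions 9-11 is
annotated as translational inhibition rather than cleavage.
"""

from mirflow import predict_targets, score_site
from mirflow._seq import revcomp

mir = "TGGAGCTCCCTTCATTCCAAT"
perfect = revcomp(mir)
exp, aln = score_site(mir, perfect)
print(f"perfect site, expectation {exp}:")
print("  miRNA  3' " + aln[0] + " 5'")
print("            " + aln[1])
print("  target 5' " + aln[2] + " 3'")

# one seed mismatch doubles its penalty (window index 10 faces miRNA
# position 11, inside the 2-13 seed)
bad = "C" if perfect[10] != "C" else "G"
mutated = perfect[:10] + bad + perfect[11:]
print("seed-region mismatch:", score_site(mir, mutated)[0])

transcripts = [
    ("SPL-like", "GCAGTGCTCTCTCTCTTCTGTCA" + perfect + "ATGGCATGATCGATCGGCACGT"),
    ("unrelated", "ACGGATTTCAGGCACGTACGGTTCAAGGCCTATGCTACCGGATCCATGGCAC"),
]
for site in predict_targets([("rsa-miR1", mir)], transcripts, cutoff=3.0):
    print(f"{site.mirna_id} -> {site.transcript_id}[{site.start}:{site.end}] "
          f"expectation {site.expectation}, {site.inhibition}")
# Only the transcript carrying the complementary site is reported; lower
# expectation = tighter complementarity.
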