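"""Predict novel miRNAs from unannotated tags via hairpin criteria.

Unannotated mapped tags are expanded into candidate precursor windows,
folded, and kept when the miRNA/miRNA* duplex has >= 16 pairs, <= 4
bulged nucleotides, and precursor MFE <= -18 kcal/mol; observing the
star strand in the reads marks a call high-confidence.
"""

from mirflow import clean_reads, collapse, filter_ncrna, identify_known, call_novel
from mirflow.simulate import SimulationConfig, simulate_libraries

cfg = SimulationConfig(seed=7, depth_per_library=20_000)
ds = simulate_libraries(cfg)
clean_vs, _ = clean_reads(ds.reads_vs, cfg.adapter5, cfg.adapter3)
clean_rs, _ = clean_reads(ds.reads_rs, cfg.adapter5, cfg.adapter3)
tags = collapse(clean_vs, clean_rs)
retained, _ = filter_ncrna(tags, ds.ncrna_catalog)
known = {a.tag.sequence for a in identify_known(retained, ds.mature_catalog)}
unannotated = [t for t in retained if t.sequence not in known]

novel = call_novel(unannotated, ds.reference)
print(novel.to_string(index=False))

truth = ds.ledger.mirnas
planted = set(truth[truth.novel].mature)
called = set(novel.mature)
print(f"\nplanted novel matures recovered: {len(planted & called)}/{len(planted)}")
# Star-strand tags are also genuine duplex products, so they may appear as
# extra calls; 'lp' and 'MFE' describe the best-scoring precursor window.
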