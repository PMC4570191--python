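# Methods

This note documents the models implemented in `mirflow`, the assumptions
behind them, the tunable parameters that matter, and the choices made
where the underlying workflow left the design open.

## Study design being emulated

The pipeline targets the classical two-library plant sRNA-seq design: one
deeply sequenced library per biological condition (here a vegetative-stage
"VS" and a reproductive-stage "RS" radish leaf library), no replicates.
All inference is therefore per-tag count arithmetic between two known
library depths; nothing in the package estimates biological dispersion,
and none of its P-values should be read as replicate-aware.

## Read cleaning

Raw reads are `insert + 3' adapter (+ tail)`. The filter order is fixed
and each discarded read is counted in exactly one category:

1. low quality — any `N`, or mean Phred < 20 when qualities are present.
   The upstream workflow never defines "low quality"; this rule is a
   declared convention of this package, exposed via `min_mean_quality`.
2. 5'-adapter contaminant — the full 5' adapter found anywhere past the
   first position (a ligation artifact).
3. 3'-adapter location — leftmost exact match of the adapter's first
   8 nt (`adapter3_seed_len`); no match → `adapter3_null`. Exact seeding
   keeps trimming deterministic and testable; tolerant matching was
   deliberately not implemented.
4. empty insert → `insert_null` (adapter dimers).
5. poly-A — insert ≥90% A (`polya_threshold`; the workflow names the
   category but not the threshold).
6. length — inserts shorter than 18 nt are counted as in published
   accounting tables; inserts longer than 30 nt go to a separate
   `longer_than_max` bucket because those tables print no over-length
   category. The partition invariant
   `high_quality = clean + Σ categories` is asserted on every run.

Passing empty adapters switches to a bypass mode for already-trimmed
inserts, which makes cleaning idempotent.

## Known-miRNA identification

Ungapped end-to-end comparison against the mature catalog: equal lengths
use Hamming distance; a length difference ≤2 slides the shorter sequence
along the longer with overhanging positions counted as mismatches; best
entry wins, ties broken by catalog order, rejected above 2 mismatches.
Indel-tolerant matching was rejected for determinism. Families derive
from identifiers (species prefix and arm/variant suffixes stripped) with
a configurable merge map uniting miR156/157 and miR165/166, whose mature
sequences are not reliably distinguishable. Structural-ncRNA removal is
exact substring matching (either strand) against the catalog — the
original workflow used BLASTn, but at 18–30 nt tag scale exact matching
is the reproducible core of that step.

## Hairpin model

Folding uses a declared base-pair-wise energy model: GC −3, AU −2,
GU −1 kcal/mol, hairpin loops ≥3 nt, total energy minimized exactly by
dynamic programming with a deterministic traceback (prefer pairing the
left end; among partners prefer the smallest index). This is *not* a
nearest-neighbour thermodynamic model: it has no stacking or loop
penalties, so long windows over-pair and absolute MFE values are much
more negative than thermodynamic ones. The −18 kcal/mol acceptance gate
is calibrated to this scale (any realistic stem clears it), and
`import_structure` accepts Vienna-style dot-bracket output from an
external folder whenever thermodynamic fidelity matters.

Because the global minimum-energy structure of a 250-nt window need not
thread the mature tag through its true duplex (bulges are free, so the
optimum may scatter the mature's pairings), duplex statistics are taken
from whichever is stronger of (a) the dominant contiguous helix in the
folded structure — pairs separated by more than 6 unpaired nt on either
strand are treated as different structural elements — and (b) a direct
antiparallel local alignment of the mature against the opposite arm
(pair +1, internal unpaired nt penalized so that bridging more than 6 nt
for one extra pair never pays). Acceptance requires mature length
18–25 nt, ≥16 duplex pairs, ≤4 unpaired nt inside the duplex (each
asymmetric nucleotide counted once) and window MFE ≤ −18 kcal/mol. The
star span is the duplex region on the opposite arm shifted 2 nt toward
its own 3' end (canonical DCL1 2-nt 3' overhangs); a tag exactly equal
to the star sequence upgrades the call to high confidence.

Candidate windows place the tag on either arm (`[start−20, end+window]`
and `[start−window, end+20]`, window 250 nt by default, clipped); the
best accepted precursor per locus is the one with lowest MFE, then
shortest, then leftmost. Tags sharing a mature sequence across loci form
one novel family whose `loci` column counts accepted loci. In
simulations ~98% of adequately expressed planted hairpins are recovered;
the remainder evaluate to a bulge-heavier maximum-pairing duplex
(bridging into flanking sequence) and are rejected — a known property of
maximizing pairs first. Star-strand tags are genuine duplex products and
may legitimately appear as additional calls.

## Differential expression

Normalization is reads-per-million of the *whole-library* clean-read
total. Zero RPM values are floored at 0.01 before the ratio; this is the
unique simple convention that reproduces both published library-specific
fold-changes (13.93 from counts 0→2,797 and 11.52 from 0→525 given the
printed clean totals), and it leaves strictly positive counts untouched.

Significance uses the exact conditional count law for two libraries of
depths N₁, N₂: given x, the second count follows
NB(x+1, N₁/(N₁+N₂)) — the Audic–Claverie statistic. The two-sided
P-value doubles the smaller of the inclusive tails and caps at 1; it is
computed through log-space negative-binomial tail functions and clamped
at 1e-300 (double precision cannot represent the true P for extreme
imbalances). Two properties of this convention are worth knowing: it is
conservative near the null (x=y gives P=1), and it is indexed by the
first count, so P(x,y,N₁,N₂) and P(y,x,N₂,N₁) agree only asymptotically
for large counts, exactly for x=y at equal depths.

Calls: up iff log₂FC ≥ 1 and P ≤ 0.05; down symmetric; boundaries
inclusive, matching the printed rule. No multiple-testing correction is
applied by default because the original decision rule uses raw P;
Benjamini–Hochberg is available behind `bh_correct=True`. Consequently
the false-discovery behaviour is only controlled for detectably
expressed miRNAs: the planted-effect suite simulates 200 miRNAs at
median 500 RPM (log-normal σ=0.8), depth 10⁵, 20 planted at |log₂FC|=2,
and checks sensitivity ≥0.9 with empirical FDR ≤0.1 over 50 seeds; with
many miRNAs at a handful of reads the raw-P rule cannot bound FDR, and
no parameter choice here pretends otherwise.

2^−ΔΔCt: relative expression 2^−((Ct_target−Ct_ref)_sample −
(Ct_target−Ct_ref)_calibrator); pure arithmetic, no amplification-
efficiency correction.

## Target prediction

Expectation score = total penalty of the optimal global gapped alignment
of the miRNA (3'→5') against a transcript window (5'→3'): mismatch 1.0,
G:U wobble 0.5 (both orientations), gap 2.0, all doubled at miRNA
positions 2–13 from the 5' end; a gap in the miRNA takes the seed factor
of the next miRNA position toward the 5' end. Windows of length m to m+2
are scanned; sites ≤ cutoff (default 3.0) are kept; overlapping spans
(≥50% of the shorter) merge keeping the lowest expectation. Inhibition
is cleavage unless any of miRNA positions 9–11 is unpaired or
mismatched. This emulates the published defaults of the standard plant
target server without claiming bit-compatibility; target-site
accessibility (UPE) energy is not computed, as it requires a partition-
function folder. For throughput, a vectorized ungapped pre-scan gates
the exact DP (`dp_margin`, default 8.0 penalty units above cutoff — a
qualifying gapped site whose ungapped version exceeds that margin would
be missed, which is vanishingly unlikely at the default).

One often-assumed invariant is deliberately *not* claimed: the score is
not invariant under jointly reverse-complementing miRNA and window,
because reverse complementation maps some plain mismatches onto G:U
wobbles (e.g. A:C → G:U) and the seed region does not transform
covariantly. Strand-direction symmetry of the wobble penalty itself is
tested instead.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes,
not any particular instrument:

- **Abundances** — log-normal family weights (σ = `abundance_dispersion`,
  default 1.5) with log-normal member weights inside each family,
  reproducing the heavy-tailed conserved ≫ novel pattern; novel hairpins
  get a small class share (6% of clean mass by default vs 55% known).
- **Lengths** — mature and background insert lengths are drawn so the
  overall clean 21-nt fraction converges to `length_mode_fraction_21nt`
  (default 0.43, the midpoint of the two real libraries' 33.33% and
  52.97%); the per-read draws for degradation/ncRNA inserts compensate
  for the fixed-length mature mass.
- **Planted fold-changes** — applied to the RS weights on the
  reads-per-million scale, with the weight difference absorbed by the
  degradation bucket so both libraries keep comparable clean totals; a
  planted miRNA's base abundance is capped so the shift can never
  exhaust that bucket. Recovery is unbiased to within ±0.2 log₂ units
  over 50 replicates at depth 10⁵.
- **Contaminants and artifacts** — `contaminant_fraction` (default 0.12)
  splits half into ncRNA fragments and the rest evenly across low-quality,
  poly-A, adapter-dimer, missing-3'-adapter, 5'-adapter-contaminant and
  short-insert reads — one class per published accounting category.
- **Hairpins** — `make_hairpin` builds mature + loop + star (+2-nt
  overhang) with requested mismatches (star base set equal to the
  opposing mature base, which cannot pair) and single-nucleotide bulges
  (bases chosen unpairable in context); each construction is verified
  against the duplex-alignment search and re-drawn deterministically
  until the planted duplex is the optimum, so evaluation recovers
  `pairs = L − mismatches` and `bulge_nt = bulges + 2·mismatches`
  exactly. Simulated novel precursors use 0–1 mismatches and no bulges
  so they also survive refolding from reference windows.
- **Sampling** — one multinomial per library over all atomic sources;
  zero counts for rare sources arise naturally and exercise the
  zero-floor rule downstream. Identical configs give byte-identical
  files.

What it does **not** emulate: platform error models (reads are exact
copies), quality-score distributions (constant Phred), genome-scale
references, isomiR processing variability, and ncRNA families with real
sequence composition. Passing tests therefore demonstrate the pipeline's
arithmetic and inferential behaviour under the assumed read-generating
process, not robustness to sequencing error or to real transcriptome
complexity.

## Problem sizes used by the test and acceptance suites

Simulated libraries use 2×10⁴–10⁵ reads over ~40 transcripts, 12 known
families and 6 novel hairpins; the planted-effect suites use 50 replicate
seeds; folding oracles enumerate all structures up to 15 nt; the
mismatch oracle covers 500 tags × 100 catalog entries. These sizes were
chosen so every statistical band (type-I error ±0.01, fold-change ±0.2,
sensitivity/FDR) is tight at desk scale.

## Known limitations

- The energy model's MFE scale is internal; only import thermodynamic
  values for publication-grade precursor reporting.
- Novel-miRNA calling maximizes duplex pairs first, which can reject a
  genuine hairpin whose best full-extent duplex is bulge-heavy (~2% of
  planted cases).
- The exact count test is valid for technical (Poisson) variation
  between two libraries only; between-replicate biological variance is
  out of scope by design.
- The family-percentage figures some studies print (shares "of all known
  miRNA reads") are not reproducible from family count tables alone and
  are not computed here.
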