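# Methods

This note records the models, parameter choices and numerical
decisions behind `mirpipe`, and what the synthetic studies do and do
not demonstrate.

## Study design being modelled

The pipeline targets the un-replicated two-library design: one pooled
small-RNA library per condition, sequenced deeply (order 10⁷ clean
reads in the motivating porcine backfat data).  All inference is
count-based and conditional; there is no dispersion estimation because
there are no replicates to estimate it from.  Users with replicated
designs should use a dispersion-aware method instead — this package
deliberately implements the single-library exact test.

## Preprocessing

Reads are scanned for the first `seed_len = 8` bases of the 3'
adapter.  An exact leftmost hit wins (partial hits at the read end
accepted down to 5 nt); only when no exact hit exists is one mismatch
tolerated in a full-length seed.  Exact-first matters: allowing a
mismatch everywhere truncates ~1% of inserts at chance near-matches.
Reads beginning with ≥10 nt of the 5' adapter (≤1 mismatch) are
discarded as adapter dimers; the 10 nt floor keeps random insert
starts (expected 5-mer collision rate ~2%) from being miscalled.
"Low quality" is operationalised as mean Phred < Q20 over the insert
or any N; FASTA input skips the quality rule silently.  Tags outside
18–30 nt are dropped; identical sequences are collapsed with
per-library counts kept separate end to end.

## Known-miRNA annotation

Matching implements the "two mismatches, gaps count as mismatches"
rule literally as Levenshtein distance ≤ 2, computed with edlib
(banded, exact for small distances).  IsomiR end offsets up to ±4 nt
are free: reference variants are enumerated by sliding each end of the
mature within its hairpin (so templated extensions use real precursor
sequence), and the best alignment minimises (mismatches, |5' offset|,
name) — deterministic total order.  Reverse-complement matching is not
attempted; small-RNA protocols are strand-preserving.  Category
precedence is known miRNA > other ncRNA > unannotated; the "other
ncRNA" check is an exact substring test against a user-supplied FASTA.
Arm assignment is by the mature midpoint relative to the hairpin
midpoint, ties broken by start position.

## Differential expression

* Normalization: `NE = count / N × 10⁶` with `N` the library's clean
  reads.  A zero NE is revised to 0.01 so ratios stay finite; a miRNA
  below 1 TPM in **both** libraries is excluded from testing (rows
  that are quiet in only one library are exactly the interesting
  ones and are kept — e.g. a 0.10 TPM / 1.35 TPM miRNA is testable and
  significant).
* Fold change: `log2(NE₂/NE₁)`, library 2 over library 1.
* Exact test: conditionally on `x` counts in library 1, the other
  count is `Y | x ~ NB(x+1, N₁/(N₁+N₂))` (the Audic–Claverie
  conditional law for a library-size ratio `N₂/N₁`).  A doubled-tail
  p-value `min(1, 2·min(P(Y≤y), P(Y≥y)))` is computed in **both**
  conditioning orientations — on `x` and on `y` — and the smaller is
  reported.  The min-orientation convention was adopted because (a) it
  is exactly symmetric under swapping the libraries, which the
  single-orientation form is not (tails differ by up to the library
  ratio), and (b) it reproduces every nonzero p-value of the bundled
  published table to its printed precision (max |Δlog10 p| ≈ 1.4×10⁻⁵
  across 54 rows), whereas single-orientation forms mismatch roughly
  half the rows.
* Numerics: tail sums use lgamma + logsumexp.  The complement tail
  `P(Y ≥ y) = 1 − P(Y ≤ y−1)` is used only when `y ≤ E[Y]`, where the
  subtracted mass is ≤ ~1/2 and the complement loses no precision;
  otherwise the upper tail is summed directly and truncated 40
  standard deviations past `y` (relative truncation error < 10⁻¹³).
  Agreement with a 250-digit direct-summation oracle is ≤ ~10⁻¹³
  relative on the tested grid.  Returned p-values are clamped to the
  smallest positive double rather than 0.
* No multiple-testing correction is applied by default (labels use raw
  p, matching the published convention); `build_table(with_bh=True)`
  adds a Benjamini–Hochberg column.

## Novel hairpin prediction

Unannotated tags are mapped by exact full-length string search on both
strands; tags with more than 20 genomic hits are set aside as
repeat-derived.  Around each locus two windows are excised — (70 up,
20 down) and (20 up, 70 down) — so a real mature is covered with its
full precursor in at least one placement for typical 60–100 nt
hairpins.  Windows fold with ViennaRNA's current default
nearest-neighbor parameters (Turner 2004); published MFEs computed
with older parameter sets agree only to a few percent, which is why
the precursor checks use a ±10% band and never bit-exact equality.

Screening criteria (defaults, all configurable): MFE ≤ −18 kcal/mol;
mature 18–26 nt; window ≤ 200 nt; all paired mature bases pairing to
one side only (no self-pairing, no terminal-loop overlap); ≥16 base
pairs counted over the mature:miR\* duplex span — the mature plus the
2-nt Dicer offset on its loop-proximal side, which is the span the
duplex physically occupies; and no asymmetric internal loop > 4 nt
between consecutive duplex pairs.  Counting pairs over the duplex span
rather than the bare mature matters at the margin: one published 20-nt
mature carries 15 paired bases under current energy parameters but 17
over its duplex span, and the duplex is what the ≥16 criterion is
about.  The predicted miR\* is the partner interval of the mature's
paired ends shifted +2 for the 3' overhangs; an observed tag matching
it within ±1 nt per end counts as supporting evidence but is never
required.

Fold-based screening alone is not specific: ~4–5% of random ~110 nt
windows form long stem-loops that satisfy every structural criterion.
The pipeline therefore folds only tags with ≥5 supporting reads
(`min_novel_reads`, configurable) — the standard read-evidence
requirement of hairpin-prediction tools — which removes near-singleton
degradation fragments while keeping any expressed candidate.  The
op-level `predict_novel` keeps `min_reads=1` so the raw behaviour
remains accessible.

Genomic context calls (exon / intron / mixed one gene / two genes /
intergenic) come from interval overlap against gene+exon features of a
GFF3 (introns inferred as inter-exon gaps).  Coordinates are 0-based
half-open internally; GFF3 output is 1-based inclusive.

## Seed edits

A candidate edit is a tag aligning end-anchored (same ±4 end slack,
no indels) to a known mature with exactly one substitution, located at
mature positions 2–8.  Indels are not edits — RNA editing is
substitution-only.  Each tag reports one event (best |5' offset|, then
name).  Because a one-substitution tag is, by the two-mismatch rule,
already annotated as a known-miRNA variant, the pipeline feeds the
seed-edit scanner every tag *not exactly explained* by a mature
(unannotated, or known with ≥1 mismatch); the scanner itself is total
over any tag set.  The spectrum table always contains all 12 ordered
substitution types, zero-filled, sorted by supporting reads.  The
method cannot distinguish editing from genomic SNPs or sequencing
error; on real data the spectrum's enrichment pattern, not any single
event, is the interpretable output.

## Clustering

Single-linkage chaining of precursor loci per chromosome with gap
(next start − running max end) strictly < 10 kb, strand-agnostic;
equivalent to connected components of the pairwise proximity graph
(property-tested).  Before clustering, the pipeline merges loci within
one precursor footprint (< 120 nt apart), so a mature and its miR\*
never masquerade as a two-member cluster.

## Synthetic data generator

The generator emulates the study's input structure with full ground
truth: uniform-random chromosomes (default 2 × 200 kb) with 20
embedded hairpins, 4 of them spaced 3 kb apart as one planted cluster
and the rest ≥15 kb apart so no accidental clusters arise; half the
hairpins are exported as the "known" reference (precursor plus 5 nt
genomic flank each side, as curated databases record stem-loops), the
rest are left for novel prediction.  Hairpins are constructed — a
GC-balanced 22-mer mature, a 10–14 nt loop, and the mature's reverse
complement as the opposite arm — so they satisfy the screening
criteria by construction, independent of any folding backend.

Libraries (default 5×10⁴ reads each) draw per-miRNA counts Poisson
around lognormal abundances; 30% of miRNAs get ±2 log2 fold changes
(balanced signs) in library 2, and the *effective* fold change after
renormalisation is recorded as truth.  Reads carry 3'-biased isomiR
offsets (5': 0.90/0.05/0.05 for 0/±1; 3': 0.50/0.20/0.15/0.10/0.05 for
0/+1/−1/+2/−2), seed-edited single-substitution variants at rate 0.02
with A→G weighted 10× over other substitutions, miR\* reads at 10% of
the mature count, and 15% background genome fragments with an 18–30 nt
length distribution centred on 22 nt — giving the overall 22 nt length
mode typical of Dicer products.  Counts are Poisson, not negative
binomial, because the inferential model under test assumes single
libraries without biological replication.  Everything flows from one
seeded generator; identical seeds give byte-identical output files.

What passing synthetic tests do *not* show: robustness to sequencing
error (none is simulated beyond the planted substitutions), to
repetitive genomes (the background is uniform-random, so mapping is
nearly unambiguous), to cross-mapping between related miRNA family
members, or to adapter variants.  Real-data behaviour on those axes is
untested.

## Problem sizes used in checks

The bundled checks run a complete synthetic study at the default scale
(2 × 200 kb genome, 20 hairpins, 2 × 5×10⁴ reads), a 2000-pair null
simulation for the type-I error rate, and p-value oracle comparisons
on count grids up to 30 at library-size ratios spanning 1:19 000 —
sizes chosen so the whole suite completes in well under a minute per
component on one core while every stage still sees hundreds to
thousands of events.

## Known limitations

* `map_to_genome` is plain string search — fine for toy genomes,
  quadratic-ish for real ones; swap in an FM-index aligner for real
  data.
* The exact test's min-orientation convention, while symmetric and
  faithful to the published numbers, is slightly anti-conservative
  relative to a single fixed orientation; the null simulation bounds
  the effect (type-I ≈ 0.04–0.05 at nominal 0.05).
* Novel-candidate specificity relies on read support plus structure;
  no shuffling-based significance (randfold-style) is computed.
* miRBase-style name matching between mature and hairpin records uses
  case-insensitive prefix identity after stripping arm suffixes; exotic
  naming schemes may need explicit placements.
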