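# Methods

This note documents the models, conventions, parameter choices and known
limitations behind `xistkit`.  The package is organised as seven library
modules — `synthetic_data`, `homology_scan`, `gene_model`, `ends_and_motifs`,
`repeat_finder`, `methylome`, `coverage` — plus `files` for interchange
formats; `examples/` holds one narrative script per capability.

## Coordinate conventions

Three frames are used (all conversions live in `coords.py`):

* **locus** — 0-based half-open indices into the gene-forward
  (transcribed-strand) sequence the generator works in;
* **scaffold** — 1-based inclusive positions on the forward strand of the
  released scaffold; the default gene sits on the minus strand, so the TSS is
  at a high scaffold coordinate and transcription runs toward lower ones
  (transcript position t maps to scaffold s as `t = tss − s + 1` within
  exon 1);
* **promoter** — +1 is the TSS base, −1 the base immediately upstream,
  position 0 does not exist.

Offsets between transcript ends are reported primarily as inclusive position
counts (two equal coordinates count 1), because that is the convention under
which a 9-bp shift is "10 bp downstream"; the plain difference is emitted
alongside.  Percentages and copy numbers round half-up (49.85 from
334/670; 91.7 from 8801/96).  Note 64.5/67 = 96.2686… rounds to 96.27.

## The synthetic locus (`synthetic_data`)

`GeneSpec` declares the gene: exon/intron lengths, strand, flank lengths,
tandem-repeat arrays (period, fractional copies, transcript start,
divergence), the promoter CpG layout, per-sex methylation probabilities, an
assembly gap, splice dinucleotides, the poly-A signal and its distance, motif
plants, RACE TSS offsets, and the expected-terminus shift.  `build_scaffold`
plants everything on a random background and returns the released scaffold
(with the N placeholder), the spliced transcript, and a truth table of every
planted coordinate.

Two presets: `desk_spec` (4,606-bp transcript, 6,021-bp span; exon 1 is
3,000 bp so the 96-mer array can sit outside the ±2 kb CpG window) and
`porcine_scale_spec` (exons 17,184/89/136/209/329/129/7,139 and introns
1,460/2,271/2,136/356/390/989: a 25,215-bp transcript over a 32,817-bp span,
with the repeat arrays at the reported porcine transcript offsets).

Choices that make the ground truth exact rather than merely likely:

* **CpG exactness.** Within ±2 kb of the TSS, background CG dinucleotides are
  rejected and resampled and CGs are planted only at the declared offsets, so
  the window holds exactly 78 sites — 13 chaining into −284..+53, 54 into
  +285..+1,727, and 11 in sparse clusters below the dense-region threshold.
  The planted YY1-type match `CCGCCATATT` at −6..+4 itself contains a CpG,
  which is why the layout includes the −5 site.  Repeat arrays that overlap
  the window use CG-free monomers, and divergence mutations inside the window
  avoid creating CGs.
* **Maximal arrays.** The two transcript-adjacent bases on each side of a
  planted repeat array are resampled to break the consensus phase, so the
  planted span is the maximal array and boundary recovery is well-defined.
  Monomers are drawn with maximal circular self-match below 0.55 at every
  lag; otherwise a head-to-tail array of the monomer would genuinely be a
  tandem repeat of a shorter period and the "true" period would be ambiguous.
* **Unambiguous ends.** The base after the terminus is never `A` (a genomic
  A-run would absorb the poly-A junction), and chance `AATAAA` occurrences
  near the 3′ end are scrubbed so the planted signal is the nearest one.
* **Splice-safe exon edges.** Junction-adjacent exon bases avoid `G`, so an
  exact spliced read can never also match genomic sequence across a `GT..AG`
  intron; with error-free reads this makes "intronic depth is exactly zero" a
  theorem rather than a high-probability event.

The generator simulates four readouts: spliced/genomic PCR amplicons (exact
substrings between unique primer sites; cDNA templates are spliced, so
intron-spanning products run short), 5′/3′ RACE clones (5′ clones start
exactly at their planted offsets; 3′ clones carry an appended poly-A tract),
bisulfite clones (per-site Bernoulli methylation with the sex's probability;
every unprotected C converts with probability `conversion_rate`, top strand
only), and paired-end reads (uniform fragments from the spliced transcript in
females; none in males).  No sequencing error, quality simulation beyond a
constant Q, or PCR bias is modelled — recovery results on this data show
algorithmic correctness, not robustness to noisy real libraries.

Default simulation sizes: 10 bisulfite clones per region (clone counts per
region are not stated in the source material; ten is a typical clone-panel
size), 90-bp paired reads with 200-bp inserts, 400-bp RACE clones,
conversion rate 0.99.

## Homology scan (`homology_scan`)

Seed-and-extend local alignment: exact k-mer seeds (k = 11) on both strands
are grouped by diagonal (band 48); each cluster defines a padded scaffold
window over which a full affine-gap Smith–Waterman (Gotoh) alignment is
computed, so reported scores equal the optimal local score of their
intervals.  The scoring scheme defaults to megablast-like values
(match +2, mismatch −3, gap of length L costs −5 − 2L); score thresholds are
parameters because raw aligner scores are tool-version-dependent — the
portable part is the *filter semantics*: merge overlapping hit intervals
(0-bp tolerance, simple union) and keep a merged region only if it carries a
hit scoring strictly above the threshold from at least `min_species`
distinct species.  The ≥-species test is applied per merged region.  In
tests the implementation is cross-checked against Biopython's
`PairwiseAligner` configured to the same gap convention; with truly random
query/scaffold pairs a seed may not exist, so oracle-equality tests plant a
homologous segment and random pairs only assert that no reported score
exceeds the oracle optimum.

## Gene model (`gene_model`)

`infer_exons` explains a spliced amplicon as an ordered chain of exact
substrings of the genomic region (longest-prefix greedy with backtracking
over 20-mer anchor occurrences; introns must be ≥ 20 bp).  Amplicons are
treated as error-free, as Sanger-validated sequences are; mismatch-tolerant
spliced alignment is deliberately out of scope.  When identical bases at
both intron ends make the junction ambiguous, the junction shifts maximally
5′, preferring any shift that yields `GT..AG`.  `fill_gap` reconstructs the
single N-run from a bridging amplicon by exact flank matching (30 bp each
side, either amplicon orientation), reporting the fill and its length delta
against the placeholder.  `build_transcript` splices exons 5′→3′ on the
transcribed strand with an explicit bijective coordinate map;
`summarize_model` emits the per-feature first-8/last-8/length table with
transcript and span totals.

## Ends and motifs (`ends_and_motifs`)

TSS calling maps each 5′ clone's 30-bp prefix to its unique scaffold
placement; distinct end positions are never merged (real TSS sets keep calls
2 bp apart).  Terminus calling strips ≥ 8 terminal As, maps the remaining
3′ probe, and resolves A-run junctions in favour of the longest genomic
match; the modal end is the call.  The poly-A signal search scans
overlapping occurrences (a signal can overlap a chance copy of itself) and
measures distance from the *signal end* to the terminus — whether such
distances are measured to the signal's first or last base is ambiguous in
the field; the convention is recorded in the output.  Motif scanning is
exact IUPAC matching on both strands (no PWM scoring), reported in promoter
coordinates.  Digests are blunt-cut: fragments between successive cut
positions, cut offset within an IUPAC recognition site.

## Repeat finder (`repeat_finder`)

Period detection votes with k-mer recurrence distances (k = 5, ≥ 4 votes),
trying smaller candidate periods first so arrays report their true period
rather than a multiple.  For each candidate period p, a lag-p self-match
profile windowed over p positions proposes rough regions; a consensus is
estimated from full-period chunks anchored at the *peak* of the windowed
signal (the rough start can be off by up to a period, so anchoring inside
keeps the phase honest), and exact boundaries are the maximum-sum subarray
of a +1 match / −3 mismatch score against the consensus phase, iterated once
with a consensus rebuilt from all full copies.  Three acceptance gates:
mean full-copy identity ≥ `min_identity` (default 0.8); span ≥
(`min_copies` − 0.2) × p — the 0.2-copy slack exists because an edge base
destroyed by divergence is indistinguishable from background; and a binomial
significance test of the lag-p self-match count against the 0.25 background
rate, Bonferroni-corrected for positions × candidate periods at α = 0.01.
The significance gate is what keeps short-period chance matches (a perfect
2 × 10-mer occurs by chance in a few kb) out of random sequence.  Copy
alignment is gapless — divergence is modelled as substitutions only — and
copy number is span/period rounded half-up to one decimal.

Parameter-recovery conditions: arrays with periods {6, 24, 96, 149} and
divergences {0, 0.05, 0.08, 0.05}.  The 6-mer array is planted exact
because at period 6 the ±0.2-copy tolerance is 1.2 bp, and a single mutated
base in the first two positions of the array removes the boundary
information no detector could recover; near-exact short-period arrays also
match what B-repeat-style regions look like.

`fold_monomer` is the Nussinov maximum-pairing recursion (Watson–Crick + GU,
minimum loop 3) with a deterministic traceback that always pairs the
leftmost admissible base; it is verified against exhaustive structure
enumeration for monomers ≤ 14 nt.  No thermodynamic model is used, so the
structure is a pairing-count argument, not a free-energy prediction.
`search_monomer` is the query-monomer mode used for absence claims (best
gapless identity below 0.7 ⇒ absent).

## Methylome (`methylome`)

CpG sites are the C positions of CG dinucleotides within ±2 kb of the TSS.
Dense regions chain sites with inter-site distance ≤ 200 bp and keep chains
of ≥ 6 sites: 200 bp splits the canonical layout at its 231-bp sparse
stretch while keeping both dense regions intact; the chaining rule itself is
a package choice, as only the resulting regions are standard.  Clone calling
places each bisulfite clone by collapsing C→T on both clone and reference —
which removes exactly the conversion degrees of freedom, so valid placements
are exact collapsed matches — then reads C as methylated and T as
unmethylated at each covered site.  Conversion QC uses non-CpG cytosines
(biologically unmethylated here, so retained Cs measure conversion failure
directly); clones below 0.95 conversion are excluded.  The aggregate is the
pooled-call fraction; the mean methylated-sites-per-clone is also emitted
because the two coincide only when every clone covers every site.  Only the
top strand is modelled.

## Coverage (`coverage`)

The mapper is exact-seeded (k-mer stride seeds, both strands) with
best-Hamming placement, ties broken leftmost then forward strand, one
placement per read; paired reads are treated as independent single ends
since coverage, not structural inference, is the goal.  Depth is normalized
by total aligned reads.  The expression check reports the exonic fraction of
aligned bases, whether coverage starts in the TSS window and ends at the
called terminus, upstream/downstream zero-depth flags, and flags positions
whose depth exceeds 5× the exonic median as repeat-ambiguity peaks — the
artifact best-hit placement produces over near-identical tandem copies.
Expression checks map with zero mismatches: junction-spanning reads stay
unaligned, which is what confines locus coverage to exons exactly.  Reads
are quality-filtered only in the trivial sense (constant qualities pass a
threshold), matching the error-free simulation.

## Problem sizes

The default test suite runs the desk-scale locus everywhere and the
porcine-scale preset for the arithmetic-anchored checks; recovery properties
use 20 seeds (repeats), 50 seeds (gene-model round trip), 200 clones
(methylation), 50 instances (alignment and folding oracles), and 3 seeds of
600–800 reads (coverage).  The acceptance script runs the full porcine-scale
pipeline with 600 read pairs and 20 clones per sex in a few seconds.

## Known limitations

* All recovery guarantees are for the error-free, substitution-only
  synthetic data; real libraries add sequencing error, indels, and PCR
  artifacts the pipeline does not model.
* The repeat finder's gapless copy model cannot represent indel divergence
  between copies, and spacered arrays are generated but not detected.
* Candidate-region selection has no E-value model; thresholds are raw
  alignment scores under the package's own scheme.
* Bisulfite analysis is single-strand and clone-based; read-based
  (paired-end) bisulfite data is out of scope.
* The homology scan is for few-kb queries (full DP matrices are kept for
  traceback); split longer references into chunks, as the tests do.
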