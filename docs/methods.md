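# Methods

## Scope

`edkin` implements the analysis of *when* adenosine-to-inosine (A-to-I)
RNA editing happens during mRNA maturation and *how* editing interacts
with pre-mRNA splicing, using RNA-seq of ordered subcellular fractions:
chromatin-associated non-polyadenylated (ChA-), chromatin-associated
polyadenylated (ChA+), nucleoplasmic polyadenylated (NpA+) and
cytoplasmic polyadenylated (CpA+) RNA.  Because inosine base-pairs like
guanosine, editing appears as A-to-G mismatches between reads and the
genome; the fraction in which a site is first seen edited approximates
the kinetic timing of the event.

The package ships a synthetic-data generator rather than depending on any
deposited data set; every statistic the pipeline produces can therefore
be scored against exact planted truth.

## Synthetic data

`synthetic.generate_reference` builds a small genome (default one 50-kb
chromosome) with multi-exon gene models on both strands, a fraction of
noncoding transcripts, repeat and SNP annotations, and two planted
structures:

* an **inverted repeat**: a 60-nt arm and its reverse complement at ~85%
  identity in the two introns flanking a designated exon — the classic
  intramolecular dsRNA substrate ADAR binds;
* an **exon–intron duplex**: an 80-nt reverse-complement copy of an exon
  segment at ~90% identity in the downstream intron.

Mutation positions in a planted arm are resampled until the pair's
maximal-scoring segment under the +1/−2 aligner keeps at least 50 nt at
≥80% identity and retains a ≥12-nt exact run for word seeding.  Without
this, a "60 nt, 85%" plant occasionally has a best local alignment of
49 nt (edge mismatches get trimmed by any maximal-segment aligner), and
the planted claim would be false under alignment semantics.

`plant_editing_truth` places editing sites on transcript-strand
adenosines with a kinetic group g ∈ {1..4} and per-fraction editing
ratios (ER): zero before fraction g, non-decreasing draws from
[0.2, 0.6] at and after it (the non-decreasing trajectory mirrors the
observed accumulation of editing along maturation and gives positive MZ
scores).  ER values are quantised to 1e-6 so the truth table round-trips
exactly through TSV.  Sites default to internal exons: intronic sequence
disappears from mature poly(A)+ RNA together with its intron, so an
intronic site cannot show coverage in the late fractions at desk scale;
terminal exons sit in the coverage ramp at transcript ends and are
avoided for the same reason.  Acceptor-site edits (the A of the
intron-terminal AG, position "2i") are planted separately.

`simulate_fraction_alignments` samples reads per transcript with
per-base-balanced rates: spliced molecules (abundance = the fraction's
splicing completeness `sc`) are read over mature coordinates and
unspliced molecules (1 − sc) over the genomic span, giving exonic depth
≈ `depth`, intronic depth ≈ (1 − sc)·`depth`, and exon–intron
boundary-spanning reads at rate 1 − sc per junction — the intronic-read
gradient that distinguishes the four fractions.  Default completeness is
(0.3, 0.6, 0.97, 1.0) along ChA-, ChA+, NpA+, CpA+.  Planted sites flip
A→G in covering reads with probability ER_f; sequencing error is uniform
substitution (default 1e-3, no indels — indels are orthogonal to every
statistic tested).  Reads are single-end, strand-specific, stored in
reference orientation as in SAM.

**Hyperediting** is simulated as reads with ~80% of their adenosines
converted (minimum 6), emitted to a separate unaligned pool.  These reads
are drawn from declared regions — by default the planted inverted-repeat
arms — because real hyperediting clusters in dsRNA; scattering it
uniformly across genes would contaminate the editing ratios of ordinary
planted sites.

What the generator does **not** model: fragment-length and GC biases,
quality-score distributions, paired-end structure, overlapping genes,
alignment artifacts of a real mapper.  Passing tests therefore
demonstrate the correctness of the statistics and decision rules, not
robustness to real-data mapping noise.

## Editing-site detection

A strand-resolved pileup is built from the alignments (splice gaps
contribute nothing).  Mismatching bases in the terminal 6 nt of a read
are discarded as a mapping-artifact guard; a base-quality floor (Q25)
applies when qualities exist, which on simulated constant-quality data is
a documented no-op; strand-bias filtering does not apply to a
strand-specific library.  A candidate site must be a transcript-strand
reference A with **≥2 edited-G reads** and **≥5 total reads**, not a
known SNP, and not inside a homopolymer run of ≥5 nt.  Sites within 4 nt
of an annotated splice junction are excluded — except in the nascent
ChA- fraction, whose abundant intronic reads make junction-proximal
mismatches trustworthy; this exception is what lets splice-site editing
be observed at all.  Non-A-G mismatch positions passing the same support
filters are recorded with their mismatch type but do not propagate.

**Hyperediting rescue**: reads that failed normal alignment are collapsed
A→G (and, for antisense transcripts seen in reference orientation, T→C),
as is the genome; the collapsed read is re-placed by exact 20-mer seeding
plus full-length comparison (≤2 collapsed-space mismatches), requiring a
unique best placement.  After reinstating the original bases a rescued
read must show ≥5 A-to-G (or T-to-C) mismatches, ≤1 other mismatch, and
edited positions spread over >50% of the read.  These thresholds are
declared defaults, all configurable.

## Kinetic classification

Per fraction, a site is **edited** (≥1 G read, regardless of coverage),
**unedited** (0 G reads at coverage ≥ k) or **undetermined** (0 G reads,
coverage < k).  A catalogued site (edited somewhere) occupies one of
3⁴ − 2⁴ = 65 status categories over four fractions.  Group g = the first
edited fraction, accepted only if every earlier fraction is confidently
unedited (k = 20) and no later fraction is confidently unedited;
violations are excluded as *coverage-ambiguous* (undetermined before the
first edit) or *reversal* (unedited after edited).  For group-1
candidates the later-fraction test uses the relaxed k = 5, which makes
expulsion from group 1 easier and the group-1 count conservative;
raising k toward 20 can only grow group 1 (a property the tests check).
The reversal test uses the k in effect for the candidate group (k = 5
when the first edit is in ChA-); which k governs this exclusion is not
externally fixed, so it is a declared, switchable choice.  The same
operation handles three-fraction designs (nuclear A-, nuclear A+,
cytosolic A+) with k = (5, 20, 20).

The **MZ score** (monotonicity z-score) of an ER trajectory is the sum
of signs of consecutive differences divided by √(number of pairs):
+√3 for a strictly increasing four-fraction trajectory.  It is undefined
when two consecutive fractions tie.  The cited literature does not print
a formula for this statistic; the sign-sum definition is this package's
own, chosen to reproduce the documented range and tie behaviour, and the
scorer is pluggable.

For metabolically labelled (4sU) vs total RNA designs,
`labelled_kinetics` classes a site *early* (edited in both, two-sided
Fisher exact p > 0.05 on the 2×2 of G vs non-G counts), *intermediate*
(edited in both, significant ER increase in total) or *late* (unedited
in labelled, edited in total).

Sequence-context enrichment around sites vs context-matched control
adenosines uses log2 frequency ratios with a common frequency floor
(0.5/(max sample size + 1)) so empty cells on both sides give zero
enrichment, plus a two-proportion z statistic.

## Splicing completeness and timing

coSI for an internal exon is S/(S + U): S counts reads spliced across
either flanking junction; U is the number of (read, boundary) crossings
of the four exon–intron boundaries of those introns, **weighted 1/2**.
The weight corrects a structural bias: an unspliced molecule exposes two
boundaries per intron while a spliced molecule exposes one junction, so
unweighted counting underestimates completeness (0.97 true completeness
would read as ≈0.942 and systematically miss a 0.95 threshold).  With
the weight, coSI is an unbiased estimator of the spliced-molecule
fraction.  A minimum of 10 informative reads is required (configurable;
no external default exists for this floor).  Timing classes: **coTS**
(cotranscriptional) if coSI ≥ 0.95 already in ChA-; **postTS** if coSI ≤
0.75 in ChA+ and ≥ 0.95 in NpA+; otherwise *other*.

Novel exon candidates are intervals bounded by two junctions, each with
≥2 supporting reads, at mean read coverage ≥10; candidates matching no
annotated exon are flagged novel.

**PSI** for a skipped exon uses junction counts only: inclusion reads I
pool the two flanking junctions, so PSI = (I/2)/((I/2) + E) with E the
skipping-junction count.  This drops the read-length normalisation some
protocols apply; junction-only counting is read-length invariant and has
a closed form the tests pin down.  Alternative-acceptor events score the
two competing acceptor junctions; retained introns use mean intron
coverage vs junction support (a declared convention — no external
default exists).  An exon needs ≥10 informative reads or ≥2 exclusion
reads, else PSI is undefined.  Events with more than one supported
pattern are *Complex*.  ΔPSI = PSI(knockdown) − PSI(control).

## Splice-site windows and edit impact

Donor (5'ss) windows are 9-mers (3 exonic + 6 intronic nt), acceptor
(3'ss) windows 23-mers (3 exonic + 20 intronic), strand-aware, labelled
from the boundary (1e..3e into the exon, 1i..20i into the intron).  The
A of the acceptor's invariant AG is "3'ss.2i"; editing it turns AG into
GG and destroys the canonical acceptor.  Splice-site strength is scored
by a first-order position-weight matrix (log2 odds vs uniform
background, 0.5 pseudocounts) trained on the annotation-derived windows
of the genome under analysis; a maximum-entropy or precomputed score
table can be plugged in through the same `score(seq)` interface.  No
third-party model files ship with the package; the PWM preserves the
quantity of interest (the sign and rough magnitude of the strength
change caused by an edit) on any genome it is trained on.

**Direction concordance** upon ADAR1 knockdown (editing lost): for a
skipped exon whose acceptor 2i was edited, restoring AG should raise
inclusion (ΔPSI > 0); for alternative-acceptor events with PSI defined
as usage of the edited-form acceptor, usage should shift back to the
original acceptor (ΔPSI < 0); retained introns should resolve
(ΔPSI < 0); Complex events are excluded as directionless.  The A3SS
convention (which acceptor's usage defines PSI) is declared and
switchable.  The synthetic knockdown/control cohort draws junction
counts binomially (depth 200 per condition) from true PSI values with a
±0.15 shift, 90% in the expected direction, so the measured concordance
re-estimates that planted rate through the full PSI machinery.

## dsRNA detection

BLASTN is replaced by an internal word-seeded (word 8), ungapped,
X-drop-extended local aligner with match +1 / mismatch −2 and
Karlin–Altschul E-values E = K·m·n·e^(−λS), λ = 1.28, K = 0.46 (the
ungapped +1/−2 parameter set).  E-values are internally consistent, not
bit-compatible with NCBI output; the alignment functions accept any
scorer with the same interface for users who want an external aligner.
Gapped alignment is unnecessary for the substitution-only homologies the
generator plants and for the detection question being asked.

**Site-centred test**: the reverse complement of the 4001-nt window
centred on a site is aligned against the site ± 200 nt.  The
neighbourhood trivially matches its own reverse complement inside the
window, so hits whose two genomic arms coincide (>50% overlap of the
shorter arm) are discarded as self-alignments; the best remaining hit
must reach length ≥50 at identity ≥80%.  **Exon–intron test**: the exon
sequence is aligned against the reverse complement of each flanking
intron (truncated to 5 kb adjacent to the exon); a duplex needs identity
>70% and E ≤ 0.001.

The **ADAR-direct-target funnel** filters splice events in order:
|ΔPSI| ≥ 0.10 in either direction → an editing site inside the exon or
within 500 nt of a boundary (measured from each boundary into the
intron, inclusive) → a passing exon–intron duplex.  Stage counts are
non-increasing by construction.  CLIP-peak overlap with the duplex span
is recorded as supporting evidence, not used as a filter.  The summary
reports the fraction of passing exons with ΔPSI > 0 (the signature of
splicing repression by ADAR binding).

## Problem sizes and numerical choices

Default analyses run on one 50-kb chromosome, 8 transcripts, read depth
30–50, ~100–200 planted sites — sizes at which every pipeline stage
completes in seconds while all decision thresholds operate exactly as
they would at scale.  Classification tests use error-free simulation so
that recovery failures indicate logic errors, not sampling noise;
detection and rescue tests use a 1e-3 error rate.  All randomness flows
through `numpy.random.default_rng` with explicit seeds; fixed seed and
configuration reproduce byte-identical bundles and reports.  Ties in the
MZ score yield "undefined" rather than zero; ER at zero coverage is
undefined rather than zero; coordinates are 1-based inclusive
internally, converted to BED/SAM conventions only at the file boundary.

## Known limitations

Real-data mode consumes alignments; read mapping itself is out of scope.
The hyperediting rescuer is exact-seeded and ungapped — adequate for the
simulated indel-free reads, weaker than a full gapped rescue on real
data.  The PWM splice-site model is first-order and genome-trained; its
absolute scores are not comparable across genomes, only score
*differences* at a fixed window are meaningful.  The funnel's ΔPSI
inputs at desk scale come from the synthetic knockdown cohort, not from
a real perturbation experiment.
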