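# edkin

Kinetics of A-to-I RNA editing across subcellular fractions, and its
impact on pre-mRNA splicing.

## The problem

ADAR enzymes deaminate adenosine to inosine in double-stranded RNA;
inosine is read as guanosine, so editing shows up in RNA-seq as A-to-G
mismatches against the genome.  Editing and splicing overlap in time and
space during mRNA maturation, which raises two questions this package
addresses for transcriptomics researchers:

1. **When does editing happen?**  RNA-seq of ordered subcellular
   fractions — chromatin-associated poly(A)⁻ (ChA⁻, nascent RNA),
   chromatin-associated poly(A)⁺ (ChA⁺), nucleoplasmic poly(A)⁺ (NpA⁺)
   and cytoplasmic poly(A)⁺ (CpA⁺) — lets each editing site be placed in
   a *kinetic group*: the first fraction, in maturation order, where
   edited reads appear.
2. **How does editing affect splicing?**  Two mechanisms are
   quantified: edits that land in splice-site consensus sequences
   (above all the acceptor's invariant AG, position 3'ss.2i, which an
   A→G edit turns into GG) and exons embedded in dsRNA structures that
   ADAR binds, detected by aligning sequence against the reverse
   complement of its neighbourhood.

## The statistics at the core

* **Per-fraction status**: a site is *edited* (≥1 G read), *unedited*
  (0 G reads at coverage ≥ k) or *undetermined* (0 G reads, coverage
  < k); over four fractions a catalogued site occupies one of
  3⁴ − 2⁴ = 65 categories.  Group g = first edited fraction, with
  earlier fractions confidently unedited (k = 20) and later fractions
  never confidently unedited (relaxed k = 5 for group-1 candidates,
  making group 1 a conservative call).
* **Editing ratio** ER = G reads / coverage; its trajectory across
  fractions is summarised by the **MZ score**
  (Σ sign(ERᵢ₊₁ − ERᵢ))/√m ∈ [−√3, +√3] for four fractions.
* **coSI** (completed splicing index) = S/(S+U) around an internal exon
  (S spliced junction reads, U weighted boundary-crossing reads);
  exons with coSI ≥ 0.95 already in ChA⁻ are cotranscriptionally
  spliced (coTS), exons with coSI ≤ 0.75 in ChA⁺ but ≥ 0.95 in NpA⁺
  post-transcriptionally spliced (postTS).
* **PSI** (percent spliced-in) for a skipped exon =
  (I/2)/((I/2)+E) from inclusion (I) and skipping (E) junction reads;
  ΔPSI = PSI(ADAR1 knockdown) − PSI(control).
* **Duplex calls**: an internal word-seeded local aligner (+1/−2,
  Karlin–Altschul E-values) tests a site's 4001-nt window against its
  ±200-nt neighbourhood (arm ≥ 50 nt at ≥ 80% identity) and an exon
  against its reverse-complemented flanking introns (identity > 70%,
  E ≤ 0.001), feeding the ADAR-direct-target funnel:
  |ΔPSI| ≥ 10% → editing within 500 nt → duplex.

A synthetic-data module generates a toy genome with gene models,
planted editing sites of known group and ER, planted inverted repeats
and exon–intron duplexes, fraction-dependent splicing completeness and
hyperedited reads — so every stage is testable against exact truth.
See `docs/methods.md` for models, parameters and limitations.

## Worked example

Run the full pipeline on a synthetic bundle:

```sh
$ edkin run --run-dir run7 --seed 7
{
  "n_sites": 175,
  "group_percent": {
    "1": 74.0,
    "2": 14.5,
    "3": 6.9,
    "4": 4.6
  },
  "group_recovery": 100.0
}
full report: run7/report.json
```

175 A-to-G sites were called (union over the four fractions): the 104
planted ordinary and acceptor-site edits plus sites created by the
simulated hyperediting cluster.  74% of categorised sites fall in group
1 (first edited in nascent chromatin RNA) — on real data this fraction
is far larger still, since most editing is cotranscriptional.  Every
planted site recovered its intended group (`group_recovery: 100.0`).
The report file adds the excluded-site tallies (coverage-ambiguous /
reversal), the coSI timing table, the splice-site-edit count with score
changes, the direction concordance of ΔPSI with the expectation for
acceptor-2i edits, and the funnel stage counts.  Library use mirrors
the CLI:

```python
import edkin
report = edkin.run_pipeline(edkin.RunConfig(outdir="run7", seed=7))
```

Individual stages are importable on their own
(`edkin.synthetic`, `edkin.caller`, `edkin.kinetics`, `edkin.splicing`,
`edkin.splice_sites`, `edkin.dsrna`).

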