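# Methods

This note documents the models and procedures implemented in `bactss`, the
parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic-data tests do and do not show.

## TSS detection

The primary-library read-start profile counts 5′ ends per position and
strand.  Position *p* is a candidate TSS iff

* `read_starts[p] >= 20` (minimum read starts), and
* `100 * (s[p] - s[q]) / max(s[q], 1) >= 250` (minimum percent increase),

where *q* is the strand-aware upstream neighbour (*p*−1 on `+`, *p*+1 on
`-`).  The increase is computed on the read-start signal by default; the
tool that popularised this rule does not publish its exact formula, so the
denominator floor `max(q, 1)` is our choice to make zero-upstream positions
well-defined, and a depth-based variant is selectable
(`DetectionConfig.increase_signal = "depth"`).  The choice is recorded in
the run manifest.

Manual curation of auto-detected TSSs is replaced by two deterministic
rules, both configurable and disableable:

1. **Local maximum** — a candidate that is not the read-start maximum
   within ±3 nt is removed (exact ties keep the smaller coordinate).  This
   collapses ragged 5′ ends onto their peak.
2. **Downstream support** — mean whole-transcriptome depth over the 20 nt
   starting at the TSS must be ≥ 5; otherwise the candidate is a processed
   end or artefact with no transcript behind it.

Every removal carries a reason string in the output.

Reads whose 5′ end begins with the ligation barcode `TACCCTAG` mark
non-primary (5′-monophosphate) ends; the filter is exact-prefix,
5′-anchored, case-insensitive, with no mismatch tolerance (none is
published).

## Classification

Distances are measured from the +1 base to the first base of the start
codon, in transcribed nucleotides, so the UTR length equals the distance
and a TSS on the start-codon base has UTR 0.  Boundary semantics (the
source rules use "maximal"/"more than" loosely; we fix inclusive bounds and
unit-test the exact boundaries):

| category | rule |
|---|---|
| sTSS  | nearest downstream same-strand ORF start at distance ∈ [0, 300] |
| pTSS  | nearest downstream same-strand ORF start at distance ∈ (300, 600] |
| nsTSS | inside a same-strand ORF, (0, 200] nt downstream of its start → start-codon revision |
| iTSS  | inside a same-strand ORF, > 200 nt downstream of its start; dropped when ≤ 300 nt from the ORF end *and* simultaneously sTSS of the next gene |
| asTSS | inside an opposite-strand ORF, or (configurable, default on) a detected opposite-strand 5′-UTR |
| nTSS  | intergenic, none of the above |

One TSS may hold several categories (e.g. asTSS of one gene and sTSS of
another).  sTSS and pTSS are mutually exclusive for a single TSS because
both are defined against the *nearest* downstream start.  TSSs of
rRNA/tRNA/other structural-RNA features are tagged and excluded from
classification.  Pure nTSSs are folded into the sTSS group for downstream
statistics (`relabeled_sTSS`), preserving the original category.

**Start-codon revision**: for an nsTSS the first codon downstream of the
TSS, in frame with the annotated stop, drawn from {ATG, GTG, TTG, CTG},
becomes the revised start.  An RBS is searched 3–14 nt upstream of the
revised start; its absence does not veto the revision (the revision record
carries `rbs_found`), because the biological evidence for the new start is
the TSS itself — the RBS is corroboration.  With no downstream in-frame
start codon the TSS is re-labelled iTSS.  Without a fitted RBS model the
matcher accepts ≥ 4/5 agreement with the canonical Shine-Dalgarno `AGGAG`;
with a model, a positive log-odds window.

**Ranking**: per gene, the sTSS/pTSS with the highest read-start count is
primary; ties break toward the TSS closest to the start codon, then the
smaller coordinate.  iTSS/asTSS/nTSS stand on their own and are not ranked.

**Leaderless**: UTR ≤ 3 nt.  The UTR histogram uses 5-nt bins over
primary + secondary TSSs.

## Motif discovery

A single fixed-width motif is fit by expectation maximization under a
ZOOPS model (zero or one occurrence per sequence).  Positional biology is
expressed as per-sequence *allowed offsets* with a uniform prior — for the
−10, offsets placing the hexamer 3′ end 3–11 nt upstream of the +1; for
the −35, 16–23 nt between its 3′ end and the −10 5′ end (searched only in
sequences that received a −10); for the RBS, width 5 with its 3′ end
3–14 nt upstream of the start codon.  A Gaussian positional prior (as in
some published EM tools) is deliberately not used: the constraint window
does the positional work and keeps the model reproducible.

Numerical choices: pseudocount 0.25 per base (so the reported objective is
the Dirichlet-MAP log-posterior, which EM makes non-decreasing — asserted
at every iteration of every run); background estimated from input base
composition; occurrence prior γ re-estimated, clipped to [10⁻³, 1−10⁻³];
convergence at objective gain < 10⁻⁶ or 200 iterations; best of 15 seeded
restarts (restart count matters: shifted local optima are the common
failure of ZOOPS EM, and restarts plus the constraint window are the
remedy).  N bases score at background probability (odds ratio 1).
"A sequence has the motif" means occurrence posterior ≥ 0.5 — no counting
rule is published for the reference analyses, so occurrence fractions are
reported but deliberately not treated as comparable beyond that.
Input ordering does not affect the fit (the model is order-invariant).

RBS windows are the 20 nt upstream of start codons of genes with UTR
≥ 20 nt (one window per gene); a window enters the EM only if its mean
purine fraction over positions −15…−6 exceeds 0.55.  The spacer is
measured from the motif 3′ end (to the +1 for promoters, to the start
codon for the RBS); anchors are recorded in the manifest.

Consensus strings use conservation casing: uppercase at column frequency
≥ 0.7, lowercase ≥ 0.4, else `n`.

## Operons and transcripts

Adjacent same-strand genes (annotation adjacency in coordinate order; an
intervening opposite-strand gene breaks adjacency) are joined when ≥ 10
sense spanning reads connect them; maximal runs form operons.  Spanning
counts are consumed as a table keyed by gene pairs — they cannot be
recovered from coverage alone, so the generator (or a SAM-processing
wrapper) must supply them.  "Expressed" for the mono/polycistronic census
means mean gene-body depth ≥ 5 (no published floor exists; configurable).
A TSS assigned to the operon's first gene is the operon's primary TSS; a
TSS on gene *k* > 1 defines the sub-operon (*k* … end) — always a
contiguous suffix, asserted on every output.  Multiple TSSs on one
internal gene collapse to one sub-operon keeping the strongest TSS.

Antisense (and intragenic/novel) transcript extents extend downstream from
the TSS while per-position depth ≥ 15, must reach ≥ 20 nt, and — when
longer than 500 nt with mean depth > 40 — additionally require depth ≥ 80
at the TSS.  The mean is the arithmetic mean over the called extent.
Novel transcripts merge nTSSs with overlapping extents as alternative
TSSs, then scan all three frames for ORFs (start ∈ {ATG, GTG, TTG, CTG},
in-frame stop inside the extent, ≥ 25 codons); the longest ORF is
reported with an RBS search 3–14 nt upstream.  Intragenic transcripts are
reported with extents but no ORF call — their role is left open.

## Statistics

* **Readthrough**: mean UTR depth (TSS→gene start, or element start when
  no TSS exists) over mean ORF depth; verdict "termination-like" at ratio
  ≥ 10.  Published terminating elements show 20–100-fold ratios and
  readthrough elements ≈ 1, so any cutoff in (2, 20) separates them; 10 is
  the midpoint on the log scale.  A zero ORF mean uses an ε floor and is
  flagged.
* **Enrichment**: two-sided Fisher exact test per functional category for
  genes with 100–300-nt UTRs (one-sided available); raw p-values plus a
  Benjamini-Hochberg column.
* **Initiation nucleotides**: base frequencies at −1/+1/+2 (strand-aware
  complementation) per category group (sTSS-group > pTSS > iTSS > asTSS,
  each TSS counted once by that priority), with top/bottom deciles of size
  ⌈n/10⌉ by read-start count (ties broken by position); categories with
  < 10 members skip deciles and are flagged.

## Synthetic data

The generator emulates the *data model* of a dRNA-seq study, not its
sequencing physics.  Defaults — chosen once as the package's study
conditions — are one 100-kb replicon, 80 CDS genes, and 50 planted TSSs of
read-start strength 40: 28 sense (spread over operon-first genes, two
internal operon genes defining sub-operons, four riboswitch loci, and
plain single genes, two of which carry a second TSS to exercise
secondary ranking), 5 putative, 5 intragenic, 5 antisense, 3 intergenic,
2 leaderless, 2 start-revision cases.  Operon runs carry spanning-read
counts (25, 15, 12, 8, 5) that straddle the joining threshold.  Promoter
and RBS consensus motifs (`TATAAT`, `TTGACA`, `AGGAG`) are planted at
legal spacers in 90 % of eligible sites; riboswitch-like loci get
UTR:ORF coverage pairs (6000:60, 2000:33, 1500:75, 1300:50) plus a 40:40
readthrough control without a TSS; 60 % of the raw reads carry the
false-positive barcode; three processed-end read-start spikes with no
downstream coverage test the curation rules.

Background read-start noise is Poisson per position (λ = 0.2, two
strands).  Whole-transcriptome depth is a noise-free block model: constant
plateaus over planted transcripts.  That is the deliberate idealisation —
it makes transcript boundaries exact so recovery can be scored at 0-nt
tolerance, but it means the tests demonstrate *rule correctness*
(thresholds, geometry, bookkeeping), not robustness to ragged coverage,
sequencing error, mapping ambiguity, or overdispersed noise, none of
which are modelled.  Placement uses generous clearances so each planted
TSS derives exactly its intended category; the generator re-derives every
category with its own geometry code (independent of the classifier) and
refuses to emit an inconsistent dataset — so the classification oracle in
the tests checks two independent implementations of the rules against
each other.

The default full run (generate → analyse → score) takes a few seconds on
one CPU; problem sizes in the test suite were chosen to keep the whole
suite under two minutes.

## Known limitations

* Circular replicons: distance computations do not wrap the origin (no
  wrapping behaviour is published; configurable off is the only mode
  implemented).
* asTSS against 3′-UTRs is not implemented — 3′-UTR extent is never
  defined in the source analyses; only detected 5′-UTRs extend the
  antisense target set.
* Spanning-read counting from BAM is out of the tested core; counts enter
  as a table.
* The EM reports a MAP objective, not the raw likelihood; with
  pseudocount → 0 they coincide.
* Exact published motif-occurrence fractions are not reproducible because
  the original counting rule is unpublished; consensus strings and spacer
  statistics are the comparable outputs.
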