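# bactss

Analysis of bacterial primary transcriptomes (dRNA-seq) — the kind of data
produced by sequencing libraries enriched for native 5′-triphosphate
transcript ends after terminator-exonuclease digestion.  Given a genome,
an annotation, and stranded per-base signals (whole-transcriptome depth and
primary-library read-start counts), `bactss`:

* detects **transcription start sites (TSSs)** with the coverage-increase
  rule (read starts ≥ 20 and ≥ 250 % increase over the upstream neighbour),
  with deterministic curation surrogates for manual inspection;
* removes false-positive 5′ ends flagged by a ligation **barcode**
  (`TACCCTAG`) in the raw reads;
* **classifies** each TSS by genomic context — sense (sTSS, ≤ 300 nt
  upstream of an ORF start), putative (pTSS, 300–600 nt), intragenic
  (iTSS, > 200 nt into an ORF), antisense (asTSS), intergenic/novel (nTSS) —
  and **revises start codons** for TSSs found ≤ 200 nt downstream of an
  annotated start;
* ranks **primary/secondary** TSSs per gene by read-start count, computes
  **5′-UTR lengths** (leaderless iff ≤ 3 nt) and their 5-nt histogram;
* discovers **promoter −10/−35 boxes** and the **Shine-Dalgarno RBS** by
  ZOOPS expectation maximization under the canonical spacer constraints
  (−10 end 3–11 nt from the +1; 16–23 nt between −35 and −10; RBS end
  3–14 nt from the start codon, searched in purine-rich (> 55 % A+G)
  windows);
* infers **operons** (≥ 10 sense spanning reads join adjacent same-strand
  genes) and **sub-operons** (an internal TSS starts the suffix of its
  parent operon);
* calls **antisense and novel transcripts** by downstream coverage
  extension (per-position depth ≥ 15 for ≥ 20 nt; long high-coverage calls
  additionally need depth ≥ 80 at the start), with ORF and RBS annotation
  of novel transcripts;
* computes **initiation-nucleotide statistics** at −1/+1/+2 with
  top/bottom-decile coverage strata, **riboswitch readthrough ratios**
  (mean UTR depth / mean ORF depth), and Fisher-exact functional-category
  enrichment of long-UTR genes.

A first-class synthetic-data generator (`bactss.simulate`) builds a toy
replicon with planted TSSs of every category, planted motifs, operons with
spanning-read counts straddling the joining threshold, antisense/novel
transcripts, riboswitch-like coverage profiles, and barcode-flagged reads —
with the full ground truth recorded, so every stage of the pipeline is
testable end to end without downloads.

## Worked example

Simulate the default dataset (one 100-kb replicon, 80 genes, 50 planted
TSSs of read-start strength 40 over Poisson λ = 0.2 background), run the
full pipeline, and score recovery against the planted truth:

```bash
bactss score --seed 1
```

```json
{
 "tss":        {"sensitivity": 1.0, "precision": 1.0, "planted": 50, "called": 50},
 "operons":    {"sensitivity": 1.0, "precision": 1.0, "planted": 3,  "called": 3},
 "suboperons": {"sensitivity": 1.0, "precision": 1.0, "planted": 2,  "called": 2},
 "antisense":  {"sensitivity": 1.0, "precision": 1.0, "planted": 5,  "called": 5},
 "novel":      {"sensitivity": 1.0, "precision": 1.0, "planted": 2,  "called": 2}
}
```

All 50 planted TSSs are recovered at position-exact tolerance with no false
positives; the three operon runs whose spanning-read counts reach 10 are
reconstructed exactly (the two runs with counts 8 and 5 correctly fall
apart into monocistronic genes); both planted sub-operons, all five
antisense transcripts and both novel transcripts (one with a planted 26-aa
ORF and an RBS) are recovered.

The same run from files:

```bash
bactss simulate --seed 1 --out-dir data/
bactss run-all \
  --genome data/genome.fasta --annotation data/annotation.gff3 \
  --depth-fwd data/depth_fwd.bedgraph --depth-rev data/depth_rev.bedgraph \
  --starts-fwd data/starts_fwd.bedgraph --starts-rev data/starts_rev.bedgraph \
  --spanning-counts data/spanning_counts.tsv --out-dir results/ --seed 1
```

writes `tss.tsv`, `operons.tsv`, `suboperons.tsv`, `transcripts.tsv`,
`motifs.tsv`, `called_features.gff3` and a `manifest.json` with all
parameter values and census counts.  On the default dataset the discovered
motif consensus strings are `TATAAT` (−10), `TTGACA` (−35) and `AGGAG`
(RBS, mean spacer 7.5 ± 2.3 nt), matching what the generator planted, and
the four riboswitch-like loci with UTR:ORF coverage ratios 100/61/20/26 are
classified termination-like while the 1:1 control is readthrough-like.

In Python the same analysis is three calls:

```python
from bactss import SyntheticConfig, simulate_and_score
report, result, dataset = simulate_and_score(SyntheticConfig(seed=1))
print(report["tss"].sensitivity)          # 1.0
print(result.motif_models["rbs"].consensus)  # AGGAG
```

## Coordinate conventions

Internal coordinates are 0-based half-open; every emitted file is 1-based
inclusive (GFF3 convention) except BedGraph, which keeps its native 0-based
half-open intervals.  A TSS position is the +1 nucleotide itself — the
first transcribed base — strand-aware.

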