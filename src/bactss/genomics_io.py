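"""Standard-format I/O and the shared coordinate/strand conventions.

Conventions used throughout the package:

* Internal coordinates are 0-based, half-open.  All emitted files use
  1-based inclusive coordinates (GFF3 convention), except BedGraph which is
  0-based half-open, its own standard.
* The position of a TSS is the +1 nucleotide itself — the first transcribed
  base — strand-aware.
* ``start < end`` always; orientation is carried by ``strand``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO

STRANDS = ("+", "-")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# IUPAC ambiguity codes other than N; normalised to N on input
_IUPAC_AMBIG = set("RYSWKMBDHV")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (ACGTN)."""
    return seq.translate(_COMPLEMENT)[::-1]


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class Replicon:
    """A single chromosome or plasmid."""

    id: str
    sequence: str
    circular: bool = False

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class Genome:
    """Set of replicons, addressable by id."""

    replicons: dict[str, Replicon] = field(default_factory=dict)

    def add(self, rep: Replicon) -> None:
        if rep.id in self.replicons:
            raise FormatError(f"duplicate replicon id: {rep.id!r}")
        self.replicons[rep.id] = rep

    def __getitem__(self, rid: str) -> Replicon:
        return self.replicons[rid]

    def __contains__(self, rid: str) -> bool:
        return rid in self.replicons

    def __iter__(self):
        return iter(self.replicons.values())

    def __len__(self) -> int:
        return len(self.replicons)

    def fetch(self, replicon_id: str, start: int, end: int, strand: str = "+") -> str:
        """Extract sequence [start, end) 0-based; '-' returns the reverse
        complement (i.e. the transcript-sense sequence for a minus-strand
        feature)."""
        seq = self.replicons[replicon_id].sequence[start:end]
        return revcomp(seq) if strand == "-" else seq


@dataclass
class GeneFeature:
    """An annotated feature. Coordinates 0-based half-open, start < end."""

    gene_id: str
    replicon_id: str
    start: int
    end: int
    strand: str
    feature_type: str = "CDS"  # CDS / rRNA / tRNA / other
    product: str = ""
    functional_category: str = ""

    @property
    def length(self) -> int:
        return self.end - self.start

    def start_codon_pos(self) -> int:
        """0-based genome position of the first base of the start codon."""
        return self.start if self.strand == "+" else self.end - 1

    def stop_side_pos(self) -> int:
        """0-based genome position of the last transcribed base."""
        return self.end - 1 if self.strand == "+" else self.start


@dataclass
class StrandedProfile:
    """Per-replicon, per-strand signal arrays.

    ``depth`` is whole-transcriptome coverage; ``read_starts`` counts
    primary-library 5'-ends whose first base maps at each position.
    """

    replicon_id: str
    strand: str
    depth: np.ndarray
    read_starts: np.ndarray

    def __post_init__(self):
        self.depth = np.asarray(self.depth)
        self.read_starts = np.asarray(self.read_starts)
        if self.depth.shape != self.read_starts.shape:
            raise ValueError("depth and read_starts must have equal length")


@dataclass
class CisElementPrediction:
    """A predicted cis-regulatory element (e.g. a riboswitch) upstream of a
    gene; coordinates 0-based half-open."""

    name: str
    rfam_accession: str
    replicon_id: str
    start: int
    end: int
    strand: str
    downstream_gene_id: str


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_genome(path) -> Genome:
    """Parse a FASTA file into a Genome.

    Sequences are uppercased, U is converted to T, and IUPAC ambiguity codes
    are normalised to N.  Non-IUPAC characters or duplicate record ids raise
    FormatError naming the offending record.
    """
    genome = Genome()
    n = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        n += 1
        seq = str(rec.seq).upper().replace("U", "T")
        bad = set(seq) - set("ACGTN") - _IUPAC_AMBIG
        if bad:
            raise FormatError(
                f"record {rec.id!r}: non-IUPAC characters {sorted(bad)}"
            )
        for code in _IUPAC_AMBIG:
            if code in seq:
                seq = seq.replace(code, "N")
        genome.add(Replicon(id=rec.id, sequence=seq))
    if n == 0:
        raise FormatError(f"empty or invalid FASTA file: {path}")
    return genome


_KEPT_TYPES = {"CDS": "CDS", "rRNA": "rRNA", "tRNA": "tRNA"}
_SKIPPED_TYPES = {"gene", "region", "exon", "source", "chromosome"}


def _parse_gff_attributes(text: str) -> dict[str, str]:
    out = {}
    for part in text.strip().split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_annotation(path, genome: Genome,
                    category_attribute: str = "functional_category") -> list[GeneFeature]:
    """Parse a GFF3 file into GeneFeatures, sorted by (replicon, start).

    CDS/rRNA/tRNA rows keep their type; container rows (gene, region, exon,
    source) are skipped; anything else becomes ``other``.  seqids must match
    replicon ids and coordinates must lie within the replicon.
    """
    feats: list[GeneFeature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 9:
                cols = line.split()
                if len(cols) < 9:
                    raise FormatError(f"{path}:{lineno}: expected 9 GFF3 columns")
                cols = cols[:8] + [" ".join(cols[8:])]
            seqid, _src, ftype, start1, end1, _score, strand, _frame, attrs = cols[:9]
            if ftype in _SKIPPED_TYPES:
                continue
            if seqid not in genome:
                raise FormatError(f"{path}:{lineno}: unknown seqid {seqid!r}")
            start1, end1 = int(start1), int(end1)
            rep = genome[seqid]
            if not (1 <= start1 <= end1 <= rep.length):
                raise FormatError(
                    f"{path}:{lineno}: coordinates {start1}-{end1} outside "
                    f"replicon {seqid!r} (length {rep.length})"
                )
            if strand not in STRANDS:
                raise FormatError(f"{path}:{lineno}: bad strand {strand!r}")
            a = _parse_gff_attributes(attrs)
            gene_id = a.get("ID") or a.get("locus_tag") or a.get("Name")
            if gene_id is None:
                raise FormatError(f"{path}:{lineno}: feature without ID")
            feats.append(GeneFeature(
                gene_id=gene_id,
                replicon_id=seqid,
                start=start1 - 1,
                end=end1,
                strand=strand,
                feature_type=_KEPT_TYPES.get(ftype, "other"),
                product=a.get("product", ""),
                functional_category=a.get(category_attribute, ""),
            ))
    feats.sort(key=lambda f: (f.replicon_id, f.start, f.end, f.gene_id))
    return feats


def _read_bedgraph_array(path, genome: Genome) -> dict[str, np.ndarray]:
    """Expand one BedGraph file (0-based half-open) to dense per-replicon
    arrays; absent positions are 0."""
    arrays = {rid: np.zeros(genome[rid].length, dtype=np.int64)
              for rid in genome.replicons}
    assigned = {rid: np.zeros(genome[rid].length, dtype=bool)
                for rid in genome.replicons}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            cols = line.split()
            if len(cols) < 4:
                raise FormatError(f"{path}:{lineno}: expected 4 BedGraph columns")
            rid, s, e, v = cols[0], int(cols[1]), int(cols[2]), cols[3]
            if rid not in arrays:
                raise FormatError(f"{path}:{lineno}: unknown replicon {rid!r}")
            val = int(float(v))
            if not (0 <= s < e <= len(arrays[rid])):
                raise FormatError(
                    f"{path}:{lineno}: interval {s}-{e} out of range for {rid!r}"
                )
            seg = arrays[rid][s:e]
            seen = assigned[rid][s:e]
            conflict = seen & (seg != val)
            if conflict.any():
                raise FormatError(
                    f"{path}:{lineno}: overlapping intervals with conflicting "
                    f"values on {rid!r} near position {s + int(np.argmax(conflict))}"
                )
            seg[~seen] = val
            assigned[rid][s:e] = True
    return arrays


def read_stranded_bedgraph(depth_fwd, depth_rev, starts_fwd, starts_rev,
                           genome: Genome) -> list[StrandedProfile]:
    """Read four BedGraph files (two signals x two strands) into dense
    StrandedProfiles, one per replicon per strand."""
    d = {"+": _read_bedgraph_array(depth_fwd, genome),
         "-": _read_bedgraph_array(depth_rev, genome)}
    r = {"+": _read_bedgraph_array(starts_fwd, genome),
         "-": _read_bedgraph_array(starts_rev, genome)}
    profiles = []
    for rid in genome.replicons:
        for strand in STRANDS:
            profiles.append(StrandedProfile(
                replicon_id=rid, strand=strand,
                depth=d[strand][rid], read_starts=r[strand][rid]))
    return profiles


def write_bedgraph(array: np.ndarray, replicon_id: str, path) -> None:
    """Write a dense array as run-length-encoded BedGraph (zeros omitted)."""
    arr = np.asarray(array)
    with open(path, "w") as fh:
        if len(arr) == 0:
            return
        change = np.flatnonzero(np.diff(arr)) + 1
        starts = np.concatenate([[0], change])
        ends = np.concatenate([change, [len(arr)]])
        for s, e in zip(starts, ends):
            v = arr[s]
            if v != 0:
                fh.write(f"{replicon_id}\t{s}\t{e}\t{v}\n")


# ---------------------------------------------------------------------------
# writers / round-trip readers for result tables
# ---------------------------------------------------------------------------

def write_gff3(features: list[GeneFeature], path, source: str = "bactss") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in sorted(features, key=lambda f: (f.replicon_id, f.start, f.end)):
            attrs = f"ID={f.gene_id}"
            if f.product:
                attrs += f";product={f.product}"
            if f.functional_category:
                attrs += f";functional_category={f.functional_category}"
            fh.write("\t".join([
                f.replicon_id, source, f.feature_type,
                str(f.start + 1), str(f.end), ".", f.strand, ".", attrs,
            ]) + "\n")


def tss_records_to_frame(records) -> pd.DataFrame:
    """Flatten TSSRecords into a table with 1-based positions."""
    rows = []
    for t in records:
        cats = sorted(t.categories)
        rows.append({
            "replicon": t.replicon_id,
            "position": t.position + 1,
            "strand": t.strand,
            "read_starts": t.read_start_count,
            "categories": ",".join(cats),
            "genes": ",".join(
                f"{c}:{g}" for c, g in sorted(t.gene_by_category.items())),
            "rank": ",".join(f"{g}:{r}" for g, r in sorted(t.rank.items())),
            "utr_length": "" if t.utr_length is None else t.utr_length,
            "leaderless": t.leaderless,
            "context_m1": t.context[0],
            "context_p1": t.context[1],
            "context_p2": t.context[2],
            "feature_class": t.feature_class,
        })
    df = pd.DataFrame(rows, columns=[
        "replicon", "position", "strand", "read_starts", "categories",
        "genes", "rank", "utr_length", "leaderless",
        "context_m1", "context_p1", "context_p2", "feature_class"])
    return df.sort_values(["replicon", "position", "strand"]).reset_index(drop=True)


def operons_to_frame(operons) -> pd.DataFrame:
    rows = []
    for op in operons:
        rows.append({
            "operon_id": op.operon_id,
            "replicon": op.replicon_id,
            "strand": op.strand,
            "genes": ",".join(op.gene_ids),
            "spanning_counts": ",".join(str(c) for c in op.spanning_counts),
            "primary_tss": "" if op.primary_tss is None else op.primary_tss + 1,
        })
    return pd.DataFrame(rows, columns=[
        "operon_id", "replicon", "strand", "genes", "spanning_counts",
        "primary_tss"])


def read_operons_table(path):
    """Round-trip reader for operons.tsv."""
    from .transcripts import Operon

    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out = []
    for _, row in df.iterrows():
        counts = ([int(c) for c in row["spanning_counts"].split(",")]
                  if row["spanning_counts"] else [])
        out.append(Operon(
            operon_id=row["operon_id"],
            replicon_id=row["replicon"],
            strand=row["strand"],
            gene_ids=row["genes"].split(","),
            spanning_counts=counts,
            primary_tss=None if row["primary_tss"] == "" else int(row["primary_tss"]) - 1,
        ))
    return out


def transcripts_to_frame(transcripts) -> pd.DataFrame:
    rows = []
    for t in transcripts:
        orf = t.orf
        rows.append({
            "replicon": t.replicon_id,
            "kind": t.kind,
            "tss_positions": ",".join(str(p + 1) for p in t.tss_positions),
            "start": t.start + 1,
            "end": t.end,
            "strand": t.strand,
            "orf_start": "" if orf is None else orf.start + 1,
            "orf_end": "" if orf is None else orf.end,
            "orf_start_codon": "" if orf is None else orf.start_codon,
            "orf_length_aa": "" if orf is None else orf.length_aa,
            "rbs_found": t.rbs_found,
        })
    df = pd.DataFrame(rows, columns=[
        "replicon", "kind", "tss_positions", "start", "end", "strand",
        "orf_start", "orf_end", "orf_start_codon", "orf_length_aa",
        "rbs_found"])
    return df.sort_values(["replicon", "start", "strand"]).reset_index(drop=True)


def motif_models_to_frame(models: dict) -> pd.DataFrame:
    """One row per PWM column per named motif model."""
    rows = []
    for name, model in models.items():
        if model is None:
            continue
        for j in range(model.width):
            rows.append({
                "motif": name,
                "column": j,
                "A": model.pwm[j, 0],
                "C": model.pwm[j, 1],
                "G": model.pwm[j, 2],
                "T": model.pwm[j, 3],
                "consensus": model.consensus,
            })
    return pd.DataFrame(rows, columns=["motif", "column", "A", "C", "G", "T",
                                       "consensus"])


def write_tables(results, out_dir) -> dict[str, str]:
    """Write the result bundle as TSV files plus a GFF3 of called features.

    ``results`` is a PipelineResult (or any object exposing the same
    attributes).  Returns {logical name: path}.  All coordinates emitted
    1-based inclusive; row order deterministic (replicon, position, strand).
    """
    os.makedirs(out_dir, exist_ok=True)
    paths = {}

    def _save(name, df):
        p = os.path.join(out_dir, name)
        df.to_csv(p, sep="\t", index=False)
        paths[name] = p

    _save("tss.tsv", tss_records_to_frame(results.tss_records))
    _save("operons.tsv", operons_to_frame(results.operons))
    sub_rows = [{
        "parent_operon": s.parent_operon_id,
        "first_gene": s.first_gene_id,
        "genes": ",".join(s.gene_ids),
        "tss": s.tss_position + 1,
    } for s in results.suboperons]
    _save("suboperons.tsv", pd.DataFrame(
        sub_rows, columns=["parent_operon", "first_gene", "genes", "tss"]))
    _save("transcripts.tsv", transcripts_to_frame(
        list(results.antisense_transcripts) + list(results.novel_transcripts)))
    _save("motifs.tsv", motif_models_to_frame(results.motif_models))

    called = []
    for t in list(results.antisense_transcripts) + list(results.novel_transcripts):
        called.append(GeneFeature(
            gene_id=f"{t.kind}_{t.replicon_id}_{t.start + 1}",
            replicon_id=t.replicon_id, start=t.start, end=t.end,
            strand=t.strand, feature_type="other", product=t.kind))
    for r in results.revised_starts:
        called.append(GeneFeature(
            gene_id=f"revised_{r.gene_id}", replicon_id=r.replicon_id,
            start=r.new_cds_start, end=r.new_cds_end, strand=r.strand,
            feature_type="CDS", product="revised start codon"))
    gff_path = os.path.join(out_dir, "called_features.gff3")
    write_gff3(called, gff_path)
    paths["called_features.gff3"] = gff_path
    return paths
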