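"""Readers/writers and coordinate/sequence conventions shared by the pipeline.

Conventions
-----------
* Genomic coordinates are 1-based inclusive (GFF convention) everywhere;
  transcript-space positions are 1-based from the 5' end.
* All pairing logic downstream operates in RNA space (A/C/G/U); this module
  converts at the boundary (``T`` -> ``U`` when extracting transcript
  sequences, and preserves ``U`` in FASTA input).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "GenomeSequence",
    "TranscriptRecord",
    "CircRNARecord",
    "FormatError",
    "CoordinateError",
    "read_fasta",
    "write_fasta",
    "read_gene_models",
    "write_gene_models",
    "extract_spliced_sequence",
    "read_count_table",
    "write_count_table",
    "read_circrna_table",
    "write_circrna_table",
]

_DNA_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_RNA_COMPLEMENT = str.maketrans("ACGUN", "UGCAN")


class FormatError(ValueError):
    """A file violated the expected on-disk format."""


class CoordinateError(ValueError):
    """A genomic coordinate fell outside the referenced sequence."""


@dataclass
class GenomeSequence:
    """One chromosome/scaffold of the reference genome (DNA, uppercase)."""

    chrom_id: str
    sequence: str

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise FormatError(f"empty sequence for chromosome {self.chrom_id!r}")
        if set(self.sequence) - set("ACGTN"):
            bad = sorted(set(self.sequence) - set("ACGTN"))
            raise FormatError(
                f"chromosome {self.chrom_id!r} contains non-DNA characters {bad}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class TranscriptRecord:
    """A spliced transcript: genomic exon structure plus (optional) RNA sequence.

    ``exons`` are (start, end) genomic intervals, 1-based inclusive, sorted by
    start and non-overlapping. For minus-strand transcripts the spliced
    sequence is the reverse complement of the concatenated exon sequence.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    biotype: str = "unknown"
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        self.exons = sorted((int(s), int(e)) for s, e in self.exons)
        prev_end = 0
        for s, e in self.exons:
            if s > e:
                raise ValueError(f"{self.transcript_id}: exon start {s} > end {e}")
            if s <= prev_end:
                raise ValueError(f"{self.transcript_id}: overlapping/unsorted exons")
            prev_end = e

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def spliced_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)


@dataclass
class CircRNARecord:
    """A circRNA defined by its back-splice junction span (1-based inclusive)."""

    circ_id: str
    chrom: str
    strand: str
    splice_start: int
    splice_end: int
    locus_type: str | None = None  # {exon, intron, intergenic}, set by annotation

    def __post_init__(self) -> None:
        if self.splice_start > self.splice_end:
            raise ValueError(
                f"{self.circ_id}: splice_start {self.splice_start} > "
                f"splice_end {self.splice_end}"
            )


def reverse_complement(seq: str) -> str:
    """Reverse complement; auto-detects RNA (contains U) vs DNA."""
    table = _RNA_COMPLEMENT if "U" in seq else _DNA_COMPLEMENT
    return seq.translate(table)[::-1]


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into ``[(id, sequence), ...]`` in file order.

    Ids are the first whitespace-delimited header token. Sequences are
    uppercased; ``U`` is preserved for RNA inputs. Duplicate ids raise.
    """
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append((rec.id, str(rec.seq).upper()))
    if not records:
        raise FormatError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _detect_dialect(text: str) -> str:
    """Auto-detect GFF3 vs GTF from the attribute-column separator."""
    for line in text.splitlines():
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) < 9:
            continue
        attrs = cols[8]
        if '"' in attrs and "gene_id" in attrs:
            return "gtf"
        if "=" in attrs:
            return "gff3"
    return "gff3"


def read_gene_models(path: str | Path, dialect: str | None = None) -> list[TranscriptRecord]:
    """Parse gene models from GFF3 or GTF into :class:`TranscriptRecord` lists.

    One record per transcript id; exons grouped and sorted; coordinates kept
    1-based inclusive. ``dialect`` is auto-detected when not given.
    """
    text = Path(path).read_text()
    if dialect is None:
        dialect = _detect_dialect(text)
    if dialect not in ("gff3", "gtf"):
        raise ValueError(f"unknown dialect {dialect!r}")

    # Pre-scan exon lines for missing parent attributes so the error can carry
    # a line number (gffutils does not surface those).
    parent_key = "transcript_id" if dialect == "gtf" else "Parent"
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 9:
            raise FormatError(f"{path}:{lineno}: expected 9 tab-separated columns")
        if cols[2] == "exon" and parent_key not in cols[8]:
            raise FormatError(
                f"{path}:{lineno}: exon feature lacks a {parent_key} attribute"
            )

    db = gffutils.create_db(
        text,
        dbfn=":memory:",
        from_string=True,
        merge_strategy="create_unique",
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )

    # gene_id lookup for GFF3: transcript feature's Parent attribute.
    tx_gene: dict[str, str] = {}
    tx_biotype: dict[str, str] = {}
    biotype_map = {
        "mRNA": "mRNA",
        "lnc_RNA": "lncRNA",
        "lncRNA": "lncRNA",
        "pre_miRNA": "precursor_miRNA",
        "transcript": "unknown",
    }
    for ftype, biotype in biotype_map.items():
        for feat in db.features_of_type(ftype):
            parents = feat.attributes.get("Parent", [feat.id])
            tx_gene[feat.id] = parents[0]
            tx_biotype[feat.id] = biotype

    groups: dict[str, dict] = {}
    for exon in db.features_of_type("exon"):
        if dialect == "gtf":
            tid = exon.attributes["transcript_id"][0]
            gid = exon.attributes.get("gene_id", [tid])[0]
        else:
            tid = exon.attributes["Parent"][0]
            gid = tx_gene.get(tid, tid)
        entry = groups.setdefault(
            tid,
            {
                "gene_id": gid,
                "chrom": exon.seqid,
                "strand": exon.strand,
                "exons": [],
                "biotype": tx_biotype.get(tid, "unknown"),
            },
        )
        entry["exons"].append((exon.start, exon.end))

    records = [
        TranscriptRecord(
            transcript_id=tid,
            gene_id=entry["gene_id"],
            chrom=entry["chrom"],
            strand=entry["strand"],
            exons=entry["exons"],
            biotype=entry["biotype"],
        )
        for tid, entry in groups.items()
    ]
    records.sort(key=lambda r: (r.chrom, r.start, r.transcript_id))
    return records


_BIOTYPE_FEATURE = {
    "mRNA": "mRNA",
    "lncRNA": "lnc_RNA",
    "precursor_miRNA": "pre_miRNA",
    "unknown": "transcript",
    "circRNA": "transcript",
}


def write_gene_models(records: Sequence[TranscriptRecord], path: str | Path) -> None:
    """Write transcripts as GFF3 (gene/transcript/exon three-level features)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        seen_genes: set[str] = set()
        for t in records:
            if t.gene_id not in seen_genes:
                seen_genes.add(t.gene_id)
                fh.write(
                    f"{t.chrom}\tcernet\tgene\t{t.start}\t{t.end}\t.\t{t.strand}\t.\t"
                    f"ID={t.gene_id}\n"
                )
            feature = _BIOTYPE_FEATURE.get(t.biotype, "transcript")
            fh.write(
                f"{t.chrom}\tcernet\t{feature}\t{t.start}\t{t.end}\t.\t{t.strand}\t.\t"
                f"ID={t.transcript_id};Parent={t.gene_id}\n"
            )
            for s, e in t.exons:
                fh.write(
                    f"{t.chrom}\tcernet\texon\t{s}\t{e}\t.\t{t.strand}\t.\t"
                    f"Parent={t.transcript_id}\n"
                )


def extract_spliced_sequence(
    genome: dict[str, GenomeSequence] | Iterable[GenomeSequence],
    t: TranscriptRecord,
) -> str:
    """Extract the spliced transcript sequence in RNA space (A/C/G/U).

    Exon sequences are concatenated 5'->3' in transcript orientation; minus
    strand transcripts are reverse complemented. ``T``->``U`` applied last.
    """
    if not isinstance(genome, dict):
        genome = {g.chrom_id: g for g in genome}
    if t.chrom not in genome:
        raise CoordinateError(f"{t.transcript_id}: unknown chromosome {t.chrom!r}")
    chrom = genome[t.chrom]
    parts = []
    for s, e in t.exons:
        if s < 1 or e > len(chrom):
            raise CoordinateError(
                f"{t.transcript_id}: exon {s}-{e} outside {t.chrom} "
                f"(length {len(chrom)})"
            )
        parts.append(chrom.sequence[s - 1 : e])
    dna = "".join(parts)
    if t.strand == "-":
        dna = str(Seq(dna).reverse_complement())
    return dna.replace("T", "U")


# ---------------------------------------------------------------------------
# Tabular interchange (TSV)
# ---------------------------------------------------------------------------

def read_count_table(path: str | Path) -> pd.DataFrame:
    """Read a feature x sample count table (first column = feature id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty:
        raise FormatError(f"empty count table {path}")
    if (df.values < 0).any():
        raise FormatError(f"negative values in count table {path}")
    return df


def write_count_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="feature_id")


_CIRC_COLUMNS = ["circ_id", "chrom", "start", "end", "strand"]


def read_circrna_table(path: str | Path) -> list[CircRNARecord]:
    """Read back-splice annotations (TSV: circ_id, chrom, start, end, strand)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _CIRC_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"circRNA table {path} missing columns {missing}")
    return [
        CircRNARecord(
            circ_id=row.circ_id,
            chrom=row.chrom,
            strand=row.strand,
            splice_start=int(row.start),
            splice_end=int(row.end),
        )
        for row in df.itertuples()
    ]


def write_circrna_table(records: Sequence[CircRNARecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            (c.circ_id, c.chrom, c.splice_start, c.splice_end, c.strand)
            for c in records
        ],
        columns=["circ_id", "chrom", "start", "end", "strand"],
    )
    df.to_csv(path, sep="\t", index=False)
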