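"""Synthetic whole-transcriptome inputs with a machine-readable truth table.

Emulates the study design the pipeline targets — 2 tissues (leaf, root) x
2 conditions (ck, st) x 3 replicates — at desk scale: a random genome with
mRNA genes (ORFs >= 300 nt), lncRNAs (200-1000 nt, longest ORF < 300 nt so
the annotation filters are exercised on both sides), circRNAs of all three
locus types, mature miRNAs with planted cleavage and target-mimic sites,
negative-binomial count matrices with planted differential expression and
planted ceRNA-triplet correlation structure, and degradome tag profiles with
peaks at the canonical cleavage positions.

Every planted fact is recorded in a :class:`TruthTable` so each downstream
stage has a recovery test. All generators are deterministic under the seed.

The noise model is a stand-in (the study sequenced real libraries and states
none): counts are negative binomial with one dispersion shared across
features, and triplet correlation is induced structurally by a shared latent
per-sample effect (positive loading on the two ceRNAs, negative on the
miRNA), keeping counts integer and marginally NB.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix
from .io_formats import (
    CircRNARecord,
    GenomeSequence,
    TranscriptRecord,
    reverse_complement,
    write_circrna_table,
    write_count_table,
    write_fasta,
    write_gene_models,
)
from .annotation import longest_orf

__all__ = [
    "PlantedDE",
    "PlantedCleavage",
    "PlantedMimic",
    "TruthTable",
    "SyntheticDataset",
    "generate_reference",
    "plant_mirna_sites",
    "rebuild_genome",
    "simulate_counts",
    "simulate_degradome",
    "generate_dataset",
    "write_dataset",
]

_RNA = "ACGU"
_CODONS = [
    a + b + c
    for a in _RNA
    for b in _RNA
    for c in _RNA
    if a + b + c not in ("UAA", "UAG", "UGA")
]
_TISSUES = ("leaf", "root")
_CONDITIONS = ("ck", "st")
_REPLICATES = (1, 2, 3)


def _rng(seed: "int | np.random.Generator") -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _random_rna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(_RNA), size=n))


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


# ---------------------------------------------------------------------------
# Truth table
# ---------------------------------------------------------------------------

@dataclass
class PlantedDE:
    feature_id: str
    tissue: str
    direction: str  # up | down
    log2fc: float


@dataclass
class PlantedCleavage:
    mirna_id: str
    transcript_id: str
    position: int  # transcript base paired to miRNA nt 10 (1-based)
    expected_category: int | None = None


@dataclass
class PlantedMimic:
    mirna_id: str
    ncrna_id: str
    site_start: int  # 1-based start of the mimic window on the ncRNA
    bulge_length: int


@dataclass
class TruthTable:
    """Machine-readable record of everything the generator planted."""

    rng_seed: int
    planted_de: list[PlantedDE] = field(default_factory=list)
    planted_cleavage: list[PlantedCleavage] = field(default_factory=list)
    planted_mimics: list[PlantedMimic] = field(default_factory=list)
    planted_cerna_triplets: list[tuple[str, str, str]] = field(default_factory=list)

    def to_json(self, path: "str | Path") -> None:
        payload = {
            "rng_seed": self.rng_seed,
            "planted_de": [asdict(x) for x in self.planted_de],
            "planted_cleavage": [asdict(x) for x in self.planted_cleavage],
            "planted_mimics": [asdict(x) for x in self.planted_mimics],
            "planted_cerna_triplets": [list(t) for t in self.planted_cerna_triplets],
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: "str | Path") -> "TruthTable":
        d = json.loads(Path(path).read_text())
        return cls(
            rng_seed=d["rng_seed"],
            planted_de=[PlantedDE(**x) for x in d["planted_de"]],
            planted_cleavage=[PlantedCleavage(**x) for x in d["planted_cleavage"]],
            planted_mimics=[PlantedMimic(**x) for x in d["planted_mimics"]],
            planted_cerna_triplets=[tuple(t) for t in d["planted_cerna_triplets"]],
        )


# ---------------------------------------------------------------------------
# Reference generation
# ---------------------------------------------------------------------------

def _design_mrna(rng: np.random.Generator) -> str:
    """Spliced mRNA (RNA space) with an ORF of >= 300 nt."""
    utr5 = _random_rna(rng, int(rng.integers(50, 150)))
    n_codons = int(rng.integers(100, 200))
    orf = "AUG" + "".join(rng.choice(_CODONS, size=n_codons)) + "UAA"
    utr3 = _random_rna(rng, int(rng.integers(100, 300)))
    return utr5 + orf + utr3


def _design_lncrna(rng: np.random.Generator, max_orf: int = 300) -> str:
    """200-1000 nt transcript whose longest forward-frame ORF is < 300 nt."""
    while True:
        seq = _random_rna(rng, int(rng.integers(200, 1001)))
        if longest_orf(seq) < max_orf:
            return seq


def generate_reference(
    n_genes: int,
    n_lncrna: int,
    n_circrna: int,
    seed: "int | np.random.Generator",
) -> tuple[dict[str, GenomeSequence], list[TranscriptRecord], list[CircRNARecord]]:
    """Random genome + gene models with all feature classes represented.

    Genes alternate between single- and two-exon structures (introns host the
    intron-type circRNAs). circRNA locus types cycle exon/intron/intergenic.
    Transcripts carry their spliced sequences; circRNAs additionally appear
    as single-exon ``circRNA``-biotype transcripts so planting and scanning
    can treat them like any other sequence. Deterministic under the seed.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if n_circrna > 0 and n_genes < 2:
        raise ValueError("circRNA generation needs at least 2 genes (sizing)")
    rng = _rng(seed)

    pieces: list[str] = []
    cursor = 0  # last filled genomic position (1-based end)

    def emit(seq_dna: str) -> tuple[int, int]:
        nonlocal cursor
        pieces.append(seq_dna)
        start = cursor + 1
        cursor += len(seq_dna)
        return start, cursor

    transcripts: list[TranscriptRecord] = []
    circs: list[CircRNARecord] = []
    gene_layout: list[dict] = []  # per-gene info for circRNA placement

    for gi in range(n_genes):
        emit(_random_dna(rng, int(rng.integers(500, 3000))))  # intergenic gap
        strand = "+" if rng.random() < 0.5 else "-"
        rna = _design_mrna(rng)
        dna = rna.replace("U", "T")
        genomic = dna if strand == "+" else reverse_complement(dna)
        two_exon = gi % 2 == 1
        gene_id = f"gene{gi + 1:03d}"
        tid = f"{gene_id}.t1"
        if two_exon:
            cut = int(rng.integers(100, len(genomic) - 100))
            ex1_start, ex1_end = emit(genomic[:cut])
            intron_start, intron_end = emit(_random_dna(rng, int(rng.integers(150, 400))))
            ex2_start, ex2_end = emit(genomic[cut:])
            exons = [(ex1_start, ex1_end), (ex2_start, ex2_end)]
            intron = (intron_start, intron_end)
        else:
            s, e = emit(genomic)
            exons = [(s, e)]
            intron = None
        transcripts.append(
            TranscriptRecord(tid, gene_id, "chr1", strand, exons, "mRNA", rna)
        )
        gene_layout.append({"tid": tid, "strand": strand, "exons": exons, "intron": intron})

    for li in range(n_lncrna):
        emit(_random_dna(rng, int(rng.integers(500, 2000))))
        strand = "+" if rng.random() < 0.5 else "-"
        rna = _design_lncrna(rng)
        dna = rna.replace("U", "T")
        s, e = emit(dna if strand == "+" else reverse_complement(dna))
        lid = f"lnc{li + 1:03d}"
        transcripts.append(
            TranscriptRecord(f"{lid}.t1", lid, "chr1", strand, [(s, e)], "lncRNA", rna)
        )

    two_exon_genes = [g for g in gene_layout if g["intron"] is not None]
    kinds = ["exon", "intron", "intergenic"]
    for ci in range(n_circrna):
        kind = kinds[ci % 3]
        cid = f"circ{ci + 1:03d}"
        if kind == "exon":
            g = gene_layout[ci % len(gene_layout)]
            es, ee = max(g["exons"], key=lambda x: x[1] - x[0])
            if ee - es + 1 < 100:
                raise ValueError(f"exons too short to host circRNA {cid} (sizing)")
            span_len = int(rng.integers(80, min(300, ee - es - 10)))
            start = int(rng.integers(es, ee - span_len + 2))
            circs.append(CircRNARecord(cid, "chr1", g["strand"], start, start + span_len - 1))
        elif kind == "intron":
            if not two_exon_genes:
                raise ValueError("no intron available for intron-type circRNA (sizing)")
            g = two_exon_genes[ci % len(two_exon_genes)]
            is_, ie = g["intron"]
            span_len = int(rng.integers(50, min(120, ie - is_ - 1)))
            start = int(rng.integers(is_ + 1, ie - span_len + 1))
            circs.append(CircRNARecord(cid, "chr1", g["strand"], start, start + span_len - 1))
        else:
            emit(_random_dna(rng, int(rng.integers(300, 800))))
            strand = "+" if rng.random() < 0.5 else "-"
            span_len = int(rng.integers(150, 400))
            s, e = emit(_random_dna(rng, span_len))
            circs.append(CircRNARecord(cid, "chr1", strand, s, e))

    emit(_random_dna(rng, 500))
    genome = {"chr1": GenomeSequence("chr1", "".join(pieces))}

    # circRNAs as sequence-bearing transcript views (single exon, circ span)
    for c in circs:
        chrom_seq = genome["chr1"].sequence
        dna = chrom_seq[c.splice_start - 1 : c.splice_end]
        if c.strand == "-":
            dna = reverse_complement(dna)
        transcripts.append(
            TranscriptRecord(
                c.circ_id,
                c.circ_id,
                "chr1",
                c.strand,
                [(c.splice_start, c.splice_end)],
                "circRNA",
                dna.replace("T", "U"),
            )
        )
    return genome, transcripts, circs


def rebuild_genome(
    genome: dict[str, GenomeSequence], transcripts: Sequence[TranscriptRecord]
) -> dict[str, GenomeSequence]:
    """Patch transcript sequences back into the genome (post-planting).

    Writes every transcript's spliced sequence into its exon intervals so
    that sequence extraction and the planted sites agree. circRNA views that
    overlap another feature (exonic/intronic types sharing their host gene's
    locus) are not written; their sequences are refreshed from the patched
    genome instead, since the host transcript owns those bases.
    """
    buf = {cid: list(g.sequence) for cid, g in genome.items()}
    others: list[tuple[str, int, int]] = [
        (t.chrom, t.start, t.end) for t in transcripts if t.biotype != "circRNA"
    ]
    refresh: list[TranscriptRecord] = []
    for t in transcripts:
        if t.sequence is None:
            continue
        if t.biotype == "circRNA" and any(
            chrom == t.chrom and s <= t.end and t.start <= e for chrom, s, e in others
        ):
            refresh.append(t)
            continue
        dna = t.sequence.replace("U", "T")
        if t.strand == "-":
            dna = reverse_complement(dna)
        offset = 0
        for s, e in t.exons:
            seg = dna[offset : offset + (e - s + 1)]
            buf[t.chrom][s - 1 : e] = list(seg)
            offset += e - s + 1
    patched = {cid: GenomeSequence(cid, "".join(chars)) for cid, chars in buf.items()}
    from .io_formats import extract_spliced_sequence

    for t in refresh:
        t.sequence = extract_spliced_sequence(patched, t)
    return patched


# ---------------------------------------------------------------------------
# Site planting
# ---------------------------------------------------------------------------

def _non_pairing_base(rng: np.random.Generator, mirna_base: str) -> str:
    partners = {"A": {"U"}, "C": {"G"}, "G": {"C", "U"}, "U": {"A", "G"}}[mirna_base]
    choices = sorted(set(_RNA) - partners)
    return str(rng.choice(choices))


def _place(
    rng: np.random.Generator,
    used: dict[str, list[tuple[int, int]]],
    host: TranscriptRecord,
    width: int,
    margin: int = 25,
) -> int | None:
    """A 1-based start for a ``width``-nt window avoiding planted intervals."""
    n = len(host.sequence or "")
    if n < width + 2 * margin:
        return None
    for _ in range(50):
        start = int(rng.integers(margin + 1, n - width - margin + 2))
        span = (start, start + width - 1)
        if all(span[1] < s or e < span[0] for s, e in used.get(host.transcript_id, [])):
            used.setdefault(host.transcript_id, []).append(span)
            return start
    return None


def plant_mirna_sites(
    transcripts: Sequence[TranscriptRecord],
    n_mirna: int,
    seed: "int | np.random.Generator",
    max_cleavage_mutations: int = 2,
    max_mimic_mismatches: int = 2,
) -> tuple[list[tuple[str, str]], TruthTable]:
    """Create mature miRNAs and plant one cleavage and one mimic site each.

    miRNA lengths are drawn from {21, 24} with a 5' U on 21-mers and a 5' A
    on 24-mers (the DCL-product composition bias taken to its extreme).
    Cleavage sites are the exact reverse complement of the miRNA written into
    an mRNA, with 0-``max_cleavage_mutations`` substitutions outside the
    doubled-penalty core so planted sites always stay below the acceptance
    score. Mimic sites are the reverse complement with a 1-4 nt bulge
    inserted between the target bases paired to miRNA positions 10-11 and
    0-``max_mimic_mismatches`` non-middle mismatches, planted into lncRNAs
    and intergenic circRNAs. Sites are planted by replacement, so transcript
    lengths and exon structures are unchanged; call :func:`rebuild_genome`
    afterwards to restore genome/transcript consistency.
    """
    rng = _rng(seed)
    seed_int = int(rng.integers(0, 2**31 - 1))
    truth = TruthTable(rng_seed=seed_int)

    mrnas = [t for t in transcripts if t.biotype == "mRNA"]
    mimic_hosts = [t for t in transcripts if t.biotype == "lncRNA"]
    circ_by_id = {t.transcript_id: t for t in transcripts if t.biotype == "circRNA"}
    # intergenic circRNAs are safe mimic hosts (their span overlaps nothing)
    mrna_intervals = [(t.start, t.end) for t in mrnas]
    for cid in sorted(circ_by_id):
        c = circ_by_id[cid]
        if all(c.end < s or e < c.start for s, e in mrna_intervals):
            mimic_hosts.append(c)
    if not mrnas or not mimic_hosts:
        raise ValueError("planting requires mRNA and ncRNA hosts")

    mirnas: list[tuple[str, str]] = []
    used: dict[str, list[tuple[int, int]]] = {}

    for mi in range(n_mirna):
        length = int(rng.choice([21, 24]))
        first = "U" if length == 21 else "A"
        mseq = first + _random_rna(rng, length - 1)
        mid = f"miR{mi + 1:03d}"
        mirnas.append((mid, mseq))
        L = length

        # --- cleavage site on an mRNA ---
        host = mrnas[mi % len(mrnas)]
        start = _place(rng, used, host, L)
        if start is None:
            raise ValueError(f"transcript {host.transcript_id} too short for a site")
        window = list(reverse_complement(mseq))
        n_mut = int(rng.integers(0, max_cleavage_mutations + 1))
        allowed = [1] + list(range(14, L + 1))  # outside the doubled core 2-13
        for i in map(int, rng.choice(allowed, size=n_mut, replace=False)):
            window[L - i] = _non_pairing_base(rng, mseq[i - 1])
        seq = host.sequence
        host.sequence = seq[: start - 1] + "".join(window) + seq[start - 1 + L :]
        truth.planted_cleavage.append(
            PlantedCleavage(mid, host.transcript_id, start + L - 10)
        )

        # --- mimic site on a lncRNA / intergenic circRNA ---
        mhost = mimic_hosts[mi % len(mimic_hosts)]
        b = int(rng.integers(1, 5))
        j = 10  # bulge inserts between target bases paired to miRNA 10-11
        wm = (
            reverse_complement(mseq[j:])
            + _random_rna(rng, b)
            + reverse_complement(mseq[:j])
        )
        Lw = L + b
        n_mm = int(rng.integers(0, max_mimic_mismatches + 1))
        non_middle = [i for i in range(1, L + 1) if not 9 <= i <= 11]
        for i in map(int, rng.choice(non_middle, size=n_mm, replace=False)):
            col = Lw - i if i <= j else Lw - i - b
            wm = wm[:col] + _non_pairing_base(rng, mseq[i - 1]) + wm[col + 1 :]
        for _ in range(20):
            mstart = _place(rng, used, mhost, Lw)
            if mstart is None:
                raise ValueError(
                    f"transcript {mhost.transcript_id} too short for a mimic site"
                )
            candidate = (
                mhost.sequence[: mstart - 1] + wm + mhost.sequence[mstart - 1 + Lw :]
            )
            if mhost.biotype != "lncRNA" or longest_orf(candidate) < 300:
                mhost.sequence = candidate
                break
        else:
            mhost.sequence = candidate
        truth.planted_mimics.append(PlantedMimic(mid, mhost.transcript_id, mstart, b))
        truth.planted_cerna_triplets.append(
            (mid, host.transcript_id, mhost.transcript_id)
        )
    return mirnas, truth


# ---------------------------------------------------------------------------
# Count simulation
# ---------------------------------------------------------------------------

def _sample_frame() -> pd.DataFrame:
    rows = [
        (f"{t}_{c}_{r}", t, c, r)
        for t in _TISSUES
        for c in _CONDITIONS
        for r in _REPLICATES
    ]
    df = pd.DataFrame(rows, columns=["sample_id", "tissue", "condition", "replicate"])
    return df.set_index("sample_id")


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    if dispersion == 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    return rng.negative_binomial(size, size / (size + mean))


def simulate_counts(
    truth: TruthTable,
    feature_classes: Mapping[str, str],
    dispersion: float = 0.1,
    lib_size: int = 1_000_000,
    seed: "int | np.random.Generator" = 0,
    latent_sd: float = 0.3,
    feature_lengths: Mapping[str, int] | None = None,
) -> dict[str, ExpressionMatrix]:
    """NB count matrices for the 2x2x3 design with planted structure.

    ``feature_classes`` maps feature id to {mRNA, lncRNA, circRNA, miRNA}.
    Gene-like features and miRNAs go into separate matrices (keys ``gene``
    and ``mirna``). Planted DE features differ between conditions by the
    planted log2FC (split symmetrically around the base mean, which is drawn
    from U(200, 800) for planted and U(40, 800) for null features). Members
    of each planted ceRNA triplet share a per-sample latent log-normal effect
    with loading +1 on the ceRNAs and -1 on the miRNA, so the two ceRNAs
    correlate positively and the miRNA negatively with them. ``lib_size``
    rescales every matrix so the expected per-sample total matches it.
    """
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    rng = _rng(seed)
    samples = _sample_frame()
    de_by_feature: dict[str, PlantedDE] = {d.feature_id: d for d in truth.planted_de}

    loadings: dict[str, list[tuple[int, float]]] = {}
    triplet_mask: list[np.ndarray] = []
    for ti, (mid, ca, cb) in enumerate(truth.planted_cerna_triplets):
        loadings.setdefault(mid, []).append((ti, -1.0))
        loadings.setdefault(ca, []).append((ti, +1.0))
        loadings.setdefault(cb, []).append((ti, +1.0))
        # latent co-expression acts in the tissue where the triplet is planted
        tissue = de_by_feature[mid].tissue if mid in de_by_feature else None
        mask = (
            (samples["tissue"] == tissue).to_numpy()
            if tissue is not None
            else np.ones(len(samples), dtype=bool)
        )
        triplet_mask.append(mask)
    n_trip = len(truth.planted_cerna_triplets)
    latent = rng.normal(0.0, 1.0, size=(n_trip, len(samples)))  # per triplet x sample

    groups = {"gene": [], "mirna": []}
    for fid in feature_classes:
        key = "mirna" if feature_classes[fid] == "miRNA" else "gene"
        groups[key].append(fid)

    out: dict[str, ExpressionMatrix] = {}
    for key, fids in groups.items():
        if not fids:
            continue
        base = np.where(
            [fid in de_by_feature for fid in fids],
            rng.uniform(200, 800, size=len(fids)),
            rng.uniform(40, 800, size=len(fids)),
        )
        mean = np.tile(base[:, None], (1, len(samples)))
        for fi, fid in enumerate(fids):
            d = de_by_feature.get(fid)
            if d is not None:
                sign = 1.0 if d.direction == "up" else -1.0
                in_tissue = (samples["tissue"] == d.tissue).to_numpy()
                is_st = (samples["condition"] == "st").to_numpy()
                shift = np.where(is_st, sign * d.log2fc / 2, -sign * d.log2fc / 2)
                mean[fi, in_tissue] *= 2.0 ** shift[in_tissue]
            for ti, loading in loadings.get(fid, []):
                lam = latent_sd * loading
                factor = np.exp(lam * latent[ti] - (latent_sd**2) / 2)
                mean[fi] *= np.where(triplet_mask[ti], factor, 1.0)
        scale = lib_size / mean.sum(axis=0).mean()
        counts = _nb_draw(rng, mean * scale, dispersion).astype(np.int64)
        values = pd.DataFrame(counts, index=fids, columns=samples.index)
        lengths = None
        if feature_lengths is not None and key == "gene":
            lengths = pd.Series({f: feature_lengths[f] for f in fids})
        out[key] = ExpressionMatrix(values, samples, "raw_count", lengths)
    return out


# ---------------------------------------------------------------------------
# Degradome simulation
# ---------------------------------------------------------------------------

def simulate_degradome(
    truth: TruthTable,
    transcript_seqs: Mapping[str, str],
    peak_reads: int = 50,
    background_rate: float = 0.01,
    seed: "int | np.random.Generator" = 0,
) -> pd.DataFrame:
    """Per-transcript per-position degradome tag abundance with planted peaks.

    Each planted cleavage site receives ``peak_reads`` tags whose 5' ends map
    to the target base paired to miRNA nt 10; every other position carries
    Poisson(``background_rate``) background. The intended category of each
    planted site given the realized profile is written back onto the truth
    records. Returns a sparse (transcript_id, position, count) table.
    """
    if peak_reads < 1:
        raise ValueError("peak_reads must be >= 1")
    if background_rate < 0:
        raise ValueError("background_rate must be >= 0")
    rng = _rng(seed)
    abund = {
        tid: rng.poisson(background_rate, size=len(seq)).astype(float)
        for tid, seq in transcript_seqs.items()
    }
    for pc in truth.planted_cleavage:
        abund[pc.transcript_id][pc.position - 1] += peak_reads

    from .degradome import DegradomeProfile, classify_category

    for pc in truth.planted_cleavage:
        profile = DegradomeProfile(pc.transcript_id, abund[pc.transcript_id])
        pc.expected_category = classify_category(profile, pc.position)

    rows = []
    for tid in sorted(abund):
        a = abund[tid]
        for pos in np.nonzero(a)[0]:
            rows.append((tid, int(pos) + 1, float(a[pos])))
    return pd.DataFrame(rows, columns=["transcript_id", "position", "count"])


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

@dataclass
class SyntheticDataset:
    genome: dict[str, GenomeSequence]
    transcripts: list[TranscriptRecord]
    circrnas: list[CircRNARecord]
    mirnas: list[tuple[str, str]]
    counts: dict[str, ExpressionMatrix]
    degradome: pd.DataFrame
    truth: TruthTable

    @property
    def transcript_seqs(self) -> dict[str, str]:
        return {t.transcript_id: t.sequence for t in self.transcripts}


def generate_dataset(
    n_genes: int = 25,
    n_lncrna: int = 15,
    n_circrna: int = 10,
    n_mirna: int = 20,
    dispersion: float = 0.1,
    lib_size: int = 1_000_000,
    peak_reads: int = 50,
    background_rate: float = 0.01,
    log2fc: float = 2.0,
    cerna_log2fc: float = 4.0,
    seed: int = 0,
) -> SyntheticDataset:
    """Full synthetic input set (default study conditions) with truth table.

    Plants one cleavage target (mRNA) and one mimic host (lncRNA/intergenic
    circRNA) per miRNA; each triplet is differentially expressed in one
    tissue (alternating leaf/root) with the miRNA moving opposite to its two
    ceRNAs, plus a handful of extra DE mRNAs and null features. Triplet
    members are planted at ``cerna_log2fc`` (strongly salt-responsive hubs,
    so the planted correlation structure is recoverable above the network's
    correlation threshold); stand-alone DE features use ``log2fc``. A mimic
    host shared by two triplets keeps one consistent direction per tissue.
    """
    rng = np.random.default_rng(seed)
    genome, transcripts, circs = generate_reference(n_genes, n_lncrna, n_circrna, rng)
    mirnas, truth = plant_mirna_sites(transcripts, n_mirna, rng)
    truth.rng_seed = seed
    genome = rebuild_genome(genome, transcripts)

    planted: dict[str, tuple[str, str]] = {}  # feature -> (tissue, direction)

    def plant(fid: str, tissue: str, direction: str, lfc: float) -> None:
        if fid not in planted:
            planted[fid] = (tissue, direction)
            truth.planted_de.append(PlantedDE(fid, tissue, direction, lfc))

    for ti, (mid, ca, cb) in enumerate(truth.planted_cerna_triplets):
        tissue = _TISSUES[ti % 2]
        mdir = "up" if ti % 4 < 2 else "down"
        # a reused ceRNA host keeps its existing direction in this tissue
        for cid in (ca, cb):
            if cid in planted and planted[cid][0] == tissue:
                mdir = "up" if planted[cid][1] == "down" else "down"
        cdir = "down" if mdir == "up" else "up"
        plant(mid, tissue, mdir, cerna_log2fc)
        for cid in (ca, cb):
            if cid not in planted or planted[cid][0] == tissue:
                plant(cid, tissue, cdir, cerna_log2fc)
    # extra DE mRNAs outside any triplet
    triplet_members = {x for t in truth.planted_cerna_triplets for x in t}
    spare = [
        t.transcript_id
        for t in transcripts
        if t.biotype == "mRNA" and t.transcript_id not in triplet_members
    ]
    for si, fid in enumerate(spare[:5]):
        truth.planted_de.append(
            PlantedDE(fid, _TISSUES[si % 2], "up" if si % 2 == 0 else "down", log2fc)
        )

    feature_classes = {t.transcript_id: t.biotype for t in transcripts}
    for mid, _ in mirnas:
        feature_classes[mid] = "miRNA"
    feature_lengths = {t.transcript_id: t.spliced_length for t in transcripts}
    counts = simulate_counts(
        truth,
        feature_classes,
        dispersion=dispersion,
        lib_size=lib_size,
        seed=rng,
        feature_lengths=feature_lengths,
    )
    degradome = simulate_degradome(
        truth,
        {t.transcript_id: t.sequence for t in transcripts if t.biotype == "mRNA"},
        peak_reads=peak_reads,
        background_rate=background_rate,
        seed=rng,
    )
    return SyntheticDataset(genome, transcripts, circs, mirnas, counts, degradome, truth)


def write_dataset(ds: SyntheticDataset, outdir: "str | Path") -> None:
    """Serialize a dataset to the pipeline's on-disk formats (deterministic)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(
        [(cid, g.sequence) for cid, g in sorted(ds.genome.items())], out / "genome.fa"
    )
    write_gene_models(
        [t for t in ds.transcripts if t.biotype != "circRNA"], out / "transcripts.gff3"
    )
    write_fasta(
        [(t.transcript_id, t.sequence) for t in ds.transcripts], out / "transcripts.fa"
    )
    write_fasta(ds.mirnas, out / "mirna_mature.fa")
    write_circrna_table(ds.circrnas, out / "circrna.tsv")
    for key, mat in sorted(ds.counts.items()):
        write_count_table(mat.values, out / f"counts_{key}.tsv")
    ds.counts["gene"].samples.to_csv(out / "samples.tsv", sep="\t")
    ds.degradome.to_csv(out / "degradome.tsv", sep="\t", index=False)
    ds.truth.to_json(out / "truth.json")
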