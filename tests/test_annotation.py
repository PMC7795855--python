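"""lncRNA filters, circRNA locus types, cis targets and the miRNA catalogue."""

import numpy as np
import pytest

from cernet.annotation import (
    assign_cis_targets,
    catalogue_mirna,
    classify_circrna,
    hairpin_check,
    identify_lncrna,
    longest_orf,
)
from cernet.io_formats import CircRNARecord, GenomeSequence, TranscriptRecord, reverse_complement


def tx(tid, strand="+", exons=((1000, 1499),), seq=None, chrom="chr1", gene=None):
    return TranscriptRecord(tid, gene or tid, chrom, strand, list(exons), "unknown", seq)


class TestLongestOrf:
    def test_simple_orf_with_stop(self):
        # AUG + 2 codons + UAA = 12 nt
        assert longest_orf("CCAUGAAACCCUAACC") == 12

    def test_no_start_is_zero(self):
        assert longest_orf("CCCUUUGGGCCC") == 0

    def test_open_ended_orf_counts_to_last_codon(self):
        assert longest_orf("AUGAAACCC") == 9


class TestIdentifyLncrna:
    mrna = [tx("m1", "+", [(1000, 1999)])]

    def test_short_transcript_discarded(self):
        cand = tx("c1", "+", [(5000, 5149)], seq="A" * 150)
        assert identify_lncrna([cand], self.mrna) == set()

    def test_same_strand_exonic_overlap_discarded(self):
        cand = tx("c1", "+", [(1999, 2498)], seq="C" * 500)
        assert identify_lncrna([cand], self.mrna) == set()

    def test_antisense_overlap_retained(self):
        cand = tx("c1", "-", [(1500, 1999)], seq="C" * 500)
        assert identify_lncrna([cand], self.mrna) == {"c1"}

    def test_low_orf_non_overlapping_retained(self, rng):
        seq = "".join(rng.choice(list("ACGU"), size=500))
        while longest_orf(seq) >= 300:
            seq = "".join(rng.choice(list("ACGU"), size=500))
        cand = tx("c1", "+", [(5000, 5499)], seq=seq)
        assert identify_lncrna([cand], self.mrna) == {"c1"}

    def test_long_orf_discarded(self):
        seq = "AUG" + "GCU" * 120 + "UAA"  # 366-nt ORF
        cand = tx("c1", "+", [(5000, 5000 + len(seq) - 1)], seq=seq)
        assert identify_lncrna([cand], self.mrna) == set()

    def test_external_coding_potential_overrides_orf(self):
        seq = "AUG" + "GCU" * 120 + "UAA"
        cand = tx("c1", "+", [(5000, 5000 + len(seq) - 1)], seq=seq)
        assert identify_lncrna([cand], self.mrna, coding_potential={"c1": False}) == {"c1"}

    def test_output_disjoint_from_mrna_and_min_length(self, dataset):
        mrnas = [t for t in dataset.transcripts if t.biotype == "mRNA"]
        cands = [t for t in dataset.transcripts if t.biotype == "lncRNA"]
        kept = identify_lncrna(cands, mrnas)
        assert kept == {t.transcript_id for t in cands}
        lengths = {t.transcript_id: t.spliced_length for t in cands}
        assert all(lengths[i] >= 200 for i in kept)


class TestClassifyCircrna:
    gene = tx("m1", "+", [(1000, 1499), (1700, 2199)])

    def test_exon_overlap(self):
        c = CircRNARecord("c", "chr1", "+", 1400, 1460)
        assert classify_circrna(c, [self.gene]) == "exon"
        assert c.locus_type == "exon"

    def test_intronic_span(self):
        c = CircRNARecord("c", "chr1", "+", 1550, 1650)
        assert classify_circrna(c, [self.gene]) == "intron"

    def test_intergenic_span(self):
        c = CircRNARecord("c", "chr1", "+", 9000, 9100)
        assert classify_circrna(c, [self.gene]) == "intergenic"

    def test_opposite_strand_does_not_count(self):
        c = CircRNARecord("c", "chr1", "-", 1400, 1460)
        assert classify_circrna(c, [self.gene]) == "intergenic"

    def test_exhaustive_and_exclusive_on_synthetic(self, dataset):
        models = [t for t in dataset.transcripts if t.biotype == "mRNA"]
        types = [classify_circrna(c, models) for c in dataset.circrnas]
        assert set(types) <= {"exon", "intron", "intergenic"}
        assert set(types) == {"exon", "intron", "intergenic"}  # all represented


class TestAssignCisTargets:
    def test_gene_within_window_paired(self):
        lnc = tx("l1", "+", [(200_000, 200_500)])
        gene = tx("g1", "+", [(150_000, 150_400)])
        (pair,) = assign_cis_targets([lnc], [gene])
        assert pair.gene_id == "g1" and abs(pair.distance) == 49_600

    def test_gene_beyond_window_not_paired(self):
        lnc = tx("l1", "+", [(400_000, 400_500)])
        gene = tx("g1", "+", [(150_000, 150_400)])
        assert assign_cis_targets([lnc], [gene]) == []

    def test_opposite_strand_overlap_distance_zero(self):
        lnc = tx("l1", "-", [(150_100, 150_300)])
        gene = tx("g1", "+", [(150_000, 150_400)])
        (pair,) = assign_cis_targets([lnc], [gene])
        assert pair.distance == 0

    def test_upstream_pairs_signed_negative(self):
        gene_plus = tx("g1", "+", [(500_000, 500_400)])
        gene_minus = tx("g2", "-", [(500_000, 500_400)])
        lnc = tx("l1", "+", [(450_000, 450_100)])  # below both genes
        pairs = {p.gene_id: p.distance for p in assign_cis_targets([lnc], [gene_plus, gene_minus])}
        assert pairs["g1"] < 0 < pairs["g2"]

    def test_agrees_with_all_pairs_bruteforce(self, rng):
        lncs = [
            tx(f"l{i}", "+", [(int(s), int(s) + 400)])
            for i, s in enumerate(rng.integers(1, 600_000, 20))
        ]
        genes = [
            tx(f"g{i}", rng.choice(["+", "-"]), [(int(s), int(s) + 800)])
            for i, s in enumerate(rng.integers(1, 600_000, 30))
        ]
        got = {(p.lncrna_id, p.gene_id, p.distance) for p in assign_cis_targets(lncs, genes)}
        want = set()
        for l in lncs:
            for g in genes:
                if l.end < g.start:
                    gap, sign = g.start - l.end, (-1 if g.strand == "+" else 1)
                elif g.end < l.start:
                    gap, sign = l.start - g.end, (-1 if g.strand == "-" else 1)
                else:
                    gap, sign = 0, 1
                if gap <= 100_000:
                    want.add((l.transcript_id, g.gene_id, sign * gap))
        assert got == want


class TestHairpinCheck:
    def test_perfect_stem_loop_passes(self, rng):
        arm = "".join(rng.choice(list("ACGU"), size=60))
        win = "A" * 30 + arm + "GAAA" + reverse_complement(arm) + "A" * 30
        assert hairpin_check(win, 31, 21)

    def test_poly_a_window_fails(self):
        assert not hairpin_check("A" * 421, 201, 21)

    def test_window_shorter_than_fold_minimum_fails(self):
        assert not hairpin_check("ACGUACGUACGUACGUACGUACGUA", 1, 21)

    def test_random_windows_rarely_pass(self, rng):
        """Monte-Carlo calibration of the frozen pair-fraction threshold."""
        passes = sum(
            hairpin_check("".join(rng.choice(list("ACGU"), size=421)), 201, 21)
            for _ in range(200)
        )
        assert passes / 200 < 0.05


class TestCatalogueMirna:
    @pytest.fixture()
    def genome_with_hairpin(self, rng):
        mature = "U" + "".join(rng.choice(list("ACGU"), size=20))
        mature_dna = mature.replace("U", "T")
        stem = ("".join(rng.choice(list("ACGT"), size=20)) + mature_dna)
        precursor = stem + "GTTTTC" + reverse_complement(stem)
        pad = "".join(rng.choice(list("ACGT"), size=300))
        pad2 = "".join(rng.choice(list("ACGT"), size=300))
        genome = {"chr1": GenomeSequence("chr1", pad + precursor + pad2)}
        return genome, mature

    def test_read_matching_reference_is_known(self, genome_with_hairpin):
        genome, mature = genome_with_hairpin
        refs = [("ref-miR1", mature)]
        res = catalogue_mirna([("r1", mature, 100)], refs, genome)
        (rec,) = res.records
        assert (rec.status, rec.mismatches) == ("known", 0)

    def test_three_mismatches_still_known(self, genome_with_hairpin):
        genome, mature = genome_with_hairpin
        mutated = "A" + "G" + "C" + mature[3:]
        refs = [("ref-miR1", mature)]
        res = catalogue_mirna([("r1", mutated, 5)], refs, genome)
        assert res.records and res.records[0].status == "known"

    def test_hairpin_locus_without_reference_is_novel(self, genome_with_hairpin):
        genome, mature = genome_with_hairpin
        res = catalogue_mirna([("r1", mature, 100)], [], genome)
        (rec,) = res.records
        assert rec.status == "novel" and rec.hairpin_pass

    def test_unmappable_read_dropped_with_reason(self, genome_with_hairpin):
        genome, _ = genome_with_hairpin
        res = catalogue_mirna([("r1", "ACGUACGUACGUACGUACGUA", 1)], [], genome)
        assert res.records == [] and res.dropped[0][0] == "r1"

    def test_length_filter_and_partition(self, genome_with_hairpin):
        genome, mature = genome_with_hairpin
        reads = [
            ("short", "ACGUACGUACGUACGUA", 1),  # 17 nt
            ("long", "A" * 26, 1),
            ("good", mature, 10),
        ]
        res = catalogue_mirna(reads, [("ref", mature)], genome)
        assert {r.mirna_id for r in res.records} | {d[0] for d in res.dropped} == {
            "short", "long", "good",
        }
        assert len(res.records) + len(res.dropped) == len(reads)

    def test_synthetic_mirnas_follow_dcl_first_nt_bias(self, dataset):
        """Emitted 21-mers are 100% 5'-U and 24-mers 100% 5'-A."""
        by_len = {}
        for _, seq in dataset.mirnas:
            by_len.setdefault(len(seq), []).append(seq[0])
        assert set(by_len) <= {21, 24}
        assert set(by_len[21]) == {"U"}
        assert set(by_len[24]) == {"A"}
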