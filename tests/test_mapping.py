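"""MAF parsing, coordinate mapping, consequence calling and aggregation."""
import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

from zfhotspot.domains import find_zf_domains
from zfhotspot.errors import InputError, ReferenceMismatchError, SchemaError
from zfhotspot.mapping import (aggregate_position_profile, cds_to_genomic,
                               classify_consequence,
                               filter_samples_by_region_mutation,
                               genomic_to_cds, map_mutation, read_maf,
                               select_isoform)
from zfhotspot.models import MISSENSE, NONSENSE, SYNONYMOUS, GeneModel

from conftest import make_gene, make_mutation

MAF_HEADER = ("Hugo_Symbol\tChromosome\tStart_Position\tReference_Allele\t"
              "Tumor_Seq_Allele2\tTumor_Sample_Barcode\tVariant_Type\n")


class TestReadMaf:
    def test_snp_rows_kept_and_indels_tallied(self, tmp_path):
        f = tmp_path / "m.maf"
        f.write_text(MAF_HEADER +
                     "G1\tchr1\t101\tA\tT\tS1\tSNP\n"
                     "G1\tchr1\t102\tC\tG\tS2\tSNP\n"
                     "G1\tchr1\t103\tC\tCA\tS1\tINS\n")
        recs, skipped = read_maf(f)
        assert len(recs) == 2
        assert skipped == {"INS": 1}

    def test_empty_file_with_header(self, tmp_path):
        f = tmp_path / "m.maf"
        f.write_text(MAF_HEADER)
        recs, skipped = read_maf(f)
        assert recs == [] and not skipped

    def test_missing_column_is_schema_error(self, tmp_path):
        f = tmp_path / "m.maf"
        f.write_text("Hugo_Symbol\tChromosome\n")
        with pytest.raises(SchemaError, match="Tumor_Sample_Barcode"):
            read_maf(f)

    def test_ref_equals_alt_rejected(self, tmp_path):
        f = tmp_path / "m.maf"
        f.write_text(MAF_HEADER + "G1\tchr1\t101\tA\tA\tS1\tSNP\n")
        recs, _ = read_maf(f)
        assert recs == []


class TestCoordinateMapping:
    TWO_EXON = [("chr1", 101, 150), ("chr1", 201, 250)]

    def test_plus_strand_counts_through_introns(self):
        gene = GeneModel("G1", "G1.t1", "+", self.TWO_EXON, "A" * 100, "K" * 33)
        assert genomic_to_cds(gene, "chr1", 205) == 55
        assert genomic_to_cds(gene, "chr1", 101) == 1
        assert genomic_to_cds(gene, "chr1", 151) is None        # intron
        assert genomic_to_cds(gene, "chr2", 101) is None        # wrong chrom

    def test_minus_strand_counts_from_top(self):
        gene = GeneModel("G1", "G1.t1", "-", [("chr1", 101, 150)], "A" * 50, "K" * 16)
        assert genomic_to_cds(gene, "chr1", 150) == 1
        assert genomic_to_cds(gene, "chr1", 101) == 50

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_round_trip_identity_on_every_base(self, strand):
        intervals = [("chr1", 101, 130), ("chr1", 181, 200), ("chr1", 301, 310)]
        L = sum(e - s + 1 for _, s, e in intervals)
        gene = GeneModel("G1", "G1.t1", strand, intervals, "A" * L, "K" * (L // 3))
        for cds_pos in range(1, L + 1):
            chrom, gpos = cds_to_genomic(gene, cds_pos)
            assert genomic_to_cds(gene, chrom, gpos) == cds_pos


class TestClassifyConsequence:
    def test_examples(self):
        atg = make_gene("G1", "ATGTAA")
        assert classify_consequence(atg, 3, "G", "A") == (1, "M", "I", MISSENSE)
        ggg = make_gene("G2", "GGGTAA")
        assert classify_consequence(ggg, 3, "G", "A") == (1, "G", "G", SYNONYMOUS)
        tgg = make_gene("G3", "TGGTAA")
        assert classify_consequence(tgg, 2, "G", "A") == (1, "W", "*", NONSENSE)

    def test_reference_mismatch_carries_both_bases(self):
        gene = make_gene("G1", "ATGTAA")
        with pytest.raises(ReferenceMismatchError, match="'A'.*'C'"):
            classify_consequence(gene, 1, "C", "G")

    def test_agrees_with_translation_oracle_on_all_substitutions(self):
        """Every substitution of every sense codon, vs translating both codons."""
        bases = "ACGT"
        sense = [a + b + c for a in bases for b in bases for c in bases
                 if str(Seq(a + b + c).translate()) != "*"]
        assert len(sense) == 61
        checked = 0
        for codon in sense:
            gene = make_gene("G", codon + "TAA")
            for pos in range(3):
                for alt in bases:
                    if alt == codon[pos]:
                        continue
                    alt_codon = codon[:pos] + alt + codon[pos + 1:]
                    ref_aa = str(Seq(codon).translate())
                    alt_aa = str(Seq(alt_codon).translate())
                    expected = (SYNONYMOUS if ref_aa == alt_aa
                                else NONSENSE if alt_aa == "*" else MISSENSE)
                    got = classify_consequence(gene, pos + 1, codon[pos], alt)
                    assert got[3] == expected, (codon, pos, alt)
                    checked += 1
        assert checked == 61 * 9


class TestSelectIsoform:
    def _iso(self, tid, start, length):
        L = length
        return GeneModel("G", tid, "+", [("chr1", start, start + L - 1)],
                         "A" * L, "K" * (L // 3))

    def test_max_mapped_wins(self):
        iso_a = self._iso("t1", 101, 30)        # covers 101..130
        iso_b = self._iso("t2", 101, 60)        # covers 101..160
        muts = [make_mutation(gpos=g) for g in (105, 125, 140, 150, 155, 158, 160)]
        assert select_isoform([iso_a, iso_b], muts).transcript_id == "t2"

    def test_tie_breaks_by_longest_cds_then_id(self):
        iso_a = self._iso("t1", 101, 300)
        iso_b = self._iso("t2", 101, 600)
        assert select_isoform([iso_a, iso_b], []).transcript_id == "t2"
        iso_c = self._iso("t0", 101, 600)
        assert select_isoform([iso_b, iso_c], []).transcript_id == "t0"

    def test_single_isoform_and_empty_error(self):
        iso = self._iso("t1", 101, 30)
        assert select_isoform([iso], []) is iso
        with pytest.raises(InputError):
            select_isoform([], [])


def _domain_gene():
    """Gene with one pattern domain starting at protein position 2."""
    protein = "M" + "CAACAAAAAAAAALAAHAAAH"
    cds = "ATG" + "".join({
        "C": "TGT", "A": "GCT", "L": "CTG", "H": "CAC"}[a] for a in protein[1:]) + "TAA"
    gene = make_gene("ZF1", cds)
    domains = find_zf_domains(gene.protein_seq, gene_id="ZF1")
    assert [d.protein_start for d in domains] == [2]
    return gene, {"ZF1": domains}


class TestAggregateProfile:
    def test_counts_averages_and_fractions(self):
        gene, domains = _domain_gene()
        # label 9 = domain index 19 = protein position 20
        muts = [make_mutation(sample=s, gene=g, protein_pos=20, consequence=MISSENSE)
                for s, g in (("S1", "ZF1"), ("S1", "ZF1"), ("S2", "ZF1"))]
        prof = aggregate_position_profile(muts, domains, ["S1", "S2"])
        assert prof.counts[9] == 3
        assert prof.per_sample_average[9] == 1.5
        assert prof.patient_fractions[9] == 1.0
        assert prof.patient_fractions["zf_domain"] == 1.0
        prof.validate()

    def test_synonymous_counted_separately(self):
        gene, domains = _domain_gene()
        muts = [make_mutation(protein_pos=20, gene="ZF1", consequence=SYNONYMOUS)]
        prof = aggregate_position_profile(muts, domains, ["S1"])
        assert prof.counts[9] == 0 and prof.synonymous_counts[9] == 1

    def test_exact_sequence_crosscheck_excludes_domain(self):
        gene, domains = _domain_gene()
        muts = [make_mutation(gene="ZF1", protein_pos=20, consequence=MISSENSE)]
        ref = {"ZF1": gene.protein_seq[:5] + "W" + gene.protein_seq[6:]}
        prof = aggregate_position_profile(muts, domains, ["S1"],
                                          gene_models={"ZF1": gene},
                                          reference_protein_check=ref)
        assert sum(prof.counts.values()) == 0
        ok = aggregate_position_profile(muts, domains, ["S1"],
                                        gene_models={"ZF1": gene},
                                        reference_protein_check={"ZF1": gene.protein_seq})
        assert ok.counts[9] == 1

    def test_empty_cohort_zero_profile(self):
        _, domains = _domain_gene()
        prof = aggregate_position_profile([], domains, [])
        assert sum(prof.counts.values()) == 0
        assert all(v == 0.0 for v in prof.patient_fractions.values())


class TestRegionFilter:
    MUTS = [
        make_mutation(sample="S1", gene="POLE", protein_pos=15, consequence=MISSENSE),
        make_mutation(sample="S2", gene="POLE", protein_pos=15, consequence=SYNONYMOUS),
        make_mutation(sample="S3", gene="OTHER", protein_pos=15, consequence=MISSENSE),
    ]

    def test_with_requires_missense_in_region(self):
        assert filter_samples_by_region_mutation(self.MUTS, "POLE", (10, 20),
                                                 "with") == {"S1"}

    def test_without_returns_complement(self):
        assert filter_samples_by_region_mutation(self.MUTS, "POLE", (10, 20),
                                                 "without") == {"S2", "S3"}

    def test_unknown_gene_and_empty_cohort(self):
        with pytest.raises(InputError):
            filter_samples_by_region_mutation(self.MUTS, "NOPE", (1, 2), "with")
        assert filter_samples_by_region_mutation([], "G", (1, 2), "with",
                                                 samples=[]) == set()


def test_map_mutation_reverse_complements_minus_strand():
    # minus-strand gene: genomic sequence is revcomp of the CDS at the locus
    cds = "ATGAAATAA"
    genomic = str(Seq(cds).reverse_complement())       # TTATTTCAT at 101..109
    gene = make_gene("G1", cds, strand="-", intervals=[("chr1", 101, 109)])
    # cds position 5 (the middle A of AAA, codon K) maps to genomic 105, base T
    rec = make_mutation(gene="G1", gpos=105, ref="T", alt="G")  # coding A->C
    out = map_mutation(gene, rec)
    assert out.cds_pos == 5 and out.protein_pos == 2
    assert (out.ref_aa, out.alt_aa) == ("K", "T")
    assert out.consequence == MISSENSE
    assert out.context == "AAA"
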