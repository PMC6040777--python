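"""MAF parsing, coordinate mapping, consequence calling and positional aggregation.

Substitutions from a MAF-like table are mapped onto one representative
transcript per gene (the isoform mapping the most mutations), classified as
missense / synonymous / nonsense with the standard genetic code, annotated
with their coding-strand trinucleotide context, and aggregated onto the
21-position zinc-finger grid per cancer cohort.
"""
from __future__ import annotations

import logging
from collections import Counter
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

from .errors import InputError, ReferenceMismatchError, SchemaError
from .models import (LABELS, MISSENSE, NONSENSE, OTHER, SYNONYMOUS, GeneModel,
                     MutationRecord, PositionProfile, ZFDomain)

log = logging.getLogger(__name__)

MAF_REQUIRED = ["Hugo_Symbol", "Chromosome", "Start_Position", "Reference_Allele",
                "Tumor_Seq_Allele2", "Tumor_Sample_Barcode", "Variant_Type"]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

CODON_TABLE = standard_dna_table.forward_table


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate_codon(codon: str) -> str:
    """Amino acid for a codon; '*' for stop."""
    return CODON_TABLE.get(codon, "*" if codon in standard_dna_table.stop_codons else "X")


# ---------------------------------------------------------------------------
# MAF input
# ---------------------------------------------------------------------------

def read_maf(path) -> tuple[list[MutationRecord], Counter]:
    """Read single-nucleotide substitutions from a MAF-like TSV.

    Returns (records, skipped) where ``skipped`` tallies non-SNP variant
    types.  Rows with identical ref and alt are rejected with a warning.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    missing = [c for c in MAF_REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required MAF columns {missing}")
    records: list[MutationRecord] = []
    skipped: Counter = Counter()
    for row in df.itertuples(index=False):
        vtype = getattr(row, "Variant_Type")
        if vtype != "SNP":
            skipped[vtype] += 1
            continue
        ref = getattr(row, "Reference_Allele")
        alt = getattr(row, "Tumor_Seq_Allele2")
        if ref == alt:
            log.warning("MAF row with ref == alt (%s) rejected", ref)
            continue
        sample = getattr(row, "Tumor_Sample_Barcode")
        if not sample:
            raise SchemaError(f"{path}: row missing Tumor_Sample_Barcode")
        records.append(MutationRecord(
            sample_id=sample,
            gene_id=getattr(row, "Hugo_Symbol"),
            chrom=getattr(row, "Chromosome"),
            genomic_pos=int(getattr(row, "Start_Position")),
            ref_base=ref, alt_base=alt))
    if skipped:
        log.info("skipped non-SNP variants: %s", dict(skipped))
    return records, skipped


# ---------------------------------------------------------------------------
# Coordinate mapping
# ---------------------------------------------------------------------------

def genomic_to_cds(gene: GeneModel, chrom: str, genomic_pos: int) -> Optional[int]:
    """Map a genomic position to a 1-based CDS coordinate, or None.

    Plus strand counts 5'->3' through the intervals in genomic order; minus
    strand counts from the highest genomic coordinate downwards.
    """
    offset = 0
    intervals = gene.cds_intervals
    if gene.strand == "+":
        for c, s, e in intervals:
            if c == chrom and s <= genomic_pos <= e:
                return offset + (genomic_pos - s) + 1
            offset += e - s + 1
    else:
        for c, s, e in reversed(intervals):
            if c == chrom and s <= genomic_pos <= e:
                return offset + (e - genomic_pos) + 1
            offset += e - s + 1
    return None


def cds_to_genomic(gene: GeneModel, cds_pos: int) -> tuple[str, int]:
    """Inverse of :func:`genomic_to_cds` (raises on out-of-range input)."""
    if not 1 <= cds_pos <= gene.cds_length:
        raise InputError(f"cds_pos {cds_pos} outside CDS of {gene.gene_id}")
    remaining = cds_pos
    intervals = gene.cds_intervals if gene.strand == "+" else list(reversed(gene.cds_intervals))
    for c, s, e in intervals:
        width = e - s + 1
        if remaining <= width:
            return (c, s + remaining - 1) if gene.strand == "+" else (c, e - remaining + 1)
        remaining -= width
    raise AssertionError("unreachable")


def cds_context(gene: GeneModel, cds_pos: int) -> Optional[str]:
    """Coding-strand reference trinucleotide around a CDS position.

    Contexts are taken from the spliced coding sequence; the first and last
    CDS base have no complete context and return None.
    """
    if cds_pos <= 1 or cds_pos >= gene.cds_length:
        return None
    return gene.cds_seq[cds_pos - 2:cds_pos + 1]


def classify_consequence(gene: GeneModel, cds_pos: int, ref_base: str,
                         alt_base: str) -> tuple[int, str, str, str]:
    """Classify a coding-strand substitution.

    Returns (protein_pos, ref_aa, alt_aa, consequence).  ``ref_base`` must
    match the coding sequence at ``cds_pos``.
    """
    model_ref = gene.cds_seq[cds_pos - 1]
    if model_ref != ref_base:
        raise ReferenceMismatchError(model_ref, ref_base,
                                     where=f"{gene.gene_id}:cds{cds_pos}")
    codon_idx = (cds_pos - 1) // 3           # 0-based
    within = (cds_pos - 1) % 3
    codon = gene.cds_seq[codon_idx * 3:codon_idx * 3 + 3]
    alt_codon = codon[:within] + alt_base + codon[within + 1:]
    ref_aa = translate_codon(codon)
    alt_aa = translate_codon(alt_codon)
    if ref_aa == "*":
        consequence = OTHER                   # stop-retained or stop-loss
    elif alt_aa == "*":
        consequence = NONSENSE
    elif ref_aa == alt_aa:
        consequence = SYNONYMOUS
    else:
        consequence = MISSENSE
    return codon_idx + 1, ref_aa, alt_aa, consequence


def map_mutation(gene: GeneModel, rec: MutationRecord) -> MutationRecord:
    """Fill CDS/protein coordinates, consequence and context for one record.

    Ref/alt are reverse-complemented onto the coding strand for minus-strand
    genes.  Positions outside the CDS leave the record unannotated with
    consequence ``noncoding/other``.
    """
    cds_pos = genomic_to_cds(gene, rec.chrom, rec.genomic_pos)
    if cds_pos is None:
        return rec
    ref, alt = rec.ref_base, rec.alt_base
    if gene.strand == "-":
        ref, alt = revcomp(ref), revcomp(alt)
    protein_pos, ref_aa, alt_aa, consequence = classify_consequence(gene, cds_pos, ref, alt)
    rec.cds_pos = cds_pos
    rec.protein_pos = protein_pos
    rec.ref_aa, rec.alt_aa = ref_aa, alt_aa
    rec.consequence = consequence
    rec.context = cds_context(gene, cds_pos)
    return rec


def map_mutations(records: Iterable[MutationRecord],
                  gene_models: dict[str, GeneModel]) -> list[MutationRecord]:
    """Annotate every record whose gene has a model; others pass through."""
    out = []
    for rec in records:
        gene = gene_models.get(rec.gene_id)
        if gene is not None:
            rec = map_mutation(gene, rec)
        out.append(rec)
    return out


def select_isoform(isoforms: Sequence[GeneModel],
                   mutations: Iterable[MutationRecord]) -> GeneModel:
    """Pick the isoform mapping the most mutations.

    Ties break by longest CDS, then lexicographically smallest transcript id.
    """
    isoforms = list(isoforms)
    if not isoforms:
        raise InputError("empty isoform list")
    muts = list(mutations)

    def mapped_count(model: GeneModel) -> int:
        return sum(genomic_to_cds(model, m.chrom, m.genomic_pos) is not None
                   for m in muts)

    return sorted(isoforms,
                  key=lambda m: (-mapped_count(m), -m.cds_length, m.transcript_id))[0]


# ---------------------------------------------------------------------------
# Positional aggregation
# ---------------------------------------------------------------------------

def _domain_passes_check(domain: ZFDomain, protein_seq: str,
                         reference_protein: Optional[str]) -> bool:
    """Exact-sequence cross-check: the 21-mer must appear verbatim at the
    stated coordinates of the cross-reference protein (vacuous when absent)."""
    if reference_protein is None:
        return True
    segment = reference_protein[domain.protein_start - 1:domain.protein_end]
    return segment == protein_seq[domain.protein_start - 1:domain.protein_end]


def aggregate_position_profile(
        mutations: Iterable[MutationRecord],
        domains: dict[str, list[ZFDomain]],
        samples: Sequence[str],
        cohort_id: str = "cohort",
        gene_models: Optional[dict[str, GeneModel]] = None,
        reference_protein_check: Optional[dict[str, str]] = None,
        focal_labels: Sequence[int] = (9, 11)) -> PositionProfile:
    """Aggregate domain mutations onto the 21-position grid.

    A mutation contributes to label L when its protein position falls at the
    index labeled L of some domain of its gene that passes the (optional)
    exact-sequence cross-check.  Patient fractions are computed over all
    ``samples``, including those with no ZF mutations.
    """
    samples = list(samples)
    sample_idx = {s: i for i, s in enumerate(samples)}
    counts = {lab: 0 for lab in LABELS}
    syn_counts = {lab: 0 for lab in LABELS}
    per_sample = np.zeros((len(samples), len(LABELS)), dtype=int)
    lab_col = {lab: j for j, lab in enumerate(LABELS)}

    usable: dict[str, list[ZFDomain]] = {}
    for gene_id, doms in domains.items():
        ref = (reference_protein_check or {}).get(gene_id)
        seq = gene_models[gene_id].protein_seq if gene_models else None
        kept = []
        for d in doms:
            if ref is not None and seq is not None and not _domain_passes_check(d, seq, ref):
                log.info("domain %s:%d fails exact-sequence cross-check; excluded",
                         gene_id, d.protein_start)
                continue
            kept.append(d)
        usable[gene_id] = kept

    zf_gene_hit: set[str] = set()
    zf_domain_hit: set[str] = set()
    focal_hit: dict[int, set[str]] = {lab: set() for lab in focal_labels}

    for m in mutations:
        if m.protein_pos is None or m.gene_id not in usable:
            continue
        if m.consequence == MISSENSE and m.sample_id in sample_idx:
            zf_gene_hit.add(m.sample_id)
        hits = [d for d in usable[m.gene_id]
                if d.protein_start <= m.protein_pos <= d.protein_end]
        assert len(hits) <= 1, "overlapping domains violate the non-overlap invariant"
        if not hits:
            continue
        label = hits[0].label_of_protein_pos(m.protein_pos)
        if m.consequence == MISSENSE:
            counts[label] += 1
            if m.sample_id in sample_idx:
                per_sample[sample_idx[m.sample_id], lab_col[label]] += 1
                zf_domain_hit.add(m.sample_id)
                if label in focal_hit:
                    focal_hit[label].add(m.sample_id)
        elif m.consequence == SYNONYMOUS:
            syn_counts[label] += 1

    n = len(samples)
    fractions: dict[object, float] = {
        "zf_gene": len(zf_gene_hit) / n if n else 0.0,
        "zf_domain": len(zf_domain_hit) / n if n else 0.0,
    }
    for lab in focal_labels:
        fractions[lab] = len(focal_hit[lab]) / n if n else 0.0

    return PositionProfile(
        cohort_id=cohort_id, counts=counts, synonymous_counts=syn_counts,
        per_sample=pd.DataFrame(per_sample, index=samples, columns=list(LABELS)),
        n_samples=n, patient_fractions=fractions)


def filter_samples_by_region_mutation(
        mutations: Iterable[MutationRecord], gene_id: str,
        protein_region: tuple[int, int], mode: str = "with",
        samples: Optional[Sequence[str]] = None) -> set[str]:
    """Split a cohort by missense status in a protein region of one gene.

    ``mode='with'`` returns samples carrying >= 1 missense mutation with
    protein position inside [a, b] of ``gene_id``; ``mode='without'`` returns
    the complement within the cohort (samples observed in the mutation list,
    or an explicit ``samples`` universe).
    """
    a, b = protein_region
    if a > b:
        raise InputError("protein_region must satisfy a <= b")
    if mode not in ("with", "without"):
        raise InputError(f"unknown mode {mode!r}")
    muts = list(mutations)
    known_genes = {m.gene_id for m in muts}
    universe = set(samples) if samples is not None else {m.sample_id for m in muts}
    if gene_id not in known_genes and samples is None:
        raise InputError(f"unknown gene {gene_id!r}")
    hit = {m.sample_id for m in muts
           if m.gene_id == gene_id and m.consequence == MISSENSE
           and m.protein_pos is not None and a <= m.protein_pos <= b}
    return hit if mode == "with" else universe - hit


# ---------------------------------------------------------------------------
# Gene-model table I/O
# ---------------------------------------------------------------------------

def read_gene_models(table_path, cds_fasta, protein_fasta) -> dict[str, GeneModel]:
    """Load gene models from a TSV plus CDS/protein FASTA keyed by transcript id.

    The table columns are gene_id, transcript_id, strand, chrom, intervals
    (semicolon-joined ``start-end`` pairs in genomic order) and is_krab.
    """
    from Bio import SeqIO

    cds = {r.id: str(r.seq) for r in SeqIO.parse(str(cds_fasta), "fasta")}
    prot = {r.id: str(r.seq) for r in SeqIO.parse(str(protein_fasta), "fasta")}
    df = pd.read_csv(table_path, sep="\t", comment="#", dtype=str)
    required = ["gene_id", "transcript_id", "strand", "chrom", "intervals", "is_krab"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{table_path}: missing gene-model columns {missing}")
    models: dict[str, GeneModel] = {}
    for row in df.itertuples(index=False):
        intervals = []
        for part in row.intervals.split(";"):
            s, e = part.split("-")
            intervals.append((row.chrom, int(s), int(e)))
        tid = row.transcript_id
        if tid not in cds or tid not in prot:
            raise InputError(f"transcript {tid} missing from FASTA inputs")
        model = GeneModel(gene_id=row.gene_id, transcript_id=tid, strand=row.strand,
                          cds_intervals=intervals, cds_seq=cds[tid],
                          protein_seq=prot[tid],
                          is_krab=str(row.is_krab).lower() in ("1", "true", "yes"))
        model.validate()
        models[row.gene_id] = model
    return models


def write_gene_models(models: dict[str, GeneModel], table_path, cds_fasta, protein_fasta):
    """Write gene models to the TSV + FASTA layout read by read_gene_models."""
    rows = []
    with open(cds_fasta, "w") as cf, open(protein_fasta, "w") as pf:
        for g in models.values():
            rows.append({
                "gene_id": g.gene_id, "transcript_id": g.transcript_id,
                "strand": g.strand, "chrom": g.cds_intervals[0][0],
                "intervals": ";".join(f"{s}-{e}" for _, s, e in g.cds_intervals),
                "is_krab": int(g.is_krab)})
            cf.write(f">{g.transcript_id}\n{g.cds_seq}\n")
            pf.write(f">{g.transcript_id}\n{g.protein_seq}\n")
    pd.DataFrame(rows).to_csv(table_path, sep="\t", index=False)


def mutations_to_table(records: Iterable[MutationRecord]) -> pd.DataFrame:
    """Flatten annotated mutation records for TSV export."""
    return pd.DataFrame([{
        "sample_id": m.sample_id, "gene_id": m.gene_id, "chrom": m.chrom,
        "genomic_pos": m.genomic_pos, "ref": m.ref_base, "alt": m.alt_base,
        "cds_pos": m.cds_pos, "protein_pos": m.protein_pos,
        "ref_aa": m.ref_aa, "alt_aa": m.alt_aa,
        "consequence": m.consequence, "context": m.context} for m in records])
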