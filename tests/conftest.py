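"""Shared fixtures: small synthetic cohorts and hand-built gene models."""
from __future__ import annotations

import numpy as np
import pytest

from zfhotspot.mapping import map_mutations, read_maf
from zfhotspot.models import GeneModel, MutationRecord
from zfhotspot.simulate import (CohortConfig, simulate_gene_models,
                                simulate_mutations)


def build_cohort(cfg: CohortConfig, tmp_path, map_records: bool = True):
    """Simulate a cohort, write/read its MAF, and map the mutations."""
    rng = np.random.default_rng(cfg.seed)
    models, planted = simulate_gene_models(cfg, rng)
    tmp_path.mkdir(parents=True, exist_ok=True)
    maf_path = tmp_path / f"{cfg.cohort_id}.maf"
    simulate_mutations(models, planted, cfg, rng, out_path=maf_path)
    records, skipped = read_maf(maf_path)
    mapped = map_mutations(records, models) if map_records else records
    samples = sorted({m.sample_id for m in mapped})
    return {"models": models, "planted": planted, "mutations": mapped,
            "samples": samples, "maf_path": maf_path, "skipped": skipped}


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    cfg = CohortConfig(seed=5, n_zf_genes=8, n_background_genes=30,
                       n_samples=30, burden_median=40)
    return build_cohort(cfg, tmp_path_factory.mktemp("cohort"))


def make_gene(gene_id: str, cds: str, strand: str = "+", chrom: str = "chr1",
              start: int = 101, intervals=None, is_krab: bool = False) -> GeneModel:
    """Single-exon (by default) gene model from a coding-strand CDS."""
    from Bio.Seq import Seq

    if intervals is None:
        intervals = [(chrom, start, start + len(cds) - 1)]
    protein = str(Seq(cds).translate())
    if protein.endswith("*"):
        protein = protein[:-1]
    model = GeneModel(gene_id=gene_id, transcript_id=f"{gene_id}.t1",
                      strand=strand, cds_intervals=intervals, cds_seq=cds,
                      protein_seq=protein, is_krab=is_krab)
    model.validate()
    return model


def make_mutation(sample="S1", gene="G1", chrom="chr1", gpos=0, ref="A",
                  alt="T", **kw) -> MutationRecord:
    return MutationRecord(sample_id=sample, gene_id=gene, chrom=chrom,
                          genomic_pos=gpos, ref_base=ref, alt_base=alt, **kw)
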