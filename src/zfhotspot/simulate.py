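"""Synthetic tumor-cohort generator.

Emulates the data the hotspot analysis consumes: ZF genes carrying tandem
arrays of pattern-valid 21-residue Cys2His2 domains (with KRAB flags and
focal codons realized in the hotspot-relevant trinucleotide contexts: AGA
arginine at label 9, pyrimidine-preceded CAC histidine at label 11),
background genes for exome-wide context rates, heavy-tailed per-sample
mutation burdens with an ultramutator fraction, trinucleotide-signature-
weighted substitution placement with injectable multiplicative fold
enrichment at chosen (label, channel) classes, a log-normal TPM matrix, and
a random interaction network with annotation sets.

All randomness flows through a numpy Generator; identical seeds give
identical outputs.  Genes live on one synthetic chromosome with alternating
strands so that reverse-complement code paths are exercised.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .domains import find_zf_domains
from .errors import ConfigError
from .mapping import cds_to_genomic, revcomp
from .models import GeneModel, ZFDomain, label_to_index
from .positional import (BASES, Channel, _BASE_CODE, _context_codes, _encode,
                         channel_tables)

# codon choices per amino acid used by the generator (no ambiguity, no stops)
_CODONS = {
    "A": ["GCA", "GCT", "GCG"], "C": ["TGC", "TGT"], "D": ["GAT", "GAC"],
    "E": ["GAA", "GAG"], "F": ["TTT", "TTC"], "G": ["GGA", "GGT", "GGC"],
    "H": ["CAC", "CAT"], "I": ["ATT", "ATC"], "K": ["AAA", "AAG"],
    "L": ["CTG", "TTA", "CTT"], "M": ["ATG"], "N": ["AAC", "AAT"],
    "P": ["CCA", "CCT", "CCG"], "Q": ["CAA", "CAG"], "R": ["CGC", "CGG", "AGA"],
    "S": ["AGC", "TCA", "TCT", "AGT", "TCG"], "T": ["ACT", "ACA", "ACG", "ACC"],
    "V": ["GTG", "GTT", "GTC"], "W": ["TGG"], "Y": ["TAT", "TAC"],
}

_CODON2AA = {c: aa for aa, cs in _CODONS.items() for c in cs}

#: residues allowed in the non-domain parts of ZF proteins.  Cysteine and
#: histidine are excluded so that no spurious domain pattern can start there
#: and planted domain coordinates are recovered exactly; glutamate, glutamine
#: and tryptophan are excluded (and glycine restricted to GGT/GGC below) so
#: that the high-weight signature channels (AGA G>T, dipyrimidine C>T and its
#: reverse complement) have no stop-gain outcomes inside ZF genes -- the
#: permutation null shuffles missense and silent mutations only, so
#: stop-gain-prone channel sites would deplete the null class.
_NTERM_ALPHABET = "ADFGIKLMNPRSTVY"

#: 21-residue domain scaffold (index 1..21); None marks the configurable
#: positions (19 = label 9, 20/21 = label 11 context).
_DOMAIN_CODONS = ["TGC", "CCT", "GAA", "TGT", "GGA", "AAA", "AGA", "TTT",
                  "TCG", "CAA", "TCA", "TCA", "CCA", "CTG", "CAG", "AGA",
                  "CAC", "AAA", None, None, "CAC"]


def pole_like_signature() -> dict:
    """POLE-exonuclease-like spectrum: AGA->ATA hugely elevated."""
    return {("AGA", "T"): 600.0}


def uv_like_signature() -> dict:
    """UV-like spectrum: C->T at dipyrimidines (CCN and TCN contexts)."""
    return {("CCN", "T"): 300.0, ("TCN", "T"): 300.0}


@dataclass
class CohortConfig:
    """Study conditions for one synthetic cohort."""

    seed: int = 0
    cohort_id: str = "SYNTH"
    n_zf_genes: int = 50
    domains_per_gene_mean: float = 8.0
    domains_per_gene_min: int = 2
    krab_probability: float = 0.5
    n_background_genes: int = 250
    background_codons_mean: float = 300.0
    background_codons_sigma: float = 0.35
    background_codons_min: int = 80
    nterm_codons: int = 200
    nterm_arg_aga: int = 40        # AGA-encoded arginines seeded in the N-term
    nterm_ser_tca: int = 48        # TCA-encoded serines (TCA-context reservoir)
    nterm_pro_cca: int = 48        # CCA-encoded prolines (CCA-context reservoir)
    linker: str = "TGEKP"
    p9_aga_prob: float = 0.15      # fraction of domains with AGA at label 9
    p11_pyr_prob: float = 0.5      # fraction with pyrimidine 5' of the p11 His
    n_samples: int = 100
    burden_median: float = 60.0
    burden_sigma: float = 1.0
    ultra_fraction: float = 0.05
    ultra_multiplier: float = 15.0
    signature: dict = field(default_factory=pole_like_signature)
    signature_base: float = 1.0
    positional_enrichment: list = field(default_factory=list)
    # (label, Channel, fold) triples
    tpm_log_mean: float = 2.3
    tpm_log_sigma: float = 1.5
    n_edges: int = 1200
    n_annotation_sets: int = 25
    annotation_set_size: int = 20
    annotation_bias: float = 0.0
    biased_genes: Optional[list] = None

    def validate(self) -> None:
        if any(w < 0 for w in self.signature.values()) or self.signature_base < 0:
            raise ConfigError("signature weights must be non-negative")
        if self.signature_base == 0 and not any(self.signature.values()):
            raise ConfigError("signature must have at least one positive weight")
        for label, channel, fold in self.positional_enrichment:
            if fold < 1:
                raise ConfigError("enrichment folds must be >= 1")
            label_to_index(label)
        for p in (self.krab_probability, self.p9_aga_prob, self.p11_pyr_prob,
                  self.ultra_fraction, self.annotation_bias):
            if not 0.0 <= p <= 1.0:
                raise ConfigError("probabilities must lie in [0,1]")


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------

#: codon restrictions applied inside ZF genes (see _NTERM_ALPHABET note)
_ZF_CODONS = dict(_CODONS, G=["GGT", "GGC"])


def _random_nterm(rng: np.random.Generator, cfg: "CohortConfig") -> list[str]:
    """Random low-complexity N-terminal region, seeded with AGA arginines and
    TCA/CCA serine-proline stretches so that each focal trinucleotide class
    has an ample non-domain site reservoir within every ZF gene."""
    n_codons = cfg.nterm_codons
    aas = rng.choice(list(_NTERM_ALPHABET), size=n_codons)
    codons = [_ZF_CODONS[a][rng.integers(len(_ZF_CODONS[a]))] for a in aas]
    n_seed = min(cfg.nterm_arg_aga + cfg.nterm_ser_tca + cfg.nterm_pro_cca,
                 n_codons)
    slots = rng.choice(n_codons, size=n_seed, replace=False)
    seeds = (["AGA"] * cfg.nterm_arg_aga + ["TCA"] * cfg.nterm_ser_tca
             + ["CCA"] * cfg.nterm_pro_cca)[:n_seed]
    for slot, codon in zip(slots, seeds):
        codons[slot] = codon
    return codons


def _domain_codons(rng: np.random.Generator, cfg: CohortConfig) -> list[str]:
    codons = list(_DOMAIN_CODONS)
    codons[18] = "AGA" if rng.random() < cfg.p9_aga_prob else "CGC"
    # the third base of codon 20 is the 5' flank of the p11 histidine codon;
    # a pyrimidine there (T or C, equal odds) places the p11 C->T channel in
    # a UV-type dipyrimidine context
    if rng.random() < cfg.p11_pyr_prob:
        codons[19] = "ACT" if rng.random() < 0.5 else "ACC"
    else:
        codons[19] = "ACG"
    return codons


def _random_background(rng: np.random.Generator, cfg: CohortConfig) -> list[str]:
    n = max(cfg.background_codons_min,
            int(rng.lognormal(np.log(cfg.background_codons_mean),
                              cfg.background_codons_sigma)))
    aas = rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=n)
    return [_CODONS[a][rng.integers(len(_CODONS[a]))] for a in aas]


def _split_exons(rng: np.random.Generator, length: int) -> list[int]:
    """Partition a CDS length into 1-3 exon widths."""
    n_exons = int(rng.integers(1, 4))
    if n_exons == 1 or length < 3 * n_exons:
        return [length]
    cuts = np.sort(rng.choice(np.arange(1, length), size=n_exons - 1, replace=False))
    bounds = [0, *cuts.tolist(), length]
    return [b - a for a, b in zip(bounds, bounds[1:])]


def simulate_gene_models(cfg: CohortConfig, rng: np.random.Generator
                         ) -> tuple[dict[str, GeneModel], dict[str, list[ZFDomain]]]:
    """Generate gene models plus the planted ZF domain coordinates."""
    cfg.validate()
    models: dict[str, GeneModel] = {}
    planted: dict[str, list[ZFDomain]] = {}
    cursor = 1000
    chrom = "chrS"
    gene_specs = []
    for i in range(cfg.n_zf_genes):
        gene_specs.append(("zf", f"ZFS{i + 1:03d}"))
    for i in range(cfg.n_background_genes):
        gene_specs.append(("bg", f"BGS{i + 1:03d}"))

    for g_num, (kind, gene_id) in enumerate(gene_specs):
        codons = [_CODONS["M"][0]]
        domains: list[ZFDomain] = []
        if kind == "zf":
            codons += _random_nterm(rng, cfg)
            n_dom = max(cfg.domains_per_gene_min,
                        int(rng.poisson(cfg.domains_per_gene_mean)))
            linker_codons = [_ZF_CODONS[a][0] for a in cfg.linker]
            for d in range(n_dom):
                if d > 0:
                    codons += linker_codons
                start = len(codons) + 1          # 1-based protein position
                codons += _domain_codons(rng, cfg)
                domains.append(ZFDomain(gene_id=gene_id, protein_start=start,
                                        protein_end=start + 20))
            is_krab = bool(rng.random() < cfg.krab_probability)
        else:
            codons += _random_background(rng, cfg)
            is_krab = False
        codons.append("TAA")
        cds = "".join(codons)
        protein = "".join(_CODON2AA[c] for c in codons[:-1])

        strand = "+" if g_num % 2 == 0 else "-"
        widths = _split_exons(rng, len(cds))
        intervals = []
        pos = cursor
        for w in widths:
            intervals.append((chrom, pos, pos + w - 1))
            pos += w + int(rng.integers(50, 200))   # intron gap
        cursor = pos + 500
        model = GeneModel(gene_id=gene_id, transcript_id=f"{gene_id}.t1",
                          strand=strand, cds_intervals=intervals, cds_seq=cds,
                          protein_seq=protein, is_krab=is_krab)
        model.validate()
        models[gene_id] = model
        if domains:
            planted[gene_id] = domains
            found = find_zf_domains(protein, gene_id=gene_id)
            starts = {d.protein_start for d in found}
            assert all(d.protein_start in starts for d in domains), \
                "planted domain not recoverable by the pattern scanner"
    return models, planted


# ---------------------------------------------------------------------------
# Mutations
# ---------------------------------------------------------------------------

def _signature_weight_tables(cfg: CohortConfig) -> np.ndarray:
    """(64, 4) weight table over (context code, alt code), strand-collapsed."""
    w = np.full((64, 4), cfg.signature_base, dtype=float)
    for (ctx_pat, alt), weight in cfg.signature.items():
        _, pair = channel_tables([Channel(ctx_pat, alt)])
        w[pair] = weight
    # a base can never "mutate" to itself: zero the self channel
    for code in range(64):
        mid = (code // 4) % 4
        w[code, mid] = 0.0
    return w


@dataclass
class _SiteTable:
    """Flattened (site, alt) sampling table across the synthetic exome."""

    gene_ids: list[str]
    gene_idx: np.ndarray      # (M,)
    cds_pos0: np.ndarray      # (M,) 0-based coding position
    alt_code: np.ndarray      # (M,)
    weight: np.ndarray        # (M,)


def _build_site_table(models: dict[str, GeneModel],
                      planted: dict[str, list[ZFDomain]],
                      cfg: CohortConfig) -> _SiteTable:
    wtab = _signature_weight_tables(cfg)
    gene_ids = sorted(models)
    g_idx_l, pos_l, alt_l, w_l = [], [], [], []
    for gi, g in enumerate(gene_ids):
        codes = _encode(models[g].cds_seq)
        ctx = _context_codes(codes)
        valid = np.nonzero(ctx >= 0)[0]
        w = wtab[ctx[valid].astype(int)]            # (V, 4)
        site_pos = np.repeat(valid, 4)
        alts = np.tile(np.arange(4), valid.size)
        weights = w.ravel()
        keep = weights > 0
        g_idx_l.append(np.full(keep.sum(), gi))
        pos_l.append(site_pos[keep])
        alt_l.append(alts[keep])
        w_l.append(weights[keep])
    table = _SiteTable(gene_ids=gene_ids,
                       gene_idx=np.concatenate(g_idx_l),
                       cds_pos0=np.concatenate(pos_l),
                       alt_code=np.concatenate(alt_l),
                       weight=np.concatenate(w_l))

    # multiplicative fold enrichment at configured (label, channel) classes
    for label, channel, fold in cfg.positional_enrichment:
        idx_in_domain = label_to_index(label)
        ctx_ok, pair_ok = channel_tables([channel])
        focal_mask = np.zeros(table.weight.size, dtype=bool)
        for gi, g in enumerate(table.gene_ids):
            doms = planted.get(g)
            if not doms:
                continue
            codes = _encode(models[g].cds_seq)
            ctx = _context_codes(codes)
            focal_pos = set()
            for d in doms:
                ppos = d.protein_start + idx_in_domain - 1
                for within in range(3):
                    focal_pos.add((ppos - 1) * 3 + within)
            rows = np.nonzero(table.gene_idx == gi)[0]
            in_focal = np.isin(table.cds_pos0[rows], np.array(sorted(focal_pos)))
            row_ctx = ctx[table.cds_pos0[rows]].astype(int)
            in_channel = pair_ok[row_ctx, table.alt_code[rows]]
            focal_mask[rows] = in_focal & in_channel
        if not focal_mask.any():
            raise ConfigError(
                f"no sites realize channel {channel} at label {label}; "
                "infeasible enrichment request")
        table.weight = table.weight.copy()
        table.weight[focal_mask] *= fold
    return table


def simulate_mutations(models: dict[str, GeneModel],
                       planted: dict[str, list[ZFDomain]],
                       cfg: CohortConfig, rng: np.random.Generator,
                       out_path=None) -> pd.DataFrame:
    """Draw per-sample burdens and place signature-weighted substitutions.

    Returns a MAF-like DataFrame (and writes it as TSV when ``out_path`` is
    given).  Ref alleles and positions are genomic (plus-strand), so the
    table round-trips through the MAF reader and coordinate mapper.
    """
    cfg.validate()
    table = _build_site_table(models, planted, cfg)
    cum = np.cumsum(table.weight)
    total_w = cum[-1]
    if total_w <= 0:
        raise ConfigError("all site weights are zero")

    n = cfg.n_samples
    burdens = rng.lognormal(np.log(cfg.burden_median), cfg.burden_sigma, size=n)
    ultra = rng.random(n) < cfg.ultra_fraction
    burdens[ultra] *= cfg.ultra_multiplier
    counts = np.maximum(1, rng.poisson(burdens))

    rows = []
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    for si in range(n):
        sample = f"{cfg.cohort_id}-S{si + 1:04d}"
        draws = np.searchsorted(cum, rng.random(counts[si]) * total_w, side="right")
        for d in draws:
            g = models[table.gene_ids[table.gene_idx[d]]]
            cds_pos = int(table.cds_pos0[d]) + 1
            ref_c = g.cds_seq[cds_pos - 1]
            alt_c = BASES[table.alt_code[d]]
            chrom, gpos = cds_to_genomic(g, cds_pos)
            if g.strand == "-":
                ref_g, alt_g = comp[ref_c], comp[alt_c]
            else:
                ref_g, alt_g = ref_c, alt_c
            rows.append((g.gene_id, chrom, gpos, ref_g, alt_g, sample, "SNP"))
    maf = pd.DataFrame(rows, columns=["Hugo_Symbol", "Chromosome", "Start_Position",
                                      "Reference_Allele", "Tumor_Seq_Allele2",
                                      "Tumor_Sample_Barcode", "Variant_Type"])
    if out_path is not None:
        maf.to_csv(out_path, sep="\t", index=False)
    return maf


def sample_ids(cfg: CohortConfig) -> list[str]:
    return [f"{cfg.cohort_id}-S{i + 1:04d}" for i in range(cfg.n_samples)]


# ---------------------------------------------------------------------------
# Expression, network, annotations
# ---------------------------------------------------------------------------

def simulate_expression(models: dict[str, GeneModel], cfg: CohortConfig,
                        rng: np.random.Generator) -> pd.DataFrame:
    """Log-normal per-gene TPM matrix, columns renormalized to 1e6."""
    genes = sorted(models)
    samples = sample_ids(cfg)
    gene_mu = rng.normal(cfg.tpm_log_mean, 1.0, size=len(genes))
    tpm = rng.lognormal(gene_mu[:, None], cfg.tpm_log_sigma,
                        size=(len(genes), len(samples)))
    tpm *= 1e6 / tpm.sum(axis=0, keepdims=True)
    return pd.DataFrame(tpm, index=genes, columns=samples)


def simulate_network_annotations(models: dict[str, GeneModel], cfg: CohortConfig,
                                 rng: np.random.Generator):
    """Fixed-edge-count random network plus (optionally biased) GMT sets.

    Returns (edge list of (u, v) pairs, list of AnnotationSet).  With
    ``annotation_bias`` b > 0, each member of an annotation set is drawn from
    ``biased_genes`` with probability b, uniformly otherwise.
    """
    from .enrichment import AnnotationSet

    genes = sorted(models)
    n = len(genes)
    max_edges = n * (n - 1) // 2
    m = min(cfg.n_edges, max_edges)
    chosen: set[tuple[int, int]] = set()
    while len(chosen) < m:
        need = m - len(chosen)
        a = rng.integers(0, n, size=2 * need + 8)
        b = rng.integers(0, n, size=2 * need + 8)
        for x, y in zip(a, b):
            if x == y:
                continue
            pair = (min(x, y), max(x, y))
            chosen.add(pair)
            if len(chosen) == m:
                break
    edges = sorted((genes[i], genes[j]) for i, j in chosen)

    biased = list(cfg.biased_genes or [])
    sets = []
    for s in range(cfg.n_annotation_sets):
        members: set[str] = set()
        while len(members) < min(cfg.annotation_set_size, n):
            if biased and rng.random() < cfg.annotation_bias:
                members.add(biased[rng.integers(len(biased))])
            else:
                members.add(genes[rng.integers(n)])
        sets.append(AnnotationSet(f"SET{s + 1:03d}", f"synthetic term {s + 1}",
                                  members))
    return edges, sets
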