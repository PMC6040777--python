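"""Positional significance machinery for zinc-finger domain hotspots.

Three tests are implemented:

* a trinucleotide-context-preserving permutation of all point mutations
  (missense and silent together) within each ZF gene's coding sequence,
  recomputing per-label missense counts after every shuffle and comparing the
  observed count at each of the 21 domain labels to the permutation null;

* a site-restricted permutation that reassigns the focal-label mutations
  across all context-matching focal codons of the ZF gene set, used to test
  gene concentration (lower tail) and the KRAB-gene fraction (upper tail);

* a Poisson-binomial test of the number of focal-site mutations in specific
  trinucleotide channels (e.g. AGA->ATA, YC->YT) against per-sample rates of
  those channels across the whole exome.

The shuffle moves each mutation independently and uniformly among all CDS
positions of its gene with the same coding-strand reference trinucleotide
(the original site included); the alternate base travels with the mutation
and its consequence is re-derived at the destination, so per-label missense
counts can change while the per-gene multiset of (context, ref, alt) is
conserved exactly.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .errors import InputError
from .mapping import revcomp, translate_codon
from .models import (LABELS, MISSENSE, SYNONYMOUS, ContextRateTest, GeneModel,
                     MutationRecord, PermutationResult, ZFDomain, label_to_index)
from .poibin import poisson_binomial_tail

log = logging.getLogger(__name__)

BASES = "ACGT"
_BASE_CODE = {b: i for i, b in enumerate(BASES)}

#: amino-acid (or '*') for each codon code 16*a + 4*b + c
_AA64 = np.array([translate_codon(a + b + c) for a in BASES for b in BASES for c in BASES])


_ENCODE_LUT = np.full(128, -1, dtype=np.int8)
for _b, _i in _BASE_CODE.items():
    _ENCODE_LUT[ord(_b)] = _i


def _encode(seq: str) -> np.ndarray:
    codes = _ENCODE_LUT[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if (codes < 0).any():
        raise InputError("sequence contains non-ACGT characters")
    return codes


def _context_codes(codes: np.ndarray) -> np.ndarray:
    """Per-position trinucleotide context code (-1 at the two ends)."""
    n = codes.size
    ctx = np.full(n, -1, dtype=np.int16)
    if n >= 3:
        ctx[1:-1] = 16 * codes[:-2].astype(np.int16) + 4 * codes[1:-1] + codes[2:]
    return ctx


def context_code(context: str) -> int:
    if len(context) != 3 or any(b not in _BASE_CODE for b in context):
        raise InputError(f"invalid trinucleotide context {context!r}")
    return 16 * _BASE_CODE[context[0]] + 4 * _BASE_CODE[context[1]] + _BASE_CODE[context[2]]


def eligible_positions(cds: str, context: str) -> list[int]:
    """1-based CDS positions whose coding-strand trinucleotide equals context."""
    codes = _encode(cds)
    ctx = _context_codes(codes)
    return [int(i) + 1 for i in np.nonzero(ctx == context_code(context))[0]]


# ---------------------------------------------------------------------------
# Per-gene index used by the vectorised permutation engine
# ---------------------------------------------------------------------------

@dataclass
class GeneIndex:
    """Precomputed lookup tables for one ZF gene."""

    gene_id: str
    is_krab: bool
    codes: np.ndarray                 # int8 (L,) base codes of the CDS
    ctx: np.ndarray                   # int16 (L,) context codes, -1 at ends
    sites_by_ctx: dict[int, np.ndarray] = field(default_factory=dict)
    consequence_label: np.ndarray = None   # int8 (L, 4): 0..20 label idx if
    # the substitution pos->alt is missense at a labeled domain position,
    # -2 if missense elsewhere (or nonsense/other), -1 if synonymous/self
    missense: np.ndarray = None       # bool (L, 4)


MISSENSE_UNLABELED = -2


def build_gene_index(gene: GeneModel, domains: Sequence[ZFDomain]) -> GeneIndex:
    """Build the site/context/consequence lookups for one gene."""
    codes = _encode(gene.cds_seq)
    L = codes.size
    ctx = _context_codes(codes)
    sites_by_ctx = {int(c): np.nonzero(ctx == c)[0]
                    for c in np.unique(ctx) if c >= 0}

    n_codons = L // 3
    cod = codes[:n_codons * 3].reshape(n_codons, 3).astype(np.int32)
    codon_code = 16 * cod[:, 0] + 4 * cod[:, 1] + cod[:, 2]
    ref_aa = _AA64[codon_code]

    # label index (0..20) for each protein position covered by a domain
    prot_label = np.full(n_codons, -1, dtype=np.int16)
    for d in domains:
        for idx in range(21):
            ppos = d.protein_start + idx       # 1-based
            if ppos <= n_codons:
                prot_label[ppos - 1] = idx

    lab = np.full((L, 4), -1, dtype=np.int8)
    miss = np.zeros((L, 4), dtype=bool)
    place = np.array([16, 4, 1], dtype=np.int32)
    for within in range(3):
        pos = np.arange(n_codons) * 3 + within
        ref_b = cod[:, within]
        for alt in range(4):
            alt_code = codon_code + (alt - ref_b) * place[within]
            alt_aa = _AA64[alt_code]
            is_self = alt == ref_b
            is_missense = (~is_self) & (ref_aa != "*") & (alt_aa != "*") & (ref_aa != alt_aa)
            miss[pos, alt] = is_missense
            labcol = np.where(is_missense,
                              np.where(prot_label >= 0, prot_label, MISSENSE_UNLABELED),
                              -1).astype(np.int8)
            lab[pos, alt] = labcol
    return GeneIndex(gene_id=gene.gene_id, is_krab=gene.is_krab, codes=codes,
                     ctx=ctx, sites_by_ctx=sites_by_ctx,
                     consequence_label=lab, missense=miss)


def _coding_alt(gene: GeneModel, rec: MutationRecord) -> str:
    return revcomp(rec.alt_base) if gene.strand == "-" else rec.alt_base


# ---------------------------------------------------------------------------
# Stand-alone shuffle (single gene)
# ---------------------------------------------------------------------------

def trinucleotide_shuffle(gene_mutations: Sequence[MutationRecord], cds: str,
                          rng: np.random.Generator) -> list[int]:
    """Reassign each mutation to a uniformly drawn same-context CDS position.

    ``cds`` is the coding-strand sequence in which positions are interpreted
    (flanking bases may be included by the caller; positions are 1-based into
    the given string).  Mutations without a context are held fixed and
    logged.  Returns the new 1-based positions, aligned with the input order.
    """
    codes = _encode(cds)
    ctx = _context_codes(codes)
    sites_by_ctx: dict[int, np.ndarray] = {}
    new_positions: list[int] = []
    n_fixed = 0
    for m in gene_mutations:
        if m.context is None or m.cds_pos is None:
            n_fixed += 1
            new_positions.append(m.cds_pos)
            continue
        code = context_code(m.context)
        if code not in sites_by_ctx:
            sites_by_ctx[code] = np.nonzero(ctx == code)[0]
        sites = sites_by_ctx[code]
        assert sites.size > 0, "original site must qualify for its own context"
        new_positions.append(int(sites[rng.integers(sites.size)]) + 1)
    if n_fixed:
        log.info("%d mutations without context held fixed in shuffle", n_fixed)
    return new_positions


# ---------------------------------------------------------------------------
# Per-label permutation test across the ZF gene set
# ---------------------------------------------------------------------------

def _collect_shuffleable(mutations: Iterable[MutationRecord],
                         gene_models: dict[str, GeneModel],
                         domains: dict[str, list[ZFDomain]]):
    """Split annotated ZF-gene point mutations (missense + silent) into
    shuffleable (context known) and fixed groups."""
    shuffleable, fixed = [], []
    for m in mutations:
        if m.gene_id not in domains or m.cds_pos is None:
            continue
        if m.consequence not in (MISSENSE, SYNONYMOUS):
            continue
        (shuffleable if m.context is not None else fixed).append(m)
    return shuffleable, fixed


def observed_label_counts(mutations: Iterable[MutationRecord],
                          gene_models: dict[str, GeneModel],
                          domains: dict[str, list[ZFDomain]]) -> np.ndarray:
    """Observed missense count at each of the 21 labels (index order 1..21)."""
    counts = np.zeros(21, dtype=int)
    for m in mutations:
        if (m.gene_id in domains and m.consequence == MISSENSE
                and m.protein_pos is not None):
            for d in domains[m.gene_id]:
                if d.protein_start <= m.protein_pos <= d.protein_end:
                    counts[m.protein_pos - d.protein_start] += 1
                    break
    return counts


def position_permutation_test(
        mutations: Iterable[MutationRecord],
        gene_models: dict[str, GeneModel],
        domains: dict[str, list[ZFDomain]],
        n_permutations: int = 10_000,
        seed: Optional[int] = None,
        rng: Optional[np.random.Generator] = None,
        max_draws_per_chunk: int = 20_000_000) -> dict[int, PermutationResult]:
    """Context-preserving permutation test of per-label missense counts.

    For each of the 21 domain labels the observed statistic is the total
    missense count at that label across all ZF genes; the null is obtained by
    shuffling every gene's point mutations within same-context sites and
    recounting.  Empirical p is the upper-tail fraction of permutations with
    a null count >= the observed count.

    Returns a dict mapping display label (-10..-1, 1..11) to a
    :class:`PermutationResult`.
    """
    if n_permutations < 1:
        raise InputError("n_permutations must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    mutations = list(mutations)
    observed = observed_label_counts(mutations, gene_models, domains)
    shuffleable, fixed_muts = _collect_shuffleable(mutations, gene_models, domains)

    indexes = {g: build_gene_index(gene_models[g], domains[g])
               for g in sorted(domains)}

    # fixed (no-context) mutations contribute a constant to every permutation
    fixed_counts = observed_label_counts(fixed_muts, gene_models, domains)

    null = np.tile(fixed_counts.astype(np.int64), (n_permutations, 1))

    if not shuffleable and not fixed_muts:
        null = np.zeros((n_permutations, 21), dtype=np.int64)

    # group shuffleable mutations by (gene, context)
    groups: dict[tuple[str, int], list[MutationRecord]] = {}
    for m in shuffleable:
        groups.setdefault((m.gene_id, context_code(m.context)), []).append(m)

    n_muts = len(shuffleable)
    chunk = max(1, min(n_permutations,
                       max_draws_per_chunk // max(1, n_muts)))
    for start in range(0, n_permutations, chunk):
        stop = min(start + chunk, n_permutations)
        P = stop - start
        for (gene_id, code) in sorted(groups):
            gi = indexes[gene_id]
            group = groups[(gene_id, code)]
            sites = gi.sites_by_ctx.get(code)
            assert sites is not None and sites.size > 0
            alts = np.array([_BASE_CODE[_coding_alt(gene_models[gene_id], m)]
                             for m in group])
            draws = rng.integers(0, sites.size, size=(P, len(group)))
            pos = sites[draws]
            labs = gi.consequence_label[pos, alts[None, :]]
            valid = labs >= 0
            if not valid.any():
                continue
            perm_idx = np.broadcast_to(np.arange(P)[:, None], labs.shape)[valid]
            flat = perm_idx * 21 + labs[valid]
            null[start:stop] += np.bincount(flat, minlength=P * 21).reshape(P, 21)

    results: dict[int, PermutationResult] = {}
    for idx in range(21):
        label = LABELS[idx]
        results[label] = PermutationResult(
            statistic_name=f"missense_at_label_{label}",
            observed=float(observed[idx]),
            null_values=null[:, idx].astype(float),
            n_permutations=n_permutations, tail="upper")
    return results


# ---------------------------------------------------------------------------
# Site-restricted permutation over focal-label codons
# ---------------------------------------------------------------------------

@dataclass
class FocalSites:
    """All CDS base positions inside focal-label codons across the ZF genes."""

    label: int
    gene_ids: list[str]                # index -> gene id
    gene_idx: np.ndarray               # int (S,)
    cds_pos: np.ndarray                # int (S,) 0-based
    ctx: np.ndarray                    # int16 (S,)
    krab: np.ndarray                   # bool per gene index
    missense: np.ndarray               # bool (S, 4)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)


def focal_codon_sites(gene_models: dict[str, GeneModel],
                      domains: dict[str, list[ZFDomain]], label: int,
                      indexes: Optional[dict[str, GeneIndex]] = None) -> FocalSites:
    """Enumerate every base of every focal-label codon, with contexts."""
    idx_in_domain = label_to_index(label)          # 1..21
    gene_ids = sorted(domains)
    krab = np.array([gene_models[g].is_krab for g in gene_ids])
    g_idx, positions, ctxs, miss_rows = [], [], [], []
    for gi_num, g in enumerate(gene_ids):
        gi = (indexes or {}).get(g) or build_gene_index(gene_models[g], domains[g])
        for d in domains[g]:
            ppos = d.protein_start + idx_in_domain - 1       # 1-based protein pos
            for within in range(3):
                p0 = (ppos - 1) * 3 + within                  # 0-based cds pos
                if p0 >= gi.codes.size:
                    continue
                g_idx.append(gi_num)
                positions.append(p0)
                ctxs.append(gi.ctx[p0])
                miss_rows.append(gi.missense[p0])
    return FocalSites(label=label, gene_ids=gene_ids,
                      gene_idx=np.array(g_idx, dtype=int),
                      cds_pos=np.array(positions, dtype=int),
                      ctx=np.array(ctxs, dtype=np.int16),
                      krab=krab,
                      missense=np.array(miss_rows, dtype=bool))


def site_restricted_permutation(
        focal_mutations: Sequence[MutationRecord],
        sites: FocalSites,
        gene_models: dict[str, GeneModel],
        statistics: Sequence[str] = ("n_distinct_genes", "krab_fraction"),
        n_permutations: int = 10_000,
        seed: Optional[int] = None,
        rng: Optional[np.random.Generator] = None) -> dict[str, PermutationResult]:
    """Randomize focal-label mutations across all context-matching focal codons.

    Each mutation moves independently and uniformly among focal-codon sites
    (gene-set-wide, not gene-restricted) whose coding-strand trinucleotide
    matches its own; missense status is re-evaluated at the destination.  The
    number of distinct mutated genes is tested on the lower tail ("fewer genes
    than expected" = concentration), the KRAB-gene fraction of missense
    mutations on the upper tail.
    """
    known = {"n_distinct_genes", "krab_fraction"}
    unknown = set(statistics) - known
    if unknown:
        raise InputError(f"unknown statistics {sorted(unknown)}")
    if rng is None:
        rng = np.random.default_rng(seed)

    muts = list(focal_mutations)
    gene_pos = {g: i for i, g in enumerate(sites.gene_ids)}

    # observed statistics from the actual placements
    obs_missense = [m for m in muts if m.consequence == MISSENSE]
    obs_genes = len({m.gene_id for m in obs_missense})
    obs_krab = (sum(gene_models[m.gene_id].is_krab for m in obs_missense)
                / len(obs_missense)) if obs_missense else 0.0

    # eligible site groups by context
    sites_by_ctx = {int(c): np.nonzero(sites.ctx == c)[0]
                    for c in np.unique(sites.ctx) if c >= 0}
    alts = []
    codes = []
    for m in muts:
        if m.context is None:
            raise InputError("focal mutation without trinucleotide context")
        code = context_code(m.context)
        if code not in sites_by_ctx:
            raise InputError(
                f"context {m.context} absent from eligible focal codons")
        codes.append(code)
        alts.append(_BASE_CODE[_coding_alt(gene_models[m.gene_id], m)])
    codes = np.array(codes, dtype=int)
    alts = np.array(alts, dtype=int)

    n = len(muts)
    G = sites.n_genes
    site_choice = np.empty((n_permutations, n), dtype=int)
    for code in sorted(set(codes.tolist())):
        cols = np.nonzero(codes == code)[0]
        pool = sites_by_ctx[code]
        site_choice[:, cols] = pool[rng.integers(0, pool.size,
                                                 size=(n_permutations, cols.size))]
    dest_missense = sites.missense[site_choice, alts[None, :]]
    dest_gene = sites.gene_idx[site_choice]

    results: dict[str, PermutationResult] = {}
    if "n_distinct_genes" in statistics:
        perm_idx = np.broadcast_to(np.arange(n_permutations)[:, None],
                                   dest_gene.shape)[dest_missense]
        flat = perm_idx * G + dest_gene[dest_missense]
        hits = np.bincount(flat, minlength=n_permutations * G).reshape(n_permutations, G)
        null_genes = (hits > 0).sum(axis=1).astype(float)
        results["n_distinct_genes"] = PermutationResult(
            statistic_name="n_distinct_genes", observed=float(obs_genes),
            null_values=null_genes, n_permutations=n_permutations, tail="lower")
    if "krab_fraction" in statistics:
        n_miss = dest_missense.sum(axis=1)
        n_krab = (dest_missense & sites.krab[dest_gene]).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(n_miss > 0, n_krab / np.maximum(n_miss, 1), 0.0)
        results["krab_fraction"] = PermutationResult(
            statistic_name="krab_fraction", observed=float(obs_krab),
            null_values=frac.astype(float), n_permutations=n_permutations,
            tail="upper")
    return results


# ---------------------------------------------------------------------------
# Context channels and the Poisson binomial context-rate test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Channel:
    """A substitution channel: reference trinucleotide (N = any base) with the
    middle base substituted to ``alt``."""

    context: str
    alt: str

    def __post_init__(self):
        if len(self.context) != 3 or any(b not in "ACGTN" for b in self.context):
            raise InputError(f"invalid channel context {self.context!r}")
        if self.alt not in "ACGT":
            raise InputError(f"invalid channel alt {self.alt!r}")


def _expand_channel(ch: Channel) -> set[tuple[int, int]]:
    """Concrete (context code, alt code) pairs for a channel, both strands."""
    pairs: set[tuple[int, int]] = set()
    options = [("ACGT" if b == "N" else b) for b in ch.context]
    for a in options[0]:
        for b in options[1]:
            for c in options[2]:
                ctx = a + b + c
                pairs.add((context_code(ctx), _BASE_CODE[ch.alt]))
                pairs.add((context_code(revcomp(ctx)),
                           _BASE_CODE[revcomp(ch.alt)]))
    return pairs


def channel_tables(channels: Sequence[Channel]) -> tuple[np.ndarray, np.ndarray]:
    """Boolean lookup tables: eligible contexts (64,) and qualifying
    (context, alt) pairs (64, 4), strand-collapsed."""
    ctx_ok = np.zeros(64, dtype=bool)
    pair_ok = np.zeros((64, 4), dtype=bool)
    for ch in channels:
        for code, alt in _expand_channel(ch):
            ctx_ok[code] = True
            pair_ok[code, alt] = True
    return ctx_ok, pair_ok


def count_eligible_sites(gene_models: dict[str, GeneModel],
                         channels: Sequence[Channel]) -> int:
    """Number of exome CDS positions whose context matches any channel on
    either strand (each site counted once)."""
    ctx_ok, _ = channel_tables(channels)
    total = 0
    for g in gene_models.values():
        ctx = _context_codes(_encode(g.cds_seq))
        valid = ctx[ctx >= 0]
        total += int(ctx_ok[valid].sum())
    return total


def compute_context_rates(mutations: Iterable[MutationRecord],
                          gene_models: dict[str, GeneModel],
                          channels: Sequence[Channel],
                          samples: Sequence[str]) -> tuple[dict[str, float], int]:
    """Per-sample exome-wide rates for the given substitution channels.

    rate(sample) = (# of the sample's coding mutations whose (context, alt)
    matches a channel on either strand) / (# eligible exome sites).  All
    cohort samples appear in the result, with rate 0 when unmutated.
    Returns (rates, n_eligible_sites).
    """
    n_eligible = count_eligible_sites(gene_models, channels)
    if n_eligible == 0:
        raise InputError("no exome sites eligible for the requested channels")
    _, pair_ok = channel_tables(channels)
    counts = {s: 0 for s in samples}
    for m in mutations:
        if m.context is None or m.cds_pos is None:
            continue
        code = context_code(m.context)
        gene = gene_models.get(m.gene_id)
        alt = _coding_alt(gene, m) if gene is not None else m.alt_base
        if pair_ok[code, _BASE_CODE[alt]] and m.sample_id in counts:
            counts[m.sample_id] += 1
    return {s: c / n_eligible for s, c in counts.items()}, n_eligible


def context_rate_test(n_sites: int, per_sample_rates: dict[str, float],
                      observed: int, channels: Sequence[Channel] = ()) -> ContextRateTest:
    """Poisson-binomial upper-tail test of the focal-site mutation count.

    The trial vector replicates each sample's exome channel rate once per
    focal site (trials = n_sites x n_samples); the p-value is
    P(X >= observed) under the Poisson binomial with those probabilities.
    """
    if n_sites < 1:
        raise InputError("n_sites must be >= 1")
    if observed < 0:
        raise InputError("observed must be >= 0")
    rates = np.array(list(per_sample_rates.values()), dtype=float)
    n_trials = n_sites * rates.size
    if observed > n_trials:
        raise InputError(f"observed {observed} exceeds {n_trials} trials")
    trials = np.repeat(rates, n_sites)
    p = poisson_binomial_tail(trials, observed)
    return ContextRateTest(contexts=tuple(channels), n_sites=n_sites,
                           per_sample_rates=dict(per_sample_rates),
                           observed=observed, p_value=p)


def count_focal_channel_sites(sites: FocalSites, channels: Sequence[Channel]) -> int:
    """Focal-codon positions whose context matches a channel (either strand)."""
    ctx_ok, _ = channel_tables(channels)
    valid = sites.ctx[sites.ctx >= 0]
    return int(ctx_ok[valid.astype(int)].sum())


def count_focal_channel_mutations(focal_mutations: Sequence[MutationRecord],
                                  gene_models: dict[str, GeneModel],
                                  channels: Sequence[Channel]) -> int:
    """Focal-label mutations whose (context, alt) matches a channel."""
    _, pair_ok = channel_tables(channels)
    n = 0
    for m in focal_mutations:
        if m.context is None:
            continue
        gene = gene_models.get(m.gene_id)
        alt = _coding_alt(gene, m) if gene is not None else m.alt_base
        if pair_ok[context_code(m.context), _BASE_CODE[alt]]:
            n += 1
    return n
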