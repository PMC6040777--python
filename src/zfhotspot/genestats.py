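"""Gene-level mutation statistics.

Covers fractional nonsynonymous/synonymous site counting (Nei-Gojobori-style:
every position contributes the fraction of its three possible substitutions
that change the amino acid, stop gains counted as nonsynonymous), normalized
missense/synonymous rate ratios, per-base missense rates, rank tests between
gene sets, expression IQR membership, and multi-cohort overlap groups.
"""
from __future__ import annotations

from itertools import combinations
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError
from .mapping import translate_codon
from .models import MISSENSE, GeneRates, MutationRecord


def count_ns_s_sites(cds_seq: str, stop_gain_nonsyn: bool = True) -> tuple[float, float]:
    """Fractional nonsynonymous and synonymous site counts for a CDS.

    Per position the nonsynonymous fraction is (number of the 3 possible
    substitutions changing the encoded amino acid) / 3; with
    ``stop_gain_nonsyn`` (default) a substitution creating a stop codon
    counts as nonsynonymous.  The two totals sum to the CDS length.  A
    terminal stop codon is permitted (stop-retaining substitutions count as
    synonymous there); an internal stop raises InputError.
    """
    if len(cds_seq) % 3:
        raise InputError("CDS length not divisible by 3")
    n_codons = len(cds_seq) // 3
    ns = 0.0
    for ci in range(n_codons):
        codon = cds_seq[ci * 3:ci * 3 + 3]
        ref_aa = translate_codon(codon)
        if ref_aa == "*" and ci < n_codons - 1:
            raise InputError(f"internal stop codon at codon index {ci + 1}")
        for within in range(3):
            changed = 0
            for alt in "ACGT":
                if alt == codon[within]:
                    continue
                alt_aa = translate_codon(codon[:within] + alt + codon[within + 1:])
                if alt_aa != ref_aa and (stop_gain_nonsyn or alt_aa != "*"):
                    changed += 1
            ns += changed / 3.0
    return ns, len(cds_seq) - ns


def normalized_rate_ratio(gene: GeneRates) -> Optional[float]:
    """(missense/ns sites) / (synonymous/s sites); None when undefined."""
    return gene.normalized_ratio


def compare_gene_sets(values_a: Sequence[float], values_b: Sequence[float],
                      alternative: str = "greater") -> float:
    """Mann-Whitney U rank test between two gene-level value sets.

    Undefined (None/NaN) values are dropped first.  Exact enumeration is used
    for small tie-free samples, the tie-corrected normal approximation
    otherwise (scipy's automatic policy).
    """
    if alternative not in ("greater", "less", "two-sided"):
        raise InputError(f"unknown alternative {alternative!r}")
    a = np.array([v for v in values_a if v is not None and np.isfinite(v)])
    b = np.array([v for v in values_b if v is not None and np.isfinite(v)])
    if a.size == 0 or b.size == 0:
        raise InputError("both gene sets must be non-empty after dropping undefined values")
    return float(stats.mannwhitneyu(a, b, alternative=alternative, method="auto").pvalue)


def missense_rate_per_base(missense_count: int, focal_missense_count: int,
                           cds_length: int, n_samples: int,
                           exclude_focal: bool = True) -> float:
    """Per-base missense rate averaged over all cohort samples.

    (missense count, optionally minus focal-label missense) divided by
    (CDS length x number of samples).
    """
    if n_samples < 1:
        raise InputError("cohort must contain at least one sample")
    count = missense_count - (focal_missense_count if exclude_focal else 0)
    return count / (cds_length * n_samples)


def gene_rates_from_mutations(mutations: Iterable[MutationRecord],
                              cds_seqs: dict[str, str],
                              n_samples: int,
                              focal_positions: Optional[dict[str, set[int]]] = None,
                              exclude_focal: bool = True) -> dict[str, GeneRates]:
    """Tally per-gene missense/synonymous counts and site totals.

    ``focal_positions`` maps gene id to the set of protein positions whose
    missense mutations are excluded from the per-base rate (the focal domain
    labels); nonsense mutations never count as missense.
    """
    counts: dict[str, list[int]] = {g: [0, 0, 0] for g in cds_seqs}  # mis, syn, focal mis
    for m in mutations:
        if m.gene_id not in counts or m.cds_pos is None:
            continue
        if m.consequence == MISSENSE:
            counts[m.gene_id][0] += 1
            focal = (focal_positions or {}).get(m.gene_id, set())
            if m.protein_pos in focal:
                counts[m.gene_id][2] += 1
        elif m.consequence == "synonymous":
            counts[m.gene_id][1] += 1
    rates = {}
    for g, (mis, syn, focal_mis) in counts.items():
        ns, s = count_ns_s_sites(cds_seqs[g])
        rates[g] = GeneRates(
            gene_id=g, ns_sites=ns, s_sites=s, missense_count=mis,
            synonymous_count=syn,
            missense_rate_per_base=missense_rate_per_base(
                mis, focal_mis, len(cds_seqs[g]), n_samples, exclude_focal))
    return rates


def expression_iqr_fraction(tpm: pd.DataFrame,
                            mutated_pairs: Iterable[tuple[str, str]]) -> Optional[float]:
    """Fraction of mutated (gene, sample) expression values inside the gene's IQR.

    Quartiles are computed per gene over all cohort samples with the
    linear-interpolation convention (numpy default, R type 7); the interval
    [Q1, Q3] is closed.  Pairs whose gene is missing from the matrix are
    skipped with a warning and excluded from the denominator; with no usable
    pairs the fraction is undefined (None).
    """
    import logging
    log = logging.getLogger(__name__)
    inside = total = 0
    q = {}
    for gene, sample in mutated_pairs:
        if gene not in tpm.index:
            log.warning("gene %s absent from TPM matrix; pair skipped", gene)
            continue
        if gene not in q:
            vals = tpm.loc[gene].to_numpy(dtype=float)
            q[gene] = (np.quantile(vals, 0.25), np.quantile(vals, 0.75))
        q1, q3 = q[gene]
        v = float(tpm.at[gene, sample])
        total += 1
        inside += int(q1 <= v <= q3)
    return inside / total if total else None


def overlap_groups(sets: dict[str, set[str]],
                   tallies: Optional[dict[str, tuple[int, int]]] = None
                   ) -> dict[tuple[str, ...], list[dict]]:
    """Partition the union of k gene sets into the 2^k - 1 membership groups.

    Keys of the result are tuples of cohort ids (the membership signature,
    in the order given); each gene appears in exactly one group, genes sorted
    alphabetically.  ``tallies`` optionally supplies per-gene
    (mutation_count, distinct_individuals) annotations.
    """
    if not sets:
        raise InputError("at least one set required")
    cohorts = list(sets)
    groups: dict[tuple[str, ...], list[dict]] = {}
    for r in range(1, len(cohorts) + 1):
        for combo in combinations(cohorts, r):
            groups[combo] = []
    union = sorted(set().union(*sets.values()))
    for gene in union:
        signature = tuple(c for c in cohorts if gene in sets[c])
        entry = {"gene": gene}
        if tallies and gene in tallies:
            entry["mutation_count"], entry["n_individuals"] = tallies[gene]
        groups[signature].append(entry)
    return groups
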