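"""Cys2His2 zinc-finger domain discovery and tandem-array analysis.

A "classic" Cys2His2 domain is a 21-residue window matching

    C x2 C x9 PSI x2 H x3 [H|C]

where PSI is a large hydrophobic residue and the final zinc ligand may be
histidine or cysteine.  The 21 residue indices carry helix-relative display
labels -10..-1, 1..11 (no 0): label 1 is the first helix residue, the
zinc-coordinating histidines sit at labels 7 and 11, and labels 9 and 11 are
the focal hotspot positions of the downstream analysis.

Two discovery modes are supported: a pure pattern scan, and an "hmm+pattern"
mode that intersects pattern matches with externally produced hmmsearch
per-domain hits (running HMMER itself is out of scope here).
"""
from __future__ import annotations

from dataclasses import dataclass

from scipy import stats

from .errors import InputError
from .models import LABELS, TestResult, ZFDomain, index_to_label

#: Large hydrophobic residues accepted at domain index 14 (the PSI wildcard).
HYDROPHOBIC = frozenset("FILMVWY")

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

DOMAIN_LENGTH = 21


def window_matches(window: str, hydrophobic: frozenset[str] = HYDROPHOBIC) -> bool:
    """Check one 21-residue window against the Cys2His2 pattern."""
    if len(window) != DOMAIN_LENGTH:
        return False
    return (window[0] == "C" and window[3] == "C" and window[13] in hydrophobic
            and window[16] == "H" and window[20] in ("H", "C"))


def find_zf_domains(protein_seq: str, gene_id: str = "",
                    hydrophobic: frozenset[str] = HYDROPHOBIC) -> list[ZFDomain]:
    """Scan a protein for classic Cys2His2 domains.

    Returns the leftmost non-overlapping matches, scanning left to right,
    sorted by start.  ``X`` is tolerated in the input but never matches a
    constrained position (and, being outside the hydrophobic set, cannot
    satisfy PSI); any other non-standard character is an error.

    Parameters
    ----------
    protein_seq : str
        Amino-acid sequence (standard 20-letter alphabet, optional X).
    gene_id : str
        Identifier copied onto the emitted domains.
    hydrophobic : frozenset of str
        The PSI alphabet; configurable, defaults to {F,I,L,M,V,W,Y}.
    """
    allowed = AMINO_ACIDS | {"X"}
    for i, aa in enumerate(protein_seq):
        if aa not in allowed:
            raise InputError(f"non-amino-acid character {aa!r} at position {i + 1}")
    domains: list[ZFDomain] = []
    i = 0
    n = len(protein_seq)
    while i + DOMAIN_LENGTH <= n:
        if window_matches(protein_seq[i:i + DOMAIN_LENGTH], hydrophobic):
            domains.append(ZFDomain(gene_id=gene_id, protein_start=i + 1,
                                    protein_end=i + DOMAIN_LENGTH))
            i += DOMAIN_LENGTH
        else:
            i += 1
    return domains


def label_positions(domain: ZFDomain) -> dict[int, int]:
    """Ordered map from domain index (1..21) to its helix-relative label."""
    labels = {i: index_to_label(i) for i in range(1, DOMAIN_LENGTH + 1)}
    domain.position_labels = labels
    return labels


@dataclass
class HMMSegment:
    """One hmmsearch per-domain hit retained after E-value filtering."""

    protein_id: str
    start: int     # alignment start in the target protein, 1-based
    end: int
    evalue: float


def parse_hmm_domain_table(path, evalue_max: float = 0.1) -> list[HMMSegment]:
    """Parse an hmmsearch ``--domtblout`` table, keeping hits with E < evalue_max.

    The independent (per-domain) E-value is used.  Rows are whitespace-
    delimited with '#' comment lines; a malformed row raises InputError with
    its line number.
    """
    segments: list[HMMSegment] = []
    try:
        fh = open(path)
    except OSError as exc:
        raise IOError(f"cannot read hmmsearch table {path}: {exc}") from exc
    with fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 22:
                raise InputError(f"{path}: malformed hmmsearch row at line {lineno}")
            try:
                evalue = float(fields[12])          # i-Evalue
                ali_from, ali_to = int(fields[17]), int(fields[18])
            except ValueError as exc:
                raise InputError(
                    f"{path}: malformed hmmsearch row at line {lineno}: {exc}") from exc
            if evalue < evalue_max:
                segments.append(HMMSegment(fields[0], ali_from, ali_to, evalue))
    return segments


def intersect_with_hmm(domains: list[ZFDomain],
                       segments: list[HMMSegment]) -> list[ZFDomain]:
    """Keep pattern matches contained in an HMM segment; tag them hmm+pattern."""
    kept = []
    for d in domains:
        for seg in segments:
            if (seg.protein_id == d.gene_id and seg.start <= d.protein_start
                    and d.protein_end <= seg.end):
                d.source = "hmm+pattern"
                kept.append(d)
                break
    return kept


def flag_tandem_neighbors(domains: list[ZFDomain], max_linker: int = 12) -> list[ZFDomain]:
    """Set ``has_cterm_neighbor`` on domains followed closely by another domain.

    The linker is the number of residues strictly between consecutive domains
    of the same protein; a domain has a C-terminal neighbor when that linker
    is <= ``max_linker``.  Input must be sorted by start within each protein.
    """
    by_gene: dict[str, list[ZFDomain]] = {}
    for d in domains:
        by_gene.setdefault(d.gene_id, []).append(d)
    for gene_domains in by_gene.values():
        starts = [d.protein_start for d in gene_domains]
        if starts != sorted(starts):
            raise InputError("domains must be sorted by protein_start within a protein")
        for this, nxt in zip(gene_domains, gene_domains[1:]):
            linker = nxt.protein_start - this.protein_end - 1
            this.has_cterm_neighbor = linker <= max_linker
        gene_domains[-1].has_cterm_neighbor = False
    return domains


def adjacency_binomial_test(subset_adjacent: int, subset_total: int,
                            reference_fraction: float) -> TestResult:
    """One-sided binomial test that a domain subset is tandem-adjacent more
    often than a reference fraction.

    p = P(X >= subset_adjacent | n = subset_total, p = reference_fraction).
    """
    if not 0 <= subset_adjacent <= subset_total:
        raise InputError(f"inconsistent counts {subset_adjacent}/{subset_total}")
    if not 0.0 <= reference_fraction <= 1.0:
        raise InputError("reference_fraction must be in [0,1]")
    p = float(stats.binom.sf(subset_adjacent - 1, subset_total, reference_fraction))
    expected = subset_total * reference_fraction
    fold = subset_adjacent / expected if expected > 0 else None
    return TestResult(statistic_name="tandem_adjacency", observed=subset_adjacent,
                      expected=expected, fold=fold, p_value=p,
                      method="binomial upper tail")


def domains_to_table(domains: list[ZFDomain]):
    """Flatten domains to a TSV-ready pandas DataFrame (fixed 21 label columns)."""
    import pandas as pd

    rows = []
    for d in domains:
        row = {"gene_id": d.gene_id, "protein_start": d.protein_start,
               "protein_end": d.protein_end, "source": d.source,
               "has_cterm_neighbor": d.has_cterm_neighbor}
        for i in range(1, DOMAIN_LENGTH + 1):
            row[f"label_{i}"] = LABELS[i - 1]
        rows.append(row)
    return pd.DataFrame(rows)
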