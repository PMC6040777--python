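"""Core data containers shared across the pipeline.

Coordinate conventions: all genomic, CDS and protein coordinates are 1-based
and inclusive (MAF convention).  CDS position 1 is the first base of the start
codon; protein position 1 is the initiator methionine.  Domain *indices* run
1..21 over the residues of a Cys2His2 zinc-finger domain; domain *labels* are
the field-standard numbering relative to the start of the DNA-binding
alpha-helix, -10..-1 then 1..11 with no 0 (the helix starts at label 1, the
two zinc-coordinating residues of the C-terminal half sit at labels 7 and 11).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .errors import InputError

#: Display labels for domain indices 1..21 (index i -> LABELS[i-1]).
LABELS: tuple[int, ...] = tuple(range(-10, 0)) + tuple(range(1, 12))

#: Consequence classes for coding substitutions.
MISSENSE = "missense"
SYNONYMOUS = "synonymous"
NONSENSE = "nonsense"
OTHER = "noncoding/other"


def index_to_label(index: int) -> int:
    """Map a domain index (1..21) to its helix-relative display label."""
    if not 1 <= index <= 21:
        raise InputError(f"domain index {index} outside 1..21")
    return LABELS[index - 1]


def label_to_index(label: int) -> int:
    """Inverse of :func:`index_to_label`."""
    try:
        return LABELS.index(label) + 1
    except ValueError:
        raise InputError(f"{label} is not a valid domain label") from None


@dataclass
class ZFDomain:
    """A single 21-residue Cys2His2 zinc-finger domain match."""

    gene_id: str
    protein_start: int               # 1-based, inclusive
    protein_end: int                 # = protein_start + 20
    position_labels: dict[int, int] = field(
        default_factory=lambda: {i: LABELS[i - 1] for i in range(1, 22)})
    has_cterm_neighbor: bool = False
    source: str = "pattern"          # "pattern" or "hmm+pattern"

    def __post_init__(self):
        if self.protein_end - self.protein_start != 20:
            raise InputError(
                f"domain {self.gene_id}:{self.protein_start} does not span 21 residues")

    def label_of_protein_pos(self, protein_pos: int) -> Optional[int]:
        """Display label for an absolute protein position, or None if outside."""
        if self.protein_start <= protein_pos <= self.protein_end:
            return index_to_label(protein_pos - self.protein_start + 1)
        return None


@dataclass
class GeneModel:
    """One representative transcript for a gene.

    ``cds_intervals`` are (chrom, start, end) in genomic order; for minus-strand
    genes the coding sequence reads from the highest genomic coordinate and
    ``cds_seq`` is already on the coding strand.  ``cds_seq`` may include the
    terminal stop codon; translation with the stop dropped must equal
    ``protein_seq``.
    """

    gene_id: str
    transcript_id: str
    strand: str
    cds_intervals: list[tuple[str, int, int]]
    cds_seq: str
    protein_seq: str
    is_krab: bool = False

    def __post_init__(self):
        if self.strand not in "+-":
            raise InputError(f"{self.gene_id}: strand must be '+' or '-'")

    @property
    def cds_length(self) -> int:
        return len(self.cds_seq)

    def validate(self) -> None:
        """Check the structural invariants; raise InputError on violation."""
        total = sum(e - s + 1 for _, s, e in self.cds_intervals)
        if total != len(self.cds_seq):
            raise InputError(
                f"{self.gene_id}: interval span {total} != CDS length {len(self.cds_seq)}")
        if len(self.cds_seq) % 3:
            raise InputError(f"{self.gene_id}: CDS length not divisible by 3")
        aa = str(Seq(self.cds_seq).translate())
        if aa.endswith("*"):
            aa = aa[:-1]
        if aa != self.protein_seq:
            raise InputError(f"{self.gene_id}: CDS translation != protein sequence")


@dataclass
class MutationRecord:
    """One somatic single-nucleotide substitution."""

    sample_id: str
    gene_id: str
    chrom: str
    genomic_pos: int
    ref_base: str
    alt_base: str
    cds_pos: Optional[int] = None       # coding-strand, 1-based
    protein_pos: Optional[int] = None   # codon index, 1-based
    ref_aa: Optional[str] = None
    alt_aa: Optional[str] = None
    consequence: str = OTHER
    context: Optional[str] = None       # coding-strand reference trinucleotide


@dataclass
class PositionProfile:
    """Per-cohort aggregation of domain mutations onto the 21-position grid."""

    cohort_id: str
    counts: dict[int, int]                   # label -> missense count
    synonymous_counts: dict[int, int]        # label -> synonymous count
    per_sample: pd.DataFrame                 # samples x labels, missense counts
    n_samples: int
    patient_fractions: dict[object, float]   # keys: 'zf_gene', 'zf_domain', labels

    @property
    def per_sample_average(self) -> dict[int, float]:
        if self.n_samples == 0:
            return {lab: 0.0 for lab in self.counts}
        return {lab: c / self.n_samples for lab, c in self.counts.items()}

    def validate(self) -> None:
        colsums = self.per_sample.sum(axis=0)
        for lab, c in self.counts.items():
            if int(colsums[lab]) != c:
                raise InputError(f"profile {self.cohort_id}: per-sample column sum "
                                 f"at label {lab} != counts")
        for v in self.patient_fractions.values():
            if not 0.0 <= v <= 1.0:
                raise InputError("patient fraction outside [0,1]")


@dataclass
class TestResult:
    """Generic observed-vs-null test summary."""

    statistic_name: str
    observed: float
    expected: Optional[float]
    fold: Optional[float]
    p_value: float
    method: str

    def summary(self) -> str:
        parts = [f"{self.statistic_name}: observed={self.observed:g}"]
        if self.expected is not None:
            parts.append(f"expected={self.expected:.4g}")
        if self.fold is not None:
            parts.append(f"fold={self.fold:.3g}")
        parts.append(f"p={self.p_value:.3g} ({self.method})")
        return "  ".join(parts)


@dataclass
class PermutationResult:
    """Result of an empirical permutation test.

    ``empirical_p`` is the plain tail fraction; when the counted tail is empty
    it is 0.0 and ``p_display`` reports the resolution bound "< 1/n".
    """

    statistic_name: str
    observed: float
    null_values: np.ndarray
    n_permutations: int
    tail: str = "upper"              # "upper" or "lower"

    def __post_init__(self):
        self.null_values = np.asarray(self.null_values, dtype=float)
        if self.tail not in ("upper", "lower"):
            raise InputError(f"unknown tail {self.tail!r}")

    @property
    def null_mean(self) -> float:
        return float(self.null_values.mean()) if self.null_values.size else float("nan")

    @property
    def fold(self) -> float:
        mean = self.null_mean
        return float(self.observed / mean) if mean > 0 else float("nan")

    @property
    def tail_count(self) -> int:
        if self.tail == "upper":
            return int(np.sum(self.null_values >= self.observed))
        return int(np.sum(self.null_values <= self.observed))

    @property
    def empirical_p(self) -> float:
        return self.tail_count / self.n_permutations

    @property
    def p_display(self) -> str:
        if self.tail_count == 0:
            return f"< {1.0 / self.n_permutations:g}"
        return f"{self.empirical_p:g}"


@dataclass
class ContextRateTest:
    """Poisson-binomial test of focal-site mutation counts against exome rates."""

    contexts: tuple
    n_sites: int
    per_sample_rates: dict[str, float]
    observed: int
    p_value: float

    @property
    def expected(self) -> float:
        return self.n_sites * sum(self.per_sample_rates.values())

    @property
    def fold(self) -> float:
        exp = self.expected
        return self.observed / exp if exp > 0 else float("nan")


@dataclass
class GeneRates:
    """Per-gene mutation counts and fractional site totals."""

    gene_id: str
    ns_sites: float
    s_sites: float
    missense_count: int
    synonymous_count: int
    missense_rate_per_base: Optional[float] = None

    @property
    def normalized_ratio(self) -> Optional[float]:
        """(missense/ns sites) / (synonymous/s sites); None when undefined."""
        if self.synonymous_count == 0 or self.s_sites == 0 or self.ns_sites == 0:
            return None
        return (self.missense_count / self.ns_sites) / (self.synonymous_count / self.s_sites)
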