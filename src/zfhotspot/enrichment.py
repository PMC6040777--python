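"""Functional enrichment: hypergeometric over-representation and the NEAT
interaction-enrichment test, with q-value correction.

The NEAT statistic is the number of network edges with one endpoint in gene
set A and the other in set B; its null is hypergeometric with population the
total degree D = 2|E|, successes the summed degree of B and draws the summed
degree of A (degree-conditioned random rewiring).  One-sided upper-tail
p-values are reported, with q-values computed across terms.  Genes in
A intersect B contribute their degree to both margins; edges inside the
intersection count once toward the observed links.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import interpolate, stats
from statsmodels.stats.multitest import multipletests

from .errors import InputError


@dataclass
class AnnotationSet:
    set_id: str
    term_name: str
    members: set[str]

    def __post_init__(self):
        if not self.members:
            raise InputError(f"annotation set {self.set_id} has no members")


def read_gmt(path) -> list[AnnotationSet]:
    """Read annotation sets from a GMT file (id, description, members...)."""
    sets = []
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                continue
            sets.append(AnnotationSet(fields[0], fields[1], set(fields[2:]) - {""}))
    return sets


@dataclass
class Network:
    """Undirected interaction network with degree bookkeeping."""

    edges: set[frozenset] = field(default_factory=set)
    allow_self_loops: bool = False

    @classmethod
    def from_edges(cls, pairs: Iterable[tuple[str, str]],
                   allow_self_loops: bool = False) -> "Network":
        net = cls(allow_self_loops=allow_self_loops)
        for a, b in pairs:
            if a == b and not allow_self_loops:
                raise InputError(f"self-loop {a}-{b} not allowed")
            net.edges.add(frozenset((a, b)))
        return net

    @classmethod
    def from_tsv(cls, path) -> "Network":
        df = pd.read_csv(path, sep="\t", comment="#", header=None, dtype=str)
        return cls.from_edges(zip(df.iloc[:, 0], df.iloc[:, 1]))

    @property
    def nodes(self) -> set[str]:
        return set().union(*self.edges) if self.edges else set()

    @property
    def degree(self) -> dict[str, int]:
        deg: dict[str, int] = {}
        for e in self.edges:
            pair = tuple(e) if len(e) == 2 else (next(iter(e)),) * 2
            for node in pair:
                deg[node] = deg.get(node, 0) + 1
        return deg

    @property
    def total_degree(self) -> int:
        return 2 * len(self.edges)


def hypergeom_set_enrichment(query: set[str], annotation_sets: Sequence[AnnotationSet],
                             background: set[str],
                             min_term_size: int = 3) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation of annotation terms.

    Per term: population |background|, successes |term ∩ background|, draws
    |query ∩ background|, p = P(X >= overlap).  Terms with fewer than
    ``min_term_size`` background members are skipped.
    """
    if not background:
        raise InputError("background gene set is empty")
    q = query & background
    rows = []
    for term in annotation_sets:
        members = term.members & background
        if len(members) < min_term_size:
            continue
        overlap = len(q & members)
        p = float(stats.hypergeom.sf(overlap - 1, len(background), len(members), len(q)))
        rows.append({"set_id": term.set_id, "term": term.term_name,
                     "term_size": len(members), "overlap": overlap, "p": p})
    df = pd.DataFrame(rows, columns=["set_id", "term", "term_size", "overlap", "p"])
    if len(df):
        df["q"] = estimate_qvalues(df["p"].to_numpy())
        df = df.sort_values(["p", "set_id"]).reset_index(drop=True)
    return df


def neat_interaction_enrichment(set_a: set[str], set_b: set[str],
                                network: Network) -> tuple[int, float, float]:
    """Degree-conditioned interaction enrichment between two gene sets.

    Returns (observed_links, expected, p) with p the upper-tail
    hypergeometric probability of at least the observed number of A-B links.
    Sets are intersected with the network nodes first; an empty intersection
    yields (0, 0.0, 1.0) with a warning.
    """
    import logging
    nodes = network.nodes
    a = set_a & nodes
    b = set_b & nodes
    if not a or not b:
        logging.getLogger(__name__).warning(
            "NEAT: a gene set is empty after intersecting with the network")
        return 0, 0.0, 1.0
    observed = sum(1 for e in network.edges
                   if (len(e & a) > 0 and len(e & b) > 0))
    deg = network.degree
    d_total = network.total_degree
    d_a = sum(deg[n] for n in a)
    d_b = sum(deg[n] for n in b)
    expected = d_a * d_b / d_total
    p = float(stats.hypergeom.sf(observed - 1, d_total, d_b, d_a))
    return observed, expected, p


def _storey_pi0(p: np.ndarray, lambdas: Optional[np.ndarray] = None) -> float:
    """Storey's smoother estimate of the null proportion pi0."""
    if lambdas is None:
        lambdas = np.arange(0.05, 0.96, 0.05)
    m = p.size
    pi0_lambda = np.array([(p > lam).sum() / (m * (1 - lam)) for lam in lambdas])
    if m < 2 or np.allclose(pi0_lambda, pi0_lambda[0]):
        return float(min(1.0, max(pi0_lambda[-1], 1e-8)))
    spline = interpolate.UnivariateSpline(lambdas, pi0_lambda, k=3,
                                          s=len(lambdas) * np.var(pi0_lambda))
    pi0 = float(spline(lambdas[-1]))
    return min(1.0, max(pi0, 1e-8))


def estimate_qvalues(p_values, method: str = "storey") -> np.ndarray:
    """q-values for a vector of p-values.

    ``bh`` is step-up Benjamini-Hochberg; ``storey`` additionally scales by
    the smoother estimate of the null proportion pi0 (lambda grid
    0.05..0.95).  q-values are monotone in p.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise InputError("p-values must lie in [0, 1]")
    if method == "bh":
        return multipletests(p, method="fdr_bh")[1]
    if method != "storey":
        raise InputError(f"unknown q-value method {method!r}")
    pi0 = _storey_pi0(p)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    q = pi0 * m * ranked / np.arange(1, m + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(m)
    out[order] = q
    return out
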