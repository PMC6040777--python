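# Methods

This note documents the statistical procedures implemented in `zfhotspot`,
the choices made where the design was genuinely open, and what the synthetic
cohorts do and do not emulate.

## Domain model

A "classic" Cys2His2 zinc finger is a 21-residue window matching
`C x2 C x9 Ψ x2 H x3 [H|C]`, where Ψ is a large hydrophobic residue.  We fix
Ψ = {F, I, L, M, V, W, Y} (the conventional large-hydrophobic alphabet; the
set is a parameter of `find_zf_domains`).  Candidate windows are resolved
**leftmost-first and non-overlapping**: real ZF arrays do not overlap, and a
greedy left-to-right scan makes the output a deterministic function of the
sequence.  Unit and acceptance tests check the scanner against an
independent brute-force window enumerator.

Positions are labeled relative to the start of the DNA-binding α-helix:
domain indices 1–10 map to −10…−1 and indices 11–21 to 1…11, with no label
0.  The anchors are fixed by the domain's landmarks — the helix starts at
label 1 (index 11), the two zinc-coordinating residues of the C-terminal
half sit at labels 7 (index 17) and 11 (index 21), and the inter-finger
contact position is label 9 (index 19).

Pattern-only discovery is the default.  An `hmm+pattern` mode intersects
pattern matches with hits from an externally produced `hmmsearch`
per-domain table (independent E-value < 0.1 by default); running HMMER
itself is out of scope.  Tandem adjacency uses the linker length — residues
strictly between consecutive domains — with "adjacent" meaning linker ≤ 12.

## Mutation mapping

Coordinates are 1-based inclusive throughout (MAF convention).  Only
single-nucleotide substitutions enter the analysis; other variant types are
tallied and dropped.  For minus-strand genes, coordinates count from the
highest genomic position and alleles are reverse-complemented onto the
coding strand.  Consequences come from the standard genetic code; a
substitution inside a (terminal) stop codon is classified
`noncoding/other`.  When a gene has several isoforms, the one mapping the
most mutations is kept (ties: longest CDS, then smallest transcript id).

The **trinucleotide context** of a mutation is the coding-strand reference
base with its two immediate neighbors, read on the *spliced* coding
sequence.  The first and last CDS base have no complete context; such
mutations are held fixed during shuffles and logged.  Contexts that span
exon junctions therefore use the spliced neighbors, which is the context
the within-CDS permutation actually operates on.

Patient fractions are computed over all samples observed in the cohort's
MAF, including samples with no ZF mutations.  An optional cross-reference
check excludes a domain unless its 21-mer appears verbatim at the stated
coordinates of a second protein source.

## Context-preserving permutation null

For each ZF gene, all point mutations with a missense or synonymous
consequence are shuffled together: each mutation moves independently to a
uniformly drawn CDS position of the same gene with the same trinucleotide,
the original position included.  The alternate base travels with the
mutation (moving a mutation without its substitution would not preserve its
identity), several mutations may land on one site (counts add; the
procedure is defined per mutation, not per site), and consequences are
re-derived at the destination — this is what lets per-label missense counts
fluctuate under the null.  Per gene, the multiset of (context, ref, alt)
triples is conserved exactly, which the test suite checks over 10,000 seeded
shuffles.

For each of the 21 labels, the observed statistic is the total missense
count at that label across all ZF genes; the empirical p-value is the
fraction of permutations whose recount is at least the observed value
(upper tail).  A zero tail is reported as "< 1/n_permutations".  The default
is 10,000 permutations; the enrichment fold is observed / null mean.  Note
that 21 labels are tested per cohort; the per-label p-values are not
multiplicity-corrected, mirroring the hypothesis-generating use of the
profile.

Two properties of this null matter for interpretation.  First, because the
enriched mutations themselves are redistributed, the measured fold
*understates* a true multiplicative enrichment f by the factor
1 + (f − 1)·φ, where φ is the fraction of a gene's same-context sites that
are focal; the bias is small only when focal sites are a small minority of
their context class.  Second, the null redistributes only missense and
silent mutations, so context classes in which many substitutions create
stop codons contribute less to the null than to the observed count.  Both
effects shaped the synthetic-cohort defaults (below).

The **site-restricted permutation** reassigns the focal-label mutations
across all context-matching focal codons of the whole ZF gene set (not
gene-restricted), re-evaluating missense status at each destination.  The
number of distinct mutated genes is tested on the lower tail ("fewer genes
than expected" = concentration; ≤ is used as the conservative convention),
the KRAB-gene fraction of missense mutations on the upper tail.

## Poisson-binomial context-rate test

For a substitution channel (a reference trinucleotide, possibly with an `N`
wildcard, plus the middle-base substitution; site and substitution matching
are strand-collapsed), each sample's exome-wide rate is its count of channel
mutations divided by the number of eligible exome sites.  The number of
focal-label channel mutations is then compared to the sum of independent
Bernoulli trials with each sample's rate replicated once per focal site —
samples with rate 0 are included as trials.  The upper tail is computed by
an exact dynamic-programming convolution with an absorbing bin at the
threshold k, accumulating P(X ≥ k) as a sum of positive terms so that very
small p-values avoid 1 − P cancellation; cost is O(n·min(k, n)).  Above
2×10⁸ units of work the implementation falls back to a refined normal
approximation with continuity and skewness corrections.  Tests compare the
DP against scipy's binomial tail (equal-p reduction, to 1e-12) and against
a 10⁶-draw Monte-Carlo oracle (within 3 standard errors).

## Gene-level statistics

Nonsynonymous/synonymous site counting is fractional: each CDS position
contributes (number of the 3 possible substitutions that change the amino
acid)/3 to the nonsynonymous total, stop gains counting as nonsynonymous
(the standard Nei–Gojobori-style convention; configurable), and the two
totals sum to the CDS length.  The normalized ratio
(missense/ns)/(synonymous/s) is undefined for genes without synonymous
mutations; such genes are excluded from comparisons.  "Other mutated genes"
in the ratio comparison means all non-focal genes with at least one missense
and one synonymous mutation.  Rank comparisons use the Mann–Whitney U test
(exact for small tie-free samples, tie-corrected normal approximation
otherwise).  Per-base missense rates average over all cohort samples, with
focal-label missense excluded when requested.  Expression IQR membership
uses linear-interpolation (type 7) quartiles and the closed interval
[Q1, Q3]; it is invariant under per-gene monotone rescaling.

## Enrichment

Annotation over-representation is the upper-tail hypergeometric with the
declared background as population; terms with fewer than 3 background
members are skipped.  The interaction test follows undirected NEAT: the
observed statistic is the number of network edges with one endpoint in each
set; the null is hypergeometric with population 2|E| (total degree),
successes Σdeg(B) and draws Σdeg(A); we report one-sided p-values with
q-values across terms.  Genes in A ∩ B contribute their degree to both
margins and intersection-internal edges count once — the published one-line
description of the modification leaves this open, so the choice is
documented here and covered by tests rather than asserted as identical to
any other implementation.  The default q-value method is Storey's (π₀
estimated by a cubic-spline smoother over λ = 0.05…0.95); step-up BH is
available where π₀ estimation is unwanted.

## Synthetic cohorts

The generator is the test bed for everything above.  It emulates:

* ZF genes as one synthetic chromosome of alternating-strand, multi-exon
  loci: an N-terminal low-complexity region (default 200 codons), then a
  tandem array of pattern-valid 21-residue domains (Poisson mean 8, min 2)
  joined by TGEKP linkers; half the genes carry a KRAB flag.  The p9
  arginine is encoded AGA in a configurable fraction of domains (default
  0.15, otherwise CGC), and the base 5′ of the p11 histidine codon is a
  pyrimidine with probability 0.5 — realizing the hotspot-relevant AGA and
  TCA/CCA contexts at the focal codons.
* Background genes (default 250, log-normal length around 300 codons) that
  supply exome-wide context rates.
* Heavy-tailed burdens: per-sample mutation counts are Poisson around a
  log-normal (median 60, σ = 1 on the synthetic mini-exome), with a 5%
  ultramutator fraction at 15× burden.
* Signature-weighted placement: substitution probabilities are proportional
  to a weight per (context, alt) channel, strand-collapsed.  The POLE-like
  default elevates AGA→ATA 600-fold over the base channel weight and the
  UV-like default elevates dipyrimidine C→T 300-fold, reflecting how
  strongly real ultramutator and UV spectra concentrate on their signature
  channels.  Positional enrichment is injected **multiplicatively** on the
  weights of focal sites matching a channel, so the configured fold is
  directly comparable to the recovered fold.

Design choices forced by the null's properties (see above): the ZF genes'
constitutive sequence avoids codons whose high-weight channel substitutions
create stop codons (no E/Q/W in the non-domain regions, glycine restricted
to GGT/GGC), because stop-gain-prone channel sites would deplete the
missense+silent shuffle class and bias the null; and each focal context has
a deliberate non-focal reservoir (AGA-arginine, TCA-serine and CCA-proline
seeds in the N-terminal region plus constitutive domain sites) so that φ —
the focal fraction of each context class — stays near 0.03 and injected
folds up to 5 are recoverable within ±20%.  Mutation probabilities are
assigned on the spliced coding-strand context, matching the analysis's
context definition; the two contextless CDS end bases are not mutable.

What the generator does **not** emulate: real codon-usage and trinucleotide
composition (the ZF-gene alphabet restrictions above are synthetic), full
96-channel signature catalogs, indels and copy number, non-coding sequence,
germline variation, mappability or sequencing artifacts, and
biologically-driven gene concentration (enrichment is uniform across focal
sites, so the gene-concentration statistic is null in simulated cohorts).
Passing tests therefore demonstrate the statistical machinery's
correctness and calibration under controlled conditions, not performance on
real tumor data.

Expression is per-gene log-normal TPM with columns renormalized to 10⁶; the
network is a fixed-edge-count random graph; annotation sets are drawn
uniformly with an optional bias toward a designated gene subset.

## Problem sizes used by the checks

The acceptance checks run at sizes chosen to make their statistical
tolerances meaningful on a single CPU: oracle equivalence on 1,000 random
proteins and 500 random CDSs; Poisson-binomial validation against a
10⁶-draw Monte-Carlo oracle at n ≤ 500; null calibration over 200 simulated
cohorts (12 ZF genes × 40 samples, 1,000 permutations each) with the
rejection rate at nominal 0.05 required to fall in [0.03, 0.07]; fold
recovery at 300 samples × 50 ZF genes with 1,000 permutations; and an
end-to-end UV-like cohort (150 samples × 30 genes, 2,000 permutations).
`scripts/acceptance.py` uses two 300 × 50 cohorts with 2,000 permutations.

## Known limitations

* The permutation fold is a biased estimator of multiplicative enrichment
  (see φ above); on real genes with few alternative context sites the
  reported fold will understate strong enrichment.
* Exome context rates are computed from the supplied gene models only;
  genes absent from the models contribute neither sites nor mutations.
* Empirical p-values have resolution 1/n_permutations and are reported
  without the +1 pseudocount; zero tails are displayed as upper bounds.
* The NEAT parameterization of overlapping sets is one defensible choice
  among several (documented above).
* `estimate_qvalues(..., "storey")` needs a reasonable spread of p-values
  for the π₀ spline; for very short p-vectors it effectively reduces to a
  truncated estimate.
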