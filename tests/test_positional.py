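"""Context-preserving shuffles, site-restricted permutations and the
Poisson-binomial context-rate test."""
import numpy as np
import pytest
from scipy import stats

from zfhotspot.domains import find_zf_domains
from zfhotspot.errors import InputError
from zfhotspot.models import MISSENSE, PermutationResult
from zfhotspot.poibin import poisson_binomial_tail
from zfhotspot.positional import (Channel, channel_tables, compute_context_rates,
                                  context_code, context_rate_test,
                                  count_eligible_sites, eligible_positions,
                                  focal_codon_sites, position_permutation_test,
                                  site_restricted_permutation,
                                  trinucleotide_shuffle)

from conftest import make_gene, make_mutation


class TestEligibleSitesAndShuffle:
    def test_eligible_target_set_enumeration(self):
        assert eligible_positions("TAGACAGAC", "AGA") == [3, 7]

    def test_unique_context_makes_shuffle_identity(self):
        muts = [make_mutation(cds_pos=2, context="TAG", alt="T")]
        rng = np.random.default_rng(0)
        assert trinucleotide_shuffle(muts, "TAGACAGAC", rng) == [2]

    def test_context_multiset_conserved_for_any_seed(self):
        cds = "TAGACAGACTTAGACC"
        muts = [make_mutation(cds_pos=3, context="AGA", alt="T"),
                make_mutation(cds_pos=7, context="AGA", alt="C"),
                make_mutation(cds_pos=5, context="ACA", alt="G")]
        before = sorted((m.context, cds[m.cds_pos - 1], m.alt_base) for m in muts)
        for seed in range(50):
            new_pos = trinucleotide_shuffle(muts, cds, np.random.default_rng(seed))
            after = sorted((cds[p - 2:p + 1], cds[p - 1], m.alt_base)
                           for p, m in zip(new_pos, muts))
            assert after == before

    def test_contextless_mutation_held_fixed(self):
        muts = [make_mutation(cds_pos=1, context=None, alt="T")]
        assert trinucleotide_shuffle(muts, "TAGACAGAC",
                                     np.random.default_rng(0)) == [1]


def _two_site_gene():
    """One ZF gene where the p9-codon context appears at exactly two sites.

    Protein: M + 21-residue domain.  The domain's p9 codon (index 19, protein
    position 20) is GCA; the only other GCA trinucleotide sits in the middle
    of another GCT-alanine run far from the domain grid... the CDS is built
    explicitly and the two-site property asserted.
    """
    protein = "M" + "CAACAAAAAAAAALAAHAAAH"
    codons = {"M": "ATG", "C": "TGT", "A": "GCT", "L": "CTG", "H": "CAC"}
    parts = [codons[a] for a in protein]
    parts[19] = "GCA"          # protein position 20 = domain index 19 = label 9
    parts[5] = "GCA"           # second, non-focal site with the same context
    cds = "".join(parts) + "TAA"
    gene = make_gene("ZF1", cds)
    domains = {"ZF1": find_zf_domains(gene.protein_seq, gene_id="ZF1")}
    # the focal context is the middle C of GCA (ctx GCA); assert exactly 2 sites
    focal_cds_pos = 19 * 3 + 2
    assert cds[focal_cds_pos - 1] == "C"
    sites = eligible_positions(cds, "GCA")
    assert len(sites) == 2 and focal_cds_pos in sites
    return gene, domains, focal_cds_pos


class TestPositionPermutationTest:
    def test_forced_placement_gives_p_one(self):
        """When the focal context is unique in the gene the null is degenerate."""
        protein = "M" + "CAACAAAAAAAAALAAHAAAH"
        codons = {"M": "ATG", "C": "TGT", "A": "GCT", "L": "CTG", "H": "CAC"}
        parts = [codons[a] for a in protein]
        parts[19] = "GCA"
        cds = "".join(parts) + "TAA"
        gene = make_gene("ZF1", cds)
        domains = {"ZF1": find_zf_domains(gene.protein_seq, gene_id="ZF1")}
        focal = 19 * 3 + 2
        assert eligible_positions(cds, "GCA") == [focal]
        mut = make_mutation(gene="ZF1", cds_pos=focal, protein_pos=20,
                            ref="C", alt="T", context="GCA", consequence=MISSENSE)
        res = position_permutation_test([mut], {"ZF1": gene}, domains,
                                        n_permutations=200, seed=0)
        assert res[9].observed == 1
        assert res[9].empirical_p == 1.0

    def test_two_equal_site_classes_match_binomial_null(self):
        """3 mutations over 2 equally likely sites: P(null >= 3) = (1/2)^3."""
        gene, domains, focal = _two_site_gene()
        muts = [make_mutation(sample=f"S{i}", gene="ZF1", cds_pos=focal,
                              protein_pos=20, ref="C", alt="T", context="GCA",
                              consequence=MISSENSE) for i in range(3)]
        res = position_permutation_test(muts, {"ZF1": gene}, domains,
                                        n_permutations=20_000, seed=1)
        assert res[9].observed == 3
        assert res[9].empirical_p == pytest.approx(0.125, abs=0.012)

    def test_zero_mutations_degenerate(self):
        gene, domains, _ = _two_site_gene()
        res = position_permutation_test([], {"ZF1": gene}, domains,
                                        n_permutations=50, seed=0)
        assert all(r.empirical_p == 1.0 for r in res.values())

    def test_seed_determinism(self):
        gene, domains, focal = _two_site_gene()
        muts = [make_mutation(gene="ZF1", cds_pos=focal, protein_pos=20,
                              ref="C", alt="T", context="GCA",
                              consequence=MISSENSE)]
        a = position_permutation_test(muts, {"ZF1": gene}, domains,
                                      n_permutations=500, seed=7)
        b = position_permutation_test(muts, {"ZF1": gene}, domains,
                                      n_permutations=500, seed=7)
        for lab in a:
            assert np.array_equal(a[lab].null_values, b[lab].null_values)


class TestPermutationResult:
    def test_fold_and_tail_reporting(self):
        r = PermutationResult("x", observed=3.0,
                              null_values=np.array([1.0, 2.0, 1.5]),
                              n_permutations=3)
        assert r.fold == pytest.approx(3.0 / 1.5)
        r2 = PermutationResult("x", observed=10.0,
                               null_values=np.zeros(100), n_permutations=100)
        assert r2.empirical_p == 0.0
        assert r2.p_display == "< 0.01"


def _two_gene_focal_setup():
    """Two ZF genes (one KRAB), each with exactly one focal-context p9 site."""
    protein = "M" + "CAACAAAAAAAAALAAHAAAH"
    codons = {"M": "ATG", "C": "TGT", "A": "GCT", "L": "CTG", "H": "CAC"}
    parts = [codons[a] for a in protein]
    parts[19] = "GCA"
    cds = "".join(parts) + "TAA"
    g1 = make_gene("ZF1", cds, is_krab=True)
    g2 = make_gene("ZF2", cds, is_krab=False)
    models = {"ZF1": g1, "ZF2": g2}
    domains = {g: find_zf_domains(models[g].protein_seq, gene_id=g)
               for g in models}
    sites = focal_codon_sites(models, domains, 9)
    return models, domains, sites


class TestSiteRestrictedPermutation:
    def test_two_mutations_two_sites_expectations(self):
        models, domains, sites = _two_gene_focal_setup()
        focal = 19 * 3 + 2
        muts = [make_mutation(sample="S1", gene="ZF1", cds_pos=focal,
                              protein_pos=20, ref="C", alt="T", context="GCA",
                              consequence=MISSENSE),
                make_mutation(sample="S2", gene="ZF1", cds_pos=focal,
                              protein_pos=20, ref="C", alt="T", context="GCA",
                              consequence=MISSENSE)]
        res = site_restricted_permutation(muts, sites, models,
                                          n_permutations=20_000, seed=2)
        genes = res["n_distinct_genes"]
        # each mutation lands on one of 2 context-matching sites (one per gene)
        assert genes.null_mean == pytest.approx(1.5, abs=0.02)
        assert genes.observed == 1.0
        # lower-tail p = P(null <= 1) = P(both in one gene) = 1/2
        assert genes.empirical_p == pytest.approx(0.5, abs=0.02)
        krab = res["krab_fraction"]
        assert krab.observed == 1.0
        assert krab.null_mean == pytest.approx(0.5, abs=0.02)

    def test_all_sites_in_krab_genes_degenerate(self):
        models, domains, sites = _two_gene_focal_setup()
        models["ZF2"].is_krab = True
        sites = focal_codon_sites(models, domains, 9)
        focal = 19 * 3 + 2
        muts = [make_mutation(gene="ZF1", cds_pos=focal, protein_pos=20,
                              ref="C", alt="T", context="GCA",
                              consequence=MISSENSE)]
        res = site_restricted_permutation(muts, sites, models,
                                          n_permutations=200, seed=0)
        assert np.all(res["krab_fraction"].null_values == 1.0)
        assert res["krab_fraction"].empirical_p == 1.0

    def test_unknown_statistic_rejected(self):
        models, domains, sites = _two_gene_focal_setup()
        with pytest.raises(InputError, match="unknown"):
            site_restricted_permutation([], sites, models,
                                        statistics=("nope",), seed=0)


class TestPoissonBinomial:
    @pytest.mark.parametrize("p,k,expected", [
        ((0.5, 0.5), 2, 0.25),
        ((0.1, 0.2), 1, 0.28),
        ((0.3,), 0, 1.0),
        ((0.3,), 2, 0.0),
    ])
    def test_closed_forms(self, p, k, expected):
        assert poisson_binomial_tail(p, k) == pytest.approx(expected, abs=1e-14)

    def test_equal_p_reduces_to_binomial(self):
        rng = np.random.default_rng(0)
        for n in (5, 50, 400):
            q = float(rng.uniform(0.01, 0.5))
            for k in (0, 1, n // 2, n):
                got = poisson_binomial_tail(np.full(n, q), k)
                assert got == pytest.approx(float(stats.binom.sf(k - 1, n, q)),
                                            abs=1e-12)

    def test_invalid_probability_rejected(self):
        with pytest.raises(InputError):
            poisson_binomial_tail([0.5, 1.2], 1)

    def test_refined_normal_close_to_exact(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(0.0, 0.3, size=2000)
        k = int(p.sum() + 2 * np.sqrt((p * (1 - p)).sum()))
        exact = poisson_binomial_tail(p, k, exact=True)
        approx = poisson_binomial_tail(p, k, exact=False)
        assert approx == pytest.approx(exact, rel=0.05)


class TestContextRates:
    def test_strand_collapse_in_channel_tables(self):
        _, pair_ok = channel_tables([Channel("AGA", "T")])
        assert pair_ok[context_code("AGA"), "ACGT".index("T")]
        assert pair_ok[context_code("TCT"), "ACGT".index("A")]
        assert not pair_ok[context_code("AGA"), "ACGT".index("C")]

    def test_rates_counts_and_zero_mutation_sample(self):
        # gene of 34 codons: AGA context occurs at known sites
        cds = "ATG" + "AGA" * 32 + "TAA"
        gene = make_gene("G1", cds)
        n_sites = count_eligible_sites({"G1": gene}, [Channel("AGA", "T")])
        assert n_sites == len(eligible_positions(cds, "AGA"))
        muts = [make_mutation(sample="S1", gene="G1", cds_pos=8, ref="G",
                              alt="T", context="AGA"),
                make_mutation(sample="S1", gene="G1", cds_pos=11, ref="G",
                              alt="T", context="AGA"),
                make_mutation(sample="S1", gene="G1", cds_pos=14, ref="G",
                              alt="C", context="AGA")]   # wrong alt, not counted
        rates, n = compute_context_rates(muts, {"G1": gene},
                                         [Channel("AGA", "T")], ["S1", "S2"])
        assert n == n_sites
        assert rates["S1"] == pytest.approx(2 / n_sites)
        assert rates["S2"] == 0.0

    def test_no_eligible_sites_is_error(self):
        gene = make_gene("G1", "ATGTAA")
        with pytest.raises(InputError):
            compute_context_rates([], {"G1": gene}, [Channel("CCC", "T")], ["S1"])


class TestContextRateTest:
    def test_single_sample_closed_form(self):
        t = context_rate_test(5, {"S1": 0.02}, 2)
        assert t.expected == pytest.approx(0.1)
        assert t.fold == pytest.approx(20.0)
        expected_p = 1 - 0.98 ** 5 - 5 * 0.02 * 0.98 ** 4
        assert t.p_value == pytest.approx(expected_p, rel=1e-10)

    def test_zero_observed_gives_p_one(self):
        assert context_rate_test(3, {"S1": 0.5}, 0).p_value == 1.0

    def test_two_sample_matches_tail_example(self):
        t = context_rate_test(1, {"S1": 0.1, "S2": 0.2}, 1)
        assert t.p_value == pytest.approx(0.28, abs=1e-12)

    def test_observed_beyond_trials_rejected(self):
        with pytest.raises(InputError):
            context_rate_test(2, {"S1": 0.1}, 3)
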