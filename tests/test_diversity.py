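import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from popconserve import (
    SimConfig,
    effective_allele_number,
    expected_heterozygosity,
    hwe_exact_test,
    locus_frequencies,
    ne_from_ld,
    observed_heterozygosity,
    pic,
    proportion_polymorphic,
    simulate_population,
)
from popconserve.diversity import DiversityError, sved_ne
from popconserve.genotypes import MISSING

from conftest import make_gm
from oracles import (
    brute_locus_stats,
    hwe_exact_fraction,
    hwe_exact_slots,
    sample_null_hwe_pvalues,
)


class TestFormulaExamples:
    @pytest.mark.parametrize(
        "freqs, expected",
        [
            ((0.5, 0.5), 0.375),
            ((1.0,), 0.0),
            ((0.9, 0.1), 1 - 0.82 - 2 * 0.81 * 0.01),
        ],
    )
    def test_pic(self, freqs, expected):
        assert pic(freqs) == pytest.approx(expected, abs=1e-15)

    @pytest.mark.parametrize(
        "freqs, expected", [((0.5, 0.5), 2.0), ((1.0,), 1.0), ((0.9, 0.1), 1 / 0.82)]
    )
    def test_effective_allele_number(self, freqs, expected):
        assert effective_allele_number(freqs) == pytest.approx(expected, abs=1e-15)

    @pytest.mark.parametrize(
        "freqs, expected", [((0.5, 0.5), 0.5), ((0.9, 0.1), 0.18)]
    )
    def test_expected_heterozygosity(self, freqs, expected):
        assert expected_heterozygosity(freqs) == pytest.approx(expected, abs=1e-15)

    def test_unbiased_he_correction(self):
        he = expected_heterozygosity((0.5, 0.5), unbiased=True, n=10)
        assert he == pytest.approx(0.5 * 20 / 19)

    def test_locus_frequencies_with_missing(self):
        p, maf, n = locus_frequencies(np.array([0, 1, 2, 2, MISSING]))
        assert (p, maf, n) == (0.625, 0.375, 4)

    def test_all_reference_column(self):
        _, maf, _ = locus_frequencies(np.zeros(8, dtype=np.int8))
        assert maf == 0.0

    def test_all_het_column_is_half(self):
        p, maf, _ = locus_frequencies(np.ones(6, dtype=np.int8))
        assert p == 0.5 and maf == 0.5

    def test_observed_heterozygosity(self):
        assert observed_heterozygosity(np.array([1, 1, 1, 1])) == 1.0
        assert observed_heterozygosity(np.array([0, 1, 2, 0, MISSING])) == 0.25

    @pytest.mark.parametrize(
        "func", [locus_frequencies, observed_heterozygosity]
    )
    def test_all_missing_column_undefined(self, func):
        with pytest.raises(DiversityError):
            func(np.full(5, MISSING))

    def test_freqs_not_summing_to_one_rejected(self):
        for func in (pic, expected_heterozygosity, effective_allele_number):
            with pytest.raises(DiversityError):
                func((0.5, 0.4))


class TestBruteForceAgreement:
    def test_randomized_loci_match_direct_recomputation(self, rng):
        for _ in range(300):
            n = int(rng.integers(4, 40))
            p_true = rng.uniform(0.05, 0.95)
            col = rng.binomial(1, p_true, size=(n, 2)).sum(axis=1)
            col[rng.random(n) < 0.1] = MISSING
            if (col == MISSING).all():
                continue
            p, maf, _ = locus_frequencies(col)
            bp, bmaf, bho, bhe, bpic, bae = brute_locus_stats(col)
            assert p == pytest.approx(bp, abs=1e-12)
            assert maf == pytest.approx(bmaf, abs=1e-12)
            assert observed_heterozygosity(col) == pytest.approx(bho, abs=1e-12)
            freqs = (1 - p, p)
            assert expected_heterozygosity(freqs) == pytest.approx(bhe, abs=1e-12)
            assert pic(freqs) == pytest.approx(bpic, abs=1e-12)
            assert effective_allele_number(freqs) == pytest.approx(bae, abs=1e-12)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(maf=st.floats(0.0, 0.5))
    def test_pic_he_maf_ordering_invariant(self, maf):
        """For any biallelic locus PIC <= He <= 2*MAF, with equality at
        the boundary frequencies."""
        freqs = (1 - maf, maf)
        v_pic, v_he = pic(freqs), expected_heterozygosity(freqs)
        assert v_pic <= v_he + 1e-15
        assert v_he <= 2 * maf + 1e-15
        if maf == 0.0:
            assert v_pic == v_he == 0.0
        if maf == 0.5:  # both statistics attain their biallelic maxima
            assert v_he == pytest.approx(0.5) and v_pic == pytest.approx(0.375)


class TestProportionPolymorphic:
    def test_all_monomorphic_is_zero(self):
        assert proportion_polymorphic([0.0] * 5) == 0.0

    def test_zero_threshold_counts_strictly_positive(self):
        assert proportion_polymorphic([0.0, 0.001, 0.3], threshold=0.0) == pytest.approx(2 / 3)

    def test_planted_below_threshold(self):
        mafs = [0.2] * 17 + [0.01] * 3
        assert proportion_polymorphic(mafs, threshold=0.05) == pytest.approx(0.85)

    def test_boundary_counts_as_polymorphic(self):
        assert proportion_polymorphic([0.05], threshold=0.05) == 1.0


class TestHWEExactTest:
    def test_monomorphic_is_one(self):
        assert hwe_exact_test(10, 0, 0) == 1.0
        assert hwe_exact_test(0, 0, 7) == 1.0

    def test_two_hets_two_individuals_full_enumeration(self):
        # alleles 2A/2B over 2 individuals: het counts {0, 2} with
        # weights 2 and 4; observing 2 hets -> p = 1 by slot enumeration
        assert hwe_exact_test(0, 2, 0) == pytest.approx(
            hwe_exact_slots(0, 2, 0), abs=1e-15
        )

    @pytest.mark.parametrize(
        "table", [(5, 10, 5), (0, 1, 0), (3, 0, 3), (12, 2, 1), (1, 7, 1)]
    )
    def test_matches_rational_oracle(self, table):
        assert hwe_exact_test(*table) == pytest.approx(
            hwe_exact_fraction(*table), abs=1e-10
        )

    def test_matches_slot_enumeration_for_tiny_n(self):
        for n in range(1, 7):
            for naa in range(n + 1):
                for nab in range(n - naa + 1):
                    nbb = n - naa - nab
                    assert hwe_exact_test(naa, nab, nbb) == pytest.approx(
                        hwe_exact_slots(naa, nab, nbb), abs=1e-12
                    )

    def test_null_distribution_matches_exact_reference(self, rng):
        """Under simulated HWE the p-value distribution coincides with
        the exact conditional null (two-sample KS); the raw distribution
        is super-uniform, as expected of a discrete exact test."""
        n = 25
        obs = []
        for _ in range(800):
            p = rng.uniform(0.1, 0.5)
            g = rng.binomial(1, p, size=(n, 2)).sum(axis=1)
            obs.append(
                hwe_exact_test(
                    int((g == 0).sum()), int((g == 1).sum()), int((g == 2).sum())
                )
            )
        ref = sample_null_hwe_pvalues(n, 0.1, 0.5, 800, np.random.default_rng(7))
        assert stats.ks_2samp(np.array(obs), ref).pvalue > 0.01
        # validity: P(p <= alpha) <= alpha (+ Monte-Carlo slack)
        for alpha in (0.01, 0.05, 0.25):
            assert (np.array(obs) <= alpha).mean() <= alpha + 0.03

    def test_small_on_planted_disequilibrium(self):
        # strong heterozygote excess
        assert hwe_exact_test(0, 30, 0) < 1e-4
        # strong heterozygote deficit
        assert hwe_exact_test(15, 0, 15) < 1e-6

    def test_negative_counts_rejected(self):
        with pytest.raises(DiversityError):
            hwe_exact_test(-1, 2, 3)


class TestNeFromLD:
    def test_sved_closed_forms(self):
        assert sved_ne(1.0, 0.5) == 0.0
        assert sved_ne(0.2, 0.5) == pytest.approx(2.0)

    def test_unstructured_population_estimate_positive_finite(self):
        gm, _ = simulate_population(
            SimConfig(
                n_chrom=4, chrom_length_bp=50_000_000, n_snps=2_000,
                n_sire_families=0, n_daughters=0, target_froh=0.0, seed=13,
            )
        )
        for method in ("per_pair", "pooled"):
            est = ne_from_ld(gm, method=method)
            assert est.n_pairs > 0
            assert np.isfinite(est.ne) and est.ne > 0

    def test_no_eligible_pairs_is_error(self):
        gm = make_gm([[0, 1], [1, 0]], chroms=["1", "2"], positions=[100, 100])
        with pytest.raises(DiversityError, match="no eligible"):
            ne_from_ld(gm)
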