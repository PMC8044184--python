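"""Unit and property tests of the Bayesian likelihood model."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cohortsnv.model import (
    BASES,
    AlleleCounts,
    InvalidBaseError,
    LikelihoodPair,
    ModelParams,
    ReadObservation,
    SamplePileup,
    allele_counts,
    base_emission,
    estimate_tumor_allele,
    joint_marginal_over_z,
    likelihood_given_f,
    likelihood_pair,
    log_likelihood_z0,
    log_likelihood_z1,
    log_multinomial_coeff,
    omit_all_normal_samples,
    per_sample_support,
    phred_to_error_prob,
    somatic_posterior,
    tin_posterior,
)
from helpers import (
    brute_marginal_log,
    brute_somatic_posterior,
    brute_tin_score,
    grid_log_z1,
    make_pileup,
    rel_err_from_logs,
)


class TestBaseEmission:
    @pytest.mark.parametrize(
        "b, x, q, expected",
        [
            ("A", "A", 0.01, 0.99),
            ("G", "A", 0.01, 0.01 / 3),
            ("T", "C", 0.3, 0.1),
        ],
    )
    def test_match_and_mismatch(self, b, x, q, expected):
        assert base_emission(b, x, q) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("x", BASES)
    def test_normalizes_over_observed_bases(self, x):
        assert sum(base_emission(b, x, 0.2) for b in BASES) == pytest.approx(1.0)

    def test_rejects_non_canonical_base(self):
        with pytest.raises(InvalidBaseError):
            base_emission("N", "A", 0.01)


class TestLikelihoodGivenF:
    @pytest.mark.parametrize(
        "bases, f, expected",
        [
            (["T"], 1.0, 0.99),
            (["A"], 0.0, 0.99),  # base equals N
            (["T"], 0.5, 0.5 * 0.99 + 0.5 * 0.01 / 3),
        ],
    )
    def test_single_read(self, bases, f, expected):
        pileup = make_pileup(bases, 0.01)
        assert likelihood_given_f(pileup, f, "A", "T") == pytest.approx(
            expected, rel=1e-9
        )

    def test_off_allele_base_is_frequency_independent(self):
        pileup = make_pileup(["G"], 0.03)
        vals = {likelihood_given_f(pileup, f, "A", "T") for f in (0.0, 0.3, 1.0)}
        assert all(v == pytest.approx(0.01) for v in vals)

    def test_requires_distinct_alleles(self):
        with pytest.raises(ValueError):
            likelihood_given_f(make_pileup(["A"]), 0.5, "A", "A")


class TestMultinomialCoeff:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            (AlleleCounts(1, 1, 0), math.log(2)),
            (AlleleCounts(5, 0, 0), 0.0),
            (AlleleCounts(2, 2, 1), math.log(30)),  # 5!/(2!2!1!)
        ],
    )
    def test_examples(self, counts, expected):
        assert log_multinomial_coeff(counts) == pytest.approx(expected, abs=1e-12)


class TestLikelihoodZ0:
    def test_single_normal_read(self):
        assert log_likelihood_z0(make_pileup(["A"], 0.01), "A", "T") == pytest.approx(
            math.log(0.99)
        )

    def test_mixed_reads_include_multinomial_coefficient(self):
        # reads [N, T]: rho = 2, each factor 0.99 and 0.01/3
        pileup = make_pileup(["A", "T"], 0.01)
        expected = math.log(2 * 0.99 * (0.01 / 3))
        assert log_likelihood_z0(pileup, "A", "T") == pytest.approx(expected)

    def test_empty_pileup_is_certain(self):
        assert log_likelihood_z0(make_pileup([]), "A", "T") == 0.0


class TestLikelihoodZ1:
    def test_single_tumor_read_closed_form(self):
        # integral of the linear integrand over [eps, 1]:
        # (0.99 * (1 - eps^2)/2 + (0.01/3) * ((1 - eps) - (1 - eps^2)/2)) / (1 - eps)
        pileup = make_pileup(["T"], 0.01)
        got = math.exp(log_likelihood_z1(pileup, "A", "T", epsilon=0.05))
        assert got == pytest.approx(0.5213333333, rel=1e-9)

    def test_empty_pileup_is_certain(self):
        assert log_likelihood_z1(make_pileup([]), "A", "T") == 0.0

    def test_uniform_noise_equals_z0(self):
        # q = 0.75 makes the emission 0.25 for every base, so f drops out
        pileup = make_pileup(["A", "T", "G", "T"], 0.75)
        assert log_likelihood_z1(pileup, "A", "T") == pytest.approx(
            log_likelihood_z0(pileup, "A", "T"), rel=1e-12
        )

    def test_matches_dense_grid(self, rng):
        for _ in range(5):
            n = int(rng.integers(1, 120))
            bases = list(rng.choice(list(BASES), size=n))
            qs = list(map(float, 10.0 ** (-rng.uniform(0.5, 4, size=n))))
            pileup = make_pileup(bases, qs)
            got = log_likelihood_z1(pileup, "A", "C", 0.05)
            want = grid_log_z1(pileup, "A", "C", 0.05)
            assert rel_err_from_logs(got, want) < 1e-8

    def test_no_underflow_at_extreme_depth(self):
        pileup = make_pileup(["A"] * 9000 + ["T"] * 1000, 1e-5)
        for fn in (log_likelihood_z0, log_likelihood_z1):
            val = fn(pileup, "A", "T")
            assert math.isfinite(val)


class TestJointMarginal:
    def test_m1_collapses_to_binary_mixture(self):
        pair = LikelihoodPair(math.log(0.4), math.log(0.7))
        mu = 0.23
        got = math.exp(joint_marginal_over_z([pair], mu))
        assert got == pytest.approx((1 - mu) * 0.4 + mu * 0.7, rel=1e-12)

    def test_mu_zero_is_product_of_null_likelihoods(self):
        pairs = [LikelihoodPair(math.log(0.5), math.log(0.9))] * 4
        assert joint_marginal_over_z(pairs, 0.0) == pytest.approx(4 * math.log(0.5))

    def test_three_sample_enumeration(self):
        pairs = [LikelihoodPair(math.log(0.5), math.log(0.25))] * 3
        got = joint_marginal_over_z(pairs, 0.1)
        assert rel_err_from_logs(got, brute_marginal_log(pairs, 0.1)) < 1e-12

    def test_rejects_empty_cohort(self):
        with pytest.raises(ValueError):
            joint_marginal_over_z([], 0.1)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        m=st.integers(1, 8),
        mu=st.floats(0.0, 0.999),
        seed=st.integers(0, 2**31 - 1),
    )
    def test_matches_enumeration_randomized(self, m, mu, seed):
        r = np.random.default_rng(seed)
        pairs = [
            LikelihoodPair(float(a), float(b))
            for a, b in r.uniform(-60, 0, size=(m, 2))
        ]
        got = joint_marginal_over_z(pairs, mu)
        assert rel_err_from_logs(got, brute_marginal_log(pairs, mu)) < 1e-10


class TestSomaticPosterior:
    def test_mu_zero_gives_zero(self):
        cohort = [make_pileup(["T"] * 5 + ["A"] * 5)]
        params = ModelParams(mu=0.0)
        assert somatic_posterior(cohort, "A", params).somatic_prob == 0.0

    def test_sample_permutation_invariance(self):
        cohort = [
            make_pileup(["T"] * 3 + ["A"] * 20, sample_id="a"),
            make_pileup(["T"] * 8 + ["A"] * 10, sample_id="b"),
            make_pileup(["G"] * 2 + ["A"] * 25, sample_id="c"),
        ]
        params = ModelParams()
        p1 = somatic_posterior(cohort, "A", params).somatic_prob
        p2 = somatic_posterior(cohort[::-1], "A", params).somatic_prob
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_strong_signal_matches_enumeration(self):
        cohort = [
            make_pileup(["T"] * 10 + ["A"] * 20, sample_id="a"),
            make_pileup(["T"] * 10 + ["A"] * 20, sample_id="b"),
        ]
        params = ModelParams(mu=1e-3)
        result = somatic_posterior(cohort, "A", params)
        assert result.somatic_prob >= 0.99
        brute_prob, brute_marg = brute_somatic_posterior(cohort, "A", mu=1e-3)
        assert result.somatic_prob == pytest.approx(brute_prob, abs=1e-9)
        for t in brute_marg:
            assert rel_err_from_logs(
                result.log_marginal_by_t[t], brute_marg[t]
            ) < 1e-6

    def test_uniform_noise_posterior_equals_prior(self):
        # With q = 0.75 every per-sample P0 equals P1, the joint marginal
        # telescopes to prod P0 and the posterior reduces to mu exactly.
        cohort = [make_pileup(["T", "G", "A", "C"], 0.75, sample_id=s)
                  for s in "ab"]
        params = ModelParams(mu=0.37)
        got = somatic_posterior(cohort, "A", params).somatic_prob
        assert got == pytest.approx(0.37, rel=1e-9)

    def test_appending_all_normal_sample_is_a_no_op_after_omission(self):
        cohort = [make_pileup(["T"] * 4 + ["A"] * 6, sample_id="a")]
        extra = make_pileup(["A"] * 30, sample_id="z")
        params = ModelParams()
        retained, _ = omit_all_normal_samples(cohort + [extra], "A")
        base = somatic_posterior(cohort, "A", params).somatic_prob
        assert somatic_posterior(retained, "A", params).somatic_prob == base

    def test_posterior_approaches_one_with_heavy_prior(self):
        cohort = [make_pileup(["T", "A", "A"])]
        assert somatic_posterior(
            cohort, "A", ModelParams(mu=0.999999)
        ).somatic_prob > 0.99


class TestTumorAlleleEstimate:
    def test_argmax(self):
        assert estimate_tumor_allele({"C": -10, "G": -5, "T": -20}, "A") == "G"

    def test_tie_breaks_lexicographically(self):
        assert estimate_tumor_allele({"C": -5.0, "G": -5.0, "T": -9.0}, "A") == "C"

    def test_requires_exactly_three_alternatives(self):
        with pytest.raises(ValueError):
            estimate_tumor_allele({"C": -1.0, "G": -2.0}, "A")

    def test_recovers_majority_non_reference_base(self):
        cohort = [
            make_pileup(["G"] * 6 + ["A"] * 20, 0.001, sample_id=s)
            for s in "abc"
        ]
        params = ModelParams()
        result = somatic_posterior(cohort, "A", params)
        assert estimate_tumor_allele(result.log_marginal_by_t, "A") == "G"
        _, brute_marg = brute_somatic_posterior(cohort, "A", params.mu)
        assert max(sorted(brute_marg), key=brute_marg.get) == "G"


class TestOmission:
    def test_retains_only_samples_with_non_normal_bases(self):
        cohort = [
            make_pileup(["A", "A", "A"], sample_id="s1"),
            make_pileup(["A", "T", "A"], sample_id="s2"),
        ]
        retained, omitted = omit_all_normal_samples(cohort, "A")
        assert [p.sample_id for p in retained] == ["s2"]
        assert omitted == ["s1"]

    def test_empty_pileup_counts_as_all_normal(self):
        retained, omitted = omit_all_normal_samples(
            [make_pileup([], sample_id="s1")], "A"
        )
        assert retained == [] and omitted == ["s1"]

    def test_all_samples_all_normal_yields_empty_cohort(self):
        cohort = [make_pileup(["A"] * 5, sample_id=s) for s in "ab"]
        retained, omitted = omit_all_normal_samples(cohort, "A")
        assert retained == [] and len(omitted) == 2


class TestTinPosterior:
    def test_clean_normal_scores_above_threshold(self):
        normal = make_pileup(["A"] * 30, 0.01, sample_id="n")
        tumor = [make_pileup(["T"] * 15 + ["A"] * 15, 0.01, sample_id="t")]
        params = ModelParams()
        score = tin_posterior(normal, tumor, "A", "T", params)
        assert score > 20
        brute = brute_tin_score(normal, tumor, "A", "T", params.mu)
        assert score == pytest.approx(brute, abs=1e-6)

    def test_contaminated_normal_scores_near_zero(self):
        normal = make_pileup(["T"] * 10 + ["A"] * 20, 0.01, sample_id="n")
        tumor = [make_pileup(["T"] * 15 + ["A"] * 15, 0.01, sample_id="t")]
        params = ModelParams()
        score = tin_posterior(normal, tumor, "A", "T", params)
        assert score < 20
        brute = brute_tin_score(normal, tumor, "A", "T", params.mu)
        assert score == pytest.approx(brute, abs=1e-6)

    def test_phred_mapping(self):
        # posterior 0.01 corresponds to a score of exactly 20
        assert -10 * math.log10(0.01) == pytest.approx(20.0)

    def test_permutation_invariance_over_tumor_samples(self):
        normal = make_pileup(["T"] * 2 + ["A"] * 28, sample_id="n")
        cohort = [
            make_pileup(["T"] * 5 + ["A"] * 10, sample_id="a"),
            make_pileup(["T"] * 2 + ["A"] * 20, sample_id="b"),
        ]
        params = ModelParams()
        s1 = tin_posterior(normal, cohort, "A", "T", params)
        s2 = tin_posterior(normal, cohort[::-1], "A", "T", params)
        assert s1 == pytest.approx(s2, rel=1e-12)


class TestPerSampleSupport:
    def test_all_normal_sample_never_supports(self):
        cohort = [make_pileup(["A"] * 10, sample_id="a")]
        assert per_sample_support(cohort, "A", "T", ModelParams()) == [0]

    def test_strong_tumor_evidence_supports(self):
        cohort = [make_pileup(["T"] * 10 + ["A"] * 10, sample_id="a")]
        assert per_sample_support(cohort, "A", "T", ModelParams()) == [1]

    def test_single_noisy_read_does_not_support(self):
        bases = ["T"] + ["A"] * 50
        qs = [0.2] + [0.001] * 50
        cohort = [make_pileup(bases, qs, sample_id="a")]
        assert per_sample_support(cohort, "A", "T", ModelParams()) == [0]


class TestInputValidation:
    def test_read_observation_rejects_bad_base(self):
        with pytest.raises(InvalidBaseError):
            ReadObservation(base="N", error_prob=0.01)

    def test_read_observation_rejects_bad_error_prob(self):
        with pytest.raises(ValueError):
            ReadObservation(base="A", error_prob=0.0)

    def test_phred_conversion_is_clamped(self):
        assert phred_to_error_prob(0) == 0.75
        assert phred_to_error_prob(200) == 1e-10
        assert phred_to_error_prob(20) == pytest.approx(0.01)

    def test_model_params_validation(self):
        with pytest.raises(ValueError):
            ModelParams(mu=1.0)
        with pytest.raises(ValueError):
            ModelParams(epsilon=0.0)

    def test_allele_counts_partition(self):
        pileup = make_pileup(["A", "T", "T", "G"], strands=[True, True, False, True])
        counts = allele_counts(pileup, "A", "T")
        assert (counts.d_n, counts.d_t, counts.d_e) == (1, 2, 1)
        assert (counts.fwd_t, counts.rev_t) == (1, 1)


class TestDeepCoverageConsistency:
    """Monte-Carlo calibration of the posterior at informative depth."""

    def test_posterior_separates_true_and_null_loci(self):
        r = np.random.default_rng(99)
        params = ModelParams(mu=1e-3)
        failures = 0
        n_each = 500
        for _ in range(n_each):
            # one clonal VAF in the informative range [0.1, 0.5] per locus;
            # right at VAF 0.1 a depth-60 pair occasionally draws too few
            # variant reads for any calibrated posterior to clear 0.99
            vaf = r.uniform(0.1, 0.5)
            cohort = []
            for s in range(2):
                n = 60
                n_t = r.binomial(n, vaf)
                cohort.append(make_pileup(["T"] * n_t + ["A"] * (n - n_t),
                                          0.01, sample_id=f"s{s}"))
            retained, _ = omit_all_normal_samples(cohort, "A")
            if retained:
                prob = somatic_posterior(retained, "A", params).somatic_prob
                if prob <= 0.99:
                    failures += 1
        for _ in range(n_each):
            cohort = []
            for s in range(2):
                bases = []
                for _ in range(60):
                    if r.random() < 0.01:
                        bases.append(str(r.choice(["C", "G", "T"])))
                    else:
                        bases.append("A")
                cohort.append(make_pileup(bases, 0.01, sample_id=f"s{s}"))
            retained, _ = omit_all_normal_samples(cohort, "A")
            if retained:
                prob = somatic_posterior(retained, "A", params).somatic_prob
                if prob >= 0.01:
                    failures += 1
        assert failures <= 0.01 * 2 * n_each
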