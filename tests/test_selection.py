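import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sigselect import (
    CancerInitiationModel,
    Channel,
    OccurrenceProbabilities,
    SignatureCatalog,
    channel_probability,
    conditional_probability,
    expected_incidence,
    fit_relative_risk,
    pairwise_selection_scan,
    poibin_pmf,
    poibin_two_tailed_test,
    select_comparable_samples,
    variance_explained,
)
from sigselect.exposures import ExposureVector


def brute_force_poibin(q):
    """Independent oracle: enumerate all 2^n Bernoulli outcomes."""
    n = len(q)
    pmf = np.zeros(n + 1)
    for bits in itertools.product([0, 1], repeat=n):
        p = 1.0
        for b, qi in zip(bits, q):
            p *= qi if b else 1 - qi
        pmf[sum(bits)] += p
    return pmf


class TestExpectedIncidence:
    def test_hand_computed_single_sequence(self):
        model = CancerInitiationModel(
            mutation_rates={"M": 0.01}, sequences=[["M"]], cancer_rates=[0.1]
        )
        assert expected_incidence(model, 10.0) == pytest.approx(0.01, abs=1e-15)

    def test_linearity_in_sequences(self):
        rates = {"A": 1e-3, "B": 2e-3}
        one = CancerInitiationModel(rates, [["A", "B"]], [0.05])
        two = CancerInitiationModel(rates, [["A", "B"], ["A", "B"]], [0.05, 0.05])
        assert expected_incidence(two, 7.0) == pytest.approx(
            2 * expected_incidence(one, 7.0)
        )

    def test_zero_time(self):
        model = CancerInitiationModel({"M": 0.01}, [["M"]], [0.1])
        assert expected_incidence(model, 0.0) == 0.0

    def test_factorial_denominator(self):
        # n = 2: I(t) = u1*u2*lambda*t^2 / 2
        model = CancerInitiationModel(
            {"A": 0.01, "B": 0.02}, [["A", "B"]], [0.1]
        )
        assert expected_incidence(model, 5.0) == pytest.approx(
            0.01 * 0.02 * 0.1 * 25 / 2
        )

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(ValueError):
            CancerInitiationModel({"M": 0.0}, [["M"]], [0.1])

    def test_mismatched_sequence_lengths_rejected(self):
        with pytest.raises(ValueError):
            CancerInitiationModel(
                {"A": 0.1, "B": 0.1}, [["A"], ["A", "B"]], [0.1, 0.1]
            )


class TestConditionalProbability:
    def test_symmetry_at_r_one(self):
        assert conditional_probability(1e-6, 1e-6, 1.0) == 0.5

    def test_hand_computed(self):
        assert conditional_probability(1e-6, 3e-6, 3.0) == pytest.approx(0.5)

    def test_large_r_limit(self):
        assert conditional_probability(1e-6, 1e-6, 1e12) == pytest.approx(1.0, abs=1e-9)

    def test_monotone_in_r(self):
        vals = [conditional_probability(2e-6, 5e-6, r) for r in (0.1, 1, 10, 100)]
        assert vals == sorted(vals)
        assert all(0 < v < 1 for v in vals)

    def test_invalid_r_rejected(self):
        with pytest.raises(ValueError):
            conditional_probability(1e-6, 1e-6, 0.0)

    def test_coincides_with_model_q(self):
        # substituting per-sample channel probabilities for rates gives the
        # same formula used by the relative-risk likelihood
        s = OccurrenceProbabilities("S", p1=0.003, p2=0.008, carries_m1=True)
        for r in (0.2, 1.0, 5.0):
            assert s.q_model(r) == pytest.approx(
                conditional_probability(0.003, 0.008, r), abs=1e-15
            )


class TestChannelProbability:
    def _vec(self, values, names):
        return ExposureVector(
            sample_id="S", signature_names=names, activity=np.asarray(values, float)
        )

    def test_single_signature(self, cosmic):
        e = self._vec(
            [1.0 if n == "Signature.1" else 0.0 for n in cosmic.names],
            list(cosmic.names),
        )
        ch = Channel.from_index(10)
        assert channel_probability(e, cosmic, ch) == pytest.approx(
            cosmic.probs[0, 10]
        )

    def test_uniform_two_signature_mixture(self):
        probs = np.zeros((2, 96))
        probs[0, 0] = 0.1
        probs[0, 1:] = 0.9 / 95
        probs[1, 0] = 0.3
        probs[1, 1:] = 0.7 / 95
        cat = SignatureCatalog(names=["a", "b"], probs=probs)
        e = self._vec([0.5, 0.5], ["a", "b"])
        assert channel_probability(e, cat, Channel.from_index(0)) == pytest.approx(0.2)

    def test_sums_to_one_over_channels(self, cosmic):
        rng = np.random.default_rng(3)
        e = self._vec(rng.dirichlet(np.ones(30)), list(cosmic.names))
        total = sum(
            channel_probability(e, cosmic, Channel.from_index(c)) for c in range(96)
        )
        assert total == pytest.approx(1.0, abs=1e-9)


class TestPoibinPmf:
    def test_half_half(self):
        np.testing.assert_allclose(poibin_pmf([0.5, 0.5]), [0.25, 0.5, 0.25])

    def test_point_mass(self):
        np.testing.assert_allclose(poibin_pmf([1.0, 1.0]), [0, 0, 1])

    def test_hand_computed(self):
        np.testing.assert_allclose(
            poibin_pmf([0.2, 0.7]), [0.24, 0.62, 0.14], atol=1e-15
        )

    def test_empty(self):
        np.testing.assert_allclose(poibin_pmf([]), [1.0])

    def test_matches_brute_force_seeded_grid(self):
        rng = np.random.default_rng(17)
        for n in range(1, 13):
            q = rng.uniform(size=n)
            np.testing.assert_allclose(
                poibin_pmf(q), brute_force_poibin(q), atol=1e-12
            )

    @given(
        st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=10)
    )
    @settings(max_examples=50, deadline=None)
    def test_sums_to_one(self, q):
        pmf = poibin_pmf(q)
        assert abs(pmf.sum() - 1.0) < 1e-12
        assert (pmf >= -1e-15).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            poibin_pmf([0.5, 1.5])


class TestPoibinTwoTailed:
    def test_tail_outcome(self):
        assert poibin_two_tailed_test([0.5, 0.5], 2) == pytest.approx(0.5)

    def test_mode_gives_one(self):
        assert poibin_two_tailed_test([0.5, 0.5], 1) == pytest.approx(1.0)

    def test_lower_bound_is_pmf(self):
        rng = np.random.default_rng(23)
        for _ in range(20):
            q = rng.uniform(size=rng.integers(2, 15))
            m = int(rng.integers(0, len(q) + 1))
            p = poibin_two_tailed_test(q, m)
            assert p >= poibin_pmf(q)[m] - 1e-12
            assert 0 < p <= 1

    def test_double_tail_variant(self):
        p = poibin_two_tailed_test([0.5, 0.5], 2, method="double_tail")
        assert p == pytest.approx(0.5)  # 2 * min(1, 0.25)

    def test_out_of_range_m_rejected(self):
        with pytest.raises(ValueError):
            poibin_two_tailed_test([0.5], 2)

    def test_null_calibration(self):
        # conservative under the discrete null
        rng = np.random.default_rng(7)
        q = rng.uniform(0.2, 0.8, size=25)
        reps = 5000
        draws = rng.uniform(size=(reps, len(q))) < q
        hits = sum(
            poibin_two_tailed_test(q, int(m1)) < 0.05 for m1 in draws.sum(axis=1)
        )
        assert hits / reps <= 0.06


class TestSelectComparableSamples:
    def test_exactly_one_rule(self):
        probs = {"A": (0.1, 0.2), "B": (0.1, 0.2), "C": (0.1, 0.2), "D": (0.1, 0.2)}
        included = select_comparable_samples(
            carriers_m1={"A", "B"},
            carriers_m2={"B", "C"},
            other_carriers=set(),
            channel_probs=probs,
        )
        ids = {s.sample_id for s in included}
        assert ids == {"A", "C"}  # B carries both, D neither

    def test_other_set_member_excludes(self):
        probs = {"A": (0.1, 0.2), "B": (0.1, 0.2)}
        included = select_comparable_samples(
            {"A", "B"}, set(), other_carriers={"B"}, channel_probs=probs
        )
        assert [s.sample_id for s in included] == ["A"]

    def test_zero_probability_excluded(self, caplog):
        probs = {"A": (0.0, 0.0)}
        with caplog.at_level("WARNING"):
            included = select_comparable_samples({"A"}, set(), set(), probs)
        assert included == []

    def test_q_formula(self):
        included = select_comparable_samples(
            {"A"}, set(), set(), {"A": (0.3, 0.1)}
        )
        assert included[0].q == pytest.approx(0.75)


class TestFitRelativeRisk:
    def _samples(self, n1, n2, p1=0.01, p2=0.01):
        out = [
            OccurrenceProbabilities(f"A{i}", p1, p2, carries_m1=True)
            for i in range(n1)
        ]
        out += [
            OccurrenceProbabilities(f"B{i}", p1, p2, carries_m1=False)
            for i in range(n2)
        ]
        return out

    def test_symmetric_case(self):
        rr = fit_relative_risk(self._samples(1, 1), seed=0)
        assert rr.r == pytest.approx(1.0, rel=1e-4)

    def test_two_to_one(self):
        # q = r/(1+r), L = q^2 (1-q) maximised at q = 2/3 -> r = 2
        rr = fit_relative_risk(self._samples(2, 1), seed=0)
        assert rr.r == pytest.approx(2.0, rel=1e-4)

    def test_grid_search_oracle(self):
        samples = self._samples(7, 3, p1=0.02, p2=0.005)
        rr = fit_relative_risk(samples, seed=0)
        # brute-force the likelihood on a fine log grid
        grid = np.exp(np.linspace(-12, 12, 200001))[:, None]
        p1 = np.array([s.p1 for s in samples])
        p2 = np.array([s.p2 for s in samples])
        y = np.array([s.carries_m1 for s in samples])
        q = grid * p1 / (grid * p1 + p2)
        ll = np.where(y, np.log(q), np.log(1 - q)).sum(axis=1)
        r_star = float(grid[int(np.argmax(ll)), 0])
        assert math.log(rr.r) == pytest.approx(math.log(r_star), abs=1e-3)

    def test_right_censored(self):
        rr = fit_relative_risk(self._samples(3, 0), seed=0)
        assert rr.censored == "right"
        assert math.isnan(rr.ci_high)

    def test_left_censored(self):
        rr = fit_relative_risk(self._samples(0, 3), seed=0)
        assert rr.censored == "left"

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            fit_relative_risk([], seed=0)

    def test_bootstrap_ci_brackets_estimate(self):
        rng = np.random.default_rng(8)
        samples = []
        for i in range(100):
            p1, p2 = rng.uniform(0.001, 0.02, size=2)
            q = 3 * p1 / (3 * p1 + p2)
            samples.append(
                OccurrenceProbabilities(f"S{i}", p1, p2, rng.uniform() < q)
            )
        rr = fit_relative_risk(samples, seed=1)
        assert rr.ci_low <= rr.r <= rr.ci_high

    def test_estimator_consistency(self):
        # spread of log r-hat around the truth shrinks as n grows
        r_true = 2.5

        def rmse(n, seed):
            rs = []
            rng = np.random.default_rng(seed)
            for _ in range(25):
                samples = []
                for i in range(n):
                    p1, p2 = rng.uniform(0.001, 0.02, size=2)
                    q = r_true * p1 / (r_true * p1 + p2)
                    samples.append(
                        OccurrenceProbabilities(f"S{i}", p1, p2, rng.uniform() < q)
                    )
                rs.append(math.log(fit_relative_risk(samples, bootstrap_iters=0, seed=0).r))
            return float(np.sqrt(np.mean((np.array(rs) - math.log(r_true)) ** 2)))

        errs = [rmse(n, 99) for n in (50, 200, 800)]
        assert errs[2] < errs[0]


class TestVarianceExplained:
    def test_perfect_fit(self):
        r2, sign = variance_explained([10, 20, 30], [0.1, 0.2, 0.3])
        assert r2 == pytest.approx(1.0)
        assert sign == 1.0

    def test_hand_computed_three_points(self):
        # closed-form OLS: R^2 = Sxy^2/(Sxx*Syy) = 15^2/(2 * 350/3) = 27/28
        r2, sign = variance_explained([10, 20, 25], [1, 2, 3])
        assert r2 == pytest.approx(27 / 28, abs=1e-12)
        assert sign == 1.0

    def test_null_near_zero(self):
        rng = np.random.default_rng(2)
        r2, _ = variance_explained(rng.uniform(size=500), rng.uniform(size=500))
        assert r2 < 0.02

    def test_constant_probabilities_rejected(self):
        with pytest.raises(ValueError):
            variance_explained([1, 2, 3], [0.5, 0.5, 0.5])

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            variance_explained([1, 2], [0.1, 0.2])


class TestPairwiseSelectionScan:
    def test_planted_risk_recovered(self):
        from sigselect import count_channels, filter_driver_nonsynonymous, fit_exposures
        from sigselect.simulate import simulate_cohort

        from conftest import equal_channel_cohort

        spec = equal_channel_cohort(4.0, n_samples=200, seed=42)
        records, truth = simulate_cohort(spec)
        drecs = filter_driver_nonsynonymous(records, {"G1", "G2"})
        fitted = fit_exposures(count_channels(records, exclude=drecs), spec.catalog)
        results = pairwise_selection_scan(
            drecs, fitted, spec.catalog, genes=["G1", "G2"],
            cancer_type="SYNTH", seed=0,
        )
        assert len(results) == 1
        r = results[0]
        rhat = r.relative_risk.r if r.m1_label.startswith("G1") else 1 / r.relative_risk.r
        assert abs(math.log(rhat / 4.0)) < 0.5
        assert r.significant

    def test_rare_mutation_excluded(self):
        from conftest import make_record

        # 9 occurrences in total: below the min_occurrence threshold
        recs = [
            make_record(sample=f"S{i}", ctype="X", pos=1, gene="G",
                        effect="nonsynonymous_SNV")
            for i in range(9)
        ]
        out = pairwise_selection_scan(
            recs, [], SignatureCatalog(["s"], np.full((1, 96), 1 / 96)),
            genes=["G"], cancer_type="X",
        )
        assert out == []

    def test_empty_when_no_mutations(self):
        out = pairwise_selection_scan(
            [], [], SignatureCatalog(["s"], np.full((1, 96), 1 / 96)),
            genes=["G"], cancer_type="X",
        )
        assert out == []
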