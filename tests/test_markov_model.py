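"""CTMC fitting: crude rates, panel likelihood, sojourns, NTRs, CI rules."""

import numpy as np
import pytest

from hypnomarkov.hypnogram_io import Hypnogram
from hypnomarkov.markov_model import (
    GeneratorMatrix,
    ModelSpec,
    NTREstimate,
    SojournEstimate,
    compare_estimates,
    crude_generator,
    fit_ctmc,
    normalized_transition_rates,
    panel_log_likelihood,
    sojourn_times,
    transition_matrix,
)
from hypnomarkov.synthetic_data import simulate_ctmc_hypnogram


def two_state_gen(a, b):
    return GeneratorMatrix.from_rates(
        ("WAKE", "SLEEP"), {("WAKE", "SLEEP"): a, ("SLEEP", "WAKE"): b}
    )


def closed_form_p(a, b, t):
    """Analytic transition matrix of the two-state chain."""
    s = a + b
    pws = a / s * (1 - np.exp(-s * t))
    psw = b / s * (1 - np.exp(-s * t))
    return np.array([[1 - pws, pws], [psw, 1 - psw]])


SPEC2 = ModelSpec(states=("WAKE", "SLEEP"), reference_group="HC-VEH")


class TestCrudeGenerator:
    def test_hand_counted_rates(self, two_state_hypnogram):
        # pairs: (W,W),(W,S),(S,S),(S,W) -> T_W = 8 s, N_WS = 1
        g = crude_generator([two_state_hypnogram], SPEC2)
        assert g.rate("WAKE", "SLEEP") == pytest.approx(0.125)
        assert g.rate("SLEEP", "WAKE") == pytest.approx(0.125)

    def test_constant_sequence_floored(self):
        h = Hypnogram(subject_id="c", group="HC-VEH", stages=("WAKE",) * 5)
        with pytest.raises(ValueError, match="SLEEP"):
            crude_generator([h], SPEC2)  # SLEEP never occupied

    def test_unobserved_transition_floored(self):
        h = Hypnogram(
            subject_id="c", group="HC-VEH", stages=("WAKE", "SLEEP", "SLEEP")
        )
        g = crude_generator([h], SPEC2)
        assert g.rate("SLEEP", "WAKE") == pytest.approx(1e-6)

    def test_pooling_is_additive(self):
        h1 = Hypnogram(subject_id="a", group="HC-VEH",
                       stages=("WAKE", "SLEEP", "WAKE", "WAKE"))
        h2 = Hypnogram(subject_id="b", group="HC-VEH",
                       stages=("WAKE", "WAKE", "SLEEP", "SLEEP"))
        # pooled: pairs starting in W: 4 (T_W=16), N_WS = 2
        g = crude_generator([h1, h2], SPEC2)
        assert g.rate("WAKE", "SLEEP") == pytest.approx(2 / 16)


class TestTransitionMatrix:
    def test_zero_generator_is_identity(self):
        g = GeneratorMatrix(states=("A", "B"), matrix=np.zeros((2, 2)))
        assert np.allclose(transition_matrix(g, 5.0), np.eye(2))

    @pytest.mark.parametrize("a,b,t", [
        (0.01, 0.02, 4.0), (1 / 174.131, 1 / 35.239, 4.0),
        (0.5, 0.1, 0.0), (2.0, 3.0, 10.0),
    ])
    def test_matches_two_state_closed_form(self, a, b, t):
        p = transition_matrix(two_state_gen(a, b), t)
        assert np.max(np.abs(p - closed_form_p(a, b, t))) < 1e-10

    def test_rows_sum_to_one_random_three_state(self, rng):
        for _ in range(20):
            q = rng.uniform(0.001, 0.5, size=(3, 3))
            np.fill_diagonal(q, 0.0)
            np.fill_diagonal(q, -q.sum(axis=1))
            g = GeneratorMatrix(states=("W", "N", "R"), matrix=q)
            p = transition_matrix(g, float(rng.uniform(0, 50)))
            assert np.max(np.abs(p.sum(axis=1) - 1)) < 1e-10
            assert np.all(p >= -1e-15) and np.all(p <= 1 + 1e-12)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            transition_matrix(two_state_gen(0.1, 0.1), -1.0)


class TestPanelLogLikelihood:
    def test_single_pair_same_state_zero_rates(self):
        h = Hypnogram(subject_id="x", group="HC-VEH", stages=("WAKE", "WAKE"))
        # tiny rates: log P_WW(4) ~ log(1) = 0
        ll = panel_log_likelihood(np.log([1e-12, 1e-12]), [h], SPEC2)
        assert ll == pytest.approx(0.0, abs=1e-9)

    def test_matches_closed_form_product(self):
        a, b = 0.03, 0.07
        h = Hypnogram(subject_id="x", group="HC-VEH",
                      stages=("WAKE", "SLEEP", "SLEEP"))
        p = closed_form_p(a, b, 4.0)
        expected = np.log(p[0, 1]) + np.log(p[1, 1])
        ll = panel_log_likelihood(np.log([a, b]), [h], SPEC2)
        assert ll == pytest.approx(expected, rel=1e-12)

    def test_optimum_is_local_maximum(self):
        h = simulate_ctmc_hypnogram(two_state_gen(0.01, 0.03), 40000, 4.0, 11,
                                    group="HC-VEH")
        fit = fit_ctmc([h], SPEC2)
        base = panel_log_likelihood(fit.params, [h], SPEC2)
        for k in range(2):
            for eps in (np.log(1.1), -np.log(1.1)):  # +/-10% on the intensity
                pert = fit.params.copy()
                pert[k] += eps
                assert panel_log_likelihood(pert, [h], SPEC2) <= base


class TestFit:
    def test_two_state_recovery_within_5pct(self):
        truth = two_state_gen(1 / 174.131, 1 / 35.239)
        data = [
            simulate_ctmc_hypnogram(truth, 20000, 4.0, np.random.default_rng([42, i]),
                                    subject_id=f"s{i}", group="HC-VEH")
            for i in range(12)
        ]
        fit = fit_ctmc(data, SPEC2)
        soj = {e.state: e.sojourn for e in sojourn_times(fit)}
        assert soj["WAKE"] == pytest.approx(174.131, rel=0.10)
        assert soj["SLEEP"] == pytest.approx(35.239, rel=0.10)
        assert fit.converged

    def test_missing_state_named_in_error(self):
        spec3 = ModelSpec(states=("WAKE", "NREM", "REM"), reference_group="HC-VEH")
        h = Hypnogram(subject_id="x", group="HC-VEH",
                      stages=("WAKE", "NREM") * 10)
        with pytest.raises(ValueError, match="REM"):
            fit_ctmc([h], spec3)

    def test_missing_group_rejected(self):
        spec = ModelSpec(states=("WAKE", "SLEEP"), reference_group="HC-VEH",
                         covariate_groups=("RD-VEH",))
        h = Hypnogram(subject_id="x", group="HC-VEH", stages=("WAKE", "SLEEP") * 5)
        with pytest.raises(ValueError, match="RD-VEH"):
            fit_ctmc([h], spec)

    def test_loglik_improves_on_crude_start(self):
        h = simulate_ctmc_hypnogram(two_state_gen(0.02, 0.05), 20000, 4.0, 3,
                                    group="HC-VEH")
        fit = fit_ctmc([h], SPEC2)
        assert fit.loglik >= fit.diagnostics["start_loglik"]

    def test_generator_rows_sum_to_zero(self):
        h = simulate_ctmc_hypnogram(two_state_gen(0.02, 0.05), 8000, 4.0, 5,
                                    group="HC-VEH")
        fit = fit_ctmc([h], SPEC2)
        q = fit.generator("HC-VEH").matrix
        assert np.max(np.abs(q.sum(axis=1))) < 1e-12
        p = transition_matrix(fit.generator("HC-VEH"), 4.0)
        assert np.max(np.abs(p.sum(axis=1) - 1)) < 1e-10

    def test_covariance_symmetric_psd(self):
        h = simulate_ctmc_hypnogram(two_state_gen(0.02, 0.05), 20000, 4.0, 6,
                                    group="HC-VEH")
        fit = fit_ctmc([h], SPEC2)
        assert np.allclose(fit.cov, fit.cov.T)
        assert np.min(np.linalg.eigvalsh(fit.cov)) >= -1e-10

    def test_parameter_count(self):
        spec2 = ModelSpec(states=("WAKE", "SLEEP"), reference_group="HC-VEH",
                          covariate_groups=("A", "B", "C"))
        assert spec2.n_free_parameters == 8
        spec3 = ModelSpec(states=("WAKE", "NREM", "REM"), reference_group="HC-VEH",
                          covariate_groups=("A", "B", "C"))
        assert spec3.n_free_parameters == 24


class TestSojourns:
    def test_reciprocal_of_exit_rates(self):
        h = simulate_ctmc_hypnogram(two_state_gen(0.02, 0.08), 20000, 4.0, 9,
                                    group="HC-VEH")
        fit = fit_ctmc([h], SPEC2)
        g = fit.generator("HC-VEH")
        soj = {e.state: e for e in sojourn_times(fit)}
        for state in ("WAKE", "SLEEP"):
            assert soj[state].sojourn == pytest.approx(
                1.0 / g.exit_rates()[g.states.index(state)]
            )
            assert 0 < soj[state].ci_low <= soj[state].sojourn <= soj[state].ci_high

    def test_point_sojourn_from_fixed_generator(self):
        g = two_state_gen(1 / 174.131, 1 / 35.239)
        assert g.sojourns()["WAKE"] == pytest.approx(174.131)
        assert GeneratorMatrix.from_rates(
            ("A", "B"), {("A", "B"): 0.1, ("B", "A"): 0.1}
        ).sojourns()["A"] == pytest.approx(10.0)

    def test_ci_narrows_with_more_subjects(self):
        truth = two_state_gen(0.01, 0.03)
        def width(n_subj, seed):
            data = [
                simulate_ctmc_hypnogram(truth, 10000, 4.0,
                                        np.random.default_rng([seed, i]),
                                        subject_id=f"s{i}", group="HC-VEH")
                for i in range(n_subj)
            ]
            fit = fit_ctmc(data, SPEC2)
            e = next(s for s in sojourn_times(fit) if s.state == "WAKE")
            return np.log(e.ci_high) - np.log(e.ci_low)
        assert width(16, 21) < width(4, 22)


class TestNTR:
    def _fit_two_groups(self, mult, seed, n=8, duration=20000):
        ref = two_state_gen(1 / 174.131, 1 / 35.239)
        test = two_state_gen(mult[0] / 174.131, mult[1] / 35.239)
        data = []
        for i in range(n):
            data.append(simulate_ctmc_hypnogram(
                ref, duration, 4.0, np.random.default_rng([seed, 0, i]),
                subject_id=f"r{i}", group="HC-VEH"))
            data.append(simulate_ctmc_hypnogram(
                test, duration, 4.0, np.random.default_rng([seed, 1, i]),
                subject_id=f"t{i}", group="RD-SSRI"))
        spec = ModelSpec(states=("WAKE", "SLEEP"), reference_group="HC-VEH",
                         covariate_groups=("RD-SSRI",))
        return fit_ctmc(data, spec)

    def test_reference_rows_are_exactly_one(self):
        fit = self._fit_two_groups((0.821, 1.384), 31, n=3, duration=5000)
        for e in normalized_transition_rates(fit):
            if e.group == "HC-VEH":
                assert e.ntr == 1.0
                assert e.ci_low is None and e.ci_high is None

    def test_beta_zero_means_unit_ntr(self):
        fit = self._fit_two_groups((1.0, 1.0), 32, n=3, duration=5000)
        forced = fit.params.copy()
        forced[2:] = 0.0
        fit2 = type(fit)(spec=fit.spec, params=forced, param_names=fit.param_names,
                         cov=fit.cov, loglik=fit.loglik, converged=True)
        for e in normalized_transition_rates(fit2):
            if e.group != "HC-VEH":
                assert e.ntr == pytest.approx(1.0)
                assert e.ci_low * e.ci_high == pytest.approx(1.0, rel=1e-9)

    def test_recovers_multiplier(self):
        fit = self._fit_two_groups((0.821, 1.384), 33)
        ntr = {(e.from_state, e.to_state): e for e in normalized_transition_rates(fit)
               if e.group == "RD-SSRI"}
        e = ntr[("WAKE", "SLEEP")]
        assert e.ntr == pytest.approx(0.821, rel=0.25)
        assert e.ci_low <= 0.821 <= e.ci_high


class TestCompareEstimates:
    def test_published_style_disjoint_intervals(self):
        a = SojournEstimate(state="REM", group="RD-VEH",
                            sojourn=20.999, ci_low=18.379, ci_high=23.994)
        b = SojournEstimate(state="REM", group="HC-SSRI",
                            sojourn=65.816, ci_low=54.183, ci_high=79.946)
        assert compare_estimates(a, b) is True

    def test_identical_intervals_not_significant(self):
        a = SojournEstimate("W", "g1", 10.0, 8.0, 12.0)
        b = SojournEstimate("W", "g2", 10.0, 8.0, 12.0)
        assert compare_estimates(a, b) is False

    def test_shared_endpoint_counts_as_overlap(self):
        a = SojournEstimate("W", "g1", 10.0, 8.0, 12.0)
        b = SojournEstimate("W", "g2", 14.0, 12.0, 16.0)
        assert compare_estimates(a, b) is False

    def test_reference_ntr_has_no_ci(self):
        e = NTREstimate("W", "S", "HC-VEH", 1.0, None, None, False)
        other = NTREstimate("W", "S", "RD-VEH", 0.5, 0.3, 0.8, True)
        with pytest.raises(ValueError):
            compare_estimates(e, other)
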