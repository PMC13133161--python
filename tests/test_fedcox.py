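import math

import numpy as np
import pytest

from fedsurv.errors import (
    ContractError,
    ConvergenceError,
    NoEventsError,
    SeparationError,
)
from fedsurv.fedcox import (
    CoxModelFit,
    EncodedCentre,
    collect_event_times,
    encode_centre,
    fit_federated_cox,
    fit_federated_cox_encoded,
    fit_pooled_cox_oracle,
    hazard_ratios,
    local_sufficient_statistics,
    server_update,
)
from fedsurv.messages import AuditLog


def _node(x, t, e, cid="n"):
    return EncodedCentre(cid, np.asarray(x, float).reshape(len(t), -1),
                         np.asarray(t, float), np.asarray(e, int))


def _split(enc: EncodedCentre, labels) -> list[EncodedCentre]:
    labels = np.asarray(labels)
    return [
        EncodedCentre(f"part{g}", enc.x[labels == g], enc.time[labels == g],
                      enc.event[labels == g])
        for g in np.unique(labels)
    ]


class TestEventTimeGrid:
    def test_union_of_node_event_times(self):
        a = _node([1, 1], [1.0, 3.0], [1, 1], "a")
        b = _node([1, 1], [3.0, 7.0], [1, 1], "b")
        assert np.array_equal(collect_event_times([a, b]), [1.0, 3.0, 7.0])

    def test_no_events_raises(self):
        a = _node([1.0], [5.0], [0], "a")
        with pytest.raises(NoEventsError):
            collect_event_times([a])

    def test_worked_cohort_grid(self, worked_node):
        assert np.array_equal(collect_event_times([worked_node]), [1.0, 2.0, 3.0])


class TestLocalStatistics:
    def test_unit_weights_at_beta_zero(self, worked_node):
        grid = collect_event_times([worked_node])
        st = local_sufficient_statistics(worked_node, np.zeros(1), grid)
        assert st.S0[0] == pytest.approx(3.0)  # everyone at risk at t=1
        assert st.S1[0, 0] == pytest.approx(2.0)  # covariate sum 1+0+1
        assert np.array_equal(st.d, [1, 1, 1])

    def test_exp_beta_weight(self):
        node = _node([1.0], [2.0], [1])
        st = local_sufficient_statistics(node, np.array([math.log(2.0)]),
                                         np.array([2.0]))
        assert st.S0[0] == pytest.approx(2.0)

    def test_dimension_mismatch(self, worked_node):
        with pytest.raises(ContractError):
            local_sufficient_statistics(worked_node, np.zeros(3),
                                        np.array([1.0, 2.0, 3.0]))

    def test_risk_sets_shrink(self, worked_node):
        grid = collect_event_times([worked_node])
        st = local_sufficient_statistics(worked_node, np.array([0.3]), grid)
        assert np.all(np.diff(st.S0) <= 1e-12)


class TestServerUpdate:
    def test_first_newton_step_closed_form(self, worked_node):
        grid = collect_event_times([worked_node])
        stats = [local_sufficient_statistics(worked_node, np.zeros(1), grid)]
        upd = server_update(stats, np.zeros(1))
        assert upd.score[0] == pytest.approx(-1.0 / 6.0, abs=1e-12)
        assert upd.information[0, 0] == pytest.approx(17.0 / 36.0, abs=1e-12)
        assert upd.beta[0] == pytest.approx(-6.0 / 17.0, abs=1e-10)

    def test_fixed_point_at_mle(self, worked_node):
        fit = fit_federated_cox_encoded([worked_node])
        grid = fit.event_times
        stats = [local_sufficient_statistics(worked_node, fit.beta, grid)]
        upd = server_update(stats, fit.beta)
        assert upd.beta[0] == pytest.approx(fit.beta[0], abs=1e-7)

    def test_split_nodes_aggregate_to_pooled(self, worked_node):
        grid = collect_event_times([worked_node])
        beta = np.array([0.25])
        pooled = server_update(
            [local_sufficient_statistics(worked_node, beta, grid)], beta
        )
        parts = _split(worked_node, [0, 0, 1])
        split = server_update(
            [local_sufficient_statistics(p, beta, grid) for p in parts], beta
        )
        assert split.score == pytest.approx(pooled.score, abs=1e-14)
        assert split.information == pytest.approx(pooled.information, abs=1e-14)
        assert split.loglik == pytest.approx(pooled.loglik, abs=1e-14)


class TestFederatedFit:
    def test_worked_cohort_analytic_mle(self, worked_node):
        fit = fit_federated_cox_encoded([worked_node])
        assert fit.converged
        assert fit.beta[0] == pytest.approx(-math.log(2.0) / 2.0, abs=1e-8)

    def test_partition_invariance(self, worked_node):
        # the same three patients split across two centres give the
        # same coefficient as the single-centre federation
        solo = fit_federated_cox_encoded([worked_node])
        for labels in ([0, 0, 1], [0, 1, 0], [0, 1, 1]):
            fed = fit_federated_cox_encoded(_split(worked_node, labels))
            assert fed.beta[0] == pytest.approx(solo.beta[0], abs=1e-10)
            assert fed.loglik == pytest.approx(solo.loglik, abs=1e-12)

    def test_matches_pooled_oracle_on_cohort(self, small_cohort, reduced_config):
        config = reduced_config
        fed = fit_federated_cox(small_cohort, config)
        oracle = fit_pooled_cox_oracle(small_cohort, config)
        assert np.max(np.abs(fed.beta - oracle.beta)) < 1e-6
        assert fed.loglik == pytest.approx(oracle.loglik, abs=1e-8)

    def test_oracle_agrees_with_lifelines_without_ties(self, small_cohort, reduced_config):
        # without tied event times the Breslow and Efron partial
        # likelihoods coincide, so an Efron-based library must
        # reproduce both coefficients and standard errors
        import pandas as pd
        from lifelines import CoxPHFitter

        config = reduced_config
        fed = fit_federated_cox(small_cohort, config)
        enc = [encode_centre(n, config) for n in small_cohort]
        times = np.concatenate([e.time for e in enc])
        assert len(np.unique(times)) == len(times)  # continuous: no ties
        df = pd.DataFrame(np.vstack([e.x for e in enc]), columns=config.covariates)
        df["time"] = times
        df["event"] = np.concatenate([e.event for e in enc])
        cph = CoxPHFitter()
        cph.fit(df, duration_col="time", event_col="event")
        # agreement limited by lifelines' own stopping rule (~1e-5)
        assert np.allclose(fed.beta, cph.params_.values, atol=1e-4)
        assert np.allclose(fed.se, cph.standard_errors_.values, rtol=1e-3)

    def test_single_centre_federation_is_local_fit(self, small_cohort, reduced_config):
        config = reduced_config
        solo = fit_federated_cox([small_cohort[0]], config)
        oracle = fit_pooled_cox_oracle(list(small_cohort[0].records), config)
        assert np.max(np.abs(solo.beta - oracle.beta)) < 1e-6

    def test_loglik_increases_across_iterations(self, small_cohort, reduced_config):
        # ascent property: refitting from the coarse one-step beta can
        # never decrease the partial likelihood at the optimum
        config = reduced_config
        fed = fit_federated_cox(small_cohort, config)
        enc = [encode_centre(n, config) for n in small_cohort]
        grid = collect_event_times(enc)
        stats0 = [local_sufficient_statistics(e, np.zeros(fed.beta.size), grid)
                  for e in enc]
        loglik0 = server_update(stats0, np.zeros(fed.beta.size)).loglik
        assert fed.loglik >= loglik0

    def test_separation_detected(self):
        # events confined to one dummy level: monotone likelihood
        rng = np.random.default_rng(0)
        n = 40
        x = np.zeros((n, 1))
        x[: n // 2, 0] = 1.0
        t = np.concatenate([rng.uniform(1, 5, n // 2), rng.uniform(6, 10, n // 2)])
        e = np.concatenate([np.ones(n // 2, int), np.zeros(n // 2, int)])
        with pytest.raises(SeparationError):
            fit_federated_cox_encoded([_node(x, t, e)])

    def test_audit_contains_only_aggregate_payloads(self, worked_node):
        audit = AuditLog()
        fit_federated_cox_encoded([worked_node], audit=audit)
        audit.assert_clean()
        kinds = set(audit.counts_by_kind())
        assert kinds <= {"event_times", "model_broadcast", "sufficient_statistics"}
        assert audit.counts_by_kind()["sufficient_statistics"] >= 2


class TestHazardRatios:
    def _fit(self, beta, var, converged=True):
        beta = np.asarray(beta, float)
        p = beta.size
        return CoxModelFit(
            beta=beta, covariance=np.diag(var), loglik=-1.0,
            score=np.zeros(p), n_iterations=5, converged=converged,
            event_times=np.array([1.0]), term_names=tuple(f"x{i}" for i in range(p)),
            n_total=10, n_events=5,
        )

    def test_wald_interval(self):
        table = hazard_ratios(self._fit([0.5], [0.01]))
        assert table.hr[0] == pytest.approx(1.6487, abs=2e-4)
        assert table.ci_low[0] == pytest.approx(math.exp(0.5 - 0.196), abs=2e-4)
        assert table.ci_high[0] == pytest.approx(math.exp(0.5 + 0.196), abs=2e-4)
        assert table.prognostic[0]

    def test_null_effect_not_prognostic(self):
        table = hazard_ratios(self._fit([0.0], [0.04]))
        assert table.hr[0] == 1.0
        assert table.ci_low[0] * table.ci_high[0] == pytest.approx(1.0)
        assert not table.prognostic[0]

    def test_wide_interval_not_prognostic(self):
        table = hazard_ratios(self._fit([-0.43], [1.0]))
        assert not table.prognostic[0]

    def test_nonconverged_fit_refused(self):
        with pytest.raises(ConvergenceError):
            hazard_ratios(self._fit([0.5], [0.01], converged=False))
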