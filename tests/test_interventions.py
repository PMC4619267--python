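import numpy as np
import pandas as pd
import pytest

from msabs import (
    InterventionSpec,
    average_covariate_shortcut,
    bootstrap_bands,
    fit_additive_constant,
    fit_cox_per_transition,
    gcomputation,
    ipw_analysis,
    ipw_weights,
    manipulate,
    nelson_aalen,
    product_integral,
    to_transition_rows,
)
from msabs.interventions import (
    PositivityError,
    SpecConflictError,
    default_report_grid,
    person_probability_paths,
)


@pytest.fixture(scope="module")
def marginal_A(markov_histories):
    return nelson_aalen(to_transition_rows(markov_histories[:800]))


class TestInterventionSpec:
    def test_json_round_trip(self):
        spec = InterventionSpec(
            kind="manipulate_intensity",
            actions=(("block", 1, 3), ("reroute", 4, 3, 2)),
        )
        assert InterventionSpec.from_json(spec.to_json()) == spec

    def test_reroute_onto_blocked_conflicts(self):
        with pytest.raises(SpecConflictError, match="blocked"):
            InterventionSpec(
                kind="manipulate_intensity",
                actions=(("block", 1, 2), ("reroute", 1, 3, 2)),
            )

    def test_invalid_reroute_target(self):
        with pytest.raises(SpecConflictError):
            InterventionSpec(
                kind="manipulate_intensity", actions=(("reroute", 1, 3, 1),)
            )

    def test_absorbing_state_protected(self):
        with pytest.raises(SpecConflictError):
            InterventionSpec(
                kind="manipulate_intensity", actions=(("block", 5, 1),)
            )


class TestManipulate:
    def test_empty_spec_is_bitwise_identity(self, marginal_A):
        out = manipulate(
            marginal_A, InterventionSpec(kind="manipulate_intensity")
        )
        assert (out.dA == marginal_A.dA).all()
        assert (out.times == marginal_A.times).all()

    def test_blocking_all_entries_into_disability(self, marginal_A):
        spec = InterventionSpec(
            kind="manipulate_intensity",
            actions=tuple(("block", h, 5) for h in (1, 2, 3, 4)),
        )
        P = product_integral(manipulate(marginal_A, spec))
        assert (P.matrices[:, :4, 4] == 0).all()  # no mass can enter state 5

    def test_reroute_conserves_exit_mass(self, marginal_A):
        # route transitions into full sick leave into partial sick leave
        # (from states where that is a genuine reroute)
        spec = InterventionSpec(
            kind="manipulate_intensity",
            actions=tuple(("reroute", h, 3, 2) for h in (1, 4)),
        )
        out = manipulate(marginal_A, spec)
        for h in (1, 4):
            # exit mass = minus diagonal; must be identical at every jump
            np.testing.assert_allclose(
                -out.dA[:, h - 1, h - 1],
                -marginal_A.dA[:, h - 1, h - 1],
                rtol=0,
                atol=1e-15,
            )
            assert (out.dA[:, h - 1, 2] == 0).all()

    def test_modularity_only_named_rows_change(self, marginal_A):
        spec = InterventionSpec(
            kind="manipulate_intensity", actions=(("block", 3, 4),)
        )
        out = manipulate(marginal_A, spec)
        # untouched rows are bitwise identical
        for h in (1, 2, 4, 5):
            assert (out.dA[:, h - 1, :] == marginal_A.dA[:, h - 1, :]).all()
        # in the touched row only (3,4) and the diagonal change
        for j in (1, 2, 5):
            assert (out.dA[:, 2, j - 1] == marginal_A.dA[:, 2, j - 1]).all()
        assert (out.dA[:, 2, 3] == 0).all()

    def test_wrong_spec_kind_rejected(self, marginal_A):
        with pytest.raises(SpecConflictError):
            manipulate(marginal_A, InterventionSpec(kind="set_exposure",
                                                    exposure_value=1))


class TestIpwWeights:
    def test_intercept_only_5050_gives_weight_two(self):
        table = pd.DataFrame({"exposure": [0, 1] * 50})
        ws = ipw_weights(table, "exposure", [])
        np.testing.assert_allclose(ws.weights.to_numpy(), 2.0, rtol=1e-6)

    def test_reciprocal_probability(self):
        # 1 exposed of 4 in z=0 -> P(E=1|z=0)=0.25 -> weight 4
        table = pd.DataFrame({"exposure": [1, 0, 0, 0], "z": [0.0] * 4})
        ws = ipw_weights(table, "exposure", [])
        assert ws.weights.iloc[0] == pytest.approx(4.0, rel=1e-4)

    def test_initial_state_target_restricted_to_contrast_states(self, markov_cohort):
        hists = markov_cohort.truth.histories()
        table = markov_cohort.covariates.assign(
            initial_state=[h.initial_state for h in hists]
        )
        ws = ipw_weights(table, "initial_state", ["z"], states=(2, 3))
        assert set(table.loc[ws.weights.index, "initial_state"]) == {2, 3}

    def test_balance_property(self, markov_cohort):
        # weighting removes the z -> exposure association built into the
        # confounded generator
        table = markov_cohort.covariates
        ws = ipw_weights(table, "exposure", ["z"])
        w = ws.weights.to_numpy()
        z = table["z"].to_numpy()
        e = table["exposure"].to_numpy()
        raw_diff = z[e == 1].mean() - z[e == 0].mean()
        m1 = np.average(z[e == 1], weights=w[e == 1])
        m0 = np.average(z[e == 0], weights=w[e == 0])
        se = np.sqrt(
            z[e == 1].var() / ws.diagnostics["effective_sample_size"] * 2
            + z[e == 0].var() / ws.diagnostics["effective_sample_size"] * 2
        )
        assert abs(raw_diff) > 0.05  # confounding is real before weighting
        assert abs(m1 - m0) < 3 * se

    def test_stabilized_weights_mean_near_one(self, markov_cohort):
        ws = ipw_weights(
            markov_cohort.covariates, "exposure", ["z"], stabilized=True
        )
        assert ws.weights.mean() == pytest.approx(1.0, abs=0.05)

    def test_positivity_warning_logged(self, caplog):
        rng = np.random.default_rng(0)
        z = rng.normal(0, 3, 400)
        p = 1 / (1 + np.exp(-3 * z))
        e = (rng.random(400) < p).astype(float)
        table = pd.DataFrame({"z": z, "exposure": e})
        with caplog.at_level("WARNING"):
            ipw_weights(table, "exposure", ["z"], floor=0.05)
        assert "positivity" in caplog.text


class TestIpwAnalysis:
    def test_unit_weights_bitwise_equal_unweighted(self, markov_cohort):
        hists = markov_cohort.truth.histories()[:400]
        exposed = [h for h in hists if h.covariates["exposure"] == 1]
        from msabs.interventions import WeightSet

        ones = WeightSet(
            weights=pd.Series(
                1.0, index=[h.person_id for h in hists], name="weight"
            ),
            target="exposure",
            coef=np.zeros(1),
            coef_names=("_intercept",),
        )
        P_w = ipw_analysis(
            hists, ones, InterventionSpec(kind="set_exposure", exposure_value=1)
        )
        P_u = product_integral(nelson_aalen(to_transition_rows(exposed)))
        assert (P_w.matrices == P_u.matrices).all()
        assert (P_w.times == P_u.times).all()

    def test_null_confounding_weighted_close_to_unweighted(self):
        from conftest import five_state_spec
        from msabs import simulate_cohort

        cohort = simulate_cohort(five_state_spec(1500, seed=5, confounded=False))
        hists = cohort.truth.histories()
        ws = ipw_weights(cohort.covariates, "exposure", ["z"])
        spec1 = InterventionSpec(kind="set_exposure", exposure_value=1)
        P_w = ipw_analysis(hists, ws, spec1)
        exposed = [h for h in hists if h.covariates["exposure"] == 1]
        P_u = product_integral(nelson_aalen(to_transition_rows(exposed)))
        for t in (180.0, 365.0):
            np.testing.assert_allclose(P_w.at(t), P_u.at(t), atol=0.02)

    def test_initial_state_scenario_uses_all_weighted_persons(self, markov_cohort):
        hists = markov_cohort.truth.histories()
        table = markov_cohort.covariates.assign(
            initial_state=[h.initial_state for h in hists]
        )
        ws = ipw_weights(table, "initial_state", ["z"], states=(2, 3))
        P = ipw_analysis(
            hists, ws, InterventionSpec(kind="set_initial_state", initial_state=3)
        )
        P.validate()
        assert P.provenance == "ipw:start=3"


class TestGComputation:
    def test_zero_exposure_coefficient_gives_exactly_zero_delta(
        self, markov_histories
    ):
        # models that do not reference the exposure at all: forcing it can
        # change nothing
        rows = to_transition_rows(markov_histories[:400], covariate_cols=["z"])
        models = fit_cox_per_transition(rows, ["z"])
        table = pd.DataFrame(
            {"z": [0.0, 1.0, 1.0], "exposure": [0.0, 1.0, 0.0]}
        )
        res = gcomputation(
            models,
            table,
            InterventionSpec(kind="set_exposure", exposure_value=1),
            destination=1,
            anchor=4,
            report_times=np.array([100.0, 365.0]),
        )
        assert (res.contrast.delta == 0).all()

    def test_single_person_cohort_mean_is_own_curve(self, markov_cohort):
        rows = to_transition_rows(
            markov_cohort.truth.histories()[:600], covariate_cols=["z", "exposure"]
        )
        models = fit_cox_per_transition(rows, ["z", "exposure"])
        table = markov_cohort.covariates.iloc[[0]]
        times = np.array([100.0, 365.0])
        res = gcomputation(
            models,
            table,
            InterventionSpec(kind="set_exposure", exposure_value=1),
            destination=1,
            anchor=3,
            report_times=times,
        )
        own = person_probability_paths(
            models, table.assign(exposure=1.0), 3, times
        )[0]
        np.testing.assert_allclose(res.scenario_curves[1], own)

    def test_initial_state_contrast_direction(self, markov_cohort):
        rows = to_transition_rows(
            markov_cohort.truth.histories()[:600], covariate_cols=["z", "exposure"]
        )
        models = fit_cox_per_transition(rows, ["z", "exposure"])
        times = np.array([180.0])
        res = gcomputation(
            models,
            markov_cohort.covariates.iloc[:100],
            InterventionSpec(kind="set_initial_state", initial_state=3),
            destination=1,
            anchor_pair=(3, 2),
            report_times=times,
        )
        assert res.contrast.delta[0] == pytest.approx(
            res.scenario_curves[3][0, 0] - res.scenario_curves[2][0, 0]
        )

    def test_missing_model_covariate_errors(self, markov_histories):
        rows = to_transition_rows(markov_histories[:200], covariate_cols=["z"])
        models = fit_cox_per_transition(rows, ["z"])
        with pytest.raises(KeyError, match="z"):
            gcomputation(
                models,
                pd.DataFrame({"exposure": [0.0]}),
                InterventionSpec(kind="set_exposure", exposure_value=1),
                destination=1,
                anchor=1,
                report_times=np.array([10.0]),
            )

    def test_saturated_cohort_equals_stratified_average(self, markov_cohort):
        # one person per covariate pattern with equal counts: the G-comp mean
        # must equal the average of the per-stratum predictions
        rows = to_transition_rows(
            markov_cohort.truth.histories()[:600], covariate_cols=["z", "exposure"]
        )
        models = fit_cox_per_transition(rows, ["z", "exposure"])
        table = pd.DataFrame({"z": [0.0, 1.0], "exposure": [0.0, 0.0]})
        times = np.array([365.0])
        res = gcomputation(
            models,
            table,
            InterventionSpec(kind="set_exposure", exposure_value=1),
            destination=1,
            anchor=3,
            report_times=times,
        )
        per_stratum = [
            person_probability_paths(
                models, pd.DataFrame({"z": [zv], "exposure": [1.0]}), 3, times
            )[0, 0, 0]
            for zv in (0.0, 1.0)
        ]
        assert res.scenario_curves[1][0, 0] == pytest.approx(
            np.mean(per_stratum), abs=1e-12
        )


class TestAverageCovariateShortcut:
    @pytest.fixture(scope="class")
    def additive_models(self, markov_cohort):
        rows = to_transition_rows(
            markov_cohort.truth.histories(), covariate_cols=["z", "exposure"]
        )
        return fit_additive_constant(rows, ["z", "exposure"])

    def test_exact_when_covariates_constant(self, additive_models):
        table = pd.DataFrame({"z": [1.0] * 5, "exposure": [0.0] * 5})
        spec = InterventionSpec(kind="set_exposure", exposure_value=1)
        times = np.array([100.0, 365.0])
        full = gcomputation(
            additive_models, table, spec, destination=1, anchor=3,
            report_times=times,
        )
        short = average_covariate_shortcut(
            additive_models, table, spec, 1, 3, times
        )
        np.testing.assert_allclose(short.delta, full.contrast.delta, atol=1e-12)

    def test_heterogeneous_close_for_small_hazards(self, additive_models, markov_cohort):
        table = markov_cohort.covariates.iloc[:300]
        spec = InterventionSpec(kind="set_exposure", exposure_value=1)
        times = np.array([100.0, 365.0])
        full = gcomputation(
            additive_models, table, spec, destination=1, anchor=3,
            report_times=times,
        )
        short = average_covariate_shortcut(
            additive_models, table, spec, 1, 3, times
        )
        np.testing.assert_allclose(short.delta, full.contrast.delta, atol=5e-3)

    def test_cox_flagged_as_approximation(self, markov_cohort):
        rows = to_transition_rows(
            markov_cohort.truth.histories()[:400], covariate_cols=["z", "exposure"]
        )
        models = fit_cox_per_transition(rows, ["z", "exposure"])
        short = average_covariate_shortcut(
            models,
            markov_cohort.covariates.iloc[:100],
            InterventionSpec(kind="set_exposure", exposure_value=1),
            1,
            3,
            np.array([100.0]),
        )
        assert "approximation" in short.note


class TestBootstrap:
    def test_single_replicate_collapses_band(self):
        rng = np.random.default_rng(1)
        data = list(rng.normal(0, 1, 50))
        bands = bootstrap_bands(lambda s: np.array([np.mean(s)]), data, B=1, seed=9)
        assert bands.lo[0] == bands.hi[0]

    def test_same_seed_bitwise_reproducible(self):
        data = list(np.arange(30.0))
        b1 = bootstrap_bands(lambda s: np.array([np.mean(s)]), data, B=25, seed=4)
        b2 = bootstrap_bands(lambda s: np.array([np.mean(s)]), data, B=25, seed=4)
        assert (b1.lo == b2.lo).all() and (b1.hi == b2.hi).all()

    def test_band_contains_point_estimate_for_smooth_statistic(self):
        rng = np.random.default_rng(2)
        data = list(rng.normal(5, 1, 200))
        bands = bootstrap_bands(
            lambda s: np.array([np.mean(s)]), data, B=200, seed=3
        )
        assert bands.lo[0] < np.mean(data) < bands.hi[0]


def test_default_report_grid():
    g = default_report_grid(730.0)
    assert g[0] == 1.0
    assert np.all(np.diff(g[:364]) == 1.0)
    assert np.all(np.diff(g[365:]) == 30.0)
    assert g[-1] <= 730.0
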