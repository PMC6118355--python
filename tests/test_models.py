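"""Learning-model traces: update rules, indexing convention, invariants."""

import numpy as np
import pytest

from threatlearn import (
    CS_MINUS,
    CS_PLUS,
    MODELS,
    beta_trace,
    generate_design,
    hybrid_trace,
    null_traces,
    observation_variable,
    rw_trace,
)
from threatlearn.models import (
    DispatchError,
    ParameterError,
    hybrid_z_grid,
    rw_z_grid,
)

from conftest import make_sequence


class TestRescorlaWagner:
    def test_initial_value_both_cs(self):
        seq = make_sequence([CS_PLUS, CS_MINUS], [1, 0])
        z = rw_trace(seq, eta=0.3).z
        assert z[0] == 0.5 and z[1] == 0.5

    def test_single_update_after_reinforced_trial(self):
        # 0.5 + 0.3 * (1 - 0.5) = 0.65 on the next CS+ trial
        seq = make_sequence([CS_PLUS, CS_MINUS, CS_PLUS], [1, 0, 0])
        z = rw_trace(seq, eta=0.3).z
        assert z[2] == pytest.approx(0.65, abs=1e-12)

    def test_near_degenerate_rate_tracks_last_outcome(self):
        seq = make_sequence([CS_PLUS] * 5, [1, 0, 1, 1, 0])
        z = rw_trace(seq, eta=1 - 1e-12).z
        assert np.allclose(z[1:], [1, 0, 1, 1], atol=1e-9)

    @pytest.mark.parametrize("eta", [0.0, 1.0, -0.2, 1.3])
    def test_rate_outside_open_interval_rejected(self, eta):
        seq = make_sequence([CS_PLUS], [1])
        with pytest.raises(ParameterError):
            rw_trace(seq, eta)

    def test_cs_minus_decays_toward_zero(self, default_seq):
        z = rw_trace(default_seq, eta=0.2).z
        minus = ~default_seq.is_cs_plus
        zm = z[minus]
        assert np.all(np.diff(zm) <= 0) and zm[-1] < 0.01

    def test_values_stay_in_unit_interval(self, default_seq):
        z = rw_trace(default_seq, eta=0.7).z
        assert np.all((z >= 0) & (z <= 1))


class TestHybrid:
    def test_direct_substitution(self):
        # k=0.6, eta0=0.5, x0=0.5, reinforced CS+ first:
        # next eta = 0.6*|0.5-1| + 0.4*0.5 = 0.5 ; next x = 0.5 + 0.5*0.5 = 0.75
        seq = make_sequence([CS_PLUS, CS_PLUS], [1, 0])
        tr = hybrid_trace(seq, k=0.6, eta0=0.5)
        assert tr.eta[1] == pytest.approx(0.5, abs=1e-12)
        assert tr.x[1] == pytest.approx(0.75, abs=1e-12)

    def test_k_to_zero_limit_is_rw_with_rate_eta0(self, default_seq):
        tr = hybrid_trace(default_seq, k=1e-12, eta0=0.5)
        rw = rw_trace(default_seq, eta=0.5)
        assert np.allclose(tr.eta, 0.5, atol=1e-9)
        assert np.allclose(tr.x, rw.z, atol=1e-8)

    def test_associability_decays_on_unreinforced_run(self):
        # long run of CS- trials: once |x - u| < eta the associability
        # decreases monotonically (checked numerically)
        seq = make_sequence([CS_MINUS] * 60, [0] * 60)
        tr = hybrid_trace(seq, k=0.4, eta0=0.5)
        eta = tr.eta
        below = np.flatnonzero(np.abs(tr.x - 0) < eta)
        start = below[0]
        assert np.all(np.diff(eta[start:]) <= 1e-12)
        assert eta[-1] < eta[0]

    def test_value_update_uses_previous_associability(self):
        seq = make_sequence([CS_PLUS, CS_PLUS, CS_PLUS], [1, 1, 0])
        tr = hybrid_trace(seq, k=0.9, eta0=0.2)
        # second update must use eta after first trial (0.9*0.5+0.1*0.2=0.47),
        # not the freshly updated one
        x1 = 0.5 + 0.2 * (1 - 0.5)
        eta1 = 0.9 * 0.5 + 0.1 * 0.2
        assert tr.x[2] == pytest.approx(x1 + eta1 * (1 - x1), abs=1e-12)

    def test_k_outside_open_interval_rejected(self):
        seq = make_sequence([CS_PLUS], [1])
        with pytest.raises(ParameterError):
            hybrid_trace(seq, k=1.0)


class TestBetaBinomial:
    def test_uninformative_prior_on_first_trials(self):
        seq = make_sequence([CS_PLUS, CS_MINUS], [1, 0])
        tr = beta_trace(seq)
        assert np.allclose(tr.prior_mean, 0.5)
        assert np.allclose(tr.v, -np.log(2))

    def test_posterior_after_one_reinforced_trial(self):
        seq = make_sequence([CS_PLUS, CS_PLUS], [1, 0])
        tr = beta_trace(seq)
        assert tr.prior_mean[1] == pytest.approx(2 / 3, abs=1e-12)

    @pytest.mark.parametrize("n", [1, 5, 30])
    def test_cs_minus_prior_mean_after_n_trials(self, n):
        seq = make_sequence([CS_MINUS] * (n + 1), [0] * (n + 1))
        tr = beta_trace(seq)
        assert tr.prior_mean[n] == pytest.approx(1 / (n + 2), abs=1e-12)

    def test_terminal_counts_on_default_design(self, default_seq):
        # 40 US over 80 CS+ trials force Beta(41, 41)
        tr = beta_trace(default_seq)
        assert tr.final_counts[CS_PLUS] == (41.0, 41.0)
        a, b = tr.final_counts[CS_MINUS]
        assert (a, b) == (1.0, 81.0)

    def test_delta_rule_equivalence(self, default_seq):
        # prior-mean increments follow an RW update with effective learning
        # rate 1/(a+b+1), per CS
        tr = beta_trace(default_seq)
        for plus in (True, False):
            sel = np.flatnonzero(default_seq.is_cs_plus == plus)
            e = tr.prior_mean[sel]
            u = default_seq.us[sel]
            counts = 2 + np.arange(len(sel))  # a+b before each trial of this CS
            inc_expected = (u[:-1] - e[:-1]) / (counts[:-1] + 1)
            assert np.allclose(np.diff(e), inc_expected, atol=1e-14)


class TestNullModels:
    def test_nl_step_series(self, default_seq):
        z = null_traces(default_seq)[1].z
        assert np.array_equal(z, default_seq.is_cs_plus.astype(float))

    def test_un_prior_count_convention(self, default_seq):
        z = null_traces(default_seq)[0].z
        t = np.arange(1, 161)
        assert np.allclose(z, -np.log(t + 1), atol=1e-14)
        assert np.all(np.diff(z) < 0)

    def test_un_posterior_count_variant(self, default_seq):
        z = null_traces(default_seq, prior_counts=False)[0].z
        assert z[0] == pytest.approx(-np.log(3))


class TestObservationVariable:
    def test_dispatch_matches_traces(self, default_seq):
        assert np.array_equal(
            observation_variable("BM", default_seq), beta_trace(default_seq).prior_mean
        )
        tr = beta_trace(default_seq)
        assert np.array_equal(
            observation_variable("BC", default_seq), tr.v + tr.prior_mean
        )
        assert np.array_equal(
            observation_variable("HM2", default_seq, k=0.3),
            hybrid_trace(default_seq, k=0.3).x,
        )
        assert np.array_equal(
            observation_variable("HM1", default_seq, k=0.3),
            hybrid_trace(default_seq, k=0.3).eta,
        )
        assert np.array_equal(
            observation_variable("RW", default_seq, eta=0.4),
            rw_trace(default_seq, eta=0.4).z,
        )

    def test_unknown_model_rejected(self, default_seq):
        with pytest.raises(DispatchError):
            observation_variable("XX", default_seq)

    def test_missing_parameter_rejected(self, default_seq):
        with pytest.raises(ParameterError):
            observation_variable("RW", default_seq)

    def test_deterministic(self, default_seq):
        a = observation_variable("BC", default_seq)
        b = observation_variable("BC", default_seq)
        assert np.array_equal(a, b)

    def test_prediction_type_series_bounded(self, default_seq):
        for model, kwargs in [("RW", dict(eta=0.3)), ("HM2", dict(k=0.3)), ("BM", {})]:
            z = observation_variable(model, default_seq, **kwargs)
            assert np.all((z >= 0) & (z <= 1)), model
        zbc = observation_variable("BC", default_seq)
        v = beta_trace(default_seq).v
        assert np.all(zbc >= v) and np.all(zbc <= v + 1)


class TestParameterGrids:
    """The vectorized grids power the fitting search; they must agree with
    the scalar traces exactly."""

    def test_rw_grid_matches_scalar(self, default_seq):
        etas = np.array([0.05, 0.3, 0.9])
        Z = rw_z_grid(default_seq, etas)
        for i, eta in enumerate(etas):
            assert np.allclose(Z[i], rw_trace(default_seq, eta).z, atol=1e-14)

    def test_hybrid_grid_matches_scalar(self, default_seq):
        ks = np.array([0.1, 0.55, 0.95])
        z_eta, z_x = hybrid_z_grid(default_seq, ks)
        for i, k in enumerate(ks):
            tr = hybrid_trace(default_seq, k)
            assert np.allclose(z_eta[i], tr.eta, atol=1e-14)
            assert np.allclose(z_x[i], tr.x, atol=1e-14)


@pytest.fixture(scope="module")
def mean_traces():
    seqs = [generate_design(seed=s) for s in range(100)]
    out = {}
    for model, kwargs in [("BM", {}), ("BC", {}), ("HM1", dict(k=0.5))]:
        per_rank = {}
        for plus in (True, False):
            zs = np.array(
                [
                    observation_variable(model, s, **kwargs)[s.is_cs_plus == plus]
                    for s in seqs
                ]
            )
            per_rank[plus] = zs.mean(axis=0)
        out[model] = per_rank
    return out


class TestAverageTrajectories:
    """Qualitative shapes of the mean traces over many random sequences:
    the ideal observer's CS+ expectation hovers near 0.5, the combined
    observation variable decays, and hybrid associability decays on the
    never-reinforced CS."""

    def test_bm_cs_plus_flat_near_half(self, mean_traces):
        m = mean_traces["BM"][True]
        # the first block trial is always a reinforced CS+, so the second
        # CS+ presentation sees E = 2/3; thereafter the mean settles at 0.5
        assert np.all(np.abs(m - 0.5) < 0.2)
        assert abs(m[-1] - 0.5) < 0.02
        assert np.std(m[40:]) < 0.01

    def test_bc_decays(self, mean_traces):
        m = mean_traces["BC"][True]
        assert m[-1] < m[0] - 2.5  # dominated by -ln(a+b)
        assert np.all(np.diff(m) < 0.05)  # essentially monotone decay

    def test_hybrid_associability_decays_on_cs_minus(self, mean_traces):
        m = mean_traces["HM1"][False]
        assert np.all(np.diff(m) <= 1e-12)
        assert m[-1] < 0.01

    def test_hybrid_associability_sustained_on_cs_plus(self, mean_traces):
        # 50% reinforcement keeps the unsigned prediction error near 0.5,
        # so the CS+ associability hovers near its starting level
        m = mean_traces["HM1"][True]
        assert np.all(np.abs(m - 0.5) < 0.1)
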