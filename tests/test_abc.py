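"""ABC machinery: priors, summaries, distances, weights, HPDI, pipeline."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import settleopt as so
from settleopt.abc import params_from_draw, simulate_summary
from settleopt.states import SCENARIOS


class TestPrior:
    def test_default_beta_shapes_match_the_stated_modes(self):
        spec = so.PriorSpec()
        for name, mode in (("p_s_save", 0.2), ("p_l_move", 0.5), ("p_h_build", 0.8)):
            a, b = getattr(spec, name)
            assert (a - 1) / (a + b - 2) == pytest.approx(mode)

    def test_draws_are_reproducible_and_in_range(self):
        a = so.sample_prior(500, seed=3)
        b = so.sample_prior(500, seed=3)
        pd.testing.assert_frame_equal(a, b)
        for name in ("p_s_save", "p_l_move", "p_h_build"):
            assert a[name].between(0, 1).all()
        assert a["build_condition"].isin([0, 1]).all()

    def test_scenario_prior_is_flat(self):
        draws = so.sample_prior(40_000, seed=5)
        freqs = draws["payoff_scenario"].value_counts(normalize=True)
        sigma = np.sqrt(0.25 * 0.75 / 40_000)
        for scenario in SCENARIOS:
            assert abs(freqs[scenario] - 0.25) < 4 * sigma

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            so.PriorSpec(p_s_save=(0, 1))
        with pytest.raises(ValueError):
            so.PriorSpec(scenario_probs=(0.5, 0.5, 0.5, -0.5))
        with pytest.raises(ValueError):
            so.sample_prior(0)


class TestSummarize:
    def test_fixture_summary_is_the_published_11_vector(self):
        stats = so.summarize(so.in_paper_fixture())
        np.testing.assert_array_equal(
            stats, [349, 264, 26, 186, 521, 304, 247, 578, 57, 81, 687]
        )
        n = 825
        assert stats[:4].sum() == stats[4:6].sum() == stats[6:8].sum() == stats[8:].sum() == n

    def test_single_household_contributes_one_count_per_block(self):
        df = pd.DataFrame(
            {
                "household": [0], "time_in_env": [5], "savings": [1], "tenure": [0],
                "family": [2], "first_house": [0], "current_house": [1],
                "transition": ["mobile-fixed"],
            }
        )
        stats = so.summarize(df)
        assert stats.sum() == 4
        assert stats[1] == 1 and stats[5] == 1 and stats[6] == 1 and stats[10] == 1

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            so.summarize(pd.DataFrame(columns=["transition", "savings", "tenure", "family"]))


class TestDistance:
    def test_identity_and_simple_example(self):
        ref = so.summarize(so.in_paper_fixture())
        assert so.distance(ref, ref) == 0.0
        a = np.zeros(11); a[0] = 10
        b = np.zeros(11); b[1] = 10
        assert so.distance(a, b) == 20.0

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.integers(0, 500), min_size=11, max_size=11),
           st.lists(st.integers(0, 500), min_size=11, max_size=11))
    def test_symmetry_and_nonnegativity(self, a, b):
        a, b = np.array(a, float), np.array(b, float)
        assert so.distance(a, b) == so.distance(b, a) >= 0.0

    def test_proportion_mode_rescales_by_sample_size(self):
        a = so.summarize(so.in_paper_fixture())
        assert so.distance(a, 2 * a, mode="proportions") == pytest.approx(0.0)
        with pytest.raises(ValueError):
            so.distance(a[:5], a)


class TestWeights:
    def test_equal_distances_give_uniform_weights(self):
        w = so.weights_from_distances([3.0] * 7)
        np.testing.assert_allclose(w, 1 / 7)

    def test_closed_form_pair(self):
        w = so.weights_from_distances([0.0, np.log(2)])
        np.testing.assert_allclose(w, [2 / 3, 1 / 3])

    def test_normalization_for_many_large_distances(self):
        rng = np.random.default_rng(8)
        d = rng.uniform(0, 2000, size=1_000_000)
        w = so.weights_from_distances(d)
        assert w.sum() == pytest.approx(1.0, abs=1e-10)
        assert (w >= 0).all()
        # weight order is the reverse of distance order
        order = np.argsort(d)
        assert (np.diff(w[order]) <= 0).all()
        with pytest.raises(ValueError):
            so.weights_from_distances([])


class TestHpdi:
    def test_constant_samples_give_zero_width(self):
        lo, hi = so.hpdi(np.full(100, 0.4))
        assert lo == hi == 0.4

    def test_uniform_samples_give_mass_width(self):
        x = np.random.default_rng(10).uniform(size=100_000)
        lo, hi = so.hpdi(x, mass=0.89)
        assert hi - lo == pytest.approx(0.89, abs=0.01)

    def test_matches_arviz_on_skewed_samples(self):
        az = pytest.importorskip("arviz")
        x = np.random.default_rng(11).beta(2, 5, size=50_000)
        lo, hi = so.hpdi(x, mass=0.89)
        ref_lo, ref_hi = az.hdi(x, hdi_prob=0.89)
        assert lo == pytest.approx(ref_lo, abs=0.01)
        assert hi == pytest.approx(ref_hi, abs=0.01)

    def test_requires_two_samples(self):
        with pytest.raises(ValueError):
            so.hpdi([0.5])


@pytest.fixture(scope="module")
def tiny_reference():
    truth = so.ModelParams(0.5, 0.75, 0.25, 0.25, 0.25,
                           build_condition=1, payoff_scenario="additive")
    times = so.generate_time_structure(40, seed=12, profile="uniform")
    ref = so.generate_reference_dataset(truth, times, seed=13)
    return truth, times, so.summarize(ref)


class TestPipeline:
    def test_single_draw_run_has_unit_weight(self, tiny_reference):
        _, times, stats = tiny_reference
        result = so.run_abc(stats, 1, times, seed=14)
        assert len(result) == 1
        assert result.weights[0] == 1.0

    def test_run_abc_is_reproducible(self, tiny_reference):
        _, times, stats = tiny_reference
        r1 = so.run_abc(stats, 8, times, seed=15)
        r2 = so.run_abc(stats, 8, times, seed=15)
        np.testing.assert_array_equal(r1.distances, r2.distances)
        pd.testing.assert_frame_equal(r1.draws, r2.draws)

    def test_checkpoint_resume_matches_uninterrupted_run(self, tiny_reference, tmp_path):
        _, times, stats = tiny_reference
        full = so.run_abc(stats, 10, times, seed=16)
        ckpt = tmp_path / "ck.json"
        partial = so.run_abc(stats, 10, times, seed=16, checkpoint_path=ckpt,
                             checkpoint_every=4)
        # truncate the checkpoint to emulate an interrupted run
        import json

        saved = json.loads(ckpt.read_text())
        saved["completed"] = 4
        saved["distances"] = saved["distances"][:4]
        ckpt.write_text(json.dumps(saved))
        resumed = so.run_abc(stats, 10, times, seed=16, checkpoint_path=ckpt)
        np.testing.assert_array_equal(resumed.distances, full.distances)
        np.testing.assert_array_equal(partial.distances, full.distances)

    def test_minimal_distance_draw_has_maximal_weight(self, tiny_reference):
        _, times, stats = tiny_reference
        result = so.run_abc(stats, 30, times, seed=17)
        assert np.argmax(result.weights) == np.argmin(result.distances)

    def test_posterior_sampling_degenerate_and_uniform(self):
        draws = so.sample_prior(50, seed=18)
        degenerate = so.ABCResult(
            draws=draws, distances=np.arange(50.0),
            weights=np.eye(50)[7], ref_stats=np.zeros(11), seed=0,
        )
        post = so.posterior_sample(degenerate, m=200, seed=19)
        assert (post["draw_index"] == 7).all()
        uniform = so.ABCResult(
            draws=draws, distances=np.zeros(50),
            weights=np.full(50, 1 / 50), ref_stats=np.zeros(11), seed=0,
        )
        post = so.posterior_sample(uniform, m=5000, seed=20)
        counts = post["draw_index"].value_counts()
        sigma = np.sqrt(5000 * (1 / 50) * (49 / 50))
        assert (np.abs(counts - 100) < 5 * sigma).all()
        assert len(so.posterior_sample(uniform, seed=0)) == 1000  # default m

    def test_posterior_predictive_shapes(self, tiny_reference):
        _, times, stats = tiny_reference
        samples = so.sample_prior(3, seed=21)
        pp = so.posterior_predictive(samples, mode="behaviour", n_agents=30, seed=22)
        assert pp.behaviour_freqs.shape == (3, 40, 3)
        assert (pp.behaviour_freqs.sum(axis=2) == 30).all()
        pp = so.posterior_predictive(
            samples, times=times, mode="datasets", n_datasets=4, seed=23, keep_datasets=True
        )
        assert pp.transition_counts.shape == (4, 4)
        assert (pp.transition_counts.sum(axis=1) == len(times)).all()
        assert len(pp.datasets) == 4 and all(len(d) == len(times) for d in pp.datasets)

    def test_validate_recovery_report_structure(self):
        truth = so.ModelParams(0.5, 0.75, 0.25, 0.25, 0.25,
                               build_condition=1, payoff_scenario="additive")
        report = so.validate_recovery(
            [truth], n_agents=40, n_candidate_draws=120, seed=24,
            m_posterior=200, n_predictive=3,
        )
        assert len(report) == 3  # one row per continuous parameter
        assert set(report["parameter"]) == {"p_s_save", "p_l_move", "p_h_build"}
        assert report["covered"].dtype == bool
        assert (report["hpdi_lo"] <= report["posterior_median"]).all()
        assert (report["posterior_median"] <= report["hpdi_hi"]).all()
        assert (report["posterior_predictive_distance"] >= 0).all()


def test_params_from_draw_uses_fixed_shocks():
    draw = {"p_s_save": 0.2, "p_l_move": 0.3, "p_h_build": 0.8,
            "build_condition": 1, "payoff_scenario": "additive"}
    params = params_from_draw(draw)
    assert params.p_s_loss == 0.25 and params.p_force_move == 0.25
    params = params_from_draw(draw, fixed={"p_s_loss": 0.1})
    assert params.p_s_loss == 0.1


def test_simulate_summary_blocks_sum_to_n(mid_params):
    rng = np.random.default_rng(25)
    stats = simulate_summary(mid_params, np.full(35, 12), rng)
    assert stats[:4].sum() == 35 and stats[4:6].sum() == 35
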