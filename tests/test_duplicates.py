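"""Three-state divergence model and duplicate-pair randomization tests."""

import itertools

import numpy as np
import pandas as pd
import pytest

from dielcycle.duplicates import (
    DivergenceModel,
    circular_phase_distance,
    fit_divergence_rates,
    iterate_model,
    phase_shift_enrichment,
    random_pairing_test,
    state_frequencies_by_ks,
    steady_state,
    step_model,
)
from dielcycle.simulate import generate_duplicate_pairs


class TestStepModel:
    def test_hand_evaluated_update(self):
        model = DivergenceModel(d=0.42, s=0.53)
        out = step_model(model, (0.30, 0.35, 0.35))
        np.testing.assert_allclose(out, [0.26675, 0.29575, 0.43750], atol=1e-12)

    def test_zero_rates_identity(self):
        model = DivergenceModel(d=0, s=0)
        f = np.array([0.2, 0.5, 0.3])
        np.testing.assert_array_equal(step_model(model, f), f)

    def test_probability_conserved(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            f = rng.dirichlet([1, 1, 1])
            d, s = rng.random(2)
            out = step_model(DivergenceModel(d, s), f)
            assert out.sum() == pytest.approx(1.0, abs=1e-12)
            assert (out >= 0).all()

    def test_identical_gap_decays_geometrically(self):
        model = DivergenceModel(d=0.3, s=0.6)
        traj = iterate_model(model, 10, (0.5, 0.2, 0.3))
        gaps = traj[:, 0] - traj[:, 1]
        ratios = gaps[1:] / gaps[:-1]
        np.testing.assert_allclose(ratios, 0.7, atol=1e-12)


class TestSteadyState:
    def test_printed_rates_give_asymptote(self):
        f = steady_state(DivergenceModel(d=0.42, s=0.53))
        assert f[2] == pytest.approx(0.42 / 0.95, abs=1e-12)
        assert abs(f[2] - 0.45) < 0.01

    def test_no_reversion_fully_diverges(self):
        assert steady_state(DivergenceModel(d=0.2, s=0.0))[2] == 1.0

    def test_iteration_converges_to_closed_form(self):
        model = DivergenceModel(d=0.42, s=0.53)
        final = iterate_model(model, 200, (1.0, 0.0, 0.0))[-1]
        np.testing.assert_allclose(final, steady_state(model), atol=1e-9)

    def test_degenerate_model_flagged(self):
        with pytest.raises(ValueError):
            steady_state(DivergenceModel(d=0, s=0))


class TestFitRates:
    def test_roundtrip_recovers_printed_rates(self):
        f = np.array([0.30, 0.35, 0.35])
        f1 = step_model(DivergenceModel(0.42, 0.53), f)
        d, s = fit_divergence_rates(f, f1)
        assert d == pytest.approx(0.42, abs=1e-12)
        assert s == pytest.approx(0.53, abs=1e-12)

    def test_stationary_input_gives_zero_rates(self):
        f = np.array([0.4, 0.3, 0.3])
        d, s = fit_divergence_rates(f, f)
        assert d == 0.0 and s == 0.0

    def test_random_roundtrips_exact(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            f = rng.dirichlet([2, 2, 2])
            if abs(f[0] - f[1]) < 1e-3 or f[2] < 1e-3:
                continue
            d, s = rng.random(2)
            f1 = step_model(DivergenceModel(d, s), f)
            dd, ss = fit_divergence_rates(f, f1)
            assert abs(dd - d) < 1e-12 and abs(ss - s) < 1e-12

    def test_unidentifiable_inputs_raise(self):
        with pytest.raises(ValueError, match="unidentifiable"):
            fit_divergence_rates([0.3, 0.3, 0.4], [0.3, 0.3, 0.4])
        with pytest.raises(ValueError, match="unidentifiable"):
            fit_divergence_rates([0.6, 0.4, 0.0], [0.6, 0.4, 0.0])


class TestKsBinning:
    def test_all_diverged(self):
        pairs = pd.DataFrame({"ks": [0.1, 0.5, 1.1], "state": ["D"] * 3})
        freqs = state_frequencies_by_ks(pairs)
        assert (freqs.f_D == 1.0).all()

    def test_half_open_bin_edges(self):
        pairs = pd.DataFrame({"ks": [0.3], "state": ["CC"]})
        freqs = state_frequencies_by_ks(pairs)
        assert freqs.ks_bin.iloc[0] == pytest.approx(0.3)

    def test_negative_ks_rejected(self):
        with pytest.raises(ValueError):
            state_frequencies_by_ks(
                pd.DataFrame({"ks": [-0.1], "state": ["CC"]})
            )

    def test_frequencies_match_generator_truth(self):
        pairs = generate_duplicate_pairs(
            d=0.42, s=0.53, initial_freqs=(0.35, 0.45, 0.20),
            ks_bins=4, pairs_per_bin=3000, seed=17,
        )
        freqs = state_frequencies_by_ks(pairs)
        traj = iterate_model(
            DivergenceModel(0.42, 0.53, f0=(0.35, 0.45, 0.20)), 3
        )
        for b in range(4):
            se = np.sqrt(0.25 / freqs.n_pairs.iloc[b])
            for j, st in enumerate(["CC", "NN", "D"]):
                assert abs(freqs[f"f_{st}"].iloc[b] - traj[b, j]) < 4 * se


class TestRandomPairing:
    def _pairs(self, c1, c2, p1=None, p2=None):
        n = len(c1)
        return pd.DataFrame({
            "gene1": [f"a{i}" for i in range(n)],
            "gene2": [f"b{i}" for i in range(n)],
            "ks": 0.1, "state": "",
            "cycling1": c1, "cycling2": c2,
            "phase1": p1 if p1 is not None else [np.nan] * n,
            "phase2": p2 if p2 is not None else [np.nan] * n,
        })

    def test_null_statistic_gives_small_z(self):
        rng = np.random.default_rng(2)
        pairs = self._pairs(rng.random(400) < 0.5, rng.random(400) < 0.5)
        res = random_pairing_test(pairs, "state", n_resamples=2000, seed=3)
        assert abs(res["z"]) < 3

    def test_exhaustive_four_pair_null(self):
        c1 = [True, True, False, False]
        c2 = [True, False, True, False]
        pairs = self._pairs(c1, c2)
        sampled = random_pairing_test(pairs, "state", n_resamples=20_000,
                                      seed=4)
        exact = [
            sum(a == b for a, b in zip(c1, perm))
            for perm in itertools.permutations(c2)
        ]
        assert sampled["null_mean"] == pytest.approx(np.mean(exact), abs=0.05)
        assert sampled["null_sd"] == pytest.approx(np.std(exact), abs=0.05)

    def test_planted_retention_detected(self):
        pairs = generate_duplicate_pairs(
            d=0.05, s=0.05, initial_freqs=(0.5, 0.5, 0.0),
            ks_bins=3, pairs_per_bin=150,
            phase_shift_kernel={0.0: 1.0}, seed=5,
        )
        state = random_pairing_test(pairs, "state", n_resamples=2000, seed=6)
        phase = random_pairing_test(pairs, "phase", n_resamples=2000, seed=7)
        assert state["z"] > 0 and state["p"] < 0.05
        assert phase["z"] > 0 and phase["p"] < 0.05

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            random_pairing_test(self._pairs([True], [True]))


class TestPhaseShiftEnrichment:
    def test_identical_phases_maximal_on_diagonal(self):
        rng = np.random.default_rng(8)
        phases = rng.choice([0.0, 3.0, 6.0, 9.0], size=200)
        pairs = pd.DataFrame({
            "cycling1": True, "cycling2": True,
            "phase1": phases, "phase2": phases,
        })
        res = phase_shift_enrichment(pairs, n_resamples=500, seed=9)
        mat = res["matrix"].to_numpy()
        assert np.nanmax(mat) == np.nanmax(np.diag(mat))

    def test_uniform_pairing_flat_enrichment(self):
        rng = np.random.default_rng(10)
        pairs = pd.DataFrame({
            "cycling1": True, "cycling2": True,
            "phase1": rng.choice(np.arange(0, 24, 3), 3000),
            "phase2": rng.choice(np.arange(0, 24, 3), 3000),
        })
        res = phase_shift_enrichment(pairs, n_resamples=300, seed=11)
        assert abs(res["slope"]) < 0.02
        assert np.allclose(res["shift_enrichment"], 1.0, atol=0.2)

    def test_small_shift_kernel_gives_inverse_linear_trend(self):
        # kernel whose |shift| enrichment declines linearly (E = 1.6 - 0.1|d|)
        kernel = {0.0: 0.2, 3.0: 0.1625, -3.0: 0.1625, 6.0: 0.125,
                  -6.0: 0.125, 9.0: 0.0875, -9.0: 0.0875, 12.0: 0.05}
        pairs = generate_duplicate_pairs(
            d=0.1, s=0.1, initial_freqs=(0.9, 0.1, 0.0),
            ks_bins=3, pairs_per_bin=4000, phase_shift_kernel=kernel, seed=12,
        )
        res = phase_shift_enrichment(pairs, n_resamples=400, seed=13)
        assert res["slope"] < 0
        assert res["r2"] > 0.8

    def test_single_phase_degenerate(self):
        pairs = pd.DataFrame({
            "cycling1": [True] * 5, "cycling2": [True] * 5,
            "phase1": 3.0, "phase2": 3.0,
        })
        res = phase_shift_enrichment(pairs, n_resamples=100, seed=14)
        assert res["degenerate"]


def test_circular_distance_capped_at_half_day():
    assert circular_phase_distance(0.0, 21.0) == 3.0
    assert circular_phase_distance(3.0, 18.0) == 9.0
    assert circular_phase_distance(0.0, 12.0) == 12.0
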