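import numpy as np
import pytest

import turnpoint as tp
from turnpoint.io import ValidationError
from turnpoint.simulate import (
    GroundTruth,
    derive_total_from_pulsed,
    paper_recipe_dataset,
    protein_latent,
    pulsed_latents,
    simulate_paired_dataset,
    simulate_pulsed_dataset,
    simulate_rate_profiles,
)


class TestRateProfiles:
    def test_null_world_constant(self, grid8):
        truth = simulate_rate_profiles(20, grid8, 0.0, 4.0, seed=0)
        assert not truth.changed.any()
        assert np.all(truth.true_synthesis == truth.true_synthesis[:, :1])

    def test_deterministic_count_and_index(self, grid8):
        truth = simulate_rate_profiles(
            200, grid8, 0.25, 4.0, change_time_index=4, seed=1
        )
        assert truth.changed.sum() == 50
        for cp in truth.change_points:
            for idx, rate, direction in cp:
                assert idx == 4 and rate == "synthesis" and direction == 1
        changed = truth.changed
        ratio = truth.true_synthesis[changed, 4] / truth.true_synthesis[changed, 3]
        np.testing.assert_allclose(ratio, 4.0)

    def test_seeded_bit_identical(self, grid8):
        a = simulate_rate_profiles(50, grid8, 0.3, 2.0, seed=9)
        b = simulate_rate_profiles(50, grid8, 0.3, 2.0, seed=9)
        assert np.array_equal(a.true_synthesis, b.true_synthesis)
        assert a.change_points == b.change_points

    def test_index_out_of_range(self, grid8):
        with pytest.raises(ValidationError):
            simulate_rate_profiles(10, grid8, 0.5, 2.0, change_time_index=7,
                                   seed=0)

    def test_interior_only_in_ground_truth(self, grid8):
        with pytest.raises(ValidationError):
            GroundTruth(
                ("a",),
                np.ones((1, 7)),
                np.ones((1, 7)),
                (((0, "synthesis", 1),),),
                0.1,
                0,
            )


class TestPulsedSimulation:
    def test_noise_free_latents_satisfy_updates(self, grid8):
        truth = simulate_rate_profiles(10, grid8, 0.3, 3.0, seed=2,
                                       base_degradation=0.2)
        X = np.full((10, 8), 100.0)
        H, M = pulsed_latents(truth, grid8, X)
        dh = grid8.intervals
        np.testing.assert_allclose(
            np.diff(H, axis=1), dh * truth.true_synthesis * X[:, :-1], rtol=1e-12
        )
        np.testing.assert_allclose(
            M[:, 1:] / M[:, :-1], np.exp(-truth.true_degradation * dh), rtol=1e-12
        )
        assert np.all(np.diff(H, axis=1) > 0)
        assert np.all(np.diff(M, axis=1) < 0)

    def test_decay_closed_form(self):
        grid = tp.TimeGrid([0, 5, 10])
        truth = GroundTruth(
            ("a",), np.full((1, 2), 0.02), np.full((1, 2), 0.1),
            ((),), 0.1, 0,
        )
        _, M = pulsed_latents(truth, grid, np.full((1, 3), 100.0), m0=50.0)
        assert M[0, 2] == pytest.approx(50 * np.exp(-1.0), rel=1e-12)

    def test_h0_offset_positive(self, grid8):
        truth = simulate_rate_profiles(5, grid8, 0, 1, seed=0)
        H, _ = pulsed_latents(truth, grid8, np.full((5, 8), 100.0))
        assert np.all(H[:, 0] > 0)
        assert np.all(H[:, 0] < 0.01 * H[:, -1])

    def test_default_noise_matches_recipe(self, grid8):
        truth = simulate_rate_profiles(5, grid8, 0, 1, seed=0)
        assert truth.noise_sd == 0.1

    def test_new_degrades_total_is_mass_action(self, grid8):
        truth = simulate_rate_profiles(8, grid8, 0, 1, seed=3,
                                       base_degradation=0.2)
        X = np.full((8, 8), 100.0)
        H, M = pulsed_latents(truth, grid8, X, new_degrades=True)
        Y = H + M
        dh = grid8.intervals
        kd = truth.true_degradation
        w = np.exp(-kd * dh[None, :])
        pred = w * Y[:, :-1] + (1 - w) * (
            truth.true_synthesis / kd
        ) * X[:, :-1]
        np.testing.assert_allclose(Y[:, 1:], pred, rtol=1e-10)


class TestDeriveTotal:
    def test_pointwise_sum(self, grid8):
        truth = simulate_rate_profiles(6, grid8, 0, 1, seed=4)
        pdata, _ = simulate_pulsed_dataset(truth, grid8, seed=4)
        total = derive_total_from_pulsed(pdata)
        np.testing.assert_allclose(
            total.product.values,
            pdata.new_channel.values + pdata.old_channel.values,
        )
        assert total.template is pdata.mrna

    def test_scale_validation(self, grid8):
        truth = simulate_rate_profiles(3, grid8, 0, 1, seed=4)
        pdata, _ = simulate_pulsed_dataset(truth, grid8, seed=4)
        from turnpoint.pulsed import PulsedDataset

        logged = PulsedDataset(
            pdata.new_channel.to_log10(), pdata.old_channel, pdata.mrna, grid8
        )
        with pytest.raises(ValidationError):
            derive_total_from_pulsed(logged)

    def test_identifiability_limit_flat_total(self, grid8):
        """Rising k_s matched by M decay: pulsed truth moves, total is flat."""
        dh = grid8.intervals
        kd = 0.1
        m0 = 100.0
        T = grid8.n_times
        X = np.full((1, T), 100.0)
        M = m0 * np.exp(-kd * np.r_[0.0, np.cumsum(dh)])
        ks = (M[:-1] - M[1:]) / (dh * X[0, :-1])  # Delta H = -Delta M
        truth = GroundTruth(
            ("a",), ks[None, :], np.full((1, T - 1), kd), ((),), 0.1, 0
        )
        H, M_lat = pulsed_latents(truth, grid8, X, m0=m0, h0_scale=0.0)
        total = H + M_lat
        assert np.ptp(total) / total[0, 0] < 1e-9
        assert np.ptp(H) > 1.0  # the channels themselves clearly move


class TestPairedSimulation:
    def test_no_missing_by_default(self, grid8):
        truth = simulate_rate_profiles(10, grid8, 0, 1, seed=5,
                                       base_degradation=0.5)
        data, _ = simulate_paired_dataset(truth, grid8, seed=5)
        assert not data.product.mask.any()

    def test_missing_cap_respected(self, grid8):
        truth = simulate_rate_profiles(100, grid8, 0, 1, seed=5,
                                       base_degradation=0.5)
        data, _ = simulate_paired_dataset(truth, grid8, missing_rate=0.25,
                                          seed=5)
        per_rep = data.product.mask.sum(axis=1)
        assert per_rep.max() <= 2

    def test_missing_rate_bound(self, grid8):
        truth = simulate_rate_profiles(5, grid8, 0, 1, seed=5,
                                       base_degradation=0.5)
        with pytest.raises(ValidationError):
            simulate_paired_dataset(truth, grid8, missing_rate=0.5, seed=5)

    def test_stationary_fixed_point(self, grid8):
        truth = simulate_rate_profiles(10, grid8, 0, 1, seed=6,
                                       base_degradation=0.5)
        X = np.full((10, 8), 100.0)
        y = protein_latent(truth, grid8, X)
        stat = truth.true_synthesis[:, :1] * 100.0 / truth.true_degradation[:, :1]
        np.testing.assert_allclose(y, np.broadcast_to(stat, y.shape), rtol=1e-12)

    def test_degradation_stability_guard(self):
        grid = tp.TimeGrid([0, 4, 8])
        truth = simulate_rate_profiles(3, grid, 0, 1, seed=0,
                                       base_degradation=0.5)
        with pytest.raises(ValidationError):
            protein_latent(truth, grid, np.full((3, 3), 100.0))

    def test_seeded_bit_identical(self, grid8):
        truth = simulate_rate_profiles(10, grid8, 0.2, 3.0, seed=8,
                                       base_degradation=0.5)
        d1, _ = simulate_paired_dataset(truth, grid8, seed=8)
        d2, _ = simulate_paired_dataset(truth, grid8, seed=8)
        assert np.array_equal(
            d1.product.values[~d1.product.mask],
            d2.product.values[~d2.product.mask],
        )

    def test_all_values_positive(self, grid8):
        truth = simulate_rate_profiles(20, grid8, 0.2, 3.0, seed=8,
                                       base_degradation=0.5)
        data, _ = simulate_paired_dataset(truth, grid8, seed=8)
        for s in (data.template, data.product):
            assert np.all(s.values[~s.mask] > 0)


class TestPaperRecipe:
    def test_order_smooth_filter_noise(self, grid8):
        data, truth = paper_recipe_dataset(60, grid8, seed=7)
        # retained set passed the monotone screen before noise was added,
        # so the noisy channels may wiggle but the count matches the truth
        assert len(data.gene_ids) == len(truth.gene_ids)
        assert len(data.gene_ids) > 0
        assert truth.noise_sd == 0.1
        # replicate noise is present (not the clean latents)
        assert not np.allclose(
            data.new_channel.values[:, :, 0], data.new_channel.values[:, :, 1]
        )
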