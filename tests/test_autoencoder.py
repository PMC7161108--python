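"""Multi-modal sparse denoising autoencoder: forward pass, penalty,
gradients, training behavior and scoring."""

import numpy as np
import pytest

import pathme.autoencoder as ae


def hand_forward(model, Xs):
    """Straight-line re-implementation of the forward pass (no batchnorm),
    composing the encoder and decoder layer equations directly."""
    P = model.params
    arch = model.arch
    a1_parts, start = [], 0
    for j, p in enumerate(arch.input_sizes):
        xj = Xs[:, start:start + p]
        a1_parts.append(np.tanh(xj @ P[f"W_enc1_{j}"] + P[f"b_enc1_{j}"]))
        start += p
    a1 = np.concatenate(a1_parts, axis=1)
    score = np.tanh(a1 @ P["W_enc2"] + P["b_enc2"])
    a3 = np.tanh(score @ P["W_dec1"] + P["b_dec1"])
    outs, start = [], 0
    for j, h in enumerate(arch.hidden_sizes):
        aj = a3[:, start:start + h]
        outs.append(np.tanh(aj @ P[f"W_dec2_{j}"] + P[f"b_dec2_{j}"]))
        start += h
    return score, np.concatenate(outs, axis=1)


def make_model(input_sizes, hidden_sizes, seed=0, batchnorm=False):
    arch = ae.AutoencoderArchitecture(list(input_sizes), list(hidden_sizes),
                                      batchnorm=batchnorm)
    return ae.AutoencoderModel.initialize(arch, seed=seed)


class TestArchitecture:
    def test_hidden_size_bound(self):
        with pytest.raises(ValueError, match="hidden size"):
            ae.AutoencoderArchitecture([6], [4])  # floor(6/2)=3

    def test_single_feature_modality_allowed(self):
        arch = ae.AutoencoderArchitecture([1, 5], [1, 2])
        assert arch.total_hidden == 3

    def test_config_range_validation(self):
        with pytest.raises(ValueError):
            ae.TrainingConfig(mini_batch_size=7)
        with pytest.raises(ValueError):
            ae.TrainingConfig(learning_rate=1.0)
        with pytest.raises(ValueError):
            ae.TrainingConfig(retention_p=0.2)
        with pytest.raises(ValueError):
            ae.TrainingConfig(optimizer="sgd")


class TestEncodeDecode:
    def test_zero_weights_give_zero_score_and_mean_reconstruction(self):
        model = make_model([2, 3], [1, 1])
        for k in model.params:
            model.params[k] = np.zeros_like(model.params[k])
        x = np.array([1.0, -2.0, 0.5, 3.0, -1.0])
        score, recon = ae.encode_decode(model, x)
        assert score == 0.0
        # tanh(0)=0 on the standardized scale -> feature means in raw units
        np.testing.assert_allclose(recon, model.feature_mean)

    def test_identity_single_feature_fixed_point(self):
        model = make_model([1], [1])
        for name in ("W_enc1_0", "W_enc2", "W_dec1", "W_dec2_0"):
            model.params[name] = np.ones_like(model.params[name])
        for name in ("b_enc1_0", "b_enc2", "b_dec1", "b_dec2_0"):
            model.params[name] = np.zeros_like(model.params[name])
        score, recon = ae.encode_decode(model, np.array([0.0]))
        assert score == 0.0
        np.testing.assert_allclose(recon, [0.0])

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_straight_line_forward_oracle(self, seed):
        rng = np.random.default_rng(seed)
        model = make_model([3, 2], [1, 1], seed=seed)
        X = rng.normal(size=(4, 5))
        model.fit_standardization(X)
        scores, recon = ae.encode_decode(model, X)
        exp_score, exp_out = hand_forward(model, model.standardize(X))
        np.testing.assert_allclose(scores, exp_score[:, 0], atol=1e-12)
        np.testing.assert_allclose(recon, model.destandardize(exp_out),
                                   atol=1e-12)

    def test_shape_and_finite_errors(self):
        model = make_model([2], [1])
        with pytest.raises(ValueError, match="features"):
            ae.encode_decode(model, np.zeros(5))
        with pytest.raises(ValueError, match="finite"):
            ae.encode_decode(model, np.array([np.nan, 1.0]))


class TestReconstructionLoss:
    def test_perfect_reconstruction_is_zero(self):
        model = make_model([1], [1])
        # tanh fixed point at 0: standardized zero input reconstructs to 0
        for name in ("W_enc1_0", "W_enc2", "W_dec1", "W_dec2_0"):
            model.params[name] = np.ones_like(model.params[name])
        for name in ("b_enc1_0", "b_enc2", "b_dec1", "b_dec2_0"):
            model.params[name] = np.zeros_like(model.params[name])
        assert ae.reconstruction_loss(model, np.array([[0.0]])) == 0.0

    def test_hand_computed_two_modality_residuals(self):
        # zero weights -> reconstruction 0 on the standardized scale;
        # identity standardization makes residuals equal the inputs:
        # patient x = (1,0 | 0,2) -> sigma = (1+0) + (0+4) = 5
        model = make_model([2, 2], [1, 1])
        for k in model.params:
            model.params[k] = np.zeros_like(model.params[k])
        X = np.array([[1.0, 0.0, 0.0, 2.0]])
        assert ae.reconstruction_loss(model, X) == pytest.approx(5.0)

    def test_duplicating_patients_leaves_sigma_unchanged(self):
        rng = np.random.default_rng(3)
        model = make_model([3], [1], seed=3)
        X = rng.normal(size=(5, 3))
        model.fit_standardization(X)
        s1 = ae.reconstruction_loss(model, X)
        s2 = ae.reconstruction_loss(model, np.vstack([X, X]))
        assert s1 == pytest.approx(s2, rel=1e-12)

    def test_empty_batch_rejected(self):
        model = make_model([2], [1])
        with pytest.raises(ValueError, match="empty"):
            ae.reconstruction_loss(model, np.empty((0, 2)))


class TestSGLPenalty:
    def test_zero_lambda(self):
        model = make_model([4, 4], [2, 2], seed=1)
        assert ae.sgl_penalty(model, 0.0, 0.5) == 0.0

    def test_single_weight_hand_value(self):
        # one modality, p=1, h=1: group weight sqrt(1*1)=1, w=2
        # (0.1/2)*(0.5*4 + 0.5*(2 + |other weights|)) with others zeroed
        model = make_model([1], [1])
        for k in model.params:
            model.params[k] = np.zeros_like(model.params[k])
        model.params["W_enc1_0"] = np.array([[2.0]])
        assert ae.sgl_penalty(model, 0.1, 0.5) == pytest.approx(0.15)

    def test_alpha_one_is_pure_lasso(self):
        model = make_model([4, 3], [2, 1], seed=2)
        lam = 0.05
        l1 = sum(np.abs(model.params[n]).sum()
                 for n in model.params if n.startswith("W_"))
        assert ae.sgl_penalty(model, lam, 1.0) == pytest.approx(lam / 2 * l1)

    def test_alpha_zero_is_group_term_only(self):
        model = make_model([4, 3], [2, 1], seed=2)
        lam = 0.05
        group = sum(np.sqrt(p * h) * (model.params[f"W_enc1_{j}"] ** 2).sum()
                    for j, (p, h) in enumerate(zip([4, 3], [2, 1])))
        assert ae.sgl_penalty(model, lam, 0.0) == pytest.approx(lam / 2 * group)

    def test_alpha_out_of_range(self):
        model = make_model([2], [1])
        with pytest.raises(ValueError):
            ae.sgl_penalty(model, 0.1, 1.5)


class TestGradients:
    @pytest.mark.parametrize("batchnorm", [False, True])
    def test_analytic_matches_finite_differences(self, batchnorm):
        rng = np.random.default_rng(0)
        model = make_model([3, 2], [1, 1], seed=1, batchnorm=batchnorm)
        X = rng.normal(size=(7, 5)) * [2, 1, 3, 0.5, 1] + [1, 0, 2, 0, -1]
        model.fit_standardization(X)
        lam, alpha = 0.01, 0.3
        grads = ae.objective_grads(model, X, lam, alpha, training=True)
        h = 1e-6
        for name, arr in model.params.items():
            it = np.nditer(arr, flags=["multi_index"])
            for _ in it:
                i = it.multi_index
                orig = arr[i]
                arr[i] = orig + h
                fp = ae.objective(model, X, lam, alpha, training=True)
                arr[i] = orig - h
                fm = ae.objective(model, X, lam, alpha, training=True)
                arr[i] = orig
                fd = (fp - fm) / (2 * h)
                an = grads[name][i]
                assert abs(fd - an) / max(abs(fd), abs(an), 1e-8) < 1e-4, name

    def test_lambda_zero_objective_is_half_sigma(self):
        rng = np.random.default_rng(5)
        model = make_model([4], [2], seed=5)
        X = rng.normal(size=(6, 4))
        model.fit_standardization(X)
        f = ae.objective(model, X, 0.0, 0.7)
        assert f == pytest.approx(0.5 * ae.reconstruction_loss(model, X),
                                  rel=1e-12)


class TestModalitySeparation:
    def test_zeroing_one_modality_leaves_other_hidden_units_unchanged(self):
        rng = np.random.default_rng(4)
        model = make_model([3, 4], [1, 2], seed=4, batchnorm=True)
        X = rng.normal(size=(6, 7))
        model.fit_standardization(X)
        Xs = model.standardize(X)
        _, _, cache1 = ae._forward(model, Xs, training=False)
        Xz = Xs.copy()
        Xz[:, :3] = 0.0  # zero modality 0 inputs
        _, _, cache2 = ae._forward(model, Xz, training=False)
        # modality 1's first-hidden activations (units 1..2) unchanged
        np.testing.assert_array_equal(cache1["a1"][:, 1:], cache2["a1"][:, 1:])
        assert not np.array_equal(cache1["a1"][:, :1], cache2["a1"][:, :1])


class TestTraining:
    def test_beats_constant_predictor_on_rank1_data(self, rank1_view_data):
        arch = ae.AutoencoderArchitecture([6], [3])
        cfg = ae.TrainingConfig(mini_batch_size=4, lam=0.0, alpha=0.5,
                                learning_rate=0.01, retention_p=1.0,
                                max_epochs=150, seed=0)
        tm = ae.train(rank1_view_data, arch, cfg)
        # all-zero weights predict tanh(0)=0 everywhere: F = p/2 on z-scores
        assert tm.loss_trace[-1] < 0.5 * rank1_view_data.shape[1]

    def test_same_seed_identical_traces(self, rank1_view_data):
        arch = ae.AutoencoderArchitecture([6], [2])
        cfg = ae.TrainingConfig(max_epochs=30, seed=11)
        t1 = ae.train(rank1_view_data, arch, cfg)
        t2 = ae.train(rank1_view_data, arch, cfg)
        assert t1.loss_trace == t2.loss_trace

    def test_early_stop_exactly_patience_after_last_improvement(
            self, rank1_view_data):
        arch = ae.AutoencoderArchitecture([6], [2])
        cfg = ae.TrainingConfig(learning_rate=0.01, max_epochs=1000, seed=0,
                                lam=0.0, retention_p=1.0)
        tm = ae.train(rank1_view_data, arch, cfg)
        assert tm.stopped_early
        # the trace ends exactly `patience` epochs after the last epoch
        # that improved the running best by >= 1e-6 relative
        trace = tm.loss_trace
        best, last_improve = np.inf, 0
        for i, v in enumerate(trace):
            if v < best * (1 - 1e-6):
                best, last_improve = v, i
        assert len(trace) == last_improve + 1 + cfg.patience

    def test_running_minimum_non_increasing(self, rank1_view_data):
        arch = ae.AutoencoderArchitecture([6], [3])
        cfg = ae.TrainingConfig(max_epochs=60, seed=3)
        tm = ae.train(rank1_view_data, arch, cfg)
        run_min = np.minimum.accumulate(tm.loss_trace)
        assert np.all(np.diff(run_min) <= 0)
        assert len(tm.loss_trace) <= cfg.max_epochs

    @pytest.mark.parametrize("optimizer", ae.OPTIMIZERS)
    def test_all_optimizers_decrease_loss(self, optimizer, rank1_view_data):
        arch = ae.AutoencoderArchitecture([6], [3])
        cfg = ae.TrainingConfig(optimizer=optimizer, max_epochs=60, seed=1,
                                lam=0.0, retention_p=1.0)
        tm = ae.train(rank1_view_data, arch, cfg)
        assert min(tm.loss_trace) < tm.loss_trace[0]

    def test_group_penalty_shrinks_noise_modality(self):
        # modality 1 carries rank-1 signal, modality 2 is pure noise;
        # strong group penalty (alpha=0) should shrink the noise branch
        rng = np.random.default_rng(0)
        n = 40
        u = rng.normal(size=n)
        signal = np.outer(u, rng.normal(size=6)) + 0.1 * rng.normal(size=(n, 6))
        noise = rng.normal(size=(n, 6))
        X = np.hstack([signal, noise])
        arch = ae.AutoencoderArchitecture([6, 6], [3, 3])
        cfg = ae.TrainingConfig(mini_batch_size=8, lam=0.05, alpha=0.0,
                                learning_rate=0.01, retention_p=1.0,
                                max_epochs=150, seed=0)
        tm = ae.train(X, arch, cfg)
        w_sig = np.abs(tm.model.params["W_enc1_0"]).mean()
        w_noise = np.abs(tm.model.params["W_enc1_1"]).mean()
        assert w_noise < w_sig


class TestTune:
    def test_budget_one_returns_single_trial(self, rank1_view_data):
        cfg, arch, cv, trials = ae.tune(rank1_view_data, [6], budget=1,
                                        folds=3, seed=0, max_epochs=25)
        assert len(trials) == 1
        assert cv == trials[0]["cv_error"]

    def test_hidden_sizes_respect_half_input_bound(self, rank1_view_data):
        _, _, _, trials = ae.tune(rank1_view_data, [6], budget=6, folds=3,
                                  seed=1, max_epochs=10)
        for t in trials:
            assert 1 <= t["hidden_sizes"][0] <= 3

    def test_too_few_patients_for_folds(self):
        with pytest.raises(ValueError, match="fold"):
            ae.tune(np.zeros((3, 4)), [4], budget=1, folds=5, seed=0)

    def test_best_not_worse_than_first_sample(self, rank1_view_data):
        _, _, cv, trials = ae.tune(rank1_view_data, [6], budget=5, folds=3,
                                   seed=2, max_epochs=25)
        assert cv <= trials[0]["cv_error"] + 1e-12


class TestScoring:
    def test_constant_rows_get_equal_scores(self):
        model = make_model([3], [1], seed=6)
        X = np.tile([1.0, 2.0, 3.0], (5, 1))
        model.fit_standardization(np.vstack([X, X + 1]))
        tm = ae.TrainedPathwayModel(model, [], ae.TrainingConfig())
        s = ae.score_patients(tm, X)
        assert np.ptp(s) == 0.0

    def test_scores_invariant_to_patient_order(self, rank1_view_data):
        arch = ae.AutoencoderArchitecture([6], [2])
        cfg = ae.TrainingConfig(max_epochs=30, seed=0)
        tm = ae.train(rank1_view_data, arch, cfg)
        s = ae.score_patients(tm, rank1_view_data)
        perm = np.random.default_rng(0).permutation(len(s))
        s_perm = ae.score_patients(tm, rank1_view_data[perm])
        np.testing.assert_allclose(s_perm, s[perm], atol=1e-12)

    def test_feature_mismatch_raises(self, rank1_view_data):
        arch = ae.AutoencoderArchitecture([6], [2])
        tm = ae.train(rank1_view_data, arch,
                      ae.TrainingConfig(max_epochs=5, seed=0))
        with pytest.raises(ValueError, match="mismatch"):
            ae.score_patients(tm, rank1_view_data[:, :4])


class TestScoreMatrix:
    def test_minmax_rescaling(self):
        m = ae.assemble_score_matrix({"PW": np.array([-1.0, 0.0, 1.0])},
                                     ["a", "b", "c"])
        np.testing.assert_allclose(m.values[0], [0.0, 0.5, 1.0])

    def test_range_contract(self):
        rng = np.random.default_rng(1)
        scores = {f"P{i}": rng.normal(size=8) for i in range(5)}
        m = ae.assemble_score_matrix(scores, [str(j) for j in range(8)])
        assert m.values.min() >= 0.0 and m.values.max() <= 1.0

    def test_constant_row_maps_to_half(self):
        m = ae.assemble_score_matrix({"PW": np.full(4, 0.3)},
                                     list("abcd"))
        np.testing.assert_allclose(m.values[0], 0.5)

    def test_patient_count_mismatch(self):
        with pytest.raises(ValueError, match="scores"):
            ae.assemble_score_matrix({"PW": np.zeros(3)}, list("ab"))


def test_model_save_load_round_trip(tmp_path, rank1_view_data):
    arch = ae.AutoencoderArchitecture([6], [2], batchnorm=True)
    tm = ae.train(rank1_view_data, arch, ae.TrainingConfig(max_epochs=10, seed=0))
    path = tmp_path / "model.json"
    tm.model.save(path)
    loaded = ae.AutoencoderModel.load(path)
    s1 = ae.score_patients(tm, rank1_view_data)
    s2, _ = ae.encode_decode(loaded, rank1_view_data)
    np.testing.assert_allclose(s1, s2, atol=1e-12)
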