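import numpy as np
import pytest

from nanossl._autograd import Tensor
from nanossl.mae_model import (
    Classifier,
    ClassifierConfig,
    MaskedAutoencoder,
    ModelConfig,
    count_parameters,
    mse_latent_loss,
)
from nanossl.preprocess import make_mask
from nanossl.training import Adam

TINY = ModelConfig(d=8, d_k=4, d_v=4, n_layers=1, h=2, p1=0.0, w=5)


def _plans(rng, B, L, m):
    ranks = np.argsort(rng.random((B, L)), axis=1)
    return np.sort(ranks[:, :m], axis=1), np.sort(ranks[:, m:], axis=1)


@pytest.fixture
def model():
    return MaskedAutoencoder(TINY, n_positions=7, seed=3).eval()


@pytest.fixture
def segments(rng):
    return rng.normal(size=(3, 7, 5))


class TestProject:
    def test_zero_weights_give_zero_latents(self, model, segments):
        for p in model.proj.parameters():
            p.data[:] = 0.0
        model.pos.data[:] = 0.0
        assert np.all(model.project(segments).array == 0.0)

    def test_positional_additivity(self, model):
        # identical subsequences at two positions differ exactly by the
        # difference of their positional embeddings
        seg = np.tile(np.linspace(0, 1, 5), (1, 7, 1))
        out = model.project(seg).array[0]
        np.testing.assert_allclose(
            out[2] - out[5], model.pos.data[2] - model.pos.data[5], atol=1e-12
        )

    def test_output_shape_default_dims(self):
        m = MaskedAutoencoder(ModelConfig(), n_positions=42, seed=0)
        out = m.project(np.zeros((3, 42, 12)))
        assert out.array.shape == (3, 42, 64)

    def test_ragged_batch_rejected(self, model):
        with pytest.raises(ValueError):
            model.project(np.zeros((3, 7, 5, 1)))


class TestEncode:
    def test_full_mode_keeps_all_positions(self, model, segments):
        out = model.encode(model.project(segments), "full")
        assert out.array.shape == (3, 7, 8)
        assert out.stage == "encoded"

    def test_visible_only_keeps_original_indices(self, model, segments, rng):
        masked, visible = _plans(rng, 3, 7, 4)
        out = model.encode(model.project(segments), "visible_only", (masked, visible))
        assert out.array.shape == (3, 3, 8)
        np.testing.assert_array_equal(out.positions, visible)

    def test_visible_count_at_reference_ratio(self):
        m = MaskedAutoencoder(ModelConfig(d=16, d_k=8, d_v=8, n_layers=1, h=2), 42, seed=0)
        plan = make_mask(42, 0.6, seed=0)
        out = m.encode(m.project(np.zeros((1, 42, 12))), "visible_only", plan)
        assert out.array.shape == (1, 17, 16)

    def test_missing_plan_errors(self, model, segments):
        with pytest.raises(ValueError):
            model.encode(model.project(segments), "visible_only", None)

    def test_permutation_equivariance_without_positions(self, model, segments):
        model.pos.data[:] = 0.0
        perm = np.array([3, 0, 6, 2, 5, 1, 4])
        out = model.encode(model.project(segments), "full").array
        out_perm = model.encode(model.project(segments[:, perm]), "full").array
        np.testing.assert_allclose(out[:, perm], out_perm, atol=1e-5)

    def test_evaluation_mode_bitwise_deterministic(self, segments):
        m = MaskedAutoencoder(ModelConfig(d=8, d_k=4, d_v=4, n_layers=2, h=2, p1=0.3, w=5),
                              n_positions=7, seed=0).eval()
        a = m.encode(m.project(segments), "full").array
        b = m.encode(m.project(segments), "full").array
        assert np.array_equal(a, b)


class TestDecoderPath:
    def test_mask_token_placement(self, model, segments):
        masked = np.array([[1, 3]] * 3)
        visible = np.array([[0, 2, 4, 5, 6]] * 3)
        X = model.project(segments)
        Hv = model.encode(X, "visible_only", (masked, visible))
        dec_in = model.build_decoder_input(Hv, (masked, visible))
        token = model.mask_token.data
        for j in [1, 3]:
            expected = np.tile(token + model.pos.data[j], (3, 1))
            np.testing.assert_allclose(dec_in.array[:, j], expected, atol=1e-12)
        np.testing.assert_allclose(dec_in.array[:, [0, 2, 4, 5, 6]], Hv.array, atol=1e-12)

    def test_mismatched_plan_rejected(self, model, segments):
        masked, visible = np.array([[1, 3]] * 3), np.array([[0, 2, 4, 5, 6]] * 3)
        X = model.project(segments)
        Hv = model.encode(X, "visible_only", (masked, visible))
        other = (np.array([[0, 3]] * 3), np.array([[1, 2, 4, 5, 6]] * 3))
        with pytest.raises(ValueError):
            model.build_decoder_input(Hv, other)

    def test_different_plans_differ_only_at_changed_positions(self, model, segments):
        X = model.project(segments)
        p1 = (np.array([[1, 3]] * 3), np.array([[0, 2, 4, 5, 6]] * 3))
        p2 = (np.array([[1, 4]] * 3), np.array([[0, 2, 3, 5, 6]] * 3))
        d1 = model.build_decoder_input(model.encode(X, "visible_only", p1), p1).array
        d2 = model.build_decoder_input(model.encode(X, "visible_only", p2), p2).array
        same = [0, 2, 5, 6]  # visible in both (self-attention over equal sets differs,
        # so compare only the mask-token columns and shared structure)
        np.testing.assert_allclose(d1[:, 1], d2[:, 1], atol=1e-12)  # masked in both

    def test_decode_full_length_and_deterministic(self, model, segments):
        masked, visible = _plans(np.random.default_rng(0), 3, 7, 4)
        X = model.project(segments)
        dec_in = model.build_decoder_input(model.encode(X, "visible_only", (masked, visible)),
                                           (masked, visible))
        out1 = model.decode(dec_in).array
        out2 = model.decode(dec_in).array
        assert out1.shape == (3, 7, 8)
        assert np.array_equal(out1, out2)

    def test_default_depth_builds(self):
        m = MaskedAutoencoder(ModelConfig(), n_positions=42, seed=0)
        assert len(m.decoder) == 8 and m.decoder[0].mix.h == 4


class TestPretrainTargets:
    def test_values_identical_to_encoder_output(self, model, segments, rng):
        masked, visible = _plans(rng, 3, 7, 4)
        Hm = model.encode(model.project(segments), "masked_only", (masked, visible))
        tgt = MaskedAutoencoder.pretrain_targets(Hm)
        np.testing.assert_array_equal(tgt.array, Hm.array)
        assert tgt.array.shape == (3, 4, 8)

    def test_gradient_isolation_on_one_layer_toy(self, rng):
        """No training signal flows into the encoder through the target branch."""
        mcfg = ModelConfig(d=4, d_k=2, d_v=2, n_layers=1, h=1, p1=0.0, w=3)
        segments = rng.normal(size=(2, 4, 3))
        masked = np.array([[1, 3], [0, 2]])
        visible = np.array([[0, 2], [1, 3]])

        def grads(isolate):
            m = MaskedAutoencoder(mcfg, n_positions=4, seed=0).eval()
            X = m.project(segments)
            Hv = m.encode(X, "visible_only", (masked, visible))
            Hm = m.encode(X, "masked_only", (masked, visible))
            tgt = m.pretrain_targets(Hm) if isolate else Hm
            F = m.decode(m.build_decoder_input(Hv, (masked, visible)))
            loss = mse_latent_loss(m.decoded_at(F, masked), tgt)
            for p in m.parameters():
                p.grad = None
            loss.backward()
            return m

    # with isolation, the loss is 0.5*d/d(pred) of ||pred - const||^2: the
    # encoder still receives gradient through the visible branch, but the
    # target branch contributes nothing; without isolation the same weights
    # receive an extra term.  Verify against finite differences of the
    # isolated objective.
        m = grads(isolate=True)
        X0 = m.project(segments)
        Hm0 = m.encode(X0, "masked_only", (masked, visible)).array.copy()

        def isolated_loss():
            X = m.project(segments)
            Hv = m.encode(X, "visible_only", (masked, visible))
            F = m.decode(m.build_decoder_input(Hv, (masked, visible)))
            Fm = m.decoded_at(F, masked).array
            return float(((Fm - Hm0) ** 2).mean())

        p = m.proj.W
        idx = (1, 2)
        eps = 1e-6
        orig = p.data[idx]
        p.data[idx] = orig + eps
        lp = isolated_loss()
        p.data[idx] = orig - eps
        lm = isolated_loss()
        p.data[idx] = orig
        num = (lp - lm) / (2 * eps)
        assert abs(num - p.grad[idx]) <= 1e-4 * max(1.0, abs(num))


class TestLossAndPooling:
    def test_mse_zero_when_equal(self, rng):
        x = Tensor(rng.normal(size=(2, 3, 4)))
        assert mse_latent_loss(x, x).item() == 0.0

    def test_mse_hand_example(self):
        f = Tensor(np.array([[1.0, 0.0], [0.0, 1.0]]))
        h = Tensor(np.zeros((2, 2)))
        assert mse_latent_loss(f, h).item() == pytest.approx(0.5)

    def test_mse_brute_force_oracle(self, rng):
        a, b = rng.normal(size=(3, 5, 6)), rng.normal(size=(3, 5, 6))
        expected = float(np.sum((a - b) ** 2) / a.size)
        assert mse_latent_loss(Tensor(a), Tensor(b)).item() == pytest.approx(
            expected, abs=1e-10
        )

    def test_mse_shape_mismatch_errors(self, rng):
        with pytest.raises(ValueError):
            mse_latent_loss(Tensor(np.zeros((2, 3))), Tensor(np.zeros((3, 2))))

    def test_pooling_of_constant_rows(self, model):
        segs = np.zeros((1, 7, 5))
        z = model.embed_event(segs)
        H = model.encode(model.project(segs), "full").array
        np.testing.assert_allclose(z.data[0], H[0].mean(axis=0), atol=1e-12)

    def test_pooling_brute_force_oracle(self, model, segments):
        z = model.embed_event(segments).data
        H = model.encode(model.project(segments), "full").array
        np.testing.assert_allclose(z, H.mean(axis=1), atol=1e-10)


class TestClassifier:
    def test_zero_weights_zero_logits(self, rng):
        clf = Classifier(ClassifierConfig(M=8, d_c=16, p2=0.0), d=8, seed=0).eval()
        for p in clf.parameters():
            p.data[:] = 0.0
        out = clf(rng.normal(size=(5, 8)))
        assert np.all(out.data == 0.0)

    def test_eight_class_output_shape(self, rng):
        clf = Classifier(ClassifierConfig(M=8), d=64, seed=0).eval()
        assert clf(rng.normal(size=(4, 64))).shape == (4, 8)
        assert clf.cfg.d_c == 256  # default hidden width

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            ClassifierConfig(M=1)
        with pytest.raises(ValueError):
            ModelConfig(p1=1.0)


class TestStructure:
    def test_parameter_count_reproducible(self):
        n1 = count_parameters(MaskedAutoencoder(ModelConfig(), 42, seed=0))
        n2 = count_parameters(MaskedAutoencoder(ModelConfig(), 42, seed=99))
        assert n1 == n2 > 0

    def test_cnn_backbone_is_drop_in(self, rng):
        """The convolutional ablation exposes identical operation signatures."""
        mcfg = ModelConfig(d=8, d_k=4, d_v=4, n_layers=1, h=2, p1=0.0, w=5, backbone="cnn")
        m = MaskedAutoencoder(mcfg, n_positions=7, seed=0).eval()
        segs = rng.normal(size=(2, 7, 5))
        masked, visible = np.array([[1, 3]] * 2), np.array([[0, 2, 4, 5, 6]] * 2)
        X = m.project(segs)
        Hv = m.encode(X, "visible_only", (masked, visible))
        F = m.decode(m.build_decoder_input(Hv, (masked, visible)))
        assert F.array.shape == (2, 7, 8)
        assert m.embed_event(segs).shape == (2, 8)

    def test_state_dict_round_trip(self, model, segments):
        state = model.state_dict()
        other = MaskedAutoencoder(TINY, n_positions=7, seed=123).eval()
        other.load_state_dict(state)
        np.testing.assert_array_equal(
            model.embed_event(segments).data, other.embed_event(segments).data
        )

    def test_training_step_changes_parameters(self, rng):
        m = MaskedAutoencoder(TINY, n_positions=7, seed=0).train()
        segs = rng.normal(size=(2, 7, 5))
        masked, visible = np.array([[1, 3]] * 2), np.array([[0, 2, 4, 5, 6]] * 2)
        X = m.project(segs)
        Hv = m.encode(X, "visible_only", (masked, visible))
        Hm = m.encode(X, "masked_only", (masked, visible))
        F = m.decode(m.build_decoder_input(Hv, (masked, visible)))
        loss = mse_latent_loss(m.decoded_at(F, masked), m.pretrain_targets(Hm))
        opt = Adam(m.parameters(), lr=1e-3)
        before = m.proj.W.data.copy()
        opt.zero_grad()
        loss.backward()
        opt.step()
        assert not np.array_equal(before, m.proj.W.data)
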