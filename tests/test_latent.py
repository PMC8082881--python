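import numpy as np
import pytest

from smalf.core_data import AssociationDataset
from smalf.latent import (
    AutoencoderConfig,
    EncoderModel,
    encode,
    reconstruction_loss,
    split_original_features,
    train_stacked_autoencoder,
)
from smalf.synthetic import generate_synthetic_dataset


def sigmoid(a):
    return 1 / (1 + np.exp(-a))


def small_config(**overrides):
    defaults = dict(
        latent_dim=4,
        hidden_dims=(8, 4),
        epochs_pretrain=30,
        epochs_finetune=60,
        seed=0,
    )
    defaults.update(overrides)
    return AutoencoderConfig(**defaults)


class TestSplitOriginalFeatures:
    def test_rows_and_columns(self):
        Y = np.array([[1, 0, 1], [0, 0, 0]], dtype=np.int8)
        ds = AssociationDataset(("m1", "m2"), ("a", "b", "c"), Y)
        M, D = split_original_features(ds)
        assert M.shape == (2, 3) and D.shape == (3, 2)
        np.testing.assert_array_equal(D, Y.T)
        np.testing.assert_array_equal(M, Y)

    def test_single_association_corner(self):
        Y = np.zeros((2, 2), dtype=np.int8)
        Y[0, 0] = 1
        ds = AssociationDataset(("m1", "m2"), ("a", "b"), Y)
        M, D = split_original_features(ds)
        assert M[0].tolist() == [1, 0]
        assert D[0].tolist() == [1, 0]

    def test_widths_match_opposite_axis(self):
        rng = np.random.default_rng(0)
        Y = (rng.random((9, 5)) < 0.3).astype(np.int8)
        ds = AssociationDataset(
            tuple(f"m{i}" for i in range(9)), tuple(f"d{j}" for j in range(5)), Y
        )
        M, D = split_original_features(ds)
        assert M.shape[1] == ds.n_disease
        assert D.shape[1] == ds.n_mirna


class TestEncode:
    def manual_model(self):
        """Hand-built 2-layer encoder for oracle comparison."""
        rng = np.random.default_rng(42)
        W1, b1 = rng.normal(size=(5, 6)), rng.normal(size=5)
        W2, b2 = rng.normal(size=(3, 5)), rng.normal(size=3)
        enc = [(W1, b1, "sigmoid"), (W2, b2, "linear")]
        dec = [(W2.T.copy(), np.zeros(5), "sigmoid"), (W1.T.copy(), np.zeros(6), "tanh")]
        cfg = AutoencoderConfig(latent_dim=3, hidden_dims=(5, 3))
        return EncoderModel(enc, dec, cfg), (W1, b1, W2, b2)

    def test_forward_pass_matches_matrix_multiply_oracle(self):
        model, (W1, b1, W2, b2) = self.manual_model()
        rng = np.random.default_rng(1)
        X = rng.random((10, 6))
        expected = sigmoid(X @ W1.T + b1) @ W2.T + b2
        got = model.encode(X)
        assert np.abs(got - expected).max() < 1e-5

    def test_zero_weight_model_encodes_to_zero(self):
        enc = [(np.zeros((3, 4)), np.zeros(3), "sigmoid"), (np.zeros((2, 3)), np.zeros(2), "linear")]
        dec = [(np.zeros((3, 2)), np.zeros(3), "sigmoid"), (np.zeros((4, 3)), np.zeros(4), "tanh")]
        model = EncoderModel(enc, dec, AutoencoderConfig(latent_dim=2, hidden_dims=(3, 2)))
        np.testing.assert_array_equal(model.encode(np.ones((5, 4))), 0.0)

    def test_identity_linear_encoder(self):
        enc = [(np.eye(2), np.zeros(2), "linear")]
        model = EncoderModel(enc, [], AutoencoderConfig(latent_dim=2, hidden_dims=(2,)))
        np.testing.assert_allclose(model.encode(np.array([[0.3, 0.7]])), [[0.3, 0.7]])

    def test_width_mismatch_errors(self):
        model, _ = self.manual_model()
        with pytest.raises(ValueError, match="width"):
            model.encode(np.zeros((2, 7)))

    def test_encode_wraps_ids(self):
        model, _ = self.manual_model()
        lf = encode(model, np.zeros((2, 6)), ids=("a", "b"))
        assert lf.ids == ("a", "b")
        assert lf.Z.shape == (2, 3)


class TestReconstructionLoss:
    def identity_model(self):
        enc = [(np.eye(3), np.zeros(3), "linear")]
        dec = [(np.eye(3), np.zeros(3), "linear")]
        return EncoderModel(enc, dec, AutoencoderConfig(latent_dim=3, hidden_dims=(3,)))

    def test_perfect_reconstruction_zero_loss(self):
        model = self.identity_model()
        X = np.random.default_rng(0).random((4, 3))
        assert reconstruction_loss(model, X, lam=0.0) == pytest.approx(0.0)

    def test_single_cell_offset_gives_unit_loss(self):
        enc = [(np.eye(3), np.array([0.0, 0.0, 1.0]), "linear")]
        dec = [(np.eye(3), np.zeros(3), "linear")]
        model = EncoderModel(enc, dec, AutoencoderConfig(latent_dim=3, hidden_dims=(3,)))
        X = np.zeros((1, 3))
        assert reconstruction_loss(model, X, lam=0.0) == pytest.approx(1.0)

    def test_jacobian_term_matches_finite_differences(self):
        rng = np.random.default_rng(7)
        W1, b1 = rng.normal(scale=0.5, size=(3, 2)), rng.normal(size=3)
        enc = [(W1, b1, "sigmoid")]
        dec = [(rng.normal(size=(2, 3)), np.zeros(2), "tanh")]
        model = EncoderModel(enc, dec, AutoencoderConfig(latent_dim=3, hidden_dims=(3,)))
        x = rng.random(2)
        # finite-difference Jacobian of h(x) = sigmoid(W1 x + b1)
        eps = 1e-6
        J = np.zeros((3, 2))
        for k in range(2):
            xp, xm = x.copy(), x.copy()
            xp[k] += eps
            xm[k] -= eps
            hp = sigmoid(W1 @ xp + b1)
            hm = sigmoid(W1 @ xm + b1)
            J[:, k] = (hp - hm) / (2 * eps)
        expected_penalty = (J**2).sum()
        loss0 = reconstruction_loss(model, x[None], lam=0.0)
        loss1 = reconstruction_loss(model, x[None], lam=1.0)
        assert loss1 - loss0 == pytest.approx(expected_penalty, abs=1e-4)


@pytest.fixture(scope="module")
def planted_matrix():
    ds = generate_synthetic_dataset(n_mirna=100, n_disease=80, seed=1)
    return split_original_features(ds.dataset)[0]


class TestTraining:
    def test_output_shape_contract(self, planted_matrix):
        model = train_stacked_autoencoder(planted_matrix, small_config())
        Z = model.encode(planted_matrix)
        assert Z.shape == (planted_matrix.shape[0], 4)

    def test_finetuning_reduces_loss(self, planted_matrix):
        cfg = small_config(hidden_dims=(32, 8), latent_dim=8)
        model = train_stacked_autoencoder(planted_matrix, cfg)
        assert model.finetune_losses[-1] < model.finetune_losses[0]
        # median of the last 10 epochs below median of the first 10
        assert np.median(model.finetune_losses[-10:]) < np.median(model.finetune_losses[:10])

    def test_identical_seed_reproduces_latents_bitwise(self, planted_matrix):
        cfg = small_config(seed=3)
        Z1 = train_stacked_autoencoder(planted_matrix, cfg).encode(planted_matrix)
        Z2 = train_stacked_autoencoder(planted_matrix, cfg).encode(planted_matrix)
        np.testing.assert_array_equal(Z1, Z2)

    def test_row_permutation_permutes_codes(self, planted_matrix):
        model = train_stacked_autoencoder(planted_matrix, small_config())
        perm = np.random.default_rng(0).permutation(planted_matrix.shape[0])
        Z = model.encode(planted_matrix)
        Zp = model.encode(planted_matrix[perm])
        np.testing.assert_allclose(Zp, Z[perm], atol=1e-12)

    def test_no_compression_warns(self):
        X = np.random.default_rng(0).random((10, 3))
        cfg = AutoencoderConfig(latent_dim=4, hidden_dims=(6, 4), epochs_pretrain=2, epochs_finetune=2)
        with pytest.warns(UserWarning, match="no compression"):
            train_stacked_autoencoder(X, cfg)

    def test_block_structure_recovered_in_latent_space(self):
        """Same-block miRNAs should be closer in code space than cross-block
        ones, on average over seeds."""
        margins = []
        for seed in range(5):
            ds = generate_synthetic_dataset(n_mirna=80, n_disease=60, seed=seed)
            M, _ = split_original_features(ds.dataset)
            cfg = small_config(hidden_dims=(32, 8), latent_dim=8, seed=seed,
                              epochs_pretrain=100, epochs_finetune=300)
            Z = train_stacked_autoencoder(M, cfg).encode(M)
            Zn = Z / (np.linalg.norm(Z, axis=1, keepdims=True) + 1e-12)
            C = Zn @ Zn.T
            same = ds.mirna_blocks[:, None] == ds.mirna_blocks[None, :]
            np.fill_diagonal(same, False)
            off_diag = ~np.eye(len(Z), dtype=bool)
            margins.append(C[same].mean() - C[~same & off_diag].mean())
        assert np.mean(margins) > 0


class TestModelSerialization:
    def test_save_load_round_trip(self, tmp_path):
        X = np.random.default_rng(0).random((20, 10))
        model = train_stacked_autoencoder(X, small_config())
        f = tmp_path / "model.npz"
        model.save(f)
        back = EncoderModel.load(f)
        np.testing.assert_array_equal(back.encode(X), model.encode(X))
        assert back.config == model.config
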