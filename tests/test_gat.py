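import numpy as np
import pytest
from rdkit import Chem

from halbde.correlation import Metrics
from halbde.errors import DivergenceError, HalBDEError
from halbde.featurize import DescriptorConfig, mol_to_graph
from halbde.gat import (GATRegressor, GATResults, GraphBatch, ModelConfig,
                        backward, forward, init_params, run_ablation)
from halbde.registry import parse_smiles
from halbde.synthetic import generate_toy_library

TINY = ModelConfig(n_gat_layers=2, attention_heads=2, hidden_dim=6,
                   head_hidden=16, max_epochs=200, patience=200,
                   val_fraction=0.0, seed=0)


@pytest.fixture(scope="module")
def toy_data():
    smiles, targets = generate_toy_library(60, "composition_linear", seed=0)
    graphs = [mol_to_graph(s) for s in smiles]
    return smiles, graphs, np.asarray(targets)


class TestNumerics:
    def test_gradients_match_finite_differences(self):
        """Hand-written backprop agrees with central finite differences."""
        graphs = [mol_to_graph(s) for s in ["CCO", "c1ccccc1F", "ClCCBr"]]
        batch = GraphBatch(graphs)
        cfg = ModelConfig(n_gat_layers=2, attention_heads=2, hidden_dim=4,
                          head_hidden=5)
        rng = np.random.default_rng(1)
        params = init_params(cfg, batch.X.shape[1], rng)
        # move attention logits off the LeakyReLU kink at zero so central
        # differences are valid
        for name in params:
            if name.endswith("_as") or name.endswith("_ad"):
                params[name] = rng.normal(0.0, 0.3, size=params[name].shape)
        y_ref = rng.normal(size=batch.n_graphs)

        def loss():
            y, _ = forward(params, cfg, batch)
            return float(np.mean((y - y_ref) ** 2))

        y, cache = forward(params, cfg, batch)
        grads = backward(params, cfg, batch, cache,
                         2.0 * (y - y_ref) / y.size)
        eps = 1e-6
        for name, arr in params.items():
            flat_ids = rng.choice(arr.size, size=min(4, arr.size),
                                  replace=False)
            for flat in flat_ids:
                idx = np.unravel_index(flat, arr.shape)
                orig = arr[idx]
                arr[idx] = orig + eps
                up = loss()
                arr[idx] = orig - eps
                down = loss()
                arr[idx] = orig
                numeric = (up - down) / (2 * eps)
                assert abs(numeric - grads[name][idx]) <= 1e-4 * max(
                    1.0, abs(numeric)), name

    def test_batch_packing_preserves_graph_sizes(self):
        graphs = [mol_to_graph(s) for s in ["C", "CC", "CCC"]]
        batch = GraphBatch(graphs)
        assert batch.n_nodes == 6
        assert np.array_equal(batch.counts, [1, 2, 3])
        # one self-loop per node on top of the symmetric bond edges
        assert batch.src.size == 2 * (0 + 1 + 2) + 6


class TestTraining:
    def test_loss_decreases_on_toy_subset(self, toy_data):
        _, graphs, targets = toy_data
        res = GATRegressor(graphs[:20], targets[:20], TINY).fit()
        hist = res.history
        assert hist.train_mse.iloc[-1] < 0.5 * hist.train_mse.iloc[0]
        assert np.isfinite(hist.train_mse).all()

    def test_same_seed_same_weights(self, toy_data):
        _, graphs, targets = toy_data
        a = GATRegressor(graphs[:15], targets[:15], TINY).fit()
        b = GATRegressor(graphs[:15], targets[:15], TINY).fit()
        for k in a.params:
            assert np.max(np.abs(a.params[k] - b.params[k])) <= 1e-6

    def test_memorization_of_five_molecules(self, toy_data):
        _, graphs, targets = toy_data
        cfg = ModelConfig(n_gat_layers=2, attention_heads=2, hidden_dim=8,
                          head_hidden=16, max_epochs=500, patience=500,
                          val_fraction=0.0, batch_size=5, seed=1)
        res = GATRegressor(graphs[:5], targets[:5], cfg).fit()
        pred = res.predict_graphs(graphs[:5])
        assert np.max(np.abs(pred - targets[:5])) <= 1.0

    def test_divergence_raises_with_epoch_and_lr(self, toy_data):
        _, graphs, targets = toy_data
        cfg = ModelConfig(n_gat_layers=1, attention_heads=1, hidden_dim=4,
                          learning_rate=1e6, max_epochs=30, patience=30,
                          val_fraction=0.0, seed=0)
        with pytest.raises(DivergenceError, match="epoch"):
            GATRegressor(graphs[:10], targets[:10] * 1e6, cfg).fit()

    def test_early_stopping_restores_best_validation_epoch(self, toy_data):
        _, graphs, targets = toy_data
        cfg = ModelConfig(n_gat_layers=1, attention_heads=2, hidden_dim=6,
                          head_hidden=8, max_epochs=120, patience=15,
                          val_fraction=0.2, seed=3)
        res = GATRegressor(graphs, targets, cfg).fit()
        assert res.best_epoch == int(res.history.val_mse.idxmin())


class TestPrediction:
    def test_permutation_invariance(self, toy_data):
        """Predictions are identical for any atom ordering of a molecule."""
        _, graphs, targets = toy_data
        res = GATRegressor(graphs[:20], targets[:20], TINY).fit()
        smiles = "CC(=O)OCCBr"
        base = res.predict_smiles(smiles)
        mol = parse_smiles(smiles)
        rng = np.random.default_rng(0)
        for _ in range(4):
            perm = rng.permutation(mol.GetNumAtoms()).tolist()
            alt = Chem.MolToSmiles(Chem.RenumberAtoms(mol, perm),
                                   canonical=False)
            assert abs(res.predict_smiles(alt) - base) <= 1e-5

    def test_feature_length_mismatch_rejected(self, toy_data):
        _, graphs, targets = toy_data
        res = GATRegressor(graphs[:10], targets[:10], TINY).fit()
        wrong = mol_to_graph("CCO", DescriptorConfig(True, False, False))
        with pytest.raises(HalBDEError, match="feature length"):
            res.predict_graphs([wrong])

    def test_evaluate_perfect_stub(self, toy_data):
        _, graphs, targets = toy_data
        res = GATRegressor(graphs[:10], targets[:10], TINY).fit()
        m = res.evaluate(graphs[:10], res.predict_graphs(graphs[:10]))
        assert isinstance(m, Metrics)
        assert m.r_squared == pytest.approx(1.0)
        assert m.rmse == pytest.approx(0.0, abs=1e-9)

    def test_empty_evaluation_set_rejected(self, toy_data):
        _, graphs, targets = toy_data
        res = GATRegressor(graphs[:10], targets[:10], TINY).fit()
        with pytest.raises(ValueError):
            res.evaluate([], [])


class TestPersistence:
    def test_bundle_round_trip(self, toy_data, tmp_path):
        _, graphs, targets = toy_data
        res = GATRegressor(graphs[:15], targets[:15], TINY).fit()
        res.save(tmp_path / "bundle")
        loaded = GATResults.load(tmp_path / "bundle")
        a = res.predict_smiles("CCOC")
        b = loaded.predict_smiles("CCOC")
        assert a == pytest.approx(b, abs=1e-12)
        assert loaded.config == res.config
        assert loaded.scaler == res.scaler


class TestCapacityAndAblation:
    def test_capacity_on_composition_rule(self):
        """On targets exactly linear in atom counts the model should be
        near-perfect out of sample."""
        smiles, targets = generate_toy_library(200, "composition_linear",
                                               seed=2)
        graphs = [mol_to_graph(s) for s in smiles]
        # counts are only recoverable under sum pooling; the linear readout
        # plus strong weight decay biases training toward the exact solution
        cfg = ModelConfig(n_gat_layers=1, readout="sum", head_hidden=0,
                          weight_decay=0.1, max_epochs=1000, patience=1000,
                          seed=0)
        rng = np.random.default_rng(0)
        perm = rng.permutation(200)
        res = GATRegressor(graphs, np.asarray(targets), cfg).fit(
            train_idx=perm[:160], test_idx=perm[160:])
        assert res.evaluate_test().r_squared >= 0.99

    def test_species_block_suffices_on_composition_rule(self):
        """Ablation control: when the target depends only on composition,
        the species block alone is essentially as good as all three."""
        smiles, targets = generate_toy_library(120, "composition_linear",
                                               seed=6)
        cfg = ModelConfig(n_gat_layers=1, readout="sum", head_hidden=0,
                          weight_decay=0.1, max_epochs=600, patience=600,
                          seed=0)
        table = run_ablation(
            smiles, targets,
            [DescriptorConfig(True, False, False), DescriptorConfig()],
            model_config=cfg, n_seeds=1)
        species = table.set_index("descriptors").loc["species", "test_r2_mean"]
        assert species >= 0.98

    def test_single_config_ablation_table(self, toy_data):
        smiles, _, targets = toy_data
        table = run_ablation(smiles, targets, [DescriptorConfig()],
                             model_config=TINY, n_seeds=1)
        assert len(table) == 1
        assert set(table.columns) >= {"descriptors", "test_r2_mean",
                                      "train_r2_mean"}


def test_halogen_identity_only_via_element_onehot():
    """The joint-task design: no feature block encodes halogen identity other
    than the element one-hot, so a model pools all three halogen centers."""
    cfg = DescriptorConfig(use_species=False, use_charge=False,
                           use_neighbor_info=True)
    vecs = {}
    for hal in ("I", "Br", "Cl"):
        g = mol_to_graph(f"O=C1O{hal}(F)c2ccccc21", cfg)
        center = [i for i in range(g.n_nodes)][3]
        vecs[hal] = g.node_features.sum(axis=0)
    # neighbor-info block cannot tell the three reagents apart
    assert np.allclose(vecs["I"], vecs["Br"])
    assert np.allclose(vecs["I"], vecs["Cl"])
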