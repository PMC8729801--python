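"""Graph featurization and the gated graph-attention classifier:
structural properties (equivariance, gating, readout invariance),
training behavior and the cross-validated ensemble."""

import numpy as np
import pytest

from druglikeness.autodiff import Tensor
from druglikeness.chem import SmilesParseError
from druglikeness.evaluation import auroc
from druglikeness.gcn import (
    N_ATOM_FEATURES,
    GraphConvClassifier,
    balanced_indices,
    classify,
    featurize,
    graph_conv_layer,
    readout,
    train_tcc,
)

# ------------------------------------------------------------ featurize


def test_feature_vector_layout():
    g = featurize("CCO")
    assert g.atom_features.shape == (3, N_ATOM_FEATURES)
    assert N_ATOM_FEATURES == 31
    # each one-hot block has exactly one active bit
    for row in g.atom_features:
        assert row[0:10].sum() == 1    # symbol
        assert row[10:17].sum() == 1   # hydrogens
        assert row[17:24].sum() == 1   # degree
        assert row[24:30].sum() == 1   # implicit valence
        assert row[30] in (0.0, 1.0)   # aromaticity


def test_benzene_features_match_chemistry():
    g = featurize("c1ccccc1")
    assert g.n_atoms == 6
    for row in g.atom_features:
        assert row[0] == 1.0       # carbon
        assert row[10 + 1] == 1.0  # one hydrogen
        assert row[17 + 2] == 1.0  # degree two
        assert row[30] == 1.0      # aromatic
    assert np.array_equal(g.adjacency, g.adjacency.T)
    assert np.all(np.diag(g.adjacency) == 0)
    assert g.adjacency.sum() == 12  # 6 ring bonds, both directions


def test_methane_features():
    g = featurize("C")
    row = g.atom_features[0]
    assert row[0] == 1.0 and row[10 + 4] == 1.0 and row[17 + 0] == 1.0
    assert row[30] == 0.0
    assert g.adjacency.shape == (1, 1)


def test_featurize_invalid_smiles():
    with pytest.raises(SmilesParseError):
        featurize("C(")


# ----------------------------------------------------------- conv layer


def _layer_params(rng, D=8, heads=4):
    dh = D // heads
    p = {}
    for h in range(heads):
        p[f"Wh{h}"] = rng.normal(size=(D, dh)) * 0.3
        p[f"bh{h}"] = rng.normal(size=(dh,)) * 0.1
    p["Wo"] = rng.normal(size=(heads * dh, D)) * 0.3
    p["bo"] = rng.normal(size=(D,)) * 0.1
    p["Wz"] = rng.normal(size=(2 * D, D)) * 0.3
    p["bz"] = rng.normal(size=(D,)) * 0.1
    return p


def test_conv_layer_permutation_equivariance():
    rng = np.random.default_rng(0)
    params = _layer_params(rng)
    molecules = ["CCO", "c1ccccc1", "CC(N)C(=O)O", "C1CCCCC1N", "CCOC(=O)C",
                 "c1ccc(O)cc1", "CC(C)CC", "NCCN", "CC(=O)NC", "c1ccncc1"]
    for smiles in molecules:
        g = featurize(smiles)
        n = g.n_atoms
        H = rng.normal(size=(n, 8))
        out = graph_conv_layer(H, g.adjacency, params)
        for _ in range(2):
            perm = rng.permutation(n)
            out_p = graph_conv_layer(H[perm], g.adjacency[np.ix_(perm, perm)],
                                     params)
            assert np.allclose(out_p, out[perm], atol=1e-10)


def test_conv_layer_gate_zero_is_identity():
    rng = np.random.default_rng(1)
    params = _layer_params(rng)
    params["Wz"] = np.zeros_like(params["Wz"])
    params["bz"] = np.full_like(params["bz"], -60.0)  # sigmoid -> 0
    g = featurize("c1ccccc1")
    H = rng.normal(size=(6, 8))
    assert np.allclose(graph_conv_layer(H, g.adjacency, params), H)


def test_conv_layer_isolated_node_uses_only_self():
    rng = np.random.default_rng(2)
    params = _layer_params(rng)
    A = np.zeros((2, 2))  # two isolated atoms
    H = rng.normal(size=(2, 8))
    out = graph_conv_layer(H, A, params)
    H2 = H.copy()
    H2[1] = rng.normal(size=8)  # perturb the other node
    out2 = graph_conv_layer(H2, A, params)
    assert np.allclose(out[0], out2[0])  # node 0 unaffected


def test_conv_layer_shape_validation():
    rng = np.random.default_rng(3)
    params = _layer_params(rng)
    with pytest.raises(ValueError):
        graph_conv_layer(rng.normal(size=(3, 8)), np.zeros((2, 2)), params)


# -------------------------------------------------------------- readout


def test_readout_permutation_invariance_and_dim():
    rng = np.random.default_rng(4)
    H = rng.normal(size=(7, 8))
    W = rng.normal(size=(8, 256))
    b = rng.normal(size=256)
    out = readout(H, W, b)
    assert out.shape == (256,)
    assert np.allclose(readout(H[rng.permutation(7)], W, b), out)


def test_readout_duplicated_graph_doubles_presum():
    rng = np.random.default_rng(5)
    H = rng.normal(size=(4, 8))
    W = np.eye(8)
    b = np.zeros(8)
    doubled = readout(np.vstack([H, H]), W, b)
    assert np.allclose(doubled, np.maximum(2 * H.sum(axis=0), 0))
    with pytest.raises(ValueError):
        readout(np.zeros((0, 8)), W, b)


# ------------------------------------------------------------- training


def test_balanced_indices_downsamples_larger_class():
    y = np.array([1] * 30 + [0] * 12)
    keep = balanced_indices(y, np.random.default_rng(0))
    assert len(keep) == 24
    assert (y[keep] == 1).sum() == (y[keep] == 0).sum() == 12


def test_fit_balances_and_builds_fold_ensemble(toy_experiment):
    tcc = toy_experiment.tcc
    assert len(tcc.fold_params_) == tcc.n_folds == 5
    assert tcc.n_training_samples_ == 600
    # training loss decreases (smoothed) in every fold
    for hist in tcc.loss_history_:
        assert np.mean(hist[-5:]) < hist[0]


def test_separable_classes_reach_high_auroc(toy_experiment):
    value = auroc(toy_experiment.tcc_pos, toy_experiment.tcc_neg)
    assert value >= 0.99


def test_predictions_strictly_inside_unit_interval(toy_experiment):
    probs = np.concatenate([toy_experiment.tcc_pos, toy_experiment.tcc_neg,
                            toy_experiment.tcc_ood])
    assert np.all((probs > 0.0) & (probs < 1.0))
    p = toy_experiment.tcc.predict_proba(["CCO"])
    assert p.shape == (1, 2)
    assert p.sum() == pytest.approx(1.0)


def test_zeroed_final_layer_outputs_half():
    model = GraphConvClassifier(node_dim=8, n_conv_layers=1, readout_dim=8,
                                mlp_hidden=8, n_folds=2, epochs=1, seed=0)
    rng = np.random.default_rng(0)
    params = model._init_params(rng)
    params["mlp_W2"].data[:] = 0.0
    params["mlp_b2"].data[:] = 0.0
    model.classes_ = np.array([0, 1])
    model.fold_params_ = [params]
    assert classify(model, "CCO") == pytest.approx(0.5)


def test_fit_input_validation():
    with pytest.raises(ValueError):
        train_tcc([], ["CC"])
    with pytest.raises(ValueError):
        GraphConvClassifier().fit(["CC", "CCC"], [1, 1])  # one class
    with pytest.raises(ValueError):
        GraphConvClassifier(n_folds=5).fit(
            ["CC", "CCC", "CCO", "CCN"], [1, 1, 0, 0])  # folds exceed class size


def test_untrained_model_raises():
    with pytest.raises(RuntimeError):
        GraphConvClassifier().decision_scores(["CC"])


def test_training_is_seed_deterministic():
    pos = ["c1ccccc1", "c1ccccc1C", "c1ccc(C)cc1", "c1ccccc1O", "c1ccc(O)cc1",
           "c1ccccc1N", "c1ccc(N)cc1", "Cc1ccccc1C", "c1ccccc1CC", "CCc1ccccc1C"]
    neg = ["CCCC", "CCCCC", "CCCCCC", "CC(C)CC", "CCOCC", "CCCO", "CCCCO",
           "CC(C)C", "CCC(C)C", "CCCCCCC"]
    runs = []
    for _ in range(2):
        m = GraphConvClassifier(node_dim=16, epochs=4, n_folds=2, seed=3,
                                batch_size=8)
        m.fit(pos + neg, [1] * 10 + [0] * 10)
        runs.append(m.decision_scores(["c1ccc(CC)cc1", "CCOC"]))
    assert np.array_equal(runs[0], runs[1])


def test_full_model_prediction_invariant_to_atom_order():
    model = GraphConvClassifier(node_dim=16, n_conv_layers=2, readout_dim=16,
                                mlp_hidden=16, seed=0)
    rng = np.random.default_rng(6)
    params = model._init_params(rng)
    g = featurize("CC(N)C(=O)O")
    n = g.n_atoms
    Xb, att, mask = model._pad_batch([g])
    base = model._forward_logits(params, Xb, att, mask).data
    for _ in range(5):
        perm = rng.permutation(n)
        Xp = Xb[:, perm]
        attp = att[:, perm][:, :, perm]
        out = model._forward_logits(params, Xp, attp, mask).data
        assert np.allclose(out, base, atol=1e-10)


def test_save_load_round_trip(tmp_path):
    pos = ["c1ccccc1", "c1ccccc1C", "c1ccc(C)cc1", "c1ccccc1O"]
    neg = ["CCCC", "CCCCC", "CCCCCC", "CC(C)CC"]
    m = GraphConvClassifier(node_dim=16, epochs=2, n_folds=2, seed=0)
    m.fit(pos + neg, [1] * 4 + [0] * 4)
    path = tmp_path / "tcc.npz"
    m.save(path)
    loaded = GraphConvClassifier.load(path)
    probe = ["c1ccccc1CC", "CCCCO"]
    assert np.array_equal(loaded.decision_scores(probe),
                          m.decision_scores(probe))
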