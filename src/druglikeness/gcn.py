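"""Attention- and gate-augmented graph convolutional classifier: the
supervised two-class (drug vs. non-drug-like) baseline.

Molecules enter as graphs G(H0, A): a 31-dimensional per-atom feature
matrix (one-hot atom symbol, hydrogen count, heavy-atom degree and
implicit valence, plus an aromaticity flag) and a binary heavy-atom
adjacency matrix.  Four graph-convolution layers update node features by
multi-head self-attention restricted to bonded neighbors plus self,
merged linearly and combined with the layer input through a learned
sigmoid gate (a gated residual).  A sum readout followed by a linear map
gives a 256-dimensional graph vector, and a two-layer MLP with a sigmoid
head outputs the probability of being a drug.  Training minimizes binary
cross-entropy with stratified K-fold cross-validation (default 5 folds);
inference averages the fold models' probabilities.  Dropout is applied
immediately before each fully connected layer during training.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from rdkit import Chem
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold

from .autodiff import Adam, Tensor, bce_with_logits, clip_global_norm, concat, masked_softmax
from .chem import SmilesParseError

__all__ = ["MolecularGraph", "featurize", "graph_conv_layer",
           "readout", "GraphConvClassifier", "classify", "train_tcc"]

_SYMBOLS = ["C", "N", "O", "S", "F", "P", "Cl", "Br", "I"]  # + else
N_ATOM_FEATURES = 10 + 7 + 7 + 6 + 1


def balanced_indices(y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Sorted indices downsampling the larger of two classes to the
    smaller one (without replacement)."""
    idx_pos = np.flatnonzero(y == 1)
    idx_neg = np.flatnonzero(y == 0)
    m = min(len(idx_pos), len(idx_neg))
    return np.sort(np.concatenate([
        rng.choice(idx_pos, size=m, replace=False),
        rng.choice(idx_neg, size=m, replace=False)]))


@dataclass(frozen=True)
class MolecularGraph:
    """Atom feature matrix (n_atoms x 31) and symmetric binary adjacency."""

    atom_features: np.ndarray
    adjacency: np.ndarray

    @property
    def n_atoms(self) -> int:
        return self.atom_features.shape[0]


def _one_hot(value, choices: list) -> list[float]:
    vec = [0.0] * (len(choices) + 1)
    vec[choices.index(value) if value in choices else len(choices)] = 1.0
    return vec


def featurize(smiles: str) -> MolecularGraph:
    """Graph representation with implicit hydrogens and order-free bonds."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"not a valid SMILES: {smiles!r}")
    feats = []
    for atom in mol.GetAtoms():
        row = (_one_hot(atom.GetSymbol(), _SYMBOLS)
               + _one_hot(atom.GetTotalNumHs(), [0, 1, 2, 3, 4, 5])
               + _one_hot(atom.GetDegree(), [0, 1, 2, 3, 4, 5])
               + _one_hot(atom.GetImplicitValence(), [0, 1, 2, 3, 4])
               + [1.0 if atom.GetIsAromatic() else 0.0])
        feats.append(row)
    n = mol.GetNumAtoms()
    adj = np.zeros((n, n))
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        adj[i, j] = adj[j, i] = 1.0
    return MolecularGraph(atom_features=np.asarray(feats), adjacency=adj)


# ----------------------------------------------------------- layer pieces

def _conv_layer(params: dict[str, Tensor], tag: str, H: Tensor,
                att_mask: np.ndarray, n_heads: int, head_dim: int) -> Tensor:
    """One gated graph-attention update on (batched) node features."""
    scale = 1.0 / math.sqrt(head_dim)
    heads = []
    for h in range(n_heads):
        P = H @ params[f"{tag}_Wh{h}"] + params[f"{tag}_bh{h}"]
        scores = (P @ P.transpose_last2()) * scale
        alpha = masked_softmax(scores, att_mask)
        heads.append(alpha @ P)
    H_att = (concat(heads, axis=-1) @ params[f"{tag}_Wo"] + params[f"{tag}_bo"]).relu()
    z = (concat([H, H_att], axis=-1) @ params[f"{tag}_Wz"] + params[f"{tag}_bz"]).sigmoid()
    return z * H_att + (1.0 - z) * H


def graph_conv_layer(H: np.ndarray, A: np.ndarray,
                     params: dict[str, np.ndarray], n_heads: int = 4) -> np.ndarray:
    """Functional single-graph forward pass of one convolution layer.

    `params` uses keys Wh{h}/bh{h} (per head), Wo/bo (merge), Wz/bz
    (gate).  Attention runs over bonded neighbors plus self.
    """
    if A.shape[0] != A.shape[1] or A.shape[0] != H.shape[0]:
        raise ValueError("feature/adjacency shapes are inconsistent")
    if not np.array_equal(A, A.T):
        raise ValueError("adjacency must be symmetric")
    tensors = {f"L_{k}": Tensor(v) for k, v in params.items()}
    att_mask = (A + np.eye(A.shape[0])) > 0
    head_dim = params["Wh0"].shape[1]
    out = _conv_layer(tensors, "L", Tensor(H), att_mask, n_heads, head_dim)
    return out.data


def readout(H: np.ndarray, W: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Sum node features, then a linear map + ReLU to the graph vector."""
    if H.shape[0] < 1:
        raise ValueError("readout requires at least one node")
    return np.maximum(H.sum(axis=0) @ W + b, 0.0)


# --------------------------------------------------------------- the model

class GraphConvClassifier(BaseEstimator, ClassifierMixin):
    """Two-class molecular classifier over SMILES, scikit-learn style.

    fit(X, y) takes SMILES strings and 0/1 labels (1 = drug).  The
    larger class is optionally downsampled to the smaller one, the data
    is split into `n_folds` stratified folds, and one model is trained
    per fold on the remaining folds; predict_proba averages the fold
    models.  Fitted attributes: ``classes_``, ``fold_params_``,
    ``fold_val_loss_``, ``loss_history_``.
    """

    def __init__(self, n_conv_layers: int = 4, n_attention_heads: int = 4,
                 node_dim: int = 64, readout_dim: int = 256,
                 mlp_hidden: int = 256, dropout_rate: float = 0.3,
                 n_folds: int = 5, learning_rate: float = 1e-3,
                 epochs: int = 80, batch_size: int = 64, seed: int = 0,
                 balance_classes: bool = True, grad_clip: float = 5.0):
        self.n_conv_layers = n_conv_layers
        self.n_attention_heads = n_attention_heads
        self.node_dim = node_dim
        self.readout_dim = readout_dim
        self.mlp_hidden = mlp_hidden
        self.dropout_rate = dropout_rate
        self.n_folds = n_folds
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.seed = seed
        self.balance_classes = balance_classes
        self.grad_clip = grad_clip

    # ------------------------------------------------------------- params
    def _head_dim(self) -> int:
        if self.node_dim % self.n_attention_heads:
            raise ValueError("node_dim must be divisible by n_attention_heads")
        return self.node_dim // self.n_attention_heads

    def _init_params(self, rng: np.random.Generator) -> dict[str, Tensor]:
        D, dh = self.node_dim, self._head_dim()

        def uniform(shape, fan_in):
            k = 1.0 / math.sqrt(fan_in)
            return Tensor(rng.uniform(-k, k, size=shape), requires_grad=True)

        p: dict[str, Tensor] = {
            "lift_W": uniform((N_ATOM_FEATURES, D), N_ATOM_FEATURES),
            "lift_b": uniform((D,), N_ATOM_FEATURES),
        }
        for l in range(self.n_conv_layers):
            tag = f"conv{l}"
            for h in range(self.n_attention_heads):
                p[f"{tag}_Wh{h}"] = uniform((D, dh), D)
                p[f"{tag}_bh{h}"] = uniform((dh,), D)
            p[f"{tag}_Wo"] = uniform((self.n_attention_heads * dh, D), D)
            p[f"{tag}_bo"] = uniform((D,), D)
            p[f"{tag}_Wz"] = uniform((2 * D, D), 2 * D)
            p[f"{tag}_bz"] = uniform((D,), 2 * D)
        p["read_W"] = uniform((D, self.readout_dim), D)
        p["read_b"] = uniform((self.readout_dim,), D)
        p["mlp_W1"] = uniform((self.readout_dim, self.mlp_hidden), self.readout_dim)
        p["mlp_b1"] = uniform((self.mlp_hidden,), self.readout_dim)
        p["mlp_W2"] = uniform((self.mlp_hidden, 1), self.mlp_hidden)
        p["mlp_b2"] = uniform((1,), self.mlp_hidden)
        return p

    # ------------------------------------------------------------ forward
    def _forward_logits(self, params: dict[str, Tensor], X: np.ndarray,
                        att_mask: np.ndarray, node_mask: np.ndarray,
                        dropout_rng: Optional[np.random.Generator] = None
                        ) -> Tensor:
        """Batched logits; dropout active iff `dropout_rng` is given."""
        H = (Tensor(X) @ params["lift_W"] + params["lift_b"]).relu()
        dh = self._head_dim()
        for l in range(self.n_conv_layers):
            H = _conv_layer(params, f"conv{l}", H, att_mask,
                            self.n_attention_heads, dh)
        summed = (H * Tensor(node_mask[..., None])).sum(axis=1)

        def drop(t: Tensor) -> Tensor:
            if dropout_rng is None or self.dropout_rate <= 0:
                return t
            keep = (dropout_rng.random(t.shape) >= self.dropout_rate)
            return t * (keep / (1.0 - self.dropout_rate))

        g = (drop(summed) @ params["read_W"] + params["read_b"]).relu()
        m1 = (drop(g) @ params["mlp_W1"] + params["mlp_b1"]).relu()
        return drop(m1) @ params["mlp_W2"] + params["mlp_b2"]

    @staticmethod
    def _pad_batch(graphs: list[MolecularGraph]
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        N = max(g.n_atoms for g in graphs)
        B = len(graphs)
        X = np.zeros((B, N, N_ATOM_FEATURES))
        att = np.zeros((B, N, N), dtype=bool)
        mask = np.zeros((B, N))
        for i, g in enumerate(graphs):
            n = g.n_atoms
            X[i, :n] = g.atom_features
            att[i, :n, :n] = (g.adjacency + np.eye(n)) > 0
            mask[i, :n] = 1.0
        return X, att, mask

    # ---------------------------------------------------------------- fit
    def fit(self, X: Sequence[str], y: Sequence[int]) -> "GraphConvClassifier":
        smiles = list(X)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("exactly two classes are required")
        rng = np.random.default_rng(np.random.SeedSequence([self.seed, 0x6C4]))
        yy = (y == self.classes_[1]).astype(int)
        if self.balance_classes:
            keep = balanced_indices(yy, rng)
            smiles = [smiles[i] for i in keep]
            yy = yy[keep]
        self.n_training_samples_ = len(smiles)
        if np.bincount(yy, minlength=2).min() < self.n_folds:
            raise ValueError("each class must have at least n_folds members")
        graphs = [featurize(s) for s in smiles]
        skf = StratifiedKFold(n_splits=self.n_folds, shuffle=True,
                              random_state=self.seed)
        self.fold_params_ = []
        self.fold_val_loss_ = []
        self.loss_history_ = []
        for fold, (tr, va) in enumerate(skf.split(np.zeros(len(yy)), yy)):
            frng = np.random.default_rng(
                np.random.SeedSequence([self.seed, 0x6C4, fold]))
            params = self._init_params(frng)
            history = self._train_fold(params, [graphs[i] for i in tr], yy[tr], frng)
            self.loss_history_.append(history)
            self.fold_val_loss_.append(
                self._eval_loss(params, [graphs[i] for i in va], yy[va]))
            self.fold_params_.append(params)
        return self

    def _train_fold(self, params: dict[str, Tensor],
                    graphs: list[MolecularGraph], y: np.ndarray,
                    rng: np.random.Generator) -> list[float]:
        opt = Adam(params, lr=self.learning_rate)
        order = sorted(range(len(graphs)), key=lambda i: graphs[i].n_atoms)
        batches = [order[i:i + self.batch_size]
                   for i in range(0, len(order), self.batch_size)]
        history = []
        for _ in range(self.epochs):
            total, count = 0.0, 0
            for b in rng.permutation(len(batches)):
                idx = batches[b]
                Xb, att, mask = self._pad_batch([graphs[i] for i in idx])
                logits = self._forward_logits(params, Xb, att, mask,
                                              dropout_rng=rng)
                loss = bce_with_logits(logits, y[idx][:, None].astype(float))
                opt.zero_grad()
                loss.backward(np.array(1.0 / len(idx)))
                clip_global_norm(params, self.grad_clip)
                opt.step()
                total += float(loss.data)
                count += len(idx)
            history.append(total / count)
        return history

    def _eval_loss(self, params: dict[str, Tensor],
                   graphs: list[MolecularGraph], y: np.ndarray) -> float:
        Xb, att, mask = self._pad_batch(graphs)
        logits = self._forward_logits(params, Xb, att, mask)
        return float(bce_with_logits(logits, y[:, None].astype(float)).data) / len(y)

    # ----------------------------------------------------------- predict
    def _check_fitted(self) -> None:
        if not hasattr(self, "fold_params_"):
            raise RuntimeError("classifier is not fitted; call fit() first")

    def decision_scores(self, X: Sequence[str]) -> np.ndarray:
        """Mean fold-model sigmoid output: probability of the positive
        class, strictly inside (0, 1)."""
        self._check_fitted()
        graphs = [featurize(s) for s in X]
        Xb, att, mask = self._pad_batch(graphs)
        probs = np.zeros(len(graphs))
        for params in self.fold_params_:
            logits = self._forward_logits(params, Xb, att, mask).data[:, 0]
            probs += 1.0 / (1.0 + np.exp(-np.clip(logits, -60, 60)))
        probs /= len(self.fold_params_)
        return np.clip(probs, 1e-12, 1.0 - 1e-12)

    def predict_proba(self, X: Sequence[str]) -> np.ndarray:
        p = self.decision_scores(X)
        return np.column_stack([1.0 - p, p])

    def predict(self, X: Sequence[str]) -> np.ndarray:
        return self.classes_[(self.decision_scores(X) > 0.5).astype(int)]

    # -------------------------------------------------------- persistence
    def save(self, path: str | Path) -> None:
        self._check_fitted()
        meta = {"config": self.get_params(),
                "classes": self.classes_.tolist(),
                "fold_val_loss": self.fold_val_loss_}
        arrays = {f"f{i}:{k}": t.data
                  for i, params in enumerate(self.fold_params_)
                  for k, t in params.items()}
        np.savez(path, __meta__=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "GraphConvClassifier":
        with np.load(path) as blob:
            meta = json.loads(bytes(blob["__meta__"]).decode())
            model = cls(**meta["config"])
            model.classes_ = np.asarray(meta["classes"])
            model.fold_val_loss_ = meta["fold_val_loss"]
            folds: dict[int, dict[str, Tensor]] = {}
            for key in blob.files:
                if key == "__meta__":
                    continue
                fold, name = key.split(":", 1)
                folds.setdefault(int(fold[1:]), {})[name] = Tensor(
                    blob[key], requires_grad=True)
        model.fold_params_ = [folds[i] for i in sorted(folds)]
        model.loss_history_ = []
        return model


# ------------------------------------------------------ functional surface

def classify(model: GraphConvClassifier, smiles: str) -> float:
    """Ensemble probability that `smiles` is a drug."""
    return float(model.decision_scores([smiles])[0])


def train_tcc(pos: Sequence[str], neg: Sequence[str],
              config: Optional[dict] = None) -> GraphConvClassifier:
    """Train the two-class model from positive/negative SMILES lists."""
    if not pos or not neg:
        raise ValueError("both classes must be non-empty")
    model = GraphConvClassifier(**(config or {}))
    X = list(pos) + list(neg)
    y = np.array([1] * len(pos) + [0] * len(neg))
    return model.fit(X, y)
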