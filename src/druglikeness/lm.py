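"""Autoregressive character-level SMILES language model and the
likelihood-based drug-likeness score.

The model factorizes the probability of a SMILES string S = (s_1..s_N),
framed by SOS/EOS sentinels, as

    p(S) = p(s_0) * prod_{t=0..N} p(s_{t+1} | s_0..s_t),   p(s_0) = 1,

with each conditional given by a stack of GRU layers feeding a softmax
over the character vocabulary.  Training on known drugs alone (no
negative set) makes p(S) a density over drug space, and the score

    score(S) = 100 + log p(S)

(natural log by default) is at most 100, with equality only when every
conditional along the sequence is 1.  Because stereochemistry matters for
drug action, a query molecule is scored as the maximum over its
stereoisomers.

The network is trained by teacher forcing with summed next-token
cross-entropy, Adam, and global-norm gradient clipping, implemented on
the in-package reverse-mode autodiff engine.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator

from . import chem
from .autodiff import Adam, Tensor, clip_global_norm, gather_rows, softmax_cross_entropy
from .tokenizer import TokenizationError, Vocabulary, build_vocabulary, encode

__all__ = [
    "SmilesLanguageModel",
    "DeterministicSequenceModel",
    "DrugLikenessScore",
    "next_token_distribution",
    "sequence_log_probability",
    "stepwise_log_probabilities",
    "drug_likeness_score",
    "score_molecule",
    "train",
]


@dataclass(frozen=True)
class DrugLikenessScore:
    """Per-molecule scoring result; score = 100 + log p (base-adjusted)."""

    smiles: str
    best_isomer: str
    log_prob: float
    score: float


def _as_smiles(item) -> str:
    if isinstance(item, chem.MoleculeRecord):
        if not item.parse_ok:
            raise chem.SmilesParseError(f"not a valid SMILES: {item.raw_smiles!r}")
        return item.canonical_smiles
    return str(item)


class SmilesLanguageModel(BaseEstimator):
    """GRU character language model over SMILES, scikit-learn style.

    Parameters follow the reference architecture (four GRU layers,
    hidden state 1024, embedding 256) but scale down freely for tests.
    ``canonicalize=True`` trains on canonical SMILES only, and
    ``stereo_sampling=True`` resamples one stereoisomer per molecule
    uniformly at random at each epoch.  ``log_base=None`` means natural
    log in the score; any other base rescales log p accordingly.

    Fitted attributes: ``vocab_`` (Vocabulary), ``params_`` (dict of
    named weight tensors), ``loss_history_`` (mean per-token nats per
    epoch), ``provenance_``.
    """

    def __init__(self, n_gru_layers: int = 4, hidden_dim: int = 1024,
                 embedding_dim: int = 256, learning_rate: float = 1e-3,
                 finetune_learning_rate: float = 1e-4, epochs: int = 30,
                 batch_size: int = 128, seed: int = 0,
                 canonicalize: bool = True, stereo_sampling: bool = True,
                 stereo_cap: int = 32, grad_clip: float = 5.0,
                 log_base: Optional[float] = None):
        self.n_gru_layers = n_gru_layers
        self.hidden_dim = hidden_dim
        self.embedding_dim = embedding_dim
        self.learning_rate = learning_rate
        self.finetune_learning_rate = finetune_learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.seed = seed
        self.canonicalize = canonicalize
        self.stereo_sampling = stereo_sampling
        self.stereo_cap = stereo_cap
        self.grad_clip = grad_clip
        self.log_base = log_base

    # ------------------------------------------------------------ setup
    def _pad_index(self) -> int:
        return self.vocab_.size  # one extra embedding row, never predicted

    def initialize(self, vocab: Vocabulary) -> "SmilesLanguageModel":
        """Allocate parameters for `vocab` without training (uniform-ish
        random weights; used for from-scratch fits and in tests)."""
        if self.n_gru_layers < 1 or self.hidden_dim < 1 or self.embedding_dim < 1:
            raise ValueError("model dimensions must be >= 1")
        rng = np.random.default_rng(self.seed)
        V, E, H = vocab.size, self.embedding_dim, self.hidden_dim
        params: dict[str, Tensor] = {}

        def uniform(shape, k):
            return Tensor(rng.uniform(-k, k, size=shape), requires_grad=True)

        params["emb"] = uniform((V + 1, E), 0.1)
        k = 1.0 / math.sqrt(H)
        for layer in range(self.n_gru_layers):
            in_dim = E if layer == 0 else H
            params[f"W_x{layer}"] = uniform((in_dim, 3 * H), k)
            params[f"W_h{layer}"] = uniform((H, 3 * H), k)
            params[f"b_x{layer}"] = uniform((3 * H,), k)
            params[f"b_h{layer}"] = uniform((3 * H,), k)
        params["W_out"] = uniform((H, V), k)
        params["b_out"] = uniform((V,), k)
        self.vocab_ = vocab
        self.params_ = params
        self.loss_history_ = []
        self.provenance_ = {"pretrained_on": None, "finetuned_on": None,
                            "epochs_run": 0, "seed": self.seed}
        return self

    # --------------------------------------------------- training corpus
    def _corpus_variants(self, X) -> list[list[str]]:
        """Per molecule, the list of strings an epoch may sample from."""
        variants = []
        for item in X:
            s = _as_smiles(item)
            if self.canonicalize:
                if self.stereo_sampling:
                    variants.append(chem.enumerate_stereoisomers(s, self.stereo_cap))
                else:
                    variants.append([chem.canonicalize(s)])
            else:
                variants.append([s])
        return variants

    def fit(self, X: Sequence, y=None) -> "SmilesLanguageModel":
        """Train from scratch on `X` (SMILES strings or MoleculeRecords)."""
        X = list(X)
        if not X:
            raise ValueError("training corpus is empty")
        variants = self._corpus_variants(X)
        vocab = build_vocabulary(s for var in variants for s in var)
        self.initialize(vocab)
        self.provenance_["pretrained_on"] = f"corpus(n={len(X)})"
        self._train(variants, lr=self.learning_rate, epochs=self.epochs)
        return self

    def finetune(self, X: Sequence, epochs: Optional[int] = None
                 ) -> "SmilesLanguageModel":
        """Continue training on a new corpus, reusing the existing
        vocabulary (characters outside it are an error)."""
        self._check_fitted()
        X = list(X)
        if not X:
            raise ValueError("fine-tuning corpus is empty")
        variants = self._corpus_variants(X)
        missing = sorted({ch for var in variants for s in var for ch in s
                          if ch not in self.vocab_.index})
        if missing:
            raise TokenizationError(
                "fine-tuning corpus contains characters outside the "
                f"pretraining vocabulary: {missing}")
        self.provenance_["finetuned_on"] = f"corpus(n={len(X)})"
        self._train(variants, lr=self.finetune_learning_rate,
                    epochs=self.epochs if epochs is None else epochs)
        return self

    def _train(self, variants: list[list[str]], lr: float, epochs: int) -> None:
        rng = np.random.default_rng(np.random.SeedSequence([self.seed, 0x7A17]))
        opt = Adam(self.params_, lr=lr)
        pad = self._pad_index()
        for _ in range(epochs):
            strings = [var[rng.integers(len(var))] if len(var) > 1 else var[0]
                       for var in variants]
            seqs = [encode(s, self.vocab_) for s in strings]
            order = sorted(range(len(seqs)), key=lambda i: len(seqs[i]))
            batches = [order[i:i + self.batch_size]
                       for i in range(0, len(order), self.batch_size)]
            total_ce, total_tok = 0.0, 0
            for b in rng.permutation(len(batches)):
                idx = [seqs[i] for i in batches[b]]
                T = max(len(s) for s in idx)
                mat = np.full((len(idx), T), pad, dtype=np.int64)
                for r, s in enumerate(idx):
                    mat[r, :len(s)] = s
                inputs, targets = mat[:, :-1], mat[:, 1:]
                mask = (targets != pad).astype(np.float64)
                targets = np.where(mask > 0, targets, 0)  # PAD is masked out
                ntok = mask.sum()
                loss = self._batch_loss(inputs, targets, mask)
                opt.zero_grad()
                loss.backward(np.array(1.0 / ntok))
                clip_global_norm(self.params_, self.grad_clip)
                opt.step()
                total_ce += float(loss.data)
                total_tok += int(ntok)
            self.loss_history_.append(total_ce / total_tok)
            self.provenance_["epochs_run"] += 1

    def _batch_loss(self, inputs: np.ndarray, targets: np.ndarray,
                    mask: np.ndarray) -> Tensor:
        p = self.params_
        B, T = inputs.shape
        H = self.hidden_dim
        hidden = [Tensor(np.zeros((B, H))) for _ in range(self.n_gru_layers)]
        loss = None
        for t in range(T):
            x = gather_rows(p["emb"], inputs[:, t])
            for layer in range(self.n_gru_layers):
                h = hidden[layer]
                gx = x @ p[f"W_x{layer}"] + p[f"b_x{layer}"]
                gh = h @ p[f"W_h{layer}"] + p[f"b_h{layer}"]
                r = (gx.slice_cols(0, H) + gh.slice_cols(0, H)).sigmoid()
                z = (gx.slice_cols(H, 2 * H) + gh.slice_cols(H, 2 * H)).sigmoid()
                n = (gx.slice_cols(2 * H, 3 * H)
                     + r * gh.slice_cols(2 * H, 3 * H)).tanh()
                h_new = n + z * (h - n)
                hidden[layer] = h_new
                x = h_new
            logits = x @ p["W_out"] + p["b_out"]
            step = softmax_cross_entropy(logits, targets[:, t], mask[:, t])
            loss = step if loss is None else loss + step
        return loss

    # ---------------------------------------------------------- inference
    def _check_fitted(self) -> None:
        if not hasattr(self, "params_"):
            raise RuntimeError("model is not fitted; call fit() or initialize()")

    def _np_param(self, name: str) -> np.ndarray:
        return self.params_[name].data

    def _all_next_log_distributions(self, indices: Sequence[int]) -> np.ndarray:
        """log p(next | prefix up to t) for every t; shape (len-?, V).

        Row t is the log next-token distribution after consuming
        indices[0..t]; one row per consumed token.
        """
        self._check_fitted()
        H = self.hidden_dim
        hidden = [np.zeros(H) for _ in range(self.n_gru_layers)]
        emb = self._np_param("emb")
        rows = []
        for tok in indices:
            x = emb[tok]
            for layer in range(self.n_gru_layers):
                h = hidden[layer]
                gx = x @ self._np_param(f"W_x{layer}") + self._np_param(f"b_x{layer}")
                gh = h @ self._np_param(f"W_h{layer}") + self._np_param(f"b_h{layer}")
                r = _sigmoid(gx[:H] + gh[:H])
                z = _sigmoid(gx[H:2 * H] + gh[H:2 * H])
                n = np.tanh(gx[2 * H:] + r * gh[2 * H:])
                h_new = n + z * (h - n)
                hidden[layer] = h_new
                x = h_new
            logits = x @ self._np_param("W_out") + self._np_param("b_out")
            rows.append(_log_softmax_vec(logits))
        return np.asarray(rows)

    def next_token_distribution(self, prefix: Sequence[int]) -> np.ndarray:
        """Probability vector over the vocabulary for the token following
        `prefix` (token indices beginning with SOS)."""
        self._check_fitted()
        prefix = list(prefix)
        if not prefix or prefix[0] != self.vocab_.sos:
            raise ValueError("prefix must begin with the SOS index")
        if any(not 0 <= t < self.vocab_.size for t in prefix):
            raise TokenizationError("prefix contains indices outside the vocabulary")
        return np.exp(self._all_next_log_distributions(prefix)[-1])

    # sklearn density-estimator convention
    def score_samples(self, X: Sequence[str]) -> np.ndarray:
        """ln p(S) for each string, scored exactly as given (no stereo
        enumeration, no canonicalization)."""
        return np.array([sequence_log_probability(self, _as_smiles(s)) for s in X])

    def score(self, X: Sequence[str], y=None) -> float:
        """Mean log-probability (sklearn model-selection hook)."""
        return float(np.mean(self.score_samples(X)))

    # -------------------------------------------------------- persistence
    def save(self, path: str | Path) -> None:
        self._check_fitted()
        meta = {
            "config": self.get_params(),
            "vocab": json.loads(self.vocab_.to_json()),
            "provenance": self.provenance_,
            "loss_history": list(self.loss_history_),
        }
        arrays = {k: t.data for k, t in self.params_.items()}
        np.savez(path, __meta__=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "SmilesLanguageModel":
        with np.load(path) as blob:
            meta = json.loads(bytes(blob["__meta__"]).decode())
            model = cls(**meta["config"])
            model.vocab_ = Vocabulary(tokens=tuple(meta["vocab"]["tokens"]))
            model.params_ = {k: Tensor(blob[k], requires_grad=True)
                             for k in blob.files if k != "__meta__"}
        model.provenance_ = meta["provenance"]
        model.loss_history_ = meta["loss_history"]
        return model


class DeterministicSequenceModel:
    """A degenerate model that assigns probability 1 to each successive
    token of one fixed target string (uniform off-path).

    It realizes the p(S)=1 limit of the score formula: scoring its own
    target yields exactly 100.
    """

    def __init__(self, target_smiles: str, vocab: Optional[Vocabulary] = None):
        self.target_smiles = target_smiles
        self.vocab_ = vocab if vocab is not None else build_vocabulary([target_smiles])
        self._target = encode(target_smiles, self.vocab_)

    def next_token_distribution(self, prefix: Sequence[int]) -> np.ndarray:
        prefix = list(prefix)
        if not prefix or prefix[0] != self.vocab_.sos:
            raise ValueError("prefix must begin with the SOS index")
        V = self.vocab_.size
        if (len(prefix) < len(self._target)
                and prefix == self._target[:len(prefix)]):
            out = np.zeros(V)
            out[self._target[len(prefix)]] = 1.0
            return out
        return np.full(V, 1.0 / V)

    def _all_next_log_distributions(self, indices: Sequence[int]) -> np.ndarray:
        rows = []
        with np.errstate(divide="ignore"):
            for t in range(len(indices)):
                rows.append(np.log(self.next_token_distribution(indices[:t + 1])))
        return np.asarray(rows)


# ----------------------------------------------------------- scoring ops

def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


def _log_softmax_vec(x: np.ndarray) -> np.ndarray:
    z = x - x.max()
    return z - np.log(np.exp(z).sum())


def next_token_distribution(model, prefix: Sequence[int]) -> np.ndarray:
    return model.next_token_distribution(prefix)


def stepwise_log_probabilities(model, smiles: str) -> np.ndarray:
    """The log factors of the Bayes factorization of p(S).

    Element 0 is ln p(s_0): every sequence starts with SOS, so p(s_0)=1
    and the element is computed as ln 1 = 0.  Elements 1..N+1 are
    ln p(s_{t+1} | s_0..s_t) up to and including the EOS step.
    """
    seq = encode(smiles, model.vocab_)
    log_rows = model._all_next_log_distributions(seq[:-1])
    p_s0 = 1.0  # the sequence starts with SOS with certainty
    terms = [math.log(p_s0)]
    for t in range(len(seq) - 1):
        terms.append(float(log_rows[t][seq[t + 1]]))
    return np.asarray(terms)


def sequence_log_probability(model, smiles: str) -> float:
    """ln p(S), accumulated in log space over the factorization."""
    return float(stepwise_log_probabilities(model, smiles).sum())


def _to_score(log_prob: float, log_base: Optional[float]) -> float:
    if log_base is None:
        return 100.0 + log_prob
    return 100.0 + log_prob / math.log(log_base)


def drug_likeness_score(model, smiles: str) -> DrugLikenessScore:
    """score = 100 + log p(S) for the string exactly as given."""
    lp = sequence_log_probability(model, smiles)
    base = getattr(model, "log_base", None)
    return DrugLikenessScore(smiles=smiles, best_isomer=smiles,
                             log_prob=lp, score=_to_score(lp, base))


def score_molecule(model, smiles: str, cap: Optional[int] = None
                   ) -> DrugLikenessScore:
    """Stereoisomer-max drug-likeness score.

    Enumerates the distinct stereoisomers of `smiles` (canonical isomeric
    forms), scores each, and returns the best; ties break toward the
    first isomer in the deterministic enumeration order.
    """
    if cap is None:
        cap = getattr(model, "stereo_cap", 32)
    isomers = chem.enumerate_stereoisomers(smiles, cap=cap)
    best: Optional[DrugLikenessScore] = None
    failures: list[str] = []
    for iso in isomers:
        try:
            cand = drug_likeness_score(model, iso)
        except TokenizationError as exc:
            failures.append(f"{iso}: {exc}")
            continue
        if best is None or cand.score > best.score:
            best = DrugLikenessScore(smiles=smiles, best_isomer=iso,
                                     log_prob=cand.log_prob, score=cand.score)
    if best is None:
        raise TokenizationError(
            "no stereoisomer of the query is encodable under the model "
            "vocabulary: " + "; ".join(failures))
    return best


def score_dataset(model, smiles_list: Sequence[str], cap: Optional[int] = None):
    """Score many molecules; returns a pandas DataFrame with columns
    smiles, best_isomer, log_prob, score."""
    import pandas as pd

    rows = [score_molecule(model, s, cap=cap) for s in smiles_list]
    return pd.DataFrame({
        "smiles": [r.smiles for r in rows],
        "best_isomer": [r.best_isomer for r in rows],
        "log_prob": [r.log_prob for r in rows],
        "score": [r.score for r in rows],
    })


def train(model: SmilesLanguageModel, corpus: Sequence, mode: str = "pretrain"
          ) -> SmilesLanguageModel:
    """Functional wrapper: mode 'pretrain' fits from scratch, 'finetune'
    continues from the current parameters with the fine-tuning rate."""
    if mode == "pretrain":
        return model.fit(corpus)
    if mode == "finetune":
        return model.finetune(corpus)
    raise ValueError(f"unknown training mode: {mode!r}")
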