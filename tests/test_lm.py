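"""Language-model behavior: distribution normalization, the factorized
sequence probability, the 100 + log p score with stereoisomer-max, the
training loop, and recovery of a known source distribution."""

import math

import numpy as np
import pytest
from scipy.stats import spearmanr

from druglikeness.lm import (
    DeterministicSequenceModel,
    SmilesLanguageModel,
    drug_likeness_score,
    next_token_distribution,
    score_molecule,
    sequence_log_probability,
    stepwise_log_probabilities,
    train,
)
from druglikeness.tokenizer import TokenizationError, build_vocabulary


def _random_model(corpus, seed=0, **kw):
    kw.setdefault("n_gru_layers", 1)
    kw.setdefault("hidden_dim", 16)
    kw.setdefault("embedding_dim", 8)
    model = SmilesLanguageModel(seed=seed, canonicalize=False,
                                stereo_sampling=False, **kw)
    return model.initialize(build_vocabulary(corpus))


# ------------------------------------------------------- distributions


def test_next_token_distribution_normalized():
    m = _random_model(["CCO", "c1ccccc1"])
    prefix = [m.vocab_.sos, m.vocab_.index["C"]]
    dist = next_token_distribution(m, prefix)
    assert dist.shape == (m.vocab_.size,)
    assert np.all(dist >= 0)
    assert abs(dist.sum() - 1.0) < 1e-6


def test_zeroed_output_layer_gives_uniform():
    m = _random_model(["CCO"])
    m.params_["W_out"].data[:] = 0.0
    m.params_["b_out"].data[:] = 0.0
    dist = m.next_token_distribution([m.vocab_.sos])
    assert np.allclose(dist, 1.0 / m.vocab_.size)


def test_prefix_must_start_with_sos():
    m = _random_model(["CCO"])
    with pytest.raises(ValueError):
        m.next_token_distribution([m.vocab_.index["C"]])


def test_overfit_single_string_concentrates_mass(tiny_overfit_lm):
    m = tiny_overfit_lm
    dist = m.next_token_distribution([m.vocab_.sos])
    assert dist[m.vocab_.index["C"]] > 0.99
    # mean per-token cross-entropy driven below 0.05 nats
    assert m.loss_history_[-1] < 0.05


# -------------------------------------------------- sequence probability


def test_sos_factor_contributes_zero():
    m = _random_model(["CCO"])
    terms = stepwise_log_probabilities(m, "CCO")
    assert terms[0] == 0.0
    assert len(terms) == len("CCO") + 2  # s0 factor + per-char + EOS step


def test_sequence_log_probability_matches_stepwise_oracle():
    m = _random_model(["CcNO1=()"], seed=1)
    rng = np.random.default_rng(5)
    chars = [t for t in m.vocab_.tokens[:-2]]
    for _ in range(50):
        s = "".join(rng.choice(chars, size=rng.integers(1, 25)))
        # oracle: query each step's distribution independently
        seq = [m.vocab_.sos] + [m.vocab_.index[c] for c in s] + [m.vocab_.eos]
        oracle = 0.0
        for t in range(len(seq) - 1):
            dist = next_token_distribution(m, seq[:t + 1])
            oracle += math.log(dist[seq[t + 1]])
        assert sequence_log_probability(m, s) == pytest.approx(oracle, abs=1e-5)


def test_uniform_model_forced_log_probability():
    # vocabulary {C, O, SOS, EOS} -> 4 effective choices per step
    m = _random_model(["CC", "CO"])
    m.params_["W_out"].data[:] = 0.0
    m.params_["b_out"].data[:] = 0.0
    assert m.vocab_.size == 4
    # "COCO" needs 5 prediction steps (4 characters + EOS)
    lp = sequence_log_probability(m, "COCO")
    assert lp == pytest.approx(5 * math.log(1 / 4))
    score = drug_likeness_score(m, "COCO").score
    assert score == pytest.approx(100 + 5 * math.log(1 / 4))


def test_uniform_model_score_strictly_decreases_with_length():
    m = _random_model(["CO"])
    m.params_["W_out"].data[:] = 0.0
    m.params_["b_out"].data[:] = 0.0
    scores = [drug_likeness_score(m, "C" * n).score for n in range(1, 6)]
    assert all(a > b for a, b in zip(scores, scores[1:]))


def test_score_bounded_by_100_for_arbitrary_models():
    rng = np.random.default_rng(8)
    for seed in range(3):
        m = _random_model(["CcNO1()=S"], seed=seed)
        chars = list(m.vocab_.tokens[:-2])
        for _ in range(10):
            s = "".join(rng.choice(chars, size=rng.integers(1, 30)))
            assert drug_likeness_score(m, s).score <= 100.0


def test_deterministic_sequence_model_attains_ceiling():
    m = DeterministicSequenceModel("c1ccccc1")
    assert drug_likeness_score(m, "c1ccccc1").score == 100.0
    assert sequence_log_probability(m, "c1ccccc1") == 0.0


def test_oov_scoring_raises():
    m = _random_model(["CC"])
    with pytest.raises(TokenizationError):
        sequence_log_probability(m, "CN")


# ------------------------------------------------------ stereoisomer max


def test_achiral_molecule_score_equals_plain_score():
    m = _random_model(["CCO"])
    assert score_molecule(m, "OCC").score == pytest.approx(
        drug_likeness_score(m, "CCO").score)
    assert score_molecule(m, "OCC").best_isomer == "CCO"


def test_stereo_max_equals_bruteforce_over_isomers():
    from druglikeness.chem import enumerate_stereoisomers

    m = _random_model(["CC(N)C(=O)O[C@@H]1"], seed=2)
    result = score_molecule(m, "CC(N)C(=O)O")
    isomers = enumerate_stereoisomers("CC(N)C(=O)O", 32)
    assert len(isomers) == 2
    best = max(isomers, key=lambda i: drug_likeness_score(m, i).score)
    assert result.best_isomer == best
    assert result.score == pytest.approx(drug_likeness_score(m, best).score)
    assert result.score >= max(
        drug_likeness_score(m, i).score for i in isomers) - 1e-12


# --------------------------------------------------------------- training


def test_training_loss_decreases_on_small_corpus(markov_recovery):
    corpus = markov_recovery.source.sample_corpus(100, seed=21)
    m = SmilesLanguageModel(n_gru_layers=1, hidden_dim=32, embedding_dim=16,
                            epochs=15, batch_size=32, seed=0,
                            canonicalize=False, stereo_sampling=False)
    m.fit(corpus)
    smoothed_end = float(np.mean(m.loss_history_[-5:]))
    assert smoothed_end <= m.loss_history_[0]


def test_empty_corpus_rejected():
    with pytest.raises(ValueError):
        SmilesLanguageModel().fit([])


def test_finetune_requires_pretraining_vocabulary():
    m = SmilesLanguageModel(n_gru_layers=1, hidden_dim=16, embedding_dim=8,
                            epochs=2, seed=0, canonicalize=False,
                            stereo_sampling=False)
    m.fit(["CCO", "CCC"])
    with pytest.raises(TokenizationError, match="N"):
        m.finetune(["CCN"])  # N never seen in pretraining
    before = m.provenance_["epochs_run"]
    train(m, ["CCO", "OCC"], mode="finetune")
    assert m.provenance_["epochs_run"] > before
    assert m.provenance_["finetuned_on"] is not None


def test_training_is_seed_deterministic():
    corpus = ["CCO", "CCN", "c1ccccc1", "CC(C)O", "CCCC"]
    runs = []
    for _ in range(2):
        m = SmilesLanguageModel(n_gru_layers=1, hidden_dim=24,
                                embedding_dim=12, epochs=5, seed=7)
        m.fit(corpus)
        runs.append(m.score_samples(["CCO", "c1ccccc1"]))
    assert np.array_equal(runs[0], runs[1])


def test_save_load_round_trip(tmp_path):
    m = SmilesLanguageModel(n_gru_layers=1, hidden_dim=16, embedding_dim=8,
                            epochs=3, seed=0)
    m.fit(["CCO", "CCN", "CCC"])
    path = tmp_path / "model.npz"
    m.save(path)
    loaded = SmilesLanguageModel.load(path)
    assert loaded.vocab_.tokens == m.vocab_.tokens
    probe = ["CCO", "CCN"]
    assert np.array_equal(loaded.score_samples(probe), m.score_samples(probe))


# ------------------------------------------------------- source recovery


def test_markov_source_recovery(markov_recovery):
    err = np.abs(markov_recovery.lp_model - markov_recovery.lp_true)
    assert float(err.mean()) < 1.0
    rho = spearmanr(markov_recovery.lp_model, markov_recovery.lp_true).statistic
    assert rho > 0.9
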