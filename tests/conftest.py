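"""Shared fixtures.

The two expensive fixtures (Markov source recovery, toy-family
experiment) are session-scoped: several tests assert different
properties of the same trained models, so each model is trained once.
"""

from pathlib import Path
from types import SimpleNamespace

import numpy as np
import pytest

from druglikeness.gcn import GraphConvClassifier
from druglikeness.lm import SmilesLanguageModel, score_molecule
from druglikeness.synthetic import ToyFamilySpec, example_markov_source, make_toy_families

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def filter_fixture_path() -> Path:
    return DATA_DIR / "filter_fixture.smi"


@pytest.fixture(scope="session")
def markov_recovery():
    """GRU trained on 5,000 strings from the known 5-symbol Markov chain,
    with exact log-probabilities for 200 held-out strings."""
    src = example_markov_source()
    train = src.sample_corpus(5000, seed=11)
    held = src.sample_corpus(200, seed=99)
    model = SmilesLanguageModel(
        n_gru_layers=2, hidden_dim=128, embedding_dim=32, epochs=20,
        batch_size=128, seed=0, canonicalize=False, stereo_sampling=False)
    model.fit(train)
    lp_model = model.score_samples(held)
    lp_true = np.array([src.log_probability(s) for s in held])
    return SimpleNamespace(source=src, model=model, held=held,
                           lp_model=lp_model, lp_true=lp_true)


@pytest.fixture(scope="session")
def toy_families():
    return make_toy_families(ToyFamilySpec(
        n_drug_like=380, n_zinc_like=380, n_nondrug_like=200, seed=0))


@pytest.fixture(scope="session")
def toy_experiment(toy_families):
    """The data-dependency experiment: a two-class GCN trained on
    drug-like vs. screening-library toys, and a language model trained
    on the drug-like toys alone, both applied to held-out data and to
    the out-of-distribution hydrocarbon family."""
    fam = toy_families
    drug_train, drug_test = fam.drug_like[:300], fam.drug_like[300:]
    zinc_train, zinc_test = fam.zinc_like[:300], fam.zinc_like[300:]
    hydrocarbons = fam.nondrug_like

    tcc = GraphConvClassifier(node_dim=32, epochs=40, n_folds=5, seed=0,
                              batch_size=64)
    tcc.fit(list(drug_train) + list(zinc_train), [1] * 300 + [0] * 300)
    tcc_pos = tcc.decision_scores(drug_test)
    tcc_neg = tcc.decision_scores(zinc_test)
    tcc_ood = tcc.decision_scores(hydrocarbons)

    lm = SmilesLanguageModel(n_gru_layers=2, hidden_dim=96, embedding_dim=32,
                             epochs=40, batch_size=64, seed=0)
    lm.fit(drug_train)
    lm_drug = np.array([score_molecule(lm, s).score for s in drug_test])
    lm_zinc = np.array([score_molecule(lm, s).score for s in zinc_test])
    lm_ood = np.array([score_molecule(lm, s).score for s in hydrocarbons])

    return SimpleNamespace(
        families=fam, tcc=tcc, lm=lm,
        drug_test=drug_test, zinc_test=zinc_test, hydrocarbons=hydrocarbons,
        tcc_pos=tcc_pos, tcc_neg=tcc_neg, tcc_ood=tcc_ood,
        lm_drug=lm_drug, lm_zinc=lm_zinc, lm_ood=lm_ood)


@pytest.fixture(scope="session")
def tiny_overfit_lm():
    """A small GRU driven to convergence on the single string "CC"."""
    model = SmilesLanguageModel(
        n_gru_layers=1, hidden_dim=32, embedding_dim=16, epochs=400,
        batch_size=4, seed=0, learning_rate=3e-3, canonicalize=False,
        stereo_sampling=False)
    return model.fit(["CC"])
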