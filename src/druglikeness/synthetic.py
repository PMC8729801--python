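"""Synthetic corpora with known statistical structure.

Two generators support end-to-end testing without any external dataset:

* :class:`MarkovSource` — a first-order Markov chain over a small set of
  genuine SMILES characters with an absorbing end-of-string state, so
  every sampled string has an analytically known probability.  A
  character language model trained on such a corpus should recover those
  probabilities, which makes the chain an exact oracle for likelihood
  scoring.
* :func:`make_toy_families` — three disjoint, template-enumerated SMILES
  families emulating the positive/negative/out-of-distribution structure
  of a drug-likeness study: nitrogen-decorated small rings (drug-like
  toys), acyclic oxygen-rich ethers and esters (screening-library toys),
  and pure hydrocarbons (the out-of-distribution family; many of them
  rings, which share scaffold features with the drug-like toys).
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .chem import FilterPolicy, canonicalize, make_record, passes_structural_filters

EOS_STATE = -1  # column index convention: last transition column is EOS


class CorpusError(ValueError):
    pass


@dataclass(frozen=True)
class MarkovSource:
    """First-order Markov string source with an absorbing EOS.

    transition_matrix has shape (k, k+1): row i gives the probability of
    moving from symbol i to each symbol (first k columns) or terminating
    (last column).  initial_probs (length k) starts the chain; empty
    strings are not produced.
    """

    alphabet: tuple[str, ...]
    initial_probs: tuple[float, ...]
    transition_matrix: tuple[tuple[float, ...], ...]
    seed: int = 0

    def __post_init__(self):
        k = len(self.alphabet)
        init = np.asarray(self.initial_probs, dtype=float)
        trans = np.asarray(self.transition_matrix, dtype=float)
        if init.shape != (k,) or trans.shape != (k, k + 1):
            raise CorpusError("initial/transition shapes do not match alphabet")
        if np.any(init < 0) or np.any(trans < 0):
            raise CorpusError("probabilities must be non-negative")
        if abs(init.sum() - 1.0) > 1e-9 or np.any(np.abs(trans.sum(axis=1) - 1.0) > 1e-9):
            raise CorpusError("probability rows must sum to 1")
        # EOS must be reachable from every state for finite expected length:
        # with strictly positive EOS hazards this is immediate; otherwise
        # check reachability through the transition graph.
        reach = trans[:, -1] > 0
        for _ in range(k):
            reach = reach | (trans[:, :-1] @ reach > 0)
        if not reach.all():
            raise CorpusError("EOS is unreachable from some state")

    @property
    def index(self) -> dict[str, int]:
        return {c: i for i, c in enumerate(self.alphabet)}

    # ---------------------------------------------------------- sampling
    def sample_corpus(self, n: int, seed: int | None = None,
                      max_len: int = 1000) -> list[str]:
        """Draw n strings; fully determined by the seed."""
        if n < 1:
            raise CorpusError("n must be >= 1")
        rng = np.random.default_rng(self.seed if seed is None else seed)
        init = np.asarray(self.initial_probs)
        trans = np.asarray(self.transition_matrix)
        k = len(self.alphabet)
        out = []
        for _ in range(n):
            chars = [int(rng.choice(k, p=init))]
            while True:
                nxt = int(rng.choice(k + 1, p=trans[chars[-1]]))
                if nxt == k:
                    break
                chars.append(nxt)
                if len(chars) > max_len:
                    raise CorpusError("chain exceeded max_len; EOS hazard too small")
            out.append("".join(self.alphabet[i] for i in chars))
        return out

    # ------------------------------------------------------------ oracle
    def log_probability(self, s: str) -> float:
        """Exact ln P(string) under the chain; -inf only for zero-probability
        transitions, an error for out-of-alphabet characters."""
        if not s:
            raise CorpusError("the chain does not emit empty strings")
        idx = self.index
        try:
            states = [idx[c] for c in s]
        except KeyError as exc:
            raise CorpusError(f"character {exc.args[0]!r} not in alphabet") from None
        trans = np.asarray(self.transition_matrix)
        with np.errstate(divide="ignore"):
            lp = math.log(self.initial_probs[states[0]]) if self.initial_probs[states[0]] > 0 else -math.inf
            for a, b in itertools.pairwise(states):
                p = trans[a, b]
                lp += math.log(p) if p > 0 else -math.inf
            p_end = trans[states[-1], -1]
            lp += math.log(p_end) if p_end > 0 else -math.inf
        return lp


def true_sequence_log_probability(source: MarkovSource, s: str) -> float:
    return source.log_probability(s)


def sample_corpus(source: MarkovSource, n: int, seed: int | None = None) -> list[str]:
    return source.sample_corpus(n, seed=seed)


def example_markov_source(seed: int = 0) -> MarkovSource:
    """The 5-symbol chain used throughout the tests.

    Alphabet {C, c, 1, O, N}; per-row EOS hazard around 0.12, so the mean
    string length is roughly 8 characters — long enough that sequence
    log-probabilities spread over several nats, short enough to train in
    seconds.  The rows are deliberately non-uniform so that a model must
    learn genuine conditional structure, not just symbol frequencies.
    """
    alphabet = ("C", "c", "1", "O", "N")
    initial = (0.45, 0.25, 0.05, 0.15, 0.10)
    #              C     c     1     O     N    EOS
    transition = (
        (0.40, 0.10, 0.05, 0.20, 0.13, 0.12),  # from C
        (0.10, 0.50, 0.20, 0.05, 0.05, 0.10),  # from c
        (0.30, 0.40, 0.02, 0.08, 0.08, 0.12),  # from 1
        (0.50, 0.10, 0.05, 0.05, 0.15, 0.15),  # from O
        (0.45, 0.10, 0.05, 0.15, 0.05, 0.20),  # from N
    )
    return MarkovSource(alphabet, initial, transition, seed=seed)


# ------------------------------------------------------------ toy families

# two-site ring templates: {a} is the principal substituent, {b} a second one
_DRUG_TEMPLATES = ["c1ccc({a})cc1{b}", "C1CCC({a})CC1{b}", "C1CC({a})CC1{b}",
                   "C1CCCC({a})CC1{b}"]
_DRUG_SUBS = [
    "N", "NC", "N(C)C", "CN", "CCN", "C(N)=O", "NC(C)=O", "CNC",
    "NCC", "NCO", "C(=O)N", "CC(N)=O", "NCCO", "N(C)CC", "CNCC",
    "NC(=O)C", "CCNC", "NCCN", "C(N)CO", "NC(C)C",
]
_DRUG_EXTRA = ["", "C", "CC", "O", "OC", "N", "CO"]

_ZINC_LEFT = ["C", "CC", "CCC", "CC(C)", "CCCC", "CC(C)C", "CCCCC", "CCC(C)"]
_ZINC_LINK = ["O", "C(=O)O", "OC(=O)", "COC", "OCC(=O)O", "C(=O)OC", "OCO"]
_ZINC_RIGHT = ["C", "CC", "CCC", "C(C)C", "CCCC", "CC(C)C", "CCO", "CCOC",
               "CC(C)O", "CCCO", "CCCC(C)C", "CC(C)CC"]

_HC_TEMPLATES = ["c1ccc({a})cc1{b}", "C1CCC({a})CC1{b}", "C1CC({a})CC1{b}",
                 "C1=CCC({a})CC1{b}", "C1CCCC({a})CC1{b}"]
# acyclic alkenes are terminal only (=CH2), so no E/Z geometry arises and
# every stereoisomer stays encodable under a ring-trained vocabulary
_HC_DECOR = ["", "C", "CC", "CCC", "C(C)C", "C=C", "CCCC", "C(C)(C)C",
             "CC(C)C", "CC=C"]
_HC_DECOR2 = ["", "C", "CC", "CCC", "C(C)C"]
_HC_CHAINS = ["CCCC", "CCCCC", "CCCCCC", "CC(C)CC", "C=CCC", "C=CCC(C)C",
              "CCC(C)C", "C=CCCC", "CCCCCCC", "CC(C)(C)C", "CC(C)CCC",
              "C=CCC=C", "CCCC(C)C", "CCCCCCCC", "CC(CC)CC", "C=CCCCC",
              "C=C(C)CCC", "CC(C)C(C)C", "CCCCC(C)C", "C=C(C)CC"]


def _has_atom(smiles: str, symbol: str) -> bool:
    from rdkit import Chem
    mol = Chem.MolFromSmiles(smiles)
    return any(a.GetSymbol() == symbol for a in mol.GetAtoms())


def _enumerate_family(parts, validator) -> list[str]:
    """Canonicalize template combinations, keep valid unique ones."""
    seen: dict[str, None] = {}
    for smiles in parts:
        rec = make_record(smiles)
        if not rec.parse_ok or not passes_structural_filters(rec, FilterPolicy()):
            continue
        can = rec.canonical_smiles
        if can not in seen and validator(can):
            seen[can] = None
    return list(seen)


@dataclass(frozen=True)
class ToyFamilySpec:
    """Counts and seed for the three toy SMILES families."""

    n_drug_like: int = 300
    n_zinc_like: int = 300
    n_nondrug_like: int = 200
    seed: int = 0

    def __post_init__(self):
        if min(self.n_drug_like, self.n_zinc_like, self.n_nondrug_like) < 1:
            raise ValueError("family counts must be >= 1")


@dataclass(frozen=True)
class ToyFamilies:
    drug_like: tuple[str, ...]
    zinc_like: tuple[str, ...]
    nondrug_like: tuple[str, ...]
    spec: ToyFamilySpec = field(default=ToyFamilySpec())

    def as_dict(self) -> dict[str, list[str]]:
        return {"drug_like": list(self.drug_like),
                "zinc_like": list(self.zinc_like),
                "nondrug_like": list(self.nondrug_like)}


def make_toy_families(spec: ToyFamilySpec = ToyFamilySpec()) -> ToyFamilies:
    """Enumerate the three disjoint families and subsample to the requested
    counts (seeded shuffle, deterministic).

    Disjointness is structural: drug-like toys contain nitrogen and a
    ring, screening-library toys contain oxygen but no nitrogen and no
    ring, hydrocarbons contain neither heteroatom.
    """
    drug_pool = _enumerate_family(
        (t.format(a=a, b=b) for t in _DRUG_TEMPLATES for a in _DRUG_SUBS
         for b in _DRUG_EXTRA),
        lambda can: _has_atom(can, "N"))
    zinc_pool = _enumerate_family(
        (l + k + r for l in _ZINC_LEFT for k in _ZINC_LINK for r in _ZINC_RIGHT),
        lambda can: _has_atom(can, "O") and not _has_atom(can, "N")
        and "1" not in can)
    hc_pool = _enumerate_family(
        itertools.chain((t.format(a=a, b=b) for t in _HC_TEMPLATES
                         for a in _HC_DECOR for b in _HC_DECOR2), _HC_CHAINS),
        lambda can: not _has_atom(can, "N") and not _has_atom(can, "O"))

    rng = np.random.default_rng(spec.seed)
    families = []
    for pool, n, name in [(drug_pool, spec.n_drug_like, "drug_like"),
                          (zinc_pool, spec.n_zinc_like, "zinc_like"),
                          (hc_pool, spec.n_nondrug_like, "nondrug_like")]:
        if len(pool) < n:
            raise ValueError(
                f"family {name} has only {len(pool)} distinct members; "
                f"{n} requested")
        pick = rng.permutation(len(pool))[:n]
        families.append(tuple(pool[i] for i in pick))
    return ToyFamilies(*families, spec=spec)


def write_family_files(families: ToyFamilies, out_dir: str | Path) -> dict[str, Path]:
    """Write one .smi per family plus a provenance JSON; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, smiles in families.as_dict().items():
        p = out_dir / f"{name}.smi"
        p.write_text("\n".join(smiles) + "\n")
        paths[name] = p
    prov = out_dir / "provenance.json"
    prov.write_text(json.dumps({
        "generator": "druglikeness.synthetic.make_toy_families",
        "seed": families.spec.seed,
        "counts": {k: len(v) for k, v in families.as_dict().items()},
    }, indent=2))
    paths["provenance"] = prov
    return paths
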