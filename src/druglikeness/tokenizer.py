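"""Character-level SMILES tokenization.

Every SMILES character is its own token (two-letter element symbols such
as Cl and Br therefore contribute two tokens each), and every encoded
sequence is wrapped in start-of-sequence (SOS) and end-of-sequence (EOS)
sentinels, so the autoregressive factorization of a string of N
characters has N+1 prediction steps (the last one predicting EOS).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

SOS = "<SOS>"
EOS = "<EOS>"

VOCAB_FORMAT_VERSION = 1


class TokenizationError(ValueError):
    """A string contains a character outside the vocabulary, or a token
    sequence violates the SOS/EOS framing."""


@dataclass(frozen=True)
class Vocabulary:
    """Bijection between tokens (single characters plus SOS/EOS) and indices.

    Ordering is deterministic: the distinct corpus characters sorted by
    code point, followed by SOS then EOS.  ``size`` counts all tokens
    including the sentinels.
    """

    tokens: tuple[str, ...]
    index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self):
        object.__setattr__(self, "index", {t: i for i, t in enumerate(self.tokens)})
        if len(self.index) != len(self.tokens):
            raise ValueError("vocabulary tokens must be distinct")
        if SOS not in self.index or EOS not in self.index:
            raise ValueError("vocabulary must contain SOS and EOS")

    @property
    def size(self) -> int:
        return len(self.tokens)

    @property
    def sos(self) -> int:
        return self.index[SOS]

    @property
    def eos(self) -> int:
        return self.index[EOS]

    def covers(self, text: str) -> bool:
        return all(ch in self.index for ch in text)

    # ------------------------------------------------------------- I/O
    def to_json(self) -> str:
        return json.dumps({"tokens": list(self.tokens), "sos": self.sos,
                           "eos": self.eos, "version": VOCAB_FORMAT_VERSION})

    @classmethod
    def from_json(cls, text: str) -> "Vocabulary":
        obj = json.loads(text)
        vocab = cls(tokens=tuple(obj["tokens"]))
        if vocab.sos != obj["sos"] or vocab.eos != obj["eos"]:
            raise ValueError("vocab.json sentinel indices are inconsistent")
        return vocab

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "Vocabulary":
        return cls.from_json(Path(path).read_text())


def build_vocabulary(corpus: Iterable[str]) -> Vocabulary:
    """Collect the distinct characters of `corpus` plus SOS/EOS.

    Raises ValueError on an empty corpus: a vocabulary without observed
    characters cannot support training or scoring.
    """
    chars: set[str] = set()
    n = 0
    for s in corpus:
        n += 1
        chars.update(s)
    if n == 0:
        raise ValueError("cannot build a vocabulary from an empty corpus")
    return Vocabulary(tokens=tuple(sorted(chars)) + (SOS, EOS))


def encode(smiles: str, vocab: Vocabulary) -> list[int]:
    """Token indices ``[SOS] + characters + [EOS]`` (length len(smiles)+2)."""
    out = [vocab.sos]
    for pos, ch in enumerate(smiles):
        try:
            out.append(vocab.index[ch])
        except KeyError:
            raise TokenizationError(
                f"character {ch!r} at position {pos} is not in the vocabulary"
            ) from None
    out.append(vocab.eos)
    return out


def decode(seq: Sequence[int], vocab: Vocabulary) -> str:
    """Inverse of :func:`encode`; validates the SOS/EOS framing."""
    if len(seq) < 2 or seq[0] != vocab.sos or seq[-1] != vocab.eos:
        raise TokenizationError("token sequence must start with SOS and end with EOS")
    body = seq[1:-1]
    if vocab.sos in body or vocab.eos in body:
        raise TokenizationError("interior SOS/EOS in token sequence")
    return "".join(vocab.tokens[i] for i in body)
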