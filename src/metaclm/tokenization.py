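"""Tokenisation of SMILES strings and potency differences.

Compounds are tokenised losslessly into three token classes: bracketed
atoms (``[nH]``, ``[O-]``), the two-character halogens ``Cl``/``Br``, and
all remaining single characters. Potency differences (pKi units) are
discretised into fixed-width bins, one token per bin; the default bin
vocabulary covers the global range -6.62 to 6.52 pKi units at width 0.01,
which yields exactly 1314 bins.

Sequence encoding for the conditional translation (SC, dPot) -> TC places
the potency-difference token after the source-compound tokens on the
encoder side, framed by START/END specials.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field

import numpy as np

START = "^"
END = "$"
PAD = "<pad>"

_TOKEN_RE = re.compile(r"\[[^\[\]]*\]|Cl|Br|.")


class TokenizationError(ValueError):
    pass


class VocabularyError(KeyError):
    pass


def tokenize_smiles(s: str) -> list[str]:
    """Split a SMILES string into atom/bond/branch tokens, losslessly.

    Bracket atoms and two-character halogens stay whole; everything else
    is a single character. ``"".join(tokens) == s`` always holds.
    """
    if not s:
        raise TokenizationError("empty SMILES string")
    tokens = _TOKEN_RE.findall(s)
    if "".join(tokens) != s or any(t in ("[", "]") for t in tokens):
        raise TokenizationError(f"unbalanced bracket in SMILES: {s!r}")
    return tokens


@dataclass(frozen=True)
class PotencyBinVocabulary:
    """Fixed-width binning of potency differences into condition tokens.

    Bins are half-open ``[lo + i*w, lo + (i+1)*w)``; the top edge ``hi``
    closes the last bin so the bin count is exactly
    ``round((hi - lo)/width)``.
    """

    lo: float = -6.62
    hi: float = 6.52
    width: float = 0.01
    clamp: bool = False

    @property
    def n_bins(self) -> int:
        return int(round((self.hi - self.lo) / self.width))

    @property
    def tokens(self) -> list[str]:
        return [self._token(i) for i in range(self.n_bins)]

    def _token(self, i: int) -> str:
        return f"<dP{i:04d}>"

    def delta_to_bin(self, delta: float) -> int:
        """Bin index of a potency difference, clamped to the last bin at hi."""
        if not math.isfinite(delta):
            raise ValueError(f"non-finite potency difference: {delta!r}")
        if not self.lo <= delta <= self.hi:
            if self.clamp:
                delta = min(max(delta, self.lo), self.hi)
            else:
                raise ValueError(
                    f"potency difference {delta} outside the bin range "
                    f"[{self.lo}, {self.hi}]; enable clamping to truncate")
        # tiny epsilon absorbs float representation error of 0.01-quantised
        # pKi values so lower bin edges land in their own bin
        idx = int(math.floor((delta - self.lo) / self.width + 1e-9))
        return min(max(idx, 0), self.n_bins - 1)

    def token_for(self, delta: float) -> str:
        return self._token(self.delta_to_bin(delta))


@dataclass
class SequenceVocabulary:
    """Symbol/index maps over chemistry tokens, bin tokens and specials."""

    symbols: list[str]
    bins: PotencyBinVocabulary = field(default_factory=PotencyBinVocabulary)

    def __post_init__(self) -> None:
        self.index = {s: i for i, s in enumerate(self.symbols)}
        if len(self.index) != len(self.symbols):
            raise ValueError("duplicate symbols in vocabulary")

    # -- construction ---------------------------------------------------
    @classmethod
    def build(cls, smiles_tokens: set[str],
              bins: PotencyBinVocabulary | None = None) -> "SequenceVocabulary":
        bins = bins or PotencyBinVocabulary()
        chem = sorted(smiles_tokens)
        symbols = [PAD, START, END] + chem + bins.tokens
        return cls(symbols, bins)

    @classmethod
    def from_pairs(cls, pairs, bins: PotencyBinVocabulary | None = None
                   ) -> "SequenceVocabulary":
        """Collect chemistry tokens from (source, target) SMILES pairs."""
        toks: set[str] = set()
        for sc, tc in pairs:
            toks.update(tokenize_smiles(sc))
            toks.update(tokenize_smiles(tc))
        return cls.build(toks, bins)

    # -- core maps ------------------------------------------------------
    def __len__(self) -> int:
        return len(self.symbols)

    @property
    def pad_id(self) -> int:
        return self.index[PAD]

    @property
    def start_id(self) -> int:
        return self.index[START]

    @property
    def end_id(self) -> int:
        return self.index[END]

    def ids(self, tokens: list[str]) -> list[int]:
        try:
            return [self.index[t] for t in tokens]
        except KeyError as exc:
            raise VocabularyError(f"symbol not in vocabulary: {exc.args[0]!r}") from None

    # -- sequence encoding ---------------------------------------------
    def encode_source(self, sc_smiles: str, delta: float) -> list[int]:
        toks = [START] + tokenize_smiles(sc_smiles) + [self.bins.token_for(delta)] + [END]
        return self.ids(toks)

    def encode_target(self, tc_smiles: str) -> list[int]:
        return self.ids([START] + tokenize_smiles(tc_smiles) + [END])

    def encode_pair(self, sc_smiles: str, tc_smiles: str, delta: float
                    ) -> tuple[list[int], list[int]]:
        return self.encode_source(sc_smiles, delta), self.encode_target(tc_smiles)

    def decode(self, ids) -> str:
        """Join token texts back into a string, dropping specials."""
        out = []
        for i in ids:
            s = self.symbols[int(i)]
            if s in (START, PAD):
                continue
            if s == END:
                break
            out.append(s)
        return "".join(out)

    # -- serialisation --------------------------------------------------
    def to_json(self) -> str:
        meta = {"symbols": self.symbols,
                "bins": {"lo": self.bins.lo, "hi": self.bins.hi,
                         "width": self.bins.width, "clamp": self.bins.clamp}}
        return json.dumps(meta, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SequenceVocabulary":
        meta = json.loads(text)
        return cls(meta["symbols"], PotencyBinVocabulary(**meta["bins"]))

    def vocab_hash(self) -> str:
        import hashlib
        return hashlib.sha1("\x00".join(self.symbols).encode()).hexdigest()[:12]


def pad_batch(seqs: list[list[int]], pad_id: int) -> np.ndarray:
    """Right-pad integer sequences into a dense [B, T] array."""
    n = max(len(s) for s in seqs)
    out = np.full((len(seqs), n), pad_id, dtype=np.int64)
    for i, s in enumerate(seqs):
        out[i, :len(s)] = s
    return out
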