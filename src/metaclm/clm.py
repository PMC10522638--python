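"""The base chemical language model (CLM): training, checkpointing,
candidate generation and reproducibility scoring.

The CLM learns the conditional translation (SC, dPot) -> TC on analogue
pair triples: given a source compound and a tokenised potency difference
it emits structural analogues expected to realise that difference.
Training minimises teacher-forced cross-entropy with Adam; a checkpoint
is recorded every epoch and the model with minimal training loss is
returned (earliest epoch on ties). Candidate generation draws a fixed
number of sequences by multinomial decoding; each decoded string is
validity-checked with RDKit and canonicalised.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from . import autodiff as ad
from .autodiff import Adam, Params
from .ccr import AnaloguePairTriple
from .chem import try_canonical_smiles
from .tokenization import SequenceVocabulary, TokenizationError, VocabularyError, pad_batch
from .transformer import ArchitectureConfig, Seq2SeqTransformer

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of the base model.

    The full-scale defaults are encoding dimension 256, batch size 64,
    learning rate 0.001 and up to 1000 training epochs. The desk-scale
    preset shrinks the architecture (not the algorithm) so the entire
    pipeline runs on one CPU in minutes.
    """

    encoding_dim: int = 256
    batch_size: int = 64
    learning_rate: float = 0.001
    max_epochs: int = 1000
    n_layers: int = 2
    n_heads: int = 4
    ff_mult: int = 4
    dropout: float = 0.0
    max_len_factor: float = 1.5  # decode budget: 1.5 x longest training target
    temperature: float = 1.0
    dtype: str = "float32"

    @classmethod
    def desk_scale(cls, **overrides) -> "ModelConfig":
        base = dict(encoding_dim=64, batch_size=32, learning_rate=0.001,
                    max_epochs=60, n_layers=1, n_heads=2, ff_mult=2)
        base.update(overrides)
        return cls(**base)

    def with_(self, **overrides) -> "ModelConfig":
        return replace(self, **overrides)


@dataclass
class TrainedModel:
    """A trained CLM: min-loss parameters plus everything needed to decode."""

    params: Params
    vocab: SequenceVocabulary
    config: ModelConfig
    loss_history: list[float]
    best_epoch: int
    max_target_len: int
    architecture: Seq2SeqTransformer

    @property
    def final_loss(self) -> float:
        return self.loss_history[self.best_epoch]

    def decode_budget(self) -> int:
        return max(4, int(np.ceil(self.config.max_len_factor * self.max_target_len)))


@dataclass
class GenerationResult:
    sc: str
    delta: float
    candidates: list[tuple[str, bool]]  # (canonical or raw string, validity flag)
    n_requested: int

    @property
    def valid_set(self) -> set[str]:
        return {s for s, ok in self.candidates if ok}


# ----------------------------------------------------------------------
# Encoding helpers
# ----------------------------------------------------------------------

def encode_triples(triples: list[AnaloguePairTriple], vocab: SequenceVocabulary
                   ) -> tuple[list[list[int]], list[list[int]]]:
    srcs, tgts = [], []
    for t in triples:
        try:
            s, g = vocab.encode_pair(t.source.structure, t.target.structure,
                                     t.delta_pot)
        except (TokenizationError, VocabularyError, ValueError) as exc:
            raise ValueError(
                f"triple ({t.source.structure}, {t.target.structure}, "
                f"{t.delta_pot:+.2f}) is not encodable: {exc}") from exc
        srcs.append(s)
        tgts.append(g)
    return srcs, tgts


def make_batches(srcs, tgts, pad_id: int, batch_size: int,
                 rng: np.random.Generator | None = None):
    order = np.arange(len(srcs))
    if rng is not None:
        rng.shuffle(order)
    for lo in range(0, len(order), batch_size):
        idx = order[lo:lo + batch_size]
        yield {"src": pad_batch([srcs[i] for i in idx], pad_id),
               "tgt": pad_batch([tgts[i] for i in idx], pad_id)}


def build_architecture(vocab: SequenceVocabulary, config: ModelConfig
                       ) -> Seq2SeqTransformer:
    arch = ArchitectureConfig(
        vocab_size=len(vocab), pad_id=vocab.pad_id, start_id=vocab.start_id,
        end_id=vocab.end_id, dim=config.encoding_dim, n_layers=config.n_layers,
        n_heads=config.n_heads, ff_mult=config.ff_mult, dropout=config.dropout,
        dtype=config.dtype)
    return Seq2SeqTransformer(arch)


# ----------------------------------------------------------------------
# Training
# ----------------------------------------------------------------------

def train(triples: list[AnaloguePairTriple], config: ModelConfig, seed: int,
          vocab: SequenceVocabulary | None = None,
          init_params: Params | None = None,
          log_path: str | Path | None = None) -> TrainedModel:
    """Train a CLM on analogue pair triples.

    Runs up to ``config.max_epochs`` epochs of Adam on the teacher-forced
    cross-entropy; the per-epoch mean loss is recorded and the parameters
    at the minimal-loss epoch (earliest on ties) are returned. Fully
    reproducible for a given seed.
    """
    if not triples:
        raise ValueError("no training triples")
    vocab = vocab or SequenceVocabulary.from_pairs(
        (t.source.structure, t.target.structure) for t in triples)
    srcs, tgts = encode_triples(triples, vocab)
    max_tgt = max(len(t) for t in tgts)

    arch = build_architecture(vocab, config)
    rng = np.random.default_rng(seed)
    if init_params is None:
        params = arch.init_params(rng)
    else:
        params = ad.clone_params(init_params)
    opt = Adam(params, lr=config.learning_rate)

    history: list[float] = []
    best_loss, best_epoch, best_params = np.inf, -1, None
    for epoch in range(config.max_epochs):
        losses, weights = [], []
        for batch in make_batches(srcs, tgts, vocab.pad_id, config.batch_size, rng):
            loss, grads = arch.loss_and_grad(params, batch)
            opt.step(grads)
            losses.append(loss)
            weights.append(batch["src"].shape[0])
        epoch_loss = float(np.average(losses, weights=weights))
        history.append(epoch_loss)
        if epoch_loss < best_loss:  # strict: earliest epoch wins ties
            best_loss, best_epoch = epoch_loss, epoch
            best_params = {k: t.data.copy() for k, t in params.items()}
    if log_path is not None:
        _write_training_log(history, log_path)

    final = {k: ad.Tensor(v) for k, v in best_params.items()}
    for t in final.values():
        t.requires_grad = True
    return TrainedModel(params=final, vocab=vocab, config=config,
                        loss_history=history, best_epoch=best_epoch,
                        max_target_len=max_tgt, architecture=arch)


def _write_training_log(history: list[float], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("epoch\tloss\n")
        for i, loss in enumerate(history):
            fh.write(f"{i}\t{loss:.6f}\n")


# ----------------------------------------------------------------------
# Generation and reproducibility
# ----------------------------------------------------------------------

def generate(model: TrainedModel, sc: str, delta: float, n: int = 50,
             seed: int = 0, temperature: float | None = None,
             greedy: bool = False) -> GenerationResult:
    """Sample ``n`` candidate target compounds for (SC, dPot).

    Each decoded string is checked for chemical validity; invalid strings
    are kept in the candidate list with a False flag rather than dropped,
    so the requested sample count is always accounted for.
    """
    vocab = model.vocab
    src = vocab.encode_source(sc, delta)
    rng = np.random.default_rng(seed)
    temp = model.config.temperature if temperature is None else temperature
    seqs = model.architecture.sample(model.params, src, n, rng,
                                     max_len=model.decode_budget(),
                                     temperature=temp, greedy=greedy)
    candidates: list[tuple[str, bool]] = []
    for ids in seqs:
        text = vocab.decode(ids)
        canon = try_canonical_smiles(text) if text else None
        candidates.append((canon, True) if canon is not None else (text, False))
    return GenerationResult(sc=sc, delta=delta, candidates=candidates,
                            n_requested=n)


def pretrain_reproducibility(model: TrainedModel,
                             held_out_triples: list[AnaloguePairTriple],
                             n: int = 50, seed: int = 0,
                             greedy: bool = False) -> float:
    """Fraction of held-out triples whose target compound is regenerated.

    For every triple the model samples ``n`` candidates for
    (SC, dPot); the triple counts as reproduced when the canonical target
    structure appears among the valid candidates.
    """
    if not held_out_triples:
        return 0.0
    hits = 0
    for i, t in enumerate(held_out_triples):
        res = generate(model, t.source.structure, t.delta_pot, n=n,
                       seed=seed + i, greedy=greedy)
        if t.target.structure in res.valid_set:
            hits += 1
    return hits / len(held_out_triples)


# ----------------------------------------------------------------------
# Checkpoint I/O
# ----------------------------------------------------------------------

def save_checkpoint(model: TrainedModel, path: str | Path) -> None:
    """Persist parameters, config, vocabulary and loss history (.npz + json)."""
    path = Path(path)
    np.savez(path.with_suffix(".npz"),
             **{k: t.data for k, t in model.params.items()})
    meta = {
        "config": model.config.__dict__,
        "vocab": json.loads(model.vocab.to_json()),
        "vocab_hash": model.vocab.vocab_hash(),
        "loss_history": model.loss_history,
        "best_epoch": model.best_epoch,
        "max_target_len": model.max_target_len,
    }
    path.with_suffix(".json").write_text(json.dumps(meta))


def load_checkpoint(path: str | Path) -> TrainedModel:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    vocab = SequenceVocabulary.from_json(json.dumps(meta["vocab"]))
    if vocab.vocab_hash() != meta["vocab_hash"]:
        raise ValueError("vocabulary hash mismatch in checkpoint")
    config = ModelConfig(**meta["config"])
    arch = build_architecture(vocab, config)
    data = np.load(path.with_suffix(".npz"))
    params = {k: ad.Tensor(data[k]) for k in data.files}
    for t in params.values():
        t.requires_grad = True
    return TrainedModel(params=params, vocab=vocab, config=config,
                        loss_history=list(meta["loss_history"]),
                        best_epoch=int(meta["best_epoch"]),
                        max_target_len=int(meta["max_target_len"]),
                        architecture=arch)
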