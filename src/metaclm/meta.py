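"""Model-agnostic meta-learning (MAML) over activity-class tasks, and
fraction-controlled fine-tuning of the resulting initialisation.

Each activity class is one task: its analogue pair triples are split
80/20 into a support set and a query set. A meta-training epoch adapts
the shared parameter vector to each task on its support set (inner
loop), evaluates the adapted model's query loss, and updates the shared
parameters on the sum of the query losses across tasks with Adam (outer
loop). The meta-gradient is the first-order MAML approximation: the
query-loss gradient evaluated at the adapted parameters, accumulated
over tasks. With an inner learning rate of zero this reduces exactly to
the ordinary multi-task gradient of the summed query loss.

Fine-tuning takes activity-cliff triples only (oriented so the target is
the more potent compound), draws a seed-frozen nested subset of the
requested fraction, and trains with a reduced learning rate, returning
the minimal-loss checkpoint. The same routine is applied to the
meta-trained initialisation (Meta-CLM) and to the plain pre-trained
initialisation (CLM), which produces the two arms of the comparison.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol, Sequence

import numpy as np

from . import autodiff as ad
from .autodiff import Adam, Params
from .ccr import AnaloguePairTriple, PairCategory
from .clm import ModelConfig, TrainedModel, encode_triples, make_batches, train
from .tokenization import SequenceVocabulary, pad_batch

log = logging.getLogger(__name__)


class DifferentiableModel(Protocol):
    """Anything exposing a loss gradient over a named parameter dict."""

    def loss_and_grad(self, params: Params, batch) -> tuple[float, dict[str, np.ndarray]]: ...

    def loss_value(self, params: Params, batch) -> float: ...


@dataclass
class MetaTask:
    class_id: str
    support: list[AnaloguePairTriple]
    query: list[AnaloguePairTriple]


@dataclass
class MetaState:
    """Meta-optimiser configuration plus the training trace."""

    inner_lr: float = 0.01
    inner_steps: int = 1
    meta_lr: float = 0.001
    # Adam epsilon for the outer optimiser. A relatively large value damps
    # the near-sign-magnitude first steps Adam takes on parameters whose
    # gradients are tiny, which matters when meta-training starts from an
    # already-converged pre-trained model.
    meta_eps: float = 1e-4
    meta_warmup_updates: int = 20
    history: list[float] = field(default_factory=list)  # summed query loss
    per_task_history: list[dict[str, float]] = field(default_factory=list)


@dataclass(frozen=True)
class FinetuneSpec:
    class_id: str
    fraction: float = 1.0
    learning_rate: float = 0.0001
    max_epochs: int = 200
    seed: int = 0

    STANDARD_FRACTIONS = (0.10, 0.25, 0.50, 1.00)


# ----------------------------------------------------------------------
# Task construction
# ----------------------------------------------------------------------

def make_tasks(class_triples: dict[str, list[AnaloguePairTriple]],
               min_pairs: int = 300, seed: int = 0,
               support_fraction: float = 0.8) -> list[MetaTask]:
    """Build one support/query task per qualifying activity class.

    Classes with fewer than ``min_pairs`` triples are excluded; the rest
    are split support/query (default 80/20) with a seed-reproducible
    shuffle.
    """
    rng = np.random.default_rng(seed)
    tasks: list[MetaTask] = []
    for class_id in sorted(class_triples):
        triples = class_triples[class_id]
        if len(triples) < min_pairs:
            log.info("class %s excluded from meta-training: %d < %d triples",
                     class_id, len(triples), min_pairs)
            continue
        order = rng.permutation(len(triples))
        n_support = int(round(support_fraction * len(triples)))
        support = [triples[i] for i in order[:n_support]]
        query = [triples[i] for i in order[n_support:]]
        tasks.append(MetaTask(class_id=class_id, support=support, query=query))
    if not tasks:
        raise ValueError(
            f"no activity class has at least {min_pairs} analogue pair triples")
    return tasks


# ----------------------------------------------------------------------
# Inner loop
# ----------------------------------------------------------------------

def inner_adapt(model: DifferentiableModel, params: Params, support_batch,
                inner_lr: float, inner_steps: int = 1) -> Params:
    """Task adaptation: ``inner_steps`` SGD steps on the support loss.

    Returns fresh parameters; the input parameter dict is never mutated.
    With ``inner_lr == 0`` the result equals the input exactly.
    """
    if inner_steps < 1:
        raise ValueError("inner_steps must be >= 1")
    adapted = ad.clone_params(params)
    for _ in range(inner_steps):
        _, grads = model.loss_and_grad(adapted, support_batch)
        for g in grads.values():
            if not np.all(np.isfinite(g)):
                raise FloatingPointError(
                    "non-finite gradient in inner adaptation step")
        adapted = ad.sgd_step(adapted, grads, inner_lr)
    return adapted


def _task_batches(task: MetaTask, vocab: SequenceVocabulary):
    s_src, s_tgt = encode_triples(task.support, vocab)
    q_src, q_tgt = encode_triples(task.query, vocab)
    pad = vocab.pad_id
    return ({"src": pad_batch(s_src, pad), "tgt": pad_batch(s_tgt, pad)},
            {"src": pad_batch(q_src, pad), "tgt": pad_batch(q_tgt, pad)})


# ----------------------------------------------------------------------
# Outer loop
# ----------------------------------------------------------------------

def _subsample(batch, size: int | None, rng: np.random.Generator):
    if size is None or size >= batch["src"].shape[0]:
        return batch
    idx = rng.choice(batch["src"].shape[0], size=size, replace=False)
    return {"src": batch["src"][idx], "tgt": batch["tgt"][idx]}


def meta_train(base: TrainedModel, tasks: Sequence[MetaTask], state: MetaState,
               epochs: int, seed: int = 0,
               tasks_per_batch: int | None = None,
               support_batch_size: int | None = None,
               query_batch_size: int | None = None,
               log_path: str | Path | None = None) -> tuple[Params, MetaState]:
    """MAML outer loop starting from the pre-trained base parameters.

    Per meta-epoch and task: adapt on the support set, evaluate the
    adapted model's query loss and its gradient at the adapted
    parameters (first-order meta-gradient), sum over tasks, and apply an
    Adam step to the shared parameters on the summed loss.
    ``state.history`` records the summed query loss per meta-epoch.

    By default every task contributes its full support and query sets to
    the single outer update of an epoch. For larger runs the task batch
    and the per-task support/query batches can be subsampled
    (``tasks_per_batch``, ``support_batch_size``, ``query_batch_size``),
    in which case an epoch performs one outer update per task batch and
    the recorded history entry sums each task's mean sampled query loss
    over the epoch.
    """
    if not tasks:
        raise ValueError("no meta-training tasks")
    arch = base.architecture
    vocab = base.vocab
    rng = np.random.default_rng(seed)
    theta = ad.clone_params(base.params)
    opt = Adam(theta, lr=state.meta_lr, eps=state.meta_eps,
               warmup_steps=state.meta_warmup_updates)
    batches = [_task_batches(t, vocab) for t in tasks]
    n_tasks = len(tasks)
    per_update = tasks_per_batch or n_tasks

    for epoch in range(epochs):
        order = rng.permutation(n_tasks) if tasks_per_batch else np.arange(n_tasks)
        epoch_losses: dict[str, list[float]] = {t.class_id: [] for t in tasks}
        for lo in range(0, n_tasks, per_update):
            group = order[lo:lo + per_update]
            total_grads = {k: np.zeros_like(t.data) for k, t in theta.items()}
            for ti in group:
                task, (support, query) = tasks[ti], batches[ti]
                sup = _subsample(support, support_batch_size, rng)
                qry = _subsample(query, query_batch_size, rng)
                adapted = inner_adapt(arch, theta, sup,
                                      state.inner_lr, state.inner_steps)
                q_loss, q_grads = arch.loss_and_grad(adapted, qry)
                epoch_losses[task.class_id].append(q_loss)
                for k in total_grads:
                    total_grads[k] += q_grads[k]
            opt.step(total_grads)
        per_task = {cid: float(np.mean(v)) for cid, v in epoch_losses.items() if v}
        summed_query_loss = float(sum(per_task.values()))
        if not math.isfinite(summed_query_loss):
            raise FloatingPointError(
                f"meta-training diverged at epoch {epoch}: summed query loss "
                f"{summed_query_loss}; last per-task losses {per_task}")
        state.history.append(summed_query_loss)
        state.per_task_history.append(per_task)
    if log_path is not None:
        _write_meta_log(state, [t.class_id for t in tasks], log_path)
    return theta, state


def _write_meta_log(state: MetaState, class_ids: list[str],
                    path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("epoch\tsummed_query_loss\t" + "\t".join(class_ids) + "\n")
        for i, (total, per_task) in enumerate(
                zip(state.history, state.per_task_history)):
            cols = "\t".join(f"{per_task[c]:.6f}" for c in class_ids)
            fh.write(f"{i}\t{total:.6f}\t{cols}\n")


# ----------------------------------------------------------------------
# Fine-tuning
# ----------------------------------------------------------------------

def fraction_subset(triples: list[AnaloguePairTriple], fraction: float,
                    seed: int) -> list[AnaloguePairTriple]:
    """Seed-frozen nested subset: the 10% subset is contained in the 25%
    subset for the same seed, making data-efficiency curves comparable."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(triples))
    n = max(1, int(round(fraction * len(triples))))
    subset = [triples[i] for i in order[:n]]
    if not subset:
        raise ValueError("fraction subset is empty")
    return subset


def finetune(init_params: Params, vocab: SequenceVocabulary,
             class_triples_ac: list[AnaloguePairTriple], spec: FinetuneSpec,
             config: ModelConfig) -> TrainedModel:
    """Fine-tune an initialisation on a class's activity-cliff triples.

    Only AC_CCR triples oriented target-more-potent are accepted. The
    same routine produces both comparison arms: pass the meta-trained
    parameters for Meta-CLM or the plain pre-trained parameters for CLM.
    """
    if not class_triples_ac:
        raise ValueError("no fine-tuning triples")
    for t in class_triples_ac:
        if t.category != PairCategory.AC_CCR:
            raise ValueError(
                f"fine-tuning requires AC_CCR triples; got {t.category.value} "
                f"for pair ({t.source.structure}, {t.target.structure})")
        if t.delta_pot < 0:
            raise ValueError(
                "fine-tuning triples must be oriented with the target as the "
                f"more potent compound; got dPot {t.delta_pot:+.2f}")
    subset = fraction_subset(class_triples_ac, spec.fraction, spec.seed)
    ft_config = config.with_(learning_rate=spec.learning_rate,
                             max_epochs=spec.max_epochs)
    return train(subset, ft_config, seed=spec.seed, vocab=vocab,
                 init_params=init_params)
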