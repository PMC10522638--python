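"""Meta-learning: task construction, inner-loop adaptation, first-order
meta-gradients, and fraction-controlled fine-tuning."""

import numpy as np
import pytest

import metaclm.autodiff as ad
from conftest import make_triple
from metaclm.autodiff import Tensor
from metaclm.ccr import PairCategory
from metaclm.clm import ModelConfig, train
from metaclm.meta import (FinetuneSpec, MetaState, MetaTask, finetune,
                          fraction_subset, inner_adapt, make_tasks, meta_train)

TINY = ModelConfig.desk_scale(encoding_dim=32, batch_size=8, max_epochs=60,
                              n_heads=2)


# ----------------------------------------------------------------------
# Stub models: differentiable objects with a handful of parameters
# ----------------------------------------------------------------------

class QuadraticStub:
    """L(w) = 0.5 * (w - c)^2, elementwise-summed; analytic everything."""

    def __init__(self, c: float = 3.0):
        self.c = c

    def loss(self, params, batch=None) -> Tensor:
        d = params["w"] - self.c
        return (d * d).sum() * 0.5

    def loss_and_grad(self, params, batch=None):
        ad.zero_grads(params)
        loss = self.loss(params, batch)
        loss.backward()
        return loss.item(), ad.grads_of(params)

    def loss_value(self, params, batch=None) -> float:
        with ad.no_grad():
            return self.loss(params, batch).item()


class NonlinearStub:
    """Tanh regression with <= 10 parameters: L = mean((tanh(Xw) - y)^2)."""

    def loss(self, params, batch) -> Tensor:
        X, y = batch
        pred = (Tensor(X) @ params["w"].reshape(-1, 1)).tanh()
        d = pred - y.reshape(-1, 1)
        return (d * d).mean()

    def loss_and_grad(self, params, batch):
        ad.zero_grads(params)
        loss = self.loss(params, batch)
        loss.backward()
        return loss.item(), ad.grads_of(params)

    def loss_value(self, params, batch) -> float:
        with ad.no_grad():
            return self.loss(params, batch).item()


def param_vec(v) -> dict:
    t = Tensor(np.asarray(v, dtype=float))
    t.requires_grad = True
    return {"w": t}


def fd_grad(f, w: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    g = np.zeros_like(w)
    for i in range(w.size):
        wp, wm = w.copy(), w.copy()
        wp[i] += eps
        wm[i] -= eps
        g[i] = (f(wp) - f(wm)) / (2 * eps)
    return g


# ----------------------------------------------------------------------
# make_tasks
# ----------------------------------------------------------------------

class TestMakeTasks:
    def _classes(self, sizes):
        return {f"T{i}": [make_triple("Cc1ccccc1", "CCc1ccccc1", 1.0)] * n
                for i, n in enumerate(sizes)}

    def test_class_below_min_pairs_excluded(self):
        tasks = make_tasks(self._classes([299, 300]), min_pairs=300, seed=0)
        assert [t.class_id for t in tasks] == ["T1"]

    def test_80_20_split_arithmetic(self):
        (task,) = make_tasks(self._classes([300]), min_pairs=300, seed=0)
        assert len(task.support) == 240
        assert len(task.query) == 60

    def test_same_seed_identical_split(self):
        classes = {"T0": [make_triple("Cc1ccccc1", "CCc1ccccc1", 1.0,
                                      sc_pki=5 + i * 0.001)
                          for i in range(40)]}
        a = make_tasks(classes, min_pairs=10, seed=4)
        b = make_tasks(classes, min_pairs=10, seed=4)
        assert [t.source.pki for t in a[0].support] == \
               [t.source.pki for t in b[0].support]

    def test_support_query_disjoint(self):
        classes = {"T0": [make_triple("Cc1ccccc1", "CCc1ccccc1", 1.0,
                                      sc_pki=5 + i * 0.001)
                          for i in range(50)]}
        (task,) = make_tasks(classes, min_pairs=10, seed=1)
        sup = {t.source.pki for t in task.support}
        qry = {t.source.pki for t in task.query}
        assert not sup & qry

    def test_no_qualifying_class_raises(self):
        with pytest.raises(ValueError):
            make_tasks(self._classes([5, 8]), min_pairs=300, seed=0)


# ----------------------------------------------------------------------
# inner_adapt
# ----------------------------------------------------------------------

class TestInnerAdapt:
    def test_zero_lr_is_identity(self):
        params = param_vec([1.0, -2.0])
        adapted = inner_adapt(QuadraticStub(), params, None, inner_lr=0.0)
        np.testing.assert_array_equal(adapted["w"].data, params["w"].data)

    def test_analytic_gradient_step(self):
        """One step on L = 0.5 (w-3)^2 from w=0 with lr 0.1 gives w=0.3."""
        params = param_vec([0.0])
        adapted = inner_adapt(QuadraticStub(c=3.0), params, None,
                              inner_lr=0.1, inner_steps=1)
        assert adapted["w"].data[0] == pytest.approx(0.3)

    def test_multiple_steps_compound(self):
        # w_{t+1} = w_t - 0.1 (w_t - 3) => geometric approach to 3
        params = param_vec([0.0])
        adapted = inner_adapt(QuadraticStub(3.0), params, None, 0.1, 3)
        assert adapted["w"].data[0] == pytest.approx(3.0 * (1 - 0.9 ** 3))

    def test_never_mutates_meta_parameters(self):
        params = param_vec([5.0])
        inner_adapt(QuadraticStub(), params, None, inner_lr=0.5, inner_steps=4)
        assert params["w"].data[0] == 5.0

    def test_deterministic(self):
        a = inner_adapt(QuadraticStub(), param_vec([1.0]), None, 0.1, 2)
        b = inner_adapt(QuadraticStub(), param_vec([1.0]), None, 0.1, 2)
        np.testing.assert_array_equal(a["w"].data, b["w"].data)


# ----------------------------------------------------------------------
# Meta-gradient correctness
# ----------------------------------------------------------------------

class TestMetaGradient:
    def setup_method(self):
        rng = np.random.default_rng(42)
        self.model = NonlinearStub()
        self.w0 = rng.normal(size=5)
        self.support = (rng.normal(size=(12, 5)), rng.normal(size=12))
        self.query = (rng.normal(size=(8, 5)), rng.normal(size=8))

    def test_first_order_meta_gradient_matches_finite_differences(self):
        """The first-order meta-gradient is the query-loss gradient at the
        adapted parameters; central finite differences of the query loss
        around the adapted point must agree to < 1e-4 relative error."""
        adapted = inner_adapt(self.model, param_vec(self.w0), self.support,
                              inner_lr=0.05, inner_steps=1)
        _, analytic = self.model.loss_and_grad(
            {"w": adapted["w"]}, self.query)
        numeric = fd_grad(
            lambda w: self.model.loss_value(param_vec(w), self.query),
            adapted["w"].data)
        rel = np.abs(analytic["w"] - numeric) / np.maximum(np.abs(numeric), 1e-12)
        assert rel.max() < 1e-4

    def test_zero_inner_lr_reduces_to_multitask_gradient(self):
        """With inner_lr = 0 the summed meta-gradient over tasks equals the
        plain gradient of the summed query loss at theta."""
        tasks = [self.support, self.query]  # two "tasks", query == their data
        total = np.zeros(5)
        for batch in tasks:
            adapted = inner_adapt(self.model, param_vec(self.w0), batch,
                                  inner_lr=0.0)
            _, g = self.model.loss_and_grad(adapted, batch)
            total += g["w"]
        numeric = fd_grad(
            lambda w: sum(self.model.loss_value(param_vec(w), b)
                          for b in tasks), self.w0)
        np.testing.assert_allclose(total, numeric, rtol=1e-6, atol=1e-9)


# ----------------------------------------------------------------------
# meta_train on the real architecture
# ----------------------------------------------------------------------

@pytest.fixture(scope="module")
def base_and_triples():
    triples = [make_triple(a, b, d) for a, b, d in [
        ("Cc1ccccc1", "CCc1ccccc1", 1.0),
        ("Oc1ccccc1", "Nc1ccccc1", 2.5),
        ("Clc1ccccc1", "Brc1ccccc1", -0.5),
        ("CCOc1ccccc1", "COc1ccccc1", 2.0),
        ("CC(C)c1ccccc1", "CCCc1ccccc1", 0.3),
    ]]
    base = train(triples, TINY.with_(max_epochs=30), seed=3)
    return base, triples


class TestMetaTrain:

    def test_query_loss_decreases_on_single_task(self, base_and_triples):
        base, triples = base_and_triples
        task = MetaTask("T0", support=triples, query=triples)
        state = MetaState(inner_lr=0.001, inner_steps=1, meta_lr=0.0005)
        _, state = meta_train(base, [task], state, epochs=40, seed=0)
        assert min(state.history) < state.history[0]

    def test_identical_tasks_have_equal_losses(self, base_and_triples):
        base, triples = base_and_triples
        tasks = [MetaTask("A", triples, triples),
                 MetaTask("B", triples, triples)]
        state = MetaState(inner_lr=0.001, inner_steps=1, meta_lr=0.0005)
        _, state = meta_train(base, tasks, state, epochs=5, seed=0)
        for per_task in state.per_task_history:
            assert per_task["A"] == pytest.approx(per_task["B"], rel=1e-12)

    def test_deterministic_for_fixed_seed(self, base_and_triples):
        base, triples = base_and_triples
        task = MetaTask("T0", support=triples[:4], query=triples[4:])
        runs = []
        for _ in range(2):
            state = MetaState(inner_lr=0.001, inner_steps=1, meta_lr=0.0005)
            _, state = meta_train(base, [task], state, epochs=4, seed=8)
            runs.append(state.history)
        assert runs[0] == runs[1]

    def test_empty_tasks_raise(self, base_and_triples):
        base, _ = base_and_triples
        with pytest.raises(ValueError):
            meta_train(base, [], MetaState(), epochs=1)


# ----------------------------------------------------------------------
# Fine-tuning
# ----------------------------------------------------------------------

def ac_triples(n=20):
    return [make_triple("Cc1ccccc1", "CCc1ccccc1", 2.0 + i * 0.01,
                        sc_pki=5.0) for i in range(n)]


class TestFinetune:
    def test_fraction_one_uses_all(self):
        assert len(fraction_subset(ac_triples(20), 1.0, seed=0)) == 20

    def test_fraction_subsets_are_nested(self):
        triples = ac_triples(200)
        small = fraction_subset(triples, 0.10, seed=3)
        large = fraction_subset(triples, 0.25, seed=3)
        assert len(small) == 20 and len(large) == 50
        small_ids = {id(t) for t in small}
        assert small_ids <= {id(t) for t in large}

    def test_ccr_category_rejected(self, tiny_triples):
        base = train(tiny_triples[:3], TINY.with_(max_epochs=5), seed=0)
        ccr_triple = make_triple("Cc1ccccc1", "CCc1ccccc1", 1.0)
        assert ccr_triple.category == PairCategory.CCR
        with pytest.raises(ValueError, match="AC_CCR"):
            finetune(base.params, base.vocab, [ccr_triple],
                     FinetuneSpec("T0"), TINY)

    def test_wrong_orientation_rejected(self, tiny_triples):
        base = train(tiny_triples[:3], TINY.with_(max_epochs=5), seed=0)
        bad = make_triple("Cc1ccccc1", "CCc1ccccc1", -2.5, sc_pki=8.0)
        with pytest.raises(ValueError, match="more potent"):
            finetune(base.params, base.vocab, [bad], FinetuneSpec("T0"), TINY)

    def test_finetune_returns_min_loss_checkpoint(self):
        triples = ac_triples(10)
        base = train(triples, TINY.with_(max_epochs=10), seed=1)
        spec = FinetuneSpec("T0", fraction=0.5, learning_rate=1e-3,
                            max_epochs=15, seed=2)
        model = finetune(base.params, base.vocab, triples, spec, TINY)
        assert model.final_loss == min(model.loss_history)
        assert len(model.loss_history) == 15
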