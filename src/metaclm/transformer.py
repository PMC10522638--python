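"""Encoder-decoder transformer for conditional sequence translation.

A standard pre-norm transformer: the encoder reads the source sequence
(source compound tokens plus the potency-difference condition token),
the decoder autoregressively emits the target compound sequence through
masked self-attention and cross-attention over the encoder states.
Implemented functionally — parameters live in a flat name->Tensor dict —
so that meta-learning can adapt copies of the parameter vector without
touching the originals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Params, Tensor

NEG_INF = -1e9


@dataclass(frozen=True)
class ArchitectureConfig:
    vocab_size: int
    pad_id: int
    start_id: int
    end_id: int
    dim: int = 256
    n_layers: int = 2
    n_heads: int = 4
    ff_mult: int = 4
    max_len: int = 256
    dropout: float = 0.0
    dtype: str = "float32"


def sinusoidal_positions(max_len: int, dim: int) -> np.ndarray:
    pos = np.arange(max_len)[:, None]
    i = np.arange(dim)[None, :]
    angle = pos / np.power(10000.0, (2 * (i // 2)) / dim)
    table = np.zeros((max_len, dim))
    table[:, 0::2] = np.sin(angle[:, 0::2])
    table[:, 1::2] = np.cos(angle[:, 1::2])
    return table


class Seq2SeqTransformer:
    """Functional transformer: all state is passed in as a parameter dict."""

    def __init__(self, config: ArchitectureConfig):
        if config.dim % config.n_heads != 0:
            raise ValueError("encoding dimension must be divisible by head count")
        self.cfg = config
        self.np_dtype = np.dtype(config.dtype)
        self._pos = sinusoidal_positions(config.max_len, config.dim).astype(
            self.np_dtype)

    # -- parameters -----------------------------------------------------
    def init_params(self, rng: np.random.Generator) -> Params:
        c = self.cfg
        p: Params = {}

        dt = self.np_dtype

        def w(name: str, *shape: int, scale: float = 0.02) -> None:
            p[name] = Tensor(rng.normal(0.0, scale, size=shape).astype(dt))
            p[name].requires_grad = True

        def zeros(name: str, *shape: int) -> None:
            p[name] = Tensor(np.zeros(shape, dtype=dt))
            p[name].requires_grad = True

        def ones(name: str, *shape: int) -> None:
            p[name] = Tensor(np.ones(shape, dtype=dt))
            p[name].requires_grad = True

        w("embed", c.vocab_size, c.dim)
        for side, n in (("enc", c.n_layers), ("dec", c.n_layers)):
            for i in range(n):
                base = f"{side}{i}"
                attns = ["self"] if side == "enc" else ["self", "cross"]
                for attn in attns:
                    for mat in ("wq", "wk", "wv", "wo"):
                        w(f"{base}.{attn}.{mat}", c.dim, c.dim)
                        zeros(f"{base}.{attn}.{mat}b", c.dim)
                    ones(f"{base}.{attn}.ln_g", c.dim)
                    zeros(f"{base}.{attn}.ln_b", c.dim)
                w(f"{base}.ff.w1", c.dim, c.dim * c.ff_mult)
                zeros(f"{base}.ff.b1", c.dim * c.ff_mult)
                w(f"{base}.ff.w2", c.dim * c.ff_mult, c.dim)
                zeros(f"{base}.ff.b2", c.dim)
                ones(f"{base}.ff.ln_g", c.dim)
                zeros(f"{base}.ff.ln_b", c.dim)
        ones("enc_final.ln_g", c.dim)
        zeros("enc_final.ln_b", c.dim)
        ones("dec_final.ln_g", c.dim)
        zeros("dec_final.ln_b", c.dim)
        w("out.w", c.dim, c.vocab_size)
        zeros("out.b", c.vocab_size)
        return p

    def n_parameters(self, params: Params) -> int:
        return sum(t.data.size for t in params.values())

    # -- building blocks -------------------------------------------------
    @staticmethod
    def _linear(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
        return x @ w + b

    def _mha(self, params: Params, base: str, x_q: Tensor, x_kv: Tensor,
             mask: np.ndarray | None) -> Tensor:
        c = self.cfg
        h, dh = c.n_heads, c.dim // c.n_heads
        bq, tq = x_q.shape[0], x_q.shape[1]
        tk = x_kv.shape[1]

        def heads(x: Tensor, t: int) -> Tensor:
            return x.reshape(bq, t, h, dh).transpose(0, 2, 1, 3)

        q = heads(self._linear(x_q, params[f"{base}.wq"], params[f"{base}.wqb"]), tq)
        k = heads(self._linear(x_kv, params[f"{base}.wk"], params[f"{base}.wkb"]), tk)
        v = heads(self._linear(x_kv, params[f"{base}.wv"], params[f"{base}.wvb"]), tk)
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / math.sqrt(dh))
        if mask is not None:
            scores = scores + mask
        att = ad.softmax(scores, axis=-1)
        ctx = (att @ v).transpose(0, 2, 1, 3).reshape(bq, tq, c.dim)
        return self._linear(ctx, params[f"{base}.wo"], params[f"{base}.wob"])

    def _ff(self, params: Params, base: str, x: Tensor) -> Tensor:
        hmid = self._linear(x, params[f"{base}.w1"], params[f"{base}.b1"]).relu()
        return self._linear(hmid, params[f"{base}.w2"], params[f"{base}.b2"])

    def _ln(self, params: Params, base: str, x: Tensor) -> Tensor:
        return ad.layer_norm(x, params[f"{base}.ln_g"], params[f"{base}.ln_b"])

    def _embed(self, params: Params, ids: np.ndarray) -> Tensor:
        x = ad.embedding(params["embed"], ids) * math.sqrt(self.cfg.dim)
        return x + self._pos[: ids.shape[1]]

    # -- forward ---------------------------------------------------------
    def _pad_mask(self, ids: np.ndarray, pad_id: int) -> np.ndarray:
        # additive mask over keys: [B, 1, 1, Tk]
        return np.where(ids == pad_id, NEG_INF, 0.0)[:, None, None, :].astype(
            self.np_dtype)

    def _causal_mask(self, t: int) -> np.ndarray:
        return np.triu(np.full((t, t), NEG_INF, dtype=self.np_dtype),
                       k=1)[None, None, :, :]

    def encode(self, params: Params, src: np.ndarray) -> tuple[Tensor, np.ndarray]:
        mask = self._pad_mask(src, self.cfg.pad_id)
        x = self._embed(params, src)
        for i in range(self.cfg.n_layers):
            base = f"enc{i}"
            xn = self._ln(params, f"{base}.self", x)
            x = x + self._mha(params, f"{base}.self", xn, xn, mask)
            x = x + self._ff(params, f"{base}.ff", self._ln(params, f"{base}.ff", x))
        return self._ln(params, "enc_final", x), mask

    def decode_logits(self, params: Params, memory: Tensor,
                      src_mask: np.ndarray, tgt_in: np.ndarray) -> Tensor:
        t = tgt_in.shape[1]
        causal = self._causal_mask(t)
        x = self._embed(params, tgt_in)
        for i in range(self.cfg.n_layers):
            base = f"dec{i}"
            xn = self._ln(params, f"{base}.self", x)
            x = x + self._mha(params, f"{base}.self", xn, xn, causal)
            x = x + self._mha(params, f"{base}.cross",
                              self._ln(params, f"{base}.cross", x), memory, src_mask)
            x = x + self._ff(params, f"{base}.ff", self._ln(params, f"{base}.ff", x))
        x = self._ln(params, "dec_final", x)
        return self._linear(x, params["out.w"], params["out.b"])

    def loss(self, params: Params, batch: dict[str, np.ndarray]) -> Tensor:
        """Teacher-forced mean token cross-entropy over non-pad positions."""
        src, tgt = batch["src"], batch["tgt"]
        memory, src_mask = self.encode(params, src)
        logits = self.decode_logits(params, memory, src_mask, tgt[:, :-1])
        tgt_out = tgt[:, 1:]
        mask = (tgt_out != self.cfg.pad_id).astype(float)
        return ad.cross_entropy_logits(logits, tgt_out, mask)

    def loss_and_grad(self, params: Params, batch: dict[str, np.ndarray]
                      ) -> tuple[float, dict[str, np.ndarray]]:
        ad.zero_grads(params)
        loss = self.loss(params, batch)
        loss.backward()
        return loss.item(), ad.grads_of(params)

    def loss_value(self, params: Params, batch: dict[str, np.ndarray]) -> float:
        with ad.no_grad():
            return self.loss(params, batch).item()

    # -- sampling --------------------------------------------------------
    def sample(self, params: Params, src_row: list[int], n: int,
               rng: np.random.Generator, max_len: int,
               temperature: float = 1.0, greedy: bool = False
               ) -> list[list[int]]:
        """Draw ``n`` target sequences for one source sequence.

        Multinomial sampling from the temperature-scaled softmax at each
        step (or the argmax when ``greedy``); generation stops per
        sequence at the END token or after ``max_len`` steps.
        """
        if n <= 0:
            return []
        c = self.cfg
        src = np.tile(np.asarray(src_row, dtype=np.int64), (n, 1))
        with ad.no_grad():
            memory, src_mask = self.encode(params, src)
            ys = np.full((n, 1), c.start_id, dtype=np.int64)
            finished = np.zeros(n, dtype=bool)
            for _ in range(max_len):
                logits = self.decode_logits(params, memory, src_mask, ys)
                step = logits.data[:, -1, :]
                if greedy:
                    nxt = step.argmax(axis=-1)
                else:
                    z = step / max(temperature, 1e-8)
                    z = z - z.max(axis=-1, keepdims=True)
                    p = np.exp(z)
                    p /= p.sum(axis=-1, keepdims=True)
                    u = rng.random((n, 1))
                    nxt = (p.cumsum(axis=-1) < u).sum(axis=-1)
                    nxt = np.minimum(nxt, c.vocab_size - 1)
                nxt = np.where(finished, c.pad_id, nxt)
                ys = np.concatenate([ys, nxt[:, None]], axis=1)
                finished |= nxt == c.end_id
                if finished.all():
                    break
        return [row.tolist() for row in ys]
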