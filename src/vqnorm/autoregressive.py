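"""Serialize latent code grids into token sentences and model them
autoregressively.

A latent grid is flattened to a 1-D "sentence" by a recorded raster
ordering (bijective, round-trippable).  A small causal transformer is
trained by next-token cross-entropy on sentences from typical subjects
only; at inference it emits, for every position, the probability it
assigned to the token actually observed there — the likelihood of
typicality of the corresponding brain segment.  Atypicality shows up as
low observed-token likelihood, a deviation from the learned pattern.

The transformer is plain NumPy with hand-written backprop: token + learned
position embeddings, pre-norm blocks of causal multi-head attention and a
GELU MLP, final layernorm and a linear head over the code vocabulary.  A
single learned start token is prepended; there is no demographic
conditioning.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from ._nn import Adam, gelu, gelu_backward, layernorm, layernorm_backward, softmax
from .types import LatentGrid


# ---------------------------------------------------------------------------
# serialization


@dataclass(frozen=True)
class OrderingSpec:
    """Raster serialization order: ``axis_order[0]`` varies slowest.

    ``reverse`` flips the corresponding axis before flattening.  The spec
    is recorded in every checkpoint so a sentence can always be mapped
    back to grid positions.
    """

    axis_order: tuple[int, int, int] = (0, 1, 2)
    reverse: tuple[bool, bool, bool] = (False, False, False)

    def __post_init__(self) -> None:
        if sorted(self.axis_order) != [0, 1, 2]:
            raise ValueError(f"axis_order must be a permutation of (0,1,2), got {self.axis_order}")


@dataclass
class TokenSequence:
    tokens: np.ndarray  # (L,) ints in [0, K)
    vocabulary_size: int
    latent_shape: tuple[int, int, int]
    ordering: OrderingSpec = OrderingSpec()
    subject_id: str | None = None

    def __post_init__(self) -> None:
        self.tokens = np.asarray(self.tokens)
        if self.tokens.ndim != 1:
            raise ValueError("tokens must be 1-D")

    def __len__(self) -> int:
        return self.tokens.shape[0]


def serialize(grid: LatentGrid, ordering: OrderingSpec = OrderingSpec(), subject_id: str | None = None) -> TokenSequence:
    """Flatten a latent grid to a token sentence under `ordering`."""
    arr = grid.codes
    for axis, rev in enumerate(ordering.reverse):
        if rev:
            arr = np.flip(arr, axis=axis)
    arr = np.transpose(arr, ordering.axis_order)
    return TokenSequence(
        arr.reshape(-1).copy(),
        vocabulary_size=grid.vocabulary_size,
        latent_shape=grid.latent_shape,
        ordering=ordering,
        subject_id=subject_id,
    )


def deserialize(
    tokens: np.ndarray,
    latent_shape: tuple[int, int, int],
    ordering: OrderingSpec = OrderingSpec(),
    vocabulary_size: int | None = None,
) -> LatentGrid:
    """Exact inverse of :func:`serialize`."""
    tokens = np.asarray(tokens)
    expected = int(np.prod(latent_shape))
    if tokens.size != expected:
        raise ValueError(
            f"token length {tokens.size} != prod(latent_shape) = {expected}"
        )
    permuted_shape = tuple(latent_shape[a] for a in ordering.axis_order)
    arr = tokens.reshape(permuted_shape)
    inverse = np.argsort(ordering.axis_order)
    arr = np.transpose(arr, inverse)
    for axis, rev in enumerate(ordering.reverse):
        if rev:
            arr = np.flip(arr, axis=axis)
    if vocabulary_size is None:
        vocabulary_size = int(arr.max()) + 1 if arr.size else 1
    return LatentGrid(np.ascontiguousarray(arr), vocabulary_size)


# ---------------------------------------------------------------------------
# causal transformer


@dataclass
class TransformerConfig:
    vocabulary_size: int = 32  # K code tokens; the start token is id K
    context_length: int = 512  # max sentence length L
    n_layers: int = 2
    n_heads: int = 4
    d_model: int = 32
    d_mlp: int = 128
    epochs: int = 30
    learning_rate: float = 3e-3
    batch_size: int = 8
    # fraction of INPUT tokens replaced by uniform random codes during
    # training (targets untouched).  Counters exposure bias: a model fit
    # only on clean typical context otherwise degrades everywhere
    # downstream of an anomalous token, smearing deviation scores across
    # the brain instead of localizing them.
    input_corruption: float = 0.1
    seed: int = 0


@dataclass
class PositionLikelihoods:
    """Per-position probability of the observed token, plus the full
    next-token distribution at every position."""

    observed: np.ndarray  # (L,) in (0, 1)
    distributions: np.ndarray  # (L, K), rows sum to 1

    def __len__(self) -> int:
        return self.observed.shape[0]


class CausalTransformer:
    def __init__(self, config: TransformerConfig, rng: np.random.Generator | None = None):
        self.config = config
        c = config
        if c.d_model % c.n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        if rng is None:
            rng = np.random.default_rng(c.seed)
        std = 0.02
        res_std = std / np.sqrt(2.0 * c.n_layers)
        p: dict[str, np.ndarray] = {
            "wte": rng.normal(0, std, (c.vocabulary_size + 1, c.d_model)),
            "wpe": rng.normal(0, std, (c.context_length, c.d_model)),
            "lnf_g": np.ones(c.d_model),
            "lnf_b": np.zeros(c.d_model),
            "head_W": rng.normal(0, std, (c.d_model, c.vocabulary_size)),
            "head_b": np.zeros(c.vocabulary_size),
        }
        for l in range(c.n_layers):
            p[f"l{l}_ln1_g"] = np.ones(c.d_model)
            p[f"l{l}_ln1_b"] = np.zeros(c.d_model)
            p[f"l{l}_Wqkv"] = rng.normal(0, std, (c.d_model, 3 * c.d_model))
            p[f"l{l}_bqkv"] = np.zeros(3 * c.d_model)
            p[f"l{l}_Wo"] = rng.normal(0, res_std, (c.d_model, c.d_model))
            p[f"l{l}_bo"] = np.zeros(c.d_model)
            p[f"l{l}_ln2_g"] = np.ones(c.d_model)
            p[f"l{l}_ln2_b"] = np.zeros(c.d_model)
            p[f"l{l}_W1"] = rng.normal(0, std, (c.d_model, c.d_mlp))
            p[f"l{l}_b1"] = np.zeros(c.d_mlp)
            p[f"l{l}_W2"] = rng.normal(0, res_std, (c.d_mlp, c.d_model))
            p[f"l{l}_b2"] = np.zeros(c.d_model)
        self.params = p

    @property
    def start_token(self) -> int:
        return self.config.vocabulary_size

    # ---- forward --------------------------------------------------------

    def forward(self, inputs: np.ndarray, need_cache: bool = False):
        """inputs: (B, T) int token ids (start token allowed).  Returns
        logits (B, T, K) and, if requested, the backward cache."""
        c = self.config
        B, T = inputs.shape
        if T > c.context_length:
            raise ValueError(
                f"sequence length {T} exceeds model context {c.context_length}; "
                "refusing to truncate"
            )
        p = self.params
        hd = c.d_model // c.n_heads
        h = p["wte"][inputs] + p["wpe"][:T]
        mask = np.triu(np.ones((T, T), dtype=bool), k=1)  # True above diagonal
        cache = {"inputs": inputs, "layers": []} if need_cache else None

        for l in range(c.n_layers):
            a, ln1c = layernorm(h, p[f"l{l}_ln1_g"], p[f"l{l}_ln1_b"])
            qkv = a @ p[f"l{l}_Wqkv"] + p[f"l{l}_bqkv"]
            q, k, v = np.split(qkv, 3, axis=-1)

            def heads(x):
                return x.reshape(B, T, c.n_heads, hd).transpose(0, 2, 1, 3)

            qh, kh, vh = heads(q), heads(k), heads(v)
            scores = qh @ kh.transpose(0, 1, 3, 2) / np.sqrt(hd)
            scores = np.where(mask, -np.inf, scores)
            att = softmax(scores, axis=-1)
            outh = att @ vh
            out = outh.transpose(0, 2, 1, 3).reshape(B, T, c.d_model)
            o = out @ p[f"l{l}_Wo"] + p[f"l{l}_bo"]
            h_mid = h + o

            m, ln2c = layernorm(h_mid, p[f"l{l}_ln2_g"], p[f"l{l}_ln2_b"])
            f_pre = m @ p[f"l{l}_W1"] + p[f"l{l}_b1"]
            f = gelu(f_pre)
            h = h_mid + f @ p[f"l{l}_W2"] + p[f"l{l}_b2"]
            if need_cache:
                cache["layers"].append(
                    dict(a=a, ln1c=ln1c, qh=qh, kh=kh, vh=vh, att=att, out=out,
                         m=m, ln2c=ln2c, f_pre=f_pre, f=f)
                )

        hf, lnfc = layernorm(h, p["lnf_g"], p["lnf_b"])
        logits = hf @ p["head_W"] + p["head_b"]
        if need_cache:
            cache["hf"] = hf
            cache["lnfc"] = lnfc
        return logits, cache

    # ---- loss / grads ---------------------------------------------------

    def loss_and_grads(self, inputs: np.ndarray, targets: np.ndarray):
        c = self.config
        B, T = inputs.shape
        hd = c.d_model // c.n_heads
        p = self.params
        logits, cache = self.forward(inputs, need_cache=True)
        probs = softmax(logits, axis=-1)
        idx = (np.arange(B)[:, None], np.arange(T)[None, :], targets)
        loss = float(-np.mean(np.log(np.maximum(probs[idx], 1e-300))))

        grads = {k: np.zeros_like(v) for k, v in p.items()}
        dlogits = probs.copy()
        dlogits[idx] -= 1.0
        dlogits /= B * T

        hf = cache["hf"]
        grads["head_W"] = np.einsum("btd,btk->dk", hf, dlogits)
        grads["head_b"] = dlogits.sum(axis=(0, 1))
        dhf = dlogits @ p["head_W"].T
        dh, grads["lnf_g"], grads["lnf_b"] = layernorm_backward(dhf, cache["lnfc"])

        for l in reversed(range(c.n_layers)):
            lc = cache["layers"][l]
            # MLP block
            dmo = dh
            grads[f"l{l}_W2"] = np.einsum("btf,btd->fd", lc["f"], dmo)
            grads[f"l{l}_b2"] = dmo.sum(axis=(0, 1))
            df = dmo @ p[f"l{l}_W2"].T
            df_pre = gelu_backward(lc["f_pre"], df)
            grads[f"l{l}_W1"] = np.einsum("btd,btf->df", lc["m"], df_pre)
            grads[f"l{l}_b1"] = df_pre.sum(axis=(0, 1))
            dm = df_pre @ p[f"l{l}_W1"].T
            dx, grads[f"l{l}_ln2_g"], grads[f"l{l}_ln2_b"] = layernorm_backward(dm, lc["ln2c"])
            dh_mid = dh + dx

            # attention block
            do = dh_mid
            grads[f"l{l}_Wo"] = np.einsum("btd,bte->de", lc["out"], do)
            grads[f"l{l}_bo"] = do.sum(axis=(0, 1))
            dout = do @ p[f"l{l}_Wo"].T
            doh = dout.reshape(B, T, c.n_heads, hd).transpose(0, 2, 1, 3)
            att, vh, qh, kh = lc["att"], lc["vh"], lc["qh"], lc["kh"]
            datt = doh @ vh.transpose(0, 1, 3, 2)
            dvh = att.transpose(0, 1, 3, 2) @ doh
            ds = att * (datt - np.sum(datt * att, axis=-1, keepdims=True))
            ds /= np.sqrt(hd)
            dqh = ds @ kh
            dkh = ds.transpose(0, 1, 3, 2) @ qh

            def merge(x):
                return x.transpose(0, 2, 1, 3).reshape(B, T, c.d_model)

            dqkv = np.concatenate([merge(dqh), merge(dkh), merge(dvh)], axis=-1)
            grads[f"l{l}_Wqkv"] = np.einsum("btd,bte->de", lc["a"], dqkv)
            grads[f"l{l}_bqkv"] = dqkv.sum(axis=(0, 1))
            da = dqkv @ p[f"l{l}_Wqkv"].T
            dx, grads[f"l{l}_ln1_g"], grads[f"l{l}_ln1_b"] = layernorm_backward(da, lc["ln1c"])
            dh = dh_mid + dx

        np.add.at(grads["wte"], cache["inputs"], dh)
        grads["wpe"][:T] = dh.sum(axis=0)
        return loss, grads

    # ---- persistence ----------------------------------------------------

    def save(self, path: str | Path, ordering: OrderingSpec | None = None, latent_shape=None) -> None:
        meta = {
            "config": asdict(self.config),
            "ordering": asdict(ordering) if ordering is not None else None,
            "latent_shape": list(latent_shape) if latent_shape is not None else None,
        }
        np.savez(Path(path), __meta__=json.dumps(meta), **self.params)

    @classmethod
    def load(cls, path: str | Path):
        with np.load(Path(path), allow_pickle=False) as data:
            meta = json.loads(str(data["__meta__"]))
            model = cls(TransformerConfig(**meta["config"]))
            for k in model.params:
                model.params[k] = data[k]
        ordering = OrderingSpec(
            tuple(meta["ordering"]["axis_order"]), tuple(meta["ordering"]["reverse"])
        ) if meta["ordering"] else None
        shape = tuple(meta["latent_shape"]) if meta["latent_shape"] else None
        return model, ordering, shape


# ---------------------------------------------------------------------------
# training and scoring


def _stack_sequences(sequences: Sequence[TokenSequence], config: TransformerConfig) -> np.ndarray:
    lengths = {len(s) for s in sequences}
    if len(lengths) != 1:
        raise ValueError(f"all sequences must share one length, got lengths {sorted(lengths)}")
    (L,) = lengths
    if L > config.context_length:
        raise ValueError(
            f"sequence length {L} exceeds model context {config.context_length}; "
            "refusing to truncate"
        )
    tokens = np.stack([np.asarray(s.tokens, dtype=np.int64) for s in sequences])
    if tokens.min() < 0 or tokens.max() >= config.vocabulary_size:
        raise ValueError(
            f"token ids must lie in [0, {config.vocabulary_size}); "
            f"found range [{tokens.min()}, {tokens.max()}]"
        )
    return tokens


def train_autoregressor(
    sequences: Sequence[TokenSequence],
    config: TransformerConfig,
    val_sequences: Sequence[TokenSequence] | None = None,
) -> tuple[CausalTransformer, dict]:
    """Train by next-token cross-entropy with teacher forcing.

    The learned start token is prepended, so position t is predicted from
    strictly preceding positions.  Returns the model and a report with the
    per-epoch training loss trace (and validation trace if provided).
    """
    tokens = _stack_sequences(sequences, config)
    n, L = tokens.shape
    rng = np.random.default_rng(config.seed)
    model = CausalTransformer(config, rng=rng)
    opt = Adam(model.params, lr=config.learning_rate)

    inputs = np.concatenate([np.full((n, 1), model.start_token), tokens[:, :-1]], axis=1)
    val_tokens = _stack_sequences(val_sequences, config) if val_sequences else None

    trace: list[float] = []
    val_trace: list[float] = []
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        total, batches = 0.0, 0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            batch_in = inputs[idx]
            if config.input_corruption > 0:
                corrupt = rng.random(batch_in.shape) < config.input_corruption
                corrupt[:, 0] = False  # keep the start token
                batch_in = np.where(
                    corrupt,
                    rng.integers(0, config.vocabulary_size, size=batch_in.shape),
                    batch_in,
                )
            loss, grads = model.loss_and_grads(batch_in, tokens[idx])
            if not np.isfinite(loss):
                raise FloatingPointError(f"training diverged (non-finite loss) at epoch {epoch}")
            opt.step(grads)
            total += loss
            batches += 1
        trace.append(total / batches)
        if val_tokens is not None:
            val_trace.append(float(np.mean([
                cross_entropy(model, TokenSequence(t, config.vocabulary_size, (len(t), 1, 1)))
                for t in val_tokens
            ])))
    report = {
        "loss_trace": trace,
        "initial_loss": trace[0],
        "final_loss": trace[-1],
        "val_loss_trace": val_trace,
    }
    return model, report


def observed_token_likelihoods(model: CausalTransformer, sequence: TokenSequence) -> PositionLikelihoods:
    """Teacher-forced scoring: one forward pass, position t holds
    P(token_t | tokens_<t, start)."""
    tokens = np.asarray(sequence.tokens, dtype=np.int64)
    if tokens.min() < 0 or tokens.max() >= model.config.vocabulary_size:
        raise ValueError(
            f"sequence vocabulary exceeds the model's: token range "
            f"[{tokens.min()}, {tokens.max()}] vs K={model.config.vocabulary_size}"
        )
    inputs = np.concatenate([[model.start_token], tokens[:-1]])[None, :]
    logits, _ = model.forward(inputs)
    dists = softmax(logits[0], axis=-1)
    observed = dists[np.arange(len(tokens)), tokens]
    return PositionLikelihoods(observed=observed, distributions=dists)


def cross_entropy(model: CausalTransformer, sequence: TokenSequence) -> float:
    """Mean next-token cross-entropy (nats) of one sequence."""
    lik = observed_token_likelihoods(model, sequence)
    return float(-np.mean(np.log(np.maximum(lik.observed, 1e-300))))
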