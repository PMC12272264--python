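"""Vector-quantized autoencoder: volumes -> discrete latent codes -> volumes.

The encoder maps each non-overlapping ``factor``^3 voxel patch to a
D-dimensional latent vector through a small MLP (a strided convolution in
all but name); the quantizer snaps each latent vector to its nearest
codebook entry (Euclidean distance, ties to the lowest index); the decoder
maps codebook vectors back to voxel patches, with a final clamp to
non-negative intensities since gray-matter density maps are non-negative.

Training minimizes reconstruction MSE plus a commitment term, with
gradients passed straight through the quantizer; the codebook itself is
maintained by exponential-moving-average cluster updates with dead-code
reseeding.  All of it is plain NumPy with hand-written gradients — the
models are deliberately small (tens of thousands of parameters).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence
import warnings

import numpy as np

from ._nn import Adam
from .types import LatentGrid, Volume3D


@dataclass
class Codebook:
    """K embedding vectors of dimension D with per-code usage counts."""

    vectors: np.ndarray  # (K, D)
    usage: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        if self.vectors.ndim != 2 or self.vectors.shape[0] < 1:
            raise ValueError("codebook must be a non-empty (K, D) array")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("codebook contains non-finite vectors")
        if self.usage is None:
            self.usage = np.zeros(self.vectors.shape[0], dtype=np.int64)

    @property
    def K(self) -> int:
        return self.vectors.shape[0]

    @property
    def D(self) -> int:
        return self.vectors.shape[1]


@dataclass
class ContinuousLatent:
    """Grid of D-dimensional encoder outputs, one per latent position."""

    vectors: np.ndarray  # (gx, gy, gz, D)

    @property
    def latent_shape(self) -> tuple[int, int, int]:
        return self.vectors.shape[:3]  # type: ignore[return-value]


@dataclass
class QuantizedLatent:
    """Grid of codebook vectors (each one an exact codebook row)."""

    vectors: np.ndarray  # (gx, gy, gz, D)

    @property
    def latent_shape(self) -> tuple[int, int, int]:
        return self.vectors.shape[:3]  # type: ignore[return-value]


@dataclass
class TokenizerConfig:
    vocabulary_size: int = 32  # K
    embedding_dim: int = 16  # D
    factor: int = 4  # spatial downsampling per axis
    hidden: int = 64
    epochs: int = 30
    learning_rate: float = 3e-3
    commitment_weight: float = 0.25
    ema_decay: float = 0.95
    batch_volumes: int = 8
    seed: int = 0


def _check_divisible(shape: Sequence[int], factor: int) -> None:
    if any(s % factor != 0 for s in shape):
        raise ValueError(
            f"volume shape {tuple(shape)} is not divisible by the "
            f"downsampling factor {factor} along every axis"
        )


def volume_to_patches(intensities: np.ndarray, factor: int) -> tuple[np.ndarray, tuple[int, int, int]]:
    """Split a 3-D array into non-overlapping factor^3 patches.

    Returns (patches, latent_shape) where patches has shape
    (prod(latent_shape), factor**3), raster (C) order over latent positions.
    """
    _check_divisible(intensities.shape, factor)
    gx, gy, gz = (s // factor for s in intensities.shape)
    p = intensities.reshape(gx, factor, gy, factor, gz, factor)
    p = p.transpose(0, 2, 4, 1, 3, 5).reshape(gx * gy * gz, factor**3)
    return p, (gx, gy, gz)


def patches_to_volume(patches: np.ndarray, latent_shape: tuple[int, int, int], factor: int) -> np.ndarray:
    gx, gy, gz = latent_shape
    v = patches.reshape(gx, gy, gz, factor, factor, factor)
    v = v.transpose(0, 3, 1, 4, 2, 5).reshape(gx * factor, gy * factor, gz * factor)
    return v


class VQTokenizer:
    """Trained encoder/decoder pair plus codebook."""

    def __init__(self, config: TokenizerConfig, rng: np.random.Generator | None = None):
        self.config = config
        c = config
        if rng is None:
            rng = np.random.default_rng(c.seed)
        p = c.factor**3

        def init(n_in, n_out):
            return rng.normal(0.0, 1.0 / np.sqrt(n_in), size=(n_in, n_out))

        self.params = {
            "enc_W1": init(p, c.hidden),
            "enc_b1": np.zeros(c.hidden),
            "enc_W2": init(c.hidden, c.embedding_dim),
            "enc_b2": np.zeros(c.embedding_dim),
            "dec_W1": init(c.embedding_dim, c.hidden),
            "dec_b1": np.zeros(c.hidden),
            "dec_W2": init(c.hidden, p),
            "dec_b2": np.zeros(p),
        }
        self.codebook = Codebook(rng.normal(0.0, 1.0, size=(c.vocabulary_size, c.embedding_dim)))
        # EMA accumulators for codebook maintenance
        self._ema_count = np.ones(c.vocabulary_size)
        self._ema_sum = self.codebook.vectors.copy()

    # ---- forward pieces -------------------------------------------------

    def _encode_patches(self, patches: np.ndarray):
        h_pre = patches @ self.params["enc_W1"] + self.params["enc_b1"]
        h = np.tanh(h_pre)
        z = h @ self.params["enc_W2"] + self.params["enc_b2"]
        return z, (patches, h)

    def _decode_vectors(self, z: np.ndarray):
        h_pre = z @ self.params["dec_W1"] + self.params["dec_b1"]
        h = np.tanh(h_pre)
        out_pre = h @ self.params["dec_W2"] + self.params["dec_b2"]
        out = np.maximum(out_pre, 0.0)  # densities are non-negative
        return out, (z, h, out_pre)

    # ---- persistence ----------------------------------------------------

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez(
            path,
            __config__=json.dumps(asdict(self.config)),
            codebook=self.codebook.vectors,
            usage=self.codebook.usage,
            **self.params,
        )

    @classmethod
    def load(cls, path: str | Path) -> "VQTokenizer":
        with np.load(Path(path), allow_pickle=False) as data:
            config = TokenizerConfig(**json.loads(str(data["__config__"])))
            tok = cls(config)
            for k in tok.params:
                tok.params[k] = data[k]
            tok.codebook = Codebook(data["codebook"], data["usage"].copy())
        return tok

    def export_codebook_csv(self, path: str | Path) -> None:
        np.savetxt(Path(path), self.codebook.vectors, delimiter=",", fmt="%.10g")


# ---------------------------------------------------------------------------
# public operations


def encode(volume: Volume3D, tokenizer: VQTokenizer) -> ContinuousLatent:
    """Map a volume to its continuous latent grid (deterministic)."""
    f = tokenizer.config.factor
    patches, latent_shape = volume_to_patches(volume.intensities, f)
    z, _ = tokenizer._encode_patches(patches)
    return ContinuousLatent(z.reshape(*latent_shape, tokenizer.config.embedding_dim))


def quantize(latent: ContinuousLatent, codebook: Codebook) -> LatentGrid:
    """Snap each latent vector to its nearest codebook entry.

    Distance is Euclidean; ties break to the lowest code index.
    """
    z = latent.vectors
    if z.shape[-1] != codebook.D:
        raise ValueError(f"latent dimension {z.shape[-1]} != codebook dimension {codebook.D}")
    flat = z.reshape(-1, codebook.D)
    codes = _nearest_codes(flat, codebook.vectors)
    return LatentGrid(codes.reshape(latent.latent_shape).astype(np.int32), codebook.K)


def _nearest_codes(flat: np.ndarray, vectors: np.ndarray) -> np.ndarray:
    # ||z - e||^2 = ||z||^2 - 2 z.e + ||e||^2 ; ||z||^2 constant per row.
    # Compute full distances to keep argmin's lowest-index tie rule exact.
    d2 = (
        np.sum(flat * flat, axis=1, keepdims=True)
        - 2.0 * flat @ vectors.T
        + np.sum(vectors * vectors, axis=1)
    )
    return np.argmin(d2, axis=1)


def embed(latent_grid: LatentGrid, codebook: Codebook) -> QuantizedLatent:
    """Pure codebook lookup: code index -> exact codebook row."""
    codes = latent_grid.codes
    if codes.size and codes.max() >= codebook.K:
        raise ValueError(f"code index {codes.max()} out of range for K={codebook.K}")
    return QuantizedLatent(codebook.vectors[codes])


def decode(quantized: QuantizedLatent, tokenizer: VQTokenizer) -> Volume3D:
    """Reconstruct a volume from quantized latents (non-negative output)."""
    c = tokenizer.config
    if quantized.vectors.shape[-1] != c.embedding_dim:
        raise ValueError(
            f"quantized latent dimension {quantized.vectors.shape[-1]} != "
            f"decoder embedding dimension {c.embedding_dim}"
        )
    flat = quantized.vectors.reshape(-1, c.embedding_dim)
    out, _ = tokenizer._decode_vectors(flat)
    vol = patches_to_volume(out, quantized.latent_shape, c.factor)
    return Volume3D(vol)


def tokenize(volume: Volume3D, tokenizer: VQTokenizer) -> LatentGrid:
    """encode -> quantize in one call."""
    return quantize(encode(volume, tokenizer), tokenizer.codebook)


# ---------------------------------------------------------------------------
# training


def train_tokenizer(
    volumes: Sequence[Volume3D], config: TokenizerConfig
) -> tuple[VQTokenizer, dict]:
    """Train the VQ autoencoder on a set of volumes.

    Returns the trained tokenizer and a report with the per-epoch loss
    trace and the final codebook usage histogram.  Raises on non-finite
    loss, naming the epoch.
    """
    if len(volumes) < 2:
        raise ValueError("need at least 2 training volumes")
    c = config
    if c.vocabulary_size < 2:
        warnings.warn("vocabulary size K < 2 is degenerate; training proceeds", stacklevel=2)

    rng = np.random.default_rng(c.seed)
    tok = VQTokenizer(c, rng=rng)
    all_patches = []
    for v in volumes:
        p, _ = volume_to_patches(v.intensities, c.factor)
        all_patches.append(p)

    # codebook init: random encoder outputs, so codes start on-distribution
    z0, _ = tok._encode_patches(np.concatenate(all_patches, axis=0))
    pick = rng.choice(len(z0), size=c.vocabulary_size, replace=len(z0) < c.vocabulary_size)
    tok.codebook.vectors[:] = z0[pick]
    tok._ema_sum = tok.codebook.vectors.copy()
    tok._ema_count[:] = 1.0

    opt = Adam(tok.params, lr=c.learning_rate)
    n_vol = len(volumes)
    trace: list[float] = []
    usage = np.zeros(c.vocabulary_size, dtype=np.int64)

    for epoch in range(c.epochs):
        order = rng.permutation(n_vol)
        epoch_loss = 0.0
        n_batches = 0
        usage[:] = 0
        for start in range(0, n_vol, c.batch_volumes):
            idx = order[start : start + c.batch_volumes]
            patches = np.concatenate([all_patches[i] for i in idx], axis=0)
            loss = _train_step(tok, opt, patches, usage)
            if not np.isfinite(loss):
                raise FloatingPointError(f"training diverged (non-finite loss) at epoch {epoch}")
            epoch_loss += loss
            n_batches += 1
        trace.append(epoch_loss / n_batches)

    tok.codebook.usage = usage.copy()
    report = {
        "loss_trace": trace,
        "initial_loss": trace[0],
        "final_loss": trace[-1],
        "codebook_usage": usage.tolist(),
        "n_dead_codes": int(np.sum(usage == 0)),
    }
    return tok, report


def _train_step(tok: VQTokenizer, opt: Adam, patches: np.ndarray, usage: np.ndarray) -> float:
    c = tok.config
    n = patches.shape[0]

    z_e, enc_cache = tok._encode_patches(patches)
    codes = _nearest_codes(z_e, tok.codebook.vectors)
    z_q = tok.codebook.vectors[codes]
    np.add.at(usage, codes, 1)

    # decoder sees the quantized vectors (straight-through on the way back)
    xhat, dec_cache = tok._decode_vectors(z_q)
    resid = xhat - patches
    rec_loss = float(np.mean(resid * resid))
    commit = z_e - z_q
    commit_loss = float(np.mean(commit * commit))
    loss = rec_loss + c.commitment_weight * commit_loss

    # ---- backward -------------------------------------------------------
    grads = {k: np.zeros_like(v) for k, v in tok.params.items()}
    dxhat = 2.0 * resid / resid.size
    _, h_dec, out_pre = dec_cache
    dout_pre = dxhat * (out_pre > 0.0)
    grads["dec_W2"] = h_dec.T @ dout_pre
    grads["dec_b2"] = dout_pre.sum(axis=0)
    dh_dec = (dout_pre @ tok.params["dec_W2"].T) * (1.0 - h_dec * h_dec)
    grads["dec_W1"] = z_q.T @ dh_dec
    grads["dec_b1"] = dh_dec.sum(axis=0)
    dz_q = dh_dec @ tok.params["dec_W1"].T

    # straight-through: reconstruction gradient copied to z_e, plus commitment
    dz_e = dz_q + c.commitment_weight * 2.0 * commit / commit.size
    p_in, h_enc = enc_cache
    grads["enc_W2"] = h_enc.T @ dz_e
    grads["enc_b2"] = dz_e.sum(axis=0)
    dh_enc = (dz_e @ tok.params["enc_W2"].T) * (1.0 - h_enc * h_enc)
    grads["enc_W1"] = p_in.T @ dh_enc
    grads["enc_b1"] = dh_enc.sum(axis=0)

    opt.step(grads)

    # ---- EMA codebook update with dead-code reseeding -------------------
    onehot_counts = np.bincount(codes, minlength=c.vocabulary_size).astype(float)
    sums = np.zeros_like(tok.codebook.vectors)
    np.add.at(sums, codes, z_e)
    d = c.ema_decay
    tok._ema_count = d * tok._ema_count + (1.0 - d) * onehot_counts
    tok._ema_sum = d * tok._ema_sum + (1.0 - d) * sums
    alive = tok._ema_count > 1e-3
    tok.codebook.vectors[alive] = tok._ema_sum[alive] / tok._ema_count[alive, None]
    dead = np.flatnonzero(~alive)
    if dead.size:
        rng = np.random.default_rng(int(n) + dead.size)  # deterministic reseed
        pick = rng.choice(n, size=dead.size, replace=n < dead.size)
        tok.codebook.vectors[dead] = z_e[pick]
        tok._ema_sum[dead] = z_e[pick]
        tok._ema_count[dead] = 1.0
    return loss
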