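"""Per-view encoder tower and discriminator.

Each view (amino-acid sequence; 3-state secondary structure) is encoded by its
own tower: token embedding + fixed sinusoidal positional encoding, a stack of
pre-LayerNorm Transformer encoder layers (multi-head self-attention + MLP,
residual connections after each block), a K-layer bidirectional GRU, and a
projection MLP producing the representation vector ``v``.  The two towers
never share parameters.  A small sigmoid-terminated feed-forward network maps
a representation (or the fused two-view representation) to a score in [0, 1];
a peptide is called positive when the score is strictly above 0.5.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor, parameter

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
STRUCT_ALPHABET = "HEC"
PAD_ID = 0
AA_TO_ID = {a: i + 1 for i, a in enumerate(AA_ALPHABET)}
STRUCT_TO_ID = {s: i + 1 for i, s in enumerate(STRUCT_ALPHABET)}


def encode_sequence_tokens(sequence: str) -> np.ndarray:
    try:
        return np.array([AA_TO_ID[c] for c in sequence], dtype=np.int64)
    except KeyError as e:
        raise ValueError(f"residue {e.args[0]!r} is not in the 20-letter alphabet") from None


def encode_structure_tokens(structure: str) -> np.ndarray:
    try:
        return np.array([STRUCT_TO_ID[c] for c in structure], dtype=np.int64)
    except KeyError as e:
        raise ValueError(f"structure state {e.args[0]!r} is not one of H/E/C") from None


@dataclass
class ModelConfig:
    """Hyperparameters of the hybrid-view model.

    ``n_encoder_layers`` is the number of Transformer encoder layers,
    ``gru_layers`` the number of stacked bidirectional GRU layers, ``proj_dim``
    the length of the representation vector v, and ``margin`` the contrastive
    margin m > 0.  Defaults are sized for CPU training; all are overridable.
    """

    d_model: int = 32
    n_encoder_layers: int = 2
    n_heads: int = 2
    gru_hidden: int = 32
    gru_layers: int = 1
    proj_dim: int = 32
    dropout: float = 0.0
    max_len: int = 250
    margin: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if self.d_model % self.n_heads != 0:
            raise ValueError("d_model must be divisible by n_heads")
        if not self.margin > 0:
            raise ValueError("margin m must be > 0")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**d)


def sinusoidal_positions(max_len: int, d_model: int) -> np.ndarray:
    """Fixed positional encoding: PE[p, 2i] = sin(p / 10000^(2i/d)),
    PE[p, 2i+1] = cos(p / 10000^(2i/d))."""
    pe = np.zeros((max_len, d_model))
    pos = np.arange(max_len)[:, None]
    i = np.arange(0, d_model, 2)
    angle = pos / np.power(10000.0, i / d_model)
    pe[:, 0::2] = np.sin(angle)
    pe[:, 1::2] = np.cos(angle[:, : d_model // 2])
    return pe


def _xavier(rng: np.random.Generator, fan_in: int, fan_out: int, shape=None) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape or (fan_in, fan_out))


class Module:
    """Tiny module base: recursive parameter collection by attribute walk."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()
        for value in vars(self).values():
            for p in _collect(value):
                if id(p) not in seen:
                    seen.add(id(p))
                    params.append(p)
        return params

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Tensor]]:
        out: list[tuple[str, Tensor]] = []
        for name, value in vars(self).items():
            out.extend(_collect_named(value, f"{prefix}{name}"))
        return out


def _collect(value):
    if isinstance(value, Tensor) and value.requires_grad:
        yield value
    elif isinstance(value, Module):
        yield from value.parameters()
    elif isinstance(value, (list, tuple)):
        for v in value:
            yield from _collect(v)


def _collect_named(value, name):
    if isinstance(value, Tensor) and value.requires_grad:
        yield name, value
    elif isinstance(value, Module):
        yield from value.named_parameters(prefix=name + ".")
    elif isinstance(value, (list, tuple)):
        for i, v in enumerate(value):
            yield from _collect_named(v, f"{name}.{i}")


class Linear(Module):
    def __init__(self, rng: np.random.Generator, n_in: int, n_out: int):
        self.W = parameter(_xavier(rng, n_in, n_out))
        self.b = parameter(np.zeros(n_out))

    def __call__(self, x: Tensor) -> Tensor:
        return ad.matmul(x, self.W) + self.b


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = parameter(np.ones(dim))
        self.beta = parameter(np.zeros(dim))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        xhat = xc * ad.power(var + self.eps, -0.5)
        return xhat * self.gamma + self.beta


class MultiHeadSelfAttention(Module):
    def __init__(self, rng: np.random.Generator, d_model: int, n_heads: int):
        self.n_heads = n_heads
        self.d_head = d_model // n_heads
        self.wq = Linear(rng, d_model, d_model)
        self.wk = Linear(rng, d_model, d_model)
        self.wv = Linear(rng, d_model, d_model)
        self.wo = Linear(rng, d_model, d_model)

    def __call__(self, x: Tensor, mask_add: np.ndarray | None = None) -> Tensor:
        B, L, D = x.shape
        H, dh = self.n_heads, self.d_head

        def split(t: Tensor) -> Tensor:  # [B,L,D] -> [B,H,L,dh]
            return ad.transpose(ad.reshape(t, (B, L, H, dh)), (0, 2, 1, 3))

        q, k, v = split(self.wq(x)), split(self.wk(x)), split(self.wv(x))
        scores = ad.matmul(q, ad.transpose(k, (0, 1, 3, 2))) * (1.0 / np.sqrt(dh))
        if mask_add is not None:
            scores = scores + Tensor(mask_add)
        attn = ad.softmax(scores, axis=-1)
        ctx = ad.matmul(attn, v)  # [B,H,L,dh]
        merged = ad.reshape(ad.transpose(ctx, (0, 2, 1, 3)), (B, L, D))
        return self.wo(merged)


class TransformerLayer(Module):
    """Pre-LN encoder layer: x + MSA(LN(x)), then x + MLP(LN(x))."""

    def __init__(self, rng: np.random.Generator, d_model: int, n_heads: int, mlp_ratio: int = 2):
        self.ln1 = LayerNorm(d_model)
        self.attn = MultiHeadSelfAttention(rng, d_model, n_heads)
        self.ln2 = LayerNorm(d_model)
        self.fc1 = Linear(rng, d_model, mlp_ratio * d_model)
        self.fc2 = Linear(rng, mlp_ratio * d_model, d_model)

    def __call__(self, x: Tensor, mask_add: np.ndarray | None = None,
                 drop: float = 0.0, rng: np.random.Generator | None = None) -> Tensor:
        h = self.attn(self.ln1(x), mask_add)
        if drop > 0:
            h = ad.dropout(h, drop, rng)
        x = x + h
        h = self.fc2(ad.relu(self.fc1(self.ln2(x))))
        if drop > 0:
            h = ad.dropout(h, drop, rng)
        return x + h


class GruCell(Module):
    """Gated recurrent unit with update gate z and reset gate r.

    z_t = sigma(W_z [h_{t-1}, x_t]); r_t = sigma(W_r [h_{t-1}, x_t]);
    htilde_t = tanh(W [r_t o h_{t-1}, x_t]);
    h_t = (1 - z_t) o h_{t-1} + z_t o htilde_t.
    Weights only (no biases), matching the gate equations as written.
    """

    def __init__(self, rng: np.random.Generator, input_size: int, hidden_size: int):
        self.input_size = input_size
        self.hidden_size = hidden_size
        n = hidden_size + input_size
        self.Wz = parameter(_xavier(rng, n, hidden_size))
        self.Wr = parameter(_xavier(rng, n, hidden_size))
        self.W = parameter(_xavier(rng, n, hidden_size))

    def step(self, x_t: Tensor, h_prev: Tensor) -> Tensor:
        hx = ad.concat([h_prev, x_t], axis=-1)
        z = ad.sigmoid(ad.matmul(hx, self.Wz))
        r = ad.sigmoid(ad.matmul(hx, self.Wr))
        rh = ad.concat([r * h_prev, x_t], axis=-1)
        htilde = ad.tanh(ad.matmul(rh, self.W))
        return (1.0 - z) * h_prev + z * htilde


def gru_step(x_t, h_prev, cell: GruCell):
    """Single GRU update on plain vectors; returns a NumPy vector."""
    with ad.no_grad():
        out = cell.step(Tensor(np.asarray(x_t, dtype=float)),
                        Tensor(np.asarray(h_prev, dtype=float)))
    return out.data


class BiGru(Module):
    """K-layer bidirectional GRU over [B, L, D]; the readout is the
    concatenated final hidden state of the last layer's two directions,
    taken at each sequence's true end (pads never advance the state)."""

    def __init__(self, rng: np.random.Generator, input_size: int, hidden_size: int, n_layers: int):
        self.hidden_size = hidden_size
        self.n_layers = n_layers
        self.fwd: list[GruCell] = []
        self.bwd: list[GruCell] = []
        for layer in range(n_layers):
            d_in = input_size if layer == 0 else 2 * hidden_size
            self.fwd.append(GruCell(rng, d_in, hidden_size))
            self.bwd.append(GruCell(rng, d_in, hidden_size))

    def __call__(self, x: Tensor, lengths: np.ndarray) -> Tensor:
        B, L, _ = x.shape
        steps = np.arange(L)
        final_f = final_b = None
        for layer in range(self.n_layers):
            cf, cb = self.fwd[layer], self.bwd[layer]
            h_f = Tensor(np.zeros((B, self.hidden_size)))
            h_b = Tensor(np.zeros((B, self.hidden_size)))
            outs_f, outs_b = [None] * L, [None] * L
            for t in range(L):
                m = Tensor((steps[t] < lengths).astype(float)[:, None])
                h_new = cf.step(x[:, t, :], h_f)
                h_f = h_new * m + h_f * (1.0 - m)
                outs_f[t] = h_f
            for t in range(L - 1, -1, -1):
                m = Tensor((steps[t] < lengths).astype(float)[:, None])
                h_new = cb.step(x[:, t, :], h_b)
                h_b = h_new * m + h_b * (1.0 - m)
                outs_b[t] = h_b
            final_f, final_b = h_f, h_b
            if layer < self.n_layers - 1:
                per_t = [ad.concat([outs_f[t], outs_b[t]], axis=-1) for t in range(L)]
                x = ad.concat([ad.reshape(p, (B, 1, 2 * self.hidden_size)) for p in per_t],
                              axis=1)  # [B, L, 2H] input to the next layer
        return ad.concat([final_f, final_b], axis=-1)  # [B, 2H]


class EncoderTower(Module):
    """One view's encoder: embedding + positions -> Transformer encoder
    -> Bi-GRU -> projection MLP -> representation v of length proj_dim."""

    def __init__(self, vocab_size: int, config: ModelConfig, rng: np.random.Generator):
        self.config = config
        self.vocab_size = vocab_size
        d = config.d_model
        self.embedding = parameter(rng.normal(0.0, 0.1, size=(vocab_size, d)))
        self.pos_table = sinusoidal_positions(config.max_len, d)  # fixed, not a parameter
        self.layers = [TransformerLayer(rng, d, config.n_heads)
                       for _ in range(config.n_encoder_layers)]
        self.bigru = BiGru(rng, d, config.gru_hidden, config.gru_layers)
        g2 = 2 * config.gru_hidden
        self.proj1 = Linear(rng, g2, g2)
        self.proj2 = Linear(rng, g2, config.proj_dim)
        self._rng = rng

    # single-sequence contract operations -----------------------------------
    def embed(self, tokens: np.ndarray) -> Tensor:
        """Embed one token sequence (1-D int array) with positional encoding.

        Embeddings are scaled by sqrt(d_model), the canonical balance against
        the O(1) sinusoidal positional vectors.
        """
        tokens = np.asarray(tokens)
        if tokens.max(initial=0) >= self.vocab_size or tokens.min(initial=0) < 0:
            raise ValueError("token id outside vocabulary")
        L = len(tokens)
        if L > self.config.max_len:
            raise ValueError(f"sequence length {L} exceeds max_len {self.config.max_len}")
        emb = ad.take(self.embedding, tokens) * np.sqrt(self.config.d_model)
        return emb + Tensor(self.pos_table[:L])

    def _embed_batch(self, tokens: np.ndarray) -> Tensor:
        B, L = tokens.shape
        emb = ad.take(self.embedding, tokens) * np.sqrt(self.config.d_model)
        return emb + Tensor(self.pos_table[:L][None, :, :])

    def transform(self, x: Tensor, mask_add: np.ndarray | None = None,
                  train: bool = False) -> Tensor:
        drop = self.config.dropout if train else 0.0
        for layer in self.layers:
            x = layer(x, mask_add, drop=drop, rng=self._rng)
        return x

    def forward_batch(self, tokens: np.ndarray, lengths: np.ndarray,
                      train: bool = False) -> Tensor:
        """Encode a right-padded [B, L] token batch to representations [B, proj_dim]."""
        B, L = tokens.shape
        mask_add = np.where(np.arange(L)[None, :] < lengths[:, None], 0.0, -1e9)
        mask_add = mask_add[:, None, None, :]  # broadcast over heads and query positions
        x = self._embed_batch(tokens)
        if train and self.config.dropout > 0:
            x = ad.dropout(x, self.config.dropout, self._rng)
        x = self.transform(x, mask_add, train=train)
        h = self.bigru(x, lengths)  # [B, 2*gru_hidden]
        v = self.proj2(ad.relu(self.proj1(h)))
        return v

    def encode(self, tokens: np.ndarray) -> np.ndarray:
        """Deterministic single-sequence representation (evaluation mode)."""
        with ad.no_grad():
            v = self.forward_batch(np.asarray(tokens)[None, :],
                                   np.array([len(tokens)]), train=False)
        return v.data[0]


def embed_with_positions(tokens, tower: EncoderTower) -> np.ndarray:
    """Token embedding plus sinusoidal positional vectors, [L, d_model]."""
    with ad.no_grad():
        return tower.embed(np.asarray(tokens)).data


def transformer_encode(x_embed, tower: EncoderTower) -> np.ndarray:
    """Run the tower's Transformer encoder stack on an [L, d_model] input."""
    with ad.no_grad():
        x = Tensor(np.asarray(x_embed, dtype=float)[None, :, :])
        return tower.transform(x).data[0]


def encode_view(tokens, tower: EncoderTower) -> np.ndarray:
    """Full tower composition: embed -> Transformer -> Bi-GRU -> projection."""
    return tower.encode(np.asarray(tokens))


class Discriminator(Module):
    """Sigmoid-terminated feed-forward scorer over a representation vector."""

    def __init__(self, rng: np.random.Generator, in_dim: int, hidden: int = 32):
        self.in_dim = in_dim
        self.fc1 = Linear(rng, in_dim, hidden)
        self.fc2 = Linear(rng, hidden, 1)

    def __call__(self, v: Tensor) -> Tensor:
        """Scores for a batch [B, in_dim] -> [B]."""
        if v.shape[-1] != self.in_dim:
            raise ValueError(f"expected representation of length {self.in_dim}, got {v.shape[-1]}")
        return ad.reshape(ad.sigmoid(self.fc2(ad.relu(self.fc1(v)))), (v.shape[0],))


def discriminate(v, disc: Discriminator) -> float:
    """Score a single representation vector; label is 1 iff score > 0.5."""
    v = np.asarray(v, dtype=float)
    with ad.no_grad():
        return float(disc(Tensor(v[None, :])).data[0])


# -- checkpointing -----------------------------------------------------------
def save_params(modules: dict[str, Module], config: ModelConfig, path) -> None:
    arrays = {}
    for mod_name, mod in modules.items():
        for pname, p in mod.named_parameters(prefix=mod_name + "."):
            arrays[pname] = p.data
    arrays["__config__"] = np.frombuffer(
        json.dumps(config.to_dict()).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_params(modules: dict[str, Module], path) -> ModelConfig:
    with np.load(path) as npz:
        config = ModelConfig.from_dict(json.loads(bytes(npz["__config__"]).decode()))
        for mod_name, mod in modules.items():
            for pname, p in mod.named_parameters(prefix=mod_name + "."):
                p.data[...] = npz[pname]
    return config
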