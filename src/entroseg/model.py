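"""Hybrid CNN-Transformer segmentation network for patch triplets.

Architecture, in the order data flows through it:

* **Encoder** — a ResNet34-style stack: 7x7/2 stem, 2x2 max-pool, then four
  layers of two-convolution residual blocks with block counts 3/4/6/3 and
  channel widths (w, 2w, 4w, 8w), total stride 32.  Each residual block
  carries a dropout after its second convolution, before the residual
  addition, to counter overfitting on small training sets.  A 96x96 triplet
  (three consecutive slices as channels) maps to an 8w x 3 x 3 feature map;
  at the default width w=64 that is 512 channels over 3x3 = 9 tokens.
* **Transformer bottleneck** — the feature map is projected by a 1x1
  convolution, flattened to N = H''*W'' tokens of dimension d, summed with a
  learnable position embedding, and passed through L pre-norm Transformer
  layers:  c' = MHA(LN(c)) + c;  c = FFN(LN(c')) + c'.
* **Decoder** — tokens are reshaped back to d x H'' x W'' and upsampled x2
  per stage with two-convolution blocks, concatenating the resolution-matched
  encoder skip at each level, until the input patch resolution is restored;
  a final 1x1 convolution emits per-pixel class scores, softmaxed over the
  two classes (background incl. vessels / aneurysm).

The network predicts the segmentation of the *centre* patch only; the
flanking slices supply through-plane context, a compromise between 2D and 3D
convolution.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import nn
from .nn import Tensor


@dataclasses.dataclass
class ModelConfig:
    in_channels: int = 3
    blocks: tuple[int, int, int, int] = (3, 4, 6, 3)  # residual blocks per layer
    width: int = 64  # stem channels; token dim d = 8 * width
    n_layers: int = 4  # Transformer depth L
    n_heads: int = 8
    ffn_mult: int = 4  # FFN hidden width = ffn_mult * d
    dropout_p: float = 0.2
    n_classes: int = 2
    patch_size: int = 96
    seed: int = 0

    @property
    def d(self) -> int:
        """Token dimension (encoder output channels)."""
        return 8 * self.width

    @property
    def n_tokens(self) -> int:
        side = self.patch_size // 32
        return side * side

    def __post_init__(self):
        if self.patch_size % 32:
            raise ValueError("patch_size must be divisible by 32 (total encoder stride)")
        if self.d % self.n_heads:
            raise ValueError(f"token dim {self.d} not divisible by n_heads={self.n_heads}")
        if not (0.0 <= self.dropout_p < 1.0):
            raise ValueError("dropout_p must be in [0, 1)")
        if self.n_layers < 1:
            raise ValueError("need at least one Transformer layer")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["blocks"] = list(d["blocks"])
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "ModelConfig":
        data = dict(data)
        data["blocks"] = tuple(data["blocks"])
        return cls(**data)


class ResidualBlock(nn.Module):
    """conv-norm-act-conv-norm with dropout before the residual addition."""

    def __init__(self, cin: int, cout: int, stride: int, dropout_p: float,
                 rng: np.random.Generator):
        super().__init__()
        self.conv1 = nn.Conv2d(cin, cout, 3, stride=stride, pad=1, bias=False, rng=rng)
        self.norm1 = nn.GroupNorm(cout)
        self.conv2 = nn.Conv2d(cout, cout, 3, stride=1, pad=1, bias=False, rng=rng)
        self.norm2 = nn.GroupNorm(cout)
        self.dropout_p = dropout_p
        self.proj = (
            nn.Conv2d(cin, cout, 1, stride=stride, bias=False, rng=rng)
            if stride != 1 or cin != cout
            else None
        )
        self._rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        out = self.norm1(self.conv1(x)).relu()
        out = self.norm2(self.conv2(out))
        out = nn.dropout(out, self.dropout_p, self._rng, self.training)
        shortcut = x if self.proj is None else self.proj(x)
        return (out + shortcut).relu()


class Encoder(nn.Module):
    """ResNet34-style encoder; returns the final feature map plus skip features."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        super().__init__()
        w = config.width
        self.stem = nn.Conv2d(config.in_channels, w, 7, stride=2, pad=3, bias=False, rng=rng)
        self.stem_norm = nn.GroupNorm(w)
        self.layers: list[list[ResidualBlock]] = []
        cin = w
        for i, n_blocks in enumerate(config.blocks):
            cout = w * 2**i
            stride = 1 if i == 0 else 2
            layer = []
            for j in range(n_blocks):
                layer.append(
                    ResidualBlock(cin, cout, stride if j == 0 else 1, config.dropout_p, rng)
                )
                cin = cout
            self.layers.append(layer)

    def __call__(self, x: Tensor) -> tuple[Tensor, list[Tensor]]:
        h, wid = x.shape[2], x.shape[3]
        if h % 32 or wid % 32:
            raise ValueError(f"input spatial size {h}x{wid} not divisible by 32")
        out = self.stem_norm(self.stem(x)).relu()
        skips = [out]  # half resolution
        out = nn.maxpool2x2(out)
        for i, layer in enumerate(self.layers):
            for block in layer:
                out = block(out)
            if i < len(self.layers) - 1:
                skips.append(out)
        return out, skips  # skips: 1/2, 1/4, 1/8, 1/16 resolution


class TransformerLayer(nn.Module):
    """Pre-norm multi-head self-attention + feed-forward, both residual."""

    def __init__(self, d: int, n_heads: int, ffn_dim: int, rng: np.random.Generator):
        super().__init__()
        self.d, self.n_heads = d, n_heads
        self.ln1 = nn.LayerNorm(d)
        self.qkv = nn.Linear(d, 3 * d, rng=rng)
        self.proj = nn.Linear(d, d, rng=rng)
        self.ln2 = nn.LayerNorm(d)
        self.ffn1 = nn.Linear(d, ffn_dim, rng=rng)
        self.ffn2 = nn.Linear(ffn_dim, d, rng=rng)

    def __call__(self, x: Tensor) -> Tensor:
        b, n, d = x.shape
        h = self.n_heads
        dh = d // h
        normed = self.ln1(x)
        qkv = self.qkv(normed).reshape(b, n, 3, h, dh)
        qkv = qkv.transpose((2, 0, 3, 1, 4)).reshape(3, b * h, n, dh)
        q_t = _select_first_axis(qkv, 0)
        k_t = _select_first_axis(qkv, 1)
        v_t = _select_first_axis(qkv, 2)
        scores = q_t.matmul(k_t.transpose((0, 2, 1))) * (1.0 / np.sqrt(dh))
        attn = nn.softmax(scores, axis=-1)
        ctx = attn.matmul(v_t)  # b*h, n, dh
        ctx = ctx.reshape(b, h, n, dh).transpose((0, 2, 1, 3)).reshape(b, n, d)
        x = x + self.proj(ctx)
        x = x + self.ffn2(self.ffn1(self.ln2(x)).relu())
        return x


def _select_first_axis(t: Tensor, index: int) -> Tensor:
    """Select t[index] along axis 0, keeping the autodiff graph."""
    out_data = t.data[index]

    def bwd(g):
        full = np.zeros_like(t.data)
        full[index] = g
        t._accumulate(full)

    return Tensor(out_data, parents=(t,), backward=bwd)


class UpBlock(nn.Module):
    """x2 nearest upsampling, optional skip concatenation, two conv-norm-act."""

    def __init__(self, cin: int, cskip: int, cout: int, rng: np.random.Generator):
        super().__init__()
        self.conv1 = nn.Conv2d(cin + cskip, cout, 3, pad=1, bias=False, rng=rng)
        self.norm1 = nn.GroupNorm(cout)
        self.conv2 = nn.Conv2d(cout, cout, 3, pad=1, bias=False, rng=rng)
        self.norm2 = nn.GroupNorm(cout)

    def __call__(self, x: Tensor, skip: Tensor | None) -> Tensor:
        x = nn.upsample2x(x)
        if skip is not None:
            if skip.shape[2:] != x.shape[2:]:
                raise ValueError(f"skip resolution {skip.shape} does not match {x.shape}")
            x = nn.concat([x, skip], axis=1)
        x = self.norm1(self.conv1(x)).relu()
        return self.norm2(self.conv2(x)).relu()


class AneurysmSegNet(nn.Module):
    """Encoder -> Transformer bottleneck -> skip-connected decoder."""

    def __init__(self, config: ModelConfig):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(config.seed)
        w, d = config.width, config.d
        self.encoder = Encoder(config, rng)
        # linear projection W_p realised as a 1x1 convolution (d -> d)
        self.token_proj = nn.Conv2d(d, d, 1, rng=rng)
        self.pos_embedding = Tensor(
            (0.02 * rng.normal(size=(1, config.n_tokens, d))).astype(np.float32),
            requires_grad=True,
        )
        self.transformer = [
            TransformerLayer(d, config.n_heads, config.ffn_mult * d, rng)
            for _ in range(config.n_layers)
        ]
        # decoder: 1/32 -> 1/16 -> 1/8 -> 1/4 -> 1/2 -> 1/1
        skip_ch = [4 * w, 2 * w, w, w]  # layer3, layer2, layer1, stem
        out_ch = [4 * w, 2 * w, w, w, w]
        self.up_blocks = []
        cin = d
        for i in range(5):
            cskip = skip_ch[i] if i < 4 else 0
            self.up_blocks.append(UpBlock(cin, cskip, out_ch[i], rng))
            cin = out_ch[i]
        self.head = nn.Conv2d(cin, config.n_classes, 1, rng=rng)
        self._drop_rng = rng

    # -- stages ------------------------------------------------------------
    def encode(self, x: Tensor) -> tuple[Tensor, list[Tensor]]:
        return self.encoder(x)

    def transformer_block(self, feature_map: Tensor) -> Tensor:
        """Tokenise the feature map, add PE once, run L Transformer layers."""
        b, d, h, w = feature_map.shape
        tokens = self.token_proj(feature_map)
        tokens = tokens.reshape(b, d, h * w).transpose((0, 2, 1))  # b, N, d
        pe: Tensor = self.pos_embedding
        if h * w != self.config.n_tokens:
            # off-design input size: bilinearly resample the PE token grid
            # (treated as a constant; training always runs at the config size)
            from scipy import ndimage as _ndi

            side = int(round(np.sqrt(self.config.n_tokens)))
            table = self.pos_embedding.data.reshape(side, side, d)
            resized = _ndi.zoom(table, (h / side, w / side, 1.0), order=1)
            pe = Tensor(resized.reshape(1, h * w, d).astype(tokens.data.dtype))
        tokens = tokens + pe
        for layer in self.transformer:
            tokens = layer(tokens)
        return tokens

    def decode(self, tokens: Tensor, skips: list[Tensor]) -> Tensor:
        b, n, d = tokens.shape
        side = int(round(np.sqrt(n)))
        x = tokens.transpose((0, 2, 1)).reshape(b, d, side, side)
        rev_skips = list(reversed(skips))  # layer3, layer2, layer1, stem
        for i, block in enumerate(self.up_blocks):
            x = block(x, rev_skips[i] if i < len(rev_skips) else None)
        return self.head(x)  # b, n_classes, H_p, W_p

    def forward(self, triplet: np.ndarray | Tensor) -> Tensor:
        """Per-pixel class probabilities for the centre patch.

        Accepts (3, s, s) or a batch (B, 3, s, s) with gray values in
        [0, 255]; returns softmax probabilities of shape (B, n_classes, s, s).
        """
        x = triplet if isinstance(triplet, Tensor) else Tensor(np.asarray(triplet))
        if x.ndim == 3:
            x = x.reshape(1, *x.shape)
        x = x * (1.0 / 255.0)
        feat, skips = self.encode(x)
        tokens = self.transformer_block(feat)
        logits = self.decode(tokens, skips)
        return nn.softmax(logits, axis=1)

    def predict_proba(self, triplet: np.ndarray) -> np.ndarray:
        """Foreground probability map(s) in eval mode, as a numpy array."""
        was_training = self.training
        self.eval()
        out = self.forward(triplet).data[:, 1]
        if was_training:
            self.train()
        return out[0] if np.asarray(triplet).ndim == 3 else out

    # -- persistence -------------------------------------------------------
    def save(self, path) -> None:
        nn.save_checkpoint(path, self, self.config.to_dict())

    @classmethod
    def load(cls, path) -> "AneurysmSegNet":
        state, config = nn.load_checkpoint(path)
        model = cls(ModelConfig.from_dict(config))
        model.load_state_dict(state)
        return model

    def load_pretrained_encoder(self, state: dict[str, np.ndarray]) -> None:
        """Optional hook: load externally trained encoder weights by name."""
        own = dict(self.encoder.named_parameters("encoder."))
        for k, v in state.items():
            if k in own and own[k].data.shape == np.asarray(v).shape:
                own[k].data = np.asarray(v).astype(own[k].data.dtype)
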