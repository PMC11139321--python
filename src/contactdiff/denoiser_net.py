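"""The conditional U-Net noise predictor and its regression twin.

In diffusion mode the network receives the noisy tile x_t concatenated
channel-wise with the conditioning Hi-C tile, plus a sinusoidal embedding of
the continuous noise level abar, and predicts the Gaussian noise that was
added.  In regression mode the identical backbone takes the Hi-C tile alone
(no noise level) and directly outputs the predicted Micro-C tile.

Backbone layout: an initial convolution, a down path of levels (two residual
blocks, a linear-attention block, a strided-conv downsample), a middle block
with vanilla attention, and a symmetric up path with skip connections.
Residual blocks use group normalization (4 groups), SiLU activations, and
feed the noise-level embedding in as a per-channel (1 + scale, shift) pair
after the first normalization layer.  Attention blocks are pre-normalized
(1 group) with a residual connection; vanilla attention is used only in the
middle block, linear attention elsewhere.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Optional, Tuple

import numpy as np

from ._nn import Conv2d, GroupNorm, Linear, Module, ModuleList, Tensor

__all__ = [
    "NetConfig",
    "noise_level_embedding",
    "ResidualBlock",
    "AttentionBlock",
    "UNet",
    "unet_forward",
    "regression_forward",
]

#: multiplier applied to the (transformed) noise level before the sinusoidal
#: embedding, so nearby levels land on distinct phases
EMBED_SCALE = 5000.0


@dataclass(frozen=True)
class NetConfig:
    """Architecture configuration for the denoiser / regression U-Net."""

    base_channels: int = 64
    depth_multipliers: Tuple[int, ...] = (1, 2, 4, 8)
    groups_residual: int = 4
    groups_attention: int = 1
    window: int = 256
    mode: str = "ddpm"  # "ddpm" or "regression"
    attn_heads: int = 4
    attn_dim_head: int = 32
    level_transform: str = "sqrt"  # embed sqrt(abar) ("sqrt") or abar ("raw")
    cond_inject: str = "multiscale"  # "input" or "multiscale"

    def __post_init__(self) -> None:
        if self.mode not in ("ddpm", "regression"):
            raise ValueError("mode must be 'ddpm' or 'regression'")
        levels = len(self.depth_multipliers)
        if self.window % (2 ** (levels - 1)):
            raise ValueError(
                f"window {self.window} not divisible by 2^{levels - 1}"
            )
        if any(m <= 0 for m in self.depth_multipliers) or list(
            self.depth_multipliers
        ) != sorted(self.depth_multipliers):
            raise ValueError("depth multipliers must be positive nondecreasing")

    @property
    def in_channels(self) -> int:
        # diffusion consumes (x_t, condition); regression the condition only
        return 2 if self.mode == "ddpm" else 1

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "NetConfig":
        d = json.loads(s)
        d["depth_multipliers"] = tuple(d["depth_multipliers"])
        return cls(**d)


def noise_level_embedding(
    level: float, dim: int, transform: str = "sqrt"
) -> np.ndarray:
    """Sinusoidal embedding of a continuous noise level in (0, 1].

    The level (or its square root, default) is scaled by a large constant and
    embedded with the transformer position-encoding frequencies; components
    are bounded in [-1, 1] and distinct levels give distinct vectors.
    """
    if dim % 2:
        raise ValueError("embedding dim must be even")
    level = np.asarray(level, dtype=np.float64)
    x = np.sqrt(level) if transform == "sqrt" else level
    x = EMBED_SCALE * x
    half = dim // 2
    freqs = np.exp(-np.log(10000.0) * np.arange(half) / max(half - 1, 1))
    args = np.multiply.outer(x, freqs)
    emb = np.concatenate([np.sin(args), np.cos(args)], axis=-1)
    return emb.astype(np.float32)


class ResidualBlock(Module):
    """conv -> norm -> (1 + scale, shift) -> SiLU, twice, with a skip.

    The noise-level embedding is projected to per-channel scale and shift
    and applied after the first normalization layer; in regression mode the
    block runs without it.
    """

    def __init__(self, cin: int, cout: int, emb_dim: Optional[int],
                 groups: int = 4, rng: Optional[np.random.Generator] = None):
        self.conv1 = Conv2d(cin, cout, 3, rng=rng)
        self.norm1 = GroupNorm(min(groups, cout), cout)
        self.conv2 = Conv2d(cout, cout, 3, rng=rng)
        self.norm2 = GroupNorm(min(groups, cout), cout)
        self.emb_proj = (
            Linear(emb_dim, 2 * cout, rng=rng) if emb_dim else None
        )
        self.shortcut = (
            Conv2d(cin, cout, 1, padding=0, rng=rng) if cin != cout else None
        )
        self.cout = cout

    def forward(self, x: Tensor, emb: Optional[Tensor] = None) -> Tensor:
        h = self.norm1(self.conv1(x))
        if self.emb_proj is not None:
            if emb is None:
                raise ValueError("diffusion residual block needs an embedding")
            ss = self.emb_proj(emb)  # (B, 2*cout)
            scale = ss.narrow(1, 0, self.cout).reshape(
                ss.shape[0], self.cout, 1, 1
            )
            shift = ss.narrow(1, self.cout, self.cout).reshape(
                ss.shape[0], self.cout, 1, 1
            )
            h = h * (1.0 + scale) + shift
        h = h.silu()
        h = self.norm2(self.conv2(h)).silu()
        skip = x if self.shortcut is None else self.shortcut(x)
        return h + skip


class AttentionBlock(Module):
    """Pre-normalized multi-head self-attention with a residual connection.

    ``linear=True`` uses the efficient linear-attention form (softmax over
    the feature axis for queries and the spatial axis for keys); otherwise
    full softmax attention over all spatial positions.
    """

    def __init__(self, channels: int, heads: int = 4, dim_head: int = 32,
                 groups: int = 1, linear: bool = True,
                 rng: Optional[np.random.Generator] = None):
        hidden = heads * dim_head
        self.heads = heads
        self.dim_head = dim_head
        self.linear = linear
        self.norm = GroupNorm(groups, channels)
        self.to_qkv = Conv2d(channels, 3 * hidden, 1, padding=0, rng=rng)
        self.to_out = Conv2d(hidden, channels, 1, padding=0, zero_init=True,
                             rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        b, c, hh, ww = x.shape
        n = hh * ww
        h, d = self.heads, self.dim_head
        qkv = self.to_qkv(self.norm(x))  # (B, 3hd, H, W)
        qkv = qkv.reshape(b, 3, h, d, n)
        q = qkv.narrow(1, 0, 1).reshape(b, h, d, n)
        k = qkv.narrow(1, 1, 1).reshape(b, h, d, n)
        v = qkv.narrow(1, 2, 1).reshape(b, h, d, n)
        scale = d ** -0.5
        if self.linear:
            q = q.softmax(axis=2) * scale
            k = k.softmax(axis=3)
            context = k.matmul(v.transpose(0, 1, 3, 2))     # (B,h,d,d)
            out = context.transpose(0, 1, 3, 2).matmul(q)   # (B,h,d,n)
        else:
            sim = q.transpose(0, 1, 3, 2).matmul(k) * scale  # (B,h,n,n)
            attn = sim.softmax(axis=3)
            out = v.matmul(attn.transpose(0, 1, 3, 2))       # (B,h,d,n)
        out = out.reshape(b, h * d, hh, ww)
        return self.to_out(out) + x


class UNet(Module):
    """Denoiser eps(x_t, condition, abar) or regression predictor."""

    def __init__(self, config: NetConfig, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.config = config
        cfg = config
        base = cfg.base_channels
        chans = [base * m for m in cfg.depth_multipliers]
        self.emb_dim = 4 * base if cfg.mode == "ddpm" else None

        self.init_conv = Conv2d(cfg.in_channels, base, 3, rng=rng)
        if self.emb_dim:
            self.emb_lin1 = Linear(base, self.emb_dim, rng=rng)
            self.emb_lin2 = Linear(self.emb_dim, self.emb_dim, rng=rng)
        else:
            self.emb_lin1 = self.emb_lin2 = None

        def res(cin, cout):
            return ResidualBlock(cin, cout, self.emb_dim,
                                 groups=cfg.groups_residual, rng=rng)

        def attn(ch, linear):
            return AttentionBlock(ch, cfg.attn_heads, cfg.attn_dim_head,
                                  groups=cfg.groups_attention, linear=linear,
                                  rng=rng)

        # in diffusion mode the condition tile is re-injected (average-pooled
        # to each scale) at every down level and the middle block, so the
        # conditioning pathway does not have to be carried through features
        self.multiscale = (cfg.mode == "ddpm"
                           and cfg.cond_inject == "multiscale")
        extra = 1 if self.multiscale else 0

        self.down_res1 = ModuleList()
        self.down_res2 = ModuleList()
        self.down_attn = ModuleList()
        self.downsamples = ModuleList()
        prev = base
        for i, ch in enumerate(chans):
            self.down_res1.append(res(prev + extra, ch))
            self.down_res2.append(res(ch, ch))
            self.down_attn.append(attn(ch, linear=True))
            if i < len(chans) - 1:
                self.downsamples.append(
                    Conv2d(ch, ch, 3, stride=2, rng=rng)
                )
            prev = ch

        mid = chans[-1]
        self.mid_res1 = res(mid + extra, mid)
        self.mid_attn = attn(mid, linear=False)
        self.mid_res2 = res(mid, mid)

        self.up_convs = ModuleList()
        self.up_res1 = ModuleList()
        self.up_res2 = ModuleList()
        self.up_attn = ModuleList()
        for i in range(len(chans) - 2, -1, -1):
            ch_hi, ch_lo = chans[i + 1], chans[i]
            self.up_convs.append(Conv2d(ch_hi, ch_lo, 3, rng=rng))
            self.up_res1.append(res(ch_lo + ch_lo, ch_lo))
            self.up_res2.append(res(ch_lo, ch_lo))
            self.up_attn.append(attn(ch_lo, linear=True))

        self.final_res = res(chans[0], base)
        self.final_conv = Conv2d(base, 1, 3, zero_init=(cfg.mode == "ddpm"),
                                 rng=rng)

    # -- forward ----------------------------------------------------------

    def _embed(self, level) -> Optional[Tensor]:
        if self.emb_dim is None:
            return None
        raw = noise_level_embedding(
            level, self.config.base_channels,
            transform=self.config.level_transform,
        )
        if raw.ndim == 1:
            raw = raw[None, :]
        emb = Tensor(raw)
        return self.emb_lin2(self.emb_lin1(emb).silu())

    def forward(self, x: Tensor, level=None) -> Tensor:
        emb = self._embed(level)
        if emb is not None and emb.shape[0] == 1 and x.shape[0] > 1:
            emb = Tensor.concat([emb] * x.shape[0], axis=0)
        cond_pyramid = None
        if self.multiscale:
            lvl = x.data[:, 1:2].astype(np.float32)  # condition channel
            cond_pyramid = [lvl]
            for _ in range(len(self.down_res1) - 1):
                b, c, hh, ww = lvl.shape
                lvl = lvl.reshape(b, c, hh // 2, 2, ww // 2, 2).mean((3, 5))
                cond_pyramid.append(lvl)
        h = self.init_conv(x)
        skips = []
        n_levels = len(self.down_res1)
        for i in range(n_levels):
            if cond_pyramid is not None:
                h = Tensor.concat([h, Tensor(cond_pyramid[i])], axis=1)
            h = self.down_res1[i](h, emb)
            h = self.down_res2[i](h, emb)
            h = self.down_attn[i](h)
            skips.append(h)
            if i < n_levels - 1:
                h = self.downsamples[i](h)
        if cond_pyramid is not None:
            h = Tensor.concat([h, Tensor(cond_pyramid[-1])], axis=1)
        h = self.mid_res1(h, emb)
        h = self.mid_attn(h)
        h = self.mid_res2(h, emb)
        for j in range(n_levels - 1):
            h = self.up_convs[j](h.upsample2())
            skip = skips[n_levels - 2 - j]
            h = Tensor.concat([h, skip], axis=1)
            h = self.up_res1[j](h, emb)
            h = self.up_res2[j](h, emb)
            h = self.up_attn[j](h)
        h = self.final_res(h, emb)
        return self.final_conv(h)

    # -- numpy convenience ------------------------------------------------

    def predict_noise(self, x_t: np.ndarray, condition: np.ndarray,
                      level: float) -> np.ndarray:
        """eps-prediction on numpy grids (batched or single tile)."""
        if self.config.mode != "ddpm":
            raise ValueError("predict_noise requires ddpm mode")
        x_t, condition, squeeze = _as_batch(x_t, condition)
        inp = Tensor(np.stack([x_t, condition], axis=1))
        out = self.forward(inp, level).data[:, 0]
        return out[0] if squeeze else out

    def predict_image(self, condition: np.ndarray) -> np.ndarray:
        """Direct Micro-C prediction in regression mode."""
        if self.config.mode != "regression":
            raise ValueError("predict_image requires regression mode")
        condition = np.asarray(condition, dtype=np.float32)
        squeeze = condition.ndim == 2
        if squeeze:
            condition = condition[None]
        out = self.forward(Tensor(condition[:, None])).data[:, 0]
        return out[0] if squeeze else out


def _as_batch(x_t, condition):
    x_t = np.asarray(x_t, dtype=np.float32)
    condition = np.asarray(condition, dtype=np.float32)
    if x_t.shape != condition.shape:
        raise ValueError("x_t and condition shapes differ")
    squeeze = x_t.ndim == 2
    if squeeze:
        x_t, condition = x_t[None], condition[None]
    return x_t, condition, squeeze


def unet_forward(net: UNet, x_t: np.ndarray, condition: np.ndarray,
                 level: float) -> np.ndarray:
    """Functional wrapper around :meth:`UNet.predict_noise`."""
    return net.predict_noise(x_t, condition, level)


def regression_forward(net: UNet, condition: np.ndarray) -> np.ndarray:
    """Functional wrapper around :meth:`UNet.predict_image`."""
    return net.predict_image(condition)
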