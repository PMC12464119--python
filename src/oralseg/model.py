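"""The OralSeg network: a hybrid encoder that fuses, at every scale, a
volumetric shifted-window self-attention branch (SwinViT) with a spatial
state-space branch (SMamba), decoded through multi-scale residual skip
connections to a per-class probability map.

Architecture summary (U-shaped):

* Patch embedding: non-overlapping 2x2x2 voxel patches projected to the
  embedding width (48 by default), giving stage-0 features at half the input
  resolution.
* Four encoder stages.  Stage s has width ``embed_size * 2**s`` and spatial
  shape ``input / (2**s * patch_embed)``.  Each stage runs (a) a pair of
  shifted-window attention blocks — window attention with relative position
  bias, alternating between unshifted and half-window-shifted windows — and
  (b) a spatial state-space block: a 1x1x1 and a 3x3x3 convolution fused and
  passed through selective state-space scans along each of the three spatial
  axes, gated and summed.  The two branch outputs are stacked (channel concat)
  and projected back to the stage width; spatial downsampling between stages
  is 2x2x2 patch merging.
* Decoder: per stage, nearest-neighbour x2 upsampling, concatenation with the
  skip feature, and residual convolution blocks (instance normalisation, the
  appropriate choice at batch size 1), ending in a full-resolution stem merge,
  a 1x1x1 convolution head and a per-voxel class activation.

The head emits one channel per class (background + 36 structures).  Because
the classes are mutually exclusive, the default decoding activation is a
softmax over channels; a literal per-channel sigmoid is available via
``head_activation="sigmoid"``.  Ablations ``swin_only`` / ``smamba_only``
drop the other encoder branch while keeping the decoder identical.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import nn
from .nn import Tensor

__all__ = ["ModelConfig", "ConfigError", "OralSegNet", "build_model",
           "save_checkpoint", "load_checkpoint"]


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class ModelConfig:
    in_channels: int = 1
    num_classes: int = 37               # 36 foreground structures + background
    stages: int = 4
    patch_embed: tuple[int, int, int] = (2, 2, 2)
    feature_dim: int = 8                # per-head attention dimension
    embed_size: int = 48                # stage-0 width; doubles per stage
    attention_window: tuple[int, int, int] = (7, 7, 7)
    smamba_kernels: tuple[int, int] = (1, 3)
    smamba_state_dim: int = 16
    decoder_residual_blocks: int = 1
    ablation: str = "full"              # full | swin_only | smamba_only
    head_activation: str = "softmax"    # softmax | sigmoid
    fusion: str = "concat"              # concat | add
    tie_axis_params: bool = False
    mlp_ratio: float = 4.0
    coord_channels: bool = True         # append normalised window coordinates

    def __post_init__(self):
        if self.stages != 4:
            raise ConfigError("the encoder is a 4-stage hierarchy")
        if self.num_classes < 2:
            raise ConfigError("num_classes must be >= 2")
        if self.embed_size % self.feature_dim:
            raise ConfigError("embed_size must be a multiple of feature_dim "
                              "(the per-head width)")
        if self.ablation not in ("full", "swin_only", "smamba_only"):
            raise ConfigError(f"unknown ablation {self.ablation!r}")
        if self.head_activation not in ("softmax", "sigmoid"):
            raise ConfigError(f"unknown head activation {self.head_activation!r}")
        if self.fusion not in ("concat", "add"):
            raise ConfigError(f"unknown fusion {self.fusion!r}")
        if sorted(self.smamba_kernels) != [1, 3]:
            raise ConfigError("smamba_kernels must be the (1, 3) pair")

    @property
    def stage_widths(self) -> tuple[int, ...]:
        return tuple(self.embed_size * 2 ** s for s in range(self.stages))

    @property
    def spatial_divisor(self) -> tuple[int, ...]:
        return tuple(p * 2 ** self.stages for p in self.patch_embed)

    def validate_input_shape(self, shape: tuple[int, int, int]) -> None:
        for a, (dim, div) in enumerate(zip(shape, self.spatial_divisor)):
            if dim % div:
                raise ConfigError(
                    f"input dim {dim} on axis {a} is not divisible by "
                    f"{div} (patch size x 2^stages); pad the input")


# ---------------------------------------------------------------------------
# shifted-window attention
# ---------------------------------------------------------------------------

def _relative_position_index(ws: tuple[int, int, int]) -> np.ndarray:
    coords = np.stack(np.meshgrid(*[np.arange(w) for w in ws],
                                  indexing="ij")).reshape(3, -1)
    rel = coords[:, :, None] - coords[:, None, :]
    for a in range(3):
        rel[a] += ws[a] - 1
    strides = ((2 * ws[1] - 1) * (2 * ws[2] - 1), 2 * ws[2] - 1, 1)
    return (rel[0] * strides[0] + rel[1] * strides[1] + rel[2]).astype(np.int64)


def _window_mask(dims, ws, shifts) -> np.ndarray | None:
    """(n_windows, T, T) additive mask: 0 within a region, -1e9 across regions
    or into padding.  Regions follow the post-roll band layout; padding (to a
    window multiple) gets its own region id."""
    ids_axes = []
    padded = [int(np.ceil(d / w)) * w for d, w in zip(dims, ws)]
    need = any(s > 0 for s in shifts) or any(p != d for p, d in zip(padded, dims))
    if not need:
        return None
    for d, w, s, p in zip(dims, ws, shifts, padded):
        ia = np.zeros(d, dtype=np.int64)
        if s > 0:
            ia[max(d - w, 0):] = 1
            ia[max(d - s, 0):] = 2
            ia = np.roll(ia, -s)
        ia = np.concatenate([ia, np.full(p - d, 3, dtype=np.int64)])
        ids_axes.append(ia)
    grid = ((ids_axes[0][:, None, None] * 4 + ids_axes[1][None, :, None]) * 4
            + ids_axes[2][None, None, :])
    nd, nh, nw = [p // w for p, w in zip(padded, ws)]
    win = grid.reshape(nd, ws[0], nh, ws[1], nw, ws[2]) \
              .transpose(0, 2, 4, 1, 3, 5).reshape(nd * nh * nw, -1)
    mask = np.where(win[:, :, None] == win[:, None, :], 0.0, -1e9)
    return mask.astype(np.float32)


class WindowAttention(nn.Module):
    def __init__(self, dim: int, window: tuple[int, int, int], head_dim: int,
                 rng: np.random.Generator):
        self.window = tuple(window)
        self.heads = dim // head_dim
        self.head_dim = head_dim
        self.qkv = nn.Linear(dim, 3 * dim, rng)
        self.proj = nn.Linear(dim, dim, rng)
        n_rel = int(np.prod([2 * w - 1 for w in window]))
        self.rel_bias = nn.Parameter(np.zeros((n_rel, self.heads)))
        self._rel_index = _relative_position_index(self.window)
        self._mask_cache: dict = {}

    def forward(self, x: Tensor, shifted: bool) -> Tensor:
        B, d, h, w, C = x.shape
        ws = self.window
        # shifting is meaningful only where the grid exceeds the window
        shifts = tuple(ws[a] // 2 if (shifted and (d, h, w)[a] > ws[a]) else 0
                       for a in range(3))
        if any(shifts):
            x = x.roll(tuple(-s for s in shifts), (1, 2, 3))
        dims = (d, h, w)
        padded = [int(np.ceil(dd / ww)) * ww for dd, ww in zip(dims, ws)]
        pad = [(0, p - dd) for p, dd in zip(padded, dims)]
        if any(p[1] for p in pad):
            x = x.pad(((0, 0), *pad, (0, 0)))
        nd, nh, nw = [p // ww for p, ww in zip(padded, ws)]
        T = ws[0] * ws[1] * ws[2]
        nwin = nd * nh * nw

        xw = x.reshape(B, nd, ws[0], nh, ws[1], nw, ws[2], C) \
              .transpose(0, 1, 3, 5, 2, 4, 6, 7) \
              .reshape(B * nwin, T, C)
        qkv = self.qkv(xw).reshape(B * nwin, T, 3, self.heads, self.head_dim) \
                          .transpose(2, 0, 3, 1, 4)
        q, k, v = qkv[0], qkv[1], qkv[2]          # (Bn, heads, T, hd)
        scores = (q @ k.transpose(0, 1, 3, 2)) * (self.head_dim ** -0.5)
        bias = self.rel_bias.take0(self._rel_index.ravel()) \
                            .reshape(T, T, self.heads).transpose(2, 0, 1)
        scores = scores + bias
        key = (dims, shifts)
        if key not in self._mask_cache:
            self._mask_cache[key] = _window_mask(dims, ws, shifts)
        mask = self._mask_cache[key]
        if mask is not None:
            scores = scores.reshape(B, nwin, self.heads, T, T) \
                     + Tensor(mask[:, None])
            scores = scores.reshape(B * nwin, self.heads, T, T)
        attn = nn.softmax(scores, axis=-1)
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(B * nwin, T, C)
        out = self.proj(out)
        out = out.reshape(B, nd, nh, nw, ws[0], ws[1], ws[2], C) \
                 .transpose(0, 1, 4, 2, 5, 3, 6, 7) \
                 .reshape(B, *padded, C)
        if any(p[1] for p in pad):
            out = out[:, :d, :h, :w, :]
        if any(shifts):
            out = out.roll(shifts, (1, 2, 3))
        return out


class SwinBlock(nn.Module):
    """Pre-norm transformer block with (optionally shifted) window attention."""

    def __init__(self, dim: int, window, head_dim: int, shifted: bool,
                 mlp_ratio: float, rng: np.random.Generator):
        self.shifted = shifted
        self.norm1 = nn.LayerNorm(dim)
        self.attn = WindowAttention(dim, window, head_dim, rng)
        self.norm2 = nn.LayerNorm(dim)
        hidden = int(dim * mlp_ratio)
        self.fc1 = nn.Linear(dim, hidden, rng)
        self.fc2 = nn.Linear(hidden, dim, rng)

    def forward(self, x: Tensor) -> Tensor:
        x = x + self.attn(self.norm1(x), self.shifted)
        return x + self.fc2(self.fc1(self.norm2(x)).gelu())


class PatchEmbed(nn.Module):
    def __init__(self, in_ch: int, dim: int, patch, rng):
        self.patch = tuple(patch)
        self.proj = nn.Linear(in_ch * int(np.prod(patch)), dim, rng)
        self.norm = nn.LayerNorm(dim)

    def forward(self, x: Tensor) -> Tensor:
        """(B, C, D, H, W) -> channels-last (B, D/p, H/p, W/p, dim)."""
        B, C, D, H, W = x.shape
        p = self.patch
        x = x.reshape(B, C, D // p[0], p[0], H // p[1], p[1], W // p[2], p[2]) \
             .transpose(0, 2, 4, 6, 1, 3, 5, 7) \
             .reshape(B, D // p[0], H // p[1], W // p[2], C * int(np.prod(p)))
        return self.norm(self.proj(x))


class PatchMerging(nn.Module):
    """2x2x2 spatial downsampling by block concatenation + linear (8C -> 2C)."""

    def __init__(self, dim: int, rng):
        self.norm = nn.LayerNorm(8 * dim)
        self.reduce = nn.Linear(8 * dim, 2 * dim, rng, bias=False)

    def forward(self, x: Tensor) -> Tensor:
        B, d, h, w, C = x.shape
        x = x.reshape(B, d // 2, 2, h // 2, 2, w // 2, 2, C) \
             .transpose(0, 1, 3, 5, 2, 4, 6, 7) \
             .reshape(B, d // 2, h // 2, w // 2, 8 * C)
        return self.reduce(self.norm(x))


# ---------------------------------------------------------------------------
# spatial state-space branch
# ---------------------------------------------------------------------------

class AxisScan(nn.Module):
    """Selective (input-dependent) diagonal state-space scan along one axis."""

    def __init__(self, dim: int, state_dim: int, rng: np.random.Generator):
        self.A_log = nn.Parameter(np.log(np.tile(np.arange(1, state_dim + 1,
                                                           dtype=np.float32),
                                                 (dim, 1))))
        self.D = nn.Parameter(np.ones(dim))
        self.to_B = nn.Linear(dim, state_dim, rng, bias=False)
        self.to_C = nn.Linear(dim, state_dim, rng, bias=False)
        self.to_dt = nn.Linear(dim, dim, rng)

    def forward(self, seq: Tensor) -> Tensor:
        """seq: (B', L, C) -> (B', L, C), forward (unidirectional) scan."""
        Bp, L, C = seq.shape
        N = self.A_log.shape[1]
        dt = self.to_dt(seq).softplus()                      # (B', L, C)
        A = -(self.A_log.exp())                              # (C, N)
        dA = (dt.reshape(Bp, L, C, 1) * A.reshape(1, 1, C, N)).exp()
        Bt = self.to_B(seq)                                  # (B', L, N)
        dBx = dt.reshape(Bp, L, C, 1) * Bt.reshape(Bp, L, 1, N) \
            * seq.reshape(Bp, L, C, 1)
        Ct = self.to_C(seq)
        y = nn.linear_scan(dA, dBx, Ct)
        return y + seq * self.D


class SMambaBlock(nn.Module):
    """Dual-kernel convolution fusion followed by gated tri-axial scans.

    u = SiLU(conv1x1(x) + conv3x3(x)); out = u + gate(u) * sum_axis scan_a(u).
    With the gate closed the block reduces to the fused convolution path.
    """

    def __init__(self, dim: int, state_dim: int, tie_axis_params: bool,
                 rng: np.random.Generator):
        self.conv1 = nn.Conv3d(dim, dim, 1, rng)
        self.conv3 = nn.Conv3d(dim, dim, 3, rng)
        if tie_axis_params:
            shared = AxisScan(dim, state_dim, rng)
            self.scans = nn.ModuleList([shared, shared, shared])
        else:
            self.scans = nn.ModuleList(
                [AxisScan(dim, state_dim, rng) for _ in range(3)])
        self.gate = nn.Conv3d(dim, dim, 1, rng)
        # the summed tri-axial scan can be an order of magnitude larger than
        # the conv path; normalise it before the gated residual
        self.scan_norm = nn.InstanceNorm3d(dim)
        self.tied = tie_axis_params

    def named_parameters(self, prefix: str = ""):
        seen = set()
        for name, p in super().named_parameters(prefix):
            if id(p) in seen:       # tied axis parameters appear once
                continue
            seen.add(id(p))
            yield name, p

    def _scan_axis(self, u: Tensor, axis: int) -> Tensor:
        """Scan along spatial `axis` (0..2 over D, H, W) of (B, C, D, H, W)."""
        B, C, D, H, W = u.shape
        spatial = (D, H, W)
        others = [a for a in range(3) if a != axis]
        perm = (0, 2 + others[0], 2 + others[1], 2 + axis, 1)
        seq = u.transpose(perm).reshape(
            B * spatial[others[0]] * spatial[others[1]], spatial[axis], C)
        y = self.scans[axis](seq)
        y = y.reshape(B, spatial[others[0]], spatial[others[1]],
                      spatial[axis], C)
        inv = np.argsort(perm)
        return y.transpose(tuple(inv))

    def forward(self, x: Tensor) -> Tensor:
        u = (self.conv1(x) + self.conv3(x)).silu()
        s = self._scan_axis(u, 0) + self._scan_axis(u, 1) + self._scan_axis(u, 2)
        return u + self.gate(u).sigmoid() * self.scan_norm(s)


# ---------------------------------------------------------------------------
# decoder
# ---------------------------------------------------------------------------

class ResidualBlock(nn.Module):
    def __init__(self, c_in: int, c_out: int, rng):
        self.conv1 = nn.Conv3d(c_in, c_out, 3, rng)
        self.in1 = nn.InstanceNorm3d(c_out)
        self.conv2 = nn.Conv3d(c_out, c_out, 3, rng)
        self.in2 = nn.InstanceNorm3d(c_out)
        self.short = nn.Conv3d(c_in, c_out, 1, rng) if c_in != c_out else None

    def forward(self, x: Tensor) -> Tensor:
        y = self.in1(self.conv1(x)).silu()
        y = self.in2(self.conv2(y))
        sc = self.short(x) if self.short is not None else x
        return (y + sc).silu()


class UpBlock(nn.Module):
    """x2 nearest upsampling + channel halving conv, skip concat, residuals."""

    def __init__(self, c_in: int, c_skip: int, c_out: int, n_res: int, rng):
        self.up_conv = nn.Conv3d(c_in, c_out, 3, rng)
        self.res = nn.ModuleList(
            [ResidualBlock(c_out + c_skip if i == 0 else c_out, c_out, rng)
             for i in range(max(1, n_res))])

    def forward(self, x: Tensor, skip: Tensor) -> Tensor:
        x = self.up_conv(nn.upsample_nearest3d(x, 2))
        if x.shape[2:] != skip.shape[2:]:
            raise ConfigError(f"decoder/skip shape mismatch: {x.shape[2:]} "
                              f"vs {skip.shape[2:]}")
        x = nn.concat([x, skip], axis=1)
        for block in self.res:
            x = block(x)
        return x


# ---------------------------------------------------------------------------
# the network
# ---------------------------------------------------------------------------

class OralSegNet(nn.Module):
    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        self.cfg = cfg
        widths = cfg.stage_widths
        hd = cfg.feature_dim
        in_ch = cfg.in_channels + (3 if cfg.coord_channels else 0)
        self._coord_cache: dict = {}
        self.patch_embed = PatchEmbed(in_ch, widths[0], cfg.patch_embed, rng)
        self.swin_stages = None
        self.smamba_stages = None
        if cfg.ablation in ("full", "swin_only"):
            self.swin_stages = nn.ModuleList([
                nn.ModuleList([
                    SwinBlock(widths[s], cfg.attention_window, hd, False,
                              cfg.mlp_ratio, rng),
                    SwinBlock(widths[s], cfg.attention_window, hd, True,
                              cfg.mlp_ratio, rng)])
                for s in range(cfg.stages)])
        if cfg.ablation in ("full", "smamba_only"):
            self.smamba_stages = nn.ModuleList([
                SMambaBlock(widths[s], cfg.smamba_state_dim,
                            cfg.tie_axis_params, rng)
                for s in range(cfg.stages)])
        both = cfg.ablation == "full" and cfg.fusion == "concat"
        self.fuse_proj = nn.ModuleList([
            nn.Conv3d(widths[s] * (2 if both else 1), widths[s], 1, rng)
            for s in range(cfg.stages)])
        self.merges = nn.ModuleList([PatchMerging(widths[s], rng)
                                     for s in range(cfg.stages - 1)])
        stem_ch = max(8, cfg.embed_size // 2)
        self.stem = nn.Conv3d(in_ch, stem_ch, 3, rng)
        n_res = cfg.decoder_residual_blocks
        self.up3 = UpBlock(widths[3], widths[2], widths[2], n_res, rng)
        self.up2 = UpBlock(widths[2], widths[1], widths[1], n_res, rng)
        self.up1 = UpBlock(widths[1], widths[0], widths[0], n_res, rng)
        self.up0 = UpBlock(widths[0], stem_ch, stem_ch, n_res, rng)
        self.head = nn.Conv3d(stem_ch, cfg.num_classes, 1, rng)
        self.head.weight.data *= 0.1   # start near-uniform class scores

    def _with_coords(self, x: Tensor) -> Tensor:
        """Append normalised in-window coordinate channels (constant inputs to
        the network, so instance identity can key on position)."""
        if not self.cfg.coord_channels:
            return x
        B = x.shape[0]
        spatial = tuple(x.shape[2:])
        if spatial not in self._coord_cache:
            axes = [np.linspace(-1.0, 1.0, n, dtype=np.float32) for n in spatial]
            grids = np.stack(np.meshgrid(*axes, indexing="ij"))  # (3, D, H, W)
            self._coord_cache[spatial] = grids[None]
        coords = np.broadcast_to(self._coord_cache[spatial],
                                 (B, 3, *spatial)).astype(np.float32)
        return nn.concat([x, Tensor(coords)], axis=1)

    # -- encoder -------------------------------------------------------------
    def encode(self, x: Tensor, _augmented: bool = False) -> list[Tensor]:
        """Feature pyramid: channels-first tensors at 1/2 .. 1/16 resolution."""
        cfg = self.cfg
        cfg.validate_input_shape(x.shape[2:])
        if not _augmented:
            x = self._with_coords(x)
        t = self.patch_embed(x)                     # channels-last
        skips: list[Tensor] = []
        for s in range(cfg.stages):
            branches = []
            if self.swin_stages is not None:
                sw = t
                for block in self.swin_stages[s]:
                    sw = block(sw)
                branches.append(sw.transpose(0, 4, 1, 2, 3))
            if self.smamba_stages is not None:
                branches.append(self.smamba_stages[s](t.transpose(0, 4, 1, 2, 3)))
            if len(branches) == 2:
                fused_in = (nn.concat(branches, axis=1)
                            if cfg.fusion == "concat"
                            else branches[0] + branches[1])
            else:
                fused_in = branches[0]
            fused = self.fuse_proj[s](fused_in)
            skips.append(fused)
            if s < cfg.stages - 1:
                t = self.merges[s](fused.transpose(0, 2, 3, 4, 1))
        return skips

    def swin_encode(self, x: Tensor) -> list[Tensor]:
        """Alias for :meth:`encode`: the per-stage feature pyramid produced
        by the (possibly hybrid) encoder."""
        return self.encode(x)

    # -- full pass -----------------------------------------------------------
    def forward_logits(self, x) -> Tensor:
        x = nn.as_tensor(x)
        self.cfg.validate_input_shape(x.shape[2:])
        xa = self._with_coords(x)
        skips = self.encode(xa, _augmented=True)
        d = skips[3]
        d = self.up3(d, skips[2])
        d = self.up2(d, skips[1])
        d = self.up1(d, skips[0])
        d = self.up0(d, self.stem(xa))
        return self.head(d)

    def forward(self, x) -> Tensor:
        """Per-class scores in [0, 1], shape (B, num_classes, D, H, W)."""
        logits = self.forward_logits(x)
        if self.cfg.head_activation == "sigmoid":
            return logits.sigmoid()
        return nn.softmax(logits, axis=1)

    def predict_scores(self, x: np.ndarray) -> np.ndarray:
        """Inference-mode forward on a (D, H, W) or (B, 1, D, H, W) array."""
        arr = np.asarray(x, dtype=np.float32)
        if arr.ndim == 3:
            arr = arr[None, None]
        with nn.no_grad():
            return self.forward(Tensor(arr)).numpy()

    # -- bookkeeping ---------------------------------------------------------
    def parameter_census(self) -> dict[str, int]:
        groups = {"embed": 0, "swin": 0, "smamba": 0, "fusion": 0,
                  "decoder": 0, "head": 0}
        for name, p in self.named_parameters():
            if name.startswith("patch_embed"):
                groups["embed"] += p.size
            elif name.startswith("swin_stages"):
                groups["swin"] += p.size
            elif name.startswith("smamba_stages"):
                groups["smamba"] += p.size
            elif name.startswith(("fuse_proj", "merges")):
                groups["fusion"] += p.size
            elif name.startswith("head"):
                groups["head"] += p.size
            else:
                groups["decoder"] += p.size
        groups["total"] = sum(groups.values())
        return groups


def build_model(cfg: ModelConfig, seed: int = 0) -> OralSegNet:
    """Construct the network with seed-deterministic initial weights."""
    return OralSegNet(cfg, np.random.default_rng(seed))


# ---------------------------------------------------------------------------
# checkpoints: npz weights + JSON sidecar (self-describing)
# ---------------------------------------------------------------------------

def save_checkpoint(model: OralSegNet, path: str | Path,
                    extra: dict | None = None,
                    scheme_json: str | None = None) -> Path:
    path = Path(path)
    np.savez_compressed(path, **model.state_dict())
    if path.suffix != ".npz":
        path = path.with_suffix(path.suffix + ".npz")
    sidecar = {"model_config": asdict(model.cfg)}
    if scheme_json is not None:
        sidecar["label_scheme"] = json.loads(scheme_json)
    if extra:
        sidecar["extra"] = extra
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return path


def load_checkpoint(path: str | Path) -> tuple[OralSegNet, dict]:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    cfg_dict = dict(sidecar["model_config"])
    for k in ("patch_embed", "attention_window", "smamba_kernels"):
        cfg_dict[k] = tuple(cfg_dict[k])
    cfg = ModelConfig(**cfg_dict)
    model = build_model(cfg, seed=0)
    with np.load(path) as data:
        model.load_state_dict({k: data[k] for k in data.files})
    return model, sidecar
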