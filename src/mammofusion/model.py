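"""The dual-view fusion network.

Two view-specific residual convolutional branches (CC and MLO, independent
weights) each map a 256x256x1 view through three residual blocks with
(32, 64, 128) filters to a 32x32x128 feature map.  The branch outputs are
fused — either by per-element sigmoid gating

    g_v = sigmoid(W_v * F_v + b_v)      (1x1 conv per view)
    F_fused = g_MLO . F_MLO + g_CC . F_CC

or by plain channel concatenation followed by a 1x1 reduction (the ablation
baseline).  The fused map optionally passes through 4-head self-attention
over the 1024 spatial tokens (residual add + layer norm), then a spatial
attention stage (channel-mean/max maps -> 7x7 conv -> sigmoid gate), and a
GAP -> 64-unit ReLU -> dropout(0.5) -> sigmoid head yields the malignancy
probability.

A note on the residual blocks: the block transform halves the spatial size
and changes the channel count, so a literal identity shortcut cannot be
added; the shortcut is a 1x1 stride-2 projection convolution, the standard
down-sampling form of residual learning.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import nn
from .nn import autograd as ag
from .nn.autograd import Tensor

__all__ = ["ModelConfig", "MammoFusionNet", "ResidualBlock", "Branch",
           "GatedFusion", "ConcatFusion", "SpatialAttention",
           "ClassificationHead", "gated_fuse", "batch_from_samples",
           "load_checkpoint", "TABLE_VARIANTS"]

BRANCH_FILTERS = (32, 64, 128)

#: The four ablation variants: (fusion_mode, use_mhsa, use_spatial_attention),
#: ordered from the concatenation baseline to the full model.
TABLE_VARIANTS = (
    ("concat", False, False),
    ("gated", False, False),
    ("gated", True, False),
    ("gated", True, True),
)


@dataclass
class ModelConfig:
    fusion_mode: str = "gated"          # {"gated", "concat"}
    use_mhsa: bool = True
    use_spatial_attention: bool = True
    input_size: int = 256
    dropout: float = 0.5
    heads: int = 4
    mhsa_residual: bool = True          # residual skip around self-attention
    spatial_map_from_fused: bool = False  # compute M_s from F_fused (pre-MHSA)
    gate_spatial_only: bool = False     # 1-channel gates instead of full-channel
    seed: int = 0

    def __post_init__(self):
        if self.fusion_mode not in ("gated", "concat"):
            raise ValueError(f"fusion_mode must be 'gated' or 'concat': {self.fusion_mode!r}")
        if self.input_size % 8:
            raise ValueError("input_size must be divisible by 8 (three 2x poolings)")
        if BRANCH_FILTERS[-1] % self.heads:
            raise ValueError(f"head count {self.heads} must divide {BRANCH_FILTERS[-1]}")


class ResidualBlock(nn.Module):
    """conv3x3 -> batch norm -> ReLU -> maxpool2x2, plus a projected shortcut.

    Output spatial dims are half the input's; channels follow the block plan.
    """

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        super().__init__()
        self.conv = nn.Conv2d(in_ch, out_ch, 3, rng, padding=1)
        self.bn = nn.BatchNorm2d(out_ch)
        self.shortcut = nn.Conv2d(in_ch, out_ch, 1, rng, stride=2, bias=False)

    def forward(self, x: Tensor) -> Tensor:
        main = ag.maxpool2x2(ag.relu(self.bn(self.conv(x))))
        short = self.shortcut(x)
        if main.shape != short.shape:
            raise RuntimeError(
                f"residual shape mismatch: main {main.shape} vs shortcut {short.shape}")
        return main + short


class Branch(nn.Module):
    """One view-specific encoder: three residual blocks, 1->32->64->128 ch."""

    def __init__(self, rng: np.random.Generator, input_size: int):
        super().__init__()
        self.input_size = input_size
        self.block1 = ResidualBlock(1, BRANCH_FILTERS[0], rng)
        self.block2 = ResidualBlock(BRANCH_FILTERS[0], BRANCH_FILTERS[1], rng)
        self.block3 = ResidualBlock(BRANCH_FILTERS[1], BRANCH_FILTERS[2], rng)

    def forward(self, x: Tensor, stages: dict | None = None) -> Tensor:
        n, h, w, c = x.shape
        if (h, w, c) != (self.input_size, self.input_size, 1):
            raise ValueError(
                f"branch expects {self.input_size}x{self.input_size}x1 input, got {h}x{w}x{c}")
        f1 = self.block1(x)
        f2 = self.block2(f1)
        f3 = self.block3(f2)
        if stages is not None:
            stages["block1"], stages["block2"], stages["block3"] = f1, f2, f3
        return f3


class GatedFusion(nn.Module):
    """Per-view sigmoid gates (1x1 conv) weighting each view before summation."""

    def __init__(self, channels: int, rng: np.random.Generator,
                 spatial_only: bool = False):
        super().__init__()
        out_ch = 1 if spatial_only else channels
        self.gate_mlo = nn.Conv2d(channels, out_ch, 1, rng)
        self.gate_cc = nn.Conv2d(channels, out_ch, 1, rng)

    def compute_gates(self, f_mlo: Tensor, f_cc: Tensor) -> tuple[Tensor, Tensor]:
        if f_mlo.shape != f_cc.shape:
            raise ValueError(f"feature shapes differ: {f_mlo.shape} vs {f_cc.shape}")
        return ag.sigmoid(self.gate_mlo(f_mlo)), ag.sigmoid(self.gate_cc(f_cc))

    def forward(self, f_mlo: Tensor, f_cc: Tensor,
                stages: dict | None = None) -> Tensor:
        g_mlo, g_cc = self.compute_gates(f_mlo, f_cc)
        if stages is not None:
            stages["g_mlo"], stages["g_cc"] = g_mlo, g_cc
        return gated_fuse(f_mlo, f_cc, g_mlo, g_cc)


def gated_fuse(f_mlo: Tensor, f_cc: Tensor, g_mlo: Tensor, g_cc: Tensor) -> Tensor:
    """F_fused = g_MLO . F_MLO + g_CC . F_CC (elementwise; gates broadcast
    over channels when spatial-only)."""
    if f_mlo.shape != f_cc.shape:
        raise ValueError(f"feature shapes differ: {f_mlo.shape} vs {f_cc.shape}")
    return ag.add(ag.mul(g_mlo, f_mlo), ag.mul(g_cc, f_cc))


class ConcatFusion(nn.Module):
    """Ablation baseline: channel concat then a 1x1 conv back to 128 channels,
    so every downstream stage sees the same shape as under gated fusion."""

    def __init__(self, channels: int, rng: np.random.Generator):
        super().__init__()
        self.reduce = nn.Conv2d(2 * channels, channels, 1, rng)

    def forward(self, f_mlo: Tensor, f_cc: Tensor,
                stages: dict | None = None) -> Tensor:
        if f_mlo.shape != f_cc.shape:
            raise ValueError(f"feature shapes differ: {f_mlo.shape} vs {f_cc.shape}")
        return self.reduce(ag.concat([f_mlo, f_cc], axis=-1))


class SpatialAttention(nn.Module):
    """M_s = sigmoid(conv7x7([mean_c(F); max_c(F)])); refined = F . M_s."""

    def __init__(self, rng: np.random.Generator):
        super().__init__()
        self.conv = nn.Conv2d(2, 1, 7, rng, padding=3)

    def attention_map(self, f: Tensor) -> Tensor:
        avg = ag.tmean(f, axis=3, keepdims=True)
        mx = ag.amax(f, axis=3, keepdims=True)
        return ag.sigmoid(self.conv(ag.concat([avg, mx], axis=-1)))

    def forward(self, f: Tensor, map_source: Tensor | None = None,
                stages: dict | None = None) -> Tensor:
        m_s = self.attention_map(f if map_source is None else map_source)
        if stages is not None:
            stages["m_s"] = m_s
        return ag.mul(f, m_s)


class ClassificationHead(nn.Module):
    """GAP -> dense(128->64) + ReLU -> dropout(0.5) -> dense(64->1) + sigmoid."""

    def __init__(self, channels: int, dropout: float, rng: np.random.Generator):
        super().__init__()
        self.fc1 = nn.Dense(channels, 64, rng)
        self.drop = nn.Dropout(dropout, rng)
        self.fc2 = nn.Dense(64, 1, rng)

    def logit(self, f: Tensor, stages: dict | None = None) -> Tensor:
        gap = nn.global_average_pool(f)
        hidden = ag.relu(self.fc1(gap))
        logit = self.fc2(self.drop(hidden))
        if stages is not None:
            stages["gap"], stages["hidden"] = gap, hidden
        return logit

    def forward(self, f: Tensor, stages: dict | None = None) -> Tensor:
        return ag.sigmoid(self.logit(f, stages))


class MammoFusionNet(nn.Module):
    """The full dual-branch fusion classifier (see module docstring).

    ``forward`` takes the two view batches as (N, H, W) arrays in [0, 1] and
    returns the malignancy probability tensor of shape (N, 1).  Passing
    ``capture`` (a dict) records every named intermediate stage, which the
    Grad-CAM module and the shape-ladder summary rely on.
    """

    def __init__(self, config: ModelConfig | None = None):
        super().__init__()
        self.config = config or ModelConfig()
        c = self.config
        rng = np.random.default_rng(c.seed)
        channels = BRANCH_FILTERS[-1]
        self.branch_mlo = Branch(rng, c.input_size)
        self.branch_cc = Branch(rng, c.input_size)
        if c.fusion_mode == "gated":
            self.fusion = GatedFusion(channels, rng, spatial_only=c.gate_spatial_only)
        else:
            self.fusion = ConcatFusion(channels, rng)
        if c.use_mhsa:
            self.mhsa = nn.MultiHeadSelfAttention(channels, c.heads, rng)
            self.ln = nn.LayerNorm(channels)
        if c.use_spatial_attention:
            self.spatial = SpatialAttention(rng)
        self.head = ClassificationHead(channels, c.dropout, rng)

    # -- helpers ------------------------------------------------------------
    @staticmethod
    def _as_nhwc(x) -> Tensor:
        if isinstance(x, Tensor):
            return x
        arr = np.asarray(x, dtype=np.float32)
        if arr.ndim == 2:
            arr = arr[None]
        if arr.ndim == 3:
            arr = arr[..., None]
        return Tensor(arr)

    def features(self, cc, mlo, capture: dict | None = None) -> Tensor:
        """Everything up to (and excluding) the classification head."""
        c = self.config
        cc, mlo = self._as_nhwc(cc), self._as_nhwc(mlo)
        f_cc = self.branch_cc(cc)
        f_mlo = self.branch_mlo(mlo)
        fused = self.fusion(f_mlo, f_cc, stages=capture)
        x = fused
        if c.use_mhsa:
            n, h, w, ch = x.shape
            tokens = ag.reshape(x, (n, h * w, ch))
            attn = self.mhsa(tokens)
            if c.mhsa_residual:
                attn = attn + tokens
            x = ag.reshape(self.ln(attn), (n, h, w, ch))
        if capture is not None:
            capture.update({"f_cc": f_cc, "f_mlo": f_mlo, "f_fused": fused,
                            "f_attn": x})
        if c.use_spatial_attention:
            map_source = fused if c.spatial_map_from_fused else None
            x = self.spatial(x, map_source=map_source, stages=capture)
        if capture is not None:
            capture["f_refined"] = x
        return x

    def forward_logit(self, cc, mlo, capture: dict | None = None) -> Tensor:
        return self.head.logit(self.features(cc, mlo, capture), stages=capture)

    def forward(self, cc, mlo, capture: dict | None = None) -> Tensor:
        prob = ag.sigmoid(self.forward_logit(cc, mlo, capture))
        if capture is not None:
            capture["prob"] = prob
        return prob

    # -- introspection & persistence ----------------------------------------
    def summary(self) -> dict:
        """Per-stage output shapes from a single dummy forward pass."""
        s = self.config.input_size
        capture: dict = {}
        stages: dict = {}
        was_training = self.training
        self.eval()
        zeros = np.zeros((1, s, s), dtype=np.float32)
        x = self._as_nhwc(zeros)
        self.branch_cc(x, stages=stages)
        self.forward(zeros, zeros, capture=capture)
        self.train(was_training)
        shapes = {f"branch.{k}": list(v.shape[1:]) for k, v in stages.items()}
        shapes.update({k: list(v.shape[1:]) for k, v in capture.items()})
        shapes["input"] = [s, s, 1]
        n_params = int(sum(p.data.size for p in self.parameters()))
        return {"config": asdict(self.config), "stages": shapes,
                "n_parameters": n_params}

    def save(self, path: str | Path) -> None:
        state = self.state_dict()
        np.savez_compressed(path, __config__=json.dumps(asdict(self.config)), **state)

    @property
    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))


def load_checkpoint(path: str | Path) -> MammoFusionNet:
    with np.load(path, allow_pickle=False) as archive:
        config = ModelConfig(**json.loads(str(archive["__config__"])))
        model = MammoFusionNet(config)
        state = {k: archive[k] for k in archive.files if k != "__config__"}
    model.load_state_dict(state)
    return model


def batch_from_samples(samples) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack a list of paired samples into (cc, mlo, labels) arrays."""
    cc = np.stack([s.cc for s in samples]).astype(np.float32)
    mlo = np.stack([s.mlo for s in samples]).astype(np.float32)
    y = np.array([s.label for s in samples], dtype=np.float32)
    return cc, mlo, y
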