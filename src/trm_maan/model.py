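"""The TRM-MAAN network.

Architecture
------------
Two per-modality feature extractors ``E`` (1-D temporal convolution projecting
the multichannel window to a common dimension ``D``, sinusoidal positional
encoding, then a stack of self-attention blocks), a *shared* convolutional
fusion trunk ``F`` (a custom conv/batch-norm/ReLU block, a 2x2 max pool, and
three ConvNeXt-style depthwise-conv/layer-norm/GELU blocks, flattened), a
modality classifier ``M`` fed through a gradient-reversal layer, and a
workload classifier ``C`` fed the concatenation of the two fused features.

``M`` exists only to drive the adversarial min-max game during training: it
tries to tell EEG-derived fused features from EMG-derived ones, while the
reversed gradients push the shared trunk toward modality-invariant features.
At inference only ``E``, ``F`` and ``C`` run.

Ablation variants (config-selected, mirroring the method's own ablations):

- ``trm_maan`` — the full model;
- ``trm``      — no adversary (no ``M``/GRL), plain concatenation fusion;
- ``maan``     — no Transformer: conv features go straight into the trunk;
- ``uni_eeg`` / ``uni_emg`` — one branch only, no adversary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np

from .autodiff import Tensor, concat
from . import nn

__all__ = [
    "ModelConfig", "VARIANTS", "positional_encoding", "MultiHeadSelfAttention",
    "TransformerBlock", "FusionTrunk", "ModalClassifier", "WorkloadClassifier",
    "TRMMAAN", "build_model", "conv_output_length",
]

VARIANTS = ("trm_maan", "trm", "maan", "uni_eeg", "uni_emg")


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    ``D`` is the common feature dimension both modality branches are projected
    to; ``k_eeg``/``k_emg`` are the temporal kernel sizes of the projection
    convs; ``n_heads``/``n_layers`` shape the attention stack;
    ``n_fusion_blocks`` counts the ConvNeXt-style blocks after the first
    custom block of the trunk. ``D_Q = D_K`` and ``D_V`` default to
    ``D / n_heads`` so the head concatenation reproduces dimension ``D``.
    """

    D: int = 40
    k_eeg: int = 3
    k_emg: int = 3
    n_heads: int = 4
    n_layers: int = 2
    n_fusion_blocks: int = 3
    D_Q: int | None = None
    D_K: int | None = None
    D_V: int | None = None
    n_classes: int = 3
    n_modalities: int = 2
    grl_lambda: float = 1.0
    trunk_channels: int = 64
    fc_hidden: int = 128
    ffn_hidden: int | None = None
    proj_stride: int = 1
    standard_transformer_block: bool = False
    pool_mode: str = "2d"  # "2d": pool time x feature; "1d": pool time only
    variant: str = "trm_maan"

    def __post_init__(self):
        if self.D_Q is None:
            self.D_Q = self.D // self.n_heads
        if self.D_K is None:
            self.D_K = self.D_Q
        if self.D_V is None:
            self.D_V = self.D // self.n_heads
        if self.ffn_hidden is None:
            self.ffn_hidden = 2 * self.D
        self.validate()

    def validate(self) -> None:
        if self.D % self.n_heads != 0:
            raise ValueError("D must be divisible by n_heads")
        if self.D_K != self.D_Q:
            raise ValueError("D_K must equal D_Q")
        if self.n_heads * self.D_V != self.D:
            raise ValueError("n_heads * D_V must equal D (head concatenation)")
        if self.n_classes < 2 or self.n_modalities < 2:
            raise ValueError("need >= 2 classes and >= 2 modalities")
        if self.k_eeg % 2 == 0 or self.k_emg % 2 == 0:
            raise ValueError("projection kernels must be odd")
        if self.grl_lambda < 0:
            raise ValueError("grl_lambda must be >= 0")
        if self.pool_mode not in ("2d", "1d"):
            raise ValueError("pool_mode must be '2d' or '1d'")
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**d)


def conv_output_length(L: int, kernel: int, stride: int) -> int:
    """Output length of the same-padded projection conv (L for stride 1)."""
    half = kernel // 2
    return (L + 2 * half - kernel) // stride + 1


def positional_encoding(L: int, D: int) -> np.ndarray:
    """Sinusoidal position encoding: ``PE[pos, 2k] = sin(pos / 10000^(2k/D))``
    and ``PE[pos, 2k+1] = cos`` of the same argument, 0-based ``pos`` and ``k``.
    """
    if D % 2 != 0:
        raise ValueError("feature dimension D must be even")
    if L < 1:
        raise ValueError("sequence length must be positive")
    pos = np.arange(L, dtype=np.float64)[:, None]
    k = np.arange(D // 2, dtype=np.float64)[None, :]
    angle = pos / np.power(10000.0, 2.0 * k / D)
    pe = np.empty((L, D), dtype=np.float64)
    pe[:, 0::2] = np.sin(angle)
    pe[:, 1::2] = np.cos(angle)
    return pe


class MultiHeadSelfAttention(nn.Module):
    """Scaled dot-product self-attention with per-head Q/K/V projections.

    Heads are concatenated directly (no output projection). The attention
    matrix of the most recent forward pass is kept on ``last_attention`` for
    inspection, and ``call_count`` counts forward invocations.
    """

    call_count = 0  # class-wide instrumentation

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        D, H = cfg.D, cfg.n_heads
        self.W_Q = nn.Parameter(rng.normal(0, 1 / math.sqrt(D), (D, H * cfg.D_Q)))
        self.W_K = nn.Parameter(rng.normal(0, 1 / math.sqrt(D), (D, H * cfg.D_K)))
        self.W_V = nn.Parameter(rng.normal(0, 1 / math.sqrt(D), (D, H * cfg.D_V)))
        self.n_heads = H
        self.D_K = cfg.D_K
        self.D_V = cfg.D_V
        self.last_attention: np.ndarray | None = None

    def _split(self, x: Tensor, dh: int) -> Tensor:
        B, L, _ = x.shape
        return x.reshape(B, L, self.n_heads, dh).transpose(0, 2, 1, 3)

    def forward(self, x: Tensor) -> Tensor:
        MultiHeadSelfAttention.call_count += 1
        B, L, D = x.shape
        q = self._split(x @ self.W_Q, self.D_K)   # [B, H, L, D_K]
        k = self._split(x @ self.W_K, self.D_K)
        v = self._split(x @ self.W_V, self.D_V)
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / math.sqrt(self.D_K))
        attn = nn.softmax(scores, axis=-1)        # rows sum to 1
        self.last_attention = attn.data
        out = attn @ v                            # [B, H, L, D_V]
        return out.transpose(0, 2, 1, 3).reshape(B, L, self.n_heads * self.D_V)


class FeedForward(nn.Module):
    def __init__(self, D: int, hidden: int, rng: np.random.Generator):
        super().__init__()
        self.fc1 = nn.Linear(D, hidden, rng)
        self.fc2 = nn.Linear(hidden, D, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).relu())


class TransformerBlock(nn.Module):
    """One encoder block.

    Default form follows the method's written definition literally:
    ``Z = LayerNorm(A + FFN(A))`` with ``A`` the multi-head attention output —
    a single residual wrapped around the feed-forward sublayer only. Setting
    ``standard_transformer_block`` restores the conventional two-residual
    post-norm block.
    """

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        self.attn = MultiHeadSelfAttention(cfg, rng)
        self.ffn = FeedForward(cfg.D, cfg.ffn_hidden, rng)
        self.norm = nn.LayerNorm(cfg.D)
        self.standard = cfg.standard_transformer_block
        if self.standard:
            self.norm_attn = nn.LayerNorm(cfg.D)

    def forward(self, x: Tensor) -> Tensor:
        a = self.attn(x)
        if self.standard:
            h = self.norm_attn(x + a)
            return self.norm(h + self.ffn(h))
        return self.norm(a + self.ffn(a))


class FusionTrunk(nn.Module):
    """Shared fusion stack F.

    Treats the ``L x D`` feature sequence as a one-channel 2-D map; applies a
    conv(k=3)/batch-norm/ReLU block, a 2x2 stride-2 max pool, then
    ``n_fusion_blocks`` ConvNeXt-style blocks (depthwise conv k=7, layer norm
    over channels, GELU), and flattens.
    """

    def __init__(self, cfg: ModelConfig, seq_len: int, rng: np.random.Generator):
        super().__init__()
        C = cfg.trunk_channels
        self.conv1 = nn.Conv2d(1, C, 3, rng)
        self.bn = nn.BatchNorm2d(C)
        if cfg.pool_mode == "2d":
            self.pool = nn.MaxPool2d(2)
            Hp, Wp = seq_len // 2, cfg.D // 2
        else:
            self.pool = nn.MaxPool2d((2, 1))
            Hp, Wp = seq_len // 2, cfg.D
        if Hp < 1 or Wp < 1:
            raise ValueError("feature map smaller than the trunk's receptive field")
        self.blocks = nn.ModuleList(
            [nn.DepthwiseConv2d(C, 7, rng) for _ in range(cfg.n_fusion_blocks)])
        self.norms = nn.ModuleList(
            [nn.LayerNorm(C) for _ in range(cfg.n_fusion_blocks)])
        self.out_dim = C * Hp * Wp

    def forward(self, z: Tensor) -> Tensor:
        B, L, D = z.shape
        x = z.reshape(B, 1, L, D)
        x = self.bn(self.conv1(x)).relu()
        x = self.pool(x)
        for conv, norm in zip(self.blocks, self.norms):
            x = conv(x)
            # ConvNeXt normalizes over channels at each spatial position
            x = norm(x.transpose(0, 2, 3, 1)).transpose(0, 3, 1, 2)
            x = x.gelu()
        return x.reshape(B, self.out_dim)


class ModalClassifier(nn.Module):
    """Two FC layers predicting the modality (EEG vs EMG) of a fused feature."""

    def __init__(self, in_dim: int, hidden: int, n_modalities: int,
                 rng: np.random.Generator):
        super().__init__()
        self.fc1 = nn.Linear(in_dim, hidden, rng)
        self.fc2 = nn.Linear(hidden, n_modalities, rng)

    def logits(self, f: Tensor) -> Tensor:
        return self.fc2(self.fc1(f).relu())

    def forward(self, f: Tensor) -> Tensor:
        return nn.softmax(self.logits(f), axis=-1)


class WorkloadClassifier(nn.Module):
    """Two FC layers mapping concatenated fused features to class probabilities."""

    def __init__(self, in_dim: int, hidden: int, n_classes: int,
                 rng: np.random.Generator):
        super().__init__()
        self.fc1 = nn.Linear(in_dim, hidden, rng)
        self.fc2 = nn.Linear(hidden, n_classes, rng)

    def logits(self, f: Tensor) -> Tensor:
        return self.fc2(self.fc1(f).relu())

    def forward(self, f: Tensor) -> Tensor:
        return nn.softmax(self.logits(f), axis=-1)


class TRMMAAN(nn.Module):
    """Full network; see module docstring for the variants."""

    def __init__(self, cfg: ModelConfig, n_channels: int, window_len: int,
                 rng: np.random.Generator | None = None):
        super().__init__()
        cfg.validate()
        rng = rng or np.random.default_rng()
        self.cfg = cfg
        self.n_channels = n_channels
        self.window_len = window_len
        self.seq_len = conv_output_length(window_len, cfg.k_eeg, cfg.proj_stride)
        seq_len_emg = conv_output_length(window_len, cfg.k_emg, cfg.proj_stride)
        if seq_len_emg != self.seq_len:
            raise ValueError("EEG and EMG projections must yield equal lengths")

        self.uses_eeg = cfg.variant != "uni_emg"
        self.uses_emg = cfg.variant != "uni_eeg"
        self.uses_transformer = cfg.variant != "maan"
        self.uses_adversary = cfg.variant in ("trm_maan", "maan")

        if self.uses_eeg:
            self.eeg_proj = nn.Conv1d(n_channels, cfg.D, cfg.k_eeg,
                                      cfg.proj_stride, rng)
            if self.uses_transformer:
                self.eeg_blocks = nn.ModuleList(
                    [TransformerBlock(cfg, rng) for _ in range(cfg.n_layers)])
        if self.uses_emg:
            self.emg_proj = nn.Conv1d(n_channels, cfg.D, cfg.k_emg,
                                      cfg.proj_stride, rng)
            if self.uses_transformer:
                self.emg_blocks = nn.ModuleList(
                    [TransformerBlock(cfg, rng) for _ in range(cfg.n_layers)])

        self.pe = positional_encoding(self.seq_len, cfg.D)
        self.trunk = FusionTrunk(cfg, self.seq_len, rng)  # SHARED across branches

        n_branches = int(self.uses_eeg) + int(self.uses_emg)
        self.workload_head = WorkloadClassifier(
            n_branches * self.trunk.out_dim, cfg.fc_hidden, cfg.n_classes, rng)
        if self.uses_adversary:
            self.modal_head = ModalClassifier(
                self.trunk.out_dim, cfg.fc_hidden, cfg.n_modalities, rng)

    # -- branch computations -------------------------------------------------

    def _extract(self, x: Tensor, modality: str) -> Tensor:
        """E: conv projection (+ positional encoding + attention stack)."""
        proj = self.eeg_proj if modality == "eeg" else self.emg_proj
        h = proj(x).transpose(0, 2, 1)            # [B, L, D]
        if self.uses_transformer:
            h = h + Tensor(self.pe)
            blocks = self.eeg_blocks if modality == "eeg" else self.emg_blocks
            for block in blocks:
                h = block(h)
        return h

    def fused_features(self, eeg: Tensor | None, emg: Tensor | None
                       ) -> dict[str, Tensor]:
        """Both branches' sequences pass through the shared trunk as one
        joint batch, so batch-norm statistics couple the modalities."""
        seqs: list[tuple[str, Tensor]] = []
        if self.uses_eeg:
            if eeg is None:
                raise ValueError("this variant requires the EEG branch input")
            seqs.append(("eeg", self._extract(eeg, "eeg")))
        if self.uses_emg:
            if emg is None:
                raise ValueError("this variant requires the EMG branch input")
            seqs.append(("emg", self._extract(emg, "emg")))
        if len(seqs) == 1:
            return {seqs[0][0]: self.trunk(seqs[0][1])}
        fused = self.trunk(concat([z for _, z in seqs], axis=0))
        n = seqs[0][1].shape[0]
        return {name: fused[i * n:(i + 1) * n]
                for i, (name, _) in enumerate(seqs)}

    def forward(self, eeg: Tensor | None, emg: Tensor | None) -> dict[str, Tensor]:
        """Returns workload logits plus (in training variants with an
        adversary) per-modality modal logits computed behind the GRL."""
        fused = self.fused_features(eeg, emg)
        feats = [fused[m] for m in ("eeg", "emg") if m in fused]
        cat = feats[0] if len(feats) == 1 else concat(feats, axis=1)
        result = {"workload_logits": self.workload_head.logits(cat),
                  "fused": fused}
        if self.uses_adversary:
            for m, f in fused.items():
                rev = nn.gradient_reversal(f, self.cfg.grl_lambda)
                result[f"modal_logits_{m}"] = self.modal_head.logits(rev)
        return result

    def predict_proba(self, eeg: np.ndarray, emg: np.ndarray) -> np.ndarray:
        """Workload class probabilities for a batch of raw windows."""
        from .autodiff import no_grad
        self.eval()
        with no_grad():
            out = self.forward(
                Tensor(eeg) if self.uses_eeg else None,
                Tensor(emg) if self.uses_emg else None)
            probs = nn.softmax(out["workload_logits"], axis=-1).data
        self.train()
        return probs

    def describe(self) -> str:
        """Layer-by-layer shape propagation summary."""
        cfg = self.cfg
        lines = [
            f"variant: {cfg.variant}",
            f"input window: [{self.n_channels} x {self.window_len}] per modality",
            f"conv projection -> [{self.seq_len} x {cfg.D}] "
            f"(kernel eeg={cfg.k_eeg} emg={cfg.k_emg}, stride={cfg.proj_stride})",
        ]
        if self.uses_transformer:
            lines.append(
                f"positional encoding + {cfg.n_layers} transformer block(s), "
                f"{cfg.n_heads} heads (D_K={cfg.D_K}, D_V={cfg.D_V})")
        lines.append(
            f"shared trunk: conv3/BN/ReLU -> maxpool ({cfg.pool_mode}) -> "
            f"{cfg.n_fusion_blocks} ConvNeXt-style block(s) -> "
            f"flatten [{self.trunk.out_dim}]")
        n_branches = int(self.uses_eeg) + int(self.uses_emg)
        lines.append(
            f"workload classifier: [{n_branches * self.trunk.out_dim}] -> "
            f"[{cfg.fc_hidden}] -> [{cfg.n_classes}]")
        if self.uses_adversary:
            lines.append(
                f"modal classifier (GRL lambda={cfg.grl_lambda}): "
                f"[{self.trunk.out_dim}] -> [{cfg.fc_hidden}] -> [{cfg.n_modalities}]")
        n_params = sum(p.size for p in self.parameters())
        lines.append(f"total parameters: {n_params}")
        return "\n".join(lines)


def build_model(cfg: ModelConfig, n_channels: int, window_len: int,
                seed: int | None = None) -> TRMMAAN:
    """Construct a TRM-MAAN model with seeded initialization."""
    return TRMMAAN(cfg, n_channels, window_len, np.random.default_rng(seed))
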