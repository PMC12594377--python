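"""Temporal-spatial kinetics models: the student, the teacher and ablations.

The **student** consumes only the video modalities (joint-center position
plus differenced velocity and acceleration, 44 channels each).  Each
modality is batch-normalized and encoded twice: temporally by a stacked
bidirectional LSTM and spatially by an attention-weighted graph convolution
over the 11-joint skeleton.  A gated network forms a convex combination of
the two encoder streams per feature; a multi-fusion module (MFM) then mixes
the modality blocks and fully connected layers map every frame to the five
kinetics targets (KAM, KFM and 3-D GRF).

The **teacher** additionally sees the privileged IMU modalities (8 sensors
× 3-axis acceleration and angular velocity) through three Bi-LSTM encoders,
the same MFM, and a single linear output layer.

``build_variant`` exposes the ablation grid used to justify each component:
eight video-only student variants and four IMU(+video) teacher variants.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .autodiff import Tensor, concat
from .exceptions import ConfigError, DimensionError
from .nn import BatchNorm, BiLSTM, Dropout, Linear, Module
from .synthetic import SkeletonGraph

__all__ = [
    "ModelConfig",
    "NodeAttention",
    "GCNLayer",
    "GCNBranch",
    "GatedFusion",
    "MultiFusionModule",
    "KineticsModel",
    "build_variant",
    "build_student",
    "build_teacher",
    "STUDENT_VARIANTS",
    "TEACHER_VARIANTS",
]

MFM_SUBMODULES = ("LWF", "WFF", "MHAF", "TMF")


@dataclass
class ModelConfig:
    """Hyperparameters shared by every variant."""

    hidden_dim: int = 64          # C, per-modality encoder width
    bilstm_layers: int = 2
    dropout: float = 0.2
    gcn_node_out: int = 16        # M', node-feature width after the GCN
    fusion: str = "mfm_gate"      # concat | gate | mfm_gate
    mfm_submodules: tuple[str, ...] = MFM_SUBMODULES
    projection_dim: int = 128     # feature-alignment width
    share_gcn_weights: bool = False
    attention_heads: int = 4
    window: int = 50              # ΔT
    head_hidden: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hidden_dim <= 0 or self.hidden_dim % 2:
            raise ConfigError("hidden_dim must be positive and even")
        if not 0.0 <= self.dropout < 1.0:
            raise ConfigError("dropout must be in [0, 1)")
        if self.fusion == "mfm_gate" and not self.mfm_submodules:
            raise ConfigError("mfm_gate fusion requires a nonempty submodule set")
        for s in self.mfm_submodules:
            if s not in MFM_SUBMODULES:
                raise ConfigError(f"unknown MFM submodule {s!r}")


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=float))


class NodeAttention(Module):
    """Softmax attention over the joint-node axis.

    Scores each node with a linear map of its own features and normalizes
    over the node axis, so the weights sum to 1 per frame; the attended
    features are the weights broadcast-multiplied onto the node features.
    """

    def __init__(self, node_features: int, n_nodes: int, rng: np.random.Generator):
        super().__init__()
        self.n_nodes = n_nodes
        self.score = Linear(node_features, 1, rng)

    def __call__(self, v_nodes: Tensor) -> tuple[Tensor, Tensor]:
        if v_nodes.shape[1] != self.n_nodes:
            raise DimensionError(
                f"expected {self.n_nodes} nodes, got {v_nodes.shape[1]}"
            )
        weights = self.score(v_nodes).softmax(axis=1)   # [BT, nodes, 1]
        return weights, weights * v_nodes


class GCNLayer(Module):
    """One graph convolution: ``ReLU(A V W + b)`` on a fixed adjacency."""

    def __init__(self, node_in: int, node_out: int, graph: SkeletonGraph,
                 rng: np.random.Generator):
        super().__init__()
        self.adjacency = graph.adjacency
        self.n_nodes = graph.n_nodes
        self.lin = Linear(node_in, node_out, rng)

    def __call__(self, v: Tensor) -> Tensor:
        if v.shape[1] != self.n_nodes:
            raise DimensionError(
                f"adjacency is {self.n_nodes}x{self.n_nodes} but input has "
                f"{v.shape[1]} nodes"
            )
        return (Tensor(self.adjacency) @ self.lin(v)).relu()


class GCNBranch(Module):
    """Attention (optional) -> GCN -> linear projection back to width C."""

    def __init__(self, node_features: int, cfg: ModelConfig, graph: SkeletonGraph,
                 rng: np.random.Generator, use_attention: bool):
        super().__init__()
        self.use_attention = use_attention
        self.n_nodes = graph.n_nodes
        self.node_features = node_features
        if use_attention:
            self.attention = NodeAttention(node_features, graph.n_nodes, rng)
        self.gcn = GCNLayer(node_features, cfg.gcn_node_out, graph, rng)
        self.project = Linear(graph.n_nodes * cfg.gcn_node_out,
                              cfg.hidden_dim, rng)
        self.last_attention: np.ndarray | None = None

    def __call__(self, x: Tensor) -> Tensor:
        B, T, F = x.shape
        v = x.reshape(B * T, self.n_nodes, self.node_features)
        if self.use_attention:
            weights, v = self.attention(v)
            self.last_attention = weights.data
        g = self.gcn(v)
        flat = g.reshape(B * T, self.n_nodes * g.shape[-1])
        return self.project(flat).reshape(B, T, -1)


class GatedFusion(Module):
    """Convex combination of two equally shaped feature streams.

    ``gate = sigmoid(FC([x_a, x_b]))``; the output is
    ``gate ⊙ x_a + (1 - gate) ⊙ x_b``, so equal inputs pass through
    unchanged for any gate value.
    """

    def __init__(self, width: int, rng: np.random.Generator):
        super().__init__()
        self.fc = Linear(2 * width, width, rng)
        self.last_gate: np.ndarray | None = None

    def __call__(self, x_a: Tensor, x_b: Tensor) -> Tensor:
        if x_a.shape != x_b.shape:
            raise DimensionError("gated fusion requires equal shapes")
        gate = self.fc(concat([x_a, x_b], axis=-1)).sigmoid()
        self.last_gate = gate.data
        return gate * x_a + (1.0 - gate) * x_b


# ---------------------------------------------------------------------------
# multi-fusion module
# ---------------------------------------------------------------------------

class _LWF(Module):
    """Learnable weighted fusion: softmax-normalized scalar weight per
    modality block, rescaled by the block count to preserve magnitude."""

    def __init__(self, n_blocks: int, block: int, rng: np.random.Generator):
        super().__init__()
        from .autodiff import Parameter
        self.n_blocks, self.block = n_blocks, block
        self.weights = Parameter(np.zeros(n_blocks))

    def __call__(self, x: Tensor) -> Tensor:
        w = self.weights.softmax(axis=0) * float(self.n_blocks)
        blocks = [x[..., i * self.block:(i + 1) * self.block] * w[i]
                  for i in range(self.n_blocks)]
        return concat(blocks, axis=-1)


class _WFF(Module):
    """Weighted feature fusion: per-channel sigmoid gate on the features."""

    def __init__(self, width: int, rng: np.random.Generator):
        super().__init__()
        self.fc = Linear(width, width, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc(x).sigmoid() * x


class _MHAF(Module):
    """Multi-head attention fusion across the modality blocks.

    Each frame's feature vector is viewed as ``n_blocks`` tokens of width
    ``block``; scaled dot-product attention with several heads lets every
    modality attend to the others, and a final linear map mixes the result.
    """

    def __init__(self, n_blocks: int, block: int, heads: int,
                 rng: np.random.Generator):
        super().__init__()
        if block % heads:
            heads = 1
        self.n_blocks, self.block, self.heads = n_blocks, block, heads
        self.q = Linear(block, block, rng)
        self.k = Linear(block, block, rng)
        self.v = Linear(block, block, rng)
        self.out = Linear(block, block, rng)

    def __call__(self, x: Tensor) -> Tensor:
        B, T, W = x.shape
        nb, bl, h = self.n_blocks, self.block, self.heads
        d = bl // h
        tokens = x.reshape(B, T, nb, bl)
        q = self.q(tokens).reshape(B, T, nb, h, d).swapaxes(2, 3)
        k = self.k(tokens).reshape(B, T, nb, h, d).swapaxes(2, 3)
        v = self.v(tokens).reshape(B, T, nb, h, d).swapaxes(2, 3)
        scores = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(d))
        attended = scores.softmax(axis=-1) @ v          # [B,T,h,nb,d]
        merged = attended.swapaxes(2, 3).reshape(B, T, nb, bl)
        return self.out(merged).reshape(B, T, W)


class _TMF(Module):
    """Temporal multi-modal fusion: each frame is fused with the window's
    temporal context (the time-averaged features) through a two-layer map."""

    def __init__(self, width: int, rng: np.random.Generator):
        super().__init__()
        self.fc1 = Linear(2 * width, width, rng)
        self.fc2 = Linear(width, width, rng)

    def __call__(self, x: Tensor) -> Tensor:
        ctx = x.mean(axis=1, keepdims=True)
        ctx_tiled = ctx + x * 0.0   # broadcast the context over frames
        return self.fc2(self.fc1(concat([x, ctx_tiled], axis=-1)).relu())


class MultiFusionModule(Module):
    """Composite of the LWF / WFF / MHAF / TMF fusion submodules.

    Any subset is selectable for ablations; the output of the selected
    submodules is averaged and added residually to the input, so the output
    width always equals the input width and the head never changes shape.
    An empty subset is a configuration error (use plain fusion instead).
    """

    def __init__(self, width: int, n_blocks: int, submodules: tuple[str, ...],
                 cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        if not submodules:
            raise ConfigError("MFM requires at least one submodule")
        if width % n_blocks:
            raise DimensionError("feature width must split into modality blocks")
        block = width // n_blocks
        self.submodules: list[Module] = []
        self.names = tuple(submodules)
        for name in submodules:
            if name == "LWF":
                self.submodules.append(_LWF(n_blocks, block, rng))
            elif name == "WFF":
                self.submodules.append(_WFF(width, rng))
            elif name == "MHAF":
                self.submodules.append(_MHAF(n_blocks, block,
                                             cfg.attention_heads, rng))
            elif name == "TMF":
                self.submodules.append(_TMF(width, rng))
            else:
                raise ConfigError(f"unknown MFM submodule {name!r}")

    def __call__(self, x: Tensor) -> Tensor:
        acc = None
        for sub in self.submodules:
            y = sub(x)
            acc = y if acc is None else acc + y
        return x + acc * (1.0 / len(self.submodules))


# ---------------------------------------------------------------------------
# variant descriptors and the unified model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VariantSpec:
    name: str
    inputs: tuple[tuple[str, int], ...]  # (batch key, channel width)
    early_fusion: bool = False
    use_bilstm: bool = True
    use_gcn: bool = False
    use_attention: bool = False
    branch_combine: str = "concat"       # concat | add | gate (both-encoder)
    use_mfm: bool = False
    head: str = "mlp"                    # mlp | linear


_VIDEO = (("jcv", 44), ("jca", 44), ("jcp", 44))
_IMU_VIDEO = (("acc", 24), ("gyr", 24), ("jcp", 44))

STUDENT_VARIANTS: dict[str, VariantSpec] = {
    "joint_pos_bilstm": VariantSpec(
        "joint_pos_bilstm", (("jcp", 44),)),
    "aug_early_fusion_bilstm": VariantSpec(
        "aug_early_fusion_bilstm", _VIDEO, early_fusion=True),
    "aug_concat_bilstm": VariantSpec(
        "aug_concat_bilstm", _VIDEO),
    "aug_concat_gcn": VariantSpec(
        "aug_concat_gcn", _VIDEO, use_bilstm=False, use_gcn=True),
    "aug_concat_attngcn": VariantSpec(
        "aug_concat_attngcn", _VIDEO, use_bilstm=False, use_gcn=True,
        use_attention=True),
    "aug_concat_bilstm_attngcn": VariantSpec(
        "aug_concat_bilstm_attngcn", _VIDEO, use_gcn=True, use_attention=True,
        branch_combine="add"),
    "aug_gate_bilstm_attngcn": VariantSpec(
        "aug_gate_bilstm_attngcn", _VIDEO, use_gcn=True, use_attention=True,
        branch_combine="gate"),
    "aug_mfm_gate_bilstm_attngcn": VariantSpec(
        "aug_mfm_gate_bilstm_attngcn", _VIDEO, use_gcn=True,
        use_attention=True, branch_combine="gate", use_mfm=True),
}

TEACHER_VARIANTS: dict[str, VariantSpec] = {
    "imu_bilstm": VariantSpec(
        "imu_bilstm", (("acc", 24), ("gyr", 24)), early_fusion=True,
        head="linear"),
    "imu_jcp_early_fusion": VariantSpec(
        "imu_jcp_early_fusion", _IMU_VIDEO, early_fusion=True, head="linear"),
    "imu_jcp_concat": VariantSpec(
        "imu_jcp_concat", _IMU_VIDEO, head="linear"),
    "imu_jcp_mfm": VariantSpec(
        "imu_jcp_mfm", _IMU_VIDEO, use_mfm=True, head="linear"),
}

ALL_VARIANTS = {**STUDENT_VARIANTS, **TEACHER_VARIANTS}

N_OUTPUTS = 5


class KineticsModel(Module):
    """A configurable kinetics estimator covering every ablation variant.

    ``forward`` takes a batch dict mapping modality keys (``jcp``, ``jcv``,
    ``jca``, ``acc``, ``gyr``) to ``[B, ΔT, channels]`` arrays and returns
    per-frame predictions ``[B, ΔT, 5]``.  ``encoder_forward`` exposes the
    pre-MFM fused features used by knowledge transfer.
    """

    def __init__(self, spec: VariantSpec, cfg: ModelConfig,
                 graph: SkeletonGraph | None = None):
        super().__init__()
        self.spec = spec
        self.cfg = cfg
        graph = graph or SkeletonGraph()
        rng = np.random.default_rng(cfg.seed)
        drop_rng = np.random.default_rng(
            np.random.SeedSequence(cfg.seed).spawn(1)[0])
        C = cfg.hidden_dim

        self.norms = [BatchNorm(width) for _, width in spec.inputs]
        self.bilstms: list[BiLSTM] = []
        self.gcn_branches: list[GCNBranch] = []
        if spec.early_fusion:
            total = sum(w for _, w in spec.inputs)
            self.bilstms = [BiLSTM(total, C, cfg.bilstm_layers, cfg.dropout,
                                   rng, )]
            self.enc_width = C
        else:
            n_mod = len(spec.inputs)
            if spec.use_bilstm:
                self.bilstms = [
                    BiLSTM(width, C, cfg.bilstm_layers, cfg.dropout, rng)
                    for _, width in spec.inputs
                ]
            if spec.use_gcn:
                shared: GCNBranch | None = None
                for _, width in spec.inputs:
                    if width % graph.n_nodes:
                        raise DimensionError(
                            f"modality width {width} does not split over "
                            f"{graph.n_nodes} joint nodes"
                        )
                    node_feat = width // graph.n_nodes
                    if cfg.share_gcn_weights and shared is not None:
                        self.gcn_branches.append(shared)
                    else:
                        branch = GCNBranch(node_feat, cfg, graph, rng,
                                           spec.use_attention)
                        self.gcn_branches.append(branch)
                        shared = branch
            self.enc_width = n_mod * C
        # dropout streams live on their own generator so eval mode is
        # unaffected by how often training sampled masks
        for b in self.bilstms:
            for d in b.dropouts:
                d.rng = drop_rng

        if spec.branch_combine == "gate" and spec.use_bilstm and spec.use_gcn:
            self.gate = GatedFusion(self.enc_width, rng)
        else:
            self.gate = None

        if spec.use_mfm:
            n_blocks = 1 if spec.early_fusion else len(spec.inputs)
            self.mfm = MultiFusionModule(self.enc_width, n_blocks,
                                         cfg.mfm_submodules, cfg, rng)
        else:
            self.mfm = None

        if spec.head == "mlp":
            self.head_layers = [Linear(self.enc_width, cfg.head_hidden, rng),
                                Linear(cfg.head_hidden, N_OUTPUTS, rng)]
        else:
            self.head_layers = [Linear(self.enc_width, N_OUTPUTS, rng)]

    # -- pieces --------------------------------------------------------
    def _normalized(self, batch: dict) -> list[Tensor]:
        outs = []
        for (key, width), bn in zip(self.spec.inputs, self.norms):
            if key not in batch:
                raise DimensionError(f"batch is missing modality {key!r}")
            x = _as_tensor(batch[key])
            if x.ndim != 3 or x.shape[-1] != width:
                raise DimensionError(
                    f"modality {key!r} must be [B, T, {width}], got {x.shape}"
                )
            if x.shape[1] != self.cfg.window:
                raise DimensionError(
                    f"window length {x.shape[1]} != configured ΔT "
                    f"{self.cfg.window}"
                )
            outs.append(bn(x))
        return outs

    def encoder_forward(self, batch: dict) -> Tensor:
        """Fused encoder features ``[B, ΔT, enc_width]`` (pre-MFM)."""
        normalized = self._normalized(batch)
        spec = self.spec
        if spec.early_fusion:
            return self.bilstms[0](concat(normalized, axis=-1))
        streams = []
        if spec.use_bilstm:
            streams.append(concat(
                [enc(x) for enc, x in zip(self.bilstms, normalized)], axis=-1))
        if spec.use_gcn:
            streams.append(concat(
                [branch(x) for branch, x in zip(self.gcn_branches, normalized)],
                axis=-1))
        if len(streams) == 1:
            return streams[0]
        if spec.branch_combine == "add":
            return streams[0] + streams[1]
        if spec.branch_combine == "gate":
            return self.gate(streams[0], streams[1])
        return concat(streams, axis=-1)  # pragma: no cover - unused combine

    def fuse(self, encoded: Tensor) -> Tensor:
        return self.mfm(encoded) if self.mfm is not None else encoded

    def head(self, fused: Tensor) -> Tensor:
        out = fused
        for i, layer in enumerate(self.head_layers):
            out = layer(out)
            if i < len(self.head_layers) - 1:
                out = out.relu()
        return out

    def forward(self, batch: dict) -> Tensor:
        return self.head(self.fuse(self.encoder_forward(batch)))

    __call__ = forward

    # -- diagnostics ---------------------------------------------------
    @property
    def last_gate(self) -> np.ndarray | None:
        return None if self.gate is None else self.gate.last_gate

    @property
    def last_attention(self) -> list[np.ndarray]:
        return [b.last_attention for b in self.gcn_branches
                if b.last_attention is not None]

    # -- freeze helpers for knowledge transfer -------------------------
    def encoder_modules(self) -> list[Module]:
        mods: list[Module] = list(self.norms) + list(self.bilstms)
        seen = set()
        for b in self.gcn_branches:
            if id(b) not in seen:
                mods.append(b)
                seen.add(id(b))
        if self.gate is not None:
            mods.append(self.gate)
        return mods

    def head_modules(self) -> list[Module]:
        mods: list[Module] = []
        if self.mfm is not None:
            mods.append(self.mfm)
        mods.extend(self.head_layers)
        return mods

    def parameters(self):
        for m in self.encoder_modules():
            yield from m.parameters()
        for m in self.head_modules():
            yield from m.parameters()

    def modules(self):
        yield self
        for m in self.encoder_modules():
            yield from m.modules()
        for m in self.head_modules():
            yield from m.modules()

    def freeze_encoder(self) -> None:
        """Freeze encoder weights *and* batch-norm statistics."""
        for m in self.encoder_modules():
            m.set_trainable(False)
            for sub in m.modules():
                if isinstance(sub, BatchNorm):
                    sub.update_stats = False

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))


def build_variant(name: str, cfg: ModelConfig | None = None,
                  graph: SkeletonGraph | None = None) -> KineticsModel:
    """Instantiate an ablation variant by name."""
    if name not in ALL_VARIANTS:
        raise ConfigError(
            f"unknown variant {name!r}; choose from {sorted(ALL_VARIANTS)}"
        )
    return KineticsModel(ALL_VARIANTS[name], cfg or ModelConfig(), graph)


def build_student(cfg: ModelConfig | None = None,
                  graph: SkeletonGraph | None = None) -> KineticsModel:
    """The full student: MFM + gate + Bi-LSTM + attention-GCN."""
    return build_variant("aug_mfm_gate_bilstm_attngcn", cfg, graph)


def build_teacher(cfg: ModelConfig | None = None,
                  graph: SkeletonGraph | None = None) -> KineticsModel:
    """The full teacher: IMU + joint position + MFM + Bi-LSTM."""
    return build_variant("imu_jcp_mfm", cfg, graph)
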