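"""The sleep-staging network: multi-scale convolution, SE channel
attention, state-space multimodal coupling, and a softmax head.

The architecture classifies one 30 s polysomnography epoch (EEG + EOG,
100 Hz, 3000 samples per modality) into the five AASM stages
W / N1 / N2 / N3 / REM.  Each modality passes through its own two-branch
multi-scale CNN (a long kernel for slow rhythms, a short kernel for fast
ones), a squeeze-and-excitation block that re-weights the 128 feature
channels, and the resulting per-modality feature sequences are fused by
a recurrent state-space coupling module in which the hidden states of the
two modalities interact through attention-weighted correlation matrices.
A two-layer fully connected head with softmax produces stage
probabilities.

Everything is built on :mod:`sleepssm.autograd`, so the full model is
differentiable end-to-end and trainable with the pipeline's Adam loop.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .autograd import Tensor, concat, stack

N_CLASSES = 5


def conv_output_length(length: int, kernel: int, stride: int) -> int:
    """Valid-mode output length: floor((L - K) / stride) + 1."""
    if length < kernel:
        raise ValueError(f"input length {length} shorter than kernel {kernel}")
    return (length - kernel) // stride + 1


# ---------------------------------------------------------------------------
# configuration


@dataclass
class MSCNNConfig:
    """Two parallel convolution branches per modality.

    The first-layer defaults follow the staging-network design: the large
    branch uses kernel 50 / stride 20, the small branch kernel 20 /
    stride 5, both with 64 filters, each followed by max-pool 4.  The
    second layer of each branch (kernel 8, stride 1, 64 filters, pool 4)
    completes the "two convolutional layers" of each branch.
    """

    large_kernel: int = 50
    large_stride: int = 20
    small_kernel: int = 20
    small_stride: int = 5
    filters: int = 64
    pool_size: int = 4
    second_kernel: int = 8
    second_stride: int = 1
    second_filters: int = 64

    def branch_lengths(self, epoch_len: int) -> tuple[list[int], list[int]]:
        """Per-stage temporal lengths of (large, small) branches."""
        out = []
        for k, s in ((self.large_kernel, self.large_stride),
                     (self.small_kernel, self.small_stride)):
            l1 = conv_output_length(epoch_len, k, s)
            p1 = l1 // self.pool_size
            l2 = conv_output_length(p1, self.second_kernel, self.second_stride)
            p2 = l2 // self.pool_size
            out.append([l1, p1, l2, p2])
        return out[0], out[1]

    @property
    def out_channels(self) -> int:
        return 2 * self.second_filters

    def aligned_length(self, epoch_len: int) -> int:
        large, small = self.branch_lengths(epoch_len)
        return min(large[-1], small[-1])


@dataclass
class SSMConfig:
    """State-space multimodal coupling module hyperparameters."""

    hidden_dim: int = 64
    n_modalities: int = 2
    #: attention refinement uses h_m(t-1) (cross-modal) by default; the
    #: literal variant re-uses h_n(t-1) for every term of the sum
    literal_attention_state: bool = False
    #: adds an explicit state-transition term h_n(t-1)·Aᵀ inside the tanh
    use_state_matrix: bool = False


@dataclass
class HeadConfig:
    hidden: int = 64
    dropout: float = 0.5


@dataclass
class ModelConfig:
    mscnn: MSCNNConfig = field(default_factory=MSCNNConfig)
    ssm: SSMConfig = field(default_factory=SSMConfig)
    head: HeadConfig = field(default_factory=HeadConfig)
    se_reduction: int = 16
    epoch_len: int = 3000
    dtype: str = "float32"

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        return cls(
            mscnn=MSCNNConfig(**d.get("mscnn", {})),
            ssm=SSMConfig(**d.get("ssm", {})),
            head=HeadConfig(**d.get("head", {})),
            se_reduction=d.get("se_reduction", 16),
            epoch_len=d.get("epoch_len", 3000),
            dtype=d.get("dtype", "float32"),
        )


# ---------------------------------------------------------------------------
# building blocks


class Block:
    """Base class: a named, flat registry of learnable tensors."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._children: dict[str, "Block"] = {}

    def _param(self, name: str, value: np.ndarray) -> Tensor:
        t = Tensor(value, requires_grad=True)
        self._params[name] = t
        return t

    def _child(self, name: str, block: "Block") -> "Block":
        self._children[name] = block
        return block

    def parameters(self) -> dict[str, Tensor]:
        out = dict(self._params)
        for cname, child in self._children.items():
            for pname, t in child.parameters().items():
                out[f"{cname}.{pname}"] = t
        return out

    def zero_grad(self) -> None:
        for t in self.parameters().values():
            t.zero_grad()


def _he(rng: np.random.Generator, shape, fan_in: int, dtype) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(dtype)


def _glorot(rng: np.random.Generator, shape, fan_in: int, fan_out: int, dtype):
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-lim, lim, size=shape).astype(dtype)


class ConvBranch(Block):
    """conv → ReLU → max-pool → conv → ReLU → max-pool, one kernel scale."""

    def __init__(self, kernel: int, stride: int, filters: int, pool: int,
                 k2: int, s2: int, f2: int, rng: np.random.Generator, dtype):
        super().__init__()
        self.stride, self.stride2, self.pool = stride, s2, pool
        self.w1 = self._param("w1", _he(rng, (filters, 1, kernel), kernel, dtype))
        self.b1 = self._param("b1", np.zeros(filters, dtype=dtype))
        self.w2 = self._param("w2", _he(rng, (f2, filters, k2), filters * k2, dtype))
        self.b2 = self._param("b2", np.zeros(f2, dtype=dtype))

    def forward(self, x: Tensor) -> Tensor:
        h = x.conv1d(self.w1, self.b1, stride=self.stride).relu()
        h = h.max_pool1d(self.pool)
        h = h.conv1d(self.w2, self.b2, stride=self.stride2).relu()
        return h.max_pool1d(self.pool)


class MultiScaleConv(Block):
    """Parallel large/small-kernel branches, aligned and channel-concatenated.

    The two branches end at different temporal lengths; both are
    adaptively max-pooled to the shorter one before concatenation so the
    result is a proper feature *sequence* (B, 2·filters, T) for the
    coupling module.
    """

    def __init__(self, cfg: MSCNNConfig, epoch_len: int,
                 rng: np.random.Generator, dtype):
        super().__init__()
        self.cfg = cfg
        self.t_out = cfg.aligned_length(epoch_len)
        self.large = self._child("large", ConvBranch(
            cfg.large_kernel, cfg.large_stride, cfg.filters, cfg.pool_size,
            cfg.second_kernel, cfg.second_stride, cfg.second_filters, rng, dtype))
        self.small = self._child("small", ConvBranch(
            cfg.small_kernel, cfg.small_stride, cfg.filters, cfg.pool_size,
            cfg.second_kernel, cfg.second_stride, cfg.second_filters, rng, dtype))

    def forward(self, x: Tensor) -> Tensor:
        """(B, 1, L) -> (B, 2·filters, T)."""
        hl = self.large.forward(x).adaptive_max_pool1d(self.t_out)
        hs = self.small.forward(x).adaptive_max_pool1d(self.t_out)
        return concat([hl, hs], axis=1)


class SEBlock(Block):
    """Squeeze-and-excitation channel attention for (B, C, T) features.

    Squeeze: global average over time gives one descriptor per channel.
    Excite: a bottleneck two-layer network (reduction ratio ``r``) with
    ReLU then sigmoid yields per-channel gates in (0, 1).  Recalibrate:
    each channel of the feature map is scaled by its gate.
    """

    def __init__(self, channels: int, reduction: int,
                 rng: np.random.Generator, dtype):
        super().__init__()
        if channels % reduction != 0:
            raise ValueError(
                f"channel count {channels} not divisible by reduction {reduction}")
        self.channels = channels
        hidden = channels // reduction
        self.w1 = self._param("w1", _glorot(rng, (channels, hidden),
                                            channels, hidden, dtype))
        self.w2 = self._param("w2", _glorot(rng, (hidden, channels),
                                            hidden, channels, dtype))

    def squeeze(self, u: Tensor) -> Tensor:
        """(B, C, T) -> (B, C): temporal global average pool."""
        return u.mean(axis=2)

    def excite(self, z: Tensor) -> Tensor:
        """(B, C) -> (B, C) gates: sigmoid(W2·relu(W1·z))."""
        return ((z @ self.w1).relu() @ self.w2).sigmoid()

    @staticmethod
    def recalibrate(u: Tensor, s: Tensor) -> Tensor:
        """Scale channel c of the feature map by gate s_c."""
        b, c = s.shape
        return u * s.reshape(b, c, 1)

    def forward(self, u: Tensor) -> Tensor:
        return self.recalibrate(u, self.excite(self.squeeze(u)))


class SSMCoupling(Block):
    """Recurrent state-space coupling of M modality feature sequences.

    Each modality n keeps a hidden state h_n(t) ∈ (−1,1)^H updated from a
    shared input projection B and per-modality correlation matrices S_n:

        h_n(t) = tanh( Σ_m h_m(t−1)·S_n + x̃_n(t)·Bᵀ )

    where x̃_n(t) is the layer-normalised input.  The states are then
    refined once through modality-to-modality attention (scaled dot
    product scores, softmax over the source modality) and re-projected:

        α_nm(t) = softmax_m( h_n(t)·h_m(t) / √H )
        h_n(t) ← tanh( Σ_m α_nm(t)·h_m(t−1)·S_n + x̃_n(t)·Bᵀ )

    After the last step each modality is mapped to the output space by E
    and the modalities are averaged with learned scalar weights W_n:
    Y = (1/M) Σ_n W_n·Y_n,  Y_n = h_n(T)·E.
    """

    def __init__(self, cfg: SSMConfig, in_dim: int,
                 rng: np.random.Generator, dtype, out_dim: int | None = None):
        super().__init__()
        self.cfg = cfg
        self.in_dim = in_dim
        self.out_dim = in_dim if out_dim is None else out_dim
        H, M, D = cfg.hidden_dim, cfg.n_modalities, in_dim
        # B maps inputs into state space; stored (D, H) so x @ B_in == x·Bᵀ
        self.b_in = self._param("b_in", _glorot(rng, (D, H), D, H, dtype))
        self.s_mats = [
            self._param(f"s_{n}", rng.normal(
                0.0, 1.0 / np.sqrt(H * M), size=(H, H)).astype(dtype))
            for n in range(M)
        ]
        if cfg.use_state_matrix:
            self.a_mat = self._param("a", rng.normal(
                0.0, 1.0 / np.sqrt(H), size=(H, H)).astype(dtype))
        else:
            self.a_mat = None
        self.e_out = self._param("e", _glorot(rng, (H, self.out_dim),
                                              H, self.out_dim, dtype))
        self.w_fuse = [self._param(f"w_{n}", np.ones((), dtype=dtype))
                       for n in range(M)]
        self.ln_gamma = [self._param(f"ln_gamma_{n}", np.ones(D, dtype=dtype))
                         for n in range(M)]
        self.ln_beta = [self._param(f"ln_beta_{n}", np.zeros(D, dtype=dtype))
                        for n in range(M)]

    # -- pieces -----------------------------------------------------------

    def attention_weights(self, h: list[Tensor]) -> Tensor:
        """(list of M (B,H)) -> (B, M, M) rows summing to 1 over m."""
        hs = stack(h, axis=1)  # B, M, H
        scale = 1.0 / np.sqrt(self.cfg.hidden_dim)
        scores = (hs @ hs.transpose(0, 2, 1)) * scale
        return scores.softmax(axis=-1)

    def _drive(self, x_t: Tensor | list[Tensor], n: int) -> Tensor:
        xt = x_t[n] if isinstance(x_t, list) else x_t
        return xt @ self.b_in

    def step(self, h_prev: list[Tensor], x_t: Tensor | list[Tensor]
             ) -> list[Tensor]:
        """One coupling update; ``x_t`` is the layer-normalised input at t
        (a single shared (B,D) tensor, or one per modality)."""
        M = self.cfg.n_modalities
        if len(h_prev) != M:
            raise ValueError(f"expected {M} modality states, got {len(h_prev)}")
        # pre-activation states (shared-history sum over modalities)
        h_pre = []
        for n in range(M):
            acc = self._drive(x_t, n)
            for m in range(M):
                acc = acc + (h_prev[m] @ self.s_mats[n])
            if self.a_mat is not None:
                acc = acc + (h_prev[n] @ self.a_mat.transpose(1, 0))
            h_pre.append(acc.tanh())
        if M == 1:
            return h_pre
        alpha = self.attention_weights(h_pre)  # B, M, M
        B = alpha.shape[0]
        h_new = []
        for n in range(M):
            acc = self._drive(x_t, n)
            for m in range(M):
                hist = h_prev[n] if self.cfg.literal_attention_state else h_prev[m]
                a_nm = alpha[:, n, m].reshape(B, 1)
                acc = acc + a_nm * (hist @ self.s_mats[n])
            if self.a_mat is not None:
                acc = acc + (h_prev[n] @ self.a_mat.transpose(1, 0))
            h_new.append(acc.tanh())
        return h_new

    def forward(self, xs: list[Tensor]) -> Tensor:
        """(list of M (B,T,D) sequences) -> fused output (B, out_dim)."""
        M = self.cfg.n_modalities
        if len(xs) != M:
            raise ValueError(f"expected {M} modality sequences, got {len(xs)}")
        T = xs[0].shape[1]
        if any(x.shape[1] != T for x in xs):
            raise ValueError(
                f"modality sequences differ in length: {[x.shape[1] for x in xs]}")
        xn = [xs[n].layer_norm(self.ln_gamma[n], self.ln_beta[n])
              for n in range(M)]
        B = xs[0].shape[0]
        dtype = xs[0].dtype
        h = [Tensor(np.zeros((B, self.cfg.hidden_dim), dtype=dtype))
             for _ in range(M)]
        for t in range(T):
            x_t = [xn[n][:, t, :] for n in range(M)]
            h = self.step(h, x_t)
        y = None
        for n in range(M):
            y_n = (h[n] @ self.e_out) * self.w_fuse[n]
            y = y_n if y is None else y + y_n
        return y * (1.0 / M)


class Head(Block):
    """Two fully connected layers with ReLU, dropout, and 5-way softmax."""

    def __init__(self, in_dim: int, cfg: HeadConfig,
                 rng: np.random.Generator, dtype):
        super().__init__()
        self.cfg = cfg
        self.w1 = self._param("w1", _he(rng, (in_dim, cfg.hidden), in_dim, dtype))
        self.b1 = self._param("b1", np.zeros(cfg.hidden, dtype=dtype))
        self.w2 = self._param("w2", _he(rng, (cfg.hidden, N_CLASSES),
                                        cfg.hidden, dtype))
        self.b2 = self._param("b2", np.zeros(N_CLASSES, dtype=dtype))

    def forward(self, x: Tensor, training: bool = False,
                rng: np.random.Generator | None = None) -> Tensor:
        h = (x @ self.w1 + self.b1).relu()
        if training and self.cfg.dropout > 0:
            if rng is None:
                raise ValueError("dropout in training mode needs an rng")
            keep = 1.0 - self.cfg.dropout
            mask = (rng.random(h.shape) < keep).astype(h.dtype) / keep
            h = h * Tensor(mask)
        return h @ self.w2 + self.b2


# ---------------------------------------------------------------------------
# full models


class _BaseClassifier(Block):
    """Shared predict/checkpoint machinery for the three variants."""

    config: ModelConfig
    variant: str = ""

    def forward(self, x: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None) -> Tensor:
        raise NotImplementedError

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Stage probabilities, rows summing to 1."""
        outs = []
        for i in range(0, len(x), batch_size):
            logits = self.forward(x[i:i + batch_size], training=False)
            outs.append(logits.softmax(axis=-1).data)
        return np.concatenate(outs, axis=0)

    def predict(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        return self.predict_proba(x, batch_size=batch_size).argmax(axis=1)

    # -- checkpointing ----------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Write weights (.npz) plus a JSON sidecar with the full config."""
        path = Path(path)
        params = {k: v.data for k, v in self.parameters().items()}
        np.savez(path.with_suffix(".npz"), **params)
        sidecar = {"variant": self.variant, "config": self.config.to_dict()}
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @staticmethod
    def load(path: str | Path) -> "_BaseClassifier":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        cfg = ModelConfig.from_dict(sidecar["config"])
        model = build_model(sidecar["variant"], cfg, seed=0)
        with np.load(path.with_suffix(".npz")) as data:
            params = model.parameters()
            for k in params:
                params[k].data = data[k].astype(params[k].dtype)
        return model

    def _check_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=self.config.dtype)
        if x.ndim != 3 or x.shape[1] != self.config.ssm.n_modalities:
            raise ValueError(
                f"expected (B, {self.config.ssm.n_modalities}, L) input, "
                f"got shape {x.shape}")
        if x.shape[2] != self.config.epoch_len:
            raise ValueError(
                f"expected epochs of {self.config.epoch_len} samples, "
                f"got {x.shape[2]}")
        return x


class SleepStager(_BaseClassifier):
    """The full model: per-modality MSCNN → SE → SSM coupling → head."""

    variant = "full"

    def __init__(self, config: ModelConfig | None = None, seed: int = 0):
        super().__init__()
        self.config = config or ModelConfig()
        cfg = self.config
        dtype = np.dtype(cfg.dtype).type
        rng = np.random.default_rng(seed)
        M = cfg.ssm.n_modalities
        C = cfg.mscnn.out_channels
        self.mscnn = [
            self._child(f"mscnn_{n}",
                        MultiScaleConv(cfg.mscnn, cfg.epoch_len, rng, dtype))
            for n in range(M)
        ]
        self.se = [
            self._child(f"se_{n}", SEBlock(C, cfg.se_reduction, rng, dtype))
            for n in range(M)
        ]
        self.coupling = self._child(
            "coupling", SSMCoupling(cfg.ssm, C, rng, dtype))
        self.head = self._child(
            "head", Head(self.coupling.out_dim, cfg.head, rng, dtype))

    def forward(self, x: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None) -> Tensor:
        x = self._check_input(x)
        B, M, L = x.shape
        seqs = []
        for n in range(M):
            xn = Tensor(x[:, n, :].reshape(B, 1, L))
            feat = self.se[n].forward(self.mscnn[n].forward(xn))  # B, C, T
            seqs.append(feat.transpose(0, 2, 1))                  # B, T, C
        fused = self.coupling.forward(seqs)
        return self.head.forward(fused, training=training, rng=rng)


class CnnSeClassifier(_BaseClassifier):
    """Ablation without the coupling module: MSCNN + SE features are
    globally average-pooled over time, concatenated across modalities and
    fed straight into the head."""

    variant = "cnn_se"

    def __init__(self, config: ModelConfig | None = None, seed: int = 0):
        super().__init__()
        self.config = config or ModelConfig()
        cfg = self.config
        dtype = np.dtype(cfg.dtype).type
        rng = np.random.default_rng(seed)
        M = cfg.ssm.n_modalities
        C = cfg.mscnn.out_channels
        self.mscnn = [
            self._child(f"mscnn_{n}",
                        MultiScaleConv(cfg.mscnn, cfg.epoch_len, rng, dtype))
            for n in range(M)
        ]
        self.se = [
            self._child(f"se_{n}", SEBlock(C, cfg.se_reduction, rng, dtype))
            for n in range(M)
        ]
        self.head = self._child("head", Head(M * C, cfg.head, rng, dtype))

    def forward(self, x, training=False, rng=None) -> Tensor:
        x = self._check_input(x)
        B, M, L = x.shape
        pooled = []
        for n in range(M):
            xn = Tensor(x[:, n, :].reshape(B, 1, L))
            feat = self.se[n].forward(self.mscnn[n].forward(xn))
            pooled.append(feat.mean(axis=2))
        return self.head.forward(concat(pooled, axis=1),
                                 training=training, rng=rng)


class SsmOnlyClassifier(_BaseClassifier):
    """Ablation without the CNN front-end: each raw modality epoch is
    reshaped into a coarse sequence of contiguous patches (default 30
    steps × 100 samples) and fed directly to the coupling module + head."""

    variant = "ssm_only"

    def __init__(self, config: ModelConfig | None = None, seed: int = 0,
                 patch_len: int = 100):
        super().__init__()
        self.config = config or ModelConfig()
        cfg = self.config
        if cfg.epoch_len % patch_len != 0:
            raise ValueError(
                f"epoch length {cfg.epoch_len} not divisible by patch {patch_len}")
        self.patch_len = patch_len
        dtype = np.dtype(cfg.dtype).type
        rng = np.random.default_rng(seed)
        self.coupling = self._child(
            "coupling", SSMCoupling(cfg.ssm, patch_len, rng, dtype))
        self.head = self._child(
            "head", Head(self.coupling.out_dim, cfg.head, rng, dtype))

    def forward(self, x, training=False, rng=None) -> Tensor:
        x = self._check_input(x)
        B, M, L = x.shape
        T = L // self.patch_len
        seqs = [Tensor(x[:, n, :].reshape(B, T, self.patch_len))
                for n in range(M)]
        fused = self.coupling.forward(seqs)
        return self.head.forward(fused, training=training, rng=rng)


VARIANTS = {
    "full": SleepStager,
    "cnn_se": CnnSeClassifier,
    "ssm_only": SsmOnlyClassifier,
}


def build_model(variant: str, config: ModelConfig | None = None,
                seed: int = 0) -> _BaseClassifier:
    """Instantiate one of the model variants with seeded initialisation."""
    try:
        cls = VARIANTS[variant]
    except KeyError:
        raise ValueError(
            f"unknown variant {variant!r}; choose from {sorted(VARIANTS)}"
        ) from None
    return cls(config, seed=seed)
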