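"""The staging network: CNN front end + attention-guided encoder-decoder.

Inputs are fixed-length sliding windows of L epochs (default 12, i.e. 6
minutes) over up to four standardized channels (activity, HRM, HRSD,
clock). Three length-preserving 1-D convolutions (kernel 9, padding 4,
stride 1, leaky ReLU) extract per-epoch features; an LSTM encoder reads
the window, and an LSTM decoder with multiplicative attention over the
encoder states emits one softmax stage distribution per epoch.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .preprocess import EpochSeries

CHECKPOINT_VERSION = 1

#: channel names per input variant, in order
VARIANTS: dict[str, tuple[str, ...]] = {
    "act": ("activity",),
    "hr": ("hrm", "hrsd"),
    "act-hr": ("activity", "hrm", "hrsd"),
    "act-hr-clock": ("activity", "hrm", "hrsd", "clock"),
}

SECONDS_PER_DAY = 86400.0


@dataclass
class ModelConfig:
    n_channels: int = 3
    n_classes: int = 3
    window: int = 12           # L, epochs per window (9/12/15 supported)
    conv_channels: int = 64
    hidden: int = 128
    kernel: int = 9
    padding: int = 4
    leaky_slope: float = 0.01
    attention: str = "general"  # or "dot"
    seed: int = 0

    def __post_init__(self):
        if self.attention not in ("general", "dot"):
            raise ValueError("attention must be 'general' or 'dot'")
        if self.window + 2 * self.padding - self.kernel + 1 != self.window:
            raise ValueError("kernel/padding must preserve window length")


@dataclass
class NormStats:
    """Per-channel affine normalization fitted on the training split.

    Channels are z-scored; the clock channel instead carries mean 0 and
    scale 86400 s so it maps to fraction-of-day in [0, 1].
    """

    mean: np.ndarray
    sd: np.ndarray

    def apply(self, x: np.ndarray) -> np.ndarray:
        return (x - self.mean[:, None]) / self.sd[:, None]

    @classmethod
    def fit(cls, channel_mats: list[np.ndarray], channels: tuple[str, ...]) -> "NormStats":
        stacked = np.concatenate(channel_mats, axis=1)
        mean = stacked.mean(axis=1)
        sd = stacked.std(axis=1)
        sd[sd == 0] = 1.0
        for i, name in enumerate(channels):
            if name == "clock":
                mean[i], sd[i] = 0.0, SECONDS_PER_DAY
        return cls(mean, sd)


def channel_matrix(series: EpochSeries, variant: str = "act-hr") -> np.ndarray:
    """Stack the variant's channels into a (C, N) matrix (raw units)."""
    if variant not in VARIANTS:
        raise ValueError(f"unknown input variant {variant!r}; choose from {sorted(VARIANTS)}")
    rows = []
    for name in VARIANTS[variant]:
        rows.append(getattr(series, name if name != "clock" else "clock"))
    return np.vstack(rows).astype(np.float64)


def make_windows(x: np.ndarray, L: int = 12,
                 stride: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """Sliding windows over a (C, N) channel matrix.

    Returns (windows, starts): windows has shape (B, C, L) with
    B = floor((N - L)/stride) + 1, and window b covers epochs
    [starts[b], starts[b] + L).
    """
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 2:
        raise ValueError("expected a (channels, epochs) matrix")
    C, N = x.shape
    if N < L:
        raise ValueError(f"series of {N} epochs is shorter than the {L}-epoch window")
    starts = np.arange(0, N - L + 1, stride)
    idx = starts[:, None] + np.arange(L)[None, :]
    return np.ascontiguousarray(x[:, idx].transpose(1, 0, 2)), starts


def attend(decoder_state: Tensor, encoder_states: Tensor,
           Wa: Tensor | None = None) -> tuple[Tensor, Tensor]:
    """Attention over encoder states for one decoding step.

    Alignment scores are dot products between the (optionally projected)
    decoder state and each encoder state; softmax gives the attention
    weights; the context vector is their weighted sum.

    decoder_state: (B, H); encoder_states: (B, L, H). Returns
    (context (B, H), weights (B, L)).
    """
    dec = ag.as_tensor(decoder_state)
    enc = ag.as_tensor(encoder_states)
    B, L, H = enc.data.shape
    if dec.data.shape != (B, H):
        raise ValueError(f"decoder state shape {dec.data.shape} incompatible "
                         f"with encoder states {enc.data.shape}")
    q = dec @ Wa if Wa is not None else dec
    scores = (enc @ q.reshape(B, H, 1)).reshape(B, L)
    weights = scores.softmax(axis=-1)
    context = (weights.reshape(B, 1, L) @ enc).reshape(B, H)
    return context, weights


class SleepStager:
    """CNN + attention seq2seq classifier over epoch windows."""

    def __init__(self, config: ModelConfig, params: dict[str, Tensor] | None = None):
        self.config = config
        self.params = params if params is not None else self._init_params()

    # -- parameters ----------------------------------------------------------
    def _init_params(self) -> dict[str, Tensor]:
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        p: dict[str, Tensor] = {}

        def uniform(*shape, fan_in):
            s = 1.0 / np.sqrt(fan_in)
            return Tensor(rng.uniform(-s, s, size=shape), requires_grad=True)

        cin = cfg.n_channels
        for i in range(3):
            p[f"conv{i}_w"] = uniform(cfg.conv_channels, cin, cfg.kernel,
                                      fan_in=cin * cfg.kernel)
            p[f"conv{i}_b"] = uniform(cfg.conv_channels, fan_in=cin * cfg.kernel)
            cin = cfg.conv_channels
        H, F = cfg.hidden, cfg.conv_channels
        for name, din in (("enc", F), ("dec", F + H)):
            p[f"{name}_Wx"] = uniform(din, 4 * H, fan_in=din)
            p[f"{name}_Wh"] = uniform(H, 4 * H, fan_in=H)
            b = np.zeros(4 * H)
            b[H:2 * H] = 1.0  # forget-gate bias
            p[f"{name}_b"] = Tensor(b, requires_grad=True)
        if cfg.attention == "general":
            p["attn_W"] = uniform(H, H, fan_in=H)
        p["out_W"] = uniform(2 * H, cfg.n_classes, fan_in=2 * H)
        p["out_b"] = Tensor(np.zeros(cfg.n_classes), requires_grad=True)
        return p

    def parameters(self) -> list[Tensor]:
        return list(self.params.values())

    def n_parameters(self) -> int:
        return int(sum(t.data.size for t in self.params.values()))

    def zero_grad(self) -> None:
        for t in self.params.values():
            t.grad = None

    def copy_params(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_params(self, state: dict[str, np.ndarray]) -> None:
        for k, t in self.params.items():
            if k not in state or state[k].shape != t.data.shape:
                raise ValueError(f"incompatible parameter {k!r} in state dict")
            t.data = np.asarray(state[k], dtype=np.float64).copy()

    # -- forward pieces ------------------------------------------------------
    def cnn_features(self, batch) -> Tensor:
        """(B, C, L) windows -> (B, F, L) features; length-preserving."""
        x = ag.as_tensor(batch)
        if x.data.ndim != 3 or x.data.shape[1] != self.config.n_channels:
            raise ValueError(f"expected (B, {self.config.n_channels}, L) input, "
                             f"got {x.data.shape}")
        for i in range(3):
            x = ag.conv1d(x, self.params[f"conv{i}_w"], self.params[f"conv{i}_b"],
                          self.config.padding)
            x = x.leaky_relu(self.config.leaky_slope)
        return x

    def _lstm_step(self, prefix: str, x_t: Tensor, h: Tensor, c: Tensor):
        H = self.config.hidden
        gates = x_t @ self.params[f"{prefix}_Wx"] + h @ self.params[f"{prefix}_Wh"] \
            + self.params[f"{prefix}_b"]
        i = gates[:, 0 * H:1 * H].sigmoid()
        f = gates[:, 1 * H:2 * H].sigmoid()
        g = gates[:, 2 * H:3 * H].tanh()
        o = gates[:, 3 * H:4 * H].sigmoid()
        c = f * c + i * g
        h = o * c.tanh()
        return h, c

    def forward(self, batch) -> Tensor:
        """(B, C, L) standardized windows -> (B, L, K) stage probabilities."""
        cfg = self.config
        feats = self.cnn_features(batch).transpose(0, 2, 1)  # (B, L, F)
        B, L, _ = feats.data.shape
        H = cfg.hidden
        zeros = Tensor(np.zeros((B, H)))
        h, c = zeros, zeros
        enc_hs = []
        for t in range(L):
            h, c = self._lstm_step("enc", feats[:, t, :], h, c)
            enc_hs.append(h)
        enc_stack = ag.stack(enc_hs, axis=1)  # (B, L, H)
        Wa = self.params.get("attn_W")
        dh, dc = h, c  # decoder starts from the encoder's final state
        context = Tensor(np.zeros((B, H)))
        logits = []
        for t in range(L):
            inp = ag.concat([feats[:, t, :], context], axis=1)  # input feeding
            dh, dc = self._lstm_step("dec", inp, dh, dc)
            context, _ = attend(dh, enc_stack, Wa)
            logits.append(ag.concat([dh, context], axis=1) @ self.params["out_W"]
                          + self.params["out_b"])
        return ag.stack(logits, axis=1).softmax(axis=-1)

    def predict_proba(self, windows: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Evaluation-mode forward pass returning a NumPy (B, L, K) array."""
        out = []
        for i in range(0, windows.shape[0], batch_size):
            out.append(self.forward(windows[i:i + batch_size]).data)
        return np.concatenate(out, axis=0)


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(path, model: SleepStager, norm: NormStats | None = None,
                    meta: dict | None = None) -> None:
    """Versioned checkpoint: config + parameters + normalization + metadata."""
    header = {"version": CHECKPOINT_VERSION, "config": asdict(model.config),
              "meta": meta or {}}
    arrays = {f"param_{k}": v.data for k, v in model.params.items()}
    if norm is not None:
        arrays["norm_mean"] = norm.mean
        arrays["norm_sd"] = norm.sd
    np.savez(path, header=np.array(json.dumps(header)), **arrays)


def load_checkpoint(path) -> tuple[SleepStager, NormStats | None, dict]:
    with np.load(path, allow_pickle=False) as z:
        header = json.loads(str(z["header"]))
        if header["version"] != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {header['version']}")
        cfg = ModelConfig(**header["config"])
        model = SleepStager(cfg)
        model.load_params({k[len("param_"):]: z[k] for k in z.files
                           if k.startswith("param_")})
        norm = None
        if "norm_mean" in z.files:
            norm = NormStats(z["norm_mean"], z["norm_sd"])
    return model, norm, header["meta"]
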