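"""Sequence staging network: feature extractor, classifier, domain discriminator.

The feature extractor applies a small 2-D convolutional encoder to each of
the 40 mel epochs in a window, then a single-head self-attention block mixes
context across the epoch sequence. The classifier maps the middle 20 epoch
features to 5-stage posteriors; the domain discriminator consumes the same
post-context features (temporal convolution + fully connected layers) and
outputs the probability that the window came from the source domain.

Inputs are standardized per frequency bin (log-power z-score against
source-domain statistics) before entering the network; adversarial and
virtual-adversarial perturbations therefore live in z-score units.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field
from typing import Optional

import numpy as np

from .autograd import Tensor, no_grad, softmax
from .sigproc import MelConfig, LABELED_EPOCHS, WINDOW_EPOCHS, EDGE_EPOCHS

LOG_FLOOR = 1e-10
PROB_CLAMP = 1e-7


# ---------------------------------------------------------------------------
# unfold ops (im2col with vectorized col2im backward)


def conv2d(x: Tensor, w: Tensor, kh: int, kw: int) -> Tensor:
    """Valid 2-D convolution of x [N, H, W] with w [kh*kw, C] -> [N, Ho, Wo, C].

    im2col + BLAS matmul forward; backward reuses the patch matrix for the
    weight gradient and scatters the input gradient with kh*kw slice adds.
    """
    n, h, wd = x.shape
    ho, wo = h - kh + 1, wd - kw + 1
    c = w.shape[1]
    view = np.lib.stride_tricks.sliding_window_view(x.data, (kh, kw), axis=(1, 2))
    patches = np.ascontiguousarray(view).reshape(n * ho * wo, kh * kw)
    out_data = (patches @ w.data).reshape(n, ho, wo, c)

    def bw(g):
        gflat = g.reshape(n * ho * wo, c)
        if w.requires_grad:
            w._accum(patches.T @ gflat)
        if x.requires_grad:
            gp = (gflat @ w.data.T).reshape(n, ho, wo, kh, kw)
            gx = np.zeros_like(x.data)
            for di in range(kh):
                for dj in range(kw):
                    gx[:, di : di + ho, dj : dj + wo] += gp[:, :, :, di, dj]
            x._accum(gx)

    return Tensor._make(out_data, (x, w), bw)


def unfold1d(x: Tensor, k: int) -> Tensor:
    """Sliding windows along axis 1 of x [B, T, D] -> [B, T-k+1, k*D]."""
    b, t, d = x.shape
    to = t - k + 1
    view = np.lib.stride_tricks.sliding_window_view(x.data, k, axis=1)
    out_data = view.transpose(0, 1, 3, 2).reshape(b, to, k * d)

    def bw(g):
        if not x.requires_grad:
            return
        gp = g.reshape(b, to, k, d)
        gx = np.zeros_like(x.data)
        for di in range(k):
            gx[:, di : di + to, :] += gp[:, :, di, :]
        x._accum(gx)

    return Tensor._make(out_data, (x,), bw)


def avgpool2d(x: Tensor, ph: int, pw: int) -> Tensor:
    """Average pooling over spatial dims of [N, H, W, C] (crops to multiples)."""
    n, h, w, c = x.shape
    h2, w2 = (h // ph) * ph, (w // pw) * pw
    r = x.data[:, :h2, :w2, :].reshape(n, h2 // ph, ph, w2 // pw, pw, c)
    out_data = r.mean(axis=(2, 4))

    def bw(g):
        if not x.requires_grad:
            return
        gx = np.zeros_like(x.data)
        expanded = g[:, :, None, :, None, :] / (ph * pw)
        gx[:, :h2, :w2, :] = np.broadcast_to(
            expanded, (n, h2 // ph, ph, w2 // pw, pw, c)
        ).reshape(n, h2, w2, c)
        x._accum(gx)

    return Tensor._make(out_data, (x,), bw)


# ---------------------------------------------------------------------------
# configuration and parameters


@dataclass
class NetConfig:
    n_mels: int = 32
    n_frames: int = 29
    conv_channels: int = 4
    kernel: int = 3
    pool: int = 2
    embed_dim: int = 16
    disc_kernel: int = 3
    disc_hidden: int = 16
    n_stages: int = 5
    # "window": each window z-scored by its own per-bin stats (absorbs static
    # channel gain/tilt differences between recording setups);
    # "dataset": z-score against stored source-domain statistics.
    normalization: str = "window"

    @property
    def conv_out(self) -> tuple[int, int]:
        ho = (self.n_mels - self.kernel + 1) // self.pool
        wo = (self.n_frames - self.kernel + 1) // self.pool
        return ho, wo

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, s: str) -> "NetConfig":
        return cls(**json.loads(s))


def init_params(config: NetConfig, rng: np.random.Generator) -> dict[str, Tensor]:
    """He-scaled random initialization; normalizer slots start as identity."""
    c, k, d = config.conv_channels, config.kernel, config.embed_dim
    ho, wo = config.conv_out
    flat = c * ho * wo

    def he(shape, fan_in):
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)
        return Tensor(w.astype(np.float32), requires_grad=True)

    def zeros(shape):
        return Tensor(np.zeros(shape, dtype=np.float32), requires_grad=True)

    p = {
        "conv_w": he((k * k, c), k * k),
        "conv_b": zeros((c,)),
        "embed_w": he((flat, d), flat),
        "embed_b": zeros((d,)),
        "attn_q": he((d, d), d),
        "attn_k": he((d, d), d),
        "attn_v": he((d, d), d),
        "attn_o": he((d, d), d),
        "attn_ob": zeros((d,)),
        "cls_w": he((d, config.n_stages), d),
        "cls_b": zeros((config.n_stages,)),
        "disc_w1": he((config.disc_kernel * d, config.disc_hidden),
                      config.disc_kernel * d),
        "disc_b1": zeros((config.disc_hidden,)),
        "disc_w2": he((config.disc_hidden, config.disc_hidden // 2),
                      config.disc_hidden),
        "disc_b2": zeros((config.disc_hidden // 2,)),
        "disc_w3": he((config.disc_hidden // 2, 1), config.disc_hidden // 2),
        "disc_b3": zeros((1,)),
    }
    # per-frequency log-power standardization (not trained by the optimizer)
    p["norm_mean"] = Tensor(np.zeros(config.n_mels, dtype=np.float32))
    p["norm_std"] = Tensor(np.ones(config.n_mels, dtype=np.float32))
    return p


TRAINABLE = lambda name: not name.startswith("norm_")


# ---------------------------------------------------------------------------
# model


@dataclass
class SleepStager:
    """Bundle of parameters + architecture (+ mel) configuration."""

    config: NetConfig
    params: dict[str, Tensor]
    mel_config: Optional[MelConfig] = None

    @classmethod
    def create(cls, config: NetConfig, rng: np.random.Generator,
               mel_config: Optional[MelConfig] = None) -> "SleepStager":
        return cls(config, init_params(config, rng), mel_config)

    # -- input pipeline ----------------------------------------------------

    def fit_normalizer(self, mel_windows: np.ndarray) -> None:
        """Per-mel-bin mean/std of log10 power from source-domain windows."""
        logp = np.log10(mel_windows + LOG_FLOOR)
        mean = logp.mean(axis=(0, 1, 3))
        std = logp.std(axis=(0, 1, 3))
        self.params["norm_mean"] = Tensor(mean.astype(np.float32))
        self.params["norm_std"] = Tensor(np.maximum(std, 1e-6).astype(np.float32))

    def normalize(self, mel_windows: np.ndarray) -> np.ndarray:
        """log10 power, z-scored per mel bin.

        In "window" mode the statistics come from the window itself (over
        its epochs and frames), which cancels static channel coloration and
        gain; in "dataset" mode the stored source-domain statistics are
        used.
        """
        logp = np.log10(mel_windows + LOG_FLOOR, dtype=np.float64)
        if self.config.normalization == "window":
            mean = logp.mean(axis=(1, 3), keepdims=True)
            std = np.maximum(logp.std(axis=(1, 3), keepdims=True), 1e-6)
        else:
            mean = self.params["norm_mean"].data[None, None, :, None]
            std = self.params["norm_std"].data[None, None, :, None]
        return ((logp - mean) / std).astype(np.float32)

    # -- forward passes ----------------------------------------------------

    def extract_features(self, x: Tensor) -> Tensor:
        """Normalized windows [B, 40, M, F] -> context features [B, 40, d]."""
        p, cfg = self.params, self.config
        b = x.shape[0]
        if x.shape[1:] != (WINDOW_EPOCHS, cfg.n_mels, cfg.n_frames):
            raise ValueError(
                f"window shape {x.shape[1:]} does not match config "
                f"({WINDOW_EPOCHS}, {cfg.n_mels}, {cfg.n_frames})"
            )
        h = x.reshape(b * WINDOW_EPOCHS, cfg.n_mels, cfg.n_frames)
        conv = (conv2d(h, p["conv_w"], cfg.kernel, cfg.kernel) + p["conv_b"]).relu()
        pooled = avgpool2d(conv, cfg.pool, cfg.pool)
        flat = pooled.reshape(b * WINDOW_EPOCHS, -1)
        e = (flat @ p["embed_w"] + p["embed_b"]).relu()
        e = e.reshape(b, WINDOW_EPOCHS, cfg.embed_dim)
        q, k, v = e @ p["attn_q"], e @ p["attn_k"], e @ p["attn_v"]
        scores = (q @ k.transpose((0, 2, 1))) * (1.0 / np.sqrt(cfg.embed_dim))
        ctx = softmax(scores, axis=-1) @ v
        return ((e + ctx) @ p["attn_o"] + p["attn_ob"]).relu()

    def classify(self, features: Tensor) -> Tensor:
        """Features [B, 40, d] -> stage posteriors [B, 20, 5] (rows sum to 1)."""
        p = self.params
        mid = features[:, EDGE_EPOCHS : EDGE_EPOCHS + LABELED_EPOCHS, :]
        logits = mid @ p["cls_w"] + p["cls_b"]
        return softmax(logits, axis=-1)

    def discriminate(self, features: Tensor) -> Tensor:
        """Features [B, 40, d] -> P(source domain) in (0, 1), shape [B]."""
        p, cfg = self.params, self.config
        u = unfold1d(features, cfg.disc_kernel)
        h = (u @ p["disc_w1"] + p["disc_b1"]).relu().mean(axis=1)
        h = (h @ p["disc_w2"] + p["disc_b2"]).relu()
        logit = (h @ p["disc_w3"] + p["disc_b3"]).reshape(-1)
        prob = logit.sigmoid()
        return 1.0 - (1.0 - prob.clip_min(PROB_CLAMP)).clip_min(PROB_CLAMP)

    def forward_posterior(self, x: Tensor) -> Tensor:
        return self.classify(self.extract_features(x))

    # -- inference helpers -------------------------------------------------

    def posterior(self, mel_windows: np.ndarray) -> np.ndarray:
        """Evaluation-mode posteriors for raw (un-normalized) mel windows."""
        with no_grad():
            return self.forward_posterior(Tensor(self.normalize(mel_windows))).data

    def features(self, mel_windows: np.ndarray) -> np.ndarray:
        with no_grad():
            return self.extract_features(Tensor(self.normalize(mel_windows))).data

    # -- persistence -------------------------------------------------------

    def save(self, path) -> None:
        arrays = {f"param_{k}": v.data for k, v in self.params.items()}
        arrays["net_config"] = np.bytes_(self.config.to_json())
        if self.mel_config is not None:
            arrays["mel_config"] = np.bytes_(self.mel_config.to_json())
        np.savez_compressed(path, **arrays)

    @classmethod
    def load(cls, path) -> "SleepStager":
        with np.load(path) as z:
            config = NetConfig.from_json(bytes(z["net_config"]).decode())
            mel_config = None
            if "mel_config" in z:
                mel_config = MelConfig.from_json(bytes(z["mel_config"]).decode())
            params = {}
            for key in z.files:
                if key.startswith("param_"):
                    name = key[len("param_"):]
                    params[name] = Tensor(z[key], requires_grad=TRAINABLE(name))
        return cls(config, params, mel_config)
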