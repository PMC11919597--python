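"""Capsule network with dynamic routing and a reconstruction decoder.

Architecture: Conv2D feature extractor -> primary capsules (reshape +
squash) -> routing-by-agreement into two digit capsules (normal / m7G)
-> class probability = L2 norm of each digit capsule -> fully-connected
decoder regenerating the input image from the winning capsule.

Training minimizes a two-sided squared-hinge margin loss on the capsule
norms plus a down-weighted reconstruction mean-squared error.

Digit capsule index convention: capsule 0 = normal site, capsule 1 = m7G
site, i.e. the capsule index equals the binary label.
"""

from __future__ import annotations

import io
import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path
from typing import Optional

import numpy as np

from .autodiff import Adam, Tensor, conv2d, linear

CHECKPOINT_FORMAT_VERSION = "capm7g-ckpt-1"

_EPS = 1e-8  # squash stabilizer; added as eps^2 under the norm's square root


def _pair(v) -> tuple[int, int]:
    return (v, v) if isinstance(v, int) else tuple(v)


@dataclass
class CapsuleNetConfig:
    """All architecture and loss hyperparameters.

    Defaults: 64x64 input, two digit capsules of dimension 32, 3 routing
    iterations, with the canonical capsule-network choices for the rest
    (conv geometry, margins m+=0.9 / m-=0.1 / lambda=0.5, reconstruction
    weight 0.0005 on the per-pixel-sum scale).
    """

    input_size: int = 64
    conv_channels: tuple[int, int] = (64, 256)
    conv_kernel: tuple = (9, 9)
    conv_stride: tuple = (1, 2)
    primary_capsule_dim: int = 8  # m
    num_digit_capsules: int = 2  # J
    digit_capsule_dim: int = 32
    routing_iterations: int = 3  # r
    margin_upper: float = 0.9  # m+
    margin_lower: float = 0.1  # m-
    margin_lambda: float = 0.5
    reconstruction_weight: float = 0.0005  # alpha, per-pixel-sum scale
    decoder_hidden: tuple[int, int] = (512, 1024)
    seed: int = 0
    #: input image shape; None means (input_size, input_size)
    input_shape: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        if self.primary_capsule_dim < 1:
            raise ValueError("primary_capsule_dim must be >= 1")
        if self.routing_iterations < 1:
            raise ValueError("routing_iterations must be >= 1")
        if not 0 < self.margin_lower < self.margin_upper <= 1:
            raise ValueError("need 0 < margin_lower < margin_upper <= 1")
        if self.margin_lambda <= 0:
            raise ValueError("margin_lambda must be > 0")
        if self.reconstruction_weight < 0:
            raise ValueError("reconstruction_weight must be >= 0")
        if self.conv_channels[1] % self.primary_capsule_dim != 0:
            raise ValueError(
                "second conv stage channels must be a multiple of "
                "primary_capsule_dim (capsule channels x m)"
            )

    # -- geometry ---------------------------------------------------------

    @property
    def image_shape(self) -> tuple[int, int]:
        return self.input_shape or (self.input_size, self.input_size)

    def conv_geometry(self) -> list[tuple[int, int]]:
        """Spatial (H, W) after each conv stage."""
        h, w = self.image_shape
        shapes = []
        for kern, stride in zip(self.conv_kernel, self.conv_stride):
            kh, kw = _pair(kern)
            sh, sw = _pair(stride)
            if h < kh or w < kw:
                raise ValueError(
                    f"conv kernel {kh}x{kw} larger than feature map {h}x{w}"
                )
            h = (h - kh) // sh + 1
            w = (w - kw) // sw + 1
            shapes.append((h, w))
        return shapes

    @property
    def num_primary_capsules(self) -> int:
        """L, derived from the conv output geometry."""
        h, w = self.conv_geometry()[-1]
        return (self.conv_channels[1] // self.primary_capsule_dim) * h * w

    # -- presets ----------------------------------------------------------

    @classmethod
    def paper(cls, seed: int = 0) -> "CapsuleNetConfig":
        """The full-scale 64x64 configuration."""
        return cls(seed=seed)

    @classmethod
    def scaled(cls, seed: int = 0) -> "CapsuleNetConfig":
        """Desk-scale 32x32 configuration used by the test suite."""
        return cls(
            input_size=32,
            conv_channels=(8, 32),
            conv_kernel=(5, 5),
            conv_stride=(2, 2),
            primary_capsule_dim=8,
            digit_capsule_dim=16,
            decoder_hidden=(64, 128),
            seed=seed,
        )

    @classmethod
    def tiny(cls, seed: int = 0) -> "CapsuleNetConfig":
        """Minimal 16x16 configuration for fast unit tests."""
        return cls(
            input_size=16,
            conv_channels=(6, 16),
            conv_kernel=(3, 3),
            conv_stride=(1, 2),
            primary_capsule_dim=8,
            digit_capsule_dim=8,
            decoder_hidden=(32, 64),
            seed=seed,
        )

    def onehot_variant(self, window_length: int) -> "CapsuleNetConfig":
        """Adapt the conv geometry to a 4 x n one-hot strip input."""
        return replace(
            self,
            input_shape=(4, window_length),
            conv_kernel=((4, _pair(self.conv_kernel[0])[1]),
                         (1, _pair(self.conv_kernel[1])[1])),
            conv_stride=((1, _pair(self.conv_stride[0])[1]),
                         (1, _pair(self.conv_stride[1])[1])),
        )

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "CapsuleNetConfig":
        raw = json.loads(text)
        for key in ("conv_channels", "decoder_hidden", "input_shape"):
            if raw.get(key) is not None:
                raw[key] = tuple(raw[key])
        for key in ("conv_kernel", "conv_stride"):
            raw[key] = tuple(v if isinstance(v, int) else tuple(v) for v in raw[key])
        return cls(**raw)


@dataclass
class RoutingState:
    """Final routing quantities of one forward pass (numpy copies)."""

    logits: np.ndarray  # b, (B, L, J)
    couplings: np.ndarray  # c, (B, L, J)
    weighted_sums: np.ndarray  # S, (B, J, D)
    outputs: np.ndarray  # v, (B, J, D)


@dataclass
class NetworkOutput:
    """Everything a forward pass produces."""

    digit_vectors: Tensor  # (B, J, D)
    probabilities: Tensor  # (B, J), p_j = ||v_j||
    reconstruction: Optional[Tensor]  # (B, H, W) in [0, 1]
    chosen_class: np.ndarray  # (B,)
    routing: RoutingState
    primary: np.ndarray  # squashed primary capsules, (B, L, m)


# ---------------------------------------------------------------------------
# core operations
# ---------------------------------------------------------------------------


def squash(s: Tensor | np.ndarray, axis: int = -1) -> Tensor:
    """squash(s) = (||s||^2 / (1 + ||s||^2)) * s / ||s||, along ``axis``.

    The norm is stabilized as sqrt(||s||^2 + eps^2) so the zero vector maps
    to the zero vector without NaN; outputs keep the input direction and
    have norm strictly below 1.
    """
    s = s if isinstance(s, Tensor) else Tensor(s)
    n2 = (s * s).sum(axis=axis, keepdims=True)
    norm = (n2 + _EPS * _EPS).sqrt()
    return s * (n2 / (1.0 + n2) / norm)


def predict_vectors(u: Tensor | np.ndarray, W: Tensor | np.ndarray) -> Tensor:
    """Prediction vectors u_hat[j|i] = W[i,j] @ u[i].

    ``u`` is (B, L, m) (or (L, m)); ``W`` is (L, J, m, D). Returns
    (B, L, J, D).
    """
    u = u if isinstance(u, Tensor) else Tensor(u)
    W = W if isinstance(W, Tensor) else Tensor(W)
    if u.data.ndim == 2:
        u = u.reshape(1, *u.shape)
    B, L, m = u.shape
    L2, J, m2, D = W.shape
    if (L, m) != (L2, m2):
        raise ValueError(f"shape mismatch: u {(L, m)}, W expects {(L2, m2)}")
    # (B, L, 1, 1, m) @ (L, J, m, D) -> (B, L, J, 1, D)
    out = u.reshape(B, L, 1, 1, m).matmul(W)
    return out.reshape(B, L, J, D)


def dynamic_routing(
    u_hat: Tensor | np.ndarray, iterations: int = 3
) -> tuple[Tensor, RoutingState]:
    """Routing by agreement between primary and digit capsules.

    Logits b start at zero. Each iteration sets c_i = softmax_j(b_i),
    S_j = sum_i c_ij u_hat[j|i], v_j = squash(S_j), then (on all but the
    last iteration) adds the agreement u_hat[j|i] . v_j to b_ij. Returns
    the final digit vectors and the final-iteration state.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    u_hat = u_hat if isinstance(u_hat, Tensor) else Tensor(u_hat)
    if u_hat.data.ndim == 3:
        u_hat = u_hat.reshape(1, *u_hat.shape)
    B, L, J, D = u_hat.shape
    b = Tensor(np.zeros((B, L, J)))
    c = S = v = None
    for it in range(iterations):
        c = b.softmax(axis=2)  # (B, L, J)
        S = (u_hat * c.reshape(B, L, J, 1)).sum(axis=1)  # (B, J, D)
        v = squash(S, axis=-1)
        if it < iterations - 1:
            agreement = (u_hat * v.reshape(B, 1, J, D)).sum(axis=3)
            b = b + agreement
    state = RoutingState(
        logits=b.data.copy(),
        couplings=c.data.copy(),
        weighted_sums=S.data.copy(),
        outputs=v.data.copy(),
    )
    return v, state


def capsule_probabilities(v: Tensor) -> Tensor:
    """p_j = ||v_j|| (Euclidean length of each digit capsule)."""
    n2 = (v * v).sum(axis=-1)
    return (n2 + _EPS * _EPS).sqrt()


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------


def margin_loss(
    probs: Tensor | np.ndarray,
    target_onehot: np.ndarray,
    m_plus: float = 0.9,
    m_minus: float = 0.1,
    lambda_: float = 0.5,
) -> Tensor:
    """Two-sided squared hinge on capsule norms, averaged over the batch.

    Per sample: sum_k [ T_k max(0, m+ - p_k)^2
                        + lambda (1 - T_k) max(0, p_k - m-)^2 ].
    """
    probs = probs if isinstance(probs, Tensor) else Tensor(probs)
    if probs.data.ndim == 1:
        probs = probs.reshape(1, *probs.shape)
        target_onehot = np.atleast_2d(target_onehot)
    T = Tensor(np.asarray(target_onehot, dtype=np.float64))
    pos = (Tensor(np.full(probs.shape, m_plus)) - probs).relu() ** 2
    neg = (probs - Tensor(np.full(probs.shape, m_minus))).relu() ** 2
    per_sample = (T * pos + (1.0 - T) * (lambda_ * neg)).sum(axis=1)
    return per_sample.mean()


def reconstruction_loss(
    original: np.ndarray, reconstructed: Tensor | np.ndarray
) -> Tensor:
    """Mean squared error over all pixels (and the batch)."""
    reconstructed = (
        reconstructed if isinstance(reconstructed, Tensor) else Tensor(reconstructed)
    )
    orig = np.asarray(original, dtype=np.float64)
    if orig.shape != reconstructed.shape:
        raise ValueError(
            f"shape mismatch: original {orig.shape}, "
            f"reconstruction {reconstructed.shape}"
        )
    diff = reconstructed - Tensor(orig)
    return (diff * diff).mean()


def total_loss(
    margin: Tensor | float,
    reconstruction: Tensor | float,
    alpha: float,
    n_pixels: int,
) -> Tensor:
    """margin + alpha * N * reconstruction_mse.

    Rescaling the per-pixel mean by the pixel count N puts alpha on the
    per-pixel-sum scale, keeping reconstruction subordinate to the margin
    term at the default alpha = 0.0005. With alpha = 0 the decoder
    contributes nothing (the without-reconstruction ablation).
    """
    margin = margin if isinstance(margin, Tensor) else Tensor(margin)
    reconstruction = (
        reconstruction if isinstance(reconstruction, Tensor) else Tensor(reconstruction)
    )
    return margin + (alpha * float(n_pixels)) * reconstruction


# ---------------------------------------------------------------------------
# models
# ---------------------------------------------------------------------------


class CapsuleNet:
    """The full capsule classifier; parameters are plain Tensors."""

    kind = "capsnet"

    def __init__(self, config: CapsuleNetConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        H, W = config.image_shape
        c1, c2 = config.conv_channels
        (k1h, k1w), (k2h, k2w) = (_pair(k) for k in config.conv_kernel)
        m = config.primary_capsule_dim
        J = config.num_digit_capsules
        D = config.digit_capsule_dim
        L = config.num_primary_capsules

        def he(*shape, fan_in):
            return Tensor(
                rng.standard_normal(shape) * np.sqrt(2.0 / fan_in), requires_grad=True
            )

        self.conv1_w = he(c1, 1, k1h, k1w, fan_in=k1h * k1w)
        self.conv1_b = Tensor(np.zeros(c1), requires_grad=True)
        self.conv2_w = he(c2, c1, k2h, k2w, fan_in=c1 * k2h * k2w)
        self.conv2_b = Tensor(np.zeros(c2), requires_grad=True)
        self.W_route = Tensor(rng.standard_normal((L, J, m, D)) * 0.05,
                              requires_grad=True)
        h1, h2 = config.decoder_hidden
        self.dec1_w = he(J * D, h1, fan_in=J * D)
        self.dec1_b = Tensor(np.zeros(h1), requires_grad=True)
        self.dec2_w = he(h1, h2, fan_in=h1)
        self.dec2_b = Tensor(np.zeros(h2), requires_grad=True)
        self.dec3_w = he(h2, H * W, fan_in=h2)
        self.dec3_b = Tensor(np.zeros(H * W), requires_grad=True)

    def parameters(self) -> dict[str, Tensor]:
        return {
            name: getattr(self, name)
            for name in (
                "conv1_w", "conv1_b", "conv2_w", "conv2_b", "W_route",
                "dec1_w", "dec1_b", "dec2_w", "dec2_b", "dec3_w", "dec3_b",
            )
        }

    # -- forward ----------------------------------------------------------

    def primary_capsules(self, images: np.ndarray) -> Tensor:
        """Conv stack -> squashed primary capsule vectors (B, L, m)."""
        cfg = self.config
        H, W = cfg.image_shape
        images = np.asarray(images, dtype=np.float64)
        if images.ndim == 2:
            images = images[None]
        if images.shape[1:] != (H, W):
            raise ValueError(
                f"expected images of shape (*, {H}, {W}), got {images.shape}"
            )
        x = Tensor(images[:, None])
        h = conv2d(x, self.conv1_w, self.conv1_b, cfg.conv_stride[0]).relu()
        h = conv2d(h, self.conv2_w, self.conv2_b, cfg.conv_stride[1])
        B = images.shape[0]
        m = cfg.primary_capsule_dim
        cc = cfg.conv_channels[1] // m
        ho, wo = cfg.conv_geometry()[-1]
        u = h.reshape(B, cc, m, ho * wo).transpose(0, 1, 3, 2).reshape(
            B, cc * ho * wo, m
        )
        return squash(u, axis=-1)

    def forward(
        self, images: np.ndarray, true_class: Optional[np.ndarray] = None
    ) -> NetworkOutput:
        """Full forward pass.

        During training pass ``true_class`` so the decoder reconstructs
        from the true-class capsule; at inference the highest-probability
        capsule is used.
        """
        cfg = self.config
        H, W = cfg.image_shape
        u = self.primary_capsules(images)
        u_hat = predict_vectors(u, self.W_route)
        v, state = dynamic_routing(u_hat, cfg.routing_iterations)
        probs = capsule_probabilities(v)
        chosen = probs.data.argmax(axis=1)
        select = true_class if true_class is not None else chosen
        B, J, D = v.shape
        mask = np.zeros((B, J, 1))
        mask[np.arange(B), np.asarray(select, dtype=int), 0] = 1.0
        masked = (v * Tensor(mask)).reshape(B, J * D)
        d = linear(masked, self.dec1_w, self.dec1_b).relu()
        d = linear(d, self.dec2_w, self.dec2_b).relu()
        recon = linear(d, self.dec3_w, self.dec3_b).sigmoid().reshape(B, H, W)
        return NetworkOutput(
            digit_vectors=v,
            probabilities=probs,
            reconstruction=recon,
            chosen_class=chosen,
            routing=state,
            primary=u.data.copy(),
        )

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        """Per-class capsule norms, shape (B, J)."""
        u = self.primary_capsules(images)
        u_hat = predict_vectors(u, self.W_route)
        v, _ = dynamic_routing(u_hat, self.config.routing_iterations)
        return capsule_probabilities(v).data

    # -- loss -------------------------------------------------------------

    def loss(
        self,
        images: np.ndarray,
        labels: np.ndarray,
        use_reconstruction: bool = True,
    ) -> tuple[Tensor, dict]:
        cfg = self.config
        labels = np.asarray(labels, dtype=int)
        out = self.forward(images, true_class=labels)
        onehot = np.eye(cfg.num_digit_capsules)[labels]
        m_loss = margin_loss(
            out.probabilities, onehot, cfg.margin_upper, cfg.margin_lower,
            cfg.margin_lambda,
        )
        alpha = cfg.reconstruction_weight if use_reconstruction else 0.0
        if alpha > 0:
            r_loss = reconstruction_loss(images, out.reconstruction)
            H, W = cfg.image_shape
            loss = total_loss(m_loss, r_loss, alpha, H * W)
            r_val = float(r_loss.data)
        else:
            loss = m_loss
            r_val = float("nan")
        return loss, {"margin": float(m_loss.data), "reconstruction": r_val}


class CnnMlpBaseline:
    """CNN + MLP head of comparable size; the without-CapsNet ablation.

    Same conv stack as the capsule model, then flatten -> hidden layer ->
    2 logits -> softmax. Trained with cross-entropy.
    """

    kind = "cnn_mlp"

    def __init__(self, config: CapsuleNetConfig, hidden: int = 64):
        self.config = config
        self.hidden = hidden
        rng = np.random.default_rng(config.seed)
        c1, c2 = config.conv_channels
        (k1h, k1w), (k2h, k2w) = (_pair(k) for k in config.conv_kernel)
        ho, wo = config.conv_geometry()[-1]
        flat = c2 * ho * wo

        def he(*shape, fan_in):
            return Tensor(
                rng.standard_normal(shape) * np.sqrt(2.0 / fan_in), requires_grad=True
            )

        self.conv1_w = he(c1, 1, k1h, k1w, fan_in=k1h * k1w)
        self.conv1_b = Tensor(np.zeros(c1), requires_grad=True)
        self.conv2_w = he(c2, c1, k2h, k2w, fan_in=c1 * k2h * k2w)
        self.conv2_b = Tensor(np.zeros(c2), requires_grad=True)
        self.fc1_w = he(flat, hidden, fan_in=flat)
        self.fc1_b = Tensor(np.zeros(hidden), requires_grad=True)
        self.fc2_w = he(hidden, 2, fan_in=hidden)
        self.fc2_b = Tensor(np.zeros(2), requires_grad=True)

    def parameters(self) -> dict[str, Tensor]:
        return {
            name: getattr(self, name)
            for name in (
                "conv1_w", "conv1_b", "conv2_w", "conv2_b",
                "fc1_w", "fc1_b", "fc2_w", "fc2_b",
            )
        }

    def _logits(self, images: np.ndarray) -> Tensor:
        cfg = self.config
        images = np.asarray(images, dtype=np.float64)
        if images.ndim == 2:
            images = images[None]
        x = Tensor(images[:, None])
        h = conv2d(x, self.conv1_w, self.conv1_b, cfg.conv_stride[0]).relu()
        h = conv2d(h, self.conv2_w, self.conv2_b, cfg.conv_stride[1]).relu()
        B = images.shape[0]
        h = h.reshape(B, -1)
        h = linear(h, self.fc1_w, self.fc1_b).relu()
        return linear(h, self.fc2_w, self.fc2_b)

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        return self._logits(images).softmax(axis=1).data

    def loss(self, images, labels, use_reconstruction: bool = True):
        labels = np.asarray(labels, dtype=int)
        logits = self._logits(images)
        logp = (logits.softmax(axis=1) + 1e-12).log()
        onehot = np.eye(2)[labels]
        nll = -(logp * Tensor(onehot)).sum(axis=1)
        loss = nll.mean()
        return loss, {"margin": float(loss.data), "reconstruction": float("nan")}


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------


def save_checkpoint(model, path: str | Path, extra: Optional[dict] = None) -> None:
    """Write config + weights + format version as a single .npz archive."""
    arrays = {f"param/{k}": t.data for k, t in model.parameters().items()}
    meta = {
        "format_version": CHECKPOINT_FORMAT_VERSION,
        "model_kind": model.kind,
        "config": json.loads(model.config.to_json()),
        "extra": extra or {},
    }
    buf = io.BytesIO()
    np.savez(buf, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **arrays)
    Path(path).write_bytes(buf.getvalue())


def load_checkpoint(path: str | Path):
    """Rebuild a model from :func:`save_checkpoint` output.

    Raises ``ValueError`` on version or shape mismatches.
    """
    with np.load(Path(path)) as npz:
        meta = json.loads(bytes(npz["meta"]).decode())
        if meta.get("format_version") != CHECKPOINT_FORMAT_VERSION:
            raise ValueError(
                f"{path}: unsupported checkpoint format "
                f"{meta.get('format_version')!r}"
            )
        config = CapsuleNetConfig.from_json(json.dumps(meta["config"]))
        kind = meta["model_kind"]
        model = CapsuleNet(config) if kind == "capsnet" else CnnMlpBaseline(config)
        for name, tensor in model.parameters().items():
            stored = npz[f"param/{name}"]
            if stored.shape != tensor.data.shape:
                raise ValueError(
                    f"{path}: weight {name} has shape {stored.shape}, "
                    f"model config expects {tensor.data.shape}"
                )
            tensor.data = stored.astype(np.float64)
    return model, meta["extra"]


def make_optimizer(model, lr: float = 0.001) -> Adam:
    return Adam(model.parameters().values(), lr=lr)
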