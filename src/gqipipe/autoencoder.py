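"""3D convolutional autoencoder for volumetric feature extraction.

The network compresses a scalar index volume through three conv + 2x2x2
max-pool stages to a bottleneck of 16 channels at 1/8 spatial resolution,
then mirrors back through three 2x upsample + conv stages to a sigmoid
reconstruction — six 3D convolutions, three pools, three upsamples in total.
On the (88, 104, 88) template grid the bottleneck is (11, 13, 11, 16),
flattened to 25,168 features per subject.

Training minimizes a voxelwise binary cross-entropy between the [0, 1]
normalized input and its reconstruction with the Adadelta optimizer
(learning rate 0.01, 50 epochs by default), updating after every volume.
Everything is plain NumPy (im2col convolutions with explicit backprop), so
runs are exactly reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AEConfig",
    "ConvAutoencoder3D",
    "FeatureMatrix",
    "PRUNE_MARGINS",
    "prune_volume",
    "normalize_intensity",
    "build_autoencoder",
    "train_autoencoder",
    "encode_and_flatten",
]

# voxels removed from the (low, high) side of each axis: (91,109,91) -> (88,104,88)
PRUNE_MARGINS = ((1, 2), (2, 3), (1, 2))
TEMPLATE_SHAPE = (91, 109, 91)
PRUNED_SHAPE = (88, 104, 88)


def prune_volume(vol: np.ndarray) -> np.ndarray:
    """Center-crop a template-grid volume from (91, 109, 91) to (88, 104, 88).

    The retained block is bit-identical to the corresponding input sub-block;
    the crop removes (1, 2) voxels along x, (2, 3) along y and (1, 2) along z.
    """
    vol = np.asarray(vol)
    if vol.shape != TEMPLATE_SHAPE:
        raise ValueError(f"expected input shape {TEMPLATE_SHAPE}, got {vol.shape}")
    (xl, xh), (yl, yh), (zl, zh) = PRUNE_MARGINS
    return vol[xl:-xh, yl:-yh, zl:-zh].copy()


def normalize_intensity(vol: np.ndarray) -> np.ndarray:
    """Min-max scale one volume into [0, 1]; a constant volume maps to zeros."""
    vol = np.asarray(vol, dtype=np.float32)
    if not np.all(np.isfinite(vol)):
        raise ValueError("volume contains non-finite values")
    lo, hi = float(vol.min()), float(vol.max())
    if hi == lo:
        return np.zeros_like(vol)
    return (vol - lo) / (hi - lo)


@dataclass(frozen=True)
class AEConfig:
    """Architecture and training recipe of the autoencoder."""

    input_shape: tuple[int, int, int] = PRUNED_SHAPE
    encoder_channels: tuple[int, int, int] = (32, 16, 16)
    decoder_channels: tuple[int, int, int] = (16, 16, 1)
    kernel_size: int = 3
    learning_rate: float = 0.01
    epochs: int = 50
    optimizer_name: str = "adadelta"
    loss_name: str = "binary cross-entropy"
    rho: float = 0.95
    epsilon: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.input_shape)
        if len(shape) != 3 or any(s <= 0 or s % 8 for s in shape):
            raise ValueError("input_shape dims must be positive and divisible by 8")
        if len(self.encoder_channels) != 3 or self.encoder_channels[-1] != 16:
            raise ValueError("encoder_channels must be 3 integers ending in 16")
        if len(self.decoder_channels) != 3 or self.decoder_channels[-1] != 1:
            raise ValueError("decoder_channels must be 3 integers ending in 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.kernel_size < 1 or self.kernel_size % 2 == 0:
            raise ValueError("kernel_size must be odd and >= 1")
        object.__setattr__(self, "input_shape", shape)

    @property
    def bottleneck_shape(self) -> tuple[int, int, int, int]:
        x, y, z = self.input_shape
        return (x // 8, y // 8, z // 8, self.encoder_channels[-1])

    @property
    def n_features(self) -> int:
        return int(np.prod(self.bottleneck_shape))


# ---------------------------------------------------------------------------
# layers (volumes are (x, y, z, channels), float32)


class _Conv3D:
    """Same-padded 3D convolution via im2col, with ReLU or linear activation."""

    def __init__(self, c_in: int, c_out: int, k: int, activation: str, rng: np.random.Generator):
        fan_in = k**3 * c_in
        scale = np.sqrt(2.0 / fan_in) if activation == "relu" else np.sqrt(1.0 / fan_in)
        self.W = rng.normal(0.0, scale, (fan_in, c_out)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.k = k
        self.c_in = c_in
        self.activation = activation
        self._cols: np.ndarray | None = None
        self._z: np.ndarray | None = None
        self._shape: tuple[int, int, int] | None = None

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        k, p = self.k, self.k // 2
        xp = np.pad(x, ((p, p), (p, p), (p, p), (0, 0)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k, k), axis=(0, 1, 2))
        # win: (X, Y, Z, c_in, k, k, k) -> (n_vox, k^3 * c_in)
        X, Y, Z = x.shape[:3]
        cols = win.transpose(0, 1, 2, 4, 5, 6, 3).reshape(X * Y * Z, k**3 * self.c_in)
        return np.ascontiguousarray(cols, dtype=np.float32)

    def forward(self, x: np.ndarray, cache: bool = False) -> np.ndarray:
        X, Y, Z = x.shape[:3]
        cols = self._im2col(x)
        z = cols @ self.W + self.b
        if cache:
            self._cols, self._shape = cols, (X, Y, Z)
        a = np.maximum(z, 0.0) if self.activation == "relu" else z
        if cache:
            self._z = z
        return a.reshape(X, Y, Z, -1)

    def backward(self, da: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        X, Y, Z = self._shape
        dz = da.reshape(X * Y * Z, -1)
        if self.activation == "relu":
            dz = dz * (self._z > 0)
        dW = self._cols.T @ dz
        db = dz.sum(axis=0)
        dcols = (dz @ self.W.T).reshape(X, Y, Z, self.k, self.k, self.k, self.c_in)
        k, p = self.k, self.k // 2
        dxp = np.zeros((X + 2 * p, Y + 2 * p, Z + 2 * p, self.c_in), dtype=np.float32)
        for a in range(k):
            for b in range(k):
                for c in range(k):
                    dxp[a : a + X, b : b + Y, c : c + Z] += dcols[:, :, :, a, b, c, :]
        self._cols = self._z = None
        return dxp[p : p + X, p : p + Y, p : p + Z], dW, db

    @property
    def params(self):
        return [self.W, self.b]


class _MaxPool3D:
    """2x2x2 max pooling; gradient routes to the first maximum per window."""

    def forward(self, x: np.ndarray, cache: bool = False) -> np.ndarray:
        X, Y, Z, C = x.shape
        w = x.reshape(X // 2, 2, Y // 2, 2, Z // 2, 2, C).transpose(0, 2, 4, 1, 3, 5, 6)
        w = w.reshape(X // 2, Y // 2, Z // 2, 8, C)
        idx = np.argmax(w, axis=3)
        out = np.take_along_axis(w, idx[:, :, :, None, :], axis=3)[:, :, :, 0, :]
        if cache:
            self._idx, self._in_shape = idx, (X, Y, Z, C)
        return out

    def backward(self, da: np.ndarray) -> np.ndarray:
        X, Y, Z, C = self._in_shape
        dw = np.zeros((X // 2, Y // 2, Z // 2, 8, C), dtype=np.float32)
        np.put_along_axis(dw, self._idx[:, :, :, None, :], da[:, :, :, None, :], axis=3)
        dw = dw.reshape(X // 2, Y // 2, Z // 2, 2, 2, 2, C).transpose(0, 3, 1, 4, 2, 5, 6)
        return dw.reshape(X, Y, Z, C)

    params: list = []


class _Upsample3D:
    """2x nearest-neighbor upsampling along every spatial axis."""

    def forward(self, x: np.ndarray, cache: bool = False) -> np.ndarray:
        return x.repeat(2, axis=0).repeat(2, axis=1).repeat(2, axis=2)

    def backward(self, da: np.ndarray) -> np.ndarray:
        X, Y, Z, C = da.shape
        return (
            da.reshape(X // 2, 2, Y // 2, 2, Z // 2, 2, C).sum(axis=(1, 3, 5))
        ).astype(np.float32)

    params: list = []


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _bce(target: np.ndarray, prob: np.ndarray, eps: float = 1e-7) -> float:
    p = np.clip(prob, eps, 1.0 - eps)
    return float(-np.mean(target * np.log(p) + (1.0 - target) * np.log(1.0 - p)))


class ConvAutoencoder3D:
    """The six-conv / three-pool / three-upsample autoencoder.

    ``encode`` returns the bottleneck activations ``(x/8, y/8, z/8, 16)``;
    ``reconstruct`` returns the sigmoid output on the input grid; ``fit``
    trains by voxelwise binary cross-entropy with per-volume Adadelta
    updates.
    """

    def __init__(self, config: AEConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        k = config.kernel_size
        e1, e2, e3 = config.encoder_channels
        d1, d2, d3 = config.decoder_channels
        self.encoder = [
            _Conv3D(1, e1, k, "relu", rng), _MaxPool3D(),
            _Conv3D(e1, e2, k, "relu", rng), _MaxPool3D(),
            _Conv3D(e2, e3, k, "relu", rng), _MaxPool3D(),
        ]
        # final conv is linear here; the sigmoid is applied by the model so
        # that training can use the numerically stable logits form of BCE
        self.decoder = [
            _Upsample3D(), _Conv3D(e3, d1, k, "relu", rng),
            _Upsample3D(), _Conv3D(d1, d2, k, "relu", rng),
            _Upsample3D(), _Conv3D(d2, d3, k, "linear", rng),
        ]
        self._layers = self.encoder + self.decoder
        self._acc_g = [np.zeros_like(p) for p in self.parameters()]
        self._acc_d = [np.zeros_like(p) for p in self.parameters()]

    # -- structure ---------------------------------------------------------
    @property
    def layer_census(self) -> dict[str, int]:
        names = {"conv": _Conv3D, "max_pool": _MaxPool3D, "upsample": _Upsample3D}
        return {
            name: sum(isinstance(l, cls) for l in self._layers)
            for name, cls in names.items()
        }

    def parameters(self) -> list[np.ndarray]:
        return [p for layer in self._layers for p in layer.params]

    # -- forward paths -----------------------------------------------------
    def _check(self, vol: np.ndarray) -> np.ndarray:
        vol = np.asarray(vol, dtype=np.float32)
        if vol.shape != self.config.input_shape:
            raise ValueError(
                f"volume shape {vol.shape} does not match input_shape {self.config.input_shape}"
            )
        return vol[..., None]

    def encode(self, vol: np.ndarray) -> np.ndarray:
        """Bottleneck activations of one volume, shape (x/8, y/8, z/8, 16)."""
        x = self._check(vol)
        for layer in self.encoder:
            x = layer.forward(x)
        return x

    def _forward_logits(self, vol: np.ndarray, cache: bool = False) -> np.ndarray:
        x = self._check(vol)
        for layer in self._layers:
            x = layer.forward(x, cache=cache)
        return x

    def reconstruct(self, vol: np.ndarray) -> np.ndarray:
        """Sigmoid reconstruction in [0, 1] on the input grid."""
        return _sigmoid(self._forward_logits(vol))[..., 0]

    # -- training ----------------------------------------------------------
    def _adadelta_step(self, grads: list[np.ndarray]) -> None:
        cfg = self.config
        for p, g, ag, ad in zip(self.parameters(), grads, self._acc_g, self._acc_d):
            ag *= cfg.rho
            ag += (1.0 - cfg.rho) * g * g
            delta = -np.sqrt(ad + cfg.epsilon) / np.sqrt(ag + cfg.epsilon) * g
            ad *= cfg.rho
            ad += (1.0 - cfg.rho) * delta * delta
            p += cfg.learning_rate * delta

    def _train_step(self, vol: np.ndarray) -> float:
        target = self._check(vol)
        logits = self._forward_logits(vol, cache=True)
        prob = _sigmoid(logits)
        loss = _bce(target, prob)
        grad = (prob - target) / target.size
        grads: list[np.ndarray] = []
        for layer in reversed(self._layers):
            if isinstance(layer, _Conv3D):
                grad, dW, db = layer.backward(grad)
                grads = [dW, db] + grads
            else:
                grad = layer.backward(grad)
        self._adadelta_step(grads)
        return loss

    def fit(self, volumes: Sequence[np.ndarray], epochs: int | None = None) -> list[float]:
        """Train on a list of [0, 1] volumes; returns per-epoch mean loss."""
        if len(volumes) == 0:
            raise ValueError("need at least one training volume")
        epochs = self.config.epochs if epochs is None else epochs
        history = []
        for _ in range(epochs):
            losses = [self._train_step(v) for v in volumes]
            history.append(float(np.mean(losses)))
        return history

    # -- persistence -------------------------------------------------------
    def save(self, path: str | Path) -> None:
        arrays = {f"p{i}": p for i, p in enumerate(self.parameters())}
        np.savez(path, **arrays)

    def load(self, path: str | Path) -> None:
        with np.load(path) as data:
            for i, p in enumerate(self.parameters()):
                p[...] = data[f"p{i}"]


# ---------------------------------------------------------------------------
# module-level operations


@dataclass(frozen=True)
class FeatureMatrix:
    """Subjects x flattened-bottleneck features, rows in manifest order.

    Flattening uses Fortran order over (x, y, z, channel), i.e. the x index
    varies fastest, then y, z, channel.
    """

    values: np.ndarray  # (n_subjects, n_features)
    subject_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 2 or v.shape[0] != len(self.subject_ids):
            raise ValueError("values must be (n_subjects, n_features)")
        if not np.all(np.isfinite(v)):
            raise ValueError("features must be finite")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "subject_ids", tuple(self.subject_ids))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=list(self.subject_ids))
        df.index.name = "subject_id"
        df.columns = [f"f{i}" for i in range(self.values.shape[1])]
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureMatrix":
        df = pd.read_csv(path, index_col="subject_id")
        return cls(values=df.to_numpy(dtype=np.float32), subject_ids=tuple(df.index.astype(str)))


def build_autoencoder(cfg: AEConfig) -> ConvAutoencoder3D:
    """Construct the model (weights initialized from ``cfg.seed``)."""
    return ConvAutoencoder3D(cfg)


def train_autoencoder(
    model: ConvAutoencoder3D,
    volumes: Sequence[np.ndarray],
    cfg: AEConfig | None = None,
) -> tuple[ConvAutoencoder3D, list[float]]:
    """Unsupervised reconstruction training; returns the model and the
    per-epoch mean loss history (empty when epochs is 0)."""
    cfg = cfg or model.config
    if len(volumes) == 0:
        raise ValueError("need at least one training volume")
    if cfg.epochs == 0:
        return model, []
    history = model.fit(volumes, epochs=cfg.epochs)
    return model, history


def encode_and_flatten(
    model: ConvAutoencoder3D,
    volumes: Sequence[np.ndarray],
    subject_ids: Sequence[str] | None = None,
) -> FeatureMatrix:
    """Encode every volume and flatten the bottleneck (x fastest)."""
    if subject_ids is None:
        subject_ids = [f"s{i:03d}" for i in range(len(volumes))]
    if len(subject_ids) != len(volumes):
        raise ValueError("subject_ids and volumes must have equal length")
    rows = [model.encode(v).ravel(order="F") for v in volumes]
    return FeatureMatrix(values=np.vstack(rows), subject_ids=tuple(subject_ids))
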