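"""Deep convolutional auto-encoder (DCAE) and focal-loss deep classifier.

The DCAE learns a low-dimensional representation of the 8 x 8 x 10 encoded
image stacks by reconstructing them through a symmetric
convolution/pooling encoder and upsampling/convolution decoder:

    h = sigma_e(W * x + b),    x' = sigma_d(W' * h + b'),
    L_mse = (1/n) sum_i ||x'_i - x_i||^2

Hidden layers use SELU with batch normalization and dropout; the decoder
output is tanh, so inputs are affinely mapped into [-1, 1] first.  The
classifier is a 4 x 50 SELU network with a sigmoid output trained with the
focal loss

    L_FL = -alpha (1 - p)^gamma log p           if y = 1
           -(1 - alpha) p^gamma log(1 - p)      if y = 0

with alpha = 1 - n_minority / n_total (~0.986 at the reference class counts)
and gamma = 3.5.  Both models use adadelta (initial step 1.0, decay 0.95),
100 epochs, batch 512 by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._nn import (
    Activation,
    Adadelta,
    BatchNorm,
    Conv2D,
    Dense,
    Dropout,
    Flatten,
    MaxPool2,
    Reshape,
    Sequential,
    Upsample2,
)

#: Input geometry of an encoded window: 8 x 8 pixels, 10 variable channels.
INPUT_SHAPE = (8, 8, 10)

_PROB_EPS = 1e-7


@dataclass
class FocalLossParams:
    """alpha in (0, 1) reweights classes; gamma >= 0 focuses on hard samples.

    gamma = 0, alpha = 0.5 reduces the loss to half the binary cross-entropy.
    """

    alpha: float = 0.986
    gamma: float = 3.5

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")


@dataclass
class AutoencoderSpec:
    """Architecture and training settings of the DCAE.

    Two conv/pool stages (8 -> 4 -> 2) feed a dense bottleneck of
    ``latent_dim`` units; the decoder mirrors them with nearest-neighbour
    upsampling (2 -> 4 -> 8) and a tanh output conv back to 10 channels.
    The 7 -> 8 time-step padding exists precisely so these two pool/upsample
    pairs round-trip the spatial size.
    """

    conv_channels: tuple[int, int] = (32, 64)
    latent_dim: int = 5
    dropout_rate: float = 0.1
    epochs: int = 100
    batch_size: int = 512
    learning_rate: float = 1.0
    rho: float = 0.95


@dataclass
class ClassifierSpec:
    """Focal-loss DNN head: four SELU hidden layers of 50 units, sigmoid out."""

    hidden_units: tuple[int, ...] = (50, 50, 50, 50)
    dropout_rate: float = 0.1
    epochs: int = 100
    batch_size: int = 512
    learning_rate: float = 1.0
    rho: float = 0.95
    focal: FocalLossParams = field(default_factory=FocalLossParams)
    threshold: float = 0.5


def compute_alpha(n_minority: int, n_total: int) -> float:
    """Focal-loss class weight: 1 - n_minority / n_total."""
    if n_total <= 0 or n_minority <= 0:
        raise ValueError("counts must be positive")
    if n_minority >= n_total:
        raise ValueError("n_minority must be smaller than n_total")
    return 1.0 - n_minority / n_total


def focal_loss(probabilities: np.ndarray, labels: np.ndarray,
               params: FocalLossParams) -> float:
    """Mean focal loss of predicted probabilities against binary labels."""
    p = np.clip(np.asarray(probabilities, dtype=float), _PROB_EPS, 1.0 - _PROB_EPS)
    y = np.asarray(labels)
    if not np.isin(y, (0, 1)).all():
        raise ValueError("labels must be binary (0/1)")
    pos = -params.alpha * (1.0 - p) ** params.gamma * np.log(p)
    neg = -(1.0 - params.alpha) * p**params.gamma * np.log(1.0 - p)
    return float(np.mean(np.where(y == 1, pos, neg)))


def _focal_loss_grad(p: np.ndarray, y: np.ndarray, params: FocalLossParams) -> np.ndarray:
    """d(mean focal loss)/dp, elementwise (before the 1/n factor)."""
    p = np.clip(p, _PROB_EPS, 1.0 - _PROB_EPS)
    a, g = params.alpha, params.gamma
    # y=1: d/dp[-a(1-p)^g log p] = a*g*(1-p)^(g-1)*log p - a*(1-p)^g / p
    dpos = a * g * (1.0 - p) ** max(g - 1.0, 0.0) * np.log(p) - a * (1.0 - p) ** g / p
    # y=0: d/dp[-(1-a) p^g log(1-p)] = -(1-a)*g*p^(g-1)*log(1-p) + (1-a)*p^g/(1-p)
    dneg = -(1.0 - a) * g * p ** max(g - 1.0, 0.0) * np.log(1.0 - p) \
        + (1.0 - a) * p**g / (1.0 - p)
    return np.where(y == 1, dpos, dneg)


def scale_stack(stacks: np.ndarray, method: str) -> np.ndarray:
    """Map image stacks into the tanh range [-1, 1].

    GASF/GADF already live there; MTF and RP values in [0, 1] are affinely
    mapped by 2x - 1.
    """
    if method in ("gasf", "gadf"):
        return np.asarray(stacks, dtype=float)
    if method in ("mtf", "rp"):
        return 2.0 * np.asarray(stacks, dtype=float) - 1.0
    raise ValueError(f"unknown encoding method {method!r}")


def _check_stacks(stacks: np.ndarray) -> np.ndarray:
    stacks = np.asarray(stacks, dtype=float)
    if stacks.ndim != 4 or stacks.shape[1:] != INPUT_SHAPE:
        raise ValueError(f"image stacks must be (N, {INPUT_SHAPE}), got {stacks.shape}")
    return stacks


class DCAE:
    """Trained deep convolutional auto-encoder (build via :func:`dcae_fit`)."""

    def __init__(self, spec: AutoencoderSpec, seed: int):
        self.spec = spec
        rng = np.random.default_rng(seed)
        c1, c2 = spec.conv_channels
        h, w, c_in = INPUT_SHAPE
        dense_in = (h // 4) * (w // 4) * c2
        drop = spec.dropout_rate
        self.encoder = Sequential([
            Conv2D(c_in, c1, rng), BatchNorm(c1), Activation("selu"), Dropout(drop),
            MaxPool2(),
            Conv2D(c1, c2, rng), BatchNorm(c2), Activation("selu"), Dropout(drop),
            MaxPool2(),
            Flatten(),
            Dense(dense_in, spec.latent_dim, rng), Activation("selu"),
        ])
        self.decoder = Sequential([
            Dense(spec.latent_dim, dense_in, rng), BatchNorm(dense_in),
            Activation("selu"), Dropout(drop),
            Reshape((h // 4, w // 4, c2)),
            Upsample2(),
            Conv2D(c2, c1, rng), BatchNorm(c1), Activation("selu"), Dropout(drop),
            Upsample2(),
            Conv2D(c1, c_in, rng), Activation("tanh"),
        ])
        self.loss_history: list[float] = []
        self.val_loss_history: list[float] = []
        self.trained = False

    # -- training ----------------------------------------------------------
    def fit(self, stacks: np.ndarray, seed: int,
            validation: np.ndarray | None = None) -> "DCAE":
        stacks = _check_stacks(stacks)
        rng = np.random.default_rng(seed)
        params = self.encoder.params() + self.decoder.params()
        opt = Adadelta(params, lr=self.spec.learning_rate, rho=self.spec.rho)
        n = len(stacks)
        batch = min(self.spec.batch_size, n)
        for _ in range(self.spec.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, batch):
                xb = stacks[order[start : start + batch]]
                z = self.encoder.forward(xb, True, rng)
                xr = self.decoder.forward(z, True, rng)
                diff = xr - xb
                loss = float(np.mean(diff**2))
                epoch_loss += loss * len(xb)
                grad = 2.0 * diff / diff.size
                opt.zero_grad()
                self.encoder.backward(self.decoder.backward(grad))
                opt.step()
            self.loss_history.append(epoch_loss / n)
            if validation is not None:
                self.val_loss_history.append(self.reconstruction_loss(validation))
        self.trained = True
        return self

    # -- inference ---------------------------------------------------------
    def encode(self, stacks: np.ndarray) -> np.ndarray:
        """Latent vectors (N, latent_dim); deterministic inference mode."""
        if not self.trained:
            raise RuntimeError("DCAE is not trained; call dcae_fit first")
        return self.encoder.predict(_check_stacks(stacks))

    def reconstruct(self, stacks: np.ndarray) -> np.ndarray:
        if not self.trained:
            raise RuntimeError("DCAE is not trained; call dcae_fit first")
        return self.decoder.predict(self.encoder.predict(_check_stacks(stacks)))

    def reconstruction_loss(self, stacks: np.ndarray) -> float:
        stacks = _check_stacks(stacks)
        z = self.encoder.predict(stacks)
        xr = self.decoder.predict(z)
        return float(np.mean((xr - stacks) ** 2))

    def get_weights(self) -> list[np.ndarray]:
        return self.encoder.get_weights() + self.decoder.get_weights()

    def set_weights(self, arrays: list[np.ndarray]) -> None:
        n_enc = len(self.encoder.get_weights())
        self.encoder.set_weights(arrays[:n_enc])
        self.decoder.set_weights(arrays[n_enc:])
        self.trained = True


def dcae_fit(stacks: np.ndarray, spec: AutoencoderSpec | None = None,
             seed: int = 0, validation: np.ndarray | None = None) -> DCAE:
    """Fit a DCAE on image stacks; records per-epoch reconstruction loss."""
    spec = spec or AutoencoderSpec()
    model = DCAE(spec, seed=seed)
    return model.fit(stacks, seed=seed + 1, validation=validation)


def dcae_encode(model: DCAE, stacks: np.ndarray) -> np.ndarray:
    """Latent representation of image stacks under a trained DCAE."""
    return model.encode(stacks)


class DNNClassifier:
    """Focal-loss deep network on the latent representation."""

    def __init__(self, n_inputs: int, spec: ClassifierSpec, seed: int):
        self.spec = spec
        self.n_inputs = n_inputs
        rng = np.random.default_rng(seed)
        layers = []
        width = n_inputs
        for units in spec.hidden_units:
            layers += [Dense(width, units, rng), BatchNorm(units),
                       Activation("selu"), Dropout(spec.dropout_rate)]
            width = units
        layers += [Dense(width, 1, rng), Activation("sigmoid")]
        self.net = Sequential(layers)
        self.loss_history: list[float] = []
        self.trained = False

    def fit(self, latents: np.ndarray, labels: np.ndarray, seed: int) -> "DNNClassifier":
        X = np.asarray(latents, dtype=float)
        y = np.asarray(labels)
        if not np.isfinite(X).all():
            raise ValueError("latent inputs contain NaN or inf")
        if not np.isin(y, (0, 1)).all():
            raise ValueError("labels must be binary (0/1)")
        rng = np.random.default_rng(seed)
        opt = Adadelta(self.net.params(), lr=self.spec.learning_rate, rho=self.spec.rho)
        n = len(X)
        batch = min(self.spec.batch_size, n)
        for _ in range(self.spec.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, batch):
                idx = order[start : start + batch]
                xb, yb = X[idx], y[idx]
                p = self.net.forward(xb, True, rng)[:, 0]
                epoch_loss += focal_loss(p, yb, self.spec.focal) * len(xb)
                dp = _focal_loss_grad(p, yb, self.spec.focal) / len(xb)
                opt.zero_grad()
                self.net.backward(dp[:, None])
                opt.step()
            self.loss_history.append(epoch_loss / n)
        self.trained = True
        return self

    def predict_proba(self, latents: np.ndarray) -> np.ndarray:
        if not self.trained:
            raise RuntimeError("classifier is not trained")
        X = np.asarray(latents, dtype=float)
        if not np.isfinite(X).all():
            raise ValueError("latent inputs contain NaN or inf")
        p = self.net.predict(X)[:, 0]
        return np.clip(p, _PROB_EPS, 1.0 - _PROB_EPS)

    def get_weights(self) -> list[np.ndarray]:
        return self.net.get_weights()

    def set_weights(self, arrays: list[np.ndarray]) -> None:
        self.net.set_weights(arrays)
        self.trained = True


def dnn_fit(latents: np.ndarray, labels: np.ndarray,
            spec: ClassifierSpec | None = None, seed: int = 0) -> DNNClassifier:
    """Fit the focal-loss classifier on latent vectors."""
    spec = spec or ClassifierSpec()
    model = DNNClassifier(np.asarray(latents).shape[1], spec, seed=seed)
    return model.fit(latents, labels, seed=seed + 1)


def predict_risk(dcae: DCAE, classifier: DNNClassifier, stacks: np.ndarray) -> np.ndarray:
    """End-to-end injury probability for encoded (and scaled) image stacks."""
    return classifier.predict_proba(dcae.encode(stacks))
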