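"""Differentiable classifier and generator networks.

The classifier is a small feedforward CNN with named layers (conv1..conv3,
fc_top); fc_top is the pre-softmax categorical layer, one unit per fixture
category, playing the role a 1000-way categorical layer plays in an
ImageNet-scale classifier. The generator is the decoder half of a trained
autoencoder — a mean-centred dense image codec whose range is a learned
affine subspace of image space, squashed into canonical range — serving as
the differentiable image prior for latent-space activation maximisation.
A paired encoder is kept for training and inversion warm starts only.

Activation-maximisation needs exactly two gradients from these networks:
d(objective)/d(image) through the classifier, and the same chained through
the generator to the latent code; both are exposed here and are checked
against finite differences in the test suite.

Layer-name aliases ("fc8" -> fc_top, "conv4" -> conv2) let run presets
written in the vocabulary of large AlexNet-style classifiers run unchanged
on the fixture networks.
"""

from __future__ import annotations

import json
import os

import numpy as np

from ._autodiff import (
    Adam,
    Conv2d,
    Dense,
    Flatten,
    MaxPool2,
    ReLU,
    Reshape,
    Sequential,
    Sigmoid,
    Softplus,
    Upsample2,
)
from .image import as_batch
from .synthetic_data import LabelledImageSet, holdout_split

LAYER_ALIASES = {"fc8": "fc_top", "conv4": "conv2"}

MIN_SAMPLES_PER_CLASS = 50


class TrainingDataError(ValueError):
    """Raised when a fixture dataset is too small to train on."""


def resolve_layer(name: str, layer_names: list[str]) -> str:
    resolved = LAYER_ALIASES.get(name, name)
    if resolved not in layer_names:
        raise ValueError(f"unknown layer {name!r}; known: {layer_names}")
    return resolved


# ---------------------------------------------------------------------------
# classifier


class ClassifierNetwork:
    """Named-layer CNN: conv1 -> conv2 -> conv3 -> fc_top.

    Named activations are taken after each block's rectifier (so conv
    activations are non-negative) and at the raw fc_top logits. Input images
    are mean-centred per channel with a mean computed on the training set;
    the mean is stored so pixel-space optimisation can clip in canonical
    range while the network sees centred values.
    """

    def __init__(self, num_classes: int, image_size: int, seed: int = 0,
                 channels: tuple[int, int, int] = (16, 32, 64),
                 dtype=np.float64):
        if image_size % 8 != 0:
            raise ValueError("image_size must be divisible by 8")
        rng = np.random.default_rng(np.random.SeedSequence((seed & 0xFFFFFFFF, 0xC1)))
        c1, c2, c3 = channels
        s8 = image_size // 8
        self.dtype = np.dtype(dtype)
        self.net = Sequential([
            Conv2d(3, c1, 3, rng, dtype), ReLU(),        # conv1 -> index 1
            MaxPool2(),
            Conv2d(c1, c2, 3, rng, dtype), ReLU(),       # conv2 -> index 4
            MaxPool2(),
            Conv2d(c2, c3, 3, rng, dtype), ReLU(),       # conv3 -> index 7
            MaxPool2(), Flatten(),
            Dense(c3 * s8 * s8, num_classes, rng, dtype)  # fc_top -> index 10
        ])
        self._name_to_index = {"conv1": 1, "conv2": 4, "conv3": 7, "fc_top": 10}
        self.layer_names = list(self._name_to_index)
        self.num_classes = num_classes
        self.image_size = image_size
        self.channels = channels
        self.seed = seed
        self.channel_mean = np.zeros(3, dtype=dtype)
        self.categories: tuple[str, ...] | None = None

    # -- forward / backward ------------------------------------------------

    def _check_batch(self, batch: np.ndarray) -> None:
        if batch.shape[1:] != (self.image_size, self.image_size, 3):
            raise ValueError(
                f"expected (N, {self.image_size}, {self.image_size}, 3) batch, "
                f"got {batch.shape}")

    def forward_batch(self, batch: np.ndarray, terminal_layer: str = "fc_top"
                      ) -> dict[str, np.ndarray]:
        """Run mean-centred forward pass up to terminal_layer; returns every
        named activation up to and including it (batched, channels-last)."""
        terminal = resolve_layer(terminal_layer, self.layer_names)
        self._check_batch(batch)
        x = np.asarray(batch, dtype=self.dtype) - self.channel_mean
        stop = self._name_to_index[terminal]
        acts: dict[str, np.ndarray] = {}
        for i, layer in enumerate(self.net.layers[: stop + 1]):
            x = layer.forward(x)
            for name, idx in self._name_to_index.items():
                if idx == i:
                    acts[name] = x
        return acts

    def backward_batch(self, terminal_layer: str, error: np.ndarray) -> np.ndarray:
        """Backpropagate an error signal at terminal_layer to the image;
        must be called right after forward_batch (uses its caches)."""
        terminal = resolve_layer(terminal_layer, self.layer_names)
        stop = self._name_to_index[terminal]
        g = error
        for layer in reversed(self.net.layers[: stop + 1]):
            g = layer.backward(g)
        return g

    def forward(self, image: np.ndarray, terminal_layer: str = "fc_top"
                ) -> dict[str, np.ndarray]:
        """Single-image forward; activations are unbatched ((C,) or (H,W,C))."""
        acts = self.forward_batch(as_batch(image), terminal_layer)
        return {k: v[0] for k, v in acts.items()}

    def backward_to_image(self, image: np.ndarray, terminal_layer: str,
                          error: np.ndarray) -> np.ndarray:
        """Gradient of <error, activations(terminal_layer)> w.r.t. the image."""
        acts = self.forward_batch(as_batch(image), terminal_layer)
        terminal = resolve_layer(terminal_layer, self.layer_names)
        if error.shape != acts[terminal].shape[1:]:
            raise ValueError(
                f"error shape {error.shape} != activation shape {acts[terminal].shape[1:]}")
        self.net.zero_grads()
        return self.backward_batch(terminal, error[None])[0]

    def logits(self, images: np.ndarray) -> np.ndarray:
        """(N,H,W,3) or (H,W,3) -> (N,C) fc_top logits."""
        return self.forward_batch(as_batch(images), "fc_top")["fc_top"]

    def predict(self, images: np.ndarray) -> np.ndarray:
        return np.argmax(self.logits(images), axis=1)

    def layer_extent(self, layer_name: str) -> int:
        """Number of 'neurons' (channels for conv, units for fc) at a layer."""
        name = resolve_layer(layer_name, self.layer_names)
        if name == "fc_top":
            return self.num_classes
        idx = self._name_to_index[name]
        return self.net.layers[idx - 1].c_out  # the conv before the ReLU


def forward(classifier: ClassifierNetwork, image: np.ndarray,
            terminal_layer: str = "fc_top") -> dict[str, np.ndarray]:
    """Module-level convenience wrapper around ClassifierNetwork.forward."""
    return classifier.forward(image, terminal_layer)


def backward_to_image(classifier: ClassifierNetwork, image: np.ndarray,
                      terminal_layer: str, error: np.ndarray) -> np.ndarray:
    return classifier.backward_to_image(image, terminal_layer, error)


# ---------------------------------------------------------------------------
# generator


class _SubtractMean:
    """Non-trainable encoder entry: centre images on the training mean."""

    def __init__(self, owner: "GeneratorNetwork"):
        self.owner = owner

    def forward(self, x):
        return x - self.owner.mean_image

    def backward(self, g):
        return g

    def params(self):
        return []

    def grads(self):
        return []


class _AddMeanClip:
    """Decoder exit: add the training mean back and clip to canonical range.

    Clipping keeps decode(z) a valid image for arbitrary codes; its gradient
    is zero for saturated pixels, the same convention pixel-space AM uses.
    """

    def __init__(self, owner: "GeneratorNetwork"):
        self.owner = owner

    def forward(self, x):
        y = x + self.owner.mean_image
        self._open = (y > 0.0) & (y < 1.0)
        return np.clip(y, 0.0, 1.0)

    def backward(self, g):
        return np.where(self._open, g, 0.0)

    def params(self):
        return []

    def grads(self):
        return []


class GeneratorNetwork:
    """Latent-to-image decoder: a mean-centred dense image codec.

    decode(z) = clip(W z + b + mean_image): codes index a learned affine
    subspace of image space (a data-driven low-dimensional image prior),
    squashed into canonical range. The paired encoder is the mirror-image
    affine map and exists only for training and inversion warm starts.
    Valid codes live in the per-dimension box [lower, upper], learned as the
    1st/99th percentiles of training-set codes and used for optional
    clamping during latent-space optimisation.
    """

    def __init__(self, latent_dim: int = 192, image_size: int = 32, seed: int = 0,
                 dtype=np.float64):
        rng = np.random.default_rng(np.random.SeedSequence((seed & 0xFFFFFFFF, 0xD6)))
        npix = image_size * image_size * 3
        self.dtype = np.dtype(dtype)
        self.mean_image = np.zeros((image_size, image_size, 3), dtype=dtype)
        dec_out = Dense(latent_dim, npix, rng, dtype)
        dec_out.w *= 0.1  # start decode(z) near the mean image
        self.decoder = Sequential([
            dec_out, Reshape((image_size, image_size, 3)), _AddMeanClip(self),
        ])
        self.encoder = Sequential([
            _SubtractMean(self), Flatten(), Dense(npix, latent_dim, rng, dtype),
        ])
        self.latent_dim = latent_dim
        self.image_size = image_size
        self.seed = seed
        self.latent_lower = np.full(latent_dim, -np.inf, dtype=dtype)
        self.latent_upper = np.full(latent_dim, np.inf, dtype=dtype)

    def _check_z(self, z: np.ndarray) -> np.ndarray:
        z = np.asarray(z, dtype=self.dtype)
        if z.shape[-1] != self.latent_dim:
            raise ValueError(f"latent length {z.shape[-1]} != {self.latent_dim}")
        if not np.isfinite(z).all():
            raise ValueError("latent vector contains non-finite entries")
        return z

    def decode_batch(self, z: np.ndarray) -> np.ndarray:
        """(N, D) codes -> (N, H, W, 3) images."""
        return self.decoder.forward(self._check_z(z))

    def decode(self, z: np.ndarray) -> np.ndarray:
        """(D,) code -> (H, W, 3) image in canonical range."""
        return self.decode_batch(self._check_z(z)[None])[0]

    def decode_backward(self, g_image: np.ndarray) -> np.ndarray:
        """Backprop an image-shaped gradient (batched, channels-last) to the
        latent; call right after decode_batch."""
        return self.decoder.backward(g_image)

    def encode_batch(self, images: np.ndarray) -> np.ndarray:
        return self.encoder.forward(as_batch(images))

    def encode(self, image: np.ndarray) -> np.ndarray:
        return self.encode_batch(image)[0]

    def clamp(self, z: np.ndarray) -> np.ndarray:
        return np.clip(z, self.latent_lower, self.latent_upper)


def decode(generator: GeneratorNetwork, z: np.ndarray) -> np.ndarray:
    return generator.decode(z)


def backward_to_latent(generator: GeneratorNetwork, classifier: ClassifierNetwork,
                       z: np.ndarray, terminal_layer: str, error: np.ndarray
                       ) -> np.ndarray:
    """Gradient of <error, activations(terminal_layer)> w.r.t. the latent z,
    chained through decode."""
    z = generator._check_z(z)
    img_batch = generator.decode_batch(z[None])
    acts = classifier.forward_batch(img_batch, terminal_layer)
    terminal = resolve_layer(terminal_layer, classifier.layer_names)
    if error.shape != acts[terminal].shape[1:]:
        raise ValueError(
            f"error shape {error.shape} != activation shape {acts[terminal].shape[1:]}")
    classifier.net.zero_grads()
    g_img = classifier.backward_batch(terminal, error[None])
    return generator.decode_backward(g_img)[0]


# ---------------------------------------------------------------------------
# training


def _require_trainable(dataset: LabelledImageSet) -> None:
    if dataset.spec.samples_per_class < MIN_SAMPLES_PER_CLASS:
        raise TrainingDataError(
            f"need >= {MIN_SAMPLES_PER_CLASS} samples/class to train fixture "
            f"networks, got {dataset.spec.samples_per_class}")


def _softmax(logits: np.ndarray) -> np.ndarray:
    e = np.exp(logits - logits.max(axis=1, keepdims=True))
    return e / e.sum(axis=1, keepdims=True)


def _augment_batch(xb: np.ndarray, rng: np.random.Generator, dtype) -> np.ndarray:
    """Noise + smoothing + contrast jitter, matched to generator artefacts."""
    out = xb.copy()
    half = len(out) // 2
    if half:  # smooth a random half with a 3x3 box filter (reflect edges)
        sel = rng.permutation(len(out))[:half]
        sm = out[sel]
        pad = np.pad(sm, ((0, 0), (1, 1), (1, 1), (0, 0)), mode="edge")
        acc = np.zeros_like(sm)
        for di in range(3):
            for dj in range(3):
                acc += pad[:, di:di + sm.shape[1], dj:dj + sm.shape[2], :]
        out[sel] = acc / 9.0
    # contrast jitter toward the batch mean, then pixel noise
    alpha = rng.uniform(0.7, 1.0, size=(len(out), 1, 1, 1)).astype(dtype)
    out = alpha * out + (1 - alpha) * out.mean(axis=(1, 2, 3), keepdims=True)
    out = out + rng.normal(0.0, 0.025, size=out.shape).astype(dtype)
    return np.clip(out, 0.0, 1.0)


def train_fixture_classifier(dataset: LabelledImageSet, epochs: int = 25,
                             seed: int = 0, lr: float = 2e-3,
                             batch_size: int = 32,
                             labels_override: np.ndarray | None = None,
                             augment: bool = True,
                             dtype=np.float32) -> ClassifierNetwork:
    """Train the reference classifier with Adam on softmax cross-entropy.

    With augment (default), minibatches are perturbed with pixel noise and
    occasional smoothing so the classifier stays reliable on the softer,
    lower-contrast images the generator produces. Deterministic given
    (dataset, epochs, seed). labels_override supports sanity checks with
    permuted labels.
    """
    _require_trainable(dataset)
    spec = dataset.spec
    clf = ClassifierNetwork(spec.num_classes, spec.image_size, seed=seed,
                            dtype=dtype)
    clf.categories = spec.categories
    labels = dataset.labels if labels_override is None else np.asarray(labels_override)
    x_tr, y_tr, _, _ = holdout_split(
        LabelledImageSet(dataset.images, labels, spec))
    batch = as_batch(x_tr).astype(dtype)
    clf.channel_mean = batch.mean(axis=(0, 1, 2), dtype=dtype)

    rng = np.random.default_rng(np.random.SeedSequence((seed & 0xFFFFFFFF, 0xA11)))
    opt = Adam(clf.net.params(), lr=lr)
    n = len(x_tr)
    for epoch in range(epochs):
        if epoch == int(epochs * 0.6):
            opt.lr = lr / 3.0
        if epoch == int(epochs * 0.85):
            opt.lr = lr / 10.0
        order = rng.permutation(n)
        for start in range(0, n, batch_size):
            idx = order[start: start + batch_size]
            xb, yb = batch[idx], y_tr[idx]
            if augment:
                xb = _augment_batch(xb, rng, dtype)
            logits = clf.forward_batch(xb, "fc_top")["fc_top"]
            p = _softmax(logits)
            g = p.copy()
            g[np.arange(len(yb)), yb] -= 1.0
            g /= len(yb)
            clf.net.zero_grads()
            clf.backward_batch("fc_top", g)
            opt.step(clf.net.grads())
    return clf


def train_fixture_generator(dataset: LabelledImageSet, epochs: int = 400,
                            seed: int = 0, lr: float = 3e-3,
                            batch_size: int = 64, latent_dim: int = 192,
                            dtype=np.float32) -> GeneratorNetwork:
    """Train the generator as a reconstructing autoencoder (MSE loss).

    The training-set mean image is the codec's fixed centring; after
    training, the valid latent box is set to the per-dimension 1st/99th
    percentiles of training-set codes.
    """
    _require_trainable(dataset)
    spec = dataset.spec
    gen = GeneratorNetwork(latent_dim, spec.image_size, seed=seed, dtype=dtype)
    x_tr, _, _, _ = holdout_split(dataset)
    batch = as_batch(x_tr).astype(dtype)
    gen.mean_image = batch.mean(axis=0, dtype=dtype)

    rng = np.random.default_rng(np.random.SeedSequence((seed & 0xFFFFFFFF, 0xAE)))
    params = gen.encoder.params() + gen.decoder.params()
    opt = Adam(params, lr=lr)
    n = len(x_tr)
    for epoch in range(epochs):
        if epoch == int(epochs * 0.65):
            opt.lr = lr / 2.5
        if epoch == int(epochs * 0.85):
            opt.lr = lr / 10.0
        order = rng.permutation(n)
        for start in range(0, n, batch_size):
            idx = order[start: start + batch_size]
            xb = batch[idx]
            z = gen.encoder.forward(xb)
            out = gen.decoder.forward(z)
            g = (2.0 * (out - xb) / out.size).astype(dtype)
            gen.encoder.zero_grads()
            gen.decoder.zero_grads()
            gz = gen.decoder.backward(g)
            gen.encoder.backward(gz)
            opt.step(gen.encoder.grads() + gen.decoder.grads())
    codes = gen.encoder.forward(batch)
    gen.latent_lower = np.quantile(codes, 0.01, axis=0).astype(dtype)
    gen.latent_upper = np.quantile(codes, 0.99, axis=0).astype(dtype)
    return gen


def reconstruction_rms(generator: GeneratorNetwork, images: np.ndarray) -> float:
    """Mean per-pixel RMS error of decode(encode(x)) over an image set."""
    batch = as_batch(images)
    out = generator.decode_batch(generator.encode_batch(images))
    return float(np.sqrt(np.mean((out - batch) ** 2)))


# ---------------------------------------------------------------------------
# persistence: .npz weights + JSON architecture sidecar


def save_classifier(clf: ClassifierNetwork, path: str | os.PathLike) -> None:
    path = os.fspath(path)
    arrays = {f"p{i}": p for i, p in enumerate(clf.net.params())}
    arrays["channel_mean"] = clf.channel_mean
    np.savez(path, **arrays)
    meta = {
        "kind": "classifier",
        "num_classes": clf.num_classes,
        "image_size": clf.image_size,
        "channels": list(clf.channels),
        "seed": clf.seed,
        "dtype": clf.dtype.name,
        "categories": list(clf.categories) if clf.categories else None,
    }
    with open(path + ".json", "w") as fh:
        json.dump(meta, fh, indent=1)


def load_classifier(path: str | os.PathLike) -> ClassifierNetwork:
    path = os.fspath(path)
    with open(path + ".json") as fh:
        meta = json.load(fh)
    clf = ClassifierNetwork(meta["num_classes"], meta["image_size"],
                            seed=meta["seed"], channels=tuple(meta["channels"]),
                            dtype=np.dtype(meta.get("dtype", "float64")))
    data = np.load(path if path.endswith(".npz") else path + ".npz")
    for i, p in enumerate(clf.net.params()):
        p[...] = data[f"p{i}"]
    clf.channel_mean = data["channel_mean"]
    if meta.get("categories"):
        clf.categories = tuple(meta["categories"])
    return clf


def save_generator(gen: GeneratorNetwork, path: str | os.PathLike) -> None:
    path = os.fspath(path)
    arrays = {f"d{i}": p for i, p in enumerate(gen.decoder.params())}
    arrays.update({f"e{i}": p for i, p in enumerate(gen.encoder.params())})
    arrays["mean_image"] = gen.mean_image
    arrays["latent_lower"] = gen.latent_lower
    arrays["latent_upper"] = gen.latent_upper
    np.savez(path, **arrays)
    meta = {
        "kind": "generator",
        "latent_dim": gen.latent_dim,
        "image_size": gen.image_size,
        "seed": gen.seed,
        "dtype": gen.dtype.name,
    }
    with open(path + ".json", "w") as fh:
        json.dump(meta, fh, indent=1)


def load_generator(path: str | os.PathLike) -> GeneratorNetwork:
    path = os.fspath(path)
    with open(path + ".json") as fh:
        meta = json.load(fh)
    gen = GeneratorNetwork(meta["latent_dim"], meta["image_size"],
                           seed=meta["seed"], dtype=np.dtype(meta["dtype"]))
    data = np.load(path if path.endswith(".npz") else path + ".npz")
    for i, p in enumerate(gen.decoder.params()):
        p[...] = data[f"d{i}"]
    for i, p in enumerate(gen.encoder.params()):
        p[...] = data[f"e{i}"]
    gen.mean_image = data["mean_image"]
    gen.latent_lower = data["latent_lower"]
    gen.latent_upper = data["latent_upper"]
    return gen
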