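"""Activation-maximisation engine.

Two optimisation loops share one structure: forward the current image to
the terminal layer, turn the activations into an error signal, backpropagate
it, and take a normalised ascent step.

* classical_am climbs directly in pixel space (the image itself is the
  optimisation variable, clipped to canonical range each step);
* generative_am climbs in the generator's latent space, so every iterate is
  decode(z) and stays on the generator's learned image manifold. The latent
  is initialised by inverting the (possibly degraded) input image, which
  anchors early iterations to the input.

Gradients are normalised by their mean absolute value before scaling by
step_size, making step sizes comparable across layers and networks. Given
fixed weights, input and config (including seed), trajectories are
bitwise reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from ._autodiff import Adam
from .error_functions import MODES
from .image import as_batch
from .networks import ClassifierNetwork, GeneratorNetwork, resolve_layer
from .presets import PhenomenologyPreset, apply_central_blur, make_preset

AM_TYPES = ("classical", "generative")
DEFAULT_STEP = {"classical": 0.02, "generative": 0.05}
DEFAULT_SNAPSHOTS = (10, 50, 100, 1000)
_EPS = 1e-12


@dataclass(frozen=True)
class AMConfig:
    """Complete parameterisation of one AM run."""

    am_type: str = "generative"
    error_function: str = "winner_take_all"
    terminal_layer: str = "fc_top"
    target_index: int | None = None
    iterations: int = 1000
    snapshot_iters: tuple[int, ...] = DEFAULT_SNAPSHOTS
    step_size: float | None = None  # None -> per-AM-type default
    latent_clamp: bool = True
    inversion_steps: int = 0
    deep_dream_initial_mask: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.am_type not in AM_TYPES:
            raise ValueError(f"am_type must be one of {AM_TYPES}")
        if self.error_function not in MODES:
            raise ValueError(f"error_function must be one of {MODES}")
        if self.iterations < 0:
            raise ValueError("iterations must be >= 0")
        snaps = tuple(sorted(self.snapshot_iters))
        object.__setattr__(self, "snapshot_iters", snaps)
        if snaps and snaps[0] < 1:
            raise ValueError("snapshot iterations must be >= 1")
        if snaps and snaps[-1] > self.iterations:
            raise ValueError(
                f"snapshot iteration {snaps[-1]} exceeds iterations={self.iterations}")
        if self.error_function == "fixed" and self.target_index is None:
            raise ValueError("fixed error function requires target_index")
        if self.step_size is not None and self.step_size <= 0:
            raise ValueError("step_size must be positive")
        if self.inversion_steps < 0:
            raise ValueError("inversion_steps must be >= 0")

    @property
    def resolved_step(self) -> float:
        return self.step_size if self.step_size is not None else DEFAULT_STEP[self.am_type]


@dataclass
class Trajectory:
    """Snapshots and per-iteration objective of one AM run.

    snapshots always include (0, input_image) — the possibly degraded input
    — plus one entry per configured snapshot iteration (1-based counting,
    'after iteration t'). objective_series[t-1] is the objective evaluated
    on the iterate entering iteration t.
    """

    snapshots: list[tuple[int, np.ndarray]]
    objective_series: np.ndarray
    config: AMConfig
    final: np.ndarray | None = None
    final_latent: np.ndarray | None = None

    @property
    def final_image(self) -> np.ndarray:
        """The image after the last iteration (for a 0-iteration generative
        run, the generator's reconstruction of the input)."""
        return self.final if self.final is not None else self.snapshots[-1][1]

    def snapshot_at(self, iteration: int) -> np.ndarray:
        for it, img in self.snapshots:
            if it == iteration:
                return img
        raise KeyError(f"no snapshot at iteration {iteration}")


# ---------------------------------------------------------------------------
# batched error-signal helpers (vectorised counterparts of error_functions)


def _batch_scalar_activation(acts: np.ndarray) -> np.ndarray:
    """(N, C) for fc; (N, H, W, C) -> per-channel mean -> (N, C)."""
    return acts if acts.ndim == 2 else acts.mean(axis=(1, 2))


def _batch_one_hot(acts: np.ndarray, idx: np.ndarray) -> np.ndarray:
    e = np.zeros_like(acts)
    rows = np.arange(acts.shape[0])
    if acts.ndim == 2:
        e[rows, idx] = 1.0
    else:
        h, w = acts.shape[1:3]
        e[rows, :, :, idx] = 1.0 / (h * w)
    return e


def _check_target(idx: int, extent: int) -> None:
    if not 0 <= idx < extent:
        raise ValueError(f"target index {idx} out of range [0, {extent})")


class _BatchErrorState:
    """Per-run error-function state (frozen WTA winners, deep-dream masks)."""

    def __init__(self, cfg: AMConfig, classifier: ClassifierNetwork,
                 input_batch: np.ndarray, targets: np.ndarray | None):
        self.cfg = cfg
        self.mask: np.ndarray | None = None
        input_acts = classifier.forward_batch(input_batch, cfg.terminal_layer)[
            resolve_layer(cfg.terminal_layer, classifier.layer_names)]
        if cfg.error_function == "fixed":
            extent = classifier.layer_extent(cfg.terminal_layer)
            for t in np.atleast_1d(targets):
                _check_target(int(t), extent)
            self.targets = np.broadcast_to(
                np.atleast_1d(targets), (input_batch.shape[0],)).astype(int)
        elif cfg.error_function == "winner_take_all":
            # winner decided once, from the original input, lowest index on ties
            self.targets = np.argmax(_batch_scalar_activation(input_acts), axis=1)
        else:
            self.targets = None
            if cfg.deep_dream_initial_mask:
                self.mask = (input_acts > 0).astype(float)

    def error(self, acts: np.ndarray) -> np.ndarray:
        if self.cfg.error_function == "deep_dream":
            return acts * self.mask if self.mask is not None else acts.copy()
        return _batch_one_hot(acts, self.targets)

    def objective(self, acts: np.ndarray, err: np.ndarray) -> np.ndarray:
        vals = (err * acts).sum(axis=tuple(range(1, acts.ndim)))
        return 0.5 * vals if self.cfg.error_function == "deep_dream" else vals


def _normalised(g: np.ndarray) -> np.ndarray:
    axes = tuple(range(1, g.ndim))
    scale = np.mean(np.abs(g), axis=axes, keepdims=True)
    return g / (scale + _EPS)


# ---------------------------------------------------------------------------
# core loops (batched; public single-image wrappers below)


def _snapshot_dict(cfg: AMConfig) -> set[int]:
    return set(cfg.snapshot_iters)


def classical_am_batch(classifier: ClassifierNetwork, inputs: np.ndarray,
                       config: AMConfig, targets=None
                       ) -> tuple[np.ndarray, np.ndarray, dict[int, np.ndarray]]:
    """Pixel-space AM over a batch. Returns (final images, objective series
    (N, iterations), snapshots {iteration: images})."""
    if config.am_type != "classical":
        raise ValueError("config.am_type must be 'classical'")
    x = as_batch(inputs).copy()
    if targets is None:
        targets = config.target_index
    state = _BatchErrorState(config, classifier, x, targets)
    layer = resolve_layer(config.terminal_layer, classifier.layer_names)
    step = config.resolved_step
    snaps_at = _snapshot_dict(config)
    objectives = np.zeros((x.shape[0], config.iterations))
    snapshots: dict[int, np.ndarray] = {}
    for t in range(1, config.iterations + 1):
        acts = classifier.forward_batch(x, layer)[layer]
        err = state.error(acts)
        objectives[:, t - 1] = state.objective(acts, err)
        classifier.net.zero_grads()
        g = classifier.backward_batch(layer, err)
        x = np.clip(x + step * _normalised(g), 0.0, 1.0)
        if t in snaps_at:
            snapshots[t] = x.copy()
    return x, objectives, snapshots


def invert_latent(generator: GeneratorNetwork, target_image: np.ndarray,
                  inversion_steps: int = 0, seed: int = 0) -> np.ndarray:
    """Latent code reconstructing target_image: encoder warm start (zeros if
    the generator has no paired encoder) refined by Adam descent on the
    reconstruction MSE."""
    z = _invert_latent_batch(generator, as_batch(target_image), inversion_steps)
    return z[0] if np.asarray(target_image).ndim == 3 else z


def _invert_latent_batch(generator: GeneratorNetwork, targets: np.ndarray,
                         inversion_steps: int) -> np.ndarray:
    if getattr(generator, "encoder", None) is not None:
        z = generator.encode_batch(targets)
    else:
        z = np.zeros((targets.shape[0], generator.latent_dim))
    if inversion_steps == 0:
        return z
    z = z.copy()
    opt = Adam([z], lr=0.05)

    def loss_of(code: np.ndarray) -> float:
        return float(np.mean((generator.decode_batch(code) - targets) ** 2))

    best_z, best_loss = z.copy(), loss_of(z)
    for _ in range(inversion_steps):
        out = generator.decode_batch(z)
        g = 2.0 * (out - targets) / out[0].size
        generator.decoder.zero_grads()
        gz = generator.decoder.backward(g)
        opt.step([gz])
        loss = loss_of(z)
        if loss < best_loss:
            best_z, best_loss = z.copy(), loss
    return best_z


def generative_am_batch(classifier: ClassifierNetwork, generator: GeneratorNetwork,
                        inputs: np.ndarray, config: AMConfig, targets=None
                        ) -> tuple[np.ndarray, np.ndarray, dict[int, np.ndarray],
                                   np.ndarray]:
    """Latent-space AM over a batch. Returns (final images, objectives,
    snapshots, final latents)."""
    if config.am_type != "generative":
        raise ValueError("config.am_type must be 'generative'")
    x_in = as_batch(inputs)
    if targets is None:
        targets = config.target_index
    state = _BatchErrorState(config, classifier, x_in, targets)
    layer = resolve_layer(config.terminal_layer, classifier.layer_names)
    step = config.resolved_step
    z = _invert_latent_batch(generator, x_in, config.inversion_steps)
    if config.latent_clamp:
        z = generator.clamp(z)
    snaps_at = _snapshot_dict(config)
    objectives = np.zeros((x_in.shape[0], config.iterations))
    snapshots: dict[int, np.ndarray] = {}
    for t in range(1, config.iterations + 1):
        x = generator.decode_batch(z)
        acts = classifier.forward_batch(x, layer)[layer]
        err = state.error(acts)
        objectives[:, t - 1] = state.objective(acts, err)
        classifier.net.zero_grads()
        g_img = classifier.backward_batch(layer, err)
        gz = generator.decode_backward(g_img)
        z = z + step * _normalised(gz)
        if config.latent_clamp:
            z = generator.clamp(z)
        if t in snaps_at:
            snapshots[t] = generator.decode_batch(z)
    return generator.decode_batch(z), objectives, snapshots, z


def _to_trajectory(input_image: np.ndarray, objectives: np.ndarray,
                   snapshots: dict[int, np.ndarray], config: AMConfig,
                   final: np.ndarray, final_latent: np.ndarray | None = None
                   ) -> Trajectory:
    entries = [(0, np.asarray(input_image).copy())]
    entries += [(t, snapshots[t][0]) for t in sorted(snapshots)]
    return Trajectory(snapshots=entries, objective_series=objectives[0],
                      config=config, final=final[0], final_latent=final_latent)


def classical_am(classifier: ClassifierNetwork, input_image: np.ndarray,
                 config: AMConfig) -> Trajectory:
    """Single-image pixel-space AM; a 0-iteration run returns the input."""
    final, obj, snaps = classical_am_batch(classifier, input_image, config)
    return _to_trajectory(input_image, obj, snaps, config, final)


def generative_am(classifier: ClassifierNetwork, generator: GeneratorNetwork,
                  input_image: np.ndarray, config: AMConfig) -> Trajectory:
    """Single-image latent-space AM.

    With iterations == 0 the final image is the generator's reconstruction
    of the input, decode(invert_latent(input)).
    """
    final, obj, snaps, z = generative_am_batch(classifier, generator,
                                               input_image, config)
    return _to_trajectory(input_image, obj, snaps, config, final, final_latent=z[0])


# ---------------------------------------------------------------------------
# preset dispatch


@dataclass
class NetworkBundle:
    classifier: ClassifierNetwork
    generator: GeneratorNetwork | None = None


def config_from_preset(preset: PhenomenologyPreset, seed: int = 0,
                       iterations: int = 1000,
                       snapshot_iters: tuple[int, ...] | None = None,
                       target_index: int | None = None,
                       step_size: float | None = None) -> AMConfig:
    """Materialise an AMConfig from a preset; for fixed-error presets the
    target is drawn from the preset's target list using the seed (unless
    given explicitly)."""
    if preset.error_function == "fixed" and target_index is None:
        rng = np.random.default_rng(np.random.SeedSequence((seed & 0xFFFFFFFF, 0x7A)))
        target_index = int(rng.choice(preset.fixed_targets))
    if snapshot_iters is None:
        snapshot_iters = tuple(t for t in DEFAULT_SNAPSHOTS if t <= iterations)
    return AMConfig(
        am_type=preset.am_type,
        error_function=preset.error_function,
        terminal_layer=preset.terminal_layer,
        target_index=target_index,
        iterations=iterations,
        snapshot_iters=snapshot_iters,
        step_size=step_size,
        seed=seed,
    )


def run_simulation(preset_or_config: str | PhenomenologyPreset | AMConfig,
                   input_image: np.ndarray,
                   networks: NetworkBundle | tuple,
                   seed: int | None = None,
                   **overrides) -> Trajectory:
    """Resolve a preset (applying its input degradation), then dispatch to
    classical_am or generative_am. Pure computation; nothing is persisted."""
    if isinstance(networks, tuple):
        networks = NetworkBundle(*networks)
    degraded = np.asarray(input_image)
    if isinstance(preset_or_config, AMConfig):
        config = preset_or_config if seed is None else replace(
            preset_or_config, seed=seed)
    else:
        preset = (make_preset(preset_or_config)
                  if isinstance(preset_or_config, str) else preset_or_config)
        if preset.degradation is not None:
            degraded = apply_central_blur(degraded, preset.degradation)
        config = config_from_preset(preset, seed=0 if seed is None else seed,
                                    **overrides)
    if config.am_type == "classical":
        return classical_am(networks.classifier, degraded, config)
    if networks.generator is None:
        raise ValueError("generative AM requires a generator network")
    return generative_am(networks.classifier, networks.generator, degraded, config)
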