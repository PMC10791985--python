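"""Error functions: how terminal-layer activations become the signal that
activation maximisation backpropagates.

Three modes, one per hallucination-relevant behaviour:

* fixed — a researcher-chosen target neuron returns the error regardless of
  the input (input-independent, hence "spontaneous" content);
* deep_dream — every neuron returns an error proportional to its current
  activation (objective 1/2 * ||a||^2), so content grows out of whatever the
  input already excites;
* winner_take_all — the single neuron most activated by the original input
  is chosen once, at the first call, and kept for the whole run; all other
  errors are zero. This mimics input-driven but maximally confident
  perception and is the benchmark (non-hallucinatory) setting.

"Neuron" at a fully connected layer is a single unit; at a convolutional
layer it is a whole channel, and the one-hot objective is that channel's
mean activation (a single spatial unit can be targeted instead via
error_fixed's `unit` argument). Argmax ties break to the lowest index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

MODES = ("fixed", "deep_dream", "winner_take_all")


@dataclass
class TargetSelection:
    """Mutable selection state for one AM run.

    For winner_take_all, frozen_index is filled in on the first call and
    never re-evaluated — the winner is decided by the original input.
    """

    mode: str
    target_index: int | None = None
    frozen_index: int | None = None

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown error-function mode {self.mode!r}")
        if self.mode == "fixed" and self.target_index is None:
            raise ValueError("fixed mode requires target_index")


def _num_neurons(activations: np.ndarray) -> int:
    """fc layers: unit count; conv layers (H, W, C): channel count."""
    return activations.shape[-1]


def _one_hot_signal(activations: np.ndarray, index: int) -> np.ndarray:
    """Error selecting one neuron: unit one-hot at fc layers; at conv layers
    a uniform map over the chosen channel so <e, a> is the channel mean."""
    n = _num_neurons(activations)
    if not 0 <= index < n:
        raise ValueError(f"target index {index} out of range [0, {n})")
    e = np.zeros_like(activations)
    if activations.ndim == 1:
        e[index] = 1.0
    else:
        e[:, :, index] = 1.0 / (activations.shape[0] * activations.shape[1])
    return e


def _channel_activation(activations: np.ndarray) -> np.ndarray:
    """Per-neuron scalar activation: identity at fc, spatial mean at conv."""
    if activations.ndim == 1:
        return activations
    return activations.mean(axis=(0, 1))


def error_fixed(activations: np.ndarray, target_index: int,
                unit: tuple[int, int] | None = None) -> np.ndarray:
    """One-hot error at a pre-selected neuron; ignores the activations
    (objective = a_target).

    At a convolutional layer the target is the whole channel by default;
    pass unit=(row, col) to target one spatial unit of that channel.
    """
    if unit is not None:
        if activations.ndim != 3:
            raise ValueError("unit targeting applies to convolutional layers only")
        n = _num_neurons(activations)
        if not 0 <= target_index < n:
            raise ValueError(f"target index {target_index} out of range [0, {n})")
        e = np.zeros_like(activations)
        e[unit[0], unit[1], target_index] = 1.0
        return e
    return _one_hot_signal(activations, target_index)


def error_deep_dream(activations: np.ndarray,
                     initial_mask: np.ndarray | None = None) -> np.ndarray:
    """Error equal to the activations themselves (objective = 1/2 ||a||^2).

    Neurons at zero activation contribute nothing. With initial_mask (a
    boolean tensor of the neurons active at iteration 0), the signal is
    restricted to those initially active neurons.
    """
    e = np.asarray(activations, dtype=float).copy()
    if initial_mask is not None:
        e = e * initial_mask
    return e


def error_winner_take_all(activations: np.ndarray,
                          selection: TargetSelection) -> np.ndarray:
    """Freeze the argmax neuron on the first call; one-hot ever after.

    At conv layers the winner is the channel with the highest mean
    activation. Ties break to the lowest index.
    """
    if selection.mode != "winner_take_all":
        raise ValueError("selection.mode must be 'winner_take_all'")
    if selection.frozen_index is None:
        selection.frozen_index = int(np.argmax(_channel_activation(activations)))
    return _one_hot_signal(activations, selection.frozen_index)


def error_signal(activations: np.ndarray, selection: TargetSelection,
                 initial_mask: np.ndarray | None = None) -> np.ndarray:
    """Dispatch on selection.mode."""
    if selection.mode == "fixed":
        return error_fixed(activations, selection.target_index)
    if selection.mode == "deep_dream":
        return error_deep_dream(activations, initial_mask)
    return error_winner_take_all(activations, selection)


def objective_value(activations: np.ndarray, selection: TargetSelection,
                    initial_mask: np.ndarray | None = None) -> float:
    """The scalar each mode climbs: a_j for one-hot modes, 1/2 ||a||^2 for
    deep-dream (equal to <e, a> in every mode)."""
    e = error_signal(activations, selection, initial_mask)
    val = float(np.sum(e * activations))
    return 0.5 * val if selection.mode == "deep_dream" else val
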