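"""Phenomenology presets: aetiology-specific parameter bundles.

Each preset fixes the three orthogonal manipulations — AM type
(veridicality), error function (spontaneity), terminal layer (complexity) —
plus, for visual-loss simulations, a central-blur degradation of the input
image that stands in for the central visual-field deficit of Charles Bonnet
Syndrome.

| preset                     | AM type    | error       | layer           | blur |
|----------------------------|------------|-------------|-----------------|------|
| benchmark                  | generative | WTA         | categorical_top | no   |
| neurodegenerative_complex  | generative | fixed       | categorical_top | no   |
| cbs_complex                | generative | fixed       | categorical_top | yes  |
| cbs_simple                 | generative | fixed       | lower_conv      | yes  |
| psychedelic_complex        | classical  | deep_dream  | categorical_top | no   |
| psychedelic_simple         | classical  | deep_dream  | lower_conv      | no   |

Layer roles are symbolic: categorical_top resolves to the classifier's top
categorical layer ("fc_top", alias "fc8") and lower_conv to the designated
lower convolutional layer ("conv2", alias "conv4").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .image import validate_image

LAYER_ROLES = {"categorical_top": "fc_top", "lower_conv": "conv2"}

# Five fixed-mode targets, mirroring a handful of randomly drawn categorical
# units; at the top layer these index fixture categories, at a conv layer
# they index channels of that layer.
DEFAULT_FIXED_TARGETS_TOP = (0, 2, 3, 5, 7)
DEFAULT_FIXED_TARGETS_CONV = (1, 7, 13, 19, 29)


@dataclass(frozen=True)
class BlurParams:
    """Soft circular Gaussian blur over the image centre.

    All lengths are fractions of min(H, W): radius_frac is the fully blurred
    disc, edge_soften_frac the feather width over which the blur fades out,
    sigma_frac the Gaussian sigma. Pixels strictly outside
    radius + feather are untouched.
    """

    center: tuple[float, float] = (0.5, 0.5)  # fractional (y, x)
    radius_frac: float = 0.40
    sigma_frac: float = 0.10
    edge_soften_frac: float = 0.05

    def __post_init__(self) -> None:
        for name in ("radius_frac", "sigma_frac", "edge_soften_frac"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.radius_frac + self.edge_soften_frac > 1.0:
            raise ValueError("radius_frac + edge_soften_frac must be <= 1")


@dataclass(frozen=True)
class PhenomenologyPreset:
    """Frozen (AM type, error function, layer role, degradation) bundle."""

    name: str
    am_type: str                      # "classical" | "generative"
    error_function: str               # "fixed" | "deep_dream" | "winner_take_all"
    terminal_layer_role: str          # "categorical_top" | "lower_conv"
    degradation: BlurParams | None = None
    fixed_targets: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if (self.fixed_targets is not None) != (self.error_function == "fixed"):
            raise ValueError("fixed_targets present iff error_function == 'fixed'")

    @property
    def terminal_layer(self) -> str:
        return LAYER_ROLES[self.terminal_layer_role]


_PRESETS: dict[str, PhenomenologyPreset] = {
    "benchmark": PhenomenologyPreset(
        "benchmark", "generative", "winner_take_all", "categorical_top"),
    "neurodegenerative_complex": PhenomenologyPreset(
        "neurodegenerative_complex", "generative", "fixed", "categorical_top",
        fixed_targets=DEFAULT_FIXED_TARGETS_TOP),
    "cbs_complex": PhenomenologyPreset(
        "cbs_complex", "generative", "fixed", "categorical_top",
        degradation=BlurParams(), fixed_targets=DEFAULT_FIXED_TARGETS_TOP),
    "cbs_simple": PhenomenologyPreset(
        "cbs_simple", "generative", "fixed", "lower_conv",
        degradation=BlurParams(), fixed_targets=DEFAULT_FIXED_TARGETS_CONV),
    "psychedelic_complex": PhenomenologyPreset(
        "psychedelic_complex", "classical", "deep_dream", "categorical_top"),
    "psychedelic_simple": PhenomenologyPreset(
        "psychedelic_simple", "classical", "deep_dream", "lower_conv"),
}

PRESET_NAMES = tuple(_PRESETS)


def make_preset(name: str) -> PhenomenologyPreset:
    """Look up the frozen parameter bundle for an aetiology."""
    try:
        return _PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; known: {', '.join(PRESET_NAMES)}") from None


def apply_central_blur(image: np.ndarray, params: BlurParams | None = None
                       ) -> np.ndarray:
    """Composite a Gaussian-blurred copy over the image through a soft
    circular mask centred on params.center.

    The mask is 1 inside radius_frac, falls smoothly to 0 across
    edge_soften_frac, and is exactly 0 beyond — so pixels strictly outside
    radius + feather are bitwise unchanged.
    """
    params = params or BlurParams()
    image = validate_image(image)
    h, w, _ = image.shape
    scale = min(h, w)
    sigma = params.sigma_frac * scale
    if sigma < 0.5:  # below half a pixel the blur is an identity
        return image.copy()
    blurred = np.stack([
        ndimage.gaussian_filter(image[:, :, c], sigma=sigma, mode="nearest")
        for c in range(3)], axis=-1)

    cy, cx = params.center[0] * h, params.center[1] * w
    yy, xx = np.mgrid[0:h, 0:w].astype(float) + 0.5
    dist = np.hypot(yy - cy, xx - cx)
    r0 = params.radius_frac * scale
    feather = max(params.edge_soften_frac * scale, 1e-9)
    t = np.clip((dist - r0) / feather, 0.0, 1.0)
    mask = (1.0 - t) ** 2 * (1.0 + 2.0 * t)  # smoothstep-style falloff, exact 0 at t=1
    out = np.where(mask[:, :, None] > 0.0,
                   mask[:, :, None] * blurred + (1.0 - mask[:, :, None]) * image,
                   image)
    return np.clip(out, 0.0, 1.0)
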