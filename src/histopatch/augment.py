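"""Random flip / rotation / translation augmentation for training patches.

Three sequential layers, applied in order: Bernoulli horizontal flip,
Bernoulli vertical flip, rotation by a uniform random angle, translation by
uniform random fractions of each dimension. Shape and label are preserved;
augmentation belongs only to the training stream.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from histopatch.patching import PatchRecord


@dataclass(frozen=True)
class AugmentSpec:
    p_hflip: float = 0.5
    p_vflip: float = 0.5
    max_rotation_degrees: float = 15.0
    max_translation_fraction: float = 0.1
    fill_mode: str = "reflect"  # or "constant"
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.p_hflip, self.p_vflip):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"flip probabilities must be in [0,1], got {p}")
        if not 0.0 <= self.max_translation_fraction < 1.0:
            raise ValueError("max_translation_fraction must be in [0, 1)")
        if self.fill_mode not in ("reflect", "constant"):
            raise ValueError(f"unknown fill_mode {self.fill_mode!r}")


def augment_pixels(pixels: np.ndarray, spec: AugmentSpec, draw: np.random.Generator) -> np.ndarray:
    """Apply the flip/rotate/translate stack to an HxWx3 array."""
    out = pixels
    if draw.random() < spec.p_hflip:
        out = np.flip(out, axis=1)
    if draw.random() < spec.p_vflip:
        out = np.flip(out, axis=0)
    angle = draw.uniform(-spec.max_rotation_degrees, spec.max_rotation_degrees)
    if angle != 0.0:
        out = ndimage.rotate(
            out,
            angle,
            axes=(0, 1),
            reshape=False,
            order=1,  # bilinear
            mode=spec.fill_mode,
            cval=0.0,
        )
    h, w = out.shape[:2]
    dy = draw.uniform(-spec.max_translation_fraction, spec.max_translation_fraction) * h
    dx = draw.uniform(-spec.max_translation_fraction, spec.max_translation_fraction) * w
    if dy != 0.0 or dx != 0.0:
        out = ndimage.shift(out, (dy, dx, 0), order=1, mode=spec.fill_mode, cval=0.0)
    return np.clip(out, 0.0, 1.0).astype(pixels.dtype)


def augment(patch: PatchRecord, spec: AugmentSpec, draw: np.random.Generator | None = None) -> PatchRecord:
    """Augment one patch; deterministic given the random state.

    With no explicit state, a generator seeded from ``spec.seed`` is used.
    """
    if draw is None:
        draw = np.random.default_rng(spec.seed)
    return replace(patch, pixels=augment_pixels(patch.pixels, spec, draw))


def expand_training_patches(
    patches: list[PatchRecord], spec: AugmentSpec, n_copies: int = 1
) -> list[PatchRecord]:
    """Offline expansion: the originals plus ``n_copies`` augmented copies of
    each, deterministic given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    out = list(patches)
    for _ in range(n_copies):
        for p in patches:
            out.append(augment(p, spec, rng))
    return out
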