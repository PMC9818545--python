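"""Macenko stain normalization for H&E images.

Stain contributions are additive in optical-density space (Beer-Lambert):
``OD = -log10(I / I0) = M @ C`` with ``M`` the 3x2 stain matrix (columns
hematoxylin, eosin) and ``C`` the per-pixel concentrations. The Macenko
estimator projects tissue OD pixels onto their top-2 principal plane and
takes the directions at extreme percentile angles as the stain vectors.
Normalization maps a patch into a template's color space by estimating the
patch's own stain model, rescaling concentrations so the per-stain 99th
percentiles match the template's, and reconstructing through the template
stain matrix.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from histopatch.io_dataset import ImageRecord
from histopatch.patching import PatchRecord

#: Macenko defaults: OD tissue threshold (beta), extreme-angle percentile
#: (alpha, i.e. the 1st/99th percentile angles), concentration scale
#: percentile, and background intensity in [0,1] pixel space.
OD_THRESHOLD = 0.15
ANGLE_PERCENTILE = 1.0
CONCENTRATION_PERCENTILE = 99.0
BACKGROUND_INTENSITY = 1.0

_EPS = 1e-6


class DegenerateImageError(ValueError):
    """Raised when an image has too little tissue (or a single stain) for
    stain-vector estimation."""


@dataclass
class StainModel:
    """Estimated stain matrix, concentration scales and background intensity.

    ``stain_matrix`` columns are unit-norm, nonnegative OD vectors; column 0
    is hematoxylin, column 1 eosin. ``max_concentrations`` holds the
    per-stain 99th-percentile concentration used for rescaling.
    """

    stain_matrix: np.ndarray
    max_concentrations: np.ndarray
    background_intensity: float = BACKGROUND_INTENSITY

    def __post_init__(self) -> None:
        self.stain_matrix = np.asarray(self.stain_matrix, dtype=float)
        self.max_concentrations = np.asarray(self.max_concentrations, dtype=float)
        if self.stain_matrix.shape != (3, 2):
            raise ValueError(f"stain matrix must be 3x2, got {self.stain_matrix.shape}")
        norms = np.linalg.norm(self.stain_matrix, axis=0)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError(f"stain matrix columns must be unit norm, got {norms}")
        if (self.stain_matrix < -1e-9).any():
            raise ValueError("stain matrix entries must be nonnegative")
        if (self.max_concentrations <= 0).any():
            raise ValueError(f"max_concentrations must be positive, got {self.max_concentrations}")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "stain_matrix": self.stain_matrix.tolist(),
                    "max_concentrations": self.max_concentrations.tolist(),
                    "background_intensity": self.background_intensity,
                },
                indent=2,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "StainModel":
        d = json.loads(Path(path).read_text())
        return cls(
            stain_matrix=np.array(d["stain_matrix"]),
            max_concentrations=np.array(d["max_concentrations"]),
            background_intensity=float(d["background_intensity"]),
        )


def rgb_to_od(pixels: np.ndarray, background_intensity: float = BACKGROUND_INTENSITY) -> np.ndarray:
    """Optical density ``-log10((I + eps) / I0)`` per channel."""
    if background_intensity <= 0:
        raise ValueError("background_intensity must be positive")
    return -np.log10((np.asarray(pixels, dtype=np.float64) + _EPS) / background_intensity)


def od_to_rgb(od: np.ndarray, background_intensity: float = BACKGROUND_INTENSITY) -> np.ndarray:
    """Invert :func:`rgb_to_od`: ``I0 * 10**(-OD)``, clipped to [0, 1]."""
    return np.clip(background_intensity * np.power(10.0, -np.asarray(od, dtype=np.float64)), 0.0, 1.0)


def _nonneg_unit(v: np.ndarray) -> np.ndarray:
    """Sign-fix a direction to nonnegative orthant (flip if the entry sum is
    negative, clip residual negatives) and unit-normalize."""
    if v.sum() < 0:
        v = -v
    v = np.clip(v, 0.0, None)
    n = np.linalg.norm(v)
    if n == 0:
        raise DegenerateImageError("estimated stain vector collapsed to zero")
    return v / n


def concentrations(
    pixels: np.ndarray,
    stain_matrix: np.ndarray,
    background_intensity: float = BACKGROUND_INTENSITY,
    method: str = "nnls",
) -> np.ndarray:
    """Per-pixel stain concentrations solved against a 3x2 stain matrix.

    ``method="nnls"`` solves the two-variable nonnegative least-squares
    problem exactly in closed form (concentrations are physical, hence
    nonnegative); ``method="clip"`` is the plain least-squares fast path
    with clipping at zero.
    """
    od = rgb_to_od(pixels, background_intensity)
    shape = od.shape[:-1]
    od = od.reshape(-1, 3)
    a = np.asarray(stain_matrix, dtype=np.float64)
    gram = a.T @ a
    rhs = od @ a  # N x 2
    unconstrained = rhs @ np.linalg.inv(gram).T
    if method == "clip":
        c = np.clip(unconstrained, 0.0, None)
    elif method == "nnls":
        # exact 2-variable NNLS: the solution is the unconstrained one if
        # feasible, else the better of the two single-stain projections
        c = unconstrained.copy()
        infeasible = (unconstrained < 0).any(axis=1)
        if infeasible.any():
            od_i = od[infeasible]
            cand = np.zeros((2, od_i.shape[0], 2))
            cand[0, :, 0] = np.clip(od_i @ a[:, 0] / gram[0, 0], 0.0, None)
            cand[1, :, 1] = np.clip(od_i @ a[:, 1] / gram[1, 1], 0.0, None)
            resid = [np.sum((od_i - cand[k] @ a.T) ** 2, axis=1) for k in range(2)]
            c[infeasible] = np.where((resid[0] <= resid[1])[:, None], cand[0], cand[1])
    else:
        raise ValueError(f"unknown concentration method {method!r}")
    return c.reshape(*shape, 2)


def estimate_stains(
    pixels: np.ndarray,
    od_threshold: float = OD_THRESHOLD,
    angle_percentile: float = ANGLE_PERCENTILE,
    background_intensity: float = BACKGROUND_INTENSITY,
) -> StainModel:
    """Macenko stain-vector estimation.

    Tissue pixels (all-channel OD >= threshold) are projected onto the top-2
    principal plane of their OD cloud; the stain vectors are the directions
    at the ``angle_percentile``-th and ``(100 - angle_percentile)``-th
    percentile angles, sign-fixed to the nonnegative orthant and
    unit-normalized. Hematoxylin (column 0) is the vector with the larger
    red-to-blue OD ratio — hematoxylin looks blue because it absorbs
    red/green light. Concentration scales are per-stain 99th percentiles
    over all pixels.
    """
    od = rgb_to_od(pixels, background_intensity).reshape(-1, 3)
    tissue = od[(od >= od_threshold).all(axis=1)]
    if tissue.shape[0] < 2:
        raise DegenerateImageError(
            f"need at least 2 tissue pixels above OD threshold {od_threshold}, got {tissue.shape[0]}"
        )
    cov = np.cov(tissue, rowvar=False)
    evals, evecs = np.linalg.eigh(cov)
    if evals[-2] <= max(1e-3 * evals[-1], 1e-12):
        raise DegenerateImageError(
            "optical-density cloud is rank 1 (single stain): cannot separate two stain vectors"
        )
    plane = evecs[:, -2:]  # top-2 principal directions
    for k in range(2):  # sign convention: entries sum nonnegative
        if plane[:, k].sum() < 0:
            plane[:, k] = -plane[:, k]
    proj = tissue @ plane
    angles = np.arctan2(proj[:, 1], proj[:, 0])
    lo = np.percentile(angles, angle_percentile)
    hi = np.percentile(angles, 100.0 - angle_percentile)
    v_lo = _nonneg_unit(plane @ np.array([np.cos(lo), np.sin(lo)]))
    v_hi = _nonneg_unit(plane @ np.array([np.cos(hi), np.sin(hi)]))
    # hematoxylin = larger red-to-blue OD ratio
    def red_blue(v: np.ndarray) -> float:
        return v[0] / (v[2] + 1e-12)

    h, e = (v_lo, v_hi) if red_blue(v_lo) >= red_blue(v_hi) else (v_hi, v_lo)
    matrix = np.stack([h, e], axis=1)
    conc = concentrations(pixels, matrix, background_intensity)
    max_c = np.percentile(conc.reshape(-1, 2), CONCENTRATION_PERCENTILE, axis=0)
    max_c = np.maximum(max_c, 1e-9)
    return StainModel(
        stain_matrix=matrix,
        max_concentrations=max_c,
        background_intensity=background_intensity,
    )


def normalize_pixels(
    pixels: np.ndarray,
    template: StainModel,
    od_threshold: float = OD_THRESHOLD,
    angle_percentile: float = ANGLE_PERCENTILE,
    method: str = "nnls",
) -> np.ndarray:
    """Map pixels into the template's color space (see module docstring)."""
    source = estimate_stains(
        pixels,
        od_threshold=od_threshold,
        angle_percentile=angle_percentile,
        background_intensity=template.background_intensity,
    )
    conc = concentrations(pixels, source.stain_matrix, template.background_intensity, method=method)
    conc = conc * (template.max_concentrations / source.max_concentrations)
    od = conc @ template.stain_matrix.T
    return od_to_rgb(od, template.background_intensity).astype(np.float32)


def normalize_to_template(
    patch: PatchRecord,
    template: StainModel,
    od_threshold: float = OD_THRESHOLD,
    angle_percentile: float = ANGLE_PERCENTILE,
    method: str = "nnls",
    fallback_passthrough: bool = False,
) -> PatchRecord:
    """Stain-normalize one patch to a template model.

    Label and grid coordinates are preserved. A degenerate patch (no
    estimable stains) raises with the patch identity attached, unless
    ``fallback_passthrough`` elects to return the patch unnormalized.
    """
    try:
        pixels = normalize_pixels(
            patch.pixels, template, od_threshold, angle_percentile, method=method
        )
    except DegenerateImageError as exc:
        if fallback_passthrough:
            return replace(patch, pixels=patch.pixels.copy())
        raise DegenerateImageError(f"patch {patch.patch_id}: {exc}") from exc
    return replace(patch, pixels=pixels)


def normalize_image(
    image: ImageRecord,
    template: StainModel,
    od_threshold: float = OD_THRESHOLD,
    angle_percentile: float = ANGLE_PERCENTILE,
    method: str = "nnls",
) -> ImageRecord:
    """Image-level normalization mode (whole image instead of per patch)."""
    pixels = normalize_pixels(image.pixels, template, od_threshold, angle_percentile, method=method)
    return ImageRecord(image_id=image.image_id, pixels=pixels, label=image.label, split=image.split)


def separate_stains(pixels: np.ndarray, model: StainModel) -> tuple[np.ndarray, np.ndarray]:
    """Single-stain reconstructions (hematoxylin image, eosin image) obtained
    by zeroing the other concentration channel."""
    conc = concentrations(pixels, model.stain_matrix, model.background_intensity)
    out = []
    for k in range(2):
        only = np.zeros_like(conc)
        only[..., k] = conc[..., k]
        out.append(
            od_to_rgb(only @ model.stain_matrix.T, model.background_intensity).astype(np.float32)
        )
    return out[0], out[1]


def angle_between_deg(u: np.ndarray, v: np.ndarray) -> float:
    """Angle between two stain vectors in degrees."""
    cos = float(np.clip(u @ v / (np.linalg.norm(u) * np.linalg.norm(v)), -1.0, 1.0))
    return float(np.degrees(np.arccos(cos)))
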