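"""Synthetic H&E-like fixture images with known stain ground truth.

Images are rendered through a two-stain Beer-Lambert model: per-pixel
optical density is ``OD = M @ C`` where ``M`` is a known 3x2 stain matrix
(columns hematoxylin, eosin; unit norm) and ``C`` the two concentration
fields, and pixels are ``background * 10**(-OD)`` plus optional Gaussian
noise. The hematoxylin field is a sum of Gaussian blobs at sampled nuclei
centers — class identity is carried by nuclei density (and mildly by blob
radius), strictly ordered normal < benign < insitu < invasive so the four
classes are separable by construction. The eosin field is a smooth random
background texture, emulating cytoplasm/stroma.

Because the generative stain matrix is known, stain-vector estimation is
checkable against ground truth; because class signal is a monotone density,
a tiny backbone suffices to separate the classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage

from histopatch.io_dataset import CLASSES, CLASS_TO_INDEX, ImageRecord

#: Default generative stain matrix (columns: hematoxylin, eosin) in RGB
#: optical-density space. Hematoxylin absorbs red/green (tissue looks blue),
#: eosin absorbs mostly green (tissue looks pink). All channels are kept
#: well away from zero so weakly stained pixels survive OD thresholding.
DEFAULT_STAIN_MATRIX = np.array(
    [
        [0.65, 0.25],
        [0.70, 0.91],
        [0.29, 0.33],
    ]
)
DEFAULT_STAIN_MATRIX = DEFAULT_STAIN_MATRIX / np.linalg.norm(DEFAULT_STAIN_MATRIX, axis=0)


@dataclass(frozen=True)
class TextureParams:
    """Per-class nuclei texture: density (nuclei per megapixel), Gaussian
    blob sigma in pixels, peak hematoxylin concentration per nucleus, and
    the fraction of the image area nuclei are confined to (confinement < 1
    makes some patches of a cancerous image look normal — deliberate patch
    label noise)."""

    nuclei_per_mpx: float
    blob_sigma: float
    amplitude: float = 2.5
    confine_fraction: float = 1.0


def _easy_textures() -> dict[str, TextureParams]:
    return {
        "normal": TextureParams(60.0, 10.0),
        "benign": TextureParams(160.0, 11.0),
        "insitu": TextureParams(380.0, 12.0),
        "invasive": TextureParams(850.0, 13.0),
    }


def _default_textures() -> dict[str, TextureParams]:
    return {
        "normal": TextureParams(80.0, 10.0),
        "benign": TextureParams(160.0, 11.0),
        "insitu": TextureParams(320.0, 12.0, confine_fraction=0.4),
        "invasive": TextureParams(640.0, 13.0),
    }


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a synthetic labelled image collection."""

    n_per_class: int = 2
    height: int = 1536
    width: int = 2048
    stain_matrix_truth: np.ndarray = field(default_factory=lambda: DEFAULT_STAIN_MATRIX.copy())
    class_texture_params: Mapping[str, TextureParams] = field(default_factory=_default_textures)
    eosin_range: tuple[float, float] = (0.2, 1.2)
    noise_sd: float = 0.005
    background_intensity: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        m = np.asarray(self.stain_matrix_truth, dtype=float)
        if m.shape != (3, 2):
            raise ValueError(f"stain_matrix_truth must be 3x2, got {m.shape}")
        norms = np.linalg.norm(m, axis=0)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError(f"stain matrix columns must be unit norm, got norms {norms}")
        cos = float(m[:, 0] @ m[:, 1])
        if cos > 1.0 - 1e-6:
            raise ValueError("stain matrix columns are collinear")
        dens = [self.class_texture_params[c].nuclei_per_mpx for c in CLASSES]
        if not all(a < b for a, b in zip(dens, dens[1:])):
            raise ValueError(f"nuclei densities must be strictly increasing in class order, got {dens}")

    @classmethod
    def easy(
        cls,
        n_per_class: int = 6,
        height: int = 768,
        width: int = 1280,
        seed: int = 0,
        noise_sd: float = 0.0,
    ) -> "FixtureSpec":
        """Well-separated densities, small images, no label noise — the
        benchmark profile. The default 768x1280 geometry yields a 2x4 grid
        of eight overlapping patches per image, enough for the
        frequency-array aggregation stage to be non-degenerate while staying
        CPU-cheap; pass an explicit 512x1024 (one-row grid) for the fastest
        unit-test profile."""
        return cls(
            n_per_class=n_per_class,
            height=height,
            width=width,
            class_texture_params=_easy_textures(),
            noise_sd=noise_sd,
            seed=seed,
        )


def _rng_for(spec: FixtureSpec, label: str, index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([spec.seed & 0x7FFFFFFF, CLASS_TO_INDEX[label], index])
    )


def concentration_fields(label: str, spec: FixtureSpec, index: int) -> tuple[np.ndarray, np.ndarray]:
    """The (hematoxylin, eosin) concentration fields for one image.

    Deterministic given ``(spec.seed, label, index)``.
    """
    params = spec.class_texture_params[label]
    h, w = spec.height, spec.width
    rng = _rng_for(spec, label, index)

    # --- hematoxylin: Gaussian blobs at sampled nuclei centers
    n_nuclei = int(rng.poisson(params.nuclei_per_mpx * h * w / 1e6))
    # a stroma-only margin at the frame border guarantees near-pure eosin
    # pixels even for the densest class (sections carry stroma at the edge),
    # keeping the extreme-percentile stain geometry well posed
    margin = int(min(3 * params.blob_sigma, h / 8, w / 8))
    if params.confine_fraction < 1.0:
        # confine nuclei to a random sub-rectangle of the given area fraction
        fy = np.sqrt(params.confine_fraction)
        ry, rx = int((h - 2 * margin) * fy), int((w - 2 * margin) * fy)
        y0 = int(rng.integers(margin, h - margin - ry + 1))
        x0 = int(rng.integers(margin, w - margin - rx + 1))
    else:
        y0, x0 = margin, margin
        ry, rx = h - 2 * margin, w - 2 * margin
    h_field = np.zeros((h, w), dtype=np.float64)
    if n_nuclei > 0:
        ys = rng.integers(y0, y0 + ry, size=n_nuclei)
        xs = rng.integers(x0, x0 + rx, size=n_nuclei)
        amps = params.amplitude * rng.lognormal(mean=0.0, sigma=0.15, size=n_nuclei)
        np.add.at(h_field, (ys, xs), amps)
        sigma = params.blob_sigma
        h_field = ndimage.gaussian_filter(h_field, sigma=sigma, truncate=3.0)
        h_field *= 2.0 * np.pi * sigma**2  # delta -> unit peak kernel

    # --- eosin: smooth low-frequency texture rescaled into eosin_range
    e_lo, e_hi = spec.eosin_range
    coarse = rng.standard_normal((max(2, h // 16), max(2, w // 16)))
    coarse = ndimage.gaussian_filter(coarse, sigma=3.0)
    e_field = ndimage.zoom(coarse, (h / coarse.shape[0], w / coarse.shape[1]), order=1)
    e_field = e_field[:h, :w]
    span = e_field.max() - e_field.min()
    if span > 0 and e_hi > e_lo:
        e_field = e_lo + (e_field - e_field.min()) * (e_hi - e_lo) / span
    else:
        e_field = np.full((h, w), e_lo, dtype=np.float64)
    # nuclei displace cytoplasm, so eosin is suppressed inside blobs; this
    # also leaves near-pure hematoxylin pixels at nuclei cores, keeping the
    # extreme-percentile stain-vector geometry well posed
    e_field = e_field * np.exp(-0.8 * h_field)
    return h_field.astype(np.float32), e_field.astype(np.float32)


def reconstruct_od(h_field: np.ndarray, e_field: np.ndarray, stain_matrix: np.ndarray) -> np.ndarray:
    """``OD = M @ C`` per pixel: the noiseless optical-density image."""
    conc = np.stack([h_field, e_field], axis=-1)  # H x W x 2
    return conc @ np.asarray(stain_matrix, dtype=conc.dtype).T


def compose_image(
    h_field: np.ndarray,
    e_field: np.ndarray,
    stain_matrix: np.ndarray,
    background_intensity: float = 1.0,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Render RGB pixels ``I0 * 10**(-M @ C) + noise``, clipped to [0, 1]."""
    od = reconstruct_od(h_field, e_field, stain_matrix)
    pixels = background_intensity * np.power(10.0, -od.astype(np.float64))
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        pixels = pixels + rng.normal(0.0, noise_sd, size=pixels.shape)
    return np.clip(pixels, 0.0, 1.0).astype(np.float32)


def render_image(label: str, spec: FixtureSpec, index: int) -> ImageRecord:
    """Render one labelled fixture image; bit-deterministic given
    ``(spec.seed, label, index)``."""
    h_field, e_field = concentration_fields(label, spec, index)
    rng = _rng_for(spec, label, index)
    rng = np.random.default_rng(rng.integers(0, 2**31))  # noise stream, decoupled from layout
    pixels = compose_image(
        h_field,
        e_field,
        spec.stain_matrix_truth,
        background_intensity=spec.background_intensity,
        noise_sd=spec.noise_sd,
        rng=rng,
    )
    return ImageRecord(image_id=f"{label}_{index:03d}", pixels=pixels, label=label)


def make_dataset(spec: FixtureSpec) -> list[ImageRecord]:
    """Render ``4 * n_per_class`` labelled images, ``n_per_class`` per class."""
    if spec.n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    return [
        render_image(label, spec, index)
        for label in CLASSES
        for index in range(spec.n_per_class)
    ]


def write_fixtures(spec: FixtureSpec, out_dir: str | Path) -> Path:
    """Write the fixture set as 8-bit TIFFs plus a ``path,label`` manifest.

    Returns the manifest path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for record in make_dataset(spec):
        fname = f"{record.image_id}.tiff"
        tifffile.imwrite(out_dir / fname, (record.pixels * 255).round().astype(np.uint8))
        rows.append((fname, record.label))
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows, columns=["path", "label"]).to_csv(manifest, index=False)
    return manifest
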