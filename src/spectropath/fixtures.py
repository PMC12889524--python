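"""Seeded synthetic data: H&E-like patches and smooth spot-expression fields.

The patch generator emulates the visual statistics the descriptor pipeline
responds to, not photorealistic histology: a near-white background,
hematoxylin-toned nuclei rendered as boundary-perturbed ellipses placed by a
Neyman-Scott cluster process (so spatial clustering is a single dial), eosin
cytoplasm halos, and additive Gaussian pixel noise. Two-class datasets shift
nuclear density, irregularity and clustering between classes, with per-slide
correlated jitter so grouped cross-validation has something to protect
against.

The spot-field generator lays spots on a square or hexagonal grid and draws
each gene as the softplus of a seeded mixture of Gaussian bumps and sinusoids
at a controlled length scale, plus Gaussian noise clipped at zero; the
noiseless field is returned separately as ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .st_denoise import SpotTable


@dataclass(frozen=True)
class MorphologyParams:
    """Dials of the synthetic H&E patch generator.

    ``nuclei_density`` is the expected nucleus count per 256x256 pixel area
    (scaled by actual patch area). Intensities are opacities in [0, 1].
    """

    nuclei_density: float = 45.0
    radius_mean: float = 7.0
    radius_sd: float = 1.5
    clustering: float = 0.5
    hematoxylin_intensity: float = 0.9
    eosin_intensity: float = 0.5
    irregularity: float = 0.3
    noise_sd: float = 6.0
    patch_size: int = 512

    def __post_init__(self) -> None:
        if min(self.nuclei_density, self.radius_mean, self.noise_sd, self.clustering) < 0:
            raise ValueError("parameters must be nonnegative")


HEMATOXYLIN_RGB = np.array([70.0, 45.0, 120.0])
EOSIN_RGB = np.array([235.0, 150.0, 185.0])


def _nucleus_centers(params: MorphologyParams, rng: np.random.Generator) -> np.ndarray:
    size = params.patch_size
    expected = params.nuclei_density * (size / 256.0) ** 2
    cluster_size = 1.0 + 4.0 * params.clustering
    n_parents = rng.poisson(max(expected / cluster_size, 1e-9))
    centers = []
    spread = 3.0 * params.radius_mean * (1.0 + params.clustering)
    for _ in range(n_parents):
        parent = rng.uniform(0, size, size=2)
        n_off = rng.poisson(cluster_size)
        if n_off == 0:
            continue
        offs = parent + rng.normal(0, spread, size=(n_off, 2))
        centers.append(offs)
    if not centers:
        return np.empty((0, 2))
    pts = np.concatenate(centers)
    inside = ((pts >= 0) & (pts < size)).all(axis=1)
    return pts[inside]


def _stamp(canvas_alpha, cy, cx, radii_fn, size):
    """Accumulate a radial occupancy stamp; radii_fn(theta) gives the boundary."""
    rmax = radii_fn.max_radius
    y0, y1 = max(int(cy - rmax), 0), min(int(cy + rmax) + 1, size)
    x0, x1 = max(int(cx - rmax), 0), min(int(cx + rmax) + 1, size)
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dy, dx = yy - cy, xx - cx
    theta = np.arctan2(dy, dx)
    rad = np.hypot(dy, dx)
    boundary = radii_fn(theta)
    inside = rad <= boundary
    np.maximum(canvas_alpha[y0:y1, x0:x1], inside.astype(np.float64), out=canvas_alpha[y0:y1, x0:x1])


class _PerturbedEllipse:
    def __init__(self, r, aspect, irregularity, rng):
        self.r = r
        self.aspect = aspect
        self.phi = rng.uniform(0, 2 * np.pi)
        self.modes = rng.integers(2, 6, size=2)
        self.amps = irregularity * rng.uniform(0.05, 0.35, size=2)
        self.phases = rng.uniform(0, 2 * np.pi, size=2)
        self.max_radius = r * max(1.0, aspect) * (1.0 + self.amps.sum()) + 1.0

    def __call__(self, theta):
        t = theta - self.phi
        base = self.r * np.sqrt(
            (np.cos(t) * self.aspect) ** 2 + np.sin(t) ** 2
        )
        wobble = 1.0 + sum(
            a * np.sin(m * theta + p) for a, m, p in zip(self.amps, self.modes, self.phases)
        )
        return base * np.maximum(wobble, 0.2)


def generate_patch(params: MorphologyParams = MorphologyParams(), seed: int = 0) -> np.ndarray:
    """One synthetic H&E-like RGB patch (uint8), deterministic per seed."""
    rng = np.random.default_rng(seed)
    size = params.patch_size
    nuc_alpha = np.zeros((size, size))
    cyto_alpha = np.zeros((size, size))
    for cy, cx in _nucleus_centers(params, rng):
        r = max(rng.normal(params.radius_mean, params.radius_sd), 1.5)
        aspect = rng.uniform(0.7, 1.0)
        shape = _PerturbedEllipse(r, aspect, params.irregularity, rng)
        halo = _PerturbedEllipse(1.9 * r, aspect, 0.5 * params.irregularity, rng)
        _stamp(cyto_alpha, cy, cx, halo, size)
        _stamp(nuc_alpha, cy, cx, shape, size)
    img = np.full((size, size, 3), 255.0)
    a_c = cyto_alpha[..., None] * params.eosin_intensity
    img = img * (1 - a_c) + EOSIN_RGB * a_c
    a_n = nuc_alpha[..., None] * params.hematoxylin_intensity
    img = img * (1 - a_n) + HEMATOXYLIN_RGB * a_n
    img += rng.normal(0, params.noise_sd, size=img.shape)
    return np.clip(img, 0, 255).astype(np.uint8)


def class_params(
    base: MorphologyParams, label: int, effect_size: float
) -> MorphologyParams:
    """Class-1 parameters: effect-scaled shifts in density, irregularity, clustering."""
    if label == 0:
        return base
    return replace(
        base,
        nuclei_density=base.nuclei_density * (1.0 + 0.6 * effect_size),
        irregularity=base.irregularity + 0.4 * effect_size,
        clustering=base.clustering + 0.3 * effect_size,
    )


def generate_two_class_dataset(
    n_per_class: int = 100,
    effect_size: float = 1.0,
    n_slides: int = 4,
    seed: int = 0,
    base: MorphologyParams | None = None,
) -> tuple[list[np.ndarray], pd.DataFrame]:
    """Labeled patch dataset with slide groups and within-slide jitter.

    Default patches are 256x256 (the dataset-scale choice documented in the
    methods note). Every slide contains patches of both classes. Returns the
    patch list and a manifest with columns label, group, magnification.
    """
    if n_slides < 2:
        raise ValueError("need at least two slides")
    base = base or MorphologyParams(patch_size=256)
    rng = np.random.default_rng(seed)
    slide_density_jitter = rng.lognormal(0.0, 0.10, size=n_slides)
    slide_noise_jitter = rng.uniform(0.8, 1.2, size=n_slides)

    patches, rows = [], []
    idx = 0
    for label in (0, 1):
        for i in range(n_per_class):
            slide = i % n_slides
            p = class_params(base, label, effect_size)
            p = replace(
                p,
                nuclei_density=p.nuclei_density * slide_density_jitter[slide],
                noise_sd=p.noise_sd * slide_noise_jitter[slide],
            )
            patches.append(generate_patch(p, seed=int(rng.integers(0, 2**31 - 1))))
            rows.append(
                {"path": f"patch_{idx:04d}.png", "label": label,
                 "group": f"slide{slide}", "magnification": "40x"}
            )
            idx += 1
    return patches, pd.DataFrame(rows)


@dataclass(frozen=True)
class SpotFieldParams:
    """Dials of the smooth spot-expression generator."""

    n_spots: int = 400
    n_genes: int = 12
    geometry: str = "hex"  # "square" | "hex"
    length_scale: float = 4.0  # in units of the grid pitch
    noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_spots < 4:
            raise ValueError("need at least 4 spots")
        if self.length_scale <= 0:
            raise ValueError("length_scale must be positive")
        if self.geometry not in ("square", "hex"):
            raise ValueError("geometry must be 'square' or 'hex'")


def _grid_positions(n_spots: int, geometry: str) -> np.ndarray:
    side = int(np.ceil(np.sqrt(n_spots)))
    rows_, cols_ = np.mgrid[0:side, 0:side]
    if geometry == "hex":
        x = cols_ + 0.5 * (rows_ % 2)
        y = rows_ * (np.sqrt(3.0) / 2.0)
    else:
        x, y = cols_.astype(float), rows_.astype(float)
    pts = np.column_stack([x.ravel(), y.ravel()])[:n_spots]
    return pts


def generate_spot_field(
    params: SpotFieldParams = SpotFieldParams(),
) -> tuple[SpotTable, np.ndarray]:
    """Spot table with noisy expression plus the noiseless ground truth."""
    rng = np.random.default_rng(params.seed)
    P = _grid_positions(params.n_spots, params.geometry)
    extent = P.max(axis=0) - P.min(axis=0)
    ls = params.length_scale
    truth = np.empty((P.shape[0], params.n_genes))
    for g in range(params.n_genes):
        field = np.zeros(P.shape[0])
        for _ in range(4):  # Gaussian bumps
            c = P.min(axis=0) + rng.uniform(0, 1, 2) * extent
            amp = rng.normal(0, 1.2)
            field += amp * np.exp(-((P - c) ** 2).sum(axis=1) / (2.0 * ls**2))
        for _ in range(2):  # long-wavelength sinusoids
            direction = rng.normal(size=2)
            direction /= np.linalg.norm(direction)
            phase = rng.uniform(0, 2 * np.pi)
            field += rng.normal(0, 0.6) * np.sin((P @ direction) / ls + phase)
        truth[:, g] = np.logaddexp(0.0, field)  # softplus keeps expression >= 0
    noisy = truth + rng.normal(0, params.noise_sd, size=truth.shape)
    noisy = np.clip(noisy, 0.0, None)
    table = SpotTable(positions=P, expression=noisy)
    return table, truth
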