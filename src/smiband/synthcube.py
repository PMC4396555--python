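"""Synthetic hyperspectral cubes with known redundancy structure.

The generator emulates the structure the band-selection method assumes of
real agricultural scenes: bands come in redundancy *groups* (every band in
a group is a noisy, slightly re-gained copy of one latent signal), pixels
belong to spatially contiguous labeled classes with well-separated
spectral signatures, a border of background pixels is labeled 0, and
sensor noise is additive Gaussian.  Because the group membership of every
band is known exactly, selection quality can be scored as the fraction of
true groups a subset covers (``group_recovery_score``).

A ``shuffle_confound`` variant replaces the last band of each group with a
pixel-shuffled copy of the group's first band.  Such a band has exactly
the marginal histogram of a genuine band but no spatial correspondence
with the scene — the adversarial case that separates spatially-aware
dissimilarity from plain mutual information.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Tuple

import numpy as np

from .raster_io import HyperspectralCube, LabelMap

__all__ = [
    "SynthConfig",
    "GroundTruthGroups",
    "GenerationError",
    "simulate",
    "group_recovery_score",
]


class GenerationError(RuntimeError):
    """Raised when no sufficiently separated signature set can be drawn."""


@dataclass
class SynthConfig:
    """Generator parameters.

    height, width
        scene size in pixels (default 48 x 48 — large enough for stable
        histograms, small enough for fast sweeps).
    n_classes
        number of labeled land-cover classes (default 5).
    n_groups, bands_per_group
        the redundancy structure: B = n_groups * bands_per_group bands,
        group j holding noisy copies of latent signal j (defaults 6 and 5,
        so B = 30).
    noise_sigma
        additive Gaussian noise std as a fraction of the unit signal range
        (default 0.05).
    gain_jitter
        within-group multiplicative gain spread; band gains are drawn
        uniformly from 1 +/- gain_jitter (default 0.05).
    layout
        "blocks" (a rectangular grid of class patches) or "voronoi"
        (nearest-seed regions).
    quantization_levels
        the cube is affinely quantized to this many integer levels
        (default 256, i.e. 8-bit sensor output).
    background_margin
        fraction of the frame labeled background 0 (default 0.1).
    shuffle_confound
        replace each group's last band with a pixel-shuffled copy of its
        first band (default off).
    """

    height: int = 48
    width: int = 48
    n_classes: int = 5
    n_groups: int = 6
    bands_per_group: int = 5
    noise_sigma: float = 0.05
    gain_jitter: float = 0.05
    layout: str = "blocks"
    quantization_levels: int = 256
    background_margin: float = 0.1
    shuffle_confound: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.height < 4 or self.width < 4:
            raise ValueError("scene must be at least 4 x 4 pixels")
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if self.n_groups < 2 or self.bands_per_group < 1:
            raise ValueError("need n_groups >= 2 and bands_per_group >= 1")
        if self.n_groups * self.bands_per_group < 2:
            raise ValueError("need at least 2 bands in total")
        if self.noise_sigma < 0 or self.gain_jitter < 0:
            raise ValueError("noise_sigma and gain_jitter must be >= 0")
        if self.layout not in ("blocks", "voronoi"):
            raise ValueError(f"unknown layout {self.layout!r}")
        if not 2 <= self.quantization_levels <= 65536:
            raise ValueError("quantization_levels must be in [2, 65536]")
        if not 0.0 <= self.background_margin < 1.0:
            raise ValueError("background_margin must be in [0, 1)")

    @property
    def n_bands(self) -> int:
        return self.n_groups * self.bands_per_group


@dataclass(frozen=True)
class GroundTruthGroups:
    """Band index -> true redundancy-group id."""

    group_of: np.ndarray

    @property
    def n_groups(self) -> int:
        return int(np.max(self.group_of)) + 1


# minimum pairwise euclidean separation between signature rows, scaled by
# sqrt(dimension) so the constraint means the same thing for any n_groups
_SEPARATION = 0.15
_ROW_ATTEMPTS = 2000


def _draw_signatures(rng: np.random.Generator, n_rows: int, dim: int) -> np.ndarray:
    min_sep = _SEPARATION * np.sqrt(dim)
    rows: list[np.ndarray] = []
    for _ in range(n_rows):
        for _attempt in range(_ROW_ATTEMPTS):
            cand = rng.uniform(size=dim)
            if all(np.linalg.norm(cand - r) >= min_sep for r in rows):
                rows.append(cand)
                break
        else:
            raise GenerationError(
                f"could not place {n_rows} signatures at separation {min_sep:.3f} "
                f"in [0,1]^{dim}; reduce n_classes or the separation"
            )
    return np.array(rows)


def _interior(cfg: SynthConfig) -> tuple[int, int, int, int]:
    br = int(round(cfg.height * cfg.background_margin / 2))
    bc = int(round(cfg.width * cfg.background_margin / 2))
    return br, cfg.height - br, bc, cfg.width - bc


def _block_layout(cfg: SynthConfig) -> np.ndarray:
    r0, r1, c0, c1 = _interior(cfg)
    C = cfg.n_classes
    nr = int(np.sqrt(C))
    while C % nr:
        nr -= 1
    nc = C // nr
    labels = np.zeros((cfg.height, cfg.width), dtype=np.int64)
    row_edges = np.linspace(r0, r1, nr + 1).astype(int)
    col_edges = np.linspace(c0, c1, nc + 1).astype(int)
    cid = 1
    for i in range(nr):
        for j in range(nc):
            labels[row_edges[i] : row_edges[i + 1], col_edges[j] : col_edges[j + 1]] = cid
            cid += 1
    return labels


def _voronoi_layout(cfg: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    r0, r1, c0, c1 = _interior(cfg)
    rr, cc = np.meshgrid(np.arange(cfg.height), np.arange(cfg.width), indexing="ij")
    for _ in range(50):
        seeds_r = rng.uniform(r0, r1, size=cfg.n_classes)
        seeds_c = rng.uniform(c0, c1, size=cfg.n_classes)
        d2 = (rr[..., None] - seeds_r) ** 2 + (cc[..., None] - seeds_c) ** 2
        assign = np.argmin(d2, axis=2) + 1
        labels = np.zeros((cfg.height, cfg.width), dtype=np.int64)
        inner = np.zeros_like(labels, dtype=bool)
        inner[r0:r1, c0:c1] = True
        labels[inner] = assign[inner]
        if len(np.unique(labels[inner])) == cfg.n_classes:
            return labels
    raise GenerationError("voronoi layout left a class empty after 50 attempts")


def simulate(cfg: SynthConfig) -> Tuple[HyperspectralCube, LabelMap, GroundTruthGroups]:
    """Generate a cube, its label map, and the true band-group assignment.

    Band ``b`` of group ``j`` at pixel ``p`` is
    ``gain_b * signature(class(p), j) + N(0, noise_sigma)``, quantized
    affinely to ``quantization_levels`` integer levels.  All randomness
    flows through one generator seeded with ``cfg.seed``, so every
    artefact is bit-reproducible.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    # row 0 is the background signature, rows 1..C the classes
    signatures = _draw_signatures(rng, cfg.n_classes + 1, cfg.n_groups)
    labels = _block_layout(cfg) if cfg.layout == "blocks" else _voronoi_layout(cfg, rng)

    latent = signatures[labels]  # (H, W, n_groups)
    B = cfg.n_bands
    group_of = np.repeat(np.arange(cfg.n_groups), cfg.bands_per_group)
    gains = 1.0 + cfg.gain_jitter * rng.uniform(-1.0, 1.0, size=B)

    data = np.empty((cfg.height, cfg.width, B))
    for b in range(B):
        data[:, :, b] = gains[b] * latent[:, :, group_of[b]]
    if cfg.noise_sigma > 0:
        data += rng.normal(0.0, cfg.noise_sigma, size=data.shape)

    names = [f"g{group_of[b]}_b{b % cfg.bands_per_group}" for b in range(B)]
    if cfg.shuffle_confound and cfg.bands_per_group >= 2:
        for j in range(cfg.n_groups):
            src = j * cfg.bands_per_group
            dst = src + cfg.bands_per_group - 1
            flat = data[:, :, src].ravel().copy()
            rng.shuffle(flat)
            data[:, :, dst] = flat.reshape(cfg.height, cfg.width)
            names[dst] += "_shuffled"

    lo, hi = float(data.min()), float(data.max())
    L = cfg.quantization_levels
    if hi > lo:
        q = np.floor((data - lo) / (hi - lo) * L)
        np.clip(q, 0, L - 1, out=q)
    else:
        q = np.zeros_like(data)
    dtype = np.uint8 if L <= 256 else np.uint16
    cube = HyperspectralCube(q.astype(dtype), band_names=names)
    return cube, LabelMap(labels), GroundTruthGroups(group_of=group_of)


def group_recovery_score(subset, groups: GroundTruthGroups) -> float:
    """Fraction of true redundancy groups covered by the selected bands."""
    indices = list(subset.indices) if hasattr(subset, "indices") else list(subset)
    if any(i < 0 or i >= len(groups.group_of) for i in indices):
        raise ValueError("subset index outside the band range")
    covered = {int(groups.group_of[i]) for i in indices}
    return len(covered) / groups.n_groups
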