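"""Histogram information metrics between spectral bands.

The redundancy structure of a hyperspectral cube is measured pairwise:
each band is quantized to ``L`` gray levels, a joint histogram of
co-occurring levels is accumulated over corresponding pixels, and from it
we estimate

* mutual information (MI), in bits::

      MI = (1/E) * sum_xy cnt(x,y) * log2( E * cnt(x,y) / (cnt_x(x) * cnt_y(y)) )

  where ``E`` is the pixel count and ``cnt_x``, ``cnt_y`` the marginal
  histograms — the plug-in estimator of ``H(X) + H(Y) - H(X,Y)``;

* spatial mutual information (SMI): the same sum with each joint-histogram
  cell weighted by a function of the co-occurring levels, by default the
  normalised absolute level difference ``|x - y| / (L - 1)``.  Because the
  weight vanishes on the diagonal, SMI of a band with itself is exactly 0,
  while a pixel-shuffled copy — indistinguishable from the original by any
  marginal-histogram statistic — scatters mass off the diagonal and scores
  above 0.  That sensitivity to spatial correspondence is what plain MI
  lacks.

``pairwise_dissimilarity`` turns either metric into the symmetric B x B
matrix that band clustering operates on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

__all__ = [
    "QuantizedBand",
    "Histogram",
    "JointHistogram",
    "WeightFunction",
    "DissimilarityMatrix",
    "absolute_difference",
    "quantize",
    "marginal_histogram",
    "joint_histogram",
    "entropy",
    "mutual_information",
    "spatial_mutual_information",
    "pairwise_dissimilarity",
    "default_bins",
    "save_dissimilarity_csv",
    "load_dissimilarity_csv",
    "plot_dissimilarity",
]


@dataclass(frozen=True)
class QuantizedBand:
    """A band mapped affinely onto integer levels ``0 .. L-1``."""

    levels: np.ndarray
    n_levels: int
    source_min: float
    source_max: float

    def __post_init__(self) -> None:
        if self.n_levels < 2:
            raise ValueError("need at least 2 quantization levels")
        lv = np.asarray(self.levels)
        if lv.size == 0:
            raise ValueError("empty band")
        if lv.min() < 0 or lv.max() >= self.n_levels:
            raise ValueError("levels out of range [0, L-1]")


@dataclass(frozen=True)
class Histogram:
    """Gray-level occupancy counts of one quantized band."""

    counts: np.ndarray

    @property
    def total(self) -> int:
        return int(np.sum(self.counts))


@dataclass(frozen=True)
class JointHistogram:
    """L x L co-occurrence counts of two quantized bands, indexed (x, y)."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError("joint histogram must be square")
        if c.min() < 0:
            raise ValueError("joint histogram counts must be nonnegative")

    @property
    def n_levels(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(np.sum(self.counts))

    def marginal_x(self) -> Histogram:
        return Histogram(np.sum(self.counts, axis=1))

    def marginal_y(self) -> Histogram:
        return Histogram(np.sum(self.counts, axis=0))

    def transpose(self) -> "JointHistogram":
        return JointHistogram(self.counts.T)


@dataclass(frozen=True)
class WeightFunction:
    """A symmetric nonnegative weight over pairs of gray-level bins.

    ``fn(x_bins, y_bins, n_levels)`` must be vectorised over integer bin
    arrays.  The default :data:`absolute_difference` weight is
    ``|x - y| / (L - 1)``: zero on the diagonal, 1 between the extreme
    levels.
    """

    fn: Callable[[np.ndarray, np.ndarray, int], np.ndarray]
    name: str

    def matrix(self, n_levels: int) -> np.ndarray:
        idx = np.arange(n_levels)
        w = np.asarray(self.fn(idx[:, None], idx[None, :], n_levels), dtype=float)
        if w.shape != (n_levels, n_levels):
            raise ValueError("weight function must return an L x L matrix")
        if np.any(w < 0):
            raise ValueError(f"weight '{self.name}' produced negative values")
        return w


absolute_difference = WeightFunction(
    fn=lambda x, y, L: np.abs(x - y) / (L - 1),
    name="absolute-difference",
)


def quantize(
    band: np.ndarray,
    n_levels: int,
    source_min: float | None = None,
    source_max: float | None = None,
) -> QuantizedBand:
    """Affinely quantize intensities to integer levels ``0 .. L-1``.

    ``level = floor((v - min) / (max - min) * L)`` clamped to ``L-1``;
    a constant band maps to all-zero levels.  Pass ``source_min`` /
    ``source_max`` to quantize against a shared (e.g. cube-global) range
    instead of the band's own.
    """
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    band = np.asarray(band, dtype=float)
    if not np.all(np.isfinite(band)):
        raise ValueError("band must be finite")
    lo = float(band.min()) if source_min is None else float(source_min)
    hi = float(band.max()) if source_max is None else float(source_max)
    if hi <= lo:
        levels = np.zeros(band.shape, dtype=np.int64)
    else:
        levels = np.floor((band - lo) / (hi - lo) * n_levels).astype(np.int64)
        np.clip(levels, 0, n_levels - 1, out=levels)
    return QuantizedBand(levels=levels, n_levels=n_levels, source_min=lo, source_max=hi)


def marginal_histogram(q: QuantizedBand) -> Histogram:
    """Occupancy counts of each gray level; total = pixel count."""
    return Histogram(np.bincount(q.levels.ravel(), minlength=q.n_levels))


def joint_histogram(qx: QuantizedBand, qy: QuantizedBand) -> JointHistogram:
    """Count co-occurring levels at corresponding pixels of two bands."""
    if qx.levels.shape != qy.levels.shape:
        raise ValueError("bands must share the same H x W shape")
    if qx.n_levels != qy.n_levels:
        raise ValueError("bands must be quantized to the same number of levels")
    L = qx.n_levels
    flat = np.bincount(qx.levels.ravel() * L + qy.levels.ravel(), minlength=L * L)
    return JointHistogram(flat.reshape(L, L))


def entropy(h: Histogram) -> float:
    """Shannon entropy -sum p log2 p in bits; empty bins contribute 0."""
    counts = np.asarray(h.counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("histogram has no entries")
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def _info_terms(counts: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Per-cell plug-in information terms cnt*log2(E*cnt/(cx*cy)) and the mask."""
    cnt = np.asarray(counts, dtype=float)
    total = cnt.sum()
    if total <= 0:
        raise ValueError("joint histogram has no entries")
    cx = cnt.sum(axis=1)
    cy = cnt.sum(axis=0)
    nz = cnt > 0
    x_idx, y_idx = np.nonzero(nz)
    vals = cnt[nz]
    terms = vals * np.log2(total * vals / (cx[x_idx] * cy[y_idx]))
    return terms, nz, total


def mutual_information(jh: JointHistogram) -> float:
    """Histogram-estimated MI in bits; always in [0, min marginal entropy]."""
    terms, _, total = _info_terms(jh.counts)
    mi = float(terms.sum() / total)
    # the estimator is exactly H(X)+H(Y)-H(X,Y); tiny negatives are fp noise
    return 0.0 if -1e-12 < mi < 0.0 else mi


def spatial_mutual_information(
    jh: JointHistogram, weight: WeightFunction = absolute_difference
) -> float:
    """Weighted-MI where each cell's term is scaled by ``weight(x, y)``.

    With the default absolute-difference weight this is exactly 0 for a
    band paired with itself (all mass on the zero-weight diagonal) and
    positive, in expectation, for a band paired with a pixel-shuffled copy.
    """
    W = weight.matrix(jh.n_levels)
    if not np.array_equal(W, W.T):
        raise ValueError(f"weight '{weight.name}' is not symmetric")
    terms, nz, total = _info_terms(jh.counts)
    return float((W[nz] * terms).sum() / total)


@dataclass
class DissimilarityMatrix:
    """Symmetric B x B band-pair dissimilarities — the clustering space."""

    values: np.ndarray
    metric_name: str
    rescaled: bool
    bins: int | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("dissimilarity matrix must be square")
        if not np.all(np.isfinite(v)):
            raise ValueError("dissimilarity matrix must be finite")
        if not np.array_equal(v, v.T):
            raise ValueError("dissimilarity matrix must be symmetric")
        self.values = v

    @property
    def n_bands(self) -> int:
        return self.values.shape[0]


def default_bins(data: np.ndarray) -> int:
    """256 bins for integer-valued data spanning at most 256 units, else 64."""
    data = np.asarray(data)
    integral = np.issubdtype(data.dtype, np.integer) or bool(
        np.all(data == np.floor(data))
    )
    if integral and float(data.max()) - float(data.min()) < 256:
        return 256
    return 64


def pairwise_dissimilarity(
    cube,
    metric: str = "smi",
    bins: int | None = None,
    weight: WeightFunction | None = None,
    global_range: bool = False,
) -> DissimilarityMatrix:
    """Build the B x B dissimilarity matrix over all band pairs.

    metric="mi"
        ``d(i,j) = 1 - 2 MI(i,j) / (H(i) + H(j))`` — one minus normalised
        MI, so identical bands sit at 0.  A pair involving a zero-entropy
        band carries no shared information and is set to ``d = 1`` (with a
        warning).
    metric="smi"
        raw SMI values, affinely rescaled over the whole matrix to [0, 1];
        duplicated bands land at the matrix minimum.
    metric="smi-scalar"
        the alternative reading in which the spatial weight is a single
        scalar — the mean normalised absolute level difference between the
        two bands — multiplying their MI; rescaled like "smi" and labelled
        distinctly in ``metric_name``.

    Each of the B(B-1)/2 pairs is computed once and mirrored, so the output
    is symmetric by construction.
    """
    if metric not in ("mi", "smi", "smi-scalar"):
        raise ValueError(f"unknown metric {metric!r}")
    B = cube.band_count
    if B < 2:
        raise ValueError("need at least 2 bands")
    L = int(bins) if bins is not None else default_bins(cube.data)
    if L < 2:
        raise ValueError("bins must be >= 2")
    lo = hi = None
    if global_range:
        lo, hi = float(cube.data.min()), float(cube.data.max())

    qs = [quantize(cube.band(b), L, lo, hi) for b in range(B)]
    flat = [q.levels.ravel() for q in qs]
    flat_scaled = [f * L for f in flat]
    margins = [np.bincount(f, minlength=L) for f in flat]
    ents = [entropy(Histogram(m)) for m in margins]

    V = np.zeros((B, B))
    if metric == "mi":
        warned = False
        for i in range(B):
            for j in range(i + 1, B):
                if ents[i] == 0.0 or ents[j] == 0.0:
                    if not warned:
                        warnings.warn(
                            "zero-entropy band encountered; its pairwise "
                            "dissimilarity is defined as 1 (no shared information)"
                        )
                        warned = True
                    d = 1.0
                else:
                    jh = JointHistogram(
                        np.bincount(flat_scaled[i] + flat[j], minlength=L * L).reshape(L, L)
                    )
                    d = 1.0 - 2.0 * mutual_information(jh) / (ents[i] + ents[j])
                    d = max(d, 0.0)
                V[i, j] = V[j, i] = d
        return DissimilarityMatrix(V, metric_name="mi", rescaled=False, bins=L)

    # smi variants: raw values then a single affine rescale to [0, 1]
    w = weight if weight is not None else absolute_difference
    W = w.matrix(L)
    if not np.array_equal(W, W.T):
        raise ValueError(f"weight '{w.name}' is not symmetric")
    for i in range(B):
        for j in range(i + 1, B):
            counts = np.bincount(flat_scaled[i] + flat[j], minlength=L * L).reshape(L, L)
            jh = JointHistogram(counts)
            if metric == "smi":
                v = spatial_mutual_information(jh, w)
            else:  # smi-scalar
                scalar = float(np.abs(flat[i] - flat[j]).mean()) / (L - 1)
                v = scalar * mutual_information(jh)
            V[i, j] = V[j, i] = v
    vmin, vmax = float(V.min()), float(V.max())
    if vmax > vmin:
        V = (V - vmin) / (vmax - vmin)
    else:
        V = np.zeros_like(V)
    name = metric if metric == "smi" else "smi-scalar"
    return DissimilarityMatrix(V, metric_name=name, rescaled=True, bins=L)


# --------------------------------------------------------------------------
# Matrix persistence / inspection


def save_dissimilarity_csv(dm: DissimilarityMatrix, path: str | Path) -> None:
    """Write the matrix as CSV with band indices as header row and column."""
    idx = [str(i) for i in range(dm.n_bands)]
    pd.DataFrame(dm.values, index=idx, columns=idx).to_csv(Path(path))


def load_dissimilarity_csv(
    path: str | Path, metric_name: str = "unknown", rescaled: bool = False
) -> DissimilarityMatrix:
    df = pd.read_csv(Path(path), index_col=0)
    values = df.to_numpy(dtype=float)
    # symmetrise away text round-off, if any
    values = 0.5 * (values + values.T)
    return DissimilarityMatrix(values, metric_name=metric_name, rescaled=rescaled)


def plot_dissimilarity(dm: DissimilarityMatrix, path: str | Path) -> None:
    """Render the matrix as a heatmap PNG for visual inspection."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(dm.values, cmap="viridis", origin="upper")
    ax.set_xlabel("band index")
    ax.set_ylabel("band index")
    ax.set_title(f"dissimilarity ({dm.metric_name})")
    fig.colorbar(im, ax=ax)
    fig.tight_layout()
    fig.savefig(Path(path), dpi=120)
    plt.close(fig)
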