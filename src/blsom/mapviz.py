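"""Derived per-lattice layers and their rendering.

Layers computed from a trained map:

* **U-matrix** — mean Euclidean distance from each weight to its lattice
  neighbors; rendered as gray levels, cluster borders show up dark.
* **Category coloring** — each lattice point is "empty" (white, no fragment
  assigned), a single category's color, or "multi" (black) when fragments of
  more than one category share it.
* **G+C% bins** — equal-count (quantile) binning of per-lattice G+C%,
  21 bins by default, for isochore-style base-content display.
* **o/e layers** — per-lattice observed/expected ratio of one degenerate
  k-mer pair, the expectation coming from that lattice point's own
  mononucleotide composition; rendered red (over) / white / blue (under).
* **Sz zones** — "specific zones": connected groups of lattice points whose
  composition is sharply distinct from the bulk, flagged either by a high
  U-matrix value or by being an island fully surrounded by empty points.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from . import kmer as _kmer
from .kmer import DegenerateKmerIndex
from .som import Assignment, SomMap, lattice_categories

__all__ = [
    "LatticeAnnotation",
    "umatrix",
    "category_coloring",
    "gc_quantile_bins",
    "lattice_gc",
    "oe_layer",
    "detect_sz_zones",
    "render_layers",
    "layer_to_tsv",
]

EMPTY = "empty"
MULTI = "multi"

#: |log2 ratio| at or above this renders saturated red/blue (ratio ~1.2).
DEFAULT_LOG2_CUTOFF = 0.263


@dataclass
class LatticeAnnotation:
    """Bundle of derived per-lattice layers for one trained map."""

    I: int
    J: int
    umatrix: np.ndarray | None = None
    color_class: np.ndarray | None = None  # (I, J) object array of labels
    gc: np.ndarray | None = None  # (I, J) float, NaN where empty
    gc_bin: np.ndarray | None = None  # (I, J) int, -1 where empty
    oe_layers: dict[str, np.ndarray] = field(default_factory=dict)
    sz_labels: np.ndarray | None = None  # (I, J) int, 0 = background


def _neighbor_offsets(neighbors: int) -> list[tuple[int, int]]:
    if neighbors == 8:
        return [(di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1) if (di, dj) != (0, 0)]
    if neighbors == 4:
        return [(-1, 0), (1, 0), (0, -1), (0, 1)]
    raise ValueError("neighbors must be 4 or 8")


def umatrix(som: SomMap, neighbors: int = 8) -> np.ndarray:
    """Mean distance from each weight to its existing lattice neighbors.

    Corner and edge points average over however many neighbors exist.
    """
    W = som.weights
    I, J, _ = W.shape
    total = np.zeros((I, J))
    count = np.zeros((I, J))
    for di, dj in _neighbor_offsets(neighbors):
        src_i = slice(max(0, -di), I - max(0, di))
        src_j = slice(max(0, -dj), J - max(0, dj))
        dst_i = slice(max(0, di), I - max(0, -di))
        dst_j = slice(max(0, dj), J - max(0, -dj))
        d = np.linalg.norm(W[dst_i, dst_j] - W[src_i, src_j], axis=-1)
        total[src_i, src_j] += d
        count[src_i, src_j] += 1.0
    return total / count


def category_coloring(assignment: Assignment, labels: Sequence[str]) -> np.ndarray:
    """Three-way per-lattice color class.

    Returns an (I, J) object array: ``"empty"`` where nothing is assigned,
    the category name where all assigned fragments share one category, and
    ``"multi"`` otherwise.
    """
    I, J = assignment.I, assignment.J
    out = np.full((I, J), EMPTY, dtype=object)
    cats: dict[int, set[str]] = {}
    for b, lab in zip(assignment.bmu, labels):
        cats.setdefault(int(b), set()).add(lab)
    for b, s in cats.items():
        out[b // J, b % J] = next(iter(s)) if len(s) == 1 else MULTI
    return out


def lattice_gc(som: SomMap, index: DegenerateKmerIndex, nonempty: np.ndarray | None = None) -> np.ndarray:
    """G+C fraction implied by each lattice point's weight vector.

    Weight vectors can carry small negative components (they start on a PCA
    plane); these are clipped at zero before reading off base content.
    Lattice points marked empty (or with an all-zero clipped weight) get NaN.
    """
    I, J, _ = som.weights.shape
    out = np.full((I, J), np.nan)
    for i in range(I):
        for j in range(J):
            if nonempty is not None and not nonempty[i, j]:
                continue
            v = np.clip(som.weights[i, j], 0.0, None)
            if v.sum() <= 0:
                continue
            out[i, j] = _kmer.gc_content(v, index)
    return out


def gc_quantile_bins(gc: np.ndarray, n_bins: int = 21) -> np.ndarray:
    """Equal-count bin ids for per-lattice G+C values.

    NaN entries (empty lattice points) get bin -1.  Ranking is by value with
    ties broken by row-major lattice order; the resulting bin counts differ
    by at most 1.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    flat = gc.ravel()
    valid = np.flatnonzero(~np.isnan(flat))
    n = len(valid)
    if n < n_bins:
        raise ValueError(f"need at least {n_bins} nonempty lattice points, have {n}")
    # stable sort on value; row-major position breaks ties deterministically
    order = valid[np.argsort(flat[valid], kind="stable")]
    bins = np.full(flat.shape, -1, dtype=np.int64)
    ranks = np.arange(n)
    bins[order] = ranks * n_bins // n
    return bins.reshape(gc.shape)


def oe_layer(
    som: SomMap,
    kmer_name: str,
    index: DegenerateKmerIndex,
) -> np.ndarray:
    """Per-lattice observed/expected ratio for one k-mer (or degenerate pair).

    Observed is the weight-vector slot value at each lattice point; expected
    comes from that same weight vector's mononucleotide composition, scaled
    to the weight vector's total, so the ratio isolates k-mer-specific
    structure from plain base content.
    """
    slot = index.slot(kmer_name)
    I, J, _ = som.weights.shape
    out = np.full((I, J), np.nan)
    for i in range(I):
        for j in range(J):
            v = np.clip(som.weights[i, j], 0.0, None)
            total = v.sum()
            if total <= 0:
                continue
            mono = _kmer.mononucleotide_composition(v, index)
            expected = _kmer.expected_frequency(mono, index, total=total)
            out[i, j] = _kmer.oe_ratio(v, expected)[slot]
    return out


def detect_sz_zones(
    umat: np.ndarray,
    color_class: np.ndarray,
    percentile: float = 90.0,
    min_size: int = 2,
) -> np.ndarray:
    """Flag "specific zones": compositionally isolated groups of lattice points.

    A nonempty lattice point is a candidate when its U-matrix value strictly
    exceeds the ``percentile``-th percentile over nonempty points (rule a);
    additionally, any 8-connected nonempty island that nowhere touches the
    map border — hence is fully surrounded by empty points — qualifies
    wholesale (rule b).  Surviving 8-connected components of at least
    ``min_size`` points are numbered 1, 2, ... in row-major order of their
    first point; the return grid holds 0 for background.
    """
    nonempty = color_class != EMPTY
    if not nonempty.any():
        return np.zeros_like(umat, dtype=np.int64)
    threshold = np.percentile(umat[nonempty], percentile)
    candidate = nonempty & (umat > threshold)

    # rule (b): islands of nonempty points not touching the lattice border
    structure = np.ones((3, 3), dtype=bool)  # 8-connectivity
    comp, n_comp = ndimage.label(nonempty, structure=structure)
    I, J = nonempty.shape
    border_labels = set(np.unique(comp[0, :])) | set(np.unique(comp[-1, :]))
    border_labels |= set(np.unique(comp[:, 0])) | set(np.unique(comp[:, -1]))
    for c in range(1, n_comp + 1):
        if c not in border_labels:
            candidate |= comp == c

    zones, n_zones = ndimage.label(candidate, structure=structure)
    out = np.zeros_like(zones)
    next_id = 1
    for c in range(1, n_zones + 1):
        mask = zones == c
        if mask.sum() >= min_size:
            out[mask] = next_id
            next_id += 1
    return out.astype(np.int64)


def annotate(
    som: SomMap,
    assignment: Assignment,
    labels: Sequence[str],
    index: DegenerateKmerIndex,
    n_gc_bins: int = 21,
    umatrix_neighbors: int = 8,
    sz_percentile: float = 90.0,
    oe_kmers: Sequence[str] = (),
) -> LatticeAnnotation:
    """Compute the full annotation bundle for a trained map."""
    umat = umatrix(som, neighbors=umatrix_neighbors)
    colors = category_coloring(assignment, labels)
    nonempty = colors != EMPTY
    gc = lattice_gc(som, index, nonempty=nonempty)
    try:
        gc_bin = gc_quantile_bins(gc, n_bins=n_gc_bins)
    except ValueError:
        gc_bin = None
    sz = detect_sz_zones(umat, colors, percentile=sz_percentile)
    layers = {name: oe_layer(som, name, index) for name in oe_kmers}
    return LatticeAnnotation(
        I=som.I,
        J=som.J,
        umatrix=umat,
        color_class=colors,
        gc=gc,
        gc_bin=gc_bin,
        oe_layers=layers,
        sz_labels=sz,
    )


def layer_to_tsv(layer: np.ndarray, path: str | Path) -> None:
    """Export a per-lattice layer as a TSV grid (row = i, column = j)."""
    pd.DataFrame(layer).to_csv(path, sep="\t", index=False, header=False)


def _render_umatrix(ax, umat: np.ndarray) -> None:
    lo, hi = float(umat.min()), float(umat.max())
    norm = (umat - lo) / (hi - lo) if hi > lo else np.zeros_like(umat)
    # larger distance -> darker
    ax.imshow(1.0 - norm.T, cmap="gray", vmin=0.0, vmax=1.0, origin="lower")
    ax.set_title("U-matrix (dark = distant neighbors)")


def _render_categories(ax, colors: np.ndarray) -> None:
    cats = sorted({c for c in colors.ravel() if c not in (EMPTY, MULTI)})
    cmap = plt.get_cmap("tab10")
    rgb = np.ones(colors.shape + (3,))
    for idx, cat in enumerate(cats):
        rgb[colors == cat] = cmap(idx % 10)[:3]
    rgb[colors == MULTI] = 0.0
    ax.imshow(np.transpose(rgb, (1, 0, 2)), origin="lower")
    ax.set_title("categories (black = multi, white = empty)")


def _render_oe(ax, layer: np.ndarray, name: str, log2_cutoff: float) -> None:
    with np.errstate(divide="ignore"):
        log2 = np.log2(layer)
    log2 = np.clip(np.nan_to_num(log2, nan=0.0, posinf=log2_cutoff, neginf=-log2_cutoff),
                   -log2_cutoff, log2_cutoff)
    ax.imshow(log2.T, cmap="RdBu_r", vmin=-log2_cutoff, vmax=log2_cutoff, origin="lower")
    ax.set_title(f"o/e {name} (red = over, blue = under; inf clipped to deepest red)")


def render_layers(
    annotation: LatticeAnnotation,
    out_dir: str | Path,
    prefix: str = "map",
    log2_cutoff: float = DEFAULT_LOG2_CUTOFF,
) -> list[Path]:
    """Render every available layer to a PNG; returns the written paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _save(fig, name: str) -> None:
        path = out_dir / f"{prefix}_{name}.png"
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
        written.append(path)

    if annotation.umatrix is not None:
        fig, ax = plt.subplots()
        _render_umatrix(ax, annotation.umatrix)
        _save(fig, "umatrix")
    if annotation.color_class is not None:
        fig, ax = plt.subplots()
        _render_categories(ax, annotation.color_class)
        _save(fig, "categories")
    if annotation.gc_bin is not None:
        fig, ax = plt.subplots()
        masked = np.ma.masked_where(annotation.gc_bin < 0, annotation.gc_bin)
        im = ax.imshow(masked.T, cmap="PiYG_r", origin="lower")
        plt.colorbar(im, ax=ax, label="G+C% bin (equal lattice counts)")
        ax.set_title("G+C% quantile bins")
        _save(fig, "gc_bins")
    for name, layer in annotation.oe_layers.items():
        fig, ax = plt.subplots()
        _render_oe(ax, layer, name, log2_cutoff)
        _save(fig, f"oe_{name}")
    if annotation.sz_labels is not None:
        fig, ax = plt.subplots()
        masked = np.ma.masked_where(annotation.sz_labels == 0, annotation.sz_labels)
        ax.imshow(masked.T, cmap="tab20", origin="lower")
        ax.set_title("Sz zones")
        _save(fig, "sz_zones")
    return written
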