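"""Batch-Learning Self-Organizing Map (BLSOM) core.

A BLSOM differs from Kohonen's on-line SOM in two ways that matter for
genome informatics:

1. **PCA initialization.**  The lattice is seeded on the plane spanned by
   the first two principal axes of the input cloud, centred on the mean
   vector, with the first lattice dimension spanning five standard
   deviations of the first principal component:

       w_ij = x_av + (5 sigma1 / I) * [b1 (i - I/2) + b2 (j - J/2)]

2. **Batch updates.**  Every epoch first associates *all* input vectors
   with their best-matching (minimal Euclidean distance) weight, then moves
   each weight toward the mean of the inputs associated within its
   (shrinking) neighborhood.  Together with deterministic tie-breaking this
   makes the trained map exactly independent of the order of the input
   rows, unlike the on-line SOM.

The lattice is rectangular; the second dimension J is sized from the ratio
of the two principal standard deviations, and the overall size targets a
mean of about four input vectors per lattice point.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from math import ceil, floor, sqrt
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .kmer import CompositionMatrix

__all__ = [
    "PcaFrame",
    "TrainConfig",
    "SomMap",
    "Assignment",
    "fit_pca",
    "size_map",
    "pca_init",
    "assign",
    "batch_update",
    "train",
    "map_queries",
]


@dataclass(frozen=True)
class PcaFrame:
    """First two principal axes of the input cloud.

    ``sigma1``/``sigma2`` are standard deviations (square roots of the two
    largest covariance eigenvalues); ``b1``/``b2`` the corresponding unit
    eigenvectors with a deterministic sign convention.
    """

    x_av: np.ndarray
    b1: np.ndarray
    b2: np.ndarray
    sigma1: float
    sigma2: float


@dataclass
class TrainConfig:
    """Training hyperparameters.

    The update schedule follows the standard batch-SOM recipe: the learning
    coefficient alpha decays linearly from ``alpha0`` to ``alpha_min`` over
    ``epochs``; the square (Chebyshev) neighborhood radius starts at
    ``ceil(I/10)`` and shrinks by one per epoch, never below 1.  Within the
    radius the neighborhood is tapered by a Gaussian of width
    ``max(0.5, beta/2)`` (``kernel="gaussian"``, the default) rather than
    averaged uniformly (``kernel="box"``): a uniform box drives neighboring
    weight vectors degenerate, which leaves interleaved lattice rows empty
    of data and hurts query mapping, while the taper keeps territory
    occupancy contiguous and lets training converge to a fixed point.
    """

    epochs: int = 100
    per_neuron: float = 4.0
    alpha0: float = 0.6
    alpha_min: float = 0.01
    beta0: int | None = None  # default ceil(I / 10)
    kernel: str = "gaussian"
    seed: int = 0

    def alpha(self, r: int) -> float:
        if self.epochs <= 1:
            return self.alpha0
        t = r / (self.epochs - 1)
        return self.alpha0 + (self.alpha_min - self.alpha0) * t

    def beta(self, r: int, I: int) -> int:
        b0 = self.beta0 if self.beta0 is not None else ceil(I / 10)
        return max(1, b0 - r)


@dataclass
class SomMap:
    """A trained (or initialized) lattice of weight vectors.

    ``weights`` has shape (I, J, d) with d the composition dimensionality.
    """

    I: int
    J: int
    weights: np.ndarray
    frame: PcaFrame
    config: TrainConfig = field(default_factory=TrainConfig)
    quantization_errors: list[float] = field(default_factory=list)
    train_categories: list[str] = field(default_factory=list)
    train_bmus: np.ndarray | None = None  # (n_train,) flat lattice ids

    def save(self, prefix: str | Path) -> None:
        """Persist as <prefix>.npz plus a JSON sidecar <prefix>.json."""
        prefix = Path(prefix)
        np.savez(
            prefix.with_suffix(".npz"),
            weights=self.weights,
            x_av=self.frame.x_av,
            b1=self.frame.b1,
            b2=self.frame.b2,
            train_bmus=self.train_bmus if self.train_bmus is not None else np.array([]),
        )
        sidecar = {
            "I": self.I,
            "J": self.J,
            "sigma1": self.frame.sigma1,
            "sigma2": self.frame.sigma2,
            "epochs": self.config.epochs,
            "per_neuron": self.config.per_neuron,
            "alpha0": self.config.alpha0,
            "alpha_min": self.config.alpha_min,
            "beta0": self.config.beta0,
            "kernel": self.config.kernel,
            "seed": self.config.seed,
            "quantization_errors": self.quantization_errors,
            "train_categories": self.train_categories,
        }
        prefix.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def load(cls, prefix: str | Path) -> "SomMap":
        prefix = Path(prefix)
        arrays = np.load(prefix.with_suffix(".npz"))
        meta = json.loads(prefix.with_suffix(".json").read_text())
        frame = PcaFrame(
            x_av=arrays["x_av"],
            b1=arrays["b1"],
            b2=arrays["b2"],
            sigma1=meta["sigma1"],
            sigma2=meta["sigma2"],
        )
        cfg = TrainConfig(
            epochs=meta["epochs"],
            per_neuron=meta["per_neuron"],
            alpha0=meta["alpha0"],
            alpha_min=meta["alpha_min"],
            beta0=meta["beta0"],
            kernel=meta.get("kernel", "gaussian"),
            seed=meta["seed"],
        )
        bmus = arrays["train_bmus"]
        return cls(
            I=meta["I"],
            J=meta["J"],
            weights=arrays["weights"],
            frame=frame,
            config=cfg,
            quantization_errors=list(meta["quantization_errors"]),
            train_categories=list(meta["train_categories"]),
            train_bmus=bmus.astype(np.int64) if bmus.size else None,
        )


@dataclass
class Assignment:
    """Best-match lattice coordinates per fragment and the inverse view."""

    I: int
    J: int
    bmu: np.ndarray  # (n,) flat lattice id = i * J + j
    distances: np.ndarray  # (n,) Euclidean distance to the BMU

    @property
    def coords(self) -> np.ndarray:
        """(n, 2) array of (i, j) lattice coordinates."""
        return np.stack([self.bmu // self.J, self.bmu % self.J], axis=1)

    def per_lattice(self) -> list[list[int]]:
        """Row ids assigned to each flat lattice id."""
        out: list[list[int]] = [[] for _ in range(self.I * self.J)]
        for row, b in enumerate(self.bmu):
            out[int(b)].append(row)
        return out


def _as_matrix(data: CompositionMatrix | np.ndarray) -> np.ndarray:
    if isinstance(data, CompositionMatrix):
        return data.matrix
    return np.asarray(data, dtype=np.float64)


def fit_pca(data: CompositionMatrix | np.ndarray) -> PcaFrame:
    """Covariance PCA of the input vectors (centred, no variable scaling).

    Returns the mean vector, the two leading unit eigenvectors (sign fixed
    so each eigenvector's largest-magnitude component is positive) and the
    standard deviations sigma1 >= sigma2 along them.
    """
    X = _as_matrix(data)
    if X.shape[0] < 3:
        raise ValueError("PCA initialization needs at least 3 input vectors")
    x_av = X.mean(axis=0)
    Xc = X - x_av
    cov = (Xc.T @ Xc) / (X.shape[0] - 1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    if X.shape[1] < 2 or eigvals[0] <= 0:
        raise ValueError("input cloud is degenerate: fewer than 2 varying dimensions")
    if eigvals[1] <= eigvals[0] * 1e-24:  # numerically rank 1
        eigvals[1] = 0.0
    b1, b2 = eigvecs[:, 0].copy(), eigvecs[:, 1].copy()
    for b in (b1, b2):
        pivot = np.argmax(np.abs(b))
        if b[pivot] < 0:
            b *= -1.0
    return PcaFrame(
        x_av=x_av,
        b1=b1,
        b2=b2,
        sigma1=float(np.sqrt(eigvals[0])),
        sigma2=float(np.sqrt(eigvals[1])),
    )


def size_map(n_fragments: int, frame: PcaFrame, per_neuron: float = 4.0) -> tuple[int, int]:
    """Choose lattice dimensions (I, J).

    J follows the stated rule — the smallest integer strictly greater than
    (sigma2/sigma1) * I — and I is solved so the lattice holds about
    ``per_neuron`` fragments per point: I = round(sqrt(n / (per_neuron * rho)))
    with rho = sigma2/sigma1, floored at 2.
    """
    if frame.sigma1 <= 0:
        raise ValueError("sigma1 must be positive to size the map")
    if n_fragments < per_neuron:
        raise ValueError("need at least per_neuron fragments to size a map")
    rho = frame.sigma2 / frame.sigma1
    if rho <= 1e-9:
        warnings.warn("sigma2 ~ 0: collapsing second lattice dimension to J = 1")
        I = max(2, round(n_fragments / per_neuron))
        return I, 1
    I = max(2, round(sqrt(n_fragments / (per_neuron * rho))))
    J = floor(rho * I) + 1  # smallest integer strictly greater than rho * I
    return I, J


def pca_init(frame: PcaFrame, I: int, J: int) -> np.ndarray:
    """Initial lattice weights on the first principal plane.

    w_ij = x_av + (5 sigma1 / I) [b1 (i - I/2) + b2 (j - J/2)], with
    i in 0..I-1 and j in 0..J-1, so the span along b1 is exactly
    5 sigma1 * (I-1)/I with lattice step 5 sigma1 / I.
    """
    if I < 1 or J < 1:
        raise ValueError("lattice dimensions must be >= 1")
    step = 5.0 * frame.sigma1 / I
    i = np.arange(I, dtype=np.float64) - I / 2.0
    j = np.arange(J, dtype=np.float64) - J / 2.0
    return (
        frame.x_av[None, None, :]
        + step * i[:, None, None] * frame.b1[None, None, :]
        + step * j[None, :, None] * frame.b2[None, None, :]
    )


def assign(data: CompositionMatrix | np.ndarray, weights: np.ndarray) -> Assignment:
    """Associate every input vector with its best-matching lattice weight.

    Distances are Euclidean; exact ties go to the smaller (i, j) in
    row-major order, which keeps assignment fully deterministic.
    """
    X = _as_matrix(data)
    I, J, d = weights.shape
    flat = weights.reshape(I * J, d)
    dists = cdist(X, flat, metric="euclidean")
    bmu = np.argmin(dists, axis=1)  # argmin returns the first (row-major) minimum
    return Assignment(I=I, J=J, bmu=bmu, distances=dists[np.arange(len(X)), bmu])


def _neighborhood_box_sum(grid: np.ndarray, radius: int) -> np.ndarray:
    """Sum of a (I, J, ...) grid over the (2r+1)^2 Chebyshev box, edge-truncated."""
    I, J = grid.shape[:2]
    # summed-area table along each lattice axis
    c = np.cumsum(grid, axis=0)
    pad = np.zeros((1,) + c.shape[1:], dtype=c.dtype)
    c = np.concatenate([pad, c], axis=0)
    hi = np.minimum(np.arange(I) + radius + 1, I)
    lo = np.maximum(np.arange(I) - radius, 0)
    rows = c[hi] - c[lo]
    c = np.cumsum(rows, axis=1)
    pad = np.zeros((c.shape[0], 1) + c.shape[2:], dtype=c.dtype)
    c = np.concatenate([pad, c], axis=1)
    hi = np.minimum(np.arange(J) + radius + 1, J)
    lo = np.maximum(np.arange(J) - radius, 0)
    return c[:, hi] - c[:, lo]


def _separable_correlate(grid: np.ndarray, ker: np.ndarray) -> np.ndarray:
    """Correlate a (I, J, ...) grid with ker along both lattice axes (zero-padded)."""
    out = grid
    for axis in (0, 1):
        n = out.shape[axis]
        acc = np.zeros_like(out)
        r = len(ker) // 2
        for t, w in enumerate(ker):
            off = t - r
            if off >= n or off <= -n:
                continue
            # dst index i collects src index i + off
            src = slice(max(0, off), min(n, n + off))
            dst = slice(max(0, -off), min(n, n - off))
            sel_src = [slice(None)] * out.ndim
            sel_dst = [slice(None)] * out.ndim
            sel_src[axis], sel_dst[axis] = src, dst
            acc[tuple(sel_dst)] += w * out[tuple(sel_src)]
        out = acc
    return out


def batch_update(
    weights: np.ndarray,
    data: CompositionMatrix | np.ndarray,
    assignment: Assignment,
    alpha: float,
    beta: int,
    kernel: str = "gaussian",
) -> np.ndarray:
    """One batch epoch: move each weight toward its neighborhood mean.

    For lattice point (i, j), S is the multiset of input vectors whose best
    match lies within Chebyshev distance ``beta`` of (i, j); the new weight
    is w + alpha * (mean(S) - w) when S is nonempty, else w unchanged.
    With the default ``"gaussian"`` kernel the mean is weighted by
    exp(-(di^2 + dj^2) / (2 sigma^2)) with sigma = max(0.5, beta/2), where
    (di, dj) is the lattice offset of the contributing best-match point;
    ``"box"`` weights every point in the radius equally.
    """
    X = _as_matrix(data)
    I, J, d = weights.shape
    # scatter per-lattice sums and counts, then smooth over the neighborhood
    sums = np.zeros((I * J, d), dtype=np.float64)
    counts = np.bincount(assignment.bmu, minlength=I * J).astype(np.float64)
    np.add.at(sums, assignment.bmu, X)
    sums = sums.reshape(I, J, d)
    counts = counts.reshape(I, J)
    if kernel == "box":
        nbr_sum = _neighborhood_box_sum(sums, beta)
        nbr_count = _neighborhood_box_sum(counts, beta)
    elif kernel == "gaussian":
        sigma = max(0.5, beta / 2.0)
        ker = np.exp(-0.5 * (np.arange(-beta, beta + 1) / sigma) ** 2)
        nbr_sum = _separable_correlate(sums, ker)
        nbr_count = _separable_correlate(counts, ker)
    else:
        raise ValueError(f"unknown kernel {kernel!r}")
    new = weights.copy()
    nonempty = nbr_count > 0
    means = nbr_sum[nonempty] / nbr_count[nonempty][:, None]
    new[nonempty] += alpha * (means - weights[nonempty])
    return new


def _canonical_order(X: np.ndarray) -> np.ndarray:
    """A row permutation depending only on row *values*, not input order.

    Sorting rows lexicographically before any accumulation makes every
    floating-point reduction identical for any permutation of the input,
    which is what turns "order independence" into an exact, bitwise
    property rather than an approximate one.
    """
    return np.lexsort(X.T[::-1])


def train(
    data: CompositionMatrix | np.ndarray,
    config: TrainConfig | None = None,
    I: int | None = None,
    J: int | None = None,
    categories: Sequence[str] | None = None,
) -> tuple[SomMap, Assignment]:
    """Train a BLSOM: PCA init, then alternating batch assign/update epochs.

    The result (weights and per-fragment mapping) is bitwise identical under
    any permutation of the input rows.  Per-epoch mean quantization error
    (mean distance of each vector to its best match) is recorded on the map.
    """
    config = config or TrainConfig()
    X = _as_matrix(data)
    if categories is None and isinstance(data, CompositionMatrix):
        categories = data.categories
    order = _canonical_order(X)
    Xs = X[order]

    frame = fit_pca(Xs)
    if I is None or J is None:
        I, J = size_map(len(Xs), frame, per_neuron=config.per_neuron)
    weights = pca_init(frame, I, J)

    qerrors: list[float] = []
    assignment = assign(Xs, weights)
    for r in range(config.epochs):
        weights = batch_update(
            weights, Xs, assignment,
            alpha=config.alpha(r), beta=config.beta(r, I), kernel=config.kernel,
        )
        if not np.isfinite(weights).all():
            raise FloatingPointError(f"non-finite weights at epoch {r}")
        assignment = assign(Xs, weights)
        qerrors.append(float(assignment.distances.mean()))

    # undo the canonical ordering so the assignment lines up with input rows
    inverse = np.empty_like(order)
    inverse[order] = np.arange(len(order))
    bmu_in_input_order = assignment.bmu[inverse]
    final = Assignment(
        I=I, J=J, bmu=bmu_in_input_order, distances=assignment.distances[inverse]
    )
    som = SomMap(
        I=I,
        J=J,
        weights=weights,
        frame=frame,
        config=config,
        quantization_errors=qerrors,
        train_categories=list(categories) if categories is not None else [],
        train_bmus=bmu_in_input_order,
    )
    return som, final


def lattice_categories(som: SomMap) -> list[str | None]:
    """Majority training category per flat lattice id (None where empty).

    Ties go to the lexicographically smallest category name.
    """
    out: list[str | None] = [None] * (som.I * som.J)
    if som.train_bmus is None or not som.train_categories:
        return out
    buckets: dict[int, dict[str, int]] = {}
    for b, cat in zip(som.train_bmus, som.train_categories):
        buckets.setdefault(int(b), {}).setdefault(cat, 0)
        buckets[int(b)][cat] += 1
    for b, tally in buckets.items():
        best = max(sorted(tally), key=lambda c: tally[c])
        out[b] = best
    return out


def map_queries(
    som: SomMap, queries: CompositionMatrix | np.ndarray
) -> tuple[Assignment, list[str]]:
    """Map new fragments onto a trained lattice and predict their category.

    Each query goes to its nearest weight; the prediction is the majority
    training category at that lattice point, or ``"unassigned"`` when no
    training fragment landed there.
    """
    Q = _as_matrix(queries)
    if Q.shape[1] != som.weights.shape[2]:
        raise ValueError("query dimensionality does not match the trained map")
    assignment = assign(Q, som.weights)
    per_lattice = lattice_categories(som)
    predictions = [
        per_lattice[int(b)] if per_lattice[int(b)] is not None else "unassigned"
        for b in assignment.bmu
    ]
    return assignment, predictions
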