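"""Synthetic genome generation with controllable compositional signatures.

The genome-signature phenomenon is low-order compositional structure, so a
low-order Markov chain over {A, C, G, T} is the natural generative stand-in
for a real genome here: its transition matrix fixes the stationary k-mer
composition, and perturbing the matrix per "species" tunes how far apart
the species signatures lie.  The module also produces order-0 ("random")
sequences of the kind used to pad real maps, and injects soft-masking and
N runs so the preparation rules are exercisable end to end.

All randomness flows through one explicitly seeded generator; outputs are
bit-identical across runs with the same spec.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .seqprep import SourceSequence

__all__ = [
    "GeneratorSpec",
    "generate_genome",
    "make_species_panel",
    "inject_mask_and_ns",
    "write_fasta",
    "stationary_distribution",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of one synthetic genome.

    ``transition`` has shape (4^order, 4): next-base probabilities given
    the preceding ``order`` bases (context code = base-4 integer, A=0..T=3).
    ``gc_target`` builds a default matrix with that G+C fraction when no
    matrix is given; ``cg_suppression`` multiplies the probability of G
    following a context ending in C by the factor and renormalizes,
    emulating vertebrate CpG suppression (0 removes CG dinucleotides
    entirely, 1 leaves them untouched).
    """

    label: str
    length: int
    seed: int
    order: int = 0
    transition: np.ndarray | None = None
    gc_target: float | None = None
    cg_suppression: float | None = None
    soft_mask_fraction: float = 0.0
    n_fraction: float = 0.0

    def resolved_transition(self) -> np.ndarray:
        """The effective (4^order, 4) matrix after defaults and suppression."""
        n_ctx = 4**self.order
        if self.transition is not None:
            P = np.array(self.transition, dtype=np.float64)
            if P.shape != (n_ctx, 4):
                raise ValueError(f"transition must have shape ({n_ctx}, 4)")
        else:
            gc = 0.5 if self.gc_target is None else self.gc_target
            row = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
            P = np.tile(row, (n_ctx, 1))
        if (P < 0).any():
            raise ValueError("transition probabilities must be nonnegative")
        P = P / P.sum(axis=1, keepdims=True)
        if self.cg_suppression is not None:
            if self.order < 1:
                raise ValueError("cg_suppression needs order >= 1")
            if not 0 <= self.cg_suppression <= 1:
                raise ValueError("cg_suppression must be in [0, 1]")
            ends_in_c = np.arange(4**self.order) % 4 == 1  # C = code 1
            P = P.copy()
            P[ends_in_c, 2] *= self.cg_suppression  # G = code 2
            rowsums = P.sum(axis=1, keepdims=True)
            if (rowsums == 0).any():
                raise ValueError("cg_suppression left a context with no outgoing probability")
            P = P / rowsums
        if not np.allclose(P.sum(axis=1), 1.0):
            raise ValueError("transition rows must sum to 1")
        return P


def _sample_chain(P: np.ndarray, order: int, length: int, rng: np.random.Generator) -> np.ndarray:
    """Sample base codes from a Markov chain of the given order.

    The per-step inverse-CDF lookups are precomputed for every context from
    one shared uniform stream, so the remaining per-step work is plain
    indexing; this keeps multi-megabase generation tractable in pure Python.
    """
    if order == 0:
        cum = np.cumsum(P[0])
        u = rng.random(length)
        return np.searchsorted(cum, u, side="right").astype(np.int64)
    n_ctx = 4**order
    cum = np.cumsum(P, axis=1)[:, :3]  # (n_ctx, 3)
    # warm-up: draw the first `order` bases i.i.d. from the mean row
    mean_cum = np.cumsum(P.mean(axis=0))[:3]
    u0 = rng.random(order)
    head = np.searchsorted(mean_cum, u0, side="right")
    u = rng.random(length - order)
    # choice[c, t] = next base when the context is c at step t
    choice = (u[None, :, None] >= cum[:, None, :]).sum(axis=2).astype(np.int8)
    seq = np.empty(length, dtype=np.int64)
    seq[:order] = head
    ctx = 0
    for b in head:
        ctx = (ctx * 4 + int(b)) % n_ctx
    mod = n_ctx // 4
    choice_list = [choice[c] for c in range(n_ctx)]
    for t in range(length - order):
        b = int(choice_list[ctx][t])
        seq[order + t] = b
        ctx = (ctx % mod) * 4 + b if order > 1 else b
    return seq


def generate_genome(spec: GeneratorSpec) -> SourceSequence:
    """Generate one synthetic genome sequence from a spec.

    Deterministic given the seed; soft-masking and N injection (if any) are
    applied after base generation via :func:`inject_mask_and_ns`.
    """
    if spec.length < 1:
        raise ValueError("length must be >= 1")
    P = spec.resolved_transition()
    rng = np.random.default_rng(spec.seed)
    codes = _sample_chain(P, spec.order, spec.length, rng)
    residues = _BASES[codes].tobytes().decode("ascii")
    src = SourceSequence(id=spec.label, residues=residues, category=spec.label)
    if spec.soft_mask_fraction or spec.n_fraction:
        src = inject_mask_and_ns(
            src, spec.soft_mask_fraction, spec.n_fraction, seed=spec.seed + 1
        )
    return src


def stationary_distribution(P: np.ndarray, order: int) -> np.ndarray:
    """Stationary distribution over contexts of the chain (left eigenvector).

    For order 0 this is just the single probability row.
    """
    if order == 0:
        return np.asarray(P[0], dtype=np.float64)
    n_ctx = 4**order
    # context transition: ctx -> (ctx drop-oldest, append b) with prob P[ctx, b]
    T = np.zeros((n_ctx, n_ctx))
    mod = n_ctx // 4
    for c in range(n_ctx):
        for b in range(4):
            T[c, (c % mod) * 4 + b if order > 1 else b] += P[c, b]
    eigvals, eigvecs = np.linalg.eig(T.T)
    i = int(np.argmin(np.abs(eigvals - 1.0)))
    pi = np.real(eigvecs[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


def make_species_panel(
    n_species: int,
    divergence: float,
    length: int,
    seed: int,
    order: int = 1,
    labels: Sequence[str] | None = None,
) -> list[SourceSequence]:
    """Generate a panel of synthetic species genomes with tunable divergence.

    All species share one base transition matrix; each species' matrix is a
    per-row mixture ``(1 - d) * base + d * species_own`` where the species'
    own rows are Dirichlet draws, so ``divergence`` d in [0, 1] moves the
    panel from statistically identical (d = 0) to fully independent
    signatures (d = 1).
    """
    if n_species < 2:
        raise ValueError("n_species must be >= 2")
    if not 0 <= divergence <= 1:
        raise ValueError("divergence must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_ctx = 4**order
    base = rng.dirichlet(np.full(4, 10.0), size=n_ctx)  # mild context structure
    if labels is None:
        labels = [f"species_{chr(ord('A') + i)}" for i in range(n_species)]
    panel = []
    for s in range(n_species):
        own = rng.dirichlet(np.full(4, 1.0), size=n_ctx)
        P = (1.0 - divergence) * base + divergence * own
        spec = GeneratorSpec(
            label=labels[s],
            length=length,
            seed=int(rng.integers(0, 2**31 - 1)),
            order=order,
            transition=P,
        )
        panel.append(generate_genome(spec))
    return panel


def inject_mask_and_ns(
    src: SourceSequence,
    soft_mask_fraction: float = 0.0,
    n_fraction: float = 0.0,
    seed: int = 0,
    run_length: int = 200,
) -> SourceSequence:
    """Lower-case random runs and/or replace random runs with N.

    Disjoint runs of ``run_length`` (the last one truncated) are placed on a
    random block grid until each requested fraction is hit exactly (to the
    nearest character), so realized fractions land well within +/-0.5% of the
    request for any sequence much longer than one run.
    """
    for frac, name in ((soft_mask_fraction, "soft_mask_fraction"), (n_fraction, "n_fraction")):
        if not 0 <= frac <= 1:
            raise ValueError(f"{name} must be in [0, 1]")
    if soft_mask_fraction + n_fraction > 1:
        raise ValueError("soft_mask_fraction + n_fraction must not exceed 1")
    if soft_mask_fraction == 0 and n_fraction == 0:
        return src
    n = len(src.residues)
    run = min(run_length, n)
    n_blocks = n // run
    rng = np.random.default_rng(seed)
    block_order = rng.permutation(n_blocks)
    residues = np.frombuffer(src.residues.encode("ascii"), dtype=np.uint8).copy()

    cursor = 0

    def take(target_chars: int) -> list[tuple[int, int]]:
        nonlocal cursor
        spans = []
        remaining = target_chars
        while remaining > 0 and cursor < n_blocks:
            b = int(block_order[cursor])
            cursor += 1
            start = b * run
            width = min(run, remaining)
            spans.append((start, start + width))
            remaining -= width
        return spans

    for start, end in take(round(n_fraction * n)):
        residues[start:end] = ord("N")
    lower = np.frombuffer(src.residues.lower().encode("ascii"), dtype=np.uint8)
    for start, end in take(round(soft_mask_fraction * n)):
        residues[start:end] = lower[start:end]
    return SourceSequence(
        id=src.id, residues=residues.tobytes().decode("ascii"), category=src.category
    )


def write_fasta(sources: Sequence[SourceSequence], path: str | Path, width: int = 80) -> None:
    """Write sources as a multi-record FASTA file (case preserved)."""
    with open(path, "w") as fh:
        for src in sources:
            fh.write(f">{src.id}\n")
            for i in range(0, len(src.residues), width):
                fh.write(src.residues[i : i + width] + "\n")
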