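"""Degenerate (reverse-complement canonical) k-mer composition.

Because DNA databases register only one strand of each duplex, strand-level
differences are usually uninformative for genome-signature work.  The
degenerate composition therefore sums the frequencies of each pair of
complementary k-mers (e.g., AAAAC and GTTTT) into one slot; for odd k this
halves the dimensionality (pentanucleotides: 1024 -> 512, "DegPenta").  For
even k, self-complementary words (e.g., ACGT) occupy singleton slots, so the
count is 4^k/2 + 4^(k/2)/2.

The module also provides the observed/expected diagnostic: each slot's
frequency divided by the frequency predicted from the vector's own
mononucleotide composition, the standard way to see over/under-represented
oligonucleotides (CpG suppression, motif enrichment) independently of base
content.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .seqprep import FragmentRecord

__all__ = [
    "DegenerateKmerIndex",
    "CompositionMatrix",
    "build_index",
    "count_kmers",
    "to_frequencies",
    "mononucleotide_composition",
    "expected_frequency",
    "oe_ratio",
    "gc_content",
    "composition_matrix",
    "revcomp",
]

_BASES = "ACGT"
# ASCII -> base code; non-ACGT (incl. IUPAC ambiguity codes) -> -1
_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(_BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    """Reverse complement (case-preserving over ACGT)."""
    return seq.translate(_COMPLEMENT)[::-1]


def _decode(code: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append(_BASES[code & 3])
        code >>= 2
    return "".join(reversed(out))


def _revcomp_code(code: int, k: int) -> int:
    rc = 0
    for _ in range(k):
        rc = (rc << 2) | (3 - (code & 3))
        code >>= 2
    return rc


@dataclass(frozen=True, eq=False)
class DegenerateKmerIndex:
    """Bijection from all 4^k k-mers onto canonical composition slots.

    In degenerate mode a k-mer and its reverse complement share a slot; the
    lexicographically smaller member of each pair names the slot, and slots
    are ordered lexicographically by that canonical member.  In plain mode
    every k-mer has its own slot in lexicographic order.
    """

    k: int
    mode: Literal["plain", "degenerate"]
    slot_of: np.ndarray = field(repr=False)  # (4^k,) int64, k-mer code -> slot
    n_slots: int = 0

    def slot(self, kmer: str) -> int:
        """Slot id of a k-mer given as a string (case-insensitive)."""
        if len(kmer) != self.k:
            raise KeyError(f"{kmer!r} is not a {self.k}-mer")
        codes = _CODE[np.frombuffer(kmer.encode(), dtype=np.uint8)]
        if (codes < 0).any():
            raise KeyError(f"{kmer!r} contains non-ACGT characters")
        code = 0
        for c in codes:
            code = (code << 2) | int(c)
        return int(self.slot_of[code])

    @property
    def slot_names(self) -> list[str]:
        """Canonical k-mer naming each slot, in slot order."""
        names = [""] * self.n_slots
        seen = np.zeros(self.n_slots, dtype=bool)
        for code in range(4**self.k):
            s = int(self.slot_of[code])
            if not seen[s]:
                seen[s] = True
                names[s] = _decode(code, self.k)
        return names

    def slot_members(self) -> list[tuple[str, ...]]:
        """All member k-mers of each slot (1 for palindromes, else 2)."""
        members: list[list[str]] = [[] for _ in range(self.n_slots)]
        for code in range(4**self.k):
            members[int(self.slot_of[code])].append(_decode(code, self.k))
        return [tuple(m) for m in members]


def build_index(k: int, mode: Literal["plain", "degenerate"] = "degenerate") -> DegenerateKmerIndex:
    """Build the slot index for all 4^k k-mers.

    ``k`` is capped at 8 (65 536 plain dimensions), the practical ceiling for
    this kind of composition analysis.
    """
    if not 1 <= k <= 8:
        raise ValueError(f"k must be in [1, 8], got {k}")
    if mode not in ("plain", "degenerate"):
        raise ValueError(f"mode must be 'plain' or 'degenerate', got {mode!r}")
    n_kmers = 4**k
    codes = np.arange(n_kmers, dtype=np.int64)
    if mode == "plain":
        return DegenerateKmerIndex(k=k, mode=mode, slot_of=codes, n_slots=n_kmers)
    # canonical code = min(code, revcomp(code)); slots ordered by canonical code
    tmp = codes.copy()
    rc = np.zeros_like(codes)
    for _ in range(k):
        rc = (rc << 2) | (3 - (tmp & 3))
        tmp >>= 2
    canonical = np.minimum(codes, rc)
    uniq, slot_of = np.unique(canonical, return_inverse=True)
    return DegenerateKmerIndex(k=k, mode=mode, slot_of=slot_of.astype(np.int64), n_slots=len(uniq))


def _encode_sequence(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii", errors="replace"), dtype=np.uint8)]


def count_kmers(frag: FragmentRecord | str, index: DegenerateKmerIndex) -> np.ndarray:
    """Count (degenerate) k-mer occurrences in a fragment.

    A width-k window slides with step 1; any window containing a non-ACGT
    character contributes nothing.  Matching is case-insensitive.  Returns a
    float vector of per-slot counts; its sum equals the number of valid
    windows scanned.
    """
    seq = frag.sequence if isinstance(frag, FragmentRecord) else frag
    k = index.k
    counts = np.zeros(index.n_slots, dtype=np.float64)
    n = len(seq)
    if n < k:
        return counts
    codes = _encode_sequence(seq)
    # k-mer integer codes by horner accumulation over k shifted views
    m = n - k + 1
    acc = np.zeros(m, dtype=np.int64)
    valid = np.ones(m, dtype=bool)
    for j in range(k):
        cj = codes[j : j + m]
        valid &= cj >= 0
        acc = (acc << 2) | np.where(cj >= 0, cj, 0)
    kmer_codes = acc[valid]
    if kmer_codes.size:
        counts += np.bincount(index.slot_of[kmer_codes], minlength=index.n_slots).astype(
            np.float64
        )
    return counts


def to_frequencies(counts: np.ndarray, effective_length: int | float) -> np.ndarray:
    """Normalize slot counts by the effective (non-N) sequence length."""
    if effective_length <= 0:
        raise ValueError(f"effective_length must be > 0, got {effective_length}")
    return np.asarray(counts, dtype=np.float64) / float(effective_length)


_PROFILE_CACHE: dict[tuple[int, str], np.ndarray] = {}


def _base_profile(index: DegenerateKmerIndex) -> np.ndarray:
    """(n_slots, 4) matrix: mean per-position base fractions of each slot.

    Entry [s, b] is the fraction of letters equal to base b among all k
    positions of all member k-mers of slot s (members averaged, so a
    complementary pair contributes each member at half weight).
    """
    key = (index.k, index.mode)
    if key in _PROFILE_CACHE:
        return _PROFILE_CACHE[key]
    k = index.k
    n_kmers = 4**k
    prof_kmer = np.zeros((n_kmers, 4), dtype=np.float64)
    codes = np.arange(n_kmers, dtype=np.int64)
    tmp = codes.copy()
    for _ in range(k):
        base = tmp & 3
        for b in range(4):
            prof_kmer[:, b] += base == b
        tmp >>= 2
    prof_kmer /= k
    prof = np.zeros((index.n_slots, 4), dtype=np.float64)
    np.add.at(prof, index.slot_of, prof_kmer)
    multiplicity = np.bincount(index.slot_of, minlength=index.n_slots).astype(np.float64)
    prof /= multiplicity[:, None]
    _PROFILE_CACHE[key] = prof
    return prof


def mononucleotide_composition(values: np.ndarray, index: DegenerateKmerIndex) -> np.ndarray:
    """Base frequencies (A, C, G, T) implied by a composition vector.

    The composition is read off the k-mer vector itself: every slot is
    expanded into its member k-mers (a complementary pair at half weight
    each), the letters are tallied weighted by the slot values, and the
    result is normalized to sum 1.  In degenerate mode this forces A = T and
    C = G by construction.
    """
    values = np.asarray(values, dtype=np.float64)
    total = values.sum()
    if total <= 0:
        raise ValueError("mononucleotide composition undefined for an all-zero vector")
    mono = values @ _base_profile(index)
    return mono / mono.sum()


def expected_frequency(
    mono: np.ndarray, index: DegenerateKmerIndex, total: float = 1.0
) -> np.ndarray:
    """Per-slot occurrence expected from a mononucleotide composition.

    A k-mer's expected probability is the product of its base frequencies;
    a degenerate slot's expectation sums its (one or two) members.  The
    result is scaled so its sum equals ``total`` — pass the observed
    vector's sum to put expectation on the observed scale.
    """
    mono = np.asarray(mono, dtype=np.float64)
    if not np.isclose(mono.sum(), 1.0):
        raise ValueError("mono frequencies must sum to 1")
    k = index.k
    n_kmers = 4**k
    # per-kmer product of base frequencies, computed positionally
    probs = np.ones(n_kmers, dtype=np.float64)
    codes = np.arange(n_kmers, dtype=np.int64)
    tmp = codes.copy()
    for _ in range(k):
        probs *= mono[tmp & 3]
        tmp >>= 2
    expected = np.zeros(index.n_slots, dtype=np.float64)
    np.add.at(expected, index.slot_of, probs)
    return expected * float(total)


def oe_ratio(observed: np.ndarray, expected: np.ndarray) -> np.ndarray:
    """Elementwise observed/expected ratio with total-function conventions.

    Slots where both observed and expected are 0 get ratio 1 (no signal);
    expected 0 with observed > 0 gets +inf (unbounded over-representation).
    """
    observed = np.asarray(observed, dtype=np.float64)
    expected = np.asarray(expected, dtype=np.float64)
    if observed.shape != expected.shape:
        raise ValueError("observed and expected must share one k-mer index")
    ratio = np.empty_like(observed)
    zero_both = (expected == 0) & (observed == 0)
    zero_exp = (expected == 0) & (observed != 0)
    ok = expected != 0
    ratio[ok] = observed[ok] / expected[ok]
    ratio[zero_both] = 1.0
    ratio[zero_exp] = np.inf
    return ratio


def gc_content(values: np.ndarray, index: DegenerateKmerIndex) -> float:
    """G + C fraction of the mononucleotide composition of a vector."""
    mono = mononucleotide_composition(values, index)
    return float(mono[1] + mono[2])


@dataclass
class CompositionMatrix:
    """Row-per-fragment composition vectors over one shared k-mer index.

    ``matrix`` holds frequency-form vectors (counts / effective length)
    unless built otherwise; ``fragments`` records provenance in row order.
    Row order is bookkeeping only — training is invariant to it.
    """

    index: DegenerateKmerIndex
    matrix: np.ndarray  # (n_fragments, n_slots) float64
    fragments: list[FragmentRecord] = field(default_factory=list)
    categories: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != self.index.n_slots:
            raise ValueError("matrix shape inconsistent with index")
        if not self.categories and self.fragments:
            self.categories = [f.category for f in self.fragments]

    @property
    def n_fragments(self) -> int:
        return self.matrix.shape[0]

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.matrix, columns=self.index.slot_names)
        meta = pd.DataFrame(
            {
                "source_id": [f.source_id for f in self.fragments] or [""] * len(df),
                "start": [f.start for f in self.fragments] or [0] * len(df),
                "end": [f.end for f in self.fragments] or [0] * len(df),
                "category": self.categories or [""] * len(df),
            }
        )
        pd.concat([meta, df], axis=1).to_csv(path, sep="\t", index=False)


def composition_matrix(
    fragments: Sequence[FragmentRecord],
    index: DegenerateKmerIndex,
    frequency: bool = True,
) -> CompositionMatrix:
    """Count every fragment and stack the vectors into a CompositionMatrix.

    With ``frequency=True`` (default) each row is normalized by the
    fragment's effective (non-N) length.
    """
    rows = np.zeros((len(fragments), index.n_slots), dtype=np.float64)
    for i, frag in enumerate(fragments):
        counts = count_kmers(frag, index)
        rows[i] = to_frequencies(counts, frag.effective_length) if frequency else counts
    return CompositionMatrix(index=index, matrix=rows, fragments=list(fragments))
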