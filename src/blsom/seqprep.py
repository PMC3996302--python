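"""Sequence preparation: FASTA input, soft-mask partitioning, windowing, N filtering.

Genomic sequences are cut into fixed-length, non-overlapping windows
("fragments"), and fragments whose content of undetermined nucleotides (N)
exceeds a threshold are excluded from downstream composition analysis.
Soft-masked input (lower-case = repeat, upper-case = unique) can be split
into its two compartments before windowing, each compartment being
concatenated and re-fragmented separately.

Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd
from Bio import SeqIO

__all__ = [
    "SourceSequence",
    "FragmentRecord",
    "read_fasta",
    "split_by_case",
    "fragment",
    "n_filter",
    "fragment_sources",
    "write_manifest",
    "DEFAULT_WINDOW",
    "DEFAULT_MAX_N_FRAC",
]

#: Default fragment window length in nucleotides.
DEFAULT_WINDOW = 100_000
#: Fragments whose non-ACGT fraction strictly exceeds this are excluded.
DEFAULT_MAX_N_FRAC = 0.20

# Anything outside A/C/G/T (either case) counts as undetermined: Ns, but
# also IUPAC ambiguity codes (R, Y, W, ...), which are collapsed onto N so
# that the counting alphabet stays closed.
_NON_ACGT = re.compile(r"[^ACGTacgt]")
_UPPER_RUN = re.compile(r"[A-Z]+")
_LOWER_RUN = re.compile(r"[a-z]+")


@dataclass(frozen=True)
class SourceSequence:
    """A raw input sequence (e.g., one FASTA record or one compartment of it)."""

    id: str
    residues: str
    category: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("SourceSequence id must be nonempty")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class FragmentRecord:
    """One fixed-length window of a source sequence.

    ``n_count`` counts every character outside {A,C,G,T} (case-insensitive);
    ``effective_length`` is the window length minus that count and is the
    normalization denominator for composition frequencies.
    """

    source_id: str
    start: int
    end: int
    sequence: str
    category: str = ""
    n_count: int = 0

    @property
    def effective_length(self) -> int:
        return (self.end - self.start) - self.n_count

    @property
    def window(self) -> int:
        return self.end - self.start


class FastaParseError(ValueError):
    pass


def read_fasta(path: str | Path, category: str | None = None) -> list[SourceSequence]:
    """Read a (possibly soft-masked) FASTA file, preserving residue case.

    Parameters
    ----------
    path
        FASTA file; multi-record files yield one :class:`SourceSequence` each.
    category
        Category label applied to every record; defaults to the record id,
        so that per-record labels double as species labels.
    """
    path = Path(path)
    records = []
    with open(path) as handle:
        first = handle.read(1)
        if first == "":
            raise FastaParseError(f"empty FASTA file: {path}")
        if first != ">":
            raise FastaParseError(f"{path}: line 1 does not start a FASTA record")
        handle.seek(0)
        for rec in SeqIO.parse(handle, "fasta"):
            residues = str(rec.seq)
            if not residues:
                raise FastaParseError(f"{path}: record {rec.id!r} has no residues")
            records.append(
                SourceSequence(
                    id=rec.id,
                    residues=residues,
                    category=category if category is not None else rec.id,
                )
            )
    if not records:
        raise FastaParseError(f"no FASTA records found in {path}")
    return records


def split_by_case(src: SourceSequence) -> tuple[SourceSequence, SourceSequence]:
    """Partition a soft-masked sequence into (unique, repeat) compartments.

    Upper-case runs are concatenated in order into the unique part, lower-case
    runs into the repeat part; either may be empty.  The character multisets of
    the two parts together reassemble the input.
    """
    unique = "".join(_UPPER_RUN.findall(src.residues))
    repeat = "".join(_LOWER_RUN.findall(src.residues))
    mk = lambda part, res: SourceSequence(
        id=f"{src.id}|{part}", residues=res, category=f"{src.category}:{part}"
    )
    return mk("unique", unique), mk("repeat", repeat)


def fragment(src: SourceSequence, window: int = DEFAULT_WINDOW) -> list[FragmentRecord]:
    """Cut a source into consecutive non-overlapping windows from position 0.

    A trailing remainder shorter than ``window`` is discarded: the analysis
    operates on fixed-length fragments only.
    """
    if window < 1:
        raise ValueError(f"window must be >= 1, got {window}")
    n_frags = len(src.residues) // window
    out = []
    for i in range(n_frags):
        start, end = i * window, (i + 1) * window
        seq = src.residues[start:end]
        n_count = len(_NON_ACGT.findall(seq))
        out.append(
            FragmentRecord(
                source_id=src.id,
                start=start,
                end=end,
                sequence=seq,
                category=src.category,
                n_count=n_count,
            )
        )
    return out


def n_filter(frag: FragmentRecord, max_n_frac: float = DEFAULT_MAX_N_FRAC) -> bool:
    """Inclusion decision for a fragment: True iff it passes the N filter.

    A fragment is excluded only when its undetermined fraction *strictly
    exceeds* ``max_n_frac`` (a fragment at exactly the threshold is kept).
    Downstream frequencies of included fragments are normalized by
    ``effective_length``, the length without Ns.
    """
    if not (0 < max_n_frac < 1):
        raise ValueError(f"max_n_frac must be in (0, 1), got {max_n_frac}")
    return frag.n_count / frag.window <= max_n_frac


def fragment_sources(
    sources: Iterable[SourceSequence],
    window: int = DEFAULT_WINDOW,
    max_n_frac: float = DEFAULT_MAX_N_FRAC,
    split_repeats: bool = False,
) -> tuple[list[FragmentRecord], list[FragmentRecord]]:
    """Fragment many sources; returns (included, excluded) fragment lists.

    With ``split_repeats`` each source is first partitioned by letter case
    into unique/repeat compartments which are fragmented independently.
    """
    included: list[FragmentRecord] = []
    excluded: list[FragmentRecord] = []
    for src in sources:
        parts: Sequence[SourceSequence]
        if split_repeats:
            uniq, rep = split_by_case(src)
            parts = [p for p in (uniq, rep) if p.residues]
        else:
            parts = [src]
        for part in parts:
            for frag in fragment(part, window=window):
                (included if n_filter(frag, max_n_frac) else excluded).append(frag)
    return included, excluded


def write_manifest(
    included: Sequence[FragmentRecord],
    excluded: Sequence[FragmentRecord],
    path: str | Path,
) -> pd.DataFrame:
    """Write the fragment manifest TSV (source_id, start, end, category, n_count, included)."""
    rows = [
        dict(
            source_id=f.source_id,
            start=f.start,
            end=f.end,
            category=f.category,
            n_count=f.n_count,
            included=flag,
        )
        for frags, flag in ((included, 1), (excluded, 0))
        for f in frags
    ]
    df = pd.DataFrame(
        rows, columns=["source_id", "start", "end", "category", "n_count", "included"]
    )
    df.to_csv(path, sep="\t", index=False)
    return df
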