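import numpy as np
import pytest

from blsom import kmer, seqprep, som, synthdata


@pytest.fixture(scope="session")
def species_panel():
    """Three 1.1 Mb synthetic species at divergence 0.5 (the clustering benchmark)."""
    return synthdata.make_species_panel(3, divergence=0.5, length=1_100_000, seed=11)


@pytest.fixture(scope="session")
def panel_split(species_panel):
    """(train_matrix, query_matrix) of 5 kb fragment compositions, 200 + 20 per species."""
    index = kmer.build_index(5, "degenerate")
    train_frags, query_frags = [], []
    for src in species_panel:
        frags, _ = seqprep.fragment_sources([src], window=5000)
        train_frags.extend(frags[:200])
        query_frags.extend(frags[200:220])
    return (
        kmer.composition_matrix(train_frags, index),
        kmer.composition_matrix(query_frags, index),
    )


@pytest.fixture(scope="session")
def trained_map(panel_split):
    """BLSOM trained on the 600-fragment panel with default schedules."""
    train_mat, _ = panel_split
    return som.train(train_mat, som.TrainConfig(epochs=100))


def brute_force_count(seq: str, k: int, degenerate: bool) -> dict[str, float]:
    """Independent dictionary-based k-mer tally (canonical pair keyed by min member)."""
    counts: dict[str, float] = {}
    seq = seq.upper()
    for i in range(len(seq) - k + 1):
        w = seq[i : i + k]
        if any(c not in "ACGT" for c in w):
            continue
        key = min(w, kmer.revcomp(w)) if degenerate else w
        counts[key] = counts.get(key, 0.0) + 1.0
    return counts
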