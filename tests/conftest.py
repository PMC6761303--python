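"""Shared fixtures and independent oracle helpers."""

from __future__ import annotations

import numpy as np
import pytest

from endobin import RunConfig, generate_mixture
from endobin.io import revcomp
from endobin.synthetic import default_two_genome_spec

BASES = "ACGT"


def random_dna(rng: np.random.Generator, length: int, n_rate: float = 0.0) -> str:
    alphabet = BASES + ("N" if n_rate > 0 else "")
    if n_rate > 0:
        p = [(1 - n_rate) / 4] * 4 + [n_rate]
        return "".join(rng.choice(list(alphabet), size=length, p=p))
    return "".join(rng.choice(list(BASES), size=length))


def both_strand_frequencies(seq: str, k: int, columns: list[str]) -> np.ndarray:
    """Independent oracle: count k-mers explicitly on both strands, then sum
    each canonical column and its reverse complement. Skips N windows."""
    counts: dict[str, int] = {}
    for strand in (seq, revcomp(seq)):
        for i in range(len(strand) - k + 1):
            w = strand[i:i + k]
            if "N" in w:
                continue
            counts[w] = counts.get(w, 0) + 1
    vec = np.array(
        [counts.get(c, 0) + (counts.get(revcomp(c), 0) if revcomp(c) != c else 0)
         for c in columns],
        dtype=float,
    )
    total = vec.sum()
    return vec / total if total else vec


def per_fragment_coverage_tally(links_rows, lengths: dict[str, int]):
    """Independent oracle: walk fragments one by one and tally counts."""
    counts = {c: 0.0 for c in lengths}
    for _, a, b, _typ in links_rows:
        placed = [c for c in (a, b) if c is not None]
        if not placed:
            continue
        if len(placed) == 2 and placed[0] != placed[1]:
            counts[placed[0]] += 0.5
            counts[placed[1]] += 0.5
        else:
            counts[placed[0]] += 1.0
    return counts


@pytest.fixture()
def cfg() -> RunConfig:
    return RunConfig(seed=7)


@pytest.fixture(scope="session")
def mixture():
    """The default two-genome study mixture (host 9x coverage, bacterial
    symbiont with 16S, 30% homology label rate, no link noise)."""
    return generate_mixture(default_two_genome_spec(seed=1))
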