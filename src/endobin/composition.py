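"""Canonical k-mer composition and GC content of contigs.

k-mers are counted on the forward strand and collapsed onto canonical
representatives (the lexicographically smaller of a k-mer and its reverse
complement). This is proportional to counting on both strands and then
combining complementary k-mers — including palindromes, which under
both-strand counting are seen once per strand and so carry the same weight
as every collapsed pair. The equivalence is asserted by the test suite
against an explicit both-strand counter.
"""

from __future__ import annotations

from itertools import product

import numpy as np
import pandas as pd

from .io import ContigSet, RunConfig, revcomp

_BASES = "ACGT"
# A<C<G<T encoded 0..3 so integer window codes order like the strings
_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(_BASES):
    _CODE[ord(_b)] = _i


def kmer_space_size(k: int) -> int:
    """Number of possible k-mers before canonical collapsing (4**k)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return 4 ** k


def canonical_kmers(k: int) -> list[str]:
    """Lexicographically sorted canonical k-mers of length k.

    canonical(w) = min(w, revcomp(w)); for odd k there are no reverse-
    complement palindromes and the space collapses exactly in half.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    canon = {min(w, revcomp(w)) for w in ("".join(p) for p in product(_BASES, repeat=k))}
    return sorted(canon)


def gc_content(seq: str) -> float:
    """(G+C)/(A+C+G+T); N is excluded from the denominator.

    Returns NaN for an all-N (or empty after masking) sequence.
    """
    if not seq:
        raise ValueError("empty sequence")
    gc = seq.count("G") + seq.count("C")
    denom = gc + seq.count("A") + seq.count("T")
    return gc / denom if denom else float("nan")


def _window_codes(seq: str, k: int) -> np.ndarray:
    """Canonical integer codes of all N-free k-windows on the forward strand."""
    arr = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    n = len(arr) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    win = np.lib.stride_tricks.sliding_window_view(arr, k)
    valid = (win >= 0).all(axis=1)
    win = win[valid]
    if not len(win):
        return np.empty(0, dtype=np.int64)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    fwd = win @ powers
    rc = (3 - win)[:, ::-1] @ powers
    return np.minimum(fwd, rc)


def kmer_frequencies(seq: str, k: int) -> np.ndarray:
    """Frequency vector over canonical k-mers for one sequence.

    Windows containing N are skipped; the vector is normalized by the
    number of counted windows. A sequence shorter than k, or with no
    N-free window, yields an all-zero vector (flagged downstream by its
    zero row sum).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    cols = canonical_kmers(k)
    codes = _window_codes(seq, k)
    if not len(codes):
        return np.zeros(len(cols))
    counts = np.bincount(codes, minlength=4 ** k).astype(float)
    col_codes = [_string_code(w) for w in cols]
    freq = counts[col_codes]
    return freq / freq.sum()


def _string_code(kmer: str) -> int:
    code = 0
    for b in kmer:
        code = code * 4 + _CODE[ord(b)]
    return int(code)


def build_kmer_matrix(contigs: ContigSet, cfg: RunConfig) -> pd.DataFrame:
    """Composition matrix for contigs passing the length filter.

    Rows: contigs with length >= ``cfg.min_contig_len`` (inclusive), sorted
    by id. Columns: canonical k-mer frequencies plus a ``gc`` side column.
    Contigs with zero countable windows keep an all-zero row.
    """
    keep = [c for c in contigs.ids if contigs.length(c) >= cfg.min_contig_len]
    if not keep:
        raise ValueError(
            f"no contig is >= {cfg.min_contig_len} nt; lower min_contig_len "
            "or check the assembly"
        )
    cols = canonical_kmers(cfg.k)
    mat = np.vstack([kmer_frequencies(contigs[c], cfg.k) for c in keep])
    df = pd.DataFrame(mat, index=pd.Index(keep, name="contig_id"), columns=cols)
    df["gc"] = [gc_content(contigs[c]) for c in keep]
    return df


def kmer_feature_columns(matrix: pd.DataFrame) -> list[str]:
    """The k-mer frequency columns of a composition matrix (excludes gc)."""
    return [c for c in matrix.columns if c != "gc"]
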