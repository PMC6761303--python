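"""Per-contig sequencing coverage in fragments per nucleotide.

Coverage here is fragment-count based, not per-base depth: each sequenced
DNA fragment contributes one count, split between contigs when its two
mates map to different contigs. Merged (single-end) fragments and pairs
are handled separately so that one fragment is never counted twice.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import ContigSet

COVERAGE_COLUMNS = ("contig_id", "length", "fragment_count", "coverage")


def compute_coverage(links: pd.DataFrame, contigs: ContigSet) -> pd.DataFrame:
    """Tally fragments per contig and normalize by contig length.

    Counting rules, per fragment:

    * both mates on the same contig, or a single-end fragment -> 1 count to
      that contig;
    * mates on two different contigs -> 0.5 counts to each;
    * one mate unplaced -> 1 count to the placed contig (a fragment was
      sequenced from it);
    * both mates unplaced -> no count.

    The total fragment count over all contigs therefore equals the number
    of fragments with at least one placed mate. Every contig of the
    assembly appears in the output, with zero coverage when unobserved.
    A contig named in ``links`` but absent from ``contigs`` is a hard error.
    """
    counts: dict[str, float] = {cid: 0.0 for cid in contigs.ids}
    a = links["contig_a"]
    b = links["contig_b"]
    named = set(a.dropna()) | set(b.dropna())
    unknown = named - set(contigs.entries)
    if unknown:
        raise ValueError(f"mate links name contigs absent from the assembly: {sorted(unknown)[:5]}")

    both = a.notna() & b.notna()
    cross = both & (a != b)
    # one full count: same-contig pairs, singles, half-placed pairs
    one_a = a.notna() & ~cross
    one_b = b.notna() & a.isna()
    for cid, n in a[one_a].value_counts().items():
        counts[cid] += float(n)
    for cid, n in b[one_b].value_counts().items():
        counts[cid] += float(n)
    for cid, n in a[cross].value_counts().items():
        counts[cid] += 0.5 * float(n)
    for cid, n in b[cross].value_counts().items():
        counts[cid] += 0.5 * float(n)

    ids = contigs.ids
    lengths = np.array([contigs.length(c) for c in ids], dtype=float)
    frag = np.array([counts[c] for c in ids], dtype=float)
    return pd.DataFrame(
        {
            "contig_id": ids,
            "length": lengths.astype(int),
            "fragment_count": frag,
            "coverage": frag / lengths,
        }
    )
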