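"""Taxonomic labeling of contigs from homology evidence.

A contig's hits (nucleotide and protein pooled with equal per-HSP weight)
are resolved to taxon labels at a chosen rank via the lineage table; the
label density — the fraction of rank-resolvable hits agreeing on the most
frequent label — must reach a threshold (default 0.75, inclusive) for the
label to be kept. Contigs with tied top labels, or with no resolvable
hits, stay unlabeled: ambiguous evidence is dropped rather than guessed.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from .io import CANONICAL_RANKS, RunConfig, SixteenSRecord

logger = logging.getLogger("endobin")

#: provenance tags, ordered roughly by trust
SOURCE_HOMOLOGY = "homology"
SOURCE_GRAPH = "graph_extension"
SOURCE_PREDICTED = "predicted"
SOURCE_CLUSTER = "cluster"
SOURCES = (SOURCE_HOMOLOGY, SOURCE_GRAPH, SOURCE_PREDICTED, SOURCE_CLUSTER)


@dataclass(frozen=True)
class Label:
    label: str
    taxon_density: float
    source: str

    def __post_init__(self):
        if not self.label:
            raise ValueError("empty taxon label")
        if not 0 < self.taxon_density <= 1:
            raise ValueError("taxon_density must be in (0,1]")
        if self.source not in SOURCES:
            raise ValueError(f"unknown label source {self.source!r}")


@dataclass
class TaxonomyLabels:
    """Per-contig, per-rank taxon labels with provenance.

    At most one label per contig per rank; contigs may be absent entirely
    (the unlabeled set).
    """

    _data: dict[str, dict[str, Label]] = field(default_factory=dict)

    def get(self, contig_id: str, rank: str) -> Label | None:
        return self._data.get(contig_id, {}).get(rank)

    def set(self, contig_id: str, rank: str, label: Label) -> None:
        self._data.setdefault(contig_id, {})[rank] = label

    def remove(self, contig_id: str, rank: str) -> None:
        ranks = self._data.get(contig_id)
        if ranks and rank in ranks:
            del ranks[rank]
            if not ranks:
                del self._data[contig_id]

    def contigs_at(self, rank: str, sources: tuple[str, ...] | None = None) -> list[str]:
        """Contigs labeled at a rank, optionally restricted by source."""
        return sorted(
            c for c, ranks in self._data.items()
            if rank in ranks and (sources is None or ranks[rank].source in sources)
        )

    def label_of(self, contig_id: str, rank: str) -> str | None:
        lab = self.get(contig_id, rank)
        return lab.label if lab else None

    def copy(self) -> "TaxonomyLabels":
        return TaxonomyLabels({c: dict(r) for c, r in self._data.items()})

    def merge(self, other: "TaxonomyLabels") -> None:
        """Absorb labels from ``other``; existing labels win."""
        for c, ranks in other._data.items():
            for rank, lab in ranks.items():
                if self.get(c, rank) is None:
                    self.set(c, rank, lab)

    def __len__(self) -> int:
        return len(self._data)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (c, rank, lab.label, lab.taxon_density, lab.source)
            for c, ranks in sorted(self._data.items())
            for rank, lab in sorted(ranks.items())
        ]
        return pd.DataFrame(
            rows, columns=["contig_id", "rank", "label", "taxon_density", "source"]
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TaxonomyLabels":
        out = cls()
        for row in df.itertuples(index=False):
            out.set(row.contig_id, row.rank,
                    Label(row.label, float(row.taxon_density), row.source))
        return out


def assign_taxonomy(
    hits: pd.DataFrame,
    lineage: pd.DataFrame,
    rank: str,
    cfg: RunConfig,
) -> TaxonomyLabels:
    """Label contigs at one rank from their pooled (filtered) homology hits.

    Each hit resolves to a label via the lineage table; hits whose taxid is
    unknown, or whose lineage lacks the rank, are dropped from the pool.
    The density of the most frequent label over the resolvable pool must
    reach ``cfg.taxon_density_min`` (inclusive) and be a unique maximum,
    else the contig stays unlabeled.
    """
    if rank not in CANONICAL_RANKS:
        raise ValueError(f"unknown rank {rank!r}")
    if rank not in lineage.columns:
        raise ValueError(f"lineage table has no {rank!r} column")

    taxid_to_label = lineage[rank].dropna().to_dict()
    resolved = hits["subject_taxid"].map(taxid_to_label)
    n_unknown = int((~hits["subject_taxid"].isin(lineage.index)).sum())
    if n_unknown:
        logger.warning("%d hits with taxids absent from the lineage table dropped", n_unknown)

    pool = hits.assign(label=resolved).dropna(subset=["label"])
    out = TaxonomyLabels()
    for contig_id, sub in pool.groupby("contig_id", sort=True):
        counts = Counter(sub["label"])
        (top, n_top), = counts.most_common(1)
        if sum(1 for v in counts.values() if v == n_top) > 1:
            continue  # tied evidence: unlabeled
        density = n_top / len(sub)
        if density >= cfg.taxon_density_min:
            out.set(contig_id, rank, Label(top, density, SOURCE_HOMOLOGY))
    return out


def identify_16s_target(
    records: list[SixteenSRecord], target_label: str, rank: str
) -> str:
    """Pick the contig whose 16S gene matches the target taxon.

    Among matching 16S records the one with the highest contig coverage
    wins (multiple rRNA operon copies in the target genome inflate its
    contig's coverage); coverage ties break deterministically by contig id,
    with a warning.
    """
    matching = [r for r in records if r.assigned_taxon.get(rank) == target_label]
    if not matching:
        found = sorted({r.assigned_taxon.get(rank, "<none>") for r in records})
        raise ValueError(
            f"no 16S gene labeled {target_label!r} at rank {rank!r}; "
            f"16S labels found: {found}"
        )
    best = sorted(matching, key=lambda r: (-r.contig_coverage, r.contig_id))
    if len(best) > 1 and best[0].contig_coverage == best[1].contig_coverage:
        logger.warning(
            "16S coverage tie between %s and %s; keeping %s",
            best[0].contig_id, best[1].contig_id, best[0].contig_id,
        )
    return best[0].contig_id
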