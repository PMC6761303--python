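"""Read-pair linkage graph and label transfer between linked contigs.

Two contigs are connected when at least one read pair has a mate on each;
edge weight is the number of supporting pairs. Because chimeric pairs can
bridge genomes, edges are filtered by weight (EDGES-style threshold) and
promiscuous vertices by degree (VERTICES-style threshold) before any label
transfer.

Transfer runs per connected component (CC) in one of three modes:

* ``extend_taxonomy`` — propagate homology labels to unlabeled contigs;
* ``correct_predictions`` — same check, but a CC with discordant labels
  has its machine-learning labels discarded and marked 'misclassified';
* ``extend_clusters`` — propagate final cluster membership (e.g. to short
  contigs excluded from composition features).

With ``vertexdist="all"`` the CC-majority label propagates to the whole
component unless the discordant fraction among reference-labeled contigs
exceeds ``mixedcomp_max``. With an integer ``vertexdist`` d, transfer is
the alternative per-source strategy: each reference-labeled vertex spreads
its own label along unweighted shortest paths up to distance d, except
that a conflicting labeled vertex at distance n truncates transfer on its
paths at distance n-2 (implemented as: never label a vertex within one
hop of a conflicting label).
"""

from __future__ import annotations

import logging
from collections import Counter

import networkx as nx
import pandas as pd

from .io import RunConfig
from .taxonomy import (
    SOURCE_CLUSTER,
    SOURCE_GRAPH,
    SOURCE_HOMOLOGY,
    SOURCE_PREDICTED,
    Label,
    TaxonomyLabels,
)

logger = logging.getLogger("endobin")

MODES = ("extend_taxonomy", "correct_predictions", "extend_clusters")

#: which label sources anchor the transfer, and which tag new labels get
_MODE_RULES = {
    "extend_taxonomy": ((SOURCE_HOMOLOGY,), SOURCE_GRAPH),
    "correct_predictions": ((SOURCE_HOMOLOGY, SOURCE_GRAPH), SOURCE_GRAPH),
    "extend_clusters": ((SOURCE_CLUSTER,), SOURCE_CLUSTER),
}

REPORT_COLUMNS = (
    "cc_id", "n_members", "n_labeled", "majority_label", "mixed_fraction",
    "action", "n_assigned", "misclassified", "members",
)


def build_graph(links: pd.DataFrame, cfg: RunConfig) -> nx.Graph:
    """Build and filter the read-pair graph from a mate-link table.

    Vertices are every contig with a placed mate (so same-contig-only
    contigs appear as isolated vertices); edges come from cross-contig
    pairs. Edges with weight < ``cfg.edges_min`` are removed first, then
    vertices whose remaining degree exceeds ``cfg.vertices_max_degree``
    are removed in a single pass (iterated to a fixed point when
    ``cfg.iterate_degree_filter`` is set).
    """
    g = nx.Graph()
    a, b = links["contig_a"], links["contig_b"]
    g.add_nodes_from(pd.concat([a, b]).dropna().unique())
    cross = a.notna() & b.notna() & (a != b)
    if cross.any():
        pairs = links.loc[cross, ["contig_a", "contig_b"]].apply(
            lambda r: tuple(sorted((r["contig_a"], r["contig_b"]))), axis=1
        )
        for (u, v), w in Counter(pairs).items():
            g.add_edge(u, v, weight=int(w))

    weak = [(u, v) for u, v, w in g.edges(data="weight") if w < cfg.edges_min]
    g.remove_edges_from(weak)
    if cfg.vertices_max_degree is not None:
        while True:
            hubs = [v for v, d in g.degree() if d > cfg.vertices_max_degree]
            g.remove_nodes_from(hubs)
            if not hubs or not cfg.iterate_degree_filter:
                break
    logger.info(
        "pair graph: %d vertices, %d edges after filtering",
        g.number_of_nodes(), g.number_of_edges(),
    )
    return g


def write_edge_list(graph: nx.Graph, path) -> None:
    rows = sorted((min(u, v), max(u, v), w) for u, v, w in graph.edges(data="weight"))
    pd.DataFrame(rows, columns=["contig_a", "contig_b", "weight"]).to_csv(
        path, sep="\t", index=False
    )


def _majority(counts: Counter) -> tuple[str | None, float]:
    """Majority label and discordant fraction; None label on a top tie."""
    (top, n_top), = counts.most_common(1)
    if sum(1 for v in counts.values() if v == n_top) > 1:
        return None, 1.0 - n_top / sum(counts.values())
    return top, 1.0 - n_top / sum(counts.values())


def transfer_labels(
    graph: nx.Graph,
    labels: TaxonomyLabels,
    rank: str,
    cfg: RunConfig,
    mode: str,
) -> tuple[TaxonomyLabels, pd.DataFrame]:
    """Run one label-transfer pass over every connected component.

    Returns updated labels (the input is not mutated) and a per-CC report.
    Existing labels are never overwritten, whatever their source.
    """
    if mode not in MODES:
        raise ValueError(f"unknown transfer mode {mode!r}; expected one of {MODES}")
    ref_sources, new_source = _MODE_RULES[mode]
    out = labels.copy()
    report_rows = []

    for cc_id, comp in enumerate(
        sorted(nx.connected_components(graph), key=lambda c: min(c))
    ):
        members = sorted(comp)
        ref = {
            c: lab.label
            for c in members
            if (lab := out.get(c, rank)) is not None and lab.source in ref_sources
        }
        misclassified: list[str] = []
        assigned = 0

        if not ref:
            action = "skipped_unlabeled"
        elif cfg.vertexdist == "all":
            counts = Counter(ref.values())
            majority, f = _majority(counts)
            if majority is None or f > cfg.mixedcomp_max:
                action = "skipped_mixed"
                if mode == "correct_predictions":
                    for c in members:
                        lab = out.get(c, rank)
                        if lab is not None and lab.source == SOURCE_PREDICTED:
                            out.remove(c, rank)
                            misclassified.append(c)
            else:
                action = "transferred"
                for c in members:
                    if out.get(c, rank) is None:
                        out.set(c, rank, Label(majority, 1.0, new_source))
                        assigned += 1
            report_rows.append(
                (cc_id, len(members), len(ref), majority, round(f, 6), action,
                 assigned, ";".join(misclassified), ";".join(members))
            )
            continue
        else:
            action, assigned = _distance_transfer(
                graph.subgraph(comp), out, rank, ref, int(cfg.vertexdist), new_source
            )
        counts = Counter(ref.values()) if ref else Counter()
        majority, f = _majority(counts) if counts else (None, float("nan"))
        report_rows.append(
            (cc_id, len(members), len(ref), majority, round(f, 6) if counts else None,
             action, assigned, ";".join(misclassified), ";".join(members))
        )

    report = pd.DataFrame(report_rows, columns=list(REPORT_COLUMNS))
    return out, report


def _distance_transfer(
    sub: nx.Graph,
    out: TaxonomyLabels,
    rank: str,
    ref: dict[str, str],
    d: int,
    new_source: str,
) -> tuple[str, int]:
    """Per-source BFS transfer with the n-2 conflict truncation.

    Each reference vertex proposes its label to unlabeled vertices within
    distance d, but never to a vertex within one hop of a vertex carrying
    a different label (a conflict at path distance n thus truncates
    transfer at n-2). Vertices receiving conflicting proposals are left
    unlabeled.
    """
    # any labeled vertex at the rank acts as a potential conflict
    labeled = {c: lab.label for c in sub if (lab := out.get(c, rank)) is not None}
    proposals: dict[str, set[str]] = {}
    truncated = False
    for src, label in sorted(ref.items()):
        conflicts = [c for c, l in labeled.items() if l != label]
        too_close: set[str] = set(conflicts)
        for c in conflicts:
            too_close.update(sub.neighbors(c))
        dist = nx.single_source_shortest_path_length(sub, src, cutoff=d)
        for v, ell in dist.items():
            if v == src or v in labeled:
                continue
            if v in too_close:
                truncated = True
                continue
            proposals.setdefault(v, set()).add(label)
    assigned = 0
    for v, labs in sorted(proposals.items()):
        if len(labs) == 1:
            out.set(v, rank, Label(next(iter(labs)), 1.0, new_source))
            assigned += 1
        else:
            truncated = True
    unreached = sum(1 for v in sub if v not in labeled and v not in proposals)
    action = "transferred"
    if truncated or unreached:
        action = "truncated_at_distance"
    return action, assigned
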