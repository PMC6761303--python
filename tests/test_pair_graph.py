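"""Read-pair graph construction and the label-transfer rules."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from endobin import RunConfig, build_graph, transfer_labels
from endobin.io import LINK_COLUMNS
from endobin.taxonomy import (
    SOURCE_GRAPH,
    SOURCE_HOMOLOGY,
    SOURCE_PREDICTED,
    Label,
    TaxonomyLabels,
)

RANK = "superkingdom"


def _links(pair_counts, same=()):
    rows = []
    i = 0
    for (a, b), n in pair_counts.items():
        for _ in range(n):
            rows.append((f"r{i}", a, b, "paired")); i += 1
    for c in same:
        rows.append((f"r{i}", c, c, "paired")); i += 1
    return pd.DataFrame(rows, columns=list(LINK_COLUMNS))


def _labels(mapping, source=SOURCE_HOMOLOGY):
    labels = TaxonomyLabels()
    for c, lab in mapping.items():
        labels.set(c, RANK, Label(lab, 1.0, source))
    return labels


class TestBuildGraph:
    def test_edge_weight_filter(self, cfg):
        g = build_graph(_links({("c1", "c2"): 12, ("c1", "c3"): 3}), cfg)
        assert list(g.edges(data="weight")) == [("c1", "c2", 12)]
        assert set(g.nodes) == {"c1", "c2", "c3"}

    def test_hub_removed_by_degree_filter(self, cfg):
        star = {("hub", f"n{i}"): 20 for i in range(6)}
        g = build_graph(_links(star), cfg)
        assert "hub" not in g and g.number_of_edges() == 0

    def test_degree_filter_disabled_keeps_hub(self, cfg):
        star = {("hub", f"n{i}"): 20 for i in range(6)}
        g = build_graph(_links(star), cfg.replace(vertices_max_degree=None))
        assert g.degree("hub") == 6

    def test_same_contig_pairs_give_isolated_vertices(self, cfg):
        g = build_graph(_links({}, same=["c1", "c2"]), cfg)
        assert set(g.nodes) == {"c1", "c2"} and g.number_of_edges() == 0


class TestTransferAll:
    def test_single_label_cc_extends_everywhere(self, cfg):
        g = nx.Graph([("L", "u1"), ("u1", "u2"), ("u2", "u3")])
        out, report = transfer_labels(g, _labels({"L": "Bacteria"}), RANK, cfg,
                                      mode="extend_taxonomy")
        for u in ("u1", "u2", "u3"):
            lab = out.get(u, RANK)
            assert lab.label == "Bacteria" and lab.source == SOURCE_GRAPH
        assert report.iloc[0]["action"] == "transferred"

    def test_mixed_cc_vetoed(self, cfg):
        g = nx.Graph([(f"b{i}", "u") for i in range(3)] + [("e", "u")])
        labels = _labels({"b0": "Bacteria", "b1": "Bacteria", "b2": "Bacteria",
                          "e": "Eukaryota"})
        out, report = transfer_labels(g, labels, RANK, cfg, mode="extend_taxonomy")
        assert report.iloc[0]["action"] == "skipped_mixed"
        assert report.iloc[0]["mixed_fraction"] == pytest.approx(0.25)
        assert out.get("u", RANK) is None

    def test_unlabeled_cc_skipped(self, cfg):
        g = nx.Graph([("u1", "u2")])
        out, report = transfer_labels(g, TaxonomyLabels(), RANK, cfg,
                                      mode="extend_taxonomy")
        assert report.iloc[0]["action"] == "skipped_unlabeled"
        assert len(out) == 0

    def test_zero_mixedcomp_vetoes_any_two_labels(self):
        cfg = RunConfig(mixedcomp_max=0.0)
        g = nx.Graph([(f"b{i}", "u") for i in range(9)] + [("e", "u")])
        labels = _labels({f"b{i}": "Bacteria" for i in range(9)} | {"e": "Eukaryota"})
        _, report = transfer_labels(g, labels, RANK, cfg, mode="extend_taxonomy")
        assert report.iloc[0]["action"] == "skipped_mixed"

    def test_homology_labels_never_overwritten(self, cfg):
        g = nx.Graph([("b1", "b2"), ("b2", "e")])
        labels = _labels({"b1": "Bacteria", "b2": "Bacteria"})
        labels.set("e", RANK, Label("Eukaryota", 1.0, SOURCE_PREDICTED))
        out, _ = transfer_labels(g, labels, RANK, cfg, mode="extend_taxonomy")
        assert out.get("e", RANK).label == "Eukaryota"

    def test_idempotent(self, cfg):
        g = nx.Graph([("L", "u1"), ("u1", "u2"), ("x1", "x2")])
        labels = _labels({"L": "Bacteria"})
        once, _ = transfer_labels(g, labels, RANK, cfg, mode="extend_taxonomy")
        twice, _ = transfer_labels(g, once, RANK, cfg, mode="extend_taxonomy")
        pd.testing.assert_frame_equal(once.to_frame(), twice.to_frame())


class TestCorrectionMode:
    def test_predictions_discarded_in_mixed_cc(self, cfg):
        g = nx.Graph([("b", "p1"), ("p1", "p2"), ("p2", "e")])
        labels = _labels({"b": "Bacteria", "e": "Eukaryota"})
        labels.set("p1", RANK, Label("Bacteria", 0.8, SOURCE_PREDICTED))
        labels.set("p2", RANK, Label("Eukaryota", 0.6, SOURCE_PREDICTED))
        out, report = transfer_labels(g, labels, RANK, cfg, mode="correct_predictions")
        assert report.iloc[0]["action"] == "skipped_mixed"
        assert out.get("p1", RANK) is None and out.get("p2", RANK) is None
        assert set(report.iloc[0]["misclassified"].split(";")) == {"p1", "p2"}
        # homology labels survive the veto
        assert out.get("b", RANK).label == "Bacteria"

    def test_concordant_cc_keeps_predictions(self, cfg):
        g = nx.Graph([("b1", "p1"), ("b2", "p1")])
        labels = _labels({"b1": "Bacteria", "b2": "Bacteria"})
        labels.set("p1", RANK, Label("Bacteria", 0.9, SOURCE_PREDICTED))
        out, report = transfer_labels(g, labels, RANK, cfg, mode="correct_predictions")
        assert report.iloc[0]["action"] == "transferred"
        assert out.get("p1", RANK).label == "Bacteria"


class TestDistanceMode:
    def test_conflict_truncates_at_n_minus_2(self):
        cfg = RunConfig(vertexdist=3)
        g = nx.Graph([("L", "u1"), ("u1", "u2"), ("u2", "X")])
        labels = _labels({"L": "Bacteria", "X": "Eukaryota"})
        out, report = transfer_labels(g, labels, RANK, cfg, mode="extend_taxonomy")
        # conflict at distance 3 from L -> L's label reaches only distance 1;
        # the symmetric transfer from X may still label u2 with X's own label
        assert out.get("u1", RANK).label == "Bacteria"
        assert out.label_of("u2", RANK) != "Bacteria"
        assert report.iloc[0]["action"] == "truncated_at_distance"

    def test_distance_limit_without_conflict(self):
        cfg = RunConfig(vertexdist=2)
        g = nx.path_graph(["L", "u1", "u2", "u3"])
        labels = _labels({"L": "Bacteria"})
        out, _ = transfer_labels(g, labels, RANK, cfg, mode="extend_taxonomy")
        assert out.get("u1", RANK) is not None and out.get("u2", RANK) is not None
        assert out.get("u3", RANK) is None

    def test_adjacent_conflict_blocks_transfer_entirely(self):
        # conflict at n<=2 means nothing beyond the source itself is labeled
        cfg = RunConfig(vertexdist=3)
        g = nx.path_graph(["L", "u1", "X"])
        labels = _labels({"L": "Bacteria", "X": "Eukaryota"})
        out, _ = transfer_labels(g, labels, RANK, cfg, mode="extend_taxonomy")
        assert out.get("u1", RANK) is None

    def test_conflicting_proposals_left_unlabeled(self):
        cfg = RunConfig(vertexdist=4)
        # u is 3 hops from both L1 and L2 which disagree; within 1 hop of none
        g = nx.path_graph(["L1", "a", "b", "u", "c", "d", "L2"])
        labels = _labels({"L1": "Bacteria", "L2": "Eukaryota"})
        out, _ = transfer_labels(g, labels, RANK, cfg, mode="extend_taxonomy")
        assert out.get("u", RANK) is None


class TestProperties:
    @pytest.mark.parametrize("seed", range(10))
    def test_labels_never_cross_components(self, seed, cfg):
        """On random multi-CC graphs, a label only spreads inside its CC."""
        rng = np.random.default_rng(seed)
        g = nx.Graph()
        label_home = {}
        for cc in range(int(rng.integers(2, 6))):
            nodes = [f"cc{cc}_n{i}" for i in range(int(rng.integers(2, 8)))]
            g.add_nodes_from(nodes)
            for _ in range(len(nodes) + 2):
                u, v = rng.choice(nodes, 2, replace=False)
                g.add_edge(u, v)
            label_home[f"taxon_{cc}"] = nodes
        labels = TaxonomyLabels()
        for taxon, nodes in label_home.items():
            labels.set(nodes[0], RANK, Label(taxon, 1.0, SOURCE_HOMOLOGY))
        out, _ = transfer_labels(g, labels, RANK, cfg, mode="extend_taxonomy")
        for taxon, nodes in label_home.items():
            for contig in out.contigs_at(RANK):
                if out.label_of(contig, RANK) == taxon:
                    assert contig in nodes

    def test_report_covers_every_cc_member_once(self, cfg, mixture):
        g = build_graph(mixture.links, cfg)
        _, report = transfer_labels(g, TaxonomyLabels(), RANK, cfg,
                                    mode="extend_taxonomy")
        members = [m for row in report["members"] for m in row.split(";")]
        assert len(members) == len(set(members)) == g.number_of_nodes()

    def test_no_cross_genome_extension_on_clean_mixture(self, cfg, mixture):
        """With zero link noise, graph-extended labels are always correct."""
        from endobin import assign_taxonomy
        from endobin.io import filter_hits

        hits = filter_hits(mixture.hits, cfg)
        labels = assign_taxonomy(hits, mixture.lineage, RANK, cfg)
        g = build_graph(mixture.links, cfg)
        out, _ = transfer_labels(g, labels, RANK, cfg, mode="extend_taxonomy")
        truth = dict(zip(mixture.truth["contig_id"], mixture.truth["superkingdom"]))
        extended = [c for c in out.contigs_at(RANK)
                    if out.get(c, RANK).source == SOURCE_GRAPH]
        assert extended, "graph extension labeled nothing"
        assert all(out.label_of(c, RANK) == truth[c] for c in extended)
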