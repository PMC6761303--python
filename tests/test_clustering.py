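"""UMAP+DBSCAN target-cluster selection and graph extension."""

import numpy as np
import pandas as pd
import pytest

from endobin import RunConfig, embed_and_cluster, select_target_cluster
from endobin.clustering import NOISE, extend_target_set, knee_eps
from endobin.composition import build_kmer_matrix
from endobin.io import ContigSet
from endobin.synthetic import sample_chain, transition_from_gc


def _genome_contigs(name, gc, n, seed, length=1500, transition=None):
    rng = np.random.default_rng(seed)
    trans = transition if transition is not None else transition_from_gc(gc, rng)
    return {f"{name}{i:03d}": sample_chain(trans, length, rng) for i in range(n)}


def _purity(frame, ids):
    sub = frame.loc[ids, "cluster"]
    top = sub.value_counts().idxmax()
    return (sub == top).mean(), top


@pytest.fixture(scope="module")
def two_genome_assignment():
    cfg = RunConfig(seed=9)
    a = _genome_contigs("a", 0.35, 150, seed=1)
    b = _genome_contigs("b", 0.60, 150, seed=2)
    features = build_kmer_matrix(ContigSet(a | b), cfg)
    assign = embed_and_cluster(features, None, cfg)
    return assign, sorted(a), sorted(b)


def test_divergent_genomes_separate(two_genome_assignment):
    assign, ids_a, ids_b = two_genome_assignment
    n_clusters = len(set(assign.clusters) - {NOISE})
    assert n_clusters >= 2
    purity_a, top_a = _purity(assign.frame, ids_a)
    purity_b, top_b = _purity(assign.frame, ids_b)
    assert purity_a >= 0.9 and purity_b >= 0.9
    assert top_a != top_b and NOISE not in (top_a, top_b)


def test_same_seed_identical_memberships():
    cfg = RunConfig(seed=9)
    contigs = ContigSet(_genome_contigs("a", 0.35, 40, seed=1)
                        | _genome_contigs("b", 0.60, 40, seed=2))
    features = build_kmer_matrix(contigs, cfg)
    a1 = embed_and_cluster(features, None, cfg)
    a2 = embed_and_cluster(features, None, cfg)
    pd.testing.assert_frame_equal(a1.frame, a2.frame)


def test_coverage_channel_separates_identical_composition():
    """Same Markov chain, 10x coverage ratio, feature_type={kmers,cov}."""
    rng = np.random.default_rng(7)
    trans = transition_from_gc(0.45, rng)
    a = _genome_contigs("a", 0.45, 120, seed=3, transition=trans)
    b = _genome_contigs("b", 0.45, 120, seed=4, transition=trans)
    cfg = RunConfig(seed=11, feature_type=("kmers", "cov"))
    contigs = ContigSet(a | b)
    features = build_kmer_matrix(contigs, cfg)
    rng2 = np.random.default_rng(12)
    cov_rows = [
        (cid, 1500, n, n / 1500)
        for cid in sorted(contigs.ids)
        for n in [rng2.poisson(300 if cid.startswith("a") else 30)]
    ]
    coverage = pd.DataFrame(cov_rows, columns=["contig_id", "length", "fragment_count", "coverage"])
    assign = embed_and_cluster(features, coverage, cfg)
    purity_a, top_a = _purity(assign.frame, sorted(a))
    purity_b, top_b = _purity(assign.frame, sorted(b))
    assert purity_a >= 0.9 and purity_b >= 0.9 and top_a != top_b


def test_single_genome_one_dominant_cluster():
    cfg = RunConfig(seed=13)
    contigs = ContigSet(_genome_contigs("a", 0.50, 120, seed=5))
    features = build_kmer_matrix(contigs, cfg)
    assign = embed_and_cluster(features, None, cfg)
    non_noise = assign.frame[assign.frame["cluster"] != NOISE]
    dominant = non_noise["cluster"].value_counts().max()
    assert dominant / len(assign.frame) >= 0.8


def test_too_few_contigs_error():
    cfg = RunConfig(seed=1)
    contigs = ContigSet(_genome_contigs("a", 0.5, 5, seed=6))
    features = build_kmer_matrix(contigs, cfg)
    with pytest.raises(ValueError, match="disabling clustering"):
        embed_and_cluster(features, None, cfg)


class TestSelectTarget:
    def test_members_of_anchor_cluster(self, two_genome_assignment):
        assign, ids_a, ids_b = two_genome_assignment
        _, top_b = _purity(assign.frame, ids_b)
        anchor = next(c for c in ids_b if assign.frame.loc[c, "cluster"] == top_b)
        target = select_target_cluster(assign, anchor)
        assert target == set(assign.members(top_b))
        assert assign.frame.loc[sorted(target), "is_target"].all()
        assert not assign.frame.loc[assign.frame["cluster"] == NOISE, "is_target"].any()

    def test_absent_anchor_error(self, two_genome_assignment):
        assign, *_ = two_genome_assignment
        with pytest.raises(KeyError, match="graph-extension"):
            select_target_cluster(assign, "ghost")

    def test_noise_anchor_error(self, two_genome_assignment):
        assign, *_ = two_genome_assignment
        noisy = assign.frame.copy()
        noisy.loc[noisy.index[0], "cluster"] = NOISE
        from endobin.clustering import ClusterAssignment

        broken = ClusterAssignment(frame=noisy, eps=assign.eps)
        with pytest.raises(ValueError, match="noise"):
            select_target_cluster(broken, noisy.index[0])


def test_graph_extension_adds_linked_short_contigs(two_genome_assignment):
    import networkx as nx

    assign, ids_a, ids_b = two_genome_assignment
    _, top_b = _purity(assign.frame, ids_b)
    anchor = next(c for c in ids_b if assign.frame.loc[c, "cluster"] == top_b)
    target = select_target_cluster(assign, anchor)
    g = nx.Graph()
    g.add_edge(anchor, "short_1", weight=20)
    g.add_edge("short_1", "short_2", weight=20)
    other = next(c for c in ids_a if assign.frame.loc[c, "cluster"] != top_b)
    g.add_edge(other, "short_host", weight=20)
    cfg = RunConfig(seed=9)
    extended, report = extend_target_set(target, assign, g, cfg)
    assert {"short_1", "short_2"} <= extended
    assert "short_host" not in extended


def test_knee_eps_positive_and_scale_covariant():
    rng = np.random.default_rng(0)
    x = rng.normal(size=(200, 2))
    e1 = knee_eps(x, 5)
    e2 = knee_eps(10 * x, 5)
    assert e1 > 0 and e2 == pytest.approx(10 * e1, rel=1e-6)
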