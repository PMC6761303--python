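"""Ensemble RF/SVM voting: recovery, determinism, vote arithmetic."""

import numpy as np
import pandas as pd
import pytest

from endobin import RunConfig, build_kmer_matrix, train_and_vote
from endobin.classifier import apply_votes, infer_rank_targets, nested_classify
from endobin.composition import build_kmer_matrix
from endobin.io import ContigSet
from endobin.synthetic import (
    GenomeSpec,
    MixtureSpec,
    generate_mixture,
    sample_chain,
    three_genome_spec,
    transition_from_gc,
)
from endobin.taxonomy import SOURCE_HOMOLOGY, SOURCE_PREDICTED, Label, TaxonomyLabels

RANK = "superkingdom"


def _two_class_dataset(n_per_class=60, n_unlabeled_per_class=20, seed=3, length=1500):
    """Contigs from two divergent Markov chains with partial labels."""
    rng = np.random.default_rng(seed)
    t_a = transition_from_gc(0.35, rng)
    t_b = transition_from_gc(0.60, rng)
    entries, labels, truth = {}, TaxonomyLabels(), {}
    for name, trans, taxon in (("a", t_a, "Eukaryota"), ("b", t_b, "Bacteria")):
        for i in range(n_per_class + n_unlabeled_per_class):
            cid = f"{name}{i:03d}"
            entries[cid] = sample_chain(trans, length, rng)
            truth[cid] = taxon
            if i < n_per_class:
                labels.set(cid, RANK, Label(taxon, 1.0, SOURCE_HOMOLOGY))
    return ContigSet(entries), labels, truth


@pytest.fixture(scope="module")
def small_sep():
    cfg = RunConfig(n_replicates=15, seed=5)
    contigs, labels, truth = _two_class_dataset()
    features = build_kmer_matrix(contigs, cfg)
    return cfg, features, labels, truth


@pytest.mark.parametrize("algo", ["svm", "rf"])
def test_separable_classes_recovered(small_sep, algo):
    cfg, features, labels, truth = small_sep
    vm = train_and_vote(features, labels, RANK, algo, cfg)
    assert vm.mean_heldout_accuracy > 0.9
    correct = sum(vm.final[c] == truth[c] for c in vm.final.index)
    assert correct / len(vm.final) > 0.9


def test_vote_fractions_sum_to_one_and_argmax_is_final(small_sep):
    cfg, features, labels, _ = small_sep
    vm = train_and_vote(features, labels, RANK, "svm", cfg)
    np.testing.assert_allclose(vm.votes.sum(axis=1), 1.0)
    assert len(vm.replicate_scores) == cfg.n_replicates
    for c in vm.final.index:
        if not pd.isna(vm.final[c]):
            assert vm.votes.loc[c, vm.final[c]] == vm.votes.loc[c].max()


def test_same_seed_identical_votes(small_sep):
    cfg, features, labels, _ = small_sep
    vm1 = train_and_vote(features, labels, RANK, "svm", cfg)
    vm2 = train_and_vote(features, labels, RANK, "svm", cfg)
    pd.testing.assert_frame_equal(vm1.votes, vm2.votes)
    pd.testing.assert_frame_equal(vm1.replicate_scores, vm2.replicate_scores)


def test_apply_votes_never_overwrites(small_sep):
    cfg, features, labels, _ = small_sep
    vm = train_and_vote(features, labels, RANK, "svm", cfg)
    out = apply_votes(labels, vm)
    for c in labels.contigs_at(RANK):
        assert out.get(c, RANK) == labels.get(c, RANK)
    predicted = [c for c in out.contigs_at(RANK)
                 if out.get(c, RANK).source == SOURCE_PREDICTED]
    assert set(predicted) == set(c for c in vm.final.index if not pd.isna(vm.final[c]))


def test_small_classes_dropped_then_error(small_sep):
    cfg, features, labels, _ = small_sep
    sparse = TaxonomyLabels()
    for i, c in enumerate(labels.contigs_at(RANK)):
        if labels.label_of(c, RANK) == "Bacteria" and i % 17 == 0:
            continue
        sparse.set(c, RANK, labels.get(c, RANK))
    # drop Bacteria below min size entirely
    tiny = TaxonomyLabels()
    bact = [c for c in labels.contigs_at(RANK) if labels.label_of(c, RANK) == "Bacteria"]
    euk = [c for c in labels.contigs_at(RANK) if labels.label_of(c, RANK) == "Eukaryota"]
    for c in euk + bact[:5]:
        tiny.set(c, RANK, labels.get(c, RANK))
    with pytest.raises(ValueError, match=">=2 classes"):
        train_and_vote(features, tiny, RANK, "svm", cfg)


def test_confident_votes_stable_under_more_replicates(small_sep):
    """Labels voted with fraction >= 0.7 barely flip (<=1%) when the
    replicate count is quadrupled."""
    _, features, labels, _ = small_sep
    lo = train_and_vote(features, labels, RANK, "svm", RunConfig(seed=5, n_replicates=100))
    hi = train_and_vote(features, labels, RANK, "svm", RunConfig(seed=5, n_replicates=400))
    confident = [c for c in lo.final.index
                 if not pd.isna(lo.final[c]) and lo.votes.loc[c, lo.final[c]] >= 0.7]
    assert confident
    flips = sum(hi.final[c] != lo.final[c] for c in confident)
    assert flips / len(confident) <= 0.01


def test_infer_rank_targets():
    lineage = pd.DataFrame(
        [
            {"taxid": 1, "superkingdom": "Bacteria", "class": "Alphaproteobacteria"},
            {"taxid": 2, "superkingdom": "Eukaryota", "class": "Saccharomycetes"},
        ]
    ).set_index("taxid")
    targets = infer_rank_targets(lineage, ("superkingdom", "class"), "Alphaproteobacteria")
    assert targets == {"superkingdom": "Bacteria", "class": "Alphaproteobacteria"}
    with pytest.raises(ValueError, match="not found"):
        infer_rank_targets(lineage, ("superkingdom",), "Cytophagia")


def test_nested_class_universe_excludes_eukaryote_truth():
    """Three-genome mixture, superkingdom -> class: the class-level run only
    sees contigs assigned to Bacteria at superkingdom."""
    cfg = RunConfig(
        n_replicates=8, seed=2, rank_sequence=("superkingdom", "class"),
        target_rank_label="Alphaproteobacteria", min_class_size=5,
    )
    mix = generate_mixture(three_genome_spec(seed=4))
    from endobin.io import filter_hits
    from endobin import assign_taxonomy, build_graph, transfer_labels

    hits = filter_hits(mix.hits, cfg)
    labels = TaxonomyLabels()
    for rank in cfg.rank_sequence:
        labels.merge(assign_taxonomy(hits, mix.lineage, rank, cfg))
    graph = build_graph(mix.links, cfg)
    for rank in cfg.rank_sequence:
        labels, _ = transfer_labels(graph, labels, rank, cfg, mode="extend_taxonomy")
    features = build_kmer_matrix(mix.contigs, cfg)
    out, vms = nested_classify(features, labels, "svm", cfg,
                               graph=graph, lineage=mix.lineage)
    assert [vm.rank for vm in vms] == ["superkingdom", "class"]
    truth_sk = dict(zip(mix.truth["contig_id"], mix.truth["superkingdom"]))
    class_universe = set(vms[1].votes.index) | {
        c for c in features.index
        if (lab := out.get(c, "class")) is not None and lab.source == SOURCE_PREDICTED
    }
    assert class_universe, "class-level iteration saw no contigs"
    assert all(truth_sk[c] == "Bacteria" for c in class_universe)
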