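"""Ensemble classification of contigs from composition features.

Random-forest and RBF-kernel SVM models are trained ``n_replicates`` times
(default 100) on stratified random splits of the labeled contigs
(``train_frac`` for training, the remainder for a held-out accuracy
estimate). Every replicate model then predicts every unlabeled contig;
a contig's vote fraction for a class is the share of replicates assigning
it that class, and its final label is the top-voted class (exact ties are
flagged ambiguous and left unlabeled). Classification can be nested over a
rank sequence, restricting each finer rank to contigs assigned to the
target lineage at the previous rank.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedShuffleSplit
from sklearn.svm import SVC

from .composition import kmer_feature_columns
from .io import RunConfig
from .pair_graph import transfer_labels
from .taxonomy import (
    SOURCE_GRAPH,
    SOURCE_HOMOLOGY,
    SOURCE_PREDICTED,
    Label,
    TaxonomyLabels,
)

logger = logging.getLogger("endobin")

ALGORITHMS = ("rf", "svm")
#: label sources usable as training truth
TRUSTED_SOURCES = (SOURCE_HOMOLOGY, SOURCE_GRAPH)


@dataclass
class VoteMatrix:
    """Ensemble voting result at one rank for one algorithm.

    ``votes``: contig x class vote fractions (rows sum to 1);
    ``final``: top-voted label per contig (NaN where tied/ambiguous);
    ``replicate_scores``: held-out accuracy per replicate.
    """

    algo: str
    rank: str
    votes: pd.DataFrame
    final: pd.Series
    replicate_scores: pd.DataFrame

    @property
    def mean_heldout_accuracy(self) -> float:
        return float(self.replicate_scores["accuracy"].mean())


def derive_seed(master: int, *parts: str) -> int:
    """Stable stage-specific seed below 2**31 derived from the master seed."""
    text = ":".join((str(master), *parts))
    return zlib.crc32(text.encode()) % (2 ** 31)


def _feature_frame(
    features: pd.DataFrame, cfg: RunConfig, coverage: pd.DataFrame | None
) -> pd.DataFrame:
    cols = kmer_feature_columns(features)
    x = features[cols].copy()
    if "gc" in cfg.feature_type:
        x["gc"] = features["gc"]
    if "cov" in cfg.feature_type:
        if coverage is None:
            raise ValueError("feature_type includes 'cov' but no coverage table given")
        cov = coverage.set_index("contig_id")["coverage"]
        x["cov"] = cov.reindex(x.index).fillna(0.0)
    return x


def train_and_vote(
    features: pd.DataFrame,
    labels: TaxonomyLabels,
    rank: str,
    algo: str,
    cfg: RunConfig,
    coverage: pd.DataFrame | None = None,
) -> VoteMatrix:
    """Repeated stratified training and ensemble voting at one rank.

    Labeled contigs are those in ``features`` carrying a homology- or
    graph-derived label at ``rank``; classes with fewer than
    ``cfg.min_class_size`` members are dropped with a warning, and fewer
    than two surviving classes is a hard error. Fully reproducible from
    ``cfg.seed``.
    """
    if algo not in ALGORITHMS:
        raise ValueError(f"unknown algorithm {algo!r}; expected one of {ALGORITHMS}")

    x = _feature_frame(features, cfg, coverage)
    labeled_ids = [c for c in x.index if (lab := labels.get(c, rank)) is not None
                   and lab.source in TRUSTED_SOURCES]
    y = pd.Series({c: labels.label_of(c, rank) for c in labeled_ids})
    class_sizes = y.value_counts()
    small = class_sizes[class_sizes < cfg.min_class_size]
    if len(small):
        logger.warning(
            "dropping classes below %d labeled contigs: %s",
            cfg.min_class_size, dict(small),
        )
        y = y[~y.isin(small.index)]
    if y.nunique() < 2:
        raise ValueError(
            f"need >=2 classes with >= {cfg.min_class_size} labeled contigs at "
            f"rank {rank!r} (got {y.nunique()}); consider graph extension of the "
            "taxonomy or looser hit/density thresholds"
        )
    train_ids = y.index.to_numpy()
    unlabeled_ids = [c for c in x.index if c not in set(train_ids)]
    classes = sorted(y.unique())

    seed = derive_seed(cfg.seed, "classifier", algo, rank)
    splitter = StratifiedShuffleSplit(
        n_splits=cfg.n_replicates, train_size=cfg.train_frac, random_state=seed
    )
    rep_seeds = np.random.SeedSequence(seed).generate_state(cfg.n_replicates)

    vote_counts = pd.DataFrame(0.0, index=unlabeled_ids, columns=classes)
    scores = []
    x_lab = x.loc[train_ids].to_numpy()
    y_lab = y.to_numpy()
    x_unl = x.loc[unlabeled_ids].to_numpy() if unlabeled_ids else None

    for rep, (tr, te) in enumerate(splitter.split(x_lab, y_lab)):
        model = _make_model(algo, cfg, int(rep_seeds[rep] % (2 ** 31)))
        model.fit(x_lab[tr], y_lab[tr])
        scores.append((rep, float(model.score(x_lab[te], y_lab[te]))))
        if x_unl is not None and len(x_unl):
            pred = model.predict(x_unl)
            for cls in classes:
                vote_counts.loc[:, cls] += (pred == cls).astype(float)

    votes = vote_counts / cfg.n_replicates
    final = pd.Series(pd.NA, index=votes.index, dtype=object)
    if len(votes):
        top = votes.max(axis=1)
        for c in votes.index:
            row = votes.loc[c]
            winners = row[row == top[c]].index
            if len(winners) == 1:
                final[c] = winners[0]
            else:
                logger.warning("ambiguous vote tie for contig %s; left unlabeled", c)
    return VoteMatrix(
        algo=algo,
        rank=rank,
        votes=votes,
        final=final,
        replicate_scores=pd.DataFrame(scores, columns=["replicate", "accuracy"]),
    )


def _make_model(algo: str, cfg: RunConfig, seed: int):
    if algo == "rf":
        return RandomForestClassifier(
            n_estimators=cfg.rf_n_estimators, random_state=seed, n_jobs=1
        )
    return SVC(kernel="rbf", C=cfg.svm_c, gamma=cfg.svm_gamma, random_state=seed)


def apply_votes(labels: TaxonomyLabels, vm: VoteMatrix) -> TaxonomyLabels:
    """Record final voted labels with source=predicted (never overwriting)."""
    out = labels.copy()
    for contig, label in vm.final.items():
        if pd.isna(label):
            continue
        if out.get(contig, vm.rank) is None:
            out.set(
                contig, vm.rank,
                Label(label, float(vm.votes.loc[contig, label]), SOURCE_PREDICTED),
            )
    return out


def infer_target_lineage(
    lineage: pd.DataFrame, target_rank_label: str
) -> tuple[str, pd.Series]:
    """Locate the target taxon label in the lineage table.

    Returns the (coarsest) rank at which the label occurs and one matching
    lineage row, from which ancestor labels can be read.
    """
    from .io import CANONICAL_RANKS

    for rank in CANONICAL_RANKS:
        if rank in lineage.columns:
            match = lineage[lineage[rank] == target_rank_label]
            if len(match):
                return rank, match.iloc[0]
    raise ValueError(
        f"label {target_rank_label!r} not found at any rank of the lineage table"
    )


def infer_rank_targets(
    lineage: pd.DataFrame, rank_sequence: tuple[str, ...], target_rank_label: str
) -> dict[str, str]:
    """Ancestor labels of the target taxon at each rank of the sequence
    (e.g. superkingdom=Bacteria for an Alphaproteobacteria target)."""
    _, row = infer_target_lineage(lineage, target_rank_label)
    targets = {}
    for rank in rank_sequence:
        if pd.isna(row.get(rank)):
            raise ValueError(f"target lineage lacks rank {rank!r}")
        targets[rank] = row[rank]
    return targets


def nested_classify(
    features: pd.DataFrame,
    labels: TaxonomyLabels,
    algo: str,
    cfg: RunConfig,
    graph=None,
    lineage: pd.DataFrame | None = None,
    coverage: pd.DataFrame | None = None,
) -> tuple[TaxonomyLabels, list[VoteMatrix]]:
    """Nested classification over ``cfg.rank_sequence`` (coarse to fine).

    Each iteration after the first restricts the contig universe to contigs
    assigned (by homology, graph extension or prediction) to the target
    lineage at the previous rank. After each rank, predictions are checked
    against the read-pair graph (mode=correct_predictions) when a graph is
    supplied.
    """
    ranks = cfg.rank_sequence
    if len(ranks) > 1 or cfg.target_rank_label is not None:
        if cfg.target_rank_label is None:
            raise ValueError("nested classification needs target_rank_label")
        if lineage is None:
            raise ValueError("nested classification needs a lineage table")
        targets = infer_rank_targets(lineage, ranks, cfg.target_rank_label)
    else:
        targets = {}

    out = labels.copy()
    universe = list(features.index)
    votematrices = []
    for i, rank in enumerate(ranks):
        if i > 0:
            prev = ranks[i - 1]
            want = targets[prev]
            universe = [c for c in universe if out.label_of(c, prev) == want]
            if not universe:
                raise ValueError(
                    f"no contigs assigned to {want!r} at rank {prev!r}; "
                    "nothing to classify at finer ranks"
                )
        vm = train_and_vote(
            features.loc[universe], out, rank, algo, cfg, coverage=coverage
        )
        out = apply_votes(out, vm)
        votematrices.append(vm)
        if graph is not None:
            out, _ = transfer_labels(graph, out, rank, cfg, mode="correct_predictions")
    return out, votematrices
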