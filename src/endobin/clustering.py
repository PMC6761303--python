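"""Final unsupervised step: embed, cluster, and anchor on the target 16S.

The contigs predicted as the target lineage are embedded from their
canonical k-mer frequencies with UMAP (default 2 components); optional GC
and coverage channels are z-score standardized and appended to the
embedding coordinates. DBSCAN then partitions the embedded contigs, the
cluster holding the target 16S contig is flagged as the target genome,
and the read-pair graph can extend that membership to contigs (typically
short ones) excluded from the composition matrix.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import DBSCAN
from sklearn.neighbors import NearestNeighbors

from .classifier import derive_seed
from .composition import kmer_feature_columns
from .io import RunConfig
from .pair_graph import transfer_labels
from .taxonomy import SOURCE_CLUSTER, Label, TaxonomyLabels

logger = logging.getLogger("endobin")

NOISE = -1
CLUSTER_RANK = "superkingdom"  # transfer machinery needs a rank slot; any fixed one works
TARGET = "target"
NONTARGET = "nontarget"


@dataclass
class ClusterAssignment:
    """Embedding coordinates + DBSCAN cluster per contig.

    ``frame`` columns: emb_0..emb_{ncomp-1}, cluster (int, -1 = noise),
    is_target (set by :func:`select_target_cluster`).
    """

    frame: pd.DataFrame
    eps: float

    @property
    def clusters(self) -> pd.Series:
        return self.frame["cluster"]

    def members(self, cluster_id: int) -> list[str]:
        return sorted(self.frame.index[self.frame["cluster"] == cluster_id])


def knee_eps(x: np.ndarray, min_samples: int) -> float:
    """DBSCAN eps from the elbow of the sorted k-NN distance curve.

    The sorted ``min_samples``-NN distances form an increasing convex
    curve; the knee is the point farthest below the chord from the first
    to the last point (a kneedle-style criterion). Falls back to the 75th
    percentile when the curve is degenerate.
    """
    nn = NearestNeighbors(n_neighbors=min_samples + 1).fit(x)
    dist, _ = nn.kneighbors(x)
    kdist = np.sort(dist[:, -1])
    if kdist[-1] <= 0:
        return 1e-3
    xs = np.linspace(0, 1, len(kdist))
    ys = (kdist - kdist[0]) / (kdist[-1] - kdist[0])
    knee = int(np.argmax(xs - ys))
    eps = float(kdist[knee])
    if eps <= 0:
        eps = float(np.percentile(kdist, 75)) or 1e-3
    return eps


def embed_and_cluster(
    features: pd.DataFrame,
    coverage: pd.DataFrame | None,
    cfg: RunConfig,
) -> ClusterAssignment:
    """UMAP embedding of the k-mer columns followed by DBSCAN.

    ``features`` must already be restricted to the predicted-target
    contigs. Deterministic under ``cfg.seed`` (UMAP runs single-threaded
    with a fixed random state).
    """
    n = len(features)
    min_needed = max(10, cfg.dbscan_min_samples)
    if n < min_needed:
        raise ValueError(
            f"only {n} contigs to cluster (need >= {min_needed}); consider "
            "disabling clustering and extracting the voted target contigs directly"
        )
    import umap

    x = features[kmer_feature_columns(features)].to_numpy()
    seed = derive_seed(cfg.seed, "clustering")
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*n_jobs.*")
        warnings.filterwarnings("ignore", message=".*random_state.*")
        reducer = umap.UMAP(
            n_components=cfg.ncomp,
            n_neighbors=min(cfg.umap_n_neighbors, n - 1),
            min_dist=cfg.umap_min_dist,
            metric="euclidean",
            random_state=seed,
            n_jobs=1,
        )
        emb = reducer.fit_transform(x)

    z = emb
    extras = []
    if "gc" in cfg.feature_type:
        extras.append(features["gc"].to_numpy())
    if "cov" in cfg.feature_type:
        if coverage is None:
            raise ValueError("feature_type includes 'cov' but no coverage table given")
        cov = coverage.set_index("contig_id")["coverage"]
        extras.append(cov.reindex(features.index).fillna(0.0).to_numpy())
    for col in extras:
        sd = col.std()
        zcol = (col - col.mean()) / sd if sd > 0 else np.zeros_like(col)
        z = np.column_stack([z, zcol])

    eps = cfg.dbscan_eps if cfg.dbscan_eps is not None else knee_eps(z, cfg.dbscan_min_samples)
    cl = DBSCAN(eps=eps, min_samples=cfg.dbscan_min_samples).fit(z)

    frame = pd.DataFrame(
        emb, index=features.index, columns=[f"emb_{i}" for i in range(cfg.ncomp)]
    )
    frame["cluster"] = cl.labels_
    frame["is_target"] = False
    n_clusters = len(set(cl.labels_) - {NOISE})
    logger.info("DBSCAN (eps=%.4g): %d clusters, %d noise points",
                eps, n_clusters, int((cl.labels_ == NOISE).sum()))
    return ClusterAssignment(frame=frame, eps=eps)


def select_target_cluster(assign: ClusterAssignment, target_16s_contig: str) -> set[str]:
    """All contigs sharing the target 16S contig's cluster.

    Flags that cluster in the assignment. A noise-classified or absent
    anchor is a hard error (the error message points to the remedy).
    """
    frame = assign.frame
    if target_16s_contig not in frame.index:
        raise KeyError(
            f"target 16S contig {target_16s_contig!r} is not in the clustered set "
            "(it may be shorter than min_contig_len or not predicted as the "
            "target lineage); use the graph-extension path to recover it"
        )
    cid = int(frame.loc[target_16s_contig, "cluster"])
    if cid == NOISE:
        emb_cols = [c for c in frame.columns if c.startswith("emb_")]
        pt = frame.loc[target_16s_contig, emb_cols].to_numpy(dtype=float)
        non_noise = frame[frame["cluster"] != NOISE]
        hint = ""
        if len(non_noise):
            d = np.linalg.norm(non_noise[emb_cols].to_numpy(dtype=float) - pt, axis=1)
            i = int(np.argmin(d))
            hint = (f"; nearest cluster is {int(non_noise['cluster'].iloc[i])} "
                    f"at embedding distance {d[i]:.3f}")
        raise ValueError(
            f"target 16S contig {target_16s_contig!r} was classified as noise{hint}; "
            "consider overriding dbscan_eps"
        )
    members = assign.members(cid)
    assign.frame.loc[members, "is_target"] = True
    if len(members) == 1:
        logger.warning("target cluster contains only the 16S contig itself")
    return set(members)


def cluster_membership_labels(assign: ClusterAssignment, target_set: set[str]) -> TaxonomyLabels:
    """Cluster membership as transferable labels (target vs nontarget).

    Noise points stay unlabeled so that graph extension can still reach
    them.
    """
    labels = TaxonomyLabels()
    for contig, row in assign.frame.iterrows():
        if int(row["cluster"]) == NOISE:
            continue
        name = TARGET if contig in target_set else NONTARGET
        labels.set(contig, CLUSTER_RANK, Label(name, 1.0, SOURCE_CLUSTER))
    return labels


def extend_target_set(
    target_set: set[str],
    assign: ClusterAssignment,
    graph,
    cfg: RunConfig,
) -> tuple[set[str], pd.DataFrame]:
    """Extend the target cluster through the read-pair graph.

    Short contigs excluded from the composition matrix (and DBSCAN noise
    points) sit in the graph; connected components anchored by clustered
    contigs transfer their membership to them under the usual rules.
    Returns the extended target set and the transfer report.
    """
    labels = cluster_membership_labels(assign, target_set)
    extended, report = transfer_labels(graph, labels, CLUSTER_RANK, cfg, mode="extend_clusters")
    out = set(target_set)
    for contig in extended.contigs_at(CLUSTER_RANK):
        if extended.label_of(contig, CLUSTER_RANK) == TARGET:
            out.add(contig)
    return out, report
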