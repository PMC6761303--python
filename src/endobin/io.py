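"""Input/output layer: run configuration, core domain containers, and readers
for every external format the pipeline consumes.

Formats handled here: FASTA (assembly contigs), SAM/BAM or a simplified
mate-TSV dialect (read-pair placements), BLAST tabular outfmt-6 with a
trailing subject-taxid column (nucleotide / protein / 16S homology hits),
a ranked-lineage TSV (taxid -> labels per rank), GFF3 (rRNA gene calls),
and YAML run configuration.

Coordinate convention: GFF3 input is 1-based inclusive and is converted to
0-based half-open on load; every internal record stores 0-based half-open
coordinates.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("endobin")

#: canonical taxonomic rank list, coarse to fine
CANONICAL_RANKS = (
    "superkingdom",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
)

#: column schema of an in-memory hit table
HIT_COLUMNS = ("query_id", "contig_id", "subject_taxid", "pident", "hsp_len", "source")

#: column schema of an in-memory mate-link table
LINK_COLUMNS = ("fragment_id", "contig_a", "contig_b", "type")

#: BLAST outfmt-6 column names; a subject-taxid column is appended last
BLAST6_COLUMNS = (
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore", "staxid",
)

HIT_SOURCES = ("nucleotide", "protein")

#: output-folder layout of a standard run
OUTPUT_FOLDERS = (
    "Taxonomy",
    "Coverage",
    "SVMoutput",
    "RFoutput",
    "ClusteringOutputSVM",
    "ClusteringOutputRF",
)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID_BASES = frozenset("ACGTN")


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase DNA string over {A,C,G,T,N}."""
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """All tunable thresholds of a run, with the tool's default values.

    Attributes
    ----------
    k : k-mer length for composition features (default 3).
    min_contig_len : minimum contig length (nt) for composition-based steps;
        the threshold is inclusive (default 1000).
    nt_min_hsp, nt_min_pident : nucleotide-hit filters, HSP length in bp
        (>=200) and percent identity (>=70); inclusive.
    prot_min_hsp, prot_min_pident : protein-hit filters, HSP length in aa
        (>=70) and percent identity (>=80); inclusive.
    taxon_density_min : minimum fraction of a contig's homology hits that
        must agree on one label for the label to be kept (default 0.75,
        inclusive).
    edges_min : minimum read-pair support for a graph edge (default 10).
    vertices_max_degree : maximum vertex degree after edge filtering; higher
        degree vertices are dropped (default 5; None disables the filter).
    mixedcomp_max : maximum tolerated fraction of discordant labeled contigs
        in a connected component before label transfer is vetoed
        (default 0.2).
    vertexdist : "all" (transfer to the whole component under the majority
        rule) or an integer hop distance for per-source transfer with the
        n-2 conflict truncation.
    n_replicates : number of train/test resampling replicates (default 100).
    train_frac : fraction of labeled contigs used for training each
        replicate (default 0.66).
    clustering_enabled : run the final UMAP+DBSCAN step (flow A) when True,
        otherwise extract the voted target contigs directly (flow B).
    ncomp : UMAP embedding dimensionality (default 2).
    feature_type : subset of {"kmers","gc","cov"}; gc/cov are standardized
        and appended to the UMAP coordinates before density clustering.
    rank_sequence : ordered ranks for nested classification, coarse to fine.
    target_rank_label : taxon label of the target organism at the last rank
        of ``rank_sequence`` (e.g. "Alphaproteobacteria").
    seed : master seed; every stochastic stage derives its own stream.
    """

    k: int = 3
    min_contig_len: int = 1000
    nt_min_hsp: int = 200
    nt_min_pident: float = 70.0
    prot_min_hsp: int = 70
    prot_min_pident: float = 80.0
    taxon_density_min: float = 0.75
    edges_min: int = 10
    vertices_max_degree: int | None = 5
    mixedcomp_max: float = 0.2
    vertexdist: int | str = "all"
    n_replicates: int = 100
    train_frac: float = 0.66
    clustering_enabled: bool = True
    ncomp: int = 2
    feature_type: tuple[str, ...] = ("kmers",)
    rank_sequence: tuple[str, ...] = ("superkingdom",)
    target_rank_label: str | None = None
    seed: int = 0
    # model hyperparameters (exposed, defaults documented in docs/methods.md)
    min_class_size: int = 10
    rf_n_estimators: int = 500
    svm_c: float = 1.0
    svm_gamma: str | float = "scale"
    umap_n_neighbors: int = 15
    umap_min_dist: float = 0.1
    dbscan_min_samples: int = 5
    dbscan_eps: float | None = None
    iterate_degree_filter: bool = False
    min_mapq: int = 0

    def __post_init__(self) -> None:
        self.feature_type = tuple(self.feature_type)
        self.rank_sequence = tuple(self.rank_sequence)
        self.validate()

    def validate(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if not 0 < self.train_frac < 1:
            raise ValueError("train_frac must be in (0,1)")
        if not 0 <= self.taxon_density_min <= 1:
            raise ValueError("taxon_density_min must be in [0,1]")
        if not 0 <= self.mixedcomp_max <= 1:
            raise ValueError("mixedcomp_max must be in [0,1]")
        if not self.feature_type:
            raise ValueError("feature_type must be nonempty")
        unknown = set(self.feature_type) - {"kmers", "gc", "cov"}
        if unknown:
            raise ValueError(f"unknown feature_type entries: {sorted(unknown)}")
        if isinstance(self.vertexdist, str) and self.vertexdist != "all":
            raise ValueError("vertexdist must be an integer or 'all'")
        if isinstance(self.vertexdist, int) and self.vertexdist < 0:
            raise ValueError("vertexdist must be >= 0")
        for rank in self.rank_sequence:
            if rank not in CANONICAL_RANKS:
                raise ValueError(f"unknown rank {rank!r}")

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load a YAML config whose keys mirror the field names; keyword
        overrides (e.g. from CLI flags) take precedence over the file."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(data) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def replace(self, **changes) -> "RunConfig":
        return dataclasses.replace(self, **changes)


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------

@dataclass
class ContigSet:
    """The assembly: contig id -> uppercase DNA sequence.

    This is the universe of the whole workflow; every other table refers to
    contigs by the ids stored here.
    """

    entries: dict[str, str]

    def __post_init__(self) -> None:
        for cid, seq in self.entries.items():
            if not cid:
                raise ValueError("empty contig id")
            if not seq:
                raise ValueError(f"contig {cid!r} has an empty sequence")

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, contig_id: str) -> bool:
        return contig_id in self.entries

    def __getitem__(self, contig_id: str) -> str:
        return self.entries[contig_id]

    @property
    def ids(self) -> list[str]:
        return sorted(self.entries)

    def length(self, contig_id: str) -> int:
        return len(self.entries[contig_id])

    @property
    def lengths(self) -> dict[str, int]:
        return {cid: len(seq) for cid, seq in self.entries.items()}

    def subset(self, contig_ids: Iterable[str]) -> "ContigSet":
        return ContigSet({cid: self.entries[cid] for cid in contig_ids})

    def write_fasta(self, path: str | Path) -> None:
        records = (
            SeqRecord(Seq(self.entries[cid]), id=cid, description="")
            for cid in self.ids
        )
        SeqIO.write(records, str(path), "fasta")


@dataclass
class SixteenSRecord:
    """A 16S rRNA gene call on a contig, with its taxonomic assignment.

    ``start``/``end`` are 0-based half-open on the contig; ``assigned_taxon``
    maps rank -> label as resolved from the 16S homology search;
    ``contig_coverage`` is in fragments per nucleotide.
    """

    contig_id: str
    start: int
    end: int
    strand: str
    assigned_taxon: dict[str, str]
    contig_coverage: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"16S coords ({self.start},{self.end}) invalid on {self.contig_id}"
            )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_contigs(path: str | Path) -> ContigSet:
    """Read an assembly FASTA into a :class:`ContigSet`.

    Ids are the first whitespace-delimited token of each header; sequences
    are uppercased and any non-ACGTN character is mapped to N (counted and
    logged). Duplicate ids and empty files are hard errors.
    """
    entries: dict[str, str] = {}
    n_masked = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        cid = rec.id
        if cid in entries:
            raise ValueError(f"duplicate contig id {cid!r} in {path}")
        seq = str(rec.seq).upper()
        if not set(seq) <= _VALID_BASES:
            clean = "".join(b if b in _VALID_BASES else "N" for b in seq)
            n_masked += sum(a != b for a, b in zip(seq, clean))
            seq = clean
        entries[cid] = seq
    if not entries:
        raise ValueError(f"no FASTA records in {path}")
    if n_masked:
        logger.warning("masked %d non-ACGTN characters to N in %s", n_masked, path)
    return ContigSet(entries)


# ---------------------------------------------------------------------------
# Homology hits (BLAST outfmt-6 + staxid)
# ---------------------------------------------------------------------------

def _parse_blast6(path: str | Path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 13:
                raise ValueError(
                    f"{path}:{lineno}: expected >=13 tab-separated columns "
                    f"(outfmt 6 + staxid), got {len(parts)}"
                )
            try:
                rows.append(
                    (parts[0], float(parts[2]), int(float(parts[3])), int(parts[-1]))
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: unparsable row: {exc}") from exc
    return pd.DataFrame(rows, columns=["query_id", "pident", "hsp_len", "subject_taxid"])


def filter_hits(hits: pd.DataFrame, cfg: RunConfig) -> pd.DataFrame:
    """Apply the source-appropriate inclusive identity/HSP-length thresholds.

    Idempotent: filtering an already-filtered table changes nothing.
    """
    nt = (hits["source"] == "nucleotide") & (
        (hits["pident"] >= cfg.nt_min_pident) & (hits["hsp_len"] >= cfg.nt_min_hsp)
    )
    prot = (hits["source"] == "protein") & (
        (hits["pident"] >= cfg.prot_min_pident) & (hits["hsp_len"] >= cfg.prot_min_hsp)
    )
    kept = hits[nt | prot].reset_index(drop=True)
    logger.info("hit filter: kept %d / %d rows", len(kept), len(hits))
    return kept


def protein_query_to_contig(query_id: str) -> str:
    """Map a gene-caller protein id ``<contig>_<n>`` to its parent contig."""
    return query_id.rsplit("_", 1)[0]


def read_hits(
    path: str | Path,
    source: str,
    cfg: RunConfig,
    contigs: ContigSet | None = None,
    query_to_contig: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Read a BLAST tabular file into a filtered hit table.

    ``source`` selects the threshold pair ("nucleotide" or "protein"); for
    protein hits the query id is mapped to its parent contig with the
    ``<contig>_<n>`` gene-caller convention, or via an explicit
    ``query_to_contig`` mapping. When ``contigs`` is given, rows naming an
    unknown contig are rejected with a logged warning count.
    """
    if source not in HIT_SOURCES:
        raise ValueError(f"unknown hit source {source!r}; expected one of {HIT_SOURCES}")
    raw = _parse_blast6(path)
    if (raw["pident"] < 0).any() or (raw["pident"] > 100).any():
        raise ValueError(f"{path}: pident outside [0,100]")
    if (raw["hsp_len"] <= 0).any():
        raise ValueError(f"{path}: non-positive HSP length")
    if source == "protein":
        if query_to_contig is not None:
            raw["contig_id"] = raw["query_id"].map(query_to_contig)
            if raw["contig_id"].isna().any():
                missing = raw.loc[raw["contig_id"].isna(), "query_id"].unique()
                raise ValueError(f"protein queries without contig mapping: {missing[:5]}")
        else:
            raw["contig_id"] = raw["query_id"].map(protein_query_to_contig)
    else:
        raw["contig_id"] = raw["query_id"]
    raw["source"] = source
    hits = filter_hits(raw[list(HIT_COLUMNS)], cfg)
    if contigs is not None:
        known = hits["contig_id"].isin(contigs.entries)
        n_bad = int((~known).sum())
        if n_bad:
            logger.warning("%s: rejected %d hit rows naming unknown contigs", path, n_bad)
            hits = hits[known].reset_index(drop=True)
    return hits


# ---------------------------------------------------------------------------
# Mate links (SAM/BAM or mate-TSV)
# ---------------------------------------------------------------------------

def _validate_links(links: pd.DataFrame) -> pd.DataFrame:
    if links["fragment_id"].duplicated().any():
        dup = links.loc[links["fragment_id"].duplicated(), "fragment_id"].iloc[0]
        raise ValueError(f"duplicate fragment id {dup!r} in mate links")
    single = links["type"] == "single"
    if (single & links["contig_b"].notna()).any():
        raise ValueError("single-end fragment with a second contig placement")
    return links.reset_index(drop=True)


def _read_mate_tsv(path: str | Path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) == 1:
                parts = line.split()
            if len(parts) != 4:
                raise ValueError(
                    f"{path}:{lineno}: mate-TSV rows need 4 columns "
                    "(read_id, contig_a, contig_b_or_dot, type); mixed dialects?"
                )
            rid, ca, cb, typ = parts
            if typ not in ("paired", "single"):
                raise ValueError(f"{path}:{lineno}: unknown fragment type {typ!r}")
            rows.append(
                (rid, None if ca == "." else ca, None if cb == "." else cb, typ)
            )
    return pd.DataFrame(rows, columns=list(LINK_COLUMNS))


def _read_mate_sam(path: str | Path, min_mapq: int = 0) -> pd.DataFrame:
    import pysam

    mode = "rb" if str(path).endswith(".bam") else "r"
    placements: dict[str, dict[int, str | None]] = {}
    paired: dict[str, bool] = {}
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as sam:
        for aln in sam:
            if aln.is_secondary or aln.is_supplementary:
                continue
            contig = None
            if not aln.is_unmapped and aln.mapping_quality >= min_mapq:
                contig = aln.reference_name
            mate = 2 if (aln.is_paired and aln.is_read2) else 1
            placements.setdefault(aln.query_name, {})[mate] = contig
            paired[aln.query_name] = aln.is_paired
    rows = []
    for rid in sorted(placements):
        p = placements[rid]
        if paired[rid]:
            rows.append((rid, p.get(1), p.get(2), "paired"))
        else:
            rows.append((rid, p.get(1), None, "single"))
    return pd.DataFrame(rows, columns=list(LINK_COLUMNS))


def read_mate_links(path: str | Path, min_mapq: int = 0) -> pd.DataFrame:
    """Read read-pair placements into a mate-link table.

    One row per sequenced fragment: (fragment_id, contig_a, contig_b, type).
    SAM/BAM input (by extension) is reduced to primary alignments only;
    unmapped mates are recorded as None (unplaced). The TSV dialect writes
    unplaced mates as ".".
    """
    if str(path).endswith((".sam", ".bam")):
        links = _read_mate_sam(path, min_mapq=min_mapq)
    else:
        links = _read_mate_tsv(path)
    return _validate_links(links)


def write_mate_tsv(links: pd.DataFrame, path: str | Path) -> None:
    out = links.fillna(".")
    out.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# Lineage table
# ---------------------------------------------------------------------------

def read_lineage(path: str | Path) -> pd.DataFrame:
    """Read a ranked-lineage TSV (taxid + one column per canonical rank).

    Returns a DataFrame indexed by integer taxid; missing ranks are NaN.
    """
    tab = pd.read_csv(path, sep="\t", dtype={"taxid": int})
    if "taxid" not in tab.columns:
        raise ValueError(f"{path}: lineage table needs a 'taxid' column")
    bad = set(tab.columns) - {"taxid", *CANONICAL_RANKS}
    if bad:
        raise ValueError(f"{path}: unknown rank columns {sorted(bad)}")
    if tab["taxid"].duplicated().any():
        raise ValueError(f"{path}: duplicate taxids")
    return tab.set_index("taxid")


def write_lineage(lineage: pd.DataFrame, path: str | Path) -> None:
    lineage.reset_index().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# 16S records (GFF3 + 16S homology hits)
# ---------------------------------------------------------------------------

def read_16s_gff(path: str | Path) -> pd.DataFrame:
    """Extract 16S rRNA gene calls from a GFF3 file (e.g. an rRNA caller's
    output). Coordinates are converted to 0-based half-open.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    rows = []
    for feat in db.all_features():
        attrs = ";".join(f"{k}={','.join(v)}" for k, v in feat.attributes.items())
        text = f"{feat.featuretype} {attrs}"
        if "16S" not in text:
            continue
        rows.append((feat.seqid, feat.start - 1, feat.end, feat.strand or "+"))
    return pd.DataFrame(rows, columns=["contig_id", "start", "end", "strand"])


def build_16s_records(
    gff: pd.DataFrame,
    hits_16s: pd.DataFrame,
    lineage: pd.DataFrame,
    coverage: pd.DataFrame | None = None,
    contigs: ContigSet | None = None,
) -> list[SixteenSRecord]:
    """Join 16S gene calls with their rRNA-database taxonomy and coverage.

    The taxon of each 16S contig is taken from its highest-identity hit in
    ``hits_16s`` (ties broken by lowest taxid for determinism); contigs
    without a hit get an empty assignment. ``coverage`` (contig_id ->
    coverage) fills ``contig_coverage``.
    """
    cov = {}
    if coverage is not None:
        cov = dict(zip(coverage["contig_id"], coverage["coverage"]))
    records = []
    for row in gff.itertuples(index=False):
        if contigs is not None:
            if row.contig_id not in contigs:
                raise ValueError(f"16S call on unknown contig {row.contig_id!r}")
            if row.end > contigs.length(row.contig_id):
                raise ValueError(f"16S coords exceed contig {row.contig_id!r}")
        sub = hits_16s[hits_16s["contig_id"] == row.contig_id]
        taxon: dict[str, str] = {}
        if len(sub):
            best = sub.sort_values(
                ["pident", "subject_taxid"], ascending=[False, True]
            ).iloc[0]
            taxid = int(best["subject_taxid"])
            if taxid in lineage.index:
                lin = lineage.loc[taxid]
                taxon = {r: lin[r] for r in CANONICAL_RANKS
                         if r in lineage.columns and pd.notna(lin[r])}
        records.append(
            SixteenSRecord(
                contig_id=row.contig_id,
                start=int(row.start),
                end=int(row.end),
                strand=row.strand,
                assigned_taxon=taxon,
                contig_coverage=float(cov.get(row.contig_id, 0.0)),
            )
        )
    return records


# ---------------------------------------------------------------------------
# Generic table round-trip + output layout
# ---------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a headered TSV in canonical column order (round-trip safe)."""
    df.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def ensure_output_layout(outdir: str | Path) -> dict[str, Path]:
    """Create the standard output-folder layout and return folder paths."""
    out = Path(outdir)
    paths = {}
    for name in OUTPUT_FOLDERS:
        p = out / name
        p.mkdir(parents=True, exist_ok=True)
        paths[name] = p
    return paths
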