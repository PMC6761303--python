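"""Truth-annotated synthetic host/symbiont mixtures.

Generates everything the pipeline consumes — assembly contigs, mate
links, homology hits, a lineage table, 16S records, and a truth map — so
every stage and the end-to-end workflow are testable without downloads.

Each genome is a first- (or second-) order Markov chain over {A,C,G,T}
whose rows are constrained to a target GC content: the GC mass of every
row equals the target, while its split between C/G (and A/T) varies per
row, giving each genome a distinctive k-mer signature at identical or
different GC. The genome is fragmented into contigs with log-normal
lengths (>= 200 nt); read-pair placements are emitted per contig in
proportion to length and a per-genome coverage multiplier, with
junction-spanning pairs linking adjacent contigs of the same genome and
an optional cross-genome noise rate. A configurable fraction of contigs
receives concordant homology hits (pident/HSP length drawn above the
default filters), with an error rate sending a contig's hits to the
wrong genome's taxid and one below-threshold decoy hit per labeled
contig to exercise load-time filtering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .coverage import compute_coverage
from .io import (
    CANONICAL_RANKS,
    HIT_COLUMNS,
    LINK_COLUMNS,
    ContigSet,
    SixteenSRecord,
    write_lineage,
    write_mate_tsv,
    write_table,
)

_BASES = np.array(list("ACGT"))


@dataclass
class GenomeSpec:
    """One source genome of a mixture."""

    name: str
    taxid: int
    lineage: dict[str, str]
    genome_length: int
    gc: float = 0.5
    transition: np.ndarray | None = None  # (4,4) order-1 or (16,4) order-2
    coverage_multiplier: float = 1.0
    n_contigs: int = 50
    contig_len_sigma: float = 0.5
    has_16s: bool = False

    def __post_init__(self) -> None:
        if self.coverage_multiplier <= 0:
            raise ValueError("coverage_multiplier must be > 0")
        if not 0 < self.gc < 1:
            raise ValueError("gc must be in (0,1)")


@dataclass
class MixtureSpec:
    """Study conditions for one synthetic mixture."""

    genomes: list[GenomeSpec]
    cross_link_noise: float = 0.0   # noise pairs per junction-spanning pair
    label_rate: float = 0.3         # fraction of contigs with homology hits
    label_error_rate: float = 0.0   # labeled contigs whose hits point to a wrong taxon
    single_end_frac: float = 0.2    # merged-fragment fraction among same-contig fragments
    protein_hits: bool = False      # also emit protein-level hits
    base_coverage: float = 0.02     # fragments/nt at coverage_multiplier 1
    junction_rate: float = 25.0     # mean pairs across a present junction, per multiplier unit
    junction_prob: float = 0.5      # probability a junction is spanned at all
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("label_rate", "label_error_rate", "single_end_frac"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0,1]")
        if self.cross_link_noise < 0:
            raise ValueError("cross_link_noise must be >= 0")


@dataclass
class SyntheticMixture:
    """All generated inputs plus the truth annotation."""

    spec: MixtureSpec
    contigs: ContigSet
    links: pd.DataFrame
    hits: pd.DataFrame            # raw (unfiltered) hit rows, HIT_COLUMNS schema
    lineage: pd.DataFrame
    sixteen_s: list[SixteenSRecord]
    truth: pd.DataFrame           # contig_id, genome, length + one column per rank

    def truth_map(self, rank: str, target_label: str) -> dict[str, str]:
        """Truth as target/other classes at one rank."""
        if rank not in self.truth.columns:
            raise ValueError(f"truth table has no {rank!r} column")
        return {
            cid: ("target" if lab == target_label else "other")
            for cid, lab in zip(self.truth["contig_id"], self.truth[rank])
        }

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Emit every input file in the formats the io layer reads."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "contigs": out / "contigs.fasta",
            "links": out / "mate_links.tsv",
            "nt_hits": out / "nt_hits.blast6",
            "lineage": out / "lineage.tsv",
            "gff_16s": out / "rrna.gff3",
            "hits_16s": out / "hits_16s.blast6",
            "truth": out / "truth.tsv",
        }
        self.contigs.write_fasta(paths["contigs"])
        write_mate_tsv(self.links, paths["links"])
        _write_blast6(self.hits[self.hits["source"] == "nucleotide"], paths["nt_hits"])
        if self.spec.protein_hits:
            paths["prot_hits"] = out / "prot_hits.blast6"
            _write_blast6(
                self.hits[self.hits["source"] == "protein"],
                paths["prot_hits"],
                protein=True,
            )
        write_lineage(self.lineage, paths["lineage"])
        _write_16s_gff(self.sixteen_s, paths["gff_16s"])
        _write_16s_blast6(self.sixteen_s, self.lineage, paths["hits_16s"])
        write_table(self.truth, paths["truth"])
        return paths


# ---------------------------------------------------------------------------
# Sequence model
# ---------------------------------------------------------------------------

def transition_from_gc(gc: float, rng: np.random.Generator, order: int = 1) -> np.ndarray:
    """Markov transition rows with exact GC mass ``gc`` and random C/G,
    A/T splits per row (splits uniform in [0.25, 0.75])."""
    n_states = 4 ** order
    at = 1.0 - gc
    u = rng.uniform(0.25, 0.75, size=n_states)
    v = rng.uniform(0.25, 0.75, size=n_states)
    return np.column_stack([at * u, gc * v, gc * (1 - v), at * (1 - u)])


def sample_chain(transition: np.ndarray, length: int, rng: np.random.Generator) -> str:
    """Sample a DNA string from an order-1 (4x4) or order-2 (16x4) chain."""
    n_states = transition.shape[0]
    if n_states not in (4, 16) or transition.shape[1] != 4:
        raise ValueError("transition must be (4,4) or (16,4)")
    order = 1 if n_states == 4 else 2
    cum = np.cumsum(transition, axis=1)
    cum[:, -1] = 1.0
    unif = rng.random(length)
    seq = np.empty(length, dtype=np.int64)
    state = int(rng.integers(n_states))
    for i in range(length):
        base = int(np.searchsorted(cum[state], unif[i], side="right"))
        base = min(base, 3)
        seq[i] = base
        state = base if order == 1 else (state % 4) * 4 + base
    return "".join(_BASES[seq])


def _contig_lengths(genome: GenomeSpec, rng: np.random.Generator) -> np.ndarray:
    raw = rng.lognormal(mean=0.0, sigma=genome.contig_len_sigma, size=genome.n_contigs)
    lens = np.maximum(200, (raw / raw.sum() * genome.genome_length)).astype(int)
    return lens


# ---------------------------------------------------------------------------
# Generator
# ---------------------------------------------------------------------------

def generate_mixture(spec: MixtureSpec) -> SyntheticMixture:
    """Generate a full mixture; byte-identical given the same spec/seed."""
    rng = np.random.default_rng(spec.seed)

    entries: dict[str, str] = {}
    contig_genome: dict[str, GenomeSpec] = {}
    per_genome_contigs: dict[str, list[str]] = {}
    for genome in spec.genomes:
        trans = genome.transition
        if trans is None:
            trans = transition_from_gc(genome.gc, rng)
        lens = _contig_lengths(genome, rng)
        if len(lens) < 2:
            raise ValueError(f"genome {genome.name}: need >= 2 contigs")
        sequence = sample_chain(trans, int(lens.sum()), rng)
        pos = 0
        ids = []
        for i, ln in enumerate(lens):
            cid = f"{genome.name}_c{i:04d}"
            entries[cid] = sequence[pos:pos + ln]
            contig_genome[cid] = genome
            ids.append(cid)
            pos += ln
        per_genome_contigs[genome.name] = ids
    contigs = ContigSet(entries)

    links = _generate_links(spec, contigs, per_genome_contigs, rng)
    hits, labeled_16s = _generate_hits(spec, contigs, contig_genome, per_genome_contigs, rng)
    lineage = _lineage_table(spec)
    coverage = compute_coverage(links, contigs)
    sixteen_s = _sixteen_s_records(spec, contigs, per_genome_contigs, coverage)

    truth_rows = []
    ranks = sorted(
        {r for g in spec.genomes for r in g.lineage}, key=CANONICAL_RANKS.index
    )
    for cid in contigs.ids:
        genome = contig_genome[cid]
        truth_rows.append(
            {"contig_id": cid, "genome": genome.name, "length": contigs.length(cid),
             **{r: genome.lineage.get(r) for r in ranks}}
        )
    truth = pd.DataFrame(truth_rows)

    return SyntheticMixture(
        spec=spec, contigs=contigs, links=links, hits=hits,
        lineage=lineage, sixteen_s=sixteen_s, truth=truth,
    )


def _generate_links(spec, contigs, per_genome_contigs, rng) -> pd.DataFrame:
    rows = []
    frag = 0

    def next_id():
        nonlocal frag
        frag += 1
        return f"f{frag:07d}"

    n_junction_total = 0
    for genome in spec.genomes:
        ids = per_genome_contigs[genome.name]
        for cid in ids:
            n = rng.poisson(spec.base_coverage * genome.coverage_multiplier
                            * contigs.length(cid))
            n_single = rng.binomial(n, spec.single_end_frac)
            for _ in range(n - n_single):
                rows.append((next_id(), cid, cid, "paired"))
            for _ in range(n_single):
                rows.append((next_id(), cid, None, "single"))
        for a, b in zip(ids, ids[1:]):
            if rng.random() >= spec.junction_prob:
                continue
            n_link = rng.poisson(spec.junction_rate * genome.coverage_multiplier)
            n_junction_total += n_link
            for _ in range(n_link):
                rows.append((next_id(), a, b, "paired"))

    if spec.cross_link_noise > 0 and len(spec.genomes) > 1:
        n_noise = rng.poisson(spec.cross_link_noise * max(n_junction_total, 1))
        names = [g.name for g in spec.genomes]
        for _ in range(n_noise):
            ga, gb = rng.choice(len(names), size=2, replace=False)
            a = per_genome_contigs[names[ga]][rng.integers(len(per_genome_contigs[names[ga]]))]
            b = per_genome_contigs[names[gb]][rng.integers(len(per_genome_contigs[names[gb]]))]
            rows.append((next_id(), a, b, "paired"))

    return pd.DataFrame(rows, columns=list(LINK_COLUMNS))


def _generate_hits(spec, contigs, contig_genome, per_genome_contigs, rng):
    taxids = {g.name: g.taxid for g in spec.genomes}
    sixteen_contigs = {
        _sixteen_s_contig(g, contigs, per_genome_contigs)
        for g in spec.genomes if g.has_16s
    }
    rows = []
    for cid in contigs.ids:
        genome = contig_genome[cid]
        # the 16S contig always has database support: its rRNA is universal
        if rng.random() >= spec.label_rate and cid not in sixteen_contigs:
            continue
        taxid = taxids[genome.name]
        if spec.label_error_rate > 0 and rng.random() < spec.label_error_rate:
            others = [t for n, t in taxids.items() if n != genome.name]
            if others:
                taxid = others[int(rng.integers(len(others)))]
        n_hits = int(rng.integers(3, 9))
        for _ in range(n_hits):
            rows.append((cid, cid, taxid, round(float(rng.uniform(72, 99.9)), 2),
                         int(rng.integers(220, 900)), "nucleotide"))
        # one below-threshold decoy, dropped by load-time filtering
        rows.append((cid, cid, taxid, round(float(rng.uniform(30, 65)), 2),
                     int(rng.integers(220, 900)), "nucleotide"))
        if spec.protein_hits:
            for j in range(int(rng.integers(1, 4))):
                rows.append((f"{cid}_{j + 1}", cid, taxid,
                             round(float(rng.uniform(82, 99.9)), 2),
                             int(rng.integers(80, 300)), "protein"))
    return pd.DataFrame(rows, columns=list(HIT_COLUMNS)), sixteen_contigs


def _sixteen_s_contig(genome, contigs, per_genome_contigs) -> str:
    ids = per_genome_contigs[genome.name]
    return max(ids, key=lambda c: (contigs.length(c), c))


def _sixteen_s_records(spec, contigs, per_genome_contigs, coverage) -> list[SixteenSRecord]:
    cov = dict(zip(coverage["contig_id"], coverage["coverage"]))
    records = []
    for genome in spec.genomes:
        if not genome.has_16s:
            continue
        cid = _sixteen_s_contig(genome, contigs, per_genome_contigs)
        length = contigs.length(cid)
        start = min(100, max(0, length - 1550))
        end = min(start + 1550, length)
        records.append(
            SixteenSRecord(
                contig_id=cid, start=start, end=end, strand="+",
                assigned_taxon=dict(genome.lineage),
                contig_coverage=float(cov.get(cid, 0.0)),
            )
        )
    return records


def _lineage_table(spec) -> pd.DataFrame:
    rows = []
    for genome in spec.genomes:
        rows.append({"taxid": genome.taxid,
                     **{r: genome.lineage.get(r) for r in CANONICAL_RANKS}})
    return pd.DataFrame(rows).set_index("taxid")


# ---------------------------------------------------------------------------
# File writers (formats the io layer reads back)
# ---------------------------------------------------------------------------

def _write_blast6(hits: pd.DataFrame, path: Path, protein: bool = False) -> None:
    with open(path, "w") as fh:
        for row in hits.itertuples(index=False):
            qseqid = row.query_id
            fh.write(
                "\t".join(
                    map(str, (
                        qseqid, f"subj|{row.subject_taxid}", row.pident, row.hsp_len,
                        0, 0, 1, row.hsp_len, 1, row.hsp_len, "1e-50", 200,
                        row.subject_taxid,
                    ))
                ) + "\n"
            )


def _write_16s_gff(records: list[SixteenSRecord], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, rec in enumerate(records):
            fh.write(
                "\t".join(map(str, (
                    rec.contig_id, "rrna_caller", "rRNA", rec.start + 1, rec.end,
                    ".", rec.strand, ".",
                    f"ID=rrna{i};Name=16S_rRNA;product=16S ribosomal RNA",
                ))) + "\n"
            )


def _write_16s_blast6(records, lineage: pd.DataFrame, path: Path) -> None:
    """16S genes vs an rRNA database: one strong hit to the source taxon."""
    taxon_to_taxid = {}
    for taxid, row in lineage.iterrows():
        key = tuple(sorted((r, v) for r, v in row.items() if pd.notna(v)))
        taxon_to_taxid[key] = taxid
    with open(path, "w") as fh:
        for rec in records:
            key = tuple(sorted(rec.assigned_taxon.items()))
            taxid = taxon_to_taxid.get(key)
            if taxid is None:
                continue
            ln = rec.end - rec.start
            fh.write(
                "\t".join(map(str, (
                    rec.contig_id, f"rrna|{taxid}", 99.5, ln, 0, 0, 1, ln, 1, ln,
                    "0.0", 2500, taxid,
                ))) + "\n"
            )


# ---------------------------------------------------------------------------
# Default study conditions
# ---------------------------------------------------------------------------

def default_two_genome_spec(seed: int = 0) -> MixtureSpec:
    """A eukaryote-like host plus one bacterial endosymbiont.

    Host:symbiont coverage 9:1; divergent GC (0.39 vs 0.55) and Markov
    structure; 30% homology label rate with no labeling error and no
    cross-genome link noise.
    """
    host = GenomeSpec(
        name="host", taxid=9001,
        lineage={"superkingdom": "Eukaryota", "phylum": "Ascomycota",
                 "class": "Saccharomycetes"},
        genome_length=280_000, gc=0.39, coverage_multiplier=9.0,
        n_contigs=140, contig_len_sigma=0.5,
    )
    symbiont = GenomeSpec(
        name="symbiont", taxid=1101,
        lineage={"superkingdom": "Bacteria", "phylum": "Proteobacteria",
                 "class": "Alphaproteobacteria"},
        genome_length=200_000, gc=0.55, coverage_multiplier=1.0,
        n_contigs=110, contig_len_sigma=0.6, has_16s=True,
    )
    return MixtureSpec(genomes=[host, symbiont], seed=seed)


def three_genome_spec(seed: int = 0) -> MixtureSpec:
    """Host plus two bacterial genomes of different classes (nested-rank
    and clustering scenarios)."""
    spec = default_two_genome_spec(seed)
    contaminant = GenomeSpec(
        name="contaminant", taxid=1202,
        lineage={"superkingdom": "Bacteria", "phylum": "Bacteroidetes",
                 "class": "Cytophagia"},
        genome_length=120_000, gc=0.33, coverage_multiplier=0.8,
        n_contigs=60, contig_len_sigma=0.5, has_16s=True,
    )
    spec.genomes.append(contaminant)
    return spec
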