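"""Annotated-genome reading/writing and downstream-gene-region extraction.

Genomes are read from GenBank flat files or FASTA + GFF3 (Biopython and
gffutils respectively); coordinates are normalized at the boundary to
0-based half-open intervals on the plus strand.  The downstream gene
region (DGR) of a gene is the 450-nt window in gene orientation spanning
relative positions -100..-1 (the last 100 nt of the gene, ending with the
stop codon) and +1..+350 (the 350 nt immediately 3'); see
:mod:`baculopolya.coords`.  For circular genomes the window wraps the
origin; for linear genomes it is truncated with an explicit flag, never
silently.
"""

from __future__ import annotations

import fnmatch
import logging
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from .coords import DGR_DOWNSTREAM, DGR_UPSTREAM

log = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

STOP_CODONS = ("TAA", "TAG", "TGA")


def revcomp(seq: str) -> str:
    return seq.upper().replace("U", "T").translate(_COMPLEMENT)[::-1]


@dataclass
class GeneAnnotation:
    gene_id: str
    name: str
    start: int  # 0-based, plus-strand frame
    end: int    # half-open
    strand: str  # '+' | '-'
    is_core: bool = False

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: bad strand {self.strand!r}")
        if self.start >= self.end:
            raise ValueError(f"{self.gene_id}: start {self.start} >= end {self.end}")
        if self.end - self.start < 6:
            raise ValueError(f"{self.gene_id}: gene shorter than 6 nt")


@dataclass
class GenomeRecord:
    id: str
    sequence: str
    circular: bool
    genes: list[GeneAnnotation] = field(default_factory=list)

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"{self.id}: empty sequence")
        for g in self.genes:
            if g.end > len(self.sequence):
                raise ValueError(f"{self.id}/{g.gene_id}: interval beyond sequence end")


@dataclass
class DGR:
    genome_id: str
    gene_id: str
    sequence: str        # gene orientation, 5'->3'
    strand: str
    source_interval: tuple[int, int]  # genomic span (may exceed length for wraps)
    up_len: int          # realized upstream extent (100 unless truncated)
    trunc_upstream: bool = False
    trunc_downstream: bool = False

    @property
    def truncated(self) -> bool:
        return self.trunc_upstream or self.trunc_downstream

    @property
    def id(self) -> str:
        return f"{self.genome_id}|{self.gene_id}"

    def rel_to_genomic(self, rel: int, genome_length: int) -> int:
        """Genomic coordinate of a relative DGR position (wrap-aware)."""
        from .coords import rel_to_idx

        i = rel_to_idx(rel, upstream=self.up_len)
        lo, hi = self.source_interval
        if self.strand == "+":
            return (lo + i) % genome_length
        return (hi - 1 - i) % genome_length


def _slice(seq: str, lo: int, hi: int, circular: bool) -> str:
    """seq[lo:hi] with modular wrap when circular; lo may be negative."""
    n = len(seq)
    if 0 <= lo and hi <= n:
        return seq[lo:hi]
    if not circular:
        raise IndexError("window exceeds linear sequence")
    return "".join(seq[i % n] for i in range(lo, hi))


def extract_dgr(genome: GenomeRecord, gene: GeneAnnotation,
                upstream: int = DGR_UPSTREAM, downstream: int = DGR_DOWNSTREAM) -> DGR:
    """The DGR of ``gene``, reported 5'->3' in gene orientation.

    Relative positions -upstream..-1 cover the gene's 3' tail (stop codon
    at -3..-1), +1..+downstream the bases immediately 3' of it.  Minus
    strand genes are reverse-complemented; circular genomes wrap; linear
    overruns and genes shorter than ``upstream`` are truncated with flags.
    """
    if gene not in genome.genes:
        raise ValueError(f"gene {gene.gene_id} does not belong to genome {genome.id}")
    n = len(genome.sequence)
    up = min(upstream, gene.end - gene.start)
    trunc_up = up < upstream
    down = downstream
    trunc_down = False
    if gene.strand == "+":
        lo, hi = gene.end - up, gene.end + down
        if not genome.circular:
            if hi > n:
                hi, trunc_down = n, True
        seq = _slice(genome.sequence, lo, hi, genome.circular)
    else:
        lo, hi = gene.start - down, gene.start + up
        if not genome.circular:
            if lo < 0:
                lo, trunc_down = 0, True
        seq = revcomp(_slice(genome.sequence, lo, hi, genome.circular))
    if trunc_up:
        log.warning("%s/%s: gene shorter than %d nt, upstream window truncated",
                    genome.id, gene.gene_id, upstream)
    if trunc_down:
        log.warning("%s/%s: linear genome end, downstream window truncated",
                    genome.id, gene.gene_id)
    return DGR(genome.id, gene.gene_id, seq, gene.strand, (lo, hi), up,
               trunc_up, trunc_down)


def select_core(genes: list[GeneAnnotation], core_names: list[str]) -> list[GeneAnnotation]:
    """Flag (and return) genes whose name matches any core-name pattern.

    Patterns are case-insensitive globs.  An empty table flags nothing
    (logged), matching the convention that core membership is pure
    configuration.
    """
    patterns = [p.strip().lower() for p in core_names if p.strip() and not p.startswith("#")]
    if not patterns:
        log.warning("empty core-gene name table: no genes flagged as core")
    hits = []
    for g in genes:
        g.is_core = any(fnmatch.fnmatch(g.name.lower(), p) for p in patterns)
        if g.is_core:
            hits.append(g)
    return hits


def load_core_names(path: str | Path | None = None) -> list[str]:
    if path is None:
        from importlib import resources

        text = (resources.files("baculopolya.data") / "core_genes.txt").read_text()
    else:
        text = Path(path).read_text()
    return [ln.strip() for ln in text.splitlines()
            if ln.strip() and not ln.startswith("#")]


# ---------------------------------------------------------------------------
# file formats


def read_genome(path: str | Path, fmt: str = "genbank",
                gff: str | Path | None = None) -> GenomeRecord:
    """Read one annotated genome (GenBank, or FASTA plus GFF3).

    Joined/spliced locations are rejected: baculovirus genes are unspliced,
    and a join here almost always indicates an origin-spanning artifact.
    """
    path = Path(path)
    if fmt == "genbank":
        return _read_genbank(path)
    if fmt == "fasta+gff3":
        if gff is None:
            raise ValueError("fasta+gff3 format requires the gff= path")
        return _read_fasta_gff(path, Path(gff))
    raise ValueError(f"unknown genome format {fmt!r}")


def _read_genbank(path: Path) -> GenomeRecord:
    try:
        rec = SeqIO.read(str(path), "genbank")
    except Exception as exc:
        raise ValueError(f"{path}: cannot parse GenBank record: {exc}") from exc
    topology = rec.annotations.get("topology")
    if topology is None:
        log.warning("%s: no topology in LOCUS line, assuming linear", path)
    genes = []
    feats = [f for f in rec.features if f.type == "gene"]
    if not feats:
        feats = [f for f in rec.features if f.type == "CDS"]
    for i, f in enumerate(feats):
        if len(f.location.parts) != 1:
            raise ValueError(f"{path} [{rec.id}]: joined location in feature {i}; "
                             "spliced genes are not supported")
        q = f.qualifiers
        name = (q.get("gene") or q.get("label") or q.get("locus_tag") or [f"gene{i:03d}"])[0]
        gid = (q.get("locus_tag") or q.get("gene") or [f"gene{i:03d}"])[0]
        genes.append(GeneAnnotation(gid, name, int(f.location.start),
                                    int(f.location.end),
                                    "+" if f.location.strand >= 0 else "-"))
    return GenomeRecord(rec.id, str(rec.seq).upper(), topology == "circular", genes)


def _read_fasta_gff(fasta: Path, gff: Path) -> GenomeRecord:
    import gffutils

    rec = SeqIO.read(str(fasta), "fasta")
    db = gffutils.create_db(str(gff), dbfn=":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique")
    circular = False
    genes = []
    for f in db.all_features():
        if f.featuretype == "region":
            circular = f.attributes.get("Is_circular", ["false"])[0].lower() == "true"
            continue
        if f.featuretype not in ("gene", "CDS"):
            continue
        gid = (f.attributes.get("ID") or [f.id])[0]
        name = (f.attributes.get("Name") or [gid])[0]
        # GFF3 is 1-based closed; gffutils keeps that convention
        genes.append(GeneAnnotation(gid, name, f.start - 1, f.end, f.strand))
    return GenomeRecord(rec.id, str(rec.seq).upper(), circular, genes)


def write_genbank(genome: GenomeRecord, path: str | Path) -> None:
    rec = SeqRecord(Seq(genome.sequence), id=genome.id, name=genome.id[:16],
                    description="synthetic genome")
    rec.annotations["molecule_type"] = "DNA"
    rec.annotations["topology"] = "circular" if genome.circular else "linear"
    rec.annotations["date"] = "01-JAN-2000"  # fixed for byte-identical output
    for g in genome.genes:
        loc = FeatureLocation(g.start, g.end, strand=1 if g.strand == "+" else -1)
        rec.features.append(SeqFeature(loc, type="gene", qualifiers={
            "gene": [g.name], "locus_tag": [g.gene_id]}))
    SeqIO.write([rec], str(path), "genbank")


def write_fasta_gff(genome: GenomeRecord, fasta_path: str | Path,
                    gff_path: str | Path) -> None:
    with open(fasta_path, "w") as fh:
        fh.write(f">{genome.id}\n")
        for i in range(0, len(genome.sequence), 70):
            fh.write(genome.sequence[i : i + 70] + "\n")
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {genome.id} 1 {len(genome.sequence)}\n")
        circ = "true" if genome.circular else "false"
        fh.write(f"{genome.id}\tbaculopolya\tregion\t1\t{len(genome.sequence)}"
                 f"\t.\t+\t.\tID=region0;Is_circular={circ}\n")
        for g in genome.genes:
            fh.write(f"{genome.id}\tbaculopolya\tgene\t{g.start + 1}\t{g.end}\t.\t"
                     f"{g.strand}\t.\tID={g.gene_id};Name={g.name}\n")


def write_dgr_fasta(dgrs: list[DGR], path: str | Path) -> None:
    """DGR multi-FASTA with ``genomeID|geneID|strand|trunc`` headers."""
    with open(path, "w") as fh:
        for d in dgrs:
            trunc = "T" if d.truncated else "F"
            fh.write(f">{d.genome_id}|{d.gene_id}|{d.strand}|{trunc}\n{d.sequence}\n")


def read_dgr_fasta(path: str | Path) -> list[DGR]:
    dgrs = []
    for rec in SeqIO.parse(str(path), "fasta"):
        genome_id, gene_id, strand, trunc = rec.id.split("|")
        seq = str(rec.seq).upper()
        up = min(DGR_UPSTREAM, len(seq))
        dgrs.append(DGR(genome_id, gene_id, seq, strand, (0, len(seq)), up,
                        trunc_upstream=trunc == "T"))
    return dgrs
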