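"""Sequence and gene-model I/O.

Core data types (:class:`ProteinRecord`, :class:`GeneModel`,
:class:`PresenceMatrix`) and readers/writers for the plain-text formats the
pipeline touches: multi-record FASTA for proteins, GFF3 or BED12 for
coding-exon gene models, and TSV for tissue presence/absence matrices.

All genomic coordinates are normalised to 0-based half-open intervals on
ingest (GFF3's 1-based closed convention is converted), so downstream
arithmetic uses a single convention.
"""

from __future__ import annotations

import io as _stdio
import logging
from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger("mipkit")

#: 20 canonical amino acids plus X for an unknown residue.  Other ambiguity
#: codes (B, Z, J, U, O) are rejected rather than silently remapped.
AMINO_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")

#: cDNA accessions deposited for the functionally characterised zebrafish
#: channels.  Note draqp9a and draqp9b are listed under the same accession in
#: the deposition record; see :func:`duplicated_accessions`.
DEPOSITED_CDNA_ACCESSIONS = {
    "draqp0a": "FJ666326",
    "draqp0b": "FJ655389",
    "draqp3a": "EU341833",
    "draqp3b": "EU341832",
    "draqp4": "FJ666327",
    "draqp7": "FJ655385",
    "draqp8aa": "FJ655386",
    "draqp8ab": "EU341834",
    "draqp8b": "FJ695516",
    "draqp9a": "FJ655387",
    "draqp9b": "FJ655387",
    "draqp10a": "FJ655388",
    "draqp10b": "EU341836",
}


def duplicated_accessions() -> dict[str, list[str]]:
    """Accessions listed for more than one gene (likely deposition typos).

    Returns a mapping accession -> gene names.  The pipeline flags these pairs
    instead of assuming either mapping is the correct one.
    """
    by_acc: dict[str, list[str]] = {}
    for gene, acc in DEPOSITED_CDNA_ACCESSIONS.items():
        by_acc.setdefault(acc, []).append(gene)
    return {acc: genes for acc, genes in by_acc.items() if len(genes) > 1}


class ParseError(ValueError):
    """Raised when an input file violates its declared format."""


class ValidationError(ValueError):
    """Raised when a parsed object violates a model invariant."""


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with a stable identifier.

    ``residues`` is an uppercase string over the 20-letter IUPAC alphabet
    plus X; a terminal ``*`` (stop) is stripped on ingest.
    """

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("protein record id must be non-empty")
        if not self.residues:
            raise ValidationError(f"{self.id}: empty sequence")
        bad = set(self.residues) - AMINO_ALPHABET
        if bad:
            raise ValidationError(
                f"{self.id}: illegal residue character(s) {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class GeneModel:
    """Coding-exon structure of one gene.

    ``exons`` are 0-based half-open genomic intervals covering coding
    sequence only, sorted by start and pairwise non-overlapping.
    """

    gene_id: str
    chromosome: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValidationError(
                f"{self.gene_id}: unknown strand symbol {self.strand!r}"
            )
        if not self.exons:
            raise ValidationError(f"{self.gene_id}: gene model needs >=1 exon")
        prev_end = None
        for start, end in self.exons:
            if end <= start:
                raise ValidationError(
                    f"{self.gene_id}: empty exon interval [{start}, {end})"
                )
            if prev_end is not None and start < prev_end:
                raise ValidationError(
                    f"{self.gene_id}: overlapping or unsorted exons at {start}"
                )
            prev_end = end

    @property
    def span(self) -> int:
        """First exon start to last exon end, in bp."""
        return self.exons[-1][1] - self.exons[0][0]


@dataclass(frozen=True)
class ExonIntronSummary:
    gene_id: str
    exon_count: int
    exon_lengths: tuple[int, ...]
    intron_lengths: tuple[int, ...]
    span: int


PRESENCE_STATES = ("present", "absent", "not-tested")


@dataclass
class PresenceMatrix:
    """Gene x tissue presence/absence matrix (data echo only, no computation)."""

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        bad = set(self.table.values.ravel()) - set(PRESENCE_STATES)
        if bad:
            raise ValidationError(f"illegal presence states {sorted(bad)}")

    @classmethod
    def read_tsv(cls, path) -> "PresenceMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col=0, dtype=str))

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> list[ProteinRecord]:
    """Read a multi-record protein FASTA.

    Residues are uppercased and a single terminal stop (``*``) is stripped.
    Illegal residue characters raise :class:`ParseError` naming the offending
    line; duplicate ids raise :class:`ValidationError`.
    """
    with open(path) as fh:
        lines = fh.readlines()
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(_stdio.StringIO("".join(lines)), "fasta"):
        if not rec.id:
            raise ParseError(f"{path}: malformed FASTA header")
        seq = str(rec.seq).upper()
        if seq.endswith("*"):
            seq = seq[:-1]
        bad = set(seq) - AMINO_ALPHABET
        if bad:
            raise ParseError(
                f"{path}:{_offending_line(lines, rec.id, bad)}: "
                f"illegal residue character(s) {sorted(bad)} in {rec.id}"
            )
        if rec.id in seen:
            raise ValidationError(f"{path}: duplicate record id {rec.id}")
        seen.add(rec.id)
        records.append(ProteinRecord(rec.id, seq, rec.description))
    return records


def _offending_line(lines: list[str], rec_id: str, bad: set[str]) -> int:
    """1-based line number of the first line containing a bad character."""
    in_record = False
    for i, line in enumerate(lines, start=1):
        if line.startswith(">"):
            in_record = line[1:].split()[0] == rec_id if line[1:].strip() else False
            continue
        if in_record and (set(line.strip().upper()) & bad):
            return i
    return 0


def write_fasta(records: list[ProteinRecord], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.id}"
            if rec.description and rec.description != rec.id:
                desc = rec.description
                if desc.startswith(rec.id):
                    desc = desc[len(rec.id):].strip()
                if desc:
                    header += f" {desc}"
            fh.write(header + "\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i:i + width] + "\n")


def translate_cds(nucleotides: str) -> str:
    """Translate a coding sequence (frame 0, standard code, stop stripped)."""
    prot = str(Seq(nucleotides).translate())
    if prot.endswith("*"):
        prot = prot[:-1]
    if "*" in prot:
        raise ValidationError("internal stop codon in CDS")
    return prot


# ---------------------------------------------------------------------------
# Gene models (GFF3 / BED12)
# ---------------------------------------------------------------------------

def read_gene_models(path, dialect: str) -> list[GeneModel]:
    """Read coding-exon gene models from GFF3 or BED12.

    Both dialects map onto the same internal 0-based half-open
    representation, so the two encodings of one gene are interchangeable.
    UTR features in GFF3 are ignored (with a logged notice); only CDS
    features contribute exon intervals.
    """
    if dialect == "gff3":
        return _read_gff3(path)
    if dialect == "bed12":
        return _read_bed12(path)
    raise ValueError(f"unknown gene-model dialect {dialect!r}")


def _read_gff3(path) -> list[GeneModel]:
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    n_utr = sum(1 for t in ("five_prime_UTR", "three_prime_UTR")
                for _ in db.features_of_type(t))
    if n_utr:
        logger.info("ignoring %d UTR feature(s); coding exons only", n_utr)
    genes: dict[str, dict] = {}
    for cds in db.features_of_type("CDS", order_by="start"):
        top = cds
        for anc in db.parents(cds):
            top = anc
        gid = top.id
        entry = genes.setdefault(
            gid, {"chrom": cds.seqid, "strand": cds.strand, "exons": []}
        )
        # GFF3 is 1-based closed; convert to 0-based half-open.
        entry["exons"].append((cds.start - 1, cds.end))
    models = []
    for gid, entry in genes.items():
        exons = tuple(sorted(entry["exons"]))
        models.append(GeneModel(gid, entry["chrom"], entry["strand"], exons))
    return models


_BED12_COLS = [
    "chrom", "chromStart", "chromEnd", "name", "score", "strand",
    "thickStart", "thickEnd", "itemRgb", "blockCount", "blockSizes",
    "blockStarts",
]


def _read_bed12(path) -> list[GeneModel]:
    table = pd.read_csv(path, sep="\t", header=None, names=_BED12_COLS,
                        comment="#")
    models = []
    for row in table.itertuples(index=False):
        sizes = [int(x) for x in str(row.blockSizes).rstrip(",").split(",")]
        starts = [int(x) for x in str(row.blockStarts).rstrip(",").split(",")]
        if len(sizes) != int(row.blockCount) or len(starts) != int(row.blockCount):
            raise ParseError(f"{path}: block fields inconsistent for {row.name}")
        exons = tuple(
            (int(row.chromStart) + s, int(row.chromStart) + s + sz)
            for s, sz in zip(starts, sizes)
        )
        models.append(GeneModel(str(row.name), str(row.chrom),
                                str(row.strand), exons))
    return models


def write_gff3(models: list[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            start1, end1 = m.exons[0][0] + 1, m.exons[-1][1]
            fh.write(
                f"{m.chromosome}\tmipkit\tgene\t{start1}\t{end1}\t.\t"
                f"{m.strand}\t.\tID={m.gene_id}\n"
            )
            mrna = f"{m.gene_id}.t1"
            fh.write(
                f"{m.chromosome}\tmipkit\tmRNA\t{start1}\t{end1}\t.\t"
                f"{m.strand}\t.\tID={mrna};Parent={m.gene_id}\n"
            )
            for i, (s, e) in enumerate(m.exons, start=1):
                fh.write(
                    f"{m.chromosome}\tmipkit\tCDS\t{s + 1}\t{e}\t.\t"
                    f"{m.strand}\t0\tID={mrna}.cds{i};Parent={mrna}\n"
                )


def write_bed12(models: list[GeneModel], path) -> None:
    with open(path, "w") as fh:
        for m in models:
            chrom_start = m.exons[0][0]
            chrom_end = m.exons[-1][1]
            sizes = ",".join(str(e - s) for s, e in m.exons)
            starts = ",".join(str(s - chrom_start) for s, _ in m.exons)
            fh.write(
                f"{m.chromosome}\t{chrom_start}\t{chrom_end}\t{m.gene_id}\t0\t"
                f"{m.strand}\t{chrom_start}\t{chrom_end}\t0\t{len(m.exons)}\t"
                f"{sizes}\t{starts}\n"
            )


def exon_intron_summary(model: GeneModel) -> ExonIntronSummary:
    """Exon count, exon/intron lengths and total span of one gene model.

    A single-exon model has an empty intron list.  Intron *i* runs from the
    end of exon *i* to the start of exon *i+1*.
    """
    exon_lengths = tuple(e - s for s, e in model.exons)
    intron_lengths = tuple(
        model.exons[i + 1][0] - model.exons[i][1]
        for i in range(len(model.exons) - 1)
    )
    return ExonIntronSummary(
        gene_id=model.gene_id,
        exon_count=len(model.exons),
        exon_lengths=exon_lengths,
        intron_lengths=intron_lengths,
        span=model.span,
    )
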