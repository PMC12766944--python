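"""Readers and writers for the formats the tool touches.

Genomes are FASTA (plain or gzip), annotations are 12-column BED (BED12)
with a converter from GTF/GFF3, and splice scores travel in a 5-column
TAB-delimited file::

    contig <TAB> offset <TAB> strand <TAB> site_type <TAB> score

where ``offset`` is the 0-based exon/intron boundary coordinate on the
forward genome, ``site_type`` is ``D`` (donor) or ``A`` (acceptor) and
``score`` is the calibrated log-odds splice score printed with two
decimals.  All coordinates are 0-based half-open internally; an intron is
the interval ``[donor_boundary, acceptor_boundary)`` on the forward strand
for plus-strand sites and the mirrored pair for minus-strand sites.
"""

from __future__ import annotations

import gzip
import logging
import re
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator

from Bio import SeqIO

logger = logging.getLogger(__name__)

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# uppercase; IUPAC ambiguity codes and anything else alphabetic become N
_NORM = {}
for _c in "ACGT":
    _NORM[ord(_c)] = _c
    _NORM[ord(_c.lower())] = _c
for _c in "RYSWKMBDHVNX":
    _NORM[ord(_c)] = "N"
    _NORM[ord(_c.lower())] = "N"
_NORMALIZE_TABLE = str.maketrans(_NORM)


class FormatError(ValueError):
    """Malformed input file; the message names the offending line."""


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def _open_text(path, mode: str = "rt") -> IO[str]:
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# Genome / FASTA


@dataclass
class Genome:
    """Named contigs of uppercase DNA over ``{A,C,G,T,N}``."""

    contigs: dict[str, str] = field(default_factory=dict)

    def __getitem__(self, name: str) -> str:
        return self.contigs[name]

    def __contains__(self, name: str) -> bool:
        return name in self.contigs

    def __len__(self) -> int:
        return len(self.contigs)

    def names(self) -> list[str]:
        return list(self.contigs)

    def items(self):
        return self.contigs.items()

    def total_length(self) -> int:
        return sum(len(s) for s in self.contigs.values())

    def validate(self) -> None:
        if not self.contigs:
            raise FormatError("genome has no contigs")
        for name, seq in self.contigs.items():
            if not name:
                raise FormatError("empty contig name")
            if not seq:
                raise FormatError(f"contig {name!r} has empty sequence")
            bad = set(seq) - set("ACGTN")
            if bad:
                raise FormatError(
                    f"contig {name!r} has characters outside ACGTN: {sorted(bad)}"
                )


def normalize_sequence(seq: str) -> str:
    out = seq.translate(_NORMALIZE_TABLE)
    bad = set(out) - set("ACGTN")
    if bad:
        raise FormatError(f"non-nucleotide characters in sequence: {sorted(bad)}")
    return out


def read_fasta(path) -> Genome:
    """Read a plain or gzip FASTA file into a :class:`Genome`.

    Sequences are uppercased, ambiguity codes map to ``N`` and multi-line
    records are concatenated.  Duplicate contig names, empty files and
    files that do not start with a header are format errors.
    """
    contigs: dict[str, str] = {}
    with _open_text(path) as fh:
        try:
            for rec in SeqIO.parse(fh, "fasta"):
                name = rec.id
                if not name:
                    raise FormatError(f"{path}: record with empty header")
                if name in contigs:
                    raise FormatError(f"{path}: duplicate contig name {name!r}")
                contigs[name] = normalize_sequence(str(rec.seq))
        except ValueError as exc:  # Biopython: text before the first '>'
            raise FormatError(f"{path}: malformed FASTA: {exc}") from exc
    if not contigs:
        raise FormatError(f"{path}: empty or headerless FASTA file")
    genome = Genome(contigs)
    genome.validate()
    return genome


def write_fasta(genome: Genome, path, width: int = 60) -> None:
    with _open_text(path, "wt") as fh:
        for name, seq in genome.contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Gene annotation / BED12

_GENEID_RE = re.compile(r"^(.+)\.[^.]+$")


@dataclass
class GeneRecord:
    """A BED12-style transcript: exon blocks in genomic coordinates."""

    contig: str
    start: int
    end: int
    strand: str
    name: str
    gene_id: str = ""
    blocks: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.gene_id:
            m = _GENEID_RE.match(self.name)
            self.gene_id = m.group(1) if m else self.name

    def validate(self) -> None:
        if self.start >= self.end:
            raise FormatError(f"{self.name}: start >= end")
        if self.strand not in "+-":
            raise FormatError(f"{self.name}: bad strand {self.strand!r}")
        if not self.blocks:
            raise FormatError(f"{self.name}: no exon blocks")
        prev_end = None
        for bs, be in self.blocks:
            if bs >= be:
                raise FormatError(f"{self.name}: empty exon block ({bs},{be})")
            if bs < self.start or be > self.end:
                raise FormatError(f"{self.name}: block outside transcript span")
            if prev_end is not None and bs < prev_end:
                raise FormatError(f"{self.name}: blocks unsorted or overlapping")
            prev_end = be

    def introns(self) -> list[tuple[int, int]]:
        """Half-open genomic intervals between consecutive exon blocks."""
        return [
            (self.blocks[i][1], self.blocks[i + 1][0])
            for i in range(len(self.blocks) - 1)
        ]

    def exon_length(self) -> int:
        return sum(be - bs for bs, be in self.blocks)


def read_bed12(path) -> list[GeneRecord]:
    records = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) != 12:
                raise FormatError(f"{path}:{lineno}: expected 12 columns, got {len(cols)}")
            try:
                contig, start, end, name = cols[0], int(cols[1]), int(cols[2]), cols[3]
                strand = cols[5]
                n_blocks = int(cols[9])
                sizes = [int(x) for x in cols[10].rstrip(",").split(",")]
                starts = [int(x) for x in cols[11].rstrip(",").split(",")]
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            if end <= start:
                raise FormatError(f"{path}:{lineno}: end <= start")
            if len(sizes) != n_blocks or len(starts) != n_blocks:
                raise FormatError(
                    f"{path}:{lineno}: blockCount {n_blocks} does not match "
                    f"blockSizes/blockStarts lengths"
                )
            blocks = [(start + st, start + st + sz) for st, sz in zip(starts, sizes)]
            rec = GeneRecord(contig, start, end, strand, name, blocks=blocks)
            rec.validate()
            records.append(rec)
    records.sort(key=lambda r: (r.contig, r.start, r.end, r.name))
    return records


def write_bed12(records: Iterable[GeneRecord], path) -> None:
    with _open_text(path, "wt") as fh:
        for r in records:
            sizes = ",".join(str(be - bs) for bs, be in r.blocks)
            starts = ",".join(str(bs - r.start) for bs, _ in r.blocks)
            fh.write(
                "\t".join(
                    [
                        r.contig,
                        str(r.start),
                        str(r.end),
                        r.name,
                        "0",
                        r.strand,
                        str(r.start),
                        str(r.end),
                        "0",
                        str(len(r.blocks)),
                        sizes,
                        starts,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# GTF / GFF3 -> BED12


def _parse_gtf_attributes(text: str) -> dict[str, str]:
    attrs = {}
    for part in text.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        if " " in part:
            key, _, value = part.partition(" ")
            attrs[key] = value.strip().strip('"')
    return attrs


def _parse_gff3_attributes(text: str) -> dict[str, str]:
    attrs = {}
    for part in text.strip().split(";"):
        if "=" in part:
            key, _, value = part.partition("=")
            attrs[key.strip()] = value.strip()
    return attrs


def convert_gff_to_bed12(path, dialect: str) -> list[GeneRecord]:
    """Convert a GTF or GFF3 annotation to BED12-style gene records.

    One record per transcript; exons are merged into sorted blocks.
    Transcripts whose exons span multiple contigs or strands are skipped
    with a logged warning.  GFF3 transcript->gene links are followed via
    ``Parent``; in GTF the ``gene_id`` attribute is used.
    """
    dialect = dialect.upper()
    if dialect not in ("GTF", "GFF3"):
        raise ValueError(f"unknown dialect {dialect!r}")
    parse_attrs = _parse_gtf_attributes if dialect == "GTF" else _parse_gff3_attributes

    exons: dict[str, list[tuple[str, int, int, str]]] = {}
    tx_gene: dict[str, str] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 columns, got {len(cols)}")
            contig, _, ftype, start1, end1, _, strand, _, attr_text = cols
            attrs = parse_attrs(attr_text)
            if dialect == "GFF3" and "ID" in attrs and "Parent" in attrs and ftype != "exon":
                # remember transcript -> gene link for any feature with both
                tx_gene.setdefault(attrs["ID"], attrs["Parent"])
            if ftype != "exon":
                continue
            if dialect == "GTF":
                tx = attrs.get("transcript_id")
                if tx and "gene_id" in attrs:
                    tx_gene.setdefault(tx, attrs["gene_id"])
            else:
                tx = attrs.get("Parent")
            if not tx:
                raise FormatError(f"{path}:{lineno}: exon without transcript identifier")
            # 1-based inclusive -> 0-based half-open
            exons.setdefault(tx, []).append((contig, int(start1) - 1, int(end1), strand))

    records = []
    n_skipped = 0
    for tx, ex in exons.items():
        contigs = {e[0] for e in ex}
        strands = {e[3] for e in ex}
        if len(contigs) > 1 or len(strands) > 1:
            n_skipped += 1
            continue
        blocks = sorted((s, e) for _, s, e, _ in ex)
        rec = GeneRecord(
            contig=ex[0][0],
            start=blocks[0][0],
            end=blocks[-1][1],
            strand=ex[0][3],
            name=tx,
            gene_id=tx_gene.get(tx, ""),
            blocks=blocks,
        )
        rec.validate()
        records.append(rec)
    if n_skipped:
        logger.warning(
            "skipped %d transcript(s) with exons on multiple contigs/strands", n_skipped
        )
    records.sort(key=lambda r: (r.contig, r.start, r.end, r.name))
    return records


# ---------------------------------------------------------------------------
# Splice-score file

SITE_TYPE_CODES = {"donor": "D", "acceptor": "A"}
CODE_SITE_TYPES = {v: k for k, v in SITE_TYPE_CODES.items()}


@dataclass(frozen=True)
class SpliceScoreRecord:
    """One scored splice boundary.

    ``offset`` is the exon/intron boundary in forward-genome coordinates:
    for a plus-strand site the donor offset is the first intron base and
    the acceptor offset is one past the last intron base; minus-strand
    sites mirror this, so an intron is always
    ``[min(donor, acceptor), max(donor, acceptor))``.
    """

    contig: str
    offset: int
    strand: str
    site_type: str  # "donor" | "acceptor"
    score: float


def implied_dinucleotide(seq: str, offset: int, strand: str, site_type: str) -> str:
    """The splice dinucleotide at a boundary, read 5'->3' on its strand."""
    if strand == "+":
        d = seq[offset : offset + 2] if site_type == "donor" else seq[offset - 2 : offset]
        return d
    d = seq[offset - 2 : offset] if site_type == "donor" else seq[offset : offset + 2]
    return reverse_complement(d)


def write_score_file(records: Iterable[SpliceScoreRecord], path) -> None:
    with _open_text(path, "wt") as fh:
        for r in records:
            code = SITE_TYPE_CODES.get(r.site_type)
            if code is None:
                raise FormatError(f"unknown site type {r.site_type!r}")
            fh.write(f"{r.contig}\t{r.offset}\t{r.strand}\t{code}\t{r.score:.2f}\n")


def read_score_file(path) -> list[SpliceScoreRecord]:
    records = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) != 5:
                raise FormatError(f"{path}:{lineno}: expected 5 columns, got {len(cols)}")
            contig, offset_s, strand, code, score_s = cols
            if code not in CODE_SITE_TYPES:
                raise FormatError(f"{path}:{lineno}: unknown site type code {code!r}")
            if strand not in "+-":
                raise FormatError(f"{path}:{lineno}: bad strand {strand!r}")
            try:
                offset = int(offset_s)
                score = float(score_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            records.append(
                SpliceScoreRecord(contig, offset, strand, CODE_SITE_TYPES[code], score)
            )
    return records


def iter_score_records(path) -> Iterator[SpliceScoreRecord]:
    yield from read_score_file(path)
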