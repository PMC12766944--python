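"""Labeled donor/acceptor example sets from a genome and its annotation.

Positive examples are annotated GT donors and AG acceptors (non-canonical
junctions are skipped).  Negative examples are unannotated GT/AG lying on
the strand *opposite* an annotated gene, which protects against
incompletely annotated same-strand sites; regions covered by genes on both
strands are excluded entirely.  Negatives are downsampled to a 1:3
positive-to-negative ratio per site type.  Each example carries a window
of ``flank`` bp on both sides of the central dinucleotide (202 bp total at
the default flank of 100), oriented 5'->3' on the site's strand.

Contigs alternate between a train/validation pool (1st, 3rd, ... in FASTA
order) and a held-out test pool (2nd, 4th, ...); the train pool is split
80/20 at the gene level and the test set is every GT/AG candidate on the
held-out contigs, labeled by the annotation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .formats import GeneRecord, Genome, implied_dinucleotide

logger = logging.getLogger(__name__)

BASE_ORDER = "ACGT"  # row order of one-hot matrices; N -> all-zero column

ENCODE_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGTN"):
    ENCODE_LUT[ord(_b)] = _i
COMPLEMENT_CODES = np.array([3, 2, 1, 0, 4], dtype=np.uint8)

_A, _C, _G, _T = 0, 1, 2, 3


@dataclass(slots=True)
class SiteExample:
    """One labeled splice-site candidate.

    ``pos`` is the forward-genome coordinate of the first base of the
    central dinucleotide; ``window`` reads 5'->3' on ``strand`` with the
    dinucleotide (GT for donors, AG for acceptors) at its center.
    """

    contig: str
    pos: int
    strand: str
    site_type: str  # "donor" | "acceptor"
    label: int  # 1 positive, 0 negative
    window: str

    @property
    def offset(self) -> int:
        """Exon/intron boundary coordinate (score-file convention)."""
        return boundary_offset(self.pos, self.strand, self.site_type)


def boundary_offset(pos: int, strand: str, site_type: str) -> int:
    if (strand == "+") == (site_type == "donor"):
        return pos
    return pos + 2


def pos_from_boundary(offset: int, strand: str, site_type: str) -> int:
    if (strand == "+") == (site_type == "donor"):
        return offset
    return offset - 2


@dataclass
class DatasetSplit:
    train: list[SiteExample]
    validation: list[SiteExample]
    test: list[SiteExample] = field(default_factory=list)


# ---------------------------------------------------------------------------
# encoding


def encode_seq(seq: str) -> np.ndarray:
    """Encode A,C,G,T,N to 0..4 (uint8)."""
    codes = ENCODE_LUT[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if codes.max(initial=0) == 255:
        raise ValueError("sequence contains characters outside ACGTN")
    return codes


def one_hot(window: str) -> np.ndarray:
    """One-hot encode a window to a 4 x L float32 matrix (rows A,C,G,T).

    ``N`` maps to an all-zero column, so column sums are 0 or 1.
    """
    codes = encode_seq(window)
    return (codes[None, :] == np.arange(4, dtype=np.uint8)[:, None]).astype(np.float32)


def windows_to_codes(windows: Sequence[str]) -> np.ndarray:
    """Stack equal-length windows into a (B, L) uint8 code matrix."""
    if not windows:
        return np.empty((0, 0), dtype=np.uint8)
    length = len(windows[0])
    flat = np.frombuffer("".join(windows).encode(), dtype=np.uint8)
    codes = ENCODE_LUT[flat].reshape(len(windows), length)
    if codes.max(initial=0) == 255:
        raise ValueError("window contains characters outside ACGTN")
    return codes


def codes_to_onehot(codes: np.ndarray) -> np.ndarray:
    """(B, L) uint8 codes -> (B, 4, L) float32 one-hot (N -> zero column)."""
    return (codes[:, None, :] == np.arange(4, dtype=np.uint8)[None, :, None]).astype(
        np.float32
    )


# ---------------------------------------------------------------------------
# window extraction


def extract_window(
    genome: Genome, contig: str, pos: int, strand: str, flank: int = 100
) -> str | None:
    """The ``2*flank + 2`` window around the dinucleotide at ``pos``.

    Minus-strand windows are reverse complemented so the site reads 5'->3'.
    Returns ``None`` when the window overruns the contig (the site is
    skipped upstream, never padded).
    """
    seq = genome[contig]
    lo, hi = pos - flank, pos + 2 + flank
    if lo < 0 or hi > len(seq):
        return None
    window = seq[lo:hi]
    if strand == "-":
        from .formats import reverse_complement

        window = reverse_complement(window)
    return window


# ---------------------------------------------------------------------------
# positive / negative site enumeration


def annotated_site_keys(
    genome: Genome, genes: Iterable[GeneRecord]
) -> set[tuple[str, int, str, str]]:
    """Canonical annotated boundaries as (contig, offset, strand, type) keys.

    Isoforms sharing a junction collapse onto one key.  Non-GT donors and
    non-AG acceptors are not included.
    """
    keys = set()
    for gene in genes:
        seq = genome[gene.contig]
        for x, y in gene.introns():
            if y - x < 4:
                continue
            d_off, a_off = (x, y) if gene.strand == "+" else (y, x)
            if implied_dinucleotide(seq, d_off, gene.strand, "donor") == "GT":
                keys.add((gene.contig, d_off, gene.strand, "donor"))
            if implied_dinucleotide(seq, a_off, gene.strand, "acceptor") == "AG":
                keys.add((gene.contig, a_off, gene.strand, "acceptor"))
    return keys


def extract_positive_sites(
    genome: Genome, genes: Iterable[GeneRecord], flank: int = 100
) -> list[SiteExample]:
    """One positive example per annotated canonical splice boundary.

    Donors without GT and acceptors without AG are skipped, as are introns
    shorter than 4 bp and sites whose window overruns the contig.
    """
    examples = []
    n_noncanonical = n_short = n_oob = 0
    seen: set[tuple[str, int, str, str]] = set()
    for gene in genes:
        seq = genome[gene.contig]
        for x, y in gene.introns():
            if y - x < 4:
                n_short += 1
                continue
            d_off, a_off = (x, y) if gene.strand == "+" else (y, x)
            for off, site_type, want in (
                (d_off, "donor", "GT"),
                (a_off, "acceptor", "AG"),
            ):
                key = (gene.contig, off, gene.strand, site_type)
                if key in seen:
                    continue
                if implied_dinucleotide(seq, off, gene.strand, site_type) != want:
                    n_noncanonical += 1
                    continue
                seen.add(key)
                pos = pos_from_boundary(off, gene.strand, site_type)
                window = extract_window(genome, gene.contig, pos, gene.strand, flank)
                if window is None:
                    n_oob += 1
                    continue
                examples.append(
                    SiteExample(gene.contig, pos, gene.strand, site_type, 1, window)
                )
    if n_short or n_noncanonical or n_oob:
        logger.warning(
            "positive sites: skipped %d short introns, %d non-canonical "
            "boundaries, %d windows at contig edges",
            n_short, n_noncanonical, n_oob,
        )
    return examples


def _dinuc_positions(codes: np.ndarray, first: int, second: int) -> np.ndarray:
    return np.where((codes[:-1] == first) & (codes[1:] == second))[0]


# (forward dinucleotide, strand of the site, site type, boundary = pos + delta)
_CANDIDATE_KINDS = (
    ((_G, _T), "+", "donor"),
    ((_A, _C), "-", "donor"),
    ((_A, _G), "+", "acceptor"),
    ((_C, _T), "-", "acceptor"),
)


def candidate_sites(codes: np.ndarray) -> list[tuple[int, str, str]]:
    """Every GT/AG splice-site candidate on both strands of one contig.

    Returns (pos, strand, site_type) tuples where ``pos`` is the forward
    coordinate of the first base of the dinucleotide, sorted by position.
    """
    out = []
    for (b1, b2), strand, site_type in _CANDIDATE_KINDS:
        for p in _dinuc_positions(codes, b1, b2):
            out.append((int(p), strand, site_type))
    out.sort(key=lambda t: (t[0], t[1], t[2]))
    return out


def enumerate_negative_sites(
    genome: Genome,
    genes: Sequence[GeneRecord],
    flank: int = 100,
    restrict_to_genes: Sequence[GeneRecord] | None = None,
) -> list[SiteExample]:
    """Unannotated GT/AG on the strand opposite an annotated gene.

    ``restrict_to_genes`` limits the spans searched (used for gene-level
    train/validation splits) while the full ``genes`` list still defines
    annotated-site exclusion and both-strand-overlap exclusion.
    """
    span_genes = genes if restrict_to_genes is None else restrict_to_genes
    annotated = annotated_site_keys(genome, genes)

    # strand coverage over all genes, for the both-strand exclusion rule
    cover: dict[str, dict[str, np.ndarray]] = {}
    for gene in genes:
        length = len(genome[gene.contig])
        per = cover.setdefault(
            gene.contig,
            {"+": np.zeros(length, dtype=bool), "-": np.zeros(length, dtype=bool)},
        )
        per[gene.strand][gene.start : gene.end] = True

    codes_cache: dict[str, np.ndarray] = {}
    examples = []
    seen: set[tuple[str, int, str, str]] = set()
    for gene in span_genes:
        contig = gene.contig
        if contig not in codes_cache:
            codes_cache[contig] = encode_seq(genome[contig])
        codes = codes_cache[contig]
        both = cover[contig]["+"] & cover[contig]["-"]
        opp = "-" if gene.strand == "+" else "+"
        for (b1, b2), strand, site_type in _CANDIDATE_KINDS:
            if strand != opp:
                continue
            seg = codes[gene.start : gene.end]
            for p_rel in _dinuc_positions(seg, b1, b2):
                pos = int(p_rel) + gene.start
                if both[pos] or both[pos + 1]:
                    continue
                off = boundary_offset(pos, strand, site_type)
                key = (contig, off, strand, site_type)
                if key in annotated or key in seen:
                    continue
                window = extract_window(genome, contig, pos, strand, flank)
                if window is None:
                    continue
                seen.add(key)
                examples.append(SiteExample(contig, pos, strand, site_type, 0, window))
    return examples


def downsample_negatives(
    positives: Sequence[SiteExample],
    negatives: Sequence[SiteExample],
    ratio: int = 3,
    seed: int = 0,
) -> list[SiteExample]:
    """Sample ``ratio`` negatives per positive, per site type, without
    replacement (all negatives are kept when supply is short)."""
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    rng = np.random.default_rng(seed)
    kept = []
    for site_type in ("donor", "acceptor"):
        n_pos = sum(1 for e in positives if e.site_type == site_type)
        pool = [e for e in negatives if e.site_type == site_type]
        want = min(ratio * n_pos, len(pool))
        idx = rng.choice(len(pool), size=want, replace=False) if pool else []
        kept.extend(pool[i] for i in sorted(idx))
    return kept


# ---------------------------------------------------------------------------
# train / validation / test split


def split_contigs(genome: Genome) -> tuple[list[str], list[str]]:
    """Partition contigs by 1-based index parity in FASTA order.

    The 1st, 3rd, ... contigs form the train/validation pool ("odd"); the
    2nd, 4th, ... are held out for testing ("even").
    """
    names = genome.names()
    return names[0::2], names[1::2]


def test_candidates(
    genome: Genome,
    genes: Sequence[GeneRecord],
    contigs: Sequence[str],
    flank: int = 100,
) -> list[SiteExample]:
    """Every window-fitting GT/AG candidate on the given contigs, labeled
    positive iff its boundary is annotated."""
    annotated = annotated_site_keys(genome, genes)
    examples = []
    for contig in contigs:
        codes = encode_seq(genome[contig])
        length = len(codes)
        for pos, strand, site_type in candidate_sites(codes):
            if pos - flank < 0 or pos + 2 + flank > length:
                continue
            off = boundary_offset(pos, strand, site_type)
            label = int((contig, off, strand, site_type) in annotated)
            window = extract_window(genome, contig, pos, strand, flank)
            examples.append(SiteExample(contig, pos, strand, site_type, label, window))
    return examples


def make_split(
    genome: Genome,
    genes: Sequence[GeneRecord],
    fraction_train: float = 0.8,
    seed: int = 0,
    flank: int = 100,
    neg_ratio: int = 3,
    with_test: bool = True,
) -> DatasetSplit:
    """Gene-level 80/20 train/validation split on odd contigs plus the
    even-contig candidate test set."""
    if len(genome) < 2:
        raise ValueError("need at least 2 contigs to split by parity")
    odd_contigs, even_contigs = split_contigs(genome)
    odd_set = set(odd_contigs)
    odd_genes = [g for g in genes if g.contig in odd_set]
    if not odd_genes:
        raise ValueError("no genes on odd contigs; cannot build training data")

    # gene-level split: all transcripts of a gene stay together
    gene_ids = sorted({g.gene_id for g in odd_genes})
    rng = np.random.default_rng(seed)
    rng.shuffle(gene_ids)
    n_train = int(len(gene_ids) * fraction_train + 0.5)
    n_train = min(max(n_train, 1), len(gene_ids) - 1) if len(gene_ids) > 1 else 1
    train_ids = set(gene_ids[:n_train])
    train_genes = [g for g in odd_genes if g.gene_id in train_ids]
    val_genes = [g for g in odd_genes if g.gene_id not in train_ids]

    parts = []
    for part_seed, subset in ((seed * 2 + 1, train_genes), (seed * 2 + 2, val_genes)):
        pos = extract_positive_sites(genome, subset, flank)
        neg = enumerate_negative_sites(genome, genes, flank, restrict_to_genes=subset)
        neg = downsample_negatives(pos, neg, neg_ratio, part_seed % (2**31))
        parts.append(pos + neg)

    test = test_candidates(genome, genes, even_contigs, flank) if with_test else []
    return DatasetSplit(train=parts[0], validation=parts[1], test=test)


def examples_to_arrays(examples: Sequence[SiteExample]) -> tuple[np.ndarray, np.ndarray]:
    """(B, L) uint8 window codes and (B,) int64 labels."""
    codes = windows_to_codes([e.window for e in examples])
    labels = np.array([e.label for e in examples], dtype=np.int64)
    return codes, labels
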