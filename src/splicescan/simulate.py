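"""Deterministic synthetic genomes with planted splice consensus motifs.

The simulator emits a multi-contig genome plus a BED12-style annotation in
which every intron starts GT and ends AG, with flanking consensus bases
(exonic G before the donor, GTRAGT at the intron 5' end, a polypyrimidine
tract and YAG at the 3' end) planted at a configurable per-position
strength.  It stands in for a real genome + annotation in every test, so
the CNN has a learnable signal without any external accession.

Per planted position the consensus set ``S`` receives total probability
``strength`` (split uniformly inside ``S``); the remaining mass is spread
over the other bases.  ``strength = |S|/4`` therefore reduces a position
to the no-signal uniform limit, e.g. 0.25 for a single-base consensus.
The central GT/AG of every annotated intron is always forced.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .formats import GeneRecord, Genome, reverse_complement

BASES = "ACGT"
_BASE_IDX = {b: i for i, b in enumerate(BASES)}
_COMP_IDX = np.array([3, 2, 1, 0], dtype=np.int8)  # A<->T, C<->G

# (offset, consensus set) pairs; offset 0 is the first intron base for the
# donor and the first exon base after the intron for the acceptor.
DONOR_MOTIF: list[tuple[int, str]] = [
    (-3, "AC"),  # M
    (-2, "A"),
    (-1, "G"),
    (0, "G"),
    (1, "T"),
    (2, "AG"),  # R
    (3, "A"),
    (4, "G"),
    (5, "T"),
]
ACCEPTOR_MOTIF: list[tuple[int, str]] = [
    *[(off, "CT") for off in range(-13, -3)],  # polypyrimidine tract (10)
    (-3, "CT"),  # Y
    (-2, "A"),
    (-1, "G"),
    (0, "G"),  # exonic
]

GENE_END_FLANK = 210  # keep all 202bp training windows extractable
MIN_GENE_GAP = 50
GC_RICH_INTRON_GC = 0.64


class CapacityError(RuntimeError):
    """Requested genes do not fit on the configured contigs."""


@dataclass
class SimConfig:
    n_contigs: int = 8
    contig_len: int = 300_000
    n_genes: int = 1000
    exon_len_range: tuple[int, int] = (80, 200)
    intron_len_range: tuple[int, int] = (60, 400)
    n_exons_range: tuple[int, int] = (5, 5)
    donor_consensus_strength: float = 0.9
    acceptor_consensus_strength: float = 0.9
    background_gc: float = 0.4
    intron_gc_mode: str = "match_background"  # or "gc_rich"
    seed: int = 1

    def validate(self) -> None:
        if not (0.0 <= self.donor_consensus_strength <= 1.0):
            raise ValueError("donor_consensus_strength outside [0,1]")
        if not (0.0 <= self.acceptor_consensus_strength <= 1.0):
            raise ValueError("acceptor_consensus_strength outside [0,1]")
        if not (0.0 < self.background_gc < 1.0):
            raise ValueError("background_gc outside (0,1)")
        if self.intron_len_range[0] < 4:
            raise ValueError("intron_len_range min must be >= 4 (room for GT..AG)")
        if self.exon_len_range[0] < 4:
            raise ValueError("exon_len_range min must be >= 4")
        if self.intron_gc_mode not in ("match_background", "gc_rich"):
            raise ValueError(f"unknown intron_gc_mode {self.intron_gc_mode!r}")
        if self.n_contigs < 1 or self.contig_len < 2 * GENE_END_FLANK + 100:
            raise ValueError("contigs too small for any gene")


def _background_probs(gc: float) -> np.ndarray:
    return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])


def _consensus_probs(consensus: str, strength: float) -> np.ndarray:
    p = np.full(4, (1.0 - strength) / (4 - len(consensus)))
    for b in consensus:
        p[_BASE_IDX[b]] = strength / len(consensus)
    return p


def _plant(
    contig: np.ndarray,
    motif: list[tuple[int, str]],
    boundary: int,
    strand: str,
    strength: float,
    rng: np.random.Generator,
    force: frozenset[int],
) -> None:
    """Write one motif instance around a splice boundary.

    ``boundary`` is the forward-genome boundary coordinate; local motif
    offsets are translated to forward coordinates (and bases complemented)
    for minus-strand sites.  Offsets in ``force`` always emit consensus
    (the GT/AG core).
    """
    for off, consensus in motif:
        if strand == "+":
            pos = boundary + off
            if off in force:
                base = _BASE_IDX[consensus]
            else:
                base = rng.choice(4, p=_consensus_probs(consensus, strength))
        else:
            pos = boundary - 1 - off
            if off in force:
                base = _COMP_IDX[_BASE_IDX[consensus]]
            else:
                base = _COMP_IDX[rng.choice(4, p=_consensus_probs(consensus, strength))]
        contig[pos] = base


_DONOR_FORCE = frozenset({0, 1})
_ACCEPTOR_FORCE = frozenset({-2, -1})


def _gene_structure(cfg: SimConfig, rng: np.random.Generator) -> tuple[list[int], list[int]]:
    n_exons = int(rng.integers(cfg.n_exons_range[0], cfg.n_exons_range[1] + 1))
    exon_lens = rng.integers(
        cfg.exon_len_range[0], cfg.exon_len_range[1] + 1, size=n_exons
    ).tolist()
    intron_lens = rng.integers(
        cfg.intron_len_range[0], cfg.intron_len_range[1] + 1, size=n_exons - 1
    ).tolist()
    return exon_lens, intron_lens


def simulate_genome(config: SimConfig) -> tuple[Genome, list[GeneRecord]]:
    """Simulate a genome and its annotation per the configuration.

    Genes are laid down left to right, cycling over contigs, with random
    gaps and at least :data:`GENE_END_FLANK` bp to contig ends so every
    training window fits.  Raises :class:`CapacityError` when the
    requested genes do not fit.  Fully reproducible for a fixed seed.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    bg = _background_probs(config.background_gc)
    contigs = [
        rng.choice(4, size=config.contig_len, p=bg).astype(np.int8)
        for _ in range(config.n_contigs)
    ]
    cursors = [GENE_END_FLANK] * config.n_contigs
    limit = config.contig_len - GENE_END_FLANK

    genes: list[GeneRecord] = []
    ci = 0
    for gi in range(config.n_genes):
        exon_lens, intron_lens = _gene_structure(config, rng)
        gene_len = sum(exon_lens) + sum(intron_lens)
        gap = int(rng.integers(MIN_GENE_GAP, 300))
        placed = False
        for attempt in range(config.n_contigs):
            c = (ci + attempt) % config.n_contigs
            start = cursors[c] + gap
            if start + gene_len <= limit:
                cursors[c] = start + gene_len
                ci = (c + 1) % config.n_contigs
                placed = True
                break
        if not placed:
            raise CapacityError(
                f"gene {gi} (len {gene_len}) does not fit on any contig; "
                f"increase contig_len or reduce n_genes"
            )

        strand = "+" if rng.random() < 0.5 else "-"
        contig = contigs[c]
        blocks = []
        pos = start
        for k, el in enumerate(exon_lens):
            blocks.append((pos, pos + el))
            pos += el
            if k < len(intron_lens):
                x, y = pos, pos + intron_lens[k]
                if config.intron_gc_mode == "gc_rich":
                    contig[x:y] = rng.choice(
                        4, size=y - x, p=_background_probs(GC_RICH_INTRON_GC)
                    )
                if strand == "+":
                    _plant(contig, DONOR_MOTIF, x, "+",
                           config.donor_consensus_strength, rng, _DONOR_FORCE)
                    _plant(contig, ACCEPTOR_MOTIF, y, "+",
                           config.acceptor_consensus_strength, rng, _ACCEPTOR_FORCE)
                else:
                    # transcription runs y-1 -> x: donor boundary y, acceptor x
                    _plant(contig, DONOR_MOTIF, y, "-",
                           config.donor_consensus_strength, rng, _DONOR_FORCE)
                    _plant(contig, ACCEPTOR_MOTIF, x, "-",
                           config.acceptor_consensus_strength, rng, _ACCEPTOR_FORCE)
                pos = y
        genes.append(
            GeneRecord(
                contig=f"contig{c + 1}",
                start=start,
                end=pos,
                strand=strand,
                name=f"g{gi + 1}.t1",
                gene_id=f"g{gi + 1}",
                blocks=blocks,
            )
        )

    base_arr = np.frombuffer(BASES.encode(), dtype=np.uint8)
    genome = Genome(
        {
            f"contig{c + 1}": base_arr[contigs[c]].tobytes().decode()
            for c in range(config.n_contigs)
        }
    )
    genes.sort(key=lambda r: (r.contig, r.start))
    return genome, genes


@dataclass
class SimulatedRead:
    """A spliced transcript read with its true genomic junctions."""

    name: str
    query: str
    contig: str
    strand: str
    junctions: frozenset = field(default_factory=frozenset)


def simulate_reads(
    genome: Genome,
    genes: list[GeneRecord],
    error_rate: float = 0.0,
    seed: int = 0,
) -> list[SimulatedRead]:
    """One spliced read per gene: exons concatenated (strand-aware), with
    substitution errors injected at ``error_rate``.

    The truth set records forward-genome ``[donor, acceptor)`` intron
    intervals regardless of strand.
    """
    if not (0.0 <= error_rate <= 0.2):
        raise ValueError("error_rate outside [0, 0.2]")
    rng = np.random.default_rng(seed)
    reads = []
    for gene in genes:
        seq = "".join(genome[gene.contig][bs:be] for bs, be in gene.blocks)
        if gene.strand == "-":
            seq = reverse_complement(seq)
        if error_rate > 0:
            arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
            hit = np.where(rng.random(len(arr)) < error_rate)[0]
            for i in hit:
                choices = [b for b in b"ACGT" if b != arr[i]]
                arr[i] = choices[rng.integers(3)]
            seq = arr.tobytes().decode()
        reads.append(
            SimulatedRead(
                name=gene.name,
                query=seq,
                contig=gene.contig,
                strand=gene.strand,
                junctions=frozenset(gene.introns()),
            )
        )
    return reads
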