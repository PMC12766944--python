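"""Whole-genome splice-site scoring.

Scans every GT and AG on both strands of each contig, scores the
surrounding window with the CNN, transforms the raw score through the
calibration table and emits :class:`~splicescan.formats.SpliceScoreRecord`
rows sorted by (contig, offset).  Contigs are processed one at a time
with bounded batches, so peak memory does not grow with genome length.
"""

from __future__ import annotations

import logging
from typing import Iterator

import numpy as np

from .calibrate import CalibrationTable, transform_score
from .dataset import (
    COMPLEMENT_CODES,
    boundary_offset,
    candidate_sites,
    codes_to_onehot,
    encode_seq,
)
from .formats import Genome, SpliceScoreRecord
from .model import SpliceCNN

logger = logging.getLogger(__name__)


def _window_codes(
    codes: np.ndarray, pos: np.ndarray, minus: np.ndarray, flank: int
) -> np.ndarray:
    """Gather (B, 2*flank+2) window code rows; minus rows are
    reverse-complemented so every window reads 5'->3' on its strand."""
    rel = np.arange(-flank, flank + 2)
    win = codes[pos[:, None] + rel[None, :]]
    if minus.any():
        win[minus] = COMPLEMENT_CODES[win[minus][:, ::-1]]
    return win


def scan_genome(
    genome: Genome,
    model: SpliceCNN,
    table: CalibrationTable,
    min_score: float | None = None,
    batch_size: int = 512,
    max_n_frac: float | None = None,
    counts: dict | None = None,
) -> Iterator[SpliceScoreRecord]:
    """Yield one scored record per GT/AG candidate, both strands.

    ``min_score`` drops records below a threshold; ``max_n_frac`` skips
    windows with more than that fraction of N.  ``counts``, if given, is
    filled with emitted/skipped tallies.
    """
    flank = (model.config.window_len - 2) // 2
    tally = {"emitted": 0, "edge_skipped": 0, "n_skipped": 0, "contigs_skipped": 0}
    for contig, seq in genome.items():
        if len(seq) < model.config.window_len:
            logger.warning("contig %s shorter than the model window; skipped", contig)
            tally["contigs_skipped"] += 1
            continue
        codes = encode_seq(seq)
        sites = candidate_sites(codes)
        in_bounds = [
            (boundary_offset(p, strand, site_type), p, strand, site_type)
            for p, strand, site_type in sites
            if p - flank >= 0 and p + 2 + flank <= len(codes)
        ]
        in_bounds.sort()
        tally["edge_skipped"] += len(sites) - len(in_bounds)
        for start in range(0, len(in_bounds), batch_size):
            chunk = in_bounds[start : start + batch_size]
            pos = np.array([s[1] for s in chunk])
            minus = np.array([s[2] == "-" for s in chunk])
            win = _window_codes(codes, pos, minus, flank)
            if max_n_frac is not None:
                n_frac = (win == 4).mean(axis=1)
                keep = n_frac <= max_n_frac
                tally["n_skipped"] += int((~keep).sum())
                chunk = [c for c, k in zip(chunk, keep) if k]
                if not chunk:
                    continue
                win = win[keep]
            raw = model.forward(codes_to_onehot(win))
            scores = transform_score(table, raw)
            for (off, _, strand, site_type), s in zip(chunk, scores):
                if min_score is not None and s < min_score:
                    continue
                tally["emitted"] += 1
                yield SpliceScoreRecord(
                    contig=contig,
                    offset=off,
                    strand=strand,
                    site_type=site_type,
                    score=float(s),
                )
    if counts is not None:
        counts.update(tally)
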