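"""Accuracy metrics: ROC curves, restricted AUC and junction accuracy.

Genome-wide splice-site scoring is evaluated with ROC curves over every
scanned GT/AG candidate.  Because an aligner only benefits from the
high-confidence regime, the headline number is the *restricted* AUC
(rAUC): the area under the ROC curve inside the region with sensitivity
(TPR) >= 0.5 and false positive rate <= 0.1, rescaled by the region's
area (0.05) so rAUC lies in [0, 1].  A perfect classifier reaches 1; a
chance-level curve never enters the region and scores 0.

Junction accuracy compares aligned introns against the annotation with
exact, strand-aware coordinates:
``% unannotated = 100 * (1 - annotated / predicted)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from sklearn.metrics import roc_curve

from .formats import GeneRecord


@dataclass
class RocCurve:
    """Threshold sweep; points ordered by descending threshold so both
    rates are monotone non-decreasing, with (0,0) and (1,1) included."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray


def roc_points(scores: Sequence[float], labels: Sequence[int]) -> RocCurve:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    classes = set(np.unique(labels).tolist())
    if classes != {0, 1}:
        raise ValueError("ROC needs both positive and negative labels")
    fpr, tpr, thr = roc_curve(labels, scores, drop_intermediate=False)
    if fpr[-1] != 1.0 or tpr[-1] != 1.0:  # pragma: no cover - sklearn includes it
        fpr = np.append(fpr, 1.0)
        tpr = np.append(tpr, 1.0)
        thr = np.append(thr, -np.inf)
    return RocCurve(fpr=fpr, tpr=tpr, thresholds=thr)


def _segment_region_area(
    x0: float, y0: float, x1: float, y1: float, max_fpr: float, min_tpr: float
) -> float:
    """Area between a ROC segment and y = min_tpr, clipped to
    x <= max_fpr and y >= min_tpr, by trapezoids with explicit
    interpolation at the x = max_fpr and y = min_tpr crossings."""
    if x0 >= max_fpr or x1 <= x0:
        return 0.0
    if x1 > max_fpr:  # clip right border
        y1 = y0 + (y1 - y0) * (max_fpr - x0) / (x1 - x0)
        x1 = max_fpr
    if y1 <= min_tpr:
        return 0.0
    if y0 < min_tpr:  # clip bottom border (tpr is non-decreasing)
        x0 = x0 + (x1 - x0) * (min_tpr - y0) / (y1 - y0)
        y0 = min_tpr
    return (x1 - x0) * ((y0 - min_tpr) + (y1 - min_tpr)) / 2.0


def restricted_auc(
    curve: RocCurve, min_tpr: float = 0.5, max_fpr: float = 0.1
) -> float:
    """Area under the curve within {fpr <= max_fpr, tpr >= min_tpr},
    scaled by the rectangle area so the result lies in [0, 1]."""
    area = 0.0
    for k in range(len(curve.fpr) - 1):
        area += _segment_region_area(
            float(curve.fpr[k]), float(curve.tpr[k]),
            float(curve.fpr[k + 1]), float(curve.tpr[k + 1]),
            max_fpr, min_tpr,
        )
    return area / (max_fpr * (1.0 - min_tpr))


@dataclass
class JunctionStats:
    predicted: int
    annotated: int
    pct_unannotated: float | None  # None when nothing was predicted

    def summary(self) -> str:
        pct = "n/a" if self.pct_unannotated is None else f"{self.pct_unannotated:.2f}%"
        return (
            f"predicted junctions : {self.predicted}\n"
            f"annotated junctions : {self.annotated}\n"
            f"% unannotated       : {pct}"
        )


def annotation_junctions(genes: Iterable[GeneRecord]) -> set[tuple[str, str, int, int]]:
    """De-duplicated (contig, strand, start, end) junction keys."""
    keys = set()
    for gene in genes:
        for x, y in gene.introns():
            keys.add((gene.contig, gene.strand, x, y))
    return keys


def junction_accuracy(
    predicted: Iterable[tuple[str, str, int, int]],
    genes: Iterable[GeneRecord],
) -> JunctionStats:
    """Exact-coordinate, strand-aware junction accuracy.

    ``predicted`` holds (contig, strand, start, end) intron intervals;
    duplicates are collapsed on both sides before counting.
    """
    truth = annotation_junctions(genes)
    pred = set(predicted)
    n_pred = len(pred)
    n_annot = sum(1 for j in pred if j in truth)
    pct = None if n_pred == 0 else 100.0 * (1.0 - n_annot / n_pred)
    return JunctionStats(predicted=n_pred, annotated=n_annot, pct_unannotated=pct)


def expected_false_positive_sites(
    genome_length: float, dinucleotide_freq: float = 2.0 / 16.0, fpr: float = 0.01
) -> float:
    """Expected count of false sites from a genome-wide scan.

    The documentation example: a 3 Gb genome times a GT frequency of 2/16
    (both strands of random DNA) times a 1% false positive rate gives
    3.75 million expected false donor sites.
    """
    return genome_length * dinucleotide_freq * fpr
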