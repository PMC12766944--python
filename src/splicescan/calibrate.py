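"""Calibration of raw CNN scores to empirical log-odds splice scores.

Raw scores in [0,1) are binned evenly into ``b`` bins (bin ``i = floor(t*b)``,
50 by default; ``t = 1`` is clamped into the last bin).  With ``P_i``
annotated and ``N_i`` unannotated sites in bin ``i`` and totals ``P``,
``N``, the calibrated score is

    s_i = 2 * log2( P_i / (P_i + N_i) * (P + N) / P )

the log odds of the model's empirical splicing probability in that bin
against the null model under which every candidate GT/AG is equally
likely to be real.  The factor 2*log2 puts the scores in half-bit units,
the scale of BLOSUM substitution matrices, so they compose with
alignment scoring.

Empty bins inherit the score of the nearest non-empty lower bin, and bins
without positives are floored at ``s_min`` (-20 by default, "effectively
never spliced") so every score is finite and safe inside the aligner.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DEFAULT_BINS = 50
DEFAULT_S_MIN = -20.0


@dataclass
class CalibrationTable:
    b: int
    P_i: np.ndarray  # per-bin positive counts
    N_i: np.ndarray  # per-bin negative counts
    s_i: np.ndarray  # per-bin calibrated score
    s_min: float = DEFAULT_S_MIN

    @property
    def P(self) -> int:
        return int(self.P_i.sum())

    @property
    def N(self) -> int:
        return int(self.N_i.sum())

    @classmethod
    def from_counts(
        cls, P_i: np.ndarray, N_i: np.ndarray, s_min: float = DEFAULT_S_MIN
    ) -> "CalibrationTable":
        P_i = np.asarray(P_i, dtype=np.int64)
        N_i = np.asarray(N_i, dtype=np.int64)
        if P_i.shape != N_i.shape or P_i.ndim != 1 or len(P_i) == 0:
            raise ValueError("P_i and N_i must be equal-length 1-D arrays")
        if (P_i < 0).any() or (N_i < 0).any():
            raise ValueError("counts must be non-negative")
        P, N = P_i.sum(), N_i.sum()
        if P == 0 or N == 0:
            raise ValueError("both annotated and unannotated sites are required")
        b = len(P_i)
        tot = P_i + N_i
        s = np.full(b, np.nan)
        occupied = tot > 0
        with np.errstate(divide="ignore"):
            s[occupied] = 2.0 * np.log2(
                (P_i[occupied] / tot[occupied]) * ((P + N) / P)
            )
        s[occupied & (P_i == 0)] = s_min
        s = np.maximum(s, s_min, where=~np.isnan(s), out=s)
        # empty bins inherit the nearest non-empty lower bin (s_min if none)
        carry = s_min
        for i in range(b):
            if np.isnan(s[i]):
                s[i] = carry
            else:
                carry = s[i]
        return cls(b=b, P_i=P_i, N_i=N_i, s_i=s, s_min=s_min)

    def to_tsv(self, path) -> None:
        from .formats import _open_text

        with _open_text(path, "wt") as fh:
            fh.write("#bin\tP_i\tN_i\ts_i\n")
            for i in range(self.b):
                fh.write(f"{i}\t{self.P_i[i]}\t{self.N_i[i]}\t{self.s_i[i]:.4f}\n")

    @classmethod
    def from_tsv(cls, path) -> "CalibrationTable":
        from .formats import _open_text

        P, N = [], []
        with _open_text(path) as fh:
            for line in fh:
                if line.startswith("#"):
                    continue
                _, p, n, _ = line.rstrip("\n").split("\t")
                P.append(int(p))
                N.append(int(n))
        return cls.from_counts(np.array(P), np.array(N))


def assign_bins(scores: np.ndarray, b: int) -> np.ndarray:
    """Bin index floor(t*b), with t = 1 clamped into bin b-1."""
    scores = np.asarray(scores, dtype=float)
    if (scores < 0).any() or (scores > 1).any():
        raise ValueError("raw scores must lie in [0, 1]")
    return np.minimum((scores * b).astype(np.int64), b - 1)


def fit_calibration(
    raw_scores: np.ndarray,
    labels: np.ndarray,
    b: int = DEFAULT_BINS,
    s_min: float = DEFAULT_S_MIN,
) -> CalibrationTable:
    """Bin raw scores and compute per-bin calibrated log-odds scores."""
    if b <= 0:
        raise ValueError("bin count must be positive")
    raw_scores = np.asarray(raw_scores, dtype=float)
    labels = np.asarray(labels)
    if raw_scores.size == 0:
        raise ValueError("no calibration input")
    if raw_scores.shape != labels.shape:
        raise ValueError("scores and labels must align")
    bins = assign_bins(raw_scores, b)
    P_i = np.bincount(bins[labels == 1], minlength=b)
    N_i = np.bincount(bins[labels == 0], minlength=b)
    return CalibrationTable.from_counts(P_i, N_i, s_min=s_min)


def transform_score(table: CalibrationTable, t) -> np.ndarray | float:
    """Calibrated score s(t); piecewise constant over the bins."""
    scalar = np.isscalar(t)
    bins = assign_bins(np.atleast_1d(np.asarray(t, dtype=float)), table.b)
    out = table.s_i[bins]
    return float(out[0]) if scalar else out
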