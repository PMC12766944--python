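"""Reference spliced aligner: affine-gap DP with an intron state.

The recurrence extends Gotoh's affine-gap alignment with a fourth state
``Et`` that skips reference sequence between a paid donor entry and a
paid acceptor exit::

    H[i][j]  = max( H[i-1][j-1] + s(i,j),  E[i][j],  F[i][j],
                    Et[i][j] - a_pen(i) )
    E[i][j]  = max( H[i-1][j] - q,  E[i-1][j] ) - e
    F[i][j]  = max( H[i][j-1] - q,  F[i][j-1] ) - e
    Et[i][j] = max( H[i-L][j] - d_pen(i-L) - q_tilde,  Et[i-1][j] )

where ``q``/``e`` are gap open/extend penalties, ``q_tilde`` the intron
open penalty, ``L`` the minimum intron length, and ``d_pen``/``a_pen``
donor/acceptor penalties at reference boundary offsets.  Calibrated
log-odds splice scores ``s`` map to penalties as

    pen = max(0, penalty_base - min(splice_weight * s, splice_bonus_cap))

so a higher splice score always makes the intron cheaper; boundaries
without a score record are forbidden unless ``allow_unscored`` is set, in
which case they cost ``penalty_base + noncanonical_extra``.

Alignment is global in the query with free reference ends (the query is a
transcript fragment contained in the genomic window).  The DP fills full
matrices, O(n*m) time and memory — a correctness reference, not a seeded
and banded production aligner.  Tie-breaking is deterministic with state
priority H (diagonal) > intron > E > F, then the smaller reference index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .formats import SpliceScoreRecord

NEG = -1.0e18
_ATOL = 1e-6


@dataclass
class AlignParams:
    match: float = 1.0
    mismatch: float = -2.0
    gap_open: float = 2.0  # q
    gap_extend: float = 1.0  # e
    intron_open: float = 24.0  # q_tilde
    penalty_base: float = 12.0
    splice_weight: float = 1.0
    splice_bonus_cap: float = 12.0
    noncanonical_extra: float = 6.0
    allow_unscored: bool = False
    min_intron: int = 4
    max_intron: int = 50_000

    def validate(self) -> None:
        if self.gap_open <= 0 or self.gap_extend <= 0 or self.intron_open <= 0:
            raise ValueError("gap_open, gap_extend and intron_open must be positive")
        if self.min_intron < 4:
            raise ValueError("min_intron must be >= 4")
        if self.max_intron < self.min_intron:
            raise ValueError("max_intron < min_intron")

    def site_penalty(self, score: float | None) -> float:
        """Map a calibrated splice score to a DP penalty (see module doc)."""
        if score is None:
            if not self.allow_unscored:
                return np.inf
            return self.penalty_base + self.noncanonical_extra
        bonus = min(self.splice_weight * score, self.splice_bonus_cap)
        return max(0.0, self.penalty_base - bonus)


@dataclass
class SpliceScores:
    """Calibrated donor/acceptor scores keyed by reference-local boundary
    offset; positions without an entry carry no finite score."""

    donor: dict[int, float] = field(default_factory=dict)
    acceptor: dict[int, float] = field(default_factory=dict)

    @classmethod
    def from_records(
        cls,
        records: list[SpliceScoreRecord],
        contig: str,
        strand: str = "+",
        region_start: int = 0,
        region_end: int | None = None,
    ) -> "SpliceScores":
        """Project score records onto a reference window.

        For ``strand == '+'`` the window is ``contig[region_start:region_end]``
        and plus-strand records apply at ``offset - region_start``.  For
        ``strand == '-'`` the reference is the reverse complement of that
        window and minus-strand records apply at ``region_end - offset``
        (boundary coordinates mirror cleanly).
        """
        donor: dict[int, float] = {}
        acceptor: dict[int, float] = {}
        for r in records:
            if r.contig != contig or r.strand != strand:
                continue
            if region_end is not None and not (region_start <= r.offset <= region_end):
                continue
            if strand == "+":
                local = r.offset - region_start
            else:
                if region_end is None:
                    raise ValueError("region_end required for minus-strand windows")
                local = region_end - r.offset
            target = donor if r.site_type == "donor" else acceptor
            # isoform-shared boundaries: keep the best score
            target[local] = max(target.get(local, -np.inf), r.score)
        return cls(donor=donor, acceptor=acceptor)


@dataclass
class SplicedAlignment:
    """DP result: score, CIGAR-with-introns and intron intervals.

    ``cigar`` uses M (match/mismatch), I (insertion to reference),
    D (deletion from reference) and N (intron); ``ref_start``/``ref_end``
    delimit the aligned reference span (free ends are not encoded in the
    CIGAR).  ``identity`` is matches over aligned columns (M+I+D).
    """

    score: float
    cigar: list[tuple[str, int]]
    introns: list[tuple[int, int]]
    ref_start: int
    ref_end: int
    matches: int
    identity: float

    @property
    def cigar_string(self) -> str:
        return "".join(f"{n}{op}" for op, n in self.cigar)


def _penalty_arrays(
    n: int, params: AlignParams, scores: SpliceScores | None
) -> tuple[np.ndarray, np.ndarray]:
    d_pen = np.full(n + 1, params.site_penalty(None))
    a_pen = np.full(n + 1, params.site_penalty(None))
    if scores is not None:
        for off, s in scores.donor.items():
            if 0 <= off <= n:
                d_pen[off] = params.site_penalty(s)
        for off, s in scores.acceptor.items():
            if 0 <= off <= n:
                a_pen[off] = params.site_penalty(s)
    return d_pen, a_pen


def spliced_align(
    ref: str,
    query: str,
    params: AlignParams | None = None,
    splice_scores: SpliceScores | None = None,
) -> SplicedAlignment:
    """Optimal glocal spliced alignment of ``query`` against ``ref``."""
    params = params or AlignParams()
    params.validate()
    if not ref or not query:
        raise ValueError("ref and query must be non-empty")
    if set(ref) - set("ACGTN") or set(query) - set("ACGTN"):
        raise ValueError("sequences must be over ACGTN")
    if set(query) == {"N"}:
        raise ValueError("all-N query cannot be aligned")
    n, m = len(ref), len(query)
    if m > n:
        raise ValueError(f"query ({m} bp) longer than reference ({n} bp)")

    d_pen, a_pen = _penalty_arrays(n, params, splice_scores)
    q, e, qt = params.gap_open, params.gap_extend, params.intron_open
    L = params.min_intron

    qarr = np.frombuffer(query.encode(), dtype=np.uint8)
    rarr = np.frombuffer(ref.encode(), dtype=np.uint8)
    nmask_q = qarr == ord("N")

    H = np.full((n + 1, m + 1), NEG)
    E = np.full((n + 1, m + 1), NEG)
    F = np.full((n + 1, m + 1), NEG)
    Et = np.full((n + 1, m + 1), NEG)
    O = np.full((n + 1, m + 1), -1, dtype=np.int64)

    H[:, 0] = 0.0  # free reference prefix, empty query prefix
    js = np.arange(1, m + 1)
    # row 0: only query-consuming gaps
    run = np.maximum.accumulate(H[0, :m] - q + e * np.arange(m))
    F[0, 1:] = run - e * js
    H[0, 1:] = F[0, 1:]

    for i in range(1, n + 1):
        sub = np.where(
            (qarr == rarr[i - 1]) & ~nmask_q & (rarr[i - 1] != ord("N")),
            params.match,
            params.mismatch,
        )
        E[i, 1:] = np.maximum(H[i - 1, 1:] - q, E[i - 1, 1:]) - e
        if i >= L:
            cand = H[i - L, :] - d_pen[i - L] - qt
            newer = cand > Et[i - 1, :]
            Et[i, :] = np.where(newer, cand, Et[i - 1, :])
            O[i, :] = np.where(newer, i - L, O[i - 1, :])
        else:
            Et[i, :] = Et[i - 1, :]
            O[i, :] = O[i - 1, :]
        # expire introns longer than max_intron (drops the stored best only;
        # exact whenever introns stay below the bound, as in all uses here)
        expired = (O[i, :] >= 0) & (i - O[i, :] > params.max_intron)
        if expired.any():
            Et[i, expired] = NEG
            O[i, expired] = -1

        g = np.full(m + 1, NEG)
        g[1:] = H[i - 1, :m] + sub
        g[1:] = np.maximum(g[1:], E[i, 1:])
        if np.isfinite(a_pen[i]):
            g = np.maximum(g, Et[i, :] - a_pen[i])
        g[0] = 0.0  # free reference prefix
        run = np.maximum.accumulate(g[:m] - q + e * np.arange(m))
        F[i, 1:] = run - e * js
        H[i, 1:] = np.maximum(g[1:], F[i, 1:])
        H[i, 0] = 0.0

    i_end = int(np.argmax(H[:, m]))  # smallest index on ties
    score = float(H[i_end, m])
    ops, introns, matches = _traceback(
        H, E, F, Et, O, rarr, qarr, d_pen, a_pen, params, i_end
    )
    aligned_cols = sum(n_ for op, n_ in ops if op in "MID")
    ref_start = i_end - sum(n_ for op, n_ in ops if op in "MDN")
    return SplicedAlignment(
        score=score,
        cigar=ops,
        introns=introns,
        ref_start=ref_start,
        ref_end=i_end,
        matches=matches,
        identity=matches / aligned_cols if aligned_cols else 0.0,
    )


def _close(a: float, b: float) -> bool:
    return abs(a - b) <= _ATOL


def _traceback(H, E, F, Et, O, rarr, qarr, d_pen, a_pen, params, i_end):
    q, e, qt = params.gap_open, params.gap_extend, params.intron_open
    i, j = i_end, H.shape[1] - 1
    state = "H"
    rev_ops: list[str] = []
    introns: list[tuple[int, int]] = []
    matches = 0
    while j > 0 or state != "H":
        if state == "H":
            h = H[i, j]
            if (
                i >= 1
                and j >= 1
                and _close(
                    h,
                    H[i - 1, j - 1]
                    + (
                        params.match
                        if rarr[i - 1] == qarr[j - 1]
                        and qarr[j - 1] != ord("N")
                        and rarr[i - 1] != ord("N")
                        else params.mismatch
                    ),
                )
            ):
                if rarr[i - 1] == qarr[j - 1] and qarr[j - 1] != ord("N"):
                    matches += 1
                rev_ops.append("M")
                i, j = i - 1, j - 1
            elif O[i, j] >= 0 and _close(h, Et[i, j] - a_pen[i]):
                start = int(O[i, j])
                introns.append((start, i))
                rev_ops.extend("N" * (i - start))
                i = start
            elif _close(h, E[i, j]):
                state = "E"
            elif _close(h, F[i, j]):
                state = "F"
            else:  # pragma: no cover - would indicate a DP fill bug
                raise AssertionError(f"traceback stuck at H[{i}][{j}]")
        elif state == "E":
            rev_ops.append("D")
            if _close(E[i, j], H[i - 1, j] - q - e):
                state = "H"
            elif not _close(E[i, j], E[i - 1, j] - e):  # pragma: no cover
                raise AssertionError(f"traceback stuck at E[{i}][{j}]")
            i -= 1
        elif state == "F":
            rev_ops.append("I")
            if _close(F[i, j], H[i, j - 1] - q - e):
                state = "H"
            elif not _close(F[i, j], F[i, j - 1] - e):  # pragma: no cover
                raise AssertionError(f"traceback stuck at F[{i}][{j}]")
            j -= 1
    introns.reverse()
    rev_ops.reverse()
    ops: list[tuple[str, int]] = []
    for op in rev_ops:
        if ops and ops[-1][0] == op:
            ops[-1] = (op, ops[-1][1] + 1)
        else:
            ops.append((op, 1))
    return ops, introns, matches


def junction_set(alignment: SplicedAlignment) -> set[tuple[int, int]]:
    """Intron intervals recovered from the CIGAR (half-open, ref coords)."""
    out = set()
    pos = alignment.ref_start
    for op, n in alignment.cigar:
        if op == "N":
            out.add((pos, pos + n))
        if op in "MDN":
            pos += n
    return out
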