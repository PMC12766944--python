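"""Independent oracles used by the test suite.

Everything here is deliberately written in plain Python loops, structured
differently from the library code it cross-checks: a classic Gotoh
affine-gap aligner, a one-intron enumeration aligner built from Gotoh
pieces, and a straight-line re-implementation of the CNN forward pass.
"""

from __future__ import annotations

import math

NEG = float("-inf")


def _sub(a: str, b: str, match: float, mismatch: float) -> float:
    if a == "N" or b == "N":
        return mismatch
    return match if a == b else mismatch


def gotoh_matrix(
    ref: str,
    query: str,
    match: float = 1.0,
    mismatch: float = -2.0,
    q: float = 2.0,
    e: float = 1.0,
    free_ref_start: bool = True,
):
    """Aggregated-state Gotoh matrix H for glocal alignment.

    H[i][j] is the best score aligning query[:j] with a suffix of ref[:i]
    (free reference start) or with exactly ref[:i] when ``free_ref_start``
    is False (leading reference bases must then be paid as gaps).
    """
    n, m = len(ref), len(query)
    H = [[NEG] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    H[0][0] = 0.0
    for i in range(1, n + 1):
        if free_ref_start:
            H[i][0] = 0.0
        else:
            E[i][0] = max(H[i - 1][0] - q, E[i - 1][0]) - e
            H[i][0] = E[i][0]
    for j in range(1, m + 1):
        F[0][j] = max(H[0][j - 1] - q, F[0][j - 1]) - e
        H[0][j] = F[0][j]
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i - 1][j] - q, E[i - 1][j]) - e
            F[i][j] = max(H[i][j - 1] - q, F[i][j - 1]) - e
            diag = H[i - 1][j - 1] + _sub(ref[i - 1], query[j - 1], match, mismatch)
            H[i][j] = max(diag, E[i][j], F[i][j])
    return H


def gotoh_glocal_score(ref, query, match=1.0, mismatch=-2.0, q=2.0, e=1.0) -> float:
    """Best glocal (global-in-query, free reference ends) affine score."""
    H = gotoh_matrix(ref, query, match, mismatch, q, e, free_ref_start=True)
    m = len(query)
    return max(H[i][m] for i in range(len(ref) + 1))


def one_intron_best_score(
    ref: str,
    query: str,
    donor_pen: dict[int, float],
    acceptor_pen: dict[int, float],
    match: float = 1.0,
    mismatch: float = -2.0,
    q: float = 2.0,
    e: float = 1.0,
    q_tilde: float = 24.0,
    min_intron: int = 4,
) -> float:
    """Exhaustive enumeration over at most one intron.

    Tries every (donor d, acceptor a, query split j) with a - d >=
    min_intron and finite penalties: score = best prefix alignment ending
    exactly at reference position d with query[:j], plus the intron cost,
    plus the best suffix alignment starting exactly at a with query[j:]
    (free reference end).  The no-intron case is plain Gotoh.
    """
    n, m = len(ref), len(query)
    best = gotoh_glocal_score(ref, query, match, mismatch, q, e)
    prefix = gotoh_matrix(ref, query, match, mismatch, q, e, free_ref_start=True)
    for d, dp in donor_pen.items():
        if not math.isfinite(dp):
            continue
        for a, ap in acceptor_pen.items():
            if a - d < min_intron or a > n or not math.isfinite(ap):
                continue
            for j in range(m + 1):
                left = prefix[d][j]
                if left == NEG:
                    continue
                suf = gotoh_matrix(
                    ref[a:], query[j:], match, mismatch, q, e, free_ref_start=False
                )
                right = max(suf[i][m - j] for i in range(n - a + 1))
                total = left + right - dp - ap - q_tilde
                if total > best:
                    best = total
    return best


def random_one_intron_instance(rng, min_intron: int = 4):
    """A small alignment instance with one scored donor/acceptor pair.

    Queries keep sequence on both sides of the candidate intron and half
    the instances carry high splice scores, so the intron state is
    exercised often; the rest draw scores from the full range to cover
    the intron-rejected regime too.
    """
    bases = list("ACGT")
    n = int(rng.integers(10, 16))
    ref = "".join(rng.choice(bases, n))
    d = int(rng.integers(2, n - min_intron - 1))
    a = int(rng.integers(d + min_intron, n - 1))
    if rng.random() < 0.5:
        ds, as_ = float(rng.uniform(10, 14)), float(rng.uniform(10, 14))
    else:
        ds, as_ = float(rng.uniform(-2, 14)), float(rng.uniform(-2, 14))
    if rng.random() < 0.7:
        query = ref[max(0, d - 4) : d] + ref[a : a + 4]
    else:
        query = "".join(rng.choice(bases, rng.integers(1, 9)))
    return ref, query, d, a, ds, as_


def forward_reference(weights: list, window_onehot) -> float:
    """Straight-line CNN forward pass with plain loops.

    ``weights`` is [conv1_w, conv2_w, dense1_w, dense1_b, dense2_w,
    dense2_b] (bias-free convolutions); ``window_onehot`` is a 4 x L
    nested list or array.  Returns the softmax probability of the
    positive class.
    """
    conv1_w, conv2_w, d1_w, d1_b, d2_w, d2_b = weights

    def conv_relu(x, w):
        n_feat = len(w)
        n_ch = len(w[0])
        k = len(w[0][0])
        lin = len(x[0])
        out = []
        for f in range(n_feat):
            row = []
            for p in range(lin - k + 1):
                acc = 0.0
                for c in range(n_ch):
                    for kk in range(k):
                        acc += w[f][c][kk] * x[c][p + kk]
                row.append(max(acc, 0.0))
            out.append(row)
        return out

    def pool3(x):
        out = []
        for row in x:
            pooled = []
            for p in range(0, len(row), 3):
                pooled.append(max(row[p : p + 3]))
            out.append(pooled)
        return out

    x = pool3(conv_relu(window_onehot, conv1_w))
    x = pool3(conv_relu(x, conv2_w))
    flat = [v for row in x for v in row]
    hidden = []
    for o in range(len(d1_w)):
        acc = d1_b[o]
        for i, v in enumerate(flat):
            acc += d1_w[o][i] * v
        hidden.append(max(acc, 0.0))
    logits = []
    for o in range(len(d2_w)):
        acc = d2_b[o]
        for i, v in enumerate(hidden):
            acc += d2_w[o][i] * v
        logits.append(acc)
    mx = max(logits)
    exps = [math.exp(z - mx) for z in logits]
    return exps[1] / sum(exps)
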