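"""Independent brute-force oracles used only by the tests.

These deliberately avoid the library paths they check: a quadratic-time
affine-gap Needleman-Wunsch scorer, a step-up Benjamini-Hochberg
enumeration, a codon-by-codon translator, and an exhaustive confusion
matrix.
"""

from __future__ import annotations

import math

NEG = float("-inf")

CODON_TABLE = {}


def _build_codon_table():
    # independent of Biopython: standard genetic code, hand-entered
    aas = (
        "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
    )
    bases = "TCAG"
    i = 0
    for a in bases:
        for b in bases:
            for c in bases:
                CODON_TABLE[a + b + c] = aas[i]
                i += 1


_build_codon_table()


def translate(seq: str) -> str:
    """Translate until the first stop codon (exclusive); '' if it starts with one."""
    out = []
    for i in range(0, len(seq) - 2, 3):
        aa = CODON_TABLE[seq[i : i + 3]]
        if aa == "*":
            break
        out.append(aa)
    return "".join(out)


def nw_affine_score(
    a: str,
    b: str,
    match: float = 5.0,
    mismatch: float = -4.0,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> float:
    """Global affine-gap alignment score; gap of length L costs open + (L-1)*extend.

    End gaps are penalized (true global alignment).
    """
    n, m = len(a), len(b)
    # M: last column aligned; X: gap in b (a consumed); Y: gap in a (b consumed)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = -gap_open - gap_extend * (i - 1)
    for j in range(1, m + 1):
        Y[0][j] = -gap_open - gap_extend * (j - 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(
                M[i - 1][j] - gap_open,
                X[i - 1][j] - gap_extend,
                Y[i - 1][j] - gap_open,
            )
            Y[i][j] = max(
                M[i][j - 1] - gap_open,
                Y[i][j - 1] - gap_extend,
                X[i][j - 1] - gap_open,
            )
    return max(M[n][m], X[n][m], Y[n][m])


def bh_stepup(pvals):
    """Brute-force Benjamini-Hochberg step-up q-values in input order."""
    n = len(pvals)
    order = sorted(range(n), key=lambda i: pvals[i])
    q = [0.0] * n
    running = math.inf
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, pvals[i] * n / rank)
        q[i] = min(running, 1.0)
    return q


def confusion_at_threshold(scores, labels, threshold):
    """Exhaustive confusion matrix; positive call = score strictly below threshold."""
    tp = fp = tn = fn = 0
    for s, y in zip(scores, labels):
        called = s < threshold
        if called and y:
            tp += 1
        elif called and not y:
            fp += 1
        elif not called and y:
            fn += 1
        else:
            tn += 1
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    return sens, spec
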