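"""Brute-force alignment oracle: exhaustive enumeration of alignment paths.

Independent of the package's dynamic programming: every monotone path of
match/insert/delete moves is walked explicitly, scoring gaps by run length
(a k-long gap costs open + (k-1) * extend).  Exponential, so only usable for
sequences of length <= ~7 — which is the point: the oracle is obviously
correct by construction.
"""

from __future__ import annotations

from genorigin import ScoringScheme
from genorigin.homology import encode


def _sub_fn(scoring: ScoringScheme):
    matrix = scoring.matrix

    def sub(ca: str, cb: str) -> int:
        ia, ib = int(encode(ca)[0]), int(encode(cb)[0])
        return int(matrix[ia, ib])

    return sub


def brute_global_score(a: str, b: str, scoring: ScoringScheme) -> int:
    """Maximum global alignment score over all alignment paths."""
    sub = _sub_fn(scoring)
    go, ge = scoring.gap_open, scoring.gap_extend
    best = [None]

    def rec(i: int, j: int, score: int, last: str) -> None:
        if i == len(a) and j == len(b):
            if best[0] is None or score > best[0]:
                best[0] = score
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, score + sub(a[i], b[j]), "M")
        if i < len(a):
            rec(i + 1, j, score - (ge if last == "U" else go), "U")
        if j < len(b):
            rec(i, j + 1, score - (ge if last == "L" else go), "L")

    rec(0, 0, 0, "M")
    return best[0]


def brute_local_score(a: str, b: str, scoring: ScoringScheme) -> int:
    """Maximum local alignment score: all start points, all stop points."""
    sub = _sub_fn(scoring)
    go, ge = scoring.gap_open, scoring.gap_extend
    best = [0]  # empty alignment scores 0

    def rec(i: int, j: int, score: int, last: str) -> None:
        if score > best[0]:
            best[0] = score
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, score + sub(a[i], b[j]), "M")
        if i < len(a):
            rec(i + 1, j, score - (ge if last == "U" else go), "U")
        if j < len(b):
            rec(i, j + 1, score - (ge if last == "L" else go), "L")

    for i in range(len(a) + 1):
        for j in range(len(b) + 1):
            rec(i, j, 0, "M")
    return best[0]
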