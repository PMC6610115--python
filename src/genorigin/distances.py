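"""Pairwise evolutionary distances under the 20-state uniform model."""

from __future__ import annotations

import math

from .homology import ScoringScheme, global_align


def expected_p_distance(total_path_length: float) -> float:
    """Expected fraction of differing sites after a given total path length.

    Closed form for the 20-state uniform substitution model:
    ``(19/20) * (1 - exp(-20 t / 19))``; saturates at 19/20.
    """
    if total_path_length < 0:
        raise ValueError("total path length must be >= 0")
    return (19.0 / 20.0) * (1.0 - math.exp(-20.0 * total_path_length / 19.0))


def poisson_correct(p: float) -> float:
    """Invert :func:`expected_p_distance`: substitutions/site from a p-distance.

    Returns ``inf`` (saturation sentinel) for p >= 0.95, where the correction
    diverges.
    """
    if p < 0:
        raise ValueError("p-distance must be >= 0")
    if p >= 0.95:
        return math.inf
    return -(19.0 / 20.0) * math.log(1.0 - 20.0 * p / 19.0)


def p_distance(aligned_a: str, aligned_b: str) -> float:
    """Mismatch fraction over gap-free, X-free aligned columns (0 if none)."""
    mismatches = 0
    comparable = 0
    for ca, cb in zip(aligned_a, aligned_b):
        if "-" in (ca, cb) or "X" in (ca, cb):
            continue
        comparable += 1
        if ca != cb:
            mismatches += 1
    return mismatches / comparable if comparable else 0.0


def corrected_alignment_distance(a: str, b: str, scoring: ScoringScheme) -> float:
    """Poisson-corrected distance from a pairwise global alignment."""
    aln = global_align(a, b, scoring)
    return poisson_correct(p_distance(aln.aligned_a, aln.aligned_b))
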