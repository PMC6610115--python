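"""In-repo similarity search: alignment, E-values, best hits, orthogroups.

The search stage is exhaustive: every query is scored against every subject
with full affine-gap Smith-Waterman dynamic programming (no heuristic
seeding), which is tractable at desk scale thanks to the batched kernel in
:mod:`genorigin._swkernel`.  Hit significance uses the Karlin-Altschul
approximation E = K * m * n * exp(-lambda * S) with configurable constants;
the defaults are the common gapped-BLOSUM62 values and an E < 1e-5 retention
threshold.

Orthogroups are connected components of reciprocal-best-hit (RBH) edges
between species, optionally augmented with within-species reciprocal-best
in-paralog edges so that lineage-specific duplicates join the family they
duplicated from (see :func:`in_paralog_pairs`).  This is a deliberately
self-contained, testable stand-in for MCL-style orthology clustering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from . import _swkernel
from .seqio import ALPHABET, Proteome

_ENCODE = {c: i for i, c in enumerate(ALPHABET)}


def encode(sequence: str) -> np.ndarray:
    """Encode a protein sequence over ACDEFGHIKLMNPQRSTVWYX as int8 indices."""
    try:
        return np.array([_ENCODE[c] for c in sequence], dtype=np.int8)
    except KeyError as exc:
        raise ValueError(f"illegal character {exc.args[0]!r} in sequence") from exc


def _default_matrix() -> np.ndarray:
    """BLOSUM62 over the package alphabet; 'X' scores 0 against everything."""
    b62 = substitution_matrices.load("BLOSUM62")
    n = len(ALPHABET)
    mat = np.zeros((n, n), dtype=np.int32)
    for i, ci in enumerate(ALPHABET[:-1]):
        for j, cj in enumerate(ALPHABET[:-1]):
            mat[i, j] = int(b62[ci][cj])
    # X row/column stay 0 by construction
    return mat


@dataclass
class ScoringScheme:
    """Alignment scoring, E-value statistics and hit filters.

    ``matrix`` is a symmetric integer substitution matrix over the 21-letter
    alphabet ``ACDEFGHIKLMNPQRSTVWYX`` (default BLOSUM62 with ``X`` neutral at
    0).  A gap of length k costs ``gap_open + (k - 1) * gap_extend``.
    """

    matrix: np.ndarray = field(default_factory=_default_matrix)
    gap_open: int = 11
    gap_extend: int = 1
    evalue_lambda: float = 0.267
    evalue_K: float = 0.041
    evalue_threshold: float = 1e-5
    min_coverage: float = 0.7

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.int32)
        if self.matrix.shape != (21, 21):
            raise ValueError("substitution matrix must be 21x21 over ACDEFGHIKLMNPQRSTVWYX")
        if not np.array_equal(self.matrix, self.matrix.T):
            raise ValueError("substitution matrix must be symmetric")
        if not (self.gap_open >= self.gap_extend >= 1):
            raise ValueError("need gap_open >= gap_extend >= 1")
        if self.evalue_lambda <= 0 or self.evalue_K <= 0:
            raise ValueError("E-value constants must be positive")
        if self.evalue_threshold <= 0:
            raise ValueError("evalue_threshold must be positive")
        if not 0.0 <= self.min_coverage <= 1.0:
            raise ValueError("min_coverage must be in [0, 1]")

    @cached_property
    def padded_matrix(self) -> np.ndarray:
        """22x22 kernel matrix; the extra row/column is the padding sentinel."""
        mat = np.full((22, 22), -100, dtype=np.int32)
        mat[:21, :21] = self.matrix
        return mat

    @cached_property
    def _bio_matrix(self):
        arr = substitution_matrices.Array(alphabet=ALPHABET, dims=2)
        for i, ci in enumerate(ALPHABET):
            for j, cj in enumerate(ALPHABET):
                arr[ci, cj] = float(self.matrix[i, j])
        return arr

    def _aligner(self, mode: str) -> Align.PairwiseAligner:
        aligner = Align.PairwiseAligner()
        aligner.mode = mode
        aligner.substitution_matrix = self._bio_matrix
        aligner.open_gap_score = -float(self.gap_open)
        aligner.extend_gap_score = -float(self.gap_extend)
        return aligner

    @cached_property
    def global_aligner(self) -> Align.PairwiseAligner:
        return self._aligner("global")

    @cached_property
    def local_aligner(self) -> Align.PairwiseAligner:
        return self._aligner("local")


@dataclass(frozen=True)
class AlignmentResult:
    """A pairwise alignment: score, gapped strings, identity and coverage.

    ``identity_fraction`` counts matches over aligned columns where both
    residues are non-gap and neither is ``X``.  ``coverage`` is the fraction
    of the first ("reference") sequence covered by aligned columns.
    """

    score: float
    aligned_a: str
    aligned_b: str
    identity_fraction: float
    coverage: float

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("gapped strings must have equal length")


@dataclass(frozen=True)
class SimilarityHit:
    """Best-scoring passing hit of a query in a subject proteome."""

    query_id: str
    subject_id: str
    score: float
    evalue: float
    identity_fraction: float
    coverage: float


@dataclass
class Orthogroup:
    """A connected component of (reciprocal) best-hit edges."""

    group_id: str
    members: dict[str, list[str]]  # species -> sorted member ids

    @property
    def species_present(self) -> list[str]:
        return sorted(s for s, m in self.members.items() if m)

    @property
    def single_copy(self) -> bool:
        return all(len(m) == 1 for m in self.members.values())

    def member(self, species: str) -> str:
        (only,) = self.members[species]
        return only


def _stats(aligned_a: str, aligned_b: str, ref_len: int) -> tuple[float, float]:
    matches = 0
    comparable = 0
    covered_a = 0
    for ca, cb in zip(aligned_a, aligned_b):
        if ca != "-" and cb != "-":
            covered_a += 1
            if ca != "X" and cb != "X":
                comparable += 1
                if ca == cb:
                    matches += 1
    identity = matches / comparable if comparable else 0.0
    coverage = covered_a / ref_len if ref_len else 0.0
    return identity, coverage


def _align(a: str, b: str, aligner: Align.PairwiseAligner) -> AlignmentResult:
    encode(a), encode(b)  # validate alphabet
    alignments = aligner.align(a, b)
    best = alignments[0]
    ga, gb = str(best[0]), str(best[1])
    # coverage is relative to the full first ("reference") sequence, which a
    # local alignment may only partially cover
    identity, coverage = _stats(ga, gb, len(a))
    return AlignmentResult(float(best.score), ga, gb, identity, coverage)


def global_align(a: str, b: str, scoring: ScoringScheme) -> AlignmentResult:
    """Optimal Needleman-Wunsch global alignment with affine gaps."""
    if not a and not b:
        return AlignmentResult(0.0, "", "", 0.0, 0.0)
    if not a or not b:
        # forced all-gap alignment; PairwiseAligner cannot traceback length-0
        gap_len = len(a) + len(b)
        score = -(scoring.gap_open + (gap_len - 1) * scoring.gap_extend)
        ga = a if a else "-" * gap_len
        gb = b if b else "-" * gap_len
        return AlignmentResult(float(score), ga, gb, 0.0, 0.0)
    return _align(a, b, scoring.global_aligner)


def local_align(a: str, b: str, scoring: ScoringScheme) -> AlignmentResult:
    """Optimal Smith-Waterman local alignment; score >= 0, may be empty."""
    if a and b:
        try:
            result = _align(a, b, scoring.local_aligner)
        except IndexError:
            # aligner yields no alignment when nothing scores positively
            result = None
        if result is not None and result.score > 0:
            return result
    return AlignmentResult(0.0, "", "", 0.0, 0.0)


def estimate_evalue(
    score: float, query_len: int, subject_total_len: int, scoring: ScoringScheme
) -> float:
    """Karlin-Altschul expected number of chance hits: K * m * n * exp(-lambda*S)."""
    if query_len <= 0 or subject_total_len <= 0:
        raise ValueError("sequence lengths must be positive")
    return scoring.evalue_K * query_len * subject_total_len * math.exp(
        -scoring.evalue_lambda * score
    )


# ---------------------------------------------------------------------------
# Batch search
# ---------------------------------------------------------------------------

def score_matrix(
    query: Proteome, subject: Proteome, scoring: ScoringScheme
) -> np.ndarray:
    """Exhaustive (n_query, n_subject) matrix of local alignment scores."""
    eq = [encode(r.sequence) for r in query]
    es = [encode(r.sequence) for r in subject]
    return _swkernel.batch_scores(
        eq, es, scoring.padded_matrix, scoring.gap_open, scoring.gap_extend
    )


def best_hits(
    query: Proteome,
    subject: Proteome,
    scoring: ScoringScheme,
    *,
    scores: np.ndarray | None = None,
    with_alignment_stats: bool = False,
) -> dict[str, SimilarityHit]:
    """Best passing subject per query.

    For each query, the subject with the maximal local score whose E-value
    passes the threshold; ties broken by lexicographically smallest subject
    id.  Queries with no passing hit are absent from the result.  Identity and
    coverage are filled from a traceback alignment only on request (they are
    not needed for counting-style analyses).
    """
    if scores is None:
        scores = score_matrix(query, subject, scoring)
    same = query is subject or (
        query.species == subject.species and query.ids() == subject.ids()
    )
    if same and len(subject) < 2:
        return {}
    subject_ids = np.array(subject.ids())
    total_len = sum(len(r) for r in subject)
    hits: dict[str, SimilarityHit] = {}
    for qi, qrec in enumerate(query):
        row = scores[qi]
        if same:
            row = row.copy()
            row[qi] = np.iinfo(row.dtype).min
        best_score = int(row.max())
        ev = estimate_evalue(best_score, len(qrec), total_len, scoring)
        if ev >= scoring.evalue_threshold:
            continue
        # deterministic tie-break: lexicographically smallest subject id
        sid = min(subject_ids[row == best_score].tolist())
        identity = coverage = float("nan")
        if with_alignment_stats:
            aln = local_align(qrec.sequence, subject[sid].sequence, scoring)
            identity, coverage = aln.identity_fraction, aln.coverage
        hits[qrec.id] = SimilarityHit(qrec.id, sid, float(best_score), ev, identity, coverage)
    return hits


def reciprocal_best_hits(
    p: Proteome,
    q: Proteome,
    scoring: ScoringScheme,
    *,
    scores: np.ndarray | None = None,
) -> set[tuple[str, str]]:
    """Pairs (p_id, q_id) that are each other's best passing hit."""
    if scores is None:
        scores = score_matrix(p, q, scoring)
    fwd = best_hits(p, q, scoring, scores=scores)
    rev = best_hits(q, p, scoring, scores=scores.T)
    return {
        (pid, hit.subject_id)
        for pid, hit in fwd.items()
        if rev.get(hit.subject_id) is not None and rev[hit.subject_id].subject_id == pid
    }


def in_paralog_pairs(
    p: Proteome,
    scoring: ScoringScheme,
    *,
    scores: np.ndarray | None = None,
    cross_best: Mapping[str, float] | None = None,
) -> set[tuple[str, str]]:
    """Within-species reciprocal best non-self pairs (recent duplicates).

    With ``cross_best`` (each gene's best threshold-passing cross-species
    alignment score), the InParanoid-style anchoring applies: both members
    must have an ortholog at all, and the pair score must be at least the
    weaker member's ortholog score — a duplication that postdates speciation
    leaves the duplicate closer to its twin than to any ortholog.  This
    rejects chance mutual-best pairs between genes that merely lack true
    paralogs (such pairs either involve a gene with no ortholog, or score
    far below both members' ortholog scores).
    """
    if scores is None:
        scores = score_matrix(p, p, scoring)
    fwd = best_hits(p, p, scoring, scores=scores)
    pairs = set()
    for pid, hit in fwd.items():
        back = fwd.get(hit.subject_id)
        if back is None or back.subject_id != pid:
            continue
        if cross_best is not None:
            if pid not in cross_best or hit.subject_id not in cross_best:
                continue
            if hit.score < min(cross_best[pid], cross_best[hit.subject_id]):
                continue
        pairs.add(tuple(sorted((pid, hit.subject_id))))
    return pairs


class _UnionFind:
    def __init__(self) -> None:
        self.parent: dict = {}

    def find(self, x):
        parent = self.parent
        if x not in parent:
            parent[x] = x
            return x
        root = x
        while parent[root] != root:
            root = parent[root]
        while parent[x] != root:
            parent[x], x = root, parent[x]
        return root

    def union(self, a, b) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            # deterministic: smaller key wins
            if rb < ra:
                ra, rb = rb, ra
            self.parent[rb] = ra


def build_orthogroups(
    rbh_na: Iterable[tuple[str, str]],
    rbh_np: Iterable[tuple[str, str]],
    rbh_ap: Iterable[tuple[str, str]],
    *,
    species: tuple[str, str, str] = ("N", "A", "P"),
    within: Mapping[str, Iterable[tuple[str, str]]] | None = None,
) -> list[Orthogroup]:
    """Connected components of the RBH union graph (union-find).

    ``rbh_na``, ``rbh_np``, ``rbh_ap`` are reciprocal-best-hit pair sets for
    the species pairs (focal, host-ref), (focal, symbiont-ref) and
    (host-ref, symbiont-ref).  ``within`` optionally maps a species tag to
    within-species in-paralog pairs so recent duplicates join their family's
    component (and flag it multi-copy) instead of floating free.
    Vertices are (species, id) pairs, so ids need only be unique per species.
    """
    sn, sa, sp = species
    uf = _UnionFind()
    edge_sets = [
        ((sn, sa), rbh_na),
        ((sn, sp), rbh_np),
        ((sa, sp), rbh_ap),
    ]
    if within:
        edge_sets.extend(((s, s), pairs) for s, pairs in sorted(within.items()))
    n_edges = 0
    for (spec_x, spec_y), pairs in edge_sets:
        for x, y in sorted(pairs):
            uf.union((spec_x, x), (spec_y, y))
            n_edges += 1
    components: dict = {}
    for node in list(uf.parent):
        components.setdefault(uf.find(node), []).append(node)
    groups = []
    for _, nodes in sorted(components.items()):
        members: dict[str, list[str]] = {s: [] for s in species}
        for spec, mid in nodes:
            members.setdefault(spec, []).append(mid)
        for m in members.values():
            m.sort()
        groups.append(members)
    groups.sort(key=lambda m: min(mid for ids in m.values() for mid in ids))
    width = max(4, len(str(len(groups))))
    return [
        Orthogroup(f"OG{idx:0{width}d}", members)
        for idx, members in enumerate(groups, start=1)
    ]


def homolog_fraction(
    query: Proteome,
    reference: Proteome,
    scoring: ScoringScheme,
    *,
    scores: np.ndarray | None = None,
) -> float:
    """Percentage of query genes with at least one passing hit in the reference."""
    if len(query) == 0:
        raise ValueError("homolog_fraction needs a non-empty query proteome")
    hits = best_hits(query, reference, scoring, scores=scores)
    return 100.0 * len(hits) / len(query)
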