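"""Triplet nearest-pair classification and homolog partitioning.

The central inference: for every single-copy orthogroup spanning the focal
species N, the host-lineage reference A and the symbiont-lineage reference P,
the three pairwise distances decide which pair is sister.  A focal gene whose
nearest relative is the host reference is of host-nuclear origin
(Pattern I); a focal gene far from the host reference is of symbiont-nuclear
origin — either sister to the symbiont reference (Pattern II) or an outgroup
to the two references (Pattern III).  Multi-copy orthogroups are tallied but
never classified; near-exact distance ties are reported as unresolved.

Distances come from pairwise global alignments: the p-distance is the
mismatch fraction over aligned columns that are gap-free and ``X``-free, with
an optional Poisson-type correction ``-(19/20) ln(1 - 20p/19)``.  The
nearest-pair decision depends only on the ordering of the three distances,
which the (monotone) correction does not change below saturation.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .distances import p_distance, poisson_correct
from .homology import Orthogroup, ScoringScheme, SimilarityHit, global_align
from .seqio import Proteome


class PatternLabel(str, enum.Enum):
    """Origin call for one orthogroup."""

    PATTERN_I = "PATTERN_I"       # focal sister to host reference -> host origin
    PATTERN_II = "PATTERN_II"     # focal sister to symbiont reference
    PATTERN_III = "PATTERN_III"   # references sister, focal outgroup
    MULTI_COPY = "MULTI_COPY"     # >1 member in some species; not classified
    UNRESOLVED = "UNRESOLVED"     # distance tie within tolerance

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class PairwiseDistances:
    """The three pairwise distances of a triplet (N-A, N-P, A-P)."""

    d_na: float
    d_np: float
    d_ap: float
    corrected: bool = False

    def __post_init__(self) -> None:
        for d in (self.d_na, self.d_np, self.d_ap):
            if d < 0:
                raise ValueError("distances must be >= 0")
            if not self.corrected and d > 1:
                raise ValueError("p-distances cannot exceed 1")


@dataclass(frozen=True)
class VennPartition:
    """Counts of focal genes by homolog presence in the two references."""

    n_unique: int
    n_only_host: int
    n_only_symbiont: int
    n_both: int

    def __post_init__(self) -> None:
        if min(self.n_unique, self.n_only_host, self.n_only_symbiont, self.n_both) < 0:
            raise ValueError("counts must be >= 0")

    @property
    def total(self) -> int:
        return self.n_unique + self.n_only_host + self.n_only_symbiont + self.n_both

    @property
    def n_homologous(self) -> int:
        """Genes with a homolog in at least one reference."""
        return self.total - self.n_unique


@dataclass
class AncestrySummary:
    """Per-label orthogroup counts plus the host/symbiont evidence tally."""

    counts: dict[PatternLabel, int]

    @property
    def n_groups(self) -> int:
        return sum(self.counts.values())

    @property
    def host_evidence(self) -> int:
        return self.counts.get(PatternLabel.PATTERN_I, 0)

    @property
    def symbiont_evidence(self) -> int:
        return self.counts.get(PatternLabel.PATTERN_II, 0) + self.counts.get(
            PatternLabel.PATTERN_III, 0
        )

    @property
    def verdict(self) -> str:
        host, symbiont = self.host_evidence, self.symbiont_evidence
        if symbiont > host:
            return "symbiont-dominant"
        if host > symbiont:
            return "host-dominant"
        return "indeterminate"


def triplet_distances(
    orthogroup: Orthogroup,
    proteomes: Mapping[str, Proteome],
    scoring: ScoringScheme,
    *,
    correction: bool = False,
    species: tuple[str, str, str] = ("N", "A", "P"),
) -> PairwiseDistances:
    """Pairwise distances of a single-copy triplet from global alignments."""
    sn, sa, sp = species
    missing = [s for s in species if not orthogroup.members.get(s)]
    if missing:
        raise ValueError(
            f"orthogroup {orthogroup.group_id} lacks members for species {missing}"
        )
    if not orthogroup.single_copy:
        raise ValueError(f"orthogroup {orthogroup.group_id} is multi-copy")
    seqs = {s: proteomes[s][orthogroup.member(s)].sequence for s in species}
    dists = {}
    for key, (x, y) in {"na": (sn, sa), "np": (sn, sp), "ap": (sa, sp)}.items():
        aln = global_align(seqs[x], seqs[y], scoring)
        p = p_distance(aln.aligned_a, aln.aligned_b)
        dists[key] = poisson_correct(p) if correction else p
    return PairwiseDistances(dists["na"], dists["np"], dists["ap"], corrected=correction)


def classify_triplet(
    distances: PairwiseDistances, tolerance: float = 1e-12
) -> PatternLabel:
    """Nearest pair names the pattern; near-ties are unresolved.

    Smallest of (d_NA, d_NP, d_AP) picks PATTERN_I / PATTERN_II / PATTERN_III
    respectively; if the two smallest distances differ by less than
    ``tolerance`` the triplet is UNRESOLVED.
    """
    triple = [
        (distances.d_na, PatternLabel.PATTERN_I),
        (distances.d_np, PatternLabel.PATTERN_II),
        (distances.d_ap, PatternLabel.PATTERN_III),
    ]
    ordered = sorted(triple, key=lambda t: t[0])
    if ordered[1][0] - ordered[0][0] < tolerance:
        return PatternLabel.UNRESOLVED
    return ordered[0][1]


def classify_dataset(
    orthogroups: Iterable[Orthogroup],
    proteomes: Mapping[str, Proteome],
    scoring: ScoringScheme,
    *,
    correction: bool = False,
    tolerance: float = 1e-12,
    species: tuple[str, str, str] = ("N", "A", "P"),
) -> tuple[AncestrySummary, pd.DataFrame]:
    """Classify every triplet-spanning orthogroup; multi-copy groups are tallied.

    Returns the summary plus a per-group table (group_id, focal_id, d_NA,
    d_NP, d_AP, label).  Label counts always sum to the number of input
    groups.  Every input group must span all three species (the upstream
    Venn partition owns genes without homologs in both references).
    """
    counts = {label: 0 for label in PatternLabel}
    rows = []
    sn = species[0]
    for og in orthogroups:
        missing = [s for s in species if not og.members.get(s)]
        if missing:
            raise ValueError(
                f"orthogroup {og.group_id} lacks members for species {missing}; "
                "classification expects triplet-spanning groups"
            )
        focal_ids = ",".join(og.members[sn])
        if not og.single_copy:
            counts[PatternLabel.MULTI_COPY] += 1
            rows.append((og.group_id, focal_ids, None, None, None, PatternLabel.MULTI_COPY.value))
            continue
        dists = triplet_distances(
            og, proteomes, scoring, correction=correction, species=species
        )
        label = classify_triplet(dists, tolerance)
        counts[label] += 1
        rows.append(
            (og.group_id, focal_ids, dists.d_na, dists.d_np, dists.d_ap, label.value)
        )
    table = pd.DataFrame(
        rows, columns=["group_id", "focal_id", "d_NA", "d_NP", "d_AP", "label"]
    )
    return AncestrySummary(counts), table


def venn_partition(
    focal: Proteome,
    hits_vs_host: Mapping[str, SimilarityHit],
    hits_vs_symbiont: Mapping[str, SimilarityHit],
) -> VennPartition:
    """Assign each focal gene to unique / host-only / symbiont-only / both.

    Membership is decided by the presence of at least one threshold-passing
    hit against each reference proteome; the four categories partition the
    focal proteome exactly.
    """
    n_unique = n_host = n_symbiont = n_both = 0
    for rec in focal:
        in_host = rec.id in hits_vs_host
        in_symbiont = rec.id in hits_vs_symbiont
        if in_host and in_symbiont:
            n_both += 1
        elif in_host:
            n_host += 1
        elif in_symbiont:
            n_symbiont += 1
        else:
            n_unique += 1
    return VennPartition(n_unique, n_host, n_symbiont, n_both)


def symbiont_evidence_tally(summary: AncestrySummary) -> tuple[int, int, str]:
    """(host_count, symbiont_count, verdict); multi-copy/unresolved excluded.

    Host evidence is the Pattern I count; symbiont evidence is
    Pattern II + Pattern III.
    """
    return summary.host_evidence, summary.symbiont_evidence, summary.verdict
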