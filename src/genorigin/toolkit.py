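"""Curated gene-toolkit presence/absence screening.

A toolkit is a curated set of marker genes (e.g. a meiosis detection toolkit,
a flagellar-gene catalogue, or plastid translocon components), each defined
by one or more reference sequences and optionally decoy paralogs — related
but functionally distinct genes that attract spurious hits.  A gene is called
present in a proteome only if its best passing hit is, by global-alignment
distance, nearer to a true reference than to every decoy; this two-class
nearest-neighbor decision reproduces the classic Rec8-versus-Rad21
disambiguation (a cohesin hit that is really the mitotic paralog must not
count as the meiotic gene) without full tree inference.

Decision rules layered on the calls:

* sexual-reproduction verdict: ``sexual`` iff at least ``threshold``
  (default 6) toolkit genes are present;
* flagellar category totals and the motile/nonmotile gene-count ratio.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from . import _swkernel
from .distances import corrected_alignment_distance
from .homology import ScoringScheme, encode, estimate_evalue, local_align
from .seqio import Proteome, read_fasta

logger = logging.getLogger("genorigin")


@dataclass(frozen=True)
class ToolkitGeneRef:
    """References and decoys for one toolkit gene."""

    name: str
    references: Mapping[str, str]  # id -> sequence (>= 1)
    decoys: Mapping[str, str] = field(default_factory=dict)
    category: str = ""

    def __post_init__(self) -> None:
        if not self.references:
            raise ValueError(f"toolkit gene {self.name!r} needs >= 1 reference sequence")
        overlap = set(self.references) & set(self.decoys)
        if overlap:
            raise ValueError(f"gene {self.name!r}: ids {sorted(overlap)} are both reference and decoy")


@dataclass
class ToolkitDefinition:
    """A named collection of toolkit genes."""

    name: str
    genes: list[ToolkitGeneRef]

    def __post_init__(self) -> None:
        names = [g.name for g in self.genes]
        if len(names) != len(set(names)):
            raise ValueError(f"toolkit {self.name!r} has duplicate gene names")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class PresenceCall:
    """Per-gene screening verdict (the X / - of a presence/absence table)."""

    gene: str
    present: bool
    best_hit_id: str | None
    nearest_label: str | None  # reference/decoy id the candidate is nearest to
    evalue: float | None

    def __post_init__(self) -> None:
        if self.present and self.best_hit_id is None:
            raise ValueError("a present call requires a passing hit")


def screen_gene(
    gene: ToolkitGeneRef, proteome: Proteome, scoring: ScoringScheme
) -> PresenceCall:
    """Screen one toolkit gene against a proteome.

    The candidate is the best hit over all reference queries that passes both
    the E-value threshold and the reference-coverage (full-length) filter.
    The gene is present iff the candidate's nearest neighbor among
    references + decoys is a true reference.
    """
    if len(proteome) == 0:
        logger.warning("screening %s against an empty proteome", gene.name)
        return PresenceCall(gene.name, False, None, None, None)
    total_len = sum(len(r) for r in proteome)
    ref_ids = sorted(gene.references)
    ref_seqs = [gene.references[r] for r in ref_ids]
    records = list(proteome)
    # score-only pass over the whole proteome, then traceback alignments for
    # the few top candidates until one passes the full-length (coverage) filter
    scores = _swkernel.batch_scores(
        [encode(s) for s in ref_seqs],
        [encode(r.sequence) for r in records],
        scoring.padded_matrix,
        scoring.gap_open,
        scoring.gap_extend,
    )
    candidates = []  # (-score, record_id, ref_id)
    for ri, ref_id in enumerate(ref_ids):
        for ci, rec in enumerate(records):
            s = int(scores[ri, ci])
            if s <= 0:
                continue
            ev = estimate_evalue(s, len(ref_seqs[ri]), total_len, scoring)
            if ev < scoring.evalue_threshold:
                candidates.append((-s, rec.id, ref_id, ev))
    best = None
    for neg_score, rec_id, ref_id, ev in sorted(candidates):
        aln = local_align(gene.references[ref_id], proteome[rec_id].sequence, scoring)
        if aln.coverage >= scoring.min_coverage:
            best = (rec_id, ev)
            break
    if best is None:
        return PresenceCall(gene.name, False, None, None, None)
    candidate_id, evalue = best
    candidate_seq = proteome[candidate_id].sequence
    nearest_label = None
    nearest_dist = None
    pool = [(rid, seq, True) for rid, seq in sorted(gene.references.items())]
    pool += [(rid, seq, False) for rid, seq in sorted(gene.decoys.items())]
    nearest_is_ref = False
    for rid, seq, is_ref in pool:
        dist = corrected_alignment_distance(candidate_seq, seq, scoring)
        if nearest_dist is None or dist < nearest_dist:
            nearest_dist, nearest_label, nearest_is_ref = dist, rid, is_ref
    return PresenceCall(gene.name, nearest_is_ref, candidate_id, nearest_label, evalue)


def screen_toolkit(
    toolkit: ToolkitDefinition, proteome: Proteome, scoring: ScoringScheme
) -> list[PresenceCall]:
    """One presence call per toolkit gene, in definition order."""
    return [screen_gene(gene, proteome, scoring) for gene in toolkit.genes]


def decide_sexual_reproduction(
    calls: Iterable[PresenceCall], threshold: int = 6
) -> str:
    """``sexual`` iff the number of present toolkit genes is >= threshold."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    n_present = sum(1 for c in calls if c.present)
    return "sexual" if n_present >= threshold else "asexual"


def presence_matrix(calls_by_species: Mapping[str, list[PresenceCall]]) -> pd.DataFrame:
    """Species x gene table in the conventional X (found) / - (not found) form."""
    data = {
        species: {c.gene: ("X" if c.present else "-") for c in calls}
        for species, calls in calls_by_species.items()
    }
    return pd.DataFrame(data).T


# ---------------------------------------------------------------------------
# Category count tables (flagellar-gene style)
# ---------------------------------------------------------------------------

@dataclass
class CategoryCountTable:
    """Per-category, per-species gene counts (e.g. flagellum substructures)."""

    counts: pd.DataFrame  # index: category, columns: species

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("category counts must be >= 0")

    @classmethod
    def from_dict(cls, data: Mapping[str, Mapping[str, int]]) -> "CategoryCountTable":
        """Build from {category: {species: count}} (row-major)."""
        return cls(pd.DataFrame(data).T.fillna(0).astype(int))

    def species(self) -> list[str]:
        return list(self.counts.columns)


def category_totals(table: CategoryCountTable, species: str) -> int:
    """Total gene count over all categories for one species column."""
    if species not in table.counts.columns:
        raise KeyError(f"unknown species {species!r} in category table")
    return int(table.counts[species].sum())


def motility_ratio(total_a: float, total_b: float) -> float:
    """Ratio of two toolkit totals (e.g. motile vs nonmotile gene counts)."""
    if total_b == 0:
        raise ZeroDivisionError("denominator total is zero")
    return total_a / total_b


# ---------------------------------------------------------------------------
# Toolkit definition I/O (FASTA + TSV)
# ---------------------------------------------------------------------------

def read_toolkit(fasta_path: str | Path, tsv_path: str | Path, *, name: str | None = None) -> ToolkitDefinition:
    """Load a toolkit from a FASTA of sequences plus a TSV of gene metadata.

    The TSV needs columns ``seq_id``, ``gene``, ``is_decoy`` (0/1) and
    optionally ``category``; every seq_id must exist in the FASTA.
    """
    fasta_path, tsv_path = Path(fasta_path), Path(tsv_path)
    pool = read_fasta(fasta_path, species="toolkit")
    rows = list(csv.DictReader(open(tsv_path), delimiter="\t"))
    required = {"seq_id", "gene", "is_decoy"}
    if rows and not required <= set(rows[0]):
        raise ValueError(f"toolkit TSV must have columns {sorted(required)}")
    genes: dict[str, dict] = {}
    for row in rows:
        sid = row["seq_id"]
        if sid not in pool:
            raise ValueError(f"toolkit TSV references unknown sequence id {sid!r}")
        entry = genes.setdefault(
            row["gene"], {"references": {}, "decoys": {}, "category": row.get("category", "")}
        )
        bucket = "decoys" if row["is_decoy"] in ("1", "true", "True") else "references"
        entry[bucket][sid] = pool[sid].sequence
    return ToolkitDefinition(
        name=name or fasta_path.stem,
        genes=[
            ToolkitGeneRef(gname, spec["references"], spec["decoys"], spec["category"])
            for gname, spec in genes.items()
        ],
    )


def write_toolkit(
    toolkit: ToolkitDefinition, fasta_path: str | Path, tsv_path: str | Path
) -> None:
    """Write a toolkit definition as editable FASTA + TSV."""
    from .seqio import ProteinRecord, write_fasta

    pool = Proteome("toolkit")
    rows = []
    for gene in toolkit.genes:
        for sid, seq in gene.references.items():
            pool.add(ProteinRecord(sid, "toolkit", seq))
            rows.append((sid, gene.name, 0, gene.category))
        for sid, seq in gene.decoys.items():
            pool.add(ProteinRecord(sid, "toolkit", seq))
            rows.append((sid, gene.name, 1, gene.category))
    write_fasta(pool, fasta_path)
    with open(tsv_path, "w", newline="\n") as fh:
        fh.write("seq_id\tgene\tis_decoy\tcategory\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
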