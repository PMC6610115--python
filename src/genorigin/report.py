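"""Reporting arithmetic, consistency checks and the pipeline driver.

Printed percentages follow the half-away-from-zero rounding convention
(25.63 -> 26, 87.13 -> 87.1), implemented exactly with decimal arithmetic.
``run_pipeline`` wires the stages together — similarity search, reciprocal
best hits, orthogroups, Venn partition, triplet classification, optional
toolkit screen — and writes TSV/JSON outputs plus a manifest sufficient to
reproduce the run byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import pandas as pd

from . import __version__
from .ancestry import (
    AncestrySummary,
    PatternLabel,
    VennPartition,
    classify_dataset,
    symbiont_evidence_tally,
    venn_partition,
)
from .homology import (
    ScoringScheme,
    best_hits,
    build_orthogroups,
    in_paralog_pairs,
    reciprocal_best_hits,
    score_matrix,
)
from .seqio import PipelineConfig, Proteome, configure_logging, logger, read_fasta
from .simulate import SimulationConfig, simulate_dataset
from .toolkit import decide_sexual_reproduction, read_toolkit, screen_toolkit


def percent(numerator: int, denominator: int, decimals: int = 0) -> float:
    """100 * n / d rounded half-away-from-zero to ``decimals`` places."""
    if denominator <= 0:
        raise ZeroDivisionError("percent needs a positive denominator")
    if numerator < 0:
        raise ValueError("numerator must be >= 0")
    quantum = Decimal(1).scaleb(-decimals)
    value = (Decimal(100) * Decimal(numerator) / Decimal(denominator)).quantize(
        quantum, rounding=ROUND_HALF_UP
    )
    return float(value)


@dataclass(frozen=True)
class FractionReport:
    """A printed percentage with its exact provenance."""

    numerator: int
    denominator: int
    decimals: int = 0

    @property
    def value(self) -> float:
        return percent(self.numerator, self.denominator, self.decimals)


def consistency_check(subject, expected_total: int) -> tuple[bool, list[str]]:
    """Verify the sum identities of a partition or summary; never raises.

    For a :class:`VennPartition`, checks that the four categories sum to the
    focal proteome size; for an :class:`AncestrySummary`, that pattern counts
    plus multi-copy plus unresolved sum to the classified-orthogroup total.
    Returns (all_passed, messages).
    """
    messages = []
    ok = True
    if isinstance(subject, VennPartition):
        total = subject.total
        name = "venn categories sum to proteome size"
    elif isinstance(subject, AncestrySummary):
        total = subject.n_groups
        name = "pattern + multi-copy + unresolved counts sum to group total"
    else:
        return False, [f"FAIL: unsupported object {type(subject).__name__}"]
    if total == expected_total:
        messages.append(f"PASS: {name} ({total} == {expected_total})")
    else:
        ok = False
        messages.append(f"FAIL: {name} ({total} != {expected_total})")
    return ok, messages


@dataclass
class PipelineResult:
    """Everything a run produced, with paths to the written artifacts."""

    venn: VennPartition
    summary: AncestrySummary
    classification: pd.DataFrame
    homolog_fractions: dict[str, float]
    toolkit_calls: list | None
    sexuality_verdict: str | None
    outputs: dict[str, Path]
    checks: list[str]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute search -> orthogroups -> classification (-> toolkit screen).

    Inputs are either the three configured FASTA files or, with
    ``config.simulate``, a dataset generated on the fly from the simulation
    parameters.  All outputs are deterministic for fixed inputs and seed.
    """
    configure_logging(config.log_level)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scoring = ScoringScheme(
        gap_open=config.gap_open,
        gap_extend=config.gap_extend,
        evalue_lambda=config.evalue_lambda,
        evalue_K=config.evalue_K,
        evalue_threshold=config.evalue_threshold,
        min_coverage=config.min_coverage,
    )
    species = (
        config.focal_species,
        config.host_ref_species,
        config.symbiont_ref_species,
    )
    toolkit = None
    if config.simulate:
        sim = simulate_dataset(
            SimulationConfig(
                n_families=config.n_families,
                topology_proportions=config.topology_proportions,
                n_unique=config.n_unique,
                n_multicopy=config.n_multicopy,
                duplication_distance=config.duplication_distance,
                internal_branch=config.internal_branch,
                terminal_branch=config.terminal_branch,
                sequence_length=config.sequence_length,
                master_seed=config.master_seed,
                species=species,
            )
        )
        sim.write(outdir / "simulated_input")
        proteomes = sim.proteomes
    else:
        paths = {
            species[0]: config.focal_fasta,
            species[1]: config.host_ref_fasta,
            species[2]: config.symbiont_ref_fasta,
        }
        for tag, p in paths.items():
            if p is None or not Path(p).exists():
                raise FileNotFoundError(f"input proteome for {tag!r} missing: {p}")
        proteomes = {tag: read_fasta(p, tag) for tag, p in paths.items()}
    if config.toolkit_fasta and config.toolkit_tsv:
        toolkit = read_toolkit(config.toolkit_fasta, config.toolkit_tsv)

    sn, sa, sp = species
    focal, host, symb = proteomes[sn], proteomes[sa], proteomes[sp]

    logger.info("search: scoring %s vs %s", sn, sa)
    scores_na = score_matrix(focal, host, scoring)
    logger.info("search: scoring %s vs %s", sn, sp)
    scores_np = score_matrix(focal, symb, scoring)
    logger.info("search: scoring %s vs %s", sa, sp)
    scores_ap = score_matrix(host, symb, scoring)
    logger.info("search: scoring %s vs itself (in-paralogs)", sn)
    scores_nn = score_matrix(focal, focal, scoring)

    hits_na = best_hits(focal, host, scoring, scores=scores_na)
    hits_np = best_hits(focal, symb, scoring, scores=scores_np)
    rbh_na = reciprocal_best_hits(focal, host, scoring, scores=scores_na)
    rbh_np = reciprocal_best_hits(focal, symb, scoring, scores=scores_np)
    rbh_ap = reciprocal_best_hits(host, symb, scoring, scores=scores_ap)
    cross_best: dict[str, float] = {}
    for hits in (hits_na, hits_np):
        for rid, hit in hits.items():
            cross_best[rid] = max(cross_best.get(rid, 0.0), hit.score)
    paralogs = in_paralog_pairs(
        focal, scoring, scores=scores_nn, cross_best=cross_best
    )

    venn = venn_partition(focal, hits_na, hits_np)
    fractions = {
        sa: 100.0 * len(hits_na) / len(focal),
        sp: 100.0 * len(hits_np) / len(focal),
    }

    groups = build_orthogroups(
        rbh_na, rbh_np, rbh_ap, species=species, within={sn: paralogs}
    )
    triplet_groups = [g for g in groups if set(g.species_present) >= set(species)]
    summary, table = classify_dataset(
        triplet_groups,
        proteomes,
        scoring,
        correction=config.poisson_correction,
        tolerance=config.tie_tolerance,
        species=species,
    )
    host_n, symb_n, verdict = symbiont_evidence_tally(summary)

    checks = []
    for obj, expected in ((venn, len(focal)), (summary, len(triplet_groups))):
        ok, msgs = consistency_check(obj, expected)
        checks.extend(msgs)
        if not ok:
            logger.error("consistency check failed: %s", msgs)

    toolkit_calls = None
    sexuality = None
    if toolkit is not None:
        toolkit_calls = screen_toolkit(toolkit, focal, scoring)
        sexuality = decide_sexual_reproduction(
            toolkit_calls, config.sexuality_threshold
        )

    outputs: dict[str, Path] = {}

    hit_rows = [
        (h.query_id, h.subject_id, ref, h.score, h.evalue)
        for ref, hits in ((sa, hits_na), (sp, hits_np))
        for h in hits.values()
    ]
    hits_path = outdir / "best_hits.tsv"
    pd.DataFrame(
        hit_rows, columns=["query", "subject", "reference_species", "score", "evalue"]
    ).to_csv(hits_path, sep="\t", index=False)
    outputs["best_hits"] = hits_path

    og_rows = [
        (g.group_id, spec, mid, g.single_copy)
        for g in groups
        for spec in species
        for mid in g.members.get(spec, [])
    ]
    og_path = outdir / "orthogroups.tsv"
    pd.DataFrame(
        og_rows, columns=["group_id", "species", "member_id", "single_copy"]
    ).to_csv(og_path, sep="\t", index=False)
    outputs["orthogroups"] = og_path

    cls_path = outdir / "classification.tsv"
    table.to_csv(cls_path, sep="\t", index=False, float_format="%.6f")
    outputs["classification"] = cls_path

    n_classified = summary.n_groups
    summary_payload = {
        "venn": {
            "unique": venn.n_unique,
            "only_host_ref": venn.n_only_host,
            "only_symbiont_ref": venn.n_only_symbiont,
            "both": venn.n_both,
            "total": venn.total,
        },
        "homolog_fraction_percent": fractions,
        "pattern_counts": {k.value: v for k, v in summary.counts.items()},
        "pattern_percent_of_classified": {
            k.value: percent(v, n_classified) if n_classified else 0.0
            for k, v in summary.counts.items()
        },
        "host_evidence": host_n,
        "symbiont_evidence": symb_n,
        "verdict": verdict,
        "sexuality_verdict": sexuality,
        "consistency": checks,
    }
    summary_path = outdir / "summary.json"
    summary_path.write_text(json.dumps(summary_payload, indent=2, sort_keys=True) + "\n")
    outputs["summary"] = summary_path

    if toolkit_calls is not None:
        tk_path = outdir / "toolkit_calls.tsv"
        pd.DataFrame(
            [
                (c.gene, "X" if c.present else "-", c.best_hit_id or "", c.nearest_label or "",
                 "" if c.evalue is None else f"{c.evalue:.3e}")
                for c in toolkit_calls
            ],
            columns=["gene", "found", "best_hit", "nearest_reference", "evalue"],
        ).to_csv(tk_path, sep="\t", index=False)
        outputs["toolkit_calls"] = tk_path

    manifest = {
        "genorigin_version": __version__,
        "python": platform.python_version(),
        "master_seed": config.master_seed,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in vars(config).items()
        },
        "output_sha256": {name: _sha256(p) for name, p in sorted(outputs.items())},
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    outputs["manifest"] = manifest_path

    return PipelineResult(
        venn=venn,
        summary=summary,
        classification=table,
        homolog_fractions=fractions,
        toolkit_calls=toolkit_calls,
        sexuality_verdict=sexuality,
        outputs=outputs,
        checks=checks,
    )
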