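"""Synthetic proteomes with known gene histories.

Generates three species proteomes — a focal species N, a host-lineage
reference A and a symbiont-lineage reference P — as a mixture of:

* single-copy triplet families whose gene tree has one of three topologies
  (sister pair NA, NP or AP, with the third species as outgroup),
* species-unique genes (fresh random sequences with no homolog anywhere),
* multi-copy families carrying an extra within-focal-species duplicate,
* optional toolkit genes with decoy paralogs for presence/absence screens.

Sequence evolution is a 20-state uniform (Jukes-Cantor-type) substitution
process: each site evolves independently and the replacement letter is
uniform over the other 19 residues.  Branch lengths are expected
substitutions per site, so the expected proportion of differing sites after a
total path length t is ``(19/20) * (1 - exp(-20 t / 19))`` — the closed form
used to validate the simulator.  There is no rate heterogeneity and no
indels: real proteomes are messier, and passing recovery tests here shows the
pipeline's logic is sound, not that real data are this clean.

Seed discipline: every family draws its own generator from
``SeedSequence(master_seed, spawn_key=(domain, index))`` where ``domain``
numbers the record classes (0 = triplet families, 1 = unique genes,
2 = multi-copy families, 3 = toolkit genes).  Fixed master seed gives
byte-identical FASTA output; changing it changes sequences but never counts.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .distances import expected_p_distance, poisson_correct  # noqa: F401  (module surface)
from .seqio import AMINO_ACIDS, Proteome, ProteinRecord, write_fasta
from .toolkit import ToolkitDefinition, ToolkitGeneRef

#: triplet topology labels: which species pair is sister
TOPOLOGY_LABELS = ("NA", "NP", "AP")


@dataclass(frozen=True)
class TripletTopology:
    """One of the three resolved rooted triplet shapes.

    The sister taxa diverge from a common ancestor reached after
    ``internal_branch`` substitutions/site from the root; each of the three
    tips then accrues ``terminal_branch`` substitutions/site (the outgroup
    hangs directly off the root).
    """

    label: str
    internal_branch: float = 0.3
    terminal_branch: float = 0.3

    def __post_init__(self) -> None:
        if self.label not in TOPOLOGY_LABELS:
            raise ValueError(f"topology label must be one of {TOPOLOGY_LABELS}")
        if self.internal_branch < 0 or self.terminal_branch < 0:
            raise ValueError("branch lengths must be >= 0")


@dataclass(frozen=True)
class ToolkitGeneSpec:
    """Ground-truth plan for one simulated toolkit gene.

    status:
        ``present``     — a homolog of the true gene is in the focal proteome;
        ``decoy_only``  — only a homolog of the decoy paralog is present
                          (the Rec8/Rad21 situation: a hit exists but its
                          nearest reference is the decoy);
        ``absent``      — no homolog at all.
    """

    name: str
    status: str = "present"
    decoy: str | None = None
    decoy_distance: float = 1.0
    category: str = "meiosis"

    def __post_init__(self) -> None:
        if self.status not in ("present", "decoy_only", "absent"):
            raise ValueError("status must be present, decoy_only or absent")
        if self.status == "decoy_only" and self.decoy is None:
            raise ValueError(f"gene {self.name}: decoy_only requires a decoy name")
        if self.decoy_distance < 0:
            raise ValueError("decoy_distance must be >= 0")


@dataclass
class SimulationConfig:
    """Generative parameters; defaults are the package's standard conditions."""

    n_families: int = 1000
    topology_proportions: tuple[float, float, float] = (0.26, 0.26, 0.48)
    n_unique: int = 50
    n_multicopy: int = 50
    duplication_distance: float = 0.5
    internal_branch: float = 0.3
    terminal_branch: float = 0.3
    sequence_length: int = 300
    master_seed: int = 1
    species: tuple[str, str, str] = ("N", "A", "P")
    toolkit_spec: tuple[ToolkitGeneSpec, ...] = ()
    toolkit_target_distance: float = 0.2

    def __post_init__(self) -> None:
        if min(self.n_families, self.n_unique, self.n_multicopy) < 0:
            raise ValueError("counts must be >= 0")
        if self.sequence_length < 0:
            raise ValueError("sequence_length must be >= 0")
        props = tuple(float(p) for p in self.topology_proportions)
        if len(props) != 3 or any(p < 0 for p in props) or abs(sum(props) - 1) > 1e-9:
            raise ValueError("topology_proportions must be 3 fractions summing to 1")
        self.topology_proportions = props


@dataclass
class SimulatedDataset:
    """Proteomes plus ground truth for every simulated record."""

    proteomes: dict[str, Proteome]
    truth: pd.DataFrame  # columns: family_id, label, species, member_id
    toolkit: ToolkitDefinition | None
    toolkit_truth: pd.DataFrame | None
    config: SimulationConfig

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write FASTA per species, truth TSV and a config echo; deterministic."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        for tag, proteome in self.proteomes.items():
            paths[tag] = write_fasta(proteome, outdir / f"{tag}.faa")
        truth_path = outdir / "truth.tsv"
        self.truth.to_csv(truth_path, sep="\t", index=False)
        paths["truth"] = truth_path
        echo = asdict(self.config)
        echo["toolkit_spec"] = [asdict(s) for s in self.config.toolkit_spec]
        cfg_path = outdir / "simulation_config.json"
        cfg_path.write_text(json.dumps(echo, indent=2, sort_keys=True) + "\n")
        paths["config"] = cfg_path
        return paths


def _rng(master_seed: int, domain: int, index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=master_seed, spawn_key=(domain, index))
    )


def sample_root_sequence(length: int, seed) -> str:
    """I.i.d. uniform sequence over the 20 canonical amino acids."""
    if length < 0:
        raise ValueError("length must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = rng.integers(0, 20, size=length)
    return "".join(AMINO_ACIDS[i] for i in idx)


def evolve_sequence(sequence: str, branch_length: float, seed) -> str:
    """Evolve a sequence along a branch under the 20-state uniform model.

    Implemented by direct draws from the exact transition distribution: with
    probability ``exp(-20 t / 19)`` a site keeps its residue through ancestry;
    otherwise it is redrawn uniformly over all 20 residues (which may
    re-select the original — multiple hits).  Expected substitutions/site
    equal ``branch_length``.
    """
    if branch_length < 0:
        raise ValueError("branch_length must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = len(sequence)
    if n == 0 or branch_length == 0:
        return sequence
    keep = math.exp(-20.0 * branch_length / 19.0)
    redraw = rng.random(n) >= keep
    if not redraw.any():
        return sequence
    new = rng.integers(0, 20, size=n)
    out = list(sequence)
    for i in np.flatnonzero(redraw):
        out[i] = AMINO_ACIDS[new[i]]
    return "".join(out)


def allocate_counts(n: int, proportions: Sequence[float]) -> list[int]:
    """Largest-remainder allocation of n items to proportions (deterministic).

    Ties in fractional remainder are broken by category order.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    quotas = [p * n for p in proportions]
    counts = [int(math.floor(q)) for q in quotas]
    short = n - sum(counts)
    remainders = sorted(
        range(len(proportions)), key=lambda i: (-(quotas[i] - counts[i]), i)
    )
    for i in remainders[:short]:
        counts[i] += 1
    return counts


def _simulate_family(
    label: str, config: SimulationConfig, rng: np.random.Generator
) -> dict[str, str]:
    """Sequences for one triplet family: root -> internal -> terminals."""
    sn, sa, sp = config.species
    root = sample_root_sequence(config.sequence_length, rng)
    ancestor = evolve_sequence(root, config.internal_branch, rng)
    sisters = {"NA": (sn, sa), "NP": (sn, sp), "AP": (sa, sp)}[label]
    out = {}
    for tag in config.species:
        parent = ancestor if tag in sisters else root
        out[tag] = evolve_sequence(parent, config.terminal_branch, rng)
    return out


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate the three proteomes and the ground-truth table."""
    sn, sa, sp = config.species
    proteomes = {tag: Proteome(tag) for tag in config.species}
    truth_rows: list[tuple[str, str, str, str]] = []

    counts = allocate_counts(config.n_families, config.topology_proportions)
    labels = [
        lab for lab, c in zip(TOPOLOGY_LABELS, counts) for _ in range(c)
    ]
    for i, label in enumerate(labels):
        rng = _rng(config.master_seed, 0, i)
        fam = f"fam{i:05d}"
        for tag, seq in _simulate_family(label, config, rng).items():
            rid = f"{tag}_{fam}"
            proteomes[tag].add(ProteinRecord(rid, tag, seq))
            truth_rows.append((fam, label, tag, rid))

    for u in range(config.n_unique * 3):
        tag = config.species[u % 3]
        rng = _rng(config.master_seed, 1, u)
        rid = f"{tag}_uni{u // 3:04d}"
        proteomes[tag].add(
            ProteinRecord(rid, tag, sample_root_sequence(config.sequence_length, rng))
        )
        truth_rows.append((f"uni{u:05d}", "UNIQUE", tag, rid))

    for m in range(config.n_multicopy):
        rng = _rng(config.master_seed, 2, m)
        fam = f"mul{m:05d}"
        label = TOPOLOGY_LABELS[m % 3]
        seqs = _simulate_family(label, config, rng)
        for tag, seq in seqs.items():
            rid = f"{tag}_{fam}"
            proteomes[tag].add(ProteinRecord(rid, tag, seq))
            truth_rows.append((fam, "MULTI", tag, rid))
        dup = evolve_sequence(seqs[sn], config.duplication_distance, rng)
        dup_id = f"{sn}_{fam}b"
        proteomes[sn].add(ProteinRecord(dup_id, sn, dup))
        truth_rows.append((fam, "MULTI", sn, dup_id))

    toolkit = None
    toolkit_truth = None
    if config.toolkit_spec:
        toolkit, tk_rows = _simulate_toolkit(config, proteomes[sn])
        toolkit_truth = pd.DataFrame(
            tk_rows, columns=["gene", "status", "target_id", "expected_present"]
        )

    truth = pd.DataFrame(
        truth_rows, columns=["family_id", "label", "species", "member_id"]
    )
    return SimulatedDataset(proteomes, truth, toolkit, toolkit_truth, config)


def _simulate_toolkit(
    config: SimulationConfig, focal: Proteome
) -> tuple[ToolkitDefinition, list[tuple]]:
    """Toolkit references/decoys plus planted focal-proteome homologs."""
    genes = []
    rows = []
    for g, spec in enumerate(config.toolkit_spec):
        rng = _rng(config.master_seed, 3, g)
        ref_seq = sample_root_sequence(config.sequence_length, rng)
        decoys = {}
        decoy_seq = None
        if spec.decoy is not None:
            decoy_seq = evolve_sequence(ref_seq, spec.decoy_distance, rng)
            decoys[f"DECOY_{spec.decoy}"] = decoy_seq
        genes.append(
            ToolkitGeneRef(
                name=spec.name,
                references={f"REF_{spec.name}": ref_seq},
                decoys=decoys,
                category=spec.category,
            )
        )
        target_id = ""
        if spec.status == "present":
            target_id = f"N_tk_{spec.name}"
            seq = evolve_sequence(ref_seq, config.toolkit_target_distance, rng)
            focal.add(ProteinRecord(target_id, focal.species, seq))
        elif spec.status == "decoy_only":
            target_id = f"N_tk_{spec.decoy}like"
            seq = evolve_sequence(decoy_seq, config.toolkit_target_distance, rng)
            focal.add(ProteinRecord(target_id, focal.species, seq))
        rows.append((spec.name, spec.status, target_id, spec.status == "present"))
    return ToolkitDefinition(name="simulated", genes=genes), rows


#: Table-style plan mirroring a meiosis detection toolkit: eight
#: meiosis-specific genes screened directly plus Rec8, whose only focal
#: homolog is nearer the mitotic cohesin paralog Rad21 (a decoy).
MEIOSIS_TOOLKIT_PLAN: tuple[ToolkitGeneSpec, ...] = (
    ToolkitGeneSpec("Spo11-2", "present"),
    ToolkitGeneSpec("Mer3", "present"),
    ToolkitGeneSpec("Hop1", "absent"),
    ToolkitGeneSpec("Dmc1", "absent"),
    ToolkitGeneSpec("Hop2", "present"),
    ToolkitGeneSpec("Mnd1", "absent"),
    ToolkitGeneSpec("Msh4", "present"),
    ToolkitGeneSpec("Msh5", "present"),
    ToolkitGeneSpec("Rec8", "decoy_only", decoy="Rad21", decoy_distance=1.0),
)
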