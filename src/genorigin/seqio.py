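"""Proteome I/O and pipeline configuration.

Protein sets are held as :class:`Proteome` objects (ordered collections of
:class:`ProteinRecord`), one per species.  Sequences are restricted to the 20
canonical amino-acid letters plus ``X`` (unknown residue).  The species tag is
always supplied by the caller (or the configuration file), never parsed from
FASTA headers, because header conventions vary wildly between proteome
releases.
"""

from __future__ import annotations

import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO

logger = logging.getLogger("genorigin")

#: The 20 canonical amino acids, alphabetical by one-letter code.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: Legal residue alphabet for stored sequences.
ALPHABET = AMINO_ACIDS + "X"
_ALPHABET_SET = frozenset(ALPHABET)


class FastaLoadError(ValueError):
    """Raised when a FASTA file violates the proteome contract."""


@dataclass(frozen=True)
class ProteinRecord:
    """A single protein sequence with its species tag.

    ``id`` must be a non-empty whitespace-free token, unique within its
    proteome.  ``sequence`` is uppercase over ``ACDEFGHIKLMNPQRSTVWYX``.
    """

    id: str
    species: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ValueError(f"record id must be a non-empty token, got {self.id!r}")
        bad = set(self.sequence) - _ALPHABET_SET
        if bad:
            raise ValueError(
                f"record {self.id!r}: illegal characters {sorted(bad)} "
                f"(alphabet is the 20 canonical amino acids plus 'X')"
            )

    def __len__(self) -> int:
        return len(self.sequence)


class Proteome:
    """Ordered, id-indexed collection of :class:`ProteinRecord` for one species."""

    def __init__(self, species: str, records: Iterable[ProteinRecord] = ()) -> None:
        self.species = species
        self._records: list[ProteinRecord] = []
        self._index: dict[str, int] = {}
        for rec in records:
            self.add(rec)

    def add(self, record: ProteinRecord) -> None:
        if record.species != self.species:
            raise ValueError(
                f"record {record.id!r} is tagged {record.species!r}, "
                f"proteome is {self.species!r}"
            )
        if record.id in self._index:
            raise ValueError(f"duplicate record id {record.id!r} in proteome {self.species!r}")
        self._index[record.id] = len(self._records)
        self._records.append(record)

    def __iter__(self) -> Iterator[ProteinRecord]:
        return iter(self._records)

    def __len__(self) -> int:
        return len(self._records)

    def __contains__(self, record_id: str) -> bool:
        return record_id in self._index

    def __getitem__(self, record_id: str) -> ProteinRecord:
        return self._records[self._index[record_id]]

    def ids(self) -> list[str]:
        return [r.id for r in self._records]

    def sequences(self) -> list[str]:
        return [r.sequence for r in self._records]

    def __repr__(self) -> str:
        return f"Proteome(species={self.species!r}, n={len(self)})"


def read_fasta(path: str | Path, species: str, *, nonstandard: str = "reject") -> Proteome:
    """Load a protein FASTA file into a :class:`Proteome`.

    The record id is the first whitespace-delimited header token; the rest of
    the header (description) is ignored.  Sequences are uppercased.  ``*`` is
    stripped from sequence ends (a common artifact of gene-model translation)
    but rejected internally.  Selenocysteine/pyrrolysine letters ``U``/``O``
    are rejected by default or masked to ``X`` with ``nonstandard="mask"``.
    """
    path = Path(path)
    if nonstandard not in ("reject", "mask"):
        raise ValueError("nonstandard must be 'reject' or 'mask'")
    proteome = Proteome(species)
    n = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        n += 1
        rid = rec.id
        if not rid:
            raise FastaLoadError(f"{path}: record {n} has an empty header")
        seq = str(rec.seq).upper().rstrip("*")
        if "*" in seq:
            raise FastaLoadError(f"{path}: record {rid!r} has an internal stop codon '*'")
        if nonstandard == "mask":
            seq = seq.replace("U", "X").replace("O", "X")
        bad = set(seq) - _ALPHABET_SET
        if bad:
            raise FastaLoadError(
                f"{path}: record {rid!r} has illegal characters {sorted(bad)}"
            )
        try:
            proteome.add(ProteinRecord(rid, species, seq))
        except ValueError as exc:
            raise FastaLoadError(f"{path}: {exc}") from exc
    if len(proteome) == 0:
        logger.warning("FASTA file %s contained no records", path)
    return proteome


def write_fasta(proteome: Proteome, path: str | Path, *, width: int = 60) -> Path:
    """Write a proteome as 60-column-wrapped FASTA; byte-deterministic."""
    path = Path(path)
    with open(path, "w", newline="\n") as fh:
        for rec in proteome:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")
    return path


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

def _check_range(name: str, value, lo=None, hi=None) -> None:
    if lo is not None and value < lo:
        raise ValueError(f"config field {name}={value} below minimum {lo}")
    if hi is not None and value > hi:
        raise ValueError(f"config field {name}={value} above maximum {hi}")


@dataclass
class PipelineConfig:
    """Validated run configuration (TOML-backed).

    Groups the scoring parameters, search thresholds, classification options,
    simulation parameters and output paths used by :func:`genorigin.report.run_pipeline`.
    """

    # inputs (either three FASTA paths, or simulate=True)
    focal_fasta: str | None = None
    host_ref_fasta: str | None = None
    symbiont_ref_fasta: str | None = None
    focal_species: str = "focal"
    host_ref_species: str = "hostref"
    symbiont_ref_species: str = "symref"
    simulate: bool = False

    # scoring / search
    gap_open: int = 11
    gap_extend: int = 1
    evalue_lambda: float = 0.267
    evalue_K: float = 0.041
    evalue_threshold: float = 1e-5
    min_coverage: float = 0.7

    # classification
    poisson_correction: bool = False
    tie_tolerance: float = 1e-12

    # simulation
    n_families: int = 1000
    topology_proportions: tuple[float, float, float] = (0.26, 0.26, 0.48)
    n_unique: int = 50
    n_multicopy: int = 50
    duplication_distance: float = 0.5
    terminal_branch: float = 0.3
    internal_branch: float = 0.3
    sequence_length: int = 300

    # toolkit screening
    toolkit_fasta: str | None = None
    toolkit_tsv: str | None = None
    sexuality_threshold: int = 6

    # output
    outdir: str = "genorigin_out"
    master_seed: int = 1
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        _check_range("gap_open", self.gap_open, 1)
        _check_range("gap_extend", self.gap_extend, 1)
        if self.gap_open < self.gap_extend:
            raise ValueError("gap_open must be >= gap_extend")
        _check_range("evalue_lambda", self.evalue_lambda, 1e-9)
        _check_range("evalue_K", self.evalue_K, 1e-12)
        _check_range("evalue_threshold", self.evalue_threshold, 0.0)
        if self.evalue_threshold <= 0:
            raise ValueError("evalue_threshold must be > 0")
        _check_range("min_coverage", self.min_coverage, 0.0, 1.0)
        _check_range("tie_tolerance", self.tie_tolerance, 0.0)
        _check_range("n_families", self.n_families, 0)
        _check_range("n_unique", self.n_unique, 0)
        _check_range("n_multicopy", self.n_multicopy, 0)
        _check_range("duplication_distance", self.duplication_distance, 0.0)
        _check_range("terminal_branch", self.terminal_branch, 0.0)
        _check_range("internal_branch", self.internal_branch, 0.0)
        _check_range("sequence_length", self.sequence_length, 0)
        _check_range("sexuality_threshold", self.sexuality_threshold, 0)
        props = tuple(float(p) for p in self.topology_proportions)
        if len(props) != 3 or any(p < 0 for p in props) or abs(sum(props) - 1.0) > 1e-9:
            raise ValueError("topology_proportions must be three fractions summing to 1")
        self.topology_proportions = props

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        flat: dict = {}
        for key, value in data.items():
            if isinstance(value, dict):
                flat.update(value)
            else:
                flat[key] = value
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(flat) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "topology_proportions" in flat:
            flat["topology_proportions"] = tuple(flat["topology_proportions"])
        return cls(**flat)


def configure_logging(level: str = "INFO") -> None:
    """Route package logs to standard error with the requested level."""
    handler = logging.StreamHandler()
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(getattr(logging, level.upper()))
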