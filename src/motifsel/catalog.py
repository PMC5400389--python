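"""Building motif catalogs from RBP motif definitions.

RNA-binding proteins (RBPs) are described in the source databases either by
IUPAC consensus strings or by position weight/score matrices.  This module
expands those descriptions into sets of unambiguous DNA k-mers (one
:class:`MotifSet` per RBP), applies the standard filters (length 5-12 after
trimming fully ambiguous terminal bases, rejection of variable-length
parenthesised consensuses) and assembles a :class:`MotifCatalog` with a
pooled, de-duplicated motif list.

The working alphabet is DNA; U is converted to T on ingestion because the
scanners operate on coding DNA sequences.
"""

from __future__ import annotations

import csv
from collections import defaultdict
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path
from typing import Iterable, Mapping, Sequence

IUPAC: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "U": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

# reverse lookup: base set -> IUPAC symbol (DNA letters only)
_SET_TO_IUPAC = {v: k for k, v in IUPAC.items() if k != "U"}

MIN_MOTIF_LEN = 5
MAX_MOTIF_LEN = 12
EXPANSION_CAP = 65536

MATRIX_THRESHOLDS = {"pwm": 0.0, "pssm": 0.25}


class MotifError(ValueError):
    """Problem parsing or converting a motif definition."""


class VariableLengthConsensusError(MotifError):
    """Consensus contains parentheses, signifying variable motif length."""


@dataclass(frozen=True)
class ConsensusRecord:
    rbp_id: str
    consensus: str
    source_kind: str = "consensus"  # consensus | pwm | pssm

    def __post_init__(self):
        if not self.consensus:
            raise MotifError(f"{self.rbp_id}: empty consensus")


@dataclass(frozen=True)
class WeightMatrix:
    rbp_id: str
    values: tuple[tuple[float, float, float, float], ...]  # rows: positions; cols A,C,G,T
    kind: str = "pwm"

    def __post_init__(self):
        if self.kind not in MATRIX_THRESHOLDS:
            raise MotifError(f"{self.rbp_id}: unknown matrix kind {self.kind!r}")
        for row in self.values:
            if len(row) != 4:
                raise MotifError(f"{self.rbp_id}: matrix rows must have 4 values")


@dataclass
class MotifSet:
    """The unambiguous k-mers associated with one RBP."""

    rbp_id: str
    motifs: frozenset[str]
    unsimulatable: bool = False
    notes: str = ""

    def __len__(self) -> int:
        return len(self.motifs)

    def lengths(self) -> list[int]:
        return sorted(len(m) for m in self.motifs)


@dataclass
class MotifCatalog:
    sets: dict[str, MotifSet] = field(default_factory=dict)

    @property
    def pooled(self) -> list[str]:
        """Union of all motifs across sets, duplicates collapsed, sorted."""
        return sorted(set().union(*(s.motifs for s in self.sets.values()))) if self.sets else []

    def __len__(self) -> int:
        return len(self.sets)


def parse_consensus(consensus: str) -> frozenset[str]:
    """Expand an IUPAC consensus into all matching unambiguous DNA motifs.

    Fully ambiguous (N) bases at the very beginning or end are trimmed before
    expansion.  Parenthesised (variable-length) consensuses are rejected.
    """
    s = consensus.strip().upper()
    if "(" in s or ")" in s:
        raise VariableLengthConsensusError(
            f"variable-length consensus rejected: {consensus!r}"
        )
    for sym in s:
        if sym not in IUPAC:
            raise MotifError(f"unknown IUPAC symbol {sym!r} in {consensus!r}")
    s = s.strip("N")
    if not s:
        return frozenset()
    n_expansions = 1
    for sym in s:
        n_expansions *= len(IUPAC[sym])
        if n_expansions > EXPANSION_CAP:
            raise MotifError(
                f"consensus {consensus!r} expands to more than {EXPANSION_CAP} motifs"
            )
    return frozenset("".join(p) for p in product(*(sorted(IUPAC[sym]) for sym in s)))


def matrix_to_consensus(matrix: WeightMatrix) -> str:
    """Convert a weight matrix to an IUPAC consensus string.

    Each position becomes the IUPAC symbol for the bases whose value strictly
    exceeds the kind's threshold (0 for PWMs, 0.25 for PSSMs).
    """
    threshold = MATRIX_THRESHOLDS[matrix.kind]
    out = []
    for pos, row in enumerate(matrix.values):
        bases = frozenset(b for b, v in zip("ACGT", row) if v > threshold)
        if not bases:
            raise MotifError(
                f"{matrix.rbp_id}: no base above threshold {threshold} at position {pos}"
            )
        out.append(_SET_TO_IUPAC[bases])
    return "".join(out)


def _length_ok(motif: str) -> bool:
    return MIN_MOTIF_LEN <= len(motif) <= MAX_MOTIF_LEN


def _is_unsimulatable(motifs: frozenset[str]) -> bool:
    """Detect sets for which dinucleotide-matched simulants cannot exist.

    A set is flagged when, for every motif length it contains, it already
    holds *every* string of that length over its base alphabet: any simulant
    assembled from the set's dinucleotides would then coincide with a real
    motif.  This covers homopolymer consensuses (e.g. AAAAAAA) and fully
    degenerate two-letter consensuses (e.g. WWWWWW).
    """
    if not motifs:
        return False
    alphabet = sorted(set("".join(motifs)))
    by_len = defaultdict(set)
    for m in motifs:
        by_len[len(m)].add(m)
    for k, ms in by_len.items():
        total = len(alphabet) ** k
        if total > EXPANSION_CAP or len(ms) < total:
            return False
    return True


def normalize_and_filter(motifs: Iterable[str]) -> tuple[frozenset[str], bool]:
    """Length-filter an expanded motif collection and flag un-simulatable sets.

    Returns ``(kept_motifs, unsimulatable)``.  Motifs shorter than 5 or longer
    than 12 bases are dropped; the flag marks sets whose dinucleotide
    composition cannot be matched by simulants (these are kept but must be
    excluded from simulant-based statistics).
    """
    kept = frozenset(m for m in motifs if _length_ok(m))
    return kept, _is_unsimulatable(kept)


def build_motif_sets(
    records: Sequence[ConsensusRecord | WeightMatrix],
    id_map: Mapping[str, str] | Iterable[tuple[str, str]] | None = None,
    exclusions: Iterable[str] = (),
) -> MotifCatalog:
    """Expand, filter and merge motif definitions into a catalog.

    ``id_map`` maps source identifiers to canonical symbols; definitions whose
    identifiers map to the same symbol are merged by motif union.  A source
    identifier mapped to two different canonical symbols is an error.
    Identifiers in ``exclusions`` (canonical or source form) are dropped.
    """
    if id_map is None:
        canonical: dict[str, str] = {}
    elif isinstance(id_map, Mapping):
        canonical = dict(id_map)
    else:
        canonical = {}
        for src, dst in id_map:
            if src in canonical and canonical[src] != dst:
                raise MotifError(
                    f"identifier {src!r} mapped to both {canonical[src]!r} and {dst!r}"
                )
            canonical[src] = dst
    excluded = set(exclusions)

    merged: dict[str, set[str]] = defaultdict(set)
    for rec in records:
        if isinstance(rec, WeightMatrix):
            consensus = matrix_to_consensus(rec)
        else:
            consensus = rec.consensus
        try:
            expanded = parse_consensus(consensus)
        except VariableLengthConsensusError:
            continue
        rbp = canonical.get(rec.rbp_id, rec.rbp_id)
        if rbp in excluded or rec.rbp_id in excluded:
            continue
        merged[rbp].update(expanded)

    catalog = MotifCatalog()
    for rbp, motifs in sorted(merged.items()):
        kept, flag = normalize_and_filter(motifs)
        if not kept:
            continue
        catalog.sets[rbp] = MotifSet(rbp_id=rbp, motifs=kept, unsimulatable=flag)
    return catalog


def pool_motifs(catalog: MotifCatalog) -> list[str]:
    """Pooled unique motif list (sorted)."""
    return catalog.pooled


# ---------------------------------------------------------------------------
# plain-text I/O


def read_consensus_tsv(path: str | Path) -> list[ConsensusRecord]:
    """Read ``rbp_id<TAB>consensus`` records (lines starting with # skipped)."""
    records = []
    with open(path) as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            records.append(ConsensusRecord(rbp_id=row[0], consensus=row[1]))
    return records


def read_matrix_tsv(path: str | Path, rbp_id: str | None = None, kind: str = "pwm") -> WeightMatrix:
    """Read one weight matrix: one row per position, 4 columns (A C G T)."""
    rows = []
    with open(path) as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            rows.append(tuple(float(v) for v in row[:4]))
    name = rbp_id or Path(path).stem
    return WeightMatrix(rbp_id=name, values=tuple(rows), kind=kind)


def write_catalog_tsv(catalog: MotifCatalog, path: str | Path) -> None:
    """Write ``rbp_id<TAB>motif``, one row per expanded motif."""
    with open(path, "w") as fh:
        for rbp in sorted(catalog.sets):
            for m in sorted(catalog.sets[rbp].motifs):
                fh.write(f"{rbp}\t{m}\n")


def read_catalog_tsv(path: str | Path) -> MotifCatalog:
    merged: dict[str, set[str]] = defaultdict(set)
    with open(path) as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            merged[row[0]].add(row[1].upper().replace("U", "T"))
    catalog = MotifCatalog()
    for rbp, motifs in sorted(merged.items()):
        kept, flag = normalize_and_filter(motifs)
        catalog.sets[rbp] = MotifSet(rbp_id=rbp, motifs=kept or frozenset(motifs), unsimulatable=flag)
    return catalog
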