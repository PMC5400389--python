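"""Nucleotide-controlled null motif sets.

The null model against which motif enrichment and conservation are judged is
a collection of *simulant* motif sets: random motif sets matched to the real
set in motif number, motif lengths and (approximately) dinucleotide
composition.  Each real motif is decomposed into dinucleotides in both
phases; simulant motifs are reassembled by sampling dinucleotides with
replacement from the pooled multiset, with a single extra base drawn from
the set's mononucleotide composition when the length is odd.

Rejection constraints mirror the construction of the real sets: simulants
may not coincide with a real motif, may not contain a mononucleotide run
longer than the longest run of that base in the real set, must be unique
within their set, and may optionally be required to avoid given substrings
(e.g. the stop codons TAA/TGA/TAG).

A second, weaker control — *random motifs* — draws bases i.i.d. from
genome-wide mononucleotide frequencies.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .catalog import MotifSet

STOP_CODONS = ("TAA", "TGA", "TAG")


class SimulantError(RuntimeError):
    """Simulant generation failed within the attempt budget."""


@dataclass
class DinucleotidePool:
    """Dinucleotide multiset of a motif set plus its mononucleotide table."""

    dinucleotides: Counter
    mono_freqs: dict[str, float]

    def __post_init__(self):
        if not self.dinucleotides:
            raise ValueError("empty dinucleotide pool")
        self._dinucs = sorted(self.dinucleotides)
        counts = np.array([self.dinucleotides[d] for d in self._dinucs], dtype=float)
        self._dinuc_p = counts / counts.sum()
        self._bases = sorted(self.mono_freqs)
        p = np.array([self.mono_freqs[b] for b in self._bases], dtype=float)
        self._mono_p = p / p.sum()

    def sample_dinucs(self, n: int, rng: np.random.Generator) -> list[str]:
        idx = rng.choice(len(self._dinucs), size=n, p=self._dinuc_p)
        return [self._dinucs[i] for i in idx]

    def sample_base(self, rng: np.random.Generator) -> str:
        return self._bases[rng.choice(len(self._bases), p=self._mono_p)]

    def frequencies(self) -> dict[str, float]:
        total = sum(self.dinucleotides.values())
        return {d: c / total for d, c in self.dinucleotides.items()}


@dataclass
class SimulantConstraints:
    forbid_real_motifs: bool = True
    max_run_per_base: dict[str, int] | None = None  # None: derive from real set
    require_unique: bool = True
    forbidden_substrings: tuple[str, ...] = ()
    max_attempts: int = 10_000


@dataclass
class SimulantCollection:
    """m simulant MotifSets, size- and length-matched to one real set."""

    real_rbp_id: str
    sets: list[MotifSet]
    seed: int

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)


def max_runs(motifs: Iterable[str]) -> dict[str, int]:
    """Longest mononucleotide run of each base across a motif collection."""
    runs = {b: 0 for b in "ACGT"}
    for m in motifs:
        for base, group in itertools.groupby(m):
            runs[base] = max(runs[base], len(list(group)))
    return runs


def _max_run_of(s: str, base: str) -> int:
    best = 0
    for b, group in itertools.groupby(s):
        if b == base:
            best = max(best, len(list(group)))
    return best


def dinucleotide_pool(motif_set: MotifSet | Iterable[str]) -> DinucleotidePool:
    """Decompose a motif set into dinucleotides in both phases.

    A motif of length k contributes floor(k/2) phase-0 dinucleotides and
    floor((k-1)/2) phase-1 dinucleotides; the two phases are pooled with
    equal weight.  The mononucleotide table is computed over all bases of all
    motifs and is used to pad odd-length simulants.
    """
    motifs = motif_set.motifs if isinstance(motif_set, MotifSet) else frozenset(motif_set)
    if not motifs:
        raise ValueError("cannot build a pool from an empty motif set")
    dinucs: Counter = Counter()
    mono: Counter = Counter()
    for m in motifs:
        for phase in (0, 1):
            for i in range(phase, len(m) - 1, 2):
                dinucs[m[i : i + 2]] += 1
        mono.update(m)
    total = sum(mono.values())
    return DinucleotidePool(
        dinucleotides=dinucs,
        mono_freqs={b: mono.get(b, 0) / total for b in "ACGT"},
    )


def _assemble_motif(k: int, pool: DinucleotidePool, rng: np.random.Generator) -> str:
    parts = pool.sample_dinucs(k // 2, rng)
    if k % 2:
        parts.append(pool.sample_base(rng))
    return "".join(parts)


def generate_simulant_set(
    real: MotifSet,
    pool: DinucleotidePool,
    constraints: SimulantConstraints | None = None,
    rng: np.random.Generator | None = None,
) -> MotifSet:
    """One simulant motif set matched to ``real`` in size and length multiset."""
    if real.unsimulatable:
        raise SimulantError(f"{real.rbp_id}: set flagged un-simulatable")
    constraints = constraints or SimulantConstraints()
    rng = rng if rng is not None else np.random.default_rng()
    run_caps = constraints.max_run_per_base or max_runs(real.motifs)
    chosen: list[str] = []
    chosen_set: set[str] = set()
    for k in real.lengths():
        for attempt in range(constraints.max_attempts):
            cand = _assemble_motif(k, pool, rng)
            if constraints.forbid_real_motifs and cand in real.motifs:
                continue
            if constraints.require_unique and cand in chosen_set:
                continue
            if any(sub in cand for sub in constraints.forbidden_substrings):
                continue
            if any(_max_run_of(cand, b) > cap for b, cap in run_caps.items()):
                continue
            chosen.append(cand)
            chosen_set.add(cand)
            break
        else:
            raise SimulantError(
                f"{real.rbp_id}: no valid length-{k} simulant in "
                f"{constraints.max_attempts} attempts"
            )
    return MotifSet(rbp_id=f"{real.rbp_id}:sim", motifs=frozenset(chosen))


def generate_simulant_collection(
    real: MotifSet,
    constraints: SimulantConstraints | None = None,
    m: int = 1000,
    seed: int = 0,
) -> SimulantCollection:
    """m independent simulant sets; set i is seeded from ``(seed, i)``."""
    if m < 1:
        raise ValueError("m must be >= 1")
    pool = dinucleotide_pool(real)
    sets = []
    for i in range(m):
        rng = np.random.default_rng([seed, i])
        sets.append(generate_simulant_set(real, pool, constraints, rng))
    return SimulantCollection(real_rbp_id=real.rbp_id, sets=sets, seed=seed)


def generate_random_motifs(
    lengths: Sequence[int],
    mono_freqs: dict[str, float],
    rng: np.random.Generator,
) -> MotifSet:
    """Random motifs with i.i.d. bases from genome mononucleotide frequencies."""
    bases = sorted(mono_freqs)
    p = np.array([mono_freqs[b] for b in bases], dtype=float)
    if not np.isclose(p.sum(), 1.0):
        raise ValueError("mononucleotide frequencies must sum to 1")
    motifs = []
    for k in lengths:
        idx = rng.choice(len(bases), size=k, p=p)
        motifs.append("".join(bases[i] for i in idx))
    return MotifSet(rbp_id="random", motifs=frozenset(motifs))
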