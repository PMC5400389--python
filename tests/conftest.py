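import sys
from pathlib import Path

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

sys.path.insert(0, str(Path(__file__).parent))

from motifsel.catalog import MotifSet
from motifsel.nulls import generate_random_motifs


@pytest.fixture
def rng():
    return np.random.default_rng(20170130)


def random_motif_set(rng, rbp_id="SET1", n=8, kmin=6, kmax=7,
                     mono=None) -> MotifSet:
    """A small random motif set drawn from mononucleotide frequencies."""
    mono = mono or {"A": 0.3, "C": 0.2, "G": 0.2, "T": 0.3}
    lengths = [int(rng.integers(kmin, kmax + 1)) for _ in range(n)]
    motifs = set()
    while len(motifs) < n:
        motifs.update(generate_random_motifs(lengths[: n - len(motifs)], mono, rng).motifs)
    return MotifSet(rbp_id=rbp_id, motifs=frozenset(sorted(motifs)[:n]))


@pytest.fixture
def small_motif_set(rng):
    return random_motif_set(rng)


def null_neutral_set(rng, n=8, kmin=6, kmax=7, rbp_id="SET1") -> MotifSet:
    """A motif set drawn from the simulant process of a random base set.

    Such a set has no dinucleotide-order preference relative to its own
    shuffle null, so its background density matches the simulant mean --
    the right starting point for planted-signal recovery experiments.
    """
    from motifsel.nulls import dinucleotide_pool, generate_simulant_set

    base = random_motif_set(rng, rbp_id="base", n=n, kmin=kmin, kmax=kmax)
    sim = generate_simulant_set(base, dinucleotide_pool(base), rng=rng)
    return MotifSet(rbp_id=rbp_id, motifs=sim.motifs)
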