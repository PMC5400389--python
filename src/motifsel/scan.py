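"""Motif scanning, density and empirical enrichment statistics.

Density of a motif set in a sequence is the fraction of bases covered by at
least one motif occurrence, with overlapping occurrences collapsed.
Enrichment of the observed density over the nucleotide-controlled null is
expressed three ways:

* ``ND`` (normalized density): (observed - simulant mean) / simulant mean.
  0 means chance frequency, 1 means twice as frequent as expected, -0.5 half.
* ``Z``: (observed - simulant mean) / simulant SD.
* empirical P: (n + 1) / (m + 1), n being the number of simulant sets whose
  statistic is at least as extreme as the observed one among m simulants
  (ties count as exceedances).

Genes belonging to one paralogous family are collapsed to a single
statistical unit, either by averaging or by picking one random member.
Coordinates are 0-based, half-open throughout; scanning is exact matching on
the sense strand only (the motifs act on the mRNA).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from ._kmer import MotifScanner, encode_seq

VALID_REGIONS = (
    "cds_intron_containing",
    "cds_intronless",
    "utr5",
    "utr3",
    "intron",
    "upstream_intronic",
    "downstream_intronic",
    "exon_flank5",
    "exon_core",
    "exon_flank3",
)

FLANK_LEN = 69
MIN_EXON_LEN = 211


@dataclass(frozen=True)
class SequenceRecord:
    gene_id: str
    seq: str
    family_id: str = ""
    region_label: str = "cds_intron_containing"
    frame_offset: int = 0

    def __post_init__(self):
        if self.region_label not in VALID_REGIONS:
            raise ValueError(f"unknown region label {self.region_label!r}")
        if not 0 <= self.frame_offset <= 2:
            raise ValueError("frame_offset must be 0, 1 or 2")


@dataclass
class EnrichmentStats:
    raw_density: float
    sim_densities: np.ndarray
    sim_mean: float
    sim_sd: float
    nd: float
    z: float
    p_enrich: float
    p_deplete: float


def coverage_mask(seq: str, motifs: Iterable[str]) -> np.ndarray:
    """Per-base boolean coverage of ``seq`` by any motif occurrence.

    Occurrences may overlap each other and themselves; covered bases are
    counted once.  Bases that are N are never covered.
    """
    return MotifScanner(motifs).mask(encode_seq(seq))


def find_occurrences(seq: str, motifs: Iterable[str]) -> list[tuple[int, int, str]]:
    """All motif occurrences as (start, end, motif), 0-based half-open."""
    scanner = MotifScanner(motifs)
    enc = encode_seq(seq)
    out = []
    for k, starts in scanner.hit_starts(enc).items():
        for s in starts:
            out.append((int(s), int(s) + k, seq[s : s + k]))
    return sorted(out)


def gene_density(seq: str, motifs: Iterable[str]) -> float:
    """Fraction of bases of ``seq`` overlapped by >=1 motif occurrence."""
    if not seq:
        raise ValueError("empty sequence")
    motifs = list(motifs)
    if not motifs:
        return 0.0
    return float(coverage_mask(seq, motifs).sum()) / len(seq)


def pooled_density(
    records: Sequence[SequenceRecord],
    motifs: Iterable[str],
    scanner: MotifScanner | None = None,
    encoded: Sequence[np.ndarray] | None = None,
) -> float:
    """Single density estimate for a motif set over many sequences.

    Covered-base counts and sequence lengths are averaged within paralogous
    families first; the pooled density is then (sum of family-mean counts) /
    (sum of family-mean lengths).
    """
    scanner = scanner or MotifScanner(motifs)
    if encoded is None:
        encoded = [encode_seq(r.seq) for r in records]
    fam_counts: dict[str, list[float]] = defaultdict(list)
    fam_lengths: dict[str, list[float]] = defaultdict(list)
    for rec, enc in zip(records, encoded):
        fam = rec.family_id or rec.gene_id
        fam_counts[fam].append(scanner.covered(enc))
        fam_lengths[fam].append(len(rec.seq))
    num = sum(float(np.mean(v)) for v in fam_counts.values())
    den = sum(float(np.mean(v)) for v in fam_lengths.values())
    if den == 0:
        raise ValueError("zero total sequence length")
    return num / den


def empirical_p(observed: float, sim_values: Sequence[float], tail: str = "upper") -> float:
    """(n+1)/(m+1) empirical P; ties count as exceedances (weak inequality)."""
    sims = np.asarray(sim_values, dtype=float)
    m = sims.size
    if m == 0:
        raise ValueError("no simulant values")
    if tail == "upper":
        n = int(np.sum(sims >= observed))
    elif tail == "lower":
        n = int(np.sum(sims <= observed))
    else:
        raise ValueError("tail must be 'upper' or 'lower'")
    return (n + 1) / (m + 1)


def normalized_stat(observed: float, sim_values: Sequence[float]) -> tuple[float, float]:
    """(ND, Z) of an observed statistic against its simulant distribution.

    ND is undefined when the simulant mean is zero (raised as ValueError;
    arises for un-simulatable homopolymer sets); Z is NaN when the simulant
    SD is zero.
    """
    sims = np.asarray(sim_values, dtype=float)
    mean = float(sims.mean())
    sd = float(sims.std(ddof=1)) if sims.size > 1 else 0.0
    if mean == 0:
        raise ValueError("simulant mean is zero; ND undefined")
    nd = (observed - mean) / mean
    z = (observed - mean) / sd if sd > 0 else float("nan")
    return nd, z


def enrichment_stats(observed: float, sim_values: Sequence[float]) -> EnrichmentStats:
    sims = np.asarray(sim_values, dtype=float)
    nd, z = normalized_stat(observed, sims)
    return EnrichmentStats(
        raw_density=observed,
        sim_densities=sims,
        sim_mean=float(sims.mean()),
        sim_sd=float(sims.std(ddof=1)) if sims.size > 1 else float("nan"),
        nd=nd,
        z=z,
        p_enrich=empirical_p(observed, sims, "upper"),
        p_deplete=empirical_p(observed, sims, "lower"),
    )


def set_enrichment(
    records: Sequence[SequenceRecord],
    real_motifs: Iterable[str],
    simulant_sets: Iterable[Iterable[str]],
) -> EnrichmentStats:
    """Pooled enrichment of one motif set against its simulant collection."""
    encoded = [encode_seq(r.seq) for r in records]
    obs = pooled_density(records, _motifs_of(real_motifs), encoded=encoded)
    sims = [
        pooled_density(records, _motifs_of(s), encoded=encoded) for s in simulant_sets
    ]
    return enrichment_stats(obs, sims)


def _motifs_of(obj) -> list[str]:
    """Accept a MotifSet-like object or a plain iterable of motif strings."""
    return sorted(getattr(obj, "motifs", obj))


def collapse_families(
    values_by_gene: Mapping[str, float],
    families: Mapping[str, str],
    mode: str = "mean",
    rng: np.random.Generator | None = None,
) -> dict[str, float]:
    """Collapse per-gene values to one value per paralogous family.

    ``mode='mean'`` averages within families; ``mode='random_pick'`` keeps a
    single random member (seed-deterministic via ``rng``).
    """
    groups: dict[str, list[str]] = defaultdict(list)
    for gene in values_by_gene:
        groups[families.get(gene, gene)].append(gene)
    out = {}
    if mode == "mean":
        for fam, genes in groups.items():
            out[fam] = float(np.mean([values_by_gene[g] for g in genes]))
    elif mode == "random_pick":
        if rng is None:
            raise ValueError("random_pick mode requires an rng")
        for fam in sorted(groups):
            genes = sorted(groups[fam])
            out[fam] = values_by_gene[genes[rng.integers(len(genes))]]
    else:
        raise ValueError("mode must be 'mean' or 'random_pick'")
    return out


def pick_family_representatives(
    genes: Sequence[str],
    families: Mapping[str, str],
    rng: np.random.Generator,
) -> list[str]:
    """One randomly picked gene per paralogous family (seed-deterministic)."""
    groups: dict[str, list[str]] = defaultdict(list)
    for g in genes:
        groups[families.get(g, g)].append(g)
    return [
        sorted(groups[fam])[rng.integers(len(groups[fam]))] for fam in sorted(groups)
    ]


def filter_rare_sets(
    real_hits_bp: Mapping[str, float],
    sim_hits_bp: Mapping[str, Sequence[float]],
    threshold_bp: float = 100.0,
) -> bool:
    """Keep a motif set only if it (or its simulants) is common enough.

    Keep iff the real hits total at least ``threshold_bp`` in *every*
    required sequence collection, OR at least half of the simulant sets reach
    the threshold in every collection.  Rare-everywhere sets carry too little
    information for reliable normalization.
    """
    collections = list(real_hits_bp)
    if not collections:
        raise ValueError("no sequence collections supplied")
    if all(real_hits_bp[c] >= threshold_bp for c in collections):
        return True
    sims_ok = []
    n_sims = None
    for c in collections:
        sims = np.asarray(sim_hits_bp[c], dtype=float)
        if n_sims is None:
            n_sims = sims.size
        sims_ok.append(sims >= threshold_bp)
    per_sim = np.logical_and.reduce(sims_ok)
    return bool(per_sim.sum() >= 0.5 * n_sims)


@dataclass(frozen=True)
class ExonRegions:
    flank5: str
    core: str
    flank3: str
    offsets: tuple[int, int, int]  # within the codon-trimmed exon


def extract_exon_regions(exon_seq: str, frame_offset: int = 0) -> ExonRegions:
    """Extract the 69-bp 5' flank, centre core and 3' flank of a coding exon.

    The exon must be at least 211 bp long before trimming; it is trimmed to
    start and end with full codons first.  When the number of codons between
    the two flanks is even (no exact mid-point), the core is placed n codons
    from the 5' flank and n-1 codons from the 3' flank.
    """
    if len(exon_seq) < MIN_EXON_LEN:
        raise ValueError(f"exon shorter than {MIN_EXON_LEN} bp")
    trimmed = exon_seq[frame_offset:]
    trimmed = trimmed[: len(trimmed) - len(trimmed) % 3]
    L = len(trimmed)
    if L < 3 * FLANK_LEN:
        raise ValueError("exon too short after codon trimming")
    gap_codons = (L - 3 * FLANK_LEN) // 3
    n5 = (gap_codons + 1) // 2  # gap odd -> inter-flank codon count even -> n, n-1
    core_off = FLANK_LEN + 3 * n5
    flank3_off = L - FLANK_LEN
    return ExonRegions(
        flank5=trimmed[:FLANK_LEN],
        core=trimmed[core_off : core_off + FLANK_LEN],
        flank3=trimmed[flank3_off:],
        offsets=(0, core_off, flank3_off),
    )
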