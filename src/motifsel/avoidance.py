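"""Selection against gaining putatively avoided motifs.

Motif sets that are *depleted* in coding sequence (enrichment P above 0.9)
are candidates for selective avoidance.  If avoidance is real, substitutions
that would create such a motif should be rare in evolution.  The test:

1. Find every 4-fold degenerate site in the focal CDS such that a single
   base substitution at the site would create at least one motif occurrence
   that is not present in the unmutated sequence at the same offset
   (*one-removed sites*).  Substituting a 4-fold third position never
   changes the protein, so any avoidance signal is purely nucleotide-level.
2. Score the orthologous base at each site: 0 if it is identical to the
   focal base or is a non-creating base; otherwise 0.25 / 0.5 / 0.75
   depending on whether 3 / 2 / 1 of the three possible substitutions would
   create a motif.  The weighting reflects how surprising the ortholog's
   motif-creating state is: if every substitution creates a motif the
   observation carries less evidence against avoidance than if only the
   ortholog's base does.
3. Sum the scores and divide by the number of sites; normalize against the
   same statistic for dinucleotide-matched simulant sets.  A negative
   normalized gain (real below simulant mean) indicates selection against
   motif gain.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from ._kmer import MotifScanner, encode_seq, window_codes
from .divergence import CodonAlignmentPair, fourfold_sites
from .scan import _motifs_of, empirical_p, normalized_stat

_POW4 = 4 ** np.arange(20, dtype=np.int64)


@dataclass(frozen=True)
class OneRemovedSite:
    gene_id: str
    position: int  # 0-based, third codon position, 4-fold degenerate
    human_base: str
    creating_bases: frozenset[str]
    ortholog_base: str | None = None

    def __post_init__(self):
        if not 1 <= len(self.creating_bases) <= 3:
            raise ValueError("creating_bases must contain 1-3 bases")
        if self.human_base in self.creating_bases:
            raise ValueError("focal base cannot be a creating base")


@dataclass
class GainStats:
    weighted_fraction: float
    n_sites: int
    sim_fractions: np.ndarray
    gain_norm: float
    p_gain: float  # small when the real fraction is below the simulant values


_BASE_ORDER = "ACGT"


def _creating_alts(
    enc: np.ndarray, scanner: MotifScanner, sites: np.ndarray
) -> np.ndarray:
    """Boolean [len(sites), 4]: does substituting base b at the site create a motif?

    A substitution creates a motif when the mutated sequence has a motif
    occurrence overlapping the site at an offset where the unmutated
    sequence has none (simultaneous destruction of other occurrences is
    ignored).
    """
    creates = np.zeros((sites.size, 4), dtype=bool)
    if sites.size == 0:
        return creates
    L = enc.size
    for k in scanner.lengths:
        codes, valid = window_codes(enc, k)
        if codes.size == 0:
            continue
        orig_hit = scanner.member(k, codes)
        # windows covering site p start at p-k+1 .. p
        for j in range(k):  # offset of the site within the window
            starts = sites - j
            ok = (starts >= 0) & (starts <= L - k)
            if not ok.any():
                continue
            st = starts[ok]
            base_orig = enc[sites[ok]].astype(np.int64)
            mult = _POW4[k - 1 - j]
            ok_idx = np.flatnonzero(ok)
            usable = valid[st] & ~orig_hit[st]
            for b in range(4):
                mutated = codes[st] + (b - base_orig) * mult
                new_hit = scanner.member(k, mutated) & usable
                creates[ok_idx[new_hit], b] = True
    # the focal base itself never "creates"
    focal = enc[sites]
    creates[np.arange(sites.size), focal] = False
    return creates


def find_one_removed_sites(
    cds: str,
    motifs: Iterable[str],
    gene_id: str = "",
    ortholog: str | None = None,
) -> list[OneRemovedSite]:
    """4-fold degenerate sites one substitution away from a motif occurrence.

    ``ortholog`` (an aligned, gap-free sequence of equal length) fills the
    sites' ortholog_base when given.
    """
    scanner = motifs if isinstance(motifs, MotifScanner) else MotifScanner(_motifs_of(motifs))
    enc = encode_seq(cds)
    sites = fourfold_sites(cds)
    creates = _creating_alts(enc, scanner, sites)
    out = []
    for idx in np.flatnonzero(creates.any(axis=1)):
        p = int(sites[idx])
        bases = frozenset(_BASE_ORDER[b] for b in np.flatnonzero(creates[idx]))
        out.append(
            OneRemovedSite(
                gene_id=gene_id,
                position=p,
                human_base=cds[p],
                creating_bases=bases,
                ortholog_base=ortholog[p] if ortholog is not None else None,
            )
        )
    return out


def score_one_removed(site: OneRemovedSite) -> float:
    """Degeneracy-weighted score of the ortholog state at a one-removed site.

    0 when the ortholog base equals the focal base or is a non-creating
    base; else 0.25, 0.5 or 0.75 for 3, 2 or 1 creating bases respectively.
    """
    if site.ortholog_base is None:
        raise ValueError("site has no ortholog base")
    if site.ortholog_base == site.human_base:
        return 0.0
    if site.ortholog_base not in site.creating_bases:
        return 0.0
    return {3: 0.25, 2: 0.5, 1: 0.75}[len(site.creating_bases)]


def weighted_gain_fraction(
    pairs: Sequence[CodonAlignmentPair],
    motifs: Iterable[str],
    weighted: bool = True,
) -> tuple[float, int]:
    """(sum of site scores / number of sites, number of sites) over gene pairs.

    With ``weighted=False`` each site instead contributes 1 when the
    ortholog base is any creating base (raw presence count).
    """
    scanner = MotifScanner(_motifs_of(motifs))
    total = 0.0
    n = 0
    for pair in pairs:
        if "-" in pair.focal or "-" in pair.ortholog:
            raise ValueError(f"{pair.gene_id}: gain analysis requires gap-free alignments")
        for site in find_one_removed_sites(
            pair.focal, scanner, gene_id=pair.gene_id, ortholog=pair.ortholog
        ):
            if site.ortholog_base not in _BASE_ORDER:
                continue
            n += 1
            if weighted:
                total += score_one_removed(site)
            elif (
                site.ortholog_base != site.human_base
                and site.ortholog_base in site.creating_bases
            ):
                total += 1.0
    if n == 0:
        return float("nan"), 0
    return total / n, n


def gain_statistics(
    pairs: Sequence[CodonAlignmentPair],
    real_motifs: Iterable[str],
    simulant_sets: Iterable[Iterable[str]],
    weighted: bool = True,
    families=None,
    rng=None,
) -> GainStats:
    """Nucleotide-normalized motif-gain statistic for one (avoided) motif set.

    gain_norm = (real fraction - simulant mean) / simulant mean; p_gain is
    the lower-tail empirical P (small when the real fraction falls below the
    simulant distribution, i.e. evidence for selection against gain).
    When a gene -> family mapping is given, one randomly picked gene per
    paralogous family is used.
    """
    if families is not None:
        from .scan import pick_family_representatives

        if rng is None:
            raise ValueError("family collapsing requires an rng")
        keep = set(
            pick_family_representatives([p.gene_id for p in pairs], families, rng)
        )
        pairs = [p for p in pairs if p.gene_id in keep]
    real, n_sites = weighted_gain_fraction(pairs, real_motifs, weighted=weighted)
    if n_sites == 0:
        raise ValueError("no one-removed sites for the real motif set")
    sims = []
    for s in simulant_sets:
        frac, n = weighted_gain_fraction(pairs, s, weighted=weighted)
        if n > 0:
            sims.append(frac)
    if not sims:
        raise ValueError("no simulant set produced one-removed sites")
    gain_norm, _ = normalized_stat(real, sims)
    return GainStats(
        weighted_fraction=real,
        n_sites=n_sites,
        sim_fractions=np.asarray(sims),
        gain_norm=gain_norm,
        p_gain=empirical_p(real, sims, "lower"),
    )
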