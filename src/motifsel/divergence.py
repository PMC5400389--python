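"""Synonymous and noncoding divergence of motif-overlapping regions.

The headline statistic is the synonymous substitution rate (dS) of the
codons that overlap a motif set, computed against a pairwise ortholog
alignment and normalized against the same quantity for simulant motif sets:

    normalized dS = (true dS - mean simulant dS) / mean simulant dS

Negative values indicate excess conservation of the motif-overlapping
sequence relative to the nucleotide-controlled expectation.

The built-in dS estimator is Nei-Gojobori (1986) counting with the
Jukes-Cantor multiple-hit correction.  Because the inference is always
relative (true vs simulant under the same estimator), first-order estimator
biases cancel; an adapter for PAML's codeml (Goldman-Yang ML) is provided
for users who have it installed.  Noncoding divergence uses the Kimura
two-parameter distance, with an analogous baseml adapter.

A complementary, model-free check compares raw divergence at 4-fold
degenerate sites inside vs outside motif coverage, stratified by the
overlapping dinucleotide: each site is counted once in the dinucleotide in
which it is the second base and once in the one in which it is the first,
and the per-dinucleotide rates are averaged with weights taken from the
motif-class dinucleotide frequencies for both classes, controlling for
composition differences.
"""

from __future__ import annotations

import math
import subprocess
import tempfile
from dataclasses import dataclass
from itertools import permutations, product
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .scan import empirical_p, normalized_stat

_TABLE = CodonTable.unambiguous_dna_by_id[1]
_BASES = "ACGT"
_CODONS = ["".join(c) for c in product(_BASES, repeat=3)]
_AA = {c: _TABLE.forward_table.get(c) for c in _CODONS}  # stops -> None
STOP_CODONS = frozenset(_TABLE.stop_codons)

#: codons whose third position is 4-fold degenerate (any base keeps the aa)
FOURFOLD_CODONS = frozenset(
    c
    for c in _CODONS
    if c not in STOP_CODONS
    and all(
        _AA[c[:2] + b] is not None and _AA[c[:2] + b] == _AA[c] for b in _BASES
    )
)


class SaturationError(ValueError):
    """Divergence too high for the distance correction to be defined."""


class NoDataError(ValueError):
    """No usable sites for the requested estimate."""


def is_fourfold_codon(codon: str) -> bool:
    """True if the codon's third position is 4-fold degenerate."""
    return codon in FOURFOLD_CODONS


# ---------------------------------------------------------------------------
# NG86 dS (precomputed per-codon tables)


def _count_sites(codon: str) -> tuple[float, float]:
    """Fractional synonymous / nonsynonymous sites of one sense codon.

    Each of the nine single-base neighbours contributes 1/3 of a site;
    neighbours that are stop codons count as nonsynonymous.
    """
    s = n = 0.0
    aa = _AA[codon]
    for i in range(3):
        for b in _BASES:
            if b == codon[i]:
                continue
            neighbour = codon[:i] + b + codon[i + 1 :]
            if _AA[neighbour] is not None and _AA[neighbour] == aa:
                s += 1.0
            else:
                n += 1.0
    return s / 3.0, n / 3.0


def _count_diffs(c1: str, c2: str) -> tuple[float, float]:
    """Pathway-averaged synonymous / nonsynonymous differences of a codon pair.

    All mutational orderings between the two codons are weighted equally;
    a step is synonymous when the two codons encode the same amino acid
    (steps between two stop codons count as synonymous, matching the common
    reference implementation of the counting method).
    """
    if c1 == c2:
        return 0.0, 0.0
    diff = [i for i in range(3) if c1[i] != c2[i]]
    paths = list(permutations(diff))
    w = 1.0 / len(paths)
    sd = nd = 0.0
    for path in paths:
        cur = c1
        for i in path:
            nxt = cur[:i] + c2[i] + cur[i + 1 :]
            if _AA[cur] == _AA[nxt]:
                sd += w
            else:
                nd += w
            cur = nxt
    return sd, nd


_SITES = {c: _count_sites(c) for c in _CODONS if c not in STOP_CODONS}
_DIFFS: dict[tuple[str, str], tuple[float, float]] = {}


def _pair_diffs(c1: str, c2: str) -> tuple[float, float]:
    key = (c1, c2)
    hit = _DIFFS.get(key)
    if hit is None:
        hit = _DIFFS[key] = _count_diffs(c1, c2)
    return hit


def _valid_codon(c: str) -> bool:
    return len(c) == 3 and all(b in _BASES for b in c) and c not in STOP_CODONS


@dataclass
class CodonAlignmentPair:
    """Gap-aware pairwise codon alignment of a focal gene and its ortholog."""

    gene_id: str
    focal: str
    ortholog: str

    def __post_init__(self):
        if len(self.focal) != len(self.ortholog):
            raise ValueError(f"{self.gene_id}: aligned sequences differ in length")
        if len(self.focal) % 3:
            raise ValueError(f"{self.gene_id}: alignment length not a multiple of 3")

    def codon_pairs(self) -> list[tuple[str, str]]:
        """Valid codon pairs (no gaps, no ambiguity, no stops in either)."""
        out = []
        for i in range(0, len(self.focal), 3):
            c1, c2 = self.focal[i : i + 3], self.ortholog[i : i + 3]
            if _valid_codon(c1) and _valid_codon(c2):
                out.append((c1, c2))
        return out


def build_codon_pairs(
    pair: CodonAlignmentPair, mask: np.ndarray
) -> list[tuple[str, str]]:
    """Codon pairs of the motif-overlapping region of an aligned gene.

    ``mask`` is the coverage mask on the focal sequence's *ungapped*
    coordinates; a codon is motif-overlapping when at least one of its three
    bases is covered.  Gap-containing or ambiguous codons are dropped.
    """
    mask = np.asarray(mask, dtype=bool)
    ungapped = sum(1 for b in pair.focal if b != "-")
    if mask.size != ungapped:
        raise ValueError(
            f"{pair.gene_id}: mask length {mask.size} != ungapped focal length {ungapped}"
        )
    out = []
    pos = 0  # ungapped focal coordinate
    for i in range(0, len(pair.focal), 3):
        c1, c2 = pair.focal[i : i + 3], pair.ortholog[i : i + 3]
        n_real = sum(1 for b in c1 if b != "-")
        covered = bool(mask[pos : pos + n_real].any())
        pos += n_real
        if covered and _valid_codon(c1) and _valid_codon(c2):
            out.append((c1, c2))
    return out


def ng86_ds(codon_pairs: Sequence[tuple[str, str]]) -> float:
    """Nei-Gojobori synonymous rate with Jukes-Cantor correction."""
    if not codon_pairs:
        raise NoDataError("no codon pairs")
    S = sum(_SITES[c1][0] + _SITES[c2][0] for c1, c2 in codon_pairs) / 2.0
    Sd = sum(_pair_diffs(c1, c2)[0] for c1, c2 in codon_pairs)
    if S == 0:
        raise NoDataError("zero synonymous sites")
    ps = Sd / S
    if ps >= 0.75:
        raise SaturationError(f"synonymous proportion {ps:.3f} >= 0.75")
    return -0.75 * math.log(1.0 - 4.0 * ps / 3.0)


def estimate_ds(
    pair_or_codons: CodonAlignmentPair | Sequence[tuple[str, str]],
    method: str = "ng86",
    external_path: str | None = None,
) -> float:
    """Synonymous divergence of a codon alignment.

    ``method='ng86'`` uses the built-in counting estimator;
    ``method='external_gy94'`` delegates to an installed PAML codeml binary
    (never silently falls back to the built-in).
    """
    if isinstance(pair_or_codons, CodonAlignmentPair):
        codons = pair_or_codons.codon_pairs()
    else:
        codons = list(pair_or_codons)
    if method == "ng86":
        return ng86_ds(codons)
    if method == "external_gy94":
        return _codeml_ds(codons, external_path or "codeml")
    raise ValueError(f"unknown method {method!r}")


def _codeml_ds(codon_pairs: Sequence[tuple[str, str]], exe: str) -> float:
    """Pairwise GY94 dS via an external PAML codeml executable."""
    import shutil

    if shutil.which(exe) is None:
        raise FileNotFoundError(
            f"external codeml executable {exe!r} not found; "
            "install PAML or use method='ng86'"
        )
    if not codon_pairs:
        raise NoDataError("no codon pairs")
    s1 = "".join(c1 for c1, _ in codon_pairs)
    s2 = "".join(c2 for _, c2 in codon_pairs)
    with tempfile.TemporaryDirectory() as tmp:
        tmp = Path(tmp)
        (tmp / "pair.phy").write_text(f" 2 {len(s1)}\nfocal\n{s1}\northo\n{s2}\n")
        (tmp / "codeml.ctl").write_text(
            "seqfile = pair.phy\noutfile = out.txt\nnoisy = 0\nverbose = 0\n"
            "runmode = -2\nseqtype = 1\nCodonFreq = 2\nmodel = 0\nNSsites = 0\n"
            "icode = 0\nfix_kappa = 0\nkappa = 2\nfix_omega = 0\nomega = 0.4\n"
        )
        subprocess.run([exe], cwd=tmp, check=True, capture_output=True)
        for line in (tmp / "out.txt").read_text().splitlines():
            if "dS =" in line:
                return float(line.split("dS =")[1].split()[0])
    raise RuntimeError("could not parse dS from codeml output")


# ---------------------------------------------------------------------------
# conservation statistics


@dataclass
class ConservationStats:
    ds_raw: float
    sim_ds: np.ndarray
    sim_mean: float
    ds_norm: float
    p_cons: float
    n_sims_failed: int = 0


def conservation_stats(
    real_ds: float, sim_ds_values: Sequence[float], n_sims_failed: int = 0
) -> ConservationStats:
    """Normalized dS and lower-tail conservation P from simulant dS values."""
    sims = np.asarray(sim_ds_values, dtype=float)
    nd, _ = normalized_stat(real_ds, sims)
    return ConservationStats(
        ds_raw=real_ds,
        sim_ds=sims,
        sim_mean=float(sims.mean()),
        ds_norm=nd,
        p_cons=empirical_p(real_ds, sims, "lower"),
        n_sims_failed=n_sims_failed,
    )


def set_conservation(
    pairs: Sequence[CodonAlignmentPair],
    real_motifs: Iterable[str],
    simulant_sets: Iterable[Iterable[str]],
    method: str = "ng86",
    families=None,
    rng: "np.random.Generator | None" = None,
) -> ConservationStats:
    """Conservation of one motif set's coverage across many gene pairs.

    For the real set and for each simulant set, the motif-overlapping codons
    of all genes are concatenated into a single estimate (the counting
    estimator is order-invariant).  Simulant sets that end up saturated or
    without data are dropped and counted.  When a gene -> family mapping is
    given, one randomly picked gene per paralogous family is used (pass a
    seeded ``rng`` for reproducibility).
    """
    from ._kmer import MotifScanner, encode_seq
    from .scan import _motifs_of, pick_family_representatives

    if families is not None:
        if rng is None:
            raise ValueError("family collapsing requires an rng")
        keep = set(
            pick_family_representatives([p.gene_id for p in pairs], families, rng)
        )
        pairs = [p for p in pairs if p.gene_id in keep]

    encoded = [encode_seq(p.focal.replace("-", "")) for p in pairs]
    gap_free = ["-" not in p.focal and "-" not in p.ortholog for p in pairs]

    def one_ds(motifs) -> float:
        scanner = MotifScanner(_motifs_of(motifs))
        codons: list[tuple[str, str]] = []
        for p, enc, clean in zip(pairs, encoded, gap_free):
            mask = scanner.mask(enc)
            if not clean:
                codons.extend(build_codon_pairs(p, mask))
                continue
            n = mask.size - mask.size % 3
            hit = np.flatnonzero(mask[:n].reshape(-1, 3).any(axis=1)) * 3
            for i in hit:
                c1, c2 = p.focal[i : i + 3], p.ortholog[i : i + 3]
                if _valid_codon(c1) and _valid_codon(c2):
                    codons.append((c1, c2))
        return ng86_ds(codons) if method == "ng86" else estimate_ds(codons, method)

    real = one_ds(real_motifs)
    sims, failed = [], 0
    for s in simulant_sets:
        try:
            sims.append(one_ds(s))
        except (SaturationError, NoDataError):
            failed += 1
    if not sims:
        raise NoDataError("all simulant sets failed")
    return conservation_stats(real, sims, n_sims_failed=failed)


# ---------------------------------------------------------------------------
# 4-fold degenerate site analysis


def fourfold_sites(cds: str) -> np.ndarray:
    """0-based positions of 4-fold degenerate third codon positions."""
    pos = []
    for i in range(0, len(cds) - 2, 3):
        if cds[i : i + 3] in FOURFOLD_CODONS:
            pos.append(i + 2)
    return np.array(pos, dtype=np.int64)


@dataclass
class FourfoldDivergence:
    table: pd.DataFrame  # columns: dinucleotide, in_motif, n_sites, n_diverged, rate
    motif_rate: float  # weighted by motif-class dinucleotide frequencies
    nonmotif_rate: float  # same weights


def fourfold_divergence(
    pairs: Sequence[CodonAlignmentPair],
    masks: Sequence[np.ndarray],
) -> FourfoldDivergence:
    """Dinucleotide-stratified divergence at 4-fold sites, motif vs nonmotif.

    Each 4-fold site is counted twice: once under the dinucleotide in which
    it is the second base (preceding base + site) and once under the one in
    which it is the first (site + following base).  Per-dinucleotide rates
    are the fraction of sites whose orthologous base differs; weighted
    averages use the motif-class dinucleotide frequencies for both classes.
    """
    counts: dict[tuple[str, bool], list[int]] = {}
    for pair, mask in zip(pairs, masks):
        focal = pair.focal.replace("-", "")
        if focal != pair.focal:
            raise ValueError(
                f"{pair.gene_id}: 4-fold analysis requires gap-free alignments"
            )
        mask = np.asarray(mask, dtype=bool)
        for p in fourfold_sites(focal):
            b_f, b_o = focal[p], pair.ortholog[p]
            if b_o not in _BASES:
                continue
            diverged = int(b_f != b_o)
            in_motif = bool(mask[p])
            contexts = []
            if p >= 1 and focal[p - 1] in _BASES:
                contexts.append(focal[p - 1] + b_f)  # site is second base
            if p + 1 < len(focal) and focal[p + 1] in _BASES:
                contexts.append(b_f + focal[p + 1])  # site is first base
            for dinuc in contexts:
                key = (dinuc, in_motif)
                if key not in counts:
                    counts[key] = [0, 0]
                counts[key][0] += 1
                counts[key][1] += diverged
    rows = [
        {
            "dinucleotide": d,
            "in_motif": m,
            "n_sites": n,
            "n_diverged": k,
            "rate": k / n,
        }
        for (d, m), (n, k) in sorted(counts.items())
    ]
    table = pd.DataFrame(rows)
    if table.empty:
        raise NoDataError("no 4-fold degenerate sites")
    motif_tab = table[table.in_motif].set_index("dinucleotide")
    non_tab = table[~table.in_motif].set_index("dinucleotide")
    shared = motif_tab.index.intersection(non_tab.index)
    if len(shared) == 0:
        # one class empty (e.g. no motif coverage): rates per stratum are
        # still reported but the weighted comparison is undefined
        return FourfoldDivergence(
            table=table, motif_rate=float("nan"), nonmotif_rate=float("nan")
        )
    w = motif_tab.loc[shared, "n_sites"].astype(float)
    w = w / w.sum()
    motif_rate = float((motif_tab.loc[shared, "rate"] * w).sum())
    nonmotif_rate = float((non_tab.loc[shared, "rate"] * w).sum())
    return FourfoldDivergence(table=table, motif_rate=motif_rate, nonmotif_rate=nonmotif_rate)


# ---------------------------------------------------------------------------
# noncoding divergence


def kimura_k80(focal: str, ortholog: str) -> float:
    """Kimura two-parameter distance of an aligned noncoding pair.

    Gap or ambiguous columns are excluded.  Raises SaturationError when the
    log arguments are non-positive (divergence too high to correct).
    """
    if len(focal) != len(ortholog):
        raise ValueError("aligned sequences differ in length")
    transitions = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
    n = ts = tv = 0
    for a, b in zip(focal.upper(), ortholog.upper()):
        if a not in _BASES or b not in _BASES:
            continue
        n += 1
        if a != b:
            if (a, b) in transitions:
                ts += 1
            else:
                tv += 1
    if n == 0:
        raise NoDataError("no valid aligned sites")
    P, Q = ts / n, tv / n
    a1 = 1.0 - 2.0 * P - Q
    a2 = 1.0 - 2.0 * Q
    if a1 <= 0 or a2 <= 0:
        raise SaturationError("K80 correction undefined (saturated divergence)")
    return -0.5 * math.log(a1) - 0.25 * math.log(a2)


def noncoding_divergence(
    focal: str,
    ortholog: str,
    method: str = "k80",
    external_path: str | None = None,
) -> float:
    """Noncoding divergence: built-in K80, or PAML baseml (model=1) adapter."""
    if method == "k80":
        return kimura_k80(focal, ortholog)
    if method == "external_baseml":
        return _baseml_dnc(focal, ortholog, external_path or "baseml")
    raise ValueError(f"unknown method {method!r}")


def _baseml_dnc(focal: str, ortholog: str, exe: str) -> float:
    import shutil

    if shutil.which(exe) is None:
        raise FileNotFoundError(
            f"external baseml executable {exe!r} not found; "
            "install PAML or use method='k80'"
        )
    with tempfile.TemporaryDirectory() as tmp:
        tmp = Path(tmp)
        (tmp / "pair.phy").write_text(f" 2 {len(focal)}\nfocal\n{focal}\northo\n{ortholog}\n")
        (tmp / "baseml.ctl").write_text(
            "seqfile = pair.phy\noutfile = out.txt\nnoisy = 0\nverbose = 0\n"
            "runmode = -2\nmodel = 1\nclock = 0\n"
        )
        subprocess.run([exe], cwd=tmp, check=True, capture_output=True)
        text = (tmp / "out.txt").read_text()
        for line in text.splitlines():
            if "tree length" in line.lower():
                return float(line.split("=")[-1].split()[0])
    raise RuntimeError("could not parse tree length from baseml output")
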