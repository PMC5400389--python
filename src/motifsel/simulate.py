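"""Synthetic datasets with known planted selection signals.

The generator emulates the statistical structure the analysis assumes,
without requiring any genome downloads:

* background CDSs from a first-order (dinucleotide) Markov model with valid
  ORF structure (ATG start, stop-free body, terminal stop);
* paralogous families built by duplicating a founder with low divergence
  confined to 4-fold degenerate sites;
* motif occurrences planted at a controlled density multiplier (>1
  enrichment, <1 depletion, 0 complete removal), frame-aware and
  stop-avoiding;
* orthologs evolved by substitutions at 4-fold degenerate sites only, with
  distinct rates inside vs outside motif coverage and optional suppression
  of substitutions that would create an avoided motif.  Confining change to
  4-fold sites keeps the protein identical and the alignment gap-free, and
  places all signal at synonymous sites -- exactly the quantity the
  conservation statistics measure;
* gene x tissue TPM tables with a controlled expression-breadth
  distribution.

Everything is deterministic given the master seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from ._kmer import MotifScanner, encode_seq
from .catalog import MotifSet
from .divergence import CodonAlignmentPair, STOP_CODONS, fourfold_sites
from .scan import SequenceRecord, _motifs_of

_BASES = "ACGT"

#: default background dinucleotide frequencies: independent draws from
#: human-like mononucleotide frequencies (A/T 0.295, C/G 0.205) with the
#: characteristic CpG depletion (CG odds ratio ~0.25).  The removed CpG mass
#: is moved to TpG and CpA and taken back out of TpA, mimicking the
#: CpG-deamination signature of real genomes; this keeps the left and right
#: marginals equal, which any realizable stationary sequence requires.
def _default_dinuc_freqs() -> dict[str, float]:
    mono = {"A": 0.295, "C": 0.205, "G": 0.205, "T": 0.295}
    f = {a + b: mono[a] * mono[b] for a in _BASES for b in _BASES}
    delta = 0.75 * mono["C"] * mono["G"]
    f["CG"] -= delta
    f["CA"] += delta
    f["TG"] += delta
    f["TA"] -= delta
    total = sum(f.values())
    return {k: v / total for k, v in f.items()}


@dataclass
class PlantedSet:
    """One motif set planted into the background with a density multiplier."""

    motif_set: MotifSet
    multiplier: float = 1.0
    conserved: bool = False  # motif-region 4-fold sites evolve at rate_motif
    avoided: bool = False  # motif-creating ortholog substitutions suppressed

    def __post_init__(self):
        if self.multiplier < 0:
            raise ValueError("multiplier must be >= 0")


@dataclass
class SimulationConfig:
    n_families: int = 40
    p_family_of_two: float = 0.2
    min_codons: int = 200
    max_codons: int = 400
    dinucleotide_freqs: dict[str, float] = field(default_factory=_default_dinuc_freqs)
    planted: list[PlantedSet] = field(default_factory=list)
    rate_motif: float = 0.04
    rate_background: float = 0.08
    gain_suppression: float = 0.0
    within_family_rate: float = 0.02
    n_tissues: int = 50
    breadth_beta: tuple[float, float] = (0.8, 1.2)
    seed: int = 0

    def __post_init__(self):
        for r in (self.rate_motif, self.rate_background, self.within_family_rate):
            if not 0 <= r <= 0.5:
                raise ValueError("substitution rates must lie in [0, 0.5]")
        if self.min_codons < 10:
            raise ValueError("CDSs must have at least 10 codons")


@dataclass
class StudyData:
    records: list[SequenceRecord]
    families: dict[str, str]
    masks: dict[str, dict[str, np.ndarray]]  # rbp_id -> gene_id -> coverage mask
    pairs: list[CodonAlignmentPair]
    expression: "object" = None  # pandas DataFrame when generated
    config: SimulationConfig | None = None


# ---------------------------------------------------------------------------
# background CDSs


def _balance(g: np.ndarray) -> np.ndarray:
    """Project a joint onto the stationary-consistent set (row sums == col
    sums) by iterative scaling; only such joints are realizable by any
    stationary sequence."""
    g = g / g.sum()
    for _ in range(500):
        r, c = g.sum(axis=1), g.sum(axis=0)
        if np.abs(r - c).max() < 1e-13:
            break
        m = 0.5 * (r + c)
        g = g * np.where(r > 0, m / np.maximum(r, 1e-300), 1.0)[:, None]
        c2 = g.sum(axis=0)
        g = g * np.where(c2 > 0, m / np.maximum(c2, 1e-300), 1.0)[None, :]
        g /= g.sum()
    return g


# third-base restrictions that keep frame-0 codons stop-free:
# prefix TA forbids A and G; prefix TG forbids A
_STOP_PREFIX = {("T", "A"): ("A", "G"), ("T", "G"): ("A",)}


def _restricted_third(trans: np.ndarray, b0: int, b1: int) -> np.ndarray:
    w = trans[b1].copy()
    for bad in _STOP_PREFIX.get((_BASES[b0], _BASES[b1]), ()):
        w[_BASES.index(bad)] = 0.0
    s = w.sum()
    if s <= 0:
        w = np.ones(4)
        for bad in _STOP_PREFIX.get((_BASES[b0], _BASES[b1]), ()):
            w[_BASES.index(bad)] = 0.0
        s = w.sum()
    return w / s


def _realized_dinucs(trans: np.ndarray) -> np.ndarray:
    """Exact realized dinucleotide joint of the stop-free codon chain.

    The generator emits bases in codon phases, with the third base
    conditionally restricted to avoid stop codons.  The chain over states
    (phase, previous base, current base) is finite; its stationary
    distribution gives the realized pair frequencies in closed form.
    """
    idx = {}
    states = []
    for phase in range(3):
        for b0 in range(4):
            for b1 in range(4):
                idx[(phase, b0, b1)] = len(states)
                states.append((phase, b0, b1))
    P = np.zeros((48, 48))
    for (phase, b0, b1), i in idx.items():
        nxt_phase = (phase + 1) % 3
        if nxt_phase == 2:
            w = _restricted_third(trans, b0, b1)
        else:
            w = trans[b1]
        for b2 in range(4):
            P[i, idx[(nxt_phase, b1, b2)]] += w[b2]
    pi = np.full(48, 1.0 / 48)
    for _ in range(2000):
        new = pi @ P
        if np.abs(new - pi).max() < 1e-14:
            pi = new
            break
        pi = new
    joint = np.zeros((4, 4))
    for (phase, b0, b1), i in idx.items():
        joint[b0, b1] += pi[i]
    return joint / joint.sum()


def _markov_tables(dinuc_freqs: dict[str, float]):
    """Start and transition probabilities of the stop-free codon chain,
    pre-compensated so that the *realized* dinucleotide joint matches the
    target.

    The target is first balanced (left marginal == right marginal, which any
    stationary sequence requires); the no-stop conditioning is then
    counteracted by a fixed-point adjustment of the input joint using the
    exact realized joint of the restricted chain.
    """
    f = np.array([dinuc_freqs.get(a + b, 0.0) for a in _BASES for b in _BASES])
    f = f.reshape(4, 4).astype(float)
    if f.sum() <= 0:
        raise ValueError("invalid dinucleotide frequencies")
    f = _balance(f)
    g = f.copy()
    trans = g / np.maximum(g.sum(axis=1, keepdims=True), 1e-300)
    for _ in range(40):
        realized = _realized_dinucs(trans)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where((realized > 0) & (f > 0), f / np.maximum(realized, 1e-300), 1.0)
        if np.abs(ratio - 1).max() < 1e-6:
            break
        g = _balance(g * np.clip(ratio, 0.2, 5.0))
        trans = g / np.maximum(g.sum(axis=1, keepdims=True), 1e-300)
    start = g.sum(axis=1)
    return start, trans


def simulate_background_cds(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[list[SequenceRecord], dict[str, str]]:
    """First-order Markov CDSs with ORF structure and paralog families.

    Bases are emitted codon-phase-aware: the third base of every internal
    codon is drawn from its conditional distribution restricted to non-stop
    codons, so no internal stop ever appears.  Returns records and the
    gene -> family mapping.  Families of size two are founder plus a copy
    diverged at 4-fold sites at the within-family rate.
    """
    start_p, trans = _markov_tables(config.dinucleotide_freqs)
    records: list[SequenceRecord] = []
    families: dict[str, str] = {}
    for f in range(config.n_families):
        fam_id = f"fam{f:04d}"
        n_codons = int(rng.integers(config.min_codons, config.max_codons + 1))
        seq = list("ATG")
        prev = _BASES.index("G")
        for j in range(3 * n_codons):
            if j % 3 == 2:
                w = _restricted_third(trans, _BASES.index(seq[-2]), prev)
            else:
                w = trans[prev]
            prev = int(rng.choice(4, p=w))
            seq.append(_BASES[prev])
        seq.append("T")
        seq.extend(["AA", "AG", "GA"][rng.integers(3)])
        founder = "".join(seq)
        n_members = 2 if rng.random() < config.p_family_of_two else 1
        for m in range(n_members):
            gene_id = f"g{f:04d}_{m}"
            s = founder
            if m > 0:
                s = _mutate_fourfold(founder, config.within_family_rate, rng)
            records.append(
                SequenceRecord(gene_id=gene_id, seq=s, family_id=fam_id)
            )
            families[gene_id] = fam_id
    return records, families


def _mutate_fourfold(seq: str, rate: float, rng: np.random.Generator) -> str:
    out = list(seq)
    for p in fourfold_sites(seq):
        if rng.random() < rate:
            alts = [b for b in _BASES if b != out[p]]
            out[p] = alts[rng.integers(3)]
    return "".join(out)


# ---------------------------------------------------------------------------
# motif planting


def _expected_density(
    motifs: Sequence[str], records: Sequence[SequenceRecord]
) -> float:
    """Expected coverage density of a motif set in the records' background.

    Uses the empirical dinucleotide (first-order Markov) composition of the
    sequences, matching the null against which enrichment is later judged:
    E[covered]/L ~ sum_m (L-k+1) P(m) k / L with P(m) from the chain.
    Overlap collapsing is ignored (hits are sparse at background densities).
    """
    counts = np.zeros((4, 4))
    total_len = 0
    for r in records:
        enc = encode_seq(r.seq)
        np.add.at(counts, (enc[:-1], enc[1:]), 1)
        total_len += len(r.seq)
    pi = counts.sum(axis=1) / counts.sum()
    trans = counts / np.maximum(counts.sum(axis=1, keepdims=True), 1e-300)
    mean_len = total_len / len(records)
    exp_cov = 0.0
    for m in motifs:
        enc = encode_seq(m)
        p = pi[enc[0]]
        for a, b in zip(enc[:-1], enc[1:]):
            p *= trans[a, b]
        exp_cov += (mean_len - len(m) + 1) * p * len(m)
    return min(exp_cov / mean_len, 1.0)


def _simulant_baseline(
    motif_set,
    motifs: Sequence[str],
    records: Sequence[SequenceRecord],
    rng: np.random.Generator,
    n_sets: int = 30,
) -> dict[str, float]:
    """Per-gene expected coverage (bases) under the dinucleotide-matched null,
    estimated from a small internal simulant collection.  Falls back to the
    Markov-analytic expectation for un-simulatable sets."""
    from .catalog import MotifSet as _MS
    from .nulls import SimulantError, dinucleotide_pool, generate_simulant_set

    mset = (
        motif_set
        if isinstance(motif_set, _MS)
        else _MS(rbp_id="planted", motifs=frozenset(motifs))
    )
    encs = {r.gene_id: encode_seq(r.seq) for r in records}
    try:
        pool = dinucleotide_pool(mset)
        totals = {g: 0.0 for g in encs}
        for i in range(n_sets):
            sim = generate_simulant_set(
                mset, pool, rng=np.random.default_rng(rng.integers(2**31))
            )
            sim_scanner = MotifScanner(sorted(sim.motifs))
            for g, enc in encs.items():
                totals[g] += sim_scanner.covered(enc)
        return {g: t / n_sets for g, t in totals.items()}
    except (SimulantError, ValueError):
        exp_density = _expected_density(motifs, records)
        return {r.gene_id: exp_density * len(r.seq) for r in records}


def codon_expanded_mask(mask: np.ndarray) -> np.ndarray:
    """Expand a per-base mask so that any touched codon is fully covered."""
    mask = np.asarray(mask, dtype=bool)
    n = mask.size - mask.size % 3
    out = np.zeros_like(mask)
    codon_hit = mask[:n].reshape(-1, 3).any(axis=1)
    out[:n] = np.repeat(codon_hit, 3)
    out[n:] = mask[n:]
    return out


def _codon_safe(seq: list[str], lo: int, hi: int) -> bool:
    """No stop codon among the frame-0 codons intersecting [lo, hi)."""
    start = (lo // 3) * 3
    end = min(len(seq) - 3, ((hi + 2) // 3) * 3)
    for i in range(start, end, 3):
        if 3 <= i <= len(seq) - 6 and "".join(seq[i : i + 3]) in STOP_CODONS:
            return False
    return True


def plant_motifs(
    records: Sequence[SequenceRecord],
    motif_set: MotifSet | Iterable[str],
    multiplier: float,
    rng: np.random.Generator,
    max_attempts: int = 1000,
) -> tuple[list[SequenceRecord], dict[str, np.ndarray]]:
    """Plant (or disrupt) motif occurrences to reach a target density.

    The target is ``multiplier`` times the pre-existing background density of
    the set (with an analytic floor when the background carries no hits).
    Insertions and disruptive edits are frame-aware and never create an
    internal stop codon.  Returns the edited records and the realized
    per-gene coverage masks of the set.
    """
    motifs = _motifs_of(motif_set)
    scanner = MotifScanner(motifs)
    seqs = {r.gene_id: list(r.seq) for r in records}
    # Per-gene target: multiplier times the nucleotide-controlled expected
    # coverage, estimated as the mean coverage of a small internal simulant
    # collection (the same null the detector later normalizes against; an
    # analytic Markov expectation would miss the dinucleotide-order effects
    # that the shuffle null preserves).  Per-gene observed counts are too
    # noisy to anchor on.
    baseline = _simulant_baseline(motif_set, motifs, records, rng)
    half_k = 0.5 * float(np.mean([len(m) for m in motifs]))
    for r in records:
        seq = seqs[r.gene_id]
        pre = scanner.covered(encode_seq(r.seq))
        target = multiplier * baseline[r.gene_id]
        if multiplier > 1:
            cov = pre
            for _ in range(max_attempts):
                # stop within half a motif of the target: the final insertion
                # overshoots by ~U(0, k), so this centres realized coverage
                if cov >= target - half_k:
                    break
                m = motifs[rng.integers(len(motifs))]
                k = len(m)
                if len(seq) < k + 7:
                    break
                p = int(rng.integers(3, len(seq) - 3 - k + 1))
                old = seq[p : p + k]
                seq[p : p + k] = list(m)
                if _codon_safe(seq, p, p + k):
                    cov = scanner.covered(encode_seq("".join(seq)))
                else:
                    seq[p : p + k] = old
        elif multiplier < 1:
            for _ in range(max_attempts):
                enc = encode_seq("".join(seq))
                if scanner.covered(enc) <= target + (half_k if multiplier > 0 else 0):
                    break
                occ = [
                    (int(s), k)
                    for k, starts in scanner.hit_starts(enc).items()
                    for s in starts
                ]
                if not occ:
                    break
                s, k = occ[rng.integers(len(occ))]
                for _ in range(50):
                    i = int(rng.integers(s, s + k))
                    if i < 3 or i >= len(seq) - 3:
                        continue
                    alt = _BASES[rng.integers(4)]
                    if alt == seq[i]:
                        continue
                    old_b = seq[i]
                    seq[i] = alt
                    new_mask = scanner.mask(encode_seq("".join(seq)))
                    if _codon_safe(seq, i, i + 1) and not new_mask[s : s + k].all():
                        break
                    seq[i] = old_b

    out_records = [
        SequenceRecord(
            gene_id=r.gene_id,
            seq="".join(seqs[r.gene_id]),
            family_id=r.family_id,
            region_label=r.region_label,
            frame_offset=r.frame_offset,
        )
        for r in records
    ]
    masks = {
        r.gene_id: scanner.mask(encode_seq(r.seq)) for r in out_records
    }
    return out_records, masks


# ---------------------------------------------------------------------------
# ortholog evolution


def _creates_motif(seq: list[str], p: int, alt: str, scanner: MotifScanner) -> bool:
    """Would substituting alt at p create a motif occurrence absent at that
    offset in the current sequence?  (Per-offset comparison; simultaneous
    destruction of overlapping occurrences is ignored.)"""
    old = seq[p]
    motif_strings = scanner.motifs
    by_len: dict[int, set[str]] = {}
    for m in motif_strings:
        by_len.setdefault(len(m), set()).add(m)
    for k, ms in by_len.items():
        lo = max(0, p - k + 1)
        hi = min(len(seq) - k, p)
        for s in range(lo, hi + 1):
            window = seq[s : s + k]
            orig = "".join(window)
            mut = orig[: p - s] + alt + orig[p - s + 1 :]
            if mut in ms and orig not in ms:
                return True
    return False


def evolve_ortholog(
    records: Sequence[SequenceRecord],
    masks: dict[str, np.ndarray] | None,
    rate_motif: float,
    rate_background: float,
    gain_suppression: float = 0.0,
    avoided: MotifSet | Iterable[str] | None = None,
    rng: np.random.Generator | None = None,
) -> list[CodonAlignmentPair]:
    """Evolve a gap-free ortholog for each record at 4-fold degenerate sites.

    Each 4-fold third position substitutes with probability ``rate_motif``
    when covered by the mask (``rate_background`` otherwise); a proposed
    substitution that would create an occurrence of the ``avoided`` set is
    rejected with probability ``gain_suppression``.
    """
    rng = rng if rng is not None else np.random.default_rng()
    avoided_scanner = (
        MotifScanner(_motifs_of(avoided)) if avoided is not None else None
    )
    pairs = []
    for rec in records:
        seq = list(rec.seq)
        mask = None if masks is None else masks.get(rec.gene_id)
        for p in fourfold_sites(rec.seq):
            in_motif = bool(mask[p]) if mask is not None else False
            rate = rate_motif if in_motif else rate_background
            if rng.random() >= rate:
                continue
            alt = [b for b in _BASES if b != seq[p]][rng.integers(3)]
            if (
                avoided_scanner is not None
                and gain_suppression > 0
                and _creates_motif(seq, p, alt, avoided_scanner)
                and rng.random() < gain_suppression
            ):
                continue
            seq[p] = alt
        pairs.append(
            CodonAlignmentPair(gene_id=rec.gene_id, focal=rec.seq, ortholog="".join(seq))
        )
    return pairs


# ---------------------------------------------------------------------------
# expression tables


def simulate_expression_table(
    gene_ids: Sequence[str],
    rng: np.random.Generator,
    n_tissues: int = 50,
    breadth: Sequence[float] | tuple[float, float] = (0.8, 1.2),
    threshold: float = 5.0,
):
    """Gene x tissue TPM table with a controlled breadth distribution.

    ``breadth`` is either Beta(a, b) parameters or one target fraction per
    gene.  Expressed tissues receive TPM strictly above the threshold
    (threshold + lognormal); the rest receive near-zero noise.
    """
    import pandas as pd

    n = len(gene_ids)
    if isinstance(breadth, tuple) and len(breadth) == 2 and np.isscalar(breadth[0]):
        targets = rng.beta(breadth[0], breadth[1], size=n)
    else:
        targets = np.asarray(breadth, dtype=float)
        if targets.size != n:
            raise ValueError("one breadth target per gene required")
    tpm = rng.uniform(0.0, 2.0, size=(n, n_tissues))
    expressed = rng.random((n, n_tissues)) < targets[:, None]
    high = threshold + rng.lognormal(mean=math.log(30.0), sigma=1.0, size=(n, n_tissues))
    tpm[expressed] = high[expressed]
    return pd.DataFrame(
        tpm, index=list(gene_ids), columns=[f"tissue{t:02d}" for t in range(n_tissues)]
    )


# ---------------------------------------------------------------------------
# end-to-end bundle


def simulate_study(config: SimulationConfig) -> StudyData:
    """Run the full generator: CDSs, planting, orthologs, expression."""
    rng = np.random.default_rng(config.seed)
    records, families = simulate_background_cds(config, rng)
    masks: dict[str, dict[str, np.ndarray]] = {}
    for planted in config.planted:
        records, m = plant_motifs(records, planted.motif_set, planted.multiplier, rng)
        masks[planted.motif_set.rbp_id] = m
    # refresh masks after all planting rounds (later edits can alter earlier sets)
    for planted in config.planted:
        scanner = MotifScanner(sorted(planted.motif_set.motifs))
        masks[planted.motif_set.rbp_id] = {
            r.gene_id: scanner.mask(encode_seq(r.seq)) for r in records
        }
    # the conserved region is codon-granular: the slow synonymous rate applies
    # to every 4-fold site of a motif-overlapping codon, the same unit the
    # conservation statistics measure
    conserved_mask: dict[str, np.ndarray] | None = None
    for planted in config.planted:
        if planted.conserved:
            m = masks[planted.motif_set.rbp_id]
            if conserved_mask is None:
                conserved_mask = {g: codon_expanded_mask(v) for g, v in m.items()}
            else:
                for g in conserved_mask:
                    conserved_mask[g] |= codon_expanded_mask(m[g])
    avoided_union: set[str] = set()
    for planted in config.planted:
        if planted.avoided:
            avoided_union.update(planted.motif_set.motifs)
    pairs = evolve_ortholog(
        records,
        conserved_mask,
        config.rate_motif,
        config.rate_background,
        gain_suppression=config.gain_suppression,
        avoided=avoided_union or None,
        rng=rng,
    )
    expression = simulate_expression_table(
        [r.gene_id for r in records],
        rng,
        n_tissues=config.n_tissues,
        breadth=config.breadth_beta,
    )
    return StudyData(
        records=records,
        families=families,
        masks=masks,
        pairs=pairs,
        expression=expression,
        config=config,
    )
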