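"""Independent brute-force / first-principles oracles used by the tests.

These deliberately avoid the package's vectorised code paths: coverage by
substring testing every window, one-removed sites by mutating and rescanning
the whole sequence, 4-fold degeneracy by translating all 64 codons, and the
dip statistic by direct linear programming on its definition.
"""

from __future__ import annotations

import numpy as np
from Bio.Seq import Seq
from scipy.optimize import linprog


def brute_coverage(seq: str, motifs) -> np.ndarray:
    """Coverage mask by testing every substring of every motif length."""
    mask = np.zeros(len(seq), dtype=bool)
    for m in set(motifs):
        k = len(m)
        for s in range(len(seq) - k + 1):
            if seq[s : s + k] == m:
                mask[s : s + k] = True
    return mask


def brute_fourfold_codons() -> set[str]:
    """Codons with a 4-fold degenerate third position, via translation."""
    bases = "ACGT"
    out = set()
    for c1 in bases:
        for c2 in bases:
            aas = {str(Seq(c1 + c2 + b).translate()) for b in bases}
            if len(aas) == 1 and "*" not in aas:
                out.update(c1 + c2 + b for b in bases)
    return out


def brute_one_removed(seq: str, motifs) -> dict[int, set[str]]:
    """position -> creating bases, by full mutate-and-rescan.

    A substitution "creates" a motif when some (start, length) window of the
    mutated sequence is in the motif set while the same window of the
    original sequence is not.
    """
    fourfold = brute_fourfold_codons()
    motifs = set(motifs)
    lengths = {len(m) for m in motifs}

    def hits(s):
        return {
            (i, k)
            for k in lengths
            for i in range(len(s) - k + 1)
            if s[i : i + k] in motifs
        }

    base_hits = hits(seq)
    out: dict[int, set[str]] = {}
    for i in range(0, len(seq) - 2, 3):
        if seq[i : i + 3] not in fourfold:
            continue
        p = i + 2
        creating = set()
        for b in "ACGT":
            if b == seq[p]:
                continue
            mut = seq[:p] + b + seq[p + 1 :]
            new = hits(mut) - base_hits
            if any(s <= p < s + k for s, k in new):
                creating.add(b)
        if creating:
            out[p] = creating
    return out


def lp_dip(x) -> float:
    """Dip statistic by LP over all mode positions (definition-level oracle).

    Minimal d such that a continuous unimodal (convex-then-concave,
    monotone, [0,1]-bounded) function fits within d of the empirical cdf in
    sup norm.
    """
    x = np.sort(np.asarray(x, dtype=float))
    n = x.size
    xu, counts = np.unique(x, return_counts=True)
    c = np.cumsum(counts)
    A, B = c / n, (c - counts) / n
    K = xu.size
    if K == 1:
        return 0.0
    best = np.inf
    for t in range(K + 1):
        nv = K + 1  # g_0..g_{K-1}, d
        cost = np.zeros(nv)
        cost[-1] = 1.0
        A_ub, b_ub = [], []
        for i in range(K):
            row = np.zeros(nv); row[i] = 1; row[-1] = -1
            A_ub.append(row); b_ub.append(B[i])
            row = np.zeros(nv); row[i] = -1; row[-1] = -1
            A_ub.append(row); b_ub.append(-A[i])
        for i in range(K - 1):
            row = np.zeros(nv); row[i] = 1; row[i + 1] = -1
            A_ub.append(row); b_ub.append(0.0)
        for i in range(1, K - 1):
            dx1, dx2 = xu[i] - xu[i - 1], xu[i + 1] - xu[i]
            if i + 1 <= t - 1:  # convex triples inside left block
                row = np.zeros(nv)
                row[i - 1] = -1 / dx1; row[i] = 1 / dx1 + 1 / dx2; row[i + 1] = -1 / dx2
                A_ub.append(row); b_ub.append(0.0)
            if i - 1 >= t:  # concave triples inside right block
                row = np.zeros(nv)
                row[i - 1] = 1 / dx1; row[i] = -1 / dx1 - 1 / dx2; row[i + 1] = 1 / dx2
                A_ub.append(row); b_ub.append(0.0)
        res = linprog(
            cost,
            A_ub=np.array(A_ub),
            b_ub=np.array(b_ub),
            bounds=[(0, 1)] * K + [(0, None)],
            method="highs",
        )
        if res.status == 0:
            best = min(best, res.fun)
    return best
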