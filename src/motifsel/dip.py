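"""Hartigans' dip statistic and Monte-Carlo dip test of unimodality.

The dip of an empirical distribution function F_n is the smallest sup-norm
distance between F_n and any unimodal (convex-then-concave) continuous
distribution function.  Large values indicate multimodality; here the test
is applied to per-RBP enrichment P values, whose bimodal shape (peaks near
0 and near 1) is the signature of coexisting enriched and depleted motif
sets.

The implementation computes the dip exactly by bisection on the band
half-width d.  Unimodal G within the band [F_n - d, F_n + d] exists iff for
some mode position (between two order statistics) a convex monotone
function fits the band on the left block, a concave monotone one on the
right block, and the two can be joined monotonically.  Block feasibility
reduces to greatest-convex-minorant violations; the junction is checked via
pairwise slope certificates that bound the minimal left endpoint and the
maximal right start value.  The construction is validated in the test suite
against an independent linear-programming oracle.

P values are Monte Carlo: the observed dip is ranked within dips of uniform
samples of the same size, p = (#{boot >= observed} + 1) / (n_boot + 1).
Uniformity of the reference is appropriate for P-value inputs; for other
data the test is conservative in the usual rank sense.  Ties in the data
are collapsed into step heights; heavy ties inflate the dip relative to a
continuous null and are reported as-is.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class DipResult:
    d_stat: float
    p: float
    n_boot: int


def _steps(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unique sorted values with F_n right values (A) and left limits (B)."""
    x = np.sort(np.asarray(x, dtype=float))
    n = x.size
    xu, counts = np.unique(x, return_counts=True)
    c = np.cumsum(counts)
    return xu, c / n, (c - counts) / n


def _prefix_violations(xu: np.ndarray, A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """v[t] = minimal band width (2d) for a convex monotone fit on prefix t.

    Feasibility of a convex monotone function within [A - d, B + d] on the
    first t points is equivalent to the greatest convex minorant of B
    staying within 2d below A; v[t] is the largest such violation.
    """
    K = xu.size
    out = np.zeros(K + 1)
    out[1] = A[0] - B[0]
    hull = [0]
    for m in range(1, K):
        while len(hull) >= 2:
            i, j = hull[-2], hull[-1]
            if (B[j] - B[i]) * (xu[m] - xu[i]) >= (B[m] - B[i]) * (xu[j] - xu[i]):
                hull.pop()
            else:
                break
        hull.append(m)
        v = 0.0
        for s in range(len(hull) - 1):
            i, j = hull[s], hull[s + 1]
            idx = np.arange(i, j + 1)
            line = B[i] + (B[j] - B[i]) * (xu[idx] - xu[i]) / (xu[j] - xu[i])
            v = max(v, float(np.max(A[idx] - line)))
        out[m + 1] = v
    return out


class _BlockGeometry:
    """Precomputed pairwise terms for junction certificates of one block.

    For band half-width d the minimal feasible endpoint of a convex
    monotone fit on the prefix ending at t is
        Vmin(t) = max(l_t, max_{j<=t} [ l_j + s_j(d) * (x_t - x_j) ]),
    with l = A - d, u = B + d and s_j(d) = max(0, max_{i<j} (l_j - u_i) /
    (x_j - x_i)).  The numerators are affine in d, so everything is two
    matrix operations per evaluation.
    """

    def __init__(self, xu: np.ndarray, A: np.ndarray, B: np.ndarray) -> None:
        K = xu.size
        dx = xu[:, None] - xu[None, :]  # x_j - x_i at [j, i]
        lower = np.tril(np.ones((K, K), dtype=bool), -1)
        with np.errstate(divide="ignore", invalid="ignore"):
            self._s0 = np.where(lower, (A[:, None] - B[None, :]) / dx, -np.inf)
            self._sd = np.where(lower, 2.0 / dx, 0.0)
        self._xdiff = xu[None, :] - xu[:, None]  # x_t - x_j at [j, t]
        self._upper = np.triu(np.ones((K, K), dtype=bool), 0)  # j <= t
        self._A = A

    def vmin(self, d: float) -> np.ndarray:
        s = np.maximum((self._s0 - d * self._sd).max(axis=1), 0.0)
        lv = (self._A[:, None] - d) + s[:, None] * self._xdiff
        lv = np.where(self._upper, lv, -np.inf)
        return np.maximum(lv.max(axis=0), self._A - d)


def dip_statistic(x) -> float:
    """Exact dip statistic of a sample (sup distance to nearest unimodal cdf)."""
    x = np.asarray(x, dtype=float)
    if x.size < 1:
        raise ValueError("empty sample")
    xu, A, B = _steps(x)
    K = xu.size
    if K == 1:
        return 0.0  # point mass: trivially unimodal
    if K == 2:
        # no shape constraints possible; only band widths bind
        return 0.5 * max(A[0] - B[0], A[1] - B[1])
    dL = _prefix_violations(xu, A, B)
    xr, Ar, Br = -xu[::-1], 1 - B[::-1], 1 - A[::-1]
    dR = _prefix_violations(xr, Ar, Br)  # dR[s]: suffix of size s
    geom_l = _BlockGeometry(xu, A, B)
    geom_r = _BlockGeometry(xr, Ar, Br)

    t_all = np.arange(K + 1)
    block = np.maximum(dL[t_all], dR[K - t_all])

    def feasible(d: float) -> bool:
        ok = block <= 2 * d + 1e-15
        if not ok.any():
            return False
        vmin = geom_l.vmin(d)  # prefix sizes 1..K at index t-1
        wmax = 1.0 - geom_r.vmin(d)[::-1]  # start values of suffixes at point i
        for t in np.flatnonzero(ok):
            if t == 0:
                if wmax[0] >= -1e-15:
                    return True
            elif t == K:
                if max(vmin[K - 1], 0.0) <= 1 + 1e-15:
                    return True
            elif max(vmin[t - 1], 0.0) <= min(wmax[t], 1.0) + 1e-15:
                return True
        return False

    lo = 0.5 * float(block.min())
    if feasible(lo):
        return lo
    hi = 0.26
    for _ in range(50):
        mid = 0.5 * (lo + hi)
        if feasible(mid):
            hi = mid
        else:
            lo = mid
        if hi - lo < 1e-11:
            break
    return hi


def dip_uniform_null(n: int, n_boot: int, rng: np.random.Generator) -> np.ndarray:
    """Dip statistics of ``n_boot`` uniform samples of size n (the MC null)."""
    return np.array([dip_statistic(rng.uniform(size=n)) for _ in range(n_boot)])


def dip_test(
    values,
    n_boot: int = 2000,
    rng: np.random.Generator | None = None,
    null_dips: np.ndarray | None = None,
) -> DipResult:
    """Monte-Carlo dip test of unimodality against a uniform reference.

    ``null_dips`` allows sharing one precomputed null distribution across
    many tests of equal sample size.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 4:
        raise ValueError("dip test requires at least 4 values")
    d = dip_statistic(values)
    if null_dips is None:
        if rng is None:
            raise ValueError("provide rng or null_dips")
        null_dips = dip_uniform_null(values.size, n_boot, rng)
    n_boot = int(len(null_dips))
    p = (int(np.sum(null_dips >= d)) + 1) / (n_boot + 1)
    return DipResult(d_stat=d, p=p, n_boot=n_boot)
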