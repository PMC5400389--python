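"""Integer k-mer encoding used by the scanners.

Sequences are encoded base-per-base as int8 (A=0, C=1, G=2, T=3, anything
else -1).  Windows of length k are packed into base-4 integers so that
membership of every window of a sequence in a motif set reduces to a single
``np.isin`` call per motif length.  Windows containing a non-ACGT base are
flagged invalid and never match.
"""

from __future__ import annotations

import numpy as np

_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

BASES = "ACGT"


def encode_seq(seq: str) -> np.ndarray:
    """Encode a DNA string as an int8 array (A=0,C=1,G=2,T=3, other=-1)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def encode_kmer(kmer: str) -> int:
    """Pack an unambiguous k-mer into its base-4 integer code."""
    code = 0
    for b in kmer:
        v = _CODE[ord(b)]
        if v < 0:
            raise ValueError(f"cannot encode ambiguous base {b!r}")
        code = code * 4 + int(v)
    return code


def window_codes(encoded: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Base-4 codes of all length-k windows plus a validity mask.

    Returns ``(codes, valid)`` of length ``len(encoded) - k + 1`` (empty when
    the sequence is shorter than k).  Invalid windows (containing a base that
    failed to encode) carry an arbitrary code and ``valid`` False.
    """
    n = encoded.size - k + 1
    if n <= 0:
        return (np.empty(0, dtype=np.int64), np.empty(0, dtype=bool))
    x = np.where(encoded < 0, 0, encoded).astype(np.int64)
    codes = np.zeros(n, dtype=np.int64)
    for j in range(k):
        codes = codes * 4 + x[j : j + n]
    bad = (encoded < 0).astype(np.int32)
    cs = np.concatenate([[0], np.cumsum(bad)])
    valid = (cs[k:] - cs[:-k]) == 0
    return codes, valid


class MotifScanner:
    """Pre-compiled exact-match scanner for a set of unambiguous DNA motifs.

    Motifs are grouped by length; hits are computed per length with one
    vectorised membership test.  Scanning is sense-strand only.
    """

    _LUT_MAX_K = 10  # 4^10 bools = 1 MB; longer motifs fall back to np.isin

    def __init__(self, motifs) -> None:
        self.motifs = sorted(set(motifs))
        by_len: dict[int, list[int]] = {}
        for m in self.motifs:
            by_len.setdefault(len(m), []).append(encode_kmer(m))
        self._codes = {k: np.array(sorted(v), dtype=np.int64) for k, v in by_len.items()}
        self._lut = {}
        for k, codes in self._codes.items():
            if k <= self._LUT_MAX_K:
                lut = np.zeros(4**k, dtype=bool)
                lut[codes] = True
                self._lut[k] = lut

    def member(self, k: int, codes: np.ndarray) -> np.ndarray:
        """Vectorised membership of window codes in the length-k motif codes."""
        lut = self._lut.get(k)
        if lut is not None:
            return lut[codes]
        return np.isin(codes, self._codes[k])

    @property
    def lengths(self) -> list[int]:
        return sorted(self._codes)

    def hit_starts(self, encoded: np.ndarray) -> dict[int, np.ndarray]:
        """Start positions of motif occurrences, keyed by motif length."""
        out = {}
        for k in self._codes:
            wc, valid = window_codes(encoded, k)
            if wc.size == 0:
                out[k] = np.empty(0, dtype=np.int64)
                continue
            hit = self.member(k, wc) & valid
            out[k] = np.flatnonzero(hit)
        return out

    def mask(self, encoded: np.ndarray) -> np.ndarray:
        """Boolean per-base coverage mask with overlapping hits collapsed."""
        n = encoded.size
        delta = np.zeros(n + 1, dtype=np.int64)
        for k, starts in self.hit_starts(encoded).items():
            if starts.size:
                np.add.at(delta, starts, 1)
                np.add.at(delta, starts + k, -1)
        return np.cumsum(delta[:-1]) > 0

    def covered(self, encoded: np.ndarray) -> int:
        return int(self.mask(encoded).sum())
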