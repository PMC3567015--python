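"""Tamura–Nei (TN93) corrected sequence divergence.

The TN93 model allows unequal base frequencies and distinguishes the two
transition classes (A↔G within purines, C↔T within pyrimidines) from
transversions.  For a sequence pair with transition proportions P1 (A↔G),
P2 (C↔T) and transversion proportion Q, and base frequencies π_A..π_T with
π_R = π_A + π_G, π_Y = π_C + π_T, the corrected distance is

    d = −k1·ln(w1) − k2·ln(w2) − k3·ln(w3)

    k1 = 2 π_A π_G / π_R          w1 = 1 − P1/(2 π_A π_G / π_R) − Q/(2 π_R)
    k2 = 2 π_T π_C / π_Y          w2 = 1 − P2/(2 π_T π_C / π_Y) − Q/(2 π_Y)
    k3 = 2 (π_R π_Y − π_A π_G π_Y/π_R − π_T π_C π_R/π_Y)
                                  w3 = 1 − Q/(2 π_R π_Y)

Base frequencies are estimated from the pooled compared sequences (a
documented, configurable choice).  A non-positive log argument means the
pair is saturated under the model and raises ``SaturationError`` naming the
offending pair.  Distances within (Dx, Dy) and between (Dxy) two population
samples are means of pairwise corrected distances; Da = Dxy − (Dx+Dy)/2 is
the net corrected divergence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .data import MISSING_CODE, encode_alignment

__all__ = [
    "SaturationError",
    "tn93_pair_distance",
    "tn93_distance",
    "base_frequencies",
    "DistanceSummary",
    "distance_summary",
]


class SaturationError(ValueError):
    """TN93 correction undefined (log argument <= 0) for a sequence pair."""


def base_frequencies(*alignments) -> np.ndarray:
    """Empirical A/C/G/T frequencies over the pooled alignments (missing ignored)."""
    counts = np.zeros(4, dtype=float)
    for aln in alignments:
        a = encode_alignment(aln)
        for b in range(4):
            counts[b] += int((a == b).sum())
    total = counts.sum()
    if total == 0:
        raise ValueError("no non-missing bases; cannot estimate base frequencies")
    return counts / total


def _count_pair(x: np.ndarray, y: np.ndarray) -> tuple[int, int, int, int]:
    """(valid sites, A<->G transitions, C<->T transitions, transversions)."""
    valid = (x < MISSING_CODE) & (y < MISSING_CODE)
    nv = int(valid.sum())
    diff = (x != y) & valid
    # codes: A=0 C=1 G=2 T=3 → purines {0,2}, pyrimidines {1,3}
    xa, ya = x[diff], y[diff]
    ts1 = int((((xa == 0) & (ya == 2)) | ((xa == 2) & (ya == 0))).sum())
    ts2 = int((((xa == 1) & (ya == 3)) | ((xa == 3) & (ya == 1))).sum())
    tv = int(diff.sum()) - ts1 - ts2
    return nv, ts1, ts2, tv


def tn93_pair_distance(x, y, freqs=None, label: str = "") -> float:
    """TN93 corrected distance between two sequences.

    ``freqs`` are the A/C/G/T frequencies to use; estimated from the two
    sequences if not given.  Raises ``SaturationError`` when the correction
    is undefined.
    """
    def _one(s):
        if isinstance(s, np.ndarray) and s.ndim == 1:
            return np.asarray(s, dtype=np.int8)
        return encode_alignment([s])[0]

    x, y = _one(x), _one(y)
    if freqs is None:
        freqs = base_frequencies(x[None, :], y[None, :])
    nv, c1, c2, cv = _count_pair(x, y)
    if nv == 0:
        raise SaturationError(f"no jointly valid site for pair {label or '(unnamed)'}")
    P1, P2, Q = c1 / nv, c2 / nv, cv / nv
    if P1 == 0 and P2 == 0 and Q == 0:
        return 0.0
    fA, fC, fG, fT = freqs
    fR, fY = fA + fG, fC + fT

    def _ln(arg: float) -> float:
        if arg <= 0:
            raise SaturationError(
                f"TN93 saturated for pair {label or '(unnamed)'}: log argument {arg:.4g} <= 0"
            )
        return math.log(arg)

    d = 0.0
    if fA * fG > 0:
        k1 = 2 * fA * fG / fR
        d += -k1 * _ln(1 - P1 / k1 - Q / (2 * fR))
    elif P1 > 0:
        raise SaturationError(
            f"TN93 undefined for pair {label or '(unnamed)'}: A<->G changes with zero purine frequency"
        )
    if fT * fC > 0:
        k2 = 2 * fT * fC / fY
        d += -k2 * _ln(1 - P2 / k2 - Q / (2 * fY))
    elif P2 > 0:
        raise SaturationError(
            f"TN93 undefined for pair {label or '(unnamed)'}: C<->T changes with zero pyrimidine frequency"
        )
    if fR * fY > 0:
        k3 = 2 * (fR * fY - fA * fG * fY / fR - fT * fC * fR / fY)
        d += -k3 * _ln(1 - Q / (2 * fR * fY))
    elif Q > 0:
        raise SaturationError(
            f"TN93 undefined for pair {label or '(unnamed)'}: transversions with degenerate frequencies"
        )
    return d


def tn93_distance(seqs_a, seqs_b=None, freqs=None, label: str = "") -> float:
    """Mean TN93 corrected distance over sequence pairs.

    With one argument (or identical alignments) the mean runs over unordered
    within-set pairs; with two distinct sets over all cross pairs.  Base
    frequencies default to the pooled compared sequences.
    """
    a = encode_alignment(seqs_a)
    if seqs_b is None:
        b = None
    else:
        b = encode_alignment(seqs_b)
        # self-comparison → within-set unordered pairs (identical singleton
        # sequences remain an ordinary cross pair at distance 0)
        if seqs_b is seqs_a or (a.shape[0] >= 2 and b.shape == a.shape
                                and np.array_equal(a, b)):
            b = None
    if freqs is None:
        freqs = base_frequencies(a) if b is None else base_frequencies(a, b)
    dists = []
    if b is None:
        n = a.shape[0]
        if n < 2:
            raise ValueError("within-set TN93 needs >= 2 sequences")
        pairs = ((i, j) for i in range(n) for j in range(i + 1, n))
        rows_b = a
    else:
        pairs = ((i, j) for i in range(a.shape[0]) for j in range(b.shape[0]))
        rows_b = b
    for i, j in pairs:
        tag = f"{label}[{i},{j}]" if label else f"[{i},{j}]"
        dists.append(tn93_pair_distance(a[i], rows_b[j], freqs=freqs, label=tag))
    return float(np.mean(dists))


@dataclass
class DistanceSummary:
    """TN93 distance summary for a taxon pair: Dx, Dy within, Dxy between, Da net."""

    Dx: float
    Dy: float
    Dxy: float

    @property
    def Da(self) -> float:  # noqa: N802
        return self.Dxy - (self.Dx + self.Dy) / 2.0


def distance_summary(pair, pooled_freqs: bool = True) -> DistanceSummary:
    """DistanceSummary for a ``TaxonPair``.

    ``pooled_freqs=True`` (default) estimates base frequencies once from the
    union of both populations and uses them for every comparison, so Dx, Dy
    and Dxy are corrected on a common scale.
    """
    freqs = base_frequencies(pair.pop1, pair.pop2) if pooled_freqs else None
    dx = tn93_distance(pair.pop1, freqs=freqs, label=f"{pair.pair_id}/pop1")
    dy = tn93_distance(pair.pop2, freqs=freqs, label=f"{pair.pair_id}/pop2")
    dxy = tn93_distance(pair.pop1, pair.pop2, freqs=freqs, label=f"{pair.pair_id}/between")
    return DistanceSummary(Dx=dx, Dy=dy, Dxy=dxy)
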