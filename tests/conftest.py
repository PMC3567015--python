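"""Shared fixtures and independent brute-force oracles.

The oracle functions here are written directly from the textbook
definitions as plain double loops over sequence pairs and sites, on string
sequences — deliberately independent of the package's vectorized and
compiled implementations.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

BASES = "ACGT"


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


def random_alignment(rng, n, L, n_states=4, missing_frac=0.0):
    """Random alignment as strings, optionally with N/gap symbols."""
    mat = rng.integers(0, n_states, size=(n, L))
    seqs = []
    alphabet = BASES + "N-"
    for row in mat:
        chars = [BASES[b] for b in row]
        if missing_frac > 0:
            miss = rng.random(L) < missing_frac
            for i in np.nonzero(miss)[0]:
                chars[i] = alphabet[4 + int(rng.integers(0, 2))]
        seqs.append("".join(chars))
    return seqs


# ---------------------------------------------------------------------------
# brute-force statistic oracles (naive O(n^2 L) loops on strings)
# ---------------------------------------------------------------------------

def _valid(a: str, b: str) -> bool:
    return a in BASES and b in BASES


def similar_alignment(rng, n, L, n_mut=8):
    """Alignment of closely related sequences (base + few substitutions each)."""
    base = [BASES[b] for b in rng.integers(0, 4, size=L)]
    seqs = []
    for _ in range(n):
        chars = list(base)
        for i in rng.choice(L, size=min(n_mut, L), replace=False):
            chars[i] = BASES[int(rng.integers(0, 4))]
        seqs.append("".join(chars))
    return seqs


def oracle_pi(seqs) -> float:
    n = len(seqs)
    props = []
    for i in range(n):
        for j in range(i + 1, n):
            diffs = valid = 0
            for a, b in zip(seqs[i], seqs[j]):
                if _valid(a, b):
                    valid += 1
                    if a != b:
                        diffs += 1
            if valid:
                props.append(diffs / valid)
    return sum(props) / len(props)


def oracle_pi_between(pop1, pop2) -> float:
    props = []
    for x in pop1:
        for y in pop2:
            diffs = valid = 0
            for a, b in zip(x, y):
                if _valid(a, b):
                    valid += 1
                    if a != b:
                        diffs += 1
            if valid:
                props.append(diffs / valid)
    return sum(props) / len(props)


def oracle_segregating_sites(seqs) -> int:
    L = len(seqs[0])
    S = 0
    for site in range(L):
        seen = {s[site] for s in seqs if s[site] in BASES}
        if len(seen) >= 2:
            S += 1
    return S


def oracle_watterson(seqs) -> float:
    n = len(seqs)
    a1 = sum(1.0 / i for i in range(1, n))
    return oracle_segregating_sites(seqs) / (a1 * len(seqs[0]))


def oracle_tajimas_d(seqs) -> float:
    """Direct transcription of the published D formula and constants."""
    n = len(seqs)
    S = oracle_segregating_sites(seqs)
    if S == 0:
        return math.nan
    total = 0
    npairs = 0
    for i in range(n):
        for j in range(i + 1, n):
            npairs += 1
            total += sum(1 for a, b in zip(seqs[i], seqs[j])
                         if _valid(a, b) and a != b)
    pi_hat = total / npairs
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    return (pi_hat - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))


def oracle_tn93(x: str, y: str, freqs) -> float:
    """Independent transcription of the published TN93 distance formula."""
    fA, fC, fG, fT = freqs
    fR, fY = fA + fG, fC + fT
    valid = ts1 = ts2 = tv = 0
    for a, b in zip(x, y):
        if not _valid(a, b):
            continue
        valid += 1
        if a == b:
            continue
        if {a, b} == {"A", "G"}:
            ts1 += 1
        elif {a, b} == {"C", "T"}:
            ts2 += 1
        else:
            tv += 1
    P1, P2, Q = ts1 / valid, ts2 / valid, tv / valid
    k1 = 2 * fA * fG / fR
    k2 = 2 * fT * fC / fY
    k3 = 2 * (fR * fY - fA * fG * fY / fR - fT * fC * fR / fY)
    d = 0.0
    if k1 > 0:
        d += -k1 * math.log(1 - P1 / k1 - Q / (2 * fR))
    if k2 > 0:
        d += -k2 * math.log(1 - P2 / k2 - Q / (2 * fY))
    if k3 != 0:
        d += -k3 * math.log(1 - Q / (2 * fR * fY))
    return d


def oracle_p_distance(x: str, y: str) -> float:
    diffs = valid = 0
    for a, b in zip(x, y):
        if _valid(a, b):
            valid += 1
            if a != b:
                diffs += 1
    return diffs / valid
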