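"""Per-pair and across-pair summary statistics from sequence alignments.

Implements the statistic vector the hierarchical ABC engine compares between
observed and simulated data: within-population nucleotide diversity (π),
between-population diversity (π_b), net divergence (π_net), Watterson's θ_W
and Tajima's D per population, plus across-pair means and variances.

All statistics exclude sites with missing data (N or gap) pairwise: a site
is dropped only for sequence pairs in which either member is missing it.
π-type statistics are per-pair proportions of differing sites averaged over
pairs, so ragged field data lose no information; on complete data this is
identical to the classical count formulas.
"""

from __future__ import annotations

import math

import numpy as np

from .data import MISSING_CODE, encode_alignment

__all__ = [
    "UndefinedStatisticError",
    "nucleotide_diversity",
    "watterson_theta",
    "tajimas_d",
    "between_diversity",
    "net_divergence",
    "segregating_sites",
    "pair_summary_vector",
    "hyper_summary",
    "study_vector",
    "study_vector_names",
    "PAIR_STAT_NAMES",
    "STAT_LAYOUT_VERSION",
]

#: per-pair statistic slots, in fixed output order
PAIR_STAT_NAMES = (
    "pi_1",
    "pi_2",
    "pi_b",
    "pi_net",
    "theta_w_1",
    "theta_w_2",
    "tajd_1",
    "tajd_2",
)

#: bumped whenever the statistic vector layout changes; written into headers
STAT_LAYOUT_VERSION = "1"


class UndefinedStatisticError(ValueError):
    """Raised when a statistic is requested from too small a sample."""


def _as_matrix(seqs) -> np.ndarray:
    return encode_alignment(seqs)


def _pairwise_mean_proportion(a: np.ndarray, b: np.ndarray | None = None) -> float:
    """Mean over sequence pairs of (differing sites / jointly valid sites).

    ``b is None`` → unordered pairs within ``a``; otherwise all cross pairs.
    Pairs with no jointly valid site are excluded from the mean.
    """
    props = []
    if b is None:
        n = a.shape[0]
        index_pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
        rows_a, rows_b = a, a
    else:
        index_pairs = [(i, j) for i in range(a.shape[0]) for j in range(b.shape[0])]
        rows_a, rows_b = a, b
    for i, j in index_pairs:
        x, y = rows_a[i], rows_b[j]
        valid = (x < MISSING_CODE) & (y < MISSING_CODE)
        nv = int(valid.sum())
        if nv == 0:
            continue
        props.append(int(((x != y) & valid).sum()) / nv)
    if not props:
        raise UndefinedStatisticError("no sequence pair shares a valid site")
    return float(np.mean(props))


def nucleotide_diversity(seqs) -> float:
    """Per-site nucleotide diversity π: mean pairwise difference proportion."""
    a = _as_matrix(seqs)
    if a.shape[0] < 2:
        raise UndefinedStatisticError(
            f"nucleotide diversity needs >= 2 sequences, got {a.shape[0]}"
        )
    return _pairwise_mean_proportion(a)


def between_diversity(pop1_seqs, pop2_seqs) -> float:
    """Per-site mean diversity π_b over all n1·n2 between-population pairs."""
    a, b = _as_matrix(pop1_seqs), _as_matrix(pop2_seqs)
    if a.shape[0] < 1 or b.shape[0] < 1:
        raise UndefinedStatisticError("between-population diversity needs >= 1 sequence per side")
    if a.shape[1] != b.shape[1]:
        raise UndefinedStatisticError("alignments differ in length")
    return _pairwise_mean_proportion(a, b)


def net_divergence(pi_b: float, pi_1: float, pi_2: float) -> float:
    """Net divergence π_net = π_b − (π_1 + π_2)/2 (Nei's d_A on raw diversities)."""
    return pi_b - (pi_1 + pi_2) / 2.0


def segregating_sites(seqs) -> int:
    """Number of sites carrying >= 2 distinct non-missing bases."""
    a = _as_matrix(seqs)
    S = 0
    for col in a.T:
        bases = col[col < MISSING_CODE]
        if bases.size >= 2 and np.unique(bases).size >= 2:
            S += 1
    return S


def _harmonic(n: int) -> float:
    return sum(1.0 / i for i in range(1, n))


def watterson_theta(seqs) -> float:
    """Watterson's θ_W per site: S / (a1 · L), a1 = Σ_{i<n} 1/i."""
    a = _as_matrix(seqs)
    n, L = a.shape
    if n < 2:
        raise UndefinedStatisticError(f"Watterson's theta needs >= 2 sequences, got {n}")
    if L == 0:
        raise UndefinedStatisticError("empty alignment")
    return segregating_sites(a) / (_harmonic(n) * L)


def _mean_pairwise_differences(a: np.ndarray) -> float:
    """Mean raw pairwise difference count (Tajima's π̂, not per site)."""
    n = a.shape[0]
    total = 0
    for i in range(n):
        for j in range(i + 1, n):
            valid = (a[i] < MISSING_CODE) & (a[j] < MISSING_CODE)
            total += int(((a[i] != a[j]) & valid).sum())
    return total / (n * (n - 1) / 2)


def tajimas_d(seqs) -> float:
    """Tajima's (1989) D with the canonical constants.

    Returns NaN (undefined sentinel) when S = 0; requires >= 3 sequences.
    """
    a = _as_matrix(seqs)
    n = a.shape[0]
    if n < 3:
        raise UndefinedStatisticError(f"Tajima's D needs >= 3 sequences, got {n}")
    S = segregating_sites(a)
    if S == 0:
        return math.nan
    a1 = _harmonic(n)
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    pi_hat = _mean_pairwise_differences(a)
    denom = math.sqrt(e1 * S + e2 * S * (S - 1))
    if denom == 0.0:  # n=3: the variance constants vanish identically
        return math.nan
    return (pi_hat - S / a1) / denom


def pair_summary_vector(pair) -> np.ndarray:
    """Ordered per-pair statistic vector (see ``PAIR_STAT_NAMES``).

    Within-population statistics on a side with fewer than 2 sequences, and
    Tajima's D wherever undefined, are NaN; the table builder maps NaN to 0
    so observed and simulated vectors stay directly comparable.
    """
    p1, p2 = pair.pop1, pair.pop2

    def _within(a):
        if a.shape[0] >= 2:
            pi = _pairwise_mean_proportion(a)
            tw = watterson_theta(a)
        else:
            pi, tw = math.nan, math.nan
        if a.shape[0] >= 3:
            d = tajimas_d(a)
        else:
            d = math.nan
        return pi, tw, d

    pi1, tw1, d1 = _within(p1)
    pi2, tw2, d2 = _within(p2)
    pib = _pairwise_mean_proportion(p1, p2)
    if math.isnan(pi1) or math.isnan(pi2):
        pinet = math.nan
    else:
        pinet = net_divergence(pib, pi1, pi2)
    return np.array([pi1, pi2, pib, pinet, tw1, tw2, d1, d2], dtype=float)


def finalize_vector(vec: np.ndarray) -> np.ndarray:
    """Map undefined (NaN) slots to 0.0 for distance computation."""
    out = np.asarray(vec, dtype=float).copy()
    out[np.isnan(out)] = 0.0
    return out


def hyper_summary(vectors) -> np.ndarray:
    """Across-pair mean and variance of every per-pair statistic.

    ``vectors`` is a (Y, k) matrix of per-pair statistics (NaN already
    finalized); returns length 2k: [mean(stat_1), …, mean(stat_k),
    var(stat_1), …, var(stat_k)] with population variance (ddof=0), so a
    single pair gives zero variances.
    """
    m = np.atleast_2d(np.asarray(vectors, dtype=float))
    return np.concatenate([m.mean(axis=0), m.var(axis=0)])


def study_vector(per_pair: np.ndarray) -> np.ndarray:
    """Full comparison vector: per-pair slots (row-major) then hyper slots."""
    m = np.atleast_2d(np.asarray(per_pair, dtype=float))
    m = finalize_vector(m)
    return np.concatenate([m.ravel(), hyper_summary(m)])


def study_vector_names(n_pairs: int) -> list[str]:
    names = [f"{s}.p{i + 1}" for i in range(n_pairs) for s in PAIR_STAT_NAMES]
    names += [f"{s}.mean" for s in PAIR_STAT_NAMES]
    names += [f"{s}.var" for s in PAIR_STAT_NAMES]
    return names
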