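"""Compiled kernels for the isolation-with-migration coalescent simulator.

Everything here works on flat arrays and is numba-compiled so that building
ABC reference tables (tens of thousands of simulated taxon-pair data sets)
runs at practical speed on one core.  The object-level API in
:mod:`codivabc.simulate` wraps these kernels.

Scaling convention (shared with the rest of the package): one time unit is
the expected pairwise coalescence time of the reference population defined
by theta_ref; a population with scaled diversity theta and locus rate
multiplier rho has pairwise coalescence rate ``rho * theta_ref / theta``,
and mutations fall per site per lineage at ``rho * theta_ref / 2`` per unit.

Mutation model: per-site 4-state chain with transition/transversion
parameter kappa and uniform base frequencies (K80/HKY form).  Sites are
independent given the genealogy, so each branch can be realised either by
explicit Poisson mutation events or by sampling every site from the exact
finite-time transition probabilities — the two are distribution-identical;
the kernel picks whichever needs fewer random draws (events on short
branches, per-site sampling on near-saturated ones).  Because the chain is
reversible and stationary, one child branch of the root is folded into its
sibling (the root sequence is sampled at that child), which removes one
long branch from deep genealogies.

Random draws are consumed in a fixed order, so the summary-statistic fast
path and the full-alignment path agree bit-for-bit through the shared
prefix of the stream for the same seed.
"""

from __future__ import annotations

import numpy as np
from numba import njit

#: guard against pathological parameter draws
MAX_EVENTS = 10_000_000
#: floor applied to theta values before building rates (avoids 0-division;
#: a floored population coalesces essentially instantly)
THETA_FLOOR = 1e-12
#: a branch expecting more than this fraction of L mutations is realised by
#: per-site transition sampling instead of explicit events
PER_SITE_THRESHOLD = 0.5


# ---------------------------------------------------------------------------
# genealogy
# ---------------------------------------------------------------------------

@njit(cache=True)
def _genealogy(n1, n2, lam1, lam2, lamA, tau, mig1, mig2):
    """Structured coalescent for two populations merging (backward) at tau.

    Returns (parent, node_time, root).  Nodes 0..n-1 are tips (pop 1 first),
    internal nodes are appended in coalescence order; parent[root] = -1.
    """
    n = n1 + n2
    n_nodes = 2 * n - 1
    parent = np.full(n_nodes, -1, np.int32)
    node_time = np.zeros(n_nodes, np.float64)

    act = np.empty(n, np.int32)
    pop = np.empty(n, np.int8)
    for i in range(n1):
        act[i] = i
        pop[i] = 0
    for i in range(n2):
        act[n1 + i] = n1 + i
        pop[n1 + i] = 1
    k = n
    nxt = n
    t = 0.0
    merged = tau <= 0.0
    events = 0

    while k > 1:
        events += 1
        if events > MAX_EVENTS:
            raise RuntimeError("coalescent event cap exceeded; pathological parameters")

        if merged:
            rate = 0.5 * k * (k - 1) * lamA
            if rate <= 0.0:
                raise RuntimeError("zero coalescence rate in ancestral population")
            t += np.random.exponential(1.0 / rate)
            i = np.random.randint(k)
            j = np.random.randint(k - 1)
            if j >= i:
                j += 1
        else:
            k1 = 0
            for a in range(k):
                if pop[a] == 0:
                    k1 += 1
            k2 = k - k1
            r1 = 0.5 * k1 * (k1 - 1) * lam1
            r2 = 0.5 * k2 * (k2 - 1) * lam2
            rm1 = k1 * mig1
            rm2 = k2 * mig2
            total = r1 + r2 + rm1 + rm2
            if total <= 0.0:
                t = tau
                merged = True
                continue
            dt = np.random.exponential(1.0 / total)
            if t + dt >= tau:
                t = tau
                merged = True
                continue
            t += dt
            u = np.random.random() * total
            if u < r1 + r2:
                target = 0 if u < r1 else 1
                kk = k1 if target == 0 else k2
                a = np.random.randint(kk)
                b = np.random.randint(kk - 1)
                if b >= a:
                    b += 1
                # map pop-local indices to positions in act
                i = -1
                j = -1
                c = 0
                for p in range(k):
                    if pop[p] == target:
                        if c == a:
                            i = p
                        if c == b:
                            j = p
                        c += 1
            else:
                # migration: flip one lineage's population label
                target = 0 if u < r1 + r2 + rm1 else 1
                kk = k1 if target == 0 else k2
                a = np.random.randint(kk)
                c = 0
                for p in range(k):
                    if pop[p] == target:
                        if c == a:
                            pop[p] = 1 - pop[p]
                            break
                        c += 1
                continue

        # coalesce active positions i and j into a new node
        node = nxt
        nxt += 1
        node_time[node] = t
        parent[act[i]] = node
        parent[act[j]] = node
        new_pop = np.int8(0) if merged else pop[i]
        # remove higher position first to keep the lower index valid
        hi = i if i > j else j
        lo = j if i > j else i
        act[hi] = act[k - 1]
        pop[hi] = pop[k - 1]
        k -= 1
        act[lo] = act[k - 1]
        pop[lo] = pop[k - 1]
        k -= 1
        act[k] = node
        pop[k] = new_pop
        k += 1

    return parent, node_time, nxt - 1


@njit(cache=True)
def _effective_branch_lengths(parent, node_time, root):
    """Branch lengths with one root-child branch folded into its sibling.

    Valid because the mutation chain is reversible and stationary: sampling
    the root state at one child and evolving the sibling over the summed
    length gives the same joint tip distribution.
    """
    n_nodes = parent.shape[0]
    blen = np.zeros(n_nodes, np.float64)
    for v in range(n_nodes):
        if v != root:
            blen[v] = node_time[parent[v]] - node_time[v]
    c1 = -1
    c2 = -1
    for v in range(n_nodes):
        if parent[v] == root:
            if c1 < 0:
                c1 = v
            else:
                c2 = v
    if c2 >= 0:
        # fold the longer root branch into the shorter one's sibling
        if blen[c1] >= blen[c2]:
            blen[c2] += blen[c1]
            blen[c1] = 0.0
        else:
            blen[c1] += blen[c2]
            blen[c2] = 0.0
    return blen


# ---------------------------------------------------------------------------
# mutation primitives
# ---------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _mutate_base(b, kappa):
    """One substitution event under the kappa-weighted kernel.

    Codes A=0 C=1 G=2 T=3; the transition partner ((b+2) % 4) has relative
    weight kappa against 1 for each of the two transversion targets.
    """
    u = np.random.random()
    if u < kappa / (kappa + 2.0):
        return (b + 2) % 4
    v = np.random.random()
    if b == 0 or b == 2:  # purine -> pyrimidine
        return np.int8(1) if v < 0.5 else np.int8(3)
    return np.int8(0) if v < 0.5 else np.int8(2)


@njit(cache=True, inline="always")
def _k80_cumulative(mu_t, kappa):
    """Cumulative per-site transition probabilities after time mu_t·(1/mu).

    ``mu_t`` is rate×time for the branch.  Returns thresholds
    (stay, stay+transition, stay+transition+first transversion); the two
    transversion targets are equiprobable.
    """
    alpha = mu_t * kappa / (kappa + 2.0)
    beta = mu_t / (kappa + 2.0)
    e1 = np.exp(-4.0 * beta)
    e2 = np.exp(-2.0 * (alpha + beta))
    p_stay = 0.25 + 0.25 * e1 + 0.5 * e2
    p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
    p_tv = 0.25 - 0.25 * e1
    return p_stay, p_stay + p_ts, p_stay + p_ts + p_tv


@njit(cache=True, inline="always")
def _evolve_site(b, t1, t2, t3, u):
    if u < t1:
        return b
    if u < t2:
        return (b + 2) % 4
    if b == 0 or b == 2:
        return np.int8(1) if u < t3 else np.int8(3)
    return np.int8(0) if u < t3 else np.int8(2)


# ---------------------------------------------------------------------------
# sparse path: explicit mutation events on compact (touched-site) columns
# ---------------------------------------------------------------------------

@njit(cache=True)
def _branch_mutations(blen, root, L, mu):
    """Poisson mutation counts per branch and their uniform site draws."""
    n_nodes = blen.shape[0]
    counts = np.zeros(n_nodes, np.int64)
    total = 0
    for v in range(n_nodes):
        if v == root:
            continue
        c = np.random.poisson(mu * L * blen[v])
        counts[v] = c
        total += c
    sites = np.empty(total, np.int64)
    k = 0
    for v in range(n_nodes):
        for _ in range(counts[v]):
            sites[k] = np.random.randint(L)
            k += 1
    return counts, sites


@njit(cache=True)
def _compact_sites(sites, L):
    """Map mutated sites to compact column indices in first-appearance order."""
    site2col = np.full(L, -1, np.int64)
    cols = np.empty(sites.shape[0], np.int64)
    touched = np.empty(sites.shape[0], np.int64)
    T = 0
    for k in range(sites.shape[0]):
        s = sites[k]
        if site2col[s] < 0:
            site2col[s] = T
            touched[T] = s
            T += 1
        cols[k] = site2col[s]
    return cols, touched[:T], T


@njit(cache=True)
def _propagate_sparse(parent, node_time, root, counts, cols, T, kappa, n_tips):
    """Root-to-tip propagation over the mutated (compact) columns."""
    n_nodes = parent.shape[0]
    seq = np.empty((n_nodes, T), np.int8)
    offs = np.zeros(n_nodes + 1, np.int64)
    for v in range(n_nodes):
        offs[v + 1] = offs[v] + counts[v]
    for c in range(T):
        seq[root, c] = np.int8(np.random.randint(4))
    order = np.argsort(-node_time)  # parents strictly precede children
    for oi in range(n_nodes):
        v = order[oi]
        if v != root:
            p = parent[v]
            for c in range(T):
                seq[v, c] = seq[p, c]
        for k in range(offs[v], offs[v + 1]):
            c = cols[k]
            seq[v, c] = _mutate_base(seq[v, c], kappa)
    return seq[:n_tips]


# ---------------------------------------------------------------------------
# dense path: full-length columns, per-site sampling on saturated branches
# ---------------------------------------------------------------------------

@njit(cache=True)
def _propagate_dense(parent, node_time, root, blen, n_tips, L, mu, kappa):
    """Root-to-tip propagation over all L sites.

    Branches expecting more than ``PER_SITE_THRESHOLD * L`` mutations are
    realised by exact per-site transition sampling; the rest by explicit
    events.  Both give the same distribution; the split only trades random
    draws.
    """
    n_nodes = parent.shape[0]
    seq = np.empty((n_nodes, L), np.int8)
    for s in range(L):
        seq[root, s] = np.int8(np.random.randint(4))
    order = np.argsort(-node_time)
    for oi in range(n_nodes):
        v = order[oi]
        if v == root:
            continue
        p = parent[v]
        for s in range(L):
            seq[v, s] = seq[p, s]
        m_exp = mu * L * blen[v]
        if m_exp > PER_SITE_THRESHOLD * L:
            t1, t2, t3 = _k80_cumulative(mu * blen[v], kappa)
            for s in range(L):
                seq[v, s] = _evolve_site(seq[v, s], t1, t2, t3, np.random.random())
        elif m_exp > 0.0:
            c = np.random.poisson(m_exp)
            for _ in range(c):
                s = np.random.randint(L)
                seq[v, s] = _mutate_base(seq[v, s], kappa)
    return seq[:n_tips]


@njit(cache=True, inline="always")
def _use_dense(blen, root, L, mu):
    for v in range(blen.shape[0]):
        if v != root and mu * L * blen[v] > PER_SITE_THRESHOLD * L:
            return True
    return False


# ---------------------------------------------------------------------------
# summary statistics (clean data, allele-count formulas)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _tajimas_d_from_counts(n, S, pi_hat):
    a1 = 0.0
    a2 = 0.0
    for i in range(1, n):
        a1 += 1.0 / i
        a2 += 1.0 / (i * i)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / (a1 * a1)
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    denom = np.sqrt(e1 * S + e2 * S * (S - 1.0))
    if denom == 0.0:  # n=3: the variance constants vanish identically
        return np.nan
    return (pi_hat - S / a1) / denom


@njit(cache=True)
def _harmonic(n):
    h = 0.0
    for i in range(1, n):
        h += 1.0 / i
    return h


@njit(cache=True)
def _count_stats(tips, n1, n2, L):
    """[pi1, pi2, pi_b, pi_net, thetaW1, thetaW2, D1, D2] from allele counts.

    ``tips`` holds the polymorphism-capable columns (all L in dense mode,
    the mutation-touched subset in sparse mode — omitted columns are
    monomorphic and contribute zero differences).  NaN marks undefined
    slots.
    """
    n = n1 + n2
    T = tips.shape[1]
    counts = np.zeros((T, 8), np.int32)  # cols 0-3 pop1, 4-7 pop2
    for i in range(n1):
        for c in range(T):
            counts[c, tips[i, c]] += 1
    for i in range(n1, n):
        for c in range(T):
            counts[c, 4 + tips[i, c]] += 1

    d1 = 0
    d2 = 0
    db = 0
    S1 = 0
    S2 = 0
    for c in range(T):
        s1 = 0
        s2 = 0
        cross = 0
        mx1 = 0
        mx2 = 0
        for b in range(4):
            x1 = counts[c, b]
            x2 = counts[c, 4 + b]
            s1 += x1 * x1
            s2 += x2 * x2
            cross += x1 * x2
            if x1 > mx1:
                mx1 = x1
            if x2 > mx2:
                mx2 = x2
        d1 += (n1 * n1 - s1) // 2
        d2 += (n2 * n2 - s2) // 2
        db += n1 * n2 - cross
        if n1 >= 2 and mx1 < n1:
            S1 += 1
        if n2 >= 2 and mx2 < n2:
            S2 += 1

    out = np.empty(8, np.float64)
    nan = np.nan
    if n1 >= 2:
        pairs1 = n1 * (n1 - 1) / 2.0
        pi1 = d1 / (pairs1 * L)
        tw1 = S1 / (_harmonic(n1) * L)
        D1 = _tajimas_d_from_counts(n1, S1, d1 / pairs1) if (n1 >= 3 and S1 > 0) else nan
    else:
        pi1 = nan
        tw1 = nan
        D1 = nan
    if n2 >= 2:
        pairs2 = n2 * (n2 - 1) / 2.0
        pi2 = d2 / (pairs2 * L)
        tw2 = S2 / (_harmonic(n2) * L)
        D2 = _tajimas_d_from_counts(n2, S2, d2 / pairs2) if (n2 >= 3 and S2 > 0) else nan
    else:
        pi2 = nan
        tw2 = nan
        D2 = nan
    pib = db / (n1 * n2 * L) if (n1 >= 1 and n2 >= 1) else nan
    pinet = pib - (pi1 + pi2) / 2.0  # NaN propagates if a side is undefined
    out[0] = pi1
    out[1] = pi2
    out[2] = pib
    out[3] = pinet
    out[4] = tw1
    out[5] = tw2
    out[6] = D1
    out[7] = D2
    return out


# ---------------------------------------------------------------------------
# seeded entry points
# ---------------------------------------------------------------------------

@njit(cache=True)
def _pair_stats(n1, n2, L, lam1, lam2, lamA, tau, mig1, mig2, mu, kappa):
    parent, node_time, root = _genealogy(n1, n2, lam1, lam2, lamA, tau, mig1, mig2)
    blen = _effective_branch_lengths(parent, node_time, root)
    n_tips = n1 + n2
    if _use_dense(blen, root, L, mu):
        tips = _propagate_dense(parent, node_time, root, blen, n_tips, L, mu, kappa)
    else:
        counts, sites = _branch_mutations(blen, root, L, mu)
        cols, touched, T = _compact_sites(sites, L)
        tips = _propagate_sparse(parent, node_time, root, counts, cols, T, kappa, n_tips)
    return _count_stats(tips, n1, n2, L)


@njit(cache=True)
def _sim_pair_stats_seeded(seed, n1, n2, L, lam1, lam2, lamA, tau,
                           mig1, mig2, mu, kappa):
    np.random.seed(seed)
    return _pair_stats(n1, n2, L, lam1, lam2, lamA, tau, mig1, mig2, mu, kappa)


@njit(cache=True)
def _mutate_full(parent, node_time, root, blen, n_tips, L, mu, kappa):
    """Full simulated alignment (n_tips, L) for one genealogy."""
    if _use_dense(blen, root, L, mu):
        return _propagate_dense(parent, node_time, root, blen, n_tips, L, mu, kappa)
    counts, sites = _branch_mutations(blen, root, L, mu)
    cols, touched, T = _compact_sites(sites, L)
    tips = _propagate_sparse(parent, node_time, root, counts, cols, T, kappa, n_tips)
    aln = np.empty((n_tips, L), np.int8)
    mask = np.zeros(L, np.uint8)
    for c in range(T):
        s = touched[c]
        mask[s] = 1
        for i in range(n_tips):
            aln[i, s] = tips[i, c]
    for s in range(L):
        if mask[s] == 0:
            b = np.int8(np.random.randint(4))
            for i in range(n_tips):
                aln[i, s] = b
    return aln


@njit(cache=True)
def _sim_pair_alignment_seeded(seed, n1, n2, L, lam1, lam2, lamA, tau,
                               mig1, mig2, mu, kappa):
    np.random.seed(seed)
    parent, node_time, root = _genealogy(n1, n2, lam1, lam2, lamA, tau, mig1, mig2)
    blen = _effective_branch_lengths(parent, node_time, root)
    return _mutate_full(parent, node_time, root, blen, n1 + n2, L, mu, kappa)


@njit(cache=True)
def _genealogy_seeded(seed, n1, n2, lam1, lam2, lamA, tau, mig1, mig2):
    np.random.seed(seed)
    return _genealogy(n1, n2, lam1, lam2, lamA, tau, mig1, mig2)


@njit(cache=True)
def _mutate_full_seeded(seed, parent, node_time, root, n_tips, L, mu, kappa):
    np.random.seed(seed)
    blen = _effective_branch_lengths(parent, node_time, root)
    return _mutate_full(parent, node_time, root, blen, n_tips, L, mu, kappa)


@njit(cache=True)
def _sim_batch(seeds, n1, n2, L, lam1, lam2, lamA, tau, mig1, mig2, mu, kappa):
    """Simulate many parameter draws for one taxon pair; (n_sims, 8) stats."""
    n_sims = seeds.shape[0]
    out = np.empty((n_sims, 8), np.float64)
    for i in range(n_sims):
        np.random.seed(seeds[i])
        out[i] = _pair_stats(n1, n2, L, lam1[i], lam2[i], lamA[i], tau[i],
                             mig1[i], mig2[i], mu, kappa)
    return out
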