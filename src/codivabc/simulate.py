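"""Two-population isolation-with-migration coalescent simulator.

One taxon pair is modelled as two descendant populations that split from an
ancestral population at time ``tau`` (looking back) and exchange migrants at
scaled rates ``m1``/``m2`` until the split.  Genealogies follow the
structured coalescent; sequences evolve under a finite-sites HKY-style
kernel with transition/transversion parameter ``kappa`` and uniform base
frequencies.

Scaling convention
------------------
All times (``tau``, branch lengths) are measured in units of the expected
pairwise coalescence time of a *reference* population with scaled diversity
``theta_ref`` (in the hierarchical engine ``theta_ref = theta_max / 2``).
For a population with per-site ``theta`` and locus rate multiplier ``rho``:

* pairwise coalescence rate: ``rho * theta_ref / theta`` per unit time,
  i.e. expected pairwise TMRCA ``theta / (rho * theta_ref)``;
* per-site mutation rate per lineage: ``rho * theta_ref / 2`` per unit time.

Consequences used as closed-form checks elsewhere: within-population
E[pi] = theta (independent of ``rho``), and with no migration
dE[pi_net]/dtau = rho * theta_ref.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from ._kernels import THETA_FLOOR

__all__ = ["PairModelParams", "Genealogy", "simulate_genealogy",
           "sprinkle_mutations", "simulate_pair_stats"]


@dataclass
class PairModelParams:
    """Demographic and mutational parameters for one taxon pair."""

    theta_1: float
    theta_2: float
    theta_a: float
    tau: float
    n1: int
    n2: int
    L: int
    theta_ref: float
    m_1: float = 0.0
    m_2: float = 0.0
    rate_multiplier: float = 1.0
    kappa: float = 4.0

    def __post_init__(self):
        if min(self.theta_1, self.theta_2, self.theta_a) < 0:
            raise ValueError("theta values must be >= 0")
        if self.tau < 0 or self.m_1 < 0 or self.m_2 < 0:
            raise ValueError("tau and migration rates must be >= 0")
        if self.n1 + self.n2 < 2:
            raise ValueError("need at least 2 sampled sequences in total")
        if self.L < 1:
            raise ValueError("locus length must be >= 1")
        if self.theta_ref < 0 or self.rate_multiplier <= 0:
            raise ValueError("theta_ref must be >= 0 and rate_multiplier > 0")

    # per-unit-time rates under the documented scaling -----------------
    @property
    def _ref(self) -> float:
        return max(self.theta_ref, THETA_FLOOR)

    def coalescence_rate(self, which: str) -> float:
        theta = {"1": self.theta_1, "2": self.theta_2, "a": self.theta_a}[which]
        return self.rate_multiplier * self._ref / max(theta, THETA_FLOOR)

    @property
    def mutation_rate(self) -> float:
        """Per-site per-lineage mutation rate per time unit."""
        return self.rate_multiplier * self.theta_ref / 2.0


@dataclass
class Genealogy:
    """Binary genealogy over n1+n2 tips; times in reference units.

    Tips 0..n1-1 sample population 1, tips n1..n1+n2-1 population 2;
    ``parent[root] == -1``.
    """

    parent: np.ndarray
    node_time: np.ndarray
    root: int
    n1: int
    n2: int
    params: PairModelParams | None = field(default=None, repr=False)

    @property
    def n_tips(self) -> int:
        return self.n1 + self.n2

    @property
    def tmrca(self) -> float:
        return float(self.node_time[self.root])

    def total_branch_length(self) -> float:
        bl = 0.0
        for v in range(len(self.parent)):
            if v != self.root:
                bl += self.node_time[self.parent[v]] - self.node_time[v]
        return float(bl)

    def _tip_populations_below(self) -> np.ndarray:
        """(n_nodes, 2) counts of pop-1/pop-2 tips in each node's subtree."""
        n_nodes = len(self.parent)
        counts = np.zeros((n_nodes, 2), dtype=np.int64)
        for tip in range(self.n_tips):
            counts[tip, 0 if tip < self.n1 else 1] = 1
        # children always have smaller index than parents (creation order)
        for v in range(n_nodes):
            p = self.parent[v]
            if p >= 0:
                counts[p] += counts[v]
        return counts

    def first_cross_coalescence_time(self) -> float:
        """Time of the shallowest node whose subtree spans both populations."""
        counts = self._tip_populations_below()
        times = [
            float(self.node_time[v])
            for v in range(self.n_tips, len(self.parent))
            if counts[v, 0] > 0 and counts[v, 1] > 0
        ]
        return min(times) if times else float("inf")


def _seed_from(rng: np.random.Generator) -> int:
    return int(rng.integers(0, 2**32 - 1))


def simulate_genealogy(params: PairModelParams, rng: np.random.Generator) -> Genealogy:
    """Draw one genealogy under the structured IM coalescent."""
    parent, node_time, root = _kernels._genealogy_seeded(
        _seed_from(rng), params.n1, params.n2,
        params.coalescence_rate("1"), params.coalescence_rate("2"),
        params.coalescence_rate("a"), params.tau, params.m_1, params.m_2,
    )
    return Genealogy(parent=parent, node_time=node_time, root=int(root),
                     n1=params.n1, n2=params.n2, params=params)


def sprinkle_mutations(genealogy: Genealogy, params: PairModelParams,
                       rng: np.random.Generator) -> np.ndarray:
    """Simulated alignment (n1+n2, L) int8 for a genealogy.

    Mutations are Poisson on branches at ``params.mutation_rate`` per site,
    hit uniform sites, and substitute under the HKY-style kernel; the root
    sequence is uniform random (the kernel's stationary distribution).
    """
    return _kernels._mutate_full_seeded(
        _seed_from(rng), genealogy.parent, genealogy.node_time, genealogy.root,
        genealogy.n_tips, params.L, params.mutation_rate, params.kappa,
    )


def simulate_pair_stats(params: PairModelParams, rng: np.random.Generator) -> np.ndarray:
    """Per-pair summary-statistic vector for one simulated data set.

    Composition of :func:`simulate_genealogy`, :func:`sprinkle_mutations`
    and the statistic definitions of :mod:`codivabc.stats`, evaluated by the
    compiled fast path (identical values; only monomorphic sites are never
    materialised).  Bit-reproducible given the generator state.
    """
    return _kernels._sim_pair_stats_seeded(
        _seed_from(rng), params.n1, params.n2, params.L,
        params.coalescence_rate("1"), params.coalescence_rate("2"),
        params.coalescence_rate("a"), params.tau, params.m_1, params.m_2,
        params.mutation_rate, params.kappa,
    )
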