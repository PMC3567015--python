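"""Hyperprior over divergence histories and per-pair nuisance parameters.

The hierarchical model: a study of Y taxon pairs shares a hyperparameter
``psi`` — the number of possible divergence times — drawn uniformly on
{1..psi_max}; ``psi`` divergence times are drawn iid U(0, tau_max); each
pair is assigned one of the ``psi`` time classes uniformly at random (some
drawn classes may end up unoccupied; the count of *realized* distinct times
is recorded alongside).  Conditional on its class, each pair gets nuisance
parameters integrated out by simulation: theta_1 = theta_2 ~
U(theta_min, theta_max), theta_ancestral = ratio * theta, and migration
rates m_1, m_2 ~ U(0, 2 * m_mean) so the configured per-barrier mean
migration rate (e.g. an IMa estimate) is matched in expectation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .simulate import PairModelParams

__all__ = ["HyperPrior", "HyperDraw", "PairMeta", "draw_hyper", "draw_hyper_batch"]


@dataclass(frozen=True)
class PairMeta:
    """Fixed observables of a pair carried into every simulation."""

    pair_id: str
    n1: int
    n2: int
    L: int
    rate_multiplier: float = 1.0

    @classmethod
    def from_pair(cls, pair) -> "PairMeta":
        return cls(pair_id=pair.pair_id, n1=pair.n1, n2=pair.n2,
                   L=pair.L, rate_multiplier=pair.rate_multiplier)


@dataclass
class HyperPrior:
    """Hyperprior configuration for one barrier set of Y taxon pairs.

    Defaults follow the full-scale analysis configuration: theta_max
    estimated as 0.15816, tau prior upper bound 3 (reference-scaled units),
    psi_max equal to the number of pairs, 1,000,000 simulated data sets and
    2,000 retained.  Desk-scale runs override ``n_sims``/``n_accept``.
    """

    n_pairs: int
    psi_max: int | None = None
    tau_max: float = 3.0
    theta_max: float = 0.15816
    theta_min: float = 0.0001
    theta_ancestral_ratio: float = 0.5
    m_mean: float = 0.0
    n_sims: int = 1_000_000
    n_accept: int = 2_000
    kappa: float = 4.0

    def __post_init__(self):
        if self.psi_max is None:
            self.psi_max = self.n_pairs
        if not (1 <= self.psi_max <= self.n_pairs):
            raise ValueError(f"psi_max must be in 1..{self.n_pairs}, got {self.psi_max}")
        if self.tau_max <= 0 or self.theta_max <= 0:
            raise ValueError("tau_max and theta_max must be > 0")
        if not (0 <= self.theta_min < self.theta_max):
            raise ValueError("need 0 <= theta_min < theta_max")
        if self.n_accept > self.n_sims:
            raise ValueError("n_accept must be <= n_sims")
        if self.m_mean < 0:
            raise ValueError("m_mean must be >= 0")

    @property
    def theta_ref(self) -> float:
        """Reference theta fixing the time scale: theta_max / 2."""
        return self.theta_max / 2.0

    def echo(self) -> dict:
        """Serializable record of the prior, logged into every output."""
        d = asdict(self)
        d["theta_ref"] = self.theta_ref
        return d


@dataclass
class HyperDraw:
    """One draw from the hyperprior for a study of Y pairs."""

    psi: int
    tau_values: np.ndarray
    assignment: np.ndarray
    pair_params: list = field(default_factory=list)

    @property
    def tau_per_pair(self) -> np.ndarray:
        return self.tau_values[self.assignment]

    @property
    def psi_realized(self) -> int:
        return int(np.unique(self.assignment).size)


def draw_hyper_batch(prior: HyperPrior, pair_meta, n: int,
                     rng: np.random.Generator) -> dict:
    """Vectorized hyperprior draws.

    Returns arrays keyed ``psi`` (n,), ``psi_realized`` (n,), ``tau`` /
    ``theta`` / ``theta_a`` / ``m1`` / ``m2`` (n, Y).
    """
    Y = len(pair_meta)
    if Y != prior.n_pairs:
        raise ValueError(f"prior configured for {prior.n_pairs} pairs, got {Y}")
    psi = rng.integers(1, prior.psi_max + 1, size=n)
    tau_classes = rng.uniform(0.0, prior.tau_max, size=(n, prior.psi_max))
    assignment = rng.integers(0, psi[:, None], size=(n, Y))
    tau = tau_classes[np.arange(n)[:, None], assignment]
    theta = rng.uniform(prior.theta_min, prior.theta_max, size=(n, Y))
    theta_a = prior.theta_ancestral_ratio * theta
    if prior.m_mean > 0:
        m1 = rng.uniform(0.0, 2.0 * prior.m_mean, size=(n, Y))
        m2 = rng.uniform(0.0, 2.0 * prior.m_mean, size=(n, Y))
    else:
        m1 = np.zeros((n, Y))
        m2 = np.zeros((n, Y))
    srt = np.sort(assignment, axis=1)
    psi_realized = 1 + (np.diff(srt, axis=1) != 0).sum(axis=1)
    return {"psi": psi, "psi_realized": psi_realized, "assignment": assignment,
            "tau": tau, "theta": theta, "theta_a": theta_a, "m1": m1, "m2": m2}


def draw_hyper(prior: HyperPrior, pair_meta, rng: np.random.Generator) -> HyperDraw:
    """One structured hyperprior draw with per-pair ``PairModelParams``."""
    Y = len(pair_meta)
    if Y != prior.n_pairs:
        raise ValueError(f"prior configured for {prior.n_pairs} pairs, got {Y}")
    psi = int(rng.integers(1, prior.psi_max + 1))
    tau_values = rng.uniform(0.0, prior.tau_max, size=psi)
    assignment = rng.integers(0, psi, size=Y)
    theta = rng.uniform(prior.theta_min, prior.theta_max, size=Y)
    if prior.m_mean > 0:
        m1 = rng.uniform(0.0, 2.0 * prior.m_mean, size=Y)
        m2 = rng.uniform(0.0, 2.0 * prior.m_mean, size=Y)
    else:
        m1 = np.zeros(Y)
        m2 = np.zeros(Y)
    params = [
        PairModelParams(
            theta_1=float(theta[j]), theta_2=float(theta[j]),
            theta_a=float(prior.theta_ancestral_ratio * theta[j]),
            tau=float(tau_values[assignment[j]]),
            n1=pm.n1, n2=pm.n2, L=pm.L, theta_ref=prior.theta_ref,
            m_1=float(m1[j]), m_2=float(m2[j]),
            rate_multiplier=pm.rate_multiplier, kappa=prior.kappa,
        )
        for j, pm in enumerate(pair_meta)
    ]
    return HyperDraw(psi=psi, tau_values=tau_values,
                     assignment=assignment.astype(int), pair_params=params)
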