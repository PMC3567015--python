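"""Model/Results interface for the hierarchical co-divergence test.

``CoDivergenceABC`` is built from the observed taxon pairs of one barrier
set plus a hyperprior; ``fit()`` runs the full hierarchical ABC analysis
(simulated reference table, rejection, optional regression adjustment) and
returns a ``CoDivergenceResults`` carrying the posterior summaries, the
accepted draws, and diagnostics.

Example
-------
>>> from codivabc import CoDivergenceABC
>>> model = CoDivergenceABC.from_preset("tuxtlas-like", seed=7)
>>> res = model.fit(n_sims=20_000, n_accept=500, seed=7)
>>> print(res.summary())            # doctest: +SKIP
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .abc import (PosteriorSummary, SimTable, abc_reject, observed_vector,
                  psi_mode_logit, regression_adjust, run_simulations, summarize)
from .io import read_study, stats_table
from .priors import HyperPrior, PairMeta

__all__ = ["CoDivergenceABC", "CoDivergenceResults"]


class CoDivergenceABC:
    """Hierarchical ABC test of simultaneous vs non-simultaneous divergence.

    Parameters
    ----------
    pairs
        List of ``TaxonPair`` objects, all flanking one barrier.
    prior
        A ``HyperPrior``; if omitted, one is built from ``prior_kwargs``
        with ``n_pairs`` taken from the data.
    """

    def __init__(self, pairs, prior: HyperPrior | None = None, **prior_kwargs):
        if not pairs:
            raise ValueError("need at least one taxon pair")
        self.pairs = list(pairs)
        if prior is None:
            prior = HyperPrior(n_pairs=len(self.pairs), **prior_kwargs)
        if prior.n_pairs != len(self.pairs):
            raise ValueError(
                f"prior configured for {prior.n_pairs} pairs but data has {len(self.pairs)}")
        self.prior = prior
        self._obs = None

    # ------------------------------------------------------------------
    @classmethod
    def from_manifest(cls, manifest_path, prior: HyperPrior | None = None,
                      **prior_kwargs) -> "CoDivergenceABC":
        """Build the model from a manifest TSV + FASTA study on disk."""
        return cls(read_study(manifest_path), prior=prior, **prior_kwargs)

    @classmethod
    def from_preset(cls, name: str, seed: int, prior: HyperPrior | None = None,
                    **prior_kwargs) -> "CoDivergenceABC":
        """Generate a named synthetic preset study and wrap it in a model.

        The preset's suggested migration-prior mean and theta scale are used
        unless overridden.
        """
        from .synthetic import generate_study, preset_scenarios

        truth = preset_scenarios(name)
        pairs, _, _ = generate_study(truth, seed=seed)
        if prior is None:
            prior_kwargs.setdefault("m_mean", truth.prior_m_mean)
            prior_kwargs.setdefault("theta_max", 2.0 * truth.theta_ref)
            prior = HyperPrior(n_pairs=truth.Y, **prior_kwargs)
        model = cls(pairs, prior=prior)
        model.truth = truth
        return model

    # ------------------------------------------------------------------
    @property
    def pair_meta(self) -> list:
        return [PairMeta.from_pair(p) for p in self.pairs]

    @property
    def observed(self) -> np.ndarray:
        """Observed comparison vector (cached)."""
        if self._obs is None:
            self._obs = observed_vector(self.pairs)
        return self._obs

    def observed_frame(self, distances: bool = True) -> pd.DataFrame:
        """Observed per-pair statistics (and TN93 distances) as a table."""
        return stats_table(self.pairs, distances=distances)

    def simulate(self, n_sims: int, seed: int) -> SimTable:
        """Reference table of ``n_sims`` draws (no rejection step)."""
        return run_simulations(self.prior, self.pair_meta, seed=seed, n_sims=n_sims)

    # ------------------------------------------------------------------
    def fit(self, seed: int, n_sims: int | None = None,
            n_accept: int | None = None, adjust: bool = False,
            table: SimTable | None = None,
            feature_mode: str = "hyper") -> "CoDivergenceResults":
        """Run the analysis and return results.

        ``n_sims``/``n_accept`` default to the prior's configured values;
        ``adjust=True`` applies the local-linear regression adjustment to
        the continuous hyperparameters and the multinomial-logit psi mode.
        ``feature_mode`` selects the ABC comparison features ("hyper" —
        rate-normalized across-pair summaries, the default analysis
        configuration — or "all" for the raw statistic vector).  A
        precomputed ``table`` (e.g. a checkpoint) can be supplied to
        re-summarise without re-simulating.
        """
        if n_accept is None:
            n_accept = self.prior.n_accept
        if table is None:
            table = self.simulate(self.prior.n_sims if n_sims is None else n_sims,
                                  seed=seed)
        obs = self.observed
        meta = self.pair_meta
        accepted, distances = abc_reject(obs, table, n_accept, pair_meta=meta,
                                         feature_mode=feature_mode)
        acc_params = table.params.iloc[accepted].reset_index(drop=True)
        weights = None
        logit = None
        if adjust:
            adj = regression_adjust(table, accepted, obs, distances,
                                    self.prior.tau_max, pair_meta=meta,
                                    feature_mode=feature_mode)
            acc_params = acc_params.assign(
                e_tau=adj["e_tau"].to_numpy(), var_tau=adj["var_tau"].to_numpy(),
                omega=adj["omega"].to_numpy())
            weights = adj["weight"].to_numpy()
            logit = psi_mode_logit(table, accepted, obs, distances,
                                   pair_meta=meta, feature_mode=feature_mode)
        provenance = dict(table.provenance)
        provenance.update({
            "fit_seed": int(seed), "n_accept": int(n_accept), "adjust": bool(adjust),
            "feature_mode": feature_mode,
            "max_accepted_distance": float(distances[accepted].max()),
        })
        posterior = summarize(acc_params, weights=weights, provenance=provenance)
        if logit is not None:
            posterior.psi_mode_logit = logit[0]
            posterior.provenance["psi_mode_logit"] = {
                "mode": logit[0], "probs": logit[1]}
        return CoDivergenceResults(
            model=self, table=table, accepted_indices=accepted,
            distances=distances, accepted=acc_params, weights=weights,
            posterior=posterior)


class CoDivergenceResults:
    """Fitted results: posterior summaries and accepted draws."""

    def __init__(self, model, table, accepted_indices, distances, accepted,
                 weights, posterior: PosteriorSummary):
        self.model = model
        self.table = table
        self.accepted_indices = accepted_indices
        self.distances = distances
        self.accepted = accepted
        self.weights = weights
        self.posterior = posterior

    # convenience accessors mirroring the posterior fields ------------
    def __getattr__(self, name):
        if name.startswith("_"):
            raise AttributeError(name)
        try:
            return getattr(self.posterior, name)
        except AttributeError:
            raise AttributeError(name) from None

    def summary(self) -> str:
        """Plain-text summary table of the hyperparameter posteriors."""
        p = self.posterior
        prior = self.model.prior
        lines = [
            "Hierarchical ABC co-divergence test",
            "=" * 51,
            f"{'taxon pairs (Y)':<34}{prior.n_pairs:>17}",
            f"{'simulated data sets':<34}{self.table.n_sims:>17}",
            f"{'accepted draws':<34}{p.n_accept:>17}",
            f"{'prior: psi ~ DU{1..psi_max}':<34}{prior.psi_max:>17}",
            f"{'prior: tau ~ U(0, tau_max)':<34}{prior.tau_max:>17.4g}",
            f"{'prior: theta_max':<34}{prior.theta_max:>17.5g}",
            "-" * 51,
            f"{'Psi mode':<34}{p.psi_mode:>17}",
            f"{'Psi mean':<34}{p.psi_mean:>17.3f}",
            f"{'Psi (realized) mode':<34}{p.psi_realized_mode:>17}",
            *( [f"{'Psi mode (multinomial logit)':<34}{p.psi_mode_logit:>17}"]
               if p.psi_mode_logit is not None else [] ),
            f"{'Omega mode':<34}{p.omega_mode:>17.4f}",
            f"{'Omega mean':<34}{p.omega_mean:>17.4f}",
            f"{'Omega 95% quantiles':<34}"
            f"{f'({p.omega_q025:.4f}-{p.omega_q975:.4f})':>17}",
            f"{'E(tau) mean':<34}{p.e_tau_mean:>17.4f}",
            "=" * 51,
            "Omega = Var(tau)/E(tau); 0 under simultaneous divergence.",
        ]
        return "\n".join(lines)

    def to_json(self, path=None):
        return self.posterior.to_json(path)

    def plot_posterior(self, ax=None):
        """Posterior density of Omega against its prior (matplotlib)."""
        import matplotlib.pyplot as plt
        from scipy.stats import gaussian_kde

        if ax is None:
            _, ax = plt.subplots()
        om_post = self.accepted["omega"].to_numpy(float)
        om_prior = self.table.params["omega"].to_numpy(float)
        grid = np.linspace(0, max(om_prior.max(), om_post.max(), 1e-6), 400)
        if np.ptp(om_prior) > 0:
            ax.plot(grid, gaussian_kde(om_prior)(grid), "r--", label="prior")
        if np.ptp(om_post) > 0:
            ax.plot(grid, gaussian_kde(om_post)(grid), "b-", label="posterior")
        ax.axvline(self.posterior.omega_mode, color="k", lw=0.8, ls=":")
        ax.set_xlabel(r"$\Omega$ = Var($\tau$)/E($\tau$)")
        ax.set_ylabel("density")
        ax.legend()
        return ax
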