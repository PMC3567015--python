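"""Hierarchical ABC engine: reference table, rejection, and posteriors.

Workflow (mirroring the three-stage analysis): (1) summary statistics from
the observed pairs, (2) a large reference table of data sets simulated from
the hyperprior, (3) rejection of all but the draws whose statistics lie
closest to the observed vector, summarised into posterior estimates of psi
(number of divergence pulses) and of the dispersion index
Omega = Var(tau)/E(tau), which is 0 under strictly simultaneous divergence.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from . import __version__ as _pkg_version
from . import _kernels
from .priors import HyperPrior, PairMeta, draw_hyper_batch
from .stats import (STAT_LAYOUT_VERSION, hyper_summary, pair_summary_vector,
                    study_vector, study_vector_names)

__all__ = [
    "omega", "effective_migrants", "SimTable", "run_simulations",
    "observed_vector", "distance_features", "abc_reject", "regression_adjust",
    "psi_mode_logit", "summarize", "PosteriorSummary", "test_codivergence",
]

#: hyperparameter columns stored per simulated row
PARAM_COLUMNS = ("psi", "psi_realized", "e_tau", "var_tau", "omega")


def omega(tau_per_pair, sample_variance: bool = False) -> float:
    """Dispersion index of divergence times: Var(tau) / E(tau).

    Population variance (divide by Y) by default; ``sample_variance=True``
    switches to the Y−1 denominator.  A vector of all zeros (simultaneous
    divergence at time zero) gives 0 by convention.
    """
    taus = np.asarray(tau_per_pair, dtype=float)
    if taus.size < 1:
        raise ValueError("need at least one divergence time")
    if np.any(taus < 0):
        raise ValueError("divergence times must be >= 0")
    mean = taus.mean()
    if mean == 0.0:
        return 0.0
    ddof = 1 if sample_variance else 0
    if ddof >= taus.size:
        raise ValueError("sample variance needs at least two pairs")
    return float(taus.var(ddof=ddof) / mean)


def effective_migrants(m: float, theta: float) -> float:
    """Effective immigrants per generation, theta * m / 2.

    Converts a scaled migration rate ``m`` (per lineage, reference-scaled)
    into 2Nm of the receiving population with diversity ``theta = 4Nu``.
    """
    if m < 0 or theta < 0:
        raise ValueError("m and theta must be >= 0")
    return theta * m / 2.0


@dataclass
class SimTable:
    """Reference table: hyperparameter draws paired with their statistics."""

    params: pd.DataFrame          # columns PARAM_COLUMNS, one row per draw
    stats: np.ndarray             # (n_sims, n_stats)
    stat_names: list
    provenance: dict = field(default_factory=dict)

    @property
    def n_sims(self) -> int:
        return len(self.params)

    def to_tsv(self, path) -> None:
        df = self.params.copy()
        for i, name in enumerate(self.stat_names):
            df[name] = self.stats[:, i]
        with open(path, "w") as fh:
            for key, val in sorted(self.provenance.items()):
                fh.write(f"# {key}={json.dumps(val)}\n")
            df.to_csv(fh, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def from_tsv(cls, path) -> "SimTable":
        provenance = {}
        with open(path) as fh:
            pos = fh.tell()
            while True:
                line = fh.readline()
                if not line.startswith("#"):
                    fh.seek(pos)
                    break
                key, _, val = line[1:].strip().partition("=")
                provenance[key.strip()] = json.loads(val)
                pos = fh.tell()
            df = pd.read_csv(fh, sep="\t")
        params = df[list(PARAM_COLUMNS)].copy()
        stat_names = [c for c in df.columns if c not in PARAM_COLUMNS]
        return cls(params=params, stats=df[stat_names].to_numpy(float),
                   stat_names=stat_names, provenance=provenance)


def observed_vector(pairs) -> np.ndarray:
    """Observed comparison vector (per-pair stats + hyper summaries)."""
    per_pair = np.vstack([pair_summary_vector(p) for p in pairs])
    return study_vector(per_pair)


def run_simulations(prior: HyperPrior, pair_meta, seed: int,
                    n_sims: int | None = None, chunk_size: int = 5_000,
                    progress=None) -> SimTable:
    """Build the simulated reference table.

    For every hyperprior draw each pair is simulated under the IM coalescent
    with its drawn sub-parameters, the per-pair statistics are computed, and
    the condensed hyperparameters (psi, realized psi, E(tau), Var(tau),
    Omega) are stored with the statistics.  Simulation runs in chunks of
    ``chunk_size`` draws (constant memory per chunk) and is deterministic
    for a given ``seed``.
    """
    pair_meta = [pm if isinstance(pm, PairMeta) else PairMeta.from_pair(pm)
                 for pm in pair_meta]
    Y = len(pair_meta)
    if n_sims is None:
        n_sims = prior.n_sims
    hyper_rng = np.random.default_rng(np.random.SeedSequence([int(seed), 1]))
    kernel_seeds = np.random.SeedSequence([int(seed), 2]).generate_state(
        n_sims * Y, dtype=np.uint32).astype(np.int64).reshape(n_sims, Y)

    theta_ref = prior.theta_ref
    n_stats = 8 * Y + 16
    stats_out = np.empty((n_sims, n_stats), dtype=np.float64)
    par_out = {k: np.empty(n_sims) for k in PARAM_COLUMNS}

    done = 0
    while done < n_sims:
        m = min(chunk_size, n_sims - done)
        b = draw_hyper_batch(prior, pair_meta, m, hyper_rng)
        per_pair = np.empty((m, Y, 8))
        for j, pm in enumerate(pair_meta):
            rho = pm.rate_multiplier
            lam1 = rho * theta_ref / np.maximum(b["theta"][:, j], _kernels.THETA_FLOOR)
            lamA = rho * theta_ref / np.maximum(b["theta_a"][:, j], _kernels.THETA_FLOOR)
            per_pair[:, j, :] = _kernels._sim_batch(
                kernel_seeds[done:done + m, j], pm.n1, pm.n2, pm.L,
                lam1, lam1.copy(), lamA, b["tau"][:, j],
                b["m1"][:, j], b["m2"][:, j],
                rho * theta_ref / 2.0, prior.kappa,
            )
        np.nan_to_num(per_pair, copy=False, nan=0.0)
        flat = per_pair.reshape(m, Y * 8)
        stats_out[done:done + m, :Y * 8] = flat
        stats_out[done:done + m, Y * 8:] = np.column_stack([
            per_pair.mean(axis=1), per_pair.var(axis=1)])
        sl = slice(done, done + m)
        par_out["psi"][sl] = b["psi"]
        par_out["psi_realized"][sl] = b["psi_realized"]
        par_out["e_tau"][sl] = b["tau"].mean(axis=1)
        par_out["var_tau"][sl] = b["tau"].var(axis=1)
        par_out["omega"][sl] = np.where(
            par_out["e_tau"][sl] > 0, par_out["var_tau"][sl] / par_out["e_tau"][sl], 0.0)
        done += m
        if progress is not None:
            progress(done, n_sims)

    provenance = {
        "seed": int(seed),
        "prior": prior.echo(),
        "pair_meta": [asdict(pm) for pm in pair_meta],
        "stat_layout_version": STAT_LAYOUT_VERSION,
        "package_version": _pkg_version,
        "distance_standardization": "per-column std of simulated table",
        "migration_prior": "uniform(0, 2*m_mean), mean matched to configured m_mean",
    }
    return SimTable(params=pd.DataFrame(par_out), stats=stats_out,
                    stat_names=study_vector_names(Y), provenance=provenance)


def _informative_columns(stats: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(keep mask, std) — columns with no variation beyond float fuzz dropped."""
    sd = stats.std(axis=0)
    scale = np.maximum(1.0, np.abs(stats.mean(axis=0)))
    return sd > 1e-12 * scale, sd


def distance_features(stats, pair_meta, mode: str = "hyper"):
    """Comparison features for the ABC distance.

    ``mode="hyper"`` (the default analysis configuration): across-pair mean
    and variance of each per-pair statistic, with the divergence statistics
    pi_b and pi_net first divided by the pair's locus rate multiplier so
    mixed fast/slow loci are on a common per-unit-time scale.  This keeps
    the distance dimension fixed at 16 whatever the number of pairs —
    hyperparameters (psi, Omega) are functions of the across-pair tau
    distribution, so exchangeable across-pair summaries are the natural
    comparison — and avoids the acceptance-rate collapse of
    high-dimensional rejection ABC.

    ``mode="all"`` uses the stored statistic vector unchanged (per-pair
    slots plus raw hyper summaries).

    ``stats`` may be one vector or a (n, k) matrix; pair metadata supplies
    the rate multipliers.
    """
    arr = np.atleast_2d(np.asarray(stats, dtype=float))
    if mode == "all":
        out = arr
    elif mode == "hyper":
        Y = len(pair_meta)
        if arr.shape[1] != 8 * Y + 16:
            raise ValueError(
                f"statistic vector has {arr.shape[1]} columns; expected "
                f"{8 * Y + 16} for {Y} pairs")
        per_pair = arr[:, :8 * Y].reshape(arr.shape[0], Y, 8).copy()
        rho = np.asarray([pm.rate_multiplier for pm in pair_meta], dtype=float)
        per_pair[:, :, 2] /= rho  # pi_b per unit reference time
        per_pair[:, :, 3] /= rho  # pi_net per unit reference time
        out = np.concatenate([per_pair.mean(axis=1), per_pair.var(axis=1)],
                             axis=1)
    else:
        raise ValueError(f"unknown feature mode {mode!r}")
    return out if np.asarray(stats).ndim == 2 else out[0]


def _features_and_names(table: SimTable, obs: np.ndarray, pair_meta,
                        feature_mode: str):
    """Feature matrix/vector and display names for the chosen distance mode."""
    obs = np.asarray(obs, dtype=float)
    if obs.shape[0] != table.stats.shape[1]:
        raise ValueError(
            f"observed vector has {obs.shape[0]} entries, table has "
            f"{table.stats.shape[1]} statistic columns")
    if feature_mode == "all" or pair_meta is None:
        return table.stats, obs, list(table.stat_names)
    F = distance_features(table.stats, pair_meta, feature_mode)
    f_obs = distance_features(obs, pair_meta, feature_mode)
    from .stats import PAIR_STAT_NAMES
    names = [f"{s}.norm_mean" for s in PAIR_STAT_NAMES] + \
            [f"{s}.norm_var" for s in PAIR_STAT_NAMES]
    return F, f_obs, names


def abc_reject(obs: np.ndarray, table: SimTable, n_accept: int,
               pair_meta=None, feature_mode: str = "all"):
    """Standardized-Euclidean rejection: keep the n_accept closest rows.

    The distance runs on the comparison features of ``feature_mode`` (see
    :func:`distance_features`; the engine's analysis default is "hyper",
    plain ``abc_reject`` defaults to the raw stored vector).  Each feature
    is standardized by the table's own standard deviation; zero-variance
    columns are excluded (with a warning).  Ties are broken by row index,
    so the result is deterministic.

    Returns ``(accepted_indices, distances_all)``.
    """
    F, f_obs, names = _features_and_names(table, obs, pair_meta, feature_mode)
    if not (0 < n_accept <= table.n_sims):
        raise ValueError("need 0 < n_accept <= n_sims")
    keep, sd = _informative_columns(F)
    if not keep.all():
        dropped = [names[i] for i in np.nonzero(~keep)[0]]
        warnings.warn(
            f"excluding {len(dropped)} zero-variance statistic column(s) "
            f"from the ABC distance: {dropped[:8]}{'...' if len(dropped) > 8 else ''}",
            stacklevel=2)
    if not keep.any():
        raise ValueError("all statistic columns have zero variance")
    z = (F[:, keep] - f_obs[keep]) / sd[keep]
    distances = np.sqrt((z * z).sum(axis=1))
    order = np.argsort(distances, kind="stable")
    return order[:n_accept].copy(), distances


def _epanechnikov_weights(distances: np.ndarray) -> np.ndarray:
    dmax = distances.max()
    if dmax == 0:
        return np.ones_like(distances)
    u = distances / (dmax * (1 + 1e-12))
    return 1.0 - u * u


def regression_adjust(table: SimTable, accepted: np.ndarray, obs: np.ndarray,
                      distances: np.ndarray, tau_max: float,
                      pair_meta=None, feature_mode: str = "all") -> pd.DataFrame:
    """Local-linear regression adjustment of the accepted continuous draws.

    Weighted (Epanechnikov at the acceptance radius) linear regression of
    each hyperparameter on the standardized statistics, evaluated at the
    observed point: adjusted_i = param_i − (s_i − s_obs)·beta, clamped to
    the prior support (Omega >= 0, E(tau) in [0, tau_max]).
    """
    F, f_obs, _ = _features_and_names(table, obs, pair_meta, feature_mode)
    keep, sd = _informative_columns(F)
    S = (F[np.ix_(accepted, np.nonzero(keep)[0])] - f_obs[keep]) / sd[keep]
    w = _epanechnikov_weights(distances[accepted])
    sw = np.sqrt(w)
    X = np.column_stack([np.ones(len(accepted)), S])
    out = {}
    for name, upper in (("e_tau", tau_max), ("var_tau", None), ("omega", None)):
        y = table.params[name].to_numpy(float)[accepted]
        beta, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
        adj = y - S @ beta[1:]
        adj = np.clip(adj, 0.0, upper if upper is not None else np.inf)
        out[name] = adj
    out["weight"] = w
    return pd.DataFrame(out, index=accepted)


def psi_mode_logit(table: SimTable, accepted: np.ndarray, obs: np.ndarray,
                   distances: np.ndarray, pair_meta=None,
                   feature_mode: str = "all", n_train: int | None = None):
    """Psi mode by weighted multinomial-logit regression at the observed point.

    The categorical regression is fitted at its own, wider kernel tolerance
    than the strict rejection set: by default on the ``max(n_accept,
    min(n_sims/10, 20000))`` draws nearest the observed point, with
    Epanechnikov weights at that radius.  A multi-class logit on the
    comparison features needs substantially more training draws than the
    retained posterior sample to evaluate stably at the observed point
    (regression tolerances larger than the rejection tolerance are standard
    in regression-ABC).  Falls back to plain weighted counts when the
    training draws contain a single psi category or the fit cannot be
    computed.  Returns ``(psi_mode, probabilities_by_category)``.
    """
    if n_train is None:
        n_train = max(len(accepted), min(table.n_sims // 10, 20_000))
    n_train = min(max(n_train, len(accepted)), table.n_sims)
    order = np.argsort(distances, kind="stable")[:n_train]
    psi = table.params["psi"].to_numpy(int)[order]
    w = _epanechnikov_weights(distances[order])
    cats = np.unique(psi)
    if cats.size == 1:
        return int(cats[0]), {int(cats[0]): 1.0}
    F, f_obs, _ = _features_and_names(table, obs, pair_meta, feature_mode)
    keep, sd = _informative_columns(F)
    S = (F[np.ix_(order, np.nonzero(keep)[0])] - f_obs[keep]) / sd[keep]
    try:
        from sklearn.linear_model import LogisticRegression
        fit = LogisticRegression(max_iter=2000, C=1.0)
        fit.fit(S, psi, sample_weight=np.maximum(w, 1e-12))
        probs = fit.predict_proba(np.zeros((1, S.shape[1])))[0]
        by_cat = {int(c): float(p) for c, p in zip(fit.classes_, probs)}
    except Exception:  # pragma: no cover - degenerate fits
        counts = {int(c): float(w[psi == c].sum()) for c in cats}
        total = sum(counts.values())
        by_cat = {c: v / total for c, v in counts.items()}
    mode = max(sorted(by_cat), key=lambda c: by_cat[c])
    return int(mode), by_cat


@dataclass
class PosteriorSummary:
    """Accepted-draw summaries of the hyperparameters."""

    psi_mode: int
    psi_mean: float
    omega_mode: float
    omega_mean: float
    omega_q025: float
    omega_q975: float
    e_tau_mean: float
    n_accept: int
    psi_realized_mode: int = 0
    psi_realized_mean: float = 0.0
    psi_mode_logit: int | None = None
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path=None, indent: int = 2):
        text = json.dumps(self.to_dict(), indent=indent, sort_keys=True)
        if path is None:
            return text
        with open(path, "w") as fh:
            fh.write(text + "\n")
        return None


def _kde_mode(values: np.ndarray, weights: np.ndarray | None = None,
              grid_size: int = 512) -> float:
    """Mode of a Gaussian KDE (Silverman bandwidth) on a grid over the range."""
    values = np.asarray(values, dtype=float)
    if np.ptp(values) == 0:
        return float(values[0])
    kde = gaussian_kde(values, bw_method="silverman", weights=weights)
    grid = np.linspace(values.min(), values.max(), grid_size)
    return float(grid[np.argmax(kde(grid))])


def _weighted_quantile(values, q, weights=None):
    values = np.asarray(values, dtype=float)
    if weights is None:
        return float(np.quantile(values, q))
    order = np.argsort(values)
    v, w = values[order], np.asarray(weights, float)[order]
    cum = np.cumsum(w) - 0.5 * w
    cum /= w.sum()
    return float(np.interp(q, cum, v))


def summarize(accepted_params: pd.DataFrame, weights=None,
              provenance: dict | None = None) -> PosteriorSummary:
    """Posterior summaries from the accepted (optionally adjusted) draws.

    psi mode/mean from plain accepted counts (the discrete hyperparameter is
    untouched by the regression adjustment; the multinomial-logit mode is
    reported separately when requested); Omega mode from a Gaussian KDE with
    Silverman bandwidth maximized on a grid over the accepted range, using
    the adjustment weights when present; Omega mean and 2.5/97.5% quantiles
    empirical.
    """
    psi = accepted_params["psi"].to_numpy()
    om = accepted_params["omega"].to_numpy(float)
    et = accepted_params["e_tau"].to_numpy(float)
    w = None if weights is None else np.asarray(weights, float)

    def _wmode(x, use_w=True):
        cats = np.unique(x)
        mass = [(x == c).sum() if (w is None or not use_w) else w[x == c].sum()
                for c in cats]
        return int(cats[int(np.argmax(mass))])

    def _wmean(x, use_w=True):
        return float(np.average(x, weights=w if use_w else None))

    kde_w = None if w is None else np.maximum(w, 1e-12)
    summary = PosteriorSummary(
        psi_mode=_wmode(psi.astype(int), use_w=False),
        psi_mean=_wmean(psi, use_w=False),
        omega_mode=_kde_mode(om, weights=kde_w),
        omega_mean=_wmean(om),
        omega_q025=_weighted_quantile(om, 0.025, w),
        omega_q975=_weighted_quantile(om, 0.975, w),
        e_tau_mean=_wmean(et),
        n_accept=len(accepted_params),
        provenance=provenance or {},
    )
    if "psi_realized" in accepted_params:
        pr = accepted_params["psi_realized"].to_numpy()
        summary.psi_realized_mode = _wmode(pr.astype(int), use_w=False)
        summary.psi_realized_mean = _wmean(pr, use_w=False)
    return summary


def test_codivergence(pairs, prior: HyperPrior, seed: int,
                      n_sims: int | None = None, n_accept: int | None = None,
                      adjust: bool = False, checkpoint_dir=None,
                      feature_mode: str = "hyper") -> PosteriorSummary:
    """End-to-end co-divergence test: observed stats → table → posterior.

    Deterministic given ``seed``; optionally writes the SimTable checkpoint,
    the accepted draws, and the posterior summary under ``checkpoint_dir``.
    """
    import pathlib

    if n_accept is None:
        n_accept = prior.n_accept
    meta = [PairMeta.from_pair(p) for p in pairs]
    obs = observed_vector(pairs)
    table = run_simulations(prior, meta, seed=seed, n_sims=n_sims)
    accepted, distances = abc_reject(obs, table, n_accept, pair_meta=meta,
                                     feature_mode=feature_mode)
    acc_params = table.params.iloc[accepted].reset_index(drop=True)
    weights = None
    if adjust:
        adj = regression_adjust(table, accepted, obs, distances, prior.tau_max,
                                pair_meta=meta, feature_mode=feature_mode)
        acc_params = acc_params.assign(
            e_tau=adj["e_tau"].to_numpy(), var_tau=adj["var_tau"].to_numpy(),
            omega=adj["omega"].to_numpy())
        weights = adj["weight"].to_numpy()
    provenance = dict(table.provenance)
    provenance.update({"n_accept": int(n_accept), "adjust": bool(adjust),
                       "feature_mode": feature_mode,
                       "max_accepted_distance": float(distances[accepted].max())})
    summary = summarize(acc_params, weights=weights, provenance=provenance)
    if adjust:
        mode, probs = psi_mode_logit(table, accepted, obs, distances,
                                     pair_meta=meta, feature_mode=feature_mode)
        summary.psi_mode_logit = mode
        summary.provenance["psi_mode_logit"] = {"mode": mode, "probs": probs}
    if checkpoint_dir is not None:
        out = pathlib.Path(checkpoint_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_tsv(out / "sim_table.tsv")
        acc = table.params.iloc[accepted].copy()
        acc["distance"] = distances[accepted]
        acc.to_csv(out / "accepted.tsv", sep="\t", index=False, float_format="%.10g")
        summary.to_json(out / "posterior.json")
    return summary
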