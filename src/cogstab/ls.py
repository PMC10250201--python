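"""Bayesian longitudinal latent state model for one task x phase.

At each time point t the two ordinal test halves measure a common latent
state S_t (true score).  Measurement follows the normal-ogive graded
response model with thresholds invariant across time, loadings fixed at 1
and error variance fixed at 1.  The first state mean is fixed at zero as
the reference; later means are free, so credible intervals for mu_t answer
whether average ability changed.  Per-time-point reliability is

    Rel_t = Var(S_t) / (Var(S_t) + 1).

Subject-level states are marginalized by Gauss-Hermite quadrature, so the
sampler only sees the structural parameters (thresholds, state means, state
SDs).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri
from sklearn.base import BaseEstimator

from . import _mcmc
from .data import DegeneracyError
from .ordinal import grm_logpmf

__all__ = ["LatentStateModel", "fit_ls", "ls_loglik", "reliability", "state_mean_change"]


def ls_loglik(category, thresholds, state):
    """Log P(Y = category | S = state) under the graded response measurement model."""
    return grm_logpmf(category, state, thresholds)


def ls_marginal_loglik(categories, thresholds, mu=0.0, var=1.0, quad_points=60):
    """Marginal log likelihood of one subject x time point cell.

    ``categories`` is the pair of observed test-half categories (``None`` for
    a missing half); ``thresholds`` the pair of threshold arrays.  The latent
    state ``S ~ N(mu, var)`` is integrated out by Gauss-Hermite quadrature.
    """
    nodes, weights = np.polynomial.hermite.hermgauss(quad_points)
    s = mu + np.sqrt(2.0 * var) * nodes
    lik = weights / np.sqrt(np.pi)
    for cat, kap in zip(categories, thresholds):
        if cat is None:
            continue
        lik = lik * np.exp(grm_logpmf(int(cat), s, kap))
    return float(np.log(lik.sum()))


def _panel_from_parcels(parcels: pd.DataFrame):
    """Reshape a one-task, one-phase parcel table into (half, subject, time) arrays.

    Returns dict with integer category arrays ``y`` of shape (2, N, T); missing
    cells are coded -1.  Categories must already be contiguous 0..K-1 per half.
    """
    req = {"subject_id", "time_point", "half", "category"}
    if not req <= set(parcels.columns):
        raise ValueError(f"parcels must have columns {sorted(req)}")
    for col in ("task", "phase"):
        if col in parcels.columns and parcels[col].nunique() > 1:
            raise ValueError(f"parcels span multiple values of {col!r}; fit one at a time")
    subjects = np.sort(parcels["subject_id"].unique())
    tps = np.sort(parcels["time_point"].unique())
    s_idx = {s: i for i, s in enumerate(subjects)}
    t_idx = {t: i for i, t in enumerate(tps)}
    y = np.full((2, len(subjects), len(tps)), -1, dtype=int)
    obs = parcels.dropna(subset=["category"])
    for rec in obs.itertuples(index=False):
        y[int(rec.half) - 1, s_idx[rec.subject_id], t_idx[rec.time_point]] = int(rec.category)
    n_cat = []
    for i in range(2):
        vals = y[i][y[i] >= 0]
        if vals.size == 0 or len(np.unique(vals)) < 2:
            raise DegeneracyError(f"half {i + 1} has fewer than 2 observed categories")
        n_cat.append(int(vals.max()) + 1)
    return {"y": y, "subjects": subjects, "time_points": tps, "n_cat": n_cat}


def _threshold_init(y_half: np.ndarray, n_cat: int) -> np.ndarray:
    """Start thresholds at the probit of marginal cumulative category frequencies."""
    vals = y_half[y_half >= 0]
    freq = np.bincount(vals, minlength=n_cat) / vals.size
    cum = np.clip(np.cumsum(freq)[:-1], 0.01, 0.99)
    kappa = ndtri(cum)
    # enforce strict increase in degenerate corners
    kappa = np.maximum.accumulate(kappa + 1e-6 * np.arange(n_cat - 1))
    return kappa


def _unpack_thresholds(block: np.ndarray, n_cat: int) -> tuple[np.ndarray, np.ndarray]:
    """(W, K-1) raw block -> ordered thresholds + log-Jacobian per walker."""
    first = block[:, :1]
    if n_cat == 2:
        return first, np.zeros(block.shape[0])
    deltas = np.exp(np.clip(block[:, 1:], -30.0, 30.0))
    kappa = np.concatenate([first, first + np.cumsum(deltas, axis=1)], axis=1)
    return kappa, block[:, 1:].sum(axis=1)


def _pack_thresholds(kappa: np.ndarray) -> np.ndarray:
    kappa = np.asarray(kappa, dtype=float)
    if kappa.size == 1:
        return kappa
    return np.concatenate([kappa[:1], np.log(np.diff(kappa))])


def _grm_prob_table(kappa: np.ndarray, eta: np.ndarray) -> np.ndarray:
    """P(Y=k | eta) for walker-wise thresholds.

    kappa: (W, K-1); eta: (W, ...) latent grid.  Returns (W, ..., K).
    """
    c = ndtr(kappa[(slice(None),) + (None,) * (eta.ndim - 1)] - eta[..., None])
    shape = eta.shape + (1,)
    lower = np.concatenate([np.zeros(shape), c], axis=-1)
    upper = np.concatenate([c, np.ones(shape)], axis=-1)
    return np.clip(upper - lower, 1e-300, 1.0)


class LatentStateModel(BaseEstimator):
    """Ordinal-probit latent state model with free state means and variances.

    Parameters
    ----------
    equal_state_variance : bool
        Constrain Var(S_t) to a single value across time points.
    quad_points : int
        Gauss-Hermite nodes for marginalizing the state.
    draws, tune : int
        Kept and warmup ensemble steps.
    walkers : int or None
        Ensemble size (default scales with dimension).
    thin : int
        Keep every ``thin``-th step.
    rhat_max : float or None
        Convergence contract; the fit raises if any reported parameter
        exceeds it.  ``None`` disables the check.
    seed : int
        Reproducibility seed for initialization and sampling.

    Attributes
    ----------
    summary_ : DataFrame indexed by parameter with mean/sd/95% CrI/R-hat/ESS.
    idata_ : arviz.InferenceData of the structural parameters.
    state_means_, state_vars_, reliability_ : tidy per-time-point frames.
    thresholds_ : posterior-mean thresholds per half.
    """

    def __init__(
        self,
        equal_state_variance: bool = False,
        quad_points: int = 15,
        draws: int = 1500,
        tune: int = 200,
        walkers: int | None = None,
        thin: int = 3,
        rhat_max: float | None = 1.01,
        seed: int = 0,
        prior_mean_sd: float = 2.0,
        prior_threshold_sd: float = 2.0,
        prior_state_sd_scale: float = 1.0,
    ):
        self.equal_state_variance = equal_state_variance
        self.quad_points = quad_points
        self.draws = draws
        self.tune = tune
        self.walkers = walkers
        self.thin = thin
        self.rhat_max = rhat_max
        self.seed = seed
        self.prior_mean_sd = prior_mean_sd
        self.prior_threshold_sd = prior_threshold_sd
        self.prior_state_sd_scale = prior_state_sd_scale

    # ------------------------------------------------------------------
    def _make_logpost(self, panel):
        y = panel["y"]
        n_cat = panel["n_cat"]
        n_t = len(panel["time_points"])
        nodes, weights = np.polynomial.hermite.hermgauss(self.quad_points)
        gw = weights / np.sqrt(np.pi)
        root2 = np.sqrt(2.0)
        n_sig = 1 if self.equal_state_variance else n_t

        sizes = [n_cat[0] - 1, n_cat[1] - 1, n_t - 1, n_sig]
        offs = np.concatenate([[0], np.cumsum(sizes)])
        ndim = offs[-1]
        tt = np.arange(n_t)

        def logpost(theta):
            theta = np.atleast_2d(np.asarray(theta, dtype=float))
            w = theta.shape[0]
            lp = np.zeros(w)
            kappas = []
            for i in range(2):
                kap, jac = _unpack_thresholds(theta[:, offs[i]:offs[i + 1]], n_cat[i])
                lp += jac - 0.5 * np.sum(kap**2, axis=1) / self.prior_threshold_sd**2
                kappas.append(kap)
            mu_free = theta[:, offs[2]:offs[3]]
            lp += -0.5 * np.sum(mu_free**2, axis=1) / self.prior_mean_sd**2
            log_sig = theta[:, offs[3]:offs[4]]
            sig = np.exp(log_sig)
            # half-Normal(scale) prior on sigma, with log-transform Jacobian
            lp += np.sum(-0.5 * (sig / self.prior_state_sd_scale) ** 2 + log_sig, axis=1)

            mu = np.concatenate([np.zeros((w, 1)), mu_free], axis=1)  # (W, T)
            sig_t = np.broadcast_to(sig, (w, n_t)) if n_sig == 1 else sig
            # latent state grid per (walker, t, node)
            s_grid = mu[:, :, None] + root2 * sig_t[:, :, None] * nodes[None, None, :]
            cell = np.ones((w, y.shape[1], n_t, self.quad_points))
            for i in range(2):
                probs = _grm_prob_table(kappas[i], s_grid)  # (W, T, Q, K)
                pt = np.moveaxis(probs, 0, 2)  # (T, Q, W, K) -> index by (t, y)
                pt = np.moveaxis(pt, 1, 3)  # (T, W, K, Q)
                yi = y[i]  # (N, T)
                safe = np.where(yi < 0, 0, yi)
                g = pt[tt[None, :], :, safe, :]  # (N, T, W, Q)
                g = np.where((yi < 0)[:, :, None, None], 1.0, g)
                cell *= np.moveaxis(g, 2, 0)  # (W, N, T, Q)
            marg = cell @ gw  # (W, N, T)
            lp += np.log(np.clip(marg, 1e-300, None)).sum(axis=(1, 2))
            return lp

        return logpost, offs, ndim

    def _param_names(self, panel):
        names = []
        for i in range(2):
            names += [f"kappa[{i + 1},{k + 1}]" for k in range(panel["n_cat"][i] - 1)]
        tps = panel["time_points"]
        names += [f"mu[{t}]" for t in tps[1:]]
        if self.equal_state_variance:
            names += ["sigma_s"]
        else:
            names += [f"sigma_s[{t}]" for t in tps]
        return names

    # ------------------------------------------------------------------
    def fit(self, parcels: pd.DataFrame):
        panel = _panel_from_parcels(parcels)
        logpost, offs, ndim = self._make_logpost(panel)
        x0 = np.zeros(ndim)
        for i in range(2):
            x0[offs[i]:offs[i + 1]] = _pack_thresholds(
                _threshold_init(panel["y"][i], panel["n_cat"][i])
            )
        x_map = _mcmc.find_map(lambda x: logpost(x)[0], x0)

        raw_names = [f"theta[{j}]" for j in range(ndim)]
        idata_raw = _mcmc.sample_posterior(
            logpost,
            x_map,
            names=raw_names,
            nwalkers=self.walkers,
            nsteps=self.tune + self.draws,
            nburn=self.tune,
            thin=self.thin,
            seed=self.seed,
        )
        # transform raw draws to interpretable parameters
        chain = np.stack([np.asarray(idata_raw.posterior[n]) for n in raw_names], axis=-1)
        c, d, _ = chain.shape
        flat = chain.reshape(-1, ndim)
        cols = {}
        names = self._param_names(panel)
        pos = 0
        for i in range(2):
            kap, _ = _unpack_thresholds(flat[:, offs[i]:offs[i + 1]], panel["n_cat"][i])
            for k in range(kap.shape[1]):
                cols[names[pos]] = kap[:, k]
                pos += 1
        for j in range(offs[2], offs[3]):
            cols[names[pos]] = flat[:, j]
            pos += 1
        for j in range(offs[3], offs[4]):
            cols[names[pos]] = np.exp(flat[:, j])
            pos += 1

        import arviz as az

        self.idata_ = az.from_dict(
            posterior={k: v.reshape(c, d) for k, v in cols.items()}
        )
        self.idata_.attrs.update(getattr(idata_raw, "attrs", {}))
        tps = panel["time_points"]
        transform = {}
        for t in tps:
            s_name = "sigma_s" if self.equal_state_variance else f"sigma_s[{t}]"
            transform[f"var_s[{t}]"] = (lambda p, s=s_name: p[s] ** 2)
            transform[f"rel[{t}]"] = (lambda p, s=s_name: p[s] ** 2 / (p[s] ** 2 + 1.0))
        self.summary_ = _mcmc.summarize_draws(self.idata_, transform=transform)
        _mcmc.check_convergence(
            self.summary_.loc[[n for n in names]], self.rhat_max, "latent state model"
        )

        self.panel_ = panel
        self.time_points_ = tps
        self.state_means_ = self._tidy("mu", tps[1:])
        self.state_vars_ = self._tidy("var_s", tps)
        self.reliability_ = self._tidy("rel", tps)
        self.thresholds_ = {
            i + 1: self.summary_.loc[
                [f"kappa[{i + 1},{k + 1}]" for k in range(panel["n_cat"][i] - 1)], "mean"
            ].to_numpy()
            for i in range(2)
        }
        self.diagnostics_ = self.summary_[["rhat", "ess_bulk"]]
        return self

    def _tidy(self, stem: str, tps) -> pd.DataFrame:
        rows = []
        for t in tps:
            s = self.summary_.loc[f"{stem}[{t}]"]
            rows.append(
                {
                    "time_point": t,
                    "mean": s["mean"],
                    "ci_low": s["ci_low"],
                    "ci_high": s["ci_high"],
                }
            )
        return pd.DataFrame(rows)

    # ------------------------------------------------------------------
    def reliability(self, t: int | None = None):
        """Posterior summary of Rel_t (draw-wise Var(S_t)/(Var(S_t)+1))."""
        rel = self.reliability_
        if t is None:
            return rel
        return rel[rel["time_point"] == t].iloc[0]

    def state_mean_change(self) -> pd.DataFrame:
        """Per time point >= 2: does the 95% CrI of mu_t exclude zero?"""
        out = self.state_means_.copy()
        out["changed"] = (out["ci_low"] > 0) | (out["ci_high"] < 0)
        return out


def fit_ls(parcels: pd.DataFrame, **kwargs) -> LatentStateModel:
    return LatentStateModel(**kwargs).fit(parcels)


def reliability(fit: LatentStateModel, t: int | None = None):
    return fit.reliability(t)


def state_mean_change(fit: LatentStateModel) -> pd.DataFrame:
    return fit.state_mean_change()
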