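"""Latent state-trait (LST) decomposition and pairwise multi-trait models.

The continuous latent response of test half i at time point t decomposes as

    Y*_it = T + zeta_t + eps_it,      eps_it ~ N(0, 1)

with a time-invariant trait T ~ N(0, Var(T)), occasion-specific state
residuals zeta_t ~ N(0, Var(zeta)) (equal variance across occasions) and
graded-response measurement through time-invariant thresholds.  Variance
components are reported as

    Con = Var(T) / (Var(T) + Var(zeta))          consistency
    OS  = 1 - Con                                 occasion specificity
    Rel = (Var(T) + Var(zeta)) / (Var(T) + Var(zeta) + 1)

all computed draw-wise from the posterior.  A trait may be segmented into
time-point blocks (each block its own trait, correlated across blocks), and
two tasks can be modelled jointly with correlated traits to estimate
cross-task trait correlations.

Traits and state residuals are marginalized by nested Gauss-Hermite
quadrature; correlated traits use the bivariate-normal kernel ratio
phi2(u, v; rho) / (phi(u) phi(v)) on the product grid.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from . import _mcmc
from .ls import (
    _grm_prob_table,
    _pack_thresholds,
    _panel_from_parcels,
    _threshold_init,
    _unpack_thresholds,
)

__all__ = [
    "LatentStateTraitModel",
    "BivariateLatentStateTraitModel",
    "fit_lst",
    "fit_bivariate_lst",
    "consistency",
    "occasion_specificity",
    "lst_reliability",
]

_ROOT2 = np.sqrt(2.0)


def _gauss_hermite(n):
    x, w = np.polynomial.hermite.hermgauss(n)
    return _ROOT2 * x, w / np.sqrt(np.pi)  # std-normal nodes and weights


_RHO_MAX = np.tanh(6.0)  # |rho| cap; quadrature degrades at the boundary anyway


def _bvn_kernel(u, rho):
    """phi2(u_i, u_j; rho)/(phi(u_i) phi(u_j)) on the product grid.

    u: (Q,) std-normal nodes; rho: (W,).  Returns (W, Q, Q).
    """
    r = np.clip(rho, -_RHO_MAX, _RHO_MAX)[:, None, None]
    uu = u[None, :, None]
    vv = u[None, None, :]
    denom = 1.0 - r**2
    return np.exp(-(r**2 * (uu**2 + vv**2) - 2 * r * uu * vv) / (2 * denom)) / np.sqrt(denom)


def _rho_from_raw(z):
    """tanh-transformed correlation with a boundary-regularizing LKJ(2)-style
    prior; returns (rho, log prior including the transform Jacobian).

    The prior density on the unconstrained scale is (1 - tanh^2 z)^2, written
    in the exp-stable form so it keeps decaying past the |rho| cap and the
    chain cannot drift along a flat tail.
    """
    rho = np.tanh(np.clip(z, -6.0, 6.0))
    az = np.abs(z)
    log_sech2 = 2.0 * (np.log(2.0) - az) - 2.0 * np.log1p(np.exp(-2.0 * az))
    return rho, 2.0 * log_sech2


def _pair_table(kappas, sigma_t, sigma_z, nodes, gw):
    """Joint probability of an (augmented) category pair given the trait node.

    Marginalizes the state residual: B[w, q, c1, c2] =
    sum_r gw_r P(Y1 = c1 | eta_qr) P(Y2 = c2 | eta_qr), where
    eta_qr = sigma_t u_q + sigma_z u_r and category K_i means "missing"
    (probability 1), so absent halves drop out of the product.
    """
    eta = sigma_t[:, None, None] * nodes[None, :, None] + sigma_z[:, None, None] * nodes[None, None, :]
    aug = []
    for kap in kappas:
        p = _grm_prob_table(kap, eta)  # (W, Q, Q, K)
        ones = np.ones(p.shape[:-1] + (1,))
        aug.append(np.concatenate([p, ones], axis=-1))
    # B: (W, Q, K1+1, K2+1)
    return np.einsum("wqrk,wqrl,r->wqkl", aug[0], aug[1], gw, optimize=True)


def _unit_G(pair_codes, B):
    """Per-subject likelihood profile over trait nodes.

    pair_codes: (N, Tb, 2) augmented category indices; B from _pair_table.
    Returns G[w, n, q] = prod_t B[w, q, c1(n,t), c2(n,t)].
    """
    w, q = B.shape[:2]
    n, tb = pair_codes.shape[:2]
    G = np.ones((w, n, q))
    for t in range(tb):
        g = B[:, :, pair_codes[:, t, 0], pair_codes[:, t, 1]]  # (W, Q, N)
        G *= np.moveaxis(g, 2, 1)
    return G


def _codes_from_panel(y, n_cat):
    """(2, N, T) categories with -1 missing -> (N, T, 2) augmented pair codes."""
    codes = np.empty(y.shape[1:] + (2,), dtype=int)
    for i in range(2):
        yi = y[i]
        codes[:, :, i] = np.where(yi < 0, n_cat[i], yi)
    return codes


def _blocks_to_columns(blocks, time_points):
    tps = list(time_points)
    if blocks is None:
        return [tps]
    flat = [t for b in blocks for t in b]
    if sorted(flat) != sorted(tps):
        raise ValueError(
            f"trait blocks {blocks} do not partition the observed time points {tps}"
        )
    return [list(b) for b in blocks]


def lst_marginal_loglik(categories, thresholds, trait_var, state_var, quad_points=40):
    """Marginal log likelihood of one subject's category array under the LST model.

    ``categories``: (T, 2) integer array (-1 for missing half); ``thresholds``
    the pair of threshold arrays.  Trait and per-occasion state residuals are
    integrated out by nested Gauss-Hermite quadrature.
    """
    cats = np.asarray(categories, dtype=int)
    nodes, gw = _gauss_hermite(quad_points)
    kappas = [np.atleast_2d(np.asarray(k, dtype=float)) for k in thresholds]
    n_cat = [k.shape[1] + 1 for k in kappas]
    codes = np.where(cats < 0, np.array(n_cat)[None, :], cats)[None, :, :]  # (N=1, T, 2)
    B = _pair_table(
        kappas,
        np.sqrt([trait_var]),
        np.sqrt([state_var]),
        nodes,
        gw,
    )
    G = _unit_G(codes, B)  # (1, 1, Q)
    return float(np.log(G[0, 0] @ gw))


class _LSTCore(BaseEstimator):
    """Shared machinery for the single-task and bivariate LST estimators."""

    def __init__(
        self,
        quad_points: int = 15,
        draws: int = 1500,
        tune: int = 200,
        walkers: int | None = None,
        thin: int = 3,
        rhat_max: float | None = 1.01,
        seed: int = 0,
        prior_threshold_sd: float = 2.0,
        prior_sd_scale: float = 1.0,
    ):
        self.quad_points = quad_points
        self.draws = draws
        self.tune = tune
        self.walkers = walkers
        self.thin = thin
        self.rhat_max = rhat_max
        self.seed = seed
        self.prior_threshold_sd = prior_threshold_sd
        self.prior_sd_scale = prior_sd_scale

    # threshold prior + transform bookkeeping -------------------------------
    def _thr_logprior(self, kap, jac):
        return jac - 0.5 * np.sum(kap**2, axis=1) / self.prior_threshold_sd**2

    def _sd_logprior(self, log_sig):
        sig = np.exp(np.clip(log_sig, -30.0, 30.0))
        return -0.5 * (sig / self.prior_sd_scale) ** 2 + log_sig

    def _sample(self, logpost, x0, raw_names):
        x_map = _mcmc.find_map(lambda x: logpost(x)[0], x0)
        return _mcmc.sample_posterior(
            logpost,
            x_map,
            names=raw_names,
            nwalkers=self.walkers,
            nsteps=self.tune + self.draws,
            nburn=self.tune,
            thin=self.thin,
            seed=self.seed,
        )

    @staticmethod
    def _flat(idata, raw_names):
        chain = np.stack([np.asarray(idata.posterior[n]) for n in raw_names], axis=-1)
        c, d, _ = chain.shape
        return chain.reshape(c * d, len(raw_names)), (c, d)

    def _ci_row(self, name):
        s = self.summary_.loc[name]
        return {
            "mean": s["mean"],
            "ci_low": s["ci_low"],
            "ci_high": s["ci_high"],
        }


class LatentStateTraitModel(_LSTCore):
    """Single-task latent state-trait model, optionally with segmented traits.

    Parameters (beyond the sampler settings shared with the bivariate model)
    ----------
    blocks : list of lists of time points, or None
        ``None`` fits one stable trait.  With blocks (e.g. ``[[1..8], [9..14]]``)
        each block has its own trait; traits are correlated across blocks
        (two blocks supported) while the state-residual variance stays common.

    Attributes
    ----------
    trait_var_, state_resid_var_ : posterior summaries (per block / shared).
    consistency_, occasion_specificity_, reliability_ : draw-wise summaries.
    trait_corr_ : between-block trait correlation summary (segmented fit only).
    summary_, idata_, diagnostics_ : full posterior bookkeeping.
    """

    def __init__(self, blocks=None, **kwargs):
        super().__init__(**kwargs)
        self.blocks = blocks

    def fit(self, parcels: pd.DataFrame):
        panel = _panel_from_parcels(parcels)
        y, n_cat = panel["y"], panel["n_cat"]
        cols = _blocks_to_columns(self.blocks, panel["time_points"])
        n_blocks = len(cols)
        if n_blocks > 2:
            raise ValueError("at most two trait blocks are supported")
        t_index = {t: j for j, t in enumerate(panel["time_points"])}
        block_codes = []
        for b in cols:
            idx = [t_index[t] for t in b]
            block_codes.append(_codes_from_panel(y[:, :, idx], n_cat))

        nodes, gw = _gauss_hermite(self.quad_points)
        sizes = [n_cat[0] - 1, n_cat[1] - 1, n_blocks, 1] + ([1] if n_blocks == 2 else [])
        offs = np.concatenate([[0], np.cumsum(sizes)])
        ndim = offs[-1]

        def logpost(theta):
            theta = np.atleast_2d(np.asarray(theta, dtype=float))
            w = theta.shape[0]
            lp = np.zeros(w)
            kappas = []
            for i in range(2):
                kap, jac = _unpack_thresholds(theta[:, offs[i]:offs[i + 1]], n_cat[i])
                lp += self._thr_logprior(kap, jac)
                kappas.append(kap)
            log_sig_t = np.clip(theta[:, offs[2]:offs[3]], -30.0, 30.0)  # (W, n_blocks)
            log_sig_z = np.clip(theta[:, offs[3]], -30.0, 30.0)
            lp += np.sum(self._sd_logprior(log_sig_t), axis=1)
            lp += self._sd_logprior(log_sig_z)
            sig_z = np.exp(log_sig_z)
            Gs = []
            for b in range(n_blocks):
                B = _pair_table(kappas, np.exp(log_sig_t[:, b]), sig_z, nodes, gw)
                Gs.append(_unit_G(block_codes[b], B))
            if n_blocks == 1:
                L = Gs[0] @ gw
            else:
                rho, rho_lp = _rho_from_raw(theta[:, offs[4]])
                lp += rho_lp
                kern = _bvn_kernel(nodes, rho)
                L = np.einsum("wnq,wnp,wqp,q,p->wn", Gs[0], Gs[1], kern, gw, gw, optimize=True)
            lp += np.log(np.clip(L, 1e-300, None)).sum(axis=1)
            return np.where(np.isfinite(lp), lp, -1e300)

        x0 = np.zeros(ndim)
        for i in range(2):
            x0[offs[i]:offs[i + 1]] = _pack_thresholds(_threshold_init(y[i], n_cat[i]))
        names = [f"kappa[{i + 1},{k + 1}]" for i in range(2) for k in range(n_cat[i] - 1)]
        names += [f"sigma_t[{b + 1}]" for b in range(n_blocks)] + ["sigma_z"]
        if n_blocks == 2:
            names += ["trait_corr"]
        raw = [f"theta[{j}]" for j in range(ndim)]
        idata_raw = self._sample(logpost, x0, raw)
        flat, (c, d) = self._flat(idata_raw, raw)

        post = {}
        pos = 0
        for i in range(2):
            kap, _ = _unpack_thresholds(flat[:, offs[i]:offs[i + 1]], n_cat[i])
            for k in range(kap.shape[1]):
                post[names[pos]] = kap[:, k]
                pos += 1
        for b in range(n_blocks):
            post[names[pos]] = np.exp(flat[:, offs[2] + b])
            pos += 1
        post[names[pos]] = np.exp(flat[:, offs[3]])
        pos += 1
        if n_blocks == 2:
            post[names[pos]] = np.tanh(np.clip(flat[:, offs[4]], -6.0, 6.0))

        import arviz as az

        self.idata_ = az.from_dict(
            posterior={k: v.reshape(c, d) for k, v in post.items()}
        )
        self.idata_.attrs.update(getattr(idata_raw, "attrs", {}))
        transform = {}
        for b in range(n_blocks):
            st, sz = f"sigma_t[{b + 1}]", "sigma_z"
            transform[f"var_t[{b + 1}]"] = lambda p, s=st: p[s] ** 2
            transform[f"con[{b + 1}]"] = (
                lambda p, s=st, z=sz: p[s] ** 2 / (p[s] ** 2 + p[z] ** 2)
            )
            transform[f"os[{b + 1}]"] = (
                lambda p, s=st, z=sz: p[z] ** 2 / (p[s] ** 2 + p[z] ** 2)
            )
            transform[f"rel[{b + 1}]"] = (
                lambda p, s=st, z=sz: (p[s] ** 2 + p[z] ** 2) / (p[s] ** 2 + p[z] ** 2 + 1.0)
            )
        transform["var_z"] = lambda p: p["sigma_z"] ** 2
        self.summary_ = _mcmc.summarize_draws(self.idata_, transform=transform)
        _mcmc.check_convergence(
            self.summary_.loc[names], self.rhat_max, "latent state-trait model"
        )

        self.panel_ = panel
        self.block_columns_ = cols
        self.n_blocks_ = n_blocks
        self.trait_var_ = pd.DataFrame(
            [{"block": b + 1, **self._ci_row(f"var_t[{b + 1}]")} for b in range(n_blocks)]
        )
        self.state_resid_var_ = self._ci_row("var_z")
        self.consistency_ = pd.DataFrame(
            [{"block": b + 1, **self._ci_row(f"con[{b + 1}]")} for b in range(n_blocks)]
        )
        self.occasion_specificity_ = pd.DataFrame(
            [{"block": b + 1, **self._ci_row(f"os[{b + 1}]")} for b in range(n_blocks)]
        )
        self.reliability_ = pd.DataFrame(
            [{"block": b + 1, **self._ci_row(f"rel[{b + 1}]")} for b in range(n_blocks)]
        )
        self.trait_corr_ = self._ci_row("trait_corr") if n_blocks == 2 else None
        self.diagnostics_ = self.summary_[["rhat", "ess_bulk"]]
        return self

    # ------------------------------------------------------------------
    def _component(self, stem: str) -> pd.DataFrame:
        draws = {}
        post = self.idata_.posterior
        for b in range(self.n_blocks_):
            st = np.asarray(post[f"sigma_t[{b + 1}]"]).reshape(-1)
            sz = np.asarray(post["sigma_z"]).reshape(-1)
            denom = st**2 + sz**2
            ok = denom > 0
            if not ok.all():
                warnings.warn(f"excluded {np.sum(~ok)} zero-variance draws")
            st, sz, denom = st[ok], sz[ok], denom[ok]
            if stem == "con":
                v = st**2 / denom
            elif stem == "os":
                v = sz**2 / denom
            else:
                v = denom / (denom + 1.0)
            draws[b + 1] = v
        return pd.DataFrame(
            [
                {
                    "block": b,
                    "mean": float(v.mean()),
                    "ci_low": float(np.quantile(v, 0.025)),
                    "ci_high": float(np.quantile(v, 0.975)),
                }
                for b, v in draws.items()
            ]
        )

    def consistency(self) -> pd.DataFrame:
        """Draw-wise Con = Var(T)/(Var(T)+Var(zeta)), summarized."""
        return self._component("con")

    def occasion_specificity(self) -> pd.DataFrame:
        """Draw-wise OS = 1 - Con, summarized."""
        return self._component("os")

    def reliability(self) -> pd.DataFrame:
        """Draw-wise Rel = (Var(T)+Var(zeta))/(Var(T)+Var(zeta)+1), summarized."""
        return self._component("rel")

    def posterior_predictive_check(
        self, n_sims: int = 200, seed: int = 0, alpha: float = 0.05
    ) -> pd.DataFrame:
        """Check per-time-point mean category scores against replications.

        Simulates cohorts of the fitted size from random posterior draws and
        compares each observed time point's mean category (both halves
        pooled) with the replicated 1-alpha band.  ``outside=True`` rows mark
        candidate misfit, e.g. trait shifts the stable-trait model misses.
        """
        rng = np.random.default_rng(seed)
        y = self.panel_["y"]
        n_cat = self.panel_["n_cat"]
        n_sub = y.shape[1]
        tps = self.panel_["time_points"]
        post = self.idata_.posterior
        sig_t = np.asarray(post["sigma_t[1]"]).reshape(-1)
        sig_z = np.asarray(post["sigma_z"]).reshape(-1)
        kappas = [
            np.stack(
                [np.asarray(post[f"kappa[{i + 1},{k + 1}]"]).reshape(-1) for k in range(n_cat[i] - 1)],
                axis=1,
            )
            for i in range(2)
        ]
        sims = np.empty((n_sims, len(tps)))
        pick = rng.integers(0, len(sig_t), size=n_sims)
        for s, j in enumerate(pick):
            T = sig_t[j] * rng.standard_normal(n_sub)
            for ti in range(len(tps)):
                z = sig_z[j] * rng.standard_normal(n_sub)
                cats = []
                for i in range(2):
                    ystar = T + z + rng.standard_normal(n_sub)
                    cats.append(np.searchsorted(kappas[i][j], ystar))
                sims[s, ti] = np.mean(np.concatenate(cats))
        rows = []
        for ti, t in enumerate(tps):
            observed = np.concatenate([y[i][:, ti][y[i][:, ti] >= 0] for i in range(2)])
            obs_mean = observed.mean() if observed.size else np.nan
            lo, hi = np.quantile(sims[:, ti], [alpha / 2, 1 - alpha / 2])
            rows.append(
                {
                    "time_point": t,
                    "observed_mean_category": obs_mean,
                    "pred_low": lo,
                    "pred_high": hi,
                    "outside": bool(obs_mean < lo or obs_mean > hi),
                }
            )
        return pd.DataFrame(rows)


class BivariateLatentStateTraitModel(_LSTCore):
    """Pairwise two-task LST model with correlated traits.

    Each task keeps its own thresholds, trait variance and state-residual
    variance; the two traits are bivariate normal with correlation rho
    (uniform prior); state residuals and errors are uncorrelated across
    tasks.  ``substantial_`` flags whether the 95% CrI of rho excludes zero
    (reported alongside the interval, never instead of it).
    """

    def fit(self, parcels_a: pd.DataFrame, parcels_b: pd.DataFrame):
        pa = parcels_a.dropna(subset=["category"])
        pb = parcels_b.dropna(subset=["category"])
        subjects = np.sort(
            np.union1d(pa["subject_id"].unique(), pb["subject_id"].unique())
        )
        overlap = np.intersect1d(pa["subject_id"].unique(), pb["subject_id"].unique())
        if overlap.size == 0:
            raise ValueError("tasks share no subjects; a joint trait model is undefined")
        phases = set(pa.get("phase", pd.Series([1])).unique()) | set(
            pb.get("phase", pd.Series([1])).unique()
        )
        if len(phases) > 1:
            raise ValueError("both tasks must come from the same phase")

        panels = []
        for p in (pa, pb):
            full = p.copy()
            # align subject axes across the two tasks
            pad = pd.DataFrame(
                {
                    "subject_id": [s for s in subjects if s not in set(p["subject_id"])],
                }
            )
            if len(pad):
                pad["time_point"] = p["time_point"].iloc[0]
                pad["half"] = 1
                pad["category"] = np.nan
                full = pd.concat([full, pad], ignore_index=True)
            panels.append(_panel_from_parcels(full[["subject_id", "time_point", "half", "category"]]))

        nodes, gw = _gauss_hermite(self.quad_points)
        n_cats = [panels[0]["n_cat"], panels[1]["n_cat"]]
        codes = [_codes_from_panel(p["y"], nc) for p, nc in zip(panels, n_cats)]
        sizes = (
            [n_cats[0][0] - 1, n_cats[0][1] - 1, n_cats[1][0] - 1, n_cats[1][1] - 1]
            + [1, 1, 1, 1, 1]
        )  # sigma_t a/b, sigma_z a/b, atanh rho
        offs = np.concatenate([[0], np.cumsum(sizes)])
        ndim = offs[-1]

        def logpost(theta):
            theta = np.atleast_2d(np.asarray(theta, dtype=float))
            w = theta.shape[0]
            lp = np.zeros(w)
            kappas = []
            for j in range(4):
                task, half = divmod(j, 2)
                kap, jac = _unpack_thresholds(
                    theta[:, offs[j]:offs[j + 1]], n_cats[task][half]
                )
                lp += self._thr_logprior(kap, jac)
                kappas.append(kap)
            log_st = [np.clip(theta[:, offs[4]], -30, 30), np.clip(theta[:, offs[5]], -30, 30)]
            log_sz = [np.clip(theta[:, offs[6]], -30, 30), np.clip(theta[:, offs[7]], -30, 30)]
            for ls in (*log_st, *log_sz):
                lp += self._sd_logprior(ls)
            rho, rho_lp = _rho_from_raw(theta[:, offs[8]])
            lp += rho_lp
            Gs = []
            for u in range(2):
                B = _pair_table(
                    kappas[2 * u : 2 * u + 2],
                    np.exp(log_st[u]),
                    np.exp(log_sz[u]),
                    nodes,
                    gw,
                )
                Gs.append(_unit_G(codes[u], B))
            kern = _bvn_kernel(nodes, rho)
            L = np.einsum("wnq,wnp,wqp,q,p->wn", Gs[0], Gs[1], kern, gw, gw, optimize=True)
            lp += np.log(np.clip(L, 1e-300, None)).sum(axis=1)
            return np.where(np.isfinite(lp), lp, -1e300)

        x0 = np.zeros(ndim)
        for j in range(4):
            task, half = divmod(j, 2)
            x0[offs[j]:offs[j + 1]] = _pack_thresholds(
                _threshold_init(panels[task]["y"][half], n_cats[task][half])
            )
        labels = ["a", "b"]
        names = []
        for j in range(4):
            task, half = divmod(j, 2)
            names += [
                f"kappa_{labels[task]}[{half + 1},{k + 1}]"
                for k in range(n_cats[task][half] - 1)
            ]
        names += ["sigma_t_a", "sigma_t_b", "sigma_z_a", "sigma_z_b", "trait_corr"]
        raw = [f"theta[{j}]" for j in range(ndim)]
        idata_raw = self._sample(logpost, x0, raw)
        flat, (c, d) = self._flat(idata_raw, raw)

        post = {}
        pos = 0
        for j in range(4):
            task, half = divmod(j, 2)
            kap, _ = _unpack_thresholds(flat[:, offs[j]:offs[j + 1]], n_cats[task][half])
            for k in range(kap.shape[1]):
                post[names[pos]] = kap[:, k]
                pos += 1
        for j in range(4):
            post[names[pos]] = np.exp(flat[:, offs[4 + j]])
            pos += 1
        post["trait_corr"] = np.tanh(np.clip(flat[:, offs[8]], -6.0, 6.0))

        import arviz as az

        self.idata_ = az.from_dict(posterior={k: v.reshape(c, d) for k, v in post.items()})
        self.idata_.attrs.update(getattr(idata_raw, "attrs", {}))
        transform = {}
        for lab in labels:
            st, sz = f"sigma_t_{lab}", f"sigma_z_{lab}"
            transform[f"con_{lab}"] = lambda p, s=st, z=sz: p[s] ** 2 / (p[s] ** 2 + p[z] ** 2)
            transform[f"rel_{lab}"] = (
                lambda p, s=st, z=sz: (p[s] ** 2 + p[z] ** 2) / (p[s] ** 2 + p[z] ** 2 + 1.0)
            )
        self.summary_ = _mcmc.summarize_draws(self.idata_, transform=transform)
        _mcmc.check_convergence(
            self.summary_.loc[names], self.rhat_max, "bivariate latent state-trait model"
        )
        self.subjects_ = subjects
        self.trait_corr_ = self._ci_row("trait_corr")
        self.substantial_ = bool(
            self.trait_corr_["ci_low"] > 0 or self.trait_corr_["ci_high"] < 0
        )
        self.components_ = self.summary_.loc[
            [f"con_{l}" for l in labels] + [f"rel_{l}" for l in labels]
        ]
        self.diagnostics_ = self.summary_[["rhat", "ess_bulk"]]
        return self


# ---------------------------------------------------------------------------
# functional wrappers

def fit_lst(parcels: pd.DataFrame, blocks=None, **kwargs) -> LatentStateTraitModel:
    return LatentStateTraitModel(blocks=blocks, **kwargs).fit(parcels)


def fit_bivariate_lst(parcels_a, parcels_b, **kwargs) -> BivariateLatentStateTraitModel:
    return BivariateLatentStateTraitModel(**kwargs).fit(parcels_a, parcels_b)


def consistency(fit: LatentStateTraitModel) -> pd.DataFrame:
    return fit.consistency()


def occasion_specificity(fit: LatentStateTraitModel) -> pd.DataFrame:
    return fit.occasion_specificity()


def lst_reliability(fit: LatentStateTraitModel) -> pd.DataFrame:
    return fit.reliability()
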