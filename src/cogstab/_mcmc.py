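"""Posterior computation backbone: MAP start, affine-invariant ensemble MCMC,
convergence checks and tidy summaries.

All latent-variable models in this package marginalize their subject-level
latent variables by Gauss-Hermite quadrature, leaving a small structural
parameter vector that is sampled with :mod:`emcee`.  Walkers are initialized
in a tight ball around the posterior mode and treated as chains for split-R̂
and effective-sample-size diagnostics via :mod:`arviz`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = ["ConvergenceError", "find_map", "sample_posterior", "summarize_draws"]


class ConvergenceError(RuntimeError):
    """The sampler did not meet the convergence contract (R̂/ESS)."""


def find_map(logpost, x0: np.ndarray, maxiter: int = 500) -> np.ndarray:
    """Posterior mode via L-BFGS-B with numerical gradients.

    ``logpost`` takes a single parameter vector.  Falls back to the best
    point seen if the optimizer reports failure.
    """
    neg = lambda x: -float(logpost(x))
    res = optimize.minimize(neg, np.asarray(x0, dtype=float), method="L-BFGS-B",
                            options={"maxiter": maxiter})
    if not np.isfinite(res.fun):
        raise RuntimeError("MAP optimization diverged; check the model inputs")
    return res.x


def numerical_hessian(logpost_vec, x: np.ndarray, h: float = 1e-3) -> np.ndarray:
    """Central-difference Hessian of the log posterior, batched through the
    vectorized density."""
    d = len(x)
    steps = h * np.maximum(np.abs(x), 1.0)
    points = [x]
    for i in range(d):
        for si in (+1, -1):
            p = x.copy()
            p[i] += si * steps[i]
            points.append(p)
    for i in range(d):
        for j in range(i + 1, d):
            for si, sj in ((1, 1), (1, -1), (-1, 1), (-1, -1)):
                p = x.copy()
                p[i] += si * steps[i]
                p[j] += sj * steps[j]
                points.append(p)
    vals = logpost_vec(np.asarray(points))
    f0 = vals[0]
    H = np.empty((d, d))
    k = 1 + 2 * d
    for i in range(d):
        H[i, i] = (vals[1 + 2 * i] - 2 * f0 + vals[2 + 2 * i]) / steps[i] ** 2
    for i in range(d):
        for j in range(i + 1, d):
            fpp, fpm, fmp, fmm = vals[k:k + 4]
            k += 4
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * steps[i] * steps[j])
    return H


def laplace_factor(logpost_vec, x_map: np.ndarray) -> np.ndarray:
    """Cholesky factor C of the Laplace covariance (cov = C @ C.T) at the mode."""
    H = numerical_hessian(logpost_vec, x_map)
    A = -(H + H.T) / 2
    # guard against indefinite curvature from flat/noisy directions
    w, V = np.linalg.eigh(A)
    w = np.clip(w, 1e-6 * np.max(np.abs(w)), None)
    cov = (V / w) @ V.T
    return np.linalg.cholesky(cov)


class _IndependenceProposal:
    """Multivariate-t independence proposal for :class:`emcee.moves.MHMove`.

    With an independence proposal every walker is an independent Markov
    chain, so treating walkers as chains in the diagnostics is exact.
    """

    def __init__(self, mean: np.ndarray, chol: np.ndarray, df: float = 8.0):
        self.mean = mean
        self.chol = chol
        self.df = df
        self._prec = np.linalg.inv(chol)
        self._ndim = len(mean)

    def logq(self, x: np.ndarray) -> np.ndarray:
        z = (np.atleast_2d(x) - self.mean) @ self._prec.T
        r2 = np.sum(z**2, axis=1)
        return -0.5 * (self.df + self._ndim) * np.log1p(r2 / self.df)

    def _mvt(self, random, n):
        # elliptical multivariate t: one chi-square mixing variable per draw,
        # matching the density used in the acceptance ratio
        z = random.standard_normal((n, self._ndim))
        u = random.chisquare(self.df, size=n)
        return z / np.sqrt(u / self.df)[:, None]

    def __call__(self, coords, random):
        new = self.mean + self._mvt(random, coords.shape[0]) @ self.chol.T
        factors = self.logq(coords) - self.logq(new)
        return new, factors

    def draw(self, random, n):
        return self.mean + self._mvt(random, n) @ self.chol.T


def sample_posterior(
    logpost_vec,
    x_map: np.ndarray,
    *,
    names: list[str],
    nwalkers: int | None = None,
    nsteps: int = 1200,
    nburn: int = 400,
    thin: int = 1,
    seed: int = 0,
    proposal_df: float = 8.0,
    proposal_scale: float = 1.1,
):
    """Metropolized independence sampling around the Laplace approximation.

    ``logpost_vec`` maps an (nwalkers, ndim) matrix to a length-nwalkers
    vector of log posterior densities.  A first stage proposes from the
    Laplace approximation at the mode; the proposal is then moment-matched
    to the pilot draws and the main stage is run.  Walkers are independent
    chains (independence proposal), so split-R̂/ESS across walkers is exact.
    ``nburn`` sizes the pilot stage; ``nsteps`` the kept stage.
    """
    import arviz as az
    import emcee

    ndim = len(x_map)
    if nwalkers is None:
        nwalkers = max(2 * ndim + 2, 32)
    nwalkers += nwalkers % 2

    C = laplace_factor(logpost_vec, x_map)
    rs = np.random.RandomState(seed & 0x7FFFFFFF)

    def run(proposal, p0, n):
        move = emcee.moves.MHMove(proposal)
        sampler = emcee.EnsembleSampler(
            nwalkers, ndim, logpost_vec, vectorize=True, moves=move
        )
        sampler.random_state = rs
        sampler.run_mcmc(p0, n, progress=False, skip_initial_state_check=True)
        return sampler

    # adaptation: start from the Laplace approximation, then moment-match the
    # proposal to pilot draws, repeating while acceptance stays poor (skewed
    # or weakly identified posteriors need a few rounds)
    pilot_len = max(nburn, 100)
    prop = _IndependenceProposal(x_map, proposal_scale * C, df=proposal_df)
    state = prop.draw(rs, nwalkers)
    cov0 = C @ C.T
    for round_ in range(5):
        pilot = run(prop, state, pilot_len)
        state = pilot.get_last_sample().coords
        acc = float(np.mean(pilot.acceptance_fraction))
        pchain = pilot.get_chain(discard=pilot_len // 2).reshape(-1, ndim)
        mean = pchain.mean(axis=0)
        cov = np.cov(pchain.T) if ndim > 1 else np.atleast_2d(np.var(pchain))
        # blend with the Laplace covariance for stability at small pilot sizes
        w = 0.85 if round_ else 0.7
        cov = w * cov + (1 - w) * cov0 + 1e-10 * np.eye(ndim)
        df = proposal_df if round_ == 0 else max(proposal_df / 2, 4)
        prop = _IndependenceProposal(
            mean, proposal_scale * np.linalg.cholesky(cov), df=df
        )
        if acc >= 0.2 and round_ >= 1:
            break
    main = run(prop, state, nsteps)
    accept = float(np.mean(main.acceptance_fraction))
    chain = main.get_chain(discard=min(50, nsteps // 10), thin=thin)

    posterior = {
        name: np.moveaxis(chain[:, :, j], 0, 1) for j, name in enumerate(names)
    }
    idata = az.from_dict(posterior=posterior)
    idata.attrs["acceptance_fraction"] = accept
    return idata


def summarize_draws(idata, transform: dict | None = None) -> pd.DataFrame:
    """Tidy per-parameter summary: mean, sd, equal-tailed 95% CrI, R̂, ESS.

    ``transform`` optionally maps *new* parameter names to draw-wise
    functions of the posterior dict (e.g. reliability from a variance).
    Derived quantities are summarized draw-wise, not from summaries.
    """
    import arviz as az

    post = {k: np.asarray(v) for k, v in idata.posterior.items()}
    if transform:
        for name, fn in transform.items():
            post[name] = fn(post)

    rows = []
    for name, draws in post.items():
        flat = draws.reshape(-1)
        da = az.convert_to_dataset({name: draws})
        rows.append(
            {
                "parameter": name,
                "mean": float(flat.mean()),
                "sd": float(flat.std(ddof=1)),
                "ci_low": float(np.quantile(flat, 0.025)),
                "ci_high": float(np.quantile(flat, 0.975)),
                "rhat": float(az.rhat(da)[name].values),
                "ess_bulk": float(az.ess(da)[name].values),
            }
        )
    return pd.DataFrame(rows).set_index("parameter")


def check_convergence(summary: pd.DataFrame, rhat_max: float | None, context: str) -> None:
    if rhat_max is None:
        return
    bad = summary[summary["rhat"] > rhat_max]
    if len(bad):
        raise ConvergenceError(
            f"{context}: R-hat above {rhat_max} for "
            f"{bad.index.tolist()} (max {bad['rhat'].max():.4f}); "
            "increase draws or check the model"
        )
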