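"""Projection-predictive selection of performance predictors.

Reference model: hierarchical binomial regression of per-time-point correct
counts on all 14 predictors plus a subject random intercept (logit link),

    k_it ~ Binomial(n_it, p_it),  logit(p_it) = b0 + x_it' beta + u_i,
    u_i ~ N(0, sigma_u^2),

fit either by a Laplace approximation of the joint posterior (default; fast
and accurate at these data sizes) or by MCMC.  Selection replaces the
reference posterior with the minimum-KL posterior of a smaller submodel:
for the binomial family the KL-optimal projection of a reference draw is the
maximum-likelihood fit of the submodel to that draw's fitted probabilities
(trial-total weighted).  A greedy forward search ranks terms by KL
reduction, with the random intercept forced to the last position so fixed
predictors get to explain variance first; per-size predictive utility
(elpd, r.m.s.e.) is estimated by Pareto-smoothed importance-sampling
leave-one-out using the reference posterior's weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logsumexp
from scipy.stats import binom
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans

from .data import PREDICTOR_CATEGORIES, PREDICTORS

__all__ = [
    "build_design",
    "HierarchicalBinomialReference",
    "ProjectedSubmodel",
    "ProjectionPath",
    "project_submodel",
    "forward_search",
    "select_submodel",
    "ProjectionPredictiveSelector",
    "performance_counts",
]

#: reference levels for categorical predictors (coefficients are contrasts
#: against these)
REFERENCE_LEVELS = {"group": "bonobo", "sex": "male", "rearing_history": "hand",
                    "observer_present": 0}


def performance_counts(trials: pd.DataFrame, task: str, phase: int) -> pd.DataFrame:
    """Correct-trial counts per subject x time point for one task and phase."""
    t = trials[(trials["task"] == task) & (trials["phase"] == phase)]
    g = t.groupby(["subject_id", "time_point"])["outcome"]
    out = g.agg(n_correct="sum", n_trials="size").reset_index()
    return out


def build_design(diary: pd.DataFrame, phase: int):
    """Expand the predictor diary into a numeric design matrix.

    Categorical predictors become treatment contrasts against the documented
    reference levels; continuous predictors are standardized.  Returns
    ``(X, term_map)`` where ``X`` is indexed by (subject_id, time_point) and
    ``term_map`` maps each of the 14 predictors to its column names.
    """
    d = diary[diary["phase"] == phase]
    wide = d.pivot_table(
        index=["subject_id", "time_point"], columns="predictor", values="value",
        aggfunc="first",
    )
    missing = set(PREDICTORS) - set(wide.columns)
    if missing:
        raise ValueError(f"diary lacks predictors: {sorted(missing)}")
    cols = {}
    term_map: dict[str, list[str]] = {}
    for pred in PREDICTORS:
        col = wide[pred]
        numeric = pd.to_numeric(col, errors="coerce")
        if numeric.isna().any():  # categorical
            ref = REFERENCE_LEVELS.get(pred)
            levels = sorted(col.astype(str).unique())
            ref = str(ref) if ref is not None else levels[0]
            names = []
            for lev in levels:
                if lev == ref:
                    continue
                name = f"{pred}[{lev}]"
                cols[name] = (col.astype(str) == lev).astype(float)
                names.append(name)
            term_map[pred] = names
        else:
            x = numeric.astype(float)
            sd = x.std()
            cols[pred] = (x - x.mean()) / (sd if sd > 0 else 1.0)
            term_map[pred] = [pred]
    X = pd.DataFrame(cols)
    dup = [n for n, c in X.items() if c.std() == 0]
    X = X.drop(columns=dup)
    for pred in term_map:
        term_map[pred] = [n for n in term_map[pred] if n in X.columns]
    # alias check: rank deficiency among retained columns
    arr = X.to_numpy()
    if arr.shape[1] and np.linalg.matrix_rank(arr - arr.mean(0)) < min(arr.shape[1], arr.shape[0] - 1):
        corr = np.corrcoef(arr.T)
        np.fill_diagonal(corr, 0)
        pairs = np.argwhere(np.abs(corr) > 0.999)
        names = [(X.columns[i], X.columns[j]) for i, j in pairs if i < j]
        raise ValueError(f"predictor matrix is rank deficient; aliased columns: {names}")
    return X, term_map


def _fit_penalized_logit(D, y_frac, weights, ridge, beta0=None, max_iter=100, tol=1e-9):
    """Damped Newton fit of a weighted logistic likelihood with diagonal ridge.

    A small floor on the penalty keeps the system well conditioned when
    penalized columns span unpenalized ones (subject dummies nest group
    dummies); step halving guards against overshooting.
    """
    p = D.shape[1]
    ridge = np.maximum(ridge, 1e-6)
    beta = np.zeros(p) if beta0 is None else beta0.copy()

    def objective(b):
        mu = np.clip(expit(D @ b), 1e-12, 1 - 1e-12)
        ll = np.sum(weights * (y_frac * np.log(mu) + (1 - y_frac) * np.log(1 - mu)))
        return ll - 0.5 * np.sum(ridge * b**2)

    obj = objective(beta)
    H = np.eye(p)
    for _ in range(max_iter):
        mu = expit(D @ beta)
        wt = weights * mu * (1 - mu) + 1e-12
        grad = D.T @ (weights * (y_frac - mu)) - ridge * beta
        H = (D * wt[:, None]).T @ D + np.diag(ridge)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        scale = 1.0
        for _ in range(25):
            cand = beta + scale * step
            cobj = objective(cand)
            if cobj >= obj - 1e-12:
                break
            scale /= 2
        if not np.isfinite(cobj):
            return beta, H, False
        moved = np.max(np.abs(scale * step))
        beta, obj = cand, cobj
        if moved < tol:
            return beta, H, True
    return beta, H, False


class HierarchicalBinomialReference(BaseEstimator):
    """Bayesian hierarchical binomial reference model (logit link).

    Parameters
    ----------
    method : {"laplace", "mcmc"}
        Posterior computation.  Laplace: joint mode of (intercept,
        coefficients, random effects) with the random-effect SD estimated by
        iterated moment matching, Gaussian draws from the curvature.  MCMC:
        ensemble sampling of the full posterior including the SD, with R̂/ESS
        diagnostics.
    random_slope : str or None
        Optional design column whose coefficient also varies by subject
        (e.g. a standardized time-point column for gaze following).
    n_draws : int
        Posterior draws retained (Laplace) or targeted (MCMC).

    Attributes
    ----------
    coef_draws_, intercept_draws_, u_draws_ : posterior draws.
    sigma_u_ : random-intercept SD (posterior mean for MCMC).
    prob_draws_ : (draws, observations) fitted success probabilities.
    loglik_draws_ : pointwise binomial log likelihood per draw.
    summary_ : coefficient summary with 95% CrIs.
    """

    def __init__(
        self,
        method: str = "laplace",
        n_draws: int = 400,
        prior_coef_sd: float = 2.5,
        prior_intercept_sd: float = 5.0,
        random_slope: str | None = None,
        seed: int = 0,
        draws: int = 1500,
        tune: int = 300,
        thin: int = 3,
        rhat_max: float | None = 1.01,
    ):
        self.method = method
        self.n_draws = n_draws
        self.prior_coef_sd = prior_coef_sd
        self.prior_intercept_sd = prior_intercept_sd
        self.random_slope = random_slope
        self.seed = seed
        self.draws = draws
        self.tune = tune
        self.thin = thin
        self.rhat_max = rhat_max

    # ------------------------------------------------------------------
    def _assemble(self, X, counts):
        merged = counts.merge(
            X.reset_index(), on=["subject_id", "time_point"], how="inner", validate="one_to_one"
        )
        if len(merged) != len(counts):
            raise ValueError("counts rows lack matching diary rows")
        self.feature_names_ = [c for c in X.columns]
        subjects = np.sort(merged["subject_id"].unique())
        self.subjects_ = subjects
        j_idx = merged["subject_id"].map({s: j for j, s in enumerate(subjects)}).to_numpy()
        return merged, j_idx

    def fit(self, X: pd.DataFrame, counts: pd.DataFrame):
        """X: design from :func:`build_design`; counts: n_correct / n_trials rows."""
        merged, j_idx = self._assemble(X, counts)
        F = merged[self.feature_names_].to_numpy(dtype=float)
        k = merged["n_correct"].to_numpy(dtype=float)
        n = merged["n_trials"].to_numpy(dtype=float)
        J = len(self.subjects_)
        nobs, p = F.shape
        Z = np.zeros((nobs, J))
        Z[np.arange(nobs), j_idx] = 1.0
        blocks = [("intercept_re", Z)]
        if self.random_slope is not None:
            s = merged[self.random_slope].to_numpy(dtype=float)
            blocks.append(("slope_re", Z * s[:, None]))

        self._obs_ = {"k": k, "n": n, "F": F, "j_idx": j_idx, "blocks": blocks}
        if self.method == "laplace":
            self._fit_laplace()
        elif self.method == "mcmc":
            self._fit_mcmc()
        else:
            raise ValueError(f"unknown method {self.method!r}")

        self.prob_draws_ = expit(self._eta_draws_)
        self.loglik_draws_ = binom.logpmf(k[None, :], n[None, :], self.prob_draws_)
        self.summary_ = self._summarize()
        return self

    # ------------------------------------------------------------------
    def _design_full(self):
        F = self._obs_["F"]
        mats = [np.ones((F.shape[0], 1)), F] + [Z for _, Z in self._obs_["blocks"]]
        return np.concatenate(mats, axis=1)

    def _fit_laplace(self):
        o = self._obs_
        k, n, F = o["k"], o["n"], o["F"]
        nobs, p = F.shape
        D = self._design_full()
        nb = len(o["blocks"])
        J = o["blocks"][0][1].shape[1]
        sig = np.ones(nb)
        y_frac = k / np.maximum(n, 1)
        beta = None
        for _ in range(25):
            ridge = np.concatenate(
                [
                    [1 / self.prior_intercept_sd**2],
                    np.full(p, 1 / self.prior_coef_sd**2),
                ]
                + [np.full(J, 1 / s**2) for s in sig]
            )
            beta, H, _ = _fit_penalized_logit(D, y_frac, n, ridge, beta0=beta)
            cov = np.linalg.inv(H)
            new_sig = []
            for b in range(nb):
                sl = slice(1 + p + b * J, 1 + p + (b + 1) * J)
                u = beta[sl]
                var = np.diag(cov)[sl]
                new_sig.append(np.sqrt(np.mean(u**2 + var)))
            new_sig = np.asarray(new_sig)
            if np.allclose(new_sig, sig, rtol=1e-4):
                sig = new_sig
                break
            sig = new_sig
        # final curvature at the mode with the converged SDs
        ridge = np.concatenate(
            [[1 / self.prior_intercept_sd**2], np.full(p, 1 / self.prior_coef_sd**2)]
            + [np.full(J, 1 / s**2) for s in sig]
        )
        beta, H, _ = _fit_penalized_logit(D, y_frac, n, ridge, beta0=beta)
        cov = np.linalg.inv(H)
        rng = np.random.default_rng(self.seed)
        L = np.linalg.cholesky((cov + cov.T) / 2 + 1e-12 * np.eye(len(beta)))
        draws = beta[None, :] + rng.standard_normal((self.n_draws, len(beta))) @ L.T
        self._store_draws(draws, sig, D)
        self.diagnostics_ = None

    def _fit_mcmc(self):
        from . import _mcmc

        o = self._obs_
        k, n, F = o["k"], o["n"], o["F"]
        nobs, p = F.shape
        nb = len(o["blocks"])
        J = o["blocks"][0][1].shape[1]
        Zmats = [Z for _, Z in o["blocks"]]
        ndim = 1 + p + nb * J + nb

        def logpost(theta):
            theta = np.atleast_2d(np.asarray(theta, dtype=float))
            w = theta.shape[0]
            b0 = theta[:, 0]
            beta = theta[:, 1:1 + p]
            lp = -0.5 * (b0 / self.prior_intercept_sd) ** 2
            lp = lp - 0.5 * np.sum((beta / self.prior_coef_sd) ** 2, axis=1)
            eta = b0[:, None] + beta @ F.T
            for b in range(nb):
                sl = slice(1 + p + b * J, 1 + p + (b + 1) * J)
                u_raw = theta[:, sl]
                log_sig = np.clip(theta[:, 1 + p + nb * J + b], -30, 30)
                sigb = np.exp(log_sig)
                lp = lp - 0.5 * np.sum(u_raw**2, axis=1)
                lp = lp - 0.5 * sigb**2 + log_sig  # half-Normal(1) + Jacobian
                eta = eta + (u_raw * sigb[:, None]) @ Zmats[b].T
            pr = expit(eta)
            ll = k[None, :] * np.log(np.clip(pr, 1e-12, 1)) + (n - k)[None, :] * np.log(
                np.clip(1 - pr, 1e-12, 1)
            )
            lp = lp + ll.sum(axis=1)
            return np.where(np.isfinite(lp), lp, -1e300)

        x0 = np.zeros(ndim)
        x_map = _mcmc.find_map(lambda x: logpost(x)[0], x0)
        raw = [f"theta[{j}]" for j in range(ndim)]
        idata = _mcmc.sample_posterior(
            logpost, x_map, names=raw, nsteps=self.tune + self.draws,
            nburn=self.tune, thin=self.thin, seed=self.seed,
        )
        chain = np.stack([np.asarray(idata.posterior[r]) for r in raw], axis=-1)
        flat = chain.reshape(-1, ndim)
        if len(flat) > self.n_draws:
            sel = np.linspace(0, len(flat) - 1, self.n_draws).astype(int)
            flat_kept = flat[sel]
        else:
            flat_kept = flat
        sig = np.exp(flat_kept[:, 1 + p + nb * J:])
        # convert non-centered to centered random effects
        centered = flat_kept.copy()
        for b in range(nb):
            sl = slice(1 + p + b * J, 1 + p + (b + 1) * J)
            centered[:, sl] = flat_kept[:, sl] * sig[:, b][:, None]
        D = self._design_full()
        self._store_draws(centered[:, : 1 + p + nb * J], sig.mean(axis=0), D, per_draw_sig=sig)
        names = ["intercept"] + self.feature_names_
        post = {nm: chain[:, :, j] for j, nm in enumerate(names)}
        post["sigma_u"] = np.exp(chain[:, :, 1 + p + nb * J])
        import arviz as az

        self.idata_ = az.from_dict(posterior=post)
        summ = _mcmc.summarize_draws(self.idata_)
        _mcmc.check_convergence(summ, self.rhat_max, "binomial reference model")
        self.diagnostics_ = summ[["rhat", "ess_bulk"]]

    def _store_draws(self, draws, sig, D, per_draw_sig=None):
        p = self._obs_["F"].shape[1]
        self.intercept_draws_ = draws[:, 0]
        self.coef_draws_ = draws[:, 1:1 + p]
        self.u_draws_ = draws[:, 1 + p:]
        self.sigma_u_ = float(sig[0])
        self.sigma_blocks_ = np.asarray(sig)
        self.sigma_u_draws_ = per_draw_sig[:, 0] if per_draw_sig is not None else None
        self._eta_draws_ = draws @ D.T

    def _summarize(self):
        rows = []
        names = ["intercept"] + self.feature_names_
        mat = np.concatenate([self.intercept_draws_[:, None], self.coef_draws_], axis=1)
        for j, nm in enumerate(names):
            d = mat[:, j]
            rows.append(
                {
                    "term": nm,
                    "mean": d.mean(),
                    "sd": d.std(ddof=1),
                    "ci_low": np.quantile(d, 0.025),
                    "ci_high": np.quantile(d, 0.975),
                }
            )
        return pd.DataFrame(rows).set_index("term")


# ---------------------------------------------------------------------------
# projection

@dataclass
class ProjectedSubmodel:
    terms: tuple
    columns: list
    coef: np.ndarray          # (clusters, n_params)
    weights: np.ndarray       # cluster weights (sum 1)
    assignment: np.ndarray    # reference draw -> cluster
    kl: float                 # weighted mean KL (per-trial scale)
    prob: np.ndarray          # (clusters, n_obs)
    with_random_intercept: bool
    n_failed: int = 0


def _binom_kl(p_ref, q_sub, totals):
    p = np.clip(p_ref, 1e-10, 1 - 1e-10)
    q = np.clip(q_sub, 1e-10, 1 - 1e-10)
    kl = totals * (p * np.log(p / q) + (1 - p) * np.log((1 - p) / (1 - q)))
    return float(kl.sum())


def _cluster_reference(ref, n_clusters, seed):
    P = ref.prob_draws_
    n_clusters = min(n_clusters, len(P))
    km = KMeans(n_clusters=n_clusters, n_init=3, random_state=seed & 0x7FFFFFFF).fit(P)
    centers = np.clip(km.cluster_centers_, 1e-6, 1 - 1e-6)
    weights = np.bincount(km.labels_, minlength=n_clusters).astype(float)
    return centers, weights / weights.sum(), km.labels_


def project_submodel(
    ref: HierarchicalBinomialReference,
    terms,
    n_clusters: int = 20,
    seed: int = 0,
    family: str = "binomial",
    _clusters=None,
) -> ProjectedSubmodel:
    """KL-project the reference posterior onto the submodel spanned by ``terms``.

    ``terms`` is a subset of the predictor names plus optionally
    ``"random_intercept"``.  Reference draws are clustered (default 20
    clusters) and cluster centers are projected; for the binomial family the
    projection of a draw is the trial-weighted ML fit of the submodel to the
    draw's fitted probabilities.  ``family="gaussian"`` projects by least
    squares on the fitted values (closed form), provided for oracle checking
    and linear outcomes.
    """
    terms = tuple(terms)
    with_re = "random_intercept" in terms
    cols = []
    for t in terms:
        if t == "random_intercept":
            continue
        if t not in ref.term_map_:
            raise ValueError(f"unknown term {t!r}")
        cols.extend(ref.term_map_[t])
    F = ref._obs_["F"]
    names = ref.feature_names_
    idx = [names.index(c) for c in cols]
    nobs = F.shape[0]
    D = np.concatenate([np.ones((nobs, 1)), F[:, idx]], axis=1)
    ridge = np.zeros(D.shape[1])
    if with_re:
        Z = ref._obs_["blocks"][0][1]
        D = np.concatenate([D, Z], axis=1)
        ridge = np.concatenate([ridge, np.full(Z.shape[1], 1 / ref.sigma_u_**2)])
    totals = ref._obs_["n"]

    if _clusters is None:
        centers, weights, assignment = _cluster_reference(ref, n_clusters, seed)
    else:
        centers, weights, assignment = _clusters

    coefs = np.empty((len(centers), D.shape[1]))
    probs = np.empty((len(centers), nobs))
    kls = np.empty(len(centers))
    n_failed = 0
    beta = None
    for c, p_ref in enumerate(centers):
        if family == "gaussian":
            W = np.diag(totals)
            A = D.T @ W @ D + np.diag(ridge)
            beta_c = np.linalg.solve(A, D.T @ (totals * p_ref))
            q = D @ beta_c
            kls[c] = float(np.sum(totals * (p_ref - q) ** 2) / 2)
        else:
            beta_c, _, ok = _fit_penalized_logit(D, p_ref, totals, ridge, beta0=beta)
            if not ok:
                n_failed += 1
            beta = beta_c
            q = expit(D @ beta_c)
            kls[c] = _binom_kl(p_ref, q, totals)
        coefs[c] = beta_c
        probs[c] = q
    kl = float(np.sum(weights * kls) / totals.sum())
    return ProjectedSubmodel(
        terms=terms,
        columns=["intercept"] + cols,
        coef=coefs,
        weights=weights,
        assignment=assignment,
        kl=kl,
        prob=probs,
        with_random_intercept=with_re,
        n_failed=n_failed,
    )


@dataclass
class ProjectionPath:
    ranking: list
    table: pd.DataFrame
    pointwise_elpd: np.ndarray = field(repr=False)  # (sizes, n_obs)
    submodels: list = field(repr=False, default=None)


def _loo_weights(ref):
    """PSIS-smoothed leave-one-out log weights of the reference draws."""
    import arviz as az

    lw, _ = az.psislw(-ref.loglik_draws_)
    return lw


def _submodel_utility(ref, sub: ProjectedSubmodel, lw):
    """LOO elpd (pointwise) and r.m.s.e. of a projected submodel."""
    k = ref._obs_["k"]
    n = ref._obs_["n"]
    # log predictive density of each reference draw's projected cluster
    logp = binom.logpmf(k[None, :], n[None, :], np.clip(sub.prob, 1e-10, 1 - 1e-10))
    logp_draws = logp[sub.assignment]  # (draws, n_obs)
    elpd_i = logsumexp(lw + logp_draws, axis=0)
    w = np.exp(lw - logsumexp(lw, axis=0))
    p_loo = np.sum(w * sub.prob[sub.assignment], axis=0)
    rmse = float(np.sqrt(np.mean((k / n - p_loo) ** 2)))
    return elpd_i, rmse


def forward_search(
    ref: HierarchicalBinomialReference,
    candidate_terms=None,
    forced_last=("random_intercept",),
    n_clusters: int = 20,
    seed: int = 0,
) -> ProjectionPath:
    """Greedy KL forward search over terms, with forced-last terms appended.

    At each step the candidate whose inclusion reduces the KL divergence
    from the reference predictive distribution the most enters the ranking.
    Terms in ``forced_last`` (the random intercept, optionally a random
    slope) only enter after every fixed predictor, so they cannot soak up
    the variance first.  Per-size elpd/r.m.s.e. come from reference-weighted
    PSIS-LOO of the projected submodels.
    """
    if candidate_terms is None:
        candidate_terms = [t for t in ref.term_map_ if ref.term_map_[t]]
    free = [t for t in candidate_terms if t not in forced_last]
    clusters = _cluster_reference(ref, n_clusters, seed)
    lw = _loo_weights(ref)

    ranking: list = []
    submodels = []
    rows = []
    pointwise = []

    def evaluate(terms):
        return project_submodel(ref, terms, seed=seed, _clusters=clusters)

    current: list = []
    sub = evaluate(current)
    elpd_i, rmse = _submodel_utility(ref, sub, lw)
    rows.append({"size": 0, "term": None, "kl": sub.kl,
                 "elpd": float(elpd_i.sum()), "rmse": rmse, "forced": False})
    pointwise.append(elpd_i)
    submodels.append(sub)

    remaining = list(free)
    while remaining:
        best = None
        for cand in remaining:
            s = evaluate(current + [cand])
            if best is None or s.kl < best[1].kl:
                best = (cand, s)
        cand, sub = best
        current.append(cand)
        remaining.remove(cand)
        ranking.append(cand)
        elpd_i, rmse = _submodel_utility(ref, sub, lw)
        rows.append({"size": len(current), "term": cand, "kl": sub.kl,
                     "elpd": float(elpd_i.sum()), "rmse": rmse, "forced": False})
        pointwise.append(elpd_i)
        submodels.append(sub)
    for t in forced_last:
        sub = evaluate(current + [t])
        current.append(t)
        ranking.append(t)
        elpd_i, rmse = _submodel_utility(ref, sub, lw)
        rows.append({"size": len(current), "term": t, "kl": sub.kl,
                     "elpd": float(elpd_i.sum()), "rmse": rmse, "forced": True})
        pointwise.append(elpd_i)
        submodels.append(sub)

    return ProjectionPath(
        ranking=ranking,
        table=pd.DataFrame(rows),
        pointwise_elpd=np.asarray(pointwise),
        submodels=submodels,
    )


def select_submodel(path: ProjectionPath, rule: str = "elpd_1se") -> dict:
    """Choose the smallest submodel whose utility matches the best one.

    ``elpd_1se``: smallest size whose elpd is within one standard error (of
    the pointwise elpd difference) of the maximum-elpd size.  The rule and
    threshold are echoed in the result.
    """
    if rule != "elpd_1se":
        raise ValueError(f"unknown rule {rule!r}")
    # selection runs over the predictor path only: forced-last terms (the
    # random intercept) are part of the final model regardless of size
    tab = path.table
    free = tab.index[~tab["forced"].fillna(False)].to_numpy()
    elpds = tab["elpd"].to_numpy()
    best = int(free[np.argmax(elpds[free])])
    nobs = path.pointwise_elpd.shape[1]
    chosen = best
    for size in free[free <= best]:
        diff = path.pointwise_elpd[best] - path.pointwise_elpd[size]
        se = float(np.std(diff, ddof=1) * np.sqrt(nobs)) if nobs > 1 else 0.0
        if elpds[size] >= elpds[best] - se:
            chosen = int(size)
            break
    terms = path.ranking[:chosen]
    return {
        "rule": rule,
        "size": chosen,
        "terms": list(terms),
        "best_size": best,
    }


class ProjectionPredictiveSelector(BaseEstimator):
    """End-to-end projection-predictive predictor selection for one task x phase.

    Fits the hierarchical binomial reference model, repeats the forward
    search (clustered projections with different seeds) to stabilize the
    ranking, evaluates the consensus path and selects the smallest adequate
    submodel by the 1-SE elpd rule.

    Attributes
    ----------
    reference_ : the fitted reference model.
    ranking_ : DataFrame of terms with mean rank over repeats and selection flags.
    path_ : ProjectionPath along the consensus ranking.
    selected_terms_ : list of selected predictors.
    """

    def __init__(
        self,
        method: str = "laplace",
        n_repeats: int = 10,
        n_clusters: int = 20,
        random_slope: str | None = None,
        seed: int = 0,
        n_draws: int = 400,
    ):
        self.method = method
        self.n_repeats = n_repeats
        self.n_clusters = n_clusters
        self.random_slope = random_slope
        self.seed = seed
        self.n_draws = n_draws

    def fit(self, counts: pd.DataFrame, diary: pd.DataFrame, phase: int | None = None):
        if phase is None:
            phase = int(diary["phase"].iloc[0])
        X, term_map = build_design(diary, phase)
        ref = HierarchicalBinomialReference(
            method=self.method,
            n_draws=self.n_draws,
            random_slope=self.random_slope,
            seed=self.seed,
        )
        ref.term_map_ = term_map
        ref.fit(X, counts)
        self.reference_ = ref

        forced = ["random_intercept"]
        ranks = {t: [] for t in term_map if term_map[t]}
        rng = np.random.default_rng(self.seed)
        paths = []
        for r in range(self.n_repeats):
            sd = int(rng.integers(0, 2**31 - 1))
            p = forward_search(
                ref, forced_last=forced, n_clusters=self.n_clusters, seed=sd
            )
            paths.append(p)
            for pos, t in enumerate(p.ranking):
                if t in ranks:
                    ranks[t].append(pos + 1)
        mean_rank = {t: float(np.mean(v)) for t, v in ranks.items()}
        consensus = sorted(mean_rank, key=mean_rank.get)

        # evaluate the consensus ordering once with the base seed
        clusters = _cluster_reference(ref, self.n_clusters, self.seed)
        lw = _loo_weights(ref)
        rows, pw, subs = [], [], []
        for size in range(len(consensus) + 2):
            if size <= len(consensus):
                terms = consensus[:size]
            else:
                terms = consensus + forced
            sub = project_submodel(ref, terms, seed=self.seed, _clusters=clusters)
            elpd_i, rmse = _submodel_utility(ref, sub, lw)
            rows.append(
                {
                    "size": size,
                    "term": (terms[-1] if size else None),
                    "kl": sub.kl,
                    "elpd": float(elpd_i.sum()),
                    "rmse": rmse,
                    "forced": size > len(consensus),
                }
            )
            pw.append(elpd_i)
            subs.append(sub)
        self.path_ = ProjectionPath(
            ranking=consensus + forced,
            table=pd.DataFrame(rows),
            pointwise_elpd=np.asarray(pw),
            submodels=subs,
        )
        sel = select_submodel(self.path_)
        self.selection_ = sel
        self.selected_terms_ = sel["terms"]
        self.ranking_ = pd.DataFrame(
            {
                "term": consensus,
                "category": [PREDICTOR_CATEGORIES.get(t, "") for t in consensus],
                "mean_rank": [mean_rank[t] for t in consensus],
                "selected": [t in sel["terms"] for t in consensus],
            }
        )
        return self
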