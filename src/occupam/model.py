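"""Bayesian dynamic (multi-season) occupancy model.

The model follows the MacKenzie et al. colonization–extinction
formulation: each site (grid cell) *i* carries a latent occupancy state
z[i, t] in year *t* that starts as Bernoulli(psi_i) and evolves as a
two-state Markov chain with colonization probability gamma[i, t] and
extinction probability eps[i, t].  Weekly detections y[i, t, j] are
Bernoulli(z[i, t] * p[i, t, j]).  The latent states are marginalized out
with the forward algorithm, so the likelihood is a product over sites of
a sum over latent trajectories.

All four probabilities are logit-linear in standardized covariates with
forest-level random intercepts:

    logit(psi_i)      = alpha_psi[f(i)]   + X_psi[i]      . beta_psi
    logit(gamma_it)   = alpha_gamma[f(i)] + X_gamma[i, t] . beta_gamma
    logit(eps_it)     = alpha_eps[f(i)]   + X_eps[i, t]   . beta_eps
    logit(p_itj)      = alpha_p[f(i)]     + X_p[i, t, j]  . beta_p

with alpha_*[f] ~ Normal(mu_*, sigma_*) across forests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .covariates import DesignSet
from .detections import EncounterHistory

__all__ = [
    "ParamVector",
    "PriorConfig",
    "PosteriorDraws",
    "MapResult",
    "link_probs",
    "site_loglik",
    "loglik_all",
    "log_prior",
    "log_posterior",
    "fit_map",
    "sample_posterior",
    "convergence_report",
    "mb_chisq_ppc",
    "DynamicOccupancyModel",
]

# linear predictors beyond +-ETA_CLIP saturate the inverse logit anyway
ETA_CLIP = 35.0
PROB_FLOOR = 1e-12


class FitError(RuntimeError):
    """Raised when every optimizer start fails to converge."""


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

@dataclass
class ParamVector:
    """All coefficients, forest intercepts and hyper-parameters.

    ``sigma_*`` are random-intercept standard deviations (strictly
    positive); ``mu_*`` are the across-forest means of the intercepts.
    """

    beta_psi: np.ndarray
    beta_gamma: np.ndarray
    beta_eps: np.ndarray
    beta_p: np.ndarray
    alpha_psi: np.ndarray
    alpha_gamma: np.ndarray
    alpha_eps: np.ndarray
    alpha_p: np.ndarray
    mu_psi: float = 0.0
    mu_gamma: float = 0.0
    mu_eps: float = 0.0
    mu_p: float = 0.0
    sigma_psi: float = 0.5
    sigma_gamma: float = 0.5
    sigma_eps: float = 0.5
    sigma_p: float = 0.5

    def __post_init__(self) -> None:
        for name in ("beta_psi", "beta_gamma", "beta_eps", "beta_p",
                     "alpha_psi", "alpha_gamma", "alpha_eps", "alpha_p"):
            setattr(self, name, np.atleast_1d(np.asarray(getattr(self, name), dtype=float)))
        n_f = {len(self.alpha_psi), len(self.alpha_gamma), len(self.alpha_eps), len(self.alpha_p)}
        if len(n_f) != 1:
            raise ValueError("forest intercept vectors must share one length")
        for s in ("sigma_psi", "sigma_gamma", "sigma_eps", "sigma_p"):
            if getattr(self, s) <= 0:
                raise ValueError(f"{s} must be strictly positive")

    @property
    def n_forests(self) -> int:
        return len(self.alpha_psi)

    # -- flat-vector round trip (log scale for the sigmas) ------------------
    def to_vector(self) -> np.ndarray:
        return np.concatenate([
            self.beta_psi, self.beta_gamma, self.beta_eps, self.beta_p,
            self.alpha_psi, self.alpha_gamma, self.alpha_eps, self.alpha_p,
            [self.mu_psi, self.mu_gamma, self.mu_eps, self.mu_p],
            np.log([self.sigma_psi, self.sigma_gamma, self.sigma_eps, self.sigma_p]),
        ])

    @classmethod
    def from_vector(cls, vec: np.ndarray, template: "ParamVector") -> "ParamVector":
        sizes = [len(template.beta_psi), len(template.beta_gamma),
                 len(template.beta_eps), len(template.beta_p)] + [template.n_forests] * 4
        splits = np.cumsum(sizes)
        parts = np.split(np.asarray(vec, dtype=float), splits)
        mus = parts[8][:4]
        log_sig = parts[8][4:8]
        return cls(
            beta_psi=parts[0], beta_gamma=parts[1], beta_eps=parts[2], beta_p=parts[3],
            alpha_psi=parts[4], alpha_gamma=parts[5], alpha_eps=parts[6], alpha_p=parts[7],
            mu_psi=mus[0], mu_gamma=mus[1], mu_eps=mus[2], mu_p=mus[3],
            sigma_psi=np.exp(log_sig[0]), sigma_gamma=np.exp(log_sig[1]),
            sigma_eps=np.exp(log_sig[2]), sigma_p=np.exp(log_sig[3]),
        )

    def param_names(self, design: "DesignSet | None" = None) -> list[str]:
        def cols(prefix, names, k):
            if names is not None:
                return [f"{prefix}[{c}]" for c in names]
            return [f"{prefix}[{i}]" for i in range(k)]

        psi_c = design.psi_cols if design is not None else None
        tr_c = design.trans_cols if design is not None else None
        p_c = design.p_cols if design is not None else None
        names = (cols("beta_psi", psi_c, len(self.beta_psi))
                 + cols("beta_gamma", tr_c, len(self.beta_gamma))
                 + cols("beta_eps", tr_c, len(self.beta_eps))
                 + cols("beta_p", p_c, len(self.beta_p)))
        for sub in ("psi", "gamma", "eps", "p"):
            names += [f"alpha_{sub}[{f}]" for f in range(self.n_forests)]
        names += [f"mu_{s}" for s in ("psi", "gamma", "eps", "p")]
        names += [f"log_sigma_{s}" for s in ("psi", "gamma", "eps", "p")]
        return names

    @classmethod
    def zeros_like_design(cls, design: "DesignSet", **kwargs) -> "ParamVector":
        return cls(
            beta_psi=np.zeros(design.X_psi.shape[1]),
            beta_gamma=np.zeros(design.X_gamma.shape[2]),
            beta_eps=np.zeros(design.X_eps.shape[2]),
            beta_p=np.zeros(design.X_p.shape[3]),
            alpha_psi=np.zeros(design.n_forests),
            alpha_gamma=np.zeros(design.n_forests),
            alpha_eps=np.zeros(design.n_forests),
            alpha_p=np.zeros(design.n_forests),
            **kwargs,
        )


@dataclass
class PriorConfig:
    """Weakly informative defaults: Normal(0, 2.5) coefficients,
    Normal(mu, sigma) forest intercepts with mu ~ Normal(0, 5) and
    sigma ~ half-Cauchy(0, 2.5)."""

    beta_sd: float = 2.5
    mu_sd: float = 5.0
    sigma_scale: float = 2.5

    def to_dict(self) -> dict:
        return {"beta_sd": self.beta_sd, "mu_sd": self.mu_sd,
                "sigma_scale": self.sigma_scale}


@dataclass
class PosteriorDraws:
    """Post-warmup draws shaped (chain, draw, dim) plus diagnostics."""

    draws: np.ndarray
    names: list[str]
    template: ParamVector
    diagnostics: pd.DataFrame | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    @property
    def n_draws(self) -> int:
        return self.draws.shape[0] * self.draws.shape[1]

    def flat(self, thin: int = 1) -> np.ndarray:
        out = self.draws[:, ::thin, :].reshape(-1, self.draws.shape[2])
        return out

    def subsample(self, n: int, seed: int | None = None) -> np.ndarray:
        flat = self.flat()
        if n >= flat.shape[0]:
            return flat
        rng = np.random.default_rng(seed)
        idx = rng.choice(flat.shape[0], size=n, replace=False)
        return flat[idx]

    def params_at(self, vec: np.ndarray) -> ParamVector:
        return ParamVector.from_vector(vec, self.template)

    def summary(self) -> pd.DataFrame:
        flat = self.flat()
        lo, hi = np.percentile(flat, [2.5, 97.5], axis=0)
        return pd.DataFrame({
            "param": self.names,
            "mean": flat.mean(axis=0),
            "sd": flat.std(axis=0),
            "lo95": lo,
            "hi95": hi,
        })


@dataclass
class MapResult:
    params: ParamVector
    vector: np.ndarray
    names: list[str]
    log_posterior: float
    log_likelihood: float
    converged: bool
    n_starts: int
    se: np.ndarray | None = None
    sigma_at_bound: bool = False


# ---------------------------------------------------------------------------
# link functions
# ---------------------------------------------------------------------------

def _inv_logit(eta: np.ndarray) -> np.ndarray:
    eta = np.asarray(eta, dtype=float)
    if not np.all(np.isfinite(eta)):
        raise FloatingPointError("non-finite linear predictor")
    return special.expit(np.clip(eta, -ETA_CLIP, ETA_CLIP))


def link_probs(params: ParamVector, design: DesignSet) -> dict:
    """Inverse-logit probabilities for all four submodels.

    Returns a dict with ``psi`` (sites,), ``gamma``/``eps``
    (sites, years-1) and ``p`` (sites, years, weeks).  ``p`` is computed
    everywhere; weeks without effort are ignored by the likelihood.
    """
    f = design.forest_index
    psi = _inv_logit(params.alpha_psi[f] + design.X_psi @ params.beta_psi)
    gamma = _inv_logit(params.alpha_gamma[f][:, None]
                       + np.einsum("itk,k->it", design.X_gamma, params.beta_gamma))
    eps = _inv_logit(params.alpha_eps[f][:, None]
                     + np.einsum("itk,k->it", design.X_eps, params.beta_eps))
    p = _inv_logit(params.alpha_p[f][:, None, None]
                   + np.einsum("itjk,k->itj", design.X_p, params.beta_p))
    return {"psi": psi, "gamma": gamma, "eps": eps, "p": p}


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

def _clip(x: np.ndarray) -> np.ndarray:
    return np.clip(x, PROB_FLOOR, 1.0 - PROB_FLOOR)


def loglik_all(Y: np.ndarray, psi: np.ndarray, gamma: np.ndarray,
               eps: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Marginal log-likelihood per site via the forward algorithm.

    ``Y`` is (sites, years, weeks) with NaN marking unsurveyed weeks.
    The per-year emission for z=1 is the product of Bernoulli(p) terms
    over surveyed weeks; for z=0 it is the indicator that no detection
    was recorded.  Renormalizing the forward vector each year keeps the
    recursion stable for long histories.
    """
    Y = np.asarray(Y, dtype=float)
    n, T, J = Y.shape
    obs = ~np.isnan(Y)
    if np.any((Y == 1) & ~obs):  # pragma: no cover - nan never equals 1
        raise ValueError("detection recorded in an unsurveyed week")
    Yf = np.nan_to_num(Y)
    p = _clip(p)
    ll1 = np.where(obs, Yf * np.log(p) + (1.0 - Yf) * np.log1p(-p), 0.0).sum(axis=2)
    det_any = (Yf == 1).any(axis=2)

    e1 = np.exp(ll1)                       # (n, T)
    e0 = np.where(det_any, 0.0, 1.0)

    psi = _clip(psi)
    a0 = (1.0 - psi) * e0[:, 0]
    a1 = psi * e1[:, 0]
    s = a0 + a1
    bad = s <= 0
    s = np.where(bad, 1.0, s)
    logz = np.log(s)
    a0, a1 = a0 / s, a1 / s
    for t in range(1, T):
        g = _clip(gamma[:, t - 1])
        e = _clip(eps[:, t - 1])
        b0 = a0 * (1.0 - g) + a1 * e
        b1 = a0 * g + a1 * (1.0 - e)
        a0 = b0 * e0[:, t]
        a1 = b1 * e1[:, t]
        s = a0 + a1
        bad |= s <= 0
        s = np.where(s <= 0, 1.0, s)
        logz += np.log(s)
        a0, a1 = a0 / s, a1 / s
    return np.where(bad, -np.inf, logz)


def site_loglik(Y_i: np.ndarray, effort_i: np.ndarray | None, psi_i: float,
                gamma_i: np.ndarray, eps_i: np.ndarray, p_i: np.ndarray) -> float:
    """Log-likelihood of one site's (years x weeks) history.

    ``effort_i`` (same shape as ``Y_i``, or None) is only used to check
    consistency: a detection in a zero-effort week is an input error.
    """
    Y_i = np.asarray(Y_i, dtype=float)
    if effort_i is not None:
        effort_i = np.asarray(effort_i, dtype=float)
        if np.any((np.nan_to_num(Y_i) == 1) & ~(effort_i > 0)):
            raise ValueError("detection recorded in a week with no effort")
    T = Y_i.shape[0]
    gamma_i = np.broadcast_to(np.atleast_1d(gamma_i), (max(T - 1, 1),))
    eps_i = np.broadcast_to(np.atleast_1d(eps_i), (max(T - 1, 1),))
    return float(loglik_all(Y_i[None], np.atleast_1d(psi_i),
                            gamma_i[None], eps_i[None], p_i[None])[0])


def enumerate_loglik(Y_i: np.ndarray, psi_i: float, gamma_i: np.ndarray,
                     eps_i: np.ndarray, p_i: np.ndarray) -> float:
    """Brute-force likelihood summing over all 2^T latent trajectories.

    Exponential in the number of years; exists as an independent check of
    the forward recursion on small instances.
    """
    Y_i = np.asarray(Y_i, dtype=float)
    T, J = Y_i.shape
    obs = ~np.isnan(Y_i)
    Yf = np.nan_to_num(Y_i)
    p_i = _clip(p_i)
    psi_i = float(_clip(np.asarray(psi_i)))
    gamma_i = _clip(np.broadcast_to(np.atleast_1d(gamma_i), (max(T - 1, 1),)))
    eps_i = _clip(np.broadcast_to(np.atleast_1d(eps_i), (max(T - 1, 1),)))
    total = 0.0
    for code in range(2 ** T):
        zs = [(code >> t) & 1 for t in range(T)]
        pr = psi_i if zs[0] else 1.0 - psi_i
        for t in range(1, T):
            if zs[t - 1]:
                pr *= (1.0 - eps_i[t - 1]) if zs[t] else eps_i[t - 1]
            else:
                pr *= gamma_i[t - 1] if zs[t] else 1.0 - gamma_i[t - 1]
        for t in range(T):
            for j in range(J):
                if not obs[t, j]:
                    continue
                if zs[t]:
                    pr *= p_i[t, j] if Yf[t, j] else 1.0 - p_i[t, j]
                elif Yf[t, j]:
                    pr *= 0.0
        total += pr
    return np.log(total) if total > 0 else -np.inf


# ---------------------------------------------------------------------------
# prior and posterior
# ---------------------------------------------------------------------------

def log_prior(params: ParamVector, prior: PriorConfig | None = None,
              jacobian: bool = True) -> float:
    """Log prior density of a full parameter vector.

    With ``jacobian=True`` (the default) the density is expressed with
    respect to log(sigma), i.e. it includes the +log(sigma) change of
    variables used by the optimizer and the sampler.
    """
    prior = prior or PriorConfig()
    sigmas = np.array([params.sigma_psi, params.sigma_gamma,
                       params.sigma_eps, params.sigma_p])
    if np.any(sigmas <= 0):
        return -np.inf
    lp = 0.0
    for beta in (params.beta_psi, params.beta_gamma, params.beta_eps, params.beta_p):
        lp += stats.norm.logpdf(beta, 0.0, prior.beta_sd).sum()
    mus = np.array([params.mu_psi, params.mu_gamma, params.mu_eps, params.mu_p])
    lp += stats.norm.logpdf(mus, 0.0, prior.mu_sd).sum()
    alphas = (params.alpha_psi, params.alpha_gamma, params.alpha_eps, params.alpha_p)
    for alpha, mu, sig in zip(alphas, mus, sigmas):
        lp += stats.norm.logpdf(alpha, mu, sig).sum()
    lp += stats.halfcauchy.logpdf(sigmas, scale=prior.sigma_scale).sum()
    if jacobian:
        lp += np.log(sigmas).sum()
    return float(lp)


class PosteriorWorkspace:
    """Precomputed quantities for fast batched posterior evaluation.

    Only the surveyed (site, year, week) entries enter the detection
    part of the likelihood, so their covariate rows are gathered once;
    per evaluation the weekly Bernoulli terms are computed on that flat
    array and reduced back to per-site-year sums with ``reduceat``.
    """

    def __init__(self, template: ParamVector, design: DesignSet,
                 Y: np.ndarray, prior: PriorConfig, noncentered: bool = False):
        self.template = template
        self.design = design
        self.prior = prior
        # non-centered: the vector carries alpha_raw with
        # alpha = mu + sigma * alpha_raw and alpha_raw ~ Normal(0, 1);
        # a pure reparametrization that de-funnels the geometry for the
        # ensemble sampler
        self.noncentered = noncentered
        Y = np.asarray(Y, dtype=float)
        n, T, J = Y.shape
        self.n, self.T, self.J = n, T, J
        kb = [len(template.beta_psi), len(template.beta_gamma),
              len(template.beta_eps), len(template.beta_p)]
        F = template.n_forests
        self.ofs = np.cumsum([0] + kb + [F] * 4 + [4, 4])

        obs_flat = np.flatnonzero(~np.isnan(Y).ravel())   # C-order: sorted by (i, t)
        it = obs_flat // J
        self.X_obs = design.X_p.reshape(n * T * J, design.X_p.shape[3])[obs_flat]
        self.f_obs = design.forest_index[obs_flat // (T * J)]
        self.y_obs = (np.nan_to_num(Y).ravel()[obs_flat] == 1.0)
        # contiguous segments of equal (i, t)
        if len(it):
            starts = np.flatnonzero(np.diff(it, prepend=it[0] - 1) != 0)
        else:
            starts = np.array([], dtype=int)
        self.seg_starts = starts
        self.seg_it = it[starts] if len(it) else np.array([], dtype=int)
        self.det_any = (np.nan_to_num(Y) == 1).any(axis=2)
        self.n_obs = len(obs_flat)

    def __call__(self, V: np.ndarray) -> np.ndarray:
        V = np.atleast_2d(np.asarray(V, dtype=float))
        m = V.shape[0]
        ofs = self.ofs
        b_psi, b_gam, b_eps, b_p = (V[:, ofs[i]:ofs[i + 1]] for i in range(4))
        a_psi, a_gam, a_eps, a_p = (V[:, ofs[4 + i]:ofs[5 + i]] for i in range(4))
        mus = V[:, ofs[8]:ofs[9]]
        log_sig = V[:, ofs[9]:ofs[9] + 4]
        sig = np.exp(log_sig)
        prior = self.prior
        design = self.design

        # prior: Normal / half-Cauchy algebra, vectorized over the batch
        lp = np.zeros(m)
        c_norm = -0.5 * np.log(2 * np.pi)
        for b in (b_psi, b_gam, b_eps, b_p):
            lp += (c_norm - np.log(prior.beta_sd)
                   - 0.5 * (b / prior.beta_sd) ** 2).sum(axis=1)
        lp += (c_norm - np.log(prior.mu_sd)
               - 0.5 * (mus / prior.mu_sd) ** 2).sum(axis=1)
        alphas = []
        for k, a in enumerate((a_psi, a_gam, a_eps, a_p)):
            if self.noncentered:
                lp += (c_norm - 0.5 * a ** 2).sum(axis=1)  # raw ~ N(0, 1)
                alphas.append(mus[:, k, None] + sig[:, k, None] * a)
            else:
                lp += (c_norm - log_sig[:, k, None]
                       - 0.5 * ((a - mus[:, k, None]) / sig[:, k, None]) ** 2
                       ).sum(axis=1)
                alphas.append(a)
        a_psi, a_gam, a_eps, a_p = alphas
        lp += (np.log(2.0 / (np.pi * prior.sigma_scale))
               - np.log1p((sig / prior.sigma_scale) ** 2)).sum(axis=1)
        lp += log_sig.sum(axis=1)  # Jacobian of the log transform

        def il(eta):
            return special.expit(np.clip(eta, -ETA_CLIP, ETA_CLIP))

        f = design.forest_index
        psi = _clip(il(a_psi[:, f] + b_psi @ design.X_psi.T))           # (m, n)
        gam = il(a_gam[:, f, None] + np.einsum("itk,mk->mit", design.X_gamma, b_gam))
        eps = il(a_eps[:, f, None] + np.einsum("itk,mk->mit", design.X_eps, b_eps))

        # weekly Bernoulli log-terms on surveyed entries only
        eta = a_p[:, self.f_obs] + b_p @ self.X_obs.T                   # (m, n_obs)
        p = _clip(il(eta))
        ll_elem = np.where(self.y_obs[None], np.log(p), np.log1p(-p))
        n, T = self.n, self.T
        ll1 = np.zeros((m, n * T))
        if self.n_obs:
            seg = np.add.reduceat(ll_elem, self.seg_starts, axis=1)
            ll1[:, self.seg_it] = seg
        ll1 = ll1.reshape(m, n, T)

        e1 = np.exp(ll1)
        e0 = np.where(self.det_any, 0.0, 1.0)[None]

        a0 = (1.0 - psi) * e0[:, :, 0]
        a1 = psi * e1[:, :, 0]
        s = a0 + a1
        bad = s <= 0
        s = np.where(bad, 1.0, s)
        logz = np.log(s)
        a0, a1 = a0 / s, a1 / s
        for t in range(1, T):
            g = _clip(gam[:, :, t - 1])
            e = _clip(eps[:, :, t - 1])
            b0 = a0 * (1.0 - g) + a1 * e
            b1 = a0 * g + a1 * (1.0 - e)
            a0 = b0 * e0[:, :, t]
            a1 = b1 * e1[:, :, t]
            s = a0 + a1
            bad |= s <= 0
            s = np.where(s <= 0, 1.0, s)
            logz += np.log(s)
            a0, a1 = a0 / s, a1 / s
        logz = np.where(bad, -np.inf, logz)
        out = lp + logz.sum(axis=1)
        return np.where(np.isfinite(out), out, -np.inf)


def _alpha_transform(ws: "PosteriorWorkspace", V: np.ndarray,
                     to_raw: bool) -> np.ndarray:
    """Map parameter vectors between centered and non-centered spaces."""
    V = np.array(V, dtype=float, copy=True)
    for k in range(4):
        sl = slice(ws.ofs[4 + k], ws.ofs[5 + k])
        mu = V[..., ws.ofs[8] + k][..., None]
        sig = np.exp(V[..., ws.ofs[9] + k])[..., None]
        if to_raw:
            V[..., sl] = (V[..., sl] - mu) / sig
        else:
            V[..., sl] = mu + sig * V[..., sl]
    return V


def log_posterior_batch(V: np.ndarray, template: ParamVector, design: DesignSet,
                        Y: np.ndarray, prior: PriorConfig,
                        workspace: PosteriorWorkspace | None = None) -> np.ndarray:
    """Log posterior for a batch of parameter vectors, shape (m, dim)."""
    ws = workspace or PosteriorWorkspace(template, design, Y, prior)
    return ws(V)


def log_posterior(vec: np.ndarray, template: ParamVector, design: DesignSet,
                  Y: np.ndarray, prior: PriorConfig) -> float:
    try:
        params = ParamVector.from_vector(vec, template)
    except ValueError:
        return -np.inf
    lp = log_prior(params, prior)
    if not np.isfinite(lp):
        return -np.inf
    probs = link_probs(params, design)
    ll = loglik_all(Y, probs["psi"], probs["gamma"], probs["eps"], probs["p"]).sum()
    if not np.isfinite(ll):
        return -np.inf
    return float(lp + ll)


# ---------------------------------------------------------------------------
# MAP fit
# ---------------------------------------------------------------------------

LOG_SIGMA_BOUNDS = (np.log(0.05), np.log(10.0))


def fit_map(history: EncounterHistory, design: DesignSet,
            prior_config: PriorConfig | None = None,
            optimizer_config: dict | None = None) -> MapResult:
    """Posterior mode as a fast, deterministic surrogate for a full fit.

    The mode is found with multi-start L-BFGS-B over the unconstrained
    vector (sigmas on the log scale).  Because the joint density of a
    hierarchical model is unbounded as sigma -> 0, log(sigma) is boxed in
    ``LOG_SIGMA_BOUNDS``; a mode on that boundary is flagged via
    ``sigma_at_bound``.
    """
    prior = prior_config or PriorConfig()
    cfg = {"n_starts": 5, "seed": 0, "maxiter": 500, "compute_se": True}
    cfg.update(optimizer_config or {})
    Y = history.Y
    if np.all(np.isnan(Y)):
        raise ValueError("all encounter histories are missing: model not identified")

    template = ParamVector.zeros_like_design(design)
    ndim = len(template.to_vector())
    names = template.param_names(design)
    nb = (len(template.beta_psi) + len(template.beta_gamma)
          + len(template.beta_eps) + len(template.beta_p))
    bounds = [(-15.0, 15.0)] * (ndim - 4) + [LOG_SIGMA_BOUNDS] * 4
    _ = nb

    ws = PosteriorWorkspace(template, design, Y, prior)

    def neg_logpost(vec):
        return -float(ws(vec[None])[0])

    rng = np.random.default_rng(cfg["seed"])
    starts = [np.concatenate([np.zeros(ndim - 4), np.full(4, np.log(0.5))])]
    for _k in range(cfg["n_starts"] - 1):
        v = np.concatenate([
            rng.normal(0.0, 0.5, ndim - 8),
            rng.normal(0.0, 1.0, 4),
            rng.normal(np.log(0.5), 0.3, 4),
        ])
        starts.append(v)

    best = None
    n_ok = 0
    for v0 in starts:
        res = optimize.minimize(neg_logpost, v0, method="L-BFGS-B", bounds=bounds,
                                options={"maxiter": cfg["maxiter"]})
        if np.isfinite(res.fun):
            n_ok += 1
            if best is None or res.fun < best.fun:
                best = res
    if best is None or n_ok == 0:
        raise FitError("no optimizer start reached a finite posterior")

    vec = best.x
    params = ParamVector.from_vector(vec, template)
    probs = link_probs(params, design)
    ll = float(loglik_all(Y, probs["psi"], probs["gamma"],
                          probs["eps"], probs["p"]).sum())
    se = None
    if cfg["compute_se"]:
        from statsmodels.tools.numdiff import approx_hess1
        with np.errstate(all="ignore"):
            H = approx_hess1(vec, neg_logpost)
        try:
            cov = np.linalg.inv(H)
            d = np.diag(cov)
            se = np.where(d > 0, np.sqrt(np.abs(d)), np.nan)
        except np.linalg.LinAlgError:
            se = np.full(ndim, np.nan)
    at_bound = bool(np.any(np.isclose(vec[-4:], LOG_SIGMA_BOUNDS[0]))
                    or np.any(np.isclose(vec[-4:], LOG_SIGMA_BOUNDS[1])))
    return MapResult(params=params, vector=vec, names=names,
                     log_posterior=-best.fun, log_likelihood=ll,
                     converged=bool(best.success), n_starts=len(starts),
                     se=se, sigma_at_bound=at_bound)


# ---------------------------------------------------------------------------
# MCMC
# ---------------------------------------------------------------------------

def sample_posterior(history: EncounterHistory, design: DesignSet,
                     prior_config: PriorConfig | None = None,
                     chains: int = 3, iter: int = 1500, warmup: int = 750,
                     seed: int | None = None, n_walkers: int | None = None,
                     init: MapResult | None = None,
                     thin: int = 1) -> PosteriorDraws:
    """Sample the marginalized posterior with an affine-invariant
    ensemble sampler (emcee).

    ``chains`` independent ensembles are run for ``iter`` stretch-move
    steps each; the first ``warmup`` steps are discarded.  Each walker
    trajectory is recorded as a chain for the rank-normalized split-R-hat
    and bulk-ESS diagnostics.  Ensembles start from a small ball around
    the posterior mode.
    """
    import emcee

    if iter <= warmup:
        raise ValueError("iter must exceed warmup")
    prior = prior_config or PriorConfig()
    Y = history.Y
    template = ParamVector.zeros_like_design(design)
    ndim = len(template.to_vector())
    names = template.param_names(design)
    nw = n_walkers or max(2 * ndim + 2, 10)
    if nw % 2:
        nw += 1

    if init is None:
        init = fit_map(history, design, prior,
                       {"n_starts": 2, "seed": 0 if seed is None else seed,
                        "compute_se": False})
    center = init.vector

    # sample in the non-centered space (alpha = mu + sigma * raw): the
    # hierarchical funnel is far closer to Gaussian there
    ws = PosteriorWorkspace(template, design, Y, prior, noncentered=True)
    center_raw = _alpha_transform(ws, center, to_raw=True)
    rng = np.random.default_rng(seed)
    # differential-evolution moves mix much better than the stretch move
    # for the correlated hierarchical posterior
    moves = [(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)]
    all_chains = []
    for c in range(chains):
        p0 = center_raw[None, :] + 0.01 * rng.standard_normal((nw, ndim))
        sampler = emcee.EnsembleSampler(nw, ndim, ws, vectorize=True,
                                        moves=moves)
        sampler._random = np.random.RandomState(rng.integers(2 ** 31))
        sampler.run_mcmc(p0, iter, progress=False)
        chain = sampler.get_chain(discard=warmup, thin=thin)  # (steps, nw, ndim)
        all_chains.append(np.moveaxis(chain, 0, 1))           # (nw, steps, ndim)
    draws = _alpha_transform(ws, np.concatenate(all_chains, axis=0),
                             to_raw=False)
    out = PosteriorDraws(draws=draws, names=names, template=template,
                         meta={"seed": seed, "chains": chains, "iter": iter,
                               "warmup": warmup, "n_walkers": nw,
                               "engine": "emcee-stretch",
                               "prior": prior.to_dict()})
    out.diagnostics = convergence_report(out)
    if not out.diagnostics["pass"].all():
        warnings.warn("convergence diagnostics failed for some parameters "
                      "(R-hat > 1.01 or ESS <= 300)", RuntimeWarning)
    return out


def convergence_report(draws: PosteriorDraws,
                       rhat_max: float = 1.01, ess_min: float = 300.0) -> pd.DataFrame:
    """Rank-normalized split-R-hat and bulk ESS for every parameter."""
    import arviz as az

    arr = draws.draws if isinstance(draws, PosteriorDraws) else np.asarray(draws)
    if arr.ndim != 3 or arr.shape[0] < 2:
        raise ValueError("convergence diagnostics require >= 2 chains")
    names = draws.names if isinstance(draws, PosteriorDraws) else [
        f"p{i}" for i in range(arr.shape[2])]
    data = az.from_dict({n: arr[:, :, i] for i, n in enumerate(names)})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rhat = az.rhat(data)
        ess = az.ess(data, method="bulk")
    rows = []
    for i, n in enumerate(names):
        r = float(rhat[n].values)
        e = float(ess[n].values)
        degenerate = float(np.std(arr[:, :, i])) == 0.0
        ok = (not degenerate) and (r <= rhat_max or np.isnan(r)) and e > ess_min
        rows.append({"param": n, "rhat": r, "ess_bulk": e, "pass": bool(ok)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# MacKenzie–Bailey goodness of fit
# ---------------------------------------------------------------------------

def _projected_psi(probs: dict) -> np.ndarray:
    """Marginal (unconditional) occupancy per site-year."""
    psi, gamma, eps = probs["psi"], probs["gamma"], probs["eps"]
    n, Tm1 = gamma.shape
    out = np.empty((n, Tm1 + 1))
    out[:, 0] = psi
    for t in range(Tm1):
        out[:, t + 1] = out[:, t] * (1 - eps[:, t]) + (1 - out[:, t]) * gamma[:, t]
    return out


def _mb_chisq(Y: np.ndarray, psi_m: np.ndarray, p: np.ndarray,
              eps_pool: float = 1e-6) -> float:
    """MacKenzie–Bailey chi-square over year x missingness cohorts.

    Site-years are grouped by year and surveyed-week pattern; within a
    cohort the expected count of each distinct observed weekly history is
    summed over sites, and a pooled remainder category absorbs the
    probability mass of unobserved histories.
    """
    n, T, J = Y.shape
    obs = ~np.isnan(Y)
    chi = 0.0
    for t in range(T):
        patterns = {}
        for i in range(n):
            key = obs[i, t].tobytes()
            patterns.setdefault(key, []).append(i)
        for key, idx in patterns.items():
            mask = np.frombuffer(key, dtype=bool)
            if not mask.any():
                continue
            idx = np.asarray(idx)
            sub = Y[idx][:, t, :][:, mask]          # (m, J_obs)
            p_sub = _clip(p[idx][:, t, :][:, mask])  # (m, J_obs)
            psi_sub = psi_m[idx, t]
            hist_types, inverse = np.unique(sub, axis=0, return_inverse=True)
            O = np.bincount(inverse, minlength=len(hist_types)).astype(float)
            # Pr(history h | site) for every (type, site) pair
            logp1 = (hist_types[:, None, :] * np.log(p_sub[None])
                     + (1 - hist_types[:, None, :]) * np.log1p(-p_sub[None])).sum(axis=2)
            pr = psi_sub[None, :] * np.exp(logp1)
            all_zero = (hist_types.sum(axis=1) == 0)
            pr[all_zero] += (1 - psi_sub)[None, :]
            E = pr.sum(axis=1)
            keep = E > eps_pool
            chi += (((O[keep] - E[keep]) ** 2) / E[keep]).sum()
            # pooled remainder: unobserved histories + tiny-E observed types
            O_rem = O[~keep].sum()
            E_rem = len(idx) - E[keep].sum()
            if E_rem > eps_pool:
                chi += (O_rem - E_rem) ** 2 / E_rem
    return float(chi)


def _simulate_replicate(Y: np.ndarray, probs: dict, rng: np.random.Generator) -> np.ndarray:
    """Replicate data from the model with the observed missingness."""
    n, T, J = Y.shape
    psi, gamma, eps, p = probs["psi"], probs["gamma"], probs["eps"], probs["p"]
    z = np.empty((n, T), dtype=int)
    z[:, 0] = rng.random(n) < psi
    for t in range(1, T):
        pr = np.where(z[:, t - 1] == 1, 1 - eps[:, t - 1], gamma[:, t - 1])
        z[:, t] = rng.random(n) < pr
    y = (rng.random((n, T, J)) < z[:, :, None] * p).astype(float)
    y[np.isnan(Y)] = np.nan
    return y


@dataclass
class MBResult:
    p_value: float
    chisq_obs: np.ndarray
    chisq_rep: np.ndarray


def mb_chisq_ppc(draws: PosteriorDraws, history: EncounterHistory,
                 design: DesignSet, n_reps: int = 100,
                 seed: int | None = None) -> MBResult:
    """Posterior predictive check of the MacKenzie–Bailey chi-square.

    For each of ``n_reps`` posterior draws the statistic is computed on
    the observed data and on one replicate simulated from that draw; the
    Bayesian p-value is the fraction of replicates with a statistic at
    least as large as the observed one.
    """
    if n_reps < 50:
        warnings.warn("n_reps < 50 gives an unstable Bayesian p-value",
                      RuntimeWarning)
    rng = np.random.default_rng(seed)
    sub = draws.subsample(n_reps, seed=None if seed is None else seed + 1)
    Y = history.Y
    obs_stats, rep_stats = [], []
    for vec in sub:
        params = draws.params_at(vec)
        probs = link_probs(params, design)
        psi_m = _projected_psi(probs)
        obs_stats.append(_mb_chisq(Y, psi_m, probs["p"]))
        y_rep = _simulate_replicate(Y, probs, rng)
        rep_stats.append(_mb_chisq(y_rep, psi_m, probs["p"]))
    obs_stats = np.asarray(obs_stats)
    rep_stats = np.asarray(rep_stats)
    return MBResult(p_value=float(np.mean(rep_stats >= obs_stats)),
                    chisq_obs=obs_stats, chisq_rep=rep_stats)


# ---------------------------------------------------------------------------
# estimator facade
# ---------------------------------------------------------------------------

class DynamicOccupancyModel:
    """Scikit-learn-style facade over the MAP/MCMC fitting routines.

    Parameters mirror :func:`sample_posterior`; ``method`` selects
    ``"map"`` (posterior mode, fast) or ``"mcmc"`` (full posterior).
    After :meth:`fit`, fitted attributes carry a trailing underscore:
    ``params_`` (posterior mode or posterior-mean parameters),
    ``draws_`` (``PosteriorDraws``, MCMC only), ``diagnostics_``,
    ``loglik_``.
    """

    def __init__(self, method: str = "mcmc", prior_config: PriorConfig | None = None,
                 chains: int = 3, iter: int = 1500, warmup: int = 750,
                 n_walkers: int | None = None, seed: int | None = None):
        self.method = method
        self.prior_config = prior_config
        self.chains = chains
        self.iter = iter
        self.warmup = warmup
        self.n_walkers = n_walkers
        self.seed = seed

    _param_names = ("method", "prior_config", "chains", "iter",
                    "warmup", "n_walkers", "seed")

    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k) for k in self._param_names}

    def set_params(self, **kwargs) -> "DynamicOccupancyModel":
        for k, v in kwargs.items():
            if k not in self._param_names:
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, history: EncounterHistory, design: DesignSet,
            **fit_kwargs) -> "DynamicOccupancyModel":
        if self.method == "map":
            res = fit_map(history, design, self.prior_config, fit_kwargs or None)
            self.map_result_ = res
            self.params_ = res.params
            self.draws_ = None
            self.diagnostics_ = None
            self.loglik_ = res.log_likelihood
        elif self.method == "mcmc":
            draws = sample_posterior(history, design, self.prior_config,
                                     chains=self.chains, iter=self.iter,
                                     warmup=self.warmup, seed=self.seed,
                                     n_walkers=self.n_walkers, **fit_kwargs)
            self.draws_ = draws
            self.diagnostics_ = draws.diagnostics
            mean_vec = draws.flat().mean(axis=0)
            self.params_ = draws.params_at(mean_vec)
            probs = link_probs(self.params_, design)
            self.loglik_ = float(loglik_all(history.Y, probs["psi"], probs["gamma"],
                                            probs["eps"], probs["p"]).sum())
        else:
            raise ValueError("method must be 'map' or 'mcmc'")
        self.design_ = design
        return self

    def predict_proba(self, design: DesignSet | None = None) -> dict:
        """Link-scale probabilities at the fitted parameters."""
        if not hasattr(self, "params_"):
            raise RuntimeError("model is not fitted")
        return link_probs(self.params_, design or self.design_)

    def score(self, history: EncounterHistory, design: DesignSet | None = None) -> float:
        probs = self.predict_proba(design)
        return float(loglik_all(history.Y, probs["psi"], probs["gamma"],
                                probs["eps"], probs["p"]).sum())
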