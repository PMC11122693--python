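"""Bayesian multilevel AR(1) location-scale model for trial-level log RTs.

Within person i, observed log RT at trial t follows

    y_it = mu_i + beta_i * x(t) + w_it
    w_it = phi_i * w_i,t-1 + eps_it,   eps_it ~ N(0, exp(omega_i))

with stationary initial state w_i1 ~ N(0, exp(omega_i) / (1 - phi_i^2)).
x(t) is the trial index centered at the person's midpoint and divided by
100, keeping the trend coefficient on a scale comparable to the mean.
Between persons, (mu_i, beta_i, phi_i, omega_i)' ~ N(gamma, Sigma).  The
person-level log residual variance omega_i is the "cognitive variability"
measure; its between-person variance tau^2_omega = Sigma[omega, omega] is
the quantity whose presence the DIC comparison tests.

Sampling is Metropolis-within-Gibbs: conjugate normal updates for the
location parameters (mu_i, beta_i) given prewhitened data, random-walk
Metropolis for (phi_i, omega_i) with phi proposals reflected at +-1,
semi-conjugate normal / inverse-Wishart updates for (gamma, Sigma), and
single-site Gibbs imputation of Tukey-masked (missing) values as latent
states so the AR chain is preserved across gaps.  All person-level updates
are vectorized across subjects.

Model variants used by the DIC random-effects test constrain omega_i to the
population value (``constrain_variability``); additional flags fix the
trend and inertia at zero and equate the mean across persons, which reduces
the model to an iid normal for oracle checks.

The deviance entering the DIC is the conditional (person-effect-level)
observed-data deviance: missing trials are marginalized analytically using
the Markov property of the AR(1) process, so the DIC is a deterministic
function of the stored draws and the observed data.
"""

from __future__ import annotations

import warnings

import arviz as az
import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import EFFECT_NAMES

__all__ = [
    "AR1LocationScaleDSEM",
    "fit_dsem",
    "compute_dic",
    "test_random_variability",
    "extract_factor_scores",
    "estimate_reliability",
    "series_to_matrix",
]

_MU, _BETA, _PHI, _OMEGA = 0, 1, 2, 3


def series_to_matrix(series: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Long preprocessed series -> (subjects x max-length) matrix plus ids.

    ``series`` needs columns subject, position (or trial order), log_rt.
    Rows are ordered by position within subject; shorter series are
    NaN-padded on the right.  Subject order follows first appearance.
    """
    if "position" in series.columns:
        series = series.sort_values(["position"], kind="stable")
    subjects = pd.unique(series["subject"])
    groups = series.groupby("subject", sort=False)["log_rt"]
    arrays = [groups.get_group(s).to_numpy(dtype=float) for s in subjects]
    T = max(len(a) for a in arrays)
    y = np.full((len(arrays), T), np.nan)
    lengths = np.empty(len(arrays), dtype=int)
    for i, a in enumerate(arrays):
        y[i, : len(a)] = a
        lengths[i] = len(a)
    return y, np.asarray(subjects), lengths


def _trend_design(lengths: np.ndarray, T: int) -> np.ndarray:
    """x_it = (t - (L_i + 1)/2) / 100 within bounds, 0 outside."""
    t = np.arange(1, T + 1)[None, :]
    x = (t - (lengths[:, None] + 1) / 2.0) / 100.0
    x[t > lengths[:, None]] = 0.0
    return x


def _reflect_unit(v: np.ndarray) -> np.ndarray:
    """Reflect proposals into (-1, 1)."""
    v = np.where(v > 1.0, 2.0 - v, v)
    v = np.where(v < -1.0, -2.0 - v, v)
    # a second pass handles very large steps
    v = np.where(v > 1.0, 2.0 - v, v)
    v = np.where(v < -1.0, -2.0 - v, v)
    return np.clip(v, -0.999999, 0.999999)


class _Partition:
    """Index bookkeeping for conditional priors within the random dims."""

    def __init__(self, random_dims: list[int]):
        self.R = list(random_dims)
        self.loc = [d for d in self.R if d in (_MU, _BETA)]
        self.dyn = [d for d in self.R if d in (_PHI, _OMEGA)]
        self.pos = {d: k for k, d in enumerate(self.R)}
        self.loc_pos = [self.pos[d] for d in self.loc]
        self.dyn_pos = [self.pos[d] for d in self.dyn]


def _cond_prior(gamma_R, Sigma_R, theta_R, target_pos, given_pos):
    """Conditional N(mean, cov) of theta[target] given theta[given]."""
    t = np.asarray(target_pos)
    g = np.asarray(given_pos)
    mu_t = gamma_R[t]
    if g.size == 0:
        cov = Sigma_R[np.ix_(t, t)]
        mean = np.broadcast_to(mu_t, (theta_R.shape[0], t.size)).copy()
        return mean, cov
    S_tt = Sigma_R[np.ix_(t, t)]
    S_tg = Sigma_R[np.ix_(t, g)]
    S_gg = Sigma_R[np.ix_(g, g)]
    K = np.linalg.solve(S_gg, S_tg.T).T  # t x g
    mean = mu_t + (theta_R[:, g] - gamma_R[g]) @ K.T
    cov = S_tt - K @ S_tg.T
    return mean, cov


def _mvn_logpdf(x, mean, cov):
    """Vectorized small-dimension MVN log density (x, mean: n x d)."""
    d = x.shape[1]
    L = np.linalg.cholesky(cov + 1e-12 * np.eye(d))
    diff = x - mean
    sol = np.linalg.solve(L, diff.T)
    q = np.sum(sol**2, axis=0)
    return -0.5 * (d * np.log(2 * np.pi) + 2 * np.sum(np.log(np.diag(L))) + q)


def _ar1_suffstats(W, inb):
    """Per-subject sufficient stats of the complete AR(1) deviations.

    Returns (w0sq, A, B, C) with A = sum_{t>=2} w_t^2, B = sum w_t w_{t-1},
    C = sum w_{t-1}^2 over in-bounds consecutive pairs.
    """
    pair = inb[:, 1:]
    wt = W[:, 1:] * pair
    wp = W[:, :-1] * pair
    A = np.sum(wt * wt, axis=1)
    B = np.sum(wt * wp, axis=1)
    C = np.sum(wp * wp, axis=1)
    return W[:, 0] ** 2, A, B, C


def _ar1_loglik(phi, omega, w0sq, A, B, C, lengths):
    """Stationary AR(1) log likelihood from sufficient statistics."""
    sig2 = np.exp(omega)
    sse = A - 2.0 * phi * B + phi**2 * C
    return -0.5 * (
        lengths * (omega + np.log(2 * np.pi))
        - np.log1p(-(phi**2))
        + (w0sq * (1.0 - phi**2) + sse) / sig2
    )


def _gap_deviance(y, x, inb, lengths, theta):
    """Observed-data conditional deviance, gaps marginalized exactly.

    For an AR(1) process the observed subsequence is Gaussian Markov: after
    a gap of g missing trials the conditional law of the deviation is
    N(phi^g * w_prev, sig2 * (1 - phi^(2g)) / (1 - phi^2)).
    """
    obs = np.isfinite(y) & inb
    mu = theta[:, _MU][:, None]
    beta = theta[:, _BETA][:, None]
    phi = theta[:, _PHI][:, None]
    sig2 = np.exp(theta[:, _OMEGA])[:, None]
    r = np.where(obs, y - mu - beta * x, 0.0)

    N, T = y.shape
    # index of the previous observed trial (or -1)
    idx = np.where(obs, np.arange(T)[None, :], -1)
    prev = np.maximum.accumulate(idx, axis=1)
    prev_excl = np.concatenate([-np.ones((N, 1), dtype=int), prev[:, :-1]], axis=1)
    first = obs & (prev_excl < 0)
    later = obs & (prev_excl >= 0)
    gap = np.where(later, np.arange(T)[None, :] - prev_excl, 1)
    r_prev = np.take_along_axis(r, np.maximum(prev_excl, 0), axis=1)

    one_m_phi2 = 1.0 - phi**2
    var_first = sig2 / one_m_phi2
    phig = phi**gap
    var_later = sig2 * (1.0 - phig**2) / one_m_phi2
    ll = np.where(
        first,
        -0.5 * (np.log(2 * np.pi * var_first) + r**2 / var_first),
        0.0,
    )
    mean_later = phig * r_prev
    ll = ll + np.where(
        later,
        -0.5 * (np.log(2 * np.pi * var_later) + (r - mean_later) ** 2 / var_later),
        0.0,
    )
    return -2.0 * float(np.sum(ll[obs]))


class AR1LocationScaleDSEM:
    """Two-level AR(1) location-scale time-series model, MCMC-estimated.

    Parameters
    ----------
    n_iterations : int, default 20000
        Total iterations per chain, including burn-in.
    burn_in : int or None
        Burn-in iterations per chain; defaults to half of ``n_iterations``.
    n_chains : int, default 2
        Independent chains (>= 2 required for convergence checking).
    thinning : int, default 1
        Keep every ``thinning``-th post-burn-in draw.
    random_state : int, default 0
        Seed; every chain derives its own stream.
    constrain_variability : bool
        Fix omega_i = gamma_omega for all i (the "no random residual
        variability" model of the DIC test).
    constrain_trend, constrain_inertia : bool
        Fix beta_i = 0 / phi_i = 0.
    constrain_mean : bool
        Fix mu_i = gamma_mu (requires ``constrain_trend``); with all four
        constraints the model is iid normal with two free parameters.
    min_trials : int, default 10
        Subjects with fewer observed trials are dropped with a warning.
    prior_gamma_sd : float, default 100
        Diffuse normal prior sd for each fixed effect.
    prior_sigma_scale : float, default 0.1
        Inverse-Wishart scale matrix is ``prior_sigma_scale * I`` with
        ``dim + 2`` degrees of freedom.  0.1 is weakly informative on the
        log-ms scale, where between-person variances span roughly 1e-4
        (trend) to 0.25 (log residual variance).

    Attributes (after fit)
    ----------------------
    scores_ : DataFrame of EAP person effects (subject, mu, beta, phi, omega)
    gamma_, Sigma_ : posterior means of the between-person parameters
    tau2_omega_ : posterior mean of Sigma[omega, omega]
    dic_, dic_components_ : model fit criterion and its parts
    psrf_ : dict of potential-scale-reduction statistics
    converged_ : True when every PSRF < 1.1
    """

    def __init__(
        self,
        n_iterations: int = 20000,
        burn_in: int | None = None,
        n_chains: int = 2,
        thinning: int = 1,
        random_state: int = 0,
        constrain_variability: bool = False,
        constrain_trend: bool = False,
        constrain_inertia: bool = False,
        constrain_mean: bool = False,
        min_trials: int = 10,
        prior_gamma_sd: float = 100.0,
        prior_sigma_scale: float = 0.1,
    ):
        self.n_iterations = n_iterations
        self.burn_in = burn_in
        self.n_chains = n_chains
        self.thinning = thinning
        self.random_state = random_state
        self.constrain_variability = constrain_variability
        self.constrain_trend = constrain_trend
        self.constrain_inertia = constrain_inertia
        self.constrain_mean = constrain_mean
        self.min_trials = min_trials
        self.prior_gamma_sd = prior_gamma_sd
        self.prior_sigma_scale = prior_sigma_scale

    # -- sklearn plumbing -------------------------------------------------
    _param_names = (
        "n_iterations", "burn_in", "n_chains", "thinning", "random_state",
        "constrain_variability", "constrain_trend", "constrain_inertia",
        "constrain_mean", "min_trials", "prior_gamma_sd", "prior_sigma_scale",
    )

    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k) for k in self._param_names}

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self._param_names:
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    # -- data handling -----------------------------------------------------
    def _validate(self, X):
        if isinstance(X, pd.DataFrame):
            y, subjects, lengths = series_to_matrix(X)
        else:
            y = np.array(X, dtype=float, copy=True)
            if y.ndim != 2:
                raise ValueError("array input must be 2-D (subjects x trials)")
            subjects = np.arange(y.shape[0])
            lengths = np.full(y.shape[0], y.shape[1])
            # trailing all-NaN tails count as series end, not missingness
            rev = np.isfinite(y)[:, ::-1]
            lengths = y.shape[1] - rev.argmax(axis=1)
            lengths[~rev.any(axis=1)] = 0
        n_obs = np.isfinite(y).sum(axis=1)
        if np.any(n_obs == 0):
            raise ValueError("series with no observed values are not allowed")
        keep = n_obs >= self.min_trials
        if not np.all(keep):
            warnings.warn(
                f"dropping {int((~keep).sum())} subject(s) with fewer than "
                f"{self.min_trials} observed trials",
                stacklevel=2,
            )
            y, subjects, lengths = y[keep], subjects[keep], lengths[keep]
        if y.shape[0] < 2:
            raise ValueError(
                "at least 2 subjects are required: the between-person "
                "covariance is unidentifiable from a single series"
            )
        if self.constrain_mean and not self.constrain_trend:
            raise ValueError("constrain_mean requires constrain_trend")
        return y, subjects, lengths

    def _random_dims(self) -> list[int]:
        dims = []
        if not self.constrain_mean:
            dims.append(_MU)
        if not self.constrain_trend:
            dims.append(_BETA)
        if not self.constrain_inertia:
            dims.append(_PHI)
        if not self.constrain_variability:
            dims.append(_OMEGA)
        return dims

    # -- the sampler -------------------------------------------------------
    def fit(self, X, y=None):
        yo, subjects, lengths = self._validate(X)
        N, T = yo.shape
        inb = np.arange(T)[None, :] < lengths[:, None]
        x = _trend_design(lengths, T)
        obs = np.isfinite(yo) & inb
        mis = inb & ~obs

        burn = self.burn_in if self.burn_in is not None else self.n_iterations // 2
        if burn >= self.n_iterations:
            raise ValueError("burn_in must be smaller than n_iterations")
        n_keep = (self.n_iterations - burn) // self.thinning
        part = _Partition(self._random_dims())
        r = len(part.R)

        chains = {
            "theta": np.empty((self.n_chains, n_keep, N, 4)),
            "gamma": np.empty((self.n_chains, n_keep, 4)),
            "Sigma": np.empty((self.n_chains, n_keep, r, r)),
            "deviance": np.empty((self.n_chains, n_keep)),
        }
        for c in range(self.n_chains):
            rng = np.random.default_rng([int(self.random_state) % (2**31), c])
            self._run_chain(
                rng, yo, x, inb, obs, mis, lengths, part, burn, n_keep,
                chains, c,
            )

        self._assemble(chains, subjects, yo, x, inb, lengths, part)
        return self

    def _run_chain(self, rng, yo, x, inb, obs, mis, lengths, part, burn,
                   n_keep, chains, c):
        N, T = yo.shape
        v0 = self.prior_gamma_sd**2
        r = len(part.R)
        nu0 = r + 2
        S0 = self.prior_sigma_scale * np.eye(r)

        # --- initial values from crude per-subject statistics
        theta = np.zeros((N, 4))
        ybar = np.nanmean(yo, axis=1)
        theta[:, _MU] = ybar
        resid_var = np.nanvar(yo, axis=1)
        theta[:, _OMEGA] = np.log(np.maximum(resid_var, 1e-6))
        if _PHI in part.R:
            theta[:, _PHI] = 0.1
        if self.constrain_mean:
            theta[:, _MU] = float(np.mean(ybar))
        if self.constrain_variability:
            theta[:, _OMEGA] = float(np.log(np.maximum(np.mean(resid_var), 1e-6)))
        gamma = np.array([
            theta[:, _MU].mean(),
            0.0,
            theta[:, _PHI].mean(),
            theta[:, _OMEGA].mean(),
        ])
        if part.R:
            Sigma_R = np.diag(
                np.maximum(np.var(theta[:, part.R], axis=0), 1e-4)
            )
        else:
            Sigma_R = np.zeros((0, 0))

        Yc = np.where(obs, yo, 0.0)
        # start missing values at the person mean
        Yc[mis] = np.broadcast_to(ybar[:, None], yo.shape)[mis]
        Yc[~inb] = 0.0

        # adaptive MH step sizes (frozen after burn-in)
        s_dyn = np.full((N, 2), 0.15)
        s_gom = 0.05
        mis_even = mis & (np.arange(T)[None, :] % 2 == 0)
        mis_odd = mis & (np.arange(T)[None, :] % 2 == 1)
        has_prev = np.concatenate([np.zeros((N, 1), bool), inb[:, :-1]], axis=1)
        has_next = np.concatenate([inb[:, 1:], np.zeros((N, 1), bool)], axis=1)

        kept = 0
        for it in range(self.n_iterations):
            mu = theta[:, _MU][:, None]
            beta = theta[:, _BETA][:, None]
            phi = theta[:, _PHI][:, None]
            sig2 = np.exp(theta[:, _OMEGA])[:, None]

            # --- 1. impute masked trials as latent states (checkerboard)
            if mis.any():
                for pm in (mis_even, mis_odd):
                    if not pm.any():
                        continue
                    W = np.where(inb, Yc - mu - beta * x, 0.0)
                    Wp = np.concatenate([np.zeros((N, 1)), W[:, :-1]], axis=1)
                    Wn = np.concatenate([W[:, 1:], np.zeros((N, 1))], axis=1)
                    both = has_prev & has_next
                    mean = np.where(
                        both, phi * (Wp + Wn) / (1.0 + phi**2),
                        np.where(has_prev, phi * Wp,
                                 np.where(has_next, phi * Wn, 0.0)),
                    )
                    var = np.where(
                        both, sig2 / (1.0 + phi**2),
                        np.where(has_prev | has_next, sig2,
                                 sig2 / (1.0 - phi**2)),
                    )
                    z = rng.standard_normal((N, T))
                    w_new = mean + np.sqrt(var) * z
                    Yc = np.where(pm, mu + beta * x + w_new, Yc)

            # --- 2. conjugate update of location parameters
            if part.loc:
                gamma_R = gamma[part.R]
                m_loc, V_loc = _cond_prior(
                    gamma_R, Sigma_R, theta[:, part.R], part.loc_pos,
                    part.dyn_pos,
                )
                sq = np.sqrt(np.clip(1.0 - phi**2, 1e-12, None))
                cols = []
                if _MU in part.loc:
                    u = inb.astype(float)
                    us = np.concatenate(
                        [sq, (1.0 - phi) * np.ones((N, T - 1))], axis=1
                    ) * u
                    cols.append(us)
                if _BETA in part.loc:
                    xs = np.concatenate(
                        [sq * x[:, :1], x[:, 1:] - phi * x[:, :-1]], axis=1
                    ) * inb
                    cols.append(xs)
                ys = np.concatenate(
                    [sq * Yc[:, :1], Yc[:, 1:] - phi * Yc[:, :-1]], axis=1
                ) * inb
                k = len(cols)
                P = np.empty((N, k, k))
                b = np.empty((N, k))
                for a_ in range(k):
                    b[:, a_] = np.sum(cols[a_] * ys, axis=1) / sig2[:, 0]
                    for b_ in range(a_, k):
                        P[:, a_, b_] = P[:, b_, a_] = (
                            np.sum(cols[a_] * cols[b_], axis=1) / sig2[:, 0]
                        )
                Vinv = np.linalg.inv(V_loc + 1e-12 * np.eye(k))
                P = P + Vinv[None, :, :]
                b = b + m_loc @ Vinv.T
                L = np.linalg.cholesky(P)
                mean = np.linalg.solve(P, b[:, :, None])[:, :, 0]
                z = rng.standard_normal((N, k))
                dev = np.linalg.solve(
                    np.transpose(L, (0, 2, 1)), z[:, :, None]
                )[:, :, 0]
                draw = mean + dev
                for j, d in enumerate(part.loc):
                    theta[:, d] = draw[:, j]
                mu = theta[:, _MU][:, None]
                beta = theta[:, _BETA][:, None]

            # --- 3. Metropolis update of (phi, omega)
            W = np.where(inb, Yc - mu - beta * x, 0.0)
            w0sq, A, B, C = _ar1_suffstats(W, inb)
            if part.dyn:
                gamma_R = gamma[part.R]
                m_dyn, V_dyn = _cond_prior(
                    gamma_R, Sigma_R, theta[:, part.R], part.dyn_pos,
                    part.loc_pos,
                )
                cur = theta[:, part.dyn]
                ll_cur = _ar1_loglik(
                    theta[:, _PHI], theta[:, _OMEGA], w0sq, A, B, C, lengths
                ) + _mvn_logpdf(cur, m_dyn, V_dyn)
                prop = theta.copy()
                z = rng.standard_normal((N, len(part.dyn)))
                for j, d in enumerate(part.dyn):
                    step = s_dyn[:, 0] if d == _PHI else s_dyn[:, 1]
                    prop[:, d] = theta[:, d] + step * z[:, j]
                prop[:, _PHI] = _reflect_unit(prop[:, _PHI])
                ll_prop = _ar1_loglik(
                    prop[:, _PHI], prop[:, _OMEGA], w0sq, A, B, C, lengths
                ) + _mvn_logpdf(prop[:, part.dyn], m_dyn, V_dyn)
                acc = np.log(rng.random(N)) < (ll_prop - ll_cur)
                for d in part.dyn:
                    theta[acc, d] = prop[acc, d]
                if it < burn:
                    rate = 2.0 / np.sqrt(it + 10.0)
                    s_dyn *= np.exp(rate * (acc[:, None] - 0.3))
                    np.clip(s_dyn, 1e-3, 2.0, out=s_dyn)

            # --- 4. common fixed effects for constrained dims
            if self.constrain_mean:
                phi = theta[:, _PHI][:, None]
                sig2 = np.exp(theta[:, _OMEGA])[:, None]
                sq = np.sqrt(np.clip(1.0 - phi**2, 1e-12, None))
                us = np.concatenate(
                    [sq, (1.0 - phi) * np.ones((N, T - 1))], axis=1
                ) * inb
                ys = np.concatenate(
                    [sq * Yc[:, :1], Yc[:, 1:] - phi * Yc[:, :-1]], axis=1
                ) * inb
                prec = np.sum(us * us / sig2) + 1.0 / v0
                mean = np.sum(us * ys / sig2) / prec
                gmu = mean + rng.standard_normal() / np.sqrt(prec)
                gamma[_MU] = gmu
                theta[:, _MU] = gmu
            if self.constrain_variability:
                W = np.where(
                    inb,
                    Yc - theta[:, _MU][:, None] - theta[:, _BETA][:, None] * x,
                    0.0,
                )
                w0sq, A, B, C = _ar1_suffstats(W, inb)
                om = gamma[_OMEGA]
                ll_cur = np.sum(_ar1_loglik(
                    theta[:, _PHI], np.full(N, om), w0sq, A, B, C, lengths
                )) - 0.5 * om**2 / v0
                om_p = om + s_gom * rng.standard_normal()
                ll_prop = np.sum(_ar1_loglik(
                    theta[:, _PHI], np.full(N, om_p), w0sq, A, B, C, lengths
                )) - 0.5 * om_p**2 / v0
                acc_g = np.log(rng.random()) < ll_prop - ll_cur
                if acc_g:
                    gamma[_OMEGA] = om_p
                theta[:, _OMEGA] = gamma[_OMEGA]
                if it < burn:
                    s_gom *= float(np.exp(
                        2.0 / np.sqrt(it + 10.0) * ((1.0 if acc_g else 0.0) - 0.3)
                    ))
                    s_gom = float(np.clip(s_gom, 1e-4, 1.0))

            # --- 5. between-person distribution (gamma_R, Sigma_R)
            if part.R:
                th_R = theta[:, part.R]
                Sinv = np.linalg.inv(Sigma_R)
                prec = N * Sinv + np.eye(r) / v0
                mean = np.linalg.solve(prec, Sinv @ th_R.sum(axis=0))
                Lp = np.linalg.cholesky(np.linalg.inv(prec))
                g_draw = mean + Lp @ rng.standard_normal(r)
                for j, d in enumerate(part.R):
                    gamma[d] = g_draw[j]
                diff = th_R - g_draw
                Sn = S0 + diff.T @ diff
                Sigma_R = stats.invwishart.rvs(
                    df=nu0 + N, scale=Sn, random_state=rng
                )
                Sigma_R = np.atleast_2d(Sigma_R)

            # --- 6. record
            if it >= burn and (it - burn) % self.thinning == 0 and kept < n_keep:
                chains["theta"][c, kept] = theta
                chains["gamma"][c, kept] = gamma
                chains["Sigma"][c, kept] = Sigma_R
                chains["deviance"][c, kept] = _gap_deviance(
                    yo, x, inb, lengths, theta
                )
                kept += 1

    # -- post-processing ---------------------------------------------------
    def _assemble(self, chains, subjects, yo, x, inb, lengths, part):
        theta = chains["theta"]
        self.draws_ = chains
        self._data = (yo, x, inb, lengths)
        self._partition = part

        eap = theta.mean(axis=(0, 1))
        self.scores_ = pd.DataFrame(eap, columns=list(EFFECT_NAMES))
        self.scores_.insert(0, "subject", subjects)
        self.subjects_ = subjects

        self.gamma_ = pd.Series(
            chains["gamma"].mean(axis=(0, 1)), index=list(EFFECT_NAMES)
        )
        r = len(part.R)
        Sigma_full = np.zeros((4, 4))
        if r:
            S_mean = chains["Sigma"].mean(axis=(0, 1))
            for a, da in enumerate(part.R):
                for b, db in enumerate(part.R):
                    Sigma_full[da, db] = S_mean[a, b]
        self.Sigma_ = pd.DataFrame(
            Sigma_full, index=list(EFFECT_NAMES), columns=list(EFFECT_NAMES)
        )
        self.tau2_omega_ = float(Sigma_full[_OMEGA, _OMEGA])

        # convergence: split-Rhat over chains for the top-level quantities
        psrf = {}
        if self.n_chains >= 2:
            ds = {"gamma": chains["gamma"], "deviance": chains["deviance"]}
            if r:
                diag = np.einsum("cdii->cdi", chains["Sigma"])
                ds["sigma_diag"] = diag
            rh = az.rhat(az.convert_to_dataset(ds))
            for name in ds:
                vals = np.atleast_1d(np.asarray(rh[name]))
                psrf[name] = vals
            psrf["max"] = float(max(np.nanmax(v) for v in psrf.values()))
        else:
            warnings.warn("PSRF requires at least 2 chains", stacklevel=2)
            psrf["max"] = np.nan
        self.psrf_ = psrf
        self.converged_ = bool(psrf.get("max", np.inf) < 1.1)
        if not self.converged_ and self.n_chains >= 2:
            warnings.warn(
                f"possible non-convergence: max PSRF = {psrf['max']:.3f}",
                stacklevel=2,
            )

        comp = compute_dic(self)
        self.dic_components_ = comp
        self.dic_ = comp["dic"]

    def factor_scores(self) -> pd.DataFrame:
        """EAP person-effect table (the variability scores live in 'omega')."""
        return self.scores_.copy()


def fit_dsem(series, constrain_variability: bool = False, **config) -> AR1LocationScaleDSEM:
    """Fit the location-scale DSEM on preprocessed series.

    ``series`` is either a long DataFrame (subject, position, log_rt) or a
    subjects x trials array with NaN marking masked trials.  Keyword
    arguments are passed to :class:`AR1LocationScaleDSEM`.
    """
    model = AR1LocationScaleDSEM(
        constrain_variability=constrain_variability, **config
    )
    return model.fit(series)


def compute_dic(fit: AR1LocationScaleDSEM) -> dict:
    """Deviance information criterion from the stored draws.

    DIC = Dbar + pD with pD = Dbar - D(thetabar); the deviance is the
    observed-data deviance conditional on the person-level effects, so the
    result is a deterministic function of the stored draws and data.
    """
    yo, x, inb, lengths = fit._data
    dbar = float(fit.draws_["deviance"].mean())
    theta_bar = fit.draws_["theta"].mean(axis=(0, 1))
    dhat = _gap_deviance(yo, x, inb, lengths, theta_bar)
    pd_ = dbar - dhat
    if pd_ < 0:
        warnings.warn(
            f"negative effective parameter count pD = {pd_:.2f}", stacklevel=2
        )
    return {"dbar": dbar, "dhat": dhat, "pd": pd_, "dic": dbar + pd_}


def test_random_variability(series, random_state: int = 0, **config) -> dict:
    """Fit the full and variability-constrained models; prefer lower DIC."""
    config.pop("constrain_variability", None)
    full = fit_dsem(series, random_state=random_state, **config)
    constrained = fit_dsem(
        series, constrain_variability=True, random_state=random_state, **config
    )
    delta = constrained.dic_ - full.dic_
    return {
        "dic_full": full.dic_,
        "dic_constrained": constrained.dic_,
        "delta_dic": delta,
        "preferred": "full" if full.dic_ < constrained.dic_ else "constrained",
        "fit_full": full,
        "fit_constrained": constrained,
    }


def extract_factor_scores(fit: AR1LocationScaleDSEM) -> pd.DataFrame:
    """EAP person scores, one row per retained subject, input order kept."""
    return fit.factor_scores()


def estimate_reliability(
    fit: AR1LocationScaleDSEM,
    n_occasions: int,
    scale_reliability: float,
    n_replicates: int = 400,
    random_state: int = 0,
) -> float:
    """Simulation-based reliability of the variability score.

    Replicate persons are drawn from the fitted between-person distribution
    (gamma, Sigma), each observed for ``n_occasions`` trials with white
    measurement noise of variance (1 - rho) / rho times the median
    within-person variance, where rho is the assumed scale reliability.
    The returned reliability is the squared correlation across replicates
    between a method-of-moments estimate of omega and its true value.
    """
    if scale_reliability <= 0 or scale_reliability > 1:
        raise ValueError("scale_reliability must be in (0, 1]")
    if n_occasions < 2:
        raise ValueError("n_occasions must be >= 2")
    tau2 = fit.tau2_omega_
    if tau2 < 1e-6:
        warnings.warn(
            "tau^2_omega is essentially zero; variability scores carry no "
            "between-person signal and reliability is 0",
            stacklevel=2,
        )
        return 0.0
    rng = np.random.default_rng(random_state)
    gamma = fit.gamma_.to_numpy()
    Sigma = fit.Sigma_.to_numpy()

    from .synthetic import draw_person_effects

    eff = draw_person_effects(n_replicates, gamma, Sigma, rng)
    mu = eff["mu"].to_numpy()
    beta = eff["beta"].to_numpy()
    phi = eff["phi"].to_numpy()
    omega = eff["omega"].to_numpy()
    sig = np.sqrt(np.exp(omega))

    M, n = n_replicates, n_occasions
    w = np.empty((M, n))
    w[:, 0] = rng.standard_normal(M) * sig / np.sqrt(1.0 - phi**2)
    eps = rng.standard_normal((M, n))
    for t in range(1, n):
        w[:, t] = phi * w[:, t - 1] + sig * eps[:, t]
    tgrid = np.arange(1, n + 1)
    x = (tgrid - (n + 1) / 2.0) / 100.0
    y = mu[:, None] + beta[:, None] * x[None, :] + w
    within_var = np.exp(omega) / (1.0 - phi**2)
    noise_var = (1.0 - scale_reliability) / scale_reliability * float(
        np.median(within_var)
    )
    y = y + rng.standard_normal((M, n)) * np.sqrt(noise_var)

    # method-of-moments: innovation variance from an OLS AR(1)-with-trend fit
    Y1, Y0 = y[:, 1:], y[:, :-1]
    X = np.stack(
        [np.ones((M, n - 1)), np.broadcast_to(x[1:], (M, n - 1)), Y0], axis=2
    )
    XtX = np.einsum("mti,mtj->mij", X, X)
    Xty = np.einsum("mti,mt->mi", X, Y1)
    coef = np.linalg.solve(XtX, Xty[..., None])[..., 0]
    pred = np.einsum("mti,mi->mt", X, coef)
    rss = np.sum((Y1 - pred) ** 2, axis=1)
    omega_hat = np.log(np.maximum(rss / (n - 1 - 3), 1e-12))
    r = np.corrcoef(omega_hat, omega)[0, 1]
    return float(r**2)
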