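"""Hierarchical Bayesian latent-trait estimation of individual MPT parameters.

Each participant i contributes one 3x3 response-frequency table.  On the
probit scale the participant's free parameter vector eta_i (order
``D_E, D_U, d_E, d_U, b, g``; ``D_N`` tied by the identifiability
restriction) is drawn from a multivariate normal,

    eta_i ~ MVN(mu, Sigma),      theta_i = Phi(eta_i)  elementwise,

so individual parameter heterogeneity and correlations between processes
are estimated jointly with the group means.  Estimation is
Metropolis-within-Gibbs:

- a blocked random-walk Metropolis step updates each eta_i (vectorized over
  participants and chains), with per-participant proposal scales adapted
  toward a target acceptance rate during burn-in only;
- mu is updated by its conjugate Gibbs step under a Normal(0, s^2 I) prior;
- Sigma is updated by its conjugate inverse-Wishart Gibbs step.  The
  inverse-Wishart draw is positive definite by construction, so no proposal
  can produce an invalid covariance.

Diagnostics follow common MCMC practice: split-Rhat (Gelman-Rubin) and an
autocorrelation-based effective sample size for the group-level quantities,
plus the T1/T2 posterior-predictive fit statistics: T1 measures the
discrepancy between observed and model-implied mean category frequencies,
T2 the discrepancy between observed and model-implied across-participant
covariances of the category counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import ndtr, ndtri

from srcmon.mpt import (
    FREE_PARAM_NAMES,
    FrequencyTable,
    MPTDomainError,
    Restriction,
    _closed_form_inversion,
    _free_to_probs,
)

K = len(FREE_PARAM_NAMES)  # 6 free parameters


@dataclass(frozen=True)
class Priors:
    """Weakly informative default priors on the probit scale."""

    mu_sd: float = 1.0          # mu_k ~ Normal(0, mu_sd^2)
    sigma_df: float = K + 2.0   # Sigma ~ InvWishart(sigma_df, sigma_scale * I)
    sigma_scale: float = 1.0


@dataclass(frozen=True)
class MCMCConfig:
    """Sampler configuration.

    The default is a desk-scale run (20,000 iterations, 10,000 burn-in,
    thinning 5, four chains).  :meth:`full_scale` returns the preset used
    for full-scale analyses: 500,000 iterations with a 250,000 burn-in,
    retaining every tenth sample.
    """

    chains: int = 4
    iterations: int = 20_000
    burn_in: int = 10_000
    thin: int = 5
    restriction: Restriction = "D_N=D_U"
    seed: int = 0
    priors: Priors = field(default_factory=Priors)
    step_init: float = 0.3
    target_accept: float = 0.35
    adapt_rate: float = 0.05
    eta_sweeps: int = 2

    def __post_init__(self) -> None:
        if self.chains < 2:
            raise MPTDomainError("config requires >= 2 chains")
        if not (self.iterations > self.burn_in >= 0):
            raise MPTDomainError("need iterations > burn_in >= 0")
        if self.thin < 1:
            raise MPTDomainError("thin must be >= 1")

    @property
    def retained_per_chain(self) -> int:
        return (self.iterations - self.burn_in) // self.thin

    @classmethod
    def full_scale(cls, **overrides) -> "MCMCConfig":
        base = dict(iterations=500_000, burn_in=250_000, thin=10)
        base.update(overrides)
        return cls(**base)


@dataclass
class PosteriorSample:
    """Retained MCMC draws for mu, Sigma and all individual parameters."""

    mu: np.ndarray       # (chains, draws, K) probit scale
    sigma: np.ndarray    # (chains, draws, K, K)
    theta: np.ndarray    # (chains, draws, n_participants, K) unit scale
    config: MCMCConfig
    param_names: tuple[str, ...] = FREE_PARAM_NAMES
    accept_rate: float = float("nan")

    @property
    def n_chains(self) -> int:
        return self.mu.shape[0]

    @property
    def n_draws(self) -> int:
        return self.mu.shape[1]

    @property
    def n_participants(self) -> int:
        return self.theta.shape[2]

    def group_level_draws(self) -> dict[str, np.ndarray]:
        """Flattened draws of the group-level means Phi(mu) on the unit scale."""
        flat = ndtr(self.mu.reshape(-1, K))
        return {name: flat[:, i] for i, name in enumerate(self.param_names)}

    def draws_frame(self):
        """Group-level draws in long columnar form (chain, iteration, values).

        Iteration numbers refer to retained draws after burn-in and
        thinning.  Suitable for writing as delimited text.
        """
        import pandas as pd

        C, R, _ = self.mu.shape
        frame = pd.DataFrame(
            {
                "chain": np.repeat(np.arange(C), R),
                "iteration": np.tile(np.arange(R), C),
            }
        )
        unit = ndtr(self.mu.reshape(C * R, K))
        for i, name in enumerate(self.param_names):
            frame[name] = unit[:, i]
        return frame


@dataclass(frozen=True)
class FitDiagnostics:
    rhat: dict[str, float] | None = None
    ess: dict[str, float] | None = None
    t1_p: float | None = None
    t2_p: float | None = None

    @property
    def max_rhat(self) -> float | None:
        return max(self.rhat.values()) if self.rhat else None


@dataclass(frozen=True)
class ParameterContrast:
    label: str
    mean: float
    median: float
    bci: tuple[float, float]

    @property
    def significant(self) -> bool:
        """True iff the 95% credibility interval excludes zero."""
        lo, hi = self.bci
        return not (lo <= 0.0 <= hi)


def _stack_counts(tables: Sequence[FrequencyTable]) -> np.ndarray:
    counts = []
    for i, t in enumerate(tables):
        if t.task != "3afc":
            raise MPTDomainError(f"participant table {i} is not 3AFC")
        if t.total == 0:
            raise MPTDomainError(f"participant table {i} has zero total count")
        counts.append(t.counts.astype(float))
    return np.stack(counts)


def _log_multinomial(eta: np.ndarray, counts: np.ndarray,
                     restriction: Restriction) -> np.ndarray:
    """Multinomial log-likelihood per (chain, participant) from probit values."""
    P = _free_to_probs(ndtr(eta), restriction)
    return np.einsum("ntr,cntr->cn", counts, np.log(np.maximum(P, 1e-300)))


def _init_eta(counts: np.ndarray, restriction: Restriction) -> np.ndarray:
    """Per-participant probit starting values from smoothed moment inversion."""
    n = counts.shape[0]
    eta0 = np.empty((n, K))
    for i in range(n):
        smoothed = counts[i] + 0.5
        p = smoothed / smoothed.sum(axis=1, keepdims=True)
        sol = _closed_form_inversion(p, restriction)
        vec = np.array([sol[name] for name in FREE_PARAM_NAMES])
        eta0[i] = ndtri(np.clip(vec, 0.02, 0.98))
    return eta0


def fit_hierarchical(
    individual_tables: Sequence[FrequencyTable],
    config: MCMCConfig | None = None,
) -> PosteriorSample:
    """Fit the latent-trait model to one 3x3 table per participant.

    Deterministic given ``config.seed`` and the data.  All chains are driven
    by a single generator seeded from the master seed; chain c occupies
    slice c of every vectorized draw, which fixes the per-chain streams.
    """
    config = config or MCMCConfig()
    counts = _stack_counts(individual_tables)
    n = counts.shape[0]
    C = config.chains
    restriction = config.restriction
    rng = np.random.default_rng(config.seed)
    pri = config.priors

    eta0 = _init_eta(counts, restriction)
    eta = np.tile(eta0, (C, 1, 1)) + 0.05 * rng.standard_normal((C, n, K))
    mu = eta.mean(axis=1)
    sigma_inv = np.tile(np.eye(K), (C, 1, 1))
    step = np.full((C, n), config.step_init)
    # proposal shape per (chain, participant): Cholesky factor of the running
    # posterior covariance of eta_i, adapted during burn-in only.  Weakly
    # identified components (individual source memory, guessing) have wide,
    # mutually correlated conditionals; a correlated proposal keeps the
    # acceptance rate up at much larger effective step sizes.
    shape = np.tile(np.eye(K), (C, n, 1, 1))
    run_mean = eta.copy()
    run_m2 = np.zeros((C, n, K, K))
    # group-level translation move: shift mu and every eta_i jointly along
    # directions adapted to the posterior covariance of mu, which carries
    # the sampler across likelihood ridges (e.g. the d-g trade-off)
    trans_chol = np.tile(0.05 * np.eye(K), (C, 1, 1))
    trans_step = np.full(C, 1.0)
    mu_mean = mu.copy()
    mu_m2 = np.zeros((C, K, K))
    scale_step = np.full(C, 0.05)
    nc_scale_step = np.full(C, 0.05)

    R = config.retained_per_chain
    mu_out = np.empty((C, R, K))
    sigma_out = np.empty((C, R, K, K))
    theta_out = np.empty((C, R, n, K))

    ll = _log_multinomial(eta, counts, restriction)
    prior_prec_diag = 1.0 / pri.mu_sd**2
    S0 = pri.sigma_scale * np.eye(K)
    nu_post = pri.sigma_df + n

    accepted = 0
    proposed = 0
    r_idx = 0
    n_sweeps = config.eta_sweeps
    for it in range(1, config.iterations + 1):
        # --- blocked random-walk Metropolis on eta, all chains/participants
        # (two sweeps per iteration: individual deviations are the
        # slowest-mixing quantities and bound the Sigma diagnostics)
        for sweep in range(n_sweeps):
            z = rng.standard_normal((C, n, K))
            prop = eta + step[..., None] * np.einsum("cnkl,cnl->cnk", shape, z)
            llp = _log_multinomial(prop, counts, restriction)
            dev = eta - mu[:, None, :]
            devp = prop - mu[:, None, :]
            lp = -0.5 * np.einsum("cnk,ckl,cnl->cn", dev, sigma_inv, dev)
            lpp = -0.5 * np.einsum("cnk,ckl,cnl->cn", devp, sigma_inv, devp)
            accept = np.log(rng.random((C, n))) < (llp + lpp - ll - lp)
            eta = np.where(accept[..., None], prop, eta)
            ll = np.where(accept, llp, ll)
            if it <= config.burn_in:
                step *= np.exp(
                    config.adapt_rate * (accept - config.target_accept)
                )
                step = np.clip(step, 1e-3, 5.0)
            else:
                accepted += int(accept.sum())
                proposed += accept.size
        if it <= config.burn_in:
            delta = eta - run_mean
            run_mean += delta / it
            run_m2 += np.einsum("cnk,cnl->cnkl", delta, eta - run_mean)
            if it >= 200 and it % 100 == 0:
                cov = run_m2 / (it - 1)
                cov = cov + 1e-5 * np.eye(K)
                chol = np.linalg.cholesky(cov)
                # normalize to unit geometric-mean scale so `step` stays
                # the overall proposal magnitude
                logdet = np.log(
                    np.diagonal(chol, axis1=-2, axis2=-1)
                ).sum(axis=-1, keepdims=True)[..., None]
                shape = chol * np.exp(-logdet / K)

        # --- joint translation of (mu, all eta) per chain
        delta = np.einsum(
            "ckl,cl->ck", trans_chol, rng.standard_normal((C, K))
        ) * trans_step[:, None]
        eta_t = eta + delta[:, None, :]
        ll_t = _log_multinomial(eta_t, counts, restriction)
        mu_t = mu + delta
        dlp_mu = -0.5 * prior_prec_diag * (
            np.sum(mu_t**2, axis=1) - np.sum(mu**2, axis=1)
        )
        acc_t = np.log(rng.random(C)) < (
            ll_t.sum(axis=1) - ll.sum(axis=1) + dlp_mu
        )
        eta = np.where(acc_t[:, None, None], eta_t, eta)
        ll = np.where(acc_t[:, None], ll_t, ll)
        mu = np.where(acc_t[:, None], mu_t, mu)
        if it <= config.burn_in:
            trans_step *= np.exp(config.adapt_rate * (acc_t - 0.25))
            trans_step = np.clip(trans_step, 1e-3, 10.0)
            dmu = mu - mu_mean
            mu_mean += dmu / it
            mu_m2 += np.einsum("ck,cl->ckl", dmu, mu - mu_mean)
            if it >= 500 and it % 200 == 0:
                cov = mu_m2 / (it - 1) + 1e-8 * np.eye(K)
                trans_chol = np.linalg.cholesky(cov)

        # --- funnel moves, alternating parameterizations per iteration:
        # centered: rescale deviations only (Sigma fixed), Jacobian n*sum(s);
        # non-centered (ASIS): rescale deviations AND Sigma together so the
        # standardized residuals stay fixed — the deviation-prior and
        # Jacobian terms cancel, leaving likelihood + Sigma-prior terms.
        # centered form
        s = scale_step[:, None] * rng.standard_normal((C, K))
        dev = eta - mu[:, None, :]
        dev_s = dev * np.exp(s)[:, None, :]
        eta_s = mu[:, None, :] + dev_s
        ll_s = _log_multinomial(eta_s, counts, restriction)
        lp_dev = -0.5 * np.einsum("cnk,ckl,cnl->c", dev, sigma_inv, dev)
        lp_dev_s = -0.5 * np.einsum("cnk,ckl,cnl->c", dev_s, sigma_inv, dev_s)
        acc_s = np.log(rng.random(C)) < (
            ll_s.sum(axis=1) - ll.sum(axis=1) + lp_dev_s - lp_dev
            + n * s.sum(axis=1)
        )
        eta = np.where(acc_s[:, None, None], eta_s, eta)
        ll = np.where(acc_s[:, None], ll_s, ll)
        if it <= config.burn_in:
            scale_step *= np.exp(config.adapt_rate * (acc_s - 0.25))
            scale_step = np.clip(scale_step, 1e-4, 1.0)
        # non-centered form
        s = nc_scale_step[:, None] * rng.standard_normal((C, K))
        dev_s = (eta - mu[:, None, :]) * np.exp(s)[:, None, :]
        eta_s = mu[:, None, :] + dev_s
        ll_s = _log_multinomial(eta_s, counts, restriction)
        inv_diag = np.diagonal(sigma_inv, axis1=1, axis2=2)
        d_iw = (
            -pri.sigma_df * s.sum(axis=1)
            - 0.5 * pri.sigma_scale
            * np.sum(inv_diag * (np.exp(-2 * s) - 1.0), axis=1)
        )
        acc_s = np.log(rng.random(C)) < (
            ll_s.sum(axis=1) - ll.sum(axis=1) + d_iw
        )
        eta = np.where(acc_s[:, None, None], eta_s, eta)
        ll = np.where(acc_s[:, None], ll_s, ll)
        scl = np.where(acc_s[:, None], np.exp(-s), 1.0)
        sigma_inv = sigma_inv * scl[:, :, None] * scl[:, None, :]
        if it <= config.burn_in:
            nc_scale_step *= np.exp(config.adapt_rate * (acc_s - 0.25))
            nc_scale_step = np.clip(nc_scale_step, 1e-4, 1.0)

        # --- Gibbs updates of mu and Sigma, batched over chains
        eta_sum = eta.sum(axis=1)
        prec = n * sigma_inv + prior_prec_diag * np.eye(K)
        chol = np.linalg.cholesky(prec)
        rhs = np.einsum("ckl,cl->ck", sigma_inv, eta_sum)
        m = np.linalg.solve(prec, rhs[..., None])[..., 0]
        z = rng.standard_normal((C, K, 1))
        mu = m + np.linalg.solve(np.transpose(chol, (0, 2, 1)), z)[..., 0]
        dev = eta - mu[:, None, :]
        S_post = S0 + np.einsum("cnk,cnl->ckl", dev, dev)
        L = np.linalg.cholesky(np.linalg.inv(S_post))
        A = np.zeros((C, K, K))
        di = np.arange(K)
        A[:, di, di] = np.sqrt(
            rng.chisquare(nu_post - di, size=(C, K))
        )
        ti, tj = np.tril_indices(K, -1)
        A[:, ti, tj] = rng.standard_normal((C, ti.size))
        LA = L @ A
        sigma_inv = LA @ np.transpose(LA, (0, 2, 1))

        if it > config.burn_in and (it - config.burn_in) % config.thin == 0:
            mu_out[:, r_idx] = mu
            sigma_out[:, r_idx] = np.linalg.inv(sigma_inv)
            theta_out[:, r_idx] = ndtr(eta)
            r_idx += 1

    return PosteriorSample(
        mu=mu_out,
        sigma=sigma_out,
        theta=theta_out,
        config=config,
        accept_rate=accepted / proposed if proposed else float("nan"),
    )


def summarize_posterior(post: PosteriorSample):
    """Group-level Phi(mu) estimates with central 95% credibility intervals.

    Returns a DataFrame with one row per parameter: posterior median (the
    reported estimate), posterior mean, and the 2.5%/97.5% quantiles.
    """
    import pandas as pd

    if post.n_draws == 0:
        raise MPTDomainError("empty posterior")
    draws = post.group_level_draws()
    rows = []
    for name in post.param_names:
        x = draws[name]
        lo, hi = np.percentile(x, [2.5, 97.5])
        display = "D_U=D_N" if (
            name == "D_U" and post.config.restriction == "D_N=D_U"
        ) else name
        rows.append(
            {
                "parameter": display,
                "estimate": float(np.median(x)),
                "mean": float(x.mean()),
                "bci_low": float(lo),
                "bci_high": float(hi),
            }
        )
    return pd.DataFrame(rows)


def _split_chains(x: np.ndarray) -> np.ndarray:
    """Split each chain in half: (C, N) -> (2C, N//2)."""
    C, N = x.shape
    half = N // 2
    return np.concatenate([x[:, :half], x[:, N - half:]], axis=0)


def _rhat_scalar(x: np.ndarray) -> float:
    """Split-Rhat for one scalar quantity given (chains, draws)."""
    x = _split_chains(np.asarray(x, float))
    m, n = x.shape
    chain_means = x.mean(axis=1)
    chain_vars = x.var(axis=1, ddof=1)
    W = chain_vars.mean()
    B_over_n = chain_means.var(ddof=1)
    scale = max(1.0, float(np.mean(x**2)))
    if W <= 1e-24 * scale:
        # constant chains: Rhat 1 by convention when the chains agree
        return 1.0 if B_over_n <= 1e-24 * scale else float("inf")
    var_hat = (n - 1) / n * W + B_over_n
    # floor at 1: the ratio dips below 1 only through finite-sample noise
    return float(max(np.sqrt(var_hat / W), 1.0))


def _ess_scalar(x: np.ndarray) -> float:
    """Effective sample size via Geyer's initial positive sequence."""
    x = np.asarray(x, float)
    m, n = x.shape
    if n < 4:
        return float(m * n)
    W = x.var(axis=1, ddof=1).mean()
    if W == 0:
        return float(m * n)
    acov = np.zeros(n)
    for c in range(m):
        xc = x[c] - x[c].mean()
        f = np.fft.rfft(xc, 2 * n)
        acov += np.fft.irfft(f * np.conj(f), 2 * n)[:n] / n
    acov /= m
    rho = acov / acov[0]
    # sum consecutive pairs until the pair sum goes non-positive
    tau = 1.0
    t = 1
    while t + 1 < n:
        pair = rho[t] + rho[t + 1]
        if pair <= 0:
            break
        tau += 2 * pair
        t += 2
    return float(m * n / tau)


def _monitored(post: PosteriorSample) -> dict[str, np.ndarray]:
    """Group-level quantities monitored for convergence: mu and Sigma diagonal."""
    out: dict[str, np.ndarray] = {}
    for i, name in enumerate(post.param_names):
        out[f"mu[{name}]"] = post.mu[:, :, i]
        out[f"sigma[{name}]"] = post.sigma[:, :, i, i]
    return out


def gelman_rubin(post: PosteriorSample) -> FitDiagnostics:
    """Split-Rhat and effective sample size for the monitored quantities.

    Rank normalization is off: the plain between/within variance ratio is
    reported.  Individual-level parameters are not monitored.
    """
    if post.n_chains < 2:
        raise MPTDomainError(
            "Rhat requires >= 2 chains; rerun fit_hierarchical with chains >= 2"
        )
    if post.n_draws < 10:
        raise MPTDomainError("Rhat requires >= 10 retained draws per chain")
    mon = _monitored(post)
    rhat = {name: _rhat_scalar(x) for name, x in mon.items()}
    ess = {name: _ess_scalar(x) for name, x in mon.items()}
    return FitDiagnostics(rhat=rhat, ess=ess)


def _t1_stat(mean_counts: np.ndarray, mean_expected: np.ndarray) -> float:
    """Chi-square-type distance between mean observed and expected tables."""
    e = np.maximum(mean_expected, 1e-12)
    return float(np.sum((mean_counts - mean_expected) ** 2 / e))


def _model_cov(m: np.ndarray, P: np.ndarray, n_items: np.ndarray) -> np.ndarray:
    """Model-implied across-participant covariance of the 9 cell counts.

    Sum of (a) the covariance of expected counts across participants and
    (b) the mean within-participant multinomial covariance (block diagonal
    over the three independent trial-type rows).
    """
    n, _, _ = P.shape
    flat_m = m.reshape(n, 9)
    cov_between = np.cov(flat_m, rowvar=False, ddof=1)
    within = np.zeros((9, 9))
    for t in range(3):
        sl = slice(3 * t, 3 * t + 3)
        p = P[:, t, :]  # (n, 3)
        nt = n_items[:, t][:, None, None]
        blocks = nt * (
            np.einsum("ij,jk->ijk", p, np.eye(3))
            - np.einsum("ij,ik->ijk", p, p)
        )
        within[sl, sl] = blocks.mean(axis=0)
    return cov_between + within


def posterior_predictive_check(
    post: PosteriorSample,
    data: Sequence[FrequencyTable],
    n_draws: int = 500,
    seed: int = 0,
) -> FitDiagnostics:
    """T1/T2 posterior-predictive p-values against the fitted data.

    For each sampled posterior draw, a replicate dataset is simulated from
    that draw's individual parameters, and the T1 (mean-frequency) and T2
    (count-covariance) discrepancies are computed for both the observed and
    the replicate data.  The p-value is the fraction of draws whose
    replicate discrepancy is at least the observed one; well-fitting models
    give p-values away from 0.
    """
    counts = _stack_counts(data)
    n = counts.shape[0]
    n_items = counts.sum(axis=2).astype(int)  # (n, 3)
    restriction = post.config.restriction
    rng = np.random.default_rng(seed)

    total = post.n_chains * post.n_draws
    take = min(n_draws, total)
    idx = rng.choice(total, size=take, replace=False)
    theta_flat = post.theta.reshape(total, n, K)

    obs_flat = counts.reshape(n, 9)
    cov_obs = np.cov(obs_flat, rowvar=False, ddof=1) if n >= 2 else None
    mean_obs = counts.mean(axis=0)

    t1_exceed = 0
    t2_exceed = 0
    for j in idx:
        P = _free_to_probs(theta_flat[j], restriction)  # (n, 3, 3)
        m = n_items[..., None] * P  # expected counts
        mean_exp = m.mean(axis=0)
        rep = np.empty_like(counts)
        for t in range(3):
            # vectorize multinomial over participants with equal totals where possible
            for i in range(n):
                rep[i, t] = rng.multinomial(n_items[i, t], P[i, t])
        t1_obs = _t1_stat(mean_obs, mean_exp)
        t1_rep = _t1_stat(rep.mean(axis=0), mean_exp)
        if t1_rep >= t1_obs:
            t1_exceed += 1
        if cov_obs is not None:
            cov_model = _model_cov(m, P, n_items)
            t2_obs = np.linalg.norm(cov_obs - cov_model)
            cov_rep = np.cov(rep.reshape(n, 9), rowvar=False, ddof=1)
            t2_rep = np.linalg.norm(cov_rep - cov_model)
            if t2_rep >= t2_obs:
                t2_exceed += 1
    t1_p = t1_exceed / take
    t2_p = t2_exceed / take if cov_obs is not None else None
    return FitDiagnostics(t1_p=t1_p, t2_p=t2_p)


_ALLOWED_EXPR_CHARS = set("+-*/(). 0123456789_")


def _eval_expression(expr: str, draws: dict[str, np.ndarray]) -> np.ndarray:
    """Evaluate an arithmetic expression over named group-level draws."""
    tokens = expr
    for name in draws:
        tokens = tokens.replace(name, "")
    if not set(tokens) <= _ALLOWED_EXPR_CHARS:
        raise MPTDomainError(f"disallowed characters in expression {expr!r}")
    try:
        result = eval(expr, {"__builtins__": {}}, dict(draws))  # noqa: S307
    except Exception as exc:
        raise MPTDomainError(f"cannot evaluate expression {expr!r}: {exc}") from exc
    arr = np.asarray(result, float)
    if arr.ndim != 1:
        raise MPTDomainError(f"expression {expr!r} did not reduce to draws")
    return arr


def parameter_contrast(
    post_a: PosteriorSample,
    expression_a: str,
    post_b: PosteriorSample | None = None,
    expression_b: str | None = None,
    label: str | None = None,
    seed: int = 0,
) -> ParameterContrast:
    """Posterior of a contrast over group-level Phi(mu) components.

    Within one posterior, ``expression_a`` (e.g. ``"d_U - d_E"``) is
    evaluated over the draws.  Between two independent groups, the two
    expressions are evaluated on their own posteriors and differenced with
    draws paired by index; if the draw counts differ, the longer sequence is
    subsampled (seeded) to the shorter.
    """
    a = _eval_expression(expression_a, post_a.group_level_draws())
    if post_b is not None:
        expression_b = expression_b or expression_a
        b = _eval_expression(expression_b, post_b.group_level_draws())
        if a.size != b.size:
            rng = np.random.default_rng(seed)
            if a.size > b.size:
                a = a[rng.choice(a.size, size=b.size, replace=False)]
            else:
                b = b[rng.choice(b.size, size=a.size, replace=False)]
        contrast = a - b
        default_label = f"({expression_a}) - ({expression_b})"
    else:
        contrast = a
        default_label = expression_a
    lo, hi = np.percentile(contrast, [2.5, 97.5])
    return ParameterContrast(
        label=label or default_label,
        mean=float(contrast.mean()),
        median=float(np.median(contrast)),
        bci=(float(lo), float(hi)),
    )
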