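"""Gibbs samplers for hierarchical whole-genome regression models.

All four models share the linear predictor y_j = mu + sum_k x_jk beta_k delta_k
+ e_j and differ in the prior on the marker effects:

* Bayes A       : delta_k = 1; beta_k ~ N(0, sigma_ak^2), one variance per
                  marker, sigma_ak^2 ~ scaled-inv-chi2(nu, S).
* Bayes B       : delta_k ~ Bernoulli(pi) with pi fixed; per-marker variances.
* Bayes Cpi     : delta_k ~ Bernoulli(pi) with pi ~ Beta(a, b); one common
                  effect variance sigma_a^2 for the included markers.
* Bayesian LASSO: delta_k = 1; beta_k | tau_k^2 ~ N(0, sigma_e^2 tau_k^2),
                  tau_k^2 ~ Exp(lambda^2/2) (Park & Casella hierarchy); the
                  full conditional of 1/tau_k^2 is inverse-Gaussian and
                  lambda^2 gets a Gamma hyperprior updated by Gibbs.

Indicator updates for Bayes B / Cpi use the collapsed (beta_k integrated out)
likelihood-ratio draw, which avoids the reducibility of naive joint sampling
at beta_k = 0.  Samplers are deterministic given the config seed.  Priors and
chain lengths are not canonical for these models; the defaults here are
explicit package choices (see McmcConfig).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import GenotypeMatrix, PhenotypeVector
from .linear import _as_matrix, _as_vector


@dataclass
class McmcConfig:
    """Chain and prior settings shared by the four samplers.

    nu / scale parameterize the scaled-inverse-chi-square prior on marker
    variances; scale=None derives S so that the prior mean marker variance
    equals 0.5 Var(y) / sum 2 p_k (1 - p_k) (a heritability-0.5 heuristic).
    """

    n_iter: int = 10_000
    burn_in: int = 2_000
    thin: int = 5
    seed: int = 0
    nu: float = 4.2
    scale: float | None = None
    pi_fixed: float = 0.05
    pi_prior: tuple[float, float] = (1.0, 1.0)
    lambda_blasso: float | None = None  # None -> Gamma(0.1, 0.1) hyperprior
    nu_e: float = 4.0

    def __post_init__(self) -> None:
        if self.burn_in >= self.n_iter:
            raise ValueError("burn_in must be smaller than n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if not 0 < self.pi_fixed <= 1:
            raise ValueError("pi_fixed must lie in (0, 1]")
        if self.nu <= 2:
            raise ValueError("nu must exceed 2 for a finite prior mean")


@dataclass
class PosteriorSummary:
    mu_mean: float
    beta_mean: np.ndarray
    inclusion_prob: np.ndarray | None = None
    pi_mean: float | None = None
    variance_traces: dict = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)
    x_means: np.ndarray | None = None

    def predict(self, X) -> np.ndarray:
        X = _as_matrix(X)
        if self.x_means is not None:
            X = X - self.x_means
        return self.mu_mean + X @ self.beta_mean


def effective_sample_size(x: np.ndarray) -> float:
    """Initial-positive-sequence ESS estimate for a scalar chain."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 10 or np.ptp(x) == 0:
        return float(n)
    xc = x - x.mean()
    acf = np.correlate(xc, xc, mode="full")[n - 1 :] / (np.arange(n, 0, -1))
    acf = acf / acf[0]
    s = 0.0
    for t in range(1, n // 2):
        if acf[t] <= 0:
            break
        s += acf[t]
    return float(n / (1.0 + 2.0 * s))


def geweke_z(x: np.ndarray, first: float = 0.1, last: float = 0.5) -> float:
    """Geweke convergence z-score comparing early vs late chain segments."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    a = x[: max(int(first * n), 2)]
    b = x[-max(int(last * n), 2) :]
    va = a.var(ddof=1) / len(a)
    vb = b.var(ddof=1) / len(b)
    if va + vb == 0:
        return 0.0
    return float((a.mean() - b.mean()) / np.sqrt(va + vb))


def _prepare(g, y, cfg):
    X = _as_matrix(g)
    y = _as_vector(y)
    if X.shape[0] != len(y):
        raise ValueError("genotypes and phenotype have mismatched sample counts")
    if np.ptp(y) == 0:
        raise ValueError("phenotype is constant")
    xbar = X.mean(axis=0)
    Xc = np.asfortranarray(X - xbar)
    xtx = np.einsum("ij,ij->j", Xc, Xc)
    var_y = float(np.var(y))
    if cfg.scale is None:
        p_freq = np.clip(X.mean(axis=0) / 2.0, 1e-6, 1 - 1e-6)
        denom = float(np.sum(2 * p_freq * (1 - p_freq)))
        prior_mean_var = 0.5 * var_y / max(denom, 1e-12)
        S = prior_mean_var * (cfg.nu - 2.0) / cfg.nu
    else:
        S = cfg.scale
    S_e = 0.5 * var_y * (cfg.nu_e - 2.0) / cfg.nu_e  # prior mean sigma_e2 = Var(y)/2
    return X, y, xbar, Xc, xtx, var_y, S, S_e


def _check_finite(val, it):
    if not np.isfinite(val):
        raise RuntimeError(f"sampler diverged (non-finite variance) at iteration {it}")


def _run_gibbs(g, y, cfg: McmcConfig, model: str) -> PosteriorSummary:
    X, y, xbar, Xc, xtx, var_y, S, S_e = _prepare(g, y, cfg)
    rng = np.random.default_rng(cfg.seed)
    n, p = Xc.shape
    nu, nu_e = cfg.nu, cfg.nu_e

    beta = np.zeros(p)
    delta = np.ones(p, dtype=bool)
    sig_k = np.full(p, nu * S / (nu - 2.0))  # Bayes A/B per-marker variances
    sig_a = nu * S / (nu - 2.0)  # Bayes Cpi common variance
    tau2 = np.ones(p)  # Blasso local scales
    lam2 = cfg.lambda_blasso**2 if cfg.lambda_blasso is not None else 1.0
    lam2_fixed = cfg.lambda_blasso is not None
    r_hyper, d_hyper = 0.1, 0.1  # Gamma hyperprior on lambda^2
    pi = cfg.pi_fixed
    a_pi, b_pi = cfg.pi_prior
    if model == "bayes_cpi":
        pi = a_pi / (a_pi + b_pi)
    mu = float(y.mean())
    sig_e = max(var_y / 2.0, 1e-12)
    e = y - mu - Xc @ beta  # residual (beta = 0 initially)

    n_keep = 0
    beta_sum = np.zeros(p)
    incl_sum = np.zeros(p)
    mu_sum = 0.0
    pi_sum = 0.0
    sig_e_trace: list[float] = []
    sig_a_trace: list[float] = []
    pi_trace: list[float] = []
    tau2_min = np.inf

    for it in range(cfg.n_iter):
        # --- marker effects ---
        if model in ("bayes_a", "blasso"):
            prior_var = sig_k if model == "bayes_a" else sig_e * tau2
            for k in range(p):
                xk = Xc[:, k]
                old = beta[k]
                rhs = xk @ e + xtx[k] * old
                prec = xtx[k] / sig_e + 1.0 / prior_var[k]
                mean = rhs / sig_e / prec
                new = mean + rng.standard_normal() / np.sqrt(prec)
                beta[k] = new
                e += xk * (old - new)
        else:  # bayes_b / bayes_cpi with collapsed indicator draws
            pi_c = min(max(pi, 1e-15), 1 - 1e-15)
            log_odds_prior = np.log(pi_c) - np.log1p(-pi_c)
            for k in range(p):
                xk = Xc[:, k]
                old_contrib = beta[k] if delta[k] else 0.0
                rhs = xk @ e + xtx[k] * old_contrib  # x_k' r_k
                v_k = sig_k[k] if model == "bayes_b" else sig_a
                q = xtx[k] * v_k / sig_e
                log_bf = -0.5 * np.log1p(q) + 0.5 * rhs**2 * v_k / (
                    sig_e * (sig_e + v_k * xtx[k])
                )
                z = np.clip(log_odds_prior + log_bf, -700.0, 700.0)
                p_incl = 1.0 / (1.0 + np.exp(-z))
                inc = rng.random() < p_incl
                if inc:
                    prec = xtx[k] / sig_e + 1.0 / v_k
                    mean = rhs / sig_e / prec
                    new = mean + rng.standard_normal() / np.sqrt(prec)
                else:
                    new = 0.0
                delta[k] = inc
                beta[k] = new
                e += xk * (old_contrib - new)

        # --- marker-variance hyperparameters ---
        if model == "bayes_a":
            sig_k = (nu * S + beta**2) / rng.chisquare(nu + 1.0, size=p)
        elif model == "bayes_b":
            chi_in = rng.chisquare(nu + 1.0, size=p)
            chi_out = rng.chisquare(nu, size=p)
            sig_k = np.where(
                delta, (nu * S + beta**2) / chi_in, nu * S / chi_out
            )
        elif model == "bayes_cpi":
            m_in = int(delta.sum())
            sig_a = (nu * S + float(beta[delta] @ beta[delta])) / rng.chisquare(
                nu + m_in
            )
            pi = rng.beta(a_pi + m_in, b_pi + p - m_in)
            pi = min(max(pi, 1e-12), 1 - 1e-12)
        else:  # blasso
            absb = np.maximum(np.abs(beta), 1e-10)
            inv_tau2 = rng.wald(np.sqrt(lam2 * sig_e) / absb, lam2)
            tau2 = 1.0 / np.maximum(inv_tau2, 1e-12)
            if not lam2_fixed:
                lam2 = rng.gamma(r_hyper + p, 1.0 / (d_hyper + tau2.sum() / 2.0))
            tau2_min = min(tau2_min, float(tau2.min()))

        # --- intercept ---
        old_mu = mu
        mu = (e + mu).mean() + rng.standard_normal() * np.sqrt(sig_e / n)
        e += old_mu - mu

        # --- residual variance ---
        if model == "blasso":
            sse = float(e @ e) + float(beta**2 @ (1.0 / tau2))
            dof = n + p + nu_e
        else:
            sse = float(e @ e)
            dof = n + nu_e
        sig_e = (sse + nu_e * S_e) / rng.chisquare(dof)
        _check_finite(sig_e, it)

        # --- retain ---
        if it >= cfg.burn_in and (it - cfg.burn_in) % cfg.thin == 0:
            n_keep += 1
            beta_sum += np.where(delta, beta, 0.0)
            incl_sum += delta
            mu_sum += mu
            pi_sum += pi
            sig_e_trace.append(sig_e)
            sig_a_trace.append(sig_a if model == "bayes_cpi" else float(np.mean(sig_k)))
            if model == "bayes_cpi":
                pi_trace.append(pi)

    sig_e_arr = np.array(sig_e_trace)
    diagnostics = {
        "ess_sigma_e2": effective_sample_size(sig_e_arr),
        "geweke_z_sigma_e2": geweke_z(sig_e_arr),
        "n_retained": n_keep,
    }
    if model == "blasso":
        diagnostics["tau2_min"] = tau2_min
    summary = PosteriorSummary(
        mu_mean=mu_sum / n_keep,
        beta_mean=beta_sum / n_keep,
        inclusion_prob=(incl_sum / n_keep) if model in ("bayes_b", "bayes_cpi") else None,
        pi_mean=(pi_sum / n_keep) if model == "bayes_cpi" else None,
        variance_traces={
            "sigma_e2": sig_e_arr,
            "sigma_a2": np.array(sig_a_trace),
            **({"pi": np.array(pi_trace)} if pi_trace else {}),
        },
        diagnostics=diagnostics,
        x_means=xbar,
    )
    return summary


def fit_bayes_a(g, y, cfg: McmcConfig | None = None) -> PosteriorSummary:
    return _run_gibbs(g, y, cfg or McmcConfig(), "bayes_a")


def fit_bayes_b(g, y, cfg: McmcConfig | None = None) -> PosteriorSummary:
    return _run_gibbs(g, y, cfg or McmcConfig(), "bayes_b")


def fit_bayes_cpi(g, y, cfg: McmcConfig | None = None) -> PosteriorSummary:
    return _run_gibbs(g, y, cfg or McmcConfig(), "bayes_cpi")


def fit_bayesian_lasso(g, y, cfg: McmcConfig | None = None) -> PosteriorSummary:
    return _run_gibbs(g, y, cfg or McmcConfig(), "blasso")


# ---------------------------------------------------------------------------
# sklearn-style wrappers
# ---------------------------------------------------------------------------

from sklearn.base import BaseEstimator, RegressorMixin  # noqa: E402


class _BayesRegressor(BaseEstimator, RegressorMixin):
    _model: str = ""

    def __init__(
        self,
        n_iter: int = 10_000,
        burn_in: int = 2_000,
        thin: int = 5,
        seed: int = 0,
        nu: float = 4.2,
        scale: float | None = None,
        pi_fixed: float = 0.05,
        pi_prior: tuple[float, float] = (1.0, 1.0),
        lambda_blasso: float | None = None,
    ):
        self.n_iter = n_iter
        self.burn_in = burn_in
        self.thin = thin
        self.seed = seed
        self.nu = nu
        self.scale = scale
        self.pi_fixed = pi_fixed
        self.pi_prior = pi_prior
        self.lambda_blasso = lambda_blasso

    def _config(self) -> McmcConfig:
        return McmcConfig(
            n_iter=self.n_iter,
            burn_in=self.burn_in,
            thin=self.thin,
            seed=self.seed,
            nu=self.nu,
            scale=self.scale,
            pi_fixed=self.pi_fixed,
            pi_prior=self.pi_prior,
            lambda_blasso=self.lambda_blasso,
        )

    def fit(self, X, y):
        self.posterior_ = _run_gibbs(X, y, self._config(), self._model)
        return self

    def predict(self, X):
        return self.posterior_.predict(X)


class BayesA(_BayesRegressor):
    """Per-marker effect variances, all markers included (delta_k = 1)."""

    _model = "bayes_a"


class BayesB(_BayesRegressor):
    """Per-marker variances with fixed inclusion probability pi."""

    _model = "bayes_b"


class BayesCPi(_BayesRegressor):
    """Common effect variance; inclusion probability pi sampled (Beta prior)."""

    _model = "bayes_cpi"


class BayesianLasso(_BayesRegressor):
    """Double-exponential shrinkage via the Park-Casella Gibbs hierarchy."""

    _model = "blasso"
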