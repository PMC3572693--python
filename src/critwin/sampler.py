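"""Markov chain Monte Carlo for the temporally smoothed probit model.

The outcome model is

    Y_i | p_i ~ Bernoulli(p_i),
    Phi^{-1}(p_i) = x_i' beta + sum_{j=1}^{ga_i} z_ij theta_j,

with weekly-effect prior theta ~ MVN(0, sigma2 * Sigma(phi)),
Sigma(phi)_jk = exp(-phi |j - k|) (exponential temporal correlation),
independent N(0, v0) priors on beta, phi ~ Uniform(0.0001, 3) and
sigma2 ~ Inverse-Gamma(3, 2).

Fitting uses latent-variable augmentation: w_i ~ N(eta_i, 1) truncated by
the outcome sign makes every conditional conjugate except phi, which gets a
random-walk Metropolis step on a logit-transformed scale. Three variants
share the engine:

* ``weekly_structured`` (model 1): weekly effects with the smoothing prior;
* ``trimester`` (model 2): three trimester-average effects, diffuse prior;
* ``weekly_naive`` (model 3): weekly effects with diffuse independent
  priors, multicollinearity unaddressed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.special import log_ndtr, ndtr, ndtri_exp

from .design import MODEL_ALIASES


@dataclass
class PriorSpec:
    """Prior hyperparameters; the defaults are the model's standard choices."""
    beta_variance: float = 1000.0
    phi_lower: float = 1e-4
    phi_upper: float = 3.0
    sigma2_shape: float = 3.0
    sigma2_scale: float = 2.0

    def __post_init__(self):
        if not self.phi_lower < self.phi_upper:
            raise ValueError("phi_lower must be below phi_upper")
        if min(self.sigma2_shape, self.sigma2_scale, self.beta_variance) <= 0:
            raise ValueError("variance hyperparameters must be positive")


@dataclass
class McmcConfig:
    n_burnin: int = 50_000
    n_samples: int = 50_000
    thin: int = 1
    seed: int = 0
    phi_proposal_sd: float = 0.6
    adapt: bool = True

    def __post_init__(self):
        if min(self.n_burnin, self.n_samples, self.thin) < 1:
            raise ValueError("iteration counts and thin must be positive")

    @classmethod
    def test_profile(cls, seed: int = 0, **kw) -> "McmcConfig":
        """Desk-scale profile: 2,000 burn-in + 2,000 kept iterations."""
        return cls(n_burnin=2_000, n_samples=2_000, seed=seed, **kw)


@dataclass
class PosteriorDraws:
    """Thinned post-burn-in draws of the parameter vector."""
    beta: np.ndarray                 # (draws, p)
    theta: np.ndarray                # (draws, g)
    sigma2_theta: np.ndarray | None  # (draws,) for the structured variant
    phi: np.ndarray | None
    phi_acceptance_rate: float | None
    model_tag: str
    beta_labels: list[str] = field(default_factory=list)
    theta_labels: list[str] = field(default_factory=list)
    week_ids: np.ndarray | None = None
    mc_errors: dict[str, float] = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return self.beta.shape[0]


def corr_matrix(phi: float, g: int) -> np.ndarray:
    """Exponential temporal correlation exp(-phi |i - j|), g x g."""
    if phi <= 0:
        raise ValueError("phi must be positive")
    if g < 1:
        raise ValueError("g must be at least 1")
    idx = np.arange(g)
    return np.exp(-phi * np.abs(idx[:, None] - idx[None, :]))


def linear_predictor(design: np.ndarray, exposure_block: np.ndarray | None,
                     beta: np.ndarray, theta: np.ndarray | None,
                     probability: bool = False) -> np.ndarray:
    """eta_i = x_i' beta + sum_j z_ij theta_j (optionally Phi(eta))."""
    eta = np.asarray(design, dtype=float) @ np.asarray(beta, dtype=float)
    if exposure_block is not None and theta is not None and np.size(theta):
        eta = eta + np.asarray(exposure_block, dtype=float) @ np.asarray(theta, dtype=float)
    if not np.all(np.isfinite(eta)):
        raise FloatingPointError("non-finite linear predictor")
    return ndtr(eta) if probability else eta


def sample_latents(y: np.ndarray, eta: np.ndarray,
                   rng: np.random.Generator) -> np.ndarray:
    """Exact truncated-normal latent draws (inverse CDF in log space).

    w_i ~ N(eta_i, 1) truncated to (0, inf) if y_i = 1, to (-inf, 0] if
    y_i = 0. Working with log_ndtr/ndtri_exp keeps the draws finite even
    when the truncation point sits many SDs into the tail.
    """
    y = np.asarray(y)
    eta = np.asarray(eta, dtype=float)
    u = np.clip(rng.random(eta.shape), 1e-300, 1.0 - 1e-16)
    logu = np.log(u)
    w = np.empty_like(eta)
    neg = y == 0
    if neg.any():
        w[neg] = eta[neg] + ndtri_exp(logu[neg] + log_ndtr(-eta[neg]))
    pos = ~neg
    if pos.any():
        # reflection of the lower-truncated case
        w[pos] = eta[pos] - ndtri_exp(logu[pos] + log_ndtr(eta[pos]))
    return w


def _mvn_from_precision(precision: np.ndarray, b: np.ndarray,
                        rng: np.random.Generator) -> np.ndarray:
    """Draw from MVN with the given precision and mean = precision^{-1} b."""
    U, low = cho_factor(precision, lower=False)
    mean = cho_solve((U, low), b)
    z = rng.standard_normal(len(b))
    return mean + solve_triangular(U, z, lower=False)


def update_beta(latents: np.ndarray, design: np.ndarray,
                exposure_block: np.ndarray | None, theta: np.ndarray | None,
                prior: PriorSpec, rng: np.random.Generator,
                xtx: np.ndarray | None = None) -> np.ndarray:
    """Conjugate normal full-conditional draw for beta."""
    X = np.asarray(design, dtype=float)
    p = X.shape[1]
    resid = np.asarray(latents, dtype=float)
    if exposure_block is not None and theta is not None and np.size(theta):
        resid = resid - exposure_block @ theta
    if xtx is None:
        xtx = X.T @ X
    precision = xtx + np.eye(p) / prior.beta_variance
    return _mvn_from_precision(precision, X.T @ resid, rng)


def update_theta(latents: np.ndarray, design: np.ndarray,
                 exposure_block: np.ndarray, beta: np.ndarray,
                 sigma2: float, phi: float, prior: PriorSpec,
                 rng: np.random.Generator, structured: bool = True,
                 ztz: np.ndarray | None = None) -> np.ndarray:
    """Full-conditional draw for the weekly (or trimester) effects.

    Structured: prior precision (sigma2 * Sigma(phi))^{-1}; diffuse
    (naive/trimester variants): I / beta_variance.
    """
    Z = np.asarray(exposure_block, dtype=float)
    g = Z.shape[1]
    if ztz is None:
        ztz = Z.T @ Z
    if structured:
        Sigma = corr_matrix(phi, g)
        prior_prec = cho_solve(cho_factor(Sigma), np.eye(g)) / sigma2
        prior_prec = 0.5 * (prior_prec + prior_prec.T)
    else:
        prior_prec = np.eye(g) / prior.beta_variance
    precision = ztz + prior_prec
    b = Z.T @ (latents - design @ beta)
    return _mvn_from_precision(precision, b, rng)


def update_sigma2(theta: np.ndarray, phi: float, prior: PriorSpec,
                  rng: np.random.Generator, size=None):
    """Conjugate Inverse-Gamma(shape + g/2, scale + theta' Sigma^{-1} theta / 2)."""
    theta = np.asarray(theta, dtype=float)
    g = theta.size
    if g:
        Sigma = corr_matrix(phi, g)
        quad = float(theta @ cho_solve(cho_factor(Sigma), theta))
    else:
        quad = 0.0
    shape = prior.sigma2_shape + g / 2.0
    scale = prior.sigma2_scale + quad / 2.0
    return scale / rng.gamma(shape, 1.0, size=size)


def _log_theta_prior(theta: np.ndarray, sigma2: float, phi: float) -> float:
    """log MVN(theta; 0, sigma2 * Sigma(phi)) up to an additive constant."""
    g = theta.size
    Sigma = corr_matrix(phi, g)
    U, low = cho_factor(Sigma)
    logdet = 2.0 * np.sum(np.log(np.diag(U)))
    quad = float(theta @ cho_solve((U, low), theta))
    return -0.5 * (g * np.log(sigma2) + logdet + quad / sigma2)


def update_phi(theta: np.ndarray, sigma2: float, phi_current: float,
               prior: PriorSpec, proposal_sd: float,
               rng: np.random.Generator) -> tuple[float, bool]:
    """Random-walk Metropolis on logit((phi - l) / (u - phi)).

    The Jacobian of the transform keeps the chain targeting the
    Uniform(l, u)-prior posterior on the phi scale; draws never leave (l, u).
    """
    lo, hi = prior.phi_lower, prior.phi_upper
    if not lo < phi_current < hi:
        raise ValueError("phi_current outside the prior support")
    psi = np.log((phi_current - lo) / (hi - phi_current))
    psi_new = psi + proposal_sd * rng.standard_normal()
    phi_new = lo + (hi - lo) / (1.0 + np.exp(-psi_new))
    # guard against round-off pinning to the boundary
    phi_new = min(max(phi_new, lo * (1 + 1e-12) + 1e-300), hi * (1 - 1e-12))

    def log_target(phi, psi_val):
        log_jac = np.log(hi - lo) + psi_val - 2.0 * np.log1p(np.exp(psi_val)) \
            if psi_val < 30 else np.log(hi - lo) - psi_val
        return _log_theta_prior(theta, sigma2, phi) + log_jac

    delta = log_target(phi_new, psi_new) - log_target(phi_current, psi)
    if np.log(rng.random()) < delta:
        return float(phi_new), True
    return float(phi_current), False


def run_mcmc(y: np.ndarray, design: np.ndarray, exposure_block: np.ndarray,
             prior: PriorSpec, config: McmcConfig,
             model="weekly_structured",
             beta_labels: list[str] | None = None,
             theta_labels: list[str] | None = None,
             week_ids: np.ndarray | None = None) -> PosteriorDraws:
    """Systematic-scan Gibbs / Metropolis-within-Gibbs fit of one variant.

    Scan order: latents -> beta -> theta -> (sigma2 -> phi for the
    structured variant). The phi proposal SD adapts toward a 0.2-0.5
    acceptance rate during burn-in and is frozen afterwards. Returns thinned
    post-burn-in draws plus the phi acceptance rate and batch-means
    Monte-Carlo standard errors of the posterior means.
    """
    variant = MODEL_ALIASES.get(model)
    if variant is None:
        raise ValueError(f"unknown model variant {model!r}")
    structured = variant == "weekly_structured"

    y = np.asarray(y, dtype=int)
    X = np.ascontiguousarray(design, dtype=float)
    Z = np.ascontiguousarray(exposure_block, dtype=float)
    n, p = X.shape
    g = Z.shape[1]
    if Z.shape[0] != n or y.shape[0] != n:
        raise ValueError("y, design and exposure block must share n")

    rng = np.random.default_rng(config.seed)
    xtx = X.T @ X
    ztz = Z.T @ Z

    beta = np.zeros(p)
    theta = np.zeros(g)
    sigma2 = 1.0
    phi = 0.5 * (prior.phi_lower + prior.phi_upper)
    proposal_sd = config.phi_proposal_sd

    n_keep = config.n_samples // config.thin
    out_beta = np.empty((n_keep, p))
    out_theta = np.empty((n_keep, g))
    out_sigma2 = np.empty(n_keep) if structured else None
    out_phi = np.empty(n_keep) if structured else None

    kept = 0
    acc_window, acc_total, phi_moves = 0, 0, 0
    total = config.n_burnin + config.n_samples
    for it in range(total):
        eta = X @ beta
        if g:
            eta += Z @ theta
        w = sample_latents(y, eta, rng)
        beta = update_beta(w, X, Z if g else None, theta if g else None,
                           prior, rng, xtx=xtx)
        if g:
            theta = update_theta(w, X, Z, beta, sigma2, phi, prior, rng,
                                 structured=structured, ztz=ztz)
            if structured:
                sigma2 = float(update_sigma2(theta, phi, prior, rng))
                phi, accepted = update_phi(theta, sigma2, phi, prior,
                                           proposal_sd, rng)
                phi_moves += 1
                acc_window += accepted
                if it >= config.n_burnin:
                    acc_total += accepted
                if config.adapt and it < config.n_burnin and (it + 1) % 100 == 0:
                    rate = acc_window / 100.0
                    if rate < 0.2:
                        proposal_sd *= 0.7
                    elif rate > 0.5:
                        proposal_sd *= 1.4
                    acc_window = 0

        if (it + 1) % 200 == 0 and not (np.isfinite(beta).all()
                                        and np.isfinite(theta).all()):
            raise FloatingPointError(f"divergent chain state at iteration {it}")

        post = it - config.n_burnin
        if post >= 0 and (post % config.thin) == 0 and kept < n_keep:
            out_beta[kept] = beta
            out_theta[kept] = theta
            if structured:
                out_sigma2[kept] = sigma2
                out_phi[kept] = phi
            kept += 1

    from .summaries import mc_error  # local import avoids a module cycle
    beta_labels = beta_labels or [f"beta_{j}" for j in range(p)]
    theta_labels = theta_labels or [f"theta_{j + 1}" for j in range(g)]
    errors: dict[str, float] = {}
    if kept >= 400:
        for j, lab in enumerate(beta_labels):
            errors[lab] = mc_error(out_beta[:kept, j])
        for j, lab in enumerate(theta_labels):
            errors[lab] = mc_error(out_theta[:kept, j])

    acc_rate = (acc_total / max(config.n_samples, 1)) if structured else None
    return PosteriorDraws(
        beta=out_beta[:kept], theta=out_theta[:kept],
        sigma2_theta=out_sigma2[:kept] if structured else None,
        phi=out_phi[:kept] if structured else None,
        phi_acceptance_rate=acc_rate, model_tag=variant,
        beta_labels=beta_labels, theta_labels=theta_labels,
        week_ids=None if week_ids is None else np.asarray(week_ids),
        mc_errors=errors)
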