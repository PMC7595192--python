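"""Blocked Gibbs sampler for the identical model — the MCMC oracle.

Deliberately simple and slow: full conditionals are sampled in a fixed
order, sharing the prior-construction code with the variational fitter so
any discrepancy between the two isolates the inference algorithm rather
than the model.  Intended for small instances only (n <= 100 enforced); its
long-run averages validate the mean-field approximation in the test suite.

Full conditionals (product-of-experts joint, see :mod:`lagkmr.model`):

* h    | rest  ~  Normal(Prec^{-1} (1/sigma^2) A'(y - X beta), Prec^{-1}),
  Prec = P(1/tau^2, 1/omega^2) + (1/sigma^2) J (x) I
* beta | rest  ~  Normal, conjugate Gaussian regression update
* sigma^2      ~  InverseGamma(a0 + n/2, b0 + ||resid||^2 / 2)
* 1/tau_t^2   ~  InverseGaussian(sqrt(lambda1^2 / h_t' K_t^+ h_t), lambda1^2)
* 1/omega_t^2 ~  InverseGaussian(sqrt(lambda2^2 / ||h_{t+1}-h_t||^2), lambda2^2)
* lambda1^2   ~  Gamma(a1 + sum_t (r_t+1)/2, d1 + sum_t tau_t^2 / 2)  (hyperprior mode)
* lambda2^2   ~  Gamma(a2 + (T-1)(n+1)/2, d2 + sum_t omega_t^2 / 2)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg as sla

from .families import sample_invgauss
from .kernels import KernelSpec
from .model import LKMRHyperparameters, WindowKernels, build_prior_precision, _ols_init


@dataclass(frozen=True)
class GibbsConfig:
    n_iterations: int = 55_000
    n_burnin: int = 5_000
    thinning: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.n_iterations > self.n_burnin >= 0:
            raise ValueError("need n_iterations > n_burnin >= 0")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")


@dataclass
class GibbsDraws:
    """Thinned post-burn-in draws."""

    h: np.ndarray  # (S, T, n)
    beta: np.ndarray  # (S, p)
    sigma2: np.ndarray  # (S,)
    tau2: np.ndarray  # (S, T)
    omega2: np.ndarray  # (S, T-1)
    lambda1_sq: np.ndarray  # (S,)
    lambda2_sq: np.ndarray  # (S,)

    @property
    def n_draws(self) -> int:
        return self.h.shape[0]

    def h_mean(self) -> np.ndarray:
        return self.h.mean(axis=0)

    def beta_mean(self) -> np.ndarray:
        return self.beta.mean(axis=0)


class GibbsSampler:
    """One-sweep-at-a-time sampler over the model's full conditionals.

    Exposed as a class so tests can drive individual sweeps (e.g. in
    Geweke-style successive-conditional simulation) with the exact code
    used by :func:`fit_gibbs`.
    """

    def __init__(self, X, Z_list, hyper: LKMRHyperparameters, kernel: KernelSpec,
                 rng: np.random.Generator):
        self.X = np.asarray(X, dtype=float)
        self.hyper = hyper
        self.rng = rng
        self.kern = WindowKernels([np.asarray(Z) for Z in Z_list], kernel)
        self.n, self.p = self.X.shape
        self.T = self.kern.T
        self.fused = hyper.fused and self.T > 1
        self.XtX = self.X.T @ self.X
        # state
        self.h = np.zeros((self.T, self.n))
        self.beta = np.zeros(self.p)
        self.sigma2 = 1.0
        self.tau2 = np.ones(self.T)
        self.omega2 = np.ones(max(self.T - 1, 0))
        if hyper.penalty_mode == "hyperprior":
            self.lambda1_sq = hyper.lambda1_sq / hyper.delta1
            self.lambda2_sq = hyper.lambda2_sq / hyper.delta2
        else:
            self.lambda1_sq = hyper.lambda1_sq
            self.lambda2_sq = hyper.lambda2_sq

    # --- individual full-conditional updates -------------------------------
    def sample_h(self, y: np.ndarray) -> None:
        Prec = build_prior_precision(self.kern, 1.0 / self.tau2,
                                     1.0 / self.omega2 if self.fused else np.zeros(0),
                                     self.fused)
        nT = self.n * self.T
        Prec += np.tile(np.eye(self.n), (self.T, self.T)) / self.sigma2
        try:
            L = np.linalg.cholesky(Prec)
        except np.linalg.LinAlgError as err:  # pragma: no cover - model bug guard
            raise RuntimeError(
                "non-positive-definite conditional precision for h; "
                "indicates a prior-construction bug"
            ) from err
        g = np.tile((y - self.X @ self.beta) / self.sigma2, self.T)
        mean = sla.cho_solve((L, True), g, check_finite=False)
        z = self.rng.standard_normal(nT)
        self.h = (mean + sla.solve_triangular(L.T, z, lower=False, check_finite=False)).reshape(self.T, self.n)

    def sample_beta(self, y: np.ndarray) -> None:
        Prec = self.XtX / self.sigma2 + np.eye(self.p) / self.hyper.beta_prior_variance
        L = np.linalg.cholesky(Prec)
        g = self.X.T @ (y - self.h.sum(axis=0)) / self.sigma2
        mean = sla.cho_solve((L, True), g, check_finite=False)
        z = self.rng.standard_normal(self.p)
        self.beta = mean + sla.solve_triangular(L.T, z, lower=False, check_finite=False)

    def sample_sigma2(self, y: np.ndarray) -> None:
        resid = y - self.X @ self.beta - self.h.sum(axis=0)
        shape = self.hyper.sigma2_shape + self.n / 2.0
        rate = self.hyper.sigma2_rate + float(resid @ resid) / 2.0
        self.sigma2 = rate / self.rng.gamma(shape)

    def sample_tau2(self) -> None:
        for t in range(self.T):
            b = max(self.kern.range_quad(t, self.h[t]), 1e-12)
            u = sample_invgauss(self.rng, np.sqrt(self.lambda1_sq / b), self.lambda1_sq)
            self.tau2[t] = 1.0 / u

    def sample_omega2(self) -> None:
        for t in range(self.T - 1):
            d = max(float(np.sum((self.h[t + 1] - self.h[t]) ** 2)), 1e-12)
            v = sample_invgauss(self.rng, np.sqrt(self.lambda2_sq / d), self.lambda2_sq)
            self.omega2[t] = 1.0 / v

    def sample_lambdas(self) -> None:
        if self.hyper.penalty_mode != "hyperprior":
            return
        half = (self.n + 1) / 2.0
        shape1 = self.hyper.lambda1_sq + sum((r + 1) / 2.0 for r in self.kern.ranks)
        rate1 = self.hyper.delta1 + float(np.sum(self.tau2)) / 2.0
        self.lambda1_sq = self.rng.gamma(shape1) / rate1
        if self.fused:
            shape2 = self.hyper.lambda2_sq + (self.T - 1) * half
            rate2 = self.hyper.delta2 + float(np.sum(self.omega2)) / 2.0
            self.lambda2_sq = self.rng.gamma(shape2) / rate2

    def sweep(self, y: np.ndarray) -> None:
        """One full cycle in the fixed order h, beta, sigma^2, scales, lambdas."""
        self.sample_h(y)
        self.sample_beta(y)
        self.sample_sigma2(y)
        self.sample_tau2()
        if self.fused:
            self.sample_omega2()
        self.sample_lambdas()

    # --- forward (generative) sampling, valid for the T=1 submodel ---------
    def sample_prior(self) -> None:
        """Draw (lambda, tau^2, h, beta, sigma^2) from the prior.

        Only exact for T = 1 (no fusion factors), where the joint is a
        normalized hierarchy; used by the Geweke-style validation.
        """
        if self.fused:
            raise ValueError("forward prior sampling is only defined for T = 1")
        hyper = self.hyper
        if hyper.penalty_mode == "hyperprior":
            self.lambda1_sq = self.rng.gamma(hyper.lambda1_sq) / hyper.delta1
        half = (self.kern.ranks[0] + 1) / 2.0
        self.tau2[0] = self.rng.gamma(half) / (self.lambda1_sq / 2.0)
        V, eig, j = self.kern.V[0], self.kern.eig[0], self.kern._j
        # h ~ N(0, tau^2 V Lambda V' + jitter P_perp)
        z = self.rng.standard_normal(self.n)
        perp = z - V @ (V.T @ z)
        zr = self.rng.standard_normal(eig.size)
        self.h[0] = V @ (np.sqrt(self.tau2[0] * eig) * zr) + np.sqrt(j) * perp
        self.beta = self.rng.standard_normal(self.p) * np.sqrt(hyper.beta_prior_variance)
        self.sigma2 = hyper.sigma2_rate / self.rng.gamma(hyper.sigma2_shape)

    def sample_data(self) -> np.ndarray:
        mean = self.X @ self.beta + self.h.sum(axis=0)
        return mean + self.rng.standard_normal(self.n) * np.sqrt(self.sigma2)


def fit_gibbs(
    design, hyper: LKMRHyperparameters | None = None,
    kernel: KernelSpec | None = None, config: GibbsConfig | None = None,
    allow_large: bool = False,
) -> GibbsDraws:
    """Run the blocked Gibbs sampler on a standardized design.

    Seeded and reproducible: same seed and config give an identical draw
    store.  Refuses n > 100 unless ``allow_large=True`` (the oracle exists
    for small cross-validation instances, not production fits).
    """
    hyper = hyper or LKMRHyperparameters()
    kernel = kernel or KernelSpec()
    config = config or GibbsConfig()
    y = np.asarray(design.y, dtype=float)
    X = np.asarray(design.X, dtype=float)
    n = X.shape[0]
    if n > 100 and not allow_large:
        raise ValueError(
            f"n = {n} exceeds the oracle's n <= 100 limit; pass allow_large=True to override"
        )
    rng = np.random.default_rng(config.seed)
    sampler = GibbsSampler(X, design.Z, hyper, kernel, rng)
    # start from the same deterministic point as the variational fitter
    sampler.beta, s2 = _ols_init(X, y, list(getattr(design, "x_names", [])) or
                                 [f"x{i}" for i in range(X.shape[1])])
    sampler.sigma2 = s2

    keep = range(config.n_burnin, config.n_iterations, config.thinning)
    S = len(keep)
    keep = set(keep)
    T = sampler.T
    out_h = np.empty((S, T, n))
    out_beta = np.empty((S, X.shape[1]))
    out_s2 = np.empty(S)
    out_tau2 = np.empty((S, T))
    out_om2 = np.empty((S, max(T - 1, 0)))
    out_l1 = np.empty(S)
    out_l2 = np.empty(S)
    s = 0
    for it in range(config.n_iterations):
        sampler.sweep(y)
        if it in keep:
            out_h[s] = sampler.h
            out_beta[s] = sampler.beta
            out_s2[s] = sampler.sigma2
            out_tau2[s] = sampler.tau2
            out_om2[s] = sampler.omega2
            out_l1[s] = sampler.lambda1_sq
            out_l2[s] = sampler.lambda2_sq
            s += 1
    return GibbsDraws(out_h, out_beta, out_s2, out_tau2, out_om2, out_l1, out_l2)
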