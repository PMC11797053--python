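"""Phylogenetically corrected association tests and signal statistics.

Covers the three comparative tools of the pipeline:

* a Bayesian phylogenetic GLMM (Poisson or Gaussian response, species
  random effect with covariance ``sigma2_p * C``) sampled by
  Metropolis-within-Gibbs, summarised by the two-sided tail probability
  pMCMC of the slope;
* Pagel's lambda by profile maximum likelihood with a likelihood-ratio
  test against lambda = 0;
* Blomberg's K with a tip-label permutation test.

Both signal statistics use the Brownian-motion covariance C from
:mod:`dietcnv.trees`; lambda rescales its off-diagonals, and K compares
the observed trait variance ratio with its Brownian expectation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize, stats

from ._mcmc import gaussian_chain, poisson_chain
from .trees import PhyloCov, lambda_max, lambda_transform

__all__ = [
    "GlmmConfig",
    "GlmmResult",
    "PValue",
    "fit_phylo_glmm",
    "pmcmc",
    "pagels_lambda",
    "blombergs_k",
    "effective_sample_size",
    "bonferroni",
]


@dataclass(frozen=True)
class GlmmConfig:
    """MCMC settings; defaults follow common practice for this model class
    (inverse-Wishart V=1, nu=0.002 prior; 1,050,000 iterations with 50,000
    burn-in and thinning 200, i.e. 5,000 retained draws)."""

    V: float = 1.0
    nu: float = 0.002
    iterations: int = 1_050_000
    burnin: int = 50_000
    thinning: int = 200
    family: str = "poisson"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.burnin >= self.iterations:
            raise ValueError("burn-in must be < iterations")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")
        if self.family not in ("poisson", "gaussian"):
            raise ValueError(f"unknown family {self.family!r}")

    def reduced(self, factor: int = 1) -> "GlmmConfig":
        """Short-chain variant for simulation studies (55k/5k/10)."""
        from dataclasses import replace
        return replace(self, iterations=55_000 // max(factor, 1),
                       burnin=5_000 // max(factor, 1), thinning=10)

    @property
    def n_retained(self) -> int:
        return (self.iterations - self.burnin) // self.thinning


@dataclass(frozen=True)
class PValue:
    """A p-value that may be a resolution bound (e.g. '< 0.0004')."""

    value: float
    is_bound: bool = False

    def __str__(self) -> str:
        return f"<{self.value:g}" if self.is_bound else f"{self.value:g}"

    def __float__(self) -> float:
        return self.value


@dataclass
class GlmmResult:
    draws: np.ndarray = field(repr=False)  # columns a, b, s2p, s2e
    pmcmc_beta: PValue
    acceptance: np.ndarray = field(repr=False)
    config: GlmmConfig

    @property
    def beta_draws(self) -> np.ndarray:
        return self.draws[:, 1]

    @property
    def beta_mean(self) -> float:
        return float(self.draws[:, 1].mean())

    @property
    def beta_ci(self) -> tuple[float, float]:
        lo, hi = np.quantile(self.draws[:, 1], [0.025, 0.975])
        return float(lo), float(hi)

    def posterior_mean(self) -> dict[str, float]:
        m = self.draws.mean(axis=0)
        return {"intercept": m[0], "beta": m[1],
                "sigma2_phylo": m[2], "sigma2_resid": m[3]}

    def ess(self) -> dict[str, float]:
        return {name: effective_sample_size(self.draws[:, i])
                for i, name in enumerate(
                    ("intercept", "beta", "sigma2_phylo", "sigma2_resid"))}


def _check_cov(cov: PhyloCov) -> np.ndarray:
    C = cov.C
    try:
        linalg.cholesky(C, lower=True)
    except linalg.LinAlgError as exc:
        raise ValueError("phylogenetic covariance is not positive definite; "
                         "check for duplicate tips or zero branch lengths"
                         ) from exc
    return C


def fit_phylo_glmm(
    y, x, cov: PhyloCov, config: GlmmConfig = GlmmConfig()
) -> GlmmResult:
    """Fit y ~ x with a phylogenetic random effect by MCMC.

    ``y`` are per-species counts (poisson family) or reals (gaussian);
    ``x`` is the per-species predictor (a 0/1 category indicator or a
    quantitative trophic level). All inputs must share the species order
    of ``cov``. Bit-reproducible under ``config.seed``.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    n = len(cov.species)
    if y.shape != (n,) or x.shape != (n,):
        raise ValueError("y, x and cov must be aligned to the same species")
    if config.family == "poisson":
        if np.any(y < 0) or np.any(y != np.round(y)):
            raise ValueError("poisson family needs non-negative integer y")
    C = _check_cov(cov)
    Cinv = linalg.inv(C)
    Cinv = 0.5 * (Cinv + Cinv.T)
    kernel = poisson_chain if config.family == "poisson" else gaussian_chain
    draws, rates = kernel(
        y, x, Cinv, config.V, config.nu,
        config.iterations, config.burnin, config.thinning,
        config.seed % (2**31),
    )
    return GlmmResult(draws=draws, pmcmc_beta=pmcmc(draws[:, 1]),
                      acceptance=rates, config=config)


def pmcmc(draws) -> PValue:
    """Two-sided Bayesian tail probability 2*min(P(b>0), P(b<0)).

    When every retained draw falls on one side the value is the chain's
    resolution bound 2/N, flagged as a bound (printed '< 2/N').
    """
    draws = np.asarray(draws, dtype=float)
    N = len(draws)
    if N == 0:
        raise ValueError("no draws")
    frac_pos = float(np.mean(draws > 0))
    frac_neg = float(np.mean(draws < 0))
    p = 2.0 * min(frac_pos, frac_neg)
    if p == 0.0:
        return PValue(2.0 / N, is_bound=True)
    return PValue(min(p, 1.0))


def effective_sample_size(chain) -> float:
    """ESS by the initial-positive-sequence autocorrelation estimator."""
    chain = np.asarray(chain, dtype=float)
    n = len(chain)
    if n < 4 or np.var(chain) == 0:
        return float(n)
    c = chain - chain.mean()
    acf = np.correlate(c, c, mode="full")[n - 1:] / (np.arange(n, 0, -1)
                                                     * np.var(chain))
    tau = 1.0
    for k in range(1, n // 2):
        if acf[k] <= 0:
            break
        tau += 2.0 * acf[k]
    return float(min(n, n / tau))


def _profile_loglik(y, C, lam, Cmax=None):
    n = len(y)
    M = lam * C
    np.fill_diagonal(M, np.diag(C))
    Lc = linalg.cholesky(M, lower=True)
    one = np.ones(n)
    iy = linalg.cho_solve((Lc, True), y)
    i1 = linalg.cho_solve((Lc, True), one)
    abar = (one @ iy) / (one @ i1)
    r = y - abar
    ir = linalg.cho_solve((Lc, True), r)
    s2 = (r @ ir) / n  # ML estimate
    if s2 <= 0:
        return -np.inf, abar, s2
    logdet = 2.0 * np.sum(np.log(np.diag(Lc)))
    ll = -0.5 * (n * np.log(2 * np.pi * s2) + logdet + n)
    return ll, abar, s2


def pagels_lambda(y, cov: PhyloCov) -> tuple[float, PValue, dict]:
    """Profile-ML estimate of Pagel's lambda with an LR test vs lambda=0.

    The trait is modelled as Gaussian with mean ``abar`` and covariance
    ``sigma2 * C(lambda)``; ``abar`` and ``sigma2`` are profiled
    analytically, lambda maximised numerically on [0, lambda_max]. The
    chi-square(1) reference for the LR test ignores the boundary at 0 and
    is therefore conservative.
    """
    y = np.asarray(y, dtype=float)
    n = len(cov.species)
    if y.shape != (n,):
        raise ValueError("y must align with cov species")
    if n < 4:
        raise ValueError("need at least 4 species")
    if np.allclose(y, y[0]):
        raise ValueError("trait is constant")
    C = _check_cov(cov)
    lmax = min(lambda_max(cov), 1.2)

    def neg(lam):
        return -_profile_loglik(y, C, lam)[0]

    # the profile likelihood can be multimodal, and often spikes in a
    # narrow window just inside the positive-definiteness boundary (hence
    # fitted values slightly above 1): scan a uniform grid densified
    # geometrically toward lmax, then refine around the best point
    coarse = np.unique(np.concatenate([
        np.linspace(0.0, lmax, 41),
        lmax * (1.0 - 2.0 ** -np.arange(6, 18)),
    ]))

    def safe_ll(lam):
        try:
            return _profile_loglik(y, C, lam)[0]
        except linalg.LinAlgError:
            return -np.inf

    coarse_ll = np.array([safe_ll(g) for g in coarse])
    k = int(np.argmax(coarse_ll))
    lo = coarse[max(k - 1, 0)]
    hi = coarse[min(k + 1, len(coarse) - 1)]
    res = optimize.minimize_scalar(lambda g: -safe_ll(g), bounds=(lo, hi),
                                   method="bounded",
                                   options={"xatol": 1e-6})
    cands = [(float(res.x), -res.fun), (float(coarse[k]), coarse_ll[k]),
             (0.0, coarse_ll[0])]
    lam_hat, ll_hat = max(cands, key=lambda t: t[1])
    ll0 = _profile_loglik(y, C, 0.0)[0]
    lr = max(0.0, 2.0 * (ll_hat - ll0))
    p = float(stats.chi2.sf(lr, df=1))
    return lam_hat, PValue(max(p, np.finfo(float).tiny)), {
        "loglik_hat": ll_hat, "loglik_0": ll0, "lr": lr}


def blombergs_k(
    y, cov: PhyloCov, n_perm: int = 999, seed: int = 0
) -> tuple[float, PValue]:
    """Blomberg's K and its tip-shuffling permutation p-value.

    K compares the observed ratio of non-phylogenetic to phylogenetic
    mean squared error with its Brownian-motion expectation; K = 1 on a
    star phylogeny for any non-constant trait, and for data generated by
    Brownian motion on the given tree E[K] is about 1.
    """
    y = np.asarray(y, dtype=float)
    n = len(cov.species)
    if y.shape != (n,):
        raise ValueError("y must align with cov species")
    if np.allclose(y, y[0]):
        raise ValueError("trait is constant")
    C = _check_cov(cov)
    Lc = linalg.cholesky(C, lower=True)
    one = np.ones(n)
    i1 = linalg.cho_solve((Lc, True), one)
    denom_expect = (np.trace(C) - n / (one @ i1)) / (n - 1)

    def k_stat(vals):
        iv = linalg.cho_solve((Lc, True), vals)
        abar = (one @ iv) / (one @ i1)
        r = vals - abar
        mse0 = (r @ r) / (n - 1)
        mse = (r @ linalg.cho_solve((Lc, True), r)) / (n - 1)
        return (mse0 / mse) / denom_expect

    K = float(k_stat(y))
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        if k_stat(rng.permutation(y)) >= K:
            exceed += 1
    p = (1 + exceed) / (n_perm + 1)
    return K, PValue(p)


def bonferroni(p: float | PValue, n_tests: int) -> PValue:
    """Reporting-layer Bonferroni adjustment: multiply by the test count."""
    val = float(p)
    bound = isinstance(p, PValue) and p.is_bound
    return PValue(min(val * n_tests, 1.0), is_bound=bound)
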