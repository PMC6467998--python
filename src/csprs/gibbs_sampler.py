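"""Block Gibbs sampler for posterior SNP effects under the continuous
shrinkage prior.

Model (standardized genotypes Z, standardized phenotype y, GWAS size N):

    y = Z beta + eps,            eps ~ N(0, sigma^2 I),  p(sigma^2) ~ 1/sigma^2
    beta_j | psi_j ~ N(0, (sigma^2/N) phi psi_j)
    psi_j ~ Gamma(a, rate delta_j),  delta_j ~ Gamma(b, rate 1)
    (auto mode)  phi^{1/2} ~ half-Cauchy(0, 1)

The sampler works in the absorbed parameterization psi'_j = phi psi_j
(the per-SNP prior variance multiplier) and delta'_j = delta_j / phi,
which is the same joint law written as

    beta_j ~ N(0, (sigma^2/N) psi'_j),
    psi'_j ~ Gamma(a, rate delta'_j),  delta'_j ~ Gamma(b, rate phi).

Only the sufficient statistics betahat = Z'y/N (from summary statistics)
and the block LD matrices D = Z'Z/N (from a reference panel) enter the
updates.  Full conditionals (state fields psi/delta hold psi'/delta'):

* per LD block: beta ~ MVN((D + T^{-1})^{-1} betahat,
  (sigma^2/N) (D + T^{-1})^{-1}),  T = diag(psi'_j);
* psi'_j ~ GIG(a - 1/2, chi = N beta_j^2 / sigma^2, 2 delta'_j);
* delta'_j ~ Gamma(a + b, rate psi'_j + phi);
* sigma^2 ~ InvGamma((N + M)/2,
  (N/2) [(1 - 2 beta'betahat + beta'D beta) + sum_j beta_j^2/psi'_j]);
* auto mode, with auxiliary w | phi ~ Gamma(1, rate phi + 1):
  phi ~ Gamma(M b + 1/2, rate sum_j delta'_j + w).

To guard against collinearity in reference-panel LD, the amount of ridge
regularization each marker contributes to the block solve, 1/psi'_j, is
bounded below by rho (default 1): psi'_j is truncated at 1/rho after
every draw, so each conditional sees the same regularized value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import lapack

from .cs_prior import JITTER_LADDER
from .sumstats_io import StandardizedEffects, perallele_from_standardized

logger = logging.getLogger(__name__)

#: below this chi, GIG(p > 0, chi, psi) is drawn from its Gamma(p) limit
_CHI_FLOOR = 1e-16

#: lower clamp on the residual quadratic form 1 - 2 b'bh + b'Db, which can
#: go negative under reference-panel mismatch
_QUAD_CLAMP = 1e-6


# ---------------------------------------------------------------------------
# generalized inverse Gaussian sampling


def _gig_two_param(lam: float, omega: np.ndarray,
                   rng: np.random.Generator) -> np.ndarray:
    """Vectorized rejection sampler for the two-parameter GIG law with
    density proportional to y^{lam-1} exp(-omega (y + 1/y) / 2), lam >= 0.

    Uses the uniformly fast three-piece exponential envelope of Devroye's
    log-concave method; the rejection constant is bounded, so the masked
    loop terminates in a few rounds regardless of the parameters.
    """
    omega = np.asarray(omega, dtype=np.float64)
    alpha = np.sqrt(omega * omega + lam * lam) - lam

    def psi_fn(x):
        return -alpha * (np.cosh(x) - 1.0) - lam * (np.expm1(x) - x)

    def dpsi_fn(x):
        return -alpha * np.sinh(x) - lam * np.expm1(x)

    # right and left design points t, s
    v = -psi_fn(np.ones_like(alpha))
    t = np.where(v > 2.0, np.sqrt(2.0 / (alpha + lam)),
                 np.where(v < 0.5, np.log(4.0 / (alpha + 2.0 * lam)), 1.0))
    v = -psi_fn(-np.ones_like(alpha))
    with np.errstate(divide="ignore", over="ignore"):
        s_small = np.minimum(
            1.0 / lam if lam > 0 else np.inf,
            np.log1p(1.0 / alpha + np.sqrt(1.0 / alpha ** 2 + 2.0 / alpha)))
    s = np.where(v > 2.0, np.sqrt(4.0 / (alpha * np.cosh(1.0) + lam)),
                 np.where(v < 0.5, s_small, 1.0))

    eta, zeta = -psi_fn(t), -dpsi_fn(t)
    theta, xi = -psi_fn(-s), dpsi_fn(-s)
    p = 1.0 / xi
    r = 1.0 / zeta
    td = t - r * eta
    sd = s - p * theta
    q = td + sd

    out = np.empty(omega.shape)
    todo = np.ones(omega.shape, dtype=bool)
    while todo.any():
        k = int(todo.sum())
        U = rng.random(k)
        V = rng.random(k)
        W = rng.random(k)
        qk, rk, pk = q[todo], r[todo], p[todo]
        tot = pk + qk + rk
        x = np.where(
            U < qk / tot, -sd[todo] + qk * V,
            np.where(U < (qk + rk) / tot,
                     td[todo] - rk * np.log(V),
                     -sd[todo] + pk * np.log(V)))
        # envelope value at x
        f1 = np.exp(-eta[todo] - zeta[todo] * (x - t[todo]))
        f2 = np.exp(-theta[todo] + xi[todo] * (x + s[todo]))
        env = np.where(x > td[todo], f1, np.where(x < -sd[todo], f2, 1.0))
        target = (-alpha[todo] * (np.cosh(x) - 1.0)
                  - lam * (np.expm1(x) - x))
        accept = W * env <= np.exp(target)
        idx = np.where(todo)[0][accept]
        out[idx] = x[accept]
        todo[idx] = False

    scale = lam / omega + np.sqrt(1.0 + (lam / omega) ** 2)
    return np.exp(out) * scale


def gig_rvs(p: float, chi, psi_param, rng: np.random.Generator):
    """Vectorized draws from GIG(p, chi, psi) with density
    x^{p-1} exp(-(chi/x + psi*x)/2) / const.

    Degenerate limits are dispatched analytically: chi -> 0 with p > 0 is
    Gamma(p, rate psi/2); psi -> 0 with p < 0 is InvGamma(-p, chi/2).
    p = +-1/2 uses the inverse-Gaussian representation; other orders fall
    back to the rejection sampler in scipy.stats.geninvgauss.
    """
    chi = np.atleast_1d(np.asarray(chi, dtype=np.float64))
    psi = np.atleast_1d(np.asarray(psi_param, dtype=np.float64))
    chi, psi = np.broadcast_arrays(chi, psi)
    if np.any(chi < 0) or np.any(psi < 0):
        raise ValueError("chi and psi must be nonnegative")
    both_zero = (chi <= 0) & (psi <= 0)
    if np.any(both_zero):
        raise ValueError("chi and psi cannot both be zero")
    out = np.empty(chi.shape, dtype=np.float64)

    chi_zero = chi < _CHI_FLOOR
    psi_zero = psi <= 0.0
    if np.any(chi_zero):
        if p <= 0:
            # no gamma limit; nudge chi off zero and use the general path
            chi = np.where(chi_zero, _CHI_FLOOR, chi)
            chi_zero = np.zeros_like(chi_zero)
        else:
            out[chi_zero] = rng.gamma(p, 2.0 / psi[chi_zero])
    if np.any(psi_zero & ~chi_zero):
        if p >= 0:
            raise ValueError("psi = 0 requires p < 0 (inverse-gamma limit)")
        sel = psi_zero & ~chi_zero
        out[sel] = (chi[sel] / 2.0) / rng.gamma(-p, 1.0, size=int(sel.sum()))

    general = ~chi_zero & ~psi_zero
    if np.any(general):
        c, s = chi[general], psi[general]
        if p == 0.5:
            # X ~ GIG(1/2, chi, psi)  <=>  1/X ~ IG(sqrt(psi/chi), psi)
            out[general] = 1.0 / rng.wald(np.sqrt(s / c), s)
        elif p == -0.5:
            out[general] = rng.wald(np.sqrt(c / s), c)
        else:
            omega = np.sqrt(c * s)
            eta = np.sqrt(c / s)
            if p >= 0:
                out[general] = eta * _gig_two_param(p, omega, rng)
            else:
                # GIG(p) = 1 / GIG(-p) with chi and psi exchanged
                out[general] = eta / _gig_two_param(-p, omega, rng)
    return out


def sample_gig(p: float, chi: float, psi_param: float,
               rng: np.random.Generator) -> float:
    """One GIG(p, chi, psi) draw; see :func:`gig_rvs`."""
    return float(gig_rvs(p, chi, psi_param, rng)[0])


# ---------------------------------------------------------------------------
# configuration and state


@dataclass
class GibbsConfig:
    """MCMC settings. Defaults (1000 iterations, 500 burn-in) suit
    simulation workloads; use 10000/5000 for real-data analyses."""

    n_iter: int = 1000
    n_burnin: int = 500
    thin: int = 1
    seed: int = 0
    rho_floor: float = 1.0
    phi: float | str = "auto"
    a: float = 1.0
    b: float = 0.5
    n_eff: int | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.n_burnin < self.n_iter):
            raise ValueError("need 0 <= n_burnin < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.rho_floor <= 0:
            raise ValueError("rho_floor must be positive")
        if self.a <= 0 or self.b <= 0:
            raise ValueError("a, b must be positive")
        if self.phi != "auto" and float(self.phi) <= 0:
            raise ValueError('phi must be positive or "auto"')

    @property
    def auto(self) -> bool:
        return self.phi == "auto"


@dataclass
class ShrinkageState:
    """Current Gibbs state over M harmonized SNPs.

    ``psi`` and ``delta`` hold the absorbed local scales psi'_j = phi
    psi_j and delta'_j = delta_j / phi (see module docstring); ``psi`` is
    therefore the per-SNP prior variance multiplier directly.
    """

    beta: np.ndarray
    psi: np.ndarray
    delta: np.ndarray
    sigma2: float = 1.0
    phi: float = 1.0
    aux_w: float = 1.0

    @classmethod
    def initial(cls, m: int, phi: float = 1.0) -> "ShrinkageState":
        return cls(beta=np.zeros(m), psi=np.ones(m), delta=np.ones(m),
                   sigma2=1.0, phi=float(phi), aux_w=1.0)


@dataclass
class PosteriorEffects:
    """Posterior mean effects and run diagnostics."""

    snp_ids: np.ndarray
    beta_std_mean: np.ndarray
    beta_perallele_mean: np.ndarray | None
    n_samples_used: int
    phi_posterior_mean: float
    traces: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.beta_std_mean)


# ---------------------------------------------------------------------------
# conditional updates


def _chol_lower(A: np.ndarray, block_id: int) -> np.ndarray:
    for jitter in (0.0,) + JITTER_LADDER:
        M = A if jitter == 0.0 else A + jitter * np.eye(A.shape[0])
        c, info = lapack.dpotrf(M, lower=1, clean=0, overwrite_a=jitter > 0)
        if info == 0:
            return c
    raise np.linalg.LinAlgError(
        f"block {block_id}: Cholesky failed after jitter ladder")


def update_beta_block(state: ShrinkageState, D: np.ndarray,
                      betahat_block: np.ndarray, idx: np.ndarray,
                      cfg: GibbsConfig, rng: np.random.Generator,
                      block_id: int = -1) -> np.ndarray:
    """Draw the effects of one LD block from their multivariate normal
    conditional and write them into ``state.beta[idx]``.

    The prior variance multiplier is floored at psi'_j <= 1/rho before
    forming A = D + T^{-1}; the draw is mean + sqrt(sigma^2/N) L^{-T} z
    from a single Cholesky factorization of A.
    """
    T = np.minimum(state.psi[idx], 1.0 / cfg.rho_floor)
    A = np.array(D, dtype=np.float64, copy=True)
    j = np.arange(A.shape[0])
    A[j, j] += 1.0 / T
    c = _chol_lower(A, block_id)
    mean, info = lapack.dpotrs(c, betahat_block, lower=1)
    if info != 0:
        raise np.linalg.LinAlgError(f"block {block_id}: dpotrs info={info}")
    z = rng.standard_normal(len(idx))
    noise, info = lapack.dtrtrs(c, z, lower=1, trans=1)
    if info != 0:
        raise np.linalg.LinAlgError(f"block {block_id}: dtrtrs info={info}")
    draw = mean + np.sqrt(state.sigma2 / cfg.n_eff) * noise
    state.beta[idx] = draw
    return draw


def update_psi_delta(state: ShrinkageState, cfg: GibbsConfig,
                     rng: np.random.Generator) -> None:
    """Draw the absorbed local scales and their hyperparameters.

    psi'_j | . ~ GIG(a - 1/2, N beta_j^2/sigma^2, 2 delta'_j), truncated
    at 1/rho (the regularization floor), then
    delta'_j | psi'_j ~ Gamma(a + b, rate psi'_j + phi).
    """
    chi = cfg.n_eff * state.beta ** 2 / state.sigma2
    psi = gig_rvs(cfg.a - 0.5, chi, 2.0 * state.delta, rng)
    np.clip(psi, 1e-300, 1.0 / cfg.rho_floor, out=psi)
    state.psi = psi
    state.delta = rng.gamma(cfg.a + cfg.b, 1.0 / (psi + state.phi))


def update_sigma2(state: ShrinkageState, betahat_all: np.ndarray,
                  block_data: list, cfg: GibbsConfig,
                  rng: np.random.Generator) -> float:
    """Draw the residual variance from its inverse-gamma conditional.

    With y'y = N the residual sum of squares equals
    N (1 - 2 beta'betahat + beta' D beta); the prior on beta contributes
    N sum_j beta_j^2 / psi'_j.  Shape (N + M)/2, scale half the sum.
    ``block_data`` is a list of (D, idx) pairs.
    """
    beta = state.beta
    quad = 1.0 - 2.0 * float(beta @ betahat_all)
    for D, idx in block_data:
        b = beta[idx]
        quad += float(b @ (D @ b))
    if quad < _QUAD_CLAMP:
        logger.warning("residual quadratic form %.3e clamped at %.0e "
                       "(reference-panel mismatch)", quad, _QUAD_CLAMP)
        quad = _QUAD_CLAMP
    prior_term = float(np.sum(beta ** 2 / state.psi))
    m = len(beta)
    shape = 0.5 * (cfg.n_eff + m)
    scale = 0.5 * cfg.n_eff * (quad + prior_term)
    state.sigma2 = scale / rng.gamma(shape, 1.0)
    return state.sigma2


def update_phi_auto(state: ShrinkageState, cfg: GibbsConfig,
                    rng: np.random.Generator) -> float:
    """Draw the global scale under the half-Cauchy prior on phi^{1/2}.

    Using the auxiliary representation of the half-Cauchy,
    w | phi ~ Gamma(1, rate phi + 1), and conditioning on the delta'
    layer (which carries phi as its rate), the conditional is
    phi ~ Gamma(M b + 1/2, rate sum_j delta'_j + w); with M = 0 it
    reduces to the pure prior chain Gamma(1/2, rate w).
    """
    state.aux_w = max(rng.gamma(1.0, 1.0 / (state.phi + 1.0)), 1e-300)
    m = len(state.beta)
    rate = float(np.sum(state.delta)) + state.aux_w
    if not np.isfinite(rate) or rate <= 0:
        raise ArithmeticError(f"invalid phi rate parameter {rate}")
    state.phi = float(rng.gamma(m * cfg.b + 0.5, 1.0 / rate))
    return state.phi


# ---------------------------------------------------------------------------
# full sampler


def _resolve_blocks(hstats: StandardizedEffects, blocks) -> list:
    """Pair each LD block with the index array of its SNPs in the
    harmonized order, checking full disjoint coverage."""
    block_data = []
    seen = np.zeros(len(hstats), dtype=bool)
    for blk in blocks:
        idx = np.array([hstats.snp_index[s] for s in blk.snp_ids],
                       dtype=np.intp)
        if seen[idx].any():
            raise ValueError(f"block {blk.block_id}: SNP assigned twice")
        seen[idx] = True
        block_data.append((blk.D, idx))
    if not seen.all():
        missing = int((~seen).sum())
        raise ValueError(f"{missing} SNPs not covered by any LD block")
    return block_data


def run_prscs(hstats: StandardizedEffects, blocks, cfg: GibbsConfig,
              maf: np.ndarray | None = None) -> PosteriorEffects:
    """Run the full Gibbs sweep and return posterior mean effects.

    Each iteration updates every block's effects in genomic order, then
    the local scales, the residual variance, and (auto mode) the global
    scale.  Posterior means average post-burn-in (optionally thinned)
    samples.  Deterministic given (inputs, seed): the main chain and each
    block draw use substreams spawned from the seed.
    """
    cfg = GibbsConfig(**{**cfg.__dict__})  # defensive copy
    if cfg.n_eff is None:
        cfg.n_eff = hstats.n_eff
    block_data = _resolve_blocks(hstats, blocks)
    betahat = hstats.betahat_std
    m = len(hstats)

    ss = np.random.SeedSequence(cfg.seed)
    children = ss.spawn(len(block_data) + 1)
    rng = np.random.default_rng(children[0])
    block_rngs = [np.random.default_rng(c) for c in children[1:]]

    state = ShrinkageState.initial(m, phi=1.0 if cfg.auto else float(cfg.phi))
    beta_sum = np.zeros(m)
    phi_sum = 0.0
    n_used = 0
    trace = {"iteration": [], "sigma2": [], "phi": [], "mean_abs_beta": []}

    for it in range(cfg.n_iter):
        for bid, (D, idx) in enumerate(block_data):
            try:
                update_beta_block(state, D, betahat[idx], idx, cfg,
                                  block_rngs[bid], block_id=bid)
            except Exception as exc:
                raise RuntimeError(
                    f"iteration {it}, block {bid}: {exc}") from exc
        update_psi_delta(state, cfg, rng)
        update_sigma2(state, betahat, block_data, cfg, rng)
        if cfg.auto:
            update_phi_auto(state, cfg, rng)

        trace["iteration"].append(it)
        trace["sigma2"].append(state.sigma2)
        trace["phi"].append(state.phi)
        trace["mean_abs_beta"].append(float(np.mean(np.abs(state.beta))))

        if it >= cfg.n_burnin and (it - cfg.n_burnin) % cfg.thin == 0:
            beta_sum += state.beta
            phi_sum += state.phi
            n_used += 1

    beta_mean = beta_sum / n_used
    snp_ids = np.empty(m, dtype=object)
    for s, i in hstats.snp_index.items():
        snp_ids[i] = s
    perallele = None
    if maf is not None:
        perallele = perallele_from_standardized(beta_mean, np.asarray(maf))
    return PosteriorEffects(
        snp_ids=snp_ids, beta_std_mean=beta_mean,
        beta_perallele_mean=perallele, n_samples_used=n_used,
        phi_posterior_mean=phi_sum / n_used,
        traces={k: np.asarray(v) for k, v in trace.items()})


#: default global-scale grid searched in non-auto mode (sqrt(phi) values)
PHI_SQRT_GRID = (1e-4, 1e-3, 1e-2, 1e-1, 1.0)


def run_prscs_grid(hstats: StandardizedEffects, blocks, cfg: GibbsConfig,
                   phi_sqrt_grid=PHI_SQRT_GRID,
                   maf: np.ndarray | None = None) -> dict:
    """Run one chain per fixed global scale; keys are sqrt(phi) values."""
    out = {}
    for ps in phi_sqrt_grid:
        c = GibbsConfig(**{**cfg.__dict__, "phi": ps ** 2})
        out[ps] = run_prscs(hstats, blocks, c, maf=maf)
    return out


def write_trace(pe: PosteriorEffects, path: str) -> None:
    """Tab-separated convergence trace (iteration, sigma2, phi,
    mean|beta|)."""
    import pandas as pd

    pd.DataFrame(pe.traces).to_csv(path, sep="\t", index=False,
                                   float_format="%.6e")
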