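"""Closed-form machinery of the continuous shrinkage prior.

The prior on a standardized SNP effect is the global-local scale mixture

    beta_j | psi_j ~ N(0, (sigma^2 / N) * phi * psi_j),

with a gamma-gamma hierarchy on the local scale,

    psi_j ~ Gamma(a, rate delta_j),    delta_j ~ Gamma(b, rate 1),

whose marginal is a beta-prime(a, b) law on psi_j.  Under this hierarchy
the shrinkage factor tau_j = 1 / (1 + phi * psi_j) follows the
three-parameter beta distribution TPB(a, b, phi), which reduces to
Beta(b, a) at phi = 1.  The shipped default (a = 1, b = 1/2) is the
Strawderman-Berger prior; a = b = 1/2 gives the horseshoe.

Fixing all scales, the posterior mean of the effect vector given marginal
estimates betahat and LD matrix D is the matrix shrinkage estimator
(D + T^{-1})^{-1} betahat with T = diag(phi * psi_j).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate
from scipy.linalg import cho_factor, cho_solve
from scipy.special import gammaln

#: diagonal jitter ladder applied when a block factorization fails
JITTER_LADDER = (1e-10, 1e-8, 1e-6)


@dataclass
class PriorSpec:
    """TPB prior parameters: a controls behaviour near zero effect, b the
    tails; phi is the global scale or "auto" for the half-Cauchy mode."""

    a: float = 1.0
    b: float = 0.5
    phi: float | str = "auto"

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ValueError("a and b must be positive")
        if self.phi != "auto" and not (
                np.isscalar(self.phi) and float(self.phi) > 0):
            raise ValueError('phi must be positive or "auto"')


def tpb_density(x, a: float, b: float, phi: float):
    """TPB(a, b, phi) density on the shrinkage factor, 0 < x < 1.

    f(x) = B(a,b)^{-1} phi^b x^{b-1} (1-x)^{a-1} [1 + (phi-1) x]^{-(a+b)}.
    """
    x = np.asarray(x, dtype=np.float64)
    if np.any(x <= 0) or np.any(x >= 1):
        raise ValueError("x must lie strictly inside (0, 1)")
    if a <= 0 or b <= 0 or phi <= 0:
        raise ValueError("a, b, phi must be positive")
    log_norm = gammaln(a + b) - gammaln(a) - gammaln(b)
    logf = (log_norm + b * np.log(phi) + (b - 1.0) * np.log(x)
            + (a - 1.0) * np.log1p(-x)
            - (a + b) * np.log1p((phi - 1.0) * x))
    out = np.exp(logf)
    return float(out) if out.ndim == 0 else out


def shrinkage_factor(phi, psi):
    """tau = 1 / (1 + phi * psi); 1 is total shrinkage, 0 none."""
    phi = np.asarray(phi, dtype=np.float64)
    psi = np.asarray(psi, dtype=np.float64)
    if np.any(phi < 0) or np.any(psi < 0):
        raise ValueError("phi and psi must be nonnegative")
    out = 1.0 / (1.0 + phi * psi)
    return float(out) if out.ndim == 0 else out


def _solve_spd(A: np.ndarray, rhs: np.ndarray,
               block_id: int = -1) -> np.ndarray:
    """Solve A x = rhs for symmetric positive-definite A with a jitter
    ladder on factorization failure."""
    for jitter in (0.0,) + JITTER_LADDER:
        try:
            M = A if jitter == 0.0 else A + jitter * np.eye(A.shape[0])
            c = cho_factor(M, lower=True, check_finite=False)
            return cho_solve(c, rhs, check_finite=False)
        except np.linalg.LinAlgError:
            continue
    cond = float(np.linalg.cond(A))
    raise np.linalg.LinAlgError(
        f"block {block_id}: SPD solve failed after jitter ladder "
        f"(condition estimate {cond:.3e})")


def posterior_mean_fixed_scales(betahat_std: np.ndarray, D: np.ndarray,
                                T_diag: np.ndarray,
                                block_id: int = -1) -> np.ndarray:
    """Posterior mean (D + T^{-1})^{-1} betahat at fixed scales.

    ``T_diag`` holds the per-SNP prior variance multipliers phi * psi_j
    (after any regularization floor); with D = I this reduces to the
    scalar rule (1 - tau_j) betahat_j.
    """
    T_diag = np.asarray(T_diag, dtype=np.float64)
    if np.any(T_diag <= 0):
        raise ValueError("T_diag must be strictly positive")
    A = np.asarray(D, dtype=np.float64).copy()
    idx = np.arange(A.shape[0])
    A[idx, idx] += 1.0 / T_diag
    return _solve_spd(A, np.asarray(betahat_std, dtype=np.float64), block_id)


def psi_marginal_density(psi, a: float, b: float):
    """Marginal mixing density of the local scale: beta-prime(a, b),
    p(psi) = B(a,b)^{-1} psi^{a-1} (1 + psi)^{-(a+b)}."""
    psi = np.asarray(psi, dtype=np.float64)
    log_norm = gammaln(a + b) - gammaln(a) - gammaln(b)
    return np.exp(log_norm + (a - 1.0) * np.log(psi)
                  - (a + b) * np.log1p(psi))


def marginal_prior_density(beta, a: float, b: float, phi: float,
                           sigma2_over_n: float,
                           tol: float = 1e-9) -> float:
    """Marginal prior density on an effect size, by quadrature over psi.

    Integrates N(beta; 0, sigma2_over_n * phi * psi) against the
    beta-prime(a, b) mixing density.  Diagnostic use only (prior plots).
    """
    if a <= 0 or b <= 0 or phi <= 0 or sigma2_over_n <= 0:
        raise ValueError("parameters must be positive")
    beta = float(beta)

    # integrate in u = log(psi): the normal kernel decays double-
    # exponentially as u -> -inf and the beta-prime tail exponentially as
    # u -> +inf, so adaptive quadrature converges for any beta
    def integrand(u: float) -> float:
        psi = np.exp(u)
        var = sigma2_over_n * phi * psi
        return (np.exp(-0.5 * beta * beta / var)
                / np.sqrt(2.0 * np.pi * var)
                * psi_marginal_density(psi, a, b) * psi)

    # the normal kernel peaks near psi = beta^2 / (sigma2_over_n * phi)
    u_peak = np.log(max(beta * beta / (sigma2_over_n * phi), 1e-12))
    lo, hi = min(u_peak, 0.0) - 60.0, max(u_peak, 0.0) + 90.0
    val, err = integrate.quad(integrand, lo, hi, epsabs=tol, epsrel=tol,
                              limit=500, points=[u_peak, 0.0])
    if not np.isfinite(val) or err > max(tol, 1e-6 * max(val, 1e-300)):
        raise ArithmeticError(
            f"quadrature failed: value {val}, error estimate {err}")
    return val


def tpb_cdf_grid(a: float, b: float, phi: float,
                 n_grid: int = 4096) -> tuple[np.ndarray, np.ndarray]:
    """Quadrature-based CDF of TPB(a, b, phi) on an interior grid,
    for diagnostics and distributional tests."""
    x = np.linspace(0.0, 1.0, n_grid + 1)
    mid = 0.5 * (x[1:] + x[:-1])
    pdf = tpb_density(mid, a, b, phi)
    cdf = np.concatenate([[0.0], np.cumsum(pdf) * (1.0 / n_grid)])
    cdf /= cdf[-1]
    return x, cdf
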