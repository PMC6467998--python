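"""Independent reference implementations used as oracles by the tests.

These are deliberately naive: an individual-level Gibbs sampler written
from residuals (no summary-statistics shortcuts), an exhaustive clumping
rule, and small closed-form helpers.  They must stay independent of the
package code paths they check.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import geninvgauss


def individual_level_gibbs(Z: np.ndarray, y: np.ndarray, *, a: float,
                           b: float, phi: float, n_iter: int,
                           n_burnin: int, seed: int,
                           rho_floor: float | None = None) -> dict:
    """Gibbs sampler on individual-level data (genotypes Z, phenotype y).

    Works directly with residuals; the only inputs are the raw data and
    the prior.  Returns posterior means of beta and traces.
    """
    rng = np.random.default_rng(seed)
    N, M = Z.shape
    beta = np.zeros(M)
    psi = np.ones(M)
    delta = np.ones(M)
    sigma2 = 1.0

    beta_sum = np.zeros(M)
    sigma2_trace = []
    n_used = 0
    ZtZ = Z.T @ Z
    Zty = Z.T @ y

    for it in range(n_iter):
        # beta | rest: N((Z'Z/N + T^-1)^-1 Z'y/N, sigma2/N (...)^-1)
        T = phi * psi
        if rho_floor is not None:
            T = np.minimum(T, 1.0 / rho_floor)
        A = ZtZ / N + np.diag(1.0 / T)
        L = np.linalg.cholesky(A)
        mean = np.linalg.solve(A, Zty / N)
        z = rng.standard_normal(M)
        beta = mean + np.sqrt(sigma2 / N) * np.linalg.solve(L.T, z)

        # psi | rest (GIG), delta | psi (gamma)
        chi = N * beta ** 2 / (sigma2 * phi)
        p_gig = a - 0.5
        psi = np.empty(M)
        for j in range(M):
            if chi[j] < 1e-16:
                psi[j] = rng.gamma(p_gig, 1.0 / delta[j])
            else:
                bb = np.sqrt(chi[j] * 2.0 * delta[j])
                psi[j] = geninvgauss.rvs(
                    p_gig, bb, scale=np.sqrt(chi[j] / (2.0 * delta[j])),
                    random_state=rng)
        if rho_floor is not None:
            # the method truncates the prior variance multiplier phi*psi
            # at 1/rho
            psi = np.minimum(psi, 1.0 / (rho_floor * phi))
        delta = rng.gamma(a + b, 1.0 / (psi + 1.0))

        # sigma2 | rest from actual residuals
        resid = y - Z @ beta
        shape = 0.5 * (N + M)
        scale = 0.5 * (resid @ resid + N * np.sum(beta ** 2 / (phi * psi)))
        sigma2 = scale / rng.gamma(shape, 1.0)
        sigma2_trace.append(sigma2)

        if it >= n_burnin:
            beta_sum += beta
            n_used += 1

    return {"beta_mean": beta_sum / n_used,
            "sigma2_trace": np.asarray(sigma2_trace)}


def brute_force_clump(table, r2_fn, window_bp: int,
                      r2_threshold: float) -> list:
    """Exhaustive application of the clumping rule.

    Visit SNPs by ascending (pval, pos, snp_id); keep a SNP unless it
    conflicts (same chromosome, center distance < window, r^2 above the
    threshold) with an already-kept SNP.  Returns kept snp_ids in the
    table's row order.
    """
    rows = table.to_dict("records")
    order = sorted(rows, key=lambda r: (r["pval"], r["pos"], r["snp_id"]))
    kept = []
    for r in order:
        conflict = False
        for k in kept:
            if k["chrom"] != r["chrom"]:
                continue
            if abs(k["pos"] - r["pos"]) >= window_bp:
                continue
            if r2_fn(k["snp_id"], r["snp_id"]) > r2_threshold:
                conflict = True
                break
        if not conflict:
            kept.append(r)
    kept_ids = {k["snp_id"] for k in kept}
    return [r["snp_id"] for r in rows if r["snp_id"] in kept_ids]


def gig_mean_bessel(p: float, chi: float, psi: float) -> float:
    """E[X] for GIG(p, chi, psi) from the Bessel-function moment formula."""
    from scipy.special import kv

    omega = np.sqrt(chi * psi)
    eta = np.sqrt(chi / psi)
    return eta * kv(p + 1.0, omega) / kv(p, omega)
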