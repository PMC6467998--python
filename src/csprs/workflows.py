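"""End-to-end simulation benchmark comparing polygenic-score methods.

One replicate: simulate a reference panel plus validation and testing
cohorts; draw an architecture; generate training summary statistics from
the sampling law of marginal estimates at the nominal GWAS size; build
weights with each method (unadjusted, P+T, LDpred-inf, grid-mode and auto
continuous-shrinkage); tune the tunable methods on the validation cohort;
and measure test-set R^2 and calibration slope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .baselines import (ClumpConfig, GenotypeR2Provider, InfConfig, clump,
                        ldpred_inf_weights, threshold_and_score_grid,
                        unadjusted_weights)
from .evaluation import ScoreSet, calibration_slope, tune
from .gibbs_sampler import PHI_SQRT_GRID, GibbsConfig, run_prscs
from .simulator import (DEFAULT_TESTING_N, DEFAULT_VALIDATION_N,
                        ArchitectureSpec, draw_effects, ld_blocks_from_cohort,
                        rss_sumstats, scale_effects_to_h2, simulate_genotypes,
                        sumstats_from_standardized)
from .sumstats_io import perallele_from_standardized

logger = logging.getLogger(__name__)

METHODS = ("unadjusted", "pt", "ldpred_inf", "prscs", "prscs_auto")


@dataclass
class BenchmarkConfig:
    """Study conditions for the desk-scale method comparison."""

    m: int = 5000
    n_blocks: int = 50
    family: str = "point_normal"
    n_causal: int = 100
    h2: float = 0.5
    n_gwas: int = 50_000
    n_ref: int = 503
    n_val: int = DEFAULT_VALIDATION_N
    n_test: int = DEFAULT_TESTING_N
    n_replicates: int = 20
    ld_decay: float = 0.9
    maf_range: tuple = (0.05, 0.5)
    n_iter: int = 1000
    n_burnin: int = 500
    phi_sqrt_grid: tuple = PHI_SQRT_GRID
    seed: int = 0
    mixture_counts: tuple = (10, 1000, 10000)


def _r2(y: np.ndarray, prs: np.ndarray) -> float:
    if np.std(prs) == 0:
        return 0.0
    c = np.corrcoef(y, prs)[0, 1]
    return float(c * c)


def run_replicate(cfg: BenchmarkConfig, seed: int) -> list[dict]:
    """One benchmark replicate; returns one record per method."""
    rng = np.random.default_rng(seed)
    n_total = cfg.n_ref + cfg.n_val + cfg.n_test
    cohort = simulate_genotypes(n_total, cfg.m, cfg.n_blocks,
                                ld_decay=cfg.ld_decay,
                                maf_range=cfg.maf_range, seed=rng)
    ref_rows = np.arange(cfg.n_ref)
    val_rows = np.arange(cfg.n_ref, cfg.n_ref + cfg.n_val)
    test_rows = np.arange(cfg.n_ref + cfg.n_val, n_total)

    blocks = ld_blocks_from_cohort(cohort, rows=ref_rows)
    spec = ArchitectureSpec(family=cfg.family, n_causal=cfg.n_causal,
                            h2=cfg.h2, mixture_counts=cfg.mixture_counts)
    beta_raw, _info = draw_effects(spec, cfg.m, rng)
    beta = scale_effects_to_h2(beta_raw, blocks, cfg.h2)

    hstats = rss_sumstats(beta, blocks, cfg.n_gwas, seed=rng, h2=cfg.h2)
    sst = sumstats_from_standardized(hstats, cohort.variants)
    maf = cohort.variants["maf"].to_numpy(dtype=np.float64)

    # validation / testing phenotypes
    noise_sd = np.sqrt(1.0 - cfg.h2)
    val = cohort.subset(val_rows)
    test = cohort.subset(test_rows)
    g_val = val.standardized() @ beta
    g_test = test.standardized() @ beta
    y_val = g_val + rng.normal(0.0, noise_sd, size=cfg.n_val)
    y_test = g_test + rng.normal(0.0, noise_sd, size=cfg.n_test)
    realized_h2 = float(g_test.var() / y_test.var())

    G_val = cohort.genotypes[val_rows]
    G_test = cohort.genotypes[test_rows]
    val_ids = np.array([f"V{i}" for i in range(cfg.n_val)])
    test_ids = np.array([f"T{i}" for i in range(cfg.n_test)])
    records = []

    def record(method, prs_test, selected=None, extra=None):
        rec = {"method": method, "r2": _r2(y_test, prs_test),
               "slope": (calibration_slope(y_test, prs_test)
                         if np.std(prs_test) > 0 else np.nan),
               "selected": selected, "realized_h2": realized_h2}
        if extra:
            rec.update(extra)
        records.append(rec)
        return rec

    # unadjusted
    w = unadjusted_weights(sst)
    record("unadjusted", G_test.astype(np.float64) @ w)

    # P+T, tuned over the threshold grid on the validation cohort
    provider = GenotypeR2Provider(cohort.genotypes[ref_rows],
                                  {s: i for i, s in
                                   enumerate(cohort.variants["snp_id"])})
    ccfg = ClumpConfig()
    retained = clump(sst, provider, ccfg)
    grid = threshold_and_score_grid(retained, sst, ccfg)
    prs_by_pt = {}
    for p_t, entry in grid.items():
        if entry["n_snps"] == 0:
            continue
        wv = entry["weights"]
        prs_by_pt[p_t] = (G_val.astype(np.float64) @ wv,
                          G_test.astype(np.float64) @ wv)
    tuned = tune(prs_by_pt,
                 ScoreSet(val_ids, np.zeros(cfg.n_val), y_val),
                 ScoreSet(test_ids, np.zeros(cfg.n_test), y_test))
    record("pt", prs_by_pt[tuned.selected][1], selected=tuned.selected)

    # LDpred-inf (h2 is an input, set to the simulation truth)
    w_inf = perallele_from_standardized(
        ldpred_inf_weights(hstats.betahat_std, blocks,
                           InfConfig(cfg.h2, cfg.m, cfg.n_gwas)), maf)
    record("ldpred_inf", G_test.astype(np.float64) @ w_inf)

    # grid-mode continuous shrinkage, phi tuned on validation
    prs_by_phi = {}
    for ps in cfg.phi_sqrt_grid:
        gcfg = GibbsConfig(n_iter=cfg.n_iter, n_burnin=cfg.n_burnin,
                           phi=ps ** 2,
                           seed=int(rng.integers(2 ** 31)))
        pe = run_prscs(hstats, blocks, gcfg, maf=maf)
        wv = pe.beta_perallele_mean
        prs_by_phi[ps] = (G_val.astype(np.float64) @ wv,
                          G_test.astype(np.float64) @ wv)
    tuned = tune(prs_by_phi,
                 ScoreSet(val_ids, np.zeros(cfg.n_val), y_val),
                 ScoreSet(test_ids, np.zeros(cfg.n_test), y_test))
    record("prscs", prs_by_phi[tuned.selected][1], selected=tuned.selected)

    # fully Bayesian global scale
    gcfg = GibbsConfig(n_iter=cfg.n_iter, n_burnin=cfg.n_burnin, phi="auto",
                       seed=int(rng.integers(2 ** 31)))
    pe = run_prscs(hstats, blocks, gcfg, maf=maf)
    record("prscs_auto", G_test.astype(np.float64) @ pe.beta_perallele_mean,
           extra={"phi_posterior_mean": pe.phi_posterior_mean})
    return records


def run_benchmark(cfg: BenchmarkConfig) -> pd.DataFrame:
    """Run all replicates; returns one row per (replicate, method)."""
    ss = np.random.SeedSequence(cfg.seed)
    rows = []
    for rep, child in enumerate(ss.spawn(cfg.n_replicates)):
        seed = int(child.generate_state(1)[0] % (2 ** 31))
        for rec in run_replicate(cfg, seed):
            rec["replicate"] = rep
            rows.append(rec)
        logger.info("replicate %d/%d done", rep + 1, cfg.n_replicates)
    return pd.DataFrame(rows)


def summarize_benchmark(table: pd.DataFrame) -> pd.DataFrame:
    """Mean and SD of test R^2 and calibration slope per method."""
    return (table.groupby("method")
            .agg(r2_mean=("r2", "mean"), r2_sd=("r2", "std"),
                 slope_mean=("slope", "mean"), slope_sd=("slope", "std"))
            .reindex(list(METHODS)))
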