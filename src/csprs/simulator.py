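"""Synthetic genotype/phenotype/summary-statistic generation.

Genotypes are produced by a Gaussian-threshold model: within each
contiguous block a latent AR(1) process with correlation ``ld_decay^|i-j|``
is thresholded, per haplotype, at the quantile of the SNP's allele
frequency, so genotype frequencies follow Hardy-Weinberg proportions and
LD decays geometrically within blocks while blocks are exactly
independent.  This is a controllable desk-scale stand-in for human LD and
deliberately matches the block-partition modeling assumption; it does not
reproduce the long-range or irregular LD of real panels.

Effect sizes are drawn on the standardized-genotype scale under several
architecture families (point-normal, point-t, point-gamma, three-component
normal mixture), rescaled so the genetic variance equals the target
heritability; phenotypes add independent normal noise so var(y) = 1.

Two summary-statistic routes are provided: a marginal GWAS on simulated
individuals, and a direct draw from the sampling law of marginal
estimates, betahat ~ N(D beta, (sigma^2/N) D) per block, which emulates a
much larger GWAS at negligible cost.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtri
from scipy.stats import t as t_dist

from . import plinkio
from .ld_reference import BlockPartition, LDBlock, compute_block_ld
from .sumstats_io import StandardizedEffects, SummaryStats

#: default inter-SNP spacing in base pairs
DEFAULT_SPACING_BP = 5_000


@dataclass
class ArchitectureSpec:
    """Effect-size distribution family with its parameters.

    ``n_causal`` is ignored for the normal mixture, which instead uses
    ``mixture_counts`` groups whose variance shares follow
    ``mixture_h2_shares``.
    """

    family: str = "point_normal"
    n_causal: int = 100
    h2: float = 0.5
    df: float = 4.0  # point_t
    shape: float = 2.0  # point_gamma
    mixture_counts: tuple = (10, 1000, 10000)
    mixture_h2_shares: tuple = (0.10, 0.20, 0.70)

    def __post_init__(self) -> None:
        if self.family not in ("point_normal", "point_t", "point_gamma",
                               "normal_mixture"):
            raise ValueError(f"unknown family {self.family!r}")
        if not (0 < self.h2 < 1):
            raise ValueError("h2 must lie in (0, 1)")
        if abs(sum(self.mixture_h2_shares) - 1.0) > 1e-12:
            raise ValueError("mixture shares must sum to 1")


@dataclass
class SimulatedCohort:
    """Genotypes with their variant table and block structure."""

    genotypes: np.ndarray  # (n, m) int8 A1 counts
    variants: pd.DataFrame  # chrom, snp_id, pos, a1, a2, maf (population)
    block_assignment: np.ndarray  # per-SNP block id
    seed: int | None = None
    beta_true: np.ndarray | None = None
    y: np.ndarray | None = None
    _z_cache: np.ndarray | None = field(default=None, repr=False)

    @property
    def n(self) -> int:
        return self.genotypes.shape[0]

    @property
    def m(self) -> int:
        return self.genotypes.shape[1]

    def standardized(self) -> np.ndarray:
        """Column-standardized genotype matrix (computed once)."""
        if self._z_cache is None:
            G = self.genotypes.astype(np.float64)
            mean = G.mean(axis=0)
            sd = G.std(axis=0)
            if np.any(sd == 0):
                raise ValueError("monomorphic SNP in cohort")
            self._z_cache = (G - mean) / sd
        return self._z_cache

    def subset(self, rows: np.ndarray) -> "SimulatedCohort":
        return SimulatedCohort(self.genotypes[rows], self.variants,
                               self.block_assignment, self.seed)


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_genotypes(n: int, m: int, n_blocks: int,
                       ld_decay: float = 0.9,
                       maf_range: tuple = (0.05, 0.5),
                       seed=0,
                       spacing_bp: int = DEFAULT_SPACING_BP,
                       chrom: str = "1") -> SimulatedCohort:
    """Gaussian-threshold genotypes with AR(1) within-block LD.

    ``m`` must divide into ``n_blocks`` contiguous equal blocks; per-SNP
    allele frequencies are uniform on ``maf_range`` (within [0.01, 0.5]).
    """
    if m % n_blocks:
        raise ValueError("m must be divisible by n_blocks")
    if not (0 <= ld_decay < 1):
        raise ValueError("ld_decay must lie in [0, 1)")
    lo, hi = maf_range
    if not (0.01 <= lo <= hi <= 0.5):
        raise ValueError("maf_range must lie within [0.01, 0.5]")
    rng = _as_rng(seed)
    mb = m // n_blocks
    maf = rng.uniform(lo, hi, size=m)
    thresh = ndtri(maf)

    geno = np.empty((n, m), dtype=np.int8)
    root = np.sqrt(1.0 - ld_decay ** 2)
    for hap in range(2):
        latent_prev = None
        for j in range(m):
            z = rng.standard_normal(n)
            if j % mb == 0 or ld_decay == 0.0:
                latent = z
            else:
                latent = ld_decay * latent_prev + root * z
            allele = latent < thresh[j]
            if hap == 0:
                geno[:, j] = allele
            else:
                geno[:, j] += allele
            latent_prev = latent

    variants = pd.DataFrame({
        "chrom": chrom,
        "snp_id": [f"rs{j + 1}" for j in range(m)],
        "pos": np.arange(m, dtype=np.int64) * spacing_bp + 1,
        "a1": "A", "a2": "G",
        "maf": maf,
    })
    block_assignment = np.repeat(np.arange(n_blocks), mb)
    return SimulatedCohort(geno, variants, block_assignment,
                           seed=None if isinstance(seed, np.random.Generator)
                           else seed)


def partition_from_cohort(cohort: SimulatedCohort,
                          spacing_bp: int = DEFAULT_SPACING_BP
                          ) -> BlockPartition:
    """BED-dialect partition whose intervals coincide with the simulated
    block boundaries."""
    ids = cohort.block_assignment
    n_blocks = int(ids.max()) + 1
    mb = cohort.m // n_blocks
    chrom = cohort.variants["chrom"].iloc[0]
    rows = pd.DataFrame({
        "chrom": chrom,
        "start": np.arange(n_blocks, dtype=np.int64) * mb * spacing_bp,
        "end": (np.arange(n_blocks, dtype=np.int64) + 1) * mb * spacing_bp,
    })
    return BlockPartition(rows)


def ld_blocks_from_cohort(cohort: SimulatedCohort,
                          rows: np.ndarray | None = None
                          ) -> list[LDBlock]:
    """Per-block LD matrices estimated from (a subset of) the cohort."""
    G = cohort.genotypes if rows is None else cohort.genotypes[rows]
    snp_ids = cohort.variants["snp_id"].to_numpy()
    blocks = []
    for bid in np.unique(cohort.block_assignment):
        cols = np.where(cohort.block_assignment == bid)[0]
        block, keep = compute_block_ld(G[:, cols],
                                       snp_ids=list(snp_ids[cols]),
                                       block_id=int(bid))
        if not keep.all():
            raise ValueError(f"monomorphic SNP in reference block {bid}")
        blocks.append(block)
    return blocks


def draw_effects(spec: ArchitectureSpec, m: int, seed=0
                 ) -> tuple[np.ndarray, dict]:
    """Draw standardized-scale effects (unit-free; rescale to a target
    heritability afterwards).

    Returns (beta, info); ``info`` records causal indices and, for the
    normal mixture, per-group index arrays.  Point-gamma effects keep the
    gamma's positive sign (the family is deliberately asymmetric).
    """
    rng = _as_rng(seed)
    beta = np.zeros(m)
    info: dict = {}
    if spec.family == "normal_mixture":
        counts = tuple(int(c) for c in spec.mixture_counts)
        if sum(counts) > m:
            raise ValueError(f"mixture counts {counts} exceed m={m}")
        chosen = rng.choice(m, size=sum(counts), replace=False)
        groups, start = [], 0
        for count, share in zip(counts, spec.mixture_h2_shares):
            idx = np.sort(chosen[start:start + count])
            start += count
            # per-SNP variance proportional to share / count so the
            # expected group variance shares match the targets
            beta[idx] = rng.normal(0.0, np.sqrt(share / count), size=count)
            groups.append(idx)
        info["groups"] = groups
        info["causal_idx"] = np.sort(chosen)
        return beta, info

    if spec.n_causal > m:
        raise ValueError(f"n_causal={spec.n_causal} exceeds m={m}")
    idx = np.sort(rng.choice(m, size=spec.n_causal, replace=False))
    if spec.family == "point_normal":
        draws = rng.standard_normal(spec.n_causal)
    elif spec.family == "point_t":
        draws = t_dist.rvs(spec.df, size=spec.n_causal, random_state=rng)
    elif spec.family == "point_gamma":
        draws = rng.gamma(spec.shape, 1.0, size=spec.n_causal)
    beta[idx] = draws
    info["causal_idx"] = idx
    return beta, info


def genetic_variance(beta: np.ndarray, blocks: list[LDBlock],
                     snp_index: dict | None = None) -> float:
    """beta' D beta accumulated over independent LD blocks."""
    total = 0.0
    offset = 0
    for blk in blocks:
        if snp_index is not None:
            idx = np.array([snp_index[s] for s in blk.snp_ids],
                           dtype=np.intp)
        else:
            idx = np.arange(offset, offset + len(blk))
            offset += len(blk)
        b = beta[idx]
        total += float(b @ (blk.D @ b))
    return total


def scale_effects_to_h2(beta: np.ndarray, blocks: list[LDBlock],
                        h2: float,
                        snp_index: dict | None = None) -> np.ndarray:
    """Rescale effects so beta' D beta = h2 under the given LD."""
    var_g = genetic_variance(beta, blocks, snp_index)
    if var_g <= 0:
        raise ValueError("zero genetic variance; cannot scale to h2 > 0")
    return beta * np.sqrt(h2 / var_g)


def simulate_phenotype(cohort: SimulatedCohort, beta_true: np.ndarray,
                       h2: float, seed=0) -> tuple[np.ndarray, np.ndarray]:
    """Phenotype y = g + e with the genetic component rescaled to
    variance ``h2`` and e ~ N(0, 1 - h2), so var(y) is about 1.

    Returns (y, beta_scaled): ``beta_scaled`` is the effect vector after
    the in-cohort rescaling and is the ground truth for recovery checks.
    """
    rng = _as_rng(seed)
    Z = cohort.standardized()
    g = Z @ beta_true
    var_g = g.var()
    if var_g <= 0:
        if h2 > 0:
            raise ValueError("zero genetic variance with h2 > 0")
        scale = 0.0
    else:
        scale = np.sqrt(h2 / var_g)
    g = g * scale
    if h2 >= 1.0:
        e = np.zeros(cohort.n)
    else:
        e = rng.normal(0.0, np.sqrt(1.0 - h2), size=cohort.n)
    y = g + e
    cohort.beta_true = beta_true * scale
    cohort.y = y
    return y, beta_true * scale


def gwas_sumstats(cohort: SimulatedCohort, y: np.ndarray
                  ) -> tuple[SummaryStats, StandardizedEffects]:
    """Marginal least-squares GWAS on the cohort.

    The standardized estimate is betahat_std = Z'y_std / N; two-sided
    p-values come from the t statistic of the marginal regression
    (N - 2 df); per-allele betas are on the original phenotype scale.
    """
    n = cohort.n
    Z = cohort.standardized()
    y = np.asarray(y, dtype=np.float64)
    y_sd = y.std()
    y_std = (y - y.mean()) / y_sd
    betahat_std = (Z.T @ y_std) / n

    r = np.clip(betahat_std, -0.999999, 0.999999)
    tstat = r * np.sqrt((n - 2) / (1.0 - r * r))
    pval = 2.0 * t_dist.sf(np.abs(tstat), df=n - 2)
    pval = np.clip(pval, 1e-323, 1.0)

    G = cohort.genotypes.astype(np.float64)
    sd_x = G.std(axis=0)
    beta_perallele = betahat_std * y_sd / sd_x
    freq = G.mean(axis=0) / 2.0

    table = cohort.variants[["snp_id", "chrom", "pos", "a1", "a2"]].copy()
    table["beta_marginal"] = beta_perallele
    table["pval"] = pval
    table["n_gwas"] = float(n)
    table["maf"] = np.minimum(freq, 1.0 - freq)
    sst = SummaryStats(table)
    index = {s: i for i, s in enumerate(table["snp_id"])}
    hstats = StandardizedEffects(betahat_std, np.full(cohort.m, float(n)),
                                 index)
    return sst, hstats


def rss_sumstats(beta_true: np.ndarray, blocks: list[LDBlock], n: int,
                 seed=0, sigma2: float | None = None,
                 h2: float | None = None,
                 snp_index: dict | None = None) -> StandardizedEffects:
    """Direct draw of marginal estimates from their sampling law,
    betahat ~ N(D beta, (sigma^2/N) D) per block.

    Supply either ``sigma2`` or ``h2`` (then sigma2 = 1 - h2).  Orders of
    magnitude faster than simulating N individuals.
    """
    if sigma2 is None:
        if h2 is None:
            raise ValueError("supply sigma2 or h2")
        sigma2 = 1.0 - h2
    rng = _as_rng(seed)
    m = len(beta_true)
    betahat = np.zeros(m)
    offset = 0
    ids = np.empty(m, dtype=object)
    for blk in blocks:
        if snp_index is not None:
            idx = np.array([snp_index[s] for s in blk.snp_ids],
                           dtype=np.intp)
        else:
            idx = np.arange(offset, offset + len(blk))
            offset += len(blk)
        D = blk.D + 1e-10 * np.eye(len(blk))
        L = np.linalg.cholesky(D)
        mean = blk.D @ beta_true[idx]
        betahat[idx] = mean + np.sqrt(sigma2 / n) * (
            L @ rng.standard_normal(len(blk)))
        for s, i in zip(blk.snp_ids, idx):
            ids[i] = s
    index = {s: i for i, s in enumerate(ids)}
    return StandardizedEffects(betahat, np.full(m, float(n)), index)


def sumstats_from_standardized(hstats: StandardizedEffects,
                               variants: pd.DataFrame) -> SummaryStats:
    """SummaryStats table (per-allele betas, normal-theory p-values) from
    standardized estimates, e.g. for running P+T on the direct
    summary-statistic route.  ``variants`` must align with ``hstats``
    order and carry snp_id, chrom, pos, a1, a2, maf."""
    from scipy.special import ndtr

    z = hstats.betahat_std * np.sqrt(hstats.n_gwas.astype(np.float64))
    pval = np.clip(2.0 * ndtr(-np.abs(z)), 1e-323, 1.0)
    maf = variants["maf"].to_numpy(dtype=np.float64)
    table = variants[["snp_id", "chrom", "pos", "a1", "a2", "maf"]].copy()
    table["beta_marginal"] = hstats.betahat_std / np.sqrt(
        2.0 * maf * (1.0 - maf))
    table["pval"] = pval
    table["n_gwas"] = hstats.n_gwas.astype(np.float64)
    return SummaryStats(table)


#: named scenario presets (desk-scale analogues of the study designs)
PRESETS = {
    "fig1_sparse_small": dict(m=5000, n_blocks=50, n_causal=100, h2=0.5,
                              family="point_normal"),
    "fig1_polygenic_small": dict(m=5000, n_blocks=50, n_causal=1000,
                                 h2=0.5, family="point_normal"),
    "h2_02_small": dict(m=5000, n_blocks=50, n_causal=100, h2=0.2,
                        family="point_normal"),
    "h2_08_small": dict(m=5000, n_blocks=50, n_causal=100, h2=0.8,
                        family="point_normal"),
    "point_t_small": dict(m=5000, n_blocks=50, n_causal=100, h2=0.5,
                          family="point_t"),
    "point_gamma_small": dict(m=5000, n_blocks=50, n_causal=100, h2=0.5,
                              family="point_gamma"),
    "mixture_small": dict(m=5000, n_blocks=50, h2=0.5,
                          family="normal_mixture",
                          mixture_counts=(10, 100, 1000)),
}

#: validation / testing cohort sizes used throughout
DEFAULT_VALIDATION_N = 3000
DEFAULT_TESTING_N = 3000


def write_cohort(prefix: str, cohort: SimulatedCohort,
                 y: np.ndarray | None = None) -> None:
    """Write the cohort as PLINK bed/bim/fam, a phenotype file and (when
    available) a tab-separated truth file of standardized effects."""
    bim = pd.DataFrame({
        "chrom": cohort.variants["chrom"],
        "snp_id": cohort.variants["snp_id"],
        "cm": 0,
        "pos": cohort.variants["pos"],
        "a1": cohort.variants["a1"],
        "a2": cohort.variants["a2"],
    })
    n = cohort.n
    fam = pd.DataFrame({
        "fid": [f"F{i}" for i in range(n)],
        "iid": [f"I{i}" for i in range(n)],
        "father": 0, "mother": 0, "sex": 0,
        "pheno": -9 if y is None else y,
    })
    plinkio.write_bed(prefix, cohort.genotypes, bim, fam)
    if y is not None:
        pheno = pd.DataFrame({"fid": fam["fid"], "iid": fam["iid"],
                              "pheno": y})
        pheno.to_csv(prefix + ".pheno", sep="\t", index=False, header=False,
                     float_format="%.6f")
    if cohort.beta_true is not None:
        truth = pd.DataFrame({"snp_id": cohort.variants["snp_id"],
                              "beta_true_std": cohort.beta_true})
        truth.to_csv(prefix + ".truth", sep="\t", index=False,
                     float_format="%.10e")
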