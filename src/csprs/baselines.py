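"""Comparator polygenic-score methods: unadjusted weights, LD clumping
with p-value thresholding (P+T), and the closed-form infinitesimal-model
posterior mean (LDpred-inf)."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .cs_prior import posterior_mean_fixed_scales
from .sumstats_io import SummaryStats

logger = logging.getLogger(__name__)

#: p-value threshold grid searched by P+T
DEFAULT_P_THRESHOLDS = (1e-8, 1e-7, 1e-6, 1e-5, 3e-5, 1e-4, 3e-4,
                        1e-3, 3e-3, 1e-2, 3e-2, 0.1, 0.3, 1.0)


@dataclass
class ClumpConfig:
    """Greedy LD-clumping rule: within ``window_bp`` of a more significant
    SNP, any SNP with squared correlation above ``r2_threshold`` is
    removed."""

    r2_threshold: float = 0.1
    window_bp: int = 250_000
    p_thresholds: tuple = DEFAULT_P_THRESHOLDS

    def __post_init__(self) -> None:
        pt = tuple(sorted(self.p_thresholds))
        if any(not (0 < p <= 1) for p in pt):
            raise ValueError("p_thresholds must lie in (0, 1]")
        self.p_thresholds = pt


@dataclass
class InfConfig:
    """Infinitesimal-model inputs: SNP heritability h2 (externally
    estimated), marker count M and GWAS sample size N."""

    h2: float
    M: int
    N: int

    def __post_init__(self) -> None:
        if not (0 < self.h2 < 1):
            raise ValueError("h2 must lie in (0, 1)")

    @property
    def ridge(self) -> float:
        return self.M / (self.N * self.h2)


def unadjusted_weights(sst: SummaryStats) -> np.ndarray:
    """Per-allele marginal effects, unchanged (the unadjusted PRS)."""
    return sst.table["beta_marginal"].to_numpy(dtype=np.float64).copy()


class GenotypeR2Provider:
    """Pairwise r^2 between SNPs computed from reference genotypes.

    Standardized columns are cached; SNPs absent from the reference are
    treated as unlinked (r^2 = 0) with a counted warning.
    """

    def __init__(self, genotypes: np.ndarray, snp_index: dict):
        G = np.asarray(genotypes, dtype=np.float64).copy()
        G[G < 0] = np.nan
        mean = np.nanmean(G, axis=0)
        idx = np.where(np.isnan(G))
        G[idx] = np.take(mean, idx[1])
        sd = G.std(axis=0)
        sd[sd == 0] = np.inf  # monomorphic -> r = 0
        self._Z = (G - G.mean(axis=0)) / sd
        self._n = G.shape[0]
        self._index = snp_index
        self.n_missing = 0

    def r2(self, snp_a: str, snp_b: str) -> float:
        ia = self._index.get(snp_a)
        ib = self._index.get(snp_b)
        if ia is None or ib is None:
            self.n_missing += 1
            return 0.0
        r = float(self._Z[:, ia] @ self._Z[:, ib]) / self._n
        return r * r

    def r2_with(self, snp_a: str, others) -> np.ndarray:
        """r^2 of one SNP against many, vectorized."""
        ia = self._index.get(snp_a)
        out = np.zeros(len(others))
        if ia is None:
            self.n_missing += len(others)
            return out
        cols = []
        keep = []
        for k, s in enumerate(others):
            ib = self._index.get(s)
            if ib is None:
                self.n_missing += 1
            else:
                cols.append(ib)
                keep.append(k)
        if cols:
            r = (self._Z[:, cols].T @ self._Z[:, ia]) / self._n
            out[np.asarray(keep)] = r ** 2
        return out


def clump(sst: SummaryStats, ld_lookup, cfg: ClumpConfig) -> np.ndarray:
    """Greedy LD clumping; returns the retained snp_ids in input order.

    SNPs are visited by ascending p (ties: smaller position, then
    lexicographic snp_id); each surviving index SNP removes every
    still-unremoved SNP on the same chromosome with center-to-center
    distance strictly below the window and r^2 above the threshold.
    ``ld_lookup`` provides ``r2(a, b)`` and optionally ``r2_with(a, ids)``.
    """
    t = sst.table
    if "pos" not in t.columns:
        raise ValueError("clumping requires chrom/pos")
    order = t.sort_values(["pval", "pos", "snp_id"],
                          kind="stable").index.to_numpy()
    removed = np.zeros(len(t), dtype=bool)
    chrom = t["chrom"].astype(str).to_numpy()
    pos = t["pos"].to_numpy(dtype=np.int64)
    ids = t["snp_id"].to_numpy()

    by_chrom: dict[str, np.ndarray] = {}
    for c in np.unique(chrom):
        rows = np.where(chrom == c)[0]
        by_chrom[c] = rows[np.argsort(pos[rows], kind="stable")]

    for i in order:
        if removed[i]:
            continue
        rows = by_chrom[chrom[i]]
        cpos = pos[rows]
        lo = np.searchsorted(cpos, pos[i] - cfg.window_bp + 1, side="left")
        hi = np.searchsorted(cpos, pos[i] + cfg.window_bp - 1, side="right")
        cand = rows[lo:hi]
        cand = cand[(cand != i) & ~removed[cand]]
        if len(cand) == 0:
            continue
        if hasattr(ld_lookup, "r2_with"):
            r2 = ld_lookup.r2_with(ids[i], ids[cand])
        else:
            r2 = np.array([ld_lookup.r2(ids[i], s) for s in ids[cand]])
        removed[cand[r2 > cfg.r2_threshold]] = True

    retained = ids[~removed]
    logger.info("clump: retained %d of %d SNPs", len(retained), len(t))
    return retained


def threshold_and_score_grid(retained, sst: SummaryStats,
                             cfg: ClumpConfig) -> dict:
    """Per-threshold P+T weight vectors aligned to the summary-statistics
    row order; weights are the per-allele marginal effects of retained
    SNPs passing p < P_T, zero elsewhere."""
    t = sst.table
    in_retained = t["snp_id"].isin(set(retained)).to_numpy()
    beta = t["beta_marginal"].to_numpy(dtype=np.float64)
    pval = t["pval"].to_numpy(dtype=np.float64)
    out = {}
    for p_t in cfg.p_thresholds:
        mask = in_retained & (pval < p_t)
        n_active = int(mask.sum())
        if n_active == 0:
            logger.warning("P_T=%g: no SNP passes; empty score", p_t)
        out[p_t] = {"weights": np.where(mask, beta, 0.0),
                    "n_snps": n_active}
    return out


def ldpred_inf_weights(betahat_std: np.ndarray, blocks,
                       cfg: InfConfig,
                       snp_index: dict | None = None) -> np.ndarray:
    """Infinitesimal-model posterior mean, per LD block:
    (D + (M / (N h2)) I)^{-1} betahat.  Standardized scale."""
    betahat = np.asarray(betahat_std, dtype=np.float64)
    out = np.zeros_like(betahat)
    offset = 0
    for blk in blocks:
        if snp_index is not None:
            idx = np.array([snp_index[s] for s in blk.snp_ids],
                           dtype=np.intp)
        else:
            idx = np.arange(offset, offset + len(blk))
            offset += len(blk)
        T_diag = np.full(len(blk), 1.0 / cfg.ridge)
        out[idx] = posterior_mean_fixed_scales(
            betahat[idx], blk.D, T_diag, block_id=blk.block_id)
    return out
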