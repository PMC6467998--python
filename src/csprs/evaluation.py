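"""Polygenic score computation, predictive metrics, tuning and
calibration.

Scores are additive: PRS_i = sum_j X_ij * b_j with X allele counts and b
per-allele weights.  Quantitative accuracy is incremental R^2 (full model
minus covariates-only); binary accuracy uses Nagelkerke's R^2 from the
likelihoods of covariate-only vs covariate-plus-PRS logistic models, plus
AUC, precision-recall AUC, and the odds ratio contrasting the top PRS
decile with the remainder.  Calibration is the OLS slope of the observed
phenotype on the PRS (1 = well calibrated).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.metrics import average_precision_score, roc_auc_score

logger = logging.getLogger(__name__)


@dataclass
class ScoreSet:
    """Aligned per-individual scores, phenotype and covariates."""

    sample_ids: np.ndarray
    prs: np.ndarray
    phenotype: np.ndarray
    covariates: np.ndarray | None = None
    binary: bool = False

    def __post_init__(self) -> None:
        self.prs = np.asarray(self.prs, dtype=np.float64)
        self.phenotype = np.asarray(self.phenotype, dtype=np.float64)
        n = len(self.sample_ids)
        if len(self.prs) != n or len(self.phenotype) != n:
            raise ValueError("misaligned score set")
        if np.any(~np.isfinite(self.prs)):
            raise ValueError("missing PRS values")
        if self.covariates is not None:
            self.covariates = np.atleast_2d(
                np.asarray(self.covariates, dtype=np.float64))
            if self.covariates.shape[0] != n:
                raise ValueError("covariate rows != samples")

    def __len__(self) -> int:
        return len(self.prs)


@dataclass
class EvalReport:
    r2: float = np.nan
    nagelkerke_r2: float = np.nan
    auc: float = np.nan
    pr_auc: float = np.nan
    or_top_decile: float = np.nan
    calibration_slope: float = np.nan
    per_split: dict = field(default_factory=dict)
    mean: dict = field(default_factory=dict)
    sd: dict = field(default_factory=dict)

    def primary(self, binary: bool) -> float:
        return self.nagelkerke_r2 if binary else self.r2

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("r2", "nagelkerke_r2", "auc", "pr_auc", "or_top_decile",
                 "calibration_slope")}


# ---------------------------------------------------------------------------
# scoring


def score_genotypes(genotypes: np.ndarray, weights: np.ndarray
                    ) -> np.ndarray:
    """Additive dot product of allele counts and per-allele weights;
    missing calls are mean-imputed per SNP."""
    G = np.asarray(genotypes, dtype=np.float64)
    w = np.asarray(weights, dtype=np.float64)
    if G.shape[1] != len(w):
        raise ValueError(f"{G.shape[1]} genotype columns, {len(w)} weights")
    if np.any(G < 0):
        G = G.copy()
        G[G < 0] = np.nan
        mean = np.nanmean(G, axis=0)
        idx = np.where(np.isnan(G))
        G[idx] = np.take(mean, idx[1])
    return G @ w


def score(genotypes: np.ndarray, geno_variants: pd.DataFrame,
          weights: pd.DataFrame) -> tuple[np.ndarray, dict]:
    """Allele-aware scoring of a weight table against target genotypes.

    ``geno_variants`` (snp_id, a1, a2) describes the genotype columns;
    ``weights`` carries snp_id, a1, a2, beta.  When a weight's alleles are
    swapped relative to the genotype coding its contribution is counted on
    2 - x copies; unmatched or irreconcilable SNPs are dropped and counted.
    """
    gv = geno_variants.reset_index(drop=True)
    col_of = {s: i for i, s in enumerate(gv["snp_id"])}
    n = genotypes.shape[0]
    prs = np.zeros(n)
    n_direct = n_flipped = n_dropped = 0
    w_cols, w_vals, flip_offset = [], [], 0.0
    for row in weights.itertuples():
        col = col_of.get(row.snp_id)
        if col is None:
            n_dropped += 1
            continue
        ga1, ga2 = gv["a1"].iat[col], gv["a2"].iat[col]
        if (row.a1, row.a2) == (ga1, ga2):
            w_cols.append(col)
            w_vals.append(row.beta)
            n_direct += 1
        elif (row.a1, row.a2) == (ga2, ga1):
            # effect allele is the genotype's other allele: x' = 2 - x
            w_cols.append(col)
            w_vals.append(-row.beta)
            flip_offset += 2.0 * row.beta
            n_flipped += 1
        else:
            n_dropped += 1
    if w_cols:
        prs = score_genotypes(genotypes[:, w_cols], np.asarray(w_vals))
    prs = prs + flip_offset
    report = {"n_direct": n_direct, "n_flipped": n_flipped,
              "n_dropped": n_dropped}
    if n_dropped:
        logger.warning("scoring: %d weight SNPs dropped (absent or "
                       "irreconcilable)", n_dropped)
    return prs, report


# ---------------------------------------------------------------------------
# metrics


def _design(covariates, extra=None):
    parts = []
    if covariates is not None:
        parts.append(np.atleast_2d(covariates))
    if extra is not None:
        parts.append(np.asarray(extra, dtype=np.float64).reshape(-1, 1))
    X = np.hstack(parts) if parts else np.empty((0, 0))
    return sm.add_constant(X, has_constant="add")


def _fit_logit(y, design):
    model = sm.Logit(y, design)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            return model.fit(disp=0, maxiter=200)
        except Exception:
            # separation makes the Newton step singular; BFGS still drives
            # the likelihood toward its supremum
            return model.fit(disp=0, maxiter=500, method="bfgs")


def nagelkerke_r2(score_set: ScoreSet) -> float:
    """Nagelkerke's R^2 of the PRS over a covariate-only logistic model.

    R^2 = [1 - (L_res / L_full)^{2/N}] / [1 - L_res^{2/N}], with L the
    likelihoods of the restricted (covariates only) and full (covariates
    plus PRS) models.
    """
    y = score_set.phenotype
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("Nagelkerke R^2 requires a 0/1 phenotype")
    n = len(y)
    if np.var(score_set.prs) == 0:
        return 0.0  # constant PRS adds nothing: L_full = L_res exactly

    full = _fit_logit(y, _design(score_set.covariates, score_set.prs))
    res = _fit_logit(y, _design(score_set.covariates, np.zeros(n))[:, :-1])
    if not (full.mle_retvals.get("converged", True)
            and res.mle_retvals.get("converged", True)):
        logger.warning("Nagelkerke: logistic fit did not fully converge "
                       "(possible separation); value reported anyway")
    r2 = 1.0 - np.exp(2.0 * (res.llf - full.llf) / n)
    r2_max = 1.0 - np.exp(2.0 * res.llf / n)
    return float(r2 / r2_max)


def incremental_r2(score_set: ScoreSet) -> float:
    """Quantitative R^2 of the PRS: full-model R^2 minus covariate-only
    R^2 (plain squared correlation when no covariates are supplied)."""
    y = score_set.phenotype
    if score_set.covariates is None:
        c = np.corrcoef(y, score_set.prs)[0, 1]
        return float(c * c)
    full = sm.OLS(y, _design(score_set.covariates, score_set.prs)).fit()
    res = sm.OLS(y, _design(score_set.covariates)).fit()
    return float(full.rsquared - res.rsquared)


def or_top_decile(score_set: ScoreSet, min_cases: int = 10) -> float:
    """Odds ratio contrasting the top 10% of PRS with the remaining 90%.
    Undefined (NaN) when the top decile holds fewer than ``min_cases``
    cases."""
    y = score_set.phenotype
    cut = np.quantile(score_set.prs, 0.9)
    top = score_set.prs >= cut
    a = float(np.sum(y[top] == 1))
    b = float(np.sum(y[top] == 0))
    c = float(np.sum(y[~top] == 1))
    d = float(np.sum(y[~top] == 0))
    if a < min_cases:
        logger.warning("top decile holds %d cases (< %d); OR undefined",
                       int(a), min_cases)
        return np.nan
    if b == 0 or c == 0:
        return np.inf
    return (a * d) / (b * c)


def calibration_slope(y: np.ndarray, prs: np.ndarray) -> float:
    """OLS slope of the observed phenotype on the PRS."""
    prs = np.asarray(prs, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    var = prs.var()
    if var == 0:
        raise ValueError("zero-variance PRS; calibration slope undefined")
    return float(np.cov(y, prs, ddof=0)[0, 1] / var)


def metrics(score_set: ScoreSet) -> EvalReport:
    """All applicable metrics for one scored split, covariate-adjusted."""
    rep = EvalReport()
    if score_set.binary:
        rep.nagelkerke_r2 = nagelkerke_r2(score_set)
        y = score_set.phenotype
        if score_set.covariates is not None:
            full = _fit_logit(y, _design(score_set.covariates,
                                         score_set.prs))
            pred = np.asarray(full.predict())
        else:
            pred = score_set.prs
        rep.auc = float(roc_auc_score(y, pred))
        rep.pr_auc = float(average_precision_score(y, pred))
        rep.or_top_decile = or_top_decile(score_set)
    else:
        rep.r2 = incremental_r2(score_set)
        rep.calibration_slope = calibration_slope(score_set.phenotype,
                                                  score_set.prs)
    return rep


def relative_improvement(r2_a: float, r2_b: float) -> float:
    """(R^2_A - R^2_B) / R^2_B."""
    if r2_b == 0:
        raise ValueError("relative improvement undefined for R^2_B = 0")
    return (r2_a - r2_b) / r2_b


# ---------------------------------------------------------------------------
# tuning


@dataclass
class TuneResult:
    selected: object
    validation_metric: float
    test_report: EvalReport
    validation_grid: dict = field(default_factory=dict)


def tune(prs_by_param: dict, validation: ScoreSet,
         testing: ScoreSet) -> TuneResult:
    """Select the parameter maximizing the primary metric on the
    validation split; report performance on the testing split only.

    ``prs_by_param`` maps each candidate parameter to a pair of PRS
    vectors (validation, testing).  Ties break toward the smallest
    parameter (strongest shrinkage).  Validation and testing sample sets
    must be disjoint.
    """
    if set(validation.sample_ids) & set(testing.sample_ids):
        raise ValueError("validation and testing samples overlap")
    best_param, best_val = None, -np.inf
    grid = {}
    for param in sorted(prs_by_param):
        prs_val, _ = prs_by_param[param]
        ss = ScoreSet(validation.sample_ids, prs_val, validation.phenotype,
                      validation.covariates, validation.binary)
        val = metrics(ss).primary(validation.binary)
        grid[param] = val
        if np.isfinite(val) and val > best_val:
            best_param, best_val = param, val
    if best_param is None:
        raise ValueError("no candidate produced a finite validation metric")
    _, prs_test = prs_by_param[best_param]
    ss_test = ScoreSet(testing.sample_ids, prs_test, testing.phenotype,
                       testing.covariates, testing.binary)
    return TuneResult(best_param, best_val, metrics(ss_test), grid)


def repeated_split_eval(prs_by_param: dict, phenotype: np.ndarray,
                        sample_ids: np.ndarray,
                        covariates: np.ndarray | None = None,
                        binary: bool = False, n_splits: int = 100,
                        val_frac: float = 1.0 / 3.0,
                        seed: int = 0) -> EvalReport:
    """Repeated random validation/testing splits with per-split tuning.

    ``prs_by_param`` maps parameters to full-cohort PRS vectors; each
    split tunes on a random ``val_frac`` of the data and evaluates on the
    remainder, and the report carries per-metric means and SDs across
    splits.
    """
    rng = np.random.default_rng(seed)
    n = len(phenotype)
    sample_ids = np.asarray(sample_ids)
    per_split: dict[str, list] = {k: [] for k in
                                  ("r2", "nagelkerke_r2", "auc", "pr_auc",
                                   "or_top_decile", "calibration_slope",
                                   "selected")}
    for _ in range(n_splits):
        perm = rng.permutation(n)
        n_val = int(round(val_frac * n))
        val_idx, test_idx = perm[:n_val], perm[n_val:]
        val = ScoreSet(sample_ids[val_idx],
                       np.zeros(n_val), phenotype[val_idx],
                       None if covariates is None else covariates[val_idx],
                       binary)
        test = ScoreSet(sample_ids[test_idx],
                        np.zeros(n - n_val), phenotype[test_idx],
                        None if covariates is None else covariates[test_idx],
                        binary)
        split_prs = {p: (v[val_idx], v[test_idx])
                     for p, v in prs_by_param.items()}
        result = tune(split_prs, val, test)
        per_split["selected"].append(result.selected)
        for k, v in result.test_report.to_dict().items():
            per_split[k].append(v)

    rep = EvalReport(per_split=per_split)
    for k in ("r2", "nagelkerke_r2", "auc", "pr_auc", "or_top_decile",
              "calibration_slope"):
        vals = np.asarray(per_split[k], dtype=np.float64)
        if np.all(np.isnan(vals)):
            continue
        rep.mean[k] = float(np.nanmean(vals))
        rep.sd[k] = float(np.nanstd(vals))
        setattr(rep, k, rep.mean[k])
    return rep
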