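"""Read, validate, harmonize and write GWAS summary statistics.

Summary statistics arrive as headered whitespace-delimited text with at
least the columns SNP, A1 (effect allele), A2 (other allele), BETA or OR,
and P; optionally N (per-SNP GWAS sample size) and MAF.  Records are
harmonized against a reference variant table (typically derived from the
LD panel's .bim plus allele frequencies) so that every effect is expressed
on the reference A1 allele, strand-ambiguous (A/T, C/G) markers are
removed, and rare reference variants (MAF < 1%) are excluded.

Two effect scales are used throughout the package:

* per-allele: the effect of one copy of A1 on the trait (log-odds for
  case-control traits), as published;
* standardized: the effect on a unit-variance phenotype of a standardized
  genotype.  The conversion is ``b_std = b_perallele * sqrt(2 f (1-f))``
  with f the A1 frequency.

The standardized marginal estimate fed to the samplers is reconstructed
from the p-value, the sign of the effect and N as sign(b) * |z(p)| / sqrt(N),
which is invariant to how the study scaled its phenotype.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtri

logger = logging.getLogger(__name__)

VALID_ALLELES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
AMBIGUOUS_PAIRS = frozenset({("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")})

#: canonical -> accepted column spellings (case-insensitive)
DEFAULT_DIALECT = {
    "snp_id": ("SNP", "ID", "RSID", "MARKERNAME"),
    "a1": ("A1", "EFFECT_ALLELE", "ALT"),
    "a2": ("A2", "OTHER_ALLELE", "REF"),
    "beta": ("BETA", "B", "EFFECT"),
    "odds_ratio": ("OR",),
    "pval": ("P", "PVAL", "P_VALUE"),
    "n_gwas": ("N", "NEFF", "N_GWAS"),
    "maf": ("MAF", "FRQ", "FREQ"),
    "se": ("SE", "STDERR"),
    "chrom": ("CHR", "CHROM"),
    "pos": ("BP", "POS", "POSITION"),
}

#: minimum reference minor allele frequency retained at harmonization
MIN_MAF = 0.01

#: smallest p-value accepted before clamping (denormal floor)
P_FLOOR = 1e-323

#: cap on |standardized marginal effect|; a standardized effect is a
#: correlation-scale quantity and cannot exceed 1
BETA_STD_CAP = 1.0


class SumstatsFormatError(ValueError):
    """Raised when a summary-statistics file violates the expected format."""


@dataclass
class SummaryStats:
    """Harmonized per-SNP marginal GWAS results.

    ``table`` columns: snp_id, a1, a2, beta_marginal, pval and optionally
    chrom, pos, n_gwas, maf.  ``beta_marginal`` is per-allele (log-odds for
    case-control studies).
    """

    table: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = self.table
        required = ["snp_id", "a1", "a2", "beta_marginal", "pval"]
        missing = [c for c in required if c not in t.columns]
        if missing:
            raise SumstatsFormatError(f"missing columns: {missing}")
        dup = t["snp_id"][t["snp_id"].duplicated()]
        if len(dup):
            raise SumstatsFormatError(
                f"duplicate snp_id: {sorted(set(dup))[:5]}")
        same = t["a1"] == t["a2"]
        if same.any():
            raise SumstatsFormatError(
                f"a1 == a2 for {t.loc[same, 'snp_id'].iloc[0]}")
        bad_p = ~((t["pval"] > 0) & (t["pval"] <= 1))
        if bad_p.any():
            raise SumstatsFormatError(
                f"p-value outside (0, 1] for {t.loc[bad_p, 'snp_id'].iloc[0]}")
        if {"chrom", "pos"}.issubset(t.columns):
            self.table = t.sort_values(
                ["chrom", "pos"], kind="stable").reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def snp_ids(self) -> np.ndarray:
        return self.table["snp_id"].to_numpy()


@dataclass
class StandardizedEffects:
    """Marginal effects on the standardized genotype/phenotype scale."""

    betahat_std: np.ndarray
    n_gwas: np.ndarray  # per-SNP sample sizes
    snp_index: dict  # snp_id -> position in betahat_std

    def __post_init__(self) -> None:
        self.betahat_std = np.asarray(self.betahat_std, dtype=np.float64)
        self.n_gwas = np.asarray(self.n_gwas)
        if not np.all(np.isfinite(self.betahat_std)):
            raise ValueError("non-finite standardized effects")
        if len(self.betahat_std) != len(self.snp_index):
            raise ValueError("snp_index length mismatch")

    @property
    def n_eff(self) -> int:
        """Single effective GWAS sample size (median of per-SNP N)."""
        return int(np.median(self.n_gwas))

    def __len__(self) -> int:
        return len(self.betahat_std)


def _resolve_columns(columns, dialect) -> dict:
    upper = {c.upper(): c for c in columns}
    resolved = {}
    for canonical, names in dialect.items():
        for name in names:
            if name.upper() in upper:
                resolved[canonical] = upper[name.upper()]
                break
    return resolved


def read_sumstats(path: str, dialect: dict | None = None,
                  n_gwas: float | None = None) -> SummaryStats:
    """Read a whitespace-delimited summary-statistics file.

    ``dialect`` maps canonical names (see :data:`DEFAULT_DIALECT`) to extra
    accepted column spellings.  OR columns are log-transformed to betas.
    Rows with non-ACGT or strand-ambiguous alleles are dropped (counted in
    ``meta``).  ``n_gwas`` supplies a global sample size when the file has
    no N column; per-SNP N takes precedence.
    """
    merged = {k: tuple(v) for k, v in DEFAULT_DIALECT.items()}
    if dialect:
        for k, v in dialect.items():
            if k not in merged:
                raise ValueError(f"unknown canonical column {k!r}")
            merged[k] = (v,) if isinstance(v, str) else tuple(v)

    raw = pd.read_csv(path, sep=r"\s+", dtype=str)
    cols = _resolve_columns(raw.columns, merged)
    for required in ("snp_id", "a1", "a2", "pval"):
        if required not in cols:
            raise SumstatsFormatError(
                f"{path}: no column found for {required!r} "
                f"(accepted: {merged[required]})")
    if "beta" not in cols and "odds_ratio" not in cols:
        raise SumstatsFormatError(
            f"{path}: neither BETA nor OR column found")

    out = pd.DataFrame({
        "snp_id": raw[cols["snp_id"]].astype(str),
        "a1": raw[cols["a1"]].astype(str).str.upper(),
        "a2": raw[cols["a2"]].astype(str).str.upper(),
    })

    def _numeric(canonical: str) -> np.ndarray:
        col = raw[cols[canonical]]
        vals = pd.to_numeric(col, errors="coerce")
        bad = vals.isna() & col.notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # header + 1-based
            raise SumstatsFormatError(
                f"{path}, line {line}: unparseable {canonical} value "
                f"{col[bad.idxmax()]!r}")
        return vals.to_numpy(dtype=np.float64)

    if "beta" in cols:
        out["beta_marginal"] = _numeric("beta")
    else:
        odds = _numeric("odds_ratio")
        if np.any(odds <= 0):
            raise SumstatsFormatError(f"{path}: non-positive odds ratio")
        out["beta_marginal"] = np.log(odds)

    pvals = _numeric("pval")
    n_zero = int(np.sum(pvals == 0))
    if n_zero:
        logger.warning("%s: %d p-values of 0 clamped to %g", path, n_zero,
                       P_FLOOR)
        pvals = np.maximum(pvals, P_FLOOR)
    out["pval"] = pvals

    if "n_gwas" in cols:
        out["n_gwas"] = _numeric("n_gwas")
    elif n_gwas is not None:
        out["n_gwas"] = float(n_gwas)
    if "maf" in cols:
        out["maf"] = _numeric("maf")
    if "se" in cols:
        out["se"] = _numeric("se")
    if "chrom" in cols:
        out["chrom"] = raw[cols["chrom"]].astype(str)
    if "pos" in cols:
        out["pos"] = _numeric("pos").astype(np.int64)

    valid = (out["a1"].isin(VALID_ALLELES) & out["a2"].isin(VALID_ALLELES)
             & (out["a1"] != out["a2"]))
    ambiguous = valid & np.array(
        [(r.a1, r.a2) in AMBIGUOUS_PAIRS for r in out.itertuples()],
        dtype=bool)
    keep = valid & ~ambiguous
    meta = {
        "n_read": len(out),
        "n_invalid_alleles": int((~valid).sum()),
        "n_ambiguous": int(ambiguous.sum()),
        "n_pval_clamped": n_zero,
    }
    if meta["n_invalid_alleles"] or meta["n_ambiguous"]:
        logger.info("%s: dropped %d rows with non-ACGT alleles, %d "
                    "strand-ambiguous rows", path,
                    meta["n_invalid_alleles"], meta["n_ambiguous"])
    return SummaryStats(out[keep].reset_index(drop=True), meta)


def harmonize(sst: SummaryStats, ref_variants: pd.DataFrame,
              min_maf: float = MIN_MAF) -> SummaryStats:
    """Align summary statistics to a reference variant table.

    ``ref_variants`` needs columns snp_id, a1, a2, maf and optionally
    chrom, pos.  Only SNPs present in both sets are kept.  When the
    summary-statistics alleles are swapped relative to the reference
    (optionally on the opposite strand) the beta sign is flipped and the
    alleles reordered; irreconcilable allele pairs and reference variants
    with MAF below ``min_maf`` are dropped.  Attrition counts are stored in
    ``meta`` and logged.
    """
    ref = ref_variants.drop_duplicates("snp_id").set_index("snp_id")
    t = sst.table
    present = t["snp_id"].isin(ref.index)
    t = t[present].reset_index(drop=True)
    r = ref.loc[t["snp_id"]]

    ra1 = r["a1"].to_numpy()
    ra2 = r["a2"].to_numpy()
    sa1 = t["a1"].to_numpy()
    sa2 = t["a2"].to_numpy()
    comp1 = np.array([_COMPLEMENT.get(a, "N") for a in sa1])
    comp2 = np.array([_COMPLEMENT.get(a, "N") for a in sa2])

    direct = (sa1 == ra1) & (sa2 == ra2)
    swapped = (sa1 == ra2) & (sa2 == ra1)
    flip_strand = (comp1 == ra1) & (comp2 == ra2) & ~direct & ~swapped
    swap_strand = (comp1 == ra2) & (comp2 == ra1) & ~direct & ~swapped
    matched = direct | swapped | flip_strand | swap_strand
    needs_sign_flip = swapped | swap_strand

    ambiguous = np.array(
        [(a, b) in AMBIGUOUS_PAIRS for a, b in zip(ra1, ra2)])
    maf = r["maf"].to_numpy(dtype=np.float64)
    minor = np.minimum(maf, 1.0 - maf)
    keep = matched & ~ambiguous & (minor >= min_maf)

    out = t[keep].copy().reset_index(drop=True)
    kept_flip = needs_sign_flip[keep]
    out["beta_marginal"] = np.where(
        kept_flip, -out["beta_marginal"], out["beta_marginal"])
    rk = r[keep]
    out["a1"] = rk["a1"].to_numpy()
    out["a2"] = rk["a2"].to_numpy()
    out["maf"] = rk["maf"].to_numpy(dtype=np.float64)
    for col in ("chrom", "pos"):
        if col in rk.columns:
            out[col] = rk[col].to_numpy()
    if "pos" in out.columns:
        out["pos"] = out["pos"].astype(np.int64)

    meta = dict(sst.meta)
    meta.update({
        "n_in": len(sst),
        "n_not_in_reference": int((~present).sum()),
        "n_allele_mismatch": int((~matched).sum()),
        "n_ambiguous_ref": int((matched & ambiguous).sum()),
        "n_low_maf": int((matched & ~ambiguous & (minor < min_maf)).sum()),
        "n_flipped": int(kept_flip.sum()),
        "n_kept": len(out),
    })
    logger.info(
        "harmonize: %(n_in)d in, %(n_kept)d kept (%(n_flipped)d sign-"
        "flipped); dropped %(n_not_in_reference)d absent from reference, "
        "%(n_allele_mismatch)d allele-mismatched, %(n_ambiguous_ref)d "
        "ambiguous, %(n_low_maf)d below the MAF floor", meta)
    return SummaryStats(out, meta)


def standardize_effects(sst: SummaryStats, route: str = "pval",
                        cap: float = BETA_STD_CAP) -> StandardizedEffects:
    """Convert marginal effects to the standardized scale.

    The default route reconstructs |beta_std| from the two-sided normal
    quantile of the p-value, z = Phi^{-1}(1 - p/2), as sign(b) * z / sqrt(N);
    ``route="beta_se"`` instead uses (beta / se) / sqrt(N) when an SE column
    is available.  Magnitudes are capped at ``cap`` with a warning.
    """
    t = sst.table
    if "n_gwas" not in t.columns:
        raise ValueError("standardize_effects requires per-SNP or global N "
                         "(read_sumstats n_gwas argument)")
    n = t["n_gwas"].to_numpy(dtype=np.float64)
    if np.any(n <= 0):
        raise ValueError("non-positive GWAS sample size")
    beta = t["beta_marginal"].to_numpy(dtype=np.float64)
    if route == "pval":
        p = np.maximum(t["pval"].to_numpy(dtype=np.float64), P_FLOOR)
        z = -ndtri(p / 2.0)  # |two-sided z|
        betahat = np.sign(beta) * z / np.sqrt(n)
    elif route == "beta_se":
        if "se" not in t.columns:
            raise ValueError("beta_se route requires an SE column")
        se = t["se"].to_numpy(dtype=np.float64)
        if np.any(se <= 0):
            raise ValueError("non-positive SE")
        betahat = (beta / se) / np.sqrt(n)
    else:
        raise ValueError(f"unknown route {route!r}")

    over = np.abs(betahat) > cap
    if over.any():
        logger.warning("%d standardized effects capped at %g",
                       int(over.sum()), cap)
        betahat = np.clip(betahat, -cap, cap)
    index = {s: i for i, s in enumerate(t["snp_id"])}
    return StandardizedEffects(betahat, n, index)


def perallele_from_standardized(beta_std: np.ndarray,
                                maf: np.ndarray) -> np.ndarray:
    """Per-allele effect from a standardized one via the genotype SD
    sqrt(2 f (1 - f)) under Hardy-Weinberg proportions."""
    sd = np.sqrt(2.0 * maf * (1.0 - maf))
    return np.asarray(beta_std, dtype=np.float64) / sd


def standardized_from_perallele(beta_perallele: np.ndarray,
                                maf: np.ndarray) -> np.ndarray:
    sd = np.sqrt(2.0 * maf * (1.0 - maf))
    return np.asarray(beta_perallele, dtype=np.float64) * sd


def write_posterior_effects(pe, path: str) -> None:
    """Write posterior per-allele weights as 6-column tab-separated text
    (chrom, snp_id, pos, a1, a2, effect), ordered by (chrom, pos)."""
    t = pe.to_frame() if hasattr(pe, "to_frame") else pe
    cols = ["chrom", "snp_id", "pos", "a1", "a2", "beta"]
    missing = [c for c in cols if c not in t.columns]
    if missing:
        raise ValueError(f"weight table missing columns {missing}")
    out = t[cols].sort_values(["chrom", "pos"], kind="stable")
    out.to_csv(path, sep="\t", header=False, index=False,
               float_format="%.10e")


def read_posterior_effects(path: str) -> pd.DataFrame:
    t = pd.read_csv(path, sep="\t", header=None,
                    names=["chrom", "snp_id", "pos", "a1", "a2", "beta"],
                    dtype={"chrom": str, "snp_id": str, "a1": str, "a2": str})
    t["pos"] = t["pos"].astype(np.int64)
    return t
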