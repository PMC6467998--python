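"""LD block partitions and per-block SNP correlation matrices.

The genome is split into approximately independent LD blocks (e.g. the
1703 European ldetect regions); all multivariate updates in the samplers
operate within a block, and LD between blocks is assumed to be zero.
Partitions are read from BED-dialect interval files (0-based, half-open);
SNP positions follow the 1-based .bim convention, so a SNP at 1-based
position p falls in block [start, end) when start < p <= end.

Block correlation matrices are estimated from a reference genotype panel:
columns are mean-imputed, standardized, and D = Z'Z / n_ref.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import plinkio

logger = logging.getLogger(__name__)


class PartitionFormatError(ValueError):
    pass


@dataclass
class BlockPartition:
    """Ordered, non-overlapping genomic intervals (chrom, start, end),
    half-open and 0-based."""

    blocks: pd.DataFrame  # columns chrom, start, end

    def __post_init__(self) -> None:
        b = self.blocks.copy()
        b["chrom"] = b["chrom"].astype(str)
        b["start"] = b["start"].astype(np.int64)
        b["end"] = b["end"].astype(np.int64)
        if (b["end"] <= b["start"]).any():
            bad = b[b["end"] <= b["start"]].iloc[0]
            raise PartitionFormatError(
                f"empty or inverted interval {bad.chrom}:{bad.start}-{bad.end}")
        b = b.sort_values(["chrom", "start"], kind="stable").reset_index(
            drop=True)
        for chrom, grp in b.groupby("chrom", sort=False):
            starts = grp["start"].to_numpy()
            ends = grp["end"].to_numpy()
            overlap = starts[1:] < ends[:-1]
            if overlap.any():
                i = int(np.argmax(overlap))
                raise PartitionFormatError(
                    f"overlapping intervals on {chrom}: "
                    f"[{starts[i]},{ends[i]}) and [{starts[i+1]},{ends[i+1]})")
        self.blocks = b

    def __len__(self) -> int:
        return len(self.blocks)


@dataclass
class LDBlock:
    """A contiguous SNP set with its reference correlation matrix."""

    snp_ids: list
    D: np.ndarray
    n_ref: int
    block_id: int = -1

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=np.float64)
        m = len(self.snp_ids)
        if self.D.shape != (m, m):
            raise ValueError(f"D shape {self.D.shape} != ({m}, {m})")
        if not np.allclose(self.D, self.D.T, atol=1e-10):
            raise ValueError("D not symmetric")

    def __len__(self) -> int:
        return len(self.snp_ids)


def load_partition(path: str) -> BlockPartition:
    """Read a BED-dialect partition file (chrom, start, end; 0-based,
    half-open).  A header line starting with 'chr'/'track'/'#' is skipped."""
    rows = pd.read_csv(path, sep=r"\s+", header=None, comment="#",
                       names=["chrom", "start", "end"], dtype=str)
    numeric = pd.to_numeric(rows["start"], errors="coerce")
    rows = rows[numeric.notna()].copy()
    rows["start"] = rows["start"].astype(np.int64)
    rows["end"] = rows["end"].astype(np.int64)
    return BlockPartition(rows)


def compute_block_ld(genotypes: np.ndarray, shrink_target: float = 0.0,
                     snp_ids: list | None = None,
                     block_id: int = -1) -> tuple[LDBlock, np.ndarray]:
    """Correlation matrix of one block from reference genotypes.

    Missing calls (negative or NaN) are mean-imputed per SNP before
    standardization.  Monomorphic SNPs are dropped; the returned boolean
    mask marks the retained columns.  ``shrink_target`` linearly shrinks
    D toward the identity: D <- (1 - s) D + s I.
    """
    G = np.asarray(genotypes, dtype=np.float64)
    n, m = G.shape
    if n < 2:
        raise ValueError("need >= 2 reference samples")
    G = G.copy()
    G[G < 0] = np.nan
    col_mean = np.nanmean(G, axis=0)
    nan_idx = np.where(np.isnan(G))
    G[nan_idx] = np.take(col_mean, nan_idx[1])

    mean = G.mean(axis=0)
    sd = G.std(axis=0)
    keep = sd > 0
    if not keep.all():
        logger.warning("dropping %d monomorphic SNPs from block %d",
                       int((~keep).sum()), block_id)
    Z = (G[:, keep] - mean[keep]) / sd[keep]
    D = (Z.T @ Z) / n
    if shrink_target:
        D = (1.0 - shrink_target) * D
        np.fill_diagonal(D, 1.0)
    D = 0.5 * (D + D.T)
    if snp_ids is None:
        snp_ids = list(np.arange(m)[keep])
    else:
        snp_ids = [s for s, k in zip(snp_ids, keep) if k]
    return LDBlock(snp_ids, D, n, block_id), keep


def map_snps_to_blocks(sst, part: BlockPartition) -> list[np.ndarray]:
    """Assign each harmonized SNP to a partition block.

    Returns index arrays into the summary-statistics row order, one per
    non-empty block, in partition order.  SNPs falling in inter-block gaps
    (or beyond the last interval) attach to the nearest preceding block of
    their chromosome; SNPs before the first interval attach to the first
    block.  A SNP on a chromosome absent from the partition is an error.
    """
    t = sst.table if hasattr(sst, "table") else sst
    if "pos" not in t.columns or "chrom" not in t.columns:
        raise ValueError("summary statistics lack chrom/pos (harmonize "
                         "against a reference first)")
    blocks = part.blocks
    assignments: dict[int, list[int]] = {}
    for chrom, grp in t.groupby(t["chrom"].astype(str), sort=False):
        cblocks = blocks[blocks["chrom"] == chrom]
        if cblocks.empty:
            raise ValueError(f"chromosome {chrom!r} absent from partition")
        starts = cblocks["start"].to_numpy()
        block_rows = cblocks.index.to_numpy()
        pos0 = grp["pos"].to_numpy(dtype=np.int64) - 1  # 0-based
        # nearest interval starting at or before the SNP; before the first
        # interval -> first block
        k = np.searchsorted(starts, pos0, side="right") - 1
        k = np.clip(k, 0, len(starts) - 1)
        for row_idx, blk in zip(grp.index.to_numpy(), block_rows[k]):
            assignments.setdefault(int(blk), []).append(int(row_idx))
    return [np.asarray(assignments[b], dtype=np.intp)
            for b in sorted(assignments)]


@dataclass
class ReferencePanel:
    """Reference genotypes with their variant table and allele frequencies."""

    genotypes: np.ndarray  # (n, m) A1 allele counts
    variants: pd.DataFrame  # snp_id, chrom, pos, a1, a2, maf
    snp_index: dict = field(init=False)

    def __post_init__(self) -> None:
        self.snp_index = {s: i for i, s in
                          enumerate(self.variants["snp_id"])}

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @classmethod
    def from_plink(cls, prefix: str) -> "ReferencePanel":
        geno, bim, _fam = plinkio.read_bed(prefix)
        freq = plinkio.allele_frequencies(geno)
        variants = pd.DataFrame({
            "snp_id": bim["snp_id"], "chrom": bim["chrom"],
            "pos": bim["pos"], "a1": bim["a1"], "a2": bim["a2"],
            "maf": freq,
        })
        return cls(geno, variants)


def build_ld_blocks(panel: ReferencePanel, sst,
                    part: BlockPartition,
                    shrink_target: float = 0.0
                    ) -> tuple[list[LDBlock], list[np.ndarray]]:
    """Per-block LD matrices for the harmonized SNP set.

    Returns (blocks, index arrays into the summary-statistics order).
    Monomorphic reference SNPs are dropped from both.
    """
    t = sst.table if hasattr(sst, "table") else sst
    snp_ids = t["snp_id"].to_numpy()
    groups = map_snps_to_blocks(sst, part)
    blocks: list[LDBlock] = []
    kept_groups: list[np.ndarray] = []
    for bid, idx in enumerate(groups):
        ids = snp_ids[idx]
        cols = [panel.snp_index[s] for s in ids]
        block, keep = compute_block_ld(
            panel.genotypes[:, cols], shrink_target=shrink_target,
            snp_ids=list(ids), block_id=bid)
        blocks.append(block)
        kept_groups.append(idx[keep])
    return blocks, kept_groups
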