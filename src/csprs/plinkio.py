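"""Minimal PLINK 1 binary fileset (.bed/.bim/.fam) reader and writer.

Implements the variant-major .bed layout: a 3-byte magic header
(0x6c, 0x1b, 0x01) followed by ceil(N/4) bytes per variant, two bits per
sample.  Two-bit codes follow the PLINK 1 convention:

    00 -> homozygous A1 (2 copies of the effect allele)
    01 -> missing
    10 -> heterozygous
    11 -> homozygous A2 (0 copies of A1)

Genotypes are returned as A1 allele counts (0/1/2) in an ``int8`` matrix of
shape (n_samples, n_variants), with missing calls encoded as -1.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

_MAGIC = bytes([0x6C, 0x1B, 0x01])

# two-bit code -> A1 dosage (missing = -1)
_CODE_TO_DOSAGE = np.array([2, -1, 1, 0], dtype=np.int8)
_DOSAGE_TO_CODE = {2: 0b00, -1: 0b01, 1: 0b10, 0: 0b11}

BIM_COLUMNS = ["chrom", "snp_id", "cm", "pos", "a1", "a2"]
FAM_COLUMNS = ["fid", "iid", "father", "mother", "sex", "pheno"]


def read_bim(path: str) -> pd.DataFrame:
    bim = pd.read_csv(
        path, sep=r"\s+", header=None, names=BIM_COLUMNS,
        dtype={"chrom": str, "snp_id": str, "a1": str, "a2": str},
    )
    bim["pos"] = bim["pos"].astype(np.int64)
    return bim


def read_fam(path: str) -> pd.DataFrame:
    return pd.read_csv(
        path, sep=r"\s+", header=None, names=FAM_COLUMNS,
        dtype={"fid": str, "iid": str},
    )


def read_bed(prefix: str) -> tuple[np.ndarray, pd.DataFrame, pd.DataFrame]:
    """Read ``prefix``.bed/.bim/.fam.

    Returns
    -------
    genotypes : (n_samples, n_variants) int8 array of A1 allele counts,
        missing calls as -1.
    bim, fam : variant and sample tables.
    """
    bim = read_bim(prefix + ".bim")
    fam = read_fam(prefix + ".fam")
    n, m = len(fam), len(bim)
    with open(prefix + ".bed", "rb") as fh:
        magic = fh.read(3)
        if magic != _MAGIC:
            raise ValueError(f"{prefix}.bed: bad magic bytes {magic!r}; "
                             "not a variant-major PLINK 1 .bed file")
        raw = np.frombuffer(fh.read(), dtype=np.uint8)
    bytes_per_variant = (n + 3) // 4
    if raw.size != bytes_per_variant * m:
        raise ValueError(
            f"{prefix}.bed: expected {bytes_per_variant * m} data bytes "
            f"for {n} samples x {m} variants, found {raw.size}")
    raw = raw.reshape(m, bytes_per_variant)
    # unpack 2-bit fields, little-endian within each byte
    codes = np.empty((m, bytes_per_variant * 4), dtype=np.uint8)
    codes[:, 0::4] = raw & 0b11
    codes[:, 1::4] = (raw >> 2) & 0b11
    codes[:, 2::4] = (raw >> 4) & 0b11
    codes[:, 3::4] = (raw >> 6) & 0b11
    geno = _CODE_TO_DOSAGE[codes[:, :n]]
    return np.ascontiguousarray(geno.T), bim, fam


def write_bed(prefix: str, genotypes: np.ndarray, bim: pd.DataFrame,
              fam: pd.DataFrame | None = None) -> None:
    """Write a variant-major PLINK 1 fileset.

    ``genotypes`` holds A1 allele counts (0/1/2, -1 for missing), shape
    (n_samples, n_variants).  ``bim`` must carry the columns of
    :data:`BIM_COLUMNS` (``cm`` defaults to 0 if absent).
    """
    geno = np.asarray(genotypes)
    n, m = geno.shape
    if len(bim) != m:
        raise ValueError(f"bim has {len(bim)} rows for {m} variants")
    if fam is None:
        fam = pd.DataFrame({
            "fid": [f"F{i}" for i in range(n)],
            "iid": [f"I{i}" for i in range(n)],
            "father": 0, "mother": 0, "sex": 0, "pheno": -9,
        })

    lut = np.empty(4, dtype=np.uint8)
    for dosage, code in _DOSAGE_TO_CODE.items():
        lut[dosage if dosage >= 0 else 3] = code  # index 3 <- missing (-1)
    idx = geno.T.astype(np.int64)
    idx[idx < 0] = 3
    codes = lut[idx]  # (m, n)

    pad = (-n) % 4
    if pad:
        codes = np.concatenate(
            [codes, np.zeros((m, pad), dtype=np.uint8)], axis=1)
    packed = (codes[:, 0::4]
              | (codes[:, 1::4] << 2)
              | (codes[:, 2::4] << 4)
              | (codes[:, 3::4] << 6)).astype(np.uint8)

    with open(prefix + ".bed", "wb") as fh:
        fh.write(_MAGIC)
        fh.write(packed.tobytes())

    out = bim.copy()
    if "cm" not in out.columns:
        out["cm"] = 0
    out[BIM_COLUMNS].to_csv(prefix + ".bim", sep="\t", header=False,
                            index=False)
    fam[FAM_COLUMNS].to_csv(prefix + ".fam", sep="\t", header=False,
                            index=False)


def allele_frequencies(genotypes: np.ndarray) -> np.ndarray:
    """Per-variant A1 allele frequency, ignoring missing calls."""
    geno = np.asarray(genotypes, dtype=np.float64)
    mask = geno >= 0
    with np.errstate(invalid="ignore"):
        freq = np.where(mask, geno, 0.0).sum(axis=0) / (2.0 * mask.sum(axis=0))
    return freq


def plink_prefix_exists(prefix: str) -> bool:
    return all(os.path.exists(prefix + ext) for ext in (".bed", ".bim", ".fam"))
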