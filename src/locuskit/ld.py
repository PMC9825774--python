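"""Reference genotype panels and on-the-fly linkage disequilibrium.

Reads PLINK 1 binary triples (.bed/.bim/.fam) into an in-memory dosage
matrix and computes pairwise LD as the squared Pearson correlation of
unphased allele dosages (composite LD).  Missing genotypes are
mean-imputed per variant before correlation; a variant left without
variance is monomorphic and yields a missing r².

The .bed format is decoded per the published PLINK 1 specification:
magic bytes 0x6C 0x1B, mode byte 0x01 (variant-major), two bits per
sample packed little-endian within each byte, each variant padded to a
whole byte.  Code 00 means two copies of the first .bim allele, 10 one
copy, 11 zero copies, and 01 a missing genotype.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .sumstats import normalize_chrom

PLINK_MAGIC = bytes((0x6C, 0x1B))
PLINK_MODE_VARIANT_MAJOR = 0x01

#: dosage value (copies of allele_1) for each 2-bit code 0b00..0b11
_CODE_TO_DOSAGE = np.array([2.0, np.nan, 1.0, 0.0])


class PlinkFormatError(ValueError):
    """The .bed file does not conform to the PLINK 1 binary format."""


class MonomorphicIndexError(ValueError):
    """The designated index variant has no variance in the panel."""


class EmptyRegionError(ValueError):
    """A region query selected zero variants."""


@dataclass
class GenotypePanel:
    """Reference genotypes: samples x variants dosages plus metadata.

    ``genotypes[i, j]`` counts copies of ``allele_1`` of variant ``j``
    carried by sample ``i`` (0, 1, 2, or NaN for missing).
    """

    samples: pd.DataFrame  # columns: fid, iid
    variants: pd.DataFrame  # columns: snp_id, chrom, pos, allele_1, allele_2
    genotypes: np.ndarray  # float (n_samples, n_variants), NaN = missing

    def __post_init__(self) -> None:
        if self.genotypes.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"genotype matrix shape {self.genotypes.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def variant_index(self, key) -> int:
        """Locate a variant by integer index, snp_id, or (chrom, pos)."""
        if isinstance(key, (int, np.integer)):
            if not 0 <= key < self.n_variants:
                raise KeyError(f"variant index {key} out of range")
            return int(key)
        if isinstance(key, str):
            hits = np.flatnonzero(self.variants["snp_id"].to_numpy() == key)
            if hits.size == 0:
                raise KeyError(f"variant id {key!r} not in panel")
            return int(hits[0])
        chrom, pos = key
        chrom = normalize_chrom([chrom]).iloc[0]
        mask = (self.variants["chrom"] == chrom) & (self.variants["pos"] == int(pos))
        hits = np.flatnonzero(mask.to_numpy())
        if hits.size == 0:
            raise KeyError(f"no variant at {chrom}:{pos} in panel")
        return int(hits[0])

    def region_indices(self, chrom, start: int, end: int) -> np.ndarray:
        """Indices of variants with ``start <= pos <= end`` on ``chrom``."""
        chrom = normalize_chrom([chrom]).iloc[0]
        mask = (
            (self.variants["chrom"] == chrom)
            & (self.variants["pos"] >= int(start))
            & (self.variants["pos"] <= int(end))
        )
        return np.flatnonzero(mask.to_numpy())


@dataclass
class LDResult:
    """r² of a set of target variants against one index variant."""

    index: int  # column index of the index variant in the panel
    target_indices: np.ndarray
    r2: np.ndarray  # aligned with target_indices; NaN = monomorphic target
    n_samples: int


def unique_entry_count(n_variants: int) -> int:
    """Number of unique entries of a symmetric n x n matrix: n(n+1)/2.

    This is the matrix-size accounting used when reasoning about very
    large LD heatmaps (e.g. the ~66,000-SNP MHC panel).
    """
    n = int(n_variants)
    return n * (n + 1) // 2


def read_plink(prefix: str | Path) -> GenotypePanel:
    """Read a PLINK 1 ``.bed``/``.bim``/``.fam`` triple.

    ``prefix`` names the files without extension.  The .bed payload must
    be variant-major; its byte length is cross-checked against the .bim
    and .fam line counts.
    """
    prefix = Path(prefix)
    bed, bim, fam = (Path(f"{prefix}{s}") for s in (".bed", ".bim", ".fam"))
    for f in (bed, bim, fam):
        if not f.exists():
            raise FileNotFoundError(f"missing PLINK file: {f}")

    fam_df = pd.read_csv(
        fam, sep=r"\s+", header=None,
        names=["fid", "iid", "father", "mother", "sex", "phenotype"],
        dtype={"fid": str, "iid": str},
    )
    bim_df = pd.read_csv(
        bim, sep=r"\s+", header=None,
        names=["chrom", "snp_id", "cm", "pos", "allele_1", "allele_2"],
        dtype={"chrom": str, "snp_id": str, "allele_1": str, "allele_2": str},
    )
    bim_df["chrom"] = normalize_chrom(bim_df["chrom"])
    n_samples, n_variants = len(fam_df), len(bim_df)

    raw = np.fromfile(bed, dtype=np.uint8)
    if raw[:2].tobytes() != PLINK_MAGIC:
        raise PlinkFormatError(
            f"{bed}: bad magic bytes {raw[:2].tobytes()!r}, expected 6c 1b"
        )
    if raw[2] != PLINK_MODE_VARIANT_MAJOR:
        raise PlinkFormatError(f"{bed}: mode byte {raw[2]:#x} is not variant-major (0x01)")

    bytes_per_variant = (n_samples + 3) // 4
    payload = raw[3:]
    if payload.size != bytes_per_variant * n_variants:
        raise PlinkFormatError(
            f"{bed}: payload of {payload.size} bytes does not match "
            f"{n_variants} variants x {bytes_per_variant} bytes/variant"
        )

    blocks = payload.reshape(n_variants, bytes_per_variant)
    # unpack 2-bit codes, little-endian within each byte
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    codes = (blocks[:, :, None] >> shifts) & 0b11  # (variants, bytes, 4)
    codes = codes.reshape(n_variants, -1)[:, :n_samples]
    genotypes = _CODE_TO_DOSAGE[codes].T  # (samples, variants)

    samples = fam_df[["fid", "iid"]]
    variants = bim_df[["snp_id", "chrom", "pos", "allele_1", "allele_2"]]
    return GenotypePanel(samples=samples, variants=variants,
                         genotypes=np.ascontiguousarray(genotypes))


def _impute_and_center(x: np.ndarray) -> np.ndarray:
    """Mean-impute missing dosages per column, then center.

    An all-missing column imputes to its (undefined) mean of zero
    variance, i.e. it is treated as monomorphic downstream.
    """
    x = np.array(x, dtype=float, copy=True)
    if x.ndim == 1:
        x = x[:, None]
    missing = np.isnan(x)
    n_obs = (~missing).sum(axis=0)
    with np.errstate(invalid="ignore"):
        col_mean = np.where(n_obs > 0, np.nansum(x, axis=0) / np.maximum(n_obs, 1), 0.0)
    x[missing] = np.broadcast_to(col_mean, x.shape)[missing]
    return x - x.mean(axis=0)


def ld_r2(panel: GenotypePanel, index, targets=None) -> LDResult:
    """r² between one index variant and a set of target variants.

    ``index`` may be an integer column index, an snp_id, or a
    (chrom, pos) pair; ``targets`` is an iterable of the same (default:
    every variant in the panel).  Monomorphic targets yield NaN; a
    monomorphic index raises :class:`MonomorphicIndexError`.
    """
    i = panel.variant_index(index)
    if targets is None:
        t_idx = np.arange(panel.n_variants)
    else:
        t_idx = np.array([panel.variant_index(t) for t in np.atleast_1d(targets)])

    x = _impute_and_center(panel.genotypes[:, [i]])[:, 0]
    sx = np.sqrt((x ** 2).sum())
    if sx == 0:
        snp = panel.variants["snp_id"].iloc[i]
        raise MonomorphicIndexError(
            f"index variant {snp!r} is monomorphic in the panel; cannot color by LD"
        )
    y = _impute_and_center(panel.genotypes[:, t_idx])
    sy = np.sqrt((y ** 2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (x @ y) / (sx * sy)
    r2 = np.where(sy > 0, r ** 2, np.nan)
    return LDResult(index=i, target_indices=t_idx, r2=r2, n_samples=panel.n_samples)


def ld_matrix(panel: GenotypePanel, region=None) -> np.ndarray:
    """Symmetric matrix of pairwise r² over a region (or the whole panel).

    ``region`` is either a (chrom, start, end) triple or an explicit
    array of variant indices.  Entries involving a monomorphic variant
    are NaN; polymorphic diagonal entries are exactly 1.
    """
    if region is None:
        idx = np.arange(panel.n_variants)
    elif isinstance(region, tuple) and len(region) == 3:
        idx = panel.region_indices(*region)
    else:
        idx = np.asarray(region, dtype=int)
    if idx.size == 0:
        raise EmptyRegionError("region selects zero variants")

    x = _impute_and_center(panel.genotypes[:, idx])
    norms = np.sqrt((x ** 2).sum(axis=0))
    poly = norms > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        xn = np.where(poly, x / np.where(poly, norms, 1.0), np.nan)
    r = xn.T @ xn
    r2 = r ** 2
    # exact unit diagonal for polymorphic variants, symmetric by construction
    np.fill_diagonal(r2, np.where(poly, 1.0, np.nan))
    r2 = (r2 + r2.T) / 2.0
    np.clip(r2, 0.0, 1.0, out=r2)
    return r2
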