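"""Harmonization ("munging") of GWAS / QTL summary statistics.

Association results are shared as delimited text in many column dialects.
This module detects which source column plays which canonical role,
normalizes chromosome labels and alleles, fills in Z-scores from whatever
effect-size information is available, clamps underflowed P values so that
-log10 P stays finite and monotone in |Z|, aligns effect alleles to a
reference genotype panel (flipping signs and frequencies as needed), and
persists the harmonized table to a columnar Arrow/Feather cache.

The canonical table is a :class:`pandas.DataFrame` with columns
``snp_id, chrom, pos, allele_effect, allele_other, z, p, neglog10p, eaf,
n, trait`` (``beta``/``se`` retained when present).  Positions are 1-based;
chromosome labels carry no ``chr`` prefix.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

logger = logging.getLogger(__name__)

#: smallest positive subnormal double -- the clamp applied to P == 0
MIN_P = float(np.nextafter(0.0, 1.0))  # ~4.94e-324

CANONICAL_FIELDS = (
    "snp_id",
    "chrom",
    "pos",
    "allele_effect",
    "allele_other",
    "beta",
    "odds_ratio",
    "se",
    "z",
    "p",
    "neglog10p",
    "eaf",
    "n",
)

# built-in synonym dictionary, all keys lower-case; extendable via config
SYNONYMS: dict[str, str] = {
    "snp_id": "snp_id", "snp": "snp_id", "snpid": "snp_id", "markername": "snp_id",
    "marker": "snp_id", "rsid": "snp_id", "rs_id": "snp_id", "rsids": "snp_id",
    "variant_id": "snp_id", "id": "snp_id",
    "chrom": "chrom", "chr": "chrom", "chromosome": "chrom", "#chr": "chrom",
    "#chrom": "chrom", "chr_id": "chrom",
    "pos": "pos", "bp": "pos", "position": "pos", "base_pair_location": "pos",
    "pos_b37": "pos", "pos_b38": "pos", "bpos": "pos",
    "allele_effect": "allele_effect", "a1": "allele_effect", "allele1": "allele_effect",
    "effect_allele": "allele_effect", "ea": "allele_effect", "alt": "allele_effect",
    "tested_allele": "allele_effect",
    "allele_other": "allele_other", "a2": "allele_other", "allele2": "allele_other",
    "other_allele": "allele_other", "non_effect_allele": "allele_other",
    "noneffect_allele": "allele_other", "nea": "allele_other", "ref": "allele_other",
    "reference_allele": "allele_other",
    "beta": "beta", "effect": "beta", "b": "beta", "est": "beta",
    "odds_ratio": "odds_ratio", "or": "odds_ratio", "oddsratio": "odds_ratio",
    "se": "se", "stderr": "se", "standard_error": "se", "se_beta": "se",
    "z": "z", "zscore": "z", "z_score": "z", "zstat": "z",
    "p": "p", "pval": "p", "p_value": "p", "p-value": "p", "pvalue": "p",
    "neglog10p": "neglog10p", "log10p": "neglog10p", "mlog10p": "neglog10p",
    "neg_log_10_p_value": "neglog10p", "lp": "neglog10p",
    "eaf": "eaf", "frq": "eaf", "af": "eaf", "freq": "eaf", "freq1": "eaf",
    "effect_allele_frequency": "eaf", "a1freq": "eaf",
    "n": "n", "n_samples": "n", "nsamples": "n", "samplesize": "n",
    "sample_size": "n", "n_total": "n", "ntotal": "n",
}

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

# canonical chromosome sort order: 1..22, X, Y, MT, then anything else
_CHROM_RANK = {str(i): i for i in range(1, 23)} | {"X": 23, "Y": 24, "MT": 25}


class SchemaError(ValueError):
    """A required canonical field cannot be resolved from the headers."""


class AmbiguousColumnError(SchemaError):
    """Two source headers map onto the same canonical field."""


class NoUsableRecordsError(ValueError):
    """Harmonization or alignment left zero usable records."""


class AlignmentError(ValueError):
    """Summary statistics could not be matched to the reference panel."""


@dataclass(frozen=True)
class ColumnSchema:
    """Mapping of canonical fields to source headers (one header each)."""

    mapping: Mapping[str, str]

    def __post_init__(self) -> None:
        unknown = set(self.mapping) - set(CANONICAL_FIELDS)
        if unknown:
            raise SchemaError(f"unknown canonical fields: {sorted(unknown)}")

    def __contains__(self, canonical: str) -> bool:
        return canonical in self.mapping

    def source(self, canonical: str) -> str:
        return self.mapping[canonical]


@dataclass
class MungeConfig:
    """Tunable policies for harmonization and panel alignment."""

    clamp_value: float = MIN_P
    #: "drop_ambiguous" (default), "drop_all", or "keep_all"
    palindromic_policy: str = "drop_ambiguous"
    #: eaf band inside which a palindromic variant is considered ambiguous
    palindromic_band: tuple[float, float] = (0.4, 0.6)
    #: "keep_first" (default) or "keep_min_p"
    duplicate_policy: str = "keep_first"
    extra_synonyms: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_file(cls, path: str | Path) -> "MungeConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        for key, value in raw.items():
            if not hasattr(cfg, key):
                raise ValueError(f"unknown config key: {key}")
            if key == "palindromic_band":
                value = tuple(value)
            setattr(cfg, key, value)
        return cfg


def detect_columns(
    headers: Sequence[str], extra_synonyms: Mapping[str, str] | None = None
) -> ColumnSchema:
    """Resolve heterogeneous headers to the canonical schema.

    Matching is case-insensitive against a built-in synonym dictionary,
    optionally extended by ``extra_synonyms`` (source header -> canonical
    field).  Raises :class:`SchemaError` when neither a position
    (chrom+pos) nor an identifier column is found, or when no statistic
    (z | beta+se | odds_ratio+se | p) is available;
    :class:`AmbiguousColumnError` when two headers claim one field.
    """
    if not headers:
        raise SchemaError("no headers given")
    table = dict(SYNONYMS)
    for src, canon in (extra_synonyms or {}).items():
        if canon not in CANONICAL_FIELDS:
            raise SchemaError(f"unknown canonical field in synonyms: {canon}")
        table[src.lower()] = canon

    mapping: dict[str, str] = {}
    for header in headers:
        canon = table.get(header.strip().lower())
        if canon is None:
            continue
        if canon in mapping:
            raise AmbiguousColumnError(
                f"both {mapping[canon]!r} and {header!r} map to canonical "
                f"field {canon!r}"
            )
        mapping[canon] = header

    has_position = ("chrom" in mapping and "pos" in mapping) or "snp_id" in mapping
    if not has_position:
        missing = "snp_id" if "chrom" in mapping or "pos" in mapping else "chrom+pos or snp_id"
        raise SchemaError(f"cannot locate variants: missing {missing} column")
    has_stat = (
        "z" in mapping
        or ("beta" in mapping and "se" in mapping)
        or ("odds_ratio" in mapping and "se" in mapping)
        or "p" in mapping
    )
    if not has_stat:
        raise SchemaError(
            "no usable statistic: need z, beta+se, odds_ratio+se, or p"
        )
    return ColumnSchema(mapping)


def read_sumstats(path: str | Path) -> pd.DataFrame:
    """Read a delimited summary-statistics file (tab/comma/whitespace,
    optionally gzipped), auto-detecting the delimiter from the header."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        first = fh.readline()
    if "\t" in first:
        sep: str = "\t"
    elif "," in first:
        sep = ","
    else:
        sep = r"\s+"
    return pd.read_csv(path, sep=sep, compression="infer")


def normalize_chrom(values: Iterable) -> pd.Series:
    """Strip ``chr`` prefixes and map numeric sex/mito aliases
    (23/25 -> X, 24 -> Y, 26 -> MT, M -> MT)."""
    s = pd.Series(list(values), dtype="object").astype(str).str.strip()
    s = s.str.replace(r"(?i)^chr", "", regex=True).str.upper()
    # integer-valued floats from numeric columns ("1.0" -> "1")
    s = s.str.replace(r"\.0$", "", regex=True)
    return s.replace({"23": "X", "24": "Y", "25": "X", "26": "MT", "M": "MT"})


def chrom_rank(values: Iterable) -> np.ndarray:
    """Sort key: autosomes numerically, then X, Y, MT, then others by name."""
    return np.array([_CHROM_RANK.get(str(c), 100) for c in values])


def compute_z(df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Fill Z-scores by source priority: provided z, then beta/se, then
    ln(OR)/se, then sign(effect) * Phi^-1(1 - p/2).

    Returns ``(z, valid)`` where records with no resolvable source, a
    non-positive SE on an SE-based path, or a P outside (0, 1] on the
    P-based path are flagged invalid.
    """
    n = len(df)
    z = np.full(n, np.nan)
    valid = np.ones(n, dtype=bool)

    def col(name: str) -> np.ndarray:
        if name in df.columns:
            return pd.to_numeric(df[name], errors="coerce").to_numpy(dtype=float)
        return np.full(n, np.nan)

    z_in, beta, orat, se, p = (col(c) for c in ("z", "beta", "odds_ratio", "se", "p"))
    need = np.isnan(z)

    use = need & np.isfinite(z_in)
    z[use] = z_in[use]
    need &= ~use

    for eff in (beta, np.log(np.where(orat > 0, orat, np.nan))):
        candidate = need & np.isfinite(eff) & np.isfinite(se)
        bad_se = candidate & (se <= 0)
        valid[bad_se] = False
        use = candidate & (se > 0)
        z[use] = eff[use] / se[use]
        need &= ~use & ~bad_se

    sign = np.where(np.isfinite(beta), np.sign(beta),
                    np.where(orat > 0, np.sign(np.log(orat)), np.nan))
    candidate = need & np.isfinite(p) & np.isfinite(sign)
    bad_p = candidate & ((p <= 0) | (p > 1))
    valid[bad_p] = False
    use = candidate & ~bad_p
    z[use] = np.where(sign[use] == 0, 0.0, sign[use]) * stats.norm.isf(p[use] / 2)
    need &= ~use & ~bad_p

    valid[need] = False  # nothing resolvable for these records
    return z, valid


def clamp_p(
    p: np.ndarray | float | None = None,
    z: np.ndarray | float | None = None,
    clamp_value: float = MIN_P,
) -> tuple[np.ndarray, np.ndarray]:
    """Clamp underflowed P values and compute a finite ``-log10 P``.

    ``p == 0`` is replaced by ``clamp_value`` (by default the smallest
    positive subnormal double).  Where a Z-score is available and the
    two-sided P underflows, ``-log10 P`` is evaluated on the log scale via
    the normal log-survival function, so it remains finite and strictly
    monotone in ``|z|`` far beyond the underflow point.
    """
    if p is None and z is None:
        raise ValueError("need p and/or z")
    z_arr = None if z is None else np.atleast_1d(np.asarray(z, dtype=float))
    if p is None:
        p_arr = 2.0 * stats.norm.sf(np.abs(z_arr))
    else:
        p_arr = np.atleast_1d(np.asarray(p, dtype=float)).copy()

    underflow = p_arr == 0.0
    p_clamped = np.where(underflow, clamp_value, p_arr)

    with np.errstate(divide="ignore"):
        neglog10p = -np.log10(p_clamped)
    if z_arr is not None:
        # exact log-scale tail for every record with a Z-score
        have_z = np.isfinite(z_arr)
        lp = -(stats.norm.logsf(np.abs(z_arr[have_z])) + np.log(2.0)) / np.log(10.0)
        out = neglog10p[have_z]
        # keep the reported P where it is informative; switch to the
        # log-scale value once P has underflowed
        out[underflow[have_z]] = np.maximum(lp[underflow[have_z]], 0.0)
        neglog10p[have_z] = out
    neglog10p = np.maximum(neglog10p, 0.0)
    return p_clamped, neglog10p


def variant_keys(df: pd.DataFrame) -> pd.Series:
    """Order-insensitive (chrom, pos, allele-pair) keys for duplicate
    detection; the allele pair is stored lexicographically."""
    a = df["allele_effect"].astype(str)
    b = df["allele_other"].astype(str)
    lo, hi = np.minimum(a, b), np.maximum(a, b)
    return (
        df["chrom"].astype(str) + ":" + df["pos"].astype("Int64").astype(str)
        + ":" + lo + ":" + hi
    )


def harmonize(
    raw: pd.DataFrame,
    schema: ColumnSchema | None = None,
    config: MungeConfig | None = None,
    trait: str = "trait",
) -> pd.DataFrame:
    """Normalize a raw table into the canonical summary-statistics table.

    Chromosome labels are canonicalized, alleles uppercased, Z-scores
    filled via :func:`compute_z`, P values clamped via :func:`clamp_p`,
    duplicate variant keys dropped (first kept by default), and rows
    sorted by (chrom, pos).  Raises :class:`NoUsableRecordsError` if
    nothing survives.
    """
    config = config or MungeConfig()
    if schema is None:
        schema = detect_columns(list(raw.columns), config.extra_synonyms)

    df = pd.DataFrame(index=raw.index)
    for canon, src in schema.mapping.items():
        df[canon] = raw[src]

    if "chrom" in df.columns:
        df["chrom"] = normalize_chrom(df["chrom"])
    if "pos" in df.columns:
        df["pos"] = pd.to_numeric(df["pos"], errors="coerce").astype("Int64")
        df = df[df["pos"].notna() & (df["pos"] >= 1)]
    for col in ("allele_effect", "allele_other"):
        if col in df.columns:
            df[col] = df[col].astype(str).str.strip().str.upper()
    for col in ("beta", "odds_ratio", "se", "z", "p", "eaf", "n"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")

    z, valid = compute_z(df)
    n_invalid = int((~valid).sum())
    if n_invalid:
        logger.info("dropped %d records with unresolvable/invalid statistics", n_invalid)
    df = df[valid].copy()
    df["z"] = z[valid]

    p_in = df["p"].to_numpy(dtype=float) if "p" in df.columns else None
    p_clamped, neglog10p = clamp_p(
        p=p_in, z=df["z"].to_numpy(), clamp_value=config.clamp_value
    )
    df["p"] = p_clamped
    df["neglog10p"] = neglog10p
    df = df[(df["p"] > 0) & (df["p"] <= 1)]

    if "snp_id" not in df.columns and {"chrom", "pos"} <= set(df.columns):
        df["snp_id"] = df["chrom"].astype(str) + ":" + df["pos"].astype(str)

    if {"chrom", "pos", "allele_effect", "allele_other"} <= set(df.columns):
        keys = variant_keys(df)
        if config.duplicate_policy == "keep_min_p":
            df = df.loc[df.assign(_k=keys).sort_values("p", kind="stable")
                        .drop_duplicates("_k").index]
            dropped = len(keys) - len(df)
        else:
            keep = ~keys.duplicated(keep="first")
            dropped = int((~keep).sum())
            df = df[keep]
        if dropped:
            logger.info("dropped %d duplicate variant keys", dropped)

    if {"chrom", "pos"} <= set(df.columns):
        df = df.assign(_rank=chrom_rank(df["chrom"])).sort_values(
            ["_rank", "chrom", "pos"], kind="stable"
        ).drop(columns="_rank")

    df["trait"] = trait
    df = df.reset_index(drop=True)
    if df.empty:
        raise NoUsableRecordsError("no usable records after harmonization")
    order = [c for c in ("snp_id", "chrom", "pos", "allele_effect", "allele_other",
                         "beta", "se", "z", "p", "neglog10p", "eaf", "n", "trait")
             if c in df.columns]
    return df[order]


def _complement(alleles: pd.Series) -> pd.Series:
    return alleles.map(lambda a: "".join(_COMPLEMENT.get(b, "N") for b in str(a)))


def align_to_reference(
    sumstats: pd.DataFrame,
    panel_variants: pd.DataFrame,
    config: MungeConfig | None = None,
) -> pd.DataFrame:
    """Align effect/other alleles to a reference panel's allele pairs.

    Records are matched by (chrom, pos).  A swapped pair flips the sign of
    z (and beta) and complements eaf; a strand-complemented pair rewrites
    the alleles to the panel's representation (with the flip rules applied
    again if also swapped).  Palindromic variants (A/T, C/G) are handled
    per ``config.palindromic_policy``; unmatched records are dropped.
    The operation is idempotent.
    """
    config = config or MungeConfig()
    panel = panel_variants[["chrom", "pos", "allele_1", "allele_2"]].copy()
    panel["chrom"] = normalize_chrom(panel["chrom"])
    panel = panel.drop_duplicates(["chrom", "pos"])

    merged = sumstats.merge(panel, on=["chrom", "pos"], how="inner")
    if merged.empty:
        raise AlignmentError(
            "zero records matched the reference panel by (chrom, pos); "
            "check that both use the same genome build"
        )

    ea, oa = merged["allele_effect"], merged["allele_other"]
    p1, p2 = merged["allele_1"], merged["allele_2"]
    ea_c, oa_c = _complement(ea), _complement(oa)

    same = (ea == p1) & (oa == p2)
    swap = (ea == p2) & (oa == p1)
    comp_same = ~same & ~swap & (ea_c == p1) & (oa_c == p2)
    comp_swap = ~same & ~swap & ~comp_same & (ea_c == p2) & (oa_c == p1)
    palindromic = ea == _complement(oa)

    matched = (same | swap | comp_same | comp_swap) & ~palindromic
    if config.palindromic_policy == "keep_all":
        matched |= palindromic & (same | swap)
    elif config.palindromic_policy == "drop_ambiguous":
        eaf = merged["eaf"] if "eaf" in merged.columns else pd.Series(np.nan, index=merged.index)
        lo, hi = config.palindromic_band
        ambiguous = eaf.isna() | ((eaf >= lo) & (eaf <= hi))
        matched |= palindromic & (same | swap) & ~ambiguous
    # "drop_all": palindromic records never match

    n_dropped = len(sumstats) - int(matched.sum())
    if n_dropped:
        logger.info("alignment dropped %d unmatched/palindromic records", n_dropped)

    out = merged[matched].copy()
    flip = (swap | comp_swap)[matched]
    for col in ("z", "beta"):
        if col in out.columns:
            out.loc[flip, col] = -out.loc[flip, col]
    if "eaf" in out.columns:
        out.loc[flip, "eaf"] = 1.0 - out.loc[flip, "eaf"]
    # rewrite alleles to the panel representation
    out["allele_effect"] = out["allele_1"]
    out["allele_other"] = out["allele_2"]
    out = out.drop(columns=["allele_1", "allele_2"]).reset_index(drop=True)
    if out.empty:
        raise NoUsableRecordsError("no records left after panel alignment")
    return out


def save_cache(sumstats: pd.DataFrame, path: str | Path) -> None:
    """Persist a harmonized table to an Arrow/Feather file (lossless)."""
    sumstats.reset_index(drop=True).to_feather(path)


def load_cache(path: str | Path) -> pd.DataFrame:
    """Load a table written by :func:`save_cache`."""
    try:
        return pd.read_feather(path)
    except (OSError, pd.errors.ParserError) as exc:  # pragma: no cover
        raise OSError(f"cannot read summary-statistics cache {path}: {exc}") from exc
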