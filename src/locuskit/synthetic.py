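"""Synthetic inputs: genotype panels, summary statistics, and GTF files.

Every input kind the toolkit consumes can be generated here so the whole
pipeline runs without downloads.

Genotype panels use a first-order copying process: within each
haplotype, the allele at marker ``j`` copies marker ``j-1`` with
probability ``rho`` and is otherwise drawn fresh as Bernoulli(f_j), with
per-marker frequencies uniform in a configured range.  Two haplotypes
sum to a diploid dosage.  ``rho`` therefore tunes LD: adjacent markers
are perfectly correlated at ``rho=1`` and independent at ``rho=0``, with
r² decaying geometrically in distance for values in between.

Summary statistics regress a simulated phenotype
``y = beta * dosage_causal + noise`` on each variant separately
(marginal simple regression), giving exact finite-sample effect sizes,
standard errors, Z-scores and two-sided P values.  Output headers can be
emitted in any of several real-world column dialects to exercise the
munging layer.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .genemodels import GeneModel, TranscriptModel, write_gtf
from .ld import PLINK_MAGIC, PLINK_MODE_VARIANT_MAJOR, GenotypePanel

#: header dialects for simulated summary statistics, keyed by a name the
#: seeded fuzzer can enumerate; values map canonical -> emitted header
DIALECTS: dict[str, dict[str, str]] = {
    "canonical": {
        "snp_id": "snp_id", "chrom": "chrom", "pos": "pos",
        "allele_effect": "allele_effect", "allele_other": "allele_other",
        "beta": "beta", "se": "se", "p": "p", "eaf": "eaf", "n": "n",
    },
    "metal": {
        "snp_id": "MarkerName", "chrom": "CHR", "pos": "BP",
        "allele_effect": "Allele1", "allele_other": "Allele2",
        "beta": "Effect", "se": "StdErr", "p": "P-value",
        "eaf": "Freq1", "n": "N",
    },
    "plink": {
        "snp_id": "SNP", "chrom": "CHR", "pos": "POS",
        "allele_effect": "A1", "allele_other": "A2",
        "beta": "BETA", "se": "SE", "p": "P", "eaf": "FRQ", "n": "N",
    },
    "gwas_catalog": {
        "snp_id": "variant_id", "chrom": "chromosome", "pos": "base_pair_location",
        "allele_effect": "effect_allele", "allele_other": "other_allele",
        "beta": "beta", "se": "standard_error", "p": "p_value",
        "eaf": "effect_allele_frequency", "n": "n",
    },
}

_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"), ("C", "A"), ("G", "T")]


@dataclass
class SimConfig:
    """Study conditions for the synthetic generator.

    Defaults describe a modest reference panel and a well-powered
    single-locus association study: 2,000 samples, 200 markers 5 kb
    apart with strong short-range LD (rho = 0.9), a causal variant in
    the middle of the region, and an effect explaining 5% of phenotypic
    variance against unit noise.
    """

    n_samples: int = 2_000
    n_variants: int = 200
    rho: float = 0.9
    freq_range: tuple[float, float] = (0.05, 0.95)
    causal_index: int | None = None  # None -> middle variant
    variance_explained: float = 0.05  # fraction of Var(y) from the causal variant
    noise_sd: float = 1.0
    chrom: str = "1"
    pos_start: int = 1_000_000
    pos_step: int = 5_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.n_variants < 1:
            raise ValueError("counts must be >= 1")
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("rho must lie in [0, 1]")
        if not 0.0 <= self.variance_explained < 1.0:
            raise ValueError("variance_explained must lie in [0, 1)")

    @property
    def causal(self) -> int:
        return self.n_variants // 2 if self.causal_index is None else self.causal_index

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=seed)


def simulate_panel(config: SimConfig, freqs: np.ndarray | None = None) -> GenotypePanel:
    """Simulate a diploid genotype panel with tunable LD decay.

    Per haplotype, marker ``j`` copies marker ``j-1`` with probability
    ``config.rho`` and is otherwise a fresh Bernoulli(f_j) draw; two
    haplotypes sum to the dosage.  Fixed seed gives identical output.
    """
    rng = np.random.default_rng(config.seed)
    n, m = config.n_samples, config.n_variants
    lo, hi = config.freq_range
    if freqs is None:
        freqs = rng.uniform(lo, hi, size=m)
    freqs = np.asarray(freqs, dtype=float)

    hap = np.empty((2 * n, m), dtype=np.int8)
    hap[:, 0] = rng.random(2 * n) < freqs[0]
    for j in range(1, m):
        fresh = rng.random(2 * n) < freqs[j]
        copy = rng.random(2 * n) < config.rho
        hap[:, j] = np.where(copy, hap[:, j - 1], fresh)
    dosage = (hap[0::2] + hap[1::2]).astype(float)

    pairs = [_ALLELE_PAIRS[int(k)] for k in rng.integers(0, len(_ALLELE_PAIRS), size=m)]
    pos = config.pos_start + config.pos_step * np.arange(m)
    variants = pd.DataFrame(
        {
            "snp_id": [f"rs{j + 1}" for j in range(m)],
            "chrom": config.chrom,
            "pos": pos,
            "allele_1": [a for a, _ in pairs],  # counted allele
            "allele_2": [b for _, b in pairs],
        }
    )
    samples = pd.DataFrame(
        {"fid": [f"F{i + 1}" for i in range(n)], "iid": [f"I{i + 1}" for i in range(n)]}
    )
    return GenotypePanel(samples=samples, variants=variants, genotypes=dosage)


def causal_beta(panel: GenotypePanel, config: SimConfig) -> float:
    """Effect size giving the configured variance explained.

    Solves beta^2 Var(g) = ve/(1 - ve) * noise_sd^2 with the empirical
    dosage variance of the causal variant.
    """
    g = panel.genotypes[:, config.causal]
    var_g = float(np.nanvar(g))
    if var_g == 0 or config.variance_explained == 0:
        return 0.0
    ve = config.variance_explained
    return float(np.sqrt(ve / (1.0 - ve) * config.noise_sd**2 / var_g))


def simulate_phenotype(panel: GenotypePanel, config: SimConfig,
                       rng: np.random.Generator | None = None) -> np.ndarray:
    rng = rng or np.random.default_rng(config.seed + 1)
    beta = causal_beta(panel, config)
    g = np.nan_to_num(panel.genotypes[:, config.causal])
    return beta * g + rng.normal(0.0, config.noise_sd, size=panel.n_samples)


def marginal_regression(panel: GenotypePanel, y: np.ndarray) -> pd.DataFrame:
    """Per-variant simple linear regression of y on dosage (with intercept).

    Returns beta_hat, se, z = beta_hat/se and the two-sided normal P for
    every variant, fully vectorized.  Monomorphic variants get NaN.
    """
    x = np.array(panel.genotypes, dtype=float)
    x = np.where(np.isnan(x), np.nanmean(x, axis=0), x)
    n = x.shape[0]
    xc = x - x.mean(axis=0)
    yc = y - y.mean()
    sxx = (xc**2).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        beta_hat = (xc * yc[:, None]).sum(axis=0) / sxx
        sse = (yc**2).sum() - beta_hat**2 * sxx
        sigma2 = np.maximum(sse, 0.0) / max(n - 2, 1)
        se = np.sqrt(sigma2 / sxx)
        z = beta_hat / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    return pd.DataFrame(
        {
            "snp_id": panel.variants["snp_id"],
            "chrom": panel.variants["chrom"],
            "pos": panel.variants["pos"],
            "allele_effect": panel.variants["allele_1"],
            "allele_other": panel.variants["allele_2"],
            "beta": beta_hat,
            "se": se,
            "z": z,
            "p": p,
            "eaf": np.nanmean(x, axis=0) / 2.0,
            "n": n,
        }
    )


def simulate_sumstats(
    panel: GenotypePanel,
    config: SimConfig,
    dialect: str | None = None,
) -> tuple[pd.DataFrame, str]:
    """Simulate a GWAS over the panel and emit raw-format summary stats.

    A phenotype with the configured causal signal is regressed on every
    variant; the table is returned under one of the real-world column
    ``DIALECTS`` (chosen from the seed when not named) so downstream
    column detection is exercised.  Returns ``(raw_table, dialect_name)``.
    """
    rng = np.random.default_rng(config.seed + 1)
    beta = causal_beta(panel, config)
    g = np.nan_to_num(panel.genotypes[:, config.causal])
    y = beta * g + rng.normal(0.0, config.noise_sd, size=panel.n_samples)
    table = marginal_regression(panel, y)

    if dialect is None:
        names = sorted(DIALECTS)
        dialect = names[int(rng.integers(len(names)))]
    headers = DIALECTS[dialect]
    raw = table[[c for c in headers]].rename(columns=headers)
    return raw, dialect


def write_plink(panel: GenotypePanel, prefix: str | Path) -> None:
    """Write a panel as a PLINK 1 .bed/.bim/.fam triple.

    Encoding is the inverse of the reader: variant-major, two bits per
    sample (00 = two copies of allele_1, 10 = one, 11 = zero,
    01 = missing), each variant padded to a whole byte.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n, m = panel.n_samples, panel.n_variants

    dosage_to_code = {2.0: 0b00, 1.0: 0b10, 0.0: 0b11}
    g = panel.genotypes
    codes = np.full((m, n), 0b01, dtype=np.uint8)  # missing by default
    for d, c in dosage_to_code.items():
        codes[(g.T == d)] = c

    padded_n = 4 * ((n + 3) // 4)
    codes_padded = np.zeros((m, padded_n), dtype=np.uint8)
    codes_padded[:, :n] = codes
    quads = codes_padded.reshape(m, -1, 4)
    packed = (
        quads[:, :, 0]
        | (quads[:, :, 1] << 2)
        | (quads[:, :, 2] << 4)
        | (quads[:, :, 3] << 6)
    ).astype(np.uint8)

    with open(f"{prefix}.bed", "wb") as fh:
        fh.write(PLINK_MAGIC)
        fh.write(bytes([PLINK_MODE_VARIANT_MAJOR]))
        fh.write(packed.tobytes())

    bim = panel.variants.assign(cm=0)[
        ["chrom", "snp_id", "cm", "pos", "allele_1", "allele_2"]
    ]
    bim.to_csv(f"{prefix}.bim", sep="\t", header=False, index=False)
    fam = panel.samples.assign(father=0, mother=0, sex=0, phenotype=-9)[
        ["fid", "iid", "father", "mother", "sex", "phenotype"]
    ]
    fam.to_csv(f"{prefix}.fam", sep="\t", header=False, index=False)


def gene_models_from_spec(spec: list[dict]) -> list[GeneModel]:
    """Build gene models from a nested dict spec, validating the nesting.

    Each entry: ``{gene_id, gene_name, biotype, chrom, strand,
    transcripts: [{transcript_id, exons: [(start, end), ...]}, ...]}``.
    Gene and transcript spans are derived from the exons.
    """
    genes = []
    for gs in spec:
        txs = []
        for ts in gs["transcripts"]:
            exons = sorted((int(s), int(e)) for s, e in ts["exons"])
            if not exons:
                raise ValueError(f"transcript {ts['transcript_id']} has no exons")
            for s, e in exons:
                if e < s:
                    raise ValueError(f"exon ({s}, {e}) has end < start")
            for (_, e1), (s2, _) in zip(exons, exons[1:]):
                if s2 <= e1:
                    raise ValueError(
                        f"overlapping exons in transcript {ts['transcript_id']}"
                    )
            txs.append(TranscriptModel(ts["transcript_id"], exons[0][0],
                                       exons[-1][1], exons))
        if not txs:
            raise ValueError(f"gene {gs['gene_id']} has no transcripts")
        genes.append(
            GeneModel(
                gene_id=gs["gene_id"],
                gene_name=gs.get("gene_name", gs["gene_id"]),
                biotype=gs.get("biotype", "protein_coding"),
                chrom=str(gs.get("chrom", "1")),
                strand=gs.get("strand", "+"),
                start=min(t.start for t in txs),
                end=max(t.end for t in txs),
                transcripts=txs,
            )
        )
    return genes


def default_gene_spec(chrom: str = "1", offset: int = 0) -> list[dict]:
    """A small two-gene / three-transcript / seven-exon annotation."""
    return [
        {
            "gene_id": "GENE0001", "gene_name": "ALPHA", "biotype": "protein_coding",
            "chrom": chrom, "strand": "+",
            "transcripts": [
                {"transcript_id": "TX0001.1",
                 "exons": [(offset + 1_100_000, offset + 1_100_500),
                           (offset + 1_101_000, offset + 1_101_400),
                           (offset + 1_102_000, offset + 1_102_300)]},
                {"transcript_id": "TX0001.2",
                 "exons": [(offset + 1_100_000, offset + 1_100_500),
                           (offset + 1_102_000, offset + 1_102_600)]},
            ],
        },
        {
            "gene_id": "GENE0002", "gene_name": "BRAVO", "biotype": "lncRNA",
            "chrom": chrom, "strand": "-",
            "transcripts": [
                {"transcript_id": "TX0002.1",
                 "exons": [(offset + 1_101_200, offset + 1_101_800),
                           (offset + 1_103_000, offset + 1_103_500)]},
            ],
        },
    ]


def write_gtf_fixture(spec: list[dict], path: str | Path,
                      dialect: str = "gencode") -> list[GeneModel]:
    """Write a spec as a valid GTF file; returns the gene models written."""
    genes = gene_models_from_spec(spec)
    write_gtf(genes, path, dialect=dialect)
    return genes
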