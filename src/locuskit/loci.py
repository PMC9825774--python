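"""GWAS locus discovery and closest-gene annotation.

A locus is a non-overlapping window of ±``half_width`` base pairs (1 Mb
by default) anchored at an index SNP, identified greedily: the most
significant remaining SNP below the genome-wide threshold (P < 5e-8 by
default) seeds a window, every SNP inside that window is removed, and
the procedure repeats.  Each locus can then be annotated with its
closest protein-coding gene, measured to the gene-body endpoints (or the
TSS, configurably).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .genemodels import GeneModel
from .sumstats import chrom_rank

GENOME_WIDE_P = 5e-8
DEFAULT_HALF_WIDTH = 1_000_000


@dataclass(frozen=True)
class ClosestGene:
    gene_id: str
    gene_name: str
    distance: int  # bp; 0 when the position lies inside the gene body


@dataclass
class Locus:
    """A ±half-width window around an index SNP."""

    chrom: str
    start: int  # bp, 1-based inclusive, floored at 1
    end: int  # bp, inclusive
    snp_id: str
    pos: int
    p: float
    neglog10p: float
    closest_gene: ClosestGene | None = field(default=None)

    def contains(self, chrom: str, pos: int) -> bool:
        return str(chrom) == self.chrom and self.start <= int(pos) <= self.end


def find_loci(
    sumstats: pd.DataFrame,
    threshold: float = GENOME_WIDE_P,
    half_width: int = DEFAULT_HALF_WIDTH,
) -> list[Locus]:
    """Greedy discovery of non-overlapping GWAS loci.

    Repeatedly anchors a closed window [pos - half_width, pos + half_width]
    at the remaining record with the smallest P (ties broken by
    chromosome order, then position, then snp_id), removes every record
    inside the window on that chromosome, and stops when no remaining
    record is below ``threshold``.  A later (less significant) window is
    truncated where it would intrude on an earlier one, so windows from
    one call never overlap on a chromosome and every significant record
    belongs to exactly one window.  Returned loci are sorted by index P
    ascending.
    """
    if sumstats.empty:
        return []
    sig = sumstats[sumstats["p"] < threshold]
    if sig.empty:
        return []

    cand = sig.assign(_rank=chrom_rank(sig["chrom"])).sort_values(
        ["p", "_rank", "chrom", "pos", "snp_id"], kind="stable"
    )
    chroms = cand["chrom"].astype(str).to_numpy()
    pos = cand["pos"].to_numpy(dtype=np.int64)
    taken: dict[str, list[tuple[int, int]]] = {}
    loci: list[Locus] = []
    for i in range(len(cand)):
        c, x = chroms[i], int(pos[i])
        if any(s <= x <= e for s, e in taken.get(c, ())):
            continue
        start, end = max(1, x - half_width), x + half_width
        # clip against earlier, higher-priority windows on this chromosome
        for s, e in taken.get(c, ()):
            if e < x:
                start = max(start, e + 1)
            elif s > x:
                end = min(end, s - 1)
        taken.setdefault(c, []).append((start, end))
        row = cand.iloc[i]
        loci.append(
            Locus(
                chrom=c,
                start=start,
                end=end,
                snp_id=str(row["snp_id"]),
                pos=x,
                p=float(row["p"]),
                neglog10p=float(row["neglog10p"]),
            )
        )
    return loci


def closest_gene(
    chrom: str,
    pos: int,
    genes: Sequence[GeneModel],
    biotype_filter: str | None = "protein_coding",
    mode: str = "body",
) -> ClosestGene | None:
    """Closest gene to a position on the same chromosome.

    Distance is 0 inside the gene body, otherwise the distance to the
    nearer gene-body endpoint (``mode="tss"`` measures to the
    strand-aware transcription start site instead).  Genes failing the
    biotype filter are ignored; ties go to the alphabetically first gene
    name.  Returns None when no qualifying gene exists on the chromosome.
    """
    chrom, pos = str(chrom), int(pos)
    best: tuple[int, str, GeneModel] | None = None
    for g in genes:
        if g.chrom != chrom:
            continue
        if biotype_filter is not None and g.biotype != biotype_filter:
            continue
        if mode == "tss":
            tss = g.start if g.strand == "+" else g.end
            d = abs(pos - tss)
        else:
            if g.start <= pos <= g.end:
                d = 0
            else:
                d = min(abs(pos - g.start), abs(pos - g.end))
        key = (d, g.gene_name)
        if best is None or key < (best[0], best[1]):
            best = (d, g.gene_name, g)
    if best is None:
        return None
    d, _, g = best
    return ClosestGene(gene_id=g.gene_id, gene_name=g.gene_name, distance=d)


def annotate_closest_genes(
    loci: Sequence[Locus],
    genes: Sequence[GeneModel],
    biotype_filter: str | None = "protein_coding",
    mode: str = "body",
) -> list[Locus]:
    """Attach the closest qualifying gene to each locus (in place)."""
    for locus in loci:
        locus.closest_gene = closest_gene(
            locus.chrom, locus.pos, genes, biotype_filter=biotype_filter, mode=mode
        )
    return list(loci)


def loci_to_frame(loci: Sequence[Locus]) -> pd.DataFrame:
    """BED-like table: 0-based half-open window, index SNP, P, gene."""
    rows = []
    for locus in loci:
        g = locus.closest_gene
        rows.append(
            {
                "chrom": locus.chrom,
                "start": locus.start - 1,  # 0-based half-open on output
                "end": locus.end,
                "snp_id": locus.snp_id,
                "pos": locus.pos,
                "p": locus.p,
                "closest_gene": g.gene_name if g else ".",
                "gene_distance": g.distance if g else -1,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "snp_id", "pos", "p",
                 "closest_gene", "gene_distance"],
    )
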