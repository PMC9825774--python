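"""Gene/transcript/exon models from GTF and gene-track layout.

GTF is tab-delimited with 1-based inclusive coordinates and a trailing
``key "value";`` attribute list.  Both the GENCODE (``gene_type``) and
Ensembl (``gene_biotype``) biotype attribute dialects are accepted.
Genes or transcripts present only through their child features are
synthesized from the span of those children.

Track layout is a greedy first-fit interval packing: items sorted by
start are placed on the lowest row whose occupied extents (gene body
united with its estimated label extent, plus padding) they do not
intersect.  Rows are unbounded, so any number of genes can be laid out.
"""

from __future__ import annotations

import gzip
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .sumstats import normalize_chrom

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


class GTFParseError(ValueError):
    """Malformed GTF content (bad coordinates, missing identifiers)."""


@dataclass
class TranscriptModel:
    """One isoform: an ordered list of non-overlapping exons."""

    transcript_id: str
    start: int
    end: int
    exons: list[tuple[int, int]] = field(default_factory=list)

    def introns(self) -> list[tuple[int, int]]:
        """Gaps between consecutive exons, 1-based inclusive."""
        out = []
        for (_, e1), (s2, _) in zip(self.exons, self.exons[1:]):
            if s2 > e1 + 1:
                out.append((e1 + 1, s2 - 1))
        return out


@dataclass
class GeneModel:
    gene_id: str
    gene_name: str
    biotype: str
    chrom: str
    strand: str
    start: int
    end: int
    transcripts: list[TranscriptModel] = field(default_factory=list)


def _parse_attributes(attr_field: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(attr_field))


def parse_gtf(path: str | Path, region: tuple[str, int, int] | None = None) -> list[GeneModel]:
    """Parse a (possibly gzipped) GTF file into gene models.

    ``region`` is an optional (chrom, start, end) filter; genes
    overlapping the region are kept.  Raises :class:`GTFParseError` with
    the line number for end < start or for exons lacking identifiers.
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open

    gene_rows: dict[str, dict] = {}
    tx_rows: dict[str, dict] = {}
    exon_rows: list[dict] = []

    with opener(path, "rt") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9:
                raise GTFParseError(f"{path}:{lineno}: expected 9 columns, got {len(parts)}")
            chrom, _source, feature, start, end, _score, strand, _frame, attrs = parts
            if feature not in ("gene", "transcript", "exon"):
                continue
            start, end = int(start), int(end)
            if end < start:
                raise GTFParseError(f"{path}:{lineno}: end {end} < start {start}")
            a = _parse_attributes(attrs)
            gene_id = a.get("gene_id")
            if not gene_id:
                raise GTFParseError(f"{path}:{lineno}: {feature} without gene_id")
            rec = {
                "chrom": normalize_chrom([chrom]).iloc[0],
                "start": start,
                "end": end,
                "strand": strand,
                "gene_id": gene_id,
                "gene_name": a.get("gene_name", gene_id),
                "biotype": a.get("gene_type", a.get("gene_biotype", "")),
                "transcript_id": a.get("transcript_id"),
            }
            if feature == "gene":
                gene_rows[gene_id] = rec
            elif feature == "transcript":
                if not rec["transcript_id"]:
                    raise GTFParseError(f"{path}:{lineno}: transcript without transcript_id")
                tx_rows[rec["transcript_id"]] = rec
            else:
                if not rec["transcript_id"]:
                    raise GTFParseError(
                        f"{path}:{lineno}: exon references no transcript (missing transcript_id)"
                    )
                exon_rows.append(rec)

    # transcripts: explicit lines, else synthesized from exon spans
    transcripts: dict[str, TranscriptModel] = {}
    tx_gene: dict[str, str] = {}
    tx_meta: dict[str, dict] = {}
    for tid, rec in tx_rows.items():
        transcripts[tid] = TranscriptModel(tid, rec["start"], rec["end"])
        tx_gene[tid] = rec["gene_id"]
        tx_meta[tid] = rec
    for rec in exon_rows:
        tid = rec["transcript_id"]
        if tid not in transcripts:
            transcripts[tid] = TranscriptModel(tid, rec["start"], rec["end"])
            tx_gene[tid] = rec["gene_id"]
            tx_meta[tid] = rec
        transcripts[tid].exons.append((rec["start"], rec["end"]))
    for tx in transcripts.values():
        tx.exons.sort()
        if tx.exons:
            tx.start = min(tx.start, tx.exons[0][0])
            tx.end = max(tx.end, max(e for _, e in tx.exons))
        for (s1, e1), (s2, e2) in zip(tx.exons, tx.exons[1:]):
            if s2 <= e1:
                raise GTFParseError(
                    f"transcript {tx.transcript_id}: overlapping exons "
                    f"({s1},{e1}) and ({s2},{e2})"
                )

    # genes: explicit lines, else synthesized from transcript spans
    genes: dict[str, GeneModel] = {}
    for gid, rec in gene_rows.items():
        genes[gid] = GeneModel(
            gene_id=gid, gene_name=rec["gene_name"], biotype=rec["biotype"],
            chrom=rec["chrom"], strand=rec["strand"],
            start=rec["start"], end=rec["end"],
        )
    for tid, tx in transcripts.items():
        gid = tx_gene[tid]
        if gid not in genes:
            meta = tx_meta[tid]
            genes[gid] = GeneModel(
                gene_id=gid, gene_name=meta["gene_name"], biotype=meta["biotype"],
                chrom=meta["chrom"], strand=meta["strand"],
                start=tx.start, end=tx.end,
            )
        g = genes[gid]
        g.start = min(g.start, tx.start)
        g.end = max(g.end, tx.end)
        g.transcripts.append(tx)
    for g in genes.values():
        g.transcripts.sort(key=lambda t: (t.start, t.end, t.transcript_id))

    out = sorted(genes.values(), key=lambda g: (g.chrom, g.start, g.gene_id))
    if region is not None:
        chrom, start, end = region
        chrom = normalize_chrom([chrom]).iloc[0]
        out = [g for g in out if g.chrom == chrom and g.start <= end and g.end >= start]
    return out


@dataclass
class TrackLayout:
    """Row assignment for track items; row 0 is the top row."""

    rows: list[int]  # aligned with the input item order
    extents: list[tuple[float, float]]  # padded plotted extent per item

    @property
    def n_rows(self) -> int:
        return max(self.rows) + 1 if self.rows else 0


def pack_rows(
    items: Sequence[tuple[float, float, float]], padding: float = 0.0
) -> TrackLayout:
    """Greedy first-fit interval packing of (start, end, label_width).

    The plotted extent of an item is its body united with a label extent
    of ``label_width`` axis units anchored at the body start, widened by
    ``padding`` on each side.  Items are sorted by start internally, so
    the layout is invariant to input permutation; each item lands on the
    lowest-index row where it overlaps nothing already placed.
    """
    extents = []
    for start, end, label_width in items:
        lo = min(start, end)
        hi = max(start, end, start + label_width)
        extents.append((lo - padding, hi + padding))

    order = sorted(
        range(len(extents)), key=lambda i: (extents[i][0], extents[i][1], tuple(items[i]))
    )
    rows = [0] * len(extents)
    row_last_end: list[float] = []  # rightmost occupied coordinate per row
    for i in order:
        lo, hi = extents[i]
        for r, last in enumerate(row_last_end):
            if lo > last:
                rows[i] = r
                row_last_end[r] = hi
                break
        else:
            rows[i] = len(row_last_end)
            row_last_end.append(hi)
    return TrackLayout(rows=rows, extents=extents)


@dataclass
class TrackGeometry:
    """Drawable primitives for a gene or isoform track."""

    exon_boxes: list[tuple[int, float, float]]  # (row, start, end)
    intron_lines: list[tuple[int, float, float]]
    labels: list[tuple[int, float, str]]  # (row, x, text)


def strand_label(name: str, strand: str) -> str:
    """Deterministic strand glyph: GENE> for +, <GENE for -."""
    return f"{name}>" if strand == "+" else f"<{name}"


def gene_track_geometry(
    genes: Sequence[GeneModel],
    layout: TrackLayout | None = None,
    label_char_width: float = 0.0,
    padding: float = 0.0,
    isoforms: bool = False,
) -> tuple[TrackGeometry, TrackLayout]:
    """Boxes, intron lines and labels for a packed gene (or isoform) track.

    In gene mode each gene draws the union of its transcripts' exons on
    one row; in isoform mode every transcript gets its own packed row
    labelled by transcript_id.  Label extents are estimated as
    ``len(label) * label_char_width`` axis units.
    """
    if isoforms:
        items = [
            (tx, strand_label(tx.transcript_id, g.strand))
            for g in genes for tx in g.transcripts
        ]
        spans = [(t.start, t.end) for t, _ in items]
        exon_lists = [t.exons for t, _ in items]
    else:
        items = [(g, strand_label(g.gene_name, g.strand)) for g in genes]
        spans = [(g.start, g.end) for g in genes]
        exon_lists = [
            _merge_intervals([e for t in g.transcripts for e in t.exons]) or
            [(g.start, g.end)]
            for g in genes
        ]

    if layout is None:
        layout = pack_rows(
            [(s, e, len(lab) * label_char_width) for (s, e), (_, lab) in zip(spans, items)],
            padding=padding,
        )
    if len(layout.rows) != len(items):
        raise ValueError("layout does not cover all track items")

    geom = TrackGeometry(exon_boxes=[], intron_lines=[], labels=[])
    for (span, exons, (obj, label)), row in zip(zip(spans, exon_lists, items), layout.rows):
        for s, e in exons:
            geom.exon_boxes.append((row, float(s), float(e)))
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 > e1:
                geom.intron_lines.append((row, float(e1), float(s2)))
        geom.labels.append((row, float(span[0]), label))
    return geom, layout


def _merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of 1-based inclusive intervals (adjacent intervals merge)."""
    ivs = sorted(intervals)
    merged: list[list[int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def write_gtf(genes: Sequence[GeneModel], path: str | Path, dialect: str = "gencode") -> None:
    """Write gene models as valid GTF (gene/transcript/exon lines).

    ``dialect`` selects the biotype attribute key: ``gene_type``
    (GENCODE) or ``gene_biotype`` (Ensembl).
    """
    if dialect not in ("gencode", "ensembl"):
        raise ValueError(f"unknown GTF dialect: {dialect}")
    bio_key = "gene_type" if dialect == "gencode" else "gene_biotype"
    lines = []
    for g in genes:
        base = (
            f'gene_id "{g.gene_id}"; gene_name "{g.gene_name}"; '
            f'{bio_key} "{g.biotype}";'
        )
        lines.append(
            f"{g.chrom}\tlocuskit\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{base}"
        )
        for tx in g.transcripts:
            tattr = f'{base} transcript_id "{tx.transcript_id}";'
            lines.append(
                f"{g.chrom}\tlocuskit\ttranscript\t{tx.start}\t{tx.end}\t.\t"
                f"{g.strand}\t.\t{tattr}"
            )
            for s, e in tx.exons:
                lines.append(
                    f"{g.chrom}\tlocuskit\texon\t{s}\t{e}\t.\t{g.strand}\t.\t{tattr}"
                )
    Path(path).write_text("\n".join(lines) + "\n")
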