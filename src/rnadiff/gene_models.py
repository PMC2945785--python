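"""Gene interval models from exon annotation.

Builds one disjoint genomic interval set per gene from a GTF/GFF3
annotation, under either of two models:

* ``union_intersection`` (default): the minimal interval set whose bases
  are contained in *every* transcript annotated for the gene — the
  "constitutive" portion of the gene.
* ``union``: every base contained in *any* exon annotation for the gene.

After per-gene construction, bases claimed by two or more genes are
removed from all genes, so the final sets are pairwise disjoint and each
counted read can be attributed unambiguously.

Coordinates are 0-based half-open internally; GTF/GFF3 input (1-based
closed) is converted on read and BED output is written natively.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, TextIO

from gffutils.feature import feature_from_line

logger = logging.getLogger("rnadiff")

__all__ = [
    "GenomicInterval",
    "Transcript",
    "GeneIntervalSet",
    "AnnotationParseError",
    "parse_annotation",
    "build_gene_model",
    "build_all_gene_models",
    "subtract_cross_gene_overlaps",
    "export_bed",
    "import_bed",
    "export_gene_table",
]


class AnnotationParseError(ValueError):
    """Raised for malformed annotation records; carries the line number."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on one chromosome strand."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class Transcript:
    """A transcript's exons, all on one chromosome and strand."""

    transcript_id: str
    gene_id: str
    exons: list[GenomicInterval] = field(default_factory=list)

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    def merged_exons(self) -> list[tuple[int, int]]:
        """Exon spans merged into sorted disjoint (start, end) pairs."""
        return _merge([(e.start, e.end) for e in self.exons])


@dataclass
class GeneIntervalSet:
    """Sorted disjoint intervals for one gene; ``length`` is L_i (bases)."""

    gene_id: str
    chrom: str
    strand: str
    intervals: list[GenomicInterval]

    @property
    def length(self) -> int:
        return sum(len(iv) for iv in self.intervals)

    def spans(self) -> list[tuple[int, int]]:
        return [(iv.start, iv.end) for iv in self.intervals]

    def contains(self, pos: int) -> bool:
        """Membership of a single base by binary search."""
        import bisect

        starts = [iv.start for iv in self.intervals]
        i = bisect.bisect_right(starts, pos) - 1
        return i >= 0 and pos < self.intervals[i].end


# ---------------------------------------------------------------------------
# interval arithmetic (sorted disjoint (start, end) span lists)


def _merge(spans: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Sort, merge overlapping and adjacent spans into canonical form."""
    out: list[tuple[int, int]] = []
    for s, e in sorted(spans):
        if out and s <= out[-1][1]:
            if e > out[-1][1]:
                out[-1] = (out[-1][0], e)
        else:
            out.append((s, e))
    return out


def _intersect(a: list[tuple[int, int]], b: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Intersection of two sorted disjoint span lists."""
    out: list[tuple[int, int]] = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s < e:
            out.append((s, e))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return _merge(out)


def _subtract(a: list[tuple[int, int]], b: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Spans of ``a`` with every base in ``b`` removed."""
    out: list[tuple[int, int]] = []
    j = 0
    for s, e in a:
        cur = s
        while j < len(b) and b[j][1] <= cur:
            j += 1
        k = j
        while k < len(b) and b[k][0] < e:
            bs, be = b[k]
            if bs > cur:
                out.append((cur, bs))
            cur = max(cur, be)
            if be >= e:
                break
            k += 1
        if cur < e:
            out.append((cur, e))
    return out


# ---------------------------------------------------------------------------
# annotation parsing


_TRANSCRIPT_TYPES = frozenset(
    {"mRNA", "transcript", "mrna"}
    | {t + "_transcript" for t in ("lnc_RNA", "nc", "pseudogenic")}
)


def _attr(feat, *names: str) -> str | None:
    for name in names:
        vals = feat.attributes.get(name)
        if vals:
            return vals[0]
    return None


def parse_annotation(source: str | TextIO) -> dict[str, list[Transcript]]:
    """Parse exon records from GTF or GFF3 text into per-gene transcripts.

    Parameters
    ----------
    source
        Path to an annotation file, or an open text stream.

    Returns
    -------
    dict
        gene_id → list of :class:`Transcript`, exons sorted by start.
        1-based closed input coordinates are converted to 0-based
        half-open.

    Raises
    ------
    AnnotationParseError
        On a malformed record (message names the line number) or an exon
        whose gene/transcript cannot be resolved.
    """
    if isinstance(source, str):
        with open(source) as fh:
            return parse_annotation(fh)

    lines = list(source)
    # First pass: GFF3 transcript features give the transcript → gene map.
    tx2gene: dict[str, str] = {}
    feats = []
    for lineno, line in enumerate(lines, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) != 9 or not (fields[3].isdigit() and fields[4].isdigit()):
            raise AnnotationParseError(f"line {lineno}: malformed record")
        try:
            feat = feature_from_line(line)
        except Exception as exc:  # malformed attribute column etc.
            raise AnnotationParseError(f"line {lineno}: malformed record ({exc})") from exc
        feats.append((lineno, feat))
        if feat.featuretype in _TRANSCRIPT_TYPES or feat.featuretype.endswith("RNA"):
            tid = _attr(feat, "ID", "transcript_id")
            gid = _attr(feat, "Parent", "gene_id")
            if tid and gid:
                tx2gene[tid] = gid

    transcripts: dict[str, Transcript] = {}
    for lineno, feat in feats:
        if feat.featuretype != "exon":
            continue
        tid = _attr(feat, "transcript_id", "Parent")
        if tid is None:
            raise AnnotationParseError(f"line {lineno}: exon lacks a transcript attribute")
        gid = _attr(feat, "gene_id") or tx2gene.get(tid)
        if gid is None:
            raise AnnotationParseError(f"line {lineno}: exon lacks a gene attribute")
        strand = feat.strand if feat.strand in "+-" else "+"
        iv = GenomicInterval(feat.seqid, feat.start - 1, feat.end, strand)
        tx = transcripts.setdefault(tid, Transcript(tid, gid))
        tx.exons.append(iv)

    genes: dict[str, list[Transcript]] = {}
    for tx in transcripts.values():
        tx.exons.sort(key=lambda iv: (iv.start, iv.end))
        genes.setdefault(tx.gene_id, []).append(tx)
    for txs in genes.values():
        txs.sort(key=lambda t: t.transcript_id)
    return genes


# ---------------------------------------------------------------------------
# model construction


def build_gene_model(
    transcripts: list[Transcript], mode: str = "union_intersection"
) -> GeneIntervalSet:
    """Build one gene's interval set from its transcripts.

    ``union_intersection`` intersects the exon base sets of all
    transcripts (constitutive bases); ``union`` takes the base-set
    union. The result is canonical: sorted, disjoint, adjacent runs
    merged.

    Raises
    ------
    ValueError
        Empty transcript list, mixed gene ids, or transcripts spanning
        multiple chromosomes/strands (callers building a whole
        annotation skip such genes with a warning instead).
    """
    if not transcripts:
        raise ValueError("no transcripts given")
    gene_ids = {t.gene_id for t in transcripts}
    if len(gene_ids) != 1:
        raise ValueError(f"transcripts from multiple genes: {sorted(gene_ids)}")
    chroms = {t.chrom for t in transcripts}
    strands = {t.strand for t in transcripts}
    if len(chroms) != 1 or len(strands) != 1:
        raise ValueError(
            f"gene {transcripts[0].gene_id} spans multiple chromosomes/strands"
        )
    if mode not in ("union_intersection", "union"):
        raise ValueError(f"unknown gene model mode: {mode!r}")

    chrom, strand = chroms.pop(), strands.pop()
    spans = transcripts[0].merged_exons()
    for tx in transcripts[1:]:
        if mode == "union_intersection":
            spans = _intersect(spans, tx.merged_exons())
        else:
            spans = _merge(spans + tx.merged_exons())
    return GeneIntervalSet(
        gene_id=transcripts[0].gene_id,
        chrom=chrom,
        strand=strand,
        intervals=[GenomicInterval(chrom, s, e, strand) for s, e in spans],
    )


def build_all_gene_models(
    genes: dict[str, list[Transcript]], mode: str = "union_intersection"
) -> list[GeneIntervalSet]:
    """Build models for every gene, skipping multi-chromosome/strand genes
    with a logged warning, then remove cross-gene overlaps."""
    models = []
    for gid in sorted(genes):
        try:
            models.append(build_gene_model(genes[gid], mode=mode))
        except ValueError as exc:
            if "multiple chromosomes" in str(exc):
                logger.warning("skipping gene %s: %s", gid, exc)
            else:
                raise
    return subtract_cross_gene_overlaps(models)


def subtract_cross_gene_overlaps(models: list[GeneIntervalSet]) -> list[GeneIntervalSet]:
    """Remove every base claimed by two or more genes from all gene sets.

    Genes reduced to zero length are retained with an empty interval
    list (they yield zero counts and fall to the expression filter
    downstream).
    """
    # Event sweep per chromosome to find bases with coverage >= 2.
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for m in models:
        for s, e in m.spans():
            by_chrom.setdefault(m.chrom, []).append((s, e))

    shared: dict[str, list[tuple[int, int]]] = {}
    for chrom, spans in by_chrom.items():
        events: list[tuple[int, int]] = []
        for s, e in spans:
            events.append((s, 1))
            events.append((e, -1))
        events.sort()
        cov = 0
        prev = None
        hot: list[tuple[int, int]] = []
        for pos, delta in events:
            if prev is not None and cov >= 2 and pos > prev:
                hot.append((prev, pos))
            cov += delta
            prev = pos
        shared[chrom] = _merge(hot)

    out = []
    for m in models:
        spans = _subtract(m.spans(), shared.get(m.chrom, []))
        out.append(
            GeneIntervalSet(
                gene_id=m.gene_id,
                chrom=m.chrom,
                strand=m.strand,
                intervals=[GenomicInterval(m.chrom, s, e, m.strand) for s, e in spans],
            )
        )
    return out


# ---------------------------------------------------------------------------
# export


def export_bed(models: list[GeneIntervalSet], sink: str | TextIO) -> None:
    """Write one BED6 line per interval (name = gene_id), coordinate sorted."""
    if isinstance(sink, str):
        with open(sink, "w") as fh:
            export_bed(models, fh)
        return
    rows = []
    for m in models:
        for iv in m.intervals:
            rows.append((iv.chrom, iv.start, iv.end, m.gene_id, 0, m.strand))
    rows.sort(key=lambda r: (r[0], r[1], r[2], r[3]))
    for r in rows:
        sink.write("\t".join(map(str, r)) + "\n")


def import_bed(source: str | TextIO) -> list[GeneIntervalSet]:
    """Read BED6 interval sets back into gene models (round-trip of
    :func:`export_bed`); genes ordered by gene_id."""
    if isinstance(source, str):
        with open(source) as fh:
            return import_bed(fh)
    acc: dict[str, GeneIntervalSet] = {}
    for line in source:
        if not line.strip():
            continue
        chrom, start, end, name, _score, strand = line.rstrip("\n").split("\t")[:6]
        iv = GenomicInterval(chrom, int(start), int(end), strand)
        if name not in acc:
            acc[name] = GeneIntervalSet(name, chrom, strand, [])
        acc[name].intervals.append(iv)
    for m in acc.values():
        m.intervals.sort(key=lambda iv: iv.start)
    return [acc[g] for g in sorted(acc)]


def export_gene_table(models: list[GeneIntervalSet], sink: str | TextIO) -> None:
    """TSV gene table: gene_id, chrom, strand, n_intervals, length."""
    if isinstance(sink, str):
        with open(sink, "w") as fh:
            export_gene_table(models, fh)
        return
    sink.write("gene_id\tchrom\tstrand\tn_intervals\tlength\n")
    for m in sorted(models, key=lambda m: m.gene_id):
        sink.write(f"{m.gene_id}\t{m.chrom}\t{m.strand}\t{len(m.intervals)}\t{m.length}\n")
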