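"""Gene models and orientation classification of gene-trap insertions.

The disruption model is the standard unidirectional gene-trap one: a cassette
integrated in the gene body *in sense* with the host gene's transcriptional
direction truncates the transcript and creates a null allele in haploid cells,
whereas an antisense integration leaves the transcript intact.  Orientation is
therefore always called relative to a :class:`GeneModel`'s strand.

Coordinates are 0-based half-open everywhere in this package (the BED
convention); GTF input (1-based, inclusive) is converted on ingest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Literal, Sequence

from .errors import ParseError, ValidationError

logger = logging.getLogger(__name__)

Strand = Literal["+", "-"]
Orientation = Literal["sense", "antisense", "outside"]

_VALID_STRANDS = frozenset({"+", "-"})


@dataclass(frozen=True)
class GeneModel:
    """One gene's genomic interval, strand and exon structure.

    ``start``/``end`` and every exon interval are 0-based half-open.  Exons may
    be empty, in which case the gene is treated as a single intronless body by
    every consumer that cares about exon structure.
    """

    gene_id: str
    symbol: str
    chrom: str
    start: int
    end: int
    strand: Strand
    exons: tuple[tuple[int, int], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.strand not in _VALID_STRANDS:
            raise ValidationError(
                f"gene {self.gene_id!r}: strand must be '+' or '-', got {self.strand!r}"
            )
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"gene {self.gene_id!r}: require 0 <= start < end, "
                f"got [{self.start}, {self.end})"
            )
        prev_end = None
        for exon_start, exon_end in self.exons:
            if not (self.start <= exon_start < exon_end <= self.end):
                raise ValidationError(
                    f"gene {self.gene_id!r}: exon [{exon_start}, {exon_end}) "
                    f"outside gene body [{self.start}, {self.end})"
                )
            if prev_end is not None and exon_start < prev_end:
                raise ValidationError(
                    f"gene {self.gene_id!r}: exons must be sorted and non-overlapping"
                )
            prev_end = exon_end

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, chrom: str, position: int) -> bool:
        return chrom == self.chrom and self.start <= position < self.end

    def in_exon(self, position: int) -> bool:
        return any(s <= position < e for s, e in self.exons)


@dataclass(frozen=True)
class OrientationPolicy:
    """How insertion orientation maps to disruptiveness.

    With ``exonic_antisense_disruptive`` (off by default) an antisense
    integration that lands in an exon is escalated to "sense" (i.e. counted as
    disruptive), the behaviour of some earlier haploid-screen pipelines in
    which any exonic cassette breaks the transcript.  The default is the
    simpler model: sense disruptive anywhere in the gene body, antisense never.
    """

    exonic_antisense_disruptive: bool = False


DEFAULT_POLICY = OrientationPolicy()


def classify_insertion(ins, gene: GeneModel,
                       policy: OrientationPolicy = DEFAULT_POLICY) -> Orientation:
    """Classify one insertion against one gene as sense/antisense/outside.

    ``ins`` needs ``chrom``, ``position`` and ``strand`` attributes (see
    :class:`trapscreen.insertions.InsertionSite`).  Total and deterministic:
    every pair maps to exactly one label.
    """
    if ins.strand not in _VALID_STRANDS:
        raise ValidationError(f"insertion strand must be '+' or '-', got {ins.strand!r}")
    if not gene.contains(ins.chrom, ins.position):
        return "outside"
    if ins.strand == gene.strand:
        return "sense"
    if policy.exonic_antisense_disruptive and gene.in_exon(ins.position):
        return "sense"
    return "antisense"


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def load_gene_models(path: str | Path,
                     format: Literal["gtf", "bed12"] | None = None) -> list[GeneModel]:
    """Load gene models from a GTF (Ensembl dialect, gene/exon features) or BED12 file.

    The format is inferred from the file extension when not given.  GTF
    coordinates (1-based inclusive) are converted to 0-based half-open.
    Duplicate gene_ids are rejected.
    """
    path = Path(path)
    if format is None:
        suffix = path.suffix.lower()
        if suffix in {".gtf", ".gff"}:
            format = "gtf"
        elif suffix == ".bed":
            format = "bed12"
        else:
            raise ValidationError(
                f"cannot infer annotation format from extension {suffix!r}; "
                "pass format='gtf' or 'bed12'"
            )
    if format == "gtf":
        genes = list(_iter_gtf(path))
    elif format == "bed12":
        genes = list(_iter_bed12(path))
    else:
        raise ValidationError(f"unknown annotation format {format!r}")

    seen: set[str] = set()
    for g in genes:
        if g.gene_id in seen:
            raise ValidationError(f"duplicate gene_id {g.gene_id!r} in {path}")
        seen.add(g.gene_id)
    return genes


def _parse_gtf_attributes(raw: str, path: Path, lineno: int) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in raw.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        try:
            key, value = chunk.split(None, 1)
        except ValueError:
            raise ParseError(f"malformed attribute {chunk!r}", str(path), lineno)
        attrs[key] = value.strip().strip('"')
    return attrs


def _iter_gtf(path: Path) -> Iterator[GeneModel]:
    # gene lines give the span, exon lines the structure; genes present only
    # as exon lines get a span inferred from their exons.
    spans: dict[str, tuple[str, int, int, str, str]] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    exon_context: dict[str, tuple[str, str]] = {}  # gene_id -> (chrom, strand)
    order: list[str] = []

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(
                    f"expected 9 tab-separated fields, got {len(fields)}",
                    str(path), lineno,
                )
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attr_s = fields
            if feature not in ("gene", "exon"):
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError:
                raise ParseError(
                    f"non-integer coordinates {start_s!r}/{end_s!r}", str(path), lineno
                )
            if strand not in _VALID_STRANDS:
                raise ValidationError(
                    f"{path}:{lineno}: unknown strand symbol {strand!r}"
                )
            attrs = _parse_gtf_attributes(attr_s, path, lineno)
            gene_id = attrs.get("gene_id")
            if not gene_id:
                raise ParseError("missing gene_id attribute", str(path), lineno)
            start, end = start1 - 1, end1  # 1-based inclusive -> 0-based half-open
            if feature == "gene":
                symbol = attrs.get("gene_name", gene_id)
                if gene_id in spans:
                    raise ValidationError(
                        f"{path}:{lineno}: duplicate gene_id {gene_id!r}"
                    )
                spans[gene_id] = (chrom, start, end, strand, symbol)
                order.append(gene_id)
            else:
                exons.setdefault(gene_id, []).append((start, end))
                exon_context.setdefault(gene_id, (chrom, strand))
                if gene_id not in spans and gene_id not in order:
                    order.append(gene_id)

    for gene_id in order:
        exon_list = tuple(sorted(exons.get(gene_id, [])))
        if gene_id in spans:
            chrom, start, end, strand, symbol = spans[gene_id]
        else:
            # gene feature absent; infer the span from the exons
            chrom, strand = exon_context[gene_id]
            start = min(s for s, _e in exon_list)
            end = max(e for _s, e in exon_list)
            symbol = gene_id
        yield GeneModel(gene_id, symbol, chrom, start, end, strand, exon_list)


def _iter_bed12(path: Path) -> Iterator[GeneModel]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ParseError(
                    f"expected 12 BED fields, got {len(fields)}", str(path), lineno
                )
            chrom, start_s, end_s, name, _score, strand = fields[:6]
            block_count_s, block_sizes_s, block_starts_s = fields[9:12]
            try:
                start, end = int(start_s), int(end_s)
                n_blocks = int(block_count_s)
                sizes = [int(x) for x in block_sizes_s.rstrip(",").split(",")]
                offsets = [int(x) for x in block_starts_s.rstrip(",").split(",")]
            except ValueError:
                raise ParseError("malformed numeric field", str(path), lineno)
            if strand not in _VALID_STRANDS:
                raise ValidationError(
                    f"{path}:{lineno}: unknown strand symbol {strand!r}"
                )
            if len(sizes) != n_blocks or len(offsets) != n_blocks:
                raise ParseError(
                    f"blockCount {n_blocks} disagrees with block lists",
                    str(path), lineno,
                )
            exons = tuple(sorted((start + off, start + off + size)
                                 for off, size in zip(offsets, sizes)))
            yield GeneModel(name, name, chrom, start, end, strand, exons)


def write_gene_models_tsv(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Export gene models as a TSV of (gene_id, symbol, chrom, start, end, strand, n_exons)."""
    with open(path, "w") as fh:
        fh.write("gene_id\tsymbol\tchrom\tstart\tend\tstrand\tn_exons\n")
        for g in genes:
            fh.write(f"{g.gene_id}\t{g.symbol}\t{g.chrom}\t{g.start}\t{g.end}\t"
                     f"{g.strand}\t{len(g.exons)}\n")


def write_gene_models_bed12(genes: Sequence[GeneModel], path: str | Path) -> None:
    """Write gene models as BED12; intronless genes become a single block."""
    with open(path, "w") as fh:
        for g in genes:
            blocks = g.exons if g.exons else ((g.start, g.end),)
            sizes = ",".join(str(e - s) for s, e in blocks)
            offsets = ",".join(str(s - g.start) for s, _e in blocks)
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\t"
                     f"{g.start}\t{g.end}\t0\t{len(blocks)}\t{sizes}\t{offsets}\n")
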