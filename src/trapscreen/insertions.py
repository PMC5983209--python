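"""Reading, deduplicating and per-gene tallying of gene-trap insertion sites.

Insertion collections are carried as pandas DataFrames with columns
``chrom`` (str), ``position`` (int, 0-based point), ``strand`` ('+'/'-'),
``sample_id`` (str) and ``read_count`` (int >= 1).  Downstream statistics use
unique integration events only; read counts are retained for filtering but
never enter any test statistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .annotation import DEFAULT_POLICY, GeneModel, OrientationPolicy
from .errors import ParseError, ValidationError

logger = logging.getLogger(__name__)

INSERTION_COLUMNS = ["chrom", "position", "strand", "sample_id", "read_count"]

Condition = Literal["treated", "control"]


class InsertionSite(NamedTuple):
    """One mapped gene-trap integration event."""

    chrom: str
    position: int
    strand: str
    sample_id: str
    read_count: int = 1


class GeneInsertionCounts(NamedTuple):
    """Per-gene tally of unique disruptive (sense) and non-disruptive (antisense) events."""

    gene_id: str
    sense: int
    antisense: int

    @property
    def total(self) -> int:
        return self.sense + self.antisense


@dataclass
class ScreenDataset:
    """Per-gene insertion counts for one sample (or a pool of samples).

    ``counts`` is indexed by gene_id with integer columns ``sense``,
    ``antisense`` and ``total``; every gene of the annotation appears, with
    zeros where no insertion overlapped.  ``library_total`` is the number of
    unique insertions genome-wide, intergenic ones included.
    """

    sample_id: str
    condition: Condition
    counts: pd.DataFrame
    library_total: int

    def __post_init__(self) -> None:
        if self.condition not in ("treated", "control"):
            raise ValidationError(
                f"condition must be 'treated' or 'control', got {self.condition!r}"
            )

    def gene(self, gene_id: str) -> GeneInsertionCounts:
        row = self.counts.loc[gene_id]
        return GeneInsertionCounts(gene_id, int(row["sense"]), int(row["antisense"]))

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    def to_tsv(self, path: str | Path) -> None:
        out = self.counts.copy()
        out["sample_id"] = self.sample_id
        out["condition"] = self.condition
        out.to_csv(path, sep="\t", index_label="gene_id")


def sites_frame(sites: Iterable[InsertionSite]) -> pd.DataFrame:
    """Build the canonical insertion DataFrame from InsertionSite records."""
    df = pd.DataFrame(list(sites), columns=INSERTION_COLUMNS)
    return _validate_frame(df)


def _validate_frame(df: pd.DataFrame) -> pd.DataFrame:
    if len(df) and (df["position"] < 0).any():
        bad = df.loc[df["position"] < 0].iloc[0]
        raise ValidationError(f"negative insertion coordinate {bad['position']}")
    if len(df) and not df["strand"].isin(["+", "-"]).all():
        bad = df.loc[~df["strand"].isin(["+", "-"]), "strand"].iloc[0]
        raise ValidationError(f"invalid strand {bad!r}")
    return df


def read_insertions(path: str | Path, sample_id: str) -> pd.DataFrame:
    """Read mapped insertion sites from a BED6 file.

    Each record is one sequenced integration event; the score column, when
    numeric, is kept as the supporting read count (default 1).  Records wider
    than one base are reduced to their start coordinate with a warning — the
    integration point is a point event.
    """
    path = Path(path)
    rows: list[tuple[str, int, str, str, int]] = []
    n_wide = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ParseError(
                    f"BED6 requires 6 columns (strand missing?), got {len(fields)}",
                    str(path), lineno,
                )
            chrom, start_s, end_s, _name, score_s, strand = fields[:6]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise ParseError(f"non-integer interval {start_s!r}..{end_s!r}",
                                 str(path), lineno)
            if start < 0:
                raise ValidationError(f"{path}:{lineno}: negative coordinate {start}")
            if strand not in ("+", "-"):
                raise ValidationError(f"{path}:{lineno}: invalid strand {strand!r}")
            if end != start + 1:
                n_wide += 1
            try:
                read_count = max(1, int(float(score_s)))
            except ValueError:
                read_count = 1
            rows.append((chrom, start, strand, sample_id, read_count))
    if n_wide:
        logger.warning(
            "%s: %d records wider than 1 bp reduced to their start coordinate",
            path, n_wide,
        )
    df = pd.DataFrame(rows, columns=INSERTION_COLUMNS)
    return _validate_frame(df)


def write_insertions_bed(df: pd.DataFrame, path: str | Path) -> None:
    """Write insertion sites as BED6 (name column carries the sample_id)."""
    with open(path, "w") as fh:
        for row in df.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.position}\t{row.position + 1}\t"
                     f"{row.sample_id}\t{row.read_count}\t{row.strand}\n")


def filter_min_reads(df: pd.DataFrame, min_reads: int = 1) -> pd.DataFrame:
    """Drop sites supported by fewer than ``min_reads`` reads (pre-deduplication)."""
    if min_reads <= 1:
        return df
    return df.loc[df["read_count"] >= min_reads].reset_index(drop=True)


def deduplicate(df: pd.DataFrame) -> pd.DataFrame:
    """Collapse to unique integration events keyed by (chrom, position, strand).

    Read counts of duplicates are summed; output is sorted by the key so the
    operation is deterministic and idempotent.  All sites must share one
    sample_id (pooling across samples is always explicit, never implicit).
    """
    if len(df) == 0:
        return df.copy()
    samples = df["sample_id"].unique()
    if len(samples) > 1:
        raise ValidationError(
            f"deduplicate expects a single sample, got {sorted(samples)}"
        )
    out = (
        df.groupby(["chrom", "position", "strand"], as_index=False, sort=True)
        .agg(read_count=("read_count", "sum"))
    )
    out["sample_id"] = samples[0]
    return out[INSERTION_COLUMNS]


def count_per_gene(df: pd.DataFrame, genes: Sequence[GeneModel],
                   policy: OrientationPolicy = DEFAULT_POLICY,
                   sample_id: str | None = None,
                   condition: Condition = "control") -> ScreenDataset:
    """Tally unique sense/antisense insertions per gene into a ScreenDataset.

    Expects deduplicated input.  An insertion inside two overlapping gene
    bodies increments both genes' tallies, so per-gene counts never depend on
    tie-breaking.  Counting is done per gene window with searchsorted over
    per-chromosome sorted position arrays, which is fast even for multi-million
    site libraries.
    """
    if sample_id is None:
        sample_id = str(df["sample_id"].iloc[0]) if len(df) else "sample"

    # per (chrom, strand) sorted position arrays, plus per-chrom combined
    by_key: dict[tuple[str, str], np.ndarray] = {}
    for (chrom, strand), sub in df.groupby(["chrom", "strand"], sort=False):
        by_key[(chrom, strand)] = np.sort(sub["position"].to_numpy())

    def window_count(chrom: str, strand: str, start: int, end: int) -> int:
        arr = by_key.get((chrom, strand))
        if arr is None:
            return 0
        return int(np.searchsorted(arr, end, side="left")
                   - np.searchsorted(arr, start, side="left"))

    records = []
    for g in genes:
        opposite = "-" if g.strand == "+" else "+"
        sense = window_count(g.chrom, g.strand, g.start, g.end)
        anti = window_count(g.chrom, opposite, g.start, g.end)
        if policy.exonic_antisense_disruptive and g.exons:
            exonic_anti = sum(window_count(g.chrom, opposite, s, e) for s, e in g.exons)
            sense += exonic_anti
            anti -= exonic_anti
        records.append((g.gene_id, sense, anti))

    counts = pd.DataFrame(records, columns=["gene_id", "sense", "antisense"])
    counts = counts.set_index("gene_id")
    counts["total"] = counts["sense"] + counts["antisense"]
    return ScreenDataset(sample_id=sample_id, condition=condition,
                         counts=counts, library_total=len(df))


def pool_datasets(datasets: Sequence[ScreenDataset],
                  sample_id: str | None = None) -> ScreenDataset:
    """Sum per-gene counts across datasets of one condition (explicit pooling)."""
    if not datasets:
        raise ValidationError("cannot pool an empty list of datasets")
    conditions = {d.condition for d in datasets}
    if len(conditions) > 1:
        raise ValidationError(f"cannot pool across conditions {sorted(conditions)}")
    universe = datasets[0].counts.index
    for d in datasets[1:]:
        if not d.counts.index.equals(universe):
            raise ValidationError("datasets to pool have different gene universes")
    counts = sum(d.counts[["sense", "antisense"]] for d in datasets)
    counts["total"] = counts["sense"] + counts["antisense"]
    return ScreenDataset(
        sample_id=sample_id or "+".join(d.sample_id for d in datasets),
        condition=datasets[0].condition,
        counts=counts,
        library_total=sum(d.library_total for d in datasets),
    )
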