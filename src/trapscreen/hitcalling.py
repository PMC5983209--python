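"""Aggregation of per-replicate comparisons into final hit lists and Venn splits."""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .errors import ValidationError
from .insertions import GeneInsertionCounts
from .screen_stats import AnalysisParams, compare_gene

HIT_CLASSES = ("sensitizer", "resistance")


@dataclass
class HitTable:
    """Final hit list for one screen, with the parameter snapshot that produced it.

    ``hits`` has one row per called gene: gene_id (index), classification,
    pooled_p, pooled_effect, and one ``p_rep<i>`` column per treated
    replicate.  Ordered by ascending pooled p, ties broken by gene_id.
    """

    screen_id: str
    hits: pd.DataFrame
    params: AnalysisParams

    @property
    def gene_ids(self) -> set[str]:
        return set(self.hits.index)

    def to_tsv(self, path: str | Path) -> None:
        out = self.hits.copy()
        for key, value in self.params.to_dict().items():
            out[f"param_{key}"] = value
        out.to_csv(path, sep="\t", index_label="gene_id")


def _pooled_comparison(replicate_results: Sequence[pd.DataFrame],
                       params: AnalysisParams) -> pd.DataFrame:
    """Re-test each gene on treated counts summed across replicates."""
    first = replicate_results[0]
    sense_t = sum(df["sense_t"] for df in replicate_results)
    anti_t = sum(df["anti_t"] for df in replicate_results)
    rows = []
    for gene_id in first.index:
        treated = GeneInsertionCounts(gene_id, int(sense_t[gene_id]), int(anti_t[gene_id]))
        control = GeneInsertionCounts(
            gene_id, int(first.loc[gene_id, "sense_c"]), int(first.loc[gene_id, "anti_c"])
        )
        rows.append(compare_gene(treated, control, params))
    return pd.DataFrame(rows).set_index("gene_id")


def call_hits(replicate_results: Sequence[pd.DataFrame],
              params: AnalysisParams = AnalysisParams(),
              screen_id: str = "screen") -> HitTable:
    """Combine per-replicate comparison tables into a hit list.

    replicate_rule = 'all': a gene is a hit iff it gets the same non-neutral
    classification in every treated replicate (genes untestable in any
    replicate are excluded); 'any': in at least one; 'pooled': treated counts
    are summed across replicates and tested once.  The control side must be
    identical across replicates (it is the same pooled/normalizing control).
    """
    if not replicate_results:
        raise ValidationError("call_hits requires at least one replicate result set")
    universe = replicate_results[0].index
    for df in replicate_results[1:]:
        if not df.index.equals(universe):
            raise ValidationError("replicate results cover different gene universes")

    pooled = _pooled_comparison(replicate_results, params)

    records = []
    for gene_id in universe:
        classes = [df.loc[gene_id, "classification"] for df in replicate_results]
        if params.replicate_rule == "all":
            if "untestable" in classes:
                continue
            called = classes[0] in HIT_CLASSES and all(c == classes[0] for c in classes)
            label = classes[0] if called else None
        elif params.replicate_rule == "any":
            hit_classes = [c for c in classes if c in HIT_CLASSES]
            called = bool(hit_classes)
            label = hit_classes[0] if called else None
        else:  # pooled
            label = pooled.loc[gene_id, "classification"]
            called = label in HIT_CLASSES
        if not called:
            continue
        rec = {
            "gene_id": gene_id,
            "classification": label,
            "pooled_p": pooled.loc[gene_id, "p_value"],
            "pooled_effect": pooled.loc[gene_id, "effect_size"],
        }
        for i, df in enumerate(replicate_results, start=1):
            rec[f"p_rep{i}"] = df.loc[gene_id, "p_value"]
        records.append(rec)

    if records:
        hits = pd.DataFrame(records).set_index("gene_id")
        # ascending pooled p; ties broken lexicographically for byte-stable output
        hits = hits.sort_index(kind="mergesort").sort_values("pooled_p",
                                                             kind="mergesort")
    else:
        hits = pd.DataFrame(
            columns=["classification", "pooled_p", "pooled_effect"]
            + [f"p_rep{i}" for i in range(1, len(replicate_results) + 1)]
        )
        hits.index.name = "gene_id"
    return HitTable(screen_id=screen_id, hits=hits, params=params)


@dataclass(frozen=True)
class VennPartition:
    """Disjoint split of two screens' hit genes."""

    unique_a: frozenset[str]
    shared: frozenset[str]
    unique_b: frozenset[str]

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "unique_a": {"count": len(self.unique_a), "genes": sorted(self.unique_a)},
            "shared": {"count": len(self.shared), "genes": sorted(self.shared)},
            "unique_b": {"count": len(self.unique_b), "genes": sorted(self.unique_b)},
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def compare_screens(a: HitTable | set[str], b: HitTable | set[str]) -> VennPartition:
    """Partition two hit lists into (unique to a, shared, unique to b).

    The three sets are disjoint and conserve sizes:
    |unique_a| + |shared| = |a| and |unique_b| + |shared| = |b|.
    """
    set_a = a.gene_ids if isinstance(a, HitTable) else set(a)
    set_b = b.gene_ids if isinstance(b, HitTable) else set(b)
    return VennPartition(
        unique_a=frozenset(set_a - set_b),
        shared=frozenset(set_a & set_b),
        unique_b=frozenset(set_b - set_a),
    )
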