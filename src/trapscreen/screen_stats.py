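"""Per-gene treated-vs-control comparison statistics.

For every gene the unique-insertion tallies form a 2x2 table

    =========  ======  ==========
    dataset     sense   antisense
    =========  ======  ==========
    treated    s_t      a_t
    control    s_c      a_c
    =========  ======  ==========

The sense ratio s/(s+a) sits near 0.5 for fitness-neutral genes (the chance
orientation ratio of the unidirectional cassette), drops below 0.5 when
disruption of the gene is selected against, and rises above 0.5 when it
confers a survival benefit.  Treated and control tables are compared with a
two-sided Fisher exact test ("sum of small p's" convention) plus a fold-change
effect size on the sense fractions; default thresholds are p <= 0.01 with an
effect size >= 1.2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .insertions import GeneInsertionCounts, ScreenDataset

ReplicateRule = Literal["all", "any", "pooled"]
Direction = Literal["sensitizer", "resistance", "both"]
Classification = Literal["sensitizer", "resistance", "neutral", "untestable"]

RESULT_COLUMNS = [
    "gene_id", "sense_t", "anti_t", "sense_c", "anti_c",
    "ratio_t", "ratio_c", "p_value", "effect_size", "classification",
]


@dataclass(frozen=True)
class AnalysisParams:
    """Hit-calling thresholds and testability rules.

    alpha
        significance threshold on the raw Fisher p-value.
    effect_cutoff
        minimum fold-change between control and treated sense fractions.
    min_total_control
        minimum unique insertions in the (pooled) control for a gene to be
        testable; genes below it are reported as untestable, never as neutral.
    replicate_rule
        'all' (every treated replicate must support the call), 'any', or
        'pooled' (treated replicates summed before testing).
    direction
        which classifications to call; the spec of the screen decides whether
        depletion (sensitizer), enrichment (resistance) or both are of
        interest.
    effect_measure
        'ratio' = fold-change of sense fractions (default); 'odds' = odds
        ratio of the 2x2 table, for users who prefer it.
    """

    alpha: float = 0.01
    effect_cutoff: float = 1.2
    min_total_control: int = 8
    replicate_rule: ReplicateRule = "all"
    direction: Direction = "both"
    effect_measure: Literal["ratio", "odds"] = "ratio"

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValidationError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.effect_cutoff < 1.0:
            raise ValidationError(
                f"effect_cutoff must be >= 1, got {self.effect_cutoff}"
            )
        if self.min_total_control < 0:
            raise ValidationError("min_total_control must be >= 0")
        if self.replicate_rule not in ("all", "any", "pooled"):
            raise ValidationError(f"unknown replicate_rule {self.replicate_rule!r}")
        if self.direction not in ("sensitizer", "resistance", "both"):
            raise ValidationError(f"unknown direction {self.direction!r}")

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "effect_cutoff": self.effect_cutoff,
            "min_total_control": self.min_total_control,
            "replicate_rule": self.replicate_rule,
            "direction": self.direction,
            "effect_measure": self.effect_measure,
        }


@dataclass(frozen=True)
class ComparisonResult:
    """Per-gene drug-vs-control statistics."""

    gene_id: str
    sense_t: int
    anti_t: int
    sense_c: int
    anti_c: int
    ratio_t: float  # nan when treated total is 0
    ratio_c: float  # nan when control total is 0
    p_value: float  # nan when untestable
    effect_size: float  # sensitizer-direction fold change; nan when untestable
    classification: Classification


def sense_ratio(counts: GeneInsertionCounts) -> float:
    """Fraction of unique insertions in the disruptive (sense) orientation."""
    total = counts.sense + counts.antisense
    if total == 0:
        raise ValidationError(
            f"gene {counts.gene_id!r}: sense ratio undefined for zero insertions"
        )
    return counts.sense / total


def fisher_two_sided(sense_t: int, anti_t: int, sense_c: int, anti_c: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[sense_t, anti_t], [sense_c, anti_c]].

    Uses the "sum of small p's" convention: the p-value is the total
    hypergeometric probability of all tables with the observed margins whose
    probability does not exceed the observed table's.
    """
    if min(sense_t, anti_t, sense_c, anti_c) < 0:
        raise ValidationError("Fisher table entries must be non-negative")
    if sense_t + anti_t + sense_c + anti_c == 0:
        raise ValidationError("Fisher test undefined for the all-zero table")
    _odds, p = stats.fisher_exact([[sense_t, anti_t], [sense_c, anti_c]],
                                  alternative="two-sided")
    return float(p)


def effect_size(ratio_c: float, ratio_t: float,
                direction: Literal["sensitizer", "resistance"] = "sensitizer") -> float:
    """Fold change between the control and treated sense fractions.

    Sensitizer direction: ratio_c / ratio_t (depletion of sense events under
    treatment gives values > 1).  Resistance direction: the reciprocal.
    Returns +inf when the denominator is 0 and the numerator positive, and 1.0
    for the degenerate 0/0 case (which testability rules catch upstream).
    """
    if math.isnan(ratio_c) or math.isnan(ratio_t):
        raise ValidationError("effect size undefined for an undefined ratio")
    num, den = (ratio_c, ratio_t) if direction == "sensitizer" else (ratio_t, ratio_c)
    if den == 0.0:
        return math.inf if num > 0 else 1.0
    return num / den


def compare_gene(treated: GeneInsertionCounts, control: GeneInsertionCounts,
                 params: AnalysisParams = AnalysisParams()) -> ComparisonResult:
    """Compare one gene's treated and control tallies and classify it.

    sensitizer: p <= alpha, sensitizer-direction effect >= cutoff, ratio_t < ratio_c.
    resistance: p <= alpha, resistance-direction effect >= cutoff, ratio_t > ratio_c.
    untestable: control below ``min_total_control`` or either ratio undefined.
    neutral: everything else.
    """
    t_total = treated.sense + treated.antisense
    c_total = control.sense + control.antisense
    ratio_t = treated.sense / t_total if t_total else math.nan
    ratio_c = control.sense / c_total if c_total else math.nan

    untestable = (
        c_total < params.min_total_control or c_total == 0 or t_total == 0
    )
    if untestable:
        return ComparisonResult(
            treated.gene_id, treated.sense, treated.antisense,
            control.sense, control.antisense,
            ratio_t, ratio_c, math.nan, math.nan, "untestable",
        )

    p = fisher_two_sided(treated.sense, treated.antisense,
                         control.sense, control.antisense)
    if params.effect_measure == "odds":
        sens_effect = _odds_effect(treated, control, "sensitizer")
        res_effect = _odds_effect(treated, control, "resistance")
    else:
        sens_effect = effect_size(ratio_c, ratio_t, "sensitizer")
        res_effect = effect_size(ratio_c, ratio_t, "resistance")

    classification: Classification = "neutral"
    if p <= params.alpha:
        if (ratio_t < ratio_c and sens_effect >= params.effect_cutoff
                and params.direction in ("sensitizer", "both")):
            classification = "sensitizer"
        elif (ratio_t > ratio_c and res_effect >= params.effect_cutoff
                and params.direction in ("resistance", "both")):
            classification = "resistance"

    return ComparisonResult(
        treated.gene_id, treated.sense, treated.antisense,
        control.sense, control.antisense,
        ratio_t, ratio_c, p, sens_effect, classification,
    )


def _odds_effect(treated: GeneInsertionCounts, control: GeneInsertionCounts,
                 direction: str) -> float:
    """Haldane-free odds ratio oriented so that > 1 supports the given direction."""
    num = control.sense * treated.antisense
    den = control.antisense * treated.sense
    if direction == "resistance":
        num, den = den, num
    if den == 0:
        return math.inf if num > 0 else 1.0
    return num / den


def compare_datasets(treated: ScreenDataset, control: ScreenDataset,
                     params: AnalysisParams = AnalysisParams()) -> pd.DataFrame:
    """Per-gene comparison of a treated dataset against a (pooled) control.

    Returns one row per gene with the :class:`ComparisonResult` fields plus an
    informational Benjamini-Hochberg ``q_value`` column (no multiple-testing
    correction enters the classification; the screen design uses a raw
    threshold with an effect-size filter).
    """
    if not treated.counts.index.equals(control.counts.index):
        raise ValidationError(
            "treated and control datasets have different gene universes"
        )
    rows = []
    for gene_id in treated.counts.index:
        res = compare_gene(treated.gene(gene_id), control.gene(gene_id), params)
        rows.append(res)
    df = pd.DataFrame(rows, columns=RESULT_COLUMNS).set_index("gene_id")
    df["q_value"] = bh_adjust(df["p_value"])
    return df


def bh_adjust(p_values: pd.Series) -> pd.Series:
    """Benjamini-Hochberg adjusted p-values; NaNs (untestable genes) pass through."""
    out = pd.Series(np.nan, index=p_values.index, dtype=float)
    mask = p_values.notna()
    if mask.any():
        out.loc[mask] = multipletests(p_values[mask].to_numpy(), method="fdr_bh")[1]
    return out
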