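"""Forward simulator for haploid gene-trap negative-selection screens.

The generative model mirrors the screen layout: a library of haploid mutant
cells, each carrying exactly one gene-trap integration at a uniformly random
genomic position with a random cassette orientation, is subjected to a
selection bottleneck.  A cell whose integration disrupts a gene (sense
orientation inside the gene body, under the default orientation policy)
survives with that gene's per-condition fitness weight; every other cell
survives with weight 1.  An additional genotype-independent ``base_survival``
models the overall severity of the bottleneck.  Surviving cells' integration
sites, deduplicated, are what the sequencer would report — so the simulator's
output feeds the exact same BED-driven pipeline as a real screen.

With all weights equal the expected per-gene sense ratio is p_sense (0.5 by
default, the chance orientation ratio); planting a sensitizer weight < 1 in
the treated condition depletes that gene's sense events after selection,
which is the signature the screen statistics are designed to detect.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import GeneModel, write_gene_models_bed12
from .errors import ValidationError
from .insertions import INSERTION_COLUMNS, Condition, write_insertions_bed

_CONDITION_CODE = {"treated": 0, "control": 1}


@dataclass(frozen=True)
class SimulationConfig:
    """Full generative description of one synthetic screen.

    fitness maps condition -> gene_id -> survival weight in [0, 1] applied to
    cells whose integration disrupts that gene; genes absent from the map are
    neutral (weight 1).  base_survival maps condition -> genotype-independent
    survival probability (default 1.0, i.e. no extra bottleneck).
    """

    n_genes: int = 2_000
    gene_length: int = 10_000
    intergenic_fraction: float = 0.5
    n_cells: int = 2_000_000
    p_sense: float = 0.5
    fitness: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    base_survival: Mapping[str, float] = field(default_factory=dict)
    n_treated_reps: int = 2
    n_control_reps: int = 4
    strand_rule: Literal["alternate", "random"] = "alternate"
    chrom: str = "chrS"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ValidationError("n_genes must be > 0")
        if self.n_cells <= 0:
            raise ValidationError("n_cells must be > 0")
        if self.gene_length <= 0:
            raise ValidationError("gene_length must be > 0")
        if not (0.0 <= self.intergenic_fraction < 1.0):
            raise ValidationError("intergenic_fraction must be in [0, 1)")
        if not (0.0 <= self.p_sense <= 1.0):
            raise ValidationError("p_sense must be in [0, 1]")
        for cond, weights in self.fitness.items():
            for gene_id, w in weights.items():
                if not (0.0 <= w <= 1.0):
                    raise ValidationError(
                        f"fitness[{cond}][{gene_id}] = {w} outside [0, 1]"
                    )
        for cond, s in self.base_survival.items():
            if not (0.0 <= s <= 1.0):
                raise ValidationError(f"base_survival[{cond}] = {s} outside [0, 1]")

    @property
    def genome_length(self) -> int:
        genic = self.n_genes * self.gene_length
        return int(round(genic / (1.0 - self.intergenic_fraction)))


@dataclass
class SimulatedScreen:
    """Simulator output: the toy genome, per-replicate insertions, and ground truth."""

    config: SimulationConfig
    genes: list[GeneModel]
    replicates: list[tuple[str, Condition, pd.DataFrame]]  # (sample_id, condition, sites)
    manifest: dict

    def write(self, outdir: str | Path) -> dict:
        """Write per-sample BED6 files, the toy genome BED12, and the manifest JSON."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        files = {}
        genome_path = outdir / "toy_genome.bed"
        write_gene_models_bed12(self.genes, genome_path)
        files["genome"] = str(genome_path)
        for sample_id, condition, sites in self.replicates:
            path = outdir / f"{sample_id}.bed"
            write_insertions_bed(sites, path)
            files[sample_id] = str(path)
        manifest = dict(self.manifest, files=files)
        manifest_path = outdir / "manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=2) + "\n")
        files["manifest"] = str(manifest_path)
        return manifest


def build_toy_genome(config: SimulationConfig) -> list[GeneModel]:
    """Lay out n_genes non-overlapping fixed-length genes on one synthetic chromosome.

    Genes are evenly spaced with equal intergenic gaps so that the genic
    fraction of the genome equals 1 - intergenic_fraction (up to rounding).
    Strands alternate +/- by default, or are Bernoulli(0.5) under
    strand_rule='random'.
    """
    genome = config.genome_length
    genic = config.n_genes * config.gene_length
    if genic > genome:
        raise ValidationError("gene lengths exceed the genome; lower intergenic_fraction")
    gap = (genome - genic) / (config.n_genes + 1)
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=[int(config.seed), 2, 0])
    )
    width = len(str(config.n_genes))
    genes = []
    for i in range(config.n_genes):
        start = int(round(gap * (i + 1) + config.gene_length * i))
        if config.strand_rule == "random":
            strand = "+" if rng.random() < 0.5 else "-"
        else:
            strand = "+" if i % 2 == 0 else "-"
        gene_id = f"G{i:0{width}d}"
        genes.append(GeneModel(gene_id, gene_id, config.chrom,
                               start, start + config.gene_length, strand))
    return genes


def _replicate_rng(config: SimulationConfig, condition: Condition,
                   rep_index: int) -> np.random.Generator:
    # keyed streams: adding replicates or conditions never perturbs earlier ones
    ss = np.random.SeedSequence(
        entropy=[int(config.seed), _CONDITION_CODE[condition], int(rep_index)]
    )
    return np.random.default_rng(ss)


def simulate_replicate(config: SimulationConfig, genes: Sequence[GeneModel],
                       condition: Condition, rep_index: int,
                       sample_id: str) -> pd.DataFrame:
    """Simulate one replicate's surviving, deduplicated insertion sites.

    Vectorized over the whole library: draw one integration per cell, decide
    sense/antisense per genic cell, apply the survival bottleneck, then
    collapse survivors to unique (position, strand) events.
    """
    rng = _replicate_rng(config, condition, rep_index)
    n = config.n_cells
    genome = config.genome_length

    positions = rng.integers(0, genome, size=n)
    sense_draw = rng.random(n) < config.p_sense  # orientation relative to host gene
    coin = rng.random(n) < 0.5  # genomic strand for intergenic integrations
    survival_draw = rng.random(n)

    starts = np.array([g.start for g in genes])
    ends = np.array([g.end for g in genes])
    gene_strand_plus = np.array([g.strand == "+" for g in genes])

    # genes are non-overlapping and sorted, so a single searchsorted locates
    # the candidate gene for every cell
    idx = np.searchsorted(starts, positions, side="right") - 1
    idx_clipped = np.clip(idx, 0, len(genes) - 1)
    genic = (idx >= 0) & (positions < ends[idx_clipped])
    gene_idx = np.where(genic, idx_clipped, -1)

    # genomic cassette strand: for genic cells, sense means matching the host
    # gene's strand; intergenic cells get a fair coin
    host_plus = gene_strand_plus[idx_clipped]
    strand_plus = np.where(genic, ~(host_plus ^ sense_draw), coin)

    # survival: disruptive (genic sense) integrations get the gene's weight
    weights = np.ones(n)
    cond_fitness = config.fitness.get(condition, {})
    if cond_fitness:
        id_to_idx = {g.gene_id: i for i, g in enumerate(genes)}
        w_by_gene = np.ones(len(genes))
        for gene_id, w in cond_fitness.items():
            if gene_id not in id_to_idx:
                raise ValidationError(f"fitness references unknown gene {gene_id!r}")
            w_by_gene[id_to_idx[gene_id]] = w
        disruptive = genic & sense_draw
        weights[disruptive] = w_by_gene[gene_idx[disruptive]]
    weights *= config.base_survival.get(condition, 1.0)

    alive = survival_draw < weights
    if not alive.any():
        raise ValidationError(
            f"no surviving cells in replicate {sample_id}; increase n_cells "
            "or relax the selection"
        )

    pos_alive = positions[alive]
    plus_alive = strand_plus[alive]
    # deduplicate on (position, strand)
    key = pos_alive * 2 + plus_alive.astype(np.int64)
    uniq, counts = np.unique(key, return_counts=True)
    df = pd.DataFrame({
        "chrom": config.chrom,
        "position": uniq // 2,
        "strand": np.where(uniq % 2 == 1, "+", "-"),
        "sample_id": sample_id,
        "read_count": counts,
    })
    return df[INSERTION_COLUMNS]


def simulate_screen(config: SimulationConfig,
                    genes: Sequence[GeneModel] | None = None) -> SimulatedScreen:
    """Simulate a full screen: treated and control replicates plus ground truth."""
    gene_list = list(genes) if genes is not None else build_toy_genome(config)
    replicates: list[tuple[str, Condition, pd.DataFrame]] = []
    survivor_counts: dict[str, int] = {}
    for rep in range(config.n_treated_reps):
        sample_id = f"treated_rep{rep + 1}"
        sites = simulate_replicate(config, gene_list, "treated", rep, sample_id)
        replicates.append((sample_id, "treated", sites))
        survivor_counts[sample_id] = int(sites["read_count"].sum())
    for rep in range(config.n_control_reps):
        sample_id = f"control_rep{rep + 1}"
        sites = simulate_replicate(config, gene_list, "control", rep, sample_id)
        replicates.append((sample_id, "control", sites))
        survivor_counts[sample_id] = int(sites["read_count"].sum())

    manifest = {
        "seed": config.seed,
        "n_genes": config.n_genes,
        "gene_length": config.gene_length,
        "genome_length": config.genome_length,
        "n_cells": config.n_cells,
        "p_sense": config.p_sense,
        "n_treated_reps": config.n_treated_reps,
        "n_control_reps": config.n_control_reps,
        "base_survival": dict(config.base_survival),
        "fitness": {cond: dict(w) for cond, w in config.fitness.items()},
        "survivors": survivor_counts,
    }
    return SimulatedScreen(config=config, genes=gene_list,
                           replicates=replicates, manifest=manifest)
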