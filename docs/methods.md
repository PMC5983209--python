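# Methods

## Disruption model and orientation calls

The analysis assumes the standard unidirectional gene-trap model in haploid
cells: an integration in the gene body whose cassette orientation matches the
gene's transcriptional direction (sense) truncates the transcript and creates
a null allele; an antisense integration leaves the transcript functional.
Orientation is therefore a property of an (insertion, gene) pair, computed by
`classify_insertion` as `sense` / `antisense` / `outside`.

Two refinements are policy switches rather than assumptions baked in:

- `OrientationPolicy.exonic_antisense_disruptive` (default **off**) escalates
  antisense insertions that land in an annotated exon to "disruptive", the
  behaviour of some earlier haploid-screen pipelines in which any exonic
  cassette breaks the transcript. The default is the simpler body-wide
  sense-only model; both are supported because published pipelines differ
  and neither can be asserted as canonical.
- An insertion inside two overlapping gene bodies is counted for **both**
  genes. Per-gene tallies must not depend on an arbitrary tie-break; the cost
  is that summed genic counts can exceed the number of genic sites when
  annotations overlap.

Coordinates are 0-based half-open throughout (the BED convention); GTF input
is converted on ingest. Insertions are point events: BED records wider than
one base are reduced to their start coordinate with a logged warning.

## Unique events, not reads

All statistics operate on unique integration events keyed by
(chromosome, position, strand) — two events at the same base on opposite
strands are distinct. Supporting read counts are retained only for an
optional `min_reads` pre-filter (default 1, i.e. no filtering); they never
enter a test statistic, because library complexity, not amplification depth,
carries the selection signal. Deduplication is deterministic (sorted output)
and idempotent.

## Per-gene comparison

For each gene the treated and (pooled) control tallies form a 2×2 table
[[s_t, a_t], [s_c, a_c]]. Three statistics are derived:

- **sense ratio** r = s/(s+a), undefined (and the gene untestable) at zero
  total — never silently zero;
- **Fisher exact p**, two-sided under the "sum of small p's" convention
  (the total hypergeometric probability of all tables with the observed
  margins at most as probable as the observed one), via
  `scipy.stats.fisher_exact`; the test suite checks it exhaustively against
  an exact-integer enumeration oracle;
- **effect size**, the fold-change of sense fractions: r_c/r_t for the
  sensitizer direction, r_t/r_c for resistance, +inf when the denominator is
  zero with a positive numerator. The fold-change of proportions is the most
  direct reading of "comparing these proportions"; an odds-ratio variant is
  available via `AnalysisParams(effect_measure="odds")` because the original
  cutoff's exact operationalization is not published.

Classification: `sensitizer` iff p ≤ alpha, sensitizer-direction effect ≥
cutoff and r_t < r_c; `resistance` symmetric; `untestable` when the control
has fewer than `min_total_control` insertions (default 8) or either ratio is
undefined; otherwise `neutral`. Defaults alpha = 0.01 and effect cutoff = 1.2
are the screen's published calling criteria. No multiple-testing correction
enters the calls — the design couples a raw threshold to an effect filter and
replicate agreement — but a Benjamini–Hochberg `q_value` column is emitted
for information.

### Controls and replicates

The four untreated control libraries are summed per gene into one pooled
control by default: pooling maximizes the control denominator, and the
original normalization formula is unpublished. Per-replicate treated tables
are each tested against this pooled control, then combined by
`replicate_rule`: `all` (default — every treated replicate must support the
same call; genes untestable in any replicate are excluded), `any`, or
`pooled` (treated counts summed before one test). `all` is the strictest
reading of a two-replicate screen design. Hit tables are ordered by ascending
pooled p with lexicographic tie-breaks, so outputs are byte-stable.

## The simulator

`trapscreen.simulate` generates the study conditions end to end:

- **Toy genome**: `n_genes` (default 2,000) non-overlapping genes of fixed
  length (default 10 kb) evenly spaced on one synthetic chromosome, strands
  alternating (or Bernoulli(0.5)); intergenic DNA is `intergenic_fraction`
  (default 0.5) of the genome, so the default genome is 40 Mb.
- **Library**: one integration per cell (the single-hit gene-trap
  assumption), `n_cells` = 2×10⁶ by default, positions uniform over the
  genome. `p_sense` (default 0.5) is the probability that a genic integration
  is in sense orientation relative to its host gene; intergenic integrations
  get a fair coin for genomic strand. This makes the neutral per-gene sense
  expectation exactly `p_sense`.
- **Selection**: a cell survives with probability
  `base_survival[condition] × w`, where w is the disrupted gene's fitness
  weight under that condition (1 for non-disruptive integrations and
  unlisted genes). Defaults: 2 treated and 4 control replicates, matching the
  screen design.
- Survivors are deduplicated and written as BED6 (read_count = surviving
  cells per site), with the toy genome as BED12 and a JSON manifest carrying
  the planted weights — the ground truth for recovery benchmarks.

Randomness: each replicate draws from an independent stream keyed as
`SeedSequence([seed, condition_code, replicate_index])`, so adding replicates
or conditions never perturbs existing ones, and identical configs give
byte-identical outputs.

What the simulator does **not** model: LAM-PCR amplification bias and
read-count noise (read counts never enter statistics), integration hotspots
(available as a per-gene bias only via custom gene layouts), multi-insertion
cells, diploidization of HAP1 cells, and cell-cycle drug effects. Passing
recovery benchmarks on this generator therefore demonstrates that the
statistics recover planted selection signals under idealized uniform
integration — not that real LAM-PCR libraries are free of the biases above.

## Calibration behaviour and measurement precision

Two properties anchor the pipeline and are recomputed by
`scripts/acceptance.py` and the test suite:

- **Neutral ratio**: in an all-neutral full-scale library the mean sense
  ratio over genes with ≥ 100 unique insertions is 0.5 within 3 Monte-Carlo
  standard errors (a 40 Mb genome at 2×10⁶ cells gives ~500 unique insertions
  per gene, so effectively all 2,000 genes qualify).
- **Null false-positive fraction**: on null screens the fraction of testable
  per-gene Fisher tests with p ≤ 0.01 stays ≤ 0.01. At these insertion
  densities the exact test's conservativeness margin is small (empirical
  level ≈ 0.009), while one 2,000-gene screen estimates the fraction with a
  Monte-Carlo standard deviation of ≈ 0.002; the fraction is therefore
  measured as the average over five independent simulated screens, which
  estimates the same quantity with adequate precision. The bound itself is
  the nominal 0.01.
- **Recovery**: 50 sensitizers planted at treated weight 0.05 among 2,000
  genes are recovered with recall ≥ 0.9 and ≤ 1% false positives among
  neutral genes under default parameters (averaged over 5 seeds).

## Reporting

- **Fishtail tables**: per-gene y = sense ratio, x = log₁₀(total unique
  insertions) in the plotted dataset — the established abundance axis.
  Because published legends describing this plot admit a second literal
  reading, x = log₁₀(sense/total) is available via `axis="sense_fraction"`;
  neither is asserted as the original. Genes with zero usable counts are
  excluded (x undefined). y shares the `sense_ratio` code path with the
  statistics, so plot and test can never drift apart.
- **Expression–sensitivity correlation**: per-tissue ordinary least squares
  of log₁₀[IC50] on gene expression over a (cell_line, expression,
  log10_ic50, tissue) table. Clusters need ≥ 6 complete lines to be
  considered; flagged clusters have positive slope and R² ≥ 0.2; significance
  is additionally marked at regression p < 0.05. Zero-variance clusters are
  skipped with a warning. Obtaining real cell-line panels is the user's
  responsibility; the stage operates on plain TSV.

## Numerical and degenerate-input conventions

- All-zero Fisher tables and zero-total sense ratios raise, and reach users
  as `untestable` classifications rather than exceptions in the per-gene path.
- Effect size 0/0 is defined as 1.0 but unreachable through `compare_gene`
  (testability rules catch those genes first).
- The exhaustive Fisher validation sweeps every table with both row sums
  ≤ 30 against exact-integer enumeration at |Δp| < 1e-9.
- Problem sizes in the test suite: unit tests run libraries of 10³–10⁵
  cells; study-scale validations run 2,000 genes × 2×10⁶ cells per replicate,
  the screen's stated design scale.

## Known limitations

- Genes are intervals; transcript isoforms, UTR-specific rules and
  promoter/enhancer effects are out of scope.
- No merging of near-adjacent insertion coordinates (±1 bp alignment jitter
  would count as distinct events).
- The correlation stage does not reproduce any specific public panel's
  tissue clustering; labels are taken as given.
- GO enrichment of hit lists is out of scope (external services).
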