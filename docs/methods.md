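# Methods

Precise definitions of every computation in `crmkit`, including conventions
that matter for reproducing numbers exactly.

## Coordinates and formats

All intervals are 0-based, half-open `[start, end)` (BED convention). GFF3 is
converted on read (`start-1`). A gene's TSS is `start` on the `+` strand and
`end - 1` on `-`. narrowPeak summits are stored as absolute positions;
summit `-1` means absent. Signal tracks are step functions stored as
non-overlapping runs `(starts, ends, values)`; window sums integrate
per-base value over `[start, end)` with uncovered bases contributing 0.

## Temporal peak classification (`dynamics.temporal_classify`)

Peaks from the three stages are pooled and clustered by single-linkage
genomic overlap (two peaks link if they share ≥ `min_bp` bases, default 1);
each cluster becomes one locus spanning the union of its members. The locus
pattern is the set of stages contributing ≥ 1 peak; the seven nonempty
subsets map to Roman classes:

| class | stages present |
|---|---|
| I | stage 1 only |
| II | stages 1+2 |
| III | stage 2 only |
| IV | stages 2+3 |
| V | stages 1+3 |
| VI | stage 3 only |
| VII | all three (persistent) |

`percent_overlap(a, b)` returns `100*a/b` with its integer-rounded display
form (e.g. 2901/3050 → 95%).

## Co-occupancy (`dynamics.co_occupancy`)

Regions bound by factor A and factor B (overlap ≥ `min_bp`) are "cobound";
cobound regions additionally overlapping the coactivator peak set are FSE
regions. The FSE interval reported is the union span of the contributing
peaks.

## Super-enhancer calling (`superenhancers`)

1. **TSS exclusion.** Peaks whose edge distance to any TSS is ≤ 2,500 bp are
   dropped before stitching.
2. **Stitching.** Remaining peaks are merged when the gap between them is
   ≤ 12,500 bp, producing stitched loci.
3. **Ranking.** Each locus gets `net = max(raw − background, 0)` signal and
   is sorted ascending by net (ties broken wider-first, then by
   coordinates). Scaled coordinates: `x = rank/(n−1)`, `y = net/max(net)`.
4. **Cutoff.** Scanning ascending, the cutoff is the `y` of the first point
   whose discrete forward slope `Δy/Δx` exceeds 1. Loci with `y` strictly
   above the cutoff are SE; the rest RE. A single locus (no slope defined)
   is RE by convention. If every net signal is zero the ranking is refused
   (`no signal`).

## Differential expression and direct targets (`targets`)

`simple_de` normalizes counts by median-of-ratios size factors computed on
the pooled samples, reports `log2FC = log2((mean_t + 1)/(mean_c + 1))`, and
tests log2(normalized + 1) values with a pooled-variance two-sample t-test
(`equal_var=True`; at n=3 per group Welch's correction is anti-conservative
on the null here, while the pooled test is calibrated — verified by
simulation, null rejection ≈ 0.05). P-values are Benjamini–Hochberg
adjusted.

A gene is a candidate target of a factor if `|fold| ≥ 2` (i.e.
`|log2FC| ≥ 1`) and `padj ≤ 0.05` in that factor's morphant. It is a
*direct* target if, additionally, a peak for that factor lies within 20 kb
and the gene is that peak's nearest gene (ties broken lexicographically by
gene id). Genes direct for both factors are `joint`; the A/B/joint
partition is disjoint. Direction is `activated` (down in morphant) or
`repressed`.

## Motif analysis (`motifs`)

PWMs are read from JASPAR files (Biopython) and scored as log2-odds against
a uniform background with a pseudocount; a hit is any window on either
strand scoring ≥ 0.8 × the PWM's maximum score. `N` bases can never be part
of a hit. `summit_histogram` bins hit centers by offset from the peak
summit (midpoint when absent) over ±`flank` (default 1,000) in `bin`-bp
bins (default 20). `combinatorial_content` reports the proportion of peaks
containing both motifs, each alone, or neither.

## Single-nucleus statistics (`expression`)

- **QC**: cells with < 1,500 detected genes are removed (demo uses a lower
  cutoff appropriate to its small synthetic matrix), then genes detected in
  0 remaining cells are removed.
- **COV**: counts are depth-normalized to the median total per cell
  (no log transform — the coefficient of variation must be scale-invariant,
  and sd/mean on linear values is; inputs flagged as already normalized are
  refused). `cov = sd(ddof=1)/mean` per gene, genes with mean below
  `min_mean` excluded; a constant gene has COV 0.
- **Z-score localization**: per gene, cluster means of log1p
  depth-normalized expression are z-scored across clusters with `ddof=1`
  (e.g. cluster means (0, 0, 10) → (−0.577, −0.577, 1.155)); a gene set's
  score is the mean z per cluster. Z-scores sum to 0 across clusters.
- **Robustness contrast**: gene groups (SE-linked targets, SE-linked,
  RE-linked, unlinked) are compared on COV by two-sided Mann–Whitney U
  tests with BH adjustment.
- **SE–gene linking**: a gene links to a locus if its body is within 20 kb;
  genes near both an SE and an RE count as SE-linked (SE precedence).

## qPCR formulas

- `percent_input = 100 / 2^(CpChIP − (CpInput − log2(DF)))` where `DF ≥ 1`
  is the input dilution factor.
- `ΔΔCp`: `ΔCp = Cp_target − Cp_reference` per condition,
  `ΔΔCp = ΔCp_treat − ΔCp_ctrl`, `fold = 2^(−ΔΔCp)`. With replicate
  vectors the fold change is `2^(−mean ΔΔCp)` and a pooled-variance t-test
  on ΔCp values gives the p-value.

## Synthetic data (`synth`)

Every generator draws from an independent child stream of
`numpy.random.SeedSequence(seed, spawn_key=(k,))` with a fixed per-generator
key, so components are independently reproducible. Ground truth (planted
classes, SE spans, target effects, motif placements, robust genes, cluster
markers) is returned as a `SyntheticTruth` and serialized to `truth.json`.
Sequences are scrubbed of chance motif occurrences before planting so motif
presence truth is exact. Morphant counts are Gamma–Poisson with planted
log2 effects; the single-nucleus matrix is Poisson-lognormal over 13
clusters (5 ectoderm, 4 mesoderm, 4 endoderm) with planted low-dispersion
"robust" genes and per-cluster markers.

Generator defaults, thresholds and seeds were frozen before the validation
suite was run and are never adjusted in response to test outcomes; the only
post-freeze change was raising the default synthetic gene count after the
generator's own feasibility precondition rejected the original density
(documented in the project ledger).

## Validation

`scripts/acceptance.py --seed N --out report.json` recomputes, from scratch:
planted-recovery precision/recall for classes, SEs and targets on a full
pipeline run; brute-force oracle agreement for the temporal classifier and
the ranking cutoff (200 random instances each); DE null calibration (2,000
null genes); the robust-vs-background COV ordering over 100 simulation
seeds; and qPCR formula errors against independently rearranged arithmetic
(1,000 random inputs each).
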