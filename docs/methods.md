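# Methods

## The analysis model

The pipeline targets a common low-throughput design: a modest panel of
genes (tens, not thousands) whose expression was measured as
reference-normalized band intensities over an ordered developmental series,
separately in several tissues and under two contrasting seasonal
cultivations.  There are no biological replicates per timepoint, so the
significance screen is a deterministic outlier rule rather than a
statistical test, and network inference is plain thresholded Pearson
correlation rather than a model-based GRN method.  Both choices trade power
for transparency: every call is recomputable by hand from the report
tables.

### Intensity normalization

`normalize_intensity(raw, background, reference)` implements
`max(raw - background, 0) / (reference - background)` per lane.  A band
fainter than its lane background is clamped to zero before division — it
means no detectable expression, not negative expression.  A reference band
not above background is a hard error naming the lane, because the ratio is
then meaningless.

### Significance screen

For one condition's genes-by-timepoints matrix, each gene gets a time-mean
`mean_t` and a time-sd `sd_t`; the cross-gene mean and sd of each of those
two statistics define two thresholds, and a gene is significant when its
`mean_t` or its (nonzero) `sd_t` reaches the respective
mean-plus-one-sd threshold.  Conventions:

* **Inclusive comparisons (`>=`)** at both thresholds.
* **Sample sd (n−1)** in both directions by default — the denominator used
  by the default sd functions of common spreadsheet software, which this
  rule is designed to match; `sd_mode="population"` switches to n.
* **Flat-gene guard**: a gene with `sd_t = 0` is never selected by the
  variability rule, even when the threshold degenerates to 0.  A constant
  series is not "highly fluctuating"; without the guard an all-flat matrix
  would select every gene through the variability rule.  The mean rule has
  no such guard: in the fully degenerate case (all genes identical) the
  inclusive threshold equals every gene's mean and all genes pass, which is
  the honest reading of an outlier rule applied to a sample with no spread.
* The cross-gene statistics are computed over **all genes present in the
  condition's matrix**, not a pre-filtered subset.

Root-specific sets subtract leaf-significant genes.  Default mode is
**season-matched** (wet-root minus wet-leaf, dry-root minus dry-leaf),
since each cultivation is screened separately; `mode="global"` subtracts
the union over seasons for a stricter root-only definition.

### Co-expression networks

Pairwise Pearson correlation over each condition's root-specific gene set,
with edges kept at `|PCC| >= 0.5` (inclusive; configurable in [0, 1]).
Undirected, unordered pairs.  A zero-variance gene has undefined
correlation; such pairs are *excluded with a warning*, never assigned 0,
because 0 would silently assert independence.  `network_scope="union"`
instead computes each condition's edges over the union of all
root-specific genes, for an overlay view in which the same node set is
highlighted per condition; the per-condition subset is the default.

Cross-condition comparison is by edge identity only — wet and dry crops
are sampled on different calendars, so series are never pooled across
conditions.  A shared pair is sign-flipped iff the product of its two
correlations is negative; a pair above threshold in one network and below
in the other is counted unique, not flipped.  The partition
(shared-same + shared-flipped + unique-a = edges-a, and symmetrically) is
an exact conservation law and is tested as such.

### TF-target network and hubs

Edges touching an annotated TF are retained and oriented TF → target as a
regulatory hypothesis; correlation is symmetric, so the orientation carries
no causal weight until promoter evidence is added.  TF–TF pairs are kept in
both orientations with a `tf_tf` flag (their regulatory direction is
genuinely ambiguous).  Hub degree counts **distinct non-TF targets**, ties
broken lexicographically for deterministic reports.

### Promoter analysis

Promoters are up to 2000 bp upstream of the **translation start site**
(first CDS base in transcript orientation; primary transcript = first mRNA
listed) — deliberately TLS, not TSS, so annotated 5'UTRs are inside the
scanned region.  GFF3 coordinates are 1-based inclusive throughout; on the
minus strand the genomic slice `[TLS+1, TLS+2000]` is reverse-complemented
so the promoter always reads 5'→3' towards the gene.  Truncation at the
chromosome boundary shortens the region.  Promoters are not trimmed at
upstream neighboring genes.

The element scanner matches IUPAC consensi exactly (no PWM scoring — the
evidence model is presence/absence of a binding site), on both strands,
overlapping hits included.  `N` in a promoter matches nothing.  Hit offsets
are negative positions relative to the TLS (−1 = immediately upstream),
referring to the 5'-most base of the matched window in gene orientation.

Edge confirmation scans the target's promoter with the elements of the TF's
family: `confirmed` (≥ 1 hit), `unconfirmed` (0 hits), `no-promoter`
(target promoter unavailable) or `no-element` (the TF family has no entry
in the element table).  The last two are deliberately distinct from
`unconfirmed`: absence of a scan is not evidence against an edge.

### Environment response

Per gene and condition, the Pearson correlation between the expression
series and precipitation aligned to the same sampling timepoints, used to
rank environment-driven against network-driven genes.

## The synthetic generator

`seasonet.synthetic.generate_dataset` emulates the study design the
analysis assumes.  Defaults (all exposed in `SynthConfig`):

| parameter | default | rationale |
|---|---|---|
| `n_genes` | 42 | size of the emulated gene panel |
| `n_timepoints` | 8 | assumed sampling cadence per crop (a design guess, exposed as a parameter) |
| `n_targets` | 8 | driver-regulated genes; with the driver, gives root-significant sets of ~9–12 of 42, the regime the screen is meant for |
| `noise_sd` | 0.1 | ~10% of the driver's dynamic range; semi-quantitative gel densitometry is noisy but the planted signal should dominate |
| `driver_gain` | 1.0 | driver = gain × max-normalized precipitation + noise |
| `target_gain`, `target_baseline` | 0.8, 1.0 | targets = baseline ± gain × driver + noise; baseline > gain keeps anti-correlated targets nonnegative without clamping at zero noise |
| `flip_fraction` | 0.6 | fraction of targets whose response sign flips between seasons — the regime where a substantial minority-to-majority of shared edges change sign |
| `leaf_decoy_count` | 3 | genes significant in leaf (and root) that leaf exclusion must remove |
| `background_level` | 0.05 | barely-detected flat genes |
| `promoter_len` | 2000 | matches the promoter definition |
| `planted_element` | GCC-box `GCCGCC`, family AP2/EREBP | the ERF-family binding element, matching the ERF-type driver |

Noise is additive Gaussian truncated at zero (intensities are
nonnegative); a lognormal multiplicative alternative is available.
Precipitation is a scaled half-cosine ramp per season (wet: decaying from
~200 mm; dry: rising), plus seeded jitter; at zero jitter wet and dry are
exactly anti-correlated.  Sign flips are planted between seasons within a
tissue; a tissue-flip mode exists but is off by default.  The mini-genome
places one gene per contig (strands alternating) so promoter extraction is
unambiguous; a multi-gene-contig mode shortens the first gene's promoter to
exercise boundary truncation.  Promoters are scrubbed of the planted
consensus on both strands before one instance is inserted into each true
target's promoter at a seeded offset; all planted structure is recorded in
`SyntheticTruth`.

What the generator does **not** emulate: gel saturation and censoring,
timepoint-to-timepoint autocorrelation of biological noise, batch effects
between crops, multiple regulators with overlapping target sets, and any
attempt to reproduce real expression values.  Passing recovery tests
therefore demonstrates the pipeline's correctness on data satisfying its
own assumptions, not performance on real RT-PCR panels.

At default noise the screen is the recall bottleneck by design:
anti-correlated targets (baseline − gain × driver) have a slightly
attenuated time-sd and sit near the variability threshold, so a few
(seed, condition) runs miss one to three of the eight planted edges while
precision stays at 1.0.  The recovery thresholds asserted in the test
suite (mean recall ≥ 0.85, mean precision ≥ 0.95, driver top hub in
≥ 19/20 seeds) were pinned once from a 200-seed calibration of exactly
this behavior.

## Numerical and engineering choices

* Correlations are computed with `numpy.corrcoef`; tests verify agreement
  with a definition-level reimplementation to 1e-12.
* All randomness flows from one integer seed through
  `numpy.random.default_rng`; generated datasets and pipeline output trees
  are byte-identical across reruns (no timestamps, sorted iteration
  everywhere).
* Missing timepoints are a hard load error, never imputed: with ~8
  timepoints both `sd_t` and PCC are too fragile for silent imputation.
* Degenerate inputs: < 2 genes or < 2 timepoints is an error for the
  screen; series shorter than 3 or with zero variance are an error or an
  undefined-correlation signal for PCC.
* Exports: Cytoscape SIF (`pp` for co-expression, `reg` for TF → target)
  and GraphML with `pcc`, `sign`, `condition` edge attributes and an
  `is_tf` node attribute; both round-trip to the same edge set.
* Problem sizes in the test suite (matrix sweeps of 3–10 genes × 3–10
  timepoints, 100–1000 randomized oracle comparisons, 20-seed recovery
  runs) were chosen to pin each property with comfortable margins while
  keeping the whole suite fast enough for routine local runs.

## Known limitations

* The two-rule screen has no error control; it is a reproducible
  description of "stands out from this panel", not a test with a p-value.
* Thresholded PCC on ~8 timepoints has a heavy null tail (|PCC| ≥ 0.5
  occurs by chance at a double-digit percentage rate for independent
  series); condition-unique edges should be read with that in mind.  The
  package reports the fractions; it does not attempt bootstrap confidence.
* TF → target orientation and promoter presence/absence evidence are
  hypotheses; an IUPAC consensus hit is weak evidence compared to PWM or
  footprinting approaches, which are out of scope.
* Leaf exclusion assumes the leaf tracks were screened with the same rule
  and panel; genes missing from a leaf matrix are treated as
  not-significant in leaf.
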