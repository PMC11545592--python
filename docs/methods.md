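# Methods

## Scope and data model

`dietmb` operates downstream of read processing: it assumes reads have
already been merged, clustered into OTUs (typically at 97% similarity)
and searched against a reference database, so its inputs are (a) a
sample × OTU matrix of non-negative integer read counts, (b) one best
hit per OTU in BLAST-tabular style (taxon, percent identity, query
coverage, score, accession; OTUs without a row are treated as
`"no match"`), and (c) a field-survey table of availability counts per
(group, genus, species). Raw-read processing, OTU clustering and the
database search itself are deliberately outside the package.

All files are TSV (UTF-8, `.` decimal). Count tables may be oriented
either way (`dialect` switch). Result tables are written at full float
precision so a write/read round trip is lossless; percentages are
rounded half-up to one decimal only in console reports.

## Filter cascade

Order matters and is fixed: read threshold → taxonomic screen → survey
harmonisation → collapse.

* **Relative read threshold** (default 0.0001, i.e. 0.01%): an OTU is
  kept when its read sum is ≥ threshold × the *input* table's grand
  total. The phrase "of the total number of reads" is read as
  dataset-wide; a per-sample mode (cells below the per-sample cutoff
  zeroed, then empty OTUs dropped) is available behind
  `per_sample_threshold` since either reading is defensible. The
  comparison is ≥, so an OTU sitting exactly on the cutoff survives.
  A property test pins the cascade order: removing the host *before*
  thresholding shrinks the total and rescues borderline OTUs, so silent
  reordering would change results.
* **Taxonomic screen**: drop order is `"no match"` → host (exact
  case-insensitive match on the configured host species) → non-prey
  (case-insensitive match of the full name or genus token against the
  exclusion list, so `"Fungi"` catches `"Fungi sp."`) → identity below
  the floor (≥ 97.0 compared exactly, no pre-rounding). Query coverage
  is parsed but not thresholded by default (`min_query_coverage`
  enables a floor). Each OTU receives exactly one reason; the audit
  table is exhaustive by construction and by test.
* **Survey harmonisation**: a kept species present in the survey
  (genus + specific epithet; abbreviated binomials like
  "Z. temminckii" are matched on the epithet) keeps its rank; a species
  absent while its genus was recorded is demoted to "Genus sp."; a
  species whose genus is also absent is likewise demoted but flagged in
  the audit note rather than discarded — faecal-only taxa are real
  detections and must survive to the selectivity stage (they are the
  D = 1 rows).
* **Collapse**: at genus rank every kept OTU maps to "Genus sp."; at
  species rank final labels are used as-is, which means two distinct
  species demoted to the same genus placeholder merge even at species
  rank (they are indistinguishable once demoted). Reads are summed per
  sample and item; samples left with zero prey reads are dropped with a
  warning and recorded on the prey table, so S is always the retained
  sample count and every retained sample has ≥ 1 prey read. Total
  prey-table reads equal the kept OTUs' reads (conservation is tested).

## Dietary metrics

%FOO, %RRA and prey-specific abundance %P are computed exactly as
defined in the README. Invariants enforced by tests: Σ%RRA = 100 (each
sample's shares sum to 1); %FOO is invariant to per-sample depth
rescaling, %RRA to per-sample positive scaling; %P ≥ the item's share
of the grand total (restricting the denominator to occupied samples can
only increase the ratio); an item occurring nowhere has %P undefined
and is reported as missing, never 0, and zero-occurrence items are
excluded from reports entirely.

The Costello diagram is reported as quadrant labels with both cutlines
at 50% — the diagram's boundary is conventionally drawn, not derived,
so 50/50 with ties (≥) assigned to the upper/right region is a declared
convention, applied consistently (a point at exactly (50, 50) is
"dominant"). The BPC/WPC and dominance diagonals are expressed through
the labels rather than as extra axes.

## Selectivity

Jacobs's D = (r − p)/(r + p − 2rp), clamped to [−1, 1] against float
rounding at the extremes; r = p returns exactly 0 and r = p = 0 is NaN
(0/0). r is the item's %RRA renormalised over its prey group so r and p
live on the same simplex — without renormalisation r would be depressed
by the other group's reads and the one-sided D = ±1 behaviour would
break; a `renormalise=False` switch provides raw %RRA/100 for
sensitivity analyses. p is the genus's share of individuals counted in
the survey for that group (counts, not biomass). Chironomid genera are
merged to family Chironomidae on both sides *before* shares are
computed. Fish and benthic invertebrates are scored separately; the
reported rows cover the union of faecal and field items, so
|D = 1| rows = faecal-only taxa and |D = −1| rows = field-only taxa,
which ties the selectivity table to the Venn-style overlap operation.

## Group comparison and rarefaction

The comparison unit is the sample: for each faecal sample the group's
read share (the two groups' shares sum to 1) and richness (the group's
items with > 0 reads). This per-sample pairing is the only unit that
yields enough observations for a rank test on a single study.
"Richness" is counted on collapsed prey items; pre-collapse OTU
richness can be obtained by running the metrics on an uncollapsed
(species-rank) table.

Mann–Whitney U uses midranks; U is reported for the first sample
(U₁ + U₂ = n₁n₂). Exact two-sided p enumerates all C(n₁+n₂, n₁)
assignments of the pooled midranks and counts |U − n₁n₂/2| at least as
extreme as observed; this reduces to the classical exact test when
there are no ties and remains a valid permutation test with them. In
`auto` mode enumeration is used for tie-free samples with
min(n) ≤ 8 (C(16,8) = 12,870 splits — cheap); otherwise the normal
approximation with tie correction and 0.5 continuity correction is
used. `scipy.stats.mannwhitneyu` is used in the test suite as an
independent oracle, never as the implementation.

Rarefaction is the exact hypergeometric expectation
E[S_m] = Σᵢ [1 − C(N − Nᵢ, m)/C(N, m)] with log-gamma evaluation of the
binomial ratios (items with N − Nᵢ < m contribute exactly 1). The
sample-based curve substitutes occupancy counts Fᵢ out of S samples.
Both curves are non-decreasing and concave and end at the observed
richness; closed forms are validated against 10⁵-draw Monte-Carlo
subsampling in the tests (agreement within 0.01).

## Synthetic generator

The generator's defaults are the study conditions the package is
validated under: S = 24 samples; negative-binomial per-sample depth
with mean 300,000 reads and dispersion 5 (a lognormal alternative sits
behind `depth_model`), floored at 1,000 reads because a failed library
would be resequenced rather than analysed; host fraction 0.70 modelled
as a single dominant OTU (host suppression by blocking primers is often
abandoned for low efficiency, leaving host-dominated libraries);
40 noise OTUs sharing 0.2% of reads (0.005% each — half the filtering
threshold, so all of them should be removed by the read filter alone);
Dirichlet concentration α = 30; 13 genus-level prey profiles in two
groups with round-number ψ and mean shares forming one dominant item,
a few moderate ones and a long tail. Per sample: incidence ~
Bernoulli(ψᵢ); composition of present items ~ Dirichlet(α·normalised
mean shares); reads allocated by a single multinomial over host, noise
and prey OTUs (an item's mass split evenly over its OTUs). Noise OTUs
cycle through the real failure modes: no hit row at all, an explicit
`"no match"`, fungal/Chromista/livestock contaminants at high identity,
and plausible prey taxa below the identity floor. One default profile's
species is deliberately absent from the generated survey (a congener is
listed instead) to exercise the demotion path.

Samples that draw no prey at all have their incidence row redrawn so S
stays controlled; this conditions incidence on "≥ 1 item present" and
would bias %FOO upward noticeably in item-poor configurations, which is
why the default set (and the recovery tests) includes a ψ = 1 anchor
item that makes empty draws impossible. A second known detection limit:
an item flagged present can still yield zero reads when its Dirichlet
share falls below ~1/depth; with α = 30 and mean shares ≥ 0.02 this
dropout is ≈ 1% of present samples and sits well inside the 3-SE
recovery tolerance used in the tests.

The truth object records the incidence matrix, realised per-sample
compositions, expected %FOO = 100ψ and expected %RRA (the realised mean
composition), and the host/noise OTU ids, so `recovery_report` can
score the pipeline against the generating process.

What the generator does *not* emulate — and therefore what passing
tests cannot certify about field data: primer and amplification bias,
chimeras, cross-sample index bleed, correlated prey occurrences
(incidence is independent across items), biomass–read-count
nonlinearity, and any sequence-level error process. It validates the
arithmetic and the filtering logic, not the molecular biology.

## Numerical and design choices

* Thresholds are compared without rounding; printed one-decimal
  rounding is display-only (half-up, matching how such percentages are
  conventionally reported).
* Metric ties in report sorting use a stable mergesort, so equal-%RRA
  items keep their column order and reruns are byte-identical (the CLI
  manifest's checksums make this checkable).
* The exact-test cutoff min(n) ≤ 8 balances enumeration cost against
  accuracy; at 8/8 exact and approximate p agree within 0.02 on random
  inputs.
* Secondary-predation removal is carried entirely by the read-count
  threshold; no dedicated co-occurrence model is attempted.
* Canonical correspondence analysis and its permutation tests are out
  of scope: standard ordination belongs to dedicated multivariate
  packages, not here.

## Problem sizes used in validation

The routine test suite runs simulations at S = 24–200 with depths of
10⁴–5·10⁴ reads/sample and 20-seed replication for bias checks; the
acceptance script uses the full default depth (3·10⁵) at S = 24 and a
50,000-read S = 200 recovery run, 5,000 null replicates for the
Mann–Whitney type-I rate, and 10⁵ Monte-Carlo draws for rarefaction.
These sizes give Monte-Carlo error comfortably below every asserted
tolerance.
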