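# Methods

## Problem setting

The pipeline integrates published differential-expression tables from
heterogeneous omics studies of one disease into a single molecular
picture. Its inputs are per-study molecule lists (raw identifier,
case/control expression ratio, p-value), study metadata (platform,
body-fluid source, patient group), an identifier → non-redundant
cluster alias map with one coarse functionality tag per cluster,
gene-set collections in GMT format, disease–gene association tables,
and regulator → target edge lists. All analysis stages are
deterministic; randomness exists only in the synthetic-data generator.

## Harmonization

**Identifier mapping.** Every raw identifier (gene symbol, protein
accession, probe id, ...) is resolved through the alias map; unmapped
records go to a side list, never silently dropped, and
|mapped| + |unmapped| = |input| is asserted throughout.

**Direction and magnitude.** A case/control ratio r > 1 is
up-regulation, r < 1 down-regulation; the fold-change magnitude is
max(r, 1/r), so a halving and a doubling are equally strong signals. A
literal rule of the form "down if below the threshold, up if above"
would label near-unity ratios as down-regulated; the reciprocal
magnitude convention is the only self-consistent reading and keeps
threshold filtering symmetric in direction (a feature at r passes iff
one at 1/r does). Tables published as signed fold-changes (−2 meaning
halved) are converted on read via a per-study convention flag.

**Within-study collapsing.** Redundant entries of one cluster within
one study are merged to a single record: the ratio is the arithmetic
mean of the group's ratios (a geometric-mean option exists for
sensitivity analysis; after direction conflicts are removed the two
never disagree in direction), and the p-value is the group minimum
(with a Fisher-combination option). The minimum was chosen because
redundant rows in curated tables are typically the same underlying
measurement reported under different identifiers, not independent
evidence; combining them as independent would overstate significance.
Groups whose members disagree in direction are dropped with a warning —
the same conservative treatment the cross-study consistency check
applies between studies.

**Thresholds.** A feature is retained iff p < 0.05 and its magnitude
reaches both its platform threshold (transcriptomics 2.0;
proteomics, peptidomics and metabolomics 1.3) and the global threshold
1.4 — i.e. the effective threshold is the larger of the two. Filtering
is monotone in every threshold. The order of operations is: map,
collapse within study, then threshold; collapsing first means the
thresholds act on the merged ratio, which is the quantity the
cross-study merge consumes.

## Cross-study consensus

Within one patient group (naïve or ERT — the groups are never merged
with each other), each cluster's thresholded per-study records are
checked for directional consistency: clusters observed with both
directions are removed as contradictions and reported; consistent
clusters are merged by averaging their ratios, recording the number of
supporting studies and the fluid sources. Consensus and removed
clusters partition the distinct input clusters.

Overlap selection returns clusters supported by at least
`min_sources` distinct units, at fluid granularity (urine/blood,
the default, matching the idea of independent biological sources) or
study granularity; both modes are exposed and every report states which
was used.

## Functionality-tag summaries

Per group, one row per tag: counts and percentages (one decimal,
half-up rounding) of total/up/down features, plus an exclusivity flag
(`all_up` / `all_down` / `mixed`). The UK (unknown) tag is an ordinary
category. Input order never affects any value.

## Enrichment statistics

**Two-sided hypergeometric test.** For a query of n genes in a
universe of N, a term of size K and overlap k, the p-value doubles the
smaller of P[X ≥ k] and P[X ≤ k] (X hypergeometric), capped at 1.
Doubling-the-smaller-tail is the most common two-sided construction; a
minimum-likelihood-sum variant is available behind a flag. The universe
defaults to the union of all genes in the loaded collection (an
explicit background list can be supplied); query genes outside the
universe are dropped with a logged count.

**Multiple testing.** "Bonferroni step-down", i.e. Holm's procedure:
sort p ascending, adjusted(i) = max over j ≤ i of min(1, (m−j+1)·p(j)),
mapped back to input order. Implemented via
`statsmodels.stats.multitest.multipletests(method="holm")`; the tests
check it against the step-down definition applied by hand.

**Term grouping.** Cohen's kappa on binary gene membership between two
significant terms, computed over the universe restricted to the query's
hit genes; an edge joins terms with κ ≥ 0.4 and groups are the
connected components. The group representative is the member with the
smallest adjusted p (lexicographic tie-break). Proprietary iterative
group-merging schemes exist in GUI tools; connected components is the
simplest deterministic choice and is stated in every report.

**Direction labels.** A term is labelled `up` if more of its hit genes
are up-regulated than down, `down` for the converse, `mixed` on a tie;
labelling a term with zero hits is an error.

**Pathway Z-score.** With r of the R measured query genes on a pathway
of n measured genes in a measured universe of N,

    z = (r − n·R/N) / sqrt( n·(R/N)·(1 − R/N)·(1 − (n−1)/(N−1)) ),

the exact standardization of the hypergeometric count (the classic
MAPPFinder statistic). Degenerate variance (R = 0, R = N or n = N)
yields z = 0 with a warning. Significance is one-sided at
z ≥ 1.6449 = Φ⁻¹(0.95) by default; a two-sided mode exists.

## Fold-change clustering

The matrix holds log2 ratios of the overlapping features (rows) per
study (columns); unreported cells are missing, and rows with fewer than
two observations are dropped. Distances are Euclidean on
pairwise-complete columns, with the sum of squares rescaled by p/m
(p columns total, m shared) so rows with different missingness remain
comparable; a pair sharing fewer than two columns is an error naming
the rows. The pipeline pre-filters such rows greedily (removing the row
with the most violating pairs first) and reports how many were dropped.
Linkage is average (UPGMA) via scipy; identical rows merge at height 0
first and ties resolve by input index, so trees are reproducible. No
distance/linkage convention is canonical for this kind of matrix, so
the defaults are recorded in every output header and are configurable.

## Disease and regulatory overlays

Diseases are ranked by the number of genes shared with the query —
the statistic such tables actually print — with alphabetical tie-break;
association scores are deliberately not modelled. The packaged curated
DisGeNET v2.1 tables for the Fabry naïve and ERT query sets list, per
disease, its intersection with the group's query; the union of the
intersections recovers the disease-annotated query lists (25 and 14
genes). Some printed count columns in the source tables disagree with
their own gene lists by one; the ranking here always uses the list.

The regulatory overlay keeps regulator → target edges whose target is
in the query. Following the CyTargetLinker convention, if fewer than
two distinct source networks are loaded the overlay is empty with an
explanatory status rather than an exception. Exports: SIF and GraphML,
with direction attributes on target nodes.

## Synthetic-data generator

The generator emulates published end-result tables, not raw
instrument data. Its default study design mirrors the Fabry dataspace:
11 studies, 7 naïve / 4 ERT, 5 urine / 6 blood, across the four
platforms, with the published cohort sizes carried as metadata.

* **Signal clusters** (default 60) are planted in 2–4 studies of one
  group with a consistent direction; 16 of them are "frequently
  reported" molecules observed in 6–9 studies across both groups and
  fluids, which is what makes a cross-source overlap matrix non-trivial
  — mirroring the real dataspace where the overlapping features are the
  most frequently reported molecules.
* **Effect sizes** are log-normal per platform (location log 2.8 for
  transcriptomics, log 1.9 for proteomics/peptidomics, log 1.8 for
  metabolomics; scale 0.2–0.25), truncated below at the platform's
  effective reporting threshold, and planted p-values lie in
  [10⁻⁶, 0.04]. The truncation reflects the nature of the emulated
  inputs: published tables only contain molecules that passed each
  study's own significance criteria.
* **Direction balance** is group-specific (P(up) = 0.8 naïve, 0.45
  ERT), reproducing the strong upward skew of the untreated group.
* **Contradictions** (10% of the signal count, as extra clusters) are
  generated like signals and then flipped in exactly one randomly
  chosen supporting study — the failure mode the consistency check
  removes.
* **Nulls** (default 140) have near-unity ratios (log-scale sd 0.12)
  and uniform p-values; redundancy is emulated by 1–3 aliases per
  cluster and a 15% chance of a same-study duplicate row under a second
  alias with a same-direction jittered ratio.
* **Gene sets**: 40 terms of size 10–25 over the cluster universe; 5
  planted terms draw 80% of their members from the signal clusters,
  background terms sample uniformly. The planted fraction was sized by
  a design-time power calculation so that a planted term's enrichment
  in the combined consensus list is detectable at the collection's
  Holm-corrected 5% level even at the smallest term size; background
  terms stay at their chance expectation n·K/N.

One master seed drives everything through spawned substreams (cluster
structure, signal draws, null draws, alias/duplicate choice), so
identical (config, seed) pairs give byte-identical tables.

**What passing the synthetic suite does and does not show.** The
generator plants clean, threshold-passing effects with independent
studies and a perfectly known alias map; real literature tables carry
correlated biases (shared cohorts, platform batch effects, selective
reporting), imperfect identifier resolution, and effect sizes that
hover at the reporting thresholds. Recovery rates on synthetic data
therefore validate the pipeline's logic — not the sensitivity of the
thresholds on real data.

## Verification strategy

Every statistical primitive is checked against an independent oracle:
Holm against the hand-applied step-down formula, kappa against an
explicitly tabulated 2×2 agreement table (1,000 random pairs) and
sklearn's implementation, the consensus merge against per-cluster
direction-multiset enumeration, hierarchical clustering against an
O(n³) brute-force UPGMA on all matrices with ≤ 6 rows, the pathway
Z-score against Monte-Carlo hypergeometric sampling, and the
hypergeometric pmf for normalization across N ≤ 200. Worked examples
(the 1/15504 perfect-overlap tail, the hand-computed Holm triples, the
0.6-kappa pair, z = 2.211 at (r,n,R,N) = (3,10,10,100)) are frozen in
the tests. The shared-gene ranking reproduces the published counts (16
for malignant neoplasm of breast in the naïve group, 8 for asthma in
the ERT group) from the packaged tables.

Problem sizes used by the default test suite and the acceptance script:
11 studies, ~200 clusters, ~580 measurement rows, 40 gene sets, 20
generator seeds — the scale of the curated dataspace itself.

## Known limitations

* The published funnel counts of the original curated dataspace (e.g.
  340 → 192 non-redundant entities, per-group totals) depended on
  database versions that are no longer available as used; they are not
  reproduction targets here, though the filters that produced them are
  implemented and fully tested.
* Gene sets are flat membership lists; GO-tree levels, evidence codes
  and pathway topology are out of scope.
* Disease ranking ignores association scores and text-mining evidence.
* No meta-analytic weighting by cohort size: studies are averaged
  unweighted, as the emulated analysis did; cohort sizes are carried as
  metadata only.
* The dendrogram depends on the (configurable) distance/linkage choice;
  no single published convention exists for this matrix, so exact tree
  shapes are not a stable output across settings.
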