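# Methods

## Scope and data model

`pulquant` implements the analysis layer of substrate-specific TBDT
expression profiling. It does not run assemblers, binners, gene callers,
HMM scanners, aligners or mass-spectrometry searches; it consumes their
standard tabular outputs (GFF3, HMMER per-domain tables, 12/13-column
tabular alignment hits, TSV count matrices) and implements the filtering,
clustering and quantification rules on top of them.

Coordinates are 1-based inclusive internally (GFF3 native); BED exports are
0-based half-open. Gene distance is always the ordinal gene index on a
contig — clustering counts genes, not base pairs — and indices restart at
zero on each contig, so clusters can never span contigs. Strand is recorded
but ignored by clustering: co-regulated PUL genes are usually co-oriented,
but the window rule is defined on neighbourhood alone.

## Feature classification

CAZyme calls are two-staged. The HMM stage applies the dbCAN parser
convention: profile coverage must exceed 0.3, and the per-domain
independent e-value must be below 1e-5 for alignments longer than 80 aa or
below 1e-3 otherwise; accepted hits on one gene overlapping by more than
half of the shorter alignment are deduplicated keeping the lower e-value.
Alignment lengths and coverages are inclusive of both endpoints. The
confirmation stage keeps a family only if an alignment to a
reference protein of that family passes e < 1e-20, query cover ≥ 40 % and
identity ≥ 30 %. Comparison conventions are uniform: e-value gates strict,
identity/coverage minima inclusive. Confirmation can only remove families,
never add them.

TBDT classification needs one hit to any panel profile at the scanner's own
reporting threshold; the SusC-like flag needs a hit to TIGR04056
specifically, and SusC-like implies TBDT. The shipped ten-profile panel
(TIGR04056 plus plug/β-barrel receptor families) is a reconstruction and
is configuration, not a fixed fact; no shipped result depends on the exact
accessions. SusD-like and sulfatase genes arrive as identifier sets from
upstream product annotation rather than being re-predicted.

Genes whose only CAZyme families are glycosyl transferases (GT*) are
labelled biosynthetic and are not clustering markers; genes mixing GT and
non-GT families count as CAZyme markers carrying only their non-GT families
into substrate logic, since the GT exclusion targets biosynthetic-only loci.

Protein functional categories (ribosomal, ABC transporter, porin, ...) use
an either-or rule: membership in a category's Pfam accession set, or a TCDB
alignment below e = 1e-10 whose TC number matches a category prefix at a
dot boundary.

## Cluster and PUL calling

Markers are genes labelled degradative CAZyme, sulfatase, TBDT or
SusD-like. Two markers on one contig link when their index difference is at
most the window (default 7, i.e. up to six intervening genes; the
alternative reading is one flag away). Linkage is transitive — clusters are
connected components and may exceed the window length, which reproduces
tandem-PUL structures where two susCD pairs share a CAZyme complement.
Components need two markers; singletons are discarded. The cluster span
covers every gene between the extreme marker indices. On a line, components
equal chains of consecutive markers with gaps ≤ window; the test suite
checks this implementation against a full pairwise-graph oracle.

A PUL is a cluster containing a TBDT and at least one degradative CAZyme
family: substrate prediction works from CAZyme content, so a TBDT/SusD pair
alone cannot support a functional call.

## Substrate prediction

Each substrate class has indicator families, a minimum count of distinct
indicators, optional veto families, and (for composite classes) indicator
groups with a minimum group count. A class is eligible when all gates pass;
exactly one eligible class yields the call, zero or several yield
`no_substrate_predicted`. The conservative ambiguity rule mirrors the large
observed "CAZyme but no substrate predicted" categories.

The shipped table is a reconstruction from characterised family functions:
laminarin GH16/GH17/GH30; alpha-glucan GH13/GH31/GH65; alginate
PL6/PL7/PL12/PL17; mannose-rich GH92/GH38/GH76; xylose-rich
GH10/GH43/GH67/GH115; fmx (fucose/mannose/xylose-containing polymers)
requires indicators from at least two of the fucose (GH29/GH95), mannose
and xylose groups. The single-sugar mannose/xylose classes veto the other
two groups' indicators so that multi-group evidence resolves to fmx instead
of an ambiguity — without those vetoes the composite class could never be
assigned. Single-group fucose evidence alone has no class and resolves to
no-substrate.

TBDT categories are a pure function of the SusC-like flag and the substrate
value (class / no-substrate / no-CAZyme), giving the standard six rows.
Percentages are rounded half-away-from-zero to one decimal.

## Taxonomy

MAG quality control retains a MAG if either estimator pair passes
completeness > 50 % with contamination (or redundancy) < 5 %; each
completeness is paired with its own tool's contamination — the conservative
reading of an ambiguous rule. Estimator values above 100 % are clamped with
a warning. Species are single-linkage components of the graph
{distance < 0.05} on a MASH-style genome distance matrix; single linkage
treats the pairwise same-species relation as transitive, and the linkage
function is isolated so average linkage can be swapped. The species
representative is the most complete member unless a member more than
100 kbp larger, with contamination no worse under both estimators and
completeness within 5 percentage points, is present — then the largest such
member wins; all ties break lexicographically, making the choice
order-invariant. The 100 kbp margin comes from the underlying protocol;
the 5-point completeness margin quantifies its "near equivalent
completeness" and both are configurable.

Protein-to-MAG assignment takes the best local hit (highest bitscore, then
lowest e-value, then lexicographic subject) among hits with identity > 99 %
and e-value < 1e-4; no full-length coverage gate is applied by default.

## Quantification

%NSAF for protein *i* in a replicate is 100·v_i/Σ_j v_j where v is the
size-adjusted spectral count; a raw-count mode divides counts by protein
length first (both vendor conventions occur in the wild, so the mode is
explicit). Replicate averaging divides by the designed replicate count
(three), counting proteins undetected in a replicate as zero — the divisor
is never the detected count. RPKM follows the printed formula exactly:
1,000,000 × ((reads mapped ÷ length in kbp) ÷ library size). Aggregation
sums per-sample values by group and conserves column totals under any
partition; cross-sample dispersion uses the sample (n−1) standard
deviation. Trailing averages take the mean of the most recent k collected
values; uncollected dates produce no point and do not reset the window, and
windows are shorter at the series head (a documented choice — the
alternative would emit no value before k points exist).

All-zero replicate columns, zero library sizes, non-positive feature
lengths, replicates missing from the design, and asymmetric distance
matrices (beyond 1e-9) are hard errors, never silent passes.

## Synthetic community

The generator's defaults are the study conditions, fixed a priori: six
proteome samples (Julian days 77–138, three replicates) and nine metagenome
samples (days 76–138); eight species × three contigs × 60 genes; every
substrate class planted as two PULs (SusC-like and plain variants); two
ambiguous PULs whose families match two classes; two sulfatase+CAZyme
clusters without TBDTs; six lone TBDTs; four near-miss decoy pairs at gap
window+1; three GT-only runs; and classifier-exercise genes whose hits are
engineered to pass or fail individual filter branches (coverage gate, the
short-alignment e-value branch, overlap deduplication, failed
confirmation). Planted blocks are spaced more than a window apart so truth
clusters are exactly the planted ones.

Expression: the TBDT share of the proteome follows the trajectory
13.9 → 21.0 % across the six samples (mean 16.7 %), and each substrate
class follows a log-linear share trajectory with the published endpoint
magnitudes (fmx 0.2 → 1.0 %, alginate 0.01 → 0.1 %, laminarin 1.0 → 0.6 %,
alpha-glucan 0.8 → 0.4 %, mannose-rich 0.15 → 0.5 %, xylose-rich
0.1 → 0.3 %); trends are kept monotone so that rank-correlation sign
recovery is well defined. Within-group protein weights are fixed
log-normal draws; replicate values are gamma-Poisson (negative-binomial,
dispersion 0.05) around the expectations, with 10 % of protein/replicate
cells dropped to missing to exercise the zero rule. The noise family is a
modelling choice — no noise model is published for these data. Clean mode
returns expectations exactly with no missing cells.

Metagenome counts are Poisson around time-constant per-gene RPKM with
class totals calibrated to the published levels (alginate 11.2,
mannose-rich 11.7) and library sizes varying up to two-fold — the flat
gene-frequency side of the decoupling. Trend-freeness is tested against
the Monte-Carlo null of the maximum |Spearman ρ| over the six class
series at the 95th percentile: a single joint test with a 5 % family-wise
false-alarm rate by construction, rather than six per-class tests.

All randomness flows from one seed through separate substreams for layout,
expression and metagenome draws, so outputs are byte-identical across runs
with the same seed.

What the generator does **not** emulate: real assemblies' fragmented
contigs and chimeric bins, shared marker genes between overlapping PULs,
CAZyme database bias across clades, protein-inference ambiguity, and
compositional coupling between classes beyond the share constraint.
Passing the recovery tests therefore shows the rules are implemented
faithfully and are recoverable under the stated noise — not that the
thresholds are optimal for any particular real dataset.

## Problem sizes and numerical choices

Default analyses run on 1,440 genes, 24 TBDTs, ~350 expressed proteins and
11 MAGs — sizes chosen so every driver and the full test suite complete in
seconds while exercising each rule with both positive and negative planted
cases. Oracle comparisons use 200 random 500-gene tables for the cluster
caller and random matrices up to 30 MAGs for species clustering.
Percentage rounding is half-away-from-zero to one decimal; %NSAF columns
are validated to sum to 100 within 1e-9 relative; all tie-breaks
(deduplication, best-hit, representatives) are deterministic and
documented above.

## Known limitations

* The HMM panel and substrate rule table are reconstructions; per-PUL calls
  on real data depend on the collections supplied in configuration.
* Phylogeny-based substrate transfer between sequence neighbours is out of
  scope: TBDTs outside CAZyme-containing clusters stay "no CAZymes" even
  when close relatives have known substrates.
* Cross-contig PULs cannot be stitched; fragmented assemblies will
  under-call clusters.
* With six proteome time points, trend statistics are sign checks, not
  effect-size estimates; the decoupling test controls only the family-wise
  false-alarm rate of the flat side.
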