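# Methods

This note documents the models and procedures implemented in `relascape`,
the defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical decisions that were genuinely
open.

## Coordinate model and overlap calling

All coordinates are 0-based, half-open (BED/narrowPeak convention); summits
are absolute positions (narrowPeak column 10 offset from start, with the
interval midpoint as fallback for `-1` or BED6 input).  Peaks within one
set must be disjoint — peak callers emit disjoint peaks — and pooled sets
can be repaired by unioning overlapping records (`merge_overlaps`).
Overlap length is `max(0, min(ends) − max(starts))` and thresholds compare
with ≥; strand is ignored for peak overlaps (peaks are unstranded) and used
only for profile mirroring and motif scanning.  Intersection exploits the
disjoint-sorted invariant: within a chromosome both starts and ends are
increasing, so candidate partners form a contiguous run found by bisection;
peaks overlapping several partners report all of them, and downstream
analyses reduce to presence/absence.

Signal tracks are sparse step functions; uncovered positions count as 0
(bedGraph convention).  Summaries are length-weighted sums/means;
meta-profiles average per-bin track means over anchors and report
SEM = sample SD / √(number of anchors), mirroring minus-strand anchors.

## Orthology projection and conservation

Alignment blocks are modelled as **ungapped proportional maps**: an offset
inside the source segment maps to `round(offset / source_len × target_len)`
in the target segment, with offsets reflected when block orientations
differ.  Real multiple-alignment blocks contain indels, but interval-level
overlap calling with a 1 bp threshold is insensitive to small internal
gaps, and the generator controls block structure exactly.  A projected
interval may be empty (unalignable → species-specific) or split across
blocks; a peak is conserved in a species if **any** fragment overlaps a peak
there by ≥ `min_overlap` bp (default 1 bp; the 1/20/50/100 grid is exposed
because conserved counts must be non-increasing along it).  Overlap after
projection is measured in target coordinates, where the partner peak lives.
Projection is an involution up to clipping, and with an identity map
conservation labelling reduces exactly to direct intersection — both are
tested.

## Binding modes

A stimulated RELA peak is Mode O if it overlaps accessibility peaks in both
conditions, OA if only after stimulation, CA if only before, C if neither;
the prebound flag (Mode P) marks overlap (≥ 1 bp) with a basal RELA peak
call and is orthogonal to the four-way partition.  An alternative,
signal-based route to prebound-like peaks — ranking all stimulated peaks by
basal signal and applying the inflection cutoff — lives in the
super-enhancer module (`top_ranked_peaks`).

## Mode preservation

Among conserved reference peaks, category proportions P(B), P(C), P(D)
(conserved in all three species / with the first partner only / with the
second only) and conditional mode probabilities p_X(species, category) are
estimated by plug-in frequencies; partner-species probabilities are
computed over the partner peaks recorded for each conserved reference peak,
with a site counting as mode X when any overlapping partner peak is (the
presence-based rule used throughout).  The expected probability that a
conserved reference mode-X site is preserved in at least one other species
is the five-term total-probability sum P(A); a brute-force enumeration over
all per-category indicator outcomes is kept as an independent oracle and a
Monte-Carlo check verifies the closed form.

The published binomial test for per-mode preserved fractions could use the
unconditional P(A) or its conditional version; the tested fraction is
k/n over reference mode-X conserved peaks, so the **conditional** null
P(A) / Σ_g p_X(ref, g) P(g) matches that denominator and is the default;
both values are emitted.  Mode P is treated as its own label via the
prebound flag.  The two-sided exact binomial p-value uses the
minimum-likelihood convention (sum of outcome probabilities ≤ that of the
observation), Bonferroni-corrected over the five labels.

## Super-enhancers, inflection cutoff, constraint ranking

Stitching merges peaks transitively at gap ≤ 12,500 bp with no promoter
exclusion (the upstream tool's defaults; both are parameters).  Region
signal is the summed treatment signal minus optional control, floored at 0;
without a track the constituent peak signals are summed (equivalent for
tracks built to integrate to peak signals).  After sorting signals
ascending and min–max scaling ranks and signals to [0, 1], the
super/typical cutoff is the tangency of a slope-1 line with the signal
curve, computed as the smallest argmin of (scaled signal − scaled rank);
released versions of the reference implementation differ subtly here
(grid search vs analytic), and the argmin form is deterministic, affine-
invariant, and matches the geometric description for convex non-decreasing
curves.  Regions strictly above the cutoff signal are super; an all-equal
signal vector is flagged degenerate with no super regions.  The same cutoff
defines top-ranked peak sets from per-peak basal/stimulated track sums, and
constraint ranking takes the top-k peaks by length-weighted mean
constraint score with deterministic id tie-breaking.

## Motif scanning

A JASPAR-style count matrix is regularised with pseudocount 1 distributed
equally over the four bases per position.  The background is an order-0 or
order-1 Markov model estimated from the scanned sequences (+1 pseudocount
per cell); under the order-1 model the first base of a window is scored
with the initial (order-0) distribution — the upstream scanner's treatment
of the first base is not documented, and the initial-distribution start
keeps windows self-contained.  Weights are natural-log likelihood ratios;
hits require weight ≥ 1 on either strand (minus-strand hits score the
reverse complement, reported at the forward-strand window start).
Overlapping hits all count: motif multiplicity is the signal of interest.
Counts per peak use hits whose start lies within ±100 bp of the summit.
The packaged matrix `data/rela_pwm_synthetic.jaspar` is a **synthetic**
RELA-like matrix with the canonical GGGRNWYYCC structure, provided for
fixtures and examples; analyses of real data should supply a database
matrix.

## Statistical kernels

Fisher's exact test (two-sided, hypergeometric-tail convention),
chi-squared with Yates's continuity correction (df = 1; degenerate margins
return p = 1), two-sided exact binomial, two-sided Mann–Whitney U, Welch's
t, and Bonferroni (`min(1, m·p)`) — all delegated to scipy.stats behind
named wrappers and verified against enumeration oracles in the test suite.
Every fold-enrichment formula reduces to `|S∩T|·|U| / (|S|·|T|)` over its
stated universe U, so a single 2×2 construction (rows: in the special set
or not; columns: in the type or not) backs all of them; the universe, the
counts in their formula-role names, the test used and the Bonferroni family
size are recorded in each result.  Family sizes follow the natural test
family (e.g. the five mode labels, or modes × gene classes); the source
analyses do not state family sizes, so they are emitted as metadata.
Variant overlap uses half-open containment (a variant at `start` counts, at
`end` does not); TSS windows are `[tss − 10 kb, tss + 10 kb)` with
multi-assignment allowed and presence-based counting per expression class.
The bias-corrected TSS enrichment restricts the universe to peaks near any
gene, removing the generic promoter-proximity advantage of conserved peaks.

## Synthetic landscapes

The generator emulates the downstream products of a three-species
(human/mouse/cow-like) stimulated-endothelium experiment, not reads.  Study
conditions are the defaults: 10,000 reference stimulated RELA peaks; 30%
conserved with at least one other species, 8% in all three (the remainder
split evenly between the two pairwise categories); mode proportions
O/C/OA/CA = 57/31/9/3; 1% prebound peaks, all Mode O, with a 2× conserved
enrichment; 25 super-enhancer neighbourhoods of 20 peaks (5% of peaks, the
lognormal(μ=1, σ=1) signal body's ×20 heavy tail), half built from
three-species-conserved peaks; prebound peaks enriched 3× in
super-enhancers and 3× near upregulated-gene TSSs and 17× among pan-cell
shared peaks; disease-variant-bearing peaks enriched 3× among
three-species-conserved peaks; motif placement 4 per peak for modes C/OA/P
versus 1 for O/CA within ±100 bp of summits.

Two constructions deserve explanation:

* **Deterministic planting.**  All label couplings are allocated with exact
  (largest-remainder) counts, hierarchically across the SE / conservation
  strata, rather than with independent Bernoulli draws.  Planted folds are
  therefore exact numbers, classifier recovery is exact, and the null
  variant (every fold set to 1, partner modes drawn independently, mixed
  SE clusters) yields fold enrichments of exactly 1 up to integer
  rounding — which is what makes a tight calibration check of the
  enrichment statistics possible at all.  Real data differ: labels are
  noisy, boundaries are fuzzy, couplings are probabilistic.  Passing tests
  show the *machinery* is correct and calibrated, not that real landscapes
  meet these assumptions.
* **Signal geometry.**  Inter-locus spacers (15–40 kb) exceed both the
  stitch distance and the TSS window, so stitching and TSS assignment
  cannot leak between loci; intra-cluster gaps (1–3 kb) are far below the
  stitch distance, so neighbourhoods stitch into single regions.  Basal
  noise is bounded (uniform on [0.1, 1.0]) with a ×50 prebound basal
  multiplier: a bounded noise distribution is dense at its top, which pins
  the inflection cutoff at the gap below the prebound population and makes
  top-ranked recovery clean; a heavy-tailed noise model would bleed into
  the cutoff region.  Prebound stimulated signal carries a ×2 boost — the
  most-induced individual peaks, mean Mode-P excess roughly an order of
  magnitude once SE membership is counted — deliberately kept below
  stitched-cluster aggregates so single prebound peaks do not masquerade as
  whole neighbourhoods.
* Mode preservation is planted as a per-partner copy probability (default
  per-mode: O 0.65, C 0.55, OA 0.05, CA 0.08, P 0.40; a scalar or `None`
  for independence); a partner that does not copy draws from the remaining
  modes proportionally, so the per-partner match probability equals the
  configured rate exactly.

The generator also emits per-species accessibility peak calls realising the
planted modes (placed or withheld deterministically, so classification
recovers labels exactly), basal RELA peak calls for prebound regions,
bedGraph tracks that integrate over each peak to its recorded signal,
a block table covering all species, gene/variant tables, cell-type peak
sets realising the sharing classes, and FASTA sequences with planted
consensus motifs.  `promoter_bias_fixture` is a separate small construction
in which conserved peaks concentrate near gene TSSs while gene classes are
assigned independently of conservation: the general TSS formula inflates
(>1.5×) and the corrected formula returns exactly 1 up to rounding.

## Problem sizes

The default landscape is 10,000 reference peaks with ~4,900 peaks in each
partner species — about one seventh of the reference study's scale, chosen
so the full pipeline (generation, conservation grid, preservation model,
SE calling, motif scan, enrichment battery) completes in well under a
minute per run.  All planted rates are scale-free; `SyntheticConfig.
for_n_peaks` rescales the absolute counts consistently.

## Known limitations

* Alignment blocks are ungapped and collinear; real alignments contain
  indels, inversions at finer scale, and paralogy, which can shift overlap
  lengths near the 1 bp threshold.
* The preservation model conditions only on the three conservation
  categories; real mode probabilities vary with signal strength and genomic
  context, so the independence expectation is a baseline, not a null in the
  causal sense.
* The inflection cutoff admits the sparse upper tail of any heavy-tailed
  body as singleton super-enhancers; this matches the reference algorithm's
  behaviour but means "SE membership" is sensitive to the signal-noise
  model.
* Accessibility evidence enters only as peak calls; nucleosome-occupancy
  tracks are consumed, never computed.
* Expression classes, variant lists and cell-type peak sets are inputs;
  no differential-expression or GWAS machinery is included.
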