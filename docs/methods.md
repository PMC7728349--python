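# Methods

This note documents the models, algorithms and numerical choices behind
cobindkit's three pipelines and its synthetic-data generators, and states
what the simulation-backed tests do and do not demonstrate about real data.

## Interval algebra

All peak arithmetic runs on 0-based half-open intervals (the BED
convention), stored per chromosome as sorted int64 start/end arrays. A
*normalized* set is sorted, pairwise disjoint and non-adjacent:
`normalize` merges overlapping **and book-ended** intervals, mirroring the
reduce defaults of the common genomic-ranges libraries, so downstream set
operations are well defined on covered bases. Consequences worth knowing:

* Book-ended intervals (one's end equals the next's start) share no base,
  so they never count as overlapping in `count_overlaps`, but they do
  coalesce during normalization.
* Strand is ignored throughout — peak calls are unstranded.
* Chromosome names are canonicalized to the `chr` dialect (`"1"` →
  `"chr1"`). Chromosomes present in only one operand contribute zero
  overlaps rather than raising.
* `intersect` is a two-pointer sweep, O(n+m) per chromosome;
  `count_overlaps` uses binary search against the disjoint subject arrays
  (an interval overlaps `[qs, qe)` iff its start < qe and end > qs).

The algebra is deliberately self-contained — it is the substrate every
other stage builds on — and is validated against two independent oracles
(per-base boolean bitmaps; quadratic all-pairs counting) and cross-checked
against pyranges in the test suite.

## Replicate consensus and co-occupancy

Consensus peaks of a factor are the genomic regions common to **all**
replicate peak lists (a fold of pairwise intersections; order-invariant,
monotonically shrinking). With a single replicate the peaks are used
as-is. After every consensus fold, regions narrower than `min_width = 5`
bp are discarded: intersection of jittered replicate boundaries produces
sliver regions that are alignment noise, not binding sites. One replicate
peak split by intersection into several common regions yields several
consensus peaks, each counted separately (plain set semantics).

The overlap percentage of factor F with CTCF is
`100 · #{F consensus peaks overlapping ≥1 CTCF consensus peak} / #{F
consensus peaks}` — each peak counted once no matter how many CTCF peaks
it touches. Full precision is kept internally; rounding to integer
percent happens only in reports.

Chromatin states are fixed combinations of histone-mark consensus sets:
single marks pass through (active promoter H3K4me3, inactive enhancer
H3K9me3, inactive promoter H3K27me3) and pairs intersect (active enhancer
H3K27ac ∩ H3K4me1, gene body H3K36me3 ∩ H3K79me2). State co-occupancy of
the CTCF-overlapping subset of a factor's peaks is evaluated per state
independently, so percentages need not sum to 100.

## Target-decoy q-values and interactor filtering

PSM confidence uses the concatenated target-decoy estimator

    FDR(s) = #{decoy scores >= s} / max(1, #{target scores >= s})
    q(x)   = min over thresholds s <= x of FDR(s), clipped to [0, 1]

with candidate thresholds at the distinct target scores. The minimum over
lower thresholds makes q monotone (a better score never has a worse q).
No +1 pseudo-count is added to the decoy count: the estimator is the
plain ratio, which keeps it transparent and exactly reproducible by
threshold enumeration. The practical consequence — scores above the top
decoy receive q = 0, so the strict-FDR region relies on the null having
enough probability mass in the extreme tail — is handled in the generator
design below. With no decoys present the null is unidentifiable; all q
are set to 0 with a warning.

An optional delta-Cn pre-filter (default cap 0.05) drops lower-ranked
candidate matches that score within the cap of the top candidate for
their spectrum.

Protein aggregation: per (accession, condition, replicate injection),
distinct-peptide and PSM counts; arithmetic mean across injections;
protein q = minimum supporting-PSM q (best-evidence rule);
`single_peptide_flag` marks proteins supported by a single distinct
peptide, which deserve skepticism regardless of q. Shared peptides count
toward every matching accession — no parsimony inference. Confidence
classes: high (q < 0.01), medium (0.01 ≤ q < 0.05), rejected otherwise;
both boundaries half-open.

Interactor filtering retains proteins that are high-confidence, have zero
evidence in the control IP (any control PSM excludes the protein — the
control-absence rule operates at protein level), and are not on the
contaminant list. The filter is idempotent and only ever removes rows.

The packaged mSWI/SNF table covers the 29 subunits of the modular
BAF/PBAF/ncBAF architecture, keyed by UniProt accession, with role
(core / signature / accessory) and per-complex membership; SMARCA2/4
(the ATPase module) are recorded under `core`.

## BLI equilibrium analysis

The measured interferogram is modelled as specific binding plus
non-specific background. Blank subtraction removes the background using
the carrier-protein trace at the same concentration, linearly
interpolated onto the signal's time grid (an exact operation for the
locally linear backgrounds it is meant to remove). The equilibrium
response is the corrected shift at t = 150 s — the end of a 120 s
association phase that follows a 30 s baseline — linearly interpolated
between bracketing samples. An alternative max-over-window read is not
used: the fixed-time read is robust to dissociation-phase transients.

K_D and B_max come from an unweighted least-squares fit of the one-site
isotherm B(c) = B_max·c/(K_D + c). Numerical choices:

* the fit runs in dimensionless units (concentrations scaled by their
  maximum, responses by their maximum magnitude), making the optimizer
  path invariant to nM-vs-µM units and response scale — the source of the
  scale-equivariance properties the tests assert;
* three deterministic starts (B_max0 = max response; K_D0 = first
  concentration reaching half of B_max0, and ×0.3 / ×3 jitters of it),
  keeping the lowest-RSS solution;
* trust-region reflective solver with tight tolerances (1e-14) and
  Jacobian-based parameter scaling;
* K_D constrained to [1 pM, 10 mM]; an estimate at those bounds clears
  the `converged` flag. All-zero response curves raise a degenerate-fit
  error rather than returning a meaningless optimum.

Kinetic (k_on/k_off) fitting is deliberately omitted: K_D here derives
from equilibrium plateaus only, so association-rate information in the
traces is unused beyond requiring the plateau to be reached.

## Synthetic-data generators

All generators take explicit seeds and are deterministic given them.

**Peaks.** `simulate_peakset` places n mutually disjoint, never
book-ended peaks uniformly (chromosomes weighted by length), widths
uniform on [150, 500] bp — typical transcription-factor peak scale — on a
100 Mb toy chromosome by default, n = 10,000. Placement is rejection
sampling against a sorted occupancy index with bounded retries.
`simulate_replicates` jitters each boundary by a rounded Gaussian
(sd 10 bp default) and drops peaks with probability 0.05 per replicate.
`simulate_cofactor` draws a Bernoulli(f) overlap label per cofactor peak
(binomial sampling, so the realized fraction carries binomial spread —
the quantity the recovery tests measure); labelled peaks are placed
inside distinct, randomly chosen base peaks, the rest disjoint from the
base set and from each other, so the planted label is exactly the
measured overlap status and normalization never merges peaks away.

**PSMs.** Decoys and incorrect targets share a N(0, 1) null; correct
targets are N(shift, 1), with shift = 3 (a 3σ effect) and a 30% null
proportion among targets by default, 5,000 + 5,000 records. A
light-tailed null is a deliberate design choice: with an
exponential-tailed (e.g. extreme-value) null, the estimated-FDR curve of
the plain ratio estimator has an asymptotic floor of roughly
(n_decoys / n_correct)·e^(−shift) — about 0.07 at these settings — so a
strict 1% cutoff would accept only the handful of scores above the top
decoy, a regime where ratio estimates are dominated by extreme-value
noise rather than by calibration. Gaussian tails give the strict cutoff
a well-populated operating point, which is what a calibration experiment
needs to be informative.

**BLI.** 1:1 Langmuir traces on a 1 s grid: zero baseline (30 s),
association B_eq·(1 − e^(−k_obs·t)) with B_eq = B_max·c/(K_D + c)
(120 s, k_obs = 0.08 s⁻¹ — fast enough that the 150 s read sits at
>99.9% of plateau), exponential dissociation at the same rate (a
single-rate simplification; the dissociation phase is not used by the
analysis). A concentration-proportional background (blank_slope·c) is
added to the raw signal and returned as the matched blank; Gaussian
noise (default sd 0.05 nm = 5% of the default B_max) is added to both.
Default concentration series are the two experimentally natural ones:
0.5–3.0 µM for the micromolar-affinity default (K_D 2.3 µM) and
10–200 nM for nanomolar-affinity runs (K_D 95 nM).

## Problem sizes used by tests and the acceptance script

Oracle equivalence uses 1,000 random instances on ≤100 kb toy genomes;
overlap recovery uses 4 planted fractions × 20 seeds at n = 10,000
peaks; FDR calibration uses 100 simulated searches of 10,000 PSMs;
K_D recovery uses 2 concentration series × 100 noisy simulations. These
sizes make the binomial/median tolerances meaningful while keeping a
full run around a minute on one CPU.

## What the synthetic tests do and do not show

The generators emulate the *statistical structure* the pipelines rely on
— controlled overlap fractions, replicate jitter/dropout, a shared
target/decoy null, Langmuir kinetics with background — not the biology
of real data. They do not model clustered peak placement (hotspots, CNV
bias), mappability artifacts, correlated replicate failures, score
dependence on peptide properties, shared-peptide ambiguity across
homologs, sensor drift, or analyte depletion. Passing recovery tests
therefore demonstrates that the estimators are correct and calibrated
under their stated assumptions; percentages and affinities from real
tracks and real interferograms additionally inherit whatever violates
those assumptions (data quality, antibody specificity, assembly
mismatches between tracks — inputs must share one genome assembly, as no
coordinate lift-over is provided).

## Known limitations

* Consensus requires overlap in *all* replicates; there is no majority
  -vote mode for experiments with many noisy replicates.
* No statistical test accompanies overlap percentages (no permutation or
  hypergeometric enrichment); they are descriptive, as is conventional
  for this analysis.
* Protein inference is by shared-peptide fan-out, not parsimony; protein
  q-values inherit the best-peptide rule's optimism for large proteins.
* The one-site fit assumes a single class of non-interacting sites and
  free-analyte concentration equal to total (no depletion correction).
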