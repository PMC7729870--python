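# Methods

## Scope and shape

`osteoid` implements the biomolecular evidence lines used to assess the
identity of archaeological human remains: collagen quality control,
dietary isotope mixing, reservoir-corrected radiocarbon calibration,
ancient-DNA authentication and consensus building, mtDNA haplogroup
assignment, and maximum-parsimony placement. It is a staged analysis
toolkit, not a single fitted model: each stage is an independent module
with its own inputs, and `osteoid.pipeline.run` composes them into one
evidence report. The report deliberately presents evidence lines without
an automated identity verdict — weighing the lines is the analyst's job.

## Collagen QC and diet (isotopes)

The atomic C/N ratio is `(C% / 12.011) / (N% / 14.007)` with molar
masses fixed at 12.011 and 14.007 g/mol. The recommended range for
well-preserved collagen defaults to [2.9, 3.6], boundaries inclusive;
ratios are reported to one decimal.

The marine dietary fraction is linear two-endmember mixing of δ¹³C,
clamped to [0, 1] and reported to 0.1 percentage point. Endmember
defaults are δ¹³C_terrestrial = −21.0‰ and δ¹³C_marine = −12.5‰
(the values of the Arneborg-style mixing methodology); both are
configurable and never baked into the formula. Outside the endmember
interval the fraction saturates at 0 or 1; between them it is affine and
exactly invertible (`d13c_from_fraction`).

Cluster comparison uses the Mahalanobis distance under the reference
cluster's sample covariance (ddof = 1), with membership defined by the
χ²(2 df) quantile at a configurable level (default 0.95). This statistic
is this package's choice — the motivating analysis only showed a scatter
plot — and the pipeline report says so. Clusters need ≥ 3 members;
numerically singular covariances (condition number > 1e12) are rejected.

## Radiocarbon calibration

Curves are tabulated (cal BP, ¹⁴C age, 1σ) triples parsed from the
standard IntCal `.14c` layout (`#` comments, comma- or
whitespace-separated, trailing Δ¹⁴C columns ignored), sorted by calendar
age and evaluated by piecewise-linear interpolation of both μ and σ with
no extrapolation.

The mixed curve for a consumer with marine dietary fraction f is

    μ_mix(θ) = (1−f)·μ_atm(θ) + f·(μ_mar(θ) + ΔR)
    σ_mix(θ)² = ((1−f)·σ_atm(θ))² + (f·σ_mar(θ))² + (f·σ_ΔR)²

ΔR applies to the marine component only, matching standard Marine20
usage. f enters as a point value; the marine fraction's own uncertainty
is not propagated (the reference treatment in calibration software is
undocumented, and for this specimen the effect is dominated by σ_ΔR).
With f = 0 the mixed curve returns the atmospheric values bit-identically.

Calibration uses a flat prior over a uniform calendar grid (default
1-year step; a minimum of 1 year is enforced) spanning the curve domain,
with the Gaussian likelihood
`L(θ) ∝ exp(−(y − μ_mix)² / 2(σ² + σ_mix²)) / sqrt(σ² + σ_mix²)`.
The computation runs in log space and the grid is trimmed to where the
likelihood exceeds 1e−12 of its maximum; if the best grid point lies
more than 38σ from the measurement (where the likelihood underflows to
zero in double precision) the date has no support and calibration
refuses. The posterior is normalized to unit mass (checked to 1e−9).

HPD range sets take grid points in decreasing density order until the
target mass is reached, merge adjacent points into ranges, and report
each range's own mass. Ranges are converted to calAD via
`calAD = 1950 − calBP` and reported rounded to 1 calendar year and 0.1%.
By construction the region is minimal-width among contiguous covers on
the grid and nested across levels (both verified by brute force in the
tests). Exact mass agreement with other calibration software is not
promised — binning and rounding conventions differ — and the tests that
compare against published ranges allow ±15 years on endpoints and
±1 percentage point on masses.

## Ancient-DNA processing

Reads arrive as plain SAM against a single mtDNA reference (parsed with
pysam; 1-based inclusive coordinates; the reference is treated as
linear — no simulated or expected read spans the rCRS origin, a
documented limitation). Filtering drops unmapped records, MAPQ below the
threshold (default 30), and any read id in a caller-supplied exclusion
list — the pluggable stand-in for external contaminant screens (BLASTN
against non-human genomes, numt matches); no alignment-based screen is
re-implemented. Terminal clipping masks the first and last aligned
bases (default 2) and is idempotent.

Damage profiling runs **before** clipping and consensus **after** it,
mirroring standard practice: authenticate on raw mapped reads, then clip
to keep mis-incorporations out of the consensus. Profiles count, per
offset from each read end in read orientation (reverse-strand reads
complemented and reversed), opportunities (reference C, or G) and hits
(read T, or A) for the C→T and G→A classes; cells with zero
opportunities are NaN, never 0. Both classes are profiled at both ends
because single- and double-stranded libraries leave different
signatures; `authenticate` checks 5′ C→T plus 3′ G→A for double-stranded
libraries and 5′/3′ C→T for single-stranded ones. The decision rule —
mean terminal rate (offsets 1–2) at least `min_ratio` (default 3×) times
the mean interior rate (offsets 11–25, floored at a pseudo-rate of 0.005
so clean simulations cannot divide by zero) at both ends — returns
`None` ("inconclusive") rather than `False` when any compared cell has
fewer than 100 opportunities.

Consensus calling is substitution-only (indels resolved in the CIGAR but
not called; inserted bases ignored, deletions contribute no counts): a
base is emitted where depth ≥ `min_depth` (default 2) and the modal
base's fraction ≥ `min_fraction` (default 0.7, both unstated in the
motivating analysis and chosen conservative), ties and everything else
emit N. Coverage breadth is the percentage of reference positions at or
above a configurable depth floor (default 1×), reported to one decimal.

## Haplogroup assignment

Variants are substitutions called between equal-length (pre-aligned)
consensus and reference; N positions are recorded as uncovered, never as
variants. The default mask removes the hypervariable A/C stretch length
polymorphism regions nps 303–315, 522–523 and 16180–16193 — keeping
np 16189, a haplogroup-B defining site — plus the hypervariable point
np 16519.

Assignment scores every node of a PhyloTree-style defining-variant tree
with the Kulczynski measure

    score = ½ · (found/expected + found/(found + private))

where the root-path defining variants at uncovered positions are dropped
from *expected* (uncovered sites reduce the evidence rather than count
against the sample — the ancient-DNA-friendly convention, noted in the
output). Degenerate ratios (expected = 0, or found + private = 0) are
defined as 1, so a reference-identical, fully covered sequence scores
1.0 at the root. Ties break to the deeper node, then lexicographically.
Scoring is weight-free (no per-site mutation-rate weights) for
transparency; imported tree variants with indel or back-mutation
notation are skipped with a warning, since only substitutions are
scored. The bundled ~25-node tree (`synth.build_fixture_tree`) is
fictional test scaffolding whose defining variants are generated against
a caller-supplied reference; real trees are user-supplied JSON.

## Maximum parsimony

Fitch small parsimony encodes each leaf state as a base set (N and gaps
are the full set — missing data, not a fifth state) and counts one
change per site wherever children's sets are disjoint, on a trifurcating-
root view of the unrooted topology. Exhaustive search enumerates all
(2n−5)!! unrooted binary topologies for n ≤ 9 and refuses beyond that;
`nni` mode runs 5 stepwise-addition starts (orders drawn from the seed)
each followed by best-improvement NNI hill-climbing, keeping the best
local optimum. All tie-breaking is lexicographic on a canonical newick
(rooted at the internal node adjacent to the alphabetically first leaf,
subtrees sorted), so exhaustive results are seed-free and reproducible.
Alignment masking maps columns to reference coordinates through a
designated reference row (gap-aware cumulative position); insertion
columns carry no coordinate and are left untouched. Bootstrap support is
out of scope.

## Synthetic-data generators

The read simulator draws truncated-normal fragment lengths (default mean
60 bp, sd 15 bp, minimum 25 bp — typical ancient-DNA fragment sizes) at
uniform positions and strands, applies geometric-decay terminal damage
(probability `terminal_rate · decay^(k−1)` at offset k; the simplest
monotone model consistent with observed terminal damage patterns) in
read orientation, then a flat per-base error rate, and emits valid
match-only-CIGAR SAM (MAPQ 60) plus a truth log of every injected event.
Curve generators produce constant, linear and wiggle shapes whose
posteriors have closed forms (a linear identity curve gives an exactly
Gaussian posterior; wiggle crossing counts set the number of posterior
modes). Isotope clusters are bivariate-normal draws. Every generator is
a deterministic function of its parameters and seed — same spec, same
seed, byte-identical output.

What the generators deliberately do not emulate: quality-score
distributions, indels, mapping ambiguity, reference bias, contamination
mixtures, and empirical (non-geometric) damage decay. Tests passing on
synthetic data therefore demonstrate the correctness of the algorithms
under the stated generative model, not performance on real sequencing
artefacts.

## Problem sizes in the test suite

The suite exercises the full simulate→consensus→assign loop on a 3 kb
random reference with the ~25-node fixture tree (700–2000 reads per
replicate, ≈10–20× depth), damage recovery over 20 replicate seeds, and
parsimony searches up to 6 taxa exhaustively (105 topologies) — sizes
chosen so the whole suite runs in well under a minute while every
statistical check retains hundreds-to-thousands of opportunities per
cell. Full-length (16,569 bp) runs work identically (the worked example
in the README uses one) and scale linearly.

## Known limitations

* The rCRS origin is treated as linear; reads spanning it are out of scope.
* No heteroplasmy or indel consensus calling; no contamination-rate
  estimation; no Bayesian sequence/phase calibration modelling or
  bomb-pulse curves.
* Calibration beyond the tabulated curve domain refuses rather than
  extrapolates.
* Exact reproduction of third-party software output (calibration mass
  rounding, consensus thresholds, haplogroup-caller weights, parsimony
  search settings) is not attempted; the method classes are
  re-implemented from their published definitions.
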