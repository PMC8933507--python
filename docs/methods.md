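# Methods

## The synthetic contact model

Every analysis stage in `hicdelta` is validated against simulated Hi-C maps
with known, planted structure. The expected intensity for a cis bin pair
(i, j) at separation s bins is

```
λ_ij = b_i b_j · max(s^−α, floor) · plaid_ij · tad_ij · loop_ij
```

and for a trans pair `λ_ij = b_i b_j · t · pref_AB`, where

- `α` (dimensionless, default 1.0) is the contact-decay exponent; the
  `decay_floor` (default 1e−5 relative to the s = 1 intensity) models the
  long-range plateau real maps show.
- `plaid_ij = 1 + δ` for same-compartment pairs and `1 − δ` otherwise, with
  compartment strength `δ ∈ [0, 1)` (default 0.2) over alternating A/B
  blocks whose lengths are exponential with mean
  `compartment_segment_length` (default 2.5 Mb) — a realistic plaid without
  sequence input.
- `tad_ij` multiplies pairs inside a declared TAD block by its enrichment
  (> 1); `loop_ij` multiplies a dot of configurable width at each anchor
  pair by intensity k > 1. Dots are slightly peaked — full amplitude k at
  the centre pixel, tapering 10% per ring — because point-like focal
  enrichment is what loop callers detect; a perfectly flat dot would leave
  the centre pixel tied with its neighbours in expectation.
- `b_i` are log-normal per-bin biases (`bias_sd`, default 0.3), the
  visibility artifacts ICE is meant to remove.
- `t` (`trans_level`, default 0.01 relative to the cis s = 1 plateau) sets
  the uniform trans background; `pref_AB` is a symmetric chromosome-pair
  preference matrix (default all ones).

Counts are sampled independently Poisson on the upper triangle, with rates
scaled so the expected total equals the target depth, then symmetrized.
Poisson (not negative binomial) is the simplest model consistent with count
data; overdispersion can be layered on by a user without changing any
interface. All planted structure (labels, biases, boundaries, loops, gene
density) derives deterministically from the config seed and is serialized
next to the maps, so tests never reach into simulator internals.

### The expansion perturbation

A second condition is derived, never re-planted: the same structural seed
with a transformed expected model.

- **Steeper short-range decay**: below `short_range_cutoff_bp` the exponent
  becomes α + Δα, continuously matched at the cutoff
  (`decay = cut^Δα · s^−(α+Δα)` for s ≤ cut). Real expansion data show a
  kink in the scaling curve without a stated functional form; continuity is
  the minimal assumption.
- **Compartment attenuation**: δ′ = γδ, γ ∈ (0, 1].
- **Class-dependent distal shifts**: contacts beyond 3 Mb between bins of
  annotated classes (e.g. constitutive-LAD-like segments) are multiplied by
  m_i · m_j. The pairwise product is chosen so that, with well-mixed
  partners, the class-mean ΔDLR gap equals log2(m) exactly. Note that when
  class segments are long relative to the 3 Mb cutoff, a class's distal
  partners are enriched for its own class and the realized gap exceeds
  log2(m); validation runs therefore use 1 Mb class segments.
- **Loop modulation**: dot amplitude k′ = 1 + (k − 1)·mult, so mult → 0
  removes a dot smoothly and mult = 1 is the identity.
- **Trans modifiers**: per-chromosome multipliers t_A · t_B on trans rates.

A deliberate property of this design: boosting a class's distal contacts
and then rebalancing redistributes signal away from its local
neighbourhood, which shifts that class's aggregate insulation profile
vertically without moving boundary positions — the same coupling between
distal gain and local loss that swelling data exhibit. No separate
"local-contact multiplier" is needed.

### What the generator does not emulate

No polymer physics, no sequence, no real karyotype; plaid blocks are
exponential rather than copied from a genome; biases are log-normal and
independent; counts are equidispersed. Passing tests therefore demonstrate
that each estimator recovers the quantity it claims to measure under its
own model assumptions — not that those assumptions hold in any particular
experiment.

## Analysis-stage choices

**Coordinates and binning.** 0-based, half-open throughout (BED
convention); short terminal bins are kept and treated as ordinary bins;
BEDPE anchors are normalized to (min, max). Bin labeling from interval
annotations uses majority-overlap in bp with exact ties and uncovered bins
mapped to "unlabeled" (the overlap rule is configurable; nothing in the
comparative metrics is sensitive to it at 100 kb with multi-bin
annotations).

**Iterative correction.** Bins with zero coverage plus the bottom 2% of
positive-coverage bins are masked before iteration (configurable). The main
diagonal is excluded from the balancing sums and from every
distance-normalized metric. Convergence is a coefficient of variation of
unmasked marginals below `tol` (default 1e−6); the bias vector is
normalized to mean 1 over unmasked bins. Non-convergence warns and returns
the partial result, flagged.

**Coarsening.** Counts are summed; the merged-bin diagonal keeps
unordered-pair semantics (intra-block pairs counted once), so the total
count is exactly conserved; a merged bin is masked only if all parts are.

**Reproducibility.** Log of positive corrected 1 Mb entries (zeros
missing), diagonal removed, per-map correlation map (entry (i, j) =
correlation of rows i and j across the genome), then correlation between
vectorized correlation maps. Spearman at both steps by default; both are
configurable to Pearson.

**Expected and z-scores.** Expected profiles are per-chromosome by default
with a genome-pooled variant for scaling curves. Distance z-scores are
computed within each separation per chromosome; diagonals that are
numerically constant (sd ≤ 1e−12 of the mean) give missing values rather
than amplifying rounding noise.

**Compartments.** PCA input is the correlation matrix of the per-chromosome
O/E map. The correlation is pairwise-complete; row pairs sharing less than
half the available coverage give missing entries imputed as 0, and rows
with no real variation are marked missing (an exactly flat map must come
out "degenerate, no compartment signal", not as noise eigenvectors). PC1 is
scaled by √eigenvalue and sign-fixed so the positive group has higher mean
gene density. The control condition's PC1 orders both conditions in saddle
differences so pixels are comparable; z-scores are computed first and
smoothing (2×2 block means, 250 → 500 kb) is applied last, matching the
stated order of operations. Compartment strength takes the top 20% of
smoothed O/E values *within each* of the A-A, B-B and A-B classes before
taking medians: a pooled threshold is also available but degenerates on
clean data, where A-B values are systematically lower and the pooled top
quintile contains no A-B pairs at all, leaving the statistic undefined.

**Insulation and boundaries.** Windows with more than half their entries
masked are missing; masked entries otherwise reduce the averaging
denominator rather than being zero-filled. Scores are log2 ratios to the
chromosome mean (raw mode available), so calls are invariant to global
rescaling. Boundaries are profile minima with prominence ≥ `min_strength`
(default 0.1); equal-minimum plateaus report their leftmost bin. Interior
missing runs of up to 2 bins are bridged by linear interpolation before
minima detection, because coverage masking preferentially hits insulated
junction bins and a minimum at the edge of a data run is otherwise
undetectable. The 20 kb/160 kb and 40 kb/520 kb parameter pairs are the
two standard settings; the "160 kb step" sometimes seen in descriptions of
the regression response is read as the 160 kb square size.

**Scaling, DLR, ICF.** Loess span 0.3 in log–log coordinates; curves are
normalized to 1 at the minimum distance; at 10 kb resolution distances are
capped at 1 Mb. Slope estimates near a planted slope break use the raw
per-distance means (`log_slope(on="raw")`) since smoothing across a kink
biases the local slope. The DLR boundary case (exactly 3 Mb) counts as
local. ICF uses inter/(inter + intra), bounded in [0, 1] — the equation
form — rather than the trans/cis odds, which is available as a derived
quantity; per-bin at 1 Mb is the plotting granularity, per-chromosome the
aggregation the equation describes. Delta metrics are (condition B − A)
with optional genome-median centring.

**Loops.** Anchor midpoints snap to their containing bin. The loop bin is a
30 kb square assembled from 10 kb bins around the midpoint pixel; the donut
is the ring beyond a 1-bin exclusion out to 5 bins, minus the row/column
stripes through the centre; donuts that leave the chromosome or are more
than half masked give a missing strength with a reason string. Strength is
computed on O/E by default (configurable), making it invariant to depth and
decay. Site pairing uses midpoint separation (> 50 kb default). Random sets
in anchor-factor enrichment match the anchor count and length distribution,
placed uniformly with chromosomes weighted by length.

**Regression.** All six categorical levels are one-hot retained (no
reference drop — 23 numeric tracks plus one 6-level categorical give
exactly 29 columns); ridge's L2 penalty (default 1.0 on standardized
features) absorbs the induced collinearity. Standardization uses the
population standard deviation; constant columns are dropped with a warning;
coefficients are reported on the standardized scale. The ridge solve is the
closed-form normal system with an unpenalized intercept; forest importances
delegate to a seeded scikit-learn `RandomForestRegressor` with impurity
importances (non-negative, summing to 1).

**Pipeline.** One global seed fans out to stage-specific derived seeds
(FNV-style hash of the stage name), so toggling one stage never shifts
another's randomness. All figure-level quantities are emitted as TSV tables
with fixed float formatting; reruns with one seed are byte-identical.

## Validation problem sizes

The test suite and `scripts/acceptance.py` run on toy genomes chosen so
each planted parameter is comfortably identifiable: 2 × 25 Mb at 100 kb and
depth 5 × 10⁶ for compartments (≈ 20 plaid segments/chromosome, PC1–label
correlation > 0.95); 11 Mb at 20 kb with ten 1 Mb TADs (enrichment 3) for
boundary calling; 2 × 10 Mb at 20 kb for scaling exponents; a 20 Mb
chromosome at 10 kb, depth 4 × 10⁷, with forty k = 4 dots for loop
metrics; 2000 bins × 29 features for regression. Boundary validation uses
`min_strength = 0.5`, sitting between the synthetic noise floor (≈ 0.25)
and the planted dip depth (log2 3 ≈ 1.58); the looser default of 0.1 is
aimed at deep real data.

## Known limitations

- Dense in-memory matrices: genomes beyond ~25k bins at the working
  resolution need chunking that the current container does not provide.
- The reproducibility metric's O(n²) pairwise correlations are practical at
  1 Mb resolution only.
- Perturbation magnitudes are free parameters of the generative model, not
  calibrated to any particular experimental system.
- Loop classification consumes motif flags; no motif scanning is performed.
- Subcompartment labels are consumed, never inferred; only PC1 (no higher
  PCs) is computed.
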