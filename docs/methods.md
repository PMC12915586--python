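# Methods

This note documents the statistical procedures, the synthetic data model,
numerical conventions, and the design decisions behind `amplitrait`.

## Trait annotation

**Alignment model.** OTU representative sequences (V4-scale, ~250–260 nt)
are matched to reference 16S regions by optimal *overlap* alignment: linear
gap cost, free end gaps on both sequences, default scoring match +1 /
mismatch −1 / gap −2. `N` never counts as a match, even against `N`.
Reported quantities follow the conventions of BLAST-style outputs:

- *identity* = identical columns / alignment columns, with interior gap
  columns counted in the denominator ("identities / alignment length");
- *query coverage* = query residues inside the aligned span / query length
  (coverage is query-side only: the amplicon should be fully explained by
  the reference region, while reference overhang is free).

Ties are broken deterministically (end cell: first maximum scanning the
final DP row then column; traceback: diagonal, then gap-in-subject, then
gap-in-query), so identity and coverage are reproducible across runs and
platforms. The forward pass is vectorised row-wise via a prefix-max
reformulation of the linear-gap recurrence; the test suite verifies exact
agreement with an independent exhaustive DP on thousands of random pairs.

**Prescreen.** An exact k-mer index (k = 11) restricts which references a
query is aligned against; queries sharing no 11-mer with any reference fall
back to a full scan. Since any near-identical pair at V4 length shares an
11-mer with overwhelming margin, the prescreen is purely a speed device and
cannot change a best hit; the fallback covers the rest.

**Best hit and thresholds.** The best hit maximises score, with ties
resolved by higher identity and then lexicographically smaller accession.
Trait assignment requires identity ≥ 95% and coverage ≥ 95% (both
configurable); failing OTUs are recorded as unassigned together with their
best-hit diagnostics. Only the best hit is used; averaging traits over
near-tied references would be a reasonable alternative but is not
implemented.

**Community-weighted means.** Per sample and per trait,
CWM = Σ nᵢtᵢ / Σ nᵢ over OTUs assigned for that trait, computed on the
*rarefied* table (rarefaction precedes everything downstream). Genome size
(Mb) and RRN are treated independently, since a reference record could
carry one trait and not the other; each CWM is reported with its assigned
read fraction, and is undefined (NaN) when that fraction is zero. Weighted
means are scale-invariant in the counts and invariant to OTU column order.

## Community statistics

All statistics are implemented from their definitions; scikit-bio supplies
only the validated `DistanceMatrix` container. scipy/scikit-bio
implementations of the same statistics appear in the test suite as
independent cross-checks, never in the analysis path.

- **Rarefaction** draws a multivariate hypergeometric sample (subsampling
  without replacement) to exactly the target depth (default 2000 reads);
  shallower samples are dropped and listed.
- **Bray–Curtis** d(a,b) = Σ|aᵢ−bᵢ| / Σ(aᵢ+bᵢ).
- **PCoA** eigendecomposes the Gower-centred matrix −½ J D² J. Bray–Curtis
  is non-Euclidean, so negative eigenvalues occur; they are reported but
  excluded from variance-explained denominators, and no Cailliez/Lingoes
  correction is applied — the most transparent convention.
- **PERMANOVA** uses sequential (Type I) sums of squares in formula order,
  computed through projection matrices of the cumulative dummy-coded model
  (`a*b` expands to `a + b + a:b`; all variables are treated as categorical
  factors). Pseudo-F per term uses the full-model residual mean square.
  p-values permute raw sample rows — within strata when a grouping column
  (e.g. site) is given — with p = (1 + exceedances)/(1 + n_perm). Site can
  thus constrain exchangeability without a mixed model, which is outside
  this package's scope.
- **Mantel** correlates (Pearson by default, Spearman optional) the
  strictly-lower-triangle entries of two distance matrices, permuting one
  matrix's rows and columns simultaneously; one-sided (R ≥ observed). When
  n! ≤ 10,000 all relabelings are enumerated and the p-value is exact.
  Temporal distance is |tₐ − t_b| on time-point indices (sampling was
  near-regular, so index coding is the default).
- **Spearman trends** use average ranks for ties and the t-approximation
  with n−2 df for p (two-sided); an exact permutation option exists for
  n ≤ 9. **Kruskal–Wallis** applies the standard tie correction with a
  chi-square p (g−1 df); with all observations identical H is reported as 0
  and p as 1. **Bonferroni**: p_adj = min(1, m·p).
- Permutation counts default to 999 (PERMANOVA, Mantel); all permutation
  tests take seeds.

## Indicator taxa screen

Counts are converted to relative abundances per sample. For each taxon
occupying ≥ 3 samples, candidate change points are the midpoints between
consecutive distinct gradient values with ≥ 3 samples on each side. At each
candidate, IndVal = 100·A·B is computed for both sides (A = side mean
abundance / sum of side means; B = side occurrence frequency) and the
partition takes the larger side. A permutation z-score (default 250
gradient shuffles, shared across candidates) standardises the observed
IndVal; the change point maximises z — the point of "strongest change" —
and the direction is the side achieving it (increaser when the
high-gradient side wins). The taxon's p-value is the permutation exceedance
probability at the selected split.

Bootstrap resampling of samples (default 500 replicates) yields *purity*
(fraction of bootstraps agreeing with the observed direction) and
*reliability* (fraction with permutation p ≤ 0.05); retention requires both
≥ 0.95. Bootstrap replicates that lose every valid split (after resampling,
fewer than two distinct gradient values or too-small sides) are excluded
from both denominators and the valid count is reported. Community-level
sum(z) curves from the full published method are not implemented.

The trait contrast compares *unweighted* mean genome size and RRN between
retained increasers and decreasers (Kruskal–Wallis p per trait); under
fast-to-slow succession the expected signature is a positive genome-size
difference and a negative RRN difference.

## Synthetic study model

The generator emulates a seedling-microbiome design: 3 compartments (air,
leaf, root) × 7 time points × 2 treatments (control, N addition) × 3 sites
× 2 replicates. Defaults, chosen once as field-realistic values:

- **Guilds.** `late_slow` (15% of taxa; genome size ~N(8.0, 0.5²) Mb, RRN ∈
  {1,2}; anchored by an exemplar at exactly 8.817 Mb / RRN 2), `early_fast`
  (15%; ~N(4.0, 0.5²) Mb, RRN ∈ {5,6,7}; anchor 5.778 Mb / RRN 3) and
  `background` (70%; ~N(5.5, 0.8²) Mb, RRN ∈ {2..5}). The generator
  validates that the slow guild has larger genomes and lower RRN than the
  fast guild.
- **Trajectories.** Log-linear per guild and compartment: root slopes
  ±0.35 per time point (late_slow up, early_fast down), leaf ±0.08, air 0 —
  strong turnover in roots, weak in leaves, none in air. N addition
  multiplies the early_fast share by 0.7.
- **Noise.** Per-taxon log-normal baselines (σ = 1), one multiplicative
  log-normal site × guild effect (log-σ = 0.15) standing in for a site
  random factor, Dirichlet compositional noise (concentration 200;
  disabled with `None`), multinomial counts at a uniform-integer depth in
  [1500, 6000] — so a realistic minority of samples falls below the
  2000-read rarefaction depth and exercises the dropping path.
- **Reference coverage.** 25% of background taxa receive OTU sequences
  unrelated to any reference, and matched OTUs diverge from their reference
  by a per-taxon target identity drawn from [0.96, 1.0] (substitutions
  placed to land within one substitution of the target). With 60 taxa this
  puts per-sample assigned read fractions in a realistic ~70–95% band.
- **Seeding.** One master seed feeds named substreams (reference,
  amplicons, counts, and one per downstream stage), so any stage is
  reproducible in isolation and two full runs are byte-identical.
- Unbalanced designs (e.g. a site lost after early time points) are
  supported through explicit `missing_cells`, not assumed by default.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: no phylogenetic structure in sequences beyond the
controlled divergence, no chimeras or clustering artefacts, no taxon-taxon
interactions or autocorrelated noise, no copy-number bias of 16S counts,
and guild trait distributions far cleaner than real reference databases.
Recovery of the planted pattern demonstrates correctness of the machinery,
not ecological inference strength on field data.

## Problem sizes and defaults in the shipped analyses

The default study (60 taxa, ~250 samples) with 999 PERMANOVA/Mantel
permutations and the indicator screen at 250 permutations × 500 bootstraps
runs in about a minute on one core; these scaled-down permutation counts
are configurable and were chosen to keep full runs interactive while
leaving permutation p-value resolution (≥ 1/1000, ≥ 1/251) adequate for the
0.05 decisions taken on them. Calibration checks in the test suite use 500
null datasets of 20 samples at 199 permutations.

## Known limitations

- Alignment is linear-gap only; affine gaps are unnecessary at V4 scale but
  would change identities on long-indel pairs.
- PERMANOVA offers sequential SS only (no Type II/III marginal tests) and
  categorical factors only.
- The indicator screen reports per-taxon results; community-level
  change-point aggregation is out of scope.
- Taxonomy assignment, functional prediction, mixed-effects models and
  autocorrelation structures are deliberately outside the package.
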