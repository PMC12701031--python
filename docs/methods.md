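# Methods

## The genetic-map model

A map is a per-chromosome sequence of markers `(position bp, cumulative cM)`
with strictly increasing positions and non-decreasing cM. Cumulative cM is
the primary stored quantity; the cM/Mb rate of an inter-marker segment is
always derived as `ΔcM / Δbp × 10⁶`, so the two representations cannot
diverge. Between markers the map is piecewise linear in cM (equivalently,
piecewise constant in rate); no smoother interpolation model is offered,
because every downstream statistic here (windowed means, hotspot flags,
concentration curves) is defined on segments. Marker positions are 1-based
at file boundaries (the VCF/PLINK convention); all interval algebra
(segments, windows, BED overlap) is 0-based half-open internally, with a
marker at position *p* sitting at coordinate *p − 1*.

Conservation is the load-bearing invariant: for any map, Σ rate × length
over segments equals cM(last) − cM(first) to 1e-9 relative, and rescaling,
averaging, PAR combination and cleanup are all written to preserve or
account for it explicitly.

## Rescaling and the consensus map

LD-based inference yields population-scaled rates; their absolute scale is
sensitive to the assumed demography. Maps are therefore rescaled per
chromosome by a single factor `target / current total` to match externally
estimated chromosome lengths — a linear operation that leaves the relative
rate profile untouched.

The consensus map across populations uses the sorted union of marker
positions restricted to the interval where *every* input is defined, and on
each union segment takes the rate `Σ wᵢrᵢ / Σ wᵢ`, with weights the number
of chromosomes behind each inference. Restricting to the intersection of
extents is a choice: extrapolating any input beyond its first or last
marker would invent rates where that population has no information.
Equivalently (and as implemented), the consensus cumulative cM is the
weighted mean of the inputs' interpolated cM, re-anchored to 0 at the first
union marker; the per-segment identity is what the tests check against
brute-force arithmetic.

## Windowed rates and missingness

A window's rate is the length-weighted mean of segment rates over the part
of the window covered by the map — i.e. `ΔcM` across the covered portion
divided by covered length. Windows with zero covered bp are reported as
missing (NaN) and excluded from correlations, never zero-filled: a window
outside the marker span carries no rate information, and zero-filling would
inject spurious ties into rank correlations.

## Multi-scale correlation

Correlations between maps are Spearman's ρ on paired window rates. Windows
of ≥10 kb tile each chromosome end to end at step = window size; 100 bp and
1 kb windows are instead placed on a sparse grid centered every 10 kb
(midpoints at 5 kb, 15 kb, …) so that adjacent small windows do not share
local autocorrelation. The 5 kb phase is a convention, configurable in
`_window_grid`. Pairs are pooled across chromosomes before ranking —
producing one ρ per map pair and scale — rather than averaging
per-chromosome coefficients; per-chromosome use is available by passing a
single-chromosome collection. Ties get mid-ranks (scipy); no p-values are
attached, as sliding-window rates are strongly autocorrelated and nominal
p-values would be meaningless.

## Concentration (skew) of recombination

All inter-marker segments are pooled, sorted by rate descending, and their
physical and genetic lengths accumulated into a Lorenz-style curve from
(0,0) to (1,1). Sorting descending makes the curve concave and places it on
or above the diagonal, with equality exactly for a uniform map. The summary
scalar — the sequence fraction at 80% of recombination — is linearly
interpolated between bracketing curve points and is invariant under
rescaling. Segments, not fixed windows, are the accumulation unit: they are
the native resolution of the map and avoid imposing a window-size choice on
the statistic.

## Assembly transfer and cleanup

Coordinate lifting itself is external; the pipeline consumes a table of
`(old chrom, old pos) → (new chrom, new pos | unmapped)` records. Steps, in
order:

1. **Inversion** of configured chromosomes whose orientation differs between
   assemblies (default {27, 32}): each cM becomes `total − cM`, anchored as
   `cM(first) + cM(last) − cM` so applying it twice is an exact involution.
   The intermediate map has decreasing cM and is carried unvalidated until
   the lift mirrors the physical axis.
2. **Lift**: unmapped markers and markers whose target chromosome differs
   from the modal target of their source chromosome are dropped and counted
   (the mode, rather than a fixed name, decides the target because the
   table alone does not say which new chromosome "is" the old one); the
   rest are re-sorted by new position, keeping their genetic positions.
   Markers landing on an occupied position are dropped (a 0 bp interval has
   no rate).
3. **Cleanup**: one left-to-right scan retains the first marker and drops
   any marker whose cM is below that of the last *retained* marker or whose
   implied rate relative to the last retained marker exceeds 50 cM/Mb —
   such spikes are transfer artifacts, not biology. Comparing against the
   last retained (not the previous input) marker guarantees a valid,
   ceiling-respecting map in a single pass and makes the operation
   idempotent, which the property tests sweep. Genetic positions are not
   re-anchored afterwards; the report records exactly how much length the
   dropped markers took with them, and per-category counts always sum to
   the input marker count.

## Hotspot detection and overlap enrichment

The chromosome-average rate is total cM over the physical span between
first and last marker — the length-weighted mean of segment rates, which is
the natural cM/Mb average (an unweighted mean of segment rates would let
many short segments dominate). Segments at ≥10× that average (inclusive at
the boundary) are flagged; consecutive flagged segments (sharing a marker)
merge; a merged run is a hotspot iff it has ≥3 bounding markers ("more than
two SNPs") and spans strictly less than 5 kb. Every reported hotspot is
re-checkable against all three rules post hoc, and the tests do so.

Overlap between interval sets is the fraction of query intervals with ≥1 bp
of overlap with any target interval, half-open semantics; a query hitting
two targets counts once. The measure is directional by construction. The
null re-places each query interval uniformly at random within its own
chromosome (length preserved, placements independent, overlaps among placed
intervals allowed — matching the behavior of a same-chromosome shuffle with
replacement); a placement of length L on a chromosome of size S has
S − L + 1 equally likely starts, which is what the analytic calibration
test checks. The empirical p-value uses the add-one estimator
`(1 + #{perm ≥ obs}) / (n + 1)`, so it is never exactly zero.

## Trio truth phasing and switch-error taxonomy

At a biallelic site, a child heterozygote is phased by Mendelian
segregation when exactly one assignment of its alleles to the parents is
consistent (at least one parent homozygous); both-parents-het sites are
undetermined, and any missing genotype or inconsistent configuration
discards the site. Undetermined and child-homozygous sites neither score
nor interrupt the adjacency of scored hets — an undetermined site between
two resolved hets is simply invisible to the scorer.

Scoring aligns the test sample's arbitrary haplotype labeling to truth at
the first scored het (no switch can be charged before any information
exists; this also makes the result invariant to globally swapping the two
test haplotypes). Each consecutive pair of scored hets yields a switch
indicator; maximal indicator runs are decomposed as: length 1 → one single
switch; length k ≥ 2 → ⌊k/2⌋ double switches (each consuming two paired
switch errors) plus (k mod 2) singles. The greedy pairing for k ≥ 3 is the
minimal-error reading: a double switch is the signature of one wrongly
phased site (often a genotyping error), so a run of three adjacent
indicators is most parsimoniously one mis-phased site plus one true switch.
Two rates share the Mendelian-phased-het denominator: the switch-error rate
counts every indicator; the phase-error rate counts singles + doubles,
charging each mis-phased site once. The denominator is the number of phased
hets rather than het *pairs*; at realistic scales (~10⁵ hets) the two
differ below printed precision, but the choice is fixed here.

## X-chromosome preparation

Diploid-only LD inference cannot consume hemizygous male X genotypes
directly, so males are paired into pseudo-diploids: a seeded shuffle, then
consecutive pairing, odd male dropped. Pairing is random because pooled
allele counts are conserved under any pairing — downstream frequency-based
inference is pairing-invariant — so nothing is gained by optimizing it.
The non-PAR effective size is scaled by 0.75 (three X chromosomes per four
autosomes at equal sex ratio), the default mutation rate is 4 × 10⁻⁹ per bp
per generation, and separately inferred PAR and non-PAR maps are
concatenated with the non-PAR cM offset by the PAR total so genetic length
is conserved. The PAR boundary is assembly-specific configuration, never
hard-coded. Chromosome accounting per population: 2(F + M) autosomal
chromosomes, 2F + 2⌊M/2⌋ X chromosomes.

## Synthetic data: what it does and does not emulate

The generators produce exactly the structures the analyses consume — maps
with planted constant-rate hotspots on a constant background, lift tables
with planted unmapped/cross-chromosome/mirrored records, trios obeying
Mendelian transmission with planted missingness and guaranteed-inconsistent
genotype configurations, and phased haplotypes with planted switch errors
defined operationally by the indicator patterns they must produce (a single
switch is a labeling crossover → one indicator; a double switch is one
flipped het → two adjacent indicators), so generator and scorer cannot
drift apart. Allele frequencies are uniform on (0.05, 0.5): only het
density matters to any consumer.

Not emulated: linkage disequilibrium, realistic site-frequency spectra,
genotyping-error processes beyond planted inconsistencies, rate variation
beyond background+hotspot, or assembly alignment. Passing tests therefore
demonstrate the correctness of the implemented logic under its stated
definitions — not the statistical performance of LD-based inference or
statistical phasers on real data, which depend on exactly the features the
simulations omit.

## Numerical choices and problem sizes

Tolerances: conservation and consensus arithmetic at 1e-9 relative; exact
equality where values are copied, not computed. Ties: mid-ranks in
correlations; the hotspot threshold is inclusive (a segment at exactly 10×
the average is flagged); the 5 kb span bound is strict. Degenerate inputs
raise rather than return silent defaults: empty query sets, zero-length
maps against positive rescale targets, disjoint consensus coverage,
fewer than 2 hets to score, fewer than 3 usable correlation windows.

Default problem sizes in the test and acceptance workflows — 10 Mb
chromosomes with ~1000 markers, 3000-site trios, 20-seed sweeps, 2000
permutations — are chosen so each planted structure is recovered exactly
(hotspot spacing ≫ marker jitter, switch events separated by ≥3 hets) while
a full run completes in seconds; the statistics being checked (exact
recovery, analytic placement probability, closed-form skew values) do not
sharpen with larger inputs.

## Known limitations

- The consensus map is undefined where any input population lacks coverage;
  regions covered by only some maps are excluded rather than averaged over
  the available subset.
- Cleanup cannot distinguish a genuine short high-rate region from a
  transfer artifact; at the 50 cM/Mb ceiling, real hotspots narrower than a
  marker interval could in principle be discarded on a transferred map.
- The switch-run decomposition for runs ≥3 is a convention; alternative
  pairings change the single/double split (never the total switch count).
- The permutation null ignores placement constraints (gaps, unassembled
  sequence); enrichment against a target set concentrated in accessible
  sequence will be conservative or anticonservative accordingly.
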