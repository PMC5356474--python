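# Methods

This note documents the models and estimators implemented in `wisentmix`,
the design decisions behind them, the synthetic-data generator's assumptions,
and the problem sizes used by the validation experiments.

## Data model

All analyses operate on *pseudo-haploid* genomes: one base per reference
position per individual, over the alphabet {A, C, G, T, N}, on a shared
coordinate frame (identical chromosome names and lengths).  Coordinates are
0-based half-open everywhere; BED output follows directly.  Internally bases
are coded A=0, C=1, G=2, T=3, N=4, so a base's purine/pyrimidine class is its
low bit — transversion masking, binary recoding and damage simulation are all
single vectorized bit operations.

Pseudo-haploidization draws one base uniformly at random among reads passing
the base- and mapping-quality cutoffs (defaults 30/30; the cutoffs are
decisions of this package, exposed as options, not published values).  Ties
are never resolved by majority vote: a heterozygous site must contribute each
allele with its read proportion for downstream allele-sharing statistics to
be unbiased.

## Transversions only

Post-mortem deamination of cytosine creates C→T (and, on the opposite
strand, G→A) miscoding lesions in historical samples.  Both are transitions:
they never change a base's purine/pyrimidine class.  All default analyses
therefore score transversions only:

* windowed divergence counts only sites whose two bases differ in R/Y class;
* ABBA/BABA counting recodes the four bases to R/Y classes *before* pattern
  matching, so a damage flip cannot create, destroy, or relabel an
  informative site — transversion-mode counts are bitwise invariant to the
  damage rate (this is asserted in the acceptance suite);
* block phylogenies are computed on the binary R/Y recoding directly.

A site like (A, C, T, G) has more than two alleles but two R/Y classes; the
R/Y formulation scores it where a strict biallelic filter would drop it.
This is a deliberate choice: it is exactly what "recode to binary characters,
then score" means, and it is what makes the damage invariance exact rather
than approximate.  The transitions-included mode (`mode="all"`) uses strict
base-level biallelic patterns instead and is provided for modern-sample
comparisons.

## Windowed divergence and distances

The genome is tiled with non-overlapping windows (default 1 Mb; terminal
windows keep their true shorter length and are flagged).  Per window and pair
of genomes, divergence = differences / comparable sites, where a site is
comparable when both genomes are non-N; windows with more than 75 % missing
data are excluded from densities and distances.  Divergence is a proportion
of comparable sites, not of window length, so missingness shifts precision,
not location.  Kernel densities use a Gaussian kernel with the rule-of-thumb
bandwidth `0.9 · min(sd, IQR/1.34) · n^(−1/5)` on a 512-point grid extended
three bandwidths past the data range.  Whole-genome distances pool
differences and comparable sites over retained windows (the comparable-site-
weighted mean of window divergences); densities pool windows across
chromosomes.  The NJ tree uses the Q criterion with Studier–Keppler branch
lengths, ties broken toward the lowest pair index; negative branch-length
estimates are kept as computed so that additive matrices round-trip exactly.

## D statistic and f̂

For genomes (P1, P2, P3, O), a site is informative when all four bases are
non-N, the P3 class differs from the O class (P3 carries the derived state
relative to the outgroup) and P1, P2 disagree.  ABBA means P2 shares the
derived state with P3, BABA means P1 does;
`D = (nABBA − nBABA) / (nABBA + nBABA)`.  Under lineage sorting alone both
patterns are equally likely and E[D] = 0.

Significance uses a weighted block jackknife over the window table: blocks
are left out one at a time, weighted by their informative-site counts, with
the delete-m(j) variance of Busing et al. (1999); with equal weights this
reduces to the classic delete-one jackknife (both modes are exposed, weighted
is the default).  Blocks with zero informative sites are dropped from M.
|Z| > 3 is flagged significant; an optional Bonferroni column is available in
the CLI for multi-test batches.  An optional chromosome include-list
restricts any test to, e.g., autosomes.

f̂ estimates the admixed genome fraction as a ratio of two pattern
imbalances: the numerator S(P1, P2, P3a, O) measures the focal individual's
excess sharing; the denominator S(P1, P3b, P3a, O) substitutes a second,
unadmixed introgressor individual into the P2 slot and measures the sharing
expected under complete introgression.  The jackknife is applied to the
ratio, with per-block weights equal to the total informative counts of both
configurations.

## Per-block phylogenies

Blocks where any taxon exceeds 50 % missing data are recorded as
insufficient ("X" blocks in the admixture map).  Remaining blocks are recoded
to binary R/Y characters and scored under the symmetric two-state (CFN)
model — stationary frequencies (½, ½), change probability
`(1 − e^(−2t))/2` along a branch of length t — with missing states
marginalized in Felsenstein pruning.  Rate heterogeneity is omitted: at
megabase scale and shallow divergence a gamma shape parameter is essentially
unidentifiable, and the binary model already absorbs the ts/tv distinction
into the recoding.

Because only 4 or 5 taxa are analysed, all unrooted topologies (3 or 15) are
enumerated; heuristic tree search is unnecessary.  Branch lengths are
optimized coordinate-wise under bound constraints ([0, 10]
substitutions/site, initialization 0.1): the site likelihood is *linear* in
`e = exp(−2t)` of any single branch, so two full pruning passes per branch
yield exact profile coefficients, after which the concave 1-D profile is
maximized by ternary search in e-space, vectorized across all windows at
once.  Windows whose round-to-round improvement falls below the tolerance
(default 1e−6; the batched experiments use 1e−3) drop out of subsequent
rounds.  The optimized likelihood never falls below its value at
initialization.  Best and runner-up log-likelihoods within 1e−9 are flagged
as ties and classified "unresolved/other" downstream — ties are never broken
silently.  Trees are reported rooted on the designated outgroup, and the
per-topology log-likelihoods are emitted so users can re-filter by Δ lnL.

## Admixture maps, ILS correction, and dating

Relative to a role assignment (focal, reference, introgressor), each scored
window is categorized by which pair forms a cherry in the rooted tree:
`species` (focal+reference), `admix` (focal+introgressor), `ils_alt`
(reference+introgressor), or `other` (remaining shapes and ties).  Category
fractions are reported over scored windows (they sum to 1); insufficient
windows are reported separately as coverage loss.

Incomplete lineage sorting produces the `admix` and `ils_alt` rooted shapes
at equal frequency (verified by simulation in the acceptance suite), so the
ILS-corrected admixed fraction is the plain excess `f_admix − f_ils_alt`,
floored at zero with a warning — deliberately the observable-frequency
estimator, not a coalescent-model expectation.

Run lengths are maximal strings of consecutive same-category windows within
a chromosome, in bp (terminal windows contribute their true length).  With
bridging enabled, insufficient-data windows flanked on *both* sides by the
category are absorbed (and counted); `other` windows always break runs —
a conservative reading of linking across missing blocks.  Tract-length
ECDFs are compared with the two-sample KS test plus a stochastic-order
verdict: distribution A is called older when its ECDF lies above B's
pointwise within a tolerance (default 0.05) and exceeds it somewhere beyond
that tolerance — an older pulse has been broken up by more generations of
recombination and therefore shows more, smaller blocks.  The package orders
events relatively; it does not convert tract lengths into calendar dates.

## The synthetic-data generator

The generator emulates the statistical structure the analyses assume, not a
full coalescent:

* **Species tree** ((P1, P2), P3-clade), O, with the P3 population
  optionally sampled twice (P3a/P3b).  Split times (generations) default to
  60 k (P1/P2), 100 k (ingroup/P3), 400 k (outgroup), 10 k (within the P3
  clade) — bovid-flavoured shape parameters controlling relative branch
  lengths.
* **ILS** — each window independently draws a genealogy class: concordant
  with probability `1 − (2/3)e^(−tau)`, each discordant class
  `(1/3)e^(−tau)`, with tau the internal branch in coalescent units.  The
  default tau = 0.44 puts ~57 % of windows on the species topology, the
  discordance scale observed in the wisent alignment.  The genealogy is
  constant within a window (blocks are the analysis unit); within-window
  recombination enters only through tract boundaries.
* **Mutation** — infinite-sites style: ancestral base uniform on ACGT; each
  branch substitutes each site with probability `mu × (branch length /
  root-to-tip length)`, so `mu` (default 0.005, bounded below 0.1) is the
  per-site substitution probability per root-to-tip lineage.  A substitution
  is a transition with odds kappa:1 (default 2), else one of the two
  transversions uniformly; with the integer base coding the three targets
  are XOR masks.
* **Admixture pulses** — tract lengths exponential with mean
  `1/(r · t_admix)` bp; tracts are laid down as a stationary Boolean process
  with start intensity `−ln(1 − f) · r · t_admix` per bp, so the *merged*
  coverage probability is exactly f.  The tract count is the rounded
  expected count (largest-remainder allocation across chromosomes) rather
  than a Poisson draw, halving the replicate variance of the realized
  fraction without biasing it.  The donor haplotype is an extra, unsampled
  lineage inside the P3 clade, so tract alleles share the P3 stem but not
  the sampled tips' private mutations — exactly the sharing structure D and
  f̂ assume.  Donors must belong to the P3 clade and recipients to {P1, P2}.
* **Damage and missingness** — on historical individuals each C→T and G→A
  with probability delta (default 0.05); every site of every individual is
  set to N with probability miss (default 0.2).  The two random streams are
  separate, so the missingness pattern at a fixed seed is identical across
  damage settings — this is what makes the bitwise damage-invariance check
  meaningful.
* **Reproducibility** — all randomness derives from one seed via spawned
  child streams; identical configs give bit-identical outputs.

What the generator does *not* model: pedigree relationships, inbreeding/ROH
structure, within-window recombination, sequencing error beyond missingness,
or reference bias.  Passing recovery tests therefore demonstrates the
estimators' correctness under the assumed block/tract structure, not
robustness to every artifact of real historical data.

## Validation experiment sizes

Chosen so each experiment carries genuine statistical power yet the whole
suite runs in minutes on one core; sizes live in
`wisentmix.experiments`:

* **Null calibration** — 100 replicates × 500 windows of 5 kb with
  mu = 0.05: a miniature stand-in for 500 × 1 Mb blocks carrying a realistic
  number of informative sites per block (damage and 20 % missingness
  included).  Checks the |Z| > 3 rate ≤ 2 %.
* **f̂ recovery** — tract physics is pinned by t_admix = 20 generations and
  r = 1e−8 (5 Mb expected tracts), so this experiment keeps real megabase
  coordinates: 12 × 20 Mb chromosomes, 20 replicates per pulse size
  f ∈ {0.05, 0.15, 0.30}; the 20-replicate mean must sit within ±0.05 of f.
  The dominant error source is the replicate-level randomness of the
  realized tract fraction, which is why the deterministic tract count
  matters.
* **Dating order** — 20 seed pairs of 150- vs 20-generation pulses
  (f = 0.15) on a 160 Mb mini-genome with r = 5e−8 and 200 kb windows: a
  five-fold linear shrinkage of a cattle-sized problem that preserves
  expected tract lengths and counts *in window units*, giving the KS test
  enough runs on both sides.  tau = 4 keeps the lineage-sorting background
  low so the quantity being dated — tract length — dominates both run-length
  sets.  The older pulse must win (ECDF above, KS p < 0.05) in ≥ 18/20 pairs.
* **Topology symmetry** — 1,000 windows at tau = 2; the two discordant
  category counts must agree within 3 binomial standard errors.
* **Damage contrast** — one simulation at delta 0 vs 0.1 with identical
  seeds: transversion-mode pattern counts equal bitwise, transitions-included
  D shifts.
* **Oracle equivalences** — the weighted jackknife SE against literal
  leave-one-out enumeration (1e−12), CFN pattern likelihoods summing to 1
  over all complete patterns (1e−10), NJ round-tripping additive 5-taxon
  matrices (1e−9), and windowed divergence against a hand count.

## Numerical and degenerate-input choices

* Zero informative sites: D undefined, reported as NaN; fewer than 2 usable
  jackknife blocks: SE undefined, flagged.  A statistic that is exactly 0
  with exactly identical leave-one-out values reports Z = 0.
* All-constant alignments optimize every topology to identical likelihood at
  zero branch lengths → tie → unresolved.
* KDE requires ≥ 2 finite values; zero-spread inputs fall back to a tiny
  positive bandwidth.
* Large-buffer allocation: the simulator raises glibc's mmap/trim thresholds
  once per process so freed genome-scale buffers are recycled from the heap;
  repeated replicates run several-fold faster and results are unaffected.

## Limitations

Pattern counting assumes genomes are already pseudo-haploid and aligned to
one frame; no BAM ingestion.  The D framework cannot distinguish admixture
from ancestral population structure — a known confound outside this
package's scope.  Dating is relative (older/younger), not absolute.  The ML
block trees support 4 or 5 taxa only, by design: exhaustive enumeration is
the point.
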