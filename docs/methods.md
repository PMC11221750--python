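# Methods

## Scope and model of the data

`admixqc` treats a cohort as phased diploid biallelic genotypes over a
shared marker grid, drawn from two source populations ("olive", code 0,
and "yellow", code 1) and their crosses. Local ancestry is a per-marker,
per-haplotype label; a tract is a maximal run of one label. Internally
tract sets are stored densely as an `int8` array over (sample, haplotype,
marker), which makes the tiling invariant (tracts cover the marker range
without gap or overlap) true by construction; tract tables with 0-based
half-open bp intervals are materialised on demand. VCF and map files are
1-based; the conversion lives only in the I/O layer.

## Differentiation statistics

Per-marker F_ST is the Weir–Cockerham two-population diploid θ computed
from the variance components a, b, c using observed sample sizes, allele
frequencies and heterozygote frequencies per population. Missing genotypes
are removed marker-wise (complete case per population); a marker where
either population retains fewer than two diploids, or where the component
denominator is non-positive (both populations monomorphic for the same
allele), is flagged undefined rather than dropped. The genome-wide
estimate is the ratio of sums Σa / Σ(a+b+c) over defined markers, which is
order-invariant and equals the per-marker estimate for a single marker.
"Fixed" markers are those with observed frequencies exactly 0 and 1 in the
two populations — equivalently θ = 1 with no within-population variance.

## AIM selection

Four stages, all deterministic: (1) retain markers with defined F_ST
strictly greater than 0.8; (2) per 100-kb window anchored at coordinate 0
per chromosome, keep the highest-F_ST marker, ties resolved to the first
marker in input order; (3) LD-prune the kept set separately within each
reference population with window 2, step 1, r² threshold 0.05;
(4) take the union of the two survivor sets and prune once more on the
pooled reference samples. r² is the squared Pearson correlation of diploid
dosages over complete cases, defined as 0 when either marker is
monomorphic. The pruning removal rule — drop the lower-MAF member of a
violating pair, ties to the later-positioned marker, pairs examined in
list order — is declared here rather than bit-matched to any external
tool, whose internal tie handling is undocumented; the exhaustive test
oracle encodes the same declared rule. Window bins are anchored at 0
because nothing in the selection procedure depends on the first marker's
offset.

## Global ancestry

The supervised estimator maximizes the standard two-way admixture
likelihood in which the two allele copies of a genotype are independent
draws from the mixed frequency q·p₀ + (1−q)·p₁. Reference frequencies are
clamped to [1e-4, 1−1e-4] so boundary frequencies cannot produce infinite
log-likelihoods; missing genotypes are skipped per sample. The
log-likelihood is concave in q, so bounded scalar maximization (tolerance
1e-6, with explicit evaluation of the endpoints, which bounded Brent
cannot reach exactly) finds the global optimum; tests verify agreement
with a 1e-4-step grid search to 5e-4. Phase is deliberately ignored
(dosage input) so degraded or unphased data remain usable.

The unsupervised K = 2 fit alternates the per-sample q maximization with
per-marker frequency updates from expected allele counts given q, stopping
when the log-likelihood gain falls below 1e-6 or after 200 iterations
(non-convergence is reported on the result object, never raised). Label
switching is anchored by taxon labels when available, else by the first
sample's majority cluster. A fit is flagged degenerate when the
pseudo-F_ST between the two fitted frequency vectors,
mean[(p₀−p₁)²/(4p̄(1−p̄))], is below 0.1: on a single-population cohort
the K = 2 optimum overfits sampling noise, so the clusters are not
literally identical, but their divergence stays at the order of 1/(2n)
(measured ≈ 0.08 for 10 single-population samples versus ≈ 0.25 for a
genuine two-population cohort at divergence 0.4).

Tract-based global ancestry is the bp-length-weighted share of ancestry-0
tracts over both haplotypes. bp weighting (rather than marker counting)
matches the karyogram reading of a genome; on truth tracts the two
estimators agree within 0.03 in tests.

## Local ancestry HMM

A two-state haplotype HMM stands in for random-forest/CRF local-ancestry
callers: the downstream procedures consume tracts, not caller internals,
and genuine RFMix-v2 `.msp.tsv` output can be read in its place. Emissions
are the population allele frequencies clamped to [ε, 1−ε] with ε = 0.005,
which doubles as an allele-error floor. Between consecutive markers at
genetic distance d Morgans the switch probability is (1 − e^{−g·d}) times
the prior of the target state, with g the generations since admixture
(default 8, near a several-generation colony; the synthetic benchmarks
use the g that generated the data). Decoding is Viterbi per chromosome,
initialised from the prior; missing alleles emit nothing. In the g → 0
limit the chain freezes into one call per chromosome; as g → ∞ it
approaches independent per-marker classification (exact up to emission
ties, which Viterbi breaks toward staying). Per-marker accuracy on the
default synthetic genome (divergence 0.4, g = 2, 5,000 markers per
chromosome) exceeds 98% in the acceptance suite.

## Phase-switch detection and unkinking

A phase switch exchanges the two haplotypes from a boundary to the
chromosome end, so in any sample it appears as simultaneous complementary
ancestry changes on both haplotypes at the same inter-marker boundary.
Detection requires exact boundary coincidence: on a shared marker grid a
phasing error lands on one boundary by construction, and a tolerance
window would risk merging genuine nearby ancestry switches. One-sided
changes are never corrected — they are admixture signal (yellow founders
carrying olive tracts are real). Unkinking scans left to right and swaps
both alleles and ancestry labels from each joint boundary onward; it is
idempotent, preserves the per-marker allele multiset, and leaves
tract-derived global ancestry unchanged (all asserted in tests). With
fully informative tracts, unkinking inverts injected switches exactly and
removes ≥ 90% of joint switches in the synthetic benchmark; with
HMM-estimated tracts at divergence 0.4 the decoded boundary can sit a few
markers off the true one, so exact-boundary detection is partial — the
realistic analogue of the partial reductions reported on real colony data.

## Trio and pedigree audits

The trio rule uses only homozygous-ancestry evidence: a marker is
inconsistent when the offspring carries two copies of ancestry X while
at least one parent carries two copies of Y ≠ X (that parent must
transmit Y). Heterozygous configurations are never flagged, and
mismatched marker grids raise instead of silently intersecting. On truth
tracts the flagged fraction is exactly 0 for every seed; corrupting a
known fraction of offspring calls to homozygous-opposite recovers that
fraction within ±0.01 wherever a parent is informative.

The label audit uses strict inequalities: olive- or yellow-labelled
samples flagged below 90% of their labelled ancestry; cross-labelled
samples flagged above 90% of either ancestry, sub-flagged "pure-like"
above 99%. Crosses genuinely can inherit a near-purebred genome (a
backcross on a short genome occasionally receives all-olive gametes), so
flags are validated against truth ancestry, not against labels.

## Genetic maps

Interval genetic length is (end − start) × rate × 100 cM; cumulative cM is
the running sum from the chromosome's first node, interpolated linearly
between nodes. Gaps in a rate map contribute 0 cM and positions outside
the mapped span clamp to the terminal values, matching common
phasing-tool behaviour; map additivity and monotonicity are property
tests. PLINK (4-column) and SHAPEIT (3-column, headered) dialects
round-trip to 1e-6 cM.

## Synthetic-data generator

The simulator emulates a two-species colony's statistical structure, not
its sequence evolution. Founder frequencies follow the Balding–Nichols
model — each population's frequency is Beta-distributed around an
ancestral frequency uniform on [0.05, 0.95] (bounded away from 0/1 to
keep the Beta parameters non-degenerate) with divergence parameter set to
the target F_ST — plus an explicit fraction of fixed differences (default
0.5%), since real diverged species carry such markers and the AIM
machinery depends on them. Founders are drawn in Hardy–Weinberg
proportions; gametes recombine under the Haldane no-interference model
(Poisson crossover count with mean equal to the chromosome's genetic
length, crossovers uniform on the cM scale), the simplest model
consistent with a rate map. Missingness is genotype-level (both
haplotypes masked jointly), as sequencing dropout manifests in VCFs.
Phase-switch injection exchanges allele sequences *and* truth tracts, so
detection tests have exact ground truth; in rate mode, coincident
even-multiplicity draws cancel and are not reported.

The default desk-scale genome is 4 chromosomes × 50 Mb at 1 cM/Mb with
~5,000 markers per chromosome — small enough for seconds-scale analyses
while leaving hundreds of 100-kb AIM windows per chromosome. What the
generator does not emulate: linkage disequilibrium within the founder
populations (founder alleles are independent across markers given the
frequencies), mutation/drift dynamics, imputation artefacts beyond
missingness, and sex chromosomes. Consequently, passing tests demonstrate
correctness of the estimators under the declared generative model, and
calibration (e.g. AIM-panel fidelity R² ≥ 0.95, supervised MAE ≤ 0.02 at
5,000 markers) under idealised no-background-LD conditions — not
performance on any particular real colony. The per-allele admixed-sample
generator (`simulate_admixed_panel`) is marginal by design and is used
only to calibrate marginal estimators; tract-bearing samples come from
the pedigree simulator.

All randomness flows through `numpy.random.default_rng` seeded per
operation; the pipeline derives per-stage seeds from one master seed, so
identical configurations reproduce outputs byte-identically.

## Numerical choices and limitations

- Frequency clamps: 1e-4 (likelihoods), 0.005 (HMM emissions).
- Optimizer: bounded scalar maximization at xatol 1e-6 plus endpoint
  checks; unsupervised stop at log-likelihood gain < 1e-6.
- Viterbi ties break toward the previous state, then state 0.
- LD pruning and AIM windowing are deterministic by declared tie rules.
- Two populations only; K > 2, D′-based LD, posterior local-ancestry
  probabilities and graphical karyograms are out of scope.
- The generations-since-admixture of a real colony is not estimated; g is
  an explicit parameter of both the simulator and the HMM.
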