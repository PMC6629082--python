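# Methods

This note records the models implemented, the defaults and why, the design
choices made where several conventions exist, and what the synthetic panels
do and do not establish.

## Data model

Genotypes are biallelic SNP calls stored as allele-B dose {0, 1, 2} with −1
for missing. Allele order is whatever the source file used — B is *not*
re-polarised to the minor allele, so frequencies are reported per file
allele and MAF is taken as min(p, 1−p) where needed. Panels are expected to
be heavily selfed (wheat-like): the code never assumes homozygosity, but
several choices below are tuned to it.

## Marker QC

Per locus, missing rate = missing calls / samples, and MAF is allele-count
based over non-missing calls (a heterozygote contributes one copy of each
allele; for an inbred panel this is nearly identical to line-count MAF).
Filters follow strict-inequality reporting conventions: a marker is removed
when missingness **exceeds** the threshold (default 0.25) or MAF is
**below** the threshold (default 0.05); a marker exactly at either boundary
survives. Removal precedence is missingness first, then MAF, which makes
the two removal counts and the retained count sum exactly to the input
count — the additive accounting used in germplasm reports. An all-missing
locus has undefined MAF (flagged, removed under missingness, never silently
treated as MAF 0).

Within-group polymorphism (for the landrace/modern partition) requires both
alleles observed in that group's non-missing calls; a locus fixed for
opposite alleles in the two groups is polymorphic in neither and is
excluded from the union count.

Decay-spaced thinning scans each chromosome left to right in map order
(ties broken by locus id) and keeps a marker only if it lies at least the
chromosome's LD-decay distance beyond the last kept marker — a
deterministic greedy rule that avoids retaining pairs in significant LD.
In the pipeline the per-chromosome distance is the maximum of the era
groups' fitted decays (conservative: spacing safe for both groups), falling
back to 1 cM where a decay could not be fitted.

## Diversity statistics

Gene diversity H = 2pq and Botstein PIC = 2pq(1 − pq) (the factored form of
1 − (p²+q²) − 2p²q²; identical algebraically, numerically stable near
monomorphism). PIC's biallelic maximum is 0.375; the often-quoted "maximum
0.5 for biallelic markers" applies to H, not PIC.

The Nei partition uses the **unweighted** mean of subpopulation frequencies
for p̄ and the unweighted mean of within-group H for H_S (Nei's 1973
convention; a `weights` argument exposes size-weighting). H_T and H_S are
averaged over loci first and D_ST, G_ST, Nm formed from the means — one
value per grouping, matching how such tables are printed — rather than
averaging per-locus ratios. No small-sample (Nei–Chesser) correction is
applied. Groupings are taken over an explicit sample subset so that admixed
accessions (q ≤ 0.5) can be excluded, as is conventional for
"structured genotypes only" tables. G_ST ≤ 0 leaves Nm undefined (NaN),
never a fabricated number.

Per-chromosome/genome summaries treat the analysed panel as one undivided
population (pooled frequencies), the convention of POPGENE-style tables.

## Linkage disequilibrium

Unphased two-locus haplotype frequencies come from EM over the
double-heterozygote ambiguity (≤100 iterations, tolerance 1e−8); with no
double heterozygotes — the overwhelming case in selfed panels — the EM
reduces to exact counting in one step. r² = D²/(pA qA pB qB); pairs with a
locus monomorphic among complete cases are skipped and excluded from means
and percentages.

The "50 cM sliding window" convention is implemented as: evaluate every
intra-chromosomal pair at genetic distance ≤ 50 cM.

Significance uses a two-sided Fisher exact test on integer haplotype
counts (largest-remainder rounding of the EM expectations), with the
chi-square approximation substituted when every cell is ≥ 5 (numerically
indistinguishable there, far cheaper). Counts are scaled to **effective
gametes** n_eff = 2n/(1 + F_IS), with F_IS the panel-wide inbreeding
coefficient (1 − mean H_obs / mean H_exp): in an inbred line the two allele
copies are near-duplicates, and testing on raw 2n copies would roughly
double-count evidence and inflate the type-I rate several-fold (empirically
~1.7% at α = 0.001 on null panels, versus ~0.06% after scaling).

Decay per chromosome: LOESS (locally linear, tricube weights, span 0.5 —
span exposed as a parameter; hyperparameters are a convention choice) of r²
on distance, evaluated on a 0.1 cM grid; the decay distance is the smallest
grid distance where the curve falls to the critical r², defined as the mean
r² over all evaluated pairs of the chromosome's genome. Reported decays are
rounded to whole cM (the precision such tables print). A curve that starts
below the critical value decays at 0; one that never crosses within the
observed range is censored (flagged, not extrapolated). Fewer than 20 pairs
leaves the decay undefined. Whether the tabulated mean r² should cover all
pairs or only significant ones is not standardised; we average all
evaluated pairs.

## Admixture model

The classic admixture model with independent allele frequencies:
P_{lk} ~ Beta(λ, λ) with λ = 1, Q_i ~ Dirichlet(α…α) with a single α
shared across populations (initial 1.0, uniform prior on (0, 10), Gaussian
Metropolis proposals with sd 0.025), and one origin indicator per allele
copy. Missing doses are skipped. Diploid genotypes contribute two copies;
inbred homozygosity needs no special casing (at K = 1 the sampler
short-circuits to the analytic Beta posterior). The correlated-frequencies
prior is not implemented; for ΔK-style model choice the independent prior
is the simpler documented default.

Per run the reported model evidence is STRUCTURE's estimator
lnP(data) = mean(L) − var(L)/2 over the post-burn-in trace of the complete
log-likelihood. Evanno's ΔK = mean|L″(K)|/sd(L(K)) over replicate runs
selects K; ΔK is undefined at the grid endpoints and wherever the replicate
sd is zero. Replicate seeds derive deterministically as
master + 1000·K + rep. Label switching between replicates is resolved by
greedy maximal-correlation column matching to the first run (ties broken by
column index) before averaging Q.

Membership classes use strict inequalities: strong q > 0.7,
moderate 0.5 < q ≤ 0.7, admixed q ≤ 0.5.

The Gibbs sweep is numba-compiled. The per-copy origin draws use an
inlined xorshift64* generator seeded from the run seed (the Beta/Dirichlet
and Metropolis draws stay on numpy's generator); a run is bit-for-bit
reproducible given its seed. Full-scale defaults mirror common practice
(burn-in 10 000, 100 000 iterations, K = 1..10, 7 replicates); the test
suite uses a scaled-down study (150 samples × 300 loci, K = 1..5, 3
replicates, 2000 + 5000 cycles) chosen as the smallest design in which ΔK
model choice is statistically stable.

## Distance, trees, ordination

Simple matching compares genotype **states** (dose 0/1/2), missing excluded
pairwise; distance = 1 − matches/comparable. Pairs with no comparable locus
are an error; fewer than 10 comparable loci is flagged. Neighbour joining
is the classic Saitou–Nei algorithm with deterministic tie-breaking
(lexicographically smallest index pair) and negative branch lengths clamped
to zero with the deficit moved to the sister branch (path lengths between
the joined nodes preserved); the root is the conventional trifurcation of
an unrooted tree. PCoA Gower-centres −D²/2 and eigendecomposes; negative
eigenvalues (simple matching distances need not be Euclidean) are excluded
from variance proportions and reported separately. The "main split" helper
annotates the tree's top-level division as the longest internal edge with
at least 20% of leaves on each side — a reporting convention, not an
inference procedure.

## Synthetic panels

The generator targets the statistics the pipeline estimates, not wheat
biology. Ancestral frequencies p₀ ~ U(0.05, 0.95); subpopulation
frequencies follow the Balding–Nichols F-model
p_k ~ Beta(p₀(1−F)/F, (1−p₀)(1−F)/F); admixture Q ~ Dirichlet(α);
allele copies are drawn from the per-sample mixture frequency; with
probability `selfing_rate` (default 0.98, wheat-like) the second copy
duplicates the first; missing calls are i.i.d. (default 5%, ≤ 25% by
construction). Maps place loci uniformly on the 21 wheat chromosomes
(1A–7D, default 160 cM each). Under this model the expected differentiation
is G_ST ≈ F(K−1)/(K−F), and drift plus the uniform p₀ floor produces a
sub-5% MAF tail so default filters always have work to do.

For LD, the linked-mode generator gives each subpopulation a pool of
founder haplotypes (default 8) drawn from its frequencies; each gamete
walks a chromosome as a founder mosaic, switching founders between adjacent
markers with probability 1 − exp(−c·Δd). This produces r² declining with
cM distance with decay speed governed by c; it is not a coalescent — no
mutation, no selection, no pedigree depth — so absolute decay distances are
not calibrated to wheat history, only the qualitative decay-versus-c
relationship is meaningful.

What passing tests show: the estimators recover the quantities their own
model generates (F-model G_ST, Dirichlet admixture Q, the simulated K,
decay ordering in c, type-I control on null panels). What they do not
show: robustness to ascertainment bias of chip markers, non-equilibrium
demography, linked selection, genotyping-error structure, or map error —
all present in real panels and all outside the generator.

The diversity-recovery check compares the G_ST estimate on near-pure
simulated subpopulations (α = 0.01, 900 samples) against the
differentiation implied by the drawn subpopulation frequencies, within
three locus-bootstrap standard errors; visible admixture attenuates
realized differentiation below the F-model value, which is why near-pure
groups (the analogue of "structured genotypes only" tables) are the right
regime for that comparison, and n = 900 keeps the finite-sample
H_S attenuation (∝ 1/n_k) negligible relative to the Monte-Carlo band.

## Numerical and degenerate-input policy

Frequencies outside [0, 1] raise; all-missing loci propagate as NaN
frequencies and are excluded with a log line, never coerced to 0. Q rows
renormalise within 1e−9 of 1 after every sweep; allele frequencies are
clamped to [1e−12, 1−1e−12] inside the sampler for log-likelihood safety.
LOESS decay grids step 0.1 cM; identical-distance degenerate inputs raise.
Thinning, NJ and column alignment specify deterministic tie-breaks so a
fixed seed reproduces byte-identical outputs; the pipeline additionally
reuses completed-stage artifacts on re-run (sentinel files), so re-running
a finished directory performs no recomputation.

## Known limitations

* Independent-frequency prior only; no LOCPRIOR, no linkage model in the
  sampler, no CLUMPP-style global label optimisation (greedy alignment
  only).
* Nei partition without small-sample bias correction.
* Fisher significance on EM-rounded counts is a pragmatic convention; a
  permutation test would be exact but far more expensive.
* No bootstrap support on trees, no D′, no haplotype blocks, no AMOVA.
* The 557-marker-style "evenly distributed common set" count is
  data-dependent; only the spacing rule is implemented, no target count.
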