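# Methods

This note documents the models implemented in `geotrace`, the design
choices made where the design was genuinely open, what the synthetic
data emulate (and do not), and the package's numerical conventions.

## Genotype model and QC

Genotypes are biallelic alternate-allele dosages g ∈ {0, 1, 2} with
explicit missing calls, read from VCF v4.2 (GT field) via cyvcf2.

Hard site filters are applied as a conjunction, so the retained set is
order-independent; the QC report attributes each removed site to the
*first* failed rule in a fixed order (indel, biallelic, min depth, max
depth, site missingness, quality, MAC) plus an any-rule total. Defaults:
mean depth ≥ 8x and ≤ a species-level cap (35–75x is the usual range
for capture data; default 50x), site missingness ≤ 0.30, quality ≥
Phred 20, minor allele count ≥ 3 (the conventional `--mac 3` reading:
MAC exactly 3 is retained). Individuals with missingness strictly
greater than 0.75 are dropped. Depth and quality are consumed from the
VCF (INFO/MD, QUAL) or a site table; they are never recomputed from
reads — read-level processing is out of scope.

**Tajima's D** is computed per capture locus (sites grouped by contig),
treating each locus as an independent reference sequence; per-site
windows would leave S = 1 everywhere and whole-dataset windows would
mix loci. π accumulates the unbiased per-site pairwise-difference
estimator 2c(m−c)/(m(m−1)) over each site's called chromosomes m; the
normalizing constants use the window's maximum called chromosome count.
Sites on loci with D > 2 or D < −2 form the putatively non-neutral
partition; undefined D (no segregating sites, or fewer than two called
diploids) counts as neutral because such loci carry no selection
evidence. The bounds are exclusive: D = ±2 exactly stays neutral.

**LD pruning** follows the indep-pairwise convention (window 50 SNPs,
step 10, r² > 0.2). r² is the squared Pearson correlation of dosages on
pairwise-complete samples (composite LD — the standard dosage shortcut
when phase is unknown). Within a window, ordered pairs are scanned
greedily; the member with higher missingness is removed, ties removing
the later site. With a window spanning the whole instance the procedure
reduces exactly to the windowless greedy rule, which is how it is
checked against a brute-force oracle.

**Duplicates** are flagged by KING-robust kinship
φ = (N_Aa,Aa − 2·N_AA,aa)/(N_Aa(i)+N_Aa(j)) over jointly called sites;
φ is undefined (NaN) when neither member is heterozygous anywhere.
Pairs with φ > 0.354 (the duplicate/monozygotic-twin threshold, the
midpoint 2^−1.5 between first-degree and self kinship) lose the member
with higher missingness (tie: later sample ID), re-evaluating after
each removal; the procedure is idempotent.

## Population structure

PCA mean-imputes missing dosages per site, centres at 2p and scales by
√(p(1−p)) — the usual genotype normalization — and eigendecomposes via
SVD. Requested axes beyond the matrix rank are truncated with a warning.

Ancestry estimation maximizes the binomial admixture likelihood over
ancestry proportions Q (rows on the simplex) and cluster allele
frequencies F by EM. EM and block-relaxation ascent share the same
stationary points; EM is simpler and adequate at this scale, but
converges slowly near the simplex boundary — parameter-recovery runs
use max_iter in the thousands with a relative tolerance of 1e-8 or
tighter. Frequencies are clamped to [1e-6, 1−1e-6] to avoid log(0).
Initialization draws Q from Dirichlet(1,…,1) and F from perturbed
observed frequencies, all seeded. Missing genotypes drop out of every
sum. Label switching is resolved by greedy matching of F rows on
correlation before any comparison across runs.

K is selected by masked-genotype cross-validation: a random 1/folds
share of called genotypes is hidden, the model refit, and hidden
dosages predicted as 2·QF; the K minimizing mean squared prediction
error across folds and replicates wins. An alternative K-selection
heuristic based on successive differences of a clustering criterion
exists for other programs; it answers a different question and is not
implemented — CV error is the single criterion here.

*Intrinsic accuracy.* At drift F = 0.1 with 1000 loci and 50 samples
per cluster, the fully converged maximum-likelihood Q carries ~0.05–0.07
RMS error against truth; this is a property of the likelihood (joint
estimation of F and Q), not of the optimizer — a supervised oracle with
known labels reaches ~0.023, and the ML error falls as expected with
more loci (≈0.023 at 4000) and stronger drift. Analyses that need Q
accurate to better than ~0.05 at these settings need more loci.

## Isolation by distance vs admixture

Geographic distances are haversine kilometres; genetic distances are
Euclidean distances between dosage vectors on pairwise-complete sites,
rescaled by √(L_total/L_used) so missingness does not shrink them (the
source analyses state only "Euclidean genetic distances derived from
allele frequencies"; this is the standard individual-level reading and
is a documented choice, not an attribution). The Mantel test correlates
upper triangles and permutes rows/columns of one matrix jointly;
p = (#{r_perm ≥ r_obs}+1)/(n_perm+1), one-sided greater because IBD
predicts a positive association. Samples whose coordinates are
untrusted (seizures, long-range markets) are excluded by default.

Triangle analysis: ancestry-informative markers are sites with allele
frequency difference ≥ 0.9 between two explicitly supplied reference
populations, each AIM oriented to the allele commoner in population B.
Hybrid index h is the B-allele fraction over called AIMs; interclass
heterozygosity is the heterozygous fraction. First-generation hybrids
between populations *fixed* at the AIMs sit at (0.5, 1.0) and first
backcrosses at (0.25, 0.5); when AIMs are differentiated but not fixed
(AFD 0.9 means up to 10% shared polymorphism) the expected
heterozygosity of true F1s drops below 1 accordingly. All points obey
het ≤ 2·min(h, 1−h) up to finite-AIM sampling slack ~2/√n_AIMs.

## Geographic assignment

A feed-forward network (default 4 hidden layers × 128 ELU units —
configurable; the desk-scale analyses here use 2 × 32) regresses
per-axis z-scored (longitude, latitude) on encoded dosages: missing
values mean-imputed from the training panel, zero-variance sites
dropped. Training is full-batch Adam on squared Euclidean loss with
inverted dropout (rate 0.25) and early stopping when the loss on a held
10% validation split has not improved for 100 epochs (desk-scale runs
use shorter patience), restoring the best snapshot. All randomness
flows through one seeded generator, so fixed seeds give bit-identical
weights.

The bootstrap ensemble resamples SNP *columns* with replacement —
B = 100 independent retrainings from fresh derived seeds (which unit is
resampled is an open choice in the source analyses; columns are the
cited method's convention). Each query gets a B-point cloud; its
centroid (arithmetic mean of lon/lat — a small-angle approximation,
fine at sub-continental extents) is the point estimate and the mean
haversine distance from cloud to centroid is the *prediction
variability*, a per-query confidence proxy. B = 1 degenerates exactly
to a single deterministic model.

Validation schemes: (i) one-third hold-out — held references are drawn
by largest-remainder allocation over an equal-sized grid over the
reference extent (4 × 4 by default), so the held set totals
round(fraction·n) while spanning the sampled range; singleton bins stay
in training; (ii) LOOCV — one retraining per held reference and no
bootstrap, trading the ensemble for n× compute exactly as the
range-wide studies do; (iii) fraction-within-radius (500 and 1000 km by
default), non-decreasing in the radius by construction. Interval
summaries are empirical 2.5/97.5 percentiles.

Known behaviour: like any squared-loss regressor, the network shrinks
predictions toward the training-coordinate mean where the genotype
signal is weak, which biases recovered trade distances slightly
*downward* (e.g., ~440 km recovered for a planted 500 km displacement
at ~150 km assignment error) and inflates LOOCV error for references in
sparsely sampled regions.

## Trade summaries and hotspots

Trade distance = haversine(seizure/market point, predicted centroid),
summarized per site-type group (n, mean, min, max); queries with no
usable seizure point are counted separately, never silently dropped.
The hotspot surface is a Gaussian product-kernel KDE over all bootstrap
points of all queries, in degree space for comparability with standard
map plots (an equal-area mode can be added trivially since all distance
math is spherical elsewhere). Bandwidth: Scott's rule per axis with a
floor of 0.05°, so a degenerate point cloud yields a finite delta-like
surface; the grid density is renormalized to integrate to 1 over the
evaluation grid within 1e-6.

## Synthetic data: what it emulates, what it does not

The simulator provides the three structures the pipeline must
discriminate, each with an immutable truth block (coordinates, ancestry
vectors, cluster labels, per-locus frequency surfaces):

* **IBD landscape** — per-locus logistic clines
  p_l(x,y) = expit(a_l + b_l·u + c_l·v) over standardized coordinates,
  slopes N(0, cline_strength²). Base frequencies are log-uniform on
  (0.02, 0.5) with random allele orientation, mimicking the 1/x neutral
  site-frequency spectrum so rare variants exist and Tajima's D is not
  artificially inflated; monomorphic draws are rejected (a deliberate
  polymorphism ascertainment, like SNP discovery, which pushes D mildly
  positive together with the spatial Wahlund effect). Logistic clines
  rather than Gaussian random fields: sufficient to induce IBD, cheap,
  and analytically controllable.
* **Discrete clusters** — Balding–Nichols Beta(p(1−F)/F, (1−p)(1−F)/F)
  cluster frequencies around ancestral p ~ U(0.1, 0.9), centers spread
  across the landscape with Gaussian within-cluster scatter (5% of the
  landscape span).
* **Admixture zone** — two parental clusters joined by a sigmoidal
  ancestry cline q(x) over a configurable km width; each allele copy
  picks parental ancestry Bernoulli(q).

Missingness is genotype-wise independent Bernoulli with site-type
rates (field site 0.05, restricted-range market 0.05, long-range market
0.15, seizure 0.20, unknown 0.30 — museum-grade degradation at the
upper end). Trade scenarios displace each chosen query's seizure point
from its true origin along a random bearing by a configurable
great-circle distance (clipped to the landscape and flagged when it
leaves it).

Defaults were fixed once as study conditions: an 18° × 18° landscape
(~2000 × 2000 km near the equator), 1000 loci, cline_strength 2 (strong
range-wide structure), drift F = 0.1, admixture-zone width 300 km. The
effect sizes of the real traded species are not published as simulator
parameters anywhere; these are calibration choices, not estimates.

Not emulated: sequencing reads and depth (missingness is the only
degradation channel), linkage between loci (sites are independent given
the frequency surfaces, so LD pruning on simulated data removes only
chance correlations), genotyping error, mtDNA, and range polygons with
real geography (water, barriers). Passing tests therefore demonstrate
correct statistics and recoverable spatial signal under these
idealizations — not field-accuracy guarantees for any real species.

## Problem sizes used in tests and the acceptance script

Desk-scale sizes chosen as the package's own test conditions: Mantel
calibration 200 null replicates of 50 points at 1000 permutations
(empirical size within [0.03, 0.07] at α = 0.05, KS uniformity on the
p grid); ancestry recovery on 2 × 50 samples × 1000 loci; K selection
on 3 × 25 samples × 300 loci over K ∈ 1..5 with 3 CV folds, 10
replicate selections; assignment recovery 300 training / 100 query
samples × 1000 SNPs with a 2 × 32 network; end-to-end trade scenario
200 samples × 600 SNPs, 40 queries, planted 500 km displacement, B =
100 bootstraps. `scripts/acceptance.py` reruns all of the above from a
single `--seed` in about a minute.
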