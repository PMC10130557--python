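# Methods

`crocokin` couples an individual-based forward simulator with
structure-robust kinship estimation so that close-kin classification can be
calibrated for the data regime typical of wildlife genetics: a few thousand
reduced-representation SNPs, strong spatial population structure, and
samples saturated with relatives.  The motivating system is the saltwater
crocodile (*Crocodylus porosus*): long-lived, age-structured, clutch
breeding, with subpopulations connected by coastal migration.  This note
records the model, the estimators, the numerical conventions, and the
limits of what the synthetic data can show.

## The forward simulator

The simulator is a non-Wright-Fisher model with overlapping generations.
Each time step represents one year and runs, in order:

1. **Reproduction.**  Every female of age ≥ 15 y mates with one uniformly
   chosen male of age ≥ 16 y from her own deme (males may mate multiply).
   She produces one offspring in the *no-clutch* scenario or a
   Poisson(λ = 15) clutch in the *clutch* scenario; all offspring of one
   female in one year share a father.  Offspring sex is 50/50.
2. **Migration.**  Every individual, regardless of age or sex, switches
   deme independently with probability *m* per year.  The default
   topology is the 2-deme island model; a 1-D stepping-stone chain is
   available for isolation-by-distance experiments.
3. **Density-dependent survival.**  Everyone in deme *d* (newborns
   included) survives the year with probability min(1, K/N_d), where N_d
   is the deme census after reproduction and migration.  This is the only
   mortality and the only density regulation.
4. **Aging** by one year.

Survival min(1, K/N) regulates the census at K and fixes the age
structure.  Under single-offspring reproduction the equilibrium annual
survival is ≈0.9, and with K = 1500 per deme the oldest living individual
is typically 50-80+ years old with the population dominated by juveniles —
the demographic signature the model is calibrated to.  Clutch
reproduction (λ = 15) shifts equilibrium survival to ≈0.8 and the maximum
age to ~30 y, and multiplies the standing full-sibling and
aunt/uncle-niece/nephew pair counts by orders of magnitude.

**Genome.**  Finite-sites bi-allelic loci on 17 equal-length,
freely-assorting chromosomes (the *C. porosus* karyotype is 2n = 34) with
Poisson(r·chrom length) crossovers per chromosome per gamete and
infinite-sites mutations at rate Poisson(μ·L) per gamete (μ = 3.5×10⁻⁹/bp,
r = 10⁻⁸/bp, L = 100 Mb by default).  The chromosome count matters: on a
single short chromosome nearly every gamete transmits an intact parental
chromosome, which produces genome-scale identity-by-descent blocks,
occasional fully homozygous individuals, and pervasive pseudo-LD that no
pruning threshold handles sensibly.  Seventeen freely assorting
chromosomes restore realistic Mendelian noise at reduced scale.

**Founders instead of burn-in.**  At full scale the model can be run for
6000 generations from a monomorphic genome.  At desk scale the founders
are seeded directly with standing variation: site frequencies drawn from
the neutral frequency spectrum P(x) ∝ 1/x, and per-deme frequencies drawn
from a Balding-Nichols Beta model around the ancestral frequency with
divergence set to the island-model equilibrium F = 1/(1 + 4K·m_g), where
m_g = min(1, 20m) converts the per-year migration probability to a
per-generation migrant fraction using a ≈20-year generation time.  For the
three migration rates (1%, 0.1%, 0.01%) this spans F ≈ 0.005 → 0.05 → 0.33,
i.e. from no visible deme separation to near-complete separation on the
leading genetic axis.  A further 150 simulated years of drift, migration
and pedigree growth run on top of this initialisation; pedigree truth is
recorded for the final 100 years, with individuals alive at the window
start entered as founders with untracked parents.

**Pedigree truth.**  All unordered pairs of sampled individuals are
labelled POP (parent-offspring), FSP (both parents shared), or
second-degree (DEG2) with subtype HSP (exactly one parent shared), GGP
(grandparent-grandchild) or FTP (full sibling of a parent); everything
else, including pairs with untracked ancestry and all third-degree
relations, is U.  Multi-path relationships (common under inbreeding) take
the closest degree, with fixed precedence POP > FSP > HSP > GGP > FTP.
The vectorised enumeration is verified against an exhaustive
relationship-walking oracle in the tests.

## Kinship estimation

The estimation chain follows the standard workflow for relatedness in
structured populations:

1. **Site filtering.**  Greedy windowed LD pruning on the squared Pearson
   correlation of genotype dosages at r² > 0.1 (the lower-minor-allele-count
   member of an offending pair is dropped; ties drop the later site),
   followed by a MAF ≥ 5% filter.  For empirical panels without genomic
   coordinates the window default is 3000 sites (i.e. all pairs tested);
   for the desk-scale simulations the window is 10 sites (~0.5 Mb), which
   covers the genuine linkage range — founders start in linkage
   equilibrium — while leaving the distance-independent correlations
   created by sampled families alone.
2. **KING-robust** φ̂ = (N_het,het − 2·N_opp-hom)/(N_het,i + N_het,j) over
   jointly observed sites: robust to allele-frequency misspecification
   but biased downward for pairs spanning distinct demes, which is exactly
   the distortion the subsequent steps remove.
3. **Unrelated/related partition with PCs** (the PC-AiR idea).  The
   individual with the most KING-robust kinships above 2^(−11/2) ≈ 0.022
   (third-degree boundary) is moved to the related set (ties: larger
   summed kinship, then lower index) until no pair in the unrelated set
   exceeds the threshold.  PCs come from an SVD of the standardised
   genotypes of the unrelated set; everyone else is projected.  The
   original method's ancestry-divergence weighting is omitted.
4. **PC-Relate.**  Per site, individual-specific allele frequencies
   p̂ = μ̂/2 are predicted for everyone by linearly regressing genotype on
   the PCs over the unrelated (training) set, with predictions clamped
   into (0, 1) (clamps counted and logged).  With q̂ = 1 − p̂ and sites
   masked per pair when either member's individual-specific MAF is below
   0.01 or the genotype is missing:

   - φ̂ = Σ (g_i − 2p̂_i)(g_j − 2p̂_j) / (4 Σ √(p̂_i q̂_i p̂_j q̂_j))
   - k̂2 = Σ h_i h_j / Σ p̂_i q̂_i p̂_j q̂_j with h = p̂², −p̂q̂, q̂² for
     g = 0, 1, 2 (the dominance-coded moment estimator; E[h_i h_j] =
     k2·(p̂q̂)² under the IBD model)
   - k̂0 = observed opposite-homozygote count / Σ (p̂_i²q̂_j² + q̂_i²p̂_j²)

   k̂0 uses the opposite-homozygote ratio for *all* pairs, not only for
   close kin.  A parent-offspring pair cannot produce an opposite
   homozygote, so this estimator pins true POPs at k̂0 ≈ 0 even when φ̂ is
   attenuated (see limitations), whereas substituting 1 − 4φ̂ + k̂2 for
   distant pairs propagates the attenuation into k0 and collapses the
   POP/FSP separation at small population size.  Method-of-moments
   estimates may fall slightly outside [0, 1]; they are reported as-is.

## Classification and scoring

Three classifiers act on (φ̂, k̂0, k̂2):

- **Euclidean nearest center** over POP (0.25, 0, 0), FSP
  (0.25, 0.25, 0.25), 2nd degree (0.125, 0.5, 0), 3rd degree
  (0.063, 0.75, 0), unrelated (0, 1, 0); ties resolve to the closer
  degree; 3rd-degree calls are reported as U.
- **Manichaikul intervals**: degree d when φ̂ ∈ (2^−(d+3/2), 2^−(d+1/2))
  for d = 1, 2, 3 (boundary values join the closer degree; φ̂ above the
  first interval is first degree), with first-degree pairs split into POP
  when k̂0 < 2^(−9/2) ≈ 0.044, FSP otherwise; d = 3 maps to U.
- **Linear SVM** over the same three features, labels {POP, FSP, DEG2, U},
  C = 1, no class weighting, unscaled features.  Multiclass handling is
  one-vs-one voting — the convention of libsvm-style implementations and
  decisive here: one-vs-rest hinge training suppresses the rare POP class
  (~0.3% of pairs) almost completely.  Each binary problem is solved by
  liblinear in the primal, so training is deterministic and handles the
  ~2.5 million desk-scale training pairs in seconds.

Performance is scored from one-vs-rest confusion counts: per-class
precision TP/(TP+FP), recall TP/(TP+FN), specificity TN/(TN+FP), macro
averages, and F1_macro = 2·P_macro·R_macro/(P_macro + R_macro).  Classes
absent from the truth vector are excluded from macro averages (logged);
in no-clutch scenarios FSP is additionally excluded, since true full
siblings are vanishingly rare there and their cluster is not meaningfully
scoreable.

**The simulation study** crosses clutch ∈ {Poisson(15), single offspring}
with m ∈ {1%, 0.1%, 0.01%}.  The desk profile runs 10 replicates per
scenario (K = 250 per deme, 250 sampled per deme — effectively the whole
final census, whose mean is K), trains the SVM on the first 3 replicates
of every scenario pooled, and evaluates all three classifiers on the 42
held-out replicates; the full-scale profile (K = 1500, 6000 generations,
50 replicates, 5 training) is one constructor call away but takes
correspondingly longer.  The desk founder panel is 20,000 SFS-seeded
sites, chosen so clutch-scenario pairs analyse roughly 900-1800
post-filter variants — the scale of the empirical panel (2958 SNPs, 1628
analysed).  The desk study completes in ~5 minutes on one CPU.

## Read-count QC and the filter cascade

The pilot QC operates on two-row reference/alternate tag counts per locus
and individual.  Calls are four-way — AB when both alleles carry ≥ 5% of
an individual's reads at the locus, AA/A0 or BB/B0 when only one allele
is seen, 00 for no reads — because a true homozygote cannot be
distinguished from a heterozygote with a null allele.  Locus filters:
median total depth over likely heterozygotes < 15; heterozygote
allele-balance ratio of median counts outside [0.33, 0.67]; an optional
excess-allele (polyploidy/contamination) flag when third-allele reads
above a count floor (default 3 reads) appear in more than 25% of
individuals at a locus (and symmetrically per individual) — configurable
because the statistic is inherently heuristic.  Individuals are removed
as lower-tail outliers of (heterozygous loci − null loci), with the
original visual inspection replaced by a deterministic median − 3·MAD
rule; a call-based MAF ≥ 2% filter closes the pilot stage.

The main cascade on 0/1/2 genotypes runs, in order: reproducibility
lower-tail outliers (skipped with a warning without scores); call rate
≥ 0.3; minor allele count ≥ 5; mean coverage in [10, 200] (skipped
without counts); one SNP per fragment (highest MAC, ties by position);
Hardy-Weinberg violation in ≥ 3 sampling populations at p < 10⁻³ (1-df
chi-square by default, the conditional exact test as an option);
individual missingness upper-tail outliers (median + 3·MAD); individual
heterozygosity > 0.36; duplicate resolution at ≥ 95% genotype identity
over jointly observed sites, keeping the less-missing member.
Low-heterozygosity individuals are flagged but not removed by default —
the original decision depended on external metadata.  Every step logs a
report row, and removals are conserved: input − Σ removed = output per
axis.  The synthetic read-count generator plants violations of each
filter (low depth, allele imbalance, universal heterozygosity, excess
nulls, duplicated individuals) and records them, so cascade recall is
testable.

## Population-genetic summaries

Per group: observed heterozygosity H_O, unbiased expected heterozygosity
uH_E = 2p̂(1−p̂)·2n/(2n−1) averaged over loci, allelic richness A_r by
hypergeometric rarefaction to the smallest group's allele count, and
F_IS = 1 − H_O/uH_E aggregated over loci (the heterozygosity-based
definition; the variance-components f differs under strong inbreeding),
with 95% locus-bootstrap confidence intervals (200 replicates).
Monomorphic groups report F_IS as missing.

Pairwise differentiation is the Weir & Cockerham (1984) θ from the a, b,
c variance components, aggregated over loci as a ratio of sums; a
brute-force per-locus re-derivation serves as the test oracle to 10⁻¹².
Significance is one-sided by locus bootstrap (fraction of resampled θ ≤ 0,
add-one smoothed; 1000 replicates) with Benjamini-Hochberg FDR control at
5% across pairs.  Slatkin's linearisation θ/(1−θ) feeds the Mantel test:
Pearson r over lower-triangle distances, permutation p-value with
add-one smoothing, deterministic for a fixed seed.

Geographic distance treats the coastline as an ordered lon/lat polyline.
Each point takes the perpendicular foot on its nearest segment in a local
equirectangular frame (longitude scaled by cos of the mean latitude);
between-region distance is the difference in along-coast arc length
(haversine segment lengths, spherical Earth R = 6371 km), while
within-region pairs use the plain great-circle distance.  At the ~10³ km
scale of a coastal study the spherical approximation errs well under 1%.

## What the synthetic data does and does not show

The generator reproduces the features that drive close-kin inference:
overlapping generations with realistic age structure, clutch-induced
sibship inflation, migration-graded population structure, pedigree truth,
and panel sizes in the low thousands of SNPs.  It does **not** model
spatially explicit habitat, age- or size-dependent fecundity, genotyping
error, allelic dropout or missing data (simulated genotypes are complete
— QC behaviour on messy data is exercised by the separate read-count
generator), ascertainment bias of a capture panel, or linkage
disequilibrium inherited from the founder population.  Passing tests
therefore demonstrate correctness of the estimators and the calibration
logic under the stated model, not field performance on raw DArT data.

Reducing the demes from K = 1500 to 250 changes the population, not just
the noise, and two desk-scale artefacts are documented rather than
patched:

- **Baseline relatedness.**  Kinship is always estimated relative to the
  training set.  In a 250-individual clutch-breeding deme (~4 breeding
  females/year) even the "unrelated" partition members are cryptic
  cousins, so φ̂ for true kin is attenuated by the baseline (~0.05-0.07
  at m ≤ 0.1%) and rampant consanguinity creates sibling and
  second-degree pairs whose genotypes are genuinely POP-like (no
  opposite homozygotes).  The SVM parent-offspring false-discovery rate
  in clutch scenarios is therefore ~15-20% at desk scale, versus < 5%
  reported at full scale: the misclassified pairs are real inbred
  relatives, not estimator errors, and no (φ, k0, k2) classifier can
  separate them.
- **Scenario ordering.**  At full scale, clutch scenarios score higher
  F1 than no-clutch; at desk scale the ordering inverts, because the
  clutch scenarios absorb the inbreeding artefacts above while no-clutch
  scenarios stay well calibrated.  Cross-scenario means and the
  between-method ordering (SVM > Manichaikul > Euclidean) are preserved.

## Numerical conventions

Single seeded `numpy` Generator threaded through reproduction → migration
→ survival per year; identical configs give bit-identical pedigrees and
genotypes.  Predicted genotype means clamp to [2ε, 2−2ε], ε = 10⁻⁶.
Pairs with no jointly observed heterozygous sites get missing KING
estimates with a warning.  Sites fixed or lost are compacted away every
25 years and at output, so emitted genotypes cover exactly the currently
polymorphic sites, in position order.  Euclidean ties and Manichaikul
interval endpoints resolve to the closer degree.  MAD-based outlier rules
use a 10⁻¹² floor so constant statistics flag nothing.  All randomised
procedures (bootstraps, permutations, SVM training) accept explicit
seeds and are reproducible.
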