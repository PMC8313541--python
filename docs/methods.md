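# Methods

This note documents the models, estimators, numerical conventions and design
choices behind hybridscope, and what the synthetic-data generator does and
does not establish.

## Coordinates and genotype codes

VCF positions are 1-based; all internal intervals, windows and BED-like
outputs are 0-based half-open. Genotypes are coded 0 (hom-ref), 1 (het),
2 (hom-alt), −1 (missing); only biallelic SNVs are represented. On VCF
ingest the default filters are biallelic SNV, site QUAL ≥ 30, per-sample
DP ≥ 10 (genotype set missing below), heterozygous allele balance in
[0.2, 0.8] — standard GATK-hardened values, all configurable; sites failing
site-level filters are marked non-callable (or dropped on request).

## Genomic distance D

For samples 1 and 2, per compared site with genotypes (g₁, g₂) and
within-individual allele frequencies a = g₁/2, b = g₂/2, the divergence
contribution is a(1−b) + b(1−a): the probability that one allele drawn
with replacement from each diploid differs. π₁ and π₂ are the heterozygous
fractions over the same compared sites, and

D = 1 − (π₁ + π₂) / (4 π₁₂).

Sites missing in either sample are excluded from numerator and denominator
alike; this is what makes the anchors exact: identical genomes give
π₁₂ = π₁/2, hence D = 0, and two unrelated HWE draws from one population
give E[π₁₂] = E[π₁] = E[π₂], hence D = 0.5. Genome-wide D aggregates the π
sums over all compared sites before forming the ratio (not a mean of
window D values). Windows with π₁₂ = 0 are flagged undefined rather than
assigned a number; in the all-pairs distance matrix a pair with compared
sites but zero divergence is a clone-like pair and gets D = 0. Negative D
(legitimately produced by close relatives) is reported raw alongside a
[0, 1]-clamped companion used for MDS.

## IBD classification and relatedness

IBS2/IBS0 are counted per window over non-missing joint genotypes; the
classification rule is exactly IBSR < 0.95 → IBD0; IBSR ≥ 0.95 ∧ D < 0.05 →
IBD2; IBSR ≥ 0.95 ∧ D > 0.05 → IBD1. The rule leaves D exactly 0.05 open;
we assign IBD1, the conservative choice that avoids inflating clone calls.
Windows with fewer than `min_informative` (default 50) IBS2+IBS0 sites, or
with undefined D, are undetermined and excluded from the IBD fractions.
r = ½ IBD1 + IBD2 over classified windows.

Two caveats this machinery inherits from its statistics:

- For a pair of *interspecific hybrids* IBSR is inflated by species-specific
  shared heterozygosity and does not reflect shared haplotypes; diploid r
  between such pairs is not meaningful. Those regions must be compared on
  phased haplotypes (below). The caller supplies the regions/pairs to treat
  this way — hybrid status comes from the ancestry module, matching the
  two-stage workflow.
- The informative-site minimum interacts with marker density: windows in
  which the pair shares a haplotype have IBS0 = 0 and therefore *fewer*
  informative sites, so an aggressive minimum at low density selectively
  discards IBD1/IBD2 windows and biases r down. Choose windows large enough
  that shared windows comfortably clear the minimum (see "scale" below).

## Interspecific phasing and haplotype identity

A hybrid's het site phases when its two alleles are diagnostic of opposite
panels: one present in panel A and absent from panel B (allele count ≤
`tolerance`, default 0) and the other present in B and absent from A.
One-sided evidence is left unresolved — the double requirement makes a
misassignment need two rare events at once, and measured error is ~10⁻³ at
three-exemplar panels with strongly drifted populations, against ~10⁻² for
the one-sided rule. Homozygous sites contribute their allele to both
haplotypes; resolved alleles always sum to the diploid genotype.

Two haplotypes are called identical in a window when disagreements /
pairwise-compared sites < 2×10⁻⁴ (tolerating residual genotyping and
phasing error); zero compared sites → undetermined. When testing whether a
child shares a haplotype with a candidate parent, include that candidate in
its population's panel: every allele the parent transmitted is then present
in the panel, which provably blocks both misassignment conditions and drops
the child-vs-parent mismatch rate to ~0.

## AIMs and the window likelihood

An AIM for target T is a variant homozygous for the diagnostic allele in
every T exemplar and with zero copies of that allele among all other
populations' exemplars; the super-population MM uses the combined MA+MS
exemplars against PU and RK. A site is skipped for target T when any T
exemplar is missing there; missing genotypes among other populations'
exemplars simply contribute no counts (so per-exemplar exclusion masks —
admixed segments — do not erase sites globally). Diagnostic alleles may be
ref or alt.

Local ancestry scores every unordered pair (P, Q) of the four base
populations per window of 500 consecutive AIMs: with m ∈ {0, 1, 2} the
number of haplotype ancestries matching the AIM's target (an MM AIM matches
MA or MS), the diagnostic-allele dosage is modeled Binomial(2, q) with
q = ε + (m/2)(1 − 2ε). The error rate ε (default 0.01) absorbs genotyping
error and residual polymorphism of "fixed" markers; the binomial dosage
form is our reconstruction of the likelihood (validated in tests against an
exhaustive scorer). Windows are non-overlapping runs of 500 AIMs in genome
order, never spanning chromosomes (a deterministic reading of "sliding",
matching block plots; step configurable via the windowing module). A window
is Unknown when any base population has < 5 usable AIMs in it or the
top-two log-likelihood margin is < 2 log-units (ties are never decided by
coin flip). Genome proportions weight each called window ½/½ over its pair
and exclude Unknown windows from the denominator, reporting the Unknown
fraction separately. Segment merging joins consecutive equal calls,
dropping Unknown windows first; runs shorter than `min_windows` are
absorbed when both flanks agree, otherwise discarded.

## Fst, pseudo-diploids, AFS

Fst is the two-level Weir–Cockerham variance-components estimator for
biallelic sites, aggregated ratio-of-sums across sites (the vcftools
"weighted" convention); sites with pbar ∈ {0, 1} or fewer than one genotyped
diploid per group contribute nothing. A second, literal scalar
transcription of the 1984 formulas lives in the test suite as the
independent oracle. Pseudo-diploids sum two caller-paired haplotype vectors
per site (unresolved → missing), enabling Fst on haplotype subsets. The
folded AFS bins minor-allele counts over 2n haplotypes using only sites
with no missing genotype among the chosen samples, minus excluded
intervals.

## Clone collapsing and MDS

Clone groups are single-linkage components of pairs with D < 0.02 ("D ≈ 0"
made operational; configurable), represented by the highest-depth member
(ties: first in sample order). MDS is classical Torgerson scaling: the
input D is treated as the distance and squared during double-centering;
negative eigenvalues (non-Euclidean D) are dropped with a warning; axis
signs are fixed by making each axis's largest-magnitude loading positive,
so results are deterministic.

## The synthetic-data generator

Founders draw per-site allele frequencies from the Balding–Nichols model:
ancestral p ~ Beta(0.5, 0.5) once per site, then population frequency
~ Beta(p(1−F)/F, (1−p)(1−F)/F), giving mean p and variance F p(1−p);
pairwise Fst between two populations is ≈ the mean of their F values.
Default drifts F = 0.89 (RK), 0.45 (MA), 0.53 (MS), 0.75 (PU) reproduce the
citrus anchor differentiations RK–MA ≈ 0.67, RK–PU ≈ 0.82, MS–MA ≈ 0.49.
Genotypes are two independent Bernoulli haplotypes (HWE). Meiosis places
Poisson(1.5)-many uniform crossovers per 30-Mbp chromosome. Clones copy
their source, flipping one allele at Bernoulli-selected sites (somatic
mutation); introgressed genomes overwrite declared segments on haplotype 0
with donor-frequency draws. Every individual carries a per-haplotype
ancestry truth track (segments tile each chromosome exactly once), plus
gamete source tracks recording which parental haplotype each interval
copied — the truth for IBD recovery tests. All randomness flows from one
seed; identical (model, pedigree, seed) is byte-identical.

Default scale is 9 chromosomes × 30 Mbp × ~12,000 segregating sites
(~10⁵ sites), a citrus-like karyotype that builds in under a second.

What the generator does *not* emulate: monomorphic sites (so heterozygosity
here is a fraction of segregating sites, not of callable bp — the 0.2–0.4%
per-bp levels of real resequencing are not reproduced), linkage
disequilibrium within populations (sites are exchangeable given the
frequencies), genotyping error outside the somatic-mutation channel,
coalescent time calibration, and structural variation. A green test
therefore certifies estimator correctness and pedigree/ancestry recovery
under the stated drift model, not robustness to sequencing artifacts.

## Scale choices in tests

Real 46× data carries >10 SNVs per kb, so a 200-kb window holds thousands
of markers; the simulator's default density is ~0.4 sites/kb. Tests
therefore use information-equivalent windows rather than the paper-scale
200 kb wherever window site counts matter: 2 Mb for pairwise D/IBSR
anchors, 1 Mb (with 40k sites/chromosome) for IBD/r recovery, and a dense
single 30-Mbp chromosome (100k sites) for introgression detection, where
the 500-AIM window must be narrow relative to a 2.4-Mbp donor segment.
Haplotype-sharing tests keep 200-kb windows, where what is counted is
crossover breakage, not site abundance. Thresholds (0.95, 0.05, 2×10⁻⁴,
500 AIMs, ≥5 AIMs/population) are never altered.

## Known limitations

- No LD-based statistical phasing; phasing requires differentiated parental
  panels and leaves within-population polymorphism unresolved.
- No HMM smoothing of ancestry calls; `merge_segments` is the deliberate,
  simpler alternative.
- No block-jackknife confidence intervals on Fst.
- Diploid IBD classification is undefined between interspecific hybrid
  pairs (use the phased route).
- r can exceed pedigree expectations' nominal values slightly through
  window-classification granularity; compare against truth-IBD when exact
  recovery matters.
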