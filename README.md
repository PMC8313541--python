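# hybridscope

Population-genomic inference for species complexes shaped by hybridization
and clonal (apomictic) reproduction — the situation found in mandarin-type
citrus, where wild and cultivated diversity decomposes into a few ancestral
populations, fixed F1 hybrid species, half-sib families, clone groups, and
multi-megabase introgressed segments.

Given multi-sample diploid genotypes (VCF) on one reference coordinate
system, the library answers, from genotypes alone:

- *Which accessions are clones of one genotype? Which are pure members of a
  population, and which are hybrids?*
- *Which pairs are parent and offspring, full sibs, or half sibs — and do a
  group of hybrids share a single parent?*
- *Which chromosome segments of each genome descend from which ancestral
  population?*

## The statistics at its core

**Genomic distance.** For two diploids with heterozygosities π₁, π₂
(fraction of compared sites heterozygous) and sequence divergence π₁₂
(probability that one allele drawn from each differs),

```
D = 1 − (π₁ + π₂) / (4 π₁₂)
```

D = 0 for clones, 0.5 for unrelated members of one panmictic population,
→1 for deeply divergent species. Clone groups (D ≈ 0) collapse to one
representative; classical MDS of the D matrix places pure populations at
the corners and F1 hybrids midway between their parents.

**Identity by descent.** Per 200-kb-scale window, IBS2 counts shared
heterozygous joint genotypes (AB|AB) and IBS0 homozygous differences
(AA|BB); the ratio `IBSR = IBS2/(IBS2+IBS0)` is 1 wherever a haplotype is
shared and has mean 2/3 for unrelated panmictic pairs, independent of
allele frequencies. Windows classify as IBD0 (IBSR < 0.95), IBD2
(IBSR ≥ 0.95, D < 0.05) or IBD1 (IBSR ≥ 0.95, D > 0.05), giving the
coefficient of relatedness `r = ½ IBD1 + IBD2` (~1 clones, ~0.5
parent–offspring, ~0.25 half sibs). For pairs of interspecific hybrids —
where species-specific alleles inflate IBSR — haplotypes are first phased
against two parental-population panels, and two haplotypes are called
identical in a window when their mismatch rate is below 2×10⁻⁴.

**Local ancestry.** Ancestry-informative markers (AIMs) are variants fixed
in one population's exemplars and absent from the others' (plus a
super-population MM for markers fixed in the combined mandarin subspecies
relative to the rest). Diploid ancestry is called in 500-AIM windows by a
binomial dosage likelihood over all unordered population pairs, requiring
≥5 AIMs per population, with merged segments and genome-wide admixture
proportions as output.

Also included: Weir–Cockerham Fst (with pseudo-diploids built from
extracted haplotypes), windowed heterozygosity in callable-site windows,
folded allele-frequency spectra, and a pedigree-aware simulator
(Balding–Nichols drift, HWE founders, Poisson recombination, clones with
somatic mutation, introgressed segments) that emits full ground truth so
every stage is testable without any sequencing data.

## Worked example

`examples/05_relatedness_family.py` simulates a half-sib family plus an
interspecific child and prints (abridged):

```
kid1 vs kid1_copy clone pair        (expect r ~ 1.0):  r = 1.00  IBD0/1/2 = 0.00/0.00/1.00
kid1 vs dad       parent-offspring  (expect r ~ 0.5):  r = 0.50  IBD0/1/2 = 0.00/1.00/0.00
kid1 vs kid2      half sibs         (expect r ~ 0.25): r = 0.13  IBD0/1/2 = 0.73/0.27/0.00
kid1-kid2 truth-IBD expectation for this genome: r = 0.15

hyb_kid's mandarin haplotype identical to a paternal haplotype in 99.1% of windows
```

The clone pair is IBD2 everywhere (r = 1); the parent–offspring pair shares
exactly one haplotype in every window (r = 0.5); the half-sib estimate 0.13
tracks the realized sharing of that particular gamete pair (0.15 — on a
3-chromosome toy genome the realized value scatters widely around the 0.25
pedigree expectation); and the interspecific child is linked to its father
by a genome-wide shared haplotype, the signature used to identify a shared
parent behind a whole hybrid family. The other examples cover simulation
(`01`), distances/clones/MDS (`02`), heterozygosity and the folded AFS
(`03`), local ancestry and introgression detection (`04`), and the full
pipeline with manifest and report (`06`).

## Acceptance script

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from a fresh simulation at ~10⁵ sites, the two analytic anchors
of the distance statistic: genome-wide D between a diploid and its exact
copy (clonal pair), and genome-wide D between two unrelated Hardy–Weinberg
founders from one panmictic population. Both are computed by running the
windowed π-aggregation pipeline end to end and written as JSON.
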