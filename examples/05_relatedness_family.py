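"""IBS/IBD relatedness and haplotype sharing in a half-sib family.

IBSR = IBS2/(IBS2+IBS0) is 1 wherever a haplotype is shared; windows are
classified IBD0/1/2 from (IBSR, D) and summarized as r = 1/2 IBD1 + IBD2.
For interspecific hybrids, shared parentage is read instead from phased
haplotypes: a child's mandarin-derived haplotype matches the shared parent
at mismatch rate < 2e-4.
"""

import numpy as np

from hybridscope.genotypes import make_windows
from hybridscope.relatedness import (
    haplotype_identity, interspecific_phase, pair_ibd,
)
from hybridscope.sim import (
    Clone, Cross, Founder, PedigreeSpec, PopulationModel, build_cohort,
    shared_parent_haplotype_fraction,
)

model = PopulationModel(n_chromosomes=3, chrom_length=30_000_000,
                        sites_per_chromosome=40_000)
entries = [Founder("dad", "MA", depth=46.0)]
for i in (1, 2, 3):
    entries += [Founder(f"mom{i}", "MA"), Cross(f"kid{i}", "dad", f"mom{i}")]
entries.append(Clone("kid1_copy", "kid1"))
# panels + an interspecific child for the phasing demonstration
entries += [Founder(f"RK{i}", "RK") for i in (1, 2, 3)]
entries += [Founder(f"MA{i}", "MA") for i in (1, 2, 3)]
entries += [Founder("RKmom", "RK"), Cross("hyb_kid", "RKmom", "dad")]
matrix, truth = build_cohort(model, PedigreeSpec(entries), seed=13)

frame = make_windows(matrix, "bp_span", 1_000_000)
for s1, s2, label in [
    ("kid1", "kid1_copy", "clone pair        (expect r ~ 1.0)"),
    ("kid1", "dad", "parent-offspring  (expect r ~ 0.5)"),
    ("kid1", "kid2", "half sibs         (expect r ~ 0.25)"),
    ("kid1", "mom2", "unrelated         (expect r ~ 0)"),
]:
    res = pair_ibd(matrix, s1, s2, frame)
    print(f"{s1:9s} vs {s2:9s} {label}: "
          f"r = {res.r:.2f}  IBD0/1/2 = {res.ibd0:.2f}/{res.ibd1:.2f}/{res.ibd2:.2f}")

# the half-sib expectation is 0.25 on average, but the realized value varies
# a lot on a 3-chromosome genome; the estimator should track the realized
# (truth) sharing for this particular pair of gametes
truth_r = shared_parent_haplotype_fraction(truth, "kid1", "kid2") / 2
print(f"\nkid1-kid2 truth-IBD expectation for this genome: r = {truth_r:.2f} "
      f"(estimator above should be within ~0.05 of it)")

# interspecific child: phase against the parental panels, then test
# haplotype identity with the father's (truth) haplotypes per 200-kb window
ph = interspecific_phase(matrix, "hyb_kid", [f"RK{i}" for i in (1, 2, 3)],
                         [f"MA{i}" for i in (1, 2, 3)] + ["dad"])
par = truth.haplotypes["dad"]
frame200 = make_windows(matrix, "bp_span", 200_000)
t0 = haplotype_identity(ph.hap_b, np.concatenate([h[0] for h in par]), frame200)
t1 = haplotype_identity(ph.hap_b, np.concatenate([h[1] for h in par]), frame200)
shared = (t0["identical"] | t1["identical"])[t0["defined"] | t1["defined"]]
print(f"\nhyb_kid's mandarin haplotype identical to a paternal haplotype in "
      f"{100 * shared.mean():.1f}% of windows")
print("(a genome-wide shared haplotype is the signature of parentage)")
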