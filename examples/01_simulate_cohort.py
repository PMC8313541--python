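"""Simulate a small multi-population citrus-like cohort and write it to disk.

Builds four differentiated ancestral populations (RK, MA, MS, PU), an
interspecific F1, an apomictic clone and an introgressed genome, then emits
VCF + metadata + truth files.
"""

from pathlib import Path

from hybridscope.sim import (
    Clone, Cross, Founder, Introgressed, PedigreeSpec, PopulationModel,
    build_cohort, emit_dataset,
)

model = PopulationModel(n_chromosomes=3, chrom_length=10_000_000,
                        sites_per_chromosome=5_000)
pedigree = PedigreeSpec([
    Founder("RK1", "RK"), Founder("RK2", "RK"),
    Founder("MA1", "MA", depth=46.0),
    Cross("F1", "RK1", "MA1"),                      # interspecific hybrid
    Clone("F1_clone", "F1", somatic_rate=1e-4),     # apomictic copy
    Introgressed("MA_intro", "MA", "PU",
                 segments=[("chr1", 3_000_000, 5_400_000)]),
])

matrix, truth = build_cohort(model, pedigree, seed=42)
paths = emit_dataset(matrix, truth, Path("scratch/example_cohort"))

print(f"cohort: {matrix.n_samples} samples x {matrix.n_sites} sites")
print(f"wrote: {', '.join(str(p) for p in paths.values())}")
print("\ntruth ancestry of the introgressed genome (one PU block on hap 0):")
print(truth.sample_ancestry("MA_intro").to_string(index=False))
# The PU interval in the truth track is the ground truth the local-ancestry
# module must recover; everything else on both haplotypes is MA.
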