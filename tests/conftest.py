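"""Shared simulated cohorts (session-scoped: each builds in ~1 s and is
reused by unit and acceptance tests)."""

import pytest

from hybridscope.sim import (
    Clone,
    Cross,
    Founder,
    Introgressed,
    PedigreeSpec,
    PopulationModel,
    build_cohort,
)

ALL_POPS = ("RK", "MA", "MS", "PU")


def exemplar_entries(n_per_pop: int = 3):
    return [
        Founder(f"{pop}{i + 1}", pop, depth=30.0 + i)
        for pop in ALL_POPS
        for i in range(n_per_pop)
    ]


def exemplar_map(n_per_pop: int = 3):
    return {pop: [f"{pop}{i + 1}" for i in range(n_per_pop)] for pop in ALL_POPS}


@pytest.fixture(scope="session")
def small_model():
    return PopulationModel(
        n_chromosomes=2, chrom_length=5_000_000, sites_per_chromosome=2_000
    )


@pytest.fixture(scope="session")
def small_cohort(small_model):
    """Tiny mixed cohort for fast unit tests."""
    ped = PedigreeSpec(
        exemplar_entries()
        + [
            Founder("MAx1", "MA"),
            Founder("MAx2", "MA"),
            Founder("RKx", "RK"),
            Cross("F1", "RKx", "MA1"),
            Clone("F1c", "F1"),
            Clone("MAx1c", "MAx1", somatic_rate=2e-3, depth=50.0),
        ]
    )
    return build_cohort(small_model, ped, seed=101)


@pytest.fixture(scope="session")
def panel_cohort():
    """Default-scale cohort: four population panels, an interspecific F1,
    a clone, and an unrelated within-population pair (~1e5 sites)."""
    model = PopulationModel()
    ped = PedigreeSpec(
        exemplar_entries()
        + [
            Founder("U1", "MA"),
            Founder("U2", "MA"),
            Founder("RKx", "RK"),
            Cross("F1", "RKx", "MA1"),
            Clone("U1c", "U1"),
        ]
    )
    matrix, truth = build_cohort(model, ped, seed=202)
    return model, matrix, truth


@pytest.fixture(scope="session")
def family_cohort():
    """Within-population half-sib family at higher marker density: one MA
    father, six MA mothers, six children, one clone of a child."""
    model = PopulationModel(sites_per_chromosome=40_000)
    entries = [Founder("dad", "MA", depth=46.0)]
    for i in range(6):
        entries.append(Founder(f"mom{i + 1}", "MA"))
        entries.append(Cross(f"kid{i + 1}", "dad", f"mom{i + 1}"))
    entries.append(Clone("kid1c", "kid1"))
    matrix, truth = build_cohort(model, PedigreeSpec(entries), seed=5)
    return model, matrix, truth


@pytest.fixture(scope="session")
def hybrid_family_cohort():
    """Interspecific half-sib family emulating a shiikuwasha-like structure:
    one shared mandarin (MA) parent crossed to six distinct RK parents, plus
    RK and MA panels for phasing."""
    model = PopulationModel()
    entries = [Founder("shared_parent", "MA", depth=46.0)]
    for i in range(6):
        entries.append(Founder(f"RKp{i + 1}", "RK"))
        entries.append(Cross(f"SH{i + 1}", f"RKp{i + 1}", "shared_parent"))
    for pop in ("RK", "MA"):
        for i in range(3):
            entries.append(Founder(f"{pop}{i + 1}", pop))
    matrix, truth = build_cohort(model, PedigreeSpec(entries), seed=11)
    return model, matrix, truth


@pytest.fixture(scope="session")
def dense_chrom_cohort():
    """One dense 30-Mbp chromosome (100k sites) with population exemplars and
    a single 2.4-Mbp pummelo segment introgressed into an MA genome."""
    model = PopulationModel(
        n_chromosomes=1, chrom_length=30_000_000, sites_per_chromosome=100_000
    )
    entries = exemplar_entries() + [
        Introgressed("tgt", "MA", "PU", [("chr1", 12_000_000, 14_400_000)]),
        Founder("MAx", "MA"),
    ]
    matrix, truth = build_cohort(model, PedigreeSpec(entries), seed=9)
    return model, matrix, truth


@pytest.fixture(scope="session")
def ancestry_cohort():
    """Nine-chromosome cohort at raised density for local-ancestry recovery:
    exemplars, an RK x MA F1, and pure extra founders."""
    model = PopulationModel(sites_per_chromosome=40_000)
    entries = exemplar_entries() + [
        Founder("RKx", "RK"),
        Cross("F1", "RKx", "MA1"),
        Founder("MAx", "MA"),
        Founder("RKy", "RK"),
    ]
    matrix, truth = build_cohort(model, PedigreeSpec(entries), seed=3)
    return model, matrix, truth
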