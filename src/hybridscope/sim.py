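"""Pedigree-aware diploid population simulator with ground truth.

Generates multi-population genotype cohorts with the structure the analysis
modules assume: differentiated ancestral populations (Balding–Nichols drift
from a shared Beta-distributed ancestral frequency), Hardy–Weinberg founders,
Poisson-recombinant gametes, F1 and backcross hybrids, half-sib families,
apomictic clones with somatic mutations, and multi-megabase introgressed
segments. Every individual carries a per-haplotype ancestry truth track, so
parameter-recovery tests need no external data.

Default scale mirrors a citrus-like genome: 9 chromosomes of 30 Mbp with
~12,000 segregating sites each (~1e5 sites genome-wide). Drift defaults are
calibrated so realized pairwise Weir–Cockerham Fst between founder sets spans
roughly 0.49 (MS–MA) to 0.82 (RK–PU), the differentiation regime of wild
mandarin-type citrus populations.

Coordinates: truth segments are 0-based half-open; VCF positions 1-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genotypes import VariantMatrix, write_matrix

__all__ = [
    "PopulationModel",
    "FrequencyTable",
    "Founder",
    "Cross",
    "Clone",
    "Introgressed",
    "PedigreeSpec",
    "Individual",
    "Gamete",
    "TruthSet",
    "simulate_frequencies",
    "sample_founder",
    "make_gamete",
    "build_cohort",
    "emit_dataset",
    "shared_parent_haplotype_fraction",
]

Segment = tuple[int, int, str]  # (start, end, population), 0-based half-open


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------


@dataclass
class PopulationModel:
    """Ancestral-population model for the Balding–Nichols generator.

    ``drift`` maps each population label to its drift parameter F in (0, 1);
    realized pairwise Fst between two populations is approximately the mean
    of their F values. Defaults reproduce the citrus anchor differentiations
    (RK–MA ~0.67, RK–PU ~0.82, MS–MA ~0.49).
    """

    populations: tuple[str, ...] = ("RK", "MA", "MS", "PU")
    drift: Mapping[str, float] = field(
        default_factory=lambda: {"RK": 0.89, "MA": 0.45, "MS": 0.53, "PU": 0.75}
    )
    ancestral_beta: tuple[float, float] = (0.5, 0.5)
    n_chromosomes: int = 9
    chrom_length: int = 30_000_000
    sites_per_chromosome: int = 12_000
    #: expected crossovers per chromosome per meiosis
    crossover_rate: float = 1.5

    def __post_init__(self) -> None:
        for pop in self.populations:
            if pop not in self.drift:
                raise ValueError(f"no drift parameter for population {pop!r}")
            f = self.drift[pop]
            if not (0.0 < f < 1.0):
                raise ValueError(f"drift F for {pop} must be strictly in (0,1), got {f}")
        if self.n_chromosomes < 1 or self.chrom_length < 2 or self.sites_per_chromosome < 1:
            raise ValueError("degenerate genome dimensions")
        if self.crossover_rate < 0:
            raise ValueError("crossover rate must be non-negative")

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["drift"] = dict(self.drift)
        return d


@dataclass
class FrequencyTable:
    """Per-population alternate-allele frequencies on a shared site list."""

    chromosomes: list[str]
    positions: list[np.ndarray]  # per chromosome, 1-based, strictly increasing
    ancestral: list[np.ndarray]
    freqs: dict[str, list[np.ndarray]]

    @property
    def n_sites(self) -> int:
        return int(sum(p.size for p in self.positions))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c, chrom in enumerate(self.chromosomes):
            df = pd.DataFrame({"chrom": chrom, "pos": self.positions[c],
                               "ancestral": self.ancestral[c]})
            for pop, arrs in self.freqs.items():
                df[pop] = arrs[c]
            rows.append(df)
        return pd.concat(rows, ignore_index=True)


def simulate_frequencies(model: PopulationModel, seed: int) -> FrequencyTable:
    """Draw site positions and per-population allele frequencies.

    For each site an ancestral frequency ``p`` is drawn once from
    Beta(*model.ancestral_beta*); each population's frequency is then drawn
    from Beta(p(1-F)/F, (1-p)(1-F)/F) — the Balding–Nichols model, whose
    frequency distribution has mean ``p`` and variance ``F p (1-p)``.
    Deterministic given (model, seed).
    """
    rng = np.random.default_rng(seed)
    a, b = model.ancestral_beta
    positions, ancestral = [], []
    freqs: dict[str, list[np.ndarray]] = {pop: [] for pop in model.populations}
    for _ in range(model.n_chromosomes):
        pos = np.unique(
            rng.integers(1, model.chrom_length + 1, size=model.sites_per_chromosome)
        )
        p = rng.beta(a, b, size=pos.size)
        p = np.clip(p, 1e-9, 1 - 1e-9)
        positions.append(pos)
        ancestral.append(p)
        for pop in model.populations:
            f = model.drift[pop]
            alpha = p * (1 - f) / f
            beta = (1 - p) * (1 - f) / f
            freqs[pop].append(rng.beta(alpha, beta))
    return FrequencyTable(list(model.chrom_names), positions, ancestral, freqs)


# ---------------------------------------------------------------------------
# Individuals and gametes
# ---------------------------------------------------------------------------


@dataclass
class Individual:
    """A simulated diploid: phased haplotypes plus per-haplotype ancestry."""

    name: str
    role: str
    population: str  # founder population, source's for clones, 'admixed' for crosses
    depth: float
    haplotypes: list[np.ndarray]  # per chromosome, shape (2, m) int8
    ancestry: list[list[list[Segment]]]  # [chrom][hap] -> tiling segments

    def genotype_vector(self) -> np.ndarray:
        return np.concatenate([h[0] + h[1] for h in self.haplotypes]).astype(np.int8)


@dataclass
class Gamete:
    haplotype: list[np.ndarray]  # per chromosome, (m,) int8
    ancestry: list[list[Segment]]
    #: per chromosome: (start, end, parental haplotype index) tiling segments
    sources: list[list[tuple[int, int, int]]]
    crossovers: list[np.ndarray]  # per chromosome, bp positions


def _founder_haplotypes(
    freqs: FrequencyTable, pop: str, rng: np.random.Generator
) -> list[np.ndarray]:
    if pop not in freqs.freqs:
        raise KeyError(f"unknown population {pop!r}")
    haps = []
    for arr in freqs.freqs[pop]:
        haps.append((rng.random((2, arr.size)) < arr).astype(np.int8))
    return haps


def sample_founder(freqs: FrequencyTable, pop: str, seed: int) -> np.ndarray:
    """Draw one founder's diploid genotype vector under HWE.

    Each site's genotype is Binomial(2, p_pop): the sum of two independent
    Bernoulli haplotypes. Returns codes {0,1,2} concatenated in genome order.
    """
    rng = np.random.default_rng(seed)
    haps = _founder_haplotypes(freqs, pop, rng)
    return np.concatenate([h[0] + h[1] for h in haps]).astype(np.int8)


def _splice_segments(segments: list[Segment], start: int, end: int) -> list[Segment]:
    """Restrict a tiling segment list to [start, end)."""
    out = []
    for s, e, lab in segments:
        s2, e2 = max(s, start), min(e, end)
        if s2 < e2:
            out.append((s2, e2, lab))
    return out


def _merge_adjacent(segments: list[Segment]) -> list[Segment]:
    out: list[Segment] = []
    for seg in segments:
        if out and out[-1][2] == seg[2] and out[-1][1] == seg[0]:
            out[-1] = (out[-1][0], seg[1], seg[2])
        else:
            out.append(seg)
    return out


def _gamete_chrom(
    hap_pair: np.ndarray,
    anc_pair: Sequence[list[Segment]],
    positions: np.ndarray,
    length: int,
    rate: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, list[Segment], list[tuple[int, int, int]], np.ndarray]:
    k = rng.poisson(rate)
    xovers = np.sort(rng.integers(1, length, size=k)) if k else np.empty(0, dtype=int)
    cur = int(rng.integers(2))
    bounds = [0, *xovers.tolist(), length]
    gamete = np.empty(positions.size, dtype=np.int8)
    ancestry: list[Segment] = []
    sources: list[tuple[int, int, int]] = []
    for s, e in zip(bounds[:-1], bounds[1:]):
        if s == e:
            continue
        a = np.searchsorted(positions, s + 1, side="left")
        b = np.searchsorted(positions, e, side="right")
        gamete[a:b] = hap_pair[cur, a:b]
        ancestry.extend(_splice_segments(anc_pair[cur], s, e))
        sources.append((s, e, cur))
        cur = 1 - cur
    return gamete, _merge_adjacent(ancestry), sources, xovers


def make_gamete(parent: Individual, model: PopulationModel,
                positions: list[np.ndarray], seed_or_rng) -> Gamete:
    """Meiosis: one recombinant gamete with ancestry and source tracking.

    Crossover count per chromosome is Poisson(*model.crossover_rate*);
    breakpoints are uniform. With rate 0 the gamete is a whole parental
    haplotype.
    """
    rng = (seed_or_rng if isinstance(seed_or_rng, np.random.Generator)
           else np.random.default_rng(seed_or_rng))
    haps, anc, srcs, xos = [], [], [], []
    for c in range(model.n_chromosomes):
        g, a, s, x = _gamete_chrom(
            parent.haplotypes[c], parent.ancestry[c], positions[c],
            model.chrom_length, model.crossover_rate, rng,
        )
        haps.append(g)
        anc.append(a)
        srcs.append(s)
        xos.append(x)
    return Gamete(haps, anc, srcs, xos)


# ---------------------------------------------------------------------------
# Pedigree
# ---------------------------------------------------------------------------


@dataclass
class Founder:
    name: str
    pop: str
    depth: float = 30.0


@dataclass
class Cross:
    """A sexual offspring of two declared parents (F1, backcross, or selfing)."""

    name: str
    parent_a: str
    parent_b: str
    depth: float = 30.0


@dataclass
class Clone:
    """Apomictic/vegetative copy of a declared individual, with optional
    per-site somatic mutation rate (one allele flipped at selected sites)."""

    name: str
    source: str
    somatic_rate: float = 0.0
    depth: float = 30.0


@dataclass
class Introgressed:
    """A founder of ``pop`` carrying donor-population segments on haplotype 0."""

    name: str
    pop: str
    donor: str
    segments: list[tuple[str, int, int]]  # (chrom, start, end), 0-based half-open
    depth: float = 30.0


PedigreeEntry = Founder | Cross | Clone | Introgressed


@dataclass
class PedigreeSpec:
    entries: list[PedigreeEntry]

    def validate(self, model: PopulationModel) -> None:
        if not self.entries:
            raise ValueError("empty pedigree: no individuals declared")
        seen: set[str] = set()
        for e in self.entries:
            if e.name in seen:
                raise ValueError(f"duplicate individual name {e.name!r}")
            if isinstance(e, Founder) and e.pop not in model.populations:
                raise ValueError(f"founder {e.name}: unknown population {e.pop!r}")
            if isinstance(e, Cross):
                for p in (e.parent_a, e.parent_b):
                    if p not in seen:
                        raise ValueError(f"cross {e.name}: parent {p!r} not declared before it")
            if isinstance(e, Clone) and e.source not in seen:
                raise ValueError(f"clone {e.name}: source {e.source!r} not declared before it")
            if isinstance(e, Introgressed):
                if e.pop not in model.populations or e.donor not in model.populations:
                    raise ValueError(f"introgressed {e.name}: unknown population")
                by_chrom: dict[str, list[tuple[int, int]]] = {}
                for chrom, s, t in e.segments:
                    if not (0 <= s < t <= model.chrom_length):
                        raise ValueError(f"introgressed {e.name}: bad segment {chrom}:{s}-{t}")
                    by_chrom.setdefault(chrom, []).append((s, t))
                for chrom, ivs in by_chrom.items():
                    ivs.sort()
                    for (s1, t1), (s2, t2) in zip(ivs[:-1], ivs[1:]):
                        if s2 < t1:
                            raise ValueError(f"introgressed {e.name}: overlapping segments on {chrom}")
            seen.add(e.name)


# ---------------------------------------------------------------------------
# Cohort assembly
# ---------------------------------------------------------------------------


@dataclass
class TruthSet:
    """Ground truth emitted alongside a simulated cohort."""

    ancestry: pd.DataFrame  # chrom, start, end, sample, haplotype, population
    pedigree: pd.DataFrame  # name, role, population, parent_a, parent_b, depth
    frequencies: FrequencyTable
    haplotypes: dict[str, list[np.ndarray]]  # truth phased haplotypes per sample
    gamete_sources: dict[str, dict[str, list[list[tuple[int, int, int]]]]]
    seed: int
    config: dict

    def sample_ancestry(self, sample: str) -> pd.DataFrame:
        return self.ancestry[self.ancestry["sample"] == sample].reset_index(drop=True)


_REF_ALT = np.array([("A", "G"), ("A", "T"), ("A", "C"), ("C", "T"),
                     ("C", "G"), ("C", "A"), ("G", "A"), ("G", "T"),
                     ("T", "C"), ("T", "G"), ("G", "C"), ("T", "A")])


def build_cohort(
    model: PopulationModel, pedigree: PedigreeSpec, seed: int
) -> tuple[VariantMatrix, TruthSet]:
    """Materialize a pedigree into a genotype matrix plus ground truth.

    All randomness flows from ``seed``; identical (model, pedigree, seed)
    yields byte-identical output.
    """
    pedigree.validate(model)
    rng = np.random.default_rng(seed)
    freqs = simulate_frequencies(model, int(rng.integers(2**31)))
    L = model.chrom_length

    individuals: dict[str, Individual] = {}
    gamete_sources: dict[str, dict[str, list[list[tuple[int, int, int]]]]] = {}
    ped_rows = []

    for e in pedigree.entries:
        if isinstance(e, Founder):
            haps = _founder_haplotypes(freqs, e.pop, rng)
            anc = [[[(0, L, e.pop)] for _ in range(2)] for _ in range(model.n_chromosomes)]
            ind = Individual(e.name, "founder", e.pop, e.depth, haps, anc)
            ped_rows.append((e.name, "founder", e.pop, None, None, e.depth))
        elif isinstance(e, Cross):
            pa, pb = individuals[e.parent_a], individuals[e.parent_b]
            ga = make_gamete(pa, model, freqs.positions, rng)
            gb = make_gamete(pb, model, freqs.positions, rng)
            haps = [np.stack([ga.haplotype[c], gb.haplotype[c]])
                    for c in range(model.n_chromosomes)]
            anc = [[ga.ancestry[c], gb.ancestry[c]] for c in range(model.n_chromosomes)]
            ind = Individual(e.name, "cross", "admixed", e.depth, haps, anc)
            gamete_sources[e.name] = {"a": ga.sources, "b": gb.sources}
            ped_rows.append((e.name, "cross", "admixed", e.parent_a, e.parent_b, e.depth))
        elif isinstance(e, Clone):
            src = individuals[e.source]
            haps = [h.copy() for h in src.haplotypes]
            if e.somatic_rate > 0:
                for c in range(model.n_chromosomes):
                    hit = rng.random(haps[c].shape[1]) < e.somatic_rate
                    which = rng.integers(2, size=int(hit.sum()))
                    idx = np.flatnonzero(hit)
                    haps[c][which, idx] = 1 - haps[c][which, idx]
            anc = [[list(a) for a in pair] for pair in
                   [src.ancestry[c] for c in range(model.n_chromosomes)]]
            ind = Individual(e.name, "clone", src.population, e.depth, haps, anc)
            ped_rows.append((e.name, "clone", src.population, e.source, None, e.depth))
        elif isinstance(e, Introgressed):
            haps = _founder_haplotypes(freqs, e.pop, rng)
            anc = [[[(0, L, e.pop)] for _ in range(2)] for _ in range(model.n_chromosomes)]
            chrom_index = {c: i for i, c in enumerate(freqs.chromosomes)}
            for chrom, s, t in e.segments:
                c = chrom_index[chrom]
                pos = freqs.positions[c]
                a = np.searchsorted(pos, s + 1, side="left")
                b = np.searchsorted(pos, t, side="right")
                donor_p = freqs.freqs[e.donor][c][a:b]
                haps[c][0, a:b] = (rng.random(b - a) < donor_p).astype(np.int8)
                base = [seg for seg in anc[c][0]]
                spliced = (_splice_segments(base, 0, s)
                           + [(s, t, e.donor)]
                           + _splice_segments(base, t, L))
                anc[c][0] = _merge_adjacent(sorted(spliced))
            ind = Individual(e.name, "introgressed", e.pop, e.depth, haps, anc)
            ped_rows.append((e.name, "introgressed", e.pop, None, None, e.depth))
        else:  # pragma: no cover
            raise TypeError(f"unknown pedigree entry {e!r}")
        individuals[e.name] = ind

    # --- assemble matrix ---
    names = [e.name for e in pedigree.entries]
    geno = np.stack([individuals[n].genotype_vector() for n in names])
    site_rows = []
    for c, chrom in enumerate(freqs.chromosomes):
        pos = freqs.positions[c]
        alle = _REF_ALT[rng.integers(len(_REF_ALT), size=pos.size)]
        site_rows.append(pd.DataFrame({
            "chrom": chrom, "pos": pos,
            "ref": alle[:, 0], "alt": alle[:, 1], "callable": True,
        }))
    sites = pd.concat(site_rows, ignore_index=True)
    samples = pd.DataFrame({
        "id": names,
        "population": [individuals[n].population for n in names],
        "role": [individuals[n].role for n in names],
        "depth": [individuals[n].depth for n in names],
    })
    matrix = VariantMatrix(sites, geno, samples,
                           chrom_lengths={c: L for c in freqs.chromosomes})

    # --- truth ---
    anc_rows = []
    for n in names:
        ind = individuals[n]
        for c, chrom in enumerate(freqs.chromosomes):
            for h in range(2):
                for s, t, pop in ind.ancestry[c][h]:
                    anc_rows.append((chrom, s, t, n, h, pop))
    ancestry = pd.DataFrame(
        anc_rows, columns=["chrom", "start", "end", "sample", "haplotype", "population"]
    )
    ped_df = pd.DataFrame(
        ped_rows, columns=["name", "role", "population", "parent_a", "parent_b", "depth"]
    )
    truth = TruthSet(
        ancestry=ancestry,
        pedigree=ped_df,
        frequencies=freqs,
        haplotypes={n: individuals[n].haplotypes for n in names},
        gamete_sources=gamete_sources,
        seed=seed,
        config={"model": model.to_dict(),
                "pedigree": [f"{type(e).__name__}:{e.name}" for e in pedigree.entries],
                "seed": seed},
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# Emission and truth helpers
# ---------------------------------------------------------------------------


def emit_dataset(matrix: VariantMatrix, truth: TruthSet, out_dir: str | Path) -> dict[str, Path]:
    """Write VCF + metadata + truth files; returns the path of each artifact.

    Truth ancestry intervals are BED-convention: 0-based, half-open starts.
    """
    import yaml

    if matrix.n_samples == 0:
        raise ValueError("refusing to emit a dataset with zero samples")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out / "cohort.vcf",
        "samples": out / "samples.tsv",
        "truth_ancestry": out / "truth_ancestry.bed",
        "frequencies": out / "truth_frequencies.tsv",
        "config": out / "config.yaml",
    }
    try:
        write_matrix(matrix, paths["vcf"])
        meta = matrix.samples.rename(columns={"id": "sample", "depth": "depth_proxy"})
        meta.to_csv(paths["samples"], sep="\t", index=False)
        truth.ancestry.to_csv(paths["truth_ancestry"], sep="\t", index=False, header=False)
        truth.frequencies.to_frame().to_csv(paths["frequencies"], sep="\t", index=False)
        with open(paths["config"], "w") as fh:
            yaml.safe_dump(truth.config, fh, sort_keys=False)
    except OSError as err:
        raise OSError(f"failed writing dataset under {out}: {err}") from err
    return paths


def shared_parent_haplotype_fraction(truth: TruthSet, child1: str, child2: str,
                                     which: str = "a") -> float:
    """Genome fraction where two siblings' gametes from the shared parent copied
    the same parental haplotype (the truth IBD1 fraction; ~1/2 for half-sibs)."""
    s1 = truth.gamete_sources[child1][which]
    s2 = truth.gamete_sources[child2][which]
    shared = total = 0
    for segs1, segs2 in zip(s1, s2):
        for a_start, a_end, ha in segs1:
            for b_start, b_end, hb in segs2:
                lo, hi = max(a_start, b_start), min(a_end, b_end)
                if lo < hi:
                    total += hi - lo
                    if ha == hb:
                        shared += hi - lo
    return shared / total if total else float("nan")
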