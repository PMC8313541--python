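"""Ancestry-informative markers and likelihood-based local ancestry.

An AIM for target population T is a biallelic variant whose diagnostic
allele is fixed (homozygous) in every T exemplar and absent from every other
population's exemplars. Because the two mandarin subspecies MA and MS are
only weakly differentiated relative to the other pairs, a super-population
``MM`` collects markers fixed in the combined MA+MS exemplars relative to PU
and RK.

Local ancestry is called in windows of 500 consecutive AIMs. For each
unordered ancestry pair (P, Q) from the base populations (including P = Q),
the window log-likelihood sums over its AIMs the binomial probability of the
observed diagnostic-allele dosage g in {0,1,2}: with m in {0,1,2} the number
of the two haplotype ancestries matching the AIM's target (an MM AIM matches
either MA or MS), the expected diagnostic-allele frequency is

    q = eps + (m/2) * (1 - 2*eps),        g ~ Binomial(2, q)

where ``eps`` absorbs genotyping error and residual polymorphism. The call
is the argmax pair; a window is Unknown when any base population has fewer
than 5 AIMs in it, or when the top-two log-likelihood margin is below the
configured threshold (ties never decided by coin flip).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genotypes import VariantMatrix, MISSING

__all__ = [
    "AIMSet",
    "AncestryTrack",
    "derive_aims",
    "window_ancestry",
    "merge_segments",
    "BASE_POPULATIONS",
    "SUPER_POPULATION",
]

BASE_POPULATIONS = ("PU", "RK", "MA", "MS")
SUPER_POPULATION = "MM"
#: the MM super-population matches either of these targets in the likelihood
SUPER_MEMBERS = ("MA", "MS")


@dataclass
class AIMSet:
    """Diagnostic markers per target population.

    ``table`` columns: site (index into the matrix), chrom, pos, target,
    allele ('ref' or 'alt' — the diagnostic allele).
    """

    table: pd.DataFrame
    exemplars: dict[str, list[str]]

    def counts(self) -> pd.Series:
        return self.table["target"].value_counts()

    def for_target(self, target: str) -> pd.DataFrame:
        return self.table[self.table["target"] == target]

    @property
    def site_indices(self) -> np.ndarray:
        """Sorted unique site indices carrying at least one AIM."""
        return np.unique(self.table["site"].to_numpy())


@dataclass
class AncestryTrack:
    """Per-window diploid ancestry calls for one sample.

    ``table`` columns: chrom, start, end, n_aims, per-population AIM counts
    (``n_<pop>``), call ('P/Q' with P<=Q alphabetically, or 'Unknown'),
    margin (top-two log-likelihood gap). ``proportions`` are
    haplotype-weighted over classified windows; Unknown is reported as the
    fraction of all windows left uncalled.
    """

    sample: str
    table: pd.DataFrame
    proportions: dict[str, float]
    unknown_fraction: float


# ---------------------------------------------------------------------------
# AIM derivation
# ---------------------------------------------------------------------------


def _interval_mask(matrix: VariantMatrix,
                   intervals: Iterable[tuple[str, int, int]]) -> np.ndarray:
    mask = np.zeros(matrix.n_sites, dtype=bool)
    chrom_arr = matrix.sites["chrom"].to_numpy()
    pos0 = matrix.sites["pos"].to_numpy() - 1
    for chrom, s, t in intervals:
        mask |= (chrom_arr == chrom) & (pos0 >= s) & (pos0 < t)
    return mask


def derive_aims(
    matrix: VariantMatrix,
    exemplar_map: Mapping[str, Sequence[str]],
    exclusions: Mapping[str, Iterable[tuple[str, int, int]]] | None = None,
    base_populations: Sequence[str] = BASE_POPULATIONS,
) -> AIMSet:
    """Derive per-population AIMs (and the MM super-population) from exemplars.

    ``exemplar_map`` maps each base population to its exemplar sample ids;
    ``exclusions`` optionally masks per-exemplar intervals (admixed segments),
    treating their genotypes as missing. For a target T a site is usable only
    if no T exemplar is missing there; missing genotypes among the other
    populations' exemplars simply contribute no allele observations.
    """
    for pop in base_populations:
        if pop not in exemplar_map or not len(exemplar_map[pop]):
            raise ValueError(f"population {pop!r} has no exemplars")

    geno: dict[str, np.ndarray] = {}
    for pop in base_populations:
        g = np.stack(
            [matrix.genotype_vector(s) for s in exemplar_map[pop]]
        ).astype(np.int16)
        if exclusions:
            for i, s in enumerate(exemplar_map[pop]):
                name = s if isinstance(s, str) else matrix.sample_ids[s]
                if name in exclusions:
                    g[i, _interval_mask(matrix, exclusions[name])] = MISSING
        geno[pop] = g

    callable_ = matrix.callable_mask

    def group_stats(g: np.ndarray):
        present = g != MISSING
        any_missing = ~present.all(axis=0)
        alt_count = np.where(present, g, 0).sum(axis=0)
        ref_count = np.where(present, 2 - g, 0).sum(axis=0)
        all_hom_alt = present.all(axis=0) & (g == 2).all(axis=0)
        all_hom_ref = present.all(axis=0) & (g == 0).all(axis=0)
        return any_missing, alt_count, ref_count, all_hom_alt, all_hom_ref

    stats = {pop: group_stats(geno[pop]) for pop in base_populations}
    combined = np.concatenate([geno[p] for p in SUPER_MEMBERS], axis=0)
    targets: dict[str, tuple] = {pop: (stats[pop], [p for p in base_populations if p != pop])
                                 for pop in base_populations}
    targets[SUPER_POPULATION] = (
        group_stats(combined),
        [p for p in base_populations if p not in SUPER_MEMBERS],
    )

    records = []
    chroms = matrix.sites["chrom"].to_numpy()
    pos = matrix.sites["pos"].to_numpy()
    for target, ((any_missing, _, _, hom_alt, hom_ref), others) in targets.items():
        other_alt = sum(stats[p][1] for p in others)
        other_ref = sum(stats[p][2] for p in others)
        alt_aim = callable_ & ~any_missing & hom_alt & (other_alt == 0)
        ref_aim = callable_ & ~any_missing & hom_ref & (other_ref == 0)
        for allele, mask in (("alt", alt_aim), ("ref", ref_aim)):
            idx = np.flatnonzero(mask)
            for j in idx:
                records.append((int(j), chroms[j], int(pos[j]), target, allele))

    table = pd.DataFrame(records, columns=["site", "chrom", "pos", "target", "allele"])
    table = table.sort_values(["site", "target"]).reset_index(drop=True)
    exem = {p: [s if isinstance(s, str) else matrix.sample_ids[s]
                for s in exemplar_map[p]] for p in base_populations}
    return AIMSet(table=table, exemplars=exem)


# ---------------------------------------------------------------------------
# Window likelihood
# ---------------------------------------------------------------------------


def _pair_label(p: str, q: str) -> str:
    return "/".join(sorted((p, q)))


def window_ancestry(
    matrix: VariantMatrix,
    sample: str | int,
    aimset: AIMSet,
    window_size: int = 500,
    epsilon: float = 0.01,
    min_aims_per_pop: int = 5,
    margin_threshold: float = 2.0,
    base_populations: Sequence[str] = BASE_POPULATIONS,
) -> AncestryTrack:
    """Likelihood-based local ancestry for one sample in AIM-count windows.

    See the module docstring for the dosage model. Windows failing the
    per-population AIM-count rule (>= ``min_aims_per_pop`` for every base
    population) or with top-two margin below ``margin_threshold`` log-units
    are Unknown.
    """
    if not (0.0 < epsilon < 0.5):
        raise ValueError("epsilon must lie strictly in (0, 0.5)")
    pops = list(base_populations)
    pairs = [tuple(sorted(pq)) for pq in
             itertools.combinations_with_replacement(pops, 2)]

    aims = aimset.table.sort_values(["site"]).reset_index(drop=True)
    sites = aims["site"].to_numpy()
    target = aims["target"].to_numpy()
    diag_alt = (aims["allele"] == "alt").to_numpy()

    g = matrix.genotype_vector(sample)
    g_at = g[sites].astype(np.int16)
    dosage = np.where(diag_alt, g_at, 2 - g_at)
    usable = g_at != MISSING

    # match count m for every (AIM target, pair) combination
    def matches(t: str, pair: tuple[str, str]) -> int:
        if t == SUPER_POPULATION:
            return sum(q in SUPER_MEMBERS for q in pair)
        return sum(q == t for q in pair)

    target_names = list(dict.fromkeys(target))
    m_table = {(t, pair): matches(t, pair) for t in target_names for pair in pairs}
    logq = {}
    for m in (0, 1, 2):
        q = epsilon + (m / 2.0) * (1.0 - 2.0 * epsilon)
        # log P(g | q) for g = 0,1,2 under Binomial(2, q)
        logq[m] = np.array([2 * np.log1p(-q), np.log(2 * q * (1 - q)), 2 * np.log(q)])

    chroms = matrix.sites["chrom"].to_numpy()
    pos = matrix.sites["pos"].to_numpy()
    site_chrom = chroms[sites]

    rows = []
    n = len(aims)
    start_idx = 0
    while start_idx < n:
        # windows never span chromosomes
        chrom = site_chrom[start_idx]
        chrom_end = start_idx
        while chrom_end < n and site_chrom[chrom_end] == chrom:
            chrom_end += 1
        for a in range(start_idx, chrom_end, window_size):
            b = min(a + window_size, chrom_end)
            w_target = target[a:b]
            w_dosage = dosage[a:b]
            w_usable = usable[a:b]
            pop_counts = {p: int(((w_target == p) & w_usable).sum()) for p in pops}
            n_aims = int(w_usable.sum())
            first, last = sites[a], sites[b - 1]
            w_start, w_end = int(pos[first]) - 1, int(pos[last])
            counts_ok = all(pop_counts[p] >= min_aims_per_pop for p in pops)
            call, margin = "Unknown", float("nan")
            if counts_ok and n_aims:
                scores = []
                for pair in pairs:
                    ll = 0.0
                    for t in target_names:
                        sel = (w_target == t) & w_usable
                        if not sel.any():
                            continue
                        ll += logq[m_table[(t, pair)]][w_dosage[sel]].sum()
                    scores.append(ll)
                order = np.argsort(scores)[::-1]
                margin = float(scores[order[0]] - scores[order[1]])
                if margin >= margin_threshold:
                    call = _pair_label(*pairs[order[0]])
            rows.append((chrom, w_start, w_end, n_aims,
                         *[pop_counts[p] for p in pops], call, margin))
        start_idx = chrom_end

    cols = ["chrom", "start", "end", "n_aims", *[f"n_{p}" for p in pops],
            "call", "margin"]
    table = pd.DataFrame(rows, columns=cols)

    called = table[table["call"] != "Unknown"]
    weights: dict[str, float] = {p: 0.0 for p in pops}
    for call in called["call"]:
        p, q = call.split("/")
        weights[p] += 0.5
        weights[q] += 0.5
    tot = sum(weights.values())
    proportions = {p: (w / tot if tot else float("nan")) for p, w in weights.items()}
    unknown_fraction = 1.0 - len(called) / len(table) if len(table) else float("nan")
    name = sample if isinstance(sample, str) else str(matrix.sample_ids[sample])
    return AncestryTrack(name, table, proportions, unknown_fraction)


# ---------------------------------------------------------------------------
# Segment merging
# ---------------------------------------------------------------------------


def merge_segments(track: AncestryTrack, min_windows: int = 2) -> pd.DataFrame:
    """Merge consecutive same-call windows into ancestry segments.

    Unknown windows are dropped before merging (they neither break nor join
    runs). Runs shorter than ``min_windows`` are absorbed into the flanking
    call when both flanks agree, otherwise discarded as Unknown. Returns a
    segment table (chrom, start, end, call, n_windows) in bp coordinates.
    """
    segs: list[list] = []  # [chrom, start, end, call, n_windows]
    out: list[list] = []
    for chrom, grp in track.table.groupby("chrom", sort=False):
        grp = grp[grp["call"] != "Unknown"]
        runs: list[list] = []
        for _, row in grp.iterrows():
            if runs and runs[-1][3] == row["call"]:
                runs[-1][2] = int(row["end"])
                runs[-1][4] += 1
            else:
                runs.append([chrom, int(row["start"]), int(row["end"]),
                             row["call"], 1])
        # phase 1: absorb short interior runs whose flanks agree
        changed = True
        while changed:
            changed = False
            for i in range(1, len(runs) - 1):
                if runs[i][4] < min_windows and runs[i - 1][3] == runs[i + 1][3]:
                    runs[i - 1][2] = runs[i + 1][2]
                    runs[i - 1][4] += runs[i][4] + runs[i + 1][4]
                    del runs[i:i + 2]
                    changed = True
                    break
        # phase 2: remaining short runs become Unknown (discarded)
        out.extend(r for r in runs if r[4] >= min_windows)
    return pd.DataFrame(out, columns=["chrom", "start", "end", "call", "n_windows"])
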