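"""Heterozygosity, pairwise genomic distance D, Weir–Cockerham Fst, folded AFS.

The central statistic is the genomic distance between two diploids::

    D = 1 - (pi1 + pi2) / (4 * pi12)

where ``pi1`` and ``pi2`` are the two samples' heterozygosities (fraction of
compared callable sites that are heterozygous) and ``pi12`` is their sequence
divergence: the probability that one allele drawn at random from each diploid
differs. D = 0 for clones, 0.5 for unrelated members of one panmictic
population, and approaches 1 for deeply divergent species.

Per site with genotypes (g1, g2) and within-sample allele frequencies
a = g1/2, b = g2/2, the pi12 contribution is ``a(1-b) + b(1-a)`` (alleles
drawn with replacement across individuals). Sites missing in either sample
are excluded from pi1, pi2 and pi12 alike, which is what makes the clone
(D=0) and panmictic (D=0.5) anchors hold exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genotypes import VariantMatrix, WindowFrame, MISSING

__all__ = [
    "PairDiversity",
    "AFS",
    "heterozygosity_windows",
    "pair_pi",
    "genomic_distance",
    "fst_wc",
    "pseudo_diploid",
    "folded_afs",
]


@dataclass
class PairDiversity:
    """Per-window diversity components for one sample pair.

    ``table`` columns: chrom, start, end, n_used, pi1, pi2, pi12, D,
    D_clamped, defined. Genome-wide values are ratio-of-sums aggregates over
    all compared sites, not means of window values.
    """

    sample1: str
    sample2: str
    table: pd.DataFrame
    genome_pi1: float
    genome_pi2: float
    genome_pi12: float
    n_used: int

    @property
    def genome_D(self) -> float:
        if self.genome_pi12 <= 0:
            return float("nan")
        return 1.0 - (self.genome_pi1 + self.genome_pi2) / (4.0 * self.genome_pi12)

    @property
    def genome_D_clamped(self) -> float:
        d = self.genome_D
        return float(np.clip(d, 0.0, 1.0)) if np.isfinite(d) else d


@dataclass
class AFS:
    """Folded minor-allele count spectrum over 2n haplotypes."""

    counts: np.ndarray  # index 0 .. n_hap//2
    n_hap: int
    n_sites: int

    def normalized(self) -> np.ndarray:
        tot = self.counts.sum()
        return self.counts / tot if tot else self.counts.astype(float)


# ---------------------------------------------------------------------------
# Heterozygosity
# ---------------------------------------------------------------------------


def heterozygosity_windows(
    matrix: VariantMatrix, sample: str | int, frame: WindowFrame
) -> pd.DataFrame:
    """Windowed heterozygosity: het callable sites / non-missing callable sites.

    Missing genotypes are excluded from numerator and denominator. Windows
    with no usable sites get NaN and ``defined=False`` rather than zero.
    """
    g = matrix.genotype_vector(sample)
    callable_ = matrix.callable_mask
    rows = []
    for chrom, start, end, mem in frame:
        gm = g[mem]
        ok = callable_[mem] & (gm != MISSING)
        n = int(ok.sum())
        het = float((gm[ok] == 1).sum() / n) if n else float("nan")
        rows.append((chrom, start, end, n, het, n > 0))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_callable", "het", "defined"])


# ---------------------------------------------------------------------------
# Pairwise D
# ---------------------------------------------------------------------------


def _pair_site_components(
    matrix: VariantMatrix, s1: str | int, s2: str | int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-site (used, het1, het2, cross) arrays for one pair."""
    g1 = matrix.genotype_vector(s1).astype(np.float64)
    g2 = matrix.genotype_vector(s2).astype(np.float64)
    used = (
        matrix.callable_mask
        & (matrix.genotype_vector(s1) != MISSING)
        & (matrix.genotype_vector(s2) != MISSING)
    )
    a, b = g1 / 2.0, g2 / 2.0
    cross = a * (1 - b) + b * (1 - a)
    return used, (g1 == 1), (g2 == 1), cross


def pair_pi(
    matrix: VariantMatrix, s1: str | int, s2: str | int, frame: WindowFrame
) -> PairDiversity:
    """Windowed pi1, pi2, pi12 and D for one sample pair (see module docstring)."""
    used, het1, het2, cross = _pair_site_components(matrix, s1, s2)
    rows = []
    tot_n = tot_h1 = tot_h2 = tot_x = 0.0
    for chrom, start, end, mem in frame:
        u = mem[used[mem]]
        n = u.size
        if n == 0:
            rows.append((chrom, start, end, 0, np.nan, np.nan, np.nan, np.nan, np.nan, False))
            continue
        p1 = float(het1[u].sum() / n)
        p2 = float(het2[u].sum() / n)
        p12 = float(cross[u].sum() / n)
        if p12 > 0:
            d = 1.0 - (p1 + p2) / (4.0 * p12)
            rows.append((chrom, start, end, n, p1, p2, p12, d,
                         float(np.clip(d, 0, 1)), True))
        else:
            rows.append((chrom, start, end, n, p1, p2, p12, np.nan, np.nan, False))
        tot_n += n
        tot_h1 += het1[u].sum()
        tot_h2 += het2[u].sum()
        tot_x += cross[u].sum()
    table = pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "n_used", "pi1", "pi2", "pi12",
                 "D", "D_clamped", "defined"],
    )
    name = lambda s: s if isinstance(s, str) else str(matrix.sample_ids[s])
    return PairDiversity(
        sample1=name(s1), sample2=name(s2), table=table,
        genome_pi1=tot_h1 / tot_n if tot_n else float("nan"),
        genome_pi2=tot_h2 / tot_n if tot_n else float("nan"),
        genome_pi12=tot_x / tot_n if tot_n else float("nan"),
        n_used=int(tot_n),
    )


def genomic_distance(pd_result: PairDiversity) -> float:
    """Genome-wide D from aggregated pi components (NaN where pi12 = 0)."""
    return pd_result.genome_D


# ---------------------------------------------------------------------------
# Weir–Cockerham Fst
# ---------------------------------------------------------------------------


def fst_wc(
    matrix: VariantMatrix,
    samples_a: Sequence[str | int],
    samples_b: Sequence[str | int],
    return_components: bool = False,
):
    """Weir–Cockerham Fst between two diploid sample groups.

    Two-level variance-components estimator for biallelic sites, aggregated
    as a ratio of sums across sites (the vcftools "weighted" convention).
    Sites monomorphic across both groups, or with fewer than one genotyped
    diploid in either group, contribute nothing. Returns NaN when no site is
    informative.
    """
    ga = np.stack([matrix.genotype_vector(s) for s in samples_a]).astype(float)
    gb = np.stack([matrix.genotype_vector(s) for s in samples_b]).astype(float)
    ga[ga == MISSING] = np.nan
    gb[gb == MISSING] = np.nan
    keep = matrix.callable_mask
    ga, gb = ga[:, keep], gb[:, keep]

    n1 = np.sum(~np.isnan(ga), axis=0).astype(float)  # diploids genotyped
    n2 = np.sum(~np.isnan(gb), axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = np.nansum(ga, axis=0) / (2 * n1)
        p2 = np.nansum(gb, axis=0) / (2 * n2)
        h1 = np.nansum(ga == 1, axis=0) / n1
        h2 = np.nansum(gb == 1, axis=0) / n2

        r = 2.0
        nbar = (n1 + n2) / r
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)

        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2

    valid = (n1 > 0) & (n2 > 0) & (nbar > 1) & (nc > 0)
    poly = valid & ~((pbar <= 0) | (pbar >= 1))
    num = np.where(poly, a, 0.0)
    den = np.where(poly, a + b + c, 0.0)
    if den.sum() == 0:
        fst = float("nan")
    else:
        fst = float(num.sum() / den.sum())
    if return_components:
        comp = pd.DataFrame({"a": np.where(poly, a, np.nan),
                             "b": np.where(poly, b, np.nan),
                             "c": np.where(poly, c, np.nan),
                             "used": poly})
        return fst, comp
    return fst


# ---------------------------------------------------------------------------
# Pseudo-diploids
# ---------------------------------------------------------------------------


def pseudo_diploid(
    matrix: VariantMatrix,
    haplotype_pairs: Sequence[tuple[np.ndarray, np.ndarray]],
    sample_ids: Sequence[str] | None = None,
) -> VariantMatrix:
    """Build diploid genotypes by summing paired haplotype allele vectors.

    Each haplotype is an int vector over the matrix's site list with alleles
    in {0,1} and ``-1`` for unresolved sites; any site unresolved in either
    haplotype of a pair becomes missing in the pseudo-diploid.
    """
    m = matrix.n_sites
    genos = []
    for h1, h2 in haplotype_pairs:
        h1 = np.asarray(h1)
        h2 = np.asarray(h2)
        if h1.shape != (m,) or h2.shape != (m,):
            raise ValueError("haplotype length does not match the site list")
        g = (h1 + h2).astype(np.int8)
        g[(h1 == MISSING) | (h2 == MISSING)] = MISSING
        genos.append(g)
    ids = list(sample_ids) if sample_ids is not None else [
        f"pseudo{i}" for i in range(len(haplotype_pairs))
    ]
    return VariantMatrix(
        sites=matrix.sites.reset_index(drop=True),
        genotypes=np.stack(genos) if genos else np.empty((0, m), dtype=np.int8),
        samples=pd.DataFrame({"id": ids}),
        chrom_lengths=matrix.chrom_lengths,
    )


# ---------------------------------------------------------------------------
# Folded AFS
# ---------------------------------------------------------------------------


def folded_afs(
    matrix: VariantMatrix,
    samples: Sequence[str | int],
    exclude_intervals: Iterable[tuple[str, int, int]] | None = None,
) -> AFS:
    """Folded minor-allele count spectrum over the given samples.

    Only sites with no missing genotype in any selected sample are used;
    sites inside ``exclude_intervals`` (chrom, start, end; 0-based half-open)
    are dropped. Alternate-allele counts k over 2n haplotypes are folded with
    2n-k into bins 0..n.
    """
    if len(samples) < 2:
        raise ValueError("need at least two samples for an AFS")
    g = np.stack([matrix.genotype_vector(s) for s in samples])
    use = matrix.callable_mask & np.all(g != MISSING, axis=0)
    if exclude_intervals:
        chrom_arr = matrix.sites["chrom"].to_numpy()
        pos0 = matrix.sites["pos"].to_numpy() - 1
        for chrom, s, t in exclude_intervals:
            use &= ~((chrom_arr == chrom) & (pos0 >= s) & (pos0 < t))
    if not use.any():
        raise ValueError("all sites excluded; AFS undefined")
    n_hap = 2 * len(samples)
    alt = g[:, use].sum(axis=0)
    minor = np.minimum(alt, n_hap - alt)
    counts = np.bincount(minor, minlength=n_hap // 2 + 1)
    return AFS(counts=counts, n_hap=n_hap, n_sites=int(use.sum()))
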