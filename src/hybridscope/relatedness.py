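"""IBS counting, IBD classification, relatedness, and interspecific phasing.

For a sample pair in a genomic window, IBS2 counts shared-heterozygous joint
genotypes (AB|AB) and IBS0 counts homozygous differences (AA|BB). The
identity-by-state ratio::

    IBSR = IBS2 / (IBS2 + IBS0)

equals 1 when the pair shares at least one haplotype across the window
(a shared haplotype makes AA|BB impossible), and has mean 2/3 for two
unrelated individuals from a panmictic population, independent of allele
frequencies. Windows are classified into IBD states with the paired genomic
distance D:

    IBSR <  0.95                ->  IBD0
    IBSR >= 0.95 and D < 0.05   ->  IBD2
    IBSR >= 0.95 and D > 0.05   ->  IBD1

(D exactly 0.05 falls to IBD1 — the conservative choice, avoiding inflated
clone calls.) The coefficient of relatedness is r = 1/2 IBD1 + IBD2 over the
classified window fractions: ~1 for clones, ~0.5 for parent-offspring,
~0.25 for half-sibs.

In genomic regions where the two samples are both interspecific hybrids,
IBSR is inflated by species-specific alleles; there IBD must be read from
phased haplotypes instead. :func:`interspecific_phase` phases a hybrid
against two parental-population panels, and :func:`haplotype_identity` calls
two haplotypes identical in a window when their mismatch rate is below
2e-4 (tolerating residual genotyping/phasing error).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .genotypes import VariantMatrix, WindowFrame, MISSING
from .divergence import pair_pi

__all__ = [
    "PairIBD",
    "PhasedPair",
    "ibs_counts",
    "ibsr",
    "classify_ibd",
    "relatedness_r",
    "pair_ibd",
    "interspecific_phase",
    "haplotype_identity",
    "DEFAULT_IBSR_THRESHOLD",
    "DEFAULT_D_THRESHOLD",
    "DEFAULT_MISMATCH_THRESHOLD",
]

DEFAULT_IBSR_THRESHOLD = 0.95
DEFAULT_D_THRESHOLD = 0.05
DEFAULT_MISMATCH_THRESHOLD = 2e-4
#: windows with fewer informative (IBS2+IBS0) sites than this are undetermined
DEFAULT_MIN_INFORMATIVE = 50


@dataclass
class PairIBD:
    """Window IBD classification and genome-wide relatedness for one pair.

    ``table`` columns: chrom, start, end, ibs2, ibs0, ibsr, D, state.
    Fractions are over classified (non-undetermined) windows and sum to 1.
    """

    sample1: str
    sample2: str
    table: pd.DataFrame
    ibd0: float
    ibd1: float
    ibd2: float
    n_classified: int

    @property
    def r(self) -> float:
        return relatedness_r(self.ibd0, self.ibd1, self.ibd2)


def ibs_counts(
    matrix: VariantMatrix, s1: str | int, s2: str | int, frame: WindowFrame
) -> pd.DataFrame:
    """Per-window IBS2 (AB|AB) and IBS0 (AA|BB) counts over non-missing
    callable joint genotypes."""
    g1 = matrix.genotype_vector(s1)
    g2 = matrix.genotype_vector(s2)
    ok = matrix.callable_mask & (g1 != MISSING) & (g2 != MISSING)
    is2 = ok & (g1 == 1) & (g2 == 1)
    is0 = ok & (((g1 == 0) & (g2 == 2)) | ((g1 == 2) & (g2 == 0)))
    rows = []
    for chrom, start, end, mem in frame:
        rows.append((chrom, start, end, int(is2[mem].sum()), int(is0[mem].sum())))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "ibs2", "ibs0"])


def ibsr(ibs2: int, ibs0: int) -> float:
    """IBS2 / (IBS2 + IBS0); NaN (undetermined) when both counts are zero."""
    tot = ibs2 + ibs0
    if tot <= 0:
        return float("nan")
    return ibs2 / tot


def classify_ibd(
    ibsr_value: float,
    window_d: float,
    ibsr_threshold: float = DEFAULT_IBSR_THRESHOLD,
    d_threshold: float = DEFAULT_D_THRESHOLD,
) -> str:
    """Assign one window's IBD state from its IBSR and D (see module docstring)."""
    if not (np.isfinite(ibsr_value) and np.isfinite(window_d)):
        return "undetermined"
    if ibsr_value < ibsr_threshold:
        return "IBD0"
    if window_d < d_threshold:
        return "IBD2"
    return "IBD1"


def relatedness_r(ibd0: float, ibd1: float, ibd2: float) -> float:
    """Coefficient of relatedness r = 1/2 IBD1 + IBD2."""
    if not np.isfinite(ibd1) or not np.isfinite(ibd2):
        return float("nan")
    return 0.5 * ibd1 + ibd2


def pair_ibd(
    matrix: VariantMatrix,
    s1: str | int,
    s2: str | int,
    frame: WindowFrame,
    min_informative: int = DEFAULT_MIN_INFORMATIVE,
    ibsr_threshold: float = DEFAULT_IBSR_THRESHOLD,
    d_threshold: float = DEFAULT_D_THRESHOLD,
) -> PairIBD:
    """Full pairwise IBD analysis over a window frame.

    Windows with fewer than ``min_informative`` IBS2+IBS0 sites, or with
    undefined D, are left undetermined and excluded from the IBD fractions.
    """
    counts = ibs_counts(matrix, s1, s2, frame)
    div = pair_pi(matrix, s1, s2, frame)
    d_vals = div.table["D"].to_numpy()
    states, ratios = [], []
    for i in range(len(counts)):
        i2, i0 = int(counts.at[i, "ibs2"]), int(counts.at[i, "ibs0"])
        rat = ibsr(i2, i0)
        ratios.append(rat)
        if i2 + i0 < min_informative:
            states.append("undetermined")
        else:
            states.append(classify_ibd(rat, d_vals[i], ibsr_threshold, d_threshold))
    table = counts.assign(ibsr=ratios, D=d_vals, state=states)
    classified = table[table["state"] != "undetermined"]
    n = len(classified)
    if n:
        frac = classified["state"].value_counts(normalize=True)
        ibd0 = float(frac.get("IBD0", 0.0))
        ibd1 = float(frac.get("IBD1", 0.0))
        ibd2 = float(frac.get("IBD2", 0.0))
    else:
        ibd0 = ibd1 = ibd2 = float("nan")
    name = lambda s: s if isinstance(s, str) else str(matrix.sample_ids[s])
    return PairIBD(name(s1), name(s2), table, ibd0, ibd1, ibd2, n)


# ---------------------------------------------------------------------------
# Interspecific phasing
# ---------------------------------------------------------------------------


@dataclass
class PhasedPair:
    """Interspecifically phased haplotypes of one hybrid sample.

    ``hap_a``/``hap_b`` carry the allele (0/1) assigned to the panel-A / B
    derived haplotype, ``-1`` where unresolved. ``status`` is one of
    'phased', 'homozygous', 'unresolved' per site. At every resolved site the
    two haplotype alleles sum to the diploid genotype.
    """

    sample: str
    hap_a: np.ndarray
    hap_b: np.ndarray
    status: np.ndarray  # '<U10'

    @property
    def resolved_mask(self) -> np.ndarray:
        return self.status != "unresolved"

    @property
    def unresolved_fraction(self) -> float:
        return float((self.status == "unresolved").mean())


def _panel_allele_counts(matrix: VariantMatrix, samples: Sequence[str | int]):
    g = np.stack([matrix.genotype_vector(s) for s in samples]).astype(np.int16)
    present = g != MISSING
    alt = np.where(present, g, 0).sum(axis=0)
    ref = np.where(present, 2 - g, 0).sum(axis=0)
    return ref, alt


def interspecific_phase(
    matrix: VariantMatrix,
    hybrid: str | int,
    panel_a: Sequence[str | int],
    panel_b: Sequence[str | int],
    tolerance: int = 0,
) -> PhasedPair:
    """Phase a putative A x B hybrid against two parental-population panels.

    A heterozygous site of the hybrid phases when one of its alleles is
    present in panel A but absent from panel B (allele count <= ``tolerance``)
    while the other allele is present in panel B but absent from panel A;
    each allele then goes to the haplotype of the panel that carries it.
    Sites with one-sided or contradictory evidence, or where both alleles
    occur in both panels, stay unresolved. Homozygous sites contribute their
    allele to both haplotypes.
    """
    if not len(panel_a) or not len(panel_b):
        raise ValueError("parental panels must be non-empty")
    g = matrix.genotype_vector(hybrid)
    ref_a, alt_a = _panel_allele_counts(matrix, panel_a)
    ref_b, alt_b = _panel_allele_counts(matrix, panel_b)

    m = matrix.n_sites
    hap_a = np.full(m, MISSING, dtype=np.int8)
    hap_b = np.full(m, MISSING, dtype=np.int8)
    status = np.full(m, "unresolved", dtype="<U10")

    hom_ref = matrix.callable_mask & (g == 0)
    hom_alt = matrix.callable_mask & (g == 2)
    hap_a[hom_ref] = hap_b[hom_ref] = 0
    hap_a[hom_alt] = hap_b[hom_alt] = 1
    status[hom_ref | hom_alt] = "homozygous"

    het = matrix.callable_mask & (g == 1)
    # an allele is attributable to one side only when it is present there and
    # effectively absent (count <= tolerance) from the other panel
    alt_from_a = (alt_a > tolerance) & (alt_b <= tolerance)
    alt_from_b = (alt_b > tolerance) & (alt_a <= tolerance)
    ref_from_a = (ref_a > tolerance) & (ref_b <= tolerance)
    ref_from_b = (ref_b > tolerance) & (ref_a <= tolerance)

    # a het site phases only when BOTH alleles are diagnostic, of opposite
    # sides; one-sided evidence is left unresolved (it is the double
    # requirement that keeps the misassignment rate negligible)
    assign_a_alt = het & alt_from_a & ref_from_b  # alt -> A, ref -> B
    assign_b_alt = het & alt_from_b & ref_from_a  # alt -> B, ref -> A

    hap_a[assign_a_alt] = 1
    hap_b[assign_a_alt] = 0
    hap_a[assign_b_alt] = 0
    hap_b[assign_b_alt] = 1
    status[assign_a_alt | assign_b_alt] = "phased"

    name = hybrid if isinstance(hybrid, str) else str(matrix.sample_ids[hybrid])
    return PhasedPair(name, hap_a, hap_b, status)


def haplotype_identity(
    h1: np.ndarray,
    h2: np.ndarray,
    frame: WindowFrame,
    threshold: float = DEFAULT_MISMATCH_THRESHOLD,
) -> pd.DataFrame:
    """Per-window identity call for two haplotypes on a shared site list.

    Sites unresolved (``-1``) in either haplotype are excluded pairwise.
    A window is 'identical' when mismatches/compared < ``threshold``,
    'distinct' otherwise, and undetermined (NaN rate, identical=False,
    defined=False) with zero compared sites.
    """
    h1 = np.asarray(h1)
    h2 = np.asarray(h2)
    if h1.shape != h2.shape:
        raise ValueError("haplotype length mismatch")
    ok = (h1 != MISSING) & (h2 != MISSING)
    mism = ok & (h1 != h2)
    rows = []
    for chrom, start, end, mem in frame:
        n = int(ok[mem].sum())
        k = int(mism[mem].sum())
        if n == 0:
            rows.append((chrom, start, end, 0, 0, np.nan, False, False))
        else:
            rate = k / n
            rows.append((chrom, start, end, n, k, rate, rate < threshold, True))
    return pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "n_compared", "n_mismatch",
                 "mismatch_rate", "identical", "defined"],
    )
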