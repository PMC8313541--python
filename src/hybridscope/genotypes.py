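"""Diploid genotype matrices, VCF I/O, site filtering and genome windowing.

Coordinate conventions (used throughout the package):

* VCF positions are 1-based; the site table stores the 1-based ``pos``.
* Windows, BED-like outputs and all internal interval arithmetic are
  0-based, half-open ``[start, end)``.

Genotypes are coded per sample per site as ``0`` hom-ref, ``1`` het,
``2`` hom-alt and ``-1`` missing. Only biallelic SNVs are represented.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FilterConfig",
    "VariantMatrix",
    "WindowFrame",
    "read_vcf",
    "write_matrix",
    "make_windows",
]

log = logging.getLogger(__name__)

MISSING = -1

_SITE_COLUMNS = ["chrom", "pos", "ref", "alt", "callable"]


@dataclass
class FilterConfig:
    """Site/genotype filters applied on VCF ingest.

    Thresholds follow common GATK-hardened practice: biallelic SNVs only,
    site QUAL >= ``min_qual``, per-sample depth >= ``min_dp`` (genotype set
    to missing below it), heterozygous allele balance within ``het_ab``.
    Set a field to ``None`` to disable that filter.
    """

    min_qual: float | None = 30.0
    min_dp: int | None = 10
    het_ab: tuple[float, float] | None = (0.2, 0.8)
    #: drop sites failing site-level filters instead of marking non-callable
    drop_failing_sites: bool = False


@dataclass
class VariantMatrix:
    """N-sample x M-site diploid genotype matrix on one reference coordinate system.

    Attributes
    ----------
    sites : DataFrame with columns chrom, pos (1-based), ref, alt, callable.
    genotypes : int8 array of shape (n_samples, n_sites).
    samples : DataFrame with column id and optional population, clone_group,
        depth columns.
    chrom_lengths : optional chromosome lengths in bp (for windowing and VCF
        contig headers); inferred from max positions when absent.
    """

    sites: pd.DataFrame
    genotypes: np.ndarray
    samples: pd.DataFrame
    chrom_lengths: dict[str, int] | None = None

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be 2-D (samples x sites)")
        n, m = self.genotypes.shape
        if len(self.samples) != n:
            raise ValueError(f"{len(self.samples)} sample rows for {n} genotype rows")
        if len(self.sites) != m:
            raise ValueError(f"{len(self.sites)} site rows for {m} genotype columns")
        bad = ~np.isin(self.genotypes, (-1, 0, 1, 2))
        if bad.any():
            raise ValueError("genotype codes must be in {-1, 0, 1, 2}")
        for chrom, grp in self.sites.groupby("chrom", sort=False):
            if not np.all(np.diff(grp["pos"].to_numpy()) > 0):
                raise ValueError(f"positions not strictly increasing on {chrom}")

    # -- basic accessors -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.genotypes.shape[1]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.samples["id"])

    def sample_index(self, sample: str | int) -> int:
        if isinstance(sample, (int, np.integer)):
            return int(sample)
        ids = list(self.samples["id"])
        try:
            return ids.index(sample)
        except ValueError:
            raise KeyError(f"unknown sample {sample!r}") from None

    def genotype_vector(self, sample: str | int) -> np.ndarray:
        return self.genotypes[self.sample_index(sample)]

    @property
    def callable_mask(self) -> np.ndarray:
        return self.sites["callable"].to_numpy(dtype=bool)

    @property
    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.sites["chrom"]))

    def chrom_length(self, chrom: str) -> int:
        if self.chrom_lengths and chrom in self.chrom_lengths:
            return int(self.chrom_lengths[chrom])
        sub = self.sites.loc[self.sites["chrom"] == chrom, "pos"]
        return int(sub.max())

    def chrom_site_range(self, chrom: str) -> tuple[int, int]:
        """Half-open site-index range of one chromosome (sites are chrom-sorted)."""
        idx = np.flatnonzero((self.sites["chrom"] == chrom).to_numpy())
        if idx.size == 0:
            raise KeyError(f"no sites on {chrom}")
        return int(idx[0]), int(idx[-1]) + 1

    def subset_samples(self, samples: Sequence[str | int]) -> "VariantMatrix":
        rows = [self.sample_index(s) for s in samples]
        return VariantMatrix(
            sites=self.sites.reset_index(drop=True),
            genotypes=self.genotypes[rows],
            samples=self.samples.iloc[rows].reset_index(drop=True),
            chrom_lengths=self.chrom_lengths,
        )


@dataclass
class WindowFrame:
    """A partition of the genome into windows.

    ``windows`` holds one row per window (chrom, start, end; 0-based
    half-open bp) and ``members[i]`` the sorted site indices of window ``i``.
    """

    windows: pd.DataFrame
    members: list[np.ndarray]
    mode: str
    size: int

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        for i in range(len(self.members)):
            row = self.windows.iloc[i]
            yield (row["chrom"], int(row["start"]), int(row["end"]), self.members[i])


# ---------------------------------------------------------------------------
# VCF I/O
# ---------------------------------------------------------------------------

_BASES = {"A", "C", "G", "T"}


def read_vcf(path: str | Path, filter_config: FilterConfig | None = None) -> VariantMatrix:
    """Read a multi-sample VCF with GT into a :class:`VariantMatrix`.

    Multi-allelic and non-SNV records are dropped (counts logged). Site and
    per-genotype filters follow ``filter_config`` (default
    :class:`FilterConfig`); sites failing site-level filters are marked
    non-callable, or dropped when ``drop_failing_sites`` is set.
    """
    from cyvcf2 import VCF

    cfg = filter_config or FilterConfig()
    path = str(path)
    vcf = VCF(path, gts012=True)
    sample_ids = list(vcf.samples)

    chroms: list[str] = []
    poss: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    callables: list[bool] = []
    gts: list[np.ndarray] = []
    n_multi = n_nonsnv = n_qual = 0

    for rec in vcf:
        if len(rec.ALT) != 1:
            n_multi += 1
            continue
        ref, alt = rec.REF, rec.ALT[0]
        if len(ref) != 1 or len(alt) != 1 or ref not in _BASES or alt not in _BASES:
            n_nonsnv += 1
            continue
        site_ok = True
        if cfg.min_qual is not None and rec.QUAL is not None and rec.QUAL < cfg.min_qual:
            site_ok = False
            n_qual += 1
        if not site_ok and cfg.drop_failing_sites:
            continue

        # gts012: 0 hom-ref, 1 het, 2 hom-alt, 3 unknown
        g = np.asarray(rec.gt_types, dtype=np.int8)
        g[g == 3] = MISSING

        if cfg.min_dp is not None:
            try:
                dp = rec.format("DP")
            except KeyError:
                dp = None
            if dp is not None:
                shallow = dp.reshape(-1).astype(float) < cfg.min_dp
                g[shallow] = MISSING
        if cfg.het_ab is not None:
            try:
                ad = rec.format("AD")
            except KeyError:
                ad = None
            if ad is not None and ad.shape[1] >= 2:
                tot = ad[:, 0].astype(float) + ad[:, 1].astype(float)
                with np.errstate(invalid="ignore", divide="ignore"):
                    ab = np.where(tot > 0, ad[:, 1] / tot, np.nan)
                lo, hi = cfg.het_ab
                bad_ab = (g == 1) & ~np.isnan(ab) & ((ab < lo) | (ab > hi))
                g[bad_ab] = MISSING

        chroms.append(rec.CHROM)
        poss.append(rec.POS)
        refs.append(ref)
        alts.append(alt)
        callables.append(site_ok)
        gts.append(g)

    if n_multi or n_nonsnv or n_qual:
        log.info(
            "read_vcf(%s): dropped %d multi-allelic and %d non-SNV records; "
            "%d sites failed QUAL",
            path, n_multi, n_nonsnv, n_qual,
        )

    sites = pd.DataFrame(
        {"chrom": chroms, "pos": poss, "ref": refs, "alt": alts, "callable": callables},
        columns=_SITE_COLUMNS,
    )
    geno = (
        np.stack(gts, axis=1)
        if gts
        else np.empty((len(sample_ids), 0), dtype=np.int8)
    )
    samples = pd.DataFrame({"id": sample_ids})
    lengths = {}
    for name, ln in zip(vcf.seqnames, vcf.seqlens or []):
        lengths[name] = ln
    return VariantMatrix(sites, geno, samples, chrom_lengths=lengths or None)


_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_matrix(matrix: VariantMatrix, path: str | Path) -> None:
    """Write a matrix as a VCF v4.2 text file (GT only). Lossless for codes
    {-1, 0, 1, 2}; missing genotypes become ``./.``."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=hybridscope\n")
        for chrom in matrix.chromosomes:
            fh.write(f"##contig=<ID={chrom},length={matrix.chrom_length(chrom)}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
        cols += matrix.sample_ids
        fh.write("\t".join(cols) + "\n")
        sites = matrix.sites
        geno = matrix.genotypes
        for j in range(matrix.n_sites):
            row = sites.iloc[j]
            flt = "PASS" if row["callable"] else "lowqual"
            fields = [
                str(row["chrom"]), str(int(row["pos"])), ".",
                row["ref"], row["alt"], ".", flt, ".", "GT",
            ]
            fields += [_GT_STR[int(g)] for g in geno[:, j]]
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# Windowing
# ---------------------------------------------------------------------------


def make_windows(
    matrix: VariantMatrix,
    mode: str,
    size: int,
    step: int | None = None,
    subset: np.ndarray | None = None,
) -> WindowFrame:
    """Partition each chromosome into windows.

    mode='bp_span'        tiles [0, chrom_length) in ``size``-bp windows
                          (optionally sliding with ``step`` < size).
    mode='callable_count' cuts after every ``size`` callable sites; the
                          terminal window per chromosome holds the remainder.
    mode='marker_count'   cuts after every ``size`` members of ``subset``
                          (site indices, e.g. an AIM list).
    """
    if size <= 0:
        raise ValueError("window size must be positive")
    if mode not in ("bp_span", "callable_count", "marker_count"):
        raise ValueError(f"unknown windowing mode {mode!r}")
    if mode == "marker_count" and subset is None:
        raise ValueError("marker_count mode needs a site-index subset")

    rows: list[tuple[str, int, int]] = []
    members: list[np.ndarray] = []
    pos = matrix.sites["pos"].to_numpy()

    for chrom in matrix.chromosomes:
        lo, hi = matrix.chrom_site_range(chrom)
        if mode == "bp_span":
            length = matrix.chrom_length(chrom)
            stp = size if step is None else step
            if stp <= 0:
                raise ValueError("step must be positive")
            cpos = pos[lo:hi]
            start = 0
            while start < length:
                end = min(start + size, length)
                # sites with 0-based coordinate (pos-1) in [start, end)
                a = np.searchsorted(cpos, start + 1, side="left")
                b = np.searchsorted(cpos, end, side="right")
                rows.append((chrom, start, end))
                members.append(np.arange(lo + a, lo + b))
                start += stp
        else:
            if mode == "callable_count":
                idx = np.arange(lo, hi)[matrix.callable_mask[lo:hi]]
            else:
                sub = np.asarray(subset)
                idx = sub[(sub >= lo) & (sub < hi)]
            if idx.size == 0:
                continue
            length = matrix.chrom_length(chrom)
            cuts = list(range(0, idx.size, size)) + [idx.size]
            prev_end = 0
            for a, b in zip(cuts[:-1], cuts[1:]):
                mem = idx[a:b]
                start = prev_end
                end = int(pos[mem[-1]]) if b < idx.size else length
                rows.append((chrom, start, end))
                members.append(mem)
                prev_end = end

    windows = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    return WindowFrame(windows=windows, members=members, mode=mode, size=size)
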