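"""Clone-group collapsing and classical MDS on the pairwise D matrix.

Accessions at genomic distance D ~ 0 are vegetative/apomictic copies of one
genotype; they are collapsed into clone groups by single linkage below a
distance threshold, each group represented by its highest-depth accession.
The remaining samples are embedded with classical (Torgerson) multi-
dimensional scaling — double-centering of the squared distance matrix
followed by eigendecomposition — so that pure populations appear as corner
clusters and F1 hybrids fall midway between their parents' clusters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .genotypes import VariantMatrix, MISSING

__all__ = [
    "DistanceMatrix",
    "MDSResult",
    "pairwise_distance_matrix",
    "collapse_clones",
    "classical_mds",
    "DEFAULT_CLONE_THRESHOLD",
]

log = logging.getLogger(__name__)

DEFAULT_CLONE_THRESHOLD = 0.02


@dataclass
class DistanceMatrix:
    """Square symmetric matrix of genome-wide clamped D with sample order."""

    values: np.ndarray
    samples: list[str]
    undefined: np.ndarray  # boolean mask of pairs where D was undefined

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if len(self.samples) != v.shape[0]:
            raise ValueError("sample list does not match matrix size")
        if not np.allclose(v, v.T, equal_nan=True):
            raise ValueError("distance matrix must be symmetric")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.samples, columns=self.samples)


@dataclass
class MDSResult:
    """Principal-coordinate embedding of a distance matrix."""

    coordinates: np.ndarray  # (n_samples, k)
    eigenvalues: np.ndarray  # decreasing, positive ones retained
    proportion: np.ndarray  # share of positive-eigenvalue dispersion per axis
    samples: list[str]

    def to_frame(self) -> pd.DataFrame:
        cols = [f"dim{i + 1}" for i in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=self.samples, columns=cols)


def pairwise_distance_matrix(
    matrix: VariantMatrix, samples: Sequence[str | int] | None = None
) -> DistanceMatrix:
    """All-pairs genome-wide D (clamped to [0,1]) via matrix products.

    pi components for each pair are aggregated over the sites callable and
    non-missing in both samples, then D = 1 - (pi1+pi2)/(4*pi12). The
    diagonal is 0 by construction; pairs with pi12 = 0 are flagged undefined
    (and set to 0 if identical, else NaN).
    """
    ids = samples if samples is not None else matrix.sample_ids
    g = np.stack([matrix.genotype_vector(s) for s in ids]).astype(np.float64)
    valid = (g != MISSING) & matrix.callable_mask
    gv = np.where(valid, g, 0.0)
    a = gv / 2.0
    v = valid.astype(np.float64)
    het = ((g == 1) & valid).astype(np.float64)

    n = v @ v.T  # shared usable sites
    # cross_ij = sum_m a_im(1-a_jm) + a_jm(1-a_im) over shared sites
    x = (a * v) @ (v - a * v).T
    cross = x + x.T
    p1 = (het * v) @ v.T  # pi1 numerator for pair (i,j)

    with np.errstate(invalid="ignore", divide="ignore"):
        d = 1.0 - (p1 + p1.T) / (4.0 * cross)
    undefined = ~(cross > 0)
    d = np.where(undefined, np.nan, d)
    # cross == 0 with shared sites implies identical homozygous genotypes
    # at every compared site: that is a clone-like pair, distance 0
    d = np.where(undefined & (n > 0), 0.0, d)
    np.fill_diagonal(d, 0.0)
    np.fill_diagonal(undefined, False)
    names = [s if isinstance(s, str) else str(matrix.sample_ids[s]) for s in ids]
    return DistanceMatrix(np.clip(d, 0.0, 1.0), names, undefined)


def collapse_clones(
    dmat: DistanceMatrix,
    depth: Sequence[float] | None = None,
    threshold: float = DEFAULT_CLONE_THRESHOLD,
) -> pd.DataFrame:
    """Single-linkage clone grouping of pairs with D < threshold.

    Each group's representative is the member with the highest sequencing
    depth (ties broken by sample-id order). Returns a table (sample, group,
    representative, is_representative).
    """
    n = len(dmat.samples)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if np.isfinite(dmat.values[i, j]) and dmat.values[i, j] < threshold:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)

    depths = list(depth) if depth is not None else [0.0] * n
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    rows = []
    for gid, (root, members) in enumerate(sorted(groups.items())):
        rep = max(members, key=lambda i: (depths[i], -members.index(i)))
        # ties by sample-id order: max on (depth, -position) keeps first-seen
        for i in members:
            rows.append((dmat.samples[i], gid, dmat.samples[rep], i == rep))
    return pd.DataFrame(rows, columns=["sample", "group", "representative",
                                       "is_representative"])


def classical_mds(dmat: DistanceMatrix, k: int = 2) -> MDSResult:
    """Classical (Torgerson) MDS: principal coordinates of a distance matrix.

    Double-centers -1/2 D^2 and eigendecomposes; the top-k positive
    eigenpairs give coordinates. Negative eigenvalues (non-Euclidean D) are
    dropped with a warning. Axis signs are fixed by making each axis's
    largest-magnitude loading positive.
    """
    d = dmat.values
    n = d.shape[0]
    if k > n - 1:
        raise ValueError(f"k={k} too large for {n} samples")
    if np.isnan(d).any():
        raise ValueError("distance matrix has undefined entries")
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    n_neg = int((evals < -1e-10 * max(1.0, abs(evals[0]))).sum())
    if n_neg:
        log.warning("classical_mds: dropping %d negative eigenvalues "
                    "(non-Euclidean distances)", n_neg)
    pos = evals > 1e-12 * max(1.0, abs(evals[0]))
    if not pos.any():
        raise ValueError("no positive eigenvalues; distances are degenerate")
    kk = min(k, int(pos.sum()))
    lam = evals[:kk]
    coords = evecs[:, :kk] * np.sqrt(lam)
    for axis in range(kk):
        i = np.argmax(np.abs(coords[:, axis]))
        if coords[i, axis] < 0:
            coords[:, axis] = -coords[:, axis]
    proportion = lam / evals[pos].sum()
    return MDSResult(coords, lam, proportion, list(dmat.samples))
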