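"""Population-structure summaries: PCoA, PERMANOVA, and Hudson FST.

PCoA is classical metric multidimensional scaling of a distance matrix
(delegated to scikit-bio).  PERMANOVA tests whether group labels explain
distance-matrix structure: the pseudo-F statistic compares between- to
within-group sums of squares on the Gower-centered matrix and its null
distribution is built by freely permuting sample labels.  FST uses the
Hudson estimator from per-deme allele counts, combined across sites as a
ratio of averages (summed numerators over summed denominators), which is
robust to rare variants in a way the average of per-site ratios is not.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix
from .sfs import _site_deme_counts

__all__ = [
    "OrdinationResult",
    "PermanovaResult",
    "pcoa",
    "permanova",
    "fst",
]


@dataclass
class OrdinationResult:
    """Principal-coordinate axes ordered by decreasing eigenvalue."""

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray
    negative_eigenvalues: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.eigenvalues) > 1e-9):
            raise ValueError("eigenvalues must be non-increasing")


@dataclass
class PermanovaResult:
    R2: float
    pseudo_F: float
    p_value: float
    n_permutations: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.R2 <= 1.0:
            raise ValueError("R2 outside [0, 1]")
        if not 0.0 < self.p_value <= 1.0:
            raise ValueError("p_value outside (0, 1]")


def _as_square(dist: pd.DataFrame | np.ndarray) -> tuple[np.ndarray, list[str]]:
    if isinstance(dist, pd.DataFrame):
        ids = list(dist.index)
        d = dist.to_numpy(dtype=float)
    else:
        d = np.asarray(dist, dtype=float)
        ids = [str(i) for i in range(len(d))]
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-12):
        raise ValueError("distance matrix must have a zero diagonal")
    return d, ids


def pcoa(dist: pd.DataFrame | np.ndarray) -> OrdinationResult:
    """Principal coordinates analysis of a symmetric distance matrix.

    Axes with negative eigenvalues (non-Euclidean distances) are dropped
    from the coordinates but reported in ``negative_eigenvalues``.
    """
    from skbio.stats.distance import DistanceMatrix
    from skbio.stats.ordination import pcoa as _skbio_pcoa

    d, ids = _as_square(dist)
    res = _skbio_pcoa(DistanceMatrix(d, ids=ids), method="eigh")
    eig = res.eigvals.to_numpy()
    pos = eig > 1e-12 * max(eig.max(), 1.0)
    coords = res.samples.to_numpy()[:, pos]
    pos_eig = eig[pos]
    return OrdinationResult(
        coordinates=pd.DataFrame(
            coords, index=ids, columns=[f"PC{i+1}" for i in range(coords.shape[1])]
        ),
        eigenvalues=pos_eig,
        proportion_explained=pos_eig / eig[eig > 0].sum(),
        negative_eigenvalues=eig[eig < 0],
    )


def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d**2
    row = a.mean(axis=1, keepdims=True)
    col = a.mean(axis=0, keepdims=True)
    return a - row - col + a.mean()


def _pseudo_f(G: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    n = len(labels)
    groups, counts = np.unique(labels, return_counts=True)
    a = len(groups)
    ss_total = np.trace(G)
    ss_within = 0.0
    for g, c in zip(groups, counts):
        idx = np.flatnonzero(labels == g)
        ss_within += np.trace(G[np.ix_(idx, idx)]) - G[np.ix_(idx, idx)].sum() / c
    # trace identity: SS_total = trace(G); within-group SS via sub-blocks
    ss_within_alt = ss_within
    ss_between = ss_total - ss_within_alt
    f = (ss_between / (a - 1)) / (ss_within_alt / (n - a))
    r2 = ss_between / ss_total
    return f, r2


def permanova(
    dist: pd.DataFrame | np.ndarray,
    labels,
    n_perm: int = 999,
    seed: int = 0,
) -> PermanovaResult:
    """Permutational multivariate ANOVA on a distance matrix.

    ``p = (1 + #{permuted F >= observed F}) / (1 + n_perm)`` with sample
    labels shuffled freely; deterministic given ``seed``.
    """
    d, ids = _as_square(dist)
    labels = np.asarray(list(labels))
    if len(labels) != len(d):
        raise ValueError("labels length must match the distance matrix")
    groups, counts = np.unique(labels, return_counts=True)
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if np.any(counts < 2):
        small = groups[counts < 2]
        raise ValueError(f"groups of size 1 are not testable: {small}")
    G = _gower_center(d)
    f_obs, r2 = _pseudo_f(G, labels)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        f_perm, _ = _pseudo_f(G, rng.permutation(labels))
        if f_perm >= f_obs:
            exceed += 1
    p = (1 + exceed) / (1 + n_perm)
    return PermanovaResult(R2=float(r2), pseudo_F=float(f_obs), p_value=float(p), n_permutations=n_perm)


def fst(gm: GenotypeMatrix, demes: tuple[str, str] | None = None):
    """Hudson FST from called genotypes: (global ratio-of-averages, per-site).

    Per site with allele frequencies ``p1, p2`` from ``n1, n2`` called
    genomes, the numerator is ``(p1 - p2)^2 - p1(1-p1)/(n1-1) -
    p2(1-p2)/(n2-1)`` and the denominator ``p1(1-p2) + p2(1-p1)``.  The
    global estimate sums numerators and denominators over sites polymorphic
    in the pooled sample; per-site values (which may be negative) are
    returned for all such sites.
    """
    if demes is None:
        names = gm.deme_names
        if len(names) != 2:
            raise ValueError(f"expected exactly two demes, found {names}")
        demes = (names[0], names[1])
    a1, n1 = _site_deme_counts(gm, demes[0])
    a2, n2 = _site_deme_counts(gm, demes[1])
    ok = (n1 >= 2) & (n2 >= 2)
    poly = ok & (a1 + a2 > 0) & (a1 + a2 < n1 + n2)
    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = a1 / np.maximum(n1, 1)
        p2 = a2 / np.maximum(n2, 1)
        num = (p1 - p2) ** 2 - p1 * (1 - p1) / np.maximum(n1 - 1, 1) - p2 * (1 - p2) / np.maximum(n2 - 1, 1)
        den = p1 * (1 - p2) + p2 * (1 - p1)
    per_site = pd.DataFrame(
        {
            "contig": gm.sites["contig"][poly],
            "pos": gm.sites["pos"][poly],
            "numerator": num[poly],
            "denominator": den[poly],
            "fst": np.clip(num[poly] / den[poly], -1.0, 1.0),
        }
    ).reset_index(drop=True)
    denom_sum = float(den[poly].sum())
    global_fst = float(num[poly].sum() / denom_sum) if denom_sum > 0 else np.nan
    return global_fst, per_site
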