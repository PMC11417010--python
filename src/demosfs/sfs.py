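"""Joint (2D) site frequency spectra: construction, folding, projection,
contig bootstrap, and plain-text serialization.

A :class:`SpectrumGrid` holds non-negative real mass on an
``(n1+1) x (n2+1)`` grid indexed by alternate-allele counts ``(i, j)`` in two
population samples of ``n1`` and ``n2`` genomes.  The monomorphic corners
``(0, 0)`` and (unfolded) ``(n1, n2)`` are masked: they carry no information
about polymorphism and are excluded from likelihoods.  Missing genotypes are
handled by hypergeometric projection: a site observed at more genomes than
the analysis target contributes the expected spectrum of a random subsample
of exactly the target size, so mass is conserved site by site.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .genotypes import MISSING, GenotypeMatrix

__all__ = [
    "SpectrumGrid",
    "projection_matrix",
    "observed_sfs",
    "bootstrap_contigs",
    "read_sfs",
    "write_sfs",
]


def _standard_mask(n1: int, n2: int, folded: bool) -> np.ndarray:
    mask = np.zeros((n1 + 1, n2 + 1), dtype=bool)
    mask[0, 0] = True
    if folded:
        i = np.arange(n1 + 1)[:, None]
        j = np.arange(n2 + 1)[None, :]
        mask |= 2 * (i + j) > (n1 + n2)
    else:
        mask[n1, n2] = True
    return mask


@dataclass
class SpectrumGrid:
    """Observed or expected joint SFS on an ``(n1+1) x (n2+1)`` grid."""

    values: np.ndarray
    folded: bool = False
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("SpectrumGrid values must be a 2D array")
        if np.any(self.values < -1e-9):
            raise ValueError("SFS entries must be non-negative")
        self.values = np.maximum(self.values, 0.0)
        if self.mask is None:
            self.mask = _standard_mask(self.n1, self.n2, self.folded)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise ValueError("mask shape mismatch")
        if self.folded:
            i = np.arange(self.n1 + 1)[:, None]
            j = np.arange(self.n2 + 1)[None, :]
            upper = 2 * (i + j) > (self.n1 + self.n2)
            if np.any(self.values[upper] > 1e-9):
                raise ValueError("folded spectrum has mass above the fold line")

    @property
    def n1(self) -> int:
        return self.values.shape[0] - 1

    @property
    def n2(self) -> int:
        return self.values.shape[1] - 1

    @property
    def mass(self) -> float:
        """Total mass on the grid, masked corners included."""
        return float(self.values.sum())

    def unmasked(self) -> np.ndarray:
        """Values at unmasked entries (the likelihood support)."""
        return self.values[~self.mask]

    def copy(self) -> "SpectrumGrid":
        return SpectrumGrid(self.values.copy(), folded=self.folded, mask=self.mask.copy())

    # -- transforms --------------------------------------------------------

    def fold(self) -> "SpectrumGrid":
        """Fold onto minor-allele counts.

        Entry ``(i, j)`` with ``i + j > (n1+n2)/2`` is added into its
        complement ``(n1-i, n2-j)``; entries exactly on the half line are
        split half-and-half with their complement (so each member of a
        complementary pair keeps the pair's average).  Total mass is
        conserved.
        """
        if self.folded:
            raise ValueError("spectrum is already folded")
        n1, n2 = self.n1, self.n2
        i = np.arange(n1 + 1)[:, None]
        j = np.arange(n2 + 1)[None, :]
        total = 2 * (i + j)
        reversed_vals = self.values[::-1, ::-1]
        out = np.where(
            total < n1 + n2,
            self.values + reversed_vals,
            np.where(total == n1 + n2, (self.values + reversed_vals) / 2.0, 0.0),
        )
        return SpectrumGrid(out, folded=True)

    def project(self, m1: int, m2: int) -> "SpectrumGrid":
        """Hypergeometric projection down to ``(m1, m2)`` genomes.

        ``S'(a, b) = sum_ij S(i, j) H(a; m1, i, n1) H(b; m2, j, n2)`` with
        ``H`` the hypergeometric sampling kernel; mass is conserved and
        projection to the same sizes is the identity.
        """
        if self.folded:
            raise ValueError("project an unfolded spectrum, then fold")
        if m1 > self.n1 or m2 > self.n2:
            raise ValueError("cannot project up")
        p1 = projection_matrix(self.n1, m1)
        p2 = projection_matrix(self.n2, m2)
        return SpectrumGrid(p1 @ self.values @ p2.T, folded=False)


def projection_matrix(n: int, m: int) -> np.ndarray:
    """``(m+1) x (n+1)`` matrix of hypergeometric subsampling probabilities.

    Column ``i`` is the pmf of the number of alternate alleles in a draw of
    ``m`` genomes without replacement from ``n`` genomes of which ``i`` carry
    the alternate allele.
    """
    if m > n:
        raise ValueError(f"cannot project {n} genomes up to {m}")
    a = np.arange(m + 1)[:, None]
    i = np.arange(n + 1)[None, :]
    return hypergeom.pmf(a, n, i, m)


def _site_deme_counts(gm: GenotypeMatrix, deme: str) -> tuple[np.ndarray, np.ndarray]:
    """Per-site (alt alleles, called genomes) for one deme."""
    idx = gm.deme_indices(deme)
    calls = gm.calls[idx, :]
    called = calls != MISSING
    alt = np.where(called, calls, 0).sum(axis=0)
    genomes = 2 * called.sum(axis=0)
    return alt.astype(np.int64), genomes.astype(np.int64)


def observed_sfs(
    gm: GenotypeMatrix,
    n1_target: int,
    n2_target: int,
    demes: tuple[str, str] | None = None,
) -> SpectrumGrid:
    """Observed unfolded joint SFS, down-projected to the target sizes.

    A site contributes only if both demes have at least the target number of
    called genomes; sites with more than the target contribute the expected
    (fractional) counts of a hypergeometric subsample.  Total grid mass then
    equals the number of contributing sites.  Excluded sites are reported
    via a warning.
    """
    if demes is None:
        names = gm.deme_names
        if len(names) != 2:
            raise ValueError(f"expected exactly two demes, found {names}")
        demes = (names[0], names[1])
    alt1, gen1 = _site_deme_counts(gm, demes[0])
    alt2, gen2 = _site_deme_counts(gm, demes[1])
    if n1_target > 2 * len(gm.deme_indices(demes[0])) or n2_target > 2 * len(
        gm.deme_indices(demes[1])
    ):
        raise ValueError("projection target exceeds available genomes")

    usable = (gen1 >= n1_target) & (gen2 >= n2_target)
    n_dropped = int((~usable).sum())
    if n_dropped:
        warnings.warn(
            f"{n_dropped} sites below the projection threshold were excluded",
            stacklevel=2,
        )
    grid = np.zeros((n1_target + 1, n2_target + 1))
    proj_cache: dict[tuple[int, int, int], np.ndarray] = {}

    def spread(a: int, n: int, m: int) -> np.ndarray:
        key = (a, n, m)
        if key not in proj_cache:
            if n == m:
                v = np.zeros(m + 1)
                v[a] = 1.0
            else:
                v = hypergeom.pmf(np.arange(m + 1), n, a, m)
            proj_cache[key] = v
        return proj_cache[key]

    for s in np.flatnonzero(usable):
        v1 = spread(int(alt1[s]), int(gen1[s]), n1_target)
        v2 = spread(int(alt2[s]), int(gen2[s]), n2_target)
        grid += np.outer(v1, v2)
    return SpectrumGrid(grid, folded=False)


def bootstrap_contigs(
    gm: GenotypeMatrix,
    n1_target: int,
    n2_target: int,
    B: int,
    seed: int,
    fold: bool = False,
    demes: tuple[str, str] | None = None,
) -> list[SpectrumGrid]:
    """Contig-bootstrap replicates of the observed SFS.

    Each replicate resamples contigs with replacement up to the original
    contig count and rebuilds the spectrum from the resampled sites,
    preserving linkage within contigs.  Deterministic given ``seed``.
    """
    contigs = gm.sites["contig"].to_numpy()
    unique = np.asarray(pd.unique(contigs))
    if len(unique) < 2:
        raise ValueError("contig bootstrap requires at least two contigs")
    site_idx_by_contig = {c: np.flatnonzero(contigs == c) for c in unique}
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(B):
        chosen = rng.choice(unique, size=len(unique), replace=True)
        idx = np.concatenate([site_idx_by_contig[c] for c in chosen])
        # renumber contig copies so positions stay strictly increasing
        sub = gm.sites.iloc[idx].reset_index(drop=True)
        sub = sub.copy()
        sub["contig"] = [f"bs{k}" for k, c in enumerate(chosen) for _ in site_idx_by_contig[c]]
        rep = GenotypeMatrix(
            sample_ids=list(gm.sample_ids),
            demes=gm.demes.copy(),
            sites=sub,
            calls=gm.calls[:, idx],
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sfs = observed_sfs(rep, n1_target, n2_target, demes=demes)
        out.append(sfs.fold() if fold else sfs)
    return out


# -- plain-text serialization (dadi/moments-compatible layout) -------------


def write_sfs(sfs: SpectrumGrid, path: str | Path) -> None:
    """Write ``(n1+1) (n2+1) folded/unfolded`` header, row-major values,
    and a mask line of 0/1 flags."""
    with open(path, "w") as fh:
        fold_word = "folded" if sfs.folded else "unfolded"
        fh.write(f"{sfs.n1 + 1} {sfs.n2 + 1} {fold_word}\n")
        fh.write(" ".join(repr(float(v)) for v in sfs.values.ravel()) + "\n")
        fh.write(" ".join("1" if m else "0" for m in sfs.mask.ravel()) + "\n")


def read_sfs(path: str | Path) -> SpectrumGrid:
    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip() and not ln.startswith("#")]
    if len(lines) < 3:
        raise ValueError("truncated SFS file")
    d1, d2, fold_word = lines[0].split()
    shape = (int(d1), int(d2))
    values = np.fromiter((float(x) for x in lines[1].split()), dtype=np.float64).reshape(shape)
    mask = np.fromiter((x == "1" for x in lines[2].split()), dtype=bool).reshape(shape)
    return SpectrumGrid(values, folded=(fold_word == "folded"), mask=mask)
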