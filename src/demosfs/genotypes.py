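"""Diploid genotype matrices: VCF ingest, site filters, and per-sample summaries.

The central container is :class:`GenotypeMatrix`, a dense matrix of called
diploid genotypes (0/1/2 alternate-allele dosage, -1 for missing) with
per-site contig/position metadata and a population (deme) label per sample.
Filters mirror a standard RAD-seq SNP cleaning pass: a per-site call-rate
threshold, a pooled minor-allele-frequency floor, and an optional cap on the
observed heterozygote fraction (collapsed paralogs genotype as ~100%
heterozygous).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

MISSING = -1

__all__ = [
    "MISSING",
    "GenotypeMatrix",
    "SiteFilterConfig",
    "apply_site_filters",
    "ibs_distance",
    "sample_heterozygosity",
    "read_popmap",
    "write_popmap",
    "read_vcf",
    "write_vcf",
]


@dataclass
class GenotypeMatrix:
    """Called diploid genotypes for a set of samples at biallelic SNPs.

    Parameters
    ----------
    sample_ids
        Ordered sample identifiers.
    demes
        Population label per sample, aligned with ``sample_ids``.
    sites
        DataFrame with columns ``contig``, ``pos``, ``ref``, ``alt``;
        positions must be strictly increasing within each contig.
    calls
        ``(n_samples, n_sites)`` int8 array of alternate-allele dosages in
        ``{0, 1, 2}``; missing calls are ``-1``.
    """

    sample_ids: list[str]
    demes: np.ndarray
    sites: pd.DataFrame
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.demes = np.asarray(self.demes, dtype=object)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.sample_ids), len(self.sites)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.sites)} sites"
            )
        bad = ~np.isin(self.calls, (MISSING, 0, 1, 2))
        if bad.any():
            raise ValueError("genotype calls must be in {-1, 0, 1, 2}")
        for contig, grp in self.sites.groupby("contig", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on {contig}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def deme_names(self) -> list[str]:
        seen: dict[str, None] = {}
        for d in self.demes:
            seen.setdefault(d, None)
        return list(seen)

    def deme_indices(self, deme: str) -> np.ndarray:
        return np.flatnonzero(self.demes == deme)

    def take_sites(self, index: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            demes=self.demes.copy(),
            sites=self.sites.iloc[index].reset_index(drop=True),
            calls=self.calls[:, index],
        )

    def take_samples(self, index: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            sample_ids=[self.sample_ids[i] for i in index],
            demes=self.demes[index],
            sites=self.sites.copy(),
            calls=self.calls[index, :],
        )

    # -- per-site summaries used by filters and the SFS builder ------------

    def called_mask(self) -> np.ndarray:
        return self.calls != MISSING

    def site_call_fraction(self) -> np.ndarray:
        return self.called_mask().sum(axis=0) / self.n_samples

    def site_alt_frequency(self) -> np.ndarray:
        """Pooled alternate-allele frequency over non-missing calls."""
        called = self.called_mask()
        alt = np.where(called, self.calls, 0).sum(axis=0)
        genomes = 2 * called.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(genomes > 0, alt / np.maximum(genomes, 1), np.nan)

    def site_het_fraction(self) -> np.ndarray:
        called = self.called_mask()
        het = ((self.calls == 1) & called).sum(axis=0)
        n_called = called.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_called > 0, het / np.maximum(n_called, 1), np.nan)


@dataclass
class SiteFilterConfig:
    """Site-level filter thresholds.

    ``min_call_fraction`` retains sites genotyped in at least that fraction
    of all samples; ``min_maf`` drops sites whose pooled minor-allele
    frequency is below the threshold (retention is inclusive: a site at
    exactly ``min_maf`` survives); ``max_het_fraction``, when set, drops
    sites with an excessive observed heterozygote fraction.
    """

    min_call_fraction: float = 0.75
    min_maf: float = 0.025
    max_het_fraction: float | None = None

    def __post_init__(self) -> None:
        for name in ("min_call_fraction", "min_maf"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.max_het_fraction is not None and not 0.0 <= self.max_het_fraction <= 1.0:
            raise ValueError("max_het_fraction outside [0, 1]")


def apply_site_filters(
    gm: GenotypeMatrix,
    cfg: SiteFilterConfig,
    return_audit: bool = False,
):
    """Apply call-rate, MAF, and heterozygosity-excess filters.

    Returns the filtered matrix (sample set and site order unchanged).  With
    ``return_audit=True`` also returns a DataFrame listing, for every input
    site, whether it survived and the first rule it violated.
    """
    if gm.n_sites == 0:
        raise ValueError("empty genotype matrix")
    call_frac = gm.site_call_fraction()
    alt_freq = gm.site_alt_frequency()
    maf = np.minimum(alt_freq, 1.0 - alt_freq)
    het = gm.site_het_fraction()

    reasons = np.array([""] * gm.n_sites, dtype=object)
    fail_call = call_frac < cfg.min_call_fraction
    fail_maf = ~fail_call & (np.isnan(maf) | (maf < cfg.min_maf))
    reasons[fail_call] = "call_fraction"
    reasons[fail_maf] = "maf"
    keep = ~fail_call & ~fail_maf
    if cfg.max_het_fraction is not None:
        fail_het = keep & (het > cfg.max_het_fraction)
        reasons[fail_het] = "het_excess"
        keep &= ~fail_het

    if not keep.any():
        warnings.warn("all sites removed by filters", stacklevel=2)
    out = gm.take_sites(np.flatnonzero(keep))
    if return_audit:
        audit = gm.sites.copy()
        audit["kept"] = keep
        audit["reason"] = reasons
        return out, audit
    return out


def ibs_distance(gm: GenotypeMatrix) -> pd.DataFrame:
    """Pairwise identity-by-state distance between samples.

    ``d(a, b)`` is the mean over sites non-missing in both samples of
    ``|g_a - g_b| / 2`` (the fraction of allele mismatches between the two
    diploid genotypes under a dosage interpretation).  A pair with no
    overlapping called sites is NaN and reported via a warning.
    """
    if gm.n_samples < 2:
        raise ValueError("need at least two samples")
    calls = gm.calls.astype(np.float64)
    calls[gm.calls == MISSING] = np.nan
    n = gm.n_samples
    d = np.zeros((n, n))
    no_overlap = []
    for a in range(n):
        diff = np.abs(calls[a + 1 :] - calls[a]) / 2.0
        counts = np.sum(~np.isnan(diff), axis=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            means = np.nanmean(diff, axis=1)
        for k, b in enumerate(range(a + 1, n)):
            if counts[k] == 0:
                no_overlap.append((gm.sample_ids[a], gm.sample_ids[b]))
                d[a, b] = d[b, a] = np.nan
            else:
                d[a, b] = d[b, a] = means[k]
    if no_overlap:
        warnings.warn(
            f"{len(no_overlap)} sample pairs share no called sites; distances set to NaN",
            stacklevel=2,
        )
    return pd.DataFrame(d, index=gm.sample_ids, columns=gm.sample_ids)


def sample_heterozygosity(gm: GenotypeMatrix) -> pd.Series:
    """Fraction of called genotypes that are heterozygous, per sample.

    Samples with no called genotypes get NaN.
    """
    called = gm.called_mask()
    n_called = called.sum(axis=1)
    het = ((gm.calls == 1) & called).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(n_called > 0, het / np.maximum(n_called, 1), np.nan)
    if np.isnan(frac).any():
        warnings.warn("samples with no called genotypes have NaN heterozygosity", stacklevel=2)
    return pd.Series(frac, index=gm.sample_ids, name="heterozygosity")


# -- interchange formats ---------------------------------------------------


def read_popmap(path: str | Path) -> dict[str, str]:
    """Read a two-column (sample, deme) population map."""
    popmap: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ValueError(f"malformed popmap line: {line!r}")
        popmap[parts[0]] = parts[1]
    return popmap


def write_popmap(gm: GenotypeMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid, deme in zip(gm.sample_ids, gm.demes):
            fh.write(f"{sid}\t{deme}\n")


def read_vcf(vcf_path: str | Path, popmap: dict[str, str] | str | Path) -> GenotypeMatrix:
    """Read biallelic SNP records from a VCF into a GenotypeMatrix.

    Multiallelic records are rejected (a count is reported via a warning);
    samples absent from the population map are dropped.
    """
    from cyvcf2 import VCF

    if not isinstance(popmap, dict):
        popmap = read_popmap(popmap)
    vcf = VCF(str(vcf_path))
    keep_idx = [i for i, s in enumerate(vcf.samples) if s in popmap]
    sample_ids = [vcf.samples[i] for i in keep_idx]
    if not sample_ids:
        raise ValueError("no VCF samples present in the population map")
    demes = np.array([popmap[s] for s in sample_ids], dtype=object)

    rows = []
    contigs, poss, refs, alts = [], [], [], []
    n_multi = 0
    # cyvcf2 gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
    remap = np.array([0, 1, MISSING, 2], dtype=np.int8)
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        gt = remap[np.asarray(var.gt_types)[keep_idx]]
        rows.append(gt)
        contigs.append(var.CHROM)
        poss.append(var.POS)
        refs.append(var.REF)
        alts.append(var.ALT[0])
    if n_multi:
        warnings.warn(f"skipped {n_multi} multiallelic records", stacklevel=2)
    sites = pd.DataFrame({"contig": contigs, "pos": poss, "ref": refs, "alt": alts})
    calls = np.array(rows, dtype=np.int8).T if rows else np.empty((len(sample_ids), 0), np.int8)
    return GenotypeMatrix(sample_ids=sample_ids, demes=demes, sites=sites, calls=calls)


_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(
    gm: GenotypeMatrix,
    path: str | Path,
    contig_lengths: dict[str, int] | None = None,
) -> None:
    """Write a minimal VCF 4.2 with diploid GT calls and ``##contig`` headers."""
    contigs: dict[str, int] = {}
    for contig, grp in gm.sites.groupby("contig", sort=False):
        length = int(grp["pos"].max())
        if contig_lengths and contig in contig_lengths:
            length = contig_lengths[contig]
        contigs[contig] = length
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=demosfs\n")
        for contig, length in contigs.items():
            fh.write(f"##contig=<ID={contig},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.sample_ids)
            + "\n"
        )
        for j in range(gm.n_sites):
            site = gm.sites.iloc[j]
            gts = "\t".join(_GT_STRINGS[int(g)] for g in gm.calls[:, j])
            fh.write(
                f"{site['contig']}\t{site['pos']}\t.\t{site['ref']}\t{site['alt']}"
                f"\t.\tPASS\t.\tGT\t{gts}\n"
            )
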