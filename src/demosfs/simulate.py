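"""Structured-coalescent simulator for one or two demes.

Simulates genealogies backward in time under piecewise demographies with
per-epoch size trajectories (sudden, linear, exponential) and constant
per-epoch migration, drops infinite-sites mutations, and emits diploid
genotype matrices with contig structure and uniform missingness, together
with a truth record for parameter-recovery experiments.

Units here are physical: deme sizes are diploid counts ``N`` (pairwise
coalescence rate ``1/(2N)`` per generation), times are generations, and
migration rates are per-generation per-lineage probabilities in the
*backward* convention -- ``m[d, e]`` is the rate at which a lineage
currently in deme ``d`` traces its ancestry into deme ``e``.  Forward in
time this is gene flow from ``e`` to ``d``.  Contigs are independent,
non-recombining loci, matching short reduced-representation tags.

Waiting times are drawn by competing exponentials; epochs with changing
sizes use thinning against the epoch's maximal total rate, so time-varying
trajectories are sampled exactly (no discretization).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .genotypes import GenotypeMatrix
from .models import DYNAMICS, DemographicModel

__all__ = [
    "PhysicalEpoch",
    "PhysicalDemography",
    "CoalescentConfig",
    "TruthRecord",
    "Genealogy",
    "NonCoalescingError",
    "physical_demography",
    "simulate_genealogy",
    "drop_mutations",
    "branch_joint_afs",
    "emit_genotype_matrix",
    "paper_emulation_config",
]


class NonCoalescingError(RuntimeError):
    """Raised when lineages cannot find a common ancestor before the cap."""


@dataclass
class PhysicalEpoch:
    """One forward-time interval in physical units (see module docstring)."""

    duration: float
    sizes: tuple[float, ...]
    dynamics: tuple[str, ...] | None = None
    mig_backward: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("epoch duration must be > 0")
        self.sizes = tuple(float(s) for s in self.sizes)
        if any(s <= 0 for s in self.sizes):
            raise ValueError("sizes must be > 0")
        k = len(self.sizes)
        if self.dynamics is None:
            self.dynamics = ("sudden",) * k
        if any(d not in DYNAMICS for d in self.dynamics):
            raise ValueError(f"dynamics must be in {DYNAMICS}")
        if self.mig_backward is None:
            self.mig_backward = np.zeros((k, k))
        self.mig_backward = np.asarray(self.mig_backward, dtype=float)
        if self.mig_backward.shape != (k, k) or np.any(self.mig_backward < 0):
            raise ValueError("mig_backward must be a non-negative (k, k) matrix")


@dataclass
class PhysicalDemography:
    """Epochs oldest-to-newest plus the ancestral equilibrium size."""

    ancestral_size: float
    epochs: list[PhysicalEpoch] = field(default_factory=list)
    split_epoch: int | None = None

    def __post_init__(self) -> None:
        if self.ancestral_size <= 0:
            raise ValueError("ancestral_size must be > 0")
        if self.split_epoch is not None:
            for k, ep in enumerate(self.epochs):
                expected = 1 if k < self.split_epoch else 2
                if len(ep.sizes) != expected:
                    raise ValueError(f"epoch {k}: {len(ep.sizes)} demes, expected {expected}")
        else:
            # without a split the deme count must be constant: either a
            # single deme throughout, or two demes that never join (island
            # models at equilibrium; isolated demes never coalesce)
            k_demes = {len(ep.sizes) for ep in self.epochs}
            if len(k_demes) > 1:
                raise ValueError("deme count may only change at a split")

    @property
    def n_demes(self) -> int:
        return len(self.epochs[-1].sizes) if self.epochs else 1

    def size_at_epoch_start(self, k: int) -> tuple[float, ...]:
        prev = (self.ancestral_size,) if k == 0 else self.epochs[k - 1].sizes
        n_now = len(self.epochs[k].sizes)
        if len(prev) < n_now:  # split (or a two-deme history from the start)
            return (prev[0],) * n_now
        return prev


def physical_demography(
    model: DemographicModel, Ne_anc: float
) -> PhysicalDemography:
    """Convert a genetic-units model to physical units.

    Sizes scale by ``Ne_anc``, durations by ``2 * Ne_anc`` generations, and
    the forward scaled migration ``M[d, e] = 2 Ne_anc m`` (genes d -> e)
    becomes the backward per-generation rate ``m[e, d] = M[d, e] / (2
    Ne_anc)``: the destination deme's lineages trace back into the source.
    """
    epochs = []
    for ep in model.epochs:
        k = ep.n_demes
        mig_b = ep.migration.T / (2.0 * Ne_anc)
        epochs.append(
            PhysicalEpoch(
                duration=ep.duration * 2.0 * Ne_anc,
                sizes=tuple(s * Ne_anc for s in ep.sizes),
                dynamics=ep.dynamics,
                mig_backward=mig_b,
            )
        )
    return PhysicalDemography(
        ancestral_size=Ne_anc, epochs=epochs, split_epoch=model.split_epoch
    )


@dataclass
class CoalescentConfig:
    """Study design for a synthetic dataset."""

    deme_sample_sizes: tuple[int, ...]
    n_contigs: int
    contig_length: int
    mu: float
    demography: PhysicalDemography
    missing_rate: float = 0.0
    seed: int = 0
    deme_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if any(n < 1 for n in self.deme_sample_sizes):
            raise ValueError("deme sample sizes must be >= 1")
        if self.mu <= 0:
            raise ValueError("mu must be > 0")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.n_contigs < 1 or self.contig_length < 1:
            raise ValueError("need at least one contig of positive length")
        if self.deme_names is None:
            self.deme_names = tuple(f"deme{d}" for d in range(len(self.deme_sample_sizes)))


@dataclass
class TruthRecord:
    """The generating configuration plus realized summary counts."""

    config: CoalescentConfig
    n_segregating: int
    deme_sample_sizes: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.n_segregating < 0:
            raise ValueError("segregating sites must be >= 0")


@dataclass
class Genealogy:
    """A coalescent tree: node arrays with times in generations.

    Leaves are nodes ``0 .. n_leaves-1`` at time 0; internal nodes follow in
    coalescence order.  ``parent`` is ``-1`` for the root.
    """

    parent: np.ndarray
    time: np.ndarray
    n_leaves: int
    leaf_demes: np.ndarray

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    def total_branch_length(self) -> float:
        nodes = np.arange(self.n_nodes - 1)  # root excluded (parent of others)
        has_parent = self.parent >= 0
        return float(np.sum(self.time[self.parent[has_parent]] - self.time[has_parent]))

    def leaf_sets(self) -> list[list[int]]:
        """Descendant leaf indices per node (leaves first, root last)."""
        sets: list[list[int]] = [[i] for i in range(self.n_leaves)]
        sets += [[] for _ in range(self.n_nodes - self.n_leaves)]
        # children coalesce before parents, so a forward pass accumulates
        for node in range(self.n_nodes - 1):
            p = self.parent[node]
            if p >= 0:
                sets[p].extend(sets[node])
        return sets


# -- backward-time segments ------------------------------------------------


def _build_segments(dem: PhysicalDemography):
    """Backward timeline: list of (t0, t1, sizes_fn, mig, n_demes, merge)."""
    segs = []
    tau = 0.0
    for k in range(len(dem.epochs) - 1, -1, -1):
        ep = dem.epochs[k]
        start_sizes = dem.size_at_epoch_start(k)
        t0, t1 = tau, tau + ep.duration

        def sizes_at(t, ep=ep, start=start_sizes, t1=t1):
            # forward fraction: 1 at epoch end (backward t0), 0 at start
            f = (t1 - t) / ep.duration
            out = []
            for d in range(len(ep.sizes)):
                s0, s1, dyn = start[d], ep.sizes[d], ep.dynamics[d]
                if dyn == "sudden":
                    out.append(s1)
                elif dyn == "linear":
                    out.append(s0 + (s1 - s0) * f)
                else:
                    out.append(s0 * (s1 / s0) ** f)
            return out

        merge = dem.split_epoch is not None and k == dem.split_epoch
        segs.append((t0, t1, sizes_at, ep.mig_backward, len(ep.sizes), merge))
        tau = t1
    # ancestral segment: normally a single deme at the equilibrium size;
    # with two demes and no split the oldest epoch's structure persists
    if dem.split_epoch is None and dem.epochs and len(dem.epochs[0].sizes) == 2:
        start = dem.size_at_epoch_start(0)
        segs.append(
            (tau, np.inf, lambda t, s=start: list(s), dem.epochs[0].mig_backward, 2, False)
        )
    else:
        segs.append(
            (tau, np.inf, lambda t, N=dem.ancestral_size: [N], np.zeros((1, 1)), 1, False)
        )
    return segs


def simulate_genealogy(
    dem: PhysicalDemography,
    deme_lineage_counts: Sequence[int],
    rng: np.random.Generator | int,
    time_cap: float = 1e12,
) -> Genealogy:
    """Simulate one genealogy under the structured coalescent.

    ``deme_lineage_counts`` are haploid lineage counts sampled at present
    per deme; when the present-day demography has a single deme the counts
    are concatenated as labelled subsamples of that deme.  Deterministic
    given the generator state; raises :class:`NonCoalescingError` if no
    common ancestor is reached by ``time_cap`` generations (e.g. two
    isolated demes with no join event).
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    counts = [int(c) for c in deme_lineage_counts]
    if any(c < 0 for c in counts) or sum(counts) < 1:
        raise ValueError("need at least one lineage")
    n_leaves = sum(counts)
    leaf_demes = np.repeat(np.arange(len(counts)), counts)

    present_demes = dem.n_demes
    # lineage state: node id and deme per active lineage
    node_of = list(range(n_leaves))
    if present_demes == 1:
        deme_of = [0] * n_leaves
    else:
        if len(counts) != present_demes:
            raise ValueError(
                f"{len(counts)} sampled demes but demography has {present_demes}"
            )
        deme_of = list(leaf_demes)

    parent = list(-np.ones(n_leaves, dtype=np.int64))
    times = [0.0] * n_leaves

    if n_leaves == 1:
        return Genealogy(
            parent=np.array(parent), time=np.array(times), n_leaves=1, leaf_demes=leaf_demes
        )

    segs = _build_segments(dem)
    tau = 0.0
    for t0, t1, sizes_at, mig, n_demes, merge in segs:
        if len(node_of) == 1:
            break
        # collapse lineages into deme 0 when entering a single-deme segment
        if n_demes == 1:
            deme_of = [0] * len(deme_of)
        seg_end = min(t1, time_cap)
        while tau < seg_end and len(node_of) > 1:
            k_per = np.bincount(deme_of, minlength=n_demes)
            # bounding sizes: trajectories are monotone within an epoch
            here = sizes_at(tau)
            there = sizes_at(seg_end) if np.isfinite(seg_end) else here
            n_min = np.minimum(here, there)
            coal_max = k_per * (k_per - 1) / 2.0 / (2.0 * n_min)
            mig_rate = (k_per[:, None] * mig).sum(axis=1) if n_demes > 1 else np.zeros(1)
            lam_max = float(coal_max.sum() + mig_rate.sum())
            if lam_max <= 0:
                tau = seg_end
                break
            tau_prop = tau + rng.exponential(1.0 / lam_max)
            if tau_prop >= seg_end:
                tau = seg_end
                break
            tau = tau_prop
            now = sizes_at(tau)
            coal = k_per * (k_per - 1) / 2.0 / (2.0 * np.asarray(now))
            lam = float(coal.sum() + mig_rate.sum())
            if rng.random() * lam_max > lam:
                continue  # thinning rejection
            u = rng.random() * lam
            event_done = False
            for d in range(n_demes):
                if u < coal[d]:
                    members = [ix for ix, dd in enumerate(deme_of) if dd == d]
                    a, b = rng.choice(len(members), size=2, replace=False)
                    ia, ib = members[a], members[b]
                    new = len(parent)
                    parent.append(-1)
                    times.append(tau)
                    parent[node_of[ia]] = new
                    parent[node_of[ib]] = new
                    node_of[ia] = new
                    for lst in (node_of, deme_of):
                        lst.pop(ib)
                    event_done = True
                    break
                u -= coal[d]
            if event_done:
                continue
            for d in range(n_demes):
                for e in range(n_demes):
                    r = k_per[d] * mig[d, e]
                    if u < r:
                        members = [ix for ix, dd in enumerate(deme_of) if dd == d]
                        deme_of[members[rng.integers(len(members))]] = e
                        event_done = True
                        break
                    u -= r
                if event_done:
                    break
        if merge:
            deme_of = [0] * len(deme_of)
        if tau >= time_cap and len(node_of) > 1:
            raise NonCoalescingError(
                f"{len(node_of)} lineages remain at the {time_cap:g}-generation cap"
            )
    if len(node_of) > 1:
        raise NonCoalescingError(
            f"{len(node_of)} lineages remain at the {time_cap:g}-generation cap"
        )
    return Genealogy(
        parent=np.asarray(parent, dtype=np.int64),
        time=np.asarray(times, dtype=np.float64),
        n_leaves=n_leaves,
        leaf_demes=leaf_demes,
    )


def drop_mutations(
    gen: Genealogy,
    contig_length: int,
    mu: float,
    rng: np.random.Generator | int,
) -> list[tuple[int, np.ndarray]]:
    """Infinite-sites mutations: ``(position, derived leaf indices)`` pairs.

    The mutation count is Poisson with mean ``mu * contig_length * total
    branch length``; each mutation lands on a branch with probability
    proportional to its length and takes a distinct position on the contig.
    Monomorphic outcomes (an empty list) are allowed.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    if not np.all(np.isfinite(gen.time)):
        raise ValueError("non-finite branch lengths")
    has_parent = gen.parent >= 0
    nodes = np.flatnonzero(has_parent)
    lengths = gen.time[gen.parent[nodes]] - gen.time[nodes]
    total = float(lengths.sum())
    if total <= 0:
        return []
    n_mut = rng.poisson(mu * contig_length * total)
    if n_mut == 0:
        return []
    if n_mut > contig_length:
        raise ValueError(
            f"{n_mut} mutations exceed the {contig_length}-bp contig "
            "(infinite-sites approximation broken; reduce mu or tree depth)"
        )
    leaf_sets = gen.leaf_sets()
    branch_idx = rng.choice(len(nodes), size=n_mut, p=lengths / total)
    positions = rng.choice(contig_length, size=n_mut, replace=False) + 1
    order = np.argsort(positions)
    return [
        (int(positions[k]), np.asarray(leaf_sets[nodes[branch_idx[k]]], dtype=np.int64))
        for k in order
    ]


def branch_joint_afs(gen: Genealogy, n_demes: int = 2) -> np.ndarray:
    """Branch lengths (generations) subtending each joint frequency class.

    Entry ``(i, j)`` sums the lengths of branches whose descendant leaves
    number ``i`` in deme 0 and ``j`` in deme 1.  Averaging over replicate
    genealogies and multiplying by the per-site mutation rate gives the
    expected joint SFS -- with far less Monte-Carlo noise than counting
    realized mutations.
    """
    counts = [int(np.sum(gen.leaf_demes == d)) for d in range(n_demes)]
    out = np.zeros(tuple(c + 1 for c in counts))
    leaf_sets = gen.leaf_sets()
    for node in range(gen.n_nodes):
        p = gen.parent[node]
        if p < 0:
            continue
        length = gen.time[p] - gen.time[node]
        leaves = leaf_sets[node]
        idx = tuple(
            int(np.sum(gen.leaf_demes[leaves] == d)) for d in range(n_demes)
        )
        out[idx] += length
    return out


_BASES = np.array(list("ACGT"))


def emit_genotype_matrix(config: CoalescentConfig):
    """Simulate a full dataset: ``(GenotypeMatrix, TruthRecord)``.

    Haplotypes are paired within demes into diploids (two consecutive
    lineages per individual), missing calls are inserted independently at
    ``missing_rate``, and sites carry contig/position metadata.  Fully
    reproducible given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n_dip = config.deme_sample_sizes
    hap_counts = [2 * n for n in n_dip]
    sample_ids = []
    demes = []
    for d, n in enumerate(n_dip):
        name = config.deme_names[d]
        sample_ids += [f"{name}_{i:03d}" for i in range(n)]
        demes += [name] * n
    n_samples = len(sample_ids)

    contig_w = max(5, len(str(config.n_contigs)))
    contig_names, positions, refs, alts = [], [], [], []
    geno_cols = []
    for c in range(config.n_contigs):
        gen = simulate_genealogy(config.demography, hap_counts, rng)
        sites = drop_mutations(gen, config.contig_length, config.mu, rng)
        for pos, carriers in sites:
            hap = np.zeros(sum(hap_counts), dtype=np.int8)
            hap[carriers] = 1
            geno = hap[0::2] + hap[1::2]  # consecutive haplotypes pair up
            geno_cols.append(geno)
            contig_names.append(f"contig{c:0{contig_w}d}")
            positions.append(pos)
            ref, alt = rng.choice(4, size=2, replace=False)
            refs.append(_BASES[ref])
            alts.append(_BASES[alt])

    calls = (
        np.array(geno_cols, dtype=np.int8).T
        if geno_cols
        else np.empty((n_samples, 0), dtype=np.int8)
    )
    if config.missing_rate > 0 and calls.size:
        miss = rng.random(calls.shape) < config.missing_rate
        calls = np.where(miss, np.int8(-1), calls)

    import pandas as pd

    gm = GenotypeMatrix(
        sample_ids=sample_ids,
        demes=np.array(demes, dtype=object),
        sites=pd.DataFrame(
            {"contig": contig_names, "pos": positions, "ref": refs, "alt": alts}
        ),
        calls=calls,
    )
    truth = TruthRecord(
        config=config,
        n_segregating=gm.n_sites,
        deme_sample_sizes=tuple(n_dip),
    )
    return gm, truth


def paper_emulation_config(seed: int = 0) -> CoalescentConfig:
    """Study-design preset emulating the published dataset's structure.

    Two demes sampled at 20 and 69 diploids over 5,000 contigs of 36 bp
    with mu = 3.92e-9, under the best-fit history: an ancestral sudden
    growth episode, a very recent split with linear growth in deme 1
    ("TampaBay") and sudden growth in deme 2 ("BiscayneBay"), and one-way
    gene flow from deme 1 to deme 2 (backward: deme-2 lineages trace into
    deme 1).
    """
    Ne = 10263.0
    gen_years = 4.0
    dem = PhysicalDemography(
        ancestral_size=Ne,
        epochs=[
            PhysicalEpoch(
                duration=(390_000 - 1_532) / gen_years,
                sizes=(51_315.0,),
            ),
            PhysicalEpoch(
                duration=1_532 / gen_years,
                sizes=(158_639.0, 1_026_319.0),
                dynamics=("linear", "sudden"),
                mig_backward=np.array([[0.0, 0.0], [4.87e-4, 0.0]]),
            ),
        ],
        split_epoch=1,
    )
    return CoalescentConfig(
        deme_sample_sizes=(20, 69),
        n_contigs=5000,
        contig_length=36,
        mu=3.92e-9,
        demography=dem,
        missing_rate=0.15,
        seed=seed,
        deme_names=("TampaBay", "BiscayneBay"),
    )
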