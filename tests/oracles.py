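"""Independent Monte-Carlo oracles for the expected-SFS engine.

Two routes: msprime (an external coalescent simulator) for histories it
supports natively, and this package's own structured-coalescent simulator
for linear size trajectories.  Both accumulate *branch-length* spectra --
the expected SFS given each genealogy -- which removes mutational noise
from the comparison.  Branch lengths are halved because a unit of scaled
time is ``2 Ne`` generations while ``theta = 4 Ne mu L`` counts mutations
at rate ``theta/2`` per branch per unit time.
"""

from __future__ import annotations

import numpy as np

from demosfs.models import CATALOG
from demosfs.simulate import branch_joint_afs, physical_demography, simulate_genealogy

MSPRIME_MODELS = ("sc1ns", "sc2ns", "sc3ns", "s2m", "s2msm", "sc2el", "sc2elsm")


def informative_entries(mc: np.ndarray, se: np.ndarray, mask: np.ndarray,
                        min_rel_mean: float = 0.02) -> np.ndarray:
    """Entries where the Monte-Carlo z-statistic is valid.

    Near-empty classes receive a handful of nonzero branch contributions at
    affordable replicate counts, so their plug-in SE (and hence z) is not
    yet normal; entries below ``min_rel_mean`` of the mean unmasked MC value
    are excluded from per-entry comparisons.
    """
    floor = min_rel_mean * mc[mask].mean()
    return mask & (se > 0) & (mc > floor)


def max_z_threshold(n_entries: int, fwer: float = 0.005) -> float:
    """Simultaneous bound for per-entry 3-SE checks.

    A per-entry |z| <= 3 test applied jointly to many entries rejects a
    perfect method with probability ~1 - 0.9973^n; this returns the
    threshold whose family-wise false-alarm rate over ``n_entries``
    independent entries is ``fwer``, so the joint check keeps the intended
    per-entry meaning.
    """
    from scipy.stats import norm

    per_entry = (1.0 - fwer) ** (1.0 / n_entries)
    return float(norm.ppf((1.0 + per_entry) / 2.0))


def msprime_demography(name: str, params):
    """msprime demography in engine units (haploid sizes = nu, time in 2 Ne)."""
    import msprime

    d = msprime.Demography()
    if name == "sc1ns":
        d.add_population(name="p1", initial_size=1.0)
        return d
    if name == "sc2ns":
        nu, T = params
        d.add_population(name="p1", initial_size=nu)
        d.add_population_parameters_change(time=T, population="p1", initial_size=1.0)
        return d
    if name == "sc3ns":
        nu1, T1, nu2, T2 = params
        d.add_population(name="p1", initial_size=nu2)
        d.add_population_parameters_change(time=T2, population="p1", initial_size=nu1)
        d.add_population_parameters_change(time=T2 + T1, population="p1", initial_size=1.0)
        return d
    if name in ("s2m", "s2msm", "sc2el", "sc2elsm"):
        if name == "s2m":
            nu1, nu2, T, M12, M21 = params
            nuA = 1.0
            TA = None
        elif name == "s2msm":
            nu1, nu2, T, M = params
            M12 = M21 = M
            nuA = 1.0
            TA = None
        elif name == "sc2el":
            nuA, TA, nu1, nu2, T, M12, M21 = params
        else:
            nuA, TA, nu1, nu2, T, M = params
            M12 = M21 = M
        d.add_population(name="p1", initial_size=nu1)
        d.add_population(name="p2", initial_size=nu2)
        d.add_population(name="anc", initial_size=nuA)
        # forward flow 2->1 (M12) = backward movement of deme-1 lineages to 2
        if M12:
            d.set_migration_rate(source="p1", dest="p2", rate=M12)
        if M21:
            d.set_migration_rate(source="p2", dest="p1", rate=M21)
        d.add_population_split(time=T, derived=["p1", "p2"], ancestral="anc")
        if TA is not None:
            d.add_population_parameters_change(time=T + TA, population="anc", initial_size=1.0)
        return d
    raise ValueError(f"no msprime mapping for {name}")


def mc_expected_sfs_msprime(name, params, n1, n2, reps, seed=1):
    """(mean, SE) of the branch-mode joint AFS at theta = 1."""
    import msprime

    d = msprime_demography(name, params)
    two_pop = "p2" in {p.name for p in d.populations}
    if two_pop:
        samples = {"p1": n1, "p2": n2}
    else:
        samples = {"p1": n1 + n2}
    afs = np.zeros((n1 + 1, n2 + 1))
    sq = np.zeros_like(afs)
    for ts in msprime.sim_ancestry(
        samples=samples, demography=d, ploidy=1, num_replicates=reps, random_seed=seed
    ):
        if two_pop:
            sets = [ts.samples(population=0), ts.samples(population=1)]
        else:
            all_s = ts.samples()
            sets = [all_s[:n1], all_s[n1:]]
        a = ts.allele_frequency_spectrum(
            sample_sets=sets, mode="branch", polarised=True, span_normalise=False
        )
        afs += a
        sq += a * a
    mean = afs / reps
    se = np.sqrt(np.maximum(sq / reps - mean**2, 0.0) / reps)
    return mean / 2.0, se / 2.0


def mc_expected_sfs_own(name, params, n1, n2, reps, seed=1, Ne=1000.0):
    """Same quantity from this package's simulator (supports linear growth)."""
    dem = physical_demography(CATALOG[name].build(params), Ne)
    rng = np.random.default_rng(seed)
    afs = np.zeros((n1 + 1, n2 + 1))
    sq = np.zeros_like(afs)
    two_pop = dem.n_demes == 2
    counts = [n1, n2] if two_pop else [n1 + n2]
    for _ in range(reps):
        g = simulate_genealogy(dem, counts, rng)
        a = branch_joint_afs(g, n_demes=2) if two_pop else None
        if not two_pop:
            # label first n1 leaves deme 0, rest deme 1
            from demosfs.simulate import Genealogy

            demes = np.zeros(n1 + n2, dtype=np.int64)
            demes[n1:] = 1
            g = Genealogy(parent=g.parent, time=g.time, n_leaves=g.n_leaves, leaf_demes=demes)
            a = branch_joint_afs(g, n_demes=2)
        a = a / (2.0 * Ne)  # generations -> units of 2 Ne
        afs += a
        sq += a * a
    mean = afs / reps
    se = np.sqrt(np.maximum(sq / reps - mean**2, 0.0) / reps)
    return mean / 2.0, se / 2.0
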