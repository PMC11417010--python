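"""Structured-coalescent simulator against closed-form expectations."""

import numpy as np
import pytest

from demosfs.genotypes import MISSING
from demosfs.simulate import (
    CoalescentConfig,
    NonCoalescingError,
    PhysicalDemography,
    PhysicalEpoch,
    branch_joint_afs,
    drop_mutations,
    emit_genotype_matrix,
    paper_emulation_config,
    physical_demography,
    simulate_genealogy,
)
from demosfs.models import CATALOG


def constant_deme(N=100.0):
    return PhysicalDemography(ancestral_size=N)


class TestGenealogy:
    def test_pairwise_tmrca_closed_form(self):
        # E[T2] = 2N generations
        N = 100.0
        rng = np.random.default_rng(1)
        t = [simulate_genealogy(constant_deme(N), [2], rng).time[-1] for _ in range(20000)]
        se = np.std(t) / np.sqrt(len(t))
        assert abs(np.mean(t) - 2 * N) <= 3 * se

    def test_single_lineage_degenerate(self):
        g = simulate_genealogy(constant_deme(), [1], np.random.default_rng(0))
        assert g.n_nodes == 1
        assert g.total_branch_length() == 0.0

    def test_between_deme_coalescence_slower(self):
        # symmetric low migration: between-deme pairs coalesce later on average
        N, m = 100.0, 1e-3
        dem = PhysicalDemography(
            ancestral_size=N,
            epochs=[
                PhysicalEpoch(
                    duration=1.0,
                    sizes=(N, N),
                    mig_backward=np.array([[0.0, m], [m, 0.0]]),
                )
            ],
        )
        rng = np.random.default_rng(2)
        within, between = [], []
        for _ in range(2000):
            g = simulate_genealogy(dem, [2, 2], rng)
            sets = g.leaf_sets()

            def tmrca(a, b):
                for node in range(g.n_leaves, g.n_nodes):
                    if a in sets[node] and b in sets[node]:
                        return g.time[node]

            within.append(tmrca(0, 1))
            between.append(tmrca(0, 2))
        assert np.mean(within) < np.mean(between)

    def test_non_coalescing_isolated_demes(self):
        dem = PhysicalDemography(
            ancestral_size=100.0,
            epochs=[PhysicalEpoch(duration=1e5, sizes=(100.0, 100.0))],
        )
        with pytest.raises(NonCoalescingError):
            simulate_genealogy(dem, [2, 2], np.random.default_rng(0), time_cap=1e5)

    def test_one_way_migration_direction(self):
        # backward m[0 -> 1] only: deme-0 lineages enter deme 1, so deme-0
        # samples share deme-1 ancestry, while deme-1 lineages never visit
        # deme 0.  With tiny deme-1 size, deme-0 pairs then coalesce fast
        # through deme 1; flipping the direction they cannot.
        N0, N1 = 1e7, 10.0
        rng = np.random.default_rng(3)

        def mean_t2(mig):
            dem = PhysicalDemography(
                ancestral_size=N0,
                epochs=[PhysicalEpoch(duration=1e6, sizes=(N0, N1), mig_backward=mig)],
            )
            ts = []
            for _ in range(300):
                g = simulate_genealogy(dem, [2, 0], rng, time_cap=1e9)
                ts.append(g.time[-1])
            return np.mean(ts)

        into1 = np.array([[0.0, 1e-2], [0.0, 0.0]])  # lineages 0 -> 1
        none = np.array([[0.0, 0.0], [1e-2, 0.0]])  # lineages 1 -> 0 (irrelevant)
        assert mean_t2(into1) < 1e5  # coalesces quickly inside tiny deme 1
        assert mean_t2(none) > 1e5  # stuck in the huge deme


class TestMutations:
    def test_zero_length_tree(self):
        g = simulate_genealogy(constant_deme(), [1], np.random.default_rng(0))
        assert drop_mutations(g, 100, 1e-3, np.random.default_rng(1)) == []

    def test_watterson_segregating_sites(self):
        N, mu, L, n = 50.0, 1e-4, 100, 10
        theta = 4 * N * mu * L
        rng = np.random.default_rng(4)
        S = []
        for _ in range(4000):
            g = simulate_genealogy(constant_deme(N), [n], rng)
            S.append(len(drop_mutations(g, L, mu, rng)))
        expected = theta * sum(1.0 / i for i in range(1, n))
        se = np.std(S) / np.sqrt(len(S))
        assert abs(np.mean(S) - expected) <= 3 * se

    def test_pairwise_diversity(self):
        # E[pi] per site = 4 N mu
        N, mu, L = 50.0, 1e-4, 200
        rng = np.random.default_rng(5)
        pis = []
        for _ in range(4000):
            g = simulate_genealogy(constant_deme(N), [2], rng)
            pis.append(len(drop_mutations(g, L, mu, rng)) / L)
        se = np.std(pis) / np.sqrt(len(pis))
        assert abs(np.mean(pis) - 4 * N * mu) <= 3 * se

    def test_unfolded_sfs_matches_theta_over_i(self):
        # observed unfolded SFS over many loci ~ theta/i per class
        N, mu, L, n = 40.0, 2e-4, 50, 8
        theta = 4 * N * mu * L
        rng = np.random.default_rng(6)
        counts = np.zeros(n + 1)
        reps = 12000
        per_rep = []
        for _ in range(reps):
            g = simulate_genealogy(constant_deme(N), [n], rng)
            xi = np.zeros(n + 1)
            for _, carriers in drop_mutations(g, L, mu, rng):
                xi[len(carriers)] += 1
            per_rep.append(xi)
            counts += xi
        per_rep = np.array(per_rep)
        mean = per_rep.mean(axis=0)
        se = per_rep.std(axis=0) / np.sqrt(reps)
        for i in range(1, n):
            assert abs(mean[i] - theta / i) <= 3 * se[i], f"class {i}"


class TestGenotypeEmission:
    def small_config(self, **kw):
        dem = constant_deme(50.0)
        defaults = dict(
            deme_sample_sizes=(3, 3),
            n_contigs=40,
            contig_length=60,
            mu=2e-4,
            demography=dem,
            missing_rate=0.0,
            seed=11,
        )
        defaults.update(kw)
        return CoalescentConfig(**defaults)

    def test_no_missing_when_rate_zero(self):
        gm, _ = emit_genotype_matrix(self.small_config())
        assert not np.any(gm.calls == MISSING)

    def test_byte_identical_given_seed(self):
        a, _ = emit_genotype_matrix(self.small_config())
        b, _ = emit_genotype_matrix(self.small_config())
        assert np.array_equal(a.calls, b.calls)
        assert a.sites.equals(b.sites)

    def test_missingness_rate(self):
        gm, _ = emit_genotype_matrix(self.small_config(missing_rate=0.3, seed=12))
        frac = np.mean(gm.calls == MISSING)
        assert abs(frac - 0.3) < 0.05

    def test_truth_record(self):
        gm, truth = emit_genotype_matrix(self.small_config())
        assert truth.n_segregating == gm.n_sites
        assert truth.deme_sample_sizes == (3, 3)

    def test_deep_divergence_high_fst(self):
        from demosfs.popstructure import fst

        N = 100.0
        dem = PhysicalDemography(
            ancestral_size=N,
            epochs=[PhysicalEpoch(duration=20 * 2 * N, sizes=(N, N))],
            split_epoch=0,
        )
        cfg = CoalescentConfig(
            deme_sample_sizes=(6, 6),
            n_contigs=300,
            contig_length=100,
            mu=1e-5,
            demography=dem,
            seed=13,
        )
        gm, _ = emit_genotype_matrix(cfg)
        global_fst, _ = fst(gm)
        assert global_fst > 0.5

    def test_within_deme_exchangeability(self):
        # genotype labels within a deme are exchangeable: compare the
        # per-sample mean dosage spread against label permutations
        gm, _ = emit_genotype_matrix(self.small_config(n_contigs=150, seed=14))
        idx = gm.deme_indices("deme0")
        dosage = gm.calls[idx, :].astype(float)
        obs = np.var(dosage.mean(axis=1))
        rng = np.random.default_rng(15)
        null = []
        for _ in range(499):
            perm = dosage.ravel().copy()
            rng.shuffle(perm)
            null.append(np.var(perm.reshape(dosage.shape).mean(axis=1)))
        p = (1 + np.sum(np.array(null) >= obs)) / 500
        assert p > 0.01

    def test_odd_haploid_pairing_guard(self):
        # diploid sample sizes are integral by construction; the config
        # rejects non-positive sizes
        with pytest.raises(ValueError):
            CoalescentConfig(
                deme_sample_sizes=(0, 3),
                n_contigs=1,
                contig_length=10,
                mu=1e-8,
                demography=constant_deme(),
            )


class TestPhysicalConversion:
    def test_round_trip_scaling(self):
        model = CATALOG["s2m"].build([2.0, 0.5, 0.3, 1.5, 0.7])
        Ne = 500.0
        dem = physical_demography(model, Ne)
        ep = dem.epochs[0]
        assert ep.duration == pytest.approx(0.3 * 2 * Ne)
        assert ep.sizes == (2.0 * Ne, 0.5 * Ne)
        # forward M12 (into deme 1 from deme 2) -> backward deme-1 lineages
        # move to deme 2 at M12 / (2 Ne)
        assert ep.mig_backward[0, 1] == pytest.approx(1.5 / (2 * Ne))
        assert ep.mig_backward[1, 0] == pytest.approx(0.7 / (2 * Ne))

    def test_emulation_preset_shape(self):
        cfg = paper_emulation_config(seed=1)
        assert cfg.deme_sample_sizes == (20, 69)
        assert cfg.n_contigs == 5000 and cfg.contig_length == 36
        assert cfg.mu == pytest.approx(3.92e-9)
        assert cfg.demography.split_epoch == 1
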