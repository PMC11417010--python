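"""Shared fixtures: tiny genotype matrices built in memory."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from demosfs.genotypes import GenotypeMatrix


def make_gm(calls, demes, contigs=None, positions=None):
    """Assemble a GenotypeMatrix from a plain call matrix (rows = samples)."""
    calls = np.asarray(calls, dtype=np.int8)
    n_samples, n_sites = calls.shape
    if contigs is None:
        contigs = [f"c{j}" for j in range(n_sites)]
    if positions is None:
        positions = []
        counter = {}
        for c in contigs:
            counter[c] = counter.get(c, 0) + 1
            positions.append(counter[c])
    sites = pd.DataFrame(
        {
            "contig": contigs,
            "pos": positions,
            "ref": ["A"] * n_sites,
            "alt": ["T"] * n_sites,
        }
    )
    return GenotypeMatrix(
        sample_ids=[f"s{i}" for i in range(n_samples)],
        demes=np.array(demes, dtype=object),
        sites=sites,
        calls=calls,
    )


@pytest.fixture
def toy_gm():
    """3 samples x 4 sites with one site violating each filter rule."""
    # site 0: clean; site 1: low call rate; site 2: low MAF (needs larger
    # sample, kept simple here); site 3: all heterozygous
    calls = [
        [1, -1, 0, 1],
        [0, -1, 0, 1],
        [2, 1, 1, 1],
    ]
    return make_gm(calls, ["A", "A", "B"])


@pytest.fixture
def two_deme_gm():
    """4 + 4 diploids, 6 clean biallelic sites on 3 contigs."""
    rng = np.random.default_rng(7)
    calls = rng.integers(0, 3, size=(8, 6)).astype(np.int8)
    contigs = ["c0", "c0", "c1", "c1", "c2", "c2"]
    return make_gm(calls, ["A"] * 4 + ["B"] * 4, contigs=contigs)
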