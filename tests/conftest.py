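"""Shared fixtures: a small fast simulation and the full study-scale one."""

from __future__ import annotations

import numpy as np
import pytest

from chipq.simulate import SimConfig, make_genome, simulate_chip


def brute_force_counts(fragments, chrom, windows):
    """O(F x W) reference overlap counter (>=1 bp rule)."""
    fs, fe = fragments.fragments(chrom)
    out = []
    for lo, hi in windows:
        out.append(int(np.sum((fs < hi) & (fe > lo))))
    return out


TINY = SimConfig(n_chromosomes=2, chromosome_length=600_000, n_tdna=12,
                 n_snorna=3, n_mirna=3, library_size=200_000, n_decoy=50,
                 seed=1)

# study-scale conditions: 400 tRNA genes, half of them bound at 8-fold
# enrichment, on a 16 Mb two-chromosome genome
STUDY = SimConfig(seed=11)


@pytest.fixture(scope="session")
def tiny_sim():
    genome, annotations, truth = make_genome(TINY)
    return TINY, genome, annotations, truth


@pytest.fixture(scope="session")
def tiny_mcf7(tiny_sim):
    cfg, genome, annotations, truth = tiny_sim
    frags, chip_truth = simulate_chip(annotations, genome.chrom_lengths, cfg,
                                      truth, "mcf7_like", seed=77)
    return frags, chip_truth


@pytest.fixture(scope="session")
def study_sim():
    genome, annotations, truth = make_genome(STUDY)
    return STUDY, genome, annotations, truth
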