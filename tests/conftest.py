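import numpy as np
import pytest

from rohscan.genotype_io import MISSING, GenotypeMatrix, MarkerMap, SampleTable
import pandas as pd


def make_markers(positions, chromosomes=None):
    """MarkerMap from plain position lists (single chromosome by default)."""
    positions = np.asarray(positions, dtype=np.int64)
    if chromosomes is None:
        chromosomes = np.ones(len(positions), dtype=np.int32)
    else:
        chromosomes = np.asarray(chromosomes, dtype=np.int32)
    ids = tuple(f"snp{c}_{p}" for c, p in zip(chromosomes, positions))
    return MarkerMap(ids=ids, chromosomes=chromosomes, positions=positions)


def make_geno(calls, positions, chromosomes=None, samples=None):
    calls = np.asarray(calls, dtype=np.int8)
    if calls.ndim == 1:
        calls = calls[None, :]
    markers = make_markers(positions, chromosomes)
    if samples is None:
        samples = tuple(f"ind{i}" for i in range(calls.shape[0]))
    return GenotypeMatrix(samples=tuple(samples), markers=markers, calls=calls)


def make_sample_table(breed_of, group_of=None):
    rows = []
    for sample, breed in breed_of.items():
        group = (group_of or {}).get(sample, "European")
        rows.append(
            {
                "sample": sample,
                "breed": breed,
                "group": group,
                "category": "cosmopolitan" if group == "Cosmopolitan" else "indigenous",
            }
        )
    return SampleTable(pd.DataFrame(rows))


@pytest.fixture
def uniform_homozygous_geno():
    """300 markers every 10 kb, one fully homozygous individual (span 2.99 Mb)."""
    positions = 10_000 * np.arange(300) + 1
    return make_geno(np.zeros(300, dtype=np.int8), positions)


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)
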