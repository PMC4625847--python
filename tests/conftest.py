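"""Shared fixtures and small builders for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from mlstpop.allele_typing import AlleleCatalog, ProfileTable
from mlstpop.seqdata_io import IsolateMeta, LocusDef, MLSTDataset


def make_table(profiles, sizes=None, locus_prefix="L"):
    """Build a ProfileTable directly from allelic profiles.

    ``profiles`` is a list of allele-number tuples (one per ST, in ST
    order); ``sizes`` optionally gives isolate counts per ST (default 1).
    Allele sequences are synthesized as distinct 6-mers.
    """
    L = len(profiles[0])
    sizes = sizes or [1] * len(profiles)
    kmers = ["".join(p) for p in itertools.product("ACGT", repeat=6)]
    locus_order = [f"{locus_prefix}{j}" for j in range(L)]
    catalogs = {}
    for j, name in enumerate(locus_order):
        k = max(p[j] for p in profiles)
        catalogs[name] = AlleleCatalog(name, kmers[:k])
    st_profiles = {i + 1: tuple(p) for i, p in enumerate(profiles)}
    st_members = {
        i + 1: [f"iso_{i + 1}_{r}" for r in range(sizes[i])]
        for i in range(len(profiles))
    }
    return ProfileTable(locus_order, catalogs, st_profiles, st_members)


def make_dataset(per_locus_seqs, meta=None):
    """Dataset from {locus: {isolate: sequence}} mappings."""
    loci = []
    sequences = {}
    for name, mapping in per_locus_seqs.items():
        lengths = {len(s) for s in mapping.values()}
        assert len(lengths) == 1
        loci.append(LocusDef(name, lengths.pop(), coding=False))
        for iso, seq in mapping.items():
            sequences[(iso, name)] = seq
    metadata = {m.isolate_id: m for m in (meta or [])}
    return MLSTDataset(loci, sequences, metadata)


def random_profiles(rng: np.random.Generator, n_st: int, n_loci: int, max_allele: int):
    """Distinct random allelic profiles."""
    seen = set()
    out = []
    while len(out) < n_st:
        p = tuple(int(x) for x in rng.integers(1, max_allele + 1, size=n_loci))
        if p not in seen:
            seen.add(p)
            out.append(p)
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


@pytest.fixture
def two_locus_dataset():
    """4 isolates, 2 loci, profiles (1,1),(1,1),(2,1),(2,1)."""
    return make_dataset(
        {
            "locA": {"i1": "AAAA", "i2": "AAAA", "i3": "AAAT", "i4": "AAAT"},
            "locB": {"i1": "CCGG", "i2": "CCGG", "i3": "CCGG", "i4": "CCGG"},
        },
        meta=[IsolateMeta(f"i{k}", source="pickle") for k in range(1, 5)],
    )
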