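"""Multilocus linkage disequilibrium: I_A, I_A^S and a permutation test.

The index of association I_A = V_D/V_e - 1 compares the observed variance
V_D of pairwise allelic mismatch counts with the variance V_e expected if
alleles at different loci were independent; the standardized form
I_A^S = I_A/(L-1) removes the dependence on the number of loci L.  Both are
zero in expectation under linkage equilibrium (free recombination) and
positive in clonal populations.

Significance is assessed by independently permuting the allele column of
each locus across profiles, which preserves allele frequencies while
destroying inter-locus association, and comparing permuted V_D to the
observed value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .allele_typing import AllelicProfile, ProfileTable
from .clonal_structure import allelic_distance
from .seqdata_io import MLSTError


class UndefinedLinkageError(MLSTError):
    pass


@dataclass
class LinkageStats:
    """Observed LD summary; permutation fields filled by the test."""

    n_units: int
    l_loci: int
    v_d: float
    v_e: float
    i_a: float
    i_a_s: float
    p_value_ia: float | None = None
    n_permutations: int = 0
    seed: int | None = None
    unit: str = "isolates"

    def to_dict(self) -> dict:
        return {
            "n_units": self.n_units,
            "l_loci": self.l_loci,
            "v_d": self.v_d,
            "v_e": self.v_e,
            "i_a": self.i_a,
            "i_a_s": self.i_a_s,
            "p_value_ia": self.p_value_ia,
            "n_permutations": self.n_permutations,
            "seed": self.seed,
            "unit": self.unit,
        }


def mismatch_distribution(profiles: list[AllelicProfile]) -> list[int]:
    """Allelic distances of all unordered profile pairs (n(n-1)/2 values)."""
    if len(profiles) < 2:
        raise MLSTError("need >= 2 profiles")
    out: list[int] = []
    for i in range(len(profiles)):
        for j in range(i + 1, len(profiles)):
            out.append(allelic_distance(profiles[i], profiles[j]))
    return out


def _profiles_for_unit(table: ProfileTable, unit: str) -> list[AllelicProfile]:
    if unit == "isolates":
        profs = []
        for st in sorted(table.st_profiles):
            profs.extend([table.st_profiles[st]] * table.st_size(st))
        return profs
    if unit == "unique_sts":
        return [table.st_profiles[st] for st in sorted(table.st_profiles)]
    raise ValueError(f"unknown unit {unit!r}")


def _vd(profile_matrix: np.ndarray) -> float:
    """Population variance of the pairwise mismatch-count distribution."""
    n = profile_matrix.shape[0]
    dists = []
    for i in range(n):
        diff = (profile_matrix[i + 1 :] != profile_matrix[i]).sum(axis=1)
        dists.append(diff)
    d = np.concatenate(dists) if dists else np.array([])
    return float(d.var())  # divide by number of pairs


def index_of_association(
    profiles: list[AllelicProfile] | ProfileTable,
    unit: str = "isolates",
    h_bias: str = "unbiased",
) -> LinkageStats:
    """Compute V_D, V_e, I_A and I_A^S.

    ``h_bias="unbiased"`` applies the n/(n-1) factor to the per-locus
    mismatch probability h_j = (n/(n-1)) (1 - sum_i p_ij^2), the LIAN
    convention; ``"biased"`` omits it.  V_e = sum_j h_j (1 - h_j).
    """
    if isinstance(profiles, ProfileTable):
        profiles = _profiles_for_unit(profiles, unit)
    if len(profiles) < 3:
        raise MLSTError("need >= 3 profiles")
    lengths = {len(p) for p in profiles}
    if len(lengths) != 1:
        raise MLSTError("profiles of unequal length")
    L = lengths.pop()
    if L < 2:
        raise UndefinedLinkageError("I_A^S undefined for a single locus")
    if h_bias not in ("unbiased", "biased"):
        raise ValueError(f"unknown h_bias {h_bias!r}")
    mat = np.asarray(profiles, dtype=np.int64)
    n = mat.shape[0]
    v_d = _vd(mat)
    v_e = 0.0
    factor = n / (n - 1) if h_bias == "unbiased" else 1.0
    for j in range(L):
        _, counts = np.unique(mat[:, j], return_counts=True)
        p = counts / n
        h_j = factor * (1.0 - float(np.sum(p**2)))
        v_e += h_j * (1.0 - h_j)
    if v_e == 0.0:
        raise UndefinedLinkageError("all loci monomorphic: V_e = 0, I_A undefined")
    i_a = v_d / v_e - 1.0
    return LinkageStats(
        n_units=n, l_loci=L, v_d=v_d, v_e=v_e, i_a=i_a, i_a_s=i_a / (L - 1), unit=unit
    )


def permutation_test(
    profiles: list[AllelicProfile] | ProfileTable,
    n_perm: int = 1000,
    seed: int | None = None,
    unit: str = "isolates",
    h_bias: str = "unbiased",
) -> LinkageStats:
    """Permutation significance test for multilocus LD.

    The null is generated by independently shuffling each locus column
    across profiles; p = (1 + #{permuted V_D >= observed V_D}) / (1 + n_perm).
    Reproducible for a given seed.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if isinstance(profiles, ProfileTable):
        profiles = _profiles_for_unit(profiles, unit)
    stats = index_of_association(profiles, unit=unit, h_bias=h_bias)
    mat = np.asarray(profiles, dtype=np.int64)
    rng = np.random.default_rng(seed)
    n, L = mat.shape
    exceed = 0
    for _ in range(n_perm):
        perm = np.empty_like(mat)
        for j in range(L):
            perm[:, j] = mat[rng.permutation(n), j]
        if _vd(perm) >= stats.v_d:
            exceed += 1
    stats.p_value_ia = (1 + exceed) / (1 + n_perm)
    stats.n_permutations = n_perm
    stats.seed = seed
    return stats
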