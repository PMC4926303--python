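"""Shared fixtures and independent oracles for the test suite.

The tabular relationship-matrix oracle below recomputes A by the textbook
recurrence (dense, O(n^2)) and is deliberately independent of the package's
Meuwissen–Luo / Colleau / Henderson code paths it is used to check.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from polledsim.pedigree import FEMALE, MALE, Pedigree

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


def tabular_a(ped: Pedigree) -> np.ndarray:
    """Dense numerator relationship matrix by the tabular method (oracle)."""
    n = len(ped)
    sire = np.concatenate(([0], ped.sire))
    dam = np.concatenate(([0], ped.dam))
    a = np.zeros((n + 1, n + 1))
    for i in range(1, n + 1):
        s, d = sire[i], dam[i]
        if s == 0:
            a[i, i] = 1.0
        else:
            for j in range(1, i):
                a[i, j] = a[j, i] = 0.5 * (a[s, j] + a[d, j])
            a[i, i] = 1.0 + 0.5 * a[s, d]
    return a[1:, 1:]


def random_pedigree(
    n_founders: int = 20,
    n_offspring: int = 180,
    seed: int = 0,
    n_generations: int = 6,
) -> Pedigree:
    """A random multi-generation pedigree with both-known or both-unknown parents."""
    rng = np.random.default_rng(seed)
    ped = Pedigree()
    half = n_founders // 2
    sexes = np.array([MALE] * half + [FEMALE] * (n_founders - half), dtype=np.int8)
    ped.add_animals(0, 0, sexes, 0, rng.normal(size=n_founders))
    per_gen = n_offspring // n_generations
    for g in range(1, n_generations + 1):
        males = ped.ids[ped.sex == MALE]
        females = ped.ids[ped.sex == FEMALE]
        k = per_gen if g < n_generations else n_offspring - per_gen * (n_generations - 1)
        sires = rng.choice(males, size=k)
        dams = rng.choice(females, size=k)
        sex = rng.integers(0, 2, size=k).astype(np.int8)
        ped.add_animals(sires, dams, sex, g, rng.normal(size=k))
    return ped


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
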