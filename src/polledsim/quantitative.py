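"""Infinitesimal-model machinery for the quantitative trait.

The quantitative trait (dairy "milk yield") is female sex-limited with
heritability 0.3 on a phenotypic variance of 1; the additive genetic
standard deviation is fixed at 0.54, the printed rounding of sqrt(0.3).
Founder true breeding values (TBV) are drawn from N(0, sigma_a^2); progeny
TBV follow the usual parent-average plus Mendelian-sampling decomposition,
with the sampling variance reduced by parental inbreeding:

    TBV = (TBV_sire + TBV_dam)/2 + m,
    m ~ N(0, 0.5 sigma_a^2 (1 - (F_sire + F_dam)/2)).

Phenotypes are a single record at first (and only) opportunity:
``y = TBV + e`` with ``e ~ N(0, var_e)`` for females, missing for males.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pedigree import FEMALE

MISSING = float("nan")


@dataclass(frozen=True)
class TraitModel:
    """Parameters of the polygenic trait.

    ``sigma_a`` is taken literally as 0.54 so ``var_a = 0.2916`` and
    ``var_e = 1 - 0.2916 = 0.7084``; the variance ratio used by BLUP is
    derived from these constants rather than from the nominal ``h2``.
    """

    h2: float = 0.3
    var_p: float = 1.0
    sigma_a: float = 0.54
    mu: float = 0.0

    def __post_init__(self):
        if not 0.0 < self.h2 < 1.0:
            raise ValueError("h2 must lie in (0, 1)")
        if self.var_e < 0.0:
            raise ValueError("residual variance cannot be negative")

    @property
    def var_a(self) -> float:
        return self.sigma_a**2

    @property
    def var_e(self) -> float:
        return self.var_p - self.var_a

    @property
    def lam(self) -> float:
        """Mixed-model shrinkage ratio var_e / var_a (~2.4294)."""
        return self.var_e / self.var_a


def sample_founder_tbv(n: int, trait: TraitModel, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` founder TBVs, i.i.d. N(mu, sigma_a^2)."""
    if n <= 0:
        raise ValueError("n must be positive")
    return rng.normal(trait.mu, trait.sigma_a, size=n)


def progeny_tbv(
    tbv_sire,
    tbv_dam,
    f_sire,
    f_dam,
    trait: TraitModel,
    rng: np.random.Generator,
) -> np.ndarray:
    """Progeny TBV: mid-parent plus a Mendelian-sampling deviate.

    Accepts scalars or aligned arrays (one progeny per entry).  With fully
    inbred parents (F = 1) the sampling variance vanishes and the progeny
    TBV is exactly the mid-parent value.
    """
    tbv_sire = np.asarray(tbv_sire, dtype=float)
    tbv_dam = np.asarray(tbv_dam, dtype=float)
    f_sire = np.asarray(f_sire, dtype=float)
    f_dam = np.asarray(f_dam, dtype=float)
    if np.any(f_sire < 0) or np.any(f_sire >= 1 + 1e-12) or np.any(f_dam < 0) or np.any(
        f_dam >= 1 + 1e-12
    ):
        raise ValueError("parental inbreeding coefficients must lie in [0, 1]")
    var_m = 0.5 * trait.var_a * (1.0 - 0.5 * (f_sire + f_dam))
    mid = 0.5 * (tbv_sire + tbv_dam)
    out = mid + rng.normal(0.0, 1.0, size=mid.shape) * np.sqrt(np.maximum(var_m, 0.0))
    return out if out.shape else float(out)


def sample_phenotypes(
    sex,
    tbv,
    trait: TraitModel,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sex-limited phenotypes: ``tbv + e`` for females, NaN for males."""
    sex = np.atleast_1d(np.asarray(sex))
    tbv = np.broadcast_to(np.asarray(tbv, dtype=float), sex.shape)
    y = np.full(sex.shape, MISSING)
    fem = sex == FEMALE
    if fem.any():
        y[fem] = tbv[fem] + rng.normal(0.0, np.sqrt(trait.var_e), size=int(fem.sum()))
    return y


def sample_phenotype(animal, trait: TraitModel, rng: np.random.Generator) -> float:
    """Single-animal convenience wrapper around :func:`sample_phenotypes`."""
    return float(sample_phenotypes([animal.sex], [animal.tbv], trait, rng)[0])
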