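"""The qualitative Mendelian trait: the autosomal dominant polled locus.

Genotypes are stored as the count ``n_P`` of dominant P alleles (0 = pp
horned, 1 = Pp, 2 = PP).  Any animal carrying at least one P allele is
genetically polled.  Recorded phenotypes may disagree with the genotype:
a configurable fraction of genetically polled calves is mis-recorded as
horned at birth (scurs/horn confusion), and the record is immutable
thereafter.  Errors are one-directional; a pp animal is never recorded
polled.

Founder genotypes are not inherited but *assigned* in the generation-0
progeny cohort so that the initial breeding situation mimics the modern
polled Holstein pool: an exact low carrier frequency, all carriers
heterozygous, carrier males concentrated in a few low-merit paternal
half-sib families (hence genetically inferior and mutually related), and
carrier females drawn from the lower half of the female merit
distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pedigree import FEMALE, MALE, Pedigree

PP_HORNED = 0  # pp
PP_HET = 1  # Pp
PP_HOM = 2  # PP

GENOTYPE_LABELS = {PP_HORNED: "pp", PP_HET: "Pp", PP_HOM: "PP"}


def _iround(x: float) -> int:
    """Round half away from zero (avoids banker's rounding surprises)."""
    return int(np.floor(x + 0.5))


@dataclass(frozen=True)
class PolledRecord:
    """Genotype plus the (possibly erroneous) phenotype recorded at birth."""

    n_p: int
    recorded_polled: int
    error_flag: bool

    def __post_init__(self):
        if self.n_p not in (0, 1, 2):
            raise ValueError("n_p must be 0, 1 or 2")
        if self.n_p == 0 and self.recorded_polled:
            raise ValueError("a pp animal cannot be recorded polled")
        if self.error_flag and not (self.n_p >= 1 and self.recorded_polled == 0):
            raise ValueError("error_flag implies a polled genotype recorded horned")

    @property
    def genetically_polled(self) -> bool:
        return self.n_p >= 1


@dataclass(frozen=True)
class AssignmentTargets:
    """Targets and mechanism knobs of the founder-assignment scheme.

    ``target_freq`` is hit exactly: ``round(2N * target_freq)`` heterozygous
    carriers are created among the N cohort members.  ``male_share`` of the
    carriers are male, sampled from the below-``stratum_quantile`` TBV
    stratum of ``n_donor_families`` paternal half-sib families (this is what
    produces both the TBV deficit and the elevated relatedness of polled
    males); the remaining carriers are females sampled at random from the
    below-median TBV half of the cohort females.  ``tbv_gap`` and
    ``kinship_boost`` document the intended direction/magnitude of the
    engineered deficits and are used for validation reporting only.
    """

    target_freq: float = 0.03
    n_donor_families: int = 3
    stratum_quantile: float = 0.5
    male_share: float = 0.05
    tbv_gap: float = 0.37
    kinship_boost: float = 0.057

    def __post_init__(self):
        if not 0.0 <= self.target_freq <= 0.5:
            raise ValueError("target_freq must lie in [0, 0.5]")
        if self.n_donor_families < 1:
            raise ValueError("need at least one donor family")
        if not 0.0 < self.stratum_quantile <= 1.0:
            raise ValueError("stratum_quantile must lie in (0, 1]")
        if not 0.0 <= self.male_share <= 1.0:
            raise ValueError("male_share must lie in [0, 1]")


def inherit_genotypes(n_p_sire, n_p_dam, rng: np.random.Generator) -> np.ndarray:
    """Mendelian transmission: one allele drawn uniformly from each parent."""
    n_p_sire = np.atleast_1d(np.asarray(n_p_sire, dtype=np.int8))
    n_p_dam = np.broadcast_to(np.asarray(n_p_dam, dtype=np.int8), n_p_sire.shape)
    if ((n_p_sire < 0) | (n_p_sire > 2) | (n_p_dam < 0) | (n_p_dam > 2)).any():
        raise ValueError("genotypes must be allele counts in {0, 1, 2}")
    n = n_p_sire.shape[0]
    from_sire = rng.random(n) < n_p_sire / 2.0
    from_dam = rng.random(n) < n_p_dam / 2.0
    return (from_sire.astype(np.int8) + from_dam.astype(np.int8)).astype(np.int8)


def inherit_genotype(n_p_sire: int, n_p_dam: int, rng: np.random.Generator) -> int:
    return int(inherit_genotypes([n_p_sire], [n_p_dam], rng)[0])


def express_phenotypes(n_p, error_rate: float, rng: np.random.Generator):
    """Recorded polled phenotype at birth with one-directional errors.

    Returns ``(recorded_polled, error_flag)`` int8/bool arrays: pp is always
    recorded horned; genetically polled animals are recorded horned with
    probability ``error_rate`` (error flagged), polled otherwise.
    """
    if not 0.0 <= error_rate < 1.0:
        raise ValueError("error_rate must lie in [0, 1)")
    n_p = np.atleast_1d(np.asarray(n_p, dtype=np.int8))
    polled = n_p >= 1
    err = polled & (rng.random(n_p.shape[0]) < error_rate)
    recorded = (polled & ~err).astype(np.int8)
    return recorded, err


def express_phenotype(genotype: int, error_rate: float, rng: np.random.Generator) -> PolledRecord:
    rec, err = express_phenotypes([genotype], error_rate, rng)
    return PolledRecord(n_p=int(genotype), recorded_polled=int(rec[0]), error_flag=bool(err[0]))


def assign_founder_genotypes(
    ped: Pedigree,
    cohort_ids,
    targets: AssignmentTargets,
    rng: np.random.Generator,
    error_rate: float = 0.0,
):
    """Engineer polled genotypes in the generation-0 progeny cohort.

    Returns ``(n_p, recorded_polled, error_flag)`` arrays aligned with
    ``cohort_ids``.  Guarantees: the realised P-allele frequency equals
    ``round(2N * target_freq) / (2N)`` exactly, every carrier is
    heterozygous, carrier males sit in a handful of low-TBV half-sib
    families and carrier females in the lower TBV half.
    """
    cohort_ids = np.asarray(cohort_ids, dtype=np.int64)
    n = cohort_ids.size
    n_carriers = _iround(2 * n * targets.target_freq)
    if n_carriers > n:
        raise ValueError(
            f"target frequency {targets.target_freq} infeasible for cohort of {n}"
        )
    n_p = np.zeros(n, dtype=np.int8)
    if n_carriers == 0:
        recorded, err = express_phenotypes(n_p, error_rate, rng)
        return n_p, recorded, err

    idx0 = cohort_ids - 1
    tbv = ped.tbv[idx0]
    sex = ped.sex[idx0]
    sires = ped.sire[idx0]
    males = np.flatnonzero(sex == MALE)
    females = np.flatnonzero(sex == FEMALE)

    # -- male carriers from donor half-sib families in the low-TBV stratum
    n_male = min(_iround(targets.male_share * n_carriers), males.size)
    chosen_males: list[int] = []
    if n_male > 0 and males.size:
        thresh = np.quantile(tbv[males], targets.stratum_quantile)
        stratum = males[tbv[males] <= thresh]
        fams: dict[int, np.ndarray] = {}
        for s in np.unique(sires[stratum]):
            fams[int(s)] = stratum[sires[stratum] == s]
        fam_ids = np.array(sorted(fams))
        k = min(targets.n_donor_families, fam_ids.size)
        donors = rng.choice(fam_ids, size=k, replace=False) if k else np.array([], int)
        # spread the quota as evenly as the family supplies allow
        pools = [rng.permutation(fams[int(s)]) for s in donors]
        taken = [0] * len(pools)
        while len(chosen_males) < n_male and any(
            taken[i] < len(pools[i]) for i in range(len(pools))
        ):
            for i, pool in enumerate(pools):
                if len(chosen_males) >= n_male:
                    break
                if taken[i] < len(pool):
                    chosen_males.append(int(pool[taken[i]]))
                    taken[i] += 1
        if len(chosen_males) < n_male:  # donors exhausted: widen to the stratum
            rest = np.setdiff1d(stratum, np.array(chosen_males, int))
            extra = rng.choice(
                rest, size=min(n_male - len(chosen_males), rest.size), replace=False
            )
            chosen_males.extend(int(x) for x in extra)
    # -- female carriers at random from the lower TBV half
    n_female = n_carriers - len(chosen_males)
    chosen_females: list[int] = []
    if n_female > 0:
        if n_female > females.size:
            raise ValueError("not enough females in cohort for the carrier quota")
        lower = females[tbv[females] <= np.median(tbv[females])]
        if lower.size >= n_female:
            chosen_females = list(rng.choice(lower, size=n_female, replace=False))
        else:
            chosen_females = list(lower)
            rest = np.setdiff1d(females, lower)
            chosen_females += list(
                rng.choice(rest, size=n_female - lower.size, replace=False)
            )
    carriers = np.array(chosen_males + [int(x) for x in chosen_females], dtype=np.int64)
    n_p[carriers] = PP_HET  # all-heterozygous start, no PP founders
    recorded, err = express_phenotypes(n_p, error_rate, rng)
    return n_p, recorded, err
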