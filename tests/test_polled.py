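"""The polled locus: inheritance, phenotype expression, founder assignment."""

import numpy as np
import pytest

from polledsim import engine
from polledsim.pedigree import MALE, FEMALE, mean_relationship
from polledsim.polled import (
    AssignmentTargets,
    PolledRecord,
    assign_founder_genotypes,
    express_phenotype,
    express_phenotypes,
    inherit_genotype,
    inherit_genotypes,
)


class TestInheritance:
    def test_fixed_crosses(self, rng):
        assert inherit_genotype(0, 0, rng) == 0  # pp x pp -> pp
        assert all(inherit_genotypes([2] * 20, [0] * 20, rng) == 1)  # PP x pp -> Pp

    def test_punnett_ratios(self, rng):
        n = 100_000
        g = inherit_genotypes([1] * n, [1] * n, rng)  # Pp x Pp
        freqs = np.bincount(g, minlength=3) / n
        for obs, exp in zip(freqs, (0.25, 0.5, 0.25)):
            assert abs(obs - exp) < 3 * np.sqrt(exp * (1 - exp) / n)

    def test_support_respects_parental_alleles(self, rng):
        # exhaustive cross table: progeny genotypes lie in the Punnett support
        support = {
            (0, 0): {0}, (0, 1): {0, 1}, (0, 2): {1},
            (1, 1): {0, 1, 2}, (1, 2): {1, 2}, (2, 2): {2},
        }
        for (gs, gd), allowed in support.items():
            out = set(inherit_genotypes([gs] * 200, [gd] * 200, rng).tolist())
            assert out <= allowed

    def test_hardy_weinberg_under_random_mating(self, rng):
        # parents at allele frequency q, random pairing -> HW progeny proportions
        n, q = 100_000, 0.3
        parents = rng.binomial(2, q, size=2 * n).astype(np.int8)
        g = inherit_genotypes(parents[:n], parents[n:], rng)
        freqs = np.bincount(g, minlength=3) / n
        hw = np.array([(1 - q) ** 2, 2 * q * (1 - q), q**2])
        for obs, exp in zip(freqs, hw):
            assert abs(obs - exp) < 3 * np.sqrt(exp * (1 - exp) / n)

    def test_invalid_genotype_rejected(self, rng):
        with pytest.raises(ValueError):
            inherit_genotypes([3], [0], rng)


class TestExpression:
    def test_no_error_cases(self, rng):
        assert express_phenotype(1, 0.0, rng).recorded_polled == 1
        rec = express_phenotype(0, 0.5, rng)
        assert rec.recorded_polled == 0 and not rec.error_flag  # pp never flagged

    def test_error_rate_recovered(self, rng):
        n = 100_000
        recorded, err = express_phenotypes(np.ones(n, dtype=np.int8), 0.02, rng)
        frac_horned = 1.0 - recorded.mean()
        assert abs(frac_horned - 0.02) < 3 * np.sqrt(0.02 * 0.98 / n)
        assert np.array_equal(err, recorded == 0)

    def test_record_validation(self):
        with pytest.raises(ValueError):
            PolledRecord(n_p=0, recorded_polled=1, error_flag=False)
        with pytest.raises(ValueError):
            PolledRecord(n_p=1, recorded_polled=1, error_flag=True)
        with pytest.raises(ValueError):
            express_phenotypes([1], 1.0, np.random.default_rng(0))


@pytest.fixture(scope="module")
def gen0_state():
    """Founder phase run up to the assignment cohort (generation 0)."""
    cfg = engine.scenario_config("CONTROL", scale_factor=50, n_replicates=1, base_seed=5)
    rep = engine.run_replicate(cfg, 0, stop_after_generation=0)
    ped = rep.pedigree
    cohort = ped.ids[ped.generation == 0]
    return ped, cohort


class TestFounderAssignment:
    def test_exact_frequency_all_heterozygous(self, gen0_state):
        ped, cohort = gen0_state
        n = cohort.size
        n_p = ped.n_polled[cohort - 1]
        expected = round(2 * n * 0.03)
        assert np.count_nonzero(n_p == 1) == expected
        assert np.count_nonzero(n_p == 2) == 0  # no PP founders
        assert n_p.sum() / (2 * n) == pytest.approx(round(2 * n * 0.03) / (2 * n))

    def test_polled_males_inferior(self, gen0_state):
        ped, cohort = gen0_state
        idx = cohort - 1
        males = cohort[ped.sex[idx] == MALE]
        polled = males[ped.n_polled[males - 1] >= 1]
        horned = males[ped.n_polled[males - 1] == 0]
        assert polled.size >= 2
        assert ped.tbv[polled - 1].mean() < ped.tbv[horned - 1].mean()

    def test_polled_males_more_related_in_half_sib_structured_cohort(self, rng):
        # a cohort with many unrelated half-sib families (the situation the
        # scheme is designed for): carrier males concentrate in a few donor
        # families, so their mean relationship exceeds the horned baseline
        from polledsim.pedigree import Pedigree

        n_sires, fam = 60, 20
        ped = Pedigree()
        sires = ped.add_animals(0, 0, MALE, 0, rng.normal(0, 0.54, n_sires))
        dams = ped.add_animals(0, 0, FEMALE, 0, rng.normal(0, 0.54, n_sires * fam))
        sex = np.tile([MALE, FEMALE], n_sires * fam // 2).astype(np.int8)
        cohort = ped.add_animals(
            np.repeat(sires, fam), dams, sex, 1, rng.normal(0, 0.54, n_sires * fam)
        )
        targets = AssignmentTargets(target_freq=0.03, male_share=0.15)
        n_p, _, _ = assign_founder_genotypes(ped, cohort, targets, rng)
        males = cohort[sex == MALE]
        polled = males[n_p[sex == MALE] >= 1]
        horned = males[n_p[sex == MALE] == 0]
        assert polled.size >= 5
        sub = np.sort(rng.choice(horned, size=150, replace=False))
        assert mean_relationship(ped, polled) > mean_relationship(ped, sub)

    def test_polled_females_inferior(self, gen0_state):
        ped, cohort = gen0_state
        idx = cohort - 1
        females = cohort[ped.sex[idx] == FEMALE]
        polled = females[ped.n_polled[females - 1] >= 1]
        horned = females[ped.n_polled[females - 1] == 0]
        assert ped.tbv[polled - 1].mean() < ped.tbv[horned - 1].mean()

    def test_zero_target_gives_all_horned(self, gen0_state, rng):
        ped, cohort = gen0_state
        n_p, rec, err = assign_founder_genotypes(
            ped, cohort, AssignmentTargets(target_freq=0.0), rng
        )
        assert not n_p.any() and not rec.any() and not err.any()

    def test_infeasible_target_rejected(self):
        with pytest.raises(ValueError):
            AssignmentTargets(target_freq=0.6)

    def test_error_model_applied_at_assignment(self, gen0_state):
        ped, cohort = gen0_state
        idx = cohort - 1
        carriers = ped.n_polled[idx] >= 1
        recorded = ped.recorded_polled[idx]
        err = ped.error_flag[idx]
        assert np.array_equal(err, carriers & (recorded == 0))
        assert not recorded[~carriers].any()


def test_allele_bookkeeping_through_generations():
    # genotype counts in a cohort must be consistent with parental gametes:
    # every progeny allele must be traceable to a parent carrying it
    cfg = engine.scenario_config("GENO-ALL", scale_factor=250, n_replicates=1,
                                 n_polled_generations=5, base_seed=2)
    rep = engine.run_replicate(cfg, 0)
    ped = rep.pedigree
    for g in range(1, 6):
        ids = ped.ids[ped.generation == g]
        idx = ids - 1
        gp = ped.n_polled[idx]
        gs = ped.n_polled[ped.sire[idx] - 1]
        gd = ped.n_polled[ped.dam[idx] - 1]
        assert np.all(gp >= (gs == 2).astype(int) + (gd == 2).astype(int))
        assert np.all(gp <= (gs >= 1).astype(int) + (gd >= 1).astype(int))
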