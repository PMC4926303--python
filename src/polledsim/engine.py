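"""Scenario catalogue, the generation loop and replicate management.

A replicate simulates a closed dairy-cattle nucleus:

1. Found the population (250 sires, 50,000 dams at full scale; TBV from the
   infinitesimal model, female phenotypes recorded).
2. Five pre-generations of unweighted pedigree-BLUP truncation selection,
   during which the dam herd grows by 12.5 % per generation up to the cap
   of 75,000.  Cohorts are labelled -4 … 0; founders are generation -5.
3. Polled genotypes are assigned to the generation-0 progeny cohort at an
   exact carrier frequency, concentrated in low-merit male half-sib
   families.
4. 25 generations of the full cycle: record phenotypes at birth, re-run
   BLUP on all data to date, weight EBVs by the scenario's polled strategy,
   select/cull per sex by weighted EBV, mate at random with equal sire use,
   transmit the polled locus, express the polled phenotype with the
   phenotyping-error model.

Everything is reproducible from ``(base_seed, replicate_index)``: each
replicate runs on an independent stream obtained by spawning the scenario's
root seed sequence with the replicate index as spawn key.

A global ``scale_factor`` divides all population sizes while preserving the
selected proportions, so selection intensity — and with it allele-frequency
and genetic-gain trajectories — is approximately scale-invariant.  Rates of
inbreeding are *not* scale-invariant (dF grows as the population shrinks).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import blup, polled, quantitative, selection
from .pedigree import ACTIVE, FEMALE, MALE, Pedigree, a_matvec
from .polled import AssignmentTargets
from .quantitative import TraitModel
from .selection import GENO, NONE, PHENO, SelectionRules, WeightingScheme

logger = logging.getLogger(__name__)

GROUPS = ("active_sires", "active_dams", "progeny_males", "progeny_females")


def _iround(x: float) -> int:
    return int(np.floor(x + 0.5))


@dataclass(frozen=True)
class ScenarioConfig:
    """All knobs of one breeding scenario."""

    name: str = "CONTROL"
    scheme: WeightingScheme = field(default_factory=WeightingScheme)
    rules: SelectionRules = field(default_factory=SelectionRules)
    trait: TraitModel = field(default_factory=TraitModel)
    targets: AssignmentTargets = field(default_factory=AssignmentTargets)
    error_rate: float = 0.02
    n_founder_males: int = 250
    n_founder_females: int = 50_000
    female_growth: float = 0.125
    n_pre_generations: int = 5
    n_polled_generations: int = 25
    n_replicates: int = 20
    base_seed: int = 20160629
    scale_factor: float = 1.0
    blup_method: str = "pcg"  # warm-started each round; see docs/methods.md
    blup_tolerance: float = 1e-8
    blup_window: int | None = None  # generations of records used; None = all

    def __post_init__(self):
        if self.scale_factor < 1:
            raise ValueError("scale_factor must be >= 1")

    # -- scaled population sizes --------------------------------------------------

    def _scaled(self, x: int, minimum: int = 1) -> int:
        return max(minimum, _iround(x / self.scale_factor))

    @property
    def n_sires_scaled(self) -> int:
        return self._scaled(self.rules.n_sires, minimum=2)

    @property
    def n_dams_scaled(self) -> int:
        return self._scaled(self.rules.n_dams, minimum=4)

    @property
    def n_founder_males_scaled(self) -> int:
        return max(self.n_sires_scaled, self._scaled(self.n_founder_males, minimum=2))

    @property
    def n_founder_females_scaled(self) -> int:
        return self._scaled(self.n_founder_females, minimum=4)

    def dam_targets(self) -> list[int]:
        """Active-dam targets for the growth rounds (cohorts -4 … 0).

        The herd grows geometrically by ``female_growth`` per generation and
        is capped at the stated constant herd size the first time the cap is
        exceeded.
        """
        cap = self.n_dams_scaled
        cur = self.n_founder_females_scaled
        out = []
        for _ in range(self.n_pre_generations):
            cur = min(_iround(cur * (1.0 + self.female_growth)), cap)
            out.append(cur)
        return out

    def generation_labels(self) -> list[int]:
        """Cohort labels in simulation order: -(n_pre-1) … n_polled."""
        return list(range(-(self.n_pre_generations - 1), self.n_polled_generations + 1))


# -- scenario catalogue ------------------------------------------------------------

_CATALOGUE: dict[str, WeightingScheme] = {
    "CONTROL": WeightingScheme(NONE, NONE, 0.0, 0.0),
    "GENO-ALL": WeightingScheme(GENO, GENO, 0.5, 0.5),
    "GENO-M": WeightingScheme(GENO, NONE, 0.5, 0.0),
    "GENO-F": WeightingScheme(NONE, GENO, 0.0, 0.5),
    "PHENO-ALL": WeightingScheme(PHENO, PHENO, 0.5, 0.5),
    "PHENO-M": WeightingScheme(PHENO, NONE, 0.5, 0.0),
    "PHENO-F": WeightingScheme(NONE, PHENO, 0.0, 0.5),
    "GENO-M-PHENO-F": WeightingScheme(GENO, PHENO, 0.5, 0.5),
    "wf-M-0.1": WeightingScheme(GENO, PHENO, 0.1, 0.5),
    "wf-M-0.5": WeightingScheme(GENO, PHENO, 0.5, 0.5),  # alias of GENO-M-PHENO-F
}


def scenario_catalogue(**overrides) -> dict[str, ScenarioConfig]:
    """The named breeding scenarios with their weighting schemes."""
    return {name: scenario_config(name, **overrides) for name in _CATALOGUE}


def scenario_config(name: str, **overrides) -> ScenarioConfig:
    """Config for a named scenario; keyword overrides for any field."""
    try:
        scheme = _CATALOGUE[name]
    except KeyError:
        raise KeyError(
            f"unknown scenario {name!r}; known: {', '.join(_CATALOGUE)}"
        ) from None
    return ScenarioConfig(name=name, scheme=scheme, **overrides)


# -- results containers -------------------------------------------------------------


@dataclass
class ReplicateResult:
    """Per-generation metrics (plus the final pedigree) of one replicate."""

    scenario: str
    replicate: int
    metrics: pd.DataFrame
    pedigree: Pedigree | None = None

    def active_summary(self, generation: int | None = None) -> dict:
        """Allele frequency, mean TBV and mean F of the active population.

        Sires and dams are pooled with their group sizes as weights.
        """
        df = self.metrics
        if generation is None:
            generation = int(df["generation"].max())
        act = df[
            (df["generation"] == generation)
            & (df["group"].isin(["active_sires", "active_dams"]))
        ]
        n = act["n"].to_numpy(float)
        w = n / n.sum()
        return {
            "generation": generation,
            "freq_P": float(w @ act["freq_P"].to_numpy(float)),
            "mean_tbv": float(w @ act["mean_tbv"].to_numpy(float)),
            "mean_F": float(w @ act["mean_F"].to_numpy(float)),
            "f_PP": float(w @ act["f_PP"].to_numpy(float)),
            "frac_polled": float(w @ act["frac_polled"].to_numpy(float)),
        }

    @property
    def fixation_generation(self) -> int | None:
        """First generation with P fixed (frequency 1) in the active population."""
        gens = sorted(
            g for g in self.metrics["generation"].unique() if g >= 0
        )
        for g in gens:
            if self.active_summary(g)["freq_P"] >= 1.0 - 1e-12:
                return int(g)
        return None


@dataclass
class ScenarioResult:
    """Replicate trajectories plus endpoint summaries for one scenario."""

    config: ScenarioConfig
    replicates: list[ReplicateResult]

    @property
    def endpoints(self) -> pd.DataFrame:
        rows = []
        for rep in self.replicates:
            s = rep.active_summary()
            fix = rep.fixation_generation
            rows.append(
                {
                    "scenario": rep.scenario,
                    "replicate": rep.replicate,
                    "freq_P": s["freq_P"],
                    "mean_tbv": s["mean_tbv"],
                    "mean_F": s["mean_F"],
                    "fixation_generation": np.nan if fix is None else fix,
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> dict:
        """Endpoint row: mean ± SD over replicates (SD flagged NaN for n=1)."""
        ep = self.endpoints
        single = len(ep) < 2
        out = {"scenario": self.config.name, "n_replicates": len(ep)}
        for col in ("freq_P", "mean_tbv", "mean_F"):
            out[col] = float(ep[col].mean())
            out[f"{col}_sd"] = float("nan") if single else float(ep[col].std(ddof=1))
        return out

    @property
    def trajectory(self) -> pd.DataFrame:
        """Per-generation, per-group mean and SD over replicates."""
        df = pd.concat([r.metrics for r in self.replicates], ignore_index=True)
        value_cols = [
            c for c in df.columns if c not in ("scenario", "replicate", "generation", "group")
        ]
        g = df.groupby(["generation", "group"])[value_cols]
        agg = g.agg(["mean", "std"])
        agg.columns = [f"{a}_{b}" for a, b in agg.columns]
        return agg.reset_index()


# -- the generation loop -------------------------------------------------------------


def _replicate_rng(config: ScenarioConfig, replicate: int) -> np.random.Generator:
    ss = np.random.SeedSequence(entropy=int(config.base_seed), spawn_key=(int(replicate),))
    return np.random.default_rng(ss)


def _progeny_inbreeding(ped: Pedigree, sires: np.ndarray, dams: np.ndarray) -> np.ndarray:
    """F of each planned progeny = half the sire-dam relationship.

    Relationships are read out of sire columns of A obtained with the
    indirect (matrix-free) method, so the cost is O(n) per distinct sire.
    """
    uniq, inv = np.unique(sires, return_inverse=True)
    n = len(ped)
    e = np.zeros((n, uniq.size))
    e[uniq - 1, np.arange(uniq.size)] = 1.0
    cols = a_matvec(ped, e)
    return 0.5 * cols[dams - 1, inv]


def _group_rows(ped: Pedigree, ids: np.ndarray, scenario: str, replicate: int,
                generation: int, group: str) -> dict:
    idx = np.asarray(ids, dtype=np.int64) - 1
    n_p = ped.n_polled[idx]
    n = idx.size
    counts = np.bincount(n_p, minlength=3)
    ebv = ped.ebv[idx]
    valid = ~np.isnan(ebv)
    mean_ebv = float(ebv[valid].mean()) if valid.any() else float("nan")
    return {
        "scenario": scenario,
        "replicate": replicate,
        "generation": generation,
        "group": group,
        "n": n,
        "freq_P": float(n_p.mean() / 2.0),
        "f_pp": counts[0] / n,
        "f_Pp": counts[1] / n,
        "f_PP": counts[2] / n,
        "frac_polled": float((ped.recorded_polled[idx] == 1).mean()),
        "mean_tbv": float(ped.tbv[idx].mean()),
        "mean_F": float(ped.f[idx].mean()),
        "mean_ebv": mean_ebv,
    }


def run_replicate(
    config: ScenarioConfig,
    replicate_index: int = 0,
    keep_pedigree: bool = True,
    stop_after_generation: int | None = None,
) -> ReplicateResult:
    """Run one replicate of a breeding scenario.

    ``stop_after_generation`` truncates the run right after the metrics of
    the given cohort label have been recorded (useful to inspect the state
    at polled-allele assignment, generation 0).
    """
    rng = _replicate_rng(config, replicate_index)
    trait = config.trait
    scheme_none = WeightingScheme()

    nm0 = config.n_founder_males_scaled
    nf0 = config.n_founder_females_scaled
    n_total_rounds = config.n_pre_generations + config.n_polled_generations
    expected = nm0 + nf0 + sum(config.dam_targets()) + (
        config.n_polled_generations * config.n_dams_scaled
    )
    ped = Pedigree(capacity=expected + 16)

    founder_gen = -config.n_pre_generations
    tbv_m = quantitative.sample_founder_tbv(nm0, trait, rng)
    male_ids = ped.add_animals(0, 0, MALE, founder_gen, tbv_m, f=0.0)
    tbv_f = quantitative.sample_founder_tbv(nf0, trait, rng)
    phen_f = quantitative.sample_phenotypes(np.full(nf0, FEMALE), tbv_f, trait, rng)
    female_ids = ped.add_animals(0, 0, FEMALE, founder_gen, tbv_f, phenotype=phen_f, f=0.0)

    active_m, active_f = male_ids, female_ids
    rows = [
        _group_rows(ped, active_m, config.name, replicate_index, founder_gen, "active_sires"),
        _group_rows(ped, active_f, config.name, replicate_index, founder_gen, "active_dams"),
    ]

    dam_targets = config.dam_targets()
    prev_sol: np.ndarray | None = None
    labels = config.generation_labels()
    for round_idx, g in enumerate(labels):
        # -- mate and create the cohort
        sire_arr, dam_arr = selection.make_matings(active_m, active_f, rng)
        f_prog = _progeny_inbreeding(ped, sire_arr, dam_arr)
        tbv = quantitative.progeny_tbv(
            ped.tbv[sire_arr - 1],
            ped.tbv[dam_arr - 1],
            ped.f[sire_arr - 1],
            ped.f[dam_arr - 1],
            trait,
            rng,
        )
        sex = (rng.random(dam_arr.size) < 0.5).astype(np.int8)  # 1 = female
        phen = quantitative.sample_phenotypes(sex, tbv, trait, rng)
        if g > 0:
            n_p = polled.inherit_genotypes(
                ped.n_polled[sire_arr - 1], ped.n_polled[dam_arr - 1], rng
            )
            rec, err = polled.express_phenotypes(n_p, config.error_rate, rng)
        else:
            n_p = np.zeros(dam_arr.size, dtype=np.int8)
            rec = np.zeros(dam_arr.size, dtype=np.int8)
            err = np.zeros(dam_arr.size, dtype=bool)
        cohort = ped.add_animals(
            sire_arr,
            dam_arr,
            sex,
            g,
            tbv,
            phenotype=phen,
            n_polled=n_p,
            recorded_polled=rec,
            error_flag=err,
            f=f_prog,
            validate=False,
        )
        if g == 0:
            n_p, rec, err = polled.assign_founder_genotypes(
                ped, cohort, config.targets, rng, error_rate=config.error_rate
            )
            lo, hi = cohort[0], cohort[-1] + 1
            ped._cols["n_polled"][lo:hi] = n_p
            ped._cols["recorded_polled"][lo:hi] = rec
            ped._cols["error_flag"][lo:hi] = err

        # -- re-estimate breeding values from scratch
        records = None
        if config.blup_window is not None:
            keep = ped.generation >= g - config.blup_window
            mask = keep & ~np.isnan(ped.phenotype)
            records = (ped.ids[mask], ped.phenotype[mask])
        mme = blup.assemble_mme(ped, records=records, trait=trait)
        x0 = None
        if prev_sol is not None and (
            config.blup_method == "pcg"
            or (config.blup_method == "auto" and mme.dim > blup.DIRECT_MAX)
        ):
            pad = np.zeros(mme.dim)
            pad[: prev_sol.size] = prev_sol
            pa = 0.5 * (pad[sire_arr] + pad[dam_arr])  # parent-average start
            pad[cohort] = pa
            x0 = pad
        mu_hat, ebv = blup.solve_ebv(
            mme, tolerance=config.blup_tolerance, method=config.blup_method, x0=x0
        )
        prev_sol = np.concatenate(([mu_hat], ebv))
        ped._cols["ebv"][1 : len(ped) + 1] = ebv

        # -- weight, select and cull
        scheme = config.scheme if g >= 0 else scheme_none
        w = selection.weighted_ebvs(
            ebv, ped.n_polled, ped.recorded_polled, ped.sex, scheme
        )
        scores = np.concatenate(([np.nan], w))  # id-indexable
        cand_m = cohort[sex == MALE]
        cand_f = cohort[sex == FEMALE]
        n_target_f = (
            dam_targets[round_idx]
            if round_idx < len(dam_targets)
            else config.n_dams_scaled
        )
        active_m, active_f = selection.select_and_cull(
            cand_m,
            cand_f,
            active_m,
            active_f,
            config.rules,
            scores,
            n_target_males=config.n_sires_scaled,
            n_target_females=n_target_f,
        )

        rows += [
            _group_rows(ped, cand_m, config.name, replicate_index, g, "progeny_males"),
            _group_rows(ped, cand_f, config.name, replicate_index, g, "progeny_females"),
            _group_rows(ped, active_m, config.name, replicate_index, g, "active_sires"),
            _group_rows(ped, active_f, config.name, replicate_index, g, "active_dams"),
        ]
        if logger.isEnabledFor(logging.INFO):
            act = rows[-2:]
            logger.info(
                "%s rep %d gen %+d: freq_P sires %.4f dams %.4f, TBV %.3f/%.3f",
                config.name,
                replicate_index,
                g,
                act[0]["freq_P"],
                act[1]["freq_P"],
                act[0]["mean_tbv"],
                act[1]["mean_tbv"],
            )
        if stop_after_generation is not None and g >= stop_after_generation:
            break

    ped._cols["status"][1 : len(ped) + 1] = 0
    ped._cols["status"][np.concatenate([active_m, active_f])] = ACTIVE
    metrics = pd.DataFrame(rows)
    return ReplicateResult(
        scenario=config.name,
        replicate=replicate_index,
        metrics=metrics,
        pedigree=ped if keep_pedigree else None,
    )


def run_scenario(
    config: ScenarioConfig,
    keep_pedigrees: bool = False,
) -> ScenarioResult:
    """Run all replicates of a scenario and aggregate them."""
    if config.n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    reps = []
    for r in range(config.n_replicates):
        reps.append(run_replicate(config, r, keep_pedigree=keep_pedigrees))
        logger.info("%s replicate %d/%d done", config.name, r + 1, config.n_replicates)
    return ScenarioResult(config=config, replicates=reps)
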