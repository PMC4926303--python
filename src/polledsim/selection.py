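"""Weighted-EBV truncation selection, culling and the mating design.

Selection for the polled trait works by adding a premium to the
quantitative EBV before ranking:

* ``GENO``:  EBV_w = EBV + wf * n_P   (gene-test semantics, true genotype)
* ``PHENO``: EBV_w = EBV + wf * PT    (PT = recorded phenotype, 0/1, so
  phenotyping errors propagate into selection)
* ``NONE``:  EBV_w = EBV  (the machinery reduces exactly to the base
  breeding scheme)

Each generation and within each sex, the current active animals and the
new candidate cohort are ranked separately by weighted EBV: the top
``(1 - repl) * n`` incumbents are retained and the top ``repl * n``
candidates admitted, so the active set always has exactly ``n`` members.
Ties are broken toward the lower animal id.  Selected sires are used
equally: the dams are randomly permuted and split into equal blocks, one
block per sire, one mating (one progeny) per dam.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pedigree import FEMALE, MALE

NONE = "NONE"
GENO = "GENO"
PHENO = "PHENO"

_STRATEGIES = (NONE, GENO, PHENO)


def _iround(x: float) -> int:
    return int(np.floor(x + 0.5))


class SelectionError(ValueError):
    """Structural problem in selection or mating inputs."""


@dataclass(frozen=True)
class WeightingScheme:
    """Per-sex polled selection strategy and weighting factor."""

    strategy_male: str = NONE
    strategy_female: str = NONE
    wf_male: float = 0.0
    wf_female: float = 0.0

    def __post_init__(self):
        for s in (self.strategy_male, self.strategy_female):
            if s not in _STRATEGIES:
                raise ValueError(f"unknown strategy {s!r}")
        for wf in (self.wf_male, self.wf_female):
            if wf < 0:
                raise ValueError("weighting factors must be non-negative")

    def for_sex(self, sex: int) -> tuple[str, float]:
        if sex == MALE:
            return self.strategy_male, self.wf_male
        return self.strategy_female, self.wf_female


@dataclass(frozen=True)
class SelectionRules:
    """Active population sizes and per-generation replacement rates."""

    n_sires: int = 250
    n_dams: int = 75_000
    repl_sires: float = 0.50
    repl_dams: float = 0.25

    def __post_init__(self):
        if self.n_sires < 1 or self.n_dams < 1:
            raise ValueError("active population sizes must be positive")
        for r in (self.repl_sires, self.repl_dams):
            if not 0.0 <= r <= 1.0:
                raise ValueError("replacement rates must lie in [0, 1]")

    @property
    def progeny_per_sire(self) -> float:
        return self.n_dams / self.n_sires


def weight_ebv(ebv: float, polled_record, sex: int, scheme: WeightingScheme) -> float:
    """Weighted EBV of one animal under the scheme applying to its sex."""
    strategy, wf = scheme.for_sex(sex)
    if strategy == NONE:
        return float(ebv)
    if strategy == GENO:
        return float(ebv + wf * polled_record.n_p)
    return float(ebv + wf * polled_record.recorded_polled)


def weighted_ebvs(
    ebv: np.ndarray,
    n_p: np.ndarray,
    recorded_polled: np.ndarray,
    sex: np.ndarray,
    scheme: WeightingScheme,
) -> np.ndarray:
    """Vectorised weighted EBVs for a whole population."""
    out = np.asarray(ebv, dtype=float).copy()
    sex = np.asarray(sex)
    for s in (MALE, FEMALE):
        strategy, wf = scheme.for_sex(s)
        if strategy == NONE:
            continue
        mask = sex == s
        bonus = n_p if strategy == GENO else recorded_polled
        out[mask] += wf * np.asarray(bonus, dtype=float)[mask]
    return out


def rank_top(ids: np.ndarray, scores: np.ndarray, k: int) -> np.ndarray:
    """Top-k ids by score, descending, ties broken toward the lower id."""
    if k < 0:
        raise ValueError("k must be non-negative")
    order = np.lexsort((ids, -np.asarray(scores, dtype=float)))
    return np.asarray(ids)[order[:k]]


def replace_active(
    incumbent_ids: np.ndarray,
    candidate_ids: np.ndarray,
    scores: np.ndarray,
    n_target: int,
    repl: float,
) -> np.ndarray:
    """One sex's selection round: cull incumbents, admit candidates.

    ``scores`` is an array of weighted EBVs indexable by animal id
    (padded: entry ``i`` is animal ``i``'s score).  The number of retained
    incumbents is ``round((1 - repl) * current size)``; the remainder of
    the ``n_target`` slots is filled from the candidates.
    """
    incumbent_ids = np.asarray(incumbent_ids, dtype=np.int64)
    candidate_ids = np.asarray(candidate_ids, dtype=np.int64)
    n_keep = min(_iround((1.0 - repl) * incumbent_ids.size), n_target)
    n_admit = n_target - n_keep
    if candidate_ids.size < n_admit:
        raise SelectionError(
            f"{n_admit} replacement slots but only {candidate_ids.size} candidates"
        )
    kept = rank_top(incumbent_ids, scores[incumbent_ids], n_keep)
    admitted = rank_top(candidate_ids, scores[candidate_ids], n_admit)
    return np.sort(np.concatenate([kept, admitted]))


def select_and_cull(
    candidates_male,
    candidates_female,
    active_males,
    active_females,
    rules: SelectionRules,
    scores: np.ndarray,
    n_target_males: int | None = None,
    n_target_females: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-sex truncation selection with EBV-based culling.

    ``scores`` is the id-indexable weighted-EBV array.  Targets default to
    the rules' active sizes; the engine passes explicit targets during the
    herd-growth phase.
    """
    nm = rules.n_sires if n_target_males is None else n_target_males
    nf = rules.n_dams if n_target_females is None else n_target_females
    new_m = replace_active(active_males, candidates_male, scores, nm, rules.repl_sires)
    new_f = replace_active(active_females, candidates_female, scores, nf, rules.repl_dams)
    return new_m, new_f


def make_matings(
    active_sires,
    active_dams,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Random mating with equal sire use; one mating per dam.

    Dams are randomly permuted and partitioned into equal contiguous
    blocks, one per sire; when the dam count is not divisible by the sire
    count the remainder dams go one-per-sire to the lowest-id sires.
    Returns aligned ``(sire_id, dam_id)`` arrays, one entry per mating.
    """
    sires = np.sort(np.asarray(active_sires, dtype=np.int64))
    dams = np.asarray(active_dams, dtype=np.int64)
    if sires.size == 0 or dams.size == 0:
        raise SelectionError("cannot mate with an empty active set")
    perm = rng.permutation(dams)
    base, rem = divmod(dams.size, sires.size)
    counts = np.full(sires.size, base, dtype=np.int64)
    counts[:rem] += 1
    sire_per_mating = np.repeat(sires, counts)
    return sire_per_mating, perm
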