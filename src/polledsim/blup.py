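"""Pedigree-BLUP animal model: y = 1*mu + Z*a + e.

Every generation the simulator re-estimates breeding values from scratch
from all phenotypes recorded so far and the full pedigree.  The only fixed
effect is the overall mean.  Henderson's mixed-model equations are

    [ n_rec   1'Z          ] [ mu ]   [ 1'y ]
    [ Z'1     Z'Z + lam A⁻¹] [ a  ] = [ Z'y ],

with ``lam = var_e / var_a`` and the sparse A-inverse from Henderson's
rules with inbreeding.  Animals without records (and without recorded
descendants) come out at their parent-average EBV, a standard property of
the equations.

Two solvers are provided: a direct sparse LU factorisation (deterministic,
used by default up to ``DIRECT_MAX`` equations) and a Jacobi-preconditioned
conjugate gradient for larger systems, which accepts a warm start.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse import linalg as spla

from .pedigree import Pedigree, a_inverse
from .quantitative import TraitModel

DIRECT_MAX = 200_000


class BlupError(RuntimeError):
    """Numerical failure while solving the mixed-model equations."""


@dataclass
class MmeSystem:
    """Assembled mixed-model equations.

    ``coef`` is symmetric positive definite once ``lam * A_inverse`` has
    been added with ``lam > 0`` and at least one record is present.  When
    ``fit_mean`` the leading equation belongs to the overall mean.
    """

    coef: sparse.csr_matrix
    rhs: np.ndarray
    lam: float
    n_animals: int
    n_records: int
    fit_mean: bool = True
    degenerate: bool = field(default=False)

    @property
    def dim(self) -> int:
        return self.coef.shape[0]


def assemble_mme(
    ped: Pedigree,
    records=None,
    trait: TraitModel | None = None,
    fit_mean: bool = True,
) -> MmeSystem:
    """Build the mixed-model equations for the given pedigree and records.

    ``records`` is a pair ``(animal_ids, values)``; by default all non-missing
    phenotypes stored in the pedigree are used.  A system with no records is
    returned flagged ``degenerate`` (the mean equation is singular).
    """
    trait = trait or TraitModel()
    n = len(ped)
    if records is None:
        mask = ~np.isnan(ped.phenotype)
        rec_ids = ped.ids[mask]
        y = ped.phenotype[mask]
    else:
        rec_ids = np.asarray(records[0], dtype=np.int64)
        y = np.asarray(records[1], dtype=np.float64)
        if rec_ids.size and (rec_ids.min() < 1 or rec_ids.max() > n):
            raise KeyError("record refers to an animal not in the pedigree")
    lam = trait.lam

    zz = np.bincount(rec_ids - 1, minlength=n).astype(np.float64)
    zy = np.bincount(rec_ids - 1, weights=y, minlength=n)
    ainv = a_inverse(ped)
    animal_block = sparse.diags(zz) + lam * ainv
    if fit_mean:
        z_row = sparse.csr_matrix(zz[None, :])
        coef = sparse.bmat(
            [
                [sparse.csr_matrix(np.array([[float(rec_ids.size)]])), z_row],
                [z_row.T, animal_block],
            ],
            format="csr",
        )
        rhs = np.concatenate(([y.sum()], zy))
    else:
        coef = animal_block.tocsr()
        rhs = zy
    return MmeSystem(
        coef=coef,
        rhs=rhs,
        lam=lam,
        n_animals=n,
        n_records=int(rec_ids.size),
        fit_mean=fit_mean,
        degenerate=rec_ids.size == 0,
    )


def solve_ebv(
    mme: MmeSystem,
    tolerance: float = 1e-8,
    method: str = "auto",
    x0: np.ndarray | None = None,
    maxiter: int = 5000,
):
    """Solve the mixed-model equations; returns ``(mu_hat, ebv)``.

    ``method`` is ``"direct"`` (sparse LU), ``"pcg"`` (Jacobi-preconditioned
    conjugate gradient on a relative-residual tolerance, optional warm start
    ``x0`` in solution order) or ``"auto"`` which picks direct below
    ``DIRECT_MAX`` equations.
    """
    if mme.degenerate and mme.fit_mean:
        raise BlupError("no records: the mean equation is degenerate")
    if method == "auto":
        method = "direct" if mme.dim <= DIRECT_MAX else "pcg"
    if method == "direct":
        lu = spla.splu(mme.coef.tocsc(), permc_spec="MMD_AT_PLUS_A")
        sol = lu.solve(mme.rhs)
    elif method == "pcg":
        diag = mme.coef.diagonal()
        m_inv = sparse.diags(1.0 / np.where(diag > 0, diag, 1.0))
        sol, info = spla.cg(
            mme.coef,
            mme.rhs,
            x0=x0,
            rtol=tolerance,
            atol=0.0,
            maxiter=maxiter,
            M=m_inv,
        )
        if info != 0:
            raise BlupError(
                f"conjugate gradient did not converge (info={info}, dim={mme.dim})"
            )
    else:
        raise ValueError(f"unknown solver method {method!r}")
    if mme.fit_mean:
        return float(sol[0]), sol[1:]
    return 0.0, sol
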