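"""Pedigree bookkeeping and relationship algebra.

The :class:`Pedigree` is an append-only, topologically ordered registry of
animals (parents always precede offspring).  It is the source of all
relationship algebra used elsewhere in the package:

* inbreeding coefficients ``F`` by the Meuwissen & Luo recursion,
* numerator relationships ``a_ij`` (tabular definition, evaluated with
  Colleau's indirect method so the full matrix is never materialised),
* the sparse inverse of the numerator relationship matrix ``A`` by
  Henderson's rules with inbreeding, as needed by the BLUP animal model,
* the per-generation rate of inbreeding ``ΔF``.

Animals are identified by 1-based integer ids equal to their insertion
order.  Unknown parents are encoded as ``0``; an animal either has both
parents known or both unknown (a founder).
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse

UNKNOWN = 0
MALE = 0
FEMALE = 1

_SEX_LABEL = {MALE: "M", FEMALE: "F"}
_SEX_CODE = {"M": MALE, "F": FEMALE}

ACTIVE = 1
CULLED = 0

_FIELDS = (
    ("sire", np.int64, 0),
    ("dam", np.int64, 0),
    ("sex", np.int8, 0),
    ("generation", np.int32, 0),
    ("tbv", np.float64, np.nan),
    ("phenotype", np.float64, np.nan),
    ("n_polled", np.int8, 0),
    ("recorded_polled", np.int8, 0),
    ("error_flag", np.bool_, False),
    ("ebv", np.float64, np.nan),
    ("f", np.float64, np.nan),
    ("status", np.int8, CULLED),
)


class PedigreeError(ValueError):
    """Structural problem in a pedigree (ordering, parent sex, cycles)."""


@dataclass
class Animal:
    """Read-only snapshot of one pedigree entry."""

    id: int
    sire_id: int
    dam_id: int
    sex: int
    generation: int
    tbv: float
    phenotype: float
    n_polled: int
    recorded_polled: int
    error_flag: bool
    ebv: float
    f: float
    status: int

    @property
    def is_founder(self) -> bool:
        return self.sire_id == UNKNOWN and self.dam_id == UNKNOWN


class Pedigree:
    """Columnar, append-only pedigree with 1-based ids.

    Internally every column is padded with a sentinel row at index 0 so that
    unknown parents (id 0) can be used directly as array indices; the
    sentinel absorbs contributions in the pedigree sweeps below.
    """

    def __init__(self, capacity: int = 1024) -> None:
        self._n = 0
        self._cap = max(int(capacity), 16)
        self._cols = {
            name: np.full(self._cap + 1, fill, dtype=dt) for name, dt, fill in _FIELDS
        }
        # depth level: 0 for founders, 1 + max(parent levels) otherwise
        self._level = np.zeros(self._cap + 1, dtype=np.int32)
        # Mendelian (within-family) variance share d_i used by both the
        # Colleau sweeps and Henderson's rules: 1 for founders,
        # 0.5 - 0.25 (F_s + F_d) otherwise.  Valid only where F is known.
        self._d = np.ones(self._cap + 1, dtype=np.float64)

    # -- basic container protocol -------------------------------------------------

    def __len__(self) -> int:
        return self._n

    @property
    def ids(self) -> np.ndarray:
        return np.arange(1, self._n + 1, dtype=np.int64)

    def _col(self, name: str) -> np.ndarray:
        """Per-animal view of a column (index i-1 holds animal i)."""
        return self._cols[name][1 : self._n + 1]

    sire = property(lambda self: self._col("sire"))
    dam = property(lambda self: self._col("dam"))
    sex = property(lambda self: self._col("sex"))
    generation = property(lambda self: self._col("generation"))
    tbv = property(lambda self: self._col("tbv"))
    phenotype = property(lambda self: self._col("phenotype"))
    n_polled = property(lambda self: self._col("n_polled"))
    recorded_polled = property(lambda self: self._col("recorded_polled"))
    error_flag = property(lambda self: self._col("error_flag"))
    ebv = property(lambda self: self._col("ebv"))
    f = property(lambda self: self._col("f"))
    status = property(lambda self: self._col("status"))

    def animal(self, aid: int) -> Animal:
        if not 1 <= aid <= self._n:
            raise KeyError(f"animal id {aid} not in pedigree of size {self._n}")
        g = {name: self._cols[name][aid] for name, _, _ in _FIELDS}
        return Animal(
            id=aid,
            sire_id=int(g["sire"]),
            dam_id=int(g["dam"]),
            sex=int(g["sex"]),
            generation=int(g["generation"]),
            tbv=float(g["tbv"]),
            phenotype=float(g["phenotype"]),
            n_polled=int(g["n_polled"]),
            recorded_polled=int(g["recorded_polled"]),
            error_flag=bool(g["error_flag"]),
            ebv=float(g["ebv"]),
            f=float(g["f"]),
            status=int(g["status"]),
        )

    # -- growth -------------------------------------------------------------------

    def _reserve(self, extra: int) -> None:
        need = self._n + extra
        if need <= self._cap:
            return
        new_cap = self._cap
        while new_cap < need:
            new_cap *= 2
        for name, dt, fill in _FIELDS:
            col = np.full(new_cap + 1, fill, dtype=dt)
            col[: self._cap + 1] = self._cols[name]
            self._cols[name] = col
        for attr in ("_level", "_d"):
            old = getattr(self, attr)
            col = np.zeros(new_cap + 1, dtype=old.dtype)
            if attr == "_d":
                col[:] = 1.0
            col[: self._cap + 1] = old
            setattr(self, attr, col)
        self._cap = new_cap

    def add_animals(
        self,
        sire,
        dam,
        sex,
        generation,
        tbv,
        phenotype=None,
        n_polled=None,
        recorded_polled=None,
        error_flag=None,
        f=None,
        validate: bool = True,
    ) -> np.ndarray:
        """Append a batch of animals; returns their new ids.

        Parents must already be present (strictly smaller id) or be
        ``UNKNOWN`` for founders; mixed known/unknown parent pairs are
        rejected.  If ``f`` is omitted the inbreeding coefficients are left
        unset (``NaN``) until :func:`inbreeding_coefficients` fills them.
        """
        sire = np.atleast_1d(np.asarray(sire, dtype=np.int64))
        (k,) = np.broadcast_shapes(
            sire.shape,
            np.atleast_1d(np.asarray(dam)).shape,
            np.atleast_1d(np.asarray(sex)).shape,
            np.atleast_1d(np.asarray(generation)).shape,
            np.atleast_1d(np.asarray(tbv)).shape,
        )
        sire = np.broadcast_to(sire, (k,))
        dam = np.broadcast_to(np.asarray(dam, dtype=np.int64), (k,))
        sex = np.broadcast_to(np.asarray(sex, dtype=np.int8), (k,))
        generation = np.broadcast_to(np.asarray(generation, dtype=np.int32), (k,))
        tbv = np.broadcast_to(np.asarray(tbv, dtype=np.float64), (k,))

        if validate:
            founder = (sire == UNKNOWN) & (dam == UNKNOWN)
            mixed = (sire == UNKNOWN) ^ (dam == UNKNOWN)
            if mixed.any():
                raise PedigreeError("animals must have both parents known or both unknown")
            known = ~founder
            if known.any():
                new_ids = self._n + 1 + np.arange(k)
                if (sire[known] >= new_ids[known]).any() or (dam[known] >= new_ids[known]).any():
                    raise PedigreeError("parents must precede offspring (smaller id)")
                # parents may sit inside this same batch: look up sex accordingly
                all_sex = np.concatenate((self._cols["sex"][: self._n + 1], sex))
                if (all_sex[sire[known]] != MALE).any():
                    raise PedigreeError("sire must be male")
                if (all_sex[dam[known]] != FEMALE).any():
                    raise PedigreeError("dam must be female")

        self._reserve(k)
        lo, hi = self._n + 1, self._n + k + 1
        ids = np.arange(lo, hi, dtype=np.int64)
        c = self._cols
        c["sire"][lo:hi] = sire
        c["dam"][lo:hi] = dam
        c["sex"][lo:hi] = sex
        c["generation"][lo:hi] = generation
        c["tbv"][lo:hi] = tbv
        if phenotype is not None:
            c["phenotype"][lo:hi] = np.broadcast_to(np.asarray(phenotype, np.float64), (k,))
        else:
            c["phenotype"][lo:hi] = np.nan
        c["n_polled"][lo:hi] = (
            0 if n_polled is None else np.broadcast_to(np.asarray(n_polled, np.int8), (k,))
        )
        c["recorded_polled"][lo:hi] = (
            0
            if recorded_polled is None
            else np.broadcast_to(np.asarray(recorded_polled, np.int8), (k,))
        )
        c["error_flag"][lo:hi] = (
            False if error_flag is None else np.broadcast_to(np.asarray(error_flag, bool), (k,))
        )
        c["ebv"][lo:hi] = np.nan
        c["f"][lo:hi] = np.nan if f is None else np.broadcast_to(np.asarray(f, np.float64), (k,))
        c["status"][lo:hi] = CULLED

        internal = (sire >= lo) | (dam >= lo)
        if not internal.any():
            self._level[lo:hi] = np.where(
                sire == UNKNOWN,
                0,
                1 + np.maximum(self._level[sire], self._level[dam]),
            )
        else:  # parents within the batch: resolve depths sequentially
            lev = self._level
            for j in range(k):
                s = sire[j]
                lev[lo + j] = 0 if s == UNKNOWN else 1 + max(lev[s], lev[dam[j]])
        fs = c["f"][sire].copy()
        fd = c["f"][dam].copy()
        self._d[lo:hi] = np.where(sire == UNKNOWN, 1.0, 0.5 - 0.25 * (fs + fd))
        self._n += k
        return ids

    # -- inbreeding / relationship algebra ----------------------------------------

    def ensure_f(self) -> np.ndarray:
        """Return the F vector, computing it with Meuwissen–Luo if unset."""
        fcol = self.f
        if np.isnan(fcol).any():
            set_inbreeding(self, inbreeding_coefficients(self))
        return self.f

    def mendelian_share(self) -> np.ndarray:
        """Per-animal d_i = Var(mendelian sampling)/sigma_a^2 (founders: 1)."""
        self.ensure_f()
        return self._d[1 : self._n + 1].copy()

    def level_blocks(self):
        """Indices (padded, id == index) grouped by pedigree depth, ascending."""
        lev = self._level[1 : self._n + 1]
        order = np.argsort(lev, kind="stable") + 1
        counts = np.bincount(lev)
        blocks = []
        start = 0
        for c in counts:
            blocks.append(order[start : start + c])
            start += c
        return blocks

    def to_frame(self) -> pd.DataFrame:
        sex = np.array([_SEX_LABEL[s] for s in self.sex])
        rec = np.where(self.recorded_polled == 1, "P", "H")
        return pd.DataFrame(
            {
                "id": self.ids,
                "sire_id": self.sire,
                "dam_id": self.dam,
                "sex": sex,
                "generation": self.generation,
                "tbv": self.tbv,
                "phenotype": self.phenotype,
                "polled_genotype": self.n_polled,
                "recorded_phenotype": rec,
                "ebv": self.ebv,
                "F": self.f,
                "status": np.where(self.status == ACTIVE, "active", "culled"),
            }
        )


def set_inbreeding(ped: Pedigree, f: np.ndarray) -> None:
    """Write an F vector into the pedigree and refresh the Mendelian shares."""
    n = len(ped)
    ped._cols["f"][1 : n + 1] = f
    sire = ped._cols["sire"][1 : n + 1]
    dam = ped._cols["dam"][1 : n + 1]
    fpad = ped._cols["f"]
    ped._d[1 : n + 1] = np.where(
        sire == UNKNOWN, 1.0, 0.5 - 0.25 * (fpad[sire] + fpad[dam])
    )


def inbreeding_coefficients(ped: Pedigree) -> np.ndarray:
    """Pedigree inbreeding coefficients by the Meuwissen & Luo recursion.

    Processes animals in id order; for animal ``i`` the diagonal
    ``a_ii = 1 + F_i`` is accumulated as ``sum_j v_j^2 d_j`` over the
    ancestors ``j`` of ``i``, where ``v_j`` are path coefficients collected
    by a descending-id traversal and ``d_j`` the within-family variance
    shares.  Founders get ``F = 0`` by definition.
    """
    n = len(ped)
    sire = ped._cols["sire"]
    dam = ped._cols["dam"]
    if n and (ped.sire >= ped.ids).any() or n and (ped.dam >= ped.ids).any():
        raise PedigreeError("pedigree is not topologically ordered (possible cycle)")
    F = np.zeros(n + 1)
    d = np.ones(n + 1)
    v = np.zeros(n + 1)
    for i in range(1, n + 1):
        s, dm = sire[i], dam[i]
        if s == UNKNOWN:
            F[i] = 0.0
            d[i] = 1.0
            continue
        d[i] = 0.5 - 0.25 * (F[s] + F[dm])
        # descending traversal of the ancestor set of i
        aii = 0.0
        v[i] = 1.0
        heap = [-i]
        in_heap = {i}
        while heap:
            j = -heapq.heappop(heap)
            vj = v[j]
            v[j] = 0.0
            aii += vj * vj * d[j]
            sj, dj = sire[j], dam[j]
            if sj != UNKNOWN:
                half = 0.5 * vj
                v[sj] += half
                v[dj] += half
                if sj not in in_heap:
                    in_heap.add(sj)
                    heapq.heappush(heap, -sj)
                if dj not in in_heap:
                    in_heap.add(dj)
                    heapq.heappush(heap, -dj)
        F[i] = aii - 1.0
    return F[1:]


def a_matvec(ped: Pedigree, x: np.ndarray) -> np.ndarray:
    """Product ``A @ x`` of the numerator relationship matrix with a vector.

    Uses the factorisation ``A = T D T'`` (T the gene-flow matrix, D the
    diagonal of Mendelian variance shares) and evaluates both triangular
    products by generation-blocked pedigree sweeps, so the cost is
    O(n) per column and A is never formed.
    """
    n = len(ped)
    x = np.asarray(x, dtype=np.float64)
    single = x.ndim == 1
    if single:
        x = x[:, None]
    if x.shape[0] != n:
        raise ValueError("x must have one row per animal")
    ped.ensure_f()
    sire = ped._cols["sire"]
    dam = ped._cols["dam"]
    d = ped._d[: n + 1]
    blocks = ped.level_blocks()

    b = np.zeros((n + 1, x.shape[1]))
    b[1:] = x
    for idx in reversed(blocks[1:]):  # founders transmit nothing upward
        contrib = 0.5 * b[idx]
        np.add.at(b, sire[idx], contrib)
        np.add.at(b, dam[idx], contrib)
        b[0] = 0.0
    y = b
    y *= d[:, None]
    for idx in blocks[1:]:
        y[idx] += 0.5 * (y[sire[idx]] + y[dam[idx]])
    out = y[1:]
    return out[:, 0] if single else out


def relationship_matrix(ped: Pedigree, subset=None) -> np.ndarray:
    """Dense numerator relationships ``a_ij`` for a subset of animals.

    ``a_ii = 1 + F_i``; off-diagonals follow the tabular recurrence.  The
    subset columns are extracted with :func:`a_matvec`, which keeps the
    cost at O(n * len(subset)).
    """
    n = len(ped)
    if subset is None:
        subset = ped.ids
    subset = np.asarray(subset, dtype=np.int64)
    if subset.size and (subset.min() < 1 or subset.max() > n):
        raise KeyError("subset member not in pedigree")
    e = np.zeros((n, subset.size))
    e[subset - 1, np.arange(subset.size)] = 1.0
    cols = a_matvec(ped, e)
    out = cols[subset - 1]
    return 0.5 * (out + out.T)  # symmetrise away float noise


def mean_relationship(ped: Pedigree, ids) -> float:
    """Mean pairwise ``a_ij`` within a group, excluding the diagonal."""
    ids = np.asarray(ids, dtype=np.int64)
    m = ids.size
    if m < 2:
        return float("nan")
    a = relationship_matrix(ped, ids)
    return float((a.sum() - np.trace(a)) / (m * (m - 1)))


def a_inverse(ped: Pedigree) -> sparse.csr_matrix:
    """Sparse inverse of A by Henderson's rules with inbreeding.

    Each animal contributes ``alpha_i = 1/d_i`` on its diagonal plus the
    usual parent cross terms; founders contribute identity entries.
    """
    n = len(ped)
    ped.ensure_f()
    sire0 = ped.sire - 1  # 0-based, -1 = unknown
    dam0 = ped.dam - 1
    alpha = 1.0 / ped._d[1 : n + 1]
    i0 = np.arange(n)
    known = sire0 >= 0

    rows = [i0]
    cols = [i0]
    vals = [alpha]
    if known.any():
        i = i0[known]
        s = sire0[known]
        dm = dam0[known]
        a = alpha[known]
        rows += [s, i, dm, i, s, dm, s, dm]
        cols += [i, s, i, dm, s, dm, dm, s]
        vals += [-a / 2, -a / 2, -a / 2, -a / 2, a / 4, a / 4, a / 4, a / 4]
    ainv = sparse.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    )
    return ainv.tocsr()


def delta_f(mean_f_t: float, mean_f_prev: float) -> float:
    """Per-generation rate of inbreeding (F_t - F_{t-1}) / (1 - F_{t-1})."""
    if mean_f_prev >= 1.0:
        raise ZeroDivisionError("previous mean inbreeding must be < 1")
    return (mean_f_t - mean_f_prev) / (1.0 - mean_f_prev)


# -- TSV interface ---------------------------------------------------------------

_TSV_COLUMNS = [
    "id",
    "sire_id",
    "dam_id",
    "sex",
    "generation",
    "tbv",
    "phenotype",
    "polled_genotype",
    "recorded_phenotype",
    "ebv",
    "F",
    "status",
]


def write_pedigree_tsv(ped: Pedigree, path) -> None:
    """Write the pedigree as a tab-separated table (one row per animal).

    Unknown parents are written as 0 and missing phenotypes as ``NA``.
    """
    ped.to_frame().to_csv(path, sep="\t", index=False, na_rep="NA")


def read_pedigree_tsv(path) -> Pedigree:
    """Load a pedigree written by :func:`write_pedigree_tsv`."""
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    missing = [c for c in _TSV_COLUMNS if c not in df.columns]
    if missing:
        raise PedigreeError(f"pedigree TSV missing columns: {missing}")
    if not (df["id"].to_numpy() == np.arange(1, len(df) + 1)).all():
        raise PedigreeError("pedigree TSV ids must be consecutive from 1")
    ped = Pedigree(capacity=len(df))
    ped.add_animals(
        sire=df["sire_id"].to_numpy(np.int64),
        dam=df["dam_id"].to_numpy(np.int64),
        sex=np.array([_SEX_CODE[s] for s in df["sex"]], dtype=np.int8),
        generation=df["generation"].to_numpy(np.int32),
        tbv=df["tbv"].to_numpy(np.float64),
        phenotype=df["phenotype"].to_numpy(np.float64),
        n_polled=df["polled_genotype"].to_numpy(np.int8),
        recorded_polled=(df["recorded_phenotype"] == "P").to_numpy().astype(np.int8),
        f=df["F"].to_numpy(np.float64),
    )
    ped._cols["ebv"][1 : len(ped) + 1] = df["ebv"].to_numpy(np.float64)
    ped._cols["status"][1 : len(ped) + 1] = np.where(
        df["status"].to_numpy() == "active", ACTIVE, CULLED
    )
    return ped
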