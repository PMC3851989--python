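"""Statistical certification of candidate modules.

Two permutation tests:

* **Weight-sum significance (p1).**  The module's weight sum C (vertex plus
  edge weights) is compared with the sums of equally-sized vertex sets drawn
  uniformly from the original integrative network; p1 is the fraction of
  random sets whose sum strictly exceeds C.
* **Mutual exclusivity (p2).**  The full alteration matrix is randomised by
  switching permutations — accepted 2x2 "double edge" swaps that preserve
  every row and column sum — and the coverage statistic (samples with at
  least one altered module unit) is recomputed on the module's columns; with
  per-gene alteration counts fixed, higher coverage means stronger
  exclusivity, and p2 is the fraction of permuted matrices whose statistic
  reaches the observed one (non-strict, so the test is conservative).

A module that fails the exclusivity test is reduced one unit at a time: the
least-exclusive pair (minimum v_ij) is located and its member with the
smaller membership entry x is removed, until the remainder is significantly
exclusive or only a pair is left.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .matrices import MutationMatrix
from .networks import IntegrativeNetwork, MutationNetwork
from .optimize import CandidateModule

logger = logging.getLogger(__name__)

__all__ = [
    "SignificanceResult",
    "ExclusivityResult",
    "CoreModule",
    "module_weight_sum",
    "significance_test",
    "switch_permute",
    "coverage_statistic",
    "exclusivity_test",
    "reduce_module",
    "default_swaps",
]

_MAX_SEED = 2**31 - 1


@dataclass(frozen=True)
class SignificanceResult:
    C: float
    n_perm: int
    r: int  # random sets with CR > C
    p1: float


@dataclass(frozen=True)
class ExclusivityResult:
    observed_stat: int
    n_perm: int
    p2: float
    swaps_per_perm: int


@dataclass
class CoreModule:
    """A certified module: the surviving unit set with its evidence."""

    unit_ids: tuple[str, ...]
    member_genes: tuple[str, ...]
    x_values: dict[str, float]
    C: float
    p1: float
    p2: float
    coverage: int  # samples with >= 1 member unit altered
    m: int  # samples in the mutation matrix
    reduction_trace: list[dict] = field(default_factory=list)

    @property
    def coverage_rate(self) -> str:
        return f"{self.coverage}/{self.m}"

    def to_dict(self) -> dict:
        return {
            "unit_ids": list(self.unit_ids),
            "member_genes": list(self.member_genes),
            "x_values": {k: float(v) for k, v in self.x_values.items()},
            "C": float(self.C),
            "p1": float(self.p1),
            "p2": float(self.p2),
            "coverage": int(self.coverage),
            "coverage_rate": self.coverage_rate,
            "reduction_trace": self.reduction_trace,
        }


# ---------------------------------------------------------------------------
# weight-sum significance test


def module_weight_sum(sn, m: IntegrativeNetwork) -> float:
    """C: sum of vertex weights plus unordered-pair edge weights of a module."""
    units = list(sn.unit_ids) if isinstance(sn, CandidateModule) else list(sn)
    return m.weight_sum(units)


def significance_test(sn, m: IntegrativeNetwork, n_perm: int = 1000,
                      rng: np.random.Generator | None = None) -> SignificanceResult:
    """Compare C with random same-size vertex sets from the original network.

    Each repetition draws b distinct units uniformly without replacement from
    ``m`` (the full network, not any reduced one) and recomputes the weight
    sum; p1 = #(CR > C) / n_perm.
    """
    rng = rng or np.random.default_rng()
    units = list(sn.unit_ids) if isinstance(sn, CandidateModule) else list(sn)
    b = len(units)
    n = m.n_units
    if b > n:
        raise ValueError(f"module size {b} exceeds network size {n}")
    c_obs = m.weight_sum(units)
    cvec = m.vertex_weight.to_numpy()
    wmat = m.edge_weight.to_numpy()
    r = 0
    for _ in range(n_perm):
        idx = rng.choice(n, size=b, replace=False)
        cr = cvec[idx].sum() + wmat[np.ix_(idx, idx)].sum() / 2.0
        if cr > c_obs:
            r += 1
    return SignificanceResult(C=float(c_obs), n_perm=n_perm, r=r, p1=r / n_perm)


# ---------------------------------------------------------------------------
# switching permutation (margin-preserving randomisation)


@njit(cache=True)
def _switch_chain(mat, rows, cols, n_swaps, max_proposals, seed):  # pragma: no cover
    np.random.seed(seed)
    nnz = rows.shape[0]
    accepted = 0
    proposals = 0
    while accepted < n_swaps and proposals < max_proposals:
        proposals += 1
        i = np.random.randint(nnz)
        j = np.random.randint(nnz)
        r1, c1 = rows[i], cols[i]
        r2, c2 = rows[j], cols[j]
        if r1 == r2 or c1 == c2:
            continue
        if mat[r1, c2] == 1 or mat[r2, c1] == 1:
            continue
        mat[r1, c1] = 0
        mat[r2, c2] = 0
        mat[r1, c2] = 1
        mat[r2, c1] = 1
        cols[i] = c2
        cols[j] = c1
        accepted += 1
    return accepted


@njit(cache=True)
def _null_coverage_stats(mat0, module_cols, n_perm, n_swaps, max_proposals,
                         seed, exclusive):  # pragma: no cover
    np.random.seed(seed)
    n_rows, n_cols = mat0.shape
    in_module = np.zeros(n_cols, np.bool_)
    for c in module_cols:
        in_module[c] = True
    nnz = 0
    for r in range(n_rows):
        for c in range(n_cols):
            nnz += mat0[r, c]
    out = np.empty(n_perm, np.int64)
    for p in range(n_perm):
        mat = mat0.copy()
        rows = np.empty(nnz, np.int64)
        cols = np.empty(nnz, np.int64)
        t = 0
        for r in range(n_rows):
            for c in range(n_cols):
                if mat[r, c] == 1:
                    rows[t] = r
                    cols[t] = c
                    t += 1
        accepted = 0
        proposals = 0
        while accepted < n_swaps and proposals < max_proposals:
            proposals += 1
            i = np.random.randint(nnz)
            j = np.random.randint(nnz)
            r1, c1 = rows[i], cols[i]
            r2, c2 = rows[j], cols[j]
            if r1 == r2 or c1 == c2:
                continue
            if mat[r1, c2] == 1 or mat[r2, c1] == 1:
                continue
            mat[r1, c1] = 0
            mat[r2, c2] = 0
            mat[r1, c2] = 1
            mat[r2, c1] = 1
            cols[i] = c2
            cols[j] = c1
            accepted += 1
        s = 0
        for r in range(n_rows):
            rowsum = 0
            for c in range(n_cols):
                if in_module[c]:
                    rowsum += mat[r, c]
            if exclusive:
                if rowsum == 1:
                    s += 1
            elif rowsum > 0:
                s += 1
        out[p] = s
    return out


def default_swaps(mat: np.ndarray, multiplier: int = 10) -> int:
    """Mixing heuristic: ``multiplier`` accepted swaps per 1-entry."""
    return int(multiplier * int(mat.sum()))


def _proposal_budget(n_swaps: int) -> int:
    # generous cap so chains on swap-poor matrices terminate
    return max(200 * n_swaps, 10_000)


def switch_permute(a: MutationMatrix | np.ndarray, n_swaps: int,
                   rng: np.random.Generator | None = None):
    """Randomise a binary matrix by accepted margin-preserving 2x2 swaps.

    Picks two 1-entries (s1,g1), (s2,g2) with distinct rows and columns and
    zeros at (s1,g2), (s2,g1), and flips the 2x2 submatrix; every row and
    column sum is invariant.  Proposals are capped, so matrices with no valid
    swap are returned unchanged.
    """
    rng = rng or np.random.default_rng()
    mat = a.indicator.to_numpy() if isinstance(a, MutationMatrix) else np.asarray(a)
    mat = mat.astype(np.int8).copy()
    rows, cols = np.nonzero(mat)
    if rows.size < 2:
        warnings.warn("matrix has fewer than two 1-entries; returned unchanged")
    else:
        seed = int(rng.integers(_MAX_SEED))
        _switch_chain(mat, rows.astype(np.int64), cols.astype(np.int64),
                      int(n_swaps), _proposal_budget(int(n_swaps)), seed)
    if isinstance(a, MutationMatrix):
        import pandas as pd

        df = pd.DataFrame(mat, index=a.sample_ids, columns=a.unit_ids)
        return MutationMatrix(indicator=df, metagene_map=dict(a.metagene_map))
    return mat


def coverage_statistic(sn, a: MutationMatrix, *, exclusive: bool = False) -> int:
    """Samples with at least one (or, with ``exclusive``, exactly one) altered
    unit among the module's columns."""
    units = list(sn.unit_ids) if isinstance(sn, CandidateModule) else list(sn)
    sub = a.indicator[units].to_numpy()
    rowsums = sub.sum(axis=1)
    return int((rowsums == 1).sum() if exclusive else (rowsums > 0).sum())


def exclusivity_test(sn, a: MutationMatrix, n_perm: int = 1000,
                     swaps_per_perm: int | None = None,
                     rng: np.random.Generator | None = None, *,
                     statistic: str = "coverage",
                     swaps_multiplier: int = 10) -> ExclusivityResult:
    """Switching-permutation test of mutual exclusivity for a unit set.

    Runs ``n_perm`` independent swap chains, each starting from the observed
    full matrix and performing ``swaps_per_perm`` accepted margin-preserving
    swaps (default 10 per 1-entry of A), and counts permutations whose
    coverage statistic over the module's columns reaches the observed value;
    with per-gene alteration counts fixed, high coverage is equivalent to
    strong exclusivity.
    """
    rng = rng or np.random.default_rng()
    units = list(sn.unit_ids) if isinstance(sn, CandidateModule) else list(sn)
    if len(units) < 2:
        raise ValueError("exclusivity test needs at least two units")
    exclusive = statistic == "exclusive_coverage"
    mat = a.indicator.to_numpy().astype(np.int8)
    col_index = {u: k for k, u in enumerate(a.unit_ids)}
    module_cols = np.array([col_index[u] for u in units], dtype=np.int64)
    observed = coverage_statistic(units, a, exclusive=exclusive)
    nnz = int(mat.sum())
    if swaps_per_perm is None:
        swaps_per_perm = default_swaps(mat, swaps_multiplier)
    if nnz < 2 or swaps_per_perm == 0:
        logger.warning("matrix admits no swaps; p2 = 1 by construction")
        return ExclusivityResult(observed_stat=observed, n_perm=n_perm, p2=1.0,
                                 swaps_per_perm=int(swaps_per_perm))
    seed = int(rng.integers(_MAX_SEED))
    stats = _null_coverage_stats(mat, module_cols, int(n_perm),
                                 int(swaps_per_perm),
                                 _proposal_budget(int(swaps_per_perm)), seed,
                                 exclusive)
    p2 = float((stats >= observed).mean())
    return ExclusivityResult(observed_stat=observed, n_perm=int(n_perm), p2=p2,
                             swaps_per_perm=int(swaps_per_perm))


# ---------------------------------------------------------------------------
# size reduction of non-exclusive modules


def _pick_removal(pair: tuple[str, str], x: dict[str, float],
                  mn: MutationNetwork) -> str:
    i, j = pair
    xi, xj = x.get(i, 0.0), x.get(j, 0.0)
    if xi < xj:
        return i
    if xj < xi:
        return j
    # equal x: drop the unit with the larger mutation count (keep the rarer
    # and hence more specific one); final tie falls to the later label.
    mi, mj = int(mn.m_i[i]), int(mn.m_i[j])
    if mi != mj:
        return i if mi > mj else j
    return max(i, j)


def reduce_module(sn, sol_x, mn: MutationNetwork, a: MutationMatrix, *,
                  alpha: float = 0.05, n_perm: int = 1000,
                  swaps_per_perm: int | None = None, swaps_multiplier: int = 10,
                  statistic: str = "coverage",
                  rng: np.random.Generator | None = None):
    """Shrink a non-exclusive module toward its exclusive core.

    While the current set fails the exclusivity test and holds more than two
    units: find the pair with minimum exclusivity weight v_ij (ties broken by
    lexicographic pair order), remove its member with the smaller membership
    entry x, and retest.  Returns ``(units, result, trace, certified)``.
    """
    rng = rng or np.random.default_rng()
    units = list(sn.unit_ids) if isinstance(sn, CandidateModule) else list(sn)
    if len(units) < 2:
        raise ValueError("reduction needs at least two units")
    if hasattr(sol_x, "x"):
        sol_x = sol_x.x
    x = {u: float(sol_x[u]) for u in units}
    trace: list[dict] = []
    res = exclusivity_test(units, a, n_perm=n_perm, swaps_per_perm=swaps_per_perm,
                           swaps_multiplier=swaps_multiplier, statistic=statistic,
                           rng=rng)
    while res.p2 >= alpha and len(units) > 2:
        pairs = sorted(
            itertools.combinations(sorted(units), 2),
            key=lambda p: (float(mn.edge_weight.loc[p[0], p[1]]), p),
        )
        worst = pairs[0]
        v_min = float(mn.edge_weight.loc[worst[0], worst[1]])
        removed = _pick_removal(worst, x, mn)
        trace.append({
            "removed": removed,
            "pair": list(worst),
            "v": v_min,
            "x_removed": x.get(removed, 0.0),
            "p2_before": res.p2,
        })
        units.remove(removed)
        res = exclusivity_test(units, a, n_perm=n_perm,
                               swaps_per_perm=swaps_per_perm,
                               swaps_multiplier=swaps_multiplier,
                               statistic=statistic, rng=rng)
    certified = res.p2 < alpha
    return units, res, trace, certified
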