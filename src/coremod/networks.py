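"""Weighted expression, mutation and integrative networks.

Three vertex- and edge-weighted graphs over the filtered unit set G:

* **Expression network (EN).**  Vertex weight ``f_i = 1 - mean_r(p_r)`` where
  ``p_r`` is the two-sample t-test p-value of expression gene *r* between the
  samples mutated / not mutated in unit *i* — a transcriptome-wide measure of
  a mutation's influence.  Edge weight ``u_ij`` is the absolute Pearson
  correlation of the two units' mutation-ordered expression vectors.
* **Mutation network (MN).**  Vertex weight ``h_i = m_i / m`` (coverage);
  edge weight ``v_ij`` = #(exactly one of i,j altered) / #(at least one
  altered) (mutual exclusivity).
* **Integrative network M.**  ``w_ij = delta*u_ij + v_ij`` and
  ``c_i = delta*xi*f_i + eta*h_i`` with balancing constants ``xi = u/f``,
  ``eta = v/h`` and ``delta = k*v/u`` derived from the weight maxima
  ``f, u, h, v``; ``k`` sets the weight of the mutation network relative to
  the expression network (default 1).

Metagenes use their collapsed mutation column on the mutation side and the
member-averaged expression profile on the expression side.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .matrices import ExpressionMatrix, GeneUniverse, MutationMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionNetwork",
    "MutationNetwork",
    "IntegrativeNetwork",
    "unit_expression",
    "mutation_ordered_expression",
    "influence_weight",
    "expression_edge_weight",
    "coverage_weight",
    "exclusivity_weight",
    "build_expression_network",
    "build_mutation_network",
    "integrate_networks",
]


@dataclass(frozen=True)
class ExpressionNetwork:
    units: tuple[str, ...]
    vertex_weight: pd.Series  # f_i
    edge_weight: pd.DataFrame  # u_ij, symmetric, zero diagonal
    d: int  # number of expression genes tested per unit


@dataclass(frozen=True)
class MutationNetwork:
    units: tuple[str, ...]
    vertex_weight: pd.Series  # h_i
    edge_weight: pd.DataFrame  # v_ij
    m: int  # samples in the mutation matrix
    m_i: pd.Series  # per-unit mutation counts


@dataclass(frozen=True)
class IntegrativeNetwork:
    """Combined network with recorded balancing constants.

    ``constants`` holds f, u, h, v (the weight maxima), xi, eta, delta and k.
    """

    units: tuple[str, ...]
    vertex_weight: pd.Series  # c_i
    edge_weight: pd.DataFrame  # w_ij
    constants: dict[str, float]

    @property
    def n_units(self) -> int:
        return len(self.units)

    def drop(self, units) -> "IntegrativeNetwork":
        """Return the network with the given units removed."""
        drop = set(units)
        keep = [u for u in self.units if u not in drop]
        return IntegrativeNetwork(
            units=tuple(keep),
            vertex_weight=self.vertex_weight.loc[keep],
            edge_weight=self.edge_weight.loc[keep, keep],
            constants=dict(self.constants),
        )

    def weight_sum(self, units) -> float:
        """Sum of vertex weights plus unordered-pair edge weights in a set."""
        units = list(units)
        if not units:
            raise ValueError("empty module")
        missing = set(units) - set(self.units)
        if missing:
            raise KeyError(f"units not in network: {sorted(missing)}")
        c = float(self.vertex_weight.loc[units].sum())
        w = float(self.edge_weight.loc[units, units].to_numpy().sum()) / 2.0
        return c + w


# ---------------------------------------------------------------------------
# expression side


def _member_average(unit: str, a: MutationMatrix, b: ExpressionMatrix,
                    samples: list[str]) -> np.ndarray:
    members = [g for g in a.metagene_map[unit] if g in set(b.gene_ids)]
    if not members:
        raise KeyError(f"unit {unit!r} has no member gene with expression data")
    skipped = [g for g in a.metagene_map[unit] if g not in set(b.gene_ids)]
    if skipped:
        logger.debug("unit %s: members without expression ignored: %s", unit, skipped)
    return b.values.loc[samples, members].to_numpy().mean(axis=1)


def unit_expression(unit: str, a: MutationMatrix, b: ExpressionMatrix,
                    universe: GeneUniverse) -> np.ndarray:
    """Per-sample expression of a unit over S (member-averaged for metagenes)."""
    return _member_average(unit, a, b, list(universe.samples))


def _order_index(unit: str, a: MutationMatrix, universe: GeneUniverse) -> np.ndarray:
    col = a.indicator.loc[list(universe.samples), unit].to_numpy()
    return np.concatenate([np.flatnonzero(col == 1), np.flatnonzero(col == 0)])


def mutation_ordered_expression(unit: str, a: MutationMatrix, b: ExpressionMatrix,
                                universe: GeneUniverse) -> np.ndarray:
    """The unit's expression over S reordered mutated-first.

    Samples with the unit altered come first (canonical order within each
    block) followed by the unaltered block.
    """
    if unit not in universe.units:
        raise KeyError(f"unit {unit!r} not in the filtered gene set G")
    e = unit_expression(unit, a, b, universe)
    return e[_order_index(unit, a, universe)]


def _group_pvalues(mask: np.ndarray, expr: np.ndarray, equal_var: bool) -> np.ndarray:
    """Per-gene two-sample t-test p-values for one mutated/non-mutated split.

    Genes with zero variance in both groups carry no evidence and get p = 1.
    """
    res = sps.ttest_ind(expr[mask], expr[~mask], axis=0, equal_var=equal_var)
    p = np.asarray(res.pvalue, dtype=float)
    n_bad = int(np.isnan(p).sum())
    if n_bad:
        logger.debug("%d degenerate t-tests set to p=1", n_bad)
    return np.nan_to_num(p, nan=1.0)


def influence_weight(unit: str, a: MutationMatrix, b: ExpressionMatrix,
                     universe: GeneUniverse, *, ttest: str = "pooled") -> float:
    """f_i = 1 - mean over all d expression genes of the differential-expression
    p-value induced by the unit's mutation status."""
    if unit not in universe.units:
        raise KeyError(f"unit {unit!r} not in the filtered gene set G")
    samples = list(universe.samples)
    mask = a.indicator.loc[samples, unit].to_numpy() == 1
    expr = b.values.loc[samples].to_numpy()
    p = _group_pvalues(mask, expr, equal_var=(ttest == "pooled"))
    return float(1.0 - p.mean())


def _abs_corr(vectors: np.ndarray) -> np.ndarray:
    """|Pearson| between rows, with constant rows contributing 0."""
    sd = vectors.std(axis=0 if vectors.ndim == 1 else 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(vectors)
    r = np.abs(np.nan_to_num(r, nan=0.0))
    r[sd == 0, :] = 0.0
    r[:, sd == 0] = 0.0
    np.fill_diagonal(r, 0.0)
    return np.clip(r, 0.0, 1.0)


def expression_edge_weight(i: str, j: str, a: MutationMatrix, b: ExpressionMatrix,
                           universe: GeneUniverse, *, edge_mode: str = "ordered") -> float:
    """u_ij: absolute Pearson correlation of the two units' expression vectors.

    ``edge_mode='ordered'`` (default) correlates the two mutation-ordered
    vectors positionally; ``'plain'`` correlates the profiles in canonical
    sample order.  A constant vector yields 0.
    """
    if i == j:
        raise ValueError("self-edges are undefined")
    if edge_mode == "ordered":
        ei = mutation_ordered_expression(i, a, b, universe)
        ej = mutation_ordered_expression(j, a, b, universe)
    else:
        ei = unit_expression(i, a, b, universe)
        ej = unit_expression(j, a, b, universe)
    return float(_abs_corr(np.vstack([ei, ej]))[0, 1])


def build_expression_network(a: MutationMatrix, b: ExpressionMatrix,
                             universe: GeneUniverse, *, ttest: str = "pooled",
                             edge_mode: str = "ordered") -> ExpressionNetwork:
    """Construct the expression network over G (vectorised)."""
    units = list(universe.units)
    samples = list(universe.samples)
    expr = b.values.loc[samples].to_numpy()
    d = expr.shape[1]
    masks = a.indicator.loc[samples, units].to_numpy().T == 1

    f = np.empty(len(units))
    for k, unit in enumerate(units):
        p = _group_pvalues(masks[k], expr, equal_var=(ttest == "pooled"))
        f[k] = 1.0 - p.mean()

    profiles = np.vstack([unit_expression(u, a, b, universe) for u in units])
    if edge_mode == "ordered":
        rows = []
        for k, unit in enumerate(units):
            order = np.concatenate(
                [np.flatnonzero(masks[k]), np.flatnonzero(~masks[k])]
            )
            rows.append(profiles[k][order])
        vectors = np.vstack(rows)
    else:
        vectors = profiles
    u = _abs_corr(vectors)
    return ExpressionNetwork(
        units=tuple(units),
        vertex_weight=pd.Series(f, index=units, name="f"),
        edge_weight=pd.DataFrame(u, index=units, columns=units),
        d=d,
    )


# ---------------------------------------------------------------------------
# mutation side


def coverage_weight(unit: str, a: MutationMatrix) -> float:
    """h_i = (samples altered in the unit) / (all samples of A)."""
    return float(a.indicator[unit].sum()) / a.m


def exclusivity_weight(i: str, j: str, a: MutationMatrix) -> float:
    """v_ij = #(exactly one altered) / #(at least one altered) over A's rows."""
    if i == j:
        raise ValueError("self-edges are undefined")
    ci = a.indicator[i].to_numpy()
    cj = a.indicator[j].to_numpy()
    either = int(((ci + cj) > 0).sum())
    if either == 0:
        logger.debug("pair (%s, %s) never altered; v set to 0", i, j)
        return 0.0
    exactly_one = int(((ci + cj) == 1).sum())
    return exactly_one / either


def build_mutation_network(a: MutationMatrix, universe: GeneUniverse, *,
                           restrict_to_common_samples: bool = False) -> MutationNetwork:
    """Construct the mutation network over G.

    Coverage and exclusivity are computed over all samples of A by default;
    ``restrict_to_common_samples`` switches to the common sample set S.
    """
    units = list(universe.units)
    df = a.indicator
    if restrict_to_common_samples:
        df = df.loc[list(universe.samples)]
    x = df[units].to_numpy().astype(np.int64)
    m = x.shape[0]
    mi = x.sum(axis=0)
    both = x.T @ x
    totals = mi[:, None] + mi[None, :]
    at_least_one = totals - both
    exactly_one = totals - 2 * both
    with np.errstate(invalid="ignore", divide="ignore"):
        v = np.where(at_least_one > 0, exactly_one / np.maximum(at_least_one, 1), 0.0)
    np.fill_diagonal(v, 0.0)
    return MutationNetwork(
        units=tuple(units),
        vertex_weight=pd.Series(mi / m, index=units, name="h"),
        edge_weight=pd.DataFrame(v, index=units, columns=units),
        m=m,
        m_i=pd.Series(mi, index=units, name="m_i"),
    )


# ---------------------------------------------------------------------------
# integration


def integrate_networks(en: ExpressionNetwork | None, mn: MutationNetwork,
                       k: float = 1.0, *, source: str = "full") -> IntegrativeNetwork:
    """Combine EN and MN into the integrative network M.

    With ``source='full'`` the balancing constants are xi = u/f, eta = v/h and
    delta = k*v/u, giving ``w_ij = delta*u_ij + v_ij`` and
    ``c_i = delta*xi*f_i + eta*h_i``; the maxima of delta*u and v then stand
    in ratio k.  ``source='mutation_only'`` drops the expression terms
    (delta = 0), leaving ``w_ij = v_ij`` and ``c_i = eta*h_i``.
    """
    if source not in ("full", "mutation_only"):
        raise ValueError(f"unknown network source {source!r}")
    h = float(mn.vertex_weight.max())
    v = float(mn.edge_weight.to_numpy().max())
    if h <= 0:
        raise ValueError("degenerate network: all coverage weights zero")
    if v <= 0:
        raise ValueError("degenerate network: all exclusivity weights zero")
    eta = v / h
    units = list(mn.units)
    vmat = mn.edge_weight.to_numpy()
    hvec = mn.vertex_weight.to_numpy()

    if source == "mutation_only":
        f = u = xi = delta = 0.0
        w = vmat.copy()
        c = eta * hvec
    else:
        if en is None or tuple(en.units) != tuple(mn.units):
            raise ValueError("expression and mutation networks must share a unit set")
        f = float(en.vertex_weight.max())
        u = float(en.edge_weight.to_numpy().max())
        if f <= 0:
            raise ValueError("degenerate network: all influence weights zero")
        if u <= 0:
            raise ValueError("degenerate network: all expression edge weights zero")
        xi = u / f
        delta = k * v / u
        w = delta * en.edge_weight.to_numpy() + vmat
        c = delta * xi * en.vertex_weight.to_numpy() + eta * hvec

    np.fill_diagonal(w, 0.0)
    return IntegrativeNetwork(
        units=tuple(units),
        vertex_weight=pd.Series(c, index=units, name="c"),
        edge_weight=pd.DataFrame(w, index=units, columns=units),
        constants={"f": f, "u": u, "h": h, "v": v,
                   "xi": xi, "eta": eta, "delta": delta, "k": float(k)},
    )
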