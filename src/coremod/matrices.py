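"""Binary alteration matrices, metagene collapsing and the shared gene universe.

Somatic point-mutation calls and gene-level copy-number calls are merged into
a single binary mutation matrix ``A`` (samples x genes, 1 = altered).  Genes
altered in exactly the same set of samples are indistinguishable to every
downstream statistic, so they are collapsed into *metagenes* before any
network is built.  The expression data then determine the shared universe:
the common samples ``S`` and the units ``G`` whose mutation status splits
``S`` into two groups of at least two samples each, the minimum for a
two-sample differential-expression test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "DataError",
    "AlterationCalls",
    "MutationMatrix",
    "ExpressionMatrix",
    "GeneUniverse",
    "build_binary_mutation_matrix",
    "collapse_metagenes",
    "compute_gene_universe",
]

METAGENE_SEP = "/"


class DataError(ValueError):
    """Raised when an input matrix violates its structural contract."""


def _check_labels(labels, what: str) -> list[str]:
    out = [str(x).strip() for x in labels]
    if len(set(out)) != len(out):
        dupes = sorted({x for x in out if out.count(x) > 1})
        raise DataError(f"duplicate {what} labels: {dupes[:5]}")
    if any(not x for x in out):
        raise DataError(f"empty {what} label")
    return out


def _normalise_frame(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    df.index = _check_labels(df.index, "sample")
    df.columns = _check_labels(df.columns, "gene")
    return df


@dataclass(frozen=True)
class AlterationCalls:
    """Binary sample x gene indicator table (1 = altered)."""

    indicator: pd.DataFrame

    def __post_init__(self):
        df = _normalise_frame(self.indicator)
        vals = df.to_numpy()
        if vals.size == 0:
            raise DataError("empty alteration table")
        if not np.isin(vals, (0, 1)).all():
            raise DataError("alteration indicators must be 0/1")
        object.__setattr__(self, "indicator", df.astype(np.int8))

    @property
    def sample_ids(self) -> list[str]:
        return list(self.indicator.index)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.indicator.columns)


@dataclass
class MutationMatrix:
    """Binary sample x unit matrix with a metagene membership map.

    A *unit* is either a single gene or a metagene; ``metagene_map`` maps each
    unit label to the ordered list of member genes (singletons map to
    themselves).
    """

    indicator: pd.DataFrame
    metagene_map: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self):
        self.indicator = _normalise_frame(self.indicator)
        vals = self.indicator.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise DataError("mutation matrix must be binary")
        self.indicator = self.indicator.astype(np.int8)
        if not self.metagene_map:
            self.metagene_map = {u: [u] for u in self.indicator.columns}
        missing = set(self.indicator.columns) - set(self.metagene_map)
        if missing:
            raise DataError(f"units missing from metagene map: {sorted(missing)[:5]}")
        for unit, members in self.metagene_map.items():
            if not members:
                raise DataError(f"metagene {unit!r} has no members")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.indicator.index)

    @property
    def unit_ids(self) -> list[str]:
        return list(self.indicator.columns)

    @property
    def m(self) -> int:
        """Number of samples (rows)."""
        return self.indicator.shape[0]

    def member_genes(self, unit: str) -> list[str]:
        return list(self.metagene_map[unit])


@dataclass(frozen=True)
class ExpressionMatrix:
    """Real-valued, already-normalised sample x gene expression table."""

    values: pd.DataFrame

    def __post_init__(self):
        df = _normalise_frame(self.values).astype(float)
        if df.size == 0:
            raise DataError("empty expression table")
        if not np.isfinite(df.to_numpy()).all():
            raise DataError("expression values must be finite")
        object.__setattr__(self, "values", df)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass(frozen=True)
class GeneUniverse:
    """Common samples and the filtered unit set shared by both data types.

    ``samples`` is the sorted intersection S of mutation and expression
    samples — the canonical sample order used by every downstream vector.
    ``units`` is G: units whose mutated / non-mutated split of S has at least
    two samples on each side.  ``group_sizes`` maps each unit in G0 to
    (n_mutated, n_non_mutated) over S.
    """

    samples: tuple[str, ...]
    g0: tuple[str, ...]
    units: tuple[str, ...]
    group_sizes: dict[str, tuple[int, int]]


def build_binary_mutation_matrix(
    somatic: AlterationCalls, cnv: AlterationCalls | None = None
) -> MutationMatrix:
    """OR-merge somatic and CNV calls over their common samples.

    Rows are the (sorted) intersection of the two sample sets, columns the
    union of the gene sets; an entry is 1 when either source reports the gene
    altered in that sample.  When ``cnv`` is None the somatic calls are used
    alone (the copy-number-free analysis mode).
    """
    if cnv is None:
        df = somatic.indicator.copy()
        df = df.loc[sorted(df.index)]
        return MutationMatrix(indicator=df)
    common = sorted(set(somatic.sample_ids) & set(cnv.sample_ids))
    if not common:
        raise DataError(
            "no common samples between somatic calls "
            f"({len(somatic.sample_ids)} samples) and CNV calls "
            f"({len(cnv.sample_ids)} samples)"
        )
    genes = list(somatic.gene_ids) + [
        g for g in cnv.gene_ids if g not in set(somatic.gene_ids)
    ]
    s = somatic.indicator.reindex(index=common, columns=genes, fill_value=0)
    c = cnv.indicator.reindex(index=common, columns=genes, fill_value=0)
    merged = ((s.to_numpy() + c.to_numpy()) > 0).astype(np.int8)
    df = pd.DataFrame(merged, index=common, columns=genes)
    return MutationMatrix(indicator=df)


def collapse_metagenes(a0: MutationMatrix) -> MutationMatrix:
    """Merge units altered in exactly the same samples into metagenes.

    All-zero columns are dropped first (they can never pass the group-size
    filter).  Each group of identical columns becomes one unit labelled by the
    member labels joined with "/" in input order; membership maps compose, so
    the operation is idempotent.
    """
    df = a0.indicator
    zero = [u for u in df.columns if df[u].sum() == 0]
    if zero:
        logger.info("dropping %d all-zero mutation columns: %s", len(zero), zero[:10])
        df = df.drop(columns=zero)
    groups: dict[bytes, list[str]] = {}
    for u in df.columns:
        key = df[u].to_numpy().tobytes()
        groups.setdefault(key, []).append(u)
    cols = {}
    metagene_map: dict[str, list[str]] = {}
    for members in groups.values():
        label = METAGENE_SEP.join(members)
        cols[label] = df[members[0]]
        genes: list[str] = []
        for u in members:
            genes.extend(a0.metagene_map[u])
        metagene_map[label] = genes
        if len(members) > 1:
            logger.info("collapsed %s into metagene %s", members, label)
    out = pd.DataFrame(cols, index=df.index)
    return MutationMatrix(indicator=out, metagene_map=metagene_map)


def compute_gene_universe(a: MutationMatrix, b: ExpressionMatrix) -> GeneUniverse:
    """Intersect samples, match units to expression data and apply the
    minimum-group-size filter.

    A metagene belongs to G0 when at least one member gene has an expression
    profile.  Over the common samples S each unit's mutation column splits S
    into mutated / non-mutated groups; G keeps the units with >= 2 samples in
    both groups.
    """
    samples = tuple(sorted(set(a.sample_ids) & set(b.sample_ids)))
    if not samples:
        raise DataError(
            f"no common samples: mutation matrix has {a.m}, "
            f"expression matrix has {len(b.sample_ids)}"
        )
    expr_genes = set(b.gene_ids)
    g0 = tuple(
        u for u in a.unit_ids if any(g in expr_genes for g in a.metagene_map[u])
    )
    if not g0:
        raise DataError(
            f"no unit has expression data ({len(a.unit_ids)} units, "
            f"{len(expr_genes)} expression genes)"
        )
    sub = a.indicator.loc[list(samples), list(g0)]
    n1 = sub.sum(axis=0).astype(int)
    n_s = len(samples)
    group_sizes = {u: (int(n1[u]), n_s - int(n1[u])) for u in g0}
    units = tuple(u for u in g0 if 2 <= group_sizes[u][0] <= n_s - 2)
    if not units:
        raise DataError(
            f"group-size filter removed every unit (|S|={n_s}, |G0|={len(g0)})"
        )
    return GeneUniverse(samples=samples, g0=g0, units=units, group_sizes=group_sizes)
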