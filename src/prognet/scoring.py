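"""Module index, combination index, cohort scoring and risk-group split.

The module index for a sample is the geometric mean of the log2 expression
values of the poor-outcome genes minus the geometric mean of the log2
values of the good-outcome genes. Geometric means of log2 values require
strict positivity; an arithmetic aggregator is available as an alternative
for data where log2 values may be non-positive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .dataio import ExpressionMatrix
from .errors import InputError, ParameterError

logger = logging.getLogger(__name__)


@dataclass
class ModuleGeneSets:
    """Disjoint poor-outcome (P) and good-outcome (N) gene sets."""

    poor: set[str] = field(default_factory=set)
    good: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.poor = set(self.poor)
        self.good = set(self.good)
        if self.poor & self.good:
            raise InputError(
                f"genes in both poor and good sets: {sorted(self.poor & self.good)[:5]}"
            )
        if not self.poor and not self.good:
            raise InputError("at least one of the poor/good sets must be non-empty")

    @property
    def genes(self) -> set[str]:
        return self.poor | self.good


def _aggregate(values: np.ndarray, names: Sequence[str], agg: str) -> float:
    if values.size == 0:
        return 0.0
    if agg == "geometric":
        nonpos = values <= 0
        if nonpos.any():
            bad = [n for n, b in zip(names, nonpos) if b]
            raise InputError(
                "geometric mean undefined: non-positive log2 value for "
                f"gene(s) {bad[:5]}"
            )
        return float(np.exp(np.mean(np.log(values))))
    if agg == "arithmetic":
        return float(np.mean(values))
    raise ParameterError(f"unknown aggregator {agg!r}")


def module_index(
    poor_values,
    good_values,
    poor_names: Sequence[str] | None = None,
    good_names: Sequence[str] | None = None,
    agg: str = "geometric",
) -> float:
    """Geometric mean of the poor-outcome values minus geometric mean of
    the good-outcome values. An empty side contributes 0."""
    poor_values = np.asarray(poor_values, dtype=float)
    good_values = np.asarray(good_values, dtype=float)
    poor_names = list(poor_names) if poor_names is not None else [
        f"P{i}" for i in range(poor_values.size)
    ]
    good_names = list(good_names) if good_names is not None else [
        f"N{i}" for i in range(good_values.size)
    ]
    return _aggregate(poor_values, poor_names, agg) - _aggregate(
        good_values, good_names, agg
    )


def combination_index(indices) -> float:
    """Arithmetic mean of per-module indices."""
    indices = np.asarray(indices, dtype=float)
    if indices.size == 0:
        raise InputError("no module indices to combine")
    return float(np.mean(indices))


def _resolve_module_rows(
    expr: ExpressionMatrix, genes: set[str], label: str, max_missing: float = 0.2
) -> dict[str, str]:
    """Map module genes to expression rows (gene -> probe id).

    When a probe-to-gene mapping is attached, the highest-variance probe is
    used per gene; otherwise row ids are matched directly. Genes missing
    from the matrix are dropped with a warning unless they exceed
    ``max_missing`` of the module."""
    if expr.probe_to_gene is None:
        rows = {g: g for g in genes if g in expr.data.index}
    else:
        var = expr.data.var(axis=1, ddof=1)
        by_gene: dict[str, str] = {}
        for probe in expr.probe_ids:
            gene = expr.gene_of(probe)
            if gene in genes:
                best = by_gene.get(gene)
                if best is None or var[probe] > var[best]:
                    by_gene[gene] = probe
        rows = by_gene
    missing = genes - set(rows)
    if missing:
        frac = len(missing) / len(genes)
        if frac > max_missing:
            raise InputError(
                f"{label}: {len(missing)}/{len(genes)} genes missing from "
                f"expression (> {max_missing:.0%}): {sorted(missing)[:5]}"
            )
        logger.warning(
            "%s: dropped %d missing gene(s): %s",
            label, len(missing), sorted(missing)[:5],
        )
    return rows


def score_cohort(
    expr: ExpressionMatrix,
    modules: Sequence,
    agg: str = "geometric",
) -> pd.DataFrame:
    """Per-sample module indices and their combination index.

    ``modules`` is a sequence of objects exposing ``poor``/``good`` gene
    sets (``ModuleGeneSets`` or ``netmodules.NetworkModule``). Returns a
    DataFrame indexed by sample id with one column per module plus a
    ``combination`` column.
    """
    if len(modules) == 0:
        raise InputError("no modules to score")
    columns: dict[str, np.ndarray] = {}
    for i, mod in enumerate(modules):
        sets = mod if isinstance(mod, ModuleGeneSets) else mod.gene_sets
        label = getattr(mod, "name", f"module_{i}")
        rows = _resolve_module_rows(expr, sets.genes, label)
        poor_rows = [rows[g] for g in sorted(sets.poor) if g in rows]
        good_rows = [rows[g] for g in sorted(sets.good) if g in rows]
        if not poor_rows and not good_rows:
            raise InputError(f"{label}: no genes resolvable in expression matrix")
        poor = expr.data.loc[poor_rows].to_numpy() if poor_rows else np.empty((0, expr.n_samples))
        good = expr.data.loc[good_rows].to_numpy() if good_rows else np.empty((0, expr.n_samples))
        scores = np.array(
            [
                module_index(
                    poor[:, s], good[:, s],
                    poor_rows, good_rows, agg=agg,
                )
                for s in range(expr.n_samples)
            ]
        )
        columns[label] = scores
    table = pd.DataFrame(columns, index=expr.sample_ids)
    table["combination"] = table.mean(axis=1)
    return table


def median_split(scores) -> pd.Series:
    """Split scores at the median: strictly greater -> ``high``, otherwise
    (including ties at the median) -> ``low``."""
    scores = pd.Series(scores, dtype=float)
    if len(scores) < 2:
        raise InputError("median split needs >= 2 samples")
    med = scores.median()
    groups = pd.Series(
        np.where(scores > med, "high", "low"), index=scores.index, name="group"
    )
    if (groups == "low").all():
        logger.warning("median_split: all scores <= median; single group")
    return groups
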