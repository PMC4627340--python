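"""Nearest-centroid molecular subtype assignment.

Centroids are per-subtype means of gene-wise z-scored reference expression
over an intrinsic gene list; samples are median-centered over the shared
intrinsic genes and assigned to the centroid with the highest Spearman rank
correlation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dataio import ExpressionMatrix
from .errors import InputError

logger = logging.getLogger(__name__)


@dataclass
class SubtypeCentroids:
    """Per-subtype standardized centroid vectors over a shared gene list.

    ``profiles`` is genes x subtypes.
    """

    profiles: pd.DataFrame

    def __post_init__(self) -> None:
        if self.profiles.shape[1] < 2:
            raise InputError("need >= 2 subtype centroids")
        if self.profiles.index.has_duplicates:
            raise InputError("duplicate genes in centroid profiles")

    @property
    def subtypes(self) -> list[str]:
        return list(self.profiles.columns)

    @property
    def genes(self) -> list[str]:
        return list(self.profiles.index)


def _collapse_probes_to_genes(expr: ExpressionMatrix) -> pd.DataFrame:
    """Average probes mapping to the same gene symbol (arithmetic mean of
    log2 values); identity when no mapping is attached."""
    if expr.probe_to_gene is None:
        return expr.data
    genes = pd.Index([expr.gene_of(p) for p in expr.probe_ids])
    return expr.data.groupby(genes).mean()


def build_centroids(
    ref_expr: ExpressionMatrix,
    ref_labels: Mapping[str, str],
    intrinsic_genes: Sequence[str],
) -> SubtypeCentroids:
    """Build standardized centroids from labeled reference samples.

    Genes are restricted to the intrinsic list, z-scored across all
    reference samples, and averaged per subtype. Intrinsic genes absent
    from the reference matrix, and genes constant across references
    (undefined z-score), are dropped with a logged count.
    """
    data = _collapse_probes_to_genes(ref_expr)
    labels = pd.Series(dict(ref_labels))
    missing = labels.index.difference(data.columns)
    if len(missing):
        raise InputError(f"labeled samples not in reference matrix: {list(missing)[:5]}")
    counts = labels.value_counts()
    if (counts < 1).any():
        raise InputError("every subtype needs >= 1 reference sample")

    found = [g for g in intrinsic_genes if g in data.index]
    dropped_absent = len(set(intrinsic_genes)) - len(set(found))
    if dropped_absent:
        logger.info("build_centroids: %d intrinsic genes absent from reference", dropped_absent)
    if len(found) < 2:
        raise InputError("need >= 2 intrinsic genes present in the reference matrix")

    sub = data.loc[found, labels.index]
    sd = sub.std(axis=1, ddof=1)
    constant = sd == 0
    if constant.any():
        logger.info("build_centroids: dropped %d constant gene(s)", int(constant.sum()))
        sub = sub.loc[~constant]
        sd = sd[~constant]
    if sub.shape[0] < 2:
        raise InputError("fewer than 2 usable intrinsic genes after dropping constants")
    z = sub.sub(sub.mean(axis=1), axis=0).div(sd, axis=0)
    centroids = z.T.groupby(labels).mean().T
    centroids = centroids[sorted(centroids.columns)]
    return SubtypeCentroids(centroids)


def assign_subtypes(
    expr: ExpressionMatrix, centroids: SubtypeCentroids
) -> pd.DataFrame:
    """Assign each sample to the subtype with the highest Spearman rank
    correlation over the shared intrinsic genes.

    Samples are median-centered over the shared intrinsic genes first.
    Returns a DataFrame indexed by sample with a ``subtype`` column and one
    correlation column per centroid. Ties are broken by subtype-name order
    with a logged warning.
    """
    data = _collapse_probes_to_genes(expr)
    shared = [g for g in centroids.genes if g in data.index]
    if not shared:
        raise InputError("no intrinsic genes shared between expression and centroids")
    if len(shared) < 2:
        raise InputError("need >= 2 shared intrinsic genes")
    sub = data.loc[shared]
    sub = sub.sub(sub.median(axis=0), axis=1)  # per-sample median-centering
    cent = centroids.profiles.loc[shared]

    sample_ranks = np.apply_along_axis(stats.rankdata, 0, sub.to_numpy())
    cent_ranks = np.apply_along_axis(stats.rankdata, 0, cent.to_numpy())

    def _std(r):
        return (r - r.mean(axis=0)) / r.std(axis=0)

    with np.errstate(invalid="ignore"):
        corr = _std(sample_ranks).T @ _std(cent_ranks) / len(shared)

    names = centroids.subtypes
    best = corr.argmax(axis=1)
    # tie detection against the argmax value
    ties = (corr == corr[np.arange(len(best)), best][:, None]).sum(axis=1) > 1
    if ties.any():
        logger.warning("assign_subtypes: %d tie(s) broken by subtype-name order", int(ties.sum()))
    result = pd.DataFrame(corr, index=expr.sample_ids, columns=names)
    result.insert(0, "subtype", [names[b] for b in best])
    return result
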