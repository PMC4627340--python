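"""Sample QC, centering, batch alignment and variance-based probe filtering."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dataio import ExpressionMatrix
from .errors import InputError, ParameterError

logger = logging.getLogger(__name__)


@dataclass
class QCReport:
    """Per-sample QC outcome: fraction of partner samples with Spearman
    correlation (over housekeeping probes) above the threshold, and whether
    the sample passed."""

    table: pd.DataFrame  # index: sample id; columns: fraction, passed

    def __post_init__(self) -> None:
        frac = self.table["fraction"].to_numpy()
        if ((frac < 0) | (frac > 1)).any():
            raise InputError("QC fractions out of [0, 1]")


def qc_filter_samples(
    expr: ExpressionMatrix,
    housekeeping_ids: Sequence[str],
    threshold: float = 0.95,
    min_fraction: float = 0.5,
) -> tuple[list[str], QCReport]:
    """Keep samples whose housekeeping-probe Spearman correlation is
    strictly greater than ``threshold`` with at least ``min_fraction`` of
    the other samples."""
    present = [h for h in housekeeping_ids if h in expr.data.index]
    if len(present) < 2:
        raise InputError(
            f"need >= 2 housekeeping probes in the matrix, found {len(present)}"
        )
    if expr.n_samples < 2:
        raise InputError("need >= 2 samples for QC")
    hk = expr.data.loc[present].to_numpy()
    # rank-transform once, then Pearson on ranks == Spearman
    ranks = np.apply_along_axis(stats.rankdata, 0, hk)
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(ranks, rowvar=False)
    np.fill_diagonal(corr, np.nan)
    above = corr > threshold
    fraction = above.sum(axis=1) / (expr.n_samples - 1)
    passed = fraction >= min_fraction
    report = QCReport(
        pd.DataFrame(
            {"fraction": fraction, "passed": passed}, index=expr.sample_ids
        )
    )
    kept = [s for s, ok in zip(expr.sample_ids, passed) if ok]
    logger.info("qc_filter_samples: kept %d / %d samples", len(kept), expr.n_samples)
    return kept, report


def median_center(expr: ExpressionMatrix, axis: str = "genes") -> ExpressionMatrix:
    """Subtract the median along the chosen axis (``genes``: per-row median
    over samples; ``samples``: per-column median over genes)."""
    if expr.data.empty:
        raise InputError("empty expression matrix")
    if axis == "genes":
        centered = expr.data.sub(expr.data.median(axis=1), axis=0)
    elif axis == "samples":
        centered = expr.data.sub(expr.data.median(axis=0), axis=1)
    else:
        raise ParameterError(f"axis must be 'genes' or 'samples', got {axis!r}")
    return ExpressionMatrix(centered, expr.probe_to_gene)


def batch_center(expr: ExpressionMatrix, batch_labels: Sequence[str]) -> ExpressionMatrix:
    """Remove additive batch offsets: per gene and batch, subtract the batch
    mean and add back the global gene mean. Within-batch correlations and
    gene-wise global means are preserved exactly.

    This is a documented stand-in for distance-weighted-discrimination
    style alignment; it removes additive inter-dataset shifts only.
    """
    labels = pd.Series(list(batch_labels), index=expr.sample_ids)
    if labels.isna().any():
        raise InputError("every sample needs a batch label")
    out = expr.data.copy()
    global_mean = expr.data.mean(axis=1)
    for batch, cols in labels.groupby(labels).groups.items():
        cols = list(cols)
        if len(cols) == 1:
            logger.warning("batch_center: batch %r has 1 sample; left unshifted", batch)
            continue
        batch_mean = expr.data[cols].mean(axis=1)
        out[cols] = expr.data[cols].sub(batch_mean - global_mean, axis=0)
    return ExpressionMatrix(out, expr.probe_to_gene)


def top_variable_probes(expr: ExpressionMatrix, k: int = 2500) -> list[str]:
    """Ids of the ``k`` probes with the largest sample variance of log2
    expression, descending; ties broken by lexicographic probe id."""
    if k > expr.n_probes:
        raise ParameterError(f"k={k} exceeds number of probes ({expr.n_probes})")
    var = expr.data.var(axis=1, ddof=1)
    order = sorted(expr.probe_ids, key=lambda p: (-var[p], p))
    return order[:k]
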