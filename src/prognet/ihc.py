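"""Allred scoring and the 3-marker composite risk score for TMA data.

Composite score per sample: Allred total for JUN minus the totals for CD8
and CD20, each total being the maximum over up to 3 evaluable cores.
Theoretical range [-16, 8]; positive scores are high risk, negative low
risk, and exactly zero is reported as indeterminate.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy import stats

from .dataio import ALLRED_MARKERS, AllredTable
from .errors import InputError

logger = logging.getLogger(__name__)


def allred_total(intensity: int, proportion: int) -> int:
    """Allred total = intensity (0-3) + proportion (0-5); the two
    components must be both zero or both positive."""
    if intensity not in range(4):
        raise InputError(f"intensity must be 0-3, got {intensity}")
    if proportion not in range(6):
        raise InputError(f"proportion must be 0-5, got {proportion}")
    if (intensity == 0) != (proportion == 0):
        raise InputError(
            f"inconsistent Allred components ({intensity}, {proportion}): "
            "intensity and proportion must be both zero or both positive"
        )
    return intensity + proportion


def sample_marker_score(cores) -> float:
    """Maximum Allred total over evaluable cores; NaN when none are
    evaluable (missing-data marker)."""
    totals = [t for t in cores if t is not None and not (isinstance(t, float) and math.isnan(t))]
    if not totals:
        return float("nan")
    return float(max(totals))


def composite_score(jun: float, cd8: float, cd20: float) -> float:
    """JUN minus CD8 minus CD20 marker totals; range [-16, 8]."""
    for name, v in (("JUN", jun), ("CD8", cd8), ("CD20", cd20)):
        if v is None or math.isnan(v):
            raise InputError(f"marker {name} missing; sample cannot be scored")
    return float(jun - cd8 - cd20)


def ihc_risk_group(score: float) -> str:
    """Strict-inequality rule: > 0 high risk, < 0 low risk, == 0
    indeterminate."""
    if not math.isfinite(score):
        raise InputError("score must be finite")
    if score > 0:
        return "high"
    if score < 0:
        return "low"
    return "indeterminate"


def score_allred_table(table: AllredTable) -> pd.DataFrame:
    """Per-sample marker totals, composite score and risk group.

    Samples missing any of the three markers entirely are excluded with a
    logged reason. Returns a DataFrame indexed by sample with columns JUN,
    CD8, CD20, composite, group.
    """
    df = table.table
    rows = {}
    for sample, sub in df.groupby("sample", sort=False):
        totals = {}
        for marker in ALLRED_MARKERS:
            cores = sub[sub["marker"] == marker]
            core_totals = [
                allred_total(int(r.intensity), int(r.proportion))
                for r in cores.itertuples()
            ]
            totals[marker] = sample_marker_score(core_totals) if core_totals else float("nan")
        try:
            comp = composite_score(totals["JUN"], totals["CD8"], totals["CD20"])
        except InputError as exc:
            logger.warning("score_allred_table: excluding sample %s: %s", sample, exc)
            continue
        rows[sample] = {
            **totals, "composite": comp, "group": ihc_risk_group(comp),
        }
    if not rows:
        raise InputError("no scorable samples in Allred table")
    return pd.DataFrame.from_dict(rows, orient="index")


def interrater_agreement(scores_a, scores_b) -> tuple[float, float]:
    """Pearson correlation between two raters' composite scores with a
    two-sided p-value."""
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape:
        raise InputError("rater score vectors must be paired")
    if a.shape[0] < 3:
        raise InputError("need n >= 3 paired scores")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise InputError("constant score vector; correlation undefined")
    r, p = stats.pearsonr(a, b)
    return float(r), float(p)
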