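"""End-to-end orchestration: discovery (QC -> variance filter -> Cox
selection -> network mapping -> MCL -> module filtering) and validation
(score an independent cohort and evaluate per module + combination).

Every run record embeds the fully resolved parameters so outputs are
reproducible from the record alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from . import __version__
from .dataio import ExpressionMatrix, InteractionNetwork, SurvivalData
from .errors import InputError, PrognetError
from .evaluate import evaluate_module
from .netmodules import (
    NetworkModule,
    filter_modules,
    map_to_network,
    mcl_cluster,
    select_outcome_probes,
    weight_edges,
)
from .preprocess import batch_center, qc_filter_samples, top_variable_probes
from .scoring import score_cohort

logger = logging.getLogger(__name__)


@dataclass
class DiscoveryParams:
    top_k: int = 2500
    alpha: float = 0.05
    min_size: int = 8
    min_corr: float = 0.25
    corr_mode: str = "signed"
    inflation: float = 2.0
    expansion: int = 2
    prune_below: float = 1e-5
    qc_threshold: float = 0.95
    qc_min_fraction: float = 0.5

    def to_dict(self) -> dict:
        return dict(vars(self))


@dataclass
class DiscoveryResult:
    modules: list[NetworkModule]
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "modules": [m.to_dict() for m in self.modules],
            "provenance": self.provenance,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DiscoveryResult":
        return cls(
            [NetworkModule.from_dict(m) for m in d["modules"]],
            dict(d.get("provenance", {})),
        )


class StageError(PrognetError):
    """Wraps a stage failure with the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[{stage}] {cause}")
        self.stage = stage
        self.cause = cause
        self.exit_code = getattr(cause, "exit_code", 1)


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PrognetError as exc:
                raise StageError(name, exc) from exc

        return wrapper

    return deco


def run_discovery(
    expr: ExpressionMatrix,
    surv: SurvivalData,
    network: InteractionNetwork,
    probe_to_gene: dict[str, str] | None = None,
    housekeeping_ids: list[str] | None = None,
    batch_labels: pd.Series | None = None,
    params: DiscoveryParams | None = None,
) -> DiscoveryResult:
    """Run the discovery chain and return the modules with provenance."""
    params = params or DiscoveryParams()

    if batch_labels is not None:
        expr = _stage("batch_center")(batch_center)(expr, batch_labels.loc[expr.sample_ids])

    qc_kept = expr.sample_ids
    if housekeeping_ids:
        qc_kept, _ = _stage("qc")(qc_filter_samples)(
            expr, housekeeping_ids, params.qc_threshold, params.qc_min_fraction
        )
        expr = expr.subset_samples(qc_kept)

    shared = [s for s in expr.sample_ids if s in set(surv.sample_ids)]
    if not shared:
        raise StageError("align", InputError("no shared samples between expression and survival"))
    expr = expr.subset_samples(shared)
    surv = surv.subset(shared)

    k = min(params.top_k, expr.n_probes)
    top = _stage("variance_filter")(top_variable_probes)(expr, k)
    expr_top = expr.subset_probes(top)

    outcome = _stage("cox_selection")(select_outcome_probes)(expr_top, surv, params.alpha)
    subgraph, gene_to_probe, unmapped = _stage("network_mapping")(map_to_network)(
        outcome, network, probe_to_gene
    )
    weighted = _stage("edge_weighting")(weight_edges)(subgraph, expr_top, gene_to_probe)
    mcl = _stage("mcl")(mcl_cluster)(
        weighted,
        inflation=params.inflation,
        expansion=params.expansion,
        prune_below=params.prune_below,
    )
    modules = _stage("module_filter")(filter_modules)(
        mcl.clusters, expr_top, outcome, gene_to_probe,
        params.min_size, params.min_corr, params.corr_mode,
    )
    logger.info("run_discovery: %d module(s) after filtering", len(modules))
    provenance = {
        "params": params.to_dict(),
        "version": __version__,
        "n_samples": len(shared),
        "n_samples_failed_qc": len(set(expr.sample_ids) ^ set(qc_kept)) if housekeeping_ids else 0,
        "n_probes_tested": expr_top.n_probes,
        "n_probes_selected": len(outcome.selected_probes),
        "n_genes_unmapped": len(unmapped),
        "mcl_converged": mcl.converged,
        "mcl_iterations": mcl.iterations,
        "n_clusters": len(mcl.clusters),
    }
    return DiscoveryResult(modules, provenance)


def run_validation(
    expr: ExpressionMatrix,
    surv: SurvivalData,
    discovery: DiscoveryResult,
    agg: str = "geometric",
) -> dict:
    """Score an independent cohort with trained modules and evaluate each
    module index plus the combination index. Returns a report dict shaped
    as one row per module + a combination row."""
    if not discovery.modules:
        raise InputError("no modules to validate")
    scores = _stage("scoring")(score_cohort)(expr, discovery.modules, agg=agg)
    report_rows = {}
    for mod in discovery.modules:
        ev = _stage("evaluation")(evaluate_module)(scores[mod.name], surv)
        report_rows[mod.name] = ev.to_dict()
    ev = _stage("evaluation")(evaluate_module)(scores["combination"], surv)
    report_rows["combination"] = ev.to_dict()
    return {
        "rows": report_rows,
        "provenance": {
            "trained": discovery.provenance,
            "agg": agg,
            "n_validation_samples": expr.n_samples,
            "version": __version__,
        },
    }
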