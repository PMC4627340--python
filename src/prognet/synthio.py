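"""Synthetic cohort generator with known ground truth.

Plants rank-1 co-expression modules that are simultaneously topologically
coherent in a random interaction network and prognostic through a
proportional-hazards link, plus low-variance housekeeping probes and
optional additive batch offsets. Every generator is a pure function of
(config, seed).

Module model: for gene g in module m, the log2 value for sample s is
``baseline + lam * f_ms + eps`` with ``lam = noise_sd * sqrt(r / (1 - r))``,
so the expected pairwise Pearson correlation within the module is ``r``.
Event times are exponential with hazard ``h0 * exp(sum_m beta_m * f_ms)``
and independent exponential censoring calibrated to the requested censored
fraction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .dataio import (
    ALLRED_MARKERS,
    AllredTable,
    ExpressionMatrix,
    InteractionNetwork,
    SurvivalData,
    write_expression,
    write_json,
    write_network,
    write_survival,
)
from .errors import ParameterError

logger = logging.getLogger(__name__)

LOG2_FLOOR = 0.5


@dataclass
class PlantedModule:
    size: int
    direction: str  # 'good' or 'poor'
    beta: float  # hazard log-ratio per unit of latent activity (magnitude)

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ParameterError("module size must be >= 1")
        if self.direction not in ("good", "poor"):
            raise ParameterError(f"direction must be 'good' or 'poor', got {self.direction!r}")
        if self.beta < 0:
            raise ParameterError("beta is a magnitude; use direction for sign")

    @property
    def signed_beta(self) -> float:
        return self.beta if self.direction == "poor" else -self.beta


@dataclass
class SyntheticConfig:
    n_genes: int
    n_samples: int
    planted_modules: list[PlantedModule] = field(default_factory=list)
    within_module_corr: float = 0.5
    baseline_log2_mean: float = 7.0
    noise_sd: float = 1.0
    background_edge_prob: float = 0.01
    module_edge_prob: float = 0.9
    censoring_rate: float = 0.25
    n_housekeeping: int = 0
    batch_offsets: list[float] | None = None
    baseline_hazard: float = 0.01  # events per month
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_samples < 1:
            raise ParameterError("n_genes and n_samples must be >= 1")
        self.planted_modules = [
            m if isinstance(m, PlantedModule) else PlantedModule(**m)
            for m in self.planted_modules
        ]
        total = sum(m.size for m in self.planted_modules)
        if total + self.n_housekeeping > self.n_genes:
            raise ParameterError(
                f"module sizes ({total}) + housekeeping ({self.n_housekeeping}) "
                f"exceed n_genes ({self.n_genes})"
            )
        if not 0 <= self.within_module_corr < 1:
            raise ParameterError("within_module_corr must be in [0, 1)")
        if self.noise_sd <= 0:
            raise ParameterError("noise_sd must be > 0 (degenerate correlations otherwise)")
        for p, nm in ((self.background_edge_prob, "background_edge_prob"),
                      (self.module_edge_prob, "module_edge_prob")):
            if not 0 <= p <= 1:
                raise ParameterError(f"{nm} must be in [0, 1]")
        if not 0 <= self.censoring_rate < 1:
            raise ParameterError("censoring_rate must be in [0, 1)")
        if self.baseline_log2_mean < 4 * self.noise_sd:
            raise ParameterError(
                "baseline_log2_mean must be >= 4 * noise_sd to keep log2 values positive"
            )
        if self.baseline_hazard <= 0:
            raise ParameterError("baseline_hazard must be > 0")

    # -- identifier layout: module genes first, then background, then HK --

    @property
    def module_gene_ids(self) -> list[list[str]]:
        out, start = [], 0
        for m in self.planted_modules:
            out.append([f"G{j:05d}" for j in range(start, start + m.size)])
            start += m.size
        return out

    @property
    def gene_ids(self) -> list[str]:
        n_regular = self.n_genes - self.n_housekeeping
        regular = [f"G{j:05d}" for j in range(n_regular)]
        hk = [f"HK{j:04d}" for j in range(self.n_housekeeping)]
        return regular + hk

    @property
    def housekeeping_ids(self) -> list[str]:
        return [f"HK{j:04d}" for j in range(self.n_housekeeping)]

    @property
    def sample_ids(self) -> list[str]:
        return [f"S{j:04d}" for j in range(self.n_samples)]


@dataclass
class GroundTruth:
    module_gene_sets: list[set[str]]
    directions: dict[str, str]  # per module gene
    activities: np.ndarray  # n_samples x n_modules latent factors
    betas: list[float]  # signed, per module
    event_times: np.ndarray | None = None  # true times before censoring
    clip_count: int = 0

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for s in self.module_gene_sets:
            if seen & s:
                raise ParameterError("module gene sets overlap")
            seen |= s


def _rng(config_seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng([config_seed, stage])


def generate_truth(config: SyntheticConfig) -> GroundTruth:
    """Draw the latent module activities and record the planted structure."""
    rng = _rng(config.seed, 0)
    gene_sets = [set(ids) for ids in config.module_gene_ids]
    directions = {
        g: m.direction
        for m, ids in zip(config.planted_modules, config.module_gene_ids)
        for g in ids
    }
    activities = rng.standard_normal((config.n_samples, len(config.planted_modules)))
    betas = [m.signed_beta for m in config.planted_modules]
    return GroundTruth(gene_sets, directions, activities, betas)


def generate_network(config: SyntheticConfig, truth: GroundTruth | None = None) -> InteractionNetwork:
    """Planted-partition random graph: within-module pairs at
    ``module_edge_prob``, all other pairs at ``background_edge_prob``."""
    rng = _rng(config.seed, 1)
    genes = config.gene_ids
    n = len(genes)
    module_of = np.full(n, -1)
    for k, ids in enumerate(config.module_gene_ids):
        for g in ids:
            module_of[genes.index(g)] = k
    iu, ju = np.triu_indices(n, k=1)
    same = (module_of[iu] >= 0) & (module_of[iu] == module_of[ju])
    prob = np.where(same, config.module_edge_prob, config.background_edge_prob)
    draw = rng.random(iu.shape[0]) < prob
    graph = nx.Graph()
    graph.add_nodes_from(genes)
    graph.add_edges_from(
        (genes[i], genes[j]) for i, j in zip(iu[draw], ju[draw])
    )
    return InteractionNetwork(graph)


def generate_expression(config: SyntheticConfig, truth: GroundTruth) -> ExpressionMatrix:
    """Rank-1 module expression on a positive log2 scale.

    Values below the positivity floor are clipped (count recorded on
    ``truth.clip_count``)."""
    rng = _rng(config.seed, 2)
    genes = config.gene_ids
    n, s = len(genes), config.n_samples
    values = config.baseline_log2_mean + config.noise_sd * rng.standard_normal((n, s))
    r = config.within_module_corr
    lam = config.noise_sd * np.sqrt(r / (1 - r))
    gene_index = {g: i for i, g in enumerate(genes)}
    for k, ids in enumerate(config.module_gene_ids):
        f = truth.activities[:, k]
        for g in ids:
            values[gene_index[g]] += lam * f
    # housekeeping probes: distinct, stable per-probe levels (sd/10 noise)
    # so that inter-sample rank correlation over them is near 1 for intact
    # samples and the QC filter is meaningfully exercisable
    n_hk = len(config.housekeeping_ids)
    hk_levels = config.baseline_log2_mean + np.linspace(-2.0, 2.0, n_hk) if n_hk else []
    for g, level in zip(config.housekeeping_ids, hk_levels):
        i = gene_index[g]
        values[i] = level + (config.noise_sd / 10) * rng.standard_normal(s)
    if config.batch_offsets:
        bounds = np.array_split(np.arange(s), len(config.batch_offsets))
        for offset, cols in zip(config.batch_offsets, bounds):
            values[:, cols] += offset
    clipped = values < LOG2_FLOOR
    truth.clip_count = int(clipped.sum())
    if truth.clip_count:
        logger.warning("generate_expression: clipped %d value(s) at %.2f",
                       truth.clip_count, LOG2_FLOOR)
        values = np.clip(values, LOG2_FLOOR, None)
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=config.sample_ids))


def batch_labels(config: SyntheticConfig) -> pd.Series | None:
    """Batch label per sample matching generate_expression's layout."""
    if not config.batch_offsets:
        return None
    bounds = np.array_split(np.arange(config.n_samples), len(config.batch_offsets))
    labels = np.empty(config.n_samples, dtype=object)
    for b, cols in enumerate(bounds):
        labels[cols] = f"batch{b}"
    return pd.Series(labels, index=config.sample_ids, name="batch")


def _calibrate_censoring(hazards: np.ndarray, target: float) -> float:
    """Rate of an independent exponential censoring time such that the
    expected censored fraction is ``target`` (bisection on the closed form
    P(C < T) = theta / (theta + h))."""
    lo, hi = 1e-12, float(hazards.max()) * 1e6

    def frac(theta: float) -> float:
        return float(np.mean(theta / (theta + hazards)))

    for _ in range(200):
        mid = np.sqrt(lo * hi)
        if frac(mid) < target:
            lo = mid
        else:
            hi = mid
    return np.sqrt(lo * hi)


def generate_survival(truth: GroundTruth, config: SyntheticConfig) -> SurvivalData:
    """Exponential event times under the proportional-hazards link, with
    independent exponential censoring at the requested censored fraction."""
    rng = _rng(config.seed, 3)
    linpred = truth.activities @ np.asarray(truth.betas) if truth.betas else np.zeros(config.n_samples)
    hazards = config.baseline_hazard * np.exp(linpred)
    t_event = rng.exponential(1.0 / hazards)
    truth.event_times = t_event
    if config.censoring_rate == 0:
        time, event = t_event, np.ones(config.n_samples, dtype=int)
    else:
        theta = _calibrate_censoring(hazards, config.censoring_rate)
        t_cens = rng.exponential(1.0 / theta, size=config.n_samples)
        time = np.minimum(t_event, t_cens)
        event = (t_event <= t_cens).astype(int)
    table = pd.DataFrame({"time": time, "event": event}, index=config.sample_ids)
    return SurvivalData(table)


def generate_cohort(config: SyntheticConfig):
    """Convenience: truth, network, expression and survival in one call."""
    truth = generate_truth(config)
    network = generate_network(config, truth)
    expr = generate_expression(config, truth)
    surv = generate_survival(truth, config)
    return truth, network, expr, surv


# ---------------------------------------------------------------------------
# IHC fixture
# ---------------------------------------------------------------------------

_TOTAL_LEVELS = np.array([0, 2, 3, 4, 5, 6, 7, 8])


def _total_to_components(total: int) -> tuple[int, int]:
    if total == 0:
        return 0, 0
    intensity = max(1, total - 5)
    return intensity, total - intensity


def generate_ihc(
    n_samples: int, risk_link: float, seed: int
) -> tuple[AllredTable, np.ndarray]:
    """Three cores x three markers of Allred scores per sample.

    JUN couples positively and CD8/CD20 negatively to a standard-normal
    latent risk with strength ``risk_link``. Returns the table and the
    latent risk vector."""
    if n_samples < 1:
        raise ParameterError("n_samples must be >= 1")
    rng = np.random.default_rng([seed, 4])
    risk = rng.standard_normal(n_samples)
    sign = {"JUN": 1.0, "CD8": -1.0, "CD20": -1.0}
    rows = []
    for i in range(n_samples):
        for marker in ALLRED_MARKERS:
            for core in (1, 2, 3):
                latent = sign[marker] * risk_link * risk[i] + rng.standard_normal()
                # monotone binning of the latent onto the 8 valid totals
                level = int(np.clip(np.floor((latent + 2.0) / 4.0 * len(_TOTAL_LEVELS)), 0,
                                    len(_TOTAL_LEVELS) - 1))
                total = int(_TOTAL_LEVELS[level])
                intensity, proportion = _total_to_components(total)
                rows.append((f"S{i:04d}", marker, core, intensity, proportion))
    table = pd.DataFrame(rows, columns=["sample", "marker", "core", "intensity", "proportion"])
    return AllredTable(table), risk


# ---------------------------------------------------------------------------
# On-disk bundle
# ---------------------------------------------------------------------------


def write_cohort(
    out_dir: str | Path,
    config: SyntheticConfig,
    truth: GroundTruth,
    network: InteractionNetwork,
    expr: ExpressionMatrix,
    surv: SurvivalData,
) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_expression(expr, out / "expression.tsv")
    write_survival(surv, out / "survival.tsv")
    write_network(network, out / "network.tsv")
    labels = batch_labels(config)
    if labels is not None:
        labels.to_csv(out / "batches.tsv", sep="\t", index_label="sample")
    with open(out / "housekeeping.txt", "w") as fh:
        for g in config.housekeeping_ids:
            fh.write(g + "\n")
    write_json(
        {
            "module_gene_sets": [sorted(s) for s in truth.module_gene_sets],
            "directions": truth.directions,
            "betas": truth.betas,
            "clip_count": truth.clip_count,
            "seed": config.seed,
        },
        out / "truth.json",
    )
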