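"""Outcome-probe selection, network mapping, edge weighting, Markov
clustering, module filtering and over-representation analysis.

The discovery chain: univariate Cox per probe -> map significant genes onto
the functional-interaction network -> weight edges by |Pearson r| of
expression -> Markov clustering (MCL) -> keep clusters of >= ``min_size``
genes whose mean pairwise expression correlation is >= ``min_corr``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .dataio import ExpressionMatrix, GeneSetCollection, InteractionNetwork
from .errors import InputError, ParameterError
from .scoring import ModuleGeneSets
from .survstats import fit_cox

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Outcome-probe selection
# ---------------------------------------------------------------------------


@dataclass
class OutcomeProbeSet:
    """Per-probe univariate Cox results with selection flags.

    ``table`` is indexed by probe id with columns: beta, se, hazard_ratio,
    p_value, variance, direction ('poor' for HR > 1, 'good' for HR < 1),
    selected (p < alpha and fit converged).
    """

    table: pd.DataFrame
    alpha: float

    @property
    def selected_probes(self) -> list[str]:
        return list(self.table.index[self.table["selected"]])

    def direction_of(self, probe: str) -> str:
        return str(self.table.loc[probe, "direction"])


def select_outcome_probes(expr: ExpressionMatrix, surv, alpha: float = 0.05) -> OutcomeProbeSet:
    """Univariate Cox fit per probe; probes with two-sided Wald p < alpha
    are selected, with direction taken from the sign of beta."""
    from .dataio import SurvivalData

    if isinstance(surv, SurvivalData):
        if list(surv.sample_ids) != list(expr.sample_ids):
            if set(surv.sample_ids) >= set(expr.sample_ids):
                surv = surv.subset(expr.sample_ids)
            else:
                raise InputError("expression samples missing from survival data")
    rows = []
    var = expr.data.var(axis=1, ddof=1)
    for probe in expr.probe_ids:
        x = expr.data.loc[probe].to_numpy()
        try:
            res = fit_cox(x, surv).result
        except InputError:
            rows.append((probe, np.nan, np.nan, np.nan, np.nan, var[probe], "na", False))
            continue
        direction = "poor" if res.beta > 0 else "good"
        selected = bool(res.converged and res.p_value < alpha)
        rows.append(
            (probe, res.beta, res.se, res.hazard_ratio, res.p_value,
             var[probe], direction, selected)
        )
    table = pd.DataFrame(
        rows,
        columns=["probe", "beta", "se", "hazard_ratio", "p_value",
                 "variance", "direction", "selected"],
    ).set_index("probe")
    logger.info(
        "select_outcome_probes: %d / %d probes selected at alpha=%g",
        int(table["selected"].sum()), len(table), alpha,
    )
    return OutcomeProbeSet(table, alpha)


# ---------------------------------------------------------------------------
# Network mapping and weighting
# ---------------------------------------------------------------------------


def map_to_network(
    probes: OutcomeProbeSet,
    network: InteractionNetwork,
    probe_to_gene: dict[str, str] | None = None,
) -> tuple[nx.Graph, dict[str, str], list[str]]:
    """Induce the network subgraph on selected genes.

    Returns ``(subgraph, gene_to_probe, unmapped_genes)``. When several
    selected probes map to one gene, the highest-variance probe is kept.
    """
    selected = probes.selected_probes
    if not selected:
        raise InputError("no selected probes to map")
    gene_to_probe: dict[str, str] = {}
    for probe in selected:
        gene = probe_to_gene.get(probe, probe) if probe_to_gene else probe
        prev = gene_to_probe.get(gene)
        if prev is None:
            gene_to_probe[gene] = probe
        else:
            v = probes.table["variance"]
            if v[probe] > v[prev]:
                logger.info(
                    "map_to_network: gene %s: probe %s replaces lower-variance %s",
                    gene, probe, prev,
                )
                gene_to_probe[gene] = probe
    in_net = [g for g in gene_to_probe if network.graph.has_node(g)]
    unmapped = sorted(g for g in gene_to_probe if g not in in_net)
    if not in_net:
        raise InputError(
            f"no selected gene maps onto the network; examples: {unmapped[:5]}"
        )
    if unmapped:
        logger.info("map_to_network: %d selected gene(s) not in network", len(unmapped))
    subgraph = network.graph.subgraph(in_net).copy()
    gene_to_probe = {g: gene_to_probe[g] for g in subgraph.nodes}
    return subgraph, gene_to_probe, unmapped


@dataclass
class WeightedNetwork:
    """Undirected simple graph whose edge weights are |Pearson r| of the
    mapped probes' expression."""

    graph: nx.Graph
    gene_to_probe: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for a, b, w in self.graph.edges(data="weight"):
            if w is None or not 0 <= w <= 1:
                raise InputError(f"edge weight out of [0,1] on {a}-{b}: {w}")


def weight_edges(
    subgraph: nx.Graph,
    expr: ExpressionMatrix,
    gene_to_probe: dict[str, str] | None = None,
) -> WeightedNetwork:
    """Assign each edge the absolute Pearson correlation of the incident
    genes' expression across samples."""
    if expr.n_samples < 3:
        raise InputError("need >= 3 samples to estimate edge correlations")
    gene_to_probe = gene_to_probe or {g: g for g in subgraph.nodes}
    missing = [g for g in subgraph.nodes if gene_to_probe.get(g) not in expr.data.index]
    if missing:
        raise InputError(f"nodes without a retained probe in expression: {missing[:5]}")
    mat = expr.data.loc[[gene_to_probe[g] for g in subgraph.nodes]].to_numpy()
    sd = mat.std(axis=1)
    zero_var = {g for g, s in zip(subgraph.nodes, sd) if s == 0}
    if zero_var:
        logger.warning(
            "weight_edges: %d zero-variance probe(s); their edges weighted 0",
            len(zero_var),
        )
    idx = {g: i for i, g in enumerate(subgraph.nodes)}
    weighted = nx.Graph()
    weighted.add_nodes_from(subgraph.nodes)
    for a, b in subgraph.edges:
        if a in zero_var or b in zero_var:
            w = 0.0
        else:
            r = np.corrcoef(mat[idx[a]], mat[idx[b]])[0, 1]
            w = float(min(abs(r), 1.0))
        weighted.add_edge(a, b, weight=w)
    return WeightedNetwork(weighted, dict(gene_to_probe))


# ---------------------------------------------------------------------------
# Markov clustering
# ---------------------------------------------------------------------------


@dataclass
class MCLResult:
    clusters: list[set[str]]
    converged: bool
    iterations: int
    max_colsum_deviation: float = 0.0  # max |column sum - 1| after inflations


def _normalize_columns(m: np.ndarray) -> np.ndarray:
    colsum = m.sum(axis=0)
    dead = colsum == 0
    if dead.any():
        # a fully pruned column restarts as a self-attractor
        m[np.flatnonzero(dead), np.flatnonzero(dead)] = 1.0
        colsum = m.sum(axis=0)
    return m / colsum


def mcl_cluster(
    wnet: WeightedNetwork | nx.Graph,
    inflation: float = 2.0,
    expansion: int = 2,
    prune_below: float = 1e-5,
    max_iter: int = 200,
    tol: float = 1e-8,
) -> MCLResult:
    """Markov clustering of a weighted graph.

    Self-loops are set to each node's maximum incident weight (1 for
    isolated nodes) to damp flow oscillation. Iterates expansion (matrix
    power) and inflation (elementwise power + column renormalization) with
    pruning of entries below ``prune_below`` until the flow matrix is
    stable. Clusters are the connected components of the limit matrix's
    support, so every node lands in exactly one cluster.
    """
    graph = wnet.graph if isinstance(wnet, WeightedNetwork) else wnet
    if graph.number_of_nodes() == 0:
        raise InputError("empty graph")
    if inflation <= 1:
        raise ParameterError("inflation must be > 1")
    if expansion < 2:
        raise ParameterError("expansion must be >= 2")
    nodes = sorted(graph.nodes)
    n = len(nodes)
    idx = {g: i for i, g in enumerate(nodes)}
    adj = np.zeros((n, n))
    for a, b, w in graph.edges(data="weight", default=1.0):
        adj[idx[a], idx[b]] = adj[idx[b], idx[a]] = float(w)
    max_w = adj.max(axis=0)
    np.fill_diagonal(adj, np.where(max_w > 0, max_w, 1.0))

    m = _normalize_columns(adj)
    converged = False
    iterations = 0
    colsum_dev = 0.0
    for iterations in range(1, max_iter + 1):
        prev = m
        m = np.linalg.matrix_power(m, expansion)
        m = m**inflation
        m[m < prune_below] = 0.0
        m = _normalize_columns(m)
        colsum_dev = max(colsum_dev, float(np.abs(m.sum(axis=0) - 1.0).max()))
        if np.abs(m - prev).max() < tol:
            converged = True
            break
    if not converged:
        logger.warning("mcl_cluster: no convergence after %d iterations", max_iter)

    support = nx.Graph()
    support.add_nodes_from(range(n))
    rows, cols = np.nonzero(m)
    support.add_edges_from(zip(rows.tolist(), cols.tolist()))
    support.remove_edges_from(nx.selfloop_edges(support))
    clusters = [
        {nodes[i] for i in comp} for comp in nx.connected_components(support)
    ]
    clusters.sort(key=lambda c: (-len(c), min(c)))
    return MCLResult(clusters, converged, iterations, colsum_dev)


# ---------------------------------------------------------------------------
# Module filtering
# ---------------------------------------------------------------------------


@dataclass
class NetworkModule:
    """A filtered cluster: gene set with per-gene outcome directions."""

    module_id: int
    genes: list[str]
    directions: dict[str, str]
    mean_pairwise_corr: float

    @property
    def size(self) -> int:
        return len(self.genes)

    @property
    def name(self) -> str:
        return f"module_{self.module_id}"

    @property
    def gene_sets(self) -> ModuleGeneSets:
        return ModuleGeneSets(
            poor={g for g in self.genes if self.directions[g] == "poor"},
            good={g for g in self.genes if self.directions[g] == "good"},
        )

    def to_dict(self) -> dict:
        return {
            "module_id": self.module_id,
            "genes": list(self.genes),
            "directions": dict(self.directions),
            "mean_pairwise_corr": self.mean_pairwise_corr,
            "size": self.size,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkModule":
        return cls(
            int(d["module_id"]), list(d["genes"]), dict(d["directions"]),
            float(d["mean_pairwise_corr"]),
        )


def mean_pairwise_correlation(
    cluster: set[str],
    expr: ExpressionMatrix,
    gene_to_probe: dict[str, str] | None = None,
    mode: str = "signed",
) -> float:
    """Mean Pearson correlation over all unordered within-cluster pairs.

    ``mode='signed'`` (default) averages signed correlations; ``'absolute'``
    averages |r|.
    """
    if len(cluster) < 2:
        return float("nan")
    gene_to_probe = gene_to_probe or {g: g for g in cluster}
    genes = sorted(cluster)
    mat = expr.data.loc[[gene_to_probe[g] for g in genes]].to_numpy()
    corr = np.corrcoef(mat)
    iu = np.triu_indices(len(genes), k=1)
    vals = corr[iu]
    if mode == "absolute":
        vals = np.abs(vals)
    elif mode != "signed":
        raise ParameterError(f"unknown correlation mode {mode!r}")
    return float(np.nanmean(vals))


def filter_modules(
    clusters: list[set[str]],
    expr: ExpressionMatrix,
    outcome: OutcomeProbeSet,
    gene_to_probe: dict[str, str] | None = None,
    min_size: int = 8,
    min_corr: float = 0.25,
    corr_mode: str = "signed",
) -> list[NetworkModule]:
    """Keep clusters with >= ``min_size`` genes and mean pairwise Pearson
    correlation >= ``min_corr``; number survivors 0..M-1 by decreasing
    size (ties by smallest member gene id)."""
    seen: set[str] = set()
    for c in clusters:
        if seen & c:
            raise InputError("clusters are not disjoint")
        seen |= c
    gene_to_probe = gene_to_probe or {g: g for c in clusters for g in c}
    kept = []
    for cluster in clusters:
        if len(cluster) < min_size:
            continue
        r = mean_pairwise_correlation(cluster, expr, gene_to_probe, corr_mode)
        if not np.isnan(r) and r >= min_corr:
            kept.append((cluster, r))
    kept.sort(key=lambda cr: (-len(cr[0]), min(cr[0])))
    modules = []
    for mid, (cluster, r) in enumerate(kept):
        genes = sorted(cluster)
        directions = {
            g: outcome.direction_of(gene_to_probe[g]) for g in genes
        }
        modules.append(NetworkModule(mid, genes, directions, r))
    return modules


# ---------------------------------------------------------------------------
# Over-representation analysis
# ---------------------------------------------------------------------------


@dataclass
class EnrichmentResult:
    """Per-set hypergeometric over-representation with BH FDR, sorted by p."""

    table: pd.DataFrame  # index: set name; overlap, set_size, universe, p_value, fdr


def hypergeom_tail(overlap, universe, set_size, draw):
    """One-sided tail P(X >= overlap) for X ~ Hypergeometric(universe,
    set_size, draw). Broadcasts over array arguments; returns a float for
    scalar input."""
    p = np.minimum(stats.hypergeom.sf(np.asarray(overlap) - 1, universe, set_size, draw), 1.0)
    return float(p) if np.ndim(overlap) == 0 else p


def enrich_module(
    module_genes,
    sets: GeneSetCollection,
    universe,
) -> EnrichmentResult:
    """One-sided hypergeometric tail P(X >= overlap) per gene set, with
    Benjamini-Hochberg FDR across all sets tested."""
    module_genes = set(module_genes)
    universe = set(universe)
    outside = module_genes - universe
    if outside:
        raise InputError(f"module genes outside the universe: {sorted(outside)[:5]}")
    if len(sets) == 0:
        raise InputError("empty gene-set collection")
    m_total = len(universe)
    n_mod = len(module_genes)
    rows = []
    for name in sets.names:
        members = sets[name] & universe
        k = len(module_genes & members)
        big_k = len(members)
        p = hypergeom_tail(k, m_total, big_k, n_mod)
        rows.append((name, k, big_k, m_total, p))
    table = pd.DataFrame(
        rows, columns=["set", "overlap", "set_size", "universe", "p_value"]
    ).set_index("set")
    table["fdr"] = multipletests(table["p_value"], method="fdr_bh")[1]
    table = table.sort_values(["p_value", "set"], kind="stable")
    return EnrichmentResult(table)
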