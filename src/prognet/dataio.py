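"""Core data types and readers/writers for the on-disk formats.

Formats supported: expression TSV and GCT 1.2, survival TSV, edge-list TSV
and SIF networks, GMT gene-set collections, Allred core tables (TSV), and a
2-column probe-to-gene mapping TSV. Readers validate and reject rather than
silently coerce; writers round-trip bit-equivalently for identifiers and to
1e-12 for numeric values.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import FormatError, InputError, ParameterError

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.12g"


# ---------------------------------------------------------------------------
# Core types
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Probe-by-sample matrix of log2 expression values.

    Parameters
    ----------
    data
        DataFrame with probe ids as index and sample ids as columns.
    probe_to_gene
        Optional mapping from probe id to gene symbol. When absent, probe
        ids are treated as gene symbols directly.
    """

    data: pd.DataFrame
    probe_to_gene: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate probe ids: {dups[:5]}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids: {dups[:5]}")
        values = self.data.to_numpy()
        if values.size and not np.isfinite(values).all():
            bad = np.argwhere(~np.isfinite(values))[0]
            raise FormatError(
                "non-finite expression value at probe "
                f"{self.data.index[bad[0]]!r}, sample {self.data.columns[bad[1]]!r}"
            )

    @property
    def probe_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_probes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def gene_of(self, probe: str) -> str:
        if self.probe_to_gene is None:
            return probe
        return self.probe_to_gene.get(probe, probe)

    def subset_probes(self, probes: Sequence[str]) -> "ExpressionMatrix":
        missing = [p for p in probes if p not in self.data.index]
        if missing:
            raise InputError(f"probes not in matrix: {missing[:5]}")
        return ExpressionMatrix(self.data.loc[list(probes)], self.probe_to_gene)

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        missing = [s for s in samples if s not in self.data.columns]
        if missing:
            raise InputError(f"samples not in matrix: {missing[:5]}")
        return ExpressionMatrix(self.data[list(samples)], self.probe_to_gene)


@dataclass
class SurvivalData:
    """Per-sample follow-up time (months), event indicator, covariates.

    ``table`` is indexed by sample id with at least columns ``time`` and
    ``event``; any further columns are covariates.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        for col in ("time", "event"):
            if col not in self.table.columns:
                raise FormatError(f"survival table missing column {col!r}")
        if self.table.index.has_duplicates:
            raise FormatError("duplicate sample ids in survival table")
        time = self.table["time"].to_numpy(dtype=float)
        if (time < 0).any():
            raise InputError("negative survival times")
        event = self.table["event"].to_numpy()
        if not np.isin(event, (0, 1)).all():
            raise FormatError("event indicator must be 0 or 1")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def time(self) -> np.ndarray:
        return self.table["time"].to_numpy(dtype=float)

    @property
    def event(self) -> np.ndarray:
        return self.table["event"].to_numpy(dtype=int)

    @property
    def covariate_names(self) -> list[str]:
        return [c for c in self.table.columns if c not in ("time", "event")]

    def subset(self, samples: Sequence[str]) -> "SurvivalData":
        missing = [s for s in samples if s not in self.table.index]
        if missing:
            raise InputError(f"samples not in survival table: {missing[:5]}")
        return SurvivalData(self.table.loc[list(samples)])


@dataclass
class InteractionNetwork:
    """Undirected simple graph of gene-gene functional interactions."""

    graph: nx.Graph

    def __post_init__(self) -> None:
        loops = list(nx.selfloop_edges(self.graph))
        if loops:
            raise InputError(f"network contains self-loops: {loops[:5]}")

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT semantics): ordered, unique names, non-empty."""

    sets: dict[str, set[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise FormatError(f"gene set {name!r} is empty")

    @property
    def names(self) -> list[str]:
        return list(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> set[str]:
        return self.sets[name]


ALLRED_MARKERS = ("JUN", "CD8", "CD20")
ALLRED_COLUMNS = ("sample", "marker", "core", "intensity", "proportion")


@dataclass
class AllredTable:
    """Long-format per-core Allred scores: sample x marker x core."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in ALLRED_COLUMNS if c not in self.table.columns]
        if missing:
            raise FormatError(f"Allred table missing columns {missing}")
        inten = self.table["intensity"].to_numpy()
        prop = self.table["proportion"].to_numpy()
        if not np.isin(inten, range(4)).all():
            raise InputError("Allred intensity out of range 0-3")
        if not np.isin(prop, range(6)).all():
            raise InputError("Allred proportion out of range 0-5")
        markers = set(self.table["marker"])
        unknown = markers - set(ALLRED_MARKERS)
        if unknown:
            raise InputError(f"unknown Allred markers: {sorted(unknown)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(pd.unique(self.table["sample"]))


# ---------------------------------------------------------------------------
# Expression I/O
# ---------------------------------------------------------------------------


def _read_numeric_table(path: Path, skiprows: int = 0, index_col=0) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", index_col=index_col, skiprows=skiprows)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad.to_numpy().argmax()]
            raise FormatError(
                f"non-numeric cell in {path} at row {row!r}, column {col!r}"
            )
        df[col] = coerced.astype(float)
    if df.isna().to_numpy().any():
        raise FormatError(f"missing values in {path}; imputation is not supported")
    return df


def read_expression(
    path: str | Path,
    format: str = "tsv",
    probe_to_gene: Mapping[str, str] | None = None,
) -> ExpressionMatrix:
    """Read an expression matrix from a TSV (header row of sample ids) or
    a GCT 1.2 file."""
    path = Path(path)
    if format == "tsv":
        df = _read_numeric_table(path)
    elif format == "gct":
        with open(path) as fh:
            version = fh.readline().strip()
            if version != "#1.2":
                raise FormatError(f"{path}: expected GCT version line '#1.2', got {version!r}")
            dims = fh.readline().split()
            if len(dims) != 2:
                raise FormatError(f"{path}: malformed GCT dimension line")
            n_rows, n_cols = int(dims[0]), int(dims[1])
        body = pd.read_csv(path, sep="\t", skiprows=2, index_col=0)
        if "Description" not in body.columns:
            raise FormatError(f"{path}: GCT body missing Description column")
        body = body.drop(columns="Description")
        if body.shape != (n_rows, n_cols):
            raise FormatError(
                f"{path}: GCT declared dims ({n_rows}, {n_cols}) "
                f"do not match body {body.shape}"
            )
        for col in body.columns:
            coerced = pd.to_numeric(body[col], errors="coerce")
            if (coerced.isna() & body[col].notna()).any():
                raise FormatError(f"{path}: non-numeric cell in column {col!r}")
            body[col] = coerced.astype(float)
        df = body
        df.index.name = None
    else:
        raise ParameterError(f"unknown expression format {format!r}")
    return ExpressionMatrix(df, dict(probe_to_gene) if probe_to_gene else None)


def write_expression(expr: ExpressionMatrix, path: str | Path, format: str = "tsv") -> None:
    path = Path(path)
    if format == "tsv":
        expr.data.to_csv(path, sep="\t", float_format=_FLOAT_FMT, index_label="probe")
    elif format == "gct":
        with open(path, "w") as fh:
            fh.write("#1.2\n")
            fh.write(f"{expr.n_probes}\t{expr.n_samples}\n")
            body = expr.data.copy()
            body.insert(0, "Description", [expr.gene_of(p) for p in expr.probe_ids])
            body.to_csv(fh, sep="\t", float_format=_FLOAT_FMT, index_label="NAME")
    else:
        raise ParameterError(f"unknown expression format {format!r}")


# ---------------------------------------------------------------------------
# Survival I/O
# ---------------------------------------------------------------------------


def read_survival(path: str | Path) -> SurvivalData:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    return SurvivalData(df)


def write_survival(surv: SurvivalData, path: str | Path) -> None:
    surv.table.to_csv(path, sep="\t", float_format=_FLOAT_FMT, index_label="sample")


# ---------------------------------------------------------------------------
# Network I/O
# ---------------------------------------------------------------------------


def read_network(path: str | Path, format: str = "edge_tsv") -> InteractionNetwork:
    """Read an undirected network from a 2-column edge TSV or a SIF file.

    Self-loops are dropped with a logged count; duplicate edges are merged.
    """
    path = Path(path)
    graph = nx.Graph()
    n_loops = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if format == "edge_tsv":
                if len(fields) < 2:
                    raise FormatError(f"{path}:{lineno}: expected 2 columns, got {len(fields)}")
                pairs = [(fields[0], fields[1])]
            elif format == "sif":
                if len(fields) == 1:
                    graph.add_node(fields[0])
                    continue
                if len(fields) < 3:
                    raise FormatError(f"{path}:{lineno}: malformed SIF line")
                source = fields[0]
                pairs = [(source, target) for target in fields[2:]]
            else:
                raise ParameterError(f"unknown network format {format!r}")
            for a, b in pairs:
                if a == b:
                    n_loops += 1
                    continue
                graph.add_edge(a, b)
    if n_loops:
        logger.info("read_network: dropped %d self-loop(s)", n_loops)
    if graph.number_of_nodes() == 0:
        logger.warning("read_network: %s contains no edges", path)
    return InteractionNetwork(graph)


def write_network(net: InteractionNetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in net.graph.edges):
            fh.write(f"{a}\t{b}\n")


# ---------------------------------------------------------------------------
# GMT I/O
# ---------------------------------------------------------------------------


def read_gmt(path: str | Path) -> GeneSetCollection:
    path = Path(path)
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs name, description and >=1 member"
                )
            name, desc, members = fields[0], fields[1], [f for f in fields[2:] if f]
            if not members:
                raise FormatError(f"{path}:{lineno}: gene set {name!r} has no members")
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
            sets[name] = set(members)
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in collection.names:
            desc = collection.descriptions.get(name, "")
            members = "\t".join(sorted(collection[name]))
            fh.write(f"{name}\t{desc}\t{members}\n")


# ---------------------------------------------------------------------------
# Mapping, Allred, JSON helpers
# ---------------------------------------------------------------------------


def read_probe_to_gene(path: str | Path) -> dict[str, str]:
    """Read a 2-column TSV mapping probe id -> gene symbol."""
    path = Path(path)
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns")
            probe, gene = fields
            if probe in mapping:
                raise FormatError(f"{path}:{lineno}: duplicate probe id {probe!r}")
            mapping[probe] = gene
    return mapping


def read_allred(path: str | Path) -> AllredTable:
    path = Path(path)
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            dtype={"sample": str, "marker": str, "core": int, "intensity": int, "proportion": int},
        )
    except (ValueError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    return AllredTable(df)


def write_allred(table: AllredTable, path: str | Path) -> None:
    table.table.to_csv(path, sep="\t", index=False)


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, set):
        return sorted(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)
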