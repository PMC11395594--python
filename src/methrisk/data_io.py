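"""Typed containers and readers/writers for the pipeline's on-disk formats.

Every stage of the pipeline exchanges data through a small set of plain-text
formats: a methylation beta matrix (TSV, CpG rows x sample columns, or the
transposed dialect), a per-sample cohort table, a CpG-to-gene annotation in
the spirit of an Illumina array manifest, a confidence-scored gene
interaction edge list, and gene sets in GMT.  The containers here enforce the
invariants downstream code relies on (unique ids, beta values in [0, 1],
stage labels in {0, 1}, simple graphs) at parse time, so later stages can
assume clean inputs.

Coordinates are 1-based inclusive, the manifest convention.  Missing beta
values are kept as NaN by the readers; model-facing stages require complete
input and :func:`impute_mean` fills gaps with the per-CpG mean.
"""

from __future__ import annotations

import json
import hashlib
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import networkx as nx


class DataFormatError(ValueError):
    """A file violated the documented dialect or a container invariant."""


# ---------------------------------------------------------------------------
# containers


@dataclass
class BetaMatrix:
    """Beta values (methylated fraction, unitless in [0, 1]).

    ``values`` has shape ``(n_cpgs, n_samples)``; missing entries are NaN.
    """

    cpg_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.cpg_ids), len(self.sample_ids)):
            raise DataFormatError(
                f"beta matrix shape {self.values.shape} does not match "
                f"{len(self.cpg_ids)} CpGs x {len(self.sample_ids)} samples"
            )
        _check_unique("cpg_id", self.cpg_ids)
        _check_unique("sample_id", self.sample_ids)
        with np.errstate(invalid="ignore"):
            bad = (self.values < 0.0) | (self.values > 1.0)
        if bad.any():
            i, j = map(int, np.argwhere(bad)[0])
            raise DataFormatError(
                f"beta value {self.values[i, j]!r} out of [0, 1] at "
                f"CpG {self.cpg_ids[i]!r}, sample {self.sample_ids[j]!r}"
            )

    @property
    def n_cpgs(self) -> int:
        return len(self.cpg_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.cpg_ids, columns=self.sample_ids)

    def subset_cpgs(self, cpg_ids: Sequence[str]) -> "BetaMatrix":
        """Row subset in the order given; unknown ids raise."""
        index = {c: i for i, c in enumerate(self.cpg_ids)}
        missing = [c for c in cpg_ids if c not in index]
        if missing:
            raise KeyError(f"CpGs absent from matrix: {missing[:5]}" +
                           (" ..." if len(missing) > 5 else ""))
        rows = [index[c] for c in cpg_ids]
        return BetaMatrix(list(cpg_ids), list(self.sample_ids), self.values[rows])

    def subset_samples(self, sample_ids: Sequence[str]) -> "BetaMatrix":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        cols = [index[s] for s in sample_ids]
        return BetaMatrix(list(self.cpg_ids), list(sample_ids), self.values[:, cols])


@dataclass
class CohortTable:
    """Per-sample metadata: age (years), disease label, binary stage.

    ``stage`` is 0 for early, 1 for late disease; age may be NaN for
    disease-only cohorts.
    """

    table: pd.DataFrame  # columns: sample_id, age, disease, stage

    def __post_init__(self) -> None:
        required = {"sample_id", "age", "disease", "stage"}
        missing = required - set(self.table.columns)
        if missing:
            raise DataFormatError(f"cohort table missing columns: {sorted(missing)}")
        _check_unique("sample_id", self.table["sample_id"].tolist())
        stage = self.table["stage"].dropna()
        if not stage.isin([0, 1]).all():
            bad = stage[~stage.isin([0, 1])].iloc[0]
            raise DataFormatError(f"stage label {bad!r} not in {{0, 1}}")
        age = self.table["age"].dropna()
        if (age < 0).any():
            raise DataFormatError("negative age in cohort table")
        self.table = self.table.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return self.table["sample_id"].tolist()

    def ages(self, sample_ids: Sequence[str] | None = None) -> np.ndarray:
        t = self.table.set_index("sample_id")
        ids = list(sample_ids) if sample_ids is not None else self.sample_ids
        return t.loc[ids, "age"].to_numpy(dtype=float)

    def stages(self, sample_ids: Sequence[str] | None = None) -> np.ndarray:
        t = self.table.set_index("sample_id")
        ids = list(sample_ids) if sample_ids is not None else self.sample_ids
        return t.loc[ids, "stage"].to_numpy(dtype=float)


@dataclass
class CpGAnnotation:
    """CpG id -> (chromosome, 1-based position, gene symbol(s), ';'-separated)."""

    table: pd.DataFrame  # columns: cpg_id, chromosome, position, gene

    def __post_init__(self) -> None:
        required = {"cpg_id", "chromosome", "position", "gene"}
        missing = required - set(self.table.columns)
        if missing:
            raise DataFormatError(f"annotation missing columns: {sorted(missing)}")
        _check_unique("cpg_id", self.table["cpg_id"].tolist())
        if (self.table["position"] < 1).any():
            raise DataFormatError("annotation position must be >= 1 (1-based)")
        self.table = self.table.reset_index(drop=True)

    def genes_for(self, cpg_id: str) -> list[str]:
        row = self.table.loc[self.table["cpg_id"] == cpg_id, "gene"]
        if row.empty:
            return []
        return [g for g in str(row.iloc[0]).split(";") if g]


@dataclass
class GeneNetwork:
    """Undirected gene interaction graph with edge confidences in [0, 1]."""

    graph: nx.Graph

    def __post_init__(self) -> None:
        if any(u == v for u, v in self.graph.edges):
            raise DataFormatError("gene network contains a self-edge")
        for u, v, d in self.graph.edges(data=True):
            c = d.get("confidence", 1.0)
            if not (0.0 <= c <= 1.0):
                raise DataFormatError(f"confidence {c!r} on edge ({u}, {v}) out of [0, 1]")

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def density_of(self, genes: Iterable[str]) -> float:
        """Loop-free edge density 2E / (n(n-1)) of the induced subgraph."""
        sub = self.graph.subgraph([g for g in genes if g in self.graph])
        n = sub.number_of_nodes()
        if n < 2:
            return 0.0
        return 2.0 * sub.number_of_edges() / (n * (n - 1))


@dataclass
class GeneSetCollection:
    """Named gene sets plus an optional explicit background universe."""

    sets: dict[str, set[str]]
    universe: set[str] | None = None

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise DataFormatError(f"gene set {name!r} is empty")


@dataclass
class MetricsReport:
    """Rows of (disease, model, auc, acc, precision, recall), each in [0, 1]."""

    table: pd.DataFrame

    COLUMNS = ["disease", "model", "auc", "acc", "precision", "recall"]

    def __post_init__(self) -> None:
        missing = set(self.COLUMNS) - set(self.table.columns)
        if missing:
            raise DataFormatError(f"metrics report missing columns: {sorted(missing)}")
        metrics = self.table[["auc", "acc", "precision", "recall"]].to_numpy(dtype=float)
        finite = metrics[np.isfinite(metrics)]
        if ((finite < 0) | (finite > 1)).any():
            raise DataFormatError("metric outside [0, 1] in report")
        self.table = self.table[self.COLUMNS].reset_index(drop=True)


@dataclass
class MarkerPanel:
    """Final marker CpG panel with gene provenance."""

    cpg_ids: list[str]
    genes: list[str]
    cpg_to_gene: dict[str, str]
    provenance: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# readers


def read_beta_matrix(path: str | Path, orientation_hint: str = "cpg_rows") -> BetaMatrix:
    """Read a beta-value TSV.

    ``orientation_hint`` is ``"cpg_rows"`` (first column = CpG ids, header =
    sample ids; the GEO series-matrix-like layout) or ``"sample_rows"`` for
    the transposed dialect.
    """
    if orientation_hint not in ("cpg_rows", "sample_rows"):
        raise ValueError(f"unknown orientation_hint {orientation_hint!r}")
    with open(path) as fh:
        width = len(fh.readline().rstrip("\n").split("\t"))
        for lineno, line in enumerate(fh, 2):
            if line.strip() and len(line.rstrip("\n").split("\t")) != width:
                raise DataFormatError(f"{path}:{lineno}: ragged row "
                                      f"(expected {width} fields)")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.isna().any():
        raise DataFormatError(f"{path}: empty id cell in first column")
    values = df.apply(pd.to_numeric, errors="raise").to_numpy(dtype=float)
    if orientation_hint == "sample_rows":
        values = values.T
        cpg_ids, sample_ids = list(df.columns), [str(i) for i in df.index]
    else:
        cpg_ids, sample_ids = [str(i) for i in df.index], list(df.columns)
    return BetaMatrix(cpg_ids, sample_ids, values)


def write_beta_matrix(beta: BetaMatrix, path: str | Path) -> None:
    df = beta.to_frame()
    df.index.name = "cpg_id"
    df.to_csv(path, sep="\t", float_format="%.6f", na_rep="")


def read_cohort(path: str | Path) -> CohortTable:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "disease": str})
    return CohortTable(df)


def write_cohort(cohort: CohortTable, path: str | Path) -> None:
    cohort.table.to_csv(path, sep="\t", index=False)


def read_annotation(path: str | Path) -> CpGAnnotation:
    df = pd.read_csv(path, sep="\t",
                     dtype={"cpg_id": str, "chromosome": str, "gene": str})
    return CpGAnnotation(df)


def write_annotation(annotation: CpGAnnotation, path: str | Path) -> None:
    annotation.table.to_csv(path, sep="\t", index=False)


def read_edges(path: str | Path, min_confidence: float = 0.0) -> GeneNetwork:
    """Read a whitespace/tab-delimited edge list ``gene_a gene_b confidence``.

    Unordered duplicates collapse to one edge (the max confidence wins);
    edges below ``min_confidence`` and self-edges are dropped.
    """
    df = pd.read_csv(path, sep=r"\s+", comment="#",
                     names=["gene_a", "gene_b", "confidence"],
                     dtype={"gene_a": str, "gene_b": str}, header=None,
                     skiprows=_edge_header_rows(path))
    g = nx.Graph()
    for a, b, c in df.itertuples(index=False):
        c = float(c)
        if a == b or c < min_confidence:
            continue
        if g.has_edge(a, b):
            g[a][b]["confidence"] = max(g[a][b]["confidence"], c)
        else:
            g.add_edge(a, b, confidence=c)
    return GeneNetwork(g)


def _edge_header_rows(path: str | Path) -> int:
    with open(path) as fh:
        first = fh.readline().split()
    # tolerate an optional header line
    if len(first) >= 3 and first[0].lower() in ("gene_a", "protein1", "node1"):
        return 1
    return 0


def write_edges(network: GeneNetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\tconfidence\n")
        for u, v, d in sorted(network.graph.edges(data=True)):
            fh.write(f"{u}\t{v}\t{d.get('confidence', 1.0):.3f}\n")


def read_gmt(path: str | Path, universe: set[str] | None = None) -> GeneSetCollection:
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise DataFormatError(
                    f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields "
                    f"(name, description, members), got {len(fields)}")
            name, _desc, *members = fields
            sets[name] = {m for m in members if m}
    return GeneSetCollection(sets, universe)


def write_gmt(collection: GeneSetCollection, path: str | Path,
              description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            fh.write("\t".join([name, description, *sorted(members)]) + "\n")


# ---------------------------------------------------------------------------
# report writing


def write_report(report, path: str | Path, *, seed: int | None = None,
                 config: Mapping | None = None) -> None:
    """Write a MetricsReport / MarkerPanel / enrichment table as TSV plus a
    JSON sidecar with run metadata (seed, config hash, library versions)."""
    path = Path(path)
    if isinstance(report, MetricsReport):
        df = report.table
    elif isinstance(report, MarkerPanel):
        df = pd.DataFrame({
            "cpg_id": report.cpg_ids,
            "gene": [report.cpg_to_gene[c] for c in report.cpg_ids],
        })
    elif isinstance(report, pd.DataFrame):
        df = report
    else:
        raise TypeError(f"cannot serialize report of type {type(report).__name__}")
    df.to_csv(path, sep="\t", index=False)
    meta = {
        "seed": seed,
        "config_hash": config_hash(config) if config is not None else None,
        "versions": {
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    path.with_suffix(path.suffix + ".meta.json").write_text(
        json.dumps(meta, indent=2, sort_keys=True) + "\n")


def config_hash(config: Mapping) -> str:
    blob = json.dumps(_jsonable(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _jsonable(obj):
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, set):
        return [_jsonable(v) for v in sorted(obj)]
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


# ---------------------------------------------------------------------------
# utilities


def impute_mean(beta: BetaMatrix) -> BetaMatrix:
    """Fill missing betas with the per-CpG mean over non-missing samples.

    A CpG missing in every sample is filled with 0.5 (uninformative midpoint).
    """
    values = beta.values.copy()
    mask = np.isnan(values)
    if mask.any():
        with np.errstate(invalid="ignore"):
            row_mean = np.nanmean(np.where(mask, np.nan, values), axis=1)
        row_mean = np.where(np.isnan(row_mean), 0.5, row_mean)
        values[mask] = np.broadcast_to(row_mean[:, None], values.shape)[mask]
    return BetaMatrix(list(beta.cpg_ids), list(beta.sample_ids), values)


def _check_unique(label: str, ids: Sequence) -> None:
    seen: set = set()
    for x in ids:
        if x in seen:
            raise DataFormatError(f"duplicate {label}: {x!r}")
        seen.add(x)
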