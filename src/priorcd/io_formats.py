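"""Typed containers and on-disk formats shared by every pipeline stage.

All tabular artifacts are plain TSV: matrices carry feature IDs in the first
column and sample IDs in the header row (CellMiner-style exports); networks
are undirected edge lists with two drug-ID columns and an optional weight
column; seed sets are one drug ID per line. Missing matrix entries are coded
as an empty cell or ``NA`` and kept as missing — never imputed to zero.

IDs are matched exactly (no case folding): NSC identifiers are numeric
strings and silent normalisation hides join bugs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_NA_VALUES = ["", "NA", "NaN", "nan"]


class FormatError(ValueError):
    """A file does not conform to the expected on-disk dialect."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


class FeatureMatrix:
    """Features x samples real matrix backed by a pandas DataFrame.

    Feature and sample IDs must be unique; values may contain NaN (missing).
    """

    _feature_axis = "feature"

    def __init__(self, data: pd.DataFrame):
        if data.index.has_duplicates:
            dups = data.index[data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate {self._feature_axis} IDs: {dups[:5]}")
        if data.columns.has_duplicates:
            dups = data.columns[data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample IDs: {dups[:5]}")
        self.data = data.astype(float)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def __eq__(self, other) -> bool:
        if not isinstance(other, FeatureMatrix):
            return NotImplemented
        return (
            self.feature_ids == other.feature_ids
            and self.sample_ids == other.sample_ids
            and np.allclose(self.values, other.values, equal_nan=True)
        )

    def __repr__(self) -> str:
        n, m = self.shape
        return f"{type(self).__name__}({n} {self._feature_axis}s x {m} samples)"


class ExpressionMatrix(FeatureMatrix):
    """mRNA/miRNA expression, or pathway activities (pathways x samples)."""


class DrugActivityMatrix(FeatureMatrix):
    """Drugs x cell lines of -log10(GI50); higher value = higher sensitivity."""

    _feature_axis = "drug"

    @property
    def drug_ids(self) -> list[str]:
        return self.feature_ids


@dataclass
class GeneSetCollection:
    """Named, non-empty sets of feature IDs (pathways, or miRNA pathways)."""

    sets: dict[str, frozenset[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
            self.sets[name] = frozenset(members)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]

    def items(self):
        return self.sets.items()


class DrugSimilarityNetwork:
    """Undirected, unweighted graph over drug IDs (the object propagated over).

    Edges are stored canonically (lexicographic endpoint order) so each
    undirected edge appears once; self-loops are rejected. An optional
    per-edge weight (the similarity r) is kept as annotation only —
    propagation treats the network as a plain adjacency.
    """

    def __init__(
        self,
        nodes: Iterable[str] = (),
        edges: Iterable[tuple] = (),
        weights: Mapping[tuple[str, str], float] | None = None,
    ):
        g = nx.Graph()
        g.add_nodes_from(str(n) for n in nodes)
        for e in edges:
            u, v = str(e[0]), str(e[1])
            if u == v:
                raise ValueError(f"self-loop edge {u!r}")
            g.add_edge(u, v)
        if weights:
            for (u, v), w in weights.items():
                if g.has_edge(u, v):
                    g[u][v]["weight"] = float(w)
        self.graph = g

    @classmethod
    def from_graph(cls, g: nx.Graph) -> "DrugSimilarityNetwork":
        net = cls.__new__(cls)
        if any(u == v for u, v in g.edges):
            raise ValueError("graph contains self-loops")
        net.graph = nx.Graph(g)
        return net

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[tuple[str, str]]:
        return {tuple(sorted((u, v))) for u, v in self.graph.edges}

    def degree(self, node: str) -> int:
        return self.graph.degree(node)

    def degree_sequence(self) -> dict[str, int]:
        return dict(self.graph.degree)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def __eq__(self, other) -> bool:
        if not isinstance(other, DrugSimilarityNetwork):
            return NotImplemented
        return self.nodes == other.nodes and self.edges == other.edges

    def __repr__(self) -> str:
        return f"DrugSimilarityNetwork({self.n_nodes} drugs, {self.n_edges} edges)"


@dataclass(frozen=True)
class SeedSet:
    """Approved therapeutic drugs for a cancer of interest (the restart set)."""

    cancer_label: str
    drug_ids: frozenset[str]

    def __post_init__(self):
        if not self.drug_ids:
            raise ValueError("seed set is empty")
        object.__setattr__(self, "drug_ids", frozenset(self.drug_ids))

    def __len__(self) -> int:
        return len(self.drug_ids)

    def without(self, drug_id: str) -> "SeedSet":
        remaining = self.drug_ids - {drug_id}
        if not remaining:
            raise ValueError("removing the drug leaves an empty seed set")
        return SeedSet(self.cancer_label, remaining)


class PriorScoreTable:
    """Per-drug prioritisation scores with optional permutation p / BH FDR.

    Backed by a DataFrame with columns drug_id, prior_score, p_value, fdr,
    rank, is_seed. Ranks are a permutation of 1..n: decreasing score, ties
    broken by drug ID.
    """

    COLUMNS = ["drug_id", "prior_score", "p_value", "fdr", "rank", "is_seed"]

    def __init__(self, frame: pd.DataFrame):
        missing = set(self.COLUMNS) - set(frame.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        frame = frame[self.COLUMNS].reset_index(drop=True)
        if (frame["prior_score"] < 0).any():
            raise ValueError("prior scores must be nonnegative")
        ranks = np.sort(frame["rank"].to_numpy())
        if not np.array_equal(ranks, np.arange(1, len(frame) + 1)):
            raise ValueError("ranks are not a permutation of 1..n")
        self.frame = frame.sort_values("rank").reset_index(drop=True)

    @classmethod
    def from_scores(
        cls,
        drug_ids: Iterable[str],
        scores: Iterable[float],
        seed_ids: Iterable[str] = (),
        p_values: Iterable[float] | None = None,
        fdr: Iterable[float] | None = None,
    ) -> "PriorScoreTable":
        drug_ids = list(drug_ids)
        seed_ids = set(seed_ids)
        frame = pd.DataFrame(
            {
                "drug_id": drug_ids,
                "prior_score": np.asarray(list(scores), dtype=float),
                "p_value": np.nan if p_values is None else list(p_values),
                "fdr": np.nan if fdr is None else list(fdr),
                "is_seed": [d in seed_ids for d in drug_ids],
            }
        )
        # decreasing score, ties by drug ID -- deterministic across platforms
        order = frame.sort_values(
            ["prior_score", "drug_id"], ascending=[False, True], kind="mergesort"
        ).index
        frame.loc[order, "rank"] = np.arange(1, len(frame) + 1)
        frame["rank"] = frame["rank"].astype(int)
        return cls(frame)

    def scores(self) -> pd.Series:
        return self.frame.set_index("drug_id")["prior_score"]

    def candidates(self, fdr_max: float | None = None) -> pd.DataFrame:
        """Non-seed drugs, optionally thresholded on FDR, in rank order."""
        out = self.frame[~self.frame["is_seed"]]
        if fdr_max is not None:
            out = out[out["fdr"] < fdr_max]
        return out.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _read_tsv_matrix(path) -> pd.DataFrame:
    path = Path(path)
    try:
        raw = pd.read_csv(
            path, sep="\t", index_col=0, dtype=str, keep_default_na=False
        )
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file") from None
    if raw.shape[1] == 0:
        raise FormatError(f"{path}: no sample columns")
    df = pd.DataFrame(index=raw.index.astype(str))
    for col in raw.columns:
        converted = pd.to_numeric(raw[col].mask(raw[col].isin(_NA_VALUES)),
                                  errors="coerce")
        bad = converted.isna() & ~raw[col].isin(_NA_VALUES)
        if bad.any():
            row = raw.index[bad.to_numpy().nonzero()[0][0]]
            raise FormatError(
                f"{path}: non-numeric value {raw.loc[row, col]!r} "
                f"at row {row!r}, column {col!r}"
            )
        df[col] = converted
    return df


def _aggregate_duplicates(df: pd.DataFrame) -> pd.DataFrame:
    """Collapse duplicate IDs by element-wise mean ignoring missing values,
    preserving order of first appearance."""
    if not df.index.has_duplicates:
        return df
    n_dup = int(df.index.duplicated().sum())
    logger.info("aggregating %d duplicate feature rows by mean", n_dup)
    return df.groupby(level=0, sort=False).mean()


def read_expression_matrix(path, aggregate: str = "mean") -> ExpressionMatrix:
    """Read a features x samples TSV, collapsing duplicate IDs by mean."""
    if aggregate != "mean":
        raise ValueError(f"unsupported aggregation {aggregate!r}")
    return ExpressionMatrix(_aggregate_duplicates(_read_tsv_matrix(path)))


def read_drug_activity_matrix(path, aggregate: str = "mean") -> DrugActivityMatrix:
    """Read a drugs x cell-lines -log10(GI50) TSV, mean-aggregating duplicates."""
    if aggregate != "mean":
        raise ValueError(f"unsupported aggregation {aggregate!r}")
    return DrugActivityMatrix(_aggregate_duplicates(_read_tsv_matrix(path)))


def write_matrix(matrix: FeatureMatrix, path, id_label: str = "id") -> None:
    df = matrix.data.copy()
    df.index.name = id_label
    df.to_csv(path, sep="\t", na_rep="NA")


def read_gmt(path) -> GeneSetCollection:
    """Read a Broad-dialect GMT file: name TAB description TAB member...

    Duplicate members within a line are deduplicated; a duplicate set name or
    a line with fewer than three fields is an error.
    """
    path = Path(path)
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {lineno}: expected >=3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            name, desc, *members = fields
            members = [m for m in members if m]
            if name in sets:
                raise FormatError(f"{path}: line {lineno}: duplicate set name {name!r}")
            if not members:
                raise FormatError(f"{path}: line {lineno}: set {name!r} has no members")
            sets[name] = frozenset(members)
            descriptions[name] = desc
    if not sets:
        raise FormatError(f"{path}: no gene sets")
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as handle:
        for name, members in collection.items():
            desc = collection.descriptions.get(name, "na")
            handle.write("\t".join([name, desc, *sorted(members)]) + "\n")


def _looks_like_header(fields: list[str]) -> bool:
    # our writer's column names, or a non-numeric third column of a
    # weighted edge list
    if [f.lower() for f in fields[:2]] == ["drug_a", "drug_b"]:
        return True
    if len(fields) < 3:
        return False
    try:
        float(fields[2])
        return False
    except ValueError:
        return True


def read_edge_list(path, has_header: bool | None = None) -> DrugSimilarityNetwork:
    """Read an undirected edge-list TSV (two ID columns, optional weight).

    Reversed and repeated rows collapse onto one canonical edge; a self-loop
    row is an error. ``has_header=None`` auto-detects a header from a
    non-numeric third column.
    """
    path = Path(path)
    edges: dict[tuple[str, str], float | None] = {}
    with open(path) as handle:
        lines = [ln.rstrip("\n") for ln in handle if ln.strip()]
    if has_header is None and lines:
        has_header = _looks_like_header(lines[0].split("\t"))
    if has_header and lines:
        lines = lines[1:]
    for lineno, line in enumerate(lines, start=1):
        fields = line.split("\t")
        if len(fields) < 2 or not fields[1]:
            raise FormatError(f"{path}: row {lineno}: fewer than two columns")
        u, v = fields[0], fields[1]
        if u == v:
            raise FormatError(f"{path}: row {lineno}: self-loop {u!r}")
        key = tuple(sorted((u, v)))
        weight = None
        if len(fields) >= 3 and fields[2]:
            try:
                weight = float(fields[2])
            except ValueError:
                raise FormatError(
                    f"{path}: row {lineno}: non-numeric weight {fields[2]!r}"
                ) from None
        edges.setdefault(key, weight)
    net = DrugSimilarityNetwork()
    for (u, v), w in edges.items():
        net.graph.add_edge(u, v)
        if w is not None:
            net.graph[u][v]["weight"] = w
    return net


def write_edge_list(net: DrugSimilarityNetwork, path, header: bool = True) -> None:
    """Write canonical edges as TSV; weight column emitted when any edge has one."""
    weighted = any("weight" in net.graph[u][v] for u, v in net.graph.edges)
    with open(path, "w") as handle:
        if header:
            cols = ["drug_a", "drug_b"] + (["weight"] if weighted else [])
            handle.write("\t".join(cols) + "\n")
        for u, v in sorted(net.edges):
            row = [u, v]
            if weighted:
                row.append(format(net.graph[u][v].get("weight", float("nan")), ".6g"))
            handle.write("\t".join(row) + "\n")


def read_seed_set(
    path, network: DrugSimilarityNetwork, cancer_label: str | None = None
) -> SeedSet:
    """Read one drug ID per line, dropping (with a warning) IDs absent from
    the network; an all-unmapped list is a hard error."""
    path = Path(path)
    with open(path) as handle:
        ids = [line.strip() for line in handle if line.strip()]
    if not ids:
        raise FormatError(f"{path}: no drug IDs")
    present = network.nodes
    mapped = [d for d in ids if d in present]
    dropped = len(ids) - len(mapped)
    if dropped:
        logger.warning(
            "%s: %d of %d seed drugs not in the network were dropped",
            path, dropped, len(ids),
        )
    if not mapped:
        raise ValueError(f"{path}: none of the {len(ids)} seed drugs map to the network")
    return SeedSet(cancer_label or path.stem, frozenset(mapped))


def write_seed_set(seeds: SeedSet, path) -> None:
    with open(path, "w") as handle:
        for d in sorted(seeds.drug_ids):
            handle.write(d + "\n")


def read_score_table(path) -> PriorScoreTable:
    frame = pd.read_csv(path, sep="\t", dtype={"drug_id": str}, na_values=_NA_VALUES)
    return PriorScoreTable(frame)


def write_score_table(table: PriorScoreTable, path) -> None:
    table.frame.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_mirna_target_map(path) -> dict[str, frozenset[str]]:
    """Read a two-column miRNA TAB target-gene interaction TSV."""
    path = Path(path)
    targets: dict[str, set[str]] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2 or not fields[0] or not fields[1]:
                raise FormatError(f"{path}: line {lineno}: expected two columns")
            targets.setdefault(fields[0], set()).add(fields[1])
    if not targets:
        raise FormatError(f"{path}: no interactions")
    return {m: frozenset(t) for m, t in targets.items()}


def write_mirna_target_map(targets: Mapping[str, frozenset[str]], path) -> None:
    with open(path, "w") as handle:
        for mirna in sorted(targets):
            for gene in sorted(targets[mirna]):
                handle.write(f"{mirna}\t{gene}\n")
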