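"""Input tables, study design and the compartment network.

Three inputs drive a systemic analysis: a wide abundance table (rows =
samples, columns = shorthand lipid names), a sample-metadata table mapping
each sample to a phenotype and a compartment (tissue / fluid), and an
undirected compartment network whose edges encode metabolic adjacency
(direct lipid exchange, e.g. serum-liver).

Missing cells and explicit zeros both mean "not detected" for presence
calling; quantitative stages exclude them from means by default.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .nomenclature import (
    LipidName,
    LipidNameError,
    UnknownLipidClassWarning,
    format_lipid_name,
    parse_lipid_name,
)

__all__ = [
    "SCHEMA_VERSION",
    "AbundanceTable",
    "StudyDesign",
    "CompartmentNetwork",
    "DataValidationError",
    "read_abundance_table",
    "read_design",
    "read_network",
    "validate_design",
    "default_network",
]

SCHEMA_VERSION = "lipidtraffic-schema-1"


class DataValidationError(ValueError):
    """Raised when an input file violates its contract."""


@dataclass
class AbundanceTable:
    """Wide matrix of signal intensities (arbitrary units), samples x variables.

    ``data`` holds the raw values with NaN for missing cells; ``variables``
    the parsed lipid names for every parseable column (canonical order =
    column order); ``unparsed`` column headers that failed to parse and
    ``unknown_classes`` class tokens that parsed but are not recognised.
    """

    data: pd.DataFrame
    variables: list[LipidName] = field(default_factory=list)
    unparsed: list[str] = field(default_factory=list)
    unknown_classes: list[str] = field(default_factory=list)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def variable_names(self) -> list[str]:
        return list(self.data.columns)

    def detected(self) -> pd.DataFrame:
        """Boolean detection mask: strictly positive signal (NaN -> False)."""
        return self.data.gt(0).fillna(False)

    def quantitative(self, missing_as_zero: bool = False) -> pd.DataFrame:
        """Values for quantitative stages.

        Default excludes both missing and zero cells (NaN); with
        ``missing_as_zero`` every non-detected cell becomes 0 instead.
        """
        if missing_as_zero:
            return self.data.fillna(0.0)
        return self.data.where(self.data > 0)


@dataclass
class StudyDesign:
    """Sample metadata: phenotype and compartment per sample, plus covariates."""

    frame: pd.DataFrame  # index = sample_id; columns phenotype, compartment, ...

    def __post_init__(self) -> None:
        missing = {"phenotype", "compartment"} - set(self.frame.columns)
        if missing:
            raise DataValidationError(f"design missing columns: {sorted(missing)}")
        if self.frame.index.has_duplicates:
            dupes = self.frame.index[self.frame.index.duplicated()].tolist()
            raise DataValidationError(f"duplicate sample ids in design: {dupes}")

    @property
    def phenotypes(self) -> list[str]:
        return sorted(self.frame["phenotype"].unique())

    @property
    def compartments(self) -> list[str]:
        return sorted(self.frame["compartment"].unique())

    def samples_in(self, phenotype: str, compartment: str) -> list[str]:
        m = (self.frame["phenotype"] == phenotype) & (
            self.frame["compartment"] == compartment
        )
        return list(self.frame.index[m])

    def covariates(self) -> list[str]:
        return [c for c in self.frame.columns if c not in ("phenotype", "compartment")]


@dataclass
class CompartmentNetwork:
    """Simple undirected graph of compartments; edges = metabolic adjacency."""

    graph: nx.Graph

    @classmethod
    def from_lists(cls, nodes: list[str], edges: list[tuple[str, str]]) -> "CompartmentNetwork":
        g = nx.Graph()
        g.add_nodes_from(nodes)
        seen: set[frozenset] = set()
        for a, b in edges:
            if a == b:
                raise DataValidationError(f"self-loop edge [{a}, {b}]")
            if a not in g.nodes or b not in g.nodes:
                raise DataValidationError(f"edge [{a}, {b}] references unknown node")
            key = frozenset((a, b))
            if key in seen:
                raise DataValidationError(f"duplicated edge [{a}, {b}]")
            seen.add(key)
            g.add_edge(a, b)
        return cls(g)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str]]:
        return [tuple(sorted(e)) for e in sorted(map(sorted, self.graph.edges))]

    def is_edge(self, a: str, b: str) -> bool:
        return self.graph.has_edge(a, b)

    def nonadjacent_pairs(self) -> list[tuple[str, str]]:
        out = []
        ns = sorted(self.graph.nodes)
        for i, a in enumerate(ns):
            for b in ns[i + 1:]:
                if not self.graph.has_edge(a, b):
                    out.append((a, b))
        return out

    def to_json(self, path: str | Path) -> None:
        payload = {
            "schema": SCHEMA_VERSION,
            "nodes": sorted(self.graph.nodes),
            "edges": [list(e) for e in self.edges],
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


def default_network() -> CompartmentNetwork:
    """Bundled default compartment network.

    Nine murine compartments with serum as the hub linked to every tissue:
    circulation is the common lipid highway between organs.  Real studies
    should supply their own adjacency; this stand-in is always overridable.
    """
    tissues = [
        "liver", "spleen", "kidney", "heart", "brain",
        "vastus muscle", "BAT", "WAT",
    ]
    return CompartmentNetwork.from_lists(
        ["serum"] + tissues, [("serum", t) for t in tissues]
    )


def _sniff_sep(path: Path, dialect: str | None) -> str:
    if dialect in ("csv", ","):
        return ","
    if dialect in ("tsv", "\t"):
        return "\t"
    if path.suffix.lower() in (".tsv", ".tab"):
        return "\t"
    if path.suffix.lower() == ".csv":
        return ","
    sample = path.read_text()[:4096]
    try:
        return csv.Sniffer().sniff(sample, delimiters=",\t;").delimiter
    except csv.Error:
        return ","


def read_abundance_table(path: str | Path, dialect: str | None = None) -> AbundanceTable:
    """Read a wide CSV/TSV abundance table (first column = sample id).

    Duplicate headers or sample ids, and negative intensities, are hard
    errors; unparseable or unknown-class columns are kept and reported.
    """
    path = Path(path)
    sep = _sniff_sep(path, dialect)
    with open(path, newline="") as fh:
        header = next(csv.reader(fh, delimiter=sep))
    names = header[1:]
    dupes = sorted({n for n in names if names.count(n) > 1})
    if dupes:
        raise DataValidationError(f"duplicate column headers: {dupes}")

    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    if df.index.has_duplicates:
        d = df.index[df.index.duplicated()].tolist()
        raise DataValidationError(f"duplicate sample ids: {d}")
    df = df.astype(float)

    neg = np.argwhere(df.to_numpy() < 0)
    if neg.size:
        cells = [f"({df.index[i]}, {df.columns[j]})" for i, j in neg[:10]]
        raise DataValidationError(f"negative intensities at {', '.join(cells)}")

    variables: list[LipidName] = []
    unparsed: list[str] = []
    unknown: list[str] = []
    rename: dict[str, str] = {}
    import warnings as _warnings

    for col in df.columns:
        with _warnings.catch_warnings(record=True) as caught:
            _warnings.simplefilter("always", UnknownLipidClassWarning)
            try:
                ln = parse_lipid_name(col)
            except LipidNameError:
                ln = None
        for w in caught:
            if issubclass(w.category, UnknownLipidClassWarning):
                unknown.append(w.message.args[1])
        if ln is None:
            unparsed.append(col)
            continue
        variables.append(ln)
        rename[col] = format_lipid_name(ln)
    df = df.rename(columns=rename)
    return AbundanceTable(df, variables, unparsed, sorted(set(unknown)))


def write_abundance_table(table: AbundanceTable, path: str | Path) -> None:
    table.data.to_csv(path, index_label="sample_id", float_format="%.10g")


def read_design(path: str | Path, dialect: str | None = None) -> StudyDesign:
    """Read sample metadata: columns sample_id, phenotype, compartment, covariates."""
    path = Path(path)
    sep = _sniff_sep(path, dialect)
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    return StudyDesign(df)


def read_network(path: str | Path) -> CompartmentNetwork:
    """Read a compartment network from JSON ``{"nodes": [...], "edges": [[a,b],...]}``."""
    payload = json.loads(Path(path).read_text())
    if "nodes" not in payload or "edges" not in payload:
        raise DataValidationError('network JSON needs "nodes" and "edges" arrays')
    return CompartmentNetwork.from_lists(
        list(payload["nodes"]), [tuple(e) for e in payload["edges"]]
    )


def validate_design(
    table: AbundanceTable, design: StudyDesign, network: CompartmentNetwork
) -> dict:
    """Cross-reference the three inputs; return per-(phenotype, compartment) counts.

    Raises :class:`DataValidationError` if a design sample is absent from the
    table or a design compartment is not a network node.
    """
    missing = [s for s in design.frame.index if s not in table.data.index]
    if missing:
        raise DataValidationError(f"design samples absent from table: {missing}")
    bad_comp = sorted(set(design.compartments) - network.nodes)
    if bad_comp:
        raise DataValidationError(f"compartments not in network: {bad_comp}")
    counts = {
        (p, c): len(design.samples_in(p, c))
        for p in design.phenotypes
        for c in design.compartments
        if design.samples_in(p, c)
    }
    return {
        "schema": SCHEMA_VERSION,
        "n_samples": len(design.frame),
        "phenotypes": design.phenotypes,
        "compartments": design.compartments,
        "counts": counts,
        "unparsed_columns": list(table.unparsed),
        "unknown_classes": list(table.unknown_classes),
    }
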