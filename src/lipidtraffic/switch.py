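"""Switch analysis: spatial classification of lipid variables over the network.

Each variable's presence pattern (the set of compartments where it is
called present for one phenotype) is classified into:

* ``A``  - ubiquitous: present in every compartment of the network;
* ``U``  - isolated: present in exactly one compartment;
* ``B``  - present in exactly two metabolically adjacent compartments;
* ``N2`` - present in exactly two non-adjacent compartments;
* ``PARTIAL`` - present in more than two but not all compartments;
* ``ABSENT``  - empty pattern.

The six labels partition all possible patterns.  PARTIAL variables are
additionally enrolled in every edge-local B-set whose both endpoints they
occupy, so that per-edge "traffic" counts reflect the edge-local criterion
while the global type-count table remains a partition.

Comparing two phenotypes yields, per node (U-sets), per edge (B-sets) and
globally, the shared/unique membership split with a Jaccard-Tanimoto
coefficient and its p-value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .dataio import CompartmentNetwork
from .nomenclature import lipid_class
from .presence import PresenceMatrix
from . import stats as _stats

__all__ = [
    "LABELS",
    "classify_pattern",
    "spanned_edges",
    "TrafficResult",
    "TrafficComparison",
    "switch_analysis",
    "compare_phenotypes",
    "count_table",
]

LABELS = ("A", "U", "B", "N2", "PARTIAL", "ABSENT")


def classify_pattern(pattern: set[str] | frozenset[str], network: CompartmentNetwork) -> str:
    """Classify one presence pattern into A/U/B/N2/PARTIAL/ABSENT."""
    pattern = frozenset(pattern)
    unknown = pattern - network.nodes
    if unknown:
        raise ValueError(f"pattern contains unknown compartments: {sorted(unknown)}")
    if not pattern:
        return "ABSENT"
    if pattern == network.nodes:
        return "A"
    if len(pattern) == 1:
        return "U"
    if len(pattern) == 2:
        a, b = sorted(pattern)
        return "B" if network.is_edge(a, b) else "N2"
    return "PARTIAL"


def spanned_edges(
    pattern: set[str] | frozenset[str], network: CompartmentNetwork
) -> list[tuple[str, str]]:
    """Network edges whose both endpoints the pattern occupies."""
    return [e for e in network.edges if e[0] in pattern and e[1] in pattern]


@dataclass
class TrafficResult:
    """Per-phenotype switch-analysis output.

    ``patterns``/``labels`` map each variable (canonical name) to its
    compartment set and global type; ``u_sets``/``b_sets``/``n2_sets``
    localise U, edge-local B and N2 variables; ``a_set`` holds the
    ubiquitous variables.  ``b_sets`` enrolls every variable occupying both
    endpoints of an edge (including PARTIAL; A-type optionally).
    """

    phenotype: str
    patterns: dict[str, frozenset[str]]
    labels: dict[str, str]
    a_set: set[str]
    u_sets: dict[str, set[str]]
    b_sets: dict[tuple[str, str], set[str]]
    n2_sets: dict[tuple[str, str], set[str]]
    partial_edges: dict[str, list[tuple[str, str]]] = field(default_factory=dict)
    network: CompartmentNetwork | None = None

    def label_counts(self) -> dict[str, int]:
        out = {lab: 0 for lab in LABELS}
        for lab in self.labels.values():
            out[lab] += 1
        return out

    def to_frame(self) -> pd.DataFrame:
        """Per-variable traffic record: variable, class, label, compartments, edges."""
        rows = []
        for var in sorted(self.labels):
            rows.append(
                {
                    "phenotype": self.phenotype,
                    "variable": var,
                    "class": lipid_class(var),
                    "label": self.labels[var],
                    "compartments": ";".join(sorted(self.patterns[var])),
                    "edges": ";".join(
                        "--".join(e) for e in self.partial_edges.get(var, [])
                    ),
                }
            )
        return pd.DataFrame(rows)


def switch_analysis(
    presence: PresenceMatrix,
    network: CompartmentNetwork,
    include_a_in_edges: bool = False,
) -> dict[str, TrafficResult]:
    """Classify every variable for every phenotype; the switch-analysis core.

    ``include_a_in_edges`` enrolls ubiquitous (A-type) variables in every
    per-edge B-set; by default they are tabulated separately, so edge pies
    show only non-ubiquitous traffic.
    """
    extra = sorted(set(presence.compartments) - network.nodes)
    if extra:
        raise ValueError(f"presence compartments not in network: {extra}")
    results: dict[str, TrafficResult] = {}
    for phen in presence.phenotypes:
        calls = presence.present.xs(phen, level=0)
        patterns: dict[str, frozenset[str]] = {}
        labels: dict[str, str] = {}
        a_set: set[str] = set()
        u_sets: dict[str, set[str]] = {n: set() for n in sorted(network.nodes)}
        b_sets: dict[tuple[str, str], set[str]] = {e: set() for e in network.edges}
        n2_sets: dict[tuple[str, str], set[str]] = {
            p: set() for p in network.nonadjacent_pairs()
        }
        partial_edges: dict[str, list[tuple[str, str]]] = {}
        for var in presence.variables:
            pat = frozenset(calls.index[calls[var]])
            patterns[var] = pat
            lab = classify_pattern(pat, network)
            labels[var] = lab
            if lab == "A":
                a_set.add(var)
                if include_a_in_edges:
                    for e in network.edges:
                        b_sets[e].add(var)
            elif lab == "U":
                (node,) = pat
                u_sets[node].add(var)
            elif lab == "B":
                b_sets[tuple(sorted(pat))].add(var)
            elif lab == "N2":
                n2_sets[tuple(sorted(pat))].add(var)
            elif lab == "PARTIAL":
                span = spanned_edges(pat, network)
                partial_edges[var] = span
                for e in span:
                    b_sets[e].add(var)
        if all(lab == "ABSENT" for lab in labels.values()) and labels:
            warnings.warn(f"phenotype {phen!r} has zero present variables")
        results[phen] = TrafficResult(
            phen, patterns, labels, a_set, u_sets, b_sets, n2_sets,
            partial_edges, network,
        )
    return results


def count_table(
    result: TrafficResult, group_dg_with_tg: bool = False
) -> pd.DataFrame:
    """Inset-style count table: rows = lipid class, columns = type labels."""
    rows: dict[str, dict[str, int]] = {}
    for var, lab in result.labels.items():
        cls = lipid_class(var, group_dg_with_tg=group_dg_with_tg)
        rows.setdefault(cls, {l: 0 for l in LABELS})[lab] += 1
    return (
        pd.DataFrame.from_dict(rows, orient="index", columns=list(LABELS))
        .fillna(0)
        .astype(int)
        .sort_index()
    )


@dataclass
class ScopeComparison:
    """Membership split and similarity statistics for one node/edge/global scope."""

    scope: str
    shared: list[str]
    only_1: list[str]
    only_2: list[str]
    jaccard: float
    pvalue: float
    method: str

    def class_counts(self) -> pd.DataFrame:
        rows = []
        for status, names in (
            ("shared", self.shared), ("only_1", self.only_1), ("only_2", self.only_2)
        ):
            for v in names:
                rows.append({"class": lipid_class(v), "status": status})
        if not rows:
            return pd.DataFrame(columns=["shared", "only_1", "only_2"])
        df = pd.DataFrame(rows)
        return df.value_counts(["class", "status"]).unstack(fill_value=0)


@dataclass
class TrafficComparison:
    """Phenotype-vs-phenotype comparison across all scopes of the network."""

    phenotype_1: str
    phenotype_2: str
    scopes: dict[str, ScopeComparison]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for key in sorted(self.scopes):
            s = self.scopes[key]
            rows.append(
                {
                    "scope": key,
                    "n_shared": len(s.shared),
                    f"n_only_{self.phenotype_1}": len(s.only_1),
                    f"n_only_{self.phenotype_2}": len(s.only_2),
                    "jaccard": s.jaccard,
                    "pvalue": s.pvalue,
                    "method": s.method,
                }
            )
        return pd.DataFrame(rows)


def _compare_sets(
    scope: str,
    set1: set[str],
    set2: set[str],
    universe: int,
    method: str,
    n_null: int,
    seed: int | None,
) -> ScopeComparison:
    res = _stats.jtc_pvalue_sets(set1, set2, universe, method=method, n_null=n_null, seed=seed)
    return ScopeComparison(
        scope,
        sorted(set1 & set2),
        sorted(set1 - set2),
        sorted(set2 - set1),
        res.j,
        res.pvalue,
        res.method,
    )


def compare_phenotypes(
    traffic1: TrafficResult,
    traffic2: TrafficResult,
    method: str = "exact",
    n_null: int = 9999,
    seed: int | None = None,
) -> TrafficComparison:
    """Compare two phenotypes' traffic results scope by scope.

    Scopes: each node's U-set, each edge's B-set, each non-adjacent pair's
    N2-set, the A-sets, and the global per-(variable, compartment) presence
    lists.  Each scope carries the three-way membership split and a
    Jaccard-Tanimoto coefficient with p-value; the p-value universe is the
    shared variable universe (variables x compartments for the global scope).
    """
    if traffic1.network is None or traffic2.network is None:
        raise ValueError("traffic results must carry their network")
    if set(traffic1.network.nodes) != set(traffic2.network.nodes) or set(
        traffic1.network.edges
    ) != set(traffic2.network.edges):
        raise ValueError("mismatched networks between traffic results")
    if set(traffic1.labels) != set(traffic2.labels):
        raise ValueError("mismatched variable universes between traffic results")
    net = traffic1.network
    n_vars = len(traffic1.labels)
    scopes: dict[str, ScopeComparison] = {}
    for node in sorted(net.nodes):
        s1, s2 = traffic1.u_sets[node], traffic2.u_sets[node]
        if s1 or s2:
            scopes[f"node:{node}"] = _compare_sets(
                f"node:{node}", s1, s2, n_vars, method, n_null, seed
            )
    for e in net.edges:
        s1, s2 = traffic1.b_sets[e], traffic2.b_sets[e]
        if s1 or s2:
            key = f"edge:{e[0]}--{e[1]}"
            scopes[key] = _compare_sets(key, s1, s2, n_vars, method, n_null, seed)
    for p in net.nonadjacent_pairs():
        key = f"pair:{p[0]}--{p[1]}"
        s1, s2 = traffic1.n2_sets[p], traffic2.n2_sets[p]
        if s1 or s2:
            scopes[key] = _compare_sets(key, s1, s2, n_vars, method, n_null, seed)
    scopes["A"] = _compare_sets("A", traffic1.a_set, traffic2.a_set, n_vars, method, n_null, seed)
    cells1 = {
        (v, c) for v, pat in traffic1.patterns.items() for c in pat
    }
    cells2 = {
        (v, c) for v, pat in traffic2.patterns.items() for c in pat
    }
    n_cells = n_vars * len(net.nodes)
    res = _stats.jtc_pvalue_sets(
        cells1, cells2, n_cells, method=method, n_null=n_null, seed=seed
    )
    scopes["global"] = ScopeComparison(
        "global",
        sorted(f"{v}@{c}" for v, c in cells1 & cells2),
        sorted(f"{v}@{c}" for v, c in cells1 - cells2),
        sorted(f"{v}@{c}" for v, c in cells2 - cells1),
        res.j,
        res.pvalue,
        res.method,
    )
    return TrafficComparison(traffic1.phenotype, traffic2.phenotype, scopes)


def write_traffic_outputs(
    results: dict[str, TrafficResult],
    comparison: TrafficComparison | None,
    out_dir: str | Path,
    group_dg_with_tg: bool = False,
) -> list[Path]:
    """Write the tabular traffic outputs; returns the file list."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    frames = [r.to_frame() for _, r in sorted(results.items())]
    traffic = pd.concat(frames, ignore_index=True)
    p = out / "traffic.csv"
    traffic.to_csv(p, index=False)
    written.append(p)
    counts = []
    for phen, r in sorted(results.items()):
        ct = count_table(r, group_dg_with_tg=group_dg_with_tg)
        ct.insert(0, "phenotype", phen)
        counts.append(ct.rename_axis("class").reset_index())
    p = out / "type_counts.csv"
    pd.concat(counts, ignore_index=True).to_csv(p, index=False)
    written.append(p)
    if comparison is not None:
        p = out / "comparison.csv"
        comparison.to_frame().to_csv(p, index=False, float_format="%.6g")
        written.append(p)
    return written
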