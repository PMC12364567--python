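"""Synthetic datasets with the statistical structure the pipeline assumes.

Two generators make the whole pipeline exercisable without any external
download:

* a multi-compartment *traffic* dataset - lipid variables planted with a
  known spatial type (A/U/B/N2/PARTIAL) per phenotype, log-normal signal
  where present, and independent Bernoulli detection dropout; and
* a serum *cohort* - two sexes whose BMI distributions differ, lipid
  features with configurable sex effects and BMI slopes on the log scale,
  and log-normal residual noise.

Planted truth is always returned (and written) beside the data, so
recovery by the presence/switch/classifier stages can be scored against
what was planted.  All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from .dataio import (
    AbundanceTable,
    CompartmentNetwork,
    StudyDesign,
    default_network,
    write_abundance_table,
)
from .nomenclature import LipidName, format_lipid_name, parse_lipid_name

__all__ = [
    "TrafficSimSpec",
    "CohortSimSpec",
    "generate_traffic_dataset",
    "generate_cohort",
    "write_traffic_dataset",
    "write_cohort",
]

_NAME_CLASSES = ("PC", "TG", "PE", "SM", "PI", "LPC", "Cer", "PS", "PA", "CE")


def _lipid_names(n: int, rng: np.random.Generator) -> list[str]:
    """Deterministic list of n distinct plausible shorthand names."""
    names: list[str] = []
    seen: set[str] = set()
    i = 0
    while len(names) < n:
        cls = _NAME_CLASSES[i % len(_NAME_CLASSES)]
        c = int(rng.integers(28, 59))
        d = int(rng.integers(0, min(9, c)))
        name = format_lipid_name(LipidName(cls, c, d))
        i += 1
        if name not in seen:
            seen.add(name)
            names.append(name)
    return names


@dataclass
class TrafficSimSpec:
    """Conditions for a planted-type multi-compartment dataset.

    Defaults mirror a murine multi-tissue study: a nine-compartment
    serum-hub network, two phenotypes, eight animals per (phenotype,
    compartment) group, and a balanced panel of planted spatial types.
    ``relocate_fraction`` re-draws the localization of that share of the
    non-A variables for the second phenotype, creating genuine
    between-phenotype traffic differences.
    """

    network: CompartmentNetwork = field(default_factory=default_network)
    phenotypes: tuple[str, str] = ("female", "male")
    n_per_group: int = 8
    counts: dict[str, int] = field(
        default_factory=lambda: {"A": 10, "U": 10, "B": 10, "N2": 10}
    )
    relocate_fraction: float = 0.25
    meanlog: float = 10.0
    sdlog: float = 1.0
    dropout: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_per_group < 3:
            raise ValueError("n_per_group must be >= 3 to exercise the 66% rule")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        if len(self.phenotypes) != 2:
            raise ValueError("exactly two phenotypes required")
        bad = set(self.counts) - {"A", "U", "B", "N2", "PARTIAL"}
        if bad:
            raise ValueError(f"unknown planted labels: {sorted(bad)}")


def _draw_localization(
    label: str, network: CompartmentNetwork, rng: np.random.Generator
) -> frozenset[str]:
    nodes = sorted(network.nodes)
    if label == "A":
        return frozenset(nodes)
    if label == "U":
        return frozenset([nodes[rng.integers(len(nodes))]])
    if label == "B":
        edges = network.edges
        return frozenset(edges[rng.integers(len(edges))])
    if label == "N2":
        pairs = network.nonadjacent_pairs()
        if not pairs:
            raise ValueError("network has no non-adjacent pair; cannot plant N2")
        return frozenset(pairs[rng.integers(len(pairs))])
    if label == "PARTIAL":
        k = int(rng.integers(3, len(nodes)))
        return frozenset(rng.choice(nodes, size=k, replace=False))
    raise ValueError(label)


def generate_traffic_dataset(
    spec: TrafficSimSpec,
) -> tuple[AbundanceTable, StudyDesign, pd.DataFrame]:
    """Generate abundance + design + planted truth for a traffic study.

    Where a variable is planted present, each sample's signal is
    log-normal(meanlog, sdlog), independently zeroed with probability
    ``dropout``; everywhere else the signal is exactly 0.
    """
    rng = np.random.default_rng(spec.seed)
    net = spec.network
    nodes = sorted(net.nodes)
    phen1, phen2 = spec.phenotypes

    n_vars = sum(spec.counts.values())
    names = _lipid_names(n_vars, rng)
    planted: list[dict] = []
    idx = 0
    for label in ("A", "U", "B", "N2", "PARTIAL"):
        for _ in range(spec.counts.get(label, 0)):
            loc1 = _draw_localization(label, net, rng)
            planted.append({"variable": names[idx], "label1": label, "loc1": loc1})
            idx += 1
    # second phenotype: same localization, except a relocated share
    for rec in planted:
        if rec["label1"] != "A" and rng.random() < spec.relocate_fraction:
            label2 = ("U", "B", "N2")[rng.integers(3)]
            try:
                rec["loc2"] = _draw_localization(label2, net, rng)
                rec["label2"] = label2
            except ValueError:
                rec["loc2"] = rec["loc1"]
                rec["label2"] = rec["label1"]
        else:
            rec["loc2"] = rec["loc1"]
            rec["label2"] = rec["label1"]

    sample_rows = []
    for phen in (phen1, phen2):
        for comp in nodes:
            for i in range(spec.n_per_group):
                sid = f"{phen}_{comp.replace(' ', '-')}_{i + 1}"
                sample_rows.append((sid, phen, comp))
    design = StudyDesign(
        pd.DataFrame(
            {"phenotype": [r[1] for r in sample_rows],
             "compartment": [r[2] for r in sample_rows]},
            index=pd.Index([r[0] for r in sample_rows], name="sample_id"),
        )
    )

    values = np.zeros((len(sample_rows), n_vars))
    loc_key = {phen1: "loc1", phen2: "loc2"}
    for j, rec in enumerate(planted):
        for i, (sid, phen, comp) in enumerate(sample_rows):
            if comp in rec[loc_key[phen]]:
                if spec.dropout and rng.random() < spec.dropout:
                    continue
                values[i, j] = rng.lognormal(spec.meanlog, spec.sdlog)
    data = pd.DataFrame(
        values, index=[r[0] for r in sample_rows], columns=names
    )
    data.index.name = "sample_id"
    table = AbundanceTable(data, [parse_lipid_name(n) for n in names], [], [])

    truth = pd.DataFrame(
        [
            {
                "variable": rec["variable"],
                "phenotype": phen,
                "label": rec[f"label{k}"],
                "compartments": ";".join(sorted(rec[f"loc{k}"])),
            }
            for rec in planted
            for k, phen in ((1, phen1), (2, phen2))
        ]
    )
    return table, design, truth


@dataclass
class CohortSimSpec:
    """Conditions for a synthetic serum cohort with sex-dimorphic lipids.

    Defaults mirror a male-skewed biobank serum cohort (4176 males, 1105
    females) whose female BMI runs higher (27.91 +/- 6.87 vs 25.68 +/-
    4.69 kg/m2).  Log-abundance of feature f is

        baseline + sex_effect[f] * 1[female] + bmi_slope[f] * BMI + noise,

    noise ~ N(0, residual_sd); reported abundances are its exponential.
    """

    n_male: int = 4176
    n_female: int = 1105
    n_features: int = 20
    sex_effects: np.ndarray | None = None
    bmi_slopes: np.ndarray | None = None
    baseline_log: float = 10.0
    residual_sd: float = 0.5
    bmi_male: tuple[float, float] = (25.68, 4.69)
    bmi_female: tuple[float, float] = (27.91, 6.87)
    age_male: tuple[float, float] = (54.12, 8.70)
    age_female: tuple[float, float] = (54.99, 8.46)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.residual_sd <= 0:
            raise ValueError("residual_sd must be > 0")
        for attr in ("sex_effects", "bmi_slopes"):
            v = getattr(self, attr)
            if v is None:
                v = np.zeros(self.n_features)
            v = np.asarray(v, dtype=float)
            if v.shape != (self.n_features,):
                raise ValueError(f"{attr} must have length n_features")
            if not np.all(np.isfinite(v)):
                raise ValueError(f"{attr} must be finite")
            setattr(self, attr, v)


def generate_cohort(spec: CohortSimSpec) -> tuple[pd.DataFrame, dict]:
    """Generate a cohort table plus generative truth.

    Truth records the planted effects and, for features without a BMI
    path, the analytic single-feature Bayes AUC Phi(|d| / sqrt(2)) with
    d = sex_effect / residual_sd (NaN where a BMI slope makes the
    within-sex spread sex-dependent).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_male + spec.n_female
    sex = np.array(["male"] * spec.n_male + ["female"] * spec.n_female)
    female = (sex == "female").astype(float)
    bmi = np.where(
        female == 1.0,
        rng.normal(*spec.bmi_female, size=n),
        rng.normal(*spec.bmi_male, size=n),
    )
    bmi = np.clip(bmi, 12.0, None)
    age = np.where(
        female == 1.0,
        rng.normal(*spec.age_female, size=n),
        rng.normal(*spec.age_male, size=n),
    )
    names = _lipid_names(spec.n_features, rng)
    log_x = (
        spec.baseline_log
        + np.outer(female, spec.sex_effects)
        + np.outer(bmi, spec.bmi_slopes)
        + rng.normal(0.0, spec.residual_sd, size=(n, spec.n_features))
    )
    cohort = pd.DataFrame(
        np.exp(log_x),
        columns=names,
        index=pd.Index([f"S{i + 1:05d}" for i in range(n)], name="subject_id"),
    )
    cohort.insert(0, "sex", sex)
    cohort.insert(1, "age", np.round(age, 2))
    cohort.insert(2, "bmi", np.round(bmi, 2))
    d = spec.sex_effects / spec.residual_sd
    bayes = np.where(
        spec.bmi_slopes == 0.0, norm.cdf(np.abs(d) / np.sqrt(2.0)), np.nan
    )
    truth = {
        "features": names,
        "sex_effects": spec.sex_effects.tolist(),
        "bmi_slopes": spec.bmi_slopes.tolist(),
        "residual_sd": spec.residual_sd,
        "bayes_auc_single_feature": bayes.tolist(),
    }
    return cohort, truth


def write_traffic_dataset(spec: TrafficSimSpec, out_dir: str | Path) -> list[Path]:
    """Write abundance.csv, design.csv, network.json and truth.csv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table, design, truth = generate_traffic_dataset(spec)
    paths = [out / "abundance.csv", out / "design.csv", out / "network.json",
             out / "truth.csv"]
    write_abundance_table(table, paths[0])
    design.frame.to_csv(paths[1], index_label="sample_id")
    spec.network.to_json(paths[2])
    truth.to_csv(paths[3], index=False)
    return paths


def write_cohort(spec: CohortSimSpec, out_dir: str | Path) -> list[Path]:
    """Write subjects.csv and truth.json."""
    import json

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort, truth = generate_cohort(spec)
    p1 = out / "subjects.csv"
    p2 = out / "truth.json"
    cohort.to_csv(p1, float_format="%.10g")
    p2.write_text(json.dumps(truth, indent=1, sort_keys=True) + "\n")
    return [p1, p2]
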