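"""End-to-end pipeline: chain the traffic and cohort analyses into one run.

A run is configured by a flat key=value mapping, executed into a single
output directory, and finished with a manifest listing every output file
with its SHA-256 checksum.  All randomness flows from the configured seed,
and no timestamps enter the outputs, so a rerun with the same config
produces byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort_ml import (
    balanced_split,
    bmi_correct,
    fit_and_evaluate,
    variable_fold_changes,
)
from .dataio import (
    SCHEMA_VERSION,
    default_network,
    read_abundance_table,
    read_design,
    read_network,
    validate_design,
)
from .presence import call_presence
from .stats import cv_summary, enfc_table
from .switch import compare_phenotypes, switch_analysis, write_traffic_outputs
from .synthetic_data import (
    CohortSimSpec,
    TrafficSimSpec,
    generate_cohort,
    write_traffic_dataset,
)

__all__ = ["DEFAULT_CONFIG", "PipelineError", "run_pipeline", "read_config"]

#: Every recognised key with its default.  Path keys left empty trigger the
#: bundled synthetic generator for that stage.
DEFAULT_CONFIG: dict[str, object] = {
    "stages": "traffic,cohort",
    "seed": 0,
    "threshold": 0.66,
    # traffic inputs (empty -> simulate)
    "abundance": "",
    "design": "",
    "network": "",
    # traffic simulation conditions
    "sim_n_per_group": 8,
    "sim_dropout": 0.0,
    # cohort input (empty -> simulate)
    "subjects": "",
    "sim_n_male": 4176,
    "sim_n_female": 1105,
    "sim_n_features": 20,
    # cohort model
    "n_per_class": 700,
    "trees": 500,
    "bmi_correct": "residualize",
}


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and cause."""


def read_config(path: str | Path) -> dict[str, object]:
    """Read a flat ``key = value`` config file; unknown keys are errors."""
    config = dict(DEFAULT_CONFIG)
    for line_no, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise PipelineError(f"config line {line_no} is not key = value: {raw!r}")
        key, _, value = line.partition("=")
        key = key.strip()
        if key not in DEFAULT_CONFIG:
            raise PipelineError(f"unknown config key {key!r}")
        default = DEFAULT_CONFIG[key]
        value = value.strip()
        config[key] = type(default)(value) if not isinstance(default, str) else value
    return config


def _echo_config(config: dict, out: Path) -> None:
    lines = [f"# {SCHEMA_VERSION} v{__version__}"]
    lines += [f"{k} = {config[k]}" for k in sorted(config)]
    (out / "config.txt").write_text("\n".join(lines) + "\n")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _demo_cohort_spec(config: dict) -> CohortSimSpec:
    """Demonstration cohort: a handful of sex-dimorphic lipids plus one
    BMI-driven feature, against a background of uninformative features."""
    n_features = int(config["sim_n_features"])
    effects = np.zeros(n_features)
    planted = [0.3, -0.3, 0.2, -0.2, 0.15]
    effects[: min(len(planted), n_features)] = planted[:n_features]
    slopes = np.zeros(n_features)
    if n_features > 5:
        slopes[5] = 0.03
    return CohortSimSpec(
        n_male=int(config["sim_n_male"]),
        n_female=int(config["sim_n_female"]),
        n_features=n_features,
        sex_effects=effects,
        bmi_slopes=slopes,
        seed=int(config["seed"]),
    )


def _run_traffic(config: dict, out: Path, files: list[Path], log: list[str]) -> None:
    seed = int(config["seed"])
    threshold = float(config["threshold"])
    tdir = out / "traffic"
    tdir.mkdir(parents=True, exist_ok=True)
    if config["abundance"]:
        table = read_abundance_table(config["abundance"])
        design = read_design(config["design"]) if config["design"] else None
        if design is None:
            raise PipelineError("traffic: abundance given without design")
        network = (
            read_network(config["network"]) if config["network"] else default_network()
        )
        log.append("traffic: user-supplied inputs")
    else:
        spec = TrafficSimSpec(
            n_per_group=int(config["sim_n_per_group"]),
            dropout=float(config["sim_dropout"]),
            seed=seed,
        )
        sim_files = write_traffic_dataset(spec, tdir / "simulated")
        files.extend(sim_files)
        table = read_abundance_table(sim_files[0])
        design = read_design(sim_files[1])
        network = read_network(sim_files[2])
        log.append(
            f"traffic: simulated inputs (n_per_group={spec.n_per_group}, "
            f"dropout={spec.dropout}, seed={seed})"
        )
    validate_design(table, design, network)
    presence = call_presence(table, design, threshold=threshold)
    p = tdir / "presence.csv"
    presence.write_csv(p)
    files.append(p)
    results = switch_analysis(presence, network)
    phens = sorted(results)
    comparison = compare_phenotypes(results[phens[0]], results[phens[1]], seed=seed)
    files.extend(write_traffic_outputs(results, comparison, tdir))
    etab = enfc_table(table, design, phens[0], phens[1])
    p = tdir / "enfc.csv"
    etab.to_csv(p, index=False, float_format="%.6g")
    files.append(p)
    cv_rows = []
    for phen in phens:
        s = cv_summary(table, design, phen)
        cv_rows.append({"phenotype": phen, "mean_cv_pct": s["mean_cv"]})
    p = tdir / "cv.csv"
    pd.DataFrame(cv_rows).to_csv(p, index=False, float_format="%.6g")
    files.append(p)
    log.append(f"traffic: threshold={threshold}, phenotypes={phens}")


def _run_cohort(config: dict, out: Path, files: list[Path], log: list[str]) -> None:
    seed = int(config["seed"])
    cdir = out / "cohort"
    cdir.mkdir(parents=True, exist_ok=True)
    if config["subjects"]:
        cohort = pd.read_csv(config["subjects"], index_col=0)
        log.append("cohort: user-supplied subjects")
    else:
        spec = _demo_cohort_spec(config)
        cohort, truth = generate_cohort(spec)
        p = cdir / "simulated_subjects.csv"
        cohort.to_csv(p, float_format="%.10g")
        files.append(p)
        p = cdir / "simulated_truth.json"
        p.write_text(json.dumps(truth, indent=1, sort_keys=True) + "\n")
        files.append(p)
        log.append(
            f"cohort: simulated subjects ({spec.n_male} male / {spec.n_female} female)"
        )
    n_per_class = int(config["n_per_class"])
    partition = balanced_split(cohort, n_per_class, seed=seed)
    trees = int(config["trees"])
    models = {"uncorrected": cohort}
    mode = str(config["bmi_correct"])
    if mode != "none":
        models["bmi_corrected"] = bmi_correct(cohort, partition[0], method=mode)
    for tag, data in models.items():
        report = fit_and_evaluate(
            data, partition, n_estimators=trees, seed=seed
        )
        p = cdir / f"metrics_{tag}.json"
        p.write_text(json.dumps(report.to_dict(), indent=1, sort_keys=True) + "\n")
        files.append(p)
        p = cdir / f"importances_{tag}.csv"
        report.importances.to_csv(p, index=False, float_format="%.6g")
        files.append(p)
        p = cdir / f"roc_{tag}.csv"
        report.roc_points.to_csv(p, index=False, float_format="%.6g")
        files.append(p)
        fc = variable_fold_changes(data, reference="male")
        p = cdir / f"fold_changes_{tag}.csv"
        fc.to_csv(p, index=False, float_format="%.6g")
        files.append(p)
        log.append(
            f"cohort[{tag}]: accuracy={report.accuracy_pct:.1f}% "
            f"AUC={report.auc_pct:.1f}% (trees={trees}, n_per_class={n_per_class})"
        )


def run_pipeline(config: dict[str, object], out_dir: str | Path) -> Path:
    """Execute the configured stages into ``out_dir``; returns the manifest path.

    Stages run in dependency order; any stage error aborts the run with a
    :class:`PipelineError` naming the stage.
    """
    merged = dict(DEFAULT_CONFIG)
    unknown = set(config) - set(DEFAULT_CONFIG)
    if unknown:
        raise PipelineError(f"unknown config keys: {sorted(unknown)}")
    merged.update(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _echo_config(merged, out)
    files: list[Path] = [out / "config.txt"]
    log: list[str] = [f"version {__version__}", f"seed {merged['seed']}"]
    stages = [s.strip() for s in str(merged["stages"]).split(",") if s.strip()]
    runners = {"traffic": _run_traffic, "cohort": _run_cohort}
    for stage in stages:
        if stage not in runners:
            raise PipelineError(f"unknown stage {stage!r}")
        try:
            runners[stage](merged, out, files, log)
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001 - name the failing stage
            raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
    log_path = out / "log.txt"
    log_path.write_text("\n".join(log) + "\n")
    files.append(log_path)
    manifest = {
        "schema": SCHEMA_VERSION,
        "version": __version__,
        "seed": int(merged["seed"]),
        "threshold": float(merged["threshold"]),
        "files": {str(p.relative_to(out)): _sha256(p) for p in sorted(set(files))},
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return manifest_path
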