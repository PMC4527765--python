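"""End-to-end orchestration: table → CMD → archetypes → selection → report."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import archetypes, ingest, kinematics, selection
from .masks import DEFAULT_PIXEL_SIZE_UM

__all__ = ["RunConfig", "run_pipeline", "write_report", "REPORT_SCHEMA_VERSION"]

REPORT_SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """Declarative configuration of one full analysis run."""

    table_path: str | None = None  # CSV-triplet directory or spreadsheet
    dialect: str = "csv-triplet"
    simulate: dict | None = None  # TableSimSpec kwargs instead of a path
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    frame_interval_min: float = 5.0
    alpha: float = 0.001
    wilcoxon_family: int | None = None  # default 3 × n_features per process
    kw_family: int | None = None  # default n_features per process
    max_lag: int = 12
    cva_standardize: bool = True
    apply_validity_parsing: bool = True
    seed: int = 0
    out_dir: str | None = None

    def validate(self) -> None:
        if (self.table_path is None) == (self.simulate is None):
            raise ValueError("exactly one of table_path or simulate must be set")
        if self.table_path is not None and not Path(self.table_path).exists():
            raise ValueError(f"input path does not exist: {self.table_path}")
        if self.alpha <= 0 or self.pixel_size_um <= 0 or self.max_lag < 1:
            raise ValueError("thresholds must be positive")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls(**data)


def _load_table(config: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    if config.simulate is not None:
        from .simulate import TableSimSpec, make_plan

        kwargs = dict(config.simulate)
        plan_kwargs = kwargs.pop("plan", None)
        if plan_kwargs:
            kwargs["archetype_plan"] = make_plan(
                n_features=kwargs.get("n_features", 150), **plan_kwargs
            )
        kwargs.setdefault("seed", config.seed)
        from .simulate import generate_feature_table

        return generate_feature_table(TableSimSpec(**kwargs))
    table = ingest.read_dataset(config.table_path, config.dialect)
    return table, None


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage in dependency order and return the report dict.

    Identical config + seed give byte-identical reports. If ``out_dir`` is
    set, the report JSON, a text summary and the per-feature CSVs are
    written there.
    """
    config.validate()
    table, truth = _load_table(config)
    feats = ingest.feature_columns(table)

    if config.apply_validity_parsing and config.table_path is not None:
        table = ingest.parse_validity(table)

    valid = table["valid"].to_numpy(bool)
    fit = kinematics.fit_linear(
        table.loc[valid, "cell_speed"], table.loc[valid, "dynamic_cell_area"]
    )
    table = kinematics.compute_cmd(table, fit)
    delta_r, delta_slope = kinematics.delta_area_coupling(table, config.pixel_size_um)
    autocorr = kinematics.speed_autocorrelation(table[valid], max_lag=config.max_lag)

    arch = {
        proc: archetypes.archetype_classify(
            table, proc, feats, alpha=config.alpha, family=config.wilcoxon_family
        )
        for proc in ("cell_speed", "cmd")
    }
    sel = selection.select_features(
        table,
        feats,
        alpha=config.alpha,
        family=config.kw_family,
        standardize=config.cva_standardize,
    )

    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "config": {k: v for k, v in asdict(config).items() if k != "out_dir"},
        "n_observations": int(len(table)),
        "n_valid": int(valid.sum()),
        "n_features": len(feats),
        "cmd_fit": {
            "k": fit.k,
            "m": fit.m,
            "pearson_r": fit.pearson_r,
            "n_obs": fit.n_obs,
        },
        "delta_area": {"pearson_r": delta_r, "slope": delta_slope},
        "autocorrelation": {
            "pearson_r": autocorr.pearson_r,
            "p_value": autocorr.p_value,
            "n_cells": int(len(autocorr.per_cell)),
        },
        "archetypes": {
            proc: {
                "n_significant": arch[proc].n_significant,
                "venn_counts": archetypes.venn_counts(arch[proc]),
            }
            for proc in arch
        },
        "selection": {"class_counts": sel.class_counts},
    }

    if truth is not None:
        confusion: dict[str, dict[str, int]] = {}
        merged = sel.per_feature.join(truth.set_index("feature")["expected_class"])
        for expected, grp in merged.groupby("expected_class"):
            confusion[expected] = {
                k: int(v) for k, v in grp["class"].value_counts().items()
            }
        report["ground_truth_confusion"] = confusion

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_report(report, out / "report.json", out / "summary.txt")
        for proc in arch:
            arch[proc].per_feature.to_csv(out / f"archetypes_{proc}.csv")
        sel.per_feature.to_csv(out / "selection.csv")
        table.to_csv(out / "observations.csv", index=False)
    return report


def _summary_lines(report: dict) -> list[str]:
    fit = report["cmd_fit"]
    lines = [
        "membrane-dynamics analysis report",
        f"observations: {report['n_valid']} valid / {report['n_observations']} total; "
        f"features: {report['n_features']}",
        f"speed-DCA fit: k = {fit['k']:.4g} um^2/(um/min), m = {fit['m']:.4g} um^2, "
        f"r = {fit['pearson_r']:.3f} (n = {fit['n_obs']})",
        f"delta-area vs speed: r = {report['delta_area']['pearson_r']:.3f}",
        f"speed autocorrelation vs mean speed: r = "
        f"{report['autocorrelation']['pearson_r']:.3f} "
        f"({report['autocorrelation']['n_cells']} cells)",
    ]
    for proc, a in report["archetypes"].items():
        lines.append(f"{proc}: {a['n_significant']} features with >=1 significant pair")
        lines.append(f"  venn: {a['venn_counts']}")
    lines.append(f"selection classes: {report['selection']['class_counts']}")
    return lines


def write_report(report: dict, json_path: str | Path, summary_path: str | Path | None = None) -> None:
    """Serialize the report deterministically (sorted keys, fixed layout)."""
    Path(json_path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    if summary_path is not None:
        Path(summary_path).write_text("\n".join(_summary_lines(report)) + "\n")
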