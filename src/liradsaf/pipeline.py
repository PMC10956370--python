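"""End-to-end orchestration: simulate -> categorize -> screen -> evaluate.

A :class:`RunConfig` fixes every input (either a synthetic-cohort spec plus
seed or a cohort CSV path) and every analysis knob; :func:`run_pipeline`
then produces the full artifact set — cohort CSV, per-contrast screening
tables, performance/comparison JSON, a Markdown report and a log — all
stamped with a hash of the configuration so a run can be matched to its
settings. Identical configs give bit-identical artifacts.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import (
    COHORT_COLUMNS,
    FEATURE_COLUMNS,
    CohortTable,
    PrevalenceSpec,
    sample_cohort,
    published_prevalence_spec,
)
from .engine import AfPanel, apply_panel, categorize_cohort
from .performance import compare_methods, evaluate_adjustment, validate_model
from .screening import screen_panel, screening_report
from .features import AF_NAMES

_BOOL_COLUMNS = FEATURE_COLUMNS


@dataclass
class RunConfig:
    """One reproducible pipeline run.

    Exactly one input mode: a synthetic spec (+ simulation seed) or a cohort
    CSV path. Defaults follow the published analysis: entry threshold 0.10,
    7:3 stratified validation split.
    """

    spec: PrevalenceSpec | None = None
    seed: int = 0
    csv_path: str | None = None
    p_enter: float = 0.10
    bypass_univariable_filter: bool = False
    zero_cell: str = "haldane"
    train_fraction: float = 0.7
    split_seed: int = 0
    out_dir: str = "results"

    def __post_init__(self) -> None:
        if (self.spec is None) == (self.csv_path is None):
            raise ValueError("exactly one input mode: spec (simulate) or csv_path")

    def digest(self) -> str:
        payload = {
            "mode": "simulate" if self.spec is not None else "csv",
            "seed": self.seed,
            "csv_path": self.csv_path,
            "spec": None
            if self.spec is None
            else {
                "prevalence": {k: list(v) for k, v in self.spec.prevalence.items()},
                "diameter_bins": {
                    k: list(v) for k, v in self.spec.diameter_bins.items()
                },
                "group_sizes": dict(self.spec.group_sizes),
                "agent_hba": dict(self.spec.agent_hba),
            },
            "p_enter": self.p_enter,
            "bypass_univariable_filter": self.bypass_univariable_filter,
            "zero_cell": self.zero_cell,
            "train_fraction": self.train_fraction,
            "split_seed": self.split_seed,
        }
        raw = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(raw).hexdigest()[:12]

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        payload = json.loads(Path(path).read_text())
        spec = None
        if "spec" in payload and payload["spec"] is not None:
            s = payload["spec"]
            if s == "published":
                spec = published_prevalence_spec()
            else:
                spec = PrevalenceSpec(
                    prevalence={k: tuple(v) for k, v in s["prevalence"].items()},
                    diameter_bins={
                        k: tuple(v) for k, v in s["diameter_bins"].items()
                    },
                    group_sizes={k: int(v) for k, v in s["group_sizes"].items()},
                    agent_hba={k: float(v) for k, v in s["agent_hba"].items()},
                )
        return cls(
            spec=spec,
            seed=int(payload.get("seed", 0)),
            csv_path=payload.get("csv_path"),
            p_enter=float(payload.get("p_enter", 0.10)),
            bypass_univariable_filter=bool(
                payload.get("bypass_univariable_filter", False)
            ),
            zero_cell=payload.get("zero_cell", "haldane"),
            train_fraction=float(payload.get("train_fraction", 0.7)),
            split_seed=int(payload.get("split_seed", 0)),
            out_dir=payload.get("out_dir", "results"),
        )


# ---------------------------------------------------------------------------
# cohort CSV IO


def write_cohort_csv(cohort: CohortTable, path: str | Path) -> None:
    """Write a cohort (plus any derived columns) as CSV, booleans as 0/1."""
    df = cohort.data.copy()
    for col in _BOOL_COLUMNS:
        df[col] = df[col].astype(bool).astype(int)
    df.to_csv(path, index=False)


def read_cohort_csv(path: str | Path) -> CohortTable:
    """Read a cohort CSV, validating schema and cell values.

    Errors name the offending column or row: missing columns, non-0/1
    boolean cells, non-numeric diameters, duplicate lesion ids.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"lesion_id": str})
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort CSV missing column(s): {missing}")
    diam = pd.to_numeric(df["diameter_mm"], errors="coerce")
    if diam.isna().any():
        row = int(np.flatnonzero(diam.isna())[0])
        raise ValueError(
            f"non-numeric diameter_mm at data row {row}: "
            f"{df['diameter_mm'].iloc[row]!r}"
        )
    df["diameter_mm"] = diam
    for col in _BOOL_COLUMNS:
        vals = pd.to_numeric(df[col], errors="coerce")
        ok = vals.isin((0, 1))
        if not ok.all():
            row = int(np.flatnonzero(~ok)[0])
            raise ValueError(
                f"column {col!r} must be 0/1; bad value at data row {row}: "
                f"{df[col].iloc[row]!r}"
            )
        df[col] = vals.astype(bool)
    if df["lesion_id"].duplicated().any():
        dup = df.loc[df["lesion_id"].duplicated(), "lesion_id"].iloc[0]
        raise ValueError(f"duplicate lesion_id: {dup!r}")
    return CohortTable(data=df, provenance=f"csv:{path.name}")


# ---------------------------------------------------------------------------
# full run


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run the full analysis and write all artifacts; returns their paths."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    digest = config.digest()
    log_lines: list[str] = [f"config_hash: {digest}"]

    if config.spec is not None:
        cohort = sample_cohort(config.spec, seed=config.seed)
        log_lines.append(f"simulate: seed={config.seed} n={len(cohort)}")
    else:
        cohort = read_cohort_csv(config.csv_path)
        log_lines.append(f"load: {config.csv_path} n={len(cohort)}")

    cohort = categorize_cohort(cohort)
    lr_counts = cohort.data["lr_initial"].value_counts().sort_index().to_dict()
    log_lines.append(f"categorize: n={len(cohort)} lr_initial={lr_counts}")

    artifacts: dict[str, Path] = {}
    screens = {}
    for contrast, key in (("all", "af_hcc"), ("lr34", "af_lr")):
        result = screen_panel(
            cohort,
            contrast=contrast,
            p_enter=config.p_enter,
            bypass_univariable_filter=config.bypass_univariable_filter,
        )
        screens[key] = result
        report = screening_report(cohort, result)
        report.insert(0, "config_hash", digest)
        p = out / f"screening_{key}.csv"
        report.to_csv(p, index=False)
        artifacts[f"screening_{key}"] = p
        log_lines.append(
            f"screen[{contrast}]: in={len(cohort)} selected={result.stepwise.selected}"
        )

    perf = {}
    categorized = {}
    for key, result in screens.items():
        panel = result.panel
        adjusted = apply_panel(cohort, panel)
        categorized[key] = adjusted
        p = out / f"cohort_{key}.csv"
        write_cohort_csv(adjusted, p)
        artifacts[f"cohort_{key}"] = p
        perf[key] = evaluate_adjustment(cohort, panel)
        log_lines.append(
            f"evaluate[{key}]: lr34_n={perf[key].n_hcc + perf[key].n_nonhcc} "
            f"sens={perf[key].sensitivity:.4f} spec={perf[key].specificity:.4f}"
        )

    comparison = compare_methods(cohort, screens["af_hcc"].panel, screens["af_lr"].panel)
    log_lines.append(f"compare: kappa={comparison.kappa:.4f}")

    validations = {}
    for key, result in screens.items():
        if not result.stepwise.selected:
            continue
        df = cohort.data
        if result.contrast == "lr34":
            df = df[df["lr_initial"].isin((3, 4))]
        y = (df["group"] == "nonHCC").to_numpy(dtype=float)
        val = validate_model(
            df[result.stepwise.selected].astype(float),
            y,
            train_fraction=config.train_fraction,
            seed=config.split_seed,
        )
        validations[key] = val
        val.net_benefit.assign(config_hash=digest).to_csv(
            out / f"net_benefit_{key}.csv", index=False
        )
        val.calibration.assign(config_hash=digest).to_csv(
            out / f"calibration_{key}.csv", index=False
        )
        artifacts[f"net_benefit_{key}"] = out / f"net_benefit_{key}.csv"
        artifacts[f"calibration_{key}"] = out / f"calibration_{key}.csv"
        log_lines.append(
            f"validate[{key}]: train_auc={val.train_auc.auc:.4f} "
            f"val_auc={val.validation_auc.auc:.4f}"
        )

    results = {
        "config_hash": digest,
        "provenance": cohort.provenance,
        "panels": {
            key: {
                "label": screens[key].panel.label,
                "malignant_afs": sorted(screens[key].panel.malignant_afs),
                "benign_afs": sorted(screens[key].panel.benign_afs),
            }
            for key in screens
        },
        "performance": {key: perf[key].as_dict() for key in perf},
        "comparison": {
            "kappa": comparison.kappa,
            "mcnemar_p_sensitivity": comparison.mcnemar_sensitivity[1],
            "mcnemar_p_specificity": comparison.mcnemar_specificity[1],
            "p_sensitivity_bonferroni": comparison.p_sensitivity_bonferroni,
            "p_specificity_bonferroni": comparison.p_specificity_bonferroni,
        },
        "validation": {
            key: {
                "train_auc": vars(v.train_auc),
                "validation_auc": vars(v.validation_auc),
            }
            for key, v in validations.items()
        },
    }
    p = out / "results.json"
    p.write_text(json.dumps(results, indent=2))
    artifacts["results"] = p

    report_md = _render_report(results)
    p = out / "report.md"
    p.write_text(report_md)
    artifacts["report"] = p

    p = out / "run.log"
    p.write_text("\n".join(log_lines) + "\n")
    artifacts["log"] = p
    return artifacts


def _render_report(results: dict) -> str:
    lines = [
        "# LI-RADS ancillary-feature adjustment report",
        "",
        f"Config hash: `{results['config_hash']}`; input: {results['provenance']}",
        "",
    ]
    for key, panel in results["panels"].items():
        lines += [
            f"## Panel {panel['label']}",
            f"- malignant AFs: {', '.join(panel['malignant_afs']) or '(none)'}",
            f"- benign AFs: {', '.join(panel['benign_afs']) or '(none)'}",
        ]
        perf = results["performance"][key]
        lines += [
            f"- LR-3/4 lesions: {perf['n_hcc']} HCC / {perf['n_nonhcc']} non-HCC",
            f"- sensitivity {perf['sensitivity']:.4f}, "
            f"specificity {perf['specificity']:.4f}",
            "",
        ]
    comp = results["comparison"]
    lines += [
        "## Method comparison",
        f"- Cohen's kappa between outcome labelings: {comp['kappa']:.3f}",
        f"- McNemar p (sensitivity, Bonferroni x2): "
        f"{comp['p_sensitivity_bonferroni']:.4f}",
        f"- McNemar p (specificity, Bonferroni x2): "
        f"{comp['p_specificity_bonferroni']:.4f}",
        "",
    ]
    if results["validation"]:
        lines.append("## Internal validation (7:3 stratified)")
        for key, v in results["validation"].items():
            lines.append(
                f"- {key}: train AUC {v['train_auc']['auc']:.3f} "
                f"({v['train_auc']['ci_low']:.3f}-{v['train_auc']['ci_high']:.3f}), "
                f"validation AUC {v['validation_auc']['auc']:.3f} "
                f"({v['validation_auc']['ci_low']:.3f}-"
                f"{v['validation_auc']['ci_high']:.3f})"
            )
        lines.append("")
    return "\n".join(lines)
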