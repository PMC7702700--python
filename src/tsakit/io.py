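"""Trial CSV input, run configuration, and analysis reports.

Trial tables are plain CSV with the header
``label,order,events_exp,total_exp,events_ctl,total_ctl``; validation
failures are reported with the offending row number.  Reports render a
completed analysis as human-readable text, schema-stable JSON (full
precision, suitable for round-tripping), or a plot-ready TSV of the
per-look boundary table.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd
import yaml

from .information import DesignSpec
from .meta import TrialRecord
from .planning import PlanResult
from .sequential import SequentialResult

__all__ = ["RunConfig", "read_trials", "load_config", "report", "boundary_table"]

CSV_COLUMNS = ["label", "order", "events_exp", "total_exp", "events_ctl", "total_ctl"]
FORMATS = ("text", "json", "tsv")


@dataclass(frozen=True)
class RunConfig:
    """A full analysis configuration (design + inputs + mode flags)."""

    design: DesignSpec
    trials_path: Optional[Path] = None
    accrued_override: Optional[int] = None
    conservative: bool = False
    exclude: Optional[str] = None
    freeze_d2: bool = False
    measure: str = "odds_ratio"
    model: str = "random_DL"


def read_trials(path: Union[str, Path]) -> list[TrialRecord]:
    """Read and validate a chronological trial table from CSV."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: nothing to analyse (empty file)") from None
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if df.empty:
        raise ValueError(f"{path}: nothing to analyse (no trial rows)")
    records: list[TrialRecord] = []
    for i, row in df.iterrows():
        rowno = i + 2  # header is line 1
        if row[CSV_COLUMNS].isna().any():
            raise ValueError(f"{path} row {rowno}: missing cell")
        try:
            records.append(
                TrialRecord(
                    label=str(row["label"]),
                    order=int(row["order"]),
                    events_exp=int(row["events_exp"]),
                    total_exp=int(row["total_exp"]),
                    events_ctl=int(row["events_ctl"]),
                    total_ctl=int(row["total_ctl"]),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path} row {rowno}: {exc}") from None
    orders = [r.order for r in records]
    if len(set(orders)) != len(orders):
        dup = sorted({o for o in orders if orders.count(o) > 1})
        raise ValueError(f"{path}: duplicate order values {dup}")
    return sorted(records, key=lambda r: r.order)


def load_config(path: Union[str, Path]) -> RunConfig:
    """Load a YAML or JSON run configuration.

    Recognised keys: ``alpha, power, p_ctl, p_exp, d2_override`` (design),
    ``trials, accrued_override, conservative, exclude, freeze_d2, measure,
    model``.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    design = DesignSpec(
        p_ctl=float(raw["p_ctl"]),
        p_exp=float(raw["p_exp"]),
        alpha=float(raw.get("alpha", 0.05)),
        power=float(raw.get("power", 0.90)),
        d2_override=(float(raw["d2_override"]) if raw.get("d2_override") is not None else None),
    )
    return RunConfig(
        design=design,
        trials_path=Path(raw["trials"]) if raw.get("trials") else None,
        accrued_override=(int(raw["accrued_override"]) if raw.get("accrued_override") is not None else None),
        conservative=bool(raw.get("conservative", False)),
        exclude=raw.get("exclude"),
        freeze_d2=bool(raw.get("freeze_d2", False)),
        measure=raw.get("measure", "odds_ratio"),
        model=raw.get("model", "random_DL"),
    )


def boundary_table(result: SequentialResult) -> pd.DataFrame:
    """Per-look boundary table with the plot-export columns."""
    rows = []
    for lk in result.looks:
        rows.append(
            {
                "t": lk.t,
                "z": lk.z,
                "efficacy_z": lk.efficacy_z,
                "futility_z": lk.futility_z if lk.futility_z is not None else float("nan"),
                "alpha_spent": lk.alpha_spent,
                "beta_spent": lk.beta_spent if lk.beta_spent is not None else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def _result_dict(result: SequentialResult, plan: Optional[PlanResult]) -> dict:
    out = {
        "measure": result.measure,
        "model": result.final_pooled.model,
        "design": {
            "alpha": result.design.alpha,
            "power": result.design.power,
            "p_ctl": result.design.p_ctl,
            "p_exp": result.design.p_exp,
            "d2_override": result.design.d2_override,
        },
        "pooled": {
            "effect": result.final_pooled.effect,
            "theta": result.final_pooled.theta,
            "se": result.final_pooled.se,
            "z": result.final_pooled.z,
            "tau2": result.final_pooled.tau2,
            "I2": result.final_pooled.I2,
            "D2": result.final_pooled.D2,
            "k": result.final_pooled.k,
        },
        "naive_ci": list(result.naive_ci),
        "adjusted_ci": list(result.adjusted_ci),
        "ris": result.ris,
        "accrued": result.final_look.accrued,
        "verdict": result.verdict,
        "looks": [
            {
                "index": lk.index,
                "trial": lk.trial_label,
                "t": lk.t,
                "z": lk.z,
                "efficacy_z": lk.efficacy_z,
                "futility_z": lk.futility_z,
                "alpha_spent": lk.alpha_spent,
                "beta_spent": lk.beta_spent,
                "ris": lk.ris,
                "accrued": lk.accrued,
                "classification": lk.classification,
            }
            for lk in result.looks
        ],
    }
    if plan is not None:
        out["plan"] = {
            "ris": plan.ris,
            "accrued": plan.accrued,
            "additional_total": plan.additional_total,
            "per_arm": plan.per_arm,
            "mode": plan.mode,
            "d2": plan.d2,
            "note": plan.note,
        }
    return out


def _text_report(result: SequentialResult, plan: Optional[PlanResult]) -> str:
    p = result.final_pooled
    eff_name = {"odds_ratio": "OR", "risk_ratio": "RR", "risk_difference": "RD"}[result.measure]
    lines = [
        "Trial sequential analysis",
        "=" * 25,
        f"Pooled {eff_name} ({p.model}, k={p.k}): {p.effect:.3f}",
        f"  naive 95% CI:    {result.naive_ci[0]:.3f} to {result.naive_ci[1]:.3f}",
        f"  adjusted CI:     {result.adjusted_ci[0]:.3f} to {result.adjusted_ci[1]:.3f}",
        f"  tau2={p.tau2:.4f}  I2={100 * p.I2:.1f}%  D2={100 * p.D2:.1f}%",
        "",
        "Look  trial            t      z     eff_z  fut_z  classification",
    ]
    for lk in result.looks:
        fz = f"{lk.futility_z:6.3f}" if lk.futility_z is not None else "     -"
        lines.append(
            f"{lk.index:>4}  {lk.trial_label:<14} {lk.t:6.3f} {lk.z:6.3f} "
            f"{lk.efficacy_z:7.3f} {fz}  {lk.classification}"
        )
    lines += [
        "",
        f"Verdict: {result.verdict}",
        f"Required information size: {result.ris} participants",
        f"Accrued: {result.final_look.accrued} participants "
        f"(fraction {result.final_look.t:.3f})",
    ]
    if result.final_look.t >= 1.0:
        lines.append("Information size reached: adjusted CI equals the naive CI.")
    if plan is not None:
        lines += [
            f"Additional participants needed: {plan.additional_total} "
            f"({plan.per_arm} per arm, 1:1)" + (f" [{plan.note}]" if plan.note else ""),
        ]
    return "\n".join(lines) + "\n"


def report(
    result: SequentialResult,
    plan: Optional[PlanResult] = None,
    fmt: str = "text",
) -> str:
    """Render a completed analysis as text, JSON, or boundary TSV."""
    if fmt not in FORMATS:
        raise ValueError(f"unknown format {fmt!r} (expected one of {FORMATS})")
    if fmt == "json":
        return json.dumps(_result_dict(result, plan), indent=2)
    if fmt == "tsv":
        return boundary_table(result).to_csv(sep="\t", index=False)
    return _text_report(result, plan)
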