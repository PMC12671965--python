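"""Result tables and figure-ready files.

Display precision follows the conventions of epidemiologic effect
tables: absolute risks and risk differences to one decimal place (in
percent / percentage points), ratio measures to two. Formatting uses
Python's round-half-even, applied to the unrounded estimates.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .inference import BootstrapResult
from .outcome import EffectEstimates, RiskCurve

__all__ = ["fmt1", "fmt2", "fmt_count_pct", "render_effects_table",
           "render_risk_curves", "render_ledger", "write_reports"]


def fmt1(x: float) -> str:
    return f"{float(x):.1f}"


def fmt2(x: float) -> str:
    return f"{float(x):.2f}"


def fmt_count_pct(count: int, total: int) -> str:
    """Baseline-table cell: "2437 (30.3)"."""
    return f"{count} ({100.0 * count / total:.1f})"


def _cell(value, ci, fmt) -> str:
    if value is None:
        return ""
    if ci is None:
        return fmt(value)
    sep = " to " if float(ci[0]) < 0 else "-"   # "[-1.1 to 2.6]" style
    return f"{fmt(value)} [{fmt(ci[0])}{sep}{fmt(ci[1])}]"


def render_effects_table(results: list[tuple[str, EffectEstimates]]) -> pd.DataFrame:
    """Formatted effect-measure table: one analysis per row, columns
    risk per arm (%), RD (percentage points), RR and average HR, each
    with its bootstrap CI when available."""
    rows = []
    for label, est in results:
        if isinstance(est, BootstrapResult):
            est = est.estimates
        ci = est.ci or {}
        rows.append({
            "analysis": label,
            "risk_ai_pct": _cell(100 * est.risk_ai_5y,
                                 tuple(100 * v for v in ci["risk_ai_5y"])
                                 if "risk_ai_5y" in ci else None, fmt1),
            "risk_tam_pct": _cell(100 * est.risk_tam_5y,
                                  tuple(100 * v for v in ci["risk_tam_5y"])
                                  if "risk_tam_5y" in ci else None, fmt1),
            "rd_pct_points": _cell(est.rd, ci.get("rd"), fmt1),
            "rr": _cell(est.rr, ci.get("rr"), fmt2),
            "avg_hr": _cell(est.avg_hr, ci.get("avg_hr"), fmt2),
        })
    columns = ["analysis", "risk_ai_pct", "risk_tam_pct",
               "rd_pct_points", "rr", "avg_hr"]
    return pd.DataFrame(rows, columns=columns)


def render_effects_numeric(results: list[tuple[str, EffectEstimates]]) -> pd.DataFrame:
    rows = []
    for label, est in results:
        if isinstance(est, BootstrapResult):
            est = est.estimates
        row = {"analysis": label, **est.as_dict()}
        for measure, (lo, hi) in (est.ci or {}).items():
            row[f"{measure}_lo"], row[f"{measure}_hi"] = lo, hi
        rows.append(row)
    return pd.DataFrame(rows)


def render_risk_curves(curves: dict[str, RiskCurve]) -> pd.DataFrame:
    """Long-format cumulative incidence file (strategy, month, hazard,
    cumulative risk) ready for plotting."""
    frames = []
    for name, curve in curves.items():
        frames.append(pd.DataFrame({
            "strategy": name, "month": curve.months,
            "hazard": curve.hazard, "cumulative_risk": curve.risk,
        }))
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["strategy", "month", "hazard", "cumulative_risk"])


def render_ledger(ledger: pd.DataFrame) -> pd.DataFrame:
    return ledger.copy()


def write_reports(out_dir, *, effects: list[tuple[str, EffectEstimates]],
                  curves: dict[str, RiskCurve] | None = None,
                  ledger: pd.DataFrame | None = None) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    render_effects_table(effects).to_csv(out / "effects_table.csv", index=False,
                                         lineterminator="\n")
    render_effects_numeric(effects).to_csv(out / "effects_numeric.csv", index=False,
                                           lineterminator="\n")
    if curves:
        render_risk_curves(curves).to_csv(out / "risk_curves.csv", index=False,
                                          lineterminator="\n")
    if ledger is not None:
        render_ledger(ledger).to_csv(out / "exclusion_ledger.csv", index=False,
                                     lineterminator="\n")
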