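"""Report rendering shared by the CLI.

The machine-readable JSON dict is the single source of numbers: the markdown
tables are rendered *from* the already-rounded JSON values, so there is no
divergent formatting path and every number in the markdown equals the
corresponding JSON field.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

from ._round import round_half_up
from .change import PairedChangeResult
from .staging import StagingResults
from .subgroups import SubgroupResult

_STEP_COLS = ("cutoff", "tp", "fp", "tn", "fn", "sensitivity", "specificity", "accuracy", "auc", "youden")


def staging_report_dict(
    results: StagingResults,
    subgroups: dict[str, SubgroupResult] | None = None,
) -> dict:
    out = {"overall": results.to_dict()}
    if subgroups:
        out["subgroups"] = {
            label: (sr.results.to_dict() if sr.results else {"n": sr.n, "warnings": ["empty stratum"]})
            for label, sr in subgroups.items()
        }
    return out


def _steps_markdown(d: dict) -> list[str]:
    lines = [
        "| Comparison | " + " | ".join(c.upper() if len(c) <= 2 else c.capitalize() for c in _STEP_COLS) + " | Status |",
        "|" + "---|" * (len(_STEP_COLS) + 2),
    ]
    for s in d["steps"]:
        if "cutoff" not in s:
            lines.append(f"| {s['comparison']} | " + " | ".join("—" for _ in _STEP_COLS) + f" | {s['reason']} |")
            continue
        status = "retained" if s["retained"] else s["reason"]
        if s["forced"]:
            status += " [forced]"
        if s["exploratory"]:
            status += " [exploratory]"
        cells = " | ".join(str(s[c]) for c in _STEP_COLS)
        lines.append(f"| {s['comparison']} | {cells} | {status} |")
    return lines


def staging_report_markdown(report: dict) -> str:
    """Markdown rendering of ``staging_report_dict`` output."""
    lines: list[str] = ["# Functional staging report", ""]
    for name, d in [("Overall", report["overall"])] + [
        (label, sub) for label, sub in report.get("subgroups", {}).items()
    ]:
        lines += [f"## {name} (n = {d.get('n', 0)})", ""]
        if "steps" not in d:
            lines += ["No analysable data in this stratum.", ""]
            continue
        lines += _steps_markdown(d)
        lines += ["", "Stage distribution:", ""]
        lines += ["| Stage | Count | % |", "|---|---|---|"]
        for row in d["stage_distribution"]:
            lines.append(f"| {row['stage']} | {row['count']} | {row['pct']} |")
        cut = ", ".join(map(str, d["cutoffs"])) or "none"
        lines += ["", f"Retained cutoffs: {cut}", ""]
        for w in d.get("warnings", []):
            lines.append(f"> warning: {w}")
        lines.append("")
    return "\n".join(lines)


def paired_change_dict(result: PairedChangeResult) -> dict:
    d = asdict(result)
    for k in ("mean_admission", "mean_discharge", "mean_difference", "sd_difference"):
        d[k] = round_half_up(d[k], 1)
    for k in ("t_statistic", "cohens_d", "d_ci_low", "d_ci_high"):
        d[k] = round_half_up(d[k], 3)
    d["p_value_display"] = "< 0.001" if result.p_value < 0.001 else f"{round_half_up(result.p_value, 3)}"
    return d


def describe_report_markdown(summary: dict, change: dict | None) -> str:
    lines = ["# Cohort description", "", f"n = {summary['n']}", ""]
    for block in ("sex", "age_band", "diagnosis", "td_level"):
        lines += [f"## {block}", "", "| Level | Count | % |", "|---|---|---|"]
        for lv, row in summary[block].items():
            lines.append(f"| {lv} | {row['count']} | {row['pct']} |")
        lines.append("")
    adm = summary["clinfit_admission"]
    dis = summary["clinfit_discharge"]
    lines += [
        "## Scores",
        "",
        f"ClinFIT on admission: mean {adm['mean']} (SD {adm['sd']}), n = {adm['n']}",
    ]
    if dis["n"]:
        lines.append(
            f"ClinFIT on discharge: mean {dis['mean']} (SD {dis['sd']}), "
            f"n = {dis['n']} ({dis['n_missing']} missing)"
        )
    else:
        lines.append("ClinFIT on discharge: no discharge scores recorded")
    lines += ["", "## Paired change", ""]
    if change is None:
        lines.append("not computable (fewer than 2 complete admission/discharge pairs)")
    else:
        lines += [
            f"mean improvement {change['mean_difference']} (SD {change['sd_difference']}) "
            f"over {change['n_pairs']} pairs",
            f"paired t = {change['t_statistic']}, p {change['p_value_display']}",
            f"Cohen's d = {change['cohens_d']} "
            f"(95% CI {change['d_ci_low']}–{change['d_ci_high']}), {change['effect_band']} effect",
        ]
    return "\n".join(lines) + "\n"


def write_report(report: dict, markdown: str, out_dir: str | Path, stem: str) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / f"{stem}.json").write_text(json.dumps(report, indent=2) + "\n", encoding="utf-8")
    (out / f"{stem}.md").write_text(markdown, encoding="utf-8")
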