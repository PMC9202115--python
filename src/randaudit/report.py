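"""Assembly of the full audit report.

Runs every audit stage over one participant table and collects the results
into a single structure with deterministic JSON and Markdown renderings.
Sections that cannot be computed (no cross-overs recorded, no risk-of-bias
answers supplied) are marked skipped with a reason rather than omitted.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import pandas as pd

from . import allocation_audit as aa
from . import imbalance_scan as sc
from .adjusted_effects import (
    DEFAULT_EARLY_COVARIATES,
    DEFAULT_LATE_COVARIATES,
    run_adjusted_analysis,
)
from .rob_domain1 import RobDomain1Assessment, render_rob_table
from .trial_model import BASELINE_COVARIATES, CT_COVARIATES, TimeStratum, _as_frame

__all__ = ["AuditReport", "build_audit_report"]


@dataclass
class AuditReport:
    metadata: dict[str, Any] = field(default_factory=dict)
    sections: dict[str, Any] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps({"metadata": self.metadata, "sections": self.sections}, indent=2, sort_keys=True)

    def to_markdown(self) -> str:
        lines = ["# Randomization-integrity audit", ""]
        for key, value in self.metadata.items():
            lines.append(f"- **{key}**: {value}")
        lines.append("")
        for name in ("allocation", "restriction", "crossover", "imbalance", "adjusted_effects", "rob_domain1"):
            section = self.sections.get(name, {"skipped": "section not computed"})
            lines.append(f"## {name.replace('_', ' ').title()}")
            lines.append("")
            if "skipped" in section:
                lines.append(f"_Skipped: {section['skipped']}_")
            else:
                lines.extend(_render_section(name, section))
            lines.append("")
        return "\n".join(lines)


def _render_section(name: str, section: Mapping[str, Any]) -> list[str]:
    if name == "allocation":
        lines = [
            "| Center | Window | Treatment | Control | Δ | Favored | Exceeds block bound |",
            "|---|---|---|---|---|---|---|",
        ]
        for row in section["strata"]:
            s = row["stratum"]
            lines.append(
                f"| {s['clinical_center']} | {s['time_stratum']} | {row['n_treatment']} | "
                f"{row['n_control']} | {row['delta']} | {row['favored_arm'] or '—'} | "
                f"{row['exceeds_block_bound'] if row['exceeds_block_bound'] is not None else '—'} |"
            )
        lines.append("")
        lines.append(
            f"{section['n_deviating']} of {len(section['strata'])} strata deviate from 1:1; "
            f"time-margin Δ: " + ", ".join(
                f"{m['stratum']['time_stratum']} {m['delta']}" for m in section["time_margins"]
            )
        )
        return lines
    if name == "restriction":
        if not section["violations"]:
            return [f"No center reached a time-strata difference of {section['threshold']}."]
        lines = ["| Center | Early | Late | Diff |", "|---|---|---|---|"]
        for v in section["violations"]:
            lines.append(f"| {v['clinical_center']} | {v['n_early']} | {v['n_late']} | {v['diff']} |")
        return lines
    if name == "crossover":
        return [
            f"{section['n_in_direction']} of {section['n_crossovers']} cross-overs in the "
            f"{section['direction']} direction; exact binomial point probability "
            f"{section['point_probability']:.2e}, one-sided tail {section['tail_probability']:.2e} "
            f"(null per-cross-over probability {section['null_prob']})."
        ]
    if name == "imbalance":
        lines = []
        for scan_name in ("ct_by_unique_stratum", "early_margin", "late_margin"):
            scan = section[scan_name]
            lines.append(f"**{scan_name}** — {scan['n_tests']} tests, {len(scan['flagged'])} flagged:")
            for r in scan["flagged"]:
                lines.append(
                    f"- {r['covariate']} ({_stratum_label(r['stratum'])}): p = {r['p_value']:.3f}, "
                    f"favors {r['favors'] or 'neither'}"
                )
            lines.append("")
        return lines
    if name == "adjusted_effects":
        lines = [
            "| Window | Endpoint | OR (95% CI), p | aOR (95% CI), p | Classification |",
            "|---|---|---|---|---|",
        ]
        adjusted = {(r["stratum"], r["endpoint"]): r for r in section["adjusted"]}
        summary = {(r["stratum"], r["endpoint"]): r for r in section["summary"]}
        for r in section["unadjusted"]:
            key = (r["stratum"], r["endpoint"])
            a = adjusted[key]
            lines.append(
                f"| {r['stratum']} | {r['endpoint']} | "
                f"{r['odds_ratio']:.1f} ({r['ci_low']:.1f}–{r['ci_high']:.1f}), p={r['p_value']:.3f} | "
                f"{a['odds_ratio']:.1f} ({a['ci_low']:.1f}–{a['ci_high']:.1f}), p={a['p_value']:.3f} | "
                f"{summary[key]['classification']} |"
            )
        return lines
    if name == "rob_domain1":
        return [section["markdown"]]
    return [json.dumps(dict(section), sort_keys=True)]


def _stratum_label(stratum: Mapping[str, Any]) -> str:
    if "clinical_center" in stratum:
        return f"{stratum['clinical_center']}/{stratum['time_stratum']}"
    return stratum["time_stratum"]


def build_audit_report(
    records: pd.DataFrame,
    *,
    alpha: float = 0.05,
    restriction_threshold: int = 3,
    max_block_size: int | None = None,
    early_covariates: Sequence[str] = DEFAULT_EARLY_COVARIATES,
    late_covariates: Sequence[str] = DEFAULT_LATE_COVARIATES,
    rob: RobDomain1Assessment | None = None,
    metadata: Mapping[str, Any] | None = None,
) -> AuditReport:
    """Run the complete audit pipeline over one participant table."""
    frame = _as_frame(records)
    report = AuditReport(metadata=dict(metadata or {}))
    report.metadata.setdefault("n_records", len(frame))
    report.metadata.setdefault("alpha", alpha)
    report.metadata.setdefault("table_hash", hashlib.sha256(frame.to_csv(index=False).encode()).hexdigest()[:16])

    # -- allocation balance
    table = aa.allocation_counts(frame)
    flagged = aa.flag_allocation_deviations(table, max_block_size)
    report.sections["allocation"] = {
        "strata": [row.to_json() for row in table.strata],
        "time_margins": [table.time_margins[ts].to_json() for ts in sorted(table.time_margins, key=lambda t: t.value)],
        "n_deviating": len(flagged),
        "max_block_size": max_block_size,
    }

    # -- restriction rule
    violations = aa.check_time_strata_restriction(frame, restriction_threshold, mode="final")
    report.sections["restriction"] = {
        "threshold": restriction_threshold,
        "violations": [
            {
                "clinical_center": v.clinical_center,
                "n_early": v.n_early,
                "n_late": v.n_late,
                "diff": v.diff,
            }
            for v in violations
        ],
    }

    # -- cross-over direction
    n_cross, to_control = aa.crossover_counts(frame)
    if n_cross == 0:
        report.sections["crossover"] = {"skipped": "no cross-overs recorded in the table"}
    else:
        k = max(to_control, n_cross - to_control)
        direction = "treatment->control" if to_control * 2 >= n_cross else "control->treatment"
        test = aa.crossover_direction_test(n_cross, k)
        report.sections["crossover"] = {
            "n_crossovers": n_cross,
            "n_in_direction": k,
            "direction": direction,
            "null_prob": test.null_prob,
            "point_probability": test.point_probability,
            "tail_probability": test.tail_probability,
        }

    # -- imbalance scans
    def _scan_json(scan: sc.ScanReport) -> dict[str, Any]:
        return {
            "n_tests": scan.n_tests,
            "results": [r.to_json() for r in scan.results],
            "flagged": [r.to_json() for r in scan.flagged],
            "diagnostics": scan.diagnostics,
        }

    report.sections["imbalance"] = {
        "ct_by_unique_stratum": _scan_json(sc.scan_ct_by_unique_stratum(frame, CT_COVARIATES, alpha)),
        "early_margin": _scan_json(sc.scan_covariates(frame, TimeStratum.EARLY, BASELINE_COVARIATES, alpha)),
        "late_margin": _scan_json(sc.scan_covariates(frame, TimeStratum.LATE, BASELINE_COVARIATES, alpha)),
    }

    # -- adjusted treatment effects
    try:
        analysis = run_adjusted_analysis(frame, early_covariates, late_covariates, alpha)
        report.sections["adjusted_effects"] = {
            "unadjusted": [e.to_json() for e in analysis.unadjusted],
            "adjusted": [e.to_json() for e in analysis.adjusted],
            "early_sensitivity": [e.to_json() for e in analysis.early_sensitivity],
            "summary": [
                {
                    "endpoint": r.endpoint.value,
                    "stratum": r.stratum.value,
                    "reported_significant": r.reported_significant,
                    "revised_significant": r.revised_significant,
                    "classification": r.classification,
                }
                for r in analysis.summary
            ],
            "n_revised_nonsignificant": analysis.n_revised_nonsignificant(),
        }
    except (ValueError, RuntimeError) as exc:
        report.sections["adjusted_effects"] = {"skipped": f"adjusted analysis failed: {exc}"}

    # -- risk-of-bias judgement
    if rob is None:
        report.sections["rob_domain1"] = {"skipped": "no signaling-question answers supplied"}
    else:
        report.sections["rob_domain1"] = {
            "judgement": rob.judgement.value,
            "table": json.loads(render_rob_table(rob, "json")),
            "markdown": render_rob_table(rob, "markdown"),
        }
    return report
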