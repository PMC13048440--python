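"""Rendering of result tables and the comparison (forest-plot) summary.

Numeric formatting follows the study's printed precision: percentages to one
decimal place, coefficients to two decimals, Likert means to three decimals.
Rates are kept at full precision internally and rounded only here.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from qualagree.agreement import BootstrapConfig, BootstrapResult, bootstrap_ci, bootstrap_mean_ci
from qualagree.audit import ErrorRateSummary
from qualagree.coding_data import CodingMatrix
from qualagree.comparison import ComparisonResult

METRIC_COLUMNS = [
    "Agreement %",
    "Cohen's kappa",
    "Gwet's AC1",
    "Jaccard",
    "Sensitivity",
    "Specificity",
    "F1",
]


def fmt_ci(point: float, lo: float, hi: float, nd: int = 2, scale: float = 1.0) -> str:
    return f"{point * scale:.{nd}f} ({lo * scale:.{nd}f}-{hi * scale:.{nd}f})"


def agreement_table(
    reference: CodingMatrix,
    coders: Mapping[str, Sequence[CodingMatrix]],
    cfg: BootstrapConfig | None = None,
) -> pd.DataFrame:
    """Pooled-agreement summary table: one row per coder plus a mean row per
    coder group, every cell "point (ci_low-ci_high)"."""
    from qualagree import agreement as ag

    cfg = cfg or BootstrapConfig()
    metric_fns = [
        (ag.percent_agreement, 1, 100.0),
        (ag.cohen_kappa, 2, 1.0),
        (ag.gwet_ac1, 2, 1.0),
        (ag.jaccard, 2, 1.0),
        (ag.sensitivity, 2, 1.0),
        (ag.specificity, 2, 1.0),
        (ag.f1, 2, 1.0),
    ]
    rows: dict[str, list[str]] = {}
    for group, members in coders.items():
        for coder in members:
            rows[coder.coder_id] = [
                _cell(bootstrap_ci(fn, reference, coder, cfg), nd, scale)
                for fn, nd, scale in metric_fns
            ]
        if len(members) > 1:
            rows[f"{group} mean"] = [
                _cell(bootstrap_mean_ci(fn, reference, list(members), cfg), nd, scale)
                for fn, nd, scale in metric_fns
            ]
    return pd.DataFrame.from_dict(rows, orient="index", columns=METRIC_COLUMNS)


def _cell(res: BootstrapResult, nd: int, scale: float) -> str:
    return fmt_ci(res.point, res.ci_low, res.ci_high, nd=nd, scale=scale)


def per_code_kappa_table(
    reference: CodingMatrix, coders: Sequence[CodingMatrix]
) -> pd.DataFrame:
    """Per-code Cohen's kappa, one column per coder (NaN = undefined)."""
    from qualagree.agreement import per_code_kappa

    data = {c.coder_id: per_code_kappa(reference, c) for c in coders}
    return pd.DataFrame(data).round(2)


def comparison_table(results: Sequence[ComparisonResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "model": r.model_id,
                "effect": round(r.effect, 4),
                "ci_low": round(r.ci[0], 4),
                "ci_high": round(r.ci[1], 4),
                "margin": r.margin,
                "p_raw": round(r.p_raw, 4),
                "p_holm": round(r.p_holm, 4),
                "p_sup_raw": round(r.p_sup_raw, 4),
                "p_sup_holm": round(r.p_sup_holm, 4),
                "noninferior": r.verdict_noninferior,
                "superior": r.verdict_superior,
            }
        )
    return pd.DataFrame(rows).set_index("model")


def audit_table(summary: ErrorRateSummary) -> pd.DataFrame:
    """Quote-verification table: count block plus error-rate block, with an
    across-model Mean (SD) column (counts for the count block, percentage
    points for the rate block)."""
    models = [m.model_id for m in summary.per_model]
    rows: dict[str, list[str]] = {}
    count_labels = {
        "exact": "Exact match",
        "partial": "Partial match",
        "no_match": "No match",
        "researcher_segment": "Researcher segments coded",
        "total": "Total segments coded",
    }
    for name, label in count_labels.items():
        cells = []
        for m in summary.per_model:
            v = getattr(m, name)
            pct = 100.0 * v / m.total if m.total else float("nan")
            cells.append(f"{v} ({pct:.1f}%)")
        mean, sd = summary.count_mean[name], summary.count_sd[name]
        rows[label] = cells + [f"{mean:.1f} ({sd:.1f})"]
    rate_labels = {
        "strict_rate": ("Strict hallucination rate", "no_match"),
        "expanded_rate": ("Expanded hallucination rate", None),
        "comprehensive_rate": ("Comprehensive error rate", None),
    }
    numerators = {
        "strict_rate": lambda m: m.no_match,
        "expanded_rate": lambda m: m.no_match + m.researcher_segment,
        "comprehensive_rate": lambda m: m.no_match + m.researcher_segment + m.partial,
    }
    for name, (label, _) in rate_labels.items():
        cells = [
            f"{numerators[name](m)}/{m.total} ({getattr(m, name):.1f}%)"
            for m in summary.per_model
        ]
        mean, sd = summary.rate_mean[name], summary.rate_sd[name]
        rows[label] = cells + [f"{mean:.1f}% ({sd:.1f}%)"]
    return pd.DataFrame.from_dict(rows, orient="index", columns=models + ["Mean (SD)"])


def write_report_tables(tables: Mapping[str, pd.DataFrame], outdir: str | Path) -> list[Path]:
    """Write each named table as CSV and GitHub-markdown under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in tables.items():
        csv_path = outdir / f"{name}.csv"
        df.to_csv(csv_path)
        md_path = outdir / f"{name}.md"
        md_path.write_text(df.to_markdown() + "\n", encoding="utf-8")
        written.extend([csv_path, md_path])
    return written


def comparison_forest_plot(
    results: Sequence[ComparisonResult], path: str | Path, title: str = ""
) -> Path:
    """Forest-plot-style summary: per-model effect with CI, zero line, and
    the dashed non-inferiority margin at -margin."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 1 + 0.8 * len(results)))
    ys = range(len(results), 0, -1)
    for y, r in zip(ys, results):
        ax.errorbar(
            r.effect,
            y,
            xerr=[[r.effect - r.ci[0]], [r.ci[1] - r.effect]],
            fmt="o",
            color="black",
            capsize=3,
        )
    if results:
        ax.axvline(0.0, color="grey", lw=0.8)
        ax.axvline(-results[0].margin, color="black", ls="--", lw=0.8)
    ax.set_yticks(list(ys))
    ax.set_yticklabels([r.model_id for r in results])
    ax.set_xlabel("effect vs. human mean (dashed line = non-inferiority margin)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
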