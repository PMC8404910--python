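"""Statistical comparison stage: normality screening, one-way ANOVA,
Kruskal–Wallis, region/experience grouping, and the full analysis report.

Mirrors the study's analysis order: per-group mean ± 2·std outlier exclusion
first, then a one-way ANOVA for task times (screened as normal), the
Kruskal–Wallis rank test for the skewed path distances and the ordinal
questionnaire scores, with D'Agostino's K² omnibus test as the normality
screen. Pairwise comparisons between conditions are reported without a
multiple-testing correction by default (a Holm adjustment is available).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, asdict
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .metrics import filter_outliers, summarize_groups

__all__ = [
    "EXPERIENCE_LEVELS",
    "TestResult",
    "one_way_anova",
    "kruskal_wallis",
    "normality_check",
    "region_of",
    "holm_adjust",
    "analysis_report",
    "render_report",
]

#: Experience categories: number of prior uses of a spinal navigation system.
EXPERIENCE_LEVELS = ("Never-10", "11-50", "51-250", ">250")


@dataclass(frozen=True)
class TestResult:
    """Outcome of one hypothesis test."""

    name: str
    statistic: float
    p_value: float
    group_labels: tuple[str, ...]
    n_per_group: tuple[int, ...]

    def __post_init__(self) -> None:
        if not 0 <= self.p_value <= 1:
            raise ValueError("p-value must lie in [0, 1]")


def _check_groups(groups: Sequence[Sequence[float]], labels) -> tuple[list[np.ndarray], tuple[str, ...]]:
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2:
        raise ValueError("need at least two groups")
    for i, g in enumerate(gs):
        if g.size < 2:
            raise ValueError(f"group {i} has n={g.size} < 2")
    if labels is None:
        labels = tuple(f"group{i}" for i in range(len(gs)))
    return gs, tuple(str(l) for l in labels)


def one_way_anova(groups: Sequence[Sequence[float]], labels=None) -> TestResult:
    """Classical one-way (between/within) F test.

    Delegates to ``scipy.stats.f_oneway``; the degenerate case of identical
    group means (zero between-group sum of squares) is reported as F = 0,
    p = 1 rather than nan.
    """
    gs, labels = _check_groups(groups, labels)
    means = np.array([g.mean() for g in gs])
    if np.allclose(means, means[0], rtol=0, atol=1e-12 * max(1.0, abs(means[0]))):
        f, p = 0.0, 1.0
    else:
        f, p = sps.f_oneway(*gs)
    return TestResult("one_way_anova", float(f), float(p), labels, tuple(g.size for g in gs))


def kruskal_wallis(groups: Sequence[Sequence[float]], labels=None) -> TestResult:
    """Kruskal–Wallis rank test with tie correction and chi-square p-value."""
    gs, labels = _check_groups(groups, labels)
    pooled = np.concatenate(gs)
    if np.all(pooled == pooled[0]):
        h, p = 0.0, 1.0
    else:
        h, p = sps.kruskal(*gs)
    return TestResult("kruskal_wallis", float(h), float(p), labels, tuple(g.size for g in gs))


def normality_check(values: Sequence[float], min_n: int = 20) -> TestResult:
    """D'Agostino's K² omnibus (skewness + kurtosis) normality test.

    Requires a reasonable sample size for the statistic's chi-square
    approximation; inputs below ``min_n`` are rejected with a diagnostic.
    """
    v = np.asarray(values, dtype=float)
    if v.size < min_n:
        raise ValueError(
            f"normality check needs n >= {min_n} for a valid K² approximation, got n={v.size}"
        )
    k2, p = sps.normaltest(v)
    return TestResult("dagostino_k2", float(k2), float(p), ("sample",), (v.size,))


_REGION_RE = re.compile(r"^(Th|L)(\d+)")


def region_of(vertebra_label: str) -> str:
    """Spinal region of a vertebra label: Th* → thoracic, L* → lumbar.

    Labels may carry a side suffix (e.g. ``"Th12-L"`` for the left pedicle at
    Th12). Cervical or otherwise unknown prefixes are rejected — the study
    fixture spans Th11–L5 only.
    """
    m = _REGION_RE.match(str(vertebra_label))
    if not m:
        raise ValueError(f"unrecognized vertebra label {vertebra_label!r} (expected Th<n> or L<n>)")
    return "thoracic" if m.group(1) == "Th" else "lumbar"


def holm_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Holm step-down adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    m = p.size
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


def _pairwise(values_by_group: dict[str, np.ndarray], test) -> list[TestResult]:
    out = []
    for a, b in combinations(sorted(values_by_group), 2):
        out.append(test([values_by_group[a], values_by_group[b]], labels=(a, b)))
    return out


def _metric_section(
    table: pd.DataFrame,
    metric: str,
    group_col: str,
    test,
    min_normality_n: int,
) -> dict:
    raw = {
        str(k): v[metric].dropna().to_numpy()
        for k, v in table.groupby(group_col)
        if v[metric].notna().sum() > 0
    }
    if not raw:
        raise ValueError(f"no data for metric {metric!r}")
    filtered = {}
    excluded = {}
    for k, v in raw.items():
        if v.size >= 2:
            kept, mask = filter_outliers(v)
            filtered[k] = kept
            excluded[k] = int((~mask).sum())
        else:
            filtered[k] = v
            excluded[k] = 0
    normality = {}
    for k, v in filtered.items():
        if v.size >= min_normality_n:
            r = normality_check(v, min_n=min_normality_n)
            normality[k] = {"statistic": r.statistic, "p_value": r.p_value, "n": v.size}
    testable = {k: v for k, v in filtered.items() if v.size >= 2}
    section = {
        "summary": {
            k: {"mean": float(v.mean()), "std": float(v.std(ddof=1)) if v.size > 1 else 0.0, "n": int(v.size)}
            for k, v in filtered.items()
        },
        "outliers_excluded": excluded,
        "normality": normality,
        "pairwise": [asdict(r) for r in _pairwise(testable, test)] if len(testable) >= 2 else [],
    }
    if len(testable) >= 2:
        omnibus = test(list(testable.values()), labels=tuple(testable.keys()))
        section["omnibus"] = asdict(omnibus)
    return section


def analysis_report(
    metric_table: pd.DataFrame,
    questionnaire_table: pd.DataFrame | None = None,
    group_by: str = "condition",
    time_test=one_way_anova,
    distance_test=kruskal_wallis,
    holm: bool = False,
    min_normality_n: int = 20,
) -> dict:
    """Full analysis over a metric table (and optional questionnaire table).

    Per metric: per-group outlier exclusion, normality screening, grouped
    mean ± std summaries, the omnibus test and all pairwise comparisons —
    a one-way ANOVA for task times and the Kruskal–Wallis test for path
    distances and questionnaire scores. Deterministic: identical inputs
    produce an identical report dict (JSON-serializable).
    """
    if group_by not in metric_table.columns:
        raise ValueError(f"metric table has no {group_by!r} column")
    if metric_table[group_by].nunique() < 1 or len(metric_table) == 0:
        raise ValueError("metric table is empty")
    report: dict = {"group_by": group_by, "metrics": {}}
    for metric, test in (("task_time_s", time_test), ("euclidean_path_mm", distance_test)):
        if metric in metric_table.columns:
            report["metrics"][metric] = _metric_section(
                metric_table, metric, group_by, test, min_normality_n
            )
    if questionnaire_table is not None:
        report["questionnaires"] = {}
        score_cols = [
            c for c in ("sus_score", "tlx_overall", "mental_demand", "visual_appeal", "intuitiveness", "interaction")
            if c in questionnaire_table.columns
        ]
        for col in score_cols:
            report["questionnaires"][col] = _metric_section(
                questionnaire_table, col, group_by, kruskal_wallis, min_normality_n
            )
    if holm:
        for sec in list(report["metrics"].values()) + list(report.get("questionnaires", {}).values()):
            ps = [r["p_value"] for r in sec["pairwise"]]
            if ps:
                for r, adj in zip(sec["pairwise"], holm_adjust(ps)):
                    r["p_holm"] = float(adj)
    return report


def render_report(report: dict) -> str:
    """Plain-text rendering of an analysis report."""
    lines: list[str] = [f"Analysis grouped by {report['group_by']}", ""]
    sections = dict(report.get("metrics", {}))
    sections.update(report.get("questionnaires", {}))
    for metric, sec in sections.items():
        lines.append(f"== {metric} ==")
        for grp, s in sec["summary"].items():
            lines.append(f"  {grp:24s} {s['mean']:8.2f} ± {s['std']:6.2f}  (n={s['n']})")
        if "omnibus" in sec:
            o = sec["omnibus"]
            lines.append(f"  omnibus {o['name']}: stat={o['statistic']:.4g}, p={o['p_value']:.4g}")
        for r in sec["pairwise"]:
            extra = f", p_holm={r['p_holm']:.4g}" if "p_holm" in r else ""
            lines.append(
                f"  {r['group_labels'][0]} vs {r['group_labels'][1]}: "
                f"{r['name']} stat={r['statistic']:.4g}, p={r['p_value']:.4g}{extra}"
            )
        lines.append("")
    return "\n".join(lines)
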