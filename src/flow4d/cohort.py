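"""Group-level aggregation: mean ± SD, confidence intervals, percent differences.

The study design is descriptive (no hypothesis tests): per metric and group
the report carries n, mean, sample SD, and a Student-t confidence interval on
the mean, plus the percent difference of each treated group against the
isolated-myectomy reference.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import AnalysisConfig
from .errors import ValidationError
from .fields import SubjectResult
from .targets import REFERENCE_GROUP, STUDY_GROUPS

#: Metrics reported, in fixed table order.
REPORT_METRICS = (
    "ke_lvot",
    "peak_velocity_lvot",
    "ke_aorta",
    "wss_aorta",
    "mv_forward",
    "av_forward",
    "dp_mean",
    "dp_max",
    "strain_lvot",
)


def summarize_group(
    values: Sequence[float], ci_level: float = 0.95
) -> tuple[int, float, float, float, float]:
    """(n, mean, sd, ci_low, ci_high) for one group's metric values.

    SD uses the n−1 denominator (0 when n = 1); the CI is
    mean ± t_{(1+level)/2, n−1} · sd/√n, degenerate at the mean for n = 1.
    """
    x = np.asarray(list(values), dtype=float)
    if x.size == 0:
        raise ValidationError("summarize_group: empty input")
    if not 0 < ci_level < 1:
        raise ValidationError("ci_level must lie in (0, 1)")
    n = x.size
    mean = float(x.mean())
    if n == 1:
        return 1, mean, 0.0, mean, mean
    sd = float(x.std(ddof=1))
    tq = float(stats.t.ppf(0.5 * (1.0 + ci_level), df=n - 1))
    half = tq * sd / np.sqrt(n)
    return n, mean, sd, mean - half, mean + half


def percent_difference(reference: float, comparison: float) -> float:
    """(comparison − reference)/|reference| × 100."""
    if reference == 0:
        raise ValidationError("percent difference undefined for a zero reference")
    return float((comparison - reference) / abs(reference) * 100.0)


def build_report(
    results: Iterable[SubjectResult],
    config: Optional[AnalysisConfig] = None,
    out_dir: str | Path | None = None,
) -> pd.DataFrame:
    """Aggregate per-subject results into the group table.

    One row per metric and group with n/mean/sd/CI; percent-difference
    columns against the isolated-myectomy reference appear when that group
    is present and more than one group exists.  Output is deterministic and
    independent of subject ordering.  When ``out_dir`` is given,
    ``cohort_table.csv`` and ``cohort_table.md`` are written there.
    """
    config = config or AnalysisConfig()
    results = sorted(results, key=lambda r: (r.group, r.subject_id))
    known_groups = list(STUDY_GROUPS)
    groups_present = []
    for r in results:
        if not r.group:
            raise ValidationError("every SubjectResult needs a group label")
        if r.group not in known_groups:
            raise ValidationError(
                f"unknown group label '{r.group}'; known: {known_groups}"
            )
        if r.group not in groups_present:
            groups_present.append(r.group)
    if not groups_present:
        raise ValidationError("no subject results to aggregate")
    groups_present = [g for g in known_groups if g in groups_present]

    rows = []
    ref_means: dict[str, float] = {}
    for metric in REPORT_METRICS:
        for group in groups_present:
            vals = [
                getattr(r, metric)
                for r in results
                if r.group == group and getattr(r, metric) is not None
            ]
            if not vals:
                continue
            n, mean, sd, lo, hi = summarize_group(vals, config.ci_level)
            if group == REFERENCE_GROUP:
                ref_means[metric] = mean
            rows.append(
                dict(metric=metric, group=group, n=n, mean=mean, sd=sd,
                     ci_low=lo, ci_high=hi)
            )
    table = pd.DataFrame(rows)

    multi_group = len(groups_present) > 1
    if multi_group and REFERENCE_GROUP in groups_present:
        def pct(row):
            if row["group"] == REFERENCE_GROUP or row["metric"] not in ref_means:
                return np.nan
            ref = ref_means[row["metric"]]
            if ref == 0:
                return np.nan
            return percent_difference(ref, row["mean"])

        table["pct_vs_reference"] = table.apply(pct, axis=1)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        table.to_csv(out_dir / "cohort_table.csv", index=False, float_format="%.6g")
        _write_markdown(table, out_dir / "cohort_table.md")
    return table


def _write_markdown(table: pd.DataFrame, path: Path) -> None:
    lines = ["| metric | group | n | mean ± SD | 95% CI |"
             + (" % vs reference |" if "pct_vs_reference" in table else ""),
             "|---|---|---|---|---|" + ("---|" if "pct_vs_reference" in table else "")]
    for _, r in table.iterrows():
        row = (
            f"| {r['metric']} | {r['group']} | {int(r['n'])} "
            f"| {r['mean']:.3g} ± {r['sd']:.2g} "
            f"| [{r['ci_low']:.3g}, {r['ci_high']:.3g}] |"
        )
        if "pct_vs_reference" in table:
            pct = r["pct_vs_reference"]
            row += " |" if np.isnan(pct) else f" {pct:+.1f}% |"
        lines.append(row)
    path.write_text("\n".join(lines) + "\n")
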