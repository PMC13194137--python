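"""Report tables in the layout clinical papers use.

Four products: a demographics table (counts with percentages, mean ± SD),
two-group comparison tables (mean ± SD per group, test statistic, p with
footnote stars), a metric-vs-scale correlation table, and a power-analysis
appendix.  Values are formatted at the precision the tables print (means
2 dp, percentages 1 dp, both rounded half-up); no multiple-testing
correction is applied and the report header says so.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SchemaError
from .morphometry import round_half_up
from .stats import (
    CorrelationResult,
    GroupComparisonResult,
    chi_square,
    required_sample_size,
)

NO_CORRECTION_NOTE = (
    "Per-variable tests; no multiple-testing correction applied. "
    "Stars: ** p < 0.01, *** p < 0.001."
)


def percent(count: int, total: int) -> float:
    """Percentage at 1 dp, half-up — the precision demographic tables print."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round_half_up(100 * count / total, 1)


def count_pct(count: int, total: int) -> str:
    return f"{count} ({percent(count, total):.1f}%)"


def mean_sd(values) -> str:
    x = np.asarray(values, dtype=float)
    return f"{round_half_up(x.mean(), 2):.2f} ± {round_half_up(x.std(ddof=1), 2):.2f}"


def format_p(p: float) -> str:
    return "< 0.001" if p < 0.001 else f"{round_half_up(p, 3):.3f}"


def demographics_table(roster: pd.DataFrame, group_col: str = "group") -> pd.DataFrame:
    """Per-group demographic profile: sex, age, education, HDRS bands.

    Counts are shown as ``n (pct%)`` with percentages within group; age as
    mean ± SD.  HDRS severity bands (19–22 / >= 23) are reported only for
    groups that carry HDRS scores.
    """
    if group_col not in roster.columns:
        raise SchemaError(f"roster lacks a {group_col!r} column")
    groups = sorted(roster[group_col].unique())
    rows: list[dict] = []

    def add(variable: str, values: dict[str, str]) -> None:
        rows.append({"variable": variable, **values})

    add("n", {g: str((roster[group_col] == g).sum()) for g in groups})
    if "sex" in roster.columns:
        for sex in ("male", "female"):
            add(
                f"sex: {sex}",
                {
                    g: count_pct(
                        int(((roster[group_col] == g) & (roster["sex"] == sex)).sum()),
                        int((roster[group_col] == g).sum()),
                    )
                    for g in groups
                },
            )
    if "age" in roster.columns:
        add("age", {g: mean_sd(roster.loc[roster[group_col] == g, "age"]) for g in groups})
    if "education" in roster.columns:
        for level in pd.unique(roster["education"].dropna()):
            add(
                f"education: {level}",
                {
                    g: count_pct(
                        int(
                            (
                                (roster[group_col] == g) & (roster["education"] == level)
                            ).sum()
                        ),
                        int((roster[group_col] == g).sum()),
                    )
                    for g in groups
                },
            )
    if "hdrs" in roster.columns:
        for label, lo, hi in (("19-22", 19, 22), (">= 23", 23, np.inf)):
            vals = {}
            for g in groups:
                sub = roster.loc[roster[group_col] == g, "hdrs"].dropna()
                if sub.empty:
                    vals[g] = "-"
                else:
                    vals[g] = count_pct(int(((sub >= lo) & (sub <= hi)).sum()), len(sub))
            add(f"hdrs: {label}", vals)
    return pd.DataFrame(rows)


def sex_balance_chi_square(roster: pd.DataFrame, group_col: str = "group"):
    """Chi-square test of the sex x group contingency table."""
    tab = pd.crosstab(roster["sex"], roster[group_col])
    return chi_square(tab.to_numpy())


def comparison_table(
    results: list[GroupComparisonResult], label_a: str, label_b: str
) -> pd.DataFrame:
    """Two-group comparison table: mean ± SD, test, statistic, p, d, stars."""
    rows = []
    for r in results:
        rows.append(
            {
                "variable": r.variable,
                label_a: f"{round_half_up(r.mean1, 2):.2f} ± {round_half_up(r.sd1, 2):.2f}",
                label_b: f"{round_half_up(r.mean2, 2):.2f} ± {round_half_up(r.sd2, 2):.2f}",
                "test": r.test,
                "statistic": round_half_up(r.statistic, 3),
                "p": format_p(r.p),
                "cohens_d": "" if r.cohens_d is None else round_half_up(r.cohens_d, 2),
                "stars": r.stars,
            }
        )
    return pd.DataFrame(rows)


def correlation_table(results: list[CorrelationResult]) -> pd.DataFrame:
    rows = [
        {
            "variable": r.pair[0],
            "scale": r.pair[1],
            "rho": round_half_up(r.rho, 3),
            "p": format_p(r.p),
            "n": r.n,
            "stars": r.stars,
        }
        for r in results
    ]
    return pd.DataFrame(rows)


def power_appendix(
    d: float = 0.5, alpha: float = 0.05, power: float = 0.80
) -> pd.DataFrame:
    """Required per-group and total n for the planned two-sample t design."""
    n = required_sample_size(d, alpha=alpha, power=power, two_sided=True)
    return pd.DataFrame(
        [
            {
                "effect_size_d": d,
                "alpha": alpha,
                "power": power,
                "n_per_group": n,
                "n_total": 2 * n,
            }
        ]
    )


def render_text_report(tables: dict[str, pd.DataFrame]) -> str:
    """Human-readable report: named tables with the star-convention footer."""
    parts = [NO_CORRECTION_NOTE, ""]
    for name, table in tables.items():
        parts.append(f"== {name} ==")
        parts.append(table.to_string(index=False))
        parts.append("")
    return "\n".join(parts)


def write_tables(tables: dict[str, pd.DataFrame], out_dir: str | Path) -> list[Path]:
    """Write each table as UTF-8 CSV plus a combined report.txt."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name, table in tables.items():
        path = out / f"{name}.csv"
        table.to_csv(path, index=False)
        written.append(path)
    text_path = out / "report.txt"
    text_path.write_text(render_text_report(tables))
    written.append(text_path)
    return written
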