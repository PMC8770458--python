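"""Group summaries and comparison statistics.

The unit of replication is the animal: per-mitochondrion records are
averaged within each animal first, and group statistics are computed over
the animal means (avoiding pseudo-replication).  Comparisons are the
standard battery for this study design: unpaired two-tailed t test, one-way
ANOVA with Tukey's post hoc, and two-way ANOVA with Sidak-adjusted pairwise
contrasts; P < 0.05 is reported as significant.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupSummary",
    "ComparisonResult",
    "summarize",
    "fold_change",
    "compare",
    "render_tables",
]

P_SIGNIFICANT = 0.05


@dataclass
class GroupSummary:
    group: str
    subtype: str
    metric: str
    per_animal_means: dict[str, float]
    mean: float
    sd: float
    sem: float
    n: int
    flags: list[str] = field(default_factory=list)


@dataclass
class ComparisonResult:
    test: str  # "t" | "anova1+tukey" | "anova2+sidak"
    statistic: float
    p_value: float
    contrasts: list[dict] = field(default_factory=list)
    significant: bool | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or math.isnan(self.p_value)):
            raise ValueError("p-value outside [0, 1]")
        if self.significant is None:
            self.significant = bool(self.p_value < P_SIGNIFICANT)


def summarize(
    records: pd.DataFrame,
    value: str,
    group_cols: tuple[str, ...] = ("group", "subtype"),
    animal_col: str = "animal",
) -> list[GroupSummary]:
    """Hierarchical mean +/- SEM: animal means first, then the group.

    ``records`` is a tidy table with one row per measured object.  SEM is
    sd/sqrt(n) over animal means (n = animals); a single-animal group is
    flagged and reports NaN sd/SEM.
    """
    if records.empty:
        return []
    missing = [c for c in (*group_cols, animal_col, value) if c not in records.columns]
    if missing:
        raise ValueError(f"records missing columns {missing}")
    out: list[GroupSummary] = []
    for keys, grp in records.groupby(list(group_cols), sort=True):
        keys = (keys,) if not isinstance(keys, tuple) else keys
        animal_means = grp.groupby(animal_col)[value].mean()
        n = len(animal_means)
        if n == 0:
            raise ValueError(f"empty group {keys}")
        mean = float(animal_means.mean())
        sd = float(animal_means.std(ddof=1)) if n > 1 else float("nan")
        sem = sd / math.sqrt(n) if n > 1 else float("nan")
        out.append(
            GroupSummary(
                group=str(keys[0]),
                subtype=str(keys[1]) if len(keys) > 1 else "",
                metric=value,
                per_animal_means={str(a): float(v) for a, v in animal_means.items()},
                mean=mean,
                sd=sd,
                sem=sem,
                n=n,
                flags=["single_animal"] if n == 1 else [],
            )
        )
    return out


def fold_change(numerator_mean: float, denominator_mean: float) -> float:
    """Ratio of group means (the fold-change style used for figure legends)."""
    if denominator_mean == 0:
        raise ZeroDivisionError("denominator group mean is zero")
    return numerator_mean / denominator_mean


def _t_test(groups: dict[str, np.ndarray]) -> ComparisonResult:
    if len(groups) != 2:
        raise ValueError("t test needs exactly two groups")
    a, b = (np.asarray(v, dtype=float) for v in groups.values())
    if np.ptp(np.concatenate([a, b])) == 0.0:
        return ComparisonResult(test="t", statistic=0.0, p_value=1.0)
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return ComparisonResult(test="t", statistic=float(t), p_value=float(p))


def _anova1_tukey(groups: dict[str, np.ndarray]) -> ComparisonResult:
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0.0:
        return ComparisonResult(test="anova1+tukey", statistic=0.0, p_value=1.0)
    f, p = stats.f_oneway(*arrays)
    labels = np.concatenate([[k] * len(v) for k, v in groups.items()])
    tk = pairwise_tukeyhsd(pooled, labels, alpha=P_SIGNIFICANT)
    from itertools import combinations

    pairs = list(combinations(tk.groupsunique, 2))
    contrasts = [
        {
            "pair": f"{a} vs {b}",
            "estimate": float(est),
            "p_adj": float(pv),
            "reject": bool(rej),
        }
        for (a, b), est, pv, rej in zip(
            pairs, tk.meandiffs, tk.pvalues, tk.reject
        )
    ]
    return ComparisonResult(
        test="anova1+tukey", statistic=float(f), p_value=float(p), contrasts=contrasts
    )


def _anova2_sidak(df: pd.DataFrame, value: str, factor_a: str, factor_b: str) -> ComparisonResult:
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    cells = df.groupby([factor_a, factor_b])[value].count().unstack()
    if cells.isna().any().any() or (cells < 1).any().any():
        raise ValueError("unbalanced two-way design with empty cells: "
                         "interaction not estimable")
    data = df.rename(columns={value: "_y", factor_a: "_fa", factor_b: "_fb"})
    model = ols("_y ~ C(_fa) * C(_fb)", data=data).fit()
    table = sm.stats.anova_lm(model, typ=2)
    f = float(table.loc["C(_fa)", "F"])
    p = float(table.loc["C(_fa)", "PR(>F)"])
    # Sidak-adjusted pairwise contrasts of factor A within each level of B
    levels_a = sorted(df[factor_a].unique())
    if len(levels_a) != 2:
        raise ValueError("Sidak contrasts here compare exactly two primary levels")
    raw = []
    for lb in sorted(df[factor_b].unique()):
        sub = df[df[factor_b] == lb]
        a = sub[sub[factor_a] == levels_a[0]][value].to_numpy(dtype=float)
        b = sub[sub[factor_a] == levels_a[1]][value].to_numpy(dtype=float)
        if np.ptp(np.concatenate([a, b])) == 0.0:
            t, pv = 0.0, 1.0
        else:
            t, pv = stats.ttest_ind(a, b, equal_var=True)
        raw.append((lb, float(np.mean(b) - np.mean(a)), float(pv)))
    m = len(raw)
    contrasts = [
        {
            "pair": f"{levels_a[0]} vs {levels_a[1]} | {lb}",
            "estimate": est,
            "p_adj": float(1.0 - (1.0 - pv) ** m),
            "reject": bool(1.0 - (1.0 - pv) ** m < P_SIGNIFICANT),
        }
        for lb, est, pv in raw
    ]
    return ComparisonResult(
        test="anova2+sidak", statistic=f, p_value=p, contrasts=contrasts
    )


def compare(
    data,
    design: dict,
) -> ComparisonResult:
    """Run the comparison named by ``design``.

    ``design['test']`` is one of ``"t"``, ``"anova1"`` (Tukey post hoc) or
    ``"anova2"`` (Sidak contrasts).  For t/anova1, ``data`` is a mapping
    group -> values; for anova2 it is a tidy DataFrame and the design names
    ``value``, ``factor_a`` (the primary comparison) and ``factor_b``.
    """
    test = design.get("test")
    if test == "t":
        return _t_test(data)
    if test == "anova1":
        if len(data) < 2:
            raise ValueError("ANOVA needs at least two groups")
        return _anova1_tukey(data)
    if test == "anova2":
        return _anova2_sidak(data, design["value"], design["factor_a"], design["factor_b"])
    raise ValueError(f"unknown test {test!r}")


_SUMMARY_COLUMNS = [
    "group", "subtype", "metric", "mean", "sd", "sem", "n", "per_animal_means", "flags",
]


def render_tables(
    summaries: list[GroupSummary],
    comparisons: list[ComparisonResult],
    out_dir,
    provenance: dict | None = None,
) -> dict[str, Path]:
    """Serialize summaries and comparisons to CSV + JSON with provenance.

    Column order is stable; an empty input yields a header-only CSV.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = [
        {
            "group": s.group,
            "subtype": s.subtype,
            "metric": s.metric,
            "mean": s.mean,
            "sd": s.sd,
            "sem": s.sem,
            "n": s.n,
            "per_animal_means": json.dumps(s.per_animal_means, sort_keys=True),
            "flags": ";".join(s.flags),
        }
        for s in summaries
    ]
    df = pd.DataFrame(rows, columns=_SUMMARY_COLUMNS)
    csv_path = out_dir / "summaries.csv"
    df.to_csv(csv_path, index=False)
    from mitomorph import __version__

    payload = {
        "provenance": {"package": "mitomorph", "version": __version__,
                       **(provenance or {})},
        "summaries": rows,
        "comparisons": [
            {
                "test": c.test,
                "statistic": c.statistic,
                "p_value": c.p_value,
                "significant": c.significant,
                "contrasts": c.contrasts,
            }
            for c in comparisons
        ],
    }
    json_path = out_dir / "report.json"
    json_path.write_text(json.dumps(payload, indent=1, sort_keys=True))
    return {"csv": csv_path, "json": json_path}
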