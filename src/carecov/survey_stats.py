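"""Descriptive cross-tabulations and bivariate tests for the survey.

Each categorical questionnaire variable is cross-tabulated against the
respondent's habitual choice group with row percentages, and compared by
uncorrected Pearson chi-square; numeric variables (age) are compared by an
independent-samples t-test (pooled variance by default). Missing values
are excluded pairwise, table by table, so each table reports its own n.
Significance is assessed at α = 0.05; p-values below 0.001 are rendered
as "<0.001" in reports while the exact value is retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class ContingencyTable:
    row_labels: list[str]
    col_labels: list[str]
    counts: np.ndarray  # rows × cols, int
    n: int

    @property
    def row_percentages(self) -> np.ndarray:
        totals = self.counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = 100.0 * self.counts / totals
        return np.round(np.where(totals > 0, pct, 0.0), 1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.row_labels, columns=self.col_labels)


@dataclass
class TestResult:
    statistic: float
    df: float
    p: float
    method: str
    alpha: float = 0.05
    warnings: list[str] = field(default_factory=list)

    @property
    def significant(self) -> bool:
        return self.p < self.alpha

    @property
    def p_display(self) -> str:
        return "<0.001" if self.p < 0.001 else f"{self.p:.3f}"


def crosstab(data: pd.DataFrame, row_var: str, col_var: str,
             row_order: list[str] | None = None,
             col_order: list[str] | None = None) -> ContingencyTable:
    """Cross-tabulate two categorical variables, dropping rows missing in
    either variable (pairwise deletion)."""
    for v in (row_var, col_var):
        if v not in data.columns:
            raise KeyError(f"variable {v!r} not in dataset")
    sub = data[[row_var, col_var]].dropna()
    tab = pd.crosstab(sub[row_var], sub[col_var])
    if row_order:
        tab = tab.reindex(index=[r for r in row_order if r in tab.index])
    if col_order:
        tab = tab.reindex(columns=[c for c in col_order if c in tab.columns])
    counts = tab.to_numpy(dtype=int) if tab.size else np.zeros((0, 0), dtype=int)
    return ContingencyTable(
        row_labels=[str(r) for r in tab.index],
        col_labels=[str(c) for c in tab.columns],
        counts=counts,
        n=int(counts.sum()),
    )


def pearson_chi2(table: ContingencyTable, correction: bool = False) -> TestResult:
    """Pearson chi-square test of independence, X² = Σ (O−E)²/E.

    No continuity correction by default. Cells with expected count below 5
    are reported in the warnings list, not an error.
    """
    counts = np.asarray(table.counts, dtype=float)
    if counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        raise ValueError("zero marginal total: expected counts undefined")
    chi2, p, df, expected = stats.chi2_contingency(counts, correction=correction)
    warns = []
    n_low = int((expected < 5).sum())
    if n_low:
        warns.append(f"{n_low} cells with expected count < 5")
    return TestResult(statistic=float(chi2), df=float(df), p=float(p),
                      method="pearson_chi2" + ("_yates" if correction else ""),
                      warnings=warns)


def two_sample_t(data: pd.DataFrame, value_var: str, group_var: str,
                 equal_var: bool = True) -> TestResult:
    """Two-sided independent-samples t-test of ``value_var`` between the
    two levels of ``group_var`` (pooled variance unless ``equal_var`` is
    False, which gives Welch's test)."""
    sub = data[[value_var, group_var]].dropna()
    groups = sub[group_var].unique()
    if len(groups) != 2:
        raise ValueError(f"group variable must be binary, found {len(groups)} levels")
    a = sub.loc[sub[group_var] == groups[0], value_var].to_numpy(dtype=float)
    b = sub.loc[sub[group_var] == groups[1], value_var].to_numpy(dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 non-missing values")
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    df = (len(a) + len(b) - 2) if equal_var else float(res.df)
    return TestResult(statistic=float(res.statistic), df=float(df),
                      p=float(res.pvalue),
                      method="t_pooled" if equal_var else "t_welch")


#: Table-1-style reporting order: (variable, type)
DEFAULT_REPORT_VARIABLES: list[tuple[str, str]] = [
    ("age", "numeric"),
    ("gender", "categorical"),
    ("occupation", "categorical"),
    ("income", "categorical"),
    ("education", "categorical"),
    ("mild_illness", "categorical"),
    ("chronic_illness", "categorical"),
    ("hospitalization", "categorical"),
    ("consultations", "categorical"),
    ("medical_cost", "categorical"),
    ("cost_burden", "categorical"),
    ("pbi", "categorical"),
    ("ever_used_benefit", "categorical"),
    ("other_insurance", "categorical"),
]


def descriptive_report(
    data: pd.DataFrame,
    variables: list[tuple[str, str]] | None = None,
    group_var: str = "choice_actual",
) -> dict:
    """Per-variable descriptive entry: crosstab + chi-square p for
    categoricals, group means + t-test p for numerics; each with its own n
    after pairwise missing exclusion."""
    if variables is None:
        variables = [(v, t) for v, t in DEFAULT_REPORT_VARIABLES if v in data.columns]
    entries = []
    for var, kind in variables:
        if kind == "categorical":
            tab = crosstab(data, var, group_var)
            test = pearson_chi2(tab) if min(tab.counts.shape, default=0) >= 2 else None
            entries.append({
                "variable": var, "type": kind, "n": tab.n,
                "rows": tab.row_labels, "cols": tab.col_labels,
                "counts": tab.counts.tolist(),
                "row_pct": tab.row_percentages.tolist(),
                "p": None if test is None else test.p,
                "p_display": None if test is None else test.p_display,
            })
        else:
            sub = data[[var, group_var]].dropna()
            test = two_sample_t(data, var, group_var)
            means = sub.groupby(group_var)[var].mean().to_dict()
            entries.append({
                "variable": var, "type": kind, "n": int(len(sub)),
                "group_means": {str(k): float(v) for k, v in means.items()},
                "p": test.p, "p_display": test.p_display,
            })
    return {"group_var": group_var, "n_total": int(len(data)), "variables": entries}


def render_report(report: dict) -> str:
    """Plain-text rendering of a descriptive report."""
    lines = [f"Descriptives by {report['group_var']} (n={report['n_total']})"]
    for e in report["variables"]:
        p = e.get("p_display") or "-"
        lines.append(f"\n{e['variable']} (n={e['n']})  p={p}")
        if e["type"] == "categorical":
            for r, row, pct in zip(e["rows"], e["counts"], e["row_pct"]):
                cells = "  ".join(f"{c} ({q:.1f}%)" for c, q in zip(row, pct))
                lines.append(f"  {r}: {cells}")
        else:
            means = "  ".join(f"{g}: {m:.1f}" for g, m in e["group_means"].items())
            lines.append(f"  mean {means}")
    return "\n".join(lines)
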