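"""Demographic tables and likelihood-ratio chi-square tests.

Case-control demographic tables are compared column-wise with the
likelihood-ratio (G²) chi-square test of independence:

    G² = 2 Σ_ij O_ij · ln(O_ij / E_ij),   E_ij = row_i · col_j / N

with zero cells contributing nothing and an upper-tail chi-square p-value
on (rows−1)·(cols−1) degrees of freedom.  Rows labelled "Unknown" are
excluded before testing by default (a substantive category such as
"Other/unknown" ethnicity is retained — exclusion is by exact label).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2

__all__ = ["ContingencyTable", "ChiSqResult", "lr_chisq_test", "demographics_table"]


@dataclass(frozen=True)
class ContingencyTable:
    """Category counts for controls and cases (two columns)."""

    labels: tuple
    controls: tuple
    cases: tuple

    def __post_init__(self) -> None:
        if not (len(self.labels) == len(self.controls) == len(self.cases)):
            raise ValueError("labels, controls and cases must have equal length")
        counts = np.array([self.controls, self.cases], dtype=float)
        if np.any(counts < 0) or np.any(counts != np.round(counts)):
            raise ValueError("counts must be nonnegative integers")

    def as_array(self) -> np.ndarray:
        return np.column_stack(
            [np.asarray(self.controls, float), np.asarray(self.cases, float)]
        )


@dataclass(frozen=True)
class ChiSqResult:
    g2: float
    df: int
    p: float
    excluded: tuple = ()


def lr_chisq_test(
    table: ContingencyTable, exclude_labels: Iterable[str] = ("Unknown",)
) -> ChiSqResult:
    """Likelihood-ratio chi-square test of case/control independence."""
    exclude = set(exclude_labels)
    keep = [i for i, lab in enumerate(table.labels) if lab not in exclude]
    excluded = tuple(lab for lab in table.labels if lab in exclude)
    obs = table.as_array()[keep]
    if obs.shape[0] < 2:
        raise ValueError("need at least 2 category rows after exclusions")
    row_sums = obs.sum(axis=1)
    col_sums = obs.sum(axis=0)
    if np.any(row_sums == 0):
        lab = [table.labels[i] for i in keep][int(np.flatnonzero(row_sums == 0)[0])]
        raise ValueError(f"zero row margin for category {lab!r}")
    if np.any(col_sums == 0):
        which = "controls" if col_sums[0] == 0 else "cases"
        raise ValueError(f"zero column margin for {which}")
    expected = np.outer(row_sums, col_sums) / obs.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(obs > 0, obs * np.log(np.where(obs > 0, obs / expected, 1.0)), 0.0)
    g2 = float(2.0 * terms.sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    return ChiSqResult(g2=g2, df=df, p=float(chi2.sf(g2, df)), excluded=excluded)


_CATEGORICAL = [
    ("age_band", "Age at consent (years)"),
    ("hrt", "HRT use"),
    ("bmi_band", "BMI (kg/m2)"),
    ("menopause", "Menopausal status"),
    ("ethnicity", "Ethnic origin"),
    ("parity", "Parity"),
]


def _median_iqr(x: pd.Series) -> str:
    # linear-interpolation quantiles
    q1, med, q3 = np.quantile(x.to_numpy(dtype=float), [0.25, 0.5, 0.75])
    return f"{med:.2f} ({q1:.2f}-{q3:.2f})"


def demographics_table(
    cohort: pd.DataFrame,
    continuous: Sequence[str] = (),
    exclude_labels: Iterable[str] = ("Unknown",),
) -> pd.DataFrame:
    """Per-study demographic summary with G² p-values per variable.

    For each study and categorical variable: control/case counts, integer
    column percentages, and the LR chi-square p (excluding "Unknown" rows
    from the test, never from the display).  Continuous columns are
    summarized as median (Q1–Q3).  In an all-control cohort the tests are
    skipped with a notice in the p-value column.
    """
    rows = []
    for study, sub in cohort.groupby("study"):
        ctrl = sub[~sub["case"]]
        case = sub[sub["case"]]
        for col, title in _CATEGORICAL:
            if col not in sub.columns:
                continue
            labels = [lab for lab in sub[col].dropna().unique()]
            labels = sorted(labels, key=lambda v: str(v))
            c_counts = ctrl[col].value_counts()
            k_counts = case[col].value_counts()
            if len(case) == 0:
                p_txt = "not tested (no cases)"
            else:
                tab = ContingencyTable(
                    labels=tuple(labels),
                    controls=tuple(int(c_counts.get(l, 0)) for l in labels),
                    cases=tuple(int(k_counts.get(l, 0)) for l in labels),
                )
                try:
                    p_txt = f"{lr_chisq_test(tab, exclude_labels).p:.4f}"
                except ValueError as exc:
                    p_txt = f"not tested ({exc})"
            for lab in labels:
                nc = int(c_counts.get(lab, 0))
                nk = int(k_counts.get(lab, 0))
                rows.append(
                    {
                        "study": study,
                        "variable": title,
                        "category": lab,
                        "controls_n": nc,
                        "controls_pct": round(100 * nc / max(len(ctrl), 1)),
                        "cases_n": nk,
                        "cases_pct": round(100 * nk / max(len(case), 1)) if len(case) else np.nan,
                        "p_value": p_txt,
                    }
                )
        for col in continuous:
            if col not in sub.columns:
                continue
            rows.append(
                {
                    "study": study,
                    "variable": col,
                    "category": "median (Q1-Q3)",
                    "controls_n": len(ctrl),
                    "controls_pct": np.nan,
                    "cases_n": len(case),
                    "cases_pct": np.nan,
                    "p_value": (
                        f"controls {_median_iqr(ctrl[col])}; "
                        f"cases {_median_iqr(case[col])}"
                        if len(case)
                        else f"controls {_median_iqr(ctrl[col])}"
                    ),
                }
            )
    return pd.DataFrame(rows)
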