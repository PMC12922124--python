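"""Statistics for sublethal antioxidant biomarker panels.

A panel holds biological-replicate measurements of one endpoint (TPC,
DPPH, HRSA, CAT, GST, GPx, SOD, ...) across treatments.  Technical
triplicates are averaged into their biological replicate before analysis
to avoid pseudo-replication.  The battery is: Shapiro-Wilk normality per
group, Levene's test of variance homogeneity, one-way ANOVA with
Bonferroni-adjusted pairwise t-tests, and Pearson correlations between
endpoints computed on treatment-level means.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ToxmixError

__all__ = [
    "BiomarkerPanel",
    "assumption_checks",
    "anova_bonferroni",
    "correlation_matrix",
]


@dataclass(frozen=True)
class BiomarkerPanel:
    """Replicate values of one endpoint per treatment.

    ``groups`` maps treatment label to the biological-replicate values.
    """

    endpoint: str
    groups: Mapping[str, Sequence[float]]
    unit: str = ""

    def __post_init__(self) -> None:
        if len(self.groups) < 2:
            raise ToxmixError("panel needs >= 2 treatments")

    @classmethod
    def from_frame(cls, endpoint: str, df: pd.DataFrame, unit: str = "") -> "BiomarkerPanel":
        """Build a panel from long-format data.

        Expects columns ``treatment, value`` and optionally
        ``bio_replicate, tech_replicate``; technical replicates are
        averaged within their biological replicate first.
        """
        sub = df[df["endpoint"] == endpoint] if "endpoint" in df else df
        if "bio_replicate" in sub.columns:
            sub = (
                sub.groupby(["treatment", "bio_replicate"], sort=False)["value"]
                .mean()
                .reset_index()
            )
        groups = {
            str(t): g["value"].to_list() for t, g in sub.groupby("treatment", sort=False)
        }
        return cls(endpoint=endpoint, groups=groups, unit=unit)

    def treatment_means(self) -> pd.Series:
        return pd.Series(
            {t: float(np.mean(v)) for t, v in self.groups.items()}, name=self.endpoint
        )


def assumption_checks(panel: BiomarkerPanel, alpha: float = 0.05) -> dict:
    """Shapiro-Wilk per group plus Levene across groups.

    Constant groups are degenerate for normality testing and reported with
    NaN statistics and a flag rather than an error.
    """
    shapiro_rows = []
    for treatment, values in panel.groups.items():
        v = np.asarray(values, float)
        if len(v) < 3:
            raise ToxmixError(
                f"group {treatment!r}: Shapiro-Wilk needs >= 3 values"
            )
        if np.ptp(v) == 0:
            shapiro_rows.append(
                {
                    "treatment": treatment,
                    "statistic": np.nan,
                    "p_value": np.nan,
                    "flag": "degenerate for normality testing",
                }
            )
            continue
        stat, p = stats.shapiro(v)
        shapiro_rows.append(
            {
                "treatment": treatment,
                "statistic": float(stat),
                "p_value": float(p),
                "flag": "non-normal" if p < alpha else "",
            }
        )
    lev_stat, lev_p = stats.levene(*[np.asarray(v, float) for v in panel.groups.values()])
    return {
        "shapiro": pd.DataFrame(shapiro_rows),
        "levene": {
            "statistic": float(lev_stat),
            "p_value": float(lev_p),
            "flag": "heteroscedastic" if lev_p < alpha else "",
        },
    }


def anova_bonferroni(panel: BiomarkerPanel, alpha: float = 0.05) -> dict:
    """One-way ANOVA with Bonferroni-adjusted pairwise t-tests.

    Pairwise comparisons are run only when the omnibus test is significant
    at ``alpha``; raw two-sided p-values are multiplied by the number of
    comparisons and capped at 1.
    """
    groups = {t: np.asarray(v, float) for t, v in panel.groups.items()}
    if any(len(v) < 2 for v in groups.values()):
        raise ToxmixError("each group needs >= 2 replicates")
    values = list(groups.values())
    k = len(values)
    n_total = sum(len(v) for v in values)
    if np.ptp(np.concatenate(values)) == 0:
        f_stat, p = 0.0, 1.0
    else:
        f_stat, p = stats.f_oneway(*values)
        f_stat, p = float(f_stat), float(p)
        if np.isnan(f_stat):  # identical groups give 0/0
            f_stat, p = 0.0, 1.0
    report = {
        "endpoint": panel.endpoint,
        "F": f_stat,
        "df_between": k - 1,
        "df_within": n_total - k,
        "p_value": p,
        "significant": p < alpha,
        "pairwise": None,
    }
    if p < alpha:
        pairs = list(combinations(groups, 2))
        m = len(pairs)
        rows = []
        for t1, t2 in pairs:
            t_stat, raw_p = stats.ttest_ind(groups[t1], groups[t2])
            rows.append(
                {
                    "treatment_1": t1,
                    "treatment_2": t2,
                    "t": float(t_stat),
                    "p_raw": float(raw_p),
                    "p_bonferroni": min(1.0, float(raw_p) * m),
                }
            )
        report["pairwise"] = pd.DataFrame(rows)
    return report


def correlation_matrix(panels: Iterable[BiomarkerPanel]) -> pd.DataFrame:
    """Pearson R between endpoints, paired across treatment-level means.

    Panels are aligned on their shared treatments (>= 3 required per
    pair).  A zero-variance endpoint yields NaN for its off-diagonal
    entries; the diagonal is exactly 1.
    """
    means = pd.DataFrame({p.endpoint: p.treatment_means() for p in panels})
    endpoints = list(means.columns)
    out = pd.DataFrame(np.eye(len(endpoints)), index=endpoints, columns=endpoints)
    for e1, e2 in combinations(endpoints, 2):
        paired = means[[e1, e2]].dropna()
        if len(paired) < 3:
            raise ToxmixError(f"{e1} vs {e2}: need >= 3 aligned treatments")
        x, y = paired[e1].to_numpy(), paired[e2].to_numpy()
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            r = np.nan
        else:
            r = float(stats.pearsonr(x, y).statistic)
        out.loc[e1, e2] = out.loc[e2, e1] = r
    return out
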