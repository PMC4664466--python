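"""Biomarker comparisons between high- and low-risk genotype groups.

For each continuous plasma marker (pg/ml), reports group means with SEM, a
two-sided Welch t-test p on raw levels (Mann-Whitney available), and a
per-level odds ratio defined as exp(beta) from a logistic regression of
group membership (high = 1) on the standardized log-transformed level —
i.e. the odds multiplier per 1 SD of log concentration.  No multiplicity
correction is applied across the panel, but a Bonferroni column is
emitted for transparency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .io_tables import PhenotypeTable
from .risk_profile import RiskAssignment


@dataclass
class BiomarkerComparison:
    name: str
    n_high: int
    n_low: int
    mean_high: float
    sem_high: float
    mean_low: float
    sem_low: float
    p_value: float
    level_or: float
    degenerate: bool = False
    note: str = ""


def _sem(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1) / np.sqrt(x.size)) if x.size > 1 else 0.0


def _level_odds_ratio(high: np.ndarray, low: np.ndarray) -> tuple[float, str]:
    """Per-1-SD-of-log-level odds ratio for being high-risk."""
    levels = np.concatenate([high, low])
    group = np.concatenate([np.ones(high.size), np.zeros(low.size)])
    if (levels <= 0).any():
        return float("nan"), "non-positive level: log OR undefined"
    x = np.log(levels)
    sd = x.std(ddof=1)
    if sd == 0:
        return 1.0, "constant level"
    z = (x - x.mean()) / sd
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(group, sm.add_constant(z)).fit(disp=0, method="newton")
        beta = float(res.params[1])
        if not np.isfinite(beta) or abs(beta) > 15:
            return float("nan"), "separation in level model"
        return float(np.exp(beta)), ""
    except (PerfectSeparationError, np.linalg.LinAlgError):
        return float("nan"), "separation in level model"


def compare_groups(
    high: np.ndarray,
    low: np.ndarray,
    name: str = "",
    test: str = "welch",
) -> BiomarkerComparison:
    """Compare one marker's levels between risk groups.

    Requires >= 2 non-missing values per group.  Degenerate inputs
    (both groups constant) get p = 1 when the constants are equal.
    """
    high = np.asarray(high, dtype=float)
    low = np.asarray(low, dtype=float)
    high = high[~np.isnan(high)]
    low = low[~np.isnan(low)]
    if high.size < 2 or low.size < 2:
        raise ValueError(f"{name or 'marker'}: need >= 2 values per group")

    if np.std(high) == 0 and np.std(low) == 0:
        equal = high[0] == low[0]
        return BiomarkerComparison(
            name=name, n_high=high.size, n_low=low.size,
            mean_high=float(high.mean()), sem_high=0.0,
            mean_low=float(low.mean()), sem_low=0.0,
            p_value=1.0 if equal else 0.0,
            level_or=1.0 if equal else float("nan"),
            degenerate=True, note="constant levels",
        )

    if test == "welch":
        p = float(stats.ttest_ind(high, low, equal_var=False).pvalue)
    elif test == "mannwhitney":
        p = float(stats.mannwhitneyu(high, low, alternative="two-sided").pvalue)
    else:
        raise ValueError(f"unknown test {test!r}")
    level_or, note = _level_odds_ratio(high, low)
    return BiomarkerComparison(
        name=name, n_high=high.size, n_low=low.size,
        mean_high=float(high.mean()), sem_high=_sem(high),
        mean_low=float(low.mean()), sem_low=_sem(low),
        p_value=p, level_or=level_or, note=note,
    )


def biomarker_panel(
    pheno: PhenotypeTable,
    assignments: list[RiskAssignment],
    test: str = "welch",
) -> list[BiomarkerComparison]:
    """One comparison per biomarker column; unusable markers are skipped.

    Samples without a risk assignment or without a measured level drop out
    per marker.  Non-significant comparisons are reported like any other.
    """
    group_by_id = {a.sample_id: a.group for a in assignments}
    out: list[BiomarkerComparison] = []
    for name in pheno.biomarker_names:
        series = pheno.biomarkers[name]
        high, low = [], []
        for sid, value in series.items():
            if np.isnan(value):
                continue
            g = group_by_id.get(sid)
            if g == "high":
                high.append(value)
            elif g == "low":
                low.append(value)
        try:
            out.append(compare_groups(np.array(high), np.array(low), name=name, test=test))
        except ValueError as exc:
            out.append(
                BiomarkerComparison(
                    name=name, n_high=len(high), n_low=len(low),
                    mean_high=float("nan"), sem_high=float("nan"),
                    mean_low=float("nan"), sem_low=float("nan"),
                    p_value=float("nan"), level_or=float("nan"),
                    degenerate=True, note=f"skipped: {exc}",
                )
            )
    return out


def panel_frame(comparisons: list[BiomarkerComparison]) -> pd.DataFrame:
    n_tests = sum(1 for c in comparisons if not np.isnan(c.p_value))
    rows = []
    for c in comparisons:
        bonf = min(1.0, c.p_value * n_tests) if not np.isnan(c.p_value) else np.nan
        rows.append(
            {
                "marker": c.name, "n_high": c.n_high, "n_low": c.n_low,
                "mean_high": c.mean_high, "sem_high": c.sem_high,
                "mean_low": c.mean_low, "sem_low": c.sem_low,
                "p_value": c.p_value, "level_or": c.level_or,
                "bonferroni_p": bonf, "degenerate": int(c.degenerate),
                "note": c.note,
            }
        )
    return pd.DataFrame(rows)
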