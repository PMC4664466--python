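"""Per-sample risk-group assignment from a fitted MDR model and its effect.

Once a k-locus model is selected by cross-validation, the final reported
cell labels are re-derived on the full dataset with T = the full-data
case:control ratio (one grid, one label per cell), every sample with
complete genotypes at the model loci is mapped to its cell's label, and
the high-vs-low group effect on the outcome is quantified by unadjusted
logistic regression (OR, Wald 95% CI, Wald p) and a Pearson chi-square on
the 2x2 group-by-outcome table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .association import Z95, odds_ratio_2x2
from .io_tables import MISSING, GenotypeMatrix
from .mdr import MdrModel, classify_cells


@dataclass
class RiskAssignment:
    sample_id: str
    group: str  # "high" or "low"
    cell: str   # e.g. "AG/CC"


@dataclass
class GroupEffect:
    or_point: float
    or_ci: tuple[float, float]
    wald_p: float
    chisq_p: float
    table: np.ndarray  # rows: high/low, cols: case/control


def _cell_key(gm: GenotypeMatrix, loci_idx: list[int], cell_codes: tuple[int, ...]) -> tuple[str, ...]:
    return tuple(
        gm.snps[j].call_str(c) for j, c in zip(loci_idx, cell_codes)
    )


def fit_full_model(
    gm: GenotypeMatrix,
    outcome: np.ndarray,
    loci: tuple[str, ...],
    t: float | None = None,
) -> MdrModel:
    """Label every genotype cell on the full dataset for the given loci."""
    loci_idx = [gm.snp_index(s) for s in loci]
    codes = gm.codes[:, loci_idx]
    high, case_counts, ctrl_counts, t_used = classify_cells(codes, outcome, t)
    k = len(loci)
    labels: dict[tuple[str, ...], str] = {}
    for flat, is_high in enumerate(high):
        cell_codes = tuple(
            (flat // 3 ** (k - 1 - d)) % 3 for d in range(k)
        )
        labels[_cell_key(gm, loci_idx, cell_codes)] = "high" if is_high else "low"
    return MdrModel(
        loci=tuple(loci), cell_labels=labels, threshold_t=t_used,
        case_counts=case_counts, control_counts=ctrl_counts,
    )


def assign_risk(
    gm: GenotypeMatrix, model: MdrModel
) -> tuple[list[RiskAssignment], list[str]]:
    """Map each complete-genotype sample to its cell's risk label.

    Returns (assignments, skipped sample ids); samples missing a genotype
    at any model locus are skipped.
    """
    loci_idx = [gm.snp_index(s) for s in model.loci]
    assignments: list[RiskAssignment] = []
    skipped: list[str] = []
    for i, sid in enumerate(gm.sample_ids):
        codes = [int(gm.codes[i, j]) for j in loci_idx]
        if MISSING in codes:
            skipped.append(sid)
            continue
        key = _cell_key(gm, loci_idx, tuple(codes))
        label = model.cell_labels.get(key, "low")  # unlabelled cell -> low risk
        assignments.append(RiskAssignment(sample_id=sid, group=label, cell="/".join(key)))
    return assignments, skipped


def group_indicator(
    assignments: list[RiskAssignment], sample_ids: list[str]
) -> np.ndarray:
    """1 = high, 0 = low, NaN = unassigned, aligned to ``sample_ids``."""
    by_id = {a.sample_id: (1.0 if a.group == "high" else 0.0) for a in assignments}
    return np.array([by_id.get(s, np.nan) for s in sample_ids])


def group_effect(group: np.ndarray, outcome: np.ndarray) -> GroupEffect:
    """High-vs-low risk-group effect on a binary outcome.

    ``group``: 1 = high risk, 0 = low risk (NaN entries dropped).  Zero
    cells fall back to a Haldane-corrected OR and Fisher's exact p.
    """
    group = np.asarray(group, dtype=float)
    outcome = np.asarray(outcome, dtype=float)
    mask = ~np.isnan(group) & ~np.isnan(outcome)
    g, y = group[mask], outcome[mask]
    if not (g == 1).any() or not (g == 0).any():
        raise ValueError("both risk groups must be non-empty")
    a = float(((g == 1) & (y == 1)).sum())  # high-risk cases
    b = float(((g == 1) & (y == 0)).sum())
    c = float(((g == 0) & (y == 1)).sum())
    d = float(((g == 0) & (y == 0)).sum())
    table = np.array([[a, b], [c, d]])

    zero_cell = 0.0 in (a, b, c, d)
    if not zero_cell:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.Logit(y, sm.add_constant(g)).fit(disp=0, method="newton")
            beta, se = float(res.params[1]), float(res.bse[1])
            or_point = float(np.exp(beta))
            ci = (float(np.exp(beta - Z95 * se)), float(np.exp(beta + Z95 * se)))
            wald_p = float(2 * stats.norm.sf(abs(beta / se)))
        except (PerfectSeparationError, np.linalg.LinAlgError):
            zero_cell = True
        else:
            chisq_p = float(stats.chi2_contingency(table, correction=False).pvalue)
            return GroupEffect(or_point, ci, wald_p, chisq_p, table)

    or_point, ci = odds_ratio_2x2(a, b, c, d)
    cells = np.array([a, b, c, d]) + 0.5
    se = float(np.sqrt((1 / cells).sum()))
    wald_p = float(2 * stats.norm.sf(abs(np.log(or_point) / se)))
    chisq_p = float(stats.fisher_exact(table)[1])
    return GroupEffect(or_point, ci, wald_p, chisq_p, table)


def risk_grid_frame(
    gm: GenotypeMatrix, outcome: np.ndarray, model: MdrModel
) -> pd.DataFrame:
    """Per-cell case/control counts and label (the figure-style grid)."""
    loci_idx = [gm.snp_index(s) for s in model.loci]
    k = len(loci_idx)
    rows = []
    for flat in range(3**k):
        cell_codes = tuple((flat // 3 ** (k - 1 - d)) % 3 for d in range(k))
        key = _cell_key(gm, loci_idx, cell_codes)
        rows.append(
            {
                "cell": "/".join(key),
                "cases": int(model.case_counts[flat]),
                "controls": int(model.control_counts[flat]),
                "label": model.cell_labels[key],
            }
        )
    return pd.DataFrame(rows)


def high_risk_case_share(assignments: list[RiskAssignment], outcome_by_id: dict[str, int]) -> float:
    """Fraction of all cases that fall in high-risk cells (full data)."""
    cases = [a for a in assignments if outcome_by_id.get(a.sample_id) == 1]
    if not cases:
        return float("nan")
    return sum(a.group == "high" for a in cases) / len(cases)
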