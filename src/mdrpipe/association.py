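"""Single-locus association: univariate screen and best-genetic-model fits.

The univariate stage (UVA) tests each SNP with a genotypic 2x3 Pearson
chi-square (df = 2, no continuity correction); an allelic 2x2 variant is
available.  The multivariate stage (MVA) fits a logistic regression of the
outcome on each of four genotype encodings

* dominant      — carries >= 1 reference allele vs. none
* co-dominant   — heterozygote vs. both homozygotes pooled
* recessive     — homozygous for the reference allele vs. the rest
* additive      — reference-allele count (0/1/2), per-allele odds ratio

and reports the encoding with the smallest Wald p as the best-fitting
genetic model, with OR = exp(beta) and a Wald 95% CI.  The reference
allele defaults to the minor allele.  No multiplicity correction is
applied at this stage; downstream permutation testing addresses it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .io_tables import MISSING, GenotypeMatrix, SnpMeta

MODEL_NAMES = ("dominant", "co_dominant", "recessive", "additive")

Z95 = float(stats.norm.ppf(0.975))


@dataclass(frozen=True)
class GeneticModel:
    name: str
    reference_allele: str

    def __post_init__(self) -> None:
        if self.name not in MODEL_NAMES:
            raise ValueError(f"unknown genetic model {self.name!r}")


@dataclass
class AssociationResult:
    snp_id: str
    gene: str
    model: GeneticModel | None
    p_value: float
    or_point: float | None = None
    or_ci: tuple[float, float] | None = None
    stage: str = "mva"
    significant: bool = False
    degenerate: bool = False
    note: str = ""


def encode(model: GeneticModel, codes: np.ndarray, meta: SnpMeta) -> np.ndarray:
    """Numeric encoding of genotype codes under a genetic model.

    ``codes`` counts copies of ``meta.allele_b``; missing entries come back
    as NaN (those samples are dropped from the fit for this SNP).
    """
    if model.reference_allele == meta.allele_b:
        ref_count = codes.astype(float)
    elif model.reference_allele == meta.allele_a:
        ref_count = 2.0 - codes
    else:
        raise ValueError(
            f"reference allele {model.reference_allele!r} is not one of "
            f"{meta.allele_a}/{meta.allele_b} for {meta.snp_id}"
        )
    ref_count = np.where(codes == MISSING, np.nan, ref_count)
    if model.name == "dominant":
        out = (ref_count >= 1).astype(float)
    elif model.name == "co_dominant":
        out = (ref_count == 1).astype(float)
    elif model.name == "recessive":
        out = (ref_count == 2).astype(float)
    else:  # additive
        out = ref_count
    return np.where(np.isnan(ref_count), np.nan, out)


def model_label(model: GeneticModel, meta: SnpMeta) -> str:
    """Human-readable rendering, e.g. ``Recessive (TT vs. TC/CC)``."""
    r = model.reference_allele
    o = meta.allele_a if r == meta.allele_b else meta.allele_b
    if model.name == "dominant":
        return f"Dominant ({r}{r}/{''.join(sorted(r + o))} vs. {o}{o})"
    if model.name == "co_dominant":
        pair = "".join(sorted(r + o))
        return f"Co-dominant ({pair} vs. {r}{r}/{o}{o})"
    if model.name == "recessive":
        return f"Recessive ({r}{r} vs. {''.join(sorted(r + o))}/{o}{o})"
    return f"Additive (number of {r} alleles)"


def minor_allele(codes: np.ndarray, meta: SnpMeta) -> str:
    """Minor allele from the observed calls (ties resolve to allele_a)."""
    valid = codes[codes != MISSING]
    if valid.size == 0:
        return meta.allele_a
    f_b = valid.mean() / 2.0
    return meta.allele_b if f_b < 0.5 else meta.allele_a


def odds_ratio_2x2(a: float, b: float, c: float, d: float) -> tuple[float, tuple[float, float]]:
    """Cross-product odds ratio with Wald 95% CI.

    Layout: a = exposed cases, b = exposed controls, c = unexposed cases,
    d = unexposed controls.  The Haldane +0.5 correction is applied to all
    cells iff any cell is zero.  A zero row or column total leaves the OR
    undefined and raises.
    """
    cells = np.array([a, b, c, d], dtype=float)
    if (cells < 0).any():
        raise ValueError("counts must be non-negative")
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        raise ValueError("odds ratio undefined: a zero row or column total")
    if (cells == 0).any():
        cells = cells + 0.5
    a, b, c, d = cells
    or_point = (a * d) / (b * c)
    se = float(np.sqrt(1 / a + 1 / b + 1 / c + 1 / d))
    lo, hi = np.exp(np.log(or_point) + np.array([-Z95, Z95]) * se)
    return float(or_point), (float(lo), float(hi))


def uva_screen(
    gm: GenotypeMatrix,
    outcome: np.ndarray,
    alpha: float = 0.10,
    test: str = "genotypic",
) -> list[AssociationResult]:
    """Per-SNP case-control screen; all results returned, p < alpha flagged.

    ``genotypic``: Pearson chi-square on the 2x3 outcome-by-genotype table
    (empty genotype columns dropped).  ``allelic``: chi-square on the 2x2
    outcome-by-allele-count table.
    """
    outcome = np.asarray(outcome)
    if outcome.shape[0] != gm.n_samples:
        raise ValueError("outcome vector is not aligned to the genotype matrix")
    results = []
    for j, meta in enumerate(gm.snps):
        col = gm.codes[:, j]
        valid = col != MISSING
        y = outcome[valid]
        g = col[valid]
        if test == "genotypic":
            table = np.array(
                [np.bincount(g[y == 1], minlength=3), np.bincount(g[y == 0], minlength=3)]
            )
            table = table[:, table.sum(axis=0) > 0]
        elif test == "allelic":
            case_b = int(g[y == 1].sum())
            ctrl_b = int(g[y == 0].sum())
            table = np.array(
                [[2 * int((y == 1).sum()) - case_b, case_b],
                 [2 * int((y == 0).sum()) - ctrl_b, ctrl_b]]
            )
            table = table[:, table.sum(axis=0) > 0]
        else:
            raise ValueError(f"unknown uva test {test!r}")

        degenerate = table.shape[1] < 2 or (table.sum(axis=1) == 0).any()
        if degenerate:
            p = 1.0
        else:
            p = float(stats.chi2_contingency(table, correction=False).pvalue)
        results.append(
            AssociationResult(
                snp_id=meta.snp_id, gene=meta.gene, model=None, p_value=p,
                stage="uva", significant=(not degenerate and p < alpha),
                degenerate=degenerate,
                note="single genotype class" if degenerate else "",
            )
        )
    return results


def _fit_logistic(y: np.ndarray, x: np.ndarray) -> tuple[float, float] | None:
    """Slope and its SE from a one-covariate logistic fit; None on failure."""
    X = sm.add_constant(x)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit(disp=0, method="newton", maxiter=100)
    except (PerfectSeparationError, np.linalg.LinAlgError, ValueError):
        return None
    beta = float(res.params[1])
    se = float(res.bse[1])
    if not np.isfinite(beta) or not np.isfinite(se) or abs(beta) > 15 or se > 50:
        return None  # effectively separated / unstable
    return beta, se


def _haldane_fallback(
    y: np.ndarray, x: np.ndarray
) -> tuple[float, float, tuple[float, float]] | None:
    """Wald p / OR / CI from the Haldane-corrected 2x2 collapse of a binary coding."""
    a = float(((x == 1) & (y == 1)).sum())
    b = float(((x == 1) & (y == 0)).sum())
    c = float(((x == 0) & (y == 1)).sum())
    d = float(((x == 0) & (y == 0)).sum())
    try:
        or_point, ci = odds_ratio_2x2(a, b, c, d)
    except ValueError:
        return None
    cells = np.array([a, b, c, d]) + (0.5 if 0 in (a, b, c, d) else 0.0)
    se = float(np.sqrt((1 / cells).sum()))
    z = np.log(or_point) / se
    p = float(2 * stats.norm.sf(abs(z)))
    return p, or_point, ci


def mva_best_model(
    gm: GenotypeMatrix,
    outcome: np.ndarray,
    alpha: float = 0.05,
    reference: str = "minor",
) -> list[AssociationResult]:
    """Best-fitting genetic model per SNP (smallest Wald p of four fits)."""
    outcome = np.asarray(outcome)
    if outcome.shape[0] != gm.n_samples:
        raise ValueError("outcome vector is not aligned to the genotype matrix")
    results = []
    for j, meta in enumerate(gm.snps):
        col = gm.codes[:, j]
        ref = minor_allele(col, meta) if reference == "minor" else reference
        best: tuple[float, GeneticModel, float, tuple[float, float], str] | None = None
        for name in MODEL_NAMES:
            model = GeneticModel(name, ref)
            x_full = encode(model, col, meta)
            mask = ~np.isnan(x_full) & np.isin(outcome, [0, 1])
            x, y = x_full[mask], outcome[mask]
            if x.size == 0 or np.all(x == x[0]):
                continue  # encoding constant: nothing to fit
            fit = _fit_logistic(y.astype(float), x)
            note = ""
            if fit is not None:
                beta, se = fit
                p = float(2 * stats.norm.sf(abs(beta / se)))
                or_point = float(np.exp(beta))
                ci = (float(np.exp(beta - Z95 * se)), float(np.exp(beta + Z95 * se)))
            elif name != "additive":
                fb = _haldane_fallback(y, x)
                if fb is None:
                    continue
                p, or_point, ci = fb
                note = "separation: Haldane-corrected 2x2"
            else:
                continue
            if best is None or p < best[0]:
                best = (p, model, or_point, ci, note)
        if best is None:
            results.append(
                AssociationResult(
                    snp_id=meta.snp_id, gene=meta.gene, model=None, p_value=1.0,
                    stage="mva", degenerate=True, note="no fittable encoding",
                )
            )
            continue
        p, model, or_point, ci, note = best
        results.append(
            AssociationResult(
                snp_id=meta.snp_id, gene=meta.gene, model=model, p_value=p,
                or_point=or_point, or_ci=ci, stage="mva",
                significant=p <= alpha, note=note,
            )
        )
    return results


def association_frame(results: list[AssociationResult], gm: GenotypeMatrix) -> pd.DataFrame:
    """Results table mirroring the classic per-SNP report layout."""
    meta_by_id = {m.snp_id: m for m in gm.snps}
    rows = []
    for r in results:
        label = model_label(r.model, meta_by_id[r.snp_id]) if r.model else "."
        rows.append(
            {
                "gene": r.gene,
                "snp_id": r.snp_id,
                "model": label,
                "p_value": r.p_value,
                "or": r.or_point if r.or_point is not None else np.nan,
                "ci_low": r.or_ci[0] if r.or_ci else np.nan,
                "ci_high": r.or_ci[1] if r.or_ci else np.nan,
                "stage": r.stage,
                "significant": int(r.significant),
                "degenerate": int(r.degenerate),
            }
        )
    return pd.DataFrame(rows)
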