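"""SNP-level quality control: call-rate and Hardy-Weinberg filters.

The exclusion stage mirrors standard candidate-gene practice: a SNP is
dropped when its call rate is strictly below ``call_rate_min`` (default
0.90) or its Hardy-Weinberg exact p-value is at or below ``hwe_alpha``
(default 0.001), with HWE evaluated in the control stratum when a
phenotype is available.  The HWE test is the exact conditional test on
heterozygote counts (Wigginton/Cutler/Abecasis recurrence); a chi-square
variant is available for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .io_tables import MISSING, GenotypeMatrix


@dataclass
class SnpQcRecord:
    snp_id: str
    call_rate: float
    maf: float
    hwe_p: float
    excluded: bool
    reason: str  # {"call_rate", "hwe", "none"}


def call_rate(gm: GenotypeMatrix, snp_id: str) -> float:
    """Fraction of samples with a non-missing call at ``snp_id``."""
    j = gm.snp_index(snp_id)
    return float((gm.codes[:, j] != MISSING).mean())


def genotype_counts(codes: np.ndarray) -> tuple[int, int, int]:
    """(n_aa, n_ab, n_bb) among non-missing codes."""
    valid = codes[codes != MISSING]
    return (int((valid == 0).sum()), int((valid == 1).sum()), int((valid == 2).sum()))


def minor_allele_freq(codes: np.ndarray) -> float:
    """MAF from non-missing calls only; NaN when no calls."""
    valid = codes[codes != MISSING]
    if valid.size == 0:
        return float("nan")
    f_b = float(valid.mean()) / 2.0
    return min(f_b, 1.0 - f_b)


def hwe_exact_p(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Two-sided exact Hardy-Weinberg p-value.

    Conditional on the observed allele counts, sums the probabilities of
    every heterozygote configuration no more probable than the observed one.
    Probabilities follow the hypergeometric-type distribution

        P(n_ab | n, n_rare) ∝ n! / (n_aa! n_ab! n_bb!) * 2^n_ab,

    computed by the standard mid-outward recurrence.  Returns a value in
    (0, 1]; a monomorphic SNP has a single attainable configuration, p = 1.
    """
    if min(n_aa, n_ab, n_bb) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_aa + n_ab + n_bb
    if n == 0:
        raise ValueError("all genotype counts are zero")

    rare = 2 * min(n_aa, n_bb) + n_ab  # copies of the rarer allele
    if rare == 0:
        return 1.0

    # heterozygote counts share the parity of the rare-allele count
    n_het_possible = rare // 2 + 1
    probs = np.zeros(n_het_possible)

    # start at the distribution mode and recurse outward
    mid = int(rare * (2 * n - rare) / (2.0 * n))
    if mid % 2 != rare % 2:
        mid += 1
    probs[mid // 2] = 1.0

    def homs(het: int) -> tuple[float, float]:
        rare_hom = (rare - het) / 2.0
        return rare_hom, n - het - rare_hom

    h = mid
    while h >= 2:
        rare_hom, common_hom = homs(h)
        probs[(h - 2) // 2] = (
            probs[h // 2] * h * (h - 1.0) / (4.0 * (rare_hom + 1.0) * (common_hom + 1.0))
        )
        h -= 2
    h = mid
    while h <= rare - 2:
        rare_hom, common_hom = homs(h)
        probs[(h + 2) // 2] = (
            probs[h // 2] * 4.0 * rare_hom * common_hom / ((h + 2.0) * (h + 1.0))
        )
        h += 2

    probs /= probs.sum()
    p_obs = probs[n_ab // 2]
    p = float(probs[probs <= p_obs * (1.0 + 1e-10)].sum())
    return min(p, 1.0)


def hwe_chisq_p(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Chi-square (df=1) Hardy-Weinberg p-value; sensitivity-analysis option."""
    n = n_aa + n_ab + n_bb
    if n == 0:
        raise ValueError("all genotype counts are zero")
    p_a = (2 * n_aa + n_ab) / (2.0 * n)
    q = 1.0 - p_a
    exp = np.array([n * p_a**2, 2 * n * p_a * q, n * q**2])
    obs = np.array([n_aa, n_ab, n_bb], dtype=float)
    if (exp == 0).any():
        return 1.0
    x2 = float(((obs - exp) ** 2 / exp).sum())
    return float(stats.chi2.sf(x2, df=1))


def filter_snps(
    gm: GenotypeMatrix,
    status: np.ndarray | None = None,
    call_rate_min: float = 0.90,
    hwe_alpha: float = 0.001,
    method: str = "exact",
) -> tuple[GenotypeMatrix, list[SnpQcRecord]]:
    """Apply the call-rate and HWE exclusion filters.

    ``status`` (1 = case, 0 = control), when given, restricts the HWE test
    to controls; call rate and MAF always use all samples.  A SNP is kept
    iff call_rate >= call_rate_min and hwe_p > hwe_alpha (boundary
    conventions: strict "<" excludes on call rate, "<=" excludes on HWE).
    """
    if gm.n_snps == 0:
        raise ValueError("empty genotype matrix")
    hwe_fn = hwe_exact_p if method == "exact" else hwe_chisq_p
    if status is not None:
        status = np.asarray(status)
        hwe_rows = status == 0
    else:
        hwe_rows = np.ones(gm.n_samples, dtype=bool)

    records: list[SnpQcRecord] = []
    keep: list[int] = []
    for j, meta in enumerate(gm.snps):
        col = gm.codes[:, j]
        cr = float((col != MISSING).mean())
        maf = minor_allele_freq(col)
        counts = genotype_counts(col[hwe_rows])
        hwe_p = hwe_fn(*counts) if sum(counts) > 0 else 1.0
        if cr < call_rate_min:
            excluded, reason = True, "call_rate"
        elif hwe_p <= hwe_alpha:
            excluded, reason = True, "hwe"
        else:
            excluded, reason = False, "none"
            keep.append(j)
        records.append(SnpQcRecord(meta.snp_id, cr, maf, hwe_p, excluded, reason))
    return gm.subset_snps(keep), records


def maf_prefilter(gm: GenotypeMatrix, min_maf: float = 0.05) -> GenotypeMatrix:
    """Drop SNPs with MAF below ``min_maf`` (assay-design-stage pre-filter)."""
    keep = [
        j for j in range(gm.n_snps)
        if not (minor_allele_freq(gm.codes[:, j]) < min_maf)
    ]
    return gm.subset_snps(keep)


def qc_report_frame(records: list[SnpQcRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "snp_id": [r.snp_id for r in records],
            "call_rate": [r.call_rate for r in records],
            "maf": [r.maf for r in records],
            "hwe_p": [r.hwe_p for r in records],
            "excluded": [int(r.excluded) for r in records],
            "reason": [r.reason for r in records],
        }
    )


def write_qc_report(records: list[SnpQcRecord], path: str | Path) -> None:
    qc_report_frame(records).to_csv(path, sep="\t", index=False, float_format="%.6g")
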