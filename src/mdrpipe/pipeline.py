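"""End-to-end orchestration: QC -> UVA -> MVA -> MDR -> risk groups -> biomarkers.

``run_pipeline`` executes the stated analysis sequence on one outcome
(case/control over all samples, or a binary sub-phenotype within cases),
writes every stage table as TSV plus a plain-text summary, and is
deterministic for a given (inputs, config, seed): report files contain no
timestamps, so identical runs are byte-identical.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import association, biomarkers as biomarkers_mod, mdr, qc, risk_profile
from ._report import format_ba_percent, format_cvc, percent
from .io_tables import (
    GenotypeMatrix,
    PhenotypeTable,
    read_genotypes,
    read_phenotypes,
)


@dataclass
class PipelineConfig:
    genotypes: str | Path | GenotypeMatrix = None  # type: ignore[assignment]
    phenotypes: str | Path | PhenotypeTable = None  # type: ignore[assignment]
    out_dir: str | Path = "mdrpipe_out"
    outcome: str = "status"  # "status" or "cal" (within cases)
    dialect: str = "tsv"
    call_rate_min: float = 0.90
    hwe_alpha: float = 0.001
    uva_alpha: float = 0.10
    mva_alpha: float = 0.05
    ks: tuple[int, ...] = (1, 2, 3)
    n_folds: int = 20
    n_perm: int = 10000
    perm_alpha: float = 0.05
    seed: int = 0
    mdr_panel_size: int | None = None  # cap the MDR pool to the top-m UVA SNPs
    biomarker_test: str = "welch"

    def __post_init__(self) -> None:
        for name in ("call_rate_min", "hwe_alpha", "uva_alpha", "mva_alpha", "perm_alpha"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")


@dataclass
class RunReport:
    out_dir: Path
    cohort: dict
    qc: pd.DataFrame
    uva: pd.DataFrame
    mva: pd.DataFrame
    mdr_report: pd.DataFrame
    mdr_search: mdr.MdrSearchReport | None
    risk_grid: pd.DataFrame | None
    risk_groups: pd.DataFrame | None
    biomarker_panel: pd.DataFrame | None
    paths: dict = field(default_factory=dict)


def summarize_cohort(pheno: PhenotypeTable) -> dict:
    """Per-stratum counts and printed-style percentages."""
    out = {
        "n_total": len(pheno.sample_ids),
        "n_cases": pheno.n_cases,
        "n_controls": pheno.n_controls,
        "case_percent": percent(pheno.n_cases, len(pheno.sample_ids)),
    }
    has_cal = ~np.isnan(pheno.cal)
    if has_cal.any():
        n_cal = int(np.nansum(pheno.cal))
        out["n_cal"] = n_cal
        out["cal_percent_of_cases"] = percent(n_cal, pheno.n_cases)
    for name in pheno.biomarker_names:
        out[f"n_{name}"] = int(pheno.biomarkers[name].notna().sum())
    return out


def _load(config: PipelineConfig) -> tuple[GenotypeMatrix, PhenotypeTable]:
    gm = config.genotypes
    if not isinstance(gm, GenotypeMatrix):
        gm = read_genotypes(gm, dialect=config.dialect)
    pheno = config.phenotypes
    if not isinstance(pheno, PhenotypeTable):
        pheno = read_phenotypes(pheno)
    return gm, pheno


def _select_outcome(
    gm: GenotypeMatrix, pheno: PhenotypeTable, outcome: str
) -> tuple[GenotypeMatrix, PhenotypeTable, np.ndarray]:
    """Restrict to samples where the outcome is defined and return its vector."""
    if outcome == "status":
        return gm, pheno, pheno.aligned_status(gm)
    if outcome == "cal":
        defined = {
            s for s, c in zip(pheno.sample_ids, pheno.cal) if not np.isnan(c)
        }
        keep = [i for i, s in enumerate(gm.sample_ids) if s in defined]
        gm2 = gm.subset_samples(keep)
        cal_by_id = dict(zip(pheno.sample_ids, pheno.cal))
        y = np.array([int(cal_by_id[s]) for s in gm2.sample_ids])
        return gm2, pheno, y
    raise ValueError(f"unknown outcome {outcome!r} (use 'status' or 'cal')")


def _mdr_pool(
    uva_results: list[association.AssociationResult],
    gm: GenotypeMatrix,
    panel_size: int | None,
) -> list[str] | None:
    if panel_size is None or panel_size >= gm.n_snps:
        return None  # all QC-passed SNPs
    ranked = sorted(uva_results, key=lambda r: (r.p_value, r.snp_id))
    return sorted(r.snp_id for r in ranked[:panel_size])


def _log(msg: str) -> None:
    print(f"[mdrpipe] {msg}", file=sys.stderr)


def run_pipeline(config: PipelineConfig) -> RunReport:
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    gm_all, pheno = _load(config)
    cohort = summarize_cohort(pheno)
    _log(f"loaded {gm_all.n_samples} samples x {gm_all.n_snps} SNPs; cohort {cohort}")

    gm_out, pheno, y = _select_outcome(gm_all, pheno, config.outcome)
    _log(f"outcome '{config.outcome}': {int(y.sum())} cases vs {int((y == 0).sum())} controls")

    # --- QC ------------------------------------------------------------
    gm_kept, records = qc.filter_snps(
        gm_out, status=y,
        call_rate_min=config.call_rate_min, hwe_alpha=config.hwe_alpha,
    )
    qc_df = qc.qc_report_frame(records)
    paths["qc"] = out_dir / "qc_report.tsv"
    qc_df.to_csv(paths["qc"], sep="\t", index=False, float_format="%.6g")
    n_excluded = int(qc_df["excluded"].sum())
    _log(f"QC: {gm_kept.n_snps} SNPs kept, {n_excluded} excluded")

    # --- single-locus association --------------------------------------
    uva_results = association.uva_screen(gm_kept, y, alpha=config.uva_alpha)
    uva_df = association.association_frame(uva_results, gm_kept)
    paths["uva"] = out_dir / "uva.tsv"
    uva_df.to_csv(paths["uva"], sep="\t", index=False, float_format="%.6g")

    mva_results = association.mva_best_model(gm_kept, y, alpha=config.mva_alpha)
    mva_df = association.association_frame(mva_results, gm_kept)
    paths["mva"] = out_dir / "mva.tsv"
    mva_df.to_csv(paths["mva"], sep="\t", index=False, float_format="%.6g")
    _log(
        f"UVA: {int(uva_df['significant'].sum())} SNPs at p < {config.uva_alpha}; "
        f"MVA: {int(mva_df['significant'].sum())} SNPs at p <= {config.mva_alpha}"
    )

    # --- MDR -----------------------------------------------------------
    pool = _mdr_pool(uva_results, gm_kept, config.mdr_panel_size)
    ks = tuple(k for k in config.ks if k <= (len(pool) if pool else gm_kept.n_snps))
    search = mdr.run_mdr(
        gm_kept, y, ks=ks, n_folds=config.n_folds, n_perm=config.n_perm,
        seed=config.seed, alpha=config.perm_alpha, snp_ids=pool,
    )
    gene_by_id = {m.snp_id: m.gene for m in gm_kept.snps}
    mdr_rows = []
    for k in ks:
        r = search.results[k]
        mdr_rows.append(
            {
                "k": k,
                "model": ", ".join(f"{gene_by_id[s]} ({s})" for s in r.loci),
                "avg_testing_ba": format_ba_percent(r.avg_testing_ba),
                "cvc": format_cvc(r.cvc, r.n_folds),
                "perm_p": r.perm_p,
                "significant": int(search.significant[k]),
            }
        )
    mdr_df = pd.DataFrame(mdr_rows)
    paths["mdr"] = out_dir / "mdr_report.tsv"
    mdr_df.to_csv(paths["mdr"], sep="\t", index=False, float_format="%.6g")
    _log(f"MDR: {mdr_df.to_dict('records')}")

    # --- risk profile + biomarkers (only for a significant model) ------
    risk_grid_df = risk_groups_df = panel_df = None
    sig_ks = [k for k in ks if search.significant[k]]
    if sig_ks:
        best_k = min(sig_ks, key=lambda k: (search.results[k].perm_p, -search.results[k].avg_testing_ba))
        best = search.results[best_k]
        model = risk_profile.fit_full_model(gm_kept, y, best.loci)
        assignments, skipped = risk_profile.assign_risk(gm_kept, model)
        group = risk_profile.group_indicator(assignments, gm_kept.sample_ids)
        effect = risk_profile.group_effect(group, y)
        risk_grid_df = risk_profile.risk_grid_frame(gm_kept, y, model)
        paths["risk_grid"] = out_dir / "risk_grid.tsv"
        risk_grid_df.to_csv(paths["risk_grid"], sep="\t", index=False)

        outcome_by_id = dict(zip(gm_kept.sample_ids, (int(v) for v in y)))
        share = risk_profile.high_risk_case_share(assignments, outcome_by_id)
        n_high = sum(a.group == "high" for a in assignments)
        n_low = len(assignments) - n_high
        risk_groups_df = pd.DataFrame(
            [
                {
                    "loci": ", ".join(best.loci),
                    "n_high": n_high,
                    "n_low": n_low,
                    "n_unassigned": len(skipped),
                    "or": effect.or_point,
                    "ci_low": effect.or_ci[0],
                    "ci_high": effect.or_ci[1],
                    "wald_p": effect.wald_p,
                    "chisq_p": effect.chisq_p,
                    "high_risk_case_percent": percent(share * 100, 100),
                }
            ]
        )
        paths["risk_groups"] = out_dir / "risk_groups.tsv"
        risk_groups_df.to_csv(paths["risk_groups"], sep="\t", index=False, float_format="%.6g")
        _log(
            f"risk groups (k={best_k}): OR={effect.or_point:.3g}, "
            f"chi-square p={effect.chisq_p:.3g}"
        )

        if pheno.biomarker_names:
            comparisons = biomarkers_mod.biomarker_panel(
                pheno, assignments, test=config.biomarker_test
            )
            panel_df = biomarkers_mod.panel_frame(comparisons)
            paths["biomarkers"] = out_dir / "biomarker_panel.tsv"
            panel_df.to_csv(paths["biomarkers"], sep="\t", index=False, float_format="%.6g")
    else:
        _log("no MDR model significant after permutation testing; risk stage skipped")

    # --- plain-text summary -------------------------------------------
    paths["summary"] = out_dir / "summary.txt"
    with open(paths["summary"], "w") as fh:
        fh.write("mdrpipe run summary\n===================\n")
        fh.write(f"outcome: {config.outcome}\nseed: {config.seed}\n")
        fh.write(
            "thresholds: call_rate_min=%g hwe_alpha=%g uva_alpha=%g mva_alpha=%g "
            "n_folds=%d n_perm=%d perm_alpha=%g\n"
            % (
                config.call_rate_min, config.hwe_alpha, config.uva_alpha,
                config.mva_alpha, config.n_folds, config.n_perm, config.perm_alpha,
            )
        )
        for key, value in cohort.items():
            fh.write(f"cohort.{key}: {value}\n")
        fh.write(f"snps_input: {gm_out.n_snps}\n")
        fh.write(f"snps_excluded: {n_excluded}\n")
        fh.write(f"snps_retained: {gm_kept.n_snps}\n")
        fh.write(f"uva_significant: {int(uva_df['significant'].sum())}\n")
        fh.write(f"mva_significant: {int(mva_df['significant'].sum())}\n")
        for row in mdr_rows:
            fh.write(
                "mdr k=%d: %s | testing BA %s | CVC %s | perm p %.4g | %s\n"
                % (
                    row["k"], row["model"], row["avg_testing_ba"], row["cvc"],
                    row["perm_p"], "significant" if row["significant"] else "ns",
                )
            )
        if risk_groups_df is not None:
            r = risk_groups_df.iloc[0]
            fh.write(
                f"risk groups: {int(r['n_high'])} high / {int(r['n_low'])} low, "
                f"OR {r['or']:.3g} (95% CI {r['ci_low']:.3g}-{r['ci_high']:.3g}), "
                f"chi-square p {r['chisq_p']:.3g}\n"
            )

    return RunReport(
        out_dir=out_dir, cohort=cohort, qc=qc_df, uva=uva_df, mva=mva_df,
        mdr_report=mdr_df, mdr_search=search, risk_grid=risk_grid_df,
        risk_groups=risk_groups_df, biomarker_panel=panel_df, paths=paths,
    )
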