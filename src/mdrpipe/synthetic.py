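"""Synthetic genotype/phenotype/biomarker generator.

Emulates the statistical structure of a candidate-gene case-control SNP
panel: a few hundred biallelic SNPs with MAF >= 5% drawn under
Hardy-Weinberg proportions, a retrospective case-control design with
fixed margins (cases and controls accrued by rejection sampling until the
requested counts are hit exactly), completely-at-random missingness,
deliberate QC failures (low-call-rate SNPs and heterozygote-deficit HWE
violators), planted single-locus marginal effects under any genetic
model, planted two-locus penetrance (epistatic) effects with weak
marginals, and lognormal biomarkers shifted by true risk-cell membership.

Defaults mirror the emulated study design: 226 cases vs 575 controls,
384 SNPs, MAF in [0.05, 0.5].
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.special import expit, logit

from .io_tables import (
    CATEGORIES,
    MISSING,
    GenotypeMatrix,
    PhenotypeTable,
    SnpMeta,
    write_genotypes,
    write_phenotypes,
)

import pandas as pd


@dataclass
class PenetranceModel:
    """Ground-truth case probabilities over a k-locus genotype table.

    ``table`` has shape (3,)*k indexed by genotype codes (minor-allele
    counts); ``baseline`` is the case probability used for samples when no
    penetrance model is planted.
    """

    loci: tuple[int, ...]
    table: np.ndarray
    baseline: float = 0.22

    def __post_init__(self) -> None:
        self.table = np.asarray(self.table, dtype=float)
        k = len(self.loci)
        if self.table.shape != (3,) * k:
            raise ValueError(f"table must have shape {(3,) * k}")
        if ((self.table < 0) | (self.table > 1)).any() or not 0 <= self.baseline <= 1:
            raise ValueError("probabilities must lie in [0, 1]")

    @classmethod
    def xor_two_locus(
        cls,
        loci: tuple[int, int],
        p_high: float = 0.45,
        p_low: float = 0.22,
    ) -> "PenetranceModel":
        """Heterozygosity-XOR epistasis: elevated penetrance iff exactly one
        of the two loci is heterozygous.  At intermediate MAFs P(het) is
        close to 1/2, so single-locus marginal effects are near null while
        the joint effect is strong."""
        table = np.full((3, 3), p_low)
        for g1 in range(3):
            for g2 in range(3):
                if (g1 == 1) != (g2 == 1):
                    table[g1, g2] = p_high
        return cls(loci=loci, table=table, baseline=p_low)

    def high_cells(self) -> np.ndarray:
        """Boolean mask over flattened cells with penetrance above baseline."""
        return (self.table > self.baseline).ravel()


@dataclass
class MarginalEffect:
    """A planted single-locus effect: odds multiplied by OR per encoding unit."""

    snp: int
    model: str  # dominant / co_dominant / recessive / additive
    odds_ratio: float


@dataclass
class BiomarkerEffect:
    """Lognormal marker, log-mean shifted for samples in true high-risk cells."""

    name: str
    log_mean: float
    log_sd: float
    log_shift_high_risk: float = 0.0


@dataclass
class SimConfig:
    n_cases: int = 226
    n_controls: int = 575
    n_snps: int = 384
    maf_range: tuple[float, float] = (0.05, 0.5)
    maf_overrides: dict = field(default_factory=dict)  # snp index -> MAF
    missing_rate: float = 0.02
    n_low_call_rate: int = 0
    low_call_missing_rate: float = 0.20
    n_hwe_violators: int = 0
    hwe_het_deficit: float = 0.6  # inbreeding-style F in [0, 1]
    baseline_risk: float = 0.22
    marginal_effects: tuple = ()
    penetrance: PenetranceModel | None = None
    biomarker_effects: tuple = ()
    n_cal: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_cases, self.n_controls, self.n_snps) <= 0:
            raise ValueError("counts must be positive")
        for rate in (self.missing_rate, self.low_call_missing_rate,
                     self.hwe_het_deficit, self.baseline_risk):
            if not 0 <= rate <= 1:
                raise ValueError("rates must lie in [0, 1]")


_MAX_BATCHES = 500


def _encode_for_effect(codes: np.ndarray, model: str) -> np.ndarray:
    if model == "dominant":
        return (codes >= 1).astype(float)
    if model == "co_dominant":
        return (codes == 1).astype(float)
    if model == "recessive":
        return (codes == 2).astype(float)
    if model == "additive":
        return codes.astype(float)
    raise ValueError(f"unknown model {model!r}")


def _draw_genotypes(
    rng: np.random.Generator,
    batch: int,
    mafs: np.ndarray,
    violator: np.ndarray,
    f_deficit: float,
) -> np.ndarray:
    """HWE draws per SNP; violators use heterozygote-deficit proportions."""
    g = rng.binomial(2, mafs, size=(batch, mafs.size)).astype(np.int8)
    if violator.any():
        q = mafs[violator]
        p = 1.0 - q
        probs = np.stack(
            [p**2 + f_deficit * p * q, 2 * p * q * (1 - f_deficit), q**2 + f_deficit * p * q]
        )  # (3, n_viol)
        cum = np.cumsum(probs, axis=0)
        u = rng.random((batch, q.size))
        g[:, violator] = (u[:, :, None] > cum.T[None, :, :]).sum(axis=2).astype(np.int8)
    return g


def _case_probability(g: np.ndarray, config: SimConfig) -> np.ndarray:
    if config.penetrance is not None:
        pm = config.penetrance
        idx = tuple(g[:, j] for j in pm.loci)
        base = pm.table[idx]
    else:
        base = np.full(g.shape[0], config.baseline_risk)
    eta = logit(np.clip(base, 1e-12, 1 - 1e-12))
    for eff in config.marginal_effects:
        eta = eta + np.log(eff.odds_ratio) * _encode_for_effect(g[:, eff.snp], eff.model)
    return expit(eta)


def _true_high_risk(g: np.ndarray, config: SimConfig) -> np.ndarray:
    if config.penetrance is None:
        return np.zeros(g.shape[0], dtype=bool)
    pm = config.penetrance
    idx = tuple(g[:, j] for j in pm.loci)
    return pm.table[idx] > pm.baseline


_ALLELE_PAIRS = [("A", "C"), ("A", "G"), ("A", "T"), ("C", "G"), ("C", "T"), ("G", "T")]


def simulate(config: SimConfig) -> tuple[GenotypeMatrix, PhenotypeTable, dict]:
    """Generate one dataset plus a truth record of every planted effect."""
    rng = np.random.default_rng(config.seed)
    m = config.n_snps

    mafs = rng.uniform(*config.maf_range, size=m)
    for j, value in config.maf_overrides.items():
        mafs[int(j)] = value

    protected = set()
    if config.penetrance is not None:
        protected.update(config.penetrance.loci)
    for eff in config.marginal_effects:
        protected.add(eff.snp)
    free = np.array([j for j in range(m) if j not in protected])
    n_special = config.n_low_call_rate + config.n_hwe_violators
    if n_special > free.size:
        raise ValueError("not enough unplanted SNPs for QC-failure slots")
    special = rng.choice(free, size=n_special, replace=False) if n_special else np.array([], int)
    low_call = np.zeros(m, dtype=bool)
    violator = np.zeros(m, dtype=bool)
    low_call[special[: config.n_low_call_rate]] = True
    violator[special[config.n_low_call_rate:]] = True

    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=m)
    snps = [
        SnpMeta(
            snp_id=f"rs{j + 1:06d}",
            allele_a=_ALLELE_PAIRS[pair_idx[j]][0],
            allele_b=_ALLELE_PAIRS[pair_idx[j]][1],
            gene=f"GENE{j // 2 + 1}",
            category=CATEGORIES[j % 3],
        )
        for j in range(m)
    ]

    # retrospective accrual: draw population candidates, keep until margins hit
    need_cases, need_ctrl = config.n_cases, config.n_controls
    case_rows: list[np.ndarray] = []
    ctrl_rows: list[np.ndarray] = []
    case_high: list[np.ndarray] = []
    ctrl_high: list[np.ndarray] = []
    for _ in range(_MAX_BATCHES):
        if need_cases <= 0 and need_ctrl <= 0:
            break
        batch = max(1000, 3 * (max(need_cases, 0) + max(need_ctrl, 0)))
        g = _draw_genotypes(rng, batch, mafs, violator, config.hwe_het_deficit)
        p_case = _case_probability(g, config)
        is_case = rng.random(batch) < p_case
        hr = _true_high_risk(g, config)
        if need_cases > 0:
            take = np.flatnonzero(is_case)[:need_cases]
            case_rows.append(g[take])
            case_high.append(hr[take])
            need_cases -= take.size
        if need_ctrl > 0:
            take = np.flatnonzero(~is_case)[:need_ctrl]
            ctrl_rows.append(g[take])
            ctrl_high.append(hr[take])
            need_ctrl -= take.size
    if need_cases > 0 or need_ctrl > 0:
        raise RuntimeError(
            "rejection sampling failed to reach requested case/control counts; "
            "the penetrance structure is incompatible with the requested margins"
        )

    codes = np.vstack(case_rows + ctrl_rows)
    high_risk_truth = np.concatenate(case_high + ctrl_high)
    n = config.n_cases + config.n_controls
    status = np.concatenate(
        [np.ones(config.n_cases, dtype=int), np.zeros(config.n_controls, dtype=int)]
    )

    # MCAR missingness (elevated on designated low-call-rate SNPs)
    rate = np.full(m, config.missing_rate)
    rate[low_call] = config.low_call_missing_rate
    miss = rng.random((n, m)) < rate
    codes = np.where(miss, np.int8(MISSING), codes)

    sample_ids = [f"S{i + 1:05d}" for i in range(n)]
    gm = GenotypeMatrix(sample_ids, snps, codes)

    cal = np.full(n, np.nan)
    if config.n_cal is not None:
        if config.n_cal > config.n_cases:
            raise ValueError("n_cal cannot exceed n_cases")
        cal[: config.n_cases] = 0.0
        chosen = rng.choice(config.n_cases, size=config.n_cal, replace=False)
        cal[chosen] = 1.0

    markers: dict[str, np.ndarray] = {}
    for eff in config.biomarker_effects:
        mu = eff.log_mean + eff.log_shift_high_risk * high_risk_truth
        values = np.exp(rng.normal(mu, eff.log_sd))
        values[status == 0] = np.nan  # markers assayed in patients only
        markers[eff.name] = values
    biomarkers = pd.DataFrame(markers, index=pd.Index(sample_ids, name="sample_id"))

    pheno = PhenotypeTable(sample_ids, status, cal, biomarkers)

    truth = {
        "seed": config.seed,
        "mafs": mafs.tolist(),
        "low_call_rate_snps": [snps[j].snp_id for j in np.flatnonzero(low_call)],
        "hwe_violator_snps": [snps[j].snp_id for j in np.flatnonzero(violator)],
        "hwe_het_deficit": config.hwe_het_deficit,
        "marginal_effects": [
            {"snp_id": snps[e.snp].snp_id, "model": e.model, "odds_ratio": e.odds_ratio}
            for e in config.marginal_effects
        ],
        "penetrance": None
        if config.penetrance is None
        else {
            "loci": [snps[j].snp_id for j in config.penetrance.loci],
            "table": config.penetrance.table.tolist(),
            "baseline": config.penetrance.baseline,
        },
        "biomarker_effects": [asdict(e) for e in config.biomarker_effects],
        "high_risk_truth": {
            sid: bool(flag) for sid, flag in zip(sample_ids, high_risk_truth) if flag
        },
    }
    return gm, pheno, truth


def study_config(seed: int = 0, **overrides) -> SimConfig:
    """A study-scale configuration: 384 SNPs, 226 cases / 575 controls, 73 of
    the cases with the binary sub-phenotype, 39 QC-failing SNPs (25 low call
    rate + 14 strong HWE violators), one planted epistatic pair and a few
    marginal effects.

    The disease is rare (baseline penetrance 0.5%), as for the emulated
    condition, so controls approximate the source population and causal
    loci remain in Hardy-Weinberg equilibrium among controls.  The planted
    pair's cell-wise odds ratio (~2.9) matches the moderate-epistasis
    setting used in the recovery experiments.
    """
    defaults = dict(
        n_cases=226,
        n_controls=575,
        n_snps=384,
        n_cal=73,
        n_low_call_rate=25,
        n_hwe_violators=14,
        hwe_het_deficit=0.8,
        missing_rate=0.02,
        low_call_missing_rate=0.20,
        baseline_risk=0.005,
        penetrance=PenetranceModel.xor_two_locus(loci=(0, 1), p_high=0.0145,
                                                 p_low=0.005),
        maf_overrides={0: 0.3, 1: 0.4},
        marginal_effects=(
            MarginalEffect(snp=2, model="dominant", odds_ratio=3.0),
            MarginalEffect(snp=3, model="recessive", odds_ratio=0.4),
        ),
        biomarker_effects=(
            BiomarkerEffect("IL-2", log_mean=2.3, log_sd=0.8, log_shift_high_risk=0.5),
            BiomarkerEffect("IL-6", log_mean=3.0, log_sd=1.0, log_shift_high_risk=0.7),
            BiomarkerEffect("TGF-b1", log_mean=9.6, log_sd=0.7, log_shift_high_risk=-0.5),
            BiomarkerEffect("IL-10", log_mean=1.8, log_sd=0.8),
        ),
        seed=seed,
    )
    defaults.update(overrides)
    return SimConfig(**defaults)


def fixture_small(seed: int = 0) -> tuple[GenotypeMatrix, PhenotypeTable, dict]:
    """Deterministic tiny dataset: 60 samples x 6 SNPs.

    SNP 1 (rs000001) predicts the outcome perfectly (cases homozygous for
    the minor allele, controls for the major), SNPs 2-3 carry a strong
    heterozygosity-XOR pair, SNPs 4-6 are noise with a few missing calls.
    """
    rng = np.random.default_rng(seed)
    n_cases, n_controls = 20, 40
    n = n_cases + n_controls
    status = np.concatenate([np.ones(n_cases, int), np.zeros(n_controls, int)])

    snps = [
        SnpMeta("rs000001", "A", "G", gene="PERF1", category="innate"),
        SnpMeta("rs000002", "C", "T", gene="PAIRA", category="adaptive"),
        SnpMeta("rs000003", "A", "C", gene="PAIRB", category="stress"),
        SnpMeta("rs000004", "G", "T", gene="NOISE1", category="innate"),
        SnpMeta("rs000005", "A", "T", gene="NOISE2", category="adaptive"),
        SnpMeta("rs000006", "C", "G", gene="NOISE3", category="stress"),
    ]
    codes = np.zeros((n, 6), dtype=np.int8)
    codes[:, 0] = np.where(status == 1, 2, 0)  # perfect predictor

    xor_cells = [(g1, g2) for g1 in range(3) for g2 in range(3) if (g1 == 1) != (g2 == 1)]
    other_cells = [(g1, g2) for g1 in range(3) for g2 in range(3) if (g1 == 1) == (g2 == 1)]
    for i in range(n):
        if status[i] == 1:
            pool = xor_cells if rng.random() < 0.9 else other_cells
        else:
            pool = other_cells if rng.random() < 0.8 else xor_cells
        g1, g2 = pool[rng.integers(len(pool))]
        codes[i, 1], codes[i, 2] = g1, g2

    codes[:, 3:] = rng.binomial(2, 0.3, size=(n, 3)).astype(np.int8)
    for j in (3, 4, 5):  # a little missingness in the noise SNPs
        drop = rng.choice(n, size=2, replace=False)
        codes[drop, j] = MISSING

    sample_ids = [f"F{i + 1:03d}" for i in range(n)]
    gm = GenotypeMatrix(sample_ids, snps, codes)

    cal = np.full(n, np.nan)
    cal[:n_cases] = 0.0
    cal[rng.choice(n_cases, size=7, replace=False)] = 1.0

    in_xor = np.array([(codes[i, 1] == 1) != (codes[i, 2] == 1) for i in range(n)])
    il2 = np.exp(rng.normal(2.3 + 0.8 * in_xor, 0.5))
    tgf = np.exp(rng.normal(9.6 - 0.6 * in_xor, 0.5))
    il2[status == 0] = np.nan
    tgf[status == 0] = np.nan
    biomarkers = pd.DataFrame(
        {"IL-2": il2, "TGF-b1": tgf}, index=pd.Index(sample_ids, name="sample_id")
    )
    pheno = PhenotypeTable(sample_ids, status, cal, biomarkers)
    truth = {
        "seed": seed,
        "perfect_snp": "rs000001",
        "pair": ["rs000002", "rs000003"],
        "high_cells": "exactly one of the pair heterozygous",
    }
    return gm, pheno, truth


def write_dataset(
    gm: GenotypeMatrix, pheno: PhenotypeTable, truth: dict, out_prefix: str | Path
) -> dict[str, Path]:
    """Emit genotypes.tsv / phenotypes.tsv / truth.json under a prefix."""
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "genotypes": out_prefix.with_suffix(".genotypes.tsv"),
        "phenotypes": out_prefix.with_suffix(".phenotypes.tsv"),
        "truth": out_prefix.with_suffix(".truth.json"),
    }
    write_genotypes(gm, paths["genotypes"], dialect="tsv")
    write_phenotypes(pheno, paths["phenotypes"])
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
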