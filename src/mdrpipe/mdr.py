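"""Multifactor dimensionality reduction (MDR) with cross-validation and
permutation testing.

MDR reduces a k-locus genotype space (3^k cells) to one binary attribute:
a cell is labelled *high-risk* when its training case:control ratio is at
least a threshold T (default: the case:control ratio of the training
split, the standard choice for unbalanced designs), and a sample is then
"predicted case" iff it falls in a high-risk cell.  Model quality is the
balanced accuracy (sensitivity + specificity) / 2 of that prediction.

The search is exhaustive over all C(m, k) locus sets.  With stratified
n-fold cross-validation, the set winning the most folds on training
balanced accuracy has the highest cross-validation consistency (CVC); ties
break on mean testing balanced accuracy, then lexicographic locus order.
Statistical significance of the best set's mean testing balanced accuracy
is an add-one empirical p-value over outcome-label permutations that
re-run the whole cross-validated search (folds held fixed).

Conventions (documented in docs/methods.md): empty training cells are
low-risk; test samples in unlabelled cells predict low-risk; samples with
a missing genotype at any model locus are excluded from that locus set's
fit (complete-case per set).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .io_tables import MISSING, GenotypeMatrix

_CACHE_BYTES = 128 * 1024 * 1024  # cache per-set cell indices up to this size


@dataclass
class MdrModel:
    """A fitted k-locus MDR classifier on one dataset."""

    loci: tuple[str, ...]
    cell_labels: dict[tuple[str, ...], str]  # genotype-call tuple -> "high"/"low"
    threshold_t: float
    case_counts: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    control_counts: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not 1 <= len(self.loci) <= 3:
            raise ValueError("MDR models use 1-3 loci")


@dataclass
class MdrCvResult:
    loci: tuple[str, ...]
    avg_testing_ba: float
    cvc: int
    n_folds: int
    perm_p: float | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.cvc <= self.n_folds:
            raise ValueError("cvc must lie in [0, n_folds]")


@dataclass
class MdrSearchReport:
    results: dict[int, MdrCvResult]
    significant: dict[int, bool]
    n_folds: int
    n_perm: int
    alpha: float


def balanced_accuracy(predicted_high: np.ndarray, outcome: np.ndarray) -> float:
    """(sensitivity + specificity) / 2, treating high-risk as predicted case."""
    predicted_high = np.asarray(predicted_high, dtype=bool)
    outcome = np.asarray(outcome)
    cases = outcome == 1
    ctrls = outcome == 0
    if not cases.any() or not ctrls.any():
        raise ValueError("balanced accuracy needs at least one case and one control")
    sens = float(predicted_high[cases].mean())
    spec = float((~predicted_high[ctrls]).mean())
    return 0.5 * (sens + spec)


def classify_cells(
    codes: np.ndarray, outcome: np.ndarray, t: float | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Label each of the 3^k genotype cells high/low risk.

    ``codes``: (n, k) genotype codes; samples with any missing code are
    excluded.  Returns (high_mask over 3^k cells, case counts, control
    counts, threshold used).  A cell is high-risk iff cases/controls >= T
    (controls 0 with cases > 0 is high; an empty cell is low).
    """
    codes = np.asarray(codes)
    if codes.ndim == 1:
        codes = codes.reshape(-1, 1)
    if codes.ndim != 2:
        raise ValueError("codes must be (n_samples, k)")
    outcome = np.asarray(outcome)
    k = codes.shape[1]
    n_cells = 3**k
    valid = (codes != MISSING).all(axis=1)
    if not valid.any():
        raise ValueError("no training samples with complete genotypes")
    g = codes[valid].astype(np.int64)
    y = outcome[valid]
    cell = g @ (3 ** np.arange(k - 1, -1, -1, dtype=np.int64))
    case_counts = np.bincount(cell[y == 1], minlength=n_cells).astype(float)
    ctrl_counts = np.bincount(cell[y == 0], minlength=n_cells).astype(float)
    if t is None:
        n_ctrl = ctrl_counts.sum()
        if n_ctrl == 0:
            raise ValueError("no controls among training samples")
        t = float(case_counts.sum() / n_ctrl)
    if t <= 0:
        raise ValueError("threshold T must be positive (no cases in training?)")
    observed = (case_counts + ctrl_counts) > 0
    # controls == 0 with cases > 0 satisfies cases >= T*0, so such cells are high
    high = observed & (case_counts >= t * ctrl_counts)
    return high, case_counts, ctrl_counts, float(t)


def stratified_folds(
    outcome: np.ndarray, n_folds: int, rng: np.random.Generator
) -> np.ndarray:
    """Random outcome-stratified fold assignment (values 0..n_folds-1)."""
    outcome = np.asarray(outcome)
    folds = np.empty(outcome.shape[0], dtype=np.int64)
    for value in (0, 1):
        idx = np.flatnonzero(outcome == value)
        if idx.size < n_folds:
            raise ValueError(
                f"class {value} has {idx.size} samples, fewer than {n_folds} folds"
            )
        perm = rng.permutation(idx)
        folds[perm] = np.arange(perm.size) % n_folds
    return folds


class _CvEngine:
    """Vectorized exhaustive k-locus search over fixed folds.

    Precomputes, per locus set, a combined (fold, cell) bin index per
    sample (missing-genotype samples land in a sentinel bin).  Each
    evaluation against an outcome vector is then two weighted bincounts
    per set, so label permutations are cheap.
    """

    def __init__(
        self,
        codes: np.ndarray,
        folds: np.ndarray,
        k: int,
        snp_indices: np.ndarray | None = None,
    ) -> None:
        self.codes = np.asarray(codes, dtype=np.int64)
        self.folds = np.asarray(folds, dtype=np.int64)
        self.n, m = self.codes.shape
        self.k = k
        self.n_folds = int(self.folds.max()) + 1
        self.n_cells = 3**k
        pool = np.arange(m) if snp_indices is None else np.asarray(snp_indices)
        if pool.size < k:
            raise ValueError(f"need at least k={k} SNPs, have {pool.size}")
        self.sets: list[tuple[int, ...]] = list(itertools.combinations(pool.tolist(), k))
        self._fc = self.n_folds * self.n_cells  # sentinel bin index
        cache_bytes = len(self.sets) * self.n * 8
        self._cached = cache_bytes <= _CACHE_BYTES
        if self._cached:
            self._combined = np.stack([self._combined_for(s) for s in self.sets])

    def _combined_for(self, locus_set: tuple[int, ...]) -> np.ndarray:
        sub = self.codes[:, list(locus_set)]
        valid = (sub != MISSING).all(axis=1)
        cell = sub @ (3 ** np.arange(self.k - 1, -1, -1, dtype=np.int64))
        combined = self.folds * self.n_cells + cell
        combined[~valid] = self._fc
        return combined

    def evaluate(self, outcome: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Training and testing balanced accuracy, shape (n_sets, n_folds).

        Entries are NaN when a fold's training or testing split lacks a
        class among the locus set's complete-genotype samples.
        """
        y = np.asarray(outcome, dtype=np.float64)
        F, C, FC = self.n_folds, self.n_cells, self._fc
        n_sets = len(self.sets)
        train_ba = np.empty((n_sets, F))
        test_ba = np.empty((n_sets, F))
        with np.errstate(invalid="ignore", divide="ignore"):
            for s in range(n_sets):
                combined = (
                    self._combined[s] if self._cached else self._combined_for(self.sets[s])
                )
                case = np.bincount(combined, weights=y, minlength=FC + 1)[:FC]
                tot = np.bincount(combined, minlength=FC + 1)[:FC]
                case = case.reshape(F, C)
                ctrl = tot.reshape(F, C).astype(np.float64) - case
                tot_case = case.sum(axis=0)
                tot_ctrl = ctrl.sum(axis=0)
                tr_case = tot_case[None, :] - case
                tr_ctrl = tot_ctrl[None, :] - ctrl
                n_case_tr = tr_case.sum(axis=1)
                n_ctrl_tr = tr_ctrl.sum(axis=1)
                high = (tr_case * n_ctrl_tr[:, None] >= tr_ctrl * n_case_tr[:, None]) & (
                    (tr_case + tr_ctrl) > 0
                )
                sens_tr = (tr_case * high).sum(axis=1) / n_case_tr
                spec_tr = (tr_ctrl * ~high).sum(axis=1) / n_ctrl_tr
                train_ba[s] = 0.5 * (sens_tr + spec_tr)
                sens_te = (case * high).sum(axis=1) / case.sum(axis=1)
                spec_te = (ctrl * ~high).sum(axis=1) / ctrl.sum(axis=1)
                test_ba[s] = 0.5 * (sens_te + spec_te)
        return train_ba, test_ba

    def search(self, outcome: np.ndarray) -> tuple[int, int, float, np.ndarray]:
        """Best locus set: (set index, cvc, mean testing BA, per-fold winners).

        Fold winners maximize training BA (ties -> lexicographically first
        set); the best set maximizes CVC, then mean testing BA, then
        lexicographic order.
        """
        train_ba, test_ba = self.evaluate(outcome)
        train_safe = np.where(np.isnan(train_ba), -np.inf, train_ba)
        winners = np.argmax(train_safe, axis=0)  # first max = lex-smallest set
        cvc = np.bincount(winners, minlength=len(self.sets))
        with np.errstate(invalid="ignore"):
            mean_test = np.array(
                [
                    np.nanmean(row) if not np.isnan(row).all() else -np.inf
                    for row in test_ba
                ]
            )
        best_cvc = cvc.max()
        candidates = np.flatnonzero(cvc == best_cvc)
        best = int(candidates[np.argmax(mean_test[candidates])])
        return best, int(cvc[best]), float(mean_test[best]), winners


def _resolve_indices(gm: GenotypeMatrix, snp_ids) -> np.ndarray | None:
    if snp_ids is None:
        return None
    return np.array([gm.snp_index(s) for s in snp_ids])


def cross_validated_search(
    gm: GenotypeMatrix,
    outcome: np.ndarray,
    k: int,
    n_folds: int = 20,
    seed: int | np.random.Generator = 0,
    snp_ids=None,
    folds: np.ndarray | None = None,
) -> MdrCvResult:
    """Exhaustive cross-validated k-locus MDR search; returns the best fit."""
    outcome = np.asarray(outcome)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if folds is None:
        folds = stratified_folds(outcome, n_folds, rng)
    engine = _CvEngine(gm.codes, folds, k, _resolve_indices(gm, snp_ids))
    best, cvc, mean_test, _ = engine.search(outcome)
    loci = tuple(gm.snps[j].snp_id for j in engine.sets[best])
    return MdrCvResult(loci=loci, avg_testing_ba=mean_test, cvc=cvc, n_folds=n_folds)


def permutation_test(
    gm: GenotypeMatrix,
    outcome: np.ndarray,
    k: int,
    n_perm: int = 10000,
    n_folds: int = 20,
    seed: int | np.random.Generator = 0,
    snp_ids=None,
) -> tuple[float, MdrCvResult]:
    """Empirical p for the best k-locus model's mean testing balanced accuracy.

    Labels are permuted ``n_perm`` times against a fixed fold partition and
    the full exhaustive search is repeated each time;
    p = (1 + #{permuted >= observed}) / (n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    outcome = np.asarray(outcome)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    folds = stratified_folds(outcome, n_folds, rng)
    engine = _CvEngine(gm.codes, folds, k, _resolve_indices(gm, snp_ids))
    best, cvc, observed, _ = engine.search(outcome)
    exceed = 0
    for _ in range(n_perm):
        y_perm = rng.permutation(outcome)
        _, _, stat, _ = engine.search(y_perm)
        if stat >= observed:
            exceed += 1
    p = (1 + exceed) / (n_perm + 1)
    loci = tuple(gm.snps[j].snp_id for j in engine.sets[best])
    result = MdrCvResult(
        loci=loci, avg_testing_ba=observed, cvc=cvc, n_folds=n_folds, perm_p=p
    )
    return p, result


def empirical_p(observed: float, permuted: np.ndarray) -> float:
    """Add-one permutation p: (1 + #{permuted >= observed}) / (B + 1)."""
    permuted = np.asarray(permuted, dtype=float)
    return float((1 + (permuted >= observed).sum()) / (permuted.size + 1))


def run_mdr(
    gm: GenotypeMatrix,
    outcome: np.ndarray,
    ks: tuple[int, ...] = (1, 2, 3),
    n_folds: int = 20,
    n_perm: int = 10000,
    seed: int = 0,
    alpha: float = 0.05,
    snp_ids=None,
) -> MdrSearchReport:
    """Full MDR sweep: per-k best model with CVC, testing BA and permutation p."""
    root = np.random.default_rng(seed)
    streams = root.spawn(len(ks))
    results: dict[int, MdrCvResult] = {}
    significant: dict[int, bool] = {}
    for k, stream in zip(ks, streams):
        p, result = permutation_test(
            gm, outcome, k, n_perm=n_perm, n_folds=n_folds, seed=stream, snp_ids=snp_ids
        )
        results[k] = result
        significant[k] = p <= alpha
    return MdrSearchReport(
        results=results, significant=significant, n_folds=n_folds,
        n_perm=n_perm, alpha=alpha,
    )
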