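"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the package's vectorized code paths:
the HWE oracle enumerates heterozygote configurations with exact integer
arithmetic, and the MDR oracle tallies cells with Python dictionaries.
"""

from __future__ import annotations

from math import factorial

import numpy as np
import pytest

from mdrpipe.io_tables import MISSING
from mdrpipe.synthetic import fixture_small


@pytest.fixture(scope="session")
def small_dataset():
    return fixture_small(seed=0)


# ---------------------------------------------------------------------------
# HWE exact-test oracle: full enumeration with exact integers
# ---------------------------------------------------------------------------

def hwe_enumeration_oracle(n_aa: int, n_ab: int, n_bb: int) -> float:
    n = n_aa + n_ab + n_bb
    rare = 2 * min(n_aa, n_bb) + n_ab
    if rare == 0:
        return 1.0

    def weight(h: int) -> int:
        rare_hom = (rare - h) // 2
        common_hom = n - h - rare_hom
        return factorial(n) * 2**h // (
            factorial(rare_hom) * factorial(h) * factorial(common_hom)
        )

    weights = {h: weight(h) for h in range(rare % 2, rare + 1, 2)}
    total = sum(weights.values())
    w_obs = weights[n_ab]
    return sum(w for w in weights.values() if w <= w_obs) / total


# ---------------------------------------------------------------------------
# MDR oracle: dictionary-tally cell labels and fold winners
# ---------------------------------------------------------------------------

def oracle_cell_labels(codes, y, t=None):
    """High-risk cell set via explicit tallies (complete-case samples)."""
    codes = np.asarray(codes)
    if codes.ndim == 1:
        codes = codes.reshape(-1, 1)
    k = codes.shape[1]
    case, ctrl = {}, {}
    for i in range(codes.shape[0]):
        if MISSING in codes[i]:
            continue
        cell = 0
        for j in range(k):
            cell = cell * 3 + int(codes[i, j])
        d = case if y[i] == 1 else ctrl
        d[cell] = d.get(cell, 0) + 1
    if t is None:
        n_ctrl = sum(ctrl.values())
        t = sum(case.values()) / n_ctrl
    high = set()
    for cell in set(case) | set(ctrl):
        ca, co = case.get(cell, 0), ctrl.get(cell, 0)
        if co == 0:
            if ca > 0:
                high.add(cell)
        elif ca / co >= t:
            high.add(cell)
    return high, case, ctrl


def _oracle_ba_in(cell_of, high, idx, y):
    cases = [i for i in idx if y[i] == 1]
    ctrls = [i for i in idx if y[i] == 0]
    if not cases or not ctrls:
        return float("nan")
    sens = np.mean([cell_of[i] in high for i in cases])
    spec = np.mean([cell_of[i] not in high for i in ctrls])
    return 0.5 * (sens + spec)


def oracle_fold_search(codes, folds, y, locus_sets, n_folds):
    """Per-fold winners and per-set (train, test) BA via explicit loops.

    Winners maximize training BA; ties resolve to the earliest set in
    ``locus_sets`` order.  Returns (winners, train_ba, test_ba).
    """
    codes = np.asarray(codes)
    S = len(locus_sets)
    train_ba = np.full((S, n_folds), np.nan)
    test_ba = np.full((S, n_folds), np.nan)
    for s, locus_set in enumerate(locus_sets):
        sub = codes[:, list(locus_set)]
        valid = [i for i in range(codes.shape[0]) if MISSING not in sub[i]]
        cell_of = {}
        for i in valid:
            cell = 0
            for v in sub[i]:
                cell = cell * 3 + int(v)
            cell_of[i] = cell
        for f in range(n_folds):
            train = [i for i in valid if folds[i] != f]
            test = [i for i in valid if folds[i] == f]
            case, ctrl = {}, {}
            for i in train:
                d = case if y[i] == 1 else ctrl
                d[cell_of[i]] = d.get(cell_of[i], 0) + 1
            n_case, n_ctrl = sum(case.values()), sum(ctrl.values())
            high = set()
            for cell in set(case) | set(ctrl):
                ca, co = case.get(cell, 0), ctrl.get(cell, 0)
                if ca * n_ctrl >= co * n_case:
                    high.add(cell)
            train_ba[s, f] = _oracle_ba_in(cell_of, high, train, y)
            test_ba[s, f] = _oracle_ba_in(cell_of, high, test, y)
    safe = np.where(np.isnan(train_ba), -np.inf, train_ba)
    winners = []
    for f in range(n_folds):
        best, best_v = 0, -np.inf
        for s in range(S):
            if safe[s, f] > best_v:
                best, best_v = s, safe[s, f]
        winners.append(best)
    return np.array(winners), train_ba, test_ba
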