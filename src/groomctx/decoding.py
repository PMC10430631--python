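"""Context decoding from baseline bins: single-neuron SVM, permutation
nulls, bootstrap pseudo-populations, and PCA separability.

Single-neuron decoding runs a linear SVM on 1-s baseline rate bins with
balanced class counts (majority context down-sampled, seeded) and
stratified 10-fold cross-validation.  Each unit's chance level comes
from its own permutation null: block labels are shuffled and the full
balanced CV re-run many times; a unit is significant when its true CV
accuracy exceeds the upper bound of the null's 95% percentile interval.
Note mean CV accuracy can fall below 50% for weak units; the null is
still centred on 50%.

Population decoding builds pseudo-population vectors by pairing
same-context bins uniformly at random across units (units come from
different sessions, so no bin correspondence exists), bootstrapping
unit sets at each size and using the lower bound of the 95% percentile
interval as that size's performance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import LinearSVC

from .baseline import BaselineSeries
from .errors import InsufficientDataError

N_FOLDS = 10
SVM_C = 1.0
CI_PERCENTILES = (2.5, 97.5)
GROOM_KIND = "grooming"
AIRFLOW_KIND = "airflow"


@dataclass(frozen=True)
class DecodingResult:
    unit_id: str
    cv_accuracy: float
    null_mean: float
    null_ci_upper: float
    significant: bool


@dataclass(frozen=True)
class PopulationCurve:
    set_sizes: np.ndarray
    mean_accuracy: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    threshold: float
    min_n_for_threshold: int | None


def _context_arrays(series: BaselineSeries) -> tuple[np.ndarray, np.ndarray]:
    x = series.rates_hz
    g = series.block_kinds == GROOM_KIND
    a = series.block_kinds == AIRFLOW_KIND
    return x[a], x[g]


def _balanced_cv_accuracy(x0: np.ndarray, x1: np.ndarray,
                          rng: np.random.Generator,
                          n_folds: int = N_FOLDS, C: float = SVM_C) -> float:
    """Mean held-out accuracy of a linear SVM over stratified folds after
    down-sampling the majority class.  ``x0``/``x1`` are (n_i, d) or 1-D."""
    x0 = np.atleast_2d(np.asarray(x0, dtype=float).T).T
    x1 = np.atleast_2d(np.asarray(x1, dtype=float).T).T
    m = min(len(x0), len(x1))
    if m < n_folds:
        raise InsufficientDataError(
            f"need >= {n_folds} bins per class, got {m}")
    X = np.concatenate([x0[rng.choice(len(x0), m, replace=False)],
                        x1[rng.choice(len(x1), m, replace=False)]])
    y = np.concatenate([np.zeros(m, dtype=int), np.ones(m, dtype=int)])
    skf = StratifiedKFold(n_folds, shuffle=True,
                          random_state=int(rng.integers(2**31)))
    accs = []
    for tr, te in skf.split(X, y):
        clf = LinearSVC(C=C, dual=False)
        clf.fit(X[tr], y[tr])
        accs.append(clf.score(X[te], y[te]))
    return float(np.mean(accs))


def svm_accuracy_single(series: BaselineSeries, seed=0,
                        n_folds: int = N_FOLDS, C: float = SVM_C) -> float:
    """Balanced stratified 10-fold CV accuracy of a linear SVM on one
    unit's 1-D baseline rate bins (airflow vs grooming)."""
    xa, xg = _context_arrays(series)
    if len(xa) == 0 or len(xg) == 0:
        raise InsufficientDataError(
            f"unit {series.unit_id}: both contexts must have bins")
    rng = np.random.Generator(np.random.PCG64(seed))
    return _balanced_cv_accuracy(xa, xg, rng, n_folds, C)


def permutation_null(series: BaselineSeries, n_perm: int = 10000, seed=0,
                     n_folds: int = N_FOLDS, C: float = SVM_C
                     ) -> tuple[np.ndarray, tuple[float, float]]:
    """Label-shuffle null of the balanced-CV accuracy.

    Every permutation reassigns bins to the two contexts at random
    (preserving class counts) and re-runs the full balanced 10-fold CV.
    Returns ``(null_accuracies, (ci_lower, ci_upper))`` with a
    percentile 95% interval.
    """
    if n_perm <= 0:
        raise ValueError("n_perm must be positive")
    if n_perm < 100:
        warnings.warn("n_perm < 100: permutation CI is unstable", stacklevel=2)
    xa, xg = _context_arrays(series)
    pooled = np.concatenate([xa, xg])
    na = len(xa)
    rng = np.random.Generator(np.random.PCG64(seed))
    null = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(len(pooled))
        null[i] = _balanced_cv_accuracy(pooled[perm[:na]], pooled[perm[na:]],
                                        rng, n_folds, C)
    ci = tuple(np.percentile(null, CI_PERCENTILES))
    return null, (float(ci[0]), float(ci[1]))


def decode_unit(series: BaselineSeries, n_perm: int = 1000, seed=0,
                n_folds: int = N_FOLDS, C: float = SVM_C) -> DecodingResult:
    """True CV accuracy plus permutation-null significance for one unit."""
    acc = svm_accuracy_single(series, seed=seed, n_folds=n_folds, C=C)
    null, (_, hi) = permutation_null(series, n_perm=n_perm, seed=seed,
                                     n_folds=n_folds, C=C)
    return DecodingResult(series.unit_id, acc, float(np.mean(null)), hi,
                          bool(acc > hi))


def z_rate_difference(series: BaselineSeries) -> float:
    """Grooming-minus-airflow difference of mean Z-scored baseline rate."""
    z = series.z_rates
    g = z[series.block_kinds == GROOM_KIND]
    a = z[series.block_kinds == AIRFLOW_KIND]
    return float(np.mean(g) - np.mean(a))


def population_curve(all_series: list[BaselineSeries],
                     set_sizes=None, n_boot: int = 10000,
                     bins_per_block: int = 60, threshold: float = 0.95,
                     seed=0, with_replacement: bool = True,
                     n_folds: int = N_FOLDS, C: float = SVM_C
                     ) -> PopulationCurve:
    """Decoding accuracy of bootstrap pseudo-populations vs set size.

    Per bootstrap draw at size k: choose k units (with replacement by
    default), sample ``bins_per_block`` bins from each unit's blocks per
    context, pair them at random across units into pseudo-population
    vectors, and run balanced 10-fold CV.  ``min_n_for_threshold`` is
    the smallest size whose CI lower bound exceeds ``threshold`` (None
    if never reached).
    """
    if not all_series:
        raise InsufficientDataError("no units supplied")
    rng = np.random.Generator(np.random.PCG64(seed))
    per_unit: list[tuple[list[np.ndarray], list[np.ndarray]]] = []
    for s in all_series:
        by_ctx: dict[str, list[np.ndarray]] = {AIRFLOW_KIND: [], GROOM_KIND: []}
        for bid in np.unique(s.block_ids):
            kind = s.block_kinds[s.block_ids == bid][0]
            if kind not in by_ctx:
                continue
            r = s.rates_for_block(int(bid))
            if len(r) < bins_per_block:
                raise InsufficientDataError(
                    f"unit {s.unit_id}: block {bid} has {len(r)} bins "
                    f"< {bins_per_block}")
            by_ctx[kind].append(r)
        per_unit.append((by_ctx[AIRFLOW_KIND], by_ctx[GROOM_KIND]))
    n_units = len(per_unit)
    if set_sizes is None:
        set_sizes = np.arange(1, n_units + 1)
    set_sizes = np.asarray(set_sizes, dtype=int)

    def _draw(k: int) -> float:
        members = (rng.integers(0, n_units, size=k) if with_replacement
                   else rng.choice(n_units, size=k, replace=False))
        cols_a, cols_g = [], []
        for ui in members:
            blocks_a, blocks_g = per_unit[ui]
            cols_a.append(np.concatenate(
                [rng.choice(r, bins_per_block, replace=False) for r in blocks_a]))
            cols_g.append(np.concatenate(
                [rng.choice(r, bins_per_block, replace=False) for r in blocks_g]))
        Xa = np.column_stack(cols_a)
        Xg = np.column_stack(cols_g)
        return _balanced_cv_accuracy(Xa, Xg, rng, n_folds, C)

    mean_acc = np.empty(len(set_sizes))
    ci_lo = np.empty(len(set_sizes))
    ci_hi = np.empty(len(set_sizes))
    for i, k in enumerate(set_sizes):
        accs = np.array([_draw(int(k)) for _ in range(n_boot)])
        mean_acc[i] = accs.mean()
        ci_lo[i], ci_hi[i] = np.percentile(accs, CI_PERCENTILES)
    above = np.flatnonzero(ci_lo > threshold)
    min_n = int(set_sizes[above[0]]) if len(above) else None
    return PopulationCurve(set_sizes, mean_acc, ci_lo, ci_hi, threshold, min_n)


def accuracy_rate_correlation(accuracies, z_diffs, min_units: int = 3
                              ) -> tuple[float | None, float | None]:
    """Pearson correlation of CV accuracy with the grooming-airflow Z
    difference, separately over units with negative and positive
    differences.  Branches with fewer than ``min_units`` units (or zero
    variance) report None."""
    acc = np.asarray(accuracies, dtype=float)
    z = np.asarray(z_diffs, dtype=float)
    if len(acc) != len(z):
        raise ValueError("accuracies and z_diffs must align")
    out = []
    for mask in (z < 0, z > 0):
        if mask.sum() < min_units or np.std(z[mask]) == 0 or np.std(acc[mask]) == 0:
            out.append(None)
        else:
            out.append(float(stats.pearsonr(acc[mask], z[mask]).statistic))
    return out[0], out[1]


def pca_separability(X: np.ndarray, labels: np.ndarray, seed=0) -> float:
    """Project population bins onto the first principal component and
    2-means cluster; returns accuracy under the best cluster-to-label
    assignment (always >= 0.5)."""
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    if X.ndim != 2 or len(X) != len(labels):
        raise ValueError("X must be (n_bins, n_units) aligned with labels")
    if np.allclose(np.var(X, axis=0), 0):
        raise ValueError("degenerate matrix: no variance to project")
    proj = PCA(n_components=1).fit_transform(X)
    km = KMeans(n_clusters=2, n_init=10,
                random_state=int(np.random.Generator(
                    np.random.PCG64(seed)).integers(2**31)))
    assign = km.fit_predict(proj)
    truth = (labels == labels[0]).astype(int)
    acc = float(np.mean(assign == truth))
    return max(acc, 1.0 - acc)
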