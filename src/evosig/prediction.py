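"""Downstream use of the learned codes: Hamming-kernel regression for
period and genre prediction, hyper-parameter cross-validation, and
temporal-trend permutation / stability analyses.

Period prediction regresses a song's chronological rank (scaled to (0, 1])
from its MAP latent code with the kernel exp(-alpha * Hamming distance);
genre prediction treats membership in each genre as a separate binary task
scored with the same kernel.  Both are scored by Pearson correlation
against the held-out truth.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.stats import pearsonr
from sklearn.base import BaseEstimator, RegressorMixin, clone
from sklearn.utils import check_random_state
from sklearn.utils.validation import check_is_fitted

from .model import (Decoder, EvolutionarySignatureModel, code_table,
                    loglik_matrix)

logger = logging.getLogger(__name__)


def period_labels(N: int) -> np.ndarray:
    """Chronological-rank labels i/N for i = 1..N (strictly increasing,
    in (0, 1])."""
    return np.arange(1, N + 1) / N


class HammingKernelRegressor(RegressorMixin, BaseEstimator):
    """Nadaraya-Watson regression on binary codes with kernel
    exp(-alpha * H), H the Hamming distance.

    Predictions are convex combinations of the training labels; alpha = 0
    gives their mean and large alpha the nearest neighbour's label.
    """

    def __init__(self, alpha: float = 1.0):
        self.alpha = alpha

    def fit(self, Z, y):
        Z = np.asarray(Z)
        y = np.asarray(y, dtype=float)
        if Z.ndim != 2 or Z.shape[0] != y.shape[0]:
            raise ValueError("Z must be 2-D with one label per row")
        if Z.shape[0] == 0:
            raise ValueError("empty training set")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        self.Z_ = Z.astype(float)
        self.y_ = y
        self.n_features_in_ = Z.shape[1]
        return self

    def predict(self, Z) -> np.ndarray:
        check_is_fitted(self, "Z_")
        Z = np.atleast_2d(np.asarray(Z, dtype=float))
        H = np.abs(Z[:, None, :] - self.Z_[None, :, :]).sum(axis=2)
        K = np.exp(-self.alpha * H)
        return (K @ self.y_) / K.sum(axis=1)


def kernel_predict(z, train_codes, y_train, alpha: float) -> float:
    """Predicted label for one code (thin wrapper over the regressor)."""
    reg = HammingKernelRegressor(alpha).fit(train_codes, y_train)
    return float(reg.predict(np.atleast_2d(z))[0])


def map_test_code(x, decoder: Decoder, prior: np.ndarray) -> np.ndarray:
    """MAP code for one held-out feature row under likelihood x marginal
    prior, by explicit enumeration in log space (ties -> lowest index)."""
    prior = np.asarray(prior, dtype=float)
    codes = code_table(decoder.B)
    L = loglik_matrix(np.atleast_2d(x), decoder, codes)[0]
    with np.errstate(divide="ignore"):
        scores = L + np.where(prior > 0, np.log(np.clip(prior, 1e-300, None)),
                              -np.inf)
    if not np.isfinite(scores).any():
        logger.warning("map_test_code: prior has zero mass everywhere; "
                       "returning likelihood argmax")
        scores = L
    return codes[int(np.argmax(scores))].astype(int)


def evaluate_period(pred, truth) -> float:
    """Pearson correlation between predicted and true period labels."""
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape or pred.size < 3:
        raise ValueError("need equal-length label vectors of size >= 3")
    if pred.std() == 0 or truth.std() == 0:
        raise ValueError("Pearson correlation undefined for zero variance")
    return float(pearsonr(pred, truth).statistic)


def evaluate_genre(test_codes, train_codes, train_genres, test_genres,
                   alpha: float = 1.0, min_genre_count: int = 10):
    """Mean Pearson correlation over per-genre binary kernel predictions.

    Genres with fewer than ``min_genre_count`` positive training songs, or
    no positive test song, are excluded; zero-variance test truths are
    skipped with a warning (their Pearson r is undefined).  Returns
    ``(mean_r, table)`` where the table carries per-genre r and the
    threshold-0.5 classification accuracy as a secondary metric.
    """
    train_codes = np.asarray(train_codes)
    test_codes = np.asarray(test_codes)
    vocab = sorted({g for gs in train_genres for g in gs})
    rows = []
    for genre in vocab:
        y_tr = np.array([genre in gs for gs in train_genres], dtype=float)
        y_te = np.array([genre in gs for gs in test_genres], dtype=float)
        if y_tr.sum() < min_genre_count or y_te.sum() < 1:
            continue
        if y_te.std() == 0:
            logger.warning("genre %r: zero-variance test truth; skipped", genre)
            continue
        scores = HammingKernelRegressor(alpha).fit(train_codes, y_tr) \
            .predict(test_codes)
        if scores.std() == 0:
            logger.warning("genre %r: constant predictions; skipped", genre)
            continue
        r = float(pearsonr(scores, y_te).statistic)
        acc = float(np.mean((scores >= 0.5) == y_te.astype(bool)))
        rows.append({"genre": genre, "r": r, "accuracy": acc,
                     "n_train_pos": int(y_tr.sum()),
                     "n_test_pos": int(y_te.sum())})
    if not rows:
        raise ValueError("no genre passes the support filter")
    table = pd.DataFrame(rows)
    return float(table["r"].mean()), table


# ---------------------------------------------------------------------------
# End-to-end period evaluation and hyper-parameter search
# ---------------------------------------------------------------------------

def period_prediction_r(model: EvolutionarySignatureModel, X_test,
                        alpha: float = 1.0, n_train: int | None = None) -> float:
    """Fit-side convenience: MAP-infer codes for held-out rows, kernel-
    regress rank labels, return Pearson r against the held-out ranks."""
    Z_tr = model.map_train_codes()
    y_tr = period_labels(Z_tr.shape[0] if n_train is None else n_train)[:Z_tr.shape[0]]
    Z_te = model.transform(X_test)
    pred = HammingKernelRegressor(alpha).fit(Z_tr, y_tr).predict(Z_te)
    return evaluate_period(pred, period_labels(Z_te.shape[0]))


DEFAULT_GAMMA_GRID = (0.1, 1.0, 10.0)
DEFAULT_WINDOW_GRID = (1, 2, 5)
DEFAULT_ALPHA_GRID = (0.25, 0.5, 1.0, 2.0, 4.0)


def cross_validate(X_train, gamma_grid=DEFAULT_GAMMA_GRID,
                   window_grid=DEFAULT_WINDOW_GRID,
                   alpha_grid=DEFAULT_ALPHA_GRID, folds: int = 5,
                   seed: int = 0, **model_kwargs):
    """Select (gamma, window, alpha) by period-prediction r.

    Folds are chronological strides of the training songs (fold k holds
    out positions k, k+folds, ...), so each fold refit sees a date-ordered
    sub-corpus.  Returns ``(best_params, table)`` with one table row per
    (gamma, window) combination carrying its best alpha and mean fold r.
    """
    if not (len(gamma_grid) and len(window_grid) and len(alpha_grid)):
        raise ValueError("grids must be non-empty")
    X_train = np.asarray(X_train)
    N = X_train.shape[0]
    pos = np.arange(N)
    rows = []
    for gamma in gamma_grid:
        for window in window_grid:
            alpha_scores = {a: [] for a in alpha_grid}
            for k in range(folds):
                hold = (pos % folds) == k
                if hold.sum() < 3 or (~hold).sum() < 3:
                    continue
                m = EvolutionarySignatureModel(
                    gamma=gamma, window=window,
                    random_state=seed + k, **model_kwargs,
                ).fit(X_train[~hold])
                Z_tr = m.map_train_codes()
                y_tr = period_labels(Z_tr.shape[0])
                Z_va = m.transform(X_train[hold])
                y_va = period_labels(int(hold.sum()))
                for a in alpha_grid:
                    pred = HammingKernelRegressor(a).fit(Z_tr, y_tr) \
                        .predict(Z_va)
                    try:
                        alpha_scores[a].append(evaluate_period(pred, y_va))
                    except ValueError:
                        alpha_scores[a].append(0.0)
            means = {a: float(np.mean(v)) if v else -np.inf
                     for a, v in alpha_scores.items()}
            best_a = max(means, key=lambda a: (means[a], -a))
            rows.append({"gamma": gamma, "window": window,
                         "alpha": best_a, "r": means[best_a]})
    table = pd.DataFrame(rows)
    best = table.loc[table["r"].idxmax()]
    best_params = {"gamma": float(best["gamma"]),
                   "window": int(best["window"]),
                   "alpha": float(best["alpha"])}
    return best_params, table


# ---------------------------------------------------------------------------
# Temporal-trend permutation test and stability analysis
# ---------------------------------------------------------------------------

def late_variance_ratio(omega: np.ndarray) -> float:
    """Across-signature mean of activation variance in the last temporal
    quartile divided by the same in the first quartile (< 1 indicates a
    late decrease in signature variance)."""
    omega = np.asarray(omega, dtype=float)
    q = max(omega.shape[0] // 4, 2)
    early = omega[:q].var(axis=0).mean()
    late = omega[-q:].var(axis=0).mean()
    return float(late / early) if early > 0 else np.inf


def variance_slope(omega: np.ndarray, n_windows: int = 8) -> float:
    """OLS slope of windowed across-signature activation variance against
    window index (negative = variance decreasing over time)."""
    omega = np.asarray(omega, dtype=float)
    T = omega.shape[0]
    n_windows = min(n_windows, max(T // 2, 1))
    bounds = np.linspace(0, T, n_windows + 1).astype(int)
    v = np.array([omega[a:b].var(axis=0).mean()
                  for a, b in zip(bounds[:-1], bounds[1:]) if b - a >= 2])
    if v.size < 2:
        return 0.0
    return float(np.polyfit(np.arange(v.size), v, 1)[0])


_STATISTICS = {"late_variance_ratio": late_variance_ratio,
               "variance_slope": variance_slope}


def permutation_trend_test(omega: np.ndarray, refit_callback,
                           statistic: str = "late_variance_ratio",
                           n_perm: int = 99, seed: int = 0) -> dict:
    """Test a temporal trend in signature activations against refits on
    permuted song orderings.

    ``refit_callback(permutation, seed)`` must refit the model with song
    rows reordered by ``permutation`` and return that fit's T x B
    activation matrix.  The observed statistic is compared to the null
    draws with p = (1 + #{null <= observed}) / (1 + n_perm), the one-sided
    p-value for decrease-type statistics (both built-ins are
    decrease-type: a small late/early variance ratio, or a negative
    windowed-variance slope).  Failed refits are skipped and logged.
    """
    if n_perm < 19:
        raise ValueError("n_perm must be >= 19")
    stat = _STATISTICS[statistic]
    rng = check_random_state(seed)
    observed = stat(omega)
    null = []
    T = np.asarray(omega).shape[0]
    for k in range(n_perm):
        perm = rng.permutation(T)
        try:
            null.append(stat(refit_callback(perm, int(rng.randint(2 ** 31)))))
        except Exception:
            logger.exception("permutation draw %d failed; skipped", k)
    null = np.array(null)
    p = (1 + int(np.sum(null <= observed))) / (1 + null.size)
    return {"statistic": statistic, "observed": observed, "null": null,
            "p_value": float(p), "n_perm": int(null.size)}


def match_signatures(omega_a: np.ndarray, omega_b: np.ndarray):
    """Match signatures of two runs by maximizing summed absolute
    trajectory correlation (assignment problem).  Returns
    ``(permutation, matched_abs_correlations)`` where signature j of run b
    is matched to signature permutation[j] of run a."""
    omega_a = np.asarray(omega_a, dtype=float)
    omega_b = np.asarray(omega_b, dtype=float)
    Ba, Bb = omega_a.shape[1], omega_b.shape[1]
    C = np.zeros((Ba, Bb))
    for i in range(Ba):
        for j in range(Bb):
            a, b = omega_a[:, i], omega_b[:, j]
            if a.std() == 0 or b.std() == 0:
                C[i, j] = 1.0 if np.allclose(a, b) else 0.0
            else:
                C[i, j] = abs(np.corrcoef(a, b)[0, 1])
    rows, cols = linear_sum_assignment(-C)
    order = np.argsort(cols)
    rows, cols = rows[order], cols[order]
    perm = rows.copy()          # perm[j] = signature of run a matched to j
    return perm, C[rows, cols]


def stability_analysis(model: EvolutionarySignatureModel, X,
                       n_runs: int = 3, subsample_fracs=(1.0,),
                       seed: int = 0) -> pd.DataFrame:
    """Refit with fresh seeds and date-ordered subsamples; match each
    run's signatures to run 0 on the songs both saw, reporting matched
    absolute trajectory correlations."""
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    X = np.asarray(X)
    N = X.shape[0]
    rng = check_random_state(seed)
    omegas, indices = [], []
    for r in range(n_runs):
        frac = subsample_fracs[r % len(subsample_fracs)]
        keep = np.sort(rng.choice(N, size=max(int(round(frac * N)), 2),
                                  replace=False)) if frac < 1.0 else np.arange(N)
        m = clone(model)
        m.set_params(random_state=seed + r)
        m.fit(X[keep])
        omegas.append(m.signature_report().activations)
        indices.append(keep)
    rows = []
    for r in range(1, n_runs):
        common = np.intersect1d(indices[0], indices[r])
        a = omegas[0][np.searchsorted(indices[0], common)]
        b = omegas[r][np.searchsorted(indices[r], common)]
        perm, corrs = match_signatures(a, b)
        for j, (i0, c) in enumerate(zip(perm, corrs)):
            rows.append({"run": r, "signature_ref": int(i0),
                         "signature_run": int(j), "abs_corr": float(c)})
    return pd.DataFrame(rows)
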