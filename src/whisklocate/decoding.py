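"""Population decoding of pole location from touch-evoked spike counts.

Each included neuron's 20-bin location tuning curve (expected spike count
per touch-response window) is interpolated to 40 bins (0.25-mm resolution
over the 10-mm range).  At every bin, 50 spike counts are drawn from a
Poisson with the interpolated mean, forming a pseudo-population design
matrix (rows = location samples, columns = neurons).  A multinomial
logistic model with elastic-net (lasso mixing 0.95) regularization is fit
on a stratified random 70% of rows and evaluated on the held-out 30%,
averaged over 10 iterations.

Because neurons were recorded serially, the design matrix is a
pseudo-population: trial-to-trial count correlations between neurons are
absent by construction.

A closed-form Poisson maximum-likelihood (Bayes) classifier over the true
rate maps serves as the performance ceiling for cross-checks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.stats import ttest_ind_from_stats
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.preprocessing import StandardScaler

logger = logging.getLogger(__name__)

N_LOCATION_BINS = 40
BIN_MM = 0.25
SAMPLES_PER_BIN = 50
TRAIN_FRACTION = 0.7
N_ITERATIONS = 10
L1_RATIO = 0.95
MIN_TOUCHES = 75
MIN_COVERAGE = 0.8
COVERAGE_BIN_MM = 0.5


def location_grid(pole_range: tuple[float, float] = (0.0, 10.0),
                  n_bins: int = N_LOCATION_BINS) -> np.ndarray:
    """Bin centers across the pole range (0.25-mm spacing by default)."""
    lo, hi = pole_range
    width = (hi - lo) / n_bins
    return lo + width * (np.arange(n_bins) + 0.5)


def meets_inclusion(locations: np.ndarray,
                    pole_range: tuple[float, float] = (0.0, 10.0),
                    min_touches: int = MIN_TOUCHES,
                    min_coverage: float = MIN_COVERAGE) -> bool:
    """Inclusion rule: >= 75 touches covering >= 80% of 0.5-mm location bins."""
    locations = np.asarray(locations, float)
    if locations.size < min_touches:
        return False
    lo, hi = pole_range
    n_cov = int(round((hi - lo) / COVERAGE_BIN_MM))
    hist, _ = np.histogram(locations, bins=n_cov, range=(lo, hi))
    return (hist > 0).mean() >= min_coverage


def interpolate_lambda(bin_stimulus: np.ndarray, bin_counts: np.ndarray,
                       grid: np.ndarray) -> np.ndarray:
    """Monotone piecewise-cubic interpolation of a count tuning curve onto
    the decoder grid, clipped at zero."""
    x = np.asarray(bin_stimulus, float)
    y = np.asarray(bin_counts, float)
    gx = np.clip(grid, x[0], x[-1])
    return np.clip(PchipInterpolator(x, y)(gx), 0.0, None)


@dataclass
class DecoderDesign:
    location_bins: np.ndarray          # (40,) bin centers, mm
    lambda_matrix: np.ndarray          # (n_neurons, 40) expected counts
    design_matrix: np.ndarray          # (40*50, n_neurons) sampled counts
    labels: np.ndarray                 # (40*50,) bin index per row
    neuron_ids: list[str]
    samples_per_bin: int = SAMPLES_PER_BIN

    @property
    def n_neurons(self) -> int:
        return self.lambda_matrix.shape[0]


def build_design(curves: list[tuple[str, np.ndarray, np.ndarray]],
                 touch_locations: dict[str, np.ndarray] | None = None,
                 pole_range: tuple[float, float] = (0.0, 10.0),
                 samples_per_bin: int = SAMPLES_PER_BIN,
                 seed: int | np.random.Generator = 0) -> DecoderDesign:
    """Assemble the Poisson-resampled design matrix.

    ``curves`` holds ``(neuron_id, bin_stimulus_mm, bin_mean_counts)`` per
    neuron; ``touch_locations`` (if given) is checked against the inclusion
    rule and failing neurons are dropped with a log entry.
    """
    rng = np.random.default_rng(seed)
    grid = location_grid(pole_range)
    lams, ids = [], []
    for nid, x, y in curves:
        if touch_locations is not None:
            locs = touch_locations.get(nid)
            if locs is None or not meets_inclusion(locs, pole_range):
                logger.info("decoder: excluding %s (inclusion rule)", nid)
                continue
        lams.append(interpolate_lambda(x, y, grid))
        ids.append(nid)
    if not lams:
        raise ValueError("no neuron passed the inclusion rule")
    lam = np.vstack(lams)                       # (n, 40)
    n_bins = grid.size
    labels = np.repeat(np.arange(n_bins), samples_per_bin)
    design = rng.poisson(
        np.repeat(lam.T, samples_per_bin, axis=0))  # (40*50, n)
    return DecoderDesign(location_bins=grid, lambda_matrix=lam,
                         design_matrix=design, labels=labels,
                         neuron_ids=ids, samples_per_bin=samples_per_bin)


@dataclass
class DecoderModel:
    coefficients: np.ndarray     # (n_classes, n_neurons), raw count space;
    intercepts: np.ndarray       # mean over the 10 iterations' fits
    location_bins: np.ndarray
    accuracy: float              # mean exact-bin accuracy over iterations
    accuracy_sd: float
    accuracies: np.ndarray
    ensemble_accuracy: float     # accuracy of the averaged coefficients
    confusion: np.ndarray        # (40, 40) row-normalized, pooled over iterations
    y_true: np.ndarray           # pooled test-set truth (bin indices)
    y_pred: np.ndarray
    eval_X: np.ndarray           # held-out rows for ensemble/subsample metrics
    eval_y: np.ndarray
    C: float                     # selected inverse regularization strength
    train_fraction: float = TRAIN_FRACTION
    n_iterations: int = N_ITERATIONS
    l1_ratio: float = L1_RATIO

    @property
    def n_classes(self) -> int:
        return len(self.location_bins)


def _make_clf(C: float, seed: int) -> LogisticRegression:
    return LogisticRegression(
        l1_ratio=L1_RATIO, C=C, solver="saga",
        max_iter=3000, tol=1e-3, random_state=seed)


def _raw_space_coefs(scaler: StandardScaler, clf: LogisticRegression,
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Fold the standardizer into the coefficients so predictions can be
    made directly from raw spike counts (needed for column subsampling)."""
    coef = clf.coef_ / scaler.scale_
    intercept = clf.intercept_ - coef @ scaler.mean_
    return coef, intercept


def fit_decoder(design: DecoderDesign,
                seed: int | np.random.Generator = 0,
                n_iterations: int = N_ITERATIONS,
                train_fraction: float = TRAIN_FRACTION,
                c_grid: tuple[float, ...] = (0.05, 0.5, 5.0),
                redraw_design: bool = False) -> DecoderModel:
    """Fit the multinomial lasso decoder over stratified 70/30 splits.

    Regularization strength is picked by 3-fold cross-validation on the
    first iteration's training split and reused for the remaining
    iterations.  With ``redraw_design`` the Poisson samples are redrawn
    each iteration instead of only re-splitting.

    The model's final coefficient matrix is the mean of the 10 iterations'
    coefficient estimates (mapped back to raw count space): each iteration
    is a resampled fit of the same population model, so averaging reduces
    estimation variance.  ``accuracy`` is the mean per-iteration test
    accuracy; ``ensemble_accuracy`` scores the averaged coefficients on
    held-out rows (a fresh Poisson draw in redraw mode, the first
    iteration's test split otherwise).
    """
    rng = np.random.default_rng(seed)
    X, y = design.design_matrix, design.labels
    if len(np.unique(y)) < 2:
        raise ValueError("labels are degenerate (single class)")
    n_classes = design.location_bins.size

    def split(ys):
        idx = np.arange(len(ys))
        return train_test_split(
            idx, train_size=train_fraction, stratify=ys,
            random_state=int(rng.integers(2**31 - 1)))

    tr_idx, te_idx = split(y)

    # one-time CV for the regularization strength
    best_C, best_acc = c_grid[0], -1.0
    if len(c_grid) > 1:
        skf = StratifiedKFold(3, shuffle=True,
                              random_state=int(rng.integers(2**31 - 1)))
        X_tr0, y_tr0 = X[tr_idx], y[tr_idx]
        for C in c_grid:
            accs = []
            for tr, va in skf.split(X_tr0, y_tr0):
                sc = StandardScaler().fit(X_tr0[tr])
                clf = _make_clf(C, int(rng.integers(2**31 - 1)))
                clf.fit(sc.transform(X_tr0[tr]), y_tr0[tr])
                accs.append(clf.score(sc.transform(X_tr0[va]), y_tr0[va]))
            acc = float(np.mean(accs))
            if acc > best_acc:
                best_acc, best_C = acc, C
    logger.info("decoder: selected C=%g", best_C)

    accs = []
    confusion = np.zeros((n_classes, n_classes))
    ys_true, ys_pred = [], []
    coefs, intercepts = [], []
    ref_eval = None
    for it in range(n_iterations):
        if it > 0:
            if redraw_design:
                X = rng.poisson(np.repeat(design.lambda_matrix.T,
                                          design.samples_per_bin, axis=0))
            tr_idx, te_idx = split(y)
        X_tr, y_tr = X[tr_idx], y[tr_idx]
        X_te, y_te = X[te_idx], y[te_idx]
        sc = StandardScaler().fit(X_tr)
        clf = _make_clf(best_C, int(rng.integers(2**31 - 1)))
        clf.fit(sc.transform(X_tr), y_tr)
        pred = clf.predict(sc.transform(X_te))
        accs.append(float((pred == y_te).mean()))
        np.add.at(confusion, (y_te, pred), 1)
        ys_true.append(y_te)
        ys_pred.append(pred)
        coef, intercept = _raw_space_coefs(sc, clf)
        coefs.append(coef)
        intercepts.append(intercept)
        if it == 0:
            ref_eval = (X_te.copy(), y_te.copy())

    row = confusion.sum(axis=1, keepdims=True)
    confusion = np.divide(confusion, row, where=row > 0,
                          out=np.zeros_like(confusion))
    coef = np.mean(coefs, axis=0)
    intercept = np.mean(intercepts, axis=0)
    if redraw_design:
        eval_X = rng.poisson(np.repeat(design.lambda_matrix.T,
                                       design.samples_per_bin, axis=0))
        eval_y = y
    else:
        eval_X, eval_y = ref_eval  # type: ignore[misc]
    ens_pred = np.argmax(eval_X @ coef.T + intercept, axis=1)
    return DecoderModel(
        coefficients=coef, intercepts=intercept,
        location_bins=design.location_bins,
        accuracy=float(np.mean(accs)), accuracy_sd=float(np.std(accs)),
        accuracies=np.array(accs),
        ensemble_accuracy=float((ens_pred == eval_y).mean()),
        confusion=confusion,
        y_true=np.concatenate(ys_true), y_pred=np.concatenate(ys_pred),
        eval_X=eval_X, eval_y=eval_y, C=best_C)


def predict_from_columns(model: DecoderModel, X: np.ndarray,
                         columns: np.ndarray | None = None) -> np.ndarray:
    """Argmax-class predictions using a subset (with multiplicity) of the
    learned per-neuron coefficients; ties go to the lower bin index."""
    if columns is None:
        logits = X @ model.coefficients.T + model.intercepts
    else:
        columns = np.asarray(columns, dtype=int)
        logits = X[:, columns] @ model.coefficients[:, columns].T \
            + model.intercepts
    return np.argmax(logits, axis=1)


def bayes_predict(lambda_matrix: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Maximum-likelihood location under independent Poisson counts with the
    true rate maps: argmax_k sum_j [x_j log lam_jk - lam_jk]."""
    lam = np.asarray(lambda_matrix, float)
    ll = X @ np.log(np.clip(lam, 1e-12, None)) - lam.sum(axis=0)
    return np.argmax(ll, axis=1)


@dataclass
class SubsampleResult:
    pool_sizes: np.ndarray
    mean_accuracy: np.ndarray
    sd_accuracy: np.ndarray
    accuracies: list[np.ndarray] = field(repr=False, default_factory=list)
    neurometric: list[np.ndarray] = field(repr=False, default_factory=list)


def subsample_population(model: DecoderModel, design: DecoderDesign,
                         pool_sizes: list[int], n_draws: int = 500,
                         seed: int | np.random.Generator = 0,
                         go_bins: np.ndarray | None = None) -> SubsampleResult:
    """Accuracy (and neurometric curves) for pools of neurons drawn with
    replacement from the trained population; coefficients are restricted to
    the drawn columns, never refit."""
    rng = np.random.default_rng(seed)
    if any(p <= 0 for p in pool_sizes):
        raise ValueError("pool sizes must be positive")
    X, y = model.eval_X, model.eval_y
    n = design.n_neurons
    if go_bins is None:
        go_bins = np.arange(model.n_classes // 2)
    means, sds, all_accs, neuros = [], [], [], []
    for k in pool_sizes:
        accs = np.empty(n_draws)
        lick = np.zeros((n_draws, model.n_classes))
        for d in range(n_draws):
            cols = rng.integers(0, n, k)
            pred = predict_from_columns(model, X, cols)
            accs[d] = (pred == y).mean()
            lick[d] = neurometric_curve(y, pred, model.n_classes, go_bins)
        means.append(accs.mean())
        sds.append(accs.std())
        all_accs.append(accs)
        neuros.append(lick)
    return SubsampleResult(pool_sizes=np.array(pool_sizes),
                           mean_accuracy=np.array(means),
                           sd_accuracy=np.array(sds),
                           accuracies=all_accs, neurometric=neuros)


def resolution_curve(y_true: np.ndarray, y_pred: np.ndarray,
                     n_classes: int = N_LOCATION_BINS) -> np.ndarray:
    """resolution[n] = fraction of predictions within n bins of the truth."""
    err = np.abs(np.asarray(y_pred) - np.asarray(y_true))
    return np.array([(err <= n).mean() for n in range(n_classes)])


def neurometric_curve(y_true: np.ndarray, y_pred: np.ndarray,
                      n_classes: int = N_LOCATION_BINS,
                      go_bins: np.ndarray | None = None) -> np.ndarray:
    """Per true location, the probability mass of 'go' (posterior-half)
    predictions = the simulated lick probability."""
    if go_bins is None:
        go_bins = np.arange(n_classes // 2)
    go = np.isin(y_pred, go_bins)
    out = np.full(n_classes, np.nan)
    for k in range(n_classes):
        sel = y_true == k
        if sel.any():
            out[k] = go[sel].mean()
    return out


def resolution_and_neurometric(model: DecoderModel,
                               go_bins: np.ndarray | None = None,
                               ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(resolution curve, neurometric lick probabilities, binary choices).

    Resolution at n = 2 bins corresponds to <= 0.5-mm error; a simulated
    lick is any location whose lick probability exceeds 50%.
    """
    res = resolution_curve(model.y_true, model.y_pred, model.n_classes)
    neuro = neurometric_curve(model.y_true, model.y_pred, model.n_classes,
                              go_bins)
    return res, neuro, neuro > 0.5


def compare_to_psychometric(neurometric_draws: np.ndarray,
                            model_locations: np.ndarray,
                            psychometric: "pd.DataFrame",
                            alpha: float = 0.05) -> "pd.DataFrame":
    """Two-sample t test per location between simulated neurometric draws
    and an externally supplied psychometric table.

    ``psychometric`` needs columns ``location_mm``, ``mean_lick_prob``,
    ``sd`` and optionally ``n`` (default 15 sessions).  A mismatched
    location grid is linearly interpolated with a warning.
    """
    import pandas as pd  # local: only this entry point needs it

    locs = np.asarray(psychometric["location_mm"], float)
    mean = np.asarray(psychometric["mean_lick_prob"], float)
    sd = np.asarray(psychometric["sd"], float)
    n_psy = int(psychometric["n"].iloc[0]) if "n" in psychometric else 15
    if locs.shape != model_locations.shape or not np.allclose(locs, model_locations):
        logger.warning("psychometric grid differs; interpolating")
        mean = np.interp(model_locations, locs, mean)
        sd = np.interp(model_locations, locs, sd)
    draws = np.asarray(neurometric_draws, float)
    rows = []
    for k, loc in enumerate(model_locations):
        col = draws[:, k]
        col = col[np.isfinite(col)]
        if col.size < 2 or sd[k] <= 0:
            rows.append((loc, np.nan, np.nan, False))
            continue
        stat, p = ttest_ind_from_stats(
            col.mean(), col.std(ddof=1) + 1e-12, col.size,
            mean[k], sd[k], n_psy, equal_var=False)
        rows.append((loc, float(stat), float(p), bool(p < alpha)))
    return pd.DataFrame(rows, columns=["location_mm", "t_stat", "p_value",
                                       "significant"])
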