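"""Repeated stratified k-fold evaluation scored by Matthews correlation.

With only ~17 positive couples out of 98, accuracy-style metrics are
dominated by the majority class; the Matthews Correlation Coefficient
(MCC) is used instead.  It behaves like a Pearson correlation between
predicted and true labels, lives in [-1, +1], and is robust to class
imbalance.

Because both the k-fold split and the random-forest fit (and, for
time-randomized surrogates, the permutation itself) are stochastic, the
whole train/test process is repeated — 50 times by default — yielding a
distribution of MCC values per variant; variants are compared by
non-overlap of mean ± SE intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .io import DyadSeries

logger = logging.getLogger(__name__)

# a feature source is either a fixed design (X, y) or a per-repetition
# regenerator rng -> (X, y), used by time-randomized surrogates which
# draw fresh permutations inside every repetition
FeatureSource = (
    tuple[np.ndarray, np.ndarray]
    | Callable[[np.random.Generator], tuple[np.ndarray, np.ndarray]]
)


@dataclass(frozen=True)
class EvalConfig:
    """Cross-validation and model settings.

    Random-forest hyperparameters are pinned to common defaults (100
    trees, unlimited depth, square-root feature rule, bootstrap
    resampling) rather than left to a library's drifting defaults.
    """

    k: int = 5
    repetitions: int = 50
    model_kind: str = "random_forest"  # or "logistic_baseline"
    rf_n_trees: int = 100
    rf_max_depth: int | None = None
    rf_feature_rule: str | float = "sqrt"
    per_fold_mcc: bool = False  # average per-fold MCCs instead of pooling
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")
        if self.model_kind not in ("random_forest", "logistic_baseline"):
            raise ValueError(f"unknown model_kind {self.model_kind!r}")


@dataclass
class PerformanceDistribution:
    """Per-variant MCC values over repetitions, with mean and SE."""

    variant_id: str
    context: str
    mcc_values: np.ndarray
    mean_mcc: float = field(init=False)
    se_mcc: float = field(init=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.mcc_values, dtype=float)
        object.__setattr__(self, "mcc_values", v)
        self.mean_mcc = float(v.mean())
        # SE over repetitions: sd / sqrt(R)
        self.se_mcc = float(v.std(ddof=1) / np.sqrt(v.size)) if v.size > 1 else 0.0
        if not -1.0 - 1e-12 <= self.mean_mcc <= 1.0 + 1e-12:
            raise ValueError("mean MCC outside [-1, 1]")


def mcc(y_true: Sequence[bool], y_pred: Sequence[bool]) -> float:
    """Matthews Correlation Coefficient of two boolean label vectors.

    (TP·TN − FP·FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)); defined as 0
    whenever any factor of the denominator vanishes (e.g. a single-class
    prediction), the conventional continuity choice.
    """
    yt = np.asarray(y_true, dtype=bool)
    yp = np.asarray(y_pred, dtype=bool)
    if yt.shape != yp.shape or yt.ndim != 1 or yt.size < 1:
        raise ValueError("label vectors must be equal-length and non-empty")
    tp = float(np.sum(yt & yp))
    tn = float(np.sum(~yt & ~yp))
    fp = float(np.sum(~yt & yp))
    fn = float(np.sum(yt & ~yp))
    denom_sq = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom_sq == 0.0:
        return 0.0
    return (tp * tn - fp * fn) / np.sqrt(denom_sq)


def _make_model(config: EvalConfig, seed: int):
    if config.model_kind == "random_forest":
        return RandomForestClassifier(
            n_estimators=config.rf_n_trees,
            max_depth=config.rf_max_depth,
            max_features=config.rf_feature_rule,
            bootstrap=True,
            random_state=seed,
            n_jobs=1,
        )
    return LogisticRegression(penalty=None, solver="lbfgs", max_iter=2000)


def _fit_predict(model, X_tr, y_tr, X_te) -> np.ndarray:
    try:
        model.fit(X_tr, y_tr)
    except Exception:
        if isinstance(model, LogisticRegression):
            # perfect separation can break the unpenalized fit; fall back
            # to a barely-regularized ridge
            logger.warning("unpenalized logistic fit failed; retrying with ridge")
            model = LogisticRegression(C=1e4, solver="lbfgs", max_iter=2000)
            model.fit(X_tr, y_tr)
        else:
            raise
    return model.predict(X_te).astype(bool)


def repeated_kfold_eval(
    features,
    config: EvalConfig,
    rng: np.random.Generator | None = None,
    variant_id: str = "original",
    context: str = "",
) -> PerformanceDistribution:
    """Repeated stratified k-fold cross-validation, one MCC per repetition.

    ``features`` is either a fixed ``(X, y)`` pair or a callable
    ``rng -> (X, y)`` invoked afresh inside every repetition (so
    time-randomized surrogates draw new permutations each time).  Per
    repetition a fresh stratified k-fold partition is drawn, the model
    is trained on k−1 folds and predicts the held-out fold, and the
    pooled held-out predictions give that repetition's MCC (per-fold
    averaging available via ``per_fold_mcc``).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    regenerate = callable(features)
    if not regenerate:
        X_fixed, y_fixed = features
        _check_labels(np.asarray(y_fixed, dtype=bool), config.k)
    values = np.empty(config.repetitions)
    for rep in range(config.repetitions):
        if regenerate:
            X, y = features(rng)
            y = np.asarray(y, dtype=bool)
            _check_labels(y, config.k)
        else:
            X, y = X_fixed, np.asarray(y_fixed, dtype=bool)
        fold_seed = int(rng.integers(2**31 - 1))
        skf = StratifiedKFold(n_splits=config.k, shuffle=True, random_state=fold_seed)
        pooled_pred = np.empty(y.size, dtype=bool)
        fold_mccs = []
        for train_idx, test_idx in skf.split(X, y):
            model = _make_model(config, seed=int(rng.integers(2**31 - 1)))
            pred = _fit_predict(model, X[train_idx], y[train_idx], X[test_idx])
            pooled_pred[test_idx] = pred
            if config.per_fold_mcc:
                fold_mccs.append(mcc(y[test_idx], pred))
        values[rep] = np.mean(fold_mccs) if config.per_fold_mcc else mcc(y, pooled_pred)
    return PerformanceDistribution(variant_id, context, values)


def _check_labels(y: np.ndarray, k: int) -> None:
    n_pos = int(y.sum())
    if n_pos == 0 or n_pos == y.size:
        raise ValueError("both label classes must be present")
    if y.size < k:
        raise ValueError("need at least k samples")
    if n_pos < k:
        logger.info(
            "only %d positives for %d folds; some test folds lack positives",
            n_pos,
            k,
        )


def baseline_features(dyad: DyadSeries) -> np.ndarray:
    """Simplified per-couple design for the logistic baseline.

    ``[mean_a, mean_b, var_a, var_b, lag-0 Pearson r]`` — the summary a
    conventional regression would use in place of the full spectrum.  A
    zero-variance partner makes the correlation undefined; it is set to
    0 with a warning.
    """
    a, b = dyad.series_a, dyad.series_b
    va, vb = float(np.var(a)), float(np.var(b))
    if va == 0.0 or vb == 0.0:
        logger.warning("zero-variance series: correlation term set to 0")
        r = 0.0
    else:
        r = float(np.corrcoef(a, b)[0, 1])
    return np.array([float(np.mean(a)), float(np.mean(b)), va, vb, r])


@dataclass
class VariantComparison:
    """Pairwise SE-overlap comparisons plus per-variant zero checks."""

    pairwise: pd.DataFrame
    vs_zero: pd.DataFrame


def compare_variants(dists: Sequence[PerformanceDistribution]) -> VariantComparison:
    """Compare performance distributions by mean ± SE interval overlap.

    Two variants differ *significantly* iff their [mean−SE, mean+SE]
    intervals are disjoint; a variant is indistinguishable from zero iff
    its interval contains 0.
    """
    if dists:
        contexts = {d.context for d in dists}
        reps = {d.mcc_values.size for d in dists}
        if len(contexts) > 1 or len(reps) > 1:
            raise ValueError("distributions must share context and repetitions")
    rows = []
    for i, d1 in enumerate(dists):
        for d2 in dists[i + 1 :]:
            lo1, hi1 = d1.mean_mcc - d1.se_mcc, d1.mean_mcc + d1.se_mcc
            lo2, hi2 = d2.mean_mcc - d2.se_mcc, d2.mean_mcc + d2.se_mcc
            rows.append(
                {
                    "variant_1": d1.variant_id,
                    "variant_2": d2.variant_id,
                    "mean_1": d1.mean_mcc,
                    "se_1": d1.se_mcc,
                    "mean_2": d2.mean_mcc,
                    "se_2": d2.se_mcc,
                    "significant": bool(hi1 < lo2 or hi2 < lo1),
                }
            )
    zero_rows = [
        {
            "variant": d.variant_id,
            "mean_mcc": d.mean_mcc,
            "se_mcc": d.se_mcc,
            "indistinguishable_from_zero": bool(
                d.mean_mcc - d.se_mcc <= 0.0 <= d.mean_mcc + d.se_mcc
            ),
        }
        for d in dists
    ]
    pair_cols = [
        "variant_1", "variant_2", "mean_1", "se_1", "mean_2", "se_2", "significant",
    ]
    zero_cols = ["variant", "mean_mcc", "se_mcc", "indistinguishable_from_zero"]
    return VariantComparison(
        pairwise=pd.DataFrame(rows, columns=pair_cols),
        vs_zero=pd.DataFrame(zero_rows, columns=zero_cols),
    )
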