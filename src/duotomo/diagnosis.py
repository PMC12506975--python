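"""Diagnostic model: standardisation, 3-step feature selection, 1D-CNN
probability of malignancy, ROC/threshold analysis, permutation importance,
and exact binomial (Clopper-Pearson) confusion statistics.

Feature selection retains features that (1) separate the classes at a Welch
t-test two-sided p below 0.01, (2) are not redundant with a stronger feature
(|Pearson r| > 0.85 pairs keep the smaller-p member), and (3) have
class-conditional density overlap below 75% (Gaussian KDE, Silverman
bandwidth on the pooled sample, shared 512-point grid).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve

from ._cnn import CNN1D
from .errors import ModelError, StandardizationError

__all__ = [
    "FeatureTable",
    "TrainedModel",
    "ConfusionCounts",
    "BinomialStats",
    "SelectionResult",
    "ROCResult",
    "standardize",
    "select_features",
    "train_cnn",
    "predict_pom",
    "roc_and_threshold",
    "permutation_importance",
    "permuted_auc",
    "clopper_pearson",
    "confusion_interval_stats",
    "mcnemar_exact",
]

LABEL_ORDER = ("benign", "malignant")


# --------------------------------------------------------------------------
# feature table and standardisation


@dataclass
class FeatureTable:
    """Per-mass feature rows with labels, split tags and an optional scaler."""

    df: pd.DataFrame                       # columns: mass_id, label, split, features
    feature_names: list[str]
    scaler: dict | None = None             # {'mean': Series, 'sd': Series}

    def rows(self, split: str | None = None) -> pd.DataFrame:
        if split is None:
            return self.df
        return self.df[self.df["split"] == split]

    def X(self, split: str | None = None, features: list[str] | None = None):
        f = features if features is not None else self.feature_names
        return self.rows(split)[list(f)].to_numpy(dtype=float)

    def y(self, split: str | None = None):
        return (self.rows(split)["label"] == "malignant").to_numpy(dtype=float)


def standardize(table: FeatureTable) -> FeatureTable:
    """Zero-mean/unit-variance scaling fitted on the training rows only.

    Uses the population SD (ddof=0).  Test rows are transformed with the
    training parameters; a zero-variance training feature is an error.
    """
    train = table.rows("train")
    if len(train) < 2:
        raise StandardizationError("need at least 2 training rows")
    mean = train[table.feature_names].mean()
    sd = train[table.feature_names].std(ddof=0)
    dead = sd[sd == 0].index.tolist()
    if dead:
        raise StandardizationError(f"zero-variance training feature(s): {dead}")
    df = table.df.copy()
    df[table.feature_names] = (df[table.feature_names] - mean) / sd
    return FeatureTable(df=df, feature_names=list(table.feature_names),
                        scaler={"mean": mean, "sd": sd})


# --------------------------------------------------------------------------
# feature selection


@dataclass
class SelectionResult:
    retained: list[str]
    diagnostics: pd.DataFrame              # feature, p_value, dropped_at, detail


def _silverman_bw(x):
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=1)
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    return 0.9 * spread * x.size ** (-0.2)


def _overlap_area(a, b, n_grid=512):
    """Integral of min of the two class densities on a shared grid."""
    pooled = np.concatenate([a, b])
    h = _silverman_bw(pooled)
    if h <= 0 or a.std() == 0 or b.std() == 0:
        return 1.0
    grid = np.linspace(pooled.min() - 3 * h, pooled.max() + 3 * h, n_grid)
    ka = stats.gaussian_kde(a, bw_method=h / a.std(ddof=1))
    kb = stats.gaussian_kde(b, bw_method=h / b.std(ddof=1))
    return float(np.trapezoid(np.minimum(ka(grid), kb(grid)), grid))


def select_features(
    table: FeatureTable,
    p_thresh: float = 0.01,
    r_thresh: float = 0.85,
    overlap_thresh: float = 0.75,
    split: str = "train",
) -> SelectionResult:
    """Three-step filter: Welch t-test, redundancy pruning, density overlap.

    Returns the retained names and a per-feature diagnostics table recording
    the step at which each dropped feature fell.  An empty retained set is a
    valid outcome, not an error.
    """
    rows = table.rows(split) if split in set(table.df["split"]) else table.df
    y = rows["label"] == "malignant"
    if y.all() or not y.any():
        raise ModelError("both classes must be present for selection")
    diag = []
    pvals = {}
    survivors = []
    for f in table.feature_names:
        a = rows.loc[~y, f].to_numpy(dtype=float)
        b = rows.loc[y, f].to_numpy(dtype=float)
        p = stats.ttest_ind(a, b, equal_var=False).pvalue
        p = 1.0 if np.isnan(p) else float(p)
        pvals[f] = p
        if p < p_thresh:
            survivors.append(f)
        else:
            diag.append({"feature": f, "p_value": p, "dropped_at": "t_test",
                         "detail": ""})
    # step 2: redundancy pruning, strongest (smallest p, then name) first
    order = sorted(survivors, key=lambda f: (pvals[f], f))
    kept = []
    for f in order:
        clash = None
        for g in kept:
            r = np.corrcoef(rows[f].astype(float), rows[g].astype(float))[0, 1]
            if np.isfinite(r) and abs(r) > r_thresh:
                clash = (g, r)
                break
        if clash is None:
            kept.append(f)
        else:
            diag.append({"feature": f, "p_value": pvals[f],
                         "dropped_at": "correlation",
                         "detail": f"|r|={abs(clash[1]):.3f} with {clash[0]}"})
    # step 3: class-conditional density overlap
    retained = []
    for f in sorted(kept, key=table.feature_names.index):
        a = rows.loc[~y, f].to_numpy(dtype=float)
        b = rows.loc[y, f].to_numpy(dtype=float)
        ov = _overlap_area(a, b)
        if ov < overlap_thresh:
            retained.append(f)
            diag.append({"feature": f, "p_value": pvals[f], "dropped_at": "",
                         "detail": f"overlap={ov:.3f}"})
        else:
            diag.append({"feature": f, "p_value": pvals[f],
                         "dropped_at": "overlap",
                         "detail": f"overlap={ov:.3f}"})
    diagnostics = pd.DataFrame(diag).sort_values("feature").reset_index(drop=True)
    return SelectionResult(retained=retained, diagnostics=diagnostics)


# --------------------------------------------------------------------------
# CNN training and prediction


@dataclass
class CNNHyperparams:
    channels: tuple = (16, 16, 32, 32)
    dense: tuple = (32, 16)
    kernel: int = 3
    dropout: float = 0.5
    lr: float = 0.01
    epochs: int = 200


@dataclass
class TrainedModel:
    net: CNN1D
    feature_names: list[str]
    hyperparams: CNNHyperparams
    seed: int
    scaler: dict | None = None
    pom_threshold: float | None = None
    loss_history: list = field(default_factory=list)


def train_cnn(
    table: FeatureTable,
    selected_features: list[str],
    hyperparams: CNNHyperparams | None = None,
    seed: int = 0,
) -> TrainedModel:
    """Fit the 1D-CNN on the (standardised) training rows; deterministic."""
    hp = hyperparams or CNNHyperparams()
    if not selected_features:
        raise ModelError("no features selected")
    y = table.y("train")
    if y.size == 0:
        y = table.y()
        X = table.X(features=selected_features)
    else:
        X = table.X("train", features=selected_features)
    if len(np.unique(y)) < 2:
        raise ModelError("training rows contain a single class")
    net = CNN1D(
        n_features=len(selected_features), channels=hp.channels, dense=hp.dense,
        kernel=hp.kernel, dropout=hp.dropout, seed=seed,
    )
    net.fit(X, y, epochs=hp.epochs, lr=hp.lr)
    return TrainedModel(
        net=net, feature_names=list(selected_features), hyperparams=hp,
        seed=seed, scaler=table.scaler, loss_history=net.loss_history,
    )


def predict_pom(model: TrainedModel, table: FeatureTable,
                split: str | None = None) -> np.ndarray:
    """Per-mass probability of malignancy; batch-order invariant."""
    missing = [f for f in model.feature_names if f not in table.df.columns]
    if missing:
        raise ModelError(f"feature-set mismatch, missing {missing}")
    return model.net.predict_proba(table.X(split, features=model.feature_names))


# --------------------------------------------------------------------------
# ROC / threshold / importance


@dataclass
class ROCResult:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    threshold: float
    sensitivity: float
    specificity: float
    counts: "ConfusionCounts"


def roc_and_threshold(
    pom: np.ndarray, labels: np.ndarray, min_sensitivity: float = 0.95
) -> ROCResult:
    """Empirical ROC and the largest threshold with sensitivity >= target.

    The decision rule is ``pom >= threshold`` -> malignant.
    """
    pom = np.asarray(pom, dtype=float)
    y = np.asarray(labels).astype(float)
    if len(np.unique(y)) < 2:
        raise ModelError("labels contain a single class")
    fpr, tpr, thr = roc_curve(y, pom)
    auc = float(roc_auc_score(y, pom))
    candidates = np.unique(pom)[::-1]
    chosen = candidates[-1]
    for t in candidates:
        if np.mean(pom[y == 1] >= t) >= min_sensitivity:
            chosen = t
            break
    pred = pom >= chosen
    counts = ConfusionCounts(
        tp=int(np.sum(pred & (y == 1))), fn=int(np.sum(~pred & (y == 1))),
        tn=int(np.sum(~pred & (y == 0))), fp=int(np.sum(pred & (y == 0))),
    )
    return ROCResult(
        fpr=fpr, tpr=tpr, thresholds=thr, auc=auc, threshold=float(chosen),
        sensitivity=counts.sensitivity, specificity=counts.specificity,
        counts=counts,
    )


def permuted_auc(model: TrainedModel, X: np.ndarray, y: np.ndarray,
                 col: int, perm: np.ndarray) -> float:
    """AUC after permuting one feature column with an explicit permutation."""
    Xp = X.copy()
    Xp[:, col] = Xp[perm, col]
    return float(roc_auc_score(y, model.net.predict_proba(Xp)))


def permutation_importance(
    model: TrainedModel,
    table: FeatureTable,
    split: str | None = None,
    n_repeats: int = 10,
    seed: int = 0,
) -> pd.Series:
    """Mean AUC drop per feature over seeded column permutations."""
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    X = table.X(split, features=model.feature_names)
    y = table.y(split)
    base = float(roc_auc_score(y, model.net.predict_proba(X)))
    rng = np.random.default_rng(seed)
    out = {}
    for j, f in enumerate(model.feature_names):
        drops = [
            base - permuted_auc(model, X, y, j, rng.permutation(len(y)))
            for _ in range(n_repeats)
        ]
        out[f] = float(np.mean(drops))
    return pd.Series(out, name="delta_auc")


# --------------------------------------------------------------------------
# exact binomial statistics


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fn: int
    tn: int
    fp: int

    @property
    def sensitivity(self) -> float:
        if self.tp + self.fn == 0:
            raise ZeroDivisionError("no positives")
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        if self.tn + self.fp == 0:
            raise ZeroDivisionError("no negatives")
        return self.tn / (self.tn + self.fp)


@dataclass(frozen=True)
class BinomialStats:
    estimate: float
    ci_lower: float
    ci_upper: float
    x: int
    n: int
    level: float


def clopper_pearson(x: int, n: int, level: float = 0.99) -> BinomialStats:
    """Exact two-sided binomial CI from beta-quantile tail inversion.

    The bounds solve the binomial tail equations; x = 0 pins the lower bound
    at 0 and x = n pins the upper bound at 1.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= x <= n:
        raise ValueError("x must lie in [0, n]")
    alpha = 1.0 - level
    lo = 0.0 if x == 0 else float(stats.beta.ppf(alpha / 2, x, n - x + 1))
    hi = 1.0 if x == n else float(stats.beta.ppf(1 - alpha / 2, x + 1, n - x))
    return BinomialStats(estimate=x / n, ci_lower=lo, ci_upper=hi,
                         x=int(x), n=int(n), level=level)


@dataclass(frozen=True)
class DiagnosticStats:
    sensitivity: BinomialStats
    specificity: BinomialStats


def confusion_interval_stats(
    counts: ConfusionCounts, level: float = 0.99
) -> DiagnosticStats:
    """Sensitivity/specificity with exact Clopper-Pearson CIs."""
    return DiagnosticStats(
        sensitivity=clopper_pearson(counts.tp, counts.tp + counts.fn, level),
        specificity=clopper_pearson(counts.tn, counts.tn + counts.fp, level),
    )


def mcnemar_exact(n01: int, n10: int) -> float:
    """Exact two-sided McNemar p-value from the discordant-pair binomial."""
    n = n01 + n10
    if n == 0:
        return 1.0
    return float(stats.binomtest(n01, n, 0.5).pvalue)
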