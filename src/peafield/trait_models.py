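"""Trait-level models: lodging score, leaf-type classification, and the
standardized-coefficient linear biomass models (Lasso-fitted or preset).

Lodging score between two imaging timepoints t1 < tk:

    score = (CH_1 - CH_k) * (CC_1 - CC_k)      with canopy coverage
          = (CH_1 - CH_k)                      height change only

A lodged plot loses height and spreads its canopy, so its CH difference is
positive and its CC difference negative, driving the product negative —
opposite in sign to an erect plot. The sign convention is kept as defined;
correlations against the field lodging ratio are reported signed.

Biomass models are linear in features standardized to zero mean and unit
SD, with the estimate divided by a fixed unit divisor:

    AGBM_est = ( sum_i coef_i * x_i + intercept ) / divisor

Two frozen presets ship with the package: the winter-trial model at
1268 ADD (features GRVI_sum, NDVI_sum, NDRE_sum, CC; divisor 1.5e4, AGBM
in kg fresh weight) and the spring-trial model at 1231 ADD (GRVI_sum,
NDVI_sum, NDVI_mean, NDRE_sum, PV; divisor 1.0e3, AGBM in g dry weight).
Preset coefficients apply to features standardized by the *current*
dataset's means and SDs, since the original training standardization is
not published; preset estimates are therefore comparable in structure but
not in absolute scale to the original study's.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import Lasso, LassoCV

class TraitModelError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Lodging
# ---------------------------------------------------------------------------

@dataclass
class LodgingScore:
    plot_id: str
    score: float
    add_pair: tuple[float, float]
    include_cc: bool


def lodging_score(feat_t1: Mapping, feat_tk: Mapping,
                  include_cc: bool = True) -> LodgingScore:
    """Multi-temporal lodging score from two feature-table rows of one plot."""
    if feat_t1["plot_id"] != feat_tk["plot_id"]:
        raise TraitModelError(
            f"mismatched plots: {feat_t1['plot_id']!r} vs {feat_tk['plot_id']!r}")
    add1, addk = float(feat_t1["ADD"]), float(feat_tk["ADD"])
    if not add1 < addk:
        raise TraitModelError(f"timepoints must satisfy ADD1 < ADDk, got {add1}, {addk}")
    dch = float(feat_t1["CH_uas"]) - float(feat_tk["CH_uas"])
    if include_cc:
        score = dch * (float(feat_t1["CC"]) - float(feat_tk["CC"]))
    else:
        score = dch
    return LodgingScore(plot_id=str(feat_t1["plot_id"]), score=score,
                        add_pair=(add1, addk), include_cc=include_cc)


def lodging_scores(features: pd.DataFrame, add1: float, addk: float,
                   include_cc: bool = True) -> pd.DataFrame:
    """Per-plot lodging scores between two ADD timepoints of a feature table."""
    t1 = features[features["ADD"] == add1].set_index("plot_id")
    tk = features[features["ADD"] == addk].set_index("plot_id")
    common = t1.index.intersection(tk.index)
    if common.empty:
        raise TraitModelError(f"no plots shared between {add1} and {addk} ADD")
    rows = []
    for pid in common:
        s = lodging_score({"plot_id": pid, "ADD": add1, **t1.loc[pid].to_dict()},
                          {"plot_id": pid, "ADD": addk, **tk.loc[pid].to_dict()},
                          include_cc=include_cc)
        rows.append({"plot_id": pid, "lodging_score": s.score})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Leaf type
# ---------------------------------------------------------------------------

@dataclass
class LeafTypeModel:
    """One-dimensional threshold classifier on plot-mean green reflectance."""

    decision_threshold: float
    high_class: str              # label assigned above the threshold
    low_class: str
    class_means: dict[str, float]
    class_sds: dict[str, float]
    training_accuracy: float


def fit_leaf_type(green_means: Sequence[float],
                  labels: Sequence[str]) -> LeafTypeModel:
    """Fit the green-band threshold separating the two pea leaf types.

    Exhaustive search over midpoints between adjacent sorted training
    values, minimizing training misclassification; ties break toward the
    lower threshold. Both classes (semi-leafless ``af`` and normal ``Af``)
    must be present.
    """
    x = np.asarray(green_means, float)
    y = np.asarray(labels)
    classes = sorted(set(y.tolist()))
    if len(classes) != 2:
        raise TraitModelError(
            f"need exactly two leaf-type classes in training labels, got {classes}")
    order = np.argsort(x, kind="stable")
    xs = x[order]
    candidates = [xs[0] - 1.0]
    candidates += [(a + b) / 2 for a, b in zip(xs[:-1], xs[1:])]
    candidates.append(xs[-1] + 1.0)
    best = None
    for thr in candidates:
        for high in classes:
            low = classes[0] if high == classes[1] else classes[1]
            pred = np.where(x > thr, high, low)
            acc = float(np.mean(pred == y))
            key = (-acc, thr)
            if best is None or key < best[0]:
                best = (key, thr, high, low, acc)
    _, thr, high, low, acc = best
    means = {c: float(np.mean(x[y == c])) for c in classes}
    sds = {c: float(np.std(x[y == c], ddof=1)) if np.sum(y == c) > 1 else 0.0
           for c in classes}
    return LeafTypeModel(decision_threshold=float(thr), high_class=high,
                         low_class=low, class_means=means, class_sds=sds,
                         training_accuracy=acc)


def classify_leaf_type(model: LeafTypeModel, green_means: Sequence[float],
                       labels: Sequence[str] | None = None):
    """Apply a fitted threshold; with labels, also report accuracy."""
    x = np.asarray(green_means, float)
    pred = np.where(x > model.decision_threshold, model.high_class, model.low_class)
    if labels is None:
        return pred
    acc = float(np.mean(pred == np.asarray(labels)))
    return pred, acc


# ---------------------------------------------------------------------------
# Standardization and linear AGBM models
# ---------------------------------------------------------------------------

def standardize_features(table: pd.DataFrame,
                         feature_names: Sequence[str]):
    """Center and scale features to zero mean and unit SD (population SD).

    Returns the standardized table plus the means and SDs, which become
    part of any fitted model so estimates are reproducible on new data.
    """
    out = table.copy()
    means: dict[str, float] = {}
    sds: dict[str, float] = {}
    for name in feature_names:
        if name not in table.columns:
            raise TraitModelError(f"feature {name!r} missing from table")
        col = table[name].to_numpy(float)
        mu, sd = float(np.mean(col)), float(np.std(col))
        if sd == 0:
            raise TraitModelError(f"feature {name!r} has zero standard deviation")
        out[name] = (col - mu) / sd
        means[name], sds[name] = mu, sd
    return out, means, sds


@dataclass
class LinearAGBMModel:
    """Linear biomass model on standardized features with a unit divisor."""

    feature_names: tuple[str, ...]
    coefficients: tuple[float, ...]
    intercept: float
    divisor: float
    standardization_means: dict[str, float] = field(default_factory=dict)
    standardization_sds: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.feature_names) != len(self.coefficients):
            raise TraitModelError("coefficients must align with feature_names")
        if not self.divisor > 0:
            raise TraitModelError(f"divisor must be > 0, got {self.divisor}")

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        doc = {"feature_names": list(self.feature_names),
               "coefficients": list(self.coefficients),
               "intercept": self.intercept, "divisor": self.divisor,
               "standardization_means": self.standardization_means,
               "standardization_sds": self.standardization_sds}
        path.write_text(json.dumps(doc, indent=1, sort_keys=True))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "LinearAGBMModel":
        doc = json.loads(Path(path).read_text())
        return cls(feature_names=tuple(doc["feature_names"]),
                   coefficients=tuple(doc["coefficients"]),
                   intercept=float(doc["intercept"]),
                   divisor=float(doc["divisor"]),
                   standardization_means=doc.get("standardization_means", {}),
                   standardization_sds=doc.get("standardization_sds", {}))


#: Winter-trial preset at 1268 ADD (AGBM in kg fresh weight).
WINTER_1268 = LinearAGBMModel(
    feature_names=("GRVI_sum", "NDVI_sum", "NDRE_sum", "CC"),
    coefficients=(1.56, -0.83, 0.75, -0.01),
    intercept=8.85,
    divisor=1.5e4,
)

#: Spring-trial preset at 1231 ADD (AGBM in g dry weight).
SPRING_1231 = LinearAGBMModel(
    feature_names=("GRVI_sum", "NDVI_sum", "NDVI_mean", "NDRE_sum", "PV"),
    coefficients=(7.80, 2.46, 4.98, 4.98, 10.73),
    intercept=87.83,
    divisor=1.0e3,
)

PRESETS = {"winter_1268": WINTER_1268, "spring_1231": SPRING_1231}


def apply_agbm_model(model: LinearAGBMModel, features: Mapping | pd.DataFrame):
    """Evaluate ``(sum coef_i * x_i + intercept) / divisor`` on standardized rows."""
    if isinstance(features, pd.DataFrame):
        missing = [f for f in model.feature_names if f not in features.columns]
        if missing:
            raise TraitModelError(f"missing features {missing}")
        x = features.loc[:, list(model.feature_names)].to_numpy(float)
        return (x @ np.asarray(model.coefficients) + model.intercept) / model.divisor
    missing = [f for f in model.feature_names if f not in features]
    if missing:
        raise TraitModelError(f"missing features {missing}")
    x = np.array([float(features[f]) for f in model.feature_names])
    return float((x @ np.asarray(model.coefficients) + model.intercept)
                 / model.divisor)


def fit_lasso_agbm(features: pd.DataFrame, agbm: pd.DataFrame,
                   feature_names: Sequence[str],
                   train_frac: float = 0.85, cv_folds: int = 5,
                   seed: int = 0, divisor: float = 1.0):
    """L1-penalized linear AGBM fit with the trial protocol.

    Features are standardized internally; the model is fit on a seeded
    ``train_frac`` split with the penalty chosen by ``cv_folds``-fold
    cross-validation over a logarithmic penalty grid on the training split,
    using the one-standard-error rule (largest penalty whose mean CV error
    is within one SE of the minimum — the conservative choice that shrinks
    noise-only predictors to zero). Validation (Pearson r and mean absolute
    error) is computed on the complete matched dataset. Returns
    ``(LinearAGBMModel, validation dict)``.
    """
    if not 0 < train_frac <= 1:
        raise TraitModelError(f"train_frac must be in (0, 1], got {train_frac}")
    merged = features.merge(agbm[["plot_id", "AGBM"]], on="plot_id")
    merged = merged.dropna(subset=list(feature_names) + ["AGBM"])
    n = len(merged)
    if n < 10:
        raise TraitModelError(f"need >= 10 matched rows to fit, got {n}")
    std, means, sds = standardize_features(merged, feature_names)
    x = std.loc[:, list(feature_names)].to_numpy(float)
    y = std["AGBM"].to_numpy(float) * divisor
    rng = np.random.default_rng(seed)
    n_train = max(cv_folds + 1, int(round(train_frac * n)))
    train_idx = rng.choice(n, size=min(n_train, n), replace=False)
    cv = LassoCV(cv=cv_folds, random_state=seed, max_iter=100000)
    cv.fit(x[train_idx], y[train_idx])
    # one-SE rule on the CV error path (alphas_ is in decreasing order)
    mean_mse = cv.mse_path_.mean(axis=1)
    se_mse = cv.mse_path_.std(axis=1, ddof=1) / np.sqrt(cv.mse_path_.shape[1])
    i_min = int(np.argmin(mean_mse))
    within = np.nonzero(mean_mse <= mean_mse[i_min] + se_mse[i_min])[0]
    alpha = float(cv.alphas_[int(within.min())])
    lasso = Lasso(alpha=alpha, max_iter=100000)
    lasso.fit(x[train_idx], y[train_idx])
    model = LinearAGBMModel(
        feature_names=tuple(feature_names),
        coefficients=tuple(float(c) for c in lasso.coef_),
        intercept=float(lasso.intercept_),
        divisor=divisor,
        standardization_means=means,
        standardization_sds=sds,
    )
    pred = apply_agbm_model(model, std)
    actual = merged["AGBM"].to_numpy(float)
    if np.ptp(pred) == 0 or np.ptp(actual) == 0:
        r, p = float("nan"), float("nan")
    else:
        r, p = stats.pearsonr(actual, pred)
    validation = {
        "r": float(r), "p": float(p),
        "mae": float(np.mean(np.abs(actual - pred))),
        "train_r2": float(lasso.score(x[train_idx], y[train_idx])),
        "alpha": alpha,
        "n": n, "n_train": int(train_idx.size),
    }
    return model, validation


def predict_entries(model: LinearAGBMModel, features: pd.DataFrame,
                    plots=None) -> pd.DataFrame:
    """Per-entry AGBM estimates: standardize, predict per plot, average per entry.

    Entries are flagged ``above_mean`` relative to the experiment-wide mean
    estimate. Features are standardized with the model's stored parameters
    when present, otherwise by the current dataset.
    """
    missing = [f for f in model.feature_names if f not in features.columns]
    if missing:
        raise TraitModelError(f"missing features {missing}")
    if "entry" not in features.columns:
        if plots is None:
            raise TraitModelError("features lack an 'entry' column and no plots given")
        entry_of = {p.plot_id: p.entry for p in plots}
        unmatched = [pid for pid in features["plot_id"] if pid not in entry_of]
        if unmatched:
            raise TraitModelError(f"plots missing from layout: {unmatched}")
        features = features.assign(entry=[entry_of[p] for p in features["plot_id"]])
    na_rows = features.loc[:, list(model.feature_names)].isna().any(axis=1)
    if na_rows.any():
        raise TraitModelError(
            f"missing feature values for plots "
            f"{features.loc[na_rows, 'plot_id'].tolist()}")
    std = features.copy()
    if model.standardization_means:
        for f in model.feature_names:
            std[f] = ((features[f].to_numpy(float) - model.standardization_means[f])
                      / model.standardization_sds[f])
    else:
        # standardize by the current dataset; a feature with no variation
        # carries no signal and standardizes to zero
        for f in model.feature_names:
            col = features[f].to_numpy(float)
            sd = float(np.std(col))
            std[f] = (col - float(np.mean(col))) / sd if sd > 0 else 0.0
    std = std.assign(AGBM_est=apply_agbm_model(model, std))
    out = std.groupby("entry", as_index=False)["AGBM_est"].mean()
    out["above_mean"] = out["AGBM_est"] > out["AGBM_est"].mean()
    return out
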