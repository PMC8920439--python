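"""Phenotypic-age clock: regression of chronological age on features.

A clock is trained on per-trajectory feature vectors labelled with
chronological age.  Training follows the imbalanced-regression recipe:
per-(feature, age-group) mean imputation, optional SMOGN oversampling of
rare-age rows, age-stratified k-fold cross-validation (preprocessing
fitted on training folds only), and one of five regressor families
(LASSO, elastic net, random forest, gradient boosting, RBF-SVM) with a
small hyperparameter grid selected inside the training folds.  Held-out
performance is reported as adjusted R-squared and RMSE.

The fitted clock predicts a *phenotypic age*; its difference from
chronological age (delta = predicted - chronological) indexes apparent
health, and the per-condition aging rate is the slope of the
origin-forced regression of predicted on chronological age.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.linear_model import ElasticNet, Lasso
from sklearn.metrics import mean_squared_error, r2_score
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

__all__ = [
    "MODEL_FAMILIES", "ClockConfig", "GroupMeanImputer", "impute", "resample_smogn",
    "PhenotypicClock", "ClockResults", "PhenotypicAgeResult", "aging_rate_slope",
]

MODEL_FAMILIES = ("lasso", "elastic_net", "random_forest", "gradient_boost", "svm")


@dataclass
class ClockConfig:
    """Training configuration for the phenotypic clock.

    ``age_bin_days`` controls both the stratification bins of the
    cross-validation splitter and the age groups of the imputer.  SMOGN
    settings follow the common defaults: rows whose age-bin relevance
    exceeds ``rarity_threshold`` are rare; synthetic rows interpolate a
    rare row toward one of its ``k_neighbors`` nearest rare neighbors,
    with Gaussian noise (scale ``noise_scale`` x feature SD) when the
    neighbor is distant.
    """

    model_family: str = "gradient_boost"
    hyperparams: dict | None = None     # fixed values; None -> small CV grid
    folds: int = 5
    age_bin_days: float = 5.0
    oversample: str = "none"            # "none" | "smogn"
    rarity_threshold: float = 0.8
    k_neighbors: int = 5
    noise_scale: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model_family not in MODEL_FAMILIES:
            raise ValueError(f"model_family must be one of {MODEL_FAMILIES}")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.age_bin_days <= 0:
            raise ValueError("age_bin_days must be > 0")
        if self.oversample not in ("none", "smogn"):
            raise ValueError("oversample must be 'none' or 'smogn'")


# ---------------------------------------------------------------------------
# imputation

class GroupMeanImputer:
    """Replace missing cells by the feature mean within an age group.

    Age groups are equal-width bins of ``bin_days``.  A group with no
    observed values for a feature falls back to the feature's global
    mean.  A feature with no observed values anywhere is an error.
    """

    def __init__(self, bin_days: float = 5.0):
        self.bin_days = bin_days
        self.group_means_: pd.DataFrame | None = None
        self.global_means_: pd.Series | None = None

    def _bins(self, ages) -> np.ndarray:
        return np.floor(np.asarray(ages, dtype=float) / self.bin_days).astype(int)

    def fit(self, X: pd.DataFrame, ages) -> "GroupMeanImputer":
        if len(X) != len(np.asarray(ages)):
            raise ValueError("ages must be known for every row")
        all_missing = [c for c in X.columns if X[c].isna().all()]
        if all_missing:
            raise ValueError(f"features missing everywhere, cannot impute: {all_missing}")
        bins = self._bins(ages)
        self.group_means_ = X.groupby(bins).mean()
        self.global_means_ = X.mean()
        return self

    def transform(self, X: pd.DataFrame, ages=None) -> pd.DataFrame:
        if self.group_means_ is None:
            raise RuntimeError("imputer is not fitted")
        out = X.copy()
        if ages is None:
            return out.fillna(self.global_means_)
        bins = self._bins(ages)
        for b in np.unique(bins):
            sel = bins == b
            if b in self.group_means_.index:
                fill = self.group_means_.loc[b].fillna(self.global_means_)
            else:
                fill = self.global_means_
            out.loc[sel] = out.loc[sel].fillna(fill)
        return out

    def fit_transform(self, X: pd.DataFrame, ages) -> pd.DataFrame:
        return self.fit(X, ages).transform(X, ages)


def impute(features: pd.DataFrame, ages, bin_days: float = 5.0) -> pd.DataFrame:
    """Convenience one-shot group-mean imputation (see GroupMeanImputer)."""
    return GroupMeanImputer(bin_days).fit_transform(features, ages)


# ---------------------------------------------------------------------------
# SMOGN oversampling

def resample_smogn(
    X,
    y,
    config: ClockConfig | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """SMOGN oversampling for imbalanced regression targets.

    Target rarity is measured by a histogram density over ``y``:
    relevance(bin) = 1 - count/max_count; bins with relevance above the
    rarity threshold are rare.  Rare bins are topped up toward the
    median count of common bins by synthesizing rows: a rare row is
    interpolated toward one of its k nearest rare neighbors when that
    neighbor is close (SMOTER step) and jittered with Gaussian noise
    when it is distant.  Original rows are never altered; output size
    >= input size; fully seeded.
    """
    if config is None:
        config = ClockConfig()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    is_frame = isinstance(X, pd.DataFrame)
    Xf = X.reset_index(drop=True) if is_frame else pd.DataFrame(np.asarray(X, dtype=float))
    yv = np.asarray(y, dtype=float)
    n = len(Xf)
    if n != len(yv):
        raise ValueError("X and y lengths differ")
    if n < 2:
        warnings.warn("SMOGN needs at least 2 rows; returning input unchanged")
        return Xf.copy(), yv.copy()

    n_bins = max(3, min(15, int(np.sqrt(n))))
    counts, edges = np.histogram(yv, bins=n_bins)
    occupied = counts > 0
    relevance = 1.0 - counts / counts.max()
    rare_bins = np.where(occupied & (relevance > config.rarity_threshold))[0]
    if rare_bins.size == 0:
        return Xf.copy(), yv.copy()
    common_counts = counts[occupied & (relevance <= config.rarity_threshold)]
    target = int(np.median(common_counts)) if common_counts.size else int(counts.max())

    bin_of = np.clip(np.digitize(yv, edges[1:-1]), 0, n_bins - 1)
    rare_mask = np.isin(bin_of, rare_bins)
    rare_idx = np.where(rare_mask)[0]

    Xv = Xf.to_numpy(dtype=float)
    sd = Xv.std(axis=0)
    sd[sd == 0] = 1.0
    y_sd = yv.std() or 1.0
    Xr = Xv[rare_idx] / sd  # standardized for neighbor search

    new_X, new_y = [], []
    for b in rare_bins:
        members = np.where(bin_of == b)[0]
        deficit = target - members.size
        for _ in range(max(deficit, 0)):
            i = rng.choice(members)
            ri = np.where(rare_idx == i)[0][0]
            d = np.linalg.norm(Xr - Xr[ri], axis=1)
            d[ri] = np.inf
            k = min(config.k_neighbors, rare_idx.size - 1)
            if k < 1:
                xi = Xv[i] + rng.normal(0.0, config.noise_scale * sd)
                yi = yv[i] + rng.normal(0.0, config.noise_scale * y_sd)
            else:
                nn = np.argsort(d)[:k]
                j_local = rng.choice(nn)
                j = rare_idx[j_local]
                if d[j_local] <= np.median(d[nn]):
                    u = rng.random()
                    xi = Xv[i] + u * (Xv[j] - Xv[i])
                    yi = yv[i] + u * (yv[j] - yv[i])
                else:
                    xi = Xv[i] + rng.normal(0.0, config.noise_scale * sd)
                    yi = yv[i] + rng.normal(0.0, config.noise_scale * y_sd)
            new_X.append(xi)
            new_y.append(yi)

    if not new_X:
        return Xf.copy(), yv.copy()
    X_out = pd.concat([Xf, pd.DataFrame(np.array(new_X), columns=Xf.columns)], ignore_index=True)
    y_out = np.concatenate([yv, np.array(new_y)])
    return X_out, y_out


# ---------------------------------------------------------------------------
# model zoo

def _make_model(config: ClockConfig):
    """Estimator (optionally wrapped in a small inner grid search)."""
    seed = config.seed
    fam = config.model_family
    hp = config.hyperparams
    if fam == "lasso":
        base = Pipeline([("scale", StandardScaler()), ("reg", Lasso(max_iter=10000))])
        grid = {"reg__alpha": [0.01, 0.1, 1.0]}
    elif fam == "elastic_net":
        base = Pipeline([("scale", StandardScaler()), ("reg", ElasticNet(max_iter=10000))])
        grid = {"reg__alpha": [0.01, 0.1, 1.0], "reg__l1_ratio": [0.2, 0.5, 0.8]}
    elif fam == "random_forest":
        base = RandomForestRegressor(n_estimators=100, random_state=seed, n_jobs=1)
        grid = {"max_features": ["sqrt", 1.0]}
    elif fam == "gradient_boost":
        base = GradientBoostingRegressor(random_state=seed, n_estimators=150)
        grid = {"learning_rate": [0.05, 0.1]}
    elif fam == "svm":
        base = Pipeline([("scale", StandardScaler()), ("reg", SVR(kernel="rbf"))])
        grid = {"reg__C": [1.0, 10.0]}
    else:  # pragma: no cover
        raise AssertionError(fam)
    if hp is not None:
        base = clone(base).set_params(**hp) if hp else clone(base)
        return base
    return GridSearchCV(base, grid, cv=3, scoring="neg_root_mean_squared_error", n_jobs=1)


def _adjusted_r2(r2: float, n: int, p: int) -> float:
    if n - p - 1 <= 0:
        return float("nan")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def _strat_bins(ages: np.ndarray, bin_days: float, folds: int) -> np.ndarray:
    """Equal-width age bins, sparse bins merged so each holds >= folds rows."""
    bins = np.floor(ages / bin_days).astype(int)
    uniq = np.sort(np.unique(bins))
    remap = {b: b for b in uniq}
    counts = {b: int((bins == b).sum()) for b in uniq}
    for b in uniq[::-1]:
        if counts[b] < folds:
            lower = [u for u in uniq if u < b and counts.get(u, 0) > 0]
            tgt = lower[-1] if lower else next((u for u in uniq if counts.get(u, 0) > 0 and u != b), b)
            if tgt != b:
                counts[tgt] += counts[b]
                counts[b] = 0
                for k, v in remap.items():
                    if v == b:
                        remap[k] = tgt
    return np.array([remap[b] for b in bins])


# ---------------------------------------------------------------------------
# the clock

class PhenotypicClock:
    """Age-regression model over a feature table (statsmodels-style).

    Build from a feature matrix and chronological ages, then ``fit()``
    to obtain a :class:`ClockResults` carrying cross-validated metrics,
    the final refit model, and prediction utilities.
    """

    def __init__(self, features: pd.DataFrame, ages, config: ClockConfig | None = None):
        self.config = config or ClockConfig()
        feats = features.select_dtypes("number")
        dropped = [c for c in features.columns if c not in feats.columns]
        if dropped:
            warnings.warn(f"ignoring non-numeric columns: {dropped}")
        self.features = feats.reset_index(drop=True)
        self.ages = np.asarray(ages, dtype=float)
        if len(self.features) != len(self.ages):
            raise ValueError("features and ages lengths differ")
        if len(self.features) < self.config.folds * 2:
            raise ValueError("too few rows for the requested number of folds")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, age_column: str = "age_days", config: ClockConfig | None = None):
        ages = df[age_column].to_numpy(dtype=float)
        drop = [age_column] + [c for c in ("track_id", "n_frames", "cohort", "condition") if c in df.columns]
        return cls(df.drop(columns=drop), ages, config)

    def fit(self) -> "ClockResults":
        """Cross-validated training followed by a refit on all rows.

        Imputation and SMOGN are fitted/applied inside each training
        fold only; held-out rows are imputed with the training fold's
        means and never influence preprocessing (leakage guard).
        """
        cfg = self.config
        X, y = self.features, self.ages
        labels = _strat_bins(y, cfg.age_bin_days, cfg.folds)
        skf = StratifiedKFold(n_splits=cfg.folds, shuffle=True, random_state=cfg.seed)
        rng = np.random.default_rng(cfg.seed)

        fold_rows = []
        fold_models, fold_imputers, fold_tests = [], [], []
        oof_pred = np.full(len(y), np.nan)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            splits = list(skf.split(X, labels))
        for fold, (tr, te) in enumerate(splits):
            imp = GroupMeanImputer(cfg.age_bin_days).fit(X.iloc[tr], y[tr])
            Xtr = imp.transform(X.iloc[tr], y[tr])
            ytr = y[tr]
            if cfg.oversample == "smogn":
                Xtr, ytr = resample_smogn(Xtr, ytr, cfg, rng)
            model = _make_model(cfg)
            model.fit(Xtr, ytr)
            Xte = imp.transform(X.iloc[te], y[te])
            pred = model.predict(Xte)
            oof_pred[te] = pred
            rmse = float(np.sqrt(mean_squared_error(y[te], pred)))
            r2 = float(r2_score(y[te], pred))
            fold_rows.append({"fold": fold, "n_test": len(te), "rmse": rmse, "r2": r2})
            fold_models.append(model)
            fold_imputers.append(imp)
            fold_tests.append(te)

        p = X.shape[1]
        heldout_r2 = float(r2_score(y, oof_pred))
        heldout_rmse = float(np.sqrt(mean_squared_error(y, oof_pred)))

        final_imp = GroupMeanImputer(cfg.age_bin_days).fit(X, y)
        Xall = final_imp.transform(X, y)
        yall = y
        if cfg.oversample == "smogn":
            Xall_fit, yall_fit = resample_smogn(Xall, yall, cfg, rng)
        else:
            Xall_fit, yall_fit = Xall, yall
        final_model = _make_model(cfg)
        final_model.fit(Xall_fit, yall_fit)
        train_pred = final_model.predict(Xall)
        train_r2 = float(r2_score(y, train_pred))
        train_rmse = float(np.sqrt(mean_squared_error(y, train_pred)))

        metrics = {
            "heldout_r2": heldout_r2,
            "heldout_adj_r2": _adjusted_r2(heldout_r2, len(y), p),
            "heldout_rmse": heldout_rmse,
            "train_r2": train_r2,
            "train_adj_r2": _adjusted_r2(train_r2, len(y), p),
            "train_rmse": train_rmse,
        }
        return ClockResults(
            config=cfg,
            feature_names=list(X.columns),
            imputer=final_imp,
            model=final_model,
            metrics=metrics,
            cv_table=pd.DataFrame(fold_rows),
            oof_predictions=pd.DataFrame({"age": y, "predicted": oof_pred}),
            _train_X=X,
            _train_y=y,
            _fold_models=fold_models,
            _fold_imputers=fold_imputers,
            _fold_tests=fold_tests,
        )


@dataclass
class PhenotypicAgeResult:
    """Per-row phenotypic ages and per-condition aging summaries."""

    table: pd.DataFrame         # predicted, chronological, delta, condition
    by_condition: pd.DataFrame  # n, mean_delta, sem_delta, slope, slope_se


@dataclass
class ClockResults:
    """Fitted clock: estimates, held-out diagnostics, prediction methods."""

    config: ClockConfig
    feature_names: list[str]
    imputer: GroupMeanImputer
    model: object
    metrics: dict[str, float]
    cv_table: pd.DataFrame
    oof_predictions: pd.DataFrame
    _train_X: pd.DataFrame = field(repr=False, default=None)
    _train_y: np.ndarray = field(repr=False, default=None)
    _fold_models: list = field(repr=False, default_factory=list)
    _fold_imputers: list = field(repr=False, default_factory=list)
    _fold_tests: list = field(repr=False, default_factory=list)

    # -- prediction ---------------------------------------------------------
    def _check_columns(self, features: pd.DataFrame) -> pd.DataFrame:
        unknown = [c for c in features.columns if c not in self.feature_names]
        if unknown:
            raise ValueError(f"unknown feature columns: {unknown}")
        missing = [c for c in self.feature_names if c not in features.columns]
        if missing:
            raise ValueError(f"missing feature columns: {missing}")
        return features[self.feature_names]

    def predict(self, features: pd.DataFrame, ages=None) -> np.ndarray:
        """Predict phenotypic age; missing cells use stored imputation means."""
        X = self._check_columns(features)
        X = self.imputer.transform(X, ages)
        return np.asarray(self.model.predict(X), dtype=float)

    def phenotypic_age(self, features: pd.DataFrame, chronological, condition=None) -> PhenotypicAgeResult:
        """Predicted age, delta = predicted - chronological, and per-
        condition mean delta +/- SEM with the origin-forced slope."""
        chron = np.asarray(chronological, dtype=float)
        pred = self.predict(features, ages=chron)
        cond = np.asarray(condition) if condition is not None else np.array(["all"] * len(pred))
        table = pd.DataFrame({
            "predicted": pred, "chronological": chron,
            "delta": pred - chron, "condition": cond,
        })
        rows = []
        for c, sub in table.groupby("condition"):
            slope, se = aging_rate_slope(sub["predicted"], sub["chronological"])
            d = sub["delta"].to_numpy()
            sem = float(d.std(ddof=1) / np.sqrt(len(d))) if len(d) > 1 else float("nan")
            rows.append({"condition": c, "n": len(d), "mean_delta": float(d.mean()),
                         "sem_delta": sem, "slope": slope, "slope_se": se})
        return PhenotypicAgeResult(table=table, by_condition=pd.DataFrame(rows))

    # -- importance ---------------------------------------------------------
    def feature_importance(self, method: str = "permutation", n_repeats: int = 5) -> pd.DataFrame:
        """Incremental held-out error from neutralizing each feature.

        Two dialects: ``permutation`` shuffles one column within each
        held-out fold (cheap, no refit); ``refit`` reruns the CV with
        the feature excluded (expensive, measures redundancy).  Both
        report the increase in held-out RMSE; higher = more important.
        """
        if method not in ("permutation", "refit"):
            raise ValueError("method must be 'permutation' or 'refit'")
        X, y = self._train_X, self._train_y
        base = self.metrics["heldout_rmse"]
        rng = np.random.default_rng(self.config.seed)
        rows = []
        if method == "permutation":
            for feat in self.feature_names:
                increases = []
                for _ in range(n_repeats):
                    oof = np.full(len(y), np.nan)
                    for model, imp, te in zip(self._fold_models, self._fold_imputers, self._fold_tests):
                        Xte = imp.transform(X.iloc[te], y[te]).copy()
                        Xte[feat] = rng.permutation(Xte[feat].to_numpy())
                        oof[te] = model.predict(Xte)
                    increases.append(np.sqrt(mean_squared_error(y, oof)) - base)
                rows.append({"feature": feat, "importance": float(np.mean(increases))})
        else:
            for feat in self.feature_names:
                sub_cfg = ClockConfig(**{**self.config.__dict__})
                sub = PhenotypicClock(X.drop(columns=[feat]), y, sub_cfg).fit()
                rows.append({"feature": feat, "importance": sub.metrics["heldout_rmse"] - base})
        out = pd.DataFrame(rows).sort_values("importance", ascending=False, ignore_index=True)
        return out

    # -- reporting ----------------------------------------------------------
    def summary(self) -> str:
        m = self.metrics
        lines = [
            f"Phenotypic clock [{self.config.model_family}] "
            f"(n={len(self._train_y)}, p={len(self.feature_names)}, {self.config.folds}-fold CV, "
            f"oversample={self.config.oversample})",
            f"  held-out: adj R2 = {m['heldout_adj_r2']:.4f}  R2 = {m['heldout_r2']:.4f}  RMSE = {m['heldout_rmse']:.3f} d",
            f"  train:    adj R2 = {m['train_adj_r2']:.4f}  R2 = {m['train_r2']:.4f}  RMSE = {m['train_rmse']:.3f} d",
        ]
        return "\n".join(lines)

    def plot_predicted_vs_chronological(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        d = self.oof_predictions
        ax.scatter(d["age"], d["predicted"], s=8, alpha=0.5)
        lim = [d["age"].min(), d["age"].max()]
        ax.plot(lim, lim, color="C3", lw=1, label="perfect prediction")
        ax.set_xlabel("chronological age (days)")
        ax.set_ylabel("predicted age (days)")
        ax.legend()
        return ax


def aging_rate_slope(predicted, chronological) -> tuple[float, float]:
    """Origin-forced regression slope of predicted on chronological age.

    slope = sum(x*y) / sum(x**2) with x = chronological, y = predicted;
    the SE comes from the no-intercept residual variance,
    sqrt(RSS/(n-1)) / sqrt(sum(x**2)).
    """
    y = np.asarray(predicted, dtype=float)
    x = np.asarray(chronological, dtype=float)
    if len(x) != len(y) or len(x) < 2:
        raise ValueError("need >= 2 paired observations")
    sxx = float(np.sum(x * x))
    if sxx == 0:
        raise ValueError("chronological ages are all zero; slope undefined")
    slope = float(np.sum(x * y) / sxx)
    resid = y - slope * x
    se = float(np.sqrt(np.sum(resid**2) / (len(x) - 1) / sxx))
    return slope, se
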