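"""Random-forest meteorological normalization ("deweathering").

A per-pollutant regression forest is trained to predict the daily
concentration from three time features (unix_time, julian_day, weekday —
proxies for long-term, seasonal and weekly emission variability) and
fourteen meteorological features. The weather-normalized series is then
obtained by Monte Carlo: for each of ``n_resamples`` passes, every analysis
day keeps its own time features but receives the complete met row of a day
drawn uniformly at random from a long historical climatology; the per-day
predictions are averaged arithmetically over the passes. What survives the
averaging is the emission-driven signal; weather-driven variability is
integrated out.

Whole met rows are drawn (all variables from the same climatology day) so
cross-variable correlation is preserved — drawing variables independently
would produce physically incoherent weather. Time features are held fixed
during resampling; resampling them would erase exactly the emission signal
the method is designed to isolate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import joblib
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.ensemble import RandomForestRegressor
from sklearn.utils.validation import check_is_fitted, check_random_state

from .ingest import MET_FEATURES, TIME_FEATURES, Climatology

MODEL_FORMAT_VERSION = 1


class EvalMetrics(NamedTuple):
    r: float
    nmse: float
    rmse: float


def evaluate(predicted, observed) -> EvalMetrics:
    """Agreement metrics between predicted and observed concentrations.

    r is the Pearson correlation; RMSE the root mean squared error; NMSE the
    mean squared error normalized by mean(observed) × mean(predicted).
    """
    p = np.asarray(predicted, float)
    o = np.asarray(observed, float)
    if p.shape != o.shape or p.ndim != 1:
        raise ValueError("predicted and observed must be equal-length 1-D vectors")
    if not (np.isfinite(p).all() and np.isfinite(o).all()):
        raise ValueError("non-finite values in evaluate() input")
    if p.std() == 0 or o.std() == 0:
        r = float("nan")  # correlation undefined for a constant vector
    else:
        r = float(np.corrcoef(p, o)[0, 1])
    mse = float(np.mean((p - o) ** 2))
    rmse = math.sqrt(mse)
    nmse = mse / (float(o.mean()) * float(p.mean()))
    return EvalMetrics(r=r, nmse=nmse, rmse=rmse)


@dataclass
class FitReport:
    """Cross-validated skill and feature importance of a fitted model."""

    r: float
    nmse: float
    rmse: float
    importances: pd.Series  # mean decrease in impurity, normalized to sum to 1
    cv_folds: int

    def __post_init__(self) -> None:
        assert abs(float(self.importances.sum()) - 1.0) < 1e-9


@dataclass
class DeweatherResult:
    """Weather-normalized daily series plus resampling metadata.

    ``frame`` has columns ``deweathered`` (mean over resample passes, clipped
    at zero) and ``se`` (Monte Carlo standard error of that mean), indexed by
    date; ``observed`` is included when the input feature table carried a
    target column.
    """

    frame: pd.DataFrame
    n_resamples: int
    seed: int | None
    climatology_period: tuple[pd.Timestamp, pd.Timestamp]

    @property
    def deweathered(self) -> pd.Series:
        return self.frame["deweathered"]


class MeteoNormalizer(BaseEstimator, RegressorMixin):
    """Per-pollutant regression forest with a weather-resampling normalizer.

    Parameters
    ----------
    n_estimators : int
        Trees in the forest (default 300).
    min_samples_leaf : int
        Minimum node size (default 5).
    max_features : int, float, str or None
        Features tried per split; the default ``"third"`` uses ⌈p/3⌉, the
        conventional regression-forest choice.
    train_fraction : float
        Share of rows used to train the final forest (default 0.70); the
        remainder is a holdout whose metrics land in ``holdout_metrics_``.
    cv_folds : int
        Folds for the cross-validated :class:`FitReport` (default 5).
    blocked_cv : bool
        Contiguous time-block folds (default) rather than random rows, to
        limit autocorrelation leakage between folds.
    random_state : int or None
        Seed for the split and the forest.

    Attributes
    ----------
    forest_ : RandomForestRegressor
    feature_names_in_ : list of str
    fit_report_ : FitReport
    holdout_metrics_ : EvalMetrics
    """

    def __init__(self, n_estimators: int = 300, min_samples_leaf: int = 5,
                 max_features="third", train_fraction: float = 0.70,
                 cv_folds: int = 5, blocked_cv: bool = True,
                 random_state=None):
        self.n_estimators = n_estimators
        self.min_samples_leaf = min_samples_leaf
        self.max_features = max_features
        self.train_fraction = train_fraction
        self.cv_folds = cv_folds
        self.blocked_cv = blocked_cv
        self.random_state = random_state

    # -- helpers ----------------------------------------------------------

    @staticmethod
    def _feature_frame(X: pd.DataFrame) -> pd.DataFrame:
        """Strip bookkeeping columns from a feature table."""
        drop = [c for c in ("complete", "target") if c in X.columns]
        return X.drop(columns=drop)

    def _make_forest(self, n_features: int, seed) -> RandomForestRegressor:
        max_features = self.max_features
        if max_features == "third":
            max_features = max(1, math.ceil(n_features / 3))
        return RandomForestRegressor(
            n_estimators=self.n_estimators,
            min_samples_leaf=self.min_samples_leaf,
            max_features=max_features,
            random_state=seed,
            n_jobs=1,
        )

    # -- estimator API -----------------------------------------------------

    def fit(self, X: pd.DataFrame, y=None) -> "MeteoNormalizer":
        """Fit the forest and compute the cross-validated fit report.

        ``X`` is a feature table from :func:`metnorm.ingest.build_features`;
        ``y`` may be omitted if the table carries a ``target`` column.
        """
        if not isinstance(X, pd.DataFrame):
            raise TypeError("X must be a feature-table DataFrame")
        if y is None:
            if "target" not in X.columns:
                raise ValueError("no y given and no 'target' column in X")
            y = X["target"]
        y = pd.Series(np.asarray(y, float), index=X.index)
        feats = self._feature_frame(X)

        keep = feats.notna().all(axis=1) & y.notna()
        feats, y = feats[keep], y[keep]
        n = len(feats)
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if n < self.cv_folds:
            raise ValueError(f"{n} rows < {self.cv_folds} CV folds")
        if float(np.std(y)) == 0.0:
            raise ValueError("constant target: nothing to model")

        rng = check_random_state(self.random_state)
        self.feature_names_in_ = list(feats.columns)
        Xmat = feats.to_numpy(float)
        yvec = y.to_numpy(float)

        # 70/30 split for the production forest + holdout metrics
        perm = rng.permutation(n)
        n_train = max(1, int(round(self.train_fraction * n)))
        train_idx, test_idx = perm[:n_train], perm[n_train:]
        self.forest_ = self._make_forest(len(self.feature_names_in_),
                                         rng.randint(np.iinfo(np.int32).max))
        self.forest_.fit(Xmat[train_idx], yvec[train_idx])
        if len(test_idx) >= 3 and np.std(yvec[test_idx]) > 0:
            self.holdout_metrics_ = evaluate(self.forest_.predict(Xmat[test_idx]),
                                             yvec[test_idx])
        else:
            self.holdout_metrics_ = None

        # k-fold CV on all rows for the fit report
        if self.blocked_cv:
            fold_indices = np.array_split(np.arange(n), self.cv_folds)
        else:
            shuffled = rng.permutation(n)
            fold_indices = np.array_split(shuffled, self.cv_folds)
        cv_pred = np.empty(n)
        for fold in fold_indices:
            mask = np.ones(n, bool)
            mask[fold] = False
            fold_forest = self._make_forest(len(self.feature_names_in_),
                                            rng.randint(np.iinfo(np.int32).max))
            fold_forest.fit(Xmat[mask], yvec[mask])
            cv_pred[fold] = fold_forest.predict(Xmat[fold])
        metrics = evaluate(cv_pred, yvec)

        imp = pd.Series(self.forest_.feature_importances_,
                        index=self.feature_names_in_)
        imp = imp / imp.sum()
        self.fit_report_ = FitReport(r=metrics.r, nmse=metrics.nmse,
                                     rmse=metrics.rmse, importances=imp,
                                     cv_folds=self.cv_folds)
        self.n_features_in_ = len(self.feature_names_in_)
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "forest_")
        if isinstance(X, pd.DataFrame):
            X = self._feature_frame(X)[self.feature_names_in_].to_numpy(float)
        return self.forest_.predict(X)

    # -- normalization -----------------------------------------------------

    def deweather(self, features: pd.DataFrame, climatology: Climatology,
                  n_resamples: int = 1000, random_state=None,
                  chunk_size: int = 25) -> DeweatherResult:
        """Weather-normalize the days in ``features``.

        Each resample pass assigns every analysis day the full met row of a
        uniformly drawn climatology day (time features unchanged), predicts,
        and the passes are averaged arithmetically per day. Negative means
        are clipped to zero (a no-op in practice for forests).
        """
        check_is_fitted(self, "forest_")
        if n_resamples < 1:
            raise ValueError("n_resamples must be >= 1")
        feats = self._feature_frame(features)
        met_cols = [c for c in self.feature_names_in_ if c not in TIME_FEATURES]
        missing = [c for c in met_cols if c not in climatology.met.columns]
        if missing:
            raise ValueError(f"climatology lacks model features: {missing}")
        pool = climatology.met[met_cols].to_numpy(float)
        if np.isnan(pool).any():
            raise ValueError("climatology contains missing values; gap-fill first")
        n_pool = len(pool)
        if n_pool == 0:
            raise ValueError("empty climatology")

        time_cols = [c for c in self.feature_names_in_ if c in TIME_FEATURES]
        time_mat = feats[time_cols].to_numpy(float)
        n_days = len(feats)
        col_order = {name: i for i, name in enumerate(self.feature_names_in_)}

        rng = np.random.default_rng(random_state)
        total = np.zeros(n_days)
        total_sq = np.zeros(n_days)
        done = 0
        while done < n_resamples:
            m = min(chunk_size, n_resamples - done)
            draws = rng.integers(0, n_pool, size=(m, n_days))
            big = np.empty((m * n_days, len(self.feature_names_in_)))
            for j, name in enumerate(time_cols):
                big[:, col_order[name]] = np.tile(time_mat[:, j], m)
            met_rows = pool[draws.ravel()]
            for j, name in enumerate(met_cols):
                big[:, col_order[name]] = met_rows[:, j]
            pred = self.forest_.predict(big).reshape(m, n_days)
            total += pred.sum(axis=0)
            total_sq += (pred**2).sum(axis=0)
            done += m

        mean = total / n_resamples
        if n_resamples > 1:
            var = (total_sq - n_resamples * mean**2) / (n_resamples - 1)
            se = np.sqrt(np.maximum(var, 0.0) / n_resamples)
        else:
            se = np.full(n_days, np.nan)
        frame = pd.DataFrame(
            {"deweathered": np.clip(mean, 0.0, None), "se": se},
            index=features.index,
        )
        if "target" in features.columns:
            frame.insert(0, "observed", features["target"].to_numpy(float))
        return DeweatherResult(
            frame=frame,
            n_resamples=n_resamples,
            seed=random_state if isinstance(random_state, (int, np.integer)) else None,
            climatology_period=climatology.period,
        )


def save_model(model: MeteoNormalizer, path) -> None:
    """Persist a fitted model with an embedded feature-schema manifest."""
    check_is_fitted(model, "forest_")
    joblib.dump(
        {
            "format_version": MODEL_FORMAT_VERSION,
            "params": model.get_params(),
            "feature_names": model.feature_names_in_,
            "forest": model.forest_,
            "fit_report": model.fit_report_,
            "holdout_metrics": model.holdout_metrics_,
        },
        path,
    )


def load_model(path) -> MeteoNormalizer:
    blob = joblib.load(path)
    if blob.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model format: {blob.get('format_version')}")
    model = MeteoNormalizer(**blob["params"])
    model.feature_names_in_ = blob["feature_names"]
    model.forest_ = blob["forest"]
    model.fit_report_ = blob["fit_report"]
    model.holdout_metrics_ = blob["holdout_metrics"]
    model.n_features_in_ = len(model.feature_names_in_)
    return model
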