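"""Vascular-age regression model and its evaluation statistics.

The central object is :class:`VascularAgeModel`, a data-bound model in the
statsmodels style: it is constructed from a per-subject feature table (78
morphological features) and the subjects' chronological ages, and its
``fit``/``fit_loocv`` methods return results objects carrying the
estimates, agreement statistics and a ``summary()`` table.

Evaluation follows the standard protocol for a single-cohort age
regressor: leave-one-out cross-validation in which, for every fold, the
remaining subjects are split 8:2 into training and validation sets
stratified by age decade, a robust scaler (per-feature median/IQR) is fit
on the training portion only, and the held-out subject is predicted by the
early-stopped network.  Accuracy is summarised by RMSE, the Pearson
correlation between estimated and true age, the coefficient of
determination, and Bland-Altman 95% limits of agreement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.preprocessing import RobustScaler

from .ann import AnnConfig, DenseRegressor
from .features import FEATURE_NAMES

__all__ = [
    "VascularAgeModel",
    "VascularAgeResults",
    "LoocvResults",
    "RegressionMetrics",
    "BlandAltman",
    "robust_scale_fit",
    "robust_scale_apply",
    "regression_metrics",
    "bland_altman",
    "feature_age_correlations",
    "stratified_split",
]


# ---------------------------------------------------------------------------
# robust scaling
# ---------------------------------------------------------------------------

def robust_scale_fit(train_features: np.ndarray | pd.DataFrame) -> RobustScaler:
    """Fit a per-feature (x - median)/IQR scaler on training data only.

    Zero-IQR (constant) features are scaled by 1 and flagged with a warning.
    """
    X = np.asarray(train_features, dtype=float)
    if X.size == 0:
        raise ValueError("empty training table")
    scaler = RobustScaler().fit(X)
    q75, q25 = np.percentile(X, [75, 25], axis=0)
    if np.any(q75 - q25 == 0):
        warnings.warn(
            "zero-IQR feature(s) scaled by 1 (centered only)", stacklevel=2
        )
    return scaler


def robust_scale_apply(
    scaler: RobustScaler, features: np.ndarray | pd.DataFrame
) -> np.ndarray:
    """Apply previously fit scaler parameters unchanged."""
    return scaler.transform(np.asarray(features, dtype=float))


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegressionMetrics:
    rmse: float
    pearson_r: float
    p_value: float
    r_squared: float
    r_defined: bool


@dataclass(frozen=True)
class BlandAltman:
    mean_diff: float
    loa_upper: float
    loa_lower: float


def regression_metrics(age_true, age_est) -> RegressionMetrics:
    """RMSE, Pearson r (two-sided p) and R^2 = 1 - SSres/SStot.

    With zero variance in either vector the correlation is undefined and
    flagged (``r_defined=False``, r and p reported as NaN).
    """
    yt = np.asarray(age_true, dtype=float).ravel()
    ye = np.asarray(age_est, dtype=float).ravel()
    if yt.size != ye.size:
        raise ValueError("length mismatch")
    if yt.size < 3:
        raise ValueError("need at least 3 pairs")
    rmse = float(np.sqrt(np.mean((ye - yt) ** 2)))
    sstot = float(np.sum((yt - yt.mean()) ** 2))
    ssres = float(np.sum((yt - ye) ** 2))
    r2 = 1.0 - ssres / sstot if sstot > 0 else np.nan
    if np.std(yt) == 0 or np.std(ye) == 0:
        return RegressionMetrics(rmse, np.nan, np.nan, r2, False)
    r, p = stats.pearsonr(yt, ye)
    return RegressionMetrics(rmse, float(r), float(p), r2, True)


def bland_altman(age_true, age_est) -> BlandAltman:
    """Mean difference (est - true) and 95% limits of agreement
    mean +/- 1.96 * sd (sample sd, n-1 denominator)."""
    yt = np.asarray(age_true, dtype=float).ravel()
    ye = np.asarray(age_est, dtype=float).ravel()
    if yt.size != ye.size:
        raise ValueError("length mismatch")
    if yt.size < 3:
        raise ValueError("need at least 3 pairs")
    d = ye - yt
    mean = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return BlandAltman(mean, mean + 1.96 * sd, mean - 1.96 * sd)


def feature_age_correlations(
    features: pd.DataFrame, ages: np.ndarray | pd.Series
) -> pd.DataFrame:
    """Pearson correlation (with two-sided p) of every feature with age.

    One row per feature in canonical order (falling back to the table's
    column order for non-canonical tables); zero-variance features are
    flagged undefined with NaN r and p.
    """
    ages = np.asarray(ages, dtype=float).ravel()
    if len(features) != ages.size:
        raise ValueError("feature table and ages disagree in length")
    if ages.size < 3:
        raise ValueError("need at least 3 subjects")
    cols = [c for c in FEATURE_NAMES if c in features.columns]
    if not cols:
        cols = list(features.columns)
    rows = []
    for c in cols:
        x = features[c].to_numpy(dtype=float)
        if np.std(x) == 0 or np.std(ages) == 0 or not np.all(np.isfinite(x)):
            rows.append({"feature": c, "pearson_r": np.nan, "p_value": np.nan,
                         "defined": False})
        else:
            r, p = stats.pearsonr(x, ages)
            rows.append({"feature": c, "pearson_r": float(r), "p_value": float(p),
                         "defined": True})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# stratified train/validation split
# ---------------------------------------------------------------------------

def stratified_split(
    ages: np.ndarray,
    val_frac: float = 0.2,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """8:2 train/validation split with (approximately) the same age
    distribution: ages are binned by decade, bins with fewer than 2
    subjects are merged with their lower neighbour, and each bin is split
    at ``val_frac`` (rounded, at least the overall rate allows per-bin
    deviation of one subject).

    Returns (train_idx, val_idx), disjoint and covering all subjects.
    """
    ages = np.asarray(ages, dtype=float).ravel()
    if rng is None:
        rng = np.random.default_rng(0)
    bins = (ages // 10).astype(int)
    # merge decades with <2 subjects into the nearest populated lower decade
    uniq = sorted(set(bins))
    counts = {u: int(np.sum(bins == u)) for u in uniq}
    remap = {}
    prev = None
    for u in uniq:
        if counts[u] < 2 and prev is not None:
            remap[u] = prev
        else:
            remap[u] = u
            prev = u
    # a leading tiny bin merges upward
    first = uniq[0]
    if counts[first] < 2 and len(uniq) > 1:
        remap[first] = remap[uniq[1]]
    bins = np.array([remap[b] for b in bins])

    train_idx, val_idx = [], []
    for u in sorted(set(bins)):
        idx = np.nonzero(bins == u)[0]
        idx = rng.permutation(idx)
        n_val = int(round(val_frac * idx.size))
        if idx.size >= 2:
            n_val = min(max(n_val, 0), idx.size - 1)
        val_idx.extend(idx[:n_val])
        train_idx.extend(idx[n_val:])
    if not train_idx:
        raise ValueError("empty training portion")
    return np.array(sorted(train_idx)), np.array(sorted(val_idx))


# ---------------------------------------------------------------------------
# results objects
# ---------------------------------------------------------------------------

@dataclass
class VascularAgeResults:
    """A single trained network with its train/validation history."""

    model: "VascularAgeModel"
    regressor: DenseRegressor
    scaler: RobustScaler
    train_idx: np.ndarray
    val_idx: np.ndarray

    def predict(self, features: pd.DataFrame | np.ndarray) -> np.ndarray:
        """Estimated vascular age (years) for new feature rows."""
        X = robust_scale_apply(self.scaler, features)
        return self.regressor.predict(X)


@dataclass
class LoocvResults:
    """Leave-one-out evaluation: per-subject estimates plus agreement stats."""

    per_subject: pd.DataFrame  # subject_id, age_true, age_est
    metrics: RegressionMetrics
    agreement: BlandAltman

    @property
    def rmse(self) -> float:
        return self.metrics.rmse

    @property
    def pearson_r(self) -> float:
        return self.metrics.pearson_r

    @property
    def r_squared(self) -> float:
        return self.metrics.r_squared

    def summary(self) -> str:
        m, ba = self.metrics, self.agreement
        lines = [
            "Vascular age estimation - leave-one-out cross-validation",
            "=" * 58,
            f"subjects                 {len(self.per_subject):>10d}",
            f"RMSE (years)             {m.rmse:>10.2f}",
            f"Pearson r                {m.pearson_r:>10.3f}   (p = {m.p_value:.3g})",
            f"R-squared                {m.r_squared:>10.3f}",
            f"Bland-Altman mean diff   {ba.mean_diff:>10.2f}  years",
            f"95% limits of agreement  {ba.loa_lower:>10.2f} .. {ba.loa_upper:.2f} years",
        ]
        return "\n".join(lines)

    def plot_scatter(self, ax=None):
        """Estimated vs. true age scatter with the identity line."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        yt = self.per_subject["age_true"]
        ye = self.per_subject["age_est"]
        ax.scatter(yt, ye, s=12, alpha=0.7)
        lim = [min(yt.min(), ye.min()) - 2, max(yt.max(), ye.max()) + 2]
        ax.plot(lim, lim, "k--", lw=1)
        ax.set_xlabel("true age (years)")
        ax.set_ylabel("estimated age (years)")
        return ax

    def plot_bland_altman(self, ax=None):
        """Bland-Altman plot of (est - true) against the pair means."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        yt = self.per_subject["age_true"].to_numpy()
        ye = self.per_subject["age_est"].to_numpy()
        ax.scatter((yt + ye) / 2, ye - yt, s=12, alpha=0.7)
        for v, style in (
            (self.agreement.mean_diff, "-"),
            (self.agreement.loa_upper, "--"),
            (self.agreement.loa_lower, "--"),
        ):
            ax.axhline(v, color="k", ls=style, lw=1)
        ax.set_xlabel("mean of true and estimated age (years)")
        ax.set_ylabel("estimated - true age (years)")
        return ax


# ---------------------------------------------------------------------------
# the model
# ---------------------------------------------------------------------------

class VascularAgeModel:
    """Age regressor bound to a per-subject feature table.

    Parameters
    ----------
    features : DataFrame
        One row per subject; columns are the 78 canonical features (extra
        metadata columns are ignored if ``from_dataframe`` is used).
    ages : array-like
        Chronological age per subject, years.
    config : AnnConfig, optional
        Network hyperparameters (defaults are the package's optimum).
    subject_ids : sequence of str, optional

    Examples
    --------
    >>> model = VascularAgeModel.from_dataframe(table, age_col="age")
    >>> res = model.fit_loocv(seed=0)
    >>> print(res.summary())
    """

    def __init__(
        self,
        features: pd.DataFrame,
        ages,
        config: AnnConfig | None = None,
        subject_ids=None,
    ):
        features = pd.DataFrame(features)
        self.feature_names = list(features.columns)
        self.X = features.to_numpy(dtype=float)
        self.y = np.asarray(ages, dtype=float).ravel()
        if self.X.shape[0] != self.y.size:
            raise ValueError("features and ages disagree in length")
        if not np.all(np.isfinite(self.X)) or not np.all(np.isfinite(self.y)):
            raise ValueError("non-finite values in features or ages")
        self.config = config if config is not None else AnnConfig(n_input=self.X.shape[1])
        if self.config.n_input != self.X.shape[1]:
            raise ValueError(
                f"config expects {self.config.n_input} inputs, table has {self.X.shape[1]}"
            )
        if subject_ids is None:
            subject_ids = [f"S{i:04d}" for i in range(self.y.size)]
        self.subject_ids = list(subject_ids)

    @classmethod
    def from_dataframe(
        cls,
        table: pd.DataFrame,
        age_col: str = "age",
        id_col: str = "subject_id",
        config: AnnConfig | None = None,
    ) -> "VascularAgeModel":
        """Build from a tidy table holding features plus metadata columns."""
        cols = [c for c in FEATURE_NAMES if c in table.columns]
        if not cols:
            meta = {age_col, id_col, "n_beats"}
            cols = [c for c in table.columns if c not in meta]
        ids = table[id_col] if id_col in table.columns else None
        return cls(table[cols], table[age_col].to_numpy(), config=config,
                   subject_ids=None if ids is None else list(ids))

    # -- single fit ------------------------------------------------------
    def fit(self, seed: int | None = None) -> VascularAgeResults:
        """Train once on a stratified 8:2 train/validation split."""
        cfg = self.config if seed is None else self.config.with_seed(seed)
        rng = np.random.default_rng(cfg.seed)
        train_idx, val_idx = stratified_split(self.y, 0.2, rng)
        scaler = robust_scale_fit(self.X[train_idx])
        reg = DenseRegressor(cfg)
        reg.fit(
            robust_scale_apply(scaler, self.X[train_idx]), self.y[train_idx],
            robust_scale_apply(scaler, self.X[val_idx]), self.y[val_idx],
        )
        return VascularAgeResults(self, reg, scaler, train_idx, val_idx)

    # -- LOOCV -----------------------------------------------------------
    def _fit_fold(
        self, test_index: int, fold_seed: int
    ) -> tuple[DenseRegressor, RobustScaler, float]:
        """Train one LOOCV fold (everything except ``test_index``) and
        predict the held-out subject.

        The scaler and the early-stopping signal see only the fold's own
        train/validation rows, never the test subject.
        """
        mask = np.ones(self.y.size, dtype=bool)
        mask[test_index] = False
        X_dev, y_dev = self.X[mask], self.y[mask]
        rng = np.random.default_rng(fold_seed)
        tr, va = stratified_split(y_dev, 0.2, rng)
        with warnings.catch_warnings():
            # constant features are reported once for the whole run by
            # fit_loocv, not once per fold
            warnings.filterwarnings("ignore", message="zero-IQR")
            scaler = robust_scale_fit(X_dev[tr])
        reg = DenseRegressor(self.config.with_seed(fold_seed))
        reg.fit(
            robust_scale_apply(scaler, X_dev[tr]), y_dev[tr],
            robust_scale_apply(scaler, X_dev[va]), y_dev[va],
        )
        pred = float(reg.predict(robust_scale_apply(scaler, self.X[[test_index]]))[0])
        return reg, scaler, pred

    def fit_loocv(self, seed: int = 0) -> LoocvResults:
        """Leave-one-out cross-validation over the bound cohort.

        Every subject is held out exactly once; per fold the remaining
        subjects are split 8:2 (age-decade stratified), the robust scaler
        and the network are fit inside the fold, and the held-out subject
        is predicted.  Requires at least 10 subjects.
        """
        n = self.y.size
        if n < 10:
            raise ValueError("LOOCV needs at least 10 subjects")
        q75, q25 = np.percentile(self.X, [75, 25], axis=0)
        if np.any(q75 - q25 == 0):
            flat = [self.feature_names[i] for i in np.nonzero(q75 - q25 == 0)[0]]
            warnings.warn(
                f"feature(s) with zero IQR scaled by 1 throughout LOOCV: {flat[:5]}",
                stacklevel=2,
            )
        preds = np.empty(n)
        for i in range(n):
            fold_seed = (int(seed) * 100003 + i) % (2**31 - 1)
            _, _, preds[i] = self._fit_fold(i, fold_seed)
        per_subject = pd.DataFrame(
            {"subject_id": self.subject_ids, "age_true": self.y, "age_est": preds}
        )
        return LoocvResults(
            per_subject=per_subject,
            metrics=regression_metrics(self.y, preds),
            agreement=bland_altman(self.y, preds),
        )
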