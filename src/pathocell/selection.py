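"""Key-parameter selection: correlation of features with tumour cellularity.

The selection procedure aggregates the labelled nucleus table on the
11-point cellularity grid (0, 0.1, ..., 1.0), regresses each feature's
level means on the grid, cross-checks the strongly correlated features
(|r| >= 0.80 by default) against an L1-regularised (lasso) fit on the raw
rows, removes near-duplicate features, and emits the surviving set ranked
by |r|. The classifier module consumes the resulting feature manifest.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.linear_model import Lasso, LassoCV
from sklearn.model_selection import KFold
from sklearn.utils.validation import check_is_fitted

from .errors import InsufficientLevelsError

TC_GRID = np.round(np.arange(0.0, 1.05, 0.1), 1)

#: Default 22-strong key-parameter manifest, mirroring the feature families
#: that correlate most strongly with cellularity: nucleus shape, regional
#: nuclei density and HSV histograms at the smallest window, and global
#: colour/concentration summaries. Lets the classifier run without
#: re-running selection on a labelled table.
DEFAULT_KEY_FEATURES: list[str] = [
    "eccentricity",
    "roundness",
    "major_axis",
    "minor_axis",
    "perimeter",
    "w30_conc_nuclei",
    "w30_hist_h_1",
    "w30_hist_h_2",
    "w30_hist_h_3",
    "w30_hist_h_4",
    "w30_hist_s_1",
    "w30_hist_s_2",
    "w30_hist_s_3",
    "w30_hist_s_4",
    "w30_hist_v_1",
    "w30_hist_v_4",
    "global_mean_h",
    "global_mean_s",
    "global_mean_v",
    "global_conc_nuclei",
    "global_conc_background",
    "stroma_filter_mean",
]

_META_COLUMNS = {"patch_id", "nucleus_label", "cluster_id", "tc_label"}


@dataclass
class FeatureSelectionStats:
    """Per-feature outcome of the selection procedure."""

    r: float
    slope: float
    selected_by_lasso: bool
    kept: bool
    zero_variance: bool = False


@dataclass
class SelectionResult:
    """Outcome of :func:`select_key_parameters`."""

    per_feature: dict[str, FeatureSelectionStats]
    tc_levels: list[float]
    kept_features: list[str] = field(default_factory=list)

    @property
    def n_selected(self) -> int:
        return len(self.kept_features)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "feature": name,
                "r": s.r,
                "slope": s.slope,
                "lasso_flag": s.selected_by_lasso,
                "kept": s.kept,
            }
            for name, s in self.per_feature.items()
        ]
        return pd.DataFrame(rows).sort_values("r", key=np.abs, ascending=False)


def _feature_names(table: pd.DataFrame) -> list[str]:
    return [
        c
        for c in table.columns
        if c not in _META_COLUMNS and pd.api.types.is_numeric_dtype(table[c])
    ]


def aggregate_by_tc(
    table: pd.DataFrame, tc_column: str = "tc_label", snap_tolerance: float = 0.025
) -> pd.DataFrame:
    """Per-level summary of each feature on the 11-point cellularity grid.

    Rows are snapped to the nearest grid level within ``snap_tolerance``;
    rows farther from every level are dropped. Output is long-form with one
    row per (tc_level, feature) carrying mean/sd/min/max.
    """
    if tc_column not in table.columns:
        raise KeyError(f"table has no {tc_column!r} column")
    tc = table[tc_column].to_numpy(dtype=float)
    nearest = np.round(tc * 10.0) / 10.0
    ok = np.abs(tc - nearest) <= snap_tolerance + 1e-12
    snapped = table.loc[ok].copy()
    snapped["tc_level"] = nearest[ok]
    levels = np.unique(snapped["tc_level"])
    if levels.size < 3:
        raise InsufficientLevelsError(
            f"need rows at >= 3 distinct cellularity levels, found {levels.size}"
        )
    feats = [f for f in _feature_names(snapped) if f != "tc_level"]
    grouped = snapped.groupby("tc_level")[feats].agg(["mean", "std", "min", "max"])
    out = grouped.stack(level=0, future_stack=True).reset_index()
    out.columns = ["tc_level", "feature", "mean", "std", "min", "max"]
    out["std"] = out["std"].fillna(0.0)
    return out.sort_values(["feature", "tc_level"]).reset_index(drop=True)


def correlate_features_to_tc(summary: pd.DataFrame) -> pd.DataFrame:
    """OLS of per-level feature means on the cellularity level.

    Returns one row per feature with the Pearson correlation ``r`` and the
    regression ``slope``; a zero-variance feature gets r = 0 and is flagged.
    """
    rows = []
    for feat, grp in summary.groupby("feature"):
        x = grp["tc_level"].to_numpy(dtype=float)
        y = grp["mean"].to_numpy(dtype=float)
        if x.size < 3:
            raise InsufficientLevelsError(f"feature {feat} has {x.size} levels")
        if np.allclose(y, y[0]):
            rows.append(
                {"feature": feat, "r": 0.0, "slope": 0.0, "zero_variance": True}
            )
            continue
        res = stats.linregress(x, y)
        rows.append(
            {
                "feature": feat,
                "r": float(res.rvalue),
                "slope": float(res.slope),
                "zero_variance": False,
            }
        )
    return pd.DataFrame(rows)


def _lambda_grid_selection(mse_mean, mse_se, alphas, rule: str) -> float:
    best = int(np.argmin(mse_mean))
    if rule == "min":
        return float(alphas[best])
    if rule == "1se":
        cutoff = mse_mean[best] + mse_se[best]
        ok = np.nonzero(mse_mean <= cutoff)[0]
        # alphas are descending in LassoCV; the largest admissible one is sparsest
        return float(alphas[ok.min()])
    raise ValueError(f"unknown lambda rule {rule!r}")


def lasso_select(
    table: pd.DataFrame,
    tc_column: str = "tc_label",
    lambda_grid: np.ndarray | None = None,
    seed: int = 0,
    rule: str = "min",
) -> list[str]:
    """Features with nonzero lasso coefficients at the cross-validated lambda.

    Features are z-scored internally; folds are fixed by ``seed``. ``rule``
    picks the CV-minimum lambda (default) or the sparser one-standard-error
    lambda (``"1se"``).
    """
    feats = _feature_names(table)
    X = table[feats].to_numpy(dtype=float)
    y = table[tc_column].to_numpy(dtype=float)
    if X.shape[0] < 2 * X.shape[1]:
        warnings.warn(
            f"only {X.shape[0]} rows for {X.shape[1]} features; "
            "lasso selection may be unstable",
            stacklevel=2,
        )
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Xz = (X - X.mean(axis=0)) / sd

    cv = KFold(n_splits=5, shuffle=True, random_state=seed)
    kwargs = {} if lambda_grid is None else {"alphas": lambda_grid}
    lcv = LassoCV(cv=cv, max_iter=50000, random_state=seed, **kwargs)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        lcv.fit(Xz, y)
    mse_mean = lcv.mse_path_.mean(axis=1)
    mse_se = lcv.mse_path_.std(axis=1) / np.sqrt(lcv.mse_path_.shape[1])
    alpha = _lambda_grid_selection(mse_mean, mse_se, lcv.alphas_, rule)
    fit = Lasso(alpha=alpha, max_iter=50000)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit.fit(Xz, y)
    return [f for f, c in zip(feats, fit.coef_) if abs(c) > 1e-10]


def select_key_parameters(
    table: pd.DataFrame,
    tc_column: str = "tc_label",
    r_threshold: float = 0.80,
    redundancy_threshold: float = 0.95,
    seed: int = 0,
    lasso_rule: str = "min",
    fallback_top_k: int | None = None,
) -> SelectionResult:
    """The full key-parameter procedure.

    A feature is kept iff |r| >= ``r_threshold`` on the level means AND it
    is lasso-selected on the raw rows AND it survives redundancy removal
    (pairwise |Pearson| > ``redundancy_threshold`` keeps the higher-|r|
    member). The kept list is ordered by |r| descending. If nothing
    survives and ``fallback_top_k`` is set, the top-k features by |r| are
    returned instead (flagged by a warning).
    """
    summary = aggregate_by_tc(table, tc_column)
    corr = correlate_features_to_tc(summary).set_index("feature")
    lasso_set = set(lasso_select(table, tc_column, seed=seed, rule=lasso_rule))

    order = corr["r"].abs().sort_values(ascending=False).index.tolist()
    feats = _feature_names(table)
    X = table[feats].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        pair_corr = pd.DataFrame(
            np.corrcoef(X, rowvar=False), index=feats, columns=feats
        ).fillna(0.0)

    surviving: list[str] = []
    redundant: set[str] = set()
    for feat in order:  # greedy, strongest first
        if any(abs(pair_corr.loc[feat, kept]) > redundancy_threshold for kept in surviving):
            redundant.add(feat)
            continue
        surviving.append(feat)

    per_feature: dict[str, FeatureSelectionStats] = {}
    kept_list: list[str] = []
    for feat in order:
        r = float(corr.loc[feat, "r"])
        kept = (
            abs(r) >= r_threshold
            and feat in lasso_set
            and feat not in redundant
        )
        per_feature[feat] = FeatureSelectionStats(
            r=r,
            slope=float(corr.loc[feat, "slope"]),
            selected_by_lasso=feat in lasso_set,
            kept=kept,
            zero_variance=bool(corr.loc[feat, "zero_variance"]),
        )
        if kept:
            kept_list.append(feat)

    if not kept_list:
        warnings.warn("no feature passed the selection rule", stacklevel=2)
        if fallback_top_k:
            kept_list = order[:fallback_top_k]
            for feat in kept_list:
                per_feature[feat].kept = True

    levels = sorted(summary["tc_level"].unique().tolist())
    return SelectionResult(
        per_feature=per_feature, tc_levels=levels, kept_features=kept_list
    )


class KeyParameterSelector(BaseEstimator, TransformerMixin):
    """Sklearn-style transformer wrapping the key-parameter procedure.

    ``fit(X, y)`` expects ``X`` as a feature DataFrame and ``y`` as the
    per-row cellularity label; ``transform`` restricts a table to the kept
    features.

    Attributes
    ----------
    kept_features_ : list of str
        Selected features ordered by |r| descending.
    result_ : SelectionResult
        Full per-feature diagnostics.
    """

    def __init__(
        self,
        r_threshold: float = 0.80,
        redundancy_threshold: float = 0.95,
        seed: int = 0,
        lasso_rule: str = "min",
        fallback_top_k: int | None = None,
    ):
        self.r_threshold = r_threshold
        self.redundancy_threshold = redundancy_threshold
        self.seed = seed
        self.lasso_rule = lasso_rule
        self.fallback_top_k = fallback_top_k

    def fit(self, X: pd.DataFrame, y=None):
        if y is None:
            raise ValueError("KeyParameterSelector requires per-row tc labels y")
        table = X.copy()
        table["tc_label"] = np.asarray(y, dtype=float)
        self.result_ = select_key_parameters(
            table,
            r_threshold=self.r_threshold,
            redundancy_threshold=self.redundancy_threshold,
            seed=self.seed,
            lasso_rule=self.lasso_rule,
            fallback_top_k=self.fallback_top_k,
        )
        self.kept_features_ = list(self.result_.kept_features)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "kept_features_")
        return X[self.kept_features_]
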