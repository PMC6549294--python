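"""Descriptor-table integration: filtering, z-scoring, the connectivity score,
PCA, culture-age classification and group statistics.

The connectivity score condenses the morphofunctional descriptor set into a
single scalar per technical replicate. Its model is fitted in four steps:

1. per experiment, the Pearson correlation of every descriptor with culture
   age (DIV) is computed on control conditions and averaged across
   experiments;
2. the pairwise inter-correlation of the descriptors is computed on the
   merged (control + treated) data;
3. descriptors are ranked by the absolute value of the average DIV
   correlation;
4. the ranked list is filtered top-down, skipping any descriptor whose
   absolute inter-correlation with an already retained one exceeds the cutoff
   (default 0.75); intensity-derived descriptors are excluded throughout as
   outlier-sensitive.

The score of a row is the weighted average of its z-scored retained
descriptors with the signed average DIV correlations as weights,
renormalised by the absolute weights of the descriptors actually present.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import GridSearchCV, StratifiedKFold, train_test_split

from .morpho import is_intensity_descriptor

__all__ = [
    "METADATA_COLUMNS",
    "descriptor_columns",
    "filter_fields",
    "filter_debris_nuclei",
    "aggregate_wells",
    "zscore",
    "normalize_to_reference",
    "ConnectivityScoreModel",
    "fit_score_model",
    "connectivity_score",
    "run_pca",
    "AgeClassifierResult",
    "train_age_classifier",
    "group_tests",
]

logger = logging.getLogger(__name__)

#: plate-layout keys treated as metadata, never as descriptors
METADATA_COLUMNS = (
    "plate", "well", "field", "DIV", "cell_type", "condition", "dose",
    "experiment", "replicate", "seed", "recording", "n_neurons",
)


def descriptor_columns(table: pd.DataFrame) -> list[str]:
    """Numeric non-metadata columns of a descriptor table."""
    return [
        c for c in table.columns
        if c not in METADATA_COLUMNS and pd.api.types.is_numeric_dtype(table[c])
    ]


# ---------------------------------------------------------------------------
# filtering and aggregation
# ---------------------------------------------------------------------------

def filter_fields(table: pd.DataFrame) -> pd.DataFrame:
    """Remove morphology rows lacking nuclei or dendrites.

    Drops rows whose nucleus count is zero or whose dendrite coverage is zero
    (or whose length-based densities are missing because no dendrite mask was
    found). Removal counts are logged.
    """
    n0 = len(table)
    keep = pd.Series(True, index=table.index)
    if "nuclei_count" in table.columns:
        keep &= table["nuclei_count"].fillna(0) > 0
    if "dendrite_density" in table.columns:
        keep &= table["dendrite_density"].fillna(0) > 0
    out = table.loc[keep].copy()
    removed = n0 - len(out)
    if removed:
        logger.info("filter_fields: removed %d/%d fields lacking nuclei or dendrites", removed, n0)
    return out


def filter_debris_nuclei(
    nucleus_table: pd.DataFrame,
    area_column: str = "projected_area",
    sd_cutoff: float = 5.0,
    group_keys: Sequence[str] = ("plate",),
) -> pd.DataFrame:
    """Drop false nuclear segmentations (debris) by the 5-sd area rule.

    A nucleus record is removed when its projected area exceeds the group
    mean by more than ``sd_cutoff`` standard deviations (mean and sd computed
    per plate). Applied to per-nucleus records before well averaging.
    """
    group_keys = [k for k in group_keys if k in nucleus_table.columns]
    areas = nucleus_table[area_column]
    if group_keys:
        grouped = nucleus_table.groupby(group_keys, sort=False)[area_column]
        mean = grouped.transform("mean")
        sd = grouped.transform(lambda a: a.std(ddof=1))
    else:
        mean = pd.Series(areas.mean(), index=areas.index)
        sd = pd.Series(areas.std(ddof=1), index=areas.index)
    keep = areas <= mean + sd_cutoff * sd.fillna(np.inf)
    removed = int((~keep).sum())
    if removed:
        logger.info("filter_debris_nuclei: removed %d/%d records", removed, len(nucleus_table))
    return nucleus_table.loc[keep].copy()


def aggregate_wells(
    table: pd.DataFrame,
    kind: str = "morphology",
    well_keys: Sequence[str] = ("experiment", "replicate", "plate", "well", "DIV",
                                "cell_type", "condition", "dose"),
) -> pd.DataFrame:
    """Average morphology fields per well; pass functional rows through.

    For the morphological assay the well is the technical replicate, so field
    rows are averaged per well. Functional recordings are already the
    technical replicate and are not averaged (to not further reduce the
    number of data points).
    """
    if kind == "functional":
        return table.copy()
    if kind != "morphology":
        raise ValueError(f"unknown table kind {kind!r}")
    keys = [k for k in well_keys if k in table.columns]
    if "well" not in keys:
        raise ValueError("well key missing from table")
    num = descriptor_columns(table)
    out = table.groupby(keys, sort=False, as_index=False)[num].mean()
    return out


# ---------------------------------------------------------------------------
# z-scoring and normalisation
# ---------------------------------------------------------------------------

def zscore(
    table: pd.DataFrame,
    group_keys: Sequence[str] = ("experiment", "replicate"),
    columns: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Z-score descriptors using the mean and sd within each group.

    Zero-sd descriptors within a group become missing; groups with a single
    row are flagged with a warning and emitted as missing.
    """
    cols = list(columns) if columns is not None else descriptor_columns(table)
    keys = [k for k in group_keys if k in table.columns]
    out = table.copy()
    grouped = out.groupby(keys, sort=False) if keys else [((), out)]
    for name, g in grouped:
        if len(g) < 2:
            warnings.warn(f"zscore: group {name} has a single row; emitted as missing")
            out.loc[g.index, cols] = np.nan
            continue
        mu = g[cols].mean()
        sd = g[cols].std(ddof=1)
        z = (g[cols] - mu) / sd.replace(0.0, np.nan)
        out.loc[g.index, cols] = z
    return out


def normalize_to_reference(
    zscored_table: pd.DataFrame,
    reference_condition: str,
    condition_key: str = "condition",
    group_keys: Sequence[str] = ("experiment", "replicate", "DIV"),
    columns: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Subtract the reference-condition group mean from every row in the group.

    Used to compare treated cultures with age-matched controls: within each
    (experiment, replicate, DIV) group the mean z-score of the reference
    condition is subtracted from all rows. Raises if any group lacks
    reference rows, listing the offending groups.
    """
    cols = list(columns) if columns is not None else descriptor_columns(zscored_table)
    keys = [k for k in group_keys if k in zscored_table.columns]
    out = zscored_table.copy()
    missing_groups = []
    for name, g in out.groupby(keys, sort=False):
        ref = g[g[condition_key] == reference_condition]
        if ref.empty:
            missing_groups.append(name)
            continue
        out.loc[g.index, cols] = g[cols] - ref[cols].mean()
    if missing_groups:
        raise ValueError(
            f"groups missing reference condition {reference_condition!r}: {missing_groups}"
        )
    return out


# ---------------------------------------------------------------------------
# connectivity score model
# ---------------------------------------------------------------------------

class ConnectivityScoreModel(TransformerMixin, BaseEstimator):
    """Weighted z-score connectivity model (sklearn-style estimator).

    Fitting selects a redundancy-pruned descriptor subset and weights each
    retained descriptor by its signed average correlation with culture age
    (DIV) on control conditions; ``transform`` maps a z-scored descriptor
    table to one scalar score per row.

    Parameters
    ----------
    intercorrelation_cutoff : float
        Maximum absolute pairwise inter-correlation allowed within the
        retained subset (default 0.75).
    exclude_intensity : bool
        Drop intensity-derived descriptors before selection (they are
        outlier-sensitive).
    div_key, experiment_key, condition_key, control_condition : str
        Metadata column names and the control-condition label.

    Attributes
    ----------
    selected_descriptors_ : list of str
        Retained descriptors in rank order.
    weights_ : pandas.Series
        Signed average DIV correlation of each retained descriptor.
    div_correlations_ : pandas.Series
        Average DIV correlation of every candidate descriptor.
    intercorrelation_ : pandas.DataFrame
        Pairwise inter-correlation matrix used in step 2.
    """

    def __init__(
        self,
        intercorrelation_cutoff: float = 0.75,
        exclude_intensity: bool = True,
        div_key: str = "DIV",
        experiment_key: str = "experiment",
        condition_key: str = "condition",
        control_condition: str = "control",
    ):
        self.intercorrelation_cutoff = intercorrelation_cutoff
        self.exclude_intensity = exclude_intensity
        self.div_key = div_key
        self.experiment_key = experiment_key
        self.condition_key = condition_key
        self.control_condition = control_condition

    def fit(self, table: pd.DataFrame, y=None) -> "ConnectivityScoreModel":
        """Fit the model on a z-scored descriptor table with metadata columns."""
        if self.div_key not in table.columns:
            raise ValueError(f"table lacks the {self.div_key!r} column")
        cols = [
            c for c in descriptor_columns(table)
            if not (self.exclude_intensity and is_intensity_descriptor(c))
        ]
        controls = (
            table[table[self.condition_key] == self.control_condition]
            if self.condition_key in table.columns
            else table
        )
        if controls[self.div_key].nunique() < 2:
            raise ValueError("need at least 2 DIV levels in the control data")

        # step 1: per-experiment DIV correlation on controls, averaged
        if self.experiment_key in controls.columns:
            per_exp = []
            for _, g in controls.groupby(self.experiment_key, sort=False):
                per_exp.append(g[cols].corrwith(g[self.div_key].astype(float)))
            div_corr = pd.concat(per_exp, axis=1).mean(axis=1)
        else:
            div_corr = controls[cols].corrwith(controls[self.div_key].astype(float))
        div_corr = div_corr.dropna()
        if div_corr.empty:
            raise ValueError("no descriptor has a defined correlation with DIV")

        # step 2: inter-correlation on the merged control + treated data
        inter = table[list(div_corr.index)].corr()

        # steps 3-4: rank by |average DIV correlation|, greedy top-down pruning
        ranked = div_corr.abs().sort_values(ascending=False).index
        retained: list[str] = []
        for name in ranked:
            if all(
                abs(inter.loc[name, kept]) <= self.intercorrelation_cutoff
                or np.isnan(inter.loc[name, kept])
                for kept in retained
            ):
                retained.append(name)

        self.selected_descriptors_ = retained
        self.weights_ = div_corr[retained].clip(-1.0, 1.0)
        self.div_correlations_ = div_corr
        self.intercorrelation_ = inter
        return self

    def transform(self, table: pd.DataFrame) -> np.ndarray:
        """Connectivity score per row of a z-scored table.

        ``score = sum_i w_i z_i / sum_i |w_i|`` over the non-missing retained
        descriptors of the row; rows where all retained descriptors are
        missing get NaN.
        """
        if not hasattr(self, "weights_"):
            raise ValueError("model is not fitted")
        cols = [c for c in self.selected_descriptors_ if c in table.columns]
        if not cols:
            raise ValueError("table contains none of the selected descriptors")
        z = table[cols].to_numpy(dtype=float)
        w = self.weights_[cols].to_numpy(dtype=float)
        present = ~np.isnan(z)
        num = np.nansum(z * w, axis=1)
        denom = (np.abs(w) * present).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            score = np.where(denom > 0, num / denom, np.nan)
        return score

    def to_dict(self) -> dict:
        """JSON-serialisable model description."""
        return {
            "selected_descriptors": list(self.selected_descriptors_),
            "weights": {k: float(v) for k, v in self.weights_.items()},
            "intercorrelation_cutoff": self.intercorrelation_cutoff,
            "div_correlations": {k: float(v) for k, v in self.div_correlations_.items()},
        }


def fit_score_model(table: pd.DataFrame, **kwargs) -> ConnectivityScoreModel:
    """Fit a :class:`ConnectivityScoreModel` on a z-scored descriptor table."""
    return ConnectivityScoreModel(**kwargs).fit(table)


def connectivity_score(
    zscored_table: pd.DataFrame, model: ConnectivityScoreModel
) -> pd.Series:
    """Scalar connectivity score per row (see model.transform)."""
    return pd.Series(model.transform(zscored_table), index=zscored_table.index,
                     name="connectivity_score")


# ---------------------------------------------------------------------------
# PCA and classification
# ---------------------------------------------------------------------------

def run_pca(
    zscored_table: pd.DataFrame,
    descriptors: Sequence[str] | None = None,
    n_components: int | None = None,
) -> dict:
    """PCA of the z-scored descriptor matrix.

    Rows with missing values are dropped. Returns projections (DataFrame
    indexed like the retained rows), loadings and explained-variance
    fractions; rank-deficient input yields components up to the rank.
    """
    cols = list(descriptors) if descriptors is not None else descriptor_columns(zscored_table)
    if len(cols) < 2:
        raise ValueError("need at least 2 descriptors for PCA")
    data = zscored_table[cols].dropna()
    if len(data) < 3:
        raise ValueError("need at least 3 complete rows for PCA")
    x = data.to_numpy(dtype=float)
    rank = int(np.linalg.matrix_rank(x - x.mean(axis=0)))
    k = min(n_components or rank, rank, len(cols), len(data) - 1)
    pca = PCA(n_components=k)
    proj = pca.fit_transform(x)
    pcs = [f"PC{i+1}" for i in range(k)]
    return {
        "projections": pd.DataFrame(proj, index=data.index, columns=pcs),
        "loadings": pd.DataFrame(pca.components_.T, index=cols, columns=pcs),
        "explained_variance_ratio": pca.explained_variance_ratio_,
    }


@dataclass
class AgeClassifierResult:
    """Trained culture-age classifier plus its held-out evaluation."""

    estimator: object
    method: str
    best_params: dict
    classes: np.ndarray
    confusion: pd.DataFrame
    mcr: float
    cv_mcr: float
    seed: int
    descriptors: list[str] = field(default_factory=list)


def train_age_classifier(
    table: pd.DataFrame,
    descriptors: Sequence[str] | None = None,
    label_key: str = "DIV",
    method: str = "random_forest",
    seed: int = 0,
    n_estimators_grid: Sequence[int] = (100, 250, 500, 1000),
    max_features_grid: Sequence = ("sqrt", 0.3, 0.6),
    cv_folds: int = 10,
    test_size: float = 1 / 3,
) -> AgeClassifierResult:
    """Train a culture-age classifier with a stratified 2/3-1/3 split.

    ``random_forest`` tunes the tree count and features-per-split by
    ``cv_folds``-fold cross-validation on the training set; ``lda`` fits a
    linear discriminant directly. Returns the test-set confusion matrix and
    misclassification rate (MCR). The split/CV seed is fixed and recorded.
    """
    cols = list(descriptors) if descriptors is not None else descriptor_columns(table)
    data = table.dropna(subset=cols)
    y = data[label_key].to_numpy()
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least 2 age classes")
    if counts.min() < 3:
        raise ValueError(f"every class needs >= 3 rows, got minimum {counts.min()}")
    x = data[cols].to_numpy(dtype=float)
    x_tr, x_te, y_tr, y_te = train_test_split(
        x, y, test_size=test_size, stratify=y, random_state=seed
    )
    folds = min(cv_folds, int(np.min(np.unique(y_tr, return_counts=True)[1])))
    cv = StratifiedKFold(n_splits=max(folds, 2), shuffle=True, random_state=seed)
    if method == "random_forest":
        grid = {
            "n_estimators": list(n_estimators_grid),
            "max_features": list(max_features_grid),
        }
        search = GridSearchCV(
            RandomForestClassifier(random_state=seed), grid, cv=cv,
            scoring="accuracy", n_jobs=1,
        )
        search.fit(x_tr, y_tr)
        est = search.best_estimator_
        best = dict(search.best_params_)
        cv_mcr = 1.0 - float(search.best_score_)
    elif method == "lda":
        est = LinearDiscriminantAnalysis()
        from sklearn.model_selection import cross_val_score

        cv_mcr = 1.0 - float(np.mean(cross_val_score(est, x_tr, y_tr, cv=cv)))
        est.fit(x_tr, y_tr)
        best = {}
    else:
        raise ValueError(f"unknown method {method!r}")
    y_pred = est.predict(x_te)
    cm = confusion_matrix(y_te, y_pred, labels=classes)
    mcr = float((y_pred != y_te).mean())
    return AgeClassifierResult(
        estimator=est,
        method=method,
        best_params=best,
        classes=classes,
        confusion=pd.DataFrame(cm, index=classes, columns=classes),
        mcr=mcr,
        cv_mcr=cv_mcr,
        seed=seed,
        descriptors=cols,
    )


# ---------------------------------------------------------------------------
# group statistics
# ---------------------------------------------------------------------------

def group_tests(
    table: pd.DataFrame,
    descriptor: str,
    grouping: str,
) -> pd.DataFrame:
    """Pairwise two-sided Wilcoxon rank-sum tests with Bonferroni correction.

    Rank-based tests are used because normality and homoscedasticity cannot
    be assumed; per-group Shapiro-Wilk and an overall Bartlett test are
    reported alongside. The Bonferroni multiplier is the number of pairwise
    comparisons for this descriptor; corrected p-values are capped at 1.
    Degenerate groups (fewer than 2 observations) are skipped with a warning.
    """
    groups = {
        name: g[descriptor].dropna().to_numpy()
        for name, g in table.groupby(grouping, sort=False)
    }
    valid = {k: v for k, v in groups.items() if len(v) >= 2}
    skipped = set(groups) - set(valid)
    for name in skipped:
        warnings.warn(f"group_tests: group {name!r} has <2 observations; skipped")
    if len(valid) < 2:
        raise ValueError("need at least 2 groups with >= 2 observations")
    pairs = list(itertools.combinations(valid.keys(), 2))
    n_tests = len(pairs)
    shapiro_p = {}
    for name, v in valid.items():
        if len(v) >= 3 and np.ptp(v) > 0:
            shapiro_p[name] = float(stats.shapiro(v).pvalue)
        else:
            shapiro_p[name] = np.nan
    try:
        bartlett_p = float(stats.bartlett(*valid.values()).pvalue)
    except ValueError:
        bartlett_p = np.nan
    rows = []
    for a, b in pairs:
        if np.ptp(np.concatenate([valid[a], valid[b]])) == 0:
            p = 1.0
        else:
            p = float(stats.mannwhitneyu(valid[a], valid[b], alternative="two-sided").pvalue)
        rows.append(
            {
                "descriptor": descriptor,
                "group_a": a,
                "group_b": b,
                "p_value": p,
                "p_bonferroni": min(p * n_tests, 1.0),
                "shapiro_p_a": shapiro_p[a],
                "shapiro_p_b": shapiro_p[b],
                "bartlett_p": bartlett_p,
            }
        )
    return pd.DataFrame(rows)
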