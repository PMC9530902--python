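"""Prediction layer: multiple linear regression of the rates and
maximum-margin classification of medium/genotype.

Features per (strain, medium) observation are the growth rate mu (h^-1) and
log10 mutation rate, plus a numeral medium code (LB=1, MAA=0, M63=-1) and a
genotype value combining the genome-reduction and MMR-deficiency indicators
either multiplicatively ("interactive") or additively ("additive"). The
regressions are ordinary least squares; the classifiers are support vector
machines (linear and Gaussian-RBF kernels) on the two quantitative features
only, under a repeated stratified 60/40 train/test protocol with nested
cross-validated hyperparameter search.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import GridSearchCV, StratifiedKFold, train_test_split
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .types import (
    ConfigurationError,
    MEDIUM_CODES,
    genotype_class,
    subseed,
    validate_rate_table,
)

#: Hyperparameter search grid: 0.001 to 100 in 10-fold increments.
CV_GRID = tuple(10.0**k for k in range(-3, 3))

#: Final fixed hyperparameters per (kernel, target), as used for the
#: published decision landscapes.
FIXED_HYPERPARAMS = {
    ("linear", "medium"): {"C": 10.0},
    ("linear", "genotype"): {"C": 100.0},
    ("rbf", "medium"): {"C": 10.0, "gamma": 1.0},
    ("rbf", "genotype"): {"C": 100.0, "gamma": 0.01},
}


def encode_features(table: pd.DataFrame, mode: str = "interactive") -> pd.DataFrame:
    """One feature row per (strain, medium) observation.

    genotype_value = gr * md (interactive) or gr + md (additive), where gr
    and md are the genome-reduction and MMR-deficiency indicators.
    """
    validate_rate_table(table)
    if mode not in ("interactive", "additive"):
        raise ConfigurationError("mode must be 'interactive' or 'additive'")
    gr = table["genome_reduced"].astype(int)
    md = table["mmr_deficient"].astype(int)
    rows = pd.DataFrame(
        {
            "mu": table["growth_rate"].astype(float),
            "log10_m": np.log10(table["mutation_rate"].astype(float)),
            "medium_code": table["medium"].map(MEDIUM_CODES),
            "gr": gr,
            "md": md,
            "genotype_value": gr * md if mode == "interactive" else gr + md,
            "medium_label": table["medium"],
            "genotype_label": [
                genotype_class(g, m) for g, m in zip(gr, md)
            ],
        }
    )
    if rows["medium_code"].isna().any():
        raise ConfigurationError("unknown medium in table")
    return rows.reset_index(drop=True)


@dataclass
class RegressionReport:
    response: str                  # "mutation" (log10 M) or "growth" (mu)
    mode: str                      # "interactive" or "additive"
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    adj_r2: float
    n: int
    dropped: list[str] = field(default_factory=list)
    fitted: np.ndarray | None = None

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"coef": self.params, "se": self.bse, "p_value": self.pvalues}
        )


def fit_mlr(rows: pd.DataFrame, response: str, mode: str) -> RegressionReport:
    """OLS regression of one rate on the other rate, medium, and genotype.

    response="mutation": log10(M) ~ mu + medium_code + genotype_value;
    response="growth":   mu ~ log10(M) + medium_code + genotype_value.
    A constant genotype column (e.g. interactive coding in a panel with no
    doubly disturbed strain) is flagged and dropped rather than breaking the
    fit; any other constant or collinear predictor raises a singularity
    error naming the columns.
    """
    if response == "mutation":
        y = rows["log10_m"]
        predictors = ["mu", "medium_code", "genotype_value"]
    elif response == "growth":
        y = rows["mu"]
        predictors = ["log10_m", "medium_code", "genotype_value"]
    else:
        raise ConfigurationError("response must be 'mutation' or 'growth'")

    dropped = []
    if rows["genotype_value"].nunique() == 1:
        predictors.remove("genotype_value")
        dropped.append("genotype_value")

    X = rows[predictors].astype(float)
    constant = [c for c in predictors if X[c].nunique() == 1]
    if constant:
        raise ConfigurationError(f"singular design: constant column(s) {constant}")
    design = sm.add_constant(X)
    if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
        raise ConfigurationError(
            f"singular design: collinear columns among {list(design.columns)}"
        )
    if len(rows) <= len(predictors) + 1:
        raise ConfigurationError("need n > number of predictors + 1")

    fit = sm.OLS(y.astype(float), design).fit()
    return RegressionReport(
        response=response,
        mode=mode,
        params=fit.params,
        bse=fit.bse,
        pvalues=fit.pvalues,
        adj_r2=float(fit.rsquared_adj),
        n=int(fit.nobs),
        dropped=dropped,
        fitted=np.asarray(fit.fittedvalues),
    )


@dataclass
class ClassificationReport:
    target: str                    # "medium" or "genotype"
    kernel: str                    # "linear" or "rbf"
    accuracies: list[float]        # one per repeat (test split)
    mean_confusion: pd.DataFrame   # mean over repeats, rows = true class
    chosen_params: list[dict]      # per repeat
    classes: list[str]
    macro_cv_scores: list[float]   # inner-CV macro-recall of chosen params
    models: list[Pipeline] = field(default_factory=list, repr=False)
    scaling: str = "z-score fitted on each training split"

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.accuracies))


def _make_grid(kernel: str) -> dict:
    grid = {"svc__C": list(CV_GRID)}
    if kernel == "rbf":
        grid["svc__gamma"] = list(CV_GRID)
    return grid


def classify(
    rows: pd.DataFrame,
    target: str = "medium",
    kernel: str = "rbf",
    test_fraction: float = 0.4,
    n_repeats: int = 5,
    seed: int = 0,
    fixed_hyperparams: bool | dict = False,
) -> ClassificationReport:
    """Repeated stratified train/test SVM classification from (mu, log10 M).

    Per repeat: a stratified 60/40 split, an inner stratified k-fold search
    over the C (and gamma) grid scored by macro-averaged recall (k = 5,
    reduced if a training class is smaller), then test accuracy of the
    refitted winner via the confusion matrix. fixed_hyperparams=True uses
    the published final values instead of the search; a dict supplies
    explicit values.
    """
    if target == "medium":
        labels = rows["medium_label"]
    elif target == "genotype":
        labels = rows["genotype_label"]
    else:
        raise ConfigurationError("target must be 'medium' or 'genotype'")
    if kernel not in ("linear", "rbf"):
        raise ConfigurationError("kernel must be 'linear' or 'rbf'")
    classes = sorted(labels.unique())
    if len(classes) < 2:
        raise ConfigurationError(
            f"classification needs >= 2 classes, found {classes}"
        )

    X = rows[["mu", "log10_m"]].to_numpy(dtype=float)
    y = labels.to_numpy()

    if fixed_hyperparams is True:
        params = FIXED_HYPERPARAMS[(kernel, target)]
    elif isinstance(fixed_hyperparams, dict):
        params = fixed_hyperparams
    else:
        params = None

    accuracies, confusions, chosen, cv_scores, models = [], [], [], [], []
    for rep in range(n_repeats):
        for attempt in range(10):
            rs = subseed(seed, "split", rep, attempt)
            X_tr, X_te, y_tr, y_te = train_test_split(
                X, y, test_size=test_fraction, stratify=y, random_state=rs
            )
            if set(y_tr) == set(classes):
                break
        else:  # pragma: no cover - stratification guarantees coverage
            raise ConfigurationError("could not obtain a split with all classes")

        if params is not None:
            svc = SVC(kernel=kernel, **params)
            model = Pipeline([("scale", StandardScaler()), ("svc", svc)])
            model.fit(X_tr, y_tr)
            chosen.append({"C": svc.C, **({"gamma": svc.gamma} if kernel == "rbf" else {})})
            cv_scores.append(float("nan"))
        else:
            min_class = int(pd.Series(y_tr).value_counts().min())
            folds = max(2, min(5, min_class))
            search = GridSearchCV(
                Pipeline([("scale", StandardScaler()), ("svc", SVC(kernel=kernel))]),
                _make_grid(kernel),
                scoring="recall_macro",
                cv=StratifiedKFold(folds, shuffle=True, random_state=rs),
                n_jobs=1,
            )
            search.fit(X_tr, y_tr)
            model = search.best_estimator_
            chosen.append(
                {k.removeprefix("svc__"): v for k, v in search.best_params_.items()}
            )
            cv_scores.append(float(search.best_score_))

        y_pred = model.predict(X_te)
        cm = confusion_matrix(y_te, y_pred, labels=classes)
        accuracies.append(float(np.trace(cm) / cm.sum()))
        confusions.append(cm)
        models.append(model)

    mean_cm = pd.DataFrame(
        np.mean(confusions, axis=0), index=classes, columns=classes
    )
    return ClassificationReport(
        target=target,
        kernel=kernel,
        accuracies=accuracies,
        mean_confusion=mean_cm,
        chosen_params=chosen,
        classes=classes,
        macro_cv_scores=cv_scores,
        models=models,
    )


def decision_landscape(
    model: Pipeline,
    bounds: tuple[float, float, float, float],
    grid_n: int = 200,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Predicted class over a (mu, log10 M) lattice, for region plots.

    bounds = (mu_min, mu_max, log10_m_min, log10_m_max). Returns
    (mu_grid, log10_m_grid, labels) with labels of shape (grid_n, grid_n).
    """
    if grid_n < 1:
        raise ConfigurationError("grid_n must be >= 1")
    mu_min, mu_max, lm_min, lm_max = bounds
    mu_ax = np.linspace(mu_min, mu_max, grid_n)
    lm_ax = np.linspace(lm_min, lm_max, grid_n)
    mu_grid, lm_grid = np.meshgrid(mu_ax, lm_ax)
    pts = np.column_stack([mu_grid.ravel(), lm_grid.ravel()])
    labels = model.predict(pts).reshape(grid_n, grid_n)
    return mu_grid, lm_grid, labels
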