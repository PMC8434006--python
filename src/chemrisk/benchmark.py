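"""Imbalanced-classification benchmark: stratified CV, balanced accuracy,
and pairwise Wilcoxon comparison tables.

The harness reproduces a standard protocol for comparing extraction/selection
pipelines on imbalanced risk classes: selection is fitted inside each
training fold only, quality is the balanced accuracy score (macro-averaged
recall), and methods are compared per classifier with the two-sided Wilcoxon
signed-rank test over paired fold scores.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import wilcoxon as _scipy_wilcoxon
from sklearn.metrics import balanced_accuracy_score
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .datagen import FeatureTable
from . import extraction
from .selection import PipelineConfig, run_selection_pipeline

ALPHA = 0.05  # significance level of the pairwise comparisons


@dataclass(frozen=True)
class ClassifierSpec:
    """A named classifier with its tuning grid and best-known preset."""

    name: str
    grid: dict
    paper_best: dict
    mlp_width: int = 32  # width of each hidden layer ("layers" reading)
    mlp_units_reading: bool = False  # alternate reading: 7 hidden units, 1 layer


def default_specs() -> dict[str, ClassifierSpec]:
    """The classifier suite with its hyperparameter grids and presets."""
    knn_grid = {"metric": ["minkowski", "euclidean", "manhattan"]}
    specs = {
        "SVC": ClassifierSpec(
            "SVC",
            grid={
                "C": [0.1, 1, 10, 100],
                "kernel": ["linear", "rbf", "poly", "sigmoid"],
                "gamma": ["scale", "auto"],
            },
            paper_best={"C": 0.1, "kernel": "rbf", "gamma": "auto"},
        ),
        "KNN3": ClassifierSpec(
            "KNN3", grid=knn_grid, paper_best={"metric": "euclidean"}
        ),
        "KNN5": ClassifierSpec(
            "KNN5", grid=knn_grid, paper_best={"metric": "euclidean"}
        ),
        "KNN7": ClassifierSpec(
            "KNN7", grid=knn_grid, paper_best={"metric": "euclidean"}
        ),
        "CART": ClassifierSpec(
            "CART",
            grid={
                "criterion": ["gini", "entropy"],
                "splitter": ["best", "random"],
                "max_depth": list(range(1, 11)),
            },
            paper_best={"criterion": "gini", "splitter": "best", "max_depth": 7},
        ),
        "GNB": ClassifierSpec("GNB", grid={}, paper_best={}),
        "MLP": ClassifierSpec(
            "MLP",
            grid={
                "n_hidden_layers": list(range(3, 11)),
                "activation": ["identity", "logistic", "tanh"],
                "alpha": [1e-5, 1e-4, 1e-3, 1e-2, 1e-1],
                "momentum": [0.0, 0.2, 0.4, 0.6, 0.8, 1.0],
            },
            paper_best={
                "n_hidden_layers": 7,
                "activation": "identity",
                "alpha": 0.01,
                "momentum": 0.6,
            },
        ),
    }
    return specs


def make_classifier(spec: ClassifierSpec, params: dict | None, seed: int = 0):
    """Instantiate the sklearn estimator behind a spec with given params."""
    p = dict(spec.paper_best if params is None else params)
    if spec.name.startswith("KNN"):
        return KNeighborsClassifier(n_neighbors=int(spec.name[3:]), **p)
    if spec.name == "SVC":
        return SVC(random_state=seed, **p)
    if spec.name == "CART":
        return DecisionTreeClassifier(random_state=seed, **p)
    if spec.name == "GNB":
        return GaussianNB(**p)
    if spec.name == "MLP":
        layers = int(p.pop("n_hidden_layers", 7))
        if spec.mlp_units_reading:
            hidden = (layers,)  # "7 hidden units" reading: one layer of 7
        else:
            hidden = (spec.mlp_width,) * layers
        momentum = p.pop("momentum", 0.6)
        return MLPClassifier(
            hidden_layer_sizes=hidden,
            solver="sgd",
            momentum=momentum,
            learning_rate_init=0.01,
            max_iter=150,
            random_state=seed,
            **p,
        )
    raise ValueError(f"unknown classifier: {spec.name}")


def tune_classifier(
    spec: ClassifierSpec, X, y, seed: int = 0, inner_folds: int = 3
) -> dict:
    """Grid search with an inner stratified CV; returns the best params."""
    if not spec.grid:
        return {}
    base = make_classifier(spec, {k: v[0] for k, v in spec.grid.items()}, seed)
    grid = spec.grid
    if spec.name == "MLP":
        # grid keys are translated inside make_classifier; tune a reduced
        # surrogate directly on the sklearn estimator
        grid = {
            "alpha": spec.grid["alpha"],
            "momentum": spec.grid["momentum"],
            "activation": spec.grid["activation"],
        }
    cv = StratifiedKFold(n_splits=inner_folds, shuffle=True, random_state=seed)
    gs = GridSearchCV(base, grid, scoring="balanced_accuracy", cv=cv, n_jobs=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        gs.fit(X, y)
    return dict(gs.best_params_)


@dataclass(frozen=True)
class MethodSpec:
    """One extraction/selection pipeline under comparison."""

    label: str
    method: str | None  # extraction backend, or None for no extraction
    criterion: str | None = None  # selection criterion, None with method=None
    config: PipelineConfig = field(default_factory=PipelineConfig)


def standard_methods(which: str = "criteria") -> list[MethodSpec]:
    """The two standard comparison panels.

    ``criteria`` compares selection criteria on plain PCA (no extraction,
    scree, Kaiser, fused, reliability); ``extractors`` compares the fused
    baseline and the reliability criterion across extraction backends.
    """
    if which == "criteria":
        return [
            MethodSpec("NO", None),
            MethodSpec("PCA_SP", "pca", "sp"),
            MethodSpec("PCA_K", "pca", "k"),
            MethodSpec("PCA_K+SP", "pca", "ksp"),
            MethodSpec("PCA'", "pca", "beta"),
        ]
    if which == "extractors":
        return [
            MethodSpec("NO", None),
            MethodSpec("PCA_K+SP", "pca", "ksp"),
            MethodSpec("PCA'", "pca", "beta"),
            MethodSpec("CCPCA_K+SP", "ccpca", "ksp"),
            MethodSpec("CCPCA'", "ccpca", "beta"),
            MethodSpec("GPCA_K+SP", "gpca", "ksp"),
            MethodSpec("GPCA'", "gpca", "beta"),
            MethodSpec("KPCA_K+SP", "kpca", "ksp"),
            MethodSpec("KPCA'", "kpca", "beta"),
        ]
    raise ValueError(f"unknown panel: {which!r}")


def _fold_features(
    table: FeatureTable, method_spec: MethodSpec, train_idx, test_idx, seed: int
):
    """Fit extraction+selection on the training rows only; return projected
    train/test matrices and the per-fold selection details."""
    X = table.values
    mean = X[train_idx].mean(axis=0)
    sd = X[train_idx].std(axis=0)
    sd[sd == 0] = 1.0
    Ztr = (X[train_idx] - mean) / sd
    Zte = (X[test_idx] - mean) / sd
    if method_spec.method is None:
        return Ztr, Zte, {"selection": None}
    sub = FeatureTable(
        Ztr,
        table.labels[train_idx],
        list(table.feature_names),
        list(table.feature_groups),
    )
    cfg = replace(method_spec.config, seed=seed)
    sel, model = run_selection_pipeline(
        sub, method=method_spec.method, criterion=method_spec.criterion, config=cfg
    )
    Ftr = extraction.transform(Ztr, model, sel)
    Fte = extraction.transform(Zte, model, sel)
    # component scores have variance ~ eigenvalue; bring them to unit scale
    # (train statistics) so kernel/distance classifiers see comparable axes
    smean = Ftr.mean(axis=0)
    ssd = Ftr.std(axis=0)
    ssd[ssd == 0] = 1.0
    Ftr = (Ftr - smean) / ssd
    Fte = (Fte - smean) / ssd
    details = {
        "selection": sorted(sel.retained_features),
        "M_retained": sel.M_retained,
    }
    return Ftr, Fte, details


def stratified_cv_bac(
    table: FeatureTable,
    method_spec: MethodSpec,
    classifier,
    folds: int = 5,
    repeats: int = 1,
    seed: int = 0,
    return_details: bool = False,
):
    """Per-fold balanced accuracy of a pipeline under repeated stratified CV.

    ``classifier`` is a :class:`ClassifierSpec` (instantiated with its
    preset) or any sklearn-style estimator.  Extraction and selection are
    fitted inside each training fold only, so no information leaks from the
    test fold.  Returns ``folds * repeats`` scores.
    """
    y = np.asarray(table.labels)
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < folds:
        raise ValueError(
            f"a class has only {counts.min()} members; use at most "
            f"{counts.min()} folds"
        )
    scores: list[float] = []
    details: list[dict] = []
    for r in range(repeats):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed + r)
        for k, (tr, te) in enumerate(skf.split(table.values, y)):
            Ftr, Fte, det = _fold_features(table, method_spec, tr, te, seed + r)
            if isinstance(classifier, ClassifierSpec):
                est = make_classifier(classifier, None, seed=seed + r)
            else:
                from sklearn.base import clone

                est = clone(classifier)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                est.fit(Ftr, y[tr])
                pred = est.predict(Fte)
            scores.append(float(balanced_accuracy_score(y[te], pred)))
            det["repeat"], det["fold"] = r, k
            details.append(det)
    bac = np.asarray(scores)
    if return_details:
        return bac, details
    return bac


@dataclass
class WilcoxonResult:
    p_value: float
    direction: int  # sign of mean(a - b)
    no_difference: bool = False


def wilcoxon_compare(bac_a, bac_b) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test on paired fold scores.

    Zero differences are dropped (signed-rank convention); the exact null
    distribution is used for up to 25 informative pairs.  All-zero
    differences give p = 1 with a no-difference flag.
    """
    a = np.asarray(bac_a, dtype=float)
    b = np.asarray(bac_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired arrays of equal length are required")
    if len(a) < 5:
        raise ValueError("need at least 5 pairs")
    d = a - b
    nz = d[d != 0]
    if len(nz) == 0:
        return WilcoxonResult(1.0, 0, no_difference=True)
    mode = "exact" if len(nz) <= 25 else "approx"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = _scipy_wilcoxon(nz, method=mode)
        except ValueError:
            res = _scipy_wilcoxon(nz, method="approx")
    return WilcoxonResult(float(res.pvalue), int(np.sign(d.mean())))


@dataclass
class BenchmarkReport:
    """Method x classifier balanced-accuracy matrix with significance marks.

    ``marks[label][clf]`` lists the 1-based row indices of the methods that
    ``label`` beats at the 0.05 level (higher mean and significant Wilcoxon).
    """

    labels: list[str]
    classifiers: list[str]
    bac_mean: pd.DataFrame  # methods x classifiers
    fold_bac: dict[str, dict[str, np.ndarray]]
    p_values: dict[str, pd.DataFrame]  # per classifier, methods x methods
    marks: dict[str, dict[str, list[int]]]


def build_report(fold_bac: dict[str, dict[str, np.ndarray]]) -> BenchmarkReport:
    """Assemble the comparison report from per-fold BAC arrays.

    ``fold_bac[label][clf]`` is the array returned by
    :func:`stratified_cv_bac`; all methods must share classifiers and fold
    counts.
    """
    labels = list(fold_bac)
    classifiers = list(next(iter(fold_bac.values())))
    mean = pd.DataFrame(
        {
            clf: [float(np.mean(fold_bac[lb][clf])) for lb in labels]
            for clf in classifiers
        },
        index=labels,
    )
    p_values: dict[str, pd.DataFrame] = {}
    marks: dict[str, dict[str, list[int]]] = {lb: {} for lb in labels}
    for clf in classifiers:
        P = pd.DataFrame(np.ones((len(labels), len(labels))), index=labels, columns=labels)
        for i, li in enumerate(labels):
            beats: list[int] = []
            for j, lj in enumerate(labels):
                if i == j:
                    continue
                res = wilcoxon_compare(fold_bac[li][clf], fold_bac[lj][clf])
                P.loc[li, lj] = res.p_value
                if (
                    res.p_value < ALPHA
                    and mean.loc[li, clf] > mean.loc[lj, clf]
                ):
                    beats.append(j + 1)
            marks[li][clf] = beats
        p_values[clf] = P
    return BenchmarkReport(labels, classifiers, mean, fold_bac, p_values, marks)


def render_report(report: BenchmarkReport, fmt: str = "text") -> str:
    """Render the two-row-per-method layout (values row, significance row)."""
    rows = []
    for i, lb in enumerate(report.labels):
        rows.append(
            [f"{i + 1}. {lb}"]
            + [f"{report.bac_mean.loc[lb, c]:.3f}" for c in report.classifiers]
        )
        rows.append(
            [""]
            + [
                ",".join(map(str, report.marks[lb][c])) or "-"
                for c in report.classifiers
            ]
        )
    df = pd.DataFrame(rows, columns=["method", *report.classifiers])
    if fmt == "csv":
        buf = io.StringIO()
        df.to_csv(buf, index=False)
        return buf.getvalue()
    if fmt == "text":
        return df.to_string(index=False)
    raise ValueError(f"unknown format: {fmt!r}")


def parse_report_csv(text: str) -> pd.DataFrame:
    """Read back a CSV rendered by :func:`render_report`."""
    return pd.read_csv(io.StringIO(text), keep_default_na=False)


def run_benchmark(
    table: FeatureTable,
    methods: list[MethodSpec] | None = None,
    classifiers: list[str] | None = None,
    folds: int = 5,
    repeats: int = 10,
    seed: int = 0,
    specs: dict[str, ClassifierSpec] | None = None,
) -> BenchmarkReport:
    """Run the full panel and build the comparison report.

    Classifiers use their best-known presets; 10 repeats of 5-fold CV give
    50 Wilcoxon pairs by default (``repeats=1`` mirrors a single-pass
    protocol).
    """
    methods = methods if methods is not None else standard_methods("criteria")
    specs = specs or default_specs()
    classifiers = classifiers if classifiers is not None else list(specs)
    fold_bac: dict[str, dict[str, np.ndarray]] = {}
    for ms in methods:
        fold_bac[ms.label] = {}
        for clf in classifiers:
            fold_bac[ms.label][clf] = stratified_cv_bac(
                table, ms, specs[clf], folds=folds, repeats=repeats, seed=seed
            )
    return build_report(fold_bac)
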