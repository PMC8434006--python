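"""Component-number estimation and feature-to-component assignment.

Implements the classical Kaiser (eigenvalue > 1), scree-acceleration and
fused criteria, and the reliability-based criterion built on a Cronbach-type
coefficient

    beta = k * rb * rd / (1 + (k - 1) * rb * rd)

where ``k`` is the number of scale features, ``rb`` the mean absolute
pairwise correlation and ``rd`` the mean absolute item-total correlation.
A feature belongs to component ``m`` when ``Phi(t_{m,i}) >= beta`` with
``Phi`` the standard normal CDF and ``t`` a configurable transform of the
component loadings; multiply-assigned features go to the component with the
largest absolute loading, and components left without members are pruned.
A kernel-SVM extension handles the ambiguous band ``[beta-, beta+]`` around
the threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtr
from sklearn.svm import SVC

from .datagen import FeatureTable
from . import extraction
from .extraction import ExtractionModel

CRITERIA = ("k", "sp", "ksp", "beta", "beta-svm")
LOADING_TRANSFORMS = ("raw", "abs", "zscore")


class SelectionWarning(UserWarning):
    pass


class EmptySelectionError(ValueError):
    """Raised when a criterion retains no component/feature."""


@dataclass
class BetaResult:
    """Reliability coefficient of a feature scale."""

    k: int
    r_bar: float  # mean absolute pairwise correlation
    r_dot_per_feature: np.ndarray  # |corr(z_i, sum_j z_j)|
    r_dot: float  # mean item-total correlation
    beta_global: float
    beta_per_feature: np.ndarray


@dataclass
class SelectionResult:
    """Outcome of a component/feature selection criterion."""

    criterion: str
    M_retained: int
    assignment: dict[str, int]  # feature name -> component index
    retained_features: list[str]
    diagnostics: dict = field(default_factory=dict)


def _beta_formula(k: int, rr: float) -> float:
    return k * rr / (1.0 + (k - 1) * rr)


def kaiser_select(eigenvalues, return_diagnostics: bool = False):
    """Number of components with eigenvalue strictly greater than 1.

    With ``return_diagnostics=True`` also reports how many eigenvalues sit
    in the band [0.9, 1.1]: a large band count means the rule is unstable
    (small sampling fluctuations move components across the threshold), the
    typical failure mode on near-identity correlation structure.
    """
    lam = np.asarray(eigenvalues, dtype=float)
    if lam.size == 0:
        raise ValueError("kaiser_select: empty eigenvalue sequence")
    m = int(np.sum(lam > 1.0))
    if not return_diagnostics:
        return m
    near_one = int(np.sum(np.abs(lam - 1.0) <= 0.1))
    diag = {"n_near_one": near_one, "unstable": near_one > 0.2 * lam.size}
    return m, diag


def scree_select(eigenvalues) -> int:
    """Elbow of the scree curve, formalized as maximum acceleration.

    ``M`` is the 1-based position of the maximum second forward difference
    ``lam[i] - 2 lam[i+1] + lam[i+2]``; ties keep the smaller ``M``.
    """
    lam = np.asarray(eigenvalues, dtype=float)
    if lam.size < 3:
        raise ValueError("scree_select needs at least 3 eigenvalues")
    accel = lam[:-2] - 2.0 * lam[1:-1] + lam[2:]
    return int(np.argmax(accel)) + 1


def fused_select(eigenvalues) -> int:
    """Fused criterion: a component must satisfy both Kaiser and scree."""
    m = min(kaiser_select(eigenvalues), scree_select(eigenvalues))
    if m == 0:
        warnings.warn(
            "fused criterion retains 0 components (all eigenvalues <= 1)",
            SelectionWarning,
        )
    return m


def compute_beta(Z) -> BetaResult:
    """Reliability coefficient of the feature set ``Z`` (samples x features).

    With a single feature the scale degenerates: the mean pairwise
    correlation is defined as 1 and beta reduces to the item-total
    correlation (which is itself 1).
    """
    X = np.asarray(Z, dtype=float) if not isinstance(Z, FeatureTable) else Z.values
    if X.ndim == 1:
        X = X[:, None]
    n, k = X.shape
    if k < 1:
        raise ValueError("compute_beta needs at least 1 feature")
    if n < 3:
        raise ValueError("compute_beta needs at least 3 samples")
    sd = X.std(axis=0)
    if (sd == 0).any():
        j = int(np.flatnonzero(sd == 0)[0])
        raise ValueError(f"zero-variance feature at column {j}")
    if k == 1:
        return BetaResult(1, 1.0, np.ones(1), 1.0, 1.0, np.ones(1))
    C = np.corrcoef(X, rowvar=False)
    iu = np.triu_indices(k, 1)
    r_bar = float(np.mean(np.abs(C[iu])))
    total = X.sum(axis=1)
    tsd = total.std()
    if tsd == 0:
        r_dot_i = np.zeros(k)
    else:
        Xc = X - X.mean(axis=0)
        tc = total - total.mean()
        r_dot_i = np.abs(Xc.T @ tc / n / (sd * tsd))
    r_dot = float(np.mean(r_dot_i))
    beta = _beta_formula(k, r_bar * r_dot)
    beta_i = np.array([_beta_formula(k, r_bar * ri) for ri in r_dot_i])
    return BetaResult(k, r_bar, r_dot_i, r_dot, float(beta), beta_i)


def beta_from_parts(k: int, r_bar_r_dot: float) -> float:
    """Closed-form beta for a given item count and correlation product."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return _beta_formula(k, r_bar_r_dot)


def _loading_stat(model: ExtractionModel, transform: str) -> np.ndarray:
    """Per-component statistic ``t_{m,i}`` fed to the normal CDF.

    ``raw`` uses eigenvector entries literally, ``abs`` the loading
    magnitudes; the default ``zscore`` standardizes loading magnitudes
    within each component so the threshold acts on the loading ranking.
    """
    if transform not in LOADING_TRANSFORMS:
        raise ValueError(f"unknown loading transform: {transform!r}")
    if transform == "raw":
        if model.method == "kpca":
            t = model.loadings.copy()  # no native eigenvector entries
        else:
            t = model.eigenvectors.copy()
    elif transform == "abs":
        t = np.abs(model.loadings)
    else:
        a = np.abs(model.loadings)
        mu = a.mean(axis=1, keepdims=True)
        sd = a.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        t = (a - mu) / sd
    return t


def resolve_multiassignment(
    candidates: dict[str, list[tuple[int, float]]],
) -> dict[str, int]:
    """Assign each multiply-classified feature to one component.

    ``candidates`` maps a feature to ``(component, |loading|)`` pairs; the
    component with the maximal absolute loading wins, exact ties go to the
    lower component index.
    """
    out = {}
    for feat, pairs in candidates.items():
        if not pairs:
            continue
        out[feat] = min(pairs, key=lambda p: (-p[1], p[0]))[0]
    return out


def _prune(assignment: dict[str, int]) -> tuple[dict[str, int], int]:
    """Drop empty components; surviving components keep their indices."""
    comps = sorted(set(assignment.values()))
    return assignment, len(comps)


def assign_features(
    model: ExtractionModel,
    beta: BetaResult,
    M_max: int,
    loading_transform: str = "zscore",
    per_feature: bool = False,
) -> SelectionResult:
    """Linear membership rule: feature i joins component m if Phi(t) >= beta.

    Uses the global beta by default (``per_feature=True`` thresholds each
    feature by its own ``beta_i``).  Features passing for several components
    are resolved to the max-|loading| component; empty components are
    removed.  ``beta = 1`` is an error: the normal CDF is strictly below 1.
    """
    if M_max < 1:
        raise ValueError("M_max must be >= 1")
    M = min(M_max, model.n_components)
    t = _loading_stat(model, loading_transform)[:M]
    phi = ndtr(t)
    thresh = beta.beta_per_feature if per_feature else beta.beta_global
    passed = phi >= np.asarray(thresh)[None, :] if per_feature else phi >= thresh
    names = model.feature_names
    candidates: dict[str, list[tuple[int, float]]] = {}
    absload = np.abs(model.loadings[:M])
    for i, nm in enumerate(names):
        pairs = [(m, float(absload[m, i])) for m in range(M) if passed[m, i]]
        if pairs:
            candidates[nm] = pairs
    assignment = resolve_multiassignment(candidates)
    if not assignment:
        raise EmptySelectionError(
            f"no feature satisfies Phi(t) >= beta (beta={float(np.max(thresh)):.4f})"
        )
    assignment, M_ret = _prune(assignment)
    return SelectionResult(
        criterion="beta",
        M_retained=M_ret,
        assignment=assignment,
        retained_features=sorted(assignment, key=names.index),
        diagnostics={
            "phi": phi,
            "beta_global": beta.beta_global,
            "per_feature": per_feature,
            "loading_transform": loading_transform,
            "M_max": M,
        },
    )


def svm_margin_select(
    model: ExtractionModel,
    beta: BetaResult,
    margin_delta: float = 0.05,
    kernel: str = "rbf",
    seed: int = 0,
    loading_transform: str = "zscore",
    per_feature: bool = False,
    M_max: int | None = None,
) -> SelectionResult:
    """Margin variant of the membership rule with a kernel-SVM decision.

    Features whose best ``Phi(t)`` clears the threshold by ``margin_delta``
    form the positive teaching examples, those at least ``margin_delta``
    below it the negative ones; a kernel SVM trained on the descriptor
    vectors ``(Phi(t_1,i), ..., Phi(t_M,i), beta_i)`` classifies the
    in-margin features.  With ``margin_delta -> 0`` the rule coincides with
    :func:`assign_features`.  The exterior labeling of the teaching sample is
    a construction of this package (flagged in the diagnostics).
    """
    if margin_delta < 0:
        raise ValueError("margin_delta must be >= 0")
    M = model.n_components if M_max is None else min(M_max, model.n_components)
    t = _loading_stat(model, loading_transform)[:M]
    phi = ndtr(t)
    best = phi.max(axis=0)
    thresh = (
        np.asarray(beta.beta_per_feature, dtype=float)
        if per_feature
        else np.full(model.n_features, beta.beta_global)
    )
    pos = best >= thresh + margin_delta
    neg = best <= thresh - margin_delta
    ambiguous = ~(pos | neg)
    keep = pos.copy()
    used_svm = False
    if ambiguous.any():
        X = np.vstack([phi, beta.beta_per_feature[None, :]]).T
        X_train = X[pos | neg]
        y_train = np.where(pos[pos | neg], 1, -1)
        if len(np.unique(y_train)) < 2:
            warnings.warn(
                "one-class teaching sample; falling back to the linear rule",
                SelectionWarning,
            )
            keep = best >= thresh
        else:
            # the teaching sample is small and its labels are deterministic,
            # so a lightly regularized boundary is appropriate
            clf = SVC(kernel=kernel, C=10.0, gamma="scale", random_state=seed)
            clf.fit(X_train, y_train)
            keep[ambiguous] = clf.predict(X[ambiguous]) == 1
            used_svm = True
    if not keep.any():
        raise EmptySelectionError("svm_margin_select kept no feature")
    names = model.feature_names
    absload = np.abs(model.loadings[:M])
    candidates = {
        names[i]: [(m, float(absload[m, i])) for m in range(M)]
        for i in np.flatnonzero(keep)
    }
    assignment = resolve_multiassignment(candidates)
    assignment, M_ret = _prune(assignment)
    return SelectionResult(
        criterion="beta-svm",
        M_retained=M_ret,
        assignment=assignment,
        retained_features=sorted(assignment, key=names.index),
        diagnostics={
            "phi": phi,
            "margin_delta": margin_delta,
            "kernel": kernel,
            "n_ambiguous": int(ambiguous.sum()),
            "used_svm": used_svm,
            "teaching_labels": "margin-exterior construction (not from source data)",
            "per_feature": per_feature,
        },
    )


def _classical_features(
    model: ExtractionModel, M: int, loading_cutoff: float
) -> tuple[dict[str, int], list[str]]:
    """Feature retention for the classical criteria.

    Every feature goes to its max-|loading| component among the retained
    ``M``; features whose best loading magnitude falls below the salient-
    loading cutoff are dropped.
    """
    if M < 1:
        return {}, []
    absload = np.abs(model.loadings[:M])
    names = model.feature_names
    best_comp = absload.argmax(axis=0)
    best_val = absload.max(axis=0)
    assignment = {
        names[i]: int(best_comp[i])
        for i in range(len(names))
        if best_val[i] >= loading_cutoff
    }
    return assignment, sorted(assignment, key=names.index)


@dataclass
class PipelineConfig:
    """Knobs of the end-to-end selection pipeline."""

    loading_transform: str = "zscore"
    loading_cutoff: float = 0.4  # salient-loading rule for classical criteria
    margin_delta: float = 0.05
    kernel: str = "rbf"
    gamma: float = 0.1  # ccpca centroid blend
    cumvar_cap: float = 0.95  # candidate components cover <= this fraction
    #: drop retained components whose member features form an unreliable
    #: scale (component beta below the global beta)
    prune_unreliable: bool = True
    per_feature_beta: bool = False
    seed: int = 0
    n_components: int | None = None
    kpca_kernel: str = "rbf"


def _prune_unreliable_components(
    result: SelectionResult, Z: np.ndarray, beta: BetaResult, names: list[str]
) -> SelectionResult:
    """Remove components whose member features fail the reliability criterion.

    Each retained component's member set forms a candidate scale.  Because a
    Cronbach-type coefficient grows mechanically with the number of items,
    the component scale is projected to the full feature count via the
    Spearman-Brown relation (i.e., its correlation product is plugged into
    the beta formula at the common length) before being compared with the
    global beta; singletons use their per-feature beta, which is already on
    that scale.  Components that fall short are dropped with their features
    -- this is how components explaining progressively less variance fall
    away.  If every component fails, the most reliable one is kept with a
    warning.
    """
    comps = sorted(set(result.assignment.values()))
    if len(comps) <= 1:
        return result
    name_to_idx = {nm: j for j, nm in enumerate(names)}
    k_total = len(names)
    comp_beta: dict[int, float] = {}
    for m in comps:
        idx = [name_to_idx[f] for f, c in result.assignment.items() if c == m]
        if len(idx) >= 2:
            bb = compute_beta(Z[:, idx])
            comp_beta[m] = float(_beta_formula(k_total, bb.r_bar * bb.r_dot))
        else:
            comp_beta[m] = float(beta.beta_per_feature[idx[0]])
    keep = [m for m in comps if comp_beta[m] >= beta.beta_global]
    if not keep:
        best = max(comp_beta, key=lambda m: comp_beta[m])
        warnings.warn(
            "every component failed the reliability criterion; keeping the "
            f"most reliable one (component {best})",
            SelectionWarning,
        )
        keep = [best]
    assignment = {f: c for f, c in result.assignment.items() if c in keep}
    result.assignment = assignment
    result.M_retained = len(keep)
    result.retained_features = sorted(assignment, key=names.index)
    result.diagnostics["component_beta"] = comp_beta
    result.diagnostics["pruned_components"] = [m for m in comps if m not in keep]
    return result


def run_selection_pipeline(
    table: FeatureTable,
    method: str = "pca",
    criterion: str = "beta",
    config: PipelineConfig | None = None,
) -> tuple[SelectionResult, ExtractionModel]:
    """Standardize, fit a backend, and apply a selection criterion.

    The candidate component budget ``M_max`` is the number of leading
    components whose cumulative explained-variance fraction stays within the
    configured cap (at least 1).
    """
    cfg = config or PipelineConfig()
    if criterion not in CRITERIA:
        raise ValueError(f"unknown criterion: {criterion!r} (use one of {CRITERIA})")
    Z = extraction.standardize(table)
    kwargs: dict = {}
    if cfg.n_components is not None:
        kwargs["n_components"] = cfg.n_components
    if method == "ccpca":
        kwargs["gamma"] = cfg.gamma
    if method == "kpca":
        kwargs["kernel"] = cfg.kpca_kernel
    model = extraction.fit(method, Z, labels=table.labels, seed=cfg.seed, **kwargs)
    cum = np.cumsum(model.explained_variance_fraction)
    lam = model.eigenvalues
    # candidate pool: leading components within the cumulative-variance cap
    # that also carry at least an average share of variance (with a near-flat
    # eigenvalue tail the cap alone would admit dozens of noise components)
    M_max = max(
        1, min(int(np.sum(cum <= cfg.cumvar_cap)), int(np.sum(lam > lam.mean())))
    )
    if criterion in ("k", "sp", "ksp"):
        if criterion == "k":
            M, kdiag = kaiser_select(lam, return_diagnostics=True)
        elif criterion == "sp":
            M = scree_select(lam)
        else:
            M = fused_select(lam)
        if M == 0:
            raise EmptySelectionError(f"criterion {criterion!r} retained 0 components")
        assignment, retained = _classical_features(model, M, cfg.loading_cutoff)
        if not retained:
            raise EmptySelectionError(
                f"criterion {criterion!r}: no feature reaches the "
                f"salient-loading cutoff {cfg.loading_cutoff}"
            )
        assignment, M_ret = _prune(assignment)
        result = SelectionResult(
            criterion=criterion,
            M_retained=M_ret,
            assignment=assignment,
            retained_features=retained,
            diagnostics={
                "M_rule": M,
                "eigenvalues": lam,
                "loading_cutoff": cfg.loading_cutoff,
            },
        )
        if criterion == "k":
            result.diagnostics["kaiser"] = kdiag
    else:
        beta = compute_beta(Z.values)
        if criterion == "beta":
            result = assign_features(
                model,
                beta,
                M_max,
                loading_transform=cfg.loading_transform,
                per_feature=cfg.per_feature_beta,
            )
        else:
            result = svm_margin_select(
                model,
                beta,
                margin_delta=cfg.margin_delta,
                kernel=cfg.kernel,
                seed=cfg.seed,
                loading_transform=cfg.loading_transform,
                per_feature=cfg.per_feature_beta,
                M_max=M_max,
            )
        if cfg.prune_unreliable:
            result = _prune_unreliable_components(
                result, Z.values, beta, model.feature_names
            )
        result.diagnostics["beta"] = beta.beta_global
        result.diagnostics["M_max"] = M_max
    result.diagnostics["method"] = method
    result.diagnostics["n_retained_features"] = len(result.retained_features)
    return result, model
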