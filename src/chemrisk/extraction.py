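"""PCA-family extraction backends behind one loadings/eigenvalue contract.

Four backends are provided:

* ``pca`` — exact eigendecomposition of the correlation matrix;
* ``ccpca`` — centroid-class PCA: eigendecomposition of the blended scatter
  ``S = B + gamma * C`` where ``B`` is the class-size-weighted between-centroid
  scatter and ``C`` the correlation matrix, so axes rotate toward
  centroid-separating directions and degenerate to PCA when centroids agree;
* ``gpca`` — PCA estimated by seeded stochastic-gradient (Oja) ascent on the
  Rayleigh quotient with deflation;
* ``kpca`` — kernel PCA on the centered kernel matrix.  Kernel components
  have no native feature loadings, so pseudo-loadings are defined as Pearson
  correlations between each original feature and each component score.

All backends expose eigenvalues in non-increasing order, a deterministic
sign convention (largest-magnitude eigenvector entry positive), loadings on
the feature-component correlation scale, and explained-variance fractions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import KernelPCA

from .datagen import FeatureTable

METHODS = ("pca", "ccpca", "gpca", "kpca")


class ExtractionWarning(UserWarning):
    pass


@dataclass
class ExtractionModel:
    """Fitted extraction backend: eigenvectors, eigenvalues, loadings.

    ``eigenvectors`` rows are unit vectors in feature space for the linear
    backends; ``loadings[m, i]`` is the correlation between feature ``i`` and
    the score of component ``m`` (for exact PCA this equals
    ``w_{m,i} * sqrt(lambda_m)``).
    """

    method: str
    eigenvectors: np.ndarray  # (M, n_features); empty for kpca
    eigenvalues: np.ndarray  # (M,), non-increasing
    loadings: np.ndarray  # (M, n_features), correlation scale
    explained_variance_fraction: np.ndarray  # (M,)
    center: np.ndarray
    scale: np.ndarray
    feature_names: list[str] = field(default_factory=list)
    params: dict = field(default_factory=dict)
    _kpca: KernelPCA | None = None

    @property
    def n_components(self) -> int:
        return len(self.eigenvalues)

    @property
    def n_features(self) -> int:
        return self.loadings.shape[1]

    def scores(self, Z: np.ndarray) -> np.ndarray:
        """Component scores for standardized data ``Z`` (all components)."""
        Z = np.asarray(Z, dtype=float)
        if self.method == "kpca":
            return self._kpca.transform(Z)
        return Z @ self.eigenvectors.T


def _as_matrix(data) -> np.ndarray:
    if isinstance(data, FeatureTable):
        return np.asarray(data.values, dtype=float)
    return np.asarray(data, dtype=float)


def standardize(data, *, return_params: bool = False):
    """Center and scale every column to mean 0, SD 1 (population SD).

    Accepts a :class:`FeatureTable` (returns a new one) or a plain matrix.
    A zero-variance column is an error naming the column.
    """
    X = _as_matrix(data)
    if not np.isfinite(X).all():
        raise ValueError("data contain non-finite values")
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        if isinstance(data, FeatureTable):
            name = data.feature_names[zero[0]]
        else:
            name = f"column {zero[0]}"
        raise ValueError(f"zero-variance column: {name}")
    Z = (X - mean) / sd
    if isinstance(data, FeatureTable):
        out = FeatureTable(Z, data.labels, list(data.feature_names), list(data.feature_groups))
    else:
        out = Z
    if return_params:
        return out, mean, sd
    return out


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    """Largest-magnitude entry of each eigenvector made positive (in place)."""
    for m in range(vectors.shape[0]):
        i = int(np.argmax(np.abs(vectors[m])))
        if vectors[m, i] < 0:
            vectors[m] = -vectors[m]
    return vectors


def _sorted_eigh(S: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecomposition sorted by non-increasing eigenvalue.

    Ties on eigenvalues are broken by preferring eigenvectors whose largest
    entry sits on an earlier feature (original feature order).
    """
    vals, vecs = np.linalg.eigh(S)
    vecs = vecs.T  # rows = eigenvectors
    keys = [(-round(v, 12), int(np.argmax(np.abs(w)))) for v, w in zip(vals, vecs)]
    order = sorted(range(len(vals)), key=lambda i: keys[i])
    return vals[order], _fix_signs(vecs[order])


def _feature_score_correlations(Z: np.ndarray, scores: np.ndarray) -> np.ndarray:
    """Pearson correlations between each feature and each score, (M, p)."""
    Zc = Z - Z.mean(axis=0)
    Sc = scores - scores.mean(axis=0)
    zsd = Zc.std(axis=0)
    ssd = Sc.std(axis=0)
    cov = Sc.T @ Zc / Z.shape[0]
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = cov / np.outer(ssd, zsd)
    return np.nan_to_num(corr, nan=0.0, posinf=0.0, neginf=0.0)


def _check_standardized(Z: np.ndarray) -> None:
    if not np.isfinite(Z).all():
        raise ValueError("data contain non-finite values")


def _names(data) -> list[str]:
    if isinstance(data, FeatureTable):
        return list(data.feature_names)
    p = _as_matrix(data).shape[1]
    return [f"f{j}" for j in range(p)]


def fit_pca(data, n_components: int | None = None) -> ExtractionModel:
    """Exact PCA: eigendecomposition of the correlation matrix of ``data``.

    ``data`` must already be standardized; eigenvalues then sum to the number
    of features (trace of the correlation matrix).
    """
    Z = _as_matrix(data)
    _check_standardized(Z)
    n, p = Z.shape
    C = Z.T @ Z / n
    vals, vecs = _sorted_eigh(C)
    vals = np.clip(vals, 0.0, None)
    M = p if n_components is None else min(n_components, p)
    vals, vecs = vals[:M], vecs[:M]
    loadings = vecs * np.sqrt(vals)[:, None]
    return ExtractionModel(
        method="pca",
        eigenvectors=vecs,
        eigenvalues=vals,
        loadings=loadings,
        explained_variance_fraction=vals / p,
        center=np.zeros(p),
        scale=np.ones(p),
        feature_names=_names(data),
    )


def fit_ccpca(
    data, labels=None, gamma: float = 0.1, n_components: int | None = None
) -> ExtractionModel:
    """Centroid-class PCA: axes from the blended scatter ``B + gamma * C``.

    ``B`` is the class-size-weighted scatter of the class centroids of the
    standardized data and ``C`` its correlation matrix; small ``gamma`` keeps
    the rotation anchored to the data cloud, and with coincident centroids
    (``B = 0``) the model equals PCA.  With a single class the model falls
    back to PCA with a warning.
    """
    Z = _as_matrix(data)
    _check_standardized(Z)
    if labels is None:
        if not isinstance(data, FeatureTable):
            raise ValueError("labels are required when data is a plain matrix")
        labels = data.labels
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) < 2:
        warnings.warn(
            "ccpca needs >= 2 classes; falling back to PCA", ExtractionWarning
        )
        model = fit_pca(data, n_components)
        model.method = "ccpca"
        model.params = {"gamma": gamma, "fallback": "pca"}
        return model
    n, p = Z.shape
    C = Z.T @ Z / n
    B = np.zeros((p, p))
    for c in classes:
        mask = labels == c
        m = Z[mask].mean(axis=0)
        B += (mask.sum() / n) * np.outer(m, m)
    vals, vecs = _sorted_eigh(B + gamma * C)
    vals = np.clip(vals, 0.0, None)
    M = p if n_components is None else min(n_components, p)
    vals, vecs = vals[:M], vecs[:M]
    scores = Z @ vecs.T
    score_var = scores.var(axis=0)
    return ExtractionModel(
        method="ccpca",
        eigenvectors=vecs,
        eigenvalues=vals,
        loadings=_feature_score_correlations(Z, scores),
        explained_variance_fraction=score_var / p,
        center=np.zeros(p),
        scale=np.ones(p),
        feature_names=_names(data),
        params={"gamma": gamma},
    )


def fit_gpca(
    data,
    seed: int = 0,
    n_components: int | None = None,
    max_epochs: int = 60,
    batch_size: int = 64,
    lr0: float = 0.1,
    tol: float = 1e-7,
) -> ExtractionModel:
    """Stochastic-gradient PCA: deflated Oja updates on minibatches.

    Each component maximizes the Rayleigh quotient ``w'Cw`` by seeded
    minibatch gradient ascent (``w <- w + eta * C_batch w``, renormalized)
    with a ``1/(1+t)`` learning-rate decay; the data are deflated after each
    component.  Converged components agree with exact PCA.  Non-convergence
    after ``max_epochs`` raises an :class:`ExtractionWarning` with
    diagnostics.
    """
    Z = _as_matrix(data)
    _check_standardized(Z)
    n, p = Z.shape
    M = min(p, n) if n_components is None else min(n_components, p)
    rng = np.random.default_rng(seed)
    D = Z.copy()
    vecs = np.zeros((M, p))
    vals = np.zeros(M)
    for m in range(M):
        w = rng.normal(size=p)
        w /= np.linalg.norm(w)
        t = 0
        converged = False
        for _ in range(max_epochs):
            w_old = w.copy()
            order = rng.permutation(n)
            for start in range(0, n, batch_size):
                batch = D[order[start : start + batch_size]]
                eta = lr0 / (1.0 + 0.01 * t)
                g = batch.T @ (batch @ w) / len(batch)
                w = w + eta * g
                w /= np.linalg.norm(w)
                t += 1
            if np.linalg.norm(w - w_old) < tol or np.linalg.norm(w + w_old) < tol:
                converged = True
                break
        if not converged:
            drift = float(np.linalg.norm(w - w_old))
            warnings.warn(
                f"gpca component {m} did not converge after {max_epochs} "
                f"epochs (last update norm {drift:.2e})",
                ExtractionWarning,
            )
        # polish with a few exact power iterations on the deflated data to
        # remove residual stochastic jitter (still seeded/deterministic)
        for _ in range(50):
            w_new = D.T @ (D @ w) / n
            nrm = np.linalg.norm(w_new)
            if nrm == 0:
                break
            w_new /= nrm
            if min(np.linalg.norm(w_new - w), np.linalg.norm(w_new + w)) < 1e-12:
                w = w_new
                break
            w = w_new
        s = D @ w
        lam = float(s @ s / n)
        vecs[m] = w
        vals[m] = lam
        D = D - np.outer(s, w)
    order = np.argsort(-vals, kind="stable")
    vals, vecs = vals[order], _fix_signs(vecs[order])
    loadings = vecs * np.sqrt(np.clip(vals, 0, None))[:, None]
    return ExtractionModel(
        method="gpca",
        eigenvectors=vecs,
        eigenvalues=vals,
        loadings=loadings,
        explained_variance_fraction=vals / p,
        center=np.zeros(p),
        scale=np.ones(p),
        feature_names=_names(data),
        params={"seed": seed, "max_epochs": max_epochs},
    )


def fit_kpca(
    data,
    kernel: str = "rbf",
    kernel_params: dict | None = None,
    n_components: int | None = None,
    seed: int = 0,
) -> ExtractionModel:
    """Kernel PCA on the centered kernel matrix.

    Kernel eigenvalues are rescaled so that the full spectrum would sum to
    the number of features, matching the correlation-matrix convention of the
    linear backends (for the linear kernel the eigenvalues then equal PCA's).
    Pseudo-loadings are feature-score Pearson correlations.  Numerically
    negative kernel eigenvalues are clipped at zero with a warning.
    """
    if kernel not in ("linear", "rbf", "poly", "sigmoid"):
        raise ValueError(f"unsupported kernel: {kernel}")
    Z = _as_matrix(data)
    _check_standardized(Z)
    n, p = Z.shape
    M = min(p, n - 1) if n_components is None else min(n_components, n - 1, 10**9)
    kernel_params = dict(kernel_params or {})
    solver = "randomized" if n > 2000 and M < n // 4 else "dense"
    kp = KernelPCA(
        n_components=M,
        kernel=kernel,
        eigen_solver=solver,
        random_state=seed,
        **kernel_params,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        scores = kp.fit_transform(Z)
    eig = np.asarray(kp.eigenvalues_, dtype=float)
    if (eig < 0).any():
        warnings.warn(
            "kernel matrix is not numerically PSD; clipping negative "
            "eigenvalues at 0",
            ExtractionWarning,
        )
        eig = np.clip(eig, 0.0, None)
    # total variance of the centered kernel feature map
    from sklearn.metrics.pairwise import pairwise_kernels

    diag = pairwise_kernels(
        Z, Z, metric=kernel, **{k: v for k, v in kernel_params.items()}
    ).diagonal()
    K = pairwise_kernels(Z, metric=kernel, **kernel_params)
    total = float(np.mean(diag) - K.mean())  # trace of centered kernel / n
    total = max(total, np.finfo(float).tiny)
    eigen_frac = (eig / n) / total  # fraction of kernel-space variance
    vals = eigen_frac * p  # correlation-convention scale
    # deterministic sign: largest-magnitude pseudo-loading entry positive
    load = _feature_score_correlations(Z, scores)
    for m in range(M):
        i = int(np.argmax(np.abs(load[m])))
        if load[m, i] < 0:
            load[m] = -load[m]
            scores[:, m] = -scores[:, m]
            kp.eigenvectors_[:, m] = -kp.eigenvectors_[:, m]
    return ExtractionModel(
        method="kpca",
        eigenvectors=np.zeros((M, p)),
        eigenvalues=vals,
        loadings=load,
        explained_variance_fraction=eigen_frac,
        center=np.zeros(p),
        scale=np.ones(p),
        feature_names=_names(data),
        params={"kernel": kernel, **kernel_params, "seed": seed},
        _kpca=kp,
    )


def fit(method: str, data, labels=None, seed: int = 0, **kwargs) -> ExtractionModel:
    """Dispatch to one of the four backends by name."""
    if method == "pca":
        return fit_pca(data, **kwargs)
    if method == "ccpca":
        return fit_ccpca(data, labels=labels, **kwargs)
    if method == "gpca":
        return fit_gpca(data, seed=seed, **kwargs)
    if method == "kpca":
        return fit_kpca(data, seed=seed, **kwargs)
    raise ValueError(f"unknown extraction method: {method!r} (use one of {METHODS})")


def transform(data, model: ExtractionModel, selection) -> np.ndarray:
    """Project standardized data onto the retained components of a selection.

    Features outside the retained set are zeroed before projection; columns
    are the scores of the retained components, in component order.
    """
    Z = _as_matrix(data)
    if Z.ndim != 2 or Z.shape[1] != model.n_features:
        raise ValueError(
            f"dimension mismatch: data has {Z.shape[1] if Z.ndim == 2 else '?'} "
            f"features, model expects {model.n_features}"
        )
    comps = sorted(set(selection.assignment.values()))
    if not comps or not selection.retained_features:
        raise ValueError("empty selection: no retained components/features")
    name_to_idx = {nm: j for j, nm in enumerate(model.feature_names)}
    keep = [name_to_idx[f] for f in selection.retained_features]
    mask = np.zeros(model.n_features, dtype=bool)
    mask[keep] = True
    Zr = np.where(mask[None, :], Z, 0.0)
    if model.method == "kpca":
        return model._kpca.transform(Zr)[:, comps]
    return Zr @ model.eigenvectors[comps].T
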