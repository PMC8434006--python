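"""Seeded synthetic chemical-hazard datasets with a planted latent-factor structure.

The generator emulates a plant-floor risk-monitoring table: 63 sensor-derived
features in three groups (toxic concentrations, physicochemical properties,
network-security telemetry), four imbalanced risk classes, a low-dimensional
latent factor structure, and a small planted subspace of informative features
that carries the class signal.  Everything is deterministic given the seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import ndtri
from scipy.stats import rankdata

RISK_CLASSES = ("no", "low", "medium", "high")

#: Cyber-telemetry channels named after the five network-security factors
#: that dominate the security component of the latent structure.
CYBER_FACTOR_NAMES = (
    "packets_lost",
    "incorrect_logins",
    "incorrect_sensor_responses",
    "email_spam",
    "network_traffic",
)

GROUP_NAMES = ("toxic", "physicochemical", "network_security")


class InvalidConfigError(ValueError):
    """Raised when a generator configuration violates its invariants."""


class ParseError(ValueError):
    """Raised when a dataset file cannot be parsed; names the offending cell."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic chemical-hazard data generator.

    Defaults reproduce the printed structure of the study conditions:
    40,000 records, feature groups of 18/28/17, minority-class prevalences
    12.1% / 4% / 3.5% (no-risk takes the remainder), four latent factors,
    and an 18-feature informative subspace split 6/7/5 across the groups.
    """

    n_samples: int = 40_000
    group_sizes: tuple[int, int, int] = (18, 28, 17)
    class_fractions: tuple[float, float, float] = (0.121, 0.04, 0.035)
    informative_per_group: tuple[int, int, int] = (6, 7, 5)
    n_latent_factors: int = 4
    #: Scale of the class-centroid spacing in the hazard subspace, in
    #: within-class latent-factor SD units (adjacent classes sit roughly
    #: this far apart along the main hazard axis).
    centroid_separation: float = 3.0
    #: Base residual noise SD on the latent-factor scale (loadings have unit
    #: dominant entries).  Informative features receive half this noise;
    #: background features a spread of 0.6-1.6 times it.
    noise_sd: float = 0.6
    #: Fraction of (non-informative) features generated as a monotone
    #: nonlinear transform of their dominant latent factor.
    nonlinear_fraction: float = 0.1
    #: Background (non-informative) channels carry a salience spectrum, as
    #: real sensor arrays do: "strong" channels follow the latent factors
    #: almost as cleanly as the informative ones, "weak" channels follow
    #: them faintly, and "junk" channels are essentially idiosyncratic
    #: noise.  Informative channels use a fixed low noise multiplier of 0.4.
    background_noise_range: tuple[float, float] = (0.45, 0.85)
    n_weak_features: int = 8
    weak_loading_scale: float = 0.45
    weak_noise_range: tuple[float, float] = (1.0, 1.45)
    n_junk_features: int = 6
    junk_loading_scale: float = 0.25
    junk_noise_mult: float = 1.2
    #: Degrees of freedom of the Student-t residual noise on the weak and
    #: junk channels: glitchy sensors produce occasional multi-sigma spikes.
    #: Informative and strong channels keep Gaussian residuals.
    heavy_tail_df: float = 3.0
    #: Strength (relative to ``centroid_separation``) of a small
    #: class-correlated contrast signature inside the informative features'
    #: residual space: class structure that variance-driven components do
    #: not align with, but centroid-guided rotation can pick up.
    contrast_shift_scale: float = 0.12
    seed: int = 0

    @property
    def n_features(self) -> int:
        return int(sum(self.group_sizes))

    def validate(self) -> None:
        if any(g <= 0 for g in self.group_sizes):
            raise InvalidConfigError("group_sizes must be positive")
        if any(f < 0 for f in self.class_fractions):
            raise InvalidConfigError("class_fractions must be non-negative")
        if sum(self.class_fractions) >= 1.0:
            raise InvalidConfigError(
                "class_fractions must sum to < 1 (no-risk takes the remainder); "
                f"got sum={sum(self.class_fractions):g}"
            )
        if len(self.informative_per_group) != len(self.group_sizes):
            raise InvalidConfigError(
                "informative_per_group must match group_sizes in length"
            )
        for k, g in zip(self.informative_per_group, self.group_sizes):
            if k < 0 or k > g:
                raise InvalidConfigError(
                    "informative_per_group must be elementwise <= group_sizes"
                )
        if self.n_latent_factors < 2:
            raise InvalidConfigError(
                "n_latent_factors must be >= 2 (hazard factor + background)"
            )
        if self.n_latent_factors > self.n_features:
            raise InvalidConfigError("n_latent_factors cannot exceed n_features")
        if not 0.0 <= self.nonlinear_fraction <= 1.0:
            raise InvalidConfigError("nonlinear_fraction must lie in [0, 1]")
        if self.noise_sd < 0:
            raise InvalidConfigError("noise_sd must be >= 0")
        for name in ("background_noise_range", "weak_noise_range"):
            lo, hi = getattr(self, name)
            if not 0 < lo <= hi:
                raise InvalidConfigError(f"{name} must satisfy 0 < lo <= hi")
        if self.n_weak_features < 0 or self.n_junk_features < 0:
            raise InvalidConfigError("tier sizes must be >= 0")
        if self.heavy_tail_df <= 2:
            raise InvalidConfigError("heavy_tail_df must be > 2 (finite variance)")
        n_background = self.n_features - sum(self.informative_per_group)
        if self.n_weak_features + self.n_junk_features > n_background:
            raise InvalidConfigError(
                "weak + junk channels must fit among the "
                f"{n_background} non-informative features"
            )
        counts = allocate_class_counts(self.n_samples, self.class_fractions)
        if any(c == 0 for c in counts):
            raise InvalidConfigError(
                f"n_samples={self.n_samples} is too small to realize all "
                f"{len(RISK_CLASSES)} risk classes (counts {counts})"
            )


@dataclass
class FeatureTable:
    """A standardized sample x feature matrix with labels and group tags."""

    values: np.ndarray  # (n_samples, n_features), float
    labels: np.ndarray  # (n_samples,), str in RISK_CLASSES
    feature_names: list[str]
    feature_groups: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        n, p = self.values.shape
        if len(self.labels) != n:
            raise ValueError("labels length must match number of rows")
        if len(self.feature_names) != p or len(self.feature_groups) != p:
            raise ValueError("feature_names/feature_groups must match columns")
        unknown = set(self.labels) - set(RISK_CLASSES)
        if unknown:
            raise ValueError(f"unknown risk classes: {sorted(unknown)}")
        if not np.isfinite(self.values).all():
            raise ValueError("values contain non-finite entries")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df["risk_class"] = self.labels
        return df

    def class_counts(self) -> dict[str, int]:
        return {c: int(np.sum(self.labels == c)) for c in RISK_CLASSES}


@dataclass
class GroundTruth:
    """The planted mechanism behind a generated table (for recovery tests)."""

    loading_matrix: np.ndarray  # (n_features, n_factors) on the standardized scale
    informative_set: list[str]
    class_centroids: dict[str, np.ndarray]  # per-class feature-space mean shift
    dominant_factor: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    nonlinear_features: list[str] = field(default_factory=list)
    junk_features: list[str] = field(default_factory=list)
    weak_features: list[str] = field(default_factory=list)
    #: realized latent factors (hazard factor first, including class shifts);
    #: kept in memory for parameter-recovery tests, not written to disk
    latent_factors: np.ndarray = field(default_factory=lambda: np.empty((0, 0)))


def _largest_remainder(total: int, fractions: np.ndarray) -> list[int]:
    """Integer shares of ``total`` by largest-remainder rounding."""
    quotas = np.asarray(fractions, dtype=float) * total
    counts = np.floor(quotas).astype(int)
    rem = quotas - counts
    order = sorted(range(len(counts)), key=lambda i: (-rem[i], i))
    for i in order[: total - counts.sum()]:
        counts[i] += 1
    return counts.tolist()


def allocate_class_counts(
    n_samples: int, class_fractions: tuple[float, ...]
) -> list[int]:
    """Largest-remainder allocation of samples to the four risk classes.

    The no-risk class receives the remainder fraction.  Exact integer counts
    sum to ``n_samples``; ties on remainders are broken by class order.
    """
    fracs = [1.0 - sum(class_fractions), *class_fractions]
    if fracs[0] <= 0:
        raise InvalidConfigError("class_fractions must sum to < 1")
    quotas = [f * n_samples for f in fracs]
    counts = [int(np.floor(q)) for q in quotas]
    short = n_samples - sum(counts)
    remainders = [q - c for q, c in zip(quotas, counts)]
    order = sorted(range(len(fracs)), key=lambda i: (-remainders[i], i))
    for i in order[:short]:
        counts[i] += 1
    return counts


def _allocate_factors_to_groups(group_sizes, n_factors) -> list[list[int]]:
    """Split factor indices across groups proportionally to group size."""
    n_groups = len(group_sizes)
    total = sum(group_sizes)
    quotas = [g * n_factors / total for g in group_sizes]
    counts = [max(1, int(np.floor(q))) for q in quotas]
    # repair to exactly n_factors, favouring large remainders
    while sum(counts) > n_factors:
        i = int(np.argmax(counts))
        counts[i] -= 1
    remainders = [q - c for q, c in zip(quotas, counts)]
    order = sorted(range(n_groups), key=lambda i: (-remainders[i], i))
    j = 0
    while sum(counts) < n_factors:
        counts[order[j % n_groups]] += 1
        j += 1
    out, start = [], 0
    for c in counts:
        out.append(list(range(start, start + c)))
        start += c
    return out


def _background_factor_pools(
    bg_sizes: list[int], n_bg_factors: int, offset: int
) -> list[list[int]]:
    """Assign background factors to feature groups.

    With at least as many factors as groups this is a proportional split;
    with fewer factors, groups left without one share the factor that
    currently carries the least feature mass (background structure common
    to several groups, e.g. overall plant activity).
    """
    n_groups = len(bg_sizes)
    if n_bg_factors >= n_groups:
        pools = _allocate_factors_to_groups([max(s, 1) for s in bg_sizes], n_bg_factors)
        return [[f + offset for f in pool] for pool in pools]
    counts = _largest_remainder(
        n_bg_factors, np.asarray(bg_sizes, dtype=float) / max(sum(bg_sizes), 1)
    )
    pools: list[list[int]] = []
    start = 0
    for c in counts:
        pools.append(list(range(start + offset, start + c + offset)))
        start += c
    mass = {f: 0.0 for f in range(offset, offset + n_bg_factors)}
    for g, pool in enumerate(pools):
        for f in pool:
            mass[f] += bg_sizes[g] / max(len(pool), 1)
    for g, pool in enumerate(pools):
        if not pool:
            f = min(mass, key=lambda k: mass[k])
            pools[g] = [f]
            mass[f] += bg_sizes[g]
    return pools


#: class positions in the 2-D hazard subspace, in units of
#: ``centroid_separation``; risk grows along the first hazard axis while the
#: two highest classes also move out along the second, so the four classes
#: are not collinear and part of the discriminant structure is lost when a
#: criterion drops the smaller hazard component.
CLASS_GEOMETRY = {
    "no": (0.0, 0.0),
    "low": (1.0, 0.09),
    "medium": (1.7, 0.495),
    "high": (2.1, 0.99),
}


def _feature_names(config: GeneratorConfig) -> tuple[list[str], list[str]]:
    names: list[str] = []
    groups: list[str] = []
    n_toxic, n_phys, n_cyber = config.group_sizes
    names += [f"toxic_{i + 1:02d}" for i in range(n_toxic)]
    groups += ["toxic"] * n_toxic
    names += [f"physchem_{i + 1:02d}" for i in range(n_phys)]
    groups += ["physicochemical"] * n_phys
    cyber = list(CYBER_FACTOR_NAMES[:n_cyber])
    cyber += [f"cyber_{i + 1:02d}" for i in range(len(cyber), n_cyber)]
    names += cyber
    groups += ["network_security"] * n_cyber
    return names, groups


def generate_dataset(config: GeneratorConfig) -> tuple[FeatureTable, GroundTruth]:
    """Draw one seeded dataset from the planted latent-factor mechanism.

    Each sample is ``x = Lambda f + eps`` with standard-normal latent
    factors ``f``.  The first factor is the *hazard factor*: its loadings
    are supported exactly on the informative features, and the risk classes
    shift its mean in equal steps of ``centroid_separation`` (within-class
    factor SD units).  Class displacement in feature space is therefore
    nonzero only on the informative features, and the class signal lies
    inside the span of the leading components.  The remaining factors are
    background structure allocated to the feature groups.  A fraction of
    background features replace the linear map with a monotone nonlinearity
    of their dominant factor; network-security channels are generated as
    log-scale counts and normal-scored.  Columns are finally standardized
    to mean 0, SD 1 (population convention).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, p = config.n_samples, config.n_features
    n_factors = config.n_latent_factors
    names, groups = _feature_names(config)

    # --- labels: exact largest-remainder counts, then a seeded shuffle
    counts = allocate_class_counts(config.n_samples, config.class_fractions)
    labels = np.repeat(np.array(RISK_CLASSES, dtype=object), counts)
    rng.shuffle(labels)
    level = np.array([RISK_CLASSES.index(c) for c in labels], dtype=float)

    # --- informative subspace: named cyber factors first, random elsewhere
    informative_idx: list[int] = []
    offset = 0
    for g, (size, k) in enumerate(zip(config.group_sizes, config.informative_per_group)):
        block = np.arange(offset, offset + size)
        if groups[offset] == "network_security":
            n_named = min(k, len(CYBER_FACTOR_NAMES), size)
            chosen = list(block[:n_named])
            if k > n_named:
                extra = rng.choice(block[n_named:], size=k - n_named, replace=False)
                chosen += sorted(int(e) for e in extra)
        else:
            chosen = sorted(int(e) for e in rng.choice(block, size=k, replace=False))
        informative_idx += chosen
        offset += size
    informative_idx = sorted(informative_idx)
    is_informative = np.zeros(p, dtype=bool)
    is_informative[informative_idx] = True

    # --- loading matrix: the leading factors form the *hazard subspace*
    # (supported exactly on the informative features; the risk classes live
    # there), the remaining factors are background structure shared by the
    # feature groups
    n_hazard = min(2, n_factors - 1)
    n_bg_factors = n_factors - n_hazard
    group_of = np.array(
        sum(([g] * s for g, s in enumerate(config.group_sizes)), []), dtype=int
    )
    bg_sizes = [
        g - k for g, k in zip(config.group_sizes, config.informative_per_group)
    ]
    bg_pools = _background_factor_pools(bg_sizes, n_bg_factors, offset=n_hazard)
    dominant = np.empty(p, dtype=int)
    # informative features split unevenly over the hazard factors (15:3 for
    # the default 18): the second hazard factor is expressed by only a few
    # channels (one per group under the defaults), so its component sits low
    # on the eigenvalue ladder -- the component an elbow rule tends to drop
    for pos, i in enumerate(informative_idx):
        dominant[i] = 1 if (n_hazard == 2 and pos % 6 == 3) else 0
    for g in range(len(config.group_sizes)):
        idx = np.flatnonzero((group_of == g) & ~is_informative)
        pool = bg_pools[g]
        # contiguous, deliberately uneven shares (3:2:... ratios) so factors
        # of the same group differ in feature mass; equal masses would make
        # the component eigenvalues degenerate and the sample axes mix
        weights = np.array([1.5 ** -(j) for j in range(len(pool))])
        shares = _largest_remainder(len(idx), weights / weights.sum())
        start = 0
        for fct, s in zip(pool, shares):
            dominant[idx[start : start + s]] = fct
            start += s
    Lambda = rng.normal(0.0, 0.12, size=(p, n_factors))
    # non-informative features carry no hazard-subspace loading, so their
    # class-centroid displacement is exactly zero
    Lambda[np.ix_(~is_informative, np.arange(n_hazard))] = 0.0
    # per-factor strength scales stagger the eigenvalue ladder further
    scale_cycle = np.array([1.00, 0.90, 1.06, 0.95, 0.85, 1.02, 0.92, 1.08])
    factor_scale = np.concatenate(
        [np.full(n_hazard, 1.0),
         scale_cycle[np.arange(max(n_bg_factors, 0)) % len(scale_cycle)]]
    )
    Lambda[np.arange(p), dominant] = factor_scale[dominant]

    # --- salience tiers: informative channels are clean, background splits
    # into strong / weak / junk
    sigma = np.empty(p)
    sigma[is_informative] = 0.4 * config.noise_sd
    n_bg = int(p - is_informative.sum())
    lo, hi = config.background_noise_range
    sigma[~is_informative] = config.noise_sd * rng.uniform(lo, hi, size=n_bg)

    bg_pool = np.flatnonzero(~is_informative)
    n_weak = min(config.n_weak_features, len(bg_pool))
    weak_idx = (
        np.sort(rng.choice(bg_pool, size=n_weak, replace=False))
        if n_weak
        else np.empty(0, dtype=int)
    )
    is_weak = np.zeros(p, dtype=bool)
    is_weak[weak_idx] = True
    Lambda[weak_idx] *= config.weak_loading_scale
    wlo, whi = config.weak_noise_range
    sigma[weak_idx] = config.noise_sd * rng.uniform(wlo, whi, size=n_weak)

    junk_pool = np.flatnonzero(~is_informative & ~is_weak)
    n_junk = min(config.n_junk_features, len(junk_pool))
    junk_idx = (
        np.sort(rng.choice(junk_pool, size=n_junk, replace=False))
        if n_junk
        else np.empty(0, dtype=int)
    )
    is_junk = np.zeros(p, dtype=bool)
    is_junk[junk_idx] = True
    Lambda[junk_idx] *= config.junk_loading_scale
    sigma[junk_idx] = config.junk_noise_mult * config.noise_sd

    # --- nonlinear background features (strong tier only)
    nl_count = int(round(config.nonlinear_fraction * p))
    bg = np.flatnonzero(~is_informative & ~is_junk & ~is_weak)
    nl_count = min(nl_count, len(bg))
    nonlinear_idx = (
        np.sort(rng.choice(bg, size=nl_count, replace=False))
        if nl_count
        else np.empty(0, dtype=int)
    )
    is_nonlinear = np.zeros(p, dtype=bool)
    is_nonlinear[nonlinear_idx] = True

    # --- assemble the matrix; risk classes shift the hazard-subspace mean
    f = rng.normal(size=(n, n_factors))
    geom = np.array([CLASS_GEOMETRY[c] for c in RISK_CLASSES])  # (4, 2)
    for h in range(n_hazard):
        f[:, h] += config.centroid_separation * geom[level.astype(int), h]
    X = f @ Lambda.T
    # class-correlated contrast signature in the informative residual space
    # (alternating-sign pattern, severity-scaled; zero off the informative set)
    contrast = np.zeros(p)
    contrast[informative_idx] = [
        (-1) ** pos for pos in range(len(informative_idx))
    ]
    contrast /= max(np.linalg.norm(contrast), 1.0)
    severity = geom[level.astype(int), 0]
    X += (
        config.contrast_shift_scale * config.centroid_separation * severity
    )[:, None] * contrast[None, :]
    for j_pos, j in enumerate(nonlinear_idx):
        fd = f[:, dominant[j]]
        # monotone nonlinearities: exponential / sign-preserving square
        X[:, j] = np.exp(0.5 * fd) if j_pos % 2 == 0 else fd * np.abs(fd)
    eps = rng.normal(size=(n, p))
    glitchy = np.flatnonzero(is_weak | is_junk)
    if glitchy.size and np.isfinite(config.heavy_tail_df):
        # unit-variance Student-t spikes on the glitchy (weak/junk) channels
        df = config.heavy_tail_df
        tnoise = rng.standard_t(df, size=(n, glitchy.size))
        eps[:, glitchy] = tnoise * np.sqrt((df - 2.0) / df)
    X += eps * sigma[None, :]

    # --- network-security channels: log-scale counts, then normal scores
    cyber_cols = np.flatnonzero(np.array(groups) == "network_security")
    for j in cyber_cols:
        z = (X[:, j] - X[:, j].mean()) / max(X[:, j].std(), 1e-12)
        count = np.round(np.exp(0.6 * z + 4.0))
        ranks = rankdata(count, method="average")
        X[:, j] = ndtri((ranks - 0.5) / n)

    pre_mean = X.mean(axis=0)
    pre_sd = X.std(axis=0)
    X = (X - pre_mean) / pre_sd

    eff_loadings = Lambda / pre_sd[:, None]
    centroids = {
        c: config.centroid_separation
        * (
            Lambda[:, :n_hazard] @ geom[RISK_CLASSES.index(c), :n_hazard]
            + config.contrast_shift_scale
            * geom[RISK_CLASSES.index(c), 0]
            * contrast
        )
        / pre_sd
        for c in RISK_CLASSES
    }
    table = FeatureTable(X, labels, names, groups)
    truth = GroundTruth(
        loading_matrix=eff_loadings,
        informative_set=[names[i] for i in informative_idx],
        class_centroids=centroids,
        dominant_factor=dominant,
        nonlinear_features=[names[i] for i in nonlinear_idx],
        junk_features=[names[i] for i in junk_idx],
        weak_features=[names[i] for i in weak_idx],
        latent_factors=f,
    )
    return table, truth


# ---------------------------------------------------------------------------
# on-disk format: CSV with a `risk_class` column + JSON sidecar for group tags


def _meta_path(path: Path) -> Path:
    return path.with_name(path.name + ".meta.json")


def write_dataset(table: FeatureTable, path: str | Path) -> Path:
    """Write a table as CSV (header + risk_class column) with a JSON sidecar
    carrying the feature-group tags.  The round trip is lossless."""
    path = Path(path)
    df = table.to_frame()
    df.to_csv(path, index=False)
    meta = {
        "feature_groups": dict(zip(table.feature_names, table.feature_groups)),
    }
    _meta_path(path).write_text(json.dumps(meta, indent=1, sort_keys=True))
    return path


def _infer_group(name: str) -> str:
    if name.startswith("toxic_"):
        return "toxic"
    if name.startswith("physchem_"):
        return "physicochemical"
    if name.startswith("cyber_") or name in CYBER_FACTOR_NAMES:
        return "network_security"
    return "feature"


def read_dataset(path: str | Path) -> FeatureTable:
    """Read a dataset CSV written by :func:`write_dataset`.

    Parse failures name the offending row/column.  The sidecar meta file is
    optional; without it, group tags are inferred from the feature names.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: file is empty or has no header") from exc
    if "risk_class" not in df.columns:
        raise ParseError(f"{path}: malformed header, missing 'risk_class' column")
    feature_names = [c for c in df.columns if c != "risk_class"]
    if not feature_names:
        raise ParseError(f"{path}: no feature columns found")
    labels = df["risk_class"].astype(str).to_numpy()
    bad = np.flatnonzero(~np.isin(labels, RISK_CLASSES))
    if bad.size:
        raise ParseError(
            f"{path}: unknown class label {labels[bad[0]]!r} in row {bad[0]}"
        )
    values = np.empty((len(df), len(feature_names)))
    for j, c in enumerate(feature_names):
        col = pd.to_numeric(df[c], errors="coerce")
        bad = np.flatnonzero(col.isna().to_numpy() & df[c].notna().to_numpy())
        if col.isna().any():
            row = int(np.flatnonzero(col.isna())[0]) if not bad.size else int(bad[0])
            raise ParseError(f"{path}: non-numeric cell in column {c!r}, row {row}")
        values[:, j] = col.to_numpy(dtype=float)

    meta_file = _meta_path(path)
    if meta_file.exists():
        meta = json.loads(meta_file.read_text())
        group_map = meta.get("feature_groups", {})
        groups = [group_map.get(nm, _infer_group(nm)) for nm in feature_names]
    else:
        groups = [_infer_group(nm) for nm in feature_names]
    return FeatureTable(values, labels, feature_names, groups)


def config_to_dict(config: GeneratorConfig) -> dict:
    return dataclasses.asdict(config)
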