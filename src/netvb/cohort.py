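"""Cohort-level statistics on fitted network parameters.

Four analyses relate subject-specific virtual-brain parameters to clinical
data:

* inter-network contrasts — for each parameter, a subject's value in one
  network minus the mean over the other networks, covariate-adjusted and
  summarized per clinical group with BCa bootstrap confidence intervals;
* backward multiple regression of cognitive domain scores (Equivalent
  Scores 0-4) on the network parameters;
* feature selection for fingerprinting — LASSO on the diagnostic class,
  then a Pearson-correlation filter, then variance-inflation-factor pruning
  down to three uncorrelated features;
* cluster-count selection by the gap statistic followed by K-means
  assignment of every subject to a fingerprint cluster.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.linear_model import LassoCV
from statsmodels.stats.outliers_influence import variance_inflation_factor

from netvb.rww import FitParams

__all__ = [
    "SubjectRecord",
    "ContrastResult",
    "RegressionResult",
    "FingerprintModel",
    "network_contrast",
    "backward_regression",
    "select_features",
    "choose_k_gap",
    "kmeans_fingerprint",
    "cohort_to_frame",
    "frame_to_cohort",
    "DOMAINS",
    "CLASS_ORDER",
]

DOMAINS = (
    "memory",
    "language_fluency",
    "visuo_constructional",
    "attention",
    "executive",
)

#: Fixed ordinal encoding of the diagnostic class for LASSO / correlation.
CLASS_ORDER = ("HC", "AD", "FTD")

NETWORKS = ("DMN", "FPN", "LN", "AN", "VN", "SMN")
PARAMS = ("G", "J_NMDA", "w_plus", "J_i")


@dataclass
class SubjectRecord:
    """One subject: diagnosis, covariates, cognition, fitted parameters."""

    id: str
    group: str
    phenotype: str
    age: float
    sex: str  # "F" or "M"
    mmse: float
    domain_scores: dict[str, float]
    params: dict[str, FitParams]
    therapy: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 <= self.mmse <= 30:
            raise ValueError(f"MMSE {self.mmse} outside [0, 30]")
        for d, v in self.domain_scores.items():
            if not 0 <= v <= 4:
                raise ValueError(f"domain score {d}={v} outside [0, 4]")

    def param_value(self, network: str, parameter: str) -> float:
        return getattr(self.params[network], parameter)


@dataclass(frozen=True)
class ContrastResult:
    """Group summary of one network-vs-rest parameter contrast."""

    group: str
    network: str
    parameter: str
    mean_difference: float
    ci_low: float
    ci_high: float
    n_boot: int
    n_subjects: int


@dataclass(frozen=True)
class RegressionResult:
    """Final model of one backward-eliminated domain regression."""

    domain: str
    retained: tuple[str, ...]
    coefficients: dict[str, float]
    r2: float
    p_model: float


@dataclass(frozen=True)
class FingerprintModel:
    """K-means fingerprint over the selected features."""

    selected_features: tuple[str, ...]
    k: int
    centroids: np.ndarray
    labels: dict[str, int]
    seed: int
    cluster_summary: pd.DataFrame | None = None


def cohort_to_frame(cohort: list[SubjectRecord]) -> pd.DataFrame:
    """Flatten a cohort to one row per subject (``<network>_<param>`` columns)."""
    rows = []
    for s in cohort:
        row: dict = {
            "id": s.id,
            "group": s.group,
            "phenotype": s.phenotype,
            "age": s.age,
            "sex": s.sex,
            "mmse": s.mmse,
        }
        row.update({d: s.domain_scores.get(d, np.nan) for d in DOMAINS})
        for net, p in s.params.items():
            for name, v in p.as_dict().items():
                row[f"{net}_{name}"] = v
        for flag, v in s.therapy.items():
            row[f"therapy_{flag}"] = bool(v)
        rows.append(row)
    return pd.DataFrame(rows).set_index("id")


def frame_to_cohort(df: pd.DataFrame) -> list[SubjectRecord]:
    """Inverse of :func:`cohort_to_frame` for round-tripping cohort CSVs."""
    cohort = []
    for sid, row in df.iterrows():
        params = {}
        for net in NETWORKS:
            cols = [f"{net}_{p}" for p in PARAMS]
            if all(c in row.index and pd.notna(row[c]) for c in cols):
                params[net] = FitParams(
                    G=row[f"{net}_G"],
                    J_NMDA=row[f"{net}_J_NMDA"],
                    w_plus=row[f"{net}_w_plus"],
                    J_i=row[f"{net}_J_i"],
                )
        therapy = {
            c.removeprefix("therapy_"): bool(row[c])
            for c in row.index
            if c.startswith("therapy_")
        }
        cohort.append(
            SubjectRecord(
                id=str(sid),
                group=str(row["group"]),
                phenotype=str(row.get("phenotype", "")),
                age=float(row["age"]),
                sex=str(row["sex"]),
                mmse=float(row["mmse"]),
                domain_scores={d: float(row[d]) for d in DOMAINS if d in row.index},
                params=params,
                therapy=therapy,
            )
        )
    return cohort


def _covariate_adjust(
    values: np.ndarray, age: np.ndarray, sex01: np.ndarray
) -> np.ndarray:
    """Remove pooled linear age/sex effects, preserving the grand level."""
    X = sm.add_constant(
        np.column_stack([age - age.mean(), sex01 - sex01.mean()]), has_constant="add"
    )
    fit = sm.OLS(values, X).fit()
    return values - X[:, 1] * fit.params[1] - X[:, 2] * fit.params[2]


def network_contrast(
    cohort: list[SubjectRecord],
    parameter: str,
    network: str,
    covariates: tuple[str, ...] = ("age", "sex"),
    n_boot: int = 2000,
    seed: int = 0,
) -> dict[str, ContrastResult]:
    """Network-vs-rest contrast of one parameter, per clinical group.

    Per subject the contrast is the parameter value in ``network`` minus the
    mean over the other networks.  Contrasts are residualized on age and sex
    across the pooled cohort, then each group's mean is reported with a BCa
    bootstrap confidence interval (fixed ``seed``).
    """
    groups = sorted({s.group for s in cohort})
    for g in groups:
        if sum(s.group == g for s in cohort) < 3:
            raise ValueError(f"group {g!r} has fewer than 3 subjects")
    contrasts = []
    for s in cohort:
        missing = [n for n in NETWORKS if n not in s.params]
        if missing:
            raise ValueError(f"subject {s.id} missing network fits {missing}")
        val = s.param_value(network, parameter)
        others = [s.param_value(n, parameter) for n in NETWORKS if n != network]
        contrasts.append(val - float(np.mean(others)))
    contrasts = np.asarray(contrasts)
    if covariates:
        age = np.array([s.age for s in cohort], dtype=float)
        sex01 = np.array([1.0 if s.sex == "M" else 0.0 for s in cohort])
        contrasts = _covariate_adjust(contrasts, age, sex01)
    out: dict[str, ContrastResult] = {}
    rng = np.random.default_rng(seed)
    for g in groups:
        vals = contrasts[np.array([s.group == g for s in cohort])]
        if np.ptp(vals) == 0:
            lo = hi = float(vals[0])
        else:
            res = stats.bootstrap(
                (vals,),
                np.mean,
                n_resamples=n_boot,
                method="BCa",
                random_state=rng,
                vectorized=False,
            )
            lo, hi = float(res.confidence_interval.low), float(
                res.confidence_interval.high
            )
        m = float(vals.mean())
        out[g] = ContrastResult(
            group=g,
            network=network,
            parameter=parameter,
            mean_difference=m,
            ci_low=min(lo, m),
            ci_high=max(hi, m),
            n_boot=n_boot,
            n_subjects=len(vals),
        )
    return out


def backward_regression(
    y: pd.Series | np.ndarray,
    X: pd.DataFrame,
    alpha: float = 0.05,
    domain: str = "",
) -> RegressionResult:
    """OLS with backward elimination of non-significant predictors.

    Repeatedly removes the predictor with the largest p-value while that
    p-value is >= ``alpha`` (one predictor per step, ties broken by column
    name for determinism), until every retained predictor is significant or
    none remain.  Reports the final model's R^2 as the explained-variance
    fraction.
    """
    X = X.copy()
    y = np.asarray(y, dtype=float)
    if len(y) <= X.shape[1] + 1:
        raise ValueError("need n > number of predictors + 1")
    const = [c for c in X.columns if np.ptp(X[c].to_numpy()) == 0]
    if const:
        raise ValueError(f"constant predictor column(s) {const}")
    cols = sorted(X.columns)
    while cols:
        design = sm.add_constant(X[cols], has_constant="add")
        rank = np.linalg.matrix_rank(design.to_numpy())
        if rank < design.shape[1]:
            raise ValueError(f"rank-deficient design over columns {cols}")
        fit = sm.OLS(y, design).fit()
        pvals = fit.pvalues.drop("const")
        worst = pvals.sort_index().sort_values(kind="stable").index[-1]
        if pvals[worst] >= alpha:
            cols.remove(worst)
        else:
            return RegressionResult(
                domain=domain,
                retained=tuple(cols),
                coefficients={c: float(fit.params[c]) for c in cols},
                r2=float(fit.rsquared),
                p_model=float(fit.f_pvalue),
            )
    return RegressionResult(
        domain=domain, retained=(), coefficients={}, r2=0.0, p_model=1.0
    )


def encode_class(labels: list[str] | np.ndarray) -> np.ndarray:
    """Ordinal encoding of diagnosis labels in the fixed documented order
    (HC=0, AD=1, FTD=2; unknown labels get subsequent codes alphabetically)."""
    labels = np.asarray(labels)
    order = [c for c in CLASS_ORDER if c in labels]
    order += sorted(set(labels) - set(CLASS_ORDER))
    mapping = {c: i for i, c in enumerate(order)}
    return np.array([mapping[v] for v in labels], dtype=float)


def select_features(
    F: pd.DataFrame,
    diagnosis: list[str] | np.ndarray,
    pcc_cutoff: float = 0.1,
    target_count: int = 3,
    seed: int = 0,
) -> tuple[str, ...]:
    """Three-stage feature reduction: LASSO -> correlation filter -> VIF.

    Stage 1 keeps the features with non-zero coefficients in a
    cross-validated LASSO of the (ordinally encoded) diagnostic class on the
    standardized features.  Stage 2 drops survivors whose absolute Pearson
    correlation with the encoded class is below ``pcc_cutoff``.  Stage 3
    iteratively drops the highest-VIF feature until ``target_count`` remain.
    """
    yv = encode_class(diagnosis)
    if len(np.unique(yv)) < 2:
        raise ValueError("need at least two diagnostic classes")
    Z = (F - F.mean()) / F.std(ddof=0)
    Z = Z.dropna(axis=1)  # drops zero-variance features
    lasso = LassoCV(cv=5, random_state=seed, max_iter=50000).fit(Z.to_numpy(), yv)
    survivors = [c for c, b in zip(Z.columns, lasso.coef_) if abs(b) > 1e-10]
    if not survivors:
        # fully sparse solution: fall back to the strongest marginal features
        corr = Z.apply(lambda col: abs(np.corrcoef(col, yv)[0, 1]))
        survivors = list(corr.sort_values(ascending=False).index[:target_count])
        warnings.warn("LASSO removed all features; using marginal correlations")
    survivors = [
        c for c in survivors if abs(np.corrcoef(Z[c], yv)[0, 1]) >= pcc_cutoff
    ]
    if len(survivors) < target_count:
        warnings.warn(
            f"only {len(survivors)} features survive the correlation filter"
        )
        return tuple(survivors)
    while len(survivors) > target_count:
        M = sm.add_constant(Z[survivors].to_numpy(), has_constant="add")
        with np.errstate(divide="ignore"):
            vifs = [variance_inflation_factor(M, i + 1) for i in range(len(survivors))]
        vifs = [np.inf if not np.isfinite(v) else v for v in vifs]
        worst = int(np.argmax(vifs))
        survivors.pop(worst)
    return tuple(survivors)


def _pooled_dispersion(X: np.ndarray, k: int, seed: int) -> float:
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(X)
    return max(float(km.inertia_), 1e-12)


def choose_k_gap(
    F: pd.DataFrame | np.ndarray, k_max: int = 10, B: int = 50, seed: int = 0
) -> int:
    """Cluster count by the gap statistic (uniform-box reference).

    Gap(k) compares log within-cluster dispersion against B reference
    datasets drawn uniformly over the bounding box of the data; the smallest
    k with ``Gap(k) >= Gap(k+1) - s(k+1)`` (one-standard-error rule) wins.
    """
    X = np.asarray(F, dtype=float)
    if X.shape[0] <= k_max:
        raise ValueError("need more subjects than k_max")
    if np.ptp(X) == 0:
        raise ValueError("degenerate (all-identical) data")
    rng = np.random.default_rng(seed)
    lo, hi = X.min(axis=0), X.max(axis=0)
    log_w = np.array(
        [np.log(_pooled_dispersion(X, k, seed)) for k in range(1, k_max + 1)]
    )
    log_w_ref = np.empty((B, k_max))
    for b in range(B):
        ref = rng.uniform(lo, hi, size=X.shape)
        ref_seed = int(rng.integers(0, 2**31 - 1))
        for k in range(1, k_max + 1):
            log_w_ref[b, k - 1] = np.log(_pooled_dispersion(ref, k, ref_seed))
    gap = log_w_ref.mean(axis=0) - log_w
    s = log_w_ref.std(axis=0, ddof=0) * np.sqrt(1.0 + 1.0 / B)
    for k in range(1, k_max):
        if gap[k - 1] >= gap[k] - s[k]:
            return k
    return k_max


def kmeans_fingerprint(
    F: pd.DataFrame,
    k: int,
    seed: int = 0,
    cohort: list[SubjectRecord] | None = None,
) -> FingerprintModel:
    """K-means labeling of subjects in the selected-feature space.

    Uses k-means++ initialization with restarts and a fixed seed.  When the
    cohort is supplied, a per-cluster summary (size, mean MMSE, therapy
    counts) is attached for reporting.
    """
    if k > F.shape[0]:
        raise ValueError("k exceeds cohort size")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(F.to_numpy(float))
    labels = {str(sid): int(l) for sid, l in zip(F.index, km.labels_)}
    summary = None
    if cohort is not None:
        by_id = {s.id: s for s in cohort}
        rows = []
        for c in range(k):
            members = [by_id[sid] for sid in labels if labels[sid] == c and sid in by_id]
            row = {
                "cluster": c,
                "n": len(members),
                "mmse_mean": float(np.mean([s.mmse for s in members]))
                if members
                else np.nan,
                "mmse_sd": float(np.std([s.mmse for s in members], ddof=1))
                if len(members) > 1
                else np.nan,
            }
            flags = {f for s in members for f in s.therapy}
            for f in sorted(flags):
                row[f"n_{f}"] = sum(bool(s.therapy.get(f)) for s in members)
            rows.append(row)
        summary = pd.DataFrame(rows).set_index("cluster")
    return FingerprintModel(
        selected_features=tuple(str(c) for c in F.columns),
        k=k,
        centroids=km.cluster_centers_,
        labels=labels,
        seed=seed,
        cluster_summary=summary,
    )
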