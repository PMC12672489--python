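"""Minimum-data-set soil quality index (MDS-SQI) pipeline.

The procedure reduces a total data set (TDS) of correlated soil indicators to
a minimum data set (MDS) and aggregates it into a single soil quality index
per sample:

1. standardize indicators; check factorability (KMO, Bartlett sphericity);
2. PCA on the sample correlation matrix, retaining components with
   eigenvalue >= 1; loadings are eigenvectors scaled by sqrt(eigenvalue);
3. assign each indicator to the component where it loads strongest
   (absolute value); within each group rank indicators by the norm value
   N_i = sqrt(sum_k U_ik^2 e_k), the eigenvalue-weighted length of the
   loading vector over retained components;
4. keep indicators within 10% of the group's best norm, then prune: walking
   down by norm, drop any indicator significantly Pearson-correlated
   (two-sided p < 0.05) with an already-kept higher-norm indicator of the
   same group; the union over groups is the MDS;
5. score each MDS indicator with the sigmoid S(x) = 1 / (1 + (x/x_m)^b)
   where x_m is the indicator's all-sample mean and b = -2.5 (more is
   better) or +2.5 (less is better);
6. weight by communality share W_i = C_i / sum C_i and form
   SQI = sum_i W_i S_i, classified into five quality classes; pattern-level
   responsiveness is the sensitivity index SI = max(SQI) / min(SQI) over
   replicates.

`SoilQualityIndex` packages steps 1-6 as a scikit-learn style estimator
(fit on a samples x indicators frame, transform to per-indicator scores,
predict the composite index); the module-level functions expose each stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .tables import (
    IndicatorTable,
    LESS_IS_BETTER,
    MORE_IS_BETTER,
)

__all__ = [
    "PCAModel", "MDSSelection", "ScoringSpec", "SQIResult", "SoilQualityIndex",
    "standardize", "kmo", "kmo_from_corr", "bartlett", "bartlett_from_corr",
    "run_pca", "norm_values", "assign_groups", "select_high_norm",
    "prune_by_correlation", "correlation_facts_from_data", "snl_score",
    "score_table", "compute_weights", "compute_sqi", "classify_sqi",
    "sensitivity_index", "run_full_pipeline",
]

#: SQI class intervals.  The published ranges overlap at their endpoints
#: ("0.37-0.46" medium vs "0.46-0.55" high, with very high strictly >0.55);
#: the convention here assigns each shared endpoint to the class whose range
#: starts there, keeping "very high" strict: very low [0, 0.28), low
#: [0.28, 0.37), medium [0.37, 0.46), high [0.46, 0.55], very high (0.55, 1].
SQI_CLASS_BOUNDS: tuple[tuple[float, str], ...] = (
    (0.28, "very low"),
    (0.37, "low"),
    (0.46, "medium"),
    (0.55, "high"),
    (1.00, "very high"),
)


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, IndicatorTable):
        return X.values
    if isinstance(X, pd.DataFrame):
        return X
    raise TypeError("expected an IndicatorTable or a pandas DataFrame")


# ---------------------------------------------------------------------------
# Stage 1: standardization and factorability diagnostics
# ---------------------------------------------------------------------------

def standardize(X) -> pd.DataFrame:
    """Center each indicator to mean 0 and scale to sample (ddof=1) sd 1."""
    df = _as_frame(X)
    if len(df) < 3:
        raise ValueError("standardization requires at least 3 samples")
    sd = df.std(ddof=1)
    zero = sd[sd == 0]
    if len(zero):
        raise ValueError(f"zero-variance indicator(s): {list(zero.index)}")
    return (df - df.mean()) / sd


def _corr(X) -> tuple[pd.DataFrame, int]:
    df = _as_frame(X)
    return df.corr(), len(df)


def kmo_from_corr(R: pd.DataFrame | np.ndarray) -> float:
    """Overall Kaiser-Meyer-Olkin sampling adequacy from a correlation matrix.

    KMO = sum r_ij^2 / (sum r_ij^2 + sum q_ij^2) over i != j, where q are the
    partial correlations obtained from the inverse correlation matrix.
    """
    R = np.asarray(R, dtype=float)
    try:
        S = np.linalg.inv(R)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "correlation matrix is singular; consider removing a redundant indicator"
        ) from exc
    if not np.isfinite(S).all() or np.linalg.cond(R) > 1e12:
        raise ValueError(
            "correlation matrix is numerically singular; consider removing a redundant indicator"
        )
    d = np.sqrt(np.diag(S))
    Q = -S / np.outer(d, d)
    off = ~np.eye(R.shape[0], dtype=bool)
    r2 = np.sum(R[off] ** 2)
    q2 = np.sum(Q[off] ** 2)
    return float(r2 / (r2 + q2))


def kmo(X) -> float:
    """Overall KMO statistic of a samples x indicators table."""
    R, _ = _corr(X)
    return kmo_from_corr(R)


def bartlett_from_corr(R: pd.DataFrame | np.ndarray, n: int) -> tuple[float, int, float]:
    """Bartlett's test of sphericity from a correlation matrix and sample size.

    chi2 = -(n - 1 - (2p + 5) / 6) ln det(R), df = p (p - 1) / 2.
    """
    R = np.asarray(R, dtype=float)
    p = R.shape[0]
    sign, logdet = np.linalg.slogdet(R)
    if sign <= 0:
        raise ValueError("correlation matrix has non-positive determinant")
    chi2 = -(n - 1 - (2 * p + 5) / 6.0) * logdet
    df = p * (p - 1) // 2
    pval = float(stats.chi2.sf(chi2, df))
    return float(chi2), int(df), pval


def bartlett(X) -> tuple[float, int, float]:
    """Bartlett's sphericity test of a samples x indicators table."""
    df = _as_frame(X)
    n, p = df.shape
    if n <= p:
        warnings.warn(
            f"Bartlett's test with n={n} <= p={p} indicators is unreliable",
            stacklevel=2,
        )
    R = df.corr()
    return bartlett_from_corr(R, n)


# ---------------------------------------------------------------------------
# Stage 2: PCA on the correlation matrix
# ---------------------------------------------------------------------------

@dataclass
class PCAModel:
    """Correlation-matrix PCA restricted to components with eigenvalue >= 1.

    ``loadings`` are eigenvectors scaled by sqrt(eigenvalue), so each entry is
    the correlation of an indicator with a component and the squared row sums
    are communalities.  ``eigenvalues_full`` keeps the complete spectrum
    (sums to the indicator count p).
    """

    indicators: list[str]
    eigenvalues: np.ndarray          # retained, non-increasing, all >= threshold
    loadings: pd.DataFrame           # indicators x retained components
    n_total: int                     # p, total indicator count
    eigenvalues_full: np.ndarray | None = None

    @property
    def n_components(self) -> int:
        return len(self.eigenvalues)

    @property
    def contribution_rate(self) -> np.ndarray:
        """Percent of total variance per retained component: e_k / p * 100."""
        return self.eigenvalues / self.n_total * 100.0

    @property
    def cumulative_rate(self) -> np.ndarray:
        return np.cumsum(self.contribution_rate)

    @property
    def communalities(self) -> pd.Series:
        """C_i = sum_k U_ik^2 over retained components, in [0, 1]."""
        return (self.loadings ** 2).sum(axis=1)


def run_pca(Z, eigenvalue_threshold: float = 1.0) -> PCAModel:
    """Eigendecompose the sample correlation matrix of a standardized table.

    Components with eigenvalue >= ``eigenvalue_threshold`` are retained (ties
    at the threshold included).  Each loading column's sign is fixed so that
    its largest-|loading| entry is positive; the convention has no effect on
    norms, communalities or groups.
    """
    df = _as_frame(Z)
    R = df.corr().to_numpy()
    evals, evecs = np.linalg.eigh(R)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    keep = evals >= eigenvalue_threshold - 1e-12
    k = int(keep.sum())
    if k < 1:
        raise ValueError("no component reaches the eigenvalue threshold")
    load = evecs[:, :k] * np.sqrt(evals[:k])
    for j in range(k):
        if load[np.argmax(np.abs(load[:, j])), j] < 0:
            load[:, j] = -load[:, j]
    return PCAModel(
        indicators=list(df.columns),
        eigenvalues=evals[:k],
        loadings=pd.DataFrame(
            load, index=df.columns, columns=[f"PC{j + 1}" for j in range(k)]
        ),
        n_total=df.shape[1],
        eigenvalues_full=evals,
    )


def norm_values(model: PCAModel) -> pd.Series:
    """Norm value per indicator: N_i = sqrt(sum_k U_ik^2 e_k).

    The eigenvalue-weighted length of the loading vector over retained
    components; larger N_i means the indicator carries more of the retained
    variance and better represents the data set.
    """
    L2 = model.loadings.to_numpy() ** 2
    return pd.Series(
        np.sqrt(L2 @ model.eigenvalues), index=model.loadings.index
    )


def assign_groups(model: PCAModel) -> pd.Series:
    """Assign each indicator to the retained component with the largest
    absolute loading (1-based index; exact ties go to the lower index)."""
    idx = np.argmax(np.abs(model.loadings.to_numpy()), axis=1)
    return pd.Series(idx + 1, index=model.loadings.index)


# ---------------------------------------------------------------------------
# Stage 3: MDS selection
# ---------------------------------------------------------------------------

@dataclass
class MDSSelection:
    """Outcome of the MDS selection chain with a per-indicator audit trail."""

    group_of: pd.Series              # indicator -> group (1-based)
    norm: pd.Series                  # indicator -> N_i
    high_norm_sets: dict[int, list[str]]   # group -> retained, norm-descending
    mds: list[str]                   # final minimum data set, grouped order
    audit: dict[str, str] = field(default_factory=dict)


def select_high_norm(
    groups: pd.Series, norms: pd.Series, band: float = 0.10
) -> dict[int, list[str]]:
    """Within each group keep indicators whose norm is within ``band`` of the
    group's highest norm (N_i >= (1 - band) * max, inclusive)."""
    out: dict[int, list[str]] = {}
    for g in sorted(groups.unique()):
        members = norms[groups[groups == g].index].sort_values(ascending=False)
        cutoff = (1.0 - band) * members.iloc[0]
        out[int(g)] = [name for name, v in members.items() if v >= cutoff]
    return out


def correlation_facts_from_data(
    df: pd.DataFrame, names: Sequence[str], alpha: float = 0.05
) -> dict[frozenset, tuple[float, bool]]:
    """Pearson r and two-sided significance (t-transform, n-2 df) for every
    pair among ``names``, keyed by the unordered pair."""
    facts: dict[frozenset, tuple[float, bool]] = {}
    names = list(names)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            r, p = stats.pearsonr(df[a], df[b])
            facts[frozenset((a, b))] = (float(r), bool(p < alpha))
    return facts


def prune_by_correlation(
    high_norm_sets: Mapping[int, Sequence[str]],
    norms: pd.Series,
    facts: Mapping[frozenset, tuple[float | None, bool]],
    groups: pd.Series | None = None,
) -> MDSSelection:
    """Greedy within-group redundancy pruning by descending norm.

    An indicator is kept unless it is significantly correlated with an
    already-kept higher-norm indicator of its own group.  A missing
    correlation fact for a needed pair is an error.
    """
    audit: dict[str, str] = {}
    mds: list[str] = []
    kept_sets: dict[int, list[str]] = {}
    for g in sorted(high_norm_sets):
        ordered = sorted(high_norm_sets[g], key=lambda n: -norms[n])
        kept: list[str] = []
        for name in ordered:
            blocker = None
            for other in kept:
                pair = frozenset((name, other))
                if pair not in facts:
                    raise KeyError(
                        f"missing correlation fact for pair ({name}, {other}) in group {g}"
                    )
                r, significant = facts[pair]
                if significant:
                    blocker = (other, r)
                    break
            if blocker is None:
                kept.append(name)
                audit[name] = f"retained (group {g}, norm {norms[name]:.3f})"
            else:
                other, r = blocker
                r_txt = "r not printed" if r is None else f"r = {r:.2f}"
                audit[name] = (
                    f"dropped-by-correlation with {other} ({r_txt}) in group {g}"
                )
        kept_sets[g] = kept
        mds.extend(kept)
    if groups is not None:
        for name in groups.index:
            if name not in audit:
                g = int(groups[name])
                audit[name] = f"below-10%-band (group {g}, norm {norms[name]:.3f})"
        group_of = groups
    else:
        group_of = pd.Series(
            {n: g for g, members in high_norm_sets.items() for n in members}
        )
    if not mds:
        raise ValueError("selection produced an empty minimum data set")
    return MDSSelection(
        group_of=group_of,
        norm=norms,
        high_norm_sets={g: list(v) for g, v in high_norm_sets.items()},
        mds=mds,
        audit=audit,
    )


# ---------------------------------------------------------------------------
# Stage 4: scoring, weighting, the index
# ---------------------------------------------------------------------------

@dataclass
class ScoringSpec:
    """Per-indicator sigmoid scoring parameters.

    ``x_m`` is the all-sample mean of each indicator; ``b`` is -2.5 for
    more-is-better indicators and +2.5 for less-is-better ones; ``a`` (the
    maximum score) is 1.
    """

    x_m: pd.Series
    b: pd.Series
    a: float = 1.0

    def __post_init__(self) -> None:
        if (self.x_m <= 0).any():
            bad = list(self.x_m[self.x_m <= 0].index)
            raise ValueError(f"scoring requires positive means; offending: {bad}")


def build_scoring_spec(
    df: pd.DataFrame,
    orientations: Mapping[str, str],
    names: Sequence[str] | None = None,
    b_magnitude: float = 2.5,
) -> ScoringSpec:
    names = list(names) if names is not None else list(df.columns)
    x_m = df[names].mean()
    b = pd.Series(
        [
            -b_magnitude if orientations.get(n, MORE_IS_BETTER) == MORE_IS_BETTER
            else b_magnitude
            for n in names
        ],
        index=names,
        dtype=float,
    )
    return ScoringSpec(x_m=x_m, b=b)


def snl_score(x: float, x_m: float, b: float, a: float = 1.0) -> float:
    """Sigmoid score S = a / (1 + (x / x_m)^b), bounded in (0, 1) for x > 0.

    Limit conventions at x = 0: score 0 when b < 0 (more is better), score 1
    when b > 0 (less is better).
    """
    if x < 0:
        raise ValueError("measurement must be non-negative")
    if not x_m > 0:
        raise ValueError("scoring mean x_m must be positive")
    if x == 0:
        return 0.0 if b < 0 else a
    return a / (1.0 + (x / x_m) ** b)


def score_table(df: pd.DataFrame, spec: ScoringSpec) -> pd.DataFrame:
    """Vectorized sigmoid scoring of the columns named in the scoring spec."""
    names = list(spec.x_m.index)
    X = df[names].to_numpy(dtype=float)
    if (X < 0).any():
        raise ValueError("measurements must be non-negative")
    ratio = X / spec.x_m.to_numpy()
    b = spec.b.to_numpy()
    with np.errstate(divide="ignore"):
        S = spec.a / (1.0 + ratio ** b)
    S = np.where((X == 0) & (b < 0), 0.0, S)
    S = np.where((X == 0) & (b > 0), spec.a, S)
    return pd.DataFrame(S, index=df.index, columns=names)


def compute_weights(communalities: pd.Series) -> pd.Series:
    """Communality-share weights W_i = C_i / sum(C_i); sums to 1."""
    if len(communalities) == 0:
        raise ValueError("cannot compute weights for an empty minimum data set")
    if (communalities <= 0).any():
        bad = list(communalities[communalities <= 0].index)
        raise ValueError(f"communalities must be positive; offending: {bad}")
    return communalities / communalities.sum()


def classify_sqi(value: float) -> str:
    """Five-class soil quality label (see `SQI_CLASS_BOUNDS` for the
    endpoint convention: 0.46 is "high", anything above 0.55 "very high")."""
    if value > 0.55:
        return "very high"
    if value >= 0.46:
        return "high"
    if value >= 0.37:
        return "medium"
    if value >= 0.28:
        return "low"
    return "very low"


def compute_sqi(scores: pd.DataFrame, weights: pd.Series) -> tuple[pd.Series, pd.Series]:
    """Weighted additive index SQI = sum_i W_i S_i with class labels."""
    if not np.isclose(weights.sum(), 1.0, atol=1e-10):
        raise ValueError("weights must sum to 1")
    S = scores[weights.index]
    if ((S <= 0) | (S >= 1)).any().any():
        raise ValueError("scores must lie strictly inside (0, 1)")
    sqi = S.mul(weights, axis=1).sum(axis=1)
    labels = sqi.map(classify_sqi)
    return sqi, labels


def sensitivity_index(sqi: pd.Series, patterns: pd.Series) -> pd.Series:
    """Pattern-level sensitivity SI = max(SQI) / min(SQI) over replicates."""
    patterns = patterns.reindex(sqi.index)
    out = {}
    for pat, vals in sqi.groupby(patterns):
        if len(vals) < 2:
            raise ValueError(f"pattern {pat!r} has fewer than 2 replicates")
        out[pat] = float(vals.max() / vals.min())
    return pd.Series(out, name="SI")


@dataclass
class SQIResult:
    """Per-sample scores, index values and class labels, plus weights and
    pattern-level aggregates."""

    scores: pd.DataFrame             # samples x MDS indicators, in (0, 1)
    sqi: pd.Series                   # per-sample index
    sqi_class: pd.Series             # per-sample class label
    weights: pd.Series               # MDS weights, sum 1
    pattern_mean: pd.Series | None = None
    pattern_sd: pd.Series | None = None
    sensitivity: pd.Series | None = None


# ---------------------------------------------------------------------------
# The estimator
# ---------------------------------------------------------------------------

class SoilQualityIndex(BaseEstimator, TransformerMixin):
    """Minimum-data-set soil quality index, scikit-learn style.

    ``fit`` learns the whole selection chain from a samples x indicators
    frame: factorability diagnostics, correlation PCA, grouping, norm-based
    retention, correlation pruning, communality weights and the all-sample
    scoring means.  ``transform`` maps (new) samples to per-indicator sigmoid
    scores on the selected MDS; ``predict`` returns the composite index.

    Parameters
    ----------
    orientations : mapping indicator -> {"more_is_better", "less_is_better"},
        optional.  Defaults to more-is-better for everything except ``BD``.
    eigenvalue_threshold : retain components with eigenvalue >= this (1.0).
    norm_band : within-group retention band on norm values (0.10 = 10%).
    alpha : two-sided significance level for correlation pruning (0.05).
    b_magnitude : |b| of the sigmoid scoring function (2.5).
    correlation_facts : optional externally supplied pairwise facts
        (unordered pair -> (r, significant)); when omitted, facts are
        computed from the training data.

    Attributes (after fit)
    ----------------------
    kmo_, bartlett_chi2_, bartlett_df_, bartlett_p_ : adequacy diagnostics.
    pca_ : PCAModel on retained components.
    norms_, groups_ : per-indicator norm values and group assignment.
    selection_ : MDSSelection with the audit trail.
    mds_ : final indicator list; weights_ : communality-share weights.
    scoring_ : ScoringSpec (x_m = all-sample means, b by orientation).
    audit_ : human-readable account of every selection decision.
    """

    def __init__(
        self,
        orientations: Mapping[str, str] | None = None,
        eigenvalue_threshold: float = 1.0,
        norm_band: float = 0.10,
        alpha: float = 0.05,
        b_magnitude: float = 2.5,
        correlation_facts: Mapping[frozenset, tuple[float | None, bool]] | None = None,
    ) -> None:
        self.orientations = orientations
        self.eigenvalue_threshold = eigenvalue_threshold
        self.norm_band = norm_band
        self.alpha = alpha
        self.b_magnitude = b_magnitude
        self.correlation_facts = correlation_facts

    # -- fitting ------------------------------------------------------------

    def _resolve_orientations(self, names: Sequence[str]) -> dict[str, str]:
        out = {n: LESS_IS_BETTER if n == "BD" else MORE_IS_BETTER for n in names}
        if self.orientations:
            for k, v in self.orientations.items():
                if v not in (MORE_IS_BETTER, LESS_IS_BETTER):
                    raise ValueError(f"unknown orientation {v!r} for {k!r}")
                out[k] = v
        return out

    def fit(self, X, y=None) -> "SoilQualityIndex":
        df = _as_frame(X)
        self.feature_names_in_ = np.asarray(df.columns, dtype=object)
        self.n_features_in_ = df.shape[1]
        orientations = self._resolve_orientations(df.columns)

        Z = standardize(df)
        self.kmo_ = kmo(df)
        self.bartlett_chi2_, self.bartlett_df_, self.bartlett_p_ = bartlett(df)
        audit = [
            f"samples: {len(df)}, indicators: {df.shape[1]}",
            f"KMO = {self.kmo_:.3f}; Bartlett chi2 = {self.bartlett_chi2_:.2f} "
            f"(df {self.bartlett_df_}, p = {self.bartlett_p_:.3g})",
        ]
        if self.kmo_ < 0.5:
            warnings.warn(f"KMO = {self.kmo_:.3f} < 0.5: data weakly factorable")
            audit.append("warning: KMO < 0.5")
        if self.bartlett_p_ >= 0.05:
            warnings.warn(
                f"Bartlett p = {self.bartlett_p_:.3g} >= 0.05: correlation "
                "matrix close to identity"
            )
            audit.append("warning: Bartlett p >= 0.05")

        self.pca_ = run_pca(Z, self.eigenvalue_threshold)
        audit.append(
            f"retained {self.pca_.n_components} components "
            f"(eigenvalues {np.round(self.pca_.eigenvalues, 3).tolist()}, "
            f"cumulative {self.pca_.cumulative_rate[-1]:.1f}% of variance)"
        )
        self.norms_ = norm_values(self.pca_)
        self.groups_ = assign_groups(self.pca_)
        high = select_high_norm(self.groups_, self.norms_, self.norm_band)
        for g, members in high.items():
            audit.append(f"group {g}: high-norm candidates {members}")

        if self.correlation_facts is not None:
            facts = dict(self.correlation_facts)
        else:
            needed = sorted({n for members in high.values() for n in members})
            facts = correlation_facts_from_data(df, needed, self.alpha)
        self.selection_ = prune_by_correlation(high, self.norms_, facts, self.groups_)
        for name in self.selection_.group_of.index:
            audit.append(f"  {name}: {self.selection_.audit[name]}")
        self.mds_ = list(self.selection_.mds)
        audit.append(f"minimum data set ({len(self.mds_)}): {self.mds_}")

        self.weights_ = compute_weights(self.pca_.communalities[self.mds_])
        audit.append(
            "weights (communality shares): "
            + ", ".join(f"{n} = {w:.3f}" for n, w in self.weights_.items())
        )
        self.scoring_ = build_scoring_spec(
            df, orientations, self.mds_, self.b_magnitude
        )
        audit.append(
            "scoring: sigmoid with |b| = "
            f"{self.b_magnitude}, x_m = all-sample means; weights sum to 1 and "
            "scores lie in (0,1), so the index is already on the 0-1 scale "
            "(no further rescaling applied)"
        )
        self.audit_ = "\n".join(audit)
        return self

    # -- application --------------------------------------------------------

    def _check_fitted(self) -> None:
        if not hasattr(self, "mds_"):
            raise RuntimeError("estimator is not fitted; call fit first")

    def transform(self, X) -> pd.DataFrame:
        """Per-indicator sigmoid scores on the MDS columns, in (0, 1)."""
        self._check_fitted()
        return score_table(_as_frame(X), self.scoring_)

    def predict(self, X) -> pd.Series:
        """Composite soil quality index per sample."""
        self._check_fitted()
        sqi, _ = compute_sqi(self.transform(X), self.weights_)
        return sqi

    def evaluate(self, X, patterns: pd.Series | None = None) -> SQIResult:
        """Full per-sample result; with ``patterns`` also pattern aggregates
        and the sensitivity index."""
        self._check_fitted()
        scores = self.transform(X)
        sqi, labels = compute_sqi(scores, self.weights_)
        result = SQIResult(
            scores=scores, sqi=sqi, sqi_class=labels, weights=self.weights_
        )
        if patterns is not None:
            patterns = patterns.reindex(sqi.index)
            result.pattern_mean = sqi.groupby(patterns).mean()
            result.pattern_sd = sqi.groupby(patterns).std(ddof=1)
            result.sensitivity = sensitivity_index(sqi, patterns)
        return result


def run_full_pipeline(
    table: IndicatorTable,
    config: Mapping | None = None,
) -> tuple[PCAModel, MDSSelection, SQIResult, str]:
    """One-call pipeline on a validated indicator table.

    Returns the PCA model, the MDS selection, the per-sample/per-pattern
    result, and the human-readable audit of every selection decision.
    """
    config = dict(config or {})
    est = SoilQualityIndex(
        orientations={s.name: s.orientation for s in table.specs},
        eigenvalue_threshold=config.get("eigenvalue_threshold", 1.0),
        norm_band=config.get("norm_band", 0.10),
        alpha=config.get("alpha", 0.05),
        b_magnitude=config.get("b_magnitude", 2.5),
        correlation_facts=config.get("correlation_facts"),
    )
    df = table.values
    est.fit(df)
    result = est.evaluate(df, patterns=table.patterns)
    return est.pca_, est.selection_, result, est.audit_
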