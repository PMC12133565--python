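"""Count normalization and differential testing.

Implements median-of-ratios size factors, variance-stabilizing
transforms, a PCA summary, a negative-binomial moment/Wald differential
test, Benjamini-Hochberg adjustment, and threshold-based up/down calling
(default: adjusted p < 0.05 and |log2 fold change| >= 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CountsMatrix",
    "NormalizedMatrix",
    "DifferentialRecord",
    "AnalysisConfig",
    "parse_counts_table",
    "write_counts_table",
    "size_factors_median_of_ratios",
    "vst_normalize",
    "pca_embed",
    "nb_wald_test",
    "bh_adjust",
    "call_differential",
]


@dataclass
class AnalysisConfig:
    """Thresholds and windows for the whole pipeline.

    ``alpha_de``/``lfc_min`` are the differential-calling thresholds
    (adjusted p < 0.05, |LFC| >= 1 by default); ``alpha_corr`` is the
    peak-gene correlation significance level on the raw p-value.
    """

    alpha_de: float = 0.05
    lfc_min: float = 1.0
    alpha_corr: float = 0.05
    corr_adjust: bool = False
    promoter_window: tuple[int, int] = (1000, 100)
    tts_window: int = 100
    min_samples: int = 2
    lfc_pseudocount: float = 0.5
    pwm_pseudocount: float = 0.8
    vst_method: str = "asinh_nb"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("alpha_de", "alpha_corr"):
            a = getattr(self, name)
            if not 0 < a < 1:
                raise ValueError(f"{name} must be in (0,1), got {a}")
        if self.lfc_min < 0:
            raise ValueError("lfc_min must be >= 0")


class CountsMatrix:
    """A features x samples matrix of non-negative integer counts with
    optional per-sample group labels ('A'/'B')."""

    def __init__(
        self,
        values: np.ndarray | pd.DataFrame,
        feature_ids: Sequence[str] | None = None,
        sample_ids: Sequence[str] | None = None,
        group_labels: dict[str, str] | None = None,
    ):
        if isinstance(values, pd.DataFrame):
            feature_ids = list(values.index)
            sample_ids = list(values.columns)
            values = values.to_numpy()
        values = np.asarray(values)
        if values.ndim != 2:
            raise ValueError("counts must be 2-dimensional")
        if not np.issubdtype(values.dtype, np.integer):
            if not np.all(values == np.floor(values)):
                raise ValueError("counts must be integers")
            values = values.astype(np.int64)
        if np.any(values < 0):
            raise ValueError("counts must be non-negative")
        self.values = values
        self.feature_ids = list(feature_ids) if feature_ids is not None else [
            f"feature_{i}" for i in range(values.shape[0])
        ]
        self.sample_ids = list(sample_ids) if sample_ids is not None else [
            f"sample_{j}" for j in range(values.shape[1])
        ]
        if len(self.feature_ids) != values.shape[0]:
            raise ValueError("feature_ids length mismatch")
        if len(self.sample_ids) != values.shape[1]:
            raise ValueError("sample_ids length mismatch")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError("duplicate feature ids")
        self.group_labels = dict(group_labels) if group_labels else {}

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.feature_ids, columns=self.sample_ids
        )

    def group_mask(self, label: str) -> np.ndarray:
        return np.array([self.group_labels.get(s) == label for s in self.sample_ids])


@dataclass
class NormalizedMatrix:
    """VST-normalized values with the size factors that produced them."""

    values: np.ndarray
    feature_ids: list[str]
    sample_ids: list[str]
    size_factors: np.ndarray
    method: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.feature_ids, columns=self.sample_ids
        )

    def row(self, feature_id: str) -> np.ndarray:
        return self.values[self.feature_ids.index(feature_id)]


@dataclass
class DifferentialRecord:
    feature_id: str
    base_mean: float
    lfc: float
    se: float
    p_raw: float
    p_adj: float = float("nan")
    call: str = "ns"


def parse_counts_table(path: str | Path) -> CountsMatrix:
    """Read a TSV count table: first column feature ids, header of sample ids.

    Rejects negative or non-integer cells, ragged rows, duplicate
    feature ids and empty data sections.
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, header=0)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"{path}: no features") from exc
    if df.shape[0] == 0:
        raise ValueError(f"{path}: no features")
    if df.isna().any().any():
        bad = np.argwhere(df.isna().to_numpy())[0]
        raise ValueError(
            f"{path}: ragged or missing cell at row {df.index[bad[0]]!r}, "
            f"column {df.columns[bad[1]]!r}"
        )
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        raise ValueError(f"{path}: non-numeric cells")
    if np.any(arr != np.floor(arr)) or np.any(arr < 0):
        bad = np.argwhere((arr != np.floor(arr)) | (arr < 0))[0]
        raise ValueError(
            f"{path}: negative or non-integer count at row {df.index[bad[0]]!r}, "
            f"column {df.columns[bad[1]]!r}"
        )
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate feature id {dup!r}")
    return CountsMatrix(df.astype(np.int64))


def write_counts_table(path: str | Path, counts: CountsMatrix) -> None:
    counts.to_frame().to_csv(path, sep="\t", index_label="feature")


def size_factors_median_of_ratios(counts: CountsMatrix | np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    factor_j = median over features positive in all samples of
    counts[i, j] / geometric_mean_i.
    """
    x = counts.values if isinstance(counts, CountsMatrix) else np.asarray(counts)
    x = x.astype(float)
    all_positive = np.all(x > 0, axis=1)
    if not np.any(all_positive):
        raise ValueError(
            "no feature has positive counts in every sample; "
            "add a pseudocount or filter samples"
        )
    ref = x[all_positive]
    log_geomean = np.mean(np.log(ref), axis=1)
    ratios = np.log(ref) - log_geomean[:, None]
    factors = np.exp(np.median(ratios, axis=0))
    factors /= np.exp(np.mean(np.log(factors)))
    return factors


def _per_feature_dispersion(
    norm: np.ndarray, groups: np.ndarray | None = None
) -> np.ndarray:
    """Per-feature moment NB dispersion a_i solving E[v] = mu + a*mu^2.

    The denominator uses a small-sample bias correction
    (E[mu_hat^2] = mu^2 + Var(mu_hat)). With group labels, means and
    variances are computed within groups so a genuine group effect does
    not inflate the estimate. Entries can be negative (sub-Poisson
    noise); callers floor or moderate them.
    """
    if groups is None:
        mu = norm.mean(axis=1)
        var = norm.var(axis=1, ddof=1)
        var_of_mean = var / norm.shape[1]
    else:
        mus, vars_, inv_n = [], [], []
        for g in np.unique(groups):
            sub = norm[:, groups == g]
            if sub.shape[1] >= 2:
                mus.append(sub.mean(axis=1))
                vars_.append(sub.var(axis=1, ddof=1))
                inv_n.append(1.0 / sub.shape[1])
        n_groups = len(mus)
        mu = np.mean(np.stack(mus), axis=0)
        var = np.mean(np.stack(vars_), axis=0)
        # Var of the average of group means
        var_of_mean = var * np.mean(inv_n) / n_groups
    denom = np.maximum(mu**2 - var_of_mean, mu**2 * 0.1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = np.where(mu >= 1.0, (var - mu) / denom, np.nan)
    return alpha


def _huber_location(values: np.ndarray, k: float = 1.345, max_iter: int = 50) -> float:
    """Huber M-estimate of location with MAD scale (robust mean)."""
    med = float(np.median(values))
    mad = float(np.median(np.abs(values - med))) * 1.4826
    if mad == 0:
        return med
    mu = med
    for _ in range(max_iter):
        r = np.clip(values - mu, -k * mad, k * mad)
        mu_new = mu + float(r.mean())
        if abs(mu_new - mu) < 1e-10:
            break
        mu = mu_new
    return mu


def _moment_dispersion(norm: np.ndarray, groups: np.ndarray | None = None) -> float:
    """Robust common NB dispersion: Huber location of the per-feature
    moment estimates, so a minority of highly variable features (e.g.
    strong latent biology) cannot drag the shared estimate. Floored at 1e-8.
    """
    alpha = _per_feature_dispersion(norm, groups)
    alpha = alpha[np.isfinite(alpha)]
    if alpha.size == 0:
        return 1e-8
    return float(max(_huber_location(alpha), 1e-8))


def vst_normalize(
    counts: CountsMatrix | np.ndarray,
    size_factors: np.ndarray | None = None,
    method: str = "asinh_nb",
) -> NormalizedMatrix:
    """Variance-stabilizing transform of size-factor-scaled counts.

    ``log2p1``: y = log2(x/s + 1). ``asinh_nb``: y = (2/sqrt(a)) *
    asinh(sqrt(a * x/s)) with a common moment-based dispersion ``a``; this
    is the classical NB stabilizer whose variance is approximately
    constant for means above ~1/a. Both are monotone in x for fixed s and
    map 0 to 0.
    """
    if isinstance(counts, CountsMatrix):
        x = counts.values.astype(float)
        feature_ids, sample_ids = counts.feature_ids, counts.sample_ids
    else:
        x = np.asarray(counts, dtype=float)
        feature_ids = [f"feature_{i}" for i in range(x.shape[0])]
        sample_ids = [f"sample_{j}" for j in range(x.shape[1])]
    if size_factors is None:
        size_factors = np.ones(x.shape[1])
    size_factors = np.asarray(size_factors, dtype=float)
    if np.any(size_factors <= 0):
        raise ValueError("size factors must be positive")
    scaled = x / size_factors[None, :]
    if method == "log2p1":
        y = np.log2(scaled + 1.0)
    elif method == "asinh_nb":
        alpha = _moment_dispersion(scaled)
        y = (2.0 / np.sqrt(alpha)) * np.arcsinh(np.sqrt(alpha * scaled))
    else:
        raise ValueError(f"unknown VST method {method!r}")
    return NormalizedMatrix(y, list(feature_ids), list(sample_ids), size_factors, method)


def pca_embed(
    normalized: NormalizedMatrix | np.ndarray, n_components: int = 2
) -> tuple[np.ndarray, np.ndarray]:
    """Centered-SVD sample embedding.

    Returns (scores, variance_fractions): scores has one row per sample;
    variance fractions are eigenvalue shares of the total variance. Sign
    convention: within each component the largest-magnitude loading is
    made positive.
    """
    values = normalized.values if isinstance(normalized, NormalizedMatrix) else np.asarray(normalized)
    data = values.T  # samples x features
    n_samples = data.shape[0]
    if n_samples < 2:
        raise ValueError("PCA needs at least two samples")
    if n_components > n_samples:
        raise ValueError(
            f"n_components={n_components} exceeds number of samples ({n_samples})"
        )
    centered = data - data.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    # deterministic orientation: largest-|loading| positive per component
    for k in range(vt.shape[0]):
        j = int(np.argmax(np.abs(vt[k])))
        if vt[k, j] < 0:
            vt[k] *= -1.0
            u[:, k] *= -1.0
    scores = u[:, :n_components] * s[:n_components]
    total_var = float(np.sum(s**2))
    frac = (s[:n_components] ** 2) / total_var if total_var > 0 else np.zeros(n_components)
    return scores, frac


def nb_wald_test(
    counts: CountsMatrix,
    groups: Sequence[str] | None = None,
    size_factors: np.ndarray | None = None,
    lfc_pseudocount: float = 0.5,
) -> list[DifferentialRecord]:
    """Negative-binomial moment/Wald test of group B vs group A.

    Per feature, on size-factor-normalized counts: group means muA, muB;
    lfc = log2((muB + c)/(muA + c)); a moment dispersion alpha_i =
    max(per-feature estimate, robust common estimate), both computed
    within groups and floored at 1e-8; delta-method standard error of the
    lfc from Var(mu_g_hat) = (mu_g + alpha_i * mu_g^2)/n_g; two-sided
    normal p on z = lfc/se. The per-feature floor protects features whose
    biological variance far exceeds the shared dispersion from being
    called on noise; the robust common floor stabilizes the tiny-n
    per-feature estimates. BH-adjusted p and up/down calls are added by
    :func:`bh_adjust` / :func:`call_differential`.
    """
    if groups is None:
        groups = [counts.group_labels[s] for s in counts.sample_ids]
    groups = np.asarray(list(groups))
    labels = sorted(set(groups))
    if len(labels) != 2:
        raise ValueError(f"need exactly 2 groups, got {labels}")
    mask_a, mask_b = groups == labels[0], groups == labels[1]
    if mask_a.sum() < 2 or mask_b.sum() < 2:
        raise ValueError("need >= 2 samples per group")
    x = counts.values.astype(float)
    if np.any(x.sum(axis=0)[mask_a] == 0) or np.any(x.sum(axis=0)[mask_b] == 0):
        raise ValueError("a sample has an all-zero library")
    if size_factors is None:
        size_factors = size_factors_median_of_ratios(counts)
    norm = x / np.asarray(size_factors)[None, :]

    c = lfc_pseudocount
    n_a, n_b = int(mask_a.sum()), int(mask_b.sum())
    mu_a = norm[:, mask_a].mean(axis=1)
    mu_b = norm[:, mask_b].mean(axis=1)
    per_feature = _per_feature_dispersion(norm, groups)
    finite = per_feature[np.isfinite(per_feature)]
    common = float(max(_huber_location(finite), 1e-8)) if finite.size else 1e-8
    alpha = np.maximum(np.nan_to_num(per_feature, nan=common), common)
    lfc = np.log2((mu_b + c) / (mu_a + c))
    var_a = (mu_a + alpha * mu_a**2) / n_a
    var_b = (mu_b + alpha * mu_b**2) / n_b
    ln2 = np.log(2.0)
    se = np.sqrt(var_a / (mu_a + c) ** 2 + var_b / (mu_b + c) ** 2) / ln2
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, lfc / np.where(se > 0, se, 1.0), 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.clip(p, 0.0, 1.0)
    base_mean = norm.mean(axis=1)
    records = [
        DifferentialRecord(
            feature_id=fid,
            base_mean=float(base_mean[i]),
            lfc=float(lfc[i]),
            se=float(se[i]),
            p_raw=float(p[i]),
        )
        for i, fid in enumerate(counts.feature_ids)
    ]
    padj = bh_adjust([r.p_raw for r in records])
    for r, q in zip(records, padj):
        r.p_adj = float(q)
    return records


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    q_(i) = min_{j >= i} p_(j) * m / j over the ascending order statistics,
    capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be 1-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    out = np.empty(m)
    out[order] = q_sorted
    return out


def call_differential(
    records: Sequence[DifferentialRecord], config: AnalysisConfig | None = None
) -> dict[str, list[str]]:
    """Threshold calls: up iff p_adj < alpha_de and lfc >= lfc_min;
    down symmetric with lfc <= -lfc_min. Mutates each record's ``call``."""
    config = config or AnalysisConfig()
    up: list[str] = []
    down: list[str] = []
    for r in records:
        if r.p_adj < config.alpha_de and r.lfc >= config.lfc_min:
            r.call = "up"
            up.append(r.feature_id)
        elif r.p_adj < config.alpha_de and r.lfc <= -config.lfc_min:
            r.call = "down"
            down.append(r.feature_id)
        else:
            r.call = "ns"
    return {"up": up, "down": down}


def differential_frame(records: Sequence[DifferentialRecord]) -> pd.DataFrame:
    """Tidy table of differential results (feature, baseMean, lfc, p, padj, call)."""
    return pd.DataFrame(
        {
            "feature": [r.feature_id for r in records],
            "baseMean": [r.base_mean for r in records],
            "lfc": [r.lfc for r in records],
            "p": [r.p_raw for r in records],
            "padj": [r.p_adj for r in records],
            "call": [r.call for r in records],
        }
    )
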