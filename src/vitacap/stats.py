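"""Ecology and group-comparison statistics for regional and dietary contrasts.

Covers the analysis layer applied to the abundance profiles: alpha
diversity (richness, Shannon), Bray–Curtis dissimilarity, principal
coordinates analysis (classical scaling), permutation AMOVA in the
mothur/Excoffier squared-distance form, Wilcoxon rank-sum tests,
Benjamini–Hochberg adjustment, a LEfSe-style linear-discriminant effect
size, and per-entity differential enrichment summaries.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import mannwhitneyu
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from statsmodels.stats.multitest import multipletests

from .profiling import ProfileTable

__all__ = [
    "Ordination",
    "AmovaResult",
    "RankTestResult",
    "LdaResult",
    "EnrichmentTable",
    "richness",
    "shannon",
    "bray_curtis",
    "pcoa",
    "amova",
    "rank_sum_test",
    "bh_adjust",
    "lda_effect_size",
    "differential_enrichment",
]


def _as_frame(profile: ProfileTable | pd.DataFrame) -> pd.DataFrame:
    return profile.data if isinstance(profile, ProfileTable) else profile


# ---------------------------------------------------------------------------
# alpha diversity
# ---------------------------------------------------------------------------

def richness(abundances: Sequence[float]) -> int:
    """Number of entities with strictly positive abundance."""
    a = np.asarray(abundances, dtype=float)
    if (a < 0).any():
        raise ValueError("negative abundances")
    return int((a > 0).sum())


def shannon(abundances: Sequence[float]) -> float:
    """Shannon index −Σ p ln p over positive proportions (natural log).

    An all-zero vector returns 0 by convention.
    """
    a = np.asarray(abundances, dtype=float)
    if (a < 0).any():
        raise ValueError("negative abundances")
    total = a.sum()
    if total == 0:
        return 0.0
    p = a[a > 0] / total
    return float(-(p * np.log(p)).sum())


# ---------------------------------------------------------------------------
# beta diversity & ordination
# ---------------------------------------------------------------------------

def bray_curtis(profile: ProfileTable | pd.DataFrame) -> pd.DataFrame:
    """Bray–Curtis dissimilarity between samples (profile columns).

    d(i,j) = Σ|x_i − x_j| / Σ(x_i + x_j), in [0, 1].  A pair of all-zero
    samples has distance 0 by convention (identical emptiness).
    """
    data = _as_frame(profile)
    if data.shape[1] < 2:
        raise ValueError("bray_curtis: need at least 2 samples")
    x = data.to_numpy(dtype=float).T
    with np.errstate(invalid="ignore", divide="ignore"):
        d = pdist(x, metric="braycurtis")
    d = np.nan_to_num(d, nan=0.0)  # all-zero pairs yield 0/0
    return pd.DataFrame(squareform(d), index=data.columns, columns=data.columns)


@dataclass(frozen=True)
class Ordination:
    """Principal-coordinates embedding.

    Axes are ordered by non-increasing eigenvalue; only non-negative
    eigenvalues are kept, and the summed magnitude of any discarded
    negative eigenvalues is reported.
    """

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray
    negative_eigenvalue_magnitude: float


def pcoa(distance: pd.DataFrame, k: int = 2) -> Ordination:
    """Classical scaling (PCoA) of a distance matrix.

    Double-centers −D²/2, eigendecomposes, and scales eigenvectors by the
    square root of their eigenvalues.  Negative eigenvalues (non-Euclidean
    distances) are dropped without correction; if fewer than ``k`` positive
    axes exist, fewer axes are returned with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    d = np.asarray(distance, dtype=float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T):
        raise ValueError("distance matrix must be square and symmetric")
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    eigvals, eigvecs = np.linalg.eigh(b)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]

    tol = max(abs(eigvals).max(), 1.0) * 1e-12
    positive = eigvals > tol
    neg_magnitude = float(-eigvals[eigvals < -tol].sum())
    n_pos = int(positive.sum())
    if n_pos == 0:  # degenerate: all points coincide
        coords = np.zeros((n, k))
        kept = np.zeros(k)
    else:
        if k > n_pos:
            warnings.warn(
                f"requested {k} axes but only {n_pos} positive eigenvalues; "
                f"returning {n_pos}",
                stacklevel=2,
            )
            k = n_pos
        kept = eigvals[positive][:k]
        coords = eigvecs[:, positive][:, :k] * np.sqrt(kept)
    total_positive = eigvals[positive].sum() if n_pos else 1.0
    ids = list(distance.index) if isinstance(distance, pd.DataFrame) else list(range(n))
    return Ordination(
        coordinates=pd.DataFrame(
            coords, index=ids, columns=[f"PC{i + 1}" for i in range(coords.shape[1])]
        ),
        eigenvalues=np.asarray(kept, dtype=float),
        proportion_explained=np.asarray(kept, dtype=float) / total_positive,
        negative_eigenvalue_magnitude=neg_magnitude,
    )


# ---------------------------------------------------------------------------
# AMOVA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AmovaResult:
    fs: float
    ss_among: float
    ss_within: float
    df_among: int
    df_within: int
    p_value: float
    n_permutations: int
    seed: Optional[int]


def _amova_ss(d2: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    n = d2.shape[0]
    ss_total = d2.sum() / (2 * n)
    ss_within = 0.0
    for g in np.unique(labels):
        idx = np.flatnonzero(labels == g)
        ss_within += d2[np.ix_(idx, idx)].sum() / (2 * len(idx))
    return ss_total - ss_within, ss_within


def amova(
    distance: pd.DataFrame,
    groups: Mapping[str, str] | pd.Series,
    n_permutations: int = 1000,
    seed: Optional[int] = None,
    exhaustive: bool = False,
) -> AmovaResult:
    """Permutation analysis of molecular variance (Excoffier/mothur form).

    Squared distances are partitioned into among- and within-group sums of
    squares; Fs = (SS_among/(k−1)) / (SS_within/(N−k)).  Significance comes
    from permuting group labels: by default ``n_permutations`` random
    relabelings with the add-one estimator p = (1 + #{Fs* ≥ Fs}) /
    (1 + n_permutations); with ``exhaustive=True`` (two groups only) every
    distinct labeling is enumerated and p = #{Fs* ≥ Fs} / #labelings,
    which includes the observed labeling itself.
    """
    groups = pd.Series(dict(groups) if not isinstance(groups, pd.Series) else groups)
    ids = list(distance.index)
    if set(ids) != set(groups.index):
        raise ValueError("group labels do not match distance matrix sample ids")
    labels = groups.loc[ids].to_numpy()
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("amova: need at least 2 groups")
    if (counts < 2).any():
        small = uniq[counts < 2]
        raise ValueError(f"amova: group(s) {list(small)} have fewer than 2 samples")

    d2 = np.asarray(distance, dtype=float) ** 2
    n, k = len(ids), len(uniq)
    ss_among, ss_within = _amova_ss(d2, labels)
    df_among, df_within = k - 1, n - k
    with np.errstate(divide="ignore", invalid="ignore"):
        fs = (ss_among / df_among) / (ss_within / df_within)
    fs = float(np.inf if ss_within == 0 and ss_among > 0 else fs)

    if exhaustive:
        if k != 2:
            raise ValueError("exhaustive enumeration implemented for 2 groups only")
        n_a = counts[0]
        hits = total = 0
        base = np.array([uniq[1]] * n, dtype=object)
        for pos in itertools.combinations(range(n), int(n_a)):
            perm = base.copy()
            perm[list(pos)] = uniq[0]
            ss_a, ss_w = _amova_ss(d2, perm)
            fs_perm = np.inf if ss_w == 0 and ss_a > 0 else (ss_a / df_among) / (ss_w / df_within)
            total += 1
            if fs_perm >= fs - 1e-12:
                hits += 1
        p = hits / total
        return AmovaResult(fs, ss_among, ss_within, df_among, df_within, p, total, seed)

    rng = np.random.default_rng(seed)
    # vectorized permutation: indicator per group, SS via quadratic forms
    perms = np.array([rng.permutation(labels) for _ in range(n_permutations)])
    ss_total = d2.sum() / (2 * n)
    ss_within_perm = np.zeros(n_permutations)
    for g, n_g in zip(uniq, counts):
        z = (perms == g).astype(float)
        ss_within_perm += np.einsum("bi,ij,bj->b", z, d2, z) / (2 * n_g)
    ss_among_perm = ss_total - ss_within_perm
    with np.errstate(divide="ignore", invalid="ignore"):
        fs_perm = (ss_among_perm / df_among) / (ss_within_perm / df_within)
    fs_perm = np.where((ss_within_perm == 0) & (ss_among_perm > 0), np.inf, fs_perm)
    p = float((1 + (fs_perm >= fs - 1e-12).sum()) / (1 + n_permutations))
    return AmovaResult(fs, ss_among, ss_within, df_among, df_within, p, n_permutations, seed)


# ---------------------------------------------------------------------------
# rank-sum test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RankTestResult:
    statistic: float  # Wilcoxon rank-sum W (rank sum of x, midranks)
    p_value: float
    method: str  # "exact" | "normal-approximation"
    tie_corrected: bool


def rank_sum_test(x: Sequence[float], y: Sequence[float]) -> RankTestResult:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) test.

    Exact null enumeration when n+m ≤ 12 and the pooled sample is tie-free;
    otherwise the normal approximation with midranks, tie correction, and
    continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("rank_sum_test: empty sample")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < pooled.size
    exact = (x.size + y.size <= 12) and not has_ties
    res = mannwhitneyu(
        x, y, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    w = float(res.statistic + x.size * (x.size + 1) / 2)  # U1 -> rank-sum W
    return RankTestResult(
        statistic=w,
        p_value=float(min(res.pvalue, 1.0)),
        method="exact" if exact else "normal-approximation",
        tie_corrected=(not exact) and has_ties,
    )


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values outside [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# LEfSe-style LDA effect size
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LdaResult:
    feature: str
    score: float  # signed, log10 scale; positive = enriched in first group
    screen_p: float
    significant: bool
    direction: str


def lda_effect_size(
    features: ProfileTable | pd.DataFrame,
    groups: Mapping[str, str] | pd.Series,
    threshold: float = 3.0,
    alpha: float = 0.05,
    n_bootstrap: int = 30,
    seed: Optional[int] = None,
) -> list[LdaResult]:
    """LEfSe-style effect sizes for a two-group contrast.

    Features (rows) are first screened per-feature by the rank-sum test;
    samples are scaled so each sums to 10^6 (the [1, 10^6] abundance axis).
    Over ``n_bootstrap`` rounds, a 2/3 subsample of each group is drawn and
    a one-dimensional linear discriminant is fit; each feature's effect is
    the average of its raw between-class mean difference and its weighted
    contribution along the discriminant.  The reported score is
    sign · log10(1 + mean bootstrap effect); a feature is significant iff
    |score| > ``threshold`` and its screen p < ``alpha``.  Constant features
    get score 0 and are never significant.
    """
    data = _as_frame(features)
    groups = pd.Series(dict(groups) if not isinstance(groups, pd.Series) else groups)
    groups = groups.loc[data.columns]
    labels = sorted(groups.unique())
    if len(labels) != 2:
        raise ValueError("lda_effect_size: exactly 2 groups required")
    idx_a = np.flatnonzero((groups == labels[0]).to_numpy())
    idx_b = np.flatnonzero((groups == labels[1]).to_numpy())
    if len(idx_a) < 3 or len(idx_b) < 3:
        raise ValueError("lda_effect_size: each group needs at least 3 samples")

    raw = data.to_numpy(dtype=float)
    colsum = raw.sum(axis=0)
    scaled = np.where(colsum > 0, raw / np.where(colsum > 0, colsum, 1.0) * 1e6, 0.0)
    x = scaled.T  # samples × features
    y = (groups == labels[0]).to_numpy().astype(int)

    rng = np.random.default_rng(seed)
    n_feat = data.shape[0]
    effects = np.zeros(n_feat)
    rounds = 0
    for _ in range(n_bootstrap):
        sub_a = rng.choice(idx_a, size=max(3, int(np.ceil(len(idx_a) * 2 / 3))), replace=False)
        sub_b = rng.choice(idx_b, size=max(3, int(np.ceil(len(idx_b) * 2 / 3))), replace=False)
        sub = np.concatenate([sub_a, sub_b])
        xs, ys = x[sub], y[sub]
        keep = xs.std(axis=0) > 0  # drop constant features for this fit
        if keep.sum() == 0:
            continue
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                lda = LinearDiscriminantAnalysis(solver="svd", n_components=1)
                lda.fit(xs[:, keep], ys)
                proj = lda.transform(xs[:, keep])[:, 0]
                w = lda.scalings_[:, 0]
        except np.linalg.LinAlgError:
            continue
        norm = np.linalg.norm(w)
        if norm == 0 or not np.isfinite(norm):
            continue
        w_unit = w / norm
        ld_gap = abs(proj[ys == 1].mean() - proj[ys == 0].mean()) / max(norm, 1e-300)
        feat_gap = np.abs(xs[ys == 1].mean(axis=0) - xs[ys == 0].mean(axis=0))
        contrib = np.zeros(n_feat)
        contrib[keep] = (np.abs(w_unit) * ld_gap + feat_gap[keep]) / 2.0
        effects += contrib
        rounds += 1
    if rounds:
        effects /= rounds

    results: list[LdaResult] = []
    mean_a = scaled[:, idx_a].mean(axis=1)
    mean_b = scaled[:, idx_b].mean(axis=1)
    for i, feat in enumerate(data.index):
        row = raw[i]
        constant = np.all(row == row[0])
        if constant:
            results.append(LdaResult(str(feat), 0.0, 1.0, False, "none"))
            continue
        screen = rank_sum_test(raw[i, idx_a], raw[i, idx_b]).p_value
        sign = 1.0 if mean_a[i] >= mean_b[i] else -1.0
        score = sign * np.log10(1.0 + effects[i])
        significant = abs(score) > threshold and screen < alpha
        direction = labels[0] if sign > 0 else labels[1]
        results.append(LdaResult(str(feat), float(score), screen, bool(significant), direction))
    return results


# ---------------------------------------------------------------------------
# differential enrichment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EnrichmentTable:
    """Per-entity two-group comparison with direction calls.

    ``table`` columns: medians and means per group, rank-sum p, adjusted p,
    direction (group with the larger median, or "none" on ties), and the
    significance flag at ``alpha``.  ``summary`` counts significant entities
    per direction.
    """

    table: pd.DataFrame
    alpha: float
    summary: dict[str, int] = field(default_factory=dict)


def differential_enrichment(
    abundance: ProfileTable | pd.DataFrame,
    groups: Mapping[str, str] | pd.Series,
    alpha: float = 0.05,
) -> EnrichmentTable:
    """Rank-sum differential abundance of every entity between two groups."""
    data = _as_frame(abundance)
    groups = pd.Series(dict(groups) if not isinstance(groups, pd.Series) else groups)
    groups = groups.loc[data.columns]
    labels = sorted(groups.unique())
    if len(labels) != 2:
        raise ValueError("differential_enrichment: exactly 2 groups required")
    a_cols = groups.index[groups == labels[0]]
    b_cols = groups.index[groups == labels[1]]
    if len(a_cols) < 2 or len(b_cols) < 2:
        raise ValueError("differential_enrichment: each group needs at least 2 samples")

    rows = []
    for entity, series in data.iterrows():
        xa = series[a_cols].to_numpy(dtype=float)
        xb = series[b_cols].to_numpy(dtype=float)
        res = rank_sum_test(xa, xb)
        med_a, med_b = float(np.median(xa)), float(np.median(xb))
        if med_a > med_b:
            direction = labels[0]
        elif med_b > med_a:
            direction = labels[1]
        else:
            direction = "none"
        rows.append(
            {
                "entity": entity,
                f"median_{labels[0]}": med_a,
                f"median_{labels[1]}": med_b,
                f"mean_{labels[0]}": float(xa.mean()),
                f"mean_{labels[1]}": float(xb.mean()),
                "p_value": res.p_value,
                "direction": direction,
            }
        )
    table = pd.DataFrame(rows).set_index("entity")
    table["p_adjusted"] = bh_adjust(table["p_value"].to_numpy())
    table["significant"] = (table["p_value"] < alpha) & (table["direction"] != "none")
    summary = {
        lab: int(((table["direction"] == lab) & table["significant"]).sum())
        for lab in labels
    }
    return EnrichmentTable(table=table, alpha=alpha, summary=summary)
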